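"""Synthetic qPCR cycle-threshold tables and densitometry records.

The Cq generator encodes a known fold change per group under the 100%
amplification-efficiency assumption: target Cq = cq_ref − log2(fold) +
noise, reference-gene Cq = cq_ref + noise, each biological sample measured
as technical duplicates (or any replicate count).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["make_cq_table", "make_densitometry_table"]


def make_cq_table(true_fold_changes: dict[str, float], cq_ref: float = 22.0,
                  noise_sd: float = 0.0, duplicates: int = 2,
                  n_samples: int = 3, seed: int = 0) -> pd.DataFrame:
    """Emit a long-format Cq table with known ground-truth fold changes.

    Columns: sample, group, gene ("target" / "reference"), replicate, cq.
    The first group key in ``true_fold_changes`` is the natural choice of
    reference group downstream; a fold of 1 there yields 2^−ΔΔCq = 1.
    """
    if any(f <= 0 for f in true_fold_changes.values()):
        raise ValueError("fold changes must be positive")
    if duplicates < 1 or n_samples < 1:
        raise ValueError("duplicates and n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for group, fold in true_fold_changes.items():
        for s in range(n_samples):
            sample = f"{group}_s{s}"
            for gene, base in (("target", cq_ref - np.log2(fold)),
                               ("reference", cq_ref)):
                for rep in range(duplicates):
                    cq = base + (rng.normal(0.0, noise_sd) if noise_sd > 0
                                 else 0.0)
                    rows.append((sample, group, gene, rep, cq))
    return pd.DataFrame(rows, columns=["sample", "group", "gene",
                                       "replicate", "cq"])


def make_densitometry_table(true_ratios: dict[str, float],
                            actin_od: float = 1.0, background: float = 0.1,
                            noise_sd: float = 0.0, replicates: int = 3,
                            n_samples: int = 3, seed: int = 0) -> pd.DataFrame:
    """Emit gel-band optical densities with known background-corrected,
    actin-normalized target ratios per group.

    Columns: sample, group, lane, replicate, target_od, target_background,
    actin_od, actin_background.
    """
    if any(r <= 0 for r in true_ratios.values()):
        raise ValueError("ratios must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    lane = 0
    for group, ratio in true_ratios.items():
        for s in range(n_samples):
            sample = f"{group}_s{s}"
            for rep in range(replicates):
                eps = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                target_net = ratio * (actin_od - background) * (1.0 + eps)
                rows.append((sample, group, lane, rep,
                             target_net + background, background,
                             actin_od, background))
                lane += 1
    return pd.DataFrame(rows, columns=["sample", "group", "lane", "replicate",
                                       "target_od", "target_background",
                                       "actin_od", "actin_background"])
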