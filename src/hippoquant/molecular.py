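"""Molecular and imaging quantifications.

Relative expression by the 2^−ΔΔCq method (technical replicates averaged on
the Cq scale, ΔCq = target − reference gene per sample, ΔΔCq anchored to
the mean ΔCq of a named reference group); Western-blot densitometry ratios
(background-corrected target over background-corrected β-actin, technical
replicates averaged per sample); and the blinded threshold-based
VGLUT1/MAP2 fluorescence ratio (total above-threshold VGLUT1 intensity over
above-threshold MAP2 pixel area).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UndefinedRatioError

__all__ = ["ChannelThresholds", "ddcq", "densitometry_ratio",
           "vglut_map2_ratio", "otsu_threshold"]


@dataclass
class ChannelThresholds:
    """Fluorescence intensity thresholds per channel.

    ``chosen_blinded`` records whether a user blinded to the condition set
    them (the provenance the analysis expects) or they came from the
    automatic fallback.
    """

    vglut1_threshold: float
    map2_threshold: float
    chosen_blinded: bool = True

    def __post_init__(self) -> None:
        if self.vglut1_threshold < 0 or self.map2_threshold < 0:
            raise ValueError("thresholds must be non-negative")


def ddcq(table: pd.DataFrame, reference_group: str,
         target_gene: str = "target", reference_gene: str = "reference"
         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Relative expression 2^−ΔΔCq per sample and per group.

    ``table`` columns: sample, group, gene, cq (replicate rows allowed).
    Technical replicates are averaged on the Cq scale before any
    exponentiation.  ΔCq = mean Cq(target) − mean Cq(reference gene) per
    sample; ΔΔCq subtracts the mean ΔCq of ``reference_group``; fold =
    2^−ΔΔCq.  The reference group's folds have geometric mean 1.

    Returns ``(per_sample, per_group)`` frames; per_group carries mean, sem
    and n of the fold changes.
    """
    required = {"sample", "group", "gene", "cq"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    mean_cq = (table.groupby(["sample", "group", "gene"], sort=False)["cq"]
               .mean().reset_index())
    wide = mean_cq.pivot_table(index=["sample", "group"], columns="gene",
                               values="cq", aggfunc="mean").reset_index()
    if target_gene not in wide.columns or wide[target_gene].isna().any():
        raise ValueError("target gene missing for one or more samples")
    if reference_gene not in wide.columns or wide[reference_gene].isna().any():
        raise ValueError("reference gene missing for one or more samples")
    wide["dcq"] = wide[target_gene] - wide[reference_gene]
    ref = wide.loc[wide["group"] == reference_group, "dcq"]
    if ref.empty:
        raise ValueError(f"reference group {reference_group!r} is empty")
    wide["ddcq"] = wide["dcq"] - ref.mean()
    wide["fold"] = 2.0 ** (-wide["ddcq"])
    per_sample = wide[["sample", "group", "dcq", "ddcq", "fold"]]
    g = per_sample.groupby("group", sort=False)["fold"]
    per_group = pd.DataFrame({
        "mean": g.mean(),
        "sem": g.apply(lambda x: x.std(ddof=1) / np.sqrt(len(x))
                       if len(x) > 1 else np.nan),
        "n": g.size(),
    }).reset_index()
    return per_sample, per_group


def densitometry_ratio(records: pd.DataFrame
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Background-corrected, β-actin-normalized optical-density ratios.

    ``records`` columns: sample, lane, target_od, target_background,
    actin_od, actin_background (plus optional group/replicate).  Per-lane
    ratio = (target − target background) / (actin − actin background);
    technical replicates average per sample before any group statistics.

    The documented contract: the ratio is invariant to multiplying all four
    ODs of a lane by a positive constant (backgrounds scale with their
    bands).  Raises :class:`UndefinedRatioError` when a lane's net actin
    OD is non-positive.
    """
    required = {"sample", "lane", "target_od", "target_background",
                "actin_od", "actin_background"}
    if not required.issubset(records.columns):
        raise ValueError(f"records must have columns {sorted(required)}")
    df = records.copy()
    if ((df["target_background"] > df["target_od"])
            | (df["actin_background"] > df["actin_od"])).any():
        raise ValueError("background exceeds raw OD in at least one lane")
    actin_net = df["actin_od"] - df["actin_background"]
    if (actin_net <= 0).any():
        raise UndefinedRatioError("non-positive net actin OD in a lane")
    df["ratio"] = (df["target_od"] - df["target_background"]) / actin_net
    cols = ["sample", "lane", "ratio"] + (
        ["group"] if "group" in df.columns else [])
    per_lane = df[cols]
    keys = ["sample"] + (["group"] if "group" in df.columns else [])
    per_sample = per_lane.groupby(keys, sort=False)["ratio"].mean().reset_index()
    return per_lane, per_sample


def otsu_threshold(channel: np.ndarray, nbins: int = 256) -> float:
    """Automatic intensity threshold (between-class variance maximization).

    Fallback for tests and unattended runs; the analysis is designed around
    operator-chosen, condition-blinded thresholds.
    """
    x = np.asarray(channel, dtype=float).ravel()
    hist, edges = np.histogram(x, bins=nbins)
    mids = 0.5 * (edges[:-1] + edges[1:])
    w = hist.astype(float)
    p = w / w.sum()
    omega = np.cumsum(p)
    mu = np.cumsum(p * mids)
    mu_t = mu[-1]
    denom = omega * (1.0 - omega)
    denom[denom == 0] = np.nan
    sigma_b = (mu_t * omega - mu) ** 2 / denom
    return float(mids[np.nanargmax(sigma_b)])


def vglut_map2_ratio(vglut: np.ndarray, map2: np.ndarray,
                     thresholds: ChannelThresholds,
                     restrict_to_map2: bool = False
                     ) -> tuple[float, dict]:
    """Total above-threshold VGLUT1 intensity per above-threshold MAP2 pixel.

    ratio = Σ VGLUT1[VGLUT1 > threshold] / #{MAP2 > threshold}.  With
    ``restrict_to_map2`` the VGLUT1 sum additionally requires the pixel to
    lie on the MAP2-positive area (puncta on identified neurites).
    Diagnostics report both mask pixel counts and the thresholds used.
    Raises :class:`UndefinedRatioError` when no MAP2 pixel is above
    threshold.
    """
    vglut = np.asarray(vglut, dtype=float)
    map2 = np.asarray(map2, dtype=float)
    if vglut.shape != map2.shape:
        raise ValueError("channels must share shape")
    vmask = vglut > thresholds.vglut1_threshold
    mmask = map2 > thresholds.map2_threshold
    if restrict_to_map2:
        vmask &= mmask
    area = int(mmask.sum())
    if area == 0:
        raise UndefinedRatioError("no above-threshold MAP2 pixels")
    total = float(vglut[vmask].sum())
    diagnostics = {
        "vglut_pixels": int(vmask.sum()),
        "map2_pixels": area,
        "vglut_sum": total,
        "vglut1_threshold": thresholds.vglut1_threshold,
        "map2_threshold": thresholds.map2_threshold,
        "chosen_blinded": thresholds.chosen_blinded,
        "restrict_to_map2": restrict_to_map2,
    }
    return total / area, diagnostics
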