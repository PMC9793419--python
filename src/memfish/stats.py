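"""Embryo-level statistics: Welch tests, localization calls, condition
summaries and reporter fluorescence (RFU) quantification.

Localization is called per embryo from the pooled enrichment profile: the
outermost bin's volume-normalized frequency is compared against a threshold
(default 1.5, midway between the random baseline of 1 and the weakest
membrane-enrichment classes seen in practice).  Group comparisons use the
Welch two-sample t-test (unequal variances, Welch-Satterthwaite degrees of
freedom), with significance stars following the smFISH literature's legend
convention; no multiple-testing correction is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats as sps
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects

from .enrich import EnrichmentProfile

logger = logging.getLogger(__name__)

__all__ = [
    "ConditionComparison",
    "EmbryoRecord",
    "MaskingError",
    "classify_localization",
    "condition_summary",
    "nuclear_rfu",
    "significance_stars",
    "welch_test",
]

# Star conventions used in the figure legends this pipeline feeds.
_STAR_LEVELS = ((5e-5, "****"), (5e-4, "***"), (5e-3, "**"), (5e-2, "*"))


class MaskingError(ValueError):
    """No nuclear voxels found when building the DAPI mask."""


def significance_stars(p: float) -> str:
    for cut, stars in _STAR_LEVELS:
        if p < cut:
            return stars
    return "ns"


@dataclass(frozen=True)
class ConditionComparison:
    """Welch two-sample t-test between two groups of per-embryo values."""

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    t: float
    df: float
    p: float
    stars: str


def welch_test(a: Sequence[float], b: Sequence[float],
               label_a: str = "a", label_b: str = "b") -> ConditionComparison:
    """Welch two-sample t-test (two-sided).

    t = (mean_a - mean_b) / sqrt(s2_a/n_a + s2_b/n_b) with the
    Welch-Satterthwaite degrees of freedom.  Groups must have n >= 2 and at
    least one group nonzero variance.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("welch_test requires at least 2 values per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 or vb == 0:
        raise ValueError("welch_test requires nonzero variance in each group")
    na, nb = len(a), len(b)
    se2a, se2b = va / na, vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2a + se2b)
    df = (se2a + se2b) ** 2 / (
        se2a**2 / (na - 1) + se2b**2 / (nb - 1)
    )
    p = 2.0 * sps.t.sf(abs(t), df)
    return ConditionComparison(
        label_a, label_b, na, nb, float(a.mean()), float(b.mean()),
        float(t), float(df), float(p), significance_stars(p),
    )


def classify_localization(
    profile: EnrichmentProfile,
    threshold: float = 1.5,
    min_spots: int = 50,
) -> str:
    """Call an embryo 'localized' iff its bin-1 (outermost 10%) normalized
    frequency is >= ``threshold``; profiles with fewer than ``min_spots``
    molecules are 'indeterminate' (flagged, not an error)."""
    if profile.total_count < min_spots:
        return "indeterminate"
    return "localized" if profile.normalized_frequency[0] >= threshold else "unlocalized"


@dataclass(frozen=True)
class EmbryoRecord:
    """Per-embryo quantification summary feeding the condition tables."""

    embryo_id: str
    stage: int
    condition: str
    profile: EnrichmentProfile          # pooled profile
    total_molecules: int
    cluster_count: int
    localization: str                   # localized | unlocalized | indeterminate
    reporter_rfu: float | None = None

    def __post_init__(self):
        if self.localization not in ("localized", "unlocalized", "indeterminate"):
            raise ValueError(f"bad localization call {self.localization!r}")

    @property
    def bin1_frequency(self) -> float:
        return float(self.profile.normalized_frequency[0])


def condition_summary(records: Iterable[EmbryoRecord]) -> pd.DataFrame:
    """Per (stage, condition) group: n, localized/unlocalized fractions
    (indeterminate embryos excluded from the fractions)."""
    records = list(records)
    if not records:
        raise ValueError("no records to summarize")
    rows = []
    df = pd.DataFrame(
        {
            "stage": [r.stage for r in records],
            "condition": [r.condition for r in records],
            "call": [r.localization for r in records],
        }
    )
    for (stage, cond), g in df.groupby(["stage", "condition"]):
        n = len(g)
        n_loc = int((g.call == "localized").sum())
        n_unloc = int((g.call == "unlocalized").sum())
        n_ind = int((g.call == "indeterminate").sum())
        n_eff = n_loc + n_unloc
        rows.append(
            {
                "stage": stage,
                "condition": cond,
                "n": n,
                "n_effective": n_eff,
                "n_indeterminate": n_ind,
                "frac_localized": n_loc / n_eff if n_eff else np.nan,
                "frac_unlocalized": n_unloc / n_eff if n_eff else np.nan,
            }
        )
        if n_eff == 0:
            logger.warning("group (stage=%s, condition=%s): all embryos indeterminate", stage, cond)
    return pd.DataFrame(rows)


def nuclear_rfu(
    reporter: np.ndarray,
    dapi: np.ndarray,
    embryo_mask: np.ndarray,
    min_object_voxels: int = 27,
) -> float:
    """Background-subtracted nuclear reporter intensity (RFU).

    The nuclear mask is an Otsu threshold of the DAPI channel inside the
    embryo mask, cleaned of objects smaller than ``min_object_voxels``.
    RFU = mean reporter inside nuclei minus mean reporter in the background
    region (outside the embryo, after eroding the complement by 2 voxels to
    avoid edge bleed).
    """
    reporter = np.asarray(reporter, dtype=float)
    dapi = np.asarray(dapi, dtype=float)
    embryo = np.asarray(embryo_mask) > 0
    if not (reporter.shape == dapi.shape == embryo.shape):
        raise ValueError("reporter, dapi and embryo_mask must share a shape")
    inside = dapi[embryo]
    if inside.size == 0:
        raise MaskingError("embryo mask is empty")
    try:
        thr = threshold_otsu(inside)
    except ValueError as exc:  # e.g. constant DAPI: nothing to segment
        raise MaskingError(f"cannot threshold DAPI: {exc}") from exc
    nuclear = (dapi > thr) & embryo
    nuclear = remove_small_objects(nuclear, max_size=min_object_voxels - 1)
    if not nuclear.any():
        raise MaskingError("no nuclear voxels found after thresholding DAPI")
    background = ndi.binary_erosion(~embryo, iterations=2)
    if not background.any():
        background = ~embryo
    if not background.any():
        raise MaskingError("no background voxels outside the embryo mask")
    return float(reporter[nuclear].mean() - reporter[background].mean())
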