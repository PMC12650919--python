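"""Voxelwise agreement metrics and paired pre/post cohort statistics.

Validation of a segmentation against manual raters uses Cohen's kappa
(chance-corrected voxel-label agreement), the union of the manual
annotations as a consensus reference, and the Dice similarity
coefficient against that consensus.  Cohort-level reporting of paired
pre/post volumes uses the per-sample relative change, its mean and
sample standard deviation, and a Student-t confidence interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .image_io import MaskStack
from .volumetry import percent_round, relative_change

__all__ = [
    "AgreementReport",
    "CohortSummary",
    "cohens_kappa",
    "dice",
    "consensus_union",
    "cohort_summary",
]


@dataclass
class AgreementReport:
    """Voxelwise agreement between two binary raters on a common grid.

    ``kappa`` is ``None`` when chance agreement ``pe`` equals 1 (both
    raters constant and identical), where the coefficient is undefined.
    ``dice`` is ``None`` when both masks are empty.
    """

    p0: float
    pe: float
    kappa: float | None
    dice: float | None
    n_voxels: int

    def as_dict(self) -> dict:
        return {"p0": self.p0, "pe": self.pe, "kappa": self.kappa,
                "dice": self.dice, "n_voxels": self.n_voxels}


def _paired(mask_a: MaskStack, mask_b: MaskStack) -> tuple[np.ndarray, np.ndarray]:
    if mask_a.shape != mask_b.shape:
        raise ValueError(f"mask shapes differ: {mask_a.shape} vs {mask_b.shape}")
    return mask_a.data, mask_b.data


def cohens_kappa(mask_a: MaskStack, mask_b: MaskStack) -> AgreementReport:
    """Chance-corrected voxel-label agreement over the full bounding grid.

    ``p0`` is the fraction of voxels where the raters agree (background
    concordance counts); ``pe`` comes from the raters' marginal label
    frequencies; kappa is ``(p0 − pe) / (1 − pe)``.
    """
    a, b = _paired(mask_a, mask_b)
    n = a.size
    n11 = int((a & b).sum())
    n00 = int((~a & ~b).sum())
    p0 = (n11 + n00) / n
    pa, pb = a.sum() / n, b.sum() / n
    pe = pa * pb + (1 - pa) * (1 - pb)
    kappa = None if math.isclose(pe, 1.0) else (p0 - pe) / (1.0 - pe)
    return AgreementReport(p0=p0, pe=pe, kappa=kappa,
                           dice=dice(mask_a, mask_b), n_voxels=n)


def dice(mask_a: MaskStack, mask_b: MaskStack) -> float | None:
    """Dice similarity coefficient ``2|A∩B| / (|A| + |B|)``; None if both empty."""
    a, b = _paired(mask_a, mask_b)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return None
    return 2.0 * int((a & b).sum()) / denom


def consensus_union(mask_a: MaskStack, mask_b: MaskStack) -> MaskStack:
    """Voxelwise OR of two annotations, used as the consensus reference."""
    a, b = _paired(mask_a, mask_b)
    return MaskStack(a | b, mask_a.voxel_spacing)


@dataclass
class CohortSummary:
    """Paired pre/post volume statistics for a cohort of samples.

    Relative changes are dimensionless fractions; the confidence
    interval is ``mean ± t_crit · sd / sqrt(n)`` with the two-sided
    Student-t quantile at ``df = n − 1``.
    """

    rel_changes: list[float]
    mean_rel: float
    sd_rel: float
    ci95: tuple[float, float]
    t_crit: float
    n: int
    mean_pre: float
    sd_pre: float
    mean_post: float
    sd_post: float

    @property
    def df(self) -> int:
        return self.n - 1

    def as_dict(self) -> dict:
        return {
            "n": self.n, "df": self.df,
            "rel_changes_pct": [percent_round(r) for r in self.rel_changes],
            "mean_rel_pct": percent_round(self.mean_rel),
            "sd_rel_pp": percent_round(self.sd_rel),
            "ci95_pct": [percent_round(c) for c in self.ci95],
            "t_crit": self.t_crit,
            "mean_pre": self.mean_pre, "sd_pre": self.sd_pre,
            "mean_post": self.mean_post, "sd_post": self.sd_post,
        }


def cohort_summary(v_pre: Sequence[float], v_post: Sequence[float],
                   alpha: float = 0.05) -> CohortSummary:
    """Summarise paired pre/post volumes.

    Per-sample relative change ``(pre − post)/pre``; mean and sample SD
    (``n − 1`` denominator); two-sided ``1 − alpha`` Student-t interval.
    Requires at least two pairs and strictly positive pre volumes.
    """
    pre = np.asarray(v_pre, dtype=float)
    post = np.asarray(v_post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post volume lists must have equal length")
    n = pre.size
    if n < 2:
        raise ValueError("confidence interval undefined for fewer than two pairs")
    if (pre <= 0).any():
        raise ValueError("all preoperative volumes must be positive")
    rel = np.array([relative_change(a, b).delta_rel for a, b in zip(pre, post)])
    mean = float(rel.mean())
    sd = float(rel.std(ddof=1))
    t_crit = float(stats.t.ppf(1.0 - alpha / 2.0, df=n - 1))
    half = t_crit * sd / math.sqrt(n)
    return CohortSummary(
        rel_changes=[float(r) for r in rel],
        mean_rel=mean, sd_rel=sd,
        ci95=(mean - half, mean + half),
        t_crit=t_crit, n=n,
        mean_pre=float(pre.mean()), sd_pre=float(pre.std(ddof=1)),
        mean_post=float(post.mean()), sd_post=float(post.std(ddof=1)),
    )
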