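"""Dosage-compensation statistics from male/female expression.

The question: after Y degeneration leaves males with a single X, is
X-linked expression equalized between the sexes?  With no compensation the
male:female expression ratio on the X (``M/F_X``) should be about half the
autosomal ratio (``M/F_A``); full chromosome-wide compensation restores
``(M/F_X)/(M/F_A)`` to ~1.  Empirically, uncompensated systems sit around
0.5–0.8 because of general expression buffering, so values above 0.8 are
read as evidence of chromosome-wide compensation.

Only genes expressed in both sexes (FPKM > 1 in each) enter any statistic;
``M/F_X`` and ``M/F_A`` are medians of per-gene ratios, computed as
``2**median(log2 M/F)`` (means are available as an option).  Location
differences between X and autosomes — within each sex and for the log2
ratio — are tested with two-sided Wilcoxon rank-sum tests, Bonferroni
corrected over all contrasts run together.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .io_tables import GeneExpression
from .sexlink import AUTOSOME, X

__all__ = [
    "DosageStats",
    "ContrastResult",
    "filter_expressed",
    "log2_mf_expression",
    "dosage_statistic",
    "xa_location_test",
    "bonferroni",
]

#: Genes need FPKM strictly above this in both sexes to count as expressed.
FPKM_THRESHOLD = 1.0


@dataclass(frozen=True)
class DosageStats:
    """Median male/female expression ratios on X and autosomes.

    ``dc_ratio = mf_x / mf_a`` is the compensation statistic: ~1 under full
    dosage compensation, ~0.5 under none.
    """

    mf_x: float
    mf_a: float
    dc_ratio: float
    n_x: int
    n_a: int

    def __post_init__(self) -> None:
        if self.n_x < 1 or self.n_a < 1:
            raise ValueError("both chromosome classes need at least one gene")
        if not math.isclose(self.dc_ratio, self.mf_x / self.mf_a, rel_tol=1e-12):
            raise ValueError("dc_ratio must equal mf_x / mf_a")


@dataclass(frozen=True)
class ContrastResult:
    """One X-vs-autosome location test with raw and adjusted p-values."""

    contrast_name: str
    statistic: float
    p_raw: float
    p_adjusted: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_raw <= 1.0 and 0.0 <= self.p_adjusted <= 1.0):
            raise ValueError("p-values must lie in [0, 1]")
        if self.p_adjusted < self.p_raw - 1e-15:
            raise ValueError("adjusted p-value cannot be below the raw p-value")


def filter_expressed(
    genes: Iterable[GeneExpression], threshold: float = FPKM_THRESHOLD
) -> list[GeneExpression]:
    """Keep genes expressed in both sexes: male AND female FPKM strictly > threshold."""
    return [g for g in genes if g.male_fpkm > threshold and g.female_fpkm > threshold]


def log2_mf_expression(gene: GeneExpression) -> float:
    """log2(male/female FPKM) of one expressed gene.

    Callers must filter first (:func:`filter_expressed`): a zero FPKM has
    no finite log ratio and violates this function's contract.
    """
    if gene.male_fpkm <= 0 or gene.female_fpkm <= 0:
        raise ValueError(
            f"gene {gene.gene_id!r} has non-positive FPKM; run filter_expressed first"
        )
    return math.log2(gene.male_fpkm / gene.female_fpkm)


def dosage_statistic(
    genes: Sequence[GeneExpression],
    linkage: Mapping[str, str],
    aggregate: str = "median",
) -> DosageStats:
    """Compute ``M/F_X``, ``M/F_A`` and their ratio over classified genes.

    ``linkage`` maps gene ids to X/autosome; genes missing from it or
    excluded are ignored.  ``aggregate`` picks the per-class summary of the
    log2 ratios: ``"median"`` (default; what boxplot-style displays show)
    or ``"mean"``.
    """
    if aggregate not in ("median", "mean"):
        raise ValueError(f"aggregate must be 'median' or 'mean', got {aggregate!r}")
    agg = np.median if aggregate == "median" else np.mean
    log_ratios = {X: [], AUTOSOME: []}
    for g in genes:
        cls = linkage.get(g.gene_id)
        if cls in log_ratios:
            log_ratios[cls].append(log2_mf_expression(g))
    for cls, values in log_ratios.items():
        if not values:
            raise ValueError(f"no {cls} genes available for the dosage statistic")
    mf_x = float(2.0 ** agg(log_ratios[X]))
    mf_a = float(2.0 ** agg(log_ratios[AUTOSOME]))
    return DosageStats(
        mf_x=mf_x,
        mf_a=mf_a,
        dc_ratio=mf_x / mf_a,
        n_x=len(log_ratios[X]),
        n_a=len(log_ratios[AUTOSOME]),
    )


#: Largest per-group size at which the exact rank-sum null is enumerated.
EXACT_MAX_N = 20


def xa_location_test(
    values_x: Sequence[float],
    values_a: Sequence[float],
    contrast_name: str = "",
    method: str = "auto",
) -> ContrastResult:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test of X vs autosomal values.

    ``method``: ``"exact"`` enumerates the null distribution (valid without
    ties), ``"asymptotic"`` uses the tie-corrected normal approximation with
    continuity correction, ``"auto"`` picks exact when both groups have
    <= 20 values and no ties are present, asymptotic otherwise.

    The returned ``p_adjusted`` equals ``p_raw``; apply :func:`bonferroni`
    to a batch of contrasts for the familywise correction.
    """
    x = np.asarray(values_x, dtype=float)
    a = np.asarray(values_a, dtype=float)
    if x.size == 0 or a.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([x, a])
    if np.ptp(combined) == 0:
        warnings.warn(
            f"all values identical in contrast {contrast_name!r}; p set to 1", stacklevel=2
        )
        u = x.size * a.size / 2.0
        return ContrastResult(contrast_name, float(u), 1.0, 1.0)
    if method == "auto":
        has_ties = np.unique(combined).size < combined.size
        method = (
            "exact" if (x.size <= EXACT_MAX_N and a.size <= EXACT_MAX_N and not has_ties)
            else "asymptotic"
        )
    res = stats.mannwhitneyu(x, a, alternative="two-sided", method=method)
    p = float(min(1.0, res.pvalue))
    return ContrastResult(contrast_name, float(res.statistic), p, p)


def bonferroni(results: Sequence[ContrastResult], m: int | None = None) -> list[ContrastResult]:
    """Bonferroni-adjust a batch of contrasts: ``p_adj = min(1, p_raw * m)``.

    ``m`` defaults to the number of contrasts in the batch and may be larger
    (when the family includes tests run elsewhere); order is preserved.
    """
    if m is None:
        m = len(results)
    if m < len(results):
        raise ValueError(f"m={m} is smaller than the number of results ({len(results)})")
    return [replace(r, p_adjusted=min(1.0, r.p_raw * m)) for r in results]
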