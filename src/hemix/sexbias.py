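"""Sex-biased gene classification and X-vs-autosome proportion tests.

A gene is male-biased when its male/female expression difference is
significant (DE p-value < 0.05) with higher male FPKM, female-biased with
higher female FPKM, and unbiased otherwise (p >= 0.05 or no p-value).  The
DE p-values are consumed as produced upstream — this package deliberately
provides no differential-expression test of its own, so that synthetic or
externally computed p-values pass through unchanged.

Whether the X carries an excess or deficit of biased genes relative to the
autosomes is tested with a 2x2 chi-square with Yates' continuity
correction, the standard small-sample-safe contingency test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .io_tables import GeneExpression
from .sexlink import AUTOSOME, X

__all__ = [
    "MALE",
    "FEMALE",
    "UNBIASED",
    "BiasCall",
    "ProportionTest",
    "DegenerateTableError",
    "classify_bias",
    "yates_chi2_2x2",
    "bias_proportion_test",
]

logger = logging.getLogger(__name__)

MALE = "male"
FEMALE = "female"
UNBIASED = "unbiased"

#: Significance level below which a DE p-value marks a gene as sex-biased.
ALPHA = 0.05


@dataclass(frozen=True)
class BiasCall:
    gene_id: str
    bias: str

    def __post_init__(self) -> None:
        if self.bias not in (MALE, FEMALE, UNBIASED):
            raise ValueError(f"invalid bias class {self.bias!r}")


@dataclass(frozen=True)
class ProportionTest:
    """Yates chi-square comparison of biased-gene proportions on X vs autosomes."""

    k_x: int   # biased genes on the X
    n_x: int   # classified genes on the X
    k_a: int
    n_a: int
    chi2: float
    p: float
    direction: str  # excess_on_X | deficit_on_X | none

    def __post_init__(self) -> None:
        if not (0 <= self.k_x <= self.n_x and 0 <= self.k_a <= self.n_a):
            raise ValueError("biased counts cannot exceed class totals")
        if self.direction not in ("excess_on_X", "deficit_on_X", "none"):
            raise ValueError(f"invalid direction {self.direction!r}")


class DegenerateTableError(ValueError):
    """A zero row or column margin leaves the chi-square test undefined."""


def classify_bias(genes: Iterable[GeneExpression], alpha: float = ALPHA) -> list[BiasCall]:
    """Call each gene male-biased, female-biased or unbiased.

    Strictly ``de_pvalue < alpha`` with unequal FPKM gives a biased call in
    the direction of the larger FPKM; a missing p-value, ``p >= alpha`` or
    exactly equal FPKM (directionless; essentially impossible outside
    synthetic data, logged when it happens) gives unbiased.  Callers should
    pass the expression-filtered gene set.
    """
    calls = []
    for g in genes:
        if g.de_pvalue is None or g.de_pvalue >= alpha:
            calls.append(BiasCall(g.gene_id, UNBIASED))
        elif g.male_fpkm > g.female_fpkm:
            calls.append(BiasCall(g.gene_id, MALE))
        elif g.male_fpkm < g.female_fpkm:
            calls.append(BiasCall(g.gene_id, FEMALE))
        else:
            logger.info("gene %s significant but with equal FPKM; called unbiased", g.gene_id)
            calls.append(BiasCall(g.gene_id, UNBIASED))
    return calls


def yates_chi2_2x2(table) -> tuple[float, float]:
    """Chi-square statistic and p-value of a 2x2 table with Yates' correction.

    ``chi2 = sum(max(|O - E| - 0.5, 0)^2 / E)`` with expectations from the
    margins; the correction is truncated at zero, so perfectly proportional
    tables score exactly 0 (p = 1).  p comes from the chi-square
    distribution with 1 degree of freedom.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {obs.shape}")
    if np.any(obs < 0) or not np.all(np.isfinite(obs)):
        raise ValueError("counts must be finite and >= 0")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise DegenerateTableError("a zero margin leaves the chi-square test undefined")
    expected = np.outer(rows, cols) / obs.sum()
    adj = np.maximum(np.abs(obs - expected) - 0.5, 0.0)
    chi2 = float(np.sum(adj**2 / expected))
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p


def bias_proportion_test(
    calls: Sequence[BiasCall],
    linkage: Mapping[str, str],
    which: str,
) -> ProportionTest:
    """Test whether the X's share of ``which``-biased genes differs from the
    autosomes' share.

    Builds the 2x2 table (biased-of-kind vs not) x (X vs autosome) over
    genes with known linkage, runs :func:`yates_chi2_2x2`, and reports the
    direction of the raw proportion difference.
    """
    if which not in (MALE, FEMALE):
        raise ValueError(f"which must be {MALE!r} or {FEMALE!r}, got {which!r}")
    k = {X: 0, AUTOSOME: 0}
    n = {X: 0, AUTOSOME: 0}
    for call in calls:
        cls = linkage.get(call.gene_id)
        if cls in n:
            n[cls] += 1
            if call.bias == which:
                k[cls] += 1
    for cls in (X, AUTOSOME):
        if n[cls] == 0:
            raise ValueError(f"no genes with {cls} linkage among the bias calls")
    table = [[k[X], n[X] - k[X]], [k[AUTOSOME], n[AUTOSOME] - k[AUTOSOME]]]
    chi2, p = yates_chi2_2x2(table)
    prop_x = k[X] / n[X]
    prop_a = k[AUTOSOME] / n[AUTOSOME]
    if math.isclose(prop_x, prop_a, rel_tol=0, abs_tol=1e-15):
        direction = "none"
    elif prop_x > prop_a:
        direction = "excess_on_X"
    else:
        direction = "deficit_on_X"
    return ProportionTest(
        k_x=k[X], n_x=n[X], k_a=k[AUTOSOME], n_a=n[AUTOSOME],
        chi2=chi2, p=p, direction=direction,
    )
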