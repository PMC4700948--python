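"""1:1 orthology from alignment hit tables and shared-X conservation tests.

Orthology is inferred the standard way for draft annotations: hits are
score-filtered, collapsed to the best hit per query, and gene pairs kept
only when the two genes are each other's unique best hit (reciprocal best
hits, RBH).  Pairs between two non-reference species can be extrapolated
through a well-annotated reference: two genes are orthologs when both are
RBH partners of the same reference gene.

Whether the X chromosome is the *same* chromosomal element in two species
is tested from the linkage classes of orthologous pairs: under independent
linkage the expected number of pairs X-linked in both species is
``n * (x1/n) * (x2/n)``; an observed/expected ratio above 1 indicates
shared (conserved) X gene content, a deficit suggests sex-chromosome
turnover.  Significance comes from a Yates chi-square on the 2x2 table of
pair linkage classes and, because the continuity correction is
conservative, also from a Monte Carlo permutation test that shuffles one
species' linkage labels across pairs (preserving both species' X fractions
and the pair count).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_tables import HitRecord
from .sexlink import AUTOSOME, X
from .sexbias import yates_chi2_2x2

__all__ = [
    "OrthologyMap",
    "SharedXResult",
    "MonteCarloResult",
    "filter_hits_by_score",
    "best_hits",
    "reciprocal_best_hits",
    "extrapolate_via_reference",
    "shared_x_test",
    "monte_carlo_shared_x",
]

#: Alignment hits below this score are discarded before RBH inference.
MIN_SCORE = 50.0


def filter_hits_by_score(
    hits: Iterable[HitRecord], min_score: float = MIN_SCORE, strict: bool = False
) -> list[HitRecord]:
    """Keep hits with score >= min_score (or > with ``strict=True``)."""
    if strict:
        return [h for h in hits if h.score > min_score]
    return [h for h in hits if h.score >= min_score]


def best_hits(hits: Iterable[HitRecord], tie_break: str | None = None) -> dict[str, str]:
    """Map each query to its single best target, or to nothing on a tie.

    Repeated hits to one target collapse to the max-scoring one first.
    Two distinct targets tying at the top score leave the query without a
    best hit (conservative default); ``tie_break="evalue"`` resolves such
    ties by the lower e-value when it is unique.
    """
    if tie_break not in (None, "evalue"):
        raise ValueError(f"tie_break must be None or 'evalue', got {tie_break!r}")
    per_query: dict[str, dict[str, HitRecord]] = {}
    for h in hits:
        targets = per_query.setdefault(h.query_id, {})
        prev = targets.get(h.target_id)
        if prev is None or h.score > prev.score:
            targets[h.target_id] = h
    best: dict[str, str] = {}
    for query, targets in per_query.items():
        top_score = max(h.score for h in targets.values())
        top = [h for h in targets.values() if h.score == top_score]
        if len(top) > 1 and tie_break == "evalue":
            with_e = [h for h in top if h.evalue is not None]
            if with_e:
                low = min(h.evalue for h in with_e)
                top = [h for h in with_e if h.evalue == low]
        if len(top) == 1:
            best[query] = top[0].target_id
    return best


def reciprocal_best_hits(
    hits_ab: Iterable[HitRecord],
    hits_ba: Iterable[HitRecord],
    min_score: float = MIN_SCORE,
    tie_break: str | None = None,
) -> list[tuple[str, str]]:
    """1:1 gene pairs (a, b) where b is a's unique best hit and vice versa.

    Both directional hit tables are score-filtered first.  The output is
    sorted and strictly 1:1 by construction.
    """
    fwd = best_hits(filter_hits_by_score(hits_ab, min_score), tie_break)
    rev = best_hits(filter_hits_by_score(hits_ba, min_score), tie_break)
    return sorted((a, b) for a, b in fwd.items() if rev.get(b) == a)


@dataclass(frozen=True)
class OrthologyMap:
    """1:1 orthologous gene pairs between two species with per-gene linkage.

    ``linkage_1`` / ``linkage_2`` map gene ids of each species to X or
    autosome; genes absent from the maps (or carrying any other label,
    e.g. excluded) are dropped by :meth:`restrict_known` before testing.
    """

    species_pair: tuple[str, str]
    pairs: Sequence[tuple[str, str]]
    linkage_1: Mapping[str, str]
    linkage_2: Mapping[str, str]

    def __post_init__(self) -> None:
        left = [a for a, _ in self.pairs]
        right = [b for _, b in self.pairs]
        if len(set(left)) != len(left) or len(set(right)) != len(right):
            raise ValueError("orthology must be 1:1: a gene appears in more than one pair")

    def restrict_known(self) -> "OrthologyMap":
        """Drop pairs lacking an X/autosome call in either species."""
        keep = [
            (a, b)
            for a, b in self.pairs
            if self.linkage_1.get(a) in (X, AUTOSOME)
            and self.linkage_2.get(b) in (X, AUTOSOME)
        ]
        return OrthologyMap(self.species_pair, keep, self.linkage_1, self.linkage_2)


def extrapolate_via_reference(
    map_ref_s1: OrthologyMap, map_ref_s2: OrthologyMap
) -> OrthologyMap:
    """Join two reference-anchored maps into a species-1/species-2 map.

    Both inputs must have the same reference species in first position;
    genes of S1 and S2 are paired iff they are RBH partners of the same
    reference gene.  The result is 1:1 because each input is.
    """
    ref1, s1 = map_ref_s1.species_pair
    ref2, s2 = map_ref_s2.species_pair
    if ref1 != ref2:
        raise ValueError(
            f"maps anchor different references: {ref1!r} vs {ref2!r}"
        )
    partner_1 = {r: g for r, g in map_ref_s1.pairs}
    partner_2 = {r: g for r, g in map_ref_s2.pairs}
    pairs = sorted(
        (partner_1[r], partner_2[r]) for r in partner_1.keys() & partner_2.keys()
    )
    return OrthologyMap(
        species_pair=(s1, s2),
        pairs=pairs,
        linkage_1=map_ref_s1.linkage_2,
        linkage_2=map_ref_s2.linkage_2,
    )


@dataclass(frozen=True)
class MonteCarloResult:
    """Permutation-test summary for the shared-X count of one species pair."""

    observed: int
    reps: int
    p_greater: float   # (1 + #{sim >= obs}) / (reps + 1)
    p_less: float
    p_two_sided: float


@dataclass(frozen=True)
class SharedXResult:
    """Observed vs expected doubly-X-linked ortholog pairs for one species pair.

    ``ratio`` > 1: excess shared X content (conservation); < 1: deficit
    (suggesting turnover).  ``chi2_p`` is the Yates chi-square p on the
    2x2 linkage table; ``mc_p`` the two-sided permutation p (None when the
    permutation test was not run).
    """

    species_pair: tuple[str, str]
    n: int
    x1: int
    x2: int
    obs_xx: int
    exp_xx: float
    ratio: float
    chi2: float
    chi2_p: float
    mc_p: float | None = None
    mc_reps: int = 0

    def __post_init__(self) -> None:
        if self.obs_xx > self.n:
            raise ValueError("observed shared-X count cannot exceed the pair count")


def _linkage_vectors(omap: OrthologyMap) -> tuple[np.ndarray, np.ndarray]:
    omap = omap.restrict_known()
    v1 = np.array([omap.linkage_1[a] == X for a, _ in omap.pairs], dtype=bool)
    v2 = np.array([omap.linkage_2[b] == X for _, b in omap.pairs], dtype=bool)
    return v1, v2


def shared_x_test(
    omap: OrthologyMap, mc_reps: int = 0, seed: int | None = None
) -> SharedXResult:
    """Test a species pair for excess/deficit of shared X-linked orthologs.

    Restricts the map to pairs with known linkage in both species, forms
    the 2x2 table [[XX, XA], [AX, AA]], and compares ``obs_xx`` with the
    independence expectation ``x1 * x2 / n``.  With ``mc_reps > 0`` also
    runs :func:`monte_carlo_shared_x` (``seed`` then required).
    """
    v1, v2 = _linkage_vectors(omap)
    n = int(v1.size)
    if n < 1:
        raise ValueError(f"no ortholog pairs with known linkage for {omap.species_pair}")
    x1 = int(v1.sum())
    x2 = int(v2.sum())
    if x1 in (0, n) or x2 in (0, n):
        raise ValueError(
            f"degenerate linkage margin for {omap.species_pair}: "
            f"x1={x1}, x2={x2} of n={n}; the contingency test is undefined"
        )
    obs_xx = int(np.sum(v1 & v2))
    exp_xx = x1 * x2 / n
    table = [
        [obs_xx, x1 - obs_xx],
        [x2 - obs_xx, n - x1 - x2 + obs_xx],
    ]
    chi2, chi2_p = yates_chi2_2x2(table)
    mc_p: float | None = None
    if mc_reps > 0:
        if seed is None:
            raise ValueError("seed is required for the Monte Carlo test")
        mc_p = monte_carlo_shared_x(omap, reps=mc_reps, seed=seed).p_two_sided
    return SharedXResult(
        species_pair=omap.species_pair,
        n=n, x1=x1, x2=x2, obs_xx=obs_xx, exp_xx=exp_xx,
        ratio=obs_xx / exp_xx, chi2=chi2, chi2_p=chi2_p,
        mc_p=mc_p, mc_reps=mc_reps if mc_p is not None else 0,
    )


#: Permutation batch cap (elements) keeping peak memory modest.
_MC_CHUNK_ELEMS = 20_000_000


def monte_carlo_shared_x(
    omap: OrthologyMap, reps: int = 10_000, seed: int | None = None
) -> MonteCarloResult:
    """Permutation test of the shared-X count.

    Each replicate shuffles species 2's linkage labels across the n pairs
    (preserving both X fractions and n) and recounts doubly-X pairs; under
    this null the count is hypergeometric.  Empirical tail probabilities
    use the add-one correction ``(b + 1) / (reps + 1)`` so no p is ever 0,
    and the two-sided p doubles the smaller tail, capped at 1.
    """
    if reps < 100:
        raise ValueError(f"reps must be >= 100, got {reps}")
    if seed is None:
        raise ValueError("a seed is required for reproducibility")
    v1, v2 = _linkage_vectors(omap)
    n = v1.size
    if n < 1:
        raise ValueError("no ortholog pairs with known linkage")
    obs = int(np.sum(v1 & v2))
    rng = np.random.default_rng(seed)
    n_ge = 0
    n_le = 0
    chunk = max(1, min(reps, _MC_CHUNK_ELEMS // max(1, n)))
    done = 0
    while done < reps:
        k = min(chunk, reps - done)
        perm = rng.permuted(np.tile(v2, (k, 1)), axis=1)
        sims = perm[:, v1].sum(axis=1)
        n_ge += int(np.sum(sims >= obs))
        n_le += int(np.sum(sims <= obs))
        done += k
    p_greater = (n_ge + 1) / (reps + 1)
    p_less = (n_le + 1) / (reps + 1)
    return MonteCarloResult(
        observed=obs,
        reps=reps,
        p_greater=p_greater,
        p_less=p_less,
        p_two_sided=min(1.0, 2.0 * min(p_greater, p_less)),
    )
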