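"""Coverage- and marker-based assignment of scaffolds to the X or autosomes.

In a male-heterogametic system the X is present once in males and twice in
females, so X-derived scaffolds show roughly half the male genomic read
depth of autosomal scaffolds while female depth is unaffected.  The
log2(male/female coverage) distribution is therefore bimodal: an autosomal
mode (which also absorbs any global difference in male vs female library
size) and an X mode one log2 unit below it.

The classifier is deliberately simple, mirroring the field's standard
procedure: take the highest-frequency histogram bin as the autosomal
centre ``a_median``, and call every scaffold whose log2 ratio falls strictly
below ``a_median - 0.5`` X-linked.  Scaffolds with zero coverage in either
sex carry no ratio and are excluded.  A stringent variant additionally
excludes an intermediate-coverage band around the threshold, where
misclassification is most likely.

For species with published X-linked and autosomal microsatellite markers,
scaffolds can instead be assigned by mapping the marker primers: a marker's
scaffold is the one hit by both the forward and the reverse primer with the
lowest combined e-value, and the scaffold inherits the marker's class.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_tables import CoverageRecord, MarkerHit

__all__ = [
    "X",
    "AUTOSOME",
    "EXCLUDED",
    "LinkageModel",
    "LinkageCall",
    "MarkerAssignment",
    "InsufficientDataError",
    "log2_coverage_ratio",
    "estimate_autosomal_mode",
    "classify_scaffolds",
    "stringent_classify",
    "assign_by_markers",
    "gene_linkage",
]

X = "X"
AUTOSOME = "autosome"
EXCLUDED = "excluded"

#: Distance (log2 units) of the X threshold below the autosomal mode: the X
#: sits at a 2-fold male-coverage reduction, so the cut is placed halfway.
THRESHOLD_OFFSET = 0.5


class InsufficientDataError(ValueError):
    """Too few informative scaffolds to locate the autosomal mode."""


@dataclass(frozen=True)
class LinkageModel:
    """Fitted autosomal mode and the derived X classification threshold."""

    a_median: float
    bin_width: float = 0.05
    threshold: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.bin_width > 0:
            raise ValueError(f"bin_width must be > 0, got {self.bin_width}")
        if not math.isfinite(self.a_median):
            raise ValueError("a_median must be finite")
        object.__setattr__(self, "threshold", self.a_median - THRESHOLD_OFFSET)


@dataclass(frozen=True)
class LinkageCall:
    """One scaffold's log2(M/F) coverage ratio and its linkage class."""

    scaffold_id: str
    log2_mf_coverage: float  # NaN when excluded
    linkage: str

    def __post_init__(self) -> None:
        if self.linkage not in (X, AUTOSOME, EXCLUDED):
            raise ValueError(f"invalid linkage {self.linkage!r}")


def log2_coverage_ratio(record: CoverageRecord) -> float | None:
    """log2(male/female) coverage of one scaffold, or ``None`` when either
    sex has zero coverage (such scaffolds are excluded from all analyses)."""
    if record.male_coverage == 0 or record.female_coverage == 0:
        return None
    # difference of logs: immune to under/overflow of the raw quotient
    return math.log2(record.male_coverage) - math.log2(record.female_coverage)


def estimate_autosomal_mode(
    ratios: Sequence[float],
    bin_width: float = 0.05,
    weights: Sequence[float] | None = None,
) -> LinkageModel:
    """Locate the autosomal mode of a log2(M/F) coverage distribution.

    A histogram with bins of ``bin_width`` is laid over the finite ratios;
    ``a_median`` is the centre of the fullest bin.  ``weights`` (e.g. gene
    counts per scaffold) optionally weight the histogram.  Ties between
    maximal bins are broken toward the bin centre nearest 0, since
    autosomes dominate the genome and an unshifted mode is the expected
    one; a tie triggers a warning.
    """
    if not bin_width > 0:
        raise ValueError(f"bin_width must be > 0, got {bin_width}")
    arr = np.asarray(ratios, dtype=float)
    w = None if weights is None else np.asarray(weights, dtype=float)
    finite = np.isfinite(arr)
    arr = arr[finite]
    if w is not None:
        w = w[finite]
    if arr.size < 2:
        raise InsufficientDataError(
            f"need >= 2 finite log2 ratios to fit the autosomal mode, got {arr.size}"
        )
    # Bin edges on a fixed lattice anchored at 0 so that equal data in a
    # shifted frame land in correspondingly shifted bins.
    lo = math.floor(arr.min() / bin_width) * bin_width
    n_bins = max(1, math.ceil((arr.max() - lo) / bin_width + 1e-9))
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(arr, bins=edges, weights=w)
    centers = edges[:-1] + bin_width / 2
    top = np.flatnonzero(counts == counts.max())
    if top.size > 1:
        warnings.warn(
            f"{top.size} histogram bins tie for the mode; choosing the one nearest 0",
            stacklevel=2,
        )
        top = top[np.lexsort((centers[top], np.abs(centers[top])))][:1]
    return LinkageModel(a_median=float(centers[top[0]]), bin_width=bin_width)


def classify_scaffolds(
    records: Iterable[CoverageRecord], model: LinkageModel
) -> list[LinkageCall]:
    """Call each scaffold X-linked, autosomal or excluded.

    Strictly below ``model.threshold`` is X; at or above it is autosomal
    (the threshold value itself is "not less than" the cut, hence
    autosomal).  Zero coverage in either sex excludes the scaffold.
    """
    calls = []
    for rec in records:
        ratio = log2_coverage_ratio(rec)
        if ratio is None:
            calls.append(LinkageCall(rec.scaffold_id, math.nan, EXCLUDED))
        else:
            linkage = X if ratio < model.threshold else AUTOSOME
            calls.append(LinkageCall(rec.scaffold_id, ratio, linkage))
    return calls


def stringent_classify(
    records: Iterable[CoverageRecord], model: LinkageModel, margin: float
) -> list[LinkageCall]:
    """Classification with an exclusion band of half-width ``margin`` around
    the threshold, removing intermediate-coverage scaffolds most at risk of
    misclassification.

    X iff ratio < threshold - margin; autosome iff ratio > threshold +
    margin; excluded otherwise.  Note that at ``margin=0`` a ratio exactly
    equal to the threshold falls in the (degenerate) band and is excluded,
    whereas :func:`classify_scaffolds` calls it autosomal.
    """
    if margin < 0:
        raise ValueError(f"margin must be >= 0, got {margin}")
    calls = []
    for rec in records:
        ratio = log2_coverage_ratio(rec)
        if ratio is None:
            calls.append(LinkageCall(rec.scaffold_id, math.nan, EXCLUDED))
        elif ratio < model.threshold - margin:
            calls.append(LinkageCall(rec.scaffold_id, ratio, X))
        elif ratio > model.threshold + margin:
            calls.append(LinkageCall(rec.scaffold_id, ratio, AUTOSOME))
        else:
            calls.append(LinkageCall(rec.scaffold_id, ratio, EXCLUDED))
    return calls


# ---------------------------------------------------------------------------
# marker-based assignment
# ---------------------------------------------------------------------------

@dataclass
class MarkerAssignment:
    """Outcome of marker-based scaffold assignment.

    ``assignments`` maps scaffolds to X/autosome; ``conflicts`` lists
    scaffolds hit by markers of both classes (left unassigned);
    ``skipped`` records markers that could not be placed, with reasons.
    """

    assignments: dict[str, str]
    conflicts: dict[str, set[str]]
    skipped: list[tuple[str, str]]


def assign_by_markers(hits: Iterable[MarkerHit]) -> MarkerAssignment:
    """Assign scaffolds to the X or autosomes from mapped marker primers.

    For each marker the candidate scaffolds are those hit by *both* its
    forward and reverse primer; among them the one with the lowest combined
    (forward + reverse, best hit per end) e-value is accepted and inherits
    the marker's class.  Markers hitting with only one primer end, or whose
    best candidates tie exactly, are skipped with a warning.  Scaffolds
    supported by markers of conflicting classes are reported and left
    unassigned.
    """
    by_marker: dict[str, list[MarkerHit]] = {}
    marker_class: dict[str, str] = {}
    for h in hits:
        by_marker.setdefault(h.marker_id, []).append(h)
        previous = marker_class.setdefault(h.marker_id, h.marker_class)
        if previous != h.marker_class:
            raise ValueError(f"marker {h.marker_id!r} carries inconsistent classes")

    votes: dict[str, set[str]] = {}  # scaffold -> marker classes supporting it
    skipped: list[tuple[str, str]] = []
    for marker_id, marker_hits in by_marker.items():
        best: dict[str, dict[str, float]] = {}  # scaffold -> end -> best e-value
        for h in marker_hits:
            ends = best.setdefault(h.scaffold_id, {})
            ends[h.primer_end] = min(ends.get(h.primer_end, math.inf), h.evalue)
        candidates = {
            s: ends["forward"] + ends["reverse"]
            for s, ends in best.items()
            if "forward" in ends and "reverse" in ends
        }
        if not candidates:
            skipped.append((marker_id, "no scaffold hit by both primer ends"))
            warnings.warn(
                f"marker {marker_id!r}: no scaffold hit by both primer ends; skipped",
                stacklevel=2,
            )
            continue
        lowest = min(candidates.values())
        winners = sorted(s for s, e in candidates.items() if e == lowest)
        if len(winners) > 1:
            skipped.append((marker_id, f"ambiguous: {', '.join(winners)} tie at {lowest:g}"))
            warnings.warn(f"marker {marker_id!r}: tied best scaffolds; skipped", stacklevel=2)
            continue
        votes.setdefault(winners[0], set()).add(marker_class[marker_id])

    assignments = {s: next(iter(c)) for s, c in votes.items() if len(c) == 1}
    conflicts = {s: c for s, c in votes.items() if len(c) > 1}
    if conflicts:
        warnings.warn(
            f"{len(conflicts)} scaffold(s) hit by markers of conflicting classes; "
            "left unassigned",
            stacklevel=2,
        )
    return MarkerAssignment(assignments=assignments, conflicts=conflicts, skipped=skipped)


def gene_linkage(
    gene_locations: Mapping[str, str],
    scaffold_linkage: Mapping[str, str] | Iterable[LinkageCall],
) -> dict[str, str]:
    """Propagate scaffold linkage classes to genes via their location map.

    Genes on scaffolds without a call (or with an ``excluded`` call) are
    marked excluded; they take part in no X-vs-autosome contrast.
    """
    if not isinstance(scaffold_linkage, Mapping):
        scaffold_linkage = {c.scaffold_id: c.linkage for c in scaffold_linkage}
    return {
        gene: scaffold_linkage.get(scaffold, EXCLUDED)
        for gene, scaffold in gene_locations.items()
    }
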