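"""Orchestration: per-species analyses and cross-species conservation tests.

``run_species`` composes the per-species stages — linkage calling from
coverage (or markers), expression filtering, dosage statistics,
X-vs-autosome location tests, sex-bias classification and proportion
tests — into one report.  ``run_pairwise`` runs the shared-X conservation
test for every species pair, via direct reciprocal best hits or by
extrapolating through a reference species.  ``run`` ties both together
from a YAML config and writes JSON/TSV reports plus a JSON-lines log with
every filter's input/output counts, so each reported number is
recomputable from the emitted intermediates.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from . import dosage, io_tables, orthology, sexbias, sexlink
from .io_tables import CoverageRecord, GeneExpression, MarkerHit
from .sexlink import AUTOSOME, EXCLUDED, X, LinkageCall, LinkageModel

__all__ = [
    "AnalysisOptions",
    "SpeciesInput",
    "RunConfig",
    "SpeciesReport",
    "PairReport",
    "run_species",
    "run_species_tables",
    "run_pairwise",
    "run",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisOptions:
    """Analysis-wide settings shared by every species.

    ``bonferroni_m`` defaults to the number of location contrasts actually
    executed in the run (3 per species); ``stringent_margin`` switches the
    linkage step to the band-exclusion variant.  ``mc_reps=0`` disables the
    permutation test.
    """

    bin_width: float = 0.05
    stringent_margin: float | None = None
    fpkm_threshold: float = 1.0
    alpha: float = 0.05
    bonferroni_m: int | None = None
    min_score: float = 50.0
    mc_reps: int = 10_000
    seed: int = 0
    ratio_aggregate: str = "median"
    weight_mode_by_genes: bool = False


@dataclass(frozen=True)
class SpeciesInput:
    """Input table paths of one species; a marker path switches linkage
    assignment from coverage to published genetic markers."""

    name: str
    coverage_path: str | None = None
    expression_path: str | None = None
    gtf_path: str | None = None
    marker_path: str | None = None


@dataclass
class RunConfig:
    """One configured study: species inputs, optional reference-anchored hit
    tables for the conservation stage, analysis options, output directory."""

    species: list[SpeciesInput]
    options: AnalysisOptions = field(default_factory=AnalysisOptions)
    outdir: str = "results"
    reference: str | None = None
    #: species name -> (reference->species hits path, species->reference hits path)
    hit_paths: dict[str, tuple[str, str]] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        species = [SpeciesInput(**entry) for entry in raw.get("species", [])]
        if not species:
            raise ValueError(f"{path}: config lists no species")
        options = AnalysisOptions(**raw.get("options", {}))
        hit_paths = {
            name: (entry["ref_to_sp"], entry["sp_to_ref"])
            for name, entry in raw.get("hits", {}).items()
        }
        return cls(
            species=species,
            options=options,
            outdir=raw.get("outdir", "results"),
            reference=raw.get("reference"),
            hit_paths=hit_paths,
        )


@dataclass
class SpeciesReport:
    """Everything computed for one species, plus filter bookkeeping."""

    name: str
    model: LinkageModel | None
    linkage_calls: list[LinkageCall]
    gene_linkage: dict[str, str]
    dosage_stats: dosage.DosageStats | None
    contrasts: list[dosage.ContrastResult]
    bias_calls: list[sexbias.BiasCall]
    proportion_tests: dict[str, sexbias.ProportionTest]
    counts: dict[str, int]
    error: str | None = None


@dataclass
class PairReport:
    species_pair: tuple[str, str]
    result: orthology.SharedXResult | None
    error: str | None = None


def _species_linkage(
    name: str,
    coverage: Sequence[CoverageRecord] | None,
    markers: Sequence[MarkerHit] | None,
    gene_locations: Mapping[str, str],
    options: AnalysisOptions,
):
    """Scaffold linkage calls + fitted model (marker mode fits no model)."""
    if markers is not None:
        assignment = sexlink.assign_by_markers(markers)
        calls = [
            LinkageCall(s, float("nan"), cls) for s, cls in sorted(assignment.assignments.items())
        ]
        return None, calls
    if coverage is None:
        raise ValueError(f"species {name!r} has neither coverage nor marker input")
    ratios, weights = [], []
    genes_per_scaffold: dict[str, int] = {}
    for g, s in gene_locations.items():
        genes_per_scaffold[s] = genes_per_scaffold.get(s, 0) + 1
    for rec in coverage:
        r = sexlink.log2_coverage_ratio(rec)
        if r is not None:
            ratios.append(r)
            weights.append(genes_per_scaffold.get(rec.scaffold_id, 0))
    model = sexlink.estimate_autosomal_mode(
        ratios,
        bin_width=options.bin_width,
        weights=weights if options.weight_mode_by_genes else None,
    )
    if options.stringent_margin is not None:
        calls = sexlink.stringent_classify(coverage, model, options.stringent_margin)
    else:
        calls = sexlink.classify_scaffolds(coverage, model)
    return model, calls


def run_species_tables(
    name: str,
    coverage: Sequence[CoverageRecord] | None,
    expression: Sequence[GeneExpression],
    gene_locations: Mapping[str, str],
    options: AnalysisOptions = AnalysisOptions(),
    markers: Sequence[MarkerHit] | None = None,
) -> SpeciesReport:
    """Per-species pipeline over in-memory tables (see :func:`run_species`)."""
    counts: dict[str, int] = {}
    model, calls = _species_linkage(name, coverage, markers, gene_locations, options)
    by_class = {X: 0, AUTOSOME: 0, EXCLUDED: 0}
    for c in calls:
        by_class[c.linkage] += 1
    counts.update({f"scaffolds_{k}": v for k, v in by_class.items()})

    genes = sexlink.gene_linkage(gene_locations, calls)
    counts["genes_located"] = len(genes)
    counts["genes_x"] = sum(1 for v in genes.values() if v == X)
    counts["genes_autosome"] = sum(1 for v in genes.values() if v == AUTOSOME)

    counts["genes_expression_in"] = len(expression)
    expressed = dosage.filter_expressed(expression, options.fpkm_threshold)
    counts["genes_expressed"] = len(expressed)
    counts["genes_expression_filtered"] = len(expression) - len(expressed)
    logger.info(
        json.dumps({"stage": "filter_expressed", "species": name,
                    "in": len(expression), "out": len(expressed)})
    )

    stats = dosage.dosage_statistic(expressed, genes, aggregate=options.ratio_aggregate)

    values = {X: {"female": [], "male": [], "log2_mf": []},
              AUTOSOME: {"female": [], "male": [], "log2_mf": []}}
    for g in expressed:
        cls = genes.get(g.gene_id)
        if cls in values:
            values[cls]["female"].append(g.female_fpkm)
            values[cls]["male"].append(g.male_fpkm)
            values[cls]["log2_mf"].append(dosage.log2_mf_expression(g))
    contrasts = [
        dosage.xa_location_test(values[X][panel], values[AUTOSOME][panel],
                                contrast_name=f"{name}:{panel}")
        for panel in ("female", "male", "log2_mf")
    ]
    contrasts = dosage.bonferroni(contrasts, options.bonferroni_m)

    bias_calls = sexbias.classify_bias(expressed, alpha=options.alpha)
    proportion_tests = {}
    for which in (sexbias.MALE, sexbias.FEMALE):
        try:
            proportion_tests[which] = sexbias.bias_proportion_test(bias_calls, genes, which)
        except (sexbias.DegenerateTableError, ValueError) as exc:
            # e.g. no biased gene anywhere: the 2x2 margin is zero
            logger.warning(
                json.dumps({"stage": "bias_proportion_test", "species": name,
                            "which": which, "skipped": str(exc)})
            )
    return SpeciesReport(
        name=name,
        model=model,
        linkage_calls=calls,
        gene_linkage=genes,
        dosage_stats=stats,
        contrasts=contrasts,
        bias_calls=bias_calls,
        proportion_tests=proportion_tests,
        counts=counts,
    )


def run_species(entry: SpeciesInput, options: AnalysisOptions = AnalysisOptions()) -> SpeciesReport:
    """Run the per-species pipeline from table files.

    Any stage failure yields a report whose ``error`` field carries the
    structured message instead of aborting sibling species (callers loop).
    """
    try:
        coverage = (
            io_tables.read_coverage_table(entry.coverage_path)
            if entry.coverage_path else None
        )
        markers = (
            io_tables.read_marker_table(entry.marker_path)
            if entry.marker_path else None
        )
        expression = io_tables.read_expression_table(entry.expression_path)
        gene_locations = io_tables.read_gene_locations(entry.gtf_path)
        return run_species_tables(
            entry.name, coverage, expression, gene_locations, options, markers=markers
        )
    except (ValueError, OSError) as exc:
        logger.error(json.dumps({"stage": "run_species", "species": entry.name,
                                 "error": str(exc)}))
        return SpeciesReport(
            name=entry.name, model=None, linkage_calls=[], gene_linkage={},
            dosage_stats=None, contrasts=[], bias_calls=[], proportion_tests={},
            counts={}, error=str(exc),
        )


def run_pairwise(
    reports: Sequence[SpeciesReport],
    hit_tables: Mapping[str, tuple[Sequence, Sequence]],
    options: AnalysisOptions = AnalysisOptions(),
    reference: str | None = None,
) -> list[PairReport]:
    """Shared-X conservation test for every pair of analyzed species.

    ``hit_tables`` maps each non-reference species name to its
    ``(reference->species, species->reference)`` hit tables; 1:1 pairs are
    inferred by reciprocal best hit against the reference and pairs between
    two non-reference species are extrapolated through it.  Pairs whose
    test is impossible (missing hits, degenerate margins) are skipped with
    an error record, not raised.
    """
    if reference is None:
        reference = reports[0].name
    by_name = {r.name: r for r in reports}
    ref_maps: dict[str, orthology.OrthologyMap] = {}
    for name, (hits_ref_sp, hits_sp_ref) in hit_tables.items():
        pairs = orthology.reciprocal_best_hits(
            hits_ref_sp, hits_sp_ref, min_score=options.min_score
        )
        ref_maps[name] = orthology.OrthologyMap(
            species_pair=(reference, name),
            pairs=pairs,
            linkage_1=by_name[reference].gene_linkage,
            linkage_2=by_name[name].gene_linkage,
        )
    out: list[PairReport] = []
    names = [r.name for r in reports]
    for a, b in itertools.combinations(names, 2):
        try:
            if a == reference:
                omap = ref_maps[b]
            elif b == reference:
                omap = ref_maps[a]
            else:
                omap = orthology.extrapolate_via_reference(ref_maps[a], ref_maps[b])
            result = orthology.shared_x_test(
                omap, mc_reps=options.mc_reps, seed=options.seed
            )
            out.append(PairReport(species_pair=(a, b), result=result))
        except (KeyError, ValueError) as exc:
            msg = f"pair ({a}, {b}) skipped: {exc}"
            logger.error(json.dumps({"stage": "run_pairwise", "pair": [a, b],
                                     "error": str(exc)}))
            out.append(PairReport(species_pair=(a, b), result=None, error=msg))
    return out


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, float) and obj != obj:  # NaN -> null
        return None
    return obj


def species_report_json(report: SpeciesReport) -> dict:
    """Condensed JSON form of a species report (omits per-gene vectors)."""
    return _to_jsonable(
        {
            "name": report.name,
            "a_median": report.model.a_median if report.model else None,
            "threshold": report.model.threshold if report.model else None,
            "dosage": report.dosage_stats,
            "contrasts": report.contrasts,
            "proportion_tests": report.proportion_tests,
            "counts": report.counts,
            "error": report.error,
        }
    )


def run(config: RunConfig) -> dict:
    """Full study: per-species reports, pairwise conservation, files on disk.

    Writes per-species ``<name>.report.json`` and ``<name>.linkage.tsv``,
    a ``pairwise.json`` mirroring the observed/expected shared-X matrix,
    and ``run_summary.json``; returns the summary dict.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    options = config.options
    reports = [run_species(entry, options) for entry in config.species]
    for rep in reports:
        with open(outdir / f"{rep.name}.report.json", "w", encoding="utf-8") as fh:
            json.dump(species_report_json(rep), fh, indent=1, sort_keys=True)
        with open(outdir / f"{rep.name}.linkage.tsv", "w", encoding="utf-8") as fh:
            fh.write("scaffold_id\tlog2_mf_coverage\tlinkage\n")
            for c in rep.linkage_calls:
                ratio = "NA" if c.log2_mf_coverage != c.log2_mf_coverage else repr(c.log2_mf_coverage)
                fh.write(f"{c.scaffold_id}\t{ratio}\t{c.linkage}\n")
    pair_reports: list[PairReport] = []
    if config.hit_paths:
        hit_tables = {
            name: (io_tables.read_hit_table(fwd), io_tables.read_hit_table(rev))
            for name, (fwd, rev) in config.hit_paths.items()
        }
        pair_reports = run_pairwise(
            reports, hit_tables, options, reference=config.reference
        )
        with open(outdir / "pairwise.json", "w", encoding="utf-8") as fh:
            json.dump([_to_jsonable(p) for p in pair_reports], fh, indent=1, sort_keys=True)
    summary = {
        "species": {r.name: species_report_json(r) for r in reports},
        "pairwise": [_to_jsonable(p) for p in pair_reports],
        "options": _to_jsonable(options),
    }
    with open(outdir / "run_summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary
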