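"""Synthetic study generator with known ground truth.

Emulates, at the summary-table level, the data regimes the pipeline
consumes: bimodal log2(male/female) genomic coverage (autosomal mode at 0,
X mode at -1, log-normal noise), FPKM-like expression with a tunable
chromosome-wide compensation level and tunable sex-bias fractions,
DE p-values with a controllable confusion structure, and multi-species
1:1 orthology whose X-linkage conservation is a dial.

Nothing at the read or sequence level is simulated — the generator starts
where the out-of-scope upstream tools (mappers, assemblers, aligners,
DE engines) end, producing exactly the tables :mod:`hemix.io_tables`
reads, plus truth labels so every estimator's parameter recovery can be
measured.

All randomness flows through one :class:`numpy.random.Generator` seeded
from the config, so identical configs give byte-identical output tables.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io_tables import (
    CoverageRecord,
    GeneExpression,
    HitRecord,
    write_coverage_table,
    write_expression_table,
    write_gene_locations,
    write_hit_table,
)
from .orthology import OrthologyMap
from .sexlink import AUTOSOME, X
from .sexbias import FEMALE, MALE, UNBIASED

__all__ = [
    "SimulationConfig",
    "SyntheticSpecies",
    "OrthologySim",
    "SyntheticStudy",
    "simulate_coverage",
    "simulate_expression",
    "simulate_orthology",
    "simulate_study",
    "write_study",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the study conditions.

    Coverage: ``x_fraction`` of scaffolds are X-linked (hemipteran X
    chromosomes carry roughly 8-13% of genes); female per-scaffold log2
    depth is Normal(log2(coverage_depth), coverage_noise_sd) and male log2
    depth adds an independent Normal(0, coverage_noise_sd) plus a -1 shift
    on the X.  ``zero_coverage_fraction`` of scaffolds get zero depth in
    one sex to exercise the exclusion path.

    Expression: female log2 FPKM is Normal(base mean, base sd); unbiased
    genes' male log2 FPKM adds Normal(0, expression_noise_sd) plus
    ``log2(compensation_level)`` on the X (the chromosome-wide
    compensation dial: 1.0 = full, 0.5 = none).  Sex-biased genes
    additionally shift male expression by +/- ``bias_effect_log2``.  DE
    p-values are Uniform(0,1) for unbiased genes and
    Beta(biased_pvalue_shape, 1) for biased ones — simulated rather than
    computed, since no DE engine is part of the pipeline.

    Orthology: every gene belongs to a 1:1 ortholog group across species;
    species k's X-linkage copies the reference species' with probability
    ``conservation_rho`` (scalar, or one value per non-reference species)
    and is otherwise redrawn at ``x_fraction``.  Directional hit tables
    make true pairs reciprocal best hits except for a ``rbh_noise``
    fraction that receive a higher-scoring off-target hit.
    """

    n_scaffolds: int = 500
    genes_per_scaffold_mean: float = 10.0
    x_fraction: float = 0.10
    coverage_depth: float = 30.0
    coverage_noise_sd: float = 0.15
    zero_coverage_fraction: float = 0.01
    compensation_level: float = 0.9
    expression_noise_sd: float = 0.25
    base_log2_fpkm_mean: float = 3.0
    base_log2_fpkm_sd: float = 1.5
    male_bias_prob_x: float = 0.04
    male_bias_prob_a: float = 0.08
    female_bias_prob_x: float = 0.10
    female_bias_prob_a: float = 0.08
    bias_effect_log2: float = 2.0
    biased_pvalue_shape: float = 0.1
    n_species: int = 2
    conservation_rho: float | tuple[float, ...] = 1.0
    rbh_noise: float = 0.02
    background_hit_prob: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_scaffolds < 1 or self.n_species < 1:
            raise ValueError("n_scaffolds and n_species must be positive")
        if not 0 < self.x_fraction < 1:
            raise ValueError("x_fraction must lie in (0, 1)")
        if not 0 < self.compensation_level <= 1:
            raise ValueError("compensation_level must lie in (0, 1]")
        if self.genes_per_scaffold_mean < 1:
            raise ValueError("genes_per_scaffold_mean must be >= 1")
        for sd in (self.coverage_noise_sd, self.expression_noise_sd):
            if sd < 0:
                raise ValueError("noise standard deviations must be >= 0")
        for label, mx, fx in (
            ("X", self.male_bias_prob_x, self.female_bias_prob_x),
            ("autosome", self.male_bias_prob_a, self.female_bias_prob_a),
        ):
            if min(mx, fx) < 0 or mx + fx >= 1:
                raise ValueError(f"bias probabilities on {label} must sum to < 1")
        if not 0 <= self.rbh_noise < 1:
            raise ValueError("rbh_noise must lie in [0, 1)")
        for rho in self.rhos():
            if not 0 <= rho <= 1:
                raise ValueError("conservation_rho values must lie in [0, 1]")

    def rhos(self) -> tuple[float, ...]:
        """Conservation level of each non-reference species vs the reference."""
        k = max(0, self.n_species - 1)
        if isinstance(self.conservation_rho, (int, float)):
            return (float(self.conservation_rho),) * k
        rhos = tuple(float(r) for r in self.conservation_rho)
        if len(rhos) != k:
            raise ValueError(
                f"need {k} conservation_rho values for {self.n_species} species, "
                f"got {len(rhos)}"
            )
        return rhos


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------

def simulate_coverage(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    scaffold_labels: Mapping[str, str] | None = None,
):
    """Per-scaffold male/female coverage with known linkage truth.

    Returns ``(records, truth)`` where ``truth`` maps every scaffold to its
    generating X/autosome label (zero-coverage scaffolds included — their
    truth is known even though the classifier must exclude them).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if scaffold_labels is None:
        ids = [f"s{i:05d}" for i in range(config.n_scaffolds)]
        is_x = rng.random(config.n_scaffolds) < config.x_fraction
    else:
        ids = list(scaffold_labels)
        is_x = np.array([scaffold_labels[s] == X for s in ids], dtype=bool)
    n = len(ids)
    sd = config.coverage_noise_sd
    female_log2 = math.log2(config.coverage_depth) + (
        rng.normal(0.0, sd, n) if sd > 0 else np.zeros(n)
    )
    shift = np.where(is_x, -1.0, 0.0)
    male_log2 = female_log2 + shift + (rng.normal(0.0, sd, n) if sd > 0 else np.zeros(n))
    female = 2.0**female_log2
    male = 2.0**male_log2
    n_zero = int(round(config.zero_coverage_fraction * n))
    if n_zero > 0:
        hit = rng.choice(n, size=n_zero, replace=False)
        male[hit[0::2]] = 0.0
        female[hit[1::2]] = 0.0
    records = [CoverageRecord(ids[i], float(male[i]), float(female[i])) for i in range(n)]
    truth = {ids[i]: (X if is_x[i] else AUTOSOME) for i in range(n)}
    return records, truth


def _partition_into_scaffolds(
    gene_ids: Sequence[str],
    is_x: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    prefix: str,
):
    """Group genes of like linkage onto scaffolds with ~Poisson sizes.

    Returns ``(gene_scaffold, scaffold_labels)``; scaffolds are pure in
    linkage by construction (in real genomes this purity is what makes
    scaffold-level classification informative for genes).
    """
    gene_scaffold: dict[str, str] = {}
    scaffold_labels: dict[str, str] = {}
    counter = 0
    for label, mask in ((X, is_x), (AUTOSOME, ~is_x)):
        members = [gene_ids[i] for i in np.flatnonzero(mask)]
        rng.shuffle(members)
        i = 0
        while i < len(members):
            size = 1 + rng.poisson(config.genes_per_scaffold_mean - 1.0)
            sid = f"{prefix}_s{counter:05d}"
            scaffold_labels[sid] = label
            for g in members[i : i + size]:
                gene_scaffold[g] = sid
            i += size
            counter += 1
    return gene_scaffold, scaffold_labels


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(
    config: SimulationConfig,
    gene_linkage: Mapping[str, str],
    gene_scaffold: Mapping[str, str],
    rng: np.random.Generator | None = None,
):
    """FPKM-like expression + DE p-values for genes with known linkage.

    Returns ``(records, bias_truth)``; ``bias_truth`` maps genes to their
    generating class (male/female/unbiased).  The compensation shift
    ``log2(compensation_level)`` applies to every X-linked gene's male
    expression (chromosome-wide mechanism); biased genes add their effect
    on top.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    genes = list(gene_linkage)
    n = len(genes)
    is_x = np.array([gene_linkage[g] == X for g in genes], dtype=bool)
    u = rng.random(n)
    p_male = np.where(is_x, config.male_bias_prob_x, config.male_bias_prob_a)
    p_female = np.where(is_x, config.female_bias_prob_x, config.female_bias_prob_a)
    bias = np.where(u < p_male, 0, np.where(u < p_male + p_female, 1, 2))  # M, F, U

    female_log2 = rng.normal(config.base_log2_fpkm_mean, config.base_log2_fpkm_sd, n)
    male_log2 = female_log2 + rng.normal(0.0, config.expression_noise_sd, n)
    male_log2 += np.where(is_x, math.log2(config.compensation_level), 0.0)
    male_log2 += np.where(bias == 0, config.bias_effect_log2, 0.0)
    male_log2 -= np.where(bias == 1, config.bias_effect_log2, 0.0)

    pvals = rng.random(n)  # uniform null for unbiased genes
    biased = bias != 2
    pvals[biased] = rng.beta(config.biased_pvalue_shape, 1.0, int(biased.sum()))

    class_names = (MALE, FEMALE, UNBIASED)
    records = []
    bias_truth = {}
    for i, g in enumerate(genes):
        records.append(
            GeneExpression(
                gene_id=g,
                scaffold_id=gene_scaffold[g],
                male_fpkm=float(2.0 ** male_log2[i]),
                female_fpkm=float(2.0 ** female_log2[i]),
                de_pvalue=float(pvals[i]),
            )
        )
        bias_truth[g] = class_names[bias[i]]
    return records, bias_truth


# ---------------------------------------------------------------------------
# orthology
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrthologySim:
    """Directional hit tables linking one species to the reference."""

    species: str
    reference: str
    hits_ref_to_sp: list[HitRecord]
    hits_sp_to_ref: list[HitRecord]
    true_pairs: list[tuple[str, str]]  # (reference gene, species gene)


def _evalue_for(score: float) -> float:
    return 10.0 ** (-score / 10.0)


def simulate_orthology(
    config: SimulationConfig,
    ref_genes: Sequence[str],
    sp_genes: Sequence[str],
    rng: np.random.Generator,
    species: str = "sp2",
    reference: str = "sp1",
) -> OrthologySim:
    """Hit tables for one species against the reference.

    ``ref_genes[i]`` and ``sp_genes[i]`` are the same ortholog group.  Each
    true pair gets a reciprocal pair of strong hits (score U(100, 300));
    background off-target hits (score U(20, 90), some below the score-50
    filter) are sprinkled per ``background_hit_prob``; an ``rbh_noise``
    fraction of groups get a spurious off-target hit outscoring the true
    one in the species->reference direction, destroying their RBH.
    """
    n = len(ref_genes)
    if len(sp_genes) != n:
        raise ValueError("gene lists must be ortholog-group aligned")
    true_scores = rng.uniform(100.0, 300.0, n)
    hits_ref_to_sp: list[HitRecord] = []
    hits_sp_to_ref: list[HitRecord] = []
    for i in range(n):
        s = float(true_scores[i])
        hits_ref_to_sp.append(HitRecord(ref_genes[i], sp_genes[i], s, _evalue_for(s)))
        hits_sp_to_ref.append(HitRecord(sp_genes[i], ref_genes[i], s, _evalue_for(s)))
    # background noise hits
    for out, queries, targets in (
        (hits_ref_to_sp, ref_genes, sp_genes),
        (hits_sp_to_ref, sp_genes, ref_genes),
    ):
        if n < 2:
            break
        with_bg = np.flatnonzero(rng.random(n) < config.background_hit_prob)
        for i in with_bg:
            j = int(rng.integers(n - 1))
            j += j >= i  # any target but the true partner
            s = float(rng.uniform(20.0, 90.0))
            out.append(HitRecord(queries[i], targets[j], s, _evalue_for(s)))
    # RBH-destroying spurious best hits
    if n >= 2 and config.rbh_noise > 0:
        broken = np.flatnonzero(rng.random(n) < config.rbh_noise)
        for i in broken:
            j = int(rng.integers(n - 1))
            j += j >= i
            s = float(true_scores[i] + rng.uniform(1.0, 50.0))
            hits_sp_to_ref.append(HitRecord(sp_genes[i], ref_genes[j], s, _evalue_for(s)))
    return OrthologySim(
        species=species,
        reference=reference,
        hits_ref_to_sp=hits_ref_to_sp,
        hits_sp_to_ref=hits_sp_to_ref,
        true_pairs=[(ref_genes[i], sp_genes[i]) for i in range(n)],
    )


# ---------------------------------------------------------------------------
# whole study
# ---------------------------------------------------------------------------

@dataclass
class SyntheticSpecies:
    """All synthetic tables and truth labels of one species."""

    name: str
    coverage: list[CoverageRecord]
    scaffold_truth: dict[str, str]
    gene_scaffold: dict[str, str]
    gene_linkage_truth: dict[str, str]
    expression: list[GeneExpression]
    bias_truth: dict[str, str]


@dataclass
class SyntheticStudy:
    """A multi-species synthetic study anchored on a reference species.

    ``species[0]`` plays the role of the well-annotated reference through
    which cross-species orthology is extrapolated.  Ortholog group i is
    gene ``{name}_g{i}`` in every species.
    """

    config: SimulationConfig
    species: list[SyntheticSpecies]
    orthology: dict[str, OrthologySim]  # non-reference species name -> sim

    @property
    def reference(self) -> str:
        return self.species[0].name

    def species_named(self, name: str) -> SyntheticSpecies:
        for sp in self.species:
            if sp.name == name:
                return sp
        raise KeyError(name)

    def true_map(self, name_a: str, name_b: str) -> OrthologyMap:
        """Ground-truth 1:1 orthology between two species (all groups)."""
        a = self.species_named(name_a)
        b = self.species_named(name_b)
        n = len(a.gene_scaffold)
        pairs = [(f"{name_a}_g{i:05d}", f"{name_b}_g{i:05d}") for i in range(n)]
        return OrthologyMap(
            species_pair=(name_a, name_b),
            pairs=pairs,
            linkage_1=a.gene_linkage_truth,
            linkage_2=b.gene_linkage_truth,
        )


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate the full multi-species study from one seeded config."""
    rng = np.random.default_rng(config.seed)
    # ortholog-group linkage, reference species first
    n_genes = int(
        np.sum(1 + rng.poisson(config.genes_per_scaffold_mean - 1.0, config.n_scaffolds))
    )
    ref_is_x = rng.random(n_genes) < config.x_fraction
    rhos = config.rhos()
    species: list[SyntheticSpecies] = []
    for k in range(config.n_species):
        name = f"sp{k + 1}"
        if k == 0:
            is_x = ref_is_x
        else:
            keep = rng.random(n_genes) < rhos[k - 1]
            redraw = rng.random(n_genes) < config.x_fraction
            is_x = np.where(keep, ref_is_x, redraw)
        gene_ids = [f"{name}_g{i:05d}" for i in range(n_genes)]
        gene_scaffold, scaffold_labels = _partition_into_scaffolds(
            gene_ids, is_x, config, rng, prefix=name
        )
        coverage, scaffold_truth = simulate_coverage(
            config, rng, scaffold_labels=scaffold_labels
        )
        gene_linkage_truth = {g: (X if is_x[i] else AUTOSOME) for i, g in enumerate(gene_ids)}
        expression, bias_truth = simulate_expression(
            config, gene_linkage_truth, gene_scaffold, rng
        )
        species.append(
            SyntheticSpecies(
                name=name,
                coverage=coverage,
                scaffold_truth=scaffold_truth,
                gene_scaffold=gene_scaffold,
                gene_linkage_truth=gene_linkage_truth,
                expression=expression,
                bias_truth=bias_truth,
            )
        )
    ref_gene_ids = [f"{species[0].name}_g{i:05d}" for i in range(n_genes)]
    orthology = {}
    for sp in species[1:]:
        sp_gene_ids = [f"{sp.name}_g{i:05d}" for i in range(n_genes)]
        orthology[sp.name] = simulate_orthology(
            config, ref_gene_ids, sp_gene_ids, rng,
            species=sp.name, reference=species[0].name,
        )
    return SyntheticStudy(config=config, species=species, orthology=orthology)


def write_study(study: SyntheticStudy, outdir: str | Path) -> dict:
    """Write every table of a study under ``outdir``; returns a manifest.

    Per species: ``<name>.coverage.tsv``, ``<name>.expression.tsv``,
    ``<name>.gtf``; per non-reference species: two directional hit tables;
    plus ``truth.json`` with every generating label.  All files re-read
    cleanly through :mod:`hemix.io_tables`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"reference": study.reference, "species": {}, "hits": {}}
    for sp in study.species:
        paths = {
            "coverage": outdir / f"{sp.name}.coverage.tsv",
            "expression": outdir / f"{sp.name}.expression.tsv",
            "gtf": outdir / f"{sp.name}.gtf",
        }
        write_coverage_table(sp.coverage, paths["coverage"])
        write_expression_table(sp.expression, paths["expression"])
        write_gene_locations(sp.gene_scaffold, paths["gtf"])
        manifest["species"][sp.name] = {k: str(v) for k, v in paths.items()}
    for name, sim in study.orthology.items():
        fwd = outdir / f"{sim.reference}_vs_{name}.hits.tsv"
        rev = outdir / f"{name}_vs_{sim.reference}.hits.tsv"
        write_hit_table(sim.hits_ref_to_sp, fwd)
        write_hit_table(sim.hits_sp_to_ref, rev)
        manifest["hits"][name] = {"ref_to_sp": str(fwd), "sp_to_ref": str(rev)}
    truth = {
        "config": asdict(study.config),
        "species": {
            sp.name: {
                "scaffold_linkage": sp.scaffold_truth,
                "gene_linkage": sp.gene_linkage_truth,
                "bias": sp.bias_truth,
            }
            for sp in study.species
        },
        "true_pairs": {name: sim.true_pairs for name, sim in study.orthology.items()},
    }
    truth_path = outdir / "truth.json"
    with open(truth_path, "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    manifest["truth"] = str(truth_path)
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
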