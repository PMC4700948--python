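#!/usr/bin/env python
"""Is the X the same chromosomal element across species?

Infers 1:1 orthology by reciprocal best hit against the reference species
(extrapolating pairs between non-reference species through it), then
tests every species pair for an excess of orthologs X-linked in both
(Yates chi-square + Monte Carlo permutation).  Writes
results/conservation.tsv and the observed/expected shared-X matrix.
"""

import argparse
import json
from pathlib import Path

from hemix import io_tables, pipeline, plots, sexlink
from hemix.pipeline import AnalysisOptions

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data-dir", type=Path, default=ROOT / "scratch" / "synthetic")
    parser.add_argument("--out-dir", type=Path, default=ROOT / "results")
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--mc-reps", type=int, default=10_000)
    args = parser.parse_args()

    manifest = json.loads((args.data_dir / "manifest.json").read_text())
    args.out_dir.mkdir(parents=True, exist_ok=True)
    options = AnalysisOptions(mc_reps=args.mc_reps, seed=args.seed)

    reports = []
    for name, paths in sorted(manifest["species"].items()):
        coverage = io_tables.read_coverage_table(paths["coverage"])
        expression = io_tables.read_expression_table(paths["expression"])
        locations = io_tables.read_gene_locations(paths["gtf"])
        reports.append(
            pipeline.run_species_tables(name, coverage, expression, locations, options)
        )
    hits = {
        name: (io_tables.read_hit_table(entry["ref_to_sp"]),
               io_tables.read_hit_table(entry["sp_to_ref"]))
        for name, entry in manifest["hits"].items()
    }
    pairs = pipeline.run_pairwise(reports, hits, options, reference=manifest["reference"])

    rows = []
    ratios = {}
    for p in pairs:
        if p.result is None:
            print(f"{p.species_pair}: {p.error}")
            continue
        r = p.result
        ratios[p.species_pair] = r.ratio
        rows.append({
            "species_1": p.species_pair[0],
            "species_2": p.species_pair[1],
            "n_orthologs": r.n,
            "obs_shared_x": r.obs_xx,
            "exp_shared_x": f"{r.exp_xx:.2f}",
            "obs_over_exp": f"{r.ratio:.3f}",
            "chi2_p": f"{r.chi2_p:.3g}",
            "mc_p": f"{r.mc_p:.3g}",
        })
        print(f"{p.species_pair[0]}-{p.species_pair[1]}: "
              f"obs/exp = {r.ratio:.2f} ({r.obs_xx}/{r.exp_xx:.1f} of {r.n}), "
              f"chi2 p = {r.chi2_p:.2g}, MC p = {r.mc_p:.2g}")

    out = args.out_dir / "conservation.tsv"
    with open(out, "w", encoding="utf-8") as fh:
        fh.write("\t".join(rows[0]) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row.values()) + "\n")
    fig_dir = args.out_dir / "figures"
    fig_dir.mkdir(exist_ok=True)
    plots.shared_x_matrix(ratios, fig_dir / "shared_x_matrix.png")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
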