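#!/usr/bin/env python
"""Quantify dosage compensation per species.

Computes, for genes expressed in both sexes (FPKM > 1), the median
male/female expression ratio on the X and the autosomes, their quotient
(M/F_X)/(M/F_A), and Bonferroni-corrected Wilcoxon tests of X-vs-autosome
location for female expression, male expression and the log2(M/F) ratio.
Writes results/dosage.tsv and per-species expression panels.
"""

import argparse
import json
from pathlib import Path

from hemix import dosage, io_tables, plots, sexlink
from hemix.sexlink import AUTOSOME, X

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data-dir", type=Path, default=ROOT / "scratch" / "synthetic")
    parser.add_argument("--out-dir", type=Path, default=ROOT / "results")
    args = parser.parse_args()

    manifest = json.loads((args.data_dir / "manifest.json").read_text())
    args.out_dir.mkdir(parents=True, exist_ok=True)
    fig_dir = args.out_dir / "figures"
    fig_dir.mkdir(exist_ok=True)

    rows = []
    for name, paths in sorted(manifest["species"].items()):
        coverage = io_tables.read_coverage_table(paths["coverage"])
        expression = io_tables.read_expression_table(paths["expression"])
        locations = io_tables.read_gene_locations(paths["gtf"])
        ratios = [r for r in map(sexlink.log2_coverage_ratio, coverage) if r is not None]
        model = sexlink.estimate_autosomal_mode(ratios)
        genes = sexlink.gene_linkage(locations, sexlink.classify_scaffolds(coverage, model))
        expressed = dosage.filter_expressed(expression)
        stats = dosage.dosage_statistic(expressed, genes)
        values = {X: {"female": [], "male": [], "log2_mf": []},
                  AUTOSOME: {"female": [], "male": [], "log2_mf": []}}
        for g in expressed:
            cls = genes.get(g.gene_id)
            if cls in values:
                values[cls]["female"].append(g.female_fpkm)
                values[cls]["male"].append(g.male_fpkm)
                values[cls]["log2_mf"].append(dosage.log2_mf_expression(g))
        contrasts = dosage.bonferroni([
            dosage.xa_location_test(values[X][p], values[AUTOSOME][p], f"{name}:{p}")
            for p in ("female", "male", "log2_mf")
        ])
        plots.expression_panels(values, fig_dir / f"{name}.expression.png", title=name)
        row = {
            "species": name,
            "n_expressed": len(expressed),
            "n_x": stats.n_x,
            "n_a": stats.n_a,
            "mf_x": f"{stats.mf_x:.4f}",
            "mf_a": f"{stats.mf_a:.4f}",
            "dc_ratio": f"{stats.dc_ratio:.4f}",
        }
        for c in contrasts:
            row[f"p_adj_{c.contrast_name.split(':')[1]}"] = f"{c.p_adjusted:.3g}"
        rows.append(row)
        print(f"{name}: (M/F_X)/(M/F_A) = {stats.dc_ratio:.3f} "
              f"({stats.n_x} X, {stats.n_a} autosomal genes)")

    out = args.out_dir / "dosage.tsv"
    with open(out, "w", encoding="utf-8") as fh:
        fh.write("\t".join(rows[0]) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row.values()) + "\n")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
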