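#!/usr/bin/env python
"""Sex-biased gene content of the X versus the autosomes.

Classifies expressed genes as male-/female-biased (DE p < 0.05, direction
from FPKM) or unbiased, then tests whether the X carries an excess or
deficit of each bias class relative to the autosomes (Yates chi-square).
Writes results/sexbias.tsv.
"""

import argparse
import json
from pathlib import Path

from hemix import dosage, io_tables, sexbias, sexlink

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data-dir", type=Path, default=ROOT / "scratch" / "synthetic")
    parser.add_argument("--out-dir", type=Path, default=ROOT / "results")
    args = parser.parse_args()

    manifest = json.loads((args.data_dir / "manifest.json").read_text())
    args.out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for name, paths in sorted(manifest["species"].items()):
        coverage = io_tables.read_coverage_table(paths["coverage"])
        expression = io_tables.read_expression_table(paths["expression"])
        locations = io_tables.read_gene_locations(paths["gtf"])
        ratios = [r for r in map(sexlink.log2_coverage_ratio, coverage) if r is not None]
        model = sexlink.estimate_autosomal_mode(ratios)
        genes = sexlink.gene_linkage(locations, sexlink.classify_scaffolds(coverage, model))
        expressed = dosage.filter_expressed(expression)
        calls = sexbias.classify_bias(expressed)
        for which in (sexbias.MALE, sexbias.FEMALE):
            t = sexbias.bias_proportion_test(calls, genes, which)
            rows.append({
                "species": name,
                "bias": which,
                "pct_x": f"{100 * t.k_x / t.n_x:.2f}",
                "pct_a": f"{100 * t.k_a / t.n_a:.2f}",
                "chi2": f"{t.chi2:.3f}",
                "p": f"{t.p:.3g}",
                "direction": t.direction,
            })
            print(f"{name} {which}-biased: X {t.k_x}/{t.n_x} vs A {t.k_a}/{t.n_a} "
                  f"-> {t.direction} (p = {t.p:.3g})")

    out = args.out_dir / "sexbias.tsv"
    with open(out, "w", encoding="utf-8") as fh:
        fh.write("\t".join(rows[0]) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row.values()) + "\n")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
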