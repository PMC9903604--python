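"""13-way expression-pattern classification and truth recovery.

Combines the three DEG contrasts per focal time point into a signed call
pattern per gene, assigns each gene one of 13 additive / dominance /
transgressive classes, summarizes the five categories (pattern-table
layout) and the high-/mid-/low-parent three-way split, and scores category
recovery against the simulator's known truth.
"""

from pathlib import Path

import pandas as pd

from triadexpress.classify import (class_recovery, class_summary,
                                   classify_matrix, parent_level_summary)
from triadexpress.expression import expressed_genes, fpkm, mean_replicates
from triadexpress.matrix import read_gene_lengths, read_matrix
from triadexpress.pipeline import render_table1

BASE = Path(__file__).resolve().parent.parent / "results"
OUT = BASE / "classification"
FOCAL_DAPS = (3, 8)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    counts = read_matrix(BASE / "sim" / "counts.tsv",
                         BASE / "sim" / "sample_sheet.tsv")
    fp = fpkm(counts, read_gene_lengths(BASE / "sim" / "gene_lengths.tsv"))
    means = mean_replicates(fp)
    truth = pd.read_csv(BASE / "sim" / "sim_truth.tsv", sep="\t",
                        index_col="gene_id")
    summaries = {}
    for dap in FOCAL_DAPS:
        degs = {key: pd.read_csv(
            BASE / "differential" / f"deg_{key}_dap{dap}.tsv",
            sep="\t", index_col="gene_id", comment="#")
            for key in ("mp", "mh", "ph")}
        universe = set.intersection(*[expressed_genes(fp, g, dap)
                                      for g in ("M", "H", "P")])
        idx = [g for g in fp.gene_ids if g in universe]
        mu = pd.DataFrame({"mu_M": means.values[f"M_d{dap}"],
                           "mu_H": means.values[f"H_d{dap}"],
                           "mu_P": means.values[f"P_d{dap}"]})
        table = classify_matrix(degs["mp"].loc[idx], degs["mh"].loc[idx],
                                degs["ph"].loc[idx], mu.loc[idx])
        table.to_csv(OUT / f"classification_dap{dap}.tsv", sep="\t",
                     index_label="gene_id")
        summ = class_summary(table)
        summaries[dap] = summ
        levels = parent_level_summary(table)
        pd.Series(levels).rename("count").to_csv(
            OUT / f"parent_level_dap{dap}.tsv", sep="\t",
            index_label="parent_level")
        t_dap = truth[truth.dap == dap]
        report = class_recovery(t_dap.loc[table.index], table)
        report.confusion.to_csv(OUT / f"recovery_dap{dap}.tsv", sep="\t")
        cat = summ["per_category"]
        print(f"{dap} DAP: {summ['total']} genes classified; additive "
              f"{cat.loc['additive', 'pct']}%, dominance "
              f"{cat.loc['ELD_M', 'pct'] + cat.loc['ELD_P', 'pct']:.2f}%, "
              f"transgressive "
              f"{cat.loc['transgressive_up', 'pct'] + cat.loc['transgressive_down', 'pct']:.2f}%")
        print(f"  parent level: {levels}; category recovery accuracy vs "
              f"truth {report.accuracy:.3f}")
    render_table1(summaries).to_csv(OUT / "pattern_table.tsv", sep="\t")


if __name__ == "__main__":
    main()
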