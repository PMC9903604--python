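"""Pairwise differential expression at the two focal time points.

At 3 DAP (peak relative growth) and 8 DAP (onset of significant hybrid
seed-coat heterosis) the hybrid is contrasted against each parent, and the
parents against each other, gene by gene: pooled-variance t on
log2(FPKM+1), BH-adjusted p < 0.05, |FC| >= 2. Writes the three DEG tables
per time point and the up/down split summaries.
"""

from pathlib import Path

import pandas as pd

from triadexpress.differential import deg_table, updown_summary, write_deg_table
from triadexpress.expression import fpkm
from triadexpress.matrix import read_gene_lengths, read_matrix

BASE = Path(__file__).resolve().parent.parent / "results"
OUT = BASE / "differential"
FOCAL_DAPS = (3, 8)
CONTRASTS = {"mp": ("P", "M"), "mh": ("M", "H"), "ph": ("P", "H")}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    counts = read_matrix(BASE / "sim" / "counts.tsv",
                         BASE / "sim" / "sample_sheet.tsv")
    fp = fpkm(counts, read_gene_lengths(BASE / "sim" / "gene_lengths.tsv"))
    summary_rows = []
    for dap in FOCAL_DAPS:
        for key, (a, b) in CONTRASTS.items():
            tab = deg_table(fp, a, b, dap)
            write_deg_table(tab, OUT / f"deg_{key}_dap{dap}.tsv")
            s = updown_summary(tab)
            s.update({"contrast": f"{b}_vs_{a}", "dap": dap})
            summary_rows.append(s)
            print(f"{b} vs {a} at {dap} DAP: {s['n_total_deg']} DEGs "
                  f"({s['n_up']} up, {s['n_down']} down"
                  + (f"; {s['pct_up']}% up)" if s["pct_up"] is not None else ")"))
    pd.DataFrame(summary_rows).to_csv(OUT / "updown_summary.tsv", sep="\t",
                                      index=False)


if __name__ == "__main__":
    main()
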