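"""Simulate the hybrid-parent triad experiment.

Generates the study design this project analyses: genotypes M (maternal),
H (hybrid) and P (paternal) sampled at six days-after-pollination time
points (2-4 and 8-10 DAP) with 3 biological replicates, ~20,000 genes with
negative-binomial counts, and a known 13-way expression-pattern class per
gene per time point. Writes the count matrix, sample sheet, gene lengths
and truth table under results/sim/.
"""

from pathlib import Path

from triadexpress.matrix import write_matrix
from triadexpress.simulate import (TriadSimSpec, simulate_experiment,
                                   write_gene_lengths, write_truth)

OUT = Path(__file__).resolve().parent.parent / "results" / "sim"
DAPS = (2, 3, 4, 8, 9, 10)
SEED = 20240915


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = TriadSimSpec(n_genes=20_000, seed=SEED)
    counts, truth = simulate_experiment(spec, daps=DAPS)
    write_matrix(counts, OUT / "counts.tsv", OUT / "sample_sheet.tsv")
    write_truth(truth, OUT / "sim_truth.tsv")
    write_gene_lengths(truth.loc[~truth.index.duplicated()],
                       OUT / "gene_lengths.tsv")
    share = (truth.category.value_counts(normalize=True) * 100).round(2)
    print(f"simulated {spec.n_genes} genes x {len(DAPS)} DAP x 3 genotypes "
          f"x {spec.n_reps} replicates (seed {SEED})")
    print("generating category shares (%):")
    print(share.to_string())
    print(f"wrote counts/truth to {OUT}")


if __name__ == "__main__":
    main()
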