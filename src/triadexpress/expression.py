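"""FPKM normalization, replicate averaging and correlation, expressed-gene
calling, and multi-set (Venn) overlap accounting.

Conventions
-----------
* FPKM[g, s] = counts[g, s] * 1e9 / (length_bp[g] * total_counts[s]).
* A gene counts as *expressed* in a (genotype, DAP) group when its replicate
  mean is at or above a threshold (default 1.0 FPKM).
* Replicate agreement is summarized as the mean pairwise squared Pearson
  correlation, by default on log2(x + 1) values because raw FPKM
  correlations are dominated by a handful of very high expressors.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix
from .utils import pct

logger = logging.getLogger(__name__)


def fpkm(counts: ExpressionMatrix, gene_lengths: pd.Series | dict) -> ExpressionMatrix:
    """Length- and depth-normalize a count matrix to FPKM."""
    if counts.unit != "counts":
        raise ValueError(f"fpkm() expects a count matrix, got unit={counts.unit!r}")
    lengths = pd.Series(gene_lengths, dtype=float)
    missing = counts.gene_ids.difference(lengths.index)
    if len(missing):
        raise ValueError(f"missing gene length for {missing[0]!r} "
                         f"({len(missing)} genes total)")
    lengths = lengths.loc[counts.gene_ids]
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0][0]
        raise ValueError(f"nonpositive length for gene {bad!r}")
    totals = counts.values.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0][0]
        raise ValueError(f"sample {bad!r} has zero total counts")
    vals = counts.values * 1e9
    vals = vals.div(lengths, axis=0).div(totals, axis=1)
    return ExpressionMatrix(values=vals, samples=counts.samples, unit="fpkm")


def mean_replicates(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Collapse replicate columns to one arithmetic-mean column per
    (genotype, DAP) group, named ``{genotype}_d{dap}``."""
    cols = {}
    meta = []
    for genotype, dap in matrix.groups():
        name = f"{genotype}_d{dap}"
        cols[name] = matrix.group_values(genotype, dap).mean(axis=1)
        meta.append({"sample_id": name, "genotype": genotype, "dap": dap, "replicate": 0})
    values = pd.DataFrame(cols, index=matrix.gene_ids)
    samples = pd.DataFrame(meta).set_index("sample_id")
    return ExpressionMatrix(values=values, samples=samples, unit=matrix.unit)


def replicate_r2(matrix: ExpressionMatrix, log: bool = True) -> tuple[pd.Series, float]:
    """Mean pairwise squared Pearson correlation between replicates.

    Returns a per-(genotype, dap) Series of mean R² over all replicate pairs
    plus the grand mean over groups. Pairs where either replicate is
    constant (undefined correlation) are excluded with a warning.
    """
    if matrix.n_genes < 2:
        raise ValueError("need >= 2 genes to correlate replicates")
    out = {}
    for genotype, dap in matrix.groups():
        block = matrix.group_values(genotype, dap).to_numpy(dtype=float)
        if block.shape[1] < 2:
            raise ValueError(f"group ({genotype}, {dap}) has < 2 replicates")
        if log:
            block = np.log2(block + 1.0)
        r2s = []
        for i, j in itertools.combinations(range(block.shape[1]), 2):
            x, y = block[:, i], block[:, j]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                logger.warning(
                    "constant replicate in group (%s, %s): pair (%d, %d) "
                    "excluded from R^2", genotype, dap, i, j)
                continue
            r = np.corrcoef(x, y)[0, 1]
            r2s.append(r * r)
        out[(genotype, dap)] = float(np.mean(r2s)) if r2s else np.nan
    series = pd.Series(out)
    series.index.names = ["genotype", "dap"]
    return series, float(series.mean())


def expressed_genes(matrix: ExpressionMatrix, genotype: str, dap: int,
                    threshold: float = 1.0) -> set[str]:
    """Genes whose replicate-mean expression is >= threshold in the group;
    with threshold 0, genes with any nonzero signal."""
    means = matrix.group_values(genotype, dap).mean(axis=1)
    if threshold == 0:
        return set(means.index[means > 0])
    return set(means.index[means >= threshold])


@dataclass
class GeneSetOverlap:
    """Exact Venn decomposition of a family of labelled gene sets.

    ``region_counts`` maps each nonempty membership pattern (a frozenset of
    labels) to the number of genes belonging to exactly those sets.
    ``overlap_fraction`` is 100 * core / per-set total, to 2 decimals.
    """

    labels: list[str]
    region_counts: dict[frozenset, int]
    totals: dict[str, int]
    core_count: int
    overlap_fraction: dict[str, float] = field(default_factory=dict)

    def union_size(self) -> int:
        return sum(self.region_counts.values())


def overlap(sets: dict[str, set]) -> GeneSetOverlap:
    """Venn region counts, core intersection, and per-set core fractions."""
    if len(sets) < 2:
        raise ValueError("need >= 2 sets")
    labels = list(sets)
    universe = set().union(*sets.values())
    regions: dict[frozenset, int] = {}
    for gene in universe:
        pattern = frozenset(lab for lab in labels if gene in sets[lab])
        regions[pattern] = regions.get(pattern, 0) + 1
    core = regions.get(frozenset(labels), 0)
    totals = {lab: len(sets[lab]) for lab in labels}
    fractions = {lab: pct(core, totals[lab]) if totals[lab] else float("nan")
                 for lab in labels}
    return GeneSetOverlap(labels=labels, region_counts=regions, totals=totals,
                          core_count=core, overlap_fraction=fractions)


def overlap_to_frame(ov: GeneSetOverlap) -> pd.DataFrame:
    """Tabular form of a Venn decomposition (one row per region)."""
    rows = [{"region": "&".join(sorted(pat)), "count": n}
            for pat, n in sorted(ov.region_counts.items(),
                                 key=lambda kv: (len(kv[0]), sorted(kv[0])))]
    return pd.DataFrame(rows)
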