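"""Pairwise per-gene differential expression between two genotypes.

The per-gene test is a two-sided pooled-variance (Student) t-test on
log2(x + 1)-transformed replicate values — with 3 replicates per group the
pooled t is exactly sized, whereas estimating separate variances is
markedly conservative at such small n; p-values are Benjamini–Hochberg adjusted across genes,
and a gene is called differential when |fold change| >= 2 (inclusive) and
adjusted p < 0.05 (strict). Fold change is computed on replicate means with
a pseudo-count of 1 in numerator and denominator.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix
from .utils import pct, ttest_p

logger = logging.getLogger(__name__)

PSEUDOCOUNT = 1.0


def gene_test(values_a, values_b) -> float:
    """Two-sided pooled-variance t p-value on log2(x + 1) values for one gene.

    Both groups constant gives p = 1 if equal, p = 0 if unequal (the
    degenerate-variance rule: zero observed noise makes any difference
    certain).
    """
    a = np.log2(np.asarray(values_a, dtype=float) + 1.0)
    b = np.log2(np.asarray(values_b, dtype=float) + 1.0)
    p = ttest_p(a, b, equal_var=True)
    if p == 0.0:
        logger.debug("degenerate-variance rule: constant unequal groups, p=0")
    return p


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _vectorized_p(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pooled-variance t p-values per row of two replicate blocks, on log2(x+1)."""
    la = np.log2(a + 1.0)
    lb = np.log2(b + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(la, lb, axis=1, equal_var=True)
        p = np.asarray(res.pvalue, dtype=float)
    # degenerate rows: both groups constant
    degenerate = (np.ptp(la, axis=1) == 0) & (np.ptp(lb, axis=1) == 0)
    if degenerate.any():
        equal = la[:, 0] == lb[:, 0]
        p[degenerate & equal] = 1.0
        p[degenerate & ~equal] = 0.0
        n_zero = int((degenerate & ~equal).sum())
        if n_zero:
            logger.info("degenerate-variance rule applied to %d genes "
                        "(constant unequal groups, p=0)", n_zero)
    return p


def deg_table(matrix: ExpressionMatrix, genotype_a: str, genotype_b: str,
              dap: int, fc_threshold: float = 2.0, alpha: float = 0.05,
              pseudocount: float = PSEUDOCOUNT) -> pd.DataFrame:
    """Full differential table for contrast b vs a at one time point.

    Columns: mean_a, mean_b, log2fc = log2((mean_b + eps)/(mean_a + eps)),
    p_raw, p_adj, call in {up, down, ns} (direction of b relative to a).
    """
    a = matrix.group_values(genotype_a, dap).to_numpy(dtype=float)
    b = matrix.group_values(genotype_b, dap).to_numpy(dtype=float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("need >= 2 replicates per genotype")
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    log2fc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))
    p_raw = _vectorized_p(a, b)
    p_adj = bh_fdr(p_raw)
    out = pd.DataFrame({
        "mean_a": mean_a, "mean_b": mean_b, "log2fc": log2fc,
        "p_raw": p_raw, "p_adj": p_adj,
    }, index=matrix.gene_ids)
    out.attrs["contrast"] = f"{genotype_a}_vs_{genotype_b}, dap={dap}"
    return call_degs(out, fc_threshold=fc_threshold, alpha=alpha)


def call_degs(deg: pd.DataFrame, fc_threshold: float = 2.0,
              alpha: float = 0.05) -> pd.DataFrame:
    """Direction calls: up if log2fc >= log2(fc_threshold) and p_adj < alpha,
    down for the mirror image, otherwise ns. FC bound inclusive, alpha strict."""
    lfc_cut = np.log2(fc_threshold)
    sig = deg["p_adj"].to_numpy() < alpha
    lfc = deg["log2fc"].to_numpy()
    call = np.where(sig & (lfc >= lfc_cut), "up",
                    np.where(sig & (lfc <= -lfc_cut), "down", "ns"))
    out = deg.copy()
    out["call"] = call
    return out


def updown_summary(deg: pd.DataFrame) -> dict:
    """Counts and 2-decimal percentages of up/down calls among all DEGs;
    percentages are None when there are no DEGs."""
    n_up = int((deg["call"] == "up").sum())
    n_down = int((deg["call"] == "down").sum())
    total = n_up + n_down
    return {
        "n_up": n_up,
        "n_down": n_down,
        "n_total_deg": total,
        "pct_up": pct(n_up, total) if total else None,
        "pct_down": pct(n_down, total) if total else None,
    }


def write_deg_table(deg: pd.DataFrame, path: str) -> None:
    with open(path, "w") as fh:
        contrast = deg.attrs.get("contrast", "unknown")
        fh.write(f"# contrast: {contrast}\n")
        deg.to_csv(fh, sep="\t", index_label="gene_id")
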