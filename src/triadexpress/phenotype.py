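"""Phenotype-side heterosis statistics.

Mid-parent values, hybrid-vs-mid-parent significance, relative growth
rates, seed-coat cell density, and qPCR 2^-ddCt relative expression
(Livak method).
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .utils import welch_p

TRAITS = ("seed_coat_area_mm2", "kernel_weight_g", "cell_density_per_0.1mm2")


def mid_parent_value(m_value: float, p_value: float) -> float:
    """Arithmetic mean of the two parental values — the additive
    expectation for the hybrid."""
    return (m_value + p_value) / 2.0


def relative_growth_rate(series: pd.DataFrame, genotype: str | None = None,
                         method: str = "ratio") -> pd.Series:
    """Day-over-day relative growth rate of a trait's per-DAP mean.

    ``method="ratio"`` gives RGR(t) = (x̄_t − x̄_{t−1}) / x̄_{t−1};
    ``method="log"`` gives the classical log-difference
    RGR(t) = ln x̄_t − ln x̄_{t−1}. Entries with a zero previous mean are
    NaN. Input is a long table with columns genotype, dap, value.
    """
    if method not in ("ratio", "log"):
        raise ValueError(f"unknown RGR method: {method!r}")
    df = series if genotype is None else series[series["genotype"] == genotype]
    means = df.groupby("dap")["value"].mean().sort_index()
    if len(means) < 2:
        raise ValueError("need >= 2 DAP values")
    prev = means.shift(1)
    with np.errstate(divide="ignore", invalid="ignore"):
        if method == "ratio":
            rgr = (means - prev) / prev
        else:
            rgr = np.log(means) - np.log(prev)
    rgr[prev == 0] = np.nan
    return rgr.iloc[1:]


def mpv_significance(h_values, m_values, p_values, max_pairs: int = 200,
                     seed: int = 0) -> float:
    """Two-sided test of hybrid replicates against a pseudo-mid-parent
    sample built from all parental pairs {(m_i + p_j)/2}, capped at
    ``max_pairs`` seeded random pairs; Welch t with the degenerate-variance
    rule."""
    h = np.asarray(h_values, dtype=float)
    m = np.asarray(m_values, dtype=float)
    p = np.asarray(p_values, dtype=float)
    if h.size < 2 or m.size < 2 or p.size < 2:
        raise ValueError("need >= 2 replicates for hybrid and each parent")
    pairs = np.array(list(itertools.product(m, p)))
    mpv = pairs.mean(axis=1)
    if mpv.size > max_pairs:
        rng = np.random.default_rng(seed)
        mpv = rng.choice(mpv, size=max_pairs, replace=False)
    return welch_p(h, mpv)


def cell_density(cell_count: float, area_mm2: float) -> float:
    """Cells per 0.1 mm² of seed-coat section."""
    if area_mm2 <= 0:
        raise ValueError("area must be > 0")
    return cell_count / (area_mm2 / 0.1)


def ddct_relative_expression(ct: pd.DataFrame, calibrator_group: str,
                             group_col: str = "genotype") -> pd.DataFrame:
    """Livak 2^-ddCt relative expression per (gene, group).

    Input columns: gene_id, ``group_col``, replicate, ct_target,
    ct_reference. dCt = ct_target − ct_reference per replicate; ddCt =
    mean dCt(group) − mean dCt(calibrator); relative expression = 2^-ddCt
    (the calibrator group is 1 by construction).
    """
    required = {"gene_id", group_col, "ct_target", "ct_reference"}
    missing = required - set(ct.columns)
    if missing:
        raise ValueError(f"Ct table lacks columns: {sorted(missing)}")
    if (ct[["ct_target", "ct_reference"]] <= 0).any().any() or \
            not np.isfinite(ct[["ct_target", "ct_reference"]]).all().all():
        raise ValueError("Ct values must be positive and finite")
    work = ct.copy()
    work["dct"] = work["ct_target"] - work["ct_reference"]
    mean_dct = work.groupby(["gene_id", group_col])["dct"].mean()
    rows = []
    for gene, sub in mean_dct.groupby(level="gene_id"):
        sub = sub.droplevel("gene_id")
        if calibrator_group not in sub.index:
            raise ValueError(f"calibrator group {calibrator_group!r} missing "
                             f"for gene {gene!r}")
        ddct = sub - sub.loc[calibrator_group]
        for group, v in ddct.items():
            rows.append({"gene_id": gene, group_col: group,
                         "ddct": float(v),
                         "relative_expression": float(2.0 ** -v)})
    return pd.DataFrame(rows)


def mpv_table(series: pd.DataFrame) -> pd.DataFrame:
    """Per-DAP genotype means, mid-parent value, and hybrid/MPV ratio for a
    long phenotype table (genotype, dap, value)."""
    means = series.pivot_table(index="dap", columns="genotype",
                               values="value", aggfunc="mean")
    out = pd.DataFrame(index=means.index)
    for g in ("M", "H", "P"):
        if g in means:
            out[f"mean_{g}"] = means[g]
    out["mpv"] = (out["mean_M"] + out["mean_P"]) / 2.0
    out["hybrid_over_mpv"] = out["mean_H"] / out["mpv"]
    return out
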