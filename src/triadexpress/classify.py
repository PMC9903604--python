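"""Thirteen-way hybrid–parent expression-pattern classification.

Every gene in a hybrid–parent triad is assigned one of 13 classes from the
signed outcomes of its three pairwise differential contrasts (M vs P,
H vs M, H vs P), then aggregated into five categories and a three-way
high-/mid-/low-parent summary.

Categories and their defining relations (H hybrid, M maternal, P paternal):

* ``additive`` — H at the arithmetic mid-parent, H ≈ (M + P) / 2; three
  classes: parents equal (conserved) or H strictly between unequal parents
  (two directions).
* ``ELD_M`` / ``ELD_P`` — expression-level dominance: H statistically
  indistinguishable from one parent while the parents differ; two classes
  each by which parent is higher.
* ``transgressive_up`` / ``transgressive_down`` — H above both parents /
  below both parents; three classes each by the parental relation
  (M > P, M = P, M < P).

Non-significance of a contrast is accepted as ≈ (no second equivalence
test is applied). Signed-call combinations that match none of the idealized
patterns (e.g. M ≈ P but H differs from exactly one parent, or M ≠ P while
H is indistinguishable from both — a dominance call needs the far parent's
contrast to be significant, or parent relabelling would not map ELD_M onto
ELD_P) are resolved by the distance fallback: the category whose idealized hybrid position
(mid-parent for additive, the matched parent for dominance) is closest to
the observed hybrid mean, with ties awarded to additive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

# canonical class table: id -> (label, category, parent_level)
CLASS_TABLE: dict[int, tuple[str, str, str]] = {
    1: ("trans_up_MgtP", "transgressive_up", "high_parent"),
    2: ("trans_up_MeqP", "transgressive_up", "high_parent"),
    3: ("trans_up_MltP", "transgressive_up", "high_parent"),
    4: ("trans_down_MgtP", "transgressive_down", "low_parent"),
    5: ("trans_down_MeqP", "transgressive_down", "low_parent"),
    6: ("trans_down_MltP", "transgressive_down", "low_parent"),
    7: ("eld_m_MgtP", "ELD_M", "high_parent"),
    8: ("eld_m_MltP", "ELD_M", "low_parent"),
    9: ("eld_p_PgtM", "ELD_P", "high_parent"),
    10: ("eld_p_PltM", "ELD_P", "low_parent"),
    11: ("add_int_MgtP", "additive", "mid_parent"),
    12: ("add_int_MltP", "additive", "mid_parent"),
    13: ("add_conserved", "additive", "mid_parent"),
}

CLASS_LABELS: tuple[str, ...] = tuple(v[0] for v in CLASS_TABLE.values())
CATEGORIES: tuple[str, ...] = ("additive", "ELD_M", "ELD_P",
                               "transgressive_up", "transgressive_down")
PARENT_LEVELS: tuple[str, ...] = ("high_parent", "mid_parent", "low_parent")

LABEL_TO_ID: dict[str, int] = {v[0]: k for k, v in CLASS_TABLE.items()}
LABEL_TO_CATEGORY: dict[str, str] = {v[0]: v[1] for v in CLASS_TABLE.values()}

_S_MP = ("M>P", "M<P", "ns")
_S_MH = ("H>M", "H<M", "ns")
_S_PH = ("H>P", "H<P", "ns")


def classify_gene(s_mp: str, s_mh: str, s_ph: str,
                  mu_M: float, mu_H: float, mu_P: float) -> tuple[int, str]:
    """Assign (class_id, category) from three signed calls and triad means.

    The decision table is evaluated in priority order: transgressive up,
    transgressive down, ELD_M, ELD_P, additive-intermediate,
    additive-conserved, then the distance fallback.
    """
    if s_mp not in _S_MP:
        raise ValueError(f"malformed M vs P call: {s_mp!r}")
    if s_mh not in _S_MH:
        raise ValueError(f"malformed H vs M call: {s_mh!r}")
    if s_ph not in _S_PH:
        raise ValueError(f"malformed H vs P call: {s_ph!r}")

    if s_mh == "H>M" and s_ph == "H>P":
        cid = {"M>P": 1, "ns": 2, "M<P": 3}[s_mp]
    elif s_mh == "H<M" and s_ph == "H<P":
        cid = {"M>P": 4, "ns": 5, "M<P": 6}[s_mp]
    elif s_mp != "ns" and s_mh == "ns" and s_ph != "ns":
        cid = 7 if s_mp == "M>P" else 8
    elif s_mp != "ns" and s_ph == "ns" and s_mh != "ns":
        cid = 9 if s_mp == "M<P" else 10
    elif s_mp == "M>P" and s_mh == "H<M" and s_ph == "H>P":
        cid = 11
    elif s_mp == "M<P" and s_mh == "H>M" and s_ph == "H<P":
        cid = 12
    elif s_mp == "ns" and s_mh == "ns" and s_ph == "ns":
        cid = 13
    else:
        cid = _fallback_class(s_mp, mu_M, mu_H, mu_P)
    return cid, CLASS_TABLE[cid][1]


def _fallback_class(s_mp: str, mu_M: float, mu_H: float, mu_P: float) -> int:
    # distance of the hybrid mean to each category's idealized position;
    # ties go to additive, then ELD_M, then ELD_P
    d_add = abs(mu_H - (mu_M + mu_P) / 2.0)
    d_m = abs(mu_H - mu_M)
    d_p = abs(mu_H - mu_P)
    best = min(d_add, d_m, d_p)
    if d_add == best:
        if s_mp == "M>P":
            return 11
        if s_mp == "M<P":
            return 12
        return 13
    if d_m == best:
        return 7 if mu_M > mu_P else 8
    return 9 if mu_P > mu_M else 10


def _signed_calls(deg_mp: pd.DataFrame, deg_mh: pd.DataFrame,
                  deg_ph: pd.DataFrame) -> pd.DataFrame:
    """Map three DEG tables to signed call symbols.

    Orientation convention: each table's ``call`` is b relative to a with
    contrasts (a=P, b=M), (a=M, b=H), (a=P, b=H), so ``up`` means M>P, H>M
    and H>P respectively.
    """
    s_mp = deg_mp["call"].map({"up": "M>P", "down": "M<P", "ns": "ns"})
    s_mh = deg_mh["call"].map({"up": "H>M", "down": "H<M", "ns": "ns"})
    s_ph = deg_ph["call"].map({"up": "H>P", "down": "H<P", "ns": "ns"})
    return pd.DataFrame({"s_mp": s_mp, "s_mh": s_mh, "s_ph": s_ph})


def classify_matrix(deg_mp: pd.DataFrame, deg_mh: pd.DataFrame,
                    deg_ph: pd.DataFrame, means: pd.DataFrame) -> pd.DataFrame:
    """Classify every gene of a triad at one time point.

    Parameters
    ----------
    deg_mp, deg_mh, deg_ph
        DEG tables (indexed by gene id, with a ``call`` column) for the
        M-vs-P, H-vs-M and H-vs-P contrasts, oriented as in
        :func:`_signed_calls`.
    means
        DataFrame indexed by gene id with columns ``mu_M``, ``mu_H``,
        ``mu_P`` (replicate-mean expression).

    Returns
    -------
    DataFrame indexed by gene id with the three signed calls, class_id,
    class_label, category, parent_level and the three means.
    """
    idx = deg_mp.index
    for other, name in ((deg_mh, "H vs M"), (deg_ph, "H vs P"), (means, "means")):
        diff = idx.symmetric_difference(other.index)
        if len(diff):
            raise ValueError(
                f"gene universe mismatch with {name} table: "
                f"{len(diff)} genes differ")
    calls = _signed_calls(deg_mp, deg_mh.loc[idx], deg_ph.loc[idx])
    mu = means.loc[idx]
    out = []
    for gene in idx:
        cid, cat = classify_gene(
            calls.at[gene, "s_mp"], calls.at[gene, "s_mh"], calls.at[gene, "s_ph"],
            mu.at[gene, "mu_M"], mu.at[gene, "mu_H"], mu.at[gene, "mu_P"])
        out.append(cid)
    table = calls.copy()
    table["class_id"] = out
    table["class_label"] = [CLASS_TABLE[c][0] for c in out]
    table["category"] = [CLASS_TABLE[c][1] for c in out]
    table["parent_level"] = [CLASS_TABLE[c][2] for c in out]
    table[["mu_M", "mu_H", "mu_P"]] = mu[["mu_M", "mu_H", "mu_P"]]
    return table


def class_summary(table: pd.DataFrame) -> dict:
    """Per-class and per-category counts with half-up 2-decimal percentages
    of all classified genes."""
    from .utils import pct

    if len(table) == 0:
        raise ValueError("empty classification table")
    total = len(table)
    per_class = (table["class_id"].value_counts()
                 .reindex(range(1, 14), fill_value=0).sort_index())
    per_class = pd.DataFrame({
        "class_label": [CLASS_TABLE[c][0] for c in per_class.index],
        "category": [CLASS_TABLE[c][1] for c in per_class.index],
        "count": per_class.values,
    }, index=per_class.index.rename("class_id"))
    per_cat = (table["category"].value_counts()
               .reindex(CATEGORIES, fill_value=0))
    per_cat = pd.DataFrame({
        "count": per_cat.values,
        "pct": [pct(n, total) for n in per_cat.values],
    }, index=per_cat.index.rename("category"))
    return {"per_class": per_class, "per_category": per_cat, "total": total}


def parent_level_summary(table: pd.DataFrame) -> dict[str, int]:
    """Counts of the high-/mid-/low-parent three-way summary.

    Mid-parent collects the additive classes; high-parent collects
    transgressive up plus dominance classes matching the higher-expressed
    parent; low-parent the mirror image.
    """
    counts = table["parent_level"].value_counts()
    return {lvl: int(counts.get(lvl, 0)) for lvl in PARENT_LEVELS}


@dataclass
class RecoveryReport:
    confusion: pd.DataFrame          # truth categories × predicted categories
    accuracy: float
    sensitivity: pd.Series           # per truth category


def class_recovery(truth: pd.DataFrame, predicted: pd.DataFrame) -> RecoveryReport:
    """Score predicted categories against simulation truth (same genes)."""
    diff = truth.index.symmetric_difference(predicted.index)
    if len(diff):
        raise ValueError(f"gene universe mismatch: {len(diff)} genes differ")
    t = truth.loc[predicted.index, "category"]
    p = predicted["category"]
    confusion = pd.crosstab(t, p).reindex(index=CATEGORIES, columns=CATEGORIES,
                                          fill_value=0)
    confusion.index.name = "truth"
    confusion.columns.name = "predicted"
    total = confusion.to_numpy().sum()
    accuracy = float(np.trace(confusion.to_numpy()) / total)
    row_sums = confusion.sum(axis=1)
    sensitivity = pd.Series(
        np.where(row_sums > 0, np.diag(confusion.to_numpy()) / row_sums.replace(0, 1), np.nan),
        index=confusion.index, name="sensitivity")
    return RecoveryReport(confusion=confusion, accuracy=accuracy,
                          sensitivity=sensitivity)
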