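"""Negative-binomial hybrid–parent triad simulator with known truth.

Emulates the study design this pipeline targets: three genotypes
(maternal line M, hybrid H, paternal line P) sampled at several days after
pollination (DAP) with 3 biological replicates each, ~20k expressed genes,
and a class structure dominated by additive expression (~85%) with ~13%
expression-level dominance and <1% transgressive genes.

The generative model: each gene draws a 13-way pattern class and a
log-normal baseline expression level; the class fixes the three genotype
mean expression levels exactly (additive classes put the hybrid at the
arithmetic mid-parent, dominance classes at the matched parent,
transgressive classes beyond the more extreme parent); expected fragment
counts are proportional to mean expression × gene length, scaled to the
library size; observed counts are negative-binomial with
var = mu + dispersion * mu^2 (Poisson when dispersion = 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .classify import CLASS_LABELS, LABEL_TO_CATEGORY, LABEL_TO_ID
from .matrix import ExpressionMatrix

# default class mixture: the composition observed in a maize seed-coat
# hybrid-parent triad at 3 DAP (direction variants within a category are
# arbitrary; category totals are what matters)
DEFAULT_CLASS_PROPORTIONS: dict[str, float] = {
    "add_conserved": 17045,
    "add_int_MgtP": 1075,
    "add_int_MltP": 1594,
    "eld_m_MgtP": 622,
    "eld_m_MltP": 790,
    "eld_p_PgtM": 1385,
    "eld_p_PltM": 529,
    "trans_up_MgtP": 15,
    "trans_up_MeqP": 3,
    "trans_up_MltP": 4,
    "trans_down_MgtP": 70,
    "trans_down_MeqP": 12,
    "trans_down_MltP": 0,
}


@dataclass
class TriadSimSpec:
    """Parameters of one simulated triad experiment.

    Attributes
    ----------
    n_genes : int
        Number of simulated genes.
    n_reps : int
        Biological replicates per genotype per time point (study design: 3).
    class_proportions : dict
        Nonnegative weight per 13-way class label; renormalized internally.
    baseline_log_mean, baseline_log_sd : float
        Natural-log mean and sd of the log-normal baseline expression level
        (arbitrary relative units; only ratios matter after normalization).
    effect_log2 : float
        log2 separation between "different" genotype means (>= 0).
    dispersion : float
        NB dispersion phi, var = mu + phi * mu^2; 0 gives Poisson counts.
    library_size : float
        Expected total fragment count per sample.
    library_jitter : float
        Per-sample uniform jitter fraction of library size (0 = uniform
        depth); exists to exercise depth normalization.
    gene_length_range : (int, int)
        Inclusive bp interval for simulated gene lengths.
    seed : int
        RNG seed; identical spec + seed gives bit-identical output.
    """

    n_genes: int = 20_000
    n_reps: int = 3
    class_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS))
    baseline_log_mean: float = 3.0
    baseline_log_sd: float = 1.5
    effect_log2: float = 3.0
    dispersion: float = 0.08
    library_size: float = 2e7
    library_jitter: float = 0.0
    gene_length_range: tuple[int, int] = (500, 5000)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.effect_log2 < 0:
            raise ValueError("effect_log2 must be >= 0")
        if not (0 <= self.library_jitter < 1):
            raise ValueError("library_jitter must be in [0, 1)")
        unknown = set(self.class_proportions) - set(CLASS_LABELS)
        if unknown:
            raise ValueError(f"unknown class labels: {sorted(unknown)}")
        total = sum(self.class_proportions.values())
        if total <= 0 or any(w < 0 for w in self.class_proportions.values()):
            raise ValueError("class_proportions must be nonnegative with a "
                             "positive sum")
        lo, hi = self.gene_length_range
        if lo <= 0 or hi < lo:
            raise ValueError("gene_length_range must be a positive interval")


def assign_class_means(baseline: float, class_label: str,
                       effect_log2: float) -> tuple[float, float, float]:
    """Idealized (mu_M, mu_H, mu_P) for one gene of a given pattern class.

    Parents that differ are placed symmetrically effect_log2 log2-units
    apart around the baseline; equal parents sit at the baseline. The
    hybrid goes to the arithmetic mid-parent (additive), to the matched
    parent (dominance), or a further effect_log2 beyond the more extreme
    parent (transgressive).
    """
    if baseline <= 0:
        raise ValueError("baseline must be > 0")
    if class_label not in LABEL_TO_ID:
        raise ValueError(f"unknown class label: {class_label!r}")
    if effect_log2 < 0:
        raise ValueError("effect_log2 must be >= 0")

    half = 2.0 ** (effect_log2 / 2.0)
    if class_label.endswith("MgtP"):
        mu_m, mu_p = baseline * half, baseline / half
    elif class_label.endswith("MltP") or class_label == "eld_p_PgtM":
        mu_m, mu_p = baseline / half, baseline * half
    elif class_label == "eld_p_PltM":
        mu_m, mu_p = baseline * half, baseline / half
    else:  # MeqP variants and add_conserved
        mu_m = mu_p = baseline

    if class_label.startswith("trans_up"):
        mu_h = max(mu_m, mu_p) * 2.0 ** effect_log2
    elif class_label.startswith("trans_down"):
        mu_h = min(mu_m, mu_p) / 2.0 ** effect_log2
    elif class_label.startswith("eld_m"):
        mu_h = mu_m
    elif class_label.startswith("eld_p"):
        mu_h = mu_p
    else:  # additive
        mu_h = (mu_m + mu_p) / 2.0
    return mu_m, mu_h, mu_p


def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: float) -> np.ndarray:
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_triad_counts(spec: TriadSimSpec, dap: int = 3
                          ) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate one triad time point: a count matrix plus per-gene truth.

    Returns the count :class:`ExpressionMatrix` (columns
    ``{genotype}_d{dap}_r{rep}``) and a truth DataFrame indexed by gene id
    with class_label, class_id, category, the three true mean expression
    levels and gene_length_bp. With ``effect_log2 == 0`` every class
    collapses to identical genotype means, so all genes are labelled
    additive-conserved.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genes = [f"gene{i:06d}" for i in range(spec.n_genes)]

    labels_pool = list(CLASS_LABELS)
    weights = np.array([spec.class_proportions.get(l, 0.0) for l in labels_pool],
                       dtype=float)
    weights /= weights.sum()
    labels = np.array(labels_pool)[
        rng.choice(len(labels_pool), size=spec.n_genes, p=weights)]
    if spec.effect_log2 == 0:
        # zero effect collapses every pattern onto one mean per gene
        labels = np.full(spec.n_genes, "add_conserved")

    baselines = rng.lognormal(spec.baseline_log_mean, spec.baseline_log_sd,
                              size=spec.n_genes)
    lo, hi = spec.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=spec.n_genes)

    mu = np.empty((spec.n_genes, 3))
    for i, (b, lab) in enumerate(zip(baselines, labels)):
        mu[i] = assign_class_means(b, lab, spec.effect_log2)

    truth = pd.DataFrame({
        "class_label": labels,
        "class_id": [LABEL_TO_ID[l] for l in labels],
        "category": [LABEL_TO_CATEGORY[l] for l in labels],
        "mu_M": mu[:, 0], "mu_H": mu[:, 1], "mu_P": mu[:, 2],
        "gene_length_bp": lengths,
    }, index=pd.Index(genes, name="gene_id"))

    cols: dict[str, np.ndarray] = {}
    meta = []
    for k, genotype in enumerate(("M", "H", "P")):
        # expected counts: abundance x length shares of the library
        w = mu[:, k] * lengths if spec.n_genes else np.array([])
        share = w / w.sum() if spec.n_genes else w
        for rep in range(1, spec.n_reps + 1):
            lib = spec.library_size
            if spec.library_jitter:
                lib *= rng.uniform(1 - spec.library_jitter,
                                   1 + spec.library_jitter)
            sid = f"{genotype}_d{dap}_r{rep}"
            cols[sid] = _nb_draw(rng, share * lib, spec.dispersion)
            meta.append({"sample_id": sid, "genotype": genotype,
                         "dap": dap, "replicate": rep})
    values = pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"),
                          dtype=float)
    samples = pd.DataFrame(meta).set_index("sample_id")
    matrix = ExpressionMatrix(values=values, samples=samples, unit="counts")
    return matrix, truth


def simulate_experiment(spec: TriadSimSpec, daps: tuple[int, ...] = (3, 8)
                        ) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate several independent time points and concatenate them.

    Each DAP is an independent draw (classes re-drawn per DAP) from a child
    seed of ``spec.seed``; the truth table gains a ``dap`` column.
    """
    spec.validate()
    seeds = np.random.SeedSequence(spec.seed).spawn(len(daps))
    mats, truths = [], []
    for dap, ss in zip(daps, seeds):
        child = replace(spec, seed=int(ss.generate_state(1)[0] % (2**31)))
        m, t = simulate_triad_counts(child, dap=dap)
        t = t.copy()
        t["dap"] = dap
        mats.append(m)
        truths.append(t)
    values = pd.concat([m.values for m in mats], axis=1)
    samples = pd.concat([m.samples for m in mats], axis=0)
    truth = pd.concat(truths, axis=0, keys=None)
    return ExpressionMatrix(values=values, samples=samples, unit="counts"), truth


# ---------------------------------------------------------------------------
# phenotype simulation

DEFAULT_GROWTH_PARAMS: dict[str, tuple[float, float, float]] = {
    # (asymptote K in mm^2, rate r per day, inflection t0 in DAP) —
    # logistic seed-coat-area-like trajectories: the hybrid starts below the
    # mid-parent value, crosses it around 7 DAP and diverges above it
    # afterwards (heterosis emerging at late DAP)
    "M": (95.0, 0.55, 6.0),
    "H": (110.0, 0.60, 7.5),
    "P": (75.0, 0.55, 6.5),
}


def simulate_phenotype_series(
    growth_params: dict[str, tuple[float, float, float]] | None = None,
    noise_sd: float = 2.0,
    seed: int = 0,
    daps: tuple[int, ...] = tuple(range(16)),
    n_reps: int = 20,
    trait: str = "seed_coat_area_mm2",
) -> pd.DataFrame:
    """Logistic trait trajectories per genotype with Gaussian replicate noise.

    Returns a long DataFrame (genotype, dap, replicate, trait, value);
    values are truncated at 0. With ``noise_sd = 0`` values lie exactly on
    the logistic curve K / (1 + exp(-r (t - t0))).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if list(daps) != sorted(set(daps)):
        raise ValueError("DAP grid must be strictly increasing")
    params = growth_params or DEFAULT_GROWTH_PARAMS
    rng = np.random.default_rng(seed)
    rows = []
    for genotype, (K, r, t0) in params.items():
        for dap in daps:
            mean = K / (1.0 + np.exp(-r * (dap - t0)))
            vals = np.maximum(mean + rng.normal(0, noise_sd, size=n_reps), 0.0)
            for rep, v in enumerate(vals, start=1):
                rows.append({"genotype": genotype, "dap": int(dap),
                             "replicate": rep, "trait": trait,
                             "value": float(v)})
    return pd.DataFrame(rows)


def write_truth(truth: pd.DataFrame, path: str) -> None:
    truth.to_csv(path, sep="\t", index_label="gene_id")


def write_gene_lengths(truth: pd.DataFrame, path: str) -> None:
    truth[["gene_length_bp"]].rename(columns={"gene_length_bp": "length_bp"}) \
        .to_csv(path, sep="\t", index_label="gene_id")
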