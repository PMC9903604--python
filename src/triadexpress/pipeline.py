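"""End-to-end pipeline: simulate (or load) → FPKM → DEG → classify →
summarize → phenotype, with a TSV report bundle.

Each stage writes plain TSVs that the next stage (and the CLI subcommands)
can read back, so stages are independently runnable and the whole bundle is
deterministic given config + seed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classify import classify_matrix, class_summary, parent_level_summary, class_recovery
from .differential import deg_table, updown_summary, write_deg_table
from .expression import (expressed_genes, fpkm, mean_replicates, overlap,
                         overlap_to_frame, replicate_r2)
from .matrix import ExpressionMatrix, read_gene_lengths, read_matrix, write_matrix
from .phenotype import mpv_significance, mpv_table, relative_growth_rate
from .simulate import (TriadSimSpec, simulate_experiment,
                       simulate_phenotype_series, write_gene_lengths, write_truth)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Flat configuration of the whole pipeline (YAML-compatible)."""

    # input paths (all optional when simulation is enabled)
    matrix_path: str | None = None
    sample_sheet_path: str | None = None
    gene_lengths_path: str | None = None
    phenotype_path: str | None = None

    # thresholds
    expressed_fpkm: float = 1.0
    fc_threshold: float = 2.0
    alpha: float = 0.05

    # focal time points for DEG + classification
    focal_daps: tuple[int, ...] = (3, 8)

    # simulation
    simulate: bool = True
    sim: TriadSimSpec = field(default_factory=TriadSimSpec)
    sim_daps: tuple[int, ...] = (3, 8)
    simulate_phenotype: bool = True
    phenotype_noise_sd: float = 2.0
    phenotype_reps: int = 20

    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.fc_threshold <= 0 or self.expressed_fpkm < 0:
            raise ValueError("thresholds must be positive")
        if not self.simulate and (self.matrix_path is None
                                  or self.sample_sheet_path is None):
            raise ValueError("either enable simulation or provide matrix_path "
                             "and sample_sheet_path")
        self.sim.validate()

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_keys = {f.name for f in dataclasses.fields(TriadSimSpec)}
        cfg_keys = {f.name for f in dataclasses.fields(cls)} - {"sim"}
        sim_kwargs, cfg_kwargs = {}, {}
        for key, value in raw.items():
            if key.startswith("sim_") and key[4:] in sim_keys:
                sim_kwargs[key[4:]] = value
            elif key in cfg_keys:
                if key in ("focal_daps", "sim_daps"):
                    value = tuple(value)
                cfg_kwargs[key] = value
            else:
                raise ValueError(f"unknown config key: {key!r}")
        if "gene_length_range" in sim_kwargs:
            sim_kwargs["gene_length_range"] = tuple(sim_kwargs["gene_length_range"])
        cfg = cls(sim=TriadSimSpec(**sim_kwargs), **cfg_kwargs)
        cfg.sim.seed = cfg.seed
        return cfg


def _stage(name):
    """Tag any stage failure with the stage name."""
    class _StageCtx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    return _StageCtx()


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run the full pipeline and write the report bundle under ``outdir``.

    Returns a dict of the in-memory results (matrices, DEG tables,
    classification tables, summaries, phenotype stats).
    """
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    with _stage("input"):
        if config.simulate:
            counts, truth = simulate_experiment(config.sim, daps=config.sim_daps)
            lengths = truth.loc[~truth.index.duplicated(), "gene_length_bp"]
            write_matrix(counts, out / "counts.tsv", out / "sample_sheet.tsv")
            write_truth(truth, out / "sim_truth.tsv")
            write_gene_lengths(truth.loc[~truth.index.duplicated()],
                               out / "gene_lengths.tsv")
            results["truth"] = truth
        else:
            counts = read_matrix(config.matrix_path, config.sample_sheet_path)
            if config.gene_lengths_path is None:
                raise ValueError("gene_lengths_path required for FPKM")
            lengths = read_gene_lengths(config.gene_lengths_path)
        results["counts"] = counts

    with _stage("normalize"):
        fpkm_matrix = fpkm(counts, lengths)
        results["fpkm"] = fpkm_matrix
        per_group_r2, grand_r2 = replicate_r2(fpkm_matrix)
        results["replicate_r2"] = (per_group_r2, grand_r2)
        per_group_r2.rename("mean_pairwise_r2").to_frame().assign(
            grand_mean=grand_r2).to_csv(out / "replicate_r2.tsv", sep="\t")
        means = mean_replicates(fpkm_matrix)
        results["means"] = means
        write_matrix(means, out / "fpkm_means.tsv")

    with _stage("expressed_overlap"):
        daps = sorted({d for _, d in fpkm_matrix.groups()})
        overlaps = {}
        for genotype in ("M", "H", "P"):
            sets = {f"dap{d}": expressed_genes(fpkm_matrix, genotype, d,
                                               config.expressed_fpkm)
                    for d in daps}
            if len(sets) >= 2:
                ov = overlap(sets)
                overlaps[genotype] = ov
                frame = overlap_to_frame(ov)
                frame.to_csv(out / f"overlap_{genotype}.tsv", sep="\t",
                             index=False)
        results["overlaps"] = overlaps

    deg_results: dict = {}
    classifications: dict = {}
    summaries: dict = {}
    with _stage("differential"):
        for dap in config.focal_daps:
            # orientation: call 'up' means M>P, H>M, H>P respectively
            degs = {
                "mp": deg_table(fpkm_matrix, "P", "M", dap,
                                config.fc_threshold, config.alpha),
                "mh": deg_table(fpkm_matrix, "M", "H", dap,
                                config.fc_threshold, config.alpha),
                "ph": deg_table(fpkm_matrix, "P", "H", dap,
                                config.fc_threshold, config.alpha),
            }
            for key, tab in degs.items():
                write_deg_table(tab, out / f"deg_{key}_dap{dap}.tsv")
            deg_results[dap] = degs
            ud = {key: updown_summary(tab) for key, tab in degs.items()}
            pd.DataFrame(ud).T.to_csv(out / f"updown_dap{dap}.tsv", sep="\t",
                                      index_label="contrast")
            results.setdefault("updown", {})[dap] = ud
    results["deg"] = deg_results

    with _stage("classify"):
        for dap in config.focal_daps:
            # classification universe: genes expressed in all three genotypes
            universe = set.intersection(*[
                expressed_genes(fpkm_matrix, g, dap, config.expressed_fpkm)
                for g in ("M", "H", "P")])
            idx = [g for g in fpkm_matrix.gene_ids if g in universe]
            degs = deg_results[dap]
            mu = pd.DataFrame({
                "mu_M": means.values[f"M_d{dap}"],
                "mu_H": means.values[f"H_d{dap}"],
                "mu_P": means.values[f"P_d{dap}"],
            })
            table = classify_matrix(degs["mp"].loc[idx], degs["mh"].loc[idx],
                                    degs["ph"].loc[idx], mu.loc[idx])
            classifications[dap] = table
            table.to_csv(out / f"classification_dap{dap}.tsv", sep="\t",
                         index_label="gene_id")
            summ = class_summary(table)
            summ["parent_level"] = parent_level_summary(table)
            summaries[dap] = summ
            summ["per_category"].to_csv(out / f"category_summary_dap{dap}.tsv",
                                        sep="\t")
            pd.Series(summ["parent_level"]).rename("count").to_csv(
                out / f"parent_level_dap{dap}.tsv", sep="\t",
                index_label="parent_level")
    results["classification"] = classifications
    results["summaries"] = summaries
    render_table1(summaries).to_csv(out / "pattern_table.tsv", sep="\t")

    if config.simulate:
        with _stage("recovery"):
            recov = {}
            for dap in config.focal_daps:
                t = results["truth"]
                t_dap = t[t["dap"] == dap]
                pred = classifications[dap]
                recov[dap] = class_recovery(t_dap.loc[pred.index], pred)
                recov[dap].confusion.to_csv(out / f"recovery_dap{dap}.tsv",
                                            sep="\t")
            results["recovery"] = recov

    with _stage("phenotype"):
        if config.phenotype_path is not None:
            pheno = pd.read_csv(config.phenotype_path, sep="\t")
        elif config.simulate_phenotype:
            pheno = simulate_phenotype_series(
                noise_sd=config.phenotype_noise_sd, seed=config.seed,
                n_reps=config.phenotype_reps)
            pheno.to_csv(out / "phenotype.tsv", sep="\t", index=False)
        else:
            pheno = None
        if pheno is not None:
            mpv = mpv_table(pheno)
            rgr = pd.DataFrame({g: relative_growth_rate(pheno, g)
                                for g in ("M", "H", "P")})
            sig = {}
            for dap in sorted(pheno["dap"].unique()):
                sub = pheno[pheno["dap"] == dap]
                sig[dap] = mpv_significance(
                    sub.loc[sub.genotype == "H", "value"],
                    sub.loc[sub.genotype == "M", "value"],
                    sub.loc[sub.genotype == "P", "value"],
                    seed=config.seed)
            mpv["p_h_vs_mpv"] = pd.Series(sig)
            mpv.to_csv(out / "phenotype_mpv.tsv", sep="\t", index_label="dap")
            rgr.to_csv(out / "phenotype_rgr.tsv", sep="\t", index_label="dap")
            results["phenotype"] = {"series": pheno, "mpv": mpv, "rgr": rgr}

    with _stage("log"):
        with open(out / "run_log.txt", "w") as fh:
            fh.write(f"triadexpress {__version__}\n")
            fh.write(f"seed: {config.seed}\n")
            fh.write(f"alpha: {config.alpha}  fc_threshold: {config.fc_threshold}  "
                     f"expressed_fpkm: {config.expressed_fpkm}\n")
            fh.write(f"focal_daps: {list(config.focal_daps)}\n")
            fh.write(f"simulate: {config.simulate}\n")
            if config.simulate:
                fh.write(f"sim: {config.sim}\n")
    return results


def render_table1(summaries: dict[int, dict]) -> pd.DataFrame:
    """Category-layout pattern table: one row pair (count, %) per DAP with
    additive / ELD_M / ELD_P / transgressive columns and the total."""
    rows = []
    for dap, summ in sorted(summaries.items()):
        cat = summ["per_category"]
        row_n = {"dap": dap, "row": "count"}
        row_p = {"dap": dap, "row": "pct"}
        for category in cat.index:
            row_n[category] = int(cat.loc[category, "count"])
            row_p[category] = cat.loc[category, "pct"]
        row_n["total"] = summ["total"]
        row_p["total"] = float(sum(cat["pct"]))
        rows.append(row_n)
        rows.append(row_p)
    if not rows:
        return pd.DataFrame()
    return pd.DataFrame(rows).set_index(["dap", "row"])
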