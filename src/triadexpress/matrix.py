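"""Gene × sample expression matrix container and TSV/CSV I/O.

The central in-memory object is :class:`ExpressionMatrix`: a nonnegative
numeric gene × sample table (counts or FPKM) tied to a sample sheet that
records, for every column, the genotype (maternal line ``M``, hybrid ``H``
or paternal line ``P``), the sampling time in days after pollination (DAP)
and the biological replicate number.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GENOTYPES = ("M", "H", "P")

SAMPLE_SHEET_COLUMNS = ("sample_id", "genotype", "dap", "replicate")


def _sep_for(path: str) -> str:
    return "," if str(path).endswith(".csv") else "\t"


@dataclass
class ExpressionMatrix:
    """Gene × sample matrix plus per-sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample id. All
        entries must be finite and >= 0.
    samples
        DataFrame indexed by sample id with columns ``genotype``, ``dap``
        and ``replicate``, covering every column of ``values``.
    unit
        Measurement unit of ``values``: ``"counts"`` or ``"fpkm"``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    unit: str = "counts"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate gene id: {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if not np.isfinite(arr).all():
            raise ValueError("expression values must be finite")
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative value at gene {self.values.index[g]!r}, "
                f"sample {self.values.columns[s]!r}"
            )
        missing = set(self.values.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples missing from sample sheet: {sorted(missing)}")
        for col in ("genotype", "dap", "replicate"):
            if col not in self.samples.columns:
                raise ValueError(f"sample sheet lacks column {col!r}")
        bad = set(self.samples["genotype"]) - set(GENOTYPES)
        if bad:
            raise ValueError(f"unknown genotype labels: {sorted(bad)}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def group_columns(self, genotype: str, dap: int) -> list[str]:
        """Sample ids of the replicate columns for one (genotype, DAP) group."""
        meta = self.samples.loc[list(self.values.columns)]
        mask = (meta["genotype"] == genotype) & (meta["dap"] == dap)
        return list(meta.index[mask])

    def groups(self) -> list[tuple[str, int]]:
        """All (genotype, dap) groups present, in sample-sheet order."""
        meta = self.samples.loc[list(self.values.columns)]
        seen: list[tuple[str, int]] = []
        for g, d in zip(meta["genotype"], meta["dap"]):
            if (g, int(d)) not in seen:
                seen.append((g, int(d)))
        return seen

    def group_values(self, genotype: str, dap: int) -> pd.DataFrame:
        cols = self.group_columns(genotype, dap)
        if not cols:
            raise ValueError(f"no samples for genotype={genotype!r}, dap={dap}")
        return self.values[cols]


def read_sample_sheet(path: str) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep=_sep_for(path))
    missing = set(SAMPLE_SHEET_COLUMNS) - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet lacks columns: {sorted(missing)}")
    if sheet["sample_id"].duplicated().any():
        dup = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample id in sheet: {dup!r}")
    sheet = sheet.set_index("sample_id")
    sheet["dap"] = sheet["dap"].astype(int)
    sheet["replicate"] = sheet["replicate"].astype(int)
    return sheet


def read_matrix(path: str, sample_sheet_path: str, unit: str = "counts") -> ExpressionMatrix:
    """Read a gene × sample TSV/CSV (first column = gene id) and its sample sheet."""
    values = pd.read_csv(path, sep=_sep_for(path), index_col=0, comment="#")
    samples = read_sample_sheet(sample_sheet_path)
    return ExpressionMatrix(values=values, samples=samples, unit=unit)


def write_matrix(matrix: ExpressionMatrix, path: str, sample_sheet_path: str | None = None) -> None:
    matrix.values.to_csv(path, sep=_sep_for(path), index_label="gene_id")
    if sample_sheet_path is not None:
        matrix.samples.to_csv(sample_sheet_path, sep=_sep_for(sample_sheet_path), index_label="sample_id")


def read_gene_lengths(path: str) -> pd.Series:
    """Read a two-column gene-length table (gene_id, length_bp)."""
    df = pd.read_csv(path, sep=_sep_for(path))
    if "gene_id" not in df.columns or "length_bp" not in df.columns:
        raise ValueError("gene length table needs columns gene_id, length_bp")
    return df.set_index("gene_id")["length_bp"]
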