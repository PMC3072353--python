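"""Readers, writers and validated containers for the pipeline's file formats.

Formats are deliberately plain text:

* expression matrix — TSV, genes in rows, samples in columns, log10 ratios
  versus a common reference RNA;
* phenotype labels — two-column TSV (``sample_id``, ``status``) with status
  coded 1 for RB1-positive and 0 for RB1-negative;
* qPCR cycle-threshold table — CSV with header
  ``sample_id,gene,replicate,ct``;
* gene sets — GMT (tab-separated: name, description, members...).

All validation is performed at construction time; a malformed file raises a
typed error from :mod:`rbratio.errors` and never a silently coerced object.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    FormatError,
    ParseError,
    RangeError,
    StructureError,
    ValidationError,
)

__all__ = [
    "ExpressionMatrix",
    "PhenotypeLabels",
    "CtTable",
    "GeneSet",
    "GeneSetCollection",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_labels",
    "write_labels",
    "read_ct_table",
    "write_ct_table",
    "read_gene_sets",
    "write_gene_sets",
    "load_cell_line_panel",
    "load_cell_line_labels",
]


def _find_duplicate(ids: Sequence[str]) -> str | None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            return i
        seen.add(i)
    return None


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples grid of log10 expression ratios.

    Values are dimensionless base-10 logarithms of each gene's expression
    relative to a common reference RNA, so any sample-wide loading term is
    a per-column additive constant.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray  # shape (n_genes, n_samples), float64

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        dup = _find_duplicate(self.gene_ids)
        if dup is not None:
            raise ValidationError(f"duplicate gene id: {dup!r}")
        dup = _find_duplicate(self.sample_ids)
        if dup is not None:
            raise ValidationError(f"duplicate sample id: {dup!r}")
        if len(self.gene_ids) < 1:
            raise ValidationError("matrix needs at least 1 gene")
        if len(self.sample_ids) < 2:
            raise ValidationError("matrix needs at least 2 samples")
        if values.ndim != 2 or values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(values)):
            g, s = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite value at gene {self.gene_ids[g]!r}, sample {self.sample_ids[s]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise ValidationError(f"gene {gene_id!r} not in matrix") from None

    def gene_values(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_index(gene_id)]

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(gene_ids)
        rows = [self.gene_index(g) for g in ids]
        return ExpressionMatrix(tuple(ids), self.sample_ids, self.values[rows])

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(sample_ids)
        try:
            cols = [self.sample_ids.index(s) for s in ids]
        except ValueError as exc:
            raise ValidationError(f"sample not in matrix: {exc}") from None
        return ExpressionMatrix(self.gene_ids, tuple(ids), self.values[:, cols])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.gene_ids), columns=list(self.sample_ids))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.values, other.values)
        )


@dataclass(frozen=True)
class PhenotypeLabels:
    """Per-sample binary RB1 functional status: 1 positive, 0 negative."""

    status: Mapping[str, int]

    def __post_init__(self) -> None:
        clean: dict[str, int] = {}
        for sid, code in dict(self.status).items():
            sid = str(sid)
            if isinstance(code, bool) or code not in (0, 1):
                raise ValidationError(
                    f"status for sample {sid!r} must be 0 or 1, got {code!r}"
                )
            clean[sid] = int(code)
        if not clean:
            raise ValidationError("labels are empty")
        object.__setattr__(self, "status", clean)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.status)

    def __getitem__(self, sample_id: str) -> int:
        try:
            return self.status[sample_id]
        except KeyError:
            raise ValidationError(f"sample {sample_id!r} has no phenotype label") from None

    def __len__(self) -> int:
        return len(self.status)

    def vector(self, sample_ids: Sequence[str]) -> np.ndarray:
        """0/1 label vector aligned to ``sample_ids``."""
        return np.array([self[s] for s in sample_ids], dtype=float)

    def n_positive(self) -> int:
        return sum(self.status.values())

    def n_negative(self) -> int:
        return len(self.status) - self.n_positive()

    def flipped(self) -> "PhenotypeLabels":
        return PhenotypeLabels({s: 1 - c for s, c in self.status.items()})


@dataclass(frozen=True)
class CtTable:
    """qPCR cycle-threshold records: (sample, gene, replicate, ct).

    Ct is the PCR cycle at which fluorescence crosses the instrument
    threshold; admissible values are (0, 50) cycles (a 50-cycle run never
    crossing is a failed well, not a measurement).
    """

    records: pd.DataFrame  # columns: sample_id, gene, replicate, ct

    REQUIRED = ("sample_id", "gene", "replicate", "ct")

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise StructureError(f"Ct table missing column(s): {', '.join(missing)}")
        df = df.loc[:, list(self.REQUIRED)].copy()
        df["sample_id"] = df["sample_id"].astype(str)
        df["gene"] = df["gene"].astype(str)
        try:
            df["replicate"] = df["replicate"].astype(int)
            df["ct"] = df["ct"].astype(float)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"Ct table has a non-numeric replicate or ct field: {exc}") from None
        bad = df[~np.isfinite(df["ct"]) | (df["ct"] <= 0) | (df["ct"] >= 50)]
        if not bad.empty:
            row = bad.iloc[0]
            raise RangeError(
                f"ct {row['ct']} for sample {row['sample_id']!r} gene {row['gene']!r} "
                "outside (0, 50) cycles"
            )
        if (df["replicate"] < 1).any():
            raise ValidationError("replicate indices must be >= 1")
        dup = df.duplicated(subset=["sample_id", "gene", "replicate"])
        if dup.any():
            row = df[dup].iloc[0]
            raise ValidationError(
                f"duplicate replicate {row['replicate']} for sample "
                f"{row['sample_id']!r} gene {row['gene']!r}"
            )
        object.__setattr__(self, "records", df.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.records)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.records["sample_id"]))

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.records["gene"]))

    def replicates(self, sample_id: str, gene: str) -> np.ndarray:
        """Replicate Ct values for one (sample, gene), in replicate order."""
        sub = self.records[
            (self.records["sample_id"] == sample_id) & (self.records["gene"] == gene)
        ].sort_values("replicate")
        return sub["ct"].to_numpy()


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        members = tuple(dict.fromkeys(self.members))  # de-duplicate, keep order
        if not members:
            raise ValidationError(f"gene set {self.name!r} is empty")
        object.__setattr__(self, "members", members)

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class GeneSetCollection:
    sets: tuple[GeneSet, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sets", tuple(self.sets))
        dup = _find_duplicate([s.name for s in self.sets])
        if dup is not None:
            raise ValidationError(f"duplicate gene-set name: {dup!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)


# ---------------------------------------------------------------------------
# expression matrix TSV

def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a genes-in-rows TSV: header row of sample ids, first column gene ids.

    Errors carry coordinates: a non-numeric cell raises :class:`ParseError`
    naming the gene row and sample column; ragged rows raise
    :class:`StructureError`; duplicate ids raise :class:`ValidationError`.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise StructureError(f"{path}: empty file") from None
        if len(header) < 3:
            raise StructureError(f"{path}: header must list at least 2 samples")
        sample_ids = header[1:]
        gene_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise StructureError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(row)}"
                )
            gene_ids.append(row[0])
            parsed: list[float] = []
            for col, cell in enumerate(row[1:]):
                try:
                    parsed.append(float(cell))
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: non-numeric value {cell!r} for gene "
                        f"{row[0]!r}, sample {sample_ids[col]!r}"
                    ) from None
            rows.append(parsed)
    if not rows:
        raise StructureError(f"{path}: no gene rows")
    return ExpressionMatrix(tuple(gene_ids), tuple(sample_ids), np.array(rows, dtype=float))


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["gene_id", *matrix.sample_ids])
        for gid, row in zip(matrix.gene_ids, matrix.values):
            writer.writerow([gid, *(repr(float(v)) for v in row)])


# ---------------------------------------------------------------------------
# phenotype labels TSV

def read_labels(path: str | Path) -> PhenotypeLabels:
    path = Path(path)
    status: dict[str, int] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or len(header) < 2:
            raise StructureError(f"{path}: expected header 'sample_id<TAB>status'")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) < 2:
                raise StructureError(f"{path}:{lineno}: expected 2 fields")
            sid = row[0]
            if sid in status:
                raise ValidationError(f"{path}:{lineno}: duplicate sample id {sid!r}")
            try:
                code = int(row[1])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: status {row[1]!r} is not an integer") from None
            status[sid] = code
    return PhenotypeLabels(status)


def write_labels(labels: PhenotypeLabels, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        fh.write("sample_id\tstatus\n")
        for sid, code in labels.status.items():
            fh.write(f"{sid}\t{code}\n")


# ---------------------------------------------------------------------------
# Ct CSV

def read_ct_table(path: str | Path) -> CtTable:
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"sample_id": str, "gene": str})
    except pd.errors.EmptyDataError:
        raise StructureError(f"{path}: empty file") from None
    return CtTable(df)


def write_ct_table(table: CtTable, path: str | Path) -> None:
    table.records.to_csv(Path(path), index=False)


# ---------------------------------------------------------------------------
# GMT gene sets

def read_gene_sets(path: str | Path) -> GeneSetCollection:
    path = Path(path)
    sets: list[GeneSet] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 member"
                )
            sets.append(GeneSet(fields[0], fields[1], tuple(fields[2:])))
    return GeneSetCollection(tuple(sets))


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *s.members]) + "\n")


# ---------------------------------------------------------------------------
# bundled reference panel

def load_cell_line_panel() -> pd.DataFrame:
    """The 30-cell-line reference panel used to derive the RB1 signature.

    Columns: ``cell_line``, ``tissue``, ``rb1_genetic_status``,
    ``rb1_functional_status`` ('+' or '-', from the CDKN2A/E2F reporter
    assay).
    """
    with resources.files("rbratio.data").joinpath("cell_line_panel.tsv").open(
        encoding="utf-8"
    ) as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    expected = {"cell_line", "tissue", "rb1_genetic_status", "rb1_functional_status"}
    if set(df.columns) != expected:
        raise StructureError("bundled cell-line panel has unexpected columns")
    if not df["rb1_functional_status"].isin(["+", "-"]).all():
        raise ValidationError("functional status must be '+' or '-'")
    return df


def load_cell_line_labels() -> PhenotypeLabels:
    """Reference-panel phenotype labels (1 = RB1-positive, 0 = RB1-negative)."""
    df = load_cell_line_panel()
    return PhenotypeLabels(
        {
            row.cell_line: 1 if row.rb1_functional_status == "+" else 0
            for row in df.itertuples()
        }
    )
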