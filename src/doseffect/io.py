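"""Readers, writers and validated containers for the tabular formats the pipeline touches.

All downstream modules consume the types defined here; no raw file handles
escape this module. Matrices and annotation are tab-separated text with a
header row; gene sets use the GMT convention. Reading is gzip-transparent
(any path ending in ``.gz`` is decompressed on the fly by pandas).

Copy numbers are on the linear scale with diploid = 2 throughout. Missing
copy-number cells (a gene with no informative marker) are encoded as NaN,
never as 0 or 2. Coordinates are 1-based and inclusive at both ends.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

ROLE_EXPRESSION = "expression"
ROLE_COPY_NUMBER = "copy_number"
_ROLES = (ROLE_EXPRESSION, ROLE_COPY_NUMBER)

_NA_STRINGS = {"", "NA", "NaN", "nan", "na", "NULL"}


class ValidationError(ValueError):
    """Raised when an input file or in-memory container violates its contract."""


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt", encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def normalize_chromosome(label: str) -> str:
    """Map 'chr13'/'Chr13'/'13' to the bare label '13' ('X', 'Y' kept as-is)."""
    label = str(label).strip()
    if label.lower().startswith("chr"):
        label = label[3:]
    if not label:
        raise ValidationError("empty chromosome label")
    return label


@dataclass
class OmicsMatrix:
    """A genes x samples matrix of real values, tagged by what it measures.

    Parameters
    ----------
    role : {"expression", "copy_number"}
        Expression matrices must be complete; copy-number matrices may
        contain NaN for genes without an informative marker in a sample.
    data : pandas.DataFrame
        Rows indexed by gene symbol, columns by sample id, float values.
    """

    role: str
    data: pd.DataFrame

    def __post_init__(self):
        self.validate()

    # -- container surface -------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def validate(self) -> None:
        if self.role not in _ROLES:
            raise ValidationError(
                f"unknown matrix role {self.role!r}; expected one of {_ROLES}"
            )
        if self.data.shape[0] == 0 or self.data.shape[1] == 0:
            raise ValidationError("matrix has no rows or no columns")
        dup_samples = self.data.columns[self.data.columns.duplicated()]
        if len(dup_samples):
            raise ValidationError(
                f"duplicate sample id(s): {sorted(set(map(str, dup_samples)))}"
            )
        if self.data.index.duplicated().any():
            dups = sorted(set(self.data.index[self.data.index.duplicated()].map(str)))
            # duplicates are legal pre-collapse; preprocess.collapse_to_genes
            # resolves them, so only flag here
            warnings.warn(
                f"matrix contains {len(dups)} duplicated gene id(s) "
                f"(e.g. {dups[:3]}); collapse before analysis",
                stacklevel=2,
            )
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("matrix values must be numeric")
        if self.role == ROLE_EXPRESSION:
            if np.isnan(values).any():
                gene = self.data.index[np.isnan(values).any(axis=1)][0]
                raise ValidationError(
                    f"expression matrix contains missing values (e.g. gene {gene!r})"
                )
        else:
            present = values[~np.isnan(values)]
            if present.size == 0:
                warnings.warn("copy-number matrix is entirely missing", stacklevel=2)
                return
            if (present <= 0).any():
                raise ValidationError(
                    "copy-number values must be positive on the linear scale "
                    "(diploid = 2)"
                )
            if np.median(present) < 1.0:
                raise ValidationError(
                    "overall median copy number < 1: input looks like log-ratios; "
                    "supply linear copy numbers with diploid = 2"
                )

    def subset(self, genes=None, samples=None) -> "OmicsMatrix":
        data = self.data
        if genes is not None:
            data = data.loc[list(genes)]
        if samples is not None:
            data = data[list(samples)]
        return OmicsMatrix(self.role, data)


@dataclass
class GeneAnnotation:
    """Genomic location per gene symbol.

    ``table`` is indexed by gene symbol with columns ``chromosome`` (bare
    label, e.g. "13"), ``tx_start`` and ``tx_end`` (1-based inclusive bp).
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        required = {"chromosome", "tx_start", "tx_end"}
        missing = required - set(t.columns)
        if missing:
            raise ValidationError(f"annotation missing column(s): {sorted(missing)}")
        if t.index.duplicated().any():
            dups = sorted(set(t.index[t.index.duplicated()].map(str)))
            raise ValidationError(f"duplicate gene symbol(s) in annotation: {dups[:5]}")
        starts = t["tx_start"].to_numpy()
        ends = t["tx_end"].to_numpy()
        if not (np.issubdtype(starts.dtype, np.integer) and np.issubdtype(ends.dtype, np.integer)):
            raise ValidationError("annotation coordinates must be integers")
        if (starts <= 0).any() or (ends <= 0).any():
            raise ValidationError("annotation coordinates must be positive")
        bad = t.index[starts > ends]
        if len(bad):
            raise ValidationError(
                f"tx_start > tx_end for gene(s): {sorted(map(str, bad))[:5]}"
            )

    @property
    def gene_symbols(self) -> list[str]:
        return list(self.table.index)

    def chromosome_of(self) -> pd.Series:
        return self.table["chromosome"]

    def midpoints(self) -> pd.Series:
        return (self.table["tx_start"] + self.table["tx_end"]) / 2.0

    def subset(self, genes: Iterable[str]) -> "GeneAnnotation":
        return GeneAnnotation(self.table.loc[list(genes)].copy())


@dataclass
class SnpCopyNumberTable:
    """Marker-level copy numbers: one row per SNP, one CN column per sample."""

    info: pd.DataFrame  # index snp_id; columns chromosome, position
    values: pd.DataFrame  # index snp_id; columns sample ids

    def __post_init__(self):
        if self.info.index.duplicated().any():
            dups = sorted(set(self.info.index[self.info.index.duplicated()].map(str)))
            raise ValidationError(f"duplicate snp_id(s): {dups[:5]}")
        if not self.info.index.equals(self.values.index):
            raise ValidationError("SNP info and value rows disagree")
        pos = self.info["position"].to_numpy()
        if not np.issubdtype(pos.dtype, np.integer) or (pos <= 0).any():
            raise ValidationError("SNP positions must be positive integers")
        if self.values.columns.duplicated().any():
            raise ValidationError("duplicate sample id(s) in SNP table")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class GeneSetCollection:
    """Named, non-empty sets of gene symbols (GMT semantics)."""

    sets: dict[str, frozenset] = field(default_factory=dict)

    def __post_init__(self):
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self):
        return len(self.sets)

    def __getitem__(self, name):
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_table_lines(path):
    """Return (header_fields, n_leading_skipped) after '#' comments/blank lines."""
    skipped = 0
    with _open_text(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                skipped += 1
                continue
            return line.rstrip("\n").split("\t"), skipped
    raise ValidationError(f"{path}: empty file")


def read_matrix(path, role: str) -> OmicsMatrix:
    """Read a genes x samples TSV (header = sample ids, first column = gene ids).

    Duplicate gene rows are tolerated (flagged, collapsed later); duplicate
    sample ids, non-numeric expression cells and empty files are errors,
    reported with a line number where possible.
    """
    header, skipped = _read_table_lines(path)
    samples = header[1:]
    if len(samples) == 0:
        raise ValidationError(f"{path}: header has no sample columns")
    seen: dict[str, int] = {}
    for s in samples:
        if s in seen:
            raise ValidationError(
                f"{path}: duplicate sample id {s!r} in header (line {skipped + 1})"
            )
        seen[s] = 1
    raw = pd.read_csv(
        path, sep="\t", comment="#", index_col=0, dtype=str, keep_default_na=False
    )
    if raw.shape[0] == 0:
        raise ValidationError(f"{path}: no data rows")
    data = raw.apply(lambda col: pd.to_numeric(col.where(~col.isin(_NA_STRINGS)), errors="coerce"))
    bad = data.isna() & ~raw.isin(_NA_STRINGS)
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        line = skipped + 1 + r + 1  # comments + header + 1-based data row
        raise ValidationError(
            f"{path}: non-numeric value {raw.iat[r, c]!r} for gene "
            f"{raw.index[r]!r}, sample {raw.columns[c]!r} (line {line})"
        )
    data.index = data.index.astype(str)
    data.index.name = "gene"
    return OmicsMatrix(role, data)


def write_matrix(matrix: OmicsMatrix, path, metadata: Mapping[str, object] | None = None) -> None:
    """Write a matrix as TSV, with optional '# key=value' metadata header lines."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if metadata:
            for key, value in metadata.items():
                fh.write(f"# {key}={value}\n")
        matrix.data.to_csv(fh, sep="\t", index_label="gene", na_rep="NA")


def read_gene_annotation(path) -> GeneAnnotation:
    """Read a BED-like TSV: gene symbol, chromosome, tx start, tx end.

    Accepts both 'chr13' and '13' chromosome dialects (normalized to bare
    labels) and tolerates an optional header line.
    """
    first, skipped = _read_table_lines(path)
    if len(first) < 4:
        raise ValidationError(f"{path}: annotation needs 4 columns, got {len(first)}")

    def _is_int(s):
        try:
            int(s)
            return True
        except ValueError:
            return False

    # a header line has non-numeric text in BOTH coordinate columns
    has_header = not _is_int(first[2]) and not _is_int(first[3])
    raw = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=0 if has_header else None,
        dtype=str,
        keep_default_na=False,
    )
    raw = raw.iloc[:, :4]
    raw.columns = ["gene", "chromosome", "tx_start", "tx_end"]
    for col in ("tx_start", "tx_end"):
        converted = pd.to_numeric(raw[col], errors="coerce")
        if converted.isna().any():
            i = int(np.argmax(converted.isna().to_numpy()))
            raise ValidationError(
                f"{path}: non-integer coordinate {raw[col].iloc[i]!r} for gene "
                f"{raw['gene'].iloc[i]!r}"
            )
        if (converted != converted.astype(int)).any():
            raise ValidationError(f"{path}: fractional coordinate in column {col}")
        raw[col] = converted.astype(int)
    raw["chromosome"] = raw["chromosome"].map(normalize_chromosome)
    table = raw.set_index("gene")
    return GeneAnnotation(table)


def write_gene_annotation(annotation: GeneAnnotation, path) -> None:
    annotation.table.to_csv(path, sep="\t", index_label="gene")


def read_snp_table(path) -> SnpCopyNumberTable:
    """Read a SNP copy-number TSV: snp_id, chromosome, position, then one
    linear-scale CN column per sample."""
    header, _ = _read_table_lines(path)
    if len(header) < 4:
        raise ValidationError(f"{path}: SNP table needs >= 4 columns")
    raw = pd.read_csv(path, sep="\t", comment="#", dtype={0: str, 1: str})
    raw.columns = ["snp_id", "chromosome", "position"] + list(raw.columns[3:])
    raw["chromosome"] = raw["chromosome"].map(normalize_chromosome)
    raw["position"] = raw["position"].astype(int)
    raw = raw.set_index("snp_id")
    info = raw[["chromosome", "position"]]
    values = raw.drop(columns=["chromosome", "position"]).astype(float)
    return SnpCopyNumberTable(info, values)


def read_gene_sets(path) -> GeneSetCollection:
    """Read a GMT file: per line, set name, description, then member genes."""
    sets: dict[str, frozenset] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}: line {lineno} has {len(fields)} field(s); "
                    "GMT needs name, description and >= 1 member"
                )
            name = fields[0]
            if name in sets:
                raise ValidationError(f"{path}: duplicate set name {name!r} (line {lineno})")
            members = frozenset(m for m in fields[2:] if m)
            if not members:
                raise ValidationError(f"{path}: set {name!r} has no members (line {lineno})")
            sets[name] = members
    if not sets:
        raise ValidationError(f"{path}: empty GMT file")
    return GeneSetCollection(sets)
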