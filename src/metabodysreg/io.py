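"""Readers and writers for on-disk artifacts.

All tabular artifacts are tab-separated text.  Expression matrices are
genes x samples with gene symbols in the first column; gene sets use the
GMT convention (one set per line: id, description, then member genes).
Missing values are serialized as the literal token ``NA`` so that every
table round-trips unambiguously.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NA_TOKEN = "NA"
#: printf-style format that round-trips IEEE doubles through text
FLOAT_FORMAT = "%.17g"

CONDITIONS = ("tumor", "normal")


class FormatError(ValueError):
    """Raised when an on-disk artifact violates its format contract."""


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------

def validate_expression(values: pd.DataFrame) -> pd.DataFrame:
    """Validate a genes x samples expression frame.

    Gene symbols are the index, sample identifiers the columns.  Values
    must be finite, numeric and non-negative; identifiers must be unique.
    """
    if values.index.has_duplicates:
        dupes = values.index[values.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate gene symbol(s): {', '.join(map(str, dupes))}")
    if values.columns.has_duplicates:
        dupes = values.columns[values.columns.duplicated()].unique().tolist()
        raise FormatError(f"duplicate sample id(s): {', '.join(map(str, dupes))}")
    try:
        arr = values.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric expression value: {exc}") from exc
    if np.isnan(arr).any():
        gene = values.index[np.isnan(arr).any(axis=1)][0]
        raise FormatError(f"missing expression value for gene {gene!r}")
    if not np.isfinite(arr).all():
        raise FormatError("non-finite expression value")
    if (arr < 0).any():
        gene = values.index[(arr < 0).any(axis=1)][0]
        raise FormatError(f"negative expression value for gene {gene!r}")
    out = pd.DataFrame(arr, index=values.index.astype(str), columns=values.columns.astype(str))
    out.index.name = "gene_id"
    return out


def read_expression(path: str | Path, aggregate: bool = False) -> pd.DataFrame:
    """Read a genes x samples expression matrix from TSV.

    Parameters
    ----------
    path
        Tab-separated file; first column gene symbols, header row sample ids.
    aggregate
        Collapse duplicated gene symbols by element-wise mean instead of
        raising an error.
    """
    path = Path(path)
    df = _read_rectangular(path)
    if df.shape[1] < 1:
        raise FormatError(f"{path}: expression matrix has no sample columns")
    df = df.apply(pd.to_numeric, errors="coerce")
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)][0]
        raise FormatError(f"{path}: non-numeric or missing value in row {bad!r}")
    if df.index.has_duplicates:
        if aggregate:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            logger.warning("%s: aggregating duplicated gene symbols by mean: %s", path, dupes)
            df = df.groupby(level=0, sort=False).mean()
        else:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(
                f"{path}: duplicate gene symbol(s): {', '.join(dupes)} "
                "(pass aggregate=True / --aggregate to collapse by mean)"
            )
    return validate_expression(df)


def write_expression(values: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(values, path, index_label="gene_id")


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleSheet:
    """Sample -> condition/cohort(/subtype) assignments for a study.

    ``frame`` is indexed by sample_id with columns ``condition``
    (tumor/normal), ``cohort`` and optional ``subtype``.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        frame = self.frame
        if frame.index.has_duplicates:
            dupes = frame.index[frame.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample id(s): {', '.join(map(str, dupes))}")
        bad = set(frame["condition"]) - set(CONDITIONS)
        if bad:
            raise FormatError(
                f"unknown condition token(s) {sorted(bad)}; accepted: {list(CONDITIONS)}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def cohorts(self) -> list[str]:
        return sorted(self.frame["cohort"].unique())

    def cohort_samples(self, cohort: str, condition: str | None = None) -> list[str]:
        sel = self.frame["cohort"] == cohort
        if condition is not None:
            sel &= self.frame["condition"] == condition
        return list(self.frame.index[sel])

    def subtypes(self, cohort: str) -> list[str]:
        """Distinct subtype labels among the cohort's tumor samples."""
        if "subtype" not in self.frame.columns:
            return []
        sel = (self.frame["cohort"] == cohort) & (self.frame["condition"] == "tumor")
        labels = self.frame.loc[sel, "subtype"].dropna()
        return sorted(labels.unique())

    def subtype_partition(self, cohort: str, subtype: str) -> "SampleSheet":
        """Restrict to one subtype's tumors plus all of the cohort's normals."""
        frame = self.frame
        sel = (frame["cohort"] == cohort) & (
            (frame["condition"] == "normal") | (frame.get("subtype") == subtype)
        )
        return SampleSheet(frame[sel].copy())

    def check_comparable(self, cohort: str) -> None:
        """A cohort entering a comparison needs >= 2 samples per condition."""
        for cond in CONDITIONS:
            n = len(self.cohort_samples(cohort, cond))
            if n < 2:
                raise FormatError(
                    f"cohort {cohort!r} has {n} {cond} sample(s); >= 2 required"
                )


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read a sample sheet TSV (columns sample_id, condition, cohort[, subtype])."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[NA_TOKEN], keep_default_na=False)
    required = {"sample_id", "condition", "cohort"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s): {sorted(missing)}")
    df = df.set_index("sample_id")
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    _write_tsv(sheet.frame, path, index_label="sample_id")


# ---------------------------------------------------------------------------
# Pathway database (GMT) and category map
# ---------------------------------------------------------------------------

@dataclass
class PathwayDB:
    """Named gene sets: pathway_id -> ordered unique member gene symbols."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, genes in self.sets.items():
            if not genes:
                raise FormatError(f"pathway {pid!r} has no genes")
            if len(set(genes)) != len(genes):
                raise FormatError(f"pathway {pid!r} has duplicated gene symbols")

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, pathway_id: str) -> bool:
        return pathway_id in self.sets

    def __getitem__(self, pathway_id: str) -> list[str]:
        return self.sets[pathway_id]

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.sets)

    def items(self):
        return self.sets.items()


def read_gmt(path: str | Path) -> PathwayDB:
    """Read gene sets in GMT format (id TAB description TAB gene...)."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} field(s); "
                    "need pathway_id, description and >= 1 gene"
                )
            pid, desc, *genes = fields
            genes = [g for g in genes if g]
            seen: dict[str, None] = {}
            for g in genes:
                if g in seen:
                    logger.warning("%s:%d: duplicated gene %r in %s; keeping first",
                                   path, lineno, g, pid)
                seen.setdefault(g)
            if pid in sets:
                raise FormatError(f"{path}:{lineno}: duplicate pathway id {pid!r}")
            sets[pid] = list(seen)
            descriptions[pid] = desc
    if not sets:
        logger.warning("%s: empty GMT file", path)
    return PathwayDB(sets, descriptions)


def write_gmt(db: PathwayDB, path: str | Path) -> None:
    with open(path, "w") as handle:
        for pid, genes in db.items():
            desc = db.descriptions.get(pid, "")
            handle.write("\t".join([pid, desc, *genes]) + "\n")


def read_category_map(path: str | Path, db: PathwayDB | None = None) -> dict[str, str]:
    """Read a pathway_id TAB category table; optionally check ids against ``db``."""
    path = Path(path)
    cmap: dict[str, str] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 tab-separated fields")
            pid, category = fields
            if lineno == 1 and pid == "pathway_id":
                continue
            cmap[pid] = category
    if db is not None:
        unknown = [pid for pid in cmap if pid not in db]
        if unknown:
            raise FormatError(f"{path}: category map references unknown pathway(s): {unknown}")
    return cmap


def write_category_map(cmap: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("pathway_id\tcategory\n")
        for pid, category in cmap.items():
            handle.write(f"{pid}\t{category}\n")


# ---------------------------------------------------------------------------
# Regulator lists
# ---------------------------------------------------------------------------

def read_regulators(path: str | Path) -> dict[str, list[str]]:
    """Read pathway_id TAB regulator rows into pathway -> regulator list."""
    path = Path(path)
    regs: dict[str, list[str]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected pathway_id TAB regulator")
            pid, reg = fields
            if lineno == 1 and pid == "pathway_id":
                continue
            regs.setdefault(pid, [])
            if reg not in regs[pid]:
                regs[pid].append(reg)
    return regs


# ---------------------------------------------------------------------------
# Generic tables
# ---------------------------------------------------------------------------

def write_table(table: pd.DataFrame, path: str | Path, index_label: str | None = None) -> None:
    """Write any labelled rectangular table as round-trippable TSV."""
    _write_tsv(table, path, index_label=index_label or table.index.name or "id")


def read_table(path: str | Path, numeric: bool = True) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table` (first column is the index)."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip",
                     na_values=[NA_TOKEN], keep_default_na=False)
    if numeric:
        for col in df.columns:
            converted = pd.to_numeric(df[col], errors="coerce")
            if not (converted.isna() & df[col].notna()).any():
                df[col] = converted
    return df


def _write_tsv(table: pd.DataFrame, path: str | Path, index_label: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", na_rep=NA_TOKEN, float_format=FLOAT_FORMAT,
                 index_label=index_label)


def _read_rectangular(path: Path) -> pd.DataFrame:
    """Read a TSV with an index column, rejecting ragged rows with line context."""
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        n_fields = len(header)
        rows = []
        index = []
        for lineno, line in enumerate(handle, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != n_fields:
                raise FormatError(
                    f"{path}:{lineno}: ragged row ({len(fields)} fields, expected {n_fields})"
                )
            index.append(fields[0])
            rows.append(fields[1:])
    return pd.DataFrame(rows, index=index, columns=header[1:])
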