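"""Readers and writers for every external format the pipeline touches.

Formats
-------
* titer tables — CSV with columns ``individual_id, group, days_post_dose2,
  titer`` (optional ``dose``); log titers are derived on read with a
  configurable base (natural log by default).
* TCR repertoires — AIRR-style TSV; only ``junction_aa`` and
  ``duplicate_count`` are mandatory, extra columns pass through.
* expression — MatrixMarket coordinate matrix (cells as rows, genes as
  columns) with a gene list and a per-cell metadata TSV as sidecars.
* gene modules — plain text, one symbol per line.
* NPX proteomics — long-format CSV ``protein, individual_id, group,
  timepoint, npx``.

Readers validate strictly and never silently coerce: every dropped row is
counted and logged.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

logger = logging.getLogger(__name__)

GROUPS = ("HD", "MGUS", "SMM", "MM")
TIMEPOINTS = ("pre", "post")
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_CDR3_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWY]+$")
MIN_CDR3_LEN = 5

TITER_COLUMNS = ["individual_id", "group", "days_post_dose2", "titer"]
NPX_COLUMNS = ["protein", "individual_id", "group", "timepoint", "npx"]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def _log_fn(base: str | float):
    if base in ("e", "ln", None):
        return np.log
    if base in ("10", 10, 10.0):
        return np.log10
    raise ValueError(f"unsupported log base: {base!r}")


# ---------------------------------------------------------------- titers


def read_titer_csv(path: str | Path, log_base: str | float = "e") -> pd.DataFrame:
    """Read a titer table; validates rows and derives ``log_titer``.

    Row-level validation errors name the offending file line (header = line 1).
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in TITER_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    for idx, row in df.iterrows():
        line = idx + 2  # header occupies line 1
        if not row["titer"] > 0:
            raise FormatError(f"{path}: nonpositive titer on line {line}")
        if row["group"] not in GROUPS:
            raise FormatError(f"{path}: unknown group {row['group']!r} on line {line}")
        if row["days_post_dose2"] < 0:
            raise FormatError(f"{path}: negative day on line {line}")
    df = df.copy()
    df["individual_id"] = df["individual_id"].astype(str)
    df["days_post_dose2"] = df["days_post_dose2"].astype(int)
    if "dose" not in df.columns:
        df["dose"] = 2
    df["log_titer"] = _log_fn(log_base)(df["titer"].to_numpy(dtype=float))
    return df


def write_titer_csv(df: pd.DataFrame, path: str | Path) -> None:
    cols = TITER_COLUMNS + [c for c in ("dose",) if c in df.columns]
    df.loc[:, cols].to_csv(path, index=False)


# ---------------------------------------------------------------- AIRR TSV


@dataclass
class AirrRead:
    """Result of reading an AIRR-style rearrangement TSV."""

    frame: pd.DataFrame
    n_dropped: int


def read_airr_tsv(path: str | Path, chain: str | None = "TRB") -> AirrRead:
    """Read clonotype records from an AIRR-style TSV.

    Rows whose ``junction_aa`` is empty or not a valid amino-acid string of
    length >= 5 are dropped (counted, logged).  If a ``locus`` column is
    present and ``chain`` is given, only matching rows are kept (not counted
    as drops — that is a filter, not a data defect).  Duplicate
    (sample, junction) rows are preserved: deduplication is the job of
    clonotype harmonization, not the reader.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["junction_aa", "duplicate_count"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory columns {missing}")
    if chain is not None and "locus" in df.columns:
        df = df[df["locus"] == chain]
    junc = df["junction_aa"].fillna("")
    valid = junc.str.len().ge(MIN_CDR3_LEN) & junc.str.fullmatch(_CDR3_RE.pattern).fillna(False)
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.info("%s: dropped %d rows with invalid junction_aa", path, n_dropped)
    df = df[valid].copy()
    df["duplicate_count"] = df["duplicate_count"].astype(int)
    if (df["duplicate_count"] < 0).any():
        raise FormatError(f"{path}: negative duplicate_count")
    return AirrRead(frame=df.reset_index(drop=True), n_dropped=n_dropped)


def write_airr_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- expression


@dataclass
class CellMatrix:
    """Cells x genes matrix with per-cell metadata.

    ``X`` is scipy sparse (CSR); integer counts when ``normalized`` is False,
    log-normalized floats afterwards.  ``cell_meta`` has one row per cell with
    at least (individual_id, group, timepoint, cell_type).
    """

    X: sparse.csr_matrix
    gene_names: list[str]
    cell_meta: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        n_cells, n_genes = self.X.shape
        if len(self.gene_names) != n_genes:
            raise FormatError(
                f"matrix has {n_genes} gene columns but {len(self.gene_names)} gene names"
            )
        if len(self.cell_meta) != n_cells:
            raise FormatError(
                f"matrix has {n_cells} cells but metadata covers {len(self.cell_meta)}"
            )
        if len(set(self.gene_names)) != len(self.gene_names):
            raise FormatError("gene names are not unique")
        if not self.normalized and self.X.nnz and self.X.data.min() < 0:
            raise FormatError("negative count entry in matrix")

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_names)}
        return np.array([lookup[g] for g in genes if g in lookup], dtype=int)


CELL_META_COLUMNS = ["individual_id", "group", "timepoint", "cell_type"]


def read_cell_matrix(
    mtx_path: str | Path, genes_path: str | Path, meta_path: str | Path
) -> CellMatrix:
    """Load a MatrixMarket matrix with gene and cell-metadata sidecars.

    Raises :class:`FormatError` stating all three cardinalities on mismatch.
    """
    mat = sparse.csr_matrix(spio.mmread(mtx_path))
    genes = [ln.split("\t")[0] for ln in Path(genes_path).read_text().splitlines() if ln.strip()]
    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    missing = [c for c in CELL_META_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"{meta_path}: missing metadata columns {missing}")
    n_cells, n_genes = mat.shape
    if n_genes != len(genes) or n_cells != len(meta):
        raise FormatError(
            f"dimension mismatch: matrix {n_cells}x{n_genes}, "
            f"{len(genes)} genes, {len(meta)} cells of metadata"
        )
    if mat.nnz and mat.data.min() < 0:
        raise FormatError(f"{mtx_path}: negative count entry")
    return CellMatrix(X=mat, gene_names=genes, cell_meta=meta.reset_index(drop=True))


def write_cell_matrix(
    cm: CellMatrix, mtx_path: str | Path, genes_path: str | Path, meta_path: str | Path
) -> None:
    spio.mmwrite(str(mtx_path), sparse.coo_matrix(cm.X))
    Path(genes_path).write_text("\n".join(cm.gene_names) + "\n")
    cm.cell_meta.to_csv(meta_path, sep="\t", index=False)


# ---------------------------------------------------------------- gene modules


def read_gene_module(path: str | Path) -> list[str]:
    """Read a gene module: one symbol per line, de-duplicated preserving order."""
    path = Path(path)
    symbols: list[str] = []
    seen = set()
    for line in path.read_text().splitlines():
        sym = line.strip()
        if not sym:
            continue
        if sym in seen:
            logger.warning("%s: duplicate gene %s ignored", path, sym)
            continue
        seen.add(sym)
        symbols.append(sym)
    if not symbols:
        raise FormatError(f"{path}: empty gene module")
    return symbols


def write_gene_module(genes: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(genes) + "\n")


# ---------------------------------------------------------------- NPX


def read_npx_csv(path: str | Path) -> pd.DataFrame:
    """Read a long-format NPX table (one record per protein/individual/timepoint)."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in NPX_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    bad_tp = set(df["timepoint"]) - set(TIMEPOINTS)
    if bad_tp:
        raise FormatError(f"{path}: unknown timepoints {sorted(bad_tp)}")
    dupes = df.duplicated(subset=["protein", "individual_id", "timepoint"])
    if dupes.any():
        raise FormatError(
            f"{path}: {int(dupes.sum())} duplicate (protein, individual, timepoint) records"
        )
    df = df.copy()
    df["individual_id"] = df["individual_id"].astype(str)
    df["npx"] = df["npx"].astype(float)
    return df


def write_npx_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.loc[:, NPX_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------- JSON


def write_json(obj, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if hasattr(o, "to_dict"):
            return o.to_dict()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_default) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
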