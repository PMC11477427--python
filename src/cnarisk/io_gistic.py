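"""Readers and writers for GISTIC thresholded copy-number matrices and
clinical survival tables, plus sample alignment between the two.

The copy-number input is the GISTIC 2 Level 4 ``all_thresholded_by_genes``
dialect: a tab-separated matrix with gene regions in rows and samples in
columns, every cell one of the five integer threshold calls

    -2  homozygous deletion
    -1  heterozygous loss
     0  diploid
    +1  one-copy gain
    +2  high-level amplification

Two dialects exist in the wild: gene symbol followed directly by sample
columns, or gene symbol followed by two annotation columns (locus id,
cytoband) before the samples.  Both are auto-detected.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("cnarisk")

VALID_CALLS = (-2, -1, 0, 1, 2)

#: header names (case/punctuation-insensitive) recognised as GISTIC
#: annotation columns rather than samples
_ANNOTATION_PATTERNS = (re.compile(r"locus[\s._]*id", re.I), re.compile(r"cytoband", re.I))


class GisticParseError(ValueError):
    """Raised when a thresholded matrix violates the five-value domain or
    its structural invariants (duplicate samples, malformed cells)."""


@dataclass
class CNAMatrix:
    """Integer gene-region x sample matrix of GISTIC threshold calls.

    Parameters
    ----------
    values : pandas.DataFrame
        Integer matrix, index = gene-region identifiers, columns = sample
        barcodes, entries in {-2, -1, 0, +1, +2}.
    annotation : pandas.DataFrame, optional
        Per-gene locus annotation (e.g. ``Locus ID``, ``Cytoband``) aligned
        to ``values.index``.
    """

    values: pd.DataFrame
    annotation: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise GisticParseError("duplicate gene identifiers in matrix")
        if self.values.columns.has_duplicates:
            raise GisticParseError("duplicate sample identifiers in matrix")
        arr = self.values.to_numpy()
        if not np.isin(arr, VALID_CALLS).all():
            bad = np.argwhere(~np.isin(arr, VALID_CALLS))[0]
            raise GisticParseError(
                f"value {arr[bad[0], bad[1]]!r} outside {{-2..+2}} at gene "
                f"{self.values.index[bad[0]]!r}, sample {self.values.columns[bad[1]]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids: list[str]) -> "CNAMatrix":
        return CNAMatrix(self.values.loc[:, sample_ids], self.annotation)


@dataclass
class SurvivalTable:
    """Per-sample right-censored survival outcome with optional cofactors.

    ``data`` is indexed by sample id and has a ``time`` column (days,
    non-negative) and an ``event`` column (1 = death observed, 0 =
    censored); any remaining columns are clinical cofactors and may hold
    missing values (excluded per-analysis, never per-sample).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("time", "event"):
            if col not in self.data.columns:
                raise ValueError(f"survival table lacks mandatory column {col!r}")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample identifiers in survival table")
        if (self.data["time"] < 0).any():
            raise ValueError("negative survival time")
        if not self.data["event"].isin([0, 1]).all():
            raise ValueError("event indicator must be 0/1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy(dtype=int)

    @property
    def cofactors(self) -> pd.DataFrame:
        return self.data.drop(columns=["time", "event"])

    def subset(self, sample_ids: list[str]) -> "SurvivalTable":
        return SurvivalTable(self.data.loc[sample_ids])


@dataclass
class Cohort:
    """A CNA matrix and a survival table over the same ordered samples."""

    cna: CNAMatrix
    surv: SurvivalTable

    def __post_init__(self) -> None:
        if self.cna.sample_ids != self.surv.sample_ids:
            raise ValueError("cohort samples differ between CNA matrix and survival table")

    @property
    def n_samples(self) -> int:
        return len(self.surv.sample_ids)


def _split_annotation_columns(columns: list[str]) -> int:
    """Number of leading non-gene columns that are locus annotation."""
    n = 0
    for col in columns[:2]:
        if any(p.search(str(col)) for p in _ANNOTATION_PATTERNS):
            n += 1
        else:
            break
    return n


def read_gistic_thresholded(path: str | Path) -> CNAMatrix:
    """Read an ``all_thresholded_by_genes``-style TSV into a :class:`CNAMatrix`.

    Auto-detects whether the two GISTIC annotation columns (locus id,
    cytoband) are present.  Duplicate gene rows keep the first occurrence
    (logged); duplicate sample columns are an error; any cell outside the
    five threshold calls raises :class:`GisticParseError` naming the cell.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) < 2:
        raise GisticParseError(f"{path}: not a tab-separated matrix")
    sample_cols = header[1:]
    n_annot = _split_annotation_columns(sample_cols)
    annot_cols = sample_cols[:n_annot]
    sample_cols = sample_cols[n_annot:]
    if len(set(sample_cols)) != len(sample_cols):
        dupes = sorted({s for s in sample_cols if sample_cols.count(s) > 1})
        raise GisticParseError(f"{path}: duplicate sample column(s) {dupes}")

    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    raw.columns = header[1:]  # undo pandas dedup-mangling, verified above

    if raw.index.has_duplicates:
        n_dup = int(raw.index.duplicated().sum())
        logger.warning("%s: dropping %d duplicate gene row(s), keeping first", path, n_dup)
        raw = raw[~raw.index.duplicated(keep="first")]

    annotation = raw[annot_cols].copy() if n_annot else None
    cells = raw[sample_cols]

    numeric = cells.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & cells.notna()
    if bad.to_numpy().any():
        g, s = np.argwhere(bad.to_numpy())[0]
        raise GisticParseError(
            f"{path}: non-numeric value {cells.iat[g, s]!r} at gene "
            f"{cells.index[g]!r}, sample {sample_cols[s]!r}"
        )
    if numeric.isna().to_numpy().any():
        g, s = np.argwhere(numeric.isna().to_numpy())[0]
        raise GisticParseError(
            f"{path}: empty cell at gene {cells.index[g]!r}, sample {sample_cols[s]!r}"
        )
    arr = numeric.to_numpy(dtype=float)
    if not (arr == np.round(arr)).all():
        g, s = np.argwhere(arr != np.round(arr))[0]
        raise GisticParseError(
            f"{path}: non-integer value {arr[g, s]!r} at gene "
            f"{cells.index[g]!r}, sample {sample_cols[s]!r}"
        )
    values = pd.DataFrame(arr.astype(np.int64), index=cells.index, columns=sample_cols)
    values.index.name = raw.index.name or "Gene Symbol"
    return CNAMatrix(values, annotation)


def write_gistic_thresholded(cna: CNAMatrix, path: str | Path) -> None:
    """Write a :class:`CNAMatrix` back to the same TSV dialect it was read
    from (annotation columns included when present)."""
    out = cna.values
    if cna.annotation is not None:
        out = pd.concat([cna.annotation, cna.values], axis=1)
    out.to_csv(path, sep="\t", index=True, index_label=cna.values.index.name or "Gene Symbol")


#: default mapping of textual event codes to the 0/1 indicator
DEFAULT_EVENT_MAP = {
    "0": 0, "1": 1, "0.0": 0, "1.0": 1,
    "alive": 0, "living": 0, "censored": 0, "false": 0,
    "dead": 1, "deceased": 1, "death": 1, "true": 1,
}


def read_clinical(
    path: str | Path,
    sample_col: str = "sample",
    time_col: str = "time",
    event_col: str = "event",
    event_map: dict[str, int] | None = None,
) -> SurvivalTable:
    """Read a tab-separated clinical table into a :class:`SurvivalTable`.

    ``sample_col``/``time_col``/``event_col`` name the mandatory columns;
    all other columns become cofactors.  Event codes are mapped through
    ``event_map`` (default handles 0/1 and dead/alive spellings,
    case-insensitively).  Rows with unparseable time or event are dropped
    with a logged count; cofactor missingness is retained as NaN.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in (sample_col, time_col, event_col):
        if col not in df.columns:
            raise ValueError(f"{path}: missing mandatory column {col!r}")
    emap = {k.lower(): v for k, v in (event_map or DEFAULT_EVENT_MAP).items()}

    time = pd.to_numeric(df[time_col], errors="coerce")
    event = df[event_col].str.strip().str.lower().map(emap)
    valid = time.notna() & (time >= 0) & event.notna()
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.info("%s: dropped %d row(s) without valid survival information", path, n_dropped)

    out = df.loc[valid].copy()
    out.index = pd.Index(out.pop(sample_col).str.strip(), name="sample")
    out = out.drop(columns=[time_col, event_col])
    # cofactors that look numeric are stored numeric, others categorical
    for col in out.columns:
        num = pd.to_numeric(out[col], errors="coerce")
        if num.notna().sum() >= out[col].notna().sum():
            out[col] = num
    out.insert(0, "time", time.loc[valid].to_numpy())
    out.insert(1, "event", event.loc[valid].astype(int).to_numpy())
    if out.index.has_duplicates:
        n_dup = int(out.index.duplicated().sum())
        logger.warning("%s: dropping %d duplicate sample row(s), keeping first", path, n_dup)
        out = out[~out.index.duplicated(keep="first")]
    return SurvivalTable(out)


def write_clinical(surv: SurvivalTable, path: str | Path) -> None:
    surv.data.to_csv(path, sep="\t", index=True, index_label="sample")


def _truncate(ids: list[str], n: int | None) -> list[str]:
    return [i[:n] for i in ids] if n else list(ids)


def align_cohort(
    cna: CNAMatrix,
    clin: SurvivalTable,
    barcode_length: int | None = 12,
) -> Cohort:
    """Pair a CNA matrix with a clinical table on the sample intersection.

    Sample identifiers frequently differ in granularity: TCGA copy-number
    columns are sample barcodes while clinical rows are 12-character
    patient barcodes.  Both sides are truncated to ``barcode_length``
    characters (``None`` disables truncation) before intersecting; when
    truncation maps several samples to one patient the first is kept.

    Raises ``ValueError`` on an empty intersection.  Alignment is
    symmetric: the retained sample set does not depend on argument roles.
    """
    cna_keys = _truncate(cna.sample_ids, barcode_length)
    clin_keys = _truncate(clin.sample_ids, barcode_length)

    cna_map: dict[str, str] = {}
    for key, orig in zip(cna_keys, cna.sample_ids):
        cna_map.setdefault(key, orig)
    clin_map: dict[str, str] = {}
    for key, orig in zip(clin_keys, clin.sample_ids):
        clin_map.setdefault(key, orig)

    shared = [k for k in cna_map if k in clin_map]
    if not shared:
        raise ValueError("no samples shared between CNA matrix and clinical table")
    logger.info(
        "aligned %d samples (dropped %d from CNA, %d from clinical)",
        len(shared), len(cna_map) - len(shared), len(clin_map) - len(shared),
    )

    cna_sub = cna.values.loc[:, [cna_map[k] for k in shared]].copy()
    cna_sub.columns = shared
    surv_sub = clin.data.loc[[clin_map[k] for k in shared]].copy()
    surv_sub.index = pd.Index(shared, name="sample")
    return Cohort(CNAMatrix(cna_sub, cna.annotation), SurvivalTable(surv_sub))
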