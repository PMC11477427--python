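"""Binary alteration modes and the recurrence filter.

Thresholded copy-number calls are collapsed into four binary modes before
screening: any deletion (*soft deletions*, C <= -1), any amplification
(*soft amplifications*, C >= +1), and the extreme-only variants (*deep
deletions*, C = -2; *deep amplifications*, C = +2).  Deep indicators are by
construction a subset of the corresponding soft indicators, and a cell can
never be both a deletion and an amplification.

Gene regions altered in fewer than ``min_recurrence`` patients (default 4)
are removed before survival screening; the filter is applied on each
mode's own indicator so a gene with many soft but few deep carriers does
not enter deep screening under-powered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_gistic import CNAMatrix

logger = logging.getLogger("cnarisk")

#: the four alteration modes, in canonical order
MODES = ("soft_del", "soft_amp", "deep_del", "deep_amp")

_MODE_RULES = {
    "soft_del": lambda c: c <= -1,
    "soft_amp": lambda c: c >= 1,
    "deep_del": lambda c: c == -2,
    "deep_amp": lambda c: c == 2,
}

DEFAULT_MIN_RECURRENCE = 4


@dataclass
class AlterationMatrix:
    """Binary gene x sample indicator matrix for one alteration mode."""

    mode: str
    indicator: pd.DataFrame  # 0/1, index genes, columns samples

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown alteration mode {self.mode!r}; expected one of {MODES}")
        if not self.indicator.isin([0, 1]).to_numpy().all():
            raise ValueError("alteration indicator must be binary")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.indicator.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.indicator.columns)

    @property
    def carrier_counts(self) -> pd.Series:
        """Number of altered samples per gene region."""
        return self.indicator.sum(axis=1)


def build_mode(cna: CNAMatrix, mode: str) -> AlterationMatrix:
    """Binarize a thresholded matrix under one of the four mode rules."""
    try:
        rule = _MODE_RULES[mode]
    except KeyError:
        raise ValueError(f"unknown alteration mode {mode!r}; expected one of {MODES}") from None
    ind = rule(cna.values).astype(np.int8)
    return AlterationMatrix(mode, ind)


def filter_recurrence(
    am: AlterationMatrix, min_recurrence: int = DEFAULT_MIN_RECURRENCE
) -> AlterationMatrix:
    """Keep only gene regions altered in >= ``min_recurrence`` samples.

    Gene order is preserved; an empty result is allowed (logged), matching
    cohorts without enough deep alterations.  Idempotent.
    """
    keep = am.indicator.sum(axis=1) >= min_recurrence
    out = AlterationMatrix(am.mode, am.indicator.loc[keep])
    if not keep.all():
        logger.info(
            "%s: recurrence filter (>=%d) removed %d of %d gene regions",
            am.mode, min_recurrence, int((~keep).sum()), len(keep),
        )
    if out.indicator.empty:
        logger.warning("%s: no gene regions pass the recurrence filter", am.mode)
    return out


def global_recurrence_prefilter(
    cna: CNAMatrix, min_recurrence: int = DEFAULT_MIN_RECURRENCE
) -> CNAMatrix:
    """Optional pre-filter dropping genes with any alteration (C != 0) in
    fewer than ``min_recurrence`` samples, before mode binarization."""
    keep = (cna.values != 0).sum(axis=1) >= min_recurrence
    return CNAMatrix(cna.values.loc[keep], None if cna.annotation is None else cna.annotation.loc[keep])


def write_mode_matrix(am: AlterationMatrix, out_dir, stem: str = "alterations") -> str:
    """Write a mode indicator matrix as TSV, mode name embedded in the filename."""
    from pathlib import Path

    path = Path(out_dir) / f"{stem}_{am.mode}.tsv"
    am.indicator.to_csv(path, sep="\t", index_label="Gene Symbol")
    return str(path)
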