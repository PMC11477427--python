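"""Risk-group assignment: coefficient sums and the three signature
algorithms, yielding eight prognostic models per cohort.

Per sample and mode, the screened gene regions the sample carries are
summed into two scores: the coefficient sum of high-risk genes
(sum of beta over carried genes with beta > 0) and of low-risk genes
(sum of |beta| over carried genes with beta < 0).  Three algorithms then
label samples:

* *single-data* — one mode at a time; H if the high-risk sum exceeds the
  low-risk sum, L for the reverse, NA on a tie or when the sample carries
  no screened alteration.  Four models (one per mode).
* *MaxSum* — amplification and deletion sums of the same depth are added
  per direction and the larger total wins; ties/zeros are NA.  Two models
  (soft, deep).
* *Combinations* — the amplification single-data label is crossed with
  the deletion single-data label, giving up to 9 groups (H/L/NA x
  H/L/NA).  Two models (soft, deep).

Hence 8 models per cohort: 4 single-data, 2 MaxSum, 2 Combinations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io_gistic import Cohort
from .modes import MODES, AlterationMatrix, build_mode, filter_recurrence, global_recurrence_prefilter
from .screening import ScreenResult, screen_mode

logger = logging.getLogger("cnarisk")

#: canonical model identifiers, in fixed reporting order
MODEL_IDS = (
    "single_soft_del", "single_soft_amp", "single_deep_del", "single_deep_amp",
    "maxsum_soft", "maxsum_deep", "combinations_soft", "combinations_deep",
)

#: relative tolerance used to call two coefficient sums a tie
TIE_RTOL = 1e-9


@dataclass
class PipelineConfig:
    """Tunable knobs of the screening + signature pipeline."""

    alpha: float = 0.05
    engine: str = "permutation"
    n_perm: int = 2000
    seed: int = 0
    min_recurrence: int = 4
    global_prefilter: bool = False      # optional C != 0 pre-filter before modes
    exhaustive_threshold: int = 2000
    ties: str = "efron"
    beta_ceiling: float = 10.0
    tie_rtol: float = TIE_RTOL
    min_group_frac: float = 0.02        # distinguishability threshold in ranking
    min_group_size: int = 1             # Combinations groups below this are flagged
    barcode_length: int = 12

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


def score_samples(
    screen: list[ScreenResult], am: AlterationMatrix
) -> pd.DataFrame:
    """Per-sample coefficient sums over screened genes of one mode.

    Returns a DataFrame indexed by sample with columns ``sum_beta_high``
    (sum of beta over carried high-risk genes) and ``sum_beta_low`` (sum
    of |beta| over carried low-risk genes).  Both are zero for samples
    with no screened alterations.
    """
    if any(r.mode != am.mode for r in screen):
        raise ValueError("screen results and alteration matrix modes differ")
    samples = am.sample_ids
    high = np.zeros(len(samples))
    low = np.zeros(len(samples))
    usable = [r for r in screen if r.gene_id in am.indicator.index and r.direction]
    if usable:
        genes = [r.gene_id for r in usable]
        betas = np.array([r.beta for r in usable])
        A = am.indicator.loc[genes].to_numpy(dtype=float)
        high = np.clip(betas, 0, None) @ A
        low = np.clip(-betas, 0, None) @ A
    return pd.DataFrame({"sum_beta_high": high, "sum_beta_low": low},
                        index=pd.Index(samples, name="sample"))


def _label(high: np.ndarray, low: np.ndarray, rtol: float) -> pd.Series:
    tie = np.isclose(high, low, rtol=rtol, atol=0.0)
    return np.where(tie, "NA", np.where(high > low, "H", "L"))


def assign_single(scores: pd.DataFrame, tie_rtol: float = TIE_RTOL) -> pd.Series:
    """H/L/NA label from one mode's coefficient sums.

    NA covers both the no-alteration case (both sums zero) and ties, in
    which the sample shows no preference for either risk group.  Float
    sums are compared with a relative tolerance to define the tie.
    """
    labels = _label(scores["sum_beta_high"].to_numpy(),
                    scores["sum_beta_low"].to_numpy(), tie_rtol)
    return pd.Series(labels, index=scores.index, name="label")


def assign_maxsum(
    amp_scores: pd.DataFrame, del_scores: pd.DataFrame, tie_rtol: float = TIE_RTOL
) -> pd.Series:
    """H/L/NA label from the combined amplification + deletion sums.

    The high-risk totals of both data types are added, likewise the
    low-risk totals, and the sample joins the direction with the greater
    total; ties and all-zero samples are NA.
    """
    if not amp_scores.index.equals(del_scores.index):
        raise ValueError("amplification and deletion scores cover different samples")
    high = (amp_scores["sum_beta_high"] + del_scores["sum_beta_high"]).to_numpy()
    low = (amp_scores["sum_beta_low"] + del_scores["sum_beta_low"]).to_numpy()
    return pd.Series(_label(high, low, tie_rtol), index=amp_scores.index, name="label")


def assign_combinations(amp_assign: pd.Series, del_assign: pd.Series) -> pd.Series:
    """Pair label crossing the amplification single-data assignment with
    the deletion one, written ``"<amp>/<del>"`` (e.g. ``"H/L"``); up to 9
    distinct groups."""
    if not amp_assign.index.equals(del_assign.index):
        raise ValueError("amplification and deletion assignments cover different samples")
    return pd.Series(amp_assign.str.cat(del_assign, sep="/"),
                     index=amp_assign.index, name="label")


@dataclass
class PipelineResult:
    """Everything the screening + signature stages produce for one cohort."""

    config: PipelineConfig
    filtered: dict[str, AlterationMatrix]          # mode -> filtered indicator
    screens: dict[str, list[ScreenResult]]         # mode -> retained genes
    scores: dict[str, pd.DataFrame]                # mode -> coefficient sums
    assignments: dict[str, pd.Series]              # model_id -> labels
    reports: dict[str, "ModelReport"] = field(default_factory=dict)  # noqa: F821
    ranking: object | None = None

    def assignments_frame(self) -> pd.DataFrame:
        rows = []
        for model_id in MODEL_IDS:
            lab = self.assignments[model_id]
            rows.append(pd.DataFrame({
                "sample": lab.index, "model_id": model_id, "label": lab.to_numpy()
            }))
        return pd.concat(rows, ignore_index=True)

    def write_assignments(self, path: str | Path) -> None:
        self.assignments_frame().to_csv(path, sep="\t", index=False)


def build_all_models(cohort: Cohort, config: PipelineConfig | None = None) -> PipelineResult:
    """Run modes -> screening -> scoring -> the three algorithms, emitting
    exactly eight models (4 single-data, 2 MaxSum, 2 Combinations).

    A mode whose screening retains no gene region yields all-zero scores,
    so its single-data model labels every sample NA (logged, not an
    error) — the situation seen in cohorts without enough deep
    alterations.  Reports and ranking are attached by
    :func:`cnarisk.evaluation.evaluate_models`.
    """
    cfg = config or PipelineConfig()
    cna = cohort.cna
    if cfg.global_prefilter:
        cna = global_recurrence_prefilter(cna, cfg.min_recurrence)

    filtered: dict[str, AlterationMatrix] = {}
    screens: dict[str, list[ScreenResult]] = {}
    scores: dict[str, pd.DataFrame] = {}
    for mode in MODES:
        am = filter_recurrence(build_mode(cna, mode), cfg.min_recurrence)
        filtered[mode] = am
        screens[mode] = screen_mode(
            am, cohort.surv, alpha=cfg.alpha, engine=cfg.engine,
            n_perm=cfg.n_perm, seed=cfg.seed,
            exhaustive_threshold=cfg.exhaustive_threshold,
            ties=cfg.ties, beta_ceiling=cfg.beta_ceiling,
        )
        scores[mode] = score_samples(screens[mode], am)

    assignments: dict[str, pd.Series] = {}
    for mode in MODES:
        assignments[f"single_{mode}"] = assign_single(scores[mode], cfg.tie_rtol)
    for depth in ("soft", "deep"):
        amp_s, del_s = scores[f"{depth}_amp"], scores[f"{depth}_del"]
        assignments[f"maxsum_{depth}"] = assign_maxsum(amp_s, del_s, cfg.tie_rtol)
        assignments[f"combinations_{depth}"] = assign_combinations(
            assignments[f"single_{depth}_amp"], assignments[f"single_{depth}_del"]
        )
    assert set(assignments) == set(MODEL_IDS)
    return PipelineResult(cfg, filtered, screens, scores, assignments)
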