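"""Model evaluation: Kaplan–Meier curves, multi-group log-rank tests,
model ranking/selection, cofactor stratification, and multivariate Cox
independence analysis.

A *model* here is a per-sample risk-group labelling (H/L/NA for
single-data and MaxSum, pair labels for Combinations).  Models are ranked
by the significance of their overall multi-group log-rank test, with a
penalty for models whose risk groups are not clinically distinguishable:
an occupied group smaller than ``min_group_frac`` of the cohort, or a
non-significant pairwise separation between the extreme groups (groups
ordered by crude event rate).  Cofactor analyses treat the NA (no-risk)
group as the reference stratum throughout.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats as sps

from .io_gistic import Cohort, SurvivalTable
from .signatures import MODEL_IDS, PipelineConfig, PipelineResult, build_all_models

logger = logging.getLogger("cnarisk")

#: default clinical level-merging maps (sparse upper levels pooled)
DEFAULT_LEVEL_MAPS = {
    "T": {"T3": "T3/T4", "T4": "T3/T4"},
    "N": {"N2": "N2/N3", "N3": "N2/N3"},
    "stage": {"iii": "iii/iv", "iv": "iii/iv"},
}
DEFAULT_AGE_CUT = 60.0


# ---------------------------------------------------------------------------
# Kaplan–Meier and multi-group log-rank
# ---------------------------------------------------------------------------

def km_curve(
    time: np.ndarray, event: np.ndarray, labels: pd.Series | np.ndarray
) -> dict[str, pd.DataFrame]:
    """Product-limit survival estimate per group.

    Returns, per occupied group, a step-function table with columns
    ``time`` and ``survival`` (starting at S(0) = 1, non-increasing).
    """
    labels = np.asarray(labels)
    out: dict[str, pd.DataFrame] = {}
    for lab in sorted(pd.unique(labels)):
        mask = labels == lab
        kmf = KaplanMeierFitter()
        kmf.fit(np.asarray(time)[mask], np.asarray(event)[mask])
        sf = kmf.survival_function_
        out[str(lab)] = pd.DataFrame({
            "time": sf.index.to_numpy(dtype=float),
            "survival": sf.iloc[:, 0].to_numpy(dtype=float),
        })
    return out


def multigroup_logrank(
    time: np.ndarray, event: np.ndarray, labels: pd.Series | np.ndarray
) -> tuple[float, int, float] | None:
    """k-group log-rank test; returns (chi-square, df, p) or ``None`` when
    undefined (fewer than two occupied groups, or no events).

    With two groups the statistic coincides with the two-group score form
    used in screening.
    """
    from .screening import prepare_logrank  # shared tie-block machinery

    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    labels = np.asarray(labels)
    groups = sorted(pd.unique(labels))
    k = len(groups)
    if k < 2 or event.sum() == 0:
        return None
    prep = prepare_logrank(time, event)
    onehot = np.stack([(labels == g).astype(float) for g in groups])

    G = onehot[:, prep.order]
    suffix = np.cumsum(G[:, ::-1], axis=1)[:, ::-1]
    n_g = suffix[:, prep.starts][:, prep.keep]            # (k, m) at-risk
    d_g = np.add.reduceat(G * prep.e_sorted, prep.starts, axis=1)[:, prep.keep]
    frac = n_g / prep.n_at_risk
    x = (d_g - prep.d * frac).sum(axis=1)                 # observed - expected
    with np.errstate(invalid="ignore", divide="ignore"):
        hyper = np.where(prep.n_at_risk > 1,
                         prep.d * (prep.n_at_risk - prep.d) / (prep.n_at_risk - 1.0),
                         0.0)
    V = np.einsum("j,gj->g", hyper, frac * (1.0 - frac)) * np.eye(k)
    off = -np.einsum("j,gj,hj->gh", hyper, frac, frac)
    np.fill_diagonal(off, 0.0)
    V = V + off

    xr, Vr = x[:-1], V[:-1, :-1]
    try:
        sol = np.linalg.solve(Vr, xr)
    except np.linalg.LinAlgError:
        sol = np.linalg.pinv(Vr) @ xr
    stat = float(xr @ sol)
    if not np.isfinite(stat) or stat < 0:
        sol = np.linalg.pinv(Vr) @ xr
        stat = float(max(xr @ sol, 0.0))
    df = k - 1
    return stat, df, float(sps.chi2.sf(stat, df))


# ---------------------------------------------------------------------------
# per-model reports and ranking
# ---------------------------------------------------------------------------

@dataclass
class ModelReport:
    """Survival summary of one risk-group model on one cohort."""

    model_id: str
    n: int
    group_sizes: dict[str, int]
    group_events: dict[str, int]
    km: dict[str, pd.DataFrame]
    overall_stat: float | None
    overall_df: int | None
    overall_p: float | None
    pairwise_p: dict[str, float] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    @property
    def n_groups(self) -> int:
        return len(self.group_sizes)

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "n": self.n,
            "group_sizes": self.group_sizes,
            "group_events": self.group_events,
            "overall_stat": self.overall_stat,
            "overall_df": self.overall_df,
            "overall_p": self.overall_p,
            "pairwise_p": self.pairwise_p,
            "flags": self.flags,
            "km": {g: {"time": df["time"].tolist(), "survival": df["survival"].tolist()}
                   for g, df in self.km.items()},
        }


def model_report(
    model_id: str,
    assignments: pd.Series,
    surv: SurvivalTable,
    min_group_size: int = 1,
) -> ModelReport:
    """Build the per-group KM curves and log-rank tests for one model.

    Groups with zero samples are omitted.  Models with fewer than two
    occupied groups (or no events) get ``overall_p = None`` and a
    ``degenerate`` flag rather than an error — the situation produced by
    modes with empty screening.
    """
    if list(assignments.index) != surv.sample_ids:
        raise ValueError("assignments and survival table are not aligned")
    time, event = surv.time, surv.event
    labels = assignments.to_numpy()
    counts = pd.Series(labels).value_counts()
    sizes = {str(g): int(counts[g]) for g in sorted(counts.index)}
    events = {str(g): int(event[labels == g].sum()) for g in sizes}

    flags = []
    small = [g for g, c in sizes.items() if c < min_group_size]
    for g in small:
        flags.append(f"small_group:{g}")

    overall = multigroup_logrank(time, event, labels)
    if overall is None:
        flags.append("degenerate")
        stat = df = p = None
    else:
        stat, df, p = overall

    pairwise: dict[str, float] = {}
    group_list = sorted(sizes)
    for i, a in enumerate(group_list):
        for b in group_list[i + 1:]:
            mask = (labels == a) | (labels == b)
            res = multigroup_logrank(time[mask], event[mask], labels[mask])
            pairwise[f"{a}|{b}"] = res[2] if res is not None else float("nan")

    return ModelReport(model_id, len(labels), sizes, events, km_curve(time, event, labels),
                       stat, df, p, pairwise, flags)


@dataclass
class RankingResult:
    table: pd.DataFrame
    order: list[str]
    selected: str | None


def _extreme_pair(report: ModelReport) -> tuple[str, str] | None:
    """Extreme risk groups = min vs max crude event rate (events / n)."""
    if report.n_groups < 2:
        return None
    rates = {g: report.group_events[g] / report.group_sizes[g] for g in report.group_sizes}
    ordered = sorted(report.group_sizes, key=lambda g: (rates[g], g))
    return ordered[0], ordered[-1]


def rank_models(
    reports: dict[str, ModelReport] | list[ModelReport],
    min_group_frac: float = 0.02,
    pairwise_alpha: float = 0.05,
) -> RankingResult:
    """Rank the eight models by significance, penalizing models whose risk
    groups are not distinguishable, and select the best surviving model.

    Primary sort: overall log-rank p ascending.  A model is *penalized*
    when any occupied group holds fewer than ``min_group_frac`` of the
    cohort, or the extreme groups (ordered by crude event rate) are not
    separated at ``pairwise_alpha``.  Degenerate models (< 2 groups) sort
    last.  Ties break by fewer groups, then by the fixed model-id order —
    a total, deterministic order.  ``selected`` is the top non-penalized,
    non-degenerate model, or ``None`` when every model is degenerate or
    penalized (the ranking table is still returned).
    """
    if isinstance(reports, list):
        reports = {r.model_id: r for r in reports}
    rows = []
    for model_id, rep in reports.items():
        model_order = MODEL_IDS.index(model_id) if model_id in MODEL_IDS else len(MODEL_IDS)
        degenerate = rep.overall_p is None
        reasons = []
        if degenerate:
            reasons.append("degenerate")
        else:
            min_n = min(rep.group_sizes.values())
            if min_n < min_group_frac * rep.n:
                reasons.append("small_group")
            pair = _extreme_pair(rep)
            if pair is not None:
                p_pair = rep.pairwise_p.get(f"{pair[0]}|{pair[1]}",
                                            rep.pairwise_p.get(f"{pair[1]}|{pair[0]}"))
                if p_pair is None or not np.isfinite(p_pair) or p_pair > pairwise_alpha:
                    reasons.append("extremes_not_separated")
        rows.append({
            "model_id": model_id,
            "p": rep.overall_p if rep.overall_p is not None else np.nan,
            "n_groups": rep.n_groups,
            "degenerate": degenerate,
            "penalized": bool(reasons) and not degenerate,
            "reasons": ";".join(reasons),
            "_order": model_order,
        })
    table = pd.DataFrame(rows)
    sort_p = table["p"].fillna(np.inf)
    table = table.assign(_p=sort_p).sort_values(
        by=["degenerate", "penalized", "_p", "n_groups", "_order"],
        kind="stable",
    ).drop(columns=["_p"]).reset_index(drop=True)
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    order = table["model_id"].tolist()
    eligible = table[~table["degenerate"] & ~table["penalized"]]
    selected = str(eligible.iloc[0]["model_id"]) if len(eligible) else None
    return RankingResult(table.drop(columns=["_order"]), order, selected)


def evaluate_models(
    result: PipelineResult, surv: SurvivalTable,
    min_group_frac: float | None = None,
) -> PipelineResult:
    """Attach the eight ModelReports and the ranking to a pipeline result."""
    frac = result.config.min_group_frac if min_group_frac is None else min_group_frac
    reports = {
        model_id: model_report(model_id, result.assignments[model_id], surv,
                               min_group_size=result.config.min_group_size)
        for model_id in MODEL_IDS
    }
    result.reports = reports
    result.ranking = rank_models(reports, min_group_frac=frac)
    return result


def run_pipeline(cohort: Cohort, config: PipelineConfig | None = None) -> PipelineResult:
    """Full analysis for one cohort: modes, screening, the eight models,
    reports, ranking."""
    result = build_all_models(cohort, config)
    return evaluate_models(result, cohort.surv)


# ---------------------------------------------------------------------------
# cofactor analyses
# ---------------------------------------------------------------------------

def _stratum_series(
    surv: SurvivalTable, cofactor: str,
    level_maps: dict | None, age_cut: float,
) -> pd.Series:
    cof = surv.cofactors
    if cofactor not in cof.columns:
        raise ValueError(f"unknown cofactor {cofactor!r}")
    col = cof[cofactor]
    if pd.api.types.is_numeric_dtype(col):
        strat = pd.Series(
            np.where(col.isna(), None,
                     np.where(col < age_cut, f"<{age_cut:g}", f">={age_cut:g}")),
            index=col.index, dtype=object)
    else:
        strat = col.astype(object)
    maps = DEFAULT_LEVEL_MAPS if level_maps is None else level_maps
    if cofactor in maps:
        strat = strat.map(lambda v: maps[cofactor].get(v, v) if v is not None else None)
    return strat


@dataclass
class StratificationReport:
    cofactor: str
    table: pd.DataFrame  # stratum, group, n, events, beta, se, ci, p, estimable


def _cox_risk_fit(sub: pd.DataFrame, labels: list[str], reference: str) -> pd.DataFrame | None:
    """Cox fit of risk-group dummies (reference omitted) on a sub-cohort."""
    design = pd.DataFrame({"T": sub["time"], "E": sub["event"]})
    for lab in labels:
        design[f"risk_{lab}"] = (sub["label"] == lab).astype(float)
    cph = CoxPHFitter()
    try:
        cph.fit(design, duration_col="T", event_col="E")
    except (ConvergenceError, ValueError):
        return None
    return cph.summary


def stratified_analysis(
    assignments: pd.Series,
    surv: SurvivalTable,
    cofactor: str,
    level_maps: dict | None = None,
    age_cut: float = DEFAULT_AGE_CUT,
    reference: str = "NA",
    min_stratum_n: int = 5,
    sig_alpha: float = 0.05,
) -> StratificationReport:
    """Within-stratum Cox estimates of each risk group versus the no-risk
    reference, for one clinical cofactor.

    Numeric cofactors (age) are dichotomized at ``age_cut``; categorical
    levels are pooled through ``level_maps`` (defaults merge T3/T4, N2/N3
    and stage iii/iv).  A group with no events inside a stratum is
    reported as non-estimable (its samples are excluded from that
    stratum's fit), mirroring forest plots that mark such groups with
    "<".  The assignments are never modified.
    """
    if list(assignments.index) != surv.sample_ids:
        raise ValueError("assignments and survival table are not aligned")
    strat = _stratum_series(surv, cofactor, level_maps, age_cut)
    df = pd.DataFrame({
        "time": surv.time, "event": surv.event,
        "label": assignments.to_numpy(), "stratum": strat.to_numpy(),
    }, index=assignments.index)
    df = df[df["stratum"].notna()]

    rows = []
    for stratum in sorted(df["stratum"].unique()):
        sub = df[df["stratum"] == stratum]
        if len(sub) < min_stratum_n:
            logger.info("%s=%s: only %d samples, stratum skipped", cofactor, stratum, len(sub))
            continue
        labels = [l for l in sorted(sub["label"].unique()) if l != reference]
        estimable = {}
        for lab in labels:
            grp = sub[sub["label"] == lab]
            estimable[lab] = int(grp["event"].sum()) > 0 and len(grp) < len(sub)
        fit_labels = [l for l in labels if estimable[l]]
        fit_sub = sub[sub["label"].isin(fit_labels + [reference])]
        summary = None
        if fit_labels and fit_sub["event"].sum() > 0 and (fit_sub["label"] == reference).any():
            summary = _cox_risk_fit(fit_sub, fit_labels, reference)
        for lab in labels:
            grp = sub[sub["label"] == lab]
            row = {
                "stratum": stratum, "group": lab,
                "n_stratum": len(sub), "n_group": len(grp),
                "events_group": int(grp["event"].sum()),
                "beta": np.nan, "se": np.nan,
                "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
                "estimable": False, "significant": False,
            }
            name = f"risk_{lab}"
            if summary is not None and name in summary.index:
                s = summary.loc[name]
                row.update({
                    "beta": float(s["coef"]), "se": float(s["se(coef)"]),
                    "ci_low": float(s["coef lower 95%"]),
                    "ci_high": float(s["coef upper 95%"]),
                    "p": float(s["p"]), "estimable": True,
                    "significant": bool(s["p"] <= sig_alpha),
                })
            rows.append(row)
    return StratificationReport(cofactor, pd.DataFrame(rows))


def _drop_redundant_columns(X: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Greedy rank-preserving column selection: constant or collinear
    columns are dropped (order of first appearance wins)."""
    dropped = []
    kept: list[str] = []
    arr = None
    for col in X.columns:
        v = X[col].to_numpy(dtype=float)
        if np.nanstd(v) == 0:
            dropped.append(col)
            continue
        cand = v[:, None] if arr is None else np.column_stack([arr, v])
        if np.linalg.matrix_rank(cand) > (0 if arr is None else np.linalg.matrix_rank(arr)):
            kept.append(col)
            arr = cand
        else:
            dropped.append(col)
    return X[kept], dropped


def multivariate_cox(
    assignments: pd.Series,
    surv: SurvivalTable,
    cofactors: list[str] | None = None,
    reference: str = "NA",
) -> pd.DataFrame:
    """Joint Cox model of the risk-group indicators and clinical cofactors.

    Complete-case analysis over the selected cofactors; risk groups enter
    as dummies against the NA reference, categorical cofactors as dummies
    against their first (sorted) level.  Constant or collinear columns are
    dropped with a warning.  Returns a tidy table (term, beta, se,
    ci_low, ci_high, p) with the fitted sample size in ``attrs['n']``.
    """
    if list(assignments.index) != surv.sample_ids:
        raise ValueError("assignments and survival table are not aligned")
    cof = surv.cofactors
    cofactors = list(cof.columns) if cofactors is None else list(cofactors)
    missing = [c for c in cofactors if c not in cof.columns]
    if missing:
        raise ValueError(f"unknown cofactor(s): {missing}")

    df = pd.DataFrame({"T": surv.time, "E": surv.event}, index=assignments.index)
    for lab in sorted(set(assignments) - {reference}):
        df[f"risk_{lab}"] = (assignments == lab).astype(float)
    for c in cofactors:
        col = cof[c]
        if pd.api.types.is_numeric_dtype(col):
            df[c] = col.astype(float)
        else:
            dummies = pd.get_dummies(col.astype(object), prefix=c)
            for dcol in sorted(dummies.columns)[1:]:
                df[dcol] = dummies[dcol].astype(float)
            df.loc[col.isna(), [c2 for c2 in dummies.columns if c2 in df.columns]] = np.nan

    df = df.dropna()
    if df.empty:
        raise ValueError("no complete-case samples for the requested cofactors")
    X, dropped = _drop_redundant_columns(df.drop(columns=["T", "E"]))
    if dropped:
        logger.warning("multivariate Cox: dropped constant/collinear term(s) %s", dropped)
    cph = CoxPHFitter()
    cph.fit(pd.concat([df[["T", "E"]], X], axis=1), duration_col="T", event_col="E")
    s = cph.summary
    out = pd.DataFrame({
        "term": s.index,
        "beta": s["coef"].to_numpy(),
        "se": s["se(coef)"].to_numpy(),
        "ci_low": s["coef lower 95%"].to_numpy(),
        "ci_high": s["coef upper 95%"].to_numpy(),
        "p": s["p"].to_numpy(),
    }).reset_index(drop=True)
    out.attrs["n"] = int(len(df))
    out.attrs["dropped"] = [str(d) for d in dropped]
    return out


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def write_model_reports(reports: dict[str, ModelReport], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({m: r.to_dict() for m, r in reports.items()}, fh, indent=1, sort_keys=True)


def write_ranking(ranking: RankingResult, path: str | Path) -> None:
    ranking.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def plot_km(report: ModelReport, path: str | Path) -> None:
    """Kaplan–Meier plot of one model's risk groups (SVG/PNG by suffix)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for lab, df in report.km.items():
        n = report.group_sizes.get(lab, 0)
        ax.step(df["time"], df["survival"], where="post", label=f"{lab} (n={n})")
    p = report.overall_p
    ax.set_title(f"{report.model_id}" + (f"  p={p:.2g}" if p is not None else ""))
    ax.set_xlabel("days")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_forest(report: StratificationReport, path: str | Path) -> None:
    """Forest plot of within-stratum risk-group coefficients."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    tab = report.table
    fig, ax = plt.subplots(figsize=(5, max(2, 0.4 * len(tab))))
    y = np.arange(len(tab))[::-1]
    for yi, (_, row) in zip(y, tab.iterrows()):
        lab = f"{row['stratum']} {row['group']} (n={row['n_group']})"
        if row["estimable"]:
            ax.plot([row["ci_low"], row["ci_high"]], [yi, yi], color="k", lw=1)
            ax.plot(row["beta"], yi, "o", color="k",
                    mfc="k" if row["significant"] else "w")
        else:
            ax.plot(0, yi, marker="$<$", color="grey")
        ax.text(-0.02, yi, lab, transform=ax.get_yaxis_transform(),
                ha="right", va="center", fontsize=7)
    ax.axvline(0, color="grey", lw=0.5, ls="--")
    ax.set_yticks([])
    ax.set_xlabel(r"$\beta$ (log hazard ratio vs NA)")
    ax.set_title(report.cofactor)
    fig.tight_layout()
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
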