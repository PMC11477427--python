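"""Synthetic GISTIC-style cohorts with planted prognostic CNA structure.

The generator emulates the statistical structure the analysis assumes:
sparse integer threshold calls in {-2..+2}, a handful of *planted* gene
regions whose carriers experience a proportional-hazards effect, and
right-censored survival times with clinical cofactors.  Hazards are
additive on the log scale across planted genes and cofactors (standard
PH), matching the additivity implicitly assumed by coefficient-sum
scoring.

Defaults describe the reference planted scenario used throughout the
test-bench: 300 samples, 200 gene regions, five deep-amplification
high-risk genes with log hazard ratio 1.5 carried by 8% of samples,
exponential baseline with a 3-year median, administrative censoring at 10
years plus random exponential censoring.  Background (null) gene regions
draw their carrier fractions from a Beta(2, 38) distribution, placing
most mass at 2–10% carriers as seen in thresholded CNA matrices.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_gistic import CNAMatrix, Cohort, SurvivalTable, align_cohort, write_gistic_thresholded
from .modes import MODES

logger = logging.getLogger("cnarisk")


@dataclass(frozen=True)
class PlantedGene:
    """A gene region with a true survival effect.

    ``mode`` decides the threshold value carriers receive (deep modes get
    +-2; soft modes get +-1 with a configurable deep admixture), ``beta``
    is the true log hazard ratio for carriers, ``carrier_fraction`` the
    fraction of samples carrying the alteration (drawn exactly, without
    replacement).
    """

    mode: str
    beta: float
    carrier_fraction: float

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if not np.isfinite(self.beta):
            raise ValueError("planted beta must be finite")
        if not 0 < self.carrier_fraction < 1:
            raise ValueError("carrier_fraction must be in (0, 1)")


@dataclass(frozen=True)
class CofactorSpec:
    """A clinical cofactor: categorical (levels + probabilities, optional
    per-level log-hazard effects) or numeric (normal, optional per-unit
    effect centred at the mean)."""

    name: str
    kind: str  # "categorical" | "numeric"
    levels: tuple[str, ...] = ()
    probs: tuple[float, ...] = ()
    mean: float = 0.0
    sd: float = 1.0
    effects: dict | float = 0.0


def default_cofactors() -> tuple[CofactorSpec, ...]:
    return (
        CofactorSpec("age", "numeric", mean=65.0, sd=10.0),
        CofactorSpec("sex", "categorical", levels=("F", "M"), probs=(0.5, 0.5)),
        CofactorSpec("stage", "categorical", levels=("i", "ii", "iii", "iv"),
                     probs=(0.3, 0.3, 0.25, 0.15)),
    )


@dataclass
class SimulationConfig:
    """Reproducible description of one synthetic cohort."""

    n_samples: int = 300
    n_genes: int = 200
    planted: tuple[PlantedGene, ...] = tuple(
        PlantedGene("deep_amp", 1.5, 0.08) for _ in range(5)
    )
    #: Beta(a, b) distribution of background per-gene carrier fractions
    background_freq_alpha: float = 2.0
    background_freq_beta: float = 38.0
    #: probability a background altered cell is deep (+-2) rather than soft
    deep_fraction: float = 0.3
    #: fraction of planted *soft* carriers upgraded to the deep value
    soft_deep_admixture: float = 0.2
    #: baseline hazard: "exponential" or "weibull" with the given shape
    baseline: str = "exponential"
    baseline_median_days: float = 1095.0
    weibull_shape: float = 1.0
    #: administrative censoring horizon (days) and random censoring rate (/day)
    censor_horizon_days: float = 3650.0
    censor_rate: float = 1.0 / 3000.0
    cofactors: tuple[CofactorSpec, ...] = field(default_factory=default_cofactors)
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimulatedCohort:
    """Generated cohort plus ground truth and provenance manifest."""

    cna: CNAMatrix             # sample-level barcodes (16 chars)
    clinical: SurvivalTable    # patient-level barcodes (12 chars)
    truth_genes: pd.DataFrame  # planted genes: gene, mode, beta_true, n_carriers
    truth_samples: pd.DataFrame  # per sample: true_lp, true_stratum
    manifest: dict

    def cohort(self, barcode_length: int = 12) -> Cohort:
        return align_cohort(self.cna, self.clinical, barcode_length=barcode_length)


def _patient_id(i: int) -> str:
    return f"TCGA-SY-{i:04d}"


def draw_survival_times(
    rng: np.random.Generator, lp: np.ndarray, cfg: SimulationConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Right-censored event times under h(t) = h0(t) * exp(lp).

    Inverse-transform sampling from the exponential or Weibull baseline,
    censored by min(administrative horizon, exponential censoring time).
    Returns (time, event).
    """
    n = lp.size
    u = rng.random(n)
    if cfg.baseline == "exponential":
        lam0 = np.log(2.0) / cfg.baseline_median_days
        t_event = -np.log(u) / (lam0 * np.exp(lp))
    elif cfg.baseline == "weibull":
        scale = cfg.baseline_median_days / np.log(2.0) ** (1.0 / cfg.weibull_shape)
        t_event = scale * (-np.log(u) / np.exp(lp)) ** (1.0 / cfg.weibull_shape)
    else:
        raise ValueError(f"unknown baseline {cfg.baseline!r}")
    t_cens = np.full(n, cfg.censor_horizon_days)
    if cfg.censor_rate > 0:
        t_cens = np.minimum(t_cens, rng.exponential(1.0 / cfg.censor_rate, size=n))
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return time, event


_MODE_VALUES = {"soft_del": -1, "deep_del": -2, "soft_amp": 1, "deep_amp": 2}


def simulate_cohort(cfg: SimulationConfig | None = None) -> SimulatedCohort:
    """Generate a thresholded CNA matrix, clinical table and ground truth.

    Planted genes receive their mode's threshold value for an exactly
    sized carrier subset drawn without replacement; background genes draw
    a Beta-distributed carrier fraction, a random sign, and a soft/deep
    depth per carrier.  Survival times follow the proportional-hazards
    model with gene effects plus any configured cofactor effects.  All
    randomness flows from ``cfg.seed``.
    """
    cfg = cfg or SimulationConfig()
    n, g = cfg.n_samples, cfg.n_genes
    if len(cfg.planted) > g:
        raise ValueError("more planted genes than gene regions")
    for pg in cfg.planted:
        if pg.carrier_fraction * n < 1:
            raise ValueError(
                f"infeasible config: carrier fraction {pg.carrier_fraction} x "
                f"n={n} yields no carriers"
            )
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x5EED]))

    gene_ids = [f"G{i + 1:04d}" for i in range(g)]
    planted_pos = rng.choice(g, size=len(cfg.planted), replace=False) if cfg.planted else np.array([], int)
    values = np.zeros((g, n), dtype=np.int64)
    lp = np.zeros(n)

    truth_rows = []
    for pos, pg in zip(planted_pos, cfg.planted):
        k = int(round(pg.carrier_fraction * n))
        carriers = rng.choice(n, size=k, replace=False)
        val = _MODE_VALUES[pg.mode]
        cell = np.full(k, val)
        if abs(val) == 1 and cfg.soft_deep_admixture > 0:
            deep = rng.random(k) < cfg.soft_deep_admixture
            cell = np.where(deep, 2 * val, val)
        values[pos, carriers] = cell
        lp[carriers] += pg.beta
        truth_rows.append({
            "gene": gene_ids[pos], "mode": pg.mode,
            "beta_true": pg.beta, "n_carriers": k,
        })

    background = np.setdiff1d(np.arange(g), planted_pos)
    freqs = rng.beta(cfg.background_freq_alpha, cfg.background_freq_beta, size=background.size)
    signs = rng.choice([-1, 1], size=background.size)
    for pos, f, s in zip(background, freqs, signs):
        mask = rng.random(n) < f
        depth = np.where(rng.random(n) < cfg.deep_fraction, 2, 1)
        values[pos, mask] = (s * depth)[mask]

    # cofactors and their hazard contributions
    cof_data: dict[str, np.ndarray] = {}
    for spec in cfg.cofactors:
        if spec.kind == "numeric":
            x = rng.normal(spec.mean, spec.sd, size=n)
            cof_data[spec.name] = x
            if isinstance(spec.effects, (int, float)) and spec.effects:
                lp += float(spec.effects) * (x - spec.mean)
        elif spec.kind == "categorical":
            probs = np.asarray(spec.probs, dtype=float)
            levels = rng.choice(spec.levels, size=n, p=probs / probs.sum())
            cof_data[spec.name] = levels
            if isinstance(spec.effects, dict):
                lp += np.array([float(spec.effects.get(l, 0.0)) for l in levels])
        else:
            raise ValueError(f"unknown cofactor kind {spec.kind!r}")

    time, event = draw_survival_times(rng, lp, cfg)

    patients = [_patient_id(i) for i in range(n)]
    samples = [p + "-01" for p in patients]
    annotation = pd.DataFrame({
        "Locus ID": np.arange(1, g + 1),
        "Cytoband": [f"{(i % 22) + 1}{'pq'[i % 2]}{(i % 3) + 1}{(i % 9) + 1}" for i in range(g)],
    }, index=pd.Index(gene_ids, name="Gene Symbol"))
    cna = CNAMatrix(
        pd.DataFrame(values, index=pd.Index(gene_ids, name="Gene Symbol"), columns=samples),
        annotation,
    )
    clin = pd.DataFrame(index=pd.Index(patients, name="sample"))
    clin["time"] = np.round(time, 6)
    clin["event"] = event
    for name, x in cof_data.items():
        clin[name] = np.round(x, 6) if np.issubdtype(np.asarray(x).dtype, np.number) else x
    clinical = SurvivalTable(clin)

    truth_genes = pd.DataFrame(truth_rows, columns=["gene", "mode", "beta_true", "n_carriers"])
    truth_genes = truth_genes.sort_values("gene").reset_index(drop=True)
    truth_samples = pd.DataFrame({
        "sample": patients,
        "true_lp": np.round(lp, 10),
        "true_stratum": np.where(lp > 0, "high", np.where(lp < 0, "low", "none")),
    })
    manifest = {"config": cfg.to_dict(), "seed": cfg.seed,
                "n_samples": n, "n_genes": g, "n_events": int(event.sum())}
    return SimulatedCohort(cna, clinical, truth_genes, truth_samples, manifest)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_fixture(sim: SimulatedCohort, out_dir: str | Path) -> dict[str, str]:
    """Write the cohort as plain-text fixture files plus a manifest.

    Emits the GISTIC-dialect matrix (with annotation columns), the
    clinical TSV, the two truth tables, and ``manifest.json`` recording
    the configuration, seed and a sha256 per file.  Same seed, same bytes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "gistic": out / "gistic_thresholded.tsv",
        "clinical": out / "clinical.tsv",
        "truth_genes": out / "truth_genes.tsv",
        "truth_samples": out / "truth_samples.tsv",
    }
    write_gistic_thresholded(sim.cna, paths["gistic"])
    sim.clinical.data.to_csv(paths["clinical"], sep="\t", index=True,
                             index_label="sample", float_format="%.6f")
    sim.truth_genes.to_csv(paths["truth_genes"], sep="\t", index=False, float_format="%.6f")
    sim.truth_samples.to_csv(paths["truth_samples"], sep="\t", index=False, float_format="%.10f")
    manifest = dict(sim.manifest)
    manifest["files"] = {k: {"name": p.name, "sha256": _sha256(p)} for k, p in paths.items()}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return {k: str(p) for k, p in {**paths, "manifest": out / "manifest.json"}.items()}
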