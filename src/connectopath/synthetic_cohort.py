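"""Synthetic cohort generator: connectivity matrices + phenotypes with
planted, recoverable effects.

Matrices are drawn from a shared geometric backbone (random 3-D region
positions, distance-decayed connection probabilities, log-normal weights)
with per-subject presence draws and weight jitter. The group effect is
planted as multiplicative attenuation of every edge incident to a set of
affected regions in ADHD subjects, so reduced local efficiency has to
emerge from the topology rather than being injected into the metrics.
Treatment response is linked linearly to each ADHD subject's measured
global-efficiency AUC plus noise; symptom scores are generated at the item
level (18 items, each 0-3) so scale invariants hold by construction.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .connectome_io import (
    CohortTable,
    ConnectivityMatrix,
    SubjectRecord,
    default_atlas,
    write_cohort_phenotypes,
    write_matrix,
    ValidationError,
)
from .network_metrics import DEFAULT_THRESHOLDS, global_efficiency_auc

#: default affected set: bilateral pallidum, putamen, thalamus and caudate
DEFAULT_AFFECTED_REGIONS: tuple[str, ...] = (
    "left_pallidum",
    "right_pallidum",
    "left_putamen",
    "right_putamen",
    "left_thalamus",
    "right_thalamus",
    "left_caudate",
    "right_caudate",
)


@dataclass
class SimulationConfig:
    n_adhd: int = 37
    n_tdc: int = 26
    n_regions: int = 82
    base_density: float = 0.35
    weight_mu: float = 3.5  # log-scale mean of streamline counts
    weight_sigma: float = 0.8
    weight_jitter_sd: float = 0.15  # per-subject log-normal jitter
    distance_decay: float = 4.0
    affected_regions: Optional[tuple[str, ...]] = None
    adhd_weight_attenuation: float = 0.7
    attenuation_jitter_sd: float = 0.05
    response_beta: float = -4000.0
    response_intercept: Optional[float] = None  # None: centre at mean latent GE
    response_mean_change: float = -35.0
    response_noise_sd: float = 12.0
    age_range: tuple[float, float] = (8.0, 17.0)
    p_male: float = 0.7
    dose_range: tuple[float, float] = (0.3, 1.5)
    p_prior_stimulant: float = 0.3
    prior_duration_mean: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_adhd < 2 or self.n_tdc < 2:
            raise ValidationError("group sizes must be >= 2")
        if not 0 < self.base_density < 1:
            raise ValidationError("base_density must lie in (0, 1)")
        if not 0 < self.adhd_weight_attenuation <= 1:
            raise ValidationError("attenuation must lie in (0, 1]")
        if self.n_regions < 4:
            raise ValidationError("n_regions must be >= 4")

    def region_names(self) -> tuple[str, ...]:
        if self.n_regions == 82:
            return default_atlas().names
        return tuple(f"region_{i:02d}" for i in range(self.n_regions))

    def resolved_affected(self) -> tuple[str, ...]:
        names = self.region_names()
        if self.affected_regions is not None:
            for r in self.affected_regions:
                if r not in names:
                    raise ValidationError(f"affected region {r!r} not in atlas")
            return tuple(self.affected_regions)
        if self.n_regions == 82:
            return DEFAULT_AFFECTED_REGIONS
        return names[: max(2, self.n_regions // 10)]


def null_config(**overrides) -> SimulationConfig:
    """Config with every planted effect switched off (calibration runs)."""
    base = dict(adhd_weight_attenuation=1.0, response_beta=0.0)
    base.update(overrides)
    return SimulationConfig(**base)


@dataclass
class GroundTruth:
    affected_regions: tuple[str, ...]
    true_response_beta: float
    latent_global_efficiency: dict[str, float]
    responders: dict[str, bool]
    config: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "affected_regions": list(self.affected_regions),
            "true_response_beta": self.true_response_beta,
            "latent_global_efficiency": self.latent_global_efficiency,
            "responders": self.responders,
            "config": self.config,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# Backbone (shared across subjects, derived only from config)
# ---------------------------------------------------------------------------


def _backbone(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Edge probabilities and base weights on the upper triangle."""
    rng = np.random.default_rng([config.seed, 1])
    n = config.n_regions
    pos = rng.uniform(0.0, 1.0, size=(n, 3))
    iu, ju = np.triu_indices(n, 1)
    d = np.linalg.norm(pos[iu] - pos[ju], axis=1)
    decay = np.exp(-config.distance_decay * d)
    p = config.base_density * decay / decay.mean()
    p = np.clip(p, 0.0, 0.98)
    base_w = rng.lognormal(mean=config.weight_mu, sigma=config.weight_sigma, size=len(iu))
    return p, base_w


# ---------------------------------------------------------------------------
# Matrices
# ---------------------------------------------------------------------------


def simulate_matrix(
    config: SimulationConfig,
    subject_group: str,
    rng: np.random.Generator,
    subject_id: str = "sim",
) -> ConnectivityMatrix:
    """Draw one subject's symmetric non-negative connectivity matrix."""
    if subject_group not in ("ADHD", "TDC"):
        raise ValidationError(f"unknown group: {subject_group!r}")
    n = config.n_regions
    names = config.region_names()
    p, base_w = _backbone(config)
    iu, ju = np.triu_indices(n, 1)
    present = rng.random(len(iu)) < p
    jitter = rng.lognormal(mean=0.0, sigma=config.weight_jitter_sd, size=len(iu))
    vals = np.where(present, base_w * jitter, 0.0)
    if subject_group == "ADHD" and config.adhd_weight_attenuation < 1.0:
        factor = config.adhd_weight_attenuation * rng.lognormal(
            0.0, config.attenuation_jitter_sd
        )
        affected_idx = {names.index(r) for r in config.resolved_affected()}
        touches = np.fromiter(
            ((i in affected_idx) or (j in affected_idx) for i, j in zip(iu, ju)),
            dtype=bool,
            count=len(iu),
        )
        vals = np.where(touches, vals * factor, vals)
    w = np.zeros((n, n))
    w[iu, ju] = vals
    w += w.T
    return ConnectivityMatrix(subject_id=subject_id, regions=names, weights=w)


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

_ADHD_ITEM_P = (0.05, 0.25, 0.40, 0.30)
_TDC_ITEM_P = (0.70, 0.22, 0.06, 0.02)
_SUBTYPES = ("combined", "inattentive", "hyperactive")
_SUBTYPE_P = (0.55, 0.35, 0.10)


def _draw_items(rng: np.random.Generator, probs, lo: int, hi: int) -> np.ndarray:
    """18 item scores (0-3) whose total falls in [lo, hi]."""
    for _ in range(1000):
        items = rng.choice(4, size=18, p=probs)
        if lo <= items.sum() <= hi:
            return items
    raise RuntimeError("could not draw item scores in range")  # pragma: no cover


def _adjust_items_to_total(
    items: np.ndarray, target: int, rng: np.random.Generator
) -> np.ndarray:
    out = items.copy()
    while out.sum() > target:
        candidates = np.flatnonzero(out > 0)
        out[rng.choice(candidates)] -= 1
    while out.sum() < target:
        candidates = np.flatnonzero(out < 3)
        out[rng.choice(candidates)] += 1
    return out


def simulate_phenotypes(
    config: SimulationConfig,
    latent_ge: Sequence[float],
    rng: np.random.Generator,
) -> list[SubjectRecord]:
    """Generate phenotype records; ``latent_ge`` has one value per ADHD subject.

    Percent symptom change for ADHD subjects is
    ``intercept + response_beta * latent_ge + N(0, response_noise_sd)``,
    realized through integer week-6 item scores (so recorded changes are
    quantized and clamped to the scale).
    """
    if len(latent_ge) != config.n_adhd:
        raise ValidationError("latent_ge must have one entry per ADHD subject")
    latent_ge = np.asarray(latent_ge, dtype=float)
    if config.response_intercept is not None:
        intercept = config.response_intercept
    else:
        intercept = config.response_mean_change - config.response_beta * float(
            np.mean(latent_ge)
        )
    streams = rng.spawn(config.n_adhd + config.n_tdc)
    records: list[SubjectRecord] = []
    for k in range(config.n_adhd):
        r = streams[k]
        sid = f"sub-adhd-{k + 1:03d}"
        items0 = _draw_items(r, _ADHD_ITEM_P, 20, 54)
        total0 = int(items0.sum())
        pct = intercept + config.response_beta * latent_ge[k] + r.normal(
            0.0, config.response_noise_sd
        )
        target6 = int(np.clip(round(total0 * (1 + pct / 100.0)), 0, 54))
        items6 = _adjust_items_to_total(items0, target6, r)
        records.append(
            SubjectRecord(
                subject_id=sid,
                group="ADHD",
                age=float(r.uniform(*config.age_range)),
                gender="male" if r.random() < config.p_male else "female",
                adhd_subtype=str(r.choice(_SUBTYPES, p=_SUBTYPE_P)),
                mph_dose_mg_per_kg=float(r.uniform(*config.dose_range)),
                prior_stimulant_6mo=bool(r.random() < config.p_prior_stimulant),
                prior_stimulant_duration=float(
                    r.exponential(config.prior_duration_mean)
                ),
                adhdrs_total_w0=total0,
                adhdrs_inatt_w0=int(items0[:9].sum()),
                adhdrs_hyper_w0=int(items0[9:].sum()),
                adhdrs_total_w6=int(items6.sum()),
                adhdrs_inatt_w6=int(items6[:9].sum()),
                adhdrs_hyper_w6=int(items6[9:].sum()),
            )
        )
    for k in range(config.n_tdc):
        r = streams[config.n_adhd + k]
        sid = f"sub-tdc-{k + 1:03d}"
        items0 = _draw_items(r, _TDC_ITEM_P, 0, 12)
        records.append(
            SubjectRecord(
                subject_id=sid,
                group="TDC",
                age=float(r.uniform(*config.age_range)),
                gender="male" if r.random() < config.p_male else "female",
                adhdrs_total_w0=int(items0.sum()),
                adhdrs_inatt_w0=int(items0[:9].sum()),
                adhdrs_hyper_w0=int(items0[9:].sum()),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Full cohort
# ---------------------------------------------------------------------------


def simulate_cohort(
    config: SimulationConfig, out_dir: Optional[str | Path] = None
) -> tuple[CohortTable, GroundTruth]:
    """Generate the full cohort; optionally write it to disk.

    Per-subject RNG streams are derived as ``default_rng([seed, 2, index])``
    so adding subjects never perturbs existing subjects' matrices.
    """
    n_total = config.n_adhd + config.n_tdc
    groups = ["ADHD"] * config.n_adhd + ["TDC"] * config.n_tdc
    matrices: list[ConnectivityMatrix] = []
    for idx in range(n_total):
        rng = np.random.default_rng([config.seed, 2, idx])
        matrices.append(simulate_matrix(config, groups[idx], rng))
    latent_ge = [
        global_efficiency_auc(matrices[k], DEFAULT_THRESHOLDS)
        for k in range(config.n_adhd)
    ]
    pheno_rng = np.random.default_rng([config.seed, 3])
    records = simulate_phenotypes(config, latent_ge, pheno_rng)
    mat_map: dict[str, ConnectivityMatrix] = {}
    for rec, mat in zip(records, matrices):
        mat.subject_id = rec.subject_id
        mat_map[rec.subject_id] = mat
    cohort = CohortTable(subjects=records, matrices=mat_map)

    responders = {}
    for rec in records[: config.n_adhd]:
        pct = 100.0 * (rec.adhdrs_total_w6 - rec.adhdrs_total_w0) / rec.adhdrs_total_w0
        responders[rec.subject_id] = bool(pct < -25.0)
    truth = GroundTruth(
        affected_regions=config.resolved_affected(),
        true_response_beta=config.response_beta,
        latent_global_efficiency={
            records[k].subject_id: latent_ge[k] for k in range(config.n_adhd)
        },
        responders=responders,
        config=dataclasses.asdict(config),
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        (out_dir / "matrices").mkdir(parents=True, exist_ok=True)
        write_cohort_phenotypes(records, out_dir / "cohort.csv")
        for sid, mat in mat_map.items():
            write_matrix(mat, out_dir / "matrices" / f"{sid}.csv")
        truth.to_json(out_dir / "ground_truth.json")
    return cohort, truth
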