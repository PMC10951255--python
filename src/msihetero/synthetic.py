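"""Synthetic MSI cohort generator with planted ground truth.

Each patient is a small pixel grid partitioned into spatially coherent
Voronoi patches, each patch assigned to one of ``k_true`` metabolic
subpopulations drawn from a per-patient Dirichlet composition. Spectra are
log-normal baselines with subpopulation-specific signature channels scaled
up multiplicatively. Survival follows an exponential model whose hazard is
multiplied when the risk subpopulation is sufficiently present; response
labels are derived from observed survival at a cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from msihetero.types import (
    RESPONSE_UNKNOWN,
    PatientDatacube,
    SurvivalRecord,
    derive_response,
)

__all__ = ["CohortConfig", "SyntheticCohort", "generate_cohort", "truth_presence"]


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort generator."""

    n_patients: int = 45
    grid_shape: tuple[int, int] = (20, 20)  # (rows, cols)
    n_channels: int = 300
    mz_range: tuple[float, float] = (50.0, 1000.0)
    k_true: int = 4
    signature_effect: float = 4.0
    n_signature_channels_per_subpop: int = 5
    dirichlet_alpha: float = 1.0
    risk_subpop: int = 1  # 1-based subpopulation index
    hazard_ratio: float = 3.0
    baseline_median_survival: float = 14.0
    censoring_rate: float = 0.2
    response_cutoff: float = 13.8
    noise_cv: float = 0.2
    # spread of the per-channel baseline log-mean (drawn once per cohort)
    baseline_mu_scale: float = 0.5
    # a patient carries the planted risk iff its true share of risk_subpop
    # strictly exceeds this fraction
    risk_presence_fraction: float = 0.25
    # Voronoi patches per patient = patches_per_subpop * k_true
    patches_per_subpop: int = 3
    seed: int = 0

    def validate(self) -> None:
        numeric = [
            self.signature_effect,
            self.dirichlet_alpha,
            self.hazard_ratio,
            self.baseline_median_survival,
            self.censoring_rate,
            self.response_cutoff,
            self.noise_cv,
            self.risk_presence_fraction,
            *self.mz_range,
        ]
        if not all(math.isfinite(v) for v in numeric):
            raise ValueError("all numeric config values must be finite")
        if self.k_true < 2:
            raise ValueError("k_true must be >= 2")
        if self.grid_shape[0] * self.grid_shape[1] < self.k_true:
            raise ValueError("grid must hold at least k_true pixels")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not (0 <= self.censoring_rate < 1):
            raise ValueError("censoring_rate must be in [0, 1)")
        if not (0 < self.risk_presence_fraction < 1):
            raise ValueError("risk_presence_fraction must be in (0, 1)")
        if self.signature_effect <= 0 or self.hazard_ratio <= 0:
            raise ValueError("signature_effect and hazard_ratio must be > 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if not (1 <= self.risk_subpop <= self.k_true):
            raise ValueError("risk_subpop must be in 1..k_true")
        if self.k_true * self.n_signature_channels_per_subpop > self.n_channels:
            raise ValueError("signature channel sets exceed available channels")
        if self.mz_range[1] <= self.mz_range[0]:
            raise ValueError("mz_range must be increasing")


@dataclass
class SyntheticCohort:
    """A generated cohort plus its planted ground truth."""

    config: CohortConfig
    datacubes: list[PatientDatacube]
    truth_labels: dict[str, np.ndarray]  # 1-based subpopulation per pixel
    truth_composition: np.ndarray  # n_patients x k_true, rows sum to 1
    survival: list[SurvivalRecord]
    signature_channels: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def patient_ids(self) -> list[str]:
        return [c.patient_id for c in self.datacubes]

    @property
    def response(self) -> np.ndarray:
        return np.array([s.response for s in self.survival])


def _voronoi_labels(rng, grid_shape, n_patches, patch_subpops):
    rows, cols = grid_shape
    seeds = rng.uniform(low=(0, 0), high=(cols, rows), size=(n_patches, 2))
    xs, ys = np.meshgrid(np.arange(cols), np.arange(rows))
    pts = np.stack([xs.ravel() + 0.5, ys.ravel() + 0.5], axis=1)
    d2 = ((pts[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    patch = np.argmin(d2, axis=1)
    coords = np.stack([xs.ravel(), ys.ravel()], axis=1)
    return coords, patch_subpops[patch]


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a deterministic synthetic cohort from ``config``.

    All randomness flows from ``config.seed`` through a single
    ``numpy.random.Generator``, so repeated calls are bit-identical.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    k = config.k_true
    n_ch = config.n_channels

    lo, hi = config.mz_range
    width = (hi - lo) / n_ch
    channels = lo + (np.arange(n_ch) + 0.5) * width

    # per-channel baseline log-mean, drawn once per cohort
    mu = rng.normal(loc=0.0, scale=config.baseline_mu_scale, size=n_ch)
    perm = rng.permutation(n_ch)
    nsig = config.n_signature_channels_per_subpop
    signature = {
        s + 1: np.sort(perm[s * nsig : (s + 1) * nsig]) for s in range(k)
    }
    log_effect = np.zeros((k, n_ch))
    for s in range(k):
        log_effect[s, signature[s + 1]] = np.log(config.signature_effect)

    n_patches = config.patches_per_subpop * k
    datacubes: list[PatientDatacube] = []
    truth_labels: dict[str, np.ndarray] = {}
    truth_comp = np.zeros((config.n_patients, k))
    width_id = max(3, len(str(config.n_patients)))

    for p in range(config.n_patients):
        pid = f"P{p + 1:0{width_id}d}"
        comp_weights = rng.dirichlet(np.full(k, config.dirichlet_alpha))
        patch_subpops = rng.choice(k, size=n_patches, p=comp_weights) + 1
        coords, labels = _voronoi_labels(rng, config.grid_shape, n_patches, patch_subpops)
        n_pix = coords.shape[0]
        z = rng.standard_normal((n_pix, n_ch))
        log_int = mu[None, :] + log_effect[labels - 1] + config.noise_cv * z
        intensities = np.exp(log_int)
        cube = PatientDatacube(pid, coords, channels, intensities)
        datacubes.append(cube)
        truth_labels[pid] = labels
        truth_comp[p] = np.bincount(labels - 1, minlength=k) / n_pix

    # survival: exponential, hazard scaled when risk subpopulation is present
    lam0 = math.log(2.0) / config.baseline_median_survival
    at_risk = truth_comp[:, config.risk_subpop - 1] > config.risk_presence_fraction
    lam = lam0 * np.where(at_risk, config.hazard_ratio, 1.0)
    event_times = rng.exponential(1.0 / lam)
    censored = rng.random(config.n_patients) < config.censoring_rate
    censor_frac = rng.random(config.n_patients)
    times = np.where(censored, np.maximum(event_times * censor_frac, 1e-9), event_times)
    events = (~censored).astype(int)

    survival = [
        SurvivalRecord(
            patient_id=datacubes[i].patient_id,
            time=float(times[i]),
            event=int(events[i]),
            response=derive_response(float(times[i]), int(events[i]), config.response_cutoff),
        )
        for i in range(config.n_patients)
    ]

    return SyntheticCohort(
        config=replace(config),
        datacubes=datacubes,
        truth_labels=truth_labels,
        truth_composition=truth_comp,
        survival=survival,
        signature_channels=signature,
    )


def truth_presence(cohort: SyntheticCohort, threshold: float) -> np.ndarray:
    """Binary patients x k_true matrix: 1 iff true share strictly exceeds threshold."""
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    return (cohort.truth_composition > threshold).astype(int)


def response_mask(cohort: SyntheticCohort) -> np.ndarray:
    """Boolean mask of patients with a known response label."""
    return cohort.response != RESPONSE_UNKNOWN
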