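"""Shared domain types for the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

RESPONSE_SENSITIVE = 1
RESPONSE_RESISTANT = 0
RESPONSE_UNKNOWN = -1


@dataclass
class PatientDatacube:
    """One patient's MSI data: per-pixel intensity vectors over shared m/z channels.

    Attributes
    ----------
    patient_id : str
        Unique patient/sample identifier.
    coords : ndarray of shape (n_pixels, 2), int
        0-based integer pixel positions, columns ``(x, y)`` with x = column,
        y = row.
    channels : ndarray of shape (n_channels,), float
        m/z values in Da, strictly increasing.
    intensities : ndarray of shape (n_pixels, n_channels), float
        Non-negative, finite intensities.
    """

    patient_id: str
    coords: np.ndarray
    channels: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=int)
        self.channels = np.asarray(self.channels, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)

    @property
    def n_pixels(self) -> int:
        return self.coords.shape[0]

    @property
    def n_channels(self) -> int:
        return self.channels.shape[0]

    def validate(self) -> None:
        """Raise ValueError on any violated structural invariant."""
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must have shape (n_pixels, 2)")
        if self.intensities.shape != (self.n_pixels, self.n_channels):
            raise ValueError(
                f"intensities shape {self.intensities.shape} does not match "
                f"({self.n_pixels}, {self.n_channels})"
            )
        if len({tuple(c) for c in self.coords}) != self.n_pixels:
            raise ValueError(f"duplicate pixel coordinates in patient {self.patient_id}")
        if self.n_channels >= 2 and not np.all(np.diff(self.channels) > 0):
            raise ValueError("channels must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")

    def copy_with(self, **kwargs) -> "PatientDatacube":
        base = dict(
            patient_id=self.patient_id,
            coords=self.coords.copy(),
            channels=self.channels.copy(),
            intensities=self.intensities.copy(),
        )
        base.update(kwargs)
        return PatientDatacube(**base)


@dataclass
class SegmentationResult:
    """Per-K clustering output over the pooled cohort.

    ``labels`` maps patient_id to a 1-based label per pixel (aligned with the
    patient's coords order). Centroids live in row-standardised space (zero
    mean, computed as the mean of assigned standardised spectra).
    """

    k: int
    labels: dict[str, np.ndarray]
    centroids: np.ndarray
    inertia: float
    n_dropped_pixels: int = 0

    def global_cluster_sizes(self) -> np.ndarray:
        sizes = np.zeros(self.k, dtype=int)
        for lab in self.labels.values():
            sizes += np.bincount(lab - 1, minlength=self.k)
        return sizes


@dataclass
class ClusterComposition:
    """Share of a patient's pixels in each of K subpopulations."""

    patient_id: str
    shares: np.ndarray
    n_pixels: int

    def __post_init__(self) -> None:
        self.shares = np.asarray(self.shares, dtype=float)
        if np.any(self.shares < 0):
            raise ValueError("shares must be non-negative")
        if abs(self.shares.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"shares of patient {self.patient_id} sum to {self.shares.sum()}, not 1"
            )

    @property
    def k(self) -> int:
        return self.shares.shape[0]


@dataclass
class SurvivalRecord:
    """Survival time (months), event indicator and derived response label.

    ``response`` is 1 (sensitive: overall survival beyond the cutoff),
    0 (resistant: observed event at or before the cutoff) or -1 (unknown:
    censored at or before the cutoff).
    """

    patient_id: str
    time: float
    event: int
    response: int = RESPONSE_UNKNOWN

    def __post_init__(self) -> None:
        if not (self.time > 0):
            raise ValueError(f"survival time must be > 0, got {self.time}")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


def derive_response(time: float, event: int, cutoff: float = 13.8) -> int:
    """Dichotomise overall survival at ``cutoff`` months.

    Survival beyond the cutoff is sensitive regardless of censoring; an
    observed event at or before the cutoff is resistant; censoring at or
    before the cutoff leaves the label unknown.
    """
    if time > cutoff:
        return RESPONSE_SENSITIVE
    if event == 1:
        return RESPONSE_RESISTANT
    return RESPONSE_UNKNOWN


@dataclass
class DiversityScore:
    patient_id: str
    D: float
    k_used: int


@dataclass
class DiversitySplit:
    """Cutoff-optimised high/low heterogeneity split.

    ``groups`` maps patient_id to "high" (D strictly above cutoff) or "low".
    ``metadata`` always carries ``selection_bias_caveat=True`` because the
    cutoff was chosen to minimise the log-rank p-value.
    """

    cutoff: float
    groups: dict[str, str]
    p_logrank: float
    robustness: bool
    metadata: dict = field(default_factory=dict)
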