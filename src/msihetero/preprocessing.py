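"""Preprocessing: TIC normalisation, peak selection, spatial denoising.

All operations return new datacubes; inputs are never mutated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from msihetero.types import PatientDatacube

logger = logging.getLogger(__name__)

__all__ = [
    "PeakList",
    "tic_normalize",
    "select_peaks",
    "reduce_to_peaks",
    "denoise_ion_images",
    "subtract_baseline",
]


@dataclass
class PeakList:
    """Selected m/z channels plus the selection statistic per peak."""

    mz: np.ndarray
    provenance: np.ndarray  # cohort-mean normalised intensity per peak
    indices: np.ndarray  # positions in the original channel axis

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        if self.mz.size >= 2 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("peak m/z values must be strictly increasing")

    def __len__(self) -> int:
        return self.mz.size


def tic_normalize(cube: PatientDatacube, drop_empty: bool = False) -> PatientDatacube:
    """Scale each pixel's spectrum to unit total ion count.

    Pixels with zero total intensity raise a ValueError naming the pixel,
    unless ``drop_empty`` is set, in which case they are removed.
    """
    totals = cube.intensities.sum(axis=1)
    empty = totals <= 0
    if empty.any():
        if not drop_empty:
            x, y = cube.coords[np.flatnonzero(empty)[0]]
            raise ValueError(
                f"pixel (x={x}, y={y}) of patient {cube.patient_id} has zero "
                "total intensity; pass drop_empty=True to discard such pixels"
            )
        keep = ~empty
        logger.info(
            "patient %s: dropping %d empty pixel(s)", cube.patient_id, int(empty.sum())
        )
        return PatientDatacube(
            cube.patient_id,
            cube.coords[keep],
            cube.channels,
            cube.intensities[keep] / totals[keep, None],
        )
    return cube.copy_with(intensities=cube.intensities / totals[:, None])


def _local_maxima(mean_spectrum: np.ndarray) -> np.ndarray:
    """Boolean mask of channels that are >= both existing neighbours."""
    m = mean_spectrum
    ok = np.ones(m.size, dtype=bool)
    if m.size > 1:
        ok[1:] &= m[1:] >= m[:-1]
        ok[:-1] &= m[:-1] >= m[1:]
    return ok


def select_peaks(
    cubes: Iterable[PatientDatacube], n_peaks: int, clamp: bool = False
) -> PeakList:
    """Pick the ``n_peaks`` channels of highest cohort-mean normalised
    intensity among local maxima of the cohort-mean spectrum.

    Ties in the mean are broken toward the lower m/z. Deterministic and
    invariant to the order of the input cubes. Asking for more peaks than
    there are local maxima raises, unless ``clamp`` allows returning all
    available maxima.
    """
    cubes = list(cubes)
    if not cubes:
        raise ValueError("no datacubes given")
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    channels = cubes[0].channels
    for c in cubes[1:]:
        if c.channels.shape != channels.shape or not np.allclose(c.channels, channels):
            raise ValueError("all datacubes must share identical channels")
    if n_peaks > channels.size:
        raise ValueError("n_peaks exceeds channel count")

    total = np.zeros(channels.size)
    n_pix = 0
    for c in cubes:
        norm = tic_normalize(c, drop_empty=True)
        total += norm.intensities.sum(axis=0)
        n_pix += norm.n_pixels
    mean = total / n_pix

    candidates = np.flatnonzero(_local_maxima(mean))
    if candidates.size < n_peaks:
        if not clamp:
            raise ValueError(
                f"only {candidates.size} local maxima available, need {n_peaks}"
            )
        logger.info("clamping n_peaks from %d to %d local maxima", n_peaks, candidates.size)
        n_peaks = candidates.size
    # stable sort by descending mean; stability keeps lower m/z first on ties
    order = np.argsort(-mean[candidates], kind="stable")
    chosen = np.sort(candidates[order[:n_peaks]])
    return PeakList(mz=channels[chosen], provenance=mean[chosen], indices=chosen)


def reduce_to_peaks(cube: PatientDatacube, peaks: PeakList) -> PatientDatacube:
    """Restrict a datacube to the selected peak channels."""
    idx = np.searchsorted(cube.channels, peaks.mz)
    if np.any(idx >= cube.channels.size) or not np.allclose(cube.channels[idx], peaks.mz):
        raise ValueError("peak m/z values not present in the cube's channel axis")
    return cube.copy_with(channels=cube.channels[idx], intensities=cube.intensities[:, idx])


def denoise_ion_images(cube: PatientDatacube, window: int = 3) -> PatientDatacube:
    """Spatial median filter applied per ion image (edge-preserving denoising).

    Each pixel's value per channel becomes the median over the window x window
    neighbourhood of pixels present in the cube; absent neighbours are
    ignored. ``window=1`` is the identity.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    if window == 1:
        return cube.copy_with()

    xs, ys = cube.coords[:, 0], cube.coords[:, 1]
    w = int(xs.max()) + 1
    h = int(ys.max()) + 1
    m = cube.n_channels
    img = np.full((h, w, m), np.nan)
    img[ys, xs, :] = cube.intensities

    r = window // 2
    padded = np.pad(img, ((r, r), (r, r), (0, 0)), constant_values=np.nan)
    stack = np.empty((window * window, h, w, m))
    idx = 0
    for dy in range(window):
        for dx in range(window):
            stack[idx] = padded[dy : dy + h, dx : dx + w, :]
            idx += 1
    with np.errstate(all="ignore"):
        out = np.nanmedian(stack, axis=0)
    return cube.copy_with(intensities=out[ys, xs, :])


def subtract_baseline(cube: PatientDatacube, window: int = 51) -> PatientDatacube:
    """Optional moving-minimum baseline subtraction along the m/z axis.

    A no-op for already peak-picked data; intended for profile-mode input.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    if window == 1:
        return cube.copy_with()
    from scipy.ndimage import minimum_filter1d

    baseline = minimum_filter1d(cube.intensities, size=window, axis=1, mode="nearest")
    return cube.copy_with(intensities=cube.intensities - baseline)


def preprocess_cohort(
    cubes: Sequence[PatientDatacube],
    n_peaks: int,
    denoise_window: int = 3,
    drop_empty: bool = True,
) -> tuple[list[PatientDatacube], PeakList]:
    """Standard preprocessing chain: TIC -> denoise -> peak reduction.

    Peak selection runs on the normalised (pre-denoising) cohort mean; the
    denoised, normalised cubes are then reduced to the selected channels and
    re-normalised so pixel spectra sum to 1 over the peak set.
    """
    normed = [tic_normalize(c, drop_empty=drop_empty) for c in cubes]
    peaks = select_peaks(normed, n_peaks=n_peaks, clamp=True)
    out = []
    for c in normed:
        c = denoise_ion_images(c, window=denoise_window)
        c = reduce_to_peaks(c, peaks)
        c = tic_normalize(c, drop_empty=drop_empty)
        out.append(c)
    return out, peaks
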