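"""Synchronous-scan shifts, excitation-emission-matrix peaks, CD bands.

Three structural probes that complement the quenching analysis:

* Synchronous fluorescence (fixed excitation-emission offset; 15 nm probes
  tyrosine, 60 nm tryptophan).  A red/blue shift of the band maximum on
  titration signals a polarity change around the fluorophores; sub-grid
  shifts are resolved by parabolic interpolation around the grid maximum.
* 3D excitation-emission matrices (EEM).  Fluorophore peaks are local
  maxima away from the first-order Rayleigh scatter ridge (lambda_ex =
  lambda_em), which is masked within a diagonal tolerance.
* Circular dichroism.  Only qualitative band descriptors (extremum
  positions and signs) are extracted — e.g. a positive band near 185 nm
  with a negative band near 200 nm is the canonical beta-sheet signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .errors import ValidationError

__all__ = [
    "SyncSeries",
    "SyncShiftResult",
    "EEM",
    "PeakRecord",
    "CDBands",
    "sync_shift",
    "eem_peaks",
    "peak_attenuation",
    "cd_bands",
]


@dataclass(frozen=True)
class SyncSeries:
    """Synchronous scans at graded quencher concentrations."""

    delta_lambda: float  # nm offset between excitation and emission
    quencher_concs: np.ndarray
    wavelengths: np.ndarray
    intensities: np.ndarray  # (n_conc, n_wavelength)

    def __post_init__(self):
        concs = np.asarray(self.quencher_concs, dtype=float)
        wl = np.asarray(self.wavelengths, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "quencher_concs", concs)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "intensities", inten)
        if concs[0] != 0:
            raise ValidationError("first concentration must be 0")
        if np.any(np.diff(wl) <= 0):
            raise ValidationError("wavelength grid must be strictly increasing")
        if inten.shape != (concs.size, wl.size):
            raise ValidationError("intensity matrix does not match grids")


@dataclass(frozen=True)
class SyncShiftResult:
    peaks: tuple  # per concentration: (lambda_max nm, peak intensity)
    verdict: str  # "red", "blue" or "none"
    shift_nm: float  # lambda_max(last) - lambda_max(first)


@dataclass(frozen=True)
class EEM:
    """Excitation-emission matrix on strictly increasing nm grids."""

    ex_grid: np.ndarray
    em_grid: np.ndarray
    intensity: np.ndarray  # (n_ex, n_em)

    def __post_init__(self):
        ex = np.asarray(self.ex_grid, dtype=float)
        em = np.asarray(self.em_grid, dtype=float)
        z = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "ex_grid", ex)
        object.__setattr__(self, "em_grid", em)
        object.__setattr__(self, "intensity", z)
        if np.any(np.diff(ex) <= 0) or np.any(np.diff(em) <= 0):
            raise ValidationError("EEM grids must be strictly increasing")
        if z.shape != (ex.size, em.size):
            raise ValidationError(
                f"intensity shape {z.shape} does not match grids "
                f"({ex.size} x {em.size})"
            )


@dataclass(frozen=True)
class PeakRecord:
    ex: float  # nm
    em: float  # nm
    intensity: float
    kind: str  # "fluorophore" or "rayleigh"


@dataclass(frozen=True)
class CDBands:
    extrema: tuple  # (wavelength nm, ellipticity, sign) with sign in {+1,-1}


def _parabolic_peak(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sub-grid peak position by a 3-point parabola around the argmax.

    Raises ValidationError when the maximum sits on the boundary or the
    scan is flat (no interior maximum).
    """
    i = int(np.argmax(y))
    if i == 0 or i == y.size - 1 or (y.max() == y.min()):
        raise ValidationError("scan has no interior maximum")
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:  # locally flat top: keep the grid point
        return float(x[i]), float(y1)
    delta = 0.5 * (y0 - y2) / denom
    step = x[i + 1] - x[i] if delta >= 0 else x[i] - x[i - 1]
    peak_x = x[i] + delta * step
    peak_y = y1 - 0.25 * (y0 - y2) * delta
    return float(peak_x), float(peak_y)


def sync_shift(series: SyncSeries, shift_tol: float = 2.0) -> SyncShiftResult:
    """Locate each scan's band maximum and judge the titration shift.

    The verdict compares the last scan's maximum with the zero-quencher
    scan's: displacement beyond ``shift_tol`` nm to longer wavelengths is
    "red", to shorter "blue", otherwise "none".  Invariant under uniform
    intensity rescaling.
    """
    if series.intensities.shape[0] < 2:
        raise ValidationError("shift analysis needs >= 2 scans")
    peaks = [
        _parabolic_peak(series.wavelengths, row) for row in series.intensities
    ]
    shift = peaks[-1][0] - peaks[0][0]
    if abs(shift) <= shift_tol:
        verdict = "none"
    elif shift > 0:
        verdict = "red"
    else:
        verdict = "blue"
    return SyncShiftResult(peaks=tuple(peaks), verdict=verdict, shift_nm=float(shift))


def eem_peaks(
    eem: EEM,
    diagonal_tol: float = 10.0,
    min_prominence: float = 0.05,
    mask_second_order: bool = False,
) -> list[PeakRecord]:
    """Pick fluorophore peaks off the scatter ridge of an EEM.

    Fluorophore peaks are strict local maxima over their 8-neighbourhood,
    at least ``min_prominence`` of the global maximum, and farther than
    ``diagonal_tol`` nm from the first-order Rayleigh diagonal (and, when
    ``mask_second_order`` is set, from the em = 2*ex ridge).  They are
    returned sorted by descending intensity, followed by one record for
    the brightest cell of the Rayleigh band when that band carries signal.
    """
    z = eem.intensity
    zmax = z.max()
    if zmax <= 0:
        return []
    exg = eem.ex_grid[:, None]
    emg = eem.em_grid[None, :]
    diag = np.abs(exg - emg) <= diagonal_tol
    if mask_second_order:
        diag |= np.abs(2 * exg - emg) <= diagonal_tol

    footprint = np.ones((3, 3), dtype=bool)
    footprint[1, 1] = False
    neighbour_max = ndimage.maximum_filter(
        z, footprint=footprint, mode="constant", cval=-np.inf
    )
    local_max = (z > neighbour_max) & (z >= min_prominence * zmax) & ~diag

    records = []
    for i, j in zip(*np.nonzero(local_max)):
        records.append(
            PeakRecord(
                ex=float(eem.ex_grid[i]),
                em=float(eem.em_grid[j]),
                intensity=float(z[i, j]),
                kind="fluorophore",
            )
        )
    records.sort(key=lambda r: -r.intensity)

    band = np.where(diag, z, -np.inf)
    if band.max() >= min_prominence * zmax:
        i, j = np.unravel_index(int(np.argmax(band)), z.shape)
        records.append(
            PeakRecord(
                ex=float(eem.ex_grid[i]),
                em=float(eem.em_grid[j]),
                intensity=float(z[i, j]),
                kind="rayleigh",
            )
        )
    return records


def peak_attenuation(
    before: PeakRecord, after: PeakRecord, position_tol: float = 2.0
) -> float:
    """Intensity ratio after/before for one peak tracked across samples.

    The two records must sit at the same (ex, em) position within
    ``position_tol`` nm; a mismatch means they are different peaks and is
    an error, not a ratio.
    """
    if abs(before.ex - after.ex) > position_tol or abs(before.em - after.em) > position_tol:
        raise ValidationError(
            f"peak positions differ beyond {position_tol} nm: "
            f"({before.ex}/{before.em}) vs ({after.ex}/{after.em})"
        )
    if before.intensity <= 0:
        raise ValidationError("reference peak intensity must be positive")
    return float(after.intensity / before.intensity)


def cd_bands(
    wavelengths: np.ndarray,
    ellipticity: np.ndarray,
    smooth_window: int = 3,
    min_amplitude_frac: float = 0.02,
) -> CDBands:
    """Local extrema of a lightly smoothed CD spectrum, with signs.

    A moving average (default window 3) suppresses single-point noise; an
    extremum is kept when its magnitude exceeds ``min_amplitude_frac`` of
    the largest absolute ellipticity.  A flat (all-zero) spectrum yields an
    empty list.
    """
    wl = np.asarray(wavelengths, dtype=float)
    y = np.asarray(ellipticity, dtype=float)
    if wl.size < 20:
        raise ValidationError("CD spectrum needs >= 20 points")
    if wl[-1] - wl[0] < 40:
        raise ValidationError("CD spectrum must span >= 40 nm")
    if np.any(np.diff(wl) <= 0):
        raise ValidationError("wavelengths must be strictly increasing")

    kernel = np.ones(smooth_window) / smooth_window
    ys = np.convolve(y, kernel, mode="same")
    scale = np.abs(ys).max()
    if scale == 0:
        return CDBands(extrema=())

    extrema = []
    maxima, _ = signal.find_peaks(ys)
    minima, _ = signal.find_peaks(-ys)
    for i in maxima:
        if abs(ys[i]) >= min_amplitude_frac * scale:
            extrema.append((float(wl[i]), float(ys[i]), 1 if ys[i] > 0 else -1))
    for i in minima:
        if abs(ys[i]) >= min_amplitude_frac * scale:
            extrema.append((float(wl[i]), float(ys[i]), 1 if ys[i] > 0 else -1))
    extrema.sort(key=lambda e: e[0])
    return CDBands(extrema=tuple(extrema))
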