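"""Synthetic instrument data with known ground truth.

Every input class the analysis pipeline consumes can be generated here
with its true parameters recorded in the output metadata, so each stage is
testable by round trip: simulate with known (Ksv, Ka, n, tau_i, ...), run
the estimator, compare with truth.

The defaults mirror the pepsin-deferasirox study conditions: protein fixed
at 1.6e-5 mol/L, quencher ladder 0-24 uM in 4 uM steps, tryptophan-band
emission near 345 nm excited at 280 nm, tri-exponential decays with a
dominant ~5.7 ns component, and an EEM on the 200-400 nm range scanned
every 5 nm.

Noise models: multiplicative Gaussian for steady-state spectra (a shot- and
gain-noise proxy), Poisson counting noise for TCSPC histograms.  All
generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import ValidationError
from .lifetime import DecayCurve
from .quenching import TitrationSeries
from .spectral import EEM, SyncSeries
from .trajectory import Atom, Trajectory

__all__ = [
    "QuenchSimSpec",
    "DecaySimSpec",
    "TrajSimSpec",
    "DEFAULT_QUENCHER_LADDER",
    "simulate_titration",
    "simulate_decay",
    "simulate_eem",
    "simulate_trajectory",
    "simulate_sync_series",
    "simulate_cd_spectrum",
    "simulate_activity_rows",
]

#: Quencher ladder of the study design: 0-24 uM in 4 uM steps (mol/L).
DEFAULT_QUENCHER_LADDER = (0.0, 4e-6, 8e-6, 1.2e-5, 1.6e-5, 2e-5, 2.4e-5)

#: Protein concentration of the study design (mol/L).
DEFAULT_PROTEIN_CONC = 1.6e-5


@dataclass(frozen=True)
class QuenchSimSpec:
    """Ground truth for a static-quenching titration.

    ``ksv_true`` drives the Stern-Volmer law F = F0 / (1 + Ksv q);
    ``ka_true``/``n_true`` drive the double-log binding law
    F = F0 / (1 + Ka q**n).  Concentrations are total added ligand.
    """

    ksv_true: float  # L/mol
    ka_true: float  # L/mol
    n_true: float = 1.0
    f0_peak: float = 1000.0  # arbitrary units
    peak_wavelength: float = 345.0  # nm
    peak_width: float = 25.0  # Gaussian sigma, nm
    quencher_concs: tuple = DEFAULT_QUENCHER_LADDER
    noise_sd: float = 0.0  # relative
    seed: int = 0

    def __post_init__(self):
        if self.ksv_true <= 0 or self.ka_true <= 0 or self.n_true <= 0:
            raise ValidationError("Ksv, Ka and n must all be positive")
        concs = np.asarray(self.quencher_concs, dtype=float)
        if concs.size < 1 or concs[0] != 0:
            raise ValidationError("concentration ladder must start at 0")
        if np.any(concs < 0) or np.any(np.diff(concs) <= 0):
            raise ValidationError(
                "concentration ladder must be non-negative and strictly increasing"
            )
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.f0_peak <= 0 or self.peak_width <= 0:
            raise ValidationError("f0_peak and peak_width must be positive")


@dataclass(frozen=True)
class DecaySimSpec:
    """Ground truth for a multi-exponential TCSPC decay."""

    lifetimes: tuple  # ns
    amplitudes: tuple  # fractions summing to 1
    total_counts: int = 10_000  # counts in the peak channel
    channel_width: float = 0.025  # ns
    n_channels: int = 1024
    seed: int = 0

    def __post_init__(self):
        taus = np.asarray(self.lifetimes, dtype=float)
        amps = np.asarray(self.amplitudes, dtype=float)
        if taus.shape != amps.shape or taus.ndim != 1:
            raise ValidationError("lifetimes and amplitudes must match in length")
        if np.any(taus <= 0):
            raise ValidationError("all lifetimes must be positive")
        if abs(amps.sum() - 1.0) > 1e-9:
            raise ValidationError("amplitudes must sum to 1 (within 1e-9)")
        if self.n_channels < 64:
            raise ValidationError("need at least 64 channels")
        if self.total_counts <= 0 or self.channel_width <= 0:
            raise ValidationError("total_counts and channel_width must be positive")


@dataclass(frozen=True)
class TrajSimSpec:
    """Ground truth for a jittered toy trajectory."""

    n_frames: int
    n_atoms: int
    jitter_sd: float = 0.0  # angstrom, per coordinate
    rigid_motion: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 2:
            raise ValidationError("need at least 2 frames")
        if self.n_atoms < 3:
            raise ValidationError("need at least 3 atoms")
        if self.jitter_sd < 0:
            raise ValidationError("jitter_sd must be >= 0")


def _gaussian_band(wavelengths, center, sigma, height):
    return height * np.exp(-0.5 * ((wavelengths - center) / sigma) ** 2)


def simulate_titration(
    spec: QuenchSimSpec,
    temperature: float = 298.0,
    law: str = "stern_volmer",
    wavelengths: np.ndarray | None = None,
) -> TitrationSeries:
    """Static-quenching titration: a Gaussian emission band attenuated
    uniformly (no spectral shift) as quencher is added.

    law
        ``"stern_volmer"``: F(q) = F0 / (1 + ksv_true * q), the linear
        Stern-Volmer form.  ``"double_log"``: F(q) = F0 / (1 + ka_true *
        q**n_true), which satisfies the double-logarithmic binding relation
        exactly.  The two coincide when n = 1 and Ka = Ksv.
    """
    if wavelengths is None:
        wavelengths = np.arange(300.0, 500.5, 1.0)
    concs = np.asarray(spec.quencher_concs, dtype=float)
    base = _gaussian_band(wavelengths, spec.peak_wavelength, spec.peak_width,
                          spec.f0_peak)
    if law == "stern_volmer":
        factors = 1.0 / (1.0 + spec.ksv_true * concs)
    elif law == "double_log":
        factors = np.where(
            concs > 0, 1.0 / (1.0 + spec.ka_true * concs**spec.n_true), 1.0
        )
    else:
        raise ValidationError(f"unknown quenching law: {law!r}")

    rng = np.random.default_rng(spec.seed)
    inten = factors[:, None] * base[None, :]
    if spec.noise_sd > 0:
        inten = inten * (1.0 + rng.normal(0.0, spec.noise_sd, size=inten.shape))
    return TitrationSeries(
        temperature=float(temperature),
        quencher_concs=concs,
        wavelengths=wavelengths,
        intensities=inten,
        protein_conc=DEFAULT_PROTEIN_CONC,
        meta={
            "ksv_true": spec.ksv_true,
            "ka_true": spec.ka_true,
            "n_true": spec.n_true,
            "f0_peak": spec.f0_peak,
            "law": law,
            "noise_sd": spec.noise_sd,
            "seed": spec.seed,
        },
    )


def simulate_decay(spec: DecaySimSpec) -> DecayCurve:
    """Poisson-noised multi-exponential decay starting at its peak.

    The expected count in channel j at time t_j (channel 0 at t = 0) is
    ``total_counts * sum_i alpha_i exp(-t_j / tau_i)``; no instrument
    response is convolved, matching a tail-fitting analysis.
    """
    t = np.arange(spec.n_channels) * spec.channel_width
    amps = np.asarray(spec.amplitudes, dtype=float)
    taus = np.asarray(spec.lifetimes, dtype=float)
    expected = spec.total_counts * (
        amps[None, :] * np.exp(-t[:, None] / taus[None, :])
    ).sum(axis=1)
    rng = np.random.default_rng(spec.seed)
    counts = rng.poisson(expected)
    return DecayCurve(
        times=t,
        counts=counts,
        meta={
            "lifetimes_true": tuple(taus),
            "amplitudes_true": tuple(amps),
            "total_counts": spec.total_counts,
            "seed": spec.seed,
            "excitation_nm": 280.0,
            "emission_nm": 345.0,
        },
    )


def simulate_eem(
    peaks: list,
    grid_step: float = 5.0,
    rayleigh_height: float = 100.0,
    rayleigh_width: float = 4.0,
    wavelength_range: tuple = (200.0, 400.0),
) -> EEM:
    """EEM on a square nm grid: Gaussian fluorophore peaks plus a
    first-order Rayleigh ridge along lambda_ex = lambda_em.

    ``peaks`` is a list of (ex_nm, em_nm, height, width) tuples whose
    centres must lie inside the grid.
    """
    lo, hi = wavelength_range
    span = hi - lo
    if grid_step <= 0 or abs(span / grid_step - round(span / grid_step)) > 1e-9:
        raise ValidationError(
            f"grid_step {grid_step} does not divide the {lo}-{hi} nm range"
        )
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    ex = grid[:, None]
    em = grid[None, :]
    z = rayleigh_height * np.exp(-0.5 * ((ex - em) / rayleigh_width) ** 2)
    for ex0, em0, height, width in peaks:
        if not (lo <= ex0 <= hi and lo <= em0 <= hi):
            raise ValidationError(
                f"peak centre ({ex0}, {em0}) lies outside the {lo}-{hi} nm grid"
            )
        z = z + height * np.exp(
            -0.5 * (((ex - ex0) ** 2 + (em - em0) ** 2) / width**2)
        )
    return EEM(ex_grid=grid.copy(), em_grid=grid.copy(), intensity=z)


def _base_structure(n_atoms: int) -> np.ndarray:
    """Deterministic helix-like backbone trace: ~3.8 A spacing, non-planar."""
    i = np.arange(n_atoms)
    theta = 2 * np.pi * i / 3.6
    return np.column_stack(
        [2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i]
    )


def simulate_trajectory(spec: TrajSimSpec) -> Trajectory:
    """Toy trajectory: frame 0 is a fixed base structure, later frames add
    iid Gaussian jitter and, optionally, a random rigid rotation +
    translation per frame."""
    rng = np.random.default_rng(spec.seed)
    base = _base_structure(spec.n_atoms)
    coords = np.empty((spec.n_frames, spec.n_atoms, 3))
    coords[0] = base
    for f in range(1, spec.n_frames):
        frame = base + rng.normal(0.0, spec.jitter_sd, size=base.shape) \
            if spec.jitter_sd > 0 else base.copy()
        if spec.rigid_motion:
            rot = Rotation.random(rng=rng)
            frame = rot.apply(frame) + rng.uniform(-20, 20, size=3)
        coords[f] = frame
    atoms = tuple(
        Atom(name="CA", element="C", resname="ALA", resid=i + 1, chain="A")
        for i in range(spec.n_atoms)
    )
    return Trajectory(coords=coords, atoms=atoms,
                      frame_times=100.0 * np.arange(spec.n_frames))


def simulate_sync_series(
    delta_lambda: float = 60.0,
    quencher_concs: tuple = DEFAULT_QUENCHER_LADDER,
    ksv: float = 4.142e4,
    center: float = 280.0,
    shift_per_conc: float = 0.0,
    sigma: float = 12.0,
    height: float = 800.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SyncSeries:
    """Synchronous scans with Stern-Volmer attenuation and an optional
    per-step drift of the band centre (nm per concentration step)."""
    wavelengths = np.arange(200.0, 400.5, 1.0)
    concs = np.asarray(quencher_concs, dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    for k, q in enumerate(concs):
        c = center + shift_per_conc * k
        band = _gaussian_band(wavelengths, c, sigma, height / (1.0 + ksv * q))
        if noise_sd > 0:
            band = band * (1.0 + rng.normal(0.0, noise_sd, size=band.shape))
        rows.append(band)
    return SyncSeries(
        delta_lambda=delta_lambda,
        quencher_concs=concs,
        wavelengths=wavelengths,
        intensities=np.array(rows),
    )


def simulate_cd_spectrum(
    positive_center: float = 185.0,
    negative_center: float = 200.0,
    amplitude: float = 10.0,
    sigma: float = 4.0,
    wavelengths: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Beta-sheet-like CD curve: a positive band below 190 nm and a
    negative band near 200 nm.  Returns (wavelengths, ellipticity)."""
    if wavelengths is None:
        wavelengths = np.arange(175.0, 260.5, 1.0)
    y = _gaussian_band(wavelengths, positive_center, sigma, amplitude) - \
        _gaussian_band(wavelengths, negative_center, sigma, amplitude)
    return wavelengths, y


def simulate_activity_rows(
    quencher_concs: tuple = DEFAULT_QUENCHER_LADDER,
    od_blank: float = 0.500,
    activation_per_molar: float = 2000.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list:
    """OD660 assay rows (conc, od) with a mild linear activation trend,
    emulating a ligand that slightly enhances the enzyme."""
    rng = np.random.default_rng(seed)
    rows = []
    for q in quencher_concs:
        od = od_blank * (1.0 + activation_per_molar * q)
        if noise_sd > 0:
            od *= 1.0 + rng.normal(0.0, noise_sd)
        rows.append((float(q), float(od)))
    return rows
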