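"""Stern-Volmer and double-logarithmic analysis of fluorescence titrations.

A titration series records protein emission spectra at increasing quencher
concentrations [Q].  The intensity ratio F0/F follows the Stern-Volmer law

    F0 / F = 1 + Ksv [Q]

whose slope Ksv, divided by the unquenched lifetime tau0, gives the
bimolecular quenching rate constant Kq = Ksv / tau0.  Diffusion limits Kq
for collisional (dynamic) quenching to roughly 2e10 L/mol/s; values orders
of magnitude above it imply ground-state complex formation (static
quenching).  For static quenchers the double-logarithmic plot

    lg[(F0 - F) / F] = lg Ka + n lg[Q]

yields the binding constant Ka (10**intercept) and the apparent number of
high-affinity sites n (slope).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError

__all__ = [
    "TitrationSeries",
    "QuenchFit",
    "BindingFit",
    "MechanismCall",
    "quench_ratios",
    "stern_volmer_fit",
    "double_log_fit",
    "classify_mechanism",
    "KQ_DIFFUSION_LIMIT",
]

#: Upper bound of the bimolecular quenching rate constant for purely
#: diffusional (dynamic) quenching, L mol^-1 s^-1.
KQ_DIFFUSION_LIMIT = 2e10


@dataclass(frozen=True)
class TitrationSeries:
    """Emission spectra at graded quencher concentrations, one temperature.

    ``intensities`` has one row per concentration on the shared
    ``wavelengths`` grid; the first concentration must be zero (it defines
    F0).  Concentrations are the *total added* ligand, the convention under
    which the Stern-Volmer and double-log models are fitted.
    """

    temperature: float  # K
    quencher_concs: np.ndarray  # mol/L, first element 0
    wavelengths: np.ndarray  # nm
    intensities: np.ndarray  # (n_conc, n_wavelength), arbitrary units
    protein_conc: float = float("nan")  # mol/L
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        concs = np.asarray(self.quencher_concs, dtype=float)
        wl = np.asarray(self.wavelengths, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "quencher_concs", concs)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "intensities", inten)
        if concs.ndim != 1 or concs.size < 1:
            raise ValidationError("need at least one concentration")
        if concs[0] != 0:
            raise ValidationError("first quencher concentration must be 0 (defines F0)")
        if np.any(np.diff(concs) <= 0):
            raise ValidationError("quencher concentrations must be strictly increasing")
        if np.any(np.diff(wl) <= 0):
            raise ValidationError("wavelength grid must be strictly increasing")
        if inten.shape != (concs.size, wl.size):
            raise ValidationError(
                f"intensities shape {inten.shape} does not match "
                f"({concs.size} concentrations, {wl.size} wavelengths)"
            )
        if self.temperature <= 0:
            raise ValidationError("temperature must be positive (kelvin)")


@dataclass(frozen=True)
class QuenchFit:
    """Stern-Volmer regression at one temperature."""

    ksv: float  # L/mol
    ksv_stderr: float
    intercept: float
    r_squared: float
    temperature: float  # K
    kq: float | None = None  # L/mol/s, set when tau0 supplied
    tau0_ns: float | None = None


@dataclass(frozen=True)
class BindingFit:
    """Double-logarithmic binding regression at one temperature."""

    ka: float  # L/mol
    n: float  # binding-site number
    log_ka_intercept: float
    r_squared: float
    temperature: float  # K

    def __post_init__(self):
        if not (self.ka > 0):
            raise ValidationError("Ka must be positive")
        if not (self.n > 0):
            raise ValidationError("n must be positive")


@dataclass(frozen=True)
class MechanismCall:
    """Quenching-mechanism verdict with its evidence trail.

    ``label`` is "static" or "dynamic" only when at least two criteria
    agree and none contradicts; otherwise "inconclusive".
    """

    label: str
    evidence: tuple


def quench_ratios(
    series: TitrationSeries, mode: str | float = "fixed"
) -> list[tuple[float, float]]:
    """F0/F per concentration, including the (0, 1.0) anchor point.

    mode
        ``"fixed"`` (default) reads every spectrum at the wavelength where
        the zero-quencher spectrum peaks — the natural choice when the
        emission maximum does not shift on binding.  ``"peak"`` reads each
        spectrum at its own maximum, ``"integrated"`` uses the band area,
        and a float reads a user wavelength (nearest grid point).
    """
    inten = series.intensities
    if isinstance(mode, (int, float)) and not isinstance(mode, bool):
        idx = int(np.argmin(np.abs(series.wavelengths - float(mode))))
        values = inten[:, idx]
    elif mode == "fixed":
        idx = int(np.argmax(inten[0]))
        values = inten[:, idx]
    elif mode == "peak":
        values = inten.max(axis=1)
    elif mode == "integrated":
        values = np.trapezoid(inten, series.wavelengths, axis=1)
    else:
        raise ValidationError(f"unknown evaluation mode: {mode!r}")

    f0 = values[0]
    if f0 <= 0:
        raise ValidationError("F0 is non-positive at the evaluation wavelength")
    out = []
    for conc, f in zip(series.quencher_concs, values):
        if f <= 0:
            raise ValidationError(
                f"non-positive intensity at quencher concentration {conc:g} mol/L"
            )
        out.append((float(conc), float(f0 / f)))
    out[0] = (0.0, 1.0)  # exact by definition
    return out


def _fit_line(x: np.ndarray, y: np.ndarray):
    """Ordinary least squares y on x; returns (slope, intercept, r2, stderr).

    Accepts two points (exact line, r2 = 1); kept separate from the public
    fitters so their >= 3-point preconditions stay enforceable.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 2:
        slope = (y[1] - y[0]) / (x[1] - x[0])
        return slope, y[0] - slope * x[0], 1.0, 0.0
    res = stats.linregress(x, y)
    return res.slope, res.intercept, res.rvalue**2, res.stderr


def stern_volmer_fit(
    ratios: Sequence[tuple[float, float]],
    temperature: float,
    tau0_ns: float | None = None,
) -> QuenchFit:
    """Unweighted OLS of F0/F on [Q]; slope = Ksv.

    When the unquenched mean lifetime ``tau0_ns`` is supplied, the
    bimolecular quenching rate constant ``kq = Ksv / tau0`` is filled in,
    with tau0 converted from ns to s inside this function only (avoiding
    the classic factor-1e9 slip).
    """
    if len(ratios) < 3:
        raise ValidationError("Stern-Volmer fit needs at least 3 points")
    q = np.array([r[0] for r in ratios], dtype=float)
    y = np.array([r[1] for r in ratios], dtype=float)
    slope, intercept, r2, stderr = _fit_line(q, y)
    kq = None
    if tau0_ns is not None:
        if tau0_ns <= 0:
            raise ValidationError("tau0 must be positive")
        kq = slope / (tau0_ns * 1e-9)
    return QuenchFit(
        ksv=float(slope),
        ksv_stderr=float(stderr),
        intercept=float(intercept),
        r_squared=float(r2),
        temperature=float(temperature),
        kq=None if kq is None else float(kq),
        tau0_ns=tau0_ns,
    )


def double_log_fit(
    ratios: Sequence[tuple[float, float]], temperature: float
) -> BindingFit:
    """Base-10 regression of lg[(F0-F)/F] on lg[Q].

    The zero-concentration anchor is excluded (its left side is undefined).
    Points where F >= F0 (ratio <= 1) carry no quenching signal and are
    dropped with a warning; at least three must survive.
    """
    pts = [(q, r) for q, r in ratios if q > 0]
    kept = []
    for q, r in pts:
        if r <= 1.0:
            warnings.warn(
                f"dropping [Q]={q:g} mol/L from double-log fit: F >= F0 "
                "(no quenching at this point)"
            )
            continue
        kept.append((q, r))
    if len(kept) < 3:
        raise ValidationError(
            f"double-log fit needs >= 3 usable points, got {len(kept)}"
        )
    lq = np.log10([q for q, _ in kept])
    ly = np.log10([r - 1.0 for _, r in kept])  # (F0-F)/F = F0/F - 1
    slope, intercept, r2, _ = _fit_line(lq, ly)
    return BindingFit(
        ka=float(10.0**intercept),
        n=float(slope),
        log_ka_intercept=float(intercept),
        r_squared=float(r2),
        temperature=float(temperature),
    )


def _trend(values: np.ndarray, rel_tol: float) -> str:
    """Classify a sequence as 'decreasing', 'increasing' or 'flat/mixed'
    using a relative tolerance to absorb fit noise."""
    steps = np.diff(values) / values[:-1]
    overall = values[-1] / values[0] - 1.0
    if np.all(steps <= rel_tol) and overall < -rel_tol:
        return "decreasing"
    if np.all(steps >= -rel_tol) and overall > rel_tol:
        return "increasing"
    return "flat/mixed"


def classify_mechanism(
    fits: Sequence[QuenchFit],
    lifetime_invariant: bool | None = None,
    trend_rel_tol: float = 0.01,
) -> MechanismCall:
    """Vote static vs. dynamic quenching from three independent criteria.

    (a) Ksv decreasing with temperature (complex destabilised by heat) votes
        static; increasing (faster diffusion) votes dynamic.
    (b) Kq above the ~2e10 L/mol/s diffusion ceiling votes static; below it,
        dynamic.  Skipped when no fit carries a Kq.
    (c) Mean-lifetime invariance on quencher addition votes static; lifetime
        shortening votes dynamic.  Skipped when no lifetime data is given.

    The label is "static"/"dynamic" only when at least two criteria agree
    and none contradicts; anything else is "inconclusive".
    """
    if len(fits) < 2:
        raise ValidationError("mechanism classification needs >= 2 temperatures")
    temps = np.array([f.temperature for f in fits], dtype=float)
    if np.unique(temps).size != temps.size:
        raise ValidationError("temperatures must be distinct")
    order = np.argsort(temps)
    ksv = np.array([fits[i].ksv for i in order], dtype=float)

    votes = {"static": 0, "dynamic": 0}
    evidence = []

    trend = _trend(ksv, trend_rel_tol)
    if trend == "decreasing":
        votes["static"] += 1
        evidence.append(("ksv_trend", "decreasing with T -> static"))
    elif trend == "increasing":
        votes["dynamic"] += 1
        evidence.append(("ksv_trend", "increasing with T -> dynamic"))
    else:
        evidence.append(("ksv_trend", "no monotone trend -> no vote"))

    kqs = [f.kq for f in fits if f.kq is not None]
    if kqs:
        kq_max = max(kqs)
        if kq_max > KQ_DIFFUSION_LIMIT:
            votes["static"] += 1
            evidence.append(
                ("kq_ceiling", f"Kq = {kq_max:.3e} > {KQ_DIFFUSION_LIMIT:.0e} -> static")
            )
        else:
            votes["dynamic"] += 1
            evidence.append(
                ("kq_ceiling", f"Kq = {kq_max:.3e} <= {KQ_DIFFUSION_LIMIT:.0e} -> dynamic")
            )
    else:
        evidence.append(("kq_ceiling", "no Kq available -> skipped"))

    if lifetime_invariant is not None:
        if lifetime_invariant:
            votes["static"] += 1
            evidence.append(("lifetime", "tau_ave invariant -> static"))
        else:
            votes["dynamic"] += 1
            evidence.append(("lifetime", "tau_ave changes -> dynamic"))
    else:
        evidence.append(("lifetime", "no lifetime data -> skipped"))

    if votes["static"] >= 2 and votes["dynamic"] == 0:
        label = "static"
    elif votes["dynamic"] >= 2 and votes["static"] == 0:
        label = "dynamic"
    else:
        label = "inconclusive"
    return MechanismCall(label=label, evidence=tuple(evidence))
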