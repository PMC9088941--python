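"""Van't Hoff thermodynamics of binding and dominant-force classification.

From binding constants Ka measured at two or more temperatures, the linear
Van't Hoff relation

    ln Ka = -dH / (R T) + dS / R

gives the enthalpy change dH (from the slope) and entropy change dS (from
the intercept) of complex formation, assuming both are constant over the
temperature range.  The Gibbs free energy follows from dG = dH - T dS; a
negative dG at every temperature marks the binding as spontaneous.

The signs of (dH, dS) indicate the dominant non-covalent force (the Ross
sign rules): both negative -> hydrogen bonding / van der Waals contacts;
both positive -> hydrophobic interaction; dH < 0 with dS > 0 ->
electrostatic interaction.

Ka enters the logarithm carrying its L/mol units, the near-universal
convention in binding studies (formally ln(Ka/c0) with c0 = 1 mol/L).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import IndeterminateForceError, ValidationError
from .quenching import BindingFit

__all__ = ["GAS_CONSTANT", "ThermoResult", "vant_hoff", "vant_hoff_from_fits",
           "gibbs", "classify_force"]

#: Molar gas constant, J mol^-1 K^-1.
GAS_CONSTANT = 8.314

_FORCE_LABELS = {
    (-1, -1): "hydrogen-bond/van-der-Waals",
    (1, 1): "hydrophobic",
    (-1, 1): "electrostatic",
    (1, -1): "unfavourable (dH > 0, dS < 0)",
}


@dataclass(frozen=True)
class ThermoResult:
    """Van't Hoff regression output.

    delta_h in kJ/mol, delta_s in J/mol/K, delta_g_per_temperature maps each
    input temperature (K) to dG in kJ/mol computed from the *unrounded*
    regression parameters.
    """

    delta_h: float
    delta_s: float
    delta_g_per_temperature: dict
    r_squared: float
    force_label: str
    spontaneous: bool
    delta_h_stderr: float = float("nan")
    delta_s_stderr: float = float("nan")


def gibbs(delta_h: float, delta_s: float, temperature: float) -> float:
    """dG = dH - T dS in kJ/mol (dH in kJ/mol, dS in J/mol/K)."""
    if temperature <= 0:
        raise ValidationError("temperature must be positive (kelvin)")
    return delta_h - temperature * delta_s / 1000.0


def classify_force(delta_h: float, delta_s: float) -> str:
    """Dominant binding force from the signs of dH and dS (Ross rules)."""
    if not (np.isfinite(delta_h) and np.isfinite(delta_s)):
        raise ValidationError("dH and dS must be finite")
    if delta_h == 0 or delta_s == 0:
        raise IndeterminateForceError(
            "force classification is undefined when dH or dS is exactly zero"
        )
    return _FORCE_LABELS[(int(np.sign(delta_h)), int(np.sign(delta_s)))]


def vant_hoff(
    ka_by_temperature: Mapping[float, float],
    weights: Mapping[float, float] | None = None,
) -> ThermoResult:
    """OLS of ln Ka on 1/T; dH = -R * slope, dS = R * intercept.

    Parameters
    ----------
    ka_by_temperature
        Temperature (K) -> binding constant (L/mol).  At least two distinct
        temperatures; all Ka positive.
    weights
        Optional temperature -> weight map for a weighted regression
        (per-point Ka uncertainties).  Unweighted by default, matching the
        usual linear Van't Hoff plot.
    """
    temps = np.array(sorted(ka_by_temperature), dtype=float)
    if temps.size < 2:
        raise ValidationError("Van't Hoff needs >= 2 temperatures")
    if np.any(temps <= 0):
        raise ValidationError("temperatures must be positive (kelvin)")
    kas = np.array([ka_by_temperature[t] for t in temps], dtype=float)
    if np.any(kas <= 0):
        raise ValidationError("all Ka must be positive")

    x = 1.0 / temps
    y = np.log(kas)
    if weights is not None:
        w = np.array([weights[t] for t in temps], dtype=float)
        W = np.diag(w)
        A = np.column_stack([x, np.ones_like(x)])
        beta, *_ = np.linalg.lstsq(np.sqrt(W) @ A, np.sqrt(W) @ y, rcond=None)
        slope, intercept = beta
        yhat = A @ beta
        ss_res = float(w @ (y - yhat) ** 2)
        ss_tot = float(w @ (y - np.average(y, weights=w)) ** 2)
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        slope_se = intercept_se = float("nan")
    elif temps.size == 2:
        slope = (y[1] - y[0]) / (x[1] - x[0])
        intercept = y[0] - slope * x[0]
        r2, slope_se, intercept_se = 1.0, 0.0, 0.0
    else:
        res = stats.linregress(x, y)
        slope, intercept = res.slope, res.intercept
        r2 = res.rvalue**2
        slope_se, intercept_se = res.stderr, res.intercept_stderr

    delta_h = -GAS_CONSTANT * slope / 1000.0  # kJ/mol
    delta_s = GAS_CONSTANT * intercept  # J/mol/K
    dg = {float(t): gibbs(delta_h, delta_s, float(t)) for t in temps}
    return ThermoResult(
        delta_h=float(delta_h),
        delta_s=float(delta_s),
        delta_g_per_temperature=dg,
        r_squared=float(r2),
        force_label=classify_force(delta_h, delta_s)
        if delta_h != 0 and delta_s != 0
        else "indeterminate",
        spontaneous=bool(all(v < 0 for v in dg.values())),
        delta_h_stderr=float(GAS_CONSTANT * slope_se / 1000.0)
        if np.isfinite(slope_se)
        else float("nan"),
        delta_s_stderr=float(GAS_CONSTANT * intercept_se)
        if np.isfinite(intercept_se)
        else float("nan"),
    )


def vant_hoff_from_fits(fits: Sequence[BindingFit]) -> ThermoResult:
    """Convenience wrapper accepting double-log binding fits directly."""
    return vant_hoff({f.temperature: f.ka for f in fits})
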