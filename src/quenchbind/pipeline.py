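"""End-to-end study orchestration: titrations -> mechanism -> binding ->
thermodynamics, with optional lifetime, spectral, activity and trajectory
stages.

A :class:`StudyConfig` names the input files per data class; only stages
whose inputs are present run.  Cross-stage wiring follows the analysis
logic: the zero-quencher mean lifetime feeds Kq; the per-temperature
binding constants feed the Van't Hoff regression; the lifetime-invariance
flag joins the Ksv trend and the Kq ceiling in the mechanism vote.  The
report is a plain dict-of-plain-values object whose JSON serialisation is
bit-identical across reruns of the same configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from . import io as qio
from .activity import inhibition_rate, relative_activity
from .errors import ConfigError
from .lifetime import fit_decay, lifetime_invariance, mean_lifetime
from .quenching import classify_mechanism, double_log_fit, quench_ratios, \
    stern_volmer_fit
from .spectral import eem_peaks, sync_shift
from .thermo import vant_hoff
from .trajectory import radius_of_gyration, rmsd_series, rmsf_per_residue

__all__ = ["StudyConfig", "StudyReport", "run_pipeline"]


@dataclass
class StudyConfig:
    """Input paths and analysis options for one study run.

    Paths are optional: an absent path skips its stage.  ``titrations``
    maps temperature (K) to a titration CSV; ``decays`` is a list of decay
    CSVs ordered as (no ligand, increasing ligand).
    """

    titrations: dict = field(default_factory=dict)  # {T(K): path}
    decays: list = field(default_factory=list)
    sync_scans: dict = field(default_factory=dict)  # {delta_lambda: path}
    eem_before: str | None = None
    eem_after: str | None = None
    cd_spectrum: str | None = None
    activity: str | None = None
    trajectory: str | None = None
    # analysis options
    evaluation_mode: str = "fixed"
    tau0_ns: float | None = None  # explicit override; else from decays[0]
    compute_kq: bool = True
    decay_components: int = 3
    lifetime_rel_tol: float = 0.02
    shift_tol_nm: float = 2.0
    eem_diagonal_tol_nm: float = 10.0
    hbond_d_max: float = 3.5
    hbond_angle_min: float = 120.0
    seed: int = 0
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "titrations" in raw:
            raw["titrations"] = {float(k): v for k, v in raw["titrations"].items()}
        if "sync_scans" in raw:
            raw["sync_scans"] = {float(k): v for k, v in raw["sync_scans"].items()}
        return cls(**raw)

    def validate(self) -> None:
        stages = {
            "titrations": bool(self.titrations),
            "decays": bool(self.decays),
            "sync_scans": bool(self.sync_scans),
            "eem": bool(self.eem_before),
            "cd": bool(self.cd_spectrum),
            "activity": bool(self.activity),
            "trajectory": bool(self.trajectory),
        }
        if not any(stages.values()):
            absent = sorted(k for k, v in stages.items() if not v)
            raise ConfigError(
                f"no input data configured; absent stages: {absent}"
            )
        temps = list(self.titrations)
        if len(set(temps)) != len(temps):
            raise ConfigError("titration temperatures must be distinct")
        if self.titrations and self.compute_kq and not self.decays \
                and self.tau0_ns is None:
            raise ConfigError(
                "Kq requested (compute_kq=True) but no decay inputs and no "
                "tau0_ns override are configured; supply one or set "
                "compute_kq=False"
            )
        for path in self._all_paths():
            if not Path(path).exists():
                raise ConfigError(f"input file does not exist: {path}")

    def _all_paths(self):
        yield from self.titrations.values()
        yield from self.decays
        yield from self.sync_scans.values()
        for p in (self.eem_before, self.eem_after, self.cd_spectrum,
                  self.activity, self.trajectory):
            if p:
                yield p

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class StudyReport:
    """All stage outputs plus provenance, JSON-serialisable."""

    sections: dict
    provenance: dict

    def to_dict(self) -> dict:
        return {"provenance": self.provenance, **self.sections}

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    def save(self, path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def _round_floats(obj, ndigits: int = 12):
    """Round floats for deterministic serialisation (12 significant-ish
    decimals keeps full practical precision)."""
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_pipeline(config: StudyConfig) -> StudyReport:
    """Execute every configured stage and assemble the study report."""
    config.validate()
    sections: dict = {}

    # --- lifetimes -------------------------------------------------------
    tau0 = config.tau0_ns
    if config.decays:
        fits = [
            fit_decay(qio.read_decay(p), n_components=config.decay_components)
            for p in config.decays
        ]
        invariant = lifetime_invariance(fits, rel_tol=config.lifetime_rel_tol)
        if tau0 is None:
            tau0 = mean_lifetime(fits[0])
        sections["lifetimes"] = {
            "fits": [
                {
                    "lifetimes_ns": list(f.lifetimes),
                    "amplitudes": list(f.amplitudes),
                    "tau_ave_ns": f.tau_ave,
                    "chi2_reduced": f.chi2_reduced,
                }
                for f in fits
            ],
            "tau0_ns": tau0,
            "invariant": invariant,
        }
    else:
        invariant = None

    # --- titrations: quenching + binding ---------------------------------
    if config.titrations:
        quench_fits, binding_fits = [], []
        for temp in sorted(config.titrations):
            series = qio.read_titration(config.titrations[temp])
            ratios = quench_ratios(series, mode=config.evaluation_mode)
            quench_fits.append(
                stern_volmer_fit(
                    ratios, temperature=temp,
                    tau0_ns=tau0 if config.compute_kq else None,
                )
            )
            binding_fits.append(double_log_fit(ratios, temperature=temp))
        sections["stern_volmer"] = [
            {"temperature_K": f.temperature, "ksv_L_per_mol": f.ksv,
             "intercept": f.intercept, "r_squared": f.r_squared,
             "kq_L_per_mol_s": f.kq}
            for f in quench_fits
        ]
        sections["binding"] = [
            {"temperature_K": f.temperature, "ka_L_per_mol": f.ka,
             "n_sites": f.n, "r_squared": f.r_squared}
            for f in binding_fits
        ]
        if len(quench_fits) >= 2:
            call = classify_mechanism(quench_fits, lifetime_invariant=invariant)
            sections["mechanism"] = {
                "label": call.label,
                "evidence": [list(e) for e in call.evidence],
            }
            thermo = vant_hoff({f.temperature: f.ka for f in binding_fits})
            sections["thermodynamics"] = {
                "delta_h_kJ_per_mol": thermo.delta_h,
                "delta_s_J_per_mol_K": thermo.delta_s,
                "delta_g_kJ_per_mol": {
                    "%g" % t: v for t, v in
                    thermo.delta_g_per_temperature.items()
                },
                "r_squared": thermo.r_squared,
                "force_label": thermo.force_label,
                "spontaneous": thermo.spontaneous,
            }

    # --- synchronous scans ----------------------------------------------
    if config.sync_scans:
        sections["synchronous"] = {}
        for dl in sorted(config.sync_scans):
            series = qio.read_sync(config.sync_scans[dl])
            res = sync_shift(series, shift_tol=config.shift_tol_nm)
            sections["synchronous"]["%g" % dl] = {
                "verdict": res.verdict,
                "shift_nm": res.shift_nm,
                "peaks": [list(p) for p in res.peaks],
            }

    # --- EEM -------------------------------------------------------------
    if config.eem_before:
        before = eem_peaks(qio.read_eem(config.eem_before),
                           diagonal_tol=config.eem_diagonal_tol_nm)
        eem_sec = {
            "before": [[p.ex, p.em, p.intensity, p.kind] for p in before]
        }
        if config.eem_after:
            after = eem_peaks(qio.read_eem(config.eem_after),
                              diagonal_tol=config.eem_diagonal_tol_nm)
            eem_sec["after"] = [[p.ex, p.em, p.intensity, p.kind] for p in after]
            bf = [p for p in before if p.kind == "fluorophore"]
            af = [p for p in after if p.kind == "fluorophore"]
            if bf and af:
                eem_sec["top_peak_attenuation"] = af[0].intensity / bf[0].intensity
        sections["eem"] = eem_sec

    # --- CD ---------------------------------------------------------------
    if config.cd_spectrum:
        from .spectral import cd_bands

        wl, ell = qio.read_cd(config.cd_spectrum)
        bands = cd_bands(wl, ell)
        sections["cd"] = {"extrema": [list(e) for e in bands.extrema]}

    # --- enzyme activity ---------------------------------------------------
    if config.activity:
        table = qio.read_activity(config.activity)
        sections["activity"] = {
            "od_blank": table.od_blank,
            "inhibition_rate_percent": [list(r) for r in inhibition_rate(table)],
            "relative_activity": [list(r) for r in relative_activity(table)],
        }

    # --- trajectory metrics ------------------------------------------------
    if config.trajectory:
        traj = qio.read_trajectory_pdb(config.trajectory)
        has_ca = any(a.name == "CA" and not a.is_ligand for a in traj.atoms)
        sel = "ca" if has_ca else "protein"
        rmsd = rmsd_series(traj, selection=sel)
        rg = radius_of_gyration(traj, selection="protein")
        rmsf = rmsf_per_residue(traj, selection=sel)
        sections["trajectory"] = {
            "rmsd_A": list(rmsd),
            "rg_A": list(rg),
            "rmsf_A": {f"{c}:{r}": v for (c, r), v in rmsf.items()},
        }

    report = StudyReport(
        sections=_round_floats(sections),
        provenance={
            "package": "quenchbind",
            "version": __version__,
            "seed": config.seed,
            "config_hash": config.config_hash(),
        },
    )
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.save(out / "report.json")
    return report
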