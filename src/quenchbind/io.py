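"""Plain-text readers and writers for every data class.

All tabular formats are CSV with an optional metadata block of
``# key: value`` lines before the header row — the shape instrument
exports are easily massaged into.  Trajectories travel as multi-model PDB
(MODEL/ENDMDL framing), read and written through MDAnalysis.

Dialects
--------
titration / sync
    first column ``wavelength_nm``, one column per quencher concentration
    with the molarity as header.  Metadata: ``temperature_K``,
    ``protein_conc_M`` (titration) or ``delta_lambda_nm`` (sync).
decay
    two columns ``time_ns, counts``.
eem
    grid: first row the emission grid, first column the excitation grid.
cd
    two columns ``wavelength_nm, ellipticity``.
activity
    two columns ``ligand_conc_M, od660`` (blank row has conc 0).
ka
    two columns ``temperature_K, ka``.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np

from .activity import ActivityTable
from .errors import ParseError, ValidationError
from .lifetime import DecayCurve
from .quenching import TitrationSeries
from .spectral import EEM, SyncSeries
from .trajectory import Atom, Trajectory

__all__ = [
    "read_table",
    "read_titration", "write_titration",
    "read_sync", "write_sync",
    "read_decay", "write_decay",
    "read_eem", "write_eem",
    "read_cd", "write_cd",
    "read_activity", "write_activity",
    "read_ka_table", "write_ka_table",
    "read_trajectory_pdb", "write_trajectory_pdb",
]

_FLOAT_FMT = "%.12g"  # 12 significant digits: lossless for instrument data


def _split_meta(path) -> tuple[dict, list, int]:
    """Return (metadata, data lines, 1-based line number of the first data
    line) from a CSV with a ``# key: value`` preamble."""
    meta: dict[str, str] = {}
    data: list[str] = []
    first = 0
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                k, v = body.split(":", 1)
                meta[k.strip()] = v.strip()
            continue
        if not data:
            first = lineno
        data.append(line)
    if not data:
        raise ParseError(f"{path}: no data rows found")
    return meta, data, first


def _parse_floats(cells, path, lineno):
    try:
        return [float(c) for c in cells]
    except ValueError as exc:
        raise ParseError(f"{path}: line {lineno}: {exc}") from None


def _write_meta(fh, meta: dict):
    for k, v in meta.items():
        fh.write(f"# {k}: {v}\n")


# ---------------------------------------------------------------------------
# spectra matrices (titration / synchronous)

def _read_spectra_matrix(path):
    meta, lines, first = _split_meta(path)
    header = [c.strip() for c in lines[0].split(",")]
    if header[0] != "wavelength_nm":
        raise ParseError(
            f"{path}: line {first}: expected first header column "
            f"'wavelength_nm', got {header[0]!r}"
        )
    concs = _parse_floats(header[1:], path, first)
    rows = []
    for off, line in enumerate(lines[1:], start=1):
        cells = line.split(",")
        if len(cells) != len(header):
            raise ParseError(
                f"{path}: line {first + off}: expected {len(header)} cells, "
                f"got {len(cells)}"
            )
        rows.append(_parse_floats(cells, path, first + off))
    arr = np.array(rows)
    wl = arr[:, 0]
    if np.any(np.diff(wl) <= 0):
        raise ValidationError(f"{path}: wavelengths must be strictly increasing")
    return meta, np.array(concs), wl, arr[:, 1:].T  # (n_conc, n_wl)


def _write_spectra_matrix(path, meta, concs, wavelengths, intensities):
    with open(path, "w") as fh:
        _write_meta(fh, meta)
        fh.write("wavelength_nm," + ",".join(_FLOAT_FMT % c for c in concs) + "\n")
        for i, wl in enumerate(wavelengths):
            row = ",".join(_FLOAT_FMT % v for v in intensities[:, i])
            fh.write((_FLOAT_FMT % wl) + "," + row + "\n")


def read_titration(path) -> TitrationSeries:
    meta, concs, wl, inten = _read_spectra_matrix(path)
    return TitrationSeries(
        temperature=float(meta.get("temperature_K", "nan")),
        quencher_concs=concs,
        wavelengths=wl,
        intensities=inten,
        protein_conc=float(meta.get("protein_conc_M", "nan")),
        meta=meta,
    )


def write_titration(series: TitrationSeries, path) -> None:
    meta = {"temperature_K": _FLOAT_FMT % series.temperature}
    if np.isfinite(series.protein_conc):
        meta["protein_conc_M"] = _FLOAT_FMT % series.protein_conc
    _write_spectra_matrix(path, meta, series.quencher_concs,
                          series.wavelengths, series.intensities)


def read_sync(path) -> SyncSeries:
    meta, concs, wl, inten = _read_spectra_matrix(path)
    if "delta_lambda_nm" not in meta:
        raise ParseError(f"{path}: missing '# delta_lambda_nm:' metadata")
    return SyncSeries(
        delta_lambda=float(meta["delta_lambda_nm"]),
        quencher_concs=concs,
        wavelengths=wl,
        intensities=inten,
    )


def write_sync(series: SyncSeries, path) -> None:
    _write_spectra_matrix(
        path,
        {"delta_lambda_nm": _FLOAT_FMT % series.delta_lambda},
        series.quencher_concs, series.wavelengths, series.intensities,
    )


# ---------------------------------------------------------------------------
# two-column tables

def _read_two_column(path, expected_header):
    meta, lines, first = _split_meta(path)
    header = [c.strip() for c in lines[0].split(",")]
    if header[: len(expected_header)] != list(expected_header):
        raise ParseError(
            f"{path}: line {first}: expected header "
            f"{','.join(expected_header)!r}, got {lines[0]!r}"
        )
    rows = []
    for off, line in enumerate(lines[1:], start=1):
        cells = line.split(",")
        if len(cells) != len(header):
            raise ParseError(
                f"{path}: line {first + off}: expected {len(header)} cells, "
                f"got {len(cells)}"
            )
        rows.append(_parse_floats(cells, path, first + off))
    return meta, np.array(rows)


def read_decay(path) -> DecayCurve:
    meta, arr = _read_two_column(path, ("time_ns", "counts"))
    return DecayCurve(times=arr[:, 0], counts=arr[:, 1], meta=meta)


def write_decay(curve: DecayCurve, path) -> None:
    with open(path, "w") as fh:
        _write_meta(fh, {k: v for k, v in curve.meta.items()
                         if isinstance(v, (str, int, float))})
        fh.write("time_ns,counts\n")
        for t, c in zip(curve.times, curve.counts):
            fh.write((_FLOAT_FMT % t) + "," + (_FLOAT_FMT % c) + "\n")


def read_cd(path):
    _, arr = _read_two_column(path, ("wavelength_nm", "ellipticity"))
    return arr[:, 0], arr[:, 1]


def write_cd(wavelengths, ellipticity, path) -> None:
    with open(path, "w") as fh:
        fh.write("wavelength_nm,ellipticity\n")
        for w, e in zip(wavelengths, ellipticity):
            fh.write((_FLOAT_FMT % w) + "," + (_FLOAT_FMT % e) + "\n")


def read_activity(path) -> ActivityTable:
    _, arr = _read_two_column(path, ("ligand_conc_M", "od660"))
    return ActivityTable.from_replicates([(r[0], r[1]) for r in arr])


def write_activity(rows, path) -> None:
    """Write raw (conc, od) rows; the blank is the conc == 0 row."""
    with open(path, "w") as fh:
        fh.write("ligand_conc_M,od660\n")
        for conc, od in rows:
            fh.write((_FLOAT_FMT % conc) + "," + (_FLOAT_FMT % od) + "\n")


def read_ka_table(path) -> dict:
    _, arr = _read_two_column(path, ("temperature_K", "ka"))
    return {float(r[0]): float(r[1]) for r in arr}


def write_ka_table(ka_by_temperature: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write("temperature_K,ka\n")
        for t in sorted(ka_by_temperature):
            fh.write((_FLOAT_FMT % t) + "," + (_FLOAT_FMT % ka_by_temperature[t]) + "\n")


# ---------------------------------------------------------------------------
# EEM grid

def read_eem(path) -> EEM:
    meta, lines, first = _split_meta(path)
    header = lines[0].split(",")
    if header[0].strip() not in ("", "ex_nm\\em_nm", "ex\\em"):
        raise ParseError(
            f"{path}: line {first}: EEM grid must start with an empty corner "
            "cell (or 'ex\\em'), then the emission grid"
        )
    em = _parse_floats(header[1:], path, first)
    ex, rows = [], []
    for off, line in enumerate(lines[1:], start=1):
        cells = line.split(",")
        if len(cells) != len(header):
            raise ParseError(
                f"{path}: line {first + off}: expected {len(header)} cells, "
                f"got {len(cells)}"
            )
        vals = _parse_floats(cells, path, first + off)
        ex.append(vals[0])
        rows.append(vals[1:])
    return EEM(ex_grid=np.array(ex), em_grid=np.array(em),
               intensity=np.array(rows))


def write_eem(eem: EEM, path) -> None:
    with open(path, "w") as fh:
        fh.write("ex\\em," + ",".join(_FLOAT_FMT % v for v in eem.em_grid) + "\n")
        for i, ex in enumerate(eem.ex_grid):
            row = ",".join(_FLOAT_FMT % v for v in eem.intensity[i])
            fh.write((_FLOAT_FMT % ex) + "," + row + "\n")


# ---------------------------------------------------------------------------
# trajectories (multi-model PDB via MDAnalysis)

def write_trajectory_pdb(traj: Trajectory, path) -> None:
    import MDAnalysis as mda

    n = traj.n_atoms
    resids = [a.resid for a in traj.atoms]
    unique = sorted(set(resids))
    resindex = [unique.index(r) for r in resids]
    u = mda.Universe.empty(
        n, n_residues=len(unique), atom_resindex=resindex, trajectory=True
    )
    u.add_TopologyAttr("name", [a.name for a in traj.atoms])
    u.add_TopologyAttr("resid", unique)
    first_of = {r: next(a for a in traj.atoms if a.resid == r) for r in unique}
    u.add_TopologyAttr("resname", [first_of[r].resname for r in unique])
    u.add_TopologyAttr("chainIDs", [a.chain for a in traj.atoms])
    u.add_TopologyAttr("elements", [a.element for a in traj.atoms])
    u.add_TopologyAttr(
        "record_types",
        ["HETATM" if a.is_ligand else "ATOM" for a in traj.atoms],
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        with mda.Writer(str(path), multiframe=True) as w:
            for f in range(traj.n_frames):
                u.atoms.positions = traj.coords[f].astype(np.float32)
                w.write(u.atoms)


def read_trajectory_pdb(path) -> Trajectory:
    """Read a multi-model PDB (MODEL/ENDMDL frames); HETATM records are
    flagged as ligand atoms."""
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        u = mda.Universe(str(path))
        records = getattr(u.atoms, "record_types",
                          np.array(["ATOM"] * len(u.atoms)))
        atoms = tuple(
            Atom(
                name=str(a.name),
                element=str(getattr(a, "element", "") or a.name[0]),
                resname=str(a.resname),
                resid=int(a.resid),
                chain=str(getattr(a, "chainID", "A") or "A"),
                is_ligand=(records[i] == "HETATM"),
            )
            for i, a in enumerate(u.atoms)
        )
        coords = np.array(
            [u.atoms.positions.astype(float).copy() for _ in u.trajectory]
        )
    return Trajectory(coords=coords, atoms=atoms)


# ---------------------------------------------------------------------------
# dispatcher

_DIALECTS = {
    "titration": read_titration,
    "sync": read_sync,
    "eem": read_eem,
    "cd": read_cd,
    "decay": read_decay,
    "activity": read_activity,
    "ka": read_ka_table,
    "trajectory": read_trajectory_pdb,
}


def read_table(path, dialect: str):
    """Read a file in one of the named dialects, returning the typed
    object for that data class."""
    try:
        reader = _DIALECTS[dialect]
    except KeyError:
        raise ValidationError(
            f"unknown dialect {dialect!r}; one of {sorted(_DIALECTS)}"
        ) from None
    return reader(path)
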