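"""Post-simulation trajectory observables.

Operates on multi-frame coordinate sets (e.g. parsed from multi-model PDB
files) and computes the observables routinely reported for protein-ligand
MD runs: RMSD time series after optimal rigid superposition (Kabsch),
per-residue RMSF about the trajectory-average structure, radius of
gyration, closest-approach ligand-residue distances, and geometric
hydrogen-bond counts (H...acceptor distance plus donor-H...acceptor angle
cutoffs).

Superposition uses the SVD-based Kabsch algorithm as implemented by
``scipy.spatial.transform.Rotation.align_vectors``, which enforces a
proper rotation (determinant +1), so mirror-image traps cannot produce
spuriously low RMSDs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import ValidationError

__all__ = [
    "Atom",
    "Trajectory",
    "DistanceSeries",
    "rmsd_series",
    "rmsf_per_residue",
    "radius_of_gyration",
    "ligand_residue_distance",
    "hbond_count",
    "superpose",
    "ATOMIC_MASSES",
]

#: Standard atomic masses (u) for the elements that occur in biomolecular
#: trajectories; unknown elements fall back to 12.0 with a warning.
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "F": 18.998, "CL": 35.45, "BR": 79.904, "I": 126.904,
    "NA": 22.990, "K": 39.098, "MG": 24.305, "CA": 40.078, "ZN": 65.38,
    "FE": 55.845, "SE": 78.971,
}

#: Maximum covalent D-H bond length (angstrom) used to attach hydrogens to
#: donor heavy atoms.
DONOR_H_CUTOFF = 1.25


@dataclass(frozen=True)
class Atom:
    """Identity of one atom, constant across frames."""

    name: str
    element: str
    resname: str
    resid: int
    chain: str = "A"
    is_ligand: bool = False
    icode: str = ""


@dataclass(frozen=True)
class Trajectory:
    """Frames of Cartesian coordinates (angstrom) over a fixed atom list."""

    coords: np.ndarray  # (n_frames, n_atoms, 3)
    atoms: tuple  # of Atom
    frame_times: np.ndarray | None = None  # ps

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", c)
        if c.ndim != 3 or c.shape[2] != 3:
            raise ValidationError("coords must have shape (n_frames, n_atoms, 3)")
        if c.shape[1] != len(self.atoms):
            raise ValidationError("atom list does not match coordinate array")
        if not np.all(np.isfinite(c)):
            raise ValidationError("coordinates must be finite")
        if self.frame_times is not None:
            ft = np.asarray(self.frame_times, dtype=float)
            object.__setattr__(self, "frame_times", ft)
            if ft.shape != (c.shape[0],):
                raise ValidationError("frame_times length must equal n_frames")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


@dataclass(frozen=True)
class DistanceSeries:
    """Per-frame ligand-residue distances with summary statistics."""

    per_frame: np.ndarray  # angstrom
    mean: float
    minimum: float


# ---------------------------------------------------------------------------
# selections

Selection = Callable[[Atom], bool] | str | Sequence[int] | None

_NAMED_SELECTIONS = {
    "all": lambda a: True,
    "ca": lambda a: a.name == "CA" and not a.is_ligand,
    "protein": lambda a: not a.is_ligand,
    "ligand": lambda a: a.is_ligand,
    "heavy": lambda a: a.element.upper() != "H",
}


def select(traj: Trajectory, selection: Selection) -> np.ndarray:
    """Resolve a selection (predicate, named string, index list or None =
    all atoms) to an integer index array."""
    if selection is None:
        return np.arange(traj.n_atoms)
    if isinstance(selection, str):
        try:
            pred = _NAMED_SELECTIONS[selection]
        except KeyError:
            raise ValidationError(
                f"unknown selection {selection!r}; named selections: "
                f"{sorted(_NAMED_SELECTIONS)}"
            ) from None
        return np.array([i for i, a in enumerate(traj.atoms) if pred(a)], dtype=int)
    if callable(selection):
        return np.array(
            [i for i, a in enumerate(traj.atoms) if selection(a)], dtype=int
        )
    return np.asarray(selection, dtype=int)


def atom_masses(atoms: Sequence[Atom]) -> np.ndarray:
    out = np.empty(len(atoms))
    unknown = set()
    for i, a in enumerate(atoms):
        m = ATOMIC_MASSES.get(a.element.upper())
        if m is None:
            unknown.add(a.element)
            m = 12.0
        out[i] = m
    if unknown:
        warnings.warn(
            f"unknown elements {sorted(unknown)}: using mass 12.0 for each"
        )
    return out


# ---------------------------------------------------------------------------
# superposition and metrics

def superpose(mobile: np.ndarray, reference: np.ndarray):
    """Kabsch superposition of one coordinate set onto another.

    Returns ``(aligned, rmsd)`` where ``aligned`` is ``mobile`` after the
    optimal proper rotation + translation onto ``reference``.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.shape[0] < 3:
        raise ValidationError(
            "superposition needs two equal sets of >= 3 atoms "
            "(fewer leaves the rotation underdetermined)"
        )
    mob_c = mobile.mean(axis=0)
    ref_c = reference.mean(axis=0)
    with warnings.catch_warnings():
        # align_vectors warns on exactly-coincident (zero-residual) input
        warnings.simplefilter("ignore", UserWarning)
        rot, _ = Rotation.align_vectors(reference - ref_c, mobile - mob_c)
    aligned = rot.apply(mobile - mob_c) + ref_c
    # RMSD from the aligned coordinates themselves: scipy's rssd loses
    # ~half the significant digits to cancellation on near-exact matches.
    rmsd = float(np.sqrt(((aligned - reference) ** 2).sum(axis=1).mean()))
    return aligned, rmsd


def rmsd_series(
    traj: Trajectory, selection: Selection = "ca", reference: int = 0
) -> np.ndarray:
    """RMSD (angstrom) of every frame to a reference frame.

    Each frame is optimally superposed on the reference over the selection
    before the deviation is measured, so global rigid motion contributes
    nothing.  Default selection: C-alpha atoms (the protein backbone trace
    conventionally used for stability plots).
    """
    idx = select(traj, selection)
    if idx.size < 3:
        raise ValidationError("RMSD needs >= 3 selected atoms")
    ref = traj.coords[reference][idx]
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        _, out[f] = superpose(traj.coords[f][idx], ref)
    return out


def rmsf_per_residue(
    traj: Trajectory,
    selection: Selection = "ca",
    window: tuple | None = None,
) -> dict:
    """Per-residue RMSF (angstrom) about the window-average structure.

    Frames in the window are superposed on the window mean (two passes:
    align to the first window frame, form the mean, re-align to it), each
    selected atom's root-mean-square displacement from its average position
    is taken, and atoms are averaged within residues.  Returns
    ``{(chain, resid): rmsf}`` in residue order.
    """
    idx = select(traj, selection)
    if idx.size < 3:
        raise ValidationError("RMSF needs >= 3 selected atoms")
    if window is None:
        window = (0, traj.n_frames)
    lo, hi = int(window[0]), int(window[1])
    if not (0 <= lo < hi <= traj.n_frames):
        raise ValidationError(f"empty or out-of-range frame window {window}")

    frames = traj.coords[lo:hi, idx, :]
    ref = frames[0]
    aligned = np.empty_like(frames)
    for f in range(frames.shape[0]):
        aligned[f], _ = superpose(frames[f], ref)
    mean = aligned.mean(axis=0)
    for f in range(frames.shape[0]):
        aligned[f], _ = superpose(aligned[f], mean)
    mean = aligned.mean(axis=0)

    sq = ((aligned - mean) ** 2).sum(axis=2).mean(axis=0)  # per selected atom
    per_atom = np.sqrt(sq)

    out: dict[tuple, list] = {}
    for k, i in enumerate(idx):
        a = traj.atoms[i]
        out.setdefault((a.chain, a.resid), []).append(per_atom[k])
    return {key: float(np.mean(v)) for key, v in out.items()}


def radius_of_gyration(
    traj: Trajectory, selection: Selection = "all", mass_weighted: bool = True
) -> np.ndarray:
    """Radius of gyration (angstrom) per frame over the selection.

    Rg = sqrt( sum_i w_i |r_i - rbar|^2 / sum_i w_i ) with w_i the atomic
    mass (or 1 when ``mass_weighted`` is off) and rbar the weighted
    centroid.  Coincident atoms give 0, not an error.
    """
    idx = select(traj, selection)
    if idx.size < 2:
        raise ValidationError("radius of gyration needs >= 2 atoms")
    w = atom_masses([traj.atoms[i] for i in idx]) if mass_weighted else np.ones(idx.size)
    pos = traj.coords[:, idx, :]
    centroid = (pos * w[None, :, None]).sum(axis=1) / w.sum()
    sq = ((pos - centroid[:, None, :]) ** 2).sum(axis=2)
    return np.sqrt((sq * w[None, :]).sum(axis=1) / w.sum())


def ligand_residue_distance(
    traj: Trajectory,
    residue: tuple | int,
    ligand: Selection = "ligand",
) -> DistanceSeries:
    """Closest-atom distance between a ligand and one residue, per frame.

    ``residue`` is a residue number or a ``(chain, resid)`` pair.  The
    per-frame value is the minimum over all ligand-atom x residue-atom
    pairs; the summary carries the mean and the minimum over frames.
    A centre-of-mass variant is not what binding-site contact analyses
    report, but can be had by pre-reducing the selections.
    """
    lig_idx = select(traj, ligand)
    if lig_idx.size == 0:
        raise ValidationError("ligand selection is empty")
    if isinstance(residue, tuple):
        chain, resid = residue
        res_idx = np.array(
            [i for i, a in enumerate(traj.atoms)
             if a.chain == chain and a.resid == resid and not a.is_ligand],
            dtype=int,
        )
    else:
        res_idx = np.array(
            [i for i, a in enumerate(traj.atoms)
             if a.resid == int(residue) and not a.is_ligand],
            dtype=int,
        )
    if res_idx.size == 0:
        available = sorted({(a.chain, a.resid) for a in traj.atoms if not a.is_ligand})
        raise ValidationError(
            f"residue {residue!r} not found; available residues: {available}"
        )
    lig = traj.coords[:, lig_idx, :]
    res = traj.coords[:, res_idx, :]
    diff = lig[:, :, None, :] - res[:, None, :, :]
    d = np.sqrt((diff**2).sum(axis=3))
    per_frame = d.reshape(traj.n_frames, -1).min(axis=1)
    return DistanceSeries(
        per_frame=per_frame,
        mean=float(per_frame.mean()),
        minimum=float(per_frame.min()),
    )


def _attached_hydrogens(traj: Trajectory, donor_idx: np.ndarray) -> dict:
    """Map each donor heavy atom to the hydrogens covalently bound to it
    (within DONOR_H_CUTOFF in frame 0)."""
    h_idx = np.array(
        [i for i, a in enumerate(traj.atoms) if a.element.upper() == "H"], dtype=int
    )
    pos = traj.coords[0]
    attached: dict[int, list] = {}
    missing = []
    for d in donor_idx:
        if h_idx.size:
            dist = np.linalg.norm(pos[h_idx] - pos[d], axis=1)
            hs = h_idx[dist <= DONOR_H_CUTOFF]
        else:
            hs = np.array([], dtype=int)
        if hs.size == 0:
            a = traj.atoms[d]
            missing.append(f"{a.resname}{a.resid}:{a.name}")
        else:
            attached[int(d)] = [int(h) for h in hs]
    if missing:
        raise ValidationError(
            "donor atoms without an attached hydrogen (within "
            f"{DONOR_H_CUTOFF} A): {missing}"
        )
    return attached


def hbond_count(
    traj: Trajectory,
    donors: Selection,
    acceptors: Selection,
    d_max: float = 3.5,
    angle_min: float = 120.0,
) -> np.ndarray:
    """Geometric hydrogen-bond count per frame.

    A bond is a donor-H...acceptor triple with H...acceptor distance at
    most ``d_max`` (angstrom) and donor-H...acceptor angle at least
    ``angle_min`` (degrees).  ``donors`` selects donor *heavy* atoms; their
    hydrogens are found by covalent proximity in frame 0, and a donor with
    no hydrogen is an error.  Each distinct (donor, H, acceptor) triple is
    counted once even when the donor and acceptor selections overlap.
    """
    donor_idx = select(traj, donors)
    acc_idx = select(traj, acceptors)
    if donor_idx.size == 0 or acc_idx.size == 0:
        raise ValidationError("donor and acceptor selections must be non-empty")
    attached = _attached_hydrogens(traj, donor_idx)

    counts = np.zeros(traj.n_frames, dtype=int)
    for f in range(traj.n_frames):
        pos = traj.coords[f]
        seen = set()
        for d, hs in attached.items():
            for h in hs:
                dh = pos[d] - pos[h]
                for a in acc_idx:
                    if a == d or a == h or (d, h, a) in seen:
                        continue
                    ha = pos[a] - pos[h]
                    dist = np.linalg.norm(ha)
                    if dist > d_max or dist == 0:
                        continue
                    cosang = np.dot(dh, ha) / (np.linalg.norm(dh) * dist)
                    # angle D-H...A: vectors H->D and H->A
                    if np.rad2deg(np.arccos(np.clip(cosang, -1, 1))) >= angle_min:
                        seen.add((d, h, int(a)))
                        counts[f] += 1
    return counts
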