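"""Trajectory statistics for ion-channel pore dynamics.

Two families of observables are computed on desk-scale trajectories:

* residue-pair **contact probability** — the fraction of frames in which
  any two heavy atoms of the residues are within a distance cutoff
  (4.2 Å by default), ranging from 0 (never in contact) to 1 (contact
  present in every frame);
* **selectivity-filter dispersion** — per-frame side-chain centers of
  mass of the filter residues (Ser/Gly set on the four P-loops), centered
  on the grand mean and summarised by per-axis spread, XY radial RMS and
  Z range.

Trajectories are read from multi-model PDB or a plain per-frame coordinate
table.  No periodic-boundary minimum-image correction is applied: input
coordinates are assumed whole-molecule/unwrapped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AtomRecord",
    "Trajectory",
    "ContactResult",
    "FilterComSeries",
    "load_trajectory",
    "write_trajectory_pdb",
    "residue_min_distance",
    "contact_probability",
    "contact_profile",
    "filter_com_series",
    "center_distribution",
    "spread_stats",
]

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

# standard atomic masses (u) for elements seen in protein heavy atoms
ATOMIC_MASS = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "SE": 78.971,
}

DEFAULT_CUTOFF = 4.2  # Å, heavy-atom contact definition


def element_from_atom_name(name: str) -> str:
    """Infer the element from a PDB atom name (leading letter convention)."""
    stripped = name.strip()
    if not stripped:
        raise ValueError("empty atom name")
    if stripped[0].isdigit():  # e.g. 1HB / 2HG hydrogens
        stripped = stripped.lstrip("0123456789")
    if stripped[:2].upper() in ("SE",) and len(stripped) >= 2:
        return "SE"
    return stripped[0].upper()


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the shared topology of a trajectory."""

    residue_index: int
    residue_name: str
    atom_name: str
    element: str = ""
    heavy: bool = field(init=False)
    sidechain: bool = field(init=False)

    def __post_init__(self) -> None:
        elem = self.element.strip().upper() or element_from_atom_name(self.atom_name)
        object.__setattr__(self, "element", elem)
        object.__setattr__(self, "heavy", elem != "H")
        object.__setattr__(self, "sidechain", self.atom_name.strip() not in BACKBONE_ATOMS)


class Trajectory:
    """A fixed atom list plus per-frame (n_atoms, 3) coordinates in Å."""

    def __init__(self, atoms: Sequence[AtomRecord], frames: Sequence[np.ndarray]):
        if not frames:
            raise ValueError("trajectory needs at least one frame")
        self.atoms = tuple(atoms)
        coords = []
        for k, fr in enumerate(frames):
            arr = np.asarray(fr, dtype=float)
            if arr.shape != (len(self.atoms), 3):
                raise ValueError(
                    f"frame {k}: expected {(len(self.atoms), 3)} coordinates, got {arr.shape}"
                )
            coords.append(arr)
        self.coords = np.stack(coords)  # (n_frames, n_atoms, 3)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def residue_indices(self) -> list[int]:
        seen: dict[int, None] = {}
        for a in self.atoms:
            seen.setdefault(a.residue_index, None)
        return list(seen)

    def atom_indices(self, residue_index: int, heavy_only: bool = True, sidechain_only: bool = False) -> np.ndarray:
        idx = [
            k
            for k, a in enumerate(self.atoms)
            if a.residue_index == residue_index
            and (a.heavy or not heavy_only)
            and (a.sidechain or not sidechain_only)
        ]
        return np.asarray(idx, dtype=int)

    def sliced(self, discard_frac: float = 0.0, stride: int = 1) -> "Trajectory":
        """Drop the leading ``discard_frac`` of frames (equilibration) and
        subsample every ``stride``-th remaining frame."""
        if not 0.0 <= discard_frac < 1.0:
            raise ValueError("discard_frac must be in [0, 1)")
        if stride < 1:
            raise ValueError("stride must be >= 1")
        start = int(round(discard_frac * self.n_frames))
        sub = self.coords[start::stride]
        if sub.shape[0] == 0:
            raise ValueError("slicing removed every frame")
        return Trajectory(self.atoms, list(sub))


@dataclass(frozen=True)
class ContactResult:
    """Contact probability of one residue pair at a distance cutoff."""

    residue_a: int
    residue_b: int
    cutoff: float
    per_frame: tuple[bool, ...]

    @property
    def n_frames(self) -> int:
        return len(self.per_frame)

    @property
    def probability(self) -> float:
        return float(np.mean(self.per_frame))


@dataclass(frozen=True)
class FilterComSeries:
    """Per-frame, per-residue side-chain center of mass (Å)."""

    residues: tuple[int, ...]
    coms: np.ndarray  # (n_frames, n_residues, 3)
    centered: bool = False

    @property
    def n_frames(self) -> int:
        return self.coms.shape[0]


# ---------------------------------------------------------------------------
# I/O


def _parse_pdb(path: Path) -> Trajectory:
    from Bio.PDB import PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # permissive PDB fields
        structure = PDBParser(QUIET=True).get_structure("traj", str(path))
    models = list(structure)
    if not models:
        raise ValueError(f"{path}: no models found")
    atoms0 = []
    keys0 = []
    for chain in models[0]:
        for res in chain:
            for atom in res:
                elem = (atom.element or "").strip()
                atoms0.append(
                    AtomRecord(
                        residue_index=res.id[1],
                        residue_name=res.resname.strip(),
                        atom_name=atom.get_name(),
                        element=elem,
                    )
                )
                keys0.append((chain.id, res.id, atom.get_name()))
    frames = []
    for mi, model in enumerate(models):
        keys = []
        coords = []
        for chain in model:
            for res in chain:
                for atom in res:
                    keys.append((chain.id, res.id, atom.get_name()))
                    coords.append(atom.get_coord())
        if keys != keys0:
            raise ValueError(f"{path}: model {mi + 1} atom list differs from model 1")
        frames.append(np.asarray(coords, dtype=float))
    return Trajectory(atoms0, frames)


def _parse_xyz_table(path: Path) -> Trajectory:
    df = pd.read_csv(path)
    required = {"frame", "residue_index", "residue_name", "atom_name", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    frames_ids = sorted(df["frame"].unique())
    first = df[df["frame"] == frames_ids[0]].reset_index(drop=True)
    atoms = [
        AtomRecord(
            residue_index=int(r.residue_index),
            residue_name=str(r.residue_name),
            atom_name=str(r.atom_name),
            element=str(r.element) if "element" in df.columns else "",
        )
        for r in first.itertuples()
    ]
    key0 = list(zip(first["residue_index"], first["atom_name"]))
    frames = []
    for fid in frames_ids:
        sub = df[df["frame"] == fid].reset_index(drop=True)
        key = list(zip(sub["residue_index"], sub["atom_name"]))
        if key != key0:
            raise ValueError(f"{path}: frame {fid} atom list differs from frame {frames_ids[0]}")
        frames.append(sub[["x", "y", "z"]].to_numpy(dtype=float))
    return Trajectory(atoms, frames)


def load_trajectory(path: str | Path, fmt: str | None = None) -> Trajectory:
    """Load a trajectory from a multi-model PDB or a frame-table CSV.

    ``fmt`` is ``"multi-model-pdb"`` or ``"xyz-table"``; when omitted it is
    inferred from the extension (.pdb vs .csv).
    """
    path = Path(path)
    if fmt is None:
        fmt = "multi-model-pdb" if path.suffix.lower() in {".pdb", ".ent"} else "xyz-table"
    if fmt == "multi-model-pdb":
        return _parse_pdb(path)
    if fmt == "xyz-table":
        return _parse_xyz_table(path)
    raise ValueError(f"unknown trajectory format {fmt!r}")


def write_trajectory_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB (fixed-format ATOM records)."""
    with open(path, "w") as fh:
        for fi in range(traj.n_frames):
            fh.write(f"MODEL     {fi + 1:4d}\n")
            for ai, atom in enumerate(traj.atoms):
                x, y, z = traj.coords[fi, ai]
                name = atom.atom_name
                # PDB atom-name column convention: 1-letter elements start col 14
                name_field = f" {name:<3s}" if len(name) < 4 else name
                fh.write(
                    f"ATOM  {ai + 1:5d} {name_field:<4s} {atom.residue_name:<3s} A"
                    f"{atom.residue_index:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                    f"  1.00  0.00          {atom.element:>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Contact statistics


def residue_min_distance(
    traj: Trajectory,
    frame: int,
    res_a: int,
    res_b: int,
    heavy_only: bool = True,
) -> float:
    """Minimum atom-pair Euclidean distance between two residues in a frame."""
    ia = traj.atom_indices(res_a, heavy_only=heavy_only)
    ib = traj.atom_indices(res_b, heavy_only=heavy_only)
    if ia.size == 0:
        raise ValueError(f"residue {res_a} has no qualifying atoms")
    if ib.size == 0:
        raise ValueError(f"residue {res_b} has no qualifying atoms")
    pa = traj.coords[frame, ia]  # (na, 3)
    pb = traj.coords[frame, ib]  # (nb, 3)
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=-1)
    return float(d.min())


def _min_distance_series(traj: Trajectory, res_a: int, res_b: int, heavy_only: bool = True) -> np.ndarray:
    ia = traj.atom_indices(res_a, heavy_only=heavy_only)
    ib = traj.atom_indices(res_b, heavy_only=heavy_only)
    if ia.size == 0:
        raise ValueError(f"residue {res_a} has no qualifying atoms")
    if ib.size == 0:
        raise ValueError(f"residue {res_b} has no qualifying atoms")
    pa = traj.coords[:, ia]  # (F, na, 3)
    pb = traj.coords[:, ib]  # (F, nb, 3)
    d = np.linalg.norm(pa[:, :, None, :] - pb[:, None, :, :], axis=-1)
    return d.reshape(traj.n_frames, -1).min(axis=1)


def contact_probability(
    traj: Trajectory,
    res_a: int,
    res_b: int,
    cutoff: float = DEFAULT_CUTOFF,
    heavy_only: bool = True,
    min_run: int = 1,
) -> ContactResult:
    """Fraction of frames in which the two residues are in heavy-atom contact.

    A frame is in contact when the minimum heavy-atom distance is within
    ``cutoff``.  ``min_run`` (default 1, i.e. no persistence smoothing)
    requires a contact to persist for at least that many consecutive frames
    before it counts — an optional stricter reading of contact "stability".
    """
    dmin = _min_distance_series(traj, res_a, res_b, heavy_only=heavy_only)
    in_contact = dmin <= cutoff
    if min_run > 1:
        kept = np.zeros_like(in_contact)
        run = 0
        for k, flag in enumerate(in_contact):
            run = run + 1 if flag else 0
            if run >= min_run:
                kept[k - run + 1 : k + 1] = True
        in_contact = kept
    return ContactResult(
        residue_a=res_a,
        residue_b=res_b,
        cutoff=cutoff,
        per_frame=tuple(bool(b) for b in in_contact),
    )


def contact_profile(
    traj: Trajectory,
    res: int,
    cutoff: float = DEFAULT_CUTOFF,
    heavy_only: bool = True,
) -> dict[int, float]:
    """Contact probability of ``res`` against every other residue."""
    if res not in traj.residue_indices:
        raise ValueError(f"residue {res} not in trajectory")
    return {
        other: contact_probability(traj, res, other, cutoff=cutoff, heavy_only=heavy_only).probability
        for other in traj.residue_indices
        if other != res
    }


# ---------------------------------------------------------------------------
# Selectivity-filter center-of-mass dispersion


def filter_com_series(
    traj: Trajectory,
    residues: Sequence[int],
    use_ca_for_gly: bool = True,
    mass_weighted: bool = True,
) -> FilterComSeries:
    """Side-chain heavy-atom center of mass per filter residue per frame.

    Glycine has no heavy side-chain atom; with ``use_ca_for_gly`` its Cα
    stands in (otherwise such residues raise).  ``mass_weighted`` selects
    mass-weighted vs geometric mean of the atom positions.
    """
    coms = np.empty((traj.n_frames, len(residues), 3))
    for ri, res in enumerate(residues):
        idx = traj.atom_indices(res, heavy_only=True, sidechain_only=True)
        if idx.size == 0:
            if use_ca_for_gly:
                idx = np.asarray(
                    [k for k, a in enumerate(traj.atoms) if a.residue_index == res and a.atom_name == "CA"],
                    dtype=int,
                )
            if idx.size == 0:
                raise ValueError(f"residue {res}: no heavy side-chain atoms (and no Cα fallback)")
        if mass_weighted:
            w = np.asarray([ATOMIC_MASS.get(traj.atoms[k].element, 12.011) for k in idx])
        else:
            w = np.ones(idx.size)
        w = w / w.sum()
        coms[:, ri, :] = np.einsum("fad,a->fd", traj.coords[:, idx], w)
    return FilterComSeries(residues=tuple(residues), coms=coms, centered=False)


def center_distribution(series: FilterComSeries) -> FilterComSeries:
    """Subtract the grand mean per axis so the pooled distribution sits at
    the origin; idempotent."""
    grand = series.coms.reshape(-1, 3).mean(axis=0)
    return FilterComSeries(residues=series.residues, coms=series.coms - grand, centered=True)


def spread_stats(series: FilterComSeries) -> dict[str, object]:
    """Dispersion summary of a centered COM distribution.

    Returns per-axis standard deviations, radial RMS in the XY plane, Z
    range, and per-residue RMSF about each residue's own mean position.
    Refuses uncentered input so an overall offset cannot masquerade as
    spread.
    """
    if not series.centered:
        raise ValueError("spread_stats requires a centered series; call center_distribution first")
    flat = series.coms.reshape(-1, 3)
    sd = flat.std(axis=0, ddof=0)
    radial_rms = float(np.sqrt(np.mean(flat[:, 0] ** 2 + flat[:, 1] ** 2)))
    z_range = float(flat[:, 2].max() - flat[:, 2].min())
    # fluctuation about each residue's own mean: isolates thermal jitter
    # from the static geometry of the filter (inter-residue offsets)
    dev = series.coms - series.coms.mean(axis=0, keepdims=True)
    dev_flat = dev.reshape(-1, 3)
    within_sd = np.sqrt(np.mean(dev_flat**2, axis=0))
    rmsf = {
        res: float(np.sqrt(np.mean(np.sum(dev[:, ri, :] ** 2, axis=1))))
        for ri, res in enumerate(series.residues)
    }
    return {
        "sd_x": float(sd[0]),
        "sd_y": float(sd[1]),
        "sd_z": float(sd[2]),
        "within_sd_x": float(within_sd[0]),
        "within_sd_y": float(within_sd[1]),
        "within_sd_z": float(within_sd[2]),
        "radial_rms_xy": radial_rms,
        "z_range": z_range,
        "rmsf_by_residue": rmsf,
    }
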