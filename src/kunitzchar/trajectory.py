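"""MD-trajectory post-processing: superposition, RMSF, H-bonds, contacts.

Trajectories arrive as multi-model PDB (MODEL/ENDMDL) at desk scale.
Statistics follow the analysis conventions of the structural stages of the
pipeline: least-squares (Kabsch) superposition before any fluctuation
measure, per-residue Cα RMSF over a frame window, geometric hydrogen-bond
occupancy with configurable distance/angle criteria, and residue-pair
close-contact occupancy below a distance cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

__all__ = [
    "Trajectory",
    "RmsfProfile",
    "superpose_frames",
    "rmsf",
    "hbond_occupancy",
    "close_contacts",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
]

# Occupancy reporting classes used when shading interface H-bonds.
STRONG_OCCUPANCY = 0.85
REPORTED_OCCUPANCY = 0.30

_SIDECHAIN_DONORS = {
    "ARG": {"NE", "NH1", "NH2"},
    "LYS": {"NZ"},
    "HIS": {"ND1", "NE2"},
    "ASN": {"ND2"},
    "GLN": {"NE2"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "TRP": {"NE1"},
}

_SIDECHAIN_ACCEPTORS = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
    "ASN": {"OD1"},
    "GLN": {"OE1"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "HIS": {"ND1", "NE2"},
}

_WATER_RESNAMES = {"HOH", "WAT", "TIP3", "SOL"}


@dataclass
class Trajectory:
    """frames x atoms x 3 coordinates (Å) with per-atom metadata.

    ``atoms`` columns: name, element, resid (1-based), resname, chain.
    """

    coords: np.ndarray
    atoms: pd.DataFrame
    frame_time_ns: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, atoms, 3)")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError("atom metadata does not match coordinate count")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        self.atoms = self.atoms.reset_index(drop=True)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def select(self, name: str | None = None, chain: str | None = None) -> np.ndarray:
        """Boolean mask over atoms by atom name and/or chain id."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if name is not None:
            mask &= (self.atoms["name"] == name).to_numpy()
        if chain is not None:
            mask &= (self.atoms["chain"] == chain).to_numpy()
        return mask

    def window(self, start: int, stop: int | None = None) -> "Trajectory":
        """Sub-trajectory over frames [start, stop)."""
        sub = self.coords[start:stop]
        if sub.shape[0] == 0:
            raise ValueError("empty frame window")
        return Trajectory(sub, self.atoms, self.frame_time_ns)


def superpose_frames(
    traj: Trajectory,
    reference_frame: int = 0,
    selection: np.ndarray | None = None,
) -> tuple[Trajectory, np.ndarray]:
    """Rigid-body least-squares superposition of every frame onto a reference.

    The optimal rotation for the selected atoms is found per frame
    (Kabsch, via quaternion-free SVD in scipy) and applied to all atoms.
    Returns the aligned trajectory and the per-frame RMSD of the selection.
    """
    sel = np.ones(traj.n_atoms, dtype=bool) if selection is None else selection
    if sel.sum() < 3:
        raise ValueError("superposition needs >= 3 selected atoms")
    ref = traj.coords[reference_frame][sel]
    ref_c = ref.mean(axis=0)
    ref0 = ref - ref_c
    aligned = np.empty_like(traj.coords)
    rmsd = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        mob = traj.coords[f][sel]
        mob_c = mob.mean(axis=0)
        rot, _ = Rotation.align_vectors(ref0, mob - mob_c)
        aligned[f] = rot.apply(traj.coords[f] - mob_c) + ref_c
        diff = aligned[f][sel] - ref
        rmsd[f] = np.sqrt(np.mean(np.sum(diff * diff, axis=1)))
    return Trajectory(aligned, traj.atoms, traj.frame_time_ns), rmsd


@dataclass
class RmsfProfile:
    """Per-residue RMSF (Å) for a named atom selection and frame window."""

    table: pd.DataFrame  # columns: chain, resid, resname, rmsf
    selection: str
    frame_window: tuple[int, int]

    def values(self) -> np.ndarray:
        return self.table["rmsf"].to_numpy()


def rmsf(
    traj: Trajectory,
    selection_name: str = "CA",
    frame_window: tuple[int, int] | None = None,
) -> RmsfProfile:
    """Per-residue RMSF about the time-mean position.

    For each selected atom, sqrt of the time-mean squared deviation from
    its time-mean position; atoms are then averaged per (chain, residue).
    The trajectory is assumed already superposed.
    """
    start, stop = frame_window if frame_window is not None else (0, traj.n_frames)
    sub = traj.window(start, stop)
    mask = sub.select(name=selection_name)
    if not mask.any():
        raise ValueError(f"no atoms named {selection_name!r}")
    xyz = sub.coords[:, mask, :]
    mean = xyz.mean(axis=0)
    dev = xyz - mean
    per_atom = np.sqrt(np.mean(np.sum(dev * dev, axis=2), axis=0))
    meta = sub.atoms.loc[mask, ["chain", "resid", "resname"]].copy()
    meta["rmsf"] = per_atom
    table = (
        meta.groupby(["chain", "resid"], sort=True)
        .agg(resname=("resname", "first"), rmsf=("rmsf", "mean"))
        .reset_index()
    )
    return RmsfProfile(table, selection_name, (start, stop))


def _donor_acceptor_indices(atoms: pd.DataFrame, include_waters: bool):
    donors, acceptors = [], []
    for i, row in atoms.iterrows():
        resname, name = row["resname"], row["name"]
        if not include_waters and resname in _WATER_RESNAMES:
            continue
        if name == "N" and resname != "PRO":
            donors.append(i)
        elif name in _SIDECHAIN_DONORS.get(resname, ()):
            donors.append(i)
        if name in ("O", "OXT"):
            acceptors.append(i)
        elif name in _SIDECHAIN_ACCEPTORS.get(resname, ()):
            acceptors.append(i)
    return np.array(donors, dtype=int), np.array(acceptors, dtype=int)


def _attached_hydrogens(traj: Trajectory, donors: np.ndarray) -> dict[int, np.ndarray]:
    """Hydrogens within covalent range (1.3 Å) of each donor, first frame."""
    atoms = traj.atoms
    h_idx = np.nonzero(
        (atoms["element"] == "H").to_numpy()
        | atoms["name"].str.startswith("H").to_numpy()
    )[0]
    out: dict[int, np.ndarray] = {}
    if h_idx.size == 0:
        return out
    frame0 = traj.coords[0]
    d = cdist(frame0[donors], frame0[h_idx])
    for k, di in enumerate(donors):
        near = h_idx[d[k] <= 1.3]
        if near.size:
            out[int(di)] = near
    return out


def occupancy_class(occupancy: float) -> str:
    if occupancy >= STRONG_OCCUPANCY:
        return "strong"
    if occupancy >= REPORTED_OCCUPANCY:
        return "reported"
    return "below"


def hbond_occupancy(
    traj: Trajectory,
    d_cut: float = 3.5,
    angle_cut: float = 150.0,
    intermolecular: bool = False,
    include_waters: bool = False,
) -> pd.DataFrame:
    """Geometric hydrogen-bond occupancy per donor-acceptor pair.

    A bond exists in a frame when the donor-acceptor distance is <= d_cut
    (Å) and, when hydrogens are present on the donor, some donor-H-acceptor
    angle is >= angle_cut (degrees). Without hydrogens the criterion is
    distance-only (heavy-atom mode). Occupancy is the exact fraction of
    frames; classes follow the 0.30/0.85 reporting thresholds.
    """
    donors, acceptors = _donor_acceptor_indices(traj.atoms, include_waters)
    if donors.size == 0 or acceptors.size == 0:
        import warnings

        warnings.warn("no donors or acceptors found; empty H-bond report")
        return pd.DataFrame(
            columns=["donor", "acceptor", "occupancy", "class", "d_cut", "angle_cut"]
        )
    hydrogens = _attached_hydrogens(traj, donors)
    atoms = traj.atoms
    chains = atoms["chain"].to_numpy()
    resids = atoms["resid"].to_numpy()
    counts = np.zeros((donors.size, acceptors.size), dtype=int)
    for f in range(traj.n_frames):
        frame = traj.coords[f]
        dist = cdist(frame[donors], frame[acceptors])
        ok = dist <= d_cut
        if not ok.any():
            continue
        for k, di in enumerate(donors):
            hs = hydrogens.get(int(di))
            if hs is None:
                continue
            for m in np.nonzero(ok[k])[0]:
                aj = acceptors[m]
                dh = frame[hs] - frame[di]
                ha = frame[aj] - frame[hs]
                # angle at H between donor and acceptor
                cosang = np.sum(-dh * ha, axis=1) / (
                    np.linalg.norm(dh, axis=1) * np.linalg.norm(ha, axis=1)
                )
                ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                if not np.any(ang >= angle_cut):
                    ok[k, m] = False
        counts += ok
    rows = []
    for k, di in enumerate(donors):
        for m, aj in enumerate(acceptors):
            if chains[di] == chains[aj] and resids[di] == resids[aj]:
                continue
            if intermolecular and chains[di] == chains[aj]:
                continue
            occ = counts[k, m] / traj.n_frames
            if occ == 0:
                continue
            rows.append(
                {
                    "donor": f"{chains[di]}:{resids[di]}:{atoms.at[di, 'resname']}:{atoms.at[di, 'name']}",
                    "acceptor": f"{chains[aj]}:{resids[aj]}:{atoms.at[aj, 'resname']}:{atoms.at[aj, 'name']}",
                    "occupancy": occ,
                    "class": occupancy_class(occ),
                    "d_cut": d_cut,
                    "angle_cut": angle_cut,
                }
            )
    report = pd.DataFrame(rows)
    return report.sort_values("occupancy", ascending=False).reset_index(drop=True) if len(report) else report


def close_contacts(
    traj: Trajectory,
    cutoff: float = 4.0,
    intermolecular: bool = True,
) -> pd.DataFrame:
    """Residue-pair contact occupancy below a distance cutoff.

    Two residues are in contact in a frame when any interatomic distance
    is < cutoff (Å). With ``intermolecular`` set, only pairs across
    different chains count and the input must contain >= 2 chains.
    """
    atoms = traj.atoms
    chains = atoms["chain"].to_numpy()
    if intermolecular and np.unique(chains).size < 2:
        raise ValueError("intermolecular mode needs >= 2 chains")
    keys = list(zip(chains, atoms["resid"].to_numpy()))
    uniq = sorted(set(keys))
    ridx = np.array([uniq.index(k) for k in keys])
    n_res = len(uniq)
    counts = np.zeros((n_res, n_res), dtype=int)
    for f in range(traj.n_frames):
        d = cdist(traj.coords[f], traj.coords[f])
        close = d < cutoff
        mat = np.zeros((n_res, n_res), dtype=bool)
        ii, jj = np.nonzero(close)
        mat[ridx[ii], ridx[jj]] = True
        counts += mat
    rows = []
    for a in range(n_res):
        for b in range(a + 1, n_res):
            if intermolecular and uniq[a][0] == uniq[b][0]:
                continue
            occ = counts[a, b] / traj.n_frames
            if occ > 0:
                rows.append(
                    {
                        "chain_a": uniq[a][0],
                        "resid_a": int(uniq[a][1]),
                        "chain_b": uniq[b][0],
                        "resid_b": int(uniq[b][1]),
                        "occupancy": occ,
                    }
                )
    return pd.DataFrame(rows, columns=["chain_a", "resid_a", "chain_b", "resid_b", "occupancy"])


def read_multimodel_pdb(path) -> Trajectory:
    """Read a MODEL/ENDMDL multi-frame PDB into a Trajectory."""
    frames: list[list[tuple[float, float, float]]] = []
    meta_rows: list[dict] = []
    current: list[tuple[float, float, float]] | None = None
    first_model = True
    with open(path) as fh:
        for line in fh:
            rec = line[:6].strip()
            if rec == "MODEL":
                current = []
            elif rec == "ENDMDL":
                if current is not None:
                    frames.append(current)
                    first_model = False
                    current = None
            elif rec in ("ATOM", "HETATM"):
                if current is None:  # single-model file without MODEL records
                    current = []
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
                current.append((x, y, z))
                if first_model:
                    element = line[76:78].strip() or line[12:16].strip()[0]
                    meta_rows.append(
                        {
                            "name": line[12:16].strip(),
                            "element": element,
                            "resid": int(line[22:26]),
                            "resname": line[17:20].strip(),
                            "chain": line[21].strip() or "A",
                        }
                    )
    if current:
        frames.append(current)
    if not frames:
        raise ValueError(f"no coordinates found in {path}")
    coords = np.array(frames, dtype=float)
    return Trajectory(coords, pd.DataFrame(meta_rows))


def write_multimodel_pdb(traj: Trajectory, path) -> None:
    atoms = traj.atoms
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"MODEL     {f + 1:4d}\n")
            for i in range(traj.n_atoms):
                x, y, z = traj.coords[f, i]
                name = atoms.at[i, "name"]
                pad_name = f" {name:<3s}" if len(name) < 4 else name
                fh.write(
                    f"ATOM  {i + 1:5d} {pad_name}{'':1s}{atoms.at[i, 'resname']:>3s} "
                    f"{atoms.at[i, 'chain']:1s}{atoms.at[i, 'resid']:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {atoms.at[i, 'element']:>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")
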