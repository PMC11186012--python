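"""File I/O: GRO/PDB topologies, XTC/TRR/multi-frame trajectories, TSV/JSON
analysis outputs, and the YAML run configuration.

MDAnalysis does the format parsing; everything is converted to the package
units (nm, ps) on the way in.  A role map — ``(residue_name, atom_name) ->
[role tags]`` — attaches the analysis labels to the topology.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .constants import MASSES
from .exceptions import ConfigurationError, FormatError
from .trajectory import Topology, Trajectory

__all__ = ["load_trajectory", "write_trajectory", "load_config", "write_tsv",
           "read_tsv", "write_json"]

_NM_PER_ANGSTROM = 0.1


def _guess_element(name: str) -> str:
    name = name.strip()
    if name[:2].capitalize() in ("Gd", "Na", "Cl"):
        return name[:2].capitalize()
    for ch in name:
        if ch.isalpha():
            return ch.upper() if ch.upper() in "HCNOPS" else ch
    return "X"


def build_topology(names, resnames, resids, role_map=None, masses=None,
                   ch_bonds=None) -> Topology:
    """Assemble a Topology, resolving a role map into index sets."""
    names = np.asarray(names, dtype=object)
    resnames = np.asarray(resnames, dtype=object)
    resids = np.asarray(resids, dtype=int)
    elements = np.asarray([_guess_element(n) for n in names], dtype=object)
    if masses is None:
        masses = np.asarray([MASSES.get(e, 0.0) for e in elements], dtype=float)
    roles: dict[str, list] = {}
    if role_map:
        keyed = {(str(rn), str(an)): tags for (rn, an), tags in role_map.items()}
        for i, (rn, an) in enumerate(zip(resnames, names)):
            for tag in keyed.get((rn, an), ()):
                roles.setdefault(tag, []).append(i)
        # a role tag mapping to zero atoms is allowed; an entry whose
        # (resname, name) pair matches nothing is a configuration error
        matched = {(str(rn), str(an)) for rn, an in zip(resnames, names)}
        for key in keyed:
            if key not in matched:
                raise ConfigurationError(
                    f"role map entry {key} matches no atom in the topology")
    return Topology(names=names, resnames=resnames, resids=resids,
                    elements=elements, masses=masses,
                    roles={k: np.asarray(v, int) for k, v in roles.items()},
                    ch_bonds=ch_bonds or [])


def load_trajectory(topology_path, trajectory_path=None, role_map=None) -> Trajectory:
    """Read a topology (GRO/PDB) and trajectory (XTC/TRR/GRO/PDB) from disk.

    ``role_map`` maps ``(residue_name, atom_name)`` pairs to lists of role
    tags.  Coordinates come back in nm, times in ps.
    """
    import MDAnalysis as mda

    topology_path = Path(topology_path)
    if not topology_path.exists():
        raise FormatError(f"topology file not found: {topology_path}")
    args = [str(topology_path)]
    if trajectory_path is not None:
        trajectory_path = Path(trajectory_path)
        if not trajectory_path.exists():
            raise FormatError(f"trajectory file not found: {trajectory_path}")
        args.append(str(trajectory_path))
    try:
        u = mda.Universe(*args)
    except (ValueError, IOError, OSError) as exc:
        raise FormatError(f"cannot read trajectory: {exc}") from exc

    try:
        masses = u.atoms.masses.copy()
        if not np.all(np.isfinite(masses)):
            masses = None
    except Exception:
        masses = None
    top = build_topology(
        names=[a.name for a in u.atoms],
        resnames=[a.resname for a in u.atoms],
        resids=[a.resid for a in u.atoms],
        role_map=role_map, masses=masses,
    )

    pos, times, boxes = [], [], []
    for ts in u.trajectory:
        if ts.dimensions is None or np.any(ts.dimensions[:3] <= 0):
            raise FormatError("frame without a valid orthorhombic box")
        if not np.allclose(ts.dimensions[3:], 90.0, atol=1e-3):
            raise FormatError("triclinic boxes are not supported")
        pos.append(ts.positions * _NM_PER_ANGSTROM)
        times.append(ts.time)
        boxes.append(ts.dimensions[:3] * _NM_PER_ANGSTROM)
    return Trajectory(topology=top, positions=np.asarray(pos),
                      times=np.asarray(times, float), box=np.asarray(boxes))


def write_trajectory(traj: Trajectory, topology_path, trajectory_path=None):
    """Write a GRO snapshot (frame 0) and optionally an XTC of all frames."""
    import MDAnalysis as mda

    n = traj.n_atoms
    u = mda.Universe.empty(n, n_residues=n, atom_resindex=np.arange(n),
                           trajectory=True)
    u.add_TopologyAttr("names", list(traj.topology.names))
    u.add_TopologyAttr("resnames", list(traj.topology.resnames))
    u.add_TopologyAttr("resids", list(traj.topology.resids))
    # collapse to true residues
    u2 = mda.Universe.empty(
        n, n_residues=len(np.unique(traj.topology.resids)),
        atom_resindex=np.unique(traj.topology.resids, return_inverse=True)[1],
        trajectory=True)
    u2.add_TopologyAttr("names", list(traj.topology.names))
    resnames = []
    seen = {}
    for rid, rn in zip(traj.topology.resids, traj.topology.resnames):
        if rid not in seen:
            seen[rid] = rn
            resnames.append(rn)
    u2.add_TopologyAttr("resnames", resnames)
    u2.add_TopologyAttr("resids", sorted(seen))
    u = u2
    u.atoms.positions = traj.positions[0] / _NM_PER_ANGSTROM
    u.dimensions = [*(traj.box[0] / _NM_PER_ANGSTROM), 90, 90, 90]
    u.atoms.write(str(topology_path))
    if trajectory_path is not None:
        with mda.Writer(str(trajectory_path), n_atoms=n) as w:
            for f in range(traj.n_frames):
                u.atoms.positions = traj.positions[f] / _NM_PER_ANGSTROM
                u.dimensions = [*(traj.box[f] / _NM_PER_ANGSTROM), 90, 90, 90]
                u.trajectory.ts.time = traj.times[f]
                w.write(u.atoms)


def load_config(path) -> dict:
    """Read the YAML run configuration; role_map keys 'RESNAME ATOMNAME'."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if "role_map" in cfg:
        parsed = {}
        for key, tags in cfg["role_map"].items():
            parts = str(key).split()
            if len(parts) != 2:
                raise ConfigurationError(
                    f"role_map key {key!r} must be 'RESNAME ATOMNAME'")
            parsed[(parts[0], parts[1])] = (
                [tags] if isinstance(tags, str) else list(tags))
        cfg["role_map"] = parsed
    return cfg


def write_tsv(df: pd.DataFrame, path):
    """Analysis-output TSV: tab separator, header line, '.' decimal."""
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj, path):
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)
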