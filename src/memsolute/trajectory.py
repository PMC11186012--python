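"""In-memory trajectory model.

A :class:`Trajectory` holds a :class:`Topology` plus dense position/box/time
arrays for all frames.  Analyses assume orthorhombic boxes and a uniform
frame spacing; both are validated at construction.  The membrane-centred
coordinate convention used throughout the package is: the mass-weighted
lipid centre of mass defines z = 0 in every frame, the outward normal of the
upper leaflet is +z and of the lower leaflet is -z, and angle analyses in
the lower leaflet flip their vectors so that 0 deg always means "pointing
out of the membrane".
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import AnalysisError, ConfigurationError, FormatError

__all__ = [
    "Topology",
    "Trajectory",
    "minimum_image",
    "center_on_membrane",
    "assign_leaflets",
]

#: Tolerance on frame-spacing uniformity, ps.
TIME_TOLERANCE_PS = 1e-6


@dataclass
class Topology:
    """Static atom table with analysis role labels.

    ``roles`` maps a role tag (e.g. ``"lipid-P"``, ``"chelate-Gd"``,
    ``"water-O"``) to a sorted integer array of atom indices.  ``ch_bonds``
    lists (carbon index, tuple of bonded hydrogen indices) pairs for
    order-parameter work.
    """

    names: np.ndarray
    resnames: np.ndarray
    resids: np.ndarray
    elements: np.ndarray
    masses: np.ndarray
    roles: dict = field(default_factory=dict)
    ch_bonds: list = field(default_factory=list)

    def __post_init__(self):
        n = len(self.names)
        for attr in ("resnames", "resids", "elements", "masses"):
            if len(getattr(self, attr)) != n:
                raise FormatError(f"topology field {attr!r} length != {n}")
        self.masses = np.asarray(self.masses, dtype=float)
        self.resids = np.asarray(self.resids, dtype=int)
        for tag, idx in self.roles.items():
            idx = np.asarray(idx, dtype=int)
            if idx.size and (idx.min() < 0 or idx.max() >= n):
                raise FormatError(f"role {tag!r} references atoms outside the topology")
            self.roles[tag] = np.unique(idx)
        for c, hs in self.ch_bonds:
            for i in (c, *hs):
                if not 0 <= i < n:
                    raise FormatError("C-H bond references a missing atom")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def select(self, tag: str) -> np.ndarray:
        """Atom indices carrying ``tag`` (empty array if the tag is unused)."""
        return self.roles.get(tag, np.empty(0, dtype=int))

    def require(self, tag: str) -> np.ndarray:
        idx = self.select(tag)
        if idx.size == 0:
            raise ConfigurationError(f"role {tag!r} resolves to no atoms")
        return idx


@dataclass
class Trajectory:
    """Frames of positions (nm) with orthorhombic boxes (nm) and times (ps)."""

    topology: Topology
    positions: np.ndarray  # (n_frames, n_atoms, 3)
    times: np.ndarray      # (n_frames,)
    box: np.ndarray        # (n_frames, 3)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise FormatError("positions must have shape (frames, atoms, 3)")
        if self.positions.shape[1] != self.topology.n_atoms:
            raise FormatError(
                f"trajectory has {self.positions.shape[1]} atoms but topology "
                f"has {self.topology.n_atoms}"
            )
        if self.box.shape != (self.n_frames, 3):
            raise FormatError("box must have shape (frames, 3)")
        if np.any(self.box <= 0):
            raise FormatError("box lengths must be positive")
        if self.n_frames > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise FormatError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[1]

    @property
    def frame_interval(self) -> float:
        """Uniform frame spacing in ps; error if the spacing is not uniform."""
        if self.n_frames < 2:
            raise AnalysisError("frame interval undefined for < 2 frames")
        dt = np.diff(self.times)
        if np.any(np.abs(dt - dt[0]) > TIME_TOLERANCE_PS):
            raise AnalysisError("nonuniform frame spacing; resampling is not supported")
        return float(dt[0])


def minimum_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap displacement vectors into the orthorhombic minimum image.

    Works on the last axis; ``box`` broadcasts against ``d``.  After wrapping
    ``|d_k| <= L_k / 2`` on every axis.
    """
    d = np.asarray(d, dtype=float)
    box = np.asarray(box, dtype=float)
    return d - box * np.round(d / box)


def membrane_com_z(traj: Trajectory, lipid_tag: str = "lipid") -> np.ndarray:
    """Per-frame mass-weighted z of the lipid centre of mass."""
    idx = traj.topology.require(lipid_tag)
    m = traj.topology.masses[idx]
    if m.sum() <= 0:
        raise AnalysisError("zero total lipid mass")
    return traj.positions[:, idx, 2] @ m / m.sum()


def center_on_membrane(traj: Trajectory, lipid_tag: str = "lipid") -> Trajectory:
    """Shift every frame along z so the lipid COM sits at z = 0.

    x and y are untouched; the same shift is applied to all atoms of a frame,
    so the operation is idempotent and translation invariant.
    """
    shift = membrane_com_z(traj, lipid_tag)
    pos = traj.positions.copy()
    pos[:, :, 2] -= shift[:, None]
    return replace(traj, positions=pos)


def assign_leaflets(traj: Trajectory, frame: int = 0) -> dict:
    """Map lipid residue id -> 'upper' | 'lower' by the sign of its P atom z.

    Assumes membrane-centred coordinates.  Every lipid must carry exactly one
    ``lipid-P`` atom.
    """
    p_idx = traj.topology.require("lipid-P")
    resids = traj.topology.resids[p_idx]
    if len(np.unique(resids)) != len(resids):
        raise AnalysisError("a lipid carries more than one P-tagged atom")
    z = traj.positions[frame, p_idx, 2]
    return {int(r): ("upper" if zz >= 0 else "lower") for r, zz in zip(resids, z)}


def leaflet_sign(traj: Trajectory, frame: int = 0) -> dict:
    """Map lipid resid -> +1 (upper) / -1 (lower); companion of assign_leaflets."""
    return {r: (1.0 if side == "upper" else -1.0)
            for r, side in assign_leaflets(traj, frame).items()}
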