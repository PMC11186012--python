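"""Global bilayer structure: area/volume per lipid, thickness metrics, tilt
angles and C-H order parameters.

Conventions: membrane-centred coordinates (lipid COM at z = 0), outward
leaflet normal +z above / -z below the midplane.  The area per lipid can be
corrected for inserted solutes by subtracting, per leaflet, the circular
footprint of each inserted chelate (diameter 0.871 nm, the distance between
opposite non-coordinated oxygens in the crystal structure).  The Luzzati
thickness D_B is read off where the water density falls to half its bulk
plateau; D_HH is the separation of the two electron-density maxima
(quadratic interpolation); D_PP/D_NN are distances between per-leaflet mean
P/N positions.  Order parameters are S_CH = <(3 cos^2 theta - 1)/2> per C-H
bond against the bilayer normal and are reported as -S_CH.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import ELECTRONS
from .exceptions import AnalysisError, ConfigurationError
from .stats import block_analysis
from .trajectory import Trajectory, leaflet_sign

__all__ = ["area_per_lipid", "density_profiles", "luzzati_thickness",
           "peak_thicknesses", "volume_per_lipid", "tilt_distribution",
           "sch_order_parameters", "mad", "CHELATE_DIAMETER"]

#: Chelate in-plane footprint diameter, nm.
CHELATE_DIAMETER = 0.871


def area_per_lipid(box_series, n_per_leaflet: int,
                   n_inserted_per_leaflet: float = 0.0,
                   chelate_diameter: float = CHELATE_DIAMETER) -> dict:
    """Raw and chelate-corrected area per lipid from the box xy area series.

    ``box_series``: (F, >=2) box lengths in nm, or a 1-D series of xy areas.
    ``n_inserted_per_leaflet`` may be fractional (time-averaged occupancy).
    """
    b = np.asarray(box_series, dtype=float)
    area = b[:, 0] * b[:, 1] if b.ndim == 2 else b
    if n_per_leaflet <= 0:
        raise ConfigurationError("n_per_leaflet must be positive")
    mean_area = float(area.mean())
    footprint = n_inserted_per_leaflet * np.pi * (chelate_diameter / 2.0) ** 2
    apl_raw = mean_area / n_per_leaflet
    apl_corr = (mean_area - footprint) / n_per_leaflet
    if area.size >= 16 and np.ptp(area) > 0:
        ci = block_analysis(area).ci_halfwidth / n_per_leaflet
    else:
        ci = 0.0
    return {"apl_raw": apl_raw, "apl_corrected": apl_corr, "ci": float(ci)}


@dataclass
class Profile:
    bin_centers: np.ndarray
    density: np.ndarray          # amu/nm^3, e-/nm^3 or atoms/nm^3
    weighting: str
    label: str = ""


def density_profiles(traj: Trajectory, selections: dict,
                     weighting: str = "mass", bin_width: float = 0.1,
                     symmetrize: bool = False, z_max: float = None) -> dict:
    """Partial density profiles along z for each named atom selection."""
    if weighting not in ("mass", "electron", "number"):
        raise ConfigurationError(f"unknown weighting {weighting!r}")
    if z_max is None:
        z_max = float(traj.box[:, 2].max()) / 2.0
    edges = np.arange(-z_max, z_max + bin_width / 2, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    area = float((traj.box[:, 0] * traj.box[:, 1]).mean())
    out = {}
    for label, idx in selections.items():
        idx = np.asarray(idx, dtype=int)
        if weighting == "mass":
            w = traj.topology.masses[idx]
        elif weighting == "electron":
            w = np.array([ELECTRONS.get(e, 0) for e in
                          traj.topology.elements[idx]], dtype=float)
        else:
            w = np.ones(idx.size)
        hist = np.zeros(centers.size)
        for f in range(traj.n_frames):
            h, _ = np.histogram(traj.positions[f, idx, 2], bins=edges,
                                weights=w)
            hist += h
        dens = hist / (traj.n_frames * area * bin_width)
        if symmetrize:
            dens = 0.5 * (dens + dens[::-1])
        out[label] = Profile(bin_centers=centers, density=dens,
                             weighting=weighting, label=label)
    return out


def luzzati_thickness(water_profile: Profile, bulk_margin: float = 1.0) -> float:
    """D_B: distance between the two half-bulk crossings of the water density.

    The bulk plateau is the mean density over the outer ``bulk_margin`` nm
    of the profile on each side.
    """
    z = water_profile.bin_centers
    d = water_profile.density
    outer = np.abs(z) > (np.abs(z).max() - bulk_margin)
    bulk = d[outer].mean()
    if bulk <= 0:
        raise AnalysisError("no bulk water plateau")
    half = 0.5 * bulk

    def crossing(zs, ds):
        """First z where the density rises through half-bulk (interpolated)."""
        for i in range(len(ds) - 1):
            if (ds[i] - half) * (ds[i + 1] - half) <= 0 and ds[i] != ds[i + 1]:
                frac = (half - ds[i]) / (ds[i + 1] - ds[i])
                return zs[i] + frac * (zs[i + 1] - zs[i])
        raise AnalysisError("water density never crosses half bulk")

    mid = np.argmin(np.abs(z))
    # scan outward from the membrane centre on each side
    z_pos = crossing(z[mid:], d[mid:])
    z_neg = -crossing((-z[: mid + 1])[::-1], d[: mid + 1][::-1])
    return float(z_pos - z_neg)


def _interp_peak(z, d, i):
    """Quadratic interpolation of a discrete maximum position."""
    if i == 0 or i == len(d) - 1:
        return float(z[i])
    denom = d[i - 1] - 2 * d[i] + d[i + 1]
    if denom == 0:
        return float(z[i])
    shift = 0.5 * (d[i - 1] - d[i + 1]) / denom
    return float(z[i] + shift * (z[1] - z[0]))


def peak_thicknesses(traj: Trajectory = None, electron_profile: Profile = None,
                     p_indices=None, n_indices=None) -> dict:
    """D_HH from the electron-density maxima; D_PP / D_NN from per-leaflet
    mean P / N atom z positions."""
    out = {}
    if electron_profile is not None:
        z = electron_profile.bin_centers
        d = electron_profile.density
        mid = np.argmin(np.abs(z))
        i_hi = mid + int(np.argmax(d[mid:]))
        i_lo = int(np.argmax(d[: mid + 1]))
        out["D_HH"] = _interp_peak(z, d, i_hi) - _interp_peak(z, d, i_lo)
    if traj is not None:
        for key, idx in (("D_PP", p_indices), ("D_NN", n_indices)):
            if idx is None:
                continue
            idx = np.asarray(idx, dtype=int)
            zs = traj.positions[:, idx, 2]
            upper = zs[zs >= 0]
            lower = zs[zs < 0]
            if upper.size == 0 or lower.size == 0:
                raise AnalysisError(f"one leaflet has no atoms for {key}")
            out[key] = float(upper.mean() - lower.mean())
    return out


def volume_per_lipid(apl: float, d_nn: float) -> float:
    """Volume per lipid = area/lipid * D_NN / 2 (nm^3)."""
    return apl * d_nn / 2.0


def tilt_distribution(traj: Trajectory, vec_indices, bin_deg: float = 1.0) -> dict:
    """Tilt-angle pdf/mean of per-lipid vectors against the outward normal.

    ``vec_indices``: sequence of (resid, tail_atom, head_atom) triples; the
    vector is tail -> head (e.g. P -> N, or chain C1 -> C_ter).  Lower-leaflet
    vectors are flipped so 0 deg means pointing out of the membrane.
    """
    signs = leaflet_sign(traj)
    angles = np.empty((traj.n_frames, len(vec_indices)))
    for j, (resid, a_tail, a_head) in enumerate(vec_indices):
        v = traj.positions[:, a_head, :] - traj.positions[:, a_tail, :]
        v = v / np.linalg.norm(v, axis=1)[:, None]
        cosang = np.clip(signs[int(resid)] * v[:, 2], -1.0, 1.0)
        angles[:, j] = np.degrees(np.arccos(cosang))
    per_frame = angles.mean(axis=1)
    edges = np.arange(0.0, 180.0 + bin_deg / 2, bin_deg)
    pdf, _ = np.histogram(angles.ravel(), bins=edges, density=True)
    if per_frame.size >= 16 and np.ptp(per_frame) > 0:
        br = block_analysis(per_frame)
        mean, ci = br.mean, br.ci_halfwidth
    else:
        mean, ci = float(per_frame.mean()), float("nan")
    return {"bin_edges": edges, "pdf": pdf, "mean": mean, "ci": ci}


def sch_order_parameters(traj: Trajectory, bond_table: pd.DataFrame,
                         split_threshold: float = 0.02) -> pd.DataFrame:
    """-S_CH per carbon from a bond table.

    ``bond_table`` columns: chain, carbon, c_index, h_index and optional
    prochiral label ('pro-R'/'pro-S' or empty).  Bonds sharing (chain,
    carbon) are merged unless they carry distinct prochiral labels AND their
    |-S_CH| difference exceeds ``split_threshold``, mirroring the usual
    forking-report convention.  cos^2 is sign-symmetric, so no leaflet flip
    is needed.
    """
    recs = []
    for _, row in bond_table.iterrows():
        v = traj.positions[:, int(row.h_index), :] \
            - traj.positions[:, int(row.c_index), :]
        cos2 = (v[:, 2] / np.linalg.norm(v, axis=1)) ** 2
        sch = float(np.mean(0.5 * (3.0 * cos2 - 1.0)))
        recs.append({"chain": row.chain, "carbon": row.carbon,
                     "prochiral": getattr(row, "prochiral", "") or "",
                     "minus_sch": -sch})
    df = pd.DataFrame(recs)
    out = []
    for (chain, carbon), grp in df.groupby(["chain", "carbon"], sort=False):
        by_label = grp.groupby("prochiral")["minus_sch"].mean()
        if len(by_label) > 1 and np.ptp(by_label.values) > split_threshold:
            for label, val in by_label.items():
                out.append({"chain": chain, "carbon": carbon,
                            "prochiral": label, "minus_sch": float(val),
                            "split": True})
        else:
            out.append({"chain": chain, "carbon": carbon, "prochiral": "",
                        "minus_sch": float(grp["minus_sch"].mean()),
                        "split": False})
    return pd.DataFrame(out)


def mad(computed: pd.DataFrame, reference: pd.DataFrame) -> float:
    """Mean absolute deviation of -S_CH against a reference table.

    Matching is on (chain, carbon); split computed values are averaged
    before matching unless the reference itself is split (then matching
    additionally uses the prochiral label).
    """
    ref_split = "prochiral" in reference.columns and \
        reference["prochiral"].astype(str).str.len().gt(0).any()
    keys = ["chain", "carbon"] + (["prochiral"] if ref_split else [])
    comp = computed.copy()
    if not ref_split:
        comp = comp.groupby(["chain", "carbon"], as_index=False,
                            sort=False)["minus_sch"].mean()
    merged = comp.merge(reference, on=keys, suffixes=("", "_ref"))
    if merged.empty:
        raise AnalysisError("no matching carbons between computed and reference")
    return float(np.mean(np.abs(merged["minus_sch"] - merged["minus_sch_ref"])))
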