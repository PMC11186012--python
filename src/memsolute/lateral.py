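"""Laterally resolved, solute-centric bilayer structure.

Per-lipid properties are binned against the minimum-image xy distance from
the solute COM; 2-D density maps are accumulated in the solute frame and
normalized by their far field; lateral (2-D) radial distribution functions
are computed per leaflet with instantaneous-area density normalization and
fitted with a damped sinusoid over an optional constant or logistic
baseline,

    g(r) = baseline(r) + A exp(-k_a r) sin(omega r + phi),

whose characteristic length 2 pi / omega measures the lateral lipid
spacing.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .exceptions import AnalysisError, ConfigurationError
from .synthetic import logistic_baseline
from .trajectory import minimum_image

__all__ = ["LateralProfile", "RdfProfile", "DampedSinusoidFit",
           "lateral_profile", "density_map", "lateral_rdf", "rdf_2d_points",
           "fit_damped_sinusoid"]


@dataclass
class LateralProfile:
    bin_edges: np.ndarray
    value: np.ndarray
    count: np.ndarray
    label: str = ""
    min_count: int = 50

    @property
    def bin_centers(self):
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def masked(self):
        return self.count < self.min_count


@dataclass
class RdfProfile:
    r: np.ndarray
    g: np.ndarray
    cumulative_n: np.ndarray
    dimensionality: str = "2D"
    metadata: dict = field(default_factory=dict)


@dataclass
class DampedSinusoidFit:
    baseline_kind: str
    baseline_params: tuple
    A: float
    k_a: float
    omega: float
    phase: float
    fit_window: tuple
    rms: float
    param_sd: dict = field(default_factory=dict)

    @property
    def characteristic_length(self) -> float:
        return 2.0 * np.pi / self.omega

    def model(self, r):
        r = np.asarray(r, float)
        if self.baseline_kind == "constant":
            base = self.baseline_params[0]
        else:
            base = logistic_baseline(r, *self.baseline_params)
        return base + self.A * np.exp(-self.k_a * r) * np.sin(
            self.omega * r + self.phase)


def lateral_profile(distances, values, bin_width: float = 0.1,
                    r_max: float = None, label: str = "",
                    min_count: int = 50) -> LateralProfile:
    """Bin per-sample property values against lateral distance.

    ``distances``/``values`` are flat arrays of paired samples (one entry
    per lipid per frame), as produced by the trajectory accessors below.
    """
    d = np.asarray(distances, dtype=float).ravel()
    v = np.asarray(values, dtype=float).ravel()
    if d.size == 0:
        raise AnalysisError("empty lateral profile input")
    if d.size != v.size:
        raise AnalysisError("distances and values length mismatch")
    if r_max is None:
        r_max = d.max()
    edges = np.arange(0.0, r_max + bin_width / 2, bin_width)
    idx = np.digitize(d, edges) - 1
    ok = (idx >= 0) & (idx < len(edges) - 1)
    sums = np.zeros(len(edges) - 1)
    cnts = np.zeros(len(edges) - 1)
    np.add.at(sums, idx[ok], v[ok])
    np.add.at(cnts, idx[ok], 1.0)
    with np.errstate(invalid="ignore"):
        mean = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    return LateralProfile(bin_edges=edges, value=mean, count=cnts,
                          label=label, min_count=min_count)


def solute_lateral_distances(traj, solute_indices, target_indices,
                             state_mask=None, same_leaflet: bool = False):
    """Minimum-image xy distances solute COM -> each target atom, per frame.

    Returns (distances, frame_idx, atom_idx) flat arrays restricted to
    frames where ``state_mask`` is True.  With ``same_leaflet`` only target
    atoms on the solute's side of the midplane (by z sign) are kept;
    membrane-centred coordinates are assumed.
    """
    solute_indices = np.asarray(solute_indices, int)
    target_indices = np.asarray(target_indices, int)
    m = traj.topology.masses[solute_indices]
    frames = range(traj.n_frames) if state_mask is None else \
        np.flatnonzero(np.asarray(state_mask, bool))
    dists, f_idx, a_idx = [], [], []
    for f in frames:
        com = (traj.positions[f, solute_indices] * m[:, None]).sum(0) / m.sum()
        tgt = target_indices
        if same_leaflet:
            tgt = tgt[np.sign(traj.positions[f, tgt, 2]) == np.sign(com[2])]
        d = traj.positions[f, tgt, :2] - com[:2]
        d = minimum_image(d, traj.box[f, :2])
        r = np.hypot(d[:, 0], d[:, 1])
        dists.append(r)
        f_idx.append(np.full(r.size, f))
        a_idx.append(tgt)
    if not dists:
        raise AnalysisError("no frames in the requested state")
    return (np.concatenate(dists), np.concatenate(f_idx),
            np.concatenate(a_idx))


def density_map(points, box, cell: float = 0.05, extent: float = None,
                normalized: bool = True, far_field: float = 2.0):
    """2-D density map of solute-frame points (n, 2) with far-field scaling.

    ``points`` are displacements from the solute COM (minimum-imaged by the
    caller or here against ``box``).  Cells with no exposure are NaN.
    Normalization divides by the mean over cells whose centre is farther
    than ``far_field`` from the origin.
    """
    pts = minimum_image(np.asarray(points, float), np.asarray(box, float))
    if extent is None:
        extent = float(np.abs(pts).max())
    edges = np.arange(-extent, extent + cell / 2, cell)
    H, _, _ = np.histogram2d(pts[:, 0], pts[:, 1], bins=(edges, edges))
    centers = 0.5 * (edges[:-1] + edges[1:])
    xx, yy = np.meshgrid(centers, centers, indexing="ij")
    if not normalized:
        return {"x": centers, "y": centers, "map": H}
    rr = np.hypot(xx, yy)
    far = rr > far_field
    if not np.any(far):
        raise AnalysisError("no far-field cells for normalization")
    mean_far = H[far].mean()
    if mean_far == 0:
        raise AnalysisError("empty far field")
    return {"x": centers, "y": centers, "map": H / mean_far}


def rdf_2d_points(centers, around, box_xy, bin_width: float = 0.02,
                  r_max: float = None, exclude_self: bool = True) -> RdfProfile:
    """2-D RDF of ``around`` points about ``centers`` in a periodic box.

    Both inputs are (n, 2) arrays for one frame (or lists of per-frame
    arrays).  Normalization uses the annulus area and the mean surface
    density of ``around`` in the instantaneous box.
    """
    if isinstance(centers, np.ndarray) and centers.ndim == 2:
        centers, around, box_xy = [centers], [around], [box_xy]
    box0 = np.asarray(box_xy[0], float)
    if r_max is None:
        r_max = float(box0.min()) / 2.0
    edges = np.arange(0.0, r_max + bin_width / 2, bin_width)
    counts = np.zeros(len(edges) - 1)
    n_centers_total = 0
    dens_sum = 0.0
    for C, A, B in zip(centers, around, box_xy):
        C = np.atleast_2d(np.asarray(C, float))
        A = np.asarray(A, float)
        B = np.asarray(B, float)
        dens_sum += A.shape[0] / (B[0] * B[1]) * C.shape[0]
        n_centers_total += C.shape[0]
        for c in C:
            d = minimum_image(A - c, B)
            r = np.hypot(d[:, 0], d[:, 1])
            if exclude_self:
                r = r[r > 1e-9]
            h, _ = np.histogram(r, bins=edges)
            counts += h
    if n_centers_total == 0:
        raise AnalysisError("no center points")
    mean_dens = dens_sum / n_centers_total
    annulus = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    g = counts / (n_centers_total * annulus * mean_dens)
    cum = np.cumsum(counts) / n_centers_total
    r_mid = 0.5 * (edges[:-1] + edges[1:])
    return RdfProfile(r=r_mid, g=g, cumulative_n=cum, dimensionality="2D",
                      metadata={"bin_width": bin_width,
                                "mean_density": mean_dens})


def lateral_rdf(traj, center_indices, around_indices, same_leaflet: bool = True,
                bin_width: float = 0.02, r_max: float = None,
                state_mask=None, center_com: bool = False) -> RdfProfile:
    """Same-leaflet lateral RDF from a trajectory.

    ``center_indices`` may be atom indices (every atom is a center) or, with
    ``center_com``, a group whose mass-weighted COM is the single center.
    Leaflet membership is by z sign in membrane-centred coordinates.
    """
    center_indices = np.asarray(center_indices, int)
    around_indices = np.asarray(around_indices, int)
    frames = range(traj.n_frames) if state_mask is None else \
        np.flatnonzero(np.asarray(state_mask, bool))
    Cs, As, Bs = [], [], []
    m = traj.topology.masses[center_indices]
    for f in frames:
        if center_com:
            com = (traj.positions[f, center_indices] * m[:, None]).sum(0) / m.sum()
            C = com[None, :]
        else:
            C = traj.positions[f, center_indices]
        if not same_leaflet:
            Cs.append(C[:, :2])
            As.append(traj.positions[f, around_indices, :2])
            Bs.append(traj.box[f, :2])
            continue
        # pair centers with around atoms of the same leaflet (z sign)
        a_sign = np.sign(traj.positions[f, around_indices, 2])
        for sign in (1.0, -1.0):
            C_l = C[np.sign(C[:, 2]) == sign]
            if C_l.shape[0] == 0:
                continue
            A_l = around_indices[a_sign == sign]
            Cs.append(C_l[:, :2])
            As.append(traj.positions[f, A_l, :2])
            Bs.append(traj.box[f, :2])
    return rdf_2d_points(Cs, As, Bs, bin_width=bin_width, r_max=r_max,
                         exclude_self=not center_com)


def fit_damped_sinusoid(rdf: RdfProfile, baseline: str = "constant",
                        r_min: float = 0.26, r_max: float = None,
                        omega_range=(2 * np.pi / 0.6, 2 * np.pi / 0.3),
                        n_starts: int = 24) -> DampedSinusoidFit:
    """Least-squares damped-sinusoid fit of a lateral RDF.

    The fit window starts at ``r_min`` (default 0.26 nm for lipid-lipid
    curves; use 0.95 nm for solute-centred curves, below which the depletion
    region is not described by the model).  Multistart over omega in
    ``omega_range``.
    """
    if baseline not in ("constant", "logistic"):
        raise ConfigurationError("baseline must be 'constant' or 'logistic'")
    sel = rdf.r >= r_min
    if r_max is not None:
        sel &= rdf.r <= r_max
    r = rdf.r[sel]
    g = rdf.g[sel]
    if r.size < 8:
        raise AnalysisError("fit window too small")
    amp0 = max((g.max() - g.min()) / 2.0, 1e-3)

    if baseline == "constant":
        def model(r, g_inf, A, k_a, omega, phase):
            return g_inf + A * np.exp(-k_a * r) * np.sin(omega * r + phase)
        base0 = (float(np.median(g)),)
        n_base = 1
    else:
        def model(r, L, k, r0, A, k_a, omega, phase):
            return logistic_baseline(r, L, k, r0) \
                + A * np.exp(-k_a * r) * np.sin(omega * r + phase)
        base0 = (float(np.median(g)), 1.0, float(r.mean()))
        n_base = 3

    best, best_sse = None, np.inf
    omegas = np.linspace(omega_range[0], omega_range[1], n_starts)
    for w0 in omegas:
        for ph0 in (0.0, np.pi / 2, np.pi, 3 * np.pi / 2):
            p0 = (*base0, amp0, 2.0, w0, ph0)
            try:
                popt, pcov = curve_fit(model, r, g, p0=p0, maxfev=5000)
            except (RuntimeError, ValueError):
                continue
            resid = model(r, *popt) - g
            sse = float(resid @ resid)
            if sse < best_sse:
                best, best_sse, best_cov = popt, sse, pcov
    if best is None:
        raise AnalysisError("damped-sinusoid fit failed to converge")

    base_params = tuple(best[:n_base])
    A, k_a, omega, phase = best[n_base:]
    if A < 0:
        A, phase = -A, phase + np.pi
    if omega < 0:
        omega, phase = -omega, np.pi - phase
    phase = float(np.mod(phase, 2 * np.pi))
    rms = float(np.sqrt(best_sse / r.size))
    if abs(A) < 1e-10:
        raise AnalysisError("zero oscillation amplitude: omega unidentifiable")
    sd = np.sqrt(np.abs(np.diag(best_cov)))
    return DampedSinusoidFit(
        baseline_kind=baseline, baseline_params=base_params, A=float(A),
        k_a=float(k_a), omega=float(omega), phase=phase,
        fit_window=(float(r[0]), float(r[-1])), rms=rms,
        param_sd={"omega": float(sd[n_base + 2]), "k_a": float(sd[n_base + 1])})
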