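"""Rotational dynamics of the chelate.

Molecule-fixed unit vectors (the normal of the plane of the four
Gd-coordinated oxygens, the Gd-O_water / Gd-H_water vectors of the
coordinated water, or the amphiphilic moment) are extracted per frame, the
second-rank Legendre orientational autocorrelation

    C(t) = < P2( u(s) . u(s+t) ) >

is computed over time origins conditioned on the solute state, and a sum of
exponentials with an optional plateau,

    C(t) = sum_i a_i exp(-t/tau_i) + a_inf,     sum_i a_i + a_inf = 1,

is fitted.  The rotational correlation time is the amplitude-weighted mean
of the fitted times, tau_R = sum a_i tau_i / sum a_i, with the plateau
("wobbling" residual) excluded.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.optimize import least_squares

from .exceptions import AnalysisError, ConfigurationError
from .stats import block_analysis

__all__ = ["VectorSeries", "AcfFit", "extract_vectors", "p2_acf", "fit_acf",
           "orientation_distribution"]

VECTOR_DEFINITIONS = ("coord-O-plane-normal", "Gd-Owater", "Gd-Hwater",
                      "amphiphilic")


@dataclass
class VectorSeries:
    times: np.ndarray            # ps
    vectors: np.ndarray          # (n, 3), unit norm; NaN rows = masked
    definition: str = ""

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        norms = np.linalg.norm(self.vectors, axis=1)
        valid = np.isfinite(norms)
        if np.any(np.abs(norms[valid] - 1.0) > 1e-6):
            self.vectors = self.vectors / norms[:, None]

    @property
    def valid(self) -> np.ndarray:
        return np.all(np.isfinite(self.vectors), axis=1)


@dataclass
class AcfFit:
    lags: np.ndarray
    C: np.ndarray
    amplitudes: np.ndarray
    taus: np.ndarray             # ps
    a_inf: float
    tau_R: float                 # ps
    fit_rms: float
    param_ci: dict = field(default_factory=dict)

    @property
    def model(self):
        def f(t):
            t = np.asarray(t, float)
            return (self.amplitudes[None, :] *
                    np.exp(-t[:, None] / self.taus[None, :])).sum(axis=1) + self.a_inf
        return f


def _plane_normal(points: np.ndarray) -> np.ndarray:
    """Unit normal of the best-fit plane (smallest principal axis)."""
    c = points - points.mean(axis=0)
    w, v = np.linalg.eigh(c.T @ c)
    if w[1] < 1e-12:      # collinear points: plane undefined
        raise AnalysisError("degenerate (collinear) coordinated-oxygen set")
    return v[:, 0]


def extract_vectors(traj, definition: str, timeline=None) -> VectorSeries:
    """Per-frame molecule-fixed unit vector of the requested definition.

    ``Gd-Owater`` / ``Gd-Hwater`` need a coordination ``timeline`` (from
    ``water_exchange.track_inner_sphere``) to know which water is bound;
    frames without a coordinated water are masked with NaN.  The sign of the
    plane normal is made continuous in time (flipped whenever the dot
    product with the previous frame is negative).
    """
    if definition not in VECTOR_DEFINITIONS:
        raise ConfigurationError(f"unknown vector definition {definition!r}")
    top = traj.topology
    n = traj.n_frames
    out = np.full((n, 3), np.nan)

    if definition == "coord-O-plane-normal":
        idx = top.require("chelate-coord-O")
        for f in range(n):
            out[f] = _plane_normal(traj.positions[f, idx])
        for f in range(1, n):
            if np.dot(out[f], out[f - 1]) < 0:
                out[f] = -out[f]
    elif definition == "amphiphilic":
        phil = top.require("chelate-hydrophilic-set")
        phob = top.require("chelate-hydrophobic-set")
        m1 = top.masses[phil] / top.masses[phil].sum()
        m2 = top.masses[phob] / top.masses[phob].sum()
        v = (traj.positions[:, phil, :] * m1[None, :, None]).sum(axis=1) \
            - (traj.positions[:, phob, :] * m2[None, :, None]).sum(axis=1)
        out = v / np.linalg.norm(v, axis=1)[:, None]
    else:
        if timeline is None:
            raise ConfigurationError(
                f"{definition} requires a coordination timeline")
        gd = top.require("chelate-Gd")[0]
        role = "water-O" if definition == "Gd-Owater" else "water-H"
        atoms = top.require(role)
        resids = top.resids[atoms]
        for f in range(n):
            wid = timeline.coordinated[f]
            if wid < 0:
                continue
            sel = atoms[resids == wid]
            if sel.size == 0:
                continue
            # average over the (1 or 2) atoms of the role in that water
            v = traj.positions[f, sel] - traj.positions[f, gd]
            v = v / np.linalg.norm(v, axis=1)[:, None]
            v = v.mean(axis=0)
            out[f] = v / np.linalg.norm(v)
    norms = np.linalg.norm(out, axis=1)
    ok = np.isfinite(norms) & (norms > 0)
    out[ok] = out[ok] / norms[ok, None]
    return VectorSeries(times=traj.times.copy(), vectors=out,
                        definition=definition)


def _p2(x):
    return 0.5 * (3.0 * x * x - 1.0)


def p2_acf(series: VectorSeries, max_lag: float, state_mask=None,
           min_pairs: int = 10):
    """Second-rank Legendre ACF averaged over time origins.

    ``max_lag`` in ps.  With a boolean ``state_mask`` (True = frame usable)
    only origin pairs whose entire span lies inside one contiguous masked
    run contribute, so no pair straddles a state transition.  Lags with
    fewer than ``min_pairs`` valid pairs are truncated.
    Returns (lags_ps, C).
    """
    v = series.vectors
    n = v.shape[0]
    if n < 2:
        raise AnalysisError("need at least two frames")
    dt = float(np.diff(series.times)[0])
    if np.any(np.abs(np.diff(series.times) - dt) > 1e-6):
        raise AnalysisError("nonuniform time grid")
    n_lags = int(np.floor(max_lag / dt)) + 1
    usable = series.valid if state_mask is None else (
        series.valid & np.asarray(state_mask, bool))

    num = np.zeros(n_lags)
    cnt = np.zeros(n_lags, dtype=int)
    # contiguous runs of usable frames
    padded = np.concatenate(([False], usable, [False]))
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    ends = np.flatnonzero(padded[:-1] & ~padded[1:])
    for s, e in zip(starts, ends):
        seg = v[s:e]
        m = e - s
        for k in range(min(n_lags, m)):
            dots = np.einsum("ij,ij->i", seg[: m - k], seg[k:])
            num[k] += _p2(dots).sum()
            cnt[k] += m - k
    keep = cnt >= min_pairs
    if not np.any(keep):
        raise AnalysisError("no usable origin pairs")
    last = int(np.max(np.flatnonzero(keep))) + 1
    lags = np.arange(last) * dt
    C = np.full(last, np.nan)
    ok = cnt[:last] > 0
    C[ok] = num[:last][ok] / cnt[:last][ok]
    keep2 = np.isfinite(C) & (cnt[:last] >= min_pairs)
    return lags[keep2], C[keep2]


def fit_acf(lags, C, n_exp: int = 2, with_plateau: bool = False,
            n_starts: int = 8, seed: int = 0) -> AcfFit:
    """Constrained multi-exponential fit of a P2 autocorrelation curve.

    Amplitudes and the optional plateau are non-negative and sum to one
    (softmax parametrization); decay times are positive.  Multistart
    initialization over log-spaced time guesses; the best residual wins.
    95% parameter CIs come from the Gauss-Newton covariance at the optimum.
    """
    lags = np.asarray(lags, dtype=float)
    C = np.asarray(C, dtype=float)
    if lags.size < n_exp * 2 + 2:
        raise AnalysisError("too few ACF points for the requested model")
    t_span = max(lags[-1], 1e-9)
    rng = np.random.default_rng(seed)
    n_amp = n_exp + (1 if with_plateau else 0)

    def unpack(theta):
        logits = np.concatenate(([0.0], theta[: n_amp - 1])) if n_amp > 1 \
            else np.array([0.0])
        amps = np.exp(logits - logits.max())
        amps = amps / amps.sum()
        taus = np.exp(theta[n_amp - 1:])
        if with_plateau:
            return amps[:-1], taus, amps[-1]
        return amps, taus, 0.0

    def resid(theta):
        a, tau, a_inf = unpack(theta)
        model = (a[None, :] * np.exp(-lags[:, None] / tau[None, :])).sum(axis=1) + a_inf
        return model - C

    best = None
    for trial in range(n_starts):
        if trial == 0:
            tau0 = np.geomspace(t_span / (10.0 * n_exp), t_span / 2.0, n_exp)
        else:
            tau0 = np.sort(np.exp(rng.uniform(
                np.log(t_span / 200.0), np.log(2.0 * t_span), n_exp)))
        theta0 = np.concatenate((np.zeros(n_amp - 1), np.log(tau0)))
        try:
            sol = least_squares(resid, theta0, method="lm", max_nfev=20000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise AnalysisError("ACF fit failed to converge from any start")

    a, tau, a_inf = unpack(best.x)
    order = np.argsort(tau)
    a, tau = a[order], tau[order]
    tau_R = float(np.sum(a * tau) / np.sum(a))
    rms = float(np.sqrt(np.mean(best.fun ** 2)))

    # parameter covariance -> 95% CI on the raw parameters
    ci = {}
    try:
        J = best.jac
        dof = max(lags.size - best.x.size, 1)
        cov = np.linalg.inv(J.T @ J) * 2.0 * best.cost / dof
        sd = np.sqrt(np.abs(np.diag(cov)))
        tcrit = sps.t.ppf(0.975, dof)
        ci["log_tau_halfwidth"] = (tcrit * sd[n_amp - 1:])[order].tolist()
    except np.linalg.LinAlgError:
        pass
    return AcfFit(lags=lags, C=C, amplitudes=a, taus=tau, a_inf=float(a_inf),
                  tau_R=tau_R, fit_rms=rms, param_ci=ci)


def orientation_distribution(series: VectorSeries, leaflet_signs=None,
                             state_mask=None, bin_deg: float = 1.0) -> dict:
    """Angle of the vector to the outward leaflet normal.

    ``leaflet_signs`` is a per-frame array of +1 (upper leaflet) / -1
    (lower); the vector is flipped in the lower leaflet so that 0 deg always
    means pointing out of the membrane.  Returns the pdf over [0, 180] deg,
    the mean angle and its blocking-analysis CI.
    """
    v = series.vectors
    usable = series.valid
    if state_mask is not None:
        usable = usable & np.asarray(state_mask, bool)
    sgn = np.ones(v.shape[0]) if leaflet_signs is None \
        else np.asarray(leaflet_signs, float)
    cosang = np.clip(sgn * v[:, 2], -1.0, 1.0)[usable]
    if cosang.size == 0:
        raise AnalysisError("no usable frames")
    ang = np.degrees(np.arccos(cosang))
    edges = np.arange(0.0, 180.0 + bin_deg / 2, bin_deg)
    pdf, _ = np.histogram(ang, bins=edges, density=True)
    if ang.size >= 16:
        br = block_analysis(ang)
        mean, ci = br.mean, br.ci_halfwidth
    else:
        mean, ci = float(ang.mean()), float("nan")
    return {"bin_edges": edges, "pdf": pdf, "mean": mean, "ci": ci}
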