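"""Synthetic input generators.

Each generator emits data with exactly the statistical structure one of the
analysis stages assumes, so the whole pipeline can be validated at desk
scale without MD trajectories:

* overdamped Langevin motion of a solute along the bilayer normal sampling
  a prescribed free-energy profile (Boltzmann stationary density),
* isotropic rotational diffusion of a unit vector with a known second-rank
  correlation time 1/(6 Dr),
* i.i.d. exponential inner-sphere water dwell times,
* idealized lattice bilayers with prescribed area/lipid, P-N tilt and C-H
  orientations,
* AR(1) scalar series for error-analysis validation,
* noisy damped-sinusoid lateral RDF curves.

Every generator is a pure function of its integer seed.  The fixtures are
geometric, not physical: they carry the observable being tested and nothing
else.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import MASSES, rt
from .exceptions import AnalysisError, ConfigurationError
from .trajectory import Topology, Trajectory

__all__ = ["PmfSpec", "gen_langevin_z", "gen_rotational_diffusion",
           "gen_exchange_dwells", "gen_toy_bilayer", "gen_ar1",
           "gen_rdf_curve"]


@dataclass
class PmfSpec:
    """Piecewise-linear free-energy profile G(z) on [0, z_max].

    ``z_knots`` (nm) and ``g_knots`` (kJ/mol) define G by linear
    interpolation; the profile is shifted so its minimum is zero.
    """

    z_knots: np.ndarray
    g_knots: np.ndarray
    temperature: float = 310.15

    def __post_init__(self):
        self.z_knots = np.asarray(self.z_knots, dtype=float)
        self.g_knots = np.asarray(self.g_knots, dtype=float)
        if self.z_knots.ndim != 1 or self.z_knots.size < 2:
            raise ConfigurationError("need at least two PMF knots")
        if np.any(np.diff(self.z_knots) <= 0):
            raise ConfigurationError("PMF knots must be strictly increasing")
        if not np.all(np.isfinite(self.g_knots)):
            raise ConfigurationError("PMF must be finite on its support")
        self.g_knots = self.g_knots - self.g_knots.min()

    @property
    def z_max(self) -> float:
        return float(self.z_knots[-1])

    def g(self, z):
        return np.interp(z, self.z_knots, self.g_knots)

    def boltzmann_density(self, z):
        """Unnormalized stationary density exp(-G/RT)."""
        return np.exp(-self.g(z) / rt(self.temperature))


def gen_langevin_z(pmf: PmfSpec, D: float = 1.0, dt: float = 1.0,
                   n_steps: int = 100_000, seed: int = 0,
                   z0: float | None = None) -> np.ndarray:
    """Overdamped Euler–Maruyama z-walk on a prescribed PMF.

    ``D`` in nm^2/ns, ``dt`` in ps.  Reflecting boundaries at 0 and z_max
    (the solute never crosses the bilayer centre; reflection at z = 0 mimics
    leaflet folding).  The stationary histogram converges to
    exp(-G(z)/RT).
    """
    rng = np.random.default_rng(seed)
    beta = 1.0 / rt(pmf.temperature)
    d_nm2_ps = D * 1e-3
    support = pmf.z_max - pmf.z_knots[0]

    # force on a fine uniform grid for O(1) lookup in the update loop
    n_grid = 4096
    zg = np.linspace(pmf.z_knots[0], pmf.z_max, n_grid + 1)
    g = pmf.g(zg)
    grad = np.gradient(g, zg)
    if not np.all(np.isfinite(grad)):
        raise AnalysisError("nonfinite PMF gradient")
    max_drift = d_nm2_ps * dt * beta * np.abs(grad).max()
    if max_drift > 0.02 * support:
        raise ConfigurationError(
            f"dt too large: drift step {max_drift:.3g} nm vs support {support:.3g} nm")
    inv_dz = n_grid / support
    z_lo = float(pmf.z_knots[0])
    z_hi = pmf.z_max

    z = float(z0) if z0 is not None else float(
        zg[np.argmin(g)])  # start at the PMF minimum
    noise = rng.standard_normal(n_steps) * np.sqrt(2.0 * d_nm2_ps * dt)
    drift_scale = d_nm2_ps * dt * beta
    out = np.empty(n_steps)
    for i in range(n_steps):
        k = int((z - z_lo) * inv_dz)
        if k < 0:
            k = 0
        elif k > n_grid:
            k = n_grid
        z = z - drift_scale * grad[k] + noise[i]
        # reflecting boundaries
        while z < z_lo or z > z_hi:
            if z < z_lo:
                z = 2.0 * z_lo - z
            else:
                z = 2.0 * z_hi - z
        out[i] = z
    return out


def _perp_unit(u, rng):
    """Random unit vector perpendicular to u."""
    while True:
        r = rng.standard_normal(3)
        p = r - np.dot(r, u) * u
        n = np.linalg.norm(p)
        if n > 1e-12:
            return p / n


def gen_rotational_diffusion(Dr: float, dt: float, n_steps: int,
                             seed: int = 0) -> np.ndarray:
    """Isotropic rotational diffusion of a unit vector.

    ``Dr`` in 1/ns, ``dt`` in ps.  Per step the vector is rotated by an angle
    sqrt(4 Dr dt)|xi| about a random axis perpendicular to it, which is exact
    to O(dt); the second-rank correlation decays as exp(-6 Dr t).
    Returns an (n_steps + 1, 3) array of unit vectors.
    """
    if Dr < 0:
        raise ConfigurationError("Dr must be >= 0")
    rng = np.random.default_rng(seed)
    u = np.array([0.0, 0.0, 1.0])
    out = np.empty((n_steps + 1, 3))
    out[0] = u
    if Dr == 0:
        out[:] = u
        return out
    dr_ps = Dr * 1e-3
    theta = np.sqrt(4.0 * dr_ps * dt) * np.abs(rng.standard_normal(n_steps))
    for i in range(n_steps):
        axis = _perp_unit(u, rng)
        # rotate u about `axis` (perpendicular to u) by theta[i]
        u = np.cos(theta[i]) * u + np.sin(theta[i]) * np.cross(axis, u)
        u /= np.linalg.norm(u)
        out[i + 1] = u
    return out


def gen_exchange_dwells(tau_m: float, n_events: int, seed: int = 0) -> np.ndarray:
    """i.i.d. exponential dwell times with mean ``tau_m`` (ns)."""
    if tau_m <= 0:
        raise ConfigurationError("tau_m must be positive")
    if n_events < 0:
        raise ConfigurationError("n_events must be >= 0")
    rng = np.random.default_rng(seed)
    return rng.exponential(tau_m, size=int(n_events))


def gen_ar1(phi: float, sigma: float, n: int, seed: int = 0) -> np.ndarray:
    """Stationary AR(1) series x_t = phi x_{t-1} + sigma eps_t."""
    if not -1.0 < phi < 1.0:
        raise ConfigurationError("phi must lie in (-1, 1)")
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal(n) * sigma
    x = np.empty(n)
    x0 = rng.standard_normal() * sigma / np.sqrt(1.0 - phi ** 2)
    prev = x0
    for i in range(n):
        prev = phi * prev + eps[i]
        x[i] = prev
    return x


def logistic_baseline(r, L, k, r0):
    return L / (1.0 + np.exp(-k * (np.asarray(r, float) - r0)))


def gen_rdf_curve(r_grid, A: float, k_a: float, omega: float, phase: float,
                  noise_sd: float = 0.0, baseline=1.0, seed: int = 0):
    """Damped-sinusoid RDF curve g(r) = baseline + A e^(-k_a r) sin(w r + phi).

    ``baseline`` is a constant or a (L, k, r0) logistic tuple.  Gaussian
    noise of sd ``noise_sd`` is added pointwise.
    """
    r = np.asarray(r_grid, dtype=float)
    if np.isscalar(baseline) or isinstance(baseline, (int, float)):
        base = float(baseline) * np.ones_like(r)
    else:
        base = logistic_baseline(r, *baseline)
    g = base + A * np.exp(-k_a * r) * np.sin(omega * r + phase)
    if noise_sd > 0:
        g = g + np.random.default_rng(seed).normal(0.0, noise_sd, size=r.size)
    return g


# ---------------------------------------------------------------------------
# toy bilayer builder

_CH_BOND_LENGTH = 0.109   # nm
_PN_DISTANCE = 0.45       # nm, P->N separation
_CHAIN_SPACING = 0.127    # nm, C-C z projection
_P_DEPTH = 1.85           # nm, |z| of the P lattice plane


def gen_toy_bilayer(n_per_leaflet: int, apl: float = 0.657,
                    pn_tilt_deg: float = 68.7, ch_polar_deg: float = 90.0,
                    jitter: float = 0.0, seed: int = 0, n_frames: int = 1,
                    n_chain_carbons: int = 4, with_water: bool = False,
                    water_density: float = 33.0, water_interface: float = 1.883,
                    water_width: float = 0.2, frame_interval: float = 10.0,
                    box_height: float = 8.0) -> Trajectory:
    """Geometric bilayer fixture on a square lattice.

    Each leaflet carries ``n_per_leaflet`` lipids (a perfect square) on a
    lattice of spacing sqrt(apl).  Each lipid has a P and an N atom with the
    P->N vector at ``pn_tilt_deg`` from the outward leaflet normal (random
    azimuth), and one straight acyl chain along the normal whose C-H bonds
    sit at polar angle ``ch_polar_deg`` from the outward normal.  Optional
    water O atoms fill the outer slabs at ``water_density`` per nm^3 with an
    error-function interface centred at ``water_interface``.
    """
    side = int(round(np.sqrt(n_per_leaflet)))
    if side * side != n_per_leaflet:
        raise ConfigurationError("n_per_leaflet must be a perfect square")
    rng = np.random.default_rng(seed)
    spacing = np.sqrt(apl)
    L = side * spacing
    box = np.array([L, L, box_height])

    names, resnames, resids, roles, ch_bonds = [], [], [], {}, []
    coords0 = []   # ideal (jitter-free) coordinates of one frame

    def add_atom(name, resname, resid, xyz, tags=()):
        idx = len(names)
        names.append(name)
        resnames.append(resname)
        resids.append(resid)
        coords0.append(xyz)
        for t in tags:
            roles.setdefault(t, []).append(idx)
        return idx

    tilt = np.radians(pn_tilt_deg)
    ch_pol = np.radians(ch_polar_deg)
    resid = 0
    for sign in (+1.0, -1.0):               # upper, lower leaflet
        for ix in range(side):
            for iy in range(side):
                resid += 1
                x = (ix + 0.5) * spacing
                y = (iy + 0.5) * spacing
                zP = sign * _P_DEPTH
                azi = rng.uniform(0, 2 * np.pi)
                p_idx = add_atom("P", "LIP", resid, (x, y, zP),
                                 ("lipid", "lipid-P"))
                # P->N at `tilt` from the outward normal (= sign * z)
                dn = _PN_DISTANCE * np.array([
                    np.sin(tilt) * np.cos(azi),
                    np.sin(tilt) * np.sin(azi),
                    sign * np.cos(tilt)])
                add_atom("N", "LIP", resid, (x + dn[0], y + dn[1], zP + dn[2]),
                         ("lipid", "lipid-N"))
                # straight chain toward the bilayer centre
                azi_h = rng.uniform(0, 2 * np.pi)
                for k in range(1, n_chain_carbons + 1):
                    zc = zP - sign * (0.25 + k * _CHAIN_SPACING)
                    c_idx = add_atom(f"C{k}", "LIP", resid, (x, y, zc),
                                     ("lipid", f"chain-carbon-{k}",
                                      "chain-carbon"))
                    h_idx = []
                    for hsgn in (0.0, np.pi):   # two H at opposite azimuths
                        dh = _CH_BOND_LENGTH * np.array([
                            np.sin(ch_pol) * np.cos(azi_h + hsgn),
                            np.sin(ch_pol) * np.sin(azi_h + hsgn),
                            sign * np.cos(ch_pol)])
                        h_idx.append(add_atom(
                            f"H{k}", "LIP", resid,
                            (x + dh[0], y + dh[1], zc + dh[2]),
                            ("lipid", "chain-H")))
                    ch_bonds.append((c_idx, tuple(h_idx)))

    if with_water:
        half = box_height / 2.0
        # rejection-sample z with an error-function interface profile
        from scipy.special import erf
        n_try = rng.poisson(water_density * L * L * box_height)
        zs = rng.uniform(-half, half, size=n_try)
        accept = rng.uniform(size=n_try) < 0.5 * (
            1.0 + erf((np.abs(zs) - water_interface) / (np.sqrt(2) * water_width)))
        zs = zs[accept]
        for z in zs:
            resid += 1
            add_atom("OW", "SOL", resid,
                     (rng.uniform(0, L), rng.uniform(0, L), z),
                     ("water", "water-O"))

    coords0 = np.asarray(coords0)
    top = Topology(
        names=np.asarray(names, dtype=object),
        resnames=np.asarray(resnames, dtype=object),
        resids=np.asarray(resids, dtype=int),
        elements=np.asarray([n[0] if n[0] != "O" else "O" for n in names],
                            dtype=object),
        masses=np.asarray([MASSES.get(n[0], 12.0) if n[0] != "O"
                           else MASSES["O"] for n in names]),
        roles={k: np.asarray(v, int) for k, v in roles.items()},
        ch_bonds=ch_bonds)

    n_atoms = coords0.shape[0]
    pos = np.empty((n_frames, n_atoms, 3))
    for f in range(n_frames):
        p = coords0.copy()
        if jitter > 0:
            p = p + rng.normal(0.0, jitter, size=p.shape)
        pos[f] = p
    times = np.arange(n_frames) * frame_interval
    boxes = np.tile(box, (n_frames, 1))
    return Trajectory(topology=top, positions=pos, times=times, box=boxes)
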