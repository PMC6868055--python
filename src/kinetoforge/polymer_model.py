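"""Bead-spring polymer model of the yeast genome with rDNA crosslinking.

The genome is discretized at ~5 kb per bead into a chain of 2803 beads, of
which a contiguous block of 361 represents the rDNA locus. Chain neighbors
are joined by Hookean springs; beads evolve by overdamped Langevin
(Brownian) dynamics inside a reflecting spherical confinement (the nuclear
envelope), with the centromere bead tethered to a point on the sphere.

rDNA beads within a capture radius of each other form transient pairwise
crosslinks at attempt rate ``k_on``; each link draws an exponential
lifetime with mean ``mu`` at creation and is removed when it expires.
Longer mean durations compact the rDNA locus into tighter clusters, which
is the image-visible signature the downstream classifier learns.

Units: nm, s, pN and pN*nm throughout. The per-axis thermal kick over one
step has variance 2*kT*dt/drag (Einstein relation).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.spatial import cKDTree

from .fluorophores import FluorophoreSet

try:
    from numba import njit
    _HAVE_NUMBA = True
except ImportError:                              # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f
        return deco

__all__ = ["PolymerParams", "PolymerState", "Trajectory", "rdna_only_params",
           "init_chain", "step_dynamics", "update_crosslinks",
           "run_trajectory", "snapshot_to_fluorophores", "IntegrationError"]


class IntegrationError(RuntimeError):
    """Raised when the integrator produces non-finite coordinates."""


@dataclass
class PolymerParams:
    """Parameters of the chain, its dynamics, and the crosslink kinetics.

    Defaults describe the full-genome chain. ``link_every`` sets how many
    dynamics steps pass between crosslink bookkeeping updates; the
    formation probability uses the elapsed interval, so the kinetics are
    insensitive to this choice as long as it stays well below ``mu``.
    """

    n_beads: int = 2803
    n_rdna_beads: int = 361
    kb_per_bead: float = 5.0
    mu: float = 0.19                  # s, mean crosslink duration
    k_on: float = 0.04                # 1/s per eligible pair
    capture_radius: float = 100.0     # nm
    spring_constant: float = 0.005    # pN/nm (chain backbone)
    # crosslink springs are softer: a bead in the condensed state carries
    # ~20 links, and its summed stiffness must stay inside the explicit-
    # Euler stability bound dt*k_total/drag < 2 or the blob detonates
    crosslink_spring_constant: float = 0.002
    rest_length: float = 50.0         # nm
    drag: float = 1.0e-5              # pN*s/nm
    kT: float = 4.1                   # pN*nm (room temperature)
    dt: float = 2.0e-4                # s
    confinement_radius: float = 1000.0
    tether_site: tuple = (0.0, 0.0, 1000.0)
    tether_spring_constant: float = 0.05
    tether_both_ends: bool = False
    link_every: int = 20

    def __post_init__(self) -> None:
        if not 0 < self.n_rdna_beads <= self.n_beads:
            raise ValueError("need 0 < n_rdna_beads <= n_beads")
        if self.mu <= 0 or self.dt <= 0 or self.confinement_radius <= 0:
            raise ValueError("mu, dt and confinement_radius must be > 0")
        if self.rest_length >= 2 * self.confinement_radius:
            raise ValueError("rest_length must be < confinement diameter")

    @property
    def rdna_slice(self) -> slice:
        start = (self.n_beads - self.n_rdna_beads) // 2
        return slice(start, start + self.n_rdna_beads)

    @property
    def rdna_indices(self) -> np.ndarray:
        s = self.rdna_slice
        return np.arange(s.start, s.stop)


def rdna_only_params(mu: float = 0.19, **overrides) -> PolymerParams:
    """Preset simulating just the 361 rDNA beads with both ends tethered.

    This keeps the crosslink kinetics and confinement of the full-genome
    model while dropping the non-rDNA chain, which the rendered (red
    channel only) images never see; it is the fast preset for image-class
    generation.
    """
    kwargs = dict(n_beads=361, n_rdna_beads=361, mu=mu,
                  tether_both_ends=True)
    kwargs.update(overrides)
    return PolymerParams(**kwargs)


@dataclass
class PolymerState:
    """Bead positions, active crosslinks and the simulation clock."""

    positions: np.ndarray                 # (n, 3) nm
    links: dict = field(default_factory=dict)   # (i, j) i<j -> (expiry s, lifetime s)
    clock: float = 0.0
    completed_lifetimes: list = field(default_factory=list)
    # cached link arrays, rebuilt when the link set changes
    _link_idx: np.ndarray | None = field(default=None, repr=False)

    def link_arrays(self) -> np.ndarray:
        if self._link_idx is None:
            self._link_idx = (np.array(sorted(self.links), dtype=int).reshape(-1, 2)
                              if self.links else np.empty((0, 2), dtype=int))
        return self._link_idx

    def invalidate_links(self) -> None:
        self._link_idx = None


def init_chain(params: PolymerParams, seed: int) -> PolymerState:
    """Random-walk initial configuration folded into the confinement sphere.

    The centromere/tether bead (index 0) starts at the tether site; each
    subsequent bead steps ``rest_length`` in a uniform random direction,
    re-drawn as needed to stay inside the sphere.
    """
    rng = np.random.default_rng(seed)
    n = params.n_beads
    r_max = params.confinement_radius
    pos = np.empty((n, 3))
    pos[0] = np.asarray(params.tether_site, dtype=float)
    pos[0] *= min(1.0, r_max / max(np.linalg.norm(pos[0]), 1e-12))
    for i in range(1, n):
        for _ in range(200):
            step = rng.normal(size=3)
            step *= params.rest_length / np.linalg.norm(step)
            cand = pos[i - 1] + step
            if np.linalg.norm(cand) <= r_max:
                pos[i] = cand
                break
        else:  # pragma: no cover - geometrically unreachable with valid params
            pos[i] = pos[i - 1] * (1.0 - params.rest_length / r_max)
    return PolymerState(pos)


def _spring_force(delta: np.ndarray, k: float, rest: float) -> np.ndarray:
    """Hookean force on the first bead of each pair; delta = other - self."""
    dist = np.linalg.norm(delta, axis=-1, keepdims=True)
    dist = np.maximum(dist, 1e-9)
    return k * (dist - rest) * delta / dist


def _forces(state: PolymerState, params: PolymerParams) -> np.ndarray:
    pos = state.positions
    n = len(pos)
    f = np.zeros_like(pos)
    # chain springs
    if n > 1:
        d = pos[1:] - pos[:-1]
        fs = _spring_force(d, params.spring_constant, params.rest_length)
        f[:-1] += fs
        f[1:] -= fs
    # crosslink springs
    idx = state.link_arrays()
    if len(idx):
        d = pos[idx[:, 1]] - pos[idx[:, 0]]
        fl = _spring_force(d, params.crosslink_spring_constant,
                           params.rest_length)
        np.add.at(f, idx[:, 0], fl)
        np.add.at(f, idx[:, 1], -fl)
    # tethers
    kt = params.tether_spring_constant
    if kt > 0:
        site = np.asarray(params.tether_site, dtype=float)
        f[0] += kt * (site - pos[0])
        if params.tether_both_ends and n > 1:
            f[-1] += kt * (site - pos[-1])
    return f


def step_dynamics(state: PolymerState, params: PolymerParams,
                  rng: np.random.Generator) -> PolymerState:
    """One overdamped-Langevin step (in place); confinement enforced after.

    position += dt/drag * F + N(0, 2*kT*dt/drag) per axis, then beads
    outside the confinement sphere are projected back onto it.
    """
    pos = state.positions
    pos += (params.dt / params.drag) * _forces(state, params)
    if params.kT > 0:
        sd = np.sqrt(2.0 * params.kT * params.dt / params.drag)
        pos += rng.normal(0.0, sd, size=pos.shape)
    # reflecting (projecting) confinement
    r = np.linalg.norm(pos, axis=1)
    outside = r > params.confinement_radius
    if outside.any():
        pos[outside] *= (params.confinement_radius / r[outside])[:, None]
    if not np.all(np.isfinite(pos)):
        raise IntegrationError(
            f"non-finite bead coordinate; reduce dt (currently {params.dt})")
    state.clock += params.dt
    return state


def update_crosslinks(state: PolymerState, params: PolymerParams,
                      rng: np.random.Generator,
                      elapsed: float | None = None) -> PolymerState:
    """Expire old links and stochastically form new ones (in place).

    Each unlinked, non-adjacent rDNA pair within ``capture_radius`` forms
    a link with probability 1 - exp(-k_on * elapsed); new links draw an
    exponential lifetime with mean ``mu``. Expired lifetimes are appended
    to ``state.completed_lifetimes``.
    """
    if elapsed is None:
        elapsed = params.dt * params.link_every
    changed = False
    expired = [p for p, (t_exp, _) in state.links.items() if t_exp <= state.clock]
    for pair in expired:
        _, lifetime = state.links.pop(pair)
        state.completed_lifetimes.append(lifetime)
        changed = True
    if params.k_on > 0 and params.capture_radius > 0:
        idx = params.rdna_indices
        tree = cKDTree(state.positions[idx])
        pairs = tree.query_pairs(params.capture_radius, output_type="ndarray")
        if len(pairs):
            pairs = idx[pairs]
            pairs.sort(axis=1)
            pairs = pairs[pairs[:, 1] - pairs[:, 0] > 1]       # skip chain neighbors
            p_form = 1.0 - np.exp(-params.k_on * elapsed)
            formed = pairs[rng.random(len(pairs)) < p_form]
            if len(formed):
                lifetimes = rng.exponential(params.mu, size=len(formed))
                for (i, j), lt in zip(formed, lifetimes):
                    key = (int(i), int(j))
                    if key not in state.links:
                        state.links[key] = (state.clock + lt, lt)
                        changed = True
    if changed:
        state.invalidate_links()
    return state


@njit(cache=True)
def _integrate_chunk(pos, link_i, link_j, k_spring, k_link, rest, k_tether,
                     site, tether_both, dt_over_drag, noise, conf_r):
    """Run noise.shape[0] overdamped steps in place (links held fixed)."""
    n_steps = noise.shape[0]
    n = pos.shape[0]
    f = np.empty((n, 3))
    for s in range(n_steps):
        for i in range(n):
            f[i, 0] = 0.0
            f[i, 1] = 0.0
            f[i, 2] = 0.0
        for i in range(n - 1):
            dx = pos[i + 1, 0] - pos[i, 0]
            dy = pos[i + 1, 1] - pos[i, 1]
            dz = pos[i + 1, 2] - pos[i, 2]
            dist = np.sqrt(dx * dx + dy * dy + dz * dz)
            if dist < 1e-9:
                dist = 1e-9
            c = k_spring * (dist - rest) / dist
            f[i, 0] += c * dx
            f[i, 1] += c * dy
            f[i, 2] += c * dz
            f[i + 1, 0] -= c * dx
            f[i + 1, 1] -= c * dy
            f[i + 1, 2] -= c * dz
        for m in range(link_i.shape[0]):
            a = link_i[m]
            b = link_j[m]
            dx = pos[b, 0] - pos[a, 0]
            dy = pos[b, 1] - pos[a, 1]
            dz = pos[b, 2] - pos[a, 2]
            dist = np.sqrt(dx * dx + dy * dy + dz * dz)
            if dist < 1e-9:
                dist = 1e-9
            c = k_link * (dist - rest) / dist
            f[a, 0] += c * dx
            f[a, 1] += c * dy
            f[a, 2] += c * dz
            f[b, 0] -= c * dx
            f[b, 1] -= c * dy
            f[b, 2] -= c * dz
        if k_tether > 0.0:
            for d in range(3):
                f[0, d] += k_tether * (site[d] - pos[0, d])
            if tether_both and n > 1:
                for d in range(3):
                    f[n - 1, d] += k_tether * (site[d] - pos[n - 1, d])
        for i in range(n):
            for d in range(3):
                pos[i, d] += dt_over_drag * f[i, d] + noise[s, i, d]
            r = np.sqrt(pos[i, 0]**2 + pos[i, 1]**2 + pos[i, 2]**2)
            if r > conf_r:
                scale = conf_r / r
                pos[i, 0] *= scale
                pos[i, 1] *= scale
                pos[i, 2] *= scale


def _advance(state: PolymerState, params: PolymerParams,
             rng: np.random.Generator, n_steps: int) -> None:
    """Advance ``n_steps`` dynamics steps without crosslink updates.

    Uses the compiled kernel when numba is available; the thermal noise is
    drawn from the same generator stream in the same order as the
    step-by-step path, so seeded trajectories are reproducible either way.
    """
    if n_steps <= 0:
        return
    if params.kT > 0:
        sd = np.sqrt(2.0 * params.kT * params.dt / params.drag)
        noise = rng.normal(0.0, sd, size=(n_steps, len(state.positions), 3))
    else:
        noise = np.zeros((n_steps, len(state.positions), 3))
    if _HAVE_NUMBA:
        idx = state.link_arrays()
        _integrate_chunk(state.positions, idx[:, 0].copy(), idx[:, 1].copy(),
                         float(params.spring_constant),
                         float(params.crosslink_spring_constant),
                         float(params.rest_length),
                         float(params.tether_spring_constant),
                         np.asarray(params.tether_site, dtype=float),
                         bool(params.tether_both_ends),
                         float(params.dt / params.drag), noise,
                         float(params.confinement_radius))
        state.clock += n_steps * params.dt
    else:                                        # pragma: no cover
        for s in range(n_steps):
            pos = state.positions
            pos += (params.dt / params.drag) * _forces(state, params)
            pos += noise[s]
            r = np.linalg.norm(pos, axis=1)
            outside = r > params.confinement_radius
            if outside.any():
                pos[outside] *= (params.confinement_radius / r[outside])[:, None]
            state.clock += params.dt
    if not np.all(np.isfinite(state.positions)):
        raise IntegrationError(
            f"non-finite bead coordinate; reduce dt (currently {params.dt})")


@dataclass
class Trajectory:
    """Sampled rDNA bead positions plus provenance."""

    rdna_positions: np.ndarray     # (n_snapshots, n_rdna, 3) nm
    times: np.ndarray              # (n_snapshots,) s
    n_links: np.ndarray            # active crosslinks at each snapshot
    params: PolymerParams
    seed: int

    @property
    def manifest(self) -> dict:
        return {"seed": int(self.seed), "params": asdict(self.params),
                "n_snapshots": int(len(self.times))}

    def radius_of_gyration(self) -> np.ndarray:
        """Rg of the rDNA block at each snapshot."""
        centered = self.rdna_positions - self.rdna_positions.mean(
            axis=1, keepdims=True)
        return np.sqrt((centered**2).sum(axis=2).mean(axis=1))


def run_trajectory(params: PolymerParams, total_steps: int, sample_every: int,
                   seed: int, burn_in_steps: int = 0) -> Trajectory:
    """Simulate and sample rDNA snapshots after an equilibration burn-in.

    Independent random sub-streams drive the thermal noise and the
    crosslink events, so crosslink kinetics are comparable across thermal
    realizations at the same master seed structure.
    """
    if not total_steps >= sample_every >= 1:
        raise ValueError("need total_steps >= sample_every >= 1")
    ss = np.random.SeedSequence(seed)
    rng_thermal, rng_links = [np.random.default_rng(s) for s in ss.spawn(2)]
    init_seed = int(ss.generate_state(1)[0] % (2**31 - 1))
    state = init_chain(params, init_seed)
    rdna = params.rdna_slice

    snapshots, times, n_links = [], [], []
    n_total = burn_in_steps + total_steps
    step = 0
    while step < n_total:
        if step % params.link_every == 0:
            update_crosslinks(state, params, rng_links)
        # advance to the next crosslink update or sample point
        to_link = params.link_every - step % params.link_every
        k = step - burn_in_steps        # sampled-phase step counter
        to_sample = sample_every - k % sample_every if k >= 0 \
            else min(-k, n_total - step)
        n_adv = min(to_link, to_sample, n_total - step)
        _advance(state, params, rng_thermal, n_adv)
        step += n_adv
        k = step - burn_in_steps
        if k >= 1 and k % sample_every == 0:
            snapshots.append(state.positions[rdna].copy())
            times.append(state.clock)
            n_links.append(len(state.links))
    return Trajectory(np.array(snapshots), np.array(times),
                      np.array(n_links, dtype=int), params, int(seed))


def snapshot_to_fluorophores(traj: Trajectory, index: int,
                             channel: str = "red",
                             center: bool = True) -> FluorophoreSet:
    """Convert one rDNA snapshot into a fluorophore set (one emitter/bead).

    With ``center`` the rDNA centroid is moved to the field origin so the
    locus sits mid-image regardless of where it drifted in the nucleus.
    """
    pos = traj.rdna_positions[index].copy()
    if center:
        pos -= pos.mean(axis=0)
    return FluorophoreSet(
        pos, np.full(len(pos), channel, dtype=object),
        provenance={"snapshot": int(index), "time_s": float(traj.times[index]),
                    "mu": traj.params.mu, "seed": traj.seed})
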