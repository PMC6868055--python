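"""Parametric 3D model of the budding-yeast mitotic spindle and kinetochore.

The model is a static geometric description of a metaphase spindle built
from electron-tomography-scale dimensions: kinetochore microtubules (kMTs)
whose plus ends sit on a 250 nm ring, axially staggered within +/-100 nm;
spindle-pole-body (SPB) marker fluorophores (Spc29) clustered at the kMT
minus ends; outer-kinetochore fluorophores (Nuf2) scattered within a short
range of each plus end; and an inner-kinetochore protein (Cse4) modeled as
straight arms running from each plus end to a convergence point that can be
displaced radially off the microtubule axis.

Coordinate convention: right-handed nm coordinates with the spindle axis
along +x and the origin at the midpoint between the sister plus-end rings
(for a half spindle, at the plus-end ring). With ``rotation="none"`` the
spindle axis is exactly the first image axis after rendering.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .fluorophores import FluorophoreSet, concat

__all__ = [
    "SpindleParams", "Nuf2Params", "Spc29Params", "KinetochoreProteinParams",
    "MicrotubuleGeometry", "build_spindle", "place_nuf2", "place_spb",
    "place_kinetochore_protein", "build_model", "generate_kinet_ensemble",
]


class ConfigurationError(ValueError):
    """Raised for inconsistent model parameters."""


@dataclass
class SpindleParams:
    """Spindle-scale geometry.

    ``n_complexes`` selects a half spindle (1) or a full bipolar spindle
    (2); ``spindle_length`` is the plus-to-minus distance of each kMT;
    ``midzone_gap`` is the axial separation between the two sister plus-end
    rings of a full spindle (the metaphase kinetochore-kinetochore
    separation). ``rotation`` is ``"none"``, ``"random"`` or a fixed
    (rx, ry, rz) Euler-angle triple in degrees.
    """

    n_complexes: int = 2
    n_microtubules: int = 16
    mt_diameter: float = 25.0
    complex_diameter: float = 250.0
    stagger_range: float = 100.0
    spindle_length: float = 350.0
    midzone_gap: float = 400.0
    easy_align: bool = True
    rotation: str | Sequence[float] = "none"

    def __post_init__(self) -> None:
        if self.n_complexes not in (1, 2):
            raise ConfigurationError("n_complexes must be 1 or 2")
        if self.n_microtubules < 1:
            raise ConfigurationError("n_microtubules must be >= 1")
        for name in ("mt_diameter", "complex_diameter", "stagger_range",
                     "spindle_length", "midzone_gap"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")


@dataclass
class Nuf2Params:
    """Outer-kinetochore fluorophores near the kMT plus ends."""

    length: float = 50.0          # nm range from the plus end
    n_per_mt: int = 8
    channel: str = "blue"

    def __post_init__(self) -> None:
        if self.length < 0 or self.n_per_mt < 0:
            raise ConfigurationError("Nuf2 length and n_per_mt must be >= 0")


@dataclass
class Spc29Params:
    """SPB marker fluorophores at the kMT minus ends."""

    length: float = 50.0          # axial spread of fluorophores per tubule
    distance_to_plus: float = 350.0
    tubule_diameter: float = 25.0
    structure_diameter: float = 150.0
    n_fluor_per_tubule: int = 20
    n_tubules: int = 16
    channel: str = "red"

    def __post_init__(self) -> None:
        if min(self.length, self.distance_to_plus, self.tubule_diameter,
               self.structure_diameter) < 0:
            raise ConfigurationError("Spc29 lengths must be >= 0")
        if self.n_fluor_per_tubule < 0 or self.n_tubules < 0:
            raise ConfigurationError("Spc29 counts must be >= 0")


@dataclass
class KinetochoreProteinParams:
    """Inner-kinetochore protein (e.g. Cse4) modeled as arms from the plus end.

    Each kMT carries ``n_arms`` straight arms of length ``arm_length``
    starting on the plus-end rim. ``n_bound_arms`` of them converge on a
    single point displaced ``radial_displacement`` nm off the microtubule
    axis; the rest orient randomly within a cone of half-angle
    ``angle_range`` degrees about the outward axis. The fluorophore sits
    at fraction ``point_marked`` along each arm.

    ``displacement_azimuth`` sets the direction of the displacement:
    ``"outward"`` (default) pushes the convergence point radially away
    from the spindle axis — kinetochores pulled radially off the spindle,
    which dilates the ring of inner-kinetochore marks deterministically —
    while ``"random"`` draws a uniform azimuth about the microtubule axis
    per kMT.
    """

    n_arms: int = 2
    n_bound_arms: int = 2
    arm_length: float = 70.0
    point_marked: float = 1.0
    radial_displacement: float = 0.0
    displacement_azimuth: str = "outward"   # or "random"
    angle_range: float = 90.0
    channel: str = "green"

    def __post_init__(self) -> None:
        if not 0 <= self.n_bound_arms <= self.n_arms:
            raise ConfigurationError("need 0 <= n_bound_arms <= n_arms")
        if not 0.0 <= self.point_marked <= 1.0:
            raise ConfigurationError("point_marked must be in [0, 1]")
        if self.radial_displacement < 0 or self.arm_length < 0:
            raise ConfigurationError("lengths must be >= 0")


@dataclass
class MicrotubuleGeometry:
    """Per-kMT geometry: plus/minus ends, outward axis, and rotation."""

    plus_ends: np.ndarray      # (n, 3) nm
    minus_ends: np.ndarray     # (n, 3) nm
    outward: np.ndarray        # (n, 3) unit vectors plus -> minus direction
    complex_id: np.ndarray     # (n,) 0 or 1
    params: SpindleParams = field(repr=False, default=None)
    rotation: Rotation = field(repr=False, default=None)

    @property
    def n_mts(self) -> int:
        return len(self.plus_ends)

    def apply_rotation(self, xyz: np.ndarray) -> np.ndarray:
        if self.rotation is None:
            return xyz
        return self.rotation.apply(xyz)


def _resolve_rotation(params: SpindleParams, rng: np.random.Generator) -> Rotation | None:
    if params.easy_align or params.rotation == "none":
        return None
    if isinstance(params.rotation, str):
        if params.rotation == "random":
            return Rotation.random(random_state=np.random.RandomState(
                rng.integers(0, 2**31 - 1)))
        raise ConfigurationError(f"unknown rotation {params.rotation!r}")
    return Rotation.from_euler("xyz", list(params.rotation), degrees=True)


def _unit_perp(axis_sign: float, azimuth: np.ndarray) -> np.ndarray:
    """Unit vectors perpendicular to the spindle (+x) axis at given azimuths."""
    return np.stack([np.zeros_like(azimuth), np.cos(azimuth), np.sin(azimuth)], axis=-1)


def build_spindle(params: SpindleParams, seed: int) -> MicrotubuleGeometry:
    """Build per-kMT plus/minus end coordinates.

    Plus ends are evenly spaced on a circle of diameter ``complex_diameter``
    centered on the spindle axis, each offset axially by an independent
    U(-stagger_range, +stagger_range) draw. Minus ends lie
    ``spindle_length`` further out along the axis. With two complexes the
    sister half-spindle is the mirror image through the spindle midplane
    with independent stagger draws, its plus-end ring ``midzone_gap`` away.
    """
    rng = np.random.default_rng(seed)
    n = params.n_microtubules
    r = params.complex_diameter / 2.0
    theta = 2.0 * np.pi * np.arange(n) / n

    plus_list, minus_list, out_list, cid = [], [], [], []
    for c in range(params.n_complexes):
        sign = 1.0 if c == 0 else -1.0
        ring_x = sign * (params.midzone_gap / 2.0 if params.n_complexes == 2 else 0.0)
        stagger = rng.uniform(-params.stagger_range, params.stagger_range, size=n) \
            if params.stagger_range > 0 else np.zeros(n)
        plus = np.column_stack([ring_x + sign * stagger,
                                r * np.cos(theta), r * np.sin(theta)])
        outward = np.tile([sign, 0.0, 0.0], (n, 1))
        minus = plus + params.spindle_length * outward
        plus_list.append(plus)
        minus_list.append(minus)
        out_list.append(outward)
        cid.append(np.full(n, c))

    rot = _resolve_rotation(params, rng)
    return MicrotubuleGeometry(np.vstack(plus_list), np.vstack(minus_list),
                               np.vstack(out_list), np.concatenate(cid),
                               params, rot)


def place_nuf2(geometry: MicrotubuleGeometry, params: Nuf2Params,
               seed: int) -> FluorophoreSet:
    """Scatter outer-kinetochore fluorophores near each plus end.

    Each kMT gets ``n_per_mt`` fluorophores at axial offsets
    U(0, ``length``) from the plus end toward the minus end, placed on the
    microtubule surface at a uniform random azimuth.
    """
    rng = np.random.default_rng(seed)
    n_mt = geometry.n_mts
    total = n_mt * params.n_per_mt
    if total == 0:
        return FluorophoreSet(np.empty((0, 3)), np.empty(0, dtype=object))
    mt_r = geometry.params.mt_diameter / 2.0
    offsets = rng.uniform(0.0, params.length, size=total) if params.length > 0 \
        else np.zeros(total)
    az = rng.uniform(0.0, 2.0 * np.pi, size=total)
    plus = np.repeat(geometry.plus_ends, params.n_per_mt, axis=0)
    outward = np.repeat(geometry.outward, params.n_per_mt, axis=0)
    pos = plus + offsets[:, None] * outward + mt_r * _unit_perp(1.0, az)
    pos = geometry.apply_rotation(pos)
    return FluorophoreSet(pos, np.full(total, params.channel, dtype=object),
                          provenance={"protein": "nuf2", "seed": int(seed)})


def place_spb(geometry: MicrotubuleGeometry, params: Spc29Params,
              seed: int) -> FluorophoreSet:
    """Place SPB marker fluorophores around the kMT minus ends.

    Per complex, ``n_tubules`` sites sit evenly on a circle of diameter
    ``structure_diameter`` at axial distance ``distance_to_plus`` beyond
    the plus-end ring; each site carries ``n_fluor_per_tubule``
    fluorophores spread uniformly within ``length`` axially and within a
    disc of diameter ``tubule_diameter`` radially.
    """
    rng = np.random.default_rng(seed)
    sp = geometry.params
    theta = 2.0 * np.pi * np.arange(params.n_tubules) / max(params.n_tubules, 1)
    r = params.structure_diameter / 2.0

    all_pos = []
    for c in range(sp.n_complexes):
        sign = 1.0 if c == 0 else -1.0
        ring_x = sign * (sp.midzone_gap / 2.0 if sp.n_complexes == 2 else 0.0)
        centers = np.column_stack([
            np.full(params.n_tubules, ring_x + sign * params.distance_to_plus),
            r * np.cos(theta), r * np.sin(theta)])
        k = params.n_fluor_per_tubule
        if k == 0 or params.n_tubules == 0:
            continue
        total = params.n_tubules * k
        axial = (rng.uniform(-0.5, 0.5, size=total) * params.length
                 if params.length > 0 else np.zeros(total))
        # uniform over the tubule cross-section disc
        rad = (params.tubule_diameter / 2.0) * np.sqrt(rng.uniform(size=total))
        az = rng.uniform(0.0, 2.0 * np.pi, size=total)
        base = np.repeat(centers, k, axis=0)
        pos = base.copy()
        pos[:, 0] += sign * axial
        pos += rad[:, None] * _unit_perp(1.0, az)
        all_pos.append(pos)

    if not all_pos:
        return FluorophoreSet(np.empty((0, 3)), np.empty(0, dtype=object))
    pos = geometry.apply_rotation(np.vstack(all_pos))
    return FluorophoreSet(pos, np.full(len(pos), params.channel, dtype=object),
                          provenance={"protein": "spc29", "seed": int(seed)})


def place_kinetochore_protein(geometry: MicrotubuleGeometry,
                              params: KinetochoreProteinParams,
                              seed: int) -> FluorophoreSet:
    """Place inner-kinetochore fluorophores on arms from the plus ends.

    Per kMT a convergence point lies on the axial continuation of the plus
    end (away from the minus end) at straight-line distance ``arm_length``
    from the plus-end center, displaced ``radial_displacement`` nm off the
    microtubule axis at a uniform random azimuth. Bound arms run from
    points on the plus-end rim to that point; unbound arms orient uniformly
    within a cone of half-angle ``angle_range`` about the outward-facing
    axis. Fluorophores sit at fraction ``point_marked`` along each arm.
    """
    rng = np.random.default_rng(seed)
    n_mt = geometry.n_mts
    if params.n_arms == 0:
        return FluorophoreSet(np.empty((0, 3)), np.empty(0, dtype=object))
    mt_r = geometry.params.mt_diameter / 2.0
    inward = -geometry.outward  # away from the minus end, toward the midzone
    d_ax = np.sqrt(max(params.arm_length**2 - params.radial_displacement**2, 0.0))

    pos_out = []
    for i in range(n_mt):
        plus = geometry.plus_ends[i]
        if params.displacement_azimuth == "random":
            u = _unit_perp(1.0, np.array(rng.uniform(0.0, 2.0 * np.pi)))
        else:
            radial = np.array([0.0, plus[1], plus[2]])
            norm = np.linalg.norm(radial)
            # on-axis MT has no defined outward direction; fall back to +y
            u = radial / norm if norm > 0 else np.array([0.0, 1.0, 0.0])
        conv = plus + d_ax * inward[i] + params.radial_displacement * u
        start_az = rng.uniform(0.0, 2.0 * np.pi, size=params.n_arms)
        starts = plus + mt_r * _unit_perp(1.0, start_az)
        # bound arms: straight rods start -> convergence point
        for j in range(params.n_bound_arms):
            pos_out.append(starts[j] + params.point_marked * (conv - starts[j]))
        # unbound arms: random direction within the cone about the inward axis
        for j in range(params.n_bound_arms, params.n_arms):
            half = np.deg2rad(params.angle_range)
            # uniform over the spherical cap of half-angle `half`
            cos_t = rng.uniform(np.cos(half), 1.0)
            sin_t = np.sqrt(1.0 - cos_t**2)
            phi = rng.uniform(0.0, 2.0 * np.pi)
            direction = cos_t * inward[i] + sin_t * _unit_perp(
                1.0, np.array(phi)).ravel()
            direction /= np.linalg.norm(direction)
            pos_out.append(starts[j] + params.point_marked *
                           params.arm_length * direction)

    pos = geometry.apply_rotation(np.array(pos_out).reshape(-1, 3))
    return FluorophoreSet(pos, np.full(len(pos), params.channel, dtype=object),
                          provenance={"protein": "kinetochore",
                                      "radial_displacement": params.radial_displacement,
                                      "seed": int(seed)})


def build_model(spindle: SpindleParams,
                seed: int,
                nuf2: Nuf2Params | None = None,
                spc29: Spc29Params | None = None,
                kinetochore: KinetochoreProteinParams | None = None,
                ) -> FluorophoreSet:
    """Build one complete model instance (all requested proteins)."""
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(4)]
    geometry = build_spindle(spindle, seeds[0])
    parts = []
    if nuf2 is not None:
        parts.append(place_nuf2(geometry, nuf2, seeds[1]))
    if spc29 is not None:
        parts.append(place_spb(geometry, spc29, seeds[2]))
    if kinetochore is not None:
        parts.append(place_kinetochore_protein(geometry, kinetochore, seeds[3]))
    prov = {"seed": int(seed), "spindle": asdict(spindle)}
    for name, p in (("nuf2", nuf2), ("spc29", spc29), ("kinetochore", kinetochore)):
        if p is not None:
            prov[name] = asdict(p)
    return concat(parts, provenance=prov)


def generate_kinet_ensemble(spindle: SpindleParams,
                            n_models: int,
                            seed: int,
                            nuf2: Nuf2Params | None = None,
                            spc29: Spc29Params | None = None,
                            kinetochore: KinetochoreProteinParams | None = None,
                            ) -> tuple[list[FluorophoreSet], list[dict]]:
    """Generate ``n_models`` independent model instances plus a manifest.

    The manifest records the per-model seed derived from the master seed so
    any single model can be regenerated in isolation.
    """
    if n_models < 1:
        raise ConfigurationError("n_models must be >= 1")
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31 - 1))
                   for s in ss.spawn(n_models)]
    models, manifest = [], []
    for i, s in enumerate(child_seeds):
        models.append(build_model(spindle, s, nuf2=nuf2, spc29=spc29,
                                  kinetochore=kinetochore))
        manifest.append({"model_index": i, "seed": s, "master_seed": int(seed)})
    return models, manifest
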