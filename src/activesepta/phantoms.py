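"""Activity phantoms and decay sampling.

A phantom is an ordered list of spheres/cylinders carrying specific
volume activity (Bq/mm^3 internally); later (inner) volumes *replace*
the background activity inside their extent, so a "2:1 hot sphere"
holds twice the background's specific activity.  Emission positions are
sampled proportionally to local specific activity and directions
isotropically; for efficiency the direction sampling can be restricted
to the cone subtending the camera, either with per-decay solid-angle
weights or by thinning (both leave detected-event statistics unbiased).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import PINHOLE_PLANE_Z_MM

MBQ_PER_UCI = 0.037  # 1 uCi = 0.037 MBq


class PhantomError(ValueError):
    pass


@dataclass
class ActivityVolume:
    """A sphere or axis-aligned cylinder with uniform specific activity.

    ``dims``: (radius,) for spheres; (radius, length) for cylinders whose
    axis is parallel to a coordinate axis (``axis`` = 0, 1 or 2).
    ``specific_activity`` in Bq/mm^3.
    """

    shape: str
    center: tuple
    dims: tuple
    specific_activity: float
    axis: int = 2

    def __post_init__(self):
        if self.shape not in ("sphere", "cylinder"):
            raise PhantomError(f"unknown shape {self.shape!r}")
        if min(self.dims) <= 0:
            raise PhantomError("dimensions must be positive")
        if self.specific_activity < 0:
            raise PhantomError("specific activity must be non-negative")

    @property
    def volume_mm3(self) -> float:
        if self.shape == "sphere":
            return 4.0 / 3.0 * np.pi * self.dims[0] ** 3
        r, length = self.dims
        return np.pi * r * r * length

    def contains(self, p) -> np.ndarray:
        p = np.atleast_2d(p) - np.asarray(self.center)
        if self.shape == "sphere":
            return np.einsum("ij,ij->i", p, p) <= self.dims[0] ** 2
        r, length = self.dims
        lat = [i for i in range(3) if i != self.axis]
        radial = p[:, lat[0]] ** 2 + p[:, lat[1]] ** 2 <= r * r
        return radial & (np.abs(p[:, self.axis]) <= length / 2.0)

    def sample_points(self, n: int, rng: np.random.Generator) -> np.ndarray:
        c = np.asarray(self.center, dtype=float)
        if self.shape == "sphere":
            d = rng.standard_normal((n, 3))
            d /= np.linalg.norm(d, axis=1, keepdims=True)
            r = self.dims[0] * rng.random(n) ** (1.0 / 3.0)
            return c + d * r[:, None]
        r, length = self.dims
        rho = r * np.sqrt(rng.random(n))
        phi = rng.uniform(0, 2 * np.pi, n)
        h = rng.uniform(-length / 2, length / 2, n)
        lat = [i for i in range(3) if i != self.axis]
        out = np.tile(c, (n, 1))
        out[:, lat[0]] += rho * np.cos(phi)
        out[:, lat[1]] += rho * np.sin(phi)
        out[:, self.axis] += h
        return out


@dataclass
class Phantom:
    """Ordered volumes; later volumes override earlier ones where they overlap."""

    volumes: list = field(default_factory=list)

    def __post_init__(self):
        if not self.volumes:
            raise PhantomError("phantom needs at least one volume")

    def specific_activity_at(self, p) -> np.ndarray:
        """Local specific activity (Bq/mm^3); later volumes take precedence."""
        p = np.atleast_2d(p)
        out = np.zeros(len(p))
        assigned = np.zeros(len(p), dtype=bool)
        for vol in reversed(self.volumes):
            inside = vol.contains(p) & ~assigned
            out[inside] = vol.specific_activity
            assigned |= inside
        return out

    @property
    def effective_activities_bq(self) -> np.ndarray:
        """Per-volume total activity after the override rule (Monte Carlo-free
        for disjoint inner volumes fully contained in the background)."""
        acts = []
        for i, vol in enumerate(self.volumes):
            a = vol.specific_activity * vol.volume_mm3
            # subtract activity displaced by later (overriding) volumes
            for later in self.volumes[i + 1:]:
                if _contained_in(later, vol):
                    a -= vol.specific_activity * later.volume_mm3
            acts.append(a)
        return np.asarray(acts)

    @property
    def total_activity_bq(self) -> float:
        return float(self.effective_activities_bq.sum())


def _contained_in(inner: ActivityVolume, outer: ActivityVolume) -> bool:
    """Conservative containment test on the inner volume's bounding sphere."""
    c = np.asarray(inner.center) - np.asarray(outer.center)
    r_in = inner.dims[0] if inner.shape == "sphere" else float(
        np.hypot(inner.dims[0], inner.dims[1] / 2))
    if outer.shape == "sphere":
        return np.linalg.norm(c) + r_in <= outer.dims[0]
    r, length = outer.dims
    lat = [i for i in range(3) if i != outer.axis]
    return (np.hypot(c[lat[0]], c[lat[1]]) + r_in <= r
            and abs(c[outer.axis]) + r_in <= length / 2)


# ---------------------------------------------------------------------------
# Specific activity (reporting boundary in uCi/cm^3)
# ---------------------------------------------------------------------------

def specific_volume_activity(activity_mbq: float, shape: str, dims_cm) -> float:
    """Specific volume activity A_V = A / Vol in uCi/cm^3.

    3.7 MBq in a 4 cm-radius sphere gives 0.373 uCi/cm^3.
    """
    dims_cm = np.atleast_1d(dims_cm)
    if shape == "sphere":
        vol_cm3 = 4.0 / 3.0 * np.pi * dims_cm[0] ** 3
    elif shape == "cylinder":
        vol_cm3 = np.pi * dims_cm[0] ** 2 * dims_cm[1]
    else:
        raise PhantomError(f"unknown shape {shape!r}")
    if vol_cm3 <= 0:
        raise PhantomError("volume must be positive")
    return float(activity_mbq / MBQ_PER_UCI / vol_cm3)


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

BACKGROUND_RADIUS_MM = 40.0
BACKGROUND_ACTIVITY_BQ = 3.7e6
HOT_SPHERE_DIAMETER_MM = 10.0
HOT_SPHERE_SPACING_MM = 20.0
HOT_TO_BACKGROUND_RATIO = 2.0
FOV_CENTER_Z_MM = 0.0  # the global origin is the FOV centre

SPECT_CYL_DIAMETER_MM = 50.0
SPECT_CYL_LENGTH_MM = 50.0
SPECT_CYL_ACTIVITY_BQ = 3.0e6
SPECT_ROD_DIAMETER_MM = 2.0
SPECT_ROD_RATIO = 10.0
SPECT_ROD_XY_MM = ((12.0, 0.0), (-8.0, -8.0))  # unstated in the source study


def make_phantom(preset: str, d_cm: float = 2.0,
                 background: bool = True) -> Phantom:
    """Construct a named phantom preset.

    Presets
    -------
    ``background_sphere``
        4 cm-radius sphere, 3.7 MBq total, centred on the FOV centre.
    ``derenzo3``
        Three 1 cm spheres, 2 cm apart, in a plane parallel to the
        collimator at distance ``d_cm``, hot:background specific activity
        2:1, inside the background sphere.
    ``tetra4``
        Tetrahedron of four 1 cm spheres with 2 cm spacing (nearest plane
        at ``d_cm``), with or without the background sphere.
    ``spect_cylinder``
        5 cm diameter x 5 cm cylinder (3 MBq) along the ring axis plus two
        2 mm rods at 10:1 specific activity ratio.
    """
    if preset == "background_sphere":
        a_v = BACKGROUND_ACTIVITY_BQ / (4 / 3 * np.pi * BACKGROUND_RADIUS_MM**3)
        return Phantom([ActivityVolume("sphere", (0, 0, FOV_CENTER_Z_MM),
                                       (BACKGROUND_RADIUS_MM,), a_v)])

    if preset == "derenzo3":
        base = make_phantom("background_sphere")
        a_bg = base.volumes[0].specific_activity
        z = PINHOLE_PLANE_Z_MM - 10.0 * d_cm   # distance d from the collimator
        s = HOT_SPHERE_SPACING_MM
        # equilateral triangle of side s centred on the camera axis
        centers = [(-s / 2, -s / (2 * np.sqrt(3)), z),
                   (s / 2, -s / (2 * np.sqrt(3)), z),
                   (0.0, s / np.sqrt(3), z)]
        hots = [ActivityVolume("sphere", c, (HOT_SPHERE_DIAMETER_MM / 2,),
                               HOT_TO_BACKGROUND_RATIO * a_bg) for c in centers]
        return Phantom(base.volumes + hots)

    if preset == "tetra4":
        s = HOT_SPHERE_SPACING_MM
        z = PINHOLE_PLANE_Z_MM - 10.0 * d_cm
        tri = [(-s / 2, -s / (2 * np.sqrt(3)), z),
               (s / 2, -s / (2 * np.sqrt(3)), z),
               (0.0, s / np.sqrt(3), z)]
        apex = (0.0, 0.0, z - s * np.sqrt(2.0 / 3.0))
        if background:
            base = make_phantom("background_sphere")
            a_bg = base.volumes[0].specific_activity
            hots = [ActivityVolume("sphere", c, (HOT_SPHERE_DIAMETER_MM / 2,),
                                   HOT_TO_BACKGROUND_RATIO * a_bg)
                    for c in tri + [apex]]
            return Phantom(base.volumes + hots)
        a_v = HOT_TO_BACKGROUND_RATIO * BACKGROUND_ACTIVITY_BQ / (
            4 / 3 * np.pi * BACKGROUND_RADIUS_MM**3)
        return Phantom([ActivityVolume("sphere", c,
                                       (HOT_SPHERE_DIAMETER_MM / 2,), a_v)
                        for c in tri + [apex]])

    if preset == "spect_cylinder":
        a_bg = SPECT_CYL_ACTIVITY_BQ / (
            np.pi * (SPECT_CYL_DIAMETER_MM / 2) ** 2 * SPECT_CYL_LENGTH_MM)
        vols = [ActivityVolume("cylinder", (0.0, 0.0, 0.0),
                               (SPECT_CYL_DIAMETER_MM / 2,
                                SPECT_CYL_LENGTH_MM), a_bg, axis=2)]
        for (x, y) in SPECT_ROD_XY_MM:
            vols.append(ActivityVolume("cylinder", (x, y, 0.0),
                                       (SPECT_ROD_DIAMETER_MM / 2,
                                        SPECT_CYL_LENGTH_MM),
                                       SPECT_ROD_RATIO * a_bg, axis=2))
        return Phantom(vols)

    raise PhantomError(f"unknown preset {preset!r}")


# ---------------------------------------------------------------------------
# Emission sampling
# ---------------------------------------------------------------------------

@dataclass
class EmissionSamples:
    """Columnar emission list: positions, unit directions, times, weights."""

    positions: np.ndarray
    directions: np.ndarray
    times_s: np.ndarray
    weights: np.ndarray

    def __len__(self) -> int:
        return len(self.positions)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "x": self.positions[:, 0], "y": self.positions[:, 1],
            "z": self.positions[:, 2], "dx": self.directions[:, 0],
            "dy": self.directions[:, 1], "dz": self.directions[:, 2],
            "t": self.times_s, "weight": self.weights})


def _isotropic_directions(n: int, rng: np.random.Generator) -> np.ndarray:
    d = rng.standard_normal((n, 3))
    return d / np.linalg.norm(d, axis=1, keepdims=True)


def _cone_directions(positions, center, radius, rng):
    """Uniform directions within each point's cone subtending the disk
    of given center/radius (padded to a bounding cone); returns
    (directions, solid-angle weights Omega/4pi)."""
    c = np.asarray(center, dtype=float)
    rel = c - positions
    dist = np.linalg.norm(rel, axis=1)
    axis = rel / dist[:, None]
    half = np.arctan2(radius, dist)
    cos_half = np.cos(half)
    u = rng.random(len(positions))
    ct = 1.0 - u * (1.0 - cos_half)          # uniform in solid angle
    st = np.sqrt(np.clip(1.0 - ct**2, 0, 1))
    phi = rng.uniform(0, 2 * np.pi, len(positions))
    helper = np.where(np.abs(axis[:, 2:3]) < 0.9,
                      np.tile([0.0, 0.0, 1.0], (len(positions), 1)),
                      np.tile([1.0, 0.0, 0.0], (len(positions), 1)))
    e1 = np.cross(helper, axis)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(axis, e1)
    d = (st * np.cos(phi))[:, None] * e1 + (st * np.sin(phi))[:, None] * e2 \
        + ct[:, None] * axis
    weights = (1.0 - cos_half) / 2.0         # Omega / 4pi
    return d, weights


def sample_emissions(phantom: Phantom, n_decays: int,
                     seed: int | None = None,
                     rng: np.random.Generator | None = None,
                     acquisition_s: float = 1.0,
                     towards=None, thin: bool = False) -> EmissionSamples:
    """Sample decay positions and directions from a phantom.

    Positions are allocated to volumes by a multinomial on the effective
    (override-corrected) activities, then drawn uniformly inside each
    volume with rejection against overriding volumes.  Directions are
    isotropic; with ``towards=(center, radius)`` they are drawn inside
    the cone subtending that disk, with weights ``Omega/4pi`` (or, with
    ``thin=True``, decays are Bernoulli-thinned by that weight so that
    all returned samples carry weight 1).  Decay times are uniform over
    the acquisition window.
    """
    if n_decays < 0:
        raise PhantomError("n_decays must be non-negative")
    rng = rng if rng is not None else np.random.default_rng(seed)
    acts = phantom.effective_activities_bq
    if acts.sum() <= 0:
        raise PhantomError("phantom has no activity")
    counts = rng.multinomial(n_decays, acts / acts.sum())
    pos_parts = []
    for vol, cnt, i in zip(phantom.volumes, counts, range(len(counts))):
        if cnt == 0:
            continue
        got = []
        need = cnt
        while need > 0:
            cand = vol.sample_points(int(need * 1.2) + 8, rng)
            # reject points overridden by any later volume
            keep = np.ones(len(cand), dtype=bool)
            for later in phantom.volumes[i + 1:]:
                keep &= ~later.contains(cand)
            cand = cand[keep][:need]
            got.append(cand)
            need -= len(cand)
        pos_parts.append(np.concatenate(got))
    positions = (np.concatenate(pos_parts) if pos_parts
                 else np.zeros((0, 3)))
    n = len(positions)
    if towards is None:
        directions = _isotropic_directions(n, rng)
        weights = np.ones(n)
    else:
        center, radius = towards
        directions, weights = _cone_directions(positions, center, radius, rng)
        if thin:
            keep = rng.random(n) < weights
            positions, directions = positions[keep], directions[keep]
            weights = np.ones(keep.sum())
            n = len(positions)
    times = rng.uniform(0.0, acquisition_s, n)
    return EmissionSamples(positions, directions, times, weights)
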