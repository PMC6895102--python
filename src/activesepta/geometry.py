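"""Constructive geometry for the active-septa multi-pinhole gamma camera.

The basic cell ("module") is a knife-edge tungsten pinhole looking at a
12 x 12 x 3 mm^3 monolithic GaGG bottom detector, with four GaGG
*active-septa* walls (2 x 10 x 5 mm^3 each, pinwheel arrangement) standing
on the bottom crystal's perimeter.  The septa act simultaneously as
collimator blades between neighbouring cells and as position-sensitive
detectors, which is what removes the multiplexing ambiguity of
conventional multi-pinhole cameras.

Conventions
-----------
* Global frame: origin at the centre of the field of view, +z towards the
  detector.  The pinhole plate centre sits at z = 45.2 mm; septa walls
  span z in [50, 55) mm and the bottom detector z in [55, 58) mm.  The
  3.8 mm gap between the plate exit face and the septa tops is what lets
  the walls intercept every cross-cell ray: the steepest ray a knife-edge
  aperture passes (tan = d'/h, 61.5 degrees off axis) still meets a wall
  before reaching a neighbouring cell.
* Module-local frame: origin at that module's pinhole centre, axes as in
  the global frame for the planar camera; the field of view is at
  negative local z.
* All element boxes are half-open ``[lo, hi)`` so that point-in-element
  lookup is unique on shared faces.
* Lengths in mm; angles in degrees at the interface, radians internally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

# ---------------------------------------------------------------------------
# Frozen geometry constants (mm / degrees)
# ---------------------------------------------------------------------------

PINHOLE_THICKNESS_MM = 2.0      #: tungsten plate thickness h
PINHOLE_INNER_DIAMETER_MM = 2.0  #: knife-edge aperture diameter d
PINHOLE_OUTER_DIAMETER_MM = 3.68  #: aperture diameter d' at the plate faces
PINHOLE_OPENING_DEG = 40.0      #: cone half-opening; tan(40 deg) reproduces d'

PINHOLE_PLANE_Z_MM = 45.2       #: global z of the pinhole plate centre

SEPTA_Z_MM = (50.0, 55.0)       #: global z-extent of the four septa walls
BOTTOM_Z_MM = (55.0, 58.0)      #: global z-extent of the bottom detector
#: the same extents in the module-local frame (origin at the pinhole centre)
SEPTA_Z_LOCAL_MM = (SEPTA_Z_MM[0] - PINHOLE_PLANE_Z_MM,
                    SEPTA_Z_MM[1] - PINHOLE_PLANE_Z_MM)
BOTTOM_Z_LOCAL_MM = (BOTTOM_Z_MM[0] - PINHOLE_PLANE_Z_MM,
                     BOTTOM_Z_MM[1] - PINHOLE_PLANE_Z_MM)
MODULE_HALF_XY_MM = 6.0         #: module footprint is 12 x 12 mm
WALL_THICKNESS_MM = 2.0         #: septa wall thickness l
WALL_LENGTH_MM = 10.0
MODULE_PITCH_MM = 12.0          #: modules abut in the 4 x 4 array

THETA_MIN_DEG = 28.5            #: minimum incidence angle onto a wall

SPECT_N_MODULES = 240
SPECT_N_AZIMUTHAL = 24          #: pinholes every 15 degrees
SPECT_N_AXIAL = 10
SPECT_PINHOLE_RADIUS_MM = 40.0  #: ~8 cm inner diameter
SPECT_AXIAL_LENGTH_MM = 120.0

ELEMENT_KINDS = ("bottom", "wall+y", "wall+x", "wall-y", "wall-x")


class GeometryError(ValueError):
    """Raised for dimensionally inconsistent geometry constants."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Box:
    """Axis-aligned half-open box ``[lo, hi)`` in some frame."""

    lo: tuple[float, float, float]
    hi: tuple[float, float, float]

    def contains(self, p) -> bool:
        p = np.asarray(p, dtype=float)
        lo = np.asarray(self.lo)
        hi = np.asarray(self.hi)
        return bool(np.all(p >= lo) and np.all(p < hi))

    @property
    def volume(self) -> float:
        lo = np.asarray(self.lo)
        hi = np.asarray(self.hi)
        return float(np.prod(hi - lo))

    def overlaps(self, other: "Box") -> bool:
        lo = np.maximum(self.lo, other.lo)
        hi = np.minimum(self.hi, other.hi)
        return bool(np.all(hi > lo))


@dataclass(frozen=True)
class DetectorElementID:
    """Identifies one of the five detector elements of one module."""

    module: int
    kind: str  # one of ELEMENT_KINDS

    def __post_init__(self):
        if self.kind not in ELEMENT_KINDS and self.kind != "block":
            raise GeometryError(f"unknown element kind {self.kind!r}")


@dataclass(frozen=True)
class PinholeSpec:
    """Knife-edge (double cone) pinhole through the tungsten plate.

    The open aperture is the union of two cones meeting at the knife edge
    (diameter ``inner_diameter_mm`` at the plate mid-plane) and opening to
    ``outer_diameter_mm`` at either plate face.
    """

    thickness_mm: float = PINHOLE_THICKNESS_MM
    inner_diameter_mm: float = PINHOLE_INNER_DIAMETER_MM
    outer_diameter_mm: float = PINHOLE_OUTER_DIAMETER_MM
    opening_deg: float = PINHOLE_OPENING_DEG
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self):
        if not (self.outer_diameter_mm > self.inner_diameter_mm > 0):
            raise GeometryError("need d' > d > 0")
        if self.thickness_mm <= 0:
            raise GeometryError("plate thickness must be positive")
        if not (0 < self.opening_deg < 180):
            raise GeometryError("opening angle out of (0, 180)")

    @property
    def cone_slope(self) -> float:
        """Radius growth per unit |z| away from the knife edge."""
        return (self.outer_diameter_mm - self.inner_diameter_mm) / self.thickness_mm

    def void_radius(self, z_local: float) -> float:
        """Aperture radius at signed plate depth ``z_local`` (0 = knife edge)."""
        half = self.thickness_mm / 2.0
        z = min(abs(z_local), half)
        return self.inner_diameter_mm / 2.0 + self.cone_slope * z


def _wall_boxes(z_extent: tuple[float, float] = SEPTA_Z_LOCAL_MM) -> dict[str, Box]:
    """Four 2 x 10 x 5 walls in pinwheel arrangement on the 12 x 12 perimeter
    (module-local frame)."""
    z0, z1 = z_extent
    h = MODULE_HALF_XY_MM
    t = WALL_THICKNESS_MM
    return {
        "wall+y": Box((-h, h - t, z0), (h - t, h, z1)),
        "wall+x": Box((h - t, -h + t, z0), (h, h, z1)),
        "wall-y": Box((-h + t, -h, z0), (h, -h + t, z1)),
        "wall-x": Box((-h, -h, z0), (-h + t, h - t, z1)),
    }


@dataclass
class ModuleGeometry:
    """One camera cell: pinhole plate, four septa walls, bottom block.

    ``origin``/``rotation`` place the module-local frame in the global
    frame: ``p_global = origin + rotation @ p_local``.
    """

    index: int = 0
    pinhole: PinholeSpec = field(default_factory=PinholeSpec)
    origin: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, PINHOLE_PLANE_Z_MM]))
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    wall_thickness_mm: float = WALL_THICKNESS_MM
    septa_z_mm: tuple[float, float] = SEPTA_Z_LOCAL_MM      # module-local
    bottom_z_mm: tuple[float, float] = BOTTOM_Z_LOCAL_MM    # module-local
    inter_septa_plate: bool = False

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.rotation = np.asarray(self.rotation, dtype=float)
        if self.septa_z_mm[1] != self.bottom_z_mm[0]:
            raise GeometryError("septa z-extent must end where the bottom begins")
        if self.wall_thickness_mm <= 0:
            raise GeometryError("wall thickness must be positive")
        wall_h = self.septa_z_mm[1] - self.septa_z_mm[0]
        bot_t = self.bottom_z_mm[1] - self.bottom_z_mm[0]
        if wall_h <= 0 or bot_t <= 0:
            raise GeometryError("z-extents must be increasing")

    @property
    def element_boxes(self) -> dict[str, Box]:
        """The five half-open element boxes in the module-local frame."""
        h = MODULE_HALF_XY_MM
        boxes = {"bottom": Box((-h, -h, self.bottom_z_mm[0]),
                               (h, h, self.bottom_z_mm[1]))}
        boxes.update(_wall_boxes(self.septa_z_mm))
        return boxes

    # -- rigid transforms ---------------------------------------------------

    def to_global(self, p_local):
        p = np.asarray(p_local, dtype=float)
        return p @ self.rotation.T + self.origin

    def to_local(self, p_global):
        p = np.asarray(p_global, dtype=float)
        return (p - self.origin) @ self.rotation

    def dir_to_local(self, d_global):
        return np.asarray(d_global, dtype=float) @ self.rotation

    def dir_to_global(self, d_local):
        return np.asarray(d_local, dtype=float) @ self.rotation.T

    @property
    def pinhole_center_global(self) -> np.ndarray:
        return self.to_global(np.zeros(3))


def build_module(
    wall_thickness_mm: float = WALL_THICKNESS_MM,
    septa_z_mm: tuple[float, float] = SEPTA_Z_LOCAL_MM,
    bottom_z_mm: tuple[float, float] = BOTTOM_Z_LOCAL_MM,
    pinhole: PinholeSpec | None = None,
    index: int = 0,
    origin=(0.0, 0.0, PINHOLE_PLANE_Z_MM),
    rotation=None,
    inter_septa_plate: bool = False,
) -> ModuleGeometry:
    """Build a single module from the frozen (or overridden) constants.

    The default module is the camera's reference cell: its pinhole centre
    at global (0, 0, 45.2) mm, so the septa walls span z in [50, 55) and
    the bottom detector z in [55, 58) in the global frame.
    """
    return ModuleGeometry(
        index=index,
        pinhole=pinhole or PinholeSpec(),
        origin=np.asarray(origin, dtype=float),
        rotation=np.eye(3) if rotation is None else np.asarray(rotation, float),
        wall_thickness_mm=wall_thickness_mm,
        septa_z_mm=septa_z_mm,
        bottom_z_mm=bottom_z_mm,
        inter_septa_plate=inter_septa_plate,
    )


@dataclass
class CameraArrayGeometry:
    """The 4 x 4 planar camera: 16 abutting modules sharing one collimator plate.

    ``inter_septa_plate_mm`` > 0 inserts thin tungsten sheets between the
    abutting septa walls of neighbouring modules (the noise-reduction
    option against through-septa leakage); the sheets sit on the module
    boundary planes over the septa z-band.
    """

    modules: list[ModuleGeometry] = field(default_factory=list)
    pitch_mm: float = MODULE_PITCH_MM
    inter_septa_plate_mm: float = 0.0

    def __post_init__(self):
        if not self.modules:
            offs = (np.arange(4) - 1.5) * self.pitch_mm
            idx = 0
            for oy in offs:
                for ox in offs:
                    self.modules.append(build_module(
                        index=idx, origin=(ox, oy, PINHOLE_PLANE_Z_MM)))
                    idx += 1
        if len(self.modules) != 16:
            raise GeometryError("camera array needs exactly 16 modules")

    @property
    def absorber_boxes(self) -> list[Box]:
        """Global-frame tungsten sheets between neighbouring septa walls."""
        if self.inter_septa_plate_mm <= 0:
            return []
        t = self.inter_septa_plate_mm / 2.0
        half = 2.0 * self.pitch_mm  # array half-width
        # sheets span from the plate exit face down to the septa bottom,
        # closing both the inter-wall path and the plate-to-wall gap
        z0 = PINHOLE_PLANE_Z_MM + PINHOLE_THICKNESS_MM / 2.0
        z1 = PINHOLE_PLANE_Z_MM + SEPTA_Z_LOCAL_MM[1]
        boxes = []
        for k in (-1, 0, 1):  # internal module boundaries
            c = k * self.pitch_mm
            boxes.append(Box((c - t, -half, z0), (c + t, half, z1)))
            boxes.append(Box((-half, c - t, z0), (half, c + t, z1)))
        return boxes


@dataclass
class SpectRingGeometry:
    """240-module cylindrical SPECT: 24 azimuthal positions x 10 axial rings.

    The cylinder axis is the global z axis.  Each module's local +z points
    radially outward, so every pinhole axis intersects the cylinder axis.
    ``rotation_offset_deg`` rotates the whole ring about its axis (used for
    the 3-degree acquisition steps).
    """

    pinhole_radius_mm: float = SPECT_PINHOLE_RADIUS_MM
    axial_length_mm: float = SPECT_AXIAL_LENGTH_MM
    rotation_offset_deg: float = 0.0
    modules: list[ModuleGeometry] = field(default_factory=list)

    def __post_init__(self):
        if not self.modules:
            idx = 0
            z_offs = (np.arange(SPECT_N_AXIAL) - (SPECT_N_AXIAL - 1) / 2.0) * MODULE_PITCH_MM
            for a, zc in enumerate(z_offs):
                for k in range(SPECT_N_AZIMUTHAL):
                    phi = np.radians(k * (360.0 / SPECT_N_AZIMUTHAL)
                                     + self.rotation_offset_deg)
                    r_hat = np.array([np.cos(phi), np.sin(phi), 0.0])
                    phi_hat = np.array([-np.sin(phi), np.cos(phi), 0.0])
                    z_hat = np.array([0.0, 0.0, 1.0])
                    # local x -> tangential, local y -> axial, local z -> radial
                    # (proper rotation: phi_hat x z_hat = r_hat)
                    rot = np.column_stack([phi_hat, z_hat, r_hat])
                    origin = self.pinhole_radius_mm * r_hat + np.array([0.0, 0.0, zc])
                    self.modules.append(build_module(index=idx, origin=origin,
                                                     rotation=rot))
                    idx += 1
        if len(self.modules) != SPECT_N_MODULES:
            raise GeometryError("SPECT ring needs exactly 240 modules")

    @property
    def angular_spacing_deg(self) -> float:
        return 360.0 / SPECT_N_AZIMUTHAL


def build_spect_ring(rotation_offset_deg: float = 0.0) -> SpectRingGeometry:
    """Build the proposed 240-module preclinical SPECT ring."""
    return SpectRingGeometry(rotation_offset_deg=rotation_offset_deg)


@dataclass
class BlockGeometry:
    """A single large scintillator block with no collimator.

    Used for the depth-of-interaction study on a semi-infinite crystal.
    The block spans ``z in [0, depth)`` with a large lateral extent.
    """

    depth_mm: float = 300.0
    half_xy_mm: float = 500.0
    modules: list[ModuleGeometry] = field(default_factory=list)

    @property
    def block_box(self) -> Box:
        h = self.half_xy_mm
        return Box((-h, -h, 0.0), (h, h, self.depth_mm))


# ---------------------------------------------------------------------------
# Element lookup
# ---------------------------------------------------------------------------

def locate_element(point, geometry) -> DetectorElementID | None:
    """Return the unique detector element whose half-open box contains ``point``.

    Works for a single module, the camera array, the SPECT ring, or a bare
    block.  Returns ``None`` when the point lies in no element (e.g. in the
    field of view).
    """
    p = np.asarray(point, dtype=float)
    if isinstance(geometry, BlockGeometry):
        return DetectorElementID(0, "block") if geometry.block_box.contains(p) else None
    modules = geometry.modules if hasattr(geometry, "modules") else [geometry]
    for mod in modules:
        q = mod.to_local(p)
        for kind, box in mod.element_boxes.items():
            if box.contains(q):
                return DetectorElementID(mod.index, kind)
    return None


# ---------------------------------------------------------------------------
# Effective path length & pinhole transmission
# ---------------------------------------------------------------------------

def effective_path_length(l_mm: float, theta_deg: float) -> float:
    """Effective wall thickness ``l / cos(theta)`` at incidence angle theta.

    At the minimum incidence angle of 28.5 degrees a 2 mm wall presents an
    effective thickness of about 2.3 mm.
    """
    if not (0 <= theta_deg < 90):
        raise ValueError("incidence angle must lie in [0, 90) degrees")
    return float(l_mm / np.cos(np.radians(theta_deg)))


def tungsten_path_mm(origin, direction, pinhole: PinholeSpec,
                     lateral_half_mm: float | None = None) -> float:
    """Exact tungsten path of a ray through one pinhole cell of the plate.

    The plate occupies ``|z| <= h/2`` (pinhole-local frame, knife edge at
    z = 0) laterally limited to ``|x|,|y| < lateral_half_mm`` (the module
    footprint; ``None`` means unbounded).  The double-cone aperture void is
    subtracted analytically: within each half-plate the void boundary
    ``|r_xy| = r_in + slope * |z|`` is linear in the ray parameter, so the
    inside/outside transitions are roots of a quadratic.

    Parameters are in the *pinhole-local* frame with the pinhole axis
    along +z and the knife edge at the origin.
    """
    o = np.asarray(origin, dtype=float)
    d = np.asarray(direction, dtype=float)
    n = np.linalg.norm(d)
    if n == 0:
        raise ValueError("zero direction vector")
    d = d / n
    half = pinhole.thickness_mm / 2.0

    # parameter interval of the slab crossing
    if abs(d[2]) < 1e-12:
        if abs(o[2]) >= half:
            return 0.0
        raise ValueError("ray parallel to and inside the plate: path undefined")
    t0 = (-half - o[2]) / d[2]
    t1 = (half - o[2]) / d[2]
    ta, tb = (t0, t1) if t0 < t1 else (t1, t0)
    ta = max(ta, 0.0)
    if tb <= ta:
        return 0.0

    if lateral_half_mm is not None:
        for ax in (0, 1):
            if abs(d[ax]) < 1e-12:
                if abs(o[ax]) >= lateral_half_mm:
                    return 0.0
            else:
                u0 = (-lateral_half_mm - o[ax]) / d[ax]
                u1 = (lateral_half_mm - o[ax]) / d[ax]
                lo, hi = (u0, u1) if u0 < u1 else (u1, u0)
                ta = max(ta, lo)
                tb = min(tb, hi)
        if tb <= ta:
            return 0.0

    r_in = pinhole.inner_diameter_mm / 2.0
    # void radius grows from r_in at the knife edge to d'/2 at either face
    slope = (pinhole.outer_diameter_mm / 2.0 - r_in) / half

    # void interval lengths within [ta, tb], split at the knife-edge plane z=0
    t_knife = (0.0 - o[2]) / d[2]
    void = 0.0
    for lo_t, hi_t, sgn in ((ta, min(tb, t_knife), -1.0), (max(ta, t_knife), tb, 1.0)):
        if hi_t <= lo_t:
            continue
        # inside-void condition: |xy(t)|^2 < (r_in + slope*sgn*z(t))^2
        A = o[:2]
        B = d[:2]
        C = r_in + slope * sgn * o[2]
        D = slope * sgn * d[2]
        a2 = B @ B - D * D
        a1 = 2.0 * (A @ B - C * D)
        a0 = A @ A - C * C
        void += _negative_interval_length(a2, a1, a0, lo_t, hi_t)
    return max((tb - ta) - void, 0.0)


def _negative_interval_length(a2: float, a1: float, a0: float,
                              lo: float, hi: float) -> float:
    """Length of ``{t in [lo, hi] : a2 t^2 + a1 t + a0 < 0}``."""
    if abs(a2) < 1e-14:
        if abs(a1) < 1e-14:
            return hi - lo if a0 < 0 else 0.0
        r = -a0 / a1
        if a1 > 0:
            return max(min(r, hi) - lo, 0.0)
        return max(hi - max(r, lo), 0.0)
    disc = a1 * a1 - 4.0 * a2 * a0
    if disc <= 0:
        return hi - lo if a2 < 0 else 0.0
    s = np.sqrt(disc)
    r1 = (-a1 - s) / (2.0 * a2)
    r2 = (-a1 + s) / (2.0 * a2)
    r1, r2 = min(r1, r2), max(r1, r2)
    if a2 > 0:  # negative between roots
        return max(min(r2, hi) - max(r1, lo), 0.0)
    # negative outside roots
    return max(min(r1, hi) - lo, 0.0) + max(hi - max(r2, lo), 0.0)


def pinhole_transmission(origin, direction, pinhole: PinholeSpec,
                         mu_w_per_mm: float, ideal_opaque: bool = False,
                         lateral_half_mm: float | None = None) -> float:
    """Survival probability of a 140 keV photon through the pinhole plate.

    ``exp(-mu_W * path_through_tungsten)``; rays through the open aperture
    have zero tungsten path and probability 1.  With ``ideal_opaque`` any
    nonzero tungsten path is fully absorbing.
    """
    path = tungsten_path_mm(origin, direction, pinhole, lateral_half_mm)
    if path == 0.0:
        return 1.0
    if ideal_opaque:
        return 0.0
    return float(np.exp(-mu_w_per_mm * path))


# ---------------------------------------------------------------------------
# Serialization / report
# ---------------------------------------------------------------------------

def geometry_to_dict(geometry) -> dict:
    """JSON/YAML-serializable description of any geometry object."""
    if isinstance(geometry, ModuleGeometry):
        return {"type": "module", "index": geometry.index,
                "origin": geometry.origin.tolist(),
                "rotation": geometry.rotation.tolist(),
                "pinhole": asdict(geometry.pinhole),
                "wall_thickness_mm": geometry.wall_thickness_mm,
                "septa_z_mm": list(geometry.septa_z_mm),
                "bottom_z_mm": list(geometry.bottom_z_mm),
                "inter_septa_plate": geometry.inter_septa_plate}
    if isinstance(geometry, CameraArrayGeometry):
        return {"type": "camera_array", "pitch_mm": geometry.pitch_mm,
                "modules": [geometry_to_dict(m) for m in geometry.modules]}
    if isinstance(geometry, SpectRingGeometry):
        return {"type": "spect_ring",
                "pinhole_radius_mm": geometry.pinhole_radius_mm,
                "axial_length_mm": geometry.axial_length_mm,
                "rotation_offset_deg": geometry.rotation_offset_deg,
                "n_modules": len(geometry.modules)}
    if isinstance(geometry, BlockGeometry):
        return {"type": "block", "depth_mm": geometry.depth_mm,
                "half_xy_mm": geometry.half_xy_mm}
    raise TypeError(f"unknown geometry {type(geometry)}")


def geometry_from_dict(d: dict):
    t = d["type"]
    if t == "module":
        ph = PinholeSpec(**{k: tuple(v) if isinstance(v, list) else v
                            for k, v in d["pinhole"].items()})
        return build_module(index=d["index"], origin=d["origin"],
                            rotation=d["rotation"], pinhole=ph,
                            wall_thickness_mm=d["wall_thickness_mm"],
                            septa_z_mm=tuple(d["septa_z_mm"]),
                            bottom_z_mm=tuple(d["bottom_z_mm"]),
                            inter_septa_plate=d["inter_septa_plate"])
    if t == "camera_array":
        return CameraArrayGeometry(modules=[geometry_from_dict(m)
                                            for m in d["modules"]],
                                   pitch_mm=d["pitch_mm"])
    if t == "spect_ring":
        return SpectRingGeometry(pinhole_radius_mm=d["pinhole_radius_mm"],
                                 axial_length_mm=d["axial_length_mm"],
                                 rotation_offset_deg=d["rotation_offset_deg"])
    if t == "block":
        return BlockGeometry(depth_mm=d["depth_mm"], half_xy_mm=d["half_xy_mm"])
    raise ValueError(f"unknown geometry type {t!r}")


def write_geometry_report(geometry, path) -> None:
    """Human-readable report: every element box in global coordinates."""
    lines = [f"geometry: {geometry_to_dict(geometry).get('type')}"]
    modules = geometry.modules if hasattr(geometry, "modules") else [geometry]
    if isinstance(geometry, BlockGeometry):
        b = geometry.block_box
        lines.append(f"block lo={b.lo} hi={b.hi}")
    else:
        for mod in modules:
            lines.append(f"module {mod.index}: pinhole at "
                         f"{np.round(mod.pinhole_center_global, 3).tolist()}")
            for kind, box in mod.element_boxes.items():
                lo = np.round(mod.to_global(box.lo), 3).tolist()
                hi = np.round(mod.to_global(box.hi), 3).tolist()
                lines.append(f"  {kind}: local {box.lo}->{box.hi} "
                             f"global {lo}->{hi}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def save_geometry(geometry, path) -> None:
    with open(path, "w") as fh:
        json.dump(geometry_to_dict(geometry), fh, indent=1)


def load_geometry(path):
    with open(path) as fh:
        return geometry_from_dict(json.load(fh))
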