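"""Synthetic voxelized adult head phantom.

Parametric geometric stand-in for a reference adult voxel phantom: nested
ellipsoids/capsules give a labeled head-and-neck volume (skin, skull, brain,
eyeballs, lenses, salivary glands, oral mucosa, thyroid, soft tissue, air)
with the anatomical landmarks needed to define gantry-tilt angles and scan
ranges (orbitomeatal line, orbital margins, caudal brain/eye extent).

Coordinate convention: right-handed, x lateral (+x left), y anterior,
z increasing caudally with the vertex (cranial top) at z = 0 mm. The
isocenter sits on the phantom midline. The orbitomeatal (OM) plane is
inclined ``om_inclination_deg`` relative to the axial plane, encoding the
fixed chin-up scan posture: a beam "tilt" of 0 deg runs along the OM plane,
and a tilt of ``-om_inclination_deg`` is perpendicular incidence.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TissueMaterial",
    "OrganLabel",
    "VoxelPhantom",
    "AnatomyParams",
    "ConstructionError",
    "material_table",
    "get_material",
    "organ_labels",
    "build_head_phantom",
    "organ_mass",
    "downsample_labels",
]

# symbol -> (Z, atomic mass)
ELEMENTS = {
    "H": (1, 1.008), "C": (6, 12.011), "N": (7, 14.007), "O": (8, 15.999),
    "Na": (11, 22.990), "Mg": (12, 24.305), "Al": (13, 26.982),
    "P": (15, 30.974), "S": (16, 32.06), "Cl": (17, 35.45),
    "Ar": (18, 39.948), "K": (19, 39.098), "Ca": (20, 40.078),
    "I": (53, 126.904),
}


class ConstructionError(ValueError):
    """Raised when anatomy parameters produce invalid geometry."""


@dataclass(frozen=True)
class TissueMaterial:
    """Elemental composition (mass fractions) and density of a tissue."""

    name: str
    density: float  # g/cm^3
    composition: dict  # element symbol -> mass fraction

    def __post_init__(self):
        if self.density <= 0:
            raise ValueError(f"material {self.name}: density must be > 0")
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(
                f"material {self.name}: mass fractions sum to {total}, not 1"
            )
        for sym in self.composition:
            if sym not in ELEMENTS:
                raise ValueError(f"material {self.name}: unknown element {sym}")

    @property
    def electrons_per_gram(self) -> float:
        """Z/A-weighted electron density [electrons/g] x N_A."""
        na = 6.02214076e23
        return na * sum(
            w * ELEMENTS[s][0] / ELEMENTS[s][1]
            for s, w in self.composition.items()
        )


# ICRU-style reference tissues. Densities in g/cm^3.
_MATERIALS = [
    TissueMaterial("air", 0.0012041,
                   {"N": 0.755, "O": 0.232, "Ar": 0.013}),
    TissueMaterial("water", 0.998, {"H": 0.1119, "O": 0.8881}),
    TissueMaterial("soft_tissue", 1.03,
                   {"H": 0.102, "C": 0.143, "N": 0.034, "O": 0.708,
                    "Na": 0.002, "P": 0.003, "S": 0.003, "Cl": 0.002,
                    "K": 0.003}),
    TissueMaterial("brain", 1.04,
                   {"H": 0.107, "C": 0.145, "N": 0.022, "O": 0.712,
                    "Na": 0.002, "P": 0.004, "S": 0.002, "Cl": 0.003,
                    "K": 0.003}),
    TissueMaterial("cortical_bone", 1.92,
                   {"H": 0.034, "C": 0.155, "N": 0.042, "O": 0.435,
                    "Na": 0.001, "Mg": 0.002, "P": 0.103, "S": 0.003,
                    "Ca": 0.225}),
    TissueMaterial("eye_lens", 1.07,
                   {"H": 0.096, "C": 0.195, "N": 0.057, "O": 0.646,
                    "Na": 0.001, "P": 0.001, "S": 0.003, "Cl": 0.001}),
    TissueMaterial("eyeball", 1.05,
                   {"H": 0.097, "C": 0.181, "N": 0.053, "O": 0.663,
                    "Na": 0.001, "P": 0.001, "S": 0.003, "Cl": 0.001}),
    TissueMaterial("skin", 1.09,
                   {"H": 0.100, "C": 0.204, "N": 0.042, "O": 0.645,
                    "Na": 0.002, "P": 0.001, "S": 0.002, "Cl": 0.003,
                    "K": 0.001}),
    TissueMaterial("thyroid", 1.05,
                   {"H": 0.104, "C": 0.119, "N": 0.024, "O": 0.745,
                    "Na": 0.002, "P": 0.001, "S": 0.001, "Cl": 0.002,
                    "K": 0.001, "I": 0.001}),
    TissueMaterial("aluminum", 2.699, {"Al": 1.0}),
]

_MATERIAL_INDEX = {m.name: m for m in _MATERIALS}


def material_table() -> list:
    """Embedded ICRU-style reference tissue table."""
    return list(_MATERIALS)


def get_material(name: str) -> TissueMaterial:
    try:
        return _MATERIAL_INDEX[name]
    except KeyError:
        raise KeyError(f"unknown material: {name}") from None


@dataclass(frozen=True)
class OrganLabel:
    id: int
    name: str
    material: TissueMaterial


# Label ids are stable: they index the uint8 voxel array.
ORGAN_NAMES = [
    "air", "skin", "skull", "brain", "eyeball_L", "eyeball_R",
    "lens_L", "lens_R", "salivary_glands", "oral_mucosa", "thyroid",
    "soft_tissue",
]

_ORGAN_MATERIAL = {
    "air": "air", "skin": "skin", "skull": "cortical_bone", "brain": "brain",
    "eyeball_L": "eyeball", "eyeball_R": "eyeball",
    "lens_L": "eye_lens", "lens_R": "eye_lens",
    "salivary_glands": "soft_tissue", "oral_mucosa": "soft_tissue",
    "thyroid": "thyroid", "soft_tissue": "soft_tissue",
}


def organ_labels() -> list:
    """The fixed label table: id, organ name, tissue material."""
    return [
        OrganLabel(i, name, get_material(_ORGAN_MATERIAL[name]))
        for i, name in enumerate(ORGAN_NAMES)
    ]


LABEL_BY_NAME = {name: i for i, name in enumerate(ORGAN_NAMES)}


@dataclass
class AnatomyParams:
    """Default dimensions of the synthetic head (all mm).

    The defaults place the eyes/lenses and the caudal brain extent such
    that, at the default chin-up OM inclination, a brain-only scan excludes
    the lens dose peak for tilts of about -5 deg and greater while a
    brain+eyes scan always contains it -- the anatomy-dependent contrast
    the pipeline is built to study.
    """

    head_semi: tuple = (75.0, 95.0, 118.0)
    head_center_y: float = 5.0
    skin_thickness: float = 3.0
    brain_center: tuple = (0.0, 2.0, 78.0)
    brain_semi: tuple = (60.0, 72.0, 62.0)
    skull_gap: float = 1.0
    skull_thickness: float = 8.0
    eye_center_x: float = 31.0
    eye_center_y: float = 72.0
    eye_center_z: float = 108.0
    eye_radius: float = 12.0
    lens_radius: float = 3.5
    orbit_margin: float = 3.0
    salivary_center: tuple = (48.0, 10.0, 160.0)
    salivary_semi: tuple = (12.0, 20.0, 22.0)
    oral_center: tuple = (0.0, 45.0, 175.0)
    oral_semi: tuple = (20.0, 25.0, 12.0)
    thyroid_center: tuple = (0.0, 15.0, 230.0)
    thyroid_semi: tuple = (18.0, 10.0, 20.0)
    neck_center_xy: tuple = (0.0, -10.0)
    neck_radius: float = 52.0
    neck_z_start: float = 190.0
    z_extent: float = 300.0
    om_inclination_deg: float = 35.0
    om_canthus_offset: float = 4.0

    def validate(self):
        if not (0.0 < self.om_canthus_offset <= self.eye_radius):
            raise ConstructionError(
                "om_canthus_offset must be in (0, eye_radius]")
        if self.lens_radius >= self.eye_radius:
            raise ConstructionError("lens_radius must be < eye_radius")
        if self.z_extent < 260.0:
            raise ConstructionError("z_extent must cover >= 260 mm caudally")
        if not (0.0 <= self.om_inclination_deg <= 60.0):
            raise ConstructionError("om_inclination_deg outside [0, 60]")
        for name, v in (("skin_thickness", self.skin_thickness),
                        ("skull_thickness", self.skull_thickness),
                        ("eye_radius", self.eye_radius),
                        ("lens_radius", self.lens_radius),
                        ("neck_radius", self.neck_radius)):
            if v <= 0:
                raise ConstructionError(f"{name} must be > 0")


@dataclass
class VoxelPhantom:
    """Labeled 3-D voxel grid with materials and anatomical landmarks.

    ``labels`` is indexed [ix, iy, iz] (x fastest when flattened in Fortran
    order; the raw-file layout is x-fastest, z-slowest). Landmarks are in
    phantom mm coordinates (vertex at z = 0, z caudal-positive).
    """

    dims: tuple
    spacing: tuple  # mm
    origin: tuple  # mm position of the corner of voxel (0,0,0)
    labels: np.ndarray  # uint8, shape dims
    landmarks: dict
    om_inclination_deg: float = 35.0
    label_table: list = field(default_factory=organ_labels)

    @property
    def voxel_volume_cm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz * 1e-3

    def axis_coords(self, axis: int) -> np.ndarray:
        """Voxel-center coordinates along an axis [mm]."""
        n = self.dims[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing[axis]

    def organ_voxel_count(self, organ_id: int) -> int:
        return int(np.count_nonzero(self.labels == organ_id))

    def material_of(self, organ_id: int) -> TissueMaterial:
        return self.label_table[organ_id].material


def _resolve_organ(phantom: VoxelPhantom, organ) -> int:
    if isinstance(organ, OrganLabel):
        organ = organ.id
    if isinstance(organ, str):
        if organ not in LABEL_BY_NAME:
            raise KeyError(f"unknown organ name: {organ}")
        organ = LABEL_BY_NAME[organ]
    organ = int(organ)
    if not (0 <= organ < len(phantom.label_table)):
        raise KeyError(f"unknown organ id: {organ}")
    return organ


def organ_mass(phantom: VoxelPhantom, organ) -> float:
    """Organ mass [g] = voxel count x voxel volume x material density."""
    oid = _resolve_organ(phantom, organ)
    n = phantom.organ_voxel_count(oid)
    if n == 0:
        raise KeyError(
            f"organ {phantom.label_table[oid].name} absent from grid")
    return n * phantom.voxel_volume_cm3 * phantom.material_of(oid).density


def _ellipsoid(x, y, z, center, semi):
    cx, cy, cz = center
    ax, ay, az = semi
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 \
        + ((z - cz) / az) ** 2 <= 1.0


def _sphere(x, y, z, center, r):
    return _ellipsoid(x, y, z, center, (r, r, r))


def build_head_phantom(spacing=(2.0, 2.0, 2.0), anatomy_params=None,
                       seed: int = 0) -> VoxelPhantom:
    """Build the synthetic voxel head phantom.

    Parameters
    ----------
    spacing : (sx, sy, sz) voxel spacing in mm, each in [0.5, 4].
    anatomy_params : AnatomyParams or None for the documented defaults.
    seed : reserved for stochastic surface detail; the default generator is
        fully deterministic and the seed only enters the phantom metadata.
    """
    spacing = tuple(float(s) for s in spacing)
    for s in spacing:
        if not (0.5 <= s <= 4.0):
            raise ValueError(f"spacing {s} mm outside [0.5, 4] mm")
    p = anatomy_params or AnatomyParams()
    p.validate()

    sx, sy, sz = spacing
    x_lo, x_hi = -80.0, 80.0
    y_lo, y_hi = -96.0, 104.0
    z_lo, z_hi = 0.0, p.z_extent
    nx = int(round((x_hi - x_lo) / sx))
    ny = int(round((y_hi - y_lo) / sy))
    nz = int(round((z_hi - z_lo) / sz))
    x = (x_lo + (np.arange(nx) + 0.5) * sx)[:, None, None]
    y = (y_lo + (np.arange(ny) + 0.5) * sy)[None, :, None]
    z = (z_lo + (np.arange(nz) + 0.5) * sz)[None, None, :]

    hc = (0.0, p.head_center_y, p.head_semi[2])
    head = _ellipsoid(x, y, z, hc, p.head_semi)
    neck = (((x - p.neck_center_xy[0]) ** 2
             + (y - p.neck_center_xy[1]) ** 2) <= p.neck_radius ** 2) \
        & (z >= p.neck_z_start)
    body = head | neck

    t = p.skin_thickness
    head_in = _ellipsoid(x, y, z, hc, tuple(a - t for a in p.head_semi))
    neck_in = (((x - p.neck_center_xy[0]) ** 2
                + (y - p.neck_center_xy[1]) ** 2)
               <= (p.neck_radius - t) ** 2) & (z >= p.neck_z_start)
    interior = head_in | neck_in

    bc, bs = p.brain_center, p.brain_semi
    skull_out = _ellipsoid(
        x, y, z, bc, tuple(a + p.skull_gap + p.skull_thickness for a in bs))
    skull_in = _ellipsoid(x, y, z, bc, tuple(a + p.skull_gap for a in bs))
    brain = _ellipsoid(x, y, z, bc, bs)

    ex, ey, ez, er = (p.eye_center_x, p.eye_center_y, p.eye_center_z,
                      p.eye_radius)
    eye_l = _sphere(x, y, z, (+ex, ey, ez), er)
    eye_r = _sphere(x, y, z, (-ex, ey, ez), er)
    ly = ey + er - p.lens_radius  # anterior pole, inside the globe
    lens_l = _sphere(x, y, z, (+ex, ly, ez), p.lens_radius)
    lens_r = _sphere(x, y, z, (-ex, ly, ez), p.lens_radius)
    orbit = _sphere(x, y, z, (+ex, ey, ez), er + p.orbit_margin) \
        | _sphere(x, y, z, (-ex, ey, ez), er + p.orbit_margin)

    sal_c, sal_s = p.salivary_center, p.salivary_semi
    sal = _ellipsoid(x, y, z, (+sal_c[0], sal_c[1], sal_c[2]), sal_s) \
        | _ellipsoid(x, y, z, (-sal_c[0], sal_c[1], sal_c[2]), sal_s)
    oral = _ellipsoid(x, y, z, p.oral_center, p.oral_semi)
    thy = _ellipsoid(x, y, z, p.thyroid_center, p.thyroid_semi)

    # mandatory organs must not collide with the brain (the orbit opening
    # through the skull is carved explicitly and is not a collision)
    for name, mask in (("eyeball", eye_l | eye_r), ("salivary_glands", sal),
                       ("oral_mucosa", oral), ("thyroid", thy)):
        if np.any(mask & brain):
            raise ConstructionError(
                f"anatomy parameters make {name} overlap brain")
    if np.any(thy & oral):
        raise ConstructionError(
            "anatomy parameters make thyroid overlap oral_mucosa")

    L = LABEL_BY_NAME
    labels = np.zeros((nx, ny, nz), dtype=np.uint8)  # air
    labels[body] = L["skin"]
    labels[interior] = L["soft_tissue"]
    labels[skull_out & ~skull_in & interior] = L["skull"]
    labels[brain] = L["brain"]
    # orbital openings: carve the skull (only) around each globe
    labels[orbit & (labels == L["skull"])] = L["soft_tissue"]
    labels[eye_l] = L["eyeball_L"]
    labels[eye_r] = L["eyeball_R"]
    labels[lens_l] = L["lens_L"]
    labels[lens_r] = L["lens_R"]
    labels[sal & (labels == L["soft_tissue"])] = L["salivary_glands"]
    labels[oral & (labels == L["soft_tissue"])] = L["oral_mucosa"]
    labels[thy & (labels == L["soft_tissue"])] = L["thyroid"]

    landmarks = {
        "vertex_z": 0.0,
        "supraorbital_z": ez - er,
        "om_line_z": ez + p.om_canthus_offset,
        "infraorbital_z": ez + er,
        "brain_caudal_z": bc[2] + bs[2],
        "eye_caudal_z": ez + er,
        "lens_z": ez,
        "lens_anterior_y": ly,
        "isocenter_xy": (0.0, p.head_center_y),
        "seed": int(seed),
    }

    ph = VoxelPhantom(
        dims=(nx, ny, nz), spacing=spacing, origin=(x_lo, y_lo, z_lo),
        labels=labels, landmarks=landmarks,
        om_inclination_deg=p.om_inclination_deg,
    )
    missing = [name for i, name in enumerate(ORGAN_NAMES)
               if ph.organ_voxel_count(i) == 0]
    if missing:
        raise ConstructionError(
            f"organs with zero voxels at spacing {spacing}: {missing}")
    return ph


def downsample_labels(phantom: VoxelPhantom, factor: int = 2) -> VoxelPhantom:
    """Downsample the label grid by an integer factor per axis.

    Nearest-neighbor subsampling (the voxel nearest each coarse-block
    center) rather than a plurality vote: subsampling preserves organ
    volumes in expectation even for structures only a few voxels across
    (lens), which a mode filter would erode.
    """
    f = int(factor)
    if any(n % f for n in phantom.dims):
        raise ValueError("dims not divisible by downsampling factor")
    h = f // 2
    new_labels = np.ascontiguousarray(phantom.labels[h::f, h::f, h::f])
    return VoxelPhantom(
        dims=new_labels.shape,
        spacing=tuple(s * f for s in phantom.spacing),
        origin=phantom.origin,
        labels=new_labels,
        landmarks=dict(phantom.landmarks),
        om_inclination_deg=phantom.om_inclination_deg,
        label_table=list(phantom.label_table),
    )
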