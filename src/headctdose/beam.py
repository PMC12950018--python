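"""CT x-ray source model.

A 120 kV-class tungsten-anode spectrum (Kramers bremsstrahlung filtered by
inherent aluminum plus W characteristic K lines), a parametric symmetric
aluminum bowtie filter, and the rotating fan-beam geometry with selectable
z-collimation (2 mm / 5 mm source model) and a gantry-tilt transform.

Tilt convention: the tilt angle is measured relative to the orbitomeatal
(OM) line, positive = upward/cranial tilt of the anterior beam portion.
The beam plane's angle against the phantom's axial plane is
``tilt_deg + om_inclination_deg`` (the phantom is scanned in a fixed
chin-up posture). The tilt transform is a rigid rotation about the lateral
(left-right, x) axis through the isocenter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SpectrumTable",
    "BowtieFilter",
    "GantryGeometry",
    "Photon",
    "al_mass_attenuation",
    "generate_spectrum",
    "apply_bowtie",
    "default_bowtie",
    "tilt_transform",
    "sample_emission",
]

# Embedded NIST-style mass attenuation table for aluminum, mu/rho [cm^2/g].
_AL_E_KEV = np.array(
    [1.0, 1.5, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0, 10.0, 15.0, 20.0, 30.0,
     40.0, 50.0, 60.0, 80.0, 100.0, 150.0])
_AL_MU_RHO = np.array(
    [1185.0, 402.2, 2263.0, 788.0, 360.5, 193.4, 115.3, 50.33, 26.23,
     7.955, 3.441, 1.128, 0.5685, 0.3681, 0.2778, 0.2018, 0.1704, 0.1378])
AL_DENSITY = 2.699  # g/cm^3


def al_mass_attenuation(energy_keV) -> np.ndarray:
    """Aluminum mu/rho [cm^2/g], log-log interpolated on the embedded table."""
    e = np.asarray(energy_keV, dtype=float)
    if np.any(e < _AL_E_KEV[0]) or np.any(e > _AL_E_KEV[-1]):
        raise ValueError("energy outside embedded Al table range [1,150] keV")
    out = np.exp(np.interp(np.log(e), np.log(_AL_E_KEV), np.log(_AL_MU_RHO)))
    return out


@dataclass
class SpectrumTable:
    """Energy-fluence table: ascending keV bins with relative weights."""

    energy_keV: np.ndarray
    relative_fluence: np.ndarray

    def __post_init__(self):
        self.energy_keV = np.asarray(self.energy_keV, dtype=float)
        self.relative_fluence = np.asarray(self.relative_fluence, dtype=float)
        if self.energy_keV.ndim != 1 or \
                self.energy_keV.shape != self.relative_fluence.shape:
            raise ValueError("spectrum arrays must be 1-D and equal length")
        if np.any(np.diff(self.energy_keV) <= 0):
            raise ValueError("energy bins must be strictly ascending")
        if np.any(self.relative_fluence < 0):
            raise ValueError("fluence weights must be non-negative")
        if not np.any(self.relative_fluence > 0):
            raise ValueError("spectrum has no positive weight")

    @property
    def total_fluence(self) -> float:
        return float(self.relative_fluence.sum())

    @property
    def mean_energy(self) -> float:
        w = self.relative_fluence
        return float((self.energy_keV * w).sum() / w.sum())

    def pdf(self) -> np.ndarray:
        return self.relative_fluence / self.relative_fluence.sum()

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.choice(self.energy_keV, size=n, p=self.pdf())


# W characteristic K lines [keV] and relative intensities (unfiltered).
_W_K_LINES = np.array([57.98, 59.32, 67.24, 69.07])
_W_K_WEIGHTS = np.array([0.57, 1.00, 0.23, 0.08])
_W_K_EDGE = 69.5


def generate_spectrum(tube_kv: float = 120.0,
                      inherent_filtration_mmAl: float = 2.5,
                      bin_width_keV: float = 1.0) -> SpectrumTable:
    """Parametric filtered bremsstrahlung spectrum.

    Kramers' law N(E) ~ (E_max - E)/E attenuated by the inherent aluminum
    filtration, plus tungsten K characteristic lines (carrying ~8% of the
    filtered fluence) when the tube voltage exceeds the W K edge. The table
    is deterministic: identical inputs give identical tables.
    """
    if not (80.0 <= tube_kv <= 140.0):
        raise ValueError("tube_kv outside [80, 140] kV")
    if inherent_filtration_mmAl < 0:
        raise ValueError("filtration must be >= 0")
    e = np.arange(bin_width_keV, tube_kv + 0.5 * bin_width_keV, bin_width_keV)
    e = e[e <= tube_kv]
    brems = np.clip(tube_kv - e, 0.0, None) / e
    fluence = brems.copy()
    if tube_kv > _W_K_EDGE:
        # anode characteristic lines (8% of the unfiltered continuum),
        # binned into their host bins before filtration so that filtering
        # the unfiltered table reproduces the filtered one exactly
        line_flux = _W_K_WEIGHTS * (0.08 * brems.sum() / _W_K_WEIGHTS.sum())
        idx = np.clip(
            np.round((_W_K_LINES - e[0]) / bin_width_keV).astype(int),
            0, len(e) - 1)
        np.add.at(fluence, idx, line_flux)
    t_cm = inherent_filtration_mmAl * 0.1
    fluence = fluence * np.exp(-al_mass_attenuation(e) * AL_DENSITY * t_cm)
    return SpectrumTable(e, fluence)


@dataclass
class BowtieFilter:
    """Fan-angle-dependent equivalent aluminum thickness [mm]."""

    fan_angle_grid: np.ndarray  # degrees
    equivalent_Al_thickness: np.ndarray  # mm

    def __post_init__(self):
        self.fan_angle_grid = np.asarray(self.fan_angle_grid, dtype=float)
        self.equivalent_Al_thickness = np.asarray(
            self.equivalent_Al_thickness, dtype=float)
        if np.any(self.equivalent_Al_thickness < 0):
            raise ValueError("bowtie thickness must be >= 0")
        # even in fan angle and non-decreasing with |angle|
        t_pos = self.thickness(np.abs(self.fan_angle_grid))
        t_neg = self.thickness(-np.abs(self.fan_angle_grid))
        if np.max(np.abs(t_pos - t_neg)) > 1e-9:
            raise ValueError("bowtie must be an even function of fan angle")
        order = np.argsort(np.abs(self.fan_angle_grid))
        if np.any(np.diff(t_pos[order]) < -1e-9):
            raise ValueError("bowtie thickness must not decrease with |angle|")

    def thickness(self, fan_angle_deg) -> np.ndarray:
        return np.interp(np.abs(fan_angle_deg),
                         np.abs(self.fan_angle_grid[np.argsort(
                             np.abs(self.fan_angle_grid))]),
                         self.equivalent_Al_thickness[np.argsort(
                             np.abs(self.fan_angle_grid))])


def default_bowtie(fan_half_angle_deg: float = 25.0,
                   edge_thickness_mm: float = 10.0) -> BowtieFilter:
    """Symmetric parametric bowtie: zero on the center ray, quadratic rise
    to ``edge_thickness_mm`` of Al at the fan edge."""
    gamma = np.linspace(0.0, fan_half_angle_deg, 26)
    t = edge_thickness_mm * (gamma / fan_half_angle_deg) ** 2
    return BowtieFilter(gamma, t)


def apply_bowtie(spectrum: SpectrumTable, fan_angle_deg: float,
                 bowtie: BowtieFilter,
                 fan_half_angle_deg: float | None = None) -> SpectrumTable:
    """Attenuate each bin by exp(-mu_Al(E) * t(fan_angle))."""
    if fan_half_angle_deg is not None and \
            abs(fan_angle_deg) > fan_half_angle_deg + 1e-12:
        raise ValueError(
            f"fan angle {fan_angle_deg} outside +/-{fan_half_angle_deg} deg")
    t_cm = float(bowtie.thickness(fan_angle_deg)) * 0.1
    atten = np.exp(-al_mass_attenuation(spectrum.energy_keV)
                   * AL_DENSITY * t_cm)
    return SpectrumTable(spectrum.energy_keV.copy(),
                         spectrum.relative_fluence * atten)


def tilt_transform(tilt_deg: float) -> np.ndarray:
    """Rigid rotation (3x3, about the lateral x axis through the isocenter)
    realizing a gantry tilt.

    Positive tilt moves the anterior (+y) portion of the beam plane
    cranially (toward smaller z; z increases caudally). tilt 0 is the
    identity; the matrix is orthonormal with determinant 1.
    """
    th = np.deg2rad(tilt_deg)
    c, s = np.cos(th), np.sin(th)
    return np.array([[1.0, 0.0, 0.0],
                     [0.0, c, s],
                     [0.0, -s, c]])


@dataclass
class GantryGeometry:
    """Rotating fan-beam geometry.

    ``tilt_deg`` is relative to the OM line (positive = cranial tilt),
    bounded to the studied [-45, +20] deg range. ``beam_width_z`` is the
    z-collimation of the source model (2 mm default; 5 mm supported,
    other values allowed with a warning).
    """

    source_to_isocenter: float = 595.0  # mm
    fan_half_angle: float = 25.0  # degrees
    beam_width_z: float = 2.0  # mm
    tilt_deg: float = 0.0
    rotation_sampling: str = "uniform_continuous"
    n_views: int = 64

    def __post_init__(self):
        if not (-45.0 <= self.tilt_deg <= 20.0):
            raise ValueError("tilt_deg outside [-45, +20] deg")
        if self.fan_half_angle <= 0:
            raise ValueError("fan_half_angle must be > 0 (degenerate fan)")
        if self.beam_width_z not in (2.0, 5.0):
            warnings.warn(
                f"non-standard beam width {self.beam_width_z} mm "
                "(source model defaults are 2 mm and 5 mm)",
                stacklevel=2)
        if self.rotation_sampling not in (
                "uniform_continuous", "fixed_n_views"):
            raise ValueError("unknown rotation_sampling mode")

    def plane_angle_deg(self, om_inclination_deg: float = 0.0) -> float:
        """Beam-plane angle against the phantom axial plane."""
        return self.tilt_deg + om_inclination_deg

    def covers_extent(self, half_extent_mm: float) -> bool:
        """Does the fan at the isocenter cover a transaxial half-extent?"""
        return half_extent_mm <= self.source_to_isocenter * np.tan(
            np.deg2rad(self.fan_half_angle))


@dataclass
class Photon:
    """Transport particle record."""

    position: np.ndarray  # mm
    direction: np.ndarray  # unit vector
    energy: float  # keV
    weight: float = 1.0

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(self.direction) - 1.0) > 1e-9:
            raise ValueError("direction must be a unit vector")
        if self.energy <= 0:
            raise ValueError("energy must be positive")
        if self.weight <= 0:
            raise ValueError("weight must be positive")


def _plane_basis(plane_angle_deg: float):
    """Orthonormal (u, v, n) of the tilted beam plane.

    v = x-hat (lateral), u = in-plane anterior-ish axis, n = plane normal.
    """
    th = np.deg2rad(plane_angle_deg)
    v = np.array([1.0, 0.0, 0.0])
    u = np.array([0.0, np.cos(th), -np.sin(th)])
    n = np.array([0.0, np.sin(th), np.cos(th)])
    return u, v, n


def sample_emission(geom: GantryGeometry, spectrum: SpectrumTable,
                    bowtie: BowtieFilter, slice_z: float,
                    rng: np.random.Generator, n: int = 1,
                    isocenter_xy=(0.0, 0.0),
                    om_inclination_deg: float = 0.0):
    """Sample ``n`` source photons for the acquisition at slice position
    ``slice_z`` (measured along the phantom z axis on the isocenter line).

    Returns (positions (n,3) mm, directions (n,3), energies keV (n,)).
    Source points lie on the circle of radius ``source_to_isocenter`` in
    the tilted plane through the slice isocenter, displaced along the plane
    normal by a uniform z-collimation offset; fan angles are uniform within
    the fan; energies follow the bowtie-filtered spectrum at the sampled
    fan angle.
    """
    phi = geom.plane_angle_deg(om_inclination_deg)
    u, v, nvec = _plane_basis(phi)
    center = np.array([isocenter_xy[0], isocenter_xy[1], slice_z])

    alpha = (rng.uniform(0.0, 2 * np.pi, n)
             if geom.rotation_sampling == "uniform_continuous"
             else 2 * np.pi * rng.integers(0, geom.n_views, n)
             / geom.n_views)
    radial = (np.cos(alpha)[:, None] * u[None, :]
              + np.sin(alpha)[:, None] * v[None, :])
    offsets = rng.uniform(-0.5, 0.5, n) * geom.beam_width_z
    pos = (center[None, :] + geom.source_to_isocenter * radial
           + offsets[:, None] * nvec[None, :])

    central = -radial  # toward the isocenter
    gamma = rng.uniform(-geom.fan_half_angle, geom.fan_half_angle, n)
    g = np.deg2rad(gamma)
    # in-plane tangential axis at each source point
    tang = np.cross(nvec[None, :], central)
    dirs = np.cos(g)[:, None] * central + np.sin(g)[:, None] * tang

    # fan-angle-binned energy sampling from the bowtie-filtered spectrum
    n_bins = 16
    edges = np.linspace(-geom.fan_half_angle, geom.fan_half_angle, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    energies = np.empty(n)
    bin_idx = np.clip(np.digitize(gamma, edges) - 1, 0, n_bins - 1)
    for b in range(n_bins):
        sel = bin_idx == b
        m = int(sel.sum())
        if m == 0:
            continue
        filt = apply_bowtie(spectrum, centers[b], bowtie)
        energies[sel] = filt.sample(m, rng)
    return pos, dirs, energies
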