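"""Scan orchestration and dose normalization.

A "scan" is a set of independent axial acquisitions at slice positions k
(measured along the phantom z axis on the isocenter line, vertex = 0 mm,
caudal positive), stepped by beam_width x pitch. Each acquisition yields
per-organ doses per emitted photon, qD(T, k), which are normalized to
absolute doses via

    D(T, k) = qD(T, k) / qK_air x nCTDI_air x At / pit

with qK_air the free-in-air kerma per photon at the isocenter, nCTDI_air
the free-in-air CTDI per mAs (0.192 mGy/mAs for the reference scanner), At
the tube current-time product (540 mAs for the CTDI_vol = 75 mGy reference
protocol) and pit the pitch (1.0). The organ dose for a scan range is the
sum of D(T, k) over slices whose centers lie inside the range; profiles
are always tallied over the full 0-260 mm extent so out-of-range tails
remain visible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .beam import BowtieFilter, GantryGeometry, SpectrumTable
from .phantom import VoxelPhantom, LABEL_BY_NAME
from .transport import (CrossSectionDB, build_cross_section_db,
                        compute_air_kerma, simulate_slice)

__all__ = [
    "ScanProtocol",
    "SliceDoseProfile",
    "OrganDoseTable",
    "normalize_dose",
    "scan_range_preset",
    "lens_peak_position",
    "run_scan",
    "tilt_sweep",
    "SCAN_RANGE_PRESETS",
    "TILT_GRID_DEG",
]

SCAN_RANGE_PRESETS = ("brain_and_eyes_i", "brain_only_ii",
                      "infraorbital_iii", "supraorbital_iv")
# The studied tilt grid: -45 to +20 deg in 5 deg increments.
TILT_GRID_DEG = tuple(range(-45, 25, 5))

PROFILE_EXTENT_MM = 260.0


@dataclass
class ScanProtocol:
    """One head-CT protocol: tilt, scan range and exposure parameters."""

    tilt_deg: float = 0.0
    scan_range: object = "brain_and_eyes_i"  # preset name or (start, end) mm
    pit: float = 1.0
    At_mAs: float = 540.0
    nCTDI_air: float = 0.192  # mGy per mAs
    tube_kv: float = 120.0
    beam_width_z: float = 2.0
    n_photons_per_slice: int = 4000
    n_batches: int = 10
    seed: int = 0
    ctdi_vol_mGy: float | None = 75.0  # annotation only

    def __post_init__(self):
        if self.pit <= 0:
            raise ValueError("pit must be > 0")
        if self.At_mAs <= 0:
            raise ValueError("At must be > 0")
        if self.nCTDI_air <= 0:
            raise ValueError("nCTDI_air must be > 0")
        if isinstance(self.scan_range, str):
            if self.scan_range not in SCAN_RANGE_PRESETS:
                raise ValueError(f"unknown scan range: {self.scan_range}")
        else:
            start, end = self.scan_range
            if not (0 <= start < end):
                raise ValueError("need 0 <= start_mm < end_mm")

    @property
    def slice_step_mm(self) -> float:
        return self.beam_width_z * self.pit


@dataclass
class SliceDoseProfile:
    """Dose versus slice position for one organ."""

    organ: str
    positions_mm: np.ndarray
    qD_mGy_per_photon: np.ndarray
    D_mGy: np.ndarray
    rel_se: np.ndarray

    def __post_init__(self):
        self.positions_mm = np.asarray(self.positions_mm, dtype=float)
        self.qD_mGy_per_photon = np.asarray(self.qD_mGy_per_photon, float)
        self.D_mGy = np.asarray(self.D_mGy, dtype=float)
        self.rel_se = np.asarray(self.rel_se, dtype=float)
        if np.any(np.diff(self.positions_mm) <= 0):
            raise ValueError("slice positions must be strictly increasing")
        if np.any(self.D_mGy < 0) or np.any(self.qD_mGy_per_photon < 0):
            raise ValueError("doses must be >= 0")


@dataclass
class OrganDoseTable:
    """Scan-range-integrated absorbed doses for one protocol."""

    protocol: ScanProtocol
    preset: str
    start_mm: float
    end_mm: float
    dose_mGy: dict  # organ -> mGy
    rel_se: dict  # organ -> relative standard error of the integral
    qK_air_mGy_per_photon: float = float("nan")


def normalize_dose(qD, qK_air: float, nCTDI_air: float = 0.192,
                   At_mAs: float = 540.0, pit: float = 1.0):
    """Absolute dose [mGy]: (qD / qK_air) x nCTDI_air x At / pit."""
    if qK_air <= 0:
        raise ValueError("qK_air must be > 0")
    if pit <= 0:
        raise ValueError("pit must be > 0")
    if nCTDI_air <= 0 or At_mAs <= 0:
        raise ValueError("nCTDI_air and At must be > 0")
    return np.asarray(qD) / qK_air * nCTDI_air * At_mAs / pit if \
        np.ndim(qD) else qD / qK_air * nCTDI_air * At_mAs / pit


def _caudal_projection(phantom: VoxelPhantom, organ_ids,
                       plane_angle_deg: float) -> float:
    """Most caudal slice position whose (tilted) beam plane still touches
    the given organs.

    The beam plane through slice k is z = k - (y - y_iso) tan(phi); the
    plane touches a voxel at (y, z) when k = z + (y - y_iso) tan(phi).
    """
    t = math.tan(math.radians(plane_angle_deg))
    _, y_iso = phantom.landmarks["isocenter_xy"]
    y = phantom.axis_coords(1)
    z = phantom.axis_coords(2)
    best = -np.inf
    for oid in organ_ids:
        mask = phantom.labels == oid
        proj = mask.any(axis=0)  # (ny, nz)
        if not proj.any():
            continue
        k = (y[:, None] - y_iso) * t + z[None, :]
        best = max(best, float(k[proj].max()))
    if not np.isfinite(best):
        raise ValueError("no voxels found for scan-range organs")
    return best


def scan_range_preset(name: str, phantom: VoxelPhantom,
                      tilt_deg: float = 0.0):
    """(start_mm, end_mm) for a named caudal scan limit.

    start is always the vertex (0 mm). Presets i/ii are tilt-aware: the end
    is the caudal extent of the target organs projected onto the slice axis
    under the beam-plane angle (tilt + OM inclination). Presets iii/iv are
    the orbital-margin landmarks defined for perpendicular incidence.
    """
    lm = phantom.landmarks
    if name == "brain_and_eyes_i":
        phi = tilt_deg + phantom.om_inclination_deg
        ids = [LABEL_BY_NAME[n] for n in
               ("brain", "eyeball_L", "eyeball_R", "lens_L", "lens_R")]
        return 0.0, _caudal_projection(phantom, ids, phi)
    if name == "brain_only_ii":
        phi = tilt_deg + phantom.om_inclination_deg
        return 0.0, _caudal_projection(phantom, [LABEL_BY_NAME["brain"]], phi)
    if name == "infraorbital_iii":
        return 0.0, float(lm["infraorbital_z"])
    if name == "supraorbital_iv":
        return 0.0, float(lm["supraorbital_z"])
    raise ValueError(f"unknown scan range preset: {name}")


def lens_peak_position(phantom: VoxelPhantom, tilt_deg: float = 0.0) -> float:
    """Predicted slice position of the lens dose peak [mm].

    The tilted beam plane through slice k intersects the lens center when
    k = z_lens + (y_lens - y_iso) tan(tilt + OM inclination).
    """
    lm = phantom.landmarks
    _, y_iso = lm["isocenter_xy"]
    phi = math.radians(tilt_deg + phantom.om_inclination_deg)
    return float(lm["lens_z"]
                 + (lm["lens_anterior_y"] - y_iso) * math.tan(phi))


def _resolve_range(protocol: ScanProtocol, phantom: VoxelPhantom):
    if isinstance(protocol.scan_range, str):
        start, end = scan_range_preset(protocol.scan_range, phantom,
                                       protocol.tilt_deg)
        return protocol.scan_range, start, end
    start, end = protocol.scan_range
    return "explicit", float(start), float(end)


def run_scan(phantom: VoxelPhantom, geom: GantryGeometry,
             spectrum: SpectrumTable, bowtie: BowtieFilter,
             protocol: ScanProtocol,
             db: CrossSectionDB | None = None,
             profile_extent_mm: float = PROFILE_EXTENT_MM,
             log=None):
    """Run a full scan: per-slice simulations plus normalization.

    Profiles always cover [0, profile_extent_mm] so that dose tails outside
    the scan range remain visible; the OrganDoseTable sums D(T, k) over
    slices whose centers lie in [start, end]. Reproducible under a fixed
    protocol seed.
    """
    preset, start, end = _resolve_range(protocol, phantom)
    if end <= start:
        raise ValueError("empty scan range")
    if db is None:
        db = build_cross_section_db()
    geom = GantryGeometry(
        source_to_isocenter=geom.source_to_isocenter,
        fan_half_angle=geom.fan_half_angle,
        beam_width_z=protocol.beam_width_z,
        tilt_deg=protocol.tilt_deg,
        rotation_sampling=geom.rotation_sampling,
        n_views=geom.n_views)
    step = protocol.slice_step_mm
    positions = np.arange(0.0, profile_extent_mm + 0.5 * step, step)
    positions = positions[positions <= profile_extent_mm + 1e-9]

    # the track-length air-kerma estimate is cheap and enters every slice
    # dose as a common normalization, so it gets a generous photon budget
    qk = compute_air_kerma(geom, spectrum, bowtie,
                           n_photons=max(protocol.n_photons_per_slice,
                                         500_000),
                           seed=protocol.seed, db=db,
                           om_inclination_deg=phantom.om_inclination_deg)
    organ_names = [lab.name for lab in phantom.label_table]
    n_org = len(organ_names)
    qd = np.zeros((positions.size, n_org))
    rel = np.zeros((positions.size, n_org))
    for i, k in enumerate(positions):
        res = simulate_slice(
            phantom, geom, spectrum, bowtie, k,
            n_photons=protocol.n_photons_per_slice,
            n_batches=protocol.n_batches, seed=protocol.seed,
            db=db, slice_key=i + 1)
        qd[i] = res.qD_mGy_per_photon
        rel[i] = res.rel_se
        if log is not None:
            worst = float(np.nanmax(rel[i])) if np.any(rel[i] > 0) else 0.0
            log.debug("slice %.1f mm: max rel. SE %.3f", k, worst)

    d = normalize_dose(qd, qk.qK_air_mGy_per_photon, protocol.nCTDI_air,
                       protocol.At_mAs, protocol.pit)
    profiles = {}
    for j, name in enumerate(organ_names):
        profiles[name] = SliceDoseProfile(
            organ=name, positions_mm=positions.copy(),
            qD_mGy_per_photon=qd[:, j], D_mGy=d[:, j], rel_se=rel[:, j])

    in_range = (positions >= start - 1e-9) & (positions <= end + 1e-9)
    dose, dose_se = {}, {}
    for j, name in enumerate(organ_names):
        total = float(d[in_range, j].sum())
        var = float(((d[in_range, j] * rel[in_range, j]) ** 2).sum())
        dose[name] = total
        dose_se[name] = math.sqrt(var) / total if total > 0 else 0.0
    table = OrganDoseTable(
        protocol=protocol, preset=preset, start_mm=start, end_mm=end,
        dose_mGy=dose, rel_se=dose_se,
        qK_air_mGy_per_photon=qk.qK_air_mGy_per_photon)
    return profiles, table


def tilt_sweep(phantom, geom, spectrum, bowtie, base_protocol: ScanProtocol,
               tilts=TILT_GRID_DEG,
               presets=("brain_and_eyes_i", "brain_only_ii"),
               db: CrossSectionDB | None = None, log=None):
    """Convenience driver over the studied tilt grid and scan ranges.

    Yields (tilt_deg, preset, OrganDoseTable) for each combination.
    """
    if db is None:
        db = build_cross_section_db()
    for tilt in tilts:
        for preset in presets:
            proto = ScanProtocol(
                tilt_deg=float(tilt), scan_range=preset,
                pit=base_protocol.pit, At_mAs=base_protocol.At_mAs,
                nCTDI_air=base_protocol.nCTDI_air,
                tube_kv=base_protocol.tube_kv,
                beam_width_z=base_protocol.beam_width_z,
                n_photons_per_slice=base_protocol.n_photons_per_slice,
                n_batches=base_protocol.n_batches,
                seed=base_protocol.seed,
                ctdi_vol_mGy=base_protocol.ctdi_vol_mGy)
            _, table = run_scan(phantom, geom, spectrum, bowtie, proto,
                                db=db, log=log)
            yield float(tilt), preset, table
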