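"""File I/O: phantom volumes, spectrum/bowtie tables, profile and dose CSVs.

Formats are deliberately plain text (or raw bytes with a JSON sidecar for
volumes) so outputs diff cleanly. Every CSV written by the pipeline embeds
a comment header with the tool version, a configuration hash and the
master seed, so reruns are fully attributable.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import warnings
from pathlib import Path

import numpy as np

from . import __version__
from .beam import BowtieFilter, SpectrumTable
from .dosimetry import OrganDoseTable, ScanProtocol, SliceDoseProfile
from .phantom import VoxelPhantom, organ_labels

__all__ = [
    "write_phantom", "read_phantom",
    "write_spectrum_tsv", "read_spectrum_tsv",
    "write_bowtie_tsv", "read_bowtie_tsv",
    "write_xsection_tsv",
    "write_profile_csv", "read_profile_csv",
    "write_dose_table_csv", "read_dose_table_csv",
    "write_metrics_csv",
    "config_hash",
]

PHANTOM_FORMAT_VERSION = 1


class ParseError(ValueError):
    pass


def config_hash(obj) -> str:
    """Short stable hash of a configuration mapping/dataclass."""
    if hasattr(obj, "__dataclass_fields__"):
        import dataclasses
        obj = dataclasses.asdict(obj)
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header_lines(seed=None, cfg_hash=None):
    lines = [f"# headctdose v{__version__}"]
    if cfg_hash is not None:
        lines.append(f"# config_hash: {cfg_hash}")
    if seed is not None:
        lines.append(f"# seed: {seed}")
    return lines


# -- phantom volume: <name>.json sidecar + <name>.raw uint8 labels ----------

def write_phantom(phantom: VoxelPhantom, path) -> None:
    """Write ``path``.json (metadata) and ``path``.raw (uint8 labels,
    x-fastest, z-slowest order, little-endian)."""
    path = Path(path)
    base = path.with_suffix("") if path.suffix in (".json", ".raw") else path
    meta = {
        "format_version": PHANTOM_FORMAT_VERSION,
        "dims": list(phantom.dims),
        "spacing_mm": list(phantom.spacing),
        "origin_mm": list(phantom.origin),
        "om_inclination_deg": phantom.om_inclination_deg,
        "landmarks": {k: (list(v) if isinstance(v, (tuple, list)) else v)
                      for k, v in phantom.landmarks.items()},
        "labels": [
            {"id": lab.id, "name": lab.name, "material": lab.material.name,
             "density_g_cm3": lab.material.density}
            for lab in phantom.label_table
        ],
    }
    base.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    # x-fastest, z-slowest: labels[ix,iy,iz] flattened in Fortran order
    base.with_suffix(".raw").write_bytes(
        np.asfortranarray(phantom.labels).tobytes(order="F"))


def read_phantom(path) -> VoxelPhantom:
    path = Path(path)
    base = path.with_suffix("") if path.suffix in (".json", ".raw") else path
    meta = json.loads(base.with_suffix(".json").read_text())
    dims = tuple(meta["dims"])
    raw = base.with_suffix(".raw").read_bytes()
    expected = dims[0] * dims[1] * dims[2]
    if len(raw) != expected:
        raise ParseError(
            f"raw file has {len(raw)} bytes, expected {expected} "
            f"for dims {dims}")
    labels = np.frombuffer(raw, dtype=np.uint8).reshape(dims, order="F")
    lm = {k: (tuple(v) if isinstance(v, list) else v)
          for k, v in meta["landmarks"].items()}
    return VoxelPhantom(
        dims=dims, spacing=tuple(meta["spacing_mm"]),
        origin=tuple(meta["origin_mm"]), labels=labels.copy(),
        landmarks=lm, om_inclination_deg=meta["om_inclination_deg"],
        label_table=organ_labels())


# -- spectrum / bowtie TSV --------------------------------------------------

def write_spectrum_tsv(spectrum: SpectrumTable, path) -> None:
    lines = _header_lines() + ["energy_keV\trelative_fluence"]
    for e, f in zip(spectrum.energy_keV, spectrum.relative_fluence):
        lines.append(f"{e:.6g}\t{f:.12g}")
    Path(path).write_text("\n".join(lines) + "\n")


def _read_two_col_tsv(path, col1, col2):
    a, b = [], []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[0] == col1:
            continue
        if len(parts) < 2:
            raise ParseError(f"line {ln}: expected two columns")
        try:
            a.append(float(parts[0]))
            b.append(float(parts[1]))
        except ValueError:
            raise ParseError(f"line {ln}: malformed number") from None
    return np.array(a), np.array(b)


def read_spectrum_tsv(path) -> SpectrumTable:
    e, f = _read_two_col_tsv(path, "energy_keV", "relative_fluence")
    return SpectrumTable(e, f)


def write_bowtie_tsv(bowtie: BowtieFilter, path) -> None:
    lines = _header_lines() + ["fan_angle_deg\tal_thickness_mm"]
    for g, t in zip(bowtie.fan_angle_grid, bowtie.equivalent_Al_thickness):
        lines.append(f"{g:.6g}\t{t:.12g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_bowtie_tsv(path) -> BowtieFilter:
    g, t = _read_two_col_tsv(path, "fan_angle_deg", "al_thickness_mm")
    return BowtieFilter(g, t)


def write_xsection_tsv(db, path) -> None:
    """Per-material TSV blocks of the cross-section tables."""
    lines = _header_lines()
    for name in db.materials:
        lines.append(f"# material: {name}")
        lines.append("energy_keV\tpe_cm2g\tincoh_cm2g\tcoh_cm2g\tmutr_cm2g")
        for i, e in enumerate(db.energy_grid):
            lines.append(
                f"{e:.6g}\t{db.pe[name][i]:.8g}\t{db.incoh[name][i]:.8g}"
                f"\t{db.coh[name][i]:.8g}\t{db.mutr[name][i]:.8g}")
    Path(path).write_text("\n".join(lines) + "\n")


# -- profile / dose-table CSV ----------------------------------------------

_PROFILE_COLS = ["organ", "slice_mm", "qD_mGy_per_photon", "D_mGy", "rel_se"]


def write_profile_csv(profiles, path, seed=None, cfg_hash=None) -> None:
    """Profiles: iterable (or dict of) SliceDoseProfile -> documented CSV."""
    if isinstance(profiles, dict):
        profiles = profiles.values()
    lines = _header_lines(seed, cfg_hash) + [",".join(_PROFILE_COLS)]
    for p in profiles:
        for k, qd, d, se in zip(p.positions_mm, p.qD_mGy_per_photon,
                                p.D_mGy, p.rel_se):
            lines.append(
                f"{p.organ},{k:.12g},{qd:.12g},{d:.12g},{se:.12g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_profile_csv(path) -> dict:
    """Read profiles; rows are re-sorted by slice position per organ."""
    rows = []
    header_seen = False
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(",")
        if not header_seen:
            if parts != _PROFILE_COLS:
                raise ParseError(
                    f"line {ln}: expected columns {_PROFILE_COLS}, "
                    f"got {parts}")
            header_seen = True
            continue
        if len(parts) != len(_PROFILE_COLS):
            raise ParseError(f"line {ln}: wrong number of columns")
        try:
            rows.append((parts[0], float(parts[1]), float(parts[2]),
                         float(parts[3]), float(parts[4])))
        except ValueError:
            raise ParseError(f"line {ln}: malformed number") from None
    if not header_seen and not rows:
        warnings.warn(f"{path}: empty profile file", stacklevel=2)
        return {}
    out = {}
    organs = sorted({r[0] for r in rows}, key=lambda o: [
        r[0] for r in rows].index(o))
    for organ in organs:
        sub = sorted([r for r in rows if r[0] == organ], key=lambda r: r[1])
        out[organ] = SliceDoseProfile(
            organ=organ,
            positions_mm=np.array([r[1] for r in sub]),
            qD_mGy_per_photon=np.array([r[2] for r in sub]),
            D_mGy=np.array([r[3] for r in sub]),
            rel_se=np.array([r[4] for r in sub]))
    return out


_DOSE_COLS = ["organ", "dose_mGy", "rel_se", "preset", "tilt_deg"]


def write_dose_table_csv(table: OrganDoseTable, path, seed=None,
                         cfg_hash=None) -> None:
    lines = _header_lines(seed, cfg_hash)
    lines.append(f"# scan_range: {table.start_mm:.6g}-{table.end_mm:.6g} mm")
    lines.append(f"# qK_air_mGy_per_photon: "
                 f"{table.qK_air_mGy_per_photon:.12g}")
    lines.append(",".join(_DOSE_COLS))
    for organ, dose in table.dose_mGy.items():
        lines.append(f"{organ},{dose:.12g},{table.rel_se[organ]:.12g},"
                     f"{table.preset},{table.protocol.tilt_deg:.6g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_dose_table_csv(path) -> dict:
    """Read a dose-table CSV as {organ: (dose_mGy, rel_se)}."""
    out = {}
    header_seen = False
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(",")
        if not header_seen:
            if parts != _DOSE_COLS:
                raise ParseError(f"line {ln}: expected {_DOSE_COLS}")
            header_seen = True
            continue
        try:
            out[parts[0]] = (float(parts[1]), float(parts[2]))
        except ValueError:
            raise ParseError(f"line {ln}: malformed number") from None
    return out


_METRIC_COLS = ["organ", "D_max_mGy", "x_peak_mm", "x1_mm", "x2_mm",
                "fwhm_mm", "range_dose_mGy", "tail_dose_mGy"]


def write_metrics_csv(metrics_rows, path, seed=None, cfg_hash=None) -> None:
    lines = _header_lines(seed, cfg_hash) + [",".join(_METRIC_COLS)]
    for m in metrics_rows:
        lines.append(
            f"{m.organ},{m.D_max_mGy:.12g},{m.x_peak_mm:.12g},"
            f"{m.x1_mm:.12g},{m.x2_mm:.12g},{m.fwhm_mm:.12g},"
            f"{m.range_dose_mGy:.12g},{m.tail_dose_mGy:.12g}")
    Path(path).write_text("\n".join(lines) + "\n")
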