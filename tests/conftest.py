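"""Shared fixtures: default phantom, beam model, cross sections, toys."""

import numpy as np
import pytest

from headctdose import (build_cross_section_db, build_head_phantom,
                        default_bowtie, generate_spectrum, GantryGeometry)
from headctdose.phantom import OrganLabel, VoxelPhantom, get_material


@pytest.fixture(scope="session")
def phantom2mm():
    return build_head_phantom(spacing=(2.0, 2.0, 2.0))


@pytest.fixture(scope="session")
def spectrum120():
    return generate_spectrum(120.0, 2.5)


@pytest.fixture(scope="session")
def bowtie():
    return default_bowtie()


@pytest.fixture(scope="session")
def xs_db():
    return build_cross_section_db()


@pytest.fixture()
def geometry():
    return GantryGeometry()


def make_box_phantom(dims, spacing, material_names, label_fill,
                     origin=None, om_inclination=0.0):
    """Small custom phantom: label_fill is a uint8 array or scalar."""
    table = [OrganLabel(i, name, get_material(name))
             for i, name in enumerate(material_names)]
    labels = np.full(dims, 0, dtype=np.uint8) if np.isscalar(label_fill) \
        else np.asarray(label_fill, dtype=np.uint8)
    if np.isscalar(label_fill):
        labels[:] = label_fill
    if origin is None:
        origin = tuple(-0.5 * d * s for d, s in zip(dims, spacing))
    return VoxelPhantom(
        dims=tuple(dims), spacing=tuple(spacing), origin=tuple(origin),
        labels=labels,
        landmarks={"isocenter_xy": (0.0, 0.0), "vertex_z": 0.0},
        om_inclination_deg=om_inclination, label_table=table)


@pytest.fixture()
def water_slab():
    """10 cm water slab along +z inside an air box (narrow-beam bench)."""
    dims = (20, 20, 60)
    spacing = (10.0, 10.0, 5.0)  # 200 x 200 x 300 mm box
    labels = np.zeros(dims, dtype=np.uint8)
    labels[:, :, 20:40] = 1  # 100 mm of water from z=-50 to +50
    return make_box_phantom(dims, spacing, ["air", "water"], labels)
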