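import numpy as np
import pytest
import trimesh

from hrapop.fixtures import OrganSpec, make_extraction_sites, make_reference_organ
from hrapop.geometry import ExtractionSite


@pytest.fixture(scope="session")
def box_organ():
    """Three disjoint 10 mm box structures with 2 mm gaps."""
    organ, _ = make_reference_organ(OrganSpec(n_structures=3, shapes=("box",)))
    return organ


@pytest.fixture(scope="session")
def adjacent_organ():
    """Three 10 mm boxes sharing faces (gap 0), for straddling sites."""
    organ, _ = make_reference_organ(OrganSpec(n_structures=3, shapes=("box",), gap=0.0))
    return organ


@pytest.fixture(scope="session")
def mixed_organ():
    """Box, sphere and prism structures."""
    organ, _ = make_reference_organ(
        OrganSpec(n_structures=3, shapes=("box", "sphere", "prism"))
    )
    return organ


@pytest.fixture(scope="session")
def straddle2_site(adjacent_organ):
    return make_extraction_sites(adjacent_organ, 1, "straddle2", seed=0)[0]


@pytest.fixture()
def unit_site():
    return ExtractionSite(id="unit", dimensions=(1.0, 1.0, 1.0))


def random_convex_mesh(rng) -> trimesh.Trimesh:
    """A random convex body: box, icosphere, or hull of random points."""
    kind = rng.integers(0, 3)
    if kind == 0:
        extents = rng.uniform(1.0, 6.0, 3)
        mesh = trimesh.creation.box(extents=extents)
    elif kind == 1:
        mesh = trimesh.creation.icosphere(subdivisions=2, radius=rng.uniform(1.0, 3.0))
    else:
        pts = rng.normal(scale=2.0, size=(30, 3))
        mesh = trimesh.convex.convex_hull(pts)
    mesh.apply_translation(rng.uniform(-2.0, 2.0, 3))
    mesh.metadata["id"] = "convex"
    mesh.metadata["label"] = "convex body"
    return mesh


def random_site(rng, near=None) -> ExtractionSite:
    center = np.zeros(3) if near is None else np.asarray(near)
    return ExtractionSite(
        id="rand",
        dimensions=tuple(rng.uniform(0.5, 3.0, 3)),
        translation=tuple(center + rng.uniform(-1.5, 1.5, 3)),
        rotation=tuple(rng.uniform(0.0, 360.0, 3)),
    )
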