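import numpy as np
import pytest
import trimesh

from quadjrf.mesh_geometry import AttachmentSite, TriMesh
from quadjrf.pipeline import load_config, run_pipeline
from quadjrf.synthetic_data import SkullParams, make_clade, write_clade


@pytest.fixture
def unit_triangle() -> AttachmentSite:
    mesh = TriMesh(
        vertices=[[0, 0, 0], [1, 0, 0], [0, 1, 0]],
        faces=[[0, 1, 2]],
    )
    return AttachmentSite(name="triangle", mesh=mesh)


@pytest.fixture
def unit_square() -> AttachmentSite:
    mesh = TriMesh(
        vertices=[[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]],
        faces=[[0, 1, 2], [0, 2, 3]],
    )
    return AttachmentSite(name="square", mesh=mesh)


@pytest.fixture(scope="session")
def icosphere_site() -> AttachmentSite:
    sphere = trimesh.creation.icosphere(subdivisions=4, radius=10.0)
    return AttachmentSite(
        name="sphere", mesh=TriMesh(np.asarray(sphere.vertices), np.asarray(sphere.faces))
    )


@pytest.fixture(scope="session")
def small_clade():
    """An 11-taxon synthetic clade with the default axis offset."""
    return make_clade(n_taxa=11, seed=20240915, base_params=SkullParams())


@pytest.fixture(scope="session")
def clade_dir(tmp_path_factory, small_clade):
    """The small clade written to disk as a ready-to-run directory."""
    d = tmp_path_factory.mktemp("clade")
    write_clade(small_clade, d, force=True)
    return d


@pytest.fixture(scope="session")
def pipeline_outputs(clade_dir):
    """Full pipeline outputs for the small clade (run once per session)."""
    cfg = load_config(clade_dir / "config.yaml")
    out = run_pipeline(cfg)
    return out
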