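import numpy as np

import fractwin as fw
from fractwin.materials import ElementMaterials


def make_bar_mesh(nv=(2, 2, 20), length=100.0, width=10.0, **mesh_kw):
    """Structured bar mesh: width x width x length mm, single-layer end sets."""
    labels = np.ones(nv, dtype=int)
    h = width / nv[0]
    assert np.isclose(nv[2] * h, length)
    cfg = fw.MeshConfig(**mesh_kw) if mesh_kw else fw.MeshConfig(end_set_fraction=0.4 * h / length)
    return fw.build_mesh(labels, h, cfg)


def uniform_materials(mesh, E=1000.0, nu=0.0):
    return ElementMaterials(
        E=np.full(mesh.n_elements, E), nu=np.full(mesh.n_elements, nu), region=mesh.region
    )
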