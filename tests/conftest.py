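import numpy as np
import pytest

import fractwin as fw


@pytest.fixture(scope="session")
def noise_free_spec():
    """Small noise-free phantom: exact calibration and clean segmentation."""
    return fw.PhantomSpec(shape=(20, 20, 40), spacing=3.0, noise_sd=0.0, seed=7)


@pytest.fixture(scope="session")
def noise_free_phantom(noise_free_spec):
    return fw.generate_phantom_volume(noise_free_spec)


@pytest.fixture(scope="session")
def small_state(noise_free_spec, noise_free_phantom):
    """Shared calibrated/segmented/meshed state of the small phantom."""
    volume, labels = noise_free_phantom
    rods = fw.rod_masks_from_layout(volume)
    cal = fw.calibrate_density(volume, rods, volume.meta["rod_densities_mg_cm3"])
    masks = fw.segment_adaptive(volume, cal)
    mesh = fw.build_mesh(masks.labels, masks.spacing)
    mats = fw.map_materials(mesh, volume, cal)
    return {
        "spec": noise_free_spec,
        "volume": volume,
        "labels": labels,
        "calibration": cal,
        "masks": masks,
        "mesh": mesh,
        "materials": mats,
    }


@pytest.fixture(scope="session")
def small_solver(small_state):
    return fw.LinearGaitSolver(small_state["mesh"], small_state["materials"], fw.BoundaryCondition())
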