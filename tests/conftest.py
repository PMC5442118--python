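"""Shared fixtures: small fast phantoms plus full-size noiseless/noisy animals."""

import pytest

from aarcmr.phantom import (AcquisitionSettings, GroupSpec, PhantomConfig,
                            assign_regions, default_tissue_params, make_animal,
                            make_geometry)

CONTROL = GroupSpec("control", 64.3, 6.1, 50.6, 6.9, n_animals=6)
IPC = GroupSpec("IPC", 59.8, 7.9, 27.9, 3.7, n_animals=10,
                edema_extent_multiplier=0.85)

#: small geometry for unit tests: 64x64, 4 slices (2 span + 2 basal remote)
SMALL_ACQ = dict(n_slices_cmr=4, n_slices_asl=4, matrix_size=64)


@pytest.fixture(scope="session")
def small_labels():
    cfg = PhantomConfig(matrix_size=64, n_slices=4, aar_fraction=0.5,
                        is_fraction_of_aar=0.5)
    geo = make_geometry(cfg)
    return assign_regions(geo, 0.5, 0.5, cfg.aar_slice_span, 1.0,
                          cfg.lv_center, 20.0)


@pytest.fixture(scope="session")
def tissue_params():
    return default_tissue_params()


@pytest.fixture(scope="session")
def noiseless_control_animal():
    """Full-size control phantom without noise: the closed-loop reference."""
    acq = AcquisitionSettings(noise_sd=0.0)
    return make_animal("ctrl_nl", CONTROL, 0.643, 0.506, 30.0, seed=11,
                       acquisition=acq)


@pytest.fixture(scope="session")
def noisy_control_animal():
    """Full-size control phantom at the default SNR."""
    return make_animal("ctrl_ny", CONTROL, 0.643, 0.506, 75.0, seed=12,
                       acquisition=AcquisitionSettings())


@pytest.fixture(scope="session")
def noiseless_ipc_animal():
    """IPC-like phantom (edema extent 0.85 of AAR), noiseless."""
    acq = AcquisitionSettings(noise_sd=0.0)
    return make_animal("ipc_nl", IPC, 0.598, 0.279, 130.0, seed=13,
                       acquisition=acq)


@pytest.fixture(scope="session")
def noiseless_maps(noiseless_control_animal):
    from aarcmr.pipeline import fit_animal
    return fit_animal(noiseless_control_animal)


@pytest.fixture(scope="session")
def per_pixel_truth():
    """Ground-truth per-pixel parameter images for an animal's label set."""
    from aarcmr.phantom import _per_pixel

    def _truth(animal, which, labels="cmr"):
        lab = animal.labels_cmr if labels == "cmr" else animal.labels_asl
        return _per_pixel(lab, animal.tissue_params, which,
                          edema_gated=which in ("t1_s", "t2_ms", "s0"))

    return _truth
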