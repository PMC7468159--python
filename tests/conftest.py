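"""Shared fixtures: rendered synthetic fields with known ground truth."""

import math

import numpy as np
import pytest

import gliamorph as gm

FIELD_SIDE = 424.0
PIXEL_SIZE = 0.415
N_CELLS = 10
SNR = 5.0


def moderate_noise_sd() -> float:
    """Noise sigma giving a process-contrast SNR of 5."""
    r = gm.CellRegime()
    return (r.intensity_process - r.intensity_background) / SNR


def render_test_field(seed: int, noise_sd: float, n_cells: int = N_CELLS):
    rng = np.random.default_rng(seed)
    specs = gm.sample_field_specs(rng, n_cells, FIELD_SIDE,
                                  gm.CellRegime(noise_sd=noise_sd))
    image, truth = gm.render_field(specs, FIELD_SIDE, PIXEL_SIZE,
                                   rng_seed=seed + 500)
    return image, truth


def match_to_truth(measurement: "gm.FieldMeasurement", truth: "gm.FieldGroundTruth"):
    """Pair each measured cell with the nearest planted cell by soma centre."""
    pairs = []
    for cell in measurement.cells:
        planted = min(truth.cells,
                      key=lambda t: math.dist(t.soma_center, cell.centroid_um))
        assert math.dist(planted.soma_center, cell.centroid_um) < 5.0
        pairs.append((cell, planted))
    return pairs


@pytest.fixture(scope="session")
def noiseless_field():
    return render_test_field(seed=101, noise_sd=0.0)


@pytest.fixture(scope="session")
def noisy_field():
    return render_test_field(seed=101, noise_sd=moderate_noise_sd())


@pytest.fixture(scope="session")
def noiseless_measurement(noiseless_field):
    image, truth = noiseless_field
    return gm.measure_field(image, gm.PipelineConfig()), truth


@pytest.fixture(scope="session")
def noisy_measurement(noisy_field):
    image, truth = noisy_field
    return gm.measure_field(image, gm.PipelineConfig()), truth
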