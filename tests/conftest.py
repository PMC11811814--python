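import numpy as np
import pytest

from dropsecr.config import AcquisitionSpec, AssayConstants, ChamberSpec, PhenotypeSpec
from dropsecr.synthgen import generate_trace_set


@pytest.fixture
def noiseless_acq():
    return AcquisitionSpec(noise_sd=0.0)


@pytest.fixture
def constants():
    return AssayConstants()


def single_cell_phenotypes(n, **kw):
    """n identical single-cell phenotypes (kwargs as for PhenotypeSpec)."""
    return [PhenotypeSpec(f"c{i}", n_cells_in_droplet=1, **kw) for i in range(n)]


@pytest.fixture
def small_noiseless_chamber(noiseless_acq):
    """5 single-cell droplets: one NOX-active (20% loss), secreting."""
    chamber = ChamberSpec(n_droplets=5)
    phens = [
        PhenotypeSpec(
            f"c{i}",
            nox_active=(i == 0),
            terminal_loss_pct=20.0 if i == 0 else 0.0,
            igg_rate=50.0,
            lactate_rate=0.4,
            ros_slope=10.0,
            n_cells_in_droplet=1,
        )
        for i in range(5)
    ]
    traces, truth = generate_trace_set(chamber, noiseless_acq, phens, seed=11)
    return chamber, noiseless_acq, traces, truth
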