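import numpy as np
import pytest

from vnsdyn.containers import AdministrationDataset, UniformSeries
from vnsdyn.series_prep import build_input_waveform, parse_administrations
from vnsdyn.synthetic import make_ground_truth, simulate_biomarker_series

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


def make_dataset(u, y, **kw):
    """Bare input/output dataset on the 1 Hz grid (onset at 0)."""
    kw.setdefault("onset_index", 0)
    return AdministrationDataset(UniformSeries(np.asarray(y, float)),
                                 UniformSeries(np.asarray(u, float)), **kw)


def truth_records(system, n_records=3, seed=0, onset=180, duration=800):
    """Administration records simulated from a ground-truth system.

    Each record is an independent day-style recording with one
    stimulus; the standard trapezoid input and a 300-sample window are
    used throughout.
    """
    records = []
    for r in range(n_records):
        u = build_input_waveform(duration, onset).values
        y = simulate_biomarker_series(system, u, duration,
                                      seed=seed * 1000 + r)
        records.extend(parse_administrations(y, [onset], subject="T",
                                             biomarker="hr"))
    for i, d in enumerate(records):
        d.administration = i
    return records


@pytest.fixture(scope="session")
def first_order_truth():
    """Noise-free first-order responder: gain -0.04, 20 s time constant."""
    return make_ground_truth(1, 12, -0.04, 20.0, 0.0, seed=11)


@pytest.fixture(scope="session")
def first_order_records(first_order_truth):
    return truth_records(first_order_truth, n_records=3, seed=1)


@pytest.fixture(scope="session")
def second_order_truth():
    return make_ground_truth(2, 15, -0.04, 25.0, 0.0, seed=5)


@pytest.fixture(scope="session")
def second_order_records(second_order_truth):
    return truth_records(second_order_truth, n_records=3, seed=2)
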