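import warnings

import numpy as np
import pytest

import thermocit as tc
from thermocit import preprocess as pre
from thermocit import smoothing as smo
from thermocit.design import noiseless

# synthetic skin temperatures near 36 degC are in range; tests that use
# abstract values (0/1 constants etc.) trip the plausibility warning on
# purpose, so silence it suite-wide
warnings.filterwarnings("ignore", message="temperatures outside the plausible skin range")


@pytest.fixture(scope="session")
def paper_design():
    """The emulated study layout: 18+12 participants, 3+12 questions, 10 s at 30 Hz."""
    return tc.StudyDesign()


@pytest.fixture(scope="session")
def tiny_design():
    """A fast design for property tests: 4+4 participants, 1+2 questions, 2 s at 5 Hz."""
    return tc.StudyDesign(
        n_guilty=4, n_innocent=4, n_relevant=1, n_irrelevant=2,
        window_s=2.0, rate_hz=5.0, seed=7,
    )


@pytest.fixture(scope="session")
def zero_noise_design(paper_design):
    return noiseless(paper_design)


def make_sample(temps, times=None, **labels):
    temps = np.asarray(temps, dtype=float)
    if times is None:
        times = np.arange(len(temps)) / 10.0
    defaults = dict(participant_id="G01", condition="guilty", question_id="Q01", relevance="RE")
    defaults.update(labels)
    return tc.FunctionSample(times=np.asarray(times, dtype=float), temps=temps, **defaults)


def corrected_decimated(design, keep_every=5, relevance=None):
    """Generate, baseline-correct and decimate; optionally filter by relevance."""
    ds = tc.generate_dataset(design)
    out = []
    for s in ds.samples:
        if relevance is not None and s.relevance != relevance:
            continue
        out.append(pre.decimate(pre.baseline_correct(s, ds.baselines[s.participant_id]), keep_every))
    return out


def smoothed_functions(design, keep_every=5, relevance=None, lam=10.0, extra_basis=2):
    """The pipeline's smoothing stage on corrected (optionally decimated) data."""
    dec = corrected_decimated(design, keep_every, relevance)
    grid = dec[0].times
    basis = smo.build_basis(float(grid[-1]), len(grid) + extra_basis, 4)
    return smo.smooth_many(dec, basis, smo.SmoothConfig(lam=lam)), grid
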