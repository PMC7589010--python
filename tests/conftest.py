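"""Shared fixtures: synthetic databases and constructed ensembles.

The expensive session-scoped ensembles are built lazily, so unit-test runs
that do not request them stay fast.  Sizes are the desk-scale study
conditions documented in docs/methods.md.  Hyaluronan carries the
restraint-fidelity, recovery and length-trend checks (its compact-chain
secondary basins make the trend strong); dermatan carries the 10-vs-20-mer
mode-ratio check (its sharply peaked end-to-end distribution gives the mode
estimate adequate power).
"""

import time

import numpy as np
import pytest

from gagbuilder.analysis import end_to_end
from gagbuilder.builder import PolymerSpec, build_chain
from gagbuilder.energetics import compute_cutoff, generate_ensemble
from gagbuilder.synthetic import generate_db

DB_SEED = 202
DB_POOL = 2000


@pytest.fixture(scope="session")
def hyaluronan_db():
    return generate_db("hyaluronan", n_per_pool=DB_POOL, seed=DB_SEED)


@pytest.fixture(scope="session")
def dermatan_db():
    return generate_db("dermatan", n_per_pool=DB_POOL, seed=303)


@pytest.fixture(scope="session")
def ens20(hyaluronan_db):
    """Retained hyaluronan 20-mer ensemble (restraint-fidelity checks)."""
    return generate_ensemble(PolymerSpec("hyaluronan", 20), hyaluronan_db,
                             2500, seed=11)


@pytest.fixture(scope="session")
def ens10(hyaluronan_db):
    return generate_ensemble(PolymerSpec("hyaluronan", 10), hyaluronan_db,
                             1500, seed=12)


@pytest.fixture(scope="session")
def ens200(hyaluronan_db):
    """1,000 retained 200-mers: the scale check and the length trend."""
    t0 = time.time()
    spec = PolymerSpec("hyaluronan", 200)
    cutoff = compute_cutoff(spec, hyaluronan_db)
    ens = generate_ensemble(spec, hyaluronan_db, 1000, seed=13,
                            cutoff=cutoff)
    ens.generation_seconds = time.time() - t0
    return ens


@pytest.fixture(scope="session")
def derm_ens20(dermatan_db):
    return generate_ensemble(PolymerSpec("dermatan", 20), dermatan_db,
                             2000, seed=21)


@pytest.fixture(scope="session")
def derm_ens10(dermatan_db):
    return generate_ensemble(PolymerSpec("dermatan", 10), dermatan_db,
                             1500, seed=22)


@pytest.fixture(scope="session")
def derm_raw_e2e(dermatan_db):
    """Unminimized geometric-sampling draws: the independent-sampling
    expectation for the 10-vs-20-mer mode-ratio check."""
    out = {}
    for n, tag in ((20, 810), (10, 820)):
        spec = PolymerSpec("dermatan", n)
        out[n] = np.array([
            end_to_end(build_chain(spec, dermatan_db,
                                   np.random.default_rng([tag, k])))
            for k in range(6000)])
    return out
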