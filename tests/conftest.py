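import numpy as np
import pytest

from lakecarbon.boxmodel import BoxModelSpec, FluxTerm
from lakecarbon.pipeline import load_table1_fixture
from lakecarbon.sensitivity import baseline_network


@pytest.fixture(scope="session")
def table1():
    """The packaged reference network with the printed (rounded) fluxes."""
    return load_table1_fixture()


@pytest.fixture(scope="session")
def table1_free():
    """Same network with the detrital/magmatic inputs left unconstrained."""
    return load_table1_fixture(free_detmag=True)


@pytest.fixture(scope="session")
def chain_baseline():
    """The full-precision baseline rebuilt from the measured anchors."""
    return baseline_network()


def make_balanced_network(rng: np.random.Generator, n_terms: int = 8) -> BoxModelSpec:
    """A random mass-balanced network with a mix of epsilon/delta terms.

    Networks whose epsilon-carried flux nearly cancels between sides are
    resampled, since those leave d13C_DIC unconstrained.
    """
    while True:
        n_in = rng.integers(2, n_terms - 1)
        n_out = n_terms - n_in
        f_in = rng.uniform(5.0, 300.0, n_in)
        f_out = rng.uniform(5.0, 300.0, n_out)
        f_out *= f_in.sum() / f_out.sum()
        terms = []
        eps_in = eps_out = 0.0
        for i, f in enumerate(f_in):
            if rng.random() < 0.6:
                terms.append(FluxTerm(f"in{i}", "input", f,
                                      epsilon=rng.uniform(-60, 60)))
                eps_in += f
            else:
                terms.append(FluxTerm(f"in{i}", "input", f,
                                      delta=rng.uniform(-60, 40)))
        for i, f in enumerate(f_out):
            if rng.random() < 0.6:
                terms.append(FluxTerm(f"out{i}", "output", f,
                                      epsilon=rng.uniform(-60, 60)))
                eps_out += f
            else:
                terms.append(FluxTerm(f"out{i}", "output", f,
                                      delta=rng.uniform(-60, 40)))
        if abs(eps_in - eps_out) > 1.0:  # keep the balance well conditioned
            return BoxModelSpec(terms=tuple(terms))
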