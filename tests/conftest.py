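import numpy as np
import pytest

from obpc import pipeline as pp
from obpc import synthetic as syn


def tiny_panel(n_stimuli: int, kind: str = "odorant") -> pp.StimulusPanel:
    """Panel of generic stimuli for tests that only need the stimulus axis."""
    return pp.StimulusPanel(tuple(
        pp.Stimulus(id=f"s{j:03d}", kind=kind, components=frozenset({j % 16}))
        for j in range(n_stimuli)))


@pytest.fixture(scope="session")
def mixture_panel():
    return syn.make_mixture_panel(seed=2)


@pytest.fixture(scope="session")
def concentration_panel():
    return syn.make_concentration_panel()


@pytest.fixture(scope="session")
def osn_tensor(mixture_panel):
    return syn.simulate_osn_tensor(mixture_panel,
                                   syn.OsnGeneratorParams(seed=3))


@pytest.fixture(scope="session")
def bouton_tensor(mixture_panel):
    return syn.simulate_bouton_tensor(mixture_panel,
                                      syn.BoutonGeneratorParams(seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
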