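import numpy as np
import pytest

import synpolar as sp


def random_instance(seed, n_neurons=5, n_nt=3, n_r=4, density=0.5):
    """Small random expression + ternary rules + mask instance."""
    rng = np.random.default_rng(seed)
    neurons = tuple(f"n{i}" for i in range(n_neurons))
    nts = tuple(f"nt{k}" for k in range(n_nt))
    rs = tuple(f"r{l}" for l in range(n_r))
    X = sp.ExpressionMatrix(neurons, nts,
                            (rng.random((n_neurons, n_nt)) < 0.6).astype(float))
    Y = sp.ExpressionMatrix(neurons, rs,
                            (rng.random((n_neurons, n_r)) < 0.5).astype(float))
    O = sp.WiringRuleNetwork(
        nts, rs,
        rng.choice([-1.0, 0.0, 1.0], size=(n_nt, n_r), p=[0.25, 0.5, 0.25]))
    present = (rng.random((n_neurons, n_neurons)) < density).astype(int)
    np.fill_diagonal(present, 0)
    mask = sp.ConnectomeMask(neurons, present)
    return X, O, Y, mask


def random_signed_network(seed, n=6, density=0.4, p_pos=0.64):
    """Random ternary signed directed network without self-loops."""
    rng = np.random.default_rng(seed)
    signs = (rng.random((n, n)) < density) * np.where(
        rng.random((n, n)) < p_pos, 1, -1)
    np.fill_diagonal(signs, 0)
    return sp.SignedConnectome(tuple(f"n{i}" for i in range(n)), signs)


@pytest.fixture(scope="session")
def planted_half_hidden():
    """One planted-model draw with half the known labels hidden (noiseless)."""
    return sp.generate(sp.PlantedModel(hide_fraction=0.5, seed=11))


@pytest.fixture()
def awc_instance():
    """One presynaptic NT, four +1 rules and one -1 rule, all expressed.

    Mirrors a glutamatergic neuron whose postsynaptic partner expresses four
    excitatory and one inhibitory receptor for the same transmitter.
    """
    neurons = ("pre", "post")
    X = sp.ExpressionMatrix(neurons, ("glu",), [[1.0], [0.0]])
    rs = ("ra", "rb", "rc", "rd", "re")
    Y = sp.ExpressionMatrix(neurons, rs,
                            [[0.0] * 5, [1.0] * 5])
    O = sp.WiringRuleNetwork(("glu",), rs, [[1.0, 1.0, 1.0, 1.0, -1.0]])
    mask = sp.ConnectomeMask(neurons, [[0, 1], [0, 0]])
    return X, O, Y, mask
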