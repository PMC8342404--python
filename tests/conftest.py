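import logging

import numpy as np
import pytest

import morphocontract as mc


@pytest.fixture(scope="session")
def params():
    return mc.default_params()


@pytest.fixture(scope="session")
def eq(params):
    return mc.default_equilibrium(params)


@pytest.fixture(scope="session", autouse=True)
def _quiet_solver_warnings():
    logging.getLogger("morphocontract.solver").setLevel(logging.ERROR)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)


def random_valid_params(rng, base, N_bar=None):
    """A randomized parameter set that satisfies the positivity invariants
    (log-uniform jitter around the packaged defaults).

    When N_bar is given, delta_N is tied to q through the logistic balance
    so that (0, N_bar, 0, rho_bar, 0, eps_bar) is a genuine equilibrium of
    the kinetics (the premise of the stability theorems).
    """
    factors = {
        name: float(np.exp(rng.uniform(-0.7, 0.7)))
        for name in base.to_dict()
        if name != "q"
    }
    kw = {name: getattr(base, name) * f for name, f in factors.items()}
    kw["q"] = base.q + rng.uniform(-0.2, 0.2)
    # keep the crowding invariant kappa_F * N_bar < 1 for N_bar = 1e4
    kw["kappa_F"] = min(kw["kappa_F"], 0.5e-4)
    if N_bar is not None:
        kw["delta_N"] = mc.derive_delta_N(kw["r_F"], kw["kappa_F"], N_bar,
                                          kw["q"])
    return base.replace(**kw).validate()
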