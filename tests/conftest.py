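import numpy as np
import pytest

import trophicflux as tf
import trophicflux.io as tio


@pytest.fixture
def chain():
    """Plant -> herbivore -> predator with X_herb=2, X_pred=1 (per node)."""
    return tf.fixture_chain()


@pytest.fixture
def chain_solution(chain):
    W = tf.compute_preferences(chain)
    eff = tf.assign_efficiencies(chain)
    losses = chain.node_loss_vector()
    sol = tf.solve_fluxes(chain, W, losses, eff)
    return chain, W, losses, eff, sol


@pytest.fixture
def default_regressions():
    return tio.load_default_metabolic_regressions()


def make_solved_web(seed, config=None, fmr=1.0):
    """Generate a guild web, fill losses, and return everything solvable."""
    web = tf.generate_web(config or tf.GeneratorConfig(seed=seed), seed=seed)
    web = tf.node_losses(web, tio.load_default_metabolic_regressions(), fmr_multiplier=fmr)
    W = tf.compute_preferences(web)
    eff = tf.assign_efficiencies(web)
    losses = web.node_loss_vector()
    return web, W, losses, eff


@pytest.fixture
def solved_web_factory():
    return make_solved_web


# hand-derived chain constants (sequential application of F = (X + L) / e_a)
E_ANIMAL, E_PLANT, E_DETRITUS = 0.906, 0.545, 0.158
F_HERB_PRED = 1.0 / E_ANIMAL
F_PLANT_HERB = (2.0 + F_HERB_PRED) / E_PLANT


@pytest.fixture
def identity_metabolic_regression():
    """ln_x0=0, a=1, E=0: X(M) = M exactly."""
    return tf.MetabolicRegression(key="identity", ln_x0=0.0, mass_exp=1.0)


def rel_diff(a, b):
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    scale = np.maximum(np.abs(b), 1e-300)
    return float(np.max(np.abs(a - b) / scale))
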