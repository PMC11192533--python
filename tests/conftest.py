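import numpy as np
import pytest

import tempoflex as tf


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def exp1_random_session():
    """One simulated Exp-1 random-order session (shared, read-only)."""
    rng = np.random.default_rng(7)
    params = tf.ObserverParams()
    plan = tf.exp1_session_plan("random", rng)
    trials = tf.simulate_discrimination_session(params, plan, rng)
    return plan, params, trials


@pytest.fixture(scope="session")
def exp2_battery():
    """One simulated Exp-2 participant: matched plans, responses, taps."""
    rng = np.random.default_rng(11)
    params = tf.ObserverParams(adapt_rate=0.3)
    disc_plan, tap_plan = tf.exp2_matched_design(rng)
    disc = tf.simulate_discrimination_session(params, disc_plan, rng)
    tap = tf.simulate_paced_tapping_session(params, tap_plan, rng)
    return disc_plan, tap_plan, params, disc, tap
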