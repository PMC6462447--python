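import numpy as np
import pytest

from seqrisk import CPTParams, Condition
from seqrisk import synthetic


def simulate_sessions(params, condition=Condition.MIXED, n_sessions=3,
                      reps_per_pair=6, seed=0, **kwargs):
    """Simulate n sessions on the standard design from one agent."""
    root = np.random.SeedSequence(seed)
    records = []
    for s, stream in enumerate(root.spawn(n_sessions)):
        kids = stream.generate_state(2) % (2**31)
        plan = synthetic.default_plan(condition, reps_per_pair=reps_per_pair,
                                      seed=int(kids[0]))
        records.extend(synthetic.simulate_session(
            plan, params, seed=int(kids[1]),
            session_id=f"{Condition(condition).value.lower()}-{s:03d}",
            **kwargs))
    return records


@pytest.fixture(scope="session")
def linear_agent_records():
    """Three MIXED sessions from a risk-neutral softmax agent (lam=10)."""
    params = CPTParams(family="prelec1", lam=10.0, rho=1.0, alpha=1.0)
    return simulate_sessions(params, n_sessions=3, seed=11)


@pytest.fixture(scope="session")
def distorting_agent_records():
    """Two MIXED sessions from a convex-utility, inverse-S agent."""
    params = CPTParams(family="prelec1", lam=10.0, rho=2.0, alpha=0.67)
    return simulate_sessions(params, n_sessions=2, seed=17)
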