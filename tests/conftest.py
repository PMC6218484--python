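import numpy as np
import pytest

import logicnet as ln


@pytest.fixture(scope="session")
def melanoma():
    net, template = ln.melanoma_fixture()
    return net, template


@pytest.fixture(scope="session")
def melanoma_truth():
    return ln.melanoma_synthetic_truth()


@pytest.fixture
def chain_net():
    """A -> B -> C feed-forward chain with one input."""
    text = """
    node A input
    node B measured
    node C measured
    A -> B kab
    B -> C kbc
    """
    return ln.parse_network(text)


def brute_force_steady_state(net, params, clamps, tol=1e-12, max_iter=20000):
    """Independent fixed-point iterator working directly off the network
    definition (dict-based, no shared code with the simulator)."""
    state = {}
    for n in net.nodes:
        if n.name in clamps:
            state[n.name] = clamps[n.name]
        elif n.constitutive:
            state[n.name] = 1.0
        else:
            state[n.name] = 0.0
    frozen = set(clamps) | {n.name for n in net.nodes if n.constitutive}
    for _ in range(max_iter):
        new = dict(state)
        for n in net.nodes:
            if n.name in frozen:
                continue
            act = 0.0
            inh = 1.0
            for inter in net.interactions:
                if inter.target != n.name:
                    continue
                xs = [state[s] for s in inter.sources]
                if inter.gate == "single":
                    g = xs[0]
                elif inter.gate == "AND":
                    g = float(np.prod(xs))
                else:
                    g = 1.0 - float(np.prod([1.0 - x for x in xs]))
                if inter.sign == "activation":
                    act += params[inter.parameter] * g
                else:
                    inh *= 1.0 - params[inter.parameter] * g
            new[n.name] = min(1.0, max(0.0, act * inh))
        delta = max(abs(new[k] - state[k]) for k in state) if state else 0.0
        state = new
        if delta < tol:
            break
    return state


@pytest.fixture(scope="session")
def brute_force():
    return brute_force_steady_state
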