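import numpy as np
import pandas as pd
import pytest

from revert.network import BooleanNetwork, BooleanRule


@pytest.fixture
def symmetric_toggle() -> BooleanNetwork:
    """A = !B, B = !A: fixed points (0,1), (1,0), one 2-cycle."""
    return BooleanNetwork(("A", "B"), {
        "A": BooleanRule("A", ("B",), (1, 0)),
        "B": BooleanRule("B", ("A",), (1, 0)),
    })


@pytest.fixture
def skewed_toggle() -> BooleanNetwork:
    """A = A & !B (fragile normal pole), B = B | !A (dominant cancer pole)."""
    return BooleanNetwork(("A", "B"), {
        "A": BooleanRule("A", ("A", "B"), (0, 0, 1, 0)),
        "B": BooleanRule("B", ("B", "A"), (1, 0, 1, 1)),
    })


@pytest.fixture
def oscillator() -> BooleanNetwork:
    """A activates B, B inhibits A: a single 4-cycle through all states."""
    return BooleanNetwork(("A", "B"), {
        "A": BooleanRule("A", ("B",), (1, 0)),
        "B": BooleanRule("B", ("A",), (0, 1)),
    })


def truth_agreement(gt, net, binarized) -> float:
    """Fraction of observed cell states on which the inferred rules agree
    with the ground-truth rules, averaged over inferred genes."""
    fracs = []
    for gene in net.genes:
        inferred = net.rules[gene]
        truth = gt.network.rules[gene]
        hits = 0
        for _, row in binarized.iterrows():
            env = row.to_dict()
            if inferred.evaluate(env) == truth.evaluate(env):
                hits += 1
        fracs.append(hits / binarized.shape[0])
    return float(np.mean(fracs))
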