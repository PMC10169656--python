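import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import footprintnet as fn

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_matrix(values: dict[str, list[float]], columns: list[str], kind="proteome",
                loc_prob=None):
    df = pd.DataFrame.from_dict(values, orient="index", columns=columns, dtype=float)
    lp = pd.Series(loc_prob, dtype=float) if loc_prob is not None else None
    return fn.OmicsMatrix(df, kind, lp)


SIX = [f"ITD-JMD.{t}.r{r}" for t in ("treated", "control") for r in (1, 2, 3)]


@pytest.fixture
def small_experiment():
    """A solvable 60-node benchmark with 4 active regulators (shared seed)."""
    net = fn.generate_prior_network(60, 3.0, 0.25, seed=11)
    regulons, reg_sites = fn.generate_regulons(net, 5, seed=12, n_kinase_regulators=10)
    truth = fn.choose_truth(regulons, 4, 1.5, seed=13)
    exp = fn.simulate_experiment(net, regulons, truth, 3, 0.25, 0.1, seed=14,
                                 reg_sites=reg_sites, genotypes=("ITD-JMD",))
    return exp, truth


@pytest.fixture
def random_prior():
    """Factory for random small signed priors with some conflicting-sign pairs."""

    def _make(seed: int, n_nodes: int = 15, p_edge: float = 0.18,
              frac_inhibitory: float = 0.35, phenotype: str = "DNA_damage"):
        rng = np.random.default_rng(seed)
        net = fn.PriorNetwork()
        names = [f"N{i:02d}" for i in range(n_nodes - 1)]
        for n in names:
            net.add_node(n)
        net.add_node(phenotype, phenotype=True)
        for u in names:
            for v in names + [phenotype]:
                if u == v:
                    continue
                if rng.random() < p_edge:
                    sign = -1 if rng.random() < frac_inhibitory else 1
                    net.add_edge(u, v, sign)
                    if rng.random() < 0.08:  # occasional conflicting duplicate
                        net.add_edge(u, v, -sign)
        if net.graph.in_degree(phenotype) == 0:
            net.add_edge(names[0], phenotype, 1)
        return net

    return _make
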