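import numpy as np
import pytest

from ptpdelim import SimulationConfig, parse_newick, simulate_dataset

WORKED_NEWICK = "((A:0.01,B:0.01):1.0,(C:0.02,D:0.02):1.0);"

# exact scores of the worked 4-tip tree, frozen from the closed form
# n·ln(n/Σℓ) − n evaluated by hand and cross-checked by exhaustive
# enumeration: multi = −2 + (2ln100 − 2) + (2ln50 − 2), single = −2 + (4ln(4/0.06) − 4)
WORKED_LOGLIK_MULTI = 11.034386382832476
WORKED_LOGLIK_SINGLE = 10.798820311519709
WORKED_AICC_MULTI = -4.068772765664953


@pytest.fixture
def worked_tree():
    return parse_newick(WORKED_NEWICK)


@pytest.fixture
def six_tip_tree():
    return parse_newick(
        "((A:0.01,B:0.012):1.0,((C:0.02,D:0.018):0.9,(E:0.03,F:0.025):1.1):0.5);"
    )


def random_mixed_tree(seed: int, min_tips: int = 4, max_tips: int = 8):
    """A small simulated tree with heterogeneous rates for oracle tests."""
    rng = np.random.default_rng(seed)
    n_tips = int(rng.integers(min_tips, max_tips + 1))
    n_species = int(rng.integers(1, max(2, n_tips // 2) + 1))
    sizes = _random_composition(rng, n_tips, n_species)
    rates = rng.uniform(10.0, 80.0, size=n_species).tolist()
    cfg = SimulationConfig(
        n_species=n_species,
        tips_per_species=sizes,
        spec_rate=1.0,
        coal_rates=rates,
        seed=int(rng.integers(2**31)),
    )
    return simulate_dataset(cfg)


def _random_composition(rng, total, parts):
    sizes = [1] * parts
    for _ in range(total - parts):
        sizes[int(rng.integers(parts))] += 1
    return sizes
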