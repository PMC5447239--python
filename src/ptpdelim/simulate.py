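"""Synthetic trees with known species structure.

The generator draws branch lengths directly from the model the delimitation
methods assume: a species "backbone" whose edges are i.i.d. exponential
with a slow speciation rate, and one within-species subtree per backbone
leaf whose edges are i.i.d. exponential with that species' (faster)
coalescent rate.  Topologies are uniform random via sequential joins.
Because lengths come straight from the exponential mixture, parameter
recovery exercises the estimators rather than model misspecification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_model import Delimitation, DEFAULT_MINBR
from .dp_delimit import ml_delimit, Model
from .tree_io import Tree, TreeNode, write_newick


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions for one simulated dataset.

    ``coal_rates`` gives one within-species rate per species; a single value
    is recycled.  Rates are in events per expected substitution per site, so
    the mean within-species branch length is 1/rate.
    """

    n_species: int = 4
    tips_per_species: int | Sequence[int] = 4
    spec_rate: float = 1.0
    coal_rates: float | Sequence[float] = 50.0
    seed: int = 0

    def species_sizes(self) -> list[int]:
        if isinstance(self.tips_per_species, int):
            return [self.tips_per_species] * self.n_species
        sizes = list(self.tips_per_species)
        if len(sizes) != self.n_species:
            raise ValueError("tips_per_species length must equal n_species")
        return sizes

    def rates(self) -> list[float]:
        if isinstance(self.coal_rates, (int, float)):
            return [float(self.coal_rates)] * self.n_species
        rates = [float(r) for r in self.coal_rates]
        if len(rates) != self.n_species:
            raise ValueError("coal_rates length must equal n_species")
        return rates

    def validate(self) -> None:
        if self.n_species < 1:
            raise ValueError("need at least one species")
        if any(s < 1 for s in self.species_sizes()):
            raise ValueError("each species needs at least one tip")
        if self.spec_rate <= 0 or any(r <= 0 for r in self.rates()):
            raise ValueError("all rates must be positive")


@dataclass(frozen=True)
class SimulatedDataset:
    tree: Tree
    truth: Delimitation
    spec_rate: float
    coal_rates: list[float]

    def truth_table(self) -> list[tuple[str, str]]:
        """(tip label, species label) rows for the truth sidecar."""
        rows = []
        for i, tips in enumerate(self.truth.species_sets(self.tree)):
            for label in sorted(tips):
                rows.append((label, f"species{i + 1}"))
        return sorted(rows)


def _random_join_topology(leaves: list[TreeNode], rng: np.random.Generator) -> TreeNode:
    """Uniform sequential random joins; lengths are filled in later."""
    pool = list(leaves)
    while len(pool) > 1:
        i, j = sorted(rng.choice(len(pool), size=2, replace=False))
        b = pool.pop(j)
        a = pool.pop(i)
        pool.append(TreeNode(children=[a, b]))
    return pool[0]


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate one tree with known delimitation and rates."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    sizes = config.species_sizes()
    rates = config.rates()

    species_roots: list[TreeNode] = []
    for s, (size, rate) in enumerate(zip(sizes, rates)):
        tips = [
            TreeNode(label=f"sp{s + 1}_t{t + 1}") for t in range(size)
        ]
        sub_root = _random_join_topology(tips, rng)
        # every edge inside the species subtree is coalescent
        for node in _descendants(sub_root):
            node.parent_edge_length = float(rng.exponential(1.0 / rate))
        species_roots.append(sub_root)

    if config.n_species == 1:
        top = species_roots[0]
    else:
        top = _random_join_topology(species_roots, rng)
        # edges between species (including those into the species roots)
        for node in _descendants(top):
            if node.parent_edge_length is None:
                node.parent_edge_length = float(
                    rng.exponential(1.0 / config.spec_rate)
                )
    tree = Tree(top)
    truth = Delimitation(frozenset(n.id for n in species_roots))
    return SimulatedDataset(tree, truth, config.spec_rate, rates)


def _descendants(root: TreeNode) -> list[TreeNode]:
    out: list[TreeNode] = []
    stack = list(root.children)
    while stack:
        n = stack.pop()
        out.append(n)
        stack.extend(n.children)
    return out


def write_dataset(dataset: SimulatedDataset, prefix: str) -> None:
    """Write <prefix>.nwk, <prefix>.truth.tsv and a metadata header."""
    with open(prefix + ".nwk", "w") as fh:
        fh.write(write_newick(dataset.tree) + "\n")
    with open(prefix + ".truth.tsv", "w") as fh:
        fh.write("# simulated truth: tip label -> species label\n")
        fh.write(f"# spec_rate={dataset.spec_rate:g}\n")
        fh.write(
            "# coal_rates=" + ",".join(f"{r:g}" for r in dataset.coal_rates) + "\n"
        )
        for label, species in dataset.truth_table():
            fh.write(f"{label}\t{species}\n")


@dataclass(frozen=True)
class RecoverySummary:
    replicates: int
    exact_recoveries: int
    mean_rate_rel_error: float | None

    @property
    def recovery_fraction(self) -> float:
        return self.exact_recoveries / self.replicates


def recovery_experiment(
    config: SimulationConfig,
    replicates: int,
    method: Model = "multi",
    minbr: float = DEFAULT_MINBR,
) -> RecoverySummary:
    """Simulate → delimit repeatedly; measure exact truth recovery.

    Rate error is the mean relative error |λ̂ − λ|/λ of the per-species
    coalescent rate estimates over exactly recovered replicates (None when
    nothing was recovered).
    """
    exact = 0
    rate_errors: list[float] = []
    for rep in range(replicates):
        cfg = SimulationConfig(
            n_species=config.n_species,
            tips_per_species=config.tips_per_species,
            spec_rate=config.spec_rate,
            coal_rates=config.coal_rates,
            seed=int(np.random.default_rng([config.seed, rep]).integers(2**31)),
        )
        ds = simulate_dataset(cfg)
        result = ml_delimit(ds.tree, method, minbr)
        if result.best.delimitation.coalescent_roots == ds.truth.coalescent_roots:
            exact += 1
            rate_errors.extend(_rate_errors(ds, minbr))
    mean_err = float(np.mean(rate_errors)) if rate_errors else None
    return RecoverySummary(replicates, exact, mean_err)


def _rate_errors(ds: SimulatedDataset, minbr: float) -> list[float]:
    errors = []
    for rid in sorted(ds.truth.coalescent_roots):
        node = ds.tree.nodes[rid]
        # tip labels encode the species index: sp<idx>_t<tip>
        some_tip = next(iter(ds.tree.subtree_tip_labels(node)))
        true_rate = ds.coal_rates[int(some_tip.split("_")[0][2:]) - 1]
        lengths = [
            n.parent_edge_length
            for n in _descendants(node)
            if n.parent_edge_length >= minbr
        ]
        if lengths:
            rate_hat = len(lengths) / sum(lengths)
            errors.append(abs(rate_hat - true_rate) / true_rate)
    return errors
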