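"""Poisson tree process likelihoods and AICc scoring.

A *delimitation* partitions the edges of a rooted binary tree into one
between-species (speciation) process and ``k`` within-species (coalescent)
processes, encoded as the set of *coalescent roots* — the roots of the
maximal subtrees whose internal edges all belong to one species.  The edge
into a coalescent root belongs to the speciation process; a tip may itself
be a coalescent root (a singleton species with no coalescent edges).

Branch lengths within each process are modelled as i.i.d. exponential.  The
single-rate model (PTP) pools all coalescent edges into one exponential; the
multi-rate model (mPTP) fits one exponential per species.  Model fit is
compared with AICc, counting one parameter per fitted rate.

Branches shorter than ``minbr`` (typically produced by identical sequences)
carry no information about either process and are excluded from every fit
and from the AICc sample size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

from .tree_io import Tree, TreeNode

DEFAULT_MINBR = 1e-4

Model = Literal["single", "multi"]


@dataclass(frozen=True)
class Delimitation:
    """A species delimitation: the set of coalescent-root node ids."""

    coalescent_roots: frozenset[int]

    @property
    def n_species(self) -> int:
        return len(self.coalescent_roots)

    def validate(self, tree: Tree) -> None:
        """Check ancestor-freeness and full tip coverage."""
        roots = self.coalescent_roots
        if not roots:
            raise ValueError("delimitation has no coalescent roots")
        for rid in roots:
            if not 0 <= rid < len(tree.nodes):
                raise ValueError(f"node id {rid} not in tree")
        covered = 0
        for rid in roots:
            node = tree.nodes[rid].parent
            while node is not None:
                if node.id in roots:
                    raise ValueError(
                        f"coalescent root {node.id} is an ancestor of {rid}"
                    )
                node = node.parent
            covered += sum(
                1 for n in _subtree_nodes(tree.nodes[rid]) if n.is_tip
            )
        if covered != tree.n_tips:
            raise ValueError(
                f"coalescent subtrees cover {covered} of {tree.n_tips} tips"
            )

    def species_sets(self, tree: Tree) -> list[frozenset[str]]:
        """Tip-label set of each species, in post-order of their roots."""
        return [
            tree.subtree_tip_labels(tree.nodes[rid])
            for rid in sorted(self.coalescent_roots)
        ]

    def is_speciation_node(self, tree: Tree, node: TreeNode) -> bool:
        """Node-level speciation membership as used for support values.

        An inner node belongs to the speciation process iff both of its
        out-edges are speciation edges (it is neither a coalescent root nor
        inside a coalescent subtree); a tip iff it is a singleton species.
        """
        if node.is_tip:
            return node.id in self.coalescent_roots
        if node.id in self.coalescent_roots:
            return False
        up = node.parent
        while up is not None:
            if up.id in self.coalescent_roots:
                return False
            up = up.parent
        return True


def _subtree_nodes(node: TreeNode) -> list[TreeNode]:
    out, stack = [], [node]
    while stack:
        n = stack.pop()
        out.append(n)
        stack.extend(n.children)
    return out


def delimitation_from_tip_groups(
    tree: Tree, groups: list[frozenset[str]] | list[set[str]]
) -> Delimitation:
    """Rebuild a delimitation from species tip sets.

    Each group must be exactly the tip set of one subtree (its coalescent
    root); used to reload delimitations from reports.
    """
    by_tipset: dict[frozenset[str], int] = {
        tree.subtree_tip_labels(n): n.id for n in tree.nodes
    }
    roots = set()
    for group in groups:
        key = frozenset(group)
        if key not in by_tipset:
            raise ValueError(
                f"tip group {sorted(key)} is not a subtree of the tree"
            )
        roots.add(by_tipset[key])
    delim = Delimitation(frozenset(roots))
    delim.validate(tree)
    return delim


def null_delimitation(tree: Tree) -> Delimitation:
    """The single-process model: the root is the only coalescent root."""
    return Delimitation(frozenset({tree.root.id}))


def all_singletons_delimitation(tree: Tree) -> Delimitation:
    """Every tip its own species; every edge a speciation edge."""
    return Delimitation(frozenset(n.id for n in tree.nodes if n.is_tip))


# ---------------------------------------------------------------------------
# exponential fits


@dataclass(frozen=True)
class ExponentialFit:
    """ML fit of an exponential rate to a set of branch lengths.

    rate = n / Σℓ and loglik = n·ln(rate) − n; an empty set contributes a
    likelihood factor of 1 (loglik 0) and no rate parameter.
    """

    n: int
    total_length: float
    rate: float | None
    loglik: float


def exp_loglik(n: int, total_length: float) -> float:
    """Maximized exponential log-likelihood for n branches of summed length."""
    if n == 0:
        return 0.0
    if total_length <= 0.0:
        raise ValueError(
            f"{n} informative branches with zero total length; "
            "the rate estimate is infinite (check minbr)"
        )
    return n * math.log(n / total_length) - n


def ml_exp_fit(lengths: list[float]) -> ExponentialFit:
    """Fit an exponential by maximum likelihood to branch lengths."""
    n = len(lengths)
    total = float(sum(lengths))
    if n == 0:
        return ExponentialFit(0, 0.0, None, 0.0)
    return ExponentialFit(n, total, n / total if total > 0 else None,
                          exp_loglik(n, total))


# ---------------------------------------------------------------------------
# edge classification


def split_edges(
    tree: Tree, delim: Delimitation, minbr: float = DEFAULT_MINBR
) -> tuple[list[float], list[list[float]], int]:
    """Classify every edge as speciation or coalescent-within-one-species.

    Returns ``(speciation_lengths, per_species_lengths, n_ignored)`` where
    only *informative* edges (length ≥ minbr) appear in the length lists and
    ``n_ignored`` counts the excluded short edges.  Every edge of the tree is
    classified exactly once: the edge above a node is a speciation edge iff
    the node is a coalescent root or an ancestor of one, otherwise it belongs
    to the species whose coalescent root is the node's nearest delimiting
    ancestor.
    """
    tree.require_rooted()
    delim.validate(tree)
    roots_sorted = sorted(delim.coalescent_roots)
    root_index = {rid: i for i, rid in enumerate(roots_sorted)}
    # owner[node] = index of the species containing the node's parent edge,
    # or -1 for speciation edges
    owner = [-1] * len(tree.nodes)
    for node in reversed(tree.nodes):  # pre-order
        if node.id in root_index:
            owner[node.id] = -1  # edge into a coalescent root is speciation
            for child in node.children:
                _mark_subtree_owner(child, root_index[node.id], owner)

    spec: list[float] = []
    per_species: list[list[float]] = [[] for _ in roots_sorted]
    n_ignored = 0
    for node in tree.nodes:
        if node.parent is None:
            continue
        length = node.parent_edge_length
        assert length is not None
        if length < minbr:
            n_ignored += 1
            continue
        which = owner[node.id]
        if which < 0:
            spec.append(length)
        else:
            per_species[which].append(length)
    return spec, per_species, n_ignored


def _mark_subtree_owner(node: TreeNode, species: int, owner: list[int]) -> None:
    stack = [node]
    while stack:
        n = stack.pop()
        owner[n.id] = species
        stack.extend(n.children)


# ---------------------------------------------------------------------------
# scored delimitations


@dataclass(frozen=True)
class ScoredDelimitation:
    delimitation: Delimitation
    model: Model
    loglik: float
    n_params: int
    n_obs: int
    aicc: float


def aicc(loglik: float, p: int, n_obs: int) -> float:
    """AICc = −2·lnL + 2p + 2p(p+1)/(n−p−1); +inf when inadmissible."""
    if n_obs - p - 1 <= 0:
        return math.inf
    return -2.0 * loglik + 2.0 * p + 2.0 * p * (p + 1) / (n_obs - p - 1)


def loglik_single(
    tree: Tree, delim: Delimitation, minbr: float = DEFAULT_MINBR
) -> ScoredDelimitation:
    """Single-rate (PTP) score: one exponential for all coalescent edges."""
    spec, per_species, _ = split_edges(tree, delim, minbr)
    pooled = [x for grp in per_species for x in grp]
    ll = exp_loglik(len(spec), sum(spec)) + exp_loglik(len(pooled), sum(pooled))
    p = (1 if spec else 0) + (1 if pooled else 0)
    n_obs = len(spec) + len(pooled)
    return ScoredDelimitation(delim, "single", ll, p, n_obs, aicc(ll, p, n_obs))


def loglik_multi(
    tree: Tree, delim: Delimitation, minbr: float = DEFAULT_MINBR
) -> ScoredDelimitation:
    """Multi-rate (mPTP) score: one exponential per delimited species.

    Species with no informative coalescent edge (singleton tips, or species
    whose edges all fall below minbr) contribute a likelihood factor of 1,
    but every delimited species carries one rate parameter λ_i in the AICc
    dimension — the model posits k rates whether or not the data inform
    them.  Without this, a delimitation of many singletons plus one
    short-branch cherry costs almost nothing and AICc systematically
    over-splits rate-homogeneous trees.
    """
    spec, per_species, _ = split_edges(tree, delim, minbr)
    ll = exp_loglik(len(spec), sum(spec))
    n_obs = len(spec)
    for grp in per_species:
        if grp:
            ll += exp_loglik(len(grp), sum(grp))
            n_obs += len(grp)
    p = (1 if spec else 0) + delim.n_species
    return ScoredDelimitation(delim, "multi", ll, p, n_obs, aicc(ll, p, n_obs))


def score_delimitation(
    tree: Tree, delim: Delimitation, model: Model, minbr: float = DEFAULT_MINBR
) -> ScoredDelimitation:
    if model == "multi":
        return loglik_multi(tree, delim, minbr)
    if model == "single":
        return loglik_single(tree, delim, minbr)
    raise ValueError(f"unknown model {model!r}")
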