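"""Metropolis–Hastings sampling of the delimitation space.

The chain moves through delimitations with two reversible moves chosen with
equal probability: SPLIT picks an inner-node coalescent root uniformly and
promotes it into the speciation process (its children become coalescent
roots); MERGE picks, uniformly, a speciation node whose two children are
both coalescent roots and demotes it, merging the two processes.  With a
uniform prior, a proposal is accepted with probability

    min(1, exp((AICc(θ) − AICc(θ′))/2) · n_fwd/n_rev)

where n_fwd and n_rev are the candidate counts of the chosen move and its
reverse, so the stationary distribution assigns each delimitation a
probability proportional to its Akaike weight exp(−AICc/2).  A move type
drawn with zero candidates is a self-transition.

Per-process coalescent fits depend only on static subtree accumulators of
the process root, so a move updates the score and candidate sets in O(1):
the per-step cost is independent of both the tree size and the number of
steps already taken.  The incrementally maintained score is verified
against a from-scratch recomputation at periodic checkpoints.

Sampled states yield a per-node support value f(u): for an inner node, the
fraction of samples in which both of its out-edges are speciation edges;
for a tip, the fraction in which it is a singleton species.  Convergence
across independent runs is summarized by ASDDSV (mean over inner nodes of
the across-run standard deviation of f) and agreement with the ML solution
by ASV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .core_model import (
    DEFAULT_MINBR,
    Delimitation,
    Model,
    aicc,
    exp_loglik,
    score_delimitation,
)
from .tree_io import Tree, write_newick

StartMode = Literal["random", "ml", "null"]


@dataclass(frozen=True)
class MCMCConfig:
    steps: int = 1_000_000
    burn_in: int | None = None  # default: 10% of steps
    sample_every: int = 1
    runs: int = 10
    seed: int = 42
    start: StartMode = "random"

    @property
    def effective_burn_in(self) -> int:
        return self.steps // 10 if self.burn_in is None else self.burn_in

    def validate(self) -> None:
        if not 0 <= self.effective_burn_in < self.steps:
            raise ValueError("burn_in must be smaller than steps")
        if self.sample_every < 1:
            raise ValueError("sample_every must be >= 1")
        if self.runs < 1:
            raise ValueError("runs must be >= 1")


@dataclass(frozen=True)
class SupportMap:
    """Per-node speciation-process frequencies from one chain."""

    values: np.ndarray  # f(u) indexed by node id
    n_samples: int

    def f(self, node_id: int) -> float:
        return float(self.values[node_id])


@dataclass
class ChainResult:
    support: SupportMap
    trace: np.ndarray  # sampled AICc values
    acceptance_rate: float
    delim_freqs: dict[frozenset[int], float] | None = None
    final: Delimitation | None = None


def random_delimitation(
    tree: Tree, rng: np.random.Generator, p_stop: float = 0.5
) -> Delimitation:
    """Recursive random delimitation: each visited node stops (becomes a
    coalescent root) with probability ``p_stop``, else its children are
    visited; tips always stop."""
    tree.require_rooted()
    roots: set[int] = set()
    stack = [tree.root]
    while stack:
        node = stack.pop()
        if node.is_tip or rng.random() < p_stop:
            roots.add(node.id)
        else:
            stack.extend(node.children)
    return Delimitation(frozenset(roots))


class _Chain:
    """Mutable chain state with O(1) split/merge updates."""

    def __init__(
        self,
        tree: Tree,
        delim: Delimitation,
        method: Model = "multi",
        minbr: float = DEFAULT_MINBR,
    ):
        tree.require_rooted()
        delim.validate(tree)
        self.tree = tree
        self.method = method
        self.minbr = minbr
        nn = len(tree.nodes)
        self.n_nodes = nn
        self.is_tip = np.array([n.is_tip for n in tree.nodes])
        self.children = [
            (n.children[0].id, n.children[1].id) if n.children else None
            for n in tree.nodes
        ]
        self.parent = [n.parent.id if n.parent else -1 for n in tree.nodes]
        # informative parent-edge flag and length per node
        self.edge_inf = [False] * nn
        self.edge_len = [0.0] * nn
        for n in tree.nodes:
            if n.parent is not None:
                self.edge_inf[n.id] = n.parent_edge_length >= minbr
                self.edge_len[n.id] = (
                    n.parent_edge_length if self.edge_inf[n.id] else 0.0
                )
        # static subtree accumulators and per-process log-likelihoods
        self.sub_n = [0] * nn
        self.sub_len = [0.0] * nn
        for n in tree.nodes:
            for c in n.children:
                self.sub_n[n.id] += self.sub_n[c.id] + (1 if self.edge_inf[c.id] else 0)
                self.sub_len[n.id] += self.sub_len[c.id] + self.edge_len[c.id]
        self.sub_ll = [
            exp_loglik(self.sub_n[i], self.sub_len[i]) if self.sub_n[i] else 0.0
            for i in range(nn)
        ]
        self.n_obs = self.sub_n[tree.root.id]
        self._init_state(delim)

    # -- state initialization -------------------------------------------------

    def _init_state(self, delim: Delimitation) -> None:
        self.coal_roots: set[int] = set(delim.coalescent_roots)
        self.split_cands: list[int] = []
        self._split_pos: dict[int, int] = {}
        self.merge_cands: list[int] = []
        self._merge_pos: dict[int, int] = {}
        self.node_state = np.zeros(self.n_nodes, dtype=np.int64)
        self.coal_ll = 0.0
        self.coal_n = 0
        self.coal_len = 0.0
        self.spec_n = 0
        self.spec_len = 0.0

        inside = set()  # nodes strictly inside a coalescent subtree
        for rid in self.coal_roots:
            stack = list(
                c.id for c in self.tree.nodes[rid].children
            )
            while stack:
                nid = stack.pop()
                inside.add(nid)
                stack.extend(c.id for c in self.tree.nodes[nid].children)
            self.coal_ll += self.sub_ll[rid]
            self.coal_n += self.sub_n[rid]
            self.coal_len += self.sub_len[rid]
            if not self.is_tip[rid]:
                self._add(self.split_cands, self._split_pos, rid)
        for node in self.tree.nodes:
            nid = node.id
            if nid in inside:
                continue
            # nid is a coalescent root or a speciation node
            if nid in self.coal_roots:
                if node.is_tip:
                    self.node_state[nid] = 1  # singleton tip
                if node.parent is not None and self.edge_inf[nid]:
                    self.spec_n += 1
                    self.spec_len += self.edge_len[nid]
            else:
                self.node_state[nid] = 1  # inner speciation node
                if node.parent is not None and self.edge_inf[nid]:
                    self.spec_n += 1
                    self.spec_len += self.edge_len[nid]
                v, w = self.children[nid]  # type: ignore[misc]
                if v in self.coal_roots and w in self.coal_roots:
                    self._add(self.merge_cands, self._merge_pos, nid)

    # -- candidate-list bookkeeping ------------------------------------------

    @staticmethod
    def _add(lst: list[int], pos: dict[int, int], x: int) -> None:
        pos[x] = len(lst)
        lst.append(x)

    @staticmethod
    def _remove(lst: list[int], pos: dict[int, int], x: int) -> None:
        i = pos.pop(x)
        last = lst.pop()
        if last != x:
            lst[i] = last
            pos[last] = i

    # -- scoring --------------------------------------------------------------

    def loglik(self) -> float:
        spec_ll = exp_loglik(self.spec_n, self.spec_len) if self.spec_n else 0.0
        if self.method == "multi":
            return self.coal_ll + spec_ll
        coal_ll = exp_loglik(self.coal_n, self.coal_len) if self.coal_n else 0.0
        return coal_ll + spec_ll

    def n_params(self) -> int:
        if self.method == "multi":
            # one rate per delimited species, identifiable or not
            return (1 if self.spec_n else 0) + len(self.coal_roots)
        return (1 if self.spec_n else 0) + (1 if self.coal_n else 0)

    def score(self) -> float:
        return aicc(self.loglik(), self.n_params(), self.n_obs)

    def delimitation(self) -> Delimitation:
        return Delimitation(frozenset(self.coal_roots))

    def check_against_full_rescore(self, tol: float = 1e-9) -> None:
        full = score_delimitation(self.tree, self.delimitation(), self.method, self.minbr)
        inc = self.score()
        if math.isinf(full.aicc) and math.isinf(inc):
            return
        if abs(full.aicc - inc) > tol * max(1.0, abs(full.aicc)):
            raise AssertionError(
                f"incremental AICc {inc} deviates from full rescore {full.aicc}"
            )

    # -- moves ----------------------------------------------------------------

    def apply_split(self, u: int) -> None:
        """Promote coalescent root u into the speciation process."""
        v, w = self.children[u]  # type: ignore[misc]
        self.coal_roots.remove(u)
        self.coal_roots.add(v)
        self.coal_roots.add(w)
        self._remove(self.split_cands, self._split_pos, u)
        for c in (v, w):
            if not self.is_tip[c]:
                self._add(self.split_cands, self._split_pos, c)
        self._add(self.merge_cands, self._merge_pos, u)
        p = self.parent[u]
        if p >= 0 and p in self._merge_pos:
            self._remove(self.merge_cands, self._merge_pos, p)
        # accumulators
        self.coal_ll += self.sub_ll[v] + self.sub_ll[w] - self.sub_ll[u]
        self.coal_n += self.sub_n[v] + self.sub_n[w] - self.sub_n[u]
        self.coal_len += self.sub_len[v] + self.sub_len[w] - self.sub_len[u]
        for c in (v, w):
            if self.edge_inf[c]:
                self.spec_n += 1
                self.spec_len += self.edge_len[c]
        # node-level speciation membership
        self.node_state[u] = 1
        for c in (v, w):
            if self.is_tip[c]:
                self.node_state[c] = 1

    def apply_merge(self, u: int) -> None:
        """Demote speciation node u; its two child processes merge."""
        v, w = self.children[u]  # type: ignore[misc]
        self.coal_roots.add(u)
        self.coal_roots.discard(v)
        self.coal_roots.discard(w)
        self._add(self.split_cands, self._split_pos, u)
        for c in (v, w):
            if not self.is_tip[c]:
                self._remove(self.split_cands, self._split_pos, c)
        self._remove(self.merge_cands, self._merge_pos, u)
        p = self.parent[u]
        if p >= 0:
            pv, pw = self.children[p]  # type: ignore[misc]
            sib = pw if pv == u else pv
            if sib in self.coal_roots and p not in self.coal_roots:
                self._add(self.merge_cands, self._merge_pos, p)
        self.coal_ll += self.sub_ll[u] - self.sub_ll[v] - self.sub_ll[w]
        self.coal_n += self.sub_n[u] - self.sub_n[v] - self.sub_n[w]
        self.coal_len += self.sub_len[u] - self.sub_len[v] - self.sub_len[w]
        for c in (v, w):
            if self.edge_inf[c]:
                self.spec_n -= 1
                self.spec_len -= self.edge_len[c]
        self.node_state[u] = 0
        for c in (v, w):
            if self.is_tip[c]:
                self.node_state[c] = 0


def propose(
    chain: _Chain, rng: np.random.Generator
) -> tuple[Delimitation, float] | None:
    """One proposal for inspection: returns (candidate, log Hastings ratio)
    or None for a self-transition.  The chain state is left unchanged."""
    split = rng.random() < 0.5
    cands = chain.split_cands if split else chain.merge_cands
    if not cands:
        return None
    u = cands[int(rng.random() * len(cands))]
    n_fwd = len(cands)
    if split:
        chain.apply_split(u)
        n_rev = len(chain.merge_cands)
        cand = chain.delimitation()
        chain.apply_merge(u)
    else:
        chain.apply_merge(u)
        n_rev = len(chain.split_cands)
        cand = chain.delimitation()
        chain.apply_split(u)
    return cand, math.log(n_fwd) - math.log(n_rev)


def acceptance_probability(
    current_aicc: float, candidate_aicc: float, log_hastings: float = 0.0
) -> float:
    """min(1, exp((AICc − AICc′)/2) · Hastings) with Akaike-weight scores."""
    if math.isinf(candidate_aicc):
        return 0.0 if not math.isinf(current_aicc) else 1.0
    if math.isinf(current_aicc):
        return 1.0
    log_alpha = (current_aicc - candidate_aicc) / 2.0 + log_hastings
    return min(1.0, math.exp(min(log_alpha, 0.0)))


def run_chain(
    tree: Tree,
    config: MCMCConfig,
    method: Model = "multi",
    minbr: float = DEFAULT_MINBR,
    start_delim: Delimitation | None = None,
    track_delimitations: bool = False,
    check_every: int = 100_000,
) -> ChainResult:
    """Run one chain; deterministic under the config seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    if start_delim is None:
        if config.start == "random":
            start_delim = random_delimitation(tree, rng)
        elif config.start == "null":
            from .core_model import null_delimitation

            start_delim = null_delimitation(tree)
        elif config.start == "ml":
            from .dp_delimit import ml_delimit

            start_delim = ml_delimit(tree, method, minbr).best.delimitation
        else:
            raise ValueError(f"unknown start mode {config.start!r}")
    chain = _Chain(tree, start_delim, method, minbr)
    cur_aicc = chain.score()

    counts = np.zeros(chain.n_nodes, dtype=np.int64)
    n_samples = 0
    trace: list[float] = []
    delim_counts: dict[frozenset[int], int] | None = {} if track_delimitations else None
    accepted = 0
    proposed = 0
    burn_in = config.effective_burn_in
    sample_every = config.sample_every

    # hot loop: draw randomness in blocks to amortize generator overhead
    block = 1 << 15
    u01 = rng.random(3 * block)
    bi = 0
    for step in range(config.steps):
        if bi >= 3 * block - 3:
            u01 = rng.random(3 * block)
            bi = 0
        split = u01[bi] < 0.5
        bi += 1
        cands = chain.split_cands if split else chain.merge_cands
        n_fwd = len(cands)
        if n_fwd:
            proposed += 1
            u = cands[int(u01[bi] * n_fwd)]
            bi += 1
            if split:
                chain.apply_split(u)
                n_rev = len(chain.merge_cands)
            else:
                chain.apply_merge(u)
                n_rev = len(chain.split_cands)
            new_aicc = chain.score()
            if math.isinf(new_aicc):
                accept = math.isinf(cur_aicc)
            else:
                log_alpha = (cur_aicc - new_aicc) / 2.0 + math.log(n_fwd / n_rev)
                accept = log_alpha >= 0.0 or u01[bi] < math.exp(log_alpha)
            bi += 1
            if accept:
                cur_aicc = new_aicc
                accepted += 1
            else:
                if split:
                    chain.apply_merge(u)
                else:
                    chain.apply_split(u)
        if step >= burn_in and (step - burn_in) % sample_every == 0:
            counts += chain.node_state
            n_samples += 1
            trace.append(cur_aicc)
            if delim_counts is not None:
                key = frozenset(chain.coal_roots)
                delim_counts[key] = delim_counts.get(key, 0) + 1
        if check_every and (step + 1) % check_every == 0:
            chain.check_against_full_rescore()

    chain.check_against_full_rescore()
    support = SupportMap(counts / max(n_samples, 1), n_samples)
    freqs = (
        {k: v / n_samples for k, v in delim_counts.items()}
        if delim_counts is not None
        else None
    )
    return ChainResult(
        support=support,
        trace=np.asarray(trace),
        acceptance_rate=accepted / proposed if proposed else 0.0,
        delim_freqs=freqs,
        final=chain.delimitation(),
    )


# ---------------------------------------------------------------------------
# diagnostics


def asddsv(support_maps: list[SupportMap], tree: Tree) -> float:
    """Mean over inner nodes of the across-run sample SD of f(u)."""
    if len(support_maps) < 2:
        raise ValueError("ASDDSV needs at least two independent runs")
    inner = [n.id for n in tree.nodes if not n.is_tip]
    mat = np.stack([m.values[inner] for m in support_maps])
    return float(np.mean(np.std(mat, axis=0, ddof=1)))


def asv(support: SupportMap, ml: Delimitation, tree: Tree) -> float:
    """Agreement between sampled supports and the ML delimitation.

    Averages f(u) over the ML delimitation's singleton tips and 1 − f(u)
    over its inner coalescent roots; 1 means perfect agreement.
    """
    terms: list[float] = []
    for rid in ml.coalescent_roots:
        if tree.nodes[rid].is_tip:
            terms.append(support.f(rid))
        else:
            terms.append(1.0 - support.f(rid))
    return float(np.mean(terms))


@dataclass(frozen=True)
class MCMCReport:
    per_run_asv: list[float]
    mean_asv: float
    asddsv_value: float | None
    mean_support: SupportMap
    acceptance_rates: list[float]
    ml_delimitation: Delimitation
    annotated_newick: str


def combine_runs(
    tree: Tree,
    config: MCMCConfig,
    method: Model = "multi",
    minbr: float = DEFAULT_MINBR,
    ml: Delimitation | None = None,
) -> MCMCReport:
    """Run ``config.runs`` independent chains and aggregate diagnostics.

    Per-run seeds are spawned deterministically from the master seed; each
    run starts from its own random delimitation.  The mean per-node supports
    are emitted as inner-node labels on an annotated newick string.
    """
    config.validate()
    if ml is None:
        from .dp_delimit import ml_delimit

        ml = ml_delimit(tree, method, minbr).best.delimitation
    seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(config.seed).spawn(config.runs)
    ]
    results = []
    for seed in seeds:
        run_cfg = MCMCConfig(
            steps=config.steps,
            burn_in=config.burn_in,
            sample_every=config.sample_every,
            runs=1,
            seed=seed,
            start=config.start,
        )
        results.append(run_chain(tree, run_cfg, method, minbr))
    maps = [r.support for r in results]
    per_run_asv = [asv(m, ml, tree) for m in maps]
    mean_vals = np.mean(np.stack([m.values for m in maps]), axis=0)
    mean_map = SupportMap(mean_vals, sum(m.n_samples for m in maps))
    annotations = {
        n.id: float(mean_vals[n.id]) for n in tree.nodes if not n.is_tip
    }
    return MCMCReport(
        per_run_asv=per_run_asv,
        mean_asv=float(np.mean(per_run_asv)),
        asddsv_value=asddsv(maps, tree) if config.runs >= 2 else None,
        mean_support=mean_map,
        acceptance_rates=[r.acceptance_rate for r in results],
        ml_delimitation=ml,
        annotated_newick=write_newick(tree, annotations),
    )
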