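"""Comparison of an inferred delimitation against a reference partition.

Precision and recall use the pairwise (Rand-style) operationalization:
precision is the fraction of co-clustered tip pairs that are conspecific in
the reference, recall the fraction of conspecific pairs that were
co-clustered; F is their harmonic mean.  This symmetric counting penalizes
both over-splitting and lumping.  RTS counts reference species whose tip
set is recovered exactly as one inferred group.  The likelihood-ratio test
compares the single-rate model nested inside the multi-rate model on one
fixed delimitation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import TextIO

from scipy.stats import chi2

from .core_model import Delimitation, ScoredDelimitation
from .tree_io import Tree


@dataclass(frozen=True)
class ReferencePartition:
    """tip label -> species label."""

    mapping: dict[str, str]

    def groups(self) -> list[frozenset[str]]:
        by_species: dict[str, set[str]] = {}
        for tip, sp in self.mapping.items():
            by_species.setdefault(sp, set()).add(tip)
        return [frozenset(v) for v in by_species.values()]

    @classmethod
    def from_tsv(cls, handle: TextIO) -> "ReferencePartition":
        """Two tab-separated columns (tip, species); '#' comments allowed."""
        mapping: dict[str, str] = {}
        for lineno, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"line {lineno}: expected two tab-separated columns"
                )
            tip, sp = parts
            if tip in mapping:
                raise ValueError(f"line {lineno}: duplicate tip {tip!r}")
            mapping[tip] = sp
        return cls(mapping)


def _check_tip_sets(pred_tips: set[str], ref_tips: set[str]) -> None:
    if pred_tips != ref_tips:
        diff = sorted(pred_tips.symmetric_difference(ref_tips))
        raise ValueError(f"tip sets differ; symmetric difference: {diff}")


def _pairs(groups: list[frozenset[str]]) -> set[frozenset[str]]:
    out: set[frozenset[str]] = set()
    for g in groups:
        out.update(frozenset(p) for p in combinations(sorted(g), 2))
    return out


def precision_recall_f(
    pred: Delimitation | list[frozenset[str]],
    ref: ReferencePartition,
    tree: Tree | None = None,
) -> tuple[float, float, float]:
    """Pairwise precision, recall and F between predicted and reference.

    0/0 conventions: a partition with no co-clustered pairs compared against
    another with none gives P = R = 1; F is 0 when P = R = 0.
    """
    pred_groups = _as_groups(pred, tree)
    ref_groups = ref.groups()
    _check_tip_sets(
        {t for g in pred_groups for t in g}, {t for g in ref_groups for t in g}
    )
    pred_pairs = _pairs(pred_groups)
    ref_pairs = _pairs(ref_groups)
    both = len(pred_pairs & ref_pairs)
    precision = both / len(pred_pairs) if pred_pairs else 1.0
    recall = both / len(ref_pairs) if ref_pairs else 1.0
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f


def rts(
    pred: Delimitation | list[frozenset[str]],
    ref: ReferencePartition,
    tree: Tree | None = None,
) -> tuple[int, float]:
    """Recovered taxonomic species: exact tip-set matches, and percentage."""
    pred_groups = set(_as_groups(pred, tree))
    ref_groups = ref.groups()
    _check_tip_sets(
        {t for g in pred_groups for t in g}, {t for g in ref_groups for t in g}
    )
    matched = sum(1 for g in ref_groups if g in pred_groups)
    return matched, 100.0 * matched / len(ref_groups)


def _as_groups(
    pred: Delimitation | list[frozenset[str]], tree: Tree | None
) -> list[frozenset[str]]:
    if isinstance(pred, Delimitation):
        if tree is None:
            raise ValueError("a tree is required to expand a Delimitation")
        return pred.species_sets(tree)
    return list(pred)


@dataclass(frozen=True)
class LRTResult:
    statistic: float
    df: int
    p_value: float | None  # None when df = 0 (k = 1: models coincide)


def lrt_nested(single: ScoredDelimitation, multi: ScoredDelimitation) -> LRTResult:
    """LRT of the multi-rate model against the nested single-rate model.

    Both scores must be computed on the identical delimitation; the statistic
    is 2·ΔlnL with df equal to the difference in fitted rate counts.
    """
    if single.delimitation.coalescent_roots != multi.delimitation.coalescent_roots:
        raise ValueError("LRT requires identical delimitations for both models")
    if multi.loglik < single.loglik - 1e-9:
        raise ValueError("multi-rate log-likelihood below single-rate: not nested")
    statistic = max(0.0, 2.0 * (multi.loglik - single.loglik))
    df = multi.n_params - single.n_params
    p = float(chi2.sf(statistic, df)) if df > 0 else None
    return LRTResult(statistic, df, p)
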