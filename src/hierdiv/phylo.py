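"""Phylogenetic diversity (q = 1) on a rooted tree and its decomposition.

Abundance diversity treats all elements as equally distinct.  When a
rooted phylogeny connecting the elements is available, each branch
segment ``i`` with length ``L_i`` carries the summed relative abundance
``a_i`` of the tips descended from it, and diversity generalises to

    qPD = ( sum_i L_i (a_i / T)**q ) ** (1 / (1 - q)),

the effective total branch length per unit time back to a fixed reference
point (the root age by default).  ``0PD`` is Faith's PD (summed branch
lengths of the lineages present); ``1PD = T exp(I / T)`` where
``I = -sum_i L_i a_i ln a_i`` is the phylogenetic entropy; ``2PD`` is a
transform of Rao's quadratic entropy, ``2PD = T / (1 - Q/T)``.  For a
tips-only tree with unit branch lengths the whole family collapses to the
ordinary Hill numbers.

The hierarchical decomposition mirrors the abundance one with entropy
``H`` replaced by ``I/T``: ``PD_alpha(l) = T exp(I_alpha(l) / T)`` with
``I_alpha(l)`` the weighted mean phylogenetic entropy of the level's
pooled branch abundances, and the beta chain and differentiation follow
unchanged.  Non-ultrametric trees use the abundance-weighted mean branch
length ``T_bar = sum_i L_i a_i`` (from system-level pooled abundances) as
the reference, so the chain stays multiplicative across levels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from collections.abc import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .diversity import ValidationError, validate_abundances
from .partition import (
    AbundanceTable,
    HierarchySpec,
    LevelDecomposition,
    _DEGENERATE_TOL,
    compute_weights,
    level_alpha_entropy,  # noqa: F401  (re-exported convenience)
    pooled_frequencies,
    weight_entropy_normalizer,
)

__all__ = [
    "PhyloTreeModel",
    "BranchAbundanceSet",
    "branch_abundances",
    "mean_branch_length",
    "phylo_entropy",
    "qPD",
    "decompose_phylo",
]

logger = logging.getLogger(__name__)

_ULTRAMETRIC_RTOL = 1e-6


@dataclass
class BranchAbundanceSet:
    """Branch lengths paired with descendant-summed relative abundances."""

    lengths: np.ndarray  # L_i, shape (B,)
    abundances: np.ndarray  # a_i in [0, 1], shape (B,)

    def __post_init__(self):
        self.lengths = np.asarray(self.lengths, float)
        self.abundances = np.asarray(self.abundances, float)
        if self.lengths.shape != self.abundances.shape:
            raise ValidationError("lengths and abundances must align")
        if (self.lengths < 0).any():
            raise ValidationError("negative branch length")
        if ((self.abundances < -1e-12) | (self.abundances > 1 + 1e-12)).any():
            raise ValidationError("branch abundance outside [0, 1]")
        self.abundances = np.clip(self.abundances, 0.0, 1.0)


class PhyloTreeModel:
    """Rooted tree prepared for branch-abundance computations.

    Wraps a dendropy tree; exposes branch lengths, a branch-by-tip
    incidence matrix (branch ancestral to tip) so that branch abundances
    are a single matrix-vector product, and root-to-tip depths for the
    ultrametricity check.
    """

    def __init__(self, tree: dendropy.Tree):
        tree = tree.clone(depth=1)
        tree.is_rooted = True
        self._tree = tree
        tips = tree.leaf_nodes()
        labels = [t.taxon.label if t.taxon is not None else None for t in tips]
        if any(lbl is None for lbl in labels):
            raise ValidationError("every tip must carry a label")
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise ValidationError(f"duplicate tip labels: {dup}")
        self.tip_labels = labels
        tip_index = {id(t): i for i, t in enumerate(tips)}
        lengths, incidence, node_depth = [], [], {}
        node_depth[id(tree.seed_node)] = float(tree.seed_node.edge.length or 0.0)
        branches = []
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                if (tree.seed_node.edge.length or 0.0) > 0:
                    branches.append(node)  # explicit root edge
                continue
            node_depth[id(node)] = node_depth[id(node.parent_node)] + float(
                node.edge.length if node.edge.length is not None else _raise_no_length(node)
            )
            branches.append(node)
        S = len(tips)
        inc = np.zeros((len(branches), S), dtype=float)
        for b, node in enumerate(branches):
            lengths.append(float(node.edge.length or 0.0))
            for leaf in node.leaf_iter():
                inc[b, tip_index[id(leaf)]] = 1.0
        self.lengths = np.asarray(lengths, float)
        self.incidence = inc
        self.tip_depths = np.array([node_depth[id(t)] for t in tips])
        depth_max = float(self.tip_depths.max())
        spread = float(self.tip_depths.max() - self.tip_depths.min())
        self.is_ultrametric = spread <= _ULTRAMETRIC_RTOL * max(depth_max, 1.0)
        self.depth = depth_max

    @classmethod
    def from_newick(cls, source: str, *, is_path: bool | None = None) -> "PhyloTreeModel":
        """Parse a Newick tree (quoted or unquoted labels, polytomies fine)."""
        if is_path is None:
            is_path = not source.lstrip().startswith("(")
        kw = {"path": source} if is_path else {"data": source}
        try:
            tree = dendropy.Tree.get(
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
                **kw,
            )
        except Exception as exc:
            raise ValidationError(f"invalid Newick tree: {exc}") from exc
        return cls(tree)

    @property
    def n_branches(self) -> int:
        return len(self.lengths)

    def graft_root_edge(self, extra: float) -> "PhyloTreeModel":
        """Move the reference point ``extra`` units older than the root."""
        if extra < 0:
            raise ValidationError("root-edge extension must be >= 0")
        tree = self._tree.clone(depth=1)
        tree.seed_node.edge.length = float(tree.seed_node.edge.length or 0.0) + extra
        return PhyloTreeModel(tree)

    def abundance_vector(self, p: Mapping[str, float] | Sequence[float]) -> np.ndarray:
        """Align tip frequencies with the internal tip order."""
        if isinstance(p, Mapping):
            missing = [k for k, v in p.items() if v > 0 and k not in self.tip_labels]
            if missing:
                raise ValidationError(f"elements absent from the tree: {sorted(missing)}")
            vec = np.array([float(p.get(lbl, 0.0)) for lbl in self.tip_labels])
        else:
            vec = np.asarray(p, float)
            if vec.shape != (len(self.tip_labels),):
                raise ValidationError(
                    f"expected {len(self.tip_labels)} tip frequencies, got {vec.shape}"
                )
        return validate_abundances(vec)


def _raise_no_length(node) -> float:
    raise ValidationError(
        f"branch above {node.taxon.label if node.taxon else 'an internal node'} "
        "has no length"
    )


def branch_abundances(
    tree: PhyloTreeModel, p: Mapping[str, float] | Sequence[float]
) -> BranchAbundanceSet:
    """Expand tip frequencies to all branches (descendant sums)."""
    vec = tree.abundance_vector(p)
    return BranchAbundanceSet(tree.lengths, tree.incidence @ vec)


def mean_branch_length(b: BranchAbundanceSet) -> float:
    """Abundance-weighted mean root-to-tip distance ``T_bar = sum L_i a_i``."""
    return float((b.lengths * b.abundances).sum())


def phylo_entropy(b: BranchAbundanceSet) -> float:
    """Phylogenetic entropy ``I = -sum L_i a_i ln a_i`` (0 ln 0 = 0)."""
    a, L = b.abundances, b.lengths
    mask = a > 0
    return float(-(L[mask] * a[mask] * np.log(a[mask])).sum())


def qPD(b: BranchAbundanceSet, q: float, reference: float) -> float:
    """Phylogenetic Hill number of order ``q`` for reference duration ``T``.

    ``q = 0`` sums the lengths of branches actually present (``a_i > 0``,
    Faith's PD); other orders weight branches by ``(a_i / T)``.
    """
    if reference <= 0:
        raise ValidationError(f"reference duration must be > 0, got {reference}")
    if q < 0:
        raise ValidationError(f"order q must be >= 0, got {q}")
    a, L = b.abundances, b.lengths
    present = a > 0
    if q == 0:
        return float(L[present].sum())
    if abs(q - 1.0) < 1e-10:
        return float(reference * np.exp(phylo_entropy(b) / reference))
    s = float((L[present] * (a[present] / reference) ** q).sum())
    return float(s ** (1.0 / (1.0 - q)))


def _level_phylo_entropy(
    table: AbundanceTable,
    hierarchy: HierarchySpec,
    weights: pd.Series,
    tree: PhyloTreeModel,
    tip_order: np.ndarray,
    level: int,
) -> float:
    """Weighted mean phylogenetic entropy over level-l pooled aggregates."""
    total = 0.0
    for agg, members in hierarchy.groups_at(level).items():
        w_agg = float(weights.loc[members].sum())
        if w_agg <= 0:
            continue
        p = pooled_frequencies(table, weights, members)
        vec = np.zeros(len(tree.tip_labels))
        np.add.at(vec, tip_order, p)
        total += w_agg * phylo_entropy(BranchAbundanceSet(tree.lengths, tree.incidence @ vec))
    return total


def decompose_phylo(
    table: AbundanceTable,
    hierarchy: HierarchySpec,
    tree: PhyloTreeModel,
    *,
    equal_weights: bool = False,
) -> LevelDecomposition:
    """Hierarchical PD decomposition sharing one reference duration.

    The reference is the root age for ultrametric trees; otherwise the
    mean branch length of the system-level pooled abundances, reused at
    every level so that ``PD_gamma = PD_alpha(1) * prod PD_beta(l)``
    remains exact.  Differentiation divides the entropy gap by
    ``T * W(l)`` with the same weight-entropy ceiling as the abundance
    decomposition.
    """
    missing = [e for e in table.elements if e not in tree.tip_labels]
    if missing:
        raise ValidationError(f"elements absent from the tree: {missing}")
    if set(table.units) != set(hierarchy.units):
        raise ValidationError("table and hierarchy unit sets differ")
    tip_pos = {lbl: i for i, lbl in enumerate(tree.tip_labels)}
    tip_order = np.array([tip_pos[e] for e in table.elements])
    weights = compute_weights(table, equal=equal_weights)

    if tree.is_ultrametric:
        T = tree.depth
    else:
        p_sys = pooled_frequencies(table, weights, table.units)
        vec = np.zeros(len(tree.tip_labels))
        np.add.at(vec, tip_order, p_sys)
        T = mean_branch_length(BranchAbundanceSet(tree.lengths, tree.incidence @ vec))
        logger.info("non-ultrametric tree: using mean branch length T_bar = %.6g", T)
    if T <= 0:
        raise ValidationError("reference duration is zero (empty tree?)")

    n = hierarchy.n_levels
    i_alpha = np.array(
        [
            _level_phylo_entropy(table, hierarchy, weights, tree, tip_order, l)
            for l in range(1, n + 1)
        ]
    )
    h_equiv = i_alpha / T  # entropy-scale values; exp gives PD/T
    pd_alpha = T * np.exp(h_equiv)
    gaps = np.clip(np.diff(h_equiv), 0.0, None)
    gaps[gaps <= _DEGENERATE_TOL] = 0.0
    pd_beta = np.exp(gaps)
    total_gap = float(h_equiv[-1] - h_equiv[0])
    degenerate = total_gap <= _DEGENERATE_TOL
    shares = np.zeros(n - 1) if degenerate else gaps / total_gap
    delta = np.zeros(n - 1)
    for l in range(1, n):
        w_norm = weight_entropy_normalizer(hierarchy, weights, l)
        delta[l - 1] = 0.0 if w_norm <= 0 else float(np.clip(gaps[l - 1] / w_norm, 0.0, 1.0))
    return LevelDecomposition(
        level_names=list(hierarchy.level_names),
        h_alpha=i_alpha,
        d_alpha=pd_alpha,
        d_beta=pd_beta,
        differentiation=delta,
        beta_info_share=shares,
        d_gamma=float(pd_alpha[-1]),
        no_beta_information=degenerate,
    )
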