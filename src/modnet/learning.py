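"""Module-network structure learning by hard EM.

A module network is the triple (C, τ, A): a module set, a regulation tree
per module, and a gene -> module assignment. The M-step relearns each
module's regulation tree by greedy recursive induction over candidate
modulator splits scored with the Normal-Gamma marginal likelihood; the
E-step visits genes in seeded random order and moves each to the module
whose (fixed) tree scores it best. Iteration stops when fewer than
``em_reassign_tol`` of the genes move in a pass.

Because moves are applied with the trees held fixed and only taken when the
gene's score does not decrease, the total log score is non-decreasing across
every E-step — exactly, not up to tolerance (totals are accumulated with
``math.fsum``).

A modulator that is a member of a module (as a target) never appears as a
split in that module's own tree, which rules out trivial self-explanation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .config import Config
from .module_init import ModuleAssignment, NGParams, ng_scores_from_moments

__all__ = [
    "LearningData",
    "TreeNode",
    "RegulationTree",
    "ModuleNetwork",
    "learn_regulation_tree",
    "module_score_of_gene",
    "em_step",
    "learn_module_network",
    "network_to_json",
]


@dataclass
class LearningData:
    """Arrays the learner operates on, shared by every module.

    ``Y``: target-gene expression (genes x samples, centered per gene when
    the pipeline's centering switch is on). ``mod_expr``: modulator
    expression on the same samples; ``thresholds``: each modulator's fitted
    k-means split value.
    """

    Y: np.ndarray
    genes: List[str]
    mod_expr: np.ndarray
    mod_ids: List[str]
    thresholds: np.ndarray

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        self.mod_expr = np.asarray(self.mod_expr, dtype=float)
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if self.Y.shape[0] != len(self.genes):
            raise ValueError("Y rows must match gene list")
        if self.mod_expr.shape[0] != len(self.mod_ids):
            raise ValueError("mod_expr rows must match modulator list")
        if self.Y.shape[1] != self.mod_expr.shape[1]:
            raise ValueError("target and modulator matrices must share samples")
        if len(self.mod_ids) != len(set(self.mod_ids)):
            raise ValueError("duplicate modulator ids")

    @property
    def n_samples(self) -> int:
        return self.Y.shape[1]

    def gene_index(self) -> Dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}


@dataclass
class TreeNode:
    """Internal node (modulator + threshold) or leaf (samples only)."""

    samples: np.ndarray
    modulator: Optional[str] = None
    threshold: Optional[float] = None
    left: Optional["TreeNode"] = None  # modulator expression < threshold
    right: Optional["TreeNode"] = None

    @property
    def is_leaf(self) -> bool:
        return self.modulator is None


@dataclass
class RegulationTree:
    """Decision tree over modulator expression partitioning the samples."""

    root: TreeNode
    params: NGParams

    def leaves(self) -> List[TreeNode]:
        out: List[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node)
            else:
                stack.extend([node.right, node.left])
        return out

    def leaf_sample_sets(self) -> List[np.ndarray]:
        return [leaf.samples for leaf in self.leaves()]

    def used_modulators(self) -> Set[str]:
        out: Set[str] = set()
        stack = [self.root]
        while stack:
            node = stack.pop()
            if not node.is_leaf:
                out.add(node.modulator)
                stack.extend([node.right, node.left])
        return out

    def depth(self) -> int:
        def _d(node: TreeNode) -> int:
            if node.is_leaf:
                return 0
            return 1 + max(_d(node.left), _d(node.right))

        return _d(self.root)

    def score_genes(self, Y: np.ndarray) -> np.ndarray:
        """Sum over leaves of the Normal-Gamma score of each gene's values."""
        total = np.zeros(Y.shape[0])
        for idx in self.leaf_sample_sets():
            sub = Y[:, idx]
            total += ng_scores_from_moments(
                idx.size, sub.sum(axis=1), (sub**2).sum(axis=1), self.params
            )
        return total

    def to_dict(self) -> dict:
        def _node(node: TreeNode) -> dict:
            if node.is_leaf:
                return {"samples": node.samples.tolist()}
            return {
                "modulator": node.modulator,
                "threshold": node.threshold,
                "left": _node(node.left),
                "right": _node(node.right),
            }

        return _node(self.root)


def _best_split(
    Ysub: np.ndarray,
    data: LearningData,
    idx: np.ndarray,
    allowed: Sequence[int],
    cfg: Config,
    params: NGParams,
) -> Optional[Tuple[str, float, np.ndarray, np.ndarray, float]]:
    """Best (modulator, threshold) split of node samples ``idx``.

    Candidates per modulator are the distinct midpoints of its sorted
    expression within the node plus its fitted global threshold, restricted
    to partitions leaving both children with >= min_leaf_size samples. The
    split penalty defaults to ln of the number of candidate pairs evaluated.
    Returns None when no split has positive penalized gain.
    """
    n = idx.size
    base = ng_scores_from_moments(
        n, Ysub.sum(axis=1), (Ysub**2).sum(axis=1), params
    ).sum()
    best_gain = -np.inf
    best: Optional[Tuple[str, float, np.ndarray, np.ndarray]] = None
    total_candidates = 0
    for mi in sorted(allowed, key=lambda i: data.mod_ids[i]):
        e = data.mod_expr[mi, idx]
        order = np.argsort(e, kind="stable")
        es = e[order]
        Yo = Ysub[:, order]
        c1 = np.cumsum(Yo, axis=1)
        c2 = np.cumsum(Yo**2, axis=1)
        tot1, tot2 = c1[:, -1], c2[:, -1]
        lo, hi = cfg.min_leaf_size, n - cfg.min_leaf_size
        if lo > hi:
            continue
        ks = np.arange(lo, hi + 1)
        distinct = es[ks - 1] < es[ks]
        k_fit = int(np.searchsorted(es, data.thresholds[mi]))
        positions: List[Tuple[int, float]] = [
            (int(k), 0.5 * (es[k - 1] + es[k])) for k in ks[distinct]
        ]
        if lo <= k_fit <= hi and es[k_fit - 1] <= data.thresholds[mi]:
            positions.append((k_fit, float(data.thresholds[mi])))
        if not positions:
            continue
        total_candidates += len(positions)
        k_arr = np.array([k for k, _ in positions])
        left = ng_scores_from_moments(
            k_arr[None, :], c1[:, k_arr - 1], c2[:, k_arr - 1], params
        )
        right = ng_scores_from_moments(
            (n - k_arr)[None, :],
            tot1[:, None] - c1[:, k_arr - 1],
            tot2[:, None] - c2[:, k_arr - 1],
            params,
        )
        raw = (left + right).sum(axis=0) - base
        j = int(np.argmax(raw))
        if raw[j] > best_gain:
            best_gain = float(raw[j])
            k, thr = positions[j]
            best = (data.mod_ids[mi], thr, idx[order[:k]], idx[order[k:]])
    if best is None:
        return None
    penalty = (
        cfg.split_penalty
        if cfg.split_penalty is not None
        else math.log(total_candidates)
    )
    gain = best_gain - penalty
    if gain <= 0:
        return None
    mod, thr, left_idx, right_idx = best
    return mod, thr, np.sort(left_idx), np.sort(right_idx), gain


def learn_regulation_tree(
    data: LearningData,
    member_rows: Sequence[int],
    allowed_mods: Sequence[int],
    cfg: Config,
    params: NGParams,
    sample_idx: Optional[np.ndarray] = None,
) -> RegulationTree:
    """Greedy recursive induction of one module's regulation tree.

    ``member_rows`` index the module's genes in ``data.Y``; ``allowed_mods``
    index the modulators eligible as splits (the caller excludes modulators
    that are members of this module). A split is accepted only if its gain
    after the penalty is strictly positive; recursion stops at
    ``max_tree_depth``.
    """
    member_rows = np.asarray(list(member_rows), dtype=int)
    if member_rows.size == 0:
        raise ValueError("cannot learn a tree for an empty module")
    if sample_idx is None:
        sample_idx = np.arange(data.n_samples)

    def build(idx: np.ndarray, depth: int) -> TreeNode:
        if depth >= cfg.max_tree_depth or idx.size < 2 * cfg.min_leaf_size:
            return TreeNode(samples=idx)
        found = _best_split(
            data.Y[np.ix_(member_rows, idx)], data, idx, allowed_mods, cfg, params
        )
        if found is None:
            return TreeNode(samples=idx)
        mod, thr, left_idx, right_idx, _ = found
        return TreeNode(
            samples=idx,
            modulator=mod,
            threshold=thr,
            left=build(left_idx, depth + 1),
            right=build(right_idx, depth + 1),
        )

    return RegulationTree(root=build(np.sort(sample_idx), 0), params=params)


def module_score_of_gene(
    gene_values: np.ndarray, tree: RegulationTree
) -> float:
    """Sum over tree leaves of the gene's Normal-Gamma score on leaf samples."""
    values = np.asarray(gene_values, dtype=float)
    covered = np.concatenate(tree.leaf_sample_sets())
    if covered.size != values.size or len(np.unique(covered)) != covered.size:
        raise ValueError("tree leaves do not partition the gene's samples")
    return float(tree.score_genes(values[None, :])[0])


@dataclass
class ModuleNetwork:
    """(C, τ, A): modules, regulation trees and the gene assignment."""

    modules: Dict[str, List[str]]
    trees: Dict[str, RegulationTree]
    assignment: Dict[str, str]
    total_log_score: float
    score_history: List[Tuple[float, float]] = field(default_factory=list)
    # (score after M-step, score after E-step) per iteration

    def split_modulators(self) -> Set[str]:
        out: Set[str] = set()
        for tree in self.trees.values():
            out |= tree.used_modulators()
        return out

    def validate(self) -> None:
        for mid, members in self.modules.items():
            used = self.trees[mid].used_modulators()
            overlap = used & set(members)
            if overlap:
                raise ValueError(
                    f"module {mid} splits on its own members: {sorted(overlap)}"
                )


def _network_from_assignment(
    assignment: Dict[str, str],
    data: LearningData,
    cfg: Config,
    params: NGParams,
) -> Tuple[Dict[str, List[str]], Dict[str, RegulationTree]]:
    """M-step: relearn every module's tree, excluding member modulators."""
    modules: Dict[str, List[str]] = {}
    for gene, mid in assignment.items():
        modules.setdefault(mid, []).append(gene)
    modules = {mid: sorted(g) for mid, g in sorted(modules.items())}
    gene_idx = data.gene_index()
    trees: Dict[str, RegulationTree] = {}
    for mid, members in modules.items():
        member_set = set(members)
        allowed = [i for i, m in enumerate(data.mod_ids) if m not in member_set]
        rows = [gene_idx[g] for g in members]
        trees[mid] = learn_regulation_tree(data, rows, allowed, cfg, params)
    return modules, trees


def _score_matrix(
    trees: Dict[str, RegulationTree], data: LearningData
) -> Tuple[List[str], np.ndarray]:
    mids = sorted(trees)
    S = np.vstack([trees[mid].score_genes(data.Y) for mid in mids])
    return mids, S


def _total_score(
    assignment: Dict[str, str],
    mids: List[str],
    S: np.ndarray,
    data: LearningData,
) -> float:
    pos = {m: i for i, m in enumerate(mids)}
    return math.fsum(
        S[pos[assignment[g]], gi] for gi, g in enumerate(data.genes) if g in assignment
    )


def em_step(
    assignment: Dict[str, str],
    data: LearningData,
    cfg: Config,
    params: NGParams,
    rng: np.random.Generator,
) -> Tuple[ModuleNetwork, float]:
    """One M-step + E-step; returns the network and the reassigned fraction.

    The E-step visits genes in a seeded random order and moves each gene to
    its best-scoring module under the fixed trees. Ties keep the current
    module; otherwise the lowest module id among the maxima wins. A
    modulator gene may not move into a module whose tree splits on it.
    """
    modules, trees = _network_from_assignment(assignment, data, cfg, params)
    mids, S = _score_matrix(trees, data)
    pos = {m: i for i, m in enumerate(mids)}
    split_users = {
        mid: trees[mid].used_modulators() for mid in mids
    }
    score_after_m = _total_score(assignment, mids, S, data)

    new_assignment = dict(assignment)
    gene_list = [g for g in data.genes if g in assignment]
    order = rng.permutation(len(gene_list))
    gene_idx = data.gene_index()
    changed = 0
    for oi in order:
        gene = gene_list[oi]
        gi = gene_idx[gene]
        cur = new_assignment[gene]
        col = S[:, gi]
        allowed = np.ones(len(mids), dtype=bool)
        for mi, mid in enumerate(mids):
            if gene in split_users[mid]:
                allowed[mi] = False
        best_val = col[allowed].max()
        if col[pos[cur]] >= best_val and allowed[pos[cur]]:
            continue  # current module ties the maximum: stay
        winners = [m for mi, m in enumerate(mids) if allowed[mi] and col[mi] == best_val]
        target = min(winners)
        if target != cur:
            new_assignment[gene] = target
            changed += 1

    pro = changed / max(len(gene_list), 1)
    score_after_e = _total_score(new_assignment, mids, S, data)
    final_modules: Dict[str, List[str]] = {}
    for gene, mid in new_assignment.items():
        final_modules.setdefault(mid, []).append(gene)
    final_modules = {m: sorted(g) for m, g in sorted(final_modules.items())}
    network = ModuleNetwork(
        modules=final_modules,
        trees={m: trees[m] for m in final_modules},
        assignment=new_assignment,
        total_log_score=score_after_e,
        score_history=[(score_after_m, score_after_e)],
    )
    return network, pro


def learn_module_network(
    initial: ModuleAssignment | Dict[str, str],
    data: LearningData,
    cfg: Config,
    seed: int,
) -> ModuleNetwork:
    """Iterate EM from an initial assignment until < em_reassign_tol move."""
    assignment = (
        dict(initial.assignment) if isinstance(initial, ModuleAssignment) else dict(initial)
    )
    if not assignment:
        raise ValueError("initial assignment is empty")
    rng = np.random.default_rng(seed)
    history: List[Tuple[float, float]] = []
    network: Optional[ModuleNetwork] = None
    for _ in range(cfg.em_max_iter):
        network, pro = em_step(assignment, data, cfg, params=NGParams(cfg.ng_alpha, cfg.ng_lambda), rng=rng)
        history.extend(network.score_history)
        assignment = network.assignment
        if pro < cfg.em_reassign_tol:
            break
    assert network is not None
    network.score_history = history
    return network


def network_to_json(network: ModuleNetwork) -> str:
    """Stable text serialization of the learned network."""
    payload = {
        "total_log_score": network.total_log_score,
        "modules": network.modules,
        "trees": {mid: tree.to_dict() for mid, tree in network.trees.items()},
    }
    return json.dumps(payload, indent=2, sort_keys=True)
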