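"""Initial module construction: thresholds, Normal-Gamma scoring, assignment.

Each candidate modulator gets a single expression threshold from a 1-D
two-cluster k-means seeded by the means of its copy-number-neutral vs
aberrant samples; the threshold is the midpoint between the two final
cluster centers. Splitting a target gene's expression at that threshold is
scored with the Normal-Gamma marginal likelihood (conjugate normal model
with unknown mean and precision, prior mean 0), and every target is assigned
to the single best-scoring modulator.

The leaf score for values x_1..x_N is the standard Normal-Gamma log marginal

    -(N/2) ln 2π + ½ ln(λ/(λ+N)) + ln Γ(α⁺) − ln Γ(α) + α ln β − α⁺ ln β⁺

with α⁺ = α + N/2, β⁺ = β + N·Var(x)/2 + N λ x̄² / (2(N+λ)) (population
variance) and β = max(1, λ(α−2)/(λ+1)) derived from (α, λ). Because the
prior mean is fixed at 0, expression should be centered per gene before
scoring (the pipeline does this by default). An empty leaf scores 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import gammaln
from sklearn.cluster import KMeans

__all__ = [
    "NGParams",
    "SplitRule",
    "ModuleAssignment",
    "fit_expression_threshold",
    "normal_gamma_log_marginal",
    "ng_scores_from_moments",
    "split_gain",
    "initial_assignment",
]

_LN_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class NGParams:
    """Normal-Gamma prior: shape ``alpha`` and precision scaling ``lam``."""

    alpha: float = 2.0
    lam: float = 0.1

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.lam <= 0:
            raise ValueError("alpha and lam must be positive")

    @property
    def beta(self) -> float:
        """Rate parameter derived from (alpha, lam), floored at 1."""
        return max(1.0, self.lam * (self.alpha - 2.0) / (self.lam + 1.0))


def ng_scores_from_moments(
    n: np.ndarray | float,
    sum_x: np.ndarray,
    sum_x2: np.ndarray,
    params: NGParams,
) -> np.ndarray:
    """Vectorized Normal-Gamma log marginal from (N, Σx, Σx²) per leaf.

    Accepts broadcastable arrays; entries with N == 0 score 0.
    """
    n = np.asarray(n, dtype=float)
    sum_x = np.asarray(sum_x, dtype=float)
    sum_x2 = np.asarray(sum_x2, dtype=float)
    safe_n = np.where(n > 0, n, 1.0)
    mean = sum_x / safe_n
    var = np.maximum(sum_x2 / safe_n - mean**2, 0.0)
    alpha, lam, beta = params.alpha, params.lam, params.beta
    a_post = alpha + n / 2.0
    b_post = beta + var * n / 2.0 + n * lam * mean**2 / (2.0 * (n + lam))
    score = (
        -(n / 2.0) * _LN_2PI
        + 0.5 * np.log(lam / (lam + n))
        + gammaln(a_post)
        - gammaln(alpha)
        + alpha * math.log(beta)
        - a_post * np.log(b_post)
    )
    return np.where(n > 0, score, 0.0)


def normal_gamma_log_marginal(
    leaf_values: Sequence[float], params: NGParams
) -> float:
    """Normal-Gamma log marginal likelihood of one leaf (0 when empty)."""
    x = np.asarray(leaf_values, dtype=float)
    if x.size == 0:
        return 0.0
    return float(
        ng_scores_from_moments(
            float(x.size), float(x.sum()), float((x**2).sum()), params
        )
    )


@dataclass(frozen=True)
class SplitRule:
    """A modulator gene together with its fitted expression threshold."""

    modulator: str
    threshold: float


def fit_expression_threshold(
    mod_expr: np.ndarray,
    mod_states: np.ndarray,
    seed: Optional[int] = None,
) -> float:
    """Two-cluster 1-D k-means threshold for one modulator's expression.

    Initial cluster centers are the mean expression of the copy-number
    neutral samples and of the aberrant samples; the aberrant class is the
    more frequent of {amplified, deleted} (the rarer class merges with
    neutral). The returned threshold is the midpoint between the two final
    cluster centers.
    """
    expr = np.asarray(mod_expr, dtype=float)
    states = np.asarray(mod_states)
    if expr.shape != states.shape:
        raise ValueError("expression and state vectors must align")
    if np.ptp(expr) == 0:
        raise ValueError("degenerate expression: all values identical")
    n_amp = int((states == 1).sum())
    n_del = int((states == -1).sum())
    aberrant = states == (1 if n_amp >= n_del else -1)
    if not aberrant.any():
        raise ValueError("no aberrant samples for this modulator")
    if aberrant.all():
        raise ValueError("no neutral samples for this modulator")
    init = np.array([[expr[~aberrant].mean()], [expr[aberrant].mean()]])
    if init[0, 0] == init[1, 0]:
        raise ValueError("degenerate expression: identical class means")
    km = KMeans(n_clusters=2, init=init, n_init=1, random_state=seed)
    km.fit(expr.reshape(-1, 1))
    c0, c1 = sorted(float(c) for c in km.cluster_centers_.ravel())
    return 0.5 * (c0 + c1)


def split_gain(
    target_values: Sequence[float],
    partition: Tuple[Sequence[int], Sequence[int]],
    params: NGParams,
    penalty: float,
) -> float:
    """Score improvement of splitting a target's samples into (A, B).

    gain = score(A) + score(B) − score(A ∪ B) − penalty. The two index sets
    must partition the sample set exactly.
    """
    values = np.asarray(target_values, dtype=float)
    a_idx = np.asarray(partition[0], dtype=int)
    b_idx = np.asarray(partition[1], dtype=int)
    combined = np.concatenate([a_idx, b_idx])
    if len(np.unique(combined)) != combined.size or combined.size != values.size:
        raise ValueError("partition must split the samples exactly")
    score_a = normal_gamma_log_marginal(values[a_idx], params)
    score_b = normal_gamma_log_marginal(values[b_idx], params)
    score_all = normal_gamma_log_marginal(values, params)
    return score_a + score_b - score_all - penalty


@dataclass
class ModuleAssignment:
    """Initial gene -> module map plus each module's founding split rule."""

    assignment: Dict[str, str]  # target gene -> module id (modulator id)
    rules: Dict[str, SplitRule]  # module id -> SplitRule
    dropped_targets: List[str] = field(default_factory=list)

    @property
    def modules(self) -> Dict[str, List[str]]:
        out: Dict[str, List[str]] = {}
        for gene, mid in self.assignment.items():
            out.setdefault(mid, []).append(gene)
        return {mid: sorted(genes) for mid, genes in sorted(out.items())}


def initial_assignment(
    targets: pd.DataFrame,
    rules: Mapping[str, SplitRule] | Sequence[SplitRule],
    params: NGParams,
    penalty: Optional[float] = None,
    modulator_expr: Optional[pd.DataFrame] = None,
) -> ModuleAssignment:
    """Assign each target gene to the single best-splitting modulator.

    For every modulator the samples are partitioned into (expression below
    threshold, expression at/above threshold); each target goes to the
    modulator whose partition yields the largest split gain. Ties break to
    the lexicographically smaller modulator id. A modulator gene is never
    assigned to its own module; the default penalty is ln(#modulators)
    (one split candidate evaluated per modulator).
    """
    if not isinstance(rules, Mapping):
        rules = {r.modulator: r for r in rules}
    if not rules:
        raise ValueError("no valid modulators with thresholds")
    if modulator_expr is None:
        missing = [m for m in rules if m not in targets.index]
        if missing:
            raise ValueError(
                f"modulator expression missing (not in targets, no modulator_expr): {missing}"
            )
        modulator_expr = targets
    mod_ids = sorted(rules)
    if penalty is None:
        penalty = math.log(len(mod_ids))

    Y = targets.to_numpy(dtype=float)
    sum_all = Y.sum(axis=1)
    sumsq_all = (Y**2).sum(axis=1)
    base = ng_scores_from_moments(Y.shape[1], sum_all, sumsq_all, params)

    gains = np.full((len(mod_ids), Y.shape[0]), -np.inf)
    for mi, mid in enumerate(mod_ids):
        expr = modulator_expr.loc[mid].to_numpy(dtype=float)
        below = expr < rules[mid].threshold
        if below.all() or not below.any():
            continue  # threshold outside the observed range: no split
        s1a = Y[:, below].sum(axis=1)
        s2a = (Y[:, below] ** 2).sum(axis=1)
        score_a = ng_scores_from_moments(int(below.sum()), s1a, s2a, params)
        score_b = ng_scores_from_moments(
            int((~below).sum()), sum_all - s1a, sumsq_all - s2a, params
        )
        gains[mi] = score_a + score_b - base - penalty

    gene_ids = [str(g) for g in targets.index]
    assignment: Dict[str, str] = {}
    dropped: List[str] = []
    for gi, gene in enumerate(gene_ids):
        col = gains[:, gi].copy()
        if gene in rules:
            col[mod_ids.index(gene)] = -np.inf  # no self-regulation
        best = int(np.argmax(col))  # argmax keeps the first (lexicographic) tie
        if not np.isfinite(col[best]):
            dropped.append(gene)
            continue
        assignment[gene] = mod_ids[best]
    used = set(assignment.values())
    kept_rules = {mid: rules[mid] for mid in mod_ids if mid in used}
    return ModuleAssignment(assignment=assignment, rules=kept_rules, dropped_targets=dropped)
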