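"""Ensemble learning, appearance filtering and driver-gene derivation.

The module-network learner is run many times per subtype; a modulator's
appearance frequency fre_app is the fraction of runs in which it appears in
at least one accepted split of the final network. Modulators with
fre_app >= appearance_threshold survive, a final learning pass restricted to
the survivors yields the subtype's candidate drivers, and pairwise set
difference across subtypes yields the subtype-specific drivers. Specific
drivers whose aberration frequency exceeds every other subtype's by more
than ``novelty_diff_threshold`` and which are absent from an optional
known-driver list are flagged novel.

Run-to-run diversity comes from bootstrap resampling of the samples in each
ensemble run (stability selection); set ``Config.ensemble_resample=False``
for deterministic repeated runs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .config import Config
from .learning import LearningData, ModuleNetwork, learn_module_network
from .module_init import (
    ModuleAssignment,
    NGParams,
    SplitRule,
    fit_expression_threshold,
    initial_assignment,
)
from .modulators import FrequencyStats

logger = logging.getLogger(__name__)

__all__ = [
    "SubtypeInputs",
    "AppearanceCounts",
    "single_run",
    "ensemble_runs",
    "filter_by_appearance",
    "final_candidates",
    "subtype_specific_drivers",
    "flag_novel_drivers",
]


@dataclass
class SubtypeInputs:
    """Expression/state matrices restricted to one subtype's samples.

    ``target_expr``: uncentered expression of the target genes (genes x
    focal samples); ``mod_expr``/``mod_states``: modulator expression and
    aberration states on the same samples.
    """

    subtype: str
    target_expr: pd.DataFrame
    mod_expr: pd.DataFrame
    mod_states: pd.DataFrame

    def __post_init__(self) -> None:
        cols = list(self.target_expr.columns)
        if list(self.mod_expr.columns) != cols or list(self.mod_states.columns) != cols:
            raise ValueError("target/modulator matrices must share samples")
        if list(self.mod_expr.index) != list(self.mod_states.index):
            raise ValueError("mod_expr and mod_states must share genes")


@dataclass
class AppearanceCounts:
    """Per-modulator counts of ensemble runs with >= 1 accepted split."""

    counts: Dict[str, int]
    n_runs: int

    def fre_app(self) -> Dict[str, float]:
        return {m: c / self.n_runs for m, c in self.counts.items()}


def _centered(Y: np.ndarray, enable: bool) -> np.ndarray:
    return Y - Y.mean(axis=1, keepdims=True) if enable else Y


def single_run(
    inputs: SubtypeInputs,
    cfg: Config,
    seed: int,
    resample: bool,
    restrict_modulators: Optional[Sequence[str]] = None,
) -> Optional[ModuleNetwork]:
    """One full learning run: thresholds -> initial assignment -> EM.

    With ``resample`` the run operates on a bootstrap resample (with
    replacement) of the subtype's samples. Modulators whose resampled state
    vector is degenerate (all aberrant, all neutral, constant expression)
    are skipped for that run. Returns None when no module can be formed.
    """
    rng = np.random.default_rng(seed)
    n = inputs.target_expr.shape[1]
    idx = rng.choice(n, size=n, replace=True) if resample else np.arange(n)

    mod_ids = [str(m) for m in inputs.mod_states.index]
    if restrict_modulators is not None:
        keep = set(str(m) for m in restrict_modulators)
        mod_ids = [m for m in mod_ids if m in keep]
    mod_expr_all = inputs.mod_expr.to_numpy(dtype=float)[:, idx]
    mod_states_all = inputs.mod_states.to_numpy()[:, idx]
    mod_pos = {str(m): i for i, m in enumerate(inputs.mod_states.index)}

    rules: Dict[str, SplitRule] = {}
    for m in mod_ids:
        row = mod_pos[m]
        try:
            thr = fit_expression_threshold(
                mod_expr_all[row], mod_states_all[row], seed=seed
            )
        except ValueError:
            continue  # degenerate in this (re)sample
        rules[m] = SplitRule(modulator=m, threshold=thr)
    if not rules:
        return None

    params = NGParams(cfg.ng_alpha, cfg.ng_lambda)
    Y = _centered(
        inputs.target_expr.to_numpy(dtype=float)[:, idx], cfg.center_expression
    )
    targets = pd.DataFrame(Y, index=inputs.target_expr.index)
    kept = sorted(rules)
    mod_expr_df = pd.DataFrame(
        np.vstack([mod_expr_all[mod_pos[m]] for m in kept]), index=kept
    )
    init = initial_assignment(targets, rules, params, modulator_expr=mod_expr_df)
    if not init.assignment:
        return None

    data = LearningData(
        Y=Y,
        genes=[str(g) for g in targets.index],
        mod_expr=mod_expr_df.to_numpy(dtype=float),
        mod_ids=kept,
        thresholds=np.array([rules[m].threshold for m in kept]),
    )
    return learn_module_network(init, data, cfg, seed=seed)


def ensemble_runs(
    inputs: SubtypeInputs, cfg: Config, master_seed: int
) -> AppearanceCounts:
    """Run the learner ``n_ensemble_runs`` times and count split appearances.

    Run r uses seed ``master_seed + r`` (r = 1..n); a modulator is counted
    in a run when it appears in at least one accepted split of that run's
    final network.
    """
    if cfg.n_ensemble_runs < 1:
        raise ValueError("n_ensemble_runs must be >= 1")
    counts = {str(m): 0 for m in inputs.mod_states.index}
    for r in range(1, cfg.n_ensemble_runs + 1):
        network = single_run(
            inputs, cfg, seed=master_seed + r, resample=cfg.ensemble_resample
        )
        if network is None:
            continue
        for m in network.split_modulators():
            counts[m] += 1
    return AppearanceCounts(counts=counts, n_runs=cfg.n_ensemble_runs)


def filter_by_appearance(counts: AppearanceCounts, threshold: float) -> List[str]:
    """Modulators with fre_app >= threshold (inclusive), sorted by id."""
    fre = counts.fre_app()
    return sorted(m for m, f in fre.items() if f >= threshold)


def final_candidates(
    inputs: SubtypeInputs,
    filtered_modulators: Sequence[str],
    cfg: Config,
    seed: int,
) -> List[str]:
    """Final learning pass restricted to the appearance-filtered modulators.

    Candidate drivers are the modulators appearing in at least one accepted
    split of the resulting network; always a subset of the filtered set.
    """
    if not filtered_modulators:
        warnings.warn(
            f"empty filtered modulator set for {inputs.subtype}; no candidates",
            stacklevel=2,
        )
        return []
    network = single_run(
        inputs, cfg, seed=seed, resample=False, restrict_modulators=filtered_modulators
    )
    if network is None:
        return []
    return sorted(network.split_modulators())


def subtype_specific_drivers(
    candidates_by_subtype: Mapping[str, Iterable[str]],
) -> Dict[str, List[str]]:
    """Candidates of each subtype minus the union of all other subtypes'."""
    subtypes = sorted(candidates_by_subtype)
    if len(subtypes) < 2:
        raise ValueError("specificity needs at least 2 subtypes")
    sets = {s: set(candidates_by_subtype[s]) for s in subtypes}
    out: Dict[str, List[str]] = {}
    for s in subtypes:
        others: Set[str] = set()
        for t in subtypes:
            if t != s:
                others |= sets[t]
        out[s] = sorted(sets[s] - others)
    return out


def flag_novel_drivers(
    specific: Iterable[str],
    mutation_freq: pd.DataFrame,
    focal: str,
    known_drivers: Optional[Iterable[str]] = None,
    diff_threshold: float = 0.2,
) -> List[str]:
    """Specific drivers passing the frequency-difference and novelty rules.

    ``mutation_freq`` holds per-subtype aberration frequencies (genes x
    subtypes). A gene is novel when its focal frequency exceeds each other
    subtype's by strictly more than ``diff_threshold`` and it is absent from
    the known-driver list (empty when none is supplied).
    """
    known = set(str(g) for g in known_drivers) if known_drivers is not None else set()
    others = [s for s in mutation_freq.columns if s != focal]
    out = []
    for gene in specific:
        gene = str(gene)
        if gene in known or gene not in mutation_freq.index:
            continue
        focal_fre = float(mutation_freq.loc[gene, focal])
        if all(focal_fre - float(mutation_freq.loc[gene, s]) > diff_threshold for s in others):
            out.append(gene)
    return sorted(out)
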