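"""Global pipeline configuration.

All thresholds of the method live here: the q-value cutoff for EMD
differential selection, the log2-ratio cutoffs for copy-number aberration
calls, the frequency filters for candidate modulators, the Normal-Gamma
prior, the tree/EM controls and the ensemble appearance filter.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Optional

import yaml


@dataclass
class Config:
    """Tunable parameters of the driver-identification pipeline.

    Defaults follow the published protocol: q < 0.1 differential selection,
    ±0.3 log2 aberration calls, >20% between-subtype frequency difference,
    aberration frequency fre > 0.6 for candidate modulators, permutation FDR
    with Δ = 0.001, a 40% ensemble appearance filter and 10-fold CV.
    """

    # differential selection
    q_threshold: float = 0.1
    n_permutations: int = 1000
    fdr_step: float = 0.001
    histogram_bin_count: Optional[int] = None  # None -> ceil(sqrt(n)), min 10

    # aberration calling / modulator nomination
    amp_threshold: float = 0.3
    del_threshold: float = -0.3
    freq_diff_threshold: float = 0.20
    modulator_freq_threshold: float = 0.6
    modulator_freq_scope: str = "focal"  # or "all": fre evaluated across all tumors

    # Normal-Gamma prior and tree learning
    ng_alpha: float = 2.0
    ng_lambda: float = 0.1
    split_penalty: Optional[float] = None  # None -> ln(#candidate splits evaluated)
    max_tree_depth: int = 3
    min_leaf_size: int = 5
    center_expression: bool = True

    # EM structure learning
    em_reassign_tol: float = 0.10
    em_max_iter: int = 50
    mstep_structure: bool = True  # False: parameters-only M-step (keep tree shapes)

    # ensemble / driver filters
    n_ensemble_runs: int = 100
    appearance_threshold: float = 0.40
    ensemble_resample: bool = True  # bootstrap samples per run (diversity source)
    novelty_diff_threshold: float = 0.2

    # validation
    cv_folds: int = 10

    master_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0.0 <= self.q_threshold <= 1.0:
            raise ValueError("q_threshold must be in [0, 1]")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.fdr_step <= 0:
            raise ValueError("fdr_step must be positive")
        if not (self.del_threshold < 0.0 < self.amp_threshold):
            raise ValueError("need del_threshold < 0 < amp_threshold")
        if not 0.0 <= self.freq_diff_threshold <= 1.0:
            raise ValueError("freq_diff_threshold must be in [0, 1]")
        if not 0.0 <= self.modulator_freq_threshold <= 1.0:
            raise ValueError("modulator_freq_threshold must be in [0, 1]")
        if self.modulator_freq_scope not in ("focal", "all"):
            raise ValueError("modulator_freq_scope must be 'focal' or 'all'")
        if self.ng_alpha <= 0 or self.ng_lambda <= 0:
            raise ValueError("Normal-Gamma parameters must be positive")
        if self.max_tree_depth < 0:
            raise ValueError("max_tree_depth must be >= 0")
        if self.min_leaf_size < 1:
            raise ValueError("min_leaf_size must be >= 1")
        if not 0.0 < self.em_reassign_tol <= 1.0:
            raise ValueError("em_reassign_tol must be in (0, 1]")
        if self.em_max_iter < 1:
            raise ValueError("em_max_iter must be >= 1")
        if self.n_ensemble_runs < 1:
            raise ValueError("n_ensemble_runs must be >= 1")
        if not 0.0 <= self.appearance_threshold <= 1.0:
            raise ValueError("appearance_threshold must be in [0, 1]")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.histogram_bin_count is not None and self.histogram_bin_count < 1:
            raise ValueError("histogram_bin_count must be >= 1")

    def bins_for(self, pooled_n: int) -> int:
        """Histogram cell count for a gene observed in ``pooled_n`` samples."""
        if self.histogram_bin_count is not None:
            return self.histogram_bin_count
        return max(10, math.ceil(math.sqrt(pooled_n)))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str) -> "Config":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
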