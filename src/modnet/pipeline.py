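"""End-to-end orchestration: from aligned matrices to a driver report.

Per subtype (focal vs rest): EMD differential selection on expression
(targets) and on copy number, aberration-frequency filters (candidate
modulators), module-network ensemble learning on the focal samples,
appearance filtering, a final restricted learning pass (candidate drivers),
then pairwise subtype specificity and novelty flags across subtypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

from .config import Config
from .dataio import Dataset, DriverReport
from .drivers import (
    AppearanceCounts,
    SubtypeInputs,
    ensemble_runs,
    filter_by_appearance,
    final_candidates,
    flag_novel_drivers,
    subtype_specific_drivers,
)
from .emd import emd_qvalues, select_differential_genes
from .modulators import (
    call_aberrations,
    frequency_stats,
    select_candidate_modulators,
)

logger = logging.getLogger(__name__)

__all__ = ["SubtypeAnalysis", "PipelineResult", "prepare_subtype_inputs", "analyze_subtype", "run_pipeline"]

_REST = "__rest__"


@dataclass
class SubtypeAnalysis:
    """Everything the pipeline derived for one focal subtype."""

    subtype: str
    diff_genes_expr: List[str]
    modulators: List[str]
    appearance: Dict[str, float]
    filtered_modulators: List[str]
    candidates: List[str]


@dataclass
class PipelineResult:
    analyses: Dict[str, SubtypeAnalysis]
    report: DriverReport


def _one_vs_rest_labels(ds: Dataset, subtype: str) -> List[str]:
    return [subtype if ds.labels[s] == subtype else _REST for s in ds.samples]


def _subtype_seed(cfg: Config, index: int) -> int:
    return (cfg.master_seed + 7919 * (index + 1)) % (2**31 - 1)


def prepare_subtype_inputs(
    ds: Dataset, subtype: str, cfg: Config, seed: int
) -> Tuple[Optional[SubtypeInputs], SubtypeAnalysis]:
    """Differential selection + modulator nomination for one subtype."""
    labels_ovr = _one_vs_rest_labels(ds, subtype)

    diff_expr = emd_qvalues(ds.expression, labels_ovr, cfg, seed=seed + 1)
    targets = select_differential_genes(diff_expr, cfg.q_threshold)

    # Converged gene subsets: candidate modulators must be differential in
    # expression AND present in the CNV universe; their copy-number evidence
    # is then the nonparametric frequency pair (freq_diff, fre), which is
    # stricter than an EMD call on the log2 ratios at this scale.
    cnv_universe = set(ds.genes_cnv)
    modulator_pool = [g for g in targets if g in cnv_universe]

    states = call_aberrations(ds.cnv, cfg.amp_threshold, cfg.del_threshold)
    groups = {subtype: ds.samples_of(subtype)}
    groups[_REST] = [s for s in ds.samples if ds.labels[s] != subtype]
    stats = frequency_stats(states, groups)
    modulators = select_candidate_modulators(
        modulator_pool, stats, focal=subtype, other=_REST, cfg=cfg
    )

    analysis = SubtypeAnalysis(
        subtype=subtype,
        diff_genes_expr=targets,
        modulators=modulators,
        appearance={},
        filtered_modulators=[],
        candidates=[],
    )
    if not modulators or not targets:
        logger.info("subtype %s: no modulators or no targets", subtype)
        return None, analysis

    focal_samples = ds.samples_of(subtype)
    inputs = SubtypeInputs(
        subtype=subtype,
        target_expr=ds.expression.loc[targets, focal_samples],
        mod_expr=ds.expression.loc[modulators, focal_samples],
        mod_states=states.loc[modulators, focal_samples],
    )
    return inputs, analysis


def analyze_subtype(
    ds: Dataset, subtype: str, cfg: Config, seed: int
) -> SubtypeAnalysis:
    """Full per-subtype analysis: filters, ensemble, final candidates."""
    inputs, analysis = prepare_subtype_inputs(ds, subtype, cfg, seed)
    if inputs is None:
        return analysis
    counts = ensemble_runs(inputs, cfg, master_seed=seed)
    analysis.appearance = counts.fre_app()
    analysis.filtered_modulators = filter_by_appearance(
        counts, cfg.appearance_threshold
    )
    if analysis.filtered_modulators:
        analysis.candidates = final_candidates(
            inputs,
            analysis.filtered_modulators,
            cfg,
            seed=seed + cfg.n_ensemble_runs + 1,
        )
    logger.info(
        "subtype %s: %d targets, %d modulators, %d filtered, %d candidates",
        subtype,
        len(analysis.diff_genes_expr),
        len(analysis.modulators),
        len(analysis.filtered_modulators),
        len(analysis.candidates),
    )
    return analysis


def run_pipeline(
    ds: Dataset,
    cfg: Config,
    known_drivers: Optional[Iterable[str]] = None,
) -> PipelineResult:
    """Run every subtype and derive specific/novel drivers and the report."""
    subtypes = ds.subtypes
    analyses = {
        s: analyze_subtype(ds, s, cfg, seed=_subtype_seed(cfg, i))
        for i, s in enumerate(subtypes)
    }
    candidates = {s: analyses[s].candidates for s in subtypes}
    specific = subtype_specific_drivers(candidates)

    states = call_aberrations(ds.cnv, cfg.amp_threshold, cfg.del_threshold)
    per_subtype_stats = frequency_stats(states, ds.labels)
    all_cand = sorted({g for c in candidates.values() for g in c})
    mutation_freq = pd.DataFrame(
        {
            s: per_subtype_stats.per_group[s].loc[all_cand, "fre"]
            if all_cand
            else pd.Series(dtype=float)
            for s in subtypes
        }
    )

    novel = {
        s: flag_novel_drivers(
            specific[s],
            mutation_freq,
            focal=s,
            known_drivers=known_drivers,
            diff_threshold=cfg.novelty_diff_threshold,
        )
        for s in subtypes
    }
    report = DriverReport(
        subtypes=subtypes,
        candidates=candidates,
        specific=specific,
        novel=novel,
        appearance={s: analyses[s].appearance for s in subtypes},
        mutation_freq=mutation_freq,
    )
    report.validate()
    return PipelineResult(analyses=analyses, report=report)
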