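"""Copy-number aberration calling and candidate-modulator nomination.

Log2 copy-number ratios are discretized into {deleted, neutral, amplified}
with inclusive thresholds (±0.3 by default). "Mutation" frequency fre is the
fraction of a group's samples carrying any aberration; candidate modulators
are the copy-number differential genes whose between-group frequency
difference exceeds 20% and whose fre exceeds 0.6 (both strict), the latter in
the focal subtype by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .config import Config

__all__ = [
    "call_aberrations",
    "FrequencyStats",
    "frequency_stats",
    "select_candidate_modulators",
]

DELETED, NEUTRAL, AMPLIFIED = -1, 0, 1


def call_aberrations(
    cnv: pd.DataFrame, amp_threshold: float = 0.3, del_threshold: float = -0.3
) -> pd.DataFrame:
    """Discretize log2 ratios: +1 if >= amp, -1 if <= del, else 0 (inclusive)."""
    if not (del_threshold < 0.0 < amp_threshold):
        raise ValueError("need del_threshold < 0 < amp_threshold")
    values = cnv.to_numpy(dtype=float)
    states = np.zeros(values.shape, dtype=np.int8)
    states[values >= amp_threshold] = AMPLIFIED
    states[values <= del_threshold] = DELETED
    return pd.DataFrame(states, index=cnv.index, columns=cnv.columns)


@dataclass
class FrequencyStats:
    """Per-group aberration frequencies: amp_freq, del_freq and fre per gene."""

    per_group: Dict[str, pd.DataFrame]
    group_sizes: Dict[str, int] = field(default_factory=dict)

    @property
    def genes(self) -> pd.Index:
        first = next(iter(self.per_group.values()))
        return first.index

    def freq_diff(self, group_a: str, group_b: str) -> pd.Series:
        """Larger of the amplification- and deletion-frequency differences."""
        a, b = self.per_group[group_a], self.per_group[group_b]
        diff = np.maximum(
            (a["amp_freq"] - b["amp_freq"]).abs(),
            (a["del_freq"] - b["del_freq"]).abs(),
        )
        return diff.rename("freq_diff")

    def fre_overall(self) -> pd.Series:
        """Aberration frequency pooled over every group (sample-weighted)."""
        total = sum(self.group_sizes.values())
        acc = None
        for g, df in self.per_group.items():
            part = df["fre"] * (self.group_sizes[g] / total)
            acc = part if acc is None else acc + part
        return acc.rename("fre")


def frequency_stats(
    states: pd.DataFrame,
    groups: Mapping[str, Sequence[str]] | pd.Series,
) -> FrequencyStats:
    """Aberration frequencies per gene for each sample group.

    ``groups`` is either a sample -> group label Series (one group per label)
    or an explicit mapping group name -> sample list (e.g. focal vs rest).
    """
    if isinstance(groups, pd.Series):
        groups = {
            str(g): list(groups.index[groups == g]) for g in sorted(groups.unique())
        }
    per_group: Dict[str, pd.DataFrame] = {}
    sizes: Dict[str, int] = {}
    for name, samples in groups.items():
        samples = list(samples)
        if not samples:
            raise ValueError(f"group '{name}' is empty")
        sub = states.loc[:, samples].to_numpy()
        n = sub.shape[1]
        per_group[str(name)] = pd.DataFrame(
            {
                "amp_freq": (sub == AMPLIFIED).sum(axis=1) / n,
                "del_freq": (sub == DELETED).sum(axis=1) / n,
                "fre": (sub != NEUTRAL).sum(axis=1) / n,
            },
            index=states.index,
        )
        sizes[str(name)] = n
    return FrequencyStats(per_group=per_group, group_sizes=sizes)


def select_candidate_modulators(
    diff_genes: Iterable[str],
    stats: FrequencyStats,
    focal: str,
    other: str,
    cfg: Config,
) -> List[str]:
    """Nominate candidate modulators among the copy-number differential genes.

    A gene passes when its focal-vs-other aberration-frequency difference
    strictly exceeds ``freq_diff_threshold`` and its fre strictly exceeds
    ``modulator_freq_threshold`` (in the focal group, or pooled over all
    groups when ``modulator_freq_scope == 'all'``).
    """
    diff_genes = set(str(g) for g in diff_genes)
    universe = [g for g in stats.genes if g in diff_genes]
    if not universe:
        warnings.warn(
            "no differential genes present in the CNV universe; "
            "returning an empty modulator set",
            stacklevel=2,
        )
        return []
    diff = stats.freq_diff(focal, other).loc[universe]
    if cfg.modulator_freq_scope == "all":
        fre = stats.fre_overall().loc[universe]
    else:
        fre = stats.per_group[focal].loc[universe, "fre"]
    keep = (diff > cfg.freq_diff_threshold) & (fre > cfg.modulator_freq_threshold)
    return sorted(str(g) for g in diff.index[keep])
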