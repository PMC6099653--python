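"""Synthetic datasets with planted module-network structure.

The generator emulates the causal chain the pipeline is built to detect:
within each subtype a few planted *modulator* genes are copy-number aberrant
in a fixed fraction of that subtype's samples; the aberration shifts the
modulator's own expression, and each modulator drives a disjoint block of
target genes whose expression shifts whenever the modulator's expression is
on the aberrant side of its threshold. Background genes (and all
non-modulator copy number) are Gaussian noise around zero. Optional decoy
genes are copy-number aberrant like modulators but expression-inert — they
pass the frequency filters and exercise the ensemble appearance filter.

Defaults (4 subtypes x 60 samples, 3 modulators x 30 targets each, 300
background genes) keep a full-pipeline run cheap on one CPU while leaving
every filter of the method non-trivial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .dataio import Dataset, align

__all__ = ["SimConfig", "SyntheticTruth", "generate_dataset"]


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; defaults define the standard study conditions."""

    n_subtypes: int = 4
    samples_per_subtype: int = 60
    n_modulators_per_subtype: int = 3
    targets_per_modulator: int = 30
    n_background_genes: int = 300
    decoys_per_subtype: int = 1
    aberration_freq: float = 0.8  # within-subtype fraction of aberrant samples
    cnv_effect: float = 1.0  # |log2 ratio| shift of aberrant samples
    expr_effect: float = 2.0  # expression shift of active modulators/targets
    noise_sigma: float = 0.5  # expression noise s.d.
    cnv_noise_sigma: float = 0.1  # copy-number noise s.d.
    seed: int = 0

    def __post_init__(self) -> None:
        if min(
            self.n_subtypes,
            self.samples_per_subtype,
            self.n_modulators_per_subtype,
            self.targets_per_modulator,
        ) < 1:
            raise ValueError("all counts must be >= 1")
        if self.n_background_genes < 0 or self.decoys_per_subtype < 0:
            raise ValueError("background/decoy counts must be >= 0")
        if not 0.0 < self.aberration_freq <= 1.0:
            raise ValueError("aberration_freq must be in (0, 1]")
        if self.noise_sigma <= 0 or self.cnv_noise_sigma <= 0:
            raise ValueError("noise scales must be positive")
        if self.n_subtypes < 2:
            raise ValueError("need at least 2 subtypes")


@dataclass
class SyntheticTruth:
    """Ground truth of the planted structure."""

    modulators: Dict[str, List[str]]  # subtype -> planted modulator genes
    targets: Dict[str, List[str]]  # modulator -> target block
    decoys: Dict[str, List[str]]  # subtype -> decoy genes
    signs: Dict[str, int]  # modulator -> aberration direction (+1 amp, -1 del)
    thresholds: Dict[str, float]  # modulator -> generating expression threshold
    background: List[str] = field(default_factory=list)

    def all_modulators(self) -> List[str]:
        return sorted(m for ms in self.modulators.values() for m in ms)


def generate_dataset(cfg: SimConfig) -> Tuple[Dataset, SyntheticTruth]:
    """Deterministically generate (expression, cnv, labels) plus the truth.

    The number of aberrant samples per planted gene is exact
    (round(aberration_freq * samples_per_subtype)), so the planted
    aberration frequencies are fixed rather than binomial.
    """
    rng = np.random.default_rng(cfg.seed)
    subtypes = [f"sub{i + 1}" for i in range(cfg.n_subtypes)]
    samples: List[str] = []
    sample_subtype: List[str] = []
    for s in subtypes:
        for i in range(cfg.samples_per_subtype):
            samples.append(f"{s}_s{i:03d}")
            sample_subtype.append(s)
    n_samples = len(samples)
    subtype_cols = {
        s: np.array([i for i, t in enumerate(sample_subtype) if t == s])
        for s in subtypes
    }

    genes: List[str] = []
    expr_rows: List[np.ndarray] = []
    cnv_rows: List[np.ndarray] = []
    truth = SyntheticTruth(
        modulators={s: [] for s in subtypes},
        targets={},
        decoys={s: [] for s in subtypes},
        signs={},
        thresholds={},
    )

    n_aberrant = int(round(cfg.aberration_freq * cfg.samples_per_subtype))
    n_aberrant = max(1, min(n_aberrant, cfg.samples_per_subtype))

    def noise(scale: float, size: int) -> np.ndarray:
        return rng.normal(0.0, scale, size)

    def plant_cnv(cols: np.ndarray, sign: int) -> Tuple[np.ndarray, np.ndarray]:
        """CNV row with an exact-count aberrant subset of ``cols``."""
        row = noise(cfg.cnv_noise_sigma, n_samples)
        chosen = cols[rng.permutation(cols.size)[:n_aberrant]]
        row[chosen] += sign * cfg.cnv_effect
        mask = np.zeros(n_samples, dtype=bool)
        mask[chosen] = True
        return row, mask

    sign_cycle = [1, -1]
    for si, s in enumerate(subtypes):
        cols = subtype_cols[s]
        for k in range(cfg.n_modulators_per_subtype):
            name = f"mod_{s}_{k}"
            sign = sign_cycle[k % 2]
            cnv_row, ab_mask = plant_cnv(cols, sign)
            expr_row = noise(cfg.noise_sigma, n_samples)
            expr_row[ab_mask] += sign * cfg.expr_effect
            genes.append(name)
            cnv_rows.append(cnv_row)
            expr_rows.append(expr_row)
            truth.modulators[s].append(name)
            truth.signs[name] = sign
            truth.thresholds[name] = sign * cfg.expr_effect / 2.0
            active = sign * expr_row > cfg.expr_effect / 2.0
            tgt_block: List[str] = []
            for j in range(cfg.targets_per_modulator):
                tname = f"tgt_{s}_{k}_{j:02d}"
                t_row = noise(cfg.noise_sigma, n_samples)
                t_row[active] += cfg.expr_effect
                genes.append(tname)
                expr_rows.append(t_row)
                cnv_rows.append(noise(cfg.cnv_noise_sigma, n_samples))
                tgt_block.append(tname)
            truth.targets[name] = tgt_block
        for k in range(cfg.decoys_per_subtype):
            name = f"dec_{s}_{k}"
            sign = sign_cycle[k % 2]
            cnv_row, _ = plant_cnv(cols, sign)
            genes.append(name)
            cnv_rows.append(cnv_row)
            expr_rows.append(noise(cfg.noise_sigma, n_samples))  # expression-inert
            truth.decoys[s].append(name)

    for b in range(cfg.n_background_genes):
        name = f"bg_{b:04d}"
        genes.append(name)
        expr_rows.append(noise(cfg.noise_sigma, n_samples))
        cnv_rows.append(noise(cfg.cnv_noise_sigma, n_samples))
        truth.background.append(name)

    expression = pd.DataFrame(np.vstack(expr_rows), index=genes, columns=samples)
    cnv = pd.DataFrame(np.vstack(cnv_rows), index=genes, columns=samples)
    labels = pd.Series(sample_subtype, index=samples, name="subtype")
    return align(expression, cnv, labels), truth
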