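"""Reading, aligning and writing the three input tables.

The pipeline consumes a gene x sample expression matrix (log-scale), a gene x
sample copy-number matrix (log2 ratios) and a sample -> subtype label table,
all tab-separated. Samples are aligned by id intersection across the three
inputs; sample and gene order is canonicalized (sorted by id) so results do
not depend on file ordering.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class Dataset:
    """Aligned expression/CNV/label triple over a shared sample set.

    ``expression`` and ``cnv`` are gene x sample DataFrames with identical,
    sorted sample columns; ``labels`` maps each of those samples to a subtype
    name. Gene universes of the two matrices may differ: candidate modulators
    later require membership in both, targets only in the expression matrix.
    """

    expression: pd.DataFrame
    cnv: pd.DataFrame
    labels: pd.Series
    load_log: Dict[str, int] = field(default_factory=dict)

    @property
    def samples(self) -> List[str]:
        return list(self.expression.columns)

    @property
    def genes_expr(self) -> List[str]:
        return list(self.expression.index)

    @property
    def genes_cnv(self) -> List[str]:
        return list(self.cnv.index)

    @property
    def subtypes(self) -> List[str]:
        return sorted(self.labels.unique())

    def samples_of(self, subtype: str) -> List[str]:
        return [s for s in self.samples if self.labels[s] == subtype]

    def validate(self) -> None:
        if list(self.expression.columns) != list(self.cnv.columns):
            raise ValueError("expression and cnv sample columns differ")
        if list(self.expression.columns) != list(self.labels.index):
            raise ValueError("labels do not cover the matrix samples")
        for name, df in (("expression", self.expression), ("cnv", self.cnv)):
            if df.index.duplicated().any():
                raise ValueError(f"duplicate gene id in {name} matrix")
            if df.isna().any().any():
                raise ValueError(f"missing values in {name} matrix after load")
        counts = self.labels.value_counts()
        if len(counts) < 2:
            raise ValueError("at least 2 subtypes are required")
        if (counts < 2).any():
            small = sorted(counts[counts < 2].index)
            raise ValueError(f"subtypes with < 2 samples: {small}")

    def __eq__(self, other: object) -> bool:  # used by idempotence tests
        if not isinstance(other, Dataset):
            return NotImplemented
        return (
            self.expression.equals(other.expression)
            and self.cnv.equals(other.cnv)
            and self.labels.equals(other.labels)
        )


def _read_matrix(path: str, what: str) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FileNotFoundError(f"{what} matrix not found: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = sorted(set(df.index[df.index.duplicated()]))
        raise ValueError(f"duplicate gene id in {what} matrix: {dups[:5]}")
    if df.columns.duplicated().any():
        raise ValueError(f"duplicate sample id in {what} matrix")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in {what} matrix: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def _read_labels(path: str) -> pd.Series:
    if not os.path.exists(path):
        raise FileNotFoundError(f"label table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("label table needs two columns: sample id, subtype")
    sample_col, label_col = df.columns[0], df.columns[1]
    if df[sample_col].duplicated().any():
        raise ValueError("duplicate sample id in label table")
    return pd.Series(df[label_col].values, index=df[sample_col].values, name="subtype")


def align(
    expression: pd.DataFrame,
    cnv: pd.DataFrame,
    labels: pd.Series,
) -> Dataset:
    """Restrict all three inputs to their shared samples and canonicalize order.

    Rows (genes) containing missing values are dropped and counted in the
    dataset's load log; no imputation is performed.
    """
    shared = sorted(set(expression.columns) & set(cnv.columns) & set(labels.index))
    if not shared:
        raise ValueError("empty sample intersection across expression/cnv/labels")
    log = {
        "samples_dropped": len(set(expression.columns) | set(cnv.columns) | set(labels.index))
        - len(shared),
        "samples_kept": len(shared),
    }
    expr = expression.loc[:, shared].sort_index()
    cnv_m = cnv.loc[:, shared].sort_index()
    for name, df in (("expression", expr), ("cnv", cnv_m)):
        bad = df.isna().any(axis=1)
        log[f"genes_dropped_{name}"] = int(bad.sum())
        if bad.any():
            logger.info("dropping %d %s genes with missing values", bad.sum(), name)
        if name == "expression":
            expr = df.loc[~bad]
        else:
            cnv_m = df.loc[~bad]
    ds = Dataset(expr, cnv_m, labels.loc[shared].astype(str), load_log=log)
    ds.validate()
    return ds


def load_dataset(expr_path: str, cnv_path: str, labels_path: str) -> Dataset:
    """Load and align the three TSV inputs (see module docstring for dialect)."""
    expression = _read_matrix(expr_path, "expression")
    cnv = _read_matrix(cnv_path, "cnv")
    labels = _read_labels(labels_path)
    ds = align(expression, cnv, labels)
    logger.info(
        "loaded dataset: %d expression genes, %d cnv genes, %d samples (%s)",
        len(ds.genes_expr),
        len(ds.genes_cnv),
        len(ds.samples),
        ds.load_log,
    )
    return ds


def write_dataset(ds: Dataset, out_dir: str) -> Dict[str, str]:
    """Write the aligned triple back to TSV (expression/cnv/labels)."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "expression": os.path.join(out_dir, "expression.tsv"),
        "cnv": os.path.join(out_dir, "cnv.tsv"),
        "labels": os.path.join(out_dir, "labels.tsv"),
    }
    ds.expression.to_csv(paths["expression"], sep="\t", index_label="gene")
    ds.cnv.to_csv(paths["cnv"], sep="\t", index_label="gene")
    lab = ds.labels.rename_axis("sample").rename("subtype").reset_index()
    lab.to_csv(paths["labels"], sep="\t", index=False)
    return paths


@dataclass
class DriverReport:
    """Per-subtype candidate/specific/novel driver gene sets with frequencies."""

    subtypes: List[str]
    candidates: Dict[str, List[str]]
    specific: Dict[str, List[str]]
    novel: Dict[str, List[str]]
    appearance: Dict[str, Dict[str, float]]  # subtype -> gene -> fre_app
    mutation_freq: pd.DataFrame  # genes x subtypes aberration frequency (fre)

    def validate(self) -> None:
        for s in self.subtypes:
            cand = set(self.candidates.get(s, []))
            spec = set(self.specific.get(s, []))
            nov = set(self.novel.get(s, []))
            if not nov <= spec <= cand:
                raise ValueError(f"novel ⊆ specific ⊆ candidate violated for {s}")


def write_driver_report(
    report: DriverReport,
    out_dir: str,
    config: Optional[dict] = None,
) -> Dict[str, str]:
    """Write one TSV per subtype plus a JSON run-metadata file.

    Each subtype table has one row per candidate driver with its ensemble
    appearance frequency, its aberration frequency in every subtype, and the
    specific/novel flags. Empty candidate sets yield header-only tables.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths: Dict[str, str] = {}
    for s in report.subtypes:
        rows = []
        spec = set(report.specific.get(s, []))
        nov = set(report.novel.get(s, []))
        app = report.appearance.get(s, {})
        for gene in sorted(report.candidates.get(s, [])):
            row = {"gene": gene, "appearance_frequency": app.get(gene, float("nan"))}
            for t in report.subtypes:
                if gene in report.mutation_freq.index:
                    row[f"mutation_frequency_{t}"] = float(report.mutation_freq.loc[gene, t])
                else:
                    row[f"mutation_frequency_{t}"] = float("nan")
            row["specific"] = int(gene in spec)
            row["novel"] = int(gene in nov)
            rows.append(row)
        cols = (
            ["gene", "appearance_frequency"]
            + [f"mutation_frequency_{t}" for t in report.subtypes]
            + ["specific", "novel"]
        )
        df = pd.DataFrame(rows, columns=cols)
        path = os.path.join(out_dir, f"drivers_{s}.tsv")
        df.to_csv(path, sep="\t", index=False)
        paths[s] = path
    meta = {"subtypes": report.subtypes}
    if config is not None:
        meta["config"] = config
    meta_path = os.path.join(out_dir, "run_metadata.json")
    with open(meta_path, "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True, default=str)
    paths["metadata"] = meta_path
    return paths


def read_driver_report(out_dir: str) -> DriverReport:
    """Re-read a written report (gene sets and flags round-trip exactly)."""
    meta_path = os.path.join(out_dir, "run_metadata.json")
    with open(meta_path, "r", encoding="utf-8") as fh:
        meta = json.load(fh)
    subtypes = meta["subtypes"]
    candidates: Dict[str, List[str]] = {}
    specific: Dict[str, List[str]] = {}
    novel: Dict[str, List[str]] = {}
    appearance: Dict[str, Dict[str, float]] = {}
    freq_rows: Dict[str, Dict[str, float]] = {}
    for s in subtypes:
        df = pd.read_csv(os.path.join(out_dir, f"drivers_{s}.tsv"), sep="\t")
        candidates[s] = [str(g) for g in df["gene"]]
        specific[s] = [str(g) for g, f in zip(df["gene"], df["specific"]) if f]
        novel[s] = [str(g) for g, f in zip(df["gene"], df["novel"]) if f]
        appearance[s] = {
            str(g): float(a) for g, a in zip(df["gene"], df["appearance_frequency"])
        }
        for _, row in df.iterrows():
            freq_rows.setdefault(str(row["gene"]), {}).update(
                {t: row[f"mutation_frequency_{t}"] for t in subtypes}
            )
    mutation_freq = pd.DataFrame.from_dict(freq_rows, orient="index").reindex(
        columns=subtypes
    )
    rep = DriverReport(subtypes, candidates, specific, novel, appearance, mutation_freq)
    rep.validate()
    return rep
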