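"""Tumor-vs-normal differential expression with the up/down call map.

Per gene and cancer, expression (TPM-like, non-negative) is compared between
the tumor and normal cohorts on the log2(TPM+1) scale.  A gene is called
*up* (or *down*) in a cancer when both gates pass:

* effect size: |log2 fold change| >= log2(1.5), where the fold change is the
  difference of cohort means of log2(x+1);
* significance: one-way ANOVA across the two cohorts, Benjamini–Hochberg
  adjusted within the cancer across the gene panel, q <= 0.05.

Per-gene totals (number of cancers up, number down) feed the mRNA-level
score of the final integration step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .registry import CancerType, sort_cancers_by_os
from .alterations import _symbols

logger = logging.getLogger(__name__)

__all__ = [
    "Cohort",
    "ExpressionMatrix",
    "DiffExprResult",
    "DiffExprMap",
    "log2_fold_change",
    "de_test",
    "bh_adjust",
    "de_map",
]


class Cohort(str, Enum):
    TUMOR = "tumor"
    NORMAL = "normal"


@dataclass
class ExpressionMatrix:
    """Gene-by-sample TPM-like matrix for one cohort of one cancer."""

    values: pd.DataFrame  # index = genes, columns = samples, floats >= 0
    cohort: Cohort

    def __post_init__(self) -> None:
        self.cohort = Cohort(self.cohort)
        arr = self.values.to_numpy()
        if arr.size and (arr < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("duplicate gene or sample labels in expression matrix")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @classmethod
    def from_tsv(cls, path: Union[str, Path], cohort: Cohort) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index.name = None
        return cls(df, cohort)

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.values.to_csv(path, sep="\t", index_label="symbol", float_format="%.6f")


@dataclass(frozen=True)
class DiffExprResult:
    gene: str
    cancer: str
    log2fc: float
    p_value: float
    q_value: float
    call: str  # up | down | ns


def _log1p2(x: np.ndarray) -> np.ndarray:
    return np.log2(np.asarray(x, dtype=float) + 1.0)


def log2_fold_change(tumor, normal) -> float:
    """mean(log2(x+1)) over tumor minus the same over normal.

    The +1 pseudo-count keeps zero-expression vectors well defined.
    """
    t = np.asarray(tumor, dtype=float)
    n = np.asarray(normal, dtype=float)
    if t.size == 0 or n.size == 0:
        raise ValueError("fold change requires non-empty vectors")
    if (t < 0).any() or (n < 0).any():
        raise ValueError("expression values must be non-negative")
    return float(_log1p2(t).mean() - _log1p2(n).mean())


def de_test(tumor, normal) -> float:
    """One-way ANOVA p-value across the two cohorts on the log2(x+1) scale.

    With two groups this is the pooled-variance F test (F = t^2).  When both
    groups are constant: p = 1 if the means agree, else 0.
    """
    t = _log1p2(tumor)
    n = _log1p2(normal)
    if t.size < 2 or n.size < 2:
        raise ValueError("each group needs >= 2 samples")
    if not (np.isfinite(t).all() and np.isfinite(n).all()):
        raise ValueError("non-finite expression values")
    if t.std() == 0.0 and n.std() == 0.0:
        return 1.0 if t.mean() == n.mean() else 0.0
    return float(stats.f_oneway(t, n).pvalue)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, returned in input order.

    q(i) = min_{j >= i} p(j) * m / j over the ascending-sorted p-values,
    capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class DiffExprMap:
    """Gene-by-cancer call map (+1 up / -1 down / 0 ns) with per-gene totals."""

    results: list[DiffExprResult]
    calls: pd.DataFrame  # genes x cancers, values in {+1, -1, 0}, NaN = not evaluable
    totals: pd.DataFrame  # index genes, columns n_up / n_down
    evaluable_cancers: list[str]

    def calls_tsv(self, path: Union[str, Path]) -> None:
        self.calls.to_csv(path, sep="\t", index_label="symbol")

    def totals_tsv(self, path: Union[str, Path]) -> None:
        self.totals.to_csv(path, sep="\t", index_label="symbol")


def _vector_de(
    tumor: pd.DataFrame, normal: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene log2FC and ANOVA p for aligned gene-by-sample matrices."""
    lt = _log1p2(tumor.to_numpy())
    ln = _log1p2(normal.to_numpy())
    lfc = lt.mean(axis=1) - ln.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.f_oneway(lt, ln, axis=1)
        p = np.asarray(res.pvalue, dtype=float)
    # constant-in-both-groups rows: scipy yields NaN; apply the convention
    degenerate = np.isnan(p)
    if degenerate.any():
        equal_means = np.isclose(lt.mean(axis=1), ln.mean(axis=1))
        p[degenerate & equal_means] = 1.0
        p[degenerate & ~equal_means] = 0.0
    return lfc, p


def de_map(
    tumor_by_cancer: Mapping[str, ExpressionMatrix],
    normal_by_cancer: Mapping[str, Optional[ExpressionMatrix]],
    registry: Sequence,
    cancers: Sequence[CancerType],
    fc_threshold: float = 1.5,
    q_threshold: float = 0.05,
) -> DiffExprMap:
    """Differential-expression call map over the panel and cancer catalog.

    BH adjustment is applied within each cancer across the gene panel.  A
    cancer without a normal cohort is marked not-evaluable (NaN column) and
    excluded from the per-gene totals.
    """
    genes = _symbols(registry)
    ordered = [c.abbreviation for c in sort_cancers_by_os(cancers)]
    log_fc_gate = np.log2(fc_threshold)

    calls = pd.DataFrame(np.nan, index=genes, columns=ordered)
    results: list[DiffExprResult] = []
    evaluable: list[str] = []

    for cancer in ordered:
        tumor = tumor_by_cancer.get(cancer)
        normal = normal_by_cancer.get(cancer)
        if tumor is None or normal is None:
            logger.warning("%s: missing %s cohort; column not evaluable",
                           cancer, "tumor" if tumor is None else "normal")
            continue
        missing = [g for g in genes if g not in tumor.values.index
                   or g not in normal.values.index]
        if missing:
            raise KeyError(f"{cancer}: genes absent from expression data: {missing}")
        evaluable.append(cancer)
        lfc, p = _vector_de(tumor.values.loc[genes], normal.values.loc[genes])
        q = bh_adjust(p)
        for i, gene in enumerate(genes):
            call = "ns"
            if q[i] <= q_threshold:
                if lfc[i] >= log_fc_gate:
                    call = "up"
                elif lfc[i] <= -log_fc_gate:
                    call = "down"
            calls.loc[gene, cancer] = {"up": 1, "down": -1, "ns": 0}[call]
            results.append(
                DiffExprResult(gene, cancer, float(lfc[i]), float(p[i]),
                               float(q[i]), call)
            )

    totals = pd.DataFrame(
        {
            "n_up": (calls[evaluable] == 1).sum(axis=1).astype(int),
            "n_down": (calls[evaluable] == -1).sum(axis=1).astype(int),
        },
        index=genes,
    )
    return DiffExprMap(results, calls, totals, evaluable)
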