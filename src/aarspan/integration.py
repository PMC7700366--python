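"""Three-level score integration and the favorable-to-unfavorable gene ranking.

Each gene receives one score per evidence level:

* DNA — its mean GISTIC score averaged across all cancers (signed copy-number
  tendency);
* mRNA — number of cancers significantly upregulating the gene minus the
  number downregulating it;
* survival — number of cancers where high expression is significantly
  unfavorable minus the number where it is favorable.

The three columns are min-max normalized to [0, 1] (a constant column maps
to 0.5) and averaged with equal weights into a composite score.  Sorting the
composite ascending ranks genes from most cancer-inhibiting (suppressor-like)
to most cancer-promoting (oncogene-like).  Pairwise Pearson correlations
between the raw columns quantify how well the evidence levels agree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "RawScores",
    "IntegrationScore",
    "dna_score",
    "mrna_score",
    "survival_score",
    "minmax_normalize",
    "composite_rank",
    "cross_level_correlation",
    "correlation_report",
    "ranking_frame",
]


class RawScores(NamedTuple):
    gene: str
    dna: float
    mrna: int
    survival: int


@dataclass(frozen=True)
class IntegrationScore:
    gene: str
    dna_score: float
    mrna_score: int
    survival_score: int
    norm_dna: float
    norm_mrna: float
    norm_survival: float
    composite: float
    rank: int  # 1 = most favorable (most cancer-inhibiting)


def dna_score(gistic_row) -> float:
    """Mean of a gene's per-cancer mean-GISTIC values."""
    row = np.asarray(gistic_row, dtype=float)
    if row.size == 0:
        raise ValueError("empty GISTIC row")
    return float(row.mean())


def mrna_score(n_up: int, n_down: int) -> int:
    """Net differential-expression direction: cancers up minus cancers down."""
    if n_up < 0 or n_down < 0:
        raise ValueError("counts must be non-negative")
    return int(n_up) - int(n_down)


def survival_score(n_unfavorable: int, n_favorable: int) -> int:
    """Net prognostic direction: unfavorable cancers minus favorable ones."""
    if n_unfavorable < 0 or n_favorable < 0:
        raise ValueError("counts must be non-negative")
    return int(n_unfavorable) - int(n_favorable)


def minmax_normalize(column) -> np.ndarray:
    """(x - min) / (max - min); a constant column maps to 0.5 throughout."""
    x = np.asarray(column, dtype=float)
    if x.size == 0:
        raise ValueError("empty column")
    span = x.max() - x.min()
    if span == 0:
        return np.full(x.shape, 0.5)
    return (x - x.min()) / span


def composite_rank(scores: Sequence[RawScores]) -> list[IntegrationScore]:
    """Normalize the three score columns, average, and rank ascending.

    Rank 1 is the most favorable (lowest composite) gene; composite ties
    break alphabetically by symbol.
    """
    if len(scores) < 2:
        raise ValueError("ranking requires >= 2 genes")
    genes = [s.gene for s in scores]
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate gene symbols in score list")
    norm_dna = minmax_normalize([s.dna for s in scores])
    norm_mrna = minmax_normalize([s.mrna for s in scores])
    norm_surv = minmax_normalize([s.survival for s in scores])
    composite = (norm_dna + norm_mrna + norm_surv) / 3.0

    order = sorted(range(len(scores)), key=lambda i: (composite[i], genes[i]))
    ranks = {i: r + 1 for r, i in enumerate(order)}
    return [
        IntegrationScore(
            gene=s.gene,
            dna_score=float(s.dna),
            mrna_score=int(s.mrna),
            survival_score=int(s.survival),
            norm_dna=float(norm_dna[i]),
            norm_mrna=float(norm_mrna[i]),
            norm_survival=float(norm_surv[i]),
            composite=float(composite[i]),
            rank=ranks[i],
        )
        for i, s in enumerate(scores)
    ]


def cross_level_correlation(col_a, col_b) -> tuple[float, float, bool]:
    """Pearson r, two-tailed p (t transform, n-2 df), and p < 0.05 flag."""
    a = np.asarray(col_a, dtype=float)
    b = np.asarray(col_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("columns must have equal length")
    if a.size < 3:
        raise ValueError("correlation requires >= 3 points")
    if a.std() == 0 or b.std() == 0:
        logger.warning("zero variance: cross-level correlation undefined")
        return float("nan"), float("nan"), False
    r, p = stats.pearsonr(a, b)
    return float(r), float(p), bool(p < 0.05)


def correlation_report(scores: Sequence[IntegrationScore]) -> pd.DataFrame:
    """Pairwise raw-score correlations: (dna, mrna), (mrna, survival), (dna, survival)."""
    cols = {
        "dna": [s.dna_score for s in scores],
        "mrna": [s.mrna_score for s in scores],
        "survival": [s.survival_score for s in scores],
    }
    rows = []
    for a, b in (("dna", "mrna"), ("mrna", "survival"), ("dna", "survival")):
        r, p, sig = cross_level_correlation(cols[a], cols[b])
        rows.append({"pair": f"{a}~{b}", "pearson_r": r, "p_value": p,
                     "significant": sig})
    return pd.DataFrame(rows)


def ranking_frame(scores: Sequence[IntegrationScore]) -> pd.DataFrame:
    """Ranking table sorted by rank, one row per gene."""
    df = pd.DataFrame([s.__dict__ for s in scores])
    return df.sort_values("rank").reset_index(drop=True)
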