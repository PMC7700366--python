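"""Expression-stratified survival analysis and the gene-by-cancer survival map.

For each gene and cancer, tumor patients are split at the median mRNA
expression of that gene (ties at the median go to the low group).  The two
groups are compared with the standard two-group log-rank test, and the
hazard ratio (high vs low) is estimated by the Mantel–Haenszel form

    HR = (O_high / E_high) / (O_low / E_low),

with observed and expected deaths accumulated over the log-rank risk-set
tabulation.  HR > 1 means high expression is unfavorable.  Significance
over the whole map uses Benjamini–Hochberg adjustment across all evaluable
gene-by-cancer cells, q <= 0.05; cells with zero observed events in either
group have no defined HR and are excluded rather than continuity-corrected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .registry import CancerType, sort_cancers_by_os
from .alterations import _symbols
from .diffexpr import ExpressionMatrix, bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalTable",
    "KmCurve",
    "SurvivalResult",
    "SurvivalMap",
    "DegenerateSplitError",
    "median_split",
    "km_estimate",
    "logrank_test",
    "hazard_ratio",
    "survival_map",
    "aggressiveness_correlation",
]


class DegenerateSplitError(ValueError):
    """All expression values identical: no median split exists."""


@dataclass
class SurvivalTable:
    """Per-sample follow-up: sample_id, time_months (> 0), event (1 = death)."""

    rows: pd.DataFrame

    COLUMNS = ("sample_id", "time_months", "event")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.rows.columns)
        if missing:
            raise ValueError(f"survival table missing columns: {sorted(missing)}")
        if self.rows["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids in survival table")
        if len(self.rows) and (self.rows["time_months"] <= 0).any():
            raise ValueError("survival times must be positive")

    def __len__(self) -> int:
        return len(self.rows)

    def subset(self, sample_ids) -> "SurvivalTable":
        mask = self.rows["sample_id"].isin(set(sample_ids))
        return SurvivalTable(self.rows[mask].reset_index(drop=True))

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "SurvivalTable":
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
        df["event"] = df["event"].astype(int)
        return cls(df)

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.rows.to_csv(path, sep="\t", index=False, float_format="%.6f")


@dataclass
class KmCurve:
    """Product-limit survival curve over the distinct event times."""

    times: np.ndarray        # distinct death times, ascending
    survival: np.ndarray     # S(t) just after each death time
    at_risk: np.ndarray      # risk-set size just before each death time

    def probability_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass(frozen=True)
class SurvivalResult:
    gene: str
    cancer: str
    hazard_ratio: Optional[float]
    logrank_p: float
    q_value: float
    direction: str  # unfavorable | favorable | ns
    n_high: int
    n_low: int


def median_split(expression: pd.Series) -> pd.Series:
    """Label samples 'high' (> median) or 'low' (<= median).

    Ties at the median go low.  Raises DegenerateSplitError when every value
    is identical (no split possible).
    """
    values = expression.astype(float)
    if len(values) < 4:
        raise ValueError("median split requires >= 4 samples")
    if values.nunique() == 1:
        raise DegenerateSplitError("all expression values identical")
    med = values.median()
    labels = pd.Series(
        np.where(values > med, "high", "low"), index=expression.index
    )
    if (labels == "high").sum() == 0:
        # heavy ties at the median can empty the high group
        raise DegenerateSplitError("median tie rule left the high group empty")
    return labels


def km_estimate(table: SurvivalTable) -> KmCurve:
    """Kaplan–Meier product-limit estimator S(t) = prod(1 - d_i/n_i)."""
    if len(table) == 0:
        raise ValueError("empty survival table")
    df = table.rows
    event_times = np.unique(df.loc[df["event"] == 1, "time_months"].to_numpy(float))
    times_all = df["time_months"].to_numpy(float)
    deaths_by_time = df[df["event"] == 1].groupby("time_months").size()

    surv, at_risk = [], []
    s = 1.0
    for t in event_times:
        n_i = int((times_all >= t).sum())
        d_i = int(deaths_by_time[t])
        s *= 1.0 - d_i / n_i
        surv.append(s)
        at_risk.append(n_i)
    return KmCurve(event_times, np.array(surv), np.array(at_risk, dtype=int))


def _logrank_tabulation(
    group_high: SurvivalTable, group_low: SurvivalTable
) -> tuple[float, float, float, float, float]:
    """Accumulate (O_high, E_high, O_low, E_low, V) over distinct event times.

    At each death time the expected high-group deaths and the hypergeometric
    variance come from the 2x2 risk-set table.
    """
    t1 = group_high.rows["time_months"].to_numpy(float)
    e1 = group_high.rows["event"].to_numpy(int)
    t2 = group_low.rows["time_months"].to_numpy(float)
    e2 = group_low.rows["event"].to_numpy(int)

    event_times = np.unique(np.concatenate([t1[e1 == 1], t2[e2 == 1]]))
    o1 = o2 = exp1 = exp2 = var = 0.0
    for t in event_times:
        n1 = float((t1 >= t).sum())
        n2 = float((t2 >= t).sum())
        d1 = float(((t1 == t) & (e1 == 1)).sum())
        d2 = float(((t2 == t) & (e2 == 1)).sum())
        n = n1 + n2
        d = d1 + d2
        o1 += d1
        o2 += d2
        exp1 += d * n1 / n
        exp2 += d * n2 / n
        if n > 1:
            var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return o1, exp1, o2, exp2, var


def logrank_test(
    group_high: SurvivalTable, group_low: SurvivalTable
) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square with 1 df, two-sided p).

    Zero total events yields (0, 1) by convention.
    """
    if len(group_high) == 0 or len(group_low) == 0:
        raise ValueError("both groups must be non-empty")
    o1, e1, o2, _, var = _logrank_tabulation(group_high, group_low)
    if o1 + o2 == 0 or var == 0:
        # no events, or no information (every death in a one-sample risk set)
        return 0.0, 1.0
    chi2 = (o1 - e1) ** 2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def hazard_ratio(
    group_high: SurvivalTable, group_low: SurvivalTable
) -> Optional[float]:
    """Mantel–Haenszel hazard ratio of high vs low expression.

    Returns None (undefined) when either group has zero observed events.
    """
    if len(group_high) == 0 or len(group_low) == 0:
        raise ValueError("both groups must be non-empty")
    o1, e1, o2, e2, _ = _logrank_tabulation(group_high, group_low)
    if o1 == 0 or o2 == 0:
        logger.info("hazard ratio undefined: zero events in one group")
        return None
    return float((o1 / e1) / (o2 / e2))


@dataclass
class SurvivalMap:
    """Gene-by-cancer survival results with per-gene direction totals."""

    results: list[SurvivalResult]
    hazard_ratios: pd.DataFrame  # genes x cancers, NaN = not evaluable
    q_values: pd.DataFrame
    directions: pd.DataFrame     # strings; '' = not evaluable
    totals: pd.DataFrame         # index genes, columns n_unfavorable / n_favorable

    def map_tsv(self, path: Union[str, Path]) -> None:
        rows = [
            {
                "symbol": r.gene,
                "cancer": r.cancer,
                "hazard_ratio": r.hazard_ratio,
                "logrank_p": r.logrank_p,
                "q_value": r.q_value,
                "direction": r.direction,
                "n_high": r.n_high,
                "n_low": r.n_low,
            }
            for r in self.results
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")

    def totals_tsv(self, path: Union[str, Path]) -> None:
        self.totals.to_csv(path, sep="\t", index_label="symbol")


def survival_map(
    tumor_by_cancer: Mapping[str, ExpressionMatrix],
    survival_by_cancer: Mapping[str, Optional[SurvivalTable]],
    registry: Sequence,
    cancers: Sequence[CancerType],
    q_threshold: float = 0.05,
) -> SurvivalMap:
    """Median-split KM/log-rank survival map over the panel and catalog.

    BH adjustment runs globally across all evaluable cells (the map is
    thresholded as a single experiment).  Cells with a degenerate split or
    an undefined HR are not evaluable and contribute nothing to the totals.
    """
    genes = _symbols(registry)
    ordered = [c.abbreviation for c in sort_cancers_by_os(cancers)]

    cells = []  # (gene, cancer, hr, p, n_high, n_low)
    for cancer in ordered:
        tumor = tumor_by_cancer.get(cancer)
        surv = survival_by_cancer.get(cancer)
        if tumor is None or surv is None:
            logger.warning("%s: missing expression or survival data; "
                           "column not evaluable", cancer)
            continue
        common = [s for s in tumor.samples
                  if s in set(surv.rows["sample_id"])]
        surv_sub = surv.subset(common)
        surv_idx = surv_sub.rows.set_index("sample_id")
        for gene in genes:
            if gene not in tumor.values.index:
                raise KeyError(f"{cancer}: gene {gene} absent from expression")
            expr = tumor.values.loc[gene, common]
            try:
                labels = median_split(expr)
            except DegenerateSplitError:
                logger.warning("%s/%s: degenerate median split", gene, cancer)
                continue
            high_ids = labels.index[labels == "high"]
            low_ids = labels.index[labels == "low"]
            high = SurvivalTable(
                surv_idx.loc[high_ids].rename_axis("sample_id")
                .reset_index()[list(SurvivalTable.COLUMNS)]
            )
            low = SurvivalTable(
                surv_idx.loc[low_ids].rename_axis("sample_id")
                .reset_index()[list(SurvivalTable.COLUMNS)]
            )
            hr = hazard_ratio(high, low)
            if hr is None:
                continue
            _, p = logrank_test(high, low)
            cells.append((gene, cancer, hr, p, len(high_ids), len(low_ids)))

    hr_df = pd.DataFrame(np.nan, index=genes, columns=ordered)
    q_df = pd.DataFrame(np.nan, index=genes, columns=ordered)
    dir_df = pd.DataFrame("", index=genes, columns=ordered)
    results: list[SurvivalResult] = []

    if cells:
        qs = bh_adjust([c[3] for c in cells])
        for (gene, cancer, hr, p, n_hi, n_lo), q in zip(cells, qs):
            if q <= q_threshold and hr > 1:
                direction = "unfavorable"
            elif q <= q_threshold and hr < 1:
                direction = "favorable"
            else:
                direction = "ns"
            hr_df.loc[gene, cancer] = hr
            q_df.loc[gene, cancer] = q
            dir_df.loc[gene, cancer] = direction
            results.append(
                SurvivalResult(gene, cancer, hr, float(p), float(q),
                               direction, n_hi, n_lo)
            )

    totals = pd.DataFrame(
        {
            "n_unfavorable": (dir_df == "unfavorable").sum(axis=1).astype(int),
            "n_favorable": (dir_df == "favorable").sum(axis=1).astype(int),
        },
        index=genes,
    )
    return SurvivalMap(results, hr_df, q_df, dir_df, totals)


def aggressiveness_correlation(
    cancers: Sequence[CancerType],
    up_counts: Mapping[str, int],
    exclude: Sequence[str] = (),
) -> tuple[float, float]:
    """Pearson correlation of median OS vs per-cancer upregulated-gene counts.

    ``exclude`` drops cancers whose normal control tissue is known to be a
    poor match (e.g. blood or bone marrow).  Zero variance in either
    variable yields (nan, nan) with a warning.
    """
    excluded = set(exclude)
    pairs = [
        (c.median_os_months, up_counts[c.abbreviation])
        for c in cancers
        if c.abbreviation in up_counts and c.abbreviation not in excluded
    ]
    if len(pairs) < 3:
        raise ValueError("correlation requires >= 3 cancers")
    x, y = map(np.asarray, zip(*pairs))
    if np.std(x) == 0 or np.std(y) == 0:
        logger.warning("zero variance: correlation undefined")
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
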