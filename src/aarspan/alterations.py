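"""Genomic-level analysis: alteration categories, frequencies, GISTIC means.

Copy-number input is a gene-by-sample matrix of thresholded GISTIC-style
calls: -2 deep deletion, -1 shallow deletion, 0 diploid, +1 low-level gain,
+2 amplification.  Discrete events (point mutations, fusions) arrive through
a minimal MAF-like table.  Two summaries are computed:

* the *alteration frequency* — the fraction of profiled patients carrying a
  mutation, fusion, amplification, deep deletion, or multiple such events in
  a gene.  Only the high-confidence +/-2 calls count as CNV alterations here;
* the *mean GISTIC score* per gene per cancer — the arithmetic mean over all
  calls including the low-level +/-1 values, giving a signed degree of
  amplification (positive) or deletion (negative) bounded in [-2, +2].

A per-residue mutation tally with a simple recurrence threshold flags
hotspot positions (e.g., a cluster of missense hits at one residue) against
a background of mutations spread across the whole protein.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .registry import CancerType, GeneRecord, sort_cancers_by_os

__all__ = [
    "VALID_CALLS",
    "CATEGORIES",
    "CONSEQUENCES",
    "CnvCallMatrix",
    "MutationTable",
    "AlterationProfile",
    "classify_sample",
    "alteration_frequency",
    "panel_alteration_frequency",
    "mean_gistic",
    "gistic_heatmap",
    "mutation_position_tally",
]

VALID_CALLS = (-2, -1, 0, 1, 2)
CATEGORIES = ("mutation", "fusion", "amplification", "deep_deletion", "multiple")
CONSEQUENCES = ("missense", "nonsense", "frameshift", "fusion", "other")


def _symbols(registry: Sequence) -> list[str]:
    """Accept either GeneRecord sequences or plain symbol strings."""
    return [r.symbol if isinstance(r, GeneRecord) else str(r) for r in registry]


@dataclass
class CnvCallMatrix:
    """Gene-by-sample matrix of thresholded copy-number calls in {-2..+2}."""

    calls: pd.DataFrame  # index = gene symbols, columns = sample ids, int

    def __post_init__(self) -> None:
        values = self.calls.to_numpy()
        if values.size and not np.isin(values, VALID_CALLS).all():
            bad = sorted(set(values.ravel()) - set(VALID_CALLS))
            raise ValueError(f"CNV calls outside {{-2..+2}}: {bad}")
        if self.calls.index.has_duplicates or self.calls.columns.has_duplicates:
            raise ValueError("duplicate gene or sample labels in CNV matrix")

    @property
    def genes(self) -> list[str]:
        return list(self.calls.index)

    @property
    def samples(self) -> list[str]:
        return list(self.calls.columns)

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "CnvCallMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index.name = None
        return cls(df.astype(int))

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.calls.to_csv(path, sep="\t", index_label="symbol")


@dataclass
class MutationTable:
    """MAF-minimal table: sample_id, gene_symbol, protein_position, consequence."""

    rows: pd.DataFrame

    COLUMNS = ("sample_id", "gene_symbol", "protein_position", "consequence")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.rows.columns)
        if missing:
            raise ValueError(f"mutation table missing columns: {sorted(missing)}")
        pos = self.rows["protein_position"].dropna()
        if len(pos) and (pos < 1).any():
            raise ValueError("protein_position must be >= 1 when present")
        bad = set(self.rows["consequence"]) - set(CONSEQUENCES)
        if bad:
            raise ValueError(f"unknown consequence classes: {sorted(bad)}")

    @classmethod
    def empty(cls) -> "MutationTable":
        return cls(
            pd.DataFrame(
                {
                    "sample_id": pd.Series(dtype=str),
                    "gene_symbol": pd.Series(dtype=str),
                    "protein_position": pd.Series(dtype="Int64"),
                    "consequence": pd.Series(dtype=str),
                }
            )
        )

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "MutationTable":
        df = pd.read_csv(
            path,
            sep="\t",
            dtype={"sample_id": str, "gene_symbol": str, "consequence": str},
        )
        if df.empty and "protein_position" not in df.columns:
            return cls.empty()
        df["protein_position"] = df["protein_position"].astype("Int64")
        return cls(df)

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.rows.to_csv(path, sep="\t", index=False)


@dataclass
class AlterationProfile:
    """Per-gene per-cancer alteration category counts and frequency."""

    gene: str
    cancer: str
    counts: dict[str, int]
    n_profiled: int
    alteration_frequency: float = field(init=False)

    def __post_init__(self) -> None:
        total = sum(self.counts.values())
        if total > self.n_profiled:
            raise ValueError("altered samples exceed profiled samples")
        self.alteration_frequency = total / self.n_profiled


def classify_sample(
    cnv_call: int, has_mutation: bool, has_fusion: bool
) -> Optional[str]:
    """Assign one alteration category to a sample for one gene.

    Amplification (+2) and deep deletion (-2) are the only CNV classes;
    +/-1 and 0 calls contribute nothing.  A sample hit by two or more
    distinct classes is "multiple"; an unaltered sample returns None.
    """
    if cnv_call not in VALID_CALLS:
        raise ValueError(f"CNV call must be in {{-2..+2}}, got {cnv_call}")
    classes = []
    if has_mutation:
        classes.append("mutation")
    if has_fusion:
        classes.append("fusion")
    if cnv_call == 2:
        classes.append("amplification")
    elif cnv_call == -2:
        classes.append("deep_deletion")
    if not classes:
        return None
    if len(classes) >= 2:
        return "multiple"
    return classes[0]


def _event_flags(muts: MutationTable, gene: str) -> tuple[set, set]:
    sub = muts.rows[muts.rows["gene_symbol"] == gene]
    fusion = set(sub.loc[sub["consequence"] == "fusion", "sample_id"])
    mutation = set(sub.loc[sub["consequence"] != "fusion", "sample_id"])
    return mutation, fusion


def alteration_frequency(
    cnv: CnvCallMatrix, muts: MutationTable, cancer: str
) -> list[AlterationProfile]:
    """Alteration category counts and frequency for every gene in the matrix."""
    samples = cnv.samples
    if not samples:
        raise ValueError(f"{cancer}: zero profiled samples")
    profiles = []
    for gene in cnv.genes:
        mut_samples, fus_samples = _event_flags(muts, gene)
        counts = {c: 0 for c in CATEGORIES}
        row = cnv.calls.loc[gene]
        for sample in samples:
            cat = classify_sample(
                int(row[sample]), sample in mut_samples, sample in fus_samples
            )
            if cat is not None:
                counts[cat] += 1
        profiles.append(AlterationProfile(gene, cancer, counts, len(samples)))
    return profiles


def panel_alteration_frequency(cnv: CnvCallMatrix, muts: MutationTable) -> float:
    """Fraction of samples altered in *any* gene of the panel.

    Always >= the largest single-gene alteration frequency.
    """
    samples = cnv.samples
    if not samples:
        raise ValueError("zero profiled samples")
    altered: set[str] = set()
    for gene in cnv.genes:
        mut_samples, fus_samples = _event_flags(muts, gene)
        row = cnv.calls.loc[gene]
        for sample in samples:
            if classify_sample(
                int(row[sample]), sample in mut_samples, sample in fus_samples
            ):
                altered.add(sample)
    return len(altered) / len(samples)


def mean_gistic(cnv: CnvCallMatrix, gene: str) -> float:
    """Arithmetic mean of a gene's calls over all samples; in [-2, +2]."""
    if gene not in cnv.calls.index:
        raise KeyError(f"gene {gene} absent from CNV matrix")
    if not cnv.samples:
        raise ValueError("zero samples in CNV matrix")
    return float(cnv.calls.loc[gene].mean())


def gistic_heatmap(
    cnv_by_cancer: Mapping[str, CnvCallMatrix],
    registry: Sequence,
    cancers: Sequence[CancerType],
) -> pd.DataFrame:
    """Mean-GISTIC gene-by-cancer matrix, columns in ascending-OS order."""
    genes = _symbols(registry)
    ordered = sort_cancers_by_os(cancers)
    missing = [
        (g, c.abbreviation)
        for c in ordered
        for g in genes
        if g not in cnv_by_cancer[c.abbreviation].calls.index
    ]
    if missing:
        raise KeyError(f"genes missing from CNV matrices (gene, cancer): {missing}")
    data = {
        c.abbreviation: [mean_gistic(cnv_by_cancer[c.abbreviation], g) for g in genes]
        for c in ordered
    }
    return pd.DataFrame(data, index=genes)


def mutation_position_tally(
    muts: MutationTable,
    gene: str,
    protein_length: int,
    hotspot_min: int = 3,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Per-residue mutation counts plus recurrent-position hotspots.

    Returns a count vector of length ``protein_length`` (1-based residues at
    index pos-1) and the residues with count >= ``hotspot_min``, as
    (position, count) pairs sorted by descending count then position.
    """
    if protein_length < 1:
        raise ValueError("protein_length must be positive")
    sub = muts.rows[muts.rows["gene_symbol"] == gene]
    positions = sub["protein_position"].dropna().astype(int)
    if len(positions) and positions.max() > protein_length:
        raise ValueError(
            f"{gene}: observed position {positions.max()} exceeds "
            f"protein_length {protein_length}"
        )
    counts = np.zeros(protein_length, dtype=int)
    for pos, n in positions.value_counts().items():
        counts[pos - 1] = n
    hotspots = [
        (int(pos + 1), int(n))
        for pos, n in enumerate(counts)
        if n >= hotspot_min
    ]
    hotspots.sort(key=lambda t: (-t[1], t[0]))
    return counts, hotspots
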