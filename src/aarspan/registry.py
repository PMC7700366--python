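"""Gene panel and cancer-type catalog.

The analysis panel covers the human aminoacyl-tRNA synthetases (aaRSs):
20 cytoplasmic and 19 mitochondrial enzymes, with glycyl- (GARS1) and
lysyl-tRNA synthetase (KARS1) shared between the two compartments, so the
panel holds 37 unique aaRS genes.  The three aaRS-interacting
multi-functional proteins (AIMP1, AIMP2, AIMP3/EEF1E1) and three benchmark
genes with established cancer roles (RB1 tumor suppressor, MYC
proto-oncogene, EIF4E translation factor) complete the 43-gene panel.

The cancer catalog lists the 33 TCGA cancer-type abbreviations with their
median overall-survival (OS) time in months.  Every heatmap produced by the
downstream analyses orders its columns by ascending median OS — from the
shortest-surviving cohort (LAML, 9 months) to the longest (BRCA, 41.8
months) — so that aggressiveness-related trends read left to right.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Locality",
    "Family",
    "GeneRecord",
    "CancerType",
    "RegistryError",
    "load_gene_registry",
    "load_cancer_table",
    "sort_cancers_by_os",
    "aars_symbols",
    "locality_counts",
]

REFERENCE_SYMBOLS = frozenset({"RB1", "MYC", "EIF4E"})
DUAL_SYMBOLS = frozenset({"GARS1", "KARS1"})


class Locality(str, Enum):
    """Subcellular compartment served by an aaRS."""

    CYTOPLASMIC = "cytoplasmic"
    MITOCHONDRIAL = "mitochondrial"
    DUAL = "dual"


class Family(str, Enum):
    AARS = "aaRS"
    AIMP = "AIMP"
    REFERENCE = "reference"


class RegistryError(ValueError):
    """Raised when a registry or cancer-table file fails validation."""


@dataclass(frozen=True)
class GeneRecord:
    symbol: str
    locality: Locality
    family: Family
    msc_member: bool

    def __post_init__(self) -> None:
        if not self.symbol or not isinstance(self.symbol, str):
            raise RegistryError("gene symbol must be a non-empty string")


@dataclass(frozen=True)
class CancerType:
    abbreviation: str
    full_name: str
    median_os_months: float

    def __post_init__(self) -> None:
        if self.median_os_months <= 0:
            raise RegistryError(
                f"{self.abbreviation}: median_os_months must be positive, "
                f"got {self.median_os_months}"
            )


def _default_path(name: str) -> Path:
    return Path(str(resources.files("aarspan.data").joinpath(name)))


def load_gene_registry(
    path: Union[str, Path, None] = None,
    *,
    require_panel_invariants: bool = True,
) -> list[GeneRecord]:
    """Load and validate a gene registry TSV (symbol/locality/family/msc_member).

    With ``require_panel_invariants`` (the default) the file must describe the
    full analysis panel: 37 unique aaRS symbols (20 cytoplasmic, 19
    mitochondrial, counting the two dual-localized genes under both), 3
    AIMPs, and exactly the reference trio RB1/MYC/EIF4E.  Disable it to load
    a custom panel (duplicate symbols and unknown tokens are still errors).

    File order is preserved.
    """
    if path is None:
        path = _default_path("gene_registry.tsv")
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"symbol", "locality", "family"}
    missing = required - set(df.columns)
    if missing:
        raise RegistryError(f"registry file missing columns: {sorted(missing)}")
    if "msc_member" not in df.columns:
        df["msc_member"] = "false"

    records: list[GeneRecord] = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        symbol = str(row.symbol).strip()
        if symbol in seen:
            raise RegistryError(f"duplicate gene symbol: {symbol}")
        seen.add(symbol)
        try:
            locality = Locality(str(row.locality).strip())
        except ValueError:
            raise RegistryError(
                f"{symbol}: unknown locality token {row.locality!r}"
            ) from None
        try:
            family = Family(str(row.family).strip())
        except ValueError:
            raise RegistryError(
                f"{symbol}: unknown family token {row.family!r}"
            ) from None
        msc = str(row.msc_member).strip().lower() in {"true", "1", "yes"}
        records.append(GeneRecord(symbol, locality, family, msc))

    if require_panel_invariants:
        _check_panel(records)
    return records


def _check_panel(records: Sequence[GeneRecord]) -> None:
    refs = {r.symbol for r in records if r.family is Family.REFERENCE}
    if refs != REFERENCE_SYMBOLS:
        raise RegistryError(
            f"reference genes must be exactly {sorted(REFERENCE_SYMBOLS)}, got {sorted(refs)}"
        )
    dual = {r.symbol for r in records if r.locality is Locality.DUAL}
    if dual != DUAL_SYMBOLS:
        raise RegistryError(
            f"dual-localized genes must be exactly {sorted(DUAL_SYMBOLS)}, got {sorted(dual)}"
        )
    counts = locality_counts(records)
    expected = {"cytoplasmic": 20, "mitochondrial": 19, "unique_aars": 37, "aimp": 3}
    for key, want in expected.items():
        if counts[key] != want:
            raise RegistryError(
                f"panel composition: expected {want} {key} genes, found {counts[key]}"
            )


def locality_counts(records: Iterable[GeneRecord]) -> dict[str, int]:
    """Count aaRS genes per compartment, counting dual genes under both."""
    recs = list(records)
    aars = [r for r in recs if r.family is Family.AARS]
    cyto = sum(r.locality in (Locality.CYTOPLASMIC, Locality.DUAL) for r in aars)
    mito = sum(r.locality in (Locality.MITOCHONDRIAL, Locality.DUAL) for r in aars)
    return {
        "cytoplasmic": cyto,
        "mitochondrial": mito,
        "unique_aars": len(aars),
        "dual": sum(r.locality is Locality.DUAL for r in aars),
        "aimp": sum(r.family is Family.AIMP for r in recs),
        "reference": sum(r.family is Family.REFERENCE for r in recs),
    }


def aars_symbols(records: Iterable[GeneRecord]) -> list[str]:
    return [r.symbol for r in records if r.family is Family.AARS]


def load_cancer_table(path: Union[str, Path, None] = None) -> list[CancerType]:
    """Load the cancer catalog TSV (abbreviation/full_name/median_os_months).

    An empty file yields an empty list with a logged warning.
    """
    if path is None:
        path = _default_path("cancer_types.tsv")
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"abbreviation", "full_name", "median_os_months"}
    missing = required - set(df.columns)
    if missing:
        raise RegistryError(f"cancer table missing columns: {sorted(missing)}")
    if df.empty:
        logger.warning("cancer table %s is empty", path)
        return []

    cancers: list[CancerType] = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        abbr = str(row.abbreviation).strip()
        if abbr in seen:
            raise RegistryError(f"duplicate cancer abbreviation: {abbr}")
        seen.add(abbr)
        os_months = float(row.median_os_months)
        cancers.append(CancerType(abbr, str(row.full_name).strip(), os_months))
    return cancers


def sort_cancers_by_os(cancers: Sequence[CancerType]) -> list[CancerType]:
    """Order cancers by ascending median OS; ties break alphabetically.

    This is the canonical column order of every gene-by-cancer map.
    """
    return sorted(cancers, key=lambda c: (c.median_os_months, c.abbreviation))
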