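"""TCGA-like synthetic cohort generator with planted gene archetypes.

Every downstream stage of the pipeline is testable against cohorts whose
ground truth is known by construction.  Each gene carries one of three
archetypes:

* ``oncogene_like`` — amplification-biased copy-number calls, tumor
  expression shifted up, high expression raises the death hazard;
* ``suppressor_like`` — the mirror image (deletion-biased, shifted down,
  high expression protective);
* ``neutral`` — symmetric low-rate copy-number noise, no expression shift,
  no survival effect.

Per cancer the generator emits thresholded CNV calls (per-gene categorical
draws over {-2..+2}), a MAF-like mutation table (per-sample per-gene
Bernoulli hits with uniform protein positions), log-normal tumor and normal
expression on the log2(TPM+1) scale, and exponential survival times with
administrative censoring at a fixed horizon.

The survival effect keys on a *designated driver gene* per cancer: patients
in the upper half of that gene's tumor expression get hazard
``baseline_hazard * exp(log_hr_per_group)``.  Drivers are assigned
round-robin over the planted (non-neutral) genes, so with at least as many
cancers as planted genes every planted gene drives at least one cancer and
the true group hazard ratio for the driver in its own cancer is exactly
``exp(log_hr_per_group)`` — a clean parameter-recovery target.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .registry import (
    CancerType,
    aars_symbols,
    load_cancer_table,
    load_gene_registry,
    sort_cancers_by_os,
)
from .alterations import VALID_CALLS, CONSEQUENCES, CnvCallMatrix, MutationTable
from .diffexpr import Cohort, ExpressionMatrix
from .survival import SurvivalTable

__all__ = [
    "ARCHETYPES",
    "SyntheticConfig",
    "SyntheticCohort",
    "default_config",
    "make_null",
    "generate_cohort",
    "assign_drivers",
    "write_cohort",
    "read_cohort",
]

ARCHETYPES = ("oncogene_like", "suppressor_like", "neutral")

_CONSEQUENCE_PROBS = (0.70, 0.10, 0.08, 0.07, 0.05)  # over CONSEQUENCES

_DEFAULT_CNV_PROBS = {
    "oncogene_like": (0.01, 0.04, 0.60, 0.20, 0.15),
    "suppressor_like": (0.15, 0.20, 0.60, 0.04, 0.01),
    "neutral": (0.02, 0.08, 0.80, 0.08, 0.02),
}
_DEFAULT_SHIFT = {"oncogene_like": 1.0, "suppressor_like": -1.0, "neutral": 0.0}
_DEFAULT_LOG_HR = {"oncogene_like": 0.7, "suppressor_like": -0.7, "neutral": 0.0}


@dataclass
class SyntheticConfig:
    n_cancers: int
    n_tumor: int
    n_normal: int
    genes: list[str]
    archetype: dict[str, str]  # symbol -> archetype; unlisted genes are neutral
    cnv_probs: dict[str, tuple] = field(
        default_factory=lambda: dict(_DEFAULT_CNV_PROBS)
    )
    expr_base_log2: float = 5.0
    expr_sd_log2: float = 1.0
    expr_shift_log2: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_SHIFT)
    )
    mutation_rate: float = 0.02
    baseline_hazard: float = 0.03  # events per month
    log_hr_per_group: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_LOG_HR)
    )
    censor_horizon_months: float = 60.0
    protein_length: int = 500
    seed: int = 0
    cancer_names: list[str] = field(default_factory=list)
    cancer_os_months: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_cancers < 1:
            raise ValueError("n_cancers must be positive")
        if self.n_tumor < 4 or self.n_normal < 4:
            raise ValueError("n_tumor and n_normal must be >= 4")
        if not self.genes:
            raise ValueError("gene list is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene symbols")
        unknown = set(self.archetype) - set(self.genes)
        if unknown:
            raise ValueError(f"archetype map names unknown genes: {sorted(unknown)}")
        bad = set(self.archetype.values()) - set(ARCHETYPES)
        if bad:
            raise ValueError(f"unknown archetype tokens: {sorted(bad)}")
        for arch, probs in self.cnv_probs.items():
            p = np.asarray(probs, dtype=float)
            if p.shape != (5,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"{arch}: cnv_probs must be 5 non-negative "
                                 "values summing to 1")
        if self.expr_sd_log2 <= 0:
            raise ValueError("expr_sd_log2 must be positive")
        if not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must lie in [0, 1]")
        if self.baseline_hazard <= 0 or self.censor_horizon_months <= 0:
            raise ValueError("baseline_hazard and censor_horizon_months "
                             "must be positive")
        # archetype sign constraints: planted effects point the right way
        if self.expr_shift_log2.get("oncogene_like", 0) < 0 or \
           self.log_hr_per_group.get("oncogene_like", 0) < 0:
            raise ValueError("oncogene_like effects must be non-negative")
        if self.expr_shift_log2.get("suppressor_like", 0) > 0 or \
           self.log_hr_per_group.get("suppressor_like", 0) > 0:
            raise ValueError("suppressor_like effects must be non-positive")
        if self.expr_shift_log2.get("neutral", 0) != 0 or \
           self.log_hr_per_group.get("neutral", 0) != 0:
            raise ValueError("neutral effects must be zero")
        if not self.cancer_names:
            self.cancer_names = [f"CAN{i + 1:02d}" for i in range(self.n_cancers)]
            self.cancer_os_months = [
                10.0 + 5.0 * i for i in range(self.n_cancers)
            ]
        if len(self.cancer_names) != self.n_cancers or \
           len(self.cancer_os_months) != self.n_cancers:
            raise ValueError("cancer_names/cancer_os_months length mismatch")

    def archetype_of(self, gene: str) -> str:
        return self.archetype.get(gene, "neutral")

    def planted_genes(self) -> list[str]:
        return [g for g in self.genes if self.archetype_of(g) != "neutral"]

    def cancer_types(self) -> list[CancerType]:
        return [
            CancerType(name, name, os)
            for name, os in zip(self.cancer_names, self.cancer_os_months)
        ]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticConfig":
        d = dict(d)
        d["cnv_probs"] = {k: tuple(v) for k, v in d["cnv_probs"].items()}
        return cls(**d)


@dataclass
class SyntheticCohort:
    config: SyntheticConfig
    cancer_types: list[CancerType]
    cnv: dict[str, CnvCallMatrix]
    mutations: dict[str, MutationTable]
    expression_tumor: dict[str, ExpressionMatrix]
    expression_normal: dict[str, ExpressionMatrix]
    survival: dict[str, SurvivalTable]
    drivers: dict[str, Optional[str]]

    @property
    def cancers(self) -> list[str]:
        return [c.abbreviation for c in self.cancer_types]


def default_config(scenario: str) -> SyntheticConfig:
    """Built-in scenarios.

    ``small``: 4 synthetic cancers x 40 symbolic genes x 60 tumor / 30 normal
    samples, two oncogene_like and two suppressor_like genes planted; fast
    enough for continuous testing.  Seed 7.

    ``paper_like``: the 10 shortest-median-OS cancers of the packaged
    catalog, the full 43-gene panel, 200 tumor / 100 normal samples per
    cancer, five oncogene_like and five suppressor_like aaRS genes planted
    (chosen to mirror the amplification/deletion trends of the real
    pan-cancer data).  Seed 42.
    """
    if scenario == "small":
        genes = [f"G{i + 1:02d}" for i in range(40)]
        archetype = {
            "G01": "oncogene_like",
            "G02": "oncogene_like",
            "G03": "suppressor_like",
            "G04": "suppressor_like",
        }
        return SyntheticConfig(
            n_cancers=4, n_tumor=60, n_normal=30,
            genes=genes, archetype=archetype, seed=7,
        )
    if scenario == "paper_like":
        registry = load_gene_registry()
        cancers = sort_cancers_by_os(load_cancer_table())[:10]
        archetype = {
            "GARS1": "oncogene_like",
            "TARS1": "oncogene_like",
            "EPRS1": "oncogene_like",
            "DARS2": "oncogene_like",
            "AIMP2": "oncogene_like",
            "NARS1": "suppressor_like",
            "SARS1": "suppressor_like",
            "QARS1": "suppressor_like",
            "LARS2": "suppressor_like",
            "RARS2": "suppressor_like",
        }
        return SyntheticConfig(
            n_cancers=10, n_tumor=200, n_normal=100,
            genes=[r.symbol for r in registry], archetype=archetype, seed=42,
            cancer_names=[c.abbreviation for c in cancers],
            cancer_os_months=[c.median_os_months for c in cancers],
        )
    raise ValueError(f"unknown scenario {scenario!r}; use 'small' or 'paper_like'")


def make_null(config: SyntheticConfig) -> SyntheticConfig:
    """Copy of a config with every planted effect removed (all genes neutral)."""
    return dataclasses.replace(config, archetype={})


def assign_drivers(config: SyntheticConfig) -> dict[str, Optional[str]]:
    """Round-robin driver gene per cancer over the planted genes, in panel order."""
    planted = config.planted_genes()
    return {
        name: (planted[i % len(planted)] if planted else None)
        for i, name in enumerate(config.cancer_names)
    }


def _back_transform(log2_values: np.ndarray) -> np.ndarray:
    """log2(TPM+1) -> TPM, clipped at zero so expression is never negative."""
    return np.clip(np.exp2(log2_values) - 1.0, 0.0, None)


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Draw a fully reproducible cohort from one RNG stream seeded once."""
    rng = np.random.default_rng(config.seed)
    drivers = assign_drivers(config)
    calls = np.array(VALID_CALLS)

    cnv: dict[str, CnvCallMatrix] = {}
    mutations: dict[str, MutationTable] = {}
    expr_t: dict[str, ExpressionMatrix] = {}
    expr_n: dict[str, ExpressionMatrix] = {}
    survival: dict[str, SurvivalTable] = {}

    for cancer in config.cancer_names:
        tumor_ids = [f"{cancer}-T{i + 1:04d}" for i in range(config.n_tumor)]
        normal_ids = [f"{cancer}-N{i + 1:04d}" for i in range(config.n_normal)]

        # CNV calls, one categorical draw per gene per tumor sample
        cnv_rows = np.empty((len(config.genes), config.n_tumor), dtype=int)
        for gi, gene in enumerate(config.genes):
            probs = np.asarray(config.cnv_probs[config.archetype_of(gene)])
            cnv_rows[gi] = rng.choice(calls, size=config.n_tumor, p=probs)
        cnv[cancer] = CnvCallMatrix(
            pd.DataFrame(cnv_rows, index=config.genes, columns=tumor_ids)
        )

        # mutations: Bernoulli hits, uniform protein positions
        mut_records = []
        for gene in config.genes:
            hits = rng.random(config.n_tumor) < config.mutation_rate
            for si in np.flatnonzero(hits):
                mut_records.append(
                    (
                        tumor_ids[si],
                        gene,
                        int(rng.integers(1, config.protein_length + 1)),
                        str(rng.choice(CONSEQUENCES, p=_CONSEQUENCE_PROBS)),
                    )
                )
        if mut_records:
            mut_df = pd.DataFrame(
                mut_records, columns=list(MutationTable.COLUMNS)
            )
            mut_df["protein_position"] = mut_df["protein_position"].astype("Int64")
            mutations[cancer] = MutationTable(mut_df)
        else:
            mutations[cancer] = MutationTable.empty()

        # expression on the log2(TPM+1) scale, archetype shift in tumors
        shifts = np.array(
            [config.expr_shift_log2[config.archetype_of(g)] for g in config.genes]
        )
        log_t = rng.normal(
            config.expr_base_log2 + shifts[:, None],
            config.expr_sd_log2,
            size=(len(config.genes), config.n_tumor),
        )
        log_n = rng.normal(
            config.expr_base_log2,
            config.expr_sd_log2,
            size=(len(config.genes), config.n_normal),
        )
        expr_t[cancer] = ExpressionMatrix(
            pd.DataFrame(_back_transform(log_t), index=config.genes,
                         columns=tumor_ids),
            Cohort.TUMOR,
        )
        expr_n[cancer] = ExpressionMatrix(
            pd.DataFrame(_back_transform(log_n), index=config.genes,
                         columns=normal_ids),
            Cohort.NORMAL,
        )

        # survival: exponential times, hazard raised/lowered for the upper
        # median-split half of the driver gene's tumor expression
        driver = drivers[cancer]
        high = np.zeros(config.n_tumor, dtype=bool)
        log_hr = 0.0
        if driver is not None:
            values = expr_t[cancer].values.loc[driver].to_numpy()
            high = values > np.median(values)
            log_hr = config.log_hr_per_group[config.archetype_of(driver)]
        hazard = config.baseline_hazard * np.exp(log_hr * high)
        raw_times = rng.exponential(1.0 / hazard)
        event = raw_times <= config.censor_horizon_months
        times = np.minimum(raw_times, config.censor_horizon_months)
        survival[cancer] = SurvivalTable(
            pd.DataFrame(
                {
                    "sample_id": tumor_ids,
                    "time_months": times,
                    "event": event.astype(int),
                }
            )
        )

    return SyntheticCohort(
        config=config,
        cancer_types=config.cancer_types(),
        cnv=cnv,
        mutations=mutations,
        expression_tumor=expr_t,
        expression_normal=expr_n,
        survival=survival,
        drivers=drivers,
    )


def write_cohort(cohort: SyntheticCohort, out_dir: Union[str, Path]) -> list[Path]:
    """Write every per-cancer table as TSV plus the generating config as JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    cancers_df = pd.DataFrame(
        {
            "abbreviation": [c.abbreviation for c in cohort.cancer_types],
            "full_name": [c.full_name for c in cohort.cancer_types],
            "median_os_months": [c.median_os_months for c in cohort.cancer_types],
        }
    )
    path = out / "cancers.tsv"
    cancers_df.to_csv(path, sep="\t", index=False)
    written.append(path)

    for cancer in cohort.cancers:
        for suffix, writer in (
            (".cnv.tsv", cohort.cnv[cancer].to_tsv),
            (".mutations.tsv", cohort.mutations[cancer].to_tsv),
            (".tumor.tsv", cohort.expression_tumor[cancer].to_tsv),
            (".normal.tsv", cohort.expression_normal[cancer].to_tsv),
            (".survival.tsv", cohort.survival[cancer].to_tsv),
        ):
            p = out / f"{cancer}{suffix}"
            writer(p)
            written.append(p)

    cfg_path = out / "cohort_config.json"
    cfg_path.write_text(
        json.dumps(cohort.config.to_dict(), indent=2, sort_keys=True) + "\n"
    )
    written.append(cfg_path)
    return written


def read_cohort(in_dir: Union[str, Path]) -> SyntheticCohort:
    """Load a cohort previously written by :func:`write_cohort`."""
    src = Path(in_dir)
    cfg = SyntheticConfig.from_dict(
        json.loads((src / "cohort_config.json").read_text())
    )
    cancers_df = pd.read_csv(src / "cancers.tsv", sep="\t")
    cancer_types = [
        CancerType(str(r.abbreviation), str(r.full_name), float(r.median_os_months))
        for r in cancers_df.itertuples(index=False)
    ]
    cnv, mutations, expr_t, expr_n, survival = {}, {}, {}, {}, {}
    for c in cancer_types:
        name = c.abbreviation
        cnv[name] = CnvCallMatrix.from_tsv(src / f"{name}.cnv.tsv")
        mutations[name] = MutationTable.from_tsv(src / f"{name}.mutations.tsv")
        expr_t[name] = ExpressionMatrix.from_tsv(src / f"{name}.tumor.tsv",
                                                 Cohort.TUMOR)
        expr_n[name] = ExpressionMatrix.from_tsv(src / f"{name}.normal.tsv",
                                                 Cohort.NORMAL)
        survival[name] = SurvivalTable.from_tsv(src / f"{name}.survival.tsv")
    return SyntheticCohort(
        config=cfg,
        cancer_types=cancer_types,
        cnv=cnv,
        mutations=mutations,
        expression_tumor=expr_t,
        expression_normal=expr_n,
        survival=survival,
        drivers=assign_drivers(cfg),
    )
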