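"""End-to-end orchestration: cohort -> four analysis stages -> ranked output.

Stage order mirrors the evidence levels: genomic alterations (GISTIC
heatmap, alteration frequencies, mutation tallies), tumor-vs-normal
differential expression, expression-stratified survival, and the
three-level score integration.  All gene-by-cancer outputs share the
ascending-median-OS column order.  A JSON manifest records the seed,
thresholds and config so a run can be reproduced bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from . import __version__
from .alterations import alteration_frequency, gistic_heatmap, mutation_position_tally
from .diffexpr import de_map
from .integration import (
    RawScores,
    composite_rank,
    correlation_report,
    dna_score,
    mrna_score,
    ranking_frame,
    survival_score,
)
from .survival import survival_map
from .synthetic import (
    SyntheticCohort,
    SyntheticConfig,
    default_config,
    generate_cohort,
    read_cohort,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "run_pipeline"]


@dataclass
class RunConfig:
    mode: str  # synthetic | ingest
    out_dir: Union[str, Path]
    synthetic: Optional[SyntheticConfig] = None
    input_dir: Optional[Union[str, Path]] = None
    fc_threshold: float = 1.5
    q_de: float = 0.05
    q_surv: float = 0.05
    hotspot_min: int = 3
    seed: Optional[int] = None  # overrides the synthetic config seed

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "ingest"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.fc_threshold <= 0 or self.hotspot_min <= 0:
            raise ValueError("thresholds must be positive")
        for q in (self.q_de, self.q_surv):
            if not 0 < q < 1:
                raise ValueError("q thresholds must lie in (0, 1)")
        if self.mode == "synthetic" and self.synthetic is None:
            raise ValueError("synthetic mode requires a SyntheticConfig")
        if self.mode == "ingest" and self.input_dir is None:
            raise ValueError("ingest mode requires input_dir")

    @classmethod
    def from_manifest(
        cls, path: Union[str, Path], out_dir: Union[str, Path, None] = None
    ) -> "RunConfig":
        """Rebuild the run configuration recorded in a manifest.

        Outputs go back to the manifest's own directory unless ``out_dir``
        is given, so a rerun reproduces the original bit-for-bit.
        """
        path = Path(path)
        d = json.loads(path.read_text())
        syn = d.get("synthetic_config")
        return cls(
            mode=d["mode"],
            out_dir=out_dir if out_dir is not None else path.parent,
            synthetic=SyntheticConfig.from_dict(syn) if syn else None,
            input_dir=d.get("input_dir"),
            fc_threshold=d["thresholds"]["fc_threshold"],
            q_de=d["thresholds"]["q_de"],
            q_surv=d["thresholds"]["q_surv"],
            hotspot_min=d["thresholds"]["hotspot_min"],
            seed=d.get("seed"),
        )


@dataclass
class RunReport:
    outputs: dict[str, Path]
    summary: dict[str, float]
    warnings: list[str] = field(default_factory=list)


def _obtain_cohort(config: RunConfig) -> SyntheticCohort:
    if config.mode == "ingest":
        return read_cohort(config.input_dir)
    syn = config.synthetic
    if config.seed is not None:
        syn = dataclasses.replace(syn, seed=config.seed)
    return generate_cohort(syn)


def run_pipeline(config: RunConfig) -> RunReport:
    """Run every stage and write all tabular outputs plus the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    warnings: list[str] = []
    stage = "cohort"
    try:
        t0 = time.perf_counter()
        cohort = _obtain_cohort(config)
        genes = cohort.config.genes
        cancers = cohort.cancer_types
        logger.info("cohort ready (%.2fs)", time.perf_counter() - t0)

        stage = "alterations"
        t0 = time.perf_counter()
        heatmap = gistic_heatmap(cohort.cnv, genes, cancers)
        outputs["gistic_heatmap"] = out / "gistic_heatmap.tsv"
        heatmap.to_csv(outputs["gistic_heatmap"], sep="\t",
                       index_label="symbol", float_format="%.6g")

        freq_rows = []
        for cancer in cohort.cancers:
            for prof in alteration_frequency(
                cohort.cnv[cancer], cohort.mutations[cancer], cancer
            ):
                freq_rows.append(
                    {"symbol": prof.gene, "cancer": prof.cancer,
                     **prof.counts, "n_profiled": prof.n_profiled,
                     "alteration_frequency": prof.alteration_frequency}
                )
        outputs["alteration_frequency"] = out / "alteration_frequency.tsv"
        pd.DataFrame(freq_rows).to_csv(
            outputs["alteration_frequency"], sep="\t", index=False,
            float_format="%.6g"
        )

        hotspot_rows = []
        for cancer in cohort.cancers:
            muts = cohort.mutations[cancer]
            for gene in genes:
                _, hotspots = mutation_position_tally(
                    muts, gene, cohort.config.protein_length,
                    hotspot_min=config.hotspot_min,
                )
                for pos, count in hotspots:
                    hotspot_rows.append(
                        {"symbol": gene, "cancer": cancer,
                         "residue": pos, "count": count}
                    )
        outputs["mutation_hotspots"] = out / "mutation_hotspots.tsv"
        pd.DataFrame(
            hotspot_rows, columns=["symbol", "cancer", "residue", "count"]
        ).to_csv(outputs["mutation_hotspots"], sep="\t", index=False)
        logger.info("alterations stage done (%.2fs)", time.perf_counter() - t0)

        stage = "diffexpr"
        t0 = time.perf_counter()
        de = de_map(
            cohort.expression_tumor, cohort.expression_normal, genes, cancers,
            fc_threshold=config.fc_threshold, q_threshold=config.q_de,
        )
        outputs["de_calls"] = out / "de_calls.tsv"
        de.calls_tsv(outputs["de_calls"])
        outputs["de_totals"] = out / "de_totals.tsv"
        de.totals_tsv(outputs["de_totals"])
        logger.info("diffexpr stage done (%.2fs)", time.perf_counter() - t0)

        stage = "survival"
        t0 = time.perf_counter()
        surv = survival_map(
            cohort.expression_tumor, cohort.survival, genes, cancers,
            q_threshold=config.q_surv,
        )
        outputs["survival_map"] = out / "survival_map.tsv"
        surv.map_tsv(outputs["survival_map"])
        outputs["survival_totals"] = out / "survival_totals.tsv"
        surv.totals_tsv(outputs["survival_totals"])
        logger.info("survival stage done (%.2fs)", time.perf_counter() - t0)

        stage = "integration"
        t0 = time.perf_counter()
        raw = [
            RawScores(
                gene=g,
                dna=dna_score(heatmap.loc[g]),
                mrna=mrna_score(int(de.totals.loc[g, "n_up"]),
                                int(de.totals.loc[g, "n_down"])),
                survival=survival_score(
                    int(surv.totals.loc[g, "n_unfavorable"]),
                    int(surv.totals.loc[g, "n_favorable"]),
                ),
            )
            for g in genes
        ]
        scores = composite_rank(raw)
        outputs["integration_ranking"] = out / "integration_ranking.tsv"
        ranking_frame(scores).to_csv(
            outputs["integration_ranking"], sep="\t", index=False,
            float_format="%.6g"
        )
        outputs["correlations"] = out / "correlations.tsv"
        correlation_report(scores).to_csv(
            outputs["correlations"], sep="\t", index=False, float_format="%.6g"
        )
        logger.info("integration stage done (%.2fs)", time.perf_counter() - t0)
    except Exception:
        for path in outputs.values():
            if path.exists():
                path.rename(path.with_suffix(path.suffix + ".partial"))
        logger.error("pipeline aborted during stage %r", stage)
        raise

    # paths recorded relative to the manifest so that identical runs into
    # different directories produce byte-identical manifests
    manifest = {
        "package": "aarspan",
        "version": __version__,
        "mode": config.mode,
        "input_dir": str(config.input_dir) if config.input_dir else None,
        "seed": config.seed if config.seed is not None
        else (cohort.config.seed if config.mode == "synthetic" else None),
        "thresholds": {
            "fc_threshold": config.fc_threshold,
            "q_de": config.q_de,
            "q_surv": config.q_surv,
            "hotspot_min": config.hotspot_min,
        },
        "synthetic_config": cohort.config.to_dict()
        if config.mode == "synthetic" else None,
        "drivers": cohort.drivers,
        "outputs": {k: v.name for k, v in sorted(outputs.items())},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    outputs["manifest"] = manifest_path

    n_sig_surv = int(surv.totals.sum().sum())
    summary = {
        "n_genes": float(len(genes)),
        "n_cancers": float(len(cancers)),
        "n_de_up_calls": float((de.calls == 1).sum().sum()),
        "n_de_down_calls": float((de.calls == -1).sum().sum()),
        "n_survival_significant": float(n_sig_surv),
    }
    return RunReport(outputs=outputs, summary=summary, warnings=warnings)
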