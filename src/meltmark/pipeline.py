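"""End-to-end pipeline: simulate or load inputs, run both headline analyses.

Stage 1 (tissue): per-cancer hypermethylation cutoffs and frequencies versus
driver-gene mutation frequencies (a Table-3-style summary). Stage 2 (plasma):
normalized methylated-fragment counts classified case versus control by ROC
with Youden-optimal cutoffs (a Table-4-style summary), plus ddPCR KRAS
detection rates and MtAF classification.
"""

from __future__ import annotations

import datetime
import logging
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import __version__
from . import io as mio
from ._utils import round_half_up
from .array_marker import marker_vs_mutation_table, summarize_cutoffs
from .classify_stats import roc_curve
from .ddpcr_mtaf import DdpcrSample, cohort_detection
from .dreaming_melt import (
    DreamingSample,
    MeltModel,
    count_methylated_fragments,
)
from .synthetic_cohorts import (
    CohortConfig,
    generate_beta_cohort,
    generate_ddpcr_cohort,
    generate_plasma_cohort,
)

logger = logging.getLogger(__name__)


def call_samples_from_sheet(
    sample_sheet: pd.DataFrame,
    well_calls: Mapping[str, Sequence],
) -> list[DreamingSample]:
    """Join per-well calls onto the sample sheet, count, and normalize."""
    samples = []
    for row in sample_sheet.itertuples(index=False):
        calls = list(well_calls.get(row.sample_id, []))
        n_amplified = sum(1 for c in calls if c.amplified)
        dropped = len(calls) - n_amplified
        if dropped:
            logger.info("sample %s: %d wells flagged no-amplification", row.sample_id, dropped)
        samples.append(
            DreamingSample(
                sample_id=row.sample_id,
                group=row.group,
                stage=None if pd.isna(row.stage) else row.stage,
                starting_plasma_volume_ml=float(row.starting_plasma_volume_ml),
                fraction_loaded=float(row.fraction_loaded),
                methylated_fragments=count_methylated_fragments(calls),
                n_wells=n_amplified,
                well_calls=tuple(calls),
            )
        )
    return samples


def classify_on_scores(
    samples: pd.DataFrame,
    control_group: str = "control",
    score_column: str = "fragments_per_ml",
    group_column: str = "group",
) -> pd.DataFrame:
    """Table-4-style summary: one ROC row per case group versus the controls."""
    controls = samples.loc[samples[group_column] == control_group, score_column].to_numpy()
    if controls.size == 0:
        raise ValueError(f"no samples in control group {control_group!r}")
    rows = []
    for group in sorted(samples[group_column].unique()):
        if group == control_group:
            continue
        cases = samples.loc[samples[group_column] == group, score_column].to_numpy()
        roc = roc_curve(cases, controls)
        rows.append(
            {
                "group": group,
                "cutoff": round_half_up(roc.optimal_cutoff, 2),
                "auc": round_half_up(roc.auc, 2),
                "tpr": round_half_up(roc.optimal.tpr, 2),
                "fpr": round_half_up(roc.optimal.fpr, 2),
                "n_cases": roc.n_cases,
                "n_controls": roc.n_controls,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(
    config: CohortConfig,
    out_dir: str | Path,
    simulate: bool = True,
    command: str = "run",
    melt_model: Optional[MeltModel] = None,
) -> Path:
    """Execute both analysis stages end-to-end and write a results tree.

    With ``simulate`` the synthetic generators produce every input file
    first; the analysis stages then read back only what they would receive
    from real data. Returns the output directory. Outputs are byte-identical
    across runs with the same (config, seed).
    """
    out = Path(out_dir)
    inputs = out / "inputs"
    results = out / "results"
    inputs.mkdir(parents=True, exist_ok=True)
    results.mkdir(parents=True, exist_ok=True)

    if not simulate:
        raise NotImplementedError(
            "run_pipeline currently orchestrates the simulate-then-analyze flow; "
            "use the stage functions (marker_vs_mutation_table, classify_on_scores) "
            "or per-stage CLI commands on real input files"
        )

    # ---- generate inputs
    tissue = generate_beta_cohort(config)
    plasma = generate_plasma_cohort(config)
    droplets = generate_ddpcr_cohort(config)
    mio.write_beta_tsv(tissue.betas, inputs / "betas.tsv")
    for ct, table in tissue.mutations.items():
        mio.write_mutation_tsv(table, inputs / f"mutations_{ct}.tsv")
    mio.write_gene_sets_json(tissue.gene_sets, inputs / "gene_sets.json")
    mio.write_dreaming_tsv(plasma, inputs / "dreaming_samples.tsv")
    mio.write_droplet_csv(droplets, inputs / "droplets.csv")

    # ---- stage 1: tissue marker screening
    summaries = marker_vs_mutation_table(
        tissue.betas,
        tissue.mutations,
        tissue.gene_sets,
        exclusion=config.exclusion,
        ratio_gene="TP53" if all(
            "TP53" in t.calls.columns for t in tissue.mutations.values()
        ) else None,
    )
    mio.write_marker_summary_tsv(summaries, results / "marker_summary.tsv")
    mio.write_marker_summary_json(summaries, results / "marker_summary.json")
    cutoffs = summarize_cutoffs(summaries)
    (results / "cutoff_summary.json").write_text(
        '{"min": %.6f, "median": %.6f, "max": %.6f}\n'
        % (cutoffs["min"], cutoffs["median"], cutoffs["max"])
    )

    # ---- stage 2: plasma classification
    frame = mio.read_dreaming_tsv(inputs / "dreaming_samples.tsv")
    table4 = classify_on_scores(frame)
    table4.to_csv(results / "plasma_classification.tsv", sep="\t", index=False)

    # ---- stage 2b: ddPCR detection + MtAF classification
    ddpcr_samples = mio.read_droplet_csv(inputs / "droplets.csv")
    detection = cohort_detection(ddpcr_samples)
    pd.DataFrame(
        [
            {
                "group": d.group,
                "n_samples": d.n_samples,
                "n_detected": d.n_detected,
                "pct_detected": d.pct_detected,
            }
            for d in detection.values()
        ]
    ).to_csv(results / "kras_detection.tsv", sep="\t", index=False)
    mio.write_mtaf_tsv(ddpcr_samples, results / "kras_mtaf.tsv")
    mtaf_frame = pd.DataFrame(
        [
            {"group": s.group, "mtaf": s.mtaf if s.mtaf is not None else 0.0}
            for s in ddpcr_samples
            if s.group in ("control", "pancreatic_late")
        ]
    )
    if (mtaf_frame["group"] == "pancreatic_late").any():
        mtaf_table = classify_on_scores(mtaf_frame, score_column="mtaf")
        mtaf_table.to_csv(results / "kras_mtaf_classification.tsv", sep="\t", index=False)

    manifest = mio.RunManifest(
        command=command,
        seed=config.seed,
        config=config.to_dict(),
        input_digests={
            p.name: mio.file_digest(p) for p in sorted(inputs.iterdir())
        },
        version=__version__,
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
    )
    mio.write_manifest(manifest, out / "manifest.json")
    return out
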