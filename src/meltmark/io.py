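"""Plain-text readers and writers for every pipeline format.

All formats are TSV/CSV/JSON (diffable, no binary containers). Readers
validate against the domain-type invariants and report offending file, line
(1-based, header = line 1) and column; writers round-trip losslessly through
the corresponding reader. Unknown columns are preserved with a warning.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .array_marker import BETA_COLUMNS, BetaCohort, GeneSet, MarkerSummary, MutationTable
from .classify_stats import RocResult
from .ddpcr_mtaf import DdpcrReaction, DdpcrSample
from .dreaming_melt import DreamingSample, MeltCurve, WellCall

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """A file violated its schema; message names file, line and column."""


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        warnings.warn(f"{path}: unknown columns {extra} preserved", stacklevel=3)


# ---------------------------------------------------------------- beta TSV

def read_beta_tsv(path: str | Path) -> BetaCohort:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "stage": str, "sex": str})
    _require_columns(df, BETA_COLUMNS, path)
    beta = pd.to_numeric(df["beta"], errors="coerce")
    bad = df.index[df["beta"].notna() & beta.isna()].tolist()
    bad += df.index[(beta < 0) | (beta > 1)].tolist()
    if bad:
        line = int(sorted(bad)[0]) + 2  # +1 header, +1 one-based
        raise SchemaError(f"{path}: line {line}, column 'beta': value outside [0, 1]")
    df["beta"] = beta
    return BetaCohort.from_frame(df)


def write_beta_tsv(cohort: BetaCohort, path: str | Path) -> None:
    cohort.samples.reindex(columns=BETA_COLUMNS).to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------ mutation TSV

def read_mutation_tsv(path: str | Path) -> MutationTable:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise SchemaError(f"{path}: first column must be sample_id")
    df = df.set_index("sample_id")
    bad = df.apply(lambda col: ~col.isin([0, 1])).any(axis=1)
    if bad.any():
        line = int(np.where(bad)[0][0]) + 2
        raise SchemaError(f"{path}: line {line}: mutation calls must be 0/1")
    return MutationTable(calls=df.astype(bool))


def write_mutation_tsv(table: MutationTable, path: str | Path) -> None:
    table.calls.astype(int).to_csv(path, sep="\t")


# ----------------------------------------------------------- gene-set JSON

def read_gene_sets_json(path: str | Path) -> dict[str, GeneSet]:
    """Read ``{cancer_type: [genes]}`` or ``{cancer_type: {gene: prevalence}}``."""
    path = Path(path)
    with open(path) as fh:
        raw = json.load(fh)
    out: dict[str, GeneSet] = {}
    for ct, genes in raw.items():
        if isinstance(genes, dict):
            out[ct] = GeneSet(cancer_type=ct, genes=tuple(genes), prevalences=dict(genes))
        else:
            out[ct] = GeneSet(cancer_type=ct, genes=tuple(genes))
    return out


def write_gene_sets_json(gene_sets: Mapping[str, GeneSet], path: str | Path) -> None:
    payload = {
        ct: (dict(gs.prevalences) if gs.prevalences else list(gs.genes))
        for ct, gs in gene_sets.items()
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)  # preserve gene order for round-trip
        fh.write("\n")


# ---------------------------------------------------------- DREAMing files

SAMPLE_SHEET_COLUMNS = ["sample_id", "group", "stage", "starting_plasma_volume_ml", "fraction_loaded"]


def read_sample_sheet_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, dtype={"sample_id": str, "group": str, "stage": str})
    _require_columns(df, SAMPLE_SHEET_COLUMNS, path)
    bad = df.index[(df["fraction_loaded"] <= 0) | (df["fraction_loaded"] > 1)].tolist()
    if bad:
        raise SchemaError(
            f"{path}: line {bad[0] + 2}, column 'fraction_loaded': must lie in (0, 1]"
        )
    return df


def read_well_curves_csv(path: str | Path) -> dict[str, dict[str, MeltCurve]]:
    """Long-format raw curves: ``sample_id,well_id,temperature,signal``."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"sample_id": str, "well_id": str})
    _require_columns(df, ["sample_id", "well_id", "temperature", "signal"], path)
    out: dict[str, dict[str, MeltCurve]] = {}
    for (sid, wid), grp in df.groupby(["sample_id", "well_id"], sort=True):
        grp = grp.sort_values("temperature")
        out.setdefault(sid, {})[wid] = MeltCurve(
            temperatures=grp["temperature"].to_numpy(float),
            signal=grp["signal"].to_numpy(float),
        )
    return out


def write_well_curves_csv(
    curves: Mapping[str, Mapping[str, MeltCurve]], path: str | Path
) -> None:
    frames = []
    for sid, wells in curves.items():
        for wid, curve in wells.items():
            frames.append(
                pd.DataFrame(
                    {
                        "sample_id": sid,
                        "well_id": wid,
                        "temperature": curve.temperatures,
                        "signal": curve.signal,
                    }
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_well_peaks_csv(path: str | Path) -> dict[str, list[WellCall]]:
    """Pre-called peaks dialect: ``sample_id,well_id,primary_tm,secondary_tm``.

    An empty ``secondary_tm`` means an unmethylated well; an empty
    ``primary_tm`` *and* ``secondary_tm`` marks a non-amplified well.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"sample_id": str, "well_id": str})
    _require_columns(df, ["sample_id", "well_id", "primary_tm", "secondary_tm"], path)
    out: dict[str, list[WellCall]] = {}
    for row in df.itertuples(index=False):
        primary = None if pd.isna(row.primary_tm) else float(row.primary_tm)
        secondary = None if pd.isna(row.secondary_tm) else float(row.secondary_tm)
        if primary is None and secondary is None:
            call = WellCall(primary_peak_tm=None, amplified=False)
        else:
            call = WellCall(
                primary_peak_tm=primary,
                secondary_peak_tm=secondary,
                is_methylated=secondary is not None,
            )
        out.setdefault(row.sample_id, []).append(call)
    return out


DREAMING_TSV_COLUMNS = [
    "sample_id",
    "group",
    "stage",
    "n_wells",
    "methylated_wells",
    "starting_plasma_volume_ml",
    "fraction_loaded",
    "equivalent_volume_ml",
    "fragments_per_ml",
]


def write_dreaming_tsv(samples: Sequence[DreamingSample], path: str | Path) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "group": s.group,
            "stage": s.stage,
            "n_wells": s.n_wells,
            "methylated_wells": s.methylated_fragments,
            "starting_plasma_volume_ml": s.starting_plasma_volume_ml,
            "fraction_loaded": s.fraction_loaded,
            "equivalent_volume_ml": s.equivalent_volume_ml,
            "fragments_per_ml": s.fragments_per_ml,
        }
        for s in samples
    ]
    pd.DataFrame(rows, columns=DREAMING_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_dreaming_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str, "stage": str})
    _require_columns(df, DREAMING_TSV_COLUMNS, path)
    return df


# ------------------------------------------------------------- droplet CSV

DROPLET_COLUMNS = [
    "sample_id",
    "group",
    "reaction_id",
    "mutant_droplets",
    "wildtype_droplets",
    "plasma_volume_assayed_ml",
]


def read_droplet_csv(path: str | Path) -> list[DdpcrSample]:
    path = Path(path)
    df = pd.read_csv(path, dtype={"sample_id": str, "group": str, "reaction_id": str})
    _require_columns(df, DROPLET_COLUMNS, path)
    neg = df.index[(df["mutant_droplets"] < 0) | (df["wildtype_droplets"] < 0)].tolist()
    if neg:
        raise SchemaError(f"{path}: line {neg[0] + 2}: droplet counts must be >= 0")
    samples = []
    for (sid, group), grp in df.groupby(["sample_id", "group"], sort=True):
        volumes = grp["plasma_volume_assayed_ml"].unique()
        if len(volumes) > 1:
            raise SchemaError(f"{path}: sample {sid}: inconsistent plasma volumes")
        samples.append(
            DdpcrSample(
                sample_id=sid,
                group=group,
                reactions=tuple(
                    DdpcrReaction(int(r.mutant_droplets), int(r.wildtype_droplets))
                    for r in grp.itertuples(index=False)
                ),
                plasma_volume_assayed_ml=float(volumes[0]),
            )
        )
    return samples


def write_droplet_csv(samples: Sequence[DdpcrSample], path: str | Path) -> None:
    rows = []
    for s in samples:
        for j, r in enumerate(s.reactions):
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "group": s.group,
                    "reaction_id": f"r{j + 1}",
                    "mutant_droplets": r.mutant_droplets,
                    "wildtype_droplets": r.wildtype_droplets,
                    "plasma_volume_assayed_ml": s.plasma_volume_assayed_ml,
                }
            )
    pd.DataFrame(rows, columns=DROPLET_COLUMNS).to_csv(path, index=False)


MTAF_TSV_COLUMNS = ["sample_id", "group", "raw_fraction", "mtaf_per_ml", "detected"]


def write_mtaf_tsv(samples: Sequence[DdpcrSample], path: str | Path) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "group": s.group,
            "raw_fraction": s.raw_fraction,
            "mtaf_per_ml": s.mtaf,
            "detected": s.detected,
        }
        for s in samples
    ]
    pd.DataFrame(rows, columns=MTAF_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------- scores & ROC

def read_score_csv(path: str | Path) -> pd.DataFrame:
    """Two-column per-sample scores: ``sample_id,score`` (extra columns kept)."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"sample_id": str})
    if "sample_id" not in df.columns or "score" not in df.columns:
        raise SchemaError(f"{path}: need columns sample_id,score")
    return df


def write_roc_json(roc: RocResult, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(roc.to_dict(), fh, indent=2)
        fh.write("\n")


def write_roc_coordinates_tsv(roc: RocResult, path: str | Path) -> None:
    pd.DataFrame(
        {"threshold": roc.thresholds, "fpr": roc.fpr, "tpr": roc.tpr}
    ).to_csv(path, sep="\t", index=False)


# ------------------------------------------------------- marker summaries

MARKER_SUMMARY_COLUMNS = [
    "cancer_type",
    "cutoff",
    "n_tumors",
    "n_hypermethylated",
    "pct_hypermethylated",
    "pct_mutated",
    "ratio_vs_gene",
]


def write_marker_summary_tsv(summaries: Sequence[MarkerSummary], path: str | Path) -> None:
    pd.DataFrame(
        [dataclasses.asdict(s) for s in summaries], columns=MARKER_SUMMARY_COLUMNS
    ).to_csv(path, sep="\t", index=False)


def write_marker_summary_json(summaries: Sequence[MarkerSummary], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump([dataclasses.asdict(s) for s in summaries], fh, indent=2)
        fh.write("\n")


# ---------------------------------------------------------------- manifest

@dataclass(frozen=True)
class RunManifest:
    """Provenance record written once per pipeline output directory."""

    command: str
    seed: int
    config: dict
    input_digests: dict[str, str]
    version: str
    timestamp: str


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(manifest: RunManifest, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(manifest), fh, indent=2, default=str)
        fh.write("\n")


def read_manifest(path: str | Path) -> RunManifest:
    with open(path) as fh:
        return RunManifest(**json.load(fh))
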