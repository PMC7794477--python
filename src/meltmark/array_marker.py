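"""Tissue-level marker screening at a single methylation-array probe.

The screening question: across solid tumor types, is hypermethylation of the
ZNF154 CpG island (array probe cg21790626) at least as recurrent as the most
common driver-gene mutations? For each cancer type a beta-value cutoff is set
at the empirical quantile excluding a stated fraction (default 95%) of that
type's normal-tissue controls; a tumor whose beta value strictly exceeds the
cutoff is called hypermethylated. The hypermethylation frequency is then
compared against the fraction of tumors carrying a non-silent SNV in a
curated per-cancer driver gene set.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from ._utils import as_float_array, percent, round_half_up
from .classify_stats import pearson_r

logger = logging.getLogger(__name__)

DEFAULT_PROBE_ID = "cg21790626"
#: Beta value below which peripheral blood is conventionally "lowly methylated".
BLOOD_BETA_THRESHOLD = 0.2

BETA_COLUMNS = ["sample_id", "cancer_type", "group", "stage", "age", "sex", "beta"]


@dataclass(frozen=True)
class BetaCohort:
    """Annotated beta values at one probe for tumor and control samples.

    ``samples`` holds one row per sample with columns ``sample_id``,
    ``cancer_type``, ``group`` ("tumor"/"control"), ``stage``, ``age``,
    ``sex`` ("F"/"M") and ``beta``; stage/age/sex may be missing. Betas are
    assumed already normalized upstream (e.g. BMIQ for 450K arrays), recorded
    by the ``normalized`` provenance flag.
    """

    samples: pd.DataFrame
    probe_id: str = DEFAULT_PROBE_ID
    normalized: bool = True

    def __post_init__(self) -> None:
        df = self.samples
        missing = [c for c in BETA_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"beta table missing columns: {missing}")
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample_ids: {dups[:5]}")
        beta = df["beta"]
        bad = df.loc[beta.notna() & ((beta < 0) | (beta > 1))]
        if len(bad):
            raise ValueError(
                f"beta values outside [0,1] for samples {bad['sample_id'].tolist()[:5]}"
            )
        bad_group = set(df["group"].unique()) - {"tumor", "control"}
        if bad_group:
            raise ValueError(f"group must be 'tumor' or 'control', got {sorted(bad_group)}")

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, probe_id: str = DEFAULT_PROBE_ID, normalized: bool = True
    ) -> "BetaCohort":
        """Build a cohort, dropping (and logging) samples with missing beta."""
        df = df.reindex(columns=BETA_COLUMNS)
        n_missing = int(df["beta"].isna().sum())
        if n_missing:
            logger.info("dropping %d samples with missing beta", n_missing)
            df = df.loc[df["beta"].notna()]
        return cls(samples=df.reset_index(drop=True), probe_id=probe_id, normalized=normalized)

    def betas(self, cancer_type: Optional[str] = None, group: Optional[str] = None) -> np.ndarray:
        df = self.samples
        if cancer_type is not None:
            df = df.loc[df["cancer_type"] == cancer_type]
        if group is not None:
            df = df.loc[df["group"] == group]
        return df["beta"].to_numpy(dtype=float)

    @property
    def cancer_types(self) -> list[str]:
        return sorted(self.samples["cancer_type"].unique())


@dataclass(frozen=True)
class MutationTable:
    """Boolean sample-by-gene matrix of non-silent SNV calls."""

    calls: pd.DataFrame  # index sample_id, columns gene symbols, dtype bool

    def __post_init__(self) -> None:
        if not all(self.calls.dtypes == bool):
            raise ValueError("mutation calls must be boolean")
        if self.calls.index.duplicated().any():
            raise ValueError("duplicate sample_ids in mutation table")

    @property
    def samples(self) -> list[str]:
        return list(self.calls.index)

    @property
    def genes(self) -> list[str]:
        return list(self.calls.columns)


@dataclass(frozen=True)
class GeneSet:
    """A per-cancer driver gene set (with optional mutation prevalences in %)."""

    cancer_type: str
    genes: tuple[str, ...]
    prevalences: Optional[Mapping[str, float]] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(self.genes))


@dataclass(frozen=True)
class MarkerSummary:
    """One cancer type's hypermethylation-vs-mutation comparison."""

    cancer_type: str
    cutoff: float
    n_tumors: int
    n_hypermethylated: int
    pct_hypermethylated: float
    pct_mutated: float
    ratio_vs_gene: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0 <= self.n_hypermethylated <= self.n_tumors:
            raise ValueError("n_hypermethylated must lie in [0, n_tumors]")
        for name in ("pct_hypermethylated", "pct_mutated"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must lie in [0, 100]")


class HypermethylationResult(NamedTuple):
    n_hypermethylated: int
    fraction: float


def compute_cutoff(
    control_betas: Sequence[float],
    exclusion: float = 0.95,
    quantile_method: str = "linear",
) -> float:
    """Beta-value cutoff exceeding the stated fraction of control samples.

    Returns the empirical ``exclusion``-quantile of the control betas (linear
    interpolation between order statistics by default). A tumor is later
    called hypermethylated iff its beta value strictly exceeds this cutoff,
    so with ``exclusion=0.95`` roughly 5% of controls fall above it.
    """
    betas = as_float_array(control_betas, "control_betas")
    if betas.size == 0:
        raise ValueError("no controls")
    if np.any((betas < 0) | (betas > 1)):
        raise ValueError("control betas must lie in [0, 1]")
    if not 0 < exclusion < 1:
        raise ValueError("exclusion must lie in (0, 1)")
    return float(np.quantile(betas, exclusion, method=quantile_method))


def hypermethylation_fraction(
    tumor_betas: Sequence[float], cutoff: float
) -> HypermethylationResult:
    """Count tumors whose beta strictly exceeds the cutoff.

    Strict inequality: a tumor with beta exactly equal to the cutoff is not
    hypermethylated (the cutoff is defined to be *exceeded*).
    """
    betas = as_float_array(tumor_betas, "tumor_betas")
    if betas.size == 0:
        raise ValueError("no tumor betas")
    if not 0 <= cutoff <= 1:
        raise ValueError("cutoff must lie in [0, 1]")
    count = int(np.sum(betas > cutoff))
    return HypermethylationResult(count, count / betas.size)


def mutated_fraction(mutations: MutationTable, gene_set: GeneSet) -> float:
    """Percent of samples with >=1 non-silent SNV across the gene set.

    Invariant to gene order and to duplicated gene listings. An empty gene set
    returns 0 with a warning (the degenerate case); genes missing from the
    table raise, listing the offenders.
    """
    genes = list(dict.fromkeys(gene_set.genes))  # dedupe, keep order
    if not genes:
        warnings.warn(
            f"empty gene set for {gene_set.cancer_type}; mutated fraction is 0",
            stacklevel=2,
        )
        return 0.0
    missing = [g for g in genes if g not in mutations.calls.columns]
    if missing:
        raise KeyError(f"genes absent from mutation table: {missing}")
    any_mut = mutations.calls[genes].any(axis=1)
    return percent(int(any_mut.sum()), len(any_mut))


def marker_vs_mutation_table(
    cohorts: Mapping[str, BetaCohort] | BetaCohort,
    mutations: Mapping[str, MutationTable],
    gene_sets: Mapping[str, GeneSet],
    exclusion: float = 0.95,
    ratio_gene: Optional[str] = None,
    quantile_method: str = "linear",
) -> list[MarkerSummary]:
    """Per-cancer comparison of hypermethylation vs driver-set mutation frequency.

    ``cohorts`` may be one multi-cancer ``BetaCohort`` or a mapping from
    cancer type to cohort. When ``ratio_gene`` is given (e.g. ``"TP53"``),
    each summary carries ``ratio_vs_gene`` = pct hypermethylated / pct mutated
    in that single gene.
    """
    if isinstance(cohorts, BetaCohort):
        cohorts = {ct: cohorts for ct in cohorts.cancer_types}
    summaries: list[MarkerSummary] = []
    for cancer_type in sorted(cohorts):
        cohort = cohorts[cancer_type]
        controls = cohort.betas(cancer_type=cancer_type, group="control")
        tumors = cohort.betas(cancer_type=cancer_type, group="tumor")
        if controls.size == 0:
            raise ValueError(f"no controls for {cancer_type}")
        cutoff = compute_cutoff(controls, exclusion, quantile_method)
        hyper = hypermethylation_fraction(tumors, cutoff)
        pct_mut = mutated_fraction(mutations[cancer_type], gene_sets[cancer_type])
        ratio = None
        if ratio_gene is not None:
            if ratio_gene not in mutations[cancer_type].calls.columns:
                warnings.warn(
                    f"{ratio_gene} absent from {cancer_type} mutation table; "
                    "ratio_vs_gene omitted",
                    stacklevel=2,
                )
                pct_single = 0.0
            else:
                single = GeneSet(cancer_type=cancer_type, genes=(ratio_gene,))
                pct_single = mutated_fraction(mutations[cancer_type], single)
            ratio = (
                round_half_up(percent(hyper.n_hypermethylated, tumors.size) / pct_single, 1)
                if pct_single > 0
                else None
            )
        summaries.append(
            MarkerSummary(
                cancer_type=cancer_type,
                cutoff=cutoff,
                n_tumors=int(tumors.size),
                n_hypermethylated=hyper.n_hypermethylated,
                pct_hypermethylated=percent(hyper.n_hypermethylated, tumors.size),
                pct_mutated=pct_mut,
                ratio_vs_gene=ratio,
            )
        )
    return summaries


def summarize_cutoffs(summaries: Sequence[MarkerSummary] | Sequence[float]) -> dict:
    """Min / median / max of the per-cancer cutoffs (mid-rank median)."""
    if len(summaries) == 0:
        raise ValueError("no summaries")
    if isinstance(summaries[0], MarkerSummary):
        cutoffs = np.array([s.cutoff for s in summaries], dtype=float)
    else:
        cutoffs = as_float_array(summaries, "cutoffs")
    return {
        "min": float(np.min(cutoffs)),
        "median": float(np.median(cutoffs)),
        "max": float(np.max(cutoffs)),
    }


@dataclass(frozen=True)
class DemographicSummary:
    """Association of beta values with donor age and sex in non-cancer tissue."""

    rho_all: Optional[float]
    rho_f: Optional[float]
    rho_m: Optional[float]
    max_beta: float
    below_blood_threshold: bool
    bin_medians: dict = field(default_factory=dict)


def demographic_association(
    cohort: BetaCohort,
    age_bin_edges: Sequence[float] = tuple(range(20, 101, 10)),
) -> DemographicSummary:
    """Pearson correlation of beta with age, overall and per sex.

    Samples lacking age are excluded. Strata with fewer than 2 samples, or
    with zero variance, report an absent (``None``) correlation rather than
    0. ``below_blood_threshold`` flags whether the maximum beta stays under
    0.2, the conventional bound for lowly methylated peripheral blood.
    """
    df = cohort.samples.loc[cohort.samples["age"].notna()]
    if df.empty:
        raise ValueError("no samples with age annotation")
    age = df["age"].to_numpy(dtype=float)
    beta = df["beta"].to_numpy(dtype=float)
    rho_all = pearson_r(age, beta)
    rhos: dict[str, Optional[float]] = {}
    for sex in ("F", "M"):
        sub = df.loc[df["sex"] == sex]
        rhos[sex] = (
            pearson_r(sub["age"].to_numpy(float), sub["beta"].to_numpy(float))
            if len(sub) >= 2
            else None
        )
    edges = np.asarray(age_bin_edges, dtype=float)
    bins = pd.cut(df["age"], bins=edges, right=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # empty bins yield NaN medians, dropped below
        med = df.groupby(bins, observed=False)["beta"].median()
    bin_medians = {str(k): float(v) for k, v in med.items() if pd.notna(v)}
    max_beta = float(beta.max())
    return DemographicSummary(
        rho_all=rho_all,
        rho_f=rhos["F"],
        rho_m=rhos["M"],
        max_beta=max_beta,
        below_blood_threshold=max_beta < BLOOD_BETA_THRESHOLD,
        bin_medians=bin_medians,
    )


def load_marker_reference() -> dict:
    """Packaged per-cancer reference: gene sets, prevalences, cutoffs, sizes."""
    with resources.files("meltmark.data").joinpath("marker_reference.json").open() as fh:
        return json.load(fh)


def reference_gene_sets() -> dict[str, GeneSet]:
    """The packaged driver gene sets as ``GeneSet`` objects."""
    ref = load_marker_reference()
    return {
        ct: GeneSet(cancer_type=ct, genes=tuple(info["genes"]), prevalences=info["genes"])
        for ct, info in ref["cancer_types"].items()
    }
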