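"""Synthetic cohorts with the statistical structure of the reported study data.

Every input the pipeline consumes can be generated here: per-cancer beta-value
cohorts with Bernoulli driver-gene mutations, plasma DREAMing samples with
negative-binomial methylated-fragment counts, and ddPCR droplet cohorts with
sparse mutant droplets. Defaults emulate the reported study conditions: the
Table-style cohort sizes and mutation prevalences, group medians of
normalized fragments per mL (controls 11.38, late-stage pancreatic 19.47,
early pancreatic 18.6, ovarian 27.30, liver 14.56, colon 64.49), plasma
volumes of 1.5-4 mL, and ddPCR detection probabilities of 9/17 (late-stage
pancreatic), 0/8 (early-stage) and 7/20 (controls).

All randomness fans out from a single root seed through counter-based
sub-streams, so any group or sample is reproducible in isolation and
identical (config, seed) pairs give bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from ._utils import child_rng, name_key
from .array_marker import BetaCohort, GeneSet, MutationTable, load_marker_reference
from .ddpcr_mtaf import DdpcrReaction, DdpcrSample
from .dreaming_melt import (
    DreamingSample,
    Epiallele,
    MeltModel,
    WellSpec,
    call_well,
    count_methylated_fragments,
    partition_copies,
    simulate_well,
)

# stream tags for seed fan-out
_TISSUE, _PLASMA, _DDPCR = 1, 2, 3


@dataclass(frozen=True)
class TissueGroupConfig:
    """Beta-value and mutation generator settings for one cancer type.

    Tumor betas are a two-component mixture: a hypermethylated component
    (``hyper_beta``) mixed with the control-like component so that the
    expected fraction of tumors exceeding the control 95% cutoff matches
    ``target_hyper_pct``. Mutation calls are independent Bernoulli draws at
    the per-gene prevalences (percent).
    """

    n_controls: int
    n_tumors: int
    target_hyper_pct: float
    gene_prevalences: dict[str, float] = field(default_factory=dict)
    #: Genes simulated in the mutation table but not part of the driver set
    #: (e.g. TP53 where it fell below the recurrence threshold).
    extra_gene_prevalences: dict[str, float] = field(default_factory=dict)
    control_beta: tuple[float, float] = (2.0, 48.0)
    hyper_beta: tuple[float, float] = (6.0, 3.0)
    control_age: tuple[float, float] = (71.5, 8.0)
    tumor_age: tuple[float, float] = (60.0, 10.0)

    def __post_init__(self) -> None:
        for pair in (self.control_beta, self.hyper_beta):
            if pair[0] <= 0 or pair[1] <= 0:
                raise ValueError("beta-distribution parameters must be positive")
        if not 0 <= self.target_hyper_pct <= 100:
            raise ValueError("target_hyper_pct must lie in [0, 100]")


@dataclass(frozen=True)
class PlasmaGroupConfig:
    """Fragment-rate settings for one plasma group.

    ``median_frags_per_ml`` is the target group median of normalized
    methylated fragments per mL; the generator converts it to a
    negative-binomial mean via the gamma-quantile median/mean ratio so the
    configured value is recovered as the sample median.
    """

    n: int
    median_frags_per_ml: float
    dispersion: float = 12.0  # NB size; larger = closer to Poisson
    stage: Optional[str] = None
    age: tuple[float, float] = (60.0, 10.0)

    def __post_init__(self) -> None:
        if self.n < 0 or self.median_frags_per_ml < 0 or self.dispersion <= 0:
            raise ValueError("invalid plasma group parameters")


@dataclass(frozen=True)
class DdpcrGroupConfig:
    """Droplet generator settings for one ddPCR group."""

    n: int
    detection_p: float
    mutant_mu: float = 4.0  # extra mutant droplets beyond the first, when detected
    wildtype_mean: float = 2500.0  # amplified wild-type droplets per reaction
    n_reactions: int = 2
    elution_fraction: float = 0.5  # fraction of the elution used for ddPCR

    def __post_init__(self) -> None:
        if not 0 <= self.detection_p <= 1:
            raise ValueError("detection_p must lie in [0, 1]")
        if self.n < 0 or self.n_reactions < 1:
            raise ValueError("invalid ddPCR group parameters")


@dataclass(frozen=True)
class CohortConfig:
    """Full parameterization of all synthetic generators."""

    seed: int = 0
    tissue: dict[str, TissueGroupConfig] = field(default_factory=dict)
    plasma: dict[str, PlasmaGroupConfig] = field(default_factory=dict)
    ddpcr: dict[str, DdpcrGroupConfig] = field(default_factory=dict)
    plasma_volume_range: tuple[float, float] = (1.5, 4.0)
    fraction_loaded_range: tuple[float, float] = (0.3, 1.0)
    exclusion: float = 0.95
    wells_per_sample: int = 96
    noise_sd: float = 0.02
    melt_model: MeltModel = field(default_factory=MeltModel)
    #: Optional multiplicative age effect on control fragment rates per decade
    #: above 70; 0 (off) by default — no established effect is assumed.
    control_age_effect: float = 0.0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        d["tissue"] = {
            k: TissueGroupConfig(**_tupled(v, "control_beta", "hyper_beta", "control_age", "tumor_age"))
            for k, v in d.get("tissue", {}).items()
        }
        d["plasma"] = {
            k: PlasmaGroupConfig(**_tupled(v, "age")) for k, v in d.get("plasma", {}).items()
        }
        d["ddpcr"] = {k: DdpcrGroupConfig(**v) for k, v in d.get("ddpcr", {}).items()}
        if "melt_model" in d and isinstance(d["melt_model"], dict):
            d["melt_model"] = MeltModel(**d["melt_model"])
        for key in ("plasma_volume_range", "fraction_loaded_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _tupled(d: dict, *keys: str) -> dict:
    d = dict(d)
    for k in keys:
        if k in d:
            d[k] = tuple(d[k])
    return d


def default_config(seed: int = 0) -> CohortConfig:
    """Defaults emulating the reported study conditions."""
    ref = load_marker_reference()
    tissue = {
        ct: TissueGroupConfig(
            n_controls=info["n_controls"],
            n_tumors=info["n_tumors"],
            target_hyper_pct=info["pct_hypermethylated"],
            gene_prevalences=dict(info["genes"]),
            extra_gene_prevalences=(
                {} if "TP53" in info["genes"] else {"TP53": info["tp53_pct"]}
            ),
        )
        for ct, info in ref["cancer_types"].items()
    }
    plasma = {
        "control": PlasmaGroupConfig(n=20, median_frags_per_ml=11.38, age=(71.5, 8.0)),
        "pancreatic_late": PlasmaGroupConfig(
            n=17, median_frags_per_ml=19.47, stage="III-IV", age=(60.0, 10.0)
        ),
        "pancreatic_early": PlasmaGroupConfig(
            n=8, median_frags_per_ml=18.6, stage="I-II", age=(60.0, 10.0)
        ),
        "ovarian": PlasmaGroupConfig(
            n=38, median_frags_per_ml=27.30, stage="III-IV", age=(59.0, 10.0)
        ),
        "liver": PlasmaGroupConfig(n=4, median_frags_per_ml=14.56, stage="III-IV"),
        "colon": PlasmaGroupConfig(n=4, median_frags_per_ml=64.49, stage="III-IV"),
    }
    ddpcr = {
        "control": DdpcrGroupConfig(n=20, detection_p=7 / 20),
        "pancreatic_late": DdpcrGroupConfig(n=17, detection_p=9 / 17),
        "pancreatic_early": DdpcrGroupConfig(n=8, detection_p=0.0),
    }
    return CohortConfig(seed=seed, tissue=tissue, plasma=plasma, ddpcr=ddpcr)


def nb_mean_for_median(median: float, dispersion: float) -> float:
    """Negative-binomial mean whose median approximates ``median``.

    Uses the gamma mixing distribution of the NB (shape = dispersion): a
    gamma with shape r and mean mu has median ``mu * gamma_ppf(0.5, r) / r``,
    so the mean is scaled by the inverse ratio. Accurate to a few percent for
    the count levels simulated here.
    """
    if median == 0:
        return 0.0
    return float(median * dispersion / gamma_dist.ppf(0.5, dispersion))


@dataclass(frozen=True)
class TissueData:
    """Generated tissue-level inputs: one multi-cancer beta cohort + mutations."""

    betas: BetaCohort
    mutations: dict[str, MutationTable]
    gene_sets: dict[str, GeneSet]


def generate_beta_cohort(config: CohortConfig) -> TissueData:
    """Beta-value cohorts and Bernoulli mutation tables for every cancer type."""
    rows = []
    mutations: dict[str, MutationTable] = {}
    gene_sets: dict[str, GeneSet] = {}
    for cancer_type in sorted(config.tissue):
        grp = config.tissue[cancer_type]
        rng = child_rng(config.seed, _TISSUE, name_key(cancer_type))
        a_c, b_c = grp.control_beta
        a_h, b_h = grp.hyper_beta
        # mixture weight so that E[frac > control 95% cutoff] hits the target
        resid = 1.0 - config.exclusion
        w = max(0.0, (grp.target_hyper_pct / 100.0 - resid) / (1.0 - resid))
        for kind, n, age_params in (
            ("control", grp.n_controls, grp.control_age),
            ("tumor", grp.n_tumors, grp.tumor_age),
        ):
            if kind == "tumor":
                is_hyper = rng.random(n) < w
                beta = np.where(
                    is_hyper, rng.beta(a_h, b_h, size=n), rng.beta(a_c, b_c, size=n)
                )
            else:
                beta = rng.beta(a_c, b_c, size=n)
            age = np.clip(rng.normal(age_params[0], age_params[1], size=n), 25, 95)
            sex = rng.choice(["F", "M"], size=n)
            for i in range(n):
                rows.append(
                    {
                        "sample_id": f"{cancer_type}_{kind}_{i:04d}",
                        "cancer_type": cancer_type,
                        "group": kind,
                        "stage": None,
                        "age": float(np.round(age[i], 1)),
                        "sex": sex[i],
                        "beta": float(np.clip(beta[i], 0.0, 1.0)),
                    }
                )
        genes = list(grp.gene_prevalences)
        all_prevalences = {**grp.gene_prevalences, **grp.extra_gene_prevalences}
        calls = pd.DataFrame(
            {
                gene: rng.random(grp.n_tumors) < prev / 100.0
                for gene, prev in all_prevalences.items()
            },
            index=pd.Index(
                [f"{cancer_type}_tumor_{i:04d}" for i in range(grp.n_tumors)],
                name="sample_id",
            ),
        )
        mutations[cancer_type] = MutationTable(calls=calls)
        gene_sets[cancer_type] = GeneSet(
            cancer_type=cancer_type,
            genes=tuple(genes),
            prevalences=dict(grp.gene_prevalences),
        )
    betas = BetaCohort(samples=pd.DataFrame(rows))
    return TissueData(betas=betas, mutations=mutations, gene_sets=gene_sets)


def generate_plasma_cohort(
    config: CohortConfig, materialize_wells: bool = False
) -> list[DreamingSample]:
    """Plasma DREAMing samples with negative-binomial fragment counts.

    Per sample: plasma volume ~ U(volume range), fraction loaded ~ U(fraction
    range), true fragment count ~ NB with mean rate x equivalent volume.
    With ``materialize_wells`` the count is partitioned across wells, each
    well's melt curve is simulated (densities uniform on 1..14) and called,
    and the fragment count is the number of methylated wells — which
    undercounts under co-occupancy, as the real assay does.
    """
    samples: list[DreamingSample] = []
    vol_lo, vol_hi = config.plasma_volume_range
    frac_lo, frac_hi = config.fraction_loaded_range
    for group in sorted(config.plasma):
        grp = config.plasma[group]
        rate_mean = nb_mean_for_median(grp.median_frags_per_ml, grp.dispersion)
        for i in range(grp.n):
            rng = child_rng(config.seed, _PLASMA, name_key(group), i)
            volume = float(rng.uniform(vol_lo, vol_hi))
            fraction = float(rng.uniform(frac_lo, frac_hi))
            eqv = volume * fraction
            age = float(np.round(np.clip(rng.normal(*grp.age), 25, 95), 1))
            mu = rate_mean * eqv
            if group == "control" and config.control_age_effect:
                mu *= max(0.1, 1.0 + config.control_age_effect * (age - 70.0) / 10.0)
            if mu == 0:
                count = 0
            else:
                r = grp.dispersion
                count = int(rng.negative_binomial(r, r / (r + mu)))
            well_calls = None
            fragments = count
            if materialize_wells:
                per_well = partition_copies(count, config.wells_per_sample, rng)
                calls = []
                for k in per_well:
                    methylated = tuple(
                        Epiallele(int(d)) for d in rng.integers(1, 15, size=int(k))
                    )
                    spec = WellSpec(methylated=methylated)
                    curve = simulate_well(
                        spec, config.melt_model, noise_sd=config.noise_sd, seed=rng
                    )
                    calls.append(call_well(curve, config.melt_model))
                well_calls = tuple(calls)
                fragments = count_methylated_fragments(calls)
            samples.append(
                DreamingSample(
                    sample_id=f"{group}_{i:03d}",
                    group=group,
                    stage=grp.stage,
                    age=age,
                    starting_plasma_volume_ml=volume,
                    fraction_loaded=fraction,
                    methylated_fragments=fragments,
                    n_wells=config.wells_per_sample if materialize_wells else None,
                    well_calls=well_calls,
                )
            )
    return samples


def generate_ddpcr_cohort(config: CohortConfig) -> list[DdpcrSample]:
    """ddPCR droplet cohorts with sparse mutant droplets.

    Detection ~ Bernoulli(group probability); a detected sample carries
    1 + Poisson(mutant_mu) mutant droplets split binomially across its
    reactions; wild-type droplets are Poisson(wildtype_mean) per reaction.
    """
    samples: list[DdpcrSample] = []
    vol_lo, vol_hi = config.plasma_volume_range
    for group in sorted(config.ddpcr):
        grp = config.ddpcr[group]
        for i in range(grp.n):
            rng = child_rng(config.seed, _DDPCR, name_key(group), i)
            starting = float(rng.uniform(vol_lo, vol_hi))
            assayed = starting * grp.elution_fraction
            detected = rng.random() < grp.detection_p
            total_mutant = int(1 + rng.poisson(grp.mutant_mu)) if detected else 0
            split = rng.multinomial(
                total_mutant, np.full(grp.n_reactions, 1.0 / grp.n_reactions)
            )
            reactions = tuple(
                DdpcrReaction(
                    mutant_droplets=int(split[j]),
                    wildtype_droplets=int(rng.poisson(grp.wildtype_mean)),
                )
                for j in range(grp.n_reactions)
            )
            samples.append(
                DdpcrSample(
                    sample_id=f"{group}_{i:03d}",
                    group=group,
                    reactions=reactions,
                    plasma_volume_assayed_ml=assayed,
                )
            )
    return samples


def with_config(config: CohortConfig, **overrides) -> CohortConfig:
    """A copy of ``config`` with fields replaced."""
    return replace(config, **overrides)
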