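"""KRAS mutant allele fractions from droplet digital PCR counts.

A plasma sample is screened for 7 KRAS alterations (G12A/C/D/R/S/V, G13D)
collapsed into a single mutant channel. The raw mutant allele fraction pools
all reactions for a sample: total mutant droplets over total amplified
droplets (mutant + wild-type). The normalized MtAF divides that fraction by
the estimated mL of plasma assayed (starting plasma volume x fraction of the
elution used), so its units are per mL — kept explicit in output headers. A
sample is "detected" iff any reaction contains at least one mutant droplet.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from ._utils import percent


@dataclass(frozen=True)
class DdpcrReaction:
    """Droplet counts for one ddPCR reaction."""

    mutant_droplets: int
    wildtype_droplets: int

    def __post_init__(self) -> None:
        if self.mutant_droplets < 0 or self.wildtype_droplets < 0:
            raise ValueError("droplet counts must be >= 0")

    @property
    def total_amplified(self) -> int:
        return self.mutant_droplets + self.wildtype_droplets


@dataclass(frozen=True)
class DdpcrSample:
    """One sample's reactions plus the plasma volume they interrogate."""

    sample_id: str
    group: str
    reactions: tuple[DdpcrReaction, ...]
    plasma_volume_assayed_ml: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "reactions", tuple(self.reactions))
        if not self.reactions:
            raise ValueError("need at least one reaction")
        if self.plasma_volume_assayed_ml <= 0:
            raise ValueError("plasma_volume_assayed_ml must be > 0")

    @property
    def total_mutant(self) -> int:
        return sum(r.mutant_droplets for r in self.reactions)

    @property
    def total_amplified(self) -> int:
        return sum(r.total_amplified for r in self.reactions)

    @property
    def detected(self) -> bool:
        return self.total_mutant >= 1

    @property
    def amplified(self) -> bool:
        """False marks assay failure (no droplets at all), distinct from MtAF 0."""
        return self.total_amplified > 0

    @property
    def raw_fraction(self) -> Optional[float]:
        return raw_mutant_fraction(self.reactions) if self.amplified else None

    @property
    def mtaf(self) -> Optional[float]:
        raw = self.raw_fraction
        return None if raw is None else normalized_mtaf(raw, self.plasma_volume_assayed_ml)


def raw_mutant_fraction(reactions: Sequence[DdpcrReaction]) -> float:
    """Pooled mutant fraction: sum of mutant over sum of amplified droplets.

    Reactions are pooled by summing droplets (not by averaging per-reaction
    fractions), so the result is invariant to how droplets are split across
    reactions.
    """
    if not reactions:
        raise ValueError("need at least one reaction")
    mutant = sum(r.mutant_droplets for r in reactions)
    total = sum(r.total_amplified for r in reactions)
    if total == 0:
        raise ValueError("no amplification: zero total amplified droplets")
    return mutant / total


def normalized_mtaf(raw_fraction: float, plasma_volume_assayed_ml: float) -> float:
    """Volume-adjusted MtAF: raw fraction divided by mL of plasma assayed."""
    if plasma_volume_assayed_ml <= 0:
        raise ValueError("plasma volume must be > 0")
    if raw_fraction < 0:
        raise ValueError("raw fraction must be >= 0")
    return raw_fraction / plasma_volume_assayed_ml


@dataclass(frozen=True)
class DetectionSummary:
    group: str
    n_samples: int
    n_detected: int
    pct_detected: float


def cohort_detection(samples: Sequence[DdpcrSample]) -> Mapping[str, DetectionSummary]:
    """Per-group count and percent of samples with any mutant droplet."""
    if not samples:
        raise ValueError("no samples")
    groups: dict[str, list[DdpcrSample]] = {}
    for s in samples:
        groups.setdefault(s.group, []).append(s)
    return {
        g: DetectionSummary(
            group=g,
            n_samples=len(members),
            n_detected=sum(1 for s in members if s.detected),
            pct_detected=percent(sum(1 for s in members if s.detected), len(members)),
        )
        for g, members in sorted(groups.items())
    }
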