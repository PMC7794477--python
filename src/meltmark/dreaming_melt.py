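"""Digital melt-curve (DREAMing) simulation, peak calling, and fragment counting.

DREAMing distributes a bisulfite-converted sample across microtiter wells so
that rare methylated epialleles land in only some wells (Poisson
partitioning) against a constant background of unmethylated template (~200
copies/well). After PCR and high-resolution melt, a well with only
unmethylated DNA shows a single negative-derivative melt peak at the
characteristic temperature Tm_u; a well carrying a methylated epiallele shows
a second, hotter peak whose shift above Tm_u is proportional to the
epiallele's methylation density (number of methylated CpGs among the 14
internal sites of the amplicon). Counting wells with a methylated peak counts
single molecules; dividing by the equivalent plasma volume loaded gives
fragments per mL of plasma, the classification score used downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from ._utils import child_rng

N_CPG_SITES = 14
#: Background copies per well expected in the assay design.
DEFAULT_BACKGROUND_COPIES = 200


@dataclass(frozen=True)
class Epiallele:
    """One DNA fragment, characterized by its methylation density (0-14 CpGs)."""

    density: int

    def __post_init__(self) -> None:
        if not (isinstance(self.density, (int, np.integer)) and 0 <= self.density <= N_CPG_SITES):
            raise ValueError(f"density must be an integer in [0, {N_CPG_SITES}]")

    @property
    def is_methylated(self) -> bool:
        return self.density >= 1


@dataclass(frozen=True)
class WellSpec:
    """Template content of one well: background plus methylated epialleles."""

    background_copies: int = DEFAULT_BACKGROUND_COPIES
    methylated: tuple[Epiallele, ...] = ()

    def __post_init__(self) -> None:
        if self.background_copies < 0:
            raise ValueError("background_copies must be >= 0")
        object.__setattr__(self, "methylated", tuple(self.methylated))
        if any(e.density < 1 for e in self.methylated):
            raise ValueError("methylated epialleles must have density >= 1")


@dataclass(frozen=True)
class MeltModel:
    """Forward model of the melt derivative curve and its temperature grid.

    The curve is a sum of Gaussian-shaped -dF/dT peaks: one at ``tm_u`` for
    the unmethylated background and one per methylated epiallele at
    ``tm_u + density * delta_per_cpg``. Peak areas are amplification-balanced:
    the 200-copy background saturates to unit area
    (``background_copies / 200``) and each methylated epiallele contributes
    ``methylated_amplitude`` area on its own, reflecting the methylation bias
    of the primers. All values are configurable; none is a claim about the
    real 175-bp amplicon.
    """

    tm_u: float = 74.0  # °C, unmethylated amplicon melt peak
    delta_per_cpg: float = 0.4  # °C shift per methylated CpG
    peak_sigma: float = 0.25  # °C, Gaussian peak width
    grid_start: float = 65.0
    grid_stop: float = 90.0
    grid_step: float = 0.1
    methylated_amplitude: float = 1.0  # area per methylated copy, background-relative
    background_saturation_copies: int = DEFAULT_BACKGROUND_COPIES
    smoothing_sigma: float = 0.15  # °C, pre-peak-calling smoothing

    def __post_init__(self) -> None:
        if self.delta_per_cpg <= 0:
            raise ValueError("delta_per_cpg must be > 0")
        if self.peak_sigma <= 0 or self.grid_step <= 0:
            raise ValueError("peak_sigma and grid_step must be > 0")

    def temperatures(self) -> np.ndarray:
        n = int(round((self.grid_stop - self.grid_start) / self.grid_step)) + 1
        return self.grid_start + self.grid_step * np.arange(n)


DEFAULT_MELT_MODEL = MeltModel()


@dataclass(frozen=True)
class MeltCurve:
    """A -dF/dT melt trace on a strictly increasing temperature grid."""

    temperatures: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        if t.shape != s.shape or t.ndim != 1:
            raise ValueError("temperatures and signal must be 1-D and equal length")
        if not np.all(np.diff(t) > 0):
            raise ValueError("temperature grid must be strictly increasing")
        if not np.all(np.isfinite(s)) or np.any(s < -1e-12):
            raise ValueError("signal must be finite and non-negative")
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "signal", s)


@dataclass(frozen=True)
class WellCall:
    """Peak-calling outcome for one well.

    ``amplified=False`` marks a flat curve ("no amplification"); such wells
    are excluded from fragment counting. When methylated, ``secondary_peak_tm``
    is the hottest peak above the separation threshold and
    ``inferred_density`` its nearest CpG count.
    """

    primary_peak_tm: Optional[float]
    secondary_peak_tm: Optional[float] = None
    is_methylated: bool = False
    inferred_density: Optional[int] = None
    amplified: bool = True

    def __post_init__(self) -> None:
        if self.is_methylated != (self.secondary_peak_tm is not None):
            raise ValueError("is_methylated must match presence of a secondary peak")
        if (
            self.secondary_peak_tm is not None
            and self.primary_peak_tm is not None
            and self.secondary_peak_tm <= self.primary_peak_tm
        ):
            raise ValueError("secondary peak must be hotter than primary")


@dataclass(frozen=True)
class DreamingSample:
    """One plasma sample's DREAMing outcome with plasma-volume normalization."""

    sample_id: str
    group: str
    starting_plasma_volume_ml: float
    fraction_loaded: float
    methylated_fragments: int
    n_wells: Optional[int] = None
    stage: Optional[str] = None
    age: Optional[float] = None
    well_calls: Optional[tuple[WellCall, ...]] = None

    def __post_init__(self) -> None:
        if not 0 < self.fraction_loaded <= 1:
            raise ValueError("fraction_loaded must lie in (0, 1]")
        if self.starting_plasma_volume_ml <= 0:
            raise ValueError("starting_plasma_volume_ml must be > 0")
        if self.methylated_fragments < 0:
            raise ValueError("methylated_fragments must be >= 0")

    @property
    def equivalent_volume_ml(self) -> float:
        return equivalent_plasma_volume(self.starting_plasma_volume_ml, self.fraction_loaded)

    @property
    def fragments_per_ml(self) -> float:
        return normalized_fragments(self.methylated_fragments, self.equivalent_volume_ml)


def tm_of_density(d: int, model: MeltModel = DEFAULT_MELT_MODEL) -> float:
    """Melt temperature of an epiallele with ``d`` methylated CpGs (linear in d)."""
    if not 0 <= d <= N_CPG_SITES:
        raise ValueError(f"density must lie in [0, {N_CPG_SITES}]")
    return model.tm_u + d * model.delta_per_cpg

def density_of_tm(tm: float, model: MeltModel = DEFAULT_MELT_MODEL, clip: bool = True) -> int:
    """Nearest methylation density for an observed secondary peak temperature."""
    d = int(round((tm - model.tm_u) / model.delta_per_cpg))
    if clip:
        d = min(max(d, 1), N_CPG_SITES)
    return d


def simulate_well(
    spec: WellSpec,
    model: MeltModel = DEFAULT_MELT_MODEL,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> MeltCurve:
    """Forward-simulate one well's -dF/dT melt curve (deterministic per seed)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    temps = model.temperatures()
    signal = np.zeros_like(temps)
    norm = 1.0 / (model.peak_sigma * np.sqrt(2 * np.pi))

    def add_peak(center: float, area: float) -> None:
        signal[:] += area * norm * np.exp(-0.5 * ((temps - center) / model.peak_sigma) ** 2)

    if spec.background_copies > 0:
        add_peak(model.tm_u, spec.background_copies / model.background_saturation_copies)
    for epi in spec.methylated:
        add_peak(tm_of_density(epi.density, model), model.methylated_amplitude)
    if spec.background_copies == 0 and not spec.methylated:
        warnings.warn("empty well: no template, flat melt curve", stacklevel=2)
    if noise_sd > 0:
        signal += rng.normal(0.0, noise_sd, size=signal.shape)
        np.clip(signal, 0.0, None, out=signal)
    return MeltCurve(temperatures=temps, signal=signal)


def call_well(
    curve: MeltCurve,
    model: MeltModel = DEFAULT_MELT_MODEL,
    min_separation: float = 0.3,
    prominence: float = 0.10,
) -> WellCall:
    """Classify one melt curve as unmethylated, methylated, or not amplified.

    Peaks are local maxima of the (lightly smoothed) curve with topographic
    prominence at least ``prominence`` times the tallest signal value. The
    well is methylated iff a peak sits at or above ``tm_u + min_separation``;
    the hottest such peak is reported and its density inferred by the inverse
    of the linear Tm model, clipped to [1, 14].
    """
    s = curve.signal
    if model.smoothing_sigma > 0:
        s = gaussian_filter1d(s, sigma=model.smoothing_sigma / model.grid_step)
    peak_floor = 0.05 / (model.peak_sigma * np.sqrt(2 * np.pi))
    if s.max() < peak_floor:  # effectively flat: nothing amplified
        return WellCall(primary_peak_tm=None, amplified=False)
    idx, _ = find_peaks(s, prominence=prominence * s.max())
    if idx.size == 0:
        return WellCall(primary_peak_tm=None, amplified=False)
    tms = curve.temperatures[idx]
    threshold = model.tm_u + min_separation
    secondary_tms = tms[tms >= threshold]
    primary_tms = tms[tms < threshold]
    primary = float(primary_tms[np.argmax(s[idx][tms < threshold])]) if primary_tms.size else None
    if secondary_tms.size:
        secondary = float(secondary_tms.max())
        return WellCall(
            primary_peak_tm=primary,
            secondary_peak_tm=secondary,
            is_methylated=True,
            inferred_density=density_of_tm(secondary, model),
        )
    return WellCall(primary_peak_tm=primary)


def partition_copies(
    n_copies: int, n_wells: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Distribute copies independently and uniformly across wells (multinomial).

    This is the finite-well version of Poisson partitioning: each copy lands
    in a uniformly random well, so per-well counts are multinomial and the
    number of occupied wells has mean ``W * (1 - (1 - 1/W)**n)``.
    """
    if n_wells < 1:
        raise ValueError("n_wells must be >= 1")
    if n_copies < 0:
        raise ValueError("n_copies must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.multinomial(n_copies, np.full(n_wells, 1.0 / n_wells))


def count_methylated_fragments(well_calls: Sequence[WellCall]) -> int:
    """Number of amplified wells called methylated (one fragment per well).

    Peaks are counted directly as fragment proxies; wells flagged "no
    amplification" contribute to neither numerator nor denominator. For the
    optional occupancy-based correction see :func:`poisson_corrected_count`.
    """
    return sum(1 for c in well_calls if c.amplified and c.is_methylated)


def poisson_corrected_count(n_methylated_wells: int, n_wells: int) -> float:
    """Poisson occupancy estimate of input copies: ``-W * ln(1 - k/W)``.

    Optional post-hoc estimator for co-occupancy (two molecules in one well
    count as one peak); not applied by default since the assay reports raw
    peak counts. Returns ``inf`` when every well is positive.
    """
    if not 0 <= n_methylated_wells <= n_wells:
        raise ValueError("need 0 <= k <= n_wells")
    if n_methylated_wells == n_wells:
        return float("inf")
    return float(-n_wells * np.log1p(-n_methylated_wells / n_wells))


def equivalent_plasma_volume(starting_volume_ml: float, fraction_loaded: float) -> float:
    """Plasma volume effectively assayed: starting volume x fraction loaded.

    ``fraction_loaded`` is the fraction of bisulfite-converted beta-actin
    targets (the cfDNA input proxy) loaded into all DREAMing wells.
    """
    if starting_volume_ml <= 0:
        raise ValueError("starting volume must be > 0")
    if not 0 < fraction_loaded <= 1:
        raise ValueError("fraction_loaded must lie in (0, 1] (cannot load more than the elution)")
    return starting_volume_ml * fraction_loaded


def normalized_fragments(count: int, equivalent_volume_ml: float) -> float:
    """Methylated fragments per mL plasma: count / equivalent volume."""
    if equivalent_volume_ml <= 0:
        raise ValueError("equivalent volume must be > 0")
    if count < 0:
        raise ValueError("count must be >= 0")
    return count / equivalent_volume_ml


@dataclass(frozen=True)
class SpikeInResult:
    """Outcome of the synthetic-target sensitivity experiment."""

    copies: int
    n_wells: int
    detected: tuple[int, ...]
    mean_absolute_error: float
    occupied: tuple[int, ...] = field(default=(), compare=False)


def spikein_sensitivity(
    copies: int,
    n_wells: int = 12,
    reps: int = 5,
    background_copies: int = DEFAULT_BACKGROUND_COPIES,
    density: int = N_CPG_SITES,
    noise_sd: float = 0.0,
    seed: int = 0,
    model: MeltModel = DEFAULT_MELT_MODEL,
) -> SpikeInResult:
    """Spike-in sensitivity: fully methylated synthetic targets across wells.

    Emulates diluting ``copies`` fully methylated (density 14) targets across
    ``n_wells`` wells of ``background_copies`` unmethylated genomic copies,
    repeated ``reps`` times; each rep partitions, simulates, calls, and counts.
    Returns per-rep detected counts and the mean absolute error |detected -
    copies|. In noiseless runs the only loss source is co-occupancy (two
    copies sharing a well yield one peak).
    """
    if copies < 0 or reps < 1:
        raise ValueError("copies must be >= 0 and reps >= 1")
    detected: list[int] = []
    occupied: list[int] = []
    for rep in range(reps):
        rng = child_rng(seed, copies, rep)
        counts = partition_copies(copies, n_wells, rng)
        occupied.append(int(np.count_nonzero(counts)))
        calls = []
        for k in counts:
            spec = WellSpec(
                background_copies=background_copies,
                methylated=tuple(Epiallele(density) for _ in range(int(k))),
            )
            curve = simulate_well(spec, model, noise_sd=noise_sd, seed=rng)
            calls.append(call_well(curve, model))
        detected.append(count_methylated_fragments(calls))
    mae = float(np.mean([abs(d - copies) for d in detected]))
    return SpikeInResult(
        copies=copies,
        n_wells=n_wells,
        detected=tuple(detected),
        mean_absolute_error=mae,
        occupied=tuple(occupied),
    )


def with_model(model: MeltModel, **overrides) -> MeltModel:
    """Convenience: a copy of ``model`` with fields replaced."""
    return replace(model, **overrides)
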