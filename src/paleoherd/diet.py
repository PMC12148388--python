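"""Collagen quality control and threshold-based C3/C4 diet classification.

C3 and C4 plants occupy distinct δ13C ranges, and consumer tissues record
plant δ13C plus a tissue-specific enrichment: about +14‰ from diet to
enamel carbonate in ruminants (e*) and about +5‰ from diet to bone
collagen. Starting from plant baselines — the modern global C3 mean
(−26.0‰, Suess-corrected by +1.5‰ for the fossil-fuel depletion of
modern CO2) and a local archaeological C3 maximum (−22.8‰) — threshold
δ13C values in consumer tissue separate closed-canopy C3 feeding, open
pure-C3 diets, and diets with a C4 contribution.

Two cutoff triples are carried for enamel: the triple derived from
baseline + e* arithmetic, and the as-published ruminant triple
(−10.7, −9.0, −14.5‰), which differs from the arithmetic by 0.3–0.4‰.
Classification uses the as-published values where they exist (ruminants)
and the derived values otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .datatypes import (
    ATOMIC_MASS_C,
    ATOMIC_MASS_N,
    CollagenSample,
    ValidationError,
)

#: Enamel-diet 13C enrichment factors (e*, ‰) by taxon group. The suid
#: value is the midpoint of the reported +13.3…+14.6 range.
ENRICHMENT_FACTORS = {
    "ruminant": 14.1,
    "cattle_cervid": 14.5,
    "suid": 13.95,
}
SUID_ENRICHMENT_RANGE = (13.3, 14.6)

#: As-published enamel cutoffs (avg-C3, max-C3, canopy) per group, ‰.
PUBLISHED_ENAMEL_CUTOFFS = {"ruminant": (-10.7, -9.0, -14.5)}


@dataclass(frozen=True)
class DietThresholds:
    """Plant baselines, corrections and tissue offsets (all ‰ VPDB)."""

    plant_avg: float = -26.0  # modern global C3 mean
    plant_max: float = -22.8  # local archaeological C3 maximum
    suess: float = 1.5  # fossil-fuel correction applied to modern baselines
    canopy_plant_archaeological: float = -28.2
    canopy_plant_modern: float = -29.7
    canopy_enamel: float = -14.5  # as-published ruminant canopy cutoff
    collagen_offset: float = 5.0  # diet -> collagen enrichment

    def __post_init__(self) -> None:
        if not self.plant_max > self.plant_avg:
            raise ValidationError("plant_max must exceed plant_avg")
        if self.canopy_plant_archaeological >= self.plant_avg:
            raise ValidationError("canopy baseline must lie below plant_avg")


DEFAULT_THRESHOLDS = DietThresholds()


@dataclass(frozen=True)
class DietClass:
    """One of canopy_C3 | pure_C3 | C4_contribution, with the cutoff that
    decided it."""

    label: str
    basis: str

    def __post_init__(self) -> None:
        if self.label not in ("canopy_C3", "pure_C3", "C4_contribution"):
            raise ValidationError(f"invalid diet label {self.label!r}")


# ---------------------------------------------------------------------------
# Collagen quality control
# ---------------------------------------------------------------------------


def atomic_cn_ratio(pctC: float, pctN: float) -> float:
    """Atomic C:N ratio from mass percentages: (%C/12.011)/(%N/14.007)."""
    if pctN <= 0:
        raise ValidationError(f"pctN must be > 0, got {pctN}")
    return (pctC / ATOMIC_MASS_C) / (pctN / ATOMIC_MASS_N)


def qc_collagen(
    sample: CollagenSample, window: tuple[float, float] = (3.2, 3.62)
) -> bool:
    """Accept a collagen sample iff its atomic C:N lies inside the window.

    Bounds are inclusive; the default window [3.2, 3.62] is the accepted
    range for well-preserved ancient mammal bone collagen.
    """
    lo, hi = window
    if not lo < hi:
        raise ValidationError("C:N window bounds must be ordered")
    return lo <= sample.cn_atomic <= hi


# ---------------------------------------------------------------------------
# Enamel cutoffs and classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnamelCutoffs:
    """Derived and as-published cutoff triples (avg-C3, max-C3, canopy, ‰)."""

    group: str
    derived: tuple[float, float, float]
    published: Optional[tuple[float, float, float]]
    max_discrepancy: float

    @property
    def active(self) -> tuple[float, float, float]:
        """The triple classification uses: as-published when available."""
        return self.published if self.published is not None else self.derived


def derive_enamel_cutoffs(
    th: DietThresholds = DEFAULT_THRESHOLDS, group: str = "ruminant"
) -> EnamelCutoffs:
    """Enamel δ13C cutoffs for a taxon group.

    Derived arithmetic: avg = plant_avg + Suess + e*; max = plant_max + e*
    (the archaeological baseline needs no Suess correction);
    canopy = archaeological canopy plant baseline + e*.
    """
    if group not in ENRICHMENT_FACTORS:
        raise ValidationError(
            f"unknown taxon group {group!r}; known: {sorted(ENRICHMENT_FACTORS)}"
        )
    e_star = ENRICHMENT_FACTORS[group]
    derived = (
        round(th.plant_avg + th.suess + e_star, 6),
        round(th.plant_max + e_star, 6),
        round(th.canopy_plant_archaeological + e_star, 6),
    )
    published = PUBLISHED_ENAMEL_CUTOFFS.get(group)
    discrepancy = (
        round(max(abs(d - p) for d, p in zip(derived, published)), 6)
        if published
        else 0.0
    )
    return EnamelCutoffs(
        group=group, derived=derived, published=published, max_discrepancy=discrepancy
    )


def classify_enamel(d13C: float, cutoffs: EnamelCutoffs) -> DietClass:
    """Classify a bulk-enamel δ13C value against the cutoff triple.

    At or below the canopy cutoff → canopy_C3; at or below the maximum-C3
    cutoff → pure_C3 (basis records whether the value also clears the
    stricter average-based cutoff); above it → C4_contribution.
    """
    avg_cut, max_cut, canopy_cut = cutoffs.active
    if not (canopy_cut < avg_cut < max_cut):
        raise ValidationError(
            f"cutoffs must be ordered canopy < avg < max, got {cutoffs.active}"
        )
    if d13C <= canopy_cut:
        return DietClass("canopy_C3", basis="canopy_cutoff")
    if d13C <= avg_cut:
        return DietClass("pure_C3", basis="avg_cutoff")
    if d13C <= max_cut:
        return DietClass("pure_C3", basis="max_cutoff")
    return DietClass("C4_contribution", basis="above_max_cutoff")


# ---------------------------------------------------------------------------
# Collagen expectations and classification
# ---------------------------------------------------------------------------


def collagen_c3_expectation(
    th: DietThresholds = DEFAULT_THRESHOLDS,
) -> tuple[float, float]:
    """Expected collagen δ13C for a 100% C3 diet (avg-based, max-based).

    avg-based = plant_avg + Suess + collagen offset; max-based =
    plant_max + collagen offset. Values above the max-based expectation
    indicate a C4 dietary component.
    """
    return (
        round(th.plant_avg + th.suess + th.collagen_offset, 6),
        round(th.plant_max + th.collagen_offset, 6),
    )


def classify_collagen(
    d13C: float, expectations: Optional[tuple[float, float]] = None
) -> DietClass:
    """Classify a collagen δ13C value against the C3 expectations."""
    if expectations is None:
        expectations = collagen_c3_expectation()
    avg_based, max_based = expectations
    if not avg_based < max_based:
        raise ValidationError("avg-based expectation must lie below max-based")
    if d13C <= avg_based:
        return DietClass("pure_C3", basis="avg_expectation")
    if d13C <= max_based:
        return DietClass("pure_C3", basis="max_expectation")
    return DietClass("C4_contribution", basis="above_max_expectation")


def plant_baseline_from_samples(values: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and maximum of measured plant δ13C values."""
    if not len(values):
        raise ValidationError("plant baseline needs at least one value")
    if any(not math.isfinite(v) for v in values):
        raise ValidationError("plant delta values must be finite")
    return (sum(values) / len(values), max(values))


def c4_fraction_diagnostic(
    d13C_diet: float, c3_end: float = -26.0, c4_end: float = -12.5
) -> float:
    """Optional two-endmember C4 mixing fraction (diagnostic only).

    A simple linear mix between C3 and C4 plant endmembers on the diet
    scale; not part of the threshold classification above, which is the
    decision procedure proper.
    """
    if c4_end <= c3_end:
        raise ValidationError("C4 endmember must exceed C3 endmember")
    frac = (d13C_diet - c3_end) / (c4_end - c3_end)
    return min(1.0, max(0.0, frac))
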