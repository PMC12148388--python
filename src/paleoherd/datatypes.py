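"""Shared domain types for faunal biomolecular analyses.

The containers here are deliberately thin: validated records for
sequentially sampled tooth enamel, MALDI-ToF peak lists, bulk isotope
measurements and taxon-by-horizon count tables, plus the analysis
configuration shared by every stage.

Conventions: δ13C and δ18O are reported in ‰ on the VPDB scale, δ15N in ‰
on the AIR scale; intra-tooth distances are millimetres from the
enamel–root junction (ERJ), increasing toward the occlusal surface.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Optional

import pandas as pd

logger = logging.getLogger("paleoherd")

#: Atomic masses used for the atomic C:N ratio (g/mol).
ATOMIC_MASS_C = 12.011
ATOMIC_MASS_N = 14.007


class PaleoherdError(Exception):
    """Base class for all package errors."""


class FormatError(PaleoherdError):
    """A file or table does not follow the documented layout."""


class ValidationError(PaleoherdError, ValueError):
    """Well-formed input that violates a domain invariant or contract."""


def configure_logging(verbosity: int = 0) -> None:
    """Route package logs to stderr; verbosity 0=WARNING, 1=INFO, 2+=DEBUG."""
    level = logging.WARNING - 10 * min(int(verbosity), 2)
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level)


# ---------------------------------------------------------------------------
# Sequential enamel samples
# ---------------------------------------------------------------------------

TAXON_LABELS = ("sheep", "goat", "sheep/goat", "other")
TOOTH_LABELS = ("M2", "M3")
JAW_LABELS = ("upper", "lower")


@dataclass(frozen=True)
class IsotopeSample:
    """One drilled enamel sample: position x (mm from the ERJ) and δ values."""

    x: float
    d18O: float
    d13C: Optional[float] = None


@dataclass(frozen=True)
class ToothSequence:
    """An ordered intra-tooth isotope sequence from one molar.

    Samples are ordered by distance from the enamel–root junction;
    distances must be strictly increasing and non-negative, with at least
    three samples and finite δ18O throughout. δ13C may be absent per
    sample. ``missing_erj`` flags teeth whose ERJ could not be located,
    which disqualifies the sequence from seasonality modelling.
    """

    specimen_id: str
    taxon: str
    tooth: str
    jaw: str
    samples: tuple[IsotopeSample, ...]
    missing_erj: bool = False

    def __post_init__(self) -> None:
        if self.taxon not in TAXON_LABELS:
            raise ValidationError(
                f"taxon must be one of {TAXON_LABELS}, got {self.taxon!r}"
            )
        if self.tooth not in TOOTH_LABELS:
            raise ValidationError(f"tooth must be M2 or M3, got {self.tooth!r}")
        if self.jaw not in JAW_LABELS:
            raise ValidationError(f"jaw must be upper or lower, got {self.jaw!r}")
        object.__setattr__(self, "samples", tuple(self.samples))
        if len(self.samples) < 3:
            raise ValidationError(
                f"{self.specimen_id}: a tooth sequence needs >= 3 samples, "
                f"got {len(self.samples)}"
            )
        xs = [s.x for s in self.samples]
        if xs[0] < 0:
            raise ValidationError(f"{self.specimen_id}: distances must be >= 0")
        for a, b in zip(xs, xs[1:]):
            if not b > a:
                raise ValidationError(
                    f"{self.specimen_id}: distances must be strictly increasing "
                    f"({a} followed by {b})"
                )
        for s in self.samples:
            if not math.isfinite(s.d18O):
                raise ValidationError(f"{self.specimen_id}: non-finite d18O")
            if s.d13C is not None and not math.isfinite(s.d13C):
                raise ValidationError(f"{self.specimen_id}: non-finite d13C")

    @property
    def x(self) -> tuple[float, ...]:
        return tuple(s.x for s in self.samples)

    @property
    def d18O(self) -> tuple[float, ...]:
        return tuple(s.d18O for s in self.samples)

    def __len__(self) -> int:
        return len(self.samples)


# ---------------------------------------------------------------------------
# Peak lists
# ---------------------------------------------------------------------------

#: Two observed m/z values closer than this (Da) are considered duplicates.
DUPLICATE_MZ_TOLERANCE = 0.01


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: Optional[float] = None


@dataclass(frozen=True)
class SpectrumPeaks:
    """A centroided peptide-mass fingerprint: sorted m/z values (Da).

    Intensities are optional and ignored by the classifier (identifications
    are presence-based).
    """

    specimen_id: str
    peaks: tuple[Peak, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "peaks", tuple(self.peaks))
        mzs = [p.mz for p in self.peaks]
        for mz in mzs:
            if not (math.isfinite(mz) and mz > 0):
                raise ValidationError(f"m/z must be positive and finite, got {mz}")
        for a, b in zip(mzs, mzs[1:]):
            if b < a:
                raise ValidationError("peaks must be sorted by ascending m/z")
            if b - a < DUPLICATE_MZ_TOLERANCE:
                raise ValidationError(
                    f"duplicate peaks within {DUPLICATE_MZ_TOLERANCE} Da: {a}, {b}"
                )

    @property
    def mz(self) -> tuple[float, ...]:
        return tuple(p.mz for p in self.peaks)

    def __len__(self) -> int:
        return len(self.peaks)


# ---------------------------------------------------------------------------
# Bulk isotope records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CollagenSample:
    """Bone-collagen measurement with elemental quality-control data."""

    specimen_id: str
    d13C: float
    d15N: float
    pctC: float
    pctN: float
    cn_atomic: float
    horizon: str

    def __post_init__(self) -> None:
        for name, v in (("pctC", self.pctC), ("pctN", self.pctN)):
            if not (0 < v <= 100):
                raise ValidationError(f"{name} must be in (0, 100], got {v}")
        for name, v in (("d13C", self.d13C), ("d15N", self.d15N)):
            if not math.isfinite(v):
                raise ValidationError(f"{name} must be finite")
        expected = (self.pctC / ATOMIC_MASS_C) / (self.pctN / ATOMIC_MASS_N)
        if abs(expected - self.cn_atomic) > 0.01:
            raise ValidationError(
                f"{self.specimen_id}: cn_atomic {self.cn_atomic:.3f} inconsistent "
                f"with %C/%N (expected {expected:.3f})"
            )


FAMILY_LABELS = ("Bovidae", "Cervidae", "Suidae", "other")


@dataclass(frozen=True)
class EnamelBulkSample:
    """Bulk (whole-crown) enamel carbonate measurement."""

    specimen_id: str
    family: str
    d13C: float
    d18O: float
    horizon: str

    def __post_init__(self) -> None:
        if self.family not in FAMILY_LABELS:
            raise ValidationError(
                f"family must be one of {FAMILY_LABELS}, got {self.family!r}"
            )
        if not (math.isfinite(self.d13C) and math.isfinite(self.d18O)):
            raise ValidationError("delta values must be finite")


# ---------------------------------------------------------------------------
# Count tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AssemblageTable:
    """Non-negative integer counts indexed by (taxon, stratigraphic horizon).

    ``kind`` records what was counted: skeletal specimens (NISP) or charred
    seeds. Backed by a pandas DataFrame (rows = taxa, columns = horizons).
    """

    counts: pd.DataFrame
    kind: str = "NISP"

    def __post_init__(self) -> None:
        if self.kind not in ("NISP", "seeds"):
            raise ValidationError(f"kind must be NISP or seeds, got {self.kind!r}")
        df = self.counts
        if df.index.duplicated().any() or df.columns.duplicated().any():
            raise ValidationError("taxon and horizon labels must be unique")
        values = df.to_numpy()
        if values.size and not (values == values.astype(int)).all():
            raise ValidationError("counts must be integers")
        if values.size and (values < 0).any():
            raise ValidationError("counts must be non-negative")
        object.__setattr__(self, "counts", df.astype(int))

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.index)

    @property
    def horizons(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def taxon_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def horizon_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)


# ---------------------------------------------------------------------------
# Analysis configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters shared by the analysis stages.

    Defaults follow the study conventions: ±0.2 Da marker-match tolerance,
    cosine-fit acceptance at r ≥ 0.92 and period X ≥ 16.0 mm, the +0.073
    cycle-fraction correction for upper sheep M3s, and a collagen atomic
    C:N acceptance window of [3.2, 3.62].
    """

    marker_tolerance_da: float = 0.2
    r_threshold: float = 0.92
    min_period_mm: float = 16.0
    upper_sheep_m3_correction: float = 0.073
    cn_window: tuple[float, float] = (3.2, 3.62)
    # cosine-fit rejection heuristics
    min_amplitude_permil: float = 0.5
    amplitude_snr_min: float = 2.0
    clear_max_fraction: float = 0.05
    # multi-start grid for the period search (mm)
    period_grid: tuple[float, float, float] = (16.0, 60.0, 2.0)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.marker_tolerance_da <= 0:
            raise ValidationError("marker tolerance must be > 0")
        if not (0 < self.r_threshold <= 1):
            raise ValidationError("r threshold must be in (0, 1]")
        lo, hi = self.cn_window
        if not lo < hi:
            raise ValidationError("C:N window bounds must be ordered")
        if self.min_period_mm <= 0:
            raise ValidationError("minimum period must be > 0")

    def with_overrides(self, **kwargs) -> "AnalysisConfig":
        return replace(self, **kwargs)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        """Load configuration overrides from a YAML mapping."""
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise FormatError(f"{path}: config must be a key/value mapping")
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
        for key in ("cn_window", "period_grid"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)


DEFAULT_CONFIG = AnalysisConfig()
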