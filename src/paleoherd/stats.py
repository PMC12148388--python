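"""Assemblage-level counting and the statistical battery.

Covers %NISP share tables, seed-category shares, descriptive range
summaries, the chi-square test of uniform counts across stratigraphic
horizons, the parametric/non-parametric group-comparison flow
(Shapiro–Wilk normality → Levene homogeneity → one-way ANOVA, else
Kruskal–Wallis) and Spearman rank correlation. Significance is assessed
at α = 0.05 throughout, with no multiple-testing correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import AssemblageTable, ValidationError

ALPHA = 0.05


# ---------------------------------------------------------------------------
# Shares
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ShareTable:
    """Per-label counts and one-decimal percentage shares."""

    counts: pd.Series
    shares_pct: pd.Series
    denominator: int

    def __post_init__(self) -> None:
        if self.denominator <= 0:
            raise ValidationError("share denominator must be > 0")


def percent_shares(
    table: AssemblageTable,
    denominator: str = "total",
    exclude: Sequence[str] = ("unidentified",),
) -> ShareTable:
    """Taxon shares of the assemblage, summed over horizons.

    ``denominator='total'`` uses every count; ``'identified'`` drops the
    taxa named in ``exclude`` from both numerator rows and denominator.
    Shares are rounded to one decimal.
    """
    totals = table.taxon_totals()
    if denominator == "identified":
        totals = totals[~totals.index.isin(exclude)]
    elif denominator != "total":
        raise ValidationError("denominator must be 'total' or 'identified'")
    denom = int(totals.sum())
    if denom <= 0:
        raise ValidationError("cannot compute shares over a zero denominator")
    shares = (100.0 * totals / denom).round(1)
    return ShareTable(counts=totals, shares_pct=shares, denominator=denom)


def seed_category_shares(
    seeds: AssemblageTable, categories: Mapping[str, str]
) -> ShareTable:
    """Shares of seed counts aggregated into user-defined categories."""
    totals = seeds.taxon_totals()
    unmapped = [t for t in totals.index if t not in categories]
    if unmapped:
        raise ValidationError(f"unmapped seed taxa: {unmapped}")
    grouped = totals.groupby(totals.index.map(categories)).sum()
    denom = int(totals.sum())
    if denom <= 0:
        raise ValidationError("cannot compute shares over a zero denominator")
    shares = (100.0 * grouped / denom).round(1)
    return ShareTable(counts=grouped, shares_pct=shares, denominator=denom)


# ---------------------------------------------------------------------------
# Descriptive summaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RangeSummary:
    min: float
    max: float
    mean: float
    sd: float
    range: float


def range_summary(values: Sequence[float]) -> RangeSummary:
    """Min, max, mean, sample standard deviation and range (max − min)."""
    if not len(values):
        raise ValidationError("range summary needs at least one value")
    arr = np.asarray(values, dtype=float)
    if not np.isfinite(arr).all():
        raise ValidationError("values must be finite")
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else float("nan")
    return RangeSummary(
        min=float(arr.min()),
        max=float(arr.max()),
        mean=float(arr.mean()),
        sd=sd,
        range=float(arr.max() - arr.min()),
    )


# ---------------------------------------------------------------------------
# Chi-square uniformity
# ---------------------------------------------------------------------------


def chisq_uniform(counts: Sequence[int]) -> tuple[float, int, float]:
    """Chi-square test of observed counts against a uniform expectation.

    Returns (statistic, degrees of freedom, upper-tail p). Expected
    counts are total/k per category.
    """
    counts = [int(c) for c in counts]
    if len(counts) < 2:
        raise ValidationError("chi-square uniformity needs >= 2 categories")
    if any(c < 0 for c in counts):
        raise ValidationError("counts must be non-negative")
    if sum(counts) == 0:
        raise ValidationError("total count must be > 0")
    statistic, p = sps.chisquare(counts)
    return float(statistic), len(counts) - 1, float(p)


# ---------------------------------------------------------------------------
# Group comparison flow
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupTestResult:
    """Outcome of the assumption-guided omnibus comparison."""

    branch: str  # parametric | nonparametric
    normality_p: float
    variance_p: float
    statistic: float
    p_value: float
    group_labels: tuple[str, ...]
    group_sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.branch not in ("parametric", "nonparametric"):
            raise ValidationError(f"invalid branch {self.branch!r}")


def compare_groups(
    values: Sequence[float],
    groups: Sequence[str],
    alpha: float = ALPHA,
    normality_on: str = "pooled",
) -> GroupTestResult:
    """Compare group means with the assumption-guided decision flow.

    Normality is tested (Shapiro–Wilk) on pooled residuals from the group
    means by default, or per group with ``normality_on='per_group'``
    (any group failing fails the assumption). If normality and variance
    homogeneity (Levene) both hold at ``alpha``, a one-way ANOVA is run;
    otherwise Kruskal–Wallis. Groups with fewer than two values are
    dropped with a warning.
    """
    if len(values) != len(groups):
        raise ValidationError("values and groups must have equal length")
    frame = pd.DataFrame({"value": np.asarray(values, dtype=float), "group": list(groups)})
    sizes = frame.groupby("group").size()
    small = sizes[sizes < 2].index.tolist()
    if small:
        warnings.warn(f"dropping single-value group(s): {small}", stacklevel=2)
        frame = frame[~frame["group"].isin(small)]
    kept = list(frame.groupby("group").groups)
    if len(kept) < 2:
        raise ValidationError("need >= 2 groups with >= 2 values each")
    arrays = [g["value"].to_numpy() for _, g in frame.groupby("group")]
    labels = tuple(str(k) for k in kept)
    group_sizes = tuple(len(a) for a in arrays)

    residuals = np.concatenate([a - a.mean() for a in arrays])
    degenerate = float(np.ptp(frame["value"].to_numpy())) == 0.0
    if degenerate:
        # identical data: every test is vacuous; report the boundary result
        return GroupTestResult(
            branch="nonparametric",
            normality_p=1.0,
            variance_p=1.0,
            statistic=0.0,
            p_value=1.0,
            group_labels=labels,
            group_sizes=group_sizes,
        )

    if normality_on == "per_group":
        norm_p = min(float(sps.shapiro(a)[1]) for a in arrays if np.ptp(a) > 0)
    elif normality_on == "pooled":
        norm_p = float(sps.shapiro(residuals)[1]) if np.ptp(residuals) > 0 else 1.0
    else:
        raise ValidationError("normality_on must be 'pooled' or 'per_group'")
    var_p = float(sps.levene(*arrays)[1])

    if norm_p >= alpha and var_p >= alpha:
        statistic, p = sps.f_oneway(*arrays)
        branch = "parametric"
    else:
        statistic, p = sps.kruskal(*arrays)
        branch = "nonparametric"
    return GroupTestResult(
        branch=branch,
        normality_p=norm_p,
        variance_p=var_p,
        statistic=float(statistic),
        p_value=float(p),
        group_labels=labels,
        group_sizes=group_sizes,
    )


def rank_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with its two-sided p value."""
    if len(x) != len(y):
        raise ValidationError("x and y must have equal length")
    if len(x) < 3:
        raise ValidationError("rank correlation needs >= 3 pairs")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)
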