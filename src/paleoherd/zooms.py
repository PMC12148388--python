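"""Taxonomic classification of collagen peptide-mass fingerprints (ZooMS).

Collagen type-I tryptic peptides differ in mass between ungulate taxa;
matching observed MALDI-ToF peaks against a small reference of diagnostic
marker masses yields genus-level identifications for fragments that defy
morphological analysis. Key discriminators:

* COL1α2 757 (+16 oxidation pair) separates sheep (m/z 3017.4 / 3033.4)
  from goat (m/z 3077.4 / 3093.4); either mass of a pair counts.
* COL1α2 375 (m/z 1154, 2028, 2044) flags Caprines without separating
  sheep from goat.
* Antilopini-specific COL1α2 375 / α2 889 masses (1182, 2056, 2072, 1532),
  a gazelle marker at 3227 and a red-deer marker at 2216 discriminate
  gazelle from deer; with insufficient markers the call degrades to the
  composite Gazella/Cervus.

Taxa outside the study region with indistinguishable fingerprints
(Nesotragus, Rupicapra) are excluded from the assignable labels.
Intensities play no role: identification is presence-based.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .datatypes import SpectrumPeaks, ValidationError

# marker roles used by the decision rules
ROLE_SHEEP_757 = "sheep_757"
ROLE_GOAT_757 = "goat_757"
ROLE_CAPRINE_375 = "caprine_375"
ROLE_ANTILOPINI = "antilopini"
ROLE_GAZELLE = "gazelle_specific"
ROLE_DEER = "deer_specific"

COMPOSITE_CAPRINE = "Ovis/Capra"
COMPOSITE_GAZELLE_DEER = "Gazella/Cervus"
UNIDENTIFIED = "unidentified"


@dataclass(frozen=True)
class PeptideMarker:
    """A named collagen peptide with its diagnostic m/z value(s)."""

    name: str
    mz_values: tuple[float, ...]
    diagnostic_for: str
    role: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "mz_values", tuple(self.mz_values))
        if not self.mz_values:
            raise ValidationError(f"marker {self.name!r} needs at least one m/z")
        if any(mz <= 0 for mz in self.mz_values):
            raise ValidationError(f"marker {self.name!r} has a non-positive m/z")


@dataclass(frozen=True)
class MarkerMatch:
    marker_name: str
    marker_mz: float
    observed_mz: float

    @property
    def error(self) -> float:
        return self.observed_mz - self.marker_mz


@dataclass(frozen=True)
class TaxonAssignment:
    """The taxon call for one spectrum, with its marker evidence."""

    specimen_id: str
    label: str
    rank: str  # species | genus | composite | unidentified
    evidence: tuple[MarkerMatch, ...] = ()

    def __post_init__(self) -> None:
        if self.rank not in ("species", "genus", "composite", "unidentified"):
            raise ValidationError(f"invalid rank {self.rank!r}")
        if self.rank != "unidentified" and not self.evidence:
            raise ValidationError("identified assignments need non-empty evidence")


@dataclass(frozen=True)
class MarkerDB:
    """Reference marker masses plus the decision rules that interpret them.

    ``min_species_markers`` is the number of matched gazelle/deer-set
    masses required before a species-level gazelle or deer call is made;
    it is capped per species at the number of masses the reference
    actually holds for that species, so a taxon represented by a single
    printed marker remains identifiable.
    """

    markers: tuple[PeptideMarker, ...]
    exclusions: tuple[str, ...] = ("Nesotragus", "Rupicapra")
    min_species_markers: int = 3

    def __post_init__(self) -> None:
        object.__setattr__(self, "markers", tuple(self.markers))
        object.__setattr__(self, "exclusions", tuple(self.exclusions))
        assignable = set(self.taxa())
        overlap = assignable & set(self.exclusions)
        if overlap:
            raise ValidationError(f"excluded taxa are assignable: {sorted(overlap)}")

    def taxa(self) -> list[str]:
        """Simulatable / assignable single-genus labels."""
        return ["Ovis", "Capra", "Gazella", "Cervus"]

    def by_role(self, role: str) -> list[PeptideMarker]:
        return [m for m in self.markers if m.role == role]

    def simulation_profile(self, taxon: str) -> list[float]:
        """All marker masses a clean spectrum of ``taxon`` should show."""
        roles = {
            "Ovis": (ROLE_SHEEP_757, ROLE_CAPRINE_375),
            "Capra": (ROLE_GOAT_757, ROLE_CAPRINE_375),
            "Gazella": (ROLE_ANTILOPINI, ROLE_GAZELLE),
            "Cervus": (ROLE_DEER,),
        }
        if taxon not in roles:
            raise ValidationError(f"unknown taxon {taxon!r}; known: {self.taxa()}")
        return sorted(mz for m in self.markers if m.role in roles[taxon] for mz in m.mz_values)

    def all_masses(self) -> list[float]:
        return sorted(mz for m in self.markers for mz in m.mz_values)

    def gazelle_deer_set(self) -> list[float]:
        """The countable marker-mass union for the >=N gazelle/deer rule."""
        roles = (ROLE_ANTILOPINI, ROLE_GAZELLE, ROLE_DEER)
        return sorted(mz for m in self.markers if m.role in roles for mz in m.mz_values)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            [
                {
                    "name": m.name,
                    "mz_values": ";".join(str(v) for v in m.mz_values),
                    "diagnostic_for": m.diagnostic_for,
                    "role": m.role,
                }
                for m in self.markers
            ]
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "MarkerDB":
        df = pd.read_csv(path)
        markers = tuple(
            PeptideMarker(
                name=str(r.name),
                mz_values=tuple(float(v) for v in str(r.mz_values).split(";")),
                diagnostic_for=str(r.diagnostic_for),
                role=str(r.role),
            )
            for r in df.itertuples(index=False)
        )
        return cls(markers=markers, **kwargs)


def default_marker_db() -> MarkerDB:
    """The marker reference used throughout: printed masses only."""
    markers = (
        PeptideMarker("COL1a2 757 (sheep)", (3017.4, 3033.4), "Ovis", ROLE_SHEEP_757),
        PeptideMarker("COL1a2 757 (goat)", (3077.4, 3093.4), "Capra", ROLE_GOAT_757),
        PeptideMarker("COL1a2 375 (Caprine)", (1154.0, 2028.0, 2044.0), COMPOSITE_CAPRINE, ROLE_CAPRINE_375),
        PeptideMarker("COL1a2 375 (Antilopini)", (1182.0, 2056.0, 2072.0), "Antilopini", ROLE_ANTILOPINI),
        PeptideMarker("a2 889 (Antilopini)", (1532.0,), "Antilopini", ROLE_ANTILOPINI),
        PeptideMarker("gazelle marker", (3227.0,), "Gazella", ROLE_GAZELLE),
        PeptideMarker("red deer marker", (2216.0,), "Cervus", ROLE_DEER),
    )
    return MarkerDB(markers=markers)


# ---------------------------------------------------------------------------
# Matching and classification
# ---------------------------------------------------------------------------


def match_markers(
    peaks: SpectrumPeaks, marker: PeptideMarker, tolerance: float
) -> list[MarkerMatch]:
    """Match a marker's masses against observed peaks within ±tolerance.

    Each observed peak is consumed by at most one marker mass and each
    mass by at most one peak; when several pairings are possible the
    smallest absolute mass error wins.
    """
    if tolerance <= 0:
        raise ValidationError("tolerance must be > 0")
    candidates = [
        (abs(p.mz - mass), mass, p.mz)
        for mass in marker.mz_values
        for p in peaks.peaks
        if abs(p.mz - mass) <= tolerance
    ]
    candidates.sort()
    matches: list[MarkerMatch] = []
    used_masses: set[float] = set()
    used_peaks: set[float] = set()
    for _, mass, mz in candidates:
        if mass in used_masses or mz in used_peaks:
            continue
        used_masses.add(mass)
        used_peaks.add(mz)
        matches.append(MarkerMatch(marker_name=marker.name, marker_mz=mass, observed_mz=mz))
    matches.sort(key=lambda m: m.marker_mz)
    return matches


def classify_spectrum(
    peaks: SpectrumPeaks,
    db: Optional[MarkerDB] = None,
    tolerance: float = 0.2,
) -> TaxonAssignment:
    """Assign the most specific taxon consistent with the matched markers.

    Caprine evidence takes precedence: a COL1α2 757 variant gives Ovis or
    Capra (both variants → composite Ovis/Capra), and COL1α2 375 alone
    gives the Caprine composite. Otherwise gazelle/deer-set matches are
    counted against the per-species marker requirement; insufficient
    evidence degrades to Gazella/Cervus, and no matches at all yields
    ``unidentified``. Excluded taxa are never returned.
    """
    if db is None:
        db = default_marker_db()
    matches_by_role: dict[str, list[MarkerMatch]] = {}
    for marker in db.markers:
        found = match_markers(peaks, marker, tolerance)
        if found:
            matches_by_role.setdefault(marker.role, []).extend(found)

    def ev(*roles: str) -> tuple[MarkerMatch, ...]:
        return tuple(m for role in roles for m in matches_by_role.get(role, ()))

    sheep = ROLE_SHEEP_757 in matches_by_role
    goat = ROLE_GOAT_757 in matches_by_role
    caprine = ROLE_CAPRINE_375 in matches_by_role
    if sheep and goat:
        return TaxonAssignment(
            peaks.specimen_id, COMPOSITE_CAPRINE, "composite",
            ev(ROLE_SHEEP_757, ROLE_GOAT_757, ROLE_CAPRINE_375),
        )
    if sheep:
        return TaxonAssignment(
            peaks.specimen_id, "Ovis", "genus", ev(ROLE_SHEEP_757, ROLE_CAPRINE_375)
        )
    if goat:
        return TaxonAssignment(
            peaks.specimen_id, "Capra", "genus", ev(ROLE_GOAT_757, ROLE_CAPRINE_375)
        )
    if caprine:
        return TaxonAssignment(
            peaks.specimen_id, COMPOSITE_CAPRINE, "composite", ev(ROLE_CAPRINE_375)
        )

    gd_matches = ev(ROLE_ANTILOPINI, ROLE_GAZELLE, ROLE_DEER)
    if gd_matches:
        n_matched = len(gd_matches)
        gazelle_specific = ROLE_GAZELLE in matches_by_role
        deer_specific = ROLE_DEER in matches_by_role
        n_gazelle_masses = len(ev(ROLE_ANTILOPINI, ROLE_GAZELLE))
        need_gazelle = min(
            db.min_species_markers,
            sum(len(m.mz_values) for m in db.by_role(ROLE_ANTILOPINI) + db.by_role(ROLE_GAZELLE)),
        )
        need_deer = min(
            db.min_species_markers,
            sum(len(m.mz_values) for m in db.by_role(ROLE_DEER)),
        )
        gazelle_call = gazelle_specific and n_gazelle_masses >= need_gazelle
        deer_call = deer_specific and len(ev(ROLE_DEER)) >= need_deer
        if gazelle_call and not deer_call:
            return TaxonAssignment(peaks.specimen_id, "Gazella", "genus", gd_matches)
        if deer_call and not gazelle_call and n_matched == len(ev(ROLE_DEER)):
            return TaxonAssignment(peaks.specimen_id, "Cervus", "genus", gd_matches)
        return TaxonAssignment(
            peaks.specimen_id, COMPOSITE_GAZELLE_DEER, "composite", gd_matches
        )

    return TaxonAssignment(peaks.specimen_id, UNIDENTIFIED, "unidentified", ())


def summarize_assignments(assignments: Sequence[TaxonAssignment]) -> dict:
    """Assemblage-level identification summary.

    Returns the submitted/identified counts, the identification rate and
    the genus-or-better rate (percent, nearest integer), and per-taxon
    shares of the identified fraction (percent, one decimal).
    """
    if not assignments:
        raise ValidationError("cannot summarize an empty assignment list")
    n_total = len(assignments)
    identified = [a for a in assignments if a.rank != "unidentified"]
    n_identified = len(identified)
    genus_or_better = [a for a in identified if a.rank in ("species", "genus")]
    taxon_counts = Counter(a.label for a in identified)
    shares = {
        label: round(100.0 * count / n_identified, 1)
        for label, count in sorted(taxon_counts.items())
    } if n_identified else {}
    return {
        "n_submitted": n_total,
        "n_identified": n_identified,
        "identification_rate_pct": round(100.0 * n_identified / n_total),
        "genus_level_rate_pct": (
            round(100.0 * len(genus_or_better) / n_identified) if n_identified else 0
        ),
        "taxon_counts": dict(sorted(taxon_counts.items())),
        "taxon_shares_pct": shares,
    }
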