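"""Readers and writers for the tabular interchange formats.

All tables are comma-separated UTF-8 with a "." decimal and one header
row (peak lists may omit the header). Reading a written table reproduces
it exactly for integers and to 1e-9 for floats.
"""

from __future__ import annotations

import csv
import math
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

from .datatypes import (
    AssemblageTable,
    CollagenSample,
    EnamelBulkSample,
    FormatError,
    IsotopeSample,
    Peak,
    SpectrumPeaks,
    ToothSequence,
    ValidationError,
)

PathLike = Union[str, Path]

SEQUENCE_COLUMNS = ["specimen_id", "taxon", "tooth", "jaw", "x_mm", "d18O", "d13C"]


def _require_columns(df: pd.DataFrame, required: Iterable[str], path: PathLike) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


# ---------------------------------------------------------------------------
# Sequential enamel tables
# ---------------------------------------------------------------------------


def read_sequence_table(path: PathLike) -> list[ToothSequence]:
    """Read sequentially sampled enamel data, one row per drilled sample.

    Columns: specimen_id, taxon, tooth, jaw, x_mm, d18O, d13C (blank δ13C
    cells allowed; blank δ18O is not). An optional ``missing_erj`` column
    (0/1) flags teeth without a locatable enamel–root junction. Rows are
    grouped by specimen and sorted by x.
    """
    df = pd.read_csv(path)
    _require_columns(df, SEQUENCE_COLUMNS[:6], path)
    sequences: list[ToothSequence] = []
    for specimen_id, group in df.groupby("specimen_id", sort=False):
        group = group.sort_values("x_mm")
        xs = group["x_mm"].to_numpy(dtype=float)
        if len(xs) > 1 and (xs[1:] <= xs[:-1]).any():
            raise ValidationError(f"{path}: duplicate x_mm within {specimen_id!r}")
        if group["d18O"].isna().any():
            raise ValidationError(f"{path}: missing d18O for {specimen_id!r}")
        samples = []
        for _, row in group.iterrows():
            d13c = row.get("d13C")
            d13c = None if d13c is None or (isinstance(d13c, float) and math.isnan(d13c)) else float(d13c)
            samples.append(IsotopeSample(x=float(row["x_mm"]), d18O=float(row["d18O"]), d13C=d13c))
        missing_erj = bool(group["missing_erj"].iloc[0]) if "missing_erj" in group else False
        sequences.append(
            ToothSequence(
                specimen_id=str(specimen_id),
                taxon=str(group["taxon"].iloc[0]),
                tooth=str(group["tooth"].iloc[0]),
                jaw=str(group["jaw"].iloc[0]),
                samples=tuple(samples),
                missing_erj=missing_erj,
            )
        )
    return sequences


def write_sequence_table(sequences: Iterable[ToothSequence], path: PathLike) -> None:
    rows = []
    for seq in sequences:
        for s in seq.samples:
            rows.append(
                {
                    "specimen_id": seq.specimen_id,
                    "taxon": seq.taxon,
                    "tooth": seq.tooth,
                    "jaw": seq.jaw,
                    "x_mm": s.x,
                    "d18O": s.d18O,
                    "d13C": "" if s.d13C is None else s.d13C,
                    "missing_erj": int(seq.missing_erj),
                }
            )
    pd.DataFrame(rows, columns=SEQUENCE_COLUMNS + ["missing_erj"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Peak lists
# ---------------------------------------------------------------------------


def read_peaklist(path: PathLike, specimen_id: Optional[str] = None) -> SpectrumPeaks:
    """Read a peptide-mass peak list.

    Accepts a one- or two-column CSV (m/z[, intensity]), with or without a
    header row, or — when the filename ends in .mzML/.mzml — the first
    spectrum of an mzML file (requires pyteomics). Peaks are sorted by
    ascending m/z.
    """
    path = Path(path)
    if path.suffix.lower() == ".mzml":
        return _read_mzml(path, specimen_id)
    pairs: list[tuple[float, Optional[float]]] = []
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.reader(fh)):
            row = [c.strip() for c in row if c.strip() != ""]
            if not row:
                continue
            try:
                mz = float(row[0])
            except ValueError:
                if i == 0:  # header row
                    continue
                raise FormatError(f"{path}: non-numeric m/z {row[0]!r} on line {i + 1}")
            intensity = float(row[1]) if len(row) > 1 else None
            if mz <= 0:
                raise ValidationError(f"{path}: m/z must be positive, got {mz}")
            pairs.append((mz, intensity))
    pairs.sort(key=lambda p: p[0])
    return SpectrumPeaks(
        specimen_id=specimen_id or path.stem,
        peaks=tuple(Peak(mz=mz, intensity=it) for mz, it in pairs),
    )


def _read_mzml(path: Path, specimen_id: Optional[str]) -> SpectrumPeaks:
    try:
        from pyteomics import mzml
    except ImportError as exc:  # pragma: no cover
        raise FormatError("reading mzML requires the 'pyteomics' package") from exc
    try:
        with mzml.read(str(path)) as reader:
            spectrum = next(iter(reader))
    except StopIteration:
        raise FormatError(f"{path}: mzML file contains no spectra")
    except Exception as exc:
        raise FormatError(f"{path}: unreadable mzML ({exc})")
    mzs = spectrum["m/z array"]
    intensities = spectrum.get("intensity array")
    order = mzs.argsort()
    peaks = tuple(
        Peak(mz=float(mzs[i]), intensity=None if intensities is None else float(intensities[i]))
        for i in order
    )
    return SpectrumPeaks(specimen_id=specimen_id or path.stem, peaks=peaks)


def write_peaklist(spectrum: SpectrumPeaks, path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        for p in spectrum.peaks:
            writer.writerow([p.mz] if p.intensity is None else [p.mz, p.intensity])


# ---------------------------------------------------------------------------
# Count tables
# ---------------------------------------------------------------------------


def read_counts_table(path: PathLike, kind: str = "NISP") -> AssemblageTable:
    """Read a taxon × horizon count table.

    The first column holds taxon labels. If the first row's remaining
    cells are numeric it is treated as data and horizons are auto-named
    H0, H1, …; otherwise it is the horizon header.
    """
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh) if any(c.strip() for c in r)]
    if not rows:
        raise FormatError(f"{path}: empty counts table")

    def _numeric(cell: str) -> bool:
        try:
            float(cell)
            return True
        except ValueError:
            return False

    first_data = 0
    if not all(_numeric(c) for c in rows[0][1:]):
        horizons = [c.strip() for c in rows[0][1:]]
        first_data = 1
    else:
        horizons = [f"H{i}" for i in range(len(rows[0]) - 1)]

    taxa, data = [], []
    for row in rows[first_data:]:
        taxa.append(row[0].strip())
        cells = []
        for cell in row[1:]:
            value = float(cell)
            if value != int(value):
                raise ValidationError(f"{path}: non-integer count {cell!r}")
            if value < 0:
                raise ValidationError(f"{path}: negative count {cell!r}")
            cells.append(int(value))
        if len(cells) != len(horizons):
            raise FormatError(f"{path}: ragged row for taxon {row[0]!r}")
        data.append(cells)
    df = pd.DataFrame(data, index=taxa, columns=horizons)
    return AssemblageTable(counts=df, kind=kind)


def write_counts_table(table: AssemblageTable, path: PathLike) -> None:
    out = table.counts.copy()
    out.index.name = "taxon"
    out.to_csv(path)


# ---------------------------------------------------------------------------
# Bulk isotope tables
# ---------------------------------------------------------------------------

COLLAGEN_COLUMNS = ["specimen_id", "d13C", "d15N", "pctC", "pctN", "cn_atomic", "horizon"]
BULK_COLUMNS = ["specimen_id", "family", "d13C", "d18O", "horizon"]


def read_collagen_table(path: PathLike) -> list[CollagenSample]:
    df = pd.read_csv(path)
    _require_columns(df, COLLAGEN_COLUMNS, path)
    return [
        CollagenSample(
            specimen_id=str(r.specimen_id),
            d13C=float(r.d13C),
            d15N=float(r.d15N),
            pctC=float(r.pctC),
            pctN=float(r.pctN),
            cn_atomic=float(r.cn_atomic),
            horizon=str(r.horizon),
        )
        for r in df.itertuples()
    ]


def write_collagen_table(samples: Iterable[CollagenSample], path: PathLike) -> None:
    pd.DataFrame(
        [
            {
                "specimen_id": s.specimen_id,
                "d13C": s.d13C,
                "d15N": s.d15N,
                "pctC": s.pctC,
                "pctN": s.pctN,
                "cn_atomic": s.cn_atomic,
                "horizon": s.horizon,
            }
            for s in samples
        ],
        columns=COLLAGEN_COLUMNS,
    ).to_csv(path, index=False)


def read_bulk_table(path: PathLike) -> list[EnamelBulkSample]:
    df = pd.read_csv(path)
    _require_columns(df, BULK_COLUMNS, path)
    return [
        EnamelBulkSample(
            specimen_id=str(r.specimen_id),
            family=str(r.family),
            d13C=float(r.d13C),
            d18O=float(r.d18O),
            horizon=str(r.horizon),
        )
        for r in df.itertuples()
    ]


def write_bulk_table(samples: Iterable[EnamelBulkSample], path: PathLike) -> None:
    pd.DataFrame(
        [
            {
                "specimen_id": s.specimen_id,
                "family": s.family,
                "d13C": s.d13C,
                "d18O": s.d18O,
                "horizon": s.horizon,
            }
            for s in samples
        ],
        columns=BULK_COLUMNS,
    ).to_csv(path, index=False)
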