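"""Core data types and tabular input/output.

The pipeline's atomic record is a single replicate measurement of one side
of one individual (:class:`WingMeasurement`).  Records are assembled into
balanced blocks (:class:`GenotypeSample`, n individuals x 2 sides x r
replicates) — the unit on which the asymmetry ANOVA operates.  Wing length
may also be derived from 2-D landmark coordinates as the Euclidean distance
between landmarks 3 and 13.

Canonical on-disk format is a long (tidy) CSV with columns
``individual, genotype, series, side, replicate, length``; a column-name
mapping accommodates other dialects.  Units are carried as an opaque
dataset-level convention and never converted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DataError",
    "WingMeasurement",
    "LandmarkSet",
    "GenotypeSample",
    "DeficiencyRecord",
    "AssemblyResult",
    "read_measurements",
    "write_measurements",
    "measurements_to_frame",
    "frame_to_measurements",
    "landmark_length",
    "read_landmarks",
    "read_deficiencies",
    "assemble_samples",
]

#: canonical column names of the measurement table
MEASUREMENT_COLUMNS = ("individual", "genotype", "series", "side", "replicate", "length")

_SIDE_TOKENS = {
    "l": "L", "left": "L", "L": "L",
    "r": "R", "right": "R", "R": "R",
}


class DataError(ValueError):
    """Fatal problem in input data (missing column, duplicate record, ...)."""


def _normalize_side(token) -> str:
    key = str(token).strip()
    side = _SIDE_TOKENS.get(key) or _SIDE_TOKENS.get(key.lower())
    if side is None:
        raise DataError(f"unrecognized side token {token!r} (expected L/R/left/right)")
    return side


@dataclass(frozen=True)
class WingMeasurement:
    """One replicate measurement of one side of one individual."""

    individual_id: str
    genotype_label: str
    series_id: str
    side: str            # "L" or "R"
    replicate: int       # 1-based
    length: float        # linear units (µm or px, dataset-constant), > 0

    def __post_init__(self):
        object.__setattr__(self, "side", _normalize_side(self.side))
        if not self.length > 0:
            raise DataError(
                f"non-positive length {self.length!r} for individual {self.individual_id!r}"
            )
        if self.replicate < 1:
            raise DataError(f"replicate index must be >= 1, got {self.replicate}")


@dataclass(frozen=True)
class LandmarkSet:
    """Digitized 2-D landmarks of one wing image (one side, one replicate)."""

    individual_id: str
    side: str
    replicate: int
    landmarks: Mapping[int, tuple[float, float]]

    def __post_init__(self):
        object.__setattr__(self, "side", _normalize_side(self.side))


@dataclass(frozen=True)
class DeficiencyRecord:
    """Metadata for one chromosomal deficiency."""

    name: str
    chromosome_arm: str = ""
    cytology_start: str = ""
    cytology_end: str = ""
    span_length: float = float("nan")   # bp or band count, unit-free downstream
    background: str = "unknown"


class GenotypeSample:
    """Balanced measurement block for one genotype in one series.

    Values are stored as an array of shape ``(n, 2, r)`` with the side axis
    ordered (L, R), which is the layout the ANOVA decomposition consumes.
    """

    SIDES = ("L", "R")

    def __init__(self, genotype_label: str, series_id: str,
                 individual_ids: Sequence[str], values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.ndim != 3 or values.shape[1] != 2:
            raise DataError(f"values must have shape (n, 2, r), got {values.shape}")
        if values.shape[0] != len(individual_ids):
            raise DataError("individual_ids length does not match values")
        self.genotype_label = genotype_label
        self.series_id = series_id
        self.individual_ids = list(individual_ids)
        self.values = values

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def r(self) -> int:
        return self.values.shape[2]

    def subset(self, keep_ids: Sequence[str]) -> "GenotypeSample":
        keep = set(keep_ids)
        idx = [i for i, iid in enumerate(self.individual_ids) if iid in keep]
        return GenotypeSample(self.genotype_label, self.series_id,
                              [self.individual_ids[i] for i in idx],
                              self.values[idx])

    def to_measurements(self) -> list[WingMeasurement]:
        out = []
        for i, iid in enumerate(self.individual_ids):
            for s, side in enumerate(self.SIDES):
                for k in range(self.r):
                    out.append(WingMeasurement(iid, self.genotype_label,
                                               self.series_id, side, k + 1,
                                               float(self.values[i, s, k])))
        return out

    def mean_size(self) -> float:
        """Mean wing length over all individuals, sides and replicates."""
        return float(self.values.mean())

    def __repr__(self):
        return (f"GenotypeSample({self.genotype_label!r}, series={self.series_id!r}, "
                f"n={self.n}, r={self.r})")


# ---------------------------------------------------------------------------
# measurement table I/O

def _resolve_columns(df: pd.DataFrame, colmap: Mapping[str, str] | None) -> pd.DataFrame:
    colmap = dict(colmap or {})
    rename = {}
    for canon in MEASUREMENT_COLUMNS:
        src = colmap.get(canon, canon)
        if src not in df.columns:
            raise DataError(f"required column {src!r} (for {canon!r}) missing from header")
        rename[src] = canon
    return df.rename(columns=rename)[list(MEASUREMENT_COLUMNS)]


def read_measurements(path, colmap: Mapping[str, str] | None = None,
                      sep: str = ",") -> list[WingMeasurement]:
    """Read a long-format measurement table into validated records.

    Raises :class:`DataError` on a missing column, a non-positive length
    (reporting the individual) or a duplicate (individual, side, replicate)
    key.  Row order is preserved.
    """
    df = pd.read_csv(path, sep=sep, dtype=str)
    df = _resolve_columns(df, colmap)
    records = []
    for row in df.itertuples(index=False):
        try:
            length = float(row.length)
        except (TypeError, ValueError):
            raise DataError(f"non-numeric length {row.length!r} for individual {row.individual!r}")
        records.append(WingMeasurement(
            individual_id=str(row.individual),
            genotype_label=str(row.genotype),
            series_id=str(row.series),
            side=str(row.side),
            replicate=int(row.replicate),
            length=length,
        ))
    seen = set()
    for m in records:
        key = (m.individual_id, m.side, m.replicate)
        if key in seen:
            raise DataError(f"duplicate record for individual {key[0]!r}, side {key[1]}, replicate {key[2]}")
        seen.add(key)
    return records


def measurements_to_frame(records: Iterable[WingMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        [(m.individual_id, m.genotype_label, m.series_id, m.side, m.replicate, m.length)
         for m in records],
        columns=list(MEASUREMENT_COLUMNS),
    )


def frame_to_measurements(df: pd.DataFrame,
                          colmap: Mapping[str, str] | None = None) -> list[WingMeasurement]:
    df = _resolve_columns(df, colmap)
    return [WingMeasurement(str(t.individual), str(t.genotype), str(t.series),
                            str(t.side), int(t.replicate), float(t.length))
            for t in df.itertuples(index=False)]


def write_measurements(records: Iterable[WingMeasurement], path, sep: str = ",") -> None:
    measurements_to_frame(records).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# landmarks

def landmark_length(lm: LandmarkSet, a: int = 3, b: int = 13) -> float:
    """Wing length as the Euclidean distance between two landmarks.

    By convention length is the distance between landmarks 3 and 13 of the
    standard 15-landmark Drosophila wing scheme.
    """
    try:
        xa, ya = lm.landmarks[a]
        xb, yb = lm.landmarks[b]
    except KeyError as exc:
        raise DataError(
            f"individual {lm.individual_id!r}: landmark {exc.args[0]} missing "
            f"(need {a} and {b} for length)"
        ) from None
    return math.hypot(xb - xa, yb - ya)


def read_landmarks(path, sep: str = ",") -> list[LandmarkSet]:
    """Read landmark CSV (individual, side, replicate, landmark_index, x, y)."""
    df = pd.read_csv(path, sep=sep)
    need = {"individual", "side", "replicate", "landmark_index", "x", "y"}
    missing = need - set(df.columns)
    if missing:
        raise DataError(f"landmark file missing columns: {sorted(missing)}")
    out = []
    for (iid, side, rep), grp in df.groupby(["individual", "side", "replicate"], sort=False):
        lms = {int(t.landmark_index): (float(t.x), float(t.y))
               for t in grp.itertuples(index=False)}
        out.append(LandmarkSet(str(iid), str(side), int(rep), lms))
    return out


def read_deficiencies(path, sep: str = "\t") -> list[DeficiencyRecord]:
    """Read deficiency metadata TSV (name, arm, cytology_start, cytology_end, span, background)."""
    df = pd.read_csv(path, sep=sep)
    if "name" not in df.columns:
        raise DataError("deficiency metadata requires a 'name' column")
    if df["name"].duplicated().any():
        dup = df.loc[df["name"].duplicated(), "name"].iloc[0]
        raise DataError(f"duplicate deficiency name {dup!r}")
    recs = []
    for t in df.itertuples(index=False):
        d = t._asdict()
        recs.append(DeficiencyRecord(
            name=str(d["name"]),
            chromosome_arm=str(d.get("arm", d.get("chromosome_arm", ""))),
            cytology_start=str(d.get("cytology_start", "")),
            cytology_end=str(d.get("cytology_end", "")),
            span_length=float(d.get("span", d.get("span_length", float("nan")))),
            background=str(d.get("background", "unknown")),
        ))
    return recs


# ---------------------------------------------------------------------------
# sample assembly

@dataclass
class AssemblyResult:
    """Samples plus an audit of every record that was not retained."""

    samples: list[GenotypeSample]
    excluded: pd.DataFrame = field(default_factory=pd.DataFrame)  # individual, genotype, series, reason
    unusable: list[tuple[str, str, str]] = field(default_factory=list)  # (genotype, series, reason)


def assemble_samples(records: Iterable[WingMeasurement],
                     min_n: int = 2) -> AssemblyResult:
    """Group records into balanced GenotypeSamples, one per (genotype, series).

    Individuals with incomplete blocks (missing side or replicate) are
    excluded and reported rather than imputed; the replicate count r must be
    constant within a sample.  A sample left with fewer than ``min_n``
    complete individuals is flagged unusable (no ANOVA possible).
    """
    records = list(records)
    excluded_rows: list[dict] = []
    unusable: list[tuple[str, str, str]] = []
    samples: list[GenotypeSample] = []
    if not records:
        return AssemblyResult(samples=[], excluded=pd.DataFrame(
            columns=["individual", "genotype", "series", "reason"]))

    df = measurements_to_frame(records)
    for (gt, ser), grp in df.groupby(["genotype", "series"], sort=False):
        # an individual forms a complete block of size k when both sides carry
        # exactly replicates 1..k; distinct complete k within a sample is fatal
        blocks: dict[str, np.ndarray] = {}
        block_sizes: dict[str, int] = {}
        for iid, sub in grp.groupby("individual", sort=False):
            per_side = {}
            for side in GenotypeSample.SIDES:
                side_rows = sub[sub["side"] == side].sort_values("replicate")
                per_side[side] = side_rows
            k = len(per_side["L"])
            complete = k >= 1 and all(
                len(rows) == k and list(rows["replicate"]) == list(range(1, k + 1))
                for rows in per_side.values())
            if complete:
                blocks[str(iid)] = np.stack(
                    [per_side[s]["length"].to_numpy(dtype=float) for s in GenotypeSample.SIDES])
                block_sizes[str(iid)] = k
            else:
                excluded_rows.append({"individual": str(iid), "genotype": gt,
                                      "series": ser, "reason": "incomplete block"})
        distinct_r = sorted(set(block_sizes.values()))
        if len(distinct_r) > 1:
            raise DataError(
                f"sample ({gt!r}, {ser!r}): mixed replicate counts {distinct_r} within a sample")
        keep_ids = list(blocks)
        keep_rows = [blocks[i] for i in keep_ids]
        if len(keep_ids) < min_n:
            unusable.append((gt, ser, f"only {len(keep_ids)} complete individuals (< {min_n})"))
            if keep_ids:
                samples.append(GenotypeSample(gt, ser, keep_ids, np.stack(keep_rows)))
            continue
        samples.append(GenotypeSample(gt, ser, keep_ids, np.stack(keep_rows)))
    excluded = pd.DataFrame(excluded_rows, columns=["individual", "genotype", "series", "reason"])
    return AssemblyResult(samples=samples, excluded=excluded, unusable=unusable)
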