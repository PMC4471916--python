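"""Labeled song sequences: parsing, repertoire measures, and descriptive statistics.

A *song sequence* is one male's ordered record of song-type labels, each type
carrying a fixed category (whistle / trill / buzz / other).  From a fixed
window of consecutive songs (533 by default) we derive the repertoire size,
the per-category repertoire sizes, and the per-category occurrence counts.
Across males, each measure is summarised by mean, sample SD and coefficient
of variation.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import FormatError, IntegrityError, StatisticsError

CATEGORIES = ("whistle", "trill", "buzz", "other")
#: Categories that carry their own repertoire/occurrence measures.
NAMED_CATEGORIES = ("whistle", "trill", "buzz")

#: Default analysis window: number of consecutive songs per male.
DEFAULT_WINDOW = 533

REQUIRED_COLUMNS = ("male_id", "position", "song_type", "category")


@dataclass(frozen=True)
class SongRecord:
    """One sung song: type label plus its (fixed) category."""

    male_id: str
    position: int
    song_type: str
    category: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise IntegrityError(
                f"male {self.male_id!r}: position must be >= 1, got {self.position}"
            )
        if self.category not in CATEGORIES:
            raise IntegrityError(
                f"male {self.male_id!r}, position {self.position}: unknown "
                f"category {self.category!r} (expected one of {CATEGORIES})"
            )


@dataclass(frozen=True)
class SongSequence:
    """Ordered songs of one male; positions must run 1..L without gaps."""

    male_id: str
    records: tuple[SongRecord, ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise IntegrityError(f"male {self.male_id!r}: empty song sequence")
        for expected, rec in enumerate(self.records, start=1):
            if rec.male_id != self.male_id:
                raise IntegrityError(
                    f"record for male {rec.male_id!r} inside sequence of "
                    f"{self.male_id!r}"
                )
            if rec.position != expected:
                raise IntegrityError(
                    f"male {self.male_id!r}: non-consecutive position "
                    f"{rec.position} (expected {expected})"
                )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def types(self) -> tuple[str, ...]:
        return tuple(r.song_type for r in self.records)

    @property
    def categories(self) -> tuple[str, ...]:
        return tuple(r.category for r in self.records)


@dataclass(frozen=True)
class RepertoireSummary:
    """Repertoire and category measures over a window of consecutive songs."""

    male_id: str
    repertoire_size: int
    whistle_repertoire: int
    trill_repertoire: int
    buzz_repertoire: int
    whistle_occurrence: int
    trill_occurrence: int
    buzz_occurrence: int
    window_length: int

    def __post_init__(self) -> None:
        for cat in NAMED_CATEGORIES:
            rep = getattr(self, f"{cat}_repertoire")
            occ = getattr(self, f"{cat}_occurrence")
            if rep > self.repertoire_size:
                raise IntegrityError(
                    f"{cat} repertoire {rep} exceeds repertoire size "
                    f"{self.repertoire_size}"
                )
            if occ < rep:
                raise IntegrityError(
                    f"{cat} occurrence {occ} below its repertoire {rep}"
                )
        total_occ = (
            self.whistle_occurrence + self.trill_occurrence + self.buzz_occurrence
        )
        if total_occ > self.window_length:
            raise IntegrityError(
                f"category occurrences sum to {total_occ} > window "
                f"{self.window_length}"
            )
        if self.repertoire_size > self.window_length:
            raise IntegrityError("repertoire size exceeds window length")

    def as_dict(self) -> dict:
        return {
            "male_id": self.male_id,
            "repertoire_size": self.repertoire_size,
            "whistle_repertoire": self.whistle_repertoire,
            "trill_repertoire": self.trill_repertoire,
            "buzz_repertoire": self.buzz_repertoire,
            "whistle_occurrence": self.whistle_occurrence,
            "trill_occurrence": self.trill_occurrence,
            "buzz_occurrence": self.buzz_occurrence,
            "window_length": self.window_length,
        }


@dataclass(frozen=True)
class MeasureStats:
    """Mean / sample SD / CV of one measure across males.

    ``cv`` is ``None`` (and ``cv_defined`` False) when the mean is zero; a CV
    of a zero-mean measure is undefined, never silently 0.
    """

    measure: str
    mean: float
    sd: float
    cv: float | None = field(default=None)

    @property
    def cv_defined(self) -> bool:
        return self.cv is not None

    def rounded(self, decimals: int = 2) -> dict:
        """Report-time rounding; internal values stay full precision."""
        return {
            "measure": self.measure,
            "mean": round(self.mean, decimals),
            "sd": round(self.sd, decimals),
            "cv": None if self.cv is None else round(self.cv, decimals),
        }


def _detect_separator(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_sequences(path: str | Path) -> list[SongSequence]:
    """Read a delimited text file of labeled songs into per-male sequences.

    The file must have columns ``male_id, position, song_type, category``
    (comma- or tab-separated, auto-detected from the header).  Positions must
    be consecutive from 1 within each male, and a song type must keep one
    category throughout the corpus.
    """
    path = Path(path)
    sep = _detect_separator(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    try:
        df["position"] = df["position"].astype(int)
    except ValueError as exc:
        raise FormatError(f"{path}: non-integer position value ({exc})") from exc

    # Corpus-wide category consistency: one category per song type.
    type_cat = df.groupby("song_type")["category"].nunique()
    drifters = type_cat[type_cat > 1].index.tolist()
    if drifters:
        raise IntegrityError(
            f"{path}: song type(s) {drifters} appear with more than one category"
        )

    sequences = []
    for male_id, grp in df.groupby("male_id", sort=True):
        grp = grp.sort_values("position")
        records = tuple(
            SongRecord(
                male_id=str(male_id),
                position=int(row.position),
                song_type=str(row.song_type),
                category=str(row.category),
            )
            for row in grp.itertuples()
        )
        positions = [r.position for r in records]
        if positions != list(range(1, len(records) + 1)):
            bad = next(
                (p for i, p in enumerate(positions, start=1) if p != i), positions[0]
            )
            raise IntegrityError(
                f"{path}: male {male_id!r} has non-consecutive positions "
                f"(first offending position {bad})"
            )
        sequences.append(SongSequence(male_id=str(male_id), records=records))
    return sequences


def compute_repertoire(
    seq: SongSequence, window: int = DEFAULT_WINDOW
) -> RepertoireSummary:
    """Repertoire and category measures over the first ``window`` songs.

    If the sequence is shorter than ``window``, the full sequence is used,
    the actual length is recorded in ``window_length``, and a warning is
    emitted.
    """
    if len(seq) == 0:  # unreachable through the constructor, kept as guard
        raise IntegrityError("empty sequence")
    if len(seq) < window:
        warnings.warn(
            f"male {seq.male_id!r}: sequence length {len(seq)} shorter than "
            f"window {window}; computing on the full sequence",
            stacklevel=2,
        )
        window = len(seq)
    recs = seq.records[:window]
    types: set[str] = set()
    cat_types: dict[str, set[str]] = {c: set() for c in NAMED_CATEGORIES}
    cat_occ: dict[str, int] = {c: 0 for c in NAMED_CATEGORIES}
    for r in recs:
        types.add(r.song_type)
        if r.category in cat_types:
            cat_types[r.category].add(r.song_type)
            cat_occ[r.category] += 1
    return RepertoireSummary(
        male_id=seq.male_id,
        repertoire_size=len(types),
        whistle_repertoire=len(cat_types["whistle"]),
        trill_repertoire=len(cat_types["trill"]),
        buzz_repertoire=len(cat_types["buzz"]),
        whistle_occurrence=cat_occ["whistle"],
        trill_occurrence=cat_occ["trill"],
        buzz_occurrence=cat_occ["buzz"],
        window_length=window,
    )


def accumulation_curve(seq: SongSequence) -> list[int]:
    """Cumulative distinct-type count after each song (repertoire saturation)."""
    seen: set[str] = set()
    curve: list[int] = []
    for r in seq.records:
        seen.add(r.song_type)
        curve.append(len(seen))
    return curve


def describe_measures(
    values: Mapping[str, Sequence[float]] | pd.DataFrame,
) -> list[MeasureStats]:
    """Mean, sample SD (n-1 denominator) and CV per measure across males.

    ``values`` maps each measure name to its per-male values (a DataFrame of
    per-male rows works too).  Requires at least two males.
    """
    if isinstance(values, pd.DataFrame):
        values = {str(c): values[c].to_list() for c in values.columns}
    out: list[MeasureStats] = []
    for name, vals in values.items():
        vals = [float(v) for v in vals]
        n = len(vals)
        if n < 2:
            raise StatisticsError(
                f"measure {name!r}: need >= 2 males, got {n}"
            )
        mean = sum(vals) / n
        sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / (n - 1))
        cv = None if mean == 0 else sd / mean
        out.append(MeasureStats(measure=name, mean=mean, sd=sd, cv=cv))
    return out


def summaries_to_frame(summaries: Iterable[RepertoireSummary]) -> pd.DataFrame:
    """Per-male summary table, one row per male."""
    return pd.DataFrame([s.as_dict() for s in summaries]).set_index("male_id")


def write_measure_report(
    stats: Iterable[MeasureStats],
    csv_path: str | Path | None = None,
    json_path: str | Path | None = None,
    decimals: int = 2,
) -> pd.DataFrame:
    """Write the across-male statistics table (rounded) as CSV and/or JSON."""
    rows = [s.rounded(decimals) for s in stats]
    df = pd.DataFrame(rows)
    if csv_path is not None:
        df.to_csv(csv_path, index=False)
    if json_path is not None:
        Path(json_path).write_text(json.dumps(rows, indent=2) + "\n")
    return df
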