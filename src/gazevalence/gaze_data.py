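"""Data model for fixations, saccades and scanpaths, with tabular I/O.

Coordinate convention (shared by every module): 0-based pixels, origin at
the top-left corner, ``x`` increasing rightward and ``y`` increasing
downward.  Times are in milliseconds from an arbitrary per-scanpath origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

#: Shortest gaze dwell that counts as a fixation (ms).
MIN_FIXATION_MS = 100.0

#: Mean-valence band (1-9 SAM scale) labelled "neutral"; both boundaries
#: are inclusive.  Below the band is "unpleasant", above is "pleasant".
NEUTRAL_VALENCE_LOW = 3.8
NEUTRAL_VALENCE_HIGH = 5.8

#: Canonical class order used for every confusion matrix and label vector.
CLASSES = ("unpleasant", "neutral", "pleasant")

FIXATION_COLUMNS = ["image_id", "observer_id", "x", "y", "t_start_ms", "t_end_ms"]
LABEL_COLUMNS = ["image_id", "mean_valence"]


class ValidationError(ValueError):
    """A record violates a fixation/scanpath invariant."""


class FormatError(ValueError):
    """A table is missing a required column or is otherwise malformed."""


@dataclass(frozen=True)
class Fixation:
    """One gaze dwell: where the gaze landed and for how long."""

    image_id: str
    observer_id: str
    x: float
    y: float
    t_start: float
    t_end: float

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    def validate(self, width: float, height: float) -> None:
        # small slack: durations are often reconstructed via float time sums
        if self.t_end - self.t_start < MIN_FIXATION_MS - 1e-6:
            raise ValidationError(
                f"fixation duration {self.t_end - self.t_start:g} ms below the "
                f"{MIN_FIXATION_MS:g} ms minimum"
            )
        if not (0 <= self.x < width) or not (0 <= self.y < height):
            raise ValidationError(
                f"fixation at ({self.x:g}, {self.y:g}) outside the "
                f"{width:g}x{height:g} image"
            )


@dataclass(frozen=True)
class Saccade:
    """A gaze shift between two consecutive fixations.

    By convention the saccade occupies the inter-fixation gap: ``t_start``
    is the end of the previous fixation and ``t_end`` the start of the
    next, so a zero-duration saccade is legal (handled downstream).
    """

    x_start: float
    y_start: float
    x_end: float
    y_end: float
    t_start: float
    t_end: float

    @property
    def dx(self) -> float:
        return self.x_end - self.x_start

    @property
    def dy(self) -> float:
        return self.y_end - self.y_start

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class Scanpath:
    """Time-ordered fixations of one observer on one image."""

    image_id: str
    observer_id: str
    fixations: list[Fixation] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.fixations)

    def __iter__(self) -> Iterator[Fixation]:
        return iter(self.fixations)

    def validate(self, width: float, height: float) -> None:
        prev_end = -np.inf
        for f in self.fixations:
            if f.image_id != self.image_id or f.observer_id != self.observer_id:
                raise ValidationError("fixation ids disagree with scanpath ids")
            if f.t_start < prev_end:
                raise ValidationError(
                    f"overlapping fixation intervals in scanpath "
                    f"({self.image_id}, {self.observer_id})"
                )
            f.validate(width, height)
            prev_end = f.t_end


@dataclass
class GazeRecordset:
    """A labelled gaze dataset: scanpaths grouped by image plus per-image
    mean valence ratings and the derived 3-class labels."""

    image_width: float = 1024.0
    image_height: float = 768.0
    scanpaths: list[Scanpath] = field(default_factory=list)
    mean_valence: dict[str, float] = field(default_factory=dict)
    valence_class: dict[str, str] = field(default_factory=dict)

    @property
    def image_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for sp in self.scanpaths:
            seen.setdefault(sp.image_id, None)
        return list(seen)

    def scanpaths_for(self, image_id: str) -> list[Scanpath]:
        return [sp for sp in self.scanpaths if sp.image_id == image_id]

    def labels(self) -> list[str]:
        """Class label per image, in ``image_ids`` order."""
        return [self.valence_class[i] for i in self.image_ids]

    def validate(self) -> None:
        if self.image_width <= 0 or self.image_height <= 0:
            raise ValidationError("image dimensions must be positive")
        for sp in self.scanpaths:
            if sp.image_id not in self.valence_class:
                raise ValidationError(f"image {sp.image_id!r} has no valence label")
            sp.validate(self.image_width, self.image_height)


def label_valence(mean_valence: float) -> str:
    """Map a mean 1-9 SAM valence rating to one of the three classes.

    Ratings in the closed band [3.8, 5.8] are neutral; lower ratings are
    unpleasant, higher are pleasant.
    """
    if not (1.0 <= mean_valence <= 9.0):
        raise ValueError(f"mean valence {mean_valence!r} outside the 1-9 scale")
    if mean_valence < NEUTRAL_VALENCE_LOW:
        return "unpleasant"
    if mean_valence > NEUTRAL_VALENCE_HIGH:
        return "pleasant"
    return "neutral"


def derive_saccades(scanpath: Scanpath | Sequence[Fixation]) -> list[Saccade]:
    """Approximate saccades from consecutive fixations.

    Saccade ``i`` runs from the location of fixation ``i`` to fixation
    ``i+1`` and occupies the inter-fixation interval.  ``n`` fixations
    yield ``n - 1`` saccades; 0 or 1 fixations yield none.
    """
    fixations = list(scanpath)
    out = []
    for a, b in zip(fixations, fixations[1:]):
        out.append(
            Saccade(
                x_start=a.x, y_start=a.y, x_end=b.x, y_end=b.y,
                t_start=a.t_end, t_end=b.t_start,
            )
        )
    return out


def _require_columns(df: pd.DataFrame, required: Iterable[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def read_fixation_table(
    path: str | Path,
    label_path: str | Path | None = None,
    width: float = 1024.0,
    height: float = 768.0,
) -> GazeRecordset:
    """Read a fixation CSV (and its companion label CSV) into a recordset.

    The fixation table needs columns ``image_id, observer_id, x, y,
    t_start_ms, t_end_ms``; the label table ``image_id, mean_valence`` and
    optionally ``valence_class`` (derived with :func:`label_valence` when
    absent).  ``label_path`` defaults to ``<path stem>_labels.csv``.

    Rows violating the fixation invariants raise :class:`ValidationError`
    naming the offending 1-based data row numbers.
    """
    path = Path(path)
    if label_path is None:
        label_path = path.with_name(path.stem + "_labels.csv")
    df = pd.read_csv(path, dtype={"image_id": str, "observer_id": str},
                     float_precision="round_trip")
    _require_columns(df, FIXATION_COLUMNS, path)
    labels = pd.read_csv(label_path, dtype={"image_id": str},
                         float_precision="round_trip")
    _require_columns(labels, LABEL_COLUMNS, label_path)

    rs = GazeRecordset(image_width=width, image_height=height)
    for _, row in labels.iterrows():
        v = float(row["mean_valence"])
        rs.mean_valence[row["image_id"]] = v
        if "valence_class" in labels.columns and isinstance(row.get("valence_class"), str):
            rs.valence_class[row["image_id"]] = row["valence_class"]
        else:
            rs.valence_class[row["image_id"]] = label_valence(v)

    bad_rows: list[str] = []
    groups: dict[tuple[str, str], list[Fixation]] = {}
    for idx, row in df.iterrows():
        fix = Fixation(
            image_id=row["image_id"], observer_id=row["observer_id"],
            x=float(row["x"]), y=float(row["y"]),
            t_start=float(row["t_start_ms"]), t_end=float(row["t_end_ms"]),
        )
        try:
            fix.validate(width, height)
        except ValidationError as exc:
            bad_rows.append(f"row {idx + 1}: {exc}")
            continue
        if fix.image_id not in rs.valence_class:
            bad_rows.append(f"row {idx + 1}: image {fix.image_id!r} has no label")
            continue
        groups.setdefault((fix.image_id, fix.observer_id), []).append(fix)
    if bad_rows:
        raise ValidationError(
            f"{path}: {len(bad_rows)} invalid row(s): " + "; ".join(bad_rows[:20])
        )

    for (img, obs), fixes in groups.items():
        fixes.sort(key=lambda f: f.t_start)
        rs.scanpaths.append(Scanpath(image_id=img, observer_id=obs, fixations=fixes))
    rs.scanpaths.sort(key=lambda sp: (sp.image_id, sp.observer_id))
    rs.validate()
    return rs


def write_fixation_table(
    recordset: GazeRecordset,
    path: str | Path,
    label_path: str | Path | None = None,
) -> None:
    """Write a recordset in the dialect :func:`read_fixation_table` accepts.

    Rows are ordered by (image_id, observer_id, t_start) so output is
    deterministic for a given recordset.
    """
    path = Path(path)
    if label_path is None:
        label_path = path.with_name(path.stem + "_labels.csv")
    rows = [
        (f.image_id, f.observer_id, f.x, f.y, f.t_start, f.t_end)
        for sp in recordset.scanpaths
        for f in sp.fixations
    ]
    rows.sort(key=lambda r: (r[0], r[1], r[4]))
    pd.DataFrame(rows, columns=FIXATION_COLUMNS).to_csv(
        path, index=False, float_format="%.17g"
    )
    label_rows = [
        (img, recordset.mean_valence[img], recordset.valence_class[img])
        for img in sorted(recordset.valence_class)
    ]
    pd.DataFrame(label_rows, columns=LABEL_COLUMNS + ["valence_class"]).to_csv(
        label_path, index=False, float_format="%.17g"
    )
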