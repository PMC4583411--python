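"""Per-image eye-movement feature representations.

Ten blocks, pooled over all observers of an image, concatenate to an
872-dimensional vector:

==========================  ====  ==============================================
block                       dims  content
==========================  ====  ==============================================
saliency_map                 300  15x20 down-sampled fixation-density map
top10_salient                 20  10 strongest density peaks (normalized x, y)
fixation_histogram           256  fixation counts on a 16x16 spatial grid
saliency_histogram            10  density values sampled at the fixations
fixation_duration_hist        60  distribution of fixation durations
saccade_duration_hist         60  distribution of inter-fixation gap durations
saccade_slope_hist            30  undirected saccade line angles, 6 deg bins
saccade_length_hist           50  Euclidean saccade amplitudes
saccade_velocity_hist         50  saccade amplitude / gap duration
saccade_orientation_hist      36  angle between successive saccades, 5 deg bins
==========================  ====  ==============================================

Histograms are normalized to probability mass (raw counts via a flag);
bins are equal-width over a fixed, dataset-global range so that absolute
scale differences between images survive the encoding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .gaze_data import Fixation, GazeRecordset, Saccade, Scanpath, derive_saccades

__all__ = [
    "BinningScheme", "SaliencyMap", "FeatureVector", "GazeFeaturizer",
    "MeanValueFeaturizer", "DEFAULT_SCHEMES", "BLOCK_SIZES",
    "fixation_duration", "saccade_length", "saccade_duration",
    "saccade_slope_angle", "saccade_orientation", "saccade_velocity",
    "build_histogram", "compute_saliency_map", "saliency_histogram",
    "fixation_histogram", "top10_salient", "extract_features",
    "feature_matrix", "mean_features",
]

#: (name, length) of the ten blocks, in concatenation order.
BLOCK_SIZES: tuple[tuple[str, int], ...] = (
    ("saliency_map", 300),
    ("top10_salient", 20),
    ("fixation_histogram", 256),
    ("saliency_histogram", 10),
    ("fixation_duration_hist", 60),
    ("saccade_duration_hist", 60),
    ("saccade_slope_hist", 30),
    ("saccade_length_hist", 50),
    ("saccade_velocity_hist", 50),
    ("saccade_orientation_hist", 36),
)

TOTAL_DIMS = sum(n for _, n in BLOCK_SIZES)  # 872

#: Names of the six mean-value features, in reporting order.
MEAN_FEATURE_NAMES = (
    "fixation_duration", "saccade_duration", "saccade_length",
    "saccade_slope", "saccade_velocity", "saccade_orientation",
)


def block_slices() -> dict[str, slice]:
    """Mapping block name -> slice into the 872-dim vector."""
    out, start = {}, 0
    for name, n in BLOCK_SIZES:
        out[name] = slice(start, start + n)
        start += n
    return out


@dataclass(frozen=True)
class BinningScheme:
    """Equal-width binning of one scalar gaze property.

    Bin centers sit at the midpoints of ``n_bins`` equal-width intervals
    spanning ``[range_low, range_high]``; values are assigned to the
    nearest center, with out-of-range values clipped into the end bins.
    """

    name: str
    n_bins: int
    range_low: float
    range_high: float

    def __post_init__(self):
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if not self.range_high > self.range_low:
            raise ValueError("range_high must exceed range_low")

    @property
    def centers(self) -> np.ndarray:
        width = (self.range_high - self.range_low) / self.n_bins
        return self.range_low + (np.arange(self.n_bins) + 0.5) * width

    def assign(self, values: np.ndarray) -> np.ndarray:
        """Bin index of each value (nearest center, ends clipped)."""
        width = (self.range_high - self.range_low) / self.n_bins
        idx = np.floor((np.asarray(values, dtype=float) - self.range_low) / width)
        return np.clip(idx, 0, self.n_bins - 1).astype(int)


# Fixed dataset-global ranges.  Durations in ms, lengths in px, velocity
# in px/ms, angles in degrees.  The saccade-duration range sits lower than
# the fixation range because inter-fixation gaps are brief.
DEFAULT_SCHEMES: dict[str, BinningScheme] = {
    "fixation_duration": BinningScheme("fixation_duration", 60, 100.0, 2000.0),
    "saccade_duration": BinningScheme("saccade_duration", 60, 0.0, 1000.0),
    "saccade_slope": BinningScheme("saccade_slope", 30, 0.0, 180.0),
    "saccade_length": BinningScheme("saccade_length", 50, 0.0, 1280.0),
    "saccade_velocity": BinningScheme("saccade_velocity", 50, 0.0, 10.0),
    "saccade_orientation": BinningScheme("saccade_orientation", 36, 0.0, 180.0),
    "saliency": BinningScheme("saliency", 10, 0.0, 1.0),
}


# ---------------------------------------------------------------------------
# scalar properties of single events

def fixation_duration(f: Fixation) -> float:
    """Dwell time of a fixation in ms (t_end - t_start)."""
    return f.t_end - f.t_start


def saccade_length(s: Saccade) -> float:
    """Euclidean amplitude of a saccade in pixels."""
    return math.hypot(s.dx, s.dy)


def saccade_duration(s: Saccade) -> float:
    """Inter-fixation gap occupied by the saccade, in ms."""
    return s.t_end - s.t_start


def saccade_slope_angle(s: Saccade) -> float | None:
    """Undirected angle of the saccade line in degrees, folded to [0, 180).

    Horizontal movement gives 0, vertical 90.  Returns ``None`` for a
    zero-displacement saccade (the slope is undefined and the event is
    excluded from the slope histogram).
    """
    if s.dx == 0 and s.dy == 0:
        return None
    return math.degrees(math.atan2(s.dy, s.dx)) % 180.0


def saccade_orientation(s_i: Saccade, s_prev: Saccade) -> float | None:
    """Angle between two successive saccade displacement vectors, degrees.

    Computed as arccos of their cosine similarity, hence in [0, 180].
    ``None`` when either displacement is zero (pair excluded).
    """
    a = np.array([s_prev.dx, s_prev.dy])
    b = np.array([s_i.dx, s_i.dy])
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return None
    cos = np.clip(a @ b / (na * nb), -1.0, 1.0)
    return math.degrees(math.acos(cos))


def saccade_velocity(s: Saccade) -> float | None:
    """Saccade amplitude over gap duration, px/ms; ``None`` if the gap has
    zero duration (excluded from the velocity histogram)."""
    dur = s.t_end - s.t_start
    if dur <= 0:
        return None
    return saccade_length(s) / dur


# ---------------------------------------------------------------------------
# histogram machinery

def build_histogram(
    values: Sequence[float] | np.ndarray,
    scheme: BinningScheme,
    counts: bool = False,
) -> np.ndarray:
    """Histogram of ``values`` under ``scheme``.

    Normalized to sum to 1 unless ``counts`` is set; an empty input gives
    an all-zero vector (the degenerate-input convention used throughout).
    """
    values = np.asarray(list(values), dtype=float)
    hist = np.zeros(scheme.n_bins)
    if values.size == 0:
        return hist
    np.add.at(hist, scheme.assign(values), 1.0)
    if not counts:
        hist /= hist.sum()
    return hist


# ---------------------------------------------------------------------------
# fixation-density (saliency) maps

@dataclass
class SaliencyMap:
    """Gaussian-smoothed fixation-density map of one image, max-normalized
    to [0, 1], with a 15x20 area-averaged coarse version."""

    full_map: np.ndarray
    sigma: float
    coarse_map: np.ndarray = field(repr=False, default=None)

    @property
    def height(self) -> int:
        return self.full_map.shape[0]

    @property
    def width(self) -> int:
        return self.full_map.shape[1]


def _pool_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Area-weighted averaging matrix mapping n_in pixels onto n_out cells.

    Entry (i, r) is the fraction of cell i covered by pixel r; rows sum
    to 1, so pooling a constant map returns that constant.
    """
    cell = n_in / n_out
    w = np.zeros((n_out, n_in))
    for i in range(n_out):
        lo, hi = i * cell, (i + 1) * cell
        for r in range(int(np.floor(lo)), min(int(np.ceil(hi)), n_in)):
            overlap = min(hi, r + 1) - max(lo, r)
            if overlap > 0:
                w[i, r] = overlap / cell
    return w


def compute_saliency_map(
    fixations: Iterable[Fixation],
    sigma: float = 10.0,
    width: int = 1024,
    height: int = 768,
    coarse_shape: tuple[int, int] = (15, 20),
) -> SaliencyMap:
    """Fixation-density map from fixations pooled across observers.

    Fixation counts are accumulated at integer pixel locations, smoothed
    with an isotropic Gaussian (4-sigma truncated support, zero-padded
    borders) and rescaled so the maximum is 1.  The coarse map averages
    the full map over a ``coarse_shape`` grid of equal-area cells and is
    min-max rescaled to [0, 1].
    """
    fixations = list(fixations)
    if not fixations:
        raise ValueError("saliency map undefined without fixations")
    counts = np.zeros((height, width))
    rows = np.clip(np.array([int(f.y) for f in fixations]), 0, height - 1)
    cols = np.clip(np.array([int(f.x) for f in fixations]), 0, width - 1)
    np.add.at(counts, (rows, cols), 1.0)
    full = gaussian_filter(counts, sigma=sigma, mode="constant", truncate=4.0)
    full /= full.max()
    coarse = _pool_matrix(height, coarse_shape[0]) @ full @ _pool_matrix(
        width, coarse_shape[1]
    ).T
    span = coarse.max() - coarse.min()
    coarse = (coarse - coarse.min()) / span if span > 0 else np.zeros_like(coarse)
    return SaliencyMap(full_map=full, sigma=sigma, coarse_map=coarse)


def saliency_histogram(
    smap: SaliencyMap,
    fixations: Iterable[Fixation],
    scheme: BinningScheme = DEFAULT_SCHEMES["saliency"],
    counts: bool = False,
) -> np.ndarray:
    """10-bin histogram of density values sampled at the fixations."""
    fixations = list(fixations)
    if not fixations:
        return np.zeros(scheme.n_bins)
    rows = np.clip([int(f.y) for f in fixations], 0, smap.height - 1)
    cols = np.clip([int(f.x) for f in fixations], 0, smap.width - 1)
    return build_histogram(smap.full_map[rows, cols], scheme, counts=counts)


def fixation_histogram(
    fixations: Iterable[Fixation],
    width: float = 1024,
    height: float = 768,
    grid: int = 16,
    counts: bool = False,
) -> np.ndarray:
    """Fixation counts over a ``grid x grid`` spatial partition of the
    image (row-major flattened), normalized to probability mass.

    On a 1024x768 image the 16x16 grid gives 64x48 px cells, roughly ten
    times the spatial error of the source eye tracker.
    """
    hist = np.zeros(grid * grid)
    cell_w, cell_h = width / grid, height / grid
    for f in fixations:
        col = min(int(f.x // cell_w), grid - 1)
        row = min(int(f.y // cell_h), grid - 1)
        hist[row * grid + col] += 1.0
    if not counts and hist.sum() > 0:
        hist /= hist.sum()
    return hist


def top10_salient(smap: SaliencyMap, n_peaks: int = 10) -> np.ndarray:
    """Locations of the strongest density peaks via inhibition of return.

    Repeatedly takes the global maximum of a working copy of the map
    (ties broken by the smallest row-major index), records its
    resolution-normalized ``(x/width, y/height)`` coordinates and zeroes
    a disk of radius ``2 * sigma`` around it.  Returns the ``n_peaks``
    pairs flattened in extraction order: (x1, y1, ..., xn, yn).
    """
    work = smap.full_map.copy()
    h, w = work.shape
    radius = 2.0 * smap.sigma
    yy, xx = np.ogrid[:h, :w]
    coords = np.empty(2 * n_peaks)
    for k in range(n_peaks):
        flat = int(np.argmax(work))
        r, c = divmod(flat, w)
        coords[2 * k] = c / w
        coords[2 * k + 1] = r / h
        work[(yy - r) ** 2 + (xx - c) ** 2 <= radius**2] = 0.0
    return coords


# ---------------------------------------------------------------------------
# pooled per-image extraction

def _pooled_events(scanpaths: Sequence[Scanpath]):
    """Pool fixations, saccades and consecutive-saccade pairs across the
    observers of one image.  Saccades never span observers."""
    fixations: list[Fixation] = []
    saccades: list[Saccade] = []
    pairs: list[tuple[Saccade, Saccade]] = []
    for sp in scanpaths:
        fixations.extend(sp.fixations)
        sac = derive_saccades(sp)
        saccades.extend(sac)
        pairs.extend(zip(sac[1:], sac[:-1]))
    return fixations, saccades, pairs


def _defined(values: Iterable[float | None]) -> list[float]:
    return [v for v in values if v is not None]


def extract_features(
    scanpaths: Sequence[Scanpath],
    width: int = 1024,
    height: int = 768,
    schemes: dict[str, BinningScheme] | None = None,
    sigma: float = 10.0,
    counts: bool = False,
) -> "FeatureVector":
    """All ten blocks for one image, pooled over its observers.

    Order-invariant in the observers; raises if the image has no
    fixations at all.
    """
    schemes = {**DEFAULT_SCHEMES, **(schemes or {})}
    fixations, saccades, pairs = _pooled_events(scanpaths)
    if not fixations:
        raise ValueError("feature vector undefined without fixations")
    smap = compute_saliency_map(fixations, sigma=sigma, width=width, height=height)
    blocks = {
        "saliency_map": smap.coarse_map.ravel(),
        "top10_salient": top10_salient(smap),
        "fixation_histogram": fixation_histogram(
            fixations, width=width, height=height, counts=counts
        ),
        "saliency_histogram": saliency_histogram(
            smap, fixations, schemes["saliency"], counts=counts
        ),
        "fixation_duration_hist": build_histogram(
            [fixation_duration(f) for f in fixations],
            schemes["fixation_duration"], counts=counts,
        ),
        "saccade_duration_hist": build_histogram(
            [saccade_duration(s) for s in saccades],
            schemes["saccade_duration"], counts=counts,
        ),
        "saccade_slope_hist": build_histogram(
            _defined(saccade_slope_angle(s) for s in saccades),
            schemes["saccade_slope"], counts=counts,
        ),
        "saccade_length_hist": build_histogram(
            [saccade_length(s) for s in saccades],
            schemes["saccade_length"], counts=counts,
        ),
        "saccade_velocity_hist": build_histogram(
            _defined(saccade_velocity(s) for s in saccades),
            schemes["saccade_velocity"], counts=counts,
        ),
        "saccade_orientation_hist": build_histogram(
            _defined(saccade_orientation(a, b) for a, b in pairs),
            schemes["saccade_orientation"], counts=counts,
        ),
    }
    return FeatureVector(blocks=blocks)


@dataclass
class FeatureVector:
    """The ten named blocks of one image, concatenating to 872 dims."""

    blocks: dict[str, np.ndarray]

    def __post_init__(self):
        for name, n in BLOCK_SIZES:
            got = np.asarray(self.blocks[name], dtype=float).ravel()
            if got.size != n:
                raise ValueError(f"block {name}: expected {n} dims, got {got.size}")
            self.blocks[name] = got

    @property
    def values(self) -> np.ndarray:
        return np.concatenate([self.blocks[name] for name, _ in BLOCK_SIZES])

    def __len__(self) -> int:
        return TOTAL_DIMS


def feature_matrix(
    recordset: GazeRecordset,
    schemes: dict[str, BinningScheme] | None = None,
    sigma: float = 10.0,
    counts: bool = False,
) -> pd.DataFrame:
    """872-column feature matrix, one row per image (``image_ids`` order),
    with block-prefixed column names like ``saliency_map_017``."""
    columns = [
        f"{name}_{i:03d}" for name, n in BLOCK_SIZES for i in range(n)
    ]
    rows = {}
    for img in recordset.image_ids:
        fv = extract_features(
            recordset.scanpaths_for(img),
            width=int(recordset.image_width),
            height=int(recordset.image_height),
            schemes=schemes, sigma=sigma, counts=counts,
        )
        rows[img] = fv.values
    return pd.DataFrame.from_dict(rows, orient="index", columns=columns)


# ---------------------------------------------------------------------------
# mean-value representation

def _raw_mean_features(recordset: GazeRecordset) -> pd.DataFrame:
    rows = {}
    for img in recordset.image_ids:
        fixations, saccades, pairs = _pooled_events(recordset.scanpaths_for(img))
        props = {
            "fixation_duration": [fixation_duration(f) for f in fixations],
            "saccade_duration": [saccade_duration(s) for s in saccades],
            "saccade_length": [saccade_length(s) for s in saccades],
            "saccade_slope": _defined(saccade_slope_angle(s) for s in saccades),
            "saccade_velocity": _defined(saccade_velocity(s) for s in saccades),
            "saccade_orientation": _defined(
                saccade_orientation(a, b) for a, b in pairs
            ),
        }
        rows[img] = [
            float(np.mean(props[name])) if props[name] else 0.0
            for name in MEAN_FEATURE_NAMES
        ]
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(MEAN_FEATURE_NAMES))


def mean_features(recordset: GazeRecordset) -> pd.DataFrame:
    """Six per-image mean-value features, min-max normalized to [0, 1]
    across the dataset's images.

    The traditional behavioral-science representation: the mean of each
    gaze property over all observers' events on the image.  Requires at
    least two images (the normalization needs a spread); a property that
    is constant across images maps to 0 by convention.
    """
    raw = _raw_mean_features(recordset)
    if len(raw) < 2:
        raise ValueError("mean-feature normalization needs at least two images")
    lo, hi = raw.min(axis=0), raw.max(axis=0)
    span = (hi - lo).replace(0.0, np.inf)  # degenerate columns -> 0
    return (raw - lo) / span


# ---------------------------------------------------------------------------
# sklearn-style wrappers

class GazeFeaturizer:
    """Transformer from a :class:`GazeRecordset` to the 872-dim matrix.

    Stateless apart from parameter bookkeeping; ``fit`` exists for
    pipeline compatibility.  ``transform`` returns a DataFrame indexed by
    image id with block-prefixed columns.
    """

    def __init__(self, schemes=None, sigma: float = 10.0, counts: bool = False):
        self.schemes = schemes
        self.sigma = sigma
        self.counts = counts

    def get_params(self, deep: bool = True) -> dict:
        return {"schemes": self.schemes, "sigma": self.sigma, "counts": self.counts}

    def set_params(self, **params) -> "GazeFeaturizer":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: GazeRecordset, y=None) -> "GazeFeaturizer":
        self.n_features_out_ = TOTAL_DIMS
        return self

    def transform(self, X: GazeRecordset) -> pd.DataFrame:
        return feature_matrix(
            X, schemes=self.schemes, sigma=self.sigma, counts=self.counts
        )

    def fit_transform(self, X: GazeRecordset, y=None) -> pd.DataFrame:
        return self.fit(X).transform(X)


class MeanValueFeaturizer:
    """Transformer for the six mean-value features.

    ``fit`` learns the per-feature min/max over the fit recordset's
    images; ``transform`` applies that normalization (clipping to [0, 1])
    so held-out images are scaled consistently with the fit set.
    """

    def __init__(self):
        pass

    def get_params(self, deep: bool = True) -> dict:
        return {}

    def set_params(self, **params) -> "MeanValueFeaturizer":
        if params:
            raise ValueError(f"unknown parameter(s) {sorted(params)}")
        return self

    def fit(self, X: GazeRecordset, y=None) -> "MeanValueFeaturizer":
        raw = _raw_mean_features(X)
        if len(raw) < 2:
            raise ValueError("mean-feature normalization needs at least two images")
        self.min_ = raw.min(axis=0)
        self.max_ = raw.max(axis=0)
        return self

    def transform(self, X: GazeRecordset) -> pd.DataFrame:
        raw = _raw_mean_features(X)
        span = (self.max_ - self.min_).replace(0.0, np.inf)
        return ((raw - self.min_) / span).clip(0.0, 1.0)

    def fit_transform(self, X: GazeRecordset, y=None) -> pd.DataFrame:
        return self.fit(X).transform(X)
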