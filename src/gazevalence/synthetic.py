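"""Synthetic labelled gaze datasets with class-conditional structure.

Free viewing of an affective image is emulated as a correlated random
walk attracted to a handful of per-image attractor points (objects of
interest).  The valence class modulates four generative knobs, in the
directions behavioral findings suggest:

* spatial spread — fixations cluster more tightly for unpleasant images
  (attentional narrowing) and spread out for pleasant ones;
* fixation duration — log-normal, longer for unpleasant images;
* saccade (step) length — larger for unpleasant images;
* turning angle — wrapped-normal forward persistence whose dispersion is
  widest for unpleasant images (larger angular changes).

``effect_magnitude`` interpolates every knob between the neutral value
(0, the null mode: all classes share one generative process) and the
full class-specific value (1).  The generator makes no claim of
physiological realism; it exists so that every pipeline stage has a
dataset whose ground truth is known.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .gaze_data import (
    CLASSES, Fixation, GazeRecordset, Scanpath, label_valence,
)

__all__ = ["SyntheticConfig", "generate", "generate_null_permutation"]

# Valence-rating intervals (1-9 SAM scale) consistent with label_valence.
_VALENCE_INTERVALS = {
    "unpleasant": (1.5, 3.7),
    "neutral": (3.8, 5.8),
    "pleasant": (5.9, 8.5),
}

# Full-effect (magnitude 1) class modulation, relative to neutral.
_SPREAD_MULT = {"unpleasant": 0.60, "neutral": 1.0, "pleasant": 1.40}
_DURATION_LOG_SHIFT = {"unpleasant": 0.25, "neutral": 0.0, "pleasant": -0.25}
_STEP_MULT = {"unpleasant": 1.30, "neutral": 1.0, "pleasant": 0.75}
_TURN_MULT = {"unpleasant": 1.55, "neutral": 1.0, "pleasant": 0.65}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generation parameters; defaults mirror the study conditions
    (24/47/24 images per class, ~25 observers, 1024x768 images, 5-s
    viewing, >=100 ms fixations)."""

    n_unpleasant: int = 24
    n_neutral: int = 47
    n_pleasant: int = 24
    n_observers: int = 25
    image_width: int = 1024
    image_height: int = 768
    viewing_window_ms: float = 5000.0
    min_fixation_ms: float = 100.0
    effect_magnitude: float = 1.0
    seed: int = 0

    # neutral-class generative baseline
    base_spread_px: float = 110.0          # fixation scatter around an attractor
    attractor_scatter_px: float = 170.0    # attractor scatter around image center
    base_duration_log_mean: float = math.log(280.0)
    duration_log_sd: float = 0.35
    base_step_px: float = 140.0            # median walk step length
    step_log_sd: float = 0.5
    base_turn_sd_deg: float = 60.0         # turning-angle dispersion
    attractor_switch_prob: float = 0.30
    velocity_log_mean: float = math.log(0.7)   # px/ms
    velocity_log_sd: float = 0.3

    # per-class modulation at full effect, overridable to plant signal in
    # a chosen subset of gaze properties (a neutral-valued table disables
    # that property's class effect entirely)
    spread_mult: dict = field(default_factory=lambda: dict(_SPREAD_MULT))
    duration_log_shift: dict = field(default_factory=lambda: dict(_DURATION_LOG_SHIFT))
    step_mult: dict = field(default_factory=lambda: dict(_STEP_MULT))
    turn_mult: dict = field(default_factory=lambda: dict(_TURN_MULT))

    def class_counts(self) -> dict[str, int]:
        return {
            "unpleasant": self.n_unpleasant,
            "neutral": self.n_neutral,
            "pleasant": self.n_pleasant,
        }

    def validate(self) -> None:
        if min(self.class_counts().values()) <= 0 or self.n_observers <= 0:
            raise ValueError("image and observer counts must be positive")
        if self.image_width <= 0 or self.image_height <= 0:
            raise ValueError("image dimensions must be positive")
        if self.viewing_window_ms < self.min_fixation_ms:
            raise ValueError(
                "viewing window shorter than one minimum-duration fixation"
            )
        if not 0.0 <= self.effect_magnitude <= 1.0:
            raise ValueError("effect magnitude must be in [0, 1]")

    # class-conditional knobs at the configured effect magnitude ------------
    def _interp(self, table: dict[str, float], cls: str) -> float:
        return 1.0 + self.effect_magnitude * (table[cls] - 1.0)

    def spread(self, cls: str) -> float:
        return self.base_spread_px * self._interp(self.spread_mult, cls)

    def attractor_scatter(self, cls: str) -> float:
        return self.attractor_scatter_px * self._interp(self.spread_mult, cls)

    def duration_log_mean(self, cls: str) -> float:
        return (
            self.base_duration_log_mean
            + self.effect_magnitude * self.duration_log_shift[cls]
        )

    def step(self, cls: str) -> float:
        return self.base_step_px * self._interp(self.step_mult, cls)

    def turn_sd_rad(self, cls: str) -> float:
        return math.radians(self.base_turn_sd_deg * self._interp(self.turn_mult, cls))


def _clip_point(x: float, y: float, w: int, h: int) -> tuple[float, float]:
    return (
        float(np.clip(x, 0.0, w - 1e-6)),
        float(np.clip(y, 0.0, h - 1e-6)),
    )


def _simulate_scanpath(
    cfg: SyntheticConfig,
    cls: str,
    attractors: np.ndarray,
    image_id: str,
    observer_id: str,
    rng: np.random.Generator,
) -> Scanpath:
    w, h = cfg.image_width, cfg.image_height
    spread = cfg.spread(cls)
    turn_sd = cfg.turn_sd_rad(cls)
    step_med = cfg.step(cls)
    dur_mu = cfg.duration_log_mean(cls)

    k = int(rng.integers(len(attractors)))
    x, y = _clip_point(*(attractors[k] + rng.normal(0, spread, 2)), w, h)
    direction = rng.uniform(0, 2 * math.pi)
    t = 0.0
    fixations: list[Fixation] = []
    while True:
        dur = max(cfg.min_fixation_ms, rng.lognormal(dur_mu, cfg.duration_log_sd))
        if t + dur > cfg.viewing_window_ms:
            break
        fixations.append(
            Fixation(image_id=image_id, observer_id=observer_id,
                     x=x, y=y, t_start=t, t_end=t + dur)
        )
        t += dur
        # choose the next gaze target
        if rng.random() < cfg.attractor_switch_prob:
            k = int(rng.integers(len(attractors)))
            nx, ny = attractors[k] + rng.normal(0, spread, 2)
        else:
            direction += rng.normal(0.0, turn_sd)
            length = rng.lognormal(math.log(step_med), cfg.step_log_sd)
            nx = x + length * math.cos(direction)
            ny = y + length * math.sin(direction)
            ax, ay = attractors[k]
            if math.hypot(nx - ax, ny - ay) > 2.5 * spread:
                nx, ny = attractors[k] + rng.normal(0, spread, 2)
        nx, ny = _clip_point(nx, ny, w, h)
        direction = math.atan2(ny - y, nx - x)
        dist = math.hypot(nx - x, ny - y)
        velocity = rng.lognormal(cfg.velocity_log_mean, cfg.velocity_log_sd)
        t += max(dist / velocity, 1.0)
        x, y = nx, ny
    return Scanpath(image_id=image_id, observer_id=observer_id, fixations=fixations)


def generate(config: SyntheticConfig) -> GazeRecordset:
    """Generate a labelled recordset under ``config``.

    Per image: 2-4 attractor points scattered (class-scaled) around the
    image center, a mean valence drawn uniformly inside the class's
    rating interval, and one simulated scanpath per observer, truncated
    at the viewing window.  Deterministic for a given config (seed
    included).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    w, h = config.image_width, config.image_height
    center = np.array([w / 2, h / 2])
    rs = GazeRecordset(image_width=float(w), image_height=float(h))
    img_no = 0
    for cls in CLASSES:
        for _ in range(config.class_counts()[cls]):
            image_id = f"img{img_no:04d}"
            img_no += 1
            lo, hi = _VALENCE_INTERVALS[cls]
            valence = float(rng.uniform(lo, hi))
            assert label_valence(valence) == cls
            rs.mean_valence[image_id] = valence
            rs.valence_class[image_id] = cls
            n_attr = int(rng.integers(2, 5))
            attractors = center + rng.normal(
                0.0, config.attractor_scatter(cls), size=(n_attr, 2)
            )
            attractors[:, 0] = np.clip(attractors[:, 0], 0.1 * w, 0.9 * w)
            attractors[:, 1] = np.clip(attractors[:, 1], 0.1 * h, 0.9 * h)
            for obs in range(config.n_observers):
                sp = _simulate_scanpath(
                    config, cls, attractors, image_id, f"obs{obs:03d}", rng
                )
                if sp.fixations:
                    rs.scanpaths.append(sp)
    rs.validate()
    return rs


def generate_null_permutation(recordset: GazeRecordset, seed: int = 0) -> GazeRecordset:
    """Same gaze data with valence labels permuted across images.

    The label multiset is conserved; only the image -> label assignment
    is shuffled (seeded), giving a chance-level calibration dataset.
    """
    images = recordset.image_ids
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(images))
    out = GazeRecordset(
        image_width=recordset.image_width,
        image_height=recordset.image_height,
        scanpaths=list(recordset.scanpaths),
    )
    for i, img in enumerate(images):
        src = images[perm[i]]
        out.mean_valence[img] = recordset.mean_valence[src]
        out.valence_class[img] = recordset.valence_class[src]
    return out
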