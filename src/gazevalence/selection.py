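"""Feature reduction and wrapper feature selection.

Two families:

* decomposition — PCA / SVD keeping the minimal number of leading
  components reaching a cumulative explained-variance threshold;
* wrapper search over binary masks — greedy sequential forward/backward
  selection, a binary genetic algorithm, and a mutated binary particle
  swarm, all maximizing the validation-set Bookmaker score of a
  downstream one-vs-rest SVM.

Masks operate either per dimension (872 bits) or per feature block
(10 bits).  A contribution analysis averages, over the masks of many
runs, the fraction of each block's dimensions that were selected,
ranking the blocks by how much of them the wrappers keep.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .evaluation import (
    CVPlan, FoldAssignment, bookmaker, confusion_matrix3, _fit_ovr_svm,
)
from .features import BLOCK_SIZES, TOTAL_DIMS, block_slices
from .gaze_data import CLASSES

__all__ = [
    "SelectionMask", "VarianceReducer", "variance_reduce",
    "make_validation_objective", "sequential_select", "ga_select",
    "pso_select", "contribution_analysis",
    "GA_DEFAULTS", "PSO_DEFAULTS",
]

GA_DEFAULTS = dict(
    population=30, generations=100, crossover_rate=0.8, mutation_rate=0.02,
    tournament=3, elitism=1,
)
PSO_DEFAULTS = dict(
    swarm=30, iterations=100, inertia=0.72, cognitive=1.49, social=1.49,
    mutation_rate=0.05, v_max=6.0,
)


@dataclass
class SelectionMask:
    """A binary feature subset with provenance.

    ``granularity`` is "dimension" (one bit per feature dimension) or
    "block" (one bit per feature block); ``objective_value`` is the
    score the search achieved; ``history`` the best-so-far trajectory
    for iterative methods.
    """

    granularity: str
    mask: np.ndarray
    method: str
    objective_value: float
    repeat: int | None = None
    fold: int | None = None
    history: list[float] = field(default_factory=list, repr=False)

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("a selection mask must select at least one element")

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())

    def get_support(self) -> np.ndarray:
        return self.mask.copy()


# ---------------------------------------------------------------------------
# decomposition

class VarianceReducer:
    """Keep the minimal leading components explaining >= ``threshold`` of
    the variance (PCA) or of the total squared singular spectrum (SVD).

    Fitted on training rows only; ``transform`` projects held-out rows.
    PCA centers the data; SVD factorizes the raw matrix, so the two agree
    when the input is already centered.
    """

    def __init__(self, threshold: float = 0.9, method: str = "pca"):
        if not 0 < threshold <= 1:
            raise ValueError("threshold must be in (0, 1]")
        if method not in ("pca", "svd"):
            raise ValueError("method must be 'pca' or 'svd'")
        self.threshold = threshold
        self.method = method

    def get_params(self, deep: bool = True) -> dict:
        return {"threshold": self.threshold, "method": self.method}

    def set_params(self, **params) -> "VarianceReducer":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None) -> "VarianceReducer":
        X = np.asarray(X, dtype=float)
        if X.shape[0] < 2:
            raise ValueError("need at least two rows")
        if np.allclose(X.var(axis=0), 0.0):
            raise ValueError("matrix has no variance to explain")
        if self.method == "pca":
            pca = PCA(n_components=min(X.shape)).fit(X)
            ratios = pca.explained_variance_ratio_
            basis = pca.components_
            self.mean_ = pca.mean_
        else:
            u, s, vt = np.linalg.svd(X, full_matrices=False)
            total = (s**2).sum()
            if total == 0:
                raise ValueError("matrix has no variance to explain")
            ratios = s**2 / total
            basis = vt
            self.mean_ = np.zeros(X.shape[1])
        nonzero = ratios > 1e-12
        if not nonzero.any():
            raise ValueError("matrix has no variance to explain")
        ratios = ratios[nonzero]
        basis = basis[nonzero]
        cum = np.cumsum(ratios)
        k = int(np.searchsorted(cum, self.threshold - 1e-12) + 1)
        k = min(k, len(ratios))
        self.components_ = basis[:k]
        self.explained_variance_ratio_ = ratios[:k]
        self.n_components_ = k
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) @ self.components_.T

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).transform(X)


def variance_reduce(X, threshold: float = 0.9, method: str = "pca"):
    """Convenience wrapper: fit a :class:`VarianceReducer` on ``X`` and
    return ``(reducer, reduced matrix)``."""
    red = VarianceReducer(threshold=threshold, method=method).fit(X)
    return red, red.transform(X)


# ---------------------------------------------------------------------------
# wrapper objective

def make_validation_objective(
    X,
    y,
    assignment: FoldAssignment | CVPlan,
    kernel: str = "linear",
    svm_params: dict | None = None,
    granularity: str = "dimension",
    classes: tuple[str, ...] = CLASSES,
    n_objective_folds: int = 1,
) -> Callable[[np.ndarray], float]:
    """Objective for wrapper search: validation Bookmaker score of a
    one-vs-rest SVM trained on the masked feature columns.

    By default one fixed train/validation split scores every candidate,
    bounding cost; pass a :class:`CVPlan` and ``n_objective_folds`` > 1
    to average the score over that many of the plan's folds (a finer,
    slower objective).  Results are memoized on the mask bits, and
    features are standardized on each split's training rows.
    Block-granularity masks are expanded to columns through the
    canonical block schema.
    """
    from sklearn.preprocessing import StandardScaler

    if isinstance(assignment, CVPlan):
        assignments = assignment.assignments[:n_objective_folds]
    else:
        assignments = [assignment]
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    params = svm_params or {"C": 1.0}
    slices = block_slices()
    splits = []
    for fa in assignments:
        scaler = StandardScaler().fit(X[fa.train])
        splits.append(
            (scaler.transform(X[fa.train]), y[fa.train],
             scaler.transform(X[fa.validation]), y[fa.validation])
        )
    cache: dict[bytes, float] = {}

    def expand(mask: np.ndarray) -> np.ndarray:
        if granularity == "block":
            cols = np.zeros(TOTAL_DIMS, dtype=bool)
            for bit, (name, _) in zip(mask, BLOCK_SIZES):
                if bit:
                    cols[slices[name]] = True
            return cols
        return np.asarray(mask, dtype=bool)

    def objective(mask: np.ndarray) -> float:
        mask = np.asarray(mask, dtype=bool)
        key = np.packbits(mask).tobytes()
        if key not in cache:
            cols = expand(mask)
            if not cols.any():
                cache[key] = -1.0
            else:
                scores = []
                for Xtr, ytr, Xva, yva in splits:
                    clf = _fit_ovr_svm(Xtr[:, cols], ytr, kernel, params)
                    pred = clf.predict(Xva[:, cols])
                    scores.append(
                        bookmaker(confusion_matrix3(yva, pred, classes))
                    )
                cache[key] = float(np.mean(scores))
        return cache[key]

    return objective


def _resolve_objective(X, y, plan, objective, granularity, kernel):
    if objective is not None:
        return objective
    if plan is None:
        raise ValueError("either an objective or a CV plan is required")
    return make_validation_objective(X, y, plan, kernel=kernel, granularity=granularity)


def _mask_length(X, granularity: str) -> int:
    if granularity == "block":
        return len(BLOCK_SIZES)
    return np.asarray(X).shape[1]


# ---------------------------------------------------------------------------
# sequential search

def sequential_select(
    X=None,
    y=None,
    plan: CVPlan | None = None,
    direction: str = "forward",
    objective: Callable[[np.ndarray], float] | None = None,
    granularity: str = "dimension",
    n_dims: int | None = None,
    kernel: str = "linear",
) -> SelectionMask:
    """Greedy sequential forward (SFS) or backward (SBS) selection.

    Forward starts from the empty mask and adds, backward starts from
    the full mask and removes, at each step the single element whose
    change most improves the objective; the search stops when no change
    strictly improves it.  Ties break toward the lowest index.  Backward
    never empties the mask.
    """
    if direction not in ("forward", "backward"):
        raise ValueError("direction must be 'forward' or 'backward'")
    d = n_dims if n_dims is not None else _mask_length(X, granularity)
    if d < 1:
        raise ValueError("need at least one candidate element")
    objective = _resolve_objective(X, y, plan, objective, granularity, kernel)

    if direction == "forward":
        mask = np.zeros(d, dtype=bool)
        current = -np.inf
    else:
        mask = np.ones(d, dtype=bool)
        current = objective(mask)
    history = [] if direction == "forward" else [current]

    while True:
        best_idx, best_score = None, current
        for i in range(d):
            if mask[i] == (direction == "forward"):
                continue
            if direction == "backward" and mask.sum() == 1:
                break
            cand = mask.copy()
            cand[i] = not cand[i]
            score = objective(cand)
            if score > best_score:
                best_idx, best_score = i, score
        if best_idx is None:
            break
        mask[best_idx] = not mask[best_idx]
        current = best_score
        history.append(current)
    if not mask.any():  # forward search that never found an improving element
        scores = [objective(np.eye(d, dtype=bool)[i]) for i in range(d)]
        mask[int(np.argmax(scores))] = True
        current = max(scores)
        history.append(current)
    return SelectionMask(
        granularity=granularity, mask=mask,
        method="sfs" if direction == "forward" else "sbs",
        objective_value=float(current), history=history,
    )


# ---------------------------------------------------------------------------
# evolutionary search

def _repair(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if not mask.any():
        mask = mask.copy()
        mask[rng.integers(mask.size)] = True
    return mask


def ga_select(
    X=None,
    y=None,
    plan: CVPlan | None = None,
    objective: Callable[[np.ndarray], float] | None = None,
    granularity: str = "dimension",
    n_dims: int | None = None,
    kernel: str = "linear",
    seed: int = 0,
    **ga_params,
) -> SelectionMask:
    """Binary genetic algorithm over feature masks.

    Tournament selection, one-point crossover, per-bit mutation and
    elitism (the best mask always survives, so the best-fitness
    trajectory is non-decreasing).  Deterministic under ``seed``.
    """
    p = {**GA_DEFAULTS, **ga_params}
    d = n_dims if n_dims is not None else _mask_length(X, granularity)
    objective = _resolve_objective(X, y, plan, objective, granularity, kernel)
    rng = np.random.default_rng(seed)

    pop = [_repair(rng.random(d) < 0.5, rng) for _ in range(p["population"])]
    fit = np.array([objective(m) for m in pop])
    best_i = int(np.argmax(fit))
    best, best_fit = pop[best_i].copy(), float(fit[best_i])
    history = [best_fit]

    for _ in range(p["generations"]):
        children = [best.copy() for _ in range(p["elitism"])]
        while len(children) < p["population"]:
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, len(pop), size=p["tournament"])
                parents.append(pop[contenders[np.argmax(fit[contenders])]])
            a, b = parents[0].copy(), parents[1].copy()
            if rng.random() < p["crossover_rate"] and d > 1:
                cut = int(rng.integers(1, d))
                a[cut:], b[cut:] = b[cut:].copy(), a[cut:].copy()
            for child in (a, b):
                flip = rng.random(d) < p["mutation_rate"]
                child ^= flip
                children.append(_repair(child, rng))
        pop = children[: p["population"]]
        fit = np.array([objective(m) for m in pop])
        gen_best = int(np.argmax(fit))
        if fit[gen_best] > best_fit:
            best, best_fit = pop[gen_best].copy(), float(fit[gen_best])
        history.append(best_fit)
    return SelectionMask(
        granularity=granularity, mask=best, method="ga",
        objective_value=best_fit, history=history,
    )


def pso_select(
    X=None,
    y=None,
    plan: CVPlan | None = None,
    objective: Callable[[np.ndarray], float] | None = None,
    granularity: str = "dimension",
    n_dims: int | None = None,
    kernel: str = "linear",
    seed: int = 0,
    init: np.ndarray | None = None,
    **pso_params,
) -> SelectionMask:
    """Mutated binary particle swarm over feature masks.

    Real-valued velocities are updated with inertia and cognitive/social
    pulls toward personal and global bests; bits flip with probability
    ``|tanh(v)|`` (a V-shaped transfer, so zero velocity leaves a
    particle in place), then mutate with a small bit-flip rate.  Returns
    the global-best mask; deterministic under ``seed``.
    """
    p = {**PSO_DEFAULTS, **pso_params}
    d = n_dims if n_dims is not None else _mask_length(X, granularity)
    objective = _resolve_objective(X, y, plan, objective, granularity, kernel)
    rng = np.random.default_rng(seed)

    if init is not None:
        pos = [np.asarray(init, dtype=bool).copy() for _ in range(p["swarm"])]
        vel = [np.zeros(d) for _ in range(p["swarm"])]
    else:
        pos = [_repair(rng.random(d) < 0.5, rng) for _ in range(p["swarm"])]
        vel = [rng.uniform(-1, 1, size=d) for _ in range(p["swarm"])]
    fit = np.array([objective(m) for m in pos])
    pbest = [m.copy() for m in pos]
    pbest_fit = fit.copy()
    g = int(np.argmax(fit))
    gbest, gbest_fit = pos[g].copy(), float(fit[g])
    history = [gbest_fit]

    for _ in range(p["iterations"]):
        for i in range(p["swarm"]):
            r1, r2 = rng.random(d), rng.random(d)
            vel[i] = (
                p["inertia"] * vel[i]
                + p["cognitive"] * r1 * (pbest[i].astype(float) - pos[i])
                + p["social"] * r2 * (gbest.astype(float) - pos[i])
            )
            np.clip(vel[i], -p["v_max"], p["v_max"], out=vel[i])
            flip = rng.random(d) < np.abs(np.tanh(vel[i]))
            newpos = pos[i] ^ flip
            if p["mutation_rate"] > 0:
                newpos ^= rng.random(d) < p["mutation_rate"]
            pos[i] = _repair(newpos, rng)
            f = objective(pos[i])
            if f > pbest_fit[i]:
                pbest[i], pbest_fit[i] = pos[i].copy(), f
                if f > gbest_fit:
                    gbest, gbest_fit = pos[i].copy(), float(f)
        history.append(gbest_fit)
    return SelectionMask(
        granularity=granularity, mask=gbest, method="pso",
        objective_value=gbest_fit, history=history,
    )


# ---------------------------------------------------------------------------
# contribution analysis

def contribution_analysis(
    masks: Sequence[SelectionMask],
    blocks: tuple[tuple[str, int], ...] = BLOCK_SIZES,
) -> pd.DataFrame:
    """Per-block contribution across a collection of selection masks.

    For dimension-granularity masks the contribution of a block in one
    run is the fraction of its dimensions selected; for block-granularity
    masks it is the block's bit.  Returns one row per block with the
    mean fraction, the block-level selection frequency, and the rank by
    mean fraction (1 = most contributing).  Invariant to mask order.
    """
    if not masks:
        raise ValueError("no masks to analyze")
    slices = {}
    start = 0
    for name, n in blocks:
        slices[name] = slice(start, start + n)
        start += n
    frac = {name: [] for name, _ in blocks}
    freq = {name: [] for name, _ in blocks}
    for m in masks:
        for name, n in blocks:
            if m.granularity == "block":
                bit = bool(m.mask[[b[0] for b in blocks].index(name)])
                frac[name].append(float(bit))
                freq[name].append(float(bit))
            else:
                sel = m.mask[slices[name]].sum() / n
                frac[name].append(float(sel))
                freq[name].append(float(sel > 0))
    out = pd.DataFrame(
        {
            "block": [name for name, _ in blocks],
            "block_size": [n for _, n in blocks],
            "mean_fraction_selected": [float(np.mean(frac[n])) for n, _ in blocks],
            "selection_frequency": [float(np.mean(freq[n])) for n, _ in blocks],
        }
    ).set_index("block")
    out["rank"] = (
        out["mean_fraction_selected"].rank(ascending=False, method="min").astype(int)
    )
    return out
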