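"""General linear convolution model for event-related respiratory responses.

The interpolated, filtered measure series Y is modelled as Y = X beta +
eps, where each design column is a unit impulse train at the event
onsets of one condition convolved with one basis component of the
response function.  Amplitudes are estimated with the Moore-Penrose
pseudoinverse, beta = pinv(X) @ Y, which equals the least-squares
solution for full-column-rank designs and the minimum-norm solution
otherwise.  The estimated beta is interpreted as the amplitude of a
brief neural input driving the respiratory system at each event.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_physio import EventTable
from .measures import InterpolatedMeasure
from .response_functions import ResponseFunction

__all__ = [
    "GLMResult",
    "build_design",
    "fit_glm",
    "fit_measure_glm",
    "contrast",
    "overall_effect_weights",
    "condition_difference_weights",
    "nonevent_onsets",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GLMResult:
    """Fitted convolution GLM.

    ``column_map`` pairs each design column with its (condition,
    component) labels; the intercept column, when present, is labelled
    ("intercept", "intercept").
    """

    X: np.ndarray
    Y: np.ndarray
    beta: np.ndarray
    residuals: np.ndarray
    column_map: tuple[tuple[str, str], ...]
    dof: int

    def beta_for(self, condition: str, component: str = "canonical") -> float:
        for i, (cond, comp) in enumerate(self.column_map):
            if cond == condition and comp == component:
                return float(self.beta[i])
        raise KeyError(f"no column for ({condition!r}, {component!r})")


def build_design(
    events: EventTable,
    rf: ResponseFunction,
    n_samples: int,
    fs: float = 10.0,
    intercept: bool = True,
    t0: float = 0.0,
) -> tuple[np.ndarray, tuple[tuple[str, str], ...]]:
    """Convolution design matrix from events and a basis set.

    Per condition, a unit impulse train at the onset samples (nearest-
    sample rounding, ties to even) is convolved with each basis column
    and truncated to ``n_samples``.  One column per (condition,
    component); an all-ones intercept column is appended last when
    requested.  ``t0`` is the time of the first data sample.
    """
    if len(events) == 0:
        raise ValueError("cannot build a design from an empty event table")
    if abs(rf.fs - fs) > 1e-9:
        raise ValueError(f"basis sampled at {rf.fs} Hz but series is {fs} Hz")
    basis = rf.sample()
    comp_names = rf.column_names()
    columns: list[np.ndarray] = []
    column_map: list[tuple[str, str]] = []
    for condition in events.condition_names:
        onsets = events.subset(condition)
        impulses = np.zeros(n_samples)
        for onset in onsets:
            k = int(np.round((onset - t0) * fs))
            if k < 0 or k >= n_samples:
                raise ValueError(f"event at {onset:.2f} s falls outside the series")
            impulses[k] += 1.0
        for c, name in enumerate(comp_names):
            col = np.convolve(impulses, basis[:, c])[:n_samples]
            columns.append(col)
            column_map.append((condition, name))
    if intercept:
        columns.append(np.ones(n_samples))
        column_map.append(("intercept", "intercept"))
    return np.column_stack(columns), tuple(column_map)


def fit_glm(
    X: np.ndarray,
    Y: np.ndarray,
    column_map: tuple[tuple[str, str], ...] | None = None,
) -> GLMResult:
    """Estimate amplitudes as beta = pinv(X) @ Y.

    Full-column-rank designs give the least-squares solution; rank-
    deficient designs resolve to the minimum-norm solution with a logged
    warning.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 1 or X.shape[0] != Y.size:
        raise ValueError(f"shape mismatch: X {X.shape}, Y {Y.shape}")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ValueError("non-finite values in design or data")
    rank = int(np.linalg.matrix_rank(X))
    if rank < X.shape[1]:
        logger.warning(
            "rank-deficient design (rank %d < %d columns): minimum-norm solution",
            rank, X.shape[1],
        )
    beta = np.linalg.pinv(X) @ Y
    residuals = Y - X @ beta
    if column_map is None:
        column_map = tuple(("column", str(i)) for i in range(X.shape[1]))
    return GLMResult(
        X=X,
        Y=Y,
        beta=beta,
        residuals=residuals,
        column_map=column_map,
        dof=X.shape[0] - rank,
    )


def fit_measure_glm(
    im: InterpolatedMeasure,
    events: EventTable,
    rf: ResponseFunction,
    intercept: bool = True,
) -> GLMResult:
    """Convenience wrapper: build the design on the series grid and fit."""
    X, cmap = build_design(
        events, rf, n_samples=im.values.size, fs=im.fs, intercept=intercept, t0=im.t0
    )
    return fit_glm(X, im.values, cmap)


def contrast(result: GLMResult, weights: np.ndarray) -> float:
    """Linear contrast w' beta of the amplitude estimates."""
    weights = np.asarray(weights, dtype=float)
    if weights.size != result.beta.size:
        raise ValueError(
            f"{weights.size} weights for {result.beta.size} design columns"
        )
    return float(weights @ result.beta)


def overall_effect_weights(
    result: GLMResult, component: str = "canonical"
) -> np.ndarray:
    """Weights averaging the chosen component's beta over all conditions."""
    idx = [
        i
        for i, (cond, comp) in enumerate(result.column_map)
        if comp == component and cond != "intercept"
    ]
    if not idx:
        raise ValueError(f"no {component!r} columns in the result")
    w = np.zeros(result.beta.size)
    w[idx] = 1.0 / len(idx)
    return w


def condition_difference_weights(
    result: GLMResult, cond_a: str, cond_b: str, component: str = "canonical"
) -> np.ndarray:
    """Weights for the beta difference cond_a - cond_b on one component."""
    w = np.zeros(result.beta.size)
    found = 0
    for i, (cond, comp) in enumerate(result.column_map):
        if comp != component:
            continue
        if cond == cond_a:
            w[i] = 1.0
            found += 1
        elif cond == cond_b:
            w[i] = -1.0
            found += 1
    if found != 2:
        raise ValueError(f"conditions {cond_a!r}, {cond_b!r} not both present")
    return w


def nonevent_onsets(
    events: EventTable,
    n: int,
    margin: float,
    seed: int | np.random.Generator | None = None,
) -> EventTable:
    """Random control time points strictly between consecutive real events.

    Each draw lies at least ``margin`` seconds from both neighbouring
    events; intervals are chosen with probability proportional to their
    feasible length, then the time uniformly within.  Labelled condition
    "nonevent"; reproducible under a fixed seed.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    starts, stops = [], []
    for a, b in zip(events.onsets[:-1], events.onsets[1:]):
        lo, hi = a + margin, b - margin
        if hi > lo:
            starts.append(lo)
            stops.append(hi)
    if not starts:
        raise ValueError("no inter-event gap can hold the requested margin")
    lengths = np.asarray(stops) - np.asarray(starts)
    probs = lengths / lengths.sum()
    onsets = []
    for _ in range(n):
        i = rng.choice(len(starts), p=probs)
        onsets.append(rng.uniform(starts[i], stops[i]))
    return EventTable(np.asarray(onsets), ("nonevent",) * n)
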