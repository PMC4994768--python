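"""Gaussian canonical response functions and basis construction.

The impulse response of the assumed respiratory LTI system is modelled
as a Gaussian, g(t) = A exp(-(t - mu)^2 / (2 sigma^2)), with latency mu
and dispersion sigma in seconds; the amplitude A is left free and
estimated in the GLM, so shipped basis functions are peak-normalised.
Shipped constants (mu, sigma): respiration period (4.20, 1.65) s,
respiration amplitude (8.07, 3.74) s, respiratory flow rate
(6.00, 3.23) s.  All shipped functions are positive-peaked; a breathing
deceleration appears as a negative estimated amplitude, not a negative
basis.

The module also provides Nelder-Mead refitting of a Gaussian to an
empirical mean curve (for deriving new response functions) and serial
orthogonalisation for multi-component bases added in chronological
order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "ResponseFunction",
    "CANONICAL_PARAMS",
    "gaussian_rf",
    "canonical_rf",
    "fit_gaussian",
    "GaussianFit",
    "orthogonalise_serial",
]

# (latency mu [s], dispersion sigma [s]) of the shipped canonical functions
CANONICAL_PARAMS: dict[str, tuple[float, float]] = {
    "rp": (4.20, 1.65),
    "ra": (8.07, 3.74),
    "rfr": (6.00, 3.23),
}


def gaussian_rf(
    grid: np.ndarray, mu: float, sigma: float, amp: float = 1.0
) -> np.ndarray:
    """Sample amp * exp(-(t - mu)^2 / (2 sigma^2)) on a time grid."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    grid = np.asarray(grid, dtype=float)
    return amp * np.exp(-((grid - mu) ** 2) / (2.0 * sigma**2))


def _gaussian_derivative(
    grid: np.ndarray, mu: float, sigma: float, amp: float = 1.0
) -> np.ndarray:
    """Analytic time derivative of the Gaussian: -(t-mu)/sigma^2 * g(t)."""
    return -(grid - mu) / sigma**2 * gaussian_rf(grid, mu, sigma, amp)


@dataclass(frozen=True)
class ResponseFunction:
    """Parametric basis set for one measure.

    ``components`` holds (mu, sigma, amp) triples; ``with_derivative``
    appends the analytic time derivative of each component as an extra
    basis column.  ``sample()`` returns the basis matrix on the
    function's grid, every column normalised to unit peak absolute
    value (the overall amplitude is estimated in the GLM).
    """

    kind: str
    components: tuple[tuple[float, float, float], ...]
    with_derivative: bool = False
    duration: float = 30.0
    fs: float = 10.0

    def __post_init__(self) -> None:
        for mu, sigma, _amp in self.components:
            if sigma <= 0:
                raise ValueError("sigma must be positive for every component")
            if self.duration < mu + 5 * sigma:
                raise ValueError(
                    f"duration {self.duration} s truncates a component "
                    f"(needs >= {mu + 5 * sigma:.2f} s)"
                )

    @property
    def grid(self) -> np.ndarray:
        return np.arange(int(round(self.duration * self.fs)) + 1) / self.fs

    @property
    def n_columns(self) -> int:
        return len(self.components) * (2 if self.with_derivative else 1)

    def column_names(self) -> list[str]:
        names = []
        for i in range(len(self.components)):
            suffix = "" if len(self.components) == 1 else f"{i + 1}"
            names.append(f"canonical{suffix}")
        if self.with_derivative:
            for i in range(len(self.components)):
                suffix = "" if len(self.components) == 1 else f"{i + 1}"
                names.append(f"derivative{suffix}")
        return names

    def sample(self, grid: np.ndarray | None = None) -> np.ndarray:
        """Basis matrix (len(grid) x n_columns), unit-peak columns."""
        g = self.grid if grid is None else np.asarray(grid, dtype=float)
        cols = [gaussian_rf(g, mu, sigma, amp) for mu, sigma, amp in self.components]
        if self.with_derivative:
            cols += [
                _gaussian_derivative(g, mu, sigma, amp)
                for mu, sigma, amp in self.components
            ]
        out = np.column_stack(cols)
        peaks = np.max(np.abs(out), axis=0)
        if np.any(peaks == 0):
            raise ValueError("a basis column is identically zero on the grid")
        return out / peaks


def canonical_rf(
    kind: str,
    with_derivative: bool = False,
    fs: float = 10.0,
    duration: float = 30.0,
) -> ResponseFunction:
    """The shipped single-Gaussian canonical response function for one measure.

    Parameters
    ----------
    kind : {"rp", "ra", "rfr"}
    with_derivative : bool
        Also include the analytic time derivative as a second basis column.
    duration : float
        Basis support in seconds; 30 s covers mu + 5 sigma for all shipped
        functions (responses do not extend beyond ~25 s).
    """
    key = kind.lower()
    if key not in CANONICAL_PARAMS:
        raise ValueError(f"kind must be one of {tuple(CANONICAL_PARAMS)}, got {kind!r}")
    mu, sigma = CANONICAL_PARAMS[key]
    return ResponseFunction(
        kind=key,
        components=((mu, sigma, 1.0),),
        with_derivative=with_derivative,
        duration=duration,
        fs=fs,
    )


@dataclass(frozen=True)
class GaussianFit:
    """Result of a Nelder-Mead Gaussian fit."""

    amp: float
    mu: float
    sigma: float
    rss: float
    converged: bool
    degenerate: bool = False


def fit_gaussian(
    curve: np.ndarray,
    grid: np.ndarray,
    init: tuple[float, float, float],
    xatol: float = 1e-6,
    fatol: float = 1e-6,
    maxiter: int = 2000,
) -> GaussianFit:
    """Fit A * exp(-(t - mu)^2 / 2 sigma^2) to a sampled curve.

    Minimises the residual sum of squares with the Nelder-Mead simplex
    algorithm from the given (A, mu, sigma) start.  The returned sigma is
    |sigma| (the model is even in sigma).  An all-zero curve is flagged
    degenerate: A -> 0 with mu, sigma unidentifiable.
    """
    curve = np.asarray(curve, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if curve.size != grid.size:
        raise ValueError("curve and grid must have equal length")
    if curve.size < 4:
        raise ValueError("need at least 4 samples to fit 3 parameters")
    if init[2] <= 0:
        raise ValueError("initial sigma must be positive")
    if np.all(curve == 0):
        return GaussianFit(0.0, init[1], abs(init[2]), 0.0, True, degenerate=True)

    def rss(theta: np.ndarray) -> float:
        a, mu, sigma = theta
        if sigma == 0:
            return float(np.sum(curve**2))
        return float(np.sum((curve - gaussian_rf(grid, mu, abs(sigma), a)) ** 2))

    res = optimize.minimize(
        rss,
        x0=np.asarray(init, dtype=float),
        method="Nelder-Mead",
        options={"xatol": xatol, "fatol": fatol, "maxiter": maxiter},
    )
    a, mu, sigma = res.x
    return GaussianFit(
        amp=float(a),
        mu=float(mu),
        sigma=float(abs(sigma)),
        rss=float(res.fun),
        converged=bool(res.success),
    )


def orthogonalise_serial(basis: np.ndarray) -> np.ndarray:
    """Serially orthogonalise basis columns in their given (chronological) order.

    Column 1 is unchanged up to peak renormalisation; each later column
    has its projection onto the span of all earlier, already-processed
    columns removed (modified Gram-Schmidt).  Output columns are
    renormalised to unit peak absolute value.

    Raises
    ------
    ValueError
        If a column is (near-)linearly dependent on its predecessors.
    """
    basis = np.array(basis, dtype=float)
    if basis.ndim != 2 or basis.shape[1] < 1:
        raise ValueError("basis must be a 2-D matrix with at least one column")
    out = basis.copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        for i in range(j):
            prev = out[:, i]
            col = col - (prev @ col) / (prev @ prev) * prev
        scale = float(np.max(np.abs(col)))
        input_scale = float(np.max(np.abs(basis[:, j])))
        if scale < 1e-10 * max(input_scale, 1e-300):
            raise ValueError(f"degenerate basis: column {j + 1} is linearly dependent")
        out[:, j] = col / scale
    return out
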