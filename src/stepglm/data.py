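"""Design-matrix container with an explicit intercept column.

Index convention used throughout the package: column 0 of ``X`` is the
constant 1 (intercept) and predictors occupy columns 1..p.  Index sets
(``S``, ``F_k``, ``B_k``, ``M_hat``) live in {0, ..., p} under this
convention, with 0 always meaning the intercept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class Dataset:
    """Response and design matrix for one GLM problem.

    Attributes
    ----------
    y : (n,) response vector.
    X : (n, p+1) design matrix, column 0 identically 1.
    names : list of p predictor labels (no entry for the intercept).
    standardized : whether predictor columns have been centred/scaled.
    means, sds : per-predictor location/scale used for standardization
        (length p; identity values when ``standardized`` is False).
    """

    y: np.ndarray
    X: np.ndarray
    names: list[str]
    standardized: bool = False
    means: np.ndarray = field(default=None)  # type: ignore[assignment]
    sds: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.asarray(self.X, dtype=float)
        n, p1 = self.X.shape
        if n != self.y.shape[0]:
            raise ValueError(f"X has {n} rows but y has {self.y.shape[0]} entries")
        if n < 2:
            raise ValueError("at least 2 observations are required")
        if not np.all(self.X[:, 0] == 1.0):
            raise ValueError("column 0 of X must be the constant intercept 1")
        if not (np.all(np.isfinite(self.X)) and np.all(np.isfinite(self.y))):
            raise ValueError("X and y must be finite with no missing values")
        if len(self.names) != p1 - 1:
            raise ValueError("names must label exactly the p predictor columns")
        if self.means is None:
            self.means = np.zeros(p1 - 1)
        if self.sds is None:
            self.sds = np.ones(p1 - 1)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1] - 1

    def subset_rows(self, idx: np.ndarray) -> "Dataset":
        """Row-subset (e.g. a CV fold) keeping the same scaling metadata."""
        return Dataset(
            y=self.y[idx],
            X=self.X[idx],
            names=list(self.names),
            standardized=self.standardized,
            means=self.means.copy(),
            sds=self.sds.copy(),
        )


def make_dataset(X, y, names=None) -> Dataset:
    """Build a :class:`Dataset` from a raw (n, p) predictor matrix.

    Prepends the intercept column; does not standardize (selection code
    standardizes internally so user-facing coefficients keep the original
    scale).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(1, p + 1)]
    design = np.empty((n, p + 1))
    design[:, 0] = 1.0
    design[:, 1:] = X
    return Dataset(y=y, X=design, names=list(names))


def standardize(data: Dataset) -> tuple[Dataset, list[int]]:
    """Centre and scale predictor columns to sample mean 0, sample SD 1.

    Returns the standardized dataset and the (1-based) indices of
    zero-variance columns, which are left centred-at-zero and must be
    excluded from any candidate scan.
    """
    if data.standardized:
        return data, [int(j) for j in np.where(data.sds == 0)[0] + 1]
    Xp = data.X[:, 1:]
    means = Xp.mean(axis=0)
    sds = Xp.std(axis=0, ddof=1)
    # numerically constant columns: sd at rounding-noise level relative to
    # the column magnitude (an exact ==0 test misses constants like 4.2
    # whose repeated-value mean rounds)
    is_const = sds <= 1e-12 * np.maximum(1.0, np.abs(means))
    degenerate = np.where(is_const)[0]
    sds = np.where(is_const, 0.0, sds)
    safe = np.where(is_const, 1.0, sds)
    Z = (Xp - means) / safe
    # second centring pass: removes the O(eps * |mean| / sd) residual mean
    # left by cancellation in near-constant columns (a constant shift, so
    # the unit sample SD is untouched)
    Z = Z - Z.mean(axis=0)
    if degenerate.size:
        warnings.warn(
            f"{degenerate.size} constant predictor column(s) excluded from selection",
            UserWarning,
            stacklevel=2,
        )
    design = np.empty_like(data.X)
    design[:, 0] = 1.0
    design[:, 1:] = Z
    out = Dataset(
        y=data.y.copy(),
        X=design,
        names=list(data.names),
        standardized=True,
        means=means,
        sds=sds,
    )
    return out, [int(j) + 1 for j in degenerate]


def destandardize_coef(beta_std: np.ndarray, S: list[int], data_std: Dataset) -> np.ndarray:
    """Map coefficients fitted on standardized columns back to the raw scale.

    ``beta_std`` aligns with index set ``S`` (which includes 0). Returns a
    full-length (p+1) vector, zero off ``S``.
    """
    p = data_std.p
    beta = np.zeros(p + 1)
    intercept = 0.0
    for b, j in zip(beta_std, S):
        if j == 0:
            intercept += b
        else:
            sd = data_std.sds[j - 1]
            m = data_std.means[j - 1]
            slope = b / sd if sd > 0 else 0.0
            beta[j] = slope
            intercept -= slope * m
    beta[0] = intercept
    return beta
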