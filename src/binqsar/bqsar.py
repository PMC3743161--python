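"""Binned-Bayesian binary QSAR classifier.

The model estimates Pr(active | descriptors) for small, unbalanced
datasets.  Training columns are standardised, decorrelated by principal
components of the correlation matrix (components dropped below an
eigenvalue-ratio condition limit), and the component scores scaled to unit
variance.  For each retained component and each class, the class-conditional
density is a mixture

    f(u | class) = (1 - smooth) * KDE(class scores) + smooth * Uniform(S)

where the kernel bandwidth follows Silverman's rule on the class sample
(floored at 1e-3) and the uniform support S spans the pooled training
scores padded by three bandwidths, shared between the classes.  The
posterior multiplies per-component likelihood ratios with the empirical
class priors, in log space.  ``smooth`` biases the posterior toward the
prior: at smooth = 1 the densities cancel and the posterior *is* the
prior; at small smooth the data dominate while the uniform floor keeps
every probability strictly inside (0, 1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class BQSARParams:
    """Classifier hyper-parameters.

    smooth
        Mixture weight of the uniform component in (0, 1]; default 0.01.
    component_limit
        Maximum number of principal components retained (None = unlimited).
    condition_limit
        Eigenvalue-ratio cutoff: components with eigenvalue below
        ``condition_limit * max_eigenvalue`` are dropped.
    decision_threshold
        Posterior probability at or above which a compound is classified
        active.
    """

    smooth: float = 0.01
    component_limit: int | None = None
    condition_limit: float = 1e-6
    decision_threshold: float = 0.5
    kde_bandwidth_floor: float = 1e-3

    def __post_init__(self) -> None:
        if not 0.0 < self.smooth <= 1.0:
            raise ValueError("smooth must be in (0, 1]")
        if self.condition_limit < 0:
            raise ValueError("condition_limit must be >= 0")
        if not 0.0 < self.decision_threshold < 1.0:
            raise ValueError("decision_threshold must be in (0, 1)")


@dataclass
class _ComponentDensity:
    """Class-conditional density of one component score: KDE + uniform."""

    centers: np.ndarray           # training scores of this class
    bandwidth: float
    support: tuple[float, float]  # shared uniform support

    def log_density(self, u: np.ndarray, smooth: float) -> np.ndarray:
        # scores outside the training support evaluate at the boundary, so
        # the uniform floor stays effective for extrapolated compounds
        lo, hi = self.support
        u = np.clip(np.atleast_1d(np.asarray(u, dtype=float)), lo, hi)
        log_unif = np.full_like(u, -math.log(hi - lo))
        if smooth >= 1.0:
            return log_unif
        z = (u[:, None] - self.centers[None, :]) / self.bandwidth
        log_kernels = -0.5 * z * z - 0.5 * LOG_2PI - math.log(self.bandwidth)
        log_kde = _logsumexp(log_kernels, axis=1) - math.log(len(self.centers))
        parts = np.stack(
            [log_kde + math.log1p(-smooth), log_unif + math.log(smooth)]
        )
        return _logsumexp(parts, axis=0)


def _logsumexp(a: np.ndarray, axis: int) -> np.ndarray:
    m = np.max(a, axis=axis, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    return np.squeeze(m, axis=axis) + np.log(np.sum(np.exp(a - m), axis=axis))


def _silverman(sample: np.ndarray, floor: float) -> float:
    n = len(sample)
    sd = float(np.std(sample, ddof=1)) if n > 1 else 0.0
    q75, q25 = np.percentile(sample, [75, 25])
    iqr = float(q75 - q25)
    spread_candidates = [s for s in (sd, iqr / 1.34) if s > 0]
    spread = min(spread_candidates) if spread_candidates else 0.0
    return max(0.9 * spread * n ** (-0.2), floor)


@dataclass
class BQSARModel:
    """A fitted binary QSAR model (see module docstring)."""

    columns: list[str]            # columns actually used by the model
    input_columns: list[str]      # full training column set (before drops)
    means: np.ndarray
    scales: np.ndarray
    axes: np.ndarray          # columns = principal axes of the correlation matrix
    eigenvalues: np.ndarray
    prior_active: float
    densities_active: list[_ComponentDensity] = field(repr=False, default_factory=list)
    densities_inactive: list[_ComponentDensity] = field(repr=False, default_factory=list)
    params: BQSARParams = field(default_factory=BQSARParams)

    @property
    def n_components(self) -> int:
        return self.axes.shape[1]

    # -- persistence -------------------------------------------------------
    def to_dict(self) -> dict:
        def dens(dd: list[_ComponentDensity]) -> list[dict]:
            return [
                {
                    "centers": d.centers.tolist(),
                    "bandwidth": d.bandwidth,
                    "support": list(d.support),
                }
                for d in dd
            ]

        return {
            "columns": self.columns,
            "input_columns": self.input_columns,
            "means": self.means.tolist(),
            "scales": self.scales.tolist(),
            "axes": self.axes.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "prior_active": self.prior_active,
            "densities_active": dens(self.densities_active),
            "densities_inactive": dens(self.densities_inactive),
            "params": {
                "smooth": self.params.smooth,
                "component_limit": self.params.component_limit,
                "condition_limit": self.params.condition_limit,
                "decision_threshold": self.params.decision_threshold,
                "kde_bandwidth_floor": self.params.kde_bandwidth_floor,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BQSARModel":
        def dens(items: list[dict]) -> list[_ComponentDensity]:
            return [
                _ComponentDensity(
                    centers=np.asarray(i["centers"], dtype=float),
                    bandwidth=float(i["bandwidth"]),
                    support=(float(i["support"][0]), float(i["support"][1])),
                )
                for i in items
            ]

        return cls(
            columns=list(d["columns"]),
            input_columns=list(d["input_columns"]),
            means=np.asarray(d["means"], dtype=float),
            scales=np.asarray(d["scales"], dtype=float),
            axes=np.asarray(d["axes"], dtype=float),
            eigenvalues=np.asarray(d["eigenvalues"], dtype=float),
            prior_active=float(d["prior_active"]),
            densities_active=dens(d["densities_active"]),
            densities_inactive=dens(d["densities_inactive"]),
            params=BQSARParams(**d["params"]),
        )

    # -- scoring -----------------------------------------------------------
    def _component_scores(self, X: np.ndarray) -> np.ndarray:
        Z = (X - self.means) / self.scales
        return (Z @ self.axes) / np.sqrt(self.eigenvalues)

    def predict_probability(self, X: np.ndarray | Sequence[float]) -> np.ndarray:
        """Posterior Pr(active | x) for one vector or a matrix of rows."""
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        X = np.atleast_2d(X)
        if X.shape[1] == len(self.input_columns) and len(self.input_columns) != len(self.columns):
            sel = [self.input_columns.index(c) for c in self.columns]
            X = X[:, sel]
        elif X.shape[1] != len(self.columns):
            raise ValueError(
                f"expected {len(self.columns)} (or {len(self.input_columns)}) "
                f"descriptor columns, got {X.shape[1]}"
            )
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite descriptor value")
        U = self._component_scores(X)
        smooth = self.params.smooth
        log_a = np.full(len(X), math.log(self.prior_active) if self.prior_active > 0 else -np.inf)
        log_i = np.full(
            len(X), math.log(1 - self.prior_active) if self.prior_active < 1 else -np.inf
        )
        for j in range(self.n_components):
            log_a = log_a + self.densities_active[j].log_density(U[:, j], smooth)
            log_i = log_i + self.densities_inactive[j].log_density(U[:, j], smooth)
        # p = 1 / (1 + exp(log_i - log_a)), stable in log space
        diff = np.clip(log_i - log_a, -700, 700)
        p = 1.0 / (1.0 + np.exp(diff))
        p = np.where(np.isfinite(log_a), p, 0.0)
        p = np.where(np.isfinite(log_i), p, np.where(np.isfinite(log_a), 1.0, p))
        return float(p[0]) if single else p

    def classify(self, X, threshold: float | None = None) -> np.ndarray | str:
        """'active' iff posterior >= threshold (ties classify active)."""
        threshold = self.params.decision_threshold if threshold is None else threshold
        if not 0.0 < threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")
        p = self.predict_probability(X)
        if np.isscalar(p):
            return "active" if p >= threshold else "inactive"
        return np.where(p >= threshold, "active", "inactive")


def fit_binary_qsar(
    X: np.ndarray,
    y: Sequence[int],
    params: BQSARParams | None = None,
    columns: Sequence[str] | None = None,
    min_n: int = 4,
) -> BQSARModel:
    """Fit the binned-Bayesian classifier on training data.

    ``X`` is compounds x descriptors, ``y`` a 0/1 vector (active = 1).
    Constant columns are dropped with a warning; standardisation and the
    decorrelating transform use training statistics only.
    """
    params = params or BQSARParams()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    y = np.asarray(y, dtype=int)
    n, d = X.shape
    if n < min_n:
        raise ValueError(f"need at least {min_n} training compounds")
    if len(y) != n:
        raise ValueError("X and y lengths differ")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    columns = list(columns) if columns is not None else [f"x{i}" for i in range(d)]
    if len(columns) != d:
        raise ValueError("column names do not match X width")
    input_columns = list(columns)

    # near-constant columns (equal values up to float rounding) carry no
    # signal and destabilise the correlation eigendecomposition
    scales_all = X.std(axis=0, ddof=0)
    keep = scales_all > 1e-12 + 1e-9 * np.abs(X.mean(axis=0))
    if not keep.any():
        raise ValueError("all descriptor columns are constant")
    if not keep.all():
        dropped = [c for c, k in zip(columns, keep) if not k]
        warnings.warn(f"dropping constant descriptor column(s): {', '.join(dropped)}")
    X = X[:, keep]
    columns = [c for c, k in zip(columns, keep) if k]
    means = X.mean(axis=0)
    scales = X.std(axis=0, ddof=0)
    Z = (X - means) / scales

    corr = (Z.T @ Z) / n
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    retain = eigvals >= params.condition_limit * eigvals[0]
    if params.component_limit is not None:
        retain &= np.arange(len(eigvals)) < params.component_limit
    eigvals, eigvecs = eigvals[retain], eigvecs[:, retain]

    U = (Z @ eigvecs) / np.sqrt(eigvals)
    act, inact = U[y == 1], U[y == 0]

    dens_a: list[_ComponentDensity] = []
    dens_i: list[_ComponentDensity] = []
    for j in range(U.shape[1]):
        ha = _silverman(act[:, j], params.kde_bandwidth_floor)
        hi = _silverman(inact[:, j], params.kde_bandwidth_floor)
        pad = 3.0 * max(ha, hi)
        support = (float(U[:, j].min() - pad), float(U[:, j].max() + pad))
        dens_a.append(_ComponentDensity(act[:, j].copy(), ha, support))
        dens_i.append(_ComponentDensity(inact[:, j].copy(), hi, support))

    return BQSARModel(
        columns=columns,
        input_columns=input_columns,
        means=means,
        scales=scales,
        axes=eigvecs,
        eigenvalues=eigvals,
        prior_active=float(np.mean(y == 1)),
        densities_active=dens_a,
        densities_inactive=dens_i,
        params=params,
    )
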