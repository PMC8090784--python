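"""Row-weighted principal component analysis with explicit retention rules.

The decomposition follows the singular-value-decomposition formulation
of duality-diagram PCA: rows (patients) carry non-negative weights that
are normalized to sum to one, columns are centered by their weighted
means, and the eigenstructure of the weighted covariance matrix is
obtained from the SVD of the weight-scaled centered matrix. Variables
enter unstandardized (covariance-metric PCA), so regions with larger
rate variance contribute more inertia.

Component retention combines a cumulative-variance floor with an
eigenvalue floor; the broken-stick rule and the scree-plot elbow are
computed as diagnostics only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import REGIONS
from .rates import ResidualTable


@dataclass
class PCAResult:
    """Eigenstructure plus the variable-level descriptive statistics.

    ``variable_coordinates`` uses the convention c_jk = e_jk * sqrt(lambda_k)
    (unit eigenvector scaled by the component's singular value), so a
    variable's squared coordinates across all components sum to its
    weighted variance. ``cos2`` (quality of variable representation) and
    ``contributions`` are the ratio statistics derived from the
    coordinates; contributions are percentages summing to 100 within
    each component.
    """

    eigenvalues: np.ndarray
    percent_variance: np.ndarray
    scores: pd.DataFrame
    variable_coordinates: pd.DataFrame
    cos2: pd.DataFrame
    contributions: pd.DataFrame
    row_weights: pd.Series
    column_means: pd.Series

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


@dataclass
class RetentionCriteria:
    """Thresholds for component retention.

    cum_var_min is the minimum cumulative share of total variance
    (default 0.90); eigen_min the absolute eigenvalue floor (default
    0.7). Broken-stick and elbow results are attached as diagnostics
    when the corresponding flags are set, never used as hard filters.
    """

    cum_var_min: float = 0.90
    eigen_min: float = 0.7
    broken_stick_diagnostic: bool = True
    elbow_diagnostic: bool = True

    def __post_init__(self):
        if not (0 < self.cum_var_min <= 1):
            raise ValueError("cum_var_min must be in (0, 1]")
        if self.eigen_min < 0:
            raise ValueError("eigen_min must be >= 0")


def _as_matrix(residuals) -> tuple[np.ndarray, list, list]:
    if isinstance(residuals, ResidualTable):
        df = residuals.residuals
    else:
        df = residuals
    cols = [c for c in df.columns if c in REGIONS] or list(df.columns)
    return df[cols].to_numpy(float), list(df.index), cols


def weighted_pca(residuals, row_weights=None) -> PCAResult:
    """Row-weighted covariance-metric PCA via SVD.

    Parameters
    ----------
    residuals : ResidualTable or DataFrame
        Patients x variables matrix of age-adjusted rates.
    row_weights : array-like, optional
        Non-negative per-patient weights (need not be normalized);
        uniform by default. Zero-weight rows do not influence the
        decomposition but still receive scores by projection.
    """
    X, ids, cols = _as_matrix(residuals)
    n, p = X.shape
    if row_weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(row_weights, float)
        if w.shape != (n,):
            raise ValueError(f"row_weights must have length {n}")
        if (w < 0).any():
            raise ValueError("row_weights must be non-negative")
        total = w.sum()
        if total <= 0:
            raise ValueError("row_weights must have positive sum")
        w = w / total
    if np.count_nonzero(w) < 3:
        raise ValueError("weighted PCA needs >= 3 patients with positive weight")
    if not np.isfinite(X).all():
        raise ValueError("residual matrix contains non-finite values")

    mu = w @ X
    Xc = X - mu
    B = np.sqrt(w)[:, None] * Xc
    _, s, Vt = np.linalg.svd(B, full_matrices=False)
    k = min(n, p)
    eigenvalues = s[:k] ** 2
    V = Vt[:k].T  # p x k unit eigenvectors

    # reproducible sign: largest-|loading| entry of each eigenvector positive
    for j in range(V.shape[1]):
        i = np.argmax(np.abs(V[:, j]))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]

    total_var = eigenvalues.sum()
    if total_var <= 0:
        percent = np.zeros_like(eigenvalues)
    else:
        percent = 100.0 * eigenvalues / total_var

    scores = Xc @ V
    coords = V * np.sqrt(eigenvalues)

    comp_names = [f"PC{j + 1}" for j in range(k)]
    coord_df = pd.DataFrame(coords, index=cols, columns=comp_names)
    return PCAResult(
        eigenvalues=eigenvalues,
        percent_variance=percent,
        scores=pd.DataFrame(scores, index=pd.Index(ids, name="patient_id"),
                            columns=comp_names),
        variable_coordinates=coord_df,
        cos2=cos2_from_coordinates(coord_df),
        contributions=contributions_from_coordinates(coord_df),
        row_weights=pd.Series(w, index=pd.Index(ids, name="patient_id")),
        column_means=pd.Series(mu, index=cols),
    )


def cos2_from_coordinates(coords: pd.DataFrame) -> pd.DataFrame:
    """Quality of variable representation: c_jk^2 / sum_k c_jk^2.

    The denominator runs over all components, so each variable's cos2
    values sum to 1. A zero-variance variable has no defined cos2 and is
    reported as NaN with a warning.
    """
    c2 = coords.to_numpy(float) ** 2
    denom = c2.sum(axis=1, keepdims=True)
    if (denom == 0).any():
        bad = [coords.index[i] for i in np.flatnonzero(denom.ravel() == 0)]
        warnings.warn(f"zero-variance variable(s), cos2 undefined: {bad}")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, c2 / denom, np.nan)
    return pd.DataFrame(out, index=coords.index, columns=coords.columns)


def contributions_from_coordinates(coords: pd.DataFrame) -> pd.DataFrame:
    """Variable contributions per component: 100 * c_jk^2 / sum_j c_jk^2."""
    c2 = coords.to_numpy(float) ** 2
    denom = c2.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, 100.0 * c2 / denom, np.nan)
    return pd.DataFrame(out, index=coords.index, columns=coords.columns)


def variable_stats(pca_or_coords) -> pd.DataFrame:
    """Tidy per-variable, per-component table of coordinate, cos2 and
    contribution (%), mirroring the layout of published PCA tables."""
    coords = (
        pca_or_coords.variable_coordinates
        if isinstance(pca_or_coords, PCAResult)
        else pd.DataFrame(pca_or_coords)
    )
    cos2 = cos2_from_coordinates(coords)
    ctr = contributions_from_coordinates(coords)
    rows = []
    for var in coords.index:
        for comp in coords.columns:
            rows.append({
                "variable": var,
                "component": comp,
                "coordinate": coords.loc[var, comp],
                "cos2": cos2.loc[var, comp],
                "contribution": ctr.loc[var, comp],
            })
    return pd.DataFrame(rows)


def broken_stick(p: int) -> np.ndarray:
    """Broken-stick thresholds b_k = (1/p) * sum_{i=k..p} 1/i.

    Expected ordered piece lengths of a unit stick broken at p-1 uniform
    points; decreasing and summing to 1.
    """
    if p < 1:
        raise ValueError("broken_stick requires p >= 1")
    inv = 1.0 / np.arange(1, p + 1)
    return np.cumsum(inv[::-1])[::-1] / p


def scree_elbow(eigenvalues) -> int:
    """Scree-plot elbow: the interior index maximizing the second
    difference of the spectrum; smallest index on ties. 1-based."""
    lam = np.asarray(eigenvalues, float)
    if len(lam) < 3:
        raise ValueError("scree_elbow requires >= 3 eigenvalues")
    second = lam[:-2] - 2 * lam[1:-1] + lam[2:]  # index i -> component i+2
    return int(np.argmax(second)) + 2


def select_from_spectrum(
    eigenvalues,
    percent_variance=None,
    criteria: RetentionCriteria | None = None,
) -> tuple[int, dict]:
    """Retention rule applied to an eigenvalue spectrum.

    Retains the smallest m whose cumulative percent variance reaches
    100*cum_var_min with lambda_m still above eigen_min; if no m
    satisfies both, falls back to the cumulative-variance rule alone
    with a warning. Returns (m, diagnostics).
    """
    criteria = criteria or RetentionCriteria()
    lam = np.asarray(eigenvalues, float)
    if percent_variance is None:
        percent_variance = 100.0 * lam / lam.sum()
    pv = np.asarray(percent_variance, float)
    cum = np.cumsum(pv)
    target = 100.0 * criteria.cum_var_min

    m = None
    for i in range(len(lam)):
        if cum[i] >= target - 1e-12 and lam[i] > criteria.eigen_min:
            m = i + 1
            break
    diagnostics: dict = {"cumulative_percent": cum.tolist()}
    if m is None:
        candidates = np.flatnonzero(cum >= target - 1e-12)
        m = int(candidates[0]) + 1 if len(candidates) else len(lam)
        warnings.warn(
            "no component count satisfies both the cumulative-variance and "
            f"eigenvalue floors; retaining {m} by cumulative variance alone "
            f"(eigenvalue {lam[m - 1]:.3g} <= {criteria.eigen_min})"
        )
        diagnostics["eigen_min_warning"] = True
    if criteria.broken_stick_diagnostic:
        bs = broken_stick(len(lam))
        diagnostics["broken_stick"] = bs.tolist()
        above = np.flatnonzero(pv / 100.0 <= bs)
        diagnostics["broken_stick_k"] = int(above[0]) if len(above) else len(lam)
    if criteria.elbow_diagnostic and len(lam) >= 3:
        diagnostics["elbow_k"] = scree_elbow(lam)
    return m, diagnostics


def select_components(
    pca: PCAResult, criteria: RetentionCriteria | None = None
) -> tuple[int, dict]:
    """Apply the retention rule to a fitted PCA (see
    :func:`select_from_spectrum`)."""
    return select_from_spectrum(pca.eigenvalues, pca.percent_variance, criteria)
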