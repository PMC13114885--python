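"""Behavioral-fraction standardization, PCA embedding and group separation.

A surgical cohort's cognition is summarized by 16 standardized behavioral
fractions (Barnes-maze acquisition and probe measures, contextual-fear
freezing measures, open-field activity measures). This module standardizes
the fraction matrix, projects it by principal component analysis, summarizes
each group as a multivariate Gaussian in the embedded space, and quantifies
pairwise group separation with the closed-form 2-Wasserstein (Bures) distance
between Gaussians.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

GROUPS = ("young-sham", "aged-sham", "young-surgery", "aged-surgery")

#: Default fraction catalog: Barnes-maze acquisition (escape latencies D1-D4,
#: D1-D2 latency change, first successful-entry session, total successful
#: entries), probe measures, contextual-fear measures and open-field measures.
FRACTION_NAMES: tuple[str, ...] = (
    "escape_latency_d1",
    "escape_latency_d2",
    "escape_latency_d3",
    "escape_latency_d4",
    "delta_latency_d1_d2",
    "first_entry_session",
    "total_successful_entries",
    "target_quadrant_time",
    "target_hole_latency",
    "target_visits",
    "freezing_time",
    "freezing_bouts",
    "high_active_time",
    "movement_time",
    "oft_distance",
    "oft_center_time",
)


class ValidationError(ValueError):
    """Raised when an input table violates the module's contracts."""


@dataclass
class BehavioralMatrix:
    """Animals x fractions value matrix with group labels.

    ``X`` holds one row per animal and one column per named behavioral
    fraction (16 by default). ``standardized`` records whether columns have
    been rescaled to cohort mean 0, SD 1.
    """

    animal_ids: list[str]
    group: list[str]
    X: np.ndarray
    columns: tuple[str, ...] = FRACTION_NAMES
    standardized: bool = False

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        n, d = self.X.shape
        if not (len(self.animal_ids) == len(self.group) == n):
            raise ValidationError("animal_ids, group and X rows must align")
        if d != len(self.columns):
            raise ValidationError("column names must match X width")
        if np.isnan(self.X).any():
            raise ValidationError("missing values in behavioral matrix")
        bad = set(self.group) - set(GROUPS)
        if bad:
            raise ValidationError(f"unknown group label(s): {sorted(bad)}")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.columns))
        df.insert(0, "group", self.group)
        df.insert(0, "animal_id", self.animal_ids)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, standardized: bool = False
                   ) -> "BehavioralMatrix":
        cols = tuple(c for c in df.columns if c not in ("animal_id", "group"))
        return cls(
            animal_ids=[str(a) for a in df["animal_id"]],
            group=list(df["group"]),
            X=df[list(cols)].to_numpy(dtype=float),
            columns=cols,
            standardized=standardized,
        )

    def rows(self, groups: tuple[str, ...] | list[str]) -> np.ndarray:
        """Boolean row mask for the given group labels."""
        gset = set(groups)
        return np.array([g in gset for g in self.group])


@dataclass
class PCAResult:
    """Principal-component embedding of a standardized fraction matrix."""

    mean_vector: np.ndarray
    components: np.ndarray        # d x k orthonormal (V_k)
    eigenvalues: np.ndarray       # k, descending
    scores: np.ndarray            # n x k (Y = (X - mean) V_k)
    explained_variance_ratio: np.ndarray


@dataclass
class GaussianSummary:
    """Gaussian (mu, Sigma) fit of one group's embedded coordinates."""

    mu: np.ndarray
    sigma: np.ndarray
    n: int


# ---------------------------------------------------------------------------


def standardize_fractions(table: BehavioralMatrix) -> BehavioralMatrix:
    """Rescale each fraction to cohort mean 0 and SD 1 (population 1/n SD).

    Fails on already-standardized input and on any zero-variance column
    (naming it).
    """
    if table.standardized:
        raise ValidationError("table is already standardized")
    mu = table.X.mean(axis=0)
    sd = table.X.std(axis=0)  # population convention for column scaling
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = [table.columns[i] for i in zero]
        raise ValidationError(f"zero-variance column(s): {names}")
    return replace(table, X=(table.X - mu) / sd, standardized=True)


def pca_project(table: BehavioralMatrix, k: int = 2) -> PCAResult:
    """Project a standardized fraction matrix onto its top-k components.

    The covariance matrix uses the 1/(n-1) convention; components come from
    an eigendecomposition, sorted by descending eigenvalue, each with its
    largest-magnitude entry made positive (deterministic sign convention).
    """
    n, d = table.X.shape
    if not table.standardized:
        raise ValidationError("PCA expects a standardized table")
    if not (1 <= k <= d):
        raise ValidationError(f"k={k} out of range [1, {d}]")
    if n < 2:
        raise ValidationError("need at least 2 samples")
    mean = table.X.mean(axis=0)
    Xc = table.X - mean
    C = Xc.T @ Xc / (n - 1)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # sign convention: largest-|entry| positive per component
    for j in range(d):
        i = np.argmax(np.abs(evecs[:, j]))
        if evecs[i, j] < 0:
            evecs[:, j] = -evecs[:, j]
    Vk = evecs[:, :k]
    return PCAResult(
        mean_vector=mean,
        components=Vk,
        eigenvalues=evals[:k],
        scores=Xc @ Vk,
        explained_variance_ratio=evals[:k] / evals.sum(),
    )


def fit_gaussian_summary(scores: np.ndarray) -> GaussianSummary:
    """Sample mean and 1/(n-1) sample covariance of embedded coordinates."""
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    n = scores.shape[0]
    if n < 2:
        raise ValidationError("Gaussian summary needs n >= 2")
    mu = scores.mean(axis=0)
    Z = scores - mu
    sigma = Z.T @ Z / (n - 1)
    sigma = 0.5 * (sigma + sigma.T)
    return GaussianSummary(mu=mu, sigma=sigma, n=n)


def _sqrtm_psd(sigma: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Symmetric PSD matrix square root via eigendecomposition.

    Eigenvalues in (-tol, 0) are clipped to 0; anything below -tol is an
    error (the matrix is not a covariance).
    """
    evals, evecs = np.linalg.eigh(0.5 * (sigma + sigma.T))
    if (evals < -tol).any():
        raise ValidationError(
            f"covariance has eigenvalue {evals.min():.3e} < -{tol}"
        )
    evals = np.clip(evals, 0.0, None)
    return (evecs * np.sqrt(evals)) @ evecs.T


def wasserstein_gaussian(
    g1: GaussianSummary, g2: GaussianSummary,
    covariance_term: str = "sqrt",
) -> float:
    """Squared 2-Wasserstein-type distance between two Gaussian summaries.

    Default (``covariance_term='sqrt'``): ||mu1 - mu2||^2 +
    ||Sigma1^(1/2) - Sigma2^(1/2)||_F^2 — the exact Bures term when the
    covariances commute. ``covariance_term='plain'`` uses
    ||Sigma1 - Sigma2||_F^2 instead. The squared form is returned (no outer
    square root). Symmetric in its arguments and nonnegative.
    """
    if g1.mu.shape != g2.mu.shape:
        raise ValidationError("dimension mismatch between summaries")
    dmu = float(np.sum((g1.mu - g2.mu) ** 2))
    if covariance_term == "sqrt":
        diff = _sqrtm_psd(g1.sigma) - _sqrtm_psd(g2.sigma)
    elif covariance_term == "plain":
        diff = g1.sigma - g2.sigma
    else:
        raise ValidationError(f"unknown covariance_term {covariance_term!r}")
    return dmu + float(np.sum(diff * diff))


def group_separation(
    table: BehavioralMatrix, group_a: str, group_b: str, k: int = 2,
    covariance_term: str = "sqrt",
) -> float:
    """Wasserstein separation between two groups in joint PCA-k space.

    The two groups' rows are pooled, embedded together, and each group is
    summarized as a Gaussian in the shared k-dimensional space.
    """
    mask = table.rows((group_a, group_b))
    sub = BehavioralMatrix(
        animal_ids=[a for a, m in zip(table.animal_ids, mask) if m],
        group=[g for g, m in zip(table.group, mask) if m],
        X=table.X[mask],
        columns=table.columns,
        standardized=table.standardized,
    )
    pca = pca_project(sub, k=k)
    ga = fit_gaussian_summary(pca.scores[sub.rows((group_a,))])
    gb = fit_gaussian_summary(pca.scores[sub.rows((group_b,))])
    return wasserstein_gaussian(ga, gb, covariance_term=covariance_term)
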