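"""Reference-anchored semi-supervised K-means phenotyping.

Aged surgical animals are partitioned into a PND-like (vulnerable) and a
non-PND-like (preserved) phenotype by two-cluster K-means with a must-link
constraint: the young-surgery reference animals are forced into one common
cluster, whose mean also seeds the first centroid. The cluster containing
the reference block is labelled non-PND.

The model/results split follows the usual fit() idiom:

>>> res = PhenotypePartition(X, mustlink_idx=ref_idx).fit(seed=0)
>>> res.labels, res.wcss_trace, res.summary()
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import adjusted_rand_score

logger = logging.getLogger(__name__)

MAX_ITER = 300


class ClusterInputError(ValueError):
    pass


def init_constrained_centroids(
    X: np.ndarray, mustlink_idx: np.ndarray, seed: int,
) -> np.ndarray:
    """Initial centroids for the constrained two-cluster problem.

    Centroid 1 is the mean of the must-link rows; centroid 2 is one row
    sampled uniformly from the unconstrained rows with the given seed.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    mustlink_idx = np.asarray(mustlink_idx, dtype=int)
    if mustlink_idx.size == 0 or mustlink_idx.size >= n:
        raise ClusterInputError("must-link set must be a nonempty strict subset")
    free = np.setdiff1d(np.arange(n), mustlink_idx)
    rng = np.random.default_rng(seed)
    c1 = X[mustlink_idx].mean(axis=0)
    c2 = X[rng.choice(free)]
    return np.vstack([c1, c2])


def _wcss(X: np.ndarray, centroids: np.ndarray, labels: np.ndarray) -> float:
    return float(np.sum((X - centroids[labels]) ** 2))


def constrained_kmeans(
    X: np.ndarray,
    mustlink_idx: np.ndarray,
    seed: int = 0,
    max_iter: int = MAX_ITER,
    constraint: str = "always",
) -> "PhenotypeResults":
    """Two-cluster Lloyd iterations with a hard must-link block.

    Assignment minimizes squared Euclidean distance per sample; the
    must-link block is assigned jointly to the single cluster minimizing its
    summed squared distance at every assignment step (``constraint='always'``).
    ``constraint='init-only'`` only biases initialization and lets plain
    Lloyd steps run, which may split the block. A cluster that empties is
    re-seeded from the point farthest from the surviving centroid (logged).
    Terminates when assignments stop changing or after ``max_iter``.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 3 or p < 1:
        raise ClusterInputError("need n >= 3 samples and p >= 1 features")
    if constraint not in ("always", "init-only"):
        raise ClusterInputError(f"unknown constraint mode {constraint!r}")
    mustlink_idx = np.asarray(mustlink_idx, dtype=int)
    centroids = init_constrained_centroids(X, mustlink_idx, seed)
    labels = np.full(n, -1, dtype=int)
    ml_mask = np.zeros(n, dtype=bool)
    ml_mask[mustlink_idx] = True
    trace: list[float] = []
    for it in range(1, max_iter + 1):
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        new = np.argmin(d2, axis=1)
        if constraint == "always":
            block = int(np.argmin(d2[ml_mask].sum(axis=0)))
            new[ml_mask] = block
        if np.array_equal(new, labels):
            trace.append(_wcss(X, centroids, labels))
            break
        labels = new
        for i in range(2):
            members = X[labels == i]
            if len(members) == 0:
                other = centroids[1 - i]
                d_other = ((X - other) ** 2).sum(axis=1)
                if constraint == "always":
                    # never tear a row out of the must-link block
                    d_other = np.where(ml_mask, -np.inf, d_other)
                far = int(np.argmax(d_other))
                logger.warning("cluster %d emptied; re-seeding from farthest "
                               "point (row %d)", i, far)
                centroids[i] = X[far]
                labels[far] = i
                members = X[labels == i]
            centroids[i] = members.mean(axis=0)
        trace.append(_wcss(X, centroids, labels))
    return PhenotypeResults(
        centroids=centroids, labels=labels,
        mustlink_idx=mustlink_idx, wcss_trace=np.asarray(trace),
        seed=seed, n_iter=it, constraint=constraint,
    )


@dataclass
class PhenotypePartition:
    """Two-cluster must-link K-means model over a feature matrix.

    Parameters
    ----------
    X : (n, p) feature matrix — standardized 16-D fractions by default, or a
        PCA-k embedding (``feature_space`` is a bookkeeping tag only).
    mustlink_idx : indices of the reference animals forced into one cluster.
    """

    X: np.ndarray
    mustlink_idx: np.ndarray
    feature_space: str = "raw-16d"
    constraint: str = "always"
    max_iter: int = MAX_ITER

    @classmethod
    def from_behavioral(cls, table, reference_group: str = "young-surgery",
                        include_groups: tuple[str, ...] = ("young-surgery",
                                                           "aged-surgery"),
                        **kw) -> "PhenotypePartition":
        """Build the model from a standardized BehavioralMatrix.

        Only the surgical groups enter the clustering; the reference group's
        rows form the must-link block.
        """
        mask = table.rows(include_groups)
        groups = [g for g, m in zip(table.group, mask) if m]
        ids = [a for a, m in zip(table.animal_ids, mask) if m]
        ml = np.flatnonzero([g == reference_group for g in groups])
        model = cls(X=table.X[mask], mustlink_idx=ml, **kw)
        model.animal_ids = ids
        model.groups = groups
        return model

    def fit(self, seed: int = 0) -> "PhenotypeResults":
        res = constrained_kmeans(self.X, self.mustlink_idx, seed=seed,
                                 max_iter=self.max_iter,
                                 constraint=self.constraint)
        res.model = self
        res.feature_space = self.feature_space
        return res


@dataclass
class PhenotypeResults:
    """Converged constrained K-means state plus phenotype labelling."""

    centroids: np.ndarray
    labels: np.ndarray
    mustlink_idx: np.ndarray
    wcss_trace: np.ndarray
    seed: int
    n_iter: int
    constraint: str = "always"
    feature_space: str = "raw-16d"
    model: PhenotypePartition | None = None

    @property
    def wcss(self) -> float:
        return float(self.wcss_trace[-1])

    def phenotypes(self, reference_idx: np.ndarray | None = None) -> np.ndarray:
        """Per-sample phenotype labels: 'non-PND' for the cluster holding the
        reference animals, 'PND' for the other cluster.

        ``reference_idx`` defaults to the must-link block and must be a
        subset of it.
        """
        ref = self.mustlink_idx if reference_idx is None else np.asarray(
            reference_idx, dtype=int)
        if not np.isin(ref, self.mustlink_idx).all():
            raise ClusterInputError("reference_ids must lie in the must-link set")
        ref_labels = np.unique(self.labels[ref])
        if ref_labels.size != 1:
            raise RuntimeError(
                "internal consistency error: reference animals split across "
                "clusters despite must-link enforcement"
            )
        non_pnd = int(ref_labels[0])
        return np.where(self.labels == non_pnd, "non-PND", "PND")

    def degenerate_separation(self, tol: float = 1e-9) -> bool:
        """True when the two centroids (nearly) coincide."""
        return bool(np.sum((self.centroids[0] - self.centroids[1]) ** 2) < tol)

    def summary(self) -> str:
        ph = self.phenotypes()
        lines = [
            "Constrained K-means phenotype partition",
            "=" * 43,
            f"samples:            {len(self.labels)}",
            f"feature space:      {self.feature_space}",
            f"constraint:         {self.constraint}",
            f"seed:               {self.seed}",
            f"iterations:         {self.n_iter}",
            f"final WCSS:         {self.wcss:.4f}",
            f"non-PND cluster:    {int((ph == 'non-PND').sum())}",
            f"PND cluster:        {int((ph == 'PND').sum())}",
            f"must-link size:     {self.mustlink_idx.size}",
        ]
        if self.degenerate_separation():
            lines.append("WARNING: degenerate separation (coincident centroids)")
        return "\n".join(lines)


def assign_pnd_labels(res: PhenotypeResults,
                      reference_idx: np.ndarray | None = None):
    """Per-animal phenotype table; reference animals reported separately.

    Returns a pandas DataFrame with columns animal_id (when known), group,
    cluster, phenotype and is_reference.
    """
    import pandas as pd

    ph = res.phenotypes(reference_idx)
    n = len(res.labels)
    is_ref = np.zeros(n, dtype=bool)
    is_ref[res.mustlink_idx] = True
    df = pd.DataFrame({
        "cluster": res.labels,
        "phenotype": ph,
        "is_reference": is_ref,
    })
    if res.model is not None and hasattr(res.model, "animal_ids"):
        df.insert(0, "group", res.model.groups)
        df.insert(0, "animal_id", res.model.animal_ids)
    return df


def ari(labels_a, labels_b) -> float:
    """Adjusted Rand Index between two labelings (chance-corrected, in [-1, 1])."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ClusterInputError("labelings must have equal length")
    return float(adjusted_rand_score(a, b))


@dataclass
class StabilityReport:
    """Pairwise ARI between constrained K-means runs across seeds."""

    seeds: list[int]
    ari_matrix: np.ndarray
    mean_ari: float


def stability_across_seeds(
    X: np.ndarray, mustlink_idx: np.ndarray, seeds: list[int],
    constraint: str = "always",
) -> StabilityReport:
    """Run the clustering once per seed and report pairwise partition ARI."""
    if len(seeds) < 2:
        raise ClusterInputError("need at least 2 seeds")
    runs = [constrained_kmeans(X, mustlink_idx, seed=s, constraint=constraint)
            for s in seeds]
    m = len(seeds)
    mat = np.ones((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            mat[i, j] = mat[j, i] = ari(runs[i].labels, runs[j].labels)
    off = mat[~np.eye(m, dtype=bool)]
    return StabilityReport(seeds=list(seeds), ari_matrix=mat,
                           mean_ari=float(off.mean()))
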