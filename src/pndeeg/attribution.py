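"""Permutation-sampling Shapley attribution for fitted classifiers.

Estimates per-sample additive feature attributions by Monte-Carlo sampling
of feature orderings: for each sampled permutation a background row is
drawn, features are switched from background to explained values one at a
time in permutation order, and each feature is credited with the resulting
change in model output. The telescoping sum makes the attribution exactly
additive per permutation — the attributions of one sample always sum to
``f(x) - f(background row)`` — so the averaged attributions sum to
``f(x) - E[f(background)]`` over the sampled backgrounds.

Mean absolute attribution across samples gives the global importance
ranking used by the top-k feature curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class AttributionError(RuntimeError):
    """Raised when attribution cannot be computed for a model."""


@dataclass
class AttributionResult:
    """Per-sample attributions plus global mean-|value| ranking."""

    feature_names: list[str]
    values: np.ndarray              # (n_samples, n_features)
    expected_value: float           # mean model output over background draws
    base_outputs: np.ndarray        # f(x) per explained sample
    background_means: np.ndarray | None = None  # per-sample E[f(bg)] over
    # that sample's own background draws; attributions sum exactly to
    # base_outputs - background_means

    def mean_abs(self) -> np.ndarray:
        return np.abs(self.values).mean(axis=0)

    def ranking(self) -> list[tuple[str, float]]:
        """Feature names with mean |attribution|, most important first."""
        ma = self.mean_abs()
        order = np.argsort(-ma, kind="stable")
        return [(self.feature_names[i], float(ma[i])) for i in order]


def shapley_values(
    predict_fn,
    X_background: np.ndarray,
    X_explain: np.ndarray,
    feature_names: list[str] | None = None,
    n_permutations: int = 64,
    seed: int = 0,
) -> AttributionResult:
    """Monte-Carlo Shapley attributions of ``predict_fn`` outputs.

    Parameters
    ----------
    predict_fn : callable mapping an (m, p) array to m scalar outputs
        (e.g. positive-class probability or decision score).
    X_background : training rows used as the reference distribution.
    X_explain : rows to attribute.
    n_permutations : sampled feature orderings per explained row.
    """
    bg = np.asarray(X_background, dtype=float)
    Xe = np.asarray(X_explain, dtype=float)
    if bg.ndim != 2 or Xe.ndim != 2 or bg.shape[1] != Xe.shape[1]:
        raise AttributionError("background and explained matrices must share width")
    n, p = Xe.shape
    names = feature_names or [f"x{j}" for j in range(p)]
    rng = np.random.default_rng(seed)
    phi = np.zeros((n, p))
    bg_means = np.zeros(n)
    try:
        base_outputs = np.asarray(predict_fn(Xe), dtype=float)
    except Exception as exc:  # pragma: no cover - surfaced, never swallowed
        raise AttributionError(f"model evaluation failed: {exc}") from exc
    for i in range(n):
        x = Xe[i]
        # build all intermediate coalition rows for every permutation, then
        # evaluate the model once on the whole batch
        rows = np.empty((n_permutations * (p + 1), p))
        perms = [rng.permutation(p) for _ in range(n_permutations)]
        for t, perm in enumerate(perms):
            z = bg[rng.integers(len(bg))].copy()
            base = t * (p + 1)
            rows[base] = z
            for step, j in enumerate(perm):
                z = z.copy()
                z[j] = x[j]
                rows[base + step + 1] = z
        out = np.asarray(predict_fn(rows), dtype=float)
        for t, perm in enumerate(perms):
            base = t * (p + 1)
            bg_means[i] += out[base]
            deltas = np.diff(out[base:base + p + 1])
            phi[i, perm] += deltas
    phi /= n_permutations
    bg_means /= n_permutations
    return AttributionResult(
        feature_names=list(names),
        values=phi,
        expected_value=float(bg_means.mean()),
        base_outputs=base_outputs,
        background_means=bg_means,
    )
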