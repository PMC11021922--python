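"""Rejection + weighted multinomial-logistic scenario choice."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression

from .reference import ReferenceTable
from .sumstats import SummaryStatVector


@dataclass
class ModelChoiceResult:
    posteriors: dict[int, float]
    n_closest: int
    distance_threshold: float
    method: str  # "logistic" or "rejection"
    rejection_proportions: dict[int, float] | None = None

    def best_scenario(self) -> int:
        return max(self.posteriors, key=self.posteriors.get)


def _standardized_deviations(
    target: SummaryStatVector, table: ReferenceTable
) -> np.ndarray:
    return (table.stats - target.values[None, :]) / table.mad[None, :]


def rejection_posteriors(
    target: SummaryStatVector, table: ReferenceTable, n_closest: int
) -> tuple[dict[int, float], np.ndarray, float]:
    """Scenario proportions among the n_closest rows (and the subset)."""
    dev = _standardized_deviations(target, table)
    dist = np.sqrt(np.sum(dev**2, axis=1))
    order = np.argsort(dist, kind="stable")[:n_closest]
    d_max = float(dist[order[-1]])
    labels = table.df["scenario"].to_numpy()[order]
    props = {
        int(s): float(np.mean(labels == s)) for s in table.scenarios
    }
    return props, order, d_max


def model_choice(
    target: SummaryStatVector,
    table: ReferenceTable,
    n_closest: int | None = None,
    ridge: float = 1e-6,
) -> ModelChoiceResult:
    """Posterior scenario probabilities by local logistic regression.

    Statistics are standardized by the table's MADs; the ``n_closest`` rows
    by Euclidean distance (default 1% of the table) enter a multinomial
    logistic regression of the scenario indicator on the standardized
    deviations, weighted by Epanechnikov kernel weights 1 - (d/d_max)^2.
    Posteriors are the fitted probabilities at deviation zero.  Degenerate
    fits fall back to the rejection proportions with a warning.
    """
    scenarios = table.scenarios
    if n_closest is None:
        n_closest = max(int(round(0.01 * table.n_rows)), 10 * len(scenarios))
    if n_closest > table.n_rows:
        raise ValueError("n_closest exceeds table size")
    if n_closest < 10 * len(scenarios):
        raise ValueError(
            f"n_closest={n_closest} too small for {len(scenarios)} scenarios"
        )
    dev = _standardized_deviations(target, table)
    dist = np.sqrt(np.sum(dev**2, axis=1))
    order = np.argsort(dist, kind="stable")[:n_closest]
    d_sel = dist[order]
    d_max = float(d_sel[-1])
    labels = table.df["scenario"].to_numpy()[order].astype(int)
    props = {int(s): float(np.mean(labels == s)) for s in scenarios}

    def _rejection(reason: str) -> ModelChoiceResult:
        warnings.warn(f"logistic model choice fell back to rejection: {reason}")
        return ModelChoiceResult(props, n_closest, d_max, "rejection", props)

    present = np.unique(labels)
    if len(present) < 2:
        return _rejection("only one scenario among accepted rows")
    if d_max == 0:
        return _rejection("all accepted rows coincide with the target")
    w = 1.0 - (d_sel / d_max) ** 2
    w = np.maximum(w, 1e-8)  # keep the boundary row in the fit
    X = dev[order]
    try:
        clf = LogisticRegression(
            penalty="l2", C=1.0 / ridge, solver="lbfgs", max_iter=2000
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(X, labels, sample_weight=w)
        probs = clf.predict_proba(np.zeros((1, X.shape[1])))[0]
    except Exception as exc:  # numerical failure -> rejection
        return _rejection(str(exc))
    posteriors = {int(s): 0.0 for s in scenarios}
    for cls, p in zip(clf.classes_, probs):
        posteriors[int(cls)] = float(p)
    total = sum(posteriors.values())
    posteriors = {s: p / total for s, p in posteriors.items()}
    return ModelChoiceResult(posteriors, n_closest, d_max, "logistic", props)
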