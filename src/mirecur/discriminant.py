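"""Fisher linear discriminant index construction and panel search.

The recurrence-predictive index is an affine score along the Fisher
discriminant direction ``w = S_w^{-1} (mu_rec - mu_non)`` where ``S_w`` is
the pooled within-class covariance.  Fisher directions are defined only up
to positive scaling, so a convention is fixed: ``w`` is scaled to unit
Euclidean norm, oriented so relapsers score higher, and the intercept is
chosen so the projected grand mean maps to score 0.  The decision cut-off
``tau`` is the midpoint of the projected class means; score >= tau predicts
recurrence.

``exhaustive_search`` fits every nonempty candidate subset up to a size
cap and ranks the panels by training accuracy (ties: higher AUC, fewer
members, lexicographic names), reproducing the best-panel-per-size table
this kind of biomarker study reports.  Published index formulas from the
motivating study are available via :func:`published_indices`.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .types import DiscriminantModel, Group, ValidationError

__all__ = [
    "fit_flda",
    "evaluate_classifier",
    "roc_auc",
    "exhaustive_search",
    "apply_index",
    "dichotomize_covariate",
    "SearchResult",
    "published_indices",
]

MAX_CANDIDATES = 20
RIDGE_CONDITION_LIMIT = 1e12


def _as_binary(y) -> np.ndarray:
    """Map group labels to 1 = recurrence, 0 = nonrecurrence."""
    arr = np.asarray(y)
    if arr.dtype.kind in "bi":
        return arr.astype(int)
    return (arr == Group.RECURRENCE.value).astype(int)


def fit_flda(X: pd.DataFrame, y) -> DiscriminantModel:
    """Fit a Fisher linear discriminant index on a patients x members frame.

    Requires at least two patients per class.  When the pooled within-class
    covariance is near-singular (condition number above 1e12) a small ridge
    ``lambda = 1e-6 * trace / dim`` is added before inversion.
    """
    yb = _as_binary(y)
    if (yb == 1).sum() < 2 or (yb == 0).sum() < 2:
        raise ValidationError("fit_flda needs >= 2 patients per class")
    members = list(X.columns)
    A = X.to_numpy(dtype=float)
    x1 = A[yb == 1]
    x0 = A[yb == 0]
    mu1 = x1.mean(axis=0)
    mu0 = x0.mean(axis=0)
    s1 = (x1 - mu1).T @ (x1 - mu1)
    s0 = (x0 - mu0).T @ (x0 - mu0)
    sw = (s1 + s0) / (len(A) - 2)
    cond = np.linalg.cond(sw) if sw.size > 1 else (
        np.inf if sw.item() == 0 else 1.0
    )
    if not np.isfinite(cond) or cond > RIDGE_CONDITION_LIMIT:
        lam = 1e-6 * np.trace(sw) / sw.shape[0]
        if lam <= 0:
            raise ValidationError(
                f"within-class covariance singular for members {members}"
            )
        sw = sw + lam * np.eye(sw.shape[0])
    w = np.linalg.solve(sw, mu1 - mu0)
    norm = np.linalg.norm(w)
    if norm == 0 or not np.all(np.isfinite(w)):
        raise ValidationError(
            f"degenerate discriminant direction for members {members}"
        )
    w = w / norm
    if (mu1 - mu0) @ w < 0:  # orient so relapsers score higher
        w = -w
    grand = A.mean(axis=0)
    b = -float(grand @ w)  # projected grand mean -> reference score 0
    tau = float(((mu1 @ w + b) + (mu0 @ w + b)) / 2.0)
    model = DiscriminantModel(
        members=members,
        coefficients=[float(c) for c in w],
        intercept=b,
        cutoff=tau,
    )
    scores = model.score(A)
    model.metrics = evaluate_classifier(model, X, yb)
    model.metrics["auc"] = roc_auc(scores, yb)
    return model


def evaluate_classifier(model: DiscriminantModel, X: pd.DataFrame, y) -> dict:
    """Training-style accuracy / sensitivity / specificity (fractions).

    Sensitivity is the fraction of recurrence patients scoring at or above
    the cut-off; specificity the fraction of nonrecurrence patients below
    it.
    """
    yb = _as_binary(y)
    if (yb == 1).sum() == 0 or (yb == 0).sum() == 0:
        raise ValidationError("both classes must be present to evaluate")
    missing = [m for m in model.members if m not in X.columns]
    if missing:
        raise ValidationError(f"expression columns missing: {missing}")
    scores = np.atleast_1d(model.score(X[model.members].to_numpy(float)))
    pred = (scores >= model.cutoff).astype(int)
    tp = int(((pred == 1) & (yb == 1)).sum())
    tn = int(((pred == 0) & (yb == 0)).sum())
    return {
        "accuracy": (tp + tn) / len(yb),
        "sensitivity": tp / (yb == 1).sum(),
        "specificity": tn / (yb == 0).sum(),
    }


def roc_auc(scores, y) -> float:
    """AUC as the normalized Mann-Whitney U statistic; ties count half."""
    yb = _as_binary(y)
    s = np.asarray(scores, dtype=float)
    pos = s[yb == 1]
    neg = s[yb == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("both classes must be present for AUC")
    from scipy.stats import rankdata

    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


@dataclass
class SearchResult:
    """All evaluated panels, ranked, plus the best panel per size."""

    entries: pd.DataFrame  # members, size, accuracy, sensitivity, specificity, auc
    models: dict[tuple[str, ...], DiscriminantModel]

    @property
    def ranking(self) -> pd.DataFrame:
        return self.entries

    def best(self) -> DiscriminantModel:
        return self.models[tuple(self.entries.iloc[0]["members"])]

    def best_per_size(self) -> pd.DataFrame:
        return (
            self.entries.sort_values("rank")
            .groupby("size", as_index=False)
            .first()
            .sort_values("size")
            .reset_index(drop=True)
        )


def exhaustive_search(
    X: pd.DataFrame, y, candidates: list[str], max_size: int | None = None
) -> SearchResult:
    """Fit every nonempty candidate subset up to ``max_size`` members.

    Ranking: accuracy desc, AUC desc, fewer members, then lexicographic
    member names — fully deterministic and invariant to input order.
    """
    candidates = list(candidates)
    if len(candidates) > MAX_CANDIDATES:
        raise ValidationError(
            f"{len(candidates)} candidates exceeds the combinatorial guard "
            f"({MAX_CANDIDATES}); narrow the candidate set"
        )
    max_size = max_size or len(candidates)
    if max_size > len(candidates):
        raise ValidationError("max_size exceeds the number of candidates")
    yb = _as_binary(y)
    rows = []
    models: dict[tuple[str, ...], DiscriminantModel] = {}
    for size in range(1, max_size + 1):
        for subset in combinations(sorted(candidates), size):
            model = fit_flda(X[list(subset)], yb)
            models[subset] = model
            rows.append(
                {
                    "members": list(subset),
                    "size": size,
                    "accuracy": model.metrics["accuracy"],
                    "sensitivity": model.metrics["sensitivity"],
                    "specificity": model.metrics["specificity"],
                    "auc": model.metrics["auc"],
                }
            )
    entries = pd.DataFrame(rows)
    entries["_names"] = entries["members"].map(lambda m: "|".join(m))
    entries = entries.sort_values(
        by=["accuracy", "auc", "size", "_names"],
        ascending=[False, False, True, True],
        kind="stable",
    ).drop(columns="_names")
    entries["rank"] = np.arange(1, len(entries) + 1)
    return SearchResult(entries=entries.reset_index(drop=True), models=models)


def apply_index(model: DiscriminantModel, x) -> tuple[float, str]:
    """Score one member-expression vector and call the predicted group.

    Missing (NaN) member values are rejected — no imputation.  A score
    exactly at the cut-off predicts recurrence.
    """
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.shape[0] != len(model.members):
        raise ValidationError(
            f"expected {len(model.members)} member values, got shape {arr.shape}"
        )
    if np.isnan(arr).any():
        raise ValidationError("missing member value; no imputation is performed")
    score = float(model.score(arr))
    group = (
        Group.RECURRENCE.value if score >= model.cutoff
        else Group.NONRECURRENCE.value
    )
    return score, group


def dichotomize_covariate(
    values, y, method: str = "youden", threshold: float | None = None
) -> tuple[float, dict]:
    """Turn a continuous clinical covariate into a binary classifier.

    ``method="youden"`` scans every midpoint between adjacent distinct
    values (plus flanking cutoffs) and picks the one maximizing
    sensitivity + specificity - 1, preferring the lower cutoff on ties;
    ``method="fixed"`` applies a supplied clinical threshold (value >
    threshold calls recurrence, matching the usual ``<=t / >t`` strata).
    Returns (cutoff, metrics incl. AUC); metrics carry a ``degenerate``
    flag when the covariate is constant.
    """
    v = np.asarray(values, dtype=float)
    yb = _as_binary(y)
    if (yb == 1).sum() == 0 or (yb == 0).sum() == 0:
        raise ValidationError("both classes must be present")

    def metrics_at(cut: float) -> dict:
        pred = (v >= cut).astype(int)
        tp = ((pred == 1) & (yb == 1)).sum()
        tn = ((pred == 0) & (yb == 0)).sum()
        return {
            "accuracy": (tp + tn) / len(yb),
            "sensitivity": tp / (yb == 1).sum(),
            "specificity": tn / (yb == 0).sum(),
        }

    if method == "fixed":
        if threshold is None:
            raise ValidationError("method='fixed' needs a threshold")
        # clinical strata are "<= t" vs "> t": predict recurrence above t
        cut = np.nextafter(float(threshold), np.inf)
        m = metrics_at(cut)
        m["auc"] = roc_auc(v, yb)
        return float(threshold), m
    if method != "youden":
        raise ValidationError(f"unknown method {method!r}")

    uniq = np.unique(v)
    if uniq.size == 1:
        m = metrics_at(uniq[0])
        m.update(auc=0.5, degenerate=True)
        return float(uniq[0]), m
    cuts = np.concatenate(
        [[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]]
    )
    best_cut, best_j = None, -np.inf
    for cut in cuts:
        m = metrics_at(cut)
        j = m["sensitivity"] + m["specificity"] - 1.0
        if j > best_j:  # strict: ties keep the earlier (lower) cutoff
            best_cut, best_j = cut, j
    m = metrics_at(best_cut)
    m["auc"] = roc_auc(v, yb)
    return float(best_cut), m


def published_indices() -> dict[str, DiscriminantModel]:
    """The two published recurrence-predictive index formulas.

    Index 1: (0.238 x miR-1225-3p) + (0.320 x miR-1260b)
             - (0.473 x miR-6875-5p) + 1.09, cut-off 0.671.
    Index 2: (0.321 x miR-1260b) - (0.216 x miR-6834-3p)
             - (0.421 x miR-6875-5p) + 3.14, cut-off 0.646.

    Training metrics are the reported best-panel values (accuracy 90.9%,
    sensitivity 84.6%, specificity 100.0%).
    """
    metrics1 = {"accuracy": 0.909, "sensitivity": 0.846,
                "specificity": 1.0, "auc": 0.897}
    metrics2 = {"accuracy": 0.909, "sensitivity": 0.846,
                "specificity": 1.0, "auc": 0.880}
    return {
        "index1": DiscriminantModel(
            members=["miR-1225-3p", "miR-1260b", "miR-6875-5p"],
            coefficients=[0.238, 0.320, -0.473],
            intercept=1.09,
            cutoff=0.671,
            metrics=metrics1,
        ),
        "index2": DiscriminantModel(
            members=["miR-1260b", "miR-6834-3p", "miR-6875-5p"],
            coefficients=[0.321, -0.216, -0.421],
            intercept=3.14,
            cutoff=0.646,
            metrics=metrics2,
        ),
    }
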