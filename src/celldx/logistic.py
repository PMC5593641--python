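"""Per-cell binary logistic scoring: normal vs aberrant.

The per-cell outcome y is dichotomous (cell originates from malignant tissue
or not) and the predictors are natural-log channel intensities, so the model
is

    logit(E[y]) = beta_0 + beta_1 x_1 + ... + beta_p x_p

fitted by maximum likelihood via iteratively reweighted least squares
(Newton-Raphson on the log-likelihood). Coefficients are reported the way
clinical tables print them: odds ratio exp(beta), delta-method standard error
OR * SE(beta), Wald z, two-sided normal p, and 95% interval
exp(beta +/- 1.959964 SE(beta)). The reporter also accepts printed (OR, SE)
pairs, so published coefficient tables can be re-derived and checked.

Decision machinery: probability cutoff scans on the 0-1 grid in steps of
0.05 (21 rows) with Youden-style selection, rank-based ROC/AUC (ties counted
1/2, i.e. the Mann-Whitney concordance probability), and the qualitative
Hosmer-Lemeshow discrimination bands for the AUC.

No ridge fallback is applied: quasi-complete separation is surfaced as an
explicit error rather than silently shrunk, keeping estimates comparable to
conventional maximum-likelihood reporting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm, rankdata

from .io import CellTable, DefinitionError

__all__ = [
    "SeparationError",
    "LogisticFit",
    "CellProbabilities",
    "ROCCurve",
    "fit_logistic",
    "fit_univariate_panel",
    "coefficient_report",
    "coefficient_report_from_printed",
    "predict_prob",
    "cutoff_scan",
    "select_cutoff",
    "roc_auc",
    "discrimination_band",
    "aberrant_by_pathology",
    "CUTOFF_PRESETS",
    "CI_MULTIPLIER",
]

#: Normal 97.5th percentile used for the printed-style 95% intervals.
CI_MULTIPLIER = 1.959964

#: Recommended operating points: 0.75 for the epithelial-cells-only model,
#: 0.9 for the all-compartments model.
CUTOFF_PRESETS = {"epithelial": 0.75, "all_cells": 0.9}

_SCORE_TOL = 1e-8
_LL_RTOL = 1e-10
_MAX_ITER = 100
_BETA_DIVERGENCE = 100.0


class SeparationError(RuntimeError):
    """Quasi-complete separation: the MLE diverges and is not reported."""


def aberrant_by_pathology(table: CellTable) -> np.ndarray:
    """Default outcome rule: cells from benign tissue are normal (0), all
    other cells are aberrant (1)."""
    return (table.data["path_category"] != "B").to_numpy()


@dataclass
class LogisticFit:
    """ML estimate of the cell-level logistic model.

    ``beta`` is ordered (intercept, markers...); ``cov_beta`` is the inverse
    observed information at the optimum.
    """

    beta: np.ndarray
    cov_beta: np.ndarray
    marker_names: tuple[str, ...]
    n_obs: int
    converged: bool
    n_iter: int
    log_likelihood: float

    @property
    def se_beta(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_beta))

    def to_json(self, path: str | Path | None = None, **extra) -> str:
        payload = {
            "marker_names": list(self.marker_names),
            "beta": self.beta.tolist(),
            "cov_beta": self.cov_beta.tolist(),
            "n_obs": self.n_obs,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "log_likelihood": self.log_likelihood,
            **extra,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "LogisticFit":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        return cls(
            beta=np.asarray(payload["beta"], dtype=float),
            cov_beta=np.asarray(payload["cov_beta"], dtype=float),
            marker_names=tuple(payload["marker_names"]),
            n_obs=int(payload["n_obs"]),
            converged=bool(payload["converged"]),
            n_iter=int(payload["n_iter"]),
            log_likelihood=float(payload["log_likelihood"]),
        )


@dataclass
class CellProbabilities:
    """Per-cell cancer probabilities under a fitted model."""

    prob: np.ndarray
    linear_predictor: np.ndarray
    cutoff: float | None = None

    def labels(self, cutoff: float | None = None) -> np.ndarray:
        """'aberrant' where prob >= cutoff, else 'normal'."""
        c = self.cutoff if cutoff is None else cutoff
        if c is None:
            raise DefinitionError("no cutoff given")
        return np.where(self.prob >= c, "aberrant", "normal")


@dataclass
class ROCCurve:
    """ROC points over all distinct score thresholds plus the AUC.

    The AUC is the Mann-Whitney concordance probability: the chance a random
    aberrant cell scores above a random normal cell, ties counted 1/2.
    """

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr})


# ---------------------------------------------------------------------------
# fitting


def _resolve_outcome(
    table: CellTable,
    outcome: Callable[[CellTable], np.ndarray] | Sequence[bool] | None,
) -> np.ndarray:
    if outcome is None:
        y = aberrant_by_pathology(table)
    elif callable(outcome):
        y = np.asarray(outcome(table))
    else:
        y = np.asarray(outcome)
    y = y.astype(float)
    if y.shape != (table.n_cells,):
        raise DefinitionError("outcome length does not match table")
    if not np.isin(y, (0.0, 1.0)).all():
        raise DefinitionError("outcome must be binary")
    return y


def _irls(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool, int, float]:
    n, q = x.shape
    beta = np.zeros(q)
    # start the intercept at the empirical logit for faster, stabler steps
    pbar = y.mean()
    beta[0] = np.log(pbar / (1.0 - pbar))
    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, _MAX_ITER + 1):
        eta = x @ beta
        p = expit(eta)
        score = x.T @ (y - p)
        w = p * (1.0 - p)
        info = (x * w[:, None]).T @ x
        try:
            delta = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(
                "singular information matrix (separation or collinear markers)"
            ) from exc
        beta = beta + delta
        if np.abs(beta).max() > _BETA_DIVERGENCE:
            raise SeparationError(
                "coefficients diverging: outcome is (quasi-)completely separated"
            )
        eta = x @ beta
        ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        if np.abs(x.T @ (y - expit(eta))).max() < _SCORE_TOL:
            converged = True
            ll_old = ll
            break
        if np.isfinite(ll_old) and abs(ll - ll_old) < _LL_RTOL * (abs(ll_old) + 1e-12):
            converged = True
            ll_old = ll
            break
        ll_old = ll
    p = expit(x @ beta)
    w = p * (1.0 - p)
    info = (x * w[:, None]).T @ x
    cov = np.linalg.inv(info)
    return beta, cov, converged, it, ll_old


def fit_logistic(
    table: CellTable,
    markers: Sequence[str] | None = None,
    outcome: Callable[[CellTable], np.ndarray] | Sequence[bool] | None = None,
) -> LogisticFit:
    """Maximum-likelihood logistic fit of aberrant-vs-normal on log intensities.

    ``outcome`` may be an explicit binary vector, a callable mapping the table
    to one, or None for the default tissue-of-origin rule (benign tissue ->
    normal cell). Convergence: max absolute score < 1e-8 or relative
    log-likelihood change < 1e-10.
    """
    if not table.is_log:
        raise DefinitionError("logistic stage expects a log-transformed table")
    markers = table.marker_names if markers is None else tuple(markers)
    x = table.intensity_matrix(markers)
    if not np.isfinite(x).all():
        raise DefinitionError("non-finite predictor values")
    y = _resolve_outcome(table, outcome)
    if y.min() == y.max():
        raise DefinitionError("outcome has a single class; cannot fit")
    design = np.column_stack([np.ones(len(y)), x])
    beta, cov, converged, n_iter, ll = _irls(design, y)
    return LogisticFit(
        beta=beta,
        cov_beta=cov,
        marker_names=tuple(markers),
        n_obs=len(y),
        converged=converged,
        n_iter=n_iter,
        log_likelihood=ll,
    )


def fit_univariate_panel(
    table: CellTable,
    markers: Sequence[str] | None = None,
    outcome: Callable[[CellTable], np.ndarray] | Sequence[bool] | None = None,
) -> list[LogisticFit]:
    """One single-predictor logistic fit per marker (association screen)."""
    markers = table.marker_names if markers is None else tuple(markers)
    return [fit_logistic(table, markers=[m], outcome=outcome) for m in markers]


# ---------------------------------------------------------------------------
# reporting


def _report_from_beta(
    beta: np.ndarray, se_beta: np.ndarray, index: Sequence[str]
) -> pd.DataFrame:
    or_ = np.exp(beta)
    z = beta / se_beta
    return pd.DataFrame(
        {
            "odds_ratio": or_,
            "se_or": or_ * se_beta,
            "z": z,
            "p_value": 2.0 * norm.sf(np.abs(z)),
            "ci_low": np.exp(beta - CI_MULTIPLIER * se_beta),
            "ci_high": np.exp(beta + CI_MULTIPLIER * se_beta),
        },
        index=list(index),
    )


def coefficient_report(fit: LogisticFit) -> pd.DataFrame:
    """Delta-method odds-ratio table, markers first then the intercept row.

    Columns mirror the conventional layout: odds_ratio, se_or, z, p_value,
    ci_low, ci_high, where OR = exp(beta), SE(OR) = OR * SE(beta),
    z = beta / SE(beta) and CI = exp(beta +/- 1.959964 SE(beta)).
    """
    order = list(range(1, len(fit.beta))) + [0]
    index = [f"ln{m}" for m in fit.marker_names] + ["_cons"]
    return _report_from_beta(fit.beta[order], fit.se_beta[order], index)


def coefficient_report_from_printed(
    odds_ratios: Sequence[float],
    se_ors: Sequence[float],
    index: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Re-derive z, p and CI columns from printed (OR, SE(OR)) pairs.

    Inverts the delta method: beta = ln(OR), SE(beta) = SE(OR) / OR. Lets a
    published coefficient table be checked for internal consistency.
    """
    or_ = np.asarray(odds_ratios, dtype=float)
    se_or = np.asarray(se_ors, dtype=float)
    if or_.shape != se_or.shape:
        raise DefinitionError("odds_ratios and se_ors must have equal length")
    if (or_ <= 0).any():
        raise DefinitionError("odds ratios must be positive")
    if (se_or <= 0).any():
        raise DefinitionError("standard errors must be positive")
    beta = np.log(or_)
    se_beta = se_or / or_
    idx = list(index) if index is not None else [f"term{i}" for i in range(len(or_))]
    return _report_from_beta(beta, se_beta, idx)


# ---------------------------------------------------------------------------
# scoring and decision machinery


def predict_prob(
    fit: LogisticFit, table: CellTable, cutoff: float | None = None
) -> CellProbabilities:
    """Inverse-logit cancer probability for every cell in the table."""
    if not table.is_log:
        raise DefinitionError("prediction expects a log-transformed table")
    x = table.intensity_matrix(fit.marker_names)
    eta = fit.beta[0] + x @ fit.beta[1:]
    return CellProbabilities(prob=expit(eta), linear_predictor=eta, cutoff=cutoff)


def _scores_truth(
    probs: CellProbabilities | np.ndarray, truth: Sequence[bool]
) -> tuple[np.ndarray, np.ndarray]:
    scores = probs.prob if isinstance(probs, CellProbabilities) else np.asarray(probs, float)
    y = np.asarray(truth).astype(bool)
    if scores.shape != y.shape:
        raise DefinitionError("scores and truth must have equal length")
    if y.all() or not y.any():
        raise DefinitionError("truth must contain both classes")
    return scores, y


def cutoff_scan(
    probs: CellProbabilities | np.ndarray, truth: Sequence[bool]
) -> pd.DataFrame:
    """Sensitivity/specificity/percent-correct on the 21-point cutoff grid.

    Cutoffs run 0.00, 0.05, ..., 1.00; a cell is called aberrant when its
    probability is >= the cutoff, so sensitivity is nonincreasing and
    specificity nondecreasing along the grid.
    """
    scores, y = _scores_truth(probs, truth)
    cutoffs = np.round(np.arange(21) * 0.05, 2)
    pred = scores[:, None] >= cutoffs[None, :]
    tp = (pred & y[:, None]).sum(axis=0)
    fp = (pred & ~y[:, None]).sum(axis=0)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    tn = n_neg - fp
    return pd.DataFrame(
        {
            "cutoff": cutoffs,
            "sensitivity": tp / n_pos,
            "specificity": tn / n_neg,
            "percent_correct": (tp + tn) / len(y),
        }
    )


def select_cutoff(scan: pd.DataFrame, rule: str = "youden") -> float:
    """Cutoff maximizing the rule over the scan; ties -> smallest cutoff."""
    if rule != "youden":
        raise DefinitionError(f"unknown cutoff rule {rule!r}")
    j = scan["sensitivity"].to_numpy() + scan["specificity"].to_numpy() - 1.0
    return float(scan["cutoff"].iloc[int(np.argmax(j))])


def roc_auc(
    probs: CellProbabilities | np.ndarray, truth: Sequence[bool]
) -> ROCCurve:
    """ROC curve and rank-based AUC (Mann-Whitney, ties counted 1/2)."""
    scores, y = _scores_truth(probs, truth)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    ranks = rankdata(scores)  # average ranks handle ties as 1/2 concordance
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    order = np.argsort(scores)[::-1]
    sorted_scores = scores[order]
    sorted_y = y[order]
    distinct = np.r_[np.flatnonzero(np.diff(sorted_scores)), len(scores) - 1]
    tps = np.cumsum(sorted_y)[distinct]
    fps = np.cumsum(~sorted_y)[distinct]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    thresholds = np.r_[np.inf, sorted_scores[distinct]]
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=float(auc))


def discrimination_band(auc: float) -> str:
    """Qualitative Hosmer-Lemeshow label for an AUC.

    0.5 -> 'none' (no better than a coin flip); (0.7, 0.8] -> 'acceptable';
    (0.8, 0.9] -> 'excellent'; (0.9, 1] -> 'outstanding'. The gap (0.5, 0.7]
    is labelled 'poor' and [0, 0.5) 'worse-than-chance' as package extensions
    of the published rules.
    """
    if not 0.0 <= auc <= 1.0:
        raise DefinitionError(f"AUC {auc} outside [0, 1]")
    if auc < 0.5:
        return "worse-than-chance"
    if auc == 0.5:
        return "none"
    if auc <= 0.7:
        return "poor"
    if auc <= 0.8:
        return "acceptable"
    if auc <= 0.9:
        return "excellent"
    return "outstanding"
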