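"""Classifier fitting and the full evaluation surface.

Two model families, each fit on a single standardized metric predictor:

* logistic regression (maximum likelihood, intercept + slope), reported in
  the classic Wald-table shape — B, SE, Wald chi-square, p, Exp(B) with its
  95% Wald CI, and accuracy at the 0.5 threshold;
* a single-hidden-layer perceptron with tanh hidden units and a softmax /
  cross-entropy output over the two classes (for a binary problem the
  logistic output scikit-learn uses is exactly the 2-class softmax).

Evaluation covers summed cross-entropy on train and test (nats), the ROC
curve and its area on test, overall and per-class accuracy at 0.5,
cumulative gain and lift (benefit) curves under descending-score ordering,
and box-plot-style predicted-score summaries per class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import log_loss, roc_auc_score, roc_curve
from sklearn.neural_network import MLPClassifier
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .lagged import LaggedDataset

__all__ = [
    "SeparationError",
    "LogisticReport",
    "MLPConfig",
    "ModelReport",
    "fit_logistic",
    "fit_mlp",
    "evaluate",
    "gain_lift_curves",
    "render_curves",
]

HIDDEN_UNITS_MIN = 1
HIDDEN_UNITS_MAX = 50
#: Candidate hidden-layer widths tried when no width is fixed.
HIDDEN_UNITS_GRID = (1, 2, 4, 8)

Scorer = Callable[[np.ndarray], np.ndarray]


class SeparationError(RuntimeError):
    """Complete/quasi-complete separation: the MLE does not exist."""


def _check_xy(x, y):
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y).ravel().astype(int)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    return x, y


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogisticReport:
    """Wald-table summary of a single-predictor logistic fit.

    ``B`` is the slope on the (standardized) metric in logit units; the
    intercept is fitted but reported separately. expB = exp(B); the CI is
    the Wald interval exp(B +/- 1.96*SE); wald = (B/SE)^2 with a 1-df
    chi-square p-value; accuracy is the training proportion correct at 0.5.
    """

    B: float
    SE: float
    wald: float
    p: float
    expB: float
    ci_low: float
    ci_high: float
    accuracy: float
    intercept: float
    intercept_se: float
    n: int


def fit_logistic(x, y) -> tuple:
    """Maximum-likelihood logistic fit of binary y on one predictor.

    Returns ``(report, scorer)`` where ``scorer`` maps x values to predicted
    injury probabilities. Raises :class:`SeparationError` on complete or
    quasi-complete separation and :class:`ValueError` on single-class y.
    """
    x, y = _check_xy(x, y)
    X = sm.add_constant(x)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, PerfectSeparationWarning) as exc:
        raise SeparationError(str(exc)) from exc
    if not res.mle_retvals.get("converged", False) or np.max(np.abs(res.params)) > 30:
        raise SeparationError(
            "logistic MLE did not converge to a finite solution (separation?)"
        )
    b0, b1 = res.params
    se0, se1 = res.bse
    wald = (b1 / se1) ** 2
    scorer: Scorer = lambda xs: expit(b0 + b1 * np.asarray(xs, dtype=float))
    report = LogisticReport(
        B=float(b1),
        SE=float(se1),
        wald=float(wald),
        p=float(stats.chi2.sf(wald, df=1)),
        expB=float(np.exp(b1)),
        ci_low=float(np.exp(b1 - 1.959963984540054 * se1)),
        ci_high=float(np.exp(b1 + 1.959963984540054 * se1)),
        accuracy=float(np.mean((scorer(x) >= 0.5) == (y == 1))),
        intercept=float(b0),
        intercept_se=float(se0),
        n=int(y.size),
    )
    return report, scorer


# ---------------------------------------------------------------------------
# multilayer perceptron
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MLPConfig:
    """Single-hidden-layer perceptron hyperparameters.

    ``hidden_units`` is clamped into [1, 50]; when None, the width is chosen
    from a small grid (1, 2, 4, 8) by cross-entropy on an internal 20%
    validation slice of the training rows, then the network is refit on all
    training rows. Activations and loss are fixed: tanh hidden layer,
    softmax/logistic output, cross-entropy error.
    """

    hidden_units: Optional[int] = None
    max_epochs: int = 500
    tolerance: float = 1e-6
    seed: int = 0

    def resolved_units(self) -> Optional[int]:
        if self.hidden_units is None:
            return None
        h = int(self.hidden_units)
        if not HIDDEN_UNITS_MIN <= h <= HIDDEN_UNITS_MAX:
            clamped = int(np.clip(h, HIDDEN_UNITS_MIN, HIDDEN_UNITS_MAX))
            warnings.warn(
                f"hidden_units={h} outside [{HIDDEN_UNITS_MIN}, {HIDDEN_UNITS_MAX}]; "
                f"clamped to {clamped}",
                RuntimeWarning, stacklevel=2,
            )
            return clamped
        return h


def _fit_one_mlp(x, y, h, config):
    net = MLPClassifier(
        hidden_layer_sizes=(h,),
        activation="tanh",
        solver="lbfgs",
        max_iter=config.max_epochs,
        tol=config.tolerance,
        random_state=int(config.seed) % (2**32),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        net.fit(x.reshape(-1, 1), y)
    return net


def fit_mlp(x, y, config: Optional[MLPConfig] = None) -> tuple:
    """Train the perceptron; returns ``(scorer, info)``.

    ``info`` carries the hidden width used and, under grid selection, the
    per-candidate validation cross-entropies. Non-convergence within
    ``max_epochs`` emits a warning from the optimizer but still returns the
    scorer, matching how the curve-based evaluation is meant to be used.
    """
    config = config or MLPConfig()
    x, y = _check_xy(x, y)
    h = config.resolved_units()
    info = {}
    if h is None:
        rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0x331]))
        perm = rng.permutation(x.size)
        n_val = max(1, x.size // 5)
        val, tr = perm[:n_val], perm[n_val:]
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[val])) < 2:
            tr = val = perm  # tiny/degenerate data: select in-sample
        losses = {}
        for cand in HIDDEN_UNITS_GRID:
            net = _fit_one_mlp(x[tr], y[tr], cand, config)
            p = net.predict_proba(x[val].reshape(-1, 1))[:, 1]
            losses[cand] = float(log_loss(y[val], p, labels=[0, 1]))
        h = min(HIDDEN_UNITS_GRID, key=lambda c: (losses[c], c))
        info["validation_cross_entropy"] = losses
    net = _fit_one_mlp(x, y, h, config)
    info["hidden_units"] = h
    scorer: Scorer = lambda xs: net.predict_proba(
        np.asarray(xs, dtype=float).reshape(-1, 1)
    )[:, 1]
    return scorer, info


# ---------------------------------------------------------------------------
# evaluation surface
# ---------------------------------------------------------------------------

def gain_lift_curves(scores, labels) -> dict:
    """Cumulative gain and lift under descending-score ordering.

    gain(q) is the fraction of all positives captured in the top q quantile
    of scores (q = k/n after each row), anchored at (0, 0); lift(q) =
    gain(q)/q, so a scoreless baseline has lift 1 and lift(1) == 1 exactly.
    Ties are broken by stable ordering. Raises ValueError with no positives.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    if scores.shape != labels.shape or scores.size == 0:
        raise ValueError("scores and labels must be equal-length and non-empty")
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("gain/lift undefined without positive labels")
    order = np.argsort(-scores, kind="stable")
    cum_pos = np.cumsum(labels[order])
    n = scores.size
    q = np.arange(1, n + 1) / n
    gain = cum_pos / n_pos
    return {
        "q": np.concatenate([[0.0], q]),
        "gain": np.concatenate([[0.0], gain]),
        "lift_q": q,
        "lift": gain / q,
    }


def _score_summary(scores: np.ndarray) -> dict:
    """Box-plot statistics (Tukey whiskers) of predicted probabilities."""
    if scores.size == 0:
        return {"n": 0}
    q1, med, q3 = np.percentile(scores, [25, 50, 75])
    iqr = q3 - q1
    in_lo = scores[scores >= q1 - 1.5 * iqr]
    in_hi = scores[scores <= q3 + 1.5 * iqr]
    lo = float(in_lo.min()) if in_lo.size else float(scores.min())
    hi = float(in_hi.max()) if in_hi.size else float(scores.max())
    return {
        "n": int(scores.size),
        "mean": float(scores.mean()),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "whisker_low": lo,
        "whisker_high": hi,
        "n_outliers": int(((scores < lo) | (scores > hi)).sum()),
    }


@dataclass
class ModelReport:
    """Full per-cell evaluation: errors, discrimination, curves, score shapes."""

    model_kind: str
    metric_name: str
    lag_days: int
    cross_entropy_train: float
    cross_entropy_test: float
    auc: Optional[float]
    auc_reason: Optional[str]
    accuracy_overall: float
    accuracy_injury: Optional[float]
    accuracy_noninjury: Optional[float]
    roc_points: dict = field(repr=False, default_factory=dict)
    gain_points: dict = field(repr=False, default_factory=dict)
    score_by_class: dict = field(repr=False, default_factory=dict)
    n_train: int = 0
    n_test: int = 0
    extra: dict = field(repr=False, default_factory=dict)


def evaluate(scorer: Scorer, dataset: LaggedDataset, *, model_kind: str,
             threshold: float = 0.5) -> ModelReport:
    """Score a fitted model on a split dataset.

    Cross-entropy is the summed negative log-likelihood in nats on each
    split half. ROC/AUC, accuracies, gain/lift and score summaries are
    computed on the test half; with a single-class test set the AUC and
    gain/lift are marked undefined rather than raised.
    """
    train, test = dataset.part("train"), dataset.part("test")
    if len(test) == 0:
        raise ValueError("test set is empty")
    y_tr = train["y"].to_numpy(dtype=int)
    y_te = test["y"].to_numpy(dtype=int)
    # raw scores rank/threshold; clipped copies keep the log-loss finite
    s_tr = np.asarray(scorer(train["x"].to_numpy(dtype=float)), dtype=float)
    s_te = np.asarray(scorer(test["x"].to_numpy(dtype=float)), dtype=float)
    p_tr = np.clip(s_tr, 1e-12, 1 - 1e-12)
    p_te = np.clip(s_te, 1e-12, 1 - 1e-12)

    pred = s_te >= threshold
    acc = float(np.mean(pred == (y_te == 1)))
    acc_inj = float(np.mean(pred[y_te == 1])) if (y_te == 1).any() else None
    acc_non = float(np.mean(~pred[y_te == 0])) if (y_te == 0).any() else None

    if len(np.unique(y_te)) < 2:
        auc, auc_reason, roc_points, gain_points = None, "single_class_test", {}, {}
    else:
        fpr, tpr, thr = roc_curve(y_te, s_te, drop_intermediate=False)
        auc = float(roc_auc_score(y_te, s_te))
        auc_reason = None
        roc_points = {"fpr": fpr, "tpr": tpr, "threshold": thr}
        gain_points = gain_lift_curves(s_te, y_te)

    return ModelReport(
        model_kind=model_kind,
        metric_name=dataset.metric_name,
        lag_days=dataset.lag_days,
        cross_entropy_train=float(log_loss(y_tr, p_tr, normalize=False, labels=[0, 1])),
        cross_entropy_test=float(log_loss(y_te, p_te, normalize=False, labels=[0, 1])),
        auc=auc,
        auc_reason=auc_reason,
        accuracy_overall=acc,
        accuracy_injury=acc_inj,
        accuracy_noninjury=acc_non,
        roc_points=roc_points,
        gain_points=gain_points,
        score_by_class={
            "injury": _score_summary(p_te[y_te == 1]),
            "noninjury": _score_summary(p_te[y_te == 0]),
        },
        n_train=int(len(train)),
        n_test=int(len(test)),
    )


def render_curves(report: ModelReport, path) -> None:
    """Write a 3-panel ROC / gain / lift figure for one evaluated cell."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    title = f"{report.metric_name}, lag {report.lag_days}d, {report.model_kind}"
    if report.roc_points:
        axes[0].plot(report.roc_points["fpr"], report.roc_points["tpr"])
        axes[0].plot([0, 1], [0, 1], "k--", lw=0.8)
        axes[0].set_title(f"ROC (AUC={report.auc:.3f})")
    axes[0].set_xlabel("false positive rate")
    axes[0].set_ylabel("true positive rate")
    if report.gain_points:
        g = report.gain_points
        axes[1].plot(g["q"], g["gain"])
        axes[1].plot([0, 1], [0, 1], "k--", lw=0.8)
        axes[2].plot(g["lift_q"], g["lift"])
        axes[2].axhline(1.0, color="k", ls="--", lw=0.8)
    axes[1].set_title("cumulative gain")
    axes[1].set_xlabel("fraction of data")
    axes[2].set_title("lift (benefit)")
    axes[2].set_xlabel("fraction of data")
    fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
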