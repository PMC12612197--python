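"""Presence-background MaxEnt with hinge features and L1 regularisation.

The model is the standard Gibbs formulation: over the background cells
b the fitted distribution is ``q_lambda(b) = exp(lambda·f(b)) / Z`` and
the weights minimise the penalised negative presence log-likelihood

    J(lambda) = -(1/m) sum_presences lambda·f(x_i)
                + log sum_background exp(lambda·f(x_b)) - log B
                + sum_j beta_j |lambda_j|,

with per-feature penalties ``beta_j = multiplier * beta_hinge * s_j / sqrt(m)``
(``beta_hinge = 0.5``, ``s_j`` the feature's standard deviation over the
presence rows). J is convex; it is minimised by L-BFGS-B after the
standard positive/negative split ``lambda = u - v`` that makes the L1
term smooth. Features are forward/reverse hinges (piecewise-linear
rectifiers scaled to [0, 1] on the training range) at quantile knots,
which give the model spline-like response curves.

Suitability is reported through the complementary log-log transform
``1 - exp(-exp(H) * r(x))`` of the relative occurrence rate
``r(x) = exp(lambda·f(x) - log Z)``, where H is the entropy of the
fitted background distribution; a uniform model scores ``1 - 1/e``
everywhere. Evaluation is by fold-wise rank-based AUC (the probability
that a random presence outscores a random background point, ties
counted half).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import rankdata

from .bias import TrainingTable

logger = logging.getLogger(__name__)

#: Base L1 penalty scale for hinge features.
BETA_HINGE = 0.5
#: Floor on the per-feature presence standard deviation used in the
#: penalty, preventing a zero penalty for presence-constant features.
_S_FLOOR = 1e-3
#: Box bound on |lambda_j|; bounded features make larger weights
#: numerically meaningless.
_LAMBDA_MAX = 200.0


# ----------------------------------------------------------------------
# Hinge basis
# ----------------------------------------------------------------------

@dataclass
class HingeBasis:
    """Forward/reverse hinge features at quantile knots.

    For covariate x with training range [lo, hi] and knot t strictly
    inside it, the forward hinge is ``max(0, x - t) / (hi - t)`` and the
    reverse hinge ``max(0, t - x) / (t - lo)``; both are in [0, 1] on
    the training range.
    """

    covariates: list[str]
    mins: dict[str, float]
    maxs: dict[str, float]
    knots: dict[str, np.ndarray]

    @property
    def feature_names(self) -> list[str]:
        names = []
        for cov in self.covariates:
            names += [f"{cov}:fwd:{t:.10g}" for t in self.knots[cov]]
            names += [f"{cov}:rev:{t:.10g}" for t in self.knots[cov]]
        return names

    @property
    def n_features(self) -> int:
        return sum(2 * len(self.knots[c]) for c in self.covariates)

    def transform(self, X: pd.DataFrame, clamp: bool = False) -> np.ndarray:
        """Feature matrix for a covariate table.

        With ``clamp`` on, covariate values outside the training range
        are moved to the nearest bound before evaluation, so projections
        never extrapolate the hinges.
        """
        cols = []
        for cov in self.covariates:
            x = X[cov].to_numpy(dtype=float)
            lo, hi = self.mins[cov], self.maxs[cov]
            if clamp:
                x = np.clip(x, lo, hi)
            t = self.knots[cov]
            fwd = np.maximum(0.0, x[:, None] - t[None, :]) / (hi - t[None, :])
            rev = np.maximum(0.0, t[None, :] - x[:, None]) / (t[None, :] - lo)
            cols.append(fwd)
            cols.append(rev)
        return np.hstack(cols)


def build_hinge_basis(X: pd.DataFrame,
                      knots_per_covariate: int = 30) -> HingeBasis:
    """Place knots at evenly spaced quantiles of each covariate.

    Knots fall strictly inside the observed [min, max]; duplicate
    quantiles are collapsed. Constant covariates carry no information
    and are excluded from the basis with a warning.
    """
    covariates, mins, maxs, knots = [], {}, {}, {}
    for cov in X.columns:
        x = X[cov].to_numpy(dtype=float)
        lo, hi = float(x.min()), float(x.max())
        if not hi > lo:
            warnings.warn(f"covariate {cov!r} is constant; excluded from the "
                          "hinge basis", stacklevel=2)
            continue
        q = np.linspace(0, 1, knots_per_covariate + 2)[1:-1]
        t = np.unique(np.quantile(x, q))
        t = t[(t > lo) & (t < hi)]
        if t.size == 0:
            t = np.array([0.5 * (lo + hi)])
        covariates.append(cov)
        mins[cov] = lo
        maxs[cov] = hi
        knots[cov] = t
    if not covariates:
        raise ValueError("no non-constant covariates available for the basis")
    return HingeBasis(covariates, mins, maxs, knots)


# ----------------------------------------------------------------------
# Fitting
# ----------------------------------------------------------------------

def feature_penalties(F_presence: np.ndarray, multiplier: float) -> np.ndarray:
    """Per-feature L1 penalties ``multiplier * 0.5 * s_j / sqrt(m)``."""
    m = F_presence.shape[0]
    s = F_presence.std(axis=0)
    return multiplier * BETA_HINGE * np.maximum(s, _S_FLOOR) / np.sqrt(m)


def maxent_objective(lam: np.ndarray, F_presence: np.ndarray,
                     F_background: np.ndarray, beta: np.ndarray) -> float:
    """The penalised negative presence log-likelihood J(lambda)."""
    B = F_background.shape[0]
    return float(
        -(F_presence @ lam).mean()
        + logsumexp(F_background @ lam)
        - np.log(B)
        + np.sum(beta * np.abs(lam))
    )


@dataclass
class MaxEntModel:
    """A fitted hinge MaxEnt model, sufficient to reproduce predictions."""

    basis: HingeBasis
    weights: np.ndarray
    beta: np.ndarray
    multiplier: float
    log_z: float
    entropy: float
    m: int
    b: int
    converged: bool = True
    n_iter: int = 0
    objective: float = np.nan

    def linear_score(self, X: pd.DataFrame, clamp: bool = False) -> np.ndarray:
        F = self.basis.transform(X, clamp=clamp)
        return F @ self.weights

    def predict(self, X: pd.DataFrame, transform: str = "cloglog",
                clamp: bool = False) -> np.ndarray:
        """Suitability scores for a covariate table.

        ``raw`` returns the relative occurrence rate r(x); ``cloglog``
        (default) and ``logistic`` map it into (0, 1).
        """
        log_r = self.linear_score(X, clamp=clamp) - self.log_z
        if transform == "raw":
            return np.exp(log_r)
        # cap the exponent: beyond it both transforms saturate at 1 exactly
        z = np.exp(np.minimum(self.entropy + log_r, 700.0))
        if transform == "cloglog":
            return 1.0 - np.exp(-z)
        if transform == "logistic":
            return z / (1.0 + z)
        raise ValueError(f"unknown transform {transform!r}")

    # -- serialisation -------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "basis": {
                "covariates": self.basis.covariates,
                "mins": self.basis.mins,
                "maxs": self.basis.maxs,
                "knots": {c: list(k) for c, k in self.basis.knots.items()},
            },
            "weights": list(self.weights),
            "beta": list(self.beta),
            "multiplier": self.multiplier,
            "log_z": self.log_z,
            "entropy": self.entropy,
            "m": self.m,
            "b": self.b,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "objective": self.objective,
        }
        text = json.dumps(doc, sort_keys=True, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "MaxEntModel":
        try:
            is_file = Path(source).exists()
        except OSError:
            is_file = False
        text = Path(source).read_text() if is_file else str(source)
        doc = json.loads(text)
        basis = HingeBasis(
            covariates=list(doc["basis"]["covariates"]),
            mins={k: float(v) for k, v in doc["basis"]["mins"].items()},
            maxs={k: float(v) for k, v in doc["basis"]["maxs"].items()},
            knots={k: np.asarray(v, dtype=float)
                   for k, v in doc["basis"]["knots"].items()},
        )
        return cls(
            basis=basis,
            weights=np.asarray(doc["weights"], dtype=float),
            beta=np.asarray(doc["beta"], dtype=float),
            multiplier=float(doc["multiplier"]),
            log_z=float(doc["log_z"]),
            entropy=float(doc["entropy"]),
            m=int(doc["m"]),
            b=int(doc["b"]),
            converged=bool(doc["converged"]),
            n_iter=int(doc["n_iter"]),
            objective=float(doc["objective"]),
        )


def fit_maxent(training: TrainingTable, basis: HingeBasis | None = None,
               multiplier: float = 2.0, tolerance: float = 1e-7,
               max_iter: int = 10_000,
               callback=None) -> MaxEntModel:
    """Fit the L1-penalised Gibbs model by bounded L-BFGS-B.

    The non-smooth |lambda| term is handled by splitting each weight
    into positive and negative parts, giving a smooth convex bound-
    constrained problem. Deterministic given inputs.
    """
    if basis is None:
        basis = build_hinge_basis(training.features)
    F = basis.transform(training.features)
    if not np.isfinite(F).all():
        raise ValueError("non-finite feature values in training data")
    is_pres = training.labels == 1
    F_p, F_b = F[is_pres], F[~is_pres]
    m, B = F_p.shape[0], F_b.shape[0]
    beta = feature_penalties(F_p, multiplier)
    p = F.shape[1]
    mean_p = F_p.mean(axis=0)

    def fun(x):
        lam = x[:p] - x[p:]
        eta = F_b @ lam
        lse = logsumexp(eta)
        q = np.exp(eta - lse)
        grad_lam = -mean_p + q @ F_b
        val = float(-(mean_p @ lam) + lse - np.log(B)
                    + np.sum(beta * (x[:p] + x[p:])))
        grad = np.concatenate([grad_lam + beta, -grad_lam + beta])
        return val, grad

    wrapped = None
    if callback is not None:
        def wrapped(x):
            callback(fun(x)[0])

    res = minimize(
        fun, np.zeros(2 * p), jac=True, method="L-BFGS-B",
        bounds=[(0.0, _LAMBDA_MAX)] * (2 * p),
        options={"ftol": tolerance, "gtol": 1e-9, "maxiter": max_iter},
        callback=wrapped,
    )
    if not res.success and "ITERATIONS" in str(res.message).upper():
        logger.warning("fit_maxent: iteration cap reached; final gradient "
                       "max |g| = %.3g", np.abs(res.jac).max())
    lam = res.x[:p] - res.x[p:]
    lam[np.abs(lam) < 1e-10] = 0.0
    eta_b = F_b @ lam
    log_z = float(logsumexp(eta_b))
    q = np.exp(eta_b - log_z)
    entropy = float(-np.sum(q * np.log(np.maximum(q, 1e-300))))
    return MaxEntModel(
        basis=basis, weights=lam, beta=beta, multiplier=multiplier,
        log_z=log_z, entropy=entropy, m=m, b=B,
        converged=bool(res.success), n_iter=int(res.nit),
        objective=float(res.fun),
    )


# ----------------------------------------------------------------------
# Evaluation
# ----------------------------------------------------------------------

def compute_auc(presence_scores, background_scores) -> float:
    """Rank-based (Mann–Whitney) AUC, ties counted half."""
    pos = np.asarray(presence_scores, dtype=float)
    neg = np.asarray(background_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score sets must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    return float((r_pos - pos.size * (pos.size + 1) / 2.0)
                 / (pos.size * neg.size))


@dataclass
class CVResult:
    """Per-fold test AUCs of a k-fold cross-validation."""

    fold_auc: list[float]
    mean_auc: float
    presence_folds: np.ndarray
    background_folds: np.ndarray
    seed: int


def _fold_assignment(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    folds = np.repeat(np.arange(k), int(np.ceil(n / k)))[:n]
    return rng.permutation(folds)


def cross_validate(training: TrainingTable, basis: HingeBasis | None = None,
                   multiplier: float = 2.0, k: int = 3,
                   seed: int = 0) -> CVResult:
    """Seeded k-fold cross-validated AUC.

    Presences and background rows are partitioned independently into k
    random folds; each fold is scored by a model fitted on the rest.
    """
    if training.m < k:
        raise ValueError(f"need at least k={k} presences, got {training.m}")
    if basis is None:
        basis = build_hinge_basis(training.features)
    rng = np.random.default_rng(seed)
    pres_folds = _fold_assignment(training.m, k, rng)
    bg_folds = _fold_assignment(training.b, k, rng)
    folds = np.empty(len(training.labels), dtype=int)
    folds[training.labels == 1] = pres_folds
    folds[training.labels == 0] = bg_folds
    aucs = []
    for fold in range(k):
        train_rows = folds != fold
        sub = TrainingTable(
            features=training.features[train_rows].reset_index(drop=True),
            labels=training.labels[train_rows],
        )
        model = fit_maxent(sub, basis=basis, multiplier=multiplier)
        test = ~train_rows
        scores = model.predict(training.features[test])
        test_labels = training.labels[test]
        aucs.append(compute_auc(scores[test_labels == 1],
                                scores[test_labels == 0]))
    return CVResult(
        fold_auc=aucs, mean_auc=float(np.mean(aucs)),
        presence_folds=pres_folds, background_folds=bg_folds, seed=seed,
    )
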