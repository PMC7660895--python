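"""Proportional-odds ordinal logistic regression baseline.

The comparison model predicts the three ordered function classes
(none < decreased < normal) from the nine annotation counts of a
haplotype's variants. Cumulative logits follow the classical
parameterization ``logit P(Y <= k | x) = zeta_k - x . beta`` with strictly
increasing thresholds ``zeta``, so covariates shift all cumulative odds by
the same amount (the proportional-odds assumption). The likelihood is
maximized with BFGS on an unconstrained reparameterization of the
thresholds; complete separation is detected and handled by an L2-penalized
refit, flagged on the fitted model.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from .core import ANNOTATION_NAMES, Function

_RANK_TO_FUNCTION = {0: Function.NONE, 1: Function.DECREASED,
                     2: Function.NORMAL}


@dataclass
class BaselineModel:
    """Fitted proportional-odds model over annotation-count features."""

    beta: np.ndarray            # (n_features,)
    thresholds: np.ndarray      # (2,), strictly increasing
    log_likelihood: float
    regularized: bool = False
    feature_names: tuple[str, ...] = ANNOTATION_NAMES

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.thresholds) > 0):
            raise ValueError("thresholds must be strictly increasing")

    def save(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["parameter", "value"])
            for name, b in zip(self.feature_names, self.beta):
                w.writerow([f"beta_{name}", f"{b:.10g}"])
            for k, z in enumerate(self.thresholds):
                w.writerow([f"zeta_{k}", f"{z:.10g}"])
            w.writerow(["log_likelihood", f"{self.log_likelihood:.10g}"])
            w.writerow(["regularized", int(self.regularized)])

    @classmethod
    def load(cls, path: str | Path) -> "BaselineModel":
        rows: dict[str, str] = {}
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for row in reader:
                rows[row["parameter"]] = row["value"]
        names = tuple(k.removeprefix("beta_") for k in rows
                      if k.startswith("beta_"))
        beta = np.array([float(rows[f"beta_{n}"]) for n in names])
        zetas = sorted(k for k in rows if k.startswith("zeta_"))
        return cls(beta=beta,
                   thresholds=np.array([float(rows[z]) for z in zetas]),
                   log_likelihood=float(rows["log_likelihood"]),
                   regularized=bool(int(rows["regularized"])),
                   feature_names=names)


def _unpack(params: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    beta = params[:p]
    z0, d = params[p], params[p + 1]
    return beta, np.array([z0, z0 + np.exp(d)])


def _nll(params: np.ndarray, x: np.ndarray, y: np.ndarray, alpha: float
         ) -> float:
    p = x.shape[1]
    beta, zetas = _unpack(params, p)
    eta = x @ beta
    u0 = expit(zetas[0] - eta)
    u1 = expit(zetas[1] - eta)
    prob = np.where(y == 0, u0, np.where(y == 1, u1 - u0, 1.0 - u1))
    prob = np.clip(prob, 1e-12, None)
    return -float(np.sum(np.log(prob))) + 0.5 * alpha * float(beta @ beta)


def fit_ordinal_logistic(
    counts: np.ndarray,
    labels: Sequence[Function] | np.ndarray,
    tol: float = 1e-8,
    separation_norm: float = 10.0,
    ridge_alpha: float = 1.0,
) -> BaselineModel:
    """Maximum-likelihood fit of the proportional-odds model.

    ``counts`` is (n, 9) non-negative annotation counts; ``labels`` are
    curated function labels (or integer ranks 0/1/2). If the unpenalized
    optimum drifts to unbounded coefficients (complete separation), the
    model is refit with an L2 penalty of ``ridge_alpha`` on the slopes and
    flagged ``regularized=True``.
    """
    x = np.asarray(counts, dtype=float)
    if x.ndim != 2:
        raise ValueError("counts must be a 2-D array")
    if np.any(x < 0):
        raise ValueError("annotation counts must be non-negative")
    y = np.array([lab.rank if isinstance(lab, Function) else int(lab)
                  for lab in labels])
    if set(np.unique(y)) - {0, 1, 2}:
        raise ValueError("labels must be none/decreased/normal")
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two classes to fit")
    if len(y) != len(x):
        raise ValueError("counts and labels length mismatch")

    n, p = x.shape
    # center features for conditioning; fold the shift back into thresholds
    mu = x.mean(axis=0)
    xc = x - mu

    def solve(alpha: float):
        x0 = np.zeros(p + 2)
        x0[p + 1] = 0.0  # gap exp(0) = 1
        res = minimize(_nll, x0, args=(xc, y, alpha), method="BFGS",
                       options={"gtol": tol, "maxiter": 2000})
        return res

    res = solve(0.0)
    beta, zetas = _unpack(res.x, p)
    regularized = False
    if (not np.all(np.isfinite(beta))) or \
            float(np.linalg.norm(beta)) > separation_norm:
        res = solve(ridge_alpha)
        beta, zetas = _unpack(res.x, p)
        regularized = True

    loglik = -_nll(res.x, xc, y, 0.0)
    # undo feature centering: logit P(Y<=k) = (zeta_k + mu.beta) - x.beta
    return BaselineModel(beta=beta, thresholds=zetas + mu @ beta,
                         log_likelihood=loglik, regularized=regularized)


def predict_ordinal(model: BaselineModel, counts: np.ndarray
                    ) -> tuple[np.ndarray, Function | list[Function]]:
    """Class probabilities and argmax label(s) for count vector(s).

    Probabilities are ordered (none, decreased, normal) and sum to 1.
    """
    x = np.asarray(counts, dtype=float)
    single = x.ndim == 1
    if single:
        x = x[None, :]
    if x.shape[1] != len(model.beta):
        raise ValueError(
            f"expected {len(model.beta)} features, got {x.shape[1]}")
    eta = x @ model.beta
    u0 = expit(model.thresholds[0] - eta)
    u1 = expit(model.thresholds[1] - eta)
    probs = np.stack([u0, u1 - u0, 1.0 - u1], axis=1)
    labels = [_RANK_TO_FUNCTION[int(k)] for k in probs.argmax(axis=1)]
    if single:
        return probs[0], labels[0]
    return probs, labels
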