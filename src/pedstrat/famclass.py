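"""Family-membership classification from PC scores by linear discriminant
analysis, and the accuracy-versus-number-of-PCs report.

The LDA is the classical Gaussian equal-covariance formulation: class means,
a pooled within-class covariance (ridge-regularized when singular, which
happens once the feature count approaches the within-class degrees of
freedom), and class priors.  Prediction is the arg-max of the log-posterior;
the default evaluation is resubstitution — the classifier is scored on the
individuals it was fitted on — because the question asked of it is how much
family structure the PCs encode, not out-of-sample generalization.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .genoio import Pedigree
from .pca import PCAResult

__all__ = [
    "LDAModel",
    "ClassificationReport",
    "fit_lda",
    "classify",
    "accuracy_by_k",
    "DEFAULT_K_GRID",
]

log = logging.getLogger(__name__)

#: the PC-count grid reported in the accuracy table
DEFAULT_K_GRID = (1, 20, 40, 60, 80, 100, 120, 140, 160, 180, 200)


@dataclass
class LDAModel:
    classes: list[str]           # sorted class labels
    means: np.ndarray            # (C, k)
    pooled_cov: np.ndarray       # (k, k), after any regularization
    priors: np.ndarray           # (C,), sums to 1
    ridge_used: float = 0.0

    @property
    def n_features(self) -> int:
        return self.means.shape[1]


def fit_lda(
    scores: np.ndarray,
    labels: np.ndarray | pd.Series | list,
    priors: str = "empirical",
    ridge_eps: float = 1e-8,
) -> LDAModel:
    """Fit equal-covariance Gaussian LDA.

    ``priors``: "empirical" (class-size proportions) or "uniform".  A
    singular pooled covariance is ridge-regularized by eps·trace/k (escalated
    tenfold until the Cholesky factorization succeeds) with a warning.
    """
    X = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("scores must be (n, k) aligned with labels")
    classes = sorted(pd.unique(y).tolist())
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    n, k = X.shape
    C = len(classes)

    means = np.empty((C, k))
    counts = np.empty(C)
    S = np.zeros((k, k))
    for c, label in enumerate(classes):
        Xc = X[y == label]
        counts[c] = len(Xc)
        means[c] = Xc.mean(axis=0)
        R = Xc - means[c]
        S += R.T @ R
    S /= max(n - C, 1)

    if priors == "empirical":
        pri = counts / n
    elif priors == "uniform":
        pri = np.full(C, 1.0 / C)
    else:
        raise ValueError(f"unknown priors {priors!r}")

    ridge = 0.0
    eps = ridge_eps
    base = np.trace(S) / k if k else 1.0
    while True:
        try:
            scipy.linalg.cho_factor(S + ridge * np.eye(k), lower=True)
            break
        except np.linalg.LinAlgError:
            ridge = eps * base if ridge == 0.0 else ridge * 10.0
            eps *= 10.0
            if ridge > base:
                raise
    if ridge > 0.0:
        warnings.warn(
            f"singular pooled covariance: ridge {ridge:.3e} added", stacklevel=2
        )
        S = S + ridge * np.eye(k)
    return LDAModel(classes, means, S, pri, ridge)


def _log_posterior(model: LDAModel, X: np.ndarray) -> np.ndarray:
    """(n, C) matrix of Gaussian equal-covariance log-posteriors up to an
    additive per-row constant."""
    cho = scipy.linalg.cho_factor(model.pooled_cov, lower=True)
    A = scipy.linalg.cho_solve(cho, model.means.T)  # (k, C) = S^-1 M'
    lin = X @ A                                      # x' S^-1 mu_c
    quad = 0.5 * np.sum(model.means.T * A, axis=0)   # 1/2 mu_c' S^-1 mu_c
    return lin - quad + np.log(model.priors)


def classify(model: LDAModel, scores: np.ndarray) -> np.ndarray:
    """Predicted class per row: arg-max log-posterior, ties broken in sorted
    class-label order (and logged)."""
    X = np.asarray(scores, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature count {X.shape[1]} does not match model ({model.n_features})"
        )
    lp = _log_posterior(model, X)
    best = lp.argmax(axis=1)  # argmax returns the first (lowest label) on ties
    ties = (lp == lp.max(axis=1, keepdims=True)).sum(axis=1) > 1
    if ties.any():
        log.info("%d tied posteriors broken by class order", int(ties.sum()))
    return np.asarray(model.classes, dtype=object)[best]


@dataclass
class ClassificationReport:
    """Per-family correct counts for each tested number of PCs.

    ``counts`` rows are families (index fid), one column per k; ``sizes``
    gives family sizes; ``overall`` the total-correct / total-individuals
    accuracy per k."""

    counts: pd.DataFrame
    sizes: pd.Series
    overall: pd.Series

    def to_table(self) -> pd.DataFrame:
        tab = self.counts.copy()
        tab.insert(0, "n_members", self.sizes)
        overall = pd.DataFrame(
            [["overall_accuracy", *self.overall.round(4).tolist()]],
            columns=["n_members", *self.counts.columns],
            index=pd.Index(["-"], name="fid"),
        )
        return pd.concat([tab, overall])

    def write(self, path, seed: int | None = None) -> None:
        with open(path, "w") as fh:
            if seed is not None:
                fh.write(f"# seed={seed}\n")
            self.to_table().to_csv(fh, sep="\t")


def accuracy_by_k(
    result: PCAResult,
    pedigree: Pedigree,
    k_list: tuple[int, ...] = DEFAULT_K_GRID,
    priors: str = "empirical",
    leave_one_out: bool = False,
) -> ClassificationReport:
    """Fit LDA on the first k PCs for each k in ``k_list`` and tabulate how
    many members of each family are assigned back to it (resubstitution by
    default; ``leave_one_out`` refits without each individual in turn)."""
    fid_of = pedigree.family_of()
    y = fid_of.loc[result.sample_ids["iid"]].to_numpy()
    sizes = pd.Series(y).value_counts().sort_index()
    sizes.index.name = "fid"

    usable = [k for k in k_list if k <= result.n_components]
    skipped = [k for k in k_list if k > result.n_components]
    if skipped:
        log.warning("skipping k values beyond computed components: %s", skipped)

    counts = {}
    overall = {}
    for k in usable:
        X = result.scores[:, :k]
        if len(sizes) == 1:
            # degenerate single-family case: everything is assigned to it
            counts[k] = sizes.copy()
            overall[k] = 1.0
            continue
        if leave_one_out:
            pred = np.empty(len(y), dtype=object)
            for i in range(len(y)):
                mask = np.ones(len(y), bool)
                mask[i] = False
                m = fit_lda(X[mask], y[mask], priors=priors)
                pred[i] = classify(m, X[i])[0]
        else:
            model = fit_lda(X, y, priors=priors)
            pred = classify(model, X)
        correct = pd.Series(y[pred == y]).value_counts().reindex(sizes.index, fill_value=0)
        counts[k] = correct
        overall[k] = correct.sum() / sizes.sum()

    return ClassificationReport(
        counts=pd.DataFrame(counts),
        sizes=sizes,
        overall=pd.Series(overall),
    )
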