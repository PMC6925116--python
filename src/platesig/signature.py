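"""The combined gene-signature score: multivariable logistic fit on the
selected genes, sample scoring, ROC/AUC, and frozen-coefficient external
validation.

The combined score is the linear predictor ``intercept + sum_g coef_g *
x[s, g]``; the logistic link is monotone, so the AUC is identical whether
computed on scores or fitted probabilities and no probability cutoff is
ever applied.  With a handful of strong predictors and a few dozen
samples, quasi-separation of the multivariable fit is expected: the fit
stops at a finite-precision estimate and flags it, and the score remains a
valid ranking (AUC depends only on ordering).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_curve as _sk_roc_curve

from .datatypes import CohortDesign, validate_expression
from .logistic import fit_logistic


@dataclass
class SignatureModel:
    """A frozen logistic score: intercept plus per-gene log-odds coefficients.

    ``coefficients`` maps gene id to log-odds per unit log2 expression, in
    the exact gene order used at fit time.  ``metadata`` carries training
    provenance (thresholds, seed, gene counts, matrix fingerprint).
    External validation applies this object with no refitting.
    """

    intercept: float
    coefficients: dict
    metadata: dict = field(default_factory=dict)
    converged: bool = True
    separation_flag: bool = False
    collinearity_flag: bool = False

    def __post_init__(self) -> None:
        if not self.coefficients:
            raise ValueError("no genes selected: signature coefficient set is empty")

    @property
    def gene_ids(self) -> list:
        return list(self.coefficients)

    def score(self, matrix: pd.DataFrame) -> np.ndarray:
        """Linear predictor per sample; every model gene must be present."""
        missing = [g for g in self.coefficients if g not in matrix.columns]
        if missing:
            raise ValueError(f"model gene {missing[0]!r} absent from matrix")
        coef = np.array([self.coefficients[g] for g in self.gene_ids])
        return self.intercept + matrix[self.gene_ids].to_numpy() @ coef


def fit_signature(
    matrix: pd.DataFrame, design: CohortDesign | np.ndarray, metadata: dict | None = None
) -> SignatureModel:
    """ML multivariable logistic fit of case status on the given genes.

    ``matrix`` must already be restricted to the selected genes.  Warns
    when samples do not comfortably exceed predictors; flags separation
    and collinearity instead of failing, because the linear predictor is
    still a usable ranking score.
    """
    validate_expression(matrix)
    if matrix.shape[1] == 0:
        raise ValueError("no genes selected")
    y = design.y(matrix.index) if isinstance(design, CohortDesign) else np.asarray(design)
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    n, k = matrix.shape
    if n <= k + 1:
        warnings.warn(
            f"{n} samples for {k} genes: fit is saturated or nearly so", stacklevel=2
        )
    X = np.column_stack([np.ones(n), matrix.to_numpy()])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn("collinear gene columns: coefficients are not unique", stacklevel=2)
    fit = fit_logistic(X, y)
    return SignatureModel(
        intercept=float(fit.beta[0]),
        coefficients={g: float(b) for g, b in zip(matrix.columns, fit.beta[1:])},
        metadata=dict(metadata or {}),
        converged=fit.converged,
        separation_flag=fit.separated,
        collinearity_flag=bool(fit.singular or np.linalg.matrix_rank(X) < X.shape[1]),
    )


def score_samples(model: SignatureModel, matrix: pd.DataFrame) -> np.ndarray:
    """Linear-predictor score for each sample of ``matrix``."""
    return model.score(matrix)


@dataclass
class RocResult:
    """AUC plus the full ROC curve.

    ``auc`` is the tie-corrected concordance probability: the fraction of
    (case, control) pairs where the case scores higher, counting ties as
    half.  ``curve`` lists (threshold, sensitivity, fpr) rows; in (FPR,
    sensitivity) space it runs from (0, 0) to (1, 1) and its trapezoidal
    area equals ``auc``.
    """

    auc: float
    curve: pd.DataFrame = field(repr=False)
    n_case: int
    n_control: int


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> RocResult:
    """ROC analysis of a score against binary labels (case = 1).

    The AUC is computed from midranks (Mann-Whitney form), which handles
    ties exactly: ``(#{case > control} + 0.5 * #{ties}) / (n1 * n0)``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if scores.shape[0] != labels.shape[0]:
        raise ValueError("scores and labels have different lengths")
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present to compute an ROC curve")
    ranks = rankdata(scores)  # midranks
    auc = (ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    fpr, tpr, thresholds = _sk_roc_curve(labels, scores, drop_intermediate=False)
    curve = pd.DataFrame({"threshold": thresholds, "sensitivity": tpr, "fpr": fpr})
    return RocResult(auc=float(auc), curve=curve, n_case=n1, n_control=n0)


def external_validate(
    model: SignatureModel, ext_matrix: pd.DataFrame, ext_design: CohortDesign
) -> RocResult:
    """Frozen-coefficient validation on an external cohort.

    The model is applied exactly as trained — gene-specific coefficients
    fixed at their training values, no refitting — and discrimination is
    summarized by the ROC against the external labels.
    """
    ext_design.check_matches(ext_matrix)
    scores = model.score(ext_matrix)
    return roc_auc(scores, ext_design.y(ext_matrix.index))


class SignatureClassifier(BaseEstimator, ClassifierMixin):
    """sklearn-compatible face of the signature model.

    ``fit(X, y)`` runs the same ML logistic fit as :func:`fit_signature`;
    ``decision_function`` returns the linear predictor, ``predict_proba``
    its logistic transform.  Mostly useful for composing with sklearn
    model-selection tooling; the pipeline itself uses
    :class:`SignatureModel` directly.
    """

    def __init__(self):
        pass

    def fit(self, X: pd.DataFrame, y) -> "SignatureClassifier":
        X = pd.DataFrame(X)
        self.model_ = fit_signature(X, np.asarray(y))
        self.classes_ = np.array([0, 1])
        self.intercept_ = np.array([self.model_.intercept])
        self.coef_ = np.array([[self.model_.coefficients[g] for g in self.model_.gene_ids]])
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def decision_function(self, X) -> np.ndarray:
        return self.model_.score(pd.DataFrame(X, columns=self.feature_names_in_))

    def predict_proba(self, X) -> np.ndarray:
        from scipy.special import expit

        p1 = expit(self.decision_function(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) > 0).astype(int)
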