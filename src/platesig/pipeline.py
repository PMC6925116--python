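"""The end-to-end discovery procedure as a single estimator.

One object implements filter -> screen -> select -> fit, and the bootstrap
re-runs *this same object* on every resample, so the internal validation
takes gene selection into account by construction: there is exactly one
code path for "the procedure", shared by the main analysis and every
bootstrap iteration.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .datatypes import CohortDesign
from .screen import LogisticGeneScreen, VarianceFilter
from .signature import SignatureModel, fit_signature, roc_auc


class DiscoveryPipeline(BaseEstimator):
    """Variance filter, univariate logistic screen, signature fit, in order.

    Parameters mirror the pipeline configuration: ``variance_fraction``
    (fraction of most-variable genes retained), ``alpha_report`` /
    ``alpha_select`` (reporting and selection p-value thresholds, strict
    ``<``), ``compute_ci`` (profile CIs are skipped inside the bootstrap
    for speed), ``apply_filter`` (callers that pass a pre-filtered matrix
    opt out).

    Fitted attributes: ``filter_``, ``screen_``, ``model_`` (``None`` when
    no gene passes selection — a *degenerate* fit), ``selected_genes_``,
    ``results_`` (the screening table), ``apparent_roc_`` (ROC of the
    fitted score on the training data itself).
    """

    def __init__(
        self,
        variance_fraction: float = 0.10,
        alpha_report: float = 0.05,
        alpha_select: float = 0.01,
        compute_ci: bool = True,
        apply_filter: bool = True,
    ):
        self.variance_fraction = variance_fraction
        self.alpha_report = alpha_report
        self.alpha_select = alpha_select
        self.compute_ci = compute_ci
        self.apply_filter = apply_filter

    def fit(self, X: pd.DataFrame, y: np.ndarray, metadata: dict | None = None):
        y = np.asarray(y, dtype=float)
        n_genes_in = X.shape[1]
        if self.apply_filter:
            self.filter_ = VarianceFilter(self.variance_fraction).fit(X)
            Xf = self.filter_.transform(X)
        else:
            self.filter_ = None
            Xf = X
        self.n_genes_in_ = n_genes_in
        self.n_genes_filtered_ = Xf.shape[1]
        self.screen_ = LogisticGeneScreen(
            self.alpha_report, self.alpha_select, compute_ci=self.compute_ci
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # empty selection handled below
            self.screen_.fit(Xf, y)
        self.results_ = self.screen_.results_
        self.selected_genes_ = self.screen_.selected_genes_
        if self.selected_genes_:
            meta = {
                "variance_fraction": self.variance_fraction,
                "alpha_report": self.alpha_report,
                "alpha_select": self.alpha_select,
                "n_genes_in": n_genes_in,
                "n_genes_filtered": self.n_genes_filtered_,
                "n_genes_selected": len(self.selected_genes_),
                **(metadata or {}),
            }
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # saturation is expected at n=38
                self.model_: SignatureModel | None = fit_signature(
                    Xf[self.selected_genes_], y, metadata=meta
                )
            self.apparent_roc_ = roc_auc(self.model_.score(Xf), y)
        else:
            self.model_ = None
            self.apparent_roc_ = None
        return self

    @property
    def degenerate_(self) -> bool:
        return self.model_ is None

    def score_samples(self, X: pd.DataFrame) -> np.ndarray:
        if self.model_ is None:
            raise ValueError("degenerate fit: no gene passed selection, no score exists")
        return self.model_.score(X)


def run_discovery(
    matrix: pd.DataFrame,
    design: CohortDesign,
    variance_fraction: float = 0.10,
    alpha_report: float = 0.05,
    alpha_select: float = 0.01,
    compute_ci: bool = True,
    metadata: dict | None = None,
) -> DiscoveryPipeline:
    """Run the full discovery procedure on a cohort."""
    design.check_matches(matrix)
    pipe = DiscoveryPipeline(variance_fraction, alpha_report, alpha_select, compute_ci)
    return pipe.fit(matrix, design.y(matrix.index), metadata=metadata)
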