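"""Discovery-stage screening: variance-decile gene filtering, mass
univariate logistic regression, threshold selection, and covariate
association checks.

The screen deliberately mirrors a gene-by-gene simple-logistic design
(case status regressed on log2 expression, one gene at a time, selection
by an unadjusted p-value threshold) rather than moderated differential
expression practice.  A Benjamini-Hochberg q-value column is attached for
information only and never drives selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import CohortDesign, validate_expression
from .logistic import fit_logistic, lr_pvalue_slope, profile_ci_slope, wald_pvalues

SCREEN_COLUMNS = [
    "gene_id", "beta", "se", "or", "ci_low", "ci_high",
    "p", "p_lr", "bh_q", "converged", "separation_flag", "selected",
]


class VarianceFilter(BaseEstimator, TransformerMixin):
    """Keep the most variable fraction of genes.

    Retains the ``floor(fraction * n_genes)`` genes with the largest sample
    variance (ddof=1) computed across all samples, cases and controls
    pooled.  Ties are broken by gene id in lexicographic order so the
    selection is deterministic.  ``statistic='mad'`` substitutes the median
    absolute deviation as the dispersion measure.
    """

    def __init__(self, fraction: float = 0.10, statistic: str = "variance"):
        self.fraction = fraction
        self.statistic = statistic

    def fit(self, X: pd.DataFrame, y=None) -> "VarianceFilter":
        X = validate_expression(X)
        if not (0.0 < self.fraction <= 1.0):
            raise ValueError(f"fraction must be in (0, 1], got {self.fraction!r}")
        if X.shape[0] < 2:
            raise ValueError("need at least 2 samples to compute a variance")
        if self.statistic == "variance":
            disp = X.var(axis=0, ddof=1)
        elif self.statistic == "mad":
            disp = (X - X.median(axis=0)).abs().median(axis=0)
        else:
            raise ValueError(f"unknown dispersion statistic {self.statistic!r}")
        k = int(np.floor(self.fraction * X.shape[1]))
        if k == 0:
            raise ValueError(
                f"fraction {self.fraction} of {X.shape[1]} genes retains 0 genes"
            )
        order = sorted(X.columns, key=lambda g: (-disp[g], str(g)))
        keep = set(order[:k])
        self.dispersion_ = disp
        self.n_genes_in_ = X.shape[1]
        # original column order is preserved in the output
        self.selected_genes_ = [g for g in X.columns if g in keep]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        missing = [g for g in self.selected_genes_ if g not in X.columns]
        if missing:
            raise ValueError(f"gene {missing[0]!r} absent from matrix")
        return X[self.selected_genes_]


def variance_filter(
    matrix: pd.DataFrame, fraction: float, statistic: str = "variance"
) -> pd.DataFrame:
    """Functional form of :class:`VarianceFilter`."""
    return VarianceFilter(fraction, statistic).fit_transform(matrix)


@dataclass
class GeneScreenResult:
    """Per-gene simple logistic fit summary.

    ``beta`` is the log-odds ratio per unit log2 expression; ``or_`` its
    exponential; ``ci_low``/``ci_high`` bound the 95% profile-likelihood
    interval on the OR scale (possibly 0/inf under separation); ``p`` is
    the two-sided Wald p-value and ``p_lr`` the likelihood-ratio p-value.
    """

    gene_id: str
    beta: float
    se: float
    or_: float
    ci_low: float
    ci_high: float
    p: float
    p_lr: float
    converged: bool
    separation_flag: bool


def fit_gene_logistic(
    x: np.ndarray, y: np.ndarray, gene_id: str = "", compute_ci: bool = True
) -> GeneScreenResult:
    """Simple logistic regression of case status on one gene's expression.

    Separation or non-convergence is flagged, never raised: estimates at
    the stopping point are returned and the profile CI may have infinite
    bounds.  A constant ``x`` (slope unidentifiable) or single-class ``y``
    is a hard input error, distinct from separation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape[0] != y.shape[0]:
        raise ValueError("x and y have different lengths")
    if x.shape[0] < 4:
        raise ValueError("need at least 4 observations")
    if np.unique(y).size < 2:
        raise ValueError("y contains a single class")
    if np.ptp(x) == 0.0:
        raise ValueError(f"constant expression for gene {gene_id!r}: slope unidentifiable")

    X = np.column_stack([np.ones_like(x), x])
    fit = fit_logistic(X, y)
    beta = float(fit.beta[1])
    se = float(fit.se[1])
    p = float(wald_pvalues(fit)[1])
    p_lr = lr_pvalue_slope(x, y, fit)
    if compute_ci:
        lo, hi = profile_ci_slope(x, y, beta, fit.loglik)
    else:
        lo, hi = np.nan, np.nan
    return GeneScreenResult(
        gene_id=gene_id,
        beta=beta,
        se=se,
        or_=float(np.exp(beta)),
        ci_low=float(np.exp(lo)),
        ci_high=float(np.exp(hi)),
        p=p,
        p_lr=p_lr,
        converged=fit.converged,
        separation_flag=fit.separated,
    )


def select_by_pvalue(pvalues: pd.Series, alpha: float) -> list:
    """Gene ids with ``p < alpha`` (strict), in ascending-p order.

    This is the selection rule of the screen, exposed on its own so it can
    be applied to any p-value table.  Ties in p break by gene id.
    """
    s = pvalues[pvalues < alpha]
    return s.sort_index(kind="mergesort").sort_values(kind="mergesort").index.tolist()


class LogisticGeneScreen(BaseEstimator, TransformerMixin):
    """Mass univariate logistic screen with threshold selection.

    Fits one simple logistic regression per gene, reports every gene with
    Wald ``p < alpha_report`` and selects every gene with ``p <
    alpha_select`` (strict inequalities, no multiplicity adjustment in the
    selection path).  ``transform`` restricts a matrix to the selected
    genes, so the screen composes as an sklearn feature selector.
    """

    def __init__(
        self,
        alpha_report: float = 0.05,
        alpha_select: float = 0.01,
        compute_ci: bool = True,
    ):
        self.alpha_report = alpha_report
        self.alpha_select = alpha_select
        self.compute_ci = compute_ci

    def fit(self, X: pd.DataFrame, y: np.ndarray) -> "LogisticGeneScreen":
        X = validate_expression(X)
        if self.alpha_select > self.alpha_report:
            raise ValueError("alpha_select must be <= alpha_report")
        y = np.asarray(y, dtype=float)
        rows, errors = [], {}
        for gene in X.columns:
            try:
                r = fit_gene_logistic(
                    X[gene].to_numpy(), y, gene_id=gene, compute_ci=self.compute_ci
                )
            except ValueError as exc:  # per-gene failures are recorded, not fatal
                errors[gene] = str(exc)
                continue
            rows.append(r)
        table = pd.DataFrame(
            {
                "gene_id": [r.gene_id for r in rows],
                "beta": [r.beta for r in rows],
                "se": [r.se for r in rows],
                "or": [r.or_ for r in rows],
                "ci_low": [r.ci_low for r in rows],
                "ci_high": [r.ci_high for r in rows],
                "p": [r.p for r in rows],
                "p_lr": [r.p_lr for r in rows],
                "converged": [r.converged for r in rows],
                "separation_flag": [r.separation_flag for r in rows],
            }
        )
        if len(table):
            table["bh_q"] = stats.false_discovery_control(table["p"], method="bh")
            table["selected"] = table["p"] < self.alpha_select
            table = table.sort_values(
                ["p", "gene_id"], kind="mergesort", ignore_index=True
            )
        else:
            table["bh_q"] = pd.Series(dtype=float)
            table["selected"] = pd.Series(dtype=bool)
        table = table[SCREEN_COLUMNS]
        self.results_ = table
        self.errors_ = errors
        pseries = table.set_index("gene_id")["p"]
        self.reported_genes_ = select_by_pvalue(pseries, self.alpha_report)
        self.selected_genes_ = select_by_pvalue(pseries, self.alpha_select)
        if not self.selected_genes_:
            warnings.warn(
                f"no gene passed the selection threshold p < {self.alpha_select}",
                stacklevel=2,
            )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        missing = [g for g in self.selected_genes_ if g not in X.columns]
        if missing:
            raise ValueError(f"gene {missing[0]!r} absent from matrix")
        return X[self.selected_genes_]


def screen_all(
    matrix: pd.DataFrame,
    design: CohortDesign,
    alpha_report: float = 0.05,
    alpha_select: float = 0.01,
    compute_ci: bool = True,
) -> tuple[pd.DataFrame, list]:
    """Screen every gene; return (results sorted by p, selected gene list)."""
    design.check_matches(matrix)
    screen = LogisticGeneScreen(alpha_report, alpha_select, compute_ci)
    screen.fit(matrix, design.y(matrix.index))
    return screen.results_, screen.selected_genes_


@dataclass
class AssociationResult:
    """Spearman association between one gene's expression and a covariate."""

    variable: str
    rho: float
    p: float


def covariate_association(
    expr: np.ndarray, covariate: np.ndarray, variable: str = ""
) -> AssociationResult:
    """Spearman rank correlation (mid-rank ties) with two-sided p-value."""
    expr = np.asarray(expr, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    if expr.shape[0] != covariate.shape[0]:
        raise ValueError("expression and covariate have different lengths")
    if expr.shape[0] < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(covariate) == 0.0 or np.ptp(expr) == 0.0:
        raise ValueError("constant vector: Spearman correlation undefined")
    rho, p = stats.spearmanr(expr, covariate)
    return AssociationResult(variable=variable, rho=float(rho), p=float(p))
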