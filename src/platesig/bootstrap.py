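"""Selection-aware bootstrap internal validation on matched pairs.

The resampling unit is the matched case-control pair: each iteration draws
pairs with replacement so every resample preserves the 1:1 matched
structure, then re-runs the *entire* discovery procedure (variance filter,
univariate screen, threshold selection, signature fit) on the resample.
Because feature selection is repeated inside every iteration, the
resulting AUC distribution reflects the optimism of the whole procedure,
not just of the final fit — the difference between an apparent AUC near 1
and an honest one.

Two summaries are offered:

* ``percentile`` (default): the empirical mean and 2.5/97.5 percentiles of
  the per-iteration *apparent* AUCs (each refit model evaluated on its own
  bootstrap sample).
* ``optimism``: Harrell-style correction — each iteration also evaluates
  its refit model on the original data; the mean of (apparent − original)
  is the optimism, subtracted from the full-data apparent AUC.

Iterations where no gene passes selection are *degenerate*: they record
the no-information AUC 0.5 (dropping them would bias the interval upward)
and are counted.  Per-iteration seeds are derived from the master seed by
a counter scheme, so results do not depend on execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import CohortDesign
from .pipeline import DiscoveryPipeline
from .signature import roc_auc

_TAG_RESAMPLE = 21


@dataclass
class BootstrapReport:
    """Summary of a selection-aware bootstrap run."""

    B: int
    auc_samples: np.ndarray = field(repr=False)
    mean_auc: float
    ci95: tuple
    n_degenerate: int
    mode: str
    seed: int
    apparent_auc: float              # full-data apparent AUC of the main fit
    optimism_corrected_auc: float | None = None
    iterations: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if len(self.auc_samples) != self.B:
            raise ValueError("auc_samples length must equal B")
        if self.n_degenerate > self.B:
            raise ValueError("n_degenerate cannot exceed B")


def resample_pairs(
    design: CohortDesign, seed: int | np.random.Generator
) -> tuple[CohortDesign, list]:
    """Draw pairs with replacement, preserving the matched structure.

    Returns the resampled design plus the list of source sample ids (the
    rows of the original matrix to take, in order).  Each drawn pair
    contributes both its case and its control; repeated draws get fresh
    unique sample and pair labels so the design invariants keep holding.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(np.random.SeedSequence([int(seed), _TAG_RESAMPLE]))
    )
    pair_ids = design.pair_ids
    members = {pid: design.members(pid) for pid in pair_ids}
    draws = rng.integers(0, len(pair_ids), size=len(pair_ids))
    records, source_ids = [], []
    for i, k in enumerate(draws):
        pid = pair_ids[k]
        case_id, control_id = members[pid]
        new_pid = f"b{i:03d}.{pid}"
        records.append((f"b{i:03d}.{case_id}", "case", new_pid))
        records.append((f"b{i:03d}.{control_id}", "control", new_pid))
        source_ids += [case_id, control_id]
    return CohortDesign.from_records(records), source_ids


def take_resample(
    matrix: pd.DataFrame, design: CohortDesign, source_ids: list
) -> pd.DataFrame:
    """Materialize the expression rows of a resample under its new labels."""
    out = matrix.loc[source_ids]
    out.index = design.sample_ids
    return out


def bootstrap_validate(
    matrix: pd.DataFrame,
    design: CohortDesign,
    B: int = 30_000,
    seed: int = 0,
    mode: str = "percentile",
    variance_fraction: float = 0.10,
    alpha_report: float = 0.05,
    alpha_select: float = 0.01,
    refilter: bool = True,
    keep_iterations: bool = True,
) -> BootstrapReport:
    """Selection-aware pair-bootstrap validation of the discovery procedure.

    ``refilter`` controls whether the variance filter is re-run inside each
    iteration (the faithful re-run of the procedure) or the caller's
    already-filtered gene set is screened as-is.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if mode not in ("percentile", "optimism"):
        raise ValueError(f"unknown bootstrap mode {mode!r}")
    design.check_matches(matrix)

    def make_pipeline() -> DiscoveryPipeline:
        return DiscoveryPipeline(
            variance_fraction=variance_fraction,
            alpha_report=alpha_report,
            alpha_select=alpha_select,
            compute_ci=False,
            apply_filter=refilter,
        )

    # the main-path fit, needed for the apparent AUC baseline; CIs are not
    y_full = design.y(matrix.index)
    main = DiscoveryPipeline(
        variance_fraction, alpha_report, alpha_select,
        compute_ci=False, apply_filter=refilter,
    ).fit(matrix, y_full)
    apparent_full = main.apparent_roc_.auc if not main.degenerate_ else 0.5

    aucs = np.empty(B)
    optimism = np.empty(B) if mode == "optimism" else None
    n_selected = np.empty(B, dtype=int)
    degenerate = np.zeros(B, dtype=bool)
    n_failed = 0
    for b in range(B):
        it_seed = np.random.SeedSequence([int(seed), _TAG_RESAMPLE, b])
        rng = np.random.default_rng(it_seed)
        redesign, source_ids = resample_pairs(design, rng)
        rematrix = take_resample(matrix, redesign, source_ids)
        y_boot = redesign.y(rematrix.index)
        try:
            pipe = make_pipeline().fit(rematrix, y_boot)
        except Exception:  # fit failures are counted, never fatal
            n_failed += 1
            pipe = None
        if pipe is None or pipe.degenerate_:
            aucs[b] = 0.5
            degenerate[b] = True
            n_selected[b] = 0
            if optimism is not None:
                optimism[b] = 0.0
            continue
        n_selected[b] = len(pipe.selected_genes_)
        apparent_b = roc_auc(pipe.score_samples(rematrix), y_boot).auc
        aucs[b] = apparent_b
        if optimism is not None:
            original_b = roc_auc(pipe.score_samples(matrix), y_full).auc
            optimism[b] = apparent_b - original_b

    ci95 = (float(np.percentile(aucs, 2.5)), float(np.percentile(aucs, 97.5)))
    report = BootstrapReport(
        B=B,
        auc_samples=aucs,
        mean_auc=float(aucs.mean()),
        ci95=ci95,
        n_degenerate=int(degenerate.sum()),
        mode=mode,
        seed=int(seed),
        apparent_auc=float(apparent_full),
        optimism_corrected_auc=(
            float(apparent_full - optimism.mean()) if optimism is not None else None
        ),
        iterations=(
            pd.DataFrame(
                {
                    "iteration": np.arange(B),
                    "n_selected": n_selected,
                    "auc": aucs,
                    "degenerate": degenerate,
                }
            )
            if keep_iterations
            else None
        ),
    )
    return report
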