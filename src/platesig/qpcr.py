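"""GeNorm-style qPCR processing for the signature-confirmation assays.

Triplicate Cq values are averaged, converted to efficiency-based relative
quantities against the highest-expressing sample (the calibrator: the
minimum mean Cq per gene), and rescaled by a per-sample normalization
factor, the geometric mean of the housekeeping-gene quantities.  The
housekeeping set's quality is reported through the GeNorm stability value
M: for gene j, the mean over partners k of the standard deviation across
samples of log2(q_j / q_k) — stable reference genes keep constant ratios
to each other, giving small M.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .syndata import QpcrBatch

REPLICATE_SD_FLAG = 0.5  # cycles; dispersion above this is flagged, never dropped


def aggregate_cq(triplicate) -> tuple[float, bool]:
    """Arithmetic mean of a Cq triplicate, with a dispersion flag.

    The flag is raised when the replicate SD (ddof=1) exceeds 0.5 cycles;
    flagged values are reported, never auto-dropped.
    """
    t = np.asarray(triplicate, dtype=float)
    if t.shape != (3,):
        raise ValueError("a Cq triplicate must have exactly 3 replicates")
    if not np.isfinite(t).all():
        raise ValueError("non-finite Cq replicate")
    return float(t.mean()), bool(t.std(ddof=1) > REPLICATE_SD_FLAG)


def relative_quantity(mean_cq, efficiency: float) -> np.ndarray:
    """Efficiency-based relative quantities from mean Cq values, one gene.

    ``q[s] = E ** (min Cq - Cq[s])`` with the smallest mean Cq (the
    highest-expressing sample) as calibrator, so q lies in (0, 1] with the
    maximum exactly 1.  Adding any constant to every Cq leaves q unchanged.
    """
    cq = np.asarray(mean_cq, dtype=float)
    if cq.size == 0:
        raise ValueError("empty sample set")
    if not (1.0 < efficiency <= 2.0):
        raise ValueError(f"efficiency must be in (1, 2], got {efficiency!r}")
    return efficiency ** (cq.min() - cq)


def stability_m(quantities: pd.DataFrame, candidates=None) -> pd.Series:
    """GeNorm stability value M for each candidate reference gene.

    ``V_jk = SD_samples(log2(q_j / q_k))`` (ddof=1) and ``M_j = mean over
    k != j of V_jk``.  Lower is more stable.  M is invariant to rescaling
    any gene's quantities by a constant.
    """
    genes = list(candidates) if candidates is not None else list(quantities.columns)
    if len(genes) < 2:
        raise ValueError("need at least 2 candidate genes to compute M")
    q = quantities[genes].to_numpy(dtype=float)
    if q.shape[0] < 2:
        raise ValueError("need at least 2 samples to compute M")
    if not (q > 0).all():
        raise ValueError("all quantities must be positive")
    logq = np.log2(q)
    m = np.empty(len(genes))
    for j in range(len(genes)):
        ratios = logq[:, [j]] - logq  # samples x genes, column k = log2(qj/qk)
        v = ratios.std(axis=0, ddof=1)
        m[j] = np.delete(v, j).mean()
    return pd.Series(m, index=genes, name="M")


def rank_reference_genes(quantities: pd.DataFrame, candidates=None) -> pd.DataFrame:
    """Iterative GeNorm elimination: repeatedly drop the least stable gene.

    Returns one row per elimination round with the gene dropped and the M
    values at that round.  Provided for reference-set exploration; the
    default normalization keeps the configured housekeeping set fixed.
    """
    genes = list(candidates) if candidates is not None else list(quantities.columns)
    rounds = []
    while len(genes) > 2:
        m = stability_m(quantities, genes)
        worst = m.sort_values(kind="mergesort").index[-1]
        rounds.append({"dropped": worst, "M_dropped": float(m[worst]),
                       "remaining": tuple(g for g in genes if g != worst)})
        genes = [g for g in genes if g != worst]
    return pd.DataFrame(rounds)


@dataclass
class NormalizedQpcr:
    """Relative quantities after housekeeping normalization."""

    quantities: pd.DataFrame = field(repr=False)   # samples x genes, normalized
    raw_quantities: pd.DataFrame = field(repr=False)
    stability: pd.Series = field(repr=False)       # M per housekeeping gene
    normalization_factor: pd.Series = field(repr=False)  # NF per sample
    dispersion_flags: pd.DataFrame = field(repr=False)   # replicate SD > 0.5 cycles

    def __post_init__(self) -> None:
        if not (self.quantities.to_numpy() > 0).all():
            raise ValueError("normalized quantities must be positive")


def normalize(batch: QpcrBatch) -> NormalizedQpcr:
    """Full GeNorm-style rescaling of a qPCR batch.

    NF[s] is the geometric mean of the housekeeping-gene relative
    quantities of sample s; every gene's quantity in sample s is divided
    by NF[s].  A global per-sample loading effect (every raw quantity of
    one sample scaled by a constant) cancels exactly.
    """
    samples, genes = list(batch.sample_ids), list(batch.gene_ids)
    mean_cq = pd.DataFrame(index=samples, columns=genes, dtype=float)
    flags = pd.DataFrame(False, index=samples, columns=genes)
    for i, s in enumerate(samples):
        for j, g in enumerate(genes):
            mean_cq.loc[s, g], flags.loc[s, g] = aggregate_cq(batch.cq[i, j])

    raw_q = pd.DataFrame(
        {g: relative_quantity(mean_cq[g].to_numpy(), batch.efficiency[g]) for g in genes},
        index=samples,
    )
    hk = list(batch.housekeeping)
    nf = pd.Series(
        np.exp(np.log(raw_q[hk].to_numpy()).mean(axis=1)), index=samples, name="NF"
    )
    normalized = raw_q.div(nf, axis=0)
    stability = (
        stability_m(raw_q, hk)
        if len(hk) >= 2
        else pd.Series(dtype=float, name="M")
    )
    return NormalizedQpcr(
        quantities=normalized,
        raw_quantities=raw_q,
        stability=stability,
        normalization_factor=nf,
        dispersion_flags=flags,
    )
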