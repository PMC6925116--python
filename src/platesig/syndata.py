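"""Synthetic matched case-control cohorts and qPCR batches.

The generator implements the simplest model consistent with matched
log-scale microarray data: per-gene Gaussian noise on the log2 scale with
gene-specific baselines and SDs, an additive random shift shared by the two
members of a matched pair (which is what justifies resampling whole pairs
downstream), and additive case-minus-control shifts for a handful of signal
genes::

    x[s, g] = mu_g + delta_g * I(s is case) + u_pair(s) + e[s, g]

    mu_g    ~ Uniform(gene_baseline_mean_range)
    sigma_g ~ Uniform(gene_sd_range)
    u_pair  ~ Normal(0, pair_effect_sd^2)   shared within a pair
    e[s, g] ~ Normal(0, sigma_g^2)          independent

Defaults emulate the discovery design this package targets: 19 matched
case-control pairs (38 arrays) and five truly up-regulated genes on a null
background.  Seeding is substreamed per purpose and per gene, so enlarging
``n_genes`` appends new columns without perturbing the draws of existing
genes.

Everything here is a pure function of (spec, seed): identical inputs
reproduce identical output bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import CASE, CONTROL, CohortDesign, validate_expression

DEFAULT_N_PAIRS = 19
DEFAULT_N_GENES = 1000

# substream tags: gene-level parameter draws must coincide between the
# discovery and external generators, the noise draws must not
_TAG_GENE_PARAMS = 11
_TAG_PAIR_EFFECT = 12
_TAG_NOISE_DISCOVERY = 13
_TAG_PAIR_EFFECT_EXTERNAL = 14
_TAG_NOISE_EXTERNAL = 15
_TAG_QPCR = 16


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one synthetic matched cohort (all on the log2 scale)."""

    n_pairs: int = DEFAULT_N_PAIRS
    n_genes: int = DEFAULT_N_GENES
    signal: tuple = ()  # ((gene index, case-minus-control delta), ...)
    gene_baseline_mean_range: tuple = (4.0, 12.0)
    gene_sd_range: tuple = (0.3, 1.0)
    pair_effect_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not (isinstance(self.n_pairs, (int, np.integer)) and self.n_pairs >= 1):
            raise ValueError(f"n_pairs must be a positive integer, got {self.n_pairs!r}")
        if not (isinstance(self.n_genes, (int, np.integer)) and self.n_genes >= 1):
            raise ValueError(f"n_genes must be a positive integer, got {self.n_genes!r}")
        object.__setattr__(self, "signal", tuple((int(g), float(d)) for g, d in self.signal))
        idx = [g for g, _ in self.signal]
        if len(set(idx)) != len(idx):
            raise ValueError("signal gene indices must be unique")
        if any(g < 0 or g >= self.n_genes for g in idx):
            raise ValueError("signal gene index out of range for n_genes")
        if not all(np.isfinite(d) for _, d in self.signal):
            raise ValueError("signal deltas must be finite")
        lo, hi = self.gene_baseline_mean_range
        if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
            raise ValueError(f"gene_baseline_mean_range invalid: {self.gene_baseline_mean_range!r}")
        lo, hi = self.gene_sd_range
        if not (np.isfinite(lo) and np.isfinite(hi) and 0 < lo <= hi):
            raise ValueError(f"gene_sd_range must be positive: {self.gene_sd_range!r}")
        if not (np.isfinite(self.pair_effect_sd) and self.pair_effect_sd >= 0):
            raise ValueError(f"pair_effect_sd must be non-negative, got {self.pair_effect_sd!r}")

    @property
    def deltas(self) -> np.ndarray:
        d = np.zeros(self.n_genes)
        for g, delta in self.signal:
            d[g] = delta
        return d


def _rng(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, tags)]))


def _gene_ids(n_genes: int) -> list[str]:
    width = max(4, len(str(n_genes - 1)))
    return [f"g{i:0{width}d}" for i in range(n_genes)]


def _gene_params(spec: SimulationSpec) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene (mu, sigma); one substream per gene keeps the prefix stable."""
    mu = np.empty(spec.n_genes)
    sigma = np.empty(spec.n_genes)
    mlo, mhi = spec.gene_baseline_mean_range
    slo, shi = spec.gene_sd_range
    for g in range(spec.n_genes):
        r = _rng(spec.seed, _TAG_GENE_PARAMS, g)
        mu[g] = r.uniform(mlo, mhi)
        sigma[g] = r.uniform(slo, shi)
    return mu, sigma


def _assemble(
    spec: SimulationSpec,
    n_pairs: int,
    pair_tag: int,
    noise_tag: int,
    pair_prefix: str,
) -> tuple[pd.DataFrame, CohortDesign]:
    mu, sigma = _gene_params(spec)
    deltas = spec.deltas
    n_samples = 2 * n_pairs

    u = _rng(spec.seed, pair_tag).normal(0.0, spec.pair_effect_sd, size=n_pairs)

    width = max(2, len(str(n_pairs)))
    pair_ids = [f"{pair_prefix}{i + 1:0{width}d}" for i in range(n_pairs)]
    sample_ids, groups, pair_col = [], [], []
    for pid in pair_ids:
        sample_ids += [f"{pid}_case", f"{pid}_ctrl"]
        groups += [CASE, CONTROL]
        pair_col += [pid, pid]
    is_case = np.array([g == CASE for g in groups], dtype=float)
    u_sample = np.repeat(u, 2)

    values = np.empty((n_samples, spec.n_genes))
    for g in range(spec.n_genes):
        e = _rng(spec.seed, noise_tag, g).normal(0.0, sigma[g], size=n_samples)
        values[:, g] = mu[g] + deltas[g] * is_case + u_sample + e

    matrix = pd.DataFrame(values, index=sample_ids, columns=_gene_ids(spec.n_genes))
    design = CohortDesign(
        pd.DataFrame({"group": groups, "pair_id": pair_col}, index=pd.Index(sample_ids))
    )
    validate_expression(matrix)
    return matrix, design


def generate_cohort(spec: SimulationSpec) -> tuple[pd.DataFrame, CohortDesign]:
    """Synthetic discovery cohort of ``spec.n_pairs`` matched pairs."""
    return _assemble(spec, spec.n_pairs, _TAG_PAIR_EFFECT, _TAG_NOISE_DISCOVERY, "P")


def generate_external_cohort(
    spec: SimulationSpec, n_per_group: int
) -> tuple[pd.DataFrame, CohortDesign]:
    """Synthetic external validation cohort (cases vs disease-free controls).

    Cases carry the same signal deltas as the discovery generator; external
    controls carry none (they stand in for a comparator population sharing
    the background profile, as stable-atherosclerosis patients do for
    healthy donors).  Gene identities, baselines and SDs coincide with the
    discovery cohort for the same spec, so a frozen discovery model can be
    applied directly.  Samples are paired 1:1 for interface uniformity only.
    """
    if not (isinstance(n_per_group, (int, np.integer)) and n_per_group >= 1):
        raise ValueError(f"n_per_group must be a positive integer, got {n_per_group!r}")
    return _assemble(
        spec, int(n_per_group), _TAG_PAIR_EFFECT_EXTERNAL, _TAG_NOISE_EXTERNAL, "E"
    )


# ---------------------------------------------------------------------------
# qPCR

@dataclass(frozen=True)
class QpcrBatch:
    """Cq triplicates for a panel of genes, plus amplification efficiencies.

    ``cq`` has shape (n_samples, n_genes, 3); ``efficiency`` maps gene id to
    its per-cycle amplification factor in (1, 2].
    """

    sample_ids: tuple
    gene_ids: tuple
    cq: np.ndarray = field(repr=False)
    efficiency: dict
    housekeeping: tuple

    def __post_init__(self) -> None:
        cq = np.asarray(self.cq, dtype=float)
        object.__setattr__(self, "cq", cq)
        if cq.shape != (len(self.sample_ids), len(self.gene_ids), 3):
            raise ValueError("cq array must have shape (n_samples, n_genes, 3)")
        if not np.isfinite(cq).all():
            raise ValueError("non-finite Cq replicate")
        if not self.housekeeping:
            raise ValueError("housekeeping gene set must be nonempty")
        missing = set(self.housekeeping) - set(self.gene_ids)
        if missing:
            raise ValueError(f"housekeeping gene {sorted(missing)[0]!r} not in gene panel")
        for gene in self.gene_ids:
            e = self.efficiency.get(gene)
            if e is None or not (1.0 < e <= 2.0):
                raise ValueError(f"efficiency for {gene!r} must be in (1, 2], got {e!r}")

    def mean_cq(self) -> pd.DataFrame:
        """Triplicate means, samples x genes."""
        return pd.DataFrame(
            self.cq.mean(axis=2), index=list(self.sample_ids), columns=list(self.gene_ids)
        )


def generate_qpcr(
    n_samples: int,
    gene_specs: list[tuple],
    housekeeping_ids: list[str],
    cq_noise_sd: float = 0.15,
    seed: int = 0,
    baseline_cq: float = 35.0,
) -> QpcrBatch:
    """Simulate triplicate Cq values for ``n_samples`` samples.

    ``gene_specs`` is a list of ``(gene_id, log2_abundance, efficiency)``
    where ``log2_abundance`` is a scalar (sample-constant, as for a
    housekeeping gene) or a length-``n_samples`` vector.  Each replicate is

        Cq = baseline_cq - log_E(2 ** log2_abundance) + Normal(0, cq_noise_sd^2)

    so with efficiency 2 a doubling of abundance lowers Cq by exactly one
    cycle.
    """
    if not (isinstance(n_samples, (int, np.integer)) and n_samples >= 1):
        raise ValueError(f"n_samples must be a positive integer, got {n_samples!r}")
    if not (np.isfinite(cq_noise_sd) and cq_noise_sd >= 0):
        raise ValueError(f"cq_noise_sd must be non-negative, got {cq_noise_sd!r}")

    gene_ids, efficiency = [], {}
    abundances = []
    for gene_id, abundance, eff in gene_specs:
        if not (1.0 < eff <= 2.0):
            raise ValueError(f"efficiency for {gene_id!r} must be in (1, 2], got {eff!r}")
        vec = np.broadcast_to(np.asarray(abundance, dtype=float), (n_samples,)).copy()
        if not np.isfinite(vec).all():
            raise ValueError(f"non-finite abundance for {gene_id!r}")
        gene_ids.append(gene_id)
        efficiency[gene_id] = float(eff)
        abundances.append(vec)

    missing = set(housekeeping_ids) - set(gene_ids)
    if missing:
        raise ValueError(f"housekeeping gene {sorted(missing)[0]!r} not in gene_specs")

    rng = _rng(seed, _TAG_QPCR)
    cq = np.empty((n_samples, len(gene_ids), 3))
    for j, (gene_id, vec) in enumerate(zip(gene_ids, abundances)):
        log_e = np.log(efficiency[gene_id])
        # log_E(2^a) = a * ln2 / ln E
        expected = baseline_cq - vec * np.log(2.0) / log_e
        cq[:, j, :] = expected[:, None] + rng.normal(0.0, cq_noise_sd, size=(n_samples, 3))

    width = max(2, len(str(n_samples)))
    sample_ids = tuple(f"Q{i + 1:0{width}d}" for i in range(n_samples))
    return QpcrBatch(
        sample_ids=sample_ids,
        gene_ids=tuple(gene_ids),
        cq=cq,
        efficiency=efficiency,
        housekeeping=tuple(housekeeping_ids),
    )
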