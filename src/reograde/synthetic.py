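"""Synthetic grade cohorts with planted reversal orderings and survival.

The generator emulates the data-generating assumptions the ordering
method relies on, so every other module is testable without any cohort
download:

* two phenotype groups (pHG1 / pHG3) of configurable size;
* ``n_planted_pairs`` reversal gene pairs on disjoint genes: within
  each sample the pair shows its class-typical ordering with
  probability ``fidelity`` (independently across pairs and samples),
  the opposite ordering otherwise — the orientation is enforced
  exactly, so the per-pair correct-vote probability IS the configured
  fidelity and the closed-form majority-vote accuracy is exact;
* background genes with gene-specific log2 baselines and i.i.d. noise,
  carrying no class signal;
* optional per-sample strictly increasing distortions and additive
  batch shifts (rank-preserving nuisance, what the method must ignore);
* optional zero inflation on a linear scale (RNA-seq-like dropout);
* exponential survival whose hazard is multiplied by ``hazard_ratio``
  in the HG3 class, with independent exponential censoring calibrated
  so each sample is censored with probability ``censoring_rate``.

All randomness flows from the single ``seed`` through spawned
generators; the same config is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom

from .expr_io import ExpressionMatrix

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_grade_cohort",
    "apply_monotone_distortion",
    "expected_classifier_accuracy",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated cohort (log2 scale unless zero-inflated)."""

    n_genes: int = 520
    n_planted_pairs: int = 10
    n_hg1: int = 20
    n_hg3: int = 20
    fidelity: float = 1.0          # per-sample P(planted pair shows class direction)
    baseline_mean: float = 8.0     # log2 units
    baseline_sd: float = 2.0
    noise_sd: float = 0.5
    pair_separation: float = 1.0   # log2 offset between a planted pair's means
    monotone_distortion: bool = False
    batch_shift_sd: float = 0.0
    zero_inflation_rate: float = 0.0  # > 0 switches output to linear scale
    reuse_genes: bool = False      # allow planted pairs to share genes
    baseline_hazard: float = 0.1   # events per study time unit in pHG1
    hazard_ratio: float = 2.0      # pHG3 vs pHG1
    censoring_rate: float = 0.2
    horizon: float | None = None   # administrative censoring time
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.5 <= self.fidelity <= 1.0:
            raise ValueError("fidelity must lie in [0.5, 1]")
        if min(self.n_genes, self.n_planted_pairs, self.n_hg1, self.n_hg3) < 1:
            raise ValueError("counts must be positive")
        if not self.reuse_genes and 2 * self.n_planted_pairs > self.n_genes:
            raise ValueError(
                f"{self.n_planted_pairs} disjoint planted pairs need "
                f"{2 * self.n_planted_pairs} genes but n_genes={self.n_genes}"
            )
        for name in ("zero_inflation_rate", "censoring_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.baseline_hazard <= 0 or self.hazard_ratio <= 0:
            raise ValueError("hazards must be positive")


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth of a simulated cohort."""

    planted_pairs: tuple[tuple[str, str], ...]  # (high-in-HG1 gene, low-in-HG1 gene)
    true_class: pd.Series                       # sample_id -> pHG1 | pHG3
    baseline_hazard: float
    hazard_ratio: float


def _gene_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"g{i + 1:0{width}d}" for i in range(n)]


def simulate_grade_cohort(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, SimulationTruth]:
    """Draw one cohort: expression matrix, clinical table, ground truth.

    The clinical table's ``grade`` column equals the true class (the
    generator's pathological labels are taken as correct); ``time`` and
    ``event`` follow the configured exponential survival model.
    """
    rng_expr, rng_pairs, rng_surv, rng_nuisance = [
        np.random.Generator(np.random.PCG64(s))
        for s in np.random.SeedSequence(config.seed).spawn(4)
    ]
    genes = _gene_ids(config.n_genes)
    n_samples = config.n_hg1 + config.n_hg3
    sample_ids = [f"HG1_{i + 1:04d}" for i in range(config.n_hg1)] + [
        f"HG3_{i + 1:04d}" for i in range(config.n_hg3)
    ]
    is_hg3 = np.array([False] * config.n_hg1 + [True] * config.n_hg3)

    # background: gene-specific baseline + iid noise, no class signal
    baseline = rng_expr.normal(config.baseline_mean, config.baseline_sd, config.n_genes)
    values = baseline[:, None] + rng_expr.normal(0.0, config.noise_sd, (config.n_genes, n_samples))

    # plant reversal pairs: orientation per sample follows the class
    # direction with probability `fidelity`, enforced exactly
    if config.reuse_genes:
        planted_idx = [
            tuple(rng_pairs.choice(config.n_genes, size=2, replace=False))
            for _ in range(config.n_planted_pairs)
        ]
    else:
        planted_idx = [(2 * k, 2 * k + 1) for k in range(config.n_planted_pairs)]
    planted_pairs = tuple((genes[i], genes[j]) for i, j in planted_idx)
    for i, j in planted_idx:
        mu = rng_expr.normal(config.baseline_mean, config.baseline_sd)
        hi = mu + config.pair_separation / 2 + rng_expr.normal(0, config.noise_sd, n_samples)
        lo = mu - config.pair_separation / 2 + rng_expr.normal(0, config.noise_sd, n_samples)
        upper = np.maximum(hi, lo)
        lower = np.minimum(hi, lo)
        tied = upper == lower
        upper[tied] += config.noise_sd * 1e-9 + 1e-12
        shows_class = rng_pairs.random(n_samples) < config.fidelity
        # class direction: gene i above gene j in pHG1, flipped in pHG3
        gene_i_high = np.where(is_hg3, ~shows_class, shows_class)
        values[i] = np.where(gene_i_high, upper, lower)
        values[j] = np.where(gene_i_high, lower, upper)

    if config.batch_shift_sd > 0:
        values += rng_nuisance.normal(0.0, config.batch_shift_sd, n_samples)[None, :]

    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=sample_ids), scale="log2"
    )
    if config.monotone_distortion:
        matrix = apply_monotone_distortion(matrix, seed=rng_nuisance.integers(2**31))
    if config.zero_inflation_rate > 0:
        linear = np.exp2(matrix.data.to_numpy())
        dropout = rng_nuisance.random(linear.shape) < config.zero_inflation_rate
        linear[dropout] = 0.0
        matrix = ExpressionMatrix(
            pd.DataFrame(linear, index=genes, columns=sample_ids), scale="linear"
        )

    hazard = config.baseline_hazard * np.where(is_hg3, config.hazard_ratio, 1.0)
    event_time = rng_surv.exponential(1.0 / hazard)
    if config.censoring_rate > 0:
        # exponential censoring at rate c/(1-c)*hazard gives P(censored) = c
        cens_rate = config.censoring_rate / (1 - config.censoring_rate) * hazard
        censor_time = rng_surv.exponential(1.0 / cens_rate)
    else:
        censor_time = np.full(n_samples, np.inf)
    if config.horizon is not None:
        censor_time = np.minimum(censor_time, config.horizon)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    clinical = pd.DataFrame(
        {
            "grade": np.where(is_hg3, "pHG3", "pHG1"),
            "time": time,
            "event": event,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    truth = SimulationTruth(
        planted_pairs=planted_pairs,
        true_class=pd.Series(
            np.where(is_hg3, "pHG3", "pHG1"), index=sample_ids, name="true_class"
        ),
        baseline_hazard=config.baseline_hazard,
        hazard_ratio=config.hazard_ratio,
    )
    return matrix, clinical, truth


def apply_monotone_distortion(matrix: ExpressionMatrix, seed: int) -> ExpressionMatrix:
    """Warp each sample by an independent strictly increasing function.

    The warp family is affine plus a softplus bend,
    ``f(x) = a + b*x + (c/d) * softplus(d*(x - t))`` with b > 0, c >= 0,
    d > 0, so f'(x) = b + c*sigmoid(d*(x-t)) > 0 everywhere: within-
    sample orderings (including exact ties) are preserved, while the
    value scale of every sample is deformed differently — a stand-in
    for cross-platform and batch distortions.
    """
    rng = np.random.Generator(np.random.PCG64(seed))
    X = matrix.data.to_numpy().copy()
    for j in range(X.shape[1]):
        col = X[:, j]
        finite = np.isfinite(col)
        lo, hi = (0.0, 1.0) if not finite.any() else (
            float(np.min(col[finite])), float(np.max(col[finite]))
        )
        a = rng.uniform(-2.0, 2.0)
        b = rng.uniform(0.5, 2.0)
        c = rng.uniform(0.0, 2.0)
        d = rng.uniform(0.5, 2.0)
        t = rng.uniform(lo, hi) if hi > lo else lo
        X[:, j] = a + b * col + (c / d) * np.logaddexp(0.0, d * (col - t))
    return ExpressionMatrix(
        pd.DataFrame(X, index=matrix.data.index, columns=matrix.data.columns),
        scale=matrix.scale,
    )


def expected_classifier_accuracy(k: int, q: float, true_class: str = "pHG3") -> float:
    """Closed-form majority-vote accuracy with k independent pairs.

    Each pair votes for the sample's true class with probability ``q``.
    A sample is called HG3 at >= ceil(k/2) HG3 votes, so a pHG3 sample
    is correct with P(Binomial(k, q) >= ceil(k/2)); a pHG1 sample is
    correct only when HG3 votes stay strictly below the threshold,
    i.e. with P(Binomial(k, q) >= k - ceil(k/2) + 1). For odd k the two
    coincide; for even k the tie at k/2 favors HG3.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must lie in [0, 1]")
    threshold = int(np.ceil(k / 2))
    if true_class == "pHG3":
        return float(binom.sf(threshold - 1, k, q))
    if true_class == "pHG1":
        return float(binom.sf(k - threshold, k, q))
    raise ValueError("true_class must be 'pHG1' or 'pHG3'")
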