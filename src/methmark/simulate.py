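"""Synthetic data generators for the full pipeline.

Three generators emulate the three assay layers:

* paired tumor/nontumor CpG-array log-ratio tables with a planted set of
  hypermethylated multi-probe genes (discovery input),
* per-cohort pyrosequencing methylation-index (MtI) distributions
  calibrated to printed group means and SDs via a [0, 100]-truncated
  normal with post-truncation moment matching,
* qMSP CT-pair cohorts whose per-stratum positivity at a given 40-dCT
  cutoff is an explicit Bernoulli parameter, with undetected-target
  dropout for methylation-negative samples.

Every generator is a pure function of its config (which carries the
seed). Random streams are consumed in sample order with a fixed number
of draws per sample, so extending a cohort leaves earlier samples'
values untouched.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .discovery import ArrayDataset
from .errors import CalibrationError, ConfigurationError

#: Printed urine-sediment MtI group means +/- SDs (percent) used as the
#: default calibration table for the three pyrosequencing-validated genes.
MTI_CALIBRATION: dict[str, dict[str, tuple[float, float]]] = {
    "DMC1": {"healthy": (10.7, 9.0), "BUD": (20.9, 13.6), "BCa": (33.6, 25.4)},
    "PENK": {"healthy": (6.4, 5.4), "BUD": (13.3, 9.9), "BCa": (51.0, 23.2)},
    "SIM2": {"healthy": (7.5, 3.7), "BUD": (22.6, 14.2), "BCa": (45.4, 21.6)},
}

#: Pyrosequencing verification cohort sizes (urine, n = 51).
PYRO_COHORT_SIZES = {"BCa": 16, "BUD": 23, "healthy": 12}


# ---------------------------------------------------------------------------
# paired CpG arrays
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArraySimConfig:
    """Design of a simulated paired tumor/nontumor array experiment.

    ``noise_sd`` is the standard deviation of the per-probe paired
    tumor-minus-normal log-ratio contrast (each channel receives
    independent noise of ``noise_sd / sqrt(2)``): the contrast is the
    quantity the paired test sees, so the generator is parameterized by
    it directly. ``effect_size`` is the mean log-ratio shift added to
    every probe of a planted gene (>= ``min_planted_probes`` probes per
    planted gene carry the shift by construction).
    """

    n_gene_total: int = 200
    n_planted_genes: int = 9
    probes_per_gene: int = 4
    n_pairs: int = 9
    effect_size: float = 1.5
    noise_sd: float = 0.5
    min_planted_probes: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.n_gene_total < 1:
            raise ConfigurationError("n_gene_total must be >= 1")
        if not (0 <= self.n_planted_genes <= self.n_gene_total):
            raise ConfigurationError(
                "n_planted_genes must satisfy 0 <= n_planted_genes <= n_gene_total"
            )
        if self.probes_per_gene < 1:
            raise ConfigurationError("probes_per_gene must be >= 1")
        if not (1 <= self.min_planted_probes <= self.probes_per_gene):
            raise ConfigurationError(
                "min_planted_probes must satisfy 1 <= min_planted_probes <= probes_per_gene"
            )
        if self.n_pairs < 2:
            raise ConfigurationError("n_pairs must be >= 2 for a paired design")
        if self.effect_size < 0:
            raise ConfigurationError("effect_size must be >= 0")
        if not self.noise_sd > 0:
            raise ConfigurationError("noise_sd must be > 0")


def generate_array_dataset(cfg: ArraySimConfig) -> ArrayDataset:
    """Simulate a probe x pair log-ratio matrix with planted hypermethylation.

    Planted genes (ground truth recorded on the returned dataset) have all
    their probes shifted by ``effect_size`` in the tumor channel. Noise
    streams are partitioned per pair, so adding pairs does not perturb the
    values of existing pairs.
    """
    cfg.validate()
    n_probes = cfg.n_gene_total * cfg.probes_per_gene
    gene_ids_unique = [f"G{i:04d}" for i in range(cfg.n_gene_total)]
    gene_ids = np.repeat(gene_ids_unique, cfg.probes_per_gene)
    probe_ids = [
        f"{g}_p{j}" for g in gene_ids_unique for j in range(cfg.probes_per_gene)
    ]
    pair_ids = [f"pair{i:02d}" for i in range(cfg.n_pairs)]

    children = np.random.SeedSequence(cfg.seed).spawn(cfg.n_pairs + 1)
    plant_rng = np.random.default_rng(children[0])
    planted_idx = plant_rng.choice(cfg.n_gene_total, cfg.n_planted_genes, replace=False)
    planted = frozenset(gene_ids_unique[i] for i in planted_idx)
    shifted = np.isin(gene_ids, list(planted))

    channel_sd = cfg.noise_sd / np.sqrt(2.0)
    tumor = np.empty((n_probes, cfg.n_pairs))
    normal = np.empty((n_probes, cfg.n_pairs))
    for j in range(cfg.n_pairs):
        rng = np.random.default_rng(children[j + 1])
        normal[:, j] = rng.normal(0.0, channel_sd, n_probes)
        tumor[:, j] = rng.normal(0.0, channel_sd, n_probes)
    tumor[shifted, :] += cfg.effect_size

    return ArrayDataset(
        probe_ids=probe_ids,
        gene_ids=list(gene_ids),
        pair_ids=pair_ids,
        tumor=tumor,
        normal=normal,
        planted_genes=planted,
    )


# ---------------------------------------------------------------------------
# pyrosequencing MtI cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortMtISpec:
    """One (group, gene) MtI cohort calibrated to a printed mean +/- SD."""

    group_label: str
    gene: str
    target_mean: float
    target_sd: float
    n: int
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.target_mean <= 100.0):
            raise ConfigurationError("target_mean must lie in [0, 100]")
        if not self.target_sd > 0:
            raise ConfigurationError("target_sd must be > 0")
        if self.n < 1:
            raise ConfigurationError("n must be >= 1")


@lru_cache(maxsize=256)
def _truncnorm_params(
    mean: float, sd: float, lower: float = 0.0, upper: float = 100.0
) -> tuple[float, float]:
    """Untruncated (mu, sigma) whose [lower, upper]-truncation has the
    requested post-truncation mean and SD, found by numeric root search.

    Raises :class:`CalibrationError` when no member of the truncated
    family attains the target moments (e.g. an SD too large for the
    interval given the mean).
    """
    if not (lower < mean < upper):
        raise CalibrationError(
            f"target mean {mean} must lie strictly inside [{lower}, {upper}]"
        )
    # hard bound: no distribution on [L, U] with this mean has larger variance
    if sd * sd >= (mean - lower) * (upper - mean):
        raise CalibrationError(
            f"target sd {sd} is infeasible on [{lower}, {upper}] for mean {mean}"
        )

    def residual(x: np.ndarray) -> np.ndarray:
        mu, log_sigma = x
        sigma = np.exp(log_sigma)
        a, b = (lower - mu) / sigma, (upper - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return np.array([m - mean, np.sqrt(v) - sd])

    sol = optimize.least_squares(
        residual, x0=np.array([mean, np.log(sd)]), xtol=1e-14, ftol=1e-14, gtol=1e-14
    )
    if not sol.success or np.max(np.abs(sol.fun)) > 1e-6:
        raise CalibrationError(
            f"moment matching failed for mean={mean}, sd={sd} on [{lower}, {upper}]"
        )
    mu, log_sigma = sol.x
    return float(mu), float(np.exp(log_sigma))


def generate_mti_cohort(spec: CohortMtISpec) -> np.ndarray:
    """Draw per-sample MtI percentages for one cohort.

    Values come from a normal truncated to [0, 100] whose post-truncation
    mean and SD equal the calibration targets; sampling is by inverse CDF
    on one uniform per sample, drawn in sample order.
    """
    spec.validate()
    mu, sigma = _truncnorm_params(spec.target_mean, spec.target_sd)
    a, b = (0.0 - mu) / sigma, (100.0 - mu) / sigma
    u = np.random.default_rng(np.random.SeedSequence(spec.seed)).random(spec.n)
    return stats.truncnorm.ppf(u, a, b, loc=mu, scale=sigma)


def generate_pyro_table(
    spec: CohortMtISpec, n_cpg: int = 4, cpg_jitter_sd: float = 0.03
) -> pd.DataFrame:
    """Per-CpG methylated fractions whose per-sample mean is the drawn MtI.

    Pyrosequencing assays here interrogate 3-5 CpGs; per-CpG fractions
    scatter around the sample's regional methylation level with a small
    jitter, centered so the written table averages back (clipping at the
    [0, 1] bounds permitting) to the drawn MtI.
    """
    if n_cpg < 1:
        raise ConfigurationError("n_cpg must be >= 1")
    mti = generate_mti_cohort(spec) / 100.0
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 1)))
    jitter = rng.normal(0.0, cpg_jitter_sd, (spec.n, n_cpg))
    jitter -= jitter.mean(axis=1, keepdims=True)
    fractions = np.clip(mti[:, None] + jitter, 0.0, 1.0)
    sample_ids = [f"{spec.group_label}_{spec.gene}_{i:04d}" for i in range(spec.n)]
    return pd.DataFrame(
        {
            "sample_id": np.repeat(sample_ids, n_cpg),
            "gene": spec.gene,
            "cpg_index": np.tile(np.arange(1, n_cpg + 1), spec.n),
            "methylated_fraction": fractions.ravel(),
        }
    )


# ---------------------------------------------------------------------------
# qMSP CT cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QmspSimSpec:
    """One cohort stratum of simulated qMSP CT pairs.

    ``positivity`` is the Bernoulli probability that a sample scores
    above the classification cutoff. Methylation-negative samples have
    an undetected target CT with probability ``dropout_rate`` and a
    detected but sub-cutoff CT pair otherwise.
    """

    group_label: str
    n: int
    positivity: float
    detected_ct_target_mean: float = 33.0
    detected_ct_target_sd: float = 2.5
    reference_ct_mean: float = 28.0
    reference_ct_sd: float = 1.5
    dropout_rate: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if self.n < 1:
            raise ConfigurationError("n must be >= 1")
        if not (0.0 <= self.positivity <= 1.0):
            raise ConfigurationError("positivity must lie in [0, 1]")
        for name in ("detected_ct_target_mean", "reference_ct_mean"):
            v = getattr(self, name)
            if not (0.0 < v < 40.0):
                raise ConfigurationError(f"{name} must lie in (0, 40)")
        if self.detected_ct_target_sd <= 0 or self.reference_ct_sd <= 0:
            raise ConfigurationError("CT standard deviations must be > 0")
        if not (0.0 <= self.dropout_rate <= 1.0):
            raise ConfigurationError("dropout_rate must lie in [0, 1]")


def _truncnorm_ppf(u, mean, sd, lower, upper):
    a = (np.asarray(lower) - mean) / sd
    b = (np.asarray(upper) - mean) / sd
    return stats.truncnorm.ppf(u, a, b, loc=mean, scale=sd)


def generate_qmsp_cohort(
    spec: QmspSimSpec,
    cutoff: float = 31.35,
    reference_ct_max: float = 38.0,
) -> pd.DataFrame:
    """Simulate one stratum of qMSP CT exports.

    Reference CTs are always detected below the reference-QC bound.
    Positive samples receive a detected target CT placed so that
    40 - (ct_target - ct_reference) exceeds ``cutoff``; negatives either
    drop out (undetected target) or receive a detected sub-cutoff pair.
    Four uniforms are consumed per sample, in sample order.
    """
    spec.validate()
    u = np.random.default_rng(np.random.SeedSequence(spec.seed)).random((spec.n, 4))
    is_pos = u[:, 0] < spec.positivity
    dropout = u[:, 1] < spec.dropout_rate

    ct_ref = _truncnorm_ppf(
        u[:, 2], spec.reference_ct_mean, spec.reference_ct_sd,
        0.0, min(40.0, reference_ct_max),
    )
    # score > cutoff  <=>  ct_target < 40 + ct_ref - cutoff
    pos_upper = np.minimum(40.0, 40.0 + ct_ref - cutoff) - 1e-9
    neg_lower = 40.0 + ct_ref - cutoff

    ct_tgt = np.full(spec.n, np.nan)
    detected = np.zeros(spec.n, dtype=bool)

    if is_pos.any():
        ct_tgt[is_pos] = _truncnorm_ppf(
            u[is_pos, 3], spec.detected_ct_target_mean, spec.detected_ct_target_sd,
            1e-9, pos_upper[is_pos],
        )
        detected[is_pos] = True
    neg_det = (~is_pos) & (~dropout) & (neg_lower < 40.0 - 1e-9)
    if neg_det.any():
        ct_tgt[neg_det] = _truncnorm_ppf(
            u[neg_det, 3], spec.detected_ct_target_mean, spec.detected_ct_target_sd,
            neg_lower[neg_det], 40.0 - 1e-9,
        )
        detected[neg_det] = True

    sample_ids = [f"{spec.group_label}_{i:04d}" for i in range(spec.n)]
    return pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": spec.group_label,
            "ct_target": np.where(detected, ct_tgt, np.nan),
            "ct_reference": ct_ref,
            "target_detected": detected,
            "reference_detected": True,
            "true_positive": is_pos,
        }
    )
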