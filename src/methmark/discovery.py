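"""Stepwise candidate-gene selection from paired tumor/normal CpG arrays.

The discovery cascade mirrors the usual two-color CpG-island microarray
workflow for paired designs: restrict to reliable probes, test each probe
for a tumor-vs-normal shift with a paired t-test, control the FDR with
Benjamini-Hochberg, require a minimum linear-scale fold change in the
hypermethylation direction, and finally promote genes supported by at
least ``min_probes`` positive probes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateDataError, SchemaError

logger = logging.getLogger(__name__)

ARRAY_COLUMNS = ["probe_id", "gene", "pair_id", "tumor_logratio", "normal_logratio"]


@dataclass
class ArrayDataset:
    """Probe x pair matrix of methylation-enrichment log-ratios.

    ``tumor`` and ``normal`` are (n_probes, n_pairs) arrays aligned with
    ``probe_ids``/``gene_ids`` (one gene per probe) and ``pair_ids``.
    ``planted_genes`` records simulation ground truth when available.
    """

    probe_ids: list[str]
    gene_ids: list[str]
    pair_ids: list[str]
    tumor: np.ndarray
    normal: np.ndarray
    reliable_mask: np.ndarray = None
    planted_genes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.tumor = np.asarray(self.tumor, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        n_probes, n_pairs = self.tumor.shape
        if self.normal.shape != (n_probes, n_pairs):
            raise SchemaError("tumor and normal matrices must have equal shape")
        if len(self.probe_ids) != n_probes or len(self.gene_ids) != n_probes:
            raise SchemaError("probe/gene id lists must match matrix rows")
        if len(self.pair_ids) != n_pairs:
            raise SchemaError("pair id list must match matrix columns")
        if self.reliable_mask is None:
            self.reliable_mask = np.ones(n_probes, dtype=bool)
        self.reliable_mask = np.asarray(self.reliable_mask, dtype=bool)
        if self.reliable_mask.shape != (n_probes,):
            raise SchemaError("reliable_mask length must equal probe count")

    @property
    def n_probes(self) -> int:
        return self.tumor.shape[0]

    @property
    def n_pairs(self) -> int:
        return self.tumor.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table, one row per probe x pair."""
        n_probes, n_pairs = self.tumor.shape
        return pd.DataFrame(
            {
                "probe_id": np.repeat(self.probe_ids, n_pairs),
                "gene": np.repeat(self.gene_ids, n_pairs),
                "pair_id": np.tile(self.pair_ids, n_probes),
                "tumor_logratio": self.tumor.ravel(),
                "normal_logratio": self.normal.ravel(),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ArrayDataset":
        missing = [c for c in ARRAY_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"probe table missing column(s): {', '.join(missing)}")
        pair_ids = list(pd.unique(df["pair_id"]))
        wide_t = df.pivot(index="probe_id", columns="pair_id", values="tumor_logratio")
        wide_n = df.pivot(index="probe_id", columns="pair_id", values="normal_logratio")
        wide_t = wide_t.loc[pd.unique(df["probe_id"]), pair_ids]
        wide_n = wide_n.loc[wide_t.index, pair_ids]
        gene_of = df.drop_duplicates("probe_id").set_index("probe_id")["gene"]
        return cls(
            probe_ids=list(wide_t.index),
            gene_ids=[gene_of[p] for p in wide_t.index],
            pair_ids=[str(p) for p in pair_ids],
            tumor=wide_t.to_numpy(),
            normal=wide_n.to_numpy(),
        )


@dataclass(frozen=True)
class ProbeTestResult:
    probe_id: str
    raw_p: float
    adjusted_p: float
    fold_change: float
    positive_call: bool


@dataclass(frozen=True)
class CandidateGene:
    gene_id: str
    n_positive_probes: int
    member_probes: tuple[str, ...]
    best_adjusted_p: float = float("nan")
    mean_fold_change: float = float("nan")


def test_probe_paired(tumor, normal) -> tuple[float, float]:
    """Paired two-sided t-test for a per-probe tumor-vs-normal shift.

    With two conditions and paired samples this is the form the generic
    "parametric ANOVA" of array software reduces to. Returns (t, p).
    A probe whose paired differences are exactly constant has zero
    variance: a nonzero constant difference is infinitely significant
    (p = 0 sentinel), a zero difference carries no information.
    """
    tumor = np.asarray(tumor, dtype=float)
    normal = np.asarray(normal, dtype=float)
    if tumor.shape != normal.shape or tumor.ndim != 1:
        raise ValueError("tumor and normal must be 1-D arrays of equal length")
    if tumor.size < 2:
        raise ValueError("paired test requires at least 2 pairs")
    if not (np.all(np.isfinite(tumor)) and np.all(np.isfinite(normal))):
        raise ValueError("paired test requires finite values")
    diffs = tumor - normal
    if np.ptp(diffs) == 0.0:
        if diffs[0] == 0.0:
            raise DegenerateDataError(
                "tumor and normal vectors are identical; the paired test is undefined"
            )
        return (np.copysign(np.inf, diffs[0]), 0.0)
    res = stats.ttest_rel(tumor, normal)
    return float(res.statistic), float(res.pvalue)


def benjamini_hochberg(raw_ps) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (capped at 1)."""
    p = np.asarray(raw_ps, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("raw_ps must be a non-empty 1-D sequence")
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _probe_stats(ds: ArrayDataset, probe_idx: np.ndarray):
    """Vectorized paired t statistics, raw p and linear fold change."""
    tumor = ds.tumor[probe_idx]
    normal = ds.normal[probe_idx]
    n = ds.n_pairs
    d = tumor - normal
    mean_d = d.mean(axis=1)
    sd_d = d.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean_d / (sd_d / np.sqrt(n))
    raw_p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    # constant nonzero difference: p = 0 sentinel; constant zero: no signal
    const = sd_d == 0.0
    raw_p[const & (mean_d != 0.0)] = 0.0
    raw_p[const & (mean_d == 0.0)] = 1.0
    fold = (2.0 ** tumor).mean(axis=1) / (2.0 ** normal).mean(axis=1)
    direction = tumor.mean(axis=1) > normal.mean(axis=1)
    return raw_p, fold, direction


def probe_test_table(
    ds: ArrayDataset, alpha: float = 0.01, fc_min: float = 2.0
) -> list[ProbeTestResult]:
    """Per-probe results over the reliable probes of the dataset."""
    idx = np.where(ds.reliable_mask)[0]
    if idx.size == 0:
        logger.warning("no reliable probes in dataset; empty probe test table")
        return []
    raw_p, fold, direction = _probe_stats(ds, idx)
    adj = benjamini_hochberg(raw_p)
    positive = (adj < alpha) & (fold >= fc_min) & direction
    return [
        ProbeTestResult(ds.probe_ids[i], float(raw_p[k]), float(adj[k]), float(fold[k]), bool(positive[k]))
        for k, i in enumerate(idx)
    ]


def select_candidates(
    ds: ArrayDataset,
    alpha: float = 0.01,
    fc_min: float = 2.0,
    min_probes: int = 2,
) -> list[CandidateGene]:
    """Run the full filter cascade and return multi-probe candidate genes.

    Genes are ranked by descending positive-probe count, then descending
    mean fold change over positive probes, with gene-id order breaking ties
    deterministically.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if fc_min <= 1.0:
        raise ValueError("fc_min must exceed 1 (hypermethylation enrichment)")
    if min_probes < 1:
        raise ValueError("min_probes must be >= 1")
    results = probe_test_table(ds, alpha=alpha, fc_min=fc_min)
    if not results:
        return []
    gene_of = dict(zip(ds.probe_ids, ds.gene_ids))
    per_gene: dict[str, list[ProbeTestResult]] = {}
    for r in results:
        if r.positive_call:
            per_gene.setdefault(gene_of[r.probe_id], []).append(r)
    candidates = [
        CandidateGene(
            gene_id=g,
            n_positive_probes=len(rs),
            member_probes=tuple(sorted(r.probe_id for r in rs)),
            best_adjusted_p=min(r.adjusted_p for r in rs),
            mean_fold_change=float(np.mean([r.fold_change for r in rs])),
        )
        for g, rs in per_gene.items()
        if len(rs) >= min_probes
    ]
    candidates.sort(key=lambda c: (-c.n_positive_probes, -c.mean_fold_change, c.gene_id))
    return candidates


def candidates_to_frame(candidates: list[CandidateGene]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [c.gene_id for c in candidates],
            "n_positive_probes": [c.n_positive_probes for c in candidates],
            "best_adjusted_p": [c.best_adjusted_p for c in candidates],
            "mean_fold_change": [c.mean_fold_change for c in candidates],
        }
    )
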