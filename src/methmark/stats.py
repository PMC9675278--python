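"""Diagnostic and association statistics for the clinical validation.

ROC/AUC with Mann-Whitney pair counting and a DeLong-type asymptotic
CI, Youden-optimal cutoff selection, sensitivity/specificity with exact
Clopper-Pearson binomial CIs, a two-sided Fisher exact test built from
hypergeometric point probabilities, and a tie-corrected Kruskal-Wallis
test. Percentages are reported to 1 decimal and p values to 3 decimals
where the clinical report requires printed parity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RocCurve:
    thresholds: np.ndarray  # ascending; includes -inf and +inf sentinels
    sens: np.ndarray        # P(score > t | case)
    spec: np.ndarray        # P(score <= t | control)
    auc: float
    auc_ci: tuple[float, float]


def _check_binary(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and aligned")
    if not labels.any() or labels.all():
        raise ValueError("both cases and controls are required")
    return scores, labels


def auc_mann_whitney(scores, labels) -> float:
    """AUC as the Mann-Whitney pair statistic U/(n1*n0), ties counted 1/2."""
    scores, labels = _check_binary(scores, labels)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    ranks = sps.rankdata(scores)
    u = ranks[labels].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _delong_variance(cases: np.ndarray, controls: np.ndarray, auc: float) -> float:
    # placement values: per-case fraction of controls beaten (+ half ties),
    # and symmetrically per control; DeLong's two-class variance estimate.
    v10 = np.array([
        np.mean((c > controls) + 0.5 * (c == controls)) for c in cases
    ])
    v01 = np.array([
        np.mean((cases > c) + 0.5 * (cases == c)) for c in controls
    ])
    m, n = len(cases), len(controls)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def roc_curve(scores, labels, level: float = 0.95) -> RocCurve:
    """Empirical ROC over midpoint thresholds with the ">" convention.

    Thresholds are the midpoints between distinct sorted scores plus
    -inf/+inf sentinels; a sample is test-positive when its score
    strictly exceeds the threshold.
    """
    scores, labels = _check_binary(scores, labels)
    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate(([-np.inf], mids, [np.inf]))
    cases = scores[labels]
    controls = scores[~labels]
    sens = np.array([(cases > t).mean() for t in thresholds])
    spec = np.array([(controls <= t).mean() for t in thresholds])
    auc = auc_mann_whitney(scores, labels)
    se = np.sqrt(_delong_variance(cases, controls, auc))
    z = sps.norm.ppf(0.5 + level / 2.0)
    ci = (max(0.0, auc - z * se), min(1.0, auc + z * se))
    return RocCurve(thresholds, sens, spec, auc, ci)


def optimal_cutoff(roc: RocCurve) -> float:
    """Threshold maximizing Youden's J = sens + spec - 1.

    Ties are broken toward higher specificity (the larger threshold);
    a fully degenerate curve therefore returns the +inf sentinel.
    """
    j = roc.sens + roc.spec - 1.0
    best = np.flatnonzero(j >= j.max() - 1e-12)
    return float(roc.thresholds[best[-1]])


# ---------------------------------------------------------------------------
# binomial performance
# ---------------------------------------------------------------------------

def clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial CI from beta quantiles, on the percent scale."""
    if not (0 <= k <= n) or n < 1:
        raise ValueError(f"invalid successes/trials: {k}/{n}")
    if not (0.0 < level < 1.0):
        raise ValueError("confidence level must lie in (0, 1)")
    alpha = 1.0 - level
    low = 0.0 if k == 0 else float(sps.beta.ppf(alpha / 2.0, k, n - k + 1))
    high = 1.0 if k == n else float(sps.beta.ppf(1.0 - alpha / 2.0, k + 1, n - k))
    return 100.0 * low, 100.0 * high


@dataclass(frozen=True)
class DiagnosticPerformance:
    cutoff: float
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: Optional[float]
    sensitivity_ci: Optional[tuple[float, float]]
    specificity: Optional[float]
    specificity_ci: Optional[tuple[float, float]]


def performance_at_cutoff(
    scores, labels, cutoff: float, level: float = 0.95
) -> DiagnosticPerformance:
    """Sensitivity/specificity (percent) with exact CIs at a fixed cutoff.

    Uses the assay's strict ">" positivity convention. An empty class is
    reported as undefined (None) rather than raising.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores > cutoff
    tp = int((pos & labels).sum())
    fn = int((~pos & labels).sum())
    fp = int((pos & ~labels).sum())
    tn = int((~pos & ~labels).sum())
    sens = sens_ci = spec = spec_ci = None
    if tp + fn > 0:
        sens = 100.0 * tp / (tp + fn)
        sens_ci = clopper_pearson(tp, tp + fn, level)
    if tn + fp > 0:
        spec = 100.0 * tn / (tn + fp)
        spec_ci = clopper_pearson(tn, tn + fp, level)
    return DiagnosticPerformance(cutoff, tp, fp, tn, fn, sens, sens_ci, spec, spec_ci)


# ---------------------------------------------------------------------------
# Fisher exact / Kruskal-Wallis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable2x2:
    """Rows = parameter stratum, columns = methylation positive/negative."""

    a: int
    b: int
    c: int
    d: int

    def validate(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def fisher_exact(t: ContingencyTable2x2) -> float:
    """Conventional two-sided Fisher exact p for a 2x2 table.

    Sums the hypergeometric point probabilities of every table with the
    same margins whose probability does not exceed the observed one
    (within a 1 + 1e-7 relative tolerance for float safety). Degenerate
    margins give p = 1 by convention.
    """
    t.validate()
    a, b, c, d = t.a, t.b, t.c, t.d
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        logger.info("fisher_exact: degenerate margin, returning p = 1")
        return 1.0
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n, c1, r1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum())
    return min(p, 1.0)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with its chi-square p (k-1 df)."""
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs at least 2 groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrs):
        raise ValueError("every group must be non-empty")
    pooled = np.concatenate(arrs)
    n = pooled.size
    if n < 3:
        raise ValueError("Kruskal-Wallis needs total n >= 3")
    ranks = sps.rankdata(pooled)
    h = 0.0
    start = 0
    for a in arrs:
        r = ranks[start:start + a.size]
        h += r.sum() ** 2 / a.size
        start += a.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie_corr = 1.0 - ((counts ** 3 - counts).sum()) / (n ** 3 - n)
    if tie_corr == 0.0:  # all values identical
        return 0.0, 1.0
    h /= tie_corr
    p = float(sps.chi2.sf(h, df=len(arrs) - 1))
    return float(h), p


# ---------------------------------------------------------------------------
# clinicopathological association tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssociationResult:
    parameter: str
    strata: tuple[str, str]
    n: tuple[int, int]
    positives: tuple[int, int]
    positivity: tuple[float, float]  # percent, 1 decimal
    table: ContingencyTable2x2
    p: float                         # 3 decimals


_PARAMETERS = {
    "sex": (("Male", "Female"), lambda r: r.sex == "M"),
    "age": (("<65", ">=65"), lambda r: r.age < 65),
    "stage": (("Ta,T1", "T2-T4"), lambda r: r.stage in ("Ta", "T1")),
    "grade": (("Low", "High"), lambda r: r.grade == "low"),
}


def association_table(samples, calls, parameter: str) -> AssociationResult:
    """Stratum positivity and Fisher p for one clinicopathological parameter.

    ``samples`` are the cancer-group records, ``calls`` a sample_id ->
    bool methylation-call mapping. Samples for which the parameter is
    undefined (unknown grade) are excluded from that table.
    """
    if parameter not in _PARAMETERS:
        raise ValueError(f"unknown parameter {parameter!r}")
    strata, in_first = _PARAMETERS[parameter]
    if parameter == "grade":
        samples = [r for r in samples if r.grade in ("low", "high")]
    if not samples:
        raise ValueError(f"parameter {parameter!r} undefined for all samples")
    counts = [[0, 0], [0, 0]]  # [stratum][pos/neg]
    for r in samples:
        row = 0 if in_first(r) else 1
        col = 0 if calls[r.sample_id] else 1
        counts[row][col] += 1
    table = ContingencyTable2x2(
        counts[0][0], counts[0][1], counts[1][0], counts[1][1]
    )
    n = (counts[0][0] + counts[0][1], counts[1][0] + counts[1][1])
    pos = (counts[0][0], counts[1][0])
    positivity = tuple(
        round(100.0 * p_ / n_, 1) if n_ else float("nan") for p_, n_ in zip(pos, n)
    )
    return AssociationResult(
        parameter=parameter,
        strata=strata,
        n=n,
        positives=pos,
        positivity=positivity,  # type: ignore[arg-type]
        table=table,
        p=round(fisher_exact(table), 3),
    )
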