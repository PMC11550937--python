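"""Endpoint statistics: log10 transforms, the test battery, LDH binning.

The battery mirrors common practice for small microbiology endpoint
datasets: concentrations are analysed on the log10 scale (with
censored values handled by an explicit limit-of-detection policy), a
Shapiro-Wilk gate routes two-sample comparisons to Welch's t-test or a
rank-sum alternative, multi-group comparisons use Dunn's rank-based
procedure with multiplicity adjustment, and binned LDH activity is
compared across groups by Pearson's chi-square test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

EXPLANT_GROUPS = ("negative_control", "positive_control", "moi1", "moi10")

#: LDH activity bins (U/L); boundary values 50 and 100 fall in the middle bin.
LDH_BINS = ("lt50", "b50_100", "gt100")


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test.

    ``significant`` is judged on ``adjusted_p`` when present, else on
    the raw p-value, against ``alpha``.  ``method`` records which test
    actually ran (e.g. whether the normality gate chose the t-test or
    the rank-sum path); ``detail`` carries test-specific extras such as
    degrees of freedom, expected counts or the compared pair.
    """

    test_name: str
    statistic: float
    p_value: float
    alpha: float
    adjusted_p: float | None = None
    method: str | None = None
    detail: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        p = self.p_value
        if not (0.0 <= p <= 1.0) and not math.isnan(p):
            raise ValueError(f"p-value {p} outside [0, 1]")

    @property
    def significant(self) -> bool:
        p = self.adjusted_p if self.adjusted_p is not None else self.p_value
        return bool(p < self.alpha)


@dataclass(frozen=True)
class ExplantEndpoint:
    """Endpoint record for one explant well (one uterus, one group)."""

    uterus_id: str
    group: str
    phage_id: str | None
    cfu_per_ml: float
    pfu_per_ml: float | None
    ldh_6h: float | None
    ldh_24h: float | None

    def __post_init__(self) -> None:
        if self.group not in EXPLANT_GROUPS:
            raise ValueError(f"group must be one of {EXPLANT_GROUPS}, got {self.group!r}")
        if self.cfu_per_ml < 0:
            raise ValueError("cfu_per_ml must be non-negative")
        if self.pfu_per_ml is not None and self.pfu_per_ml < 0:
            raise ValueError("pfu_per_ml must be non-negative")


def log10_transform(
    concentration: float, lod: float | None = None, policy: str = "half_lod"
) -> float | None:
    """log10 of a per-mL concentration with censoring policy.

    Zero (censored) values are imputed at half the limit of detection
    (default), at the LOD itself, or dropped (returns None, flagged to
    the caller by the None).
    """
    if concentration < 0:
        raise ValueError("concentration must be non-negative")
    if concentration > 0:
        return math.log10(concentration)
    if policy == "drop":
        return None
    if lod is None or lod <= 0:
        raise ValueError(f"policy {policy!r} needs a positive limit of detection")
    if policy == "half_lod":
        return math.log10(lod / 2.0)
    if policy == "lod":
        return math.log10(lod)
    raise ValueError(f"unknown censoring policy {policy!r}")


def two_sample_test(
    x: Sequence[float], y: Sequence[float], alpha: float = 0.05
) -> TestResult:
    """Two-sample location test with a Shapiro-Wilk normality gate.

    Both samples normal at ``alpha`` -> unpaired Welch t-test; otherwise
    Mann-Whitney rank-sum.  Degenerate all-tied data short-circuits to a
    no-difference result.  ``method`` records the path taken.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("each sample needs n >= 3 to assess normality")
    if np.ptp(np.concatenate([x, y])) == 0:
        return TestResult("two_sample", 0.0, 1.0, alpha, method="degenerate_all_tied")

    def _normal(s: np.ndarray) -> bool:
        if np.ptp(s) == 0:  # Shapiro-Wilk undefined on constant data
            return False
        return sps.shapiro(s).pvalue > alpha

    if _normal(x) and _normal(y):
        stat, p = sps.ttest_ind(x, y, equal_var=False)
        method = "welch_t"
    else:
        stat, p = sps.mannwhitneyu(x, y, alternative="two-sided")
        method = "mann_whitney_u"
    return TestResult("two_sample", float(stat), float(p), alpha, method=method)


def dunn_multiple_comparison(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    adjustment: str = "bonferroni",
) -> list[TestResult]:
    """Dunn's rank-based pairwise comparisons across k groups.

    All observations are pooled and mid-ranked; for each pair (i, j)
    the z statistic is ``(Rbar_i - Rbar_j) / SE`` with

        SE = sqrt((N(N+1)/12 - T) * (1/n_i + 1/n_j)),
        T  = sum(t^3 - t) / (12 (N - 1))  over tie groups of size t,

    and a two-sided normal p-value.  P-values are adjusted over the
    tested pairs (``bonferroni`` default, also ``holm`` or ``none``).
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("Dunn's procedure needs at least two groups")
    arrays = {g: np.asarray(groups[g], dtype=float) for g in names}
    for g, a in arrays.items():
        if len(a) == 0:
            raise ValueError(f"group {g!r} is empty")

    pooled = np.concatenate([arrays[g] for g in names])
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_rank: dict[str, float] = {}
    start = 0
    for g in names:
        n = len(arrays[g])
        mean_rank[g] = float(np.mean(ranks[start : start + n]))
        start += n

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    pairs = [(names[i], names[j]) for i in range(len(names))
             for j in range(i + 1, len(names))]
    zs, ps = [], []
    for gi, gj in pairs:
        se = math.sqrt(var_base * (1.0 / len(arrays[gi]) + 1.0 / len(arrays[gj])))
        if se == 0:  # every pooled value tied
            zs.append(0.0)
            ps.append(1.0)
            continue
        z = (mean_rank[gi] - mean_rank[gj]) / se
        zs.append(z)
        ps.append(2.0 * sps.norm.sf(abs(z)))

    m = len(pairs)
    if adjustment == "bonferroni":
        adj = [min(1.0, p * m) for p in ps]
    elif adjustment == "holm":
        order = np.argsort(ps)
        adj_arr = np.empty(m)
        running = 0.0
        for rank_idx, idx in enumerate(order):
            running = max(running, (m - rank_idx) * ps[idx])
            adj_arr[idx] = min(1.0, running)
        adj = list(adj_arr)
    elif adjustment == "none":
        adj = [None] * m
    else:
        raise ValueError(f"unknown adjustment {adjustment!r}")

    return [
        TestResult(
            "dunn",
            float(z),
            float(p),
            alpha,
            adjusted_p=a,
            method=f"dunn_{adjustment}",
            detail={"pair": pair},
        )
        for pair, z, p, a in zip(pairs, zs, ps, adj)
    ]


def ldh_bin(value: float) -> str:
    """Bin an LDH activity (U/L): [0,50) -> lt50, [50,100] -> b50_100, >100 -> gt100."""
    if value < 0:
        raise ValueError("LDH activity must be non-negative")
    if value < 50:
        return "lt50"
    if value <= 100:
        return "b50_100"
    return "gt100"


def chi_square_contingency(table) -> TestResult:
    """Pearson chi-square on a bins x groups count table (no continuity correction).

    ``detail`` carries the expected counts, degrees of freedom and a
    small-sample warning flag when any expected count is below 5.
    Zero-margin rows/columns are rejected as degenerate.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if np.any(arr < 0) or not np.allclose(arr, np.round(arr)):
        raise ValueError("table must contain non-negative integer counts")
    if arr.sum() == 0:
        raise ValueError("all-zero contingency table")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError(
            "zero row/column margin: drop the empty category before testing"
        )
    res = sps.chi2_contingency(arr, correction=False)
    return TestResult(
        "chi_square",
        float(res.statistic),
        float(res.pvalue),
        alpha=0.05,
        method="pearson_chi2",
        detail={
            "dof": int(res.dof),
            "expected": res.expected_freq,
            "low_expected_warning": bool(np.any(res.expected_freq < 5)),
        },
    )


def ldh_contingency(
    endpoints: Iterable[ExplantEndpoint], timepoint: str = "combined"
) -> pd.DataFrame:
    """Bin LDH values and cross-tabulate bins x groups.

    ``timepoint``: "6h", "24h" or "combined" (both readings pooled;
    the 6 h / 24 h question is reported separately and combined because
    it is ambiguous whether they should be tested jointly).
    """
    if timepoint not in ("6h", "24h", "combined"):
        raise ValueError("timepoint must be '6h', '24h' or 'combined'")
    counts = pd.DataFrame(0, index=list(LDH_BINS), columns=list(EXPLANT_GROUPS))
    for e in endpoints:
        values = []
        if timepoint in ("6h", "combined") and e.ldh_6h is not None:
            values.append(e.ldh_6h)
        if timepoint in ("24h", "combined") and e.ldh_24h is not None:
            values.append(e.ldh_24h)
        for v in values:
            counts.loc[ldh_bin(v), e.group] += 1
    return counts


def summarize_endpoints(
    endpoints: Iterable[ExplantEndpoint],
    lod: float = 100.0,
    policy: str = "half_lod",
) -> pd.DataFrame:
    """Per-group mean +/- sd of CFU/mL and PFU/mL on linear and log10 scales."""
    rows = []
    by_group: dict[str, list[ExplantEndpoint]] = {}
    for e in endpoints:
        by_group.setdefault(e.group, []).append(e)
    for group, items in by_group.items():
        cfu = np.array([e.cfu_per_ml for e in items], dtype=float)
        log_cfu = np.array(
            [v for v in (log10_transform(c, lod, policy) for c in cfu) if v is not None]
        )
        pfu_vals = [e.pfu_per_ml for e in items if e.pfu_per_ml is not None]
        row = {
            "group": group,
            "n": len(items),
            "cfu_mean": float(np.mean(cfu)),
            "cfu_sd": float(np.std(cfu, ddof=1)) if len(cfu) > 1 else math.nan,
            "log10_cfu_mean": float(np.mean(log_cfu)) if len(log_cfu) else math.nan,
            "log10_cfu_sd": float(np.std(log_cfu, ddof=1))
            if len(log_cfu) > 1
            else math.nan,
        }
        if pfu_vals:
            pfu = np.asarray(pfu_vals, dtype=float)
            log_pfu = np.array(
                [v for v in (log10_transform(p, lod, policy) for p in pfu)
                 if v is not None]
            )
            row.update(
                pfu_mean=float(np.mean(pfu)),
                pfu_sd=float(np.std(pfu, ddof=1)) if len(pfu) > 1 else math.nan,
                log10_pfu_mean=float(np.mean(log_pfu)) if len(log_pfu) else math.nan,
            )
        rows.append(row)
    return pd.DataFrame(rows)
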