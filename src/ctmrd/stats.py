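"""Cohort-level metrics and the nonparametric group comparisons.

Contingency metrics treat radiological recurrence as the reference truth and
MRD status as the test: sensitivity = TP/(TP+FN) over recurrent patients,
specificity = TN/(TN+FP) over disease-free patients, and the per-arm
recurrence rates are TP/(TP+FP) and FN/(FN+TN).  Ratios with empty
denominators are reported as missing (None), never as 0.

Group tests implement the statistics directly; reference distributions
(t, chi-square, normal) come from scipy.  Fisher's exact test enumerates
the full hypergeometric table space; the rank tests switch from exact
enumeration to a continuity-corrected normal approximation above n = 25.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm, t as t_dist

from .caller import CTDNA_PRIVATE, TISSUE_DERIVED
from .longitudinal import PatientRecord, eligible_calls


# ---------------------------------------------------------------------------
# contingency metrics


@dataclass
class ContingencyMetrics:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @staticmethod
    def _ratio(num: int, den: int) -> Optional[float]:
        return num / den if den > 0 else None

    @property
    def sensitivity(self) -> Optional[float]:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> Optional[float]:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> Optional[float]:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> Optional[float]:
        return self._ratio(self.tn, self.tn + self.fn)

    @property
    def recurrence_rate_positive(self) -> Optional[float]:
        return self.ppv

    @property
    def recurrence_rate_negative(self) -> Optional[float]:
        return self._ratio(self.fn, self.fn + self.tn)


def contingency(records: Sequence[PatientRecord], status_field: str) -> ContingencyMetrics:
    """2x2 of MRD status against recurrence.

    ``status_field`` is ``landmark_status`` or ``longitudinal_status``;
    landmark-unsampled patients are excluded from the landmark table.
    """
    if status_field not in ("landmark_status", "longitudinal_status"):
        raise ValueError(f"unknown status_field {status_field!r}")
    tp = fp = fn = tn = 0
    for r in records:
        status = getattr(r, status_field)
        if status == "unsampled":
            continue
        positive = status == "positive"
        recurred = r.dfs_event
        if positive and recurred:
            tp += 1
        elif positive:
            fp += 1
        elif recurred:
            fn += 1
        else:
            tn += 1
    m = ContingencyMetrics(tp=tp, fp=fp, fn=fn, tn=tn)
    if m.n == 0:
        raise ValueError("contingency: no analyzable patients")
    return m


def from_counts(tp: int, fp: int, fn: int, tn: int) -> ContingencyMetrics:
    """Build the metrics straight from printed 2x2 counts."""
    return ContingencyMetrics(tp=tp, fp=fp, fn=fn, tn=tn)


def percent(x: Optional[float], decimals: int = 1) -> Optional[float]:
    """Proportion -> percentage, rounded half-up to ``decimals``."""
    if x is None:
        return None
    q = 10**decimals
    return math.floor(x * 100 * q + 0.5) / q


# ---------------------------------------------------------------------------
# group tests


def _ranks_with_ties(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mid-ranks and the tie-group sizes."""
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values), dtype=float)
    sorted_vals = values[order]
    ties = []
    i = 0
    while i < len(values):
        j = i
        while j < len(values) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0  # average of ranks i+1..j
        ties.append(j - i)
        i = j
    return ranks, np.asarray(ties, dtype=float)


def _exact_rank_sum_p(doubled_ranks: np.ndarray, n1: int, observed_doubled: int) -> float:
    """Two-sided exact p for the rank-sum by full enumeration.

    ``doubled_ranks`` are 2x mid-ranks (integers even with ties).  Enumerates
    all subsets of size n1 by dynamic programming over the achievable sums.
    """
    total = int(doubled_ranks.sum())
    mean2 = n1 * total / len(doubled_ranks)  # expected doubled rank-sum
    # dp[j] maps sum -> count using j chosen items
    dp = [dict() for _ in range(n1 + 1)]
    dp[0][0] = 1
    for r in doubled_ranks.astype(int):
        for j in range(min(n1, len(dp)) - 1, -1, -1):
            if not dp[j]:
                continue
            nxt = dp[j + 1]
            for s, c in dp[j].items():
                nxt[s + r] = nxt.get(s + r, 0) + c
    counts = dp[n1]
    total_count = sum(counts.values())
    obs_dev = abs(observed_doubled - mean2)
    extreme = sum(c for s, c in counts.items() if abs(s - mean2) >= obs_dev - 1e-9)
    return extreme / total_count


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann–Whitney U; exact below n = 25 total, else normal
    approximation with tie correction and continuity correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks, ties = _ranks_with_ties(pooled)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u = min(u1, n1 * n2 - u1)
    n = n1 + n2
    if n <= 25:
        doubled = np.rint(2 * ranks).astype(int)
        p = _exact_rank_sum_p(doubled, n1, int(round(2 * r1)))
        return u, min(1.0, p)
    mu = n1 * n2 / 2.0
    tie_term = float(np.sum(ties**3 - ties)) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return u, 1.0
    z = (abs(u1 - mu) - 0.5) / math.sqrt(sigma2)
    return u, float(2 * norm.sf(max(z, 0.0)))


def t_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided pooled-variance two-sample Student t-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    if sp2 <= 0:
        return 0.0, 1.0
    t = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    return float(t), float(2 * t_dist.sf(abs(t), df))


def chi_square(table: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Pearson chi-square on an r x c contingency table (no Yates)."""
    obs = np.asarray(table, dtype=float)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    n = obs.sum()
    if n <= 0:
        raise ValueError("chi_square: empty table")
    expected = row @ col / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(expected > 0, (obs - expected) ** 2 / expected, 0.0)
    stat = float(terms.sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return stat, float(chi2_dist.sf(stat, df))


def fisher_exact(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2, by full hypergeometric
    enumeration (sum of all tables with probability <= the observed)."""
    (a, b), (c, d) = table
    r1, c1, n = a + b, a + c, a + b + c + d
    if n == 0:
        raise ValueError("fisher_exact: empty table")

    def log_comb(n_, k_):
        return math.lgamma(n_ + 1) - math.lgamma(k_ + 1) - math.lgamma(n_ - k_ + 1)

    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    denom = log_comb(n, c1)
    logps = {
        k: log_comb(r1, k) + log_comb(n - r1, c1 - k) - denom for k in range(lo, hi + 1)
    }
    p_obs = logps[a]
    p = sum(math.exp(lp) for lp in logps.values() if lp <= p_obs + 1e-9)
    odds = (a * d) / (b * c) if b * c > 0 else math.inf
    return odds, min(1.0, p)


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped (Wilcoxon convention); exact enumeration of
    sign assignments below n = 25 nonzero pairs, else tie-corrected normal
    approximation with continuity correction.  Identical vectors give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired test with unequal lengths")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 0.0, 1.0
    ranks, ties = _ranks_with_ties(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    if n <= 25:
        doubled = np.rint(2 * ranks).astype(int)
        # enumerate all 2^n sign assignments by DP over doubled positive-rank sums
        dp = {0: 1}
        for r in doubled:
            nxt: dict[int, int] = {}
            for s, c in dp.items():
                nxt[s] = nxt.get(s, 0) + c
                nxt[s + r] = nxt.get(s + r, 0) + c
            dp = nxt
        total = sum(dp.values())
        obs_dev = abs(2 * w_pos - 2 * mu)
        extreme = sum(c for s, c in dp.items() if abs(s - 2 * mu) >= obs_dev - 1e-9)
        return w_pos, min(1.0, extreme / total)
    tie_term = float(np.sum(ties**3 - ties)) / 48.0
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = (abs(w_pos - mu) - 0.5) / math.sqrt(sigma2)
    return w_pos, float(2 * norm.sf(max(z, 0.0)))


def group_tests(kind: str, *args) -> tuple[float, float]:
    """Dispatch to the named two-sample/contingency test."""
    dispatch = {
        "mann_whitney": mann_whitney,
        "t_test": t_test,
        "chi_square": chi_square,
        "fisher_exact": fisher_exact,
        "wilcoxon_signed_rank": wilcoxon_signed_rank,
    }
    if kind not in dispatch:
        raise ValueError(f"unknown test kind {kind!r}")
    return dispatch[kind](*args)


# ---------------------------------------------------------------------------
# mutation-type composition


@dataclass
class CompositionTable:
    n_tissue_only: int
    n_private_only: int
    n_both: int
    #: per-class VAF summaries over passing variants: class -> (median, lo, hi)
    vaf_summary: dict[str, tuple[float, float, float]]

    @property
    def n(self) -> int:
        return self.n_tissue_only + self.n_private_only + self.n_both

    @property
    def proportions(self) -> dict[str, Optional[float]]:
        n = self.n
        if n == 0:
            return {"tissue_only": None, "private_only": None, "both": None}
        return {
            "tissue_only": self.n_tissue_only / n,
            "private_only": self.n_private_only / n,
            "both": self.n_both / n,
        }


def summarize_composition(records: Sequence[PatientRecord]) -> CompositionTable:
    """Per-patient mutation-type composition over all eligible positive calls.

    Only longitudinally positive patients contribute; a patient's class set
    is the union over the passing variants of their eligible positive calls.
    """
    tissue_only = private_only = both = 0
    vafs: dict[str, list[float]] = {TISSUE_DERIVED: [], CTDNA_PRIVATE: []}
    for r in records:
        if r.longitudinal_status != "positive":
            continue
        classes: set[str] = set()
        for call in eligible_calls(r, r.calls):
            for cv in call.passing_variants:
                classes.add(cv.variant_class)
                vafs[cv.variant_class].append(cv.observation.vaf)
        if classes == {TISSUE_DERIVED}:
            tissue_only += 1
        elif classes == {CTDNA_PRIVATE}:
            private_only += 1
        elif classes:
            both += 1
    summary = {}
    for cls, vals in vafs.items():
        if vals:
            arr = np.asarray(vals)
            summary[cls] = (float(np.median(arr)), float(arr.min()), float(arr.max()))
    return CompositionTable(
        n_tissue_only=tissue_only,
        n_private_only=private_only,
        n_both=both,
        vaf_summary=summary,
    )


def composition_from_counts(n_tissue_only: int, n_private_only: int, n_both: int) -> CompositionTable:
    return CompositionTable(
        n_tissue_only=n_tissue_only,
        n_private_only=n_private_only,
        n_both=n_both,
        vaf_summary={},
    )
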