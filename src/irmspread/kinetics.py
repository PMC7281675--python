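"""Cohort-level kinetics: attachment curves, phase durations, endpoint
fractions, and the Wilcoxon rank-sum comparison between substrates.

A cohort table has one row per platelet (id, substrate, attachment time or
censoring horizon, phase durations, endpoint class).  The attachment curve
is a scaled empirical CDF of attachment times; phase durations are simple
differences of annotated stage onsets times the frame interval; endpoint
fractions summarise how many platelets ended as unattached, filopodial
(arrested before the filopodia-to-lamellipodia switch) or fully spread.

The rank-sum test uses full enumeration of rank assignments when the pooled
sample is small (exact, midranks under ties) and the tie- and
continuity-corrected normal approximation otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .io import ENDPOINT_CLASSES, PhaseAnnotation

__all__ = [
    "COHORT_COLUMNS",
    "RankTestResult",
    "make_cohort_table",
    "attachment_curve",
    "phase_durations",
    "endpoint_fractions",
    "wilcoxon_rank_sum",
    "EXACT_MAX_N",
]

COHORT_COLUMNS = [
    "platelet_id", "substrate", "attachment_time", "censored",
    "filopodial_duration", "lamellipodial_duration", "endpoint_class",
]

#: largest pooled sample size for which the exact enumeration branch is used
EXACT_MAX_N = 12


def make_cohort_table(records: list[dict]) -> pd.DataFrame:
    """Assemble and validate a cohort table from per-platelet records."""
    df = pd.DataFrame(records, columns=COHORT_COLUMNS)
    if df["platelet_id"].duplicated().any():
        dupes = df.loc[df["platelet_id"].duplicated(), "platelet_id"].tolist()
        raise ValueError(f"duplicate platelet_id: {dupes}")
    bad = ~df["endpoint_class"].isin(ENDPOINT_CLASSES)
    if bad.any():
        raise ValueError(
            f"unknown endpoint_class values: {df.loc[bad, 'endpoint_class'].tolist()}")
    for col in ("attachment_time", "filopodial_duration", "lamellipodial_duration"):
        if (df[col].dropna() < 0).any():
            raise ValueError(f"negative values in {col}")
    df["censored"] = df["censored"].fillna(False).astype(bool)
    return df


def attachment_curve(cohort: pd.DataFrame, substrate: str,
                     time_grid: np.ndarray) -> np.ndarray:
    """Percentage of platelets attached by each time point (0..100).

    ``value(t) = 100 * #{attachment_time <= t} / n_group``; censored
    platelets never count as attached, so the curve is a scaled empirical
    CDF: non-decreasing, right-continuous, bounded by 100.
    """
    time_grid = np.asarray(time_grid, dtype=np.float64)
    if time_grid.size and np.any(np.diff(time_grid) <= 0):
        raise ValueError("time_grid must be strictly increasing")
    group = cohort[cohort["substrate"] == substrate]
    if group.empty:
        raise ValueError(f"no platelets for substrate {substrate!r}")
    times = group.loc[~group["censored"], "attachment_time"].dropna().to_numpy()
    n = len(group)
    return 100.0 * np.searchsorted(np.sort(times), time_grid, side="right") / n


def phase_durations(annotations: list[PhaseAnnotation],
                    frame_interval: float) -> pd.DataFrame:
    """Per-platelet filopodial and lamellipodial durations in seconds.

    filopodial = (lamellipodia onset - filopodia onset) * interval;
    lamellipodial = (spread - lamellipodia onset) * interval.  A missing
    stage yields a missing duration, never zero.
    """
    rows = []
    for ann in annotations:
        fil = lam = np.nan
        if ann.filopodia_onset_frame is not None and \
                ann.lamellipodia_onset_frame is not None:
            fil = (ann.lamellipodia_onset_frame
                   - ann.filopodia_onset_frame) * frame_interval
        if ann.lamellipodia_onset_frame is not None and \
                ann.spread_frame is not None:
            lam = (ann.spread_frame
                   - ann.lamellipodia_onset_frame) * frame_interval
        rows.append({"platelet_id": ann.platelet_id,
                     "filopodial_duration": fil,
                     "lamellipodial_duration": lam,
                     "endpoint_class": ann.endpoint_class})
    return pd.DataFrame(rows)


def endpoint_fractions(cohort: pd.DataFrame, substrate: str
                       ) -> tuple[dict[str, float], int]:
    """Fractions of each endpoint class in the substrate group, plus group n."""
    group = cohort[cohort["substrate"] == substrate]
    n = len(group)
    if n == 0:
        raise ValueError(f"no platelets for substrate {substrate!r}")
    counts = group["endpoint_class"].value_counts()
    return {c: counts.get(c, 0) / n for c in ENDPOINT_CLASSES}, n


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum


@dataclass(frozen=True)
class RankTestResult:
    statistic: float      # rank-sum of the first sample
    p_value: float        # two-sided
    n1: int
    n2: int
    method: str           # "exact" or "asymptotic"

    def __post_init__(self):
        if not (0 < self.p_value <= 1):
            raise ValueError(f"p_value {self.p_value} outside (0, 1]")
        lo = self.n1 * (self.n1 + 1) / 2
        hi = self.n1 * (2 * (self.n1 + self.n2) - self.n1 + 1) / 2
        if not (lo - 1e-9 <= self.statistic <= hi + 1e-9):
            raise ValueError(
                f"rank-sum {self.statistic} outside combinatorial bounds "
                f"[{lo}, {hi}]")


def _exact_rank_sum_p(ranks: np.ndarray, n1: int, w_obs: float) -> float:
    """Two-sided p by full enumeration of which pooled midranks go to group 1.

    Exact under the permutation null even with ties (midranks).  Two-sided p
    is twice the smaller tail probability, capped at 1, which for the
    symmetric tie-free null matches the textbook doubling rule; identical
    samples sit at the centre and give p = 1.
    """
    n = len(ranks)
    total = comb(n, n1)
    le = ge = 0
    eps = 1e-9
    for idx in combinations(range(n), n1):
        w = ranks[list(idx)].sum()
        if w <= w_obs + eps:
            le += 1
        if w >= w_obs - eps:
            ge += 1
    return min(1.0, 2.0 * min(le, ge) / total)


def wilcoxon_rank_sum(a, b) -> RankTestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    The statistic reported is the rank-sum of *a* in the pooled sample
    (midranks under ties).  For pooled sizes up to EXACT_MAX_N the p-value
    is computed by full enumeration over rank assignments; larger samples
    use the normal approximation with tie and continuity correction.  The
    test is invariant under any common strictly monotone transform of both
    samples, since only ranks enter.
    """
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # midranks
    w = float(ranks[:n1].sum())
    if n1 + n2 <= EXACT_MAX_N:
        p = _exact_rank_sum_p(ranks, n1, w)
        method = "exact"
    else:
        # U statistic of sample a; scipy applies tie + continuity correction
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
        # normal tail mass can underflow to 0 for extreme shifts; keep p > 0
        p = max(float(res.pvalue), float(np.nextafter(0.0, 1.0)))
        method = "asymptotic"
    return RankTestResult(statistic=w, p_value=p, n1=n1, n2=n2, method=method)
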