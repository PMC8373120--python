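"""Differential splicing, survival association, and candidate prioritization.

The screen combines three layers of evidence per splicing event:

1. a two-sided Wilcoxon rank-sum (Mann-Whitney U) comparison of PSI between
   tumor and control samples, with the exact null distribution when both
   groups are small (n <= 8) and tie-free;
2. disease-free-survival association: samples are dichotomized at the median
   PSI of the event (ties to the low group) and compared with a one-degree
   log-rank test on the Kaplan-Meier curves;
3. a cascade of six exclusion criteria plus shortlist filters (alternative
   segment length in 30-300 bp, coding-region location, tumor-high PSI)
   producing the final candidate table.

The exclusion criteria, applied per event (an event firing any criterion is
excluded):

  c1  PSI is NA in >= 2/3 of all samples (insufficient read support);
  c2  in-frame micro-segment: length divisible by 3 affecting < 5 amino acids;
  c3  no significant survival association (log-rank p >= alpha);
  c4  no significant tumor-control PSI difference (rank-sum p >= alpha);
  c5  PSI is NA in more than 4 control samples;
  c6  |dPSI| no more than 0.1 (0.1 exactly is excluded).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

DEFAULT_ALPHA = 0.05
DEFAULT_DELTA_PSI_CUTOFF = 0.1
DEFAULT_LENGTH_WINDOW = (30, 300)


@dataclass
class SurvivalRecord:
    """One subject: follow-up time (months) and event indicator (1 = DFS event)."""

    sample_id: str
    time: float
    event: int

    def __post_init__(self):
        if self.time <= 0:
            raise ValueError(f"time must be positive, got {self.time}")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0 or 1, got {self.event}")


def read_survival_tsv(path) -> list[SurvivalRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return [
        SurvivalRecord(str(r.sample_id), float(r.time_months), int(r.event_01))
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Differential PSI


def _rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann-Whitney p: exact when both n <= 8 and no ties, else
    normal approximation with tie correction."""
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if np.ptp(pooled) == 0:
        return 1.0  # all observations identical: no evidence either way
    method = "exact" if (len(x) <= 8 and len(y) <= 8 and not has_ties) else "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


def differential_psi(
    psi: pd.DataFrame, group_labels: Mapping[str, str] | pd.Series, tumor_label: str = "tumor"
) -> pd.DataFrame:
    """Per-event tumor-vs-control PSI comparison.

    ``group_labels`` maps sample id to a group name; the group equal to
    ``tumor_label`` is the case group, everything else is control. Returns a
    DataFrame indexed by event with columns delta_psi, wilcoxon_p,
    n_tumor_used, n_control_used. dPSI = mean(tumor) - mean(control) over
    non-NA values; p is NA when either group has fewer than 2 usable values.
    """
    labels = pd.Series(dict(group_labels))
    tumor_cols = [c for c in psi.columns if labels.get(c) == tumor_label]
    control_cols = [c for c in psi.columns if c in labels.index and labels[c] != tumor_label]
    rows = []
    for event_id, row in psi.iterrows():
        t = row[tumor_cols].dropna().to_numpy(dtype=float)
        c = row[control_cols].dropna().to_numpy(dtype=float)
        delta = t.mean() - c.mean() if len(t) and len(c) else math.nan
        p = _rank_sum_p(t, c) if len(t) >= 2 and len(c) >= 2 else math.nan
        rows.append((event_id, delta, p, len(t), len(c)))
    return pd.DataFrame(
        rows, columns=["event_id", "delta_psi", "wilcoxon_p", "n_tumor_used", "n_control_used"]
    ).set_index("event_id")


# ---------------------------------------------------------------------------
# Survival


@dataclass
class KMEstimate:
    """Kaplan-Meier product-limit curve as a right-continuous step function."""

    times: np.ndarray  # event times where the curve steps down
    survival: np.ndarray  # S(t) just after each step

    def at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(records: Sequence[SurvivalRecord]) -> KMEstimate:
    """Product-limit survival estimate with right censoring."""
    if not records:
        raise ValueError("no survival records")
    kmf = KaplanMeierFitter()
    kmf.fit(
        durations=[r.time for r in records],
        event_observed=[r.event for r in records],
    )
    sf = kmf.survival_function_["KM_estimate"]
    # keep only times where the curve actually steps (event times)
    steps = sf[sf.diff().fillna(0) != 0]
    return KMEstimate(times=steps.index.to_numpy(float), survival=steps.to_numpy(float))


def logrank_test(
    group_a: Sequence[SurvivalRecord], group_b: Sequence[SurvivalRecord]
) -> tuple[float, float]:
    """One-degree-of-freedom log-rank comparison; returns (chi2 statistic, p).

    p is NA when neither group contains an observed event.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if not any(r.event for r in group_a) and not any(r.event for r in group_b):
        return 0.0, math.nan
    res = _ll_logrank(
        durations_A=[r.time for r in group_a],
        durations_B=[r.time for r in group_b],
        event_observed_A=[r.event for r in group_a],
        event_observed_B=[r.event for r in group_b],
    )
    return float(res.test_statistic), float(res.p_value)


def survival_association(
    psi: pd.DataFrame, survival: Sequence[SurvivalRecord]
) -> pd.DataFrame:
    """Median-PSI dichotomization + log-rank per event.

    For each event, samples with both a non-NA PSI and a survival record are
    split at the median PSI (ties assigned to the low group) and the two
    groups compared with the log-rank test. Degenerate splits (constant PSI,
    or an empty side) yield p = NA. Requires >= 4 overlapping samples.
    """
    by_sample = {r.sample_id: r for r in survival}
    shared = [c for c in psi.columns if c in by_sample]
    if len(shared) < 4:
        raise ValueError(f"only {len(shared)} samples shared between PSI and survival")
    rows = []
    for event_id, row in psi.loc[:, shared].iterrows():
        vals = row.dropna()
        if len(vals) < 4 or vals.nunique() < 2:
            rows.append((event_id, math.nan, math.nan, 0, 0))
            continue
        med = float(vals.median())
        low_ids = vals.index[vals <= med]
        high_ids = vals.index[vals > med]
        if len(low_ids) == 0 or len(high_ids) == 0:
            rows.append((event_id, math.nan, math.nan, len(high_ids), len(low_ids)))
            continue
        low = [by_sample[s] for s in low_ids]
        high = [by_sample[s] for s in high_ids]
        stat, p = logrank_test(high, low)
        rows.append((event_id, stat, p, len(high), len(low)))
    return pd.DataFrame(
        rows, columns=["event_id", "logrank_stat", "logrank_p", "n_high", "n_low"]
    ).set_index("event_id")


# ---------------------------------------------------------------------------
# Candidate cascade

CRITERION_COLUMNS = ["c1_na_two_thirds", "c2_inframe_micro", "c3_no_survival",
                     "c4_no_differential", "c5_control_na", "c6_small_delta"]
SHORTLIST_COLUMNS = ["length_in_30_300", "in_cds", "high_tumor_psi"]


def apply_prioritization(
    events,
    differential: pd.DataFrame,
    survival_results: pd.DataFrame,
    psi: pd.DataFrame,
    group_labels: Mapping[str, str] | pd.Series,
    alpha: float = DEFAULT_ALPHA,
    delta_psi_cutoff: float = DEFAULT_DELTA_PSI_CUTOFF,
    length_window: tuple[int, int] = DEFAULT_LENGTH_WINDOW,
    max_control_na: int = 4,
    tumor_label: str = "tumor",
    use_fdr: bool = False,
) -> pd.DataFrame:
    """Apply the six exclusion criteria and shortlist filters.

    Returns one row per event with a boolean flag per criterion (True = the
    criterion fires, i.e. the event is excluded by it), the shortlist flags,
    and ``retained``: no criterion fired and every shortlist flag holds.
    Events missing from either evidence table are dropped with reason
    ``incomplete evidence``. ``use_fdr`` switches c3/c4 to Benjamini-Hochberg
    adjusted p-values (off by default: nominal p is the reported convention).
    """
    labels = pd.Series(dict(group_labels))
    control_cols = [c for c in psi.columns if c in labels.index and labels[c] != tumor_label]

    ev_list = list(events)
    ev_index = {ev.event_id: ev for ev in ev_list}
    surv_p = survival_results["logrank_p"].copy()
    diff_p = differential["wilcoxon_p"].copy()
    if use_fdr:
        from statsmodels.stats.multitest import multipletests

        for ser in (surv_p, diff_p):
            ok = ser.notna()
            if ok.any():
                ser.loc[ok] = multipletests(ser[ok], method="fdr_bh")[1]

    rows = []
    dropped = []
    for event_id, ev in ev_index.items():
        if (
            event_id not in differential.index
            or event_id not in survival_results.index
            or event_id not in psi.index
        ):
            dropped.append(event_id)
            continue
        d = differential.loc[event_id]
        na_frac_all = float(psi.loc[event_id].isna().mean())
        n_control_na = int(psi.loc[event_id, control_cols].isna().sum())
        delta = float(d["delta_psi"])
        lp = surv_p.get(event_id, math.nan)
        wp = diff_p.get(event_id, math.nan)

        c1 = na_frac_all >= 2.0 / 3.0
        c2 = ev.alt_length % 3 == 0 and ev.alt_length // 3 < 5
        c3 = not (not math.isnan(lp) and lp < alpha)
        c4 = not (not math.isnan(wp) and wp < alpha)
        c5 = n_control_na > max_control_na
        c6 = math.isnan(delta) or abs(delta) <= delta_psi_cutoff

        length_ok = length_window[0] <= ev.alt_length <= length_window[1]
        tumor_high = not math.isnan(delta) and delta > 0

        retained = (
            not any((c1, c2, c3, c4, c5, c6)) and length_ok and ev.in_cds and tumor_high
        )
        rows.append(
            (event_id, ev.gene_id, ev.alt_length, delta, wp, lp,
             c1, c2, c3, c4, c5, c6, length_ok, ev.in_cds, tumor_high, retained)
        )

    out = pd.DataFrame(
        rows,
        columns=["event_id", "gene_id", "alt_length", "delta_psi", "wilcoxon_p", "logrank_p"]
        + CRITERION_COLUMNS + SHORTLIST_COLUMNS + ["retained"],
    ).set_index("event_id")
    out.attrs["dropped_incomplete_evidence"] = dropped
    return out
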