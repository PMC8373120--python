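"""Differential screen, survival analysis and the candidate cascade."""

import math

import numpy as np
import pandas as pd
import pytest

from spliceprio.events import SpliceEvent
from spliceprio.prioritize import (
    SurvivalRecord,
    apply_prioritization,
    differential_psi,
    km_estimate,
    logrank_test,
    survival_association,
)

from _oracles import exact_rank_sum_p, logrank_stat_oracle


def psi_frame(tumor_vals, control_vals, event_id="ev"):
    data = {f"T{i}": v for i, v in enumerate(tumor_vals)}
    data.update({f"N{i}": v for i, v in enumerate(control_vals)})
    return pd.DataFrame(data, index=[event_id])


def labels_for(df):
    return {c: ("tumor" if c.startswith("T") else "control") for c in df.columns}


class TestDifferentialPsi:
    def test_exact_small_sample_p(self):
        # tumor ranks {3,4}, control {1,2}: the most extreme of C(4,2)=6
        # assignments, two-sided exact p = 2/6
        df = psi_frame([0.3, 0.4], [0.1, 0.2])
        res = differential_psi(df, labels_for(df))
        assert res.loc["ev", "wilcoxon_p"] == pytest.approx(2 / 6)
        assert res.loc["ev", "delta_psi"] == pytest.approx(0.2)

    def test_identical_groups_give_p_one_delta_zero(self):
        df = psi_frame([0.5, 0.5, 0.5], [0.5, 0.5, 0.5])
        res = differential_psi(df, labels_for(df))
        assert res.loc["ev", "wilcoxon_p"] == 1.0
        assert res.loc["ev", "delta_psi"] == 0.0

    def test_small_group_yields_na(self):
        df = psi_frame([0.4, 0.5, 0.6], [0.2])
        res = differential_psi(df, labels_for(df))
        assert math.isnan(res.loc["ev", "wilcoxon_p"])
        assert res.loc["ev", "n_control_used"] == 1

    def test_na_values_dropped_before_testing(self):
        df = psi_frame([0.5, 0.7, np.nan], [0.1, 0.2, np.nan])
        res = differential_psi(df, labels_for(df))
        assert res.loc["ev", "n_tumor_used"] == 2
        assert res.loc["ev", "delta_psi"] == pytest.approx(0.6 - 0.15)

    @pytest.mark.parametrize(
        "tumor,control",
        [
            ([0.9, 0.7, 0.5], [0.2, 0.4]),
            ([0.12, 0.5, 0.31, 0.77], [0.4, 0.9, 0.05]),
            ([0.6, 0.61], [0.59, 0.58, 0.3, 0.9]),
        ],
    )
    def test_matches_full_enumeration_oracle(self, tumor, control):
        df = psi_frame(tumor, control)
        res = differential_psi(df, labels_for(df))
        assert res.loc["ev", "wilcoxon_p"] == pytest.approx(
            exact_rank_sum_p(tumor, control), abs=1e-12
        )

    def test_planted_shift_power(self):
        """A 0.25 PSI shift at depth 100, 20 vs 10 samples, is detected with
        power >= 0.8 at alpha 0.05 (500 seeded replicates)."""
        rng = np.random.default_rng(123)
        hits = 0
        n_rep = 500
        for _ in range(n_rep):
            d_t = rng.poisson(100, size=20)
            d_c = rng.poisson(100, size=10)
            pi_c, pi_t = 0.4, 0.65
            inc_t = rng.binomial(d_t, 2 * pi_t / (1 + pi_t))
            inc_c = rng.binomial(d_c, 2 * pi_c / (1 + pi_c))
            est_t = (inc_t / 2) / (inc_t / 2 + (d_t - inc_t))
            est_c = (inc_c / 2) / (inc_c / 2 + (d_c - inc_c))
            df = psi_frame(est_t, est_c)
            res = differential_psi(df, labels_for(df))
            hits += res.loc["ev", "wilcoxon_p"] < 0.05
        assert hits / n_rep >= 0.8


class TestKaplanMeier:
    def test_product_limit_by_hand(self):
        rec = [SurvivalRecord(f"s{i}", t, 1) for i, t in enumerate([1, 2, 3])]
        km = km_estimate(rec)
        assert km.at(1) == pytest.approx(2 / 3)
        assert km.at(2) == pytest.approx(1 / 3)
        assert km.at(3) == pytest.approx(0.0)

    def test_all_censored_flat_curve(self):
        rec = [SurvivalRecord(f"s{i}", t, 0) for i, t in enumerate([5, 10, 15])]
        km = km_estimate(rec)
        for t in (1, 7, 20):
            assert km.at(t) == 1.0

    def test_censoring_respected(self):
        rec = [SurvivalRecord("a", 5, 1), SurvivalRecord("b", 10, 0)]
        km = km_estimate(rec)
        assert km.at(5) == pytest.approx(0.5)
        assert km.at(9.9) == pytest.approx(0.5)


class TestLogrank:
    def test_identical_groups_stat_zero_p_one(self):
        g = [SurvivalRecord(f"s{i}", t, 1) for i, t in enumerate([2, 4, 6])]
        g2 = [SurvivalRecord(f"r{i}", t, 1) for i, t in enumerate([2, 4, 6])]
        stat, p = logrank_test(g, g2)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_no_events_anywhere_gives_na(self):
        a = [SurvivalRecord("a", 5, 0)]
        b = [SurvivalRecord("b", 7, 0)]
        stat, p = logrank_test(a, b)
        assert math.isnan(p)

    @pytest.mark.parametrize(
        "times_a,times_b,events_a,events_b",
        [
            ([1, 2, 3], [10, 11, 12], [1, 1, 1], [1, 1, 1]),
            ([3, 5, 9, 11], [2, 4, 8], [1, 0, 1, 1], [1, 1, 0]),
            ([1, 1, 2, 6, 7], [2, 3, 4, 9], [1, 1, 0, 1, 1], [0, 1, 1, 1]),
        ],
    )
    def test_statistic_matches_definitional_oracle(self, times_a, times_b, events_a, events_b):
        a = [SurvivalRecord(f"a{i}", t, e) for i, (t, e) in enumerate(zip(times_a, events_a))]
        b = [SurvivalRecord(f"b{i}", t, e) for i, (t, e) in enumerate(zip(times_b, events_b))]
        stat, _ = logrank_test(a, b)
        times = np.array(times_a + times_b, float)
        events = np.array(events_a + events_b)
        in_a = np.array([True] * len(times_a) + [False] * len(times_b))
        assert stat == pytest.approx(logrank_stat_oracle(times, events, in_a), abs=1e-8)

    def test_power_at_hazard_ratio_e(self):
        """Across a median split with hazard ratio e^1 and n=100, the log-rank
        detects the difference at alpha 0.05 in >= 90% of 200 replicates."""
        rng = np.random.default_rng(31)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            t_high = rng.exponential(1.0 / (0.02 * math.e), size=50)
            t_low = rng.exponential(1.0 / 0.02, size=50)
            cens = rng.uniform(0, 150, size=100)
            times = np.concatenate([t_high, t_low])
            obs = (times <= cens).astype(int)
            times = np.minimum(times, cens)
            a = [SurvivalRecord(f"a{i}", max(t, 1e-3), int(e))
                 for i, (t, e) in enumerate(zip(times[:50], obs[:50]))]
            b = [SurvivalRecord(f"b{i}", max(t, 1e-3), int(e))
                 for i, (t, e) in enumerate(zip(times[50:], obs[50:]))]
            _, p = logrank_test(a, b)
            hits += p < 0.05
        assert hits / n_rep >= 0.90


class TestSurvivalAssociation:
    def test_constant_psi_degenerate_split_is_na(self):
        psi = pd.DataFrame({f"s{i}": 0.5 for i in range(6)}, index=["ev"])
        surv = [SurvivalRecord(f"s{i}", i + 1.0, 1) for i in range(6)]
        res = survival_association(psi, surv)
        assert math.isnan(res.loc["ev", "logrank_p"])

    def test_median_ties_go_to_low_group(self):
        psi = pd.DataFrame(
            {"s0": 0.2, "s1": 0.5, "s2": 0.5, "s3": 0.9, "s4": 0.8, "s5": 0.95},
            index=["ev"],
        )
        surv = [SurvivalRecord(f"s{i}", i + 1.0, 1) for i in range(6)]
        res = survival_association(psi, surv)
        # median 0.65: low {0.2, 0.5, 0.5}, high {0.8, 0.9, 0.95}
        assert res.loc["ev", "n_low"] == 3
        assert res.loc["ev", "n_high"] == 3

    def test_doubled_hazard_recovered(self):
        rng = np.random.default_rng(11)
        n = 100
        psi_vals = np.concatenate([rng.uniform(0.6, 0.9, 50), rng.uniform(0.1, 0.4, 50)])
        hazard = np.where(psi_vals > 0.5, 0.08, 0.04)
        times = rng.exponential(1.0 / hazard)
        psi = pd.DataFrame({f"s{i}": psi_vals[i] for i in range(n)}, index=["ev"])
        surv = [SurvivalRecord(f"s{i}", max(times[i], 1e-3), 1) for i in range(n)]
        res = survival_association(psi, surv)
        assert res.loc["ev", "logrank_p"] < 0.05

    def test_too_few_shared_samples_raises(self):
        psi = pd.DataFrame({"s0": 0.5, "s1": 0.4}, index=["ev"])
        surv = [SurvivalRecord("s0", 1.0, 1), SurvivalRecord("s1", 2.0, 0)]
        with pytest.raises(ValueError, match="shared"):
            survival_association(psi, surv)


# ---------------------------------------------------------------------------
# Cascade


def build_event(alt_length, in_cds=True, event_id="ev"):
    return SpliceEvent(
        event_id=event_id,
        event_type="CASSETTE",
        gene_id="g",
        chrom="chr1",
        strand="+",
        alt_segment=(1000, 1000 + alt_length),
        flank_upstream=(800, 900),
        flank_downstream=(2000, 2100),
        inclusion_junctions=frozenset({(900, 1000), (1000 + alt_length, 2000)}),
        exclusion_junctions=frozenset({(900, 2000)}),
        in_cds=in_cds,
    )


def evidence(event_id="ev", delta=0.2, wp=0.01, lp=0.01, psi_df=None):
    diff = pd.DataFrame(
        {"delta_psi": [delta], "wilcoxon_p": [wp], "n_tumor_used": [4], "n_control_used": [4]},
        index=[event_id],
    )
    surv = pd.DataFrame(
        {"logrank_stat": [5.0], "logrank_p": [lp], "n_high": [4], "n_low": [4]},
        index=[event_id],
    )
    if psi_df is None:
        psi_df = psi_frame([0.6, 0.7, 0.65, 0.7], [0.4, 0.45, 0.5, 0.42], event_id)
    return diff, surv, psi_df


class TestCascade:
    def test_full_evidence_event_retained(self):
        ev = build_event(84)
        diff, surv, psi = evidence()
        table = apply_prioritization([ev], diff, surv, psi, labels_for(psi))
        assert bool(table.loc["ev", "retained"])

    def test_inframe_micro_segment_excluded(self):
        ev = build_event(12)  # multiple of 3, 4 amino acids
        diff, surv, psi = evidence()
        table = apply_prioritization([ev], diff, surv, psi, labels_for(psi))
        assert bool(table.loc["ev", "c2_inframe_micro"])
        assert not bool(table.loc["ev", "retained"])

    def test_delta_psi_exactly_point_one_excluded(self):
        ev = build_event(84)
        diff, surv, psi = evidence(delta=0.1)
        table = apply_prioritization([ev], diff, surv, psi, labels_for(psi))
        assert bool(table.loc["ev", "c6_small_delta"])
        assert not bool(table.loc["ev", "retained"])

    def test_control_na_criterion(self):
        ev = build_event(84)
        psi = psi_frame([0.6] * 8, [np.nan] * 5 + [0.5] * 3)
        diff, surv, _ = evidence()
        table = apply_prioritization([ev], diff, surv, psi, labels_for(psi))
        assert bool(table.loc["ev", "c5_control_na"])

    def test_na_two_thirds_criterion(self):
        ev = build_event(84)
        psi = psi_frame([np.nan] * 7 + [0.6], [np.nan, 0.4, 0.5])
        diff, surv, _ = evidence()
        table = apply_prioritization([ev], diff, surv, psi, labels_for(psi))
        assert bool(table.loc["ev", "c1_na_two_thirds"])

    def test_incomplete_evidence_dropped_with_reason(self):
        evs = [build_event(84), build_event(90, event_id="missing")]
        diff, surv, psi = evidence()
        table = apply_prioritization(evs, diff, surv, psi, labels_for(psi))
        assert "missing" not in table.index
        assert table.attrs["dropped_incomplete_evidence"] == ["missing"]

    def test_cascade_is_monotone_in_thresholds(self):
        rng = np.random.default_rng(5)
        evs, diffs, survs, psis = [], [], [], []
        for i in range(40):
            eid = f"e{i}"
            evs.append(build_event(int(rng.integers(20, 400)), in_cds=bool(rng.random() < 0.8),
                                   event_id=eid))
            d, s, p = evidence(
                event_id=eid,
                delta=float(rng.uniform(-0.4, 0.4)),
                wp=float(rng.uniform(0, 0.2)),
                lp=float(rng.uniform(0, 0.2)),
            )
            diffs.append(d)
            survs.append(s)
            psis.append(p)
        diff, surv, psi = pd.concat(diffs), pd.concat(survs), pd.concat(psis)
        strict = apply_prioritization(evs, diff, surv, psi, labels_for(psi),
                                      alpha=0.05, delta_psi_cutoff=0.1)
        relaxed = apply_prioritization(evs, diff, surv, psi, labels_for(psi),
                                       alpha=0.15, delta_psi_cutoff=0.05)
        kept_strict = set(strict.index[strict["retained"]])
        kept_relaxed = set(relaxed.index[relaxed["retained"]])
        assert kept_strict <= kept_relaxed

    def test_retained_equals_intersection_of_survivor_sets(self):
        rng = np.random.default_rng(9)
        evs, diffs, survs, psis = [], [], [], []
        for i in range(30):
            eid = f"e{i}"
            evs.append(build_event(int(rng.integers(10, 350)), event_id=eid))
            d, s, p = evidence(event_id=eid, delta=float(rng.uniform(-0.3, 0.3)),
                               wp=float(rng.uniform(0, 0.1)), lp=float(rng.uniform(0, 0.1)))
            diffs.append(d)
            survs.append(s)
            psis.append(p)
        table = apply_prioritization(evs, pd.concat(diffs), pd.concat(survs),
                                     pd.concat(psis), labels_for(psis[0]))
        crit_cols = [c for c in table.columns if c.startswith("c")]
        short_cols = ["length_in_30_300", "in_cds", "high_tumor_psi"]
        expected = (~table[crit_cols]).all(axis=1) & table[short_cols].all(axis=1)
        assert (table["retained"] == expected).all()
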