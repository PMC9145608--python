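"""Control-anchored gates, marker statistics, quadrants, replicate tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import cytoplate as cp
from cytoplate.gating import GateSet
from conftest import marker_ledger_table, random_cell_table


def table_from_values(values, channel="m"):
    values = np.asarray(values, dtype=float)
    return pd.DataFrame({
        "well_id": "W",
        f"{channel}_integrated": values,
    })


class TestDefineGate:
    def test_degenerate_control_gates_nothing(self):
        ct = table_from_values(np.full(200, 5.0))
        gate = cp.define_gate(ct, "m")
        assert gate.threshold == 5.0
        assert cp.percent_positive(ct, gate).percent_positive == 0.0

    def test_median_quantile_splits_control_in_half(self, rng):
        ct = table_from_values(rng.lognormal(8, 0.5, 10001))
        gate = cp.define_gate(ct, "m", q=0.5)
        pct = cp.percent_positive(ct, gate).percent_positive
        assert pct == pytest.approx(50.0, abs=1.0)

    def test_nominal_false_positive_rate_on_fresh_controls(self, rng):
        """Fresh draws from the CT distribution re-gate at ~1-q positive."""
        dist = lambda n: rng.lognormal(8, 0.5, n)  # noqa: E731
        gate = cp.define_gate(table_from_values(dist(10000)), "m", q=0.99)
        fresh = table_from_values(dist(10000))
        pct = cp.percent_positive(fresh, gate).percent_positive
        # binomial 99.9% CI around 1% at n=10000 is ~±0.33 points
        assert pct == pytest.approx(1.0, abs=0.6)

    def test_too_few_control_cells(self):
        with pytest.raises(ValueError, match="pool"):
            cp.define_gate(table_from_values(np.ones(50)), "m")

    def test_missing_channel(self):
        with pytest.raises(KeyError, match="absent"):
            cp.define_gate(table_from_values(np.ones(200)), "absent")


class TestPercentPositive:
    def test_all_below_threshold(self):
        gate = cp.Gate(channel="m", threshold=10.0)
        stats = cp.percent_positive(table_from_values([1, 2, 9, 10]), gate)
        assert stats.percent_positive == 0.0
        assert np.isnan(stats.mean_integrated_intensity_of_positives)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cp.percent_positive(table_from_values([]), cp.Gate("m", 1.0))

    def test_matches_brute_force_loop(self, rng):
        for _ in range(10):
            tab = random_cell_table(rng, n=int(rng.integers(5, 100)))
            thr = float(rng.lognormal(8, 1.5))
            gate = cp.Gate(channel="a", threshold=thr)
            stats = cp.percent_positive(tab, gate)
            count = sum(1 for v in tab["a_integrated"] if v > thr)
            assert stats.n_positive == count
            assert stats.percent_positive == pytest.approx(100 * count / len(tab))
            if count:
                manual_mean = np.mean(
                    [v for v in tab["a_integrated"] if v > thr]
                )
                assert stats.mean_integrated_intensity_of_positives == \
                    pytest.approx(manual_mean)

    def test_recovers_generator_positive_fraction(self):
        """CT-anchored 0.99 gate on a 50/50 mixture lands within 3 points."""
        tab = marker_ledger_table(seed=0, n=2000, positive_fraction=0.5)
        ct = marker_ledger_table(seed=99, n=2000, positive_fraction=0.0)
        gate = cp.define_gate(ct, "m", q=0.99)
        est = cp.percent_positive(tab, gate).percent_positive
        truth = 100 * tab["m_positive"].mean()
        assert est == pytest.approx(truth, abs=3.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        values=st.lists(st.floats(0, 1e6), min_size=1, max_size=60),
        t1=st.floats(0, 1e6),
        t2=st.floats(0, 1e6),
    )
    def test_raising_threshold_never_raises_percent(self, values, t1, t2):
        lo, hi = sorted((t1, t2))
        tab = table_from_values(values)
        p_lo = cp.percent_positive(tab, cp.Gate("m", lo)).percent_positive
        p_hi = cp.percent_positive(tab, cp.Gate("m", hi)).percent_positive
        assert p_hi <= p_lo


class TestFoldChange:
    @staticmethod
    def _stats(pct):
        return cp.MarkerStats(channel="m", condition="", n_cells=100,
                              percent_positive=pct,
                              mean_integrated_intensity_of_positives=1.0,
                              n_positive=int(pct), threshold=1.0)

    def test_basic_ratio(self):
        assert cp.fold_change(self._stats(40.0), self._stats(20.0)) == 2.0

    def test_identity(self):
        assert cp.fold_change(self._stats(33.0), self._stats(33.0)) == 1.0

    def test_five_fold_double_positive_shift(self):
        # the ~five-fold treated/untreated shift of a double-positive subset
        assert cp.fold_change(self._stats(74.4), self._stats(15.7)) == \
            pytest.approx(4.74, abs=0.01)

    def test_zero_denominator_warns_and_flags_inf(self):
        with pytest.warns(RuntimeWarning, match="undefined"):
            fc = cp.fold_change(self._stats(10.0), self._stats(0.0))
        assert np.isinf(fc)


class TestQuadrantAnalysis:
    @staticmethod
    def _gates(channels, thresholds):
        gs = GateSet()
        for ch, t in zip(channels, thresholds):
            gs.add(cp.Gate(channel=ch, threshold=t))
        return gs

    def test_single_marker_all_positive(self):
        tab = table_from_values(np.full(50, 100.0))
        res = cp.quadrant_analysis(tab, self._gates(["m"], [1.0]))
        assert res.fraction(m=True) == 1.0
        assert res.fraction(m=False) == 0.0

    def test_three_marker_partition_sums_to_one_exactly(self, rng):
        tab = random_cell_table(rng, n=500)
        res = cp.quadrant_analysis(
            tab, self._gates(["a", "b", "c"], rng.lognormal(8, 1, 3))
        )
        assert len(res.table) == 8
        assert res.table["fraction"].sum() == 1.0
        assert res.table["count"].sum() == len(tab)

    def test_marginals_equal_independent_percent_positive(self, rng):
        tab = random_cell_table(rng, n=400)
        gates = self._gates(["a", "b"], rng.lognormal(8, 1, 2))
        res = cp.quadrant_analysis(tab, gates)
        for ch in ("a", "b"):
            indep = cp.percent_positive(tab, gates[ch]).percent_positive
            assert res.marginals[ch] == pytest.approx(indep)
            assert 100 * res.fraction(**{ch: True}) == pytest.approx(indep)

    def test_independent_markers_multiply(self, rng):
        n = 10000
        tab = pd.DataFrame({
            "well_id": "W",
            "a_integrated": rng.normal(0, 1, n),
            "b_integrated": rng.normal(0, 1, n),
        })
        res = cp.quadrant_analysis(tab, self._gates(["a", "b"], [0.0, 0.0]))
        # binomial 99.9% CI around 0.25 at n=10000: ±3.3 sd ≈ ±0.0143
        assert res.fraction(a=True, b=True) == pytest.approx(0.25, abs=0.015)

    def test_duplicate_channels_rejected(self):
        tab = table_from_values(np.ones(10))
        with pytest.raises(ValueError, match="duplicate"):
            cp.quadrant_analysis(tab, [cp.Gate("m", 1.0), cp.Gate("m", 2.0)])


class TestChannelOverlapCheck:
    @staticmethod
    def _single_stain_tables(bleed=0.0, seed=0, n=400):
        """Simulate one single-stained small well per marker through images."""
        import dataclasses

        markers = ["m1", "m2"]
        tables = {}
        for i, stained in enumerate(markers):
            mm = {
                ch: cp.MarkerModel(positive_fraction=1.0 if ch == stained else 0.0)
                for ch in markers
            }
            bt = np.eye(3)
            if bleed:
                bt[1 + i, 1 + (1 - i)] = bleed  # stained marker into the other
            p = cp.WellSimParams(
                n_cells=60, image_shape=(768, 768), marker_models=mm,
                bleedthrough=bt, noise_sd=0.0, seed=seed + i,
            )
            images, _ = cp.simulate_well(p)
            mask = cp.segment_nuclei(images["hoechst"])
            tables[stained] = cp.apply_mask(mask, images)
        return tables

    @staticmethod
    def _ct_gates(markers=("m1", "m2"), seed=50):
        gs = GateSet()
        for i, ch in enumerate(markers):
            ct = marker_ledger_table(seed=seed + i, n=500,
                                     positive_fraction=0.0, channel=ch)
            gs.add(cp.define_gate(ct, ch, q=0.99))
        return gs

    def test_clean_channels_pass(self):
        tables = self._single_stain_tables(bleed=0.0)
        report = cp.channel_overlap_check(tables, self._ct_gates())
        assert report.attrs["passed"]
        assert (report["off_target_percent"] <= report["tolerance_percent"]).all()

    def test_strong_bleedthrough_fails(self):
        tables = self._single_stain_tables(bleed=0.20)
        report = cp.channel_overlap_check(tables, self._ct_gates())
        assert not report.attrs["passed"]

    def test_missing_single_stain_table_lists_markers(self):
        tables = self._single_stain_tables()
        del tables["m2"]
        with pytest.raises(ValueError, match="m2"):
            cp.channel_overlap_check(tables, self._ct_gates())

    def test_empty_gate_set_gives_empty_report(self):
        report = cp.channel_overlap_check({}, GateSet())
        assert len(report) == 0
        assert report.attrs["passed"]


class TestCompareReplicates:
    def test_identical_groups_not_significant(self):
        res = cp.compare_replicates([3.0, 3.0, 3.0], [3.0, 3.0, 3.0])
        assert res.p_value == 1.0
        assert not res.significant

    def test_separated_groups_significant(self):
        res = cp.compare_replicates(
            [0.0, 0.01, -0.01], [10.0, 10.01, 9.99]
        )
        assert res.significant

    def test_matches_textbook_formula(self):
        """Hand-computed pooled-variance t on a 3-vs-3 example."""
        a, b = [1.0, 2.0, 3.0], [2.0, 4.0, 6.0]
        res = cp.compare_replicates(a, b)
        # sp^2 = (2*1 + 2*4)/4 = 2.5; t = -2 / sqrt(2.5 * 2/3)
        assert res.t_statistic == pytest.approx(-2 / np.sqrt(2.5 * 2 / 3))
        assert res.t_statistic == pytest.approx(-1.549193, abs=1e-6)
        assert res.p_value == pytest.approx(0.196261, abs=1e-6)
        assert not res.significant

    def test_requires_two_replicates(self):
        with pytest.raises(ValueError, match="replicates"):
            cp.compare_replicates([1.0], [1.0, 2.0])
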