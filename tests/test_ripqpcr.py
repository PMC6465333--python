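"""Cp arithmetic: % input, fold enrichments, relative expression, QC, aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cotranscoloc.ripqpcr import (
    MissingCp,
    aggregate_replicates,
    fold_enrichment,
    percent_input,
    relative_expression,
    relative_fold_enrichment,
    rt_minus_qc,
)
from cotranscoloc.synthetic import CpSimParams, simulate_cp_table


class TestPercentInput:
    def test_formula_constant_identity(self):
        assert percent_input(26.644, 20.000) == 100.0

    def test_equal_cps(self):
        assert percent_input(20.0, 20.0) == pytest.approx(100 * 2**-6.644)

    def test_exponent_minus_three(self):
        assert percent_input(18.000, 14.356) == pytest.approx(12.5)

    def test_missing_cp_propagates(self):
        with pytest.raises(MissingCp):
            percent_input(float("nan"), 20.0)

    @given(
        cp_in=st.floats(10, 35),
        cp_ip=st.floats(10, 35),
        shift=st.floats(0.1, 5),
    )
    @settings(max_examples=40, deadline=None)
    def test_monotonicity_and_cycle_doubling(self, cp_in, cp_ip, shift):
        base = percent_input(cp_in, cp_ip)
        assert percent_input(cp_in, cp_ip + shift) < base  # decreasing in cp_ip
        assert percent_input(cp_in + shift, cp_ip) > base  # increasing in cp_input
        assert percent_input(cp_in, cp_ip + 1.0) == pytest.approx(base / 2)
        assert percent_input(cp_in, cp_ip - 1.0) == pytest.approx(base * 2)


class TestFoldEnrichment:
    def test_equal_cps_give_one(self):
        fold, method = fold_enrichment(23.0, 23.0)
        assert fold == 1.0 and method == "single_delta"

    def test_single_delta(self):
        assert fold_enrichment(25.0, 28.0)[0] == pytest.approx(8.0)

    def test_double_delta(self):
        fold, method = fold_enrichment(22.0, 25.0, cp_input_ip=20.0, cp_input_mock=21.0)
        assert fold == pytest.approx(4.0) and method == "double_delta"

    def test_one_input_only_is_error(self):
        with pytest.raises(ValueError, match="both"):
            fold_enrichment(22.0, 25.0, cp_input_ip=20.0)

    def test_identity_for_any_cp(self):
        for cp in (15.0, 25.0, 35.0):
            assert fold_enrichment(cp, cp)[0] == 1.0


class TestRelative:
    def test_equal_folds(self):
        assert relative_fold_enrichment(2.0, 2.0) == 1.0

    def test_division(self):
        assert relative_fold_enrichment(8.0, 2.0) == 4.0

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            relative_fold_enrichment(8.0, 0.0)

    def test_recovers_efficiency_ratio_from_simulation(self):
        p = CpSimParams(ip_efficiency={"Taf8": 0.2, "Taf10": 0.05, "Gapdh": 0.05},
                        mock_efficiency=0.001, cp_noise_sd=0.0, n_bio=1, n_tech=1,
                        include_rt_minus=False, seed=0)
        t = simulate_cp_table(p)

        def fe(gene):
            g = t[(t["gene"] == gene)]
            cp = {r: g.loc[g["role"] == r, "cp"].iloc[0] for r in ("ip", "mock")}
            return fold_enrichment(cp["ip"], cp["mock"])[0]

        assert relative_fold_enrichment(fe("Taf8"), fe("Taf10")) == pytest.approx(
            0.2 / 0.05
        )

    def test_relative_expression(self):
        assert relative_expression(20, 20, 20, 20) == 1.0
        assert relative_expression(25, 20, 23, 20) == pytest.approx(0.25)

    def test_simulated_knockdown(self):
        # halving the target abundance at fixed reference: one extra cycle
        cp_t1, cp_t2 = 21.0, 20.0
        assert relative_expression(cp_t1, 18.0, cp_t2, 18.0) == pytest.approx(0.5)


class TestRtMinusQC:
    def _table(self, cp_minus):
        return pd.DataFrame(
            [
                dict(gene="Taf8", role="ip", rt="plus", bio_rep=1, tech_rep=1, cp=20.0),
                dict(gene="Taf8", role="ip", rt="minus", bio_rep=1, tech_rep=1,
                     cp=cp_minus),
            ]
        )

    def test_wide_gap_passes(self):
        report = rt_minus_qc(self._table(35.0))
        assert report["passed"].all()

    def test_narrow_gap_fails(self):
        report = rt_minus_qc(self._table(27.0))
        assert not report["passed"].any()

    def test_undetected_minus_rt_passes(self):
        report = rt_minus_qc(self._table(np.nan))
        assert report["passed"].all()

    def test_no_minus_rows_warns(self):
        t = self._table(35.0)
        with pytest.warns(UserWarning, match="skipped"):
            report = rt_minus_qc(t[t["rt"] == "plus"])
        assert report.empty

    def test_duplicate_rows_rejected(self):
        t = pd.concat([self._table(35.0)] * 2, ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            rt_minus_qc(t)


class TestAggregate:
    def test_single_replicate_sd_undefined(self):
        p = CpSimParams(cp_noise_sd=0.0, n_bio=1, n_tech=1, include_rt_minus=False,
                        seed=0)
        recs = aggregate_replicates(simulate_cp_table(p), "percent_input")
        assert all(r.sd is None for r in recs)
        assert all("SD undefined" in r.note for r in recs)

    def test_identical_replicates_sd_zero(self):
        p = CpSimParams(cp_noise_sd=0.0, n_bio=2, n_tech=2, include_rt_minus=False,
                        seed=0)
        recs = aggregate_replicates(simulate_cp_table(p), "percent_input")
        assert all(r.sd == 0.0 for r in recs)

    def test_noise_free_mean_equals_100x_efficiency(self):
        p = CpSimParams(ip_efficiency=0.10, cp_noise_sd=0.0, n_bio=2, n_tech=2,
                        include_rt_minus=False, seed=0)
        recs = aggregate_replicates(simulate_cp_table(p), "percent_input")
        for r in recs:
            assert r.value == pytest.approx(10.0, abs=1e-9)

    def test_noisy_aggregate_within_three_sd(self):
        sd_cp = 0.2
        p = CpSimParams(ip_efficiency=0.10, cp_noise_sd=sd_cp, n_bio=3, n_tech=2,
                        include_rt_minus=False, seed=12)
        recs = aggregate_replicates(simulate_cp_table(p), "percent_input")
        # percent_input involves a difference of two tech-averaged Cps; the
        # log2 SD of each biological value is sd_cp * sqrt(2/2), and the mean
        # over 3 biological replicates shrinks it by sqrt(3)
        log_sd = sd_cp * np.sqrt(2 / 2) / np.sqrt(3)
        tol = 10.0 * (2 ** (3 * log_sd) - 1)
        for r in recs:
            assert abs(r.value - 10.0) <= tol

    def test_row_order_invariance(self):
        p = CpSimParams(cp_noise_sd=0.3, n_bio=3, n_tech=2, seed=3)
        t = simulate_cp_table(p)
        shuffled = t.sample(frac=1.0, random_state=9).reset_index(drop=True)
        r1 = aggregate_replicates(t, "fold_enrichment")
        r2 = aggregate_replicates(shuffled, "fold_enrichment")
        for a, b in zip(r1, r2):
            assert a.gene == b.gene
            assert a.value == pytest.approx(b.value, rel=1e-12)

    def test_missing_role_reported_incomputable(self):
        p = CpSimParams(cp_noise_sd=0.0, n_bio=1, n_tech=1, include_rt_minus=False,
                        seed=0)
        t = simulate_cp_table(p)
        t = t[~((t["gene"] == "Taf8") & (t["role"] == "ip"))]
        recs = aggregate_replicates(t, "percent_input")
        by_gene = {r.gene: r for r in recs}
        assert np.isnan(by_gene["Taf8"].value)
        assert "missing" in by_gene["Taf8"].note

    def test_qc_failing_combination_excluded(self):
        rows = []
        for role, cp in (("input", 24.0), ("ip", 20.0)):
            for bio in (1, 2):
                rows.append(dict(gene="g", role=role, rt="plus", bio_rep=bio,
                                 tech_rep=1, cp=cp))
                # contaminated -RT for ip only: gap 5 < 10
                minus = cp + (5.0 if role == "ip" else 20.0)
                rows.append(dict(gene="g", role=role, rt="minus", bio_rep=bio,
                                 tech_rep=1, cp=minus))
        recs = aggregate_replicates(pd.DataFrame(rows), "percent_input")
        assert np.isnan(recs[0].value)  # ip rows removed by QC
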