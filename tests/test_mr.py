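"""Instrument selection and Mendelian randomisation estimators."""

import numpy as np
import pytest

from gwaskit import (
    InstrumentSet,
    InsufficientInstrumentsError,
    LDMatrix,
    NoInstrumentsError,
    VariantKey,
    build_instrument_set,
    default_variant_grid,
    fdr_adjust,
    ivw_mr,
    mr_egger,
    select_instruments_cis,
    select_instruments_genomewide,
    wald_ratio,
)

from conftest import make_table, random_ld


def make_instruments(bx, sx, by, sy):
    m = len(bx)
    return InstrumentSet(
        keys=default_variant_grid(m),
        bx=np.asarray(bx, float),
        sx=np.asarray(sx, float),
        by=np.asarray(by, float),
        sy=np.asarray(sy, float),
    )


class TestWaldRatio:
    def test_worked_delta_value(self):
        theta, se = wald_ratio(0.1, 0.01, 0.05, 0.02, "delta")
        assert theta == pytest.approx(0.5)
        assert se == pytest.approx(np.sqrt(0.0425), abs=1e-12)
        assert se == pytest.approx(0.2062, abs=1e-4)

    def test_zero_outcome_effect(self):
        theta, se = wald_ratio(0.2, 0.05, 0.0, 0.03, "delta")
        assert theta == 0.0
        assert se == pytest.approx(0.03 / 0.2)

    def test_delta_se_never_below_first_order(self, rng):
        for _ in range(50):
            bx, sx, by, sy = rng.uniform(0.01, 1, 4)
            _, s1 = wald_ratio(bx, sx, by, sy, "first_order")
            _, s2 = wald_ratio(bx, sx, by, sy, "delta")
            assert s2 >= s1

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(ValueError):
            wald_ratio(0.0, 0.01, 0.1, 0.02)


class TestGreedyPruning:
    def test_fully_dependent_set_keeps_only_best(self):
        m = 5
        ld = LDMatrix(variants=default_variant_grid(m), r=np.ones((m, m)))
        leads = [(v, p, 0.3) for v, p in zip(ld.variants, [1e-9, 1e-12, 1e-10, 1e-8, 1e-11])]
        out = select_instruments_genomewide(leads, ld)
        assert out == [ld.variants[1]]

    def test_fully_independent_set_keeps_all_in_p_order(self):
        m = 4
        ld = LDMatrix(variants=default_variant_grid(m), r=np.eye(m))
        ps = [1e-9, 1e-12, 1e-10, 1e-8]
        leads = [(v, p, 0.3) for v, p in zip(ld.variants, ps)]
        out = select_instruments_genomewide(leads, ld)
        assert [ps[ld.index_of(k)] for k in out] == sorted(ps)
        assert len(out) == 4

    def test_low_maf_candidates_excluded(self):
        m = 3
        ld = LDMatrix(variants=default_variant_grid(m), r=np.eye(m))
        leads = [
            (ld.variants[0], 1e-9, 0.3),
            (ld.variants[1], 1e-12, 0.005),  # below MAF > 1%
            (ld.variants[2], 1e-10, 0.02),
        ]
        out = select_instruments_genomewide(leads, ld)
        assert ld.variants[1] not in out and len(out) == 2

    def test_certification_on_random_ld(self, rng):
        for _ in range(20):
            m = int(rng.integers(5, 40))
            ld = random_ld(rng, m)
            leads = [(v, p, 0.3) for v, p in zip(ld.variants, rng.uniform(1e-12, 1e-8, m))]
            out = select_instruments_genomewide(leads, ld, r2_thresh=0.05)
            for i in range(len(out)):
                for j in range(i + 1, len(out)):
                    assert ld.r2_between(out[i], out[j]) < 0.05


class TestCisSelection:
    def test_window_and_significance_restriction(self, rng):
        m = 50
        table = make_table(
            np.full(m, 0.5), np.full(m, 0.05), positions=1_000 + 10_000 * np.arange(m)
        )
        ld = LDMatrix(
            variants=table.keys(), r=np.eye(m)
        )
        gene = ("1", 200_000, 250_000)
        out = select_instruments_cis(table, gene, ld, window=50_000)
        for k in out:
            assert 150_000 <= k.pos <= 300_000

    def test_single_significant_variant(self):
        table = make_table([0.5, 0.01], [0.05, 0.05], positions=[10_000, 20_000])
        ld = LDMatrix(variants=table.keys(), r=np.eye(2))
        out = select_instruments_cis(table, ("1", 5_000, 25_000), ld, window=10_000)
        assert out == [table.keys()[0]]

    def test_three_independent_signals_all_selected(self, rng):
        # block-diagonal LD: three tight blocks, independent across blocks
        block = np.full((5, 5), 0.95)
        np.fill_diagonal(block, 1.0)
        r = np.kron(np.eye(3), block)
        m = 15
        variants = default_variant_grid(m)
        ld = LDMatrix(variants=variants, r=r)
        table = make_table(
            np.full(m, 0.5), np.full(m, 0.05),
            positions=[v.pos for v in variants],
        )
        out = select_instruments_cis(table, ("1", 1_000, 15_000), ld, window=10_000)
        assert len(out) == 3
        # brute-force post-condition: pairwise r2 < 0.01 and every candidate
        # is either selected or in LD with a selected instrument
        for i in range(3):
            for j in range(i + 1, 3):
                assert ld.r2_between(out[i], out[j]) < 0.01
        for v in variants:
            assert any(ld.r2_between(v, k) >= 0.01 for k in out)

    def test_empty_candidates_raise_typed_error(self):
        table = make_table([0.001], [0.05])
        ld = LDMatrix(variants=table.keys(), r=np.eye(1))
        with pytest.raises(NoInstrumentsError):
            select_instruments_cis(table, ("1", 5_000, 6_000), ld, window=100)


class TestIVW:
    def test_identical_ratios_have_zero_heterogeneity(self):
        inst = make_instruments([0.2, 0.4, 0.5], [0.01] * 3, [0.1, 0.2, 0.25], [0.02] * 3)
        est = ivw_mr(inst, "first_order")
        assert est.beta == pytest.approx(0.5)
        assert est.Q == pytest.approx(0.0, abs=1e-20)
        # zero heterogeneity: multiplicative scale floored at 1
        w = np.array([0.2, 0.4, 0.5]) ** 2 / 0.02**2
        assert est.se == pytest.approx(1 / np.sqrt(w.sum()))

    def test_hand_arithmetic_two_instruments(self):
        # theta = (0.2, 0.4), per-ratio se = 0.1 -> w = 100 each
        inst = make_instruments([1.0, 1.0], [1e-6] * 2, [0.2, 0.4], [0.1] * 2)
        est = ivw_mr(inst, "first_order")
        assert est.beta == pytest.approx(0.3)
        assert est.Q == pytest.approx(2.0)
        assert est.Q_df == 1
        se0 = 1 / np.sqrt(200)
        assert est.se == pytest.approx(se0 * np.sqrt(2))

    def test_single_instrument_degrades_to_wald(self):
        inst = make_instruments([0.1], [0.01], [0.05], [0.02])
        est = ivw_mr(inst, "delta")
        assert est.single_instrument
        theta, se = wald_ratio(0.1, 0.01, 0.05, 0.02, "delta")
        assert est.beta == pytest.approx(theta)
        assert est.se == pytest.approx(se)

    def test_scale_equivariance_with_repeated_instrument(self):
        base = make_instruments([0.2] * 3, [0.01] * 3, [0.1] * 3, [0.02] * 3)
        scaled = make_instruments([0.4] * 3, [0.01] * 3, [0.1] * 3, [0.02] * 3)
        b1 = ivw_mr(base, "first_order").beta
        b2 = ivw_mr(scaled, "first_order").beta
        assert b2 == pytest.approx(b1 / 2.0)

    def test_mre_se_never_below_fixed_effect(self, rng):
        for _ in range(20):
            J = int(rng.integers(2, 30))
            inst = make_instruments(
                rng.uniform(0.1, 0.5, J), rng.uniform(0.005, 0.02, J),
                rng.normal(0.1, 0.05, J), rng.uniform(0.01, 0.05, J),
            )
            est = ivw_mr(inst, "delta")
            theta = inst.by / inst.bx
            var = inst.sy**2 / inst.bx**2 + inst.by**2 * inst.sx**2 / inst.bx**4
            se_fixed = 1 / np.sqrt(np.sum(1 / var))
            assert est.se >= se_fixed - 1e-15
            assert est.ci_low <= est.beta <= est.ci_high


class TestEgger:
    def test_collinear_points_fit_exactly(self):
        # by = 0.03 + 0.5 bx exactly: residual Q = 0
        bx = np.array([0.1, 0.2, 0.3])
        by = 0.03 + 0.5 * bx
        inst = make_instruments(bx, [0.01] * 3, by, [0.02] * 3)
        est = mr_egger(inst)
        assert est.Q == pytest.approx(0.0, abs=1e-18)
        assert est.beta == pytest.approx(0.5)
        assert est.intercept == pytest.approx(0.03)

    def test_requires_three_instruments(self):
        inst = make_instruments([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.02] * 2)
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger(inst)

    def test_orientation_invariance(self, rng):
        # flipping the reported allele of some instruments must not change the fit
        J = 20
        bx = rng.uniform(0.1, 0.4, J)
        by = 0.02 + 0.5 * bx + rng.normal(0, 0.01, J)
        inst = make_instruments(bx, np.full(J, 0.01), by, np.full(J, 0.02))
        flip = rng.random(J) < 0.5
        sign = np.where(flip, -1.0, 1.0)
        flipped = make_instruments(bx * sign, np.full(J, 0.01), by * sign, np.full(J, 0.02))
        e1, e2 = mr_egger(inst), mr_egger(flipped)
        assert e1.beta == pytest.approx(e2.beta, abs=1e-12)
        assert e1.intercept == pytest.approx(e2.intercept, abs=1e-12)

    def test_constant_pleiotropy_lands_in_intercept(self, rng):
        J = 50
        bx_true = rng.uniform(0.1, 0.5, J)
        bx = bx_true + rng.normal(0, 0.005, J)
        by = 0.5 * bx_true + 0.05 + rng.normal(0, 0.01, J)
        inst = make_instruments(bx, np.full(J, 0.005), by, np.full(J, 0.01))
        est = mr_egger(inst)
        assert est.intercept == pytest.approx(0.05, abs=0.01)
        assert est.ci_low <= 0.5 <= est.ci_high

    def test_slope_without_intercept_equals_ivw(self, rng):
        # constrained-intercept WLS of by on bx with 1/sy^2 weights is
        # algebraically the first-order IVW estimate
        J = 15
        bx = rng.uniform(0.1, 0.5, J)
        by = 0.4 * bx + rng.normal(0, 0.02, J)
        sy = rng.uniform(0.01, 0.05, J)
        inst = make_instruments(bx, np.full(J, 1e-8), by, sy)
        w = 1 / sy**2
        slope_no_intercept = np.sum(w * bx * by) / np.sum(w * bx**2)
        est = ivw_mr(inst, "first_order")
        assert est.beta == pytest.approx(slope_no_intercept, abs=1e-10)


class TestBuildInstrumentSet:
    def test_outcome_harmonised_and_missing_dropped(self, rng):
        exp = make_table([0.3, 0.4, 0.5], [0.02] * 3)
        out_df = exp.df.iloc[:2].copy()
        out_df["effect_allele"] = "A"  # opposite orientation
        out_df["beta"] = [-0.15, -0.2]
        out_df["eaf"] = 0.7
        from gwaskit import SummaryStatsTable

        outcome = SummaryStatsTable(df=out_df)
        inst = build_instrument_set(exp, outcome, exp.keys())
        assert len(inst) == 2
        assert inst.n_dropped_unmatched == 1
        assert np.allclose(inst.by, [0.15, 0.2])  # flipped back to exposure allele

    def test_no_shared_instruments_raises(self):
        exp = make_table([0.3], [0.02])
        outcome = make_table([0.3], [0.02], positions=[99_000])
        with pytest.raises(NoInstrumentsError):
            build_instrument_set(exp, outcome, exp.keys())


class TestFDR:
    def test_all_ones_flag_nothing(self):
        assert not fdr_adjust([1.0, 1.0, 1.0]).any()

    def test_single_p_reduces_to_raw_threshold(self):
        assert fdr_adjust([0.01], q=0.05).all()
        assert not fdr_adjust([0.06], q=0.05).any()

    def test_hand_step_up_example(self):
        flags = fdr_adjust([0.001, 0.01, 0.02, 0.8], q=0.05)
        assert flags.tolist() == [True, True, True, False]

    def test_flags_monotone_in_p(self, rng):
        p = rng.uniform(0.0001, 1, 50)
        flags = fdr_adjust(p)
        if flags.any():
            assert p[flags].max() <= p[~flags].min() or not (~flags).any()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.0, 0.5])
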