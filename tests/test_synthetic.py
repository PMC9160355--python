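import numpy as np
import pytest
from scipy import stats

from rhoterm.bubble_scan import detect_bubbles, window_profile
from rhoterm.errors import ValidationError
from rhoterm.qpcr import classify_strength, fold_change_from_ct
from rhoterm.synthetic import (
    BubbleSpec,
    MotifChainSpec,
    gen_correlated_pairs,
    gen_ct_table,
    gen_kinetic_series,
    gen_sequence_with_planted_features,
)


class TestSequenceGenerator:
    def test_same_seed_identical_output(self):
        args = dict(
            length=800,
            bubbles=[BubbleSpec(100, 200, 25.0)],
            motifs=[MotifChainSpec(500, 2, (11,))],
            pauses=[700],
        )
        a, _ = gen_sequence_with_planted_features(seed=42, **args)
        b, _ = gen_sequence_with_planted_features(seed=42, **args)
        c, _ = gen_sequence_with_planted_features(seed=43, **args)
        assert a.residues == b.residues
        assert a.residues != c.residues

    def test_planted_bubble_detected_overlapping_location(self):
        rec, _ = gen_sequence_with_planted_features(
            1000, [BubbleSpec(300, 300, 30.0)], seed=7
        )
        bubbles = detect_bubbles(window_profile(rec, 78, 10), threshold=15.0)
        assert any(b.start < 600 and b.end > 300 for b in bubbles)

    def test_realized_amplitude_near_target(self):
        diffs = []
        for seed in range(30):
            rec, _ = gen_sequence_with_planted_features(
                1000, [BubbleSpec(300, 300, 30.0)], seed=seed
            )
            p = window_profile(rec, 78, 10)
            inside = [
                d for s, d in zip(p.starts, p.diff) if 300 <= s and s + 78 <= 600
            ]
            diffs.append(np.mean(inside))
        assert np.mean(diffs) == pytest.approx(30.0, abs=3.0)

    def test_background_composition_balanced(self):
        rec, _ = gen_sequence_with_planted_features(20_000, seed=1)
        counts = {b: rec.residues.count(b) for b in "ACGT"}
        for b in "ACGT":
            assert counts[b] / 20_000 == pytest.approx(0.25, abs=0.02)

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ValidationError):
            gen_sequence_with_planted_features(
                100, [BubbleSpec(50, 100, 20.0)], seed=0
            )
        with pytest.raises(ValidationError):
            gen_sequence_with_planted_features(
                500, [BubbleSpec(0, 300, 20.0), BubbleSpec(200, 100, 20.0)], seed=0
            )

    def test_false_positive_bubble_rates_on_featureless_background(self):
        """Composition noise alone yields ~half of windows positive at the
        bare %C > %G rule, a few short spurious bubbles per kb at half a
        typical planted amplitude, and ~none at the full amplitude."""
        at_zero, at_half, at_full = [], [], []
        for seed in range(100):
            rec, _ = gen_sequence_with_planted_features(1000, seed=seed)
            p = window_profile(rec, 78, 10)
            at_zero.append(len(detect_bubbles(p)))
            at_half.append(len(detect_bubbles(p, threshold=15.0)))
            at_full.append(len(detect_bubbles(p, threshold=30.0)))
        assert np.mean(at_zero) > 3  # the bare rule is noise-dominated
        assert np.mean(at_half) < 4
        assert np.mean(at_full) < 0.05


class TestCtGenerator:
    def test_noiseless_roundtrip_all_fold_changes(self):
        truth = {"a": 1.0, "b": 2.0, "c": 4.0, "d": 10.0, "e": 30.0, "f": 66.6}
        recs, _ = gen_ct_table(truth, replicates=3, ct_noise_sd=0.0, seed=2)
        for gene, fc in truth.items():
            got = fold_change_from_ct(recs, gene, "rho_N340S").mean_fc
            assert got == pytest.approx(fc, rel=1e-9)

    def test_reference_ct_invariant_across_strains(self):
        recs, _ = gen_ct_table({"a": 4.0}, seed=3)
        assert len({r.ct_reference for r in recs}) == 1

    def test_unity_fold_change_classifies_weak(self):
        recs, _ = gen_ct_table(
            {g: 1.0 for g in "abcd"}, replicates=4, ct_noise_sd=0.1, seed=4
        )
        for g in "abcd":
            fc = fold_change_from_ct(recs, g, "rho_N340S")
            assert classify_strength(fc).value == "weak_or_non"

    def test_pinned_wt_baseline_shared_across_tables(self):
        wt = {"a": 5.0}
        r1, _ = gen_ct_table({"a": 8.0}, strain="m1", ct_noise_sd=0.0, seed=1,
                             wt_delta_ct=wt)
        r2, _ = gen_ct_table({"a": 2.0}, strain="m2", ct_noise_sd=0.0, seed=9,
                             wt_delta_ct=wt)
        pooled = r1 + [r for r in r2 if r.strain == "m2"]
        assert fold_change_from_ct(pooled, "a", "m2").mean_fc == pytest.approx(2.0)


class TestCorrelatedPairs:
    def test_extreme_r2_fits_near_one(self):
        pairs, _ = gen_correlated_pairs(100, 0.999, seed=0)
        from rhoterm.assoc import linear_fit

        x, y = zip(*pairs)
        assert linear_fit(x, y).r2 > 0.99

    def test_null_p_values_uniform(self):
        """At true r2 = 0 the slope p-values are Uniform(0,1) (KS test)."""
        from rhoterm.assoc import linear_fit

        ps = []
        for seed in range(300):
            pairs, _ = gen_correlated_pairs(20, 0.0, seed=seed)
            x, y = zip(*pairs)
            ps.append(linear_fit(x, y).p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_invalid_r2_rejected(self):
        with pytest.raises(ValidationError):
            gen_correlated_pairs(10, 1.0, seed=0)


class TestKineticSeriesGenerator:
    def test_noiseless_decay_matches_model(self):
        df, truth = gen_kinetic_series(
            "decay", {"A": 50.0, "lam": 0.25}, design=[0, 1, 2, 4], noise=0.0
        )
        assert truth.decay_params == (50.0, 0.25)
        np.testing.assert_allclose(
            df.signal, 50.0 * np.exp(-0.25 * df.t_min), rtol=1e-12
        )

    def test_binding_truth_recorded(self):
        df, truth = gen_kinetic_series(
            "binding", {"bmax": 1.0, "kd": 5.0, "n": 2.0},
            design=[1, 2, 5, 10, 20], noise=0.0,
        )
        assert truth.binding_params == (1.0, 5.0, 2.0)
        assert df.frac_bound.iloc[-1] > 0.9

    def test_seed_reproducibility(self):
        a, _ = gen_kinetic_series("decay", {"A": 1.0, "lam": 0.1},
                                  design=[0, 1, 2, 3], noise=0.1, seed=5)
        b, _ = gen_kinetic_series("decay", {"A": 1.0, "lam": 0.1},
                                  design=[0, 1, 2, 3], noise=0.1, seed=5)
        assert a.equals(b)
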