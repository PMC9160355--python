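import numpy as np
import pytest

from oracles import brute_bubbles, brute_profile
from rhoterm.bubble_scan import WindowProfile, detect_bubbles, window_profile
from rhoterm.errors import TooShortError
from rhoterm.synthetic import BubbleSpec, gen_sequence_with_planted_features


def _profile_from_diff(diff, window=70, step=10):
    diff = np.asarray(diff, dtype=float)
    return WindowProfile(
        window_size=window, step=step,
        starts=np.arange(len(diff)) * step,
        pctC=np.maximum(diff, 0.0), pctG=np.maximum(-diff, 0.0), diff=diff,
    )


class TestWindowProfile:
    def test_homopolymer_single_window(self):
        p = window_profile("C" * 70, 70, 10)
        assert p.n_windows == 1
        assert p.pctC[0] == 100 and p.pctG[0] == 0 and p.diff[0] == 100

    def test_window_count_formula(self):
        p = window_profile("A" * 100, 70, 10)
        assert list(p.starts) == [0, 10, 20, 30]

    def test_balanced_cg_repeat_zero_diff(self):
        p = window_profile("CG" * 50, 70, 10)
        assert np.all(p.pctC == 50) and np.all(p.pctG == 50)
        assert np.all(p.diff == 0)

    def test_ambiguity_codes_count_as_neither(self):
        p = window_profile("N" * 35 + "C" * 35, 70, 10)
        assert p.pctC[0] == 50 and p.pctG[0] == 0

    def test_too_short_sequence(self):
        with pytest.raises(TooShortError):
            window_profile("ACGT", 70, 10)

    def test_matches_brute_force_oracle(self, random_sequences):
        for seq in random_sequences[:20]:
            p = window_profile(seq, 70, 10)
            oracle = brute_profile(seq, 70, 10)
            assert p.n_windows == len(oracle)
            for k, (s, pc, pg, d) in enumerate(oracle):
                assert p.starts[k] == s
                assert p.pctC[k] == pytest.approx(pc)
                assert p.diff[k] == pytest.approx(d)


class TestDetectBubbles:
    def test_two_run_example(self):
        """diff [0,5,10,5,0,-3,4,6] -> runs over windows 1-3 and 6-7."""
        bubbles = detect_bubbles(_profile_from_diff([0, 5, 10, 5, 0, -3, 4, 6]))
        assert len(bubbles) == 2
        b1, b2 = bubbles
        assert (b1.first_window, b1.last_window) == (1, 3)
        assert b1.length == 90 and b1.area == pytest.approx(200.0)
        assert (b2.first_window, b2.last_window) == (6, 7)
        assert b2.length == 80 and b2.area == pytest.approx(100.0)

    def test_homopolymer_single_full_bubble(self):
        p = window_profile("C" * 200, 70, 10)
        (b,) = detect_bubbles(p)
        assert b.first_window == 0 and b.last_window == p.n_windows - 1
        assert b.avg_diff == b.max_diff == 100

    def test_no_positive_windows_empty(self):
        assert detect_bubbles(_profile_from_diff([0, -1, -5, 0])) == []

    def test_zero_diff_breaks_runs(self):
        """Qualification is strictly diff > 0; a 0 window splits a bubble."""
        bubbles = detect_bubbles(_profile_from_diff([3, 0, 3]))
        assert [(b.first_window, b.last_window) for b in bubbles] == [(0, 0), (2, 2)]

    @pytest.mark.parametrize("extent", ["footprint", "center"])
    def test_matches_brute_force_on_random_sequences(
        self, random_sequences, extent
    ):
        """Bubble runs equal an independent enumeration on random DNA."""
        for seq in random_sequences[:30]:
            p = window_profile(seq, 70, 10)
            got = detect_bubbles(p, extent=extent)
            expected = brute_bubbles(seq, 70, 10, extent=extent)
            assert len(got) == len(expected)
            for b, (i, j, s, e, ln, area, mx, mpc, av) in zip(got, expected):
                assert (b.first_window, b.last_window) == (i, j)
                assert (b.start, b.end, b.length) == (s, e, ln)
                assert b.area == pytest.approx(area)
                assert b.max_diff == pytest.approx(mx)
                assert b.max_pctC == pytest.approx(mpc)
                assert b.avg_diff == pytest.approx(av)

    def test_positive_windows_exactly_covered(self, random_sequences):
        """Union of bubble window ranges == the set of diff>0 windows."""
        for seq in random_sequences[:30]:
            p = window_profile(seq, 70, 10)
            covered = set()
            for b in detect_bubbles(p):
                covered.update(range(b.first_window, b.last_window + 1))
            assert covered == set(np.flatnonzero(p.diff > 0).tolist())

    def test_length_overhang_bounds(self, random_sequences):
        """Footprint lengths stay inside the sequence with bounded overhang;
        center-convention extents are disjoint and tile within L_t."""
        for seq in random_sequences[:30]:
            p = window_profile(seq, 70, 10)
            footprint = detect_bubbles(p)
            n_pos = int((p.diff > 0).sum())
            for b in footprint:
                assert 0 <= b.start < b.end <= len(seq)
                n_run = b.last_window - b.first_window + 1
                assert b.length == n_run * 10 + 60  # quantized + overhang
            assert sum(b.length for b in footprint) <= n_pos * 10 + len(footprint) * 60
            center = detect_bubbles(p, extent="center")
            assert sum(b.length for b in center) <= len(seq)
            for a, b in zip(center, center[1:]):
                assert a.end <= b.start

    def test_avg_diff_bounded_by_max_diff(self, random_sequences):
        for seq in random_sequences[:30]:
            for b in detect_bubbles(window_profile(seq, 70, 10)):
                assert b.avg_diff <= b.max_diff + 1e-12
                assert b.length > 0 and b.area > 0

    def test_inserting_c_inside_bubble_grows_area(self):
        """Monotonicity: turning A->C inside a planted bubble cannot shrink it."""
        rec, _ = gen_sequence_with_planted_features(
            600, [BubbleSpec(150, 200, 25.0)], seed=3
        )
        p = window_profile(rec.residues, 70, 10)
        base = max(detect_bubbles(p), key=lambda b: b.area)
        s = list(rec.residues)
        changed = [i for i in range(200, 320) if s[i] == "A"][:15]
        for i in changed:
            s[i] = "C"
        p2 = window_profile("".join(s), 70, 10)
        richer = max(detect_bubbles(p2), key=lambda b: b.area)
        assert richer.area >= base.area
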