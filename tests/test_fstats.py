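"""Site-pattern statistics against brute-force oracles and exact identities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from conftest import freq_table
from mosaicscan.fstats import (
    UndefinedStatisticError,
    block_jackknife,
    dxy,
    dxy_alignment,
    f2,
    f3,
    f4,
    f4_ratio,
    fd_statistic,
    patterson_d,
    scan_windows,
)
from mosaicscan.popio import GenomicWindow, WindowAlignment


def brute_force_d(p1, p2, p3, po):
    """Independent spreadsheet-style oracle: explicit per-site loop."""
    abba = baba = 0.0
    for a, b, c, d in zip(p1, p2, p3, po):
        abba += (1 - a) * b * c * (1 - d)
        baba += a * (1 - b) * c * (1 - d)
    return (abba - baba) / (abba + baba)


class TestPattersonD:
    def test_zero_when_p1_equals_p2(self):
        t = freq_table({"P1": [0.2, 0.5, 0.9], "P2": [0.2, 0.5, 0.9],
                        "P3": [0.3, 0.6, 0.1], "O": [0.0, 0.0, 0.0]})
        assert patterson_d(t, "P1", "P2", "P3", "O").estimate == pytest.approx(0.0)

    def test_single_pure_abba_site(self):
        t = freq_table({"P1": [0.0], "P2": [1.0], "P3": [1.0], "O": [0.0]})
        assert patterson_d(t, "P1", "P2", "P3", "O").estimate == pytest.approx(1.0)

    def test_four_site_table_matches_oracle(self):
        cols = {
            "P1": [0.0, 1.0, 0.2, 0.5],
            "P2": [0.5, 0.0, 0.8, 0.5],
            "P3": [0.5, 1.0, 0.5, 0.9],
            "O": [0.0, 0.0, 0.0, 0.0],
        }
        expected = brute_force_d(cols["P1"], cols["P2"], cols["P3"], cols["O"])
        got = patterson_d(freq_table(cols), "P1", "P2", "P3", "O")
        assert got.estimate == pytest.approx(expected)
        assert got.n_sites == 4

    def test_missing_sites_skipped(self):
        cols = {"P1": [0.0, math.nan], "P2": [1.0, 0.5], "P3": [1.0, 0.5], "O": [0.0, 0.0]}
        got = patterson_d(freq_table(cols), "P1", "P2", "P3", "O")
        assert got.n_sites == 1
        assert got.estimate == pytest.approx(1.0)

    def test_zero_denominator_raises(self):
        t = freq_table({"P1": [0.0], "P2": [0.0], "P3": [0.0], "O": [0.0]})
        with pytest.raises(UndefinedStatisticError, match="denominator"):
            patterson_d(t, "P1", "P2", "P3", "O")

    def test_swapping_p1_p2_negates_d(self, rng):
        cols = {k: rng.uniform(0, 1, 50) for k in ("P1", "P2", "P3", "O")}
        t = freq_table(cols)
        d12 = patterson_d(t, "P1", "P2", "P3", "O").estimate
        d21 = patterson_d(t, "P2", "P1", "P3", "O").estimate
        assert d12 == pytest.approx(-d21)
        assert -1.0 <= d12 <= 1.0

    def test_general_formula_coincides_under_polarization(self, rng):
        cols = {k: rng.uniform(0, 1, 30) for k in ("P1", "P2", "P3")}
        cols["O"] = np.zeros(30)
        t = freq_table(cols)
        assert patterson_d(t, "P1", "P2", "P3", "O").estimate == pytest.approx(
            patterson_d(t, "P1", "P2", "P3", "O", general=True).estimate
        )


class TestFStatistics:
    def test_f4_with_repeated_population_is_zero(self, rng):
        cols = {k: rng.uniform(0, 1, 20) for k in ("A", "B", "C", "D")}
        t = freq_table(cols)
        assert f4(t, "A", "B", "C", "C").estimate == pytest.approx(0.0)
        assert f4(t, "A", "A", "C", "D").estimate == pytest.approx(0.0)

    def test_f2_nonnegative_zero_iff_identical(self, rng):
        cols = {"A": rng.uniform(0, 1, 20), "B": rng.uniform(0, 1, 20)}
        t = freq_table(cols)
        assert f2(t, "A", "B").estimate > 0
        t2 = freq_table({"A": cols["A"], "B": cols["A"]})
        assert f2(t2, "A", "B").estimate == pytest.approx(0.0)

    def test_five_site_f3_f4_match_oracle(self):
        cols = {
            "X": [0.1, 0.9, 0.5, 0.3, 0.7],
            "A": [0.0, 0.8, 0.6, 0.3, 0.2],
            "B": [0.2, 1.0, 0.1, 0.9, 0.7],
            "C": [0.5, 0.5, 0.5, 0.0, 1.0],
        }
        f3_oracle = np.mean([(x - a) * (x - b) for x, a, b in zip(cols["X"], cols["A"], cols["B"])])
        f4_oracle = np.mean([(x - a) * (b - c) for x, a, b, c in
                             zip(cols["X"], cols["A"], cols["B"], cols["C"])])
        t = freq_table(cols)
        assert f3(t, "X", "A", "B").estimate == pytest.approx(f3_oracle)
        assert f4(t, "X", "A", "B", "C").estimate == pytest.approx(f4_oracle)

    @settings(max_examples=25, deadline=None)
    @given(
        arrays(float, (12, 5), elements=st.floats(0, 1, allow_nan=False, width=32))
    )
    def test_f4_additivity_exact(self, freq):
        t = freq_table({p: freq[:, i] for i, p in enumerate("ABCDE")})
        lhs = f4(t, "A", "B", "C", "D").estimate
        rhs = f4(t, "A", "B", "C", "E").estimate + f4(t, "A", "B", "E", "D").estimate
        assert lhs == pytest.approx(rhs, abs=1e-12)


class TestBlockJackknife:
    def test_zero_variance_flagged(self):
        cols = {"P1": [0.0] * 9, "P2": [1.0] * 9, "P3": [1.0] * 9, "O": [0.0] * 9}
        r = block_jackknife(freq_table(cols), "D", ("P1", "P2", "P3", "O"), n_blocks=3)
        assert r.se == 0.0
        assert math.isnan(r.z)
        assert r.significant() is None

    def test_three_block_closed_form(self):
        # one site per block with p1=1/2, p2=(1+d)/2, p3=1, pO=0:
        # ABBA-BABA = d/2 and ABBA+BABA = 1/2, so per-block D = d with
        # equal block weights
        per_block = [0.1, 0.2, 0.3]
        cols = {
            "P1": [0.5] * 3,
            "P2": [(1 + d) / 2 for d in per_block],
            "P3": [1.0] * 3,
            "O": [0.0] * 3,
        }
        r = block_jackknife(freq_table(cols), "D", ("P1", "P2", "P3", "O"), n_blocks=3)
        # hand computation of the delete-one jackknife
        loo = [(sum(per_block) - d) / 2.0 for d in per_block]
        m = 3
        se = math.sqrt((m - 1) / m * sum((x - np.mean(loo)) ** 2 for x in loo))
        assert r.estimate == pytest.approx(np.mean(per_block))
        assert r.se == pytest.approx(se)
        assert r.z == pytest.approx(r.estimate / se)

    def test_empty_denominator_block_merged(self):
        cols = {
            "P1": [0.0, 0.0, 0.0, 0.0],
            "P2": [0.0, 0.0, 1.0, 1.0],
            "P3": [0.0, 0.0, 1.0, 1.0],
            "O": [0.0, 0.0, 0.0, 0.0],
        }
        # blocks of 2: first block has zero denominator -> merged, SE defined over rest
        r = block_jackknife(freq_table(cols), "D", ("P1", "P2", "P3", "O"), n_blocks=2)
        assert r.estimate == pytest.approx(1.0)


class TestF4Ratio:
    def test_boundaries(self, rng):
        a = rng.uniform(0, 1, 200)
        o = np.zeros(200)
        b = rng.uniform(0, 1, 200)
        c = rng.uniform(0, 1, 200)
        t = freq_table({"A": a, "O": o, "X": b, "B": b, "C": c})
        assert f4_ratio(t, "A", "O", "X", "B", "C").estimate == pytest.approx(1.0)
        t = freq_table({"A": a, "O": o, "X": c, "B": b, "C": c})
        assert f4_ratio(t, "A", "O", "X", "B", "C").estimate == pytest.approx(0.0)

    def test_tiny_denominator_raises(self):
        t = freq_table({"A": [0.5], "O": [0.5], "X": [0.1], "B": [0.3], "C": [0.3]})
        with pytest.raises(UndefinedStatisticError):
            f4_ratio(t, "A", "O", "X", "B", "C")


class TestDxy:
    def test_identical_monomorphic(self):
        t = freq_table({"X": [0.0, 1.0], "Y": [0.0, 1.0]})
        assert dxy(t, "X", "Y", accessible_length=2) == pytest.approx(0.0)

    def test_two_single_sequences(self):
        aln = WindowAlignment(
            GenomicWindow("c", 0, 10),
            [("x", "X", "AAAAAAAAAA"), ("y", "Y", "TTTAAAAAAA")],
        )
        assert dxy_alignment(aln, "X", "Y") == pytest.approx(0.3)

    def test_symmetry_and_monotonicity(self, rng):
        x = rng.uniform(0, 1, 30)
        y = rng.uniform(0, 1, 30)
        t = freq_table({"X": x, "Y": y})
        assert dxy(t, "X", "Y") == pytest.approx(dxy(t, "Y", "X"))
        # adding a differing site cannot decrease span-normalised numerator
        t_more = freq_table({"X": np.append(x, 0.0), "Y": np.append(y, 1.0)})
        L = 31
        assert dxy(t_more, "X", "Y", accessible_length=L) >= dxy(t, "X", "Y", accessible_length=L)

    def test_empty_window_gives_missing(self):
        t = freq_table({"X": [math.nan], "Y": [0.5]})
        assert math.isnan(dxy(t, "X", "Y"))


class TestFd:
    def test_complete_sharing_gives_one(self):
        shared = [0.8, 0.6, 0.9]
        t = freq_table({"P1": [0.1, 0.0, 0.2], "P2": shared, "P3": shared,
                        "O": [0.0, 0.0, 0.0]})
        fd, s, s_d = fd_statistic(t, "P1", "P2", "P3", "O")
        assert s > 0
        assert fd == pytest.approx(1.0)

    def test_p1_equals_p2_gives_missing(self):
        t = freq_table({"P1": [0.3, 0.5], "P2": [0.3, 0.5], "P3": [0.9, 0.8],
                        "O": [0.0, 0.0]})
        fd, s, _ = fd_statistic(t, "P1", "P2", "P3", "O")
        assert s == pytest.approx(0.0)
        assert math.isnan(fd)

    def test_six_site_window_matches_oracle(self):
        cols = {
            "P1": [0.0, 0.1, 0.5, 0.2, 0.0, 0.3],
            "P2": [0.9, 0.8, 0.5, 0.6, 1.0, 0.1],
            "P3": [1.0, 0.7, 0.9, 0.3, 0.8, 0.2],
            "O": [0.0, 0.0, 0.1, 0.0, 0.0, 0.0],
        }
        # independent site-by-site oracle
        s = s_d = 0.0
        for a, b, c, d in zip(cols["P1"], cols["P2"], cols["P3"], cols["O"]):
            s += (1 - a) * b * c * (1 - d) - a * (1 - b) * c * (1 - d)
            pd_ = max(b, c)
            s_d += (1 - a) * pd_ * pd_ * (1 - d) - a * (1 - pd_) * pd_ * (1 - d)
        fd, got_s, got_sd = fd_statistic(freq_table(cols), "P1", "P2", "P3", "O")
        assert got_s == pytest.approx(s)
        assert got_sd == pytest.approx(s_d)
        assert fd == pytest.approx(s / s_d)

    def test_fd_at_most_one_when_p2_dominates(self, rng):
        p1 = rng.uniform(0, 0.3, 40)
        p2 = np.clip(p1 + rng.uniform(0, 0.7, 40), 0, 1)
        cols = {"P1": p1, "P2": p2, "P3": rng.uniform(0, 1, 40), "O": np.zeros(40)}
        fd, s, _ = fd_statistic(freq_table(cols), "P1", "P2", "P3", "O")
        if not math.isnan(fd):
            assert fd <= 1.0 + 1e-12


class TestScanWindows:
    def test_five_windows_per_megabase(self, rng):
        n = 100
        t = freq_table({"X": rng.uniform(0, 1, n), "Y": rng.uniform(0, 1, n)})
        t.pos[:] = np.sort(rng.choice(1_000_000, size=n, replace=False))
        table = scan_windows(t, window_length=200_000, dxy_pairs=[("X", "Y")])
        assert len(table) == 5
        assert set(table.columns) >= {"chrom", "start", "end", "n_sites", "dxy_X_Y"}

    def test_empty_window_flagged_missing(self):
        t = freq_table({"X": [0.5, 0.5], "Y": [0.1, 0.9]})
        t.pos[:] = [10, 500_010]  # nothing in the middle window
        table = scan_windows(t, window_length=200_000, dxy_pairs=[("X", "Y")])
        middle = table[(table.start == 200_000)]
        assert int(middle["n_sites"].iloc[0]) == 0
        assert math.isnan(middle["dxy_X_Y"].iloc[0])

    def test_requires_a_statistic(self, rng):
        t = freq_table({"X": [0.5], "Y": [0.1]})
        with pytest.raises(ValueError):
            scan_windows(t)
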