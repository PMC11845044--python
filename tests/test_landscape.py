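"""Windowing, smoothing, detection-probability correction, and statistics."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st
import statsmodels.api as sm

from meiomap import landscape as ls
from meiomap.events import EventList, RecombinationEvent, call_all
from meiomap.genotype_io import MarkerMap


def _co(pos, chrom="chr1", tid="t1"):
    return RecombinationEvent(
        event_id=f"e{pos}", tetrad_id=tid, chrom=chrom, kind="CO",
        pos=pos, ci_left=pos, ci_right=pos, spores=("s1", "s2"),
    )


def _nco(start, end, chrom="chr1", tid="t1", n_markers=3):
    return RecombinationEvent(
        event_id=f"n{start}", tetrad_id=tid, chrom=chrom, kind="NCO",
        pos=(start + end) // 2, ci_left=start, ci_right=end, spores=("s1",),
        n_markers=n_markers, tract_start=start, tract_end=end,
        max_start=start, max_end=end, length_mid=end - start,
    )


class TestMakeWindows:
    @pytest.mark.parametrize(
        "size,expected",
        [
            (60_000, [(0, 20_000), (20_000, 40_000), (40_000, 60_000)]),
            (50_000, [(0, 20_000), (20_000, 40_000), (40_000, 50_000)]),
            (19_999, [(0, 19_999)]),
        ],
    )
    def test_window_layout(self, size, expected):
        win = ls.make_windows({"chr1": size})
        assert [(r.start, r.end) for r in win.itertuples()] == expected

    def test_invalid_width(self):
        with pytest.raises(ValueError):
            ls.make_windows({"chr1": 100}, width=0)


class TestCountInWindows:
    def test_assignment_and_boundary(self):
        win = ls.make_windows({"chr1": 60_000})
        el = EventList([_co(25_000), _co(20_000)])
        out = ls.count_in_windows(el, win)
        # both in the second window: 25,000 inside, 20,000 by half-open rule
        assert list(out["co_raw"]) == [0, 2, 0]

    def test_event_outside_windows_errors(self):
        win = ls.make_windows({"chr1": 60_000})
        with pytest.raises(ValueError, match="outside"):
            ls.count_in_windows(EventList([_co(70_000)]), win)

    def test_uniform_placement_is_multinomial(self):
        rng = np.random.default_rng(0)
        win = ls.make_windows({"chr1": 200_000})  # 10 windows
        pos = rng.integers(0, 200_000, size=10_000)
        el = EventList([_co(int(p)) for p in pos])
        out = ls.count_in_windows(el, win)
        chi2, p = st.chisquare(out["co_raw"])
        assert p > 0.01


class TestSmoothCo:
    def _table(self, co, markers, chrom="chr1"):
        n = len(co)
        return pd.DataFrame(
            {
                "chrom": [chrom] * n,
                "start": np.arange(n) * 20_000,
                "end": (np.arange(n) + 1) * 20_000,
                "co_raw": co,
                "marker_count": markers,
            }
        )

    def test_even_split_over_marker_free_run(self):
        t = self._table([5, 2, 0, 1, 4], [10, 0, 0, 0, 7])
        out = ls.smooth_co(t)
        assert list(out["co_smoothed"]) == [5.0, 1.0, 1.0, 1.0, 4.0]

    def test_no_marker_free_windows_unchanged(self):
        t = self._table([3, 1, 2], [5, 5, 5])
        out = ls.smooth_co(t)
        assert list(out["co_smoothed"]) == [3.0, 1.0, 2.0]

    def test_conservation_exact_on_random_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = rng.integers(3, 40)
            t = self._table(
                rng.poisson(2, size=n).tolist(),
                (rng.random(n) < 0.4).astype(int) * rng.poisson(5, size=n),
            )
            out = ls.smooth_co(t)
            assert float(np.sum(out["co_smoothed"].to_numpy())) == float(
                np.sum(t["co_raw"].to_numpy(dtype=float))
            )


class TestDetectionProbability:
    def test_marker_at_every_bp(self):
        pos = np.arange(0, 20_000)
        p = ls.nco_detection_probability((0, 20_000), pos, 550, 200, 3, seed=0)
        assert p == 1.0

    def test_no_markers(self):
        p = ls.nco_detection_probability((0, 20_000), np.empty(0), 550, 200, 3, seed=0)
        assert p == 0.0

    def test_window_shorter_than_tract_undefined(self):
        p = ls.nco_detection_probability((0, 400), np.array([100]), 550, 100, 1, seed=0)
        assert np.isnan(p)

    @staticmethod
    def _exact(window, pos, tract, min_markers):
        """Exhaustive enumeration over every feasible placement."""
        start, end = window
        hits = 0
        total = 0
        for s in range(start, end - tract + 1):
            total += 1
            n = np.searchsorted(pos, s + tract) - np.searchsorted(pos, s)
            if n >= min_markers:
                hits += 1
        return hits / total if total else float("nan")

    @pytest.mark.parametrize(
        "markers,min_markers",
        [
            ([10_000], 1),
            ([100, 5_000, 5_200, 5_400, 19_900], 3),
            ([2_000, 2_100, 2_200], 2),
            (list(range(0, 20_000, 400)), 3),
            ([1, 19_999], 1),
        ],
    )
    def test_monte_carlo_matches_enumeration(self, markers, min_markers):
        pos = np.array(markers)
        window = (0, 20_000)
        exact = self._exact(window, pos, 550, min_markers)
        n_reps = 10_000
        mc = ls.nco_detection_probability(window, pos, 550, n_reps, min_markers, seed=3)
        se = np.sqrt(max(exact * (1 - exact), 1e-6) / n_reps)
        assert abs(mc - exact) <= 3 * se

    def test_single_marker_exact_value(self):
        # one marker mid-window: 550 of the 19,451 feasible placements hit it
        exact = self._exact((0, 20_000), np.array([10_000]), 550, 1)
        assert exact == pytest.approx(550 / 19_451)

    def test_monotone_in_nested_marker_sets(self):
        rng = np.random.default_rng(5)
        base = np.sort(rng.choice(20_000, size=10, replace=False))
        bigger = np.sort(np.append(base, 15_123))
        p1 = self._exact((0, 20_000), base, 550, 2)
        p2 = self._exact((0, 20_000), bigger, 550, 2)
        assert p2 >= p1


class TestCorrectNco:
    def _win(self, raw, prob):
        return pd.DataFrame({"nco_raw": raw, "detection_prob": prob})

    def test_arithmetic(self):
        out = ls.correct_nco(self._win([4, 2], [0.5, 1.0]))
        assert list(out["nco_corrected"]) == [8.0, 2.0]

    def test_zero_probability_flagged(self):
        out = ls.correct_nco(self._win([3], [0.0]))
        assert np.isnan(out["nco_corrected"].iloc[0])

    def test_scale_consistency(self):
        raw = [1, 4, 7]
        prob = [0.2, 0.5, 0.9]
        a = ls.correct_nco(self._win(raw, prob))["nco_corrected"]
        b = ls.correct_nco(self._win([2 * r for r in raw], prob))["nco_corrected"]
        assert np.allclose(b, 2 * a)

    def test_corrected_at_least_raw(self):
        rng = np.random.default_rng(2)
        raw = rng.poisson(3, 50)
        prob = rng.uniform(0.05, 1.0, 50)
        out = ls.correct_nco(self._win(raw, prob))
        assert np.all(out["nco_corrected"] >= out["nco_raw"] - 1e-12)

    def test_gradient_correction_unbiased(self):
        """Uniform true conversion rate across a 10x marker-density gradient:
        raw counts rise with density, corrected counts do not."""
        rng = np.random.default_rng(17)
        n_win, width, tract = 100, 20_000, 550
        L = n_win * width
        dens = np.linspace(1.0, 10.0, n_win)  # markers per kb
        pos = np.sort(
            np.concatenate(
                [
                    rng.integers(i * width, (i + 1) * width, size=rng.poisson(d * width / 1000))
                    for i, d in enumerate(dens)
                ]
            )
        )
        pos = np.unique(pos)
        starts = rng.integers(0, L - tract, size=4000)  # uniform true tracts
        covered = (np.searchsorted(pos, starts + tract) - np.searchsorted(pos, starts)) >= 1
        mid = starts + tract // 2
        raw = np.bincount(mid[covered] // width, minlength=n_win)
        win = pd.DataFrame(
            {"chrom": "chr1", "start": np.arange(n_win) * width,
             "end": (np.arange(n_win) + 1) * width, "nco_raw": raw}
        )
        mm = MarkerMap(pd.DataFrame({"chrom": "chr1", "pos": pos,
                                     "allele_a": "A", "allele_b": "G"}))
        win = ls.detection_probabilities(win, mm, tract, 10_000, min_markers=1, seed=23)
        win = ls.correct_nco(win)
        X = sm.add_constant(dens)
        raw_fit = sm.OLS(win["nco_raw"].to_numpy(dtype=float), X).fit()
        cor_fit = sm.OLS(win["nco_corrected"].to_numpy(), X).fit()
        lo, hi = raw_fit.conf_int()[1]
        assert lo > 0  # raw counts biased upward with density
        lo, hi = cor_fit.conf_int()[1]
        assert lo < 0 < hi  # corrected slope indistinguishable from zero


class TestGc:
    def test_all_gc(self):
        win = ls.make_windows({"chr1": 8}, width=4)
        assert np.allclose(ls.gc_content("GCGCGCGC", win, "chr1"), [1.0, 1.0])

    def test_half_gc(self):
        win = ls.make_windows({"chr1": 8}, width=8)
        assert np.allclose(ls.gc_content("ATGCATGC", win, "chr1"), [0.5])

    def test_n_bases_excluded(self):
        win = ls.make_windows({"chr1": 8}, width=8)
        assert np.allclose(ls.gc_content("GGNNNNAA", win, "chr1"), [0.5])
        win2 = ls.make_windows({"chr1": 4}, width=4)
        assert np.isnan(ls.gc_content("NNNN", win2, "chr1"))[0]

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=1000))
        win = ls.make_windows({"chr1": 1000}, width=128)
        got = ls.gc_content(seq, win, "chr1")
        want = [
            sum(c in "GC" for c in seq[r.start:r.end]) / (r.end - r.start)
            for r in win.itertuples()
        ]
        assert np.allclose(got, want)

    def test_sequence_too_short(self):
        win = ls.make_windows({"chr1": 100}, width=50)
        with pytest.raises(ValueError, match="shorter"):
            ls.gc_content("ACGT", win, "chr1")


class TestDownsample:
    def test_full_density_reproduces_calls_and_zero_gives_none(self, dense_clean_cross):
        cs = dense_clean_cross
        mm = cs.parents.marker_map
        region = ("chr1", 0, 500_000)
        cur = mm.density_per_kb(*region)
        full = call_all(cs.tetrads[:6], mm, cs.config.chrom_lengths).to_frame()
        table, reg = ls.downsample_experiment(
            cs.tetrads[:6], mm, region, [cur, 0.0], n_reps=2, seed=9
        )
        at_full = table[table["density"] == cur]
        assert (at_full["co_count"] == (full["kind"] == "CO").sum()).all()
        assert (at_full["nco_count"] == (full["kind"] == "NCO").sum()).all()
        at_zero = table[table["density"] == 0.0]
        assert (at_zero["co_count"] == 0).all() and (at_zero["nco_count"] == 0).all()

    def test_density_above_available_rejected(self, dense_clean_cross):
        cs = dense_clean_cross
        with pytest.raises(ValueError, match="available"):
            ls.downsample_experiment(
                cs.tetrads[:2], cs.parents.marker_map, ("chr1", 0, 500_000),
                [1000.0], n_reps=1, seed=0,
            )

    def test_nco_count_rises_and_tract_length_falls_with_density(self, dense_clean_cross):
        cs = dense_clean_cross
        table, reg = ls.downsample_experiment(
            cs.tetrads, cs.parents.marker_map, ("chr1", 0, 500_000),
            [1.0, 2.0, 3.5, 5.0], n_reps=5, seed=10,
        )
        reg = reg.set_index("response")
        assert reg.loc["nco_count", "slope"] > 0
        assert reg.loc["mean_tract_length", "slope"] < 0


class TestLandscapeStats:
    def _win(self, co, nco, intro=None, chrom="chr1"):
        n = len(co)
        df = pd.DataFrame(
            {
                "chrom": [chrom] * n,
                "start": np.arange(n) * 20_000,
                "end": (np.arange(n) + 1) * 20_000,
                "co_smoothed": co,
                "nco_corrected": nco,
            }
        )
        if intro is not None:
            df["introgression"] = intro
        return df

    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        w = self._win(rng.poisson(3, 50).astype(float), rng.poisson(2, 50).astype(float))
        out = ls.landscape_stats(w, w.copy())
        assert out["spearman"]["co_smoothed"]["rho"] == pytest.approx(1.0)

    def test_independent_tables_near_zero(self):
        rng = np.random.default_rng(1)
        n = 400
        a = self._win(rng.poisson(3, n).astype(float), rng.poisson(2, n).astype(float))
        b = self._win(rng.poisson(3, n).astype(float), rng.poisson(2, n).astype(float))
        out = ls.landscape_stats(a, b)
        assert abs(out["spearman"]["co_smoothed"]["rho"]) < 3 / np.sqrt(n)

    def test_shift_detected_by_wilcoxon(self):
        rng = np.random.default_rng(2)
        n = 100
        base = rng.normal(10, 2, n)
        intro = np.array([1] * 50 + [0] * 50)
        co = np.where(intro == 1, base + 2.0, base)
        w = self._win(co, np.full(n, 1.0), intro=intro)
        out = ls.landscape_stats(w, w.copy())
        assert out["wilcoxon"]["a:co_smoothed:intro_vs_bg"]["p"] < 0.01

    def test_mismatched_coordinates_rejected(self):
        a = self._win(np.ones(5), np.ones(5))
        b = self._win(np.ones(6), np.ones(6))
        with pytest.raises(ValueError, match="coordinates"):
            ls.landscape_stats(a, b)


class TestWindowGlm:
    def _synthetic(self, rng, n=500, gc_beta=30.0, intro_beta=-3.0):
        gc = rng.uniform(0.3, 0.5, n)
        intro = (rng.random(n) < 0.3).astype(int)
        cross = rng.choice(["a", "b"], n)
        y = 2.0 + gc_beta * gc + intro_beta * intro + rng.normal(0, 1.5, n)
        return pd.DataFrame(
            {"co": y, "gc": gc, "introgression": intro, "cross": cross}
        )

    def test_intercept_only_is_mean(self):
        rng = np.random.default_rng(4)
        df = self._synthetic(rng)
        res = ls.fit_window_glm(df, "co", ["1"], drop_nonsig_interaction=False)
        assert res.estimate("Intercept") == pytest.approx(df["co"].mean())

    def test_recovers_planted_coefficients(self):
        rng = np.random.default_rng(5)
        df = self._synthetic(rng)
        res = ls.fit_window_glm(
            df, "co", ["cross", "introgression", "gc", "introgression:cross"]
        )
        lo, hi = res.conf_int("gc")
        assert lo < 30.0 < hi
        lo, hi = res.conf_int("introgression")
        assert lo < -3.0 < hi
        # interaction absent from the generative model: dropped
        assert res.dropped_terms == ["introgression:cross"]

    def test_gaussian_identity_equals_least_squares(self):
        rng = np.random.default_rng(6)
        df = self._synthetic(rng, n=200)
        res = ls.fit_window_glm(df, "co", ["introgression", "gc"],
                                drop_nonsig_interaction=False)
        X = np.column_stack([np.ones(len(df)), df["introgression"], df["gc"]])
        beta, *_ = np.linalg.lstsq(X, df["co"].to_numpy(), rcond=None)
        assert np.allclose(res.table["estimate"].to_numpy(), beta, atol=1e-8)

    def test_collinear_terms_named(self):
        rng = np.random.default_rng(7)
        df = self._synthetic(rng, n=100)
        df["gc2"] = df["gc"]
        with pytest.raises(ValueError, match="collinear"):
            ls.fit_window_glm(df, "co", ["gc", "gc2"], drop_nonsig_interaction=False)


class TestAssemble:
    def test_full_table_invariants(self, small_cross):
        cs = small_cross
        el = call_all(cs.tetrads, cs.parents.marker_map, cs.config.chrom_lengths)
        seqs = {c: cs.parents.sequence_str(c) for c in cs.config.chrom_lengths}
        win = ls.assemble_window_table(
            el, cs.parents.marker_map, cs.config.chrom_lengths,
            sequences=seqs, introgressions=cs.parents.introgressions,
            cross="test", n_reps=500, seed=0,
        )
        assert {"co_raw", "co_smoothed", "nco_raw", "nco_corrected", "marker_count",
                "gc", "introgression", "detection_prob"} <= set(win.columns)
        for chrom in cs.config.chrom_lengths:
            sub = win[win["chrom"] == chrom]
            assert float(np.sum(sub["co_smoothed"].to_numpy())) == float(
                np.sum(sub["co_raw"].to_numpy(dtype=float)))
        assert win["gc"].between(0, 1).all()
        assert win["detection_prob"].between(0, 1).all()
        ok = win["nco_corrected"].notna()
        assert (win.loc[ok, "nco_corrected"] >= win.loc[ok, "nco_raw"] - 1e-12).all()
        # introgression flag matches the simulated design on chr1
        flagged = win[(win["chrom"] == "chr1") & (win["introgression"] == 1)]
        assert flagged["start"].min() == 100_000 and flagged["end"].max() == 180_000
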