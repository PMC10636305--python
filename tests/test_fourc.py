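"""Viewpoint profiles, Poisson loop calling, differential/AS/ROC analyses."""

import math

import numpy as np
import pandas as pd
import pytest

import trichrom as tc
from trichrom.contacts import PAIRS_COLUMNS
from trichrom.fourc import (
    evaluate_profile,
    label_bins,
    local_background,
    local_background_track,
)

from conftest import REGION_2MB, VIEWPOINT, tri4c_profile


def table_from_distal(coords, chrom="c", total=None):
    coords = list(coords)
    df = pd.DataFrame(
        [
            ("r%d" % k, chrom, 10, "+", 0, chrom, int(p), "+", 1, float(k), ".", 1)
            for k, p in enumerate(coords)
        ],
        columns=PAIRS_COLUMNS,
    )
    df["viewpoint_id"] = "vp"
    return tc.ContactTable(df)


def poisson_tail_oracle(m, lam):
    """Upper tail by direct series summation from k = m upward."""
    total, k = 0.0, m
    term = math.exp(-lam) * lam ** m / math.factorial(m)
    while term > 1e-30 or k < m + 10:
        total += term
        k += 1
        term *= lam / k
        if k > m + 2000:
            break
    return total


class TestBinProfile:
    def test_manual_window_counts(self):
        t = table_from_distal([1000, 1049, 1100])
        prof = tc.bin_profile(t, ("c", 10, 20), region=(0, 2000))
        df = prof.df.set_index("start")
        assert df.loc[1000, "M"] == 3  # window [800, 1300)
        assert df.loc[600, "M"] == 0   # window [400, 900)
        assert df.loc[800, "M"] == 2   # window [600, 1100): 1000 and 1049

    def test_empty_table_gives_zero_profile(self):
        t = table_from_distal([])
        prof = tc.bin_profile(t, ("c", 10, 20), region=(0, 1000))
        assert prof.df["M"].sum() == 0 and prof.total_contacts == 0

    def test_normalisation_per_10k_contacts(self):
        # 6 reads in one bin's window, 19,994 elsewhere: M_norm = 6e4/2e4 = 3
        coords = [50_000 + k for k in range(6)]
        coords += list(np.linspace(150_000, 190_000, 19_994).astype(int))
        prof = tc.bin_profile(
            table_from_distal(coords), ("c", 10, 20), region=(0, 200_000)
        )
        assert prof.total_contacts == 20_000
        assert prof.df.set_index("start").loc[50_000, "M"] == 6
        assert prof.df.set_index("start").loc[50_000, "M_norm"] == 3.0

    def test_window_must_be_odd_multiple_of_step(self):
        t = table_from_distal([100])
        with pytest.raises(ValueError):
            tc.bin_profile(t, ("c", 10, 20), step=100, window=400)


class TestLocalBackground:
    def test_uniform_density_gives_window_expectation(self):
        t = table_from_distal(range(50, 100_000, 100))  # 1 read / 100 bp
        prof = tc.bin_profile(t, ("c", 0, 10), region=(0, 100_000))
        n = local_background(prof, 500)
        assert n == pytest.approx(5.0)

    def test_max_over_scales_picks_densest_span(self):
        # empty 5 kb span around the bin, 900 reads spread over the 50 kb span
        coords = [p for p in range(25_000, 75_000, 56) if abs(p - 50_000) > 2600]
        t = table_from_distal(coords)
        prof = tc.bin_profile(t, ("c", 0, 10), region=(0, 100_000))
        raw = prof.df["raw"].to_numpy()
        i = 500  # bin at 50 kb
        n = local_background(prof, i)
        # oracle: best density over inclusive ±h spans minus the ±1 kb zone
        best = 0.0
        S = np.concatenate(([0], np.cumsum(raw)))
        for h in (25, 50, 100, 250):
            reads = S[min(i + h + 1, len(raw))] - S[max(i - h, 0)]
            excl = S[i + 11] - S[i - 10]
            length = (min(i + h, len(raw) - 1) - max(i - h, 0) + 1) * 100
            best = max(best, max(reads - excl, 0.5) / (length - 2100))
        assert n == pytest.approx(500 * best)
        assert n > 0

    def test_all_zero_background_floors_and_p_is_one_for_zero_counts(self):
        t = table_from_distal([])
        prof = tc.bin_profile(t, ("c", 0, 10), region=(0, 100_000))
        n = local_background(prof, 500)
        assert 0 < n < 0.1
        assert tc.poisson_pvalue(0, n) == 1.0

    def test_bin_outside_profile_is_an_error(self):
        t = table_from_distal([100])
        prof = tc.bin_profile(t, ("c", 0, 10), region=(0, 1000))
        with pytest.raises(IndexError):
            local_background(prof, 99)

    def test_mass_correction_scales_expectation_with_window_mass(self):
        raw = np.full(1000, 1.0)
        mass = np.full(1000, 100.0)
        mass[500] = 200.0  # one bin carries double taggable mass
        n_plain = local_background_track(raw, 100, 500)
        n_mass = local_background_track(raw, 100, 500, mass=mass)
        assert n_plain[500] == pytest.approx(5.0)
        assert n_mass[500] == pytest.approx(n_mass[100] * (600 / 500), rel=0.01)


class TestPoisson:
    @pytest.mark.parametrize(
        "m,lam,expected",
        [(0, 3.7, 1.0), (4, 1.0, 0.018988156), (2, 2.5, 0.71270250)],
    )
    def test_known_tail_values(self, m, lam, expected):
        assert tc.poisson_pvalue(m, lam) == pytest.approx(expected, abs=1e-8)

    def test_matches_series_summation(self):
        for m in (0, 1, 5, 17, 50):
            for lam in (0.3, 2.0, 9.5, 20.0):
                assert tc.poisson_pvalue(m, lam) == pytest.approx(
                    poisson_tail_oracle(m, lam), abs=1e-12
                )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            tc.poisson_pvalue(3, 0.0)
        with pytest.raises(ValueError):
            tc.poisson_pvalue(-1, 1.0)


class TestCallLoops:
    def test_single_replicate_flag_undefined(self, fmap_2mb):
        prof, _ = tri4c_profile(fmap_2mb, seed=21,
                                loops=[tc.LoopSpec(1_200_000, 8.0)])
        loops = tc.call_loops(prof, fragment_map=fmap_2mb)
        hit = [l for l in loops if l.start < 1_200_000 < l.end]
        assert hit and hit[0].reproducible is None

    def test_two_replicates_recover_injected_loop(self, fmap_2mb):
        L = [tc.LoopSpec(1_200_000, 8.0)]
        p1, _ = tri4c_profile(fmap_2mb, seed=22, loops=L)
        p2, _ = tri4c_profile(fmap_2mb, seed=23, loops=L)
        loops = tc.call_loops([p1, p2], fragment_map=fmap_2mb)
        assert len(loops) == 1
        (loop,) = loops
        assert loop.start < 1_200_000 < loop.end
        assert loop.reproducible is True
        assert loop.end - loop.start >= 500
        assert abs(loop.strength - 3.0) < 0.8

    def test_zero_contact_profile_calls_nothing(self, caplog):
        t = table_from_distal([])
        prof = tc.bin_profile(t, ("c", 0, 10), region=(0, 100_000))
        with caplog.at_level("WARNING"):
            assert tc.call_loops(prof) == []

    def test_loop_strength_is_depth_invariant(self, fmap_2mb):
        # scaling the library leaves log2 FE at the summit unchanged in mean
        L = [tc.LoopSpec(1_300_000, 6.0)]
        strengths = {}
        for n in (50_000, 200_000):
            vals = []
            for seed in range(4):
                prof, _ = tri4c_profile(fmap_2mb, seed=500 + seed, loops=L, n=n)
                loops = tc.call_loops(prof, fragment_map=fmap_2mb)
                hit = [l for l in loops if l.start < 1_300_000 < l.end]
                if hit:
                    vals.append(hit[0].strength)
            strengths[n] = np.mean(vals)
        assert abs(strengths[50_000] - strengths[200_000]) < 0.5


class TestDistanceModel:
    def test_power_law_decay_recovered(self, regular_fmap_1mb):
        spec = tc.SimulationSpec(
            mode="4c", seed=31, n_molecules=400_000, viewpoint=(500_000, 501_000),
            alpha=1.0,
        )
        table, _ = tc.simulate_tri4c(spec, regular_fmap_1mb)
        prof = tc.bin_profile(
            tc.dedup_contacts(table), ("sim", 500_000, 501_000),
            region=(0, 1_000_000),
        )
        n_dist = tc.distance_model_background(prof)
        d = prof.viewpoint_distance()
        mid = (d > 20_000) & (d < 200_000)
        # binned comparison against c/d over the central distance range
        m = prof.df["M"].to_numpy()[mid]
        expect = m.sum() / (1.0 / d[mid]).sum() / d[mid]
        ratio = n_dist[mid] / expect
        assert 0.9 < np.median(ratio) < 1.1

    def test_flat_profile_gives_constant_expectation(self):
        t = table_from_distal(range(50, 200_000, 100))
        prof = tc.bin_profile(t, ("c", 100_000, 100_100), region=(0, 200_000))
        n_dist = tc.distance_model_background(prof)
        inner = n_dist[100:1900]
        assert np.allclose(inner, prof.df["M"].mean(), rtol=0.1)

    def test_injected_loop_enriched_against_distance_model(self, regular_fmap_1mb):
        spec = tc.SimulationSpec(
            mode="4c", seed=32, n_molecules=200_000,
            viewpoint=(500_000, 501_000), loops=[tc.LoopSpec(700_000, 8.0)],
        )
        table, _ = tc.simulate_tri4c(spec, regular_fmap_1mb)
        prof = tc.bin_profile(
            tc.dedup_contacts(table), ("sim", 500_000, 501_000),
            region=(0, 1_000_000),
        )
        n_dist = tc.distance_model_background(prof)
        i = 7000  # bin at the injected anchor
        assert prof.df["M"].iloc[i] / n_dist[i] > 2.0

    def test_all_zero_profile_is_an_error(self):
        t = table_from_distal([])
        prof = tc.bin_profile(t, ("c", 0, 10), region=(0, 100_000))
        with pytest.raises(ValueError):
            tc.distance_model_background(prof)

    def test_local_and_distance_backgrounds_agree_on_flat_decay(
        self, regular_fmap_1mb
    ):
        # alpha = 0: no distance trend, both backgrounds must find the same loop
        spec = tc.SimulationSpec(
            mode="4c", seed=33, n_molecules=100_000, alpha=0.0,
            viewpoint=(500_000, 501_000), loops=[tc.LoopSpec(250_000, 8.0)],
        )
        table, _ = tc.simulate_tri4c(spec, regular_fmap_1mb)
        prof = tc.bin_profile(
            tc.dedup_contacts(table), ("sim", 500_000, 501_000),
            region=(0, 1_000_000),
        )
        found = {}
        for bg in ("local", "distance"):
            loops = tc.call_loops(prof.df.pipe(lambda _: prof), background=bg)
            found[bg] = {
                (l.start, l.end) for l in loops if l.start < 250_000 < l.end
            }
        assert found["local"] and found["local"] == found["distance"]


class TestDifferential:
    def _loop(self, start, end):
        return tc.LoopCall("sim", start, end, start, 1.0, 0.0)

    def test_identical_profiles_show_no_change(self, fmap_2mb):
        prof, _ = tri4c_profile(fmap_2mb, seed=41)
        loops = [self._loop(1_200_000, 1_201_000), self._loop(1_400_000, 1_400_500)]
        res = tc.differential_loop_test(prof, prof, loops)
        assert np.allclose(res["log2_fold_change"], 0.0)
        assert not res["significant"].any()

    def test_global_scaling_is_normalised_away(self, fmap_2mb):
        # condition B = every contact of A duplicated: a pure depth change
        spec = tc.SimulationSpec(
            mode="4c", seed=42, n_molecules=50_000, viewpoint=VIEWPOINT[1:]
        )
        table, _ = tc.simulate_tri4c(spec, fmap_2mb)
        prof_a = tc.bin_profile(table, VIEWPOINT, region=REGION_2MB)
        doubled = tc.ContactTable(
            pd.concat([table.df, table.df], ignore_index=True), dict(table.meta)
        )
        prof_b = tc.bin_profile(doubled, VIEWPOINT, region=REGION_2MB)
        loops = [
            self._loop(s, s + 1000) for s in range(1_100_000, 1_600_000, 50_000)
        ]
        res = tc.differential_loop_test(prof_a, prof_b, loops)
        assert not res["significant"].any()
        # residual fold change is only the 0.5-pseudocount asymmetry
        assert np.abs(res["log2_fold_change"]).max() < 0.1

    def test_condition_specific_loop_is_detected(self, fmap_2mb):
        L = [tc.LoopSpec(1_100_000, 3.0)]
        prof_a, _ = tri4c_profile(fmap_2mb, seed=44, n=200_000)
        prof_b, _ = tri4c_profile(fmap_2mb, seed=45, n=200_000, loops=L)
        loops = [self._loop(1_099_500, 1_100_500)] + [
            self._loop(s, s + 1000) for s in range(1_300_000, 1_700_000, 50_000)
        ]
        res = tc.differential_loop_test(prof_a, prof_b, loops)
        assert bool(res.loc[0, "significant"])
        assert res.loc[0, "log2_fold_change"] > 1.0
        assert not res.loc[1:, "significant"].any()

    def test_zero_totals_error(self):
        t = table_from_distal([])
        prof = tc.bin_profile(t, ("c", 0, 10), region=(0, 1000))
        with pytest.raises(ValueError):
            tc.differential_loop_test(prof, prof, [self._loop(0, 100)])


class TestAlleleSpecific:
    @staticmethod
    def binom_two_sided_oracle(k, n, p=0.5):
        """Sum of P(X = j) over all j with P(X = j) <= P(X = k)."""
        pmf = [math.comb(n, j) * p ** j * (1 - p) ** (n - j) for j in range(n + 1)]
        pk = pmf[k]
        return sum(q for q in pmf if q <= pk * (1 + 1e-12))

    def test_imbalance_matches_exact_binomial_summation(self):
        res = tc.allele_specific_test([30], [10], 1000, 1000)
        oracle = self.binom_two_sided_oracle(30, 40)
        assert res.loc[0, "p"] == pytest.approx(oracle, rel=1e-9)
        assert 1e-4 < oracle < 1e-2

    def test_balanced_counts_give_p_one(self):
        res = tc.allele_specific_test([25], [25], 500, 500)
        assert res.loc[0, "p"] == pytest.approx(1.0)

    def test_imbalanced_loops_rank_lowest(self):
        rng = np.random.default_rng(8)
        n_loops = 40
        imb = set(range(10))
        ref, alt = [], []
        for k in range(n_loops):
            total = 120
            p = 2 / 3 if k in imb else 0.5
            r = rng.binomial(total, p)
            ref.append(r)
            alt.append(total - r)
        res = tc.allele_specific_test(ref, alt, 10_000, 10_000)
        top10 = set(res.nsmallest(10, "p")["loop"])
        assert len(top10 & imb) >= 8

    def test_zero_zero_loops_are_omitted(self, caplog):
        with caplog.at_level("WARNING"):
            res = tc.allele_specific_test([0, 5], [0, 5], 100, 100)
        assert res["loop"].tolist() == [1]


class TestROC:
    def test_all_pairs_counting(self):
        auc, _ = tc.roc_auc([3, 1, 2, 0], [True, True, False, False])
        assert auc == 0.75

    def test_perfect_separation_and_all_ties(self):
        auc, pts = tc.roc_auc([5, 6, 1, 2], [True, True, False, False])
        assert auc == 1.0
        assert pts.iloc[-1]["tpr"] == 1.0 and pts.iloc[-1]["fpr"] == 1.0
        auc, _ = tc.roc_auc([1, 1, 1, 1], [True, False, True, False])
        assert auc == 0.5

    def test_single_class_is_an_error(self):
        with pytest.raises(ValueError):
            tc.roc_auc([1, 2], [True, True])

    def test_bin_labelling_by_interval_overlap(self):
        t = table_from_distal([100])
        prof = tc.bin_profile(t, ("c", 0, 10), region=(0, 1000))
        mask = label_bins(prof, [(250, 450)])
        assert mask.tolist() == [False, False, True, True, True] + [False] * 5

    def test_scores_separate_injected_loops_from_background(self, fmap_2mb):
        L = [tc.LoopSpec(1_200_000, 8.0), tc.LoopSpec(1_450_000, 8.0)]
        prof, _ = tri4c_profile(fmap_2mb, seed=46, loops=L)
        evaluate_profile(prof, fragment_map=fmap_2mb)
        tested = prof.df["tested"].to_numpy()
        positives = label_bins(
            prof, [(1_199_950, 1_200_050), (1_449_950, 1_450_050)]
        )
        auc, _ = tc.roc_auc(
            prof.df["score"].to_numpy()[tested], positives[tested]
        )
        assert auc > 0.98
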