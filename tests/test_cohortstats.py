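"""Cohort statistics: exact-test oracles, calibration, tracking."""

import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stemvar import cohortstats, sigfit, synth
from stemvar.sigfit import CHANNELS


def binomial_oracle(k, n, p, alternative):
    """Brute-force binomial tail/minlike summation with exact combinatorics."""
    pf = Fraction(p).limit_denominator(10**9)
    pmf = [Fraction(comb(n, j)) * pf**j * (1 - pf) ** (n - j) for j in range(n + 1)]
    if alternative == "greater":
        return float(sum(pmf[k:]))
    if alternative == "less":
        return float(sum(pmf[: k + 1]))
    return float(sum(q for q in pmf if q <= pmf[k] * (1 + Fraction(1, 10**7))))


def mannwhitney_oracle(x, y):
    """Exact two-sided rank-sum p by enumerating all group assignments."""
    pooled = sorted(x) + sorted(y)
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"
    n1 = len(x)
    ranks = {v: i + 1 for i, v in enumerate(sorted(pooled))}
    u_obs = sum(ranks[v] for v in x) - n1 * (n1 + 1) / 2

    us = []
    for combo in itertools.combinations(range(len(pooled)), n1):
        r = sum(i + 1 for i in combo)
        us.append(r - n1 * (n1 + 1) / 2)
    us = np.array(us)
    p_le = (us <= u_obs).mean()
    p_ge = (us >= u_obs).mean()
    return min(1.0, 2 * min(p_le, p_ge))


class TestBinomialPrevalence:
    def test_reported_blood_cohort_enrichment(self):
        # 3 hits of 17 lines against the 11/452 fibroblast background
        p = cohortstats.binomial_prevalence_test(3, 17, 11 / 452)
        assert round(p, 4) == 0.0076

    def test_sidedness_robust_at_reported_counts(self):
        g = cohortstats.binomial_prevalence_test(3, 17, 11 / 452, "greater")
        t = cohortstats.binomial_prevalence_test(3, 17, 11 / 452, "two-sided")
        assert round(g, 4) == round(t, 4) == 0.0076

    def test_zero_hits_give_p_one(self):
        assert cohortstats.binomial_prevalence_test(0, 20, 0.1, "greater") == 1.0

    def test_matches_enumeration_all_small_n(self):
        for n in range(1, 13):
            for k in range(n + 1):
                for p0 in (0.024, 0.3, 0.5):
                    for alt in ("greater", "less", "two-sided"):
                        got = cohortstats.binomial_prevalence_test(k, n, p0, alt)
                        want = binomial_oracle(k, n, p0, alt)
                        assert got == pytest.approx(want, abs=1e-12), (k, n, p0, alt)

    def test_invalid_background_rejected(self):
        with pytest.raises(ValueError):
            cohortstats.binomial_prevalence_test(1, 10, 1.5)


class TestBurdenTest:
    def test_extreme_separation_exact_p(self):
        p = cohortstats.burden_vs_group_test(
            [1, 2, 3, 10, 11, 12], ["a"] * 3 + ["b"] * 3
        )
        assert p == pytest.approx(0.1, abs=1e-12)
        assert p == pytest.approx(mannwhitney_oracle([1, 2, 3], [10, 11, 12]))

    def test_exact_branch_matches_enumeration(self, rng):
        for _ in range(20):
            n1, n2 = rng.integers(2, 6, size=2)
            vals = rng.permutation(100)[: n1 + n2].astype(float)
            x, y = vals[:n1], vals[n1:]
            got = cohortstats.burden_vs_group_test(
                np.concatenate([x, y]), ["a"] * n1 + ["b"] * n2
            )
            assert got == pytest.approx(mannwhitney_oracle(list(x), list(y)), rel=1e-9)

    def test_exchangeable_data_large_p(self, rng):
        burdens = rng.normal(1000, 100, 40)
        labels = ["a"] * 20 + ["b"] * 20
        assert cohortstats.burden_vs_group_test(burdens, labels) > 0.05

    def test_null_pvalues_approximately_uniform(self, rng):
        ps = []
        for _ in range(200):
            burdens = rng.normal(0, 1, 36)
            labels = ["a"] * 18 + ["b"] * 18
            ps.append(cohortstats.burden_vs_group_test(burdens, labels))
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            cohortstats.burden_vs_group_test([1, 2, 3], ["a", "a", "a"])


class TestPassageCorrelation:
    def test_perfect_linear_exposure(self):
        df = pd.DataFrame({"passage": [5, 10, 15, 20], "Oxidative": [10, 20, 30, 40]})
        r, p = cohortstats.passage_exposure_correlation(df, "Oxidative")
        assert r == pytest.approx(1.0)

    def test_permuted_passages_centered_on_zero(self, rng):
        rs = []
        for _ in range(50):
            df = pd.DataFrame(
                {"passage": rng.permutation(30), "Oxidative": rng.normal(100, 10, 30)}
            )
            rs.append(cohortstats.passage_exposure_correlation(df, "Oxidative")[0])
        assert abs(np.mean(rs)) < 0.1

    def test_simulated_culture_accumulation_detected(self):
        # exposure grows with passage number when culture mutations accrue
        sigs = sigfit.fallback_signatures()
        rows = []
        for i, passages in enumerate([4, 8, 12, 16, 20, 24, 28, 32]):
            cfg = synth.SimConfig(
                seed=100 + i, n_subclones=1, subclone_fractions=(0.5,),
                ancestral_mutations=30, uv_rate_per_subclone=50.0,
                culture_rate_per_passage=10.0, passages=passages,
                neutral_tail_mutations=0, n_germline_sites=0,
            )
            parent, _ = synth.simulate_parent_population(cfg)
            derived = synth.simulate_derived_line(parent, cfg, 0, seed=200 + i)
            ev = synth.truth_events(derived)
            catalog = sigfit.build_catalog(ev[ev["mut_class"] == "SNV"])
            est = sigfit.fit_exposures(catalog, sigs)
            rows.append({"passage": passages, "Oxidative": est.exposures["Oxidative"]})
        r, p = cohortstats.passage_exposure_correlation(pd.DataFrame(rows), "Oxidative")
        assert r > 0.8 and p < 0.01

    def test_zero_variance_flagged_nan(self):
        df = pd.DataFrame({"passage": [5, 5, 5], "Oxidative": [1.0, 2.0, 3.0]})
        r, p = cohortstats.passage_exposure_correlation(df, "Oxidative")
        assert np.isnan(r) and np.isnan(p)


class TestPairHeterogeneity:
    def _calls(self, positions):
        df = pd.DataFrame({"pos": list(positions)})
        df["chrom"] = "chr1"
        df["ref"] = "C"
        df["alt"] = "T"
        return df[["chrom", "pos", "ref", "alt"]]

    def test_identical_sets_concordant(self):
        calls = self._calls(range(100, 150))
        cat = pd.Series(np.ones(96), index=list(CHANNELS))
        pair = cohortstats.pair_heterogeneity(calls, calls, cat, cat)
        assert pair.n_shared == 50 and pair.concordant

    def test_disjoint_sets_discordant(self):
        a, b = self._calls(range(100, 150)), self._calls(range(500, 550))
        cat = pd.Series(np.ones(96), index=list(CHANNELS))
        pair = cohortstats.pair_heterogeneity(a, b, cat, cat)
        assert pair.n_shared == 0 and not pair.concordant

    def test_same_vs_different_subclone_lines(self, small_config):
        from stemvar import paircall

        parent, _ = synth.simulate_parent_population(small_config)

        def line_calls(subclone, seed):
            derived = synth.simulate_derived_line(parent, small_config, subclone, seed=seed)
            counts = synth.sample_read_counts(parent, derived, small_config, seed=seed + 1)
            calls = paircall.call_variants(counts).calls
            # the symmetric caller also flags mutations lost in the derived
            # line; sister-pair comparison concerns mutations the lines carry
            calls = calls[calls["derived_vaf"] >= 0.2]
            return calls, sigfit.build_catalog(calls)

        calls_a, cat_a = line_calls(0, 301)
        calls_b, cat_b = line_calls(0, 401)
        calls_c, cat_c = line_calls(1, 501)
        same = cohortstats.pair_heterogeneity(calls_a, calls_b, cat_a, cat_b)
        diff = cohortstats.pair_heterogeneity(calls_a, calls_c, cat_a, cat_c)
        assert same.concordant
        assert not diff.concordant


class TestDriverOverlap:
    def test_reported_cohort_fraction(self):
        hits = {f"L{i}": (["BCOR"] if i < 177 else []) for i in range(452)}
        _, pct = cohortstats.driver_overlap(hits, ["BCOR", "TP53"])
        assert pct == 39

    def test_toy_cohort(self):
        hits = {
            "a": ["BCOR"], "b": ["TP53"], "c": ["BCOR", "TP53"],
            "d": [], "e": [], "f": [], "g": [], "h": ["OTHER"],
        }
        per_line, pct = cohortstats.driver_overlap(hits, ["BCOR", "TP53"])
        assert pct == 38  # 3 of 8
        assert per_line["h"] == set()

    def test_no_hits_zero_percent(self):
        _, pct = cohortstats.driver_overlap({"a": [], "b": []}, ["BCOR"])
        assert pct == 0

    def test_empty_census_rejected(self):
        with pytest.raises(ValueError):
            cohortstats.driver_overlap({"a": ["BCOR"]}, [])


class TestTrackSubclones:
    def _table(self, entries):
        return pd.DataFrame(
            [("chrX", pos, "C", "T", alt) for pos, alt in entries],
            columns=["chrom", "pos", "ref", "alt", "alt_reads"],
        )

    def test_classifications(self):
        parent = self._table([(100, 5), (200, 0), (300, 0)])
        subs = {
            "s1": self._table([(100, 3), (200, 2), (300, 0)]),
            "s2": self._table([(100, 4), (200, 0), (300, 0)]),
        }
        m = cohortstats.track_subclones(parent, subs)
        cls = m.classification
        assert cls[("chrX", 100, "C", "T")] == "recapitulated"
        assert cls[("chrX", 200, "C", "T")] == "new_in_subclone"
        assert cls[("chrX", 300, "C", "T")] == "absent"

    def test_missing_sample_marked_unavailable(self):
        parent = self._table([(100, 5)])
        subs = {"s1": self._table([])}
        m = cohortstats.track_subclones(parent, subs)
        assert m.presence.loc[("chrX", 100, "C", "T"), "s1"] is pd.NA

    def test_classification_exhaustive_and_exclusive(self, rng):
        entries = [(int(p), int(a)) for p, a in zip(range(1, 40), rng.integers(0, 3, 39))]
        parent = self._table(entries)
        subs = {
            f"s{j}": self._table(
                [(int(p), int(a)) for p, a in zip(range(1, 40), rng.integers(0, 3, 39))]
            )
            for j in range(3)
        }
        m = cohortstats.track_subclones(parent, subs)
        assert len(m.classification) == 39
        assert set(m.classification) <= {"recapitulated", "new_in_subclone", "absent"}
        assert sum(m.summary().values()) == 39


class TestPrevalencePercent:
    def test_reported_percentages(self):
        assert cohortstats.prevalence_percent(21, 78, 1) == 26.9
        assert cohortstats.prevalence_percent(3, 17) == 18
        assert cohortstats.prevalence_percent(24, 95) == 25

    def test_half_rounds_away_from_zero(self):
        assert cohortstats.prevalence_percent(1, 8) == 13  # 12.5 -> 13
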