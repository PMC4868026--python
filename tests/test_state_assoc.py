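import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cnvtrait.state_assoc import (assign_probe_states, bonferroni_alpha,
                                  cnv_plus_frequency, detect_regions,
                                  family_permutation_scan,
                                  family_permutation_test, meta_analyze,
                                  restrict_to_covered, x_association)

PROBES = pd.DataFrame({
    "probe_id": [f"p{i}" for i in range(10)],
    "chrom": ["1"] * 5 + ["X"] * 5,
    "pos": list(range(1000, 6000, 1000)) + list(range(1000, 6000, 1000)),
})


def _call(sample, chrom, start, end, cn):
    return {"sample_id": sample, "chrom": chrom, "start_bp": start,
            "end_bp": end, "copy_number": cn, "n_snps": 5,
            "confidence": 20.0}


class TestStateMatrix:
    SEXES = pd.Series({"A": "M", "B": "F"})

    def test_autosomal_duplication_is_cnv_plus(self):
        calls = pd.DataFrame([_call("A", "1", 1500, 3500, 3)])
        st = assign_probe_states(calls, PROBES, self.SEXES,
                                 sample_ids=["A", "B"])
        assert st.loc["A", ["p1", "p2"]].all()
        assert not st.loc["A", "p0"] and not st.loc["A", "p3"]
        assert not st.loc["B"].any()

    def test_male_x_single_copy_is_baseline(self):
        calls = pd.DataFrame([_call("A", "X", 1500, 3500, 1),
                              _call("B", "X", 1500, 3500, 1)])
        st = assign_probe_states(calls, PROBES, self.SEXES,
                                 sample_ids=["A", "B"])
        assert not st.loc["A"].any()       # cn 1 is the male X baseline
        assert st.loc["B", ["p6", "p7"]].all()  # deletion in a female

    def test_male_x_diploid_is_cnv_plus(self):
        calls = pd.DataFrame([_call("A", "X", 1500, 3500, 2)])
        st = assign_probe_states(calls, PROBES, self.SEXES,
                                 sample_ids=["A"])
        assert st.loc["A", ["p6", "p7"]].all()

    def test_unknown_sex_on_x_raises(self):
        calls = pd.DataFrame([_call("C", "X", 1500, 3500, 2)])
        with pytest.raises(ValueError, match="sex"):
            assign_probe_states(calls, PROBES, self.SEXES,
                                sample_ids=["C"])

    def test_column_sums_match_brute_force(self, rng):
        samples = [f"S{i}" for i in range(30)]
        sexes = pd.Series({s: ("M" if i % 2 else "F")
                           for i, s in enumerate(samples)})
        rows = []
        for s in samples:
            for _ in range(rng.integers(0, 4)):
                chrom = str(rng.choice(["1", "X"]))
                start = int(rng.integers(500, 5000))
                end = start + int(rng.integers(0, 2500))
                cn = int(rng.choice([0, 1, 2, 3]))
                if cn == baseline(chrom, sexes[s]):
                    cn += 1
                rows.append(_call(s, chrom, start, end, cn))
        calls = pd.DataFrame(rows)
        st = assign_probe_states(calls, PROBES, sexes, sample_ids=samples)
        for _, probe in PROBES.iterrows():
            for s in samples:
                expected = any(
                    c["chrom"] == probe["chrom"]
                    and c["start_bp"] <= probe["pos"] <= c["end_bp"]
                    and c["copy_number"] != baseline(c["chrom"], sexes[s])
                    for c in rows if c["sample_id"] == s)
                assert st.loc[s, probe["probe_id"]] == expected

    def test_restrict_to_covered(self):
        calls = pd.DataFrame([_call("A", "1", 1500, 3500, 1)])
        st = assign_probe_states(calls, PROBES, self.SEXES,
                                 sample_ids=["A", "B"])
        covered = restrict_to_covered(st)
        assert list(covered.columns) == ["p1", "p2"]
        empty = restrict_to_covered(st & False)
        assert empty.shape[1] == 0


def baseline(chrom, sex):
    return 1 if (str(chrom) == "X" and sex == "M") else 2


class TestPermutationTest:
    def test_perfect_association_minimal_p(self, rng):
        n = 40
        fams = pd.Series([f"F{i}" for i in range(n)])
        state = pd.Series(np.r_[np.ones(6), np.zeros(n - 6)])
        scores = pd.Series(state.to_numpy(), dtype=float)
        res = family_permutation_test(state, scores, fams, n_perms=99,
                                      seed=0, adaptive=False)
        assert res.p == pytest.approx(1 / 100)
        assert res.direction == 1

    def test_monomorphic_state_untestable(self, rng):
        n = 20
        fams = pd.Series([f"F{i}" for i in range(n)])
        res = family_permutation_test(pd.Series(np.zeros(n)),
                                      pd.Series(rng.standard_normal(n)),
                                      fams, n_perms=99, seed=0)
        assert res.p == 1.0 and res.direction == 0

    def test_adaptive_stops_early_under_null(self, rng):
        n = 200
        fams = pd.Series(np.repeat([f"F{i}" for i in range(n // 2)], 2))
        state = pd.Series((rng.random(n) < 0.2).astype(float))
        scores = pd.Series(rng.standard_normal(n))
        res = family_permutation_test(state, scores, fams, n_perms=10_000,
                                      seed=1, adaptive=True)
        assert res.n_perms_used < 10_000
        assert res.p > 0.01

    def test_scan_agrees_with_single_probe_test(self, rng):
        n = 60
        fams = pd.Series(np.repeat([f"F{i}" for i in range(n // 2)], 2),
                         index=[f"S{i}" for i in range(n)])
        states = pd.DataFrame(
            rng.random((n, 4)) < 0.15,
            index=fams.index, columns=["a", "b", "c", "d"])
        scores = pd.Series(rng.standard_normal(n), index=fams.index)
        scan = family_permutation_scan(states, scores, fams, n_perms=500,
                                       seed=3)
        single = family_permutation_test(
            states["b"].astype(float).set_axis(scores.index), scores, fams,
            n_perms=500, seed=3, adaptive=False)
        row = scan.set_index("probe_id").loc["b"]
        # same slope and direction; p equal up to Monte-Carlo discreteness
        assert row["slope"] == pytest.approx(single.slope)
        assert row["direction"] == single.direction
        assert abs(row["p"] - single.p) < 0.1


class TestMetaAnalysis:
    def _table(self, p, direction, N):
        return pd.DataFrame({"probe_id": [f"p{i}" for i in range(len(p))],
                             "p": p, "direction": direction, "N": N})

    def test_equal_z_equal_n(self):
        p0 = 2 * stats.norm.sf(1.96)
        a = self._table([p0], [1], [100])
        b = self._table([p0], [1], [100])
        meta = meta_analyze(a, b)
        assert meta.loc[0, "Z"] == pytest.approx(1.96 * np.sqrt(2), rel=1e-3)

    def test_opposite_directions_cancel(self):
        p0 = 0.01
        meta = meta_analyze(self._table([p0], [1], [80]),
                            self._table([p0], [-1], [80]))
        assert meta.loc[0, "Z"] == pytest.approx(0.0, abs=1e-12)
        assert meta.loc[0, "p_meta"] == pytest.approx(1.0)

    def test_single_cohort_probes_excluded(self):
        a = self._table([0.01, 0.02], [1, 1], [100, 100])
        b = self._table([0.03], [1], [50])
        meta = meta_analyze(a, b)
        assert list(meta["probe_id"]) == ["p0"]

    def test_matches_arithmetic_oracle(self, rng):
        n = 200
        pa, pb = rng.uniform(1e-6, 1, n), rng.uniform(1e-6, 1, n)
        da, db = rng.choice([-1, 1], n), rng.choice([-1, 1], n)
        na, nb = rng.integers(20, 500, n), rng.integers(20, 500, n)
        meta = meta_analyze(self._table(pa, da, na), self._table(pb, db, nb))
        za = stats.norm.isf(pa / 2) * da
        zb = stats.norm.isf(pb / 2) * db
        expected = (np.sqrt(na) * za + np.sqrt(nb) * zb) / np.sqrt(na + nb)
        assert np.allclose(meta["Z"], expected, atol=1e-12)


class TestXAssociation:
    def _setup(self, rng, male_effect=2.0, female_effect=2.0, n=120):
        ids = [f"S{i}" for i in range(n)]
        sexes = pd.Series(["M"] * (n // 2) + ["F"] * (n // 2), index=ids)
        fams = pd.Series([f"F{i // 2}" for i in range(n)], index=ids)
        state = np.zeros(n, dtype=bool)
        state[rng.choice(n, n // 5, replace=False)] = True
        states = pd.DataFrame({"px": state}, index=ids)
        scores = pd.Series(rng.standard_normal(n), index=ids)
        scores[state & (sexes == "M").to_numpy()] += male_effect
        scores[state & (sexes == "F").to_numpy()] += female_effect
        return states, scores, fams, sexes

    def test_equal_strata_combine_to_sqrt2(self, rng):
        states, scores, fams, sexes = self._setup(rng)
        per_sex, combined = x_association(states, scores, fams, sexes,
                                          n_perms=400, seed=1)
        za = stats.norm.isf(per_sex["M"].loc[0, "p"] / 2)
        zb = stats.norm.isf(per_sex["F"].loc[0, "p"] / 2)
        nm, nf = per_sex["M"].loc[0, "N"], per_sex["F"].loc[0, "N"]
        expected = (np.sqrt(nm) * za + np.sqrt(nf) * zb) / np.sqrt(nm + nf)
        assert combined.loc[0, "Z"] == pytest.approx(expected)

    def test_monomorphic_stratum_passthrough(self, rng):
        states, scores, fams, sexes = self._setup(rng)
        states.loc[sexes == "F", "px"] = False  # females monomorphic
        per_sex, combined = x_association(states, scores, fams, sexes,
                                          n_perms=400, seed=2)
        zm = stats.norm.isf(per_sex["M"].loc[0, "p"] / 2) * \
            per_sex["M"].loc[0, "direction"]
        assert combined.loc[0, "Z"] == pytest.approx(zm)
        assert combined.loc[0, "n_strata"] == 1


class TestRegions:
    def _results(self, ps, chrom="1"):
        return pd.DataFrame({
            "probe_id": [f"p{i}" for i in range(len(ps))],
            "chrom": chrom, "pos": np.arange(len(ps)) * 1000 + 1000,
            "p": ps})

    def test_four_probe_region_called(self):
        res = self._results([0.004, 0.003, 0.03, 0.04, 0.5, 0.9])
        regions = detect_regions(res)
        assert len(regions) == 1
        r = regions.iloc[0]
        assert r["n_probes"] == 4
        assert r["probe_ids"] == "p0,p1,p2,p3"

    def test_flat_p_yields_nothing(self):
        assert len(detect_regions(self._results([0.5] * 8))) == 0

    def test_single_core_probe_insufficient(self):
        res = self._results([0.03, 0.001, 0.03, 0.04, 0.5])
        assert len(detect_regions(res)) == 0

    def test_core_without_enough_flankers_insufficient(self):
        res = self._results([0.004, 0.003, 0.03, 0.5])
        assert len(detect_regions(res)) == 0

    def test_untested_probe_breaks_run(self):
        res = self._results([0.004, 0.003, 0.03, 0.04])
        probe_index = {"p0": 0, "p1": 1, "p2": 2, "p3": 4}  # gap before p3
        assert len(detect_regions(res, probe_index=probe_index)) == 0
        contiguous = {"p0": 0, "p1": 1, "p2": 2, "p3": 3}
        assert len(detect_regions(res, probe_index=contiguous)) == 1

    def test_chromosome_change_breaks_run(self):
        res = self._results([0.004, 0.003, 0.03, 0.04])
        res.loc[2:, "chrom"] = "2"
        assert len(detect_regions(res)) == 0

    def test_matches_window_enumeration(self, rng):
        for _ in range(60):
            ps = 10 ** rng.uniform(-4, 0, 40)
            res = self._results(ps)
            got = detect_regions(res)
            expected = brute_force_regions(ps, 0.005, 2, 0.05, 2)
            assert len(got) == len(expected)
            for r, (lo, hi) in zip(got.itertuples(), expected):
                assert r.probe_ids.split(",")[0] == f"p{lo}"
                assert r.probe_ids.split(",")[-1] == f"p{hi - 1}"


def brute_force_regions(ps, core_p, core_len, flank_p, flank_len):
    """Exhaustive enumeration of maximal qualifying runs."""
    ps = np.asarray(ps)
    n = len(ps)
    runs = []
    i = 0
    while i < n:
        if ps[i] < flank_p:
            j = i
            while j + 1 < n and ps[j + 1] < flank_p:
                j += 1
            cores = [k for k in range(i, j - core_len + 2)
                     if all(ps[k:k + core_len] < core_p)]
            if cores and (j - i + 1) >= core_len + flank_len:
                runs.append((i, j + 1))
            i = j + 1
        else:
            i += 1
    return runs


class TestThresholds:
    def test_two_trait_autosomal_alpha(self):
        alpha = bonferroni_alpha(0.05, 2, 5173)
        assert f"{alpha:.1e}" == "4.8e-06"

    def test_identity_case(self):
        assert bonferroni_alpha(0.05, 1, 1) == 0.05

    def test_intensity_scale_alpha(self):
        assert bonferroni_alpha(0.05, 2, 704_855) == pytest.approx(
            3.5466e-08, rel=1e-3)

    def test_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0, 10)


class TestCnvPlusFrequency:
    def test_planted_carriers_percentage(self, rng):
        n = 500
        ids = [f"S{i}" for i in range(n)]
        states = pd.DataFrame(False, index=ids, columns=["a", "b"])
        carriers = rng.choice(n, 9, replace=False)
        states.iloc[carriers, :] = True
        freq = cnv_plus_frequency(states, ["a", "b"])
        assert freq["any_probe_pct"] == pytest.approx(1.8)

    def test_extremes(self):
        states = pd.DataFrame(False, index=["A", "B"], columns=["a"])
        assert cnv_plus_frequency(states, ["a"])["any_probe_pct"] == 0.0
        assert cnv_plus_frequency(~states, ["a"])["any_probe_pct"] == 100.0
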