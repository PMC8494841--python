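"""Score construction: amyloid cutoff, APOE handling, clumping, thresholds,
the scoring formula, and standardization."""

import warnings

import numpy as np
import pandas as pd
import pytest

from cogpgs import (
    THRESHOLDS,
    apoe_allele_counts,
    classify_ab_status,
    clump,
    exclude_apoe_region,
    score,
    standardize_scores,
    threshold_series,
)
from conftest import make_geno, make_records


class TestAbStatus:
    @pytest.mark.parametrize(
        "ratio,expected",
        [(0.089, "positive"), (0.09, "negative"), (0.20, "negative"), (0.05, "positive")],
    )
    def test_strict_cutoff(self, ratio, expected):
        assert classify_ab_status(ratio) == expected

    @pytest.mark.parametrize("ratio", [0.0, -0.1, float("nan"), None])
    def test_invalid_ratio_missing_status(self, ratio):
        with pytest.warns(UserWarning, match="invalid"):
            assert classify_ab_status(ratio) is None


class TestApoeRegion:
    def _records(self, pos_list, ids=None):
        return pd.DataFrame(
            {
                "id": ids or [f"v{i}" for i in range(len(pos_list))],
                "chrom": ["19"] * len(pos_list),
                "pos": pos_list,
                "a1": ["C"] * len(pos_list),
                "a2": ["T"] * len(pos_list),
                "beta": [0.1] * len(pos_list),
                "p": [0.01] * len(pos_list),
            }
        )

    def test_inside_region_removed_boundary_inclusive(self):
        recs = self._records([44_399_999, 44_400_000, 45_000_000, 46_500_000, 46_500_001])
        out = exclude_apoe_region(recs)
        assert list(out["pos"]) == [44_399_999, 46_500_001]

    def test_epsilon_snps_reintroduced_when_genotyped(self):
        recs = self._records([45_411_941, 45_412_079, 45_000_000],
                             ids=["rs429358", "rs7412", "other"])
        geno = make_geno(
            np.array([[1.0, 0.0], [0.0, 1.0]]).T,
            chrom=["19", "19"], pos=[45_411_941, 45_412_079],
            ids=["rs429358", "rs7412"],
        )
        out = exclude_apoe_region(recs, geno)
        assert set(out["id"]) == {"rs429358", "rs7412"}

    def test_epsilon_snps_dropped_with_warning_when_not_genotyped(self):
        recs = self._records([45_411_941], ids=["rs429358"])
        geno = make_geno(np.zeros((2, 1)), chrom=["1"], pos=[500], ids=["x"])
        with pytest.warns(UserWarning, match="rs429358"):
            out = exclude_apoe_region(recs, geno)
        assert out.empty


class TestApoeCounts:
    @pytest.mark.parametrize(
        "d4,d2,e4,e2",
        [(2, 0, 2, 0), (0, 2, 0, 2), (1, 1, 1, 1), (0, 0, 0, 0), (1, 0, 1, 0)],
    )
    def test_haplotype_table(self, d4, d2, e4, e2):
        st = apoe_allele_counts(d4, d2)
        assert (st.e4, st.e2) == (e4, e2)

    @pytest.mark.parametrize("d4,d2", [(2, 1), (1, 2), (2, 2)])
    def test_impossible_combinations_raise(self, d4, d2):
        with pytest.raises(ValueError):
            apoe_allele_counts(d4, d2)


def _corr_pair(n, r2_target, rng):
    """Two dosage columns with controllable squared correlation."""
    x = rng.binomial(2, 0.5, n).astype(float)
    if r2_target >= 0.99:
        return x, x.copy()
    noise = rng.binomial(2, 0.5, n).astype(float)
    lam = np.sqrt(r2_target)
    y = np.where(rng.random(n) < lam, x, noise)
    return x, y


class TestClump:
    def _panel(self, positions, dosages, ps, chrom=None):
        geno = make_geno(dosages, pos=positions, chrom=chrom)
        recs = make_records(geno, beta=[0.1] * len(positions), p=ps)
        return geno, recs

    def test_correlated_neighbor_removed(self):
        rng = np.random.default_rng(0)
        x, y = _corr_pair(400, 0.8, rng)
        geno, recs = self._panel([1_000_000, 1_200_000], np.column_stack([x, y]),
                                 [1e-6, 1e-4])
        out = clump(recs, geno)
        assert list(out["id"]) == ["v1"]

    def test_uncorrelated_pair_both_kept(self):
        rng = np.random.default_rng(1)
        x = rng.binomial(2, 0.5, 2000).astype(float)
        y = rng.binomial(2, 0.5, 2000).astype(float)
        geno, recs = self._panel([1_000_000, 1_050_000], np.column_stack([x, y]),
                                 [1e-6, 1e-4])
        out = clump(recs, geno)
        assert set(out["id"]) == {"v1", "v2"}

    def test_distant_pair_kept_despite_high_r2(self):
        rng = np.random.default_rng(2)
        x, _ = _corr_pair(400, 1.0, rng)
        geno, recs = self._panel([1_000_000, 2_500_001], np.column_stack([x, x]),
                                 [1e-6, 1e-4])
        out = clump(recs, geno)
        assert set(out["id"]) == {"v1", "v2"}

    def test_missing_variant_dropped_with_warning(self):
        rng = np.random.default_rng(3)
        geno = make_geno(rng.binomial(2, 0.4, (50, 1)).astype(float), pos=[100])
        recs = pd.DataFrame(
            {
                "id": ["v1", "ghost"], "chrom": ["1", "1"], "pos": [100, 200],
                "a1": ["G", "G"], "a2": ["A", "A"], "beta": [0.1, 0.1],
                "p": [0.01, 0.001],
            }
        )
        with pytest.warns(UserWarning, match="absent"):
            out = clump(recs, geno)
        assert list(out["id"]) == ["v1"]

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        """Greedy definition re-applied from scratch at every step."""
        rng = np.random.default_rng(100 + seed)
        m = int(rng.integers(5, 16))
        n = 120
        cols = []
        j = 0
        while j < m:
            x = rng.binomial(2, rng.uniform(0.1, 0.5), n).astype(float)
            cols.append(x)
            j += 1
            if j < m and rng.random() < 0.5:  # correlated neighbour
                _, y = _corr_pair(n, rng.uniform(0.0, 1.0), rng)
                lam = rng.uniform(0, 1)
                noise = rng.binomial(2, 0.3, n).astype(float)
                y = np.where(rng.random(n) < lam, x, noise)
                cols.append(y)
                j += 1
        m = len(cols)
        pos = sorted(rng.choice(np.arange(1, 4000) * 1000, size=m, replace=False))
        chrom = list(rng.choice(["1", "2"], size=m))
        geno = make_geno(np.column_stack(cols), pos=[int(p) for p in pos], chrom=chrom)
        recs = make_records(geno, beta=rng.normal(0, 0.2, m), p=rng.uniform(0, 1, m))

        got = list(clump(recs, geno, r2_max=0.1, window_kb=1000)["id"])

        # oracle: literal restatement of the rule
        remaining = recs.sort_values(["p", "chrom", "pos", "id"]).reset_index(drop=True)
        kept = []
        while len(remaining):
            best = remaining.iloc[0]
            kept.append(best["id"])
            drop = [0]
            for i in range(1, len(remaining)):
                row = remaining.iloc[i]
                if row["chrom"] != best["chrom"]:
                    continue
                if abs(row["pos"] - best["pos"]) > 1000 * 1000:
                    continue
                a = geno.dosages[:, geno.variant_index(best["id"])]
                b = geno.dosages[:, geno.variant_index(row["id"])]
                r = np.corrcoef(a, b)[0, 1]
                if r * r >= 0.1:
                    drop.append(i)
            remaining = remaining.drop(remaining.index[drop]).reset_index(drop=True)
        assert got == kept

    def test_no_violating_pair_survives(self, small_study):
        geno = small_study.genotypes
        out = clump(small_study.summary_stats, geno)
        for i in range(len(out)):
            for j in range(i + 1, len(out)):
                a, b = out.iloc[i], out.iloc[j]
                if a["chrom"] != b["chrom"] or abs(a["pos"] - b["pos"]) > 1_000_000:
                    continue
                da = geno.dosages[:, geno.variant_index(a["id"])]
                db = geno.dosages[:, geno.variant_index(b["id"])]
                ok = ~(np.isnan(da) | np.isnan(db))
                r = np.corrcoef(da[ok], db[ok])[0, 1]
                assert r * r < 0.1


class TestThresholdSeries:
    def test_levels_and_nesting(self):
        recs = pd.DataFrame(
            {
                "id": ["a", "b", "c"], "chrom": ["1"] * 3, "pos": [1, 2, 3],
                "a1": ["G"] * 3, "a2": ["A"] * 3, "beta": [0.1] * 3,
                "p": [0.04, 1e-9, 0.2],
            }
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            series = threshold_series(recs)
        assert set(series[1]["id"]) == {"a", "b"}
        for k in range(2, 8):
            assert list(series[k]["id"]) == ["b"]
        for k in range(2, 8):
            assert set(series[k]["id"]) <= set(series[k - 1]["id"])

    def test_cutoffs_are_the_seven_standard_levels(self):
        assert THRESHOLDS == (5e-2, 5e-3, 5e-4, 5e-5, 5e-6, 5e-7, 5e-8)


class TestScore:
    def test_single_variant_printed_formula(self):
        geno = make_geno(np.array([[2.0]]))
        recs = make_records(geno, beta=[0.693], p=[0.01])
        ss = score(geno, recs)
        assert ss.scores.iloc[0] == pytest.approx(0.693 * 2 / (2 * 1))

    def test_missing_genotype_maf_substitution(self):
        # second sample missing; cohort MAF 0.25 from the other two samples
        geno = make_geno(np.array([[1.0], [np.nan], [0.0], [0.0], [0.0]])[:4])
        recs = make_records(geno, beta=[1.0], p=[0.01])
        ss = score(geno, recs)
        # MAF = mean(1,0,0)/2 = 1/6 -> substitution 2/6
        assert ss.scores.iloc[1] == pytest.approx((2 / 6) / 2)
        assert ss.m.iloc[1] == 0

    def test_missing_substitution_quarter_example(self):
        d = np.array([[np.nan], [1.0], [0.0], [1.0], [0.0], [0.0]])
        geno = make_geno(d)
        recs = make_records(geno, beta=[1.0], p=[0.01])
        ss = score(geno, recs)
        # observed freq 2/10 = 0.2 ... use explicit MAF: mean dosage 0.4 -> p=0.2
        assert ss.scores.iloc[0] == pytest.approx(0.2 * 2 / 2)

    def test_allele_swap_and_mismatch(self):
        geno = make_geno(np.array([[2.0], [0.0]]), a1=["G"], a2=["A"])
        swapped = make_records(geno, beta=[0.5], p=[0.01])
        swapped.loc[0, ["a1", "a2"]] = ["A", "G"]
        ss = score(geno, swapped)
        # effect allele A: dosage = 2 - G
        assert ss.scores.iloc[0] == pytest.approx(0.0)
        assert ss.scores.iloc[1] == pytest.approx(0.5 * 2 / 2)
        bad = make_records(geno, beta=[0.5], p=[0.01])
        bad.loc[0, ["a1", "a2"]] = ["C", "T"]
        with pytest.raises(ValueError, match="v1"):
            score(geno, bad)

    @pytest.mark.parametrize("strict", [False, True])
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_elementwise_oracle(self, seed, strict):
        rng = np.random.default_rng(200 + seed)
        n, m = 10, 20
        d = rng.choice([0.0, 1.0, 2.0], size=(n, m))
        d[rng.random((n, m)) < 0.1] = np.nan
        geno = make_geno(d)
        recs = make_records(geno, beta=rng.normal(0, 0.3, m), p=rng.uniform(0, 1, m))
        ss = score(geno, recs, strict_denominator=strict)
        freq = np.nanmean(d, axis=0) / 2  # aligned effect-allele frequency
        for i in range(n):
            total, m_obs = 0.0, 0
            for j in range(m):
                g = d[i, j]
                if np.isnan(g):
                    total += recs["beta"][j] * freq[j] * 2
                else:
                    total += recs["beta"][j] * g
                    m_obs += 1
            denom = 2 * max(m_obs, 1) if strict else 2 * m
            assert ss.scores.iloc[i] == pytest.approx(total / denom, rel=1e-12)

    def test_invariant_to_variant_and_sample_order(self):
        rng = np.random.default_rng(7)
        d = rng.choice([0.0, 1.0, 2.0], size=(8, 5))
        geno = make_geno(d)
        recs = make_records(geno, beta=rng.normal(0, 0.2, 5), p=rng.uniform(0, 1, 5))
        base = score(geno, recs).scores
        perm_v = rng.permutation(5)
        shuffled = score(geno, recs.iloc[perm_v].reset_index(drop=True)).scores
        pd.testing.assert_series_equal(base, shuffled)
        perm_s = rng.permutation(8)
        geno2 = geno.subset(sample_mask=perm_s)
        reordered = score(geno2, recs).scores
        np.testing.assert_allclose(base.to_numpy()[perm_s], reordered.to_numpy())

    @pytest.mark.parametrize("with_missing", [False, True])
    def test_flip_invariance_of_standardized_scores(self, with_missing):
        """Listing a record on the other allele (negated weight) shifts raw
        scores by a constant and leaves standardized scores unchanged
        (effect alleles kept minor so the MAF substitution is symmetric)."""
        rng = np.random.default_rng(11)
        n, m = 40, 6
        d = rng.binomial(2, rng.uniform(0.1, 0.45, m), size=(n, m)).astype(float)
        if with_missing:
            d[rng.random((n, m)) < 0.1] = np.nan
        geno = make_geno(d)
        recs = make_records(geno, beta=rng.normal(0, 0.3, m), p=rng.uniform(0, 1, m))
        flipped = recs.copy()
        flip = [0, 2, 5]
        for j in flip:
            flipped.loc[j, ["a1", "a2"]] = [recs.loc[j, "a2"], recs.loc[j, "a1"]]
            flipped.loc[j, "beta"] = -recs.loc[j, "beta"]
        z1 = standardize_scores(score(geno, recs)).scores
        z2 = standardize_scores(score(geno, flipped)).scores
        np.testing.assert_allclose(z1.to_numpy(), z2.to_numpy(), atol=1e-10)


class TestStandardize:
    def test_basic_and_idempotent(self):
        geno = make_geno(np.array([[0.0], [1.0], [2.0]]))
        recs = make_records(geno, beta=[2.0], p=[0.01])
        ss = score(geno, recs)
        z = standardize_scores(ss)
        np.testing.assert_allclose(z.scores.to_numpy(), [-1.0, 0.0, 1.0])
        z2 = standardize_scores(z)
        np.testing.assert_allclose(z.scores.to_numpy(), z2.scores.to_numpy(), atol=1e-12)

    def test_contract_mean_zero_sd_one(self, small_study):
        from cogpgs import score_threshold_series

        scores = score_threshold_series(small_study.genotypes, small_study.summary_stats)
        for ss in scores.values():
            x = ss.scores.to_numpy()
            assert abs(x.mean()) < 1e-12
            assert x.std(ddof=1) == pytest.approx(1.0, rel=1e-12)

    def test_zero_variance_rejected(self):
        geno = make_geno(np.ones((3, 1)))
        recs = make_records(geno, beta=[1.0], p=[0.01])
        with pytest.raises(ValueError):
            standardize_scores(score(geno, recs))
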