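"""Leave-one-out decomposition into amyloid-dependent/independent subsets."""

import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from cogpgs import (
    decompose,
    loo_scan,
    per_variant_ab_association,
    prs_ab_association,
    rank_and_nest,
    refine_partial,
    score,
    select_dependent,
    select_independent,
    standardize_scores,
)
from cogpgs.mediation import _as_binary
from conftest import make_geno, make_records


def _panel(n=300, m=6, seed=0, driver=None, driver_strength=1.5):
    """Dosage panel plus amyloid status optionally driven by one variant."""
    rng = np.random.default_rng(seed)
    d = rng.binomial(2, rng.uniform(0.2, 0.4, m), size=(n, m)).astype(float)
    geno = make_geno(d, pos=[j * 2_000_000 for j in range(1, m + 1)])
    logit = -0.3 * np.ones(n)
    if driver is not None:
        zd = (d[:, driver] - d[:, driver].mean()) / d[:, driver].std()
        logit = logit + driver_strength * zd
    ab = pd.Series(
        (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float),
        index=pd.Index(geno.samples, name="sample"),
    )
    recs = make_records(geno, beta=rng.uniform(0.1, 0.3, m), p=rng.uniform(0, 1e-6, m))
    return geno, recs, ab, rng


class TestAbAssociation:
    def test_planted_logistic_effect_recovered(self):
        betas = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            n = 400
            z = pd.Series(rng.normal(size=n),
                          index=pd.Index([f"s{i}" for i in range(n)], name="sample"))
            p = 1 / (1 + np.exp(-(-0.2 + 0.4 * z)))
            ab = pd.Series((rng.random(n) < p).astype(float), index=z.index)
            betas.append(prs_ab_association(z, ab).beta)
        assert np.mean(betas) == pytest.approx(0.4, abs=0.1)

    def test_separation_flagged(self):
        rng = np.random.default_rng(1)
        n = 200
        z = pd.Series(rng.normal(size=n),
                      index=pd.Index([f"s{i}" for i in range(n)], name="sample"))
        ab = pd.Series((z > z.median()).astype(float), index=z.index)
        res = prs_ab_association(z, ab)
        assert res.separation
        assert np.isnan(res.p)

    def test_monomorphic_variant_rejected(self):
        ab = pd.Series([0.0, 1.0] * 10,
                       index=pd.Index([f"s{i}" for i in range(20)], name="sample"))
        mono = pd.Series(np.ones(20), index=ab.index)
        with pytest.raises(ValueError):
            per_variant_ab_association(mono, ab)


class TestLooScan:
    def test_single_driver_removal_raises_p_most(self):
        geno, recs, ab, _ = _panel(n=500, m=3, seed=2, driver=0)
        tab = loo_scan(recs, geno, ab)
        assert tab.loc[tab["delta"].idxmax(), "id"] == "v1"
        assert tab.set_index("id").loc["v1", "candidate"] == "dependent"

    def test_zero_weight_variant_removal_is_noop(self):
        geno, recs, ab, _ = _panel(n=400, m=4, seed=3, driver=1)
        recs.loc[3, "beta"] = 0.0
        tab = loo_scan(recs, geno, ab).set_index("id")
        assert tab.loc["v4", "p_loo"] == pytest.approx(tab.loc["v4", "p_full"],
                                                       abs=1e-10)

    def test_needs_three_variants(self):
        geno, recs, ab, _ = _panel(m=3, seed=4)
        with pytest.raises(ValueError):
            loo_scan(recs.iloc[:2], geno, ab)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_from_scratch_oracle(self, seed):
        """Each row re-derived independently: rebuild the reduced score by
        hand and run the logistic fit directly through statsmodels."""
        geno, recs, ab, _ = _panel(n=250, m=7, seed=10 + seed, driver=2)
        tab = loo_scan(recs, geno, ab).set_index("id")
        for i in range(len(recs)):
            reduced = recs.drop(index=i).reset_index(drop=True)
            z = standardize_scores(score(geno, reduced)).scores
            X = sm.add_constant(pd.DataFrame({"z": z}))
            fit = sm.Logit(_as_binary(ab), X).fit(disp=0)
            vid = recs.iloc[i]["id"]
            assert tab.loc[vid, "p_loo"] == pytest.approx(float(fit.pvalues["z"]),
                                                          rel=1e-8)


class TestRankAndNest:
    def test_k_equal_n_reproduces_full_score_results(self):
        geno, recs, ab, rng = _panel(n=300, m=5, seed=5, driver=0)
        slope = pd.Series(rng.normal(size=300), index=ab.index)
        tab = loo_scan(recs, geno, ab)
        scan = rank_and_nest(tab, recs, geno, ab, slope, order="ascending",
                            n_boot=50, seed=0)
        full = standardize_scores(score(geno, recs)).scores
        X = sm.add_constant(pd.DataFrame({"z": full}))
        fit = sm.OLS(slope, X).fit()
        last = scan.iloc[-1]
        assert last["k"] == 5
        assert last["beta_unadj"] == pytest.approx(float(fit.params["z"]), rel=1e-8)
        assert last["p_unadj"] == pytest.approx(float(fit.pvalues["z"]), rel=1e-8)

    def test_nesting_property(self):
        geno, recs, ab, rng = _panel(n=300, m=6, seed=6, driver=1)
        slope = pd.Series(rng.normal(size=300), index=ab.index)
        tab = loo_scan(recs, geno, ab)
        for order in ("ascending", "descending"):
            scan = rank_and_nest(tab, recs, geno, ab, slope, order=order,
                                n_boot=20, seed=0)
            sets = [set(v.split(",")) for v in scan["variants"]]
            for a, b in zip(sets, sets[1:]):
                assert a < b

    def test_invalid_order_rejected(self):
        geno, recs, ab, rng = _panel(m=4, seed=7)
        tab = loo_scan(recs, geno, ab)
        with pytest.raises(ValueError):
            rank_and_nest(tab, recs, geno, ab, ab, order="sideways")


def _mk_scan(rows, order="ascending"):
    df = pd.DataFrame(
        rows, columns=["k", "p_unadj", "p_adj", "mediation_significant"]
    )
    df.attrs["order"] = order
    return df


class TestSelection:
    def test_independent_all_qualifying_gives_n(self):
        scan = _mk_scan([(k, 0.01, 0.01, False) for k in range(1, 6)])
        assert select_independent(scan) == 5

    def test_independent_none_qualifying(self):
        scan = _mk_scan([(k, 0.5, 0.5, True) for k in range(1, 4)])
        with pytest.warns(UserWarning, match="no nested model"):
            assert select_independent(scan) is None

    def test_independent_gap_logged_largest_wins(self):
        scan = _mk_scan(
            [(1, 0.01, 0.01, False), (2, 0.5, 0.5, False), (3, 0.01, 0.01, False)]
        )
        with pytest.warns(UserWarning, match="non-contiguous"):
            assert select_independent(scan) == 3

    def test_dependent_rule(self):
        scan = _mk_scan(
            [(1, 0.01, 0.2, False), (2, 0.01, 0.3, False), (3, 0.01, 0.01, False)],
            order="descending",
        )
        assert select_dependent(scan) == 2

    def test_order_mismatch_rejected(self):
        asc = _mk_scan([(1, 0.01, 0.01, False)])
        with pytest.raises(ValueError):
            select_dependent(asc)
        desc = _mk_scan([(1, 0.01, 0.01, False)], order="descending")
        with pytest.raises(ValueError):
            select_independent(desc)


class TestRefineAndDecompose:
    def test_singleton_dependent_set_skips_refinement(self):
        geno, recs, ab, rng = _panel(m=4, seed=8)
        slope = pd.Series(rng.normal(size=300), index=ab.index)
        with pytest.warns(UserWarning, match="skipped"):
            labels = refine_partial(["v1"], recs, geno, ab, slope)
        assert labels == {"v1": "dependent"}

    def test_classes_partition_and_contract(self):
        """Every variant gets exactly one class; refinement never relabels
        variants outside the selected dependent set."""
        geno, recs, ab, rng = _panel(n=400, m=8, seed=9, driver=3)
        slope = pd.Series(
            -0.3 * _as_binary(ab) + rng.normal(0, 0.5, 400), index=ab.index
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dec = decompose(recs, geno, ab, slope, scan_n_boot=50, seed=0)
        tab = dec.per_variant
        assert tab["class"].isin(["independent", "dependent", "partial"]).all()
        assert len(tab) == 8
        if dec.k_dependent:
            desc_order = tab.sort_values("rank_descending")["id"].tolist()
            dep_set = set(desc_order[: dec.k_dependent])
            partials = set(tab.loc[tab["class"] == "partial", "id"])
            assert partials <= dep_set

    def test_direct_only_panel_keeps_slope_signal_without_mediation(self):
        """With amyloid independent of the score and a real direct effect,
        the ascending selection keeps (near) the full panel and the
        dependent selection finds nothing."""
        rng = np.random.default_rng(20)
        n, m = 500, 6
        d = rng.binomial(2, 0.3, size=(n, m)).astype(float)
        geno = make_geno(d, pos=[j * 2_000_000 for j in range(1, m + 1)])
        recs = make_records(geno, beta=rng.uniform(0.2, 0.4, m),
                            p=rng.uniform(0, 1e-6, m))
        burden = d @ recs["beta"].to_numpy()
        burden = (burden - burden.mean()) / burden.std()
        idx = pd.Index(geno.samples, name="sample")
        ab = pd.Series(rng.integers(0, 2, n).astype(float), index=idx)
        slope = pd.Series(-0.4 * burden + 0.6 * rng.normal(size=n), index=idx)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dec = decompose(recs, geno, ab, slope, scan_n_boot=80, seed=1)
        assert dec.k_independent is not None and dec.k_independent >= m - 1
        assert (dec.per_variant["class"] == "independent").sum() >= m - 1

    def test_mediated_only_panel_selects_dependent_model(self):
        """Amyloid driven by the score and the slope driven by amyloid: the
        unadjusted association is lost under adjustment, so the dependent
        selection succeeds."""
        rng = np.random.default_rng(21)
        n, m = 600, 5
        d = rng.binomial(2, 0.3, size=(n, m)).astype(float)
        geno = make_geno(d, pos=[j * 2_000_000 for j in range(1, m + 1)])
        recs = make_records(geno, beta=rng.uniform(0.2, 0.4, m),
                            p=rng.uniform(0, 1e-6, m))
        burden = d @ recs["beta"].to_numpy()
        burden = (burden - burden.mean()) / burden.std()
        idx = pd.Index(geno.samples, name="sample")
        ab = pd.Series(
            (rng.random(n) < 1 / (1 + np.exp(-(-0.2 + 1.5 * burden)))).astype(float),
            index=idx,
        )
        slope = pd.Series(-0.5 * ab + 0.4 * rng.normal(size=n), index=idx)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dec = decompose(recs, geno, ab, slope, scan_n_boot=80, seed=2)
        assert dec.k_dependent is not None and dec.k_dependent >= 2
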