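"""Marker filtering, genome scan, QTL declaration, r2/effects, clustering."""

import numpy as np
import pandas as pd
import pytest

import rilqtl as rq
from rilqtl.scan import declare_qtls


def _toy_map(positions, chrom="c1"):
    table = pd.DataFrame({
        "marker": [f"m{i + 1}" for i in range(len(positions))],
        "chrom": chrom, "pos_cM": positions})
    return rq.GeneticMap(table=table, chromosomes=((chrom, max(positions)),))


def _scan_table(pvals, positions, chrom="c1", col="p_constitutive"):
    t = pd.DataFrame({
        "marker": [f"m{i + 1}" for i in range(len(pvals))],
        "chrom": chrom, "pos_cM": positions, col: pvals})
    other = ("p_responsive" if col == "p_constitutive" else "p_constitutive")
    t[other] = 1.0
    return t


def _qtl(trait, chrom, lo, hi, kind="constitutive"):
    return rq.QTLRecord(trait=trait, kind=kind, chrom=chrom, peak_marker="x",
                        peak_pos_cM=(lo + hi) / 2, ci_start_cM=lo,
                        ci_end_cM=hi, p_peak=1e-9)


class TestFilterMarkers:
    def test_monomorphic_and_missing_thresholds(self):
        n = 50
        rng = np.random.default_rng(0)
        base = rng.choice([1.0, -1.0], size=n)
        mono = np.ones(n)
        miss16 = base.copy().astype(float)
        miss16[:8] = np.nan    # 8/50 = 16%
        miss14 = base.copy().astype(float)
        miss14[:7] = np.nan    # 7/50 = 14%
        calls = pd.DataFrame({"ok": base, "mono": mono,
                              "m16": miss16, "m14": miss14},
                             index=[f"L{i}" for i in range(n)])
        geno = rq.RILGenotypes(calls=calls)
        kept = rq.filter_markers(geno, max_missing=0.15)
        assert list(kept.marker_ids) == ["ok", "m14"]

    def test_parental_polymorphism_and_hand_count(self):
        # 10 markers, 3 designed to fail: 1 monomorphic between parents,
        # 1 with a missing parental call, 1 with 20% missing among lines
        n = 20
        rng = np.random.default_rng(1)
        calls = {}
        p1, p2 = {}, {}
        for i in range(10):
            name = f"m{i}"
            calls[name] = rng.choice([1.0, -1.0], size=n)
            p1[name], p2[name] = 1.0, -1.0
        p2["m3"] = 1.0            # monomorphic between parents
        p1["m5"] = np.nan         # parental call missing
        col = calls["m7"].astype(float).copy()
        col[:4] = np.nan          # 4/20 = 20% missing
        calls["m7"] = col
        geno = rq.RILGenotypes(calls=pd.DataFrame(
            calls, index=[f"L{i}" for i in range(n)]))
        kept = rq.filter_markers(geno, parents=(pd.Series(p1), pd.Series(p2)),
                                 max_missing=0.15)
        assert len(kept.marker_ids) == 7
        assert set(kept.marker_ids) == {f"m{i}" for i in range(10)} - {"m3", "m5", "m7"}

    def test_all_filtered_is_an_error(self):
        calls = pd.DataFrame({"m": np.ones(10)}, index=[f"L{i}" for i in range(10)])
        with pytest.raises(ValueError, match="all markers"):
            rq.filter_markers(rq.RILGenotypes(calls=calls))


class TestDeclareQTLs:
    def test_forced_adjacency_example(self):
        """Frozen enumeration: runs [m2..m4] and [m6] -> two QTLs with
        peak/CI fixed by the adjacency rule."""
        gmap = _toy_map([0, 10, 20, 30, 40, 50])
        t = _scan_table([0.1, 1e-6, 1e-7, 1e-6, 0.2, 1e-6],
                        [0, 10, 20, 30, 40, 50])
        qtls = declare_qtls(t, gmap, alpha=5e-5, kind="constitutive")
        assert len(qtls) == 2
        assert (qtls[0].peak_pos_cM, qtls[0].ci_start_cM, qtls[0].ci_end_cM) \
            == (20.0, 10.0, 30.0)
        assert (qtls[1].peak_pos_cM, qtls[1].ci_start_cM, qtls[1].ci_end_cM) \
            == (50.0, 50.0, 50.0)

    def test_threshold_is_strict(self):
        gmap = _toy_map([0.0, 10.0])
        t = _scan_table([5e-5, 4.9e-5], [0.0, 10.0])
        qtls = declare_qtls(t, gmap, alpha=5e-5, kind="constitutive")
        assert len(qtls) == 1
        assert qtls[0].peak_marker == "m2"

    def test_no_signal_empty(self):
        gmap = _toy_map([0.0, 10.0])
        t = _scan_table([0.5, 0.9], [0.0, 10.0])
        assert declare_qtls(t, gmap, kind="constitutive") == []

    def test_peak_tie_broken_toward_midpoint(self):
        gmap = _toy_map([0, 10, 20, 30, 40])
        t = _scan_table([1e-8, 1e-6, 1e-8, 1e-8, 0.5], [0, 10, 20, 30, 40])
        qtls = declare_qtls(t, gmap, kind="constitutive")
        # run spans 0..30, midpoint 15; tied minima at 0, 20, 30 -> 20 wins
        assert qtls[0].peak_pos_cM == 20.0


@pytest.fixture(scope="module")
def balanced_null():
    gmap = rq.simulate_genetic_map(2, 10, 80.0, seed=3)
    geno = rq.simulate_ril_genotypes(gmap, 120, seed=3)
    comp = rq.TrueComponents(sigma2_g=1.0, sigma2_gy=0, sigma2_ge=0,
                             sigma2_bloc=0, sigma2_E=2.0)
    trial = rq.simulate_trial_phenotypes(geno, [], rq.TrialDesign(), comp,
                                         seed=3)
    return gmap, geno, trial


def stratum_anova_oracle(df, geno, marker):
    """Independent stratum-level fixed-effects ANOVA of a single marker.

    Constitutive: OLS of line means on the allele, t-test with lines-2 df.
    Responsive: OLS with line dummies and the within-line design, F-test of
    the allele x scenario column against the within-line residual.
    """
    from scipy import stats as st
    sub = df.assign(x=df["line"].map(geno.calls[marker])).dropna(subset=["x"])
    # between stratum
    lm = sub.groupby("line").agg(y=("trait", "mean"), x=("x", "first"))
    X = np.column_stack([np.ones(len(lm)), lm["x"].to_numpy()])
    yv = lm["y"].to_numpy()
    b, *_ = np.linalg.lstsq(X, yv, rcond=None)
    r = yv - X @ b
    dfb = len(lm) - 2
    se = np.sqrt((r @ r) / dfb * np.linalg.inv(X.T @ X)[1, 1])
    p_const = 2 * st.t.sf(abs(b[1] / se), dfb)
    # within stratum
    ni = (sub["scenario"] == "NI").astype(float).to_numpy()
    cols = [pd.get_dummies(sub["line"], dtype=float).to_numpy(), ni[:, None]]
    for yr in sorted(sub["year"].unique())[1:]:
        yd = (sub["year"] == yr).astype(float).to_numpy()
        cols += [yd[:, None], (yd * ni)[:, None]]
    W0 = np.hstack(cols)
    W1 = np.hstack([W0, (sub["x"].to_numpy() * ni)[:, None]])
    yv = sub["trait"].to_numpy()

    def rss(M):
        bb, *_ = np.linalg.lstsq(M, yv, rcond=None)
        rr = yv - M @ bb
        return float(rr @ rr)

    dfw = len(sub) - np.linalg.matrix_rank(W1)
    f = (rss(W0) - rss(W1)) / (rss(W1) / dfw)
    p_resp = st.f.sf(f, 1, dfw)
    return p_const, p_resp


class TestScan:
    def test_matches_stratum_anova_oracle_on_balanced_design(
            self, balanced_null):
        """On a balanced design the mixed-model Wald tests reduce to the
        classical stratum ANOVA: a line-mean regression for the marker term
        and a within-line F-test for the marker x scenario term."""
        gmap, geno, trial = balanced_null
        res = rq.MarkerScanModel(trial.phenotypes, geno, gmap, "trait").fit()
        df = trial.phenotypes[~trial.phenotypes["is_check"]]
        for _, row in res.table.iterrows():
            p_c, p_r = stratum_anova_oracle(df, geno, row["marker"])
            assert row["p_constitutive"] == pytest.approx(p_c, rel=1e-2)
            assert row["p_responsive"] == pytest.approx(p_r, rel=1e-2)

    def test_marker_order_permutation_invariant(self, balanced_null):
        gmap, geno, trial = balanced_null
        model = rq.MarkerScanModel(trial.phenotypes, geno, gmap, "trait")
        markers = list(geno.marker_ids)
        a = model.fit(markers=markers).table.set_index("marker")
        rng = np.random.default_rng(0)
        b = model.fit(markers=rng.permutation(markers)).table.set_index("marker")
        pd.testing.assert_frame_equal(a.sort_index(), b.sort_index())

    def test_single_allele_class_flagged_untestable(self, balanced_null):
        gmap, geno, trial = balanced_null
        calls = geno.calls.copy()
        calls.iloc[:, 0] = 1.0  # wipe variation at the first marker
        geno2 = rq.RILGenotypes(calls=calls)
        res = rq.MarkerScanModel(trial.phenotypes, geno2, gmap, "trait").fit(
            markers=[calls.columns[0]])
        row = res.table.iloc[0]
        assert not row["testable"]
        assert row["p_constitutive"] == 1.0 and row["p_responsive"] == 1.0

    def test_responsive_qtl_hits_interaction_not_main_term(self):
        """A purely scenario-dependent allele effect shows up in the
        marker x scenario test, far below the marker main-effect test."""
        gmap = rq.simulate_genetic_map(1, 10, 100.0, seed=6)
        geno = rq.simulate_ril_genotypes(gmap, 200, seed=6)
        comp = rq.TrueComponents(sigma2_g=1.0, sigma2_gy=0.2, sigma2_ge=0.2,
                                 sigma2_bloc=0.0, sigma2_E=2.0)
        p_resp, p_const = [], []
        for rep in range(5):
            trial = rq.simulate_trial_phenotypes(
                geno, [rq.QTLEffectSpec("chr1_m0005", 0.0, 1.0)],
                rq.TrialDesign(), comp, seed=100 + rep)
            res = rq.MarkerScanModel(trial.phenotypes, geno, gmap,
                                     "trait").fit(markers=["chr1_m0005"])
            p_resp.append(res.table["p_responsive"].iloc[0])
            p_const.append(res.table["p_constitutive"].iloc[0])
        assert np.median(p_resp) < 1e-4
        assert np.median(p_resp) < np.median(p_const) * 1e-2

    def test_allele_relabel_flips_effect_sign_only(self, balanced_null):
        gmap, geno, trial = balanced_null
        corrected = trial.phenotypes
        lsm = {s: rq.lsmeans(corrected, "trait", s) for s in ("all", "I", "NI")}
        qtl = rq.QTLRecord(trait="trait", kind="constitutive", chrom="chr1",
                           peak_marker="chr1_m0004", peak_pos_cM=10.0,
                           ci_start_cM=0.0, ci_end_cM=20.0, p_peak=1e-9)
        eff = rq.qtl_effect(lsm, geno, qtl)
        flipped = rq.RILGenotypes(calls=-geno.calls)
        eff_f = rq.qtl_effect(lsm, flipped, qtl)
        assert eff_f == pytest.approx(-eff, abs=1e-12)
        assert rq.qtl_r2(lsm["I"], lsm["NI"], geno, qtl) == pytest.approx(
            rq.qtl_r2(lsm["I"], lsm["NI"], flipped, qtl), abs=1e-9)


class TestQtlR2AndEffect:
    def _lsm(self, values, scope):
        return rq.LsMeans(values=pd.Series(values), scope=scope)

    def test_null_marker_r2_near_zero(self):
        rng = np.random.default_rng(7)
        lines = [f"L{i}" for i in range(250)]
        geno = rq.RILGenotypes(calls=pd.DataFrame(
            {"m": rng.choice([1.0, -1.0], size=250)}, index=lines))
        lsm_I = self._lsm(pd.Series(rng.normal(size=250), index=lines), "I")
        lsm_NI = self._lsm(pd.Series(rng.normal(size=250), index=lines), "NI")
        qtl = _qtl("t", "c1", 0, 10)
        qtl = rq.QTLRecord(**{**qtl.__dict__, "peak_marker": "m"})
        assert rq.qtl_r2(lsm_I, lsm_NI, geno, qtl) < 1.0

    def test_deterministic_allele_signal_partitioned_correctly(self):
        lines = [f"L{i}" for i in range(20)]
        x = np.array([1.0, -1.0] * 10)
        geno = rq.RILGenotypes(calls=pd.DataFrame({"m": x}, index=lines))
        vals = pd.Series(np.where(x > 0, 2.0, -2.0), index=lines)
        jitter = pd.Series(np.linspace(-0.01, 0.01, 20), index=lines)
        lsm_I = self._lsm(vals + jitter, "I")
        lsm_NI = self._lsm(vals - jitter, "NI")
        base = _qtl("t", "c1", 0, 10)
        qc = rq.QTLRecord(**{**base.__dict__, "peak_marker": "m"})
        qr = rq.QTLRecord(**{**base.__dict__, "peak_marker": "m",
                             "kind": "responsive"})
        # the reduced constitutive model keeps x*e, which still fits the NI
        # half perfectly: the R2 drop is 100 minus the interaction share (50%)
        assert rq.qtl_r2(lsm_I, lsm_NI, geno, qc) == pytest.approx(50.0, abs=0.5)
        assert rq.qtl_r2(lsm_I, lsm_NI, geno, qr) < 1.0

    def test_r2_equals_squared_semipartial_correlation(self):
        """Independent algebra: the R2 drop from removing one regressor is
        the squared correlation between the response and that regressor
        residualized on the remaining ones."""
        rng = np.random.default_rng(8)
        lines = [f"L{i}" for i in range(18)]
        x = rng.choice([1.0, -1.0], size=18)
        geno = rq.RILGenotypes(calls=pd.DataFrame({"m": x}, index=lines))
        lsm_I = self._lsm(pd.Series(rng.normal(size=18) + 0.8 * x,
                                    index=lines), "I")
        lsm_NI = self._lsm(pd.Series(rng.normal(size=18) - 0.3 * x,
                                     index=lines), "NI")
        base = _qtl("t", "c1", 0, 10)
        qc = rq.QTLRecord(**{**base.__dict__, "peak_marker": "m"})
        got = rq.qtl_r2(lsm_I, lsm_NI, geno, qc)
        y = np.concatenate([lsm_I.values.to_numpy(), lsm_NI.values.to_numpy()])
        e = np.concatenate([np.zeros(18), np.ones(18)])
        xs = np.concatenate([x, x])
        others = np.column_stack([np.ones(36), e, xs * e])
        resid_x = xs - others @ np.linalg.lstsq(others, xs, rcond=None)[0]
        resid_y = y - others @ np.linalg.lstsq(others, y, rcond=None)[0]
        sp2 = 100.0 * (resid_x @ resid_y) ** 2 / (
            (resid_x @ resid_x) * float((y - y.mean()) @ (y - y.mean())))
        assert got == pytest.approx(sp2, abs=1e-8)

    def test_effect_arithmetic_and_zero_range_error(self):
        lines = [f"L{i}" for i in range(10)]
        x = np.array([1.0] * 5 + [-1.0] * 5)
        geno = rq.RILGenotypes(calls=pd.DataFrame({"m": x}, index=lines))
        vals = pd.Series(np.where(x > 0, 6.0, 4.0), index=lines)
        vals.iloc[0] = 10.0  # stretch the range to 10 - 0
        vals.iloc[-1] = 0.0
        base = _qtl("t", "c1", 0, 10)
        qc = rq.QTLRecord(**{**base.__dict__, "peak_marker": "m"})
        lsm = {"all": self._lsm(vals, "all")}
        got = rq.qtl_effect(lsm, geno, qc)
        diff = vals[x > 0].mean() - vals[x < 0].mean()
        assert got == pytest.approx(diff / 10.0)
        const = {"all": self._lsm(pd.Series(1.0, index=lines), "all")}
        with pytest.raises(ValueError, match="range"):
            rq.qtl_effect(const, geno, qc)

    def test_equal_class_means_give_zero_effect(self):
        lines = [f"L{i}" for i in range(8)]
        x = np.array([1.0, -1.0] * 4)
        geno = rq.RILGenotypes(calls=pd.DataFrame({"m": x}, index=lines))
        vals = pd.Series([1.0, 1.0, 3.0, 3.0, 5.0, 5.0, 7.0, 7.0], index=lines)
        base = _qtl("t", "c1", 0, 10)
        qc = rq.QTLRecord(**{**base.__dict__, "peak_marker": "m"})
        assert rq.qtl_effect({"all": self._lsm(vals, "all")}, geno, qc) == 0.0

    def test_planted_responsive_effect_recovered(self, small_geno):
        d = 0.8
        comp = rq.TrueComponents(sigma2_g=0.3, sigma2_gy=0.05, sigma2_ge=0.05,
                                 sigma2_bloc=0.0, sigma2_E=0.2)
        trial = rq.simulate_trial_phenotypes(
            small_geno, [rq.QTLEffectSpec("chr1_m0010", 0.0, d)],
            rq.TrialDesign(), comp, seed=41)
        t = trial.phenotypes
        lsm = {s: rq.lsmeans(t, "trait", s) for s in ("all", "I", "NI")}
        base = _qtl("trait", "chr1", 0, 10, kind="responsive")
        q = rq.QTLRecord(**{**base.__dict__, "peak_marker": "chr1_m0010"})
        eff = rq.qtl_effect(lsm, small_geno, q)
        resp = (lsm["NI"].values - lsm["I"].values).dropna()
        expected = 2 * d / (resp.max() - resp.min())
        assert eff > 0
        assert eff == pytest.approx(expected, rel=0.30)


class TestClusters:
    def test_different_chromosomes_never_cluster(self):
        qtls = [_qtl("a", "c1", 10, 30), _qtl("b", "c2", 10, 30)]
        clusters, singles = rq.cluster_qtls(qtls, "constitutive")
        assert clusters == [] and len(singles) == 2

    def test_single_linkage_chaining(self):
        qtls = [_qtl("a", "c1", 10, 30), _qtl("b", "c1", 25, 40),
                _qtl("c", "c1", 38, 50)]
        clusters, singles = rq.cluster_qtls(qtls, "constitutive")
        assert len(clusters) == 1 and singles == []
        assert clusters[0].traits == ("a", "b", "c")
        assert (clusters[0].span_start_cM, clusters[0].span_end_cM) == (10, 50)

    def test_disjoint_intervals_stay_singletons(self):
        qtls = [_qtl("a", "c1", 10, 20), _qtl("b", "c1", 21, 30)]
        clusters, singles = rq.cluster_qtls(qtls, "constitutive")
        assert clusters == [] and len(singles) == 2

    def test_touching_endpoints_count_as_overlap(self):
        qtls = [_qtl("a", "c1", 10, 20), _qtl("b", "c1", 20, 30)]
        clusters, _ = rq.cluster_qtls(qtls, "constitutive")
        assert len(clusters) == 1

    def test_same_trait_pair_not_a_cluster(self):
        qtls = [_qtl("a", "c1", 10, 20), _qtl("a", "c1", 15, 30)]
        clusters, singles = rq.cluster_qtls(qtls, "constitutive")
        assert clusters == [] and len(singles) == 2
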