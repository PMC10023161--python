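"""Differential binding exact test and gene-set overlap statistics."""

import numpy as np
import pytest
from scipy import stats

from clipforge.differential import (
    DifferentialError,
    differential_binding,
    estimate_common_dispersion,
    gain_loss_distribution,
    overlap_enrichment,
)


def hypergeom_fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by enumerating the hypergeometric support."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    pmf = {k: stats.hypergeom.pmf(k, n, r1, c1) for k in range(lo, hi + 1)}
    obs = pmf[a]
    return min(sum(p for p in pmf.values() if p <= obs * (1 + 1e-9)), 1.0)


class TestDifferentialBinding:
    def run2(self, wt, ko, **kw):
        ids = [f"p{i}" for i in range(len(wt))]
        return differential_binding(ids, np.array(wt), np.array(ko), **kw)

    def test_identical_counts_all_ns(self):
        wt = [[50, 60], [10, 12], [200, 190]]
        res = self.run2(wt, wt)
        assert all(r.klass == "NS" for r in res)
        assert all(r.log2fc == pytest.approx(0.0) for r in res)

    def test_poisson_limit_matches_binomial_oracle(self):
        wt = [[120, 130], [30, 28], [300, 310]]
        ko = [[40, 45], [30, 29], [100, 95]]
        res = self.run2(wt, ko, fixed_dispersion=0.0)
        for r, w_pair, k_pair in zip(res, wt, ko):
            s = sum(w_pair) + sum(k_pair)
            oracle = stats.binomtest(sum(k_pair), s, 0.5).pvalue
            assert r.p == pytest.approx(oracle, rel=1e-9)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(8)
        wt = rng.integers(5, 400, size=(12, 2))
        ko = rng.integers(5, 400, size=(12, 2))
        fwd = self.run2(wt.tolist(), ko.tolist())
        rev = self.run2(ko.tolist(), wt.tolist())
        for f, r in zip(fwd, rev):
            assert f.p == pytest.approx(r.p, rel=1e-9)
            swap = {"Gain": "Loss", "Loss": "Gain", "NS": "NS"}
            assert r.klass == swap[f.klass]
            assert r.log2fc == pytest.approx(-f.log2fc, abs=1e-9)

    def test_class_exclusivity_and_fdr_gate(self):
        rng = np.random.default_rng(9)
        wt = rng.integers(5, 400, size=(20, 2))
        ko = rng.integers(5, 400, size=(20, 2))
        res = self.run2(wt.tolist(), ko.tolist())
        for r in res:
            assert r.klass in ("Gain", "Loss", "NS")
            if r.klass != "NS":
                assert r.fdr < 0.05
                assert (r.log2fc > 0) == (r.klass == "Gain")

    def test_library_size_normalization(self):
        # doubling one library's counts along with its size leaves the
        # normalized fold change and the call unchanged
        res_a = self.run2([[100, 100]], [[50, 50]],
                          library_sizes={"WT_IP1": 1000, "WT_IP2": 1000,
                                         "KO_IP1": 1000, "KO_IP2": 1000})
        res_b = self.run2([[200, 100]], [[50, 50]],
                          library_sizes={"WT_IP1": 2000, "WT_IP2": 1000,
                                         "KO_IP1": 1000, "KO_IP2": 1000})
        assert res_a[0].log2fc == pytest.approx(res_b[0].log2fc, abs=0.05)
        assert res_a[0].klass == res_b[0].klass

    def test_replicate_shape_enforced(self):
        with pytest.raises(DifferentialError):
            differential_binding(["p0"], np.array([[1, 2, 3]]), np.array([[1, 2, 3]]))

    def test_dispersion_estimator_recovers_magnitude(self):
        rng = np.random.default_rng(10)
        phi = 0.05
        size = 1 / phi
        means = rng.uniform(50, 500, 200)
        wt = np.stack([rng.negative_binomial(size, size / (size + means)),
                       rng.negative_binomial(size, size / (size + means))], axis=1)
        ko = np.stack([rng.negative_binomial(size, size / (size + means)),
                       rng.negative_binomial(size, size / (size + means))], axis=1)
        est = estimate_common_dispersion(wt.astype(float), ko.astype(float))
        assert 0.5 * phi < est < 2.0 * phi

    def test_loss_peaks_recovered(self, wt_run):
        from clipforge.peaks import RegionCounter
        from clipforge.simulate import simulate_clip_experiment

        cfg = wt_run["config"]
        ko = simulate_clip_experiment(
            wt_run["genome"], wt_run["annotation"], wt_run["truth"], cfg, "KO"
        )
        wc = RegionCounter(wt_run["fragments"])
        kc = RegionCounter(ko)
        sel = wt_run["selected"]
        ids = [f"p{i}" for i in range(len(sel))]
        wcnt = [[wc.count(s, *r.interval()) for s in ("IP1", "IP2")] for r in sel]
        kcnt = [[kc.count(s, *r.interval()) for s in ("IP1", "IP2")] for r in sel]
        libs = {"WT_IP1": wc.totals["IP1"], "WT_IP2": wc.totals["IP2"],
                "KO_IP1": kc.totals["IP1"], "KO_IP2": kc.totals["IP2"]}
        res = differential_binding(ids, wcnt, kcnt, libs)
        loss_truth = [p for p in wt_run["truth"].planted_peaks
                      if p.ko_fate == "loss" and p.enrichment >= 8]
        assert loss_truth
        for p in loss_truth:
            classes = [d.klass for r, d in zip(sel, res)
                       if r.chrom == p.chrom and r.start < p.end and r.end > p.start]
            assert "Loss" in classes


class TestOverlapEnrichment:
    def make_sets(self, n_class, n_in, n_targets, n_universe):
        universe = {f"g{i}" for i in range(n_universe)}
        klass = {f"g{i}" for i in range(n_class)}
        targets = {f"g{i}" for i in range(n_in)} | {
            f"g{i}" for i in range(n_class, n_class + n_targets - n_in)
        }
        return targets, klass, universe

    def test_printed_percentage_arithmetic(self):
        targets, klass, universe = self.make_sets(340, 41, 952, 14000)
        res = overlap_enrichment(targets, klass, universe)
        assert res.n_targets_in_class == 41
        assert round(res.percentage) == 12

    def test_fisher_matches_enumeration_on_toy_universe(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            universe = {f"g{i}" for i in range(10)}
            targets = set(rng.choice(sorted(universe), size=4, replace=False))
            klass = set(rng.choice(sorted(universe), size=5, replace=False))
            res = overlap_enrichment(targets, klass, universe)
            a = len(targets & klass)
            b = len(klass) - a
            c = len(targets) - a
            d = 10 - len(klass) - c
            assert res.p == pytest.approx(hypergeom_fisher_oracle(a, b, c, d),
                                          rel=1e-9)

    def test_universe_padding_keeps_percentage_changes_p(self):
        targets, klass, universe = self.make_sets(40, 20, 100, 500)
        res1 = overlap_enrichment(targets, klass, universe)
        padded = universe | {f"pad{i}" for i in range(2000)}
        res2 = overlap_enrichment(targets, klass, padded)
        assert res1.percentage == res2.percentage
        assert res1.p != res2.p

    def test_degenerate_targets_equal_universe(self):
        universe = {f"g{i}" for i in range(10)}
        res = overlap_enrichment(universe, set(list(universe)[:3]), universe)
        assert res.degenerate

    def test_validation(self):
        with pytest.raises(DifferentialError):
            overlap_enrichment({"x"}, {"a"}, {"a"})
        with pytest.raises(DifferentialError):
            overlap_enrichment(set(), set(), {"a"})


class TestGainLossDistribution:
    def test_printed_fifty_percent(self):
        deg = {f"g{i}": "down" for i in range(40)}
        deg.update({f"u{i}": "up" for i in range(30)})
        deg.update({f"i{i}": "invariant" for i in range(100)})
        loss = {f"g{i}" for i in range(20)}
        df, p = gain_loss_distribution(set(), loss, deg)
        down = df.set_index("class").loc["down"]
        assert down["n_loss"] == 20
        assert down["pct_loss"] == pytest.approx(50.0)
        assert p < 0.05

    def test_no_loss_peaks(self):
        deg = {"a": "down", "b": "up"}
        df, p = gain_loss_distribution(set(), set(), deg)
        assert (df["n_loss"] == 0).all()
        assert p == 1.0

    def test_fisher_matches_enumeration_on_toy(self):
        deg = {f"g{i}": ("down" if i < 5 else "invariant") for i in range(12)}
        loss = {"g0", "g1", "g2", "g6"}
        _, p = gain_loss_distribution(set(), loss, deg)
        # down: 3 of 5 carry loss; rest: 1 of 7
        assert p == pytest.approx(hypergeom_fisher_oracle(3, 2, 1, 6), rel=1e-9)
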