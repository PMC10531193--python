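"""Loess normalization, NB differential test, KS shift, motifs, states."""

import math

import numpy as np
import pandas as pd
import pytest

from regelex import diffacc, synthio


@pytest.fixture(scope="module")
def spike_data():
    return synthio.simulate_atac_counts(
        600, (10, 11), spike_fraction=0.05, spike_log2fc=2.0, seed=22
    )


class TestLoessNormalize:
    def test_identical_samples_give_zero_offsets(self):
        rng = np.random.default_rng(0)
        col = rng.poisson(100, size=300).astype(float)
        counts = pd.DataFrame(
            np.tile(col[:, None], (1, 6)), columns=[f"s{i}" for i in range(6)]
        )
        off = diffacc.loess_normalize(counts)
        assert np.abs(off.to_numpy()).max() < 1e-6

    def test_offsets_center_to_zero_per_element(self, spike_data):
        counts, _, _ = spike_data
        off = diffacc.loess_normalize(counts)
        assert np.abs(off.to_numpy().sum(axis=1)).max() < 1e-8

    def test_uniform_doubling_recovered_in_offsets(self):
        counts, _, _ = synthio.simulate_atac_counts(
            800, (10, 11), libsize_sd=0.0, spike_fraction=0.0, seed=30
        )
        doubled = counts.copy()
        doubled.iloc[:, 0] = doubled.iloc[:, 0] * 2
        off = diffacc.loess_normalize(doubled)
        rel = off.iloc[:, 0] - off.iloc[:, 1:].mean(axis=1)
        assert rel.mean() == pytest.approx(1.0, abs=0.05)
        assert rel.std() < 0.1  # constant across abundance

    def test_abundance_dependent_bias_removed(self):
        counts, _, _ = synthio.simulate_atac_counts(
            800, (10, 11), libsize_sd=0.0, spike_fraction=0.0, seed=31
        )
        X = counts.to_numpy(float)
        log2c = np.log2(X + 0.5)
        A = log2c.mean(axis=1)
        biased = X.copy()
        biased[:, 1] = biased[:, 1] * 2 ** (0.5 * (A - A.mean()))
        cb = pd.DataFrame(biased, columns=counts.columns)
        off = diffacc.loess_normalize(cb)
        log2b = np.log2(biased + 0.5)
        resid = (log2b[:, 1] - log2b.mean(axis=1)) - off.iloc[:, 1].to_numpy()
        slope = np.polyfit(log2b.mean(axis=1), resid, 1)[0]
        assert abs(slope) < 0.05

    def test_all_zero_matrix_raises(self):
        with pytest.raises(ValueError):
            diffacc.loess_normalize(pd.DataFrame(np.zeros((5, 4))))


class TestDifferentialTest:
    def test_spiked_element_with_strong_signal_detected(self):
        # 4-fold spikes, dispersion 0.1, 10 vs 11 samples: every spiked
        # element with baseline mean around 200 (log2 mean 7-8) is found.
        # The abundance range extends beyond the spikes so the trended
        # normalization sees a non-differential majority at every abundance.
        counts, samples, truth = synthio.simulate_atac_counts(
            1000, (10, 11), baseline_logmean_range=(3.0, 10.0), dispersion=0.1,
            spike_fraction=0.05, spike_log2fc=2.0, seed=40,
        )
        res = diffacc.test_differential(counts, None, samples["group"])
        strong = truth.loc[truth["is_differential"] & truth["base_log2mean"].between(7, 8),
                           "element_id"]
        assert len(strong) >= 3
        assert (res.loc[strong, "q"] < 0.05).all()

    def test_all_zero_element_reported_untested(self, spike_data):
        counts, samples, _ = spike_data
        counts = counts.copy()
        counts.iloc[0] = 0
        res = diffacc.test_differential(counts, None, samples["group"])
        assert not res["tested"].iloc[0]
        assert np.isnan(res["p"].iloc[0])

    def test_group_swap_negates_log2fc_keeps_p(self, spike_data):
        counts, samples, _ = spike_data
        off = diffacc.loess_normalize(counts)
        res1 = diffacc.test_differential(counts, off, samples["group"])
        swapped = samples["group"].map({"g1": "g2", "g2": "g1"})
        res2 = diffacc.test_differential(counts, off, swapped)
        tested = res1["tested"]
        np.testing.assert_allclose(
            res1.loc[tested, "log2fc"], -res2.loc[tested, "log2fc"], atol=1e-6
        )
        np.testing.assert_allclose(res1.loc[tested, "p"], res2.loc[tested, "p"], atol=1e-9)

    def test_bh_q_dominates_p_and_is_monotone(self, spike_data):
        counts, samples, _ = spike_data
        res = diffacc.test_differential(counts, None, samples["group"]).dropna(subset=["p"])
        assert (res["q"] >= res["p"] - 1e-12).all()
        by_p = res.sort_values("p")
        assert (np.diff(by_p["q"]) >= -1e-12).all()

    def test_small_group_raises(self, spike_data):
        counts, _, _ = spike_data
        groups = ["a"] + ["b"] * (counts.shape[1] - 1)
        with pytest.raises(ValueError):
            diffacc.test_differential(counts, None, groups)


def _ks_oracle(x, y):
    """Textbook two-sample KS: D by ECDF scan, p by the asymptotic
    Kolmogorov series."""
    x, y = np.sort(x), np.sort(y)
    allv = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, allv, side="right") / len(x)
    cdf_y = np.searchsorted(y, allv, side="right") / len(y)
    D = np.abs(cdf_x - cdf_y).max()
    en = math.sqrt(len(x) * len(y) / (len(x) + len(y)))
    t = (en + 0.12 + 0.11 / en) * D
    p = 2 * sum((-1) ** (j - 1) * math.exp(-2 * j**2 * t**2) for j in range(1, 101))
    return D, min(max(p, 0.0), 1.0)


class TestKsShift:
    def test_identical_samples(self):
        v = np.arange(10.0)
        D, p = diffacc.ks_shift_test(v, v)
        assert D == 0.0 and p == 1.0

    def test_disjoint_supports(self):
        D, _ = diffacc.ks_shift_test([1.0, 2.0], [10.0, 11.0])
        assert D == 1.0

    def test_matches_textbook_implementation(self):
        rng = np.random.default_rng(5)
        q = rng.normal(0, 1, 500)
        b = rng.normal(0.5, 1, 5000)
        D, p = diffacc.ks_shift_test(q, b)
        D0, p0 = _ks_oracle(q, b)
        assert D == pytest.approx(D0, abs=1e-6)
        assert p == pytest.approx(p0, rel=0.1)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            diffacc.ks_shift_test([], [1.0])


def _hypergeom_fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    n = a + b + c + d
    row1, col1 = a + b, a + c

    def pmf(k):
        return (
            math.comb(col1, k) * math.comb(n - col1, row1 - k) / math.comb(n, row1)
        )

    p_obs = pmf(a)
    return sum(pmf(k) for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1)
               if pmf(k) <= p_obs * (1 + 1e-9))


class TestMotifEnrichment:
    @staticmethod
    def build(n_diff_with, n_diff, n_bg_with, n_bg):
        diff = {f"d{i}" for i in range(n_diff)}
        bg = {f"b{i}" for i in range(n_bg)}
        hits = {f"d{i}": {"m"} for i in range(n_diff_with)}
        hits.update({f"b{i}": {"m"} for i in range(n_bg_with)})
        return diff, bg, hits

    def test_worked_odds_ratio_and_exact_p(self):
        diff, bg, hits = self.build(30, 100, 10, 100)
        out = diffacc.motif_enrichment(diff, bg, hits)
        row = out.set_index("motif").loc["m"]
        assert row["odds_ratio"] == pytest.approx((30 * 90) / (70 * 10), rel=1e-9)
        assert row["p"] == pytest.approx(_hypergeom_fisher_oracle(30, 70, 10, 90), rel=1e-6)

    def test_equal_proportions_null(self):
        diff, bg, hits = self.build(20, 100, 20, 100)
        row = diffacc.motif_enrichment(diff, bg, hits).set_index("motif").loc["m"]
        assert row["odds_ratio"] == pytest.approx(1.0)
        assert row["p"] == pytest.approx(1.0)

    def test_zero_cell_reports_infinite_odds(self):
        diff, bg, hits = self.build(10, 20, 0, 20)
        row = diffacc.motif_enrichment(diff, bg, hits).set_index("motif").loc["m"]
        assert np.isinf(row["odds_ratio"])
        assert 0 < row["p"] <= 1

    def test_overlapping_sets_raise(self):
        with pytest.raises(ValueError):
            diffacc.motif_enrichment({"x"}, {"x", "y"}, {})


class TestStateTransitions:
    def marks(self, rows):
        return pd.DataFrame(rows, columns=["H3K27ac", "H3K4me1"],
                            index=[f"e{i}" for i in range(len(rows))])

    def test_state_rule(self):
        pre = self.marks([[2.0, 2.0], [0.1, 2.0], [0.1, 0.1]])
        per, _ = diffacc.state_transitions(pre, pre)
        assert list(per["state_pre"]) == ["active", "poised", "inactive"]

    def test_poised_to_active_transition(self):
        pre = self.marks([[0.1, 2.0]])
        post = self.marks([[2.0, 2.0]])
        per, table = diffacc.state_transitions(pre, post)
        assert per.iloc[0].tolist() == ["poised", "active"]
        assert table.loc["poised", "active"] == 1

    def test_table_marginals_conserve_pre_counts(self):
        rng = np.random.default_rng(7)
        pre = self.marks(rng.normal(1, 1, size=(100, 2)))
        post = self.marks(rng.normal(1, 1, size=(100, 2)))
        per, table = diffacc.state_transitions(pre, post)
        for s in diffacc.CHROMATIN_STATES:
            assert table.loc[s].sum() == (per["state_pre"] == s).sum()

    def test_missing_mark_raises(self):
        bad = pd.DataFrame({"H3K27ac": [1.0]})
        with pytest.raises(ValueError, match="H3K4me1"):
            diffacc.state_transitions(bad, bad)
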