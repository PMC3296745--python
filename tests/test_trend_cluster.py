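import re

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dosagescan import trend_cluster
from dosagescan.trend_cluster import (
    ClusterReport,
    TrendTable,
    bin_trend_table,
    cluster_randomness_test,
    downregulation_trend,
    find_gene_clusters,
    linear_by_linear_test,
)


class TestBinning:
    def test_default_region_bins(self):
        t = bin_trend_table([50, 200, 700], [True, False, True])
        assert list(t.table["n"]) == [1, 1, 1]
        assert list(t.table["bin"]) == ["1-100", "101-500", ">500"]

    def test_empty_bins_retained(self):
        t = bin_trend_table([50, 60], [True, False])
        assert list(t.table["n"]) == [2, 0, 0]

    def test_all_in_one_bin_trend_is_na(self):
        t = bin_trend_table([10, 20, 30], [True, False, True])
        m2, p = linear_by_linear_test(t)
        assert np.isnan(m2) and np.isnan(p)

    def test_monotone_plant_recovered(self):
        rng = np.random.default_rng(1)
        counts, flags = [], []
        for i, (c, rate) in enumerate([(50, 0.1), (300, 0.3), (700, 0.5)]):
            counts += [c] * 200
            flags += list(rng.random(200) < rate)
        t = bin_trend_table(counts, flags)
        pct = t.table["pct"].to_numpy()
        assert pct[0] < pct[1] < pct[2]


class TestLinearByLinear:
    def test_perfect_gradient_closed_form(self):
        t = bin_trend_table([50] * 10 + [200] * 10,
                            [False] * 10 + [True] * 10)
        m2, p = linear_by_linear_test(t)
        assert m2 == pytest.approx(19.0)  # (N-1) * r^2 with r = 1

    def test_flat_proportions(self):
        t = bin_trend_table([50] * 10 + [200] * 10 + [700] * 10,
                            ([True] * 5 + [False] * 5) * 3)
        m2, p = linear_by_linear_test(t)
        assert m2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_expanded_unit_level_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            n = rng.integers(5, 40, size=3)
            k = [int(rng.integers(0, ni + 1)) for ni in n]
            counts = np.repeat([50, 200, 700], n)
            flags = np.concatenate([
                [True] * k[i] + [False] * (n[i] - k[i]) for i in range(3)
            ])
            t = bin_trend_table(counts, flags)
            m2, _ = linear_by_linear_test(t)
            # brute force: expand to unit vectors and correlate
            scores = np.repeat([1, 2, 3], n).astype(float)
            y = flags.astype(float)
            if np.std(y) == 0 or np.std(scores) == 0:
                assert np.isnan(m2)
                continue
            r = np.corrcoef(scores, y)[0, 1]
            assert m2 == pytest.approx((len(y) - 1) * r**2, rel=1e-9)

    def test_invariance_under_affine_score_change(self):
        t = bin_trend_table([50] * 8 + [200] * 12 + [700] * 6,
                            [True, False] * 4 + [True] * 8 + [False] * 4
                            + [True] * 4 + [False] * 2)
        m2, _ = linear_by_linear_test(t)
        t2 = TrendTable(table=t.table.assign(score=t.table["score"] * 10 - 3),
                        n_total=t.n_total)
        m2b, _ = linear_by_linear_test(t2)
        assert m2 == pytest.approx(m2b)


class TestDownTrend:
    def test_monotone_fractions(self):
        counts = [0] * 10 + [1] * 10 + [3] * 10 + [10] * 10
        rng = np.random.default_rng(3)
        down = ([True] * 1 + [False] * 9 + [True] * 2 + [False] * 8
                + [True] * 3 + [False] * 7 + [True] * 4 + [False] * 6)
        out = downregulation_trend(counts, down)
        assert out["rho_bins"] == pytest.approx(1.0)

    def test_constant_fractions(self):
        counts = [0] * 10 + [1] * 10 + [3] * 10
        down = ([True] * 2 + [False] * 8) * 3
        out = downregulation_trend(counts, down)
        assert out["rho_bins"] == 0.0 and out["p_bins"] == 1.0

    def test_planted_silencing_slope_detected(self):
        rng = np.random.default_rng(4)
        n = 500
        counts = rng.integers(0, 21, n)
        down = rng.random(n) < (0.05 + 0.03 * counts)
        out = downregulation_trend(counts, down)
        assert out["rho_units"] > 0 and out["p_units"] < 0.01


def oracle_runs(statuses):
    s = "".join("d" if x in ("up", "down") else "n" for x in statuses)
    return [(m.start(), m.end() - 1) for m in re.finditer(r"d{2,}", s)]


class TestClusters:
    def test_definition_case(self):
        rep = find_gene_clusters(["up", "up", "unchanged", "down"])
        assert rep.runs == [(0, 1)]
        assert rep.clustered_fraction == pytest.approx(2 / 3)

    def test_no_deregulated_genes(self):
        rep = find_gene_clusters(["unchanged"] * 5)
        assert np.isnan(rep.clustered_fraction)

    def test_mixed_direction_run_allowed(self):
        rep = find_gene_clusters(["down", "up", "down"])
        assert rep.runs == [(0, 2)] and rep.clustered == 3

    def test_matches_regex_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            statuses = rng.choice(["up", "down", "unchanged"],
                                  size=rng.integers(2, 50),
                                  p=[0.2, 0.2, 0.6])
            rep = find_gene_clusters(statuses)
            assert rep.runs == oracle_runs(statuses)

    def test_flipping_gap_gene_never_decreases_fraction(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            statuses = list(rng.choice(["up", "down", "unchanged"], size=30,
                                       p=[0.25, 0.25, 0.5]))
            base = find_gene_clusters(statuses)
            for i in range(1, 29):
                if statuses[i] == "unchanged" and \
                        statuses[i - 1] != "unchanged" and \
                        statuses[i + 1] != "unchanged":
                    flipped = statuses.copy()
                    flipped[i] = "up"
                    new = find_gene_clusters(flipped)
                    if not np.isnan(base.clustered_fraction):
                        assert new.clustered_fraction >= base.clustered_fraction


class TestClusterRandomness:
    def test_extreme_clustering_rejected(self):
        statuses = ["up"] * 12 + ["unchanged"] * 88
        rep = find_gene_clusters(statuses)
        out = cluster_randomness_test(rep, n_monte_carlo=5000, seed=0)
        assert out["p"] < 1e-4 and out["p_mc"] < 0.01

    def test_seed_reproducibility_and_convergence(self):
        rng = np.random.default_rng(7)
        statuses = list(rng.choice(["up", "unchanged"], size=60, p=[0.3, 0.7]))
        rep = find_gene_clusters(statuses)
        a = cluster_randomness_test(rep, n_monte_carlo=5000, seed=42)
        b = cluster_randomness_test(rep, n_monte_carlo=5000, seed=42)
        assert a == b
        c = cluster_randomness_test(rep, n_monte_carlo=5000, seed=43)
        assert abs(a["p_mc"] - c["p_mc"]) < 0.02

    def test_type_one_error_calibrated(self):
        rejections = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            statuses = list(rng.choice(["up", "down", "unchanged"], size=80,
                                       p=[0.15, 0.15, 0.7]))
            rep = find_gene_clusters(statuses)
            if rep.n_deregulated < 10:
                continue
            out = cluster_randomness_test(rep, n_monte_carlo=400, seed=seed)
            if out["p_mc"] < 0.05:
                rejections += 1
        assert rejections / n_seeds < 0.10

    def test_too_few_genes_gives_na(self):
        rep = find_gene_clusters(["up", "unchanged"])
        out = cluster_randomness_test(rep)
        assert np.isnan(out["p"])
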