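import numpy as np
import pandas as pd
import pytest

from dosagescan import cna_builder, mrr_finder
from dosagescan.io_model import SnpDataset

from conftest import make_dataset


def dataset_with_intervals(intervals, positions, directions=None):
    """States where sample i is altered exactly on its interval(s)."""
    states = {}
    for s, ivs in intervals.items():
        vec = []
        for p in positions:
            code = 2
            for k, (lo, hi) in enumerate(ivs):
                if lo <= p <= hi:
                    d = directions[s][k] if directions else "gain"
                    code = 3 if d == "gain" else 1
            vec.append(code)
        states[s] = vec
    return make_dataset(positions, states)


class TestRecurrentSnps:
    def test_all_gained(self):
        ds = make_dataset([1], {"A": [3], "B": [3], "C": [3], "D": [3]})
        assert mrr_finder.recurrent_altered_snps(ds).iloc[0] == "recurrent-gained"

    def test_one_normal_breaks_recurrence(self):
        ds = make_dataset([1], {"A": [3], "B": [3], "C": [3], "D": [2]})
        assert mrr_finder.recurrent_altered_snps(ds).iloc[0] == "none"

    def test_mixed_direction(self):
        ds = make_dataset([1], {"A": [3], "B": [1], "C": [3], "D": [4]})
        assert mrr_finder.recurrent_altered_snps(ds).iloc[0] == "recurrent-mixed"

    def test_matches_columnwise_brute_force(self):
        rng = np.random.default_rng(5)
        mat = rng.choice([0, 1, 2, 3, 4], size=(1000, 4),
                         p=[0.05, 0.25, 0.3, 0.3, 0.1])
        ds = make_dataset(range(1, 1001),
                          {f"s{j}": mat[:, j] for j in range(4)})
        got = mrr_finder.recurrent_altered_snps(ds)
        for i in range(1000):
            row = mat[i]
            if (row == 2).any():
                exp = "none"
            elif all(v in (3, 4) for v in row):
                exp = "recurrent-gained"
            elif all(v in (0, 1) for v in row):
                exp = "recurrent-deleted"
            else:
                exp = "recurrent-mixed"
            assert got.iloc[i] == exp


class TestFindMrrs:
    def test_identical_cnas_give_identity_mrr(self):
        pos = list(range(100, 501, 50))
        ds = dataset_with_intervals(
            {s: [(100, 500)] for s in "ABCD"}, pos)
        cnas = cna_builder.build_all_cnas(ds)
        (m,) = mrr_finder.find_mrrs(cnas, ds)
        assert (m.start, m.end, m.direction) == (100, 500, "gained")
        assert m.mrr_id == "1-1"

    def test_missing_in_one_sample_gives_none(self):
        pos = list(range(100, 501, 50))
        ds = dataset_with_intervals(
            {"A": [(100, 500)], "B": [(100, 500)], "C": [(100, 500)],
             "D": []}, pos)
        cnas = cna_builder.build_all_cnas(ds)
        assert mrr_finder.find_mrrs(cnas, ds) == []

    def test_staggered_intersection(self):
        pos = list(range(100, 701, 25))
        ds = dataset_with_intervals(
            {"A": [(100, 500)], "B": [(200, 600)], "C": [(300, 700)],
             "D": [(250, 650)]}, pos)
        cnas = cna_builder.build_all_cnas(ds)
        (m,) = mrr_finder.find_mrrs(cnas, ds)
        assert (m.start, m.end) == (300, 500)
        # per-base-pair membership oracle over the probe coordinate range
        coverage = np.zeros(701, dtype=int)
        for cl in cnas.values():
            for c in cl:
                coverage[c.start:c.end + 1] += 1
        full = np.flatnonzero(coverage == 4)
        assert full.min() == 300 and full.max() == 500
        assert np.all(np.diff(full) == 1)

    def test_combined_direction(self):
        pos = list(range(100, 501, 50))
        ds = dataset_with_intervals(
            {"A": [(100, 500)], "B": [(100, 500)], "C": [(100, 500)],
             "D": [(100, 500)]},
            pos,
            directions={"A": ["gain"], "B": ["gain"], "C": ["loss"],
                        "D": ["gain"]},
        )
        cnas = cna_builder.build_all_cnas(ds)
        mrrs = mrr_finder.find_mrrs(cnas, ds, require_recurrent_snp=False)
        assert {m.direction for m in mrrs} == {"combined"}

    def test_fewer_than_two_samples_rejected(self):
        ds = make_dataset([1, 2], {"A": [3, 3]})
        cnas = cna_builder.build_all_cnas(ds)
        with pytest.raises(ValueError):
            mrr_finder.find_mrrs(cnas, ds)

    def test_random_sets_match_per_bp_oracle(self):
        rng = np.random.default_rng(6)
        L = 3000
        for _ in range(25):
            pos = np.sort(rng.choice(np.arange(1, L), 200, replace=False))
            mat = rng.choice([1, 2, 3], size=(200, 4), p=[0.25, 0.5, 0.25])
            ds = make_dataset(pos, {f"s{j}": mat[:, j] for j in range(4)})
            cnas = cna_builder.build_all_cnas(ds)
            got = mrr_finder.find_mrrs(cnas, ds, require_recurrent_snp=False)
            cover = np.zeros(L + 2, dtype=int)
            for cl in cnas.values():
                for c in cl:
                    cover[c.start:c.end + 1] += 1
            mask = cover == 4
            # maximal covered segments that contain >= 1 probe
            segs = []
            i = 1
            while i <= L:
                if mask[i]:
                    j = i
                    while j + 1 <= L and mask[j + 1]:
                        j += 1
                    if ((pos >= i) & (pos <= j)).any():
                        segs.append((i, j))
                    i = j + 1
                else:
                    i += 1
            assert [(m.start, m.end) for m in got] == segs

    def test_intersection_covered_by_every_sample(self, sim_mrrs, sim_cnas):
        for m in sim_mrrs:
            for s, cl in sim_cnas.items():
                assert any(c.chrom == m.chrom and c.start <= m.start
                           and c.end >= m.end for c in cl)

    def test_recurrent_snps_inside_at_most_one_mrr(self, sim_bundle, sim_mrrs):
        ds = sim_bundle["dataset"]
        rec = mrr_finder.recurrent_altered_snps(ds)
        pos = ds.probes["pos"].to_numpy()
        chrom = ds.probes["chrom"].to_numpy()
        for i in np.flatnonzero((rec != "none").to_numpy()):
            hits = [m for m in sim_mrrs
                    if m.chrom == chrom[i] and m.start <= pos[i] <= m.end]
            assert len(hits) <= 1


class TestSummaries:
    def test_mean_log2_arithmetic(self):
        ds = make_dataset([100, 200], {"A": [3, 3]},
                          log2={"A": [0.2, 0.4]})
        cnas = {"A": cna_builder.build_all_cnas(ds)["A"],
                "B": cna_builder.build_all_cnas(ds)["A"]}
        # reuse the same interval for a second pseudo-sample
        ds2 = make_dataset([100, 200], {"A": [3, 3], "B": [3, 3]},
                           log2={"A": [0.2, 0.4], "B": [0.2, 0.4]})
        cnas = cna_builder.build_all_cnas(ds2)
        (m,) = mrr_finder.find_mrrs(cnas, ds2)
        table = mrr_finder.summarize_mrr([m], ds2)
        assert table["mean_log2"].iloc[0] == pytest.approx(0.3)

    def test_degenerate_all_zero_log2(self):
        ds = make_dataset([100, 200], {"A": [3, 3], "B": [3, 3]},
                          log2={"A": [0.0, 0.0], "B": [0.0, 0.0]})
        cnas = cna_builder.build_all_cnas(ds)
        (m,) = mrr_finder.find_mrrs(cnas, ds)
        table = mrr_finder.summarize_mrr([m], ds)
        assert table["mean_log2"].iloc[0] == 0.0
        assert table["neg_log10_p"].iloc[0] == 0.0

    def test_sampling_recovers_planted_mean(self):
        rng = np.random.default_rng(10)
        n = 100
        vals = rng.normal(0.3, 0.05, n)
        ds = make_dataset(range(1, n + 1), {"A": [3] * n, "B": [3] * n},
                          log2={"A": vals, "B": vals})
        cnas = cna_builder.build_all_cnas(ds)
        (m,) = mrr_finder.find_mrrs(cnas, ds)
        table = mrr_finder.summarize_mrr([m], ds)
        se = 0.05 / np.sqrt(2 * n)
        assert abs(table["mean_log2"].iloc[0] - vals.mean()) < 1e-12
        assert abs(table["mean_log2"].iloc[0] - 0.3) < 4 * 0.05 / np.sqrt(n)
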