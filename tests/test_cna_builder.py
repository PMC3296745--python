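from itertools import groupby

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dosagescan import cna_builder
from dosagescan.cna_builder import Cna, build_cnas, classify_snp_state
from dosagescan.io_model import SnpTrack

from conftest import make_dataset, make_probes


def oracle_runs(states, chroms):
    """Independent run reconstruction: group consecutive probes by
    (chromosome, alteration sign) with itertools.groupby."""
    sign = [1 if s in (3, 4) else (-1 if s in (0, 1) else 0) for s in states]
    runs = []
    i = 0
    for (chrom, sgn), grp in groupby(zip(chroms, sign), key=lambda t: t):
        n = len(list(grp))
        if sgn != 0:
            runs.append((i, i + n - 1, "gain" if sgn > 0 else "loss"))
        i += n
    return runs


@pytest.mark.parametrize("state,expected", [
    (0, "loss"), (1, "loss"), (2, "normal"), (3, "gain"), (4, "gain"),
])
def test_state_classification(state, expected):
    assert classify_snp_state(state) == expected


def test_invalid_state_rejected():
    with pytest.raises(ValueError):
        classify_snp_state(5)


def test_single_run_definition():
    ds = make_dataset([100, 200, 300, 400, 500], {"A": [2, 3, 3, 3, 2]})
    cnas = build_cnas(ds.track("A"), ds.probes)
    assert len(cnas) == 1
    c = cnas[0]
    assert (c.direction, c.n_snps, c.start, c.end) == ("gain", 3, 200, 400)


def test_all_normal_yields_nothing():
    ds = make_dataset([1, 2, 3], {"A": [2, 2, 2]})
    assert build_cnas(ds.track("A"), ds.probes) == []


def test_isolated_altered_snp_is_single_snp_cna():
    ds = make_dataset([10, 20, 30], {"A": [2, 4, 2]})
    (c,) = build_cnas(ds.track("A"), ds.probes)
    assert c.n_snps == 1 and c.start == c.end == 20


def test_direction_change_breaks_run():
    ds = make_dataset([1, 2, 3, 4], {"A": [3, 3, 1, 1]})
    cnas = build_cnas(ds.track("A"), ds.probes)
    assert [c.direction for c in cnas] == ["gain", "loss"]
    assert [c.n_snps for c in cnas] == [2, 2]


def test_runs_do_not_cross_chromosomes():
    import pandas as pd
    from dosagescan.io_model import SnpDataset
    probes = pd.concat([make_probes([100, 200]),
                        make_probes([50, 150], chrom="chr2", offset=2)],
                       ignore_index=True)
    states = pd.DataFrame({"A": [3, 3, 3, 3]})
    ds = SnpDataset(probes=probes, states=states)
    cnas = build_cnas(ds.track("A"), ds.probes)
    assert [(c.chrom, c.n_snps) for c in cnas] == [("chr1", 2), ("chr2", 2)]


def test_random_tracks_match_linear_scan_oracle():
    rng = np.random.default_rng(7)
    for _ in range(200):
        n = int(rng.integers(1, 60))
        states = rng.choice([0, 1, 2, 3, 4], size=n,
                            p=[0.02, 0.2, 0.4, 0.3, 0.08])
        n_chr1 = int(rng.integers(0, n + 1))
        chroms = ["chr1"] * n_chr1 + ["chr2"] * (n - n_chr1)
        import pandas as pd
        from dosagescan.io_model import SnpDataset
        probes = pd.DataFrame({
            "snp_id": [f"s{i}" for i in range(n)],
            "chrom": chroms,
            "pos": list(range(100, 100 + 10 * n, 10)),
        })
        ds = SnpDataset(probes=probes, states=pd.DataFrame({"A": states}))
        cnas = build_cnas(ds.track("A"), ds.probes)
        expected = oracle_runs(states, chroms)
        got = [
            (probes["pos"].tolist().index(c.start),
             probes["pos"].tolist().index(c.end), c.direction)
            for c in cnas
        ]
        assert got == expected
        # count conservation and direction homogeneity
        assert sum(c.n_snps for c in cnas) == int((states != 2).sum())
        for c in cnas:
            idx = [probes.loc[probes["snp_id"] == sid].index[0]
                   for sid in c.snp_ids]
            signs = {classify_snp_state(int(states[i])) for i in idx}
            assert signs == {c.direction}


@settings(derandomize=True, max_examples=60, deadline=None)
@given(st.lists(st.integers(min_value=0, max_value=4), min_size=1,
                max_size=40))
def test_count_conservation_and_homogeneity(states):
    """Every altered probe belongs to exactly one run, and no run mixes
    gain and loss members — for arbitrary state vectors."""
    ds = make_dataset(range(10, 10 + 10 * len(states), 10), {"A": states})
    cnas = build_cnas(ds.track("A"), ds.probes)
    assert sum(c.n_snps for c in cnas) == sum(s != 2 for s in states)
    seen = set()
    for c in cnas:
        assert c.direction in ("gain", "loss")
        assert not (set(c.snp_ids) & seen)
        seen |= set(c.snp_ids)


def test_idempotence_on_reconstructed_states():
    rng = np.random.default_rng(8)
    n = 80
    states = rng.choice([1, 2, 3], size=n, p=[0.25, 0.5, 0.25])
    ds = make_dataset(range(100, 100 + 10 * n, 10), {"A": states})
    cnas = build_cnas(ds.track("A"), ds.probes)
    rebuilt = np.full(n, 2)
    for c in cnas:
        for sid in c.snp_ids:
            i = ds.probes.index[ds.probes["snp_id"] == sid][0]
            rebuilt[i] = 3 if c.direction == "gain" else 1
    ds2 = make_dataset(range(100, 100 + 10 * n, 10), {"A": rebuilt})
    cnas2 = build_cnas(ds2.track("A"), ds2.probes)
    assert [(c.start, c.end, c.direction) for c in cnas] == \
        [(c.start, c.end, c.direction) for c in cnas2]


class TestGenomeFraction:
    def test_arithmetic(self):
        c = Cna("a.1", "a", "chr1", 1, 500, "gain", tuple("ab"))
        assert cna_builder.genome_altered_fraction([c], {"chr1": 1000}) == 50.0

    def test_empty(self):
        assert cna_builder.genome_altered_fraction([], {"chr1": 1000}) == 0.0

    def test_missing_length_errors(self):
        c = Cna("a.1", "a", "chr9", 1, 10, "gain", ("x",))
        with pytest.raises(KeyError):
            cna_builder.genome_altered_fraction([c], {"chr1": 1000})

    def test_planted_truth_recovery(self):
        # plant two disjoint fully-altered regions of known span
        pos = list(range(1000, 101_000, 1000))
        states = [2] * len(pos)
        for i, p in enumerate(pos):
            if 10_000 <= p <= 20_000 or 50_000 <= p <= 60_000:
                states[i] = 3
        ds = make_dataset(pos, {"A": states})
        cnas = build_cnas(ds.track("A"), ds.probes)
        frac = cna_builder.genome_altered_fraction(cnas, {"chr1": 200_000})
        planted = (20_000 - 10_000 + 1) + (60_000 - 50_000 + 1)
        assert frac == pytest.approx(100 * planted / 200_000)


class TestComposition:
    def test_small_example(self):
        ds = make_dataset([1, 2, 3, 4, 5], {"A": [3, 3, 1, 4, 2]})
        row = cna_builder.state_composition_summary(ds).iloc[0]
        assert row["pct_gain"] == 50.0
        assert row["pct_single_deletion"] == 25.0
        assert row["pct_amplification"] == 25.0
        assert row["pct_altered"] == 80.0

    def test_all_normal(self):
        ds = make_dataset([1, 2], {"A": [2, 2]})
        row = cna_builder.state_composition_summary(ds).iloc[0]
        assert row["n_altered"] == 0 and row["pct_altered"] == 0.0

    def test_sampling_recovers_class_probabilities(self):
        rng = np.random.default_rng(9)
        n = 50_000
        p = {"gain": 0.455, "single_deletion": 0.485,
             "amplification": 0.055, "double_deletion": 0.005}
        states = rng.choice([3, 1, 4, 0], size=n, p=list(p.values()))
        ds = make_dataset(range(1, n + 1), {"A": states})
        row = cna_builder.state_composition_summary(ds).iloc[0]
        for name, prob in p.items():
            se = np.sqrt(prob * (1 - prob) / n)
            assert abs(row[f"pct_{name}"] / 100 - prob) < 3 * se
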