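import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cndiverse import (
    CNVR,
    CallConfig,
    SimConfig,
    build_genome,
    call_strain,
    normalize_track,
    rank_sum_test,
    round_half_up,
    segment,
    simulate_population,
)
from cndiverse.calling import test_significance as significance_filter
from conftest import make_track, uniform_depth_frame


@pytest.fixture(scope="module")
def genome():
    return build_genome(1, 200_000, 0.45, seed=2)


class TestRounding:
    @pytest.mark.parametrize(
        "x,expected",
        [(0.49, 0), (0.5, 1), (1.49, 1), (1.5, 2), (2.4, 2), (0.0, 0), (3.5, 4)],
    )
    def test_round_half_up(self, x, expected):
        assert round_half_up(x) == expected


class TestNormalize:
    def test_uniform_depth_gives_unit_ratio(self, genome):
        track = normalize_track(uniform_depth_frame(genome), genome)
        assert np.allclose(track.data["ratio"], 1.0)
        assert (track.data["cn_state"] == 1).all()

    def test_doubled_region_gives_state_two(self, genome):
        tab = uniform_depth_frame(genome)
        region = (tab["start"] >= 50_000) & (tab["start"] < 52_500)
        tab.loc[region, "depth"] = 60
        track = normalize_track(tab, genome)
        assert np.allclose(track.data.loc[region, "ratio"], 2.0, atol=0.01)
        assert (track.data.loc[region, "cn_state"] == 2).all()
        assert (track.data.loc[~region, "cn_state"] == 1).all()

    def test_monotone_gc_bias_removed(self):
        """A depth field with strong monotone GC bias loses its correlation
        with GC after binned-median correction (|r| < 0.05)."""
        genome = build_genome(1, 1_000_000, 0.45, seed=4)
        rng = np.random.default_rng(8)
        starts = genome.window_starts("chr1", 250)
        gc = np.clip(0.45 + 0.05 * rng.standard_normal(len(starts)), 0.30, 0.60)
        bias = 1.0 + 2.0 * (gc - 0.30)
        depth = rng.poisson(30 * bias)
        tab = pd.DataFrame({"chrom": "chr1", "start": starts, "depth": depth, "gc": gc})
        assert len(tab) >= 2000
        r_raw = np.corrcoef(depth, gc)[0, 1]
        assert r_raw > 0.3
        track = normalize_track(tab, genome)
        r_corr = np.corrcoef(track.data["ratio"], gc)[0, 1]
        assert abs(r_corr) < 0.05

    def test_rejects_majority_zero_depth(self, genome):
        tab = uniform_depth_frame(genome)
        tab.loc[: int(0.6 * len(tab)), "depth"] = 0
        with pytest.raises(ValueError, match="zero"):
            normalize_track(tab, genome)

    def test_rejects_track_not_tiling_genome(self, genome):
        tab = uniform_depth_frame(genome).iloc[::2]
        with pytest.raises(ValueError, match="tile"):
            normalize_track(tab, genome)

    def test_scale_invariance(self, genome):
        """Multiplying all depths by a constant leaves ratios and states
        unchanged."""
        tab = uniform_depth_frame(genome)
        rng = np.random.default_rng(3)
        tab["depth"] = rng.poisson(30, len(tab))
        t1 = normalize_track(tab, genome)
        tab2 = tab.assign(depth=tab["depth"] * 7)
        t2 = normalize_track(tab2, genome)
        assert np.allclose(t1.data["ratio"], t2.data["ratio"])
        assert (t1.data["cn_state"] == t2.data["cn_state"]).all()


class TestSegment:
    def test_single_duplication_run(self, genome):
        track = make_track(genome, states={"chr1": [1, 1, 2, 2, 2, 1]})
        (r,) = segment(track, min_windows=1)
        assert (r.start, r.end, r.cn, r.event_class) == (500, 1250, 2, "dup")

    def test_two_deletion_runs_split_by_neutral_window(self, genome):
        track = make_track(genome, states={"chr1": [0, 0, 1, 0, 0]})
        regions = segment(track, min_windows=2)
        assert [(r.start, r.end, r.cn) for r in regions] == [
            (0, 500, 0),
            (750, 1250, 0),
        ]

    def test_all_neutral_gives_nothing(self, genome):
        assert segment(make_track(genome), min_windows=1) == []

    def test_min_windows_discards_short_runs(self, genome):
        track = make_track(genome, states={"chr1": [2, 1, 1, 0, 0, 0]})
        regions = segment(track, min_windows=2)
        assert [(r.start, r.end) for r in regions] == [(750, 1500)]

    def test_windows_belong_to_at_most_one_region(self, genome):
        rng = np.random.default_rng(12)
        states = rng.choice([0, 1, 2, 3], size=400, p=[0.1, 0.6, 0.2, 0.1])
        regions = segment(make_track(genome, states={"chr1": states}), min_windows=1)
        covered = set()
        for r in regions:
            for w in range(r.start, r.end, 250):
                assert w not in covered
                covered.add(w)

    def test_cnvr_cannot_be_baseline(self):
        with pytest.raises(ValueError):
            CNVR("s", "chr1", 0, 500, 1, "dup", 0.01, 2)


class TestRankSum:
    def test_clear_shift_is_significant(self):
        rng = np.random.default_rng(5)
        cand = rng.normal(2.0, 0.1, 20)
        neut = rng.normal(1.0, 0.1, 500)
        assert rank_sum_test(cand, neut) < 1e-6

    def test_exact_enumeration_matches_brute_force(self):
        """Small-sample p-values equal an explicit enumeration of all
        rank assignments."""
        rng = np.random.default_rng(6)
        for n1, n2 in [(1, 3), (2, 5), (3, 4)]:
            x = rng.normal(0, 1, n1)
            y = rng.normal(0, 1, n2)
            p = rank_sum_test(x, y)
            # brute force: U distribution over all equally likely splits
            pooled = np.concatenate([x, y])
            ranks = pooled.argsort().argsort() + 1
            u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
            us = []
            for comb in itertools.combinations(range(n1 + n2), n1):
                u = ranks[list(comb)].sum() - n1 * (n1 + 1) / 2
                us.append(u)
            us = np.array(us)
            mu = n1 * n2 / 2
            p_brute = np.mean(np.abs(us - mu) >= abs(u_obs - mu) - 1e-12)
            assert p == pytest.approx(p_brute, abs=1e-12)

    def test_single_window_vs_three_neutral(self):
        p = rank_sum_test(np.array([5.0]), np.array([1.0, 1.1, 0.9]))
        assert p == pytest.approx(0.5)


class TestSignificance:
    def test_strong_candidate_retained_weak_rejected(self, genome):
        rng = np.random.default_rng(7)
        n = genome.n_windows("chr1", 250)
        ratio = rng.normal(1.0, 0.1, n)
        ratio[100:120] = rng.normal(2.0, 0.1, 20)
        tab = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": genome.window_starts("chr1", 250),
                "depth": 30,
                "gc": 0.45,
                "ratio": ratio,
                "cn_state": round_half_up(ratio),
            }
        )
        from cndiverse import WindowTrack

        track = WindowTrack("s1", 250, tab)
        cand = CNVR("s1", "chr1", 100 * 250, 120 * 250, 2, "dup", float("nan"), 20)
        kept = significance_filter(cand, track, alpha=0.05)
        assert kept is not None and kept.p_value < 1e-10


class TestCallStrain:
    def test_recovers_embedded_events(self, genome):
        big = build_genome(4, 750_000, 0.4, seed=1)
        cfg = SimConfig(
            n_strains=1,
            n_loci=10,
            p_subtelomeric=0.3,
            dup_size_dist=(np.log(2500.0), 0.3),
            del_size_dist=(0.0, 1.0),
            seed=31,
        )
        events, tracks = simulate_population(big, cfg)
        from cndiverse import precision_recall, truth_intervals_by_strain

        truth = truth_intervals_by_strain(events)
        _, cnvrs = call_strain(
            tracks["strain_001"], big, CallConfig(min_windows=4), strain_id="strain_001"
        )
        pr = precision_recall({"strain_001": cnvrs}, truth)
        assert pr["recall"] >= 0.9

    def test_event_free_strain_rarely_calls(self, genome):
        cfg = SimConfig(n_strains=1, n_loci=0, seed=41)
        _, tracks = simulate_population(genome, cfg)
        _, cnvrs = call_strain(tracks["strain_001"], genome, CallConfig())
        assert len(cnvrs) <= 2  # bounded by the type-I property at this size

    def test_deterministic_output(self, genome, tmp_path):
        from cndiverse.calling import write_cnvr_bed

        cfg = SimConfig(n_strains=1, n_loci=8, p_subtelomeric=0.3, seed=43)
        _, tracks = simulate_population(genome, cfg)
        for name in ("a.bed", "b.bed"):
            _, cnvrs = call_strain(tracks["strain_001"], genome, CallConfig(), "s1")
            write_cnvr_bed(cnvrs, tmp_path / name)
        assert (tmp_path / "a.bed").read_bytes() == (tmp_path / "b.bed").read_bytes()

    @given(scale=st.integers(min_value=2, max_value=50))
    @settings(max_examples=10, deadline=None)
    def test_calls_invariant_to_depth_scaling(self, genome, scale):
        cfg = SimConfig(n_strains=1, n_loci=6, p_subtelomeric=0.3, seed=47)
        _, tracks = simulate_population(genome, cfg)
        tab = tracks["strain_001"]
        _, base = call_strain(tab, genome, CallConfig(), "s1")
        _, scaled = call_strain(
            tab.assign(depth=tab["depth"] * scale), genome, CallConfig(), "s1"
        )
        assert [(r.start, r.end, r.cn) for r in base] == [
            (r.start, r.end, r.cn) for r in scaled
        ]


def test_cnvr_bed_round_trip(tmp_path):
    from cndiverse.calling import read_cnvr_bed, write_cnvr_bed

    cnvrs = [
        CNVR("s1", "chr1", 500, 1250, 2, "dup", 0.001, 3),
        CNVR("s1", "chr2", 0, 500, 0, "del", 0.02, 2),
    ]
    path = write_cnvr_bed(cnvrs, tmp_path / "s1.bed")
    back = read_cnvr_bed(path, "s1")
    assert [(r.chromosome, r.start, r.end, r.cn, r.event_class) for r in back] == [
        (r.chromosome, r.start, r.end, r.cn, r.event_class) for r in cnvrs
    ]
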