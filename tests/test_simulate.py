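"""Simulator: event application, derived observables, clone generation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import htrec as h
from htrec.genome import Breakend, Junction, Segment, TemplatedInsertionParams
from htrec.simulate import PROFILES, simulate_clone


def brute_force_depth(dc):
    """Per-base copy-number oracle: count segment coverage directly."""
    depth = np.full(dc.genome.length, dc.genome.baseline_cn - 1, dtype=int)
    for seg in dc.segments:
        depth[seg.start : seg.end] += 1
    return depth


def profile_to_array(cn, length):
    out = np.empty(length, dtype=int)
    for s, e, v in cn.segments:
        out[s:e] = v
    return out


class TestNewGenome:
    def test_identity(self):
        dc = h.new_genome(10**6)
        assert dc.segments == (Segment(0, 10**6, True),)
        assert h.derive_junctions(dc) == []
        assert h.derive_copy_number(dc).segments == ((0, 10**6, 2),)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            h.new_genome(0)


class TestSimpleEvents:
    def test_deletion(self):
        dc = h.apply_deletion(h.new_genome(1000), (100, 200))
        assert dc.length == 900
        (j,) = h.derive_junctions(dc)
        assert (j.a.pos, j.a.side, j.b.pos, j.b.side) == (99, "R", 200, "L")
        assert h.derive_copy_number(dc).segments == ((0, 100, 2), (100, 200, 1), (200, 1000, 2))

    def test_deletion_outside_retained_sequence_rejected(self):
        dc = h.apply_deletion(h.new_genome(1000), (100, 200))
        with pytest.raises(ValueError, match="forward-retained"):
            h.apply_deletion(dc, (150, 180))

    def test_tandem_duplication(self):
        dc = h.apply_tandem_duplication(h.new_genome(1000), (100, 200))
        assert dc.length == 1100
        (j,) = h.derive_junctions(dc)
        assert (j.a.pos, j.a.side, j.b.pos, j.b.side) == (100, "L", 199, "R")
        assert h.classify_junction(j) == "duplication_type"
        assert h.derive_copy_number(dc).segments == ((0, 100, 2), (100, 200, 3), (200, 1000, 2))

    def test_inversion(self):
        dc = h.apply_inversion(h.new_genome(1000), (100, 200))
        assert dc.length == 1000
        js = h.derive_junctions(dc)
        assert len(js) == 2
        sides = sorted((j.a.side, j.b.side) for j in js)
        assert sides == [("L", "L"), ("R", "R")]
        assert h.derive_copy_number(dc).segments == ((0, 1000, 2),)

    def test_full_chromosome_inversion_has_no_junctions(self):
        dc = h.apply_inversion(h.new_genome(1000), (0, 1000))
        assert h.derive_junctions(dc) == []


class TestTemplatedInsertion:
    PARAMS = TemplatedInsertionParams(50_000, 20_000, 300_000, 100, inverted=True)

    def test_length_and_copy_number(self):
        dc = h.apply_templated_insertion(h.new_genome(10**6), self.PARAMS)
        assert dc.length == 10**6 + 20_000 - 100
        cn = h.derive_copy_number(dc)
        assert (50_000, 70_000, 3) in cn.segments  # template gains a copy
        assert (300_000, 300_100, 1) in cn.segments  # site loses its bases

    def test_junctions_flank_template_and_site(self):
        dc = h.apply_templated_insertion(h.new_genome(10**6), self.PARAMS)
        js = h.derive_junctions(dc)
        assert len(js) == 2
        for j in js:
            poss = {j.a.pos, j.b.pos}
            near_template = any(abs(p - b) <= 1 for p in poss for b in (50_000, 70_000))
            near_site = any(abs(p - 300_000) <= 101 for p in poss)
            assert near_template and near_site

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            TemplatedInsertionParams(50_000, 20_000, 60_000, 100)


class TestBfb:
    def test_one_cycle_fold_back_and_gain(self, rng):
        dc = h.apply_bfb_cycles(h.new_genome(10**6), 1, rng)
        js = h.derive_junctions(dc)
        assert len(js) == 1
        (j,) = js
        assert j.a.side == j.b.side  # inverted orientation
        assert abs(j.a.pos - j.b.pos) <= 10_000
        cn = h.derive_copy_number(dc, bin_size=1000)
        # retained arm adjacent to the fusion gains one copy; distal arm lost
        assert max(c for _, _, c in cn.segments) == 3
        assert cn.segments[-1][2] == 1

    def test_three_cycles_staircase(self):
        dc = h.apply_bfb_cycles(h.new_genome(10**6), 3, rng=np.random.default_rng(7))
        js = h.derive_junctions(dc)
        assert len(js) == 3
        assert all(j.a.side == j.b.side for j in js)
        cn = h.derive_copy_number(dc, bin_size=1000)
        f_max = max(j.b.pos for j in js)
        # CN steps are monotone non-decreasing toward the fused end
        prox = [c for _, e, c in cn.segments if e <= f_max - 1000]
        assert prox == sorted(prox)
        assert prox[-1] > prox[0]

    def test_rejects_zero_cycles(self, rng):
        with pytest.raises(ValueError):
            h.apply_bfb_cycles(h.new_genome(10**6), 0, rng)


class TestChromothripsis:
    def test_retain_all_preserves_length_and_cn(self):
        dc = h.apply_chromothripsis(
            h.new_genome(10**6), (200_000, 800_000), 10, 1.0, np.random.default_rng(5)
        )
        assert dc.length == 10**6
        assert h.derive_copy_number(dc).segments == ((0, 10**6, 2),)

    def test_two_cn_states_inside_region(self):
        dc = h.apply_chromothripsis(
            h.new_genome(10**6), (200_000, 800_000), 20, 0.5, np.random.default_rng(5)
        )
        cn = h.derive_copy_number(dc)
        states = {c for _, _, c in cn.overlapping(200_000, 800_000)}
        assert states <= {1, 2}
        assert 1 in states

    def test_junction_sides_near_uniform(self):
        """Monte-Carlo over seeds: each of the 4 side categories ~ 1/4."""
        counts = {("R", "L"): 0, ("L", "R"): 0, ("R", "R"): 0, ("L", "L"): 0}
        for seed in range(200):
            dc = h.apply_chromothripsis(
                h.new_genome(10**6), (200_000, 800_000), 20, 0.5,
                np.random.default_rng(seed),
            )
            for j in h.derive_junctions(dc):
                counts[(j.a.side, j.b.side)] += 1
        total = sum(counts.values())
        for c in counts.values():
            assert abs(c / total - 0.25) < 0.05


@st.composite
def random_event_list(draw):
    """A feasible sequence of simple events on a small genome."""
    ops = []
    n = draw(st.integers(min_value=0, max_value=4))
    for _ in range(n):
        kind = draw(st.sampled_from(["del", "dup", "inv"]))
        start = draw(st.integers(min_value=0, max_value=90_000))
        size = draw(st.integers(min_value=10, max_value=5_000))
        ops.append((kind, start, start + size))
    return ops


class TestDeriveCopyNumber:
    @given(random_event_list())
    def test_matches_per_base_oracle(self, ops):
        dc = h.new_genome(100_000)
        appliers = {
            "del": h.apply_deletion,
            "dup": h.apply_tandem_duplication,
            "inv": h.apply_inversion,
        }
        for kind, s, e in ops:
            try:
                dc = appliers[kind](dc, (s, e))
            except ValueError:
                continue  # interval no longer in retained forward sequence
        expected = brute_force_depth(dc)
        got = profile_to_array(h.derive_copy_number(dc, bin_size=1), 100_000)
        assert np.array_equal(got, expected)

    def test_binned_profile_of_bfb(self, rng):
        dc = h.apply_bfb_cycles(h.new_genome(100_000), 2, rng)
        expected = brute_force_depth(dc)
        got = profile_to_array(h.derive_copy_number(dc, bin_size=1), 100_000)
        assert np.array_equal(got, expected)

    def test_bad_bin_size(self):
        with pytest.raises(ValueError):
            h.derive_copy_number(h.new_genome(1000), bin_size=0)


class TestDeriveJunctions:
    def test_deletion_plus_disjoint_duplication(self):
        dc = h.new_genome(10_000)
        dc = h.apply_deletion(dc, (1_000, 2_000))
        dc = h.apply_tandem_duplication(dc, (5_000, 6_000))
        assert len(h.derive_junctions(dc)) == 2

    def test_invariant_under_recanonicalization(self):
        dc = h.apply_inversion(h.new_genome(10_000), (2_000, 3_000))
        js1 = h.derive_junctions(dc)
        js2 = h.derive_junctions(dc.with_segments(tuple(dc.segments)))
        assert js1 == js2

    def test_length_conservation(self):
        dc = h.new_genome(1_000_000)
        dc = h.apply_deletion(dc, (10_000, 30_000))
        dc = h.apply_tandem_duplication(dc, (400_000, 450_000))
        p = TemplatedInsertionParams(600_000, 5_000, 800_000, 50, True)
        dc = h.apply_templated_insertion(dc, p)
        assert dc.length == 1_000_000 - 20_000 + 50_000 + 5_000 - 50


class TestSimulateClone:
    def test_wild_type_counts_and_classes(self):
        r = simulate_clone("wild_type", 42)
        assert 8 <= len(r.events) <= 12
        classes = {e.event_class for e in r.events}
        assert classes <= {"deletion", "tandem_duplication", "inversion"}

    def test_wild_type_deletions_below_10kb(self):
        r = simulate_clone("wild_type", 42)
        for ev in r.events:
            if ev.event_class == "deletion":
                s, e = ev.params["interval"]
                assert e - s < 10_000

    def test_rtel1_null_event_count(self):
        r = simulate_clone("rtel1_null", 42)
        assert len(r.events) >= 15

    def test_seeded_reproducibility(self):
        r1 = simulate_clone("rtel1_null", 7)
        r2 = simulate_clone("rtel1_null", 7)
        assert r1.junctions == r2.junctions
        assert r1.copy_number == r2.copy_number
        assert r1.events == r2.events

    def test_templated_insertion_bounds(self):
        """Sampled parameters honor the reported ranges."""
        seen = 0
        for seed in range(25):
            for ev in simulate_clone("rtel1_null", seed).events:
                if ev.event_class != "templated_insertion":
                    continue
                seen += 1
                p = ev.params
                assert 6 <= p["site_deletion_len"] <= 1_000
                assert 2_000 <= p["template_len"] <= 100_000
                mid = p["template_start"] + p["template_len"] // 2
                assert abs(p["insertion_pos"] - mid) >= 10_000
        assert seen > 10

    def test_unknown_profile_rejected(self):
        with pytest.raises(ValueError):
            simulate_clone("nonsense", 1)
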