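"""Tiling-path planner, digest prediction, size filter, assembly verification."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from snrcm.containment import ContainmentParams
from snrcm.reference import find_sites_naive, min_cover_bruteforce
from snrcm.simulate import _apply_errors
from snrcm.tiling import (FosmidAlignment, TilingGapError, choose_release_enzyme,
                          find_sites, find_tiling_path, predict_digest_fragments,
                          size_filter_reads, verify_assembly)
from snrcm.util import SnrcmError, decode, encode, random_dna


class TestTilingPath:
    def test_single_spanning_fosmid(self):
        path = find_tiling_path((1_000, 30_000),
                                [FosmidAlignment("c1", (0, 40_000))], 500)
        assert path.clone_ids == ["c1"]
        assert path.covered_interval[0] <= 1_000 and path.covered_interval[1] >= 30_000

    def test_two_fosmids_with_overlap(self):
        path = find_tiling_path((0, 58_000), [
            FosmidAlignment("a", (0, 40_000)),
            FosmidAlignment("b", (35_000, 70_000)),
        ], 500)
        assert path.clone_ids == ["a", "b"]
        assert path.pairwise_overlaps_bp == [5_000]

    def test_gap_reports_first_uncovered_coordinate(self):
        with pytest.raises(TilingGapError) as err:
            find_tiling_path((0, 58_000), [
                FosmidAlignment("a", (0, 20_000)),
                FosmidAlignment("b", (30_000, 60_000)),
            ], 500)
        assert err.value.gap == (20_000, 58_000)

    def test_strand_discordant_excluded_by_default(self):
        als = [FosmidAlignment("a", (0, 60_000), strand="-")]
        with pytest.raises(TilingGapError):
            find_tiling_path((0, 50_000), als, 500)
        path = find_tiling_path((0, 50_000), als, 500, allow_strand_discordant=True)
        assert path.clone_ids == ["a"]

    def test_greedy_matches_bruteforce_on_random_instances(self, rng):
        """Greedy furthest-reach cardinality equals exhaustive minimum."""
        for _ in range(20):
            target = (500, 500 + int(rng.integers(3_000, 40_000)))
            ivs = {}
            pos = target[0] - int(rng.integers(0, 1_000))
            i = 0
            while pos < target[1]:  # guarantee coverability
                ln = int(rng.integers(3_000, 20_000))
                ivs[f"c{i:02d}"] = (pos, pos + ln)
                pos += ln - int(rng.integers(600, min(2_500, ln)))
                i += 1
            for j in range(int(rng.integers(0, 6))):
                s = int(rng.integers(0, target[1] + 3_000))
                ivs[f"r{j:02d}"] = (s, s + int(rng.integers(2_000, 15_000)))
            als = [FosmidAlignment(k, v) for k, v in ivs.items()]
            greedy = len(find_tiling_path(target, als, 500).clone_ids)
            assert greedy == min_cover_bruteforce(target, ivs, 500)

    def test_split_cluster_trio_needs_three_clones(self, small_library):
        """The planted ~58 kb cluster is recovered by exactly 3 clones."""
        community = small_library["community"]
        bgc = next(b for b in community.bgcs if b.class_label == "NRPS-like")
        als = [FosmidAlignment(c.clone_id, c.insert_interval)
               for c in small_library["clones"]
               if c.fragment_id == bgc.fragment_id
               and c.insert_interval[1] > bgc.start and c.insert_interval[0] < bgc.end]
        path = find_tiling_path((bgc.start, bgc.end), als, 500)
        assert len(path.clone_ids) == 3
        assert all(o >= 500 for o in path.pairwise_overlaps_bp)


class TestDigest:
    def test_circular_two_sites_like_published_construct(self):
        """Circular 73 kb molecule cut at 0 and 57,000 -> 57 kb + 16 kb."""
        res = predict_digest_fragments(73_000, topology="circular",
                                       site_positions=[0, 57_000])
        assert sorted(res.fragment_lengths_bp) == [16_000, 57_000]

    def test_linear_single_cut(self):
        res = predict_digest_fragments(10_000, topology="linear", site_positions=[4_000])
        assert res.fragment_lengths_bp == [4_000, 6_000]

    def test_planted_sites_found_by_naive_oracle(self, rng):
        for _ in range(10):
            seq = random_dna(rng, 4_000, 0.5)
            for _ in range(int(rng.integers(1, 4))):
                p = int(rng.integers(0, len(seq) - 8))
                seq = seq[:p] + "GTTTAAAC" + seq[p + 8:]
            assert find_sites(seq, "GTTTAAAC") == find_sites_naive(seq, "GTTTAAAC")

    @given(st.integers(0, 2**31 - 1), st.sampled_from(["circular", "linear"]))
    def test_fragment_lengths_conserve_molecule_length(self, seed, topology):
        rng = np.random.default_rng(seed)
        seq = random_dna(rng, int(rng.integers(500, 3_000)), 0.5)
        p = int(rng.integers(0, len(seq) - 8))
        seq = seq[:p] + "ATTTAAAT" + seq[p + 8:]
        res = predict_digest_fragments(seq, "ATTTAAAT", topology=topology)
        assert sum(res.fragment_lengths_bp) == len(seq)
        n_sites = len(res.site_positions)
        expected = n_sites if topology == "circular" else n_sites + 1
        assert len(res.fragment_lengths_bp) == expected

    def test_reverse_strand_site_detected_once(self):
        seq = "C" * 100 + "GGATCCTT" + "C" * 100  # non-palindromic probe
        assert find_sites(seq, "AAGGATCC") == [100]

    def test_zero_sites_circular_warns(self, rng):
        with pytest.warns(UserWarning):
            res = predict_digest_fragments(random_dna(rng, 400, 0.5), "ATTTAAAT")
        assert res.fragment_lengths_bp == []

    def test_enzyme_panel_prefers_two_fragments(self, rng):
        seq = random_dna(rng, 60_000, 0.55)
        res = choose_release_enzyme(seq)
        assert res.site_positions
        assert sum(res.fragment_lengths_bp) == len(seq)


class TestSizeFilter:
    def test_assignment_and_rejection(self):
        groups = size_filter_reads([("a", "A" * 16_500), ("b", "A" * 30_000)],
                                   [57_000, 16_000], 0.1)
        assert [r[0] for r in groups[16_000]] == ["a"]
        assert groups[57_000] == []

    def test_tie_goes_to_smaller_size(self):
        groups = size_filter_reads([("t", "A" * 1_500)], [1_400, 1_600], 0.1)
        assert [r[0] for r in groups[1_400]] == ["t"]
        assert groups[1_600] == []

    def test_zero_tolerance_only_exact(self):
        groups = size_filter_reads([("x", "A" * 1_000), ("y", "A" * 1_001)], [1_000], 0.0)
        assert [r[0] for r in groups[1_000]] == ["x"]

    def test_invalid_tolerance(self):
        with pytest.raises(SnrcmError):
            size_filter_reads([], [100], 0.6)


class TestVerifyAssembly:
    def _reads_from(self, seq, n, rng, error=None):
        out = []
        codes = encode(seq)
        for i in range(n):
            ln = int(len(seq) * rng.uniform(0.9, 1.0))
            s = int(rng.integers(0, len(seq) - ln + 1))
            obs = codes[s:s + ln]
            if error:
                obs, _ = _apply_errors(obs, error, rng)
            out.append((f"r{i}", decode(obs)))
        return out

    def test_correct_assembly_passes(self, rng):
        frags = [random_dna(rng, 6_000, 0.5), random_dna(rng, 2_500, 0.5)]
        groups = {len(f): self._reads_from(f, 6, rng) for f in frags}
        res = verify_assembly(groups, {len(f): f for f in frags}, ContainmentParams())
        assert res.passed

    def test_internal_deletion_fails_affected_fragment(self, rng):
        """Reads from a molecule missing 1.5 kb cannot cover the reference."""
        ref = random_dna(rng, 8_000, 0.5)
        deleted = ref[:3_000] + ref[4_500:]  # 1.5 kb internal deletion
        groups = {len(ref): self._reads_from(deleted, 8, rng)}
        res = verify_assembly(groups, {len(ref): ref}, ContainmentParams())
        assert not res.passed
        assert res.fragments[0].covered_fraction < 0.95

    def test_unrelated_reads_leave_fragments_uncovered(self, rng):
        ref = random_dna(rng, 5_000, 0.5)
        noise = [(f"n{i}", random_dna(rng, 4_800, 0.5)) for i in range(5)]
        res = verify_assembly({len(ref): noise}, {len(ref): ref}, ContainmentParams())
        assert not res.passed

    def test_empty_group_is_uncovered(self):
        res = verify_assembly({}, {1_000: "A" * 1_000}, ContainmentParams())
        assert not res.passed and res.fragments[0].best_read_id is None
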