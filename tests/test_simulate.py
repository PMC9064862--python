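"""Fixture generator: determinism, geometry, pooling, read error models."""

import numpy as np
import pytest

from snrcm.simulate import (BGCSpec, GeometryError, SimulationConfig, _apply_errors,
                            build_fosmid_library, generate_community, load_vector,
                            simulate_long_reads, simulate_short_reads)
from snrcm.util import SnrcmError, encode, revcomp


def _tiny_config(**kw):
    base = dict(
        n_fragments=1, fragment_len_bp=(100_000, 100_000), n_clones=8, pool_size=4,
        long_read_coverage=2.0,
        bgc_plan=[BGCSpec("lasso", 4_000)],
        seed=11,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestGenerateCommunity:
    def test_truth_matches_request(self):
        com = generate_community(_tiny_config())
        assert len(com.fragments) == 1
        (bgc,) = com.bgcs
        assert bgc.end - bgc.start == 4_000
        frag = com.fragments[bgc.fragment_id]
        assert 0 <= bgc.start < bgc.end <= len(frag)
        labels = {g.label for g in bgc.gene_layout}
        assert {"A", "B1", "B2", "C"} <= labels

    def test_determinism_byte_identical(self):
        a = generate_community(_tiny_config())
        b = generate_community(_tiny_config())
        assert a.fragments == b.fragments
        assert [(x.bgc_id, x.start, x.end) for x in a.bgcs] == \
               [(x.bgc_id, x.start, x.end) for x in b.bgcs]

    def test_impossible_geometry_raises(self):
        cfg = _tiny_config(fragment_len_bp=(40_000, 40_000),
                           bgc_plan=[BGCSpec("NRPS-like", 58_000)])
        with pytest.raises(GeometryError, match="NRPS"):
            generate_community(cfg)

    def test_invalid_rates_rejected(self):
        cfg = _tiny_config()
        cfg.long_read_error["sub"] = 1.5
        with pytest.raises(SnrcmError):
            cfg.validate()


class TestLibrary:
    def test_pool_sizes_partition_clones(self):
        cfg = _tiny_config(n_clones=41, pool_size=20)
        com = generate_community(cfg)
        clones = build_fosmid_library(com, cfg)
        pools = {}
        for c in clones:
            pools[c.pool_id] = pools.get(c.pool_id, 0) + 1
        assert pools == {0: 20, 1: 20, 2: 1}
        assert sum(pools.values()) == cfg.n_clones

    def test_insert_roundtrip_from_fragment(self):
        cfg = _tiny_config()
        com = generate_community(cfg)
        clones = build_fosmid_library(com, cfg)
        vector = load_vector()
        for c in clones[:5]:
            s, e = c.insert_interval
            insert = com.fragments[c.fragment_id][s:e]
            if c.insert_strand == "-":
                insert = revcomp(insert)
            assert c.full_sequence == vector + insert
            assert cfg.insert_len_bp[0] <= c.insert_length <= cfg.insert_len_bp[1]

    def test_insert_range_exceeding_fragments_raises(self):
        cfg = _tiny_config(fragment_len_bp=(99_000, 100_000), insert_len_bp=(99_500, 100_000),
                           bgc_plan=[])
        cfg.n_fragments = 1
        com = generate_community(cfg)
        # shrink the only fragment below the insert minimum
        com.fragments = {k: v[:50_000] for k, v in com.fragments.items()}
        with pytest.raises(SnrcmError, match="insert length range"):
            build_fosmid_library(com, cfg)

    def test_oversized_cluster_gets_three_designated_clones(self):
        cfg = _tiny_config(n_fragments=1, bgc_plan=[BGCSpec("NRPS-like", 58_000)], n_clones=3,
                           pool_size=4)
        com = generate_community(cfg)
        clones = build_fosmid_library(com, cfg)
        trio = [c for c in clones if c.designated_for and "NRPS" in c.designated_for]
        assert len(trio) == 3
        bgc = com.bgcs[0]
        ivs = sorted(c.insert_interval for c in trio)
        assert ivs[0][0] <= bgc.start and ivs[-1][1] >= bgc.end
        # no two of the three cover the whole cluster
        import itertools
        for a, b in itertools.combinations(ivs, 2):
            first, second = sorted([a, b])
            two_cover = (first[0] <= bgc.start and second[1] >= bgc.end
                         and first[1] >= second[0])
            assert not two_cover


class TestLongReads:
    def test_zero_error_reads_are_exact_substrings(self):
        cfg = _tiny_config(long_read_error={"sub": 0.0, "ins": 0.0, "del": 0.0})
        com = generate_community(cfg)
        clones = build_fosmid_library(com, cfg)
        reads, truth = simulate_long_reads(clones, cfg)
        by_id = {c.clone_id: c for c in clones}
        assert len(reads) > 0
        for r in reads[:40]:
            mol = by_id[r.clone_id].full_sequence
            s, e = r.true_interval
            doubled = mol + mol
            expected = doubled[s:e]
            if r.strand == "-":
                expected = revcomp(expected)
            assert r.sequence == expected
            assert r.errors_applied == {"sub": 0, "ins": 0, "del": 0}

    def test_determinism(self):
        cfg = _tiny_config()
        com = generate_community(cfg)
        clones = build_fosmid_library(com, cfg)
        r1, t1 = simulate_long_reads(clones, cfg)
        r2, t2 = simulate_long_reads(clones, cfg)
        assert [x.sequence for x in r1] == [x.sequence for x in r2]
        assert t1.equals(t2)

    def test_reads_truncated_at_molecule_length(self):
        cfg = _tiny_config(long_read_len={"median_bp": 80_000, "sigma": 0.3, "min_bp": 1_000},
                           long_read_coverage=1.0)
        com = generate_community(cfg)
        clones = build_fosmid_library(com, cfg)
        reads, truth = simulate_long_reads(clones, cfg)
        by_id = {c.clone_id: len(c.full_sequence) for c in clones}
        assert any(r.truncated for r in reads)
        for r in reads:
            assert len(r.sequence) <= by_id[r.clone_id] + r.errors_applied["ins"]

    def test_realized_substitution_rate_matches_binomial_expectation(self, rng):
        """Mean per-base mismatch over many substitution-only reads converges
        to the configured rate (binomial expectation)."""
        rate = 0.05
        n_reads, read_len = 10_000, 10_000
        total_mismatch = 0
        template = rng.integers(0, 4, size=read_len).astype(np.uint8)
        for _ in range(n_reads):
            obs, counts = _apply_errors(template, {"sub": rate, "ins": 0.0, "del": 0.0}, rng)
            total_mismatch += int((obs != template).sum())
            assert counts["sub"] == int((obs != template).sum())
        realized = total_mismatch / (n_reads * read_len)
        assert abs(realized - rate) <= 0.005


class TestShortReads:
    def test_paired_reads_fixed_length_and_orientation(self):
        cfg = _tiny_config(short_read_coverage=0.5,
                           short_read_error={"sub": 0.0, "ins": 0.0, "del": 0.0})
        com = generate_community(cfg)
        clones = build_fosmid_library(com, cfg)
        recs, truth = simulate_short_reads(clones, cfg)
        assert len(recs) > 0
        by_id = {c.clone_id: c.full_sequence for c in clones}
        for (rid, r1, q1, r2, q2), row in zip(recs[:30], truth.itertuples()):
            assert len(r1) == len(r2) == cfg.short_read_len
            mol = by_id[row.clone_id]
            frag = (mol + mol)[row.start:row.end]
            assert r1 == frag[: cfg.short_read_len]
            assert r2 == revcomp(frag[-cfg.short_read_len:])

    def test_deterministic_pair_count_from_coverage(self):
        cfg = _tiny_config(short_read_coverage=20.0)
        com = generate_community(cfg)
        clones = build_fosmid_library(com, cfg)[:1]
        recs, _ = simulate_short_reads(clones, cfg)
        mol_len = len(clones[0].full_sequence)
        assert len(recs) == round(20.0 * mol_len / (2 * cfg.short_read_len))


def test_error_application_order_replayable(rng):
    """Substitutions, then deletions, then insertions: counts recorded."""
    codes = encode("ACGT" * 500)
    obs, counts = _apply_errors(codes, {"sub": 0.05, "ins": 0.02, "del": 0.02}, rng)
    assert obs.size == codes.size + counts["ins"] - counts["del"]
    assert all(v >= 0 for v in counts.values())
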