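"""Containment miner: filters, region import, verdicts, oracle equivalence."""

import numpy as np
import pytest

from snrcm.containment import (CALL_ABSENT, CALL_COMPLETE, CALL_PARTIAL, BGCRegion, Contig,
                               ContainmentParams, filter_contigs, import_regions,
                               mine_single_read_containment, summarize_by_class)
from snrcm.reference import containment_reference
from snrcm.seqio import write_gff3, GffRecord
from snrcm.simulate import _apply_errors
from snrcm.util import SnrcmError, decode, encode, random_dna, revcomp


@pytest.fixture
def params():
    return ContainmentParams()


class TestFilterContigs:
    def test_inclusive_boundary(self):
        contigs = [Contig(f"c{i}", "A" * n) for i, n in enumerate((39_999, 40_000, 41_000))]
        kept = filter_contigs(contigs, 40_000)
        assert [c.contig_id for c in kept] == ["c1", "c2"]

    def test_zero_threshold_is_identity(self):
        contigs = [Contig("a", "ACGT"), Contig("b", "A")]
        assert filter_contigs(contigs, 0) == contigs

    def test_empty_input(self):
        assert filter_contigs([], 40_000) == []


class TestImportRegions:
    def test_coordinate_conversion_and_edge_flag(self, tmp_path):
        contig = random_dna(np.random.default_rng(0), 50_000, 0.5)
        path = tmp_path / "regions.gff3"
        write_gff3(path, [
            GffRecord(seqid="ctg", type="region", start=1_000, end=5_000,
                      attributes={"ID": "r1", "class": "lasso"}),
            GffRecord(seqid="ctg", type="region", start=45_000, end=50_000,
                      attributes={"ID": "r2", "class": "terpene"}),
        ])
        regions = import_regions(path, {"ctg": contig})
        assert (regions[0].start, regions[0].end) == (1_000, 5_000)
        assert not regions[0].on_contig_edge
        assert regions[1].on_contig_edge  # abuts the contig end

    def test_gff_one_based_convention(self, tmp_path):
        path = tmp_path / "r.gff3"
        path.write_text("##gff-version 3\nctg\tsrc\tregion\t1001\t5000\t.\t+\t.\tID=r1\n")
        regions = import_regions(path, {"ctg": "A" * 50_000})
        assert (regions[0].start, regions[0].end) == (1_000, 5_000)

    def test_out_of_bounds_region_names_id(self, tmp_path):
        path = tmp_path / "r.gff3"
        path.write_text("##gff-version 3\nctg\tsrc\tregion\t1\t99\t.\t+\t.\tID=bad_region\n")
        with pytest.raises(SnrcmError, match="bad_region"):
            import_regions(path, {"ctg": "ACGT" * 10})

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = tmp_path / "r.gff3"
        path.write_text("##gff-version 3\nctg\tonly\tthree\n")
        with pytest.raises(SnrcmError, match="line 2"):
            import_regions(path, {"ctg": "ACGT"})


class TestMineSingleRead:
    def test_verbatim_region_in_read_is_complete(self, rng, params):
        region = random_dna(rng, 3_000, 0.5)
        read = random_dna(rng, 8_000, 0.5) + region + random_dna(rng, 9_000, 0.5)
        v = mine_single_read_containment(region, [("r1", read)], params)
        assert v.call == CALL_COMPLETE
        assert v.covered_fraction == pytest.approx(1.0)
        assert v.identity == pytest.approx(1.0)
        assert v.best_read_id == "r1"

    def test_region_straddling_two_reads_is_partial(self, rng, params):
        region = random_dna(rng, 3_000, 0.5)
        r1 = random_dna(rng, 2_000, 0.5) + region[:1_800]
        r2 = region[1_200:] + random_dna(rng, 2_000, 0.5)
        v = mine_single_read_containment(region, [("a", r1), ("b", r2)], params)
        assert v.call == CALL_PARTIAL
        assert v.covered_fraction < params.min_chain_coverage

    def test_empty_read_set_is_absent_with_warning(self, params):
        with pytest.warns(UserWarning):
            v = mine_single_read_containment("ACGT" * 100, [], params)
        assert v.call == CALL_ABSENT
        assert v.covered_fraction == 0.0

    def test_region_shorter_than_kmer_errors(self, params):
        with pytest.raises(SnrcmError, match="kmer"):
            mine_single_read_containment("ACGTACGT", [("r", "ACGT" * 100)], params)

    def test_reverse_strand_containment_detected(self, rng, params):
        region = random_dna(rng, 2_500, 0.5)
        read = random_dna(rng, 1_000, 0.5) + revcomp(region) + random_dna(rng, 1_000, 0.5)
        v = mine_single_read_containment(region, [("r", read)], params)
        assert v.call == CALL_COMPLETE
        assert v.strand == "-"

    def test_strand_symmetry(self, rng, params):
        """Reverse-complementing every read leaves verdicts unchanged."""
        region = random_dna(rng, 1_500, 0.5)
        emb, _ = _apply_errors(encode(region), {"sub": 0.04, "ins": 0.0, "del": 0.0}, rng)
        reads = [("r1", random_dna(rng, 500, 0.5) + decode(emb) + random_dna(rng, 700, 0.5)),
                 ("r2", random_dna(rng, 3_000, 0.5))]
        fwd = mine_single_read_containment(region, reads, params)
        rc = mine_single_read_containment(region, [(i, revcomp(s)) for i, s in reads], params)
        assert fwd.call == rc.call
        assert fwd.covered_fraction == pytest.approx(rc.covered_fraction, abs=1e-6)
        assert fwd.identity == pytest.approx(rc.identity, abs=1e-6)

    def test_raising_coverage_threshold_never_promotes(self, rng):
        region = random_dna(rng, 1_000, 0.5)
        read = random_dna(rng, 300, 0.5) + region[:800]
        loose = mine_single_read_containment(region, [("r", read)], ContainmentParams(min_chain_coverage=0.5))
        strict = mine_single_read_containment(region, [("r", read)], ContainmentParams(min_chain_coverage=0.95))
        assert loose.call == CALL_COMPLETE and strict.call == CALL_PARTIAL

    @pytest.mark.parametrize("kind", ["complete", "partial", "absent", "revcomp"])
    def test_oracle_equivalence_by_instance_kind(self, rng, params, kind):
        """Verdicts match the exhaustive infix-alignment oracle at 5% error."""
        for _ in range(6):
            L = int(rng.integers(400, 2_001))
            region = random_dna(rng, L, 0.5)
            err = {"sub": 0.05, "ins": 0.0, "del": 0.0}
            if kind == "complete":
                emb, _ = _apply_errors(encode(region), err, rng)
                read = random_dna(rng, 600, 0.5) + decode(emb) + random_dna(rng, 600, 0.5)
            elif kind == "partial":
                frac = rng.uniform(0.35, 0.65)
                emb, _ = _apply_errors(encode(region[: int(L * frac)]), err, rng)
                read = random_dna(rng, 700, 0.5) + decode(emb)
            elif kind == "absent":
                read = random_dna(rng, int(rng.integers(1_000, 4_000)), 0.5)
            else:
                emb, _ = _apply_errors(encode(region), err, rng)
                read = random_dna(rng, 400, 0.5) + revcomp(decode(emb)) + random_dna(rng, 400, 0.5)
            mine = mine_single_read_containment(region, [("r", read)], params)
            ref = containment_reference(region, read, params)
            assert mine.call == ref.call


class TestSummaries:
    def test_counts_by_class(self):
        regions = [BGCRegion("r1", "c", 0, 100, "lasso"),
                   BGCRegion("r2", "c", 0, 100, "lasso"),
                   BGCRegion("r3", "c", 0, 100, "terpene")]
        from snrcm.containment import ContainmentVerdict
        verdicts = [ContainmentVerdict("r1", CALL_COMPLETE),
                    ContainmentVerdict("r2", CALL_PARTIAL),
                    ContainmentVerdict("r3", CALL_COMPLETE)]
        assert summarize_by_class(verdicts, regions) == {"lasso": 1, "terpene": 1}

    def test_no_complete_calls_empty_summary(self):
        from snrcm.containment import ContainmentVerdict
        regions = [BGCRegion("r1", "c", 0, 100, "lasso")]
        assert summarize_by_class([ContainmentVerdict("r1", CALL_PARTIAL)], regions) == {}

    def test_unknown_region_raises(self):
        from snrcm.containment import ContainmentVerdict
        with pytest.raises(SnrcmError, match="ghost"):
            summarize_by_class([ContainmentVerdict("ghost", CALL_COMPLETE)], [])


def test_planted_library_recall(small_library):
    """Every planted BGC fitting one insert is complete; the split one is not."""
    from snrcm.simulate import fits_single_insert

    verdict_by_id = {v.region_id: v for v in small_library["verdicts"]}
    for bgc in small_library["community"].bgcs:
        v = verdict_by_id[bgc.bgc_id]
        if fits_single_insert(bgc, small_library["config"]):
            assert v.call == CALL_COMPLETE, bgc.bgc_id
        else:
            assert v.call == CALL_PARTIAL
            assert v.covered_fraction < 1.0
    counts = summarize_by_class(small_library["verdicts"], small_library["regions"])
    assert sum(counts.values()) == 2
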