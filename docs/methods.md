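# Methods

`snrcm` is an in-silico implementation of a cluster-recovery workflow for
pooled metagenomic fosmid libraries sequenced with long and short reads.  The
central idea is simple: every long read derives from exactly one clone
molecule, so a candidate biosynthetic gene cluster (BGC) that aligns
*completely within a single read* is proven to be captured on a single
insert and can be recovered directly.  Around that test the package models
the full recovery path: library simulation with ground truth, rule-based
lasso peptide annotation, serial-dilution clone isolation, and multi-clone
tiling assembly with restriction-digest verification.

## The simulated study system

The generator (`snrcm.simulate`) emulates the sampling regime of a real
soil-metagenome fosmid library at desk scale.  Defaults (all in
`SimulationConfig`) are the packaged study conditions:

| parameter | default | meaning |
|---|---|---|
| fragments | 6 of 70–100 kb, GC 0.60 | the accessible community DNA (soil communities are GC-rich) |
| clones | 500, pools of 2000 | inserts 30–45 kb in a synthetic 8,139 bp vector, circular molecules |
| long reads | 20× per clone | lognormal lengths (median 12 kb, σ = 0.55), truncated to [1 kb, molecule]; reads may span the vector–insert junction (flagged) |
| long-read errors | 3% sub, 1% ins, 1% del | applied substitutions → deletions → insertions, positions drawn without replacement per category, so oracles can replay counts |
| short reads | 2 × 150 bp, deterministic pair count `round(cov·len/300)` | not consumed downstream (assembly is out of scope); provided for completeness |
| planted BGCs | 2 lasso (4.2/5 kb), bacteriocin (6 kb), terpene (9 kb), lanthipeptide (12 kb), NRPS-like (58 kb) | five fit one insert; the NRPS-like cluster cannot |

Coordinates are 0-based half-open everywhere in memory; GFF3 is 1-based
inclusive on disk only.  Identical config + seed reproduces byte-identical
outputs; one global seed fans out to per-stage seeds via
`sha256(seed:stage) mod 2^31`.

Two generator properties are deliberate models of real library sampling
rather than uniform randomness:

* **Guaranteed capture.**  Each single-insert cluster receives one designated
  clone whose insert contains it (random clones may add more).  A real
  library of 83,700 × ~37 kb inserts samples each captured locus a handful
  of times; at 500 clones over a ~0.5 Mb community, uniform sampling would
  either badly over- or under-sample loci depending on arithmetic accidents.
* **The oversized cluster is split across exactly three inserts.**  Its host
  fragment is excluded from random clone sampling and receives three
  designated clones whose intervals tile the cluster with ≥ 2 kb overlaps
  such that *no two* of them cover it (left clone reaches ~42% into the
  cluster, right clone starts at ~58%).  This pins the fixture contract — a
  large cluster recoverable only by a 3-clone tiling path — independent of
  the seed.

What the simulation does **not** model: chimeric molecules, basecaller
signal artifacts, quality-score realism, host-genome contamination,
cloning bias.  Passing tests therefore demonstrate the algorithms' behavior
under a clean error model, not performance on raw instrument data.

## Single-read containment mining

`mine_regions` decides, per candidate region, whether at least one read
contains it:

1. **Seeding** — shared 15-mers between the region (both strands) and each
   read, found by rolling 2-bit codes, a 4^k bit-filter and a sorted-table
   lookup, in one pass over all reads for all regions.
2. **Chaining** — anchors are binned by diagonal (window ± `band_bp`), the
   densest window is kept, anchors are made colinear and split at region
   gaps > `max_gap_bp`; the densest run estimates coverage and locates the
   read window.
3. **Extension** — a banded (± `band_bp`) query-global edit-distance DP
   aligns the whole region inside the chain-selected read window (sentinel
   padding charges overhangs one edit per base).  From the optimal path:
   `identity = 1 − editDistance / region_len` and `covered_fraction` = the
   fraction of region positions aligned opposite a real read base.
4. **Verdict** — `complete_on_single_read` iff one read reaches
   `covered_fraction ≥ 0.95` and `identity ≥ 0.80`; `absent` iff fewer than
   3 shared k-mer anchors exist on any read; `partial` otherwise.  Ties
   among supporting reads break by (coverage, identity, read id).

The thresholds are explicit stand-ins: the underlying laboratory method
names a BLAST alignment but no cutoffs, so 0.95/0.80 are package defaults,
exposed on the CLI and in `ContainmentParams`.  Only the full region
interval (not a "core") is required to be covered.  A chain uses one strand
only; a region is never called complete from mixed-strand fragments of one
read.

**Validation** is dual-route: `snrcm.reference.containment_reference`
recomputes the verdict with an exhaustive infix alignment over the whole
read (edlib) plus a literal shared-k-mer count, using the same thresholds;
tests require 100% verdict agreement on randomized instances.  Instances are
drawn as clear containments, partial overlaps (containment fraction
0.35–0.65) and unrelated reads: in the 0.75–0.95 fraction range the 0.80
identity threshold itself changes sides depending on how an aligner charges
the unrelated tail, so no two optimal aligners are guaranteed to agree there
— a property of the thresholds, not of either implementation.

With the 58 kb region the DP costs ~1 s per candidate read (58k rows ×
1001-wide band); at most `max_candidates_aligned = 8` chains per region are
extended, with an early stop once no remaining chain can beat the best
coverage by its bounded underestimate (0.35).

## Lasso peptide annotation

`classify_gene` applies keyword/size rules (shipped as
`data/lasso_rules.yaml`, regex over description and domain tag,
case-insensitive) with precedence B2 > B1 > C > D > A on multi-match; all
fired rules are recorded, and a single gene firing both B1 and B2 evidence
counts as a fused B.  Size windows generalize the sizes observed across
characterized clusters (B1 276–303, B2 375–471, C 1863–1929, D 810–822 bp)
with margins.  An A gene needs either a "predicted lasso peptide" domain
annotation or (≤ 210 bp) a passing precursor scan — the scan result enters
`GeneEvidence.precursor_pass`, mirroring how small precursors are annotated
by manual inspection of translated sequence.

`scan_precursors` enumerates ORFs (ATG/GTG/TTG starts to the first in-frame
stop, both strands, 20–70 aa) and every leader/core split satisfying:
leader ≥ 8 aa; ring donor at core position 1 (Gly strictly, or Gly/Ala/
Ser/Cys relaxed); an Asp/Glu ring acceptor at core position 7, 8 or 9
(ring of 7–9 residues — the conventional macrolactam geometry; the exact
"appropriate distance" is an interpretation and configurable); tail ≥ 3 aa
after the acceptor; and a Thr-like residue (T/S/L/A/C/V/I) at leader
position −2.  All candidates are reported, ranked by (Gly donor, Asp over
Glu, Thr at −2, shorter tail) — nothing is silently selected, since real
clusters can present several plausible precursors.  A naive triple-loop
enumeration in `snrcm.reference` must produce the identical candidate set.

Completeness: a cluster is `complete` iff A and C are present and the B
function is covered (B1 + B2, or a fused B); the D transporter is reported
separately because transporter-bearing lasso clusters correlate with
antimicrobial activity.

## Serial-dilution recovery

With target frequency *f* (default 1/2000) and *c* cells per tube,
`p_tube = 1 − (1 − f)^round(c)` and `p_round = 1 − (1 − p_tube)^n_tubes`.
The OD-to-density factor 8 × 10⁸ cells/ml per OD600 unit is the unique value
consistent with the published worked example (0.25 × 10⁻⁵ OD ≈ 2000
cells/ml); it is a config default, not a biological claim.  Cell counts per
tube are exact rounded counts by default, matching the "≈ N cells"
protocol phrasing; a `--poisson` mode draws Poisson(c) instead (its analytic
check is then `1 − exp(−fc)`).  PCR detection is perfect by default; a
false-negative rate is a knob.

The default protocol reproduces the published rounds — 200 cells/tube over
16–32 tubes, then 40 cells/tube, then plating at the 10⁻⁷ dilution, where
each single colony is a founder cell (a "tube" with c = 1, 24 colonies
screened).  Between rounds the planner updates the expected frequency to
`E[K | K ≥ 1]/c`.  The stochastic twin (`simulate_recovery`) draws binomial
tube occupancies, carries the positive tube's composition forward, and
re-attempts a failed round from the same stock up to 3 times (a dilution is
not consumed by an attempt); the analytic `p_round_success` always refers to
a single attempt, which is what the Monte-Carlo test checks.

## Tiling assembly and digest verification

`find_tiling_path` is classical minimum interval covering by greedy
furthest-reach, with the extra constraint that consecutive clones overlap by
≥ `min_overlap_bp` (default 500 — recombination-based assembly needs
homologous overlap; vector hooks are short but clone–clone overlaps in
practice are much larger).  Greedy is optimal for this objective (the
reachable state is monotone in the current reach); tests verify cardinality
against exhaustive subset search.  Failures name the first uncovered
coordinate.  Strand-discordant clone alignments are excluded by default.

`predict_digest_fragments` locates a recognition site on both strands
(palindromes once), cuts at the site midpoint, and returns fragment lengths
that provably sum to the molecule length (circular: #fragments = #sites;
linear: #sites + 1).  The pipeline's TAR-planning stage assembles
vector + cluster into a circular construct and picks, from a panel of real
8-bp rare cutters, an enzyme releasing exactly two well-sized fragments —
the same selection criterion a bench scientist applies when choosing a
release enzyme.  `size_filter_reads` bins reads within a relative tolerance
(default 10%) of the expected fragment sizes, nearer size on ambiguity, ties
to the smaller; `verify_assembly` then re-uses the containment criterion per
fragment and passes only if every fragment is completely contained in some
size-matched read.

## Problem sizes and determinism

The packaged demo (`snrcm.pipeline.demo_config`) runs 500 clones at 20×
long-read coverage (~460 Mb of simulated reads), mines six regions, and
completes all stages in under two minutes on one CPU; unit tests use
libraries of 12–40 clones.  Every stochastic step is driven by
`numpy.random.default_rng` seeded through the per-stage fan-out, so reruns
with the same config and seed reproduce identical outputs and manifest
checksums.

## Known limitations

* Containment calls near the coverage/identity thresholds are aligner-
  convention-dependent (see above); the defaults are not calibrated against
  any real BLAST setting.
* The error model is i.i.d. per base; real Nanopore errors are homopolymer-
  biased, so real-data identity distributions will be wider.
* `supporting_reads` lists only reads that were chain-selected and aligned
  (at most `max_candidates_aligned`), not every read that would pass.
* The dilution model ignores growth competition between clones and assumes
  the positive tube's composition is preserved by overnight growth.
* Tiling planning trusts end-sequencing alignments; misassembled reference
  contigs would mislead it (the verification stage exists for that reason).
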