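# Methods

## The amplicon model

`editcall.reference.AmpliconReference` describes a single PCR amplicon
(default 1,626 bp) from a gene carrying a T→A stop point mutation on the
coding strand. All coordinates are 0-based half-open internally; reports
use 1-based inclusive only where explicitly labelled. The stored base
sequence is the *unedited mutant* (SCID) allele — the sequence actually
present in the cells being edited — and the other alleles derive from it:

| allele | derivation |
|---|---|
| SCID | base sequence, `A` at the mutation position |
| WILD_TYPE | mutation position reverted to `T` |
| CORRECTED | WILD_TYPE plus two silent substitutions at −6 and −3 |

The two silent substitutions plus the reverted base create one `WCCGGW`
(BsaWI) occurrence occupying positions `[scid_pos−7, scid_pos−1)`, i.e.
ending 2 nt upstream of the mutated base. The nuclease cleavage window is
modelled as a 5-bp spacer starting 32 nt downstream of the mutation (the
half-site geometry of the heterodimeric nuclease is not modelled; the
window width is configurable). A fixed recurrent 44-bp deletion is part of
the reference model, centred on the cleavage window and stored at its
canonical (left-aligned) start so the simulator and classifier agree on
its breakpoints.

Reference construction draws a uniform random sequence from a seeded
generator (numpy PCG64, recorded in the sidecar metadata), installs the
feature bases, and then *scrubs* stray `WCCGGW` occurrences — in the SCID
allele, the CORRECTED allele, and the recurrent-deletion derivative of
both — by deterministically mutating one non-feature base per occurrence
and rescanning. `WCCGGW` is its own reverse complement, so one strand
suffices; `digest_pool` scans both strands for non-palindromic patterns.
The scrub guarantees the diagnostic-site count is exactly 0 for unedited
and 1 for corrected molecules, including across the fixed deletion
junction; without it a ~1.6-kb random sequence would contain ~1.6
accidental sites and the RFLP readout would not be a clean correction
assay.

## The read generator

`simulate_reads` emulates single-end MiSeq-style amplicon reads (default
150 bp, constant Q30) drawn from a four-component mixture: unedited,
NHEJ indel, clean HDR, and HDR with an associated cleavage-window indel.
Defaults encode the modelled study conditions: `p_indel = 0.18`,
`p_hdr = 0.0153`, `p_hdr_indel = 0.0019` (an 11.25% with-indel share of
total correction), remainder wild-type; half of indel events are the
recurrent 44-bp deletion. Non-recurrent deletions are Geometric(mean 4 bp,
truncated at 60), insertions Geometric(mean 2 bp) with uniform random
content, and 30% of non-recurrent indels are insertions. Per-base
substitution errors (default 0.001, matching Q30) are applied after the
structural edit; orientation is randomised 50/50. Truth labels are written
to a separate table, never encoded in read names.

Two generator rules keep ground truth well defined:

* **Canonical truth placement.** An indel's position is reported (and
  accepted) at its left-aligned canonical form; a draw whose canonical
  form no longer involves the cleavage window (because it shifted left
  through a repeat) is redrawn. Indel starts are restricted downstream of
  the point mutation so the diagnostic region is never disrupted.
  Without these rules the truth label is not recoverable from the read
  sequence even in principle, and "classifier equals truth" would be
  ill-posed.
* **Primer-anchored read starts.** Read start positions are drawn from a
  window that (a) keeps the diagnostic substitutions and the full cleavage
  window inside every read even after a maximal 60-bp deletion, and
  (b) leaves at least `min_flank = 35` bases of anchor upstream of the
  point mutation. Amplicon reads in a real experiment begin at a fixed
  primer, so a narrow start window is the faithful model; it also reflects
  a genuine identifiability limit — a corrected read whose upstream anchor
  is shorter than ~27 bp carries its 3 diagnostic mismatches in a flank
  too weak to pin a 44-bp deletion against coincidental alternatives, for
  any aligner using this scoring.

What the generator deliberately does **not** model: PCR bias and chimeras,
paired-end overlap, position- or quality-dependent error profiles,
microhomology at deletion junctions. Passing tests therefore demonstrate
correctness of the calling logic under idealised noise, not robustness to
every artefact of real libraries.

## Alignment and classification

Reads are aligned to the SCID allele — not the literal wild type — so the
mutated base itself never scores as a mismatch; the three diagnostic
positions are then evaluated explicitly. Orientation is chosen by edit
distance (edlib, both strands). Substitution-only reads (edlib CIGAR free
of indels) take a fast path: their column map is unique. Reads with
candidate indels are refined with an affine-gap semi-global alignment
(Biopython PairwiseAligner; match +2, mismatch −4, gap open −10, extend −1
per additional base; free end gaps on the reference only) on a reference
slice padded by 130 bp around the edlib locus — the pad must exceed the
longest deletion plus flank because edit-distance seeding can misplace
reads whose flank on one side of a long deletion is short. Indels are then
left-normalised: an operation is shifted stepwise left while the displaced
column keeps its match status, yielding the leftmost score-equivalent
placement (verified against brute-force enumeration in the tests).

The quality filter accepts a read iff (a) identity outside the cleavage
neighbourhood (window ± 10 bp) is ≥ 0.90 over aligned columns and (b) the
aligned span covers all three diagnostic positions and the full window.
Classification then applies, in order:

1. all 3 diagnostic bases present → HDR; with a window-involving indel →
   `HDR_WITH_INDEL`, else `HDR_CORRECTED`; but if extra mismatches
   (outside the diagnostic positions) exceed `max_extra_mismatches`
   (default 2) the read is `UNCLASSIFIED("mismatches")` — a call resting
   on 3 specific bases needs a noise guard, whereas indel evidence does
   not, so the cap applies only to HDR calls;
2. otherwise a window-involving indel → `NHEJ_INDEL`. An insertion
   anchored at either end of the half-open window counts as involving it
   (closed-interval rule, configurable), since boundary insertions do
   change the amplicon length at the cut site;
3. otherwise 1–2 diagnostic matches → `UNCLASSIFIED("partial_hdr")` —
   partial signatures are reported, never counted as correction;
4. otherwise `WT`. Substitutions inside the window without an indel stay
   WT: only length-changing events count as indels.

Sample summaries use the passed-filter denominator throughout, report
percentages to two decimals (half-away-from-zero), and tally a deletion
spectrum of left-aligned (start, length) events; any entry holding ≥ 20%
of deletion events is flagged recurrent.

## Assay models

`digest_pool` cuts every molecule at every recognition-site occurrence
(cut offset 1 for `W^CCGGW`) and reports per-molecule fragment lengths
(conserved by construction), a band table, and the digested fraction. A
band-intensity proxy (count × length) accompanies raw counts, since
densitometry weights material rather than molecules. Molecules whose indel
destroyed the site are undigested, which couples deletion of the
diagnostic region to loss of the correction signal. On error-free
recurrent-deletion pools the digested fraction equals the truth HDR
fraction exactly; with random insertion/deletion junctions, rare
accidental `WCCGGW` junction motifs (~1% of junction reads) make the
equality approximate — the observed run in `analysis/04` differed by one
read in 10,000.

`surveyor_estimate` inverts `f = 1 − (1−p)²` as `p̂ = 1 − √(1−f)`. The
model assumes complete denaturation/reannealing at equilibrium, perfect
cleavage of any mismatched duplex, and pairwise-distinct mutants; with `k`
equally frequent mutants the exact cleavable fraction is
`1 − (1−p)² − p²/k`, so the estimate carries a small downward bias of
order `p²/2k`. Both the raw cleaved fraction and the square-root estimate
are reported, as gel quantifications in the field sometimes quote the
uncorrected band fraction.

## Off-target differentials

`compute_differential` is treated-minus-mock on percentage scales, rounded
half-away-from-zero to two decimals, propagating ND. When raw summaries
are available the subtraction uses unrounded values; when reproducing
printed tables it uses the printed (already rounded) cells, which is why
two bundled table cells differ from re-derivation by exactly 0.01.
Negative differentials are assay background and are never clipped.
`aggregate_differentials` pools non-ND off-target rows (on-target excluded
by default, toggleable); the bundled tables pool cultured-cell and mouse
cohorts into 36 off-target differentials (mean 0.03, range −0.88 to 1.34).
The mouse cohort uses one animal's spleen as a shared background column
rather than paired mocks, mirroring the original design.

## Problem sizes and tolerances

Simulation-based checks use 10,000 reads per condition (40,000 for the
study-condition recovery run, where total correction is only ~1.7% and the
with-indel share needs ~700 correction reads for a stable estimate);
binomial comparisons use 3-standard-error bounds computed from the
realised truth fractions. Heteroduplex simulations use 30,000–40,000
duplexes. Percent values are reported to two decimals; the surveyor
inversion is exact to machine precision. Degenerate inputs are explicit:
empty pools and all-ND aggregates raise; zero passed reads produce an
explicit empty summary rather than a division error; all-N reads are
reported unalignable and filtered with a reason.

## Known limitations

* The classifier is single-amplicon and single-end: no genome-wide
  mapping, UMI handling, paired-end merging, or base-quality
  recalibration.
* The "high-quality read" thresholds (identity 0.90, mismatch cap 2) are
  declared defaults of this implementation, not reconstructions of the
  original custom script, whose criteria are unpublished.
* Whether published per-site `%Indels` columns include indel-associated
  correction events is ambiguous; summaries report both conventions
  (`pct_indels` includes them, `pct_indels_nhej_only` excludes them).
* The recurrent 44-bp deletion's true breakpoints are unpublished; the
  model fixes a canonical deletion centred on the cleavage window.
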