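"""Alignment, quality filter, per-read classification and summaries."""

import numpy as np
import pytest

from editcall import (align_read, classify_read, classify_sample, calls_to_frame,
                      passes_quality_filter, summarize_sample, deletion_spectrum,
                      simulate_reads, reverse_complement, make_allele)
from editcall.classify import AlignmentParams, ClassifyParams, OutcomeCall
from editcall.simulate import SimulationConfig
from editcall.util import canonical_deletion


def read_window(ref):
    """A read start that keeps all diagnostic features inside a 150-bp read."""
    return ref.scid_pos - 40


def spanning_read(seq, ref, length=150):
    start = read_window(ref)
    return seq[start:start + length]


# ---------------------------------------------------------------------------
# alignment

def test_exact_substring_aligns_perfectly(ref, scid):
    read = spanning_read(scid, ref)
    aln = align_read(read, ref)
    assert aln.orientation == "forward"
    assert not aln.deletions and not aln.insertions
    assert aln.identity_outside(ref, 10) == 1.0
    start = read_window(ref)
    assert aln.ref_span == (start, start + 150)
    # coordinate round-trip: every aligned column returns the read base
    assert all(scid[pos] == b for pos, b in aln.pairs.items())


def test_reverse_complement_read_is_orientation_normalised(ref, scid):
    read = reverse_complement(spanning_read(scid, ref))
    aln = align_read(read, ref)
    assert aln.orientation == "reverse-complement"
    assert not aln.deletions and not aln.insertions


def test_44bp_deletion_recovered_as_single_operation(ref, scid):
    s, L = ref.recurrent_deletion
    start = read_window(ref)
    molecule = scid[:s] + scid[s + L:]
    read = molecule[start:start + 150]
    aln = align_read(read, ref)
    assert aln.deletions == [(s, L)]
    assert not aln.insertions


def test_deletion_in_repeat_reports_leftmost_equivalent_start(ref, scid):
    # find a homopolymer run of >=3 downstream of the cleavage window and
    # delete 2 bases at its right edge; the aligner must report the leftmost
    # score-equivalent placement, as enumerated by brute force
    cw1 = ref.cleavage_window[1]
    run_start = None
    for i in range(cw1 + 5, cw1 + 200):
        if scid[i] == scid[i + 1] == scid[i + 2]:
            run_start = i
            break
    assert run_start is not None, "test reference lacks a homopolymer run"
    del_start, L = run_start + 1, 2
    molecule = scid[:del_start] + scid[del_start + L:]
    read_start = del_start - 70
    read = molecule[read_start:read_start + 150]
    derived = scid[:del_start] + scid[del_start + L:]
    equivalent = [j for j in range(len(scid) - L + 1)
                  if scid[:j] + scid[j + L:] == derived]
    aln = align_read(read, ref)
    assert aln.deletions == [(min(equivalent), L)]
    assert min(equivalent) == canonical_deletion(scid, del_start, L)


def test_alignment_input_errors(ref):
    with pytest.raises(ValueError):
        align_read("", ref)
    with pytest.raises(ValueError):
        align_read("A" * (ref.length + 1), ref)
    aln = align_read("N" * 100, ref)
    assert aln.unalignable
    ok, reason = passes_quality_filter(aln, ref)
    assert not ok and reason == "unalignable"


# ---------------------------------------------------------------------------
# quality filter

def test_perfect_spanning_read_passes_filter(ref, scid):
    aln = align_read(spanning_read(scid, ref), ref)
    ok, reason = passes_quality_filter(aln, ref)
    assert ok and reason is None


def test_read_missing_diagnostic_region_fails_span(ref, scid):
    start = ref.scid_pos + 5   # downstream of all diagnostic positions
    aln = align_read(scid[start:start + 120], ref)
    ok, reason = passes_quality_filter(aln, ref)
    assert not ok and reason == "span"


def test_noisy_read_fails_identity(ref, scid):
    rng = np.random.default_rng(0)
    start = read_window(ref)
    read = list(scid[start:start + 150])
    cw0, cw1 = ref.cleavage_window
    outside = [i for i in range(150)
               if not (cw0 - 10 <= start + i < cw1 + 10)]
    for i in rng.choice(outside, size=int(0.15 * len(outside)), replace=False):
        read[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[i]]
    aln = align_read("".join(read), ref)
    assert aln.identity_outside(ref, 10) < 0.90
    ok, reason = passes_quality_filter(aln, ref)
    assert not ok and reason == "identity"


# ---------------------------------------------------------------------------
# classification

def classify_seq(seq, ref, **params):
    return classify_read(align_read(seq, ref), ref, ClassifyParams(**params))


def test_scid_read_is_wildtype_category(ref, scid):
    call = classify_seq(spanning_read(scid, ref), ref)
    assert call.category == "WT"
    assert call.n_diag_subs_matched == 0
    assert not call.indel_overlaps_cleavage


def test_recurrent_deletion_without_diag_subs_is_nhej(ref, scid):
    s, L = ref.recurrent_deletion
    molecule = scid[:s] + scid[s + L:]
    call = classify_seq(spanning_read(molecule, ref), ref)
    assert call.category == "NHEJ_INDEL"
    assert call.indel_overlaps_cleavage
    assert call.deletions == [(s, L)]


def test_three_substitutions_without_indel_is_corrected(ref, corrected):
    call = classify_seq(spanning_read(corrected, ref), ref)
    assert call.category == "HDR_CORRECTED"
    assert call.n_diag_subs_matched == 3
    assert call.extra_mismatches == 0


def test_three_substitutions_plus_window_deletion_is_hdr_with_indel(ref, corrected):
    s, L = ref.recurrent_deletion
    molecule = corrected[:s] + corrected[s + L:]
    call = classify_seq(spanning_read(molecule, ref), ref)
    assert call.category == "HDR_WITH_INDEL"
    assert call.n_diag_subs_matched == 3


def test_partial_diagnostic_signature_is_unclassified(ref, scid):
    pos, _, diag_base = ref.diag_subs[0]
    partial = scid[:pos] + diag_base + scid[pos + 1:]
    call = classify_seq(spanning_read(partial, ref), ref)
    assert call.category == "UNCLASSIFIED"
    assert call.filter_reason == "partial_hdr"
    assert call.n_diag_subs_matched == 1


def test_too_many_extra_mismatches_voids_an_hdr_call(ref, corrected):
    start = read_window(ref)
    read = list(corrected[start:start + 150])
    # 3 mismatches far from the diagnostic region and the cleavage window
    for i in (2, 5, 8):
        read[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[i]]
    call = classify_seq("".join(read), ref)
    assert call.extra_mismatches == 3
    assert call.category == "UNCLASSIFIED" and call.filter_reason == "mismatches"
    relaxed = classify_seq("".join(read), ref, max_extra_mismatches=5)
    assert relaxed.category == "HDR_CORRECTED"


def test_insertion_window_boundary_rule(ref, scid):
    cw0, cw1 = ref.cleavage_window
    ins = "C" if scid[cw1 - 1] != "C" else "G"   # content that cannot left-shift
    molecule = scid[:cw1] + ins + scid[cw1:]
    closed = classify_seq(spanning_read(molecule, ref), ref,
                          insertion_window_rule="closed")
    half = classify_seq(spanning_read(molecule, ref), ref,
                        insertion_window_rule="half-open")
    assert closed.category == "NHEJ_INDEL"
    assert half.category == "WT"


def test_substitutions_inside_window_without_indel_are_not_indels(ref, scid):
    cw0, _ = ref.cleavage_window
    mutated = scid[:cw0] + {"A": "C", "C": "G", "G": "T", "T": "A"}[scid[cw0]] \
        + scid[cw0 + 1:]
    call = classify_seq(spanning_read(mutated, ref), ref)
    assert call.category == "WT"
    assert not call.indel_overlaps_cleavage
    assert call.extra_mismatches == 1


# ---------------------------------------------------------------------------
# sample-level properties

def test_error_free_classification_matches_truth(ref):
    cfg = SimulationConfig(n_reads=1500, p_wt=0.55, p_indel=0.3, p_hdr=0.1,
                           p_hdr_indel=0.05, error_rate=0.0, seed=21)
    reads, truth = simulate_reads(ref, cfg)
    df = calls_to_frame(classify_sample(reads, ref)).merge(truth, on="read_id")
    assert df.passed_filter.all()
    assert (df.category_x == df.category_y).all()


def test_reverse_complementing_every_read_leaves_summary_unchanged(ref):
    cfg = SimulationConfig(n_reads=400, seed=22, error_rate=0.002)
    reads, _ = simulate_reads(ref, cfg)
    flipped = [(rid, reverse_complement(seq), qual[::-1]) for rid, seq, qual in reads]
    a = summarize_sample(classify_sample(reads, ref), "fwd")
    b = summarize_sample(classify_sample(flipped, ref), "rc")
    assert a.counts == b.counts
    assert a.pct_indels == b.pct_indels
    assert a.pct_corrected == b.pct_corrected
    assert a.deletion_spectrum.equals(b.deletion_spectrum)


def make_call(category, passed=True, dels=()):
    return OutcomeCall(read_id="x", category=category,
                       indel_overlaps_cleavage=bool(dels),
                       n_diag_subs_matched=3 if category.startswith("HDR") else 0,
                       extra_mismatches=0, passed_filter=passed,
                       filter_reason=None, deletions=list(dels), insertions=[])


def test_summary_percentages_use_passed_denominator():
    calls = ([make_call("WT")] * 80 + [make_call("NHEJ_INDEL", dels=[(10, 4)])] * 18
             + [make_call("UNCLASSIFIED")] * 2)
    s = summarize_sample(calls, "toy")
    assert s.passed_filter == 100
    assert s.pct_indels == 18.00
    assert s.pct_corrected == 0.00
    assert sum(s.percentages.values()) == pytest.approx(100.0, abs=0.05)


def test_correction_with_indel_share_of_total_correction():
    calls = ([make_call("WT")] * 91 + [make_call("HDR_CORRECTED")] * 8
             + [make_call("HDR_WITH_INDEL", dels=[(10, 44)])])
    s = summarize_sample(calls, "toy")
    assert s.pct_corrected == 8.00
    assert s.pct_indels == 1.00
    assert s.pct_correction_with_indel_of_total_correction == pytest.approx(11.11)


def test_empty_sample_reports_zeroes_not_division_errors():
    calls = [make_call("UNCLASSIFIED", passed=False)] * 5
    s = summarize_sample(calls, "empty")
    assert s.passed_filter == 0
    assert s.pct_indels == 0.0 and s.pct_corrected == 0.0
    assert s.deletion_spectrum.empty


def test_deletion_spectrum_tally_and_recurrent_flag():
    calls = ([make_call("NHEJ_INDEL", dels=[(825, 44)])] * 60
             + [make_call("NHEJ_INDEL", dels=[(840, 3)])] * 30
             + [make_call("HDR_WITH_INDEL", dels=[(825, 44)])] * 10)
    spec = deletion_spectrum(calls, recurrent_share_threshold=0.2)
    assert spec.iloc[0].tolist() == [825, 44, 70, 0.7, True]
    assert spec.iloc[1].tolist() == [840, 3, 30, 0.3, True]
    none = deletion_spectrum([make_call("WT")] * 10)
    assert none.empty
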