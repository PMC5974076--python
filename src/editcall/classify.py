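"""Per-read editing-outcome classification from amplicon alignments.

Each read is aligned semi-globally (free end gaps on the reference) to the
SCID allele of the amplicon -- the unedited sequence actually present in
the sample -- and classified from three pieces of evidence:

* whether any indel operation involves the nuclease cleavage window
  (length-changing NHEJ signature);
* how many of the 3 diagnostic positions (reverted point mutation + 2
  silent substitutions forming the BsaWI site) carry the corrected base
  (HDR signature);
* the number of additional mismatches (sequencing-noise guard for calls
  that rest on the 3 diagnostic bases).

Categories: WT, NHEJ_INDEL, HDR_CORRECTED, HDR_WITH_INDEL, UNCLASSIFIED.
Reads first pass a quality filter: sufficient identity outside the
cleavage neighbourhood and an aligned span covering both the diagnostic
positions and the full cleavage window.

Alignment is seeded with edlib (orientation choice + coarse location,
bit-parallel edit distance) and refined with an affine-gap semi-global
dynamic program (match +2, mismatch -4, gap open -10, extend -1) on a
padded reference slice; indels are then left-normalised so equivalent
placements in repeats report a canonical (leftmost) start.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import edlib
import numpy as np
import pandas as pd
from Bio import Align

from .reference import AmpliconReference, reverse_complement
from .util import round_half_away

__all__ = [
    "AlignmentParams",
    "ClassifyParams",
    "AlignmentResult",
    "OutcomeCall",
    "SampleSummary",
    "align_read",
    "passes_quality_filter",
    "classify_read",
    "classify_sample",
    "summarize_sample",
    "deletion_spectrum",
    "calls_to_frame",
]

CALL_CATEGORIES = ("WT", "NHEJ_INDEL", "HDR_CORRECTED", "HDR_WITH_INDEL", "UNCLASSIFIED")


@dataclass(frozen=True)
class AlignmentParams:
    match: int = 2
    mismatch: int = -4
    gap_open: int = -10       # cost of a length-1 gap
    gap_extend: int = -1      # per additional gapped base
    slice_pad: int = 130      # reference padding around the edlib locus; must
                              # exceed the longest deletion plus flank, because
                              # edit-distance seeding can misplace reads whose
                              # flank on one side of a long deletion is short


@dataclass(frozen=True)
class ClassifyParams:
    min_identity: float = 0.90
    neighborhood_pad: int = 10        # cleavage window padding excluded from identity
    max_extra_mismatches: int = 2     # tolerance for diagnostic-based (HDR) calls
    insertion_window_rule: str = "closed"   # "closed" | "half-open"


@dataclass
class AlignmentResult:
    read_id: str
    orientation: str                          # "forward" | "reverse-complement"
    read_seq: str                             # orientation-normalised sequence
    ref_span: tuple[int, int]                 # half-open aligned reference span
    pairs: dict[int, str]                     # ref_pos -> read base (aligned columns)
    deletions: list[tuple[int, int]]          # (ref start, length), left-aligned
    insertions: list[tuple[int, int, str]]    # (ref anchor, length, inserted seq)
    score: float = 0.0
    unalignable: bool = False

    def identity_outside(self, ref: AmpliconReference, pad: int) -> float:
        lo = ref.cleavage_window[0] - pad
        hi = ref.cleavage_window[1] + pad
        total = matches = 0
        for pos, base in self.pairs.items():
            if lo <= pos < hi:
                continue
            total += 1
            if base == ref.sequence[pos]:
                matches += 1
        return matches / total if total else 0.0


def _pairwise_aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = params.match
    a.mismatch_score = params.mismatch
    a.open_gap_score = params.gap_open
    a.extend_gap_score = params.gap_extend
    # free end gaps on the reference (read aligned within the amplicon)
    a.open_left_deletion_score = 0
    a.extend_left_deletion_score = 0
    a.open_right_deletion_score = 0
    a.extend_right_deletion_score = 0
    return a


def _left_normalise(ref_seq: str, aln: AlignmentResult) -> None:
    """Shift each indel to the leftmost score-equivalent placement.

    A deletion ``ref[s:s+L]`` may move one step left when the column at
    ``s-1`` keeps its match status against ``ref[s+L-1]``; insertions
    rotate analogously.  This is the sequence-level normalisation that
    makes recurrent deletions in repeats tally at a canonical start.
    """
    new_dels = []
    for s, L in aln.deletions:
        while True:
            prev = s - 1
            if prev not in aln.pairs or any(d[0] <= prev < d[0] + d[1] for d in new_dels):
                break
            base = aln.pairs[prev]
            if (base == ref_seq[prev]) != (base == ref_seq[s + L - 1]):
                break
            if any(a == s - 1 or a == s + L - 1 for a, _, _ in aln.insertions):
                break
            aln.pairs[s + L - 1] = aln.pairs.pop(prev)
            s -= 1
        new_dels.append((s, L))
    aln.deletions = sorted(new_dels)

    new_ins = []
    for anchor, L, seq in aln.insertions:
        while True:
            prev = anchor - 1
            if prev not in aln.pairs or any(s <= prev < s + d for s, d in aln.deletions):
                break
            base = aln.pairs[prev]
            # shifting the gap left rotates the insertion: the previously
            # aligned read base joins the insertion head and the insertion's
            # last base becomes the column aligned at ``prev``
            tail = seq[-1]
            if (base == ref_seq[prev]) != (tail == ref_seq[prev]):
                break
            aln.pairs[prev] = tail
            seq = base + seq[:-1]
            anchor -= 1
        new_ins.append((anchor, L, seq))
    aln.insertions = sorted(new_ins)


def align_read(read: str | tuple[str, str] | tuple[str, str, str],
               ref: AmpliconReference,
               params: AlignmentParams | None = None,
               _aligner: Align.PairwiseAligner | None = None) -> AlignmentResult:
    """Orientation-normalised semi-global alignment of one read.

    ``read`` may be a bare sequence or a ``(read_id, seq[, qual])`` tuple.
    Raises for empty reads or reads longer than the reference; an all-N
    read yields an ``unalignable`` result.
    """
    params = params or AlignmentParams()
    if isinstance(read, str):
        read_id, seq = "read", read
    else:
        read_id, seq = read[0], read[1]
    seq = seq.upper()
    if not seq:
        raise ValueError("empty read")
    if len(seq) > ref.length:
        raise ValueError("read longer than reference amplicon")
    if set(seq) <= {"N"}:
        return AlignmentResult(read_id, "forward", seq, (0, 0), {}, [], [],
                               unalignable=True)

    fwd = edlib.align(seq, ref.sequence, mode="HW", task="distance")
    rc_seq = reverse_complement(seq)
    rev = edlib.align(rc_seq, ref.sequence, mode="HW", task="distance")
    if rev["editDistance"] < fwd["editDistance"]:
        orientation, oriented = "reverse-complement", rc_seq
    else:
        orientation, oriented = "forward", seq
    loc = edlib.align(oriented, ref.sequence, mode="HW", task="path")
    lo, hi = loc["locations"][0]
    if "I" not in loc["cigar"] and "D" not in loc["cigar"]:
        # substitution-only read: the column map is unique, no affine
        # refinement or indel normalisation needed
        pairs = {lo + k: oriented[k] for k in range(len(oriented))}
        return AlignmentResult(read_id, orientation, oriented,
                               (lo, lo + len(oriented)), pairs, [], [],
                               score=float(params.match * len(oriented)
                                           + (params.mismatch - params.match)
                                           * loc["editDistance"]))
    s0 = max(0, lo - params.slice_pad)
    s1 = min(ref.length, hi + 1 + params.slice_pad)

    aligner = _aligner or _pairwise_aligner(params)
    best = aligner.align(ref.sequence[s0:s1], oriented)[0]
    tgt_blocks, qry_blocks = best.aligned

    pairs: dict[int, str] = {}
    deletions: list[tuple[int, int]] = []
    insertions: list[tuple[int, int, str]] = []
    prev_t = prev_q = None
    for (t0, t1), (q0, q1) in zip(tgt_blocks, qry_blocks):
        if prev_t is not None:
            if t0 > prev_t:
                deletions.append((s0 + prev_t, t0 - prev_t))
            if q0 > prev_q:
                insertions.append((s0 + t0, q0 - prev_q, oriented[prev_q:q0]))
        for k in range(t1 - t0):
            pairs[s0 + t0 + k] = oriented[q0 + k]
        prev_t, prev_q = t1, q1
    if not pairs:
        return AlignmentResult(read_id, orientation, oriented, (0, 0), {}, [], [],
                               unalignable=True)
    ref_span = (min(pairs), max(pairs) + 1)
    aln = AlignmentResult(read_id, orientation, oriented, ref_span, pairs,
                          deletions, insertions, score=best.score)
    _left_normalise(ref.sequence, aln)
    aln.ref_span = (min(aln.pairs), max(aln.pairs) + 1)
    return aln


@dataclass
class OutcomeCall:
    read_id: str
    category: str
    indel_overlaps_cleavage: bool
    n_diag_subs_matched: int
    extra_mismatches: int
    passed_filter: bool
    filter_reason: str | None
    deletions: list[tuple[int, int]] = field(default_factory=list)
    insertions: list[tuple[int, int, str]] = field(default_factory=list)


def passes_quality_filter(aln: AlignmentResult, ref: AmpliconReference,
                          params: ClassifyParams | None = None
                          ) -> tuple[bool, str | None]:
    """High-quality read extraction by alignment to the template.

    A read passes iff its identity outside the cleavage neighbourhood meets
    the threshold and its aligned span covers every diagnostic position and
    the full cleavage window.
    """
    params = params or ClassifyParams()
    if aln.unalignable:
        return False, "unalignable"
    lo_req = min(ref.diag_positions())
    hi_req = ref.cleavage_window[1]
    if not (aln.ref_span[0] <= lo_req and aln.ref_span[1] >= hi_req):
        return False, "span"
    if aln.identity_outside(ref, params.neighborhood_pad) < params.min_identity:
        return False, "identity"
    return True, None


def _indel_overlaps_window(aln: AlignmentResult, ref: AmpliconReference,
                           rule: str) -> bool:
    cw0, cw1 = ref.cleavage_window
    for s, L in aln.deletions:
        if s < cw1 and s + L > cw0:
            return True
    hi = cw1 if rule == "closed" else cw1 - 1
    for anchor, _, _ in aln.insertions:
        if cw0 <= anchor <= hi:
            return True
    return False


def classify_read(aln: AlignmentResult, ref: AmpliconReference,
                  params: ClassifyParams | None = None) -> OutcomeCall:
    """Assign an editing-outcome category to one aligned read.

    NHEJ indels are length-changing events involving any base of the
    cleavage window; correction requires all 3 diagnostic bases.  Reads
    with a partial diagnostic signature and no qualifying indel, and
    diagnostic-complete reads with too many extra mismatches, are reported
    UNCLASSIFIED rather than forced into a category.
    """
    params = params or ClassifyParams()
    passed, reason = passes_quality_filter(aln, ref, params)
    diag = ref.corrected_bases()
    n_diag = sum(1 for pos, base in diag.items() if aln.pairs.get(pos) == base)
    extra = sum(1 for pos, b in aln.pairs.items()
                if b != ref.sequence[pos] and pos not in diag)
    overlaps = _indel_overlaps_window(aln, ref, params.insertion_window_rule)
    if not passed:
        category = "UNCLASSIFIED"
    elif n_diag == 3:
        if extra > params.max_extra_mismatches:
            category, reason = "UNCLASSIFIED", "mismatches"
        else:
            category = "HDR_WITH_INDEL" if overlaps else "HDR_CORRECTED"
    elif overlaps:
        category = "NHEJ_INDEL"
    elif n_diag > 0:
        category, reason = "UNCLASSIFIED", "partial_hdr"
    else:
        category = "WT"
    return OutcomeCall(
        read_id=aln.read_id,
        category=category,
        indel_overlaps_cleavage=overlaps,
        n_diag_subs_matched=n_diag,
        extra_mismatches=extra,
        passed_filter=passed,
        filter_reason=reason,
        deletions=list(aln.deletions),
        insertions=list(aln.insertions),
    )


def classify_sample(reads: Iterable[tuple[str, str, str] | tuple[str, str]],
                    ref: AmpliconReference,
                    align_params: AlignmentParams | None = None,
                    params: ClassifyParams | None = None) -> list[OutcomeCall]:
    align_params = align_params or AlignmentParams()
    params = params or ClassifyParams()
    aligner = _pairwise_aligner(align_params)
    calls = []
    for read in reads:
        aln = align_read(read, ref, align_params, _aligner=aligner)
        calls.append(classify_read(aln, ref, params))
    return calls


def calls_to_frame(calls: list[OutcomeCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        dels = ";".join(f"{s}:{L}" for s, L in c.deletions)
        ins = ";".join(f"{a}:{L}" for a, L, _ in c.insertions)
        rows.append((c.read_id, c.category, c.indel_overlaps_cleavage,
                     c.n_diag_subs_matched, c.extra_mismatches, c.passed_filter,
                     c.filter_reason or "", dels, ins))
    return pd.DataFrame(rows, columns=[
        "read_id", "category", "indel_overlaps_cleavage", "n_diag_subs_matched",
        "extra_mismatches", "passed_filter", "filter_reason", "deletions",
        "insertions"])


@dataclass
class SampleSummary:
    label: str
    total_reads: int
    passed_filter: int
    counts: dict[str, int]
    percentages: dict[str, float]           # per category, of passed reads
    pct_indels: float                        # NHEJ_INDEL + HDR_WITH_INDEL
    pct_indels_nhej_only: float              # excludes correction-associated indels
    pct_corrected: float                     # HDR_CORRECTED only
    pct_correction_with_indel_of_total_correction: float
    deletion_spectrum: pd.DataFrame

    def to_dict(self) -> dict:
        d = {
            "label": self.label,
            "total_reads": self.total_reads,
            "passed_filter": self.passed_filter,
            "counts": self.counts,
            "percentages": self.percentages,
            "pct_indels": self.pct_indels,
            "pct_indels_nhej_only": self.pct_indels_nhej_only,
            "pct_corrected": self.pct_corrected,
            "pct_correction_with_indel_of_total_correction":
                self.pct_correction_with_indel_of_total_correction,
        }
        return d


def summarize_sample(calls: list[OutcomeCall] | pd.DataFrame,
                     label: str = "sample",
                     recurrent_share_threshold: float = 0.2) -> SampleSummary:
    """Aggregate per-read calls into sample-level editing frequencies.

    Percentages use the passed-filter denominator and are reported to 2
    decimals.  ``pct_corrected`` deliberately excludes HDR_WITH_INDEL (the
    headline correction frequency counts only clean corrections); the
    correction-with-indel share is reported relative to total correction.
    """
    df = calls if isinstance(calls, pd.DataFrame) else calls_to_frame(calls)
    total = len(df)
    passed = df[df["passed_filter"]]
    n_pass = len(passed)
    counts = {c: 0 for c in CALL_CATEGORIES}
    counts.update(passed["category"].value_counts().to_dict())
    if n_pass == 0:
        empty = pd.DataFrame(columns=["del_start", "del_length", "count", "share",
                                      "recurrent"])
        return SampleSummary(label, total, 0, counts,
                             {c: 0.0 for c in CALL_CATEGORIES},
                             0.0, 0.0, 0.0, 0.0, empty)
    pcts = {c: round_half_away(100.0 * counts[c] / n_pass, 2) for c in CALL_CATEGORIES}
    n_indel = counts["NHEJ_INDEL"] + counts["HDR_WITH_INDEL"]
    n_corr_total = counts["HDR_CORRECTED"] + counts["HDR_WITH_INDEL"]
    with_indel_share = (100.0 * counts["HDR_WITH_INDEL"] / n_corr_total
                        if n_corr_total else 0.0)
    spectrum = deletion_spectrum(df, recurrent_share_threshold)
    return SampleSummary(
        label=label,
        total_reads=total,
        passed_filter=n_pass,
        counts=counts,
        percentages=pcts,
        pct_indels=round_half_away(100.0 * n_indel / n_pass, 2),
        pct_indels_nhej_only=round_half_away(100.0 * counts["NHEJ_INDEL"] / n_pass, 2),
        pct_corrected=round_half_away(100.0 * counts["HDR_CORRECTED"] / n_pass, 2),
        pct_correction_with_indel_of_total_correction=round_half_away(with_indel_share, 2),
        deletion_spectrum=spectrum,
    )


def deletion_spectrum(calls: list[OutcomeCall] | pd.DataFrame,
                      recurrent_share_threshold: float = 0.2) -> pd.DataFrame:
    """Tally of left-aligned deletion events from indel-bearing calls.

    Any (start, length) carrying at least ``recurrent_share_threshold`` of
    all deletion events is flagged recurrent.
    """
    df = calls if isinstance(calls, pd.DataFrame) else calls_to_frame(calls)
    sel = df[df["category"].isin(["NHEJ_INDEL", "HDR_WITH_INDEL"])]
    tally: dict[tuple[int, int], int] = {}
    for dels in sel["deletions"]:
        if not dels:
            continue
        for item in dels.split(";"):
            s, L = (int(x) for x in item.split(":"))
            tally[(s, L)] = tally.get((s, L), 0) + 1
    if not tally:
        return pd.DataFrame(columns=["del_start", "del_length", "count", "share",
                                     "recurrent"])
    total = sum(tally.values())
    rows = [(s, L, n, n / total, n / total >= recurrent_share_threshold)
            for (s, L), n in tally.items()]
    out = pd.DataFrame(rows, columns=["del_start", "del_length", "count", "share",
                                      "recurrent"])
    return (out.sort_values(["count", "del_start", "del_length"],
                            ascending=[False, True, True])
               .reset_index(drop=True))
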