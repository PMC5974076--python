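"""Synthetic amplicon-read generation with ground-truth editing outcomes.

The generator emulates the statistical structure of MiSeq amplicon data
from a nuclease + repair-template editing experiment: single-end reads
spanning the target site, drawn from a mixture of

* unedited (SCID-allele) molecules,
* NHEJ outcomes -- molecules carrying an insertion or deletion that
  involves the nuclease cleavage window, a configurable fraction of which
  are the fixed recurrent 44-bp deletion,
* HDR outcomes -- corrected-allele molecules (3 diagnostic substitutions),
* HDR outcomes additionally carrying a cleavage-window indel,

with uniform per-base substitution errors applied after the structural
edit, and read orientation randomised 50/50.  Truth labels are emitted in
a separate table (never encoded in read names), so the classifier is
tested blind.

Defaults encode the modelled study conditions: 18% NHEJ indels and 1.53%
pure correction with a correction-with-indel share of 11.25% of total
correction, reads of 150 bp at constant Q30.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .reference import AmpliconReference, make_allele, reverse_complement
from .util import canonical_deletion, canonical_insertion

__all__ = [
    "SimulationConfig",
    "CATEGORIES",
    "simulate_reads",
    "write_fastq",
    "read_fastq",
    "make_heteroduplex_pool",
    "RECURRENT",
]

CATEGORIES = ("WT", "NHEJ_INDEL", "HDR_CORRECTED", "HDR_WITH_INDEL")
RECURRENT = "recurrent_44bp_deletion"

TRUTH_COLUMNS = ["read_id", "category", "indel_type", "indel_start",
                 "indel_length", "is_recurrent_deletion"]


class SimulationConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition knobs for the read generator.

    ``proportions`` are the truth-category sampling weights (wild-type,
    NHEJ indel, pure HDR, HDR with associated indel).  ``read_window`` is
    the inclusive range of read start positions on the reference; it must
    keep the diagnostic substitutions and the full cleavage window inside
    every read, otherwise reads are unclassifiable by construction.
    """

    n_reads: int = 10_000
    p_wt: float = 0.8028
    p_indel: float = 0.18
    p_hdr: float = 0.0153
    p_hdr_indel: float = 0.0019
    recurrent_del_frac: float = 0.5
    del_mean_length: float = 4.0      # geometric mean of non-recurrent deletions
    del_max_length: int = 60
    ins_mean_length: float = 2.0
    ins_del_ratio: float = 0.3        # P(non-recurrent indel is an insertion)
    error_rate: float = 0.001         # per-base substitution errors (Q30)
    read_length: int = 150
    read_window: tuple[int, int] | None = None   # inclusive read-start range
    min_flank: int = 35   # anchor length upstream of the point mutation; amplicon
                          # reads start near a fixed primer, and a short anchor
                          # carrying the 3 diagnostic mismatches cannot pin a
                          # long deletion unambiguously
    seed: int = 0
    base_quality: int = 30

    @property
    def proportions(self) -> dict[str, float]:
        return {"WT": self.p_wt, "NHEJ_INDEL": self.p_indel,
                "HDR_CORRECTED": self.p_hdr, "HDR_WITH_INDEL": self.p_hdr_indel}

    def validate(self, ref: AmpliconReference) -> tuple[int, int]:
        ps = self.proportions
        if any(p < 0 or p > 1 for p in ps.values()):
            raise SimulationConfigError("category proportions must be in [0, 1]")
        if abs(sum(ps.values()) - 1.0) > 1e-9:
            raise SimulationConfigError("category proportions must sum to 1")
        if not 0 <= self.recurrent_del_frac <= 1:
            raise SimulationConfigError("recurrent_del_frac must be in [0, 1]")
        lo_feat = min(ref.diag_positions() + (ref.bsawi_span[0],))
        hi_feat = ref.cleavage_window[1]
        if self.read_window is not None:
            lo, hi = self.read_window
        else:
            # every read must retain the diagnostic region and, even after a
            # maximal deletion, still reach past the cleavage window
            lo = hi_feat + self.del_max_length - self.read_length
            hi = min(lo_feat - 1, ref.scid_pos - self.min_flank)
        if lo > hi or lo < 0 or hi + self.read_length > ref.length:
            raise SimulationConfigError("read_window cannot host classifiable reads")
        if hi >= lo_feat or lo + self.read_length < hi_feat:
            raise SimulationConfigError(
                "read_window must keep diagnostic substitutions and the cleavage "
                "window inside every read")
        return lo, hi


def _sample_indel(rng: np.random.Generator, ref: AmpliconReference,
                  cfg: SimulationConfig, template: str
                  ) -> tuple[str, int, int, str, bool]:
    """Draw one structural edit whose canonical form involves the cleavage window.

    Returns (type, start, length, inserted_seq, is_recurrent) with start the
    left-aligned (canonical) placement, matching the classifier's indel
    normalisation so truth labels are recoverable from sequence alone.
    Starts are constrained downstream of the point-mutation site so the
    diagnostic region is never disrupted.
    """
    cw0, cw1 = ref.cleavage_window
    if rng.random() < cfg.recurrent_del_frac:
        start, length = ref.recurrent_deletion
        return "D", start, length, "", True
    for _ in range(1000):
        if rng.random() < cfg.ins_del_ratio:
            length = int(min(rng.geometric(1.0 / cfg.ins_mean_length),
                             cfg.del_max_length))
            anchor = int(rng.integers(cw0, cw1 + 1))   # closed window
            ins = "".join(rng.choice(list("ACGT"), size=length))
            anchor, ins = canonical_insertion(template, anchor, ins)
            if cw0 <= anchor <= cw1:
                return "I", anchor, length, ins, False
        else:
            length = int(min(rng.geometric(1.0 / cfg.del_mean_length),
                             cfg.del_max_length))
            lo = max(ref.scid_pos + 1, cw0 - length + 1)
            start = canonical_deletion(template, int(rng.integers(lo, cw1)), length)
            if start > ref.scid_pos and start < cw1 and start + length > cw0:
                return "D", start, length, "", False
    raise SimulationConfigError("cannot place an indel overlapping the cleavage window")


def _edit_molecule(seq: str, kind: str, start: int, length: int, ins: str) -> str:
    if kind == "D":
        return seq[:start] + seq[start + length:]
    return seq[:start] + ins + seq[start:]


def simulate_reads(ref: AmpliconReference, cfg: SimulationConfig
                   ) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Generate reads and their truth table.

    Returns ``(reads, truth)`` where ``reads`` is a list of
    ``(read_id, sequence, quality_string)`` and ``truth`` a DataFrame with
    columns ``read_id, category, indel_type, indel_start, indel_length,
    is_recurrent_deletion``.  Fully determined by ``cfg.seed``.
    """
    lo, hi = cfg.validate(ref)
    rng = np.random.default_rng(cfg.seed)
    scid = make_allele(ref, "SCID").sequence
    corrected = make_allele(ref, "CORRECTED").sequence
    qual = chr(cfg.base_quality + 33) * cfg.read_length

    cats = list(CATEGORIES)
    probs = np.array([cfg.proportions[c] for c in cats])
    # one categorical draw per read keeps the seed stream aligned across
    # configs that differ only in proportions (monotonicity property)
    u = rng.random(cfg.n_reads)
    cum = np.cumsum(probs)
    cat_idx = np.searchsorted(cum, u, side="right").clip(max=len(cats) - 1)

    reads: list[tuple[str, str, str]] = []
    rows = []
    width = len(str(max(cfg.n_reads - 1, 1)))
    for i in range(cfg.n_reads):
        category = cats[cat_idx[i]]
        template = scid if category in ("WT", "NHEJ_INDEL") else corrected
        indel = None
        if category in ("NHEJ_INDEL", "HDR_WITH_INDEL"):
            indel = _sample_indel(rng, ref, cfg, template)
            kind, start, length, ins, recurrent = indel
            molecule = _edit_molecule(template, kind, start, length, ins)
        else:
            molecule = template
        start_pos = int(rng.integers(lo, hi + 1))
        # edits are downstream of the diagnostic region, hence downstream of
        # every allowed read start: molecule coords == reference coords at start_pos
        seq = molecule[start_pos:start_pos + cfg.read_length]
        if cfg.error_rate > 0:
            n_err = rng.binomial(cfg.read_length, cfg.error_rate)
            if n_err:
                pos = rng.choice(cfg.read_length, size=n_err, replace=False)
                chars = list(seq)
                for j in pos:
                    alt = [b for b in "ACGT" if b != chars[j]]
                    chars[j] = alt[int(rng.integers(3))]
                seq = "".join(chars)
        if rng.random() < 0.5:
            seq = reverse_complement(seq)
        read_id = f"r{i:0{width}d}"
        reads.append((read_id, seq, qual))
        if indel is None:
            rows.append((read_id, category, "", -1, 0, False))
        else:
            kind, start, length, _, recurrent = indel
            rows.append((read_id, category, kind, start, length, recurrent))
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    return reads, truth


def write_fastq(reads: list[tuple[str, str, str]], path: str | Path) -> None:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt", newline="\n") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual[:len(seq)]}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str, str]]:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    out = []
    with opener(path, "rt") as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            qual = fh.readline().strip()
            out.append((header.strip().lstrip("@").split()[0], seq, qual))
    return out


def make_heteroduplex_pool(allele_fractions: dict[str, float], n_duplexes: int,
                           seed: int = 0) -> pd.DataFrame:
    """Denature/reanneal model of the Surveyor (Cel-I) assay.

    Strand pairs are drawn i.i.d. from ``allele_fractions`` (keys are
    distinct molecular species, e.g. allele names or sequences); a duplex
    is cleavable iff its two strands derive from non-identical species.
    """
    if not allele_fractions:
        raise ValueError("empty allele pool")
    fracs = np.array(list(allele_fractions.values()), dtype=float)
    if (fracs < 0).any() or abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError("allele fractions must be non-negative and sum to 1")
    names = np.array(list(allele_fractions.keys()), dtype=object)
    rng = np.random.default_rng(seed)
    top = rng.choice(len(names), size=n_duplexes, p=fracs)
    bottom = rng.choice(len(names), size=n_duplexes, p=fracs)
    return pd.DataFrame({
        "strand_top": names[top],
        "strand_bottom": names[bottom],
        "cleavable": top != bottom,
    })
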