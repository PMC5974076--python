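"""In-silico analogues of the two gel assays.

* BsaWI RFLP digestion: each molecule of a pool is cut at every occurrence
  of the recognition pattern (default ``WCCGGW``, cut after the first
  base); the fraction of molecules cut at least once quantifies
  HDR-corrected material, because only corrected molecules carry the
  engineered site.  Molecules whose indel has destroyed the site are
  counted undigested, modelling the coupling between cleavage-window
  deletions and loss of the diagnostic band.

* Surveyor (Cel-I) heteroduplex cleavage: after denaturing and reannealing
  a PCR pool with mutant fraction p, the fraction of cleavable
  (mismatched) duplexes is f = 1 - (1-p)^2 - (sum of squared mutant
  fractions); inverting the two-species case gives the standard indel
  estimate p_hat = 1 - sqrt(1 - f).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .reference import BSAWI_PATTERN, find_recognition_sites, reverse_complement

__all__ = ["DigestResult", "SurveyorEstimate", "digest_pool", "surveyor_estimate"]


@dataclass(frozen=True)
class SurveyorEstimate:
    cleaved_fraction: float
    estimated_indel_fraction: float


@dataclass
class DigestResult:
    n_molecules: int
    digested: int
    band_table: pd.DataFrame       # fragment length, molecule count, intensity proxy
    fragments: list[list[int]]     # per-molecule fragment lengths

    @property
    def digested_fraction(self) -> float:
        return self.digested / self.n_molecules if self.n_molecules else 0.0


def _is_palindromic(pattern: str) -> bool:
    return reverse_complement(pattern) == pattern


def digest_pool(sequences: list[str], pattern: str = BSAWI_PATTERN,
                cut_offset: int = 1) -> DigestResult:
    """Cut every molecule at every recognition site; tally band lengths.

    ``cut_offset`` is the cut position within the pattern (1 for W^CCGGW).
    The pattern is scanned on one strand; if it is not its own reverse
    complement, the reverse-strand occurrences are scanned too.  The band
    intensity proxy is molecule count x fragment length (densitometry
    weights material, not molecules).
    """
    if not sequences:
        raise ValueError("empty molecule pool")
    if not 0 <= cut_offset < len(pattern):
        raise ValueError("cut_offset must fall within the pattern")
    both_strands = not _is_palindromic(pattern)
    fragments: list[list[int]] = []
    digested = 0
    band: dict[int, int] = {}
    for seq in sequences:
        cuts = {s + cut_offset for s in find_recognition_sites(seq, pattern)}
        if both_strands:
            n = len(seq)
            for s in find_recognition_sites(reverse_complement(seq), pattern):
                cuts.add(n - (s + cut_offset))
        cuts = sorted(c for c in cuts if 0 < c < len(seq))
        if cuts:
            digested += 1
        bounds = [0] + cuts + [len(seq)]
        lens = [bounds[i + 1] - bounds[i] for i in range(len(bounds) - 1)]
        fragments.append(lens)
        for L in lens:
            band[L] = band.get(L, 0) + 1
    table = pd.DataFrame(sorted(band.items()), columns=["length", "count"])
    table["intensity"] = table["length"] * table["count"]
    return DigestResult(len(sequences), digested, table, fragments)


def surveyor_estimate(f: float) -> SurveyorEstimate:
    """Invert the reannealing closed form f = 1 - (1-p)^2 for the indel fraction.

    Assumes mutant molecules are pairwise distinct (mutant:mutant duplexes
    cleavable), the regime of scattered NHEJ indels.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError("cleaved fraction must be in [0, 1]")
    return SurveyorEstimate(cleaved_fraction=f,
                            estimated_indel_fraction=1.0 - math.sqrt(1.0 - f))
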