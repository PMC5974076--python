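"""Annotated amplicon reference model.

The reference describes a single PCR amplicon from a gene carrying a point
mutation (the *scid* T->A stop mutation as modelled on the coding strand),
together with every coordinate the downstream stages need:

* ``scid_pos`` -- the mutated base (SCID allele carries ``scid_mut_base``,
  the wild-type and corrected alleles carry ``scid_wt_base``);
* a zinc-finger-nuclease cleavage window a fixed distance downstream of the
  point mutation (default 32 nt, the distance between mutation and nuclease
  target site);
* two silent diagnostic substitutions 3 and 6 bp upstream of the mutation
  which, together with the reverted mutation, engineer a BsaWI recognition
  site (``WCCGGW``) ending 2 nt upstream of the mutation -- the molecular
  signature of homology-directed correction;
* the fixed recurrent 44-bp deletion centred on the cleavage window, stored
  here so the simulator and the classifier agree on its breakpoints.

All coordinates are 0-based, half-open.  The base sequence stored in
:class:`AmpliconReference` is the SCID allele: that is the sequence present
in the cells being edited and therefore the template reads are aligned to.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .util import canonical_deletion
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Layout",
    "AmpliconReference",
    "AlleleVariant",
    "ALLELE_NAMES",
    "BSAWI_PATTERN",
    "build_reference",
    "make_allele",
    "find_recognition_sites",
    "reverse_complement",
    "write_reference",
    "load_reference",
]

BSAWI_PATTERN = "WCCGGW"

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

ALLELE_NAMES = ("WILD_TYPE", "SCID", "CORRECTED")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class ReferenceConstructionError(RuntimeError):
    """Raised when no sequence satisfying all reference invariants is found."""


@dataclass(frozen=True)
class Layout:
    """Feature offsets of the amplicon, all relative to ``scid_pos``.

    Defaults follow the modelled editing system: diagnostic substitutions at
    -6 and -3, the engineered WCCGGW site occupying ``[-7, -1)``, a 5-bp
    cleavage window starting 32 nt downstream, and a 44-bp recurrent
    deletion centred on that window.
    """

    scid_pos: int | None = None          # None -> centre of the amplicon
    diag_offsets: tuple[int, int] = (-6, -3)
    cleavage_offset: int = 32
    cleavage_width: int = 5
    recurrent_del_length: int = 44
    scid_wt_base: str = "T"
    scid_mut_base: str = "A"


@dataclass(frozen=True)
class AmpliconReference:
    """Wild-type amplicon coordinates with the SCID allele as base sequence."""

    sequence: str                        # SCID allele
    scid_pos: int
    scid_wt_base: str
    scid_mut_base: str
    cleavage_window: tuple[int, int]     # half-open
    diag_subs: tuple[tuple[int, str, str], ...]  # (pos, scid base, corrected base)
    bsawi_span: tuple[int, int]          # half-open, engineered site location
    recurrent_deletion: tuple[int, int]  # (start, length)
    label: str = "amplicon"
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        validate_reference(self)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def diag_positions(self) -> tuple[int, ...]:
        """The 3 positions diagnostic of correction (2 silent subs + scid base)."""
        return tuple(p for p, _, _ in self.diag_subs) + (self.scid_pos,)

    def corrected_bases(self) -> dict[int, str]:
        """Expected base at each diagnostic position in a corrected molecule."""
        out = {p: b for p, _, b in self.diag_subs}
        out[self.scid_pos] = self.scid_wt_base
        return out


@dataclass(frozen=True)
class AlleleVariant:
    name: str
    sequence: str


def find_recognition_sites(seq: str, pattern: str = BSAWI_PATTERN) -> list[int]:
    """All 0-based start positions where an IUPAC pattern matches ``seq``.

    Overlapping matches are reported; matching is on the given strand only.
    """
    pattern = pattern.upper()
    seq = seq.upper()
    sets = []
    for ch in pattern:
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC code in pattern: {ch!r}")
        sets.append(IUPAC[ch])
    k = len(pattern)
    hits = []
    for i in range(len(seq) - k + 1):
        if all(seq[i + j] in sets[j] for j in range(k)):
            hits.append(i)
    return hits


def _apply_subs(seq: str, subs: dict[int, str]) -> str:
    chars = list(seq)
    for p, b in subs.items():
        chars[p] = b
    return "".join(chars)


def _delete(seq: str, start: int, length: int) -> str:
    return seq[:start] + seq[start + length:]


def make_allele(ref: AmpliconReference, name: str) -> AlleleVariant:
    """Derive an allele sequence from the reference.

    SCID is the stored base sequence; WILD_TYPE reverts the scid base;
    CORRECTED additionally carries the two silent diagnostic substitutions.
    """
    if name == "SCID":
        seq = ref.sequence
    elif name == "WILD_TYPE":
        seq = _apply_subs(ref.sequence, {ref.scid_pos: ref.scid_wt_base})
    elif name == "CORRECTED":
        seq = _apply_subs(ref.sequence, ref.corrected_bases())
    else:
        raise ValueError(f"unknown allele name: {name!r} (expected one of {ALLELE_NAMES})")
    return AlleleVariant(name, seq)


def validate_reference(ref: AmpliconReference) -> None:
    n = len(ref.sequence)
    p = ref.scid_pos
    if set(ref.sequence) - set("ACGT"):
        raise ValueError("reference sequence must be A/C/G/T only")
    if not (0 <= p < n):
        raise ValueError("scid_pos outside sequence")
    cw = ref.cleavage_window
    if not (p < cw[0] < cw[1] <= n):
        raise ValueError("cleavage window must lie downstream of scid_pos, inside the amplicon")
    if ref.sequence[p] != ref.scid_mut_base:
        raise ValueError("base sequence must carry the scid mutation at scid_pos")
    if len(ref.diag_subs) != 2:
        raise ValueError("exactly 2 diagnostic substitutions expected")
    for pos, scid_base, diag_base in ref.diag_subs:
        if ref.sequence[pos] != scid_base:
            raise ValueError("diag_subs wild-type base mismatch with sequence")
        if scid_base == diag_base:
            raise ValueError("diagnostic substitution must change the base")
    ds, dl = ref.recurrent_deletion
    if not (0 <= ds and ds + dl <= n):
        raise ValueError("recurrent deletion outside the amplicon")
    lo, hi = ref.bsawi_span
    corrected = _apply_subs(ref.sequence, ref.corrected_bases())
    in_span = [s for s in find_recognition_sites(corrected) if lo <= s and s + len(BSAWI_PATTERN) <= hi]
    if len(in_span) != 1:
        raise ValueError("corrected allele must carry exactly one BsaWI site inside bsawi_span")
    scid_in_span = [s for s in find_recognition_sites(ref.sequence)
                    if lo <= s and s + len(BSAWI_PATTERN) <= hi]
    if scid_in_span:
        raise ValueError("SCID allele must carry no BsaWI site inside bsawi_span")


def _scrub_targets(seq: str, layout_ctx: dict) -> list[str]:
    """The molecule sequences that must be free of stray BsaWI sites.

    The engineered site in the corrected allele (and its recurrent-deletion
    derivative) is the single allowed occurrence.
    """
    subs = layout_ctx["corrected_subs"]
    ds, dl = layout_ctx["recurrent_deletion"]
    corrected = _apply_subs(seq, subs)
    return [seq, corrected, _delete(seq, ds, dl), _delete(corrected, ds, dl)]


def build_reference(length: int = 1626, seed: int = 7, layout: Layout | None = None,
                    label: str = "amplicon") -> AmpliconReference:
    """Build a seeded random amplicon reference satisfying every invariant.

    A uniform random A/C/G/T sequence is drawn, the feature bases (scid
    mutation, the four fixed bases of the engineered BsaWI site, diagnostic
    substitution placeholders) are installed, and then any accidental WCCGGW
    occurrence -- in the SCID allele, the corrected allele, or either
    allele's recurrent-deletion junction -- is removed by deterministically
    mutating one non-feature base.  WCCGGW is self-reverse-complementary, so
    a single-strand scan covers both strands.
    """
    layout = layout or Layout()
    if length < 200:
        raise ValueError("amplicon length must be >= 200")
    rng = np.random.default_rng(seed)
    p = layout.scid_pos if layout.scid_pos is not None else length // 2
    cw = (p + layout.cleavage_offset, p + layout.cleavage_offset + layout.cleavage_width)
    # recurrent deletion centred on the cleavage window
    centre = (cw[0] + cw[1]) / 2
    del_start = math.floor(centre - layout.recurrent_del_length / 2 + 0.5)
    del_ = (del_start, layout.recurrent_del_length)
    bsawi_span = (p - 7, p - 1)
    off_a, off_b = sorted(layout.diag_offsets)
    if (off_a, off_b) != (-6, -3):
        # Non-default placements are allowed but must keep the engineered
        # site construction (pattern ending 2 nt upstream) coherent.
        raise ValueError("diag_offsets other than (-6, -3) are not supported by the "
                         "engineered-site geometry")
    if not (bsawi_span[0] >= 0 and del_[0] >= 0 and del_[0] + del_[1] <= length
            and cw[1] <= length):
        raise ValueError("layout places features outside the amplicon")

    seq = list(rng.choice(list("ACGT"), size=length))
    # engineered site WCCGGW at [p-7, p-1): fixed bases at p-7, p-5, p-4, p-2
    seq[p - 7] = str(rng.choice(["A", "T"]))
    seq[p - 5] = "C"
    seq[p - 4] = "G"
    seq[p - 2] = str(rng.choice(["A", "T"]))
    # diagnostic placeholders: SCID base differs from the corrected base
    seq[p - 6] = str(rng.choice(["A", "G", "T"]))   # corrected -> C
    seq[p - 3] = str(rng.choice(["A", "C", "T"]))   # corrected -> G
    seq[p] = layout.scid_mut_base
    seq = "".join(seq)

    diag_subs = ((p - 6, seq[p - 6], "C"), (p - 3, seq[p - 3], "G"))
    ctx = {
        "corrected_subs": {p - 6: "C", p - 3: "G", p: layout.scid_wt_base},
        "recurrent_deletion": del_,
    }
    protected = set(range(p - 7, p + 1)) | set(range(cw[0], cw[1]))
    engineered_start = p - 7
    seq = _scrub(seq, ctx, protected, engineered_start, del_)

    # store the recurrent deletion at its canonical (left-aligned) start so
    # the simulator and the classifier's indel normalisation agree on it
    canon = canonical_deletion(seq, del_[0], del_[1])
    if canon <= p or canon + del_[1] <= cw[0]:
        raise ReferenceConstructionError(
            "recurrent deletion left-aligns outside the cleavage region")
    del_ = (canon, del_[1])

    ref = AmpliconReference(
        sequence=seq,
        scid_pos=p,
        scid_wt_base=layout.scid_wt_base,
        scid_mut_base=layout.scid_mut_base,
        cleavage_window=cw,
        diag_subs=diag_subs,
        bsawi_span=bsawi_span,
        recurrent_deletion=del_,
        label=label,
        meta={"seed": seed, "length": length, "rng": "numpy-PCG64"},
    )
    return ref


def _scrub(seq: str, ctx: dict, protected: set[int], engineered_start: int,
           del_: tuple[int, int]) -> str:
    """Remove stray WCCGGW occurrences by mutating one base per occurrence."""
    k = len(BSAWI_PATTERN)
    # base that breaks the pattern at each offset
    breaker = {0: "C", 1: "A", 2: "A", 3: "A", 4: "A", 5: "C"}
    ds, dl = del_
    for _ in range(200):
        offending: int | None = None     # reference coordinate to mutate
        off_j: int | None = None         # offset within the pattern
        for mol_idx, mol in enumerate(_scrub_targets(seq, ctx)):
            deleted = mol_idx >= 2
            corrected = mol_idx in (1, 3)
            for s in find_recognition_sites(mol):
                # map molecule coordinate back to reference coordinate
                coords = [(c + dl if (deleted and c >= ds) else c) for c in range(s, s + k)]
                if corrected and coords[0] == engineered_start:
                    continue  # the one allowed site
                cand = [(c, j) for j, c in enumerate(coords) if c not in protected]
                if not cand:
                    raise ReferenceConstructionError(
                        "cannot scrub a BsaWI occurrence overlapping protected features")
                offending, off_j = cand[0]
                break
            if offending is not None:
                break
        if offending is None:
            return seq
        chars = list(seq)
        chars[offending] = breaker[off_j]
        seq = "".join(chars)
    raise ReferenceConstructionError("failed to build a reference free of stray BsaWI sites")


# ---------------------------------------------------------------------------
# I/O: FASTA + JSON sidecar

def write_reference(ref: AmpliconReference, fasta_path: str | Path) -> Path:
    """Write the reference FASTA (SCID allele) and its JSON coordinate sidecar."""
    fasta_path = Path(fasta_path)
    rec = SeqRecord(Seq(ref.sequence), id=ref.label, description="SCID allele amplicon")
    with open(fasta_path, "w") as fh:
        SeqIO.write([rec], fh, "fasta")
    sidecar = {
        "label": ref.label,
        "scid_pos": ref.scid_pos,
        "scid_wt_base": ref.scid_wt_base,
        "scid_mut_base": ref.scid_mut_base,
        "cleavage_window": list(ref.cleavage_window),
        "diag_subs": [list(t) for t in ref.diag_subs],
        "bsawi_span": list(ref.bsawi_span),
        "recurrent_deletion": list(ref.recurrent_deletion),
        "coordinate_convention": "0-based half-open",
        "meta": ref.meta,
    }
    sidecar_path = fasta_path.with_suffix(fasta_path.suffix + ".json")
    sidecar_path.write_text(json.dumps(sidecar, indent=2) + "\n")
    return sidecar_path


def load_reference(fasta_path: str | Path) -> AmpliconReference:
    fasta_path = Path(fasta_path)
    rec = next(SeqIO.parse(str(fasta_path), "fasta"))
    sidecar_path = fasta_path.with_suffix(fasta_path.suffix + ".json")
    sc = json.loads(sidecar_path.read_text())
    return AmpliconReference(
        sequence=str(rec.seq).upper(),
        scid_pos=sc["scid_pos"],
        scid_wt_base=sc["scid_wt_base"],
        scid_mut_base=sc["scid_mut_base"],
        cleavage_window=tuple(sc["cleavage_window"]),
        diag_subs=tuple(tuple(t) for t in sc["diag_subs"]),
        bsawi_span=tuple(sc["bsawi_span"]),
        recurrent_deletion=tuple(sc["recurrent_deletion"]),
        label=sc.get("label", rec.id),
        meta=sc.get("meta", {}),
    )
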