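#!/usr/bin/env python
"""Build the annotated amplicon reference used by every later step.

The amplicon models a 1,626-bp region around a T->A stop point mutation:
a 5-bp nuclease cleavage window starting 32 nt downstream of the mutation,
two silent substitutions 3 and 6 bp upstream that (with the reverted
mutation) engineer a diagnostic WCCGGW restriction site, and a fixed
recurrent 44-bp deletion centred on the cleavage window.  Writes
results/ref.fa plus its JSON coordinate sidecar and prints the feature map.
"""

import argparse
from pathlib import Path

from editcall import build_reference, make_allele, find_recognition_sites, \
    write_reference

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=7)
    args = ap.parse_args()

    ref = build_reference(length=1626, seed=args.seed)
    out = ROOT / "results" / "ref.fa"
    out.parent.mkdir(exist_ok=True)
    sidecar = write_reference(ref, out)

    corrected = make_allele(ref, "CORRECTED").sequence
    print(f"amplicon length        : {ref.length} bp")
    print(f"point mutation         : position {ref.scid_pos} "
          f"({ref.scid_wt_base}->{ref.scid_mut_base})")
    print(f"cleavage window        : {ref.cleavage_window} "
          f"({ref.cleavage_window[0] - ref.scid_pos} nt downstream)")
    print(f"diagnostic subs        : {[d[0] for d in ref.diag_subs]}")
    print(f"engineered site        : {find_recognition_sites(corrected)} "
          f"(span {ref.bsawi_span}); unedited allele has "
          f"{len(find_recognition_sites(ref.sequence))} sites")
    print(f"recurrent deletion     : start {ref.recurrent_deletion[0]}, "
          f"length {ref.recurrent_deletion[1]} bp")
    print(f"wrote {out} and {sidecar}")


if __name__ == "__main__":
    main()
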