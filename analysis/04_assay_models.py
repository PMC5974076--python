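#!/usr/bin/env python
"""In-silico gel assays on the simulated samples.

BsaWI RFLP: digest the zfn_donor read pool; only corrected molecules carry
the engineered site, so the digested fraction quantifies total HDR.
Surveyor (Cel-I): reanneal a pool with the zfn sample's indel fraction and
invert the cleaved-duplex fraction back to an indel estimate.
Writes results/assays.json.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from editcall import (build_reference, digest_pool, make_heteroduplex_pool,
                      read_fastq, surveyor_estimate)

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=42)
    args = ap.parse_args()
    build_reference(length=1626, seed=7)   # fail early if model invalid
    out = {}

    fq = ROOT / "scratch" / "zfn_donor.fastq"
    if not fq.exists():
        raise SystemExit(f"{fq} missing -- run 02_simulate_samples.py first")
    seqs = [s for _, s, _ in read_fastq(fq)]
    truth = pd.read_csv(ROOT / "scratch" / "zfn_donor.truth.tsv", sep="\t")
    res = digest_pool(seqs)
    truth_hdr = truth.category.isin(["HDR_CORRECTED", "HDR_WITH_INDEL"]).mean()
    out["bsawi"] = {"digested_fraction": res.digested_fraction,
                    "truth_hdr_fraction": float(truth_hdr),
                    "n_molecules": res.n_molecules}
    print(f"BsaWI digest: {100 * res.digested_fraction:.2f}% cut "
          f"(truth HDR incl. indel-associated: {100 * truth_hdr:.2f}%)")

    p = 0.18
    k = 40
    fractions = {"WT": 1 - p, **{f"mut{i}": p / k for i in range(k)}}
    pool = make_heteroduplex_pool(fractions, 30_000, seed=args.seed)
    f_hat = float(pool.cleavable.mean())
    est = surveyor_estimate(f_hat)
    out["surveyor"] = {"true_indel_fraction": p,
                       "cleaved_fraction": est.cleaved_fraction,
                       "estimated_indel_fraction": est.estimated_indel_fraction,
                       "n_duplexes": len(pool)}
    print(f"Surveyor: cleaved {100 * f_hat:.2f}% -> indel estimate "
          f"{100 * est.estimated_indel_fraction:.2f}% (true {100 * p:.0f}%)")

    path = ROOT / "results" / "assays.json"
    path.parent.mkdir(exist_ok=True)
    path.write_text(json.dumps(out, indent=2) + "\n")
    print(f"wrote {path}")


if __name__ == "__main__":
    main()
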