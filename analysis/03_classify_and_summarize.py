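#!/usr/bin/env python
"""Classify the simulated samples and summarise editing outcomes.

Reads the FASTQ files produced by 02_simulate_samples.py, aligns each read
to the unedited allele, classifies it (WT / NHEJ indel / corrected /
corrected-with-indel / unclassified) and writes, per sample:
  scratch/<name>.calls.tsv          per-read calls
  results/<name>.summary.json       editing frequencies
  results/<name>.spectrum.tsv       deletion spectrum
and prints the headline percentages, checking them against truth.
"""

import json
from pathlib import Path

import pandas as pd

from editcall import (build_reference, classify_sample, calls_to_frame,
                      read_fastq, summarize_sample)

ROOT = Path(__file__).resolve().parents[1]
SAMPLES = ["mock", "zfn", "zfn_donor"]


def main():
    ref = build_reference(length=1626, seed=7)
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    for name in SAMPLES:
        fq = ROOT / "scratch" / f"{name}.fastq"
        if not fq.exists():
            raise SystemExit(f"{fq} missing -- run 02_simulate_samples.py first")
        reads = read_fastq(fq)
        calls = classify_sample(reads, ref)
        summary = summarize_sample(calls, label=name)
        calls_to_frame(calls).to_csv(ROOT / "scratch" / f"{name}.calls.tsv",
                                     sep="\t", index=False)
        (results / f"{name}.summary.json").write_text(
            json.dumps(summary.to_dict(), indent=2) + "\n")
        summary.deletion_spectrum.to_csv(results / f"{name}.spectrum.tsv",
                                         sep="\t", index=False)
        truth = pd.read_csv(ROOT / "scratch" / f"{name}.truth.tsv", sep="\t")
        truth_indel = 100 * truth.category.isin(["NHEJ_INDEL", "HDR_WITH_INDEL"]).mean()
        print(f"{name}: indels {summary.pct_indels}% (truth {truth_indel:.2f}%), "
              f"corrected {summary.pct_corrected}%, "
              f"with-indel share {summary.pct_correction_with_indel_of_total_correction}%")
        if not summary.deletion_spectrum.empty:
            top = summary.deletion_spectrum.iloc[0]
            print(f"    top deletion: {int(top.del_length)} bp "
                  f"({100 * top.share:.1f}% of deletions, recurrent={bool(top.recurrent)})")


if __name__ == "__main__":
    main()
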