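# editcall

Amplicon deep-sequencing analysis of targeted gene editing: per-read
classification of editing outcomes (NHEJ indels vs HDR correction),
sample-level editing frequencies, off-target differential statistics, and
in-silico models of the two classic gel assays (mismatch-nuclease
"Surveyor" cleavage and diagnostic RFLP digestion).

The package models a zinc-finger-nuclease correction experiment at a
*Prkdc* amplicon: cells carry a T→A stop point mutation (the *scid*
allele); the nuclease cuts 32 nt downstream of it; a repair template
reverts the mutation and installs two silent substitutions 3 and 6 bp
upstream, which together engineer a diagnostic BsaWI site (`WCCGGW`)
ending 2 nt upstream of the mutated base. Reads are therefore classified
by two orthogonal signatures:

* **NHEJ indel** — a length-changing operation (insertion or deletion)
  that involves any base of the nuclease cleavage window; a fixed
  recurrent 44-bp deletion spanning the window is tracked explicitly.
* **HDR correction** — all 3 diagnostic substitutions present
  (1 reverting the point mutation + 2 creating the BsaWI site).
  Correction can co-occur with a cleavage-window indel; the headline
  correction frequency excludes such indel-associated events, and their
  share of total correction is reported separately.

Because no raw reads are publicly deposited for this experimental system,
the package includes a first-class read simulator with ground-truth labels
(`editcall.simulate`), so every stage is testable end to end.

## The statistics in brief

For a sample with `n` filter-passing reads and per-category counts `k_c`:

    %indels     = 100 · (k_NHEJ + k_HDR+indel) / n
    %corrected  = 100 · k_HDR / n                    (excludes indel-associated)
    with-indel share = 100 · k_HDR+indel / (k_HDR + k_HDR+indel)

Off-target activity at a site is the differential of indel percentages,
`Δ = %indels(treated) − %indels(mock)`, rounded half-away-from-zero to two
decimals and propagating ND (not determined); aggregates (mean, min, max)
pool non-ND off-target sites.

The Surveyor model: denature/reanneal a pool with mutant fraction `p`
(mutants pairwise distinct), so the cleavable heteroduplex fraction is
`f = 1 − (1−p)² − p²/k → 1 − (1−p)²`, inverted as `p̂ = 1 − √(1−f)`.
The RFLP model cuts each molecule at every `WCCGGW` occurrence; only
corrected molecules carry the engineered site.

## Worked example

```
python analysis/01_build_reference.py
python analysis/02_simulate_samples.py
python analysis/03_classify_and_summarize.py
python analysis/04_assay_models.py
python analysis/05_offtarget_differentials.py
```

Step 03 prints, for 10,000 simulated reads per sample:

```
mock: indels 0.0% (truth 0.00%), corrected 0.0%, with-indel share 0.0%
zfn: indels 18.31% (truth 18.31%), corrected 0.0%, with-indel share 0.0%
    top deletion: 44 bp (59.7% of deletions, recurrent=True)
zfn_donor: indels 18.21% (truth 18.21%), corrected 1.44%, with-indel share 11.11%
    top deletion: 44 bp (58.5% of deletions, recurrent=True)
```

i.e. the classifier recovers the simulated nuclease sample's 18% indel
rate exactly, calls 1.44% of the donor-treated sample cleanly corrected
(truth 1.53% minus sampling noise), attributes 11.11% of total correction
to indel-associated events, and identifies the 44-bp recurrent deletion as
the dominant spectrum entry. Step 05 re-derives every treated-minus-mock
differential in the bundled per-site indel tables and prints the pooled
off-target aggregate:

```
cells not reproduced within 0.01: 0
pooled off-target aggregate: mean 0.03%, range -0.88% to 1.34% over 36 sites
```

The same functionality is exposed as a CLI (`editcall make-ref`,
`simulate`, `classify`, `digest`, `surveyor`, `offtarget`); run
`editcall --help`.

## Layout

* `src/editcall/` — library: `reference` (annotated amplicon model),
  `simulate` (ground-truth read generator, heteroduplex pool), `classify`
  (alignment, quality filter, outcome calls, summaries, deletion
  spectrum), `assays` (RFLP digest, Surveyor arithmetic), `offtarget`
  (differentials, aggregates, bundled tables), `cli`.
* `analysis/` — numbered narrative drivers writing to `results/`.
* `docs/methods.md` — model, parameters, and design notes.
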