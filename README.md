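# wgsqc

Quality assessment of whole-genome tumour/normal sequence pairs.

When cancer genomes are sequenced at different centres, over several
years and under evolving protocols, their quality varies in ways that
bias somatic-mutation calling. `wgsqc` computes a non-redundant set of
five quality-control measures on a matched normal/tumour pair of
aligned reads (coordinate-sorted, indexed BAMs against a shared
reference FASTA), thresholds each one, and summarises the pair as a
0–5 star rating in half-star steps. A built-in synthetic-data
generator produces reference genomes and BAM pairs with ground-truthed
quality defects, so the whole pipeline is testable offline.

All measures exclude duplicate reads, reads with mapping quality zero,
and supplementary/secondary alignments, and are restricted to the
autosomes plus X and Y (naming dialect auto-detected).

## The five measures

1. **Mean coverage** — mean number of filtered reads covering each
   position whose reference base is known:
   `C̄ = (1/n) Σᵢ xᵢ`, with `xᵢ` the read depth at position `i` and `n`
   the number of non-N included positions. Pass: ≥ 25× normal, ≥ 30×
   tumour.
2. **Evenness of coverage** — two complementary statistics on 10 kb
   windowed, total-coverage-normalized read counts:
   *MoM*, the median over the mean of the window counts (1.0 = even;
   pass inside 0.99–1.06 for the normal, 0.92–1.09 for the tumour; the
   5 Mb-window MoM is also reported as a diagnostic), and *FWHM*, the
   full width at half maximum of the kernel density of GC-corrected
   coverage over the main copy-number state (pass ≤ 0.20 normal,
   ≤ 0.34 tumour). The GC correction is a two-step lowess fit of
   normalized coverage against window GC: the first fit, on all
   windows, identifies the main copy-number state (the residual-density
   main peak); the second, on those windows only, is the correction
   function. This makes FWHM insensitive to both GC bias and
   copy-number aberrations.
3. **Somatic-mutation-calling coverage** — the number of positions
   jointly covered by ≥ 8 filtered reads in the normal and ≥ 14 in the
   tumour, the depths a somatic caller needs to attempt a call. Pass:
   ≥ 2.6 Gb on a human genome, expressed by default as the equivalent
   fraction (2.6 Gb of the 2,835,690,481 uniquely mappable bases of a
   female genome ≈ 0.917) so that any reference size works.
4. **Paired reads mapping to different chromosomes** — the percentage
   of paired, both-ends-mapped reads on included chromosomes whose mate
   maps to a different chromosome. Genuine rearrangements stay well
   under 1%; an excess indicates library chimeras. Pass: ≤ 3%.
5. **Ratio of difference in edits between paired reads** —
   `max(Σ r1_edits, Σ r2_edits) / min(Σ r1_edits, Σ r2_edits)`, where an
   edit is a read base differing from the reference (substitutions
   only, counted from the MD tag, or NM minus CIGAR indel bases).
   Sequencing-cycle damage inflates one side. Pass: ratio < 2.

**Star rating.** Per measure: 1 star if both samples pass, ½ if only
the normal passes, 0 otherwise; the joint callable measure awards 1 or
0. The normal is weighted because nothing biological excuses a failing
normal. Total 0–5; a low rating is a result, not an error.

## Worked example

`examples/rate_a_pair.py` simulates the default synthetic pair
(two 1 Mb contigs, 30× normal / 35× tumour, 1% chimeric pairs,
balanced 0.002 per-base mismatch rates) and rates it:

```
mean_coverage normal[mean_coverage=30.06] pass(normal=True, tumour=True) stars=1.0
evenness      normal[mom_10kb=0.9999, mom_5mb=1, fwhm=0.04462] pass(normal=True, tumour=True) stars=1.0
callable      normal[callable_bases=1.992e+06, callable_fraction=0.9998] pass(normal=True, tumour=True) stars=1.0
interchrom    normal[interchrom_pct=0.9932] pass(normal=True, tumour=True) stars=1.0
edit_ratio    normal[edit_ratio=1.006, r1_edits=5.971e+04, r2_edits=6.006e+04] pass(normal=True, tumour=True) stars=1.0
total stars: 5.0  (5.0 = both samples pass every measure)
```

Mean coverage lands on the 30× target, MoM on 1.0, FWHM at the
counting-noise floor, the chimera estimate on the injected 1%, and the
edit ratio on 1 — a clean pair, 5.0 stars. The other examples
demonstrate the GC-bias correction (`gc_bias_correction.py`: an
injected ±20% GC trend inflates uncorrected FWHM to 0.26; correction
returns it to 0.048) and recovery of a two-fold edit imbalance
(`edit_imbalance.py`).

For real data there is an equivalent CLI:

```
wgsqc run --normal normal.bam --tumour tumour.bam --reference ref.fa --out qc/
wgsqc simulate --seed 7 --out simdir/
wgsqc annotate-vcf --vcf calls.vcf --report qc/qc_report.tsv --out calls.qc.vcf
```

`run` writes a one-row TSV report with every raw value, pass flag and
star; `annotate-vcf` embeds the rating as a single header line before
`#CHROM`. Thresholds can be overridden with a flat YAML file
(`--thresholds`), and `--clip-overlaps` counts mate-overlapping
positions once for short-insert protocols.

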