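"""Inject a GC-dependent coverage bias and watch the correction remove it.

Simulates one sample with a monotone GC-efficiency curve spanning about
+-20% across the observed GC range, fits the two-step lowess model and
compares the FWHM of the coverage density before and after correction.
Uncorrected FWHM is inflated by the GC trend; corrected FWHM returns to
the counting-noise floor (compare with the clean sample), which is why
the evenness measure is insensitive to GC bias.
"""

import dataclasses
import tempfile

from wgsqc import (
    DEFAULT_POLICY,
    bin_coverage,
    build_grid,
    correct_coverage,
    fit_gc_bias,
    fwhm_of_main_state,
    load_reference_index,
)
from wgsqc.synthetic import SimulationSpec, linear_gc_bias, make_reference, simulate_sample

with tempfile.TemporaryDirectory() as work:
    base = SimulationSpec(seed=3, interchrom_rate=0.0, duplicate_rate=0.0,
                          mapq0_rate=0.0, supplementary_rate=0.0)
    biased = dataclasses.replace(base, gc_bias=linear_gc_bias(1.33, center=0.43))
    fasta = f"{work}/reference.fa"
    make_reference(base, fasta)
    ref = load_reference_index(fasta)
    grid = build_grid(ref, 10_000)

    for label, spec in (("clean", base), ("gc-biased", biased)):
        bam = f"{work}/{label}.bam"
        simulate_sample(spec, fasta, bam, target_depth=20.0, sample=label)
        profile = bin_coverage(bam, DEFAULT_POLICY, grid)
        model = fit_gc_bias(profile)
        corrected = correct_coverage(profile, model)
        before = fwhm_of_main_state(profile.normalized[profile.retained],
                                    model.main_state_mask)
        after = fwhm_of_main_state(corrected, model.main_state_mask)
        print(f"{label:10s} FWHM uncorrected={before:.4f}  corrected={after:.4f}")

    print("\nThe biased sample's uncorrected FWHM is several-fold larger; "
          "after correction both samples sit at the same noise floor "
          "(threshold for a normal sample: 0.20).")
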