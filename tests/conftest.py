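"""Shared fixtures: hand-built toy BAMs and session-scoped simulations."""

import dataclasses

import pysam
import pytest

from wgsqc import (
    DEFAULT_POLICY,
    ReadRecord,
    bin_coverage,
    build_grid,
    correct_coverage,
    fit_gc_bias,
    fwhm_of_main_state,
    load_reference_index,
)
from wgsqc.synthetic import (
    CopySegment,
    SimulationSpec,
    linear_gc_bias,
    make_reference,
    simulate_pair,
    simulate_sample,
)


def write_bam(path, contig_lengths, rows):
    """Write a coordinate-sorted, indexed BAM from row dicts.

    Each row: contig, pos, and optionally qname, flag, mapq, cigar,
    seq, mate_contig, mate_pos, tags (dict).
    """
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": n, "LN": ln} for n, ln in contig_lengths.items()],
    }
    path = str(path)
    unsorted = path + ".unsorted.bam"
    with pysam.AlignmentFile(unsorted, "wb", header=header) as out:
        for i, row in enumerate(rows):
            a = pysam.AlignedSegment(out.header)
            a.query_name = row.get("qname", f"r{i}")
            a.flag = row.get("flag", 0)
            a.reference_id = out.header.get_tid(row["contig"])
            a.reference_start = row["pos"]
            a.mapping_quality = row.get("mapq", 60)
            cigar = row.get("cigar", "100M")
            a.cigarstring = cigar
            qlen = a.infer_query_length() or 0
            a.query_sequence = row.get("seq", "A" * qlen)
            if "mate_contig" in row:
                a.next_reference_id = out.header.get_tid(row["mate_contig"])
                a.next_reference_start = row.get("mate_pos", row["pos"])
            else:
                a.next_reference_id = -1
            for tag, val in row.get("tags", {}).items():
                a.set_tag(tag, val)
            out.write(a)
    pysam.sort("-o", path, unsorted)
    pysam.index(path)
    import os
    os.remove(unsorted)
    return path


def write_fasta(path, contigs):
    """Write a FASTA (+ index) from {name: sequence}."""
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n{seq}\n")
    pysam.faidx(str(path))
    return str(path)


def make_record(**kwargs) -> ReadRecord:
    """A ReadRecord with sensible defaults, for stream-level tests."""
    defaults = dict(
        query_name="q", contig="1", start=0, end=100, mapq=60,
        is_paired=True, is_read1=True, is_read2=False, is_duplicate=False,
        is_supplementary=False, is_secondary=False, is_unmapped=False,
        mate_unmapped=False, cigar=((0, 100),), edit_distance=None,
        mismatch_string=None, mate_contig="1",
    )
    defaults.update(kwargs)
    return ReadRecord(**defaults)


@pytest.fixture(scope="session")
def sim_root(tmp_path_factory):
    return tmp_path_factory.mktemp("sims")


@pytest.fixture(scope="session")
def default_pair(sim_root):
    """The default-condition tumour/normal simulation (30x/35x, 2 x 1 Mb)."""
    spec = SimulationSpec(seed=42)
    out = sim_root / "default_pair"
    normal_bam, tumour_bam, manifest = simulate_pair(spec, out)
    ref = load_reference_index(out / "reference.fa")
    return {
        "spec": spec,
        "normal_bam": normal_bam,
        "tumour_bam": tumour_bam,
        "manifest": manifest,
        "ref": ref,
    }


@pytest.fixture(scope="session")
def default_pair_metrics(default_pair):
    from wgsqc.pipeline import compute_sample_metrics

    normal, normal_depth = compute_sample_metrics(
        default_pair["normal_bam"], default_pair["ref"])
    tumour, tumour_depth = compute_sample_metrics(
        default_pair["tumour_bam"], default_pair["ref"])
    return {"normal": normal, "tumour": tumour,
            "normal_depth": normal_depth, "tumour_depth": tumour_depth}


def _gc_case(spec, fasta, grid, bam_path, *, depth, segs=(), tag="s"):
    gt = simulate_sample(spec, fasta, bam_path, target_depth=depth,
                         copy_segments=segs, sample=tag)
    profile = bin_coverage(bam_path, DEFAULT_POLICY, grid)
    model = fit_gc_bias(profile)
    corrected = correct_coverage(profile, model)
    return {
        "ground_truth": gt,
        "profile": profile,
        "model": model,
        "corrected": corrected,
        "fwhm": fwhm_of_main_state(corrected, model.main_state_mask),
        "fwhm_uncorrected": fwhm_of_main_state(
            profile.normalized[profile.retained], model.main_state_mask),
    }


@pytest.fixture(scope="session")
def gc_lab(sim_root):
    """Matched simulations on one reference: clean, GC-biased, aneuploid.

    All three share seed and genome so FWHM comparisons isolate the
    injected defect.  The bias spans roughly +-20% across the observed
    GC range; the copy segment puts 20% of the genome at copy ratio 2.
    """
    out = sim_root / "gc_lab"
    out.mkdir()
    base = SimulationSpec(seed=11, interchrom_rate=0.0, duplicate_rate=0.0,
                          mapq0_rate=0.0, supplementary_rate=0.0)
    fasta = str(out / "reference.fa")
    make_reference(base, fasta)
    ref = load_reference_index(fasta)
    grid = build_grid(ref, 10_000)
    depth = 20.0
    bias = linear_gc_bias(1.33, center=0.43)
    biased_spec = dataclasses.replace(base, gc_bias=bias)
    return {
        "ref": ref,
        "grid": grid,
        "bias": bias,
        "clean": _gc_case(base, fasta, grid, str(out / "clean.bam"),
                          depth=depth, tag="clean"),
        "biased": _gc_case(biased_spec, fasta, grid, str(out / "biased.bam"),
                           depth=depth, tag="biased"),
        "cna": _gc_case(base, fasta, grid, str(out / "cna.bam"), depth=depth,
                        segs=(CopySegment("1", 0, 400_000, 2.0),), tag="cna"),
    }


@pytest.fixture(scope="session")
def imbalanced_sample(sim_root):
    """Default-scale sample with a two-fold read-1/read-2 mismatch imbalance."""
    out = sim_root / "imbalanced"
    out.mkdir()
    spec = SimulationSpec(seed=42, r1_mismatch_rate=0.004, r2_mismatch_rate=0.002)
    fasta = str(out / "reference.fa")
    make_reference(spec, fasta)
    bam = str(out / "sample.bam")
    gt = simulate_sample(spec, fasta, bam, target_depth=30.0, sample="imb")
    return {"spec": spec, "bam": bam, "ref": load_reference_index(fasta),
            "ground_truth": gt}


@pytest.fixture(scope="session")
def defect_invariance_pair(sim_root):
    """The same sample simulated without and with injected defect reads.

    Same seed and base parameters; only the duplicate/MAPQ-0/
    supplementary rates differ, so the policy-filtered read content is
    identical by construction.
    """
    out = sim_root / "defects"
    out.mkdir()
    base = SimulationSpec(seed=5, normal_depth=15.0,
                          duplicate_rate=0.0, mapq0_rate=0.0,
                          supplementary_rate=0.0)
    noisy = dataclasses.replace(base, duplicate_rate=0.2, mapq0_rate=0.05,
                                supplementary_rate=0.02)
    fasta = str(out / "reference.fa")
    make_reference(base, fasta)
    clean_bam = str(out / "clean.bam")
    noisy_bam = str(out / "noisy.bam")
    simulate_sample(base, fasta, clean_bam, target_depth=15.0, sample="s")
    simulate_sample(noisy, fasta, noisy_bam, target_depth=15.0, sample="s")
    return {"ref": load_reference_index(fasta),
            "clean_bam": clean_bam, "noisy_bam": noisy_bam}
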