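"""Synthetic reference genomes and tumour/normal read pairs with ground truth.

Generates a FASTA reference with controllable per-window GC composition
and N runs, and coordinate-sorted, indexed BAM pairs whose reads carry
correct pairing flags, NM/MD tags and injectable quality defects:
flagged duplicates, MAPQ-0 and supplementary reads, inter-chromosomal
chimeric pairs, GC-dependent coverage bias, copy-number segments in the
tumour, and asymmetric read-1/read-2 mismatch rates.  Every defect is
recorded in a :class:`GroundTruth` so each QC measure can be validated
against what was injected.

Reads are emitted as if perfectly aligned — placement is truth, there is
no aligner in the loop — because the QC consumes alignments; alignment
error is out of scope.  Defect reads (duplicates, MAPQ-0, supplementary)
are extra copies of existing fragments drawn from an independent random
stream, so the policy-filtered content of a simulation is bit-identical
across defect settings at the same seed.
"""

from __future__ import annotations

import dataclasses
import json
import os
import tempfile
from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Tuple

import numpy as np
import pysam

__all__ = [
    "ContigSpec",
    "CopySegment",
    "SimulationSpec",
    "GroundTruth",
    "linear_gc_bias",
    "make_reference",
    "simulate_sample",
    "simulate_pair",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
# substitution target: deterministic transversion/transition cycle
_SUBST = {"A": "G", "G": "A", "C": "T", "T": "C"}

_GC_BLOCK = 10_000  # GC composition varies on the analysis-window scale
_GC_BLOCK_SD = 0.08  # spread of block GC around the contig target


@dataclass(frozen=True)
class ContigSpec:
    """One synthetic contig: length, GC target, and N runs (half-open)."""

    name: str
    length: int
    gc: float = 0.41
    n_runs: tuple = ()


@dataclass(frozen=True)
class CopySegment:
    """A tumour copy-number segment; coverage scales by ``copy_ratio``."""

    contig: str
    start: int
    end: int
    copy_ratio: float


@dataclass(frozen=True)
class SimulationSpec:
    """All knobs of one synthetic tumour/normal experiment.

    Defaults describe a clean, realistically sized desk-scale pair: two
    1 Mb contigs at human-like GC with a 4 kb gap each, 100 bp paired
    reads with inserts between 200 and 800 bp, 30x normal / 35x tumour,
    a few percent of flagged duplicate and MAPQ-0 reads, 1% chimeric
    pairs and a balanced 0.002 per-base mismatch rate.
    """

    seed: int = 0
    contigs: tuple = (
        ContigSpec("1", 1_000_000, gc=0.41, n_runs=((495_000, 499_000),)),
        ContigSpec("2", 1_000_000, gc=0.45, n_runs=((495_000, 499_000),)),
    )
    read_length: int = 100
    insert_mean: float = 450.0
    insert_sd: float = 100.0
    insert_min: int = 200
    insert_max: int = 800
    normal_depth: float = 30.0
    tumour_depth: float = 35.0
    duplicate_rate: float = 0.05
    mapq0_rate: float = 0.02
    supplementary_rate: float = 0.01
    interchrom_rate: float = 0.01
    r1_mismatch_rate: float = 0.002
    r2_mismatch_rate: float = 0.002
    gc_bias: Optional[Callable[[np.ndarray], np.ndarray]] = None
    copy_segments: tuple = ()  # applied to the tumour sample only

    def __post_init__(self):
        for rate in (self.duplicate_rate, self.mapq0_rate, self.supplementary_rate,
                     self.interchrom_rate, self.r1_mismatch_rate, self.r2_mismatch_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if self.normal_depth <= 0 or self.tumour_depth <= 0:
            raise ValueError("target depth must be positive")
        for seg in self.copy_segments:
            if seg.copy_ratio <= 0:
                raise ValueError("copy_ratio must be positive")
        if self.insert_min < 2 * self.read_length:
            raise ValueError("insert_min below twice the read length "
                             "would overlap the mates")


def linear_gc_bias(slope: float, center: float = 0.40,
                   floor: float = 0.2) -> Callable[[np.ndarray], np.ndarray]:
    """Monotone GC-efficiency curve: 1 + slope * (gc - center), floored."""

    def bias(gc):
        return np.maximum(1.0 + slope * (np.asarray(gc, dtype=float) - center), floor)

    bias.label = f"linear(slope={slope}, center={center})"
    return bias


@dataclass
class GroundTruth:
    """What was actually injected into one simulated sample."""

    sample: str
    target_depth: float
    n_fragments: int
    n_chimeric_pairs: int
    r1_mismatch_total: int
    r2_mismatch_total: int
    # per 10 kb window, in grid order over the spec's contigs
    window_contig: list
    window_start: list
    window_gc: list
    window_copy_ratio: list
    window_weight: list  # copy_ratio x gc_bias = expected relative coverage
    window_fragments: list  # realized fragment count per window

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _rng_streams(seed: int, salt: int):
    ss = np.random.SeedSequence([seed, salt])
    frag_ss, mm_ss, extra_ss, ref_ss = ss.spawn(4)
    return (np.random.default_rng(frag_ss), np.random.default_rng(mm_ss),
            np.random.default_rng(extra_ss), np.random.default_rng(ref_ss))


def make_reference(spec: SimulationSpec, fasta_path) -> None:
    """Write a deterministic FASTA (+ .fai) for the spec's contigs.

    Each contig is built from 10 kb blocks whose GC targets are drawn
    around the contig target and recentred so they average to it
    exactly; N runs then overwrite the specified intervals.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7]))
    with open(fasta_path, "w") as fh:
        for contig in spec.contigs:
            n_blocks = -(-contig.length // _GC_BLOCK)
            block_gc = rng.normal(contig.gc, _GC_BLOCK_SD, n_blocks)
            # recentre over the bases that survive the N runs, so the
            # known-base GC of the contig hits the target
            survive = np.zeros(n_blocks)
            for b in range(n_blocks):
                s, e = b * _GC_BLOCK, min((b + 1) * _GC_BLOCK, contig.length)
                n_over = sum(max(0, min(e, ne) - max(s, ns))
                             for ns, ne in contig.n_runs)
                survive[b] = (e - s) - n_over
            if survive.sum() > 0:
                block_gc += contig.gc - np.average(block_gc, weights=survive)
            block_gc = np.clip(block_gc, 0.05, 0.95)
            seq = np.empty(contig.length, dtype=np.uint8)
            for b in range(n_blocks):
                s = b * _GC_BLOCK
                e = min(s + _GC_BLOCK, contig.length)
                g = block_gc[b]
                p = [(1 - g) / 2, g / 2, g / 2, (1 - g) / 2]
                seq[s:e] = rng.choice(_BASES, size=e - s, p=p)
            for s, e in contig.n_runs:
                if not (0 <= s < e <= contig.length):
                    raise ValueError(f"N run ({s}, {e}) outside contig {contig.name}")
                seq[s:e] = ord("N")
            fh.write(f">{contig.name}\n")
            text = seq.tobytes().decode("ascii")
            for i in range(0, len(text), 60):
                fh.write(text[i:i + 60] + "\n")
    pysam.faidx(str(fasta_path))


def _window_table(spec: SimulationSpec, seqs: dict, copy_segments):
    """Per-10kb-window contig, start, gc, copy ratio and sampling weight."""
    rows = []
    segs = list(copy_segments)
    for contig in spec.contigs:
        arr = seqs[contig.name]
        is_gc = (arr == ord("G")) | (arr == ord("C"))
        is_n = arr == ord("N")
        for s in range(0, contig.length, _GC_BLOCK):
            e = min(s + _GC_BLOCK, contig.length)
            known = (e - s) - int(is_n[s:e].sum())
            gc = float(is_gc[s:e].sum()) / known if known else 0.0
            mid = (s + e) // 2
            cr = 1.0
            for seg in segs:
                if seg.contig == contig.name and seg.start <= mid < seg.end:
                    cr = seg.copy_ratio
            rows.append((contig.name, s, e, gc, cr))
    contigs = [r[0] for r in rows]
    starts = np.array([r[1] for r in rows])
    ends = np.array([r[2] for r in rows])
    gcs = np.array([r[3] for r in rows])
    crs = np.array([r[4] for r in rows])
    bias = spec.gc_bias(gcs) if spec.gc_bias is not None else np.ones(len(gcs))
    return contigs, starts, ends, gcs, crs, crs * bias


def _mismatch_read(seq: str, positions, rl: int):
    """Apply substitutions; returns (seq, NM, MD, realized count)."""
    chars = list(seq)
    hit = []
    for p in sorted(positions):
        ref = chars[p]
        if ref == "N":
            continue  # no defined substitution against an unknown base
        chars[p] = _SUBST[ref]
        hit.append((p, ref))
    if not hit:
        return seq, 0, str(rl), 0
    md = []
    prev = 0
    for p, ref in hit:
        md.append(f"{p - prev}{ref}")
        prev = p + 1
    md.append(str(rl - prev))
    return "".join(chars), len(hit), "".join(md), len(hit)


def simulate_sample(spec: SimulationSpec, fasta_path, bam_path, *,
                    target_depth: float, copy_segments: Sequence[CopySegment] = (),
                    sample: str = "normal", salt: int = 0) -> GroundTruth:
    """Simulate one sample's coordinate-sorted, indexed BAM.

    Fragment counts per 10 kb window are Poisson with mean
    ``depth * window / (2 * read_length)`` scaled by the window's
    copy ratio and GC efficiency; fragment starts are uniform within the
    window.  Deterministic given (spec.seed, salt).
    """
    rng_frag, rng_mm, rng_extra, _ = _rng_streams(spec.seed, salt)
    rl = spec.read_length
    names = [c.name for c in spec.contigs]
    lengths = {c.name: c.length for c in spec.contigs}
    seqs_str = {}
    seqs = {}
    with pysam.FastaFile(str(fasta_path)) as fa:
        for name in names:
            s = fa.fetch(name).upper()
            seqs_str[name] = s
            seqs[name] = np.frombuffer(s.encode("ascii"), dtype=np.uint8)

    w_contig, w_start, w_end, w_gc, w_cr, w_weight = _window_table(
        spec, seqs, copy_segments)
    expected = target_depth * (w_end - w_start) * w_weight / (2 * rl)
    counts = rng_frag.poisson(expected)
    n_frag = int(counts.sum())
    if n_frag < 1000:
        raise ValueError(
            f"only {n_frag} fragments; depth/length too small for a meaningful sample"
        )

    frag_contig = np.repeat(np.arange(len(counts)), counts)
    starts = np.repeat(w_start, counts) + (
        rng_frag.random(n_frag) * np.repeat(w_end - w_start, counts)
    ).astype(np.int64)
    contig_idx = {n: i for i, n in enumerate(names)}
    frag_cname = np.array([w_contig[w] for w in frag_contig], dtype=object)
    frag_clen = np.array([lengths[c] for c in frag_cname])

    inserts = np.clip(
        np.rint(rng_frag.normal(spec.insert_mean, spec.insert_sd, n_frag)),
        spec.insert_min, spec.insert_max,
    ).astype(np.int64)
    over = starts + inserts > frag_clen
    starts[over] = frag_clen[over] - inserts[over]

    chimeric = rng_frag.random(n_frag) < spec.interchrom_rate
    if chimeric.any() and len(names) < 2:
        raise ValueError("chimeric pairs need at least two contigs")
    mate_cname = frag_cname.copy()
    mate_pos = starts + inserts - rl
    if chimeric.any():
        idx = np.nonzero(chimeric)[0]
        for i in idx:
            own = contig_idx[frag_cname[i]]
            other = names[(own + int(rng_frag.integers(1, len(names)))) % len(names)]
            mate_cname[i] = other
            mate_pos[i] = int(rng_frag.integers(0, lengths[other] - rl))

    n1 = rng_mm.binomial(rl, spec.r1_mismatch_rate, n_frag)
    n2 = rng_mm.binomial(rl, spec.r2_mismatch_rate, n_frag)

    def _positions(n):
        if n == 1:
            return [int(rng_mm.integers(0, rl))]
        return list(rng_mm.choice(rl, size=n, replace=False))

    dup = rng_extra.random(n_frag) < spec.duplicate_rate
    mq0 = rng_extra.random(n_frag) < spec.mapq0_rate
    supp = rng_extra.random(n_frag) < spec.supplementary_rate

    r1_total = r2_total = 0
    window_frag = counts.astype(int)

    tmpdir = tempfile.mkdtemp(prefix="wgsqc_sim_")
    sam_path = os.path.join(tmpdir, "unsorted.sam")
    try:
        with open(sam_path, "w") as sam:
            sam.write("@HD\tVN:1.6\tSO:unknown\n")
            for name in names:
                sam.write(f"@SQ\tSN:{name}\tLN:{lengths[name]}\n")
            cigar = f"{rl}M"
            for i in range(n_frag):
                qname = f"{sample}_frag{i}"
                cname = frag_cname[i]
                p1 = int(starts[i])
                mc = mate_cname[i]
                p2 = int(mate_pos[i])
                seq1 = seqs_str[cname][p1:p1 + rl]
                seq2 = seqs_str[mc][p2:p2 + rl]
                if n1[i]:
                    seq1, nm1, md1, hits = _mismatch_read(seq1, _positions(n1[i]), rl)
                    r1_total += hits
                else:
                    nm1, md1 = 0, str(rl)
                if n2[i]:
                    seq2, nm2, md2, hits = _mismatch_read(seq2, _positions(n2[i]), rl)
                    r2_total += hits
                else:
                    nm2, md2 = 0, str(rl)
                if chimeric[i]:
                    f1, f2, tlen = 97, 145, 0
                else:
                    f1, f2, tlen = 99, 147, int(inserts[i])
                line1 = (f"{qname}\t{{flag}}\t{cname}\t{p1 + 1}\t{{mapq}}\t{cigar}\t"
                         f"{'=' if mc == cname else mc}\t{p2 + 1}\t{tlen}\t{seq1}\t*\t"
                         f"NM:i:{nm1}\tMD:Z:{md1}\n")
                line2 = (f"{qname}\t{{flag}}\t{mc}\t{p2 + 1}\t{{mapq}}\t{cigar}\t"
                         f"{'=' if mc == cname else cname}\t{p1 + 1}\t{-tlen}\t{seq2}\t*\t"
                         f"NM:i:{nm2}\tMD:Z:{md2}\n")
                sam.write(line1.format(flag=f1, mapq=60))
                sam.write(line2.format(flag=f2, mapq=60))
                if dup[i]:
                    sam.write(line1.replace(qname, qname + "d", 1).format(
                        flag=f1 | 0x400, mapq=60))
                    sam.write(line2.replace(qname, qname + "d", 1).format(
                        flag=f2 | 0x400, mapq=60))
                if mq0[i]:
                    sam.write(line1.replace(qname, qname + "m", 1).format(
                        flag=f1, mapq=0))
                    sam.write(line2.replace(qname, qname + "m", 1).format(
                        flag=f2, mapq=0))
                if supp[i]:
                    sam.write(line1.format(flag=f1 | 0x800, mapq=60))
        pysam.sort("-o", str(bam_path), "-O", "bam", sam_path)
        pysam.index(str(bam_path))
    finally:
        if os.path.exists(sam_path):
            os.remove(sam_path)
        os.rmdir(tmpdir)

    return GroundTruth(
        sample=sample,
        target_depth=target_depth,
        n_fragments=n_frag,
        n_chimeric_pairs=int(chimeric.sum()),
        r1_mismatch_total=r1_total,
        r2_mismatch_total=r2_total,
        window_contig=list(w_contig),
        window_start=[int(x) for x in w_start],
        window_gc=[float(x) for x in w_gc],
        window_copy_ratio=[float(x) for x in w_cr],
        window_weight=[float(x) for x in w_weight],
        window_fragments=[int(x) for x in window_frag],
    )


def simulate_pair(spec: SimulationSpec, out_dir) -> Tuple[str, str, dict]:
    """Reference + normal/tumour BAMs + ground-truth manifest in ``out_dir``.

    The tumour applies the spec's copy segments and tumour depth; the
    normal is diploid everywhere.  Returns (normal_bam, tumour_bam,
    manifest dict); the manifest is also written as ground_truth.json.
    """
    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    fasta = os.path.join(out_dir, "reference.fa")
    make_reference(spec, fasta)
    normal_bam = os.path.join(out_dir, "normal.bam")
    tumour_bam = os.path.join(out_dir, "tumour.bam")
    gt_normal = simulate_sample(spec, fasta, normal_bam,
                                target_depth=spec.normal_depth,
                                sample="normal", salt=0)
    gt_tumour = simulate_sample(spec, fasta, tumour_bam,
                                target_depth=spec.tumour_depth,
                                copy_segments=spec.copy_segments,
                                sample="tumour", salt=1)
    manifest = {
        "seed": spec.seed,
        "reference": fasta,
        "parameters": {
            k: v for k, v in dataclasses.asdict(spec).items()
            if k not in ("contigs", "copy_segments", "gc_bias")
        },
        "gc_bias": getattr(spec.gc_bias, "label", None) if spec.gc_bias else None,
        "contigs": [dataclasses.asdict(c) for c in spec.contigs],
        "copy_segments": [dataclasses.asdict(s) for s in spec.copy_segments],
        "normal": gt_normal.to_dict(),
        "tumour": gt_tumour.to_dict(),
    }
    with open(os.path.join(out_dir, "ground_truth.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    return normal_bam, tumour_bam, manifest
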