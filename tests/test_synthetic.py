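"""The synthetic reference and read-pair generator itself."""

import numpy as np
import pysam
import pytest

from wgsqc.pair_integrity import _md_substitutions
from wgsqc.synthetic import (
    ContigSpec,
    SimulationSpec,
    make_reference,
    simulate_sample,
)

SMALL = SimulationSpec(
    seed=3,
    contigs=(ContigSpec("A", 120_000, gc=0.40, n_runs=((50_000, 62_000),)),
             ContigSpec("B", 100_000, gc=0.50)),
    interchrom_rate=0.02,
)


def gc_fraction(seq):
    known = [b for b in seq if b != "N"]
    return sum(b in "GC" for b in known) / len(known)


@pytest.fixture(scope="module")
def small_sim(tmp_path_factory):
    out = tmp_path_factory.mktemp("small_sim")
    fasta = str(out / "ref.fa")
    make_reference(SMALL, fasta)
    bam = str(out / "s.bam")
    gt = simulate_sample(SMALL, fasta, bam, target_depth=10.0, sample="s")
    return {"fasta": fasta, "bam": bam, "gt": gt, "dir": out}


class TestMakeReference:
    def test_gc_targets_met(self, small_sim):
        with pysam.FastaFile(small_sim["fasta"]) as fa:
            for contig in SMALL.contigs:
                gc = gc_fraction(fa.fetch(contig.name))
                assert abs(gc - contig.gc) < 0.02

    def test_n_runs_exact(self, small_sim):
        with pysam.FastaFile(small_sim["fasta"]) as fa:
            seq = fa.fetch("A")
        assert set(seq[50_000:62_000]) == {"N"}
        assert "N" not in seq[:50_000] and "N" not in seq[62_000:]
        known = sum(b != "N" for b in seq)
        assert known == 120_000 - 12_000

    def test_same_seed_identical_bytes(self, small_sim, tmp_path):
        other = tmp_path / "again.fa"
        make_reference(SMALL, other)
        with open(small_sim["fasta"], "rb") as a, open(other, "rb") as b:
            assert a.read() == b.read()

    def test_infeasible_n_run_rejected(self, tmp_path):
        bad = SimulationSpec(contigs=(ContigSpec("A", 1000, n_runs=((900, 1200),)),))
        with pytest.raises(ValueError, match="N run"):
            make_reference(bad, tmp_path / "bad.fa")


def fetch_all(bam_path):
    with pysam.AlignmentFile(bam_path) as bam:
        return [
            (r.query_name, r.flag, r.reference_name, r.reference_start,
             r.next_reference_name, r.next_reference_start,
             r.get_tag("NM"), r.get_tag("MD"), r.query_sequence)
            for r in bam.fetch()
        ]


class TestSimulateSample:
    def test_deterministic_under_seed(self, small_sim, tmp_path):
        bam2 = str(tmp_path / "again.bam")
        gt2 = simulate_sample(SMALL, small_sim["fasta"], bam2,
                              target_depth=10.0, sample="s")
        assert gt2 == small_sim["gt"]
        assert fetch_all(bam2) == fetch_all(small_sim["bam"])

    def test_nm_matches_md_and_reference(self, small_sim):
        with pysam.FastaFile(small_sim["fasta"]) as fa:
            seqs = {n: fa.fetch(n) for n in fa.references}
        checked = 0
        for r in pysam.AlignmentFile(small_sim["bam"]).fetch():
            nm, md = r.get_tag("NM"), r.get_tag("MD")
            assert nm == _md_substitutions(md)
            ref = seqs[r.reference_name][r.reference_start:r.reference_end]
            mismatches = sum(a != b for a, b in zip(r.query_sequence, ref))
            assert mismatches == nm
            checked += 1
        assert checked > 1000

    def test_mate_fields_reciprocal(self, small_sim):
        primary = {}
        for r in pysam.AlignmentFile(small_sim["bam"]).fetch():
            if r.is_supplementary or r.is_duplicate:
                continue
            primary.setdefault(r.query_name, []).append(r)
        for qname, pair in primary.items():
            assert len(pair) == 2, qname
            r1 = next(r for r in pair if r.is_read1)
            r2 = next(r for r in pair if r.is_read2)
            assert r1.next_reference_name == r2.reference_name
            assert r1.next_reference_start == r2.reference_start
            assert r2.next_reference_name == r1.reference_name
            assert r2.next_reference_start == r1.reference_start

    def test_chimeric_pairs_cross_contigs(self, small_sim):
        gt = small_sim["gt"]
        cross = 0
        for r in pysam.AlignmentFile(small_sim["bam"]).fetch():
            if r.is_read1 and not (r.is_duplicate or r.is_supplementary) \
                    and r.mapping_quality > 0 and not r.query_name.endswith("m"):
                if r.next_reference_name != r.reference_name:
                    cross += 1
                    assert not r.is_proper_pair
        assert cross == gt.n_chimeric_pairs > 0

    def test_zero_chimera_rate_means_none(self, tmp_path):
        import dataclasses
        spec = dataclasses.replace(SMALL, interchrom_rate=0.0)
        bam = str(tmp_path / "clean.bam")
        make_reference(spec, tmp_path / "r.fa")
        gt = simulate_sample(spec, tmp_path / "r.fa", bam, target_depth=10.0)
        assert gt.n_chimeric_pairs == 0
        for r in pysam.AlignmentFile(bam).fetch():
            assert r.next_reference_name == r.reference_name

    def test_realized_window_fragments_track_expectation(self, small_sim):
        gt = small_sim["gt"]
        counts = np.array(gt.window_fragments, dtype=float)
        weights = np.array(gt.window_weight)
        rl, depth = SMALL.read_length, gt.target_depth
        expected = depth * 10_000 * weights / (2 * rl)
        # Poisson: every window within 5 SD of its mean
        sd = np.sqrt(expected)
        assert np.all(np.abs(counts - expected) <= 5 * np.maximum(sd, 1))

    def test_mismatch_totals_near_injected_rates(self, small_sim):
        gt = small_sim["gt"]
        # substitutions landing on N reference bases are skipped, so the
        # expectation scales by the known-base fraction of the genome
        genome = sum(c.length for c in SMALL.contigs)
        n_bases = sum(e - s for c in SMALL.contigs for s, e in c.n_runs)
        known_frac = 1 - n_bases / genome
        lam1 = gt.n_fragments * SMALL.read_length * SMALL.r1_mismatch_rate * known_frac
        lam2 = gt.n_fragments * SMALL.read_length * SMALL.r2_mismatch_rate * known_frac
        assert abs(gt.r1_mismatch_total - lam1) <= 3 * np.sqrt(lam1)
        assert abs(gt.r2_mismatch_total - lam2) <= 3 * np.sqrt(lam2)

    def test_too_few_fragments_rejected(self, tmp_path):
        tiny = SimulationSpec(contigs=(ContigSpec("A", 25_000),
                                       ContigSpec("B", 25_000)))
        make_reference(tiny, tmp_path / "r.fa")
        with pytest.raises(ValueError, match="fragments"):
            simulate_sample(tiny, tmp_path / "r.fa", str(tmp_path / "t.bam"),
                            target_depth=0.5)
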