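"""Reading alignments, the read-exclusion policy, and per-position depth.

All QC measures operate on the same filtered view of a coordinate-sorted,
indexed BAM: duplicate reads, reads with mapping quality zero, and
supplementary/secondary alignments are discarded, and only reads mapped to
the included chromosomes (by default the autosomes plus X and Y) are
considered.  Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterator, Optional, Sequence

import numpy as np
import pysam
from pyfaidx import Fasta

__all__ = [
    "FilterPolicy",
    "ReadRecord",
    "ReferenceIndex",
    "DEFAULT_POLICY",
    "load_reference_index",
    "filtered_reads",
    "depth_vector",
]

# chromosome naming dialects tried in order when auto-detecting the
# included set; first dialect with any match wins
_HUMAN_CHROMS = [str(c) for c in range(1, 23)] + ["X", "Y"]
_DIALECTS = (_HUMAN_CHROMS, ["chr" + c for c in _HUMAN_CHROMS])


@dataclass(frozen=True)
class FilterPolicy:
    """Which reads are excluded before any measure is computed.

    The defaults reproduce the standard policy for pan-cancer WGS QC:
    no duplicates, no MAPQ-0 reads, no supplementary (or secondary)
    alignments.  ``clip_mate_overlaps`` additionally counts a position
    covered by both mates of one pair only once in depth; it is off by
    default because large-insert protocols rarely produce overlapping
    mates, but short-insert libraries should enable it to avoid inflating
    coverage.
    """

    exclude_duplicates: bool = True
    exclude_mapq_zero: bool = True
    exclude_supplementary: bool = True
    exclude_secondary: bool = True
    exclude_unmapped: bool = True
    clip_mate_overlaps: bool = False

    def passes(self, read: "pysam.AlignedSegment") -> bool:
        if self.exclude_unmapped and read.is_unmapped:
            return False
        if self.exclude_duplicates and read.is_duplicate:
            return False
        if self.exclude_mapq_zero and read.mapping_quality == 0:
            return False
        if self.exclude_supplementary and read.is_supplementary:
            return False
        if self.exclude_secondary and read.is_secondary:
            return False
        return True


DEFAULT_POLICY = FilterPolicy()


@dataclass
class ReadRecord:
    """Minimal view of one aligned read, detached from the BAM backend."""

    query_name: str
    contig: str
    start: int
    end: int  # half-open end of the reference-consumed span
    mapq: int
    is_paired: bool
    is_read1: bool
    is_read2: bool
    is_duplicate: bool
    is_supplementary: bool
    is_secondary: bool
    is_unmapped: bool
    mate_unmapped: bool
    cigar: tuple
    edit_distance: Optional[int] = None  # NM tag
    mismatch_string: Optional[str] = None  # MD tag
    mate_contig: Optional[str] = None

    @classmethod
    def from_pysam(cls, read: pysam.AlignedSegment) -> "ReadRecord":
        try:
            nm = read.get_tag("NM")
        except KeyError:
            nm = None
        try:
            md = read.get_tag("MD")
        except KeyError:
            md = None
        mate = None
        if read.is_paired and not read.mate_is_unmapped:
            mate = read.next_reference_name
        return cls(
            query_name=read.query_name,
            contig=read.reference_name,
            start=read.reference_start,
            end=read.reference_end,
            mapq=read.mapping_quality,
            is_paired=read.is_paired,
            is_read1=read.is_read1,
            is_read2=read.is_read2,
            is_duplicate=read.is_duplicate,
            is_supplementary=read.is_supplementary,
            is_secondary=read.is_secondary,
            is_unmapped=read.is_unmapped,
            mate_unmapped=bool(read.is_paired and read.mate_is_unmapped),
            cigar=tuple(read.cigartuples or ()),
            edit_distance=nm,
            mismatch_string=md,
            mate_contig=mate,
        )


class ReferenceIndex:
    """Contig names, lengths and known-base (non-N) counts of a reference.

    ``included_contigs`` is the ordered subset of contigs every measure is
    restricted to.  When not given it is auto-detected: human autosomes
    1-22 plus X and Y in whichever naming dialect ("1" or "chr1") the
    FASTA uses; if neither dialect matches, all contigs are included
    (non-human or synthetic references).
    """

    def __init__(self, fasta_path: str | os.PathLike,
                 included_contigs: Optional[Sequence[str]] = None):
        self.fasta_path = str(fasta_path)
        if not os.path.exists(self.fasta_path):
            raise FileNotFoundError(self.fasta_path)
        self._fasta = Fasta(self.fasta_path, as_raw=True, sequence_always_upper=True)
        self.contig_names: tuple = tuple(self._fasta.keys())
        self.lengths: dict = {c: len(self._fasta[c]) for c in self.contig_names}
        for c, n in self.lengths.items():
            if n == 0:
                raise ValueError(f"contig {c!r} has zero length")
        if included_contigs is None:
            included_contigs = self._detect_included()
        else:
            missing = set(included_contigs) - set(self.contig_names)
            if missing:
                raise ValueError(f"included contigs absent from FASTA: {sorted(missing)}")
        self.included_contigs: tuple = tuple(included_contigs)
        self._known_cache: dict = {}

    def _detect_included(self) -> list:
        present = set(self.contig_names)
        for dialect in _DIALECTS:
            hits = [c for c in dialect if c in present]
            if hits:
                return hits
        return list(self.contig_names)

    def sequence(self, contig: str) -> str:
        return str(self._fasta[contig][:])

    def known_mask(self, contig: str) -> np.ndarray:
        """Boolean array, True where the reference base is not N."""
        if contig not in self._known_cache:
            seq = np.frombuffer(self.sequence(contig).encode("ascii"), dtype=np.uint8)
            self._known_cache[contig] = seq != ord("N")
        return self._known_cache[contig]

    def known_bases(self, contig: str) -> int:
        return int(self.known_mask(contig).sum())

    @property
    def total_known_bases(self) -> int:
        return sum(self.known_bases(c) for c in self.included_contigs)


def load_reference_index(fasta_path, included_contigs=None) -> ReferenceIndex:
    """Open a FASTA (building a .fai if needed) and index its contigs."""
    return ReferenceIndex(fasta_path, included_contigs)


def _open_bam(bam_path) -> pysam.AlignmentFile:
    bam = pysam.AlignmentFile(str(bam_path), "rb")
    if not bam.has_index():
        bam.close()
        raise ValueError(
            f"{bam_path}: no index found; input must be coordinate-sorted and indexed"
        )
    return bam


def filtered_reads(bam_path, policy: FilterPolicy = DEFAULT_POLICY,
                   contigs: Optional[Sequence[str]] = None) -> Iterator[ReadRecord]:
    """Stream policy-passing reads on the given contigs, in coordinate order."""
    with _open_bam(bam_path) as bam:
        header_contigs = set(bam.references)
        if contigs is None:
            contigs = bam.references
        for contig in contigs:
            if contig not in header_contigs:
                raise ValueError(f"contig {contig!r} absent from BAM header")
            for read in bam.fetch(contig):
                if policy.passes(read):
                    yield ReadRecord.from_pysam(read)


def depth_vector(bam_path, policy: FilterPolicy = DEFAULT_POLICY,
                 contigs: Optional[Sequence[str]] = None) -> dict:
    """Per-position filtered read depth, one int32 array per contig.

    A read covers the positions its CIGAR consumes on the reference
    (M/=/X/D), i.e. ``reference_start`` to ``reference_end``.  With
    ``clip_mate_overlaps`` the overlap of the two mates of a pair is
    counted once.
    """
    with _open_bam(bam_path) as bam:
        header = {name: length for name, length in zip(bam.references, bam.lengths)}
        if contigs is None:
            contigs = bam.references
        depths = {}
        for contig in contigs:
            if contig not in header:
                raise ValueError(f"contig {contig!r} absent from BAM header")
            n = header[contig]
            diff = np.zeros(n + 1, dtype=np.int32)
            pending: dict = {}
            for read in bam.fetch(contig):
                if not policy.passes(read):
                    continue
                s, e = read.reference_start, read.reference_end
                diff[s] += 1
                diff[e] -= 1
                if policy.clip_mate_overlaps and read.is_paired \
                        and not read.mate_is_unmapped \
                        and read.next_reference_name == contig:
                    if read.query_name in pending:
                        ms, me = pending.pop(read.query_name)
                        os_, oe = max(s, ms), min(e, me)
                        if os_ < oe:  # subtract doubly counted overlap
                            diff[os_] -= 1
                            diff[oe] += 1
                    else:
                        pending[read.query_name] = (s, e)
            depths[contig] = np.cumsum(diff[:-1], dtype=np.int32)
    return depths
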