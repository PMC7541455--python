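"""Paired-read discordance measures.

Two statistics on the filtered read stream of one sample:

* the percentage of paired reads whose mate maps to a different
  chromosome (restricted to the included chromosomes, both ends mapped) —
  an excess indicates library chimeras rather than genuine rearrangement;
* the imbalance between the total mismatch ("edit") counts of read 1 and
  read 2 across the whole dataset, max over min — sequencing-cycle damage
  shows up as a ratio well above 1.

An edit is a read base that differs from the reference (a substitution);
indels are not edits.  Per-read edits come from the MD tag when present,
otherwise from NM minus the CIGAR's inserted and deleted bases.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .alignment_io import ReadRecord

__all__ = [
    "PairIntegrityMetrics",
    "count_read_edits",
    "edit_totals",
    "edit_ratio",
    "interchrom_pair_pct",
    "pair_integrity_metrics",
]

_MD_TOKEN = re.compile(r"(\d+)|(\^[A-Za-z]+)|([A-Za-z])")

# BAM CIGAR ops that insert or delete read/reference bases
_CIGAR_INS, _CIGAR_DEL = 1, 2

MAX_UNSCORED_FRACTION = 0.10


def _md_substitutions(md: str) -> int:
    """Number of substituted bases in an MD string.

    Single letters are substitutions; letters following ``^`` describe a
    deletion and are not counted.
    """
    subs = 0
    for m in _MD_TOKEN.finditer(md):
        if m.group(3):
            subs += 1
    return subs


def count_read_edits(read: ReadRecord) -> Optional[int]:
    """Substitution count for one read, or None if unscorable.

    MD is authoritative when present.  The NM fallback subtracts the
    CIGAR's total inserted and deleted bases (NM counts indel bases,
    the edit definition does not), floored at zero.
    """
    if read.mismatch_string is not None:
        return _md_substitutions(read.mismatch_string)
    if read.edit_distance is not None:
        indel = sum(length for op, length in read.cigar if op in (_CIGAR_INS, _CIGAR_DEL))
        return max(read.edit_distance - indel, 0)
    return None


@dataclass
class PairIntegrityMetrics:
    interchrom_pct: float
    r1_edits: int
    r2_edits: int
    unscored_reads: int = 0

    @property
    def edit_ratio(self) -> float:
        return edit_ratio(self.r1_edits, self.r2_edits)


def edit_totals(reads: Iterable[ReadRecord]) -> tuple:
    """Total edits for read-1 and read-2 flags over a filtered stream.

    Reads carrying neither MD nor NM are tallied as unscored and
    excluded; more than 10% unscored is an error.
    """
    r1 = r2 = 0
    scored = unscored = 0
    for read in reads:
        edits = count_read_edits(read)
        if edits is None:
            unscored += 1
            continue
        scored += 1
        if read.is_read1:
            r1 += edits
        elif read.is_read2:
            r2 += edits
    total = scored + unscored
    if total and unscored > MAX_UNSCORED_FRACTION * total:
        raise ValueError(
            f"{unscored}/{total} reads lack both NM and MD tags; cannot score edits"
        )
    return r1, r2


def edit_ratio(r1_edits: int, r2_edits: int) -> float:
    """max(r1, r2) / min(r1, r2); 1.0 is perfect balance.

    Symmetric in its arguments.  If one total is zero and the other
    positive the ratio is +inf (which fails the threshold); two zero
    totals give 1.0 by convention.
    """
    if r1_edits < 0 or r2_edits < 0:
        raise ValueError("edit totals must be non-negative")
    lo, hi = min(r1_edits, r2_edits), max(r1_edits, r2_edits)
    if hi == 0:
        return 1.0
    if lo == 0:
        return math.inf
    return hi / lo


def interchrom_pair_pct(reads: Iterable[ReadRecord], included: Sequence[str]) -> float:
    """Percent of paired reads whose mate maps to a different chromosome.

    Only reads that are paired, with both ends mapped and both contigs in
    ``included``, enter the denominator; the numerator additionally
    requires the two contigs to differ.
    """
    included_set = set(included)
    inter = eligible = 0
    for read in reads:
        if not read.is_paired or read.mate_unmapped or read.mate_contig is None:
            continue
        if read.contig not in included_set or read.mate_contig not in included_set:
            continue
        eligible += 1
        if read.contig != read.mate_contig:
            inter += 1
    if eligible == 0:
        raise ValueError("no eligible paired reads on the included contigs")
    return 100.0 * inter / eligible


def pair_integrity_metrics(reads: Iterable[ReadRecord],
                           included: Sequence[str]) -> PairIntegrityMetrics:
    """Both discordance measures in a single pass over the stream."""
    included_set = set(included)
    inter = eligible = 0
    r1 = r2 = 0
    scored = unscored = 0
    for read in reads:
        edits = count_read_edits(read)
        if edits is None:
            unscored += 1
        else:
            scored += 1
            if read.is_read1:
                r1 += edits
            elif read.is_read2:
                r2 += edits
        if read.is_paired and not read.mate_unmapped and read.mate_contig is not None \
                and read.contig in included_set and read.mate_contig in included_set:
            eligible += 1
            if read.contig != read.mate_contig:
                inter += 1
    if eligible == 0:
        raise ValueError("no eligible paired reads on the included contigs")
    total = scored + unscored
    if total and unscored > MAX_UNSCORED_FRACTION * total:
        raise ValueError(
            f"{unscored}/{total} reads lack both NM and MD tags; cannot score edits"
        )
    return PairIntegrityMetrics(
        interchrom_pct=100.0 * inter / eligible,
        r1_edits=r1,
        r2_edits=r2,
        unscored_reads=unscored,
    )
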