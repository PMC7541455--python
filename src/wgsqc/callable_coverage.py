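"""Somatic-mutation-calling coverage: jointly well-covered bases.

A somatic caller needs enough reads in both samples at a site to attempt
a call; the conventional minimum is 8 reads in the normal and 14 in the
tumour.  This module counts the reference positions meeting both depth
requirements simultaneously, over the included contigs and excluding
positions whose reference base is N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment_io import ReferenceIndex

__all__ = ["CallableResult", "callable_bases"]

DEFAULT_MIN_NORMAL_DEPTH = 8
DEFAULT_MIN_TUMOUR_DEPTH = 14
#: absolute pass threshold used for full human genomes (2.6 Gb)
DEFAULT_THRESHOLD_BASES = 2_600_000_000
#: the same threshold as a fraction of the known included genome
#: (2.6e9 over the 2,835,690,481 uniquely mappable bases of a female
#: genome), usable on references of any size
DEFAULT_THRESHOLD_FRACTION = 2_600_000_000 / 2_835_690_481


@dataclass
class CallableResult:
    callable_bases: int
    total_known_bases: int
    min_normal_depth: int = DEFAULT_MIN_NORMAL_DEPTH
    min_tumour_depth: int = DEFAULT_MIN_TUMOUR_DEPTH

    @property
    def callable_fraction(self) -> float:
        return self.callable_bases / self.total_known_bases


def callable_bases(normal_depth: dict, tumour_depth: dict, ref: ReferenceIndex,
                   min_normal_depth: int = DEFAULT_MIN_NORMAL_DEPTH,
                   min_tumour_depth: int = DEFAULT_MIN_TUMOUR_DEPTH) -> CallableResult:
    """Count positions with normal depth >= 8 and tumour depth >= 14.

    Both thresholds are inclusive.  Positions whose reference base is N
    are excluded from numerator and denominator.
    """
    count = 0
    total = 0
    for contig in ref.included_contigs:
        if contig not in normal_depth or contig not in tumour_depth:
            raise ValueError(f"missing depth vector for contig {contig!r}")
        dn = np.asarray(normal_depth[contig])
        dt = np.asarray(tumour_depth[contig])
        if len(dn) != len(dt) or len(dn) != ref.lengths[contig]:
            raise ValueError(f"mismatched position spaces on contig {contig!r}")
        mask = ref.known_mask(contig)
        count += int(((dn >= min_normal_depth) & (dt >= min_tumour_depth) & mask).sum())
        total += int(mask.sum())
    return CallableResult(
        callable_bases=count,
        total_known_bases=total,
        min_normal_depth=min_normal_depth,
        min_tumour_depth=min_tumour_depth,
    )
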