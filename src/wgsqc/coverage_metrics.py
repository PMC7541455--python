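"""Mean coverage and windowed coverage profiles.

Mean coverage is the mean filtered read depth over all included reference
positions whose base is known (not N).  Windowed profiles count filtered
reads per fixed-size window (each read assigned to the window containing
its alignment midpoint) and normalize by the genome-wide mean window
count, so 1.0 means average coverage.  The evenness statistic MoM is the
median of the window counts divided by their mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

from .alignment_io import FilterPolicy, ReferenceIndex, _open_bam

__all__ = [
    "WindowGrid",
    "CoverageProfile",
    "build_grid",
    "mean_coverage",
    "bin_coverage",
    "median_over_mean",
]

#: windows with more than this fraction of N reference bases are dropped
#: before normalization (telomere/centromere gaps would otherwise
#: contribute structural zeros)
DEFAULT_MAX_N_FRACTION = 0.5


@dataclass
class WindowGrid:
    """Fixed-size tiling of the included contigs, half-open intervals."""

    window_size: int
    contig: np.ndarray  # str per window
    start: np.ndarray
    end: np.ndarray
    gc_fraction: np.ndarray  # of known bases in the window
    n_fraction: np.ndarray

    def __len__(self) -> int:
        return len(self.start)


def build_grid(ref: ReferenceIndex, window_size: int) -> WindowGrid:
    """Tile every included contig with ``window_size`` windows.

    The last window of a contig may be shorter.  GC fraction is computed
    over the non-N bases of each window (0 for all-N windows).
    """
    contigs, starts, ends, gcs, nfracs = [], [], [], [], []
    for c in ref.included_contigs:
        seq = np.frombuffer(ref.sequence(c).encode("ascii"), dtype=np.uint8)
        length = ref.lengths[c]
        is_gc = (seq == ord("G")) | (seq == ord("C"))
        is_n = seq == ord("N")
        for s in range(0, length, window_size):
            e = min(s + window_size, length)
            n_count = int(is_n[s:e].sum())
            known = (e - s) - n_count
            gc = float(is_gc[s:e].sum()) / known if known else 0.0
            contigs.append(c)
            starts.append(s)
            ends.append(e)
            gcs.append(gc)
            nfracs.append(n_count / (e - s))
    return WindowGrid(
        window_size=window_size,
        contig=np.array(contigs, dtype=object),
        start=np.array(starts, dtype=np.int64),
        end=np.array(ends, dtype=np.int64),
        gc_fraction=np.array(gcs, dtype=float),
        n_fraction=np.array(nfracs, dtype=float),
    )


@dataclass
class CoverageProfile:
    """Per-window filtered read counts on a grid, plus normalized coverage.

    ``retained`` marks windows that survive the N-fraction cut; raw
    counts exist for every window but ``normalized`` is NaN on dropped
    windows and averages exactly 1 over retained ones.
    """

    grid: WindowGrid
    raw_count: np.ndarray
    retained: np.ndarray
    normalized: np.ndarray = field(init=False)

    def __post_init__(self):
        if not self.retained.any():
            raise ValueError("all windows dropped by the N-fraction cut")
        mean = self.raw_count[self.retained].mean()
        if mean == 0:
            raise ValueError("no reads assigned to any retained window")
        norm = np.full(len(self.raw_count), np.nan)
        norm[self.retained] = self.raw_count[self.retained] / mean
        self.normalized = norm

    def to_tsv(self, path) -> None:
        """BED-like export: contig, start, end, raw, normalized, gc."""
        g = self.grid
        with open(path, "w") as fh:
            fh.write("contig\tstart\tend\traw_count\tnormalized\tgc_fraction\n")
            for i in range(len(g)):
                fh.write(
                    f"{g.contig[i]}\t{g.start[i]}\t{g.end[i]}\t"
                    f"{self.raw_count[i]:g}\t{self.normalized[i]:.6g}\t"
                    f"{g.gc_fraction[i]:.4f}\n"
                )


def mean_coverage(depth: dict, ref: ReferenceIndex) -> float:
    """Mean depth over known (non-N) positions of the included contigs.

    Positions whose reference base is N are excluded from both the sum
    and the denominator.
    """
    total = 0.0
    n = 0
    for contig in ref.included_contigs:
        if contig not in depth:
            raise ValueError(f"no depth vector for included contig {contig!r}")
        d = depth[contig]
        if len(d) != ref.lengths[contig]:
            raise ValueError(f"depth vector length mismatch on {contig!r}")
        mask = ref.known_mask(contig)
        total += float(d[mask].sum())
        n += int(mask.sum())
    if n == 0:
        raise ValueError("reference has no known bases on the included contigs")
    return total / n


def bin_coverage(bam_path, policy: FilterPolicy, grid: WindowGrid,
                 max_n_fraction: float = DEFAULT_MAX_N_FRACTION) -> CoverageProfile:
    """Count policy-passing reads per window of ``grid``.

    Each read goes to exactly one window: the one containing the midpoint
    of its reference span, so window counts sum to the filtered read
    count.
    """
    if len(grid) == 0:
        raise ValueError("empty window grid")
    contig_order = list(dict.fromkeys(grid.contig))
    # per-contig window offset; grid windows are contiguous per contig
    offsets = {}
    for c in contig_order:
        idx = np.nonzero(grid.contig == c)[0]
        offsets[c] = int(idx[0])
    counts = np.zeros(len(grid), dtype=np.int64)
    ws = grid.window_size
    with _open_bam(bam_path) as bam:
        for c in contig_order:
            if c not in set(bam.references):
                raise ValueError(f"contig {c!r} absent from BAM header")
            off = offsets[c]
            n_windows = int((grid.contig == c).sum())
            for read in bam.fetch(c):
                if not policy.passes(read):
                    continue
                mid = (read.reference_start + read.reference_end) // 2
                w = off + min(mid // ws, n_windows - 1)
                counts[w] += 1
    retained = grid.n_fraction <= max_n_fraction
    return CoverageProfile(grid=grid, raw_count=counts.astype(float), retained=retained)


def median_over_mean(profile: CoverageProfile) -> float:
    """MoM evenness: median window count / mean window count.

    1.0 for perfectly even coverage; skewed by localized over- or
    under-coverage.  An even number of windows uses the midpoint of the
    two central values.
    """
    counts = profile.raw_count[profile.retained]
    if len(counts) < 2:
        raise ValueError("MoM needs at least 2 retained windows")
    mean = counts.mean()
    if mean == 0:
        raise ValueError("mean window count is zero")
    return float(np.median(counts) / mean)
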