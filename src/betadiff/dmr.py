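"""Per-nucleotide probability tracks for differentially methylated regions.

Instead of calling hard DMR intervals with ad-hoc minimum-length and gap
rules, each covered position carries the probability P(p1 > p2) computed by
the exact Beta method, and downstream analysis works on that track directly:
kernel smoothing at a chosen bandwidth (methylation is spatially correlated),
fixed-size window averaging, and mean probability over annotated regions.
No thresholds or boundaries are ever imposed here.

Coordinate conventions: track positions are 1-based (as in the position-file
input); intervals are half-open [start, end) in that same 1-based space;
bedGraph output converts to the format's 0-based half-open convention, and
BED3 input is converted from it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PositionTrack",
    "GenomicInterval",
    "smooth_track",
    "window_average",
    "region_mean",
    "write_bedgraph",
    "read_bed3",
]

#: Gaussian kernel weights are truncated beyond this many bandwidths.
KERNEL_TRUNCATION = 4.0


@dataclass(frozen=True)
class PositionTrack:
    """Probability values at sorted, unique 1-based positions on one chromosome."""

    chrom: str
    positions: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.int64)
        val = np.asarray(self.values, dtype=float)
        if pos.size == 0:
            raise ValueError("track must contain at least one position")
        if pos.size != val.size:
            raise ValueError("positions and values must have equal length")
        if pos[0] < 1:
            raise ValueError("positions are 1-based: minimum allowed is 1")
        if pos.size > 1 and not (np.diff(pos) > 0).all():
            raise ValueError("positions must be strictly increasing")
        if ((val < 0.0) | (val > 1.0)).any():
            raise ValueError("track values must lie in [0, 1]")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "values", val)

    def __len__(self) -> int:
        return int(self.positions.size)


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval [start, end) in the track's 1-based coordinate space."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (self.end > self.start >= 0):
            raise ValueError(
                f"interval requires end > start >= 0, got [{self.start}, {self.end})"
            )


def smooth_track(track: PositionTrack, bandwidth: float) -> PositionTrack:
    """Gaussian-kernel (Nadaraya–Watson) smoothing over genomic distance.

    Each output value is the kernel-weighted average of the input values at
    covered positions within ``KERNEL_TRUNCATION`` bandwidths, evaluated at
    the input positions themselves.  No imputation at uncovered bases.  Every
    output lies within [min, max] of its contributing inputs, so the [0, 1]
    range is preserved.
    """
    if bandwidth <= 0:
        raise ValueError(f"bandwidth must be positive, got {bandwidth}")
    pos = track.positions.astype(float)
    val = track.values
    radius = KERNEL_TRUNCATION * bandwidth
    out = np.empty_like(val)
    lo = np.searchsorted(pos, pos - radius, side="left")
    hi = np.searchsorted(pos, pos + radius, side="right")
    inv2 = 1.0 / (2.0 * bandwidth * bandwidth)
    for i in range(pos.size):
        d = pos[lo[i]:hi[i]] - pos[i]
        w = np.exp(-d * d * inv2)
        out[i] = np.dot(w, val[lo[i]:hi[i]]) / w.sum()
    return PositionTrack(track.chrom, track.positions.copy(), np.clip(out, 0.0, 1.0))


def window_average(track: PositionTrack, window: int) -> PositionTrack:
    """Clump consecutive covered positions into fixed-size block averages.

    Non-overlapping blocks of ``window`` consecutive covered positions are
    replaced by a single entry at the block's first position carrying the
    block mean; a trailing partial block is averaged over its own size, so
    the total sum(mean * block size) is conserved.
    """
    if window < 1 or not float(window).is_integer():
        raise ValueError(f"window must be a positive integer, got {window}")
    window = int(window)
    if window == 1:
        return track
    n = len(track)
    starts = np.arange(0, n, window)
    new_pos = track.positions[starts]
    new_val = np.array([
        track.values[s:s + window].mean() for s in starts
    ])
    return PositionTrack(track.chrom, new_pos, new_val)


def region_mean(track: PositionTrack, regions) -> np.ndarray:
    """Mean track probability inside each half-open region [start, end).

    Regions with no covered positions report NaN as an explicit no-data
    marker.  Regions must be on the track's chromosome.
    """
    out = np.empty(len(regions))
    for i, region in enumerate(regions):
        if region.chrom != track.chrom:
            raise ValueError(
                f"region on {region.chrom!r} does not match track chromosome "
                f"{track.chrom!r}"
            )
        lo = np.searchsorted(track.positions, region.start, side="left")
        hi = np.searchsorted(track.positions, region.end, side="left")
        out[i] = track.values[lo:hi].mean() if hi > lo else np.nan
    return out


def write_bedgraph(track: PositionTrack, path) -> None:
    """Write the track as bedGraph (0-based half-open single-base intervals)."""
    with open(path, "w", encoding="utf-8") as fh:
        for pos, value in zip(track.positions, track.values):
            fh.write(f"{track.chrom}\t{pos - 1}\t{pos}\t{value:.6g}\n")


def read_bed3(path) -> list[GenomicInterval]:
    """Read BED3 intervals, converting 0-based half-open to the internal
    1-based half-open convention."""
    intervals = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >= 3 BED fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinates") from exc
            intervals.append(GenomicInterval(fields[0], start + 1, end + 1))
    return intervals
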