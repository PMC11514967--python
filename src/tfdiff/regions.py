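"""Contiguous-bin regions over an aligned sequence window.

Sequences are aligned so that index 0 of the window corresponds to bp
`-halfwidth` relative to the anchor point (the core-motif midpoint, or the
peak summit in skip-anchoring mode). A Region is a run of consecutive bins;
its bp_span is expressed in this anchor-relative frame.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["Region", "bin_layout", "all_contiguous_regions", "region_overlap_fraction"]


@dataclass(frozen=True)
class Region:
    first_bin: int
    last_bin: int  # inclusive
    bp_start: int  # anchor-relative, inclusive
    bp_end: int  # anchor-relative, exclusive

    @property
    def n_bins(self) -> int:
        return self.last_bin - self.first_bin + 1

    @property
    def bp_span(self) -> tuple[int, int]:
        return (self.bp_start, self.bp_end)

    def __str__(self) -> str:  # used in feature names / reports
        return f"[{self.bp_start:+d}:{self.bp_end:+d}]"


def bin_layout(seq_length: int, n_bins: int, offset: int | None = None) -> list[Region]:
    """Partition a window of `seq_length` bp into `n_bins` contiguous bins.

    Widths differ by at most 1 bp; the leading bins take the remainder
    (1000 bp / 7 bins -> six 143-bp bins then one 142-bp bin). `offset` is
    the anchor-relative coordinate of window index 0 (default -seq_length//2).
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if n_bins > seq_length:
        raise ValueError("more bins than base pairs")
    if offset is None:
        offset = -(seq_length // 2)
    base, rem = divmod(seq_length, n_bins)
    regions = []
    start = 0
    for b in range(n_bins):
        width = base + (1 if b < rem else 0)
        regions.append(Region(b, b, start + offset, start + width + offset))
        start += width
    return regions


def all_contiguous_regions(bins: list[Region]) -> list[Region]:
    """Every region made of consecutive bins: n*(n+1)/2 regions for n bins."""
    out = []
    for i in range(len(bins)):
        for j in range(i, len(bins)):
            out.append(Region(i, j, bins[i].bp_start, bins[j].bp_end))
    return out


def region_overlap_fraction(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Overlap of bp interval `a` with `b`, as a fraction of the shorter one."""
    lo = max(a[0], b[0])
    hi = min(a[1], b[1])
    inter = max(0, hi - lo)
    shorter = min(a[1] - a[0], b[1] - b[0])
    return inter / shorter if shorter > 0 else 0.0
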