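"""ChIP-seq peak sets: BED I/O, partitioning, Jaccard distance, windows.

Coordinates are 0-based half-open (BED convention) everywhere internally.
Two peaks "match" when their interval distance is at most `window_bp`
(overlap counts as distance 0) — the `bedtools window` criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Peak", "PeakSet", "PeakPartition", "read_bed", "partition_peaks",
    "jaccard_distance", "rebalance", "extract_window",
]


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int
    end: int
    summit_offset: int | None = None  # relative to start, in [0, end-start)
    name: str | None = None

    @property
    def summit(self) -> int:
        if self.summit_offset is not None:
            return self.start + self.summit_offset
        return (self.start + self.end) // 2


@dataclass
class PeakSet:
    intervals: list[Peak]
    genome_id: str = ""
    _by_chrom: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        for p in self.intervals:
            if p.start >= p.end:
                raise ValueError(f"invalid interval {p.chrom}:{p.start}-{p.end}")
            if p.summit_offset is not None and not 0 <= p.summit_offset < p.end - p.start:
                raise ValueError(f"summit outside interval {p.chrom}:{p.start}-{p.end}")
        self.intervals = sorted(self.intervals, key=lambda p: (p.chrom, p.start, p.end))
        self._by_chrom = None

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def by_chrom(self) -> dict[str, list[Peak]]:
        if self._by_chrom is None:
            d: dict[str, list[Peak]] = {}
            for p in self.intervals:
                d.setdefault(p.chrom, []).append(p)
            self._by_chrom = d
        return self._by_chrom

    def write_bed(self, path) -> None:
        with open(path, "w") as fh:
            for p in self.intervals:
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.name or '.'}\n")


@dataclass
class PeakPartition:
    unique_a: PeakSet
    unique_b: PeakSet
    common: PeakSet  # matched peaks of both experiments, merged
    window_bp: int
    n_matched_a: int = 0
    n_matched_b: int = 0


def read_bed(path, genome_id: str = "", summit_column: int | None = None) -> PeakSet:
    """Read BED3/BED6/narrowPeak intervals.

    `summit_column` (1-based; 10 for narrowPeak) names a column holding the
    summit offset from the interval start; otherwise the summit is the
    interval midpoint.
    """
    peaks = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{ln}: fewer than 3 tab-separated columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as e:
                raise ValueError(f"{path}:{ln}: non-integer coordinates") from e
            if end <= start:
                raise ValueError(f"{path}:{ln}: end <= start")
            summit = None
            if summit_column is not None and len(fields) >= summit_column:
                summit = int(fields[summit_column - 1])
                if summit < 0:  # narrowPeak convention: -1 = no summit
                    summit = None
            name = fields[3] if len(fields) > 3 else None
            peaks.append(Peak(fields[0], start, end, summit, name))
    return PeakSet(peaks, genome_id=genome_id)


def _match_mask(a: PeakSet, b: PeakSet, window_bp: int) -> np.ndarray:
    """Boolean per a-peak: does some b-peak lie within window_bp of it?"""
    out = np.zeros(len(a), dtype=bool)
    b_by = b.by_chrom()
    for chrom, peaks in a.by_chrom().items():
        bs = b_by.get(chrom, [])
        starts = np.array([p.start for p in bs])
        ends = np.array([p.end for p in bs])
        base = next(i for i, p in enumerate(a.intervals) if p.chrom == chrom)
        for k, p in enumerate(peaks):
            if len(bs):
                # distance 0 when overlapping; gap otherwise
                dist = np.maximum(0, np.maximum(starts - p.end + 1, p.start - ends + 1))
                out[base + k] = bool((dist <= window_bp).any())
    return out


def partition_peaks(a: PeakSet, b: PeakSet, window_bp: int = 1000) -> PeakPartition:
    """Split two experiments into experiment-unique and common peaks.

    A peak of A is common iff some peak of B lies within `window_bp` of it
    (and symmetrically); the unique sets are the complements. Every input
    peak lands in exactly one of {unique, matched}.
    """
    if a.genome_id != b.genome_id:
        raise ValueError(f"genome mismatch: {a.genome_id!r} vs {b.genome_id!r}")
    ma = _match_mask(a, b, window_bp)
    mb = _match_mask(b, a, window_bp)
    unique_a = PeakSet([p for p, m in zip(a.intervals, ma) if not m], a.genome_id)
    unique_b = PeakSet([p for p, m in zip(b.intervals, mb) if not m], b.genome_id)
    common = PeakSet([p for p, m in zip(a.intervals, ma) if m]
                     + [p for p, m in zip(b.intervals, mb) if m], a.genome_id)
    return PeakPartition(unique_a, unique_b, common, window_bp,
                         n_matched_a=int(ma.sum()), n_matched_b=int(mb.sum()))


def _merge_count(peaks: list[tuple[str, int, int]], window_bp: int) -> int:
    """Number of clusters after merging intervals closer than window_bp."""
    n = 0
    last_chrom, last_end = None, None
    for chrom, start, end in sorted(peaks):
        if chrom != last_chrom or start - last_end > window_bp:
            n += 1
            last_chrom, last_end = chrom, end
        else:
            last_end = max(last_end, end)
    return n


def jaccard_distance(a: PeakSet, b: PeakSet, window_bp: int = 1000) -> float:
    """1 - |A∩B| / |A∪B| counted on merged matched peaks.

    The intersection is the number of merged clusters among peaks matched
    across the two experiments; the union is the merged count of all peaks
    (mirroring a bedtools window + merge construction).
    """
    if len(a) == 0 and len(b) == 0:
        raise ValueError("Jaccard distance undefined for two empty sets")
    part = partition_peaks(a, b, window_bp)
    inter = _merge_count([(p.chrom, p.start, p.end) for p in part.common], window_bp)
    union = _merge_count([(p.chrom, p.start, p.end) for p in list(a) + list(b)], window_bp)
    return 1.0 - inter / union


def rebalance(class1: list, class2: list, seed: int) -> tuple[list, list]:
    """Randomly down-sample the larger class so both have equal size.

    The smaller class is returned unchanged; removal from the larger class is
    uniform without replacement and reproducible under `seed`. Already
    balanced inputs are returned as-is.
    """
    if not class1 or not class2:
        raise ValueError("both classes must be non-empty")
    n = min(len(class1), len(class2))
    rng = np.random.default_rng(seed)

    def sub(lst):
        if len(lst) == n:
            return lst
        keep = np.sort(rng.choice(len(lst), size=n, replace=False))
        return [lst[i] for i in keep]

    return sub(class1), sub(class2)


def extract_window(genome, chrom: str, center: int, halfwidth: int) -> str | None:
    """Uppercase genomic sequence of [center-halfwidth, center+halfwidth).

    `genome` is a pyfaidx.Fasta or any mapping of chromosome -> string.
    Returns None when the window overflows the chromosome (caller logs and
    discards); raises KeyError for an absent chromosome.
    """
    if chrom not in genome:
        raise KeyError(f"chromosome {chrom!r} absent from genome")
    ref = genome[chrom]
    length = len(ref)
    start, end = center - halfwidth, center + halfwidth
    if start < 0 or end > length:
        return None
    return str(ref[start:end]).upper()
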