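"""Nucleotidic-environment features: (k-mer, region) variables.

A sequence window is segmented into `n_bins` (default 7) near-equal bins and
a feature is the frequency of a short k-mer (2-4 bp) within a region of
consecutive bins. For each 2-mer the region of consecutive bins whose
regional frequency best discriminates the classes (folded AUROC) is found by
exhaustive enumeration of the n*(n+1)/2 contiguous regions; the 2-mer is
then iteratively extended by one nucleotide on either side, re-optimizing
the region, keeping an extension only when the folded AUROC gains at least
`min_gain`.

Counting convention: a k-mer window belongs to the bin (region) containing
its START; windows containing an N, or overflowing the sequence end, are
excluded from both numerator and denominator. The core motif must already be
masked so no feature can leak core information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .motifs import ALPHABET, AlignedSequence, encode
from .regions import Region, all_contiguous_regions, bin_layout

__all__ = ["NEFeature", "KmerRegionCounts", "kmer_frequency",
           "best_region_for_kmer", "explore_ne_features"]

_BASE_IDX = {c: i for i, c in enumerate(ALPHABET)}


@dataclass(frozen=True)
class NEFeature:
    kmer: str
    region: Region
    train_auroc: float  # folded, in [0.5, 1]

    @property
    def name(self) -> str:
        return f"NE:{self.kmer}@{self.region}"


def _kmer_id(kmer: str) -> int:
    i = 0
    for c in kmer:
        if c not in _BASE_IDX:
            raise ValueError(f"k-mer alphabet must be ACGT, got {kmer!r}")
        i = i * 4 + _BASE_IDX[c]
    return i


def _seq_strings(seqs) -> list[str]:
    return [s.seq if isinstance(s, AlignedSequence) else s for s in seqs]


class KmerRegionCounts:
    """Per-sequence, per-bin occurrence counts of every k-mer (k = 2..max_k).

    Regional frequencies for any contiguous-bin region are exact aggregates
    of the per-bin counts (windows are assigned to the bin of their start).
    """

    def __init__(self, seqs, n_bins: int = 7, max_k: int = 4, min_k: int = 2):
        strings = _seq_strings(seqs)
        if not strings:
            raise ValueError("no sequences")
        L = len(strings[0])
        if any(len(s) != L for s in strings):
            raise ValueError("sequences must share one length")
        self.n_bins = n_bins
        self.seq_length = L
        self.bins = bin_layout(L, n_bins)
        self.offset = self.bins[0].bp_start
        codes = np.stack([encode(s) for s in strings])
        n = codes.shape[0]
        # bin index of each window start
        edges = np.array([b.bp_end - self.offset for b in self.bins])
        start_bin = np.searchsorted(edges, np.arange(L), side="right")
        self.counts: dict[int, np.ndarray] = {}
        self.valid: dict[int, np.ndarray] = {}
        for k in range(min_k, max_k + 1):
            nw = L - k + 1
            ids = np.zeros((n, nw), dtype=np.int64)
            bad = np.zeros((n, nw), dtype=bool)
            for j in range(k):
                c = codes[:, j : j + nw]
                bad |= c == 4
                ids = ids * 4 + np.where(c == 4, 0, c)
            nk = 4**k
            sb = start_bin[:nw]
            flat = (np.arange(n)[:, None] * n_bins + sb[None, :]) * nk + ids
            cnt = np.bincount(flat[~bad].ravel(), minlength=n * n_bins * nk)
            self.counts[k] = cnt.reshape(n, n_bins, nk)
            v = np.zeros((n, nw), dtype=np.int64)
            v[~bad] = 1
            self.valid[k] = np.stack(
                [v[:, sb == b].sum(axis=1) for b in range(n_bins)], axis=1
            )

    def frequencies(self, kmer: str, region: Region) -> np.ndarray:
        """Per-sequence regional frequency of `kmer` (0 when no valid window)."""
        k = len(kmer)
        sl = slice(region.first_bin, region.last_bin + 1)
        num = self.counts[k][:, sl, _kmer_id(kmer)].sum(axis=1)
        den = self.valid[k][:, sl].sum(axis=1)
        return np.where(den > 0, num / np.maximum(den, 1), 0.0)

    def region_frequency_matrix(self, kmer: str) -> tuple[list[Region], np.ndarray]:
        """Frequencies of `kmer` in every contiguous region: (regions, (m, n))."""
        k = len(kmer)
        cnum = np.concatenate(
            [np.zeros((self.counts[k].shape[0], 1)),
             np.cumsum(self.counts[k][:, :, _kmer_id(kmer)], axis=1)], axis=1)
        cden = np.concatenate(
            [np.zeros((self.valid[k].shape[0], 1)),
             np.cumsum(self.valid[k], axis=1)], axis=1)
        regions = all_contiguous_regions(self.bins)
        num = np.stack([cnum[:, r.last_bin + 1] - cnum[:, r.first_bin]
                        for r in regions])
        den = np.stack([cden[:, r.last_bin + 1] - cden[:, r.first_bin]
                        for r in regions])
        return regions, np.where(den > 0, num / np.maximum(den, 1), 0.0)

    def best_region(self, kmer: str, labels) -> tuple[Region, float]:
        """Most discriminant contiguous-bin region for `kmer` (folded AUROC).

        Ties go to the widest region, then the leftmost.
        """
        from .stats import folded_auroc_rows

        regions, freqs = self.region_frequency_matrix(kmer)
        aurocs = folded_auroc_rows(freqs, labels)
        keys = [(a, r.n_bins, -r.first_bin) for a, r in zip(aurocs, regions)]
        i = max(range(len(keys)), key=keys.__getitem__)
        return regions[i], float(aurocs[i])


def kmer_frequency(seq, kmer: str, region: Region | None = None,
                   n_bins: int = 7) -> float:
    """Frequency of `kmer` among valid windows starting in `region`.

    Standalone single-sequence counterpart of KmerRegionCounts.frequencies
    (same start-in-region convention). `region=None` means the whole
    sequence.
    """
    _kmer_id(kmer)  # validate alphabet
    s = seq.seq if isinstance(seq, AlignedSequence) else seq
    L, k = len(s), len(kmer)
    if region is None:
        lo, hi = 0, L
    else:
        off = -(L // 2)
        lo, hi = region.bp_start - off, region.bp_end - off
    lo = max(lo, 0)
    hi = min(hi, L - k + 1)
    num = den = 0
    for i in range(lo, hi):
        w = s[i : i + k]
        if "N" in w:
            continue
        den += 1
        num += w == kmer
    return num / den if den else 0.0


def best_region_for_kmer(kmer: str, seqs, labels, n_bins: int = 7) -> tuple[Region, float]:
    counts = KmerRegionCounts(seqs, n_bins=n_bins, max_k=len(kmer), min_k=len(kmer))
    return counts.best_region(kmer, labels)


def explore_ne_features(seqs, labels, n_bins: int = 7, max_k: int = 4,
                        min_gain: float = 0.01, include_seeds: bool = False,
                        counts: KmerRegionCounts | None = None) -> list[NEFeature]:
    """DExTER-style exploration: 2-mer seeds, greedy extension to 4-mers.

    Must be run on the training split only, with the core motif masked.
    Returns the de-duplicated final (k-mer, region) variables; with
    `include_seeds`, every 2-mer seed variable is also kept.
    """
    labels = np.asarray(labels)
    if counts is None:
        counts = KmerRegionCounts(seqs, n_bins=n_bins, max_k=max_k)
    found: dict[tuple, NEFeature] = {}

    def record(kmer, region, a):
        key = (kmer, region.first_bin, region.last_bin)
        if key not in found or found[key].train_auroc < a:
            found[key] = NEFeature(kmer, region, a)

    for i in range(16):
        seed_kmer = ALPHABET[i // 4] + ALPHABET[i % 4]
        region, a = counts.best_region(seed_kmer, labels)
        if include_seeds:
            record(seed_kmer, region, a)
        cur_kmer, cur_region, cur_a = seed_kmer, region, a
        while len(cur_kmer) < max_k:
            best_ext = None
            for base in ALPHABET:
                for cand in (base + cur_kmer, cur_kmer + base):
                    r, ca = counts.best_region(cand, labels)
                    if best_ext is None or ca > best_ext[2]:
                        best_ext = (cand, r, ca)
            if best_ext is None or best_ext[2] < cur_a + min_gain:
                break
            cur_kmer, cur_region, cur_a = best_ext
        record(cur_kmer, cur_region, cur_a)
    return sorted(found.values(), key=lambda f: -f.train_auroc)
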