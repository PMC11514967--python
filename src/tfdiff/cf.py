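"""Co-factor features: (library PWM, region) variables via a max-lattice.

For every PWM of a motif library, each (core-masked) sequence is segmented
into `n_bins` (default 13) equal bins and the best log-odds window score per
bin is stored (window assigned to the bin holding its start; both strands;
windows with N never win). The best score over any region of consecutive
bins is then the max over its member bins — computed for all n*(n+1)/2
regions by the children-max recurrence of the region lattice. The region
whose scores best separate the classes (folded AUROC, training rows only)
defines the feature; the per-sequence feature value is the best score in
that region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .motifs import NEG_INF, PWM, AlignedSequence, encode, scan_scores
from .regions import Region, all_contiguous_regions, bin_layout
from .stats import folded_auroc

__all__ = ["CFFeature", "bin_best_scores", "lattice_region_scores",
           "best_region_for_pwm", "cf_scan_library", "BinScoreMatrix"]


@dataclass(frozen=True)
class CFFeature:
    pwm_name: str
    region: Region
    train_auroc: float  # folded

    @property
    def name(self) -> str:
        return f"CF:{self.pwm_name}@{self.region}"


def _floor_score(pwm: PWM) -> float:
    """Sentinel for bins with no valid window: below any achievable score."""
    return pwm.min_score() - 1.0


class BinScoreMatrix:
    """Per-bin best scores of one PWM over many sequences: (n_seqs, n_bins)."""

    def __init__(self, seqs, pwm: PWM, n_bins: int = 13):
        strings = [s.seq if isinstance(s, AlignedSequence) else s for s in seqs]
        L = len(strings[0])
        self.bins = bin_layout(L, n_bins)
        self.pwm = pwm
        codes = np.stack([encode(s) for s in strings])
        sc = scan_scores(codes, pwm).max(axis=-1)  # (n, n_windows) strand max
        nw = sc.shape[1]
        offset = self.bins[0].bp_start
        floor = _floor_score(pwm)
        cols = []
        for b in self.bins:
            lo, hi = b.bp_start - offset, min(b.bp_end - offset, nw)
            if hi <= lo:
                cols.append(np.full(codes.shape[0], floor))
                continue
            best = sc[:, lo:hi].max(axis=1)
            cols.append(np.where(best > NEG_INF, best, floor))
        self.scores = np.stack(cols, axis=1)

    def region_scores(self) -> dict[Region, np.ndarray]:
        return lattice_region_scores(self.scores, self.bins)


def bin_best_scores(seq, pwm: PWM, n_bins: int = 13) -> np.ndarray:
    """Best window score per bin for one sequence (see module docstring)."""
    return BinScoreMatrix([seq], pwm, n_bins=n_bins).scores[0]


def lattice_region_scores(bin_scores: np.ndarray, bins: list[Region] | None = None):
    """Best score of every contiguous-bin region, by the children-max lattice.

    `bin_scores`: (n_bins,) or (n_seqs, n_bins). A region of width w has two
    children of width w-1; its score is the max of theirs. Returns a dict
    Region -> scores, with bp spans taken from `bins` (default: unit spans).
    """
    arr = np.atleast_2d(np.asarray(bin_scores, dtype=float))
    n = arr.shape[1]
    if bins is None:
        bins = bin_layout(n, n, offset=0)
    level = {i: arr[:, i] for i in range(n)}  # width-1 nodes, keyed by first bin
    out = {Region(i, i, bins[i].bp_start, bins[i].bp_end): level[i] for i in range(n)}
    for width in range(2, n + 1):
        nxt = {}
        for i in range(n - width + 1):
            j = i + width - 1
            nxt[i] = np.maximum(level[i], level[i + 1])
            out[Region(i, j, bins[i].bp_start, bins[j].bp_end)] = nxt[i]
        level = nxt
    if np.ndim(bin_scores) == 1:
        return {r: float(v[0]) for r, v in out.items()}
    return out


def best_region_for_pwm(pwm: PWM, seqs, labels, n_bins: int = 13,
                        matrix: BinScoreMatrix | None = None) -> CFFeature:
    """Region whose per-sequence best scores best separate the classes.

    Training rows only; folded AUROC; ties widest-then-leftmost.
    """
    from .stats import folded_auroc_rows

    if matrix is None:
        matrix = BinScoreMatrix(seqs, pwm, n_bins=n_bins)
    region_scores = matrix.region_scores()
    regions = list(region_scores)
    aurocs = folded_auroc_rows(np.stack([region_scores[r] for r in regions]),
                               labels)
    keys = [(a, r.n_bins, -r.first_bin) for a, r in zip(aurocs, regions)]
    i = max(range(len(keys)), key=keys.__getitem__)
    return CFFeature(pwm.name or "pwm", regions[i], float(aurocs[i]))


def cf_scan_library(library: list[PWM], train_seqs, train_labels, all_seqs=None,
                    n_bins: int = 13, whole_sequence: bool = False,
                    ) -> tuple[list[CFFeature], np.ndarray]:
    """One (PWM, region) feature per library PWM + per-sequence columns.

    Regions are selected on `train_seqs`/`train_labels` only; feature values
    (best score in the selected region) are then computed for `all_seqs`
    (default: the training sequences). With `whole_sequence`, every region is
    forced to the lattice top (the whole window) — the position-agnostic
    TFcoop-style baseline. The target TF's own PWM may legitimately remain in
    the library. Core motifs must already be masked.
    """
    if not library:
        raise ValueError("empty PWM library")
    if all_seqs is None:
        all_seqs = train_seqs
    features, columns = [], []
    for pwm in library:
        m_train = BinScoreMatrix(train_seqs, pwm, n_bins=n_bins)
        if whole_sequence:
            top = Region(0, n_bins - 1, m_train.bins[0].bp_start, m_train.bins[-1].bp_end)
            a = folded_auroc(m_train.scores.max(axis=1), train_labels)
            feat = CFFeature(pwm.name or "pwm", top, a)
        else:
            feat = best_region_for_pwm(pwm, train_seqs, train_labels, matrix=m_train)
        features.append(feat)
        m_all = m_train if all_seqs is train_seqs else BinScoreMatrix(all_seqs, pwm, n_bins=n_bins)
        sl = slice(feat.region.first_bin, feat.region.last_bin + 1)
        columns.append(m_all.scores[:, sl].max(axis=1))
    return features, np.stack(columns, axis=1)
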