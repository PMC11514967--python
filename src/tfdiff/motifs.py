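"""Motif models: PPMs, log-odds PWMs, scanning, anchoring and simplicity.

Nucleotide order is fixed as A, C, G, T throughout (axis of length 4).
Sequences are encoded as int8 codes A=0, C=1, G=2, T=3, N(=anything else)=4;
any scan window containing an N scores -inf and can never be a best hit.

Two kinds of PWM coexist deliberately:

* scanning PWMs (log-odds of a database PPM against a background), used to
  locate the most likely binding site on each sequence, and
* discriminative PWMs (logistic-regression coefficients, see `tfdiff.dm`),
  used only to score already-aligned sites, never to scan.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace

import numpy as np

ALPHABET = "ACGT"
_CODES = np.full(256, 4, dtype=np.int8)
for _i, _c in enumerate(ALPHABET):
    _CODES[ord(_c)] = _i
    _CODES[ord(_c.lower())] = _i

NEG_INF = -1e30  # finite stand-in for -inf: safe in sums, below any real score

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string into int8 codes (A0 C1 G2 T3, other -> 4)."""
    return _CODES[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PPM:
    """Position probability matrix: probs[k, j] with columns summing to 1."""

    probs: np.ndarray  # (K, 4)
    name: str = ""

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        if p.ndim != 2 or p.shape[1] != 4:
            raise ValueError("PPM must be a K x 4 matrix")
        if (p < -1e-12).any():
            raise ValueError("PPM probabilities must be non-negative")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each PPM position must sum to 1")

    @property
    def length(self) -> int:
        return self.probs.shape[0]


@dataclass(frozen=True)
class PWM:
    """Position weight matrix: additive per-position scores weights[k, j]."""

    weights: np.ndarray  # (K, 4)
    source: str = "jaspar_logodds"  # or "discriminative"
    name: str = ""

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.ndim != 2 or w.shape[1] != 4:
            raise ValueError("PWM must be a K x 4 matrix")
        if not np.isfinite(w).all():
            raise ValueError("PWM weights must be finite")

    @property
    def length(self) -> int:
        return self.weights.shape[0]

    def reverse_complement(self) -> "PWM":
        return replace(self, weights=self.weights[::-1, ::-1])

    def max_score(self) -> float:
        return float(self.weights.max(axis=1).sum())

    def min_score(self) -> float:
        return float(self.weights.min(axis=1).sum())

    def consensus(self) -> str:
        return "".join(ALPHABET[j] for j in self.weights.argmax(axis=1))


@dataclass(frozen=True)
class MotifHit:
    offset: int  # window start relative to the scanned sequence start
    strand: str  # '+' or '-'
    score: float


@dataclass
class AlignedSequence:
    """A window aligned on its most likely binding site.

    `seq` is in motif orientation: when the best core hit was on the minus
    strand the whole window has been reverse-complemented, so anchor-relative
    positions are comparable across sequences. `core_span` is the [start, end)
    index range of the core-motif occurrence within `seq` (None in
    skip-anchoring mode).
    """

    seq: str
    label: int  # 1 = class 1, 0 = class 2
    anchor: tuple[str, int] | None = None  # (chromosome, genome coordinate)
    core_span: tuple[int, int] | None = None
    core_strand: str | None = None
    source_id: str | None = None
    _codes: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def codes(self) -> np.ndarray:
        if self._codes is None:
            self._codes = encode(self.seq)
        return self._codes


# ---------------------------------------------------------------------------
# JASPAR I/O


def read_jaspar(path_or_handle) -> list[PPM]:
    """Read JASPAR-format PFMs (counts) and normalize each column to a PPM.

    Accepts both the bracketed dialect (``A [ 3 5 0 ]``) and the plain
    4-row count dialect; parsing is delegated to Bio.motifs.
    """
    from Bio import motifs as bio_motifs

    if hasattr(path_or_handle, "read"):
        records = bio_motifs.parse(path_or_handle, "jaspar")
    else:
        with open(path_or_handle) as fh:
            records = bio_motifs.parse(fh, "jaspar")
    out = []
    for m in records:
        counts = np.array([m.counts[b] for b in ALPHABET], dtype=float).T  # (K, 4)
        sums = counts.sum(axis=1)
        if (sums <= 0).any():
            raise ValueError(f"motif {m.matrix_id or m.name}: column with zero total count")
        name = " ".join(x for x in (m.matrix_id, m.name) if x)
        out.append(PPM(counts / sums[:, None], name=name))
    if not out:
        raise ValueError("no motif found in JASPAR input")
    return out


def read_jaspar_one(path_or_handle) -> PPM:
    ppms = read_jaspar(path_or_handle)
    if len(ppms) != 1:
        raise ValueError(f"expected exactly one motif, found {len(ppms)}")
    return ppms[0]


def write_jaspar(ppm: PPM, handle, scale: float = 1.0) -> None:
    """Write a PPM in the bracketed JASPAR dialect (probabilities x scale)."""
    own = isinstance(handle, str)
    fh = open(handle, "w") if own else handle
    try:
        fh.write(f">{ppm.name or 'motif'}\n")
        for j, base in enumerate(ALPHABET):
            row = " ".join(f"{v * scale:.6f}" for v in ppm.probs[:, j])
            fh.write(f"{base} [ {row} ]\n")
    finally:
        if own:
            fh.close()


def jaspar_roundtrip(ppm: PPM) -> PPM:
    buf = io.StringIO()
    write_jaspar(ppm, buf, scale=1e6)
    buf.seek(0)
    return read_jaspar_one(buf)


# ---------------------------------------------------------------------------
# PPM -> scanning PWM, scanning, thresholds


def ppm_to_pwm(
    ppm: PPM,
    background: np.ndarray | tuple = (0.25, 0.25, 0.25, 0.25),
    pseudocount: float = 0.01,
) -> PWM:
    """Log-odds conversion: w[k,j] = log2((p + pc*bg_j) / ((1+pc)*bg_j))."""
    bg = np.asarray(background, dtype=float)
    if not math.isclose(bg.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("background must sum to 1")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if pseudocount == 0 and (ppm.probs == 0).any():
        raise ValueError("zero probability with zero pseudocount gives infinite weight")
    w = np.log2((ppm.probs + pseudocount * bg) / ((1 + pseudocount) * bg))
    return PWM(w, source="jaspar_logodds", name=ppm.name)


def _strand_scores(codes: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Scores of all windows of one strand. codes: (L,) or (n, L)."""
    K = weights.shape[0]
    w5 = np.concatenate([weights, np.full((K, 1), NEG_INF)], axis=1)  # N column
    single = codes.ndim == 1
    if single:
        codes = codes[None, :]
    L = codes.shape[1]
    nw = L - K + 1
    if nw < 1:
        raise ValueError("sequence shorter than the PWM")
    out = np.zeros((codes.shape[0], nw))
    for k in range(K):
        out += w5[k, codes[:, k : k + nw]]
    np.maximum(out, NEG_INF, out=out)  # windows with >1 N would underflow below the floor
    return out[0] if single else out


def scan_scores(codes: np.ndarray, pwm: PWM) -> np.ndarray:
    """Window scores on both strands: shape (..., n_windows, 2).

    Strand 0 is '+'; strand 1 scores the reverse complement of each window
    (equivalently: the reverse-complement PWM applied to the forward window).
    """
    fwd = _strand_scores(codes, pwm.weights)
    rev = _strand_scores(codes, pwm.weights[::-1, ::-1])
    return np.stack([fwd, rev], axis=-1)


def best_hit_scores(codes: np.ndarray, pwm: PWM) -> np.ndarray:
    """Best window score over both strands per sequence. codes: (n, L)."""
    s = scan_scores(codes, pwm)
    return s.max(axis=(-2, -1))


def score_threshold(
    pwm: PWM,
    pvalue: float = 1e-4,
    background: np.ndarray | tuple = (0.25, 0.25, 0.25, 0.25),
    precision: float = 1e-3,
) -> float:
    """Score threshold with P(score >= t) <= pvalue under a 0-order background.

    The exact null distribution of the PWM score on random sequences is
    computed by dynamic programming on weights discretized to `precision`
    (the standard FIMO/MOODS construction). Returns the smallest achievable
    threshold honoring the p-value; conservative by at most one grid step.
    """
    bg = np.asarray(background, dtype=float)
    w = np.round(pwm.weights / precision).astype(np.int64)  # (K, 4)
    mins = w.min(axis=1)
    w0 = w - mins[:, None]
    total = int(w0.max(axis=1).sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    top = 0
    for k in range(w0.shape[0]):
        new = np.zeros(total + 1)
        for j in range(4):
            s = int(w0[k, j])
            new[s : top + s + 1] += bg[j] * dist[: top + 1]
        top += int(w0[k].max())
        dist = new
    tail = np.cumsum(dist[::-1])[::-1]  # tail[s] = P(shifted score >= s)
    idx = np.searchsorted(-tail, -pvalue)  # smallest s with tail <= pvalue
    return float((idx + mins.sum()) * precision)


def scan_best_hit(
    seq: str | np.ndarray,
    pwm: PWM,
    span: tuple[int, int] | None = None,
    threshold: float | None = None,
    center: float | None = None,
) -> MotifHit | None:
    """Best PWM occurrence on either strand, or None.

    `span` restricts window starts to [lo, hi - K] with window ends <= hi
    (both relative to the sequence start). Ties are broken toward the hit
    whose midpoint is closest to `center` (default: span midpoint), then
    leftmost; '+' strand wins over '-' at exact ties. A window containing N
    scores -inf and never wins.
    """
    codes = seq if isinstance(seq, np.ndarray) else encode(seq)
    K = pwm.length
    lo, hi = (0, len(codes)) if span is None else span
    lo = max(lo, 0)
    hi = min(hi, len(codes))
    if hi - lo < K:
        raise ValueError("scan span shorter than the PWM")
    s = scan_scores(codes[lo:hi], pwm)  # (n_windows, 2)
    best = s.max()
    if best <= NEG_INF or (threshold is not None and best < threshold):
        return None
    if center is None:
        center = (lo + hi) / 2
    cand = np.argwhere(s >= best - 1e-12)
    starts = cand[:, 0] + lo
    mids = starts + (K - 1) / 2
    order = np.lexsort((cand[:, 1], starts, np.abs(mids - center)))
    w, strand = cand[order[0]]
    return MotifHit(offset=int(w + lo), strand="+-"[strand], score=float(s[w, strand]))


# ---------------------------------------------------------------------------
# Anchoring and version selection


def anchor_peak_window(
    raw_window: str,
    pwm: PWM,
    halfwidth: int = 500,
    threshold: float | None = None,
    orient: bool = True,
) -> tuple[str, tuple[int, int], str] | None:
    """Align one raw window on its best core hit.

    `raw_window` must be at least 2*halfwidth long, with the nominal summit
    at its center; the best hit within `halfwidth` of the summit anchors a
    2*halfwidth window centered on the hit midpoint. Returns
    (aligned_seq, core_span, strand) or None when no hit passes or the
    anchored window would overflow the raw window.
    """
    L = len(raw_window)
    summit = L // 2
    K = pwm.length
    lo, hi = summit - halfwidth, summit + halfwidth
    hit = scan_best_hit(raw_window, pwm, span=(max(lo, 0), min(hi, L)),
                        threshold=threshold, center=summit)
    if hit is None:
        return None
    mid = hit.offset + K // 2
    start, end = mid - halfwidth, mid + halfwidth
    if start < 0 or end > L:
        return None
    window = raw_window[start:end].upper()
    core_start = hit.offset - start
    if orient and hit.strand == "-":
        window = reverse_complement(window)
        core_start = len(window) - (core_start + K)
    return window, (core_start, core_start + K), hit.strand


def anchor_sequences(
    raw_windows: list[str],
    label: int,
    pwm: PWM,
    halfwidth: int = 500,
    threshold: float | None = None,
    orient: bool = True,
    source_ids: list | None = None,
) -> tuple[list[AlignedSequence], float]:
    """Anchor a class of raw windows; returns (aligned, dropped_fraction)."""
    out = []
    for i, w in enumerate(raw_windows):
        res = anchor_peak_window(w, pwm, halfwidth, threshold, orient)
        if res is None:
            continue
        seq, span, strand = res
        out.append(AlignedSequence(seq, label, core_span=span, core_strand=strand,
                                   source_id=None if source_ids is None else source_ids[i]))
    dropped = 1.0 - len(out) / len(raw_windows) if raw_windows else 0.0
    return out, dropped


def center_on_summit(raw_windows: list[str], label: int, halfwidth: int = 500,
                     source_ids: list | None = None) -> list[AlignedSequence]:
    """Skip-anchoring mode: keep every window, centered on the summit."""
    out = []
    for i, w in enumerate(raw_windows):
        summit = len(w) // 2
        start, end = summit - halfwidth, summit + halfwidth
        if start < 0 or end > len(w):
            continue
        out.append(AlignedSequence(w[start:end].upper(), label,
                                   source_id=None if source_ids is None else source_ids[i]))
    return out


def select_pwm_version(
    versions: list[PPM],
    windows: list[str],
    labels,
    halfwidth: int = 500,
    background=(0.25, 0.25, 0.25, 0.25),
    pseudocount: float = 0.01,
) -> tuple[int, PWM, float]:
    """Pick the motif version whose best-hit score best separates the classes.

    Each candidate PPM is converted to a log-odds PWM; per sequence the best
    window score over both strands within `halfwidth` of the summit ranks the
    sequences, and the version with the highest (folded) AUROC wins. Returns
    (index, scanning PWM, auroc). The winning AUROC doubles as the
    "original PWM" baseline of the report.
    """
    from .stats import folded_auroc

    if not versions:
        raise ValueError("empty version list")
    best = None
    for i, ppm in enumerate(versions):
        pwm = ppm_to_pwm(ppm, background, pseudocount)
        scores = []
        for w in windows:
            summit = len(w) // 2
            codes = encode(w)[max(0, summit - halfwidth): summit + halfwidth]
            scores.append(float(scan_scores(codes, pwm).max()))
        a = folded_auroc(scores, labels)
        if best is None or a > best[2]:
            best = (i, pwm, a)
    return best


# ---------------------------------------------------------------------------
# Class PPMs, masking, simplicity


def estimate_class_ppms(core_subseqs_a: list[str], core_subseqs_b: list[str],
                        pseudocount: float = 0.0) -> tuple[PPM, PPM]:
    """Per-class PPMs by per-position nucleotide frequency of the core sites.

    Emitted alongside the discriminative PWM to help interpret it. N
    positions are ignored in the counts.
    """
    lengths = {len(s) for s in list(core_subseqs_a) + list(core_subseqs_b)}
    if len(lengths) > 1:
        raise ValueError("sites must all have the same length")
    return (_ppm_from_sites(core_subseqs_a, pseudocount, "class1"),
            _ppm_from_sites(core_subseqs_b, pseudocount, "class2"))


def _ppm_from_sites(sites: list[str], pseudocount: float, name: str) -> PPM:
    if not sites:
        raise ValueError("no sites")
    K = len(sites[0])
    if any(len(s) != K for s in sites):
        raise ValueError("sites must all have the same length")
    codes = np.stack([encode(s) for s in sites])
    counts = np.zeros((K, 4)) + pseudocount
    for j in range(4):
        counts[:, j] += (codes == j).sum(axis=0)
    sums = counts.sum(axis=1)
    if (sums <= 0).any():
        raise ValueError("position with no informative nucleotide")
    return PPM(counts / sums[:, None], name=name)


def mask_core(s: AlignedSequence) -> AlignedSequence:
    """Replace the core-motif span by N's (idempotent); length unchanged."""
    if s.core_span is None:
        raise ValueError("cannot mask: sequence has no recorded core span")
    a, b = s.core_span
    masked = s.seq[:a] + "N" * (b - a) + s.seq[b:]
    return AlignedSequence(masked, s.label, s.anchor, s.core_span, s.core_strand, s.source_id)


def gini_coefficient(pwm: PWM | np.ndarray) -> float:
    """Gini coefficient of the absolute PWM weights (Lorenz construction).

    All K*4 weights are pooled, sorted by absolute value, and the discrete
    Lorenz curve of cumulative weight share vs. cumulative count share gives
    G = A / (A + B). 0 = all weights equal; -> 1 when a single weight
    carries everything. Invariant to rescaling all weights by c != 0.
    """
    w = pwm.weights if isinstance(pwm, PWM) else np.asarray(pwm, dtype=float)
    x = np.sort(np.abs(w).ravel())
    n = x.size
    total = x.sum()
    if total == 0:
        raise ValueError("Gini undefined for an all-zero PWM")
    i = np.arange(1, n + 1)
    return float(((2 * i - n - 1) * x).sum() / (n * total))
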