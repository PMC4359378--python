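"""PWM scoring and scanning at a fractional score cutoff.

A PWM is a 4 x L matrix of per-position base weights (log-odds against a
uniform background when built from counts or probabilities).  A window's
score fraction is ``(raw - score_min) / (score_max - score_min)`` where
score_min / score_max are the worst / best attainable sums; scanning
reports every window on both strands whose fraction reaches the cutoff
(default 0.85), with minus-strand hits mapped back to forward
coordinates.  Ambiguous bases (N) contribute the position minimum, i.e.
they are scored conservatively.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class MotifHit:
    seq_id: str
    position: int        # 0-based start on forward coordinates
    strand: str          # '+' or '-'
    score_fraction: float


class PWM:
    """Position weight matrix with attainable score range.

    ``matrix`` rows are A, C, G, T; columns are motif positions.
    """

    def __init__(self, matrix: np.ndarray, name: str = "pwm"):
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape[0] != 4 or matrix.shape[1] < 4:
            raise ValueError("PWM must be 4 x L with L >= 4")
        if not np.isfinite(matrix).all():
            raise ValueError("PWM weights must be finite")
        self.name = name
        self.matrix = matrix
        self.score_min = float(matrix.min(axis=0).sum())
        self.score_max = float(matrix.max(axis=0).sum())
        if self.score_min == self.score_max:
            raise ValueError("degenerate PWM: score_min equals score_max")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @classmethod
    def from_counts(cls, counts: np.ndarray, name: str = "pwm",
                    pseudocount: float = 0.25) -> "PWM":
        """Log-odds PWM from a base-count (or probability) matrix against
        a uniform background, with ``pseudocount`` added per cell."""
        counts = np.asarray(counts, dtype=float)
        probs = (counts + pseudocount) / (counts + pseudocount).sum(axis=0)
        return cls(np.log2(probs / 0.25), name=name)

    @classmethod
    def from_consensus(cls, consensus: str, name: str | None = None,
                       match_count: float = 10.0) -> "PWM":
        """PWM strongly favouring an exact consensus sequence."""
        counts = np.zeros((4, len(consensus)))
        for j, base in enumerate(consensus.upper()):
            counts[_BASE_INDEX[base], j] = match_count
        return cls.from_counts(counts, name=name or consensus)

    def reverse_complement(self) -> "PWM":
        return PWM(self.matrix[::-1, ::-1], name=f"{self.name}_rc")


def read_pwm(path) -> PWM:
    """Tabular PWM file: a header line ``>name`` then 4 labeled rows
    (A/C/G/T) of whitespace-separated weights, interpreted as counts."""
    with open(path) as fh:
        header = fh.readline().strip()
        name = header.lstrip(">").strip() or "pwm"
        rows = {}
        for line in fh:
            fields = line.split()
            if not fields:
                continue
            rows[fields[0].upper()] = [float(x) for x in fields[1:]]
    try:
        counts = np.array([rows[b] for b in BASES])
    except KeyError as exc:
        raise ValueError(f"PWM file missing row for base {exc}") from None
    return PWM.from_counts(counts, name=name)


def _encode(seq: str) -> np.ndarray:
    """ACGT -> 0..3, anything else -> 4 (scored as position minimum)."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(len(arr), 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def score_window(window: str, pwm: PWM) -> tuple[float, float]:
    """Raw score and score fraction of a single window (len == L)."""
    if len(window) != pwm.length:
        raise ValueError(f"window length {len(window)} != PWM length {pwm.length}")
    codes = _encode(window)
    mins = pwm.matrix.min(axis=0)
    raw = 0.0
    for j, c in enumerate(codes):
        raw += mins[j] if c == 4 else pwm.matrix[c, j]
    frac = (raw - pwm.score_min) / (pwm.score_max - pwm.score_min)
    return raw, frac


def _scan_one_strand(codes: np.ndarray, pwm: PWM) -> np.ndarray:
    """Score fractions for every window start (vectorized)."""
    L = pwm.length
    n = len(codes) - L + 1
    if n <= 0:
        return np.empty(0)
    mins = pwm.matrix.min(axis=0)
    padded = np.vstack([pwm.matrix, mins])  # row 4 = N scoring
    scores = np.zeros(n)
    for j in range(L):
        scores += padded[codes[j:j + n], j]
    return (scores - pwm.score_min) / (pwm.score_max - pwm.score_min)


def scan_sequence(seq: str, pwm: PWM, cutoff: float = 0.85,
                  both_strands: bool = True, seq_id: str = "") -> list[MotifHit]:
    """All motif hits with score fraction >= cutoff, sorted by position.

    Minus-strand matches are found by scanning with the
    reverse-complement PWM and reported at their forward-strand start.
    """
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must be in (0, 1]")
    if len(seq) < pwm.length:
        return []
    codes = _encode(seq)
    hits = []
    fr = _scan_one_strand(codes, pwm)
    for pos in np.where(fr >= cutoff - 1e-12)[0]:
        hits.append(MotifHit(seq_id, int(pos), "+", float(fr[pos])))
    if both_strands:
        fr_rc = _scan_one_strand(codes, pwm.reverse_complement())
        for pos in np.where(fr_rc >= cutoff - 1e-12)[0]:
            hits.append(MotifHit(seq_id, int(pos), "-", float(fr_rc[pos])))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def peak_window_sequence(seq: str, summit: int, window: int = 100
                         ) -> tuple[str, int, bool]:
    """``window`` bp of sequence centered on a summit.

    Returns (subsequence, window start, truncated_flag); the window is
    truncated (and flagged) where it runs past the sequence ends.
    """
    half = window // 2
    lo = summit - half
    hi = summit + (window - half)
    truncated = lo < 0 or hi > len(seq)
    lo_c, hi_c = max(lo, 0), min(hi, len(seq))
    return seq[lo_c:hi_c], lo_c, truncated


def peaks_with_hits(peaks, sequences: dict[str, str], pwm: PWM,
                    cutoff: float = 0.85, min_hits: int = 1,
                    window: int = 100) -> float:
    """Fraction of peaks whose summit-centered window carries at least
    ``min_hits`` motif hits."""
    if len(peaks) == 0:
        raise ValueError("empty peak set")
    n_with = 0
    for iv in peaks:
        sub, _, _ = peak_window_sequence(
            sequences[iv.chrom], iv.effective_summit, window
        )
        if len(scan_sequence(sub, pwm, cutoff)) >= min_hits:
            n_with += 1
    return n_with / len(peaks)


def motif_density_profile(hits: list[MotifHit], summits: dict[str, int] | pd.Series,
                          window: int = 800, bin_size: int = 10) -> np.ndarray:
    """Hit-start density around summits: hits per bp per peak, in
    ``window / bin_size`` bins centered on the summit.

    ``hits`` positions must be absolute on the same coordinates as
    ``summits`` (one summit per seq_id).
    """
    if window % bin_size:
        raise ValueError("window must be an even multiple of bin_size")
    n_bins = window // bin_size
    half = window // 2
    counts = np.zeros(n_bins)
    summits = dict(summits)
    n_summits = len(summits)
    if n_summits == 0:
        raise ValueError("no summits supplied")
    for h in hits:
        if h.seq_id not in summits:
            continue
        rel = h.position - summits[h.seq_id]
        b = (rel + half) // bin_size
        if 0 <= b < n_bins:
            counts[int(b)] += 1
    return counts / (n_summits * bin_size)


def hits_to_frame(hits: list[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "seq_id": [h.seq_id for h in hits],
            "position": [h.position for h in hits],
            "strand": [h.strand for h in hits],
            "score_fraction": [h.score_fraction for h in hits],
        }
    )
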