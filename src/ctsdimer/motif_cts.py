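"""PWM log-odds scanning and clustered CTCF-target-site (CTS) classification.

CTCF binds a ~20-bp consensus; regions co-bound by CTCF and its paralog BORIS
tend to contain two closely spaced motif copies ("clustered CTSes", 2xCTS)
that allow the two 11-zinc-finger proteins to co-occupy one region.  This
module scores windows against a position weight matrix, scans regions around
peak summits on both strands, and labels peaks 0x / 1x / 2x_or_more by the
number of retained non-overlapping motif hits.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ctsdimer.genomic_io import Peak, ValidationError

logger = logging.getLogger(__name__)

PSEUDOCOUNT = 1e-3
BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class PWM:
    """Position frequency matrix (width x 4, columns A,C,G,T) with log-odds.

    Scores are in bits: per position, ``log2(p / background)`` with
    pseudocount-smoothed frequencies ``p = (f + 1e-3) / (1 + 4e-3)``.
    """

    freq: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.freq.ndim != 2 or self.freq.shape[1] != 4:
            raise ValidationError(f"PWM frequency matrix must be W x 4, got {self.freq.shape}")
        if np.any(np.abs(self.freq.sum(axis=1) - 1.0) > 1e-9):
            raise ValidationError("PWM columns must each sum to 1")

    @property
    def width(self) -> int:
        return self.freq.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        smoothed = (self.freq + PSEUDOCOUNT) / (1.0 + 4 * PSEUDOCOUNT)
        return np.log2(smoothed / self.background)

    @property
    def max_score(self) -> float:
        """Best achievable log-odds score (sum of per-position maxima)."""
        return float(self.log_odds.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.freq.argmax(axis=1))


def read_pwm(path: str | os.PathLike, background: Sequence[float] | None = None) -> PWM:
    """Read a whitespace-delimited frequency/count table as a PWM.

    Accepts W x 4 or 4 x W layouts (auto-detected: a table whose rows sum to
    ~1 is taken as W x 4, otherwise a 4-row table is transposed) and tolerates
    JASPAR-style headers (``>...``) and row labels (``A [ 1 2 3 ]``).  Count
    matrices are normalised column-wise.
    """
    rows: list[list[float]] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith(("#", ">")):
                continue
            line = line.replace("[", " ").replace("]", " ")
            fields = line.split()
            if fields and fields[0].upper() in ("A", "C", "G", "T"):
                fields = fields[1:]
            if fields:
                rows.append([float(x) for x in fields])
    mat = np.asarray(rows, dtype=float)
    if mat.ndim != 2:
        raise ValidationError(f"{path}: could not parse PWM table")
    if mat.shape[1] == 4 and np.allclose(mat.sum(axis=1), 1.0, atol=1e-6):
        freq = mat
    elif mat.shape[0] == 4:
        freq = mat.T
    elif mat.shape[1] == 4:
        freq = mat
    else:
        raise ValidationError(f"{path}: PWM must have 4 rows or 4 columns, got {mat.shape}")
    sums = freq.sum(axis=1, keepdims=True)
    if np.any(sums <= 0):
        raise ValidationError(f"{path}: PWM column with non-positive total")
    freq = freq / sums
    kwargs = {} if background is None else {"background": np.asarray(background, float)}
    return PWM(freq=freq, **kwargs)


@dataclass(frozen=True)
class MotifHit:
    """A scored motif occurrence; coordinates 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str
    score: float


@dataclass(frozen=True)
class CTSClass:
    """Per-peak motif count classification: 0x, 1x, or 2x_or_more."""

    peak_id: str
    n_hits: int
    label: str
    spacing: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        expected = "0x" if self.n_hits == 0 else ("1x" if self.n_hits == 1 else "2x_or_more")
        if self.label != expected:
            raise ValidationError(f"label {self.label} inconsistent with n_hits={self.n_hits}")


def _encode(seq: str) -> np.ndarray:
    """Map a DNA string to indices 0..3, with 4 for N/other."""
    idx = np.full(len(seq), 4, dtype=np.int64)
    for base, i in _BASE_INDEX.items():
        idx[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = i
    return idx


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def score_window(seq: str, pwm: PWM, strand: str = "+") -> float:
    """Log-odds score (bits) of a window exactly ``pwm.width`` long.

    The minus strand scores the reverse complement; ``N`` positions contribute
    0 bits (the background expectation).
    """
    if len(seq) != pwm.width:
        raise ValidationError(f"window length {len(seq)} != PWM width {pwm.width}")
    if strand not in ("+", "-"):
        raise ValidationError(f"unknown strand {strand!r}")
    if strand == "-":
        seq = reverse_complement(seq)
    idx = _encode(seq.upper())
    lo = np.hstack([pwm.log_odds, np.zeros((pwm.width, 1))])  # column 4: N -> 0 bits
    return float(lo[np.arange(pwm.width), idx].sum())


def _window_scores(seq: str, pwm: PWM) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised plus/minus scores for every window start in ``seq``."""
    W = pwm.width
    idx = _encode(seq.upper())
    n_win = len(seq) - W + 1
    if n_win <= 0:
        return np.empty(0), np.empty(0)
    lo = np.hstack([pwm.log_odds, np.zeros((W, 1))])
    windows = np.lib.stride_tricks.sliding_window_view(idx, W)
    plus = lo[np.arange(W), windows].sum(axis=1)
    # minus strand: reverse complement of the window == complement matrix reversed
    comp = np.array([3, 2, 1, 0, 4])
    lo_rc = lo[::-1][:, comp]
    minus = lo_rc[np.arange(W), windows].sum(axis=1)
    return plus, minus


def scan_region(
    genome: Mapping[str, str],
    region: tuple[str, int, int],
    pwm: PWM,
    min_score_frac: float = 0.8,
) -> list[MotifHit]:
    """Scan both strands of a region, returning non-overlapping hits by start.

    Windows scoring at least ``min_score_frac * pwm.max_score`` are kept and
    overlaps resolved greedily by descending score (ties: leftmost start,
    then + strand).  A region shorter than the PWM yields no hits.
    """
    chrom, start, end = region
    if chrom not in genome:
        raise ValidationError(f"unknown chromosome {chrom!r}")
    seq = genome[chrom][max(0, start):end]
    offset = max(0, start)
    plus, minus = _window_scores(seq, pwm)
    if plus.size == 0:
        return []
    threshold = min_score_frac * pwm.max_score
    candidates: list[tuple[float, int, int, str]] = []
    for strand, scores, order in (("+", plus, 0), ("-", minus, 1)):
        for pos in np.flatnonzero(scores >= threshold - 1e-9):
            candidates.append((float(scores[pos]), int(pos), order, strand))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    kept: list[MotifHit] = []
    for score, pos, _, strand in candidates:
        s = offset + pos
        e = s + pwm.width
        if all(e <= h.start or s >= h.end for h in kept):
            kept.append(MotifHit(chrom, s, e, strand, score))
    kept.sort(key=lambda h: h.start)
    return kept


def classify_cts(
    peaks: Sequence[Peak],
    genome: Mapping[str, str],
    pwm: PWM,
    flank: int = 150,
    min_score_frac: float = 0.8,
) -> list[CTSClass]:
    """Classify peaks by motif count in a window around the summit.

    Scans ``[summit - flank, summit + flank)`` on both strands; the label is
    0x/1x/2x_or_more by the number of retained hits, and ``spacing`` records
    the gaps (next start minus previous end) between consecutive hits.  Peaks
    whose summit falls outside the genome are logged and skipped.
    """
    out: list[CTSClass] = []
    for peak in peaks:
        seq = genome.get(peak.chrom)
        if seq is None or not (0 <= peak.summit < len(seq)):
            logger.warning("peak %s: summit outside genome; skipped", peak.name)
            continue
        hits = scan_region(
            genome,
            (peak.chrom, peak.summit - flank, min(len(seq), peak.summit + flank)),
            pwm,
            min_score_frac=min_score_frac,
        )
        n = len(hits)
        label = "0x" if n == 0 else ("1x" if n == 1 else "2x_or_more")
        spacing = tuple(
            hits[i + 1].start - hits[i].end for i in range(n - 1)
        )
        out.append(CTSClass(peak_id=peak.name, n_hits=n, label=label, spacing=spacing))
    return out
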