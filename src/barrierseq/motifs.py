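"""PWM log-odds scanning of nucleotide sequences.

The scanner reports every window on both strands whose log2-odds score
against the background reaches the threshold, including overlapping
occurrences — counts from the two strands are combined. Tandem (2x)
search pairs single hits within a sequence with no inter-motif distance
constraint. Column shuffling produces the position-shuffled control motif
with unchanged letter weights.

Scores are log2 odds in bits: ``sum_j log2(p'_j(base_j) / bg(base_j))``
where ``p'`` are the motif probabilities with a small pseudo-probability
added (FIMO-like), so a perfect consensus match attains the maximum score
and mismatches are penalized by the information content of the position.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .core import GenomicInterval

__all__ = [
    "PWM",
    "MotifHit",
    "read_meme_pwm",
    "write_meme_pwm",
    "scan_pwm",
    "scan_tandem",
    "shuffle_pwm_columns",
    "reverse_complement",
]

ALPHABET = "ACGT"
_CODE = np.full(128, -1, dtype=np.int8)
for _i, _b in enumerate(ALPHABET):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Map a sequence over {A,C,G,T,N} to codes 0..3, N (or other) -> -1."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class PWM:
    """Position weight matrix over ACGT with a background model.

    ``probs`` has shape (width, 4), each row summing to 1; ``background``
    sums to 1. ``pseudo`` is the pseudo-probability added to each entry
    (then renormalized) before taking log-odds, so zero probabilities
    never map to -inf.
    """

    name: str
    probs: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    pseudo: float = 1e-3

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=np.float64)
        bg = np.asarray(self.background, dtype=np.float64)
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise ValueError("probs must have shape (width, 4)")
        if probs.shape[0] < 4:
            raise ValueError("PWM width must be >= 4")
        if (probs < 0).any() or np.abs(probs.sum(axis=1) - 1).max() > 1e-6:
            raise ValueError("each PWM row must be a probability vector")
        if bg.shape != (4,) or abs(bg.sum() - 1) > 1e-6 or (bg <= 0).any():
            raise ValueError("background must be a positive probability vector")
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "background", bg)

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """(width, 4) matrix of log2 odds with pseudo-probability applied."""
        p = (self.probs + self.pseudo) / (1 + 4 * self.pseudo)
        return np.log2(p / self.background)

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.probs.argmax(axis=1))

    @property
    def max_score(self) -> float:
        """Score of the consensus word — an upper bound for any window."""
        return float(self.log_odds.max(axis=1).sum())

    def information_content(self) -> float:
        """Total information in bits, sum over positions of 2 - H(p)."""
        p = self.probs
        with np.errstate(divide="ignore", invalid="ignore"):
            h = np.where(p > 0, -p * np.log2(p), 0.0).sum(axis=1)
        return float((2.0 - h).sum())

    def default_threshold(self, fraction: float = 0.8) -> float:
        """Score cutoff as a fraction of the consensus score."""
        return fraction * self.max_score

    def reverse_complement(self) -> "PWM":
        return PWM(
            name=self.name,
            probs=self.probs[::-1, ::-1].copy(),
            background=self.background[::-1].copy(),
            pseudo=self.pseudo,
        )


@dataclass(frozen=True)
class MotifHit:
    """A motif occurrence: genome window, strand, log2-odds score in bits."""

    interval: GenomicInterval
    score: float
    motif: str

    @property
    def strand(self) -> str:
        return self.interval.strand


def read_meme_pwm(path: str | Path) -> list[PWM]:
    """Parse MEME minimal motif format into a list of :class:`PWM`.

    Requires a ``MEME version`` header; takes background frequencies from
    the file or uniform if absent; raises on probability rows that do not
    sum to ~1.
    """
    lines = Path(path).read_text().splitlines()
    if not any(ln.strip().startswith("MEME version") for ln in lines):
        raise ValueError(f"{path}: not MEME minimal format (no 'MEME version')")
    background = np.full(4, 0.25)
    pwms: list[PWM] = []
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            i += 1
            toks: list[str] = []
            while i < len(lines) and lines[i].strip() and not lines[i].startswith("MOTIF"):
                toks.extend(lines[i].split())
                i += 1
            freq = {toks[j]: float(toks[j + 1]) for j in range(0, len(toks), 2)}
            background = np.array([freq.get(b, 0.25) for b in ALPHABET])
            background = background / background.sum()
            continue
        if line.startswith("MOTIF"):
            name = line.split()[1] if len(line.split()) > 1 else f"motif{len(pwms)+1}"
            i += 1
            while i < len(lines) and not lines[i].strip().startswith(
                "letter-probability matrix"
            ):
                i += 1
            if i == len(lines):
                raise ValueError(f"{path}: MOTIF {name} has no probability matrix")
            i += 1
            rows: list[list[float]] = []
            while i < len(lines):
                stripped = lines[i].strip()
                if not stripped or stripped.startswith(("MOTIF", "URL")):
                    break
                vals = [float(x) for x in stripped.split()]
                if len(vals) != 4:
                    raise ValueError(
                        f"{path}: MOTIF {name}: expected 4 columns per row"
                    )
                if abs(sum(vals) - 1.0) > 1e-2:
                    raise ValueError(
                        f"{path}: MOTIF {name}: row does not sum to ~1: {vals}"
                    )
                rows.append(vals)
                i += 1
            probs = np.array(rows)
            probs = probs / probs.sum(axis=1, keepdims=True)
            pwms.append(PWM(name=name, probs=probs, background=background))
            continue
        i += 1
    if not pwms:
        raise ValueError(f"{path}: no MOTIF blocks found")
    return pwms


def write_meme_pwm(pwms: Iterable[PWM], path: str | Path) -> None:
    """Write motifs in MEME minimal format (round-trips with the reader)."""
    pwms = list(pwms)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        fh.write("strands: + -\n\n")
        bg = pwms[0].background if pwms else np.full(4, 0.25)
        fh.write("Background letter frequencies\n")
        fh.write(
            " ".join(f"{b} {bg[i]:.6f}" for i, b in enumerate(ALPHABET)) + "\n\n"
        )
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.width} "
                f"nsites= 20 E= 0\n"
            )
            for row in pwm.probs:
                fh.write(" " + " ".join(f"{v:.9f}" for v in row) + "\n")
            fh.write("\n")


def _window_scores(codes: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """Score every window of len(log_odds); windows containing N get -inf."""
    w = log_odds.shape[0]
    n_win = codes.size - w + 1
    if n_win <= 0:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)
    valid = (windows >= 0).all(axis=1)
    safe = np.where(windows >= 0, windows, 0)
    scores = log_odds[np.arange(w), safe].sum(axis=1)
    scores[~valid] = -np.inf
    return scores


def scan_pwm(
    seq: str,
    pwm: PWM,
    threshold: float,
    chrom: str = ".",
    origin: int = 0,
) -> list[MotifHit]:
    """Scan *seq* on both strands, reporting every window scoring >= threshold.

    Overlapping occurrences are retained; windows containing N are
    skipped. Hit coordinates are genome coordinates of the window
    (``origin`` + offset) regardless of strand; the strand of the match
    is recorded on the hit. Hits are ordered by position, then strand
    (+ before -).
    """
    if threshold > pwm.max_score:
        warnings.warn(
            f"threshold {threshold:.3f} exceeds maximum attainable score "
            f"{pwm.max_score:.3f} for motif {pwm.name}; no hits possible",
            stacklevel=2,
        )
        return []
    codes = encode(seq)
    w = pwm.width
    fwd = _window_scores(codes, pwm.log_odds)
    rev = _window_scores(codes, pwm.reverse_complement().log_odds)
    cand: list[tuple[int, str, float]] = []
    for strand, scores in (("+", fwd), ("-", rev)):
        for off in np.flatnonzero(scores >= threshold):
            cand.append((int(off), strand, float(scores[off])))
    cand.sort(key=lambda t: (t[0], t[1]))  # "+" sorts before "-"
    return [
        MotifHit(
            interval=GenomicInterval(
                chrom, origin + off, origin + off + w,
                name=pwm.name, score=score, strand=strand,
            ),
            score=score,
            motif=pwm.name,
        )
        for off, strand, score in cand
    ]


def scan_tandem(
    seq: str,
    pwm: PWM,
    threshold: float,
    chrom: str = ".",
    origin: int = 0,
) -> list[tuple[MotifHit, MotifHit]]:
    """All unordered pairs of single hits within one sequence.

    Any spacing (no inter-motif distance threshold) and any strand
    combination qualify; k single hits yield k*(k-1)/2 pairs.
    """
    singles = scan_pwm(seq, pwm, threshold, chrom, origin)
    return [
        (singles[i], singles[j])
        for i in range(len(singles))
        for j in range(i + 1, len(singles))
    ]


def shuffle_pwm_columns(pwm: PWM, seed: int) -> PWM:
    """Permute PWM positions, preserving the column multiset.

    The permutation is drawn from the given seed and is never the
    identity (for width >= 2), so the shuffled control always differs
    positionally from the original even though per-column weights — and
    hence total information content — are unchanged.
    """
    if pwm.width < 2:
        raise ValueError("cannot shuffle a width-1 PWM")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(pwm.width)
    while (perm == np.arange(pwm.width)).all():
        perm = rng.permutation(pwm.width)
    return PWM(
        name=f"{pwm.name}_shuffled",
        probs=pwm.probs[perm].copy(),
        background=pwm.background.copy(),
        pseudo=pwm.pseudo,
    )


def count_hits_per_interval(
    sequences: dict[str, str],
    intervals,
    pwm: PWM,
    threshold: float,
) -> dict[str, int]:
    """Combined two-strand hit counts per interval (keyed by interval name).

    *sequences* maps chromosome name to full chromosome sequence.
    """
    counts: dict[str, int] = {}
    for iv in intervals:
        seq = sequences[iv.chrom][iv.start:iv.end]
        counts[iv.name] = len(scan_pwm(seq, pwm, threshold, iv.chrom, iv.start))
    return counts
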