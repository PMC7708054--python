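"""Position-probability-matrix motif models and exact-threshold sequence scanning.

A :class:`Motif` is a per-position base-probability model (PPM) of a
transcription-factor binding site.  Scanning converts the PPM to a log-odds
matrix against a 0-order background, discretizes the scores to a fixed grid,
and computes the *exact* distribution of window scores under the background by
dynamic-programming convolution.  The score threshold for a target p-value
(default 1e-4, the usual FIMO setting for plant promoter scans) is then exact
with respect to the discretized matrix, and every reported hit carries the
p-value from the same distribution.

Coordinates are 0-based half-open throughout; minus-strand hits are reported
in forward-strand coordinates.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "DNA_ALPHABET",
    "BackgroundModel",
    "Motif",
    "MotifHit",
    "MotifParseError",
    "parse_meme_motifs",
    "write_meme_motifs",
    "log_odds",
    "discretized_scores",
    "score_distribution",
    "threshold_for_pvalue",
    "scan_sequence",
    "reverse_complement",
]

log = logging.getLogger(__name__)

DNA_ALPHABET = "ACGT"
#: grid steps per bit used to discretize log-odds scores for the exact p-value
#: dynamic programme; part of the scanning contract (tests and oracles fix it).
DEFAULT_GRID = 1000
DEFAULT_PSEUDOCOUNT = 1e-3

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_ENCODE = np.full(256, -1, dtype=np.int64)
for _i, _c in enumerate(DNA_ALPHABET):
    _ENCODE[ord(_c)] = _i
    _ENCODE[ord(_c.lower())] = _i


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    """Map a DNA string to integer codes A,C,G,T -> 0..3; anything else -> -1."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE[raw]


class MotifParseError(ValueError):
    """Raised for malformed motif documents; message names the motif and line."""


@dataclass(frozen=True)
class BackgroundModel:
    """0-order background base composition used for log-odds scoring."""

    p_a: float = 0.25
    p_c: float = 0.25
    p_g: float = 0.25
    p_t: float = 0.25

    def __post_init__(self) -> None:
        probs = self.as_array()
        if np.any(probs <= 0):
            raise ValueError("background probabilities must be strictly positive")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError(f"background probabilities sum to {probs.sum()}, not 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.p_a, self.p_c, self.p_g, self.p_t], dtype=float)

    @classmethod
    def uniform(cls) -> "BackgroundModel":
        return cls()

    @classmethod
    def from_sequences(cls, seqs, pseudocount: float = 1.0) -> "BackgroundModel":
        """0-order model estimated from observed base counts (N ignored)."""
        counts = np.full(4, float(pseudocount))
        for s in seqs:
            codes = _encode(s)
            codes = codes[codes >= 0]
            counts += np.bincount(codes, minlength=4)[:4]
        p = counts / counts.sum()
        return cls(*p)

    @classmethod
    def from_file(cls, path) -> "BackgroundModel":
        """Read ``<base> <probability>`` pairs (MEME background format subset)."""
        probs = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                for base, value in zip(parts[::2], parts[1::2]):
                    if base.upper() in DNA_ALPHABET:
                        probs[base.upper()] = float(value)
        if set(probs) != set(DNA_ALPHABET):
            raise ValueError(f"background file {path} must give A,C,G,T frequencies")
        return cls(probs["A"], probs["C"], probs["G"], probs["T"])


@dataclass(frozen=True)
class Motif:
    """A DNA binding motif as a position probability matrix.

    The PPM is stored after pseudocount regularization: ``pseudocount`` is
    added to every cell and columns renormalized, so no entry is exactly zero
    and log-odds scores stay finite.
    """

    id: str
    ppm: np.ndarray  # shape (W, 4), rows sum to 1
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    source: str = "user"

    def __post_init__(self) -> None:
        ppm = np.asarray(self.ppm, dtype=float)
        object.__setattr__(self, "ppm", ppm)
        if ppm.ndim != 2 or ppm.shape[1] != 4:
            raise ValueError(f"motif {self.id}: ppm must be W x 4")
        if not 1 <= ppm.shape[0] <= 30:
            raise ValueError(f"motif {self.id}: width {ppm.shape[0]} outside [1, 30]")
        if np.any(ppm < 0):
            raise ValueError(f"motif {self.id}: negative probability")
        sums = ppm.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ValueError(f"motif {self.id}: rows must sum to 1 (got {sums})")

    @classmethod
    def from_raw_ppm(
        cls,
        motif_id: str,
        raw: np.ndarray,
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
        source: str = "user",
    ) -> "Motif":
        """Regularize a raw probability matrix: add pseudocount, renormalize."""
        raw = np.asarray(raw, dtype=float) + pseudocount
        ppm = raw / raw.sum(axis=1, keepdims=True)
        return cls(motif_id, ppm, pseudocount=pseudocount, source=source)

    @property
    def width(self) -> int:
        return int(self.ppm.shape[0])

    @property
    def consensus(self) -> str:
        return "".join(DNA_ALPHABET[b] for b in self.ppm.argmax(axis=1))


@dataclass(frozen=True)
class MotifHit:
    """One scored motif occurrence, forward-strand coordinates, half-open."""

    motif_id: str
    sequence_id: str
    start: int
    end: int
    strand: str  # '+' or '-'
    score: float  # log-odds, bits
    p_value: float  # P(background window score >= observed)

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad hit interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not 0 < self.p_value <= 1:
            raise ValueError(f"p_value {self.p_value} outside (0, 1]")

    @property
    def sort_key(self):
        return (self.sequence_id, self.start, self.motif_id, self.strand)


# ---------------------------------------------------------------------------
# MEME minimal format
# ---------------------------------------------------------------------------

_MOTIF_RE = re.compile(r"^MOTIF\s+(\S+)(?:\s+(\S+))?")
_MATRIX_RE = re.compile(
    r"^letter-probability matrix:(?:\s+alength=\s*(\d+))?(?:\s+w=\s*(\d+))?"
)


def parse_meme_motifs(
    text: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    source: str = "user",
) -> list[Motif]:
    """Parse a MEME minimal-format document into a list of :class:`Motif`.

    Only the DNA alphabet is accepted.  Column sums are checked to within
    0.01 before pseudocount regularization; violations raise
    :class:`MotifParseError` naming the motif and line number.
    """
    lines = text.splitlines()
    motifs: list[Motif] = []
    i = 0
    n = len(lines)
    alphabet_ok = True  # absent ALPHABET line defaults to DNA
    while i < n:
        line = lines[i].strip()
        if line.startswith("ALPHABET"):
            declared = line.split("=", 1)[-1].strip() if "=" in line else line.split(None, 1)[-1]
            alphabet_ok = set(declared.upper()) == set(DNA_ALPHABET)
            if not alphabet_ok:
                raise MotifParseError(
                    f"line {i + 1}: non-DNA alphabet {declared!r}; only ACGT is supported"
                )
            i += 1
            continue
        m = _MOTIF_RE.match(line)
        if not m:
            i += 1
            continue
        motif_id = m.group(1)
        # find the letter-probability matrix header
        i += 1
        while i < n and not lines[i].strip().startswith("letter-probability matrix"):
            if _MOTIF_RE.match(lines[i].strip()):
                raise MotifParseError(
                    f"motif {motif_id}, line {i + 1}: no letter-probability matrix"
                )
            i += 1
        if i >= n:
            raise MotifParseError(f"motif {motif_id}: missing letter-probability matrix")
        hm = _MATRIX_RE.match(lines[i].strip())
        alength = int(hm.group(1)) if hm.group(1) else 4
        width = int(hm.group(2)) if hm.group(2) else None
        if alength != 4:
            raise MotifParseError(
                f"motif {motif_id}, line {i + 1}: alength={alength}, expected 4 (DNA)"
            )
        i += 1
        rows: list[list[float]] = []
        while i < n:
            row_line = lines[i].strip()
            if not row_line or row_line.startswith(("MOTIF", "URL", "letter-probability")):
                break
            parts = row_line.split()
            try:
                values = [float(x) for x in parts]
            except ValueError:
                break
            if len(values) != 4:
                raise MotifParseError(
                    f"motif {motif_id}, line {i + 1}: expected 4 probabilities, got {len(values)}"
                )
            if abs(sum(values) - 1.0) > 0.01:
                raise MotifParseError(
                    f"motif {motif_id}, line {i + 1}: column sums to {sum(values):.4f}, not ~1"
                )
            rows.append(values)
            i += 1
            if width is not None and len(rows) == width:
                break
        if not rows:
            raise MotifParseError(f"motif {motif_id}: empty probability matrix")
        if width is not None and len(rows) != width:
            raise MotifParseError(
                f"motif {motif_id}: header declares w={width} but {len(rows)} rows found"
            )
        motifs.append(
            Motif.from_raw_ppm(motif_id, np.array(rows), pseudocount=pseudocount, source=source)
        )
    ids = [m.id for m in motifs]
    if len(set(ids)) != len(ids):
        raise MotifParseError("duplicate motif ids in document")
    return motifs


def write_meme_motifs(motifs, handle_or_path, bg: BackgroundModel | None = None) -> None:
    """Write motifs as a MEME minimal-format document."""
    bg = bg or BackgroundModel.uniform()
    own = isinstance(handle_or_path, (str, bytes)) or hasattr(handle_or_path, "__fspath__")
    fh = open(handle_or_path, "w") if own else handle_or_path
    try:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(
            "A {:.5f} C {:.5f} G {:.5f} T {:.5f}\n\n".format(*bg.as_array())
        )
        for motif in motifs:
            fh.write(f"MOTIF {motif.id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {motif.width} nsites= 20 E= 0\n"
            )
            for row in motif.ppm:
                fh.write(" ".join(f"{p:.6f}" for p in row) + "\n")
            fh.write("\n")
    finally:
        if own:
            fh.close()


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def log_odds(motif: Motif, bg: BackgroundModel) -> np.ndarray:
    """Log-odds matrix in bits: entry[i, b] = log2(ppm[i, b] / bg[b])."""
    return np.log2(motif.ppm / bg.as_array()[None, :])


def discretized_scores(
    motif: Motif, bg: BackgroundModel, grid: int = DEFAULT_GRID
) -> np.ndarray:
    """Integer log-odds matrix on a 1/grid-bit lattice (the scanning scores)."""
    return np.rint(log_odds(motif, bg) * grid).astype(np.int64)


def score_distribution(
    motif: Motif, bg: BackgroundModel, grid: int = DEFAULT_GRID
) -> tuple[int, np.ndarray]:
    """Exact distribution of the discretized score of a random background W-mer.

    Returns ``(min_score, probs)`` where ``probs[k]`` is the probability that
    the integer window score equals ``min_score + k``.  Computed by convolving
    the per-position score distributions (independent positions under the
    0-order background).
    """
    q = discretized_scores(motif, bg, grid)
    p_bg = bg.as_array()
    mins = q.min(axis=1)
    cur = np.array([1.0])
    cur_lo = 0
    for i in range(motif.width):
        span = int(q[i].max() - mins[i])
        new = np.zeros(len(cur) + span)
        for b in range(4):
            off = int(q[i, b] - mins[i])
            new[off : off + len(cur)] += p_bg[b] * cur
        cur = new
        cur_lo += int(mins[i])
    return cur_lo, cur


def _survival(probs: np.ndarray) -> np.ndarray:
    """sf[k] = P(score >= min_score + k); clipped to [0, 1] against fp error."""
    return np.clip(np.cumsum(probs[::-1])[::-1], 0.0, 1.0)


def _threshold_grid(
    motif: Motif, bg: BackgroundModel, p: float, grid: int = DEFAULT_GRID
) -> int:
    """Smallest integer score t with P(score >= t) <= p, in grid units.

    If even the maximum attainable score has tail probability above ``p``
    (possible for short motifs at stringent p), the returned threshold is one
    grid step above the maximum, so a scan yields no hits; this is logged.
    """
    if not 0 < p < 1 + 1e-12:
        raise ValueError(f"p must be in (0, 1], got {p}")
    lo, probs = score_distribution(motif, bg, grid)
    sf = _survival(probs)
    idx = np.nonzero(sf <= p)[0]
    if len(idx) == 0:
        log.warning(
            "motif %s: no W-mer attains p-value <= %g (best is %g); scan will yield no hits",
            motif.id,
            p,
            sf[-1],
        )
        return lo + len(probs)  # max score + one grid step
    return lo + int(idx[0])


def threshold_for_pvalue(
    motif: Motif, bg: BackgroundModel, p: float, grid: int = DEFAULT_GRID
) -> float:
    """Score threshold in bits for a target p-value.

    The smallest discretized score ``t`` such that a random background W-mer
    scores ``>= t`` with probability at most ``p``; exact with respect to the
    grid-discretized log-odds matrix.
    """
    return _threshold_grid(motif, bg, p, grid) / grid


def scan_sequence(
    seq: str,
    motifs,
    bg: BackgroundModel,
    p: float,
    sequence_id: str = "seq",
    grid: int = DEFAULT_GRID,
) -> list[MotifHit]:
    """Scan both strands of ``seq`` for every motif at p-value threshold ``p``.

    Windows containing N (or any non-ACGT character) are skipped.  Hits are
    sorted by (sequence_id, start, motif_id, strand); minus-strand hits are
    reported in forward coordinates.  Overlapping hits are all reported.
    """
    length = len(seq)
    fwd = _encode(seq)
    rev = _encode(reverse_complement(seq))
    hits: list[MotifHit] = []
    for motif in motifs:
        w = motif.width
        if length < w:
            continue
        q = discretized_scores(motif, bg, grid)
        t_grid = _threshold_grid(motif, bg, p, grid)
        lo, probs = score_distribution(motif, bg, grid)
        sf = _survival(probs)
        for strand, codes in (("+", fwd), ("-", rev)):
            n_win = length - w + 1
            bad = codes < 0
            clipped = np.where(bad, 0, codes)
            scores = np.zeros(n_win, dtype=np.int64)
            for i in range(w):
                scores += q[i, clipped[i : i + n_win]]
            bad_win = (
                np.convolve(bad.astype(np.int64), np.ones(w, dtype=np.int64), "valid") > 0
            )
            for j in np.nonzero((scores >= t_grid) & ~bad_win)[0]:
                s = int(scores[j])
                pv = float(sf[s - lo]) if s - lo < len(sf) else float(sf[-1])
                pv = min(max(pv, np.nextafter(0, 1)), 1.0)
                if strand == "+":
                    start = int(j)
                else:
                    start = length - (int(j) + w)
                hits.append(
                    MotifHit(
                        motif_id=motif.id,
                        sequence_id=sequence_id,
                        start=start,
                        end=start + w,
                        strand=strand,
                        score=s / grid,
                        p_value=pv,
                    )
                )
    hits.sort(key=lambda h: h.sort_key)
    return hits
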