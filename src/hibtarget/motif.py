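"""Position-weight-matrix scanning with exact score p-values.

A position frequency matrix (PFM) of base counts is converted to a log-odds
position weight matrix (PWM, base-2, rounded to a fixed number of decimals)
against an order-0 background model.  Because the weights live on a fixed
rounding lattice, the distribution of the score of a random background window
can be computed exactly by dynamic programming over motif columns, which gives
every scanned window an exact p-value.  Scanning is vectorised over whole
chromosomes and covers both strands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
# code 4 = ambiguous (N or anything outside ACGT)
_ENCODE = np.full(256, 4, dtype=np.int8)
for _b, _i in _BASE_INDEX.items():
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 codes A=0, C=1, G=2, T=3, ambiguous=4."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def reverse_complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTNacgtn", "TGCANtgcan"))[::-1]


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """Base counts per motif column; rows ordered A, C, G, T."""

    counts: np.ndarray  # shape (4, width)

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise ValueError("PFM must have shape (4, width)")
        if counts.shape[1] < 1:
            raise ValueError("PFM must have at least one column")
        if np.any(counts < 0):
            raise ValueError("PFM counts must be non-negative")
        if np.any(counts.sum(axis=0) <= 0):
            raise ValueError("every PFM column must have a positive total")
        object.__setattr__(self, "counts", counts)

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def column_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.counts, axis=0))


def read_pfm(path, dialect: str = "rows-are-bases") -> PositionFrequencyMatrix:
    """Read a whitespace-delimited count matrix.

    ``rows-are-bases``: 4 rows (A, C, G, T order), one column per motif
    position.  ``rows-are-positions``: the transpose.  Rows may carry a
    leading base letter (``A  12 3 ...``), in which case base order is
    normalised from the labels.
    """
    if dialect not in ("rows-are-bases", "rows-are-positions"):
        raise ValueError(f"unknown PFM dialect: {dialect!r}")
    rows = []
    labels = []
    with open(path) as fh:
        for line in fh:
            line = line.strip().replace("[", " ").replace("]", " ").replace("|", " ")
            if not line or line.startswith("#") or line.startswith(">"):
                continue
            toks = line.split()
            label = None
            if toks[0].rstrip(":").upper() in _BASE_INDEX:
                label = toks[0].rstrip(":").upper()
                toks = toks[1:]
            try:
                rows.append([float(t) for t in toks])
            except ValueError as e:
                raise ValueError(f"non-numeric cell in PFM {path}: {e}") from None
            labels.append(label)
    mat = np.asarray(rows, dtype=float)
    if mat.ndim != 2 or 4 not in mat.shape:
        raise ValueError("PFM must have one dimension of size 4")
    if dialect == "rows-are-positions":
        mat = mat.T
        labels = [None] * mat.shape[0]
    if mat.shape[0] != 4:
        raise ValueError("PFM rows must be the 4 bases under this dialect")
    if all(l is not None for l in labels) and len(labels) == 4:
        order = [labels.index(b) for b in BASES]
        mat = mat[order]
    return PositionFrequencyMatrix(mat)


@dataclass(frozen=True)
class BackgroundModel:
    """Order-0 (Bernoulli) base composition with pseudo-probability smoothing."""

    probs: np.ndarray  # shape (4,), order A, C, G, T
    bg_pseudo: float = 0.01

    def __post_init__(self):
        probs = np.asarray(self.probs, dtype=float)
        if probs.shape != (4,):
            raise ValueError("background must have 4 probabilities")
        if abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError("background probabilities must sum to 1")
        if np.any(probs <= 0):
            raise ValueError("background probabilities must be positive")
        object.__setattr__(self, "probs", probs)

    @classmethod
    def uniform(cls) -> "BackgroundModel":
        return cls(np.full(4, 0.25), bg_pseudo=0.0)


def build_background(
    sequences: Iterable[str], bg_pseudo: float = 0.01
) -> BackgroundModel:
    """Estimate a Bernoulli background from sequences.

    Ambiguous bases are excluded from the counts.  The empirical frequencies
    are mixed with the uniform distribution at total mass ``4 * bg_pseudo``
    so that every base has probability at least ``bg_pseudo``.
    """
    counts = np.zeros(4)
    seen = False
    for seq in sequences:
        seen = True
        codes = encode_sequence(seq)
        counts += np.bincount(codes[codes < 4], minlength=4)
    if not seen:
        raise ValueError("empty sequence set")
    total = counts.sum()
    if total == 0:
        raise ValueError("no unambiguous bases in the sequence set")
    freqs = counts / total
    probs = freqs * (1.0 - 4.0 * bg_pseudo) + bg_pseudo
    probs = probs / probs.sum()
    return BackgroundModel(probs, bg_pseudo=bg_pseudo)


@dataclass(frozen=True)
class PositionWeightMatrix:
    """Base-2 log-odds weights rounded to ``decimals`` places.

    The integer lattice representation (weights times ``10**decimals``) is
    what both the scanner and the exact p-value DP operate on, so hit scores
    and the score distribution are always mutually consistent.
    """

    weights: np.ndarray  # shape (4, width), rounded floats
    background: BackgroundModel
    pseudocount: float = 1.0
    decimals: int = 1
    int_weights: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != 4:
            raise ValueError("PWM weights must have shape (4, width)")
        if not np.all(np.isfinite(w)):
            raise ValueError("PWM weights must be finite")
        scale = 10**self.decimals
        object.__setattr__(self, "weights", w)
        object.__setattr__(
            self, "int_weights", np.rint(w * scale).astype(np.int64)
        )

    @property
    def width(self) -> int:
        return self.weights.shape[1]

    @property
    def scale(self) -> int:
        return 10**self.decimals

    @property
    def max_score(self) -> float:
        return self.weights.max(axis=0).sum()

    @property
    def min_score(self) -> float:
        return self.weights.min(axis=0).sum()

    def reverse_complement(self) -> "PositionWeightMatrix":
        return PositionWeightMatrix(
            self.weights[::-1, ::-1].copy(),
            background=self.background,
            pseudocount=self.pseudocount,
            decimals=self.decimals,
        )


def pfm_to_pwm(
    pfm: PositionFrequencyMatrix,
    background: BackgroundModel,
    pseudocount: float = 1.0,
    decimals: int = 1,
) -> PositionWeightMatrix:
    """Log-odds transform with background-proportional pseudocounts.

    weight(b, j) = round(log2(((n_bj + pc * p_b) / (N_j + pc)) / p_b), decimals)
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if decimals < 0:
        raise ValueError("decimals must be >= 0")
    probs = background.probs[:, None]
    totals = pfm.column_totals[None, :]
    corrected = (pfm.counts + pseudocount * probs) / (totals + pseudocount)
    if np.any(corrected <= 0):
        raise ValueError(
            "zero corrected frequency (zero count with zero pseudocount)"
        )
    weights = np.round(np.log2(corrected / probs), decimals)
    # -0.0 -> 0.0 for clean reporting
    weights = weights + 0.0
    return PositionWeightMatrix(
        weights, background=background, pseudocount=pseudocount, decimals=decimals
    )


class ScoreDistribution:
    """Exact distribution of the PWM score of a random background window.

    ``support`` holds the achievable integer lattice scores in increasing
    order, ``probs`` their probabilities, and ``pvalues`` the upper-tail
    P(S >= s) at each support point.
    """

    def __init__(self, support: np.ndarray, probs: np.ndarray, scale: int):
        self.support = np.asarray(support, dtype=np.int64)
        self.probs = np.asarray(probs, dtype=float)
        self.scale = scale
        self.pvalues = np.minimum(self.probs[::-1].cumsum()[::-1], 1.0)

    @property
    def scores(self) -> np.ndarray:
        """Support on the score (float) scale."""
        return self.support / self.scale

    def pvalue_of_int(self, int_score) -> np.ndarray:
        """Upper-tail p-value P(S >= s) for integer lattice score(s)."""
        idx = np.searchsorted(self.support, np.asarray(int_score))
        idx = np.clip(idx, 0, len(self.support) - 1)
        out = self.pvalues[idx]
        return np.where(np.asarray(int_score) > self.support[-1], 0.0, out)

    def pvalue(self, score) -> np.ndarray:
        int_score = np.rint(np.asarray(score, dtype=float) * self.scale).astype(
            np.int64
        )
        return self.pvalue_of_int(int_score)

    def score_threshold(self, pval_upper: float):
        """Smallest integer lattice score whose p-value is <= pval_upper.

        Returns None when no achievable score is that significant.
        """
        ok = self.pvalues <= pval_upper
        if not ok.any():
            return None
        return int(self.support[np.argmax(ok)])


def score_distribution(pwm: PositionWeightMatrix) -> ScoreDistribution:
    """Exact score distribution by DP convolution over motif columns.

    Works on the integer lattice (score times 10**decimals), so for small
    widths the result is identical to exhaustive enumeration of all 4^w words.
    """
    iw = pwm.int_weights
    probs = pwm.background.probs
    cur = np.array([1.0])
    cur_lo = 0
    for j in range(pwm.width):
        col = iw[:, j]
        new_lo = cur_lo + int(col.min())
        new_hi = cur_lo + len(cur) - 1 + int(col.max())
        new = np.zeros(new_hi - new_lo + 1)
        for b in range(4):
            off = cur_lo + int(col[b]) - new_lo
            new[off : off + len(cur)] += probs[b] * cur
        cur = new
        cur_lo = new_lo
    support = np.arange(cur_lo, cur_lo + len(cur))
    nz = cur > 0
    return ScoreDistribution(support[nz], cur[nz], pwm.scale)


@dataclass(frozen=True)
class MotifHit:
    """One scored window passing the p-value threshold (0-based, half-open)."""

    seq_id: str
    start: int
    end: int
    strand: str
    score: float
    pvalue: float


def _window_scores(codes: np.ndarray, iw: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Integer scores of all windows plus a validity mask (no ambiguous base)."""
    w = iw.shape[1]
    n = len(codes) - w + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=bool)
    # 5th row scores ambiguous bases 0; such windows are masked out below
    lut = np.vstack([iw, np.zeros((1, w), dtype=np.int64)])
    scores = np.zeros(n, dtype=np.int64)
    for j in range(w):
        scores += lut[codes[j : j + n], j]
    bad = (codes == 4).astype(np.int32)
    cbad = np.concatenate([[0], np.cumsum(bad)])
    valid = (cbad[w:] - cbad[:-w]) == 0
    return scores, valid


def scan(
    pwm: PositionWeightMatrix,
    sequences: Mapping[str, str],
    pval_upper: float = 5e-7,
    two_strand: bool = True,
    dist: ScoreDistribution | None = None,
) -> list[MotifHit]:
    """Scan named sequences for windows with exact p-value <= ``pval_upper``.

    Both strands are scored at the same forward-strand coordinates when
    ``two_strand`` is set; windows containing ambiguous bases are skipped.
    Hits are sorted by (seq_id, start, strand).
    """
    if not (0 < pval_upper <= 1):
        raise ValueError("pval_upper must be in (0, 1]")
    if dist is None:
        dist = score_distribution(pwm)
    thr = dist.score_threshold(pval_upper)
    hits: list[MotifHit] = []
    if thr is None:
        return hits
    w = pwm.width
    strand_mats = [("+", pwm.int_weights)]
    if two_strand:
        strand_mats.append(("-", pwm.reverse_complement().int_weights))
    for seq_id in sorted(sequences):
        seq = sequences[seq_id]
        bad = set(seq.upper()) - set("ACGTN")
        if bad:
            raise ValueError(f"sequence alphabet outside ACGTN: {sorted(bad)}")
        codes = encode_sequence(seq)
        per_seq: list[MotifHit] = []
        for strand, iw in strand_mats:
            scores, valid = _window_scores(codes, iw)
            idx = np.nonzero(valid & (scores >= thr))[0]
            if len(idx) == 0:
                continue
            pvals = dist.pvalue_of_int(scores[idx])
            per_seq.extend(
                MotifHit(
                    seq_id=seq_id,
                    start=int(i),
                    end=int(i) + w,
                    strand=strand,
                    score=float(scores[i]) / pwm.scale,
                    pvalue=float(p),
                )
                for i, p in zip(idx, pvals)
            )
        per_seq.sort(key=lambda h: (h.start, h.strand))
        hits.extend(per_seq)
    return hits


def hits_to_table(hits: Sequence[MotifHit]):
    """Hits as a pandas DataFrame (TSV-ready)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "seq_id": h.seq_id,
                "start0": h.start,
                "end": h.end,
                "strand": h.strand,
                "score": h.score,
                "pvalue": h.pvalue,
            }
            for h in hits
        ],
        columns=["seq_id", "start0", "end", "strand", "score", "pvalue"],
    )


def write_bed(hits: Sequence[MotifHit], path, name: str = "motif") -> None:
    """Write hits as BED6 with the score scaled by 100."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.seq_id}\t{h.start}\t{h.end}\t{name}\t"
                f"{int(round(h.score * 100))}\t{h.strand}\n"
            )
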