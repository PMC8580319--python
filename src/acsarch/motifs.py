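"""Ungapped protein motifs: background models, PWMs, exact p-values, scanning.

A motif is a position weight matrix over the 20 standard amino acids (an
arbitrary reduced alphabet is supported for testing).  Window scores are
log-odds in bits against a background composition; position p-values are
computed from the *exact* null score distribution obtained by column-wise
convolution over integer-scaled scores, the same mechanism motif-search
tools use for their position p-values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

#: The 20 standard amino acids, in alphabetical one-letter order.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Letters treated as ambiguous/non-standard in protein sequences.
AMBIGUOUS = set("XBZJUO*-.")

#: Default per-window position p-value below which a motif counts as present.
DEFAULT_P_THRESHOLD = 1e-4

#: Default MEME-style pseudocount (total pseudo-observations, spread
#: proportionally to the background).
DEFAULT_PSEUDOCOUNT = 0.375

#: Integer score bins per bit used for the exact null distribution.
DEFAULT_SCALE = 1000

#: Discovery bounds on motif width.
MIN_WIDTH, MAX_WIDTH = 6, 50

ACS_MOTIF_IDS = tuple(f"ACS{i}" for i in range(1, 10))
AAT_MOTIF_ID = "AAT"


class MotifError(ValueError):
    """Raised for unusable motif/background inputs."""


def _letter_index(alphabet: str) -> dict[str, int]:
    return {a: i for i, a in enumerate(alphabet)}


def encode(sequence: str, alphabet: str = AA_ALPHABET) -> np.ndarray:
    """Encode a sequence as integer indices; unknown letters map to len(alphabet)."""
    idx = _letter_index(alphabet)
    n = len(alphabet)
    return np.fromiter((idx.get(c, n) for c in sequence.upper()), dtype=np.int64,
                       count=len(sequence))


@dataclass(frozen=True)
class BackgroundModel:
    """A null amino-acid composition (the model scores are log-odds against).

    Parameters
    ----------
    frequencies:
        Array of per-letter probabilities, parallel to ``alphabet``.  Must be
        strictly positive and sum to 1.
    alphabet:
        Letter ordering; defaults to the 20 standard amino acids.
    """

    frequencies: np.ndarray
    alphabet: str = AA_ALPHABET

    def __post_init__(self) -> None:
        freqs = np.asarray(self.frequencies, dtype=float)
        object.__setattr__(self, "frequencies", freqs)
        if freqs.shape != (len(self.alphabet),):
            raise MotifError(
                f"background has {freqs.shape} frequencies for alphabet "
                f"of size {len(self.alphabet)}"
            )
        if not np.all(freqs > 0):
            raise MotifError("every background frequency must be > 0")
        if abs(freqs.sum() - 1.0) > 1e-9:
            raise MotifError(f"background frequencies sum to {freqs.sum()!r}, not 1")

    @classmethod
    def uniform(cls, alphabet: str = AA_ALPHABET) -> "BackgroundModel":
        n = len(alphabet)
        return cls(np.full(n, 1.0 / n), alphabet)

    @classmethod
    def from_mapping(cls, freqs: Mapping[str, float],
                     alphabet: str = AA_ALPHABET) -> "BackgroundModel":
        return cls(np.array([freqs[a] for a in alphabet], dtype=float), alphabet)

    def __getitem__(self, letter: str) -> float:
        return float(self.frequencies[self.alphabet.index(letter)])

    def as_mapping(self) -> dict[str, float]:
        return {a: float(f) for a, f in zip(self.alphabet, self.frequencies)}


def estimate_background(sequences: Iterable[str],
                        alphabet: str = AA_ALPHABET) -> BackgroundModel:
    """Maximum-likelihood background composition with a +1 pseudocount per letter.

    Non-standard letters (X, B, Z, U, *) are excluded from counting.  Raises
    :class:`MotifError` if no standard residues are present at all.
    """
    seqs = list(sequences)
    if not seqs:
        raise MotifError("cannot estimate a background from zero sequences")
    n = len(alphabet)
    counts = np.zeros(n, dtype=float)
    for seq in seqs:
        enc = encode(seq, alphabet)
        std = enc[enc < n]
        counts += np.bincount(std, minlength=n)
    if counts.sum() == 0:
        raise MotifError("input contains no standard residues")
    counts += 1.0
    return BackgroundModel(counts / counts.sum(), alphabet)


@dataclass(frozen=True)
class MotifModel:
    """An ungapped probabilistic motif (PWM) with count/probability/log-odds views.

    ``log_odds[i, a] = log2(probabilities[i, a] / background[a])`` in bits.
    """

    motif_id: str
    counts: np.ndarray            # (width, |alphabet|), non-negative reals
    probabilities: np.ndarray     # rows sum to 1
    log_odds: np.ndarray          # bits
    nsites: float
    background: BackgroundModel

    def __post_init__(self) -> None:
        w = self.width
        n = len(self.background.alphabet)
        for name in ("counts", "probabilities", "log_odds"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.shape != (w, n):
                raise MotifError(f"{name} has shape {arr.shape}, expected {(w, n)}")
        row_sums = self.probabilities.sum(axis=1)
        if np.any(np.abs(row_sums - 1.0) > 1e-9):
            raise MotifError("probability rows must each sum to 1")

    @property
    def width(self) -> int:
        return int(np.asarray(self.counts).shape[0])

    @property
    def alphabet(self) -> str:
        return self.background.alphabet

    @property
    def consensus(self) -> str:
        return "".join(self.alphabet[i] for i in self.probabilities.argmax(axis=1))

    def information_content(self) -> float:
        """Total relative entropy vs the background, in bits."""
        p = self.probabilities
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, p * np.log2(p / self.background.frequencies), 0.0)
        return float(terms.sum())


def build_motif_model(instances: Sequence[str], background: BackgroundModel,
                      pseudocount: float = DEFAULT_PSEUDOCOUNT,
                      motif_id: str = "motif",
                      allow_any_width: bool = False) -> MotifModel:
    """Build a PWM from equal-length ungapped instance strings.

    ``probabilities[i, a] = (counts[i, a] + pseudocount * background[a]) /
    (nsites_i + pseudocount)``, where ``nsites_i`` counts standard letters in
    column i (ambiguous letters are excluded from counting).

    Raises on ragged instances, zero instances, and widths outside the
    discovery bound [6, 50] unless ``allow_any_width``.
    """
    if not instances:
        raise MotifError("cannot build a motif from zero instances")
    width = len(instances[0])
    if any(len(s) != width for s in instances):
        raise MotifError("motif instances must all have the same length")
    if not allow_any_width and not (MIN_WIDTH <= width <= MAX_WIDTH):
        raise MotifError(
            f"width {width} outside the discovery bound [{MIN_WIDTH}, {MAX_WIDTH}]"
            " (pass allow_any_width=True to override)"
        )
    if pseudocount < 0:
        raise MotifError("pseudocount must be non-negative")
    n = len(background.alphabet)
    counts = np.zeros((width, n), dtype=float)
    for s in instances:
        enc = encode(s, background.alphabet)
        for i, a in enumerate(enc):
            if a < n:
                counts[i, a] += 1.0
    return motif_from_counts(counts, background, pseudocount, motif_id)


def motif_from_counts(counts: np.ndarray, background: BackgroundModel,
                      pseudocount: float = DEFAULT_PSEUDOCOUNT,
                      motif_id: str = "motif") -> MotifModel:
    """Turn a (possibly fractional) count matrix into a normalized MotifModel."""
    counts = np.asarray(counts, dtype=float)
    nsites_per_col = counts.sum(axis=1)
    denom = nsites_per_col + pseudocount
    if np.any(denom <= 0):
        raise MotifError("zero observations and zero pseudocount in some column")
    probs = (counts + pseudocount * background.frequencies) / denom[:, None]
    # guard against exact zeros (possible only at pseudocount 0)
    with np.errstate(divide="ignore"):
        log_odds = np.log2(probs / background.frequencies)
    return MotifModel(
        motif_id=motif_id,
        counts=counts,
        probabilities=probs,
        log_odds=log_odds,
        nsites=float(nsites_per_col.max()) if counts.size else 0.0,
        background=background,
    )


def motif_from_probabilities(probs: np.ndarray, background: BackgroundModel,
                             motif_id: str = "motif",
                             nsites: float = 20.0) -> MotifModel:
    """Wrap an explicit probability matrix (e.g. read from a motif file)."""
    probs = np.asarray(probs, dtype=float)
    with np.errstate(divide="ignore"):
        log_odds = np.log2(probs / background.frequencies)
    return MotifModel(
        motif_id=motif_id,
        counts=probs * nsites,
        probabilities=probs,
        log_odds=log_odds,
        nsites=float(nsites),
        background=background,
    )


@dataclass(frozen=True)
class ScoreDistribution:
    """Exact PMF of integer-scaled window scores under the background.

    ``pmf[k]`` is the null probability of integer score ``min_score + k``;
    one integer unit equals ``1/scale`` bits.  Quantization rounds log-odds
    *down*, so the resulting p-values are conservative (never smaller than
    the unquantized truth).
    """

    min_score: int
    pmf: np.ndarray
    scale: int
    int_scores: np.ndarray   # (width, |alphabet|+1): quantized scores, 0 for ambiguous
    survival: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        sf = np.cumsum(self.pmf[::-1])[::-1]
        object.__setattr__(self, "survival", sf)

    def p_value(self, int_score: int) -> float:
        """Null probability of an integer window score >= ``int_score``."""
        k = int_score - self.min_score
        if k <= 0:
            return 1.0
        if k >= len(self.pmf):
            # windows are scored with the same quantized matrix, so scores
            # never exceed the support; clamp defensively to the top mass
            return float(self.survival[-1])
        return float(self.survival[k])


def score_distribution(motif: MotifModel, background: BackgroundModel | None = None,
                       scale: int = DEFAULT_SCALE) -> ScoreDistribution:
    """Exact null distribution of window scores by column-wise convolution.

    The log-odds matrix is quantized to ``floor(score * scale)`` (conservative
    p-values); minus infinity entries (zero probability cells at pseudocount
    0) are clamped to the most negative finite column score minus one bin so
    the support stays finite.
    """
    if background is None:
        background = motif.background
    if scale < 1:
        raise MotifError("scale must be a positive integer")
    lo = motif.log_odds * scale
    finite = np.isfinite(lo)
    if not finite.all():
        floor_val = lo[finite].min() - scale if finite.any() else -scale
        lo = np.where(finite, lo, floor_val)
    int_scores = np.floor(lo).astype(np.int64)
    n = len(background.alphabet)
    # ambiguous letters contribute zero log-odds in scanning
    int_scores = np.hstack([int_scores, np.zeros((motif.width, 1), dtype=np.int64)])

    pmf = np.array([1.0])
    offset = 0
    for i in range(motif.width):
        col = int_scores[i, :n]
        cmin, cmax = int(col.min()), int(col.max())
        new = np.zeros(len(pmf) + (cmax - cmin), dtype=float)
        for a in range(n):
            sh = int(col[a]) - cmin
            new[sh:sh + len(pmf)] += pmf * background.frequencies[a]
        pmf = new
        offset += cmin
    total = pmf.sum()
    if abs(total - 1.0) > 1e-9:
        pmf = pmf / total
    return ScoreDistribution(min_score=offset, pmf=pmf, scale=scale,
                             int_scores=int_scores)


@dataclass(frozen=True)
class MotifHit:
    """One scored window: 0-based ``start``, score in bits, position p-value."""

    motif_id: str
    sequence_id: str
    start: int
    width: int
    score: float
    p_value: float

    @property
    def end(self) -> int:
        """0-based exclusive end."""
        return self.start + self.width

    @property
    def start_1based(self) -> int:
        return self.start + 1

    @property
    def end_1based(self) -> int:
        """1-based inclusive end, matching crystal-structure residue numbering."""
        return self.start + self.width

    def overlaps(self, other: "MotifHit") -> bool:
        return self.start < other.end and other.start < self.end


def scan_sequence(sequence: str, motif: MotifModel,
                  background: BackgroundModel | None = None,
                  p_threshold: float = DEFAULT_P_THRESHOLD,
                  sequence_id: str = "query",
                  dist: ScoreDistribution | None = None) -> list[MotifHit]:
    """All windows whose position p-value is <= ``p_threshold``, sorted by start.

    Ambiguous letters contribute zero log-odds; windows with more than 50%
    ambiguous letters are skipped.  A sequence shorter than the motif yields
    an empty result with a warning rather than an error.
    """
    if background is None:
        background = motif.background
    w = motif.width
    if len(sequence) < w:
        warnings.warn(
            f"sequence {sequence_id!r} (length {len(sequence)}) is shorter than "
            f"motif {motif.motif_id!r} (width {w}); no windows scanned",
            stacklevel=2,
        )
        return []
    if dist is None:
        dist = score_distribution(motif, background)
    n = len(background.alphabet)
    enc = encode(sequence, background.alphabet)
    n_windows = len(sequence) - w + 1
    scores = np.zeros(n_windows, dtype=np.int64)
    ambig = (enc >= n).astype(np.int64)
    ambig_in_window = np.convolve(ambig, np.ones(w, dtype=np.int64), mode="valid")
    for i in range(w):
        scores += dist.int_scores[i][enc[i:i + n_windows]]
    hits: list[MotifHit] = []
    for j in range(n_windows):
        if ambig_in_window[j] * 2 > w:
            continue
        p = dist.p_value(int(scores[j]))
        if p <= p_threshold:
            hits.append(MotifHit(
                motif_id=motif.motif_id, sequence_id=sequence_id, start=j,
                width=w, score=scores[j] / dist.scale, p_value=p,
            ))
    return hits


def sequence_p_value(sequence: str, motif: MotifModel,
                     background: BackgroundModel | None = None,
                     dist: ScoreDistribution | None = None,
                     sequence_id: str = "query") -> float:
    """Sequence-level p-value of the best window: 1 - (1 - p_min)^W.

    W is the number of scorable windows.  Under the exact null this is the
    independence approximation to P(best window scores this well); positive
    dependence between overlapping windows and the conservative score
    quantization make it stochastically >= Uniform(0,1) on background-only
    sequences.
    """
    if background is None:
        background = motif.background
    hits = scan_sequence(sequence, motif, background, p_threshold=1.0,
                         sequence_id=sequence_id, dist=dist)
    if not hits:
        return 1.0
    p_min = min(h.p_value for h in hits)
    return float(-np.expm1(len(hits) * np.log1p(-p_min))) if p_min < 1.0 else 1.0


def best_hit(hits: Iterable[MotifHit]) -> MotifHit | None:
    """Lowest-p-value hit; ties broken by smaller start."""
    best: MotifHit | None = None
    for h in hits:
        if best is None or (h.p_value, h.start) < (best.p_value, best.start):
            best = h
    return best


@dataclass(frozen=True)
class MotifArchitecture:
    """Per-sequence summary of which motifs are present and whether in order.

    ``complete`` means: every one of the nine ACS motifs has a retained hit,
    the retained hits' starts strictly increase with motif index, and no two
    retained hits overlap — the full ordered architecture the classification
    rule requires.
    """

    sequence_id: str
    presence: dict[str, MotifHit | None]
    ordered: bool
    aat_present: bool
    complete: bool


def assess_architecture(hits: Iterable[MotifHit],
                        required: Sequence[str] = ACS_MOTIF_IDS,
                        aat_id: str = AAT_MOTIF_ID) -> MotifArchitecture:
    """Reduce scan hits to an ordered-architecture verdict.

    For each required motif the lowest-p-value hit is retained (ties to the
    smaller start).  ``ordered`` is False when retained hits are not at
    strictly increasing starts in motif order or when any two overlap.
    """
    by_motif: dict[str, list[MotifHit]] = {}
    seq_ids = set()
    for h in hits:
        by_motif.setdefault(h.motif_id, []).append(h)
        seq_ids.add(h.sequence_id)
    if len(seq_ids) > 1:
        raise MotifError(f"hits refer to multiple sequences: {sorted(seq_ids)}")
    sequence_id = seq_ids.pop() if seq_ids else ""

    presence: dict[str, MotifHit | None] = {
        m: best_hit(by_motif.get(m, [])) for m in required
    }
    kept = [presence[m] for m in required if presence[m] is not None]
    all_present = all(presence[m] is not None for m in required)

    ordered = True
    retained = [presence[m] for m in required]
    last_end = -1
    prev_start = -1
    for h in retained:
        if h is None:
            continue
        if h.start <= prev_start or h.start < last_end:
            ordered = False
            break
        prev_start = h.start
        last_end = h.end
    # any overlap among retained hits (also across non-adjacent motifs)
    if ordered:
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                if kept[i].overlaps(kept[j]):
                    ordered = False
    aat = best_hit(by_motif.get(aat_id, []))
    return MotifArchitecture(
        sequence_id=sequence_id,
        presence=presence,
        ordered=ordered,
        aat_present=aat is not None,
        complete=all_present and ordered,
    )


def hits_to_table(hits: Iterable[MotifHit]):
    """Scan output as a DataFrame with 1-based inclusive coordinates."""
    import pandas as pd

    rows = [
        {
            "sequence_id": h.sequence_id,
            "motif_id": h.motif_id,
            "start_1based": h.start_1based,
            "end_1based": h.end_1based,
            "score_bits": h.score,
            "p_value": h.p_value,
        }
        for h in hits
    ]
    return pd.DataFrame(rows, columns=["sequence_id", "motif_id", "start_1based",
                                       "end_1based", "score_bits", "p_value"])
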