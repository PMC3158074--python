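"""Position-weight-matrix scanning of regulatory sequences.

A :class:`MotifMatrix` holds additive per-position base scores in the native
units of the matrix (no log-odds conversion or background model is applied,
because published low/high binding-potential thresholds are quoted in those
native units).  Scanning slides the matrix over both strands of a sequence and
returns the best-scoring window.

Coordinate convention: positions are 0-based, half-open.  Human-readable
reports (BED column 2/3) keep the same convention; only the CLI's text
summaries print 1-based coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, FormatError

ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: index used for ambiguous (N) bases in encoded sequences
_N_CODE = 4


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MotifMatrix:
    """Position-specific scoring matrix over the DNA alphabet.

    Parameters
    ----------
    name : str
        Identifier of the motif (e.g. the factor it models).
    scores : ndarray of shape (width, 4)
        Additive score for each position x base, columns ordered A, C, G, T.
    low_threshold : float, optional
        Score below which a site is classified as *low* binding potential.
        Strict inequality: ``score < low_threshold`` is low, anything else
        (including the threshold itself) is high.
    """

    name: str
    scores: np.ndarray
    low_threshold: float | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 4:
            raise FormatError(
                f"PWM '{self.name}' must be rectangular with 4 columns (A,C,G,T); "
                f"got shape {self.scores.shape}"
            )
        if self.scores.shape[0] < 1:
            raise FormatError(f"PWM '{self.name}' must have width >= 1")

    @property
    def width(self) -> int:
        return self.scores.shape[0]

    @property
    def max_score(self) -> float:
        """Maximal achievable score (sum of per-position maxima)."""
        return float(self.scores.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        """A maximal-scoring word (first base by A<C<G<T on per-position ties)."""
        return "".join(ALPHABET[i] for i in self.scores.argmax(axis=1))

    def reverse_complement(self) -> "MotifMatrix":
        """Matrix scoring the minus strand: rows reversed, columns A<->T, C<->G."""
        return MotifMatrix(self.name, self.scores[::-1, ::-1], self.low_threshold)


@dataclass(frozen=True)
class SiteHit:
    """Best-scoring motif window on a sequence (0-based half-open start)."""

    sequence_id: str
    position: int
    strand: str
    score: float


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a DNA string to integer codes A=0 C=1 G=2 T=3 N=4."""
    table = np.full(256, -1, dtype=np.int8)
    for i, base in enumerate(ALPHABET):
        table[ord(base)] = i
    table[ord("N")] = _N_CODE
    codes = table[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]
    if (codes < 0).any():
        bad = seq[int(np.argmax(codes < 0))]
        raise FormatError(f"sequence contains non-DNA character {bad!r}")
    return codes.astype(np.intp)


def _extended_scores(pwm: MotifMatrix) -> np.ndarray:
    """Score table with a 5th column for N = per-position minimum entry."""
    return np.column_stack([pwm.scores, pwm.scores.min(axis=1)])


def score_window(pwm: MotifMatrix, seq: str, pos: int, strand: str = "+") -> float:
    """Score one window of ``seq`` starting at ``pos`` on the given strand.

    The minus-strand score of a window equals the plus-strand score of its
    reverse complement.  N bases contribute the position's minimum entry.
    """
    if strand not in "+-":
        raise ContractError(f"strand must be '+' or '-', got {strand!r}")
    if pos < 0 or pos + pwm.width > len(seq):
        raise ContractError(
            f"window [{pos}, {pos + pwm.width}) out of bounds for sequence of "
            f"length {len(seq)}"
        )
    codes = encode_sequence(seq[pos : pos + pwm.width])
    matrix = pwm if strand == "+" else pwm.reverse_complement()
    ext = _extended_scores(matrix)
    # sequential accumulation in position order, matching the sliding-window
    # scanner bit for bit so exact score ties agree between the two paths
    total = 0.0
    for j in range(pwm.width):
        total += float(ext[j, codes[j]])
    return total


def _window_scores(ext: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """All window scores of an encoded sequence for one (extended) matrix."""
    width = ext.shape[0]
    n_win = codes.size - width + 1
    out = np.zeros(n_win)
    for j in range(width):
        out += ext[j, codes[j : j + n_win]]
    return out


def best_site_score(pwm: MotifMatrix, seq: str, sequence_id: str = "") -> SiteHit:
    """Best motif window over all positions and both strands.

    Ties are broken by smallest start position, then by the plus strand.
    """
    if len(seq) < pwm.width:
        raise ContractError(
            f"sequence length {len(seq)} shorter than PWM width {pwm.width}"
        )
    codes = encode_sequence(seq)
    fwd = _window_scores(_extended_scores(pwm), codes)
    rev = _window_scores(_extended_scores(pwm.reverse_complement()), codes)
    best = max(fwd.max(), rev.max())
    # earliest position wins; '+' beats '-' at the same position
    fwd_pos = np.flatnonzero(fwd == best)
    rev_pos = np.flatnonzero(rev == best)
    cand: list[tuple[int, int, str]] = []
    if fwd_pos.size:
        cand.append((int(fwd_pos[0]), 0, "+"))
    if rev_pos.size:
        cand.append((int(rev_pos[0]), 1, "-"))
    pos, _, strand = min(cand)
    return SiteHit(sequence_id=sequence_id, position=pos, strand=strand, score=float(best))


def classify_binding_potential(score: float, pwm: MotifMatrix) -> str:
    """Classify a score as ``"low"`` (strictly below the threshold) or ``"high"``."""
    if pwm.low_threshold is None:
        raise ContractError(f"PWM '{pwm.name}' carries no low/high threshold")
    return "low" if score < pwm.low_threshold else "high"


def piggyback_candidates(
    sequences: Iterable, pwm_primary: MotifMatrix, pwm_partner: MotifMatrix
) -> list[str]:
    """Sequences a factor may bind indirectly by piggybacking a partner factor.

    A candidate has a *low* best score for the primary matrix and a *high*
    best score for the partner matrix, mirroring the low-AP2alpha/high-p53
    filter used to flag indirect (protein-protein mediated) binding.  Note the
    partner is scored here with a single generic PWM; dimeric-site models such
    as p53mh are approximated by that single matrix.
    """
    out: list[str] = []
    for rec in sequences:
        primary = best_site_score(pwm_primary, rec.sequence, rec.id)
        partner = best_site_score(pwm_partner, rec.sequence, rec.id)
        if (
            classify_binding_potential(primary.score, pwm_primary) == "low"
            and classify_binding_potential(partner.score, pwm_partner) == "high"
        ):
            out.append(rec.id)
    return out


def site_occurrence_comparison(
    named_sets: Mapping[str, Sequence], pwm: MotifMatrix
) -> tuple[dict[str, float], pd.DataFrame]:
    """Fraction of sequences per named set carrying a high-scoring site.

    For each set (typically the top-k most strongly bound sequences of one
    experiment) the fraction of members whose best site scores at or above the
    matrix threshold is computed, plus the pairwise ratio matrix between sets.
    """
    if pwm.low_threshold is None:
        raise ContractError(f"PWM '{pwm.name}' carries no low/high threshold")
    fractions: dict[str, float] = {}
    for label, seqs in named_sets.items():
        seqs = list(seqs)
        if not seqs:
            raise ContractError(f"set '{label}' is empty")
        n_high = sum(
            best_site_score(pwm, rec.sequence, rec.id).score >= pwm.low_threshold
            for rec in seqs
        )
        fractions[label] = n_high / len(seqs)
    labels = list(fractions)
    ratio = pd.DataFrame(
        [
            [
                fractions[a] / fractions[b] if fractions[b] > 0 else np.inf
                for b in labels
            ]
            for a in labels
        ],
        index=labels,
        columns=labels,
    )
    return fractions, ratio


def scan_all(pwm: MotifMatrix, sequences: Iterable) -> list[SiteHit]:
    """Best hit per sequence, in input order."""
    return [best_site_score(pwm, rec.sequence, rec.id) for rec in sequences]


def write_bed(hits: Iterable[SiteHit], path, width: int = 1) -> None:
    """Write best hits as BED6 (0-based half-open; score col 5, strand col 6)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.sequence_id}\t{h.position}\t{h.position + width}\t"
                f"{h.sequence_id}_site\t{h.score:g}\t{h.strand}\n"
            )
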