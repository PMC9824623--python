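"""Candidate scanning and per-candidate feature measurements.

A *candidate* is a fixed-width window centred on one exact occurrence of the
TGTC core (either strand).  From it the over-representation method derives
four features — position relative to the start codon (P), a significance
z-score for the candidate's motif word (Sc), genome-wide occurrence of the
word (O), and the fraction of auxin-responsive promoters carrying the word
(D) — and the discriminant method derives the Z-curve triple and GC%.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_formats import ExpressionRecord, GeneModel, SequenceRecord

__all__ = [
    "CandidateMotif",
    "BackgroundModel",
    "revcomp",
    "find_all",
    "count_overlapping",
    "scan_candidates",
    "candidate_word",
    "compute_position",
    "zscore_from_expected",
    "compute_significance_score",
    "compute_occurrence",
    "compute_density",
    "zcurve",
    "gc_content",
]

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_CORE = "TGTC"
DEFAULT_WINDOW = 100


def revcomp(seq: str) -> str:
    """Reverse complement over the ACGTN alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def find_all(haystack: str, needle: str) -> list[int]:
    """All (overlapping) start positions of ``needle`` in ``haystack``."""
    out = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def count_overlapping(haystack: str, needle: str) -> int:
    return len(find_all(haystack, needle))


@dataclass(frozen=True)
class CandidateMotif:
    """A core-anchored window: the object being classified.

    ``core_hits`` lists every core occurrence inside the window as
    ``(offset, strand)`` pairs sorted by offset — the anchoring core plus any
    neighbouring cores, which feed the site-context evidence.
    """

    seq_id: str
    start: int
    end: int
    strand: str
    core_start: int
    window_sequence: str
    core_hits: tuple[tuple[int, str], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.window_sequence):
            raise ValueError("window sequence length does not match interval")
        if not self.core_hits:
            raise ValueError("candidate window must contain at least one core")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def core_offset(self) -> int:
        """Offset of the anchoring core within the window."""
        return self.core_start - self.start


def scan_candidates(
    sequences: Sequence[SequenceRecord],
    core: str = DEFAULT_CORE,
    window: int = DEFAULT_WINDOW,
) -> list[CandidateMotif]:
    """Locate every exact core occurrence on either strand of every record.

    Reverse-strand hits are found through the reverse complement of the core
    on the forward sequence.  The window of ``window`` bp is centred on the
    core; windows clipped by a sequence edge, and windows containing N, are
    dropped (with a debug log).  For a palindromic core only forward-strand
    candidates are emitted (the two strands coincide).
    """
    if not sequences:
        raise ValueError("empty sequence set")
    if window < len(core):
        raise ValueError(f"window ({window}) shorter than core ({len(core)})")
    core = core.upper()
    rc_core = revcomp(core)
    left = (window - len(core)) // 2
    candidates: list[CandidateMotif] = []
    for rec in sequences:
        seq = rec.sequence
        hits = [(pos, "+") for pos in find_all(seq, core)]
        if rc_core != core:
            hits += [(pos, "-") for pos in find_all(seq, rc_core)]
        hits.sort()
        for pos, strand in hits:
            w_start = pos - left
            w_end = w_start + window
            if w_start < 0 or w_end > len(seq):
                logger.debug("dropping edge-clipped candidate %s:%d", rec.id, pos)
                continue
            win = seq[w_start:w_end]
            if "N" in win:
                logger.debug("dropping N-containing window %s:%d", rec.id, pos)
                continue
            in_win = [(p - w_start, s) for p, s in hits if w_start <= p <= w_end - len(core)]
            candidates.append(
                CandidateMotif(
                    seq_id=rec.id,
                    start=w_start,
                    end=w_end,
                    strand=strand,
                    core_start=pos,
                    window_sequence=win,
                    core_hits=tuple(sorted(in_win)),
                )
            )
    return candidates


def candidate_word(candidate: CandidateMotif, word_length: int = 6, core_length: int = 4) -> str:
    """The candidate's motif word: core-oriented ``word_length``-mer at the core.

    For a '+' candidate this is the window sequence starting at the core; for
    a '-' candidate the reverse complement of the corresponding stretch, so the
    word always starts with the core.  Falls back to the available stretch when
    the window is too short to extend.
    """
    off = candidate.core_offset
    win = candidate.window_sequence
    if candidate.strand == "+":
        return win[off : min(off + word_length, len(win))]
    lo = max(0, off + core_length - word_length)
    return revcomp(win[lo : off + core_length])


def compute_position(candidate: CandidateMotif, gene: GeneModel) -> int:
    """Signed offset of the candidate from the A of the ATG, transcription-oriented.

    Upstream (promoter side) is negative: a motif starting 354 bp upstream of
    the start codon returns -354 on either gene strand.
    """
    if candidate.seq_id != gene.chrom:
        raise ValueError(
            f"candidate on {candidate.seq_id!r} but gene {gene.gene_id!r} on {gene.chrom!r}"
        )
    if gene.strand == "+":
        return candidate.start - gene.cds_start
    return gene.cds_start - candidate.start


class BackgroundModel:
    """Order-k Markov model of the training sequences (forward strand).

    Supplies the expected count of a word for the significance z-score.  The
    initial context distribution is the empirical k-mer frequency; conditional
    frequencies per context sum to one.
    """

    def __init__(
        self,
        order: int,
        initial: Mapping[str, float],
        transitions: Mapping[str, Mapping[str, float]],
    ) -> None:
        if order < 0:
            raise ValueError("order must be >= 0")
        self.order = order
        self.initial = dict(initial)
        self.transitions = {k: dict(v) for k, v in transitions.items()}

    @classmethod
    def fit(cls, sequences: Iterable[SequenceRecord], order: int = 2) -> "BackgroundModel":
        init_counts: Counter[str] = Counter()
        trans_counts: dict[str, Counter[str]] = {}
        for rec in sequences:
            seq = rec.sequence
            for i in range(len(seq) - order):
                ctx = seq[i : i + order]
                nxt = seq[i + order]
                if "N" in ctx or nxt == "N":
                    continue
                init_counts[ctx] += 1
                trans_counts.setdefault(ctx, Counter())[nxt] += 1
        if not init_counts:
            raise ValueError("no usable context in training sequences")
        total = sum(init_counts.values())
        initial = {k: v / total for k, v in init_counts.items()}
        transitions = {
            ctx: {b: n / sum(cnt.values()) for b, n in cnt.items()}
            for ctx, cnt in trans_counts.items()
        }
        return cls(order=order, initial=initial, transitions=transitions)

    def word_probability(self, word: str) -> float:
        """Probability of observing ``word`` at a fixed position under the model."""
        word = word.upper()
        if len(word) <= self.order:
            raise ValueError(f"word {word!r} shorter than model context ({self.order})")
        ctx = word[: self.order]
        try:
            p = self.initial[ctx] if self.order > 0 else 1.0
            for i in range(self.order, len(word)):
                p *= self.transitions[word[i - self.order : i]][word[i]]
        except KeyError as exc:
            raise ValueError(f"background model lacks frequencies for context {exc}") from exc
        return p

    def expected_count(self, word: str, total_positions: int) -> float:
        """Expected both-strand occurrences of ``word`` over ``total_positions``
        per-strand scan positions."""
        if total_positions <= 0:
            raise ValueError("total_positions must be positive")
        p = self.word_probability(word)
        rc = revcomp(word)
        p_rc = p if rc == word else self.word_probability(rc)
        return total_positions * (p + p_rc)

    def to_dict(self) -> dict:
        return {"order": self.order, "initial": self.initial, "transitions": self.transitions}

    @classmethod
    def from_dict(cls, d: dict) -> "BackgroundModel":
        return cls(order=int(d["order"]), initial=d["initial"], transitions=d["transitions"])


def zscore_from_expected(observed_count: float, expected_count: float) -> float:
    """Poisson z-score ``(observed - E) / sqrt(E)`` with an expectation floor of 0.5."""
    e = max(float(expected_count), 0.5)
    return (float(observed_count) - e) / math.sqrt(e)


def compute_significance_score(
    observed_count: int,
    background: BackgroundModel,
    total_positions: int,
    *,
    word: str,
) -> float:
    """Over-representation z-score of ``word`` against the background model."""
    return zscore_from_expected(observed_count, background.expected_count(word, total_positions))


def compute_occurrence(core: str, genome: Sequence[SequenceRecord]) -> int:
    """Exact occurrences of ``core`` on both strands across all records.

    A palindromic word is counted on both strands, i.e. twice per forward hit.
    """
    if not genome:
        raise ValueError("empty genome")
    core = core.upper()
    rc = revcomp(core)
    total = 0
    for rec in genome:
        total += count_overlapping(rec.sequence, core)
        total += count_overlapping(rec.sequence, rc)
    return total


def compute_density(
    core: str,
    promoters: Sequence[SequenceRecord],
    expression: Sequence[ExpressionRecord],
    fc_threshold: float = 2.0,
) -> float:
    """Fraction of auxin-responsive promoters containing the word (either strand).

    A gene is responsive when ``|log2FC| >= log2(fc_threshold)`` — two-fold up
    or down by default.
    """
    if fc_threshold <= 0:
        raise ValueError("fc_threshold must be positive")
    cut = math.log2(fc_threshold)
    responsive = {r.gene_id for r in expression if abs(r.log2_fc) >= cut}
    pool = [p for p in promoters if p.id in responsive]
    if not pool:
        raise ValueError("no responsive promoters: density is undefined")
    core = core.upper()
    rc = revcomp(core)
    hit = sum(1 for p in pool if core in p.sequence or rc in p.sequence)
    return hit / len(pool)


def _base_frequencies(sequence: str) -> tuple[float, float, float, float]:
    seq = sequence.upper().replace("N", "")
    if not seq:
        raise ValueError("sequence empty after removing N")
    n = len(seq)
    return (
        seq.count("A") / n,
        seq.count("C") / n,
        seq.count("G") / n,
        seq.count("T") / n,
    )


def zcurve(sequence: str) -> tuple[float, float, float]:
    """Z-curve composition triple of a DNA sequence.

    With base frequencies a1, c1, g1, t1:
    x1 = (a1+g1)-(c1+t1) (purine/pyrimidine), y1 = (a1+c1)-(g1+t1)
    (amino/keto), z1 = (a1+t1)-(g1+c1) (weak/strong bonds); each in [-1, 1].
    """
    a1, c1, g1, t1 = _base_frequencies(sequence)
    return (a1 + g1) - (c1 + t1), (a1 + c1) - (g1 + t1), (a1 + t1) - (g1 + c1)


def gc_content(sequence: str) -> float:
    """(G + C) / length, N excluded."""
    _, c1, g1, _ = _base_frequencies(sequence)
    return g1 + c1
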