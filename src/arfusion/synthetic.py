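"""Synthetic desk-scale benchmark: promoters with planted composite AuxREs.

The generator emulates the data shapes of an ARF ChIP-Seq study: a set of
upstream (promoter) sequences in which a configurable fraction carries one
planted composite auxin response element — multiple TGTCTC cores with
controlled spacing and orientation — plus a narrowPeak file whose summits sit
on the planted elements (with optional decoy peaks on element-free ground)
and an auxin-response expression table in which planted genes are strongly
responsive.  All randomness flows from a single seed, so every artifact is
byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import revcomp
from .io_formats import ExpressionRecord, PeakRecord, SequenceRecord

__all__ = [
    "BenchmarkConfig",
    "generate_genome",
    "generate_expression",
    "generate_peaks",
    "generate_benchmark",
    "promoter_id",
]

BASES = "ACGT"


@dataclass(frozen=True)
class BenchmarkConfig:
    """Study conditions for the synthetic benchmark.

    Defaults: 400 promoters of 1.5 kb, half carrying a planted element of two
    TGTCTC cores spaced 5-50 nt apart (inside the <50 nt envelope typical of
    composite AuxREs), AT-rich background, planted genes at mean |log2FC| 2.0
    (sd 0.5) versus 0 for the rest, and 25% decoy peaks.
    """

    n_promoters: int = 400
    promoter_length: int = 1500
    planted_fraction: float = 0.5
    cores_per_element: int = 2
    core_word: str = "TGTCTC"
    spacing_min: int = 5
    spacing_max: int = 50
    orientation_mix: dict = field(
        default_factory=lambda: {"DR": 1 / 3, "ER": 1 / 3, "IR": 1 / 3}
    )
    composition: dict = field(
        default_factory=lambda: {"A": 0.3, "C": 0.2, "G": 0.2, "T": 0.3}
    )
    effect: float = 2.0  # mean |log2FC| of planted genes
    noise_sd: float = 0.5
    decoy_peak_fraction: float = 0.25
    peak_width_min: int = 150
    peak_width_max: int = 300
    summit_jitter: int = 10
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_promoters < 1 or self.promoter_length < 1:
            raise ValueError("n_promoters and promoter_length must be positive")
        for name in ("planted_fraction", "decoy_peak_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.cores_per_element < 1:
            raise ValueError("cores_per_element must be >= 1")
        if not 0 <= self.spacing_min <= self.spacing_max:
            raise ValueError("require 0 <= spacing_min <= spacing_max")
        if abs(sum(self.orientation_mix.values()) - 1.0) > 1e-9:
            raise ValueError("orientation_mix must sum to 1")
        if set(self.orientation_mix) - {"DR", "ER", "IR"}:
            raise ValueError("orientation_mix keys must be DR/ER/IR")
        if abs(sum(self.composition.values()) - 1.0) > 1e-9:
            raise ValueError("composition must sum to 1")
        if set(self.composition) != set("ACGT"):
            raise ValueError("composition must cover exactly A, C, G, T")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def promoter_id(i: int) -> str:
    return f"prom{i:05d}"


_BASE_ARRAY = np.array(list(BASES))


def _random_dna(rng: np.random.Generator, length: int, composition: dict) -> str:
    probs = [composition[b] for b in BASES]
    idx = rng.choice(4, size=length, p=probs)
    return "".join(_BASE_ARRAY[idx])


def _build_element(rng: np.random.Generator, cfg: BenchmarkConfig, composition: dict):
    """One composite element: core words joined by random spacers.

    Returns (sequence, core offsets within element, core strands, spacings,
    realized orientation classes).  The first core sits on '+'; each later
    core keeps the previous strand for DR and flips it for IR/ER, the realized
    class being read off the resulting strand pair.
    """
    word = cfg.core_word.upper()
    orientations = list(cfg.orientation_mix.keys())
    probs = list(cfg.orientation_mix.values())
    strands = ["+"]
    spacings: list[int] = []
    classes: list[str] = []
    for _ in range(cfg.cores_per_element - 1):
        wanted = str(rng.choice(orientations, p=probs))
        prev = strands[-1]
        nxt = prev if wanted == "DR" else ("-" if prev == "+" else "+")
        if prev == nxt:
            realized = "DR"
        else:
            realized = "IR" if (prev, nxt) == ("+", "-") else "ER"
        strands.append(nxt)
        classes.append(realized)
        spacings.append(int(rng.integers(cfg.spacing_min, cfg.spacing_max + 1)))
    parts = []
    offsets = []
    pos = 0
    for k, strand in enumerate(strands):
        if k > 0:
            spacer = _random_dna(rng, spacings[k - 1], composition)
            parts.append(spacer)
            pos += len(spacer)
        offsets.append(pos)
        parts.append(word if strand == "+" else revcomp(word))
        pos += len(word)
    return "".join(parts), offsets, strands, spacings, classes


def generate_genome(config: BenchmarkConfig) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Generate the promoter set and the planted-element truth table.

    The truth table has one row per planted promoter: promoter id, element
    start/end (0-based half-open within the promoter), core count, and
    comma-joined core strands, spacings and orientation classes.
    """
    rng = np.random.default_rng(config.seed)
    n_planted = int(round(config.planted_fraction * config.n_promoters))
    planted_idx = set(
        rng.choice(config.n_promoters, size=n_planted, replace=False).tolist()
    )
    records = []
    rows = []
    for i in range(config.n_promoters):
        pid = promoter_id(i)
        seq = _random_dna(rng, config.promoter_length, config.composition)
        if i in planted_idx:
            elem, offsets, strands, spacings, classes = _build_element(
                rng, config, config.composition
            )
            if len(elem) > config.promoter_length:
                raise ValueError(
                    f"element ({len(elem)} bp) longer than promoter "
                    f"({config.promoter_length} bp)"
                )
            start = int(rng.integers(0, config.promoter_length - len(elem) + 1))
            seq = seq[:start] + elem + seq[start + len(elem) :]
            rows.append(
                {
                    "promoter_id": pid,
                    "element_start": start,
                    "element_end": start + len(elem),
                    "n_cores": len(strands),
                    "core_offsets": ",".join(str(start + o) for o in offsets),
                    "core_strands": ",".join(strands),
                    "spacings": ",".join(map(str, spacings)),
                    "orientations": ",".join(classes),
                }
            )
        records.append(SequenceRecord(id=pid, sequence=seq))
    truth = pd.DataFrame(
        rows,
        columns=[
            "promoter_id",
            "element_start",
            "element_end",
            "n_cores",
            "core_offsets",
            "core_strands",
            "spacings",
            "orientations",
        ],
    )
    return records, truth


def generate_expression(truth: pd.DataFrame, config: BenchmarkConfig) -> list[ExpressionRecord]:
    """Auxin-response table: planted genes draw log2FC ~ +/-N(effect, sd),
    unplanted genes ~ N(0, sd)."""
    rng = np.random.default_rng(config.seed + 1)
    planted = set(truth["promoter_id"]) if len(truth) else set()
    out = []
    for i in range(config.n_promoters):
        pid = promoter_id(i)
        if pid in planted:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            fc = sign * rng.normal(config.effect, config.noise_sd)
        else:
            fc = rng.normal(0.0, config.noise_sd)
        out.append(ExpressionRecord(gene_id=pid, log2_fc=float(fc)))
    return out


def generate_peaks(
    truth: pd.DataFrame,
    config: BenchmarkConfig,
    max_tries_per_decoy: int = 10_000,
) -> list[PeakRecord]:
    """One peak per planted element (summit at the element centre +/- jitter)
    plus ``decoy_peak_fraction`` additional peaks on element-free ground."""
    rng = np.random.default_rng(config.seed + 2)
    L = config.promoter_length
    peaks: list[PeakRecord] = []
    taken: dict[str, list[tuple[int, int]]] = {}

    element_spans = {
        str(row.promoter_id): (int(row.element_start), int(row.element_end))
        for row in truth.itertuples()
    }

    for row in truth.itertuples():
        pid = str(row.promoter_id)
        width = int(rng.integers(config.peak_width_min, config.peak_width_max + 1))
        width = min(width, L)
        center = (int(row.element_start) + int(row.element_end)) // 2
        jitter = int(rng.integers(-config.summit_jitter, config.summit_jitter + 1))
        summit = min(max(center + jitter, 0), L - 1)
        start = summit - width // 2
        start = min(max(start, 0), L - width)
        peaks.append(
            PeakRecord(
                chrom=pid,
                start=start,
                end=start + width,
                name=f"peak_{pid}",
                score=0,
                strand=".",
                signal_value=float(row.n_cores),
                p_value=-1.0,
                q_value=-1.0,
                summit_offset=summit - start,
            )
        )
        taken.setdefault(pid, []).append((start, start + width))

    n_decoys = int(round(config.decoy_peak_fraction * len(peaks)))
    placed = 0
    tries = 0
    while placed < n_decoys:
        if tries >= max_tries_per_decoy * max(n_decoys, 1):
            raise RuntimeError(f"placed only {placed}/{n_decoys} decoy peaks")
        tries += 1
        i = int(rng.integers(0, config.n_promoters))
        pid = promoter_id(i)
        width = int(rng.integers(config.peak_width_min, config.peak_width_max + 1))
        width = min(width, L)
        start = int(rng.integers(0, L - width + 1))
        end = start + width
        elem = element_spans.get(pid)
        if elem is not None and elem[0] - 50 < end and start < elem[1] + 50:
            continue
        if any(s < end and start < e for s, e in taken.get(pid, [])):
            continue
        taken.setdefault(pid, []).append((start, end))
        peaks.append(
            PeakRecord(
                chrom=pid,
                start=start,
                end=end,
                name=f"decoy_{pid}_{placed}",
                score=0,
                strand=".",
                signal_value=0.0,
                p_value=-1.0,
                q_value=-1.0,
                summit_offset=width // 2,
            )
        )
        placed += 1
    return peaks


def generate_benchmark(config: BenchmarkConfig):
    """Generate the full fixture bundle.

    Returns ``(promoters, truth, expression, peaks)``.
    """
    promoters, truth = generate_genome(config)
    expression = generate_expression(truth, config)
    peaks = generate_peaks(truth, config)
    return promoters, truth, expression, peaks
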