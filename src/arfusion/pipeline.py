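"""End-to-end training, scanning and evaluation of the fusion predictor.

Training (on promoter-anchored sequence records, ChIP peaks and an
auxin-response expression table):

1. extract gold-standard summit windows and matched random controls;
2. scan TGTC-core candidates genome-wide and measure their features
   (position, significance z-score, occurrence, density, Z-curve, GC%);
3. fit the three-class discriminant (site / other-regulatory / background)
   for the f1/f2 plane;
4. build quantile fuzzy partitions and learn the proposition of every
   confidence region of the three learning graphs from the labelled
   gold/control candidates.

Scanning evaluates each candidate's three fuzzy-region masses (plus the
optional site-context mass) and fuses them by Dempster's rule into the final
belief and pignistic decision score.

The pipeline treats every input record as the upstream (promoter) sequence of
the identically named gene, with the start codon immediately past its 3' end;
explicit gene anchors can be supplied to override this.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import ds_engine, evaluation, features, fuzzy_regions
from .ds_engine import (
    DEFAULT_CONTEXT_RULES,
    ContextRule,
    MassFunction,
    SiteContext,
    TotalConflictError,
    decision_score,
    fuse_all,
    site_context_mass,
)
from .features import (
    BackgroundModel,
    CandidateMotif,
    candidate_word,
    revcomp,
    scan_candidates,
    zscore_from_expected,
)
from .fuzzy_regions import RegionGrid, RegionThresholds, default_grids, fuzzy_mass
from .io_formats import ExpressionRecord, GeneModel, PeakRecord, SequenceRecord
from .lda import DiscriminantModel, fit_lda, project

__all__ = [
    "PipelineConfig",
    "TrainedModel",
    "train",
    "scan",
    "score_candidates",
    "fuse_frame",
    "score_gold_records",
    "evaluate",
    "split_peaks",
    "save_model",
    "load_model",
    "NO_CORE_SCORE",
    "ALL_SOURCES",
    "METHOD1_SOURCES",
]

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1
ALL_SOURCES = ("sc_p", "o_d", "f1_f2")
METHOD1_SOURCES = ("sc_p", "o_d")
# sequences with no core at all rank just below a fully ignorant candidate
NO_CORE_SCORE = 0.49

_LDA_FEATURES = ("x1", "y1", "z1", "gc")


@dataclass(frozen=True)
class PipelineConfig:
    """Tunables of the predictor (defaults are the trained study conditions)."""

    core: str = "TGTC"
    window: int = 100
    word_length: int = 6
    fc_threshold: float = 2.0
    background_order: int = 2
    thresholds: RegionThresholds = field(default_factory=RegionThresholds)
    context_rules: tuple[ContextRule, ...] = DEFAULT_CONTEXT_RULES

    def to_dict(self) -> dict:
        return {
            "core": self.core,
            "window": self.window,
            "word_length": self.word_length,
            "fc_threshold": self.fc_threshold,
            "background_order": self.background_order,
            "thresholds": {
                "p4": self.thresholds.p4,
                "p3": self.thresholds.p3,
                "p2": self.thresholds.p2,
                "min_support": self.thresholds.min_support,
            },
            "context_rules": [
                {
                    "min_cores": r.min_cores,
                    "max_spacing": r.max_spacing,
                    "mass": list(r.mass),
                    "orientation": r.orientation,
                }
                for r in self.context_rules
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        thr = d.get("thresholds", {})
        return cls(
            core=d["core"],
            window=int(d["window"]),
            word_length=int(d["word_length"]),
            fc_threshold=float(d["fc_threshold"]),
            background_order=int(d["background_order"]),
            thresholds=RegionThresholds(
                p4=thr.get("p4", 0.90),
                p3=thr.get("p3", 0.70),
                p2=thr.get("p2", 0.55),
                min_support=thr.get("min_support", 5.0),
            ),
            context_rules=tuple(
                ContextRule(
                    min_cores=int(r["min_cores"]),
                    max_spacing=r["max_spacing"],
                    mass=tuple(r["mass"]),
                    orientation=r.get("orientation"),
                )
                for r in d.get("context_rules", [])
            )
            or DEFAULT_CONTEXT_RULES,
        )


@dataclass
class TrainedModel:
    """Serialized state of a trained predictor."""

    config: PipelineConfig
    background: BackgroundModel
    total_positions: int
    word_stats: dict[str, dict[str, float]]
    lda: DiscriminantModel
    grids: dict[str, RegionGrid]

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "config": self.config.to_dict(),
            "background": self.background.to_dict(),
            "total_positions": self.total_positions,
            "word_stats": self.word_stats,
            "lda": self.lda.to_dict(),
            "grids": {k: g.to_dict() for k, g in self.grids.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainedModel":
        version = d.get("schema_version")
        if version != SCHEMA_VERSION:
            raise ValueError(f"unsupported model schema version {version!r}")
        return cls(
            config=PipelineConfig.from_dict(d["config"]),
            background=BackgroundModel.from_dict(d["background"]),
            total_positions=int(d["total_positions"]),
            word_stats=d["word_stats"],
            lda=DiscriminantModel.from_dict(d["lda"]),
            grids={k: RegionGrid.from_dict(g) for k, g in d["grids"].items()},
        )


def save_model(model: TrainedModel, path) -> None:
    Path(path).write_text(json.dumps(model.to_dict()))


def load_model(path) -> TrainedModel:
    try:
        data = json.loads(Path(path).read_text())
        return TrainedModel.from_dict(data)
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise ValueError(f"corrupt or incompatible model file {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Feature assembly


def _default_anchor(rec_id: str, length: int) -> GeneModel:
    return GeneModel(gene_id=rec_id, chrom=rec_id, strand="+", cds_start=length)


def _anchors(
    promoters: Sequence[SequenceRecord],
    gene_models: Mapping[str, GeneModel] | None,
) -> dict[str, GeneModel]:
    out = {}
    for rec in promoters:
        if gene_models and rec.id in gene_models:
            out[rec.id] = gene_models[rec.id]
        else:
            out[rec.id] = _default_anchor(rec.id, len(rec))
    return out


def _kmer_counts(promoters: Sequence[SequenceRecord], k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for rec in promoters:
        seq = rec.sequence
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            counts[w] = counts.get(w, 0) + 1
    return counts


def compute_word_stats(
    words: set[str],
    promoters: Sequence[SequenceRecord],
    expression: Sequence[ExpressionRecord],
    background: BackgroundModel,
    fc_threshold: float,
) -> tuple[dict[str, dict[str, float]], int]:
    """Occurrence, significance z-score and responsive-promoter density for
    every distinct motif word, from single passes over the sequence set."""
    if not words:
        raise ValueError("no motif words to score")
    k = len(next(iter(words)))
    if any(len(w) != k for w in words):
        # words clipped at sequence edges: score them individually
        k = max(len(w) for w in words)
    counts = _kmer_counts(promoters, k)
    total_positions = sum(max(len(r) - k + 1, 0) for r in promoters)

    cut = np.log2(fc_threshold)
    responsive_ids = {r.gene_id for r in expression if abs(r.log2_fc) >= cut}
    responsive = [p for p in promoters if p.id in responsive_ids]
    if not responsive:
        raise ValueError("no responsive promoters: density is undefined")
    resp_kmers = []
    for rec in responsive:
        seq = rec.sequence
        resp_kmers.append({seq[i : i + k] for i in range(len(seq) - k + 1)})

    stats = {}
    for w in words:
        if len(w) == k:
            occ = counts.get(w, 0) + counts.get(revcomp(w), 0)
        else:  # edge-clipped short word: direct scan
            occ = features.compute_occurrence(w, promoters)
        sc = zscore_from_expected(occ, background.expected_count(w, total_positions))
        rc = revcomp(w)
        if len(w) == k:
            dens = sum(1 for s in resp_kmers if w in s or rc in s) / len(resp_kmers)
        else:
            dens = sum(
                1 for rec in responsive if w in rec.sequence or rc in rec.sequence
            ) / len(responsive)
        stats[w] = {"occurrence": float(occ), "sc": float(sc), "density": float(dens)}
    return stats, total_positions


def _fallback_word_stats(
    word: str, background: BackgroundModel, total_positions: int
) -> dict[str, float]:
    """Stats for a word never seen in training: absent from the training
    genome and from responsive promoters."""
    return {
        "occurrence": 0.0,
        "sc": zscore_from_expected(0, background.expected_count(word, total_positions)),
        "density": 0.0,
    }


def candidate_feature_frame(
    candidates: Sequence[CandidateMotif],
    anchors: Mapping[str, GeneModel],
    word_stats: Mapping[str, Mapping[str, float]],
    background: BackgroundModel,
    total_positions: int,
    config: PipelineConfig,
) -> pd.DataFrame:
    """Per-candidate feature table (one row per candidate, original order)."""
    rows = []
    for cand in candidates:
        word = candidate_word(cand, config.word_length, len(config.core))
        ws = word_stats.get(word)
        if ws is None:
            ws = _fallback_word_stats(word, background, total_positions)
        x1, y1, z1 = features.zcurve(cand.window_sequence)
        rows.append(
            {
                "chrom": cand.seq_id,
                "start": cand.start,
                "end": cand.end,
                "strand": cand.strand,
                "core_start": cand.core_start,
                "word": word,
                "position": features.compute_position(cand, anchors[cand.seq_id]),
                "sc": ws["sc"],
                "occurrence": ws["occurrence"],
                "density": ws["density"],
                "x1": x1,
                "y1": y1,
                "z1": z1,
                "gc": features.gc_content(cand.window_sequence),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Training


def _point_in(intervals: list[tuple[int, int]], pos: int) -> bool:
    return any(lo <= pos < hi for lo, hi in intervals)


def _zone_labels(
    candidates: Sequence[CandidateMotif],
    gold: Sequence[evaluation.GoldRecord],
    controls: Sequence[evaluation.GoldRecord],
    peaks: Sequence[PeakRecord],
) -> list[str]:
    """Assign each candidate (by its core position) to gold / flank /
    control / outside."""
    gold_iv: dict[str, list[tuple[int, int]]] = {}
    for g in gold:
        gold_iv.setdefault(g.seq_id, []).append((g.start, g.end))
    ctrl_iv: dict[str, list[tuple[int, int]]] = {}
    for c in controls:
        ctrl_iv.setdefault(c.seq_id, []).append((c.start, c.end))
    peak_iv: dict[str, list[tuple[int, int]]] = {}
    for p in peaks:
        peak_iv.setdefault(p.chrom, []).append((p.start, p.end))
    zones = []
    for cand in candidates:
        pos = cand.core_start
        if _point_in(gold_iv.get(cand.seq_id, []), pos):
            zones.append("gold")
        elif _point_in(peak_iv.get(cand.seq_id, []), pos):
            zones.append("flank")
        elif _point_in(ctrl_iv.get(cand.seq_id, []), pos):
            zones.append("control")
        else:
            zones.append("outside")
    return zones


def train(
    promoters: Sequence[SequenceRecord],
    peaks: Sequence[PeakRecord],
    expression: Sequence[ExpressionRecord],
    *,
    config: PipelineConfig | None = None,
    gene_models: Mapping[str, GeneModel] | None = None,
    seed: int = 0,
) -> TrainedModel:
    """Train the fusion predictor; see the module docstring for the steps."""
    config = config or PipelineConfig()
    if not peaks:
        raise ValueError("training requires at least one peak (positive binding event)")
    gold = evaluation.build_gold_standard(list(peaks), list(promoters))
    controls = evaluation.generate_controls(
        list(peaks), list(promoters), count=len(gold), seed=seed
    )
    candidates = scan_candidates(promoters, config.core, config.window)
    if not candidates:
        raise ValueError("no core candidates found in the training sequences")

    background = BackgroundModel.fit(promoters, order=config.background_order)
    words = {candidate_word(c, config.word_length, len(config.core)) for c in candidates}
    word_stats, total_positions = compute_word_stats(
        words, promoters, expression, background, config.fc_threshold
    )
    anchors = _anchors(promoters, gene_models)
    feats = candidate_feature_frame(
        candidates, anchors, word_stats, background, total_positions, config
    )
    zones = _zone_labels(candidates, gold, controls, peaks)
    feats["zone"] = zones

    lda_classes = {"gold": "site", "flank": "other", "control": "background"}
    lda_rows = feats[feats["zone"].isin(lda_classes)]
    labels = [lda_classes[z] for z in lda_rows["zone"]]
    for cls_name in ("site", "other", "background"):
        if labels.count(cls_name) < 2:
            raise ValueError(
                f"degenerate training: class {cls_name!r} has fewer than 2 candidates"
            )
    lda_model = fit_lda(
        lda_rows[list(_LDA_FEATURES)].to_numpy(),
        labels,
        feature_names=_LDA_FEATURES,
        positive_label="site",
    )
    F = project(lda_model, feats[list(_LDA_FEATURES)].to_numpy())
    feats["f1"], feats["f2"] = F[:, 0], F[:, 1]

    training = feats[feats["zone"].isin({"gold", "control"})].copy()
    training["label"] = (training["zone"] == "gold").astype(int)
    if training["label"].nunique() < 2:
        raise ValueError("degenerate training: gold or control candidates missing")

    grids: dict[str, RegionGrid] = {}
    for name, template in default_grids().items():
        xs = training[template.axis_x].to_numpy()
        ys = training[template.axis_y].to_numpy()
        px, py = template.build(xs, ys)
        pts = list(zip(xs, ys, training["label"].to_numpy()))
        grid = fuzzy_regions.fit_regions(pts, px, py, config.thresholds, name=name)
        grids[name] = grid
        logger.info(
            "grid %s: %s", name, [[str(p) for p in row] for row in grid.propositions]
        )
    return TrainedModel(
        config=config,
        background=background,
        total_positions=total_positions,
        word_stats=word_stats,
        lda=lda_model,
        grids=grids,
    )


# ---------------------------------------------------------------------------
# Scanning / fusion


def score_candidates(
    promoters: Sequence[SequenceRecord],
    model: TrainedModel,
    *,
    gene_models: Mapping[str, GeneModel] | None = None,
) -> pd.DataFrame:
    """Candidate table with the mass triple of every evidence source.

    Columns ``<source>_h1/_h2/_theta`` hold the fuzzy-region masses of the
    three learning graphs; ``ctx_*`` the site-context evidence.  Fusion over
    any subset is then a cheap fold (see :func:`fuse_frame`).
    """
    cfg = model.config
    candidates = scan_candidates(promoters, cfg.core, cfg.window)
    if not candidates:
        return pd.DataFrame()
    anchors = _anchors(promoters, gene_models)
    feats = candidate_feature_frame(
        candidates, anchors, model.word_stats, model.background, model.total_positions, cfg
    )
    axis = {"sc_p": ("sc", "position"), "o_d": ("occurrence", "density"), "f1_f2": ("f1", "f2")}
    F = project(model.lda, feats[list(_LDA_FEATURES)].to_numpy())
    feats["f1"], feats["f2"] = F[:, 0], F[:, 1]
    for name in ALL_SOURCES:
        ax, ay = axis[name]
        triples = [
            fuzzy_mass(x, y, model.grids[name]).as_tuple()
            for x, y in zip(feats[ax], feats[ay])
        ]
        arr = np.asarray(triples)
        feats[f"{name}_h1"], feats[f"{name}_h2"], feats[f"{name}_theta"] = (
            arr[:, 0],
            arr[:, 1],
            arr[:, 2],
        )
    ctx_triples = [
        site_context_mass(
            SiteContext.from_core_hits(c.core_hits, len(cfg.core)), cfg.context_rules
        ).as_tuple()
        for c in candidates
    ]
    arr = np.asarray(ctx_triples)
    feats["ctx_h1"], feats["ctx_h2"], feats["ctx_theta"] = arr[:, 0], arr[:, 1], arr[:, 2]
    return feats


def fuse_frame(
    frame: pd.DataFrame,
    sources: Sequence[str] = ALL_SOURCES,
    site_context: bool = True,
) -> pd.DataFrame:
    """Fuse the selected per-source masses row-wise by Dempster's rule.

    A row whose sources are in exact total conflict (one source certain of
    H1, another certain of H2) has no defined orthogonal sum; such a candidate
    is scored as pure ignorance with a warning.
    """
    if frame.empty:
        out = frame.copy()
        for col in ("m_H1", "m_H2", "m_ignorance", "decision_score"):
            out[col] = []
        return out
    unknown = [s for s in sources if s not in ALL_SOURCES]
    if unknown:
        raise ValueError(f"unknown evidence sources {unknown!r}")
    if not sources and not site_context:
        raise ValueError("at least one evidence source required")
    fused = []
    conflicts = 0
    cols = [(f"{s}_h1", f"{s}_h2", f"{s}_theta") for s in sources]
    if site_context:
        cols.append(("ctx_h1", "ctx_h2", "ctx_theta"))
    mats = [frame[list(c)].to_numpy() for c in cols]
    for i in range(len(frame)):
        masses = [MassFunction(*mat[i]) for mat in mats]
        try:
            m = fuse_all(masses)
        except TotalConflictError:
            conflicts += 1
            m = ds_engine.VACUOUS
        fused.append((m.h1, m.h2, m.theta, decision_score(m)))
    if conflicts:
        logger.warning("%d candidate(s) in total conflict scored as ignorance", conflicts)
    arr = np.asarray(fused)
    out = frame.copy()
    out["m_H1"], out["m_H2"], out["m_ignorance"], out["decision_score"] = (
        arr[:, 0],
        arr[:, 1],
        arr[:, 2],
        arr[:, 3],
    )
    return out


def scan(
    promoters: Sequence[SequenceRecord],
    model: TrainedModel,
    *,
    gene_models: Mapping[str, GeneModel] | None = None,
    sources: Sequence[str] = ALL_SOURCES,
    site_context: bool = True,
) -> pd.DataFrame:
    """Scan sequences and return fused per-candidate predictions."""
    frame = score_candidates(promoters, model, gene_models=gene_models)
    return fuse_frame(frame, sources=sources, site_context=site_context)


def score_gold_records(
    records: Sequence[evaluation.GoldRecord], predictions: pd.DataFrame
) -> np.ndarray:
    """Sequence-level scores: the maximum candidate decision score inside each
    gold interval; intervals without any core score ``NO_CORE_SCORE``."""
    scores = np.full(len(records), NO_CORE_SCORE)
    if predictions.empty:
        return scores
    by_chrom = dict(tuple(predictions.groupby("chrom", sort=False)))
    for i, rec in enumerate(records):
        sub = by_chrom.get(rec.seq_id)
        if sub is None:
            continue
        inside = sub[(sub["core_start"] >= rec.start) & (sub["core_start"] < rec.end)]
        if len(inside):
            scores[i] = float(inside["decision_score"].max())
    return scores


def evaluate(
    model: TrainedModel,
    peaks: Sequence[PeakRecord],
    promoters: Sequence[SequenceRecord],
    *,
    seed: int,
    n_controls: int | None = None,
    gene_models: Mapping[str, GeneModel] | None = None,
    sources: Sequence[str] = ALL_SOURCES,
    site_context: bool = True,
    candidate_frame: pd.DataFrame | None = None,
) -> dict:
    """Score gold-standard positives vs matched controls; report AUC/AUPR.

    ``candidate_frame`` (the output of :func:`score_candidates`) may be passed
    to reuse feature computation across ablations.
    """
    positives = evaluation.build_gold_standard(list(peaks), list(promoters))
    controls = evaluation.generate_controls(
        list(peaks), list(promoters), count=n_controls or len(positives), seed=seed
    )
    if candidate_frame is None:
        candidate_frame = score_candidates(promoters, model, gene_models=gene_models)
    preds = fuse_frame(candidate_frame, sources=sources, site_context=site_context)
    records = list(positives) + list(controls)
    labels = np.array([r.label for r in records])
    scores = score_gold_records(records, preds)
    roc = evaluation.roc_auc(scores, labels)
    aupr = evaluation.pr_aupr(scores, labels)
    return {
        "auc": roc.auc,
        "aupr": aupr,
        "n_pos": int(labels.sum()),
        "n_neg": int(len(labels) - labels.sum()),
        "seed": seed,
        "fpr": roc.fpr.tolist(),
        "tpr": roc.tpr.tolist(),
    }


def split_peaks(
    peaks: Sequence[PeakRecord], test_fraction: float = 0.3, seed: int = 0
) -> tuple[list[PeakRecord], list[PeakRecord]]:
    """Seeded train/test split by peak."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(peaks))
    n_test = max(int(round(test_fraction * len(peaks))), 1)
    test = [peaks[i] for i in idx[:n_test]]
    train_ = [peaks[i] for i in idx[n_test:]]
    if not train_:
        raise ValueError("split leaves no training peaks")
    return train_, test
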