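"""SMIC similarity, accumulating seed-set clustering and trace segmentation.

The similarity between two samples is judged in *quality*, not quantity:
over the vector of significant-set scores, a position is a CGS
(co-expressed gene set) when both scores lie on the same side of the zero
average, and a DGS (differentially expressed gene set) when they lie on
opposite sides.  With weight theta in [0.5, 1] — the probability that an
observed concordance is not a random event — the similarity is the linear
likelihood form

    L(theta) = N_cgs * theta + N_dgs * (1 - theta).

Because L is linear in theta, its maximum over [0.5, 1] is attained at an
endpoint, so the maximum-likelihood similarity has the closed form

    smic_mle = max(N_cgs, (N_cgs + N_dgs) / 2).

The accumulating clustering starts from a control-derived seed vector and
greedily absorbs, at each step, the candidate with the highest *average*
similarity to all current seeds.  Mild cases (still control-like) enter
first, so the resulting order tracks disease severity.  The per-step
winner-score trace is then smoothed with a loess curve and split into
classes at flex points — ranks where the fitted curve's curvature changes
sign.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping

import numpy as np
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io import PhenotypeTable
from .scoring import GeneSetScoreMatrix

logger = logging.getLogger("igsa")

SimilarityMethod = Literal["smic_mle", "smic_fixed", "euclidean", "pearson", "spearman"]


@dataclass(frozen=True)
class SignVectorPair:
    """Positionwise sign comparison of two score vectors.

    ``n_tied`` counts positions where either value is exactly 0 — a zero has
    no direction, so it is neither concordant nor discordant (this also
    keeps the all-zero start seed from spuriously matching everything).
    """

    n_cgs: int
    n_dgs: int
    n_tied: int


@dataclass(frozen=True)
class SimilarityConfig:
    method: SimilarityMethod = "smic_mle"
    theta: float | None = None

    def __post_init__(self) -> None:
        if self.method == "smic_fixed":
            if self.theta is None or not 0.5 <= self.theta <= 1.0:
                raise ValueError("smic_fixed requires theta in [0.5, 1]")


@dataclass
class ClusteringResult:
    ordered_ids: list[str]
    trace: list[float]  # winner's average-similarity score at selection time
    start_seed: np.ndarray
    class_of: dict[str, int] = field(default_factory=dict)  # filled by segment_trace


@dataclass(frozen=True)
class SegmentationConfig:
    loess_span: float = 0.5
    min_class_size: int = 3
    #: a curvature run only counts as an arc when the slope change across it
    #: is at least this fraction of the trace's mean absolute slope; filters
    #: residual smoothing wiggles on essentially straight traces
    flex_strength: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.loess_span <= 1:
            raise ValueError("loess_span must be in (0, 1]")
        if self.min_class_size < 1:
            raise ValueError("min_class_size must be >= 1")
        if self.flex_strength < 0:
            raise ValueError("flex_strength must be >= 0")


def count_signs(u: np.ndarray, v: np.ndarray) -> SignVectorPair:
    """Count CGS (same sign, both nonzero), DGS (opposite) and tied positions."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1 or u.size < 1:
        raise ValueError(f"need equal-length 1-d vectors, got {u.shape} and {v.shape}")
    prod = u * v
    n_cgs = int(np.sum(prod > 0))
    n_dgs = int(np.sum(prod < 0))
    return SignVectorPair(n_cgs=n_cgs, n_dgs=n_dgs, n_tied=u.size - n_cgs - n_dgs)


def smic(u: np.ndarray, v: np.ndarray, cfg: SimilarityConfig) -> float:
    """SMIC similarity L(theta), MLE or at a fixed theta."""
    pair = count_signs(u, v)
    if cfg.method == "smic_fixed":
        return pair.n_cgs * cfg.theta + pair.n_dgs * (1.0 - cfg.theta)
    if cfg.method == "smic_mle":
        # linear in theta on [0.5, 1]: max at an endpoint
        return max(float(pair.n_cgs), (pair.n_cgs + pair.n_dgs) / 2.0)
    raise ValueError(f"not a SMIC method: {cfg.method!r}")


def baseline_similarity(u: np.ndarray, v: np.ndarray, cfg: SimilarityConfig) -> float:
    """Comparison similarities: negated Euclidean distance, Pearson, Spearman.

    Euclidean distance is negated so that "higher = more similar" holds for
    every method and the greedy argmax is uniform.  Correlations on a
    zero-variance vector are undefined; they return 0 with a warning.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("length mismatch")
    if cfg.method == "euclidean":
        return -float(np.linalg.norm(u - v))
    if cfg.method in ("pearson", "spearman"):
        if np.ptp(u) == 0 or np.ptp(v) == 0:
            logger.warning("zero-variance vector: %s similarity set to 0", cfg.method)
            return 0.0
        if cfg.method == "pearson":
            return float(stats.pearsonr(u, v).statistic)
        return float(stats.spearmanr(u, v).statistic)
    raise ValueError(f"not a baseline method: {cfg.method!r}")


def similarity(u: np.ndarray, v: np.ndarray, cfg: SimilarityConfig) -> float:
    if cfg.method in ("smic_mle", "smic_fixed"):
        return smic(u, v, cfg)
    return baseline_similarity(u, v, cfg)


def make_start_seed(
    scores: GeneSetScoreMatrix,
    pheno: PhenotypeTable,
    mode: Literal["samples", "genesets"] = "samples",
) -> np.ndarray:
    """Build the clustering start seed.

    ``samples`` mode: per-set mean score over control samples — the
    "healthy profile" the mildest cases resemble most.  ``genesets`` mode:
    gene sets carry no control/case tag, so the start seed is the zero
    vector of length = number of samples.
    """
    if mode == "genesets":
        return np.zeros(len(scores.sample_ids))
    if mode != "samples":
        raise ValueError(f"unknown mode {mode!r}")
    controls = [s for s in scores.sample_ids if pheno.group_of.get(s) == "control"]
    if not controls:
        raise ValueError("samples mode needs at least one control sample")
    idx = [scores.sample_ids.index(s) for s in controls]
    return scores.scores[:, idx].mean(axis=1)


def accumulate_cluster(
    vectors: Mapping[str, np.ndarray],
    start_seed: np.ndarray,
    cfg: SimilarityConfig = SimilarityConfig(),
) -> ClusteringResult:
    """Greedy severity ordering by average similarity to the growing seed set.

    At each step every remaining candidate's mean similarity to all current
    seeds (start seed included, on equal footing) is computed and the
    argmax is moved from the candidate set to the seed set; its score at
    selection time is recorded in the trace.  Ties are broken by
    lexicographic id (logged), so the result is deterministic.
    """
    if not vectors:
        raise ValueError("need at least one candidate")
    start_seed = np.asarray(start_seed, dtype=float)
    for cid, vec in vectors.items():
        if np.asarray(vec).shape != start_seed.shape:
            raise ValueError(
                f"candidate {cid!r} has length {np.asarray(vec).size}, "
                f"start seed has {start_seed.size}"
            )
    candidates = {cid: np.asarray(vec, dtype=float) for cid, vec in vectors.items()}
    seeds: list[np.ndarray] = [start_seed]
    # running sum of similarities to seeds, updated incrementally
    sim_sum = {cid: similarity(vec, start_seed, cfg) for cid, vec in candidates.items()}
    ordered: list[str] = []
    trace: list[float] = []
    while candidates:
        n_seeds = len(seeds)
        best_id = None
        best_score = -np.inf
        tie = False
        for cid in sorted(candidates):
            score = sim_sum[cid] / n_seeds
            if score > best_score:
                best_id, best_score, tie = cid, score, False
            elif score == best_score:
                tie = True
        if tie:
            logger.info(
                "similarity tie at step %d resolved lexicographically -> %s",
                len(ordered) + 1,
                best_id,
            )
        winner = candidates.pop(best_id)
        del sim_sum[best_id]
        ordered.append(best_id)
        trace.append(float(best_score))
        seeds.append(winner)
        for cid, vec in candidates.items():
            sim_sum[cid] += similarity(vec, winner, cfg)
    return ClusteringResult(ordered_ids=ordered, trace=trace, start_seed=start_seed)


def _flex_points(fitted: np.ndarray, min_run: int, flex_strength: float) -> list[int]:
    """Ranks (0-based) where the fitted curve's second difference changes sign.

    A sign change only counts between genuine arcs: runs where the
    curvature keeps its sign for at least ``min_run`` consecutive points
    AND the slope change accumulated across the run is at least
    ``flex_strength`` times the trace's mean absolute slope — transient
    wiggles from smoothing noise on an essentially straight trace are not
    class boundaries.  Curvature below 1e-8 of the fitted range is treated
    as zero (an exactly linear trace has no flex points).  The cut is
    placed before the first point carrying the new curvature sign.
    """
    n = fitted.size
    if n < 3:
        return []
    d2 = np.diff(fitted, 2)  # d2[i] = curvature at rank i+1
    span = max(float(np.ptp(fitted)), 1e-300)
    tol = 1e-8 * span
    mean_slope = span / (n - 1)
    signs = np.where(d2 > tol, 1, np.where(d2 < -tol, -1, 0))
    # maximal runs of nonzero constant sign
    runs: list[tuple[int, int, int]] = []  # (sign, start, end) inclusive, d2 index
    i = 0
    while i < signs.size:
        if signs[i] == 0:
            i += 1
            continue
        j = i
        while j + 1 < signs.size and signs[j + 1] == signs[i]:
            j += 1
        runs.append((int(signs[i]), i, j))
        i = j + 1
    persistent = [
        r
        for r in runs
        if r[2] - r[1] + 1 >= min_run
        and abs(d2[r[1] : r[2] + 1].sum()) >= flex_strength * mean_slope
    ]
    flex: list[int] = []
    for prev, cur in zip(persistent, persistent[1:]):
        if prev[0] != cur[0]:
            # cut before the first point whose curvature has the new sign
            # (d2[i] is the curvature at trace index i + 1)
            flex.append(cur[1] + 1)
    return flex


def segment_trace(
    result: ClusteringResult, cfg: SegmentationConfig = SegmentationConfig()
) -> ClusteringResult:
    """Split the ordering into severity classes at loess flex points.

    Fits a loess curve to the similarity trace against rank, finds flex
    points (curvature sign changes of the fitted curve) and cuts the
    ordering there, subject to ``min_class_size``.  Degenerate traces
    (fewer than 3 points, or no flex point) give a single class.
    Classes are contiguous, numbered 1..k in rank order.
    """
    n = len(result.trace)
    if n == 0:
        return replace(result, class_of={})
    boundaries: list[int] = []
    if n >= 3:
        ranks = np.arange(1, n + 1, dtype=float)
        fitted = lowess(
            np.asarray(result.trace, dtype=float),
            ranks,
            frac=cfg.loess_span,
            return_sorted=False,
        )
        candidates = _flex_points(
            np.asarray(fitted),
            min_run=cfg.min_class_size,
            flex_strength=cfg.flex_strength,
        )
        last = 0
        for b in sorted(candidates):
            if b - last >= cfg.min_class_size and n - b >= cfg.min_class_size:
                boundaries.append(b)
                last = b
    class_of: dict[str, int] = {}
    cls = 1
    cuts = set(boundaries)
    for i, sample in enumerate(result.ordered_ids):
        if i in cuts:
            cls += 1
        class_of[sample] = cls
    return replace(result, class_of=class_of)


def double_cluster(
    scores: GeneSetScoreMatrix,
    pheno: PhenotypeTable,
    significant: list[str],
    cfg: SimilarityConfig = SimilarityConfig(),
) -> tuple[list[str], list[str], np.ndarray]:
    """Cluster case samples and significant sets jointly; return marker matrix.

    Samples are ordered by the accumulating clustering over
    significant-set score vectors (control-mean start seed); sets are
    ordered the same way over their per-sample score vectors restricted to
    cases (zero start seed).  The marker matrix is the boolean
    ``score > 0`` over (ordered sets x ordered case samples) — a dot marks
    a set expressed above the average in that sample.
    """
    missing = [s for s in significant if s not in scores.set_names]
    if missing:
        raise KeyError(f"sets not in score matrix: {missing}")
    if not significant:
        raise ValueError("need at least one significant set")
    cases = [s for s in scores.sample_ids if pheno.group_of.get(s) == "case"]
    if not cases:
        raise ValueError("no case samples to cluster")
    set_idx = {name: scores.set_names.index(name) for name in significant}
    case_idx = {s: scores.sample_ids.index(s) for s in cases}

    sig_rows = np.array([scores.scores[set_idx[name]] for name in significant])
    sample_vectors = {s: sig_rows[:, case_idx[s]] for s in cases}
    sample_seed_full = make_start_seed(scores, pheno, mode="samples")
    sample_seed = np.array([sample_seed_full[set_idx[name]] for name in significant])
    sample_order = accumulate_cluster(sample_vectors, sample_seed, cfg).ordered_ids

    case_cols = [case_idx[s] for s in cases]
    set_vectors = {name: sig_rows[i, case_cols] for i, name in enumerate(significant)}
    zero_seed = np.zeros(len(cases))
    set_order = accumulate_cluster(set_vectors, zero_seed, cfg).ordered_ids

    marker = np.array(
        [
            [scores.scores[set_idx[name], scores.sample_ids.index(s)] > 0 for s in sample_order]
            for name in set_order
        ],
        dtype=bool,
    )
    return sample_order, set_order, marker
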