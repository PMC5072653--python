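"""Per-sample normalization and gene-set expression scoring.

Normalization converts each gene's raw log-scale values into deviations of
its per-sample *proportion* from the cross-sample average:

    norm(g, j) = g_ij / sum_j g_ij  -  1 / N

where N is the number of samples.  Positive values mean the gene carries an
above-average share of its own total expression in that sample
("up-regulated" there); negative means below average.  Each retained gene's
normalized row sums to exactly zero, so the grand average score is zero by
construction — later stages use 0 as the up/down threshold.

A gene set's expression in a sample is then the arithmetic mean of the
normalized values over the genes shared between the set and the matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSetCollection, ValidationError

logger = logging.getLogger("igsa")


@dataclass
class NormalizedMatrix:
    """Proportion-deviation expression; every retained row sums to 0."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    dropped_genes: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class GeneSetScoreMatrix:
    """Gene-set x sample score matrix with per-set intersection support."""

    set_names: list[str]
    sample_ids: list[str]
    scores: np.ndarray  # shape (n_sets, n_samples)
    support: dict[str, int]  # |Q_i ∩ S|, identical across samples (dense matrix)
    excluded_sets: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.set_names, columns=self.sample_ids)

    def row(self, set_name: str) -> np.ndarray:
        return self.scores[self.set_names.index(set_name)]

    def column(self, sample_id: str) -> np.ndarray:
        return self.scores[:, self.sample_ids.index(sample_id)]


def normalize_expression(expr: ExpressionMatrix) -> NormalizedMatrix:
    """Normalize raw log-scale expression to proportion deviations.

    Genes whose values sum to zero across samples (no signal at all) are
    dropped and reported in ``dropped_genes`` — the proportion is undefined
    for them and they carry no between-sample information.
    """
    values = np.asarray(expr.values, dtype=float)
    if expr.n_samples < 2:
        raise ValidationError("normalization needs at least 2 samples")
    if not np.all(np.isfinite(values)):
        raise ValidationError("non-finite expression values")
    row_sums = values.sum(axis=1)
    keep = row_sums != 0.0
    dropped = [g for g, k in zip(expr.gene_ids, keep) if not k]
    if dropped:
        logger.warning(
            "dropping %d gene(s) with zero total expression: %s%s",
            len(dropped),
            ", ".join(dropped[:5]),
            "..." if len(dropped) > 5 else "",
        )
    kept_values = values[keep]
    normalized = kept_values / row_sums[keep, None] - 1.0 / expr.n_samples
    return NormalizedMatrix(
        gene_ids=[g for g, k in zip(expr.gene_ids, keep) if k],
        sample_ids=list(expr.sample_ids),
        values=normalized,
        dropped_genes=dropped,
    )


def score_gene_sets(
    norm: NormalizedMatrix, sets: GeneSetCollection, min_support: int = 1
) -> GeneSetScoreMatrix:
    """Average normalized expression over each set's genes, per sample.

    Sets whose intersection with the retained genes is smaller than
    ``min_support`` are excluded from the score matrix and listed in
    ``excluded_sets``.  Since the matrix is dense, the gene universe is the
    same for all samples, so support is a per-set count.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    if len(sets) == 0:
        raise ValidationError("empty gene-set collection")
    index_of = {g: i for i, g in enumerate(norm.gene_ids)}
    names: list[str] = []
    rows: list[np.ndarray] = []
    support: dict[str, int] = {}
    excluded: list[str] = []
    for name, genes in sets.sets.items():
        idx = [index_of[g] for g in genes if g in index_of]
        if len(idx) < min_support:
            excluded.append(name)
            continue
        names.append(name)
        support[name] = len(idx)
        rows.append(norm.values[idx].mean(axis=0))
    if excluded:
        logger.warning(
            "excluded %d gene set(s) with < %d matrix genes: %s%s",
            len(excluded),
            min_support,
            ", ".join(excluded[:5]),
            "..." if len(excluded) > 5 else "",
        )
    if not names:
        raise ValidationError(
            f"no gene set has at least {min_support} gene(s) in the matrix; "
            "check that GMT and matrix use the same gene identifier namespace"
        )
    return GeneSetScoreMatrix(
        set_names=names,
        sample_ids=list(norm.sample_ids),
        scores=np.vstack(rows),
        support=support,
        excluded_sets=excluded,
    )
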