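"""Sign-count enrichment: which gene sets skew up or down in cases?

For each gene set, every sample is classified by the sign of its set score
(positive = above the zero cross-sample average, which is exact after
normalization).  The up/down counts, split by control/case group, form a
2x2 contingency table tested with the two-sided Fisher exact test; p-values
are FDR-adjusted across sets.  Significant sets are labelled SUP
(significantly up-regulated pathway — cases skew positive relative to
controls) or SDP (down-regulated).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io import CASE, CONTROL, ExpressionMatrix, GeneSetCollection, PhenotypeTable
from .scoring import GeneSetScoreMatrix, normalize_expression, score_gene_sets

logger = logging.getLogger("igsa")

Direction = Literal["SUP", "SDP", "none"]


@dataclass(frozen=True)
class ContingencyTable:
    """Counts of samples with set score > 0 ("up") vs <= 0, by group.

    A score of exactly 0 counts as "not above average" (down row); exact
    zeros are measure-zero for real data but the table must partition all
    samples.
    """

    n_case_up: int
    n_case_down: int
    n_ctrl_up: int
    n_ctrl_down: int

    def __post_init__(self) -> None:
        if min(self.n_case_up, self.n_case_down, self.n_ctrl_up, self.n_ctrl_down) < 0:
            raise ValueError("contingency counts must be nonnegative")


@dataclass
class EnrichmentRecord:
    set_name: str
    table: ContingencyTable
    p: float
    fdr: float
    direction: Direction


def build_contingency(
    scores: GeneSetScoreMatrix, pheno: PhenotypeTable, set_name: str
) -> ContingencyTable:
    """Count up/down samples for one set, split by group."""
    if set_name not in scores.set_names:
        raise KeyError(f"unknown gene set {set_name!r}")
    row = scores.row(set_name)
    n_ties = int(np.sum(row == 0.0))
    if n_ties:
        logger.info("set %s: %d score(s) exactly 0 counted as down", set_name, n_ties)
    counts = {(CASE, True): 0, (CASE, False): 0, (CONTROL, True): 0, (CONTROL, False): 0}
    for sample, score in zip(scores.sample_ids, row):
        counts[(pheno.group_of[sample], score > 0.0)] += 1
    return ContingencyTable(
        n_case_up=counts[(CASE, True)],
        n_case_down=counts[(CASE, False)],
        n_ctrl_up=counts[(CONTROL, True)],
        n_ctrl_down=counts[(CONTROL, False)],
    )


def fisher_exact_two_sided(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p for a 2x2 table with fixed margins.

    Sums hypergeometric probabilities of all tables (with the observed
    margins) no more probable than the observed one — the standard
    minimum-likelihood convention.  Computed with exact integer binomial
    coefficients, so ties between table probabilities are resolved exactly;
    the only floating-point step is the final division.  Degenerate margins
    (an empty row or column) give p = 1.
    """
    a, b = table.n_case_up, table.n_case_down
    c, d = table.n_ctrl_up, table.n_ctrl_down
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if n == 0 or r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    # weight of table with k cases up: C(r1, k) * C(r2, c1 - k); common
    # denominator C(n, c1) cancels in the comparison
    k_min = max(0, c1 - r2)
    k_max = min(r1, c1)
    w_obs = math.comb(r1, a) * math.comb(r2, c1 - a)
    total = 0
    tail = 0
    for k in range(k_min, k_max + 1):
        w = math.comb(r1, k) * math.comb(r2, c1 - k)
        total += w
        if w <= w_obs:
            tail += w
    return tail / total


def bh_fdr(p_values: Sequence[float], method: str = "bh") -> list[float]:
    """FDR-adjust p-values, order-preserving with the input.

    ``method`` is ``bh`` (Benjamini–Hochberg step-up, the default) or
    ``by`` (Benjamini–Yekutieli, valid under arbitrary dependence).
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    sm_method = {"bh": "fdr_bh", "by": "fdr_by"}.get(method)
    if sm_method is None:
        raise ValueError(f"unknown FDR method {method!r}")
    _, adjusted, _, _ = multipletests(p, alpha=0.05, method=sm_method)
    return [float(q) for q in adjusted]


def classify_direction(
    table: ContingencyTable, fdr: float, threshold: float = 0.01
) -> Direction:
    """SUP/SDP call from the up-fractions of cases vs controls.

    Direction comes from the same counts that confer significance: SUP when
    the case up-fraction exceeds the control up-fraction, SDP when lower.
    Insignificant sets and exact fraction ties get "none".
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    if fdr >= threshold:
        return "none"
    n_case = table.n_case_up + table.n_case_down
    n_ctrl = table.n_ctrl_up + table.n_ctrl_down
    if n_case == 0 or n_ctrl == 0:
        return "none"
    case_frac = table.n_case_up / n_case
    ctrl_frac = table.n_ctrl_up / n_ctrl
    if case_frac > ctrl_frac:
        return "SUP"
    if case_frac < ctrl_frac:
        return "SDP"
    logger.warning("significant set with tied up-fractions; direction left as none")
    return "none"


def run_enrichment(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    pheno: PhenotypeTable,
    fdr_threshold: float = 0.01,
    min_support: int = 1,
    fdr_method: str = "bh",
) -> list[EnrichmentRecord]:
    """Full enrichment stage: normalize, score, test, adjust, classify.

    Returns one record per retained set, sorted by p ascending then set
    name; records with fdr < ``fdr_threshold`` carry a SUP/SDP direction.
    """
    norm = normalize_expression(expr)
    scores = score_gene_sets(norm, sets, min_support=min_support)
    return enrich_scores(
        scores, pheno, fdr_threshold=fdr_threshold, fdr_method=fdr_method
    )


def enrich_scores(
    scores: GeneSetScoreMatrix,
    pheno: PhenotypeTable,
    fdr_threshold: float = 0.01,
    fdr_method: str = "bh",
) -> list[EnrichmentRecord]:
    """Enrichment from a precomputed score matrix (see run_enrichment)."""
    tables = [build_contingency(scores, pheno, name) for name in scores.set_names]
    p_values = [fisher_exact_two_sided(t) for t in tables]
    fdrs = bh_fdr(p_values, method=fdr_method)
    records = [
        EnrichmentRecord(
            set_name=name,
            table=t,
            p=p,
            fdr=q,
            direction=classify_direction(t, q, fdr_threshold),
        )
        for name, t, p, q in zip(scores.set_names, tables, p_values, fdrs)
    ]
    records.sort(key=lambda r: (r.p, r.set_name))
    return records


def records_to_frame(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    """Result table with the documented fixed column order."""
    return pd.DataFrame.from_records(
        [
            {
                "set": r.set_name,
                "n_case_up": r.table.n_case_up,
                "n_case_down": r.table.n_case_down,
                "n_ctrl_up": r.table.n_ctrl_up,
                "n_ctrl_down": r.table.n_ctrl_down,
                "p": r.p,
                "fdr": r.fdr,
                "direction": r.direction,
            }
            for r in records
        ],
        columns=[
            "set",
            "n_case_up",
            "n_case_down",
            "n_ctrl_up",
            "n_ctrl_down",
            "p",
            "fdr",
            "direction",
        ],
    )
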