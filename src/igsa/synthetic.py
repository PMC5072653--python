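"""Synthetic cohorts with planted differential gene sets and a severity gradient.

Generates log-scale expression matrices where some disjoint gene sets are
shifted up (or down) in case samples, with the shift growing linearly along
a per-case severity in (0, 1] — emulating the amplification of aberrant
expression as disease progresses.  The returned ground truth (planted set
names, per-case severity) supports power, false-discovery and
ordering-recovery experiments.

Defaults describe a cohort in the range the method targets: 2000 genes,
20 controls + 20 cases, 100 gene sets of 15 genes of which 15 are planted
up and 15 down (roughly a third of sets carrying signal), a 1.5 log2 shift
at maximal severity and cell-level noise of 0.3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .io import CASE, CONTROL, ExpressionMatrix, GeneSetCollection, PhenotypeTable


@dataclass(frozen=True)
class SimulationSpec:
    n_genes: int = 2000
    n_controls: int = 20
    n_cases: int = 20
    n_sets: int = 100
    set_size: int = 15
    n_planted_up: int = 15
    n_planted_down: int = 15
    effect: float = 1.5  # log2 shift at maximal severity
    severity: Literal["linear", "constant"] = "linear"
    noise_sd: float = 0.3
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted_up + self.n_planted_down > self.n_sets:
            raise ValueError("planted sets exceed n_sets")
        if self.set_size * self.n_sets > self.n_genes:
            raise ValueError("disjoint sets need set_size * n_sets <= n_genes")
        if self.effect < 0 or self.noise_sd <= 0:
            raise ValueError("effect must be >= 0 and noise_sd > 0")
        if min(self.n_controls, self.n_cases) < 1:
            raise ValueError("need at least one control and one case")


@dataclass
class GroundTruth:
    planted_up: list[str]
    planted_down: list[str]
    severity_of: dict[str, float]  # case sample id -> severity in (0, 1]


def simulate_cohort(
    spec: SimulationSpec,
) -> tuple[ExpressionMatrix, GeneSetCollection, PhenotypeTable, GroundTruth]:
    """Generate one cohort, fully reproducible from ``spec.seed``.

    Baseline log-expression per gene is Normal(baseline_mean, baseline_sd)
    truncated at 0; each cell adds Normal(0, noise_sd) noise.  In case
    sample j with severity s_j, genes of planted-up sets gain
    ``effect * s_j`` and genes of planted-down sets lose the same amount;
    all values are floored at 0 so the matrix stays valid log-scale input.
    Gene sets are disjoint, drawn from a shuffled gene list.
    """
    rng = np.random.default_rng(spec.seed)
    width = len(str(max(spec.n_genes, spec.n_sets, spec.n_controls, spec.n_cases)))
    genes = [f"G{i:0{width}d}" for i in range(1, spec.n_genes + 1)]
    controls = [f"ctrl{j:0{width}d}" for j in range(1, spec.n_controls + 1)]
    cases = [f"case{j:0{width}d}" for j in range(1, spec.n_cases + 1)]
    samples = controls + cases

    shuffled = list(genes)
    rng.shuffle(shuffled)
    sets = {
        f"SET{i:0{width}d}": frozenset(shuffled[i * spec.set_size : (i + 1) * spec.set_size])
        for i in range(spec.n_sets)
    }
    set_names = list(sets)
    planted_up = set_names[: spec.n_planted_up]
    planted_down = set_names[spec.n_planted_up : spec.n_planted_up + spec.n_planted_down]

    if spec.severity == "linear":
        severities = [(j + 1) / spec.n_cases for j in range(spec.n_cases)]
    elif spec.severity == "constant":
        severities = [1.0] * spec.n_cases
    else:
        raise ValueError(f"unknown severity model {spec.severity!r}")
    severity_of = dict(zip(cases, severities))

    baseline = np.maximum(
        rng.normal(spec.baseline_mean, spec.baseline_sd, size=spec.n_genes), 0.0
    )
    values = baseline[:, None] + rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, len(samples)))

    gene_index = {g: i for i, g in enumerate(genes)}
    up_rows = np.array(sorted(gene_index[g] for name in planted_up for g in sets[name]), dtype=int)
    down_rows = np.array(
        sorted(gene_index[g] for name in planted_down for g in sets[name]), dtype=int
    )
    for j, s in enumerate(severities):
        col = spec.n_controls + j
        if up_rows.size:
            values[up_rows, col] += spec.effect * s
        if down_rows.size:
            values[down_rows, col] -= spec.effect * s
    values = np.maximum(values, 0.0)

    expr = ExpressionMatrix(gene_ids=genes, sample_ids=samples, values=values)
    collection = GeneSetCollection(
        sets=sets, descriptions={name: "synthetic" for name in sets}
    )
    pheno = PhenotypeTable(
        group_of={**{s: CONTROL for s in controls}, **{s: CASE for s in cases}}
    )
    truth = GroundTruth(
        planted_up=planted_up, planted_down=planted_down, severity_of=severity_of
    )
    return expr, collection, pheno, truth


@dataclass
class TraceTruth:
    junction: int | None  # 1-based rank of the curvature change, if any


def simulate_trace(
    kind: Literal["linear", "two_arc"], n: int, seed: int = 0
) -> tuple[np.ndarray, TraceTruth]:
    """Fixture traces for segmentation: a noisy line or two opposite arcs.

    ``linear`` is a + b*rank plus small noise (no curvature change, one
    class expected).  ``two_arc`` concatenates a concave and a convex
    quadratic joined at rank n // 2, which is returned as the ground-truth
    junction.
    """
    if n < 5:
        raise ValueError("need n >= 5")
    rng = np.random.default_rng(seed)
    ranks = np.arange(1, n + 1, dtype=float)
    if kind == "linear":
        trace = 5.0 + 0.25 * ranks + rng.normal(0.0, 0.05, size=n)
        return trace, TraceTruth(junction=None)
    if kind == "two_arc":
        junction = n // 2
        trace = np.empty(n)
        left = ranks[:junction]
        right = ranks[junction:]
        # concave arc peaking mid-left, then convex arc dipping mid-right;
        # continuous at the junction
        trace[:junction] = -0.15 * (left - junction / 2.0) ** 2
        offset = trace[junction - 1]
        trace[junction:] = (
            0.15 * (right - (junction + n) / 2.0) ** 2
            + offset
            - 0.15 * (ranks[junction] - (junction + n) / 2.0) ** 2
        )
        trace += rng.normal(0.0, 0.05, size=n)
        return trace, TraceTruth(junction=junction)
    raise ValueError(f"unknown trace kind {kind!r}")
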