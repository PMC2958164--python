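"""Differential probeset selection by the J5 metric with jackknife stabilization.

The J5 score of a probe for a pairwise group contrast is its group-mean
difference divided by the array-wide average absolute group-mean difference:

    J5(g) = (mean_a(g) - mean_b(g)) / ( (1/N) * sum_j |mean_a(j) - mean_b(j)| )

By construction the mean of |J5| over probes is exactly 1, so the default
threshold of 4 selects probes whose contrast is at least four times the
array-wide average. J5 is a *selection* score, not a statistical test: no
per-gene p-values are produced and no gene-level multiple-testing correction
is applied — inference is deferred to the pathway level.

With very few replicates a single aberrant chip can push a probe over the
threshold, so selection is stabilised by a jackknife: in each of a fixed
number of rounds one sample is removed from each group (round-robin over the
samples, wrapping; optionally after a seeded shuffle) and J5 is recomputed.
A probe is selected only if it clears the threshold on the full data *and*
in every round. Selection is two-tailed (|J5| >= threshold), capturing both
elevated and lowered expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, ParameterError
from .io import ExpressionMatrix

__all__ = [
    "DifferentialResult",
    "j5_scores",
    "jackknife_select",
    "pairwise_comparisons",
    "venn_partition",
]

VENN_REGIONS = ("A", "B", "C", "AB", "AC", "BC", "ABC")


@dataclass
class DifferentialResult:
    """J5 selection outcome for one pairwise group contrast.

    ``selected`` holds probes passing the threshold on the full data and in
    every jackknife round; it is always a subset of ``passes_full``.
    ``jackknife_survival`` counts, per probe, the rounds in which the
    threshold was cleared (0..iterations).
    """

    contrast: tuple[str, str]
    j5: pd.Series
    threshold: float
    iterations: int
    passes_full: frozenset
    jackknife_survival: pd.Series
    selected: frozenset

    def __post_init__(self) -> None:
        if not self.selected <= self.passes_full:
            raise ParameterError("selected must be a subset of passes_full")

    def to_frame(self) -> pd.DataFrame:
        """Per-probe table: j5, passes_full, jk_survival, selected."""
        return pd.DataFrame(
            {
                "j5": self.j5,
                "passes_full": self.j5.index.isin(list(self.passes_full)),
                "jk_survival": self.jackknife_survival.reindex(self.j5.index),
                "selected": self.j5.index.isin(list(self.selected)),
            }
        ).rename_axis("probe_id")


def _group_samples(m: ExpressionMatrix, label: str) -> list[str]:
    if label not in set(m.groups):
        raise ParameterError(f"unknown group label {label!r}")
    return m.samples_in_group(label)


def j5_scores(m: ExpressionMatrix, group_a: str, group_b: str) -> pd.Series:
    """Signed J5 score per probe for the contrast ``group_a - group_b``.

    Swapping the groups negates every score; rescaling all intensities leaves
    scores unchanged (numerator and denominator scale together).
    """
    sa = _group_samples(m, group_a)
    sb = _group_samples(m, group_b)
    if not sa or not sb:
        raise ParameterError("both groups need at least one sample")
    diff = m.intensities[sa].mean(axis=1) - m.intensities[sb].mean(axis=1)
    denom = float(np.abs(diff).mean())
    if denom == 0.0:
        raise DegenerateInputError(
            f"all group means identical for contrast {group_a}-{group_b}"
        )
    return diff / denom


def jackknife_select(
    m: ExpressionMatrix,
    group_a: str,
    group_b: str,
    threshold: float = 4.0,
    iterations: int = 4,
    seed: int | None = None,
) -> DifferentialResult:
    """Select probes with |J5| >= threshold on the full data and every jackknife round.

    Round k removes the (k mod group size)-th sample from each group — in
    label order, or after a per-group seeded shuffle when ``seed`` is given —
    and recomputes J5 on the remaining samples. The scheme is deterministic
    given the seed and covers every sample once iterations reaches the group
    size.
    """
    if threshold <= 0:
        raise ParameterError(f"threshold must be positive, got {threshold}")
    if iterations < 0:
        raise ParameterError(f"iterations must be nonnegative, got {iterations}")
    sa = _group_samples(m, group_a)
    sb = _group_samples(m, group_b)
    if iterations > 0 and (len(sa) < 2 or len(sb) < 2):
        raise ParameterError("each group needs >= 2 samples to drop one per round")
    if seed is not None:
        rng = np.random.default_rng(seed)
        sa = [sa[i] for i in rng.permutation(len(sa))]
        sb = [sb[i] for i in rng.permutation(len(sb))]

    full = j5_scores(m, group_a, group_b)
    passes_full = frozenset(full.index[np.abs(full) >= threshold])
    survival = pd.Series(0, index=full.index, dtype=int)
    selected = set(passes_full)
    for k in range(iterations):
        keep = [s for i, s in enumerate(sa) if i != k % len(sa)]
        keep += [s for i, s in enumerate(sb) if i != k % len(sb)]
        round_j5 = j5_scores(m.subset_samples(keep), group_a, group_b)
        passed = np.abs(round_j5) >= threshold
        survival += passed.astype(int)
        selected &= set(round_j5.index[passed])
    return DifferentialResult(
        contrast=(group_a, group_b),
        j5=full,
        threshold=float(threshold),
        iterations=iterations,
        passes_full=passes_full,
        jackknife_survival=survival,
        selected=frozenset(selected),
    )


def pairwise_comparisons(
    m: ExpressionMatrix,
    group_order: tuple[str, str, str] = ("P", "J", "A"),
    threshold: float = 4.0,
    iterations: int = 4,
    seed: int | None = None,
) -> dict[str, DifferentialResult]:
    """Run all three age-ordered pairwise contrasts with identical settings.

    For group order (P, J, A) — youngest to oldest — the contrasts are
    A-P, A-J and J-P, keyed as ``"A-P"`` etc.
    """
    if len(group_order) != 3 or len(set(group_order)) != 3:
        raise ParameterError("group_order must be three distinct labels")
    labels = set(m.groups)
    missing = [g for g in group_order if g not in labels]
    if missing:
        raise ParameterError(f"groups absent from matrix: {missing}")
    g1, g2, g3 = group_order
    results: dict[str, DifferentialResult] = {}
    for a, b in ((g3, g1), (g3, g2), (g2, g1)):
        results[f"{a}-{b}"] = jackknife_select(
            m, a, b, threshold=threshold, iterations=iterations, seed=seed
        )
    return results


def venn_partition(list_a, list_b, list_c) -> dict[str, int]:
    """Counts for the 7 exclusive regions of the 3-set Venn diagram.

    Keys: ``A``, ``B``, ``C`` (exclusive to one list), ``AB``, ``AC``, ``BC``
    (exactly two), ``ABC`` (all three). The counts sum to the union size.
    """
    a, b, c = set(list_a), set(list_b), set(list_c)
    abc = a & b & c
    return {
        "A": len(a - b - c),
        "B": len(b - a - c),
        "C": len(c - a - b),
        "AB": len((a & b) - abc),
        "AC": len((a & c) - abc),
        "BC": len((b & c) - abc),
        "ABC": len(abc),
    }
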