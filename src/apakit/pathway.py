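"""Per-sample summed-Z pathway summary scores and group comparison.

Each gene in a user-supplied set is Z-scored across all cohort samples
(mean 0, SD 1 with the n-1 denominator); a sample's pathway score is the sum
of its Z scores over the usable genes.  Higher scores mean higher average
expression of the set.  Scores are compared between sample groups with a
two-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffapa import GroupAssignment
from .io_formats import GeneSampleMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("empty gene set")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate ids in gene set")


@dataclass
class ScoreVector:
    scores: pd.Series
    genes_used: list[str]
    genes_dropped: list[str] = field(default_factory=list)


def zscore_matrix(expression: GeneSampleMatrix, genes: GeneSet | Sequence[str]) -> pd.DataFrame:
    """Z-score each requested gene's expression across all cohort samples.

    Genes absent from the matrix or with zero SD are dropped with a warning;
    the dropped list is available on ``DataFrame.attrs["genes_dropped"]``.
    """
    ids = list(genes.genes) if isinstance(genes, GeneSet) else list(genes)
    if expression.data.shape[1] < 2:
        raise ValueError("need >= 2 samples to Z-score")
    present = [g for g in ids if g in expression.data.index]
    absent = [g for g in ids if g not in expression.data.index]
    sub = expression.data.loc[present].astype(float)
    sd = sub.std(axis=1, ddof=1)
    usable = sd > 0
    dropped = absent + list(sub.index[~usable])
    if dropped:
        logger.warning("zscore_matrix: dropping %d unusable gene(s): %s", len(dropped), dropped[:5])
    sub = sub.loc[usable]
    if sub.empty:
        raise ValueError("no usable gene in the set (all absent or zero variance)")
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd[usable], axis=0)
    z.attrs["genes_dropped"] = dropped
    return z


def summary_score(z: pd.DataFrame) -> ScoreVector:
    """Per-sample sum of Z scores over the genes of the set."""
    scores = z.sum(axis=0)
    scores.name = "summary_score"
    return ScoreVector(
        scores=scores,
        genes_used=list(z.index),
        genes_dropped=list(z.attrs.get("genes_dropped", [])),
    )


def pathway_score(expression: GeneSampleMatrix, genes: GeneSet | Sequence[str]) -> ScoreVector:
    """Convenience: Z-score then sum."""
    return summary_score(zscore_matrix(expression, genes))


def compare_score_groups(scores: ScoreVector, groups: GroupAssignment) -> dict[str, float]:
    """Two-sided Wilcoxon rank-sum of summary scores, condition vs control."""
    s = scores.scores
    cond = s[[x for x in groups.samples("condition") if x in s.index]].to_numpy(dtype=float)
    ctrl = s[[x for x in groups.samples("control") if x in s.index]].to_numpy(dtype=float)
    if cond.size == 0 or ctrl.size == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(cond, ctrl, alternative="two-sided", method="asymptotic")
    return {
        "p": float(res.pvalue),
        "median_condition": float(np.median(cond)),
        "median_control": float(np.median(ctrl)),
        "n_condition": int(cond.size),
        "n_control": int(ctrl.size),
    }
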