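"""Sample stratification and per-gene differential 3'UTR calling.

Samples are split into condition and control either by mutation status
(loss-of-function = nonsense or frameshift calls for a gene, the classes
presumed to abolish protein function; missense does not qualify) or by
expression quartile (condition = below the 25th percentile, control = above
the 75th).  Each gene's metric is then compared between groups with a
two-sided Wilcoxon rank-sum test (or Student's t-test), p-values are
Benjamini-Hochberg adjusted across tested genes, and genes are classed
lengthened / shortened / unchanged at q < alpha.  For both supported metric
dialects a larger value means a longer 3'UTR (more distal poly(A)-site use),
so "lengthened" always means a larger metric in the condition group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneSampleMatrix, MAFRecord

LOF_CLASSES = frozenset({"Nonsense_Mutation", "Frame_Shift_Ins", "Frame_Shift_Del"})

CONDITION = "condition"
CONTROL = "control"
EXCLUDED = "excluded"


@dataclass
class GroupAssignment:
    """sample -> {condition, control, excluded}, plus the rule that produced it."""

    assignments: pd.Series
    note: str

    def __post_init__(self) -> None:
        bad = set(self.assignments.unique()) - {CONDITION, CONTROL, EXCLUDED}
        if bad:
            raise ValueError(f"invalid group labels: {sorted(bad)}")

    def samples(self, group: str) -> list[str]:
        return list(self.assignments.index[self.assignments == group])

    def swapped(self) -> "GroupAssignment":
        """Return a copy with condition and control roles exchanged."""
        mapping = {CONDITION: CONTROL, CONTROL: CONDITION, EXCLUDED: EXCLUDED}
        return GroupAssignment(self.assignments.map(mapping), note=self.note + " (swapped)")


def stratify_by_mutation(
    maf: list[MAFRecord],
    roster: list[str],
    gene: str = "APC",
    classes: frozenset[str] = LOF_CLASSES,
) -> GroupAssignment:
    """Condition = samples with >= 1 qualifying mutation record for ``gene``.

    ``roster`` lists every sample in the cohort so that wild-type samples
    (absent from the MAF) land in the control group.
    """
    if not roster:
        raise ValueError("empty sample roster")
    if len(set(roster)) != len(roster):
        raise ValueError("duplicate samples in roster")
    hit = {
        r.sample_barcode
        for r in maf
        if r.gene_symbol == gene and r.variant_classification in classes
    }
    labels = pd.Series(
        [CONDITION if s in hit else CONTROL for s in roster], index=roster, dtype=object
    )
    note = f"mutation stratification: gene={gene} classes={sorted(classes)}"
    return GroupAssignment(labels, note=note)


def stratify_by_expression_quartiles(
    expression: GeneSampleMatrix,
    gene: str,
    low_is_condition: bool = True,
) -> GroupAssignment:
    """Condition = samples strictly below Q1 of ``gene`` expression, control
    strictly above Q3; the interquartile middle is excluded.

    Quartiles use linear interpolation; samples tied exactly with a quartile
    boundary are excluded (strict inequalities).  ``low_is_condition=False``
    swaps the roles.
    """
    if gene not in expression.data.index:
        raise ValueError(f"gene {gene!r} not present in expression matrix")
    vals = expression.data.loc[gene].dropna()
    if len(vals) < 8:
        raise ValueError(f"need >= 8 samples with expression for {gene!r}, got {len(vals)}")
    q1, q3 = np.percentile(vals.to_numpy(dtype=float), [25, 75])
    if q1 == q3:
        raise ValueError(f"degenerate quartiles for {gene!r} (Q1 == Q3 == {q1})")
    low = vals.index[vals < q1]
    high = vals.index[vals > q3]
    labels = pd.Series(EXCLUDED, index=vals.index, dtype=object)
    labels[low] = CONDITION if low_is_condition else CONTROL
    labels[high] = CONTROL if low_is_condition else CONDITION
    role = "low" if low_is_condition else "high"
    note = f"expression quartile stratification: gene={gene} condition={role} (<Q1)" \
        if low_is_condition else f"expression quartile stratification: gene={gene} condition=high (>Q3)"
    return GroupAssignment(labels, note=note)


def test_differential_apa(
    utr: GeneSampleMatrix,
    groups: GroupAssignment,
    test: str = "wilcoxon",
    alpha: float = 0.05,
    min_per_group: int = 10,
) -> pd.DataFrame:
    """Per-gene two-group comparison of the 3'UTR metric with BH adjustment.

    Returns one row per gene with group sizes, group means and medians,
    ``delta`` (condition mean - control mean), the test statistic, raw p,
    BH q, and a class label: ``lengthened`` (q < alpha, delta > 0),
    ``shortened`` (q < alpha, delta < 0), ``unchanged`` (tested, q >= alpha),
    or ``untested`` (fewer than ``min_per_group`` non-missing values in
    either group; excluded from the BH family).

    The Wilcoxon p uses the normal approximation with tie and continuity
    corrections; ``test="ttest"`` uses a two-sided Student's t-test.
    """
    if utr.tag != "utr_metric":
        raise ValueError("test_differential_apa expects a utr_metric matrix")
    if test not in ("wilcoxon", "ttest"):
        raise ValueError(f"unknown test {test!r}")

    cond = [s for s in groups.samples(CONDITION) if s in utr.data.columns]
    ctrl = [s for s in groups.samples(CONTROL) if s in utr.data.columns]
    if not cond or not ctrl:
        raise ValueError("both condition and control groups must be non-empty")

    A = utr.data[cond].to_numpy(dtype=float)   # genes x n_condition
    B = utr.data[ctrl].to_numpy(dtype=float)
    nA = np.isfinite(A).sum(axis=1)
    nB = np.isfinite(B).sum(axis=1)
    testable = (nA >= min_per_group) & (nB >= min_per_group)
    if not testable.any():
        raise ValueError("no gene has enough non-missing values in both groups")

    genes = np.asarray(utr.genes)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows become untested
        meanA = np.nanmean(np.where(np.isfinite(A), A, np.nan), axis=1)
        meanB = np.nanmean(np.where(np.isfinite(B), B, np.nan), axis=1)
        medA = np.nanmedian(np.where(np.isfinite(A), A, np.nan), axis=1)
        medB = np.nanmedian(np.where(np.isfinite(B), B, np.nan), axis=1)

    stat = np.full(len(genes), np.nan)
    p = np.full(len(genes), np.nan)
    At, Bt = A[testable], B[testable]
    if test == "wilcoxon":
        res = stats.mannwhitneyu(
            At, Bt, axis=1, nan_policy="omit",
            alternative="two-sided", method="asymptotic", use_continuity=True,
        )
        stat[testable] = np.asarray(res.statistic, dtype=float)
        p[testable] = np.asarray(res.pvalue, dtype=float)
    else:
        res = stats.ttest_ind(At, Bt, axis=1, nan_policy="omit", equal_var=True)
        stat[testable] = np.asarray(res.statistic, dtype=float)
        p[testable] = np.asarray(res.pvalue, dtype=float)

    q = np.full(len(genes), np.nan)
    q[testable] = multipletests(p[testable], method="fdr_bh")[1]

    delta = meanA - meanB
    cls = np.full(len(genes), "untested", dtype=object)
    sig = testable & (q < alpha)
    cls[testable] = "unchanged"
    cls[sig & (delta > 0)] = "lengthened"
    cls[sig & (delta < 0)] = "shortened"

    return pd.DataFrame(
        {
            "gene": genes,
            "n_condition": nA,
            "n_control": nB,
            "mean_condition": meanA,
            "mean_control": meanB,
            "median_condition": medA,
            "median_control": medB,
            "delta": delta,
            "statistic": stat,
            "p": p,
            "q": q,
            "class": cls,
        }
    )
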