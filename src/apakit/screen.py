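"""Genome-wide expression vs median-3'UTR Pearson screen and cohort comparison.

For each gene in a cohort, the screen correlates its expression (TPM) with
the per-sample median 3'UTR metric across samples.  A positive r means higher
expression of the gene tracks globally longer 3'UTRs (more distal poly(A)-site
use) in that cohort.  Screens from multiple cohorts are compared by
correlating their per-gene r-vectors pairwise; cohorts whose regulatory
signal diverges from the rest (e.g. a lineage where the usual poly(A)-site
regulators are decoupled) show a low median pairwise correlation and are
flagged as outliers by a Tukey fence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GeneSampleMatrix

MIN_SHARED_SAMPLES = 10
MIN_PAIRED_OBS = 10
MIN_SHARED_GENES = 100


@dataclass
class ScreenResult:
    """Per-gene Pearson records plus the genes that could not be tested."""

    records: pd.DataFrame  # columns: gene, r, p, p_adj, n
    skipped: pd.DataFrame  # columns: gene, reason
    n_samples: int

    def r_vector(self) -> pd.Series:
        return self.records.set_index("gene")["r"]


@dataclass
class CohortSimilarity:
    """Pairwise Pearson similarity of per-gene r-vectors across cohorts."""

    matrix: pd.DataFrame        # symmetric, unit diagonal
    median_pairwise: pd.Series  # per cohort, median of off-diagonal row
    n_shared_genes: int

    @property
    def cohorts(self) -> list[str]:
        return list(self.matrix.index)


def pearson_pvalue(r: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Two-sided Pearson p via the exact t-transform with n-2 df."""
    r = np.asarray(r, dtype=float)
    n = np.asarray(n, dtype=float)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    # |r| = 1 exactly -> t infinite -> p = 0 (below any reportable floor)
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    return np.minimum(p, 1.0)


def screen_cohort(expression: GeneSampleMatrix, median_utr: pd.Series) -> ScreenResult:
    """Pearson-correlate every gene's TPM with the sample-level median 3'UTR.

    Genes with zero variance or fewer than 10 paired observations are skipped
    and listed in the ``skipped`` report.  Bonferroni adjustment uses the
    number of genes actually tested.
    """
    if expression.tag != "expression_tpm":
        raise ValueError("screen_cohort expects an expression_tpm matrix")
    shared = [s for s in expression.samples if s in median_utr.index and not np.isnan(median_utr[s])]
    if len(shared) < MIN_SHARED_SAMPLES:
        raise ValueError(
            f"need >= {MIN_SHARED_SAMPLES} shared samples, got {len(shared)}"
        )

    X = expression.data[shared].to_numpy(dtype=float)            # genes x samples
    y = median_utr.loc[shared].to_numpy(dtype=float)             # samples
    genes = np.asarray(expression.genes)

    mask = np.isfinite(X)                                        # y is finite by construction
    n = mask.sum(axis=1)

    Xz = np.where(mask, X, 0.0)
    Y = np.where(mask, y[None, :], 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mx = Xz.sum(axis=1) / n
        my = Y.sum(axis=1) / n
        dx = np.where(mask, X - mx[:, None], 0.0)
        dy = np.where(mask, y[None, :] - my[:, None], 0.0)
        sxy = (dx * dy).sum(axis=1)
        sxx = (dx * dx).sum(axis=1)
        syy = (dy * dy).sum(axis=1)
        r = sxy / np.sqrt(sxx * syy)

    testable = (n >= MIN_PAIRED_OBS) & (sxx > 0) & (syy > 0)
    reasons = np.where(
        n < MIN_PAIRED_OBS, "too_few_paired_observations",
        np.where(sxx <= 0, "zero_variance_expression", "zero_variance_median_utr"),
    )
    skipped = pd.DataFrame({"gene": genes[~testable], "reason": reasons[~testable]})

    r_t = np.clip(r[testable], -1.0, 1.0)
    n_t = n[testable]
    p = pearson_pvalue(r_t, n_t)
    m = int(testable.sum())
    records = pd.DataFrame(
        {
            "gene": genes[testable],
            "r": r_t,
            "p": p,
            "p_adj": np.minimum(1.0, p * m),
            "n": n_t.astype(int),
        }
    )
    return ScreenResult(records=records, skipped=skipped, n_samples=len(shared))


def compare_cohorts(r_vectors: Mapping[str, pd.Series]) -> CohortSimilarity:
    """Pairwise Pearson correlation of per-gene r-vectors across cohorts.

    Vectors are aligned on the intersection of tested genes; the intersection
    size is reported on the result.  Each cohort's summary is the median of
    its off-diagonal row.
    """
    if len(r_vectors) < 3:
        raise ValueError("need >= 3 cohorts to compare")
    names = list(r_vectors)
    shared: pd.Index | None = None
    for v in r_vectors.values():
        idx = v.dropna().index
        shared = idx if shared is None else shared.intersection(idx)
    assert shared is not None
    if len(shared) < MIN_SHARED_GENES:
        raise ValueError(
            f"gene intersection across cohorts too small: {len(shared)} < {MIN_SHARED_GENES}"
        )
    mat = np.column_stack([r_vectors[c].loc[shared].to_numpy(dtype=float) for c in names])
    corr = np.corrcoef(mat, rowvar=False)
    sim = pd.DataFrame(corr, index=names, columns=names)
    off = sim.where(~np.eye(len(names), dtype=bool))
    med = off.median(axis=1)
    med.name = "median_pairwise_r"
    return CohortSimilarity(matrix=sim, median_pairwise=med, n_shared_genes=len(shared))


def rank_outliers(similarity: CohortSimilarity) -> pd.DataFrame:
    """Rank cohorts by median pairwise r and flag low outliers.

    A cohort is flagged when its median pairwise value falls below
    Q1 - 1.5*IQR of the cohort medians (lower Tukey fence).  The full ranking
    is always emitted; the flag is advisory.
    """
    med = similarity.median_pairwise
    q1, q3 = np.percentile(med.to_numpy(), [25, 75])
    fence = q1 - 1.5 * (q3 - q1)
    out = pd.DataFrame(
        {
            "cohort": med.index,
            "median_pairwise_r": med.to_numpy(),
            "outlier": med.to_numpy() < fence,
        }
    ).sort_values("median_pairwise_r", kind="mergesort", ignore_index=True)
    return out
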