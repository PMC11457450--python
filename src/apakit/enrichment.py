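"""Resampling enrichment of a target gene set among differential-APA classes.

Given a differential-APA table and a designated target set (e.g. genes bound
by an RNA-binding protein in a CLIP experiment), the observed fraction of
targets in each class (lengthened / shortened / unchanged) is compared with
an empirical null built from random gene sets of the same size drawn without
replacement from the tested universe.  A delta-shift comparison (rank-sum on
per-gene effect sizes, targets vs non-targets) is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

CLASSES = ("lengthened", "shortened", "unchanged")

DEFAULT_B = 10_000  # draws in the empirical null


def _tested(diff: pd.DataFrame) -> pd.DataFrame:
    return diff[diff["class"] != "untested"]


def observed_class_fractions(targets: Iterable[str], diff: pd.DataFrame) -> tuple[pd.Series, int]:
    """Class fractions over the intersection of targets with tested genes.

    Returns ``(fractions, m)`` where ``m`` is the intersection size; the
    three fractions sum to 1.
    """
    tested = _tested(diff)
    sub = tested[tested["gene"].isin(set(targets))]
    m = len(sub)
    if m == 0:
        raise ValueError("no target gene overlaps the tested universe")
    frac = sub["class"].value_counts(normalize=True).reindex(CLASSES, fill_value=0.0)
    frac.name = "fraction"
    return frac, m


@dataclass
class EnrichmentResult:
    m: int
    observed: pd.Series           # fraction per class
    null_mean: pd.Series
    null_sd: pd.Series
    empirical_p: pd.Series        # one-sided P(null >= observed), plus-one corrected
    B: int
    seed: int
    null_fractions: pd.DataFrame  # B x 3, for diagnostics/output


def subsample_null(
    diff: pd.DataFrame,
    targets: Iterable[str],
    B: int = DEFAULT_B,
    seed: int = 17,
) -> EnrichmentResult:
    """Empirical null of class fractions from random size-m gene sets.

    Each of the B draws samples m genes without replacement from the tested
    universe; per-class counts of such a draw follow the multivariate
    hypergeometric distribution, which is what is sampled.  The per-class
    empirical p is the plus-one estimator
    ``(1 + #{null fraction >= observed}) / (B + 1)``, so it is never 0.
    """
    tested = _tested(diff)
    observed, m = observed_class_fractions(targets, diff)
    n_universe = len(tested)
    if m > n_universe:
        raise ValueError(f"target-set size {m} exceeds tested universe {n_universe}")
    counts = tested["class"].value_counts().reindex(CLASSES, fill_value=0)
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_hypergeometric(counts.to_numpy(), m, size=B) / m
    null = pd.DataFrame(draws, columns=CLASSES)
    obs = observed.to_numpy()
    p = (1 + (draws >= obs[None, :]).sum(axis=0)) / (B + 1)
    return EnrichmentResult(
        m=m,
        observed=observed,
        null_mean=null.mean().rename("null_mean"),
        null_sd=null.std(ddof=1).rename("null_sd"),
        empirical_p=pd.Series(p, index=CLASSES, name="empirical_p"),
        B=B,
        seed=seed,
        null_fractions=null,
    )


def compare_delta_targets(targets: Iterable[str], diff: pd.DataFrame) -> dict[str, float]:
    """Two-sided rank-sum test of per-gene delta, targets vs non-targets.

    A more positive delta means a longer 3'UTR in the condition group; the
    test asks whether target genes shift differently from the rest of the
    tested universe.  Returns the p-value and both group medians and sizes.
    """
    tested = _tested(diff)
    is_target = tested["gene"].isin(set(targets)).to_numpy()
    d = tested["delta"].to_numpy(dtype=float)
    a, b = d[is_target], d[~is_target]
    if a.size == 0 or b.size == 0:
        raise ValueError("both target and non-target groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return {
        "p": float(res.pvalue),
        "median_targets": float(np.median(a)),
        "median_others": float(np.median(b)),
        "n_targets": int(a.size),
        "n_others": int(b.size),
    }


def read_gene_list(path, ortholog_map=None) -> set[str]:
    """Read a one-gene-per-line list, optionally translating identifiers
    through a two-column (source -> target) ortholog TSV."""
    with open(path) as fh:
        genes = [line.strip() for line in fh if line.strip() and not line.startswith("#")]
    if ortholog_map is not None:
        mapping = pd.read_csv(ortholog_map, sep="\t", header=None, comment="#", dtype=str)
        lut = dict(zip(mapping.iloc[:, 0], mapping.iloc[:, 1]))
        genes = [lut[g] for g in genes if g in lut]
    return set(genes)
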