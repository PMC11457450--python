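"""Gene-level 3'UTR metrics from proximal/distal region counts.

The relative expression difference (RED) of a gene in a sample is

    RED = log2((distal + pc) / (proximal + pc))

with pseudocount ``pc`` (default 1).  Larger RED means relatively more reads
in the distal 3'UTR segment, i.e. more distal poly(A)-site use and a longer
3'UTR on average.  Genes with fewer than ``min_total`` reads across both
regions are reported as missing rather than as unstable ratios.

The per-sample median of the gene-level metric ("median 3'UTR") summarizes
global poly(A)-site selection for that sample.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .io_formats import GeneSampleMatrix

logger = logging.getLogger(__name__)

DEFAULT_PSEUDOCOUNT = 1.0
DEFAULT_MIN_TOTAL = 10


def compute_red(
    proximal_count: int,
    distal_count: int,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    min_total: int = DEFAULT_MIN_TOTAL,
) -> float:
    """log2 distal/proximal read ratio, or NaN when too few reads.

    Returns NaN (missing) when ``proximal + distal < min_total`` or when a
    zero pseudocount would make the ratio undefined; never returns infinity.
    """
    if proximal_count < 0 or distal_count < 0:
        raise ValueError("region counts must be non-negative")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if proximal_count + distal_count < min_total:
        return math.nan
    num = distal_count + pseudocount
    den = proximal_count + pseudocount
    if num == 0 or den == 0:
        return math.nan
    return math.log2(num / den)


def quantify_cohort(
    counts: pd.DataFrame,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    min_total: int = DEFAULT_MIN_TOTAL,
) -> GeneSampleMatrix:
    """Turn a long region-count table into a RED metric matrix.

    ``counts`` needs columns gene, sample, proximal_count, distal_count with
    unique (gene, sample) pairs; absent pairs come out missing.
    """
    required = {"gene", "sample", "proximal_count", "distal_count"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"count table missing column(s): {sorted(missing)}")
    if counts.duplicated(subset=["gene", "sample"]).any():
        dup = counts[counts.duplicated(subset=["gene", "sample"])].iloc[0]
        raise ValueError(f"duplicate (gene, sample) pair: ({dup['gene']}, {dup['sample']})")

    prox = counts["proximal_count"].to_numpy(dtype=float)
    dist = counts["distal_count"].to_numpy(dtype=float)
    if (prox < 0).any() or (dist < 0).any():
        raise ValueError("region counts must be non-negative")
    total = prox + dist
    with np.errstate(divide="ignore", invalid="ignore"):
        red = np.log2((dist + pseudocount) / (prox + pseudocount))
    red[total < min_total] = np.nan
    red[~np.isfinite(red)] = np.nan

    long = counts[["gene", "sample"]].copy()
    long["red"] = red
    wide = long.pivot(index="gene", columns="sample", values="red")
    wide.index.name = None
    wide.columns.name = None
    return GeneSampleMatrix(wide, tag="utr_metric", dialect="red_log_ratio")


def median_utr(utr: GeneSampleMatrix) -> pd.Series:
    """Per-sample median of the gene-level 3'UTR metric, skipping missing cells.

    Samples with no non-missing gene are reported missing, with a warning.
    """
    if utr.tag != "utr_metric":
        raise ValueError("median_utr expects a utr_metric matrix")
    med = utr.data.median(axis=0, skipna=True)
    empty = utr.data.notna().sum(axis=0) == 0
    if empty.any():
        logger.warning(
            "median_utr: %d sample(s) have no non-missing gene: %s",
            int(empty.sum()), list(utr.data.columns[empty])[:5],
        )
        med[empty] = np.nan
    med.name = "median_utr"
    return med
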