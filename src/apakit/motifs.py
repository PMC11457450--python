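"""IUPAC motif scanning of 3'UTR sequences and class-level presence enrichment.

Motifs are degenerate DNA words over the IUPAC alphabet (S = G/C, M = A/C,
W = A/T, ...).  Sequences are scanned on the sense strand only — 3'UTRs are
supplied in transcript orientation and RNA-binding proteins read the mRNA —
with overlapping matches allowed; an N in the sequence matches nothing.

``TOP_ENRICHED_MOTIFS`` holds the five G/C-rich motifs most enriched in
3'UTRs that lengthen upon APC loss of function; any IUPAC motif list is
accepted by the scanning and enrichment functions.
"""

from __future__ import annotations

import re
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

#: The five most significantly enriched motifs in lengthened 3'UTRs.
TOP_ENRICHED_MOTIFS: tuple[str, ...] = (
    "CSGGCCMC", "GCCCCS", "GGGGGAS", "CGGSCC", "CCCWGSCC",
)


def validate_motif(motif: str) -> str:
    if not motif:
        raise ValueError("empty motif")
    motif = motif.upper()
    bad = set(motif) - set(IUPAC)
    if bad:
        raise ValueError(f"illegal IUPAC character(s) {sorted(bad)} in motif {motif!r}")
    return motif


def _motif_regex(motif: str) -> re.Pattern[str]:
    # lookahead so overlapping matches are all reported; classes contain only
    # ACGT, so an N in the sequence can never match
    body = "".join(c if len(IUPAC[c]) == 1 else f"[{IUPAC[c]}]" for c in motif)
    return re.compile(f"(?=({body}))")


def scan_sequence(sequence: str, motif: str) -> list[int]:
    """Return ascending 0-based start positions of all (overlapping) matches."""
    motif = validate_motif(motif)
    return [m.start() for m in _motif_regex(motif).finditer(sequence.upper())]


def has_motif(sequence: str, motifs: Sequence[str]) -> bool:
    """True if the sequence contains >= 1 match of >= 1 motif."""
    return any(scan_sequence(sequence, m) for m in motifs)


def presence_by_class(
    diff: pd.DataFrame,
    sequences: Mapping[str, str],
    motifs: Sequence[str] = TOP_ENRICHED_MOTIFS,
    bootstrap_B: int = 1000,
    seed: int = 17,
    continuity: bool = False,
) -> pd.DataFrame:
    """Motif-presence fraction per APA class, with bootstrap CI and chi-squared.

    For each class (lengthened / shortened / unchanged) the fraction of genes
    whose longest 3'UTR contains at least one of the motifs is computed over
    the classed genes that have a sequence (genes without one are dropped and
    counted in ``n_dropped_no_sequence`` on ``DataFrame.attrs``).  Each class
    is compared to the unchanged reference with a 2x2 chi-squared test (df=1,
    no continuity correction unless ``continuity=True``); the 95% CI is a
    percentile bootstrap over genes within the class.
    """
    motifs = [validate_motif(m) for m in motifs]
    rng = np.random.default_rng(seed)

    presence: dict[str, np.ndarray] = {}
    dropped = 0
    for cls in ("lengthened", "shortened", "unchanged"):
        genes = diff.loc[diff["class"] == cls, "gene"]
        with_seq = [g for g in genes if g in sequences]
        dropped += len(genes) - len(with_seq)
        presence[cls] = np.array([has_motif(sequences[g], motifs) for g in sorted(with_seq)], dtype=bool)

    if presence["unchanged"].size == 0:
        raise ValueError("unchanged class is empty: no reference for enrichment")

    ref = presence["unchanged"]
    rows = []
    for cls in ("lengthened", "shortened", "unchanged"):
        ind = presence[cls]
        n, k = ind.size, int(ind.sum())
        frac = k / n if n else np.nan
        if n:
            boot = rng.choice(ind.astype(float), size=(bootstrap_B, n), replace=True).mean(axis=1)
            ci_low, ci_high = np.percentile(boot, [2.5, 97.5])
        else:
            ci_low = ci_high = np.nan
        table = np.array(
            [[k, n - k], [int(ref.sum()), ref.size - int(ref.sum())]], dtype=float
        )
        if n == 0 or (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            chi2, p = 0.0, 1.0  # degenerate margin: no evidence of difference
        else:
            chi2, p, _, _ = stats.chi2_contingency(table, correction=continuity)
        rows.append(
            {
                "class": cls, "n_genes": n, "n_with_motif": k, "fraction": frac,
                "ci_low": ci_low, "ci_high": ci_high, "chi2_statistic": chi2, "p": p,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["n_dropped_no_sequence"] = dropped
    return out
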