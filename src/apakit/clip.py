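"""CLIP binding sites and their position relative to poly(A) signals.

Replicate sliding-window counts are pooled, windows below a read threshold
are discarded, and overlapping surviving windows are merged into binding
sites.  Around each site the nearest canonical poly(A) hexamer (AATAAA or
ATTAAA) is located up- and downstream within +-500 bp in transcript
orientation (downstream positive), and the signed distances are summarized
by a kernel-density mode.  Binding sites are also related to annotated
poly(A) sites binned by 5'->3' rank within the 3'UTR (proximal /
intermediate / distal).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import BedRecord, GenomicInterval
from .synthetic import PAS_HEXAMERS, reverse_complement

DEFAULT_MIN_READS = 50
SEARCH_RADIUS = 500


@dataclass(frozen=True)
class BindingSite:
    interval: GenomicInterval
    gene: str = "unknown"

    @property
    def center(self) -> int:
        """Floor midpoint of the interval."""
        return self.interval.midpoint


@dataclass(frozen=True)
class PolyASiteRecord:
    """An annotated poly(A) site with its 5'->3' rank bin within the 3'UTR."""

    interval: GenomicInterval
    gene: str
    rank_bin: str  # proximal | intermediate | distal

    def __post_init__(self) -> None:
        if self.rank_bin not in ("proximal", "intermediate", "distal"):
            raise ValueError(f"invalid rank_bin {self.rank_bin!r}")


@dataclass
class FlankingDistances:
    """Signed distances (bp) from a site center to the nearest hexamer in each
    direction; None when no hexamer lies within the search radius."""

    upstream: int | None
    downstream: int | None
    truncated: bool = False


@dataclass
class DistanceProfile:
    distances: np.ndarray
    grid: np.ndarray
    density: np.ndarray
    mode: float
    bandwidth: float


@dataclass
class BinnedDistanceResult:
    distances: dict[str, np.ndarray]
    pairwise_p: pd.DataFrame
    n_excluded_single_site_genes: int
    medians: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# windows -> binding sites
# ---------------------------------------------------------------------------

def pool_and_filter_windows(
    windows: Sequence[BedRecord], min_reads: int = DEFAULT_MIN_READS
) -> list[BindingSite]:
    """Pool replicate counts, drop windows under ``min_reads``, merge overlaps.

    Each window's replicate counts sit in its BED extra columns; vectors must
    have the same length across windows.  Surviving windows that overlap on
    the same contig and strand are merged into the union interval before the
    center is computed.
    """
    if not windows:
        return []
    n_rep = len(windows[0].extra)
    for w in windows:
        if len(w.extra) != n_rep:
            raise ValueError(
                f"ragged replicate vectors: expected {n_rep} columns, "
                f"got {len(w.extra)} for window {w.name!r}"
            )
    surviving = [w for w in windows if sum(w.extra) >= min_reads]
    surviving.sort(key=lambda w: (w.interval.contig, w.interval.strand, w.interval.start))

    sites: list[BindingSite] = []
    current: BedRecord | None = None
    cur_end = 0
    for w in surviving:
        if (
            current is not None
            and w.interval.contig == current.interval.contig
            and w.interval.strand == current.interval.strand
            and w.interval.start < cur_end
        ):
            cur_end = max(cur_end, w.interval.end)
            continue
        if current is not None:
            iv = GenomicInterval(
                current.interval.contig, current.interval.start, cur_end, current.interval.strand
            )
            sites.append(BindingSite(interval=iv, gene=current.name))
        current, cur_end = w, w.interval.end
    if current is not None:
        iv = GenomicInterval(
            current.interval.contig, current.interval.start, cur_end, current.interval.strand
        )
        sites.append(BindingSite(interval=iv, gene=current.name))
    return sites


# ---------------------------------------------------------------------------
# hexamer search
# ---------------------------------------------------------------------------

def extract_context(
    sequence: str, center: int, strand: str, radius: int = SEARCH_RADIUS
) -> tuple[str, int]:
    """Cut a +-radius window around a genomic center, in transcript orientation.

    Returns ``(context, center_index)``; for minus-strand sites the context is
    reverse-complemented so downstream (3') is always to the right.
    """
    lo = max(0, center - radius)
    hi = min(len(sequence), center + radius + 1)
    context = sequence[lo:hi]
    idx = center - lo
    if strand == "-":
        context = reverse_complement(context)
        idx = len(context) - 1 - idx
    return context, idx


def find_flanking_pas(
    context: str,
    center_index: int | None = None,
    max_distance: int = SEARCH_RADIUS,
    hexamers: Sequence[str] = PAS_HEXAMERS,
) -> FlankingDistances:
    """Nearest canonical hexamer up- and downstream of the site center.

    ``context`` is in transcript orientation; distances are hexamer start
    minus center, downstream positive.  A hexamer starting exactly at the
    center counts as downstream (distance 0).  If the context is shorter than
    the full +-max_distance span the available span is searched and the
    result flagged truncated.
    """
    context = context.upper()
    if center_index is None:
        center_index = len(context) // 2
    if not (0 <= center_index < len(context)):
        raise ValueError("center_index outside context")
    starts: list[int] = []
    for hx in hexamers:
        start = context.find(hx)
        while start != -1:
            starts.append(start)
            start = context.find(hx, start + 1)
    offsets = np.array(sorted(s - center_index for s in starts), dtype=int)
    up = offsets[(offsets < 0) & (offsets >= -max_distance)]
    down = offsets[(offsets >= 0) & (offsets <= max_distance)]
    truncated = (center_index < max_distance) or (len(context) - center_index - 1 < max_distance)
    return FlankingDistances(
        upstream=int(up.max()) if up.size else None,
        downstream=int(down.min()) if down.size else None,
        truncated=truncated,
    )


def flanking_distances_for_sites(
    sites: Sequence[BindingSite],
    sequences: Mapping[str, str],
    radius: int = SEARCH_RADIUS,
) -> pd.DataFrame:
    """Per-site nearest up/downstream hexamer distances from genomic sequences.

    ``sequences`` maps contig -> genomic-orientation sequence; minus-strand
    contexts are reverse-complemented at this boundary.
    """
    rows = []
    for s in sites:
        seq = sequences.get(s.interval.contig)
        if seq is None:
            continue
        context, idx = extract_context(seq, s.center, s.interval.strand, radius)
        fl = find_flanking_pas(context, idx, max_distance=radius)
        rows.append(
            {
                "gene": s.gene, "contig": s.interval.contig, "center": s.center,
                "strand": s.interval.strand, "upstream": fl.upstream,
                "downstream": fl.downstream, "truncated": fl.truncated,
            }
        )
    if not rows:
        raise ValueError("no site maps to a supplied sequence")
    return pd.DataFrame(rows)


def pooled_signed_distances(table: pd.DataFrame, nearest_only: bool = False) -> np.ndarray:
    """Collect signed distances from a flanking-distance table.

    By default both the nearest upstream and nearest downstream hexamer of
    each site contribute; ``nearest_only`` keeps just the globally nearest.
    """
    out: list[float] = []
    for _, row in table.iterrows():
        up, down = row["upstream"], row["downstream"]
        cand = [d for d in (up, down) if d is not None and not pd.isna(d)]
        if not cand:
            continue
        if nearest_only:
            out.append(min(cand, key=abs))
        else:
            out.extend(cand)
    return np.asarray(out, dtype=float)


# ---------------------------------------------------------------------------
# density mode
# ---------------------------------------------------------------------------

def density_mode(
    distances: Sequence[float],
    grid_min: int = -SEARCH_RADIUS,
    grid_max: int = SEARCH_RADIUS,
    bw_method: str | float = "silverman",
) -> DistanceProfile:
    """Gaussian KDE of signed distances on a 1-bp grid; mode = argmax.

    Ties in density are broken toward the smallest offset.  Requires >= 20
    distances.  A degenerate all-equal sample yields a point mass at that
    offset.
    """
    d = np.asarray(distances, dtype=float)
    if d.size < 20:
        raise ValueError(f"need >= 20 distances for a density estimate, got {d.size}")
    grid = np.arange(grid_min, grid_max + 1, dtype=float)
    if np.ptp(d) == 0:
        density = np.zeros_like(grid)
        density[np.argmin(np.abs(grid - d[0]))] = 1.0
        return DistanceProfile(d, grid, density, float(d[0]), bandwidth=0.0)
    kde = stats.gaussian_kde(d, bw_method=bw_method)
    density = kde(grid)
    # round away float jitter so exact density ties resolve to the smaller offset
    scaled = np.round(density / density.max(), 10)
    mode = float(grid[int(np.argmax(scaled))])
    bandwidth = float(kde.factor * d.std(ddof=1))
    return DistanceProfile(d, grid, density, mode, bandwidth)


# ---------------------------------------------------------------------------
# rank-binned annotated poly(A) sites
# ---------------------------------------------------------------------------

def assign_rank_bins(pas: Sequence[BedRecord]) -> tuple[list[PolyASiteRecord], int]:
    """Bin each gene's annotated poly(A) sites by 5'->3' rank.

    The most 5' site (lowest genomic coordinate on +, highest on -) is
    proximal, the most 3' distal, anything between intermediate.  Genes with
    a single annotated site are excluded; their count is returned.
    """
    by_gene: dict[str, list[BedRecord]] = {}
    for r in pas:
        by_gene.setdefault(r.name, []).append(r)
    records: list[PolyASiteRecord] = []
    n_excluded = 0
    for gene, recs in by_gene.items():
        if len(recs) < 2:
            n_excluded += 1
            continue
        strand = recs[0].interval.strand
        ordered = sorted(recs, key=lambda r: r.interval.start, reverse=(strand == "-"))
        for rank, r in enumerate(ordered):
            bin_ = (
                "proximal" if rank == 0
                else "distal" if rank == len(ordered) - 1
                else "intermediate"
            )
            records.append(PolyASiteRecord(interval=r.interval, gene=gene, rank_bin=bin_))
    return records, n_excluded


def distances_to_binned_sites(
    sites: Sequence[BindingSite], pas: Sequence[PolyASiteRecord]
) -> BinnedDistanceResult:
    """Absolute site-center to poly(A)-site distances grouped by rank bin.

    Each binding site contributes one distance to every annotated site of its
    gene.  The hexamer coordinate is its transcript-orientation start
    (genomic start on +, end-1 on -).  Bin pairs are compared with two-sided
    Wilcoxon rank-sum tests.
    """
    by_gene: dict[str, list[PolyASiteRecord]] = {}
    for p in pas:
        by_gene.setdefault(p.gene, []).append(p)
    dist: dict[str, list[float]] = {"proximal": [], "intermediate": [], "distal": []}
    any_overlap = False
    for s in sites:
        for p in by_gene.get(s.gene, []):
            any_overlap = True
            pos = p.interval.start if p.interval.strand == "+" else p.interval.end - 1
            dist[p.rank_bin].append(abs(s.center - pos))
    if not any_overlap:
        raise ValueError("no binding site shares a gene with an annotated poly(A) site")

    arrays = {k: np.asarray(v, dtype=float) for k, v in dist.items()}
    bins = [b for b in ("proximal", "intermediate", "distal") if arrays[b].size]
    pmat = pd.DataFrame(np.nan, index=bins, columns=bins)
    for a, b in combinations(bins, 2):
        p = stats.mannwhitneyu(arrays[a], arrays[b], alternative="two-sided").pvalue
        pmat.loc[a, b] = pmat.loc[b, a] = p
    medians = {b: float(np.median(arrays[b])) for b in bins}
    return BinnedDistanceResult(
        distances=arrays, pairwise_p=pmat,
        n_excluded_single_site_genes=0, medians=medians,
    )
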