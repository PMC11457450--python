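"""Synthetic cohorts with known ground truth for every pipeline stage.

The generators emulate the statistical structure the analyses assume:

* a single latent per-sample state ``u_s`` (global poly(A)-site selection)
  that loads on most genes' 3'UTR metric, so the per-sample median is a
  meaningful global summary;
* "regulator" genes whose log-expression tracks ``u_s`` with a known sign
  (decoupled cohorts set the slopes to zero, emulating a lineage where the
  usual regulators are disconnected);
* mutation cohorts where loss-of-function samples carry nonsense/frameshift
  records and their target genes' metric is shifted by a known delta;
* 3'UTR sequences with planted IUPAC motif instances;
* overdispersed proximal/distal region counts (negative binomial);
* CLIP windows planted a known distance upstream of canonical poly(A)
  hexamers, on both strands, with Poisson replicate counts.

Every generator is deterministic given its seed and returns a
:class:`SimTruth` ledger describing exactly what was planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import BedRecord, GeneSampleMatrix, GenomicInterval, MAFRecord
from .motifs import IUPAC, TOP_ENRICHED_MOTIFS, validate_motif

PAS_HEXAMERS = ("AATAAA", "ATTAAA")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class CohortSimConfig:
    """Knobs of the latent-state cohort generator.

    ``regulator_effect`` is the slope of regulator log-expression on the
    latent state; ``gene_loading_mean`` the mean loading of the UTR metric on
    that state.  ``decoupled`` zeroes the regulator slopes while leaving the
    APA structure intact.
    """

    n_samples: int = 200
    n_genes: int = 2000
    n_regulators_pos: int = 5
    n_regulators_neg: int = 5
    regulator_effect: float = 0.6
    gene_loading_mean: float = 1.0
    noise_sd_utr: float = 1.0
    noise_sd_expr: float = 0.5
    decoupled: bool = False
    seed: int = 17
    regulator_genes: dict[str, int] | None = None  # gene -> sign; overrides random choice

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_genes", "n_regulators_pos", "n_regulators_neg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.noise_sd_utr <= 0 or self.noise_sd_expr <= 0:
            raise ValueError("noise SDs must be > 0")
        if self.n_regulators_pos + self.n_regulators_neg > self.n_genes:
            raise ValueError("more regulators than genes")


@dataclass
class SimTruth:
    """Ground-truth ledger for a simulated dataset; fields unused by a given
    generator stay at their defaults."""

    seed: int = 0
    regulators: dict[str, int] = field(default_factory=dict)   # gene -> +1 / -1
    latent_state: pd.Series | None = None                      # sample -> u_s
    target_genes: frozenset[str] = frozenset()
    delta: float = 0.0
    lof_samples: frozenset[str] = frozenset()
    motif_genes: frozenset[str] = frozenset()
    motif_plants: dict[str, list[tuple[int, str]]] = field(default_factory=dict)
    distal_fraction: pd.DataFrame | None = None                # f_gs
    d_true: float | None = None
    jitter_sd: float | None = None
    pas_positions: dict[str, list[int]] = field(default_factory=dict)  # transcript coords
    bound_pas_index: dict[str, int] = field(default_factory=dict)
    gene_strand: dict[str, str] = field(default_factory=dict)


def _gene_ids(n: int, prefix: str = "gene") -> list[str]:
    return [f"{prefix}{i:05d}" for i in range(n)]


def simulate_cohort(config: CohortSimConfig) -> tuple[GeneSampleMatrix, GeneSampleMatrix, SimTruth]:
    """Simulate one cohort: TPM expression, a UTR-metric matrix, and truth.

    The UTR metric is ``Y_gs = mu_g + lambda_g * u_s + noise`` with loadings
    drawn around ``gene_loading_mean`` (positive for the large majority of
    genes), so the per-sample median tracks ``u_s``.  Regulator genes'
    log-expression is ``alpha_r + sign * regulator_effect * u_s + noise``;
    all other genes are independent of ``u``.  TPM = exp(log-expression).
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    samples = [f"sample{i:04d}" for i in range(config.n_samples)]

    u = rng.standard_normal(config.n_samples)

    mu = rng.normal(0.0, 1.0, config.n_genes)
    lam = rng.normal(config.gene_loading_mean, 0.5, config.n_genes)
    utr_vals = (
        mu[:, None]
        + lam[:, None] * u[None, :]
        + rng.normal(0.0, config.noise_sd_utr, (config.n_genes, config.n_samples))
    )
    utr = GeneSampleMatrix(
        pd.DataFrame(utr_vals, index=genes, columns=samples),
        tag="utr_metric", dialect="length_like",
    )

    if config.regulator_genes is not None:
        missing = set(config.regulator_genes) - set(genes)
        if missing:
            raise ValueError(f"regulator_genes outside gene universe: {sorted(missing)[:5]}")
        reg_idx = np.array([genes.index(g) for g in config.regulator_genes])
        signs = np.array(list(config.regulator_genes.values()))
    else:
        n_reg = config.n_regulators_pos + config.n_regulators_neg
        reg_idx = rng.choice(config.n_genes, size=n_reg, replace=False)
        signs = np.array([+1] * config.n_regulators_pos + [-1] * config.n_regulators_neg)

    alpha = rng.normal(2.0, 1.0, config.n_genes)
    slope = np.zeros(config.n_genes)
    if not config.decoupled:
        slope[reg_idx] = signs * config.regulator_effect
    log_expr = (
        alpha[:, None]
        + slope[:, None] * u[None, :]
        + rng.normal(0.0, config.noise_sd_expr, (config.n_genes, config.n_samples))
    )
    expression = GeneSampleMatrix(
        pd.DataFrame(np.exp(log_expr), index=genes, columns=samples), tag="expression_tpm"
    )

    truth = SimTruth(
        seed=config.seed,
        regulators={genes[i]: int(s) for i, s in zip(reg_idx, signs)},
        latent_state=pd.Series(u, index=samples, name="u"),
    )
    return expression, utr, truth


def simulate_cohort_panel(
    n_cohorts: int,
    decoupled_indices: Sequence[int] = (),
    config: CohortSimConfig | None = None,
    seed: int = 17,
) -> dict[str, tuple[GeneSampleMatrix, GeneSampleMatrix, SimTruth]]:
    """Simulate several cohorts sharing one regulator panel.

    The regulator identities and signs are drawn once from ``seed`` and reused
    in every cohort (the same biology expressed in different sample sets), so
    coupled cohorts produce concordant per-gene correlation screens.  Cohorts
    listed in ``decoupled_indices`` keep the same APA structure but sever the
    regulator-expression link.  Each cohort gets an independent sub-seed
    derived from ``seed``.
    """
    base = config or CohortSimConfig()
    rng = np.random.default_rng(seed)
    genes = _gene_ids(base.n_genes)
    n_reg = base.n_regulators_pos + base.n_regulators_neg
    reg_idx = rng.choice(base.n_genes, size=n_reg, replace=False)
    signs = [+1] * base.n_regulators_pos + [-1] * base.n_regulators_neg
    panel = {genes[i]: s for i, s in zip(reg_idx, signs)}
    sub_seeds = np.random.SeedSequence(seed).generate_state(n_cohorts) % (2**31)
    out = {}
    for j in range(n_cohorts):
        cfg = CohortSimConfig(
            **{
                **base.__dict__,
                "seed": int(sub_seeds[j]),
                "decoupled": j in set(decoupled_indices),
                "regulator_genes": panel,
            }
        )
        out[f"cohort{j}"] = simulate_cohort(cfg)
    return out


def simulate_mutation_cohort(
    n_samples: int = 100,
    lof_fraction: float = 0.5,
    target_genes: Sequence[str] = (),
    delta: float = 2.0,
    n_genes: int = 1000,
    noise_sd: float = 1.0,
    missense_fraction: float = 0.3,
    seed: int = 17,
) -> tuple[GeneSampleMatrix, list[MAFRecord], SimTruth]:
    """Mutation-stratified cohort: LOF samples' target genes shift by +delta.

    LOF samples carry one nonsense or frameshift-deletion record for APC;
    a fraction of the remaining samples carry a missense record, which must
    NOT trigger loss-of-function stratification downstream.
    """
    if not target_genes:
        raise ValueError("target_genes must be non-empty")
    if not (0.0 < lof_fraction < 1.0):
        raise ValueError("lof_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)

    targets = list(dict.fromkeys(target_genes))
    background = [g for g in _gene_ids(n_genes) if g not in set(targets)]
    genes = targets + background[: n_genes - len(targets)]
    samples = [f"sample{i:04d}" for i in range(n_samples)]

    n_lof = max(1, int(round(lof_fraction * n_samples)))
    lof = set(rng.choice(samples, size=n_lof, replace=False).tolist())

    mu = rng.normal(0.0, 1.0, len(genes))
    vals = mu[:, None] + rng.normal(0.0, noise_sd, (len(genes), n_samples))
    is_target = np.isin(genes, targets)
    is_lof = np.array([s in lof for s in samples])
    vals[np.ix_(is_target, is_lof)] += delta
    utr = GeneSampleMatrix(
        pd.DataFrame(vals, index=genes, columns=samples),
        tag="utr_metric", dialect="length_like",
    )

    maf: list[MAFRecord] = []
    for s in samples:
        if s in lof:
            cls = rng.choice(["Nonsense_Mutation", "Frame_Shift_Del", "Frame_Shift_Ins"])
            maf.append(MAFRecord(s, "APC", str(cls)))
        elif rng.random() < missense_fraction:
            maf.append(MAFRecord(s, "APC", "Missense_Mutation"))

    truth = SimTruth(
        seed=seed,
        target_genes=frozenset(targets),
        delta=delta,
        lof_samples=frozenset(lof),
    )
    return utr, maf, truth


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def expand_motif_instance(rng: np.random.Generator, motif: str) -> str:
    """One concrete DNA word drawn uniformly from a degenerate motif."""
    return "".join(IUPAC[c][rng.integers(len(IUPAC[c]))] for c in validate_motif(motif))


def simulate_utr_sequences(
    gene_ids: Sequence[str],
    motif_bearing_ids: Sequence[str],
    motifs: Sequence[str] = TOP_ENRICHED_MOTIFS,
    length: int = 500,
    gc: float = 0.5,
    seed: int = 17,
) -> tuple[dict[str, str], SimTruth]:
    """I.i.d. background sequences; motif-bearing genes get >= 1 planted
    concrete instance of a randomly chosen motif at a random position."""
    bearing = set(motif_bearing_ids)
    unknown = bearing - set(gene_ids)
    if unknown:
        raise ValueError(f"motif_bearing_ids not in gene_ids: {sorted(unknown)[:5]}")
    rng = np.random.default_rng(seed)
    motifs = [validate_motif(m) for m in motifs]
    seqs: dict[str, str] = {}
    plants: dict[str, list[tuple[int, str]]] = {}
    for g in gene_ids:
        seq = _random_sequence(rng, length, gc)
        if g in bearing:
            word = expand_motif_instance(rng, motifs[rng.integers(len(motifs))])
            pos = int(rng.integers(0, length - len(word) + 1))
            seq = seq[:pos] + word + seq[pos + len(word):]
            plants[g] = [(pos, word)]
        seqs[g] = seq
    truth = SimTruth(seed=seed, motif_genes=frozenset(bearing), motif_plants=plants)
    return seqs, truth


def simulate_region_counts(
    distal_fraction: pd.DataFrame,
    depth: float = 100.0,
    dispersion: float = 20.0,
    seed: int = 17,
) -> tuple[pd.DataFrame, SimTruth]:
    """Negative-binomial proximal/distal counts around a true distal fraction.

    ``distal_fraction`` is a gene x sample matrix of true ratios f_gs:
    proximal counts have mean ``depth``, distal counts mean ``depth * f_gs``.
    Variance is mean + mean^2/dispersion (standard RNA-seq overdispersion).
    Returns a long table (gene, sample, proximal_count, distal_count).
    """
    if (distal_fraction.to_numpy(dtype=float) < 0).any():
        raise ValueError("distal fractions must be >= 0")
    if depth < 0 or dispersion <= 0:
        raise ValueError("depth must be >= 0 and dispersion > 0")
    rng = np.random.default_rng(seed)

    def _nb(mean: np.ndarray) -> np.ndarray:
        mean = np.asarray(mean, dtype=float)
        out = np.zeros(mean.shape, dtype=np.int64)
        pos = mean > 0
        p = dispersion / (dispersion + mean[pos])
        out[pos] = rng.negative_binomial(dispersion, p)
        return out

    f = distal_fraction.to_numpy(dtype=float)
    prox = _nb(np.full(f.shape, depth))
    dist = _nb(depth * f)
    genes = np.repeat(distal_fraction.index.to_numpy(), f.shape[1])
    samples = np.tile(distal_fraction.columns.to_numpy(), f.shape[0])
    counts = pd.DataFrame(
        {
            "gene": genes,
            "sample": samples,
            "proximal_count": prox.ravel(),
            "distal_count": dist.ravel(),
        }
    )
    truth = SimTruth(seed=seed, distal_fraction=distal_fraction.copy())
    return counts, truth


def _scrub_hexamers(seq: str, rng: np.random.Generator, keep: set[int] | None = None) -> str:
    """Destroy accidental canonical poly(A) hexamers so planted ones are the
    only instances (positions in ``keep`` are preserved)."""
    keep = keep or set()
    kept_bases = {k + j for k in keep for j in range(6)}
    chars = list(seq)
    changed = True
    while changed:
        changed = False
        s = "".join(chars)
        for hx in PAS_HEXAMERS:
            start = s.find(hx)
            while start != -1:
                if start not in keep:
                    # flip a base of this instance that no kept hexamer uses
                    for j in range(6):
                        if start + j not in kept_bases:
                            chars[start + j] = "G" if chars[start + j] != "G" else "C"
                            changed = True
                            break
                    if changed:
                        break
                start = s.find(hx, start + 1)
            if changed:
                break
    return "".join(chars)


def simulate_clip_dataset(
    n_sites: int = 500,
    d_true: float = 62.0,
    jitter_sd: float = 10.0,
    n_replicates: int = 4,
    read_mean: float = 25.0,
    utr_length: int = 2000,
    max_pas_per_utr: int = 4,
    n_noise_windows: int = 50,
    noise_read_mean: float = 5.0,
    window_halfwidth: int = 25,
    seed: int = 17,
) -> tuple[list[BedRecord], dict[str, str], list[BedRecord], SimTruth]:
    """Plant CLIP windows a known distance upstream of poly(A) hexamers.

    One synthetic 3'UTR per bound site, assigned a random strand; sequences
    are emitted in genomic orientation keyed by contig.  Each UTR carries 1-4
    canonical hexamers (AATAAA/ATTAAA) at recorded transcript positions with
    accidental hexamers scrubbed; one hexamer is chosen as bound and a CLIP
    window of width ``2*window_halfwidth + 1`` is centered
    ``d_true + Normal(0, jitter_sd)`` upstream of its start (transcript
    orientation, downstream positive).  Per-replicate window counts are
    Poisson(``read_mean``); ``n_noise_windows`` unbound windows with
    Poisson(``noise_read_mean``) counts exercise the read filter.  The
    poly(A) BED lists every hexamer with its gene; 5'->3' order per gene is
    recorded in the truth ledger.
    """
    rng = np.random.default_rng(seed)
    windows: list[BedRecord] = []
    polyadb: list[BedRecord] = []
    seqs: dict[str, str] = {}
    truth = SimTruth(seed=seed, d_true=d_true, jitter_sd=jitter_sd)

    margin = 600  # keeps windows and +-500 bp contexts inside the UTR
    for i in range(n_sites):
        gene = f"utr{i:05d}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_pas = int(rng.integers(1, max_pas_per_utr + 1))
        # hexamer transcript positions, spaced >= 200 bp, inside [margin, L - margin)
        span = utr_length - 2 * margin
        pos = np.sort(rng.choice(span // 200, size=n_pas, replace=False)) * 200
        pas_t = (margin + pos + rng.integers(0, 150, size=n_pas)).tolist()

        seq_t = _random_sequence(rng, utr_length, gc=0.45)
        chars = list(seq_t)
        for p in pas_t:
            hx = PAS_HEXAMERS[rng.integers(2)]
            chars[p:p + 6] = hx
        seq_t = _scrub_hexamers("".join(chars), rng, keep=set(pas_t))

        bound = int(rng.integers(n_pas))
        offset = d_true + rng.normal(0.0, jitter_sd)
        center_t = int(round(pas_t[bound] - offset))

        if strand == "+":
            genomic_seq = seq_t
            center_g = center_t
            pas_g = [(p, p + 6) for p in pas_t]
        else:
            genomic_seq = reverse_complement(seq_t)
            center_g = utr_length - 1 - center_t
            pas_g = [(utr_length - (p + 6), utr_length - p) for p in pas_t]

        seqs[gene] = genomic_seq
        counts = rng.poisson(read_mean, size=n_replicates).astype(float)
        windows.append(
            BedRecord(
                interval=GenomicInterval(
                    gene, center_g - window_halfwidth, center_g + window_halfwidth + 1, strand
                ),
                name=gene, score=float(counts.sum()), extra=tuple(counts),
            )
        )
        for start, end in pas_g:
            polyadb.append(
                BedRecord(GenomicInterval(gene, start, end, strand), name=gene, score=0.0)
            )
        truth.pas_positions[gene] = list(pas_t)
        truth.bound_pas_index[gene] = bound
        truth.gene_strand[gene] = strand

    for j in range(n_noise_windows):
        gene = f"utr{rng.integers(n_sites):05d}"
        strand = truth.gene_strand[gene]
        start = int(rng.integers(0, utr_length - 51))
        counts = rng.poisson(noise_read_mean, size=n_replicates).astype(float)
        windows.append(
            BedRecord(
                interval=GenomicInterval(gene, start, start + 51, strand),
                name=gene, score=float(counts.sum()), extra=tuple(counts),
            )
        )

    return windows, seqs, polyadb, truth


def validate_truth(
    truth: SimTruth,
    matrices: Sequence[GeneSampleMatrix] = (),
    sequences: Mapping[str, str] | None = None,
) -> None:
    """Check every planted identifier exists in the emitted data; raise if not."""
    gene_universe: set[str] = set()
    sample_universe: set[str] = set()
    for m in matrices:
        gene_universe |= set(m.genes)
        sample_universe |= set(m.samples)
    if sequences:
        gene_universe |= set(sequences)

    planted_genes = set(truth.regulators) | set(truth.target_genes) | set(truth.motif_genes)
    missing = planted_genes - gene_universe
    if missing:
        raise AssertionError(f"planted genes absent from emitted data: {sorted(missing)[:5]}")
    missing_samples = set(truth.lof_samples) - sample_universe
    if matrices and missing_samples:
        raise AssertionError(f"planted samples absent: {sorted(missing_samples)[:5]}")
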