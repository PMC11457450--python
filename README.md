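# apakit

Statistical toolkit for **alternative polyadenylation (APA)** analysis in bulk
RNA-seq cohorts. Most human genes carry several poly(A) sites in their 3′UTR;
which site is used sets the 3′UTR length and thereby the regulatory surface of
the transcript (miRNA and RBP binding sites). `apakit` implements the
computational machinery needed to connect poly(A)-site selection to its
regulators across tumor cohorts:

- **3′UTR quantification** — gene-level relative expression difference
  `RED = log2((distal reads + pc) / (proximal reads + pc))` from
  proximal/distal region counts, and the per-sample **median 3′UTR** summary
  of global poly(A)-site selection.
- **Correlation screen** — per-gene Pearson correlation of expression (TPM)
  with the median 3′UTR, with Bonferroni adjustment; pairwise comparison of
  per-gene r-vectors across cohorts and Tukey-fence flagging of outlier
  cohorts whose regulatory couplings diverge from the rest.
- **Differential APA** — sample stratification by mutation status
  (nonsense/frameshift loss-of-function vs all others) or by expression
  quartiles, then a per-gene two-sided Wilcoxon rank-sum test (or Student's
  t), Benjamini–Hochberg correction, and lengthened / shortened / unchanged
  calls at q < 0.05.
- **Motif enrichment** — IUPAC motif scanning of 3′UTR sequences and
  per-class presence fractions with bootstrap CIs and 2×2 chi-squared tests
  against the unchanged class (five G/C-rich motifs associated with 3′UTR
  lengthening ship as built-in constants).
- **CLIP / poly(A) positional analysis** — pooling of replicate CLIP window
  counts, a ≥50-read filter, merging into binding sites, signed distances to
  the nearest canonical poly(A) hexamer (AATAAA/ATTAAA) within ±500 bp in
  transcript orientation, a Gaussian-KDE density mode, and distances to
  annotated poly(A) sites binned by 5′→3′ rank (proximal / intermediate /
  distal).
- **Target-set enrichment** — a subsampling empirical null (random gene sets
  of matched size, default 10,000 draws) for the fraction of a target set in
  each APA class, plus a rank-sum delta-shift comparison.
- **Pathway scores** — per-sample summed-Z expression score over a gene set,
  compared between strata with a rank-sum test.
- **Synthetic data** — generators for every input above with an explicit
  ground-truth ledger (planted regulators, shifts, motif instances, CLIP
  offsets), used by the test suite for end-to-end parameter-recovery checks.

## Worked example

Simulate a cohort in which a latent per-sample state drives global
poly(A)-site selection and ten regulator genes track that state, then run the
expression–APA screen:

```python
import apakit

cfg = apakit.CohortSimConfig(n_samples=200, n_genes=2000, seed=7)
expr, utr, truth = apakit.simulate_cohort(cfg)

med = apakit.median_utr(utr)                    # per-sample global summary
res = apakit.screen_cohort(expr, med)           # per-gene Pearson records
recs = res.records.set_index("gene")
for gene, sign in sorted(truth.regulators.items()):
    row = recs.loc[gene]
    print(f"{gene}  planted {sign:+d}   r = {row.r:+.3f}   p_adj = {row.p_adj:.2e}")
```

Output:

```
gene00121  planted +1   r = +0.668   p_adj = 6.46e-24
gene00142  planted +1   r = +0.605   p_adj = 4.46e-18
gene00245  planted +1   r = +0.673   p_adj = 2.14e-24
gene00541  planted -1   r = -0.713   p_adj = 5.39e-29
gene00564  planted -1   r = -0.707   p_adj = 2.95e-28
gene01116  planted +1   r = +0.642   p_adj = 2.47e-21
gene01456  planted +1   r = +0.644   p_adj = 1.72e-21
gene01476  planted -1   r = -0.606   p_adj = 4.06e-18
gene01557  planted -1   r = -0.669   p_adj = 5.13e-24
gene01639  planted -1   r = -0.628   p_adj = 4.50e-20
```

Every planted regulator is recovered with the correct sign at Bonferroni
significance: a positive `r` means higher expression of that gene tracks
globally longer 3′UTRs (more distal poly(A)-site use) across samples.

## Command line

The same stages are exposed as one executable with subcommands:

```
apakit simulate --kind cohort --outdir sim --seed 17
apakit quantify --counts counts.tsv --outdir quant
apakit screen --expression expr.tsv --utr utr.tsv --outdir screen1
apakit compare-cohorts --screen-tsv COAD screen1/screen.tsv ... --outdir cmp
apakit diffapa --utr utr.tsv --maf muts.maf --gene APC --outdir diff
apakit motifs --diffapa-tsv diff/diffapa.tsv --fasta utr.fa --outdir motifs
apakit clip --windows win.bed --fasta utr.fa --polyadb pas.bed --outdir clip
apakit enrich --diffapa-tsv diff/diffapa.tsv --targets targets.txt --outdir enr
apakit score --expression expr.tsv --gene-set egfr.txt --stratify-gene APC --outdir sc
```

Inputs are plain text: TSV gene×sample matrices, GDC-dialect MAF tables, BED6
(with per-replicate counts in extra columns for CLIP windows), and FASTA.
Each run writes a JSON log of its resolved parameters and seed.

## Acceptance script

`scripts/acceptance.py` re-runs the whole pipeline from scratch on freshly
simulated data — cohort panel with one decoupled cohort, mutation-stratified
differential APA, motif presence, target-set enrichment, RED quantification
from region counts, CLIP offset recovery, and pathway scoring — printing the
recomputed summaries and writing the results JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

See `docs/methods.md` for the statistical model behind each stage, parameter
defaults, and known limitations.
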