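# Methods

`cnvset` tests whether large, rare copy-number variants (CNVs) found in
cases of a disorder are enriched for genes belonging to curated functional
gene sets, using a covariate-adjusted logistic regression framework, and
provides the supporting machinery: CNV quality control, gene annotation, a
permutation null for whole-battery excess, stepwise conditional selection,
single-gene tests, burden analyses, and a synthetic-data generator with
known embedded effects.

## The enrichment model

Each QC-passing CNV is one observation. Its phenotype (1 = found in a case,
0 = in a control) is modelled as

```
(a)  logit pr(case) = stratum + b1·size_kb + b2·n_genes_total
(b)  logit pr(case) = (a) + beta_set · n_genes_in_set
```

where `stratum` is the study × genotyping-chip factor (indicator coding
with a reference level), `size_kb` the CNV length in kilobases,
`n_genes_total` the number of genes whose span the CNV overlaps by ≥1 bp,
and `n_genes_in_set` the number of those genes belonging to the set under
test. A CNV hitting k members of a set contributes k through this one
covariate, never k rows, so co-localised set members cannot inflate the
test. Conditioning sets (for residual scans) enter model (a) as additional
hit-count covariates.

The statistic is Δdev = dev(a) − dev(b) ≥ 0, referred one-sided via the
signed root

```
z = sign(beta_set)·sqrt(Δdev),     p = 1 − Φ(z).
```

Only enrichment *in cases* is of interest, hence one-sided; this signed-root
construction is exact under the χ²₁ asymptotics of the likelihood-ratio test
and returns p = 0.5 when beta_set = 0, which is also what degenerate
covariates (set never hit, or hit identically across CNVs) report. The
odds ratio is exp(beta_set) per additional set gene hit, with a Wald 95%
interval from the observed information. Single-gene tests are the identical
machinery with a singleton set, making the covariate a 0/1 indicator.

Fitting is by iteratively reweighted least squares: convergence at
max |score| < 1e-8, capped at 50 iterations. Under quasi-complete separation
the coefficient diverges but the deviance converges, so the capped deviance
is used and the test remains defined; collinear columns are handled by
least-squares steps, so a redundant covariate changes the deviance by
exactly zero (residual p = 0.5). Strata containing only cases or only
controls are dropped row-wise with a warning (their indicator is
unidentifiable); constant covariates are dropped with a warning.

Multiple testing uses Bonferroni with a caller-supplied test count — for a
battery of S sets tested in the combined / deletion-only / duplication-only
analyses the pipeline corrects over 3·S by default — capped at 1.

## Quality control

Applied in order to collated post-calling tables, with 0-based half-open
coordinates throughout (a 1-based input dialect is converted on read):

1. **Re-joining** — within each (sample, chromosome, copy-state) group,
   calls separated by a gap smaller than 50% of their combined length are
   merged (span = envelope, probe counts summed), iterated to a fixpoint.
   The rewrite system is confluent: merging only enlarges spans, so a merge
   can never disable another, and the fixpoint is order-independent.
2. **Low-copy repeats** — a call is removed when the union of LCR intervals
   covers strictly more than 50% of its length.
3. **Probe density** — removed when mapped probes in [start, end) fall below
   1 per 20 kb. Density is recounted from the probe position map, not the
   stored probe count, which can double-count after merging; with no map the
   stored count is used and a warning issued.
4. **Frequency** — calls of the same copy-state are single-linkage clustered
   at ≥50% reciprocal overlap; a cluster whose distinct carriers exceed 1%
   of all genotyped samples is removed entirely. Per-copy-state clustering
   is used (a deletion and a duplication at one locus are different
   variants).
5. **Size/probes** — retained iff length ≥ 100 kb and probe count ≥ 15
   (boundaries inclusive).

A separate step removes calls overlapping known disease loci by ≥1 bp, for
the sensitivity re-analysis; any-overlap was chosen because a threshold rule
would leave fragments of established signals in place.

Sample-level intensity-based QC cannot be recomputed from call tables; a
hook accepts an externally produced pass list instead.

## Permutation null for battery-wide excess

Case-control status is shuffled between CNVs from the same study × chip
stratum, preserving each stratum's case/control CNV counts, so platform
composition is held fixed under the null. For thresholds P_thr (default
0.01 and 0.001) the observed count of sets with p < P_thr is compared with
the permuted count distribution; the empirical p is the proportion of
permutations reaching the observed count, reported as "< 1/n_perm" when
none does. The permutation unit is the CNV, not the individual — a sample
with several CNVs may receive discordant permuted labels; this is the
convention of the CNV-level regression itself. One master seed spawns one
substream per permutation, so results are independent of evaluation order
and worker count.

## Stepwise minimal set and burden

From the sets surviving correction, greedy forward selection repeatedly
adds the candidate with the smallest residual p (conditioning on those
already selected) until no candidate has residual p < 0.05 (uncorrected;
configurable). Ties break by smaller p, then name. Candidates identical to
a selected set become collinear and report p = 0.5, so they are never
selected twice. All per-step p-values are retained for audit.

Burden analyses regress case status on CNV size, total genes hit, or the
number of genes hit in the union of all correction-surviving sets
("CNS_SZ"-style union, built per analysis), with stratum covariates always
present and optional conditioning on the other predictors; tests are
one-sided toward case excess, matching the enrichment convention. A
predictor lying in the linear span of the conditioning model is flagged
degenerate (p = 0.5).

## Synthetic data: what it emulates, and what not

The generator draws a genome (non-overlapping genes with lognormal lengths
placed by Dirichlet gaps; a jittered regular probe grid; LCR intervals), a
battery of overlapping gene sets (lognormal sizes; a configurable fraction
of each set drawn from a shared hub pool, giving a controlled expected
pairwise Jaccard), and per-stratum CNVs (truncated-lognormal lengths with a
100 kb floor, per copy-state; uniform placement), then assigns phenotypes
from exactly the logistic model the analysis fits, with covariates computed
by the production annotation code.

Defaults are fixed once to mirror the shape of a large schizophrenia CNV
study at desk scale: three strata (a large Illumina stratum and two
Affymetrix strata) totalling 4,000 CNVs at overall case fraction 0.4374;
40% deletions; deletion lengths with median 160 kb, duplications 250 kb
(σ = 0.7 on the log scale); a 100 Mb, 3-chromosome genome with 1,600 genes
(median 20 kb) and 5 kb probe spacing; 134 sets with median size ≈25 genes
(clipped to 5–300); b_size = 5·10⁻⁴ per kb and b_total = 0.03 per gene as
baseline nuisance effects; no set effects unless requested. Per-stratum
intercepts are calibrated so the expected case fraction matches each
stratum's target; realized counts are random, and downstream permutation
conditions on the realized counts.

Not emulated: sequence context, recurrent-CNV mutational mechanisms
(hotspots, NAHR), linkage structure, genuine per-individual CNV burden
correlation (phenotype is assigned per CNV by default; a per-individual
mode shares one phenotype across a sample's CNVs to probe that assumption),
and gene-set curation biases. A green calibration test therefore
establishes that the statistic behaves correctly under its own model
assumptions — not that those assumptions hold in any particular real
dataset.

## Numerical choices

- IRLS: score tolerance 1e-8, 50-iteration cap, step-halving keeps the
  deviance monotone; covariance by pseudo-inverse of the observed
  information (finite under collinearity).
- Δdev is clamped at 0 against roundoff; z = 0 maps to p = 0.5 exactly.
- Set size covariate is kilobases, linear. The scale only reparameterizes
  the nuisance model; tests are invariant to it.
- Empirical permutation p uses k/n_perm with an explicit "< 1/n_perm"
  upper bound at k = 0, mirroring how such tables are usually printed;
  expected counts are rounded to 1 decimal only in the report writer.
- Reported p-values are full precision in TSVs; the human-readable summary
  rounds p to 2 significant figures and ORs to 2 decimals.

## Known limitations

- Wald intervals (and the signed-root p) are asymptotic; for very small
  sets hit by a handful of CNVs the one-sided p is discrete-ish and the
  Firth-style penalized alternative is not implemented (separation is
  handled by the deviance cap instead, which keeps the test but not the OR
  stable; ORs under separation should be read as unbounded).
- The frequency filter's reciprocal-overlap clustering is one standard
  operationalization of "frequency"; boundary behaviour differs from
  locus-based definitions for nested CNVs of very different lengths.
- Heavy calibration suites are run scaled down in CI-sized environments
  (documented per test); the acceptance harness runs the stated scales.
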