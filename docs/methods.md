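# Methods

## The screening model

The package treats drug responsiveness as a phenotype to be explained by
basal gene expression, in two statistically independent tiers whose results
are only combined by set intersection.

### Tier 1: panel correlation screen

Per probe, the sample Pearson correlation *r* between log2 expression and
log₁₀(GI₅₀) across a cell-line panel. GI₅₀ is stored in molar units and
log10-transformed on ingestion; the log base is fixed. Significance uses
the exact identity between the correlation coefficient and a Student-*t*
statistic under the bivariate-normal null,

t = r·√df / √(1 − r²), df = n − 2,

with the two-tailed tail probability from `scipy.stats.t`. For the full
60-sample panel df = 58; *n* is counted per probe from pairwise-complete
observations, so probes with missing cells get a smaller df rather than an
imputed value. Probes with zero variance are skipped (r undefined), not
assigned r = 0, so they cannot dilute downstream counts. |r| = 1 exactly
maps to the smallest positive double rather than P = 0, preserving the
P ∈ (0, 1] contract; the event is logged. The screen computes the
correlation directly rather than through a fitted regression — the slope
test and the correlation test are the same test, and the correlation
contract is simpler.

Direction lists are ranked by descending |r| with ties broken by ascending
probe ID (the published tables are |r|-ordered and state no tie rule).
Collapse to unique transcripts removes genes whose probes reach
significance in both directions — a conservative choice, since an
ambiguous sign cannot anchor a directional signature; the event is logged.

### Tier 2: paired differential screen

*Detection.* A probe is a valid signal if its detection P value is below
`detection_alpha` (default 0.01) in **at least one** sample. The per-sample
rule is the package's own (only the probe-level count of the original
platform pipeline is documented); "at least one" is the most permissive
reading and errs toward keeping probes, which the later statistical filters
can still reject.

*Normalisation.* Raw positive intensities are log2-transformed and
full-quantile normalised (every sample receives the mean sorted profile).
The original platform pipeline is package-specific and not fully
specifiable; quantile normalisation is the closest widely understood,
exactly reproducible equivalent. Matrices already on the log2 scale skip
this stage.

*Moderation.* Per-probe residual variances s² are pooled over all design
groups (the one-way layout over pairs × phenotypes, residual df
d = N − G). Under the hierarchical model s² ~ s₀²·F(d, d₀), the log
variance has variance ψ′(d/2) + ψ′(d₀/2); the excess of the observed
spread of log s² over the sampling term ψ′(d/2) identifies d₀ by trigamma
inversion (Newton), and the mean of log s² then identifies s₀². This is
the standard moderated-t moment fit; the implementation agrees with
limma's `fitFDist` to ~6 decimals on shared fixtures (tested). When the
observed spread shows no excess dispersion the prior is degenerate:
d₀ = ∞ with prior variance equal to the mean variance, i.e. all probes
share one variance. d₀ = 0 is accepted as the explicit no-shrinkage limit
and reproduces the ordinary pooled-variance t exactly (tested).

*Testing.* Per pair, the moderated t of (sensitive mean − resistant mean)
with variance ṽ·(1/n₁ + 1/n₂), ṽ = (d₀s₀² + d·s²)/(d₀ + d), df = d₀ + d
(normal when d₀ = ∞). The combined P is the maximum over pairs — the
intersection-union test for "deviates in every pair" — and BH FDR is
computed on the combined P. This joint/max-P convention is conservative by
construction; the original per-pair bookkeeping is not documented.

*Congruence rule.* A probe passes iff every pair shows the same direction,
a linear fold change 2^|Δlog2| **strictly greater** than `fc_min`
(default 1.5; a fold change of exactly 1.5 fails), and per-pair raw
P < 0.01; and the FDR q on the combined P is < 0.05. Fold changes are
computed from differences of log2 group means, so the threshold is applied
post-normalisation and pre-moderation (the moderated statistic shares the
mean difference; only its denominator is shrunk).

### Tier 3: integration

Pure per-direction set intersection on gene symbols, case-insensitive and
whitespace-stripped — the only key the two array platforms share. No
significance re-weighting, no rank aggregation. Invariants asserted on
every run: each overlap is a subset of both parents; the two overlaps are
disjoint.

## Assay calculations

* Kinetic rates: ordinary least squares over the whole 31-point,
  one-minute-interval window. No lag-phase detection or windowing — the
  traces are linear by design of the assay. Exactly scale-equivariant.
* G6PD-specific activity: rate(G6P+6PG) − rate(6PG). May be negative with
  noisy rates; returned unclamped with a warning, because clamping is a
  presentation choice that destroys information.
* Normalised cell death: 100 − 100·(treated viable fraction / untreated
  viable fraction); untreated-vs-itself is exactly 0 by construction, and
  negative values (treatment improving viability) are allowed and flagged.
* geNorm factor: geometric mean of ≥ 2 reference-gene relative quantities.
  The geNorm stability measure M (reference-gene ranking) is out of scope;
  only the normalisation factor is used downstream.

## Synthetic data: what it emulates and what it does not

Generators are pure functions of their spec (seed included) and emit the
same TSV formats the readers consume.

* **Panel** (default 60 samples): log₁₀(GI₅₀) standard normal around
  10⁻⁵·⁵ M (a realistic 10⁻⁷–10⁻⁴ M span). A planted probe is constructed
  as x = ρ·z + √(1 − ρ²)·ε on the standardised phenotype z, so its
  population correlation is exactly ρ — which makes the Fisher-z oracle
  and power calculations exact. Null probes are independent Gaussian
  noise.
* **Paired experiment** (default 2 pairs × 2 phenotypes × 3 replicates):
  Gaussian log2 noise (sd 0.25) around per-probe log-normal baselines
  (mean 8, sd 1.5); planted genes shifted by log2FC in the sensitive
  groups of *every* pair (directionally congruent by construction);
  many-to-one probe→gene maps via a configurable probes-per-gene draw;
  detection P near zero for expressed probes and uniform for a
  configurable absent fraction (default 0.3). Three replicates per group
  is the default because the original replicate structure is not
  documented; it is the minimum design with a usable residual df per
  group.
* **Matched study** (`gen_integrated_study`): both platforms over a shared
  gene universe, with 1 sensitivity-associated and 6 resistance-associated
  genes planted to pass *both* tiers (panel ρ = ∓0.65, paired
  log2FC = ±1.5), plus paired-only planted genes carrying
  platform-specific symbols — mimicking the partial annotation overlap of
  two real array platforms. Default 6,000 probes per platform; large
  enough that the panel's ~5% null false-positive rate and the paired
  screen's FDR behaviour are exercised at realistic scale while keeping a
  full run in seconds.

Not emulated: probe-level bead models, chip/batch effects, inter-gene
correlation structure, heavy-tailed intensity noise. Passing tests
therefore demonstrate correctness of the statistical machinery under its
own assumptions (Gaussian log-scale noise, independent probes), not
robustness to real microarray artefacts.

## Numerical choices

* Full quantile normalisation uses stable sorts; ties are resolved by
  input order, deterministically.
* Trigamma inversion: Newton iteration, 50-step cap, relative tolerance
  1e-10.
* BH q-values via the reverse cumulative-minimum formulation; verified
  exactly equal to the brute-force double-loop definition and to
  statsmodels' `fdr_bh` on random fixtures.
* TSV writers use `%.17g` so every IEEE double round-trips bit-exactly;
  readers parse with pandas' round-trip float precision. Missing cells
  stay NaN ("absent") and all statistics are pairwise-complete.
* Pipeline outputs are byte-deterministic for identical inputs and
  thresholds; `manifest.json` records input/output SHA-256 checksums and
  every threshold as applied.

## Problem sizes in the checks

The verification runs use panels of 2,000 null probes × 60 samples
(10 seeds) for calibration, 1,000 simulations per sign for power at
ρ = ±0.5, 200 simulated 400-probe paired experiments for the global-null
FDR check, and the 6,000-probe-per-platform matched study for end-to-end
recovery — sizes chosen so each property is measured with comfortable
Monte-Carlo precision while a full run stays in seconds.

## Known limitations

* The detection rule, normalisation method, ANOVA design matrix, and
  per-pair vs joint FDR bookkeeping of the original platform pipeline are
  under-documented; the package's concrete choices (stated above) are
  reasonable conventions, not reconstructions.
* The moderated test assumes equal within-group variances across all
  design groups for a probe (a single pooled s²).
* Gene-symbol matching at integration cannot resolve probes whose
  platform annotations disagree; symbol-level matching is the only common
  key implemented.
* Real-data outputs (specific gene identities and counts from external
  panel/paired datasets) depend on those datasets and are out of scope;
  the pipeline accepts real-shaped inputs and emits the published table
  schemas.
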