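# Methods

This note documents the statistical procedures phosphopipe implements, the
defaults it ships, and the design choices made where the workflow admits
more than one defensible option.

## The analysis chain

The pipeline operates on a MaxQuant-style phosphosite quantification table
(one reporter-intensity column per TMT channel) together with a matching
protein quantification table and a channel design (group and replicate per
channel). The stages run in a fixed order:

1. **Class-I filtering.** A phosphosite identification carries a
   localization probability — the posterior confidence that the phosphate
   sits on the reported residue rather than a neighbouring S/T/Y. Sites
   with localization probability ≥ 0.75 ("class I") are retained. The
   boundary is *inclusive* by default, following the conventional class-I
   definition; a `strict` switch gives the strictly-greater variant.

2. **Row normalization.** Each site's (and each protein's) intensities are
   divided by the mean of that row's non-missing values, putting every row
   on a common ratio scale with mean 1. Missing values stay missing — an
   empty TMT cell is never imputed to 0, which would otherwise poison
   downstream ratios. Rows with no positive values are dropped with a
   warning. Normalization is idempotent on complete rows.

3. **Protein-level calibration.** To read phosphorylation changes net of
   protein-abundance changes, each normalized site value is divided by the
   parent protein's normalized value in the same channel. When the parent
   protein was not quantified at all, the site's normalized values are used
   directly and flagged (`protein_quantified=False`). When the protein *is*
   present but a particular channel value is missing or non-positive, that
   channel becomes missing — the fallback applies only to wholly
   unquantified proteins, not to individually bad denominators.

4. **QC.** Channel-channel Pearson correlation on pairwise-complete rows
   (pairs with fewer than 3 complete rows are reported as missing), and a
   PCA of the channels over complete rows. Features (sites) are
   mean-centered but not variance-scaled, because the values are already
   ratio-normalized to a common scale; within-group replicates should
   cluster and groups should separate when real regulation is present.

5. **Differential phosphorylation.** Per site, a pooled-variance
   (Student's) two-sample t-test between the reference group (A) and the
   comparison group (B), by default on log2-transformed calibrated values —
   the natural scale for multiplicative TMT ratios and symmetric in
   up/down. A `log_scale=False` route tests the raw scale. The fold change
   is the linear-scale ratio of group means (B over A). A site is called
   **up** when p < α and FC ≥ f, **down** when p < α and FC ≤ 1/f,
   otherwise **ns**; defaults α = 0.05, f = 1.5, with the FC boundary
   inclusive. Benjamini–Hochberg q-values are reported as an extra column
   but do not drive the direction calls (site-level phosphoproteomics
   screens conventionally gate on raw p plus fold change). Degenerate
   rows follow a fixed contract: zero pooled variance with equal means
   gives (t=0, p=1); with unequal means, (t=±∞, p=0); rows with fewer than
   two values in either group are reported `ns` with reason
   `insufficient_data`, never silently dropped. The t sign convention is
   t = (mean_B − mean_A)/se, so t > 0 corresponds to "up".

6. **Protein aggregation and overlaps.** Direction calls roll up to
   per-protein counts of up/down sites and a category (up-only, down-only,
   both, none); utilities cross-tabulate phospho-regulated proteins against
   proteome-level DE sets and compute overlap fractions
   (|A∩B|/|A|, percentage rounded to one decimal). Sets defined by p-only
   (no FC filter) and by p+FC are distinct first-class objects: inhibitor
   comparisons use the p-only sets, while the stringent regulated sets add
   the fold-change filter.

7. **Kinase–substrate prediction and enrichment.** A GPS-family scorer:
   the similarity of two 15-mer flanking windows is the sum over the 15
   aligned positions of their BLOSUM62 substitution score, with any
   position involving the terminal-padding character `_` contributing 0;
   a site's score for a kinase is the arithmetic mean of its similarity to
   the kinase's reference substrate windows. Negative substitution scores
   are kept (they carry discriminative information). Per kinase, a score
   cutoff is set at the (1 − FPR) empirical quantile of background scores
   (ties resolved upward), with FPR defaulting to 0.02; the background is
   the experiment's own quantified windows with flanks permuted around the
   fixed center, which preserves both amino-acid composition and the S/T/Y
   center mix without external data. Predictions are gated by residue
   class (S/T kinases never claim Y sites and vice versa). Enrichment of a
   kinase's predicted substrates among up-regulated (and separately,
   down-regulated) sites against the remainder of the quantified class-I
   universe is tested with a one-sided (greater) Fisher's exact test — a
   two-sided test would also flag depletion, which is not the question.
   Kinases rank by p with substrate count as tiebreak; significant kinases
   roll up to family counts (CAMK, CMGC, AGC, ...).

8. **Over-representation analysis.** Generic hypergeometric upper-tail
   ORA of a protein hit list against user-supplied GMT gene sets, with BH
   adjustment. The background defaults to all proteins quantified in the
   experiment (the only background constructible without external data,
   and standard practice for expression-derived hit lists); set members
   are intersected with the background before counting, and annotation is
   protein-level (a protein with several regulated sites counts once).

## The synthetic-data generator

`simulate.generate_experiment` produces the site table, protein table,
design, kinase reference and ground-truth labels for a complete experiment.
What it emulates, and the defaults:

* **Design**: 3 groups (caput, corpus, cauda) × 5 replicate channels — a
  15-plex TMT layout.
* **Abundance model**: multiplicative throughout. A site's channel value is
  `base × group_effect × 2^N(0, noise_sd_log2)` with log-normal bases, so
  planted log2 effects are exact in the noiseless group means and the
  log2-scale t-test operates under exact normal theory. `noise_sd_log2`
  defaults to 0.25 — a typical within-group spread for TMT ratio data; the
  generator exposes it because real instrument noise varies by study.
* **Planted effects**: a fraction `frac_diff_sites` (default 0.1) of sites
  receives a ±`effect_log2fc` (default 1.5) log2 shift in the last group
  versus the first, split evenly between up and down; intermediate groups
  get a linear ramp (half the effect for the middle of three), reproducing
  the intermediate corpus phenotype so that PCA/correlation QC shows the
  caput→corpus→cauda ordering.
* **Residue mix**: S/T/Y drawn at 0.891/0.1024/0.0066 — the composition
  observed in sperm class-I phosphoproteomes.
* **Localization**: a mixture with most mass above 0.9 and a configurable
  fraction (default 0.15) below 0.75, so the class-I filter is exercised;
  planted sites are always class I so recovery is well-defined.
* **Protein table**: protein intensities are generated independently of
  their sites' planted effects by default (phosphorylation regulation in
  this setting is largely abundance-independent); a `couple_proteins`
  switch makes proteins inherit their sites' effects to verify that the
  calibration step cancels them. A fraction `frac_protein_unquantified`
  (default 0.1, exact by construction) of sites references proteins absent
  from the protein table, exercising the calibration fallback.
* **Kinases**: planted kinases (defaults: a CAMK-family kinase active in
  the up direction with the canonical basophilic Φ-x-R-x-x-S-Φ motif, and
  a CMGC-family kinase in the down direction with the proline-directed
  S-P-x-K motif) imprint their consensus on 60% of the regulated sites in
  their direction; 10 decoy kinases with random 3-position motifs populate
  the reference for the enrichment test to reject. Windows are padded with
  `_` beyond protein termini.
* **Determinism**: one seeded generator drives every draw in a fixed
  order; identical config + seed reproduces byte-identical output files.

What it does **not** emulate: raw spectra, co-isolation interference,
isotope impurity, peptide-to-site rollup, missingness mechanisms that
depend on abundance, or inter-plex batch structure. Passing recovery tests
on this generator therefore demonstrates the correctness and calibration of
the statistical chain under its stated error model, not robustness to
MS-specific artifacts.

## Numerical choices and degenerate inputs

* Fisher and ORA p-values come from the exact hypergeometric tail; the
  test suite verifies both against an independent big-integer enumeration
  oracle (|Δp| < 1e-10), and the pooled t p-values against numeric
  integration of the explicit t density (|Δp| < 1e-8).
* Cutoff calibration resolves ties upward, guaranteeing the background
  fraction at or above the cutoff never exceeds the nominal FPR; when
  FPR < 1/n the cutoff strictly exceeds every background score.
* Odds ratios use an infinity sentinel when bc = 0 with a > 0, and 0 when
  a = 0.
* Overlap percentages are rounded to one decimal at the reporting boundary
  only; fractions are kept exact internally.

## Calibration subtlety worth knowing

After protein calibration, sites sharing a parent protein divide by the
same noisy protein row, which correlates their test statistics. Each site's
t-test remains exactly calibrated (measured null type-I error 0.0497 over
30 replicate null experiments at p < 0.05), but the *realized* significant
fraction of a single experiment has roughly 1.5× the binomial standard
deviation (measured 0.0090 vs 0.0061 binomial at ~1275 tested sites with
~10 sites/protein). The acceptance script therefore reports the null
significant fraction (and the held-out kinase-cutoff FPR) averaged over 5
replicate experiments — a lower-variance estimate of the same rate.

## Problem sizes

Simulated experiments in the tests and the acceptance script use 400–4000
sites over 80–400 proteins with 5 replicates per group — large enough for
stable rate estimates and planted-effect recovery, small enough that the
full suite runs in well under a minute. Kinase-ranking recovery uses 20
replicate experiments of 400 sites with 12 kinases (2 planted + 10 decoys)
and 400-window backgrounds.

## Known limitations

* No moderated (limma-style) variance shrinkage; with 5v5 designs the
  plain Student t-test is adequately powered for |log2FC| ≥ 1 at the noise
  levels modelled, but small-n designs would benefit from shrinkage.
* Motif scoring uses sequence similarity only; a full kinase–substrate
  predictor would add protein–protein interaction context, which requires
  external data this pipeline does not consume.
* The ORA treats gene sets as flat (no GO-graph topology or term
  redundancy handling).
* Single-plex designs only: no cross-plex batch correction or reference-
  channel bridging.
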