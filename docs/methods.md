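# Methods note

This note records the model underlying `etstargets`, the defaults it
ships with, what the synthetic data generator does and does not emulate,
and the numerical conventions that affect results.

## Study design being modeled

Five engineered prostate cell-line models probe ETV1 and ETV4 programs:
shETV1-LNCaP, shETV1-MDA-PCa-2b, shETV4-MDA-PCa-2b and shETV4-PC3
(silencing), and PNT2-ETV1 (overexpression in a benign line). Each model
has one control population and two independently derived manipulated
populations ("clones"). Candidate genes from the cell-line screen are
then evaluated in a tumor cohort of 50 carcinomas (14 PEA3-rearranged, of
which 12 ETV1 and 2 ETV4; 22 ERG-rearranged; 14 ETS-negative) and 9
normal prostate tissues, with stage (24 pT3 / 26 pT2 by default) and
Gleason annotations on the carcinomas.

## Fold-change algebra

Expression is handled on the log2 scale. For manipulated mean `a` and
control mean `b`, the signed fold change is `+2^(a-b)` if `a >= b`, else
`-2^(b-a)`; |FC| is always ≥ 1 and sign carries direction. Per-model
consensus is the arithmetic mean of the clone FCs, defined only when the
clones agree in sign (a value of exactly +1.0 agrees only with +1.0);
disagreement yields a missing value, which fails every downstream
threshold. Geometric averaging is available as an option. For silencing
models the consensus FC is sign-flipped onto the association axis
(+1.0 is left unsigned), so a positive association value always means the
gene moves with the ETS factor.

## Set rules and comparators

- Specific targets use an **inclusive** comparator (|FC| ≥ 1.5 in both
  models of one factor): the rule is phrased as "no less than".
- Shared targets require |FC| ≥ 1.5 in the same direction in ≥ 3 of the
  4 silencing models. ETV1 and ETV4 themselves are excluded from all
  lists.
- Phenotype cascades use **strict** comparators (`> 1.2`, `> 1.5`):
  - invasion-or-AIG: same-sign > 1.2 in shETV4-PC3, shETV1-LNCaP and
    PNT2-ETV1, vetoed by a same-direction > 1.2 change in
    shETV1-MDA-PCa-2b;
  - AIG: > 1.5 in both shETV4 models, same veto;
  - invasion: > 1.5 in shETV1-LNCaP and PNT2-ETV1, vetoed only when
    *both* MDA-PCa-2b models echo the change above 1.2.
- Sets are computed independently; overlaps are reported (a shared target
  that also clears both specific rules appears in all three lists), and
  opposite-direction double membership between the ETV1 and ETV4 lists is
  flagged as *inverse*. The union cardinality follows
  inclusion–exclusion, e.g. 13 + 26 + 24 − 2 = 61 at the study effect
  structure.

## Statistics

- **Mann–Whitney U** (cohort group comparisons): exact two-sided p when
  the smaller group has ≤ 8 samples and there are no ties, otherwise the
  tie-corrected normal approximation *without* continuity correction.
- **Student's t** (assay endpoints): pooled-variance two-sample t by
  default.
- **Pearson chi-square** (panel 2×2 tables): closed form
  `N(ad−bc)² / ((a+b)(c+d)(a+c)(b+d))`, 1 df, no Yates correction. This
  matches the test named in the original analysis but is known to be
  anti-conservative at n = 50 per-rule (measured 6.5–8% type-I at
  α = 0.05), and selecting the best of three rules compounds this.
  Calibration checks in this package therefore use a permutation null —
  stage labels permuted within the carcinomas — under which the
  best-of-three false-positive rate is ≈ 11%. Fisher's exact test is
  provided as an alternative.
- **Percentile thresholds** use numpy's linear-interpolation quantile
  (index `(n−1)·q/100`); flagging is strictly-below-threshold; a sample
  is panel-positive when ≥ k of the 7 genes are flagged. The default rule
  grid is (percentile 10, k=1), (25, 2), (50, 4).
- **Covariate independence** declares a finding independent of age and
  PSA when both Mann–Whitney p-values are ≥ 0.05. Note this is a
  conjunction of two tests: under the null it holds in ≈ 0.95² ≈ 90% of
  draws, not 95%.
- Multiple-testing correction (Benjamini–Hochberg) is available but off
  by default, matching the original per-test reporting.

## Synthetic data generator

The generator exists so the rules and statistics can be tested against a
known ground truth; its defaults are the study conditions.

What it emulates:

- i.i.d. Gaussian noise on the log2 scale around a per-gene baseline
  drawn from Uniform(6, 10);
- planted per-gene roles (ETS-specific up/down, shared, inverse,
  phenotype-program members, panel genes down-shifted in pT3) with the
  study cardinalities (61 targets as 13/26/24−2; phenotype programs of
  81/17/27); shared targets shift in all four silencing models;
  invasion-or-AIG genes are planted at the log2 midpoint of the
  (1.2, 1.5) window so they clear the 1.2 rule but not the 1.5 rules;
- the cohort composition (9 NPT + 50 PCa with the subtype, stage and
  Gleason margins above), ages ~ N(64, 7) and log-normal PSA;
- knockdown/overexpression of the manipulated factor itself (−2 / +4
  log2).

What it does **not** emulate: gene–gene correlation, array normalization
artifacts, batch effects, clone-specific biology beyond shared control
noise, missing data, or any relationship between the cell-line and
cohort matrices (they are drawn independently). Effect sizes are
homogeneous within a role class rather than gene-specific.

Default noise: sd 0.1 (target screen, |planted l2fc| = 1.0), 0.05
(phenotype screen), 0.4 (cohort, planted stage shift −1.5 log2). With a
single manipulated replicate per population the shared control column
correlates the two clone fold-changes; the phenotype screen is therefore
run at three replicates per population in the reproduction scripts,
which the generator supports via `n_replicates`.

## Determinism

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; no global state is used. The pipeline writes
a manifest with a configuration hash (seed excluded) and sha256 digests
of every artifact, and identical seeds produce byte-identical outputs.
Floating-point output uses 8 significant digits, enough to round-trip
through the TSV readers.

## Limitations

- Threshold rules are brittle near their cutoffs by construction; genes
  whose true fold change sits close to 1.2 or 1.5 flip membership under
  noise. The tests quantify this with recall/false-positive margins
  rather than exact set equality on noisy draws.
- The uncorrected chi-square p-values should be read as the original
  analysis reported them, not as calibrated tail probabilities; use the
  permutation machinery (`etstargets.synthetic.permute_labels`) or
  Fisher's exact test for calibrated inference.
- The synthetic cohort cannot validate biological claims about the
  panel genes; it only validates that the software finds what was
  planted at the stated effect sizes.
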