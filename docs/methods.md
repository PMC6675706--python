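# Methods

## The screening model

`cernascreen` implements a competing-endogenous-RNA (ceRNA) candidate
screen over matched lncRNA, miRNA and mRNA expression profiles. The ceRNA
hypothesis holds that a lncRNA carrying binding sites for a miRNA can
sequester ("sponge") that miRNA, de-repressing the miRNA's mRNA targets.
If a (lncRNA ℓ, miRNA μ, mRNA m) triplet behaves this way across a cohort,
its pairwise expression correlations carry a characteristic sign pattern:

    r(ℓ, μ) < 0,    r(μ, m) < 0,    r(ℓ, m) > 0.

The screen combines two evidence channels:

1. **Target evidence** — Watson–Crick seed complementarity. A canonical
   site on a transcript is anchored by an exact match to the reverse
   complement of the miRNA seed (nucleotides 2–7); flanking nucleotides
   refine the class (`8mer` > `7mer-m8` > `7mer-A1` > `6mer`, TargetScan's
   hierarchy). One seed-core locus is reported once with its best class.
   G:U wobble is not accepted in the seed, and no conservation,
   thermodynamic or context scoring is applied: this is a pure
   complementarity scan, so its predictions are a superset of what
   conservation-filtered catalogs (miRcode, TargetScan) would report.
2. **Expression evidence** — pairwise Pearson correlation with the exact
   t-based two-sided p-value, `t = r·√((n−2)/(1−r²))` on `n−2` degrees of
   freedom. Each of the three edges must carry the expected sign at
   p < α.

The screen proceeds stepwise, mirroring how such analyses are run in
practice: drop unexpressed genes; for each lncRNA take the miRNAs with ≥ 1
seed site on it; keep anti-correlated lncRNA–miRNA edges; take each
surviving miRNA's seed-match mRNA targets (optionally intersected with a
user panel, e.g. an apoptosis gene array); keep anti-correlated
miRNA–mRNA edges; keep triplets whose lncRNA–mRNA correlation is positive
and significant. All surviving triplets are returned with full edge
statistics, ordered by |r(lncRNA, mRNA)| descending; the package does not
adjudicate further among survivors (in the motivating analysis that last
step used orthogonal wet-lab evidence, which is out of scope here).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.05 | per-edge two-sided significance level; **no multiplicity correction** by default, since the screen is per-edge thresholding, not family-wise inference. A Benjamini–Hochberg option exists (`bh_correction`) but is off. |
| `expression_fraction` | 0.5 | a gene is "expressed" if nonzero in ≥ this fraction of samples. The cutoff is not standardized in the literature; 50 % is a conservative, reproducible choice and is logged with every run. |
| `site_types` | all four | site classes accepted as target evidence. |
| IHC bins | <25 / 25–49 / ≥50 % | percent positive tumor cells → negative / low / high; boundaries inclusive on the left of each upper bin (25 → low, 50 → high). |
| DE thresholds | p < 0.05, &#124;log2FC&#124; > 1 | both strict inequalities; a gene at exactly &#124;log2FC&#124; = 1 is excluded. |

Correlations are computed on `log2(x+1)`-transformed values whenever a
matrix is flagged linear-scale; log-scale input is used as-is. The raw
(untransformed) behaviour is available by flagging the matrix as `log`,
for sensitivity checks. A perfect correlation reports the smallest
positive double rather than p = 0, keeping p in (0, 1].

Triple-negative (basal-like) samples are those annotated negative for all
of ER, PR and HER2; samples with any `unknown` receptor status are
excluded rather than imputed, because exclusion is the only reproducible
reading of a receptor-defined subtype.

The 2×2 association test is the Pearson chi-squared
`n(ad−bc)² / [(a+b)(c+d)(a+c)(b+d)]` with df = 1; Yates continuity
correction is exposed as a flag (default off) since reports rarely state
whether it was applied. A zero marginal raises instead of returning 0/1.

## The sponge-model simulator

`simulate_cerna_dataset` generates the study conditions the screen is
designed for: a cohort of `n_samples = 58` triple-negative samples with
one planted triplet among `50` decoy miRNAs and `200` decoy mRNAs.
Per sample,

    L ~ LogNormal(log 2, σ),   Mtot ~ LogNormal(log 20, σ),
    M = Mtot / (1 + k·L),      T = B / (1 + g·M),   B ~ LogNormal(log 10, σ),

with sponge strength `k = 5`, repression strength `g = 5` and log-scale
noise `σ = 0.2` by default. The saturable forms are the minimal
mechanistic description of competitive sequestration and miRNA-mediated
repression; they produce the ceRNA sign pattern at every positive (k, g).
The baseline medians are chosen so both occupancy terms sit in their
sensitive regimes (k·L ≈ 10, g·M ≈ 9 at defaults): the planted triplet
represents a genuinely coupled sponge rather than a marginal one. Decoy
genes are independent log-normals with gene-specific latent means
(Normal(log 5, 0.5²)), so decoy edges are null. An optional
negative-binomial rendering (`nb_dispersion`) converts abundances to
overdispersed counts.

Randomness is driven by one seed through a `SeedSequence` split per
matrix, with planted genes drawn from their own stream — enlarging a
decoy pool never perturbs the planted draws.

`simulate_study_sequences` supplies the matching target-evidence channel:
every gene gets a random-background transcript (lncRNAs 1500 nt, mRNA
3′UTR-like transcripts 1000 nt — round figures near human medians), and
every planted (lncRNA, miRNA) and (miRNA, mRNA) pair gets one embedded
8mer site. Chance seed sites in the random background are deliberately
left in place: decoy pairs acquire target support at the sparsity random
sequence dictates, exactly as chance seed matches occur in real
transcriptomes. This makes false-positive routes through the screen
possible and gives the precision/recall benchmark teeth.
`universal_target_support` is a harsher stress stub that grants *every*
pair support; under it the screen's precision drops well below the
sequence-channel benchmark because every decoy mRNA becomes testable
against every miRNA.

`simulate_sequences` (used for scanner fixtures and the worked examples)
additionally rejection-corrects the background until a full scan reports
*exactly* the requested sites — no accidental sites and no embedded site
silently upgraded to a higher class by its flanks.

### What the simulator does and does not emulate

It reproduces the statistical geometry the screen relies on: cohort-scale
sample size, a mechanistically coupled triplet with the (−, −, +) sign
pattern, null decoys, and seed-site evidence with realistic chance
sparsity. It does **not** model batch effects, tumor purity, subtype
mixtures, shared miRNA regulation among decoys, count-depth variation
(unless NB rendering is enabled), or kinetic ceRNA dynamics. Passing the
recovery benchmark therefore shows the screen is correct and well
calibrated under the sponge model's assumptions — not that it is robust
to the confounders of consortium data.

## Numerical and procedural choices

* Pearson r is computed from centered sums of products and clamped to
  [−1, 1]; p-values come from the exact t distribution (`scipy.stats.t`),
  never a normal approximation.
* Pairs whose overlap vector is constant are returned in an explicit
  skipped list, not silently dropped; an empty sample intersection is an
  error.
* Genes containing `NA` cells are dropped (with a logged warning) when a
  matrix is read, so every correlation runs over complete vectors.
* Output ordering is fully deterministic: triplets by |r(lncRNA, mRNA)|
  descending, then lexicographic ids; the screen contains no randomness.
* Transcript coordinates are 1-based inclusive in the native output; the
  `--bed` dialect converts starts to 0-based half-open.
* The `run` subcommand writes a manifest (version, resolved config,
  SHA-256 input digests, seed, timestamp); re-running an identical config
  reproduces byte-identical data outputs.

## Benchmarks computed by `scripts/acceptance.py`

All quantities are recomputed at run time from the given `--seed`:
the worked seed-site examples (a 6mer at 110–115 on a synthetic HCP5-like
lncRNA; a 7mer at 1268–1274 on a synthetic BIRC3-like 3′UTR — both
stand-ins generated with fixed seeds, labelled synthetic, carrying the
documented site classes and coordinates), the chi-squared statistic on the
10/2/7/11 immunohistochemistry cross-tabulation (≈ 5.79), the maximum
deviation of Pearson r from a plain-Python covariance-formula oracle over
1000 random vectors (≈ 2 × 10⁻¹⁶), the fraction of 2000 independent edges
passing p < 0.05 (≈ 0.05), and mean recall/precision of the planted
triplet over 20 simulation replicates at the default study conditions
(recall ≥ 0.9 observed; precision ≈ 0.8). Problem sizes (2000 null edges,
20 replicates) are chosen to put Monte-Carlo error well inside the bands
being checked while keeping the whole script under a few seconds.

## Known limitations

* Seed matching is complementarity-only; without conservation or context
  filtering, per-transcript site counts exceed curated catalogs.
* The screen's false-discovery behaviour is driven by the correlation
  geometry: conditioning on r(ℓ, μ) < 0 and r(μ, m) < 0 enriches for
  r(ℓ, m) > 0 even under the null, so surviving decoy triplets are more
  common than α³ naïvely suggests. Precision estimates from the benchmark
  quantify this under the sponge model only.
* No partial-correlation, conditional-independence or mediation scoring;
  no multiple-testing correction by default — by design, as a
  candidate-generation screen.
* Sample sizes near the default (58) give limited power for |r| < 0.3;
  the α = 0.05 edge test detects |r| ≳ 0.26.
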