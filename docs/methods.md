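# Methods

`cinscreen` implements a two-pronged in-silico screen for drugs that might
counteract a drug-induced toxicity — the motivating case is
cisplatin-induced nephrotoxicity (CIN) — and the synthetic data machinery
needed to validate every stage against planted ground truth.

## 1. Gene-expression signature construction (`signature`)

**Model.** Each study contributes a gene × sample matrix of RNA-seq counts
with a two-group design (control vs treated). Counts for gene *g* in
sample *j* are modelled as negative binomial with mean `s_j · μ_g(group)`
and dispersion φ, using the mean/dispersion parameterization
`Var = μ + φμ²` so that a planted log2 effect of Δ multiplies the treated
group mean by exactly 2^Δ.

**Normalization.** Per-sample scale factors `s_j` are the exponentiated
30%-trimmed mean (15% per tail) of the per-gene log-ratios against the
geometric-mean reference sample, computed on genes expressed in every
sample, then rescaled to geometric mean 1. This is the trimmed-ratio
family used throughout count-based DE analysis; on exactly proportional
libraries it recovers the library-size ratio split symmetrically
(e.g. factors (1/√2, √2) when one library doubles the other).

**Differential test.** Per gene, a Wald test on the log2 ratio of
pseudo-counted normalized group means (pseudo-count 0.5, avoiding
infinities at zero). The variance of the log2 fold change follows the
delta method, `SE² = [(1/ā + φ)/n_c + (1/b̄ + φ)/n_t]/ln²2`, with the
dispersion φ estimated per gene by method of moments pooled across groups
and shrunk 70/30 toward the common (median) dispersion. The statistic is
referred to a t distribution with `n − 2 + 8` degrees of freedom: the
residual df plus a prior-df credit for the information the common
dispersion borrows across thousands of genes. The prior df was calibrated
on the generator's own null simulations so that null p-values are uniform
(KS distance from U(0,1) ≤ 0.04 at 2000 genes) while 4-fold planted
effects at n = 4/group, φ = 0.1 are recalled at ≥ 90% at a 1% FDR.
A plain normal reference is anti-conservative here (the dispersion is
estimated), and the unmoderated t(n−2) reference overcorrects.

**FDR.** Benjamini–Hochberg step-up (default threshold 1%, applied per
dataset before intersection). Implemented via
`statsmodels.stats.multitest`; the test suite checks it against a
brute-force step-up oracle.

**Ortholog mapping.** Non-human symbols are translated through a
(source, human) table: unmapped symbols are dropped and reported,
one-to-many sources expand to all targets (maximizing recall), and a
human symbol receiving conflicting directions from different sources is
dropped as conflicting — this preserves the up/down disjointness
invariant. Symbols are upper-cased only after mapping, so mouse/human
joins happen exclusively through the table.

**Intersection.** The signature is the direction-consistent intersection:
up = ∩ of per-dataset up-sets, down = ∩ of down-sets (≥ 2 datasets). A
gene called up in some datasets and down in another drops out of both
automatically.

**Enrichment.** One-sided hypergeometric over-representation of the
signature genes against a user-supplied gene-set collection (GMT),
sets intersected with the stated universe first, BH-adjusted across sets.

## 2. Connectivity scoring (`connectivity`)

For each reference perturbagen (a gene score profile, e.g. z-scored
differential expression), genes are ranked by score descending (ties
broken lexicographically by gene id, for determinism) and a weighted
Kolmogorov–Smirnov running sum is computed for the query's up and down
sets separately: hits advance by `|score| / Σ|score over the set|`
(weight exponent 1), misses retreat by `1/(N − N_hits)`; the enrichment
score (ES) is the extremum of largest magnitude, positive on ties (to
float precision, 1e-9 relative).

The combined score is `WTCS = (ES_up − ES_down)/2` when the two ES
disagree in sign or either is zero, else 0 — a perturbagen must move the
up and down sets coherently to score at all. WTCS is normalized within
each perturbagen group and sign by the mean |WTCS| of same-sign members
(NCS), and `tau = sign(NCS) · 100 · P(touchstone |NCS| < |NCS|)` with
strict inequality, so NCS = 0 maps to tau = 0 exactly. The touchstone
defaults to all perturbagens in the supplied library. Chemicals with
tau < 0 (threshold configurable) are the reversal candidates.

## 3. Adverse-event screen (`faers_screen`)

Reports arrive as three `$`-delimited tables keyed by `primaryid`
(DEMO: primaryid/caseid/caseversion, DRUG: primaryid/drugname,
REAC: primaryid/pt). Curation steps:

1. **Deduplication** — one report per case: highest `caseversion`, ties
   broken by highest primaryid. Version order is the recency signal;
   date fields are outside the dialect.
2. **ATC collation** — verbatim drug strings normalized (trim, uppercase,
   collapse whitespace) and mapped to ATC level-5 codes via a synonym
   table; variants collapsing to one code count once per case; unmapped
   strings are dropped and tallied.
3. **Cohort** — cases whose drug set contains the causative drug A
   (e.g. cisplatin, L01XA01).
4. **Screen** — for every co-medication in ≥ `min_exposed` cohort cases
   (default 3, a conventional disproportionality floor), the 2×2 table
   d1r1/d1r0/d0r1/d0r0 of exposure × indexed reaction within the cohort,
   `ROR = (d1r1/d1r0)/(d0r1/d0r0)` and the Woolf interval
   `exp(ln ROR ± 1.959964 · √(Σ 1/cell))`. Tables with any zero cell get
   the Haldane–Anscombe +0.5 on all cells (flagged `corrected`); a table
   with an empty d1 or d0 margin is undefined and excluded. Protective ⇔
   CI upper bound < 1, i.e. a one-sided 2.5% criterion per drug. No
   multiple-testing correction is applied by default, mirroring the
   CI-only convention of disproportionality screens; a BH option exists
   but is off.

All drugs on a case count as co-administered; suspect/concomitant roles
are not modelled.

## 4. Candidate intersection (`candidates`)

Perturbagen names and ATC codes are bridged by a user-supplied mapping
table (synthetic runs generate their own); names are lower-cased and
common salt suffixes stripped before lookup. Identities supported by
both screens rank first (tau ascending, then CI upper bound ascending).
`run_pipeline` orchestrates all stages from a config (file inputs or
`simulate:` blocks), writes every intermediate artifact, a
`summary.json`, and a seeded, config-hashed run log; a missing
adverse-event input produces a connectivity-only report with null
pharmacovigilance fields.

## 5. Synthetic data (`synthetic_data`)

The generators define the package's validation conditions; all are pure
functions of their spec including the seed.

**Transcriptome** (defaults: 3 studies — two "mouse", one "human" —
2000 genes, 4 samples/group, planted 152 up + 56 down shared genes at
|log2FC| = 2, φ = 0.1, 5% study-private DE genes, baseline means
log-uniform on [50, 2000]). The planted signature sizes mirror the shape
of the published CIN signature; effect size, dispersion and group size
are conventional benchmark settings for small bulk RNA-seq designs (the
original studies publish no effect-size estimates). Counts are
gamma-Poisson draws. The ortholog table for mouse studies is emitted
alongside, with 5% unmapped and 5% one-to-many sources to exercise the
mapping edge cases.

**Adverse events** (defaults: 200,000 cases, drug-A prevalence 0.1,
indexed-reaction probability 0.3 given drug A / 0.05 otherwise, one
protective co-drug at multiplier 0.3 and prevalence 0.2, one risk co-drug
at multiplier 3.0, eight null co-drugs, 20% duplicated cases). The
reaction is drawn per case from a logistic model whose logit is shifted
by Σ log(odds multiplier) over co-drugs present, so each co-drug's
conditional odds ratio equals its multiplier. Duplicated cases are also
emitted as an earlier version whose drug list is perturbed with
probability 0.5, making deduplication correctness observable. Each case
carries 3 distractor reactions from a 40-term vocabulary.

**Perturbagen library** (defaults: 200 perturbagens × 1000 genes, 5
reversers, 5 mimickers, reversal strength 0.8, noise SD 1.0). Background
scores are i.i.d. N(0, noise_sd²); reversers subtract
`strength × 3.0` score units from query-up genes and add it to
query-down genes (mimickers the opposite). The shift scale of 3.0 is an
absolute constant rather than a multiple of the noise, so the
noise → 0 limit stays well-defined (a reverser then ranks every
query-down gene above every query-up gene).

**What the simulations do not emulate:** read-level sequencing noise,
batch effects, realistic MedDRA reaction hierarchies, drug–drug
interactions beyond independent multiplicative odds, suspect/concomitant
role annotations, and the composition of any real perturbagen catalog.
Passing tests therefore demonstrate the pipeline's statistical
correctness under its stated model, not performance on any specific
public dataset.

## 6. Numerical choices and degenerate inputs

- Zero-count genes get p = 1, lfc = 0; all-zero samples are an error.
- Enrichment with an all-zero hit-score set falls back to equal hit
  weights.
- Gene-rank ties break lexicographically; perturbagen result ties break
  by id; dedup ties by primaryid — every ordering is deterministic.
- Group-mean NCS denominators are computed on sorted absolute values so
  results are invariant to perturbagen order.
- Seeds: the pipeline derives stage seeds as seed, seed+1, seed+2 to
  decouple the three generators.

## 7. Problem sizes

The test suite and the acceptance script run the screens at the default
simulation sizes above; replicate counts (5–20 seeds per operating
characteristic, 2000 interval-coverage replicates, 10,000 oracle tables)
were chosen to make the Monte-Carlo bands in the tests tight while
keeping a full run in the minutes range on one core.

## 8. Known limitations

- The DE test is a moderated Wald approximation, not an exact NB
  likelihood-ratio test; it is calibrated at the simulated operating
  point (n ≥ 4/group, moderate dispersion) and untested at n = 2.
- tau percentiles are computed against the supplied library itself by
  default; absolute tau values are not comparable across libraries.
- The ROR screen inherits all usual caveats of spontaneous-report
  disproportionality (reporting bias, confounding by indication);
  a protective flag is a screening signal, not an effect estimate.
- Name→ATC harmonization is table-driven; real-data use requires a
  curated mapping.
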