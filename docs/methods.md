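# Methods

This note documents the models, procedures and numerical choices behind
`dreamcue`, what the synthetic-data generator does and does not emulate, and
the known limitations.

## Session model

A targeted-dream-incubation session is a deterministic event schedule in
whole seconds. The parameters, with defaults:

| parameter | default | meaning |
|---|---|---|
| `latency_min_s`, `latency_max_s` | participant-chosen | window for the preparatory period before the first cue |
| `dwell_s` | 180 | time in the target state per trial |
| `report_s` | 60 | report window after each prompt |
| `return_s` | 420 | return-to-state period between trials |
| `n_trials` | 4 | cue/report rounds per session |

The realized latency is a uniform integer draw on the closed window,
reproducible from the session's seed. The cue plays once at the end of the
latency and once at the start of each return period, so every dwell is
preceded by a cue; this is one concrete reading of a cue played
"intermittently", chosen because it preserves the per-trial structure
(exactly `n_trials` cues and report prompts, `n_trials − 1` returns). The
session ends with the last report window — the return period exists only to
re-enter the state for a following trial. With defaults the post-latency
duration is 4·(180+60) + 3·420 = 2220 s, i.e. 50 minutes for a 13-minute
latency. Real-time execution records sub-second jitter in the event log but
never alters the schedule; simulated execution realizes offsets exactly.

The inclusion screen is a conjunction: a participant is analyzable iff they
report *no* sleep in the FMT session and at least "half asleep" in the
hypnagogia session. Because hypnagogia and wakeful mind-wandering blend into
each other, the screen is deliberately strict; applied to the generator's
defaults it retains roughly 61% of recruits.

## Text processing

Sentence segmentation is rule-based (terminal `.`, `!`, `?` with an
abbreviation guard list) rather than model-based, trading linguistic
sophistication for bit-reproducibility. Cue-word filtering removes exact,
case-insensitive occurrences of the cue word and its simple plural
(`tree/trees`, `fork/forks`) and drops sentences emptied by the removal.
Derivatives ("forked") are kept: the filter targets prompt words literally.
Removing meta-commentary from raw reports (apologies to the experimenter and
the like) is the caller's responsibility.

## Embedding measures

*Prompt centrality* is the mean cosine similarity between each sentence of a
cue-filtered report and the bare lowercase cue word; *temporal coherence* is
the mean cosine similarity of strictly consecutive sentence pairs (width 2,
stride 1), defined only for reports with at least two sentences — a
one-sentence report yields a missing value, which regressions drop listwise.
Both are plain averages over an `Embedder` interface, so any deterministic
sentence-to-vector map can back them.

Two backends ship. The default is a hashed token-count embedder: tokens are
lowercased word characters, each hashed by keyed blake2b into one of 512
buckets. It is deterministic across platforms, dependency-free, and
non-negative (so its cosines lie in [0, 1]); with it the whole semantics
pipeline is reproducible to 1e-12. It captures lexical overlap only — two
sentences with no shared tokens score ~0 regardless of meaning — so passing
tests on synthetic text demonstrate the *pipeline*, not semantic validity.
The transformer sentence-encoder backend (512-d) provides actual semantics
when its runtime is installed; it is never required by the tests.

## Mixed models

Report-level measures are related to covariates with linear mixed models
containing a random intercept per participant, estimated by full maximum
likelihood (not REML) so that nested fixed-effect models are comparable by
likelihood-ratio test, χ² = 2(ℓ_full − ℓ_reduced) with df equal to the
difference in fixed-parameter counts. A full-model log-likelihood below the
reduced one beyond 1e-6 raises (a fit failure, not a test result). Boundary
(zero) variance estimates are accepted silently: with no planted group
variance the model collapses to ordinary regression, which is correct
behavior. The default optimizer occasionally fails on intercept-only
models; the fit then retries with a derivative-free method.

Calibration is verified by simulation: under a df = 1 null the LRT p-values
are uniform (KS test), and at the planted slope β = 0.20 with 80
participants × 2 conditions the 95% Wald interval covers the truth in ≈ 94%
of 200 replicates.

## Incorporation statistics

Rate tests use the Pearson goodness-of-fit statistic with no continuity
correction, against a default chance benchmark p₀ = 0.5 — the convention
under which 73/80 yields χ²(1) = 54.45 and 34/37 yields 25.97 — and the 2×2
Pearson statistic (again uncorrected) for between-cohort comparisons.

Agreement between raters reports three views of the same annotations:
Pearson *r* on per-report total counts, Cohen's κ on a derived categorical
label (default: presence/absence of any cued incorporation per report —
pluggable, since the appropriate unit of analysis is a design choice), and a
paired *t* on totals with df = N − 1 over matched report units. When
multiple raters exist downstream analyses default to the first rater's
counts, with averaging available.

The factorial analysis handles up to three 2-level within-subject factors by
signed contrast scores per participant; each effect's F is exactly the
square of the paired t on its contrast (an algebraic identity for 2-level
designs, asserted in tests), with partial η² = F/(F + df_error).

## Probe statistics

The 13-item family is corrected together: 11 paired-t p-values plus the
model p-values of the binary (logistic LRT vs intercept-only) and 4-category
(baseline-category multinomial logit, atemporal reference) items, adjusted by
the Benjamini–Hochberg step-up rule adjusted_(k) = min_{j≥k} p_(j)·m/j,
clipped at 1. The implementation delegates to the standard step-up routine
and is tested against a brute-force min-over-tail oracle. Likert items are
treated as continuous throughout (t-tests, correlations, EFA). Complete
separation in the logistic model is flagged; the odds ratio then falls back
to the Haldane–Anscombe-corrected table and the LRT to the table's
G statistic.

Partial correlations come from the inverse correlation matrix,
r_ij = −P_ij/√(P_ii·P_jj), each pair thereby controlling for every other
variable in the set; p-values use the t approximation with df = n − k.
The computation is verified against a regress-out-residuals oracle at 1e-8.

### Parallel analysis

A common-factors (not principal-components) reduction: eigenvalues of the
correlation matrix with squared multiple correlations on the diagonal,
compared against the same reduction of `n_iter` (≥ 100) standard-normal
datasets of identical shape. The retained count is the leading run of
observed eigenvalues exceeding the reference. The default reference is the
mean of the random eigenvalues, with the 95th percentile available: the mean
criterion is the more common default but is anticonservative under pure
noise (each noise eigenvalue beats the mean reference with probability
≈ ½), so null-behavior guarantees hold for the percentile criterion. On the
generator's planted 4-factor batteries at n = 300 the mean criterion
recovers 4 factors in ≥ 90% of seeds.

### Exploratory factor analysis

Maximum-likelihood extraction profiles the loadings out of the Wishart
likelihood: for uniquenesses Ψ the objective is Σ_{j>k}(λ_j − ln λ_j − 1)
over the trailing eigenvalues of Ψ^(−1/2) R Ψ^(−1/2), minimized by L-BFGS-B
over log Ψ with uniquenesses bounded in [0.005, 1] (the conventional floor;
an item on the floor — communality ≈ 1 — is flagged as a Heywood case, which
genuinely occurs for factors carried by only two items). Oblimin rotation
(γ = 0, i.e. quartimin) uses the oblique gradient-projection algorithm.
Deterministic output conventions: each factor's largest-magnitude loading is
made positive, and factors are ordered by descending sum-of-squares loadings
diag(Φ Λ′Λ). Communalities are the unrotated row sums of squares (rotation-
invariant); proportions of variance divide by the item count and proportions
explained by the total SS. The unrotated solution's communalities agree with
an independent ML factor-analysis implementation to 0.05, and on planted
structures (loadings 0.7, n = 300 discretized Likert responses) the mean
absolute loading error after factor matching is ≈ 0.05 (< 0.10).

The |loading| ≥ 0.40 threshold for "substantial" is inclusive, and items
substantial on more than one factor are reported as cross-loadings.

## Synthetic-data model

The generator plants every parameter the analyses later estimate:

- **Cohort**: 132 recruited, each independently compliant with probability
  80/132; compliant participants receive two counterbalanced sessions
  (condition order × cue assignment cycling over a 4-cell Latin square).
- **Incorporations**: cued direct/indirect counts are zero-inflated
  Poisson — zero with probability 1 − p_any (p_any = 0.91), otherwise
  Poisson(2.85)/Poisson(1.68) draws conditioned on a positive total. The
  zero-inflation is the generator's own device: independent Poisson draws at
  those means would put the any-incorporation rate near 0.99, which is not a
  realistic study condition. Uncued counts default to exactly zero (an
  optional leak rate exists). Reports realize the counts through fixed
  sentence templates — direct mentions contain the cue word verbatim, exactly
  once per mention; indirect mentions draw from a per-cue associate lexicon —
  shuffled among distractor sentences, so synthetic annotations need no
  human rater and ground truth is recoverable from the text itself.
- **Probes**: the 11 Likert items are Λf + shift + ε with f standard normal
  (optionally correlated), a default 4-factor loading pattern at 0.7 over a
  3/3/3/2 item partition, residual SDs completing unit variance, per-item
  condition shifts (defaults mirror the scale of observed
  hypnagogia-vs-FMT differences, e.g. +0.31 on freedom of thought flow),
  discretized at fixed thresholds (−1.5, −0.5, 0.5, 1.5) onto 1..5. The
  categorical items use planted per-condition probabilities, including a
  higher present-focus rate in FMT.
- **Seeding**: one master seed is split into independent per-product
  streams, so regenerating one product does not perturb the others; the same
  seed gives byte-identical files.

What the generator does **not** emulate: linguistically coherent narratives
(distractor sentences are a small fixed pool), semantic structure visible to
a real embedder, rater disagreement beyond simple additive count noise,
item-level floor/ceiling asymmetries, and any dependence of probe responses
on the report content. Tests passing on synthetic data therefore validate
the statistical machinery and its calibration, not claims about real dream
reports.

## Problem sizes used in the checks

The recovery studies run at the study's own scale where that is what is
being claimed (80 participants × 2 conditions; n = 300 for factor-structure
recovery, 100–200 replicates or seeds per study), and at reduced scale where
only calibration is at stake (null LRT uniformity uses 40-participant
cohorts, whose calibration is size-agnostic). The full suite and the
reproduction script each complete in well under a minute of simulation time
per study on a single CPU.

## Known limitations

- The fallback embedder measures token overlap; prompt centrality computed
  with it is near zero whenever reports share no vocabulary with the cue
  word after filtering. Semantic conclusions require the transformer
  backend.
- The ML-EFA objective is non-convex; different uniqueness starts can reach
  different local optima on pathological inputs. The classic start
  (1 − k/2p)/diag(R⁻¹) is used and has been stable on all tested inputs.
- Two-item factors are only weakly identified in ML extraction and can
  produce Heywood cases; they are flagged, not repaired.
- The multinomial contrast reports relative-risk ratios against a single
  reference category; with sparse categories the Wald-scale estimates are
  unstable even though the model LRT remains well-behaved (empty categories
  are dropped with a warning).
- `within_subject_anova` covers 2-level within-subject factors only, which
  is exact for this design but not a general ANOVA replacement.
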