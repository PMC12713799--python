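# dreamcue

Sensor-free, timer-driven **targeted dream incubation (TDI)** sessions and a
full analysis toolkit for comparing thought content across **hypnagogia**
(the sleep-onset state, N1) and **freely moving thought (FMT)**, a form of
wakeful mind-wandering.

TDI steers sleep-onset mentation toward a chosen theme by replaying a cue
message ("Remember to think of a Fork/Tree") around sleep onset and prompting
thought reports at scheduled times. Classically this required physiological
sensing to detect N1; `dreamcue` implements the timer-only alternative: a
participant-chosen sleep-latency window, fixed dwell / report / return
periods, and a handful of trials per session. The same machinery cues FMT in
wakeful participants, giving a two-condition within-subject design with a
post-session vigilance screen deciding which participants are analyzable.

## What the package computes

**Session engine** (`dreamcue.session`) — deterministic schedules
(`draw_latency`, `build_timeline`), execution against a real or simulated
clock (`run_session`), and the vigilance inclusion screen: keep a participant
iff they stayed fully awake during FMT *and* slept at least halfway during
hypnagogia.

**Reports** (`dreamcue.corpus`) — rule-based sentence segmentation and
cue-word filtering (the cue word and its plural are removed before any
similarity to the cue is computed, so literal mentions cannot inflate it).

**Incorporation scoring** (`dreamcue.incorporation`) — cell tallies of
direct/indirect incorporations of cued vs uncued objects; inter-rater
agreement (Pearson *r* on counts, Cohen's κ on presence/absence, paired *t*);
fully within-subject factorial contrasts where every 2-level effect satisfies
*F* = *t*²; and incorporation-*rate* tests: for *k* of *n* participants with
at least one cued incorporation,

χ² = (k − np₀)²/(np₀) + ((n−k) − n(1−p₀))²/(n(1−p₀)),  df = 1 (p₀ = ½, no continuity correction),

plus the analogous 2×2 Pearson test between two cohorts.

**Semantics** (`dreamcue.semantics`) — two embedding-derived report measures:
*prompt centrality* (mean cosine similarity of each sentence to the cue word)
and *temporal coherence* (mean cosine similarity of consecutive sentence
pairs; defined only for ≥ 2 sentences). Both run over a pluggable embedder;
the default is a deterministic 512-d hashed token-count backend, with a
transformer sentence-encoder backend available when its runtime is installed.
Random-intercept linear mixed models (ML) relate the measures to covariates,
with likelihood-ratio tests χ² = 2(ℓ_full − ℓ_reduced) between nested fits.

**Thought probes** (`dreamcue.probes`) — the 13-item phenomenology battery
(11 Likert items, binary intentionality, 4-category temporality): paired
two-sided *t* contrasts plus logistic / multinomial condition models,
corrected as one family by Benjamini–Hochberg; partial correlations from the
precision matrix, r_ij = −P_ij/√(P_ii P_jj); common-factors parallel
analysis (SMC-reduced correlation eigenvalues vs random reference); and
exploratory factor analysis with maximum-likelihood extraction and oblimin
(γ = 0) rotation, reporting loadings, communalities *h*², factor
correlations, and the variance decomposition. Loadings with |λ| ≥ 0.40 are
marked substantial.

**Synthetic cohorts** (`dreamcue.synthgen`) — seeded generators for the whole
study: a recruited pool with a planted compliance rate, counterbalanced
sessions, reports with planted (zero-inflated Poisson) incorporation counts,
and probe responses from a planted latent-factor model — all emitted with a
ground-truth record so every analysis can be validated offline.

## Worked example

```python
from dreamcue.incorporation import chisq_vs_chance, chisq_two_proportions
from dreamcue.probes import bh_adjust

# 73 of 80 participants reported >= 1 cued incorporation online;
# 34 of 37 across comparable in-person studies
print(chisq_vs_chance(73, 80, 0.5))       # (54.45, 1, 1.59e-13)
print(chisq_vs_chance(34, 37, 0.5))       # (25.97, 1, 3.46e-07)
print(chisq_two_proportions(73, 80, 34, 37))  # (0.0133, 1, 0.908)

raw = [0.018, 0.027, 0.032, 0.138, 0.171, 0.334, 0.430,
       0.438, 0.465, 0.518, 0.552, 0.726, 0.753]
print(bh_adjust(raw).round(3))
# [0.139 0.139 0.139 0.445 0.445 0.652 0.652 0.652 0.652 0.652 0.652 0.753 0.753]
```

The first two chi-squares say each cohort's incorporation rate (91% online,
92% in person) is far above the 50% chance benchmark; the third says the two
rates do not differ (p = 0.91), i.e. the timer-only remote procedure cues
thought content about as effectively as sensor-based laboratory protocols.
The BH-adjusted column shows no item-level phenomenology contrast survives
correction across the 13-test family.

A full synthetic study from the shell:

```bash
dreamcue synth --seed 7 --out cohort/
dreamcue screen --vigilance cohort/vigilance.csv --out screened.csv
dreamcue score --annotations cohort/annotations.csv --out scored/
dreamcue semantics --reports cohort/reports.csv --out semantic_scores.csv
dreamcue probes --data cohort/probes.csv --out probe_results/
```

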