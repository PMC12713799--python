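"""Synthetic two-condition within-subject cohorts with known ground truth.

The generator emulates the structure of a remote targeted-dream-incubation
study: a recruited pool screened down by the vigilance criterion, two
counterbalanced sessions per retained participant (hypnagogia and freely
moving thought, one cue object each), typed thought reports whose direct
and indirect cue incorporations are planted at controlled rates, rater
annotations derived from those planted counts (with optional rater
noise), and 13-item probe responses drawn from a planted latent-factor
model with per-item condition shifts.  Everything is driven by one master
seed split into independent per-product streams, and the planted values
are emitted alongside the data as a GroundTruth record so downstream
analyses can be validated against known truth.

Incorporation counts follow a zero-inflated Poisson scheme: with
probability ``1 - p_any`` a cued report contains no incorporation at all;
otherwise direct/indirect counts are drawn from the planted Poisson rates
conditioned on a non-zero total.  The zero-inflation reproduces a
realistic "at least one incorporation" rate, which independent Poisson
draws at the planted means would push near 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .corpus import ThoughtReport
from .incorporation import Annotation
from .probes import LIKERT_ITEMS
from .session import (
    Condition,
    CueObject,
    SessionConfig,
    VigilanceLevel,
)

__all__ = ["CohortParams", "GroundTruth", "generate_cohort", "generate_probe_data", "write_cohort"]

# Associate lexicon for indirect incorporations; rating synthetic reports
# needs no human because indirect mentions are exact template lookups.
INDIRECT_LEXICON = {
    CueObject.TREE: ("branches", "leaves", "roots", "forest", "plants"),
    CueObject.FORK: ("spoon", "cutlery", "knife", "dinner table", "utensils"),
}

DIRECT_TEMPLATES = (
    "I dreamed of a {cue} standing right in front of me.",
    "At some point a {cue} drifted into my thoughts.",
    "I kept picturing the {cue} from the recording.",
    "There was a giant {cue} in the scene I imagined.",
)

INDIRECT_TEMPLATES = (
    "I imagined {assoc} all around me.",
    "My mind wandered to {assoc} for a while.",
    "I pictured {assoc} without really meaning to.",
)

DISTRACTOR_SENTENCES = (
    "I thought about what to cook for dinner tonight.",
    "My mind drifted to an old conversation with a friend.",
    "I remembered a beach I visited as a child.",
    "I was worried about an email I still have to send.",
    "A song kept playing over and over in my head.",
    "I imagined walking through my childhood home.",
)

# Default planted latent structure: four factors over the 11 Likert items,
# mirroring valence / unusualness / concerns-words / emotional-intensity
# style groupings, loadings 0.7.
DEFAULT_FACTOR_ITEMS = (
    ("positive_valence", "negative_valence", "images"),
    ("novelty", "bizarreness", "topical_shifts"),
    ("words", "current_concerns", "freedom_of_flow"),
    ("meaningfulness", "emotionality"),
)

# Planted per-item mean shift (hypnagogia minus FMT) on the latent scale.
DEFAULT_CONDITION_SHIFTS = {
    "freedom_of_flow": 0.31,
    "words": -0.24,
    "bizarreness": 0.18,
}

LIKERT_THRESHOLDS = (-1.5, -0.5, 0.5, 1.5)


def default_loading_matrix(loading: float = 0.7) -> pd.DataFrame:
    lam = pd.DataFrame(
        0.0,
        index=list(LIKERT_ITEMS),
        columns=[f"F{j + 1}" for j in range(len(DEFAULT_FACTOR_ITEMS))],
    )
    for j, items in enumerate(DEFAULT_FACTOR_ITEMS):
        for it in items:
            lam.loc[it, f"F{j + 1}"] = loading
    return lam


@dataclass(frozen=True)
class CohortParams:
    """Planted study conditions for a synthetic cohort."""

    n_recruited: int = 132
    p_compliant: float = 80.0 / 132.0
    lambda_direct: float = 2.85
    lambda_indirect: float = 1.68
    p_any: float = 0.91
    uncued_rate: float = 0.0
    rater2_noise_sd: float = 0.0
    loading_matrix: Optional[pd.DataFrame] = None  # items x factors
    factor_correlations: Optional[np.ndarray] = None
    residual_sd: Optional[np.ndarray] = None
    condition_shifts: Optional[dict] = None
    latency_min_s: int = 600
    latency_max_s: int = 900
    p_spontaneous: dict = field(
        default_factory=lambda: {"hypnagogia": 0.75, "fmt": 0.55}
    )
    # temporality category probabilities per condition (none, past, present, future)
    temporality_probs: dict = field(
        default_factory=lambda: {
            "hypnagogia": (0.25, 0.35, 0.20, 0.20),
            "fmt": (0.17, 0.28, 0.30, 0.25),
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_compliant", "p_any", "uncued_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.lambda_direct < 0 or self.lambda_indirect < 0:
            raise ValueError("rates must be >= 0")
        if self.n_recruited < 1:
            raise ValueError("n_recruited must be >= 1")
        lam = self.loading_matrix
        if lam is not None and list(lam.index) != list(LIKERT_ITEMS):
            raise ValueError("loading matrix rows must be the 11 Likert items, in order")


@dataclass(frozen=True)
class GroundTruth:
    """Per-participant planted values emitted alongside the synthetic data."""

    compliance: pd.DataFrame  # participant_id, compliant
    incorporations: pd.DataFrame  # per report: planted direct/indirect counts
    factor_scores: pd.DataFrame  # per participant x condition latent scores
    params: CohortParams


@dataclass(frozen=True)
class SyntheticCohort:
    sessions: list[SessionConfig]
    vigilance: pd.DataFrame
    reports: list[ThoughtReport]
    annotations: list[Annotation]
    probes: pd.DataFrame
    truth: GroundTruth


def _spawn(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def _planted_counts(rng: np.random.Generator, params: CohortParams) -> tuple[int, int]:
    """Zero-inflated cued (direct, indirect) counts: zero with prob
    1 - p_any, else Poisson draws conditioned on a positive total."""
    if rng.random() >= params.p_any:
        return 0, 0
    for _ in range(1000):
        d = rng.poisson(params.lambda_direct)
        i = rng.poisson(params.lambda_indirect)
        if d + i >= 1:
            return int(d), int(i)
    return 1, 0  # unreachable unless both rates are ~0


def _report_text(
    rng: np.random.Generator, cue: CueObject, n_direct: int, n_indirect: int,
    uncued: CueObject, n_uncued_direct: int, n_uncued_indirect: int,
) -> str:
    sents: list[str] = []
    word = cue.value.lower()
    for i in range(n_direct):
        sents.append(DIRECT_TEMPLATES[i % len(DIRECT_TEMPLATES)].format(cue=word))
    lex = INDIRECT_LEXICON[cue]
    for i in range(n_indirect):
        sents.append(INDIRECT_TEMPLATES[i % len(INDIRECT_TEMPLATES)].format(assoc=lex[i % len(lex)]))
    uword = uncued.value.lower()
    for i in range(n_uncued_direct):
        sents.append(DIRECT_TEMPLATES[i % len(DIRECT_TEMPLATES)].format(cue=uword))
    ulex = INDIRECT_LEXICON[uncued]
    for i in range(n_uncued_indirect):
        sents.append(INDIRECT_TEMPLATES[i % len(INDIRECT_TEMPLATES)].format(assoc=ulex[i % len(ulex)]))
    n_distract = int(rng.integers(2, 5))
    idx = rng.choice(len(DISTRACTOR_SENTENCES), size=n_distract, replace=False)
    sents.extend(DISTRACTOR_SENTENCES[i] for i in idx)
    order = rng.permutation(len(sents))
    return " ".join(sents[i] for i in order)


def generate_probe_data(
    params: CohortParams, n: int, rng: np.random.Generator | None = None,
    condition: str = "hypnagogia",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Likert probe items for one condition: item = Lambda f + shift + eps,
    discretized at fixed thresholds onto 1..5.  Returns (items table,
    latent factor scores)."""
    if rng is None:
        rng = _spawn(params.seed, 17)
    lam = params.loading_matrix if params.loading_matrix is not None else default_loading_matrix()
    L = lam.to_numpy(dtype=float)
    p, k = L.shape
    Phi = params.factor_correlations if params.factor_correlations is not None else np.eye(k)
    if params.residual_sd is not None:
        res_sd = np.asarray(params.residual_sd, dtype=float)
    else:
        res_sd = np.sqrt(np.clip(1.0 - np.diag(L @ Phi @ L.T), 0.05, None))
    shifts = dict(DEFAULT_CONDITION_SHIFTS if params.condition_shifts is None else params.condition_shifts)
    shift_vec = np.array([shifts.get(it, 0.0) for it in lam.index])
    sign = 0.5 if condition == "hypnagogia" else -0.5
    f = rng.multivariate_normal(np.zeros(k), Phi, size=n, method="cholesky")
    eps = rng.standard_normal((n, p)) * res_sd
    latent = f @ L.T + eps + sign * shift_vec
    items = np.digitize(latent, LIKERT_THRESHOLDS) + 1  # 1..5
    items_df = pd.DataFrame(items, columns=list(lam.index))
    scores_df = pd.DataFrame(f, columns=list(lam.columns))
    return items_df, scores_df


def generate_cohort(params: CohortParams | None = None) -> SyntheticCohort:
    """Generate a full synthetic cohort with ground truth.

    Counterbalancing is deterministic in participant index over the four
    cells of (condition order) x (cue assignment).
    """
    if params is None:
        params = CohortParams()
    rng_v = _spawn(params.seed, 1)  # vigilance
    rng_c = _spawn(params.seed, 2)  # counts
    rng_r = _spawn(params.seed, 3)  # report text
    rng_p = _spawn(params.seed, 4)  # probes
    rng_n = _spawn(params.seed, 5)  # rater noise
    rng_l = _spawn(params.seed, 6)  # latencies / session seeds

    vig_rows, sessions = [], []
    reports: list[ThoughtReport] = []
    annotations: list[Annotation] = []
    truth_inc_rows, truth_comp_rows, probe_rows, factor_rows = [], [], [], []

    lam = params.loading_matrix if params.loading_matrix is not None else default_loading_matrix()

    for i in range(params.n_recruited):
        pid = f"P{i + 1:04d}"
        compliant = bool(rng_v.random() < params.p_compliant)
        truth_comp_rows.append({"participant_id": pid, "compliant": compliant})
        if compliant:
            hyp_level = VigilanceLevel.FULLY_ASLEEP if rng_v.random() < 0.4 else VigilanceLevel.HALF_ASLEEP
            fmt_level = VigilanceLevel.DID_NOT_SLEEP
        else:
            # a non-compliant participant fails at least one criterion
            mode = rng_v.integers(3)
            hyp_level = VigilanceLevel.DID_NOT_SLEEP if mode in (0, 2) else VigilanceLevel.HALF_ASLEEP
            fmt_level = (
                VigilanceLevel.HALF_ASLEEP if mode in (1, 2) else VigilanceLevel.DID_NOT_SLEEP
            )
        vig_rows.append({"participant_id": pid, "condition": "hypnagogia", "level": hyp_level.value})
        vig_rows.append({"participant_id": pid, "condition": "fmt", "level": fmt_level.value})
        if not compliant:
            continue

        # counterbalancing: 4 cells over (order, cue assignment)
        cell = i % 4
        cond_order = (
            (Condition.HYPNAGOGIA, Condition.FMT) if cell % 2 == 0 else (Condition.FMT, Condition.HYPNAGOGIA)
        )
        cue_first = CueObject.FORK if cell < 2 else CueObject.TREE
        cue_second = CueObject.TREE if cue_first == CueObject.FORK else CueObject.FORK
        cues = {cond_order[0]: cue_first, cond_order[1]: cue_second}

        for cond in cond_order:
            cue = cues[cond]
            uncued = CueObject.TREE if cue == CueObject.FORK else CueObject.FORK
            sessions.append(
                SessionConfig(
                    participant_id=pid,
                    condition=cond,
                    cue_object=cue,
                    latency_min_s=params.latency_min_s,
                    latency_max_s=params.latency_max_s,
                    rng_seed=int(rng_l.integers(2**31 - 1)),
                )
            )
            d, ind = _planted_counts(rng_c, params)
            ud = int(rng_c.poisson(params.uncued_rate))
            ui = int(rng_c.poisson(params.uncued_rate))
            text = _report_text(rng_r, cue, d, ind, uncued, ud, ui)
            reports.append(ThoughtReport(pid, cond, cue, text))
            truth_inc_rows.append(
                {
                    "participant_id": pid,
                    "condition": cond.value,
                    "cue_object": cue.value,
                    "direct_cued": d,
                    "indirect_cued": ind,
                    "direct_uncued": ud,
                    "indirect_uncued": ui,
                }
            )
            counts = {
                f"direct_{cue.value.lower()}": d,
                f"indirect_{cue.value.lower()}": ind,
                f"direct_{uncued.value.lower()}": ud,
                f"indirect_{uncued.value.lower()}": ui,
            }
            annotations.append(
                Annotation(rater_id="R1", participant_id=pid, condition=cond, cue_object=cue, **counts)
            )
            noisy = {
                key: max(0, val + int(np.round(rng_n.normal(0.0, params.rater2_noise_sd))))
                if params.rater2_noise_sd > 0
                else val
                for key, val in counts.items()
            }
            annotations.append(
                Annotation(rater_id="R2", participant_id=pid, condition=cond, cue_object=cue, **noisy)
            )

    compliance = pd.DataFrame(truth_comp_rows)
    compliant_ids = compliance.loc[compliance["compliant"], "participant_id"].tolist()
    n_comp = len(compliant_ids)

    for cond in ("hypnagogia", "fmt"):
        items_df, scores_df = generate_probe_data(params, n_comp, rng_p, condition=cond)
        p_spont = params.p_spontaneous[cond]
        tprobs = params.temporality_probs[cond]
        intent = np.where(rng_p.random(n_comp) < p_spont, "spontaneous", "deliberate")
        temp_idx = rng_p.choice(4, size=n_comp, p=tprobs)
        temp = np.array(["none", "past", "present", "future"])[temp_idx]
        for j, pid in enumerate(compliant_ids):
            probe_rows.append(
                {
                    "participant_id": pid,
                    "condition": cond,
                    **{it: int(items_df.iloc[j][it]) for it in LIKERT_ITEMS},
                    "intentionality": str(intent[j]),
                    "temporality": str(temp[j]),
                }
            )
            factor_rows.append(
                {"participant_id": pid, "condition": cond, **scores_df.iloc[j].to_dict()}
            )

    truth = GroundTruth(
        compliance=compliance,
        incorporations=pd.DataFrame(truth_inc_rows),
        factor_scores=pd.DataFrame(factor_rows),
        params=params,
    )
    return SyntheticCohort(
        sessions=sessions,
        vigilance=pd.DataFrame(vig_rows),
        reports=reports,
        annotations=annotations,
        probes=pd.DataFrame(probe_rows),
        truth=truth,
    )


def write_cohort(cohort: SyntheticCohort, outdir) -> None:
    """Write every product as delimited text in the formats the analysis
    readers consume."""
    from .incorporation import write_annotations

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "participant_id": s.participant_id,
                "condition": s.condition.value,
                "cue_object": s.cue_object.value,
                "latency_min_s": s.latency_min_s,
                "latency_max_s": s.latency_max_s,
                "dwell_s": s.dwell_s,
                "n_trials": s.n_trials,
                "report_s": s.report_s,
                "return_s": s.return_s,
                "rng_seed": s.rng_seed,
            }
            for s in cohort.sessions
        ]
    ).to_csv(out / "sessions.csv", index=False)
    cohort.vigilance.to_csv(out / "vigilance.csv", index=False)
    pd.DataFrame(
        [
            {
                "participant_id": r.participant_id,
                "condition": r.condition.value,
                "cue_object": r.cue_object.value,
                "text": r.text,
            }
            for r in cohort.reports
        ]
    ).to_csv(out / "reports.csv", index=False)
    write_annotations(cohort.annotations, out / "annotations.csv")
    cohort.probes.to_csv(out / "probes.csv", index=False)
    cohort.truth.compliance.to_csv(out / "truth_compliance.csv", index=False)
    cohort.truth.incorporations.to_csv(out / "truth_incorporations.csv", index=False)
    cohort.truth.factor_scores.to_csv(out / "truth_factor_scores.csv", index=False)
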