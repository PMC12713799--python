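"""Cue-incorporation scoring and its statistics.

Two raters count, per report, direct incorporations of the cue (literal
mentions, e.g. "I dreamed of becoming a tree") and indirect ones (semantic
associates, e.g. "watering big plants").  This module tallies those counts
across a cohort, quantifies inter-rater agreement (Pearson r on counts,
Cohen's kappa on presence/absence labels, paired t on totals), tests
whether cued content dominates uncued content (fully within-subject
factorial contrasts), and compares incorporation *rates* (the share of
participants with at least one cued incorporation) against chance and
between cohorts with Pearson chi-square tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import cohen_kappa_score

from .session import Condition, CueObject

__all__ = [
    "Annotation",
    "IncorporationTable",
    "AgreementResult",
    "tally",
    "any_incorporation_rate",
    "chisq_vs_chance",
    "chisq_two_proportions",
    "agreement",
    "within_subject_anova",
    "corr_with_probes",
    "read_annotations",
    "write_annotations",
]

COUNT_COLUMNS = ("direct_fork", "indirect_fork", "direct_tree", "indirect_tree")


@dataclass(frozen=True)
class Annotation:
    """One rater's incorporation counts for one report
    (participant x condition)."""

    rater_id: str
    participant_id: str
    condition: Condition
    cue_object: CueObject
    direct_fork: int = 0
    indirect_fork: int = 0
    direct_tree: int = 0
    indirect_tree: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "condition", Condition(self.condition))
        object.__setattr__(self, "cue_object", CueObject(self.cue_object))
        for col in COUNT_COLUMNS:
            v = getattr(self, col)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"{col} must be a non-negative integer, got {v!r}")

    def count(self, content: CueObject, kind: Literal["direct", "indirect"]) -> int:
        return getattr(self, f"{kind}_{CueObject(content).value.lower()}")

    def cued_total(self) -> int:
        return self.count(self.cue_object, "direct") + self.count(self.cue_object, "indirect")

    def uncued_total(self) -> int:
        other = CueObject.TREE if self.cue_object == CueObject.FORK else CueObject.FORK
        return self.count(other, "direct") + self.count(other, "indirect")

    def total(self) -> int:
        return sum(getattr(self, c) for c in COUNT_COLUMNS)


@dataclass(frozen=True)
class IncorporationTable:
    """Cell means and SDs across participants, indexed by
    (cue session, incorporation content, incorporation type)."""

    cells: pd.DataFrame  # columns: cue, content, type, mean, sd, n

    def cell(self, cue: CueObject, content: CueObject, kind: str) -> tuple[float, float]:
        m = self.cells
        row = m[
            (m["cue"] == CueObject(cue).value)
            & (m["content"] == CueObject(content).value)
            & (m["type"] == kind)
        ]
        if row.empty:
            raise KeyError((cue, content, kind))
        return float(row["mean"].iloc[0]), float(row["sd"].iloc[0])


@dataclass(frozen=True)
class AgreementResult:
    pearson_r: float
    pearson_p: float
    kappa: float
    paired_t: float
    paired_t_df: int
    paired_t_p: float
    n_units: int


def _to_frame(annotations: Iterable[Annotation]) -> pd.DataFrame:
    rows = []
    for a in annotations:
        rows.append(
            {
                "rater_id": a.rater_id,
                "participant_id": a.participant_id,
                "condition": a.condition.value,
                "cue_object": a.cue_object.value,
                **{c: getattr(a, c) for c in COUNT_COLUMNS},
                "cued_total": a.cued_total(),
                "uncued_total": a.uncued_total(),
                "total": a.total(),
            }
        )
    return pd.DataFrame(rows)


def tally(annotations: Sequence[Annotation]) -> IncorporationTable:
    """Cell means/SDs across participants for every
    (cue session) x (content) x (type) combination.

    Raises on duplicate (rater, participant, condition) keys.
    """
    df = _to_frame(annotations)
    if df.empty:
        raise ValueError("no annotations")
    keys = df[["rater_id", "participant_id", "condition"]]
    if keys.duplicated().any():
        dup = keys[keys.duplicated()].iloc[0].tolist()
        raise ValueError(f"duplicate annotation key: {dup}")
    records = []
    for cue in CueObject:
        sub = df[df["cue_object"] == cue.value]
        for content in CueObject:
            for kind in ("direct", "indirect"):
                col = f"{kind}_{content.value.lower()}"
                vals = sub[col].to_numpy(dtype=float)
                records.append(
                    {
                        "cue": cue.value,
                        "content": content.value,
                        "type": kind,
                        "relation": "cued" if content == cue else "uncued",
                        "mean": float(np.mean(vals)) if len(vals) else np.nan,
                        "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan,
                        "n": int(len(vals)),
                    }
                )
    return IncorporationTable(pd.DataFrame(records))


def any_incorporation_rate(
    annotations: Sequence[Annotation], scope: Condition | None = None
) -> tuple[int, int, float]:
    """(k, n, k/n): participants with at least one incorporation of their
    *cued* item (direct or indirect), optionally restricted to one
    condition.  Annotations must come from a single rater (or an upstream
    merge)."""
    df = _to_frame(annotations)
    if df.empty:
        raise ValueError("no annotations")
    if df["rater_id"].nunique() > 1:
        raise ValueError("rate is defined for one rater; filter or merge first")
    if scope is not None:
        df = df[df["condition"] == Condition(scope).value]
    if df.empty:
        raise ValueError(f"no annotations in scope {scope}")
    per_part = df.groupby("participant_id")["cued_total"].sum()
    k = int((per_part >= 1).sum())
    n = int(per_part.size)
    return k, n, k / n


def chisq_vs_chance(k: int, n: int, p0: float = 0.5) -> tuple[float, int, float]:
    """Pearson goodness-of-fit of ``k`` successes in ``n`` against a null
    proportion ``p0`` (no continuity correction).  Returns (chi2, df, p)."""
    if not (0.0 < p0 < 1.0):
        raise ValueError("p0 must be in (0, 1)")
    if n <= 0 or not (0 <= k <= n):
        raise ValueError("need 0 <= k <= n, n > 0")
    expected = np.array([n * p0, n * (1 - p0)])
    observed = np.array([k, n - k])
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, 1, p


def chisq_two_proportions(
    k1: int, n1: int, k2: int, n2: int
) -> tuple[float, int, float]:
    """Pearson chi-square on the 2x2 table comparing ``k1/n1`` with
    ``k2/n2`` (no continuity correction).  Returns (chi2, df, p)."""
    for k, n in ((k1, n1), (k2, n2)):
        if n <= 0 or not (0 <= k <= n):
            raise ValueError("need 0 <= k <= n, n > 0 in both groups")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("a zero margin makes the test undefined")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


def agreement(
    r1: Sequence[Annotation],
    r2: Sequence[Annotation],
    unit_rule=None,
) -> AgreementResult:
    """Inter-rater agreement over matched (participant, condition) units.

    ``pearson_r`` and the paired t are computed on total counts per unit;
    kappa on the categorical labels derived by ``unit_rule`` (default:
    presence/absence of any cued incorporation in the report).
    """
    if unit_rule is None:
        unit_rule = lambda a: int(a.cued_total() >= 1)
    key = lambda a: (a.participant_id, a.condition.value)
    m1 = {key(a): a for a in r1}
    m2 = {key(a): a for a in r2}
    if len(m1) != len(r1) or len(m2) != len(r2):
        raise ValueError("duplicate units within a rater")
    shared = sorted(set(m1) & set(m2))
    if len(shared) < 3:
        raise ValueError(f"need >= 3 matched units, got {len(shared)}")
    t1 = np.array([m1[k].total() for k in shared], dtype=float)
    t2 = np.array([m2[k].total() for k in shared], dtype=float)
    lab1 = [unit_rule(m1[k]) for k in shared]
    lab2 = [unit_rule(m2[k]) for k in shared]
    r, rp = stats.pearsonr(t1, t2)
    if lab1 == lab2:
        kappa = 1.0  # cohen_kappa_score is NaN when only one label occurs
    else:
        kappa = float(cohen_kappa_score(lab1, lab2))
    if np.allclose(t1, t2):
        tt_stat, tt_p = 0.0, 1.0
    else:
        tt = stats.ttest_rel(t1, t2)
        tt_stat, tt_p = float(tt.statistic), float(tt.pvalue)
    return AgreementResult(
        pearson_r=float(r),
        pearson_p=float(rp),
        kappa=kappa,
        paired_t=tt_stat,
        paired_t_df=len(shared) - 1,
        paired_t_p=tt_p,
        n_units=len(shared),
    )


def within_subject_anova(
    cells: pd.DataFrame,
    factors: Sequence[str],
    value: str = "value",
    participant: str = "participant_id",
) -> pd.DataFrame:
    """Fully within-subject factorial ANOVA for up to three 2-level factors.

    Each main effect and interaction is evaluated through its signed
    contrast score per participant (the +-1 product coding of its factors
    applied to that participant's cell means); the F statistic is the
    square of the paired t on those scores, with df = (1, n-1) and
    partial eta^2 = F / (F + df_error).  For 2-level designs this is the
    exact classical repeated-measures ANOVA.
    """
    factors = list(factors)
    if not (1 <= len(factors) <= 3):
        raise ValueError("need 1..3 within factors")
    levels = {f: sorted(cells[f].unique()) for f in factors}
    for f, lv in levels.items():
        if len(lv) != 2:
            raise ValueError(f"factor {f!r} must have exactly 2 levels, has {lv}")
    n_cells = 2 ** len(factors)
    wide = cells.pivot_table(
        index=participant, columns=factors, values=value, aggfunc="mean"
    )
    if wide.isna().any().any() or wide.shape[1] != n_cells:
        raise ValueError("design must be complete: every participant needs every cell")
    results = []
    n = wide.shape[0]
    for k in range(1, len(factors) + 1):
        for effect in combinations(factors, k):
            signs = np.ones(wide.shape[1])
            for f in effect:
                idx = wide.columns.get_level_values(f) if len(factors) > 1 else wide.columns
                signs = signs * np.where(np.asarray(idx) == levels[f][0], 1.0, -1.0)
            scores = wide.to_numpy() @ signs / (n_cells / 2 ** len(effect))
            mean = scores.mean()
            se = scores.std(ddof=1) / np.sqrt(n)
            if se == 0:
                t = 0.0
                p = 1.0
            else:
                t = mean / se
                p = float(2 * stats.t.sf(abs(t), df=n - 1))
            F = t * t
            results.append(
                {
                    "effect": ":".join(effect),
                    "F": F,
                    "df_num": 1,
                    "df_den": n - 1,
                    "p": p,
                    "partial_eta_sq": F / (F + (n - 1)) if F > 0 else 0.0,
                }
            )
    return pd.DataFrame(results)


def corr_with_probes(
    incorporation_counts: Sequence[float], probe_item_scores: Sequence[float]
) -> tuple[float, float]:
    """Pearson correlation (and two-sided p) between per-participant
    incorporation counts and a probe item's scores."""
    x = np.asarray(incorporation_counts, dtype=float)
    y = np.asarray(probe_item_scores, dtype=float)
    if x.shape != y.shape:
        raise ValueError("inputs must be matched per participant")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# I/O


def read_annotations(path) -> list[Annotation]:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype={c: int for c in COUNT_COLUMNS})
    return [
        Annotation(
            rater_id=str(r.rater_id),
            participant_id=str(r.participant_id),
            condition=Condition(r.condition),
            cue_object=CueObject(r.cue_object),
            direct_fork=int(r.direct_fork),
            indirect_fork=int(r.indirect_fork),
            direct_tree=int(r.direct_tree),
            indirect_tree=int(r.indirect_tree),
        )
        for r in df.itertuples()
    ]


def write_annotations(annotations: Sequence[Annotation], path) -> None:
    df = _to_frame(annotations)[
        ["rater_id", "participant_id", "condition", "cue_object", *COUNT_COLUMNS]
    ]
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df.to_csv(path, sep=sep, index=False)
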