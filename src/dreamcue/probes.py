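"""Thought-probe phenomenology statistics.

The 13-item probe battery (11 Likert items on thought content and
structure, one binary intentionality item, one 4-category temporality
item) is compared between the hypnagogia and freely-moving-thought
conditions with:

* paired two-sided t contrasts on the 11 Likert items (treated as
  continuous), plus logistic / multinomial condition contrasts for the
  two categorical items, all corrected as one family with the
  Benjamini-Hochberg step-up procedure;
* partial Pearson correlations over the Likert items (per condition)
  plus covariates, each pair controlling for every remaining variable,
  computed from the precision (inverse correlation) matrix;
* Horn-style parallel analysis under a common-factors model (squared
  multiple correlations on the reduced correlation diagonal) to choose a
  factor count, followed by an exploratory factor analysis with
  maximum-likelihood extraction and oblimin (gamma = 0) rotation.

Maximum-likelihood extraction profiles the loadings out of the Wishart
likelihood and optimizes the uniquenesses numerically (the classic
Lawley-Maxwell formulation); oblimin rotation uses the gradient-projection
algorithm.  Factor order (descending sum-of-squares loadings) and sign
(largest-magnitude loading positive) are normalized so output is
deterministic and comparable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests
import statsmodels.api as sm

__all__ = [
    "LIKERT_ITEMS",
    "ProbeResponse",
    "ContrastResult",
    "PartialCorrMatrix",
    "EFAResult",
    "paired_contrast",
    "bh_adjust",
    "binary_item_contrast",
    "multinomial_item_contrast",
    "contrast_table",
    "partial_correlations",
    "parallel_analysis",
    "efa",
    "substantial_loadings",
    "read_probe_table",
]

LIKERT_ITEMS = (
    "positive_valence",
    "negative_valence",
    "images",
    "words",
    "novelty",
    "freedom_of_flow",
    "topical_shifts",
    "meaningfulness",
    "current_concerns",
    "bizarreness",
    "emotionality",
)

INTENTIONALITY_LEVELS = ("deliberate", "spontaneous")
TEMPORALITY_LEVELS = ("none", "past", "present", "future")  # reference first


@dataclass(frozen=True)
class ProbeResponse:
    """One condition's 13-item record for one participant."""

    participant_id: str
    condition: str
    likert: dict  # item name -> int in 1..5
    intentionality: str
    temporality: str

    def __post_init__(self) -> None:
        missing = set(LIKERT_ITEMS) - set(self.likert)
        if missing:
            raise ValueError(f"missing Likert items: {sorted(missing)}")
        for k in LIKERT_ITEMS:
            v = self.likert[k]
            if v not in (1, 2, 3, 4, 5):
                raise ValueError(f"{k}={v!r} outside the 1..5 Likert scale")
        if self.intentionality not in INTENTIONALITY_LEVELS:
            raise ValueError(f"bad intentionality {self.intentionality!r}")
        if self.temporality not in TEMPORALITY_LEVELS:
            raise ValueError(f"bad temporality {self.temporality!r}")


@dataclass(frozen=True)
class ContrastResult:
    item: str
    estimate: Optional[float]  # hypnagogia - FMT mean difference; None for models
    raw_p: float
    bh_p: Optional[float] = None


# ---------------------------------------------------------------------------
# Item-level contrasts


def paired_contrast(
    item: str, data: pd.DataFrame, conditions: tuple[str, str] = ("hypnagogia", "fmt")
) -> ContrastResult:
    """Two-sided paired t contrast for a Likert item.

    ``data`` is long: one row per participant x condition with an ``item``
    column.  The estimate is mean(first condition - second condition).
    """
    wide = data.pivot(index="participant_id", columns="condition", values=item)
    for c in conditions:
        if c not in wide.columns:
            raise ValueError(f"condition {c!r} absent")
    wide = wide.dropna(subset=list(conditions))
    diffs = (wide[conditions[0]] - wide[conditions[1]]).to_numpy(dtype=float)
    if np.std(diffs, ddof=1) == 0:
        if np.allclose(diffs, 0):
            return ContrastResult(item=item, estimate=0.0, raw_p=1.0)
        raise ValueError("zero-variance non-zero differences")
    t = stats.ttest_rel(wide[conditions[0]], wide[conditions[1]])
    return ContrastResult(item=item, estimate=float(diffs.mean()), raw_p=float(t.pvalue))


def bh_adjust(raw_p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(raw_p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def binary_item_contrast(
    data: pd.DataFrame,
    item: str = "intentionality",
    positive: str = "spontaneous",
    condition_col: str = "condition",
    reference_condition: str = "fmt",
) -> dict:
    """Condition effect on a binary item via binomial logistic regression:
    likelihood-ratio test of the condition term against the intercept-only
    model, with the condition odds ratio.

    Complete separation is flagged; the odds ratio then falls back to the
    Haldane-Anscombe-corrected 2x2 table while the LRT (which stays finite
    as the G statistic of the table) is reported from the contingency
    likelihood.
    """
    y = (data[item] == positive).astype(int).to_numpy()
    cond = (data[condition_col] != reference_condition).astype(int).to_numpy()
    if len(np.unique(cond)) < 2:
        raise ValueError("both conditions must be present")
    table = np.array(
        [
            [np.sum((cond == 1) & (y == 1)), np.sum((cond == 1) & (y == 0))],
            [np.sum((cond == 0) & (y == 1)), np.sum((cond == 0) & (y == 0))],
        ],
        dtype=float,
    )
    separated = np.any(table == 0)
    if not separated:
        X = sm.add_constant(cond.astype(float))
        full = sm.Logit(y, X).fit(disp=0)
        null = sm.Logit(y, np.ones((len(y), 1))).fit(disp=0)
        chi2 = max(2.0 * (full.llf - null.llf), 0.0)
        odds_ratio = float(np.exp(full.params[1]))
    else:
        g, p_g, _, _ = stats.chi2_contingency(
            table + 0.0, correction=False, lambda_="log-likelihood"
        )
        chi2 = float(g)
        t = table + 0.5
        odds_ratio = float((t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0]))
    p = float(stats.chi2.sf(chi2, 1))
    return {
        "item": item,
        "chi2": float(chi2),
        "df": 1,
        "p": p,
        "odds_ratio": odds_ratio,
        "separated": bool(separated),
    }


def multinomial_item_contrast(
    data: pd.DataFrame,
    item: str = "temporality",
    reference_category: str = "none",
    condition_col: str = "condition",
    reference_condition: str = "fmt",
) -> dict:
    """Condition effect on a polytomous item via a baseline-category
    multinomial logit.  Relative-risk ratios (exp of the condition
    coefficient) are reported per non-reference category, both as ratios
    and as percent change; the model p is the LRT of the condition term.
    Empty categories are dropped with a warning entry."""
    values = data[item].astype(str)
    counts = values.value_counts()
    if counts.get(reference_category, 0) == 0:
        raise ValueError(f"reference category {reference_category!r} is empty")
    dropped = [c for c in values.unique() if counts[c] == 0]
    cats = [reference_category] + sorted(
        c for c in counts.index if c != reference_category and counts[c] > 0
    )
    codes = pd.Categorical(values, categories=cats).codes
    keep = codes >= 0
    cond = (data[condition_col] != reference_condition).astype(float).to_numpy()[keep]
    ycod = codes[keep]
    X = sm.add_constant(cond)
    full = sm.MNLogit(ycod, X).fit(disp=0, maxiter=200)
    null = sm.MNLogit(ycod, np.ones((len(ycod), 1))).fit(disp=0, maxiter=200)
    chi2 = max(2.0 * (full.llf - null.llf), 0.0)
    df = len(cats) - 1
    rrr = {}
    coefs = np.asarray(full.params)
    for j, cat in enumerate(cats[1:]):
        beta = float(coefs[1, j])
        rrr[cat] = {
            "rrr": float(np.exp(beta)),
            "percent_change": float((np.exp(beta) - 1.0) * 100.0),
        }
    return {
        "item": item,
        "chi2": float(chi2),
        "df": df,
        "p": float(stats.chi2.sf(chi2, df)),
        "reference_category": reference_category,
        "rrr": rrr,
        "dropped_categories": dropped,
    }


def contrast_table(
    data: pd.DataFrame, conditions: tuple[str, str] = ("hypnagogia", "fmt")
) -> pd.DataFrame:
    """The full 13-item family: 11 paired t contrasts plus the binary and
    multinomial model contrasts, BH-corrected together.  Returns a tidy
    table sorted by raw p."""
    rows = []
    for item in LIKERT_ITEMS:
        c = paired_contrast(item, data, conditions)
        rows.append({"item": item, "estimate": c.estimate, "raw_p": c.raw_p})
    b = binary_item_contrast(data, reference_condition=conditions[1])
    rows.append({"item": "intentionality", "estimate": np.nan, "raw_p": b["p"]})
    m = multinomial_item_contrast(data, reference_condition=conditions[1])
    rows.append({"item": "temporality", "estimate": np.nan, "raw_p": m["p"]})
    out = pd.DataFrame(rows)
    out["bh_p"] = bh_adjust(out["raw_p"].to_numpy())
    return out.sort_values("raw_p", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Partial correlations


@dataclass(frozen=True)
class PartialCorrMatrix:
    variables: tuple[str, ...]
    r: pd.DataFrame  # symmetric, unit diagonal
    p: pd.DataFrame  # two-sided, NaN diagonal
    n: int


def partial_correlations(data: pd.DataFrame, variables: Sequence[str] | None = None) -> PartialCorrMatrix:
    """Pairwise partial Pearson correlations, each controlling for every
    other variable, from the inverse correlation (precision) matrix:
    r_ij = -P_ij / sqrt(P_ii P_jj).

    Two-sided p-values use the t approximation with df = n - k where k is
    the number of variables (2 of interest + k-2 controls).
    """
    if variables is None:
        variables = list(data.columns)
    X = data[list(variables)].dropna().to_numpy(dtype=float)
    n, k = X.shape
    if n <= k:
        raise ValueError(f"need more observations ({n}) than variables ({k})")
    R = np.corrcoef(X, rowvar=False)
    if not np.all(np.isfinite(R)):
        raise ValueError("constant variable: correlation undefined")
    try:
        P = np.linalg.inv(R)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular correlation matrix") from exc
    d = np.sqrt(np.outer(np.diag(P), np.diag(P)))
    pr = -P / d
    np.fill_diagonal(pr, 1.0)
    pr = np.clip((pr + pr.T) / 2.0, -1.0, 1.0)
    df = n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = pr * np.sqrt(df / (1.0 - pr**2))
    pv = 2.0 * stats.t.sf(np.abs(tstat), df)
    np.fill_diagonal(pv, np.nan)
    idx = list(variables)
    return PartialCorrMatrix(
        variables=tuple(idx),
        r=pd.DataFrame(pr, index=idx, columns=idx),
        p=pd.DataFrame(pv, index=idx, columns=idx),
        n=n,
    )


# ---------------------------------------------------------------------------
# Parallel analysis and EFA


def _reduced_eigenvalues(R: np.ndarray) -> np.ndarray:
    """Eigenvalues of the correlation matrix with squared multiple
    correlations (SMC) on the diagonal — the common-factors reduction."""
    try:
        Rinv = np.linalg.inv(R)
    except np.linalg.LinAlgError:
        # smooth a non-invertible correlation matrix
        w, V = np.linalg.eigh(R)
        w = np.maximum(w, 1e-8)
        R = V @ np.diag(w) @ V.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
        Rinv = np.linalg.inv(R)
    smc = 1.0 - 1.0 / np.diag(Rinv)
    Rr = R.copy()
    np.fill_diagonal(Rr, smc)
    return np.sort(np.linalg.eigvalsh(Rr))[::-1]


def parallel_analysis(
    data: pd.DataFrame | np.ndarray,
    n_iter: int = 200,
    seed: int | np.random.Generator = 0,
    criterion: Literal["mean", "p95"] = "mean",
) -> int:
    """Suggested common-factor count: the number of leading eigenvalues of
    the SMC-reduced observed correlation matrix exceeding the mean (or
    95th percentile) of reduced eigenvalues from ``n_iter`` random normal
    datasets of the same shape."""
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100 for a stable reference")
    X = np.asarray(data, dtype=float)
    n, p = X.shape
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    obs = _reduced_eigenvalues(np.corrcoef(X, rowvar=False))
    rand = np.empty((n_iter, p))
    for i in range(n_iter):
        Z = rng.standard_normal((n, p))
        rand[i] = _reduced_eigenvalues(np.corrcoef(Z, rowvar=False))
    ref = rand.mean(axis=0) if criterion == "mean" else np.percentile(rand, 95, axis=0)
    k = 0
    for o, r in zip(obs, ref):
        if o > r:
            k += 1
        else:
            break
    return k


def _ml_objective(log_psi: np.ndarray, R: np.ndarray, k: int) -> float:
    psi = np.exp(log_psi)
    sc = 1.0 / np.sqrt(psi)
    Rs = R * np.outer(sc, sc)
    lam = np.sort(np.linalg.eigvalsh(Rs))[::-1]
    tail = lam[k:]
    tail = np.maximum(tail, 1e-12)
    return float(np.sum(tail - np.log(tail) - 1.0))


def _ml_loadings(psi: np.ndarray, R: np.ndarray, k: int) -> np.ndarray:
    sc = 1.0 / np.sqrt(psi)
    Rs = R * np.outer(sc, sc)
    w, V = np.linalg.eigh(Rs)
    order = np.argsort(w)[::-1]
    w, V = w[order[:k]], V[:, order[:k]]
    load = V * np.sqrt(np.maximum(w - 1.0, 0.0))
    return (np.sqrt(psi)[:, None]) * load


def _quartimin(L: np.ndarray) -> tuple[float, np.ndarray]:
    """Oblimin (gamma = 0) criterion value and gradient."""
    L2 = L**2
    k = L.shape[1]
    N = np.ones((k, k)) - np.eye(k)
    f = float(np.sum(L2 * (L2 @ N)) / 4.0)
    G = L * (L2 @ N)
    return f, G


def _gpa_oblique(
    A: np.ndarray, maxiter: int = 1000, tol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Gradient-projection oblique rotation of the loading matrix ``A``
    minimizing the quartimin criterion.  Returns (pattern, factor
    correlation matrix, converged)."""
    k = A.shape[1]
    T = np.eye(k)
    Ti = np.linalg.inv(T)
    L = A @ Ti.T
    f, Gq = _quartimin(L)
    G = -(L.T @ Gq @ Ti).T
    al = 1.0
    converged = False
    for _ in range(maxiter):
        Gp = G - T @ np.diag(np.sum(T * G, axis=0))
        s = np.linalg.norm(Gp)
        if s < tol:
            converged = True
            break
        al *= 2.0
        for _ in range(60):
            X = T - al * Gp
            v = 1.0 / np.sqrt(np.sum(X**2, axis=0))
            Tt = X @ np.diag(v)
            Ti = np.linalg.inv(Tt)
            L = A @ Ti.T
            ft, Gq = _quartimin(L)
            if ft < f - 0.5 * s**2 * al:
                break
            al /= 2.0
        T = Tt
        f = ft
        G = -(L.T @ Gq @ Ti).T
    Phi = T.T @ T
    return L, Phi, converged


@dataclass(frozen=True)
class EFAResult:
    loadings: pd.DataFrame  # pattern matrix, items x factors
    communalities: pd.Series  # h^2 per item
    uniquenesses: pd.Series
    factor_correlations: pd.DataFrame
    ss_loadings: pd.Series
    proportion_var: pd.Series
    cumulative_var: pd.Series
    proportion_explained: pd.Series
    cumulative_proportion: pd.Series
    n_factors: int
    n_obs: int
    objective: float
    converged: bool
    heywood: bool


def efa(
    data: pd.DataFrame,
    n_factors: int,
    rotation: Literal["oblimin", "none"] = "oblimin",
) -> EFAResult:
    """Exploratory factor analysis: maximum-likelihood extraction on the
    correlation matrix, oblimin (gamma = 0) rotation.

    Factors are ordered by descending sum-of-squares loadings and
    sign-normalized (largest-magnitude loading positive).  Communalities
    exceeding 1 - 1e-3 flag a Heywood case.
    """
    items = list(data.columns)
    X = data.dropna().to_numpy(dtype=float)
    n, p = X.shape
    if not (1 <= n_factors <= (p - 1) // 2 + 1):
        # Lederman-style admissibility guard: need positive df or a
        # just-identified model
        max_k = (p - 1) // 2 + 1
        raise ValueError(f"n_factors must be in 1..{max_k} for {p} items")
    R = np.corrcoef(X, rowvar=False)
    if not np.all(np.isfinite(R)):
        raise ValueError("constant item: correlation matrix undefined")
    # start at the classic heuristic (1 - k/(2p)) / diag(R^-1)
    start = (1.0 - 0.5 * n_factors / p) / np.diag(np.linalg.inv(R))
    start = np.clip(start, 0.005, 1.0)
    res = optimize.minimize(
        _ml_objective,
        np.log(start),
        args=(R, n_factors),
        method="L-BFGS-B",
        bounds=[(np.log(0.005), np.log(1.0))] * p,
        options={"maxiter": 1000, "ftol": 1e-12, "gtol": 1e-9},
    )
    psi = np.exp(res.x)
    A = _ml_loadings(psi, R, n_factors)  # unrotated (orthogonal) loadings
    h2 = np.sum(A**2, axis=1)
    heywood = bool(np.any(h2 > 1.0 - 1e-3))
    if rotation == "oblimin" and n_factors > 1:
        L, Phi, rot_ok = _gpa_oblique(A)
    else:
        L, Phi, rot_ok = A.copy(), np.eye(n_factors), True
    if not (res.success or res.status == 0) and not np.isfinite(res.fun):
        raise RuntimeError(f"ML extraction failed: {res.message}")
    # sign convention: largest-magnitude loading of each factor positive
    for j in range(n_factors):
        i = np.argmax(np.abs(L[:, j]))
        if L[i, j] < 0:
            L[:, j] *= -1
            Phi[j, :] *= -1
            Phi[:, j] *= -1
    # order factors by descending SS loadings (oblique convention:
    # diag(Phi @ L' @ L))
    ss = np.diag(Phi @ L.T @ L)
    order = np.argsort(ss)[::-1]
    L = L[:, order]
    Phi = Phi[np.ix_(order, order)]
    ss = ss[order]
    names = [f"Factor{j + 1}" for j in range(n_factors)]
    prop = ss / p
    prop_expl = ss / ss.sum()
    return EFAResult(
        loadings=pd.DataFrame(L, index=items, columns=names),
        communalities=pd.Series(h2, index=items, name="h2"),
        uniquenesses=pd.Series(psi, index=items, name="uniqueness"),
        factor_correlations=pd.DataFrame(Phi, index=names, columns=names),
        ss_loadings=pd.Series(ss, index=names, name="ss_loadings"),
        proportion_var=pd.Series(prop, index=names, name="proportion_var"),
        cumulative_var=pd.Series(np.cumsum(prop), index=names, name="cumulative_var"),
        proportion_explained=pd.Series(prop_expl, index=names, name="proportion_explained"),
        cumulative_proportion=pd.Series(
            np.cumsum(prop_expl), index=names, name="cumulative_proportion"
        ),
        n_factors=n_factors,
        n_obs=n,
        objective=float(res.fun),
        converged=bool(res.success) and rot_ok,
        heywood=heywood,
    )


def substantial_loadings(result: EFAResult, threshold: float = 0.40) -> pd.DataFrame:
    """Boolean mask of loadings with |value| >= threshold (inclusive), with
    a ``cross_loading`` column marking items substantial on more than one
    factor."""
    mask = result.loadings.abs() >= threshold
    mask = mask.copy()
    mask["cross_loading"] = mask.sum(axis=1) > 1
    return mask


# ---------------------------------------------------------------------------
# I/O


def read_probe_table(path) -> pd.DataFrame:
    """Read the probe battery as a delimited table with columns
    participant_id, condition, the 11 Likert item columns, intentionality,
    temporality.  Validates ranges via ProbeResponse."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    needed = {"participant_id", "condition", *LIKERT_ITEMS, "intentionality", "temporality"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"probe table missing columns: {sorted(missing)}")
    for row in df.itertuples():
        ProbeResponse(
            participant_id=str(row.participant_id),
            condition=str(row.condition),
            likert={k: int(getattr(row, k)) for k in LIKERT_ITEMS},
            intentionality=str(row.intentionality),
            temporality=str(row.temporality),
        )
    return df
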