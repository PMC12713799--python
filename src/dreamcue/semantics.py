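"""Embedding-derived semantic structure of thought reports.

Two report-level measures:

* **prompt centrality** — the mean cosine similarity between each sentence
  of a (cue-word-filtered) report and the cue word itself, a proxy for how
  semantically close the reported thought content stays to the incubated
  theme;
* **temporal coherence** — the mean cosine similarity between consecutive
  sentence pairs (a width-2, stride-1 sliding window), a proxy for how
  smoothly content unfolds; defined only for reports with two or more
  sentences.

Both are embedder-agnostic averages.  The default backend is a
deterministic hashed token-count embedder (512 dimensions, fixed hash key)
so the whole pipeline is reproducible offline; a transformer
sentence-encoder backend can be plugged in through the same interface
when its runtime is available.

The measures are related to report-level covariates with linear
mixed models (random intercept per participant, ML estimation) and
likelihood-ratio tests between nested fits.
"""

from __future__ import annotations

import hashlib
import re
import warnings
from abc import ABC, abstractmethod
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .corpus import SentenceSet, ThoughtReport, filter_prompt_words, segment_sentences
from .session import Condition, CueObject

__all__ = [
    "Embedder",
    "HashedTokenEmbedder",
    "UniversalSentenceEmbedder",
    "SemanticScores",
    "MixedModelFit",
    "cosine",
    "prompt_centrality",
    "temporal_coherence",
    "score_reports",
    "fit_random_intercept",
    "likelihood_ratio_test",
]


class Embedder(ABC):
    """A deterministic sentence -> fixed-dimension vector mapping."""

    name: str
    dimension: int

    @abstractmethod
    def embed(self, sentence: str) -> np.ndarray: ...

    def embed_many(self, sentences: Sequence[str]) -> np.ndarray:
        return np.stack([self.embed(s) for s in sentences])


class HashedTokenEmbedder(Embedder):
    """Token-count vectors via a keyed 64-bit hash into a fixed number of
    buckets.  Deterministic across runs and platforms; all components are
    non-negative, so cosine similarities lie in [0, 1]."""

    def __init__(self, dimension: int = 512, hash_key: bytes = b"dreamcue-v1"):
        self.name = f"hashed-token-{dimension}"
        self.dimension = dimension
        self._key = hash_key

    def _bucket(self, token: str) -> int:
        h = hashlib.blake2b(token.encode("utf-8"), key=self._key, digest_size=8)
        return int.from_bytes(h.digest(), "big") % self.dimension

    def tokens(self, sentence: str) -> list[str]:
        return re.findall(r"[a-z0-9']+", sentence.lower())

    def embed(self, sentence: str) -> np.ndarray:
        vec = np.zeros(self.dimension)
        for tok in self.tokens(sentence):
            vec[self._bucket(tok)] += 1.0
        return vec


class UniversalSentenceEmbedder(Embedder):
    """Transformer sentence-encoder backend (512-d).  Requires the optional
    ``tensorflow_hub`` runtime; constructing it without that installed
    raises ImportError."""

    MODULE_URL = "https://tfhub.dev/google/universal-sentence-encoder-large/5"

    def __init__(self, module_url: str | None = None):
        try:
            import tensorflow_hub as hub  # type: ignore
        except ImportError as exc:  # pragma: no cover - optional backend
            raise ImportError(
                "the transformer sentence-encoder backend needs tensorflow_hub; "
                "install it or use the default HashedTokenEmbedder"
            ) from exc
        self._model = hub.load(module_url or self.MODULE_URL)  # pragma: no cover
        self.name = "universal-sentence-encoder"  # pragma: no cover
        self.dimension = 512  # pragma: no cover

    def embed(self, sentence: str) -> np.ndarray:  # pragma: no cover
        return np.asarray(self._model([sentence])[0])


def get_embedder(name: str = "fallback") -> Embedder:
    if name in ("fallback", "hashed"):
        return HashedTokenEmbedder()
    if name == "use":
        return UniversalSentenceEmbedder()
    raise ValueError(f"unknown embedder backend {name!r}")


# ---------------------------------------------------------------------------
# Similarity measures


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity dot(u, v) / (|u| |v|), clipped to [-1, 1].

    A zero vector signals a degenerate embedding and raises.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine undefined for a zero vector")
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))


def prompt_centrality(
    s: SentenceSet, cue_word: str, embedder: Embedder
) -> Optional[float]:
    """Mean cosine similarity of each sentence to the (bare, lowercase)
    cue word.  The sentence set is expected to be cue-word-filtered
    already.  Returns None for an empty sentence set."""
    if len(s) == 0:
        return None
    cue_vec = embedder.embed(cue_word.lower())
    sims = [cosine(embedder.embed(sent), cue_vec) for sent in s]
    return float(np.mean(sims))


def temporal_coherence(s: SentenceSet, embedder: Embedder) -> Optional[float]:
    """Mean cosine similarity of consecutive sentence pairs; None (missing)
    for reports with fewer than two sentences."""
    if len(s) < 2:
        return None
    vecs = embedder.embed_many(list(s))
    sims = [cosine(vecs[i], vecs[i + 1]) for i in range(len(s) - 1)]
    return float(np.mean(sims))


@dataclass(frozen=True)
class SemanticScores:
    participant_id: str
    condition: Condition
    cue_object: CueObject
    prompt_centrality: Optional[float]
    temporal_coherence: Optional[float]
    n_sentences: int


def score_reports(
    reports: Sequence[ThoughtReport], embedder: Embedder | None = None
) -> pd.DataFrame:
    """Full per-report pipeline: segment -> filter cue words -> centrality
    and coherence.  Returns a tidy table (one row per report)."""
    if embedder is None:
        embedder = HashedTokenEmbedder()
    rows = []
    for rep in reports:
        sents = filter_prompt_words(segment_sentences(rep.text, rep), rep.cue_object)
        pc = prompt_centrality(sents, rep.cue_object.value.lower(), embedder)
        tc = temporal_coherence(sents, embedder)
        rows.append(
            {
                "participant_id": rep.participant_id,
                "condition": rep.condition.value,
                "cue_object": rep.cue_object.value,
                "prompt_centrality": pc,
                "temporal_coherence": tc,
                "n_sentences": len(sents),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Mixed models


@dataclass(frozen=True)
class MixedModelFit:
    """A random-intercept linear mixed model fitted by maximum likelihood."""

    formula: str
    params: pd.Series
    bse: pd.Series
    group_var: float
    llf: float
    n_obs: int
    n_groups: int
    df_model: int  # number of fixed-effect parameters

    def __getitem__(self, term: str) -> float:
        return float(self.params[term])


def fit_random_intercept(
    data: pd.DataFrame, formula: str, groups: str = "participant_id"
) -> MixedModelFit:
    """Fit ``formula`` with a random intercept for ``groups`` by maximum
    likelihood (ML, not REML, so nested fixed-effect fits are comparable
    with likelihood-ratio tests).  Rows with missing model variables are
    dropped listwise."""
    cols = set(re.findall(r"[A-Za-z_][A-Za-z0-9_]*", formula)) & set(data.columns)
    sub = data.dropna(subset=sorted(cols | {groups}))
    if sub[groups].nunique() < 2:
        raise ValueError("need at least 2 groups for a random intercept")
    with warnings.catch_warnings():
        # boundary (zero) variance estimates are legitimate here
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, sub, groups=sub[groups])
        try:
            fit = model.fit(reml=False)
        except np.linalg.LinAlgError:
            fit = model.fit(reml=False, method="powell")
    if not np.isfinite(fit.llf):
        raise ValueError("mixed model fit failed: non-finite log-likelihood")
    return MixedModelFit(
        formula=formula,
        params=fit.fe_params,
        bse=fit.bse_fe,
        group_var=float(np.asarray(fit.cov_re)[0, 0]),
        llf=float(fit.llf),
        n_obs=int(fit.nobs),
        n_groups=int(sub[groups].nunique()),
        df_model=len(fit.fe_params),
    )


def likelihood_ratio_test(
    full: MixedModelFit, reduced: MixedModelFit, tol: float = 1e-6
) -> tuple[float, int, float]:
    """LRT between nested ML fits: chi2 = 2(llf_full - llf_reduced),
    df = difference in fixed-effect parameter counts."""
    df = full.df_model - reduced.df_model
    if df < 0:
        raise ValueError("reduced model must be nested in (smaller than) full")
    delta = full.llf - reduced.llf
    if delta < -tol:
        raise ValueError(
            f"full model log-likelihood below reduced ({delta:.3g}); fit failure"
        )
    chi2 = max(2.0 * delta, 0.0)
    if df == 0:
        # identical model structures: nothing to test
        return chi2, 0, 1.0
    return chi2, df, float(stats.chi2.sf(chi2, df))
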