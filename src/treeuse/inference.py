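"""AICc multimodel inference over candidate tree-use models.

The candidate set is every subset of the main-effect predictors (tree
size, canopy cover, leaf nitrogen, connectivity, height), with the leaf-N
x connectivity interaction added only to subsets containing both parents.
Each candidate is fitted as a log-link GLMM with an animal-level random
intercept — Poisson for visit counts, Gamma for residence time and
time-to-return — and ranked by the small-sample Akaike information
criterion

    AICc = -2 logL + 2k + 2k(k+1) / (n - k - 1).

Akaike weights follow, the confidence set keeps models with delta AICc
strictly below a threshold (default 2), and coefficients are model-
averaged across that set.  "Natural" (conditional) averaging — each term
averaged over the models that contain it, with weights renormalized over
those models — is the default; "full" averaging substitutes zero for
absent terms.  Unconditional standard errors combine within-model SEs and
between-model spread:

    SE_t = sum_i w_i * sqrt(se_it^2 + (b_it - b_bar_t)^2).

Continuous predictors are standardized (mean 0, SD 1) before fitting so
estimates are comparable across terms; the ordinal cover category is coded
{low: 0, medium: 1, high: 2} and then standardized like the rest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .glmm import fit_glmm

__all__ = [
    "ModelRecord",
    "AveragedEstimate",
    "aicc",
    "akaike_weights",
    "confidence_set",
    "model_average",
    "build_candidate_set",
    "standardize_predictors",
    "fit_tree_use_model",
    "fit_candidate_set",
    "rank_models",
]

DEFAULT_PREDICTORS = ("dbh", "cover", "leaf_n", "connectivity", "height")
DEFAULT_INTERACTION = ("leaf_n", "connectivity")
COVER_CODES = {"low": 0, "medium": 1, "high": 2}


@dataclass
class ModelRecord:
    """One fitted candidate model with its information-theoretic summary."""

    terms: tuple[str, ...]
    response: str
    family: str
    loglik: float
    k: int
    n: int
    coefficients: dict[str, tuple[float, float]]
    converged: bool = True
    aicc: float = math.nan
    delta: float = math.nan
    weight: float = math.nan

    @property
    def formula(self) -> str:
        rhs = " + ".join(self.terms) if self.terms else "1"
        return f"{self.response} ~ {rhs}"


@dataclass
class AveragedEstimate:
    term: str
    estimate: float
    se: float
    n_models: int


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample-corrected AIC; requires n > k + 1."""
    if k < 0:
        raise ValueError("k must be non-negative")
    if n <= k + 1:
        raise ValueError(f"AICc needs n > k + 1 (got n={n}, k={k})")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aiccs) -> np.ndarray:
    """exp(-delta/2) weights, normalized to sum to one."""
    a = np.asarray(list(aiccs), float)
    if a.size == 0:
        raise ValueError("need at least one model")
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def rank_models(records: list[ModelRecord]) -> list[ModelRecord]:
    """Compute AICc, delta and weights; sort best-first.

    Non-converged records are excluded from ranking.  Ties in AICc break
    to the model with fewer parameters.
    """
    ok = [r for r in records if r.converged]
    if not ok:
        raise ValueError("no converged models to rank")
    for r in ok:
        r.aicc = aicc(r.loglik, r.k, r.n)
    ok.sort(key=lambda r: (r.aicc, r.k))
    best = ok[0].aicc
    weights = akaike_weights([r.aicc for r in ok])
    for r, w in zip(ok, weights):
        r.delta = r.aicc - best
        r.weight = float(w)
    return ok


def confidence_set(records: list[ModelRecord],
                   delta_threshold: float = 2.0) -> list[ModelRecord]:
    """Models with delta AICc strictly below the threshold (ranked input)."""
    return [r for r in records if r.delta < delta_threshold]


def model_average(records: list[ModelRecord], method: str = "natural",
                  include_intercept: bool = True) -> list[AveragedEstimate]:
    """Model-averaged coefficients over a (confidence) set of models.

    Weights are renormalized within the set.  With ``method="natural"``
    each term is averaged over the models containing it, re-renormalizing
    weights over those models; with ``method="full"`` absent terms
    contribute an estimate of 0 with SE 0.  The unconditional SE adds the
    between-model spread of estimates to the within-model SEs.
    """
    if method not in ("natural", "full"):
        raise ValueError("method must be 'natural' or 'full'")
    if not records:
        raise ValueError("empty model set")
    w = np.array([r.weight for r in records], float)
    w = w / w.sum()
    terms: list[str] = []
    for r in records:
        for t in r.coefficients:
            if t not in terms:
                terms.append(t)
    out = []
    for t in terms:
        if t == "const" and not include_intercept:
            continue
        present = np.array([t in r.coefficients for r in records])
        beta = np.array([r.coefficients[t][0] if p else 0.0
                         for r, p in zip(records, present)])
        se = np.array([r.coefficients[t][1] if p else 0.0
                       for r, p in zip(records, present)])
        if method == "natural":
            wt = w * present
            wt = wt / wt.sum()
        else:
            wt = w
        est = float(np.sum(wt * beta))
        use = wt > 0
        unc_se = float(np.sum(wt[use] * np.sqrt(se[use] ** 2
                                                + (beta[use] - est) ** 2)))
        out.append(AveragedEstimate(term=t, estimate=est, se=unc_se,
                                    n_models=int(present.sum())))
    return out


def build_candidate_set(predictors=DEFAULT_PREDICTORS,
                        interaction: tuple[str, str] | None =
                        DEFAULT_INTERACTION) -> list[tuple[str, ...]]:
    """All main-effect subsets, plus interaction-augmented versions.

    Includes the intercept-only model (empty tuple).  The interaction term
    ``"a:b"`` is added (as an extra candidate) only to subsets containing
    both parents, preserving marginality.
    """
    predictors = tuple(predictors)
    if len(predictors) == 0:
        raise ValueError("need at least one predictor")
    subsets = [tuple(c) for r in range(len(predictors) + 1)
               for c in combinations(predictors, r)]
    out = list(subsets)
    if interaction is not None:
        a, b = interaction
        term = f"{a}:{b}"
        for s in subsets:
            if a in s and b in s:
                out.append(s + (term,))
    return out


def standardize_predictors(table: pd.DataFrame,
                           columns=DEFAULT_PREDICTORS) -> pd.DataFrame:
    """Center/scale predictors to mean 0, SD 1 (cover coded 0/1/2 first).

    Standardization uses the whole table so every candidate model sees the
    same design columns.  Constant columns are left centered at zero.
    """
    out = table.copy()
    for col in columns:
        if col not in out.columns:
            continue
        vals = out[col]
        if vals.dtype == object or isinstance(vals.dtype, pd.CategoricalDtype):
            vals = vals.map(COVER_CODES)
            if vals.isna().any():
                raise ValueError(
                    f"column {col!r}: unknown category (expected "
                    f"{sorted(COVER_CODES)})")
        vals = vals.astype(float)
        sd = vals.std(ddof=0)
        out[col] = (vals - vals.mean()) / sd if sd > 0 else vals - vals.mean()
    return out


def _design_matrix(table: pd.DataFrame, terms: tuple[str, ...]
                   ) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(table))]
    names = ["const"]
    for t in terms:
        if ":" in t:
            a, b = t.split(":")
            cols.append(table[a].to_numpy(float) * table[b].to_numpy(float))
        else:
            cols.append(table[t].to_numpy(float))
        names.append(t)
    return np.column_stack(cols), names


_FAMILY_FOR_RESPONSE = {"revisits": "poisson", "rt": "gamma", "ttor": "gamma"}
_RESPONSE_COLUMNS = {"revisits": "n_visits", "rt": "mean_rt_h",
                     "ttor": "mean_ttor_h"}


def fit_tree_use_model(table: pd.DataFrame, response: str,
                       terms: tuple[str, ...], family: str | None = None,
                       group_col: str = "animal_id",
                       response_col: str | None = None,
                       n_nodes: int = 15) -> ModelRecord:
    """Fit one candidate GLMM on an analysis table.

    ``table`` must hold the (already standardized) predictor columns, the
    grouping column, and the response column (defaulting per response:
    ``n_visits`` for revisits, ``mean_rt_h`` for rt, ``mean_ttor_h`` for
    ttor).  Rows with missing response or predictors are dropped.  ``k``
    counts the intercept, fixed-effect terms, the random-intercept
    variance, and (for Gamma) the shape parameter.
    """
    family = family or _FAMILY_FOR_RESPONSE.get(response)
    if family is None:
        raise ValueError(f"no default family for response {response!r}; "
                         "pass family=")
    response_col = response_col or _RESPONSE_COLUMNS.get(response, response)
    main_cols = sorted({p for t in terms for p in t.split(":")})
    needed = [response_col, group_col] + main_cols
    data = table.dropna(subset=needed)
    y = data[response_col].to_numpy(float)
    X, names = _design_matrix(data, terms)
    res = fit_glmm(y, X, data[group_col].to_numpy(), family=family,
                   n_nodes=n_nodes, exog_names=names)
    return ModelRecord(
        terms=tuple(terms), response=response, family=family,
        loglik=res.loglik, k=res.n_params, n=res.n_obs,
        coefficients=res.coefficients(), converged=res.converged)


def fit_candidate_set(table: pd.DataFrame, response: str,
                      candidates: list[tuple[str, ...]] | None = None,
                      predictors=DEFAULT_PREDICTORS,
                      interaction=DEFAULT_INTERACTION,
                      **fit_kwargs) -> list[ModelRecord]:
    """Fit and rank every candidate model for one response."""
    if candidates is None:
        candidates = build_candidate_set(predictors, interaction)
    records = [fit_tree_use_model(table, response, terms, **fit_kwargs)
               for terms in candidates]
    return rank_models(records)


def model_table(records: list[ModelRecord]) -> pd.DataFrame:
    """Ranked model table: formula, k, loglik, AICc, delta, weight."""
    return pd.DataFrame([{
        "formula": r.formula, "k": r.k, "n": r.n, "loglik": r.loglik,
        "aicc": r.aicc, "delta": r.delta, "weight": r.weight,
    } for r in records])


def averaged_table(estimates: list[AveragedEstimate]) -> pd.DataFrame:
    return pd.DataFrame([{
        "term": e.term, "estimate": e.estimate, "se": e.se,
        "n_models": e.n_models,
    } for e in estimates])
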