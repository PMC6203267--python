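"""Bayesian model averaging over linear models of a well-being measure.

Candidate predictors are binary or continuous features built from the
syndrome-group structure (similarity-partition indicators), CART-derived
covariate dichotomies, and their interactions.  Every admissible subset
of candidates defines a linear model (the intercept is always included);
the marginal likelihood of each model has a closed form under a Zellner
g-prior on the slopes with reference priors on the intercept and error
variance:

    y = alpha + X_M beta_M + eps,  eps ~ N(0, sigma^2 I)
    p(alpha) ∝ 1,  p(sigma^2) ∝ 1/sigma^2
    beta_M | sigma^2 ~ N(0, g sigma^2 (X_M' X_M)^{-1})   (X_M centered)

which gives

    log m(y | M) = lgamma((n-1)/2) - ((n-1)/2) log(pi) - (1/2) log n
                   - ((n-1)/2) log TSS
                   + ((n-1-k)/2) log(1+g) - ((n-1)/2) log(1 + g (1-R^2)).

With a uniform prior over admissible models, posterior model
probabilities are proportional to the marginal likelihoods; a
predictor's inclusion probability is the summed probability of models
containing it, and model-averaged coefficient moments follow from the
per-model posterior (a scaled-t with mean g/(1+g) times the OLS slope).
The default ``g = n`` is the unit-information prior.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from math import lgamma, log, pi
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["Candidate", "ModelSpec", "BMAResult", "log_marginal",
           "enumerate_models", "bma_fit", "make_candidates"]

log_ = logging.getLogger(__name__)

MAX_CANDIDATES = 20


@dataclass(frozen=True)
class Candidate:
    """One candidate predictor column.

    ``parents`` names the two main effects of an interaction term; the
    hierarchy rule only admits models containing both parents whenever
    the interaction is selected.
    """

    name: str
    values: np.ndarray
    parents: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


@dataclass(frozen=True)
class ModelSpec:
    """A subset of candidates, as a bit tuple over the candidate list."""

    included: tuple[bool, ...]

    @property
    def size(self) -> int:
        return sum(self.included)

    def names(self, candidates: Sequence[Candidate]) -> list[str]:
        return [c.name for c, on in zip(candidates, self.included) if on]


def enumerate_models(candidates: Sequence[Candidate],
                     hierarchy: bool = True) -> list[ModelSpec]:
    """All admissible candidate subsets (the null model included).

    With ``hierarchy`` on, an interaction may only appear alongside both
    of its parent main effects.
    """
    p = len(candidates)
    if p > MAX_CANDIDATES:
        raise ValueError(
            f"{p} candidates exceed the exhaustive-enumeration guard "
            f"({MAX_CANDIDATES}); reduce the candidate set (model-space "
            "sampling is out of scope)")
    names = [c.name for c in candidates]
    models = []
    for r in range(p + 1):
        for idx in combinations(range(p), r):
            chosen = set(idx)
            if hierarchy:
                ok = True
                for i in chosen:
                    par = candidates[i].parents
                    if par and not all(names.index(q) in chosen for q in par):
                        ok = False
                        break
                if not ok:
                    continue
            models.append(ModelSpec(tuple(i in chosen for i in range(p))))
    return models


def log_marginal(y: np.ndarray, X: np.ndarray | None, g: float,
                 names: Sequence[str] | None = None) -> float:
    """Closed-form log marginal likelihood of one model.

    ``X`` holds the selected slope columns (no intercept; ``None`` or
    zero columns for the null model).  Raises on a rank-deficient
    centered design, naming the offending columns.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    yc = y - y.mean()
    tss = float(yc @ yc)
    if tss <= 0:
        raise ValueError("response has zero variance")
    base = lgamma((n - 1) / 2) - ((n - 1) / 2) * log(pi) - 0.5 * log(n) \
        - ((n - 1) / 2) * log(tss)
    if X is None or X.size == 0 or X.shape[1] == 0:
        return base
    X = np.asarray(X, dtype=float)
    k = X.shape[1]
    if n <= k + 1:
        raise ValueError(f"n={n} too small for a model with {k} slopes")
    Xc = X - X.mean(axis=0)
    if np.linalg.matrix_rank(Xc) < k:
        lab = list(names) if names is not None else [f"col{j}" for j in range(k)]
        raise ValueError(f"rank-deficient design: columns {lab} are collinear "
                         "after centering")
    coef, _, _, _ = np.linalg.lstsq(Xc, yc, rcond=None)
    rss = float(np.sum((yc - Xc @ coef) ** 2))
    r2 = 1.0 - rss / tss
    return base + ((n - 1 - k) / 2) * log(1 + g) \
        - ((n - 1) / 2) * log(1 + g * (1 - r2))


@dataclass
class BMAResult:
    candidates: list[str]
    models: pd.DataFrame           # one row per model: terms, k, logml, prob
    inclusion: pd.Series           # per-candidate inclusion probability
    coef_mean: pd.Series           # model-averaged posterior mean per candidate
    coef_sd: pd.Series             # model-averaged posterior sd per candidate
    n: int = 0
    g: float = 0.0
    dropped: list[str] = field(default_factory=list)

    def top_models(self, k: int = 10) -> pd.DataFrame:
        return self.models.nlargest(k, "prob").reset_index(drop=True)


def _model_moments(yc: np.ndarray, Xc: np.ndarray, g: float) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean and variance of the slopes within one model."""
    n, k = Xc.shape
    q = g / (1.0 + g)
    XtX = Xc.T @ Xc
    bhat = np.linalg.solve(XtX, Xc.T @ yc)
    tss = float(yc @ yc)
    r2 = 1.0 - float(np.sum((yc - Xc @ bhat) ** 2)) / tss
    mean = q * bhat
    # sigma^2 | y ~ InvGamma((n-1)/2, s_g/2) with s_g = TSS (1 - q R^2)
    s_g = tss * (1.0 - q * r2)
    if n <= 3:
        raise ValueError("need n > 3 for finite posterior coefficient variance")
    var = q * (s_g / (n - 3)) * np.diag(np.linalg.inv(XtX))
    return mean, var


def bma_fit(y: np.ndarray, candidates: Sequence[Candidate],
            g_policy: str | float = "unit-information",
            hierarchy: bool = True) -> BMAResult:
    """Exhaustive Bayesian model averaging over the candidate set.

    A uniform prior over admissible models combines with the closed-form
    marginal likelihoods; rank-deficient models are dropped with a
    warning and probabilities renormalized.
    """
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(y)
    for c in candidates:
        if len(c.values) != len(y):
            raise ValueError(f"candidate {c.name!r} length mismatch")
        mask &= np.isfinite(c.values)
    y = y[mask]
    cand = [Candidate(c.name, c.values[mask], c.parents) for c in candidates]
    n = len(y)
    g = float(n) if g_policy == "unit-information" else float(g_policy)

    models = enumerate_models(cand, hierarchy=hierarchy)
    names = [c.name for c in cand]
    yc = y - y.mean()

    rows, kept, dropped = [], [], []
    for m in models:
        sel = [i for i, on in enumerate(m.included) if on]
        X = np.column_stack([cand[i].values for i in sel]) if sel else None
        label = "+".join(names[i] for i in sel) or "(null)"
        try:
            lml = log_marginal(y, X, g, names=[names[i] for i in sel])
        except ValueError as err:
            log_.warning("dropping model %s: %s", label, err)
            dropped.append(label)
            continue
        kept.append((m, sel, X))
        rows.append({"model": label, "k": len(sel), "logml": lml})

    table = pd.DataFrame(rows)
    w = np.exp(table["logml"].to_numpy() - table["logml"].max())
    w /= w.sum()
    table["prob"] = w

    incl = np.zeros(len(cand))
    avg_mean = np.zeros(len(cand))
    avg_m2 = np.zeros(len(cand))  # E[beta_j^2] across model space
    for (m, sel, X), prob in zip(kept, w):
        if not sel:
            continue
        Xc = X - X.mean(axis=0)
        mean, var = _model_moments(yc, Xc, g)
        for pos, j in enumerate(sel):
            incl[j] += prob
            avg_mean[j] += prob * mean[pos]
            avg_m2[j] += prob * (var[pos] + mean[pos] ** 2)
    avg_var = avg_m2 - avg_mean**2

    return BMAResult(
        candidates=names,
        models=table.sort_values("prob", ascending=False).reset_index(drop=True),
        inclusion=pd.Series(incl, index=names),
        coef_mean=pd.Series(avg_mean, index=names),
        coef_sd=pd.Series(np.sqrt(np.maximum(avg_var, 0.0)), index=names),
        n=n, g=g, dropped=dropped,
    )


def make_candidates(cohort: pd.DataFrame,
                    partitions: dict[str, Sequence[str]] | None = None,
                    thresholds: dict[str, Sequence[float]] | None = None,
                    interactions: Sequence[tuple[str, str]] = ()) -> list[Candidate]:
    """Build a candidate list from group partitions and CART thresholds.

    ``partitions`` maps a candidate name to the set of groups whose
    membership indicator it is (e.g. the two-group split found at stage
    1).  ``thresholds`` maps a covariate column to split points; each
    yields an indicator ``covariate > t`` (so the CART's left/right
    dichotomy).  ``interactions`` are (name, name) pairs multiplying two
    already-defined candidates, with hierarchy parents recorded.
    """
    cands: dict[str, Candidate] = {}
    for name, groups in (partitions or {}).items():
        cands[name] = Candidate(name, cohort["group"].isin(list(groups))
                                .to_numpy(float))
    for col, ts in (thresholds or {}).items():
        if col == "wessex_max":
            base = (cohort["wessex"].to_numpy(float) == 9.0).astype(float)
        else:
            base = cohort[col].to_numpy(float)
        for t in ts:
            cname = f"{col}_gt_{t:g}"
            cands[cname] = Candidate(cname, (base > t).astype(float))
    for a, b in interactions:
        if a not in cands or b not in cands:
            raise ValueError(f"interaction parents {a!r}, {b!r} must be candidates")
        cands[f"{a}:{b}"] = Candidate(f"{a}:{b}", cands[a].values * cands[b].values,
                                      parents=(a, b))
    return list(cands.values())
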