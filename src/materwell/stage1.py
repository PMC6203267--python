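"""Stage-1 Bayesian linear regression of a well-being measure on syndrome group.

The model treats a continuous questionnaire total (positive gain,
positive affect or depression) as normal around a group-structured mean
with the autism group (ASD) as the base level:

    y_i ~ N(x_i' beta, sigma^2)
    beta_ASD            ~ N(eta_A, eps_A^2)      (intercept)
    beta_diff_g         ~ N(eta_B, eps_B^2)      (one per non-ASD group)
    sigma^2             ~ InvGamma(nu, omega)

All coefficient priors are independent normals, so the conditional
posterior of beta given sigma^2 is multivariate normal and the
conditional of sigma^2 given beta is inverse gamma; the two-block Gibbs
sampler below alternates these exact conditionals.

Posterior functionals mirror the study's reporting: central credible
intervals at 20/50/80/90%, per-group absolute means (intercept plus
difference), the posterior probability that a group differs from ASD
(the larger one-sided tail probability of the difference coefficient),
the posterior predictive probability of scoring above the clinical
depression cut-off, and a greedy similarity grouping of syndromes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from materwell.cohort import GROUPS

__all__ = [
    "PriorSpec",
    "DesignMatrix",
    "PosteriorDraws",
    "default_priors",
    "build_design",
    "gibbs_linreg",
    "summarize_posterior",
    "group_mean_draws",
    "prob_difference",
    "prob_clinical",
    "group_by_similarity",
]

CONTINUOUS_MEASURES = ("pgs", "pas5", "hads")


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters of the stage-1 prior.

    ``eta_a``/``eps_a`` are the mean and *standard deviation* of the
    normal prior on the ASD base coefficient; ``eta_b``/``eps_b``
    likewise for each syndrome-difference coefficient (and any extra
    covariate column).  ``nu``/``omega`` are the inverse-gamma shape and
    scale for the error variance, used directly as printed (not the
    halved convention of some software).
    """

    eta_a: float
    eps_a: float
    eta_b: float = 0.0
    eps_b: float = 2.0
    nu: float = 0.001
    omega: float = 0.001

    def __post_init__(self) -> None:
        for name in ("eps_a", "eps_b", "nu", "omega"):
            if getattr(self, name) <= 0:
                raise ValueError(f"PriorSpec.{name} must be > 0")


#: fixed prior hyperparameters per continuous measure
_DEFAULT_PRIORS = {
    "hads": PriorSpec(eta_a=7.6, eps_a=0.5),
    "pgs": PriorSpec(eta_a=21.0, eps_a=2.0),
    "pas5": PriorSpec(eta_a=15.0, eps_a=0.5),
}


def default_priors(measure: str) -> PriorSpec:
    """The fixed prior specification for a continuous measure."""
    if measure not in _DEFAULT_PRIORS:
        raise ValueError(f"no default prior for measure {measure!r}")
    return _DEFAULT_PRIORS[measure]


@dataclass
class DesignMatrix:
    y: np.ndarray
    X: np.ndarray
    columns: list[str]
    groups: list[str]  # non-reference groups, one indicator column each
    reference: str
    measure: str

    def __post_init__(self) -> None:
        if self.X.shape != (len(self.y), len(self.columns)):
            raise ValueError("design shape does not match labels")


_COVARIATE_BUILDERS = {
    "child_age": lambda df: df["child_age"].to_numpy(float),
    "maternal_age": lambda df: df["maternal_age"].to_numpy(float),
    "child_male": lambda df: df["child_male"].to_numpy(float),
    "wessex": lambda df: df["wessex"].to_numpy(float),
    # "at maximum vs below" ability contrast; 9 is the scale maximum
    "wessex_max": lambda df: (df["wessex"].to_numpy(float) == 9.0).astype(float),
}


def build_design(cohort: pd.DataFrame, measure: str,
                 covariates: Sequence[str] = (),
                 reference: str = "ASD") -> DesignMatrix:
    """Build the base-level-coded design for one measure.

    The reference group maps to the intercept; every other group present
    in the cohort gets a 0/1 difference indicator (ordered as in the
    canonical group list, unknown labels last).  Rows with a missing
    response are dropped (complete case per measure).
    """
    if measure not in CONTINUOUS_MEASURES:
        raise ValueError(f"unknown measure {measure!r}; "
                         f"expected one of {CONTINUOUS_MEASURES}")
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    for cov in covariates:
        if cov not in _COVARIATE_BUILDERS:
            raise ValueError(f"unknown covariate {cov!r}; "
                             f"expected one of {sorted(_COVARIATE_BUILDERS)}")

    df = cohort.loc[cohort[measure].notna()].reset_index(drop=True)
    present = set(df["group"])
    order = [g for g in GROUPS if g in present and g != reference]
    order += sorted(present - set(GROUPS) - {reference})

    n = len(df)
    cols = [np.ones(n)]
    names = [f"beta[{reference}]"]
    for g in order:
        cols.append((df["group"] == g).to_numpy(float))
        names.append(f"diff[{g}]")
    for cov in covariates:
        cols.append(_COVARIATE_BUILDERS[cov](df))
        names.append(cov)
    X = np.column_stack(cols) if n else np.empty((0, len(names)))
    return DesignMatrix(y=df[measure].to_numpy(float), X=X, columns=names,
                        groups=order, reference=reference, measure=measure)


@dataclass
class PosteriorDraws:
    beta: np.ndarray    # (draws, p)
    sigma2: np.ndarray  # (draws,)
    columns: list[str]
    groups: list[str]
    reference: str
    measure: str
    meta: dict = field(default_factory=dict)


def _prior_moments(design: DesignMatrix, prior: PriorSpec) -> tuple[np.ndarray, np.ndarray]:
    p = len(design.columns)
    m0 = np.full(p, prior.eta_b, dtype=float)
    s0 = np.full(p, prior.eps_b, dtype=float)
    m0[0], s0[0] = prior.eta_a, prior.eps_a
    return m0, s0


def gibbs_linreg(design: DesignMatrix, prior: PriorSpec,
                 iterations: int = 20_000, burn_in: int = 2_000,
                 thin: int = 1, seed: int = 0) -> PosteriorDraws:
    """Two-block Gibbs sampler for the stage-1 model.

    Alternates the exact conditionals
    ``beta | sigma^2, y ~ N(Vn (V0^-1 m0 + X'y / sigma^2), Vn)`` with
    ``Vn = (V0^-1 + X'X / sigma^2)^-1``, and
    ``sigma^2 | beta, y ~ InvGamma(nu + n/2, omega + RSS/2)``.
    With zero data rows the conditionals collapse to the prior, so the
    sampler draws from the prior exactly.
    """
    if not (iterations > burn_in >= 0):
        raise ValueError("need iterations > burn_in >= 0")
    if thin < 1:
        raise ValueError("thin must be >= 1")
    y, X = design.y, design.X
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(X))):
        raise ValueError("non-finite values in y or X")

    rng = np.random.default_rng(seed)
    n, p = X.shape
    m0, s0 = _prior_moments(design, prior)
    v0inv = 1.0 / s0**2
    v0inv_m0 = v0inv * m0
    XtX = X.T @ X
    Xty = X.T @ y
    shape_post = prior.nu + n / 2.0

    sigma2 = float(np.var(y)) if n > 1 and np.var(y) > 0 else 1.0
    n_keep = (iterations - burn_in + thin - 1) // thin
    beta_out = np.empty((n_keep, p))
    sig_out = np.empty(n_keep)
    kept = 0
    for it in range(iterations):
        prec = np.diag(v0inv) + XtX / sigma2
        L = np.linalg.cholesky(prec)
        mean = np.linalg.solve(prec, v0inv_m0 + Xty / sigma2)
        z = rng.standard_normal(p)
        beta = mean + np.linalg.solve(L.T, z)

        if n > 0:
            resid = y - X @ beta
            scale_post = prior.omega + 0.5 * float(resid @ resid)
        else:
            scale_post = prior.omega
        # tiny shapes (nu = 0.001 with no data) can underflow to exactly 0
        sigma2 = scale_post / max(rng.gamma(shape_post), np.finfo(float).tiny)

        if it >= burn_in and (it - burn_in) % thin == 0:
            beta_out[kept] = beta
            sig_out[kept] = sigma2
            kept += 1

    return PosteriorDraws(
        beta=beta_out, sigma2=sig_out, columns=list(design.columns),
        groups=list(design.groups), reference=design.reference,
        measure=design.measure,
        meta={"iterations": iterations, "burn_in": burn_in, "thin": thin,
              "seed": seed, "n": n},
    )


def save_draws(draws: PosteriorDraws, path) -> None:
    """Persist retained draws as CSV with a ``#``-comment metadata header."""
    import json
    from pathlib import Path

    meta = dict(draws.meta, columns=draws.columns, groups=draws.groups,
                reference=draws.reference, measure=draws.measure)
    body = pd.DataFrame(draws.beta, columns=draws.columns)
    body["sigma2"] = draws.sigma2
    Path(path).write_text("# " + json.dumps(meta) + "\n"
                          + body.to_csv(index=False, float_format="%.17g"))


def load_draws(path) -> PosteriorDraws:
    """Read draws written by :func:`save_draws`."""
    import json
    from pathlib import Path

    text = Path(path).read_text().splitlines()
    if not text or not text[0].startswith("# "):
        raise ValueError(f"{path} lacks the metadata header line")
    meta = json.loads(text[0][2:])
    from io import StringIO

    # the default fast float parser can be off by one ulp
    body = pd.read_csv(StringIO("\n".join(text[1:])),
                       float_precision="round_trip")
    columns = meta.pop("columns")
    return PosteriorDraws(
        beta=body[columns].to_numpy(float),
        sigma2=body["sigma2"].to_numpy(float), columns=columns,
        groups=meta.pop("groups"), reference=meta.pop("reference"),
        measure=meta.pop("measure"), meta=meta)


def group_mean_draws(draws: PosteriorDraws, group: str) -> np.ndarray:
    """Posterior draws of a group's absolute mean (intercept + difference)."""
    base = draws.beta[:, 0]
    if group == draws.reference:
        return base
    try:
        j = draws.columns.index(f"diff[{group}]")
    except ValueError:
        raise ValueError(f"group {group!r} has no difference column") from None
    return base + draws.beta[:, j]


def summarize_posterior(draws: PosteriorDraws,
                        levels: Sequence[float] = (0.2, 0.5, 0.8, 0.9)) -> pd.DataFrame:
    """Posterior means and central credible intervals.

    Rows cover each regression coefficient, the error variance, and each
    group's absolute mean; columns are ``mean`` plus ``lo{L}``/``hi{L}``
    for each level (percent).  Intervals at increasing levels nest.
    """
    if draws.beta.shape[0] < 100:
        raise ValueError("need at least 100 retained draws to summarize")
    quantities: dict[str, np.ndarray] = {
        name: draws.beta[:, j] for j, name in enumerate(draws.columns)
    }
    quantities["sigma2"] = draws.sigma2
    for g in [draws.reference] + draws.groups:
        quantities[f"mean[{g}]"] = group_mean_draws(draws, g)

    rows = {}
    for name, x in quantities.items():
        row = {"mean": float(np.mean(x))}
        for lev in sorted(levels):
            lo, hi = np.quantile(x, [(1 - lev) / 2, (1 + lev) / 2])
            row[f"lo{int(round(lev * 100))}"] = float(lo)
            row[f"hi{int(round(lev * 100))}"] = float(hi)
        rows[name] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def prob_difference(draws: PosteriorDraws, group: str) -> float:
    """Posterior probability that a group differs from the reference.

    Defined as ``max(P(diff > 0), P(diff < 0))`` over the difference
    coefficient's draws: 0.5 means the group is indistinguishable from
    ASD, values near 1 mean the posteriors are highly unlikely to be
    equivalent.
    """
    if group == draws.reference:
        raise ValueError("no self-comparison with the reference group")
    j = draws.columns.index(f"diff[{group}]")
    d = draws.beta[:, j]
    p_pos = float(np.mean(d > 0) + 0.5 * np.mean(d == 0))
    return max(p_pos, 1.0 - p_pos)


def prob_clinical(draws: PosteriorDraws, group: str, cutoff: float = 7.0,
                  mode: str = "integrate") -> float:
    """Posterior predictive probability of scoring above a clinical cut-off.

    A new dyad's score is ``N(mu_group, sigma^2)``; the probability of
    exceeding the cut-off (default 7, the upper end of the HADS "normal"
    band) is averaged over posterior draws (``mode="integrate"``) or
    evaluated at the posterior means (``mode="plugin"``).  At ``sigma ->
    0`` with the mean exactly at the cut-off the probability is 0.5 by
    continuity.
    """
    if not 0.0 <= cutoff <= 21.0:
        raise ValueError("cutoff must lie in [0, 21]")
    mu = group_mean_draws(draws, group)
    sd = np.sqrt(draws.sigma2)
    if mode == "plugin":
        mu = np.array([mu.mean()])
        sd = np.array([np.sqrt(draws.sigma2.mean())])
    elif mode != "integrate":
        raise ValueError(f"unknown mode {mode!r}")
    degenerate = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (cutoff - mu) / np.where(degenerate, 1.0, sd)
    z = np.where(degenerate, np.sign(cutoff - mu) * 1e12, z)
    return float(np.mean(stats.norm.sf(z)))


def _pairwise_prob(mu_a: np.ndarray, mu_b: np.ndarray) -> float:
    d = mu_a - mu_b
    p = float(np.mean(d > 0) + 0.5 * np.mean(d == 0))
    return max(p, 1.0 - p)


def group_by_similarity(draws: PosteriorDraws, threshold: float = 0.9) -> list[list[str]]:
    """Greedy partition of groups into posterior-similarity clusters.

    Groups are ordered by posterior mean; each joins the current cluster
    while its pairwise probability-of-difference with *every* member
    stays below the threshold, otherwise it starts a new cluster.
    Deterministic given the draws.
    """
    names = [draws.reference] + draws.groups
    mus = {g: group_mean_draws(draws, g) for g in names}
    order = sorted(names, key=lambda g: float(np.mean(mus[g])))
    clusters: list[list[str]] = []
    for g in order:
        if clusters and all(_pairwise_prob(mus[g], mus[h]) < threshold
                            for h in clusters[-1]):
            clusters[-1].append(g)
        else:
            clusters.append([g])
    return clusters
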