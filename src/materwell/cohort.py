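"""Synthetic cohort generation, scale scoring and exclusion filtering.

A cohort is a set of mother/child dyads, one per family, spanning an
autism reference group (ASD) and 13 genetic syndromes.  Each dyad
carries demographics (child and maternal age, child gender, a Wessex
self-help score used as an ability proxy) and item-level responses to
four questionnaires:

* **PGS** — Positive Gain Scale, 7 Likert items (1-5), reverse coded so
  that higher totals mean more positive gain; total 7-35.
* **PAS5** — 5-item short Positive Affect Scale, items 1-5; total 5-25.
* **HADS-D** — 7-item depression subscale of the Hospital Anxiety and
  Depression Scale, items 0-3; total 0-21 (scores above 7 indicate
  clinically significant depression).
* **QRSF** — Parent and Family Problems subscale of the Questionnaire on
  Resources and Stress (short form), 7 true/false items; the stress
  score is the count of "true" responses, 0-7.

The generator draws a latent well-being level per dyad (group mean +
covariate effects + person-level noise), spreads it over items with
independent item noise, and discretizes each item by *randomized
rounding* (floor plus a Bernoulli on the fractional part) followed by
clipping to the item range.  Randomized rounding is mean-unbiased and
clipping has a censored-normal closed form, so the exact expected scale
score implied by any configuration is computable (`expected_score`) and
is recorded in the latent-truth output for recovery testing.  True/false
items are the 0-1 special case: the construction reduces to a Bernoulli
draw whose success probability is the censored mean.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MEASURES",
    "GROUPS",
    "CohortConfig",
    "MeasureEffects",
    "RawCohort",
    "CohortTruth",
    "ConfigError",
    "default_config",
    "generate_cohort",
    "score_scales",
    "apply_exclusions",
    "cronbach_alpha",
    "expected_score",
]


class ConfigError(ValueError):
    """A cohort configuration field is invalid."""


#: measure name -> (number of items, item minimum, item maximum)
MEASURES: dict[str, tuple[int, int, int]] = {
    "pgs": (7, 1, 5),
    "pas5": (5, 1, 5),
    "hads": (7, 0, 3),
    "stress": (7, 0, 1),
}

#: closed score ranges implied by the item structure
SCORE_RANGES: dict[str, tuple[int, int]] = {
    m: (k * lo, k * hi) for m, (k, lo, hi) in MEASURES.items()
}

#: group labels, reference group (ASD) first
GROUPS: tuple[str, ...] = (
    "ASD", "AS", "CdLS", "DS", "FXS", "PMS", "PWS",
    "RTT", "RTS", "SMS", "Soto", "TSC", "1p36", "8p23",
)

# Demographic defaults per group: n, child age (mean, sd), maternal age
# (mean, sd), proportion male, probability the Wessex self-help score is
# at its maximum.  These emulate the published cohort's layout (712
# dyads in total).  Rett syndrome's self-help proportion is not
# reported; a small value reflects the severe self-help impairment
# characteristic of the syndrome.
_DEMOGRAPHICS: dict[str, tuple[int, tuple[float, float], tuple[float, float], float, float]] = {
    "ASD":  (66, (15.5, 6.5), (47.9, 6.8), 0.864, 0.892),
    "AS":   (28, (10.9, 3.3), (40.8, 4.9), 0.464, 0.143),
    "CdLS": (44, (12.8, 8.2), (45.1, 9.1), 0.477, 0.409),
    "DS":   (29, (25.4, 11.8), (59.1, 12.3), 0.533, 0.900),
    "FXS":  (102, (15.0, 8.2), (45.6, 9.5), 1.000, 0.882),
    "PMS":  (31, (11.3, 8.4), (42.3, 9.9), 0.452, 0.226),
    "PWS":  (101, (12.2, 8.1), (44.5, 8.5), 0.523, 0.782),
    "RTT":  (87, (20.1, 10.2), (50.7, 9.2), 0.000, 0.050),
    "RTS":  (47, (21.3, 10.5), (49.8, 9.9), 0.553, 0.809),
    "SMS":  (20, (11.6, 7.2), (43.7, 8.5), 0.600, 0.600),
    "Soto": (38, (15.3, 9.3), (46.3, 8.3), 0.684, 0.842),
    "TSC":  (71, (18.8, 10.7), (48.1, 10.3), 0.606, 0.662),
    "1p36": (26, (10.9, 8.9), (41.2, 10.8), 0.786, 0.423),
    "8p23": (22, (10.8, 5.5), (39.6, 6.1), 0.682, 0.591),
}

# Default latent group means per measure (the study-condition profile
# the generator emulates).
_LATENT_MEANS: dict[str, dict[str, float]] = {
    "pgs": {
        "ASD": 21.66, "AS": 21.55, "CdLS": 21.66, "DS": 22.42, "FXS": 21.66,
        "PMS": 22.98, "PWS": 21.06, "RTT": 22.71, "RTS": 22.70, "SMS": 21.70,
        "Soto": 21.78, "TSC": 21.64, "1p36": 21.64, "8p23": 21.89,
    },
    "pas5": {
        "ASD": 15.25, "AS": 16.60, "CdLS": 15.51, "DS": 15.93, "FXS": 15.77,
        "PMS": 16.03, "PWS": 15.65, "RTT": 17.23, "RTS": 15.07, "SMS": 15.62,
        "Soto": 15.53, "TSC": 15.32, "1p36": 15.63, "8p23": 16.86,
    },
    "hads": {
        "ASD": 7.12, "AS": 6.03, "CdLS": 6.92, "DS": 4.79, "FXS": 5.61,
        "PMS": 6.13, "PWS": 6.12, "RTT": 4.70, "RTS": 5.36, "SMS": 7.66,
        "Soto": 5.42, "TSC": 5.88, "1p36": 6.96, "8p23": 4.82,
    },
    "stress": {
        "ASD": 6.0, "AS": 5.0, "CdLS": 5.0, "DS": 3.0, "FXS": 4.0,
        "PMS": 5.0, "PWS": 4.0, "RTT": 4.0, "RTS": 5.0, "SMS": 6.0,
        "Soto": 4.0, "TSC": 5.0, "1p36": 5.0, "8p23": 4.0,
    },
}

# Residual dispersion defaults: person-level sd on the scale-score
# metric and per-item noise sd on the item metric.
_NOISE_DEFAULTS: dict[str, tuple[float, float]] = {
    "pgs": (3.2, 0.6),
    "pas5": (2.0, 0.6),
    "hads": (2.3, 0.5),
    "stress": (1.6, 0.30),
}

#: sample means of the default cohort used to center covariates so that
#: group latent means stay interpretable as group-typical scores
CHILD_AGE_CENTER = 15.2
MATERNAL_AGE_CENTER = 46.6


@dataclass(frozen=True)
class MeasureEffects:
    """Latent structure of one outcome measure.

    ``group_means`` are latent scale-score means per group;
    ``child_age`` / ``maternal_age`` are slopes per year (ages are
    centered at the cohort-typical 15.2 / 46.6 years); ``wessex_max`` is
    the shift for dyads whose Wessex self-help score is at the maximum.
    ``interactions`` are (group subset, covariate name, coefficient)
    triples adding covariate effects only within the subset.
    """

    group_means: Mapping[str, float]
    child_age: float = 0.0
    maternal_age: float = 0.0
    wessex_max: float = 0.0
    interactions: tuple[tuple[frozenset, str, float], ...] = ()
    person_sd: float = 1.0
    item_sd: float = 0.5


@dataclass(frozen=True)
class CohortConfig:
    group_names: tuple[str, ...] = GROUPS
    group_sizes: tuple[int, ...] = tuple(_DEMOGRAPHICS[g][0] for g in GROUPS)
    child_age_mean_sd: tuple[tuple[float, float], ...] = tuple(
        _DEMOGRAPHICS[g][1] for g in GROUPS
    )
    maternal_age_mean_sd: tuple[tuple[float, float], ...] = tuple(
        _DEMOGRAPHICS[g][2] for g in GROUPS
    )
    p_male: tuple[float, ...] = tuple(_DEMOGRAPHICS[g][3] for g in GROUPS)
    p_max_selfhelp: tuple[float, ...] = tuple(_DEMOGRAPHICS[g][4] for g in GROUPS)
    outcome_effects: Mapping[str, MeasureEffects] = field(
        default_factory=lambda: {
            m: MeasureEffects(
                group_means=dict(_LATENT_MEANS[m]),
                person_sd=_NOISE_DEFAULTS[m][0],
                item_sd=_NOISE_DEFAULTS[m][1],
            )
            for m in MEASURES
        }
    )
    missing_item_rate: float = 0.0
    p_nonmother: float = 0.0
    p_child_under2: float = 0.0
    wessex_min: int = 3
    wessex_max: int = 9
    scq_mean: float = 22.0
    scq_sd: float = 4.0
    scq_floor: int = 15
    seed: int = 0

    def validate(self) -> None:
        ng = len(self.group_names)
        for name in ("group_sizes", "child_age_mean_sd", "maternal_age_mean_sd",
                     "p_male", "p_max_selfhelp"):
            if len(getattr(self, name)) != ng:
                raise ConfigError(f"{name}: length {len(getattr(self, name))} "
                                  f"does not match {ng} groups")
        if any(int(n) < 1 for n in self.group_sizes):
            raise ConfigError("group_sizes: all sizes must be >= 1")
        for name in ("p_male", "p_max_selfhelp"):
            vals = getattr(self, name)
            if any(not 0.0 <= p <= 1.0 for p in vals):
                raise ConfigError(f"{name}: probabilities must lie in [0, 1]")
        for name in ("missing_item_rate", "p_nonmother", "p_child_under2"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name}: must lie in [0, 1]")
        if not self.wessex_min < self.wessex_max:
            raise ConfigError("wessex_min: must be below wessex_max")
        for m in MEASURES:
            if m not in self.outcome_effects:
                raise ConfigError(f"outcome_effects: missing measure {m!r}")
            eff = self.outcome_effects[m]
            if eff.person_sd < 0 or eff.item_sd < 0:
                raise ConfigError(f"outcome_effects[{m!r}]: noise sds must be >= 0")
            missing = set(self.group_names) - set(eff.group_means)
            if missing:
                raise ConfigError(
                    f"outcome_effects[{m!r}].group_means: missing groups {sorted(missing)}")


def default_config(**overrides) -> CohortConfig:
    """The bundled default configuration (14 groups, 712 dyads)."""
    return dataclasses.replace(CohortConfig(), **overrides)


@dataclass
class RawCohort:
    """Item-level responses plus demographics, one entry per dyad."""

    group: np.ndarray
    child_age: np.ndarray
    maternal_age: np.ndarray
    child_male: np.ndarray
    wessex: np.ndarray
    respondent_role: np.ndarray
    scq_total: np.ndarray  # NaN outside the ASD group
    items: dict[str, np.ndarray]  # measure -> (n, k) float array, NaN = missing

    def __len__(self) -> int:
        return len(self.group)


@dataclass
class CohortTruth:
    """Generating truth retained for parameter-recovery testing."""

    config: CohortConfig
    latent_group_means: dict[str, dict[str, float]]
    #: exact expected scale score per dyad under the generator
    expected_dyad_scores: dict[str, np.ndarray]
    #: expected scale score averaged within group
    expected_group_scores: dict[str, dict[str, float]]
    covariate_coefs: dict[str, dict[str, float]]


def load_cohort_config(path) -> CohortConfig:
    """Read a :class:`CohortConfig` from a YAML file.

    The file holds a ``groups`` mapping (ordered; per-group ``n``,
    ``child_age``/``maternal_age`` as [mean, sd], ``p_male``,
    ``p_max_selfhelp``), a ``measures`` mapping (per-measure
    ``group_means``, covariate slopes, ``person_sd``, ``item_sd``), and
    optional scalar fields.  The bundled ``data/study_cohort.yaml``
    reproduces the default 14-group / 712-dyad layout.
    """
    import yaml

    raw = yaml.safe_load(Path(path).read_text())
    groups = raw.pop("groups")
    names = tuple(groups)
    effects = {}
    for m, spec in raw.pop("measures").items():
        inter = tuple(
            (frozenset(gs), cov, float(coef))
            for gs, cov, coef in spec.pop("interactions", []))
        effects[m] = MeasureEffects(
            group_means={g: float(v) for g, v in spec.pop("group_means").items()},
            interactions=inter, **spec)
    cfg = CohortConfig(
        group_names=names,
        group_sizes=tuple(int(groups[g]["n"]) for g in names),
        child_age_mean_sd=tuple(tuple(groups[g]["child_age"]) for g in names),
        maternal_age_mean_sd=tuple(tuple(groups[g]["maternal_age"])
                                   for g in names),
        p_male=tuple(float(groups[g]["p_male"]) for g in names),
        p_max_selfhelp=tuple(float(groups[g]["p_max_selfhelp"])
                             for g in names),
        outcome_effects=effects, **raw)
    cfg.validate()
    return cfg


def save_cohort_config(config: CohortConfig, path) -> None:
    """Write a :class:`CohortConfig` as the YAML layout read back by
    :func:`load_cohort_config`."""
    import yaml

    doc: dict = {"groups": {}, "measures": {}}
    for i, g in enumerate(config.group_names):
        doc["groups"][g] = {
            "n": int(config.group_sizes[i]),
            "child_age": [float(v) for v in config.child_age_mean_sd[i]],
            "maternal_age": [float(v) for v in config.maternal_age_mean_sd[i]],
            "p_male": float(config.p_male[i]),
            "p_max_selfhelp": float(config.p_max_selfhelp[i]),
        }
    for m, eff in config.outcome_effects.items():
        spec = {
            "group_means": {g: float(v) for g, v in eff.group_means.items()},
            "child_age": float(eff.child_age),
            "maternal_age": float(eff.maternal_age),
            "wessex_max": float(eff.wessex_max),
            "person_sd": float(eff.person_sd),
            "item_sd": float(eff.item_sd),
        }
        if eff.interactions:
            spec["interactions"] = [[sorted(gs), cov, float(coef)]
                                    for gs, cov, coef in eff.interactions]
        doc["measures"][m] = spec
    for name in ("missing_item_rate", "p_nonmother", "p_child_under2",
                 "wessex_min", "wessex_max", "scq_mean", "scq_sd",
                 "scq_floor", "seed"):
        doc[name] = getattr(config, name)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def bundled_config_path() -> "Path":
    """Path of the bundled study-layout cohort configuration."""
    return Path(__file__).parent / "data" / "study_cohort.yaml"


def _censored_normal_mean(mu: np.ndarray, sd: float, lo: float, hi: float) -> np.ndarray:
    """E[clip(Z, lo, hi)] for Z ~ N(mu, sd^2) (censored-normal mean)."""
    mu = np.asarray(mu, dtype=float)
    if sd == 0:
        return np.clip(mu, lo, hi)
    a = (lo - mu) / sd
    b = (hi - mu) / sd
    Fa, Fb = stats.norm.cdf(a), stats.norm.cdf(b)
    fa, fb = stats.norm.pdf(a), stats.norm.pdf(b)
    return lo * Fa + hi * (1.0 - Fb) + mu * (Fb - Fa) - sd * (fb - fa)


def expected_score(measure: str, latent_mean, person_sd: float, item_sd: float):
    """Exact expected scale score for a latent scale-score mean.

    Each item's pre-discretization value is N(latent_mean/k,
    (person_sd/k)^2 + item_sd^2) marginally; randomized rounding is
    mean-preserving, so the expected item value is the censored-normal
    mean over the item range and the expected score is k times it.
    """
    k, lo, hi = MEASURES[measure]
    sd = float(np.hypot(person_sd / k, item_sd))
    return k * _censored_normal_mean(np.asarray(latent_mean, dtype=float) / k, sd, lo, hi)


def _randomized_round(z: np.ndarray, lo: int, hi: int, rng: np.random.Generator) -> np.ndarray:
    base = np.floor(z)
    val = base + (rng.random(z.shape) < (z - base))
    return np.clip(val, lo, hi)


def generate_cohort(config: CohortConfig | None = None,
                    seed: int | None = None) -> tuple[RawCohort, CohortTruth]:
    """Draw a full synthetic cohort and its generating truth.

    Reproducible: the same (config, seed) pair always yields an
    identical cohort.  ``seed`` overrides ``config.seed`` when given.
    """
    config = config if config is not None else CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    groups, child_age, maternal_age, child_male, wessex = [], [], [], [], []
    roles, scq = [], []
    for gi, g in enumerate(config.group_names):
        n = int(config.group_sizes[gi])
        groups.extend([g] * n)

        m, s = config.child_age_mean_sd[gi]
        lo = (2.0 - m) / s
        child_age.append(stats.truncnorm.rvs(lo, np.inf, loc=m, scale=s,
                                             size=n, random_state=rng))
        m, s = config.maternal_age_mean_sd[gi]
        lo = (18.0 - m) / s
        maternal_age.append(stats.truncnorm.rvs(lo, np.inf, loc=m, scale=s,
                                                size=n, random_state=rng))
        child_male.append((rng.random(n) < config.p_male[gi]).astype(int))

        at_max = rng.random(n) < config.p_max_selfhelp[gi]
        below = rng.integers(config.wessex_min, config.wessex_max, size=n)
        wessex.append(np.where(at_max, config.wessex_max, below))

        role = np.full(n, "mother", dtype=object)
        if config.p_nonmother > 0:
            role[rng.random(n) < config.p_nonmother] = "other"
        roles.append(role)
        if g == "ASD":
            draw = np.round(rng.normal(config.scq_mean, config.scq_sd, size=n))
            scq.append(np.maximum(draw, config.scq_floor))
        else:
            scq.append(np.full(n, np.nan))

    group_arr = np.array(groups, dtype=object)
    child_age = np.concatenate(child_age)
    maternal_age = np.concatenate(maternal_age)
    child_male = np.concatenate(child_male)
    wessex = np.concatenate(wessex)
    roles = np.concatenate(roles)
    scq = np.concatenate(scq)
    n_total = len(group_arr)
    if config.p_child_under2 > 0:
        under = rng.random(n_total) < config.p_child_under2
        child_age = np.where(under, 1.0, child_age)

    wessex_at_max = (wessex == config.wessex_max).astype(float)
    ca_c = child_age - CHILD_AGE_CENTER
    ma_c = maternal_age - MATERNAL_AGE_CENTER
    covariate_values = {"child_age": ca_c, "maternal_age": ma_c,
                        "wessex_max": wessex_at_max}

    items: dict[str, np.ndarray] = {}
    expected_dyad: dict[str, np.ndarray] = {}
    expected_group: dict[str, dict[str, float]] = {}
    coefs: dict[str, dict[str, float]] = {}
    for measure, (k, lo, hi) in MEASURES.items():
        eff = config.outcome_effects[measure]
        mu = np.array([eff.group_means[g] for g in group_arr], dtype=float)
        mu += eff.child_age * ca_c + eff.maternal_age * ma_c
        mu += eff.wessex_max * wessex_at_max
        for gset, cov, coef in eff.interactions:
            mask = np.isin(group_arr, list(gset)).astype(float)
            mu += coef * mask * covariate_values[cov]

        person = mu + rng.normal(0.0, eff.person_sd, size=n_total)
        z = person[:, None] / k + rng.normal(0.0, eff.item_sd, size=(n_total, k))
        vals = _randomized_round(z, lo, hi, rng).astype(float)
        if measure == "pgs":
            vals = 6.0 - vals  # stored on the original (unreversed) coding
        if config.missing_item_rate > 0:
            vals[rng.random(vals.shape) < config.missing_item_rate] = np.nan
        items[measure] = vals

        exp_dyad = expected_score(measure, mu, eff.person_sd, eff.item_sd)
        expected_dyad[measure] = exp_dyad
        expected_group[measure] = {
            g: float(exp_dyad[group_arr == g].mean()) for g in config.group_names
        }
        coefs[measure] = {"child_age": eff.child_age,
                          "maternal_age": eff.maternal_age,
                          "wessex_max": eff.wessex_max}

    raw = RawCohort(group=group_arr, child_age=child_age, maternal_age=maternal_age,
                    child_male=child_male, wessex=wessex, respondent_role=roles,
                    scq_total=scq, items=items)
    truth = CohortTruth(
        config=config,
        latent_group_means={m: dict(config.outcome_effects[m].group_means)
                            for m in MEASURES},
        expected_dyad_scores=expected_dyad,
        expected_group_scores=expected_group,
        covariate_coefs=coefs,
    )
    return raw, truth


def _score_one(vals: np.ndarray, k: int, min_frac: float = 0.75) -> tuple[np.ndarray, np.ndarray]:
    """Prorated total score and completion fraction per row.

    Scales with at least ``min_frac`` of items answered are prorated
    (mean of answered items times the item count, rounded half-up);
    below that the score is missing.
    """
    answered = np.sum(~np.isnan(vals), axis=1)
    frac = answered / k
    mean = np.where(answered > 0,
                    np.nansum(vals, axis=1) / np.maximum(answered, 1), np.nan)
    score = np.floor(mean * k + 0.5)  # round half-up
    score = np.where(frac >= min_frac, score, np.nan)
    return score, frac


def score_scales(raw: RawCohort, min_frac: float = 0.75) -> pd.DataFrame:
    """Score the four scales, returning one row per dyad.

    PGS items are stored on their original coding and reverse coded here
    (1<->5, 2<->4) before summation, so higher totals mean more positive
    gain.  Returns the cohort table columns plus bookkeeping columns
    (respondent role, SCQ total, per-scale completion fractions) used by
    :func:`apply_exclusions`.
    """
    out = {
        "group": raw.group,
        "child_age": raw.child_age,
        "maternal_age": raw.maternal_age,
        "child_male": raw.child_male,
        "wessex": raw.wessex,
    }
    for measure, (k, _, _) in MEASURES.items():
        vals = raw.items[measure]
        if measure == "pgs":
            vals = 6.0 - vals  # reverse code
        score, frac = _score_one(vals, k, min_frac)
        out[measure] = score
        out[f"frac_{measure}"] = frac
    out["respondent_role"] = raw.respondent_role
    out["scq_total"] = raw.scq_total
    return pd.DataFrame(out)


#: canonical cohort-table column order for I/O
COHORT_COLUMNS = ["group", "child_age", "maternal_age", "child_male",
                  "wessex", "pgs", "pas5", "hads", "stress"]


def apply_exclusions(records: pd.DataFrame, scq_cutoff: int = 15,
                     min_frac: float = 0.75) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the study's exclusion rules and return (retained, ledger).

    Rules, applied in order (each record is counted once, under the
    first rule it fails): non-mother respondent; child younger than 2
    years; under 75% completion on any analysed scale; ASD dyads with an
    SCQ total below the cut-off (default 15; scoring exactly at the
    cut-off is retained).
    """
    ledger = {"role": 0, "age": 0, "completion": 0, "scq": 0}
    if len(records) == 0:
        return records.reindex(columns=COHORT_COLUMNS), ledger

    role_ok = records["respondent_role"].astype(str).str.contains("mother")
    age_ok = records["child_age"] >= 2.0
    frac_cols = [f"frac_{m}" for m in MEASURES]
    completion_ok = (records[frac_cols] >= min_frac).all(axis=1)
    scq_ok = (records["group"] != "ASD") | (records["scq_total"] >= scq_cutoff)

    reason = np.select(
        [~role_ok, ~age_ok, ~completion_ok, ~scq_ok],
        ["role", "age", "completion", "scq"],
        default="",
    )
    for key in ledger:
        ledger[key] = int(np.sum(reason == key))
    retained = records.loc[reason == "", COHORT_COLUMNS].reset_index(drop=True)
    return retained, ledger


def cronbach_alpha(item_matrix) -> float:
    """Cronbach's alpha internal-consistency coefficient.

    alpha = k/(k-1) * (1 - sum of item variances / variance of totals),
    computed on listwise-complete rows with sample (n-1) variances.  For
    dichotomous items this equals the Kuder-Richardson (KR-20)
    coefficient.  Raises ``ValueError`` when the total score has zero
    variance (alpha undefined).
    """
    x = np.asarray(item_matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 items")
    x = x[~np.isnan(x).any(axis=1)]
    if x.shape[0] < 2:
        raise ValueError("need at least 2 complete rows")
    k = x.shape[1]
    total_var = np.var(x.sum(axis=1), ddof=1)
    if total_var == 0:
        raise ValueError("total-score variance is zero: alpha undefined")
    item_var = np.var(x, axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))
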