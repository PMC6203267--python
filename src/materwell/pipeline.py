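"""End-to-end orchestration of the three-stage analysis workflow.

For each continuous measure (positive gain, positive affect,
depression) the pipeline runs: stage-1 Bayesian regression on syndrome
group; CART on the ability proxy and ages to find dichotomization
thresholds; and BMA over syndrome-partition indicators, CART-derived
dichotomies and their interactions.  Stress runs the CART followed by
the ordinal probit model (no BMA — the outcome is an ordered count).

Every stage draws its seed deterministically from the master seed and
the stage name, so a rerun with the same configuration produces
byte-identical outputs and any single stage can be re-run in isolation.
All tabular outputs are CSV; the run manifest is a plain-text key=value
file capturing config, seeds and the analysis conventions exercised.
"""

from __future__ import annotations

import dataclasses
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from materwell import bma, cart, cohort as cohort_mod, ordinal, stage1
from materwell.cohort import COHORT_COLUMNS, GROUPS, MEASURES

__all__ = ["AnalysisConfig", "run_pipeline", "read_cohort", "write_report",
           "stage_seed"]

log_ = logging.getLogger(__name__)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    return int(np.random.SeedSequence(
        [int(master_seed), zlib.crc32(stage.encode())]
    ).generate_state(1)[0] & 0x7FFF_FFFF)


@dataclass(frozen=True)
class AnalysisConfig:
    """Configuration of a full pipeline run."""

    cohort_path: str | None = None          # None -> synthesize the default cohort
    out_dir: str = "materwell_run"
    master_seed: int = 0
    measures: tuple[str, ...] = ("pgs", "pas5", "hads", "stress")
    priors: Mapping[str, stage1.PriorSpec] = field(
        default_factory=lambda: {m: stage1.default_priors(m)
                                 for m in stage1.CONTINUOUS_MEASURES})
    iterations: int = 20_000
    burn_in: int = 2_000
    thin: int = 1
    stress_iterations: int = 50_000
    stress_burn_in: int = 5_000
    stress_thin: int = 10
    cart_params: cart.TreeParams = field(default_factory=cart.TreeParams)
    cart_covariates: tuple[str, ...] = ("wessex", "wessex_max",
                                        "child_age", "maternal_age")
    similarity_threshold: float = 0.9
    g_policy: str | float = "unit-information"
    hierarchy: bool = True
    clinical_cutoff: float = 7.0
    stress_profile_ages: tuple[float, ...] = (8.0, 16.0)

    def validate(self) -> None:
        for m in self.measures:
            if m not in MEASURES:
                raise ValueError(f"unknown measure {m!r}")
            if m != "stress" and m not in self.priors:
                raise ValueError(f"measure {m!r} has no prior specification")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        simple = {"cohort_path", "out_dir", "master_seed", "iterations",
                  "burn_in", "thin", "stress_iterations", "stress_burn_in",
                  "stress_thin", "similarity_threshold", "g_policy",
                  "hierarchy", "clinical_cutoff"}
        for key, val in raw.items():
            if key in simple:
                kwargs[key] = val
            elif key == "measures":
                kwargs["measures"] = tuple(val)
            elif key == "stress_profile_ages":
                kwargs["stress_profile_ages"] = tuple(float(v) for v in val)
            elif key == "cart":
                kwargs["cart_params"] = cart.TreeParams(**val)
            elif key == "cart_covariates":
                kwargs["cart_covariates"] = tuple(val)
            elif key == "priors":
                kwargs["priors"] = {m: stage1.PriorSpec(**spec)
                                    for m, spec in val.items()}
            else:
                raise ValueError(f"unknown configuration key {key!r}")
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg


_FLOAT_FMT = "%.10g"


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort table from CSV (missing values as empty fields)."""
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file {path} lacks required columns: {missing}")
    extra = [c for c in df.columns if c not in COHORT_COLUMNS]
    if extra:
        log_.warning("ignoring unknown cohort columns: %s", extra)
    df = df[COHORT_COLUMNS].copy()
    df["group"] = df["group"].astype(str)
    for col in COHORT_COLUMNS[1:]:
        df[col] = pd.to_numeric(df[col])
    return df


def write_report(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a report (or cohort) table as CSV with stable formatting."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def _synthesize_cohort(seed: int) -> pd.DataFrame:
    raw, _ = cohort_mod.generate_cohort(cohort_mod.default_config(seed=seed))
    scored = cohort_mod.score_scales(raw)
    table, ledger = cohort_mod.apply_exclusions(scored)
    log_.info("synthetic cohort: %d dyads retained, exclusions %s",
              len(table), ledger)
    return table


def _group_order(table: pd.DataFrame) -> list[str]:
    present = set(table["group"])
    return [g for g in GROUPS if g in present] + sorted(present - set(GROUPS))


def _stage1_report(draws: stage1.PosteriorDraws, clinical: bool,
                   cutoff: float) -> pd.DataFrame:
    rows = []
    for g in [draws.reference] + draws.groups:
        mu = stage1.group_mean_draws(draws, g)
        lo, hi = np.quantile(mu, [0.05, 0.95])
        row = {
            "group": g,
            "posterior_mean": float(np.mean(mu)),
            "cri90_lo": float(lo),
            "cri90_hi": float(hi),
            "prob_difference": (np.nan if g == draws.reference
                                else stage1.prob_difference(draws, g)),
        }
        if clinical:
            row["prob_clinical"] = stage1.prob_clinical(draws, g, cutoff=cutoff)
        rows.append(row)
    return pd.DataFrame(rows)


#: exhaustive enumeration stays fast below this many candidates
_PIPELINE_CANDIDATE_CAP = 12


def _bma_candidates(table: pd.DataFrame, clusters: list[list[str]],
                    thresholds: dict[str, list[float]]) -> list[bma.Candidate]:
    """Candidates: syndrome-partition indicators (lowest-mean cluster as
    baseline), CART threshold dichotomies, and partition x dichotomy
    interactions up to a size cap that keeps exhaustive enumeration cheap."""
    partitions = {f"synd_grp{i + 1}": grp
                  for i, grp in enumerate(clusters[1:], start=0)}
    cands = bma.make_candidates(table, partitions=partitions,
                                thresholds=thresholds)
    names = [c.name for c in cands]
    inter = [(p, t) for p in partitions for t in names if t not in partitions]
    inter = inter[:max(0, _PIPELINE_CANDIDATE_CAP - len(names))]
    if inter:
        cands = bma.make_candidates(table, partitions=partitions,
                                    thresholds=thresholds, interactions=inter)
    return cands


def _stress_design(table: pd.DataFrame) -> tuple[np.ndarray, list[str], pd.DataFrame]:
    df = table.loc[table["stress"].notna()].reset_index(drop=True)
    order = [g for g in _group_order(df) if g != "ASD"]
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for g in order:
        cols.append((df["group"] == g).to_numpy(float))
        names.append(f"group[{g}]")
    cols.append((df["wessex"].to_numpy(float) == 9.0).astype(float))
    names.append("wessex_max")
    age = df["child_age"].to_numpy(float)
    cols.append(age)
    names.append("child_age")
    for g in order:
        cols.append(age * (df["group"] == g).to_numpy(float))
        names.append(f"child_age:{g}")
    return np.column_stack(cols), names, df


def _stress_profile(names: list[str], group: str, wessex_max: float,
                    age: float) -> np.ndarray:
    x = np.zeros(len(names))
    x[names.index("intercept")] = 1.0
    if f"group[{group}]" in names:
        x[names.index(f"group[{group}]")] = 1.0
        x[names.index(f"child_age:{group}")] = age
    x[names.index("wessex_max")] = wessex_max
    x[names.index("child_age")] = age
    return x


def run_pipeline(config: AnalysisConfig) -> dict[str, pd.DataFrame]:
    """Run the full workflow and write all artifacts under ``out_dir``.

    Returns the report tables keyed by artifact name.  Any stage failure
    aborts with an error naming the stage; the manifest marks the run
    incomplete until the final line is written.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from materwell import __version__  # deferred: avoids import cycle

    manifest: list[tuple[str, object]] = [
        ("package_version", __version__),
        ("master_seed", config.master_seed),
        ("complete", "no"),
    ]
    results: dict[str, pd.DataFrame] = {}

    def _fail(stage: str, err: Exception) -> Exception:
        _write_manifest(out / "manifest.txt", manifest)
        return RuntimeError(f"pipeline stage {stage!r} failed: {err}")

    # --- cohort -----------------------------------------------------------
    try:
        if config.cohort_path is None:
            seed = stage_seed(config.master_seed, "cohort")
            manifest.append(("seed.cohort", seed))
            table = _synthesize_cohort(seed)
        else:
            table = read_cohort(config.cohort_path)
            manifest.append(("cohort_path", config.cohort_path))
    except Exception as err:  # noqa: BLE001 - stage-named abort
        raise _fail("cohort", err) from err
    write_report(table, out / "cohort.csv")
    results["cohort"] = table
    manifest.append(("n_dyads", len(table)))

    for measure in config.measures:
        if measure == "stress":
            continue
        # --- stage 1 ------------------------------------------------------
        try:
            seed = stage_seed(config.master_seed, f"stage1-{measure}")
            manifest.append((f"seed.stage1.{measure}", seed))
            design = stage1.build_design(table, measure)
            draws = stage1.gibbs_linreg(design, config.priors[measure],
                                        iterations=config.iterations,
                                        burn_in=config.burn_in,
                                        thin=config.thin, seed=seed)
            report = _stage1_report(draws, clinical=(measure == "hads"),
                                    cutoff=config.clinical_cutoff)
            clusters = stage1.group_by_similarity(
                draws, threshold=config.similarity_threshold)
        except Exception as err:  # noqa: BLE001
            raise _fail(f"stage1-{measure}", err) from err
        write_report(report, out / f"report_{measure}.csv")
        results[f"report_{measure}"] = report
        manifest.append((f"clusters.{measure}",
                         " | ".join(",".join(c) for c in clusters)))

        # --- CART ---------------------------------------------------------
        try:
            tree = cart.fit_tree(table, measure,
                                 covariates=config.cart_covariates,
                                 params=config.cart_params)
            thresholds = {v: cart.extract_thresholds(tree, v)
                          for v in config.cart_covariates}
            thr_rows = [{"measure": measure, "variable": v, "threshold": t}
                        for v, ts in thresholds.items() for t in ts]
        except Exception as err:  # noqa: BLE001
            raise _fail(f"cart-{measure}", err) from err
        (out / f"cart_{measure}.txt").write_text(tree.render() + "\n")
        thr_table = pd.DataFrame(thr_rows,
                                 columns=["measure", "variable", "threshold"])
        write_report(thr_table, out / f"cart_{measure}.csv")
        results[f"cart_{measure}"] = thr_table

        # --- BMA ----------------------------------------------------------
        try:
            cands = _bma_candidates(
                table, clusters,
                {v: ts for v, ts in thresholds.items() if ts and v != "wessex"})
            fit = bma.bma_fit(table[measure].to_numpy(float), cands,
                              g_policy=config.g_policy,
                              hierarchy=config.hierarchy)
        except Exception as err:  # noqa: BLE001
            raise _fail(f"bma-{measure}", err) from err
        bma_table = pd.DataFrame({
            "candidate": fit.candidates,
            "inclusion_prob": fit.inclusion.to_numpy(),
            "posterior_mean": fit.coef_mean.to_numpy(),
            "posterior_sd": fit.coef_sd.to_numpy(),
        })
        write_report(bma_table, out / f"bma_{measure}.csv")
        results[f"bma_{measure}"] = bma_table

    # --- stress -----------------------------------------------------------
    if "stress" in config.measures:
        try:
            tree = cart.fit_tree(table, "stress",
                                 covariates=config.cart_covariates,
                                 params=config.cart_params)
            (out / "cart_stress.txt").write_text(tree.render() + "\n")
            seed = stage_seed(config.master_seed, "stress")
            manifest.append(("seed.stress", seed))
            X, names, df = _stress_design(table)
            fit = ordinal.fit_ordinal_probit(
                X, df["stress"].to_numpy(int), columns=names, n_categories=8,
                iterations=config.stress_iterations,
                burn_in=config.stress_burn_in, thin=config.stress_thin,
                seed=seed)

            rows = []
            mean_age = float(df["child_age"].mean())
            for g in _group_order(df):
                med, (lo, hi) = ordinal.posterior_median_rating(
                    fit, _stress_profile(names, g, 0.0, mean_age))
                pv, slope = ordinal.age_trend_pvalue(fit, None if g == "ASD" else g)
                rows.append({"group": g, "median": med, "cri90_lo": lo,
                             "cri90_hi": hi, "age_trend_pvalue": pv,
                             "age_slope_mean": slope})
            stress_report = pd.DataFrame(rows)

            prof_rows = []
            for g in _group_order(df):
                for age in config.stress_profile_ages:
                    probs = ordinal.category_probs(
                        fit, _stress_profile(names, g, 0.0, age))
                    med, (lo, hi) = ordinal.posterior_median_rating(
                        fit, _stress_profile(names, g, 0.0, age))
                    row = {"group": g, "wessex": "below_max", "child_age": age,
                           "median": med, "cri90_lo": lo, "cri90_hi": hi}
                    row.update({f"p{k}": float(probs[k]) for k in range(8)})
                    prof_rows.append(row)
            stress_profiles = pd.DataFrame(prof_rows)
        except Exception as err:  # noqa: BLE001
            raise _fail("stress", err) from err
        write_report(stress_report, out / "report_stress.csv")
        write_report(stress_profiles, out / "stress_profiles.csv")
        results["report_stress"] = stress_report
        results["stress_profiles"] = stress_profiles

    manifest.append(("conventions", "prob_difference=max one-sided tail; "
                     "clinical cutoff>%.3g integrated over sigma^2; "
                     "similarity threshold=%.3g; g=%s"
                     % (config.clinical_cutoff, config.similarity_threshold,
                        config.g_policy)))
    manifest = [kv for kv in manifest if kv != ("complete", "no")]
    manifest.append(("complete", "yes"))
    _write_manifest(out / "manifest.txt", manifest)
    return results


def _write_manifest(path: Path, entries: Sequence[tuple[str, object]]) -> None:
    path.write_text("".join(f"{k}={v}\n" for k, v in entries))
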