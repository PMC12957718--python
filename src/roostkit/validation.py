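"""Simulation-based validation harnesses.

These run the whole machinery against its own generative truth: fixed-
effect recovery coverage for the attendance model, discrimination of the
plasticity and selective-mortality scenarios, and type-I calibration of
the nest-permutation test under the generator's no-assortment setting.
Both the test suite and the acceptance script drive them; sizes are
chosen so each check completes in minutes on one CPU.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .association import (
    build_relatedness_registry,
    classify_association_nights,
    permute_nests,
)
from .detection import assign_intervals, extract_night_locations
from .models import ModelSpec, fit_attendance_model, plasticity_mortality_suite
from .synthetic import (
    AttendanceTruth,
    PopulationConfig,
    make_fixture,
    simulate_mortality_scenario,
    truth_interval_units,
)

RECOVERY_TERMS = ("intercept", "age", "age2", "sex_male", "breeding")


def recovery_config(n_winters: int = 4) -> PopulationConfig:
    """Juvenile-cohort fixture at study-like size for parameter recovery.

    Cohorts reach back three years before the monitoring window so the
    four winters hold the age mix (1..7) of the full six-winter study and
    breeding birds are represented.
    """
    return PopulationConfig(n_juvenile_tagged=148, n_adult_tagged=0,
                            n_winters=n_winters, cohort_years_before=3)


def parameter_recovery_check(n_replicates: int = 20, seed: int = 0,
                             truth: AttendanceTruth | None = None) -> dict:
    """Coverage of the generative fixed effects by the fitted 95% intervals.

    Per replicate: simulate a juvenile-tagged population (148 birds, 4
    winters) from the generative truth, build the latent bird-block
    units, fit the full weighted mixed model with the generator's age
    standardisation, and record whether each true fixed effect lies in
    its Wald 95% interval.  Returns per-term coverage counts and the
    estimates.
    """
    truth = truth or AttendanceTruth()
    true_values = dict(intercept=truth.beta_intercept, age=truth.beta_age,
                       age2=truth.beta_age2, sex_male=truth.beta_sex_male,
                       breeding=truth.beta_breeding)
    covered = {t: 0 for t in RECOVERY_TERMS}
    estimates = []
    for rep in range(n_replicates):
        cfg = recovery_config()
        pop, fixes, tt = make_fixture(cfg, truth, seed=seed * 10007 + rep)
        units = truth_interval_units(tt, pop)
        spec = ModelSpec.juvenile(age_center=truth.age_center,
                                  age_scale=truth.age_scale)
        fit = fit_attendance_model(units, spec)
        s = fit.summary.set_index("term")
        row = {"replicate": rep, "converged": fit.converged}
        for t in RECOVERY_TERMS:
            lo, hi = float(s.loc[t, "lower"]), float(s.loc[t, "upper"])
            ok = lo <= true_values[t] <= hi
            covered[t] += int(ok)
            row[t] = float(s.loc[t, "estimate"])
            row[f"{t}_covered"] = ok
        estimates.append(row)
    return dict(n_replicates=n_replicates, covered=covered,
                truth=true_values, estimates=pd.DataFrame(estimates),
                min_coverage=min(covered.values()))


def suite_discrimination_check(n_seeds: int = 20, seed: int = 0) -> dict:
    """Correct labelling of the two ageing-vs-mortality scenarios.

    ``plasticity``: a within-individual age decline with no longevity
    effect must be labelled plasticity (age persists, longevity interval
    covers 0).  ``selective``: attendance set by longevity with no
    within-individual change must yield a detected longevity effect
    without a persisting age effect.
    """
    results = {"plasticity": 0, "selective": 0}
    labels = {"plasticity": [], "selective": []}
    for kind, want in (("plasticity", {"plasticity"}),
                       ("selective", {"selective_mortality"})):
        for rep in range(n_seeds):
            units, deaths = simulate_mortality_scenario(
                kind, seed=seed * 7919 + rep)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = plasticity_mortality_suite(units, deaths)
            labels[kind].append(res.interpretation)
            results[kind] += int(res.interpretation in want)
    return dict(n_seeds=n_seeds, correct=results, labels=labels)


def calibration_fixture_config(seed: int = 0) -> PopulationConfig:
    """Small no-assortment population for permutation calibration.

    Juvenile-tagged birds only, one winter: the kin labels then shuffle
    within a single large brood stratum, so the permutation support is
    rich and the null p-value granularity stays small.  (Tiny per-sex
    pair-slot strata would tie many null draws with the observed
    assignment and make the p-value artificially conservative.)
    """
    return PopulationConfig(
        n_juvenile_tagged=48, n_adult_tagged=0, n_winters=1,
        n_major_roosts=2, n_satellite_roosts=2, seed=seed, assortment=False)


def permutation_calibration_check(n_runs: int = 400, n_iter: int = 200,
                                  seed: int = 0, alpha: float = 0.05,
                                  statistic: str = "dist_cr_without") -> dict:
    """Type-I calibration of the fixed-direction permutation p-value.

    Under the generator's no-assortment setting (positions independent of
    the mate/kin registry) the one-sided p-value of any statistic should
    be uniform; the check records the rejection rate at ``alpha`` and the
    collected p-values for distribution tests.
    """
    rng = np.random.default_rng(seed)
    pvals = []
    rejections = 0
    used = 0
    for run in range(n_runs):
        run_seed = int(rng.integers(2**31 - 1))
        cfg = calibration_fixture_config(seed=run_seed)
        pop, fixes, _ = make_fixture(cfg)
        nights = assign_intervals(extract_night_locations(fixes))
        reg = _registry_from_pop(pop)
        try:
            assoc = classify_association_nights(nights, reg)
            perm = permute_nests(assoc, n_iter=n_iter, seed=run_seed + 1)
        except ValueError:
            continue
        row = perm[perm.statistic == statistic]
        if not len(row):
            continue
        p = float(row.p_greater.iloc[0])
        pvals.append(p)
        rejections += int(p <= alpha)
        used += 1
    return dict(n_runs=used, alpha=alpha, statistic=statistic,
                rejection_rate=rejections / used if used else np.nan,
                p_values=np.asarray(pvals))


def _registry_from_pop(pop):
    nx = pop.nests.set_index("nest_id")
    broods = pop.broods.copy()
    broods["nest_x"] = nx.x.reindex(broods.nest_id).to_numpy()
    broods["nest_y"] = nx.y.reindex(broods.nest_id).to_numpy()
    pairs = pop.pairs.copy()
    if len(pairs):
        pairs["nest_x"] = nx.x.reindex(pairs.nest_id).to_numpy()
        pairs["nest_y"] = nx.y.reindex(pairs.nest_id).to_numpy()
    return build_relatedness_registry(broods, pairs, pop.individuals)
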