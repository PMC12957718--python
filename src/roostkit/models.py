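"""Weighted mixed models of communal-roost attendance and diagnostics.

The response is attendance (0/1) of a bird in a five-night block, weighted
by proximity to the study area (weights in [0, 1] multiply log-likelihood
contributions).  Two cohort models are fitted: birds tagged as juveniles
(fixed effects: standardised age, age squared, sex, breeding status) and
birds tagged as adults (sex only; their age is unknown and all bred).
Both include a bird random intercept, a correlated bird-by-winter random
intercept and slope over the standardised within-winter block sequence,
and a winter random intercept.

Also here: posterior-style marginal predictions, event-rate classification
accuracy, binned-residual diagnostics, latent-scale adjusted repeatability,
Cramer's V, an age-versus-longevity model suite separating behavioural
plasticity from selective mortality, and an information-criterion model
comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .glmm import GLMMFit, RandomTerm, fit_glmm, refit, simulate_response
from .synthetic import standardize_interval_index

LOGIT_RESIDUAL_VARIANCE = np.pi**2 / 3


@dataclass
class ModelSpec:
    """Fixed/random structure of an attendance model."""

    cohort: str = "juvenile"
    fixed: tuple = ("age", "age2", "sex", "breeding_status")
    random_bird: bool = True
    random_bird_winter: bool = True
    random_winter: bool = True
    use_weights: bool = True
    age_center: float | None = None   # None: standardise by sample mean/sd
    age_scale: float | None = None

    def __post_init__(self):
        if self.cohort not in ("juvenile", "adult"):
            raise ValueError("cohort must be 'juvenile' or 'adult'")
        if self.cohort == "adult" and (
                "age" in self.fixed or "breeding_status" in self.fixed):
            raise ValueError(
                "the adult-cohort model excludes age and breeding status")

    @classmethod
    def juvenile(cls, **kw):
        return cls(cohort="juvenile", **kw)

    @classmethod
    def adult(cls, **kw):
        return cls(cohort="adult", fixed=("sex",), **kw)


@dataclass
class AttendanceFit:
    """A fitted attendance model with its design bookkeeping."""

    glmm: GLMMFit
    spec: ModelSpec
    summary: pd.DataFrame          # term, estimate, se, lower, upper
    variance_components: dict
    age_center: float | None
    age_scale: float | None
    units: pd.DataFrame
    engine: dict = field(default_factory=dict)

    @property
    def converged(self) -> bool:
        return self.glmm.converged

    @property
    def flags(self) -> list:
        return self.glmm.flags

    def coefficient(self, term: str) -> float:
        row = self.summary.set_index("term").loc[term]
        return float(row.estimate)

    def interval(self, term: str):
        row = self.summary.set_index("term").loc[term]
        return float(row.lower), float(row.upper)


def _design(units: pd.DataFrame, spec: ModelSpec):
    df = units.copy()
    if "tag_class" in df.columns:
        df = df[df.tag_class == spec.cohort]
    if spec.cohort == "juvenile" and "age" in spec.fixed:
        df = df[df.age.notna()]
    df = df.reset_index(drop=True)
    if df.bird_id.nunique() < 2 or df.winter_id.nunique() < 2:
        raise ValueError("attendance model needs >= 2 birds and >= 2 winters")

    cols = [np.ones(len(df))]
    names = ["intercept"]
    center = scale = None
    if "age" in spec.fixed:
        age = df.age.to_numpy(dtype=float)
        center = spec.age_center if spec.age_center is not None else float(age.mean())
        scale = spec.age_scale if spec.age_scale is not None else float(age.std())
        if scale == 0:
            raise ValueError("age has zero variance")
        z = (age - center) / scale
        cols.append(z)
        names.append("age")
        if "age2" in spec.fixed:
            cols.append(z**2)
            names.append("age2")
    if "sex" in spec.fixed:
        cols.append((df.sex.to_numpy() == "m").astype(float))
        names.append("sex_male")
    if "breeding_status" in spec.fixed:
        cols.append(df.breeding_status.to_numpy(dtype=float))
        names.append("breeding")
    X = np.column_stack(cols)

    z_seq = standardize_interval_index(df.interval_index.to_numpy())
    terms = []
    if spec.random_bird:
        terms.append(RandomTerm("bird", pd.factorize(df.bird_id)[0]))
    if spec.random_bird_winter:
        bw = pd.factorize(df.bird_id.astype(str) + ":" + df.winter_id.astype(str))[0]
        terms.append(RandomTerm("bird_winter", bw,
                                np.column_stack([np.ones(len(df)), z_seq])))
    if spec.random_winter:
        terms.append(RandomTerm("winter", pd.factorize(df.winter_id)[0]))

    w = df.weight.to_numpy(dtype=float) if spec.use_weights and "weight" in df.columns else None
    y = df.attendance.to_numpy(dtype=float)
    flat = [n for n, col in zip(names[1:], X[:, 1:].T) if np.ptp(col) == 0]
    if flat or np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn(
            "rank-deficient fixed-effect design"
            + (f" (constant columns: {flat})" if flat else "")
            + "; affected coefficients are held near zero by the ridge")
    return df, y, X, names, terms, w, center, scale


def fit_attendance_model(units: pd.DataFrame, spec: ModelSpec | None = None,
                         engine_options: dict | None = None) -> AttendanceFit:
    """Fit the weighted binomial mixed model for one cohort.

    Maximises the Laplace-approximate weighted marginal likelihood; a
    non-converged or separated fit is returned flagged, never silently.
    """
    spec = spec or ModelSpec.juvenile()
    engine_options = dict(engine_options or {})
    df, y, X, names, terms, w, center, scale = _design(units, spec)
    glmm = fit_glmm(y, X, terms, weights=w, fixed_names=names, **engine_options)

    ci = glmm.wald_interval()
    summary = pd.DataFrame(dict(
        term=names, estimate=glmm.beta, se=glmm.se_beta,
        lower=ci[:, 0], upper=ci[:, 1]))
    vc = {}
    if spec.random_bird:
        vc["sd_bird"] = glmm.sd("bird")
    if spec.random_bird_winter:
        vc["sd_bird_winter"] = glmm.sd("bird_winter", 0)
        vc["sd_slope"] = glmm.sd("bird_winter", 1)
        vc["cor_intercept_slope"] = glmm.correlation("bird_winter")
    if spec.random_winter:
        vc["sd_winter"] = glmm.sd("winter")

    engine = dict(method="laplace_pirls", n_outer_evals=glmm.n_outer_evals,
                  converged=glmm.converged, flags=list(glmm.flags),
                  loglik=glmm.loglik, options=engine_options)
    if not glmm.converged:
        warnings.warn(f"attendance model flagged: {glmm.flags}")
    return AttendanceFit(glmm=glmm, spec=spec, summary=summary,
                         variance_components=vc, age_center=center,
                         age_scale=scale, units=df, engine=engine)


def original_scale_age_coefficients(fit: AttendanceFit) -> dict:
    """Back-transform the standardised age terms to the raw age scale.

    With z = (a - m)/s the quadratic c1 z + c2 z^2 equals
    (c1/s - 2 c2 m / s^2) a + (c2 / s^2) a^2 + const.
    """
    if "age" not in fit.spec.fixed:
        raise ValueError("fit has no age term")
    s = fit.summary.set_index("term")
    c1 = float(s.loc["age", "estimate"])
    c2 = float(s.loc["age2", "estimate"]) if "age2" in s.index else 0.0
    m, sc = fit.age_center, fit.age_scale
    return dict(age=c1 / sc - 2 * c2 * m / sc**2, age2=c2 / sc**2)


def predict_attendance(fit: AttendanceFit, covariates: pd.DataFrame,
                       n_draws: int = 4000, seed: int = 0,
                       marginal: bool = True) -> pd.DataFrame:
    """Population-level attendance probability for covariate combinations.

    Draws fixed effects from their Wald distribution and, when
    ``marginal``, integrates over new bird/winter/bird-winter intercepts
    by Monte Carlo (the block-sequence slope contributes nothing at the
    average block, where the sequence covariate is 0).  Returns median and
    a 95% interval of the expected probability.
    """
    rng = np.random.default_rng(seed)
    cov = covariates.copy()
    rows = []
    fitted_ages = fit.units.age.dropna() if "age" in fit.units else pd.Series(dtype=float)
    beta_draws = rng.multivariate_normal(
        fit.glmm.beta, (fit.glmm.vcov_beta + fit.glmm.vcov_beta.T) / 2, size=n_draws)
    var_int = 0.0
    for name in ("bird", "winter"):
        if name in fit.glmm.covariances:
            var_int += fit.glmm.variance(name)
    if "bird_winter" in fit.glmm.covariances:
        var_int += fit.glmm.variance("bird_winter", 0)
    re = rng.standard_normal(n_draws) * np.sqrt(var_int) if marginal else 0.0

    for _, r in cov.iterrows():
        x = np.zeros(len(fit.glmm.fixed_names))
        for i, name in enumerate(fit.glmm.fixed_names):
            if name == "intercept":
                x[i] = 1.0
            elif name == "age":
                a = float(r["age"])
                if len(fitted_ages) and not (fitted_ages.min() <= a <= fitted_ages.max()):
                    warnings.warn(f"age {a} outside the fitted range")
                x[i] = (a - fit.age_center) / fit.age_scale
            elif name == "age2":
                x[i] = ((float(r["age"]) - fit.age_center) / fit.age_scale) ** 2
            elif name == "sex_male":
                x[i] = float(r.get("sex", "f") == "m") if "sex" in r else float(r.get("sex_male", 0))
            elif name == "breeding":
                x[i] = float(r.get("breeding_status", r.get("breeding", 0)))
        p = expit(beta_draws @ x + re)
        rows.append(dict(probability=float(np.median(p)),
                         lower=float(np.quantile(p, 0.025)),
                         upper=float(np.quantile(p, 0.975))))
    return pd.concat([cov.reset_index(drop=True),
                      pd.DataFrame(rows)], axis=1)


def classification_accuracy(fit: AttendanceFit,
                            units: pd.DataFrame | None = None) -> float:
    """Weighted proportion of units classified correctly at the
    observed-event-rate threshold (predictions above the observed
    proportion of ones count as positive)."""
    df = fit.units if units is None else units
    y = df.attendance.to_numpy(dtype=float) if units is not None else fit.glmm._y
    p = fit.glmm.fitted
    if units is not None and len(units) != len(p):
        raise ValueError("units do not match the fitted model")
    w = fit.glmm._weights
    threshold = float(np.mean(y))
    pred = (p > threshold).astype(float)
    return float(np.sum(w * (pred == y)) / np.sum(w))


def binned_residuals(fit: AttendanceFit, n_bins: int = 20,
                     plot_path=None) -> pd.DataFrame:
    """Mean residual per equal-count bin of fitted probability, with
    +/- 2 SE bands; the standard visual check for a binomial regression."""
    p = fit.glmm.fitted
    y = fit.glmm._y
    if n_bins > len(p):
        raise ValueError("more bins than observations")
    order = np.argsort(p, kind="stable")
    rows = []
    for k, idx in enumerate(np.array_split(order, n_bins)):
        pb, yb = p[idx], y[idx]
        resid = float(np.mean(yb - pb))
        se = float(np.sqrt(np.mean(pb * (1 - pb)) / len(idx)))
        rows.append(dict(bin=k + 1, n=len(idx), mean_fitted=float(np.mean(pb)),
                         mean_residual=resid, band=2 * se,
                         within=abs(resid) <= 2 * se))
    table = pd.DataFrame(rows)
    if plot_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        ax.axhline(0, color="grey", lw=0.8)
        ax.plot(table.mean_fitted, table.band, "--", color="grey")
        ax.plot(table.mean_fitted, -table.band, "--", color="grey")
        ax.plot(table.mean_fitted, table.mean_residual, "o", ms=4)
        ax.set_xlabel("mean fitted probability")
        ax.set_ylabel("mean residual")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return table


def latent_repeatability(var_bird: float, var_winter: float = 0.0) -> float:
    """Latent-scale adjusted repeatability of a logit mixed model:
    R = var_bird / (var_bird + var_winter + pi^2/3)."""
    if var_bird < 0 or var_winter < 0:
        raise ValueError("variances must be >= 0")
    denom = var_bird + var_winter + LOGIT_RESIDUAL_VARIANCE
    if denom == 0:
        raise ValueError("total variance is zero; repeatability undefined")
    return float(var_bird / denom)


def adjusted_repeatability(fit: AttendanceFit, n_boot: int = 0,
                           seed: int = 0) -> dict:
    """Adjusted repeatability (latent scale) with an optional parametric
    bootstrap CI (simulate from the fit, refit, recompute R)."""
    if "bird" not in fit.glmm.covariances or "winter" not in fit.glmm.covariances:
        raise ValueError("repeatability needs bird and winter intercepts")
    r = latent_repeatability(fit.glmm.variance("bird"),
                             fit.glmm.variance("winter"))
    out = dict(R=r, n_boot=n_boot)
    if n_boot:
        rng = np.random.default_rng(seed)
        draws = []
        for _ in range(n_boot):
            y_sim = simulate_response(fit.glmm, rng)
            bfit = refit(fit.glmm, y_sim, polish_beta=False, maxfev=150)
            draws.append(latent_repeatability(bfit.variance("bird"),
                                              bfit.variance("winter")))
        out["lower"] = float(np.quantile(draws, 0.025))
        out["upper"] = float(np.quantile(draws, 0.975))
        out["draws"] = draws
    return out


def cramers_v(a, b):
    """Cramer's V association between two categorical vectors, with the
    chi-square p-value."""
    a = pd.Series(a)
    b = pd.Series(b)
    if len(a) != len(b):
        raise ValueError("vectors must have equal length")
    table = pd.crosstab(a, b)
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("both variables need at least two levels")
    chi2, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    n = table.to_numpy().sum()
    v = float(np.sqrt(chi2 / (n * (min(table.shape) - 1))))
    return v, float(p)


# ---------------------------------------------------------------------------
# Behavioural plasticity vs. selective mortality
# ---------------------------------------------------------------------------

@dataclass
class SuiteResult:
    fits: dict
    comparison: pd.DataFrame
    vif: pd.DataFrame
    interpretation: str
    n_birds: int


def _suite_design(df, include_age, include_longevity, include_bird,
                  quadratic_age=True):
    cols = [np.ones(len(df))]
    names = ["intercept"]
    if include_age:
        z = (df.age.to_numpy(dtype=float) - df.age.mean()) / df.age.std()
        cols.append(z)
        names.append("age")
        if quadratic_age:
            cols.append(z**2)
            names.append("age2")
    if include_longevity:
        lv = df.longevity.to_numpy(dtype=float)
        cols.append((lv - lv.mean()) / lv.std())
        names.append("longevity")
    cols.append((df.sex.to_numpy() == "m").astype(float))
    names.append("sex_male")
    cols.append(df.breeding_status.to_numpy(dtype=float))
    names.append("breeding")
    jd = df.julian.to_numpy(dtype=float)
    cols.append((jd - jd.mean()) / (jd.std() if jd.std() else 1.0))
    names.append("julian_date")
    X = np.column_stack(cols)
    terms = [RandomTerm("winter", pd.factorize(df.winter_id)[0])]
    if include_bird:
        terms.append(RandomTerm("bird", pd.factorize(df.bird_id)[0]))
    return X, names, terms


def variance_inflation_factors(X: np.ndarray, names) -> pd.DataFrame:
    """VIF of each non-intercept column of a fixed-effect design."""
    rows = []
    keep = [i for i, n in enumerate(names) if n != "intercept"]
    for i in keep:
        others = [j for j in range(X.shape[1]) if j != i]
        xj = X[:, i]
        coef, *_ = np.linalg.lstsq(X[:, others], xj, rcond=None)
        resid = xj - X[:, others] @ coef
        tss = np.sum((xj - xj.mean()) ** 2)
        r2 = 1 - np.sum(resid**2) / tss if tss > 0 else 0.0
        rows.append(dict(term=names[i], vif=float(1 / max(1 - r2, 1e-12))))
    return pd.DataFrame(rows)


def plasticity_mortality_suite(units: pd.DataFrame, deaths: pd.DataFrame,
                               engine_options: dict | None = None) -> SuiteResult:
    """Four weighted binomial models separating within-individual ageing
    from selective disappearance.

    Restricted to confirmed-dead, juvenile-tagged birds (their longevity,
    the age at confirmed death in winters, is known exactly).  All models
    share sex, breeding status and a Julian-date covariate (days from
    Nov 1, standardised) with a winter random intercept and the unit
    weights; they differ in carrying age (quadratic), a bird random
    intercept, and longevity:

    ==================  ====  =========  ====
    model               age   longevity  bird
    ==================  ====  =========  ====
    age                 yes   no         no
    age_bird            yes   no         yes
    longevity_bird      no    yes        yes
    age_longevity_bird  yes   yes        yes
    ==================  ====  =========  ====

    An age effect that persists once longevity is in the model indicates
    behavioural plasticity; an additional longevity effect indicates
    selective mortality (both can operate).
    """
    engine_options = dict(engine_options or {})
    deaths = deaths.copy()
    df = units.merge(deaths[["bird_id", "longevity"]], on="bird_id", how="inner")
    if "tag_class" in df.columns:
        df = df[df.tag_class == "juvenile"]
    df = df[df.age.notna()].reset_index(drop=True)
    if not len(df):
        raise ValueError("no units from confirmed-dead juvenile-tagged birds")
    bad = df.groupby("bird_id").apply(
        lambda g: g.age.max() > g.longevity.iloc[0], include_groups=False)
    if bad.any():
        raise ValueError("longevity below last observed age for: "
                         + ", ".join(bad.index[bad]))
    df["julian"] = (df.interval_index.to_numpy(dtype=float) - 1) * 5 + 2.5

    have_longevity = df.longevity.nunique() >= 2
    if not have_longevity:
        warnings.warn("fewer than two longevity levels; longevity models skipped")
    # a two-point age range makes the quadratic term collinear with age
    quadratic_age = df.age.nunique() >= 3
    if not quadratic_age:
        warnings.warn("fewer than three age levels; quadratic age term dropped")

    plan = {
        "age": (True, False, False),
        "age_bird": (True, False, True),
        "longevity_bird": (False, True, True),
        "age_longevity_bird": (True, True, True),
    }
    w = df.weight.to_numpy(dtype=float) if "weight" in df.columns else None
    y = df.attendance.to_numpy(dtype=float)
    fits = {}
    comp_rows = []
    for name, (inc_age, inc_lon, inc_bird) in plan.items():
        if inc_lon and not have_longevity:
            continue
        X, names, terms = _suite_design(df, inc_age, inc_lon, inc_bird,
                                        quadratic_age)
        opts = dict(engine_options)
        # the interpretation reads only the final model's intervals; the
        # cheaper conditional covariance suffices for the others
        opts.setdefault("se_method",
                        "joint" if name == "age_longevity_bird" else "conditional")
        g = fit_glmm(y, X, terms, weights=w, fixed_names=names, **opts)
        fits[name] = g
        ci = g.wald_interval()
        for i, term in enumerate(names):
            comp_rows.append(dict(model=name, term=term,
                                  estimate=float(g.beta[i]),
                                  lower=float(ci[i, 0]), upper=float(ci[i, 1])))
    comparison = pd.DataFrame(comp_rows)

    X4, names4, _ = _suite_design(df, True, have_longevity, True,
                                  quadratic_age)
    vif = variance_inflation_factors(X4, names4)
    if (vif.vif >= 2).any():
        warnings.warn("variance inflation factor >= 2 among suite covariates")

    interpretation = "undetermined"
    if "age_longevity_bird" in fits:
        c = comparison[comparison.model == "age_longevity_bird"].set_index("term")
        age_persists = any(
            (c.loc[t, "lower"] > 0) or (c.loc[t, "upper"] < 0)
            for t in ("age", "age2") if t in c.index)
        lon_effect = (c.loc["longevity", "lower"] > 0) or (c.loc["longevity", "upper"] < 0)
        if age_persists and not lon_effect:
            interpretation = "plasticity"
        elif age_persists and lon_effect:
            interpretation = "both"
        elif lon_effect:
            interpretation = "selective_mortality"
        else:
            interpretation = "neither"
    return SuiteResult(fits=fits, comparison=comparison, vif=vif,
                       interpretation=interpretation,
                       n_birds=int(df.bird_id.nunique()))


def compare_models(fits: dict) -> pd.DataFrame:
    """Information-criterion comparison of fits on identical data.

    The criterion is an AIC-style approximation to the expected log
    predictive density based on the *marginal* (Laplace) likelihood:
    elpd ~= loglik - k, with k the number of fixed-effect plus variance
    parameters.  The conditional likelihood would flatter the more
    flexible random-effect structure, so it is not used for ranking;
    it only provides the pointwise spread behind the difference SEs.
    """
    items = list(fits.items())
    ref = items[0][1]
    for _, f in items[1:]:
        if len(f._y) != len(ref._y) or not np.allclose(f._y, ref._y) or \
                not np.allclose(f._weights, ref._weights):
            raise ValueError("models compare only on identical response and weights")
    rows = []
    pointwise = {}
    for name, f in items:
        k = f.n_fixed + f.n_theta
        pointwise[name] = f._weights * f.pointwise_loglik
        rows.append(dict(model=name, elpd=float(f.loglik - k), k=k))
    table = pd.DataFrame(rows).sort_values("elpd", ascending=False,
                                           ignore_index=True)
    best = table.model.iloc[0]
    diffs, ses = [], []
    for name in table.model:
        d = pointwise[best] - pointwise[name]
        diffs.append(float(table.elpd.iloc[0] - table.set_index("model")
                           .loc[name, "elpd"]))
        ses.append(float(np.sqrt(len(d) * np.var(d))))
    table["elpd_diff"] = diffs
    table["se_diff"] = ses
    return table
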