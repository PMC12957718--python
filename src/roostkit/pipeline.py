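"""Interchange formats, run configuration and the end-to-end pipeline.

Timestamps are stored UTC (ISO-8601) and interpreted on a fixed CET clock
for night assignment; interchange coordinates are WGS84 and planar metres
stay internal.  Every run writes a ``summary.json`` with a provenance
record (config hash, seed, package versions) and each CSV output carries
the provenance hash as a leading comment line.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .geo import TransverseMercator, polygon_to_planar, read_study_area
from .detection import (
    DetectionConfig,
    assign_intervals,
    attach_covariates,
    cluster_roost_sites,
    compute_weights,
    detect_attendance,
    extract_night_locations,
    project_coordinates,
)
from .models import (
    ModelSpec,
    adjusted_repeatability,
    binned_residuals,
    classification_accuracy,
    cramers_v,
    fit_attendance_model,
    plasticity_mortality_suite,
)
from .association import (
    build_relatedness_registry,
    classify_association_nights,
    observed_summaries,
    permute_nests,
    seasonal_association_trend,
)

log = logging.getLogger("roostkit")


def configure_logging(level=logging.INFO):
    """Structured logs to stderr (the CLI entry point calls this)."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter(
        "%(asctime)s %(name)s %(levelname)s %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(level)


class PipelineError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved."""

    def __init__(self, stage, cause):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


REQUIRED_FIX_COLUMNS = ("bird_id", "timestamp", "lon", "lat")


def read_fixes(path) -> pd.DataFrame:
    """Read a GPS-fix CSV (bird_id, timestamp, lon, lat).

    Rows with unparseable timestamps or coordinates are rejected; their
    1-based row numbers are logged and counted in ``df.attrs['n_malformed']``.
    Output is stably sorted by bird and time.
    """
    df = pd.read_csv(path, comment="#", dtype={"bird_id": str},
                     float_precision="round_trip")
    missing = [c for c in REQUIRED_FIX_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"fixes file {path} lacks columns: {missing}")
    ts = pd.to_datetime(df.timestamp, errors="coerce", utc=True, format="ISO8601")
    lon = pd.to_numeric(df.lon, errors="coerce")
    lat = pd.to_numeric(df.lat, errors="coerce")
    bad = ts.isna() | lon.isna() | lat.isna() | (lat.abs() > 90) | (lon.abs() > 180)
    if bad.any():
        rows = (np.flatnonzero(bad) + 2).tolist()  # 1-based incl. header
        log.warning("read_fixes: rejected %d malformed rows (lines %s%s)",
                    bad.sum(), rows[:10], "..." if len(rows) > 10 else "")
    out = pd.DataFrame(dict(bird_id=df.bird_id, timestamp=ts, lon=lon, lat=lat))
    out = out.loc[~bad].sort_values(["bird_id", "timestamp"], kind="stable",
                                    ignore_index=True)
    out.attrs["n_malformed"] = int(bad.sum())
    return out


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", float_precision="round_trip")


@dataclass
class RunConfig:
    """Paths, thresholds and switches of one pipeline run."""

    fixes: str = "fixes.csv"
    individuals: str = "individuals.csv"
    broods: str = "broods.csv"
    pairs: str = "pairs.csv"
    study_area: str = "study_area.geojson"
    out_dir: str = "roostkit_out"
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    projection_lon0: float | None = None    # default: study-area centroid
    projection_lat0: float | None = None
    n_permutations: int = 1000
    run_models: bool = True
    run_suite: bool = True
    run_associations: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        det = DetectionConfig(**raw.pop("detection", {}))
        return cls(detection=det, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def provenance_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path, prov: str):
    with open(path, "w") as fh:
        fh.write(f"# provenance: {prov}\n")
        df.to_csv(fh, index=False)


def derive_longevity(individuals: pd.DataFrame) -> pd.DataFrame:
    """Longevity (age in winters at confirmed death) for dead
    juvenile-tagged birds."""
    df = individuals.copy()
    df = df[(df.tag_class == "juvenile")]
    df = df[df.death_date.notna() & (df.death_date.astype(str) != "")]
    if not len(df):
        return pd.DataFrame(columns=["bird_id", "longevity"])
    dd = pd.to_datetime(df.death_date)
    by = pd.to_numeric(df.birth_year)
    longevity = (dd.dt.year - by + (dd.dt.month >= 11).astype(int)).clip(lower=1)
    return pd.DataFrame(dict(bird_id=df.bird_id, longevity=longevity.astype(int)))


def run_pipeline(config: RunConfig) -> dict:
    """Detect -> model -> suite -> associations, writing all stage outputs.

    Returns the summary report (also written to ``summary.json``).  A
    stage failure raises :class:`PipelineError` naming the stage; outputs
    of completed stages remain on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = config.provenance_hash()
    report: dict = {"provenance": {
        "config_hash": prov, "seed": config.seed,
        "roostkit_version": __version__,
        "numpy_version": np.__version__, "pandas_version": pd.__version__,
        "config": config.to_dict(),
    }, "stages": {}}

    def stage(name):
        def deco(fn):
            try:
                log.info("stage %s ...", name)
                fn()
            except Exception as e:  # noqa: BLE001 - reported with stage name
                _dump_summary(report, out)
                raise PipelineError(name, e) from e
        return deco

    state: dict = {}

    @stage("read")
    def _read():
        fixes = read_fixes(config.fixes)
        if not len(fixes):
            raise ValueError("no valid fixes")
        area_ll = read_study_area(config.study_area)
        c = area_ll.centroid
        projection = TransverseMercator(
            lon0=config.projection_lon0 if config.projection_lon0 is not None else c.x,
            lat0=config.projection_lat0 if config.projection_lat0 is not None else c.y,
        )
        state.update(fixes=fixes, projection=projection,
                     area=polygon_to_planar(area_ll, projection),
                     individuals=read_table(config.individuals),
                     broods=read_table(config.broods),
                     pairs=read_table(config.pairs))
        report["stages"]["read"] = dict(
            n_fixes=len(fixes), n_malformed=fixes.attrs.get("n_malformed", 0),
            n_individuals=len(state["individuals"]),
            projection=projection.spec)

    @stage("detect")
    def _detect():
        fixes = project_coordinates(state["fixes"], state["projection"])
        nights = extract_night_locations(fixes, config.detection)
        nights = assign_intervals(nights, config=config.detection)
        if not len(nights):
            raise ValueError("no night locations inside the seasonal window")
        night_counts, units = detect_attendance(nights, config.detection)
        units = compute_weights(units, nights, state["area"])
        units = attach_covariates(units, state["individuals"])
        sites = cluster_roost_sites(nights, config.detection.radius)
        state.update(nights=nights, units=units, night_counts=night_counts)
        _write_csv(nights, out / "night_locations.csv", prov)
        _write_csv(units, out / "interval_units.csv", prov)
        _write_csv(sites, out / "roost_sites.csv", prov)
        report["stages"]["detect"] = dict(
            n_nights=len(nights), n_units=len(units),
            attendance_rate=float(units.attendance.mean()),
            n_roost_sites=len(sites),
            pct_birds_ever_communal=float(
                100 * units.groupby("bird_id").attendance.max().mean()),
        )

    @stage("model")
    def _model():
        if not config.run_models:
            return
        units = state["units"]
        fits = {}
        mstats = {}
        for cohort, spec in (("juvenile", ModelSpec.juvenile()),
                             ("adult", ModelSpec.adult())):
            sub = units[units.tag_class == cohort]
            if not len(sub) or sub.bird_id.nunique() < 2 or sub.winter_id.nunique() < 2:
                log.warning("cohort %s too small; model skipped", cohort)
                continue
            fit = fit_attendance_model(sub, spec)
            fits[cohort] = fit
            rep_spec = ModelSpec(cohort=cohort, fixed=spec.fixed,
                                 random_bird_winter=False)
            rep_fit = fit_attendance_model(sub, rep_spec)
            mstats[cohort] = dict(
                coefficients=fit.summary.to_dict("records"),
                variance_components=fit.variance_components,
                accuracy=classification_accuracy(fit),
                repeatability=adjusted_repeatability(rep_fit)["R"],
                flags=fit.flags,
            )
            _write_csv(fit.summary, out / f"fit_summary_{cohort}.csv", prov)
            diag = out / "diagnostics"
            diag.mkdir(exist_ok=True)
            br = binned_residuals(fit, n_bins=min(20, len(sub)),
                                  plot_path=diag / f"binned_residuals_{cohort}.png")
            _write_csv(br, diag / f"binned_residuals_{cohort}.csv", prov)
        juv = units[(units.tag_class == "juvenile") & units.age.notna()]
        if len(juv) and juv.age.nunique() > 1 and juv.breeding_status.nunique() > 1:
            v, p = cramers_v(juv.age.astype(int), juv.breeding_status)
            mstats["cramers_v_age_breeding"] = dict(v=v, p=p)
        state["fits"] = fits
        report["stages"]["model"] = mstats

    @stage("suite")
    def _suite():
        if not config.run_suite:
            return
        deaths = derive_longevity(state["individuals"])
        units = state["units"]
        dead_units = units.merge(deaths, on="bird_id")
        if deaths.empty or dead_units.bird_id.nunique() < 5:
            log.warning("too few confirmed-dead birds; suite skipped")
            return
        suite = plasticity_mortality_suite(units, deaths)
        _write_csv(suite.comparison, out / "suite_summary.csv", prov)
        report["stages"]["suite"] = dict(
            n_birds=suite.n_birds, interpretation=suite.interpretation,
            max_vif=float(suite.vif.vif.max()))

    @stage("associations")
    def _assoc():
        if not config.run_associations:
            return
        registry = build_relatedness_registry(
            state["broods"], state["pairs"], state["individuals"],
            projection=state["projection"])
        assoc = classify_association_nights(state["nights"], registry,
                                            config.detection)
        _write_csv(assoc.records, out / "association_records.csv", prov)
        eligible = assoc.records[assoc.records.eligible == 1]
        if not len(eligible):
            log.warning("no eligible bird-nights; association tests skipped")
            return
        obs = observed_summaries(assoc.records)
        perm = permute_nests(assoc, n_iter=config.n_permutations,
                             seed=config.seed)
        _write_csv(perm, out / "permutation_results.csv", prov)
        trends = seasonal_association_trend(assoc)
        trend_rows = [dict(response=k, **{kk: vv for kk, vv in v.items()
                                          if kk != "fit"})
                      for k, v in trends.items() if v is not None]
        _write_csv(pd.DataFrame(trend_rows), out / "trend_fits.csv", prov)
        report["stages"]["associations"] = dict(
            n_eligible=int(len(eligible)),
            observed={k: (None if v != v else round(float(v), 3))
                      for k, v in obs.items()},
            permutation=perm.drop(columns=["p_label"]).to_dict("records"),
            trends={r["response"]: {k: v for k, v in r.items() if k != "response"}
                    for r in trend_rows},
        )

    _dump_summary(report, out)
    log.info("pipeline done -> %s", out / "summary.json")
    return report


def _dump_summary(report, out: Path):
    with open(out / "summary.json", "w") as fh:
        json.dump(report, fh, indent=1, default=_json_default, sort_keys=True)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.ndarray,)):
        return o.tolist()
    return str(o)
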