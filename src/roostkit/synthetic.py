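"""Seeded synthetic tracked population of wintering red kites.

Generates individuals (juvenile- and adult-tagged), broods, breeding pairs,
communal roost sites (major + satellite) and nightly GPS fixes over one or
more November--January winters, with a fully recorded generative truth so
that every downstream stage (night-location extraction, attendance
detection, mixed models, association permutation tests) has known
parameters to recover.

The attendance mechanism mirrors the structure of the attendance model:
a bird's latent probability of communal roosting in a five-night block is
the inverse logit of a linear predictor with fixed effects (standardised
age, age squared, sex, breeding status, a seasonal within-winter trend)
plus bird, winter and correlated bird-winter intercept/slope random
effects.  The latent state is drawn once per bird x five-night block and
holds for the block's nights, so the block-level model the pipeline fits
is exactly the generative model.

Attending birds roost at a communal site chosen with distance-decay
weights from their anchor (nest or natal home range); non-attending
breeders roost at their nest, co-locating with their mate; non-attending
non-breeders roost on a natal-nest-anchored home range.  Fixes follow the
tag duty cycle (07:00--21:00 local, hourly by default): evening fixes from
civil dusk, plus the 07:00 fix of the next morning when before civil dawn,
each with isotropic within-night scatter.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit
from shapely.geometry import Point, Polygon

from .geo import TransverseMercator, polygon_to_lonlat, write_study_area

# Five-night blocks anchored at Nov 1: 19 per winter (the last has 2 nights).
N_INTERVALS = 19
INTERVAL_INDEX_MEAN = 10.0
INTERVAL_INDEX_SD = float(np.std(np.arange(1, N_INTERVALS + 1)))


def standardize_interval_index(index):
    """Fixed within-winter standardisation of the 5-night block index (1..19)."""
    return (np.asarray(index, dtype=float) - INTERVAL_INDEX_MEAN) / INTERVAL_INDEX_SD


def _default_migration_table() -> dict:
    # Probability a bird spends the whole winter away from the study region
    # (partial migration: first-winter birds and females migrate most).
    return {
        ("f", 1): 0.70, ("m", 1): 0.60,
        ("f", 2): 0.50, ("m", 2): 0.35,
        ("f", 3): 0.40, ("m", 3): 0.25,
        ("f", 4): 0.30, ("m", 4): 0.15,
        ("f", "adult"): 0.30, ("m", "adult"): 0.15,
    }


def _default_mortality_table() -> dict:
    # Annual mortality by age (winters); first-year mortality is high.
    return {1: 0.45, 2: 0.22, 3: 0.15, "older": 0.10, "adult": 0.10}


@dataclass
class PopulationConfig:
    """Generative settings for the synthetic tracked population."""

    n_juvenile_tagged: int = 148
    n_adult_tagged: int = 68
    sex_ratio: float = 0.5              # proportion of males
    n_winters: int = 6
    first_winter_year: int = 2016
    # juvenile cohorts may predate the first winter by this many years, so a
    # short monitoring window can still hold the age mix of a longer study
    cohort_years_before: int = 0
    study_area_km2: float = 387.0
    n_major_roosts: int = 3
    n_satellite_roosts: int = 5
    roost_size_mean_nov: float = 54.0   # national-count scale (incl. untagged)
    roost_size_mean_jan: float = 40.0
    within_night_scatter_sd: float = 11.3   # m per coordinate; median pairwise ~ 18.9 m
    fix_interval_minutes: int = 60
    duty_window: tuple = (7, 21)        # local clock hours (CET)
    migration_absence_prob: dict = field(default_factory=_default_migration_table)
    annual_mortality_prob: dict = field(default_factory=_default_mortality_table)
    seed: int = 0

    # placement parameters (metres)
    satellite_max_distance: float = 2000.0
    satellite_min_distance: float = 500.0
    roost_choice_scale: float = 5000.0      # exp(-d / scale) site weights
    roost_spread_sd: float = 40.0           # scatter of birds within a site
    nest_jitter_sd: float = 30.0
    home_range_offset_sd: float = 1500.0
    home_night_sd: float = 60.0
    mate_displacement_sd: float = 700.0
    # projection anchor (western Switzerland)
    lon0: float = 7.2
    lat0: float = 46.75
    # no-assortment switch: positions become independent of the registry
    # geometry (random home anchors for everyone, no pair/kin co-location),
    # so node-permutation p-values should be uniform -- the type-I
    # calibration setting
    assortment: bool = True

    def __post_init__(self):
        for name in ("n_juvenile_tagged", "n_adult_tagged", "n_winters",
                     "n_major_roosts", "n_satellite_roosts"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_juvenile_tagged + self.n_adult_tagged <= 0:
            raise ValueError("population must contain at least one bird")
        if not 0 <= self.sex_ratio <= 1:
            raise ValueError("sex_ratio must be in [0, 1]")
        for table in (self.migration_absence_prob, self.annual_mortality_prob):
            for v in table.values():
                if not 0 <= v <= 1:
                    raise ValueError("probabilities must be in [0, 1]")
        if not (0 <= self.duty_window[0] < self.duty_window[1] <= 24):
            raise ValueError("duty window must be an interval within the day")


@dataclass
class AttendanceTruth:
    """Generative attendance parameters (log-odds scale).

    Defaults follow the juvenile-cohort estimates of the winter communal
    roosting analysis this package reproduces: intercept -0.441, age -0.27,
    age^2 -0.453, male +1.731, breeder -1.296, with random-effect SDs
    1.624 (bird), 1.852 / 1.394 (bird-winter intercept / slope,
    correlation -0.581) and 0.345 (winter).  Age enters standardised as
    (age - age_center) / age_scale.
    """

    beta_intercept: float = -0.441
    beta_age: float = -0.27
    beta_age2: float = -0.453
    beta_sex_male: float = 1.731
    beta_breeding: float = -1.296
    sd_bird: float = 1.624
    sd_bird_winter: float = 1.852
    sd_slope: float = 1.394
    sd_winter: float = 0.345
    cor_intercept_slope: float = -0.581
    seasonal_logit_slope: float = -0.15   # per standardised block index
    pair_coroost_prob: float = 0.7
    kin_coroost_prob: float = 0.05
    age_center: float = 3.0
    age_scale: float = 1.5

    def __post_init__(self):
        for name in ("sd_bird", "sd_bird_winter", "sd_slope", "sd_winter"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not -1 <= self.cor_intercept_slope <= 1:
            raise ValueError("correlation must be in [-1, 1]")
        for name in ("pair_coroost_prob", "kin_coroost_prob"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")

    def linear_predictor(self, age, male, breeding, z_seq):
        z_age = (np.asarray(age, dtype=float) - self.age_center) / self.age_scale
        return (
            self.beta_intercept
            + self.beta_age * z_age
            + self.beta_age2 * z_age**2
            + self.beta_sex_male * np.asarray(male, dtype=float)
            + self.beta_breeding * np.asarray(breeding, dtype=float)
            + self.seasonal_logit_slope * np.asarray(z_seq, dtype=float)
        )


@dataclass
class Population:
    """Generated individuals, registries and geography."""

    individuals: pd.DataFrame   # bird_id, sex, tag_class, birth_year, tag_year,
                                # natal_nest_id, first_breeding_year, breeding_nest_id,
                                # death_date, mate_id
    broods: pd.DataFrame        # nest_id, year, bird_id
    pairs: pd.DataFrame         # year, bird_id_1, bird_id_2, nest_id
    roost_sites: pd.DataFrame   # site_id, kind, x, y
    nests: pd.DataFrame         # nest_id, x, y
    presence: pd.DataFrame      # bird_id, winter_id, present (0/1 migration)
    study_area: Polygon         # planar metres
    projection: TransverseMercator
    config: PopulationConfig
    truth_params: AttendanceTruth


@dataclass
class TruthTable:
    """Latent generative state for every emitted bird-night."""

    nights: pd.DataFrame    # bird_id, winter_id, night_date, interval_index,
                            # attend, site_id, x, y, eta, p
    effects: pd.DataFrame   # bird_id, winter_id, effect, value


def _winter_age(winter_id, birth_year):
    """Age counted in winter seasons (first winter after fledging = 1)."""
    return winter_id - birth_year + 1


def _square_study_area(area_km2: float) -> Polygon:
    side = math.sqrt(area_km2 * 1e6)
    return Polygon([(0, 0), (side, 0), (side, side), (0, side)])


def _random_point_in(polygon: Polygon, rng) -> np.ndarray:
    minx, miny, maxx, maxy = polygon.bounds
    while True:
        p = rng.uniform([minx, miny], [maxx, maxy])
        if polygon.contains(Point(p)):
            return p


def generate_population(
    config: PopulationConfig,
    truth: AttendanceTruth | None = None,
    seed: int | None = None,
) -> Population:
    """Generate individuals, broods, pairs, nests and roost sites.

    Deterministic given the seed (``config.seed`` unless overridden).
    """
    truth = truth if truth is not None else AttendanceTruth()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    area = _square_study_area(config.study_area_km2)
    proj = TransverseMercator(
        lon0=config.lon0, lat0=config.lat0,
        false_easting=math.sqrt(config.study_area_km2 * 1e6) / 2,
        false_northing=math.sqrt(config.study_area_km2 * 1e6) / 2,
    )
    years = list(range(config.first_winter_year,
                       config.first_winter_year + config.n_winters))

    # --- roost sites -------------------------------------------------------
    sites = []
    majors = []
    for i in range(config.n_major_roosts):
        for _ in range(1000):
            p = _random_point_in(area, rng)
            if all(np.hypot(*(p - q)) > 3000 for q in majors):
                break
        majors.append(p)
        sites.append((f"R{i:02d}", "major", p[0], p[1]))
    for j in range(config.n_satellite_roosts):
        if not majors:
            raise ValueError("satellite roosts require at least one major roost")
        anchor = majors[rng.integers(len(majors))]
        for _ in range(1000):
            d = rng.uniform(config.satellite_min_distance, config.satellite_max_distance)
            th = rng.uniform(0, 2 * math.pi)
            p = anchor + d * np.array([math.cos(th), math.sin(th)])
            if area.contains(Point(p)):
                break
        sites.append((f"S{j:02d}", "satellite", p[0], p[1]))
    roost_sites = pd.DataFrame(sites, columns=["site_id", "kind", "x", "y"])

    # --- adults ------------------------------------------------------------
    nests = {}

    def new_nest():
        nid = f"N{len(nests):04d}"
        nests[nid] = _random_point_in(area, rng)
        return nid

    rows = []
    n_adult_m = int(round(config.n_adult_tagged * config.sex_ratio))
    adult_sexes = ["m"] * n_adult_m + ["f"] * (config.n_adult_tagged - n_adult_m)
    rng.shuffle(adult_sexes)
    for i, sex in enumerate(adult_sexes):
        tag_year = int(rng.choice(years))
        rows.append(dict(
            bird_id=f"A{i:03d}", sex=sex, tag_class="adult",
            birth_year=pd.NA, tag_year=tag_year, natal_nest_id=pd.NA,
            first_breeding_year=tag_year, breeding_nest_id=pd.NA,
            death_date=pd.NA, mate_id=pd.NA,
        ))
    adults = pd.DataFrame(rows) if rows else pd.DataFrame(
        columns=["bird_id", "sex", "tag_class", "birth_year", "tag_year",
                 "natal_nest_id", "first_breeding_year", "breeding_nest_id",
                 "death_date", "mate_id"])

    # pair tagged adults with each other where possible
    pair_records = []
    if len(adults):
        males = list(adults.index[adults.sex == "m"])
        females = list(adults.index[adults.sex == "f"])
        rng.shuffle(males)
        rng.shuffle(females)
        n_pairs = int(min(len(males), len(females)) * 0.5)
        for mi, fi in zip(males[:n_pairs], females[:n_pairs]):
            nid = new_nest()
            adults.loc[mi, ["breeding_nest_id", "mate_id"]] = [nid, adults.loc[fi, "bird_id"]]
            adults.loc[fi, ["breeding_nest_id", "mate_id"]] = [nid, adults.loc[mi, "bird_id"]]
        for idx in adults.index:
            if pd.isna(adults.loc[idx, "breeding_nest_id"]):
                adults.loc[idx, "breeding_nest_id"] = new_nest()  # untagged mate

    # --- juveniles in broods ----------------------------------------------
    juv_rows = []
    brood_rows = []
    adult_pairs = adults.dropna(subset=["mate_id"]) if len(adults) else adults
    n_left = config.n_juvenile_tagged
    b = 0
    cohort_years = list(range(config.first_winter_year - config.cohort_years_before,
                              config.first_winter_year + config.n_winters))
    while n_left > 0:
        size = int(rng.choice([1, 2, 3], p=[0.30, 0.45, 0.25]))
        size = min(size, n_left)
        year = int(rng.choice(cohort_years))
        # occasionally the brood belongs to a tagged pair breeding that year
        nest_id = None
        if len(adult_pairs):
            cands = adult_pairs[(adult_pairs.tag_year <= year) & (adult_pairs.sex == "m")]
            if len(cands) and rng.random() < 0.25:
                nest_id = cands.iloc[rng.integers(len(cands))]["breeding_nest_id"]
        if nest_id is None:
            nest_id = new_nest()
        for _ in range(size):
            bird_id = f"J{len(juv_rows):03d}"
            sex = "m" if rng.random() < config.sex_ratio else "f"
            settle_age = max(3, int(round(rng.normal(4.14, 0.90))))
            juv_rows.append(dict(
                bird_id=bird_id, sex=sex, tag_class="juvenile",
                birth_year=year, tag_year=year, natal_nest_id=nest_id,
                first_breeding_year=year + settle_age - 1,
                breeding_nest_id=pd.NA, death_date=pd.NA, mate_id=pd.NA,
            ))
            brood_rows.append(dict(nest_id=nest_id, year=year, bird_id=bird_id))
        n_left -= size
        b += 1
    juveniles = pd.DataFrame(juv_rows) if juv_rows else adults.iloc[0:0].copy()
    individuals = pd.concat([juveniles, adults], ignore_index=True)

    # juvenile breeders: assign a nest; pair some with unpaired tagged breeders
    unpaired = list(individuals.index[
        individuals.mate_id.isna() & (individuals.tag_class == "adult")])
    for idx in individuals.index[individuals.tag_class == "juvenile"]:
        row = individuals.loc[idx]
        if row.first_breeding_year >= years[0] + config.n_winters + 2:
            continue  # never breeds within horizon, no nest needed
        partner = None
        if unpaired and rng.random() < 0.5:
            opp = [j for j in unpaired if individuals.loc[j, "sex"] != row.sex]
            if opp:
                partner = opp[rng.integers(len(opp))]
                unpaired.remove(partner)
        if partner is not None:
            nid = individuals.loc[partner, "breeding_nest_id"]
            individuals.loc[idx, ["breeding_nest_id", "mate_id"]] = [
                nid, individuals.loc[partner, "bird_id"]]
            individuals.loc[partner, "mate_id"] = row.bird_id
        else:
            individuals.loc[idx, "breeding_nest_id"] = new_nest()

    # --- mortality ---------------------------------------------------------
    mort = config.annual_mortality_prob
    for idx in individuals.index:
        row = individuals.loc[idx]
        for year in years:
            if year < row.tag_year:
                continue
            if row.tag_class == "adult":
                p = mort.get("adult", mort.get("older", 0.1))
            else:
                age = _winter_age(year, row.birth_year)
                p = mort.get(age, mort.get("older", 0.1))
            if rng.random() < p:
                day = int(rng.integers(0, 365))
                individuals.loc[idx, "death_date"] = (
                    pd.Timestamp(year=year, month=2, day=1) + pd.Timedelta(days=day))
                break

    # --- migration presence -----------------------------------------------
    # Migrants are only partially absent: they either leave late (present
    # early in the winter) or return early (present late in the winter).
    mig = config.migration_absence_prob
    pres_rows = []
    for idx in individuals.index:
        row = individuals.loc[idx]
        for year in years:
            if year < row.tag_year:
                continue
            if row.tag_class == "adult":
                key = (row.sex, "adult")
            else:
                age = _winter_age(year, row.birth_year)
                key = (row.sex, min(age, max(k[1] for k in mig if isinstance(k[1], int))))
            p_away = mig.get(key, 0.2)
            if rng.random() < p_away:
                if rng.random() < 0.5:   # late departure
                    first, last = 0, int(rng.integers(10, 46))
                else:                    # early return
                    first, last = int(rng.integers(45, 81)), 91
            else:
                first, last = 0, 91
            pres_rows.append(dict(bird_id=row.bird_id, winter_id=year,
                                  present=1, first_day=first, last_day=last))
    presence = pd.DataFrame(pres_rows)

    # --- registries --------------------------------------------------------
    broods = pd.DataFrame(brood_rows, columns=["nest_id", "year", "bird_id"])
    pair_records = []
    seen = set()
    for idx in individuals.index:
        row = individuals.loc[idx]
        if pd.isna(row.mate_id) or row.bird_id in seen:
            continue
        mate = individuals[individuals.bird_id == row.mate_id].iloc[0]
        seen.update({row.bird_id, mate.bird_id})
        start = int(max(row.first_breeding_year, mate.first_breeding_year))
        for year in years:
            if year < start:
                continue
            dead_row = pd.notna(row.death_date) and pd.Timestamp(row.death_date) < pd.Timestamp(year=year, month=11, day=1)
            dead_mate = pd.notna(mate.death_date) and pd.Timestamp(mate.death_date) < pd.Timestamp(year=year, month=11, day=1)
            if dead_row or dead_mate:
                continue
            pair_records.append(dict(year=year, bird_id_1=row.bird_id,
                                     bird_id_2=mate.bird_id,
                                     nest_id=row.breeding_nest_id))
    pairs = pd.DataFrame(pair_records,
                         columns=["year", "bird_id_1", "bird_id_2", "nest_id"])

    nests_df = pd.DataFrame(
        [(nid, xy[0], xy[1]) for nid, xy in nests.items()],
        columns=["nest_id", "x", "y"],
    )

    # impossible-config guard: breeders need nests inside the area
    if len(nests_df) == 0 and (individuals.first_breeding_year.notna().any()):
        if config.n_juvenile_tagged + config.n_adult_tagged > 0 and area.area <= 0:
            raise ValueError("study area cannot host any nest")

    return Population(
        individuals=individuals, broods=broods, pairs=pairs,
        roost_sites=roost_sites, nests=nests_df, presence=presence,
        study_area=area, projection=proj, config=config, truth_params=truth,
    )


# ---------------------------------------------------------------------------
# Night simulation
# ---------------------------------------------------------------------------

def winter_nights(year: int):
    """The 92 nights of a Nov 1 -- Jan 31 winter, as a DatetimeIndex."""
    return pd.date_range(f"{year}-11-01", f"{year + 1}-01-31", freq="D")


def night_interval_index(night_dates, winter_year):
    """1-based five-night block index since Nov 1 of the winter."""
    anchor = pd.Timestamp(year=winter_year, month=11, day=1)
    days = (pd.DatetimeIndex(night_dates) - anchor).days
    return (days // 5 + 1).astype(int)


def simulate_winter_nights(
    pop: Population,
    truth: AttendanceTruth | None = None,
    config: PopulationConfig | None = None,
    seed: int | None = None,
):
    """Simulate nightly roosting decisions, positions and GPS fixes.

    Returns ``(fixes, truth_table)``.  ``fixes`` has columns bird_id,
    timestamp (UTC), lon, lat, x, y; ``truth_table`` records the latent
    attendance state, roost site and nightly position of every bird-night
    plus all random-effect draws.
    """
    truth = truth if truth is not None else pop.truth_params
    config = config if config is not None else pop.config
    rng = np.random.default_rng((config.seed if seed is None else seed) + 1)

    ind = pop.individuals.set_index("bird_id")
    nest_xy = pop.nests.set_index("nest_id")[["x", "y"]] if len(pop.nests) else pd.DataFrame(columns=["x", "y"])
    site_xy = pop.roost_sites[["x", "y"]].to_numpy() if len(pop.roost_sites) else np.zeros((0, 2))
    years = list(range(config.first_winter_year,
                       config.first_winter_year + config.n_winters))

    # static per-bird anchors and bird-level random effects
    bird_ids = list(ind.index)
    n_birds = len(bird_ids)
    a_bird = rng.normal(0, truth.sd_bird, n_birds)
    anchors = np.zeros((n_birds, 2))
    home_centers = np.zeros((n_birds, 2))
    for i, bid in enumerate(bird_ids):
        row = ind.loc[bid]
        if pd.notna(row.natal_nest_id) and row.natal_nest_id in nest_xy.index:
            base = nest_xy.loc[row.natal_nest_id].to_numpy(dtype=float)
        elif pd.notna(row.breeding_nest_id) and row.breeding_nest_id in nest_xy.index:
            base = nest_xy.loc[row.breeding_nest_id].to_numpy(dtype=float)
        else:
            base = _random_point_in(pop.study_area, rng)
        if config.assortment:
            home_centers[i] = base + rng.normal(0, config.home_range_offset_sd, 2)
            anchors[i] = base
        else:
            home_centers[i] = _random_point_in(pop.study_area, rng)
            anchors[i] = home_centers[i]

    cov = np.array([
        [truth.sd_bird_winter**2,
         truth.cor_intercept_slope * truth.sd_bird_winter * truth.sd_slope],
        [truth.cor_intercept_slope * truth.sd_bird_winter * truth.sd_slope,
         truth.sd_slope**2],
    ])
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(2))

    presence = pop.presence.set_index(["bird_id", "winter_id"])
    pairs_by_year = {y: g for y, g in pop.pairs.groupby("year")} if len(pop.pairs) else {}
    sib_map = {}
    for _, g in pop.broods.groupby(["nest_id", "year"]):
        members = list(g.bird_id)
        for m in members:
            sib_map.setdefault(m, set()).update(x for x in members if x != m)
    parent_map = {}
    for _, brood in pop.broods.iterrows():
        pr = pop.pairs[(pop.pairs.nest_id == brood.nest_id) & (pop.pairs.year == brood.year)]
        for _, p in pr.iterrows():
            parent_map.setdefault(brood.bird_id, set()).update({p.bird_id_1, p.bird_id_2})

    effect_rows = [dict(bird_id=b, winter_id=-1, effect="bird_intercept", value=v)
                   for b, v in zip(bird_ids, a_bird)]
    night_frames = []
    fix_frames = []

    z_seq_all = standardize_interval_index(np.arange(1, N_INTERVALS + 1))

    for year in years:
        w_eff = rng.normal(0, truth.sd_winter)
        effect_rows.append(dict(bird_id="", winter_id=year,
                                effect="winter_intercept", value=w_eff))
        nights = winter_nights(year)
        n_nights = len(nights)
        iidx = night_interval_index(nights, year)

        # which birds are tracked this winter, and their presence window
        active = []
        windows = []
        for i, bid in enumerate(bird_ids):
            row = ind.loc[bid]
            if row.tag_year > year:
                continue
            if pd.notna(row.death_date) and pd.Timestamp(row.death_date) < nights[0]:
                continue
            try:
                prow = presence.loc[(bid, year)]
            except KeyError:
                continue
            if int(prow.present) == 0:
                continue
            windows.append((int(prow.get("first_day", 0)),
                            int(prow.get("last_day", n_nights - 1))))
            active.append(i)
        if not active:
            continue
        active = np.array(active)
        n_act = len(active)
        windows = np.array(windows)

        bw = rng.standard_normal((n_act, 2)) @ chol.T
        for j, i in enumerate(active):
            effect_rows.append(dict(bird_id=bird_ids[i], winter_id=year,
                                    effect="bw_intercept", value=bw[j, 0]))
            effect_rows.append(dict(bird_id=bird_ids[i], winter_id=year,
                                    effect="bw_slope", value=bw[j, 1]))

        male = np.array([ind.loc[bird_ids[i], "sex"] == "m" for i in active], dtype=float)
        breeding = np.zeros(n_act)
        age = np.zeros(n_act)
        for j, i in enumerate(active):
            row = ind.loc[bird_ids[i]]
            breeding[j] = float(pd.notna(row.first_breeding_year)
                                and row.first_breeding_year <= year)
            if row.tag_class == "juvenile":
                age[j] = _winter_age(year, row.birth_year)
            else:
                age[j] = np.nan  # unknown; adults use the age-free predictor

        # latent per-interval attendance
        eta_int = np.zeros((n_act, N_INTERVALS))
        for k in range(N_INTERVALS):
            z = z_seq_all[k]
            age_term = np.where(np.isnan(age), 0.0,
                                np.nan_to_num(
                                    truth.beta_age * (age - truth.age_center) / truth.age_scale
                                    + truth.beta_age2 * ((age - truth.age_center) / truth.age_scale) ** 2))
            eta_int[:, k] = (
                truth.beta_intercept
                + age_term
                + truth.beta_sex_male * male
                + truth.beta_breeding * breeding
                + truth.seasonal_logit_slope * z
                + a_bird[active] + w_eff + bw[:, 0] + bw[:, 1] * z
            )
        attend_int = (rng.random((n_act, N_INTERVALS)) < expit(eta_int)).astype(int)

        # site-choice weights per bird (distance decay from the anchor)
        if len(site_xy):
            d = np.hypot(anchors[active, 0][:, None] - site_xy[None, :, 0],
                         anchors[active, 1][:, None] - site_xy[None, :, 1])
            site_w = np.exp(-d / config.roost_choice_scale)
            site_w /= site_w.sum(axis=1, keepdims=True)
            site_cum = np.cumsum(site_w, axis=1)

        death = np.array([
            np.datetime64(pd.Timestamp(ind.loc[bird_ids[i], "death_date"]), "D")
            if pd.notna(ind.loc[bird_ids[i], "death_date"]) else np.datetime64("2200-01-01")
            for i in active
        ])

        pos = np.full((n_act, n_nights, 2), np.nan)
        site_of = np.full((n_act, n_nights), -1, dtype=int)
        alive = (np.asarray(nights.values, dtype="datetime64[D]")[None, :] < death[:, None])
        day_idx = np.arange(n_nights)[None, :]
        alive &= (day_idx >= windows[:, 0][:, None]) & (day_idx <= windows[:, 1][:, None])
        attend_night = attend_int[:, iidx - 1].astype(bool) & alive
        if len(site_xy) == 0:
            attend_night[:] = False

        # attending birds at a chosen communal site
        if len(site_xy):
            u = rng.random((n_act, n_nights))
            choice = (u[:, :, None] > site_cum[:, None, :]).sum(axis=2)
            jj, nn = np.where(attend_night)
            site_of[jj, nn] = choice[jj, nn]
            pos[jj, nn] = site_xy[choice[jj, nn]] + rng.normal(
                0, config.roost_spread_sd, (len(jj), 2))

        # non-attending: breeders at nest, others on home range
        id_to_j = {bird_ids[i]: j for j, i in enumerate(active)}
        nest_pos = np.zeros((n_act, 2))
        for j, i in enumerate(active):
            row = ind.loc[bird_ids[i]]
            if config.assortment and breeding[j] and pd.notna(row.breeding_nest_id) \
                    and row.breeding_nest_id in nest_xy.index:
                nest_pos[j] = nest_xy.loc[row.breeding_nest_id].to_numpy(dtype=float)
            else:
                nest_pos[j] = home_centers[i]
        non = (~attend_night) & alive
        jj, nn = np.where(non)
        is_breeder = breeding[jj] > 0
        jitter = rng.normal(0, 1, (len(jj), 2))
        pos[jj[is_breeder], nn[is_breeder]] = (
            nest_pos[jj[is_breeder]] + jitter[is_breeder] * config.nest_jitter_sd)
        pos[jj[~is_breeder], nn[~is_breeder]] = (
            nest_pos[jj[~is_breeder]] + jitter[~is_breeder] * config.home_night_sd)

        # mate co-roosting: when both pair members are non-attending, they sit
        # at the shared nest with prob pair_coroost_prob, otherwise one is
        # displaced off-territory for the night
        year_pairs = pairs_by_year.get(year) if config.assortment else None
        if year_pairs is not None:
            for _, prow in year_pairs.iterrows():
                j1 = id_to_j.get(prow.bird_id_1)
                j2 = id_to_j.get(prow.bird_id_2)
                if j1 is None or j2 is None:
                    continue
                both_non = non[j1] & non[j2]
                nts = np.where(both_non)[0]
                if len(nts) == 0:
                    continue
                apart = nts[rng.random(len(nts)) >= truth.pair_coroost_prob]
                if len(apart):
                    which = rng.random(len(apart)) < 0.5
                    moved = np.where(which, j1, j2)
                    disp = rng.normal(0, config.mate_displacement_sd, (len(apart), 2))
                    small = np.hypot(disp[:, 0], disp[:, 1]) < 400
                    disp[small] *= 3.0
                    for m, nt, dxy in zip(moved, apart, disp):
                        pos[m, nt] = pos[m, nt] + dxy

        # occasional kin co-roosting for non-attending non-breeders
        if truth.kin_coroost_prob > 0 and config.assortment:
            for j, i in enumerate(active):
                bid = bird_ids[i]
                kin = (sib_map.get(bid, set()) | parent_map.get(bid, set()))
                kin_js = [id_to_j[k] for k in sorted(kin) if k in id_to_j]
                if not kin_js or breeding[j]:
                    continue
                nts = np.where(non[j])[0]
                if not len(nts):
                    continue
                move = nts[rng.random(len(nts)) < truth.kin_coroost_prob]
                for nt in move:
                    kj = kin_js[rng.integers(len(kin_js))]
                    if alive[kj, nt] and np.isfinite(pos[kj, nt, 0]):
                        pos[j, nt] = pos[kj, nt] + rng.normal(0, 25, 2)

        # truth rows
        jj, nn = np.where(alive)
        night_frames.append(pd.DataFrame(dict(
            bird_id=[bird_ids[active[j]] for j in jj],
            winter_id=year,
            night_date=nights[nn],
            interval_index=iidx[nn],
            attend=attend_night[jj, nn].astype(int),
            site_id=[
                pop.roost_sites.site_id.iloc[s] if s >= 0 else ""
                for s in site_of[jj, nn]
            ],
            x=pos[jj, nn, 0], y=pos[jj, nn, 1],
            eta=eta_int[jj, iidx[nn] - 1],
            p=expit(eta_int[jj, iidx[nn] - 1]),
        )))

        # fixes on the duty cycle
        fix_frames.append(_emit_fixes(pop, config, rng, nights, pos, alive,
                                      [bird_ids[i] for i in active]))

    empty_nights = pd.DataFrame(columns=[
        "bird_id", "winter_id", "night_date", "interval_index", "attend",
        "site_id", "x", "y", "eta", "p"])
    nights_df = (pd.concat(night_frames, ignore_index=True)
                 if night_frames else empty_nights)
    empty_fixes = pd.DataFrame(columns=["bird_id", "timestamp", "lon", "lat", "x", "y"])
    fixes_df = (pd.concat([f for f in fix_frames if len(f)], ignore_index=True)
                if any(len(f) for f in fix_frames) else empty_fixes)
    if len(fixes_df):
        fixes_df = fixes_df.sort_values(["bird_id", "timestamp"], kind="stable",
                                        ignore_index=True)
    effects_df = pd.DataFrame(effect_rows)
    return fixes_df, TruthTable(nights=nights_df, effects=effects_df)


def _emit_fixes(pop, config, rng, nights, pos, alive, active_ids):
    """Duty-cycle fixes for one winter: evening fixes from civil dusk to the
    duty end, plus next-morning fixes from the duty start until civil dawn."""
    from .geo import twilight_times

    n_act, n_nights = pos.shape[0], len(nights)
    cx, cy = pop.study_area.centroid.x, pop.study_area.centroid.y
    clon, clat = pop.projection.inverse(cx, cy)
    duty_start, duty_end = config.duty_window
    step_h = config.fix_interval_minutes / 60.0

    rows_bird, rows_time, rows_x, rows_y = [], [], [], []
    for k, night in enumerate(nights):
        d = night.date()
        dawn2, _ = twilight_times(d + timedelta(days=1), clon, clat)
        _, dusk = twilight_times(d, clon, clat)
        # local (CET) fractional hours of dusk and next dawn
        dusk_h = (pd.Timestamp(dusk) + pd.Timedelta(hours=1)) - pd.Timestamp(d)
        dusk_h = dusk_h.total_seconds() / 3600.0
        dawn_h = (pd.Timestamp(dawn2) + pd.Timedelta(hours=1)) - pd.Timestamp(d + timedelta(days=1))
        dawn_h = dawn_h.total_seconds() / 3600.0
        evening = np.arange(math.ceil(dusk_h / step_h) * step_h, duty_end + 1e-9, step_h)
        morning = np.arange(duty_start, min(dawn_h, duty_end) - 1e-9, step_h)
        offsets = np.concatenate([evening, 24.0 + morning])  # hours after local midnight of d
        who = np.where(alive[:, k] & np.isfinite(pos[:, k, 0]))[0]
        if not len(who) or not len(offsets):
            continue
        # UTC timestamps (CET = UTC+1)
        t0 = pd.Timestamp(d, tz="UTC") - pd.Timedelta(hours=1)
        times = t0 + pd.to_timedelta(offsets, unit="h")
        for j in who:
            rows_bird.extend([active_ids[j]] * len(times))
            rows_time.append(times)
            noise = rng.normal(0, config.within_night_scatter_sd, (len(times), 2))
            rows_x.append(pos[j, k, 0] + noise[:, 0])
            rows_y.append(pos[j, k, 1] + noise[:, 1])
    if not rows_bird:
        return pd.DataFrame(columns=["bird_id", "timestamp", "lon", "lat", "x", "y"])
    x = np.concatenate(rows_x)
    y = np.concatenate(rows_y)
    lon, lat = pop.projection.inverse(x, y)
    return pd.DataFrame(dict(
        bird_id=rows_bird,
        timestamp=pd.DatetimeIndex(np.concatenate([t.values for t in rows_time])).tz_localize("UTC"),
        lon=lon, lat=lat, x=x, y=y,
    ))


# ---------------------------------------------------------------------------
# Truth-derived modelling units and summaries
# ---------------------------------------------------------------------------

def truth_interval_units(truth: TruthTable, pop: Population) -> pd.DataFrame:
    """Latent bird x winter x five-night-block units (weight 1).

    The block-level latent attendance state is constant within a block by
    construction, so these units realise the generative model exactly;
    they are the input for parameter-recovery checks.
    """
    tn = truth.nights
    if not len(tn):
        return pd.DataFrame(columns=[
            "bird_id", "winter_id", "interval_index", "attendance", "weight",
            "age", "sex", "breeding_status", "n_nights_observed"])
    g = tn.groupby(["bird_id", "winter_id", "interval_index"], as_index=False).agg(
        attendance=("attend", "max"), n_nights_observed=("attend", "size"))
    ind = pop.individuals.set_index("bird_id")
    g["sex"] = ind.sex.reindex(g.bird_id).to_numpy()
    tc = ind.tag_class.reindex(g.bird_id).to_numpy()
    by = ind.birth_year.reindex(g.bird_id).to_numpy()
    fb = ind.first_breeding_year.reindex(g.bird_id).to_numpy()
    age = np.where(tc == "juvenile",
                   g.winter_id.to_numpy() - pd.array(by, dtype="Float64").to_numpy(dtype=float) + 1,
                   np.nan)
    g["age"] = age
    g["tag_class"] = tc
    fbf = pd.array(fb, dtype="Float64").to_numpy(dtype=float)
    g["breeding_status"] = (
        np.nan_to_num(fbf, nan=np.inf) <= g.winter_id.to_numpy()).astype(int)
    g["weight"] = 1.0
    return g


def median_within_night_scatter(fixes: pd.DataFrame, max_nights: int = 2000,
                                seed: int = 0) -> float:
    """Median over bird-nights of the median pairwise distance between a
    night's fixes (planar metres); the empirical counterpart of the
    within-night GPS scatter."""
    df = fixes.copy()
    local = pd.DatetimeIndex(df.timestamp).tz_convert("UTC") + pd.Timedelta(hours=1)
    # fixes before noon belong to the previous night
    df["night"] = (local - pd.Timedelta(hours=12)).date
    rng = np.random.default_rng(seed)
    meds = []
    groups = list(df.groupby(["bird_id", "night"]))
    if len(groups) > max_nights:
        idx = rng.choice(len(groups), max_nights, replace=False)
        groups = [groups[i] for i in idx]
    for _, g in groups:
        if len(g) < 2:
            continue
        xy = g[["x", "y"]].to_numpy()
        from scipy.spatial.distance import pdist
        meds.append(np.median(pdist(xy)))
    return float(np.median(meds)) if meds else float("nan")


def simulate_mortality_scenario(kind: str, n_birds: int = 43,
                                first_year: int = 2016, seed: int = 0,
                                beta_age: float = -0.9,
                                beta_longevity: float = 1.2,
                                sd_bird: float = 0.8,
                                sd_winter: float = 0.3):
    """Bird-block units for the plasticity-vs-selective-mortality check.

    Confirmed-dead birds are tracked from age 1 until their death age
    (longevity, 2..7 winters, staggered cohorts).  Under
    ``kind='plasticity'`` attendance declines within individuals with
    age and longevity has no effect; under ``kind='selective'`` each
    bird's attendance level is set by its longevity (short-lived birds
    roost communally more) with no within-bird change.  Returns
    ``(units, deaths)`` ready for
    :func:`roostkit.models.plasticity_mortality_suite`.
    """
    if kind not in ("plasticity", "selective"):
        raise ValueError("kind must be 'plasticity' or 'selective'")
    rng = np.random.default_rng(seed)
    rows = []
    deaths = []
    for b in range(n_birds):
        longevity = int(rng.integers(2, 8))
        birth = first_year + int(rng.integers(0, 4))
        sex = "m" if rng.random() < 0.5 else "f"
        a_b = rng.normal(0, sd_bird)
        deaths.append(dict(bird_id=f"D{b:03d}", longevity=longevity))
        for age in range(1, longevity + 1):
            winter = birth + age - 1
            breeding = int(age >= 4)
            z_age = (age - 3.0) / 1.5
            z_lon = (longevity - 4.5) / 1.7
            for block in range(1, N_INTERVALS + 1):
                if kind == "plasticity":
                    eta = 0.3 + beta_age * z_age + 0.5 * (sex == "m") \
                        - 0.4 * breeding + a_b
                else:
                    eta = -0.3 + beta_longevity * (-z_lon) + 0.5 * (sex == "m") \
                        - 0.4 * breeding + a_b
                rows.append(dict(bird_id=f"D{b:03d}", winter_id=winter,
                                 interval_index=block, age=age, sex=sex,
                                 breeding_status=breeding, weight=1.0,
                                 tag_class="juvenile", eta=eta))
    units = pd.DataFrame(rows)
    w_eff = {w: rng.normal(0, sd_winter) for w in units.winter_id.unique()}
    units["eta"] = units.eta + units.winter_id.map(w_eff)
    units["attendance"] = (rng.random(len(units)) < expit(units.eta)).astype(int)
    units["n_nights_observed"] = 5
    return units.drop(columns="eta"), pd.DataFrame(deaths)


# ---------------------------------------------------------------------------
# Fixture interchange
# ---------------------------------------------------------------------------

FIXTURE_FILES = ("fixes.csv", "individuals.csv", "broods.csv", "pairs.csv",
                 "truth.csv", "truth_effects.csv", "study_area.geojson",
                 "fixture_meta.json")


def write_fixture(pop: Population, fixes: pd.DataFrame, truth: TruthTable,
                  out_dir) -> dict:
    """Write the CSV/GeoJSON interchange fixture consumed by the pipeline."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    fx = fixes[["bird_id", "timestamp", "lon", "lat"]].copy()
    fx["timestamp"] = pd.DatetimeIndex(fx.timestamp).strftime("%Y-%m-%dT%H:%M:%SZ")
    fx.to_csv(out / "fixes.csv", index=False)

    ind = pop.individuals.copy()
    if len(ind):
        ind["death_date"] = [
            pd.Timestamp(d).strftime("%Y-%m-%d") if pd.notna(d) else ""
            for d in ind.death_date]
    ind.to_csv(out / "individuals.csv", index=False)

    nest_xy = pop.nests.set_index("nest_id") if len(pop.nests) else None

    def nest_lonlat(nest_ids):
        if nest_xy is None or not len(nest_ids):
            return np.zeros(0), np.zeros(0)
        xy = nest_xy.reindex(nest_ids)
        return pop.projection.inverse(xy.x.to_numpy(), xy.y.to_numpy())

    broods = pop.broods.copy()
    if len(broods):
        lon, lat = nest_lonlat(broods.nest_id)
        broods["nest_lon"], broods["nest_lat"] = lon, lat
    broods.to_csv(out / "broods.csv", index=False)

    pairs = pop.pairs.copy()
    if len(pairs):
        lon, lat = nest_lonlat(pairs.nest_id)
        pairs["nest_lon"], pairs["nest_lat"] = lon, lat
    pairs.to_csv(out / "pairs.csv", index=False)

    tn = truth.nights.copy()
    if len(tn):
        tn["night_date"] = pd.DatetimeIndex(tn.night_date).strftime("%Y-%m-%d")
    tn.to_csv(out / "truth.csv", index=False)
    truth.effects.to_csv(out / "truth_effects.csv", index=False)

    write_study_area(out / "study_area.geojson",
                     polygon_to_lonlat(pop.study_area, pop.projection))
    meta = dict(projection=pop.projection.spec,
                seed=pop.config.seed,
                config={k: v for k, v in asdict(pop.config).items()
                        if not isinstance(v, dict)},
                truth=asdict(pop.truth_params))
    with open(out / "fixture_meta.json", "w") as fh:
        json.dump(meta, fh, indent=1, default=str)
    return {name: out / name for name in FIXTURE_FILES}


def make_fixture(config: PopulationConfig | None = None,
                 truth: AttendanceTruth | None = None,
                 seed: int | None = None):
    """Convenience: generate a population and its winter fixes in one call."""
    config = config if config is not None else PopulationConfig()
    truth = truth if truth is not None else AttendanceTruth()
    pop = generate_population(config, truth, seed=seed)
    fixes, truth_table = simulate_winter_nights(pop, truth, config, seed=seed)
    return pop, fixes, truth_table
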