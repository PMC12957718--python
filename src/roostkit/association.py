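"""Assortative roosting with mates and kin, tested by nest permutation.

Eligible bird-nights (the bird has at least one GPS-tagged mate, parent,
offspring or intra-year sibling transmitting in the study region during
that five-night block) are classified into four categories: communal vs.
non-communal roosting, with vs. without a mate-or-kin partner within the
detection radius that night.  Observed category shares, mean distances
from the nightly location to the bird's nest, and the mate / parent-
offspring / sibling composition of co-roosting events are compared to a
node-permutation null that shuffles natal-brood assignments within cohort
years and breeding-nest assignments within seasons; relationships, nest
coordinates, eligibility and all statistics are recomputed per iteration
on the unchanged spatial data, through the same code path that produces
the observed values.  Directional p-values are the proportion of null
draws at least as extreme as the observed value in the direction of the
observed deviation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import Point, Polygon

from .detection import DetectionConfig, detect_attendance
from .glmm import RandomTerm, fit_glmm
from .synthetic import standardize_interval_index

log = logging.getLogger("roostkit")

PARTNER_PRECEDENCE = ("mate", "parent_offspring", "sibling")
_EMPTY: frozenset = frozenset()


class RegistryError(ValueError):
    """Inconsistent brood or pair registries."""


@dataclass
class RelatednessRegistry:
    """Per-year mate links and static kin links with nest coordinates."""

    mates_by_year: dict          # year -> {bird: set(mates)}
    parents: dict                # bird -> set (parent-offspring, symmetric)
    siblings: dict               # bird -> set
    natal_brood: dict            # bird -> (nest_id, year)
    brood_members: dict          # (nest_id, year) -> list of birds
    nest_xy: dict                # nest_id -> (x, y)
    breeding_nest: dict          # (bird, year) -> nest_id
    birth_year: dict             # bird -> cohort year (juvenile-tagged)
    sex: dict = field(default_factory=dict)   # bird -> 'f' | 'm'

    def partners(self, bird, year):
        """Dyad labels for a bird-year, with precedence
        mate > parent-offspring > sibling."""
        out = {}
        for sib in self.siblings.get(bird, ()):
            out[sib] = "sibling"
        for par in self.parents.get(bird, ()):
            out[par] = "parent_offspring"
        for mate in self.mates_by_year.get(year, {}).get(bird, ()):
            out[mate] = "mate"
        return out

    def nest_of(self, bird, year):
        """Registry nest for a bird-year: the breeding nest when breeding
        that season, else the natal nest.  None when unknown."""
        nid = self.breeding_nest.get((bird, year))
        if nid is None and bird in self.natal_brood:
            nid = self.natal_brood[bird][0]
        if nid is None:
            return None
        return self.nest_xy.get(nid)


def build_relatedness_registry(broods: pd.DataFrame, pairs: pd.DataFrame,
                               individuals: pd.DataFrame,
                               projection=None) -> RelatednessRegistry:
    """Derive mate, parent-offspring and sibling links from the registries.

    ``broods`` rows: nest_id, year, bird_id (+ nest_lon/nest_lat or
    nest_x/nest_y); ``pairs`` rows: year, bird_id_1, bird_id_2, nest_id
    (+ coordinates).  Lon/lat columns are projected to planar metres with
    ``projection`` when planar columns are absent.
    """

    def _xy(df, prefix="nest"):
        if f"{prefix}_x" in df.columns:
            return df[f"{prefix}_x"].to_numpy(float), df[f"{prefix}_y"].to_numpy(float)
        if f"{prefix}_lon" in df.columns:
            if projection is None:
                raise ValueError("lon/lat nests need a projection")
            return projection.forward(df[f"{prefix}_lon"].to_numpy(float),
                                      df[f"{prefix}_lat"].to_numpy(float))
        return None, None

    nest_xy = {}
    for df in (broods, pairs):
        if df is None or not len(df):
            continue
        x, y = _xy(df)
        if x is not None:
            for nid, xi, yi in zip(df.nest_id, x, y):
                nest_xy[nid] = (float(xi), float(yi))

    natal_brood = {}
    brood_members = {}
    siblings = {}
    if broods is not None and len(broods):
        dup = broods.groupby(["bird_id", "year"]).size()
        if (dup > 1).any():
            raise RegistryError("a bird appears in two broods of one year")
        seen_years = broods.groupby("bird_id")["year"].nunique()
        if (seen_years > 1).any():
            raise RegistryError("a bird has broods in multiple years")
        for (nid, year), g in broods.groupby(["nest_id", "year"]):
            members = list(g.bird_id)
            brood_members[(nid, year)] = members
            for m in members:
                natal_brood[m] = (nid, year)
                siblings[m] = set(members) - {m}

    mates_by_year = {}
    breeding_nest = {}
    if pairs is not None and len(pairs):
        for year, g in pairs.groupby("year"):
            m = {}
            for _, row in g.iterrows():
                for a, b in ((row.bird_id_1, row.bird_id_2),
                             (row.bird_id_2, row.bird_id_1)):
                    prev = m.setdefault(a, set())
                    if prev and b not in prev:
                        raise RegistryError(
                            f"conflicting pair records for {a} in {year}")
                    prev.add(b)
                    breeding_nest[(a, year)] = row.nest_id
            mates_by_year[int(year)] = m

    parents = {}
    if pairs is not None and len(pairs):
        for _, row in pairs.iterrows():
            for chick in brood_members.get((row.nest_id, row.year), ()):
                for parent in (row.bird_id_1, row.bird_id_2):
                    parents.setdefault(chick, set()).add(parent)
                    parents.setdefault(parent, set()).add(chick)

    birth_year = {}
    if individuals is not None and len(individuals):
        juv = individuals[individuals.tag_class == "juvenile"]
        for _, row in juv.iterrows():
            if pd.notna(row.birth_year):
                birth_year[row.bird_id] = int(row.birth_year)
        # birds that breed but are not in `pairs` (untagged mate) still have
        # a usable breeding nest when individuals carries one
        if "breeding_nest_id" in individuals.columns and \
                "first_breeding_year" in individuals.columns:
            for _, row in individuals.iterrows():
                if pd.isna(row.breeding_nest_id) or pd.isna(row.first_breeding_year):
                    continue
                years = {y for (_, y) in breeding_nest} | set(mates_by_year)
                for y in years:
                    if y >= row.first_breeding_year:
                        breeding_nest.setdefault((row.bird_id, int(y)),
                                                 row.breeding_nest_id)

    sex = {}
    if individuals is not None and len(individuals) and "sex" in individuals.columns:
        sex = dict(zip(individuals.bird_id, individuals.sex))

    return RelatednessRegistry(
        mates_by_year=mates_by_year, parents=parents, siblings=siblings,
        natal_brood=natal_brood, brood_members=brood_members,
        nest_xy=nest_xy, breeding_nest=breeding_nest, birth_year=birth_year,
        sex=sex)


# ---------------------------------------------------------------------------
# Classification of bird-nights
# ---------------------------------------------------------------------------

@dataclass
class AssociationData:
    """Classified eligible bird-nights plus the proximity structure the
    permutation null re-uses."""

    records: pd.DataFrame        # bird_id, night_date, winter_id, interval_index,
                                 # communal, with_mate_or_kin, partner_types,
                                 # nest_distance, eligible, x, y
    proximity: dict              # (bird_id, night_date) -> set of other bird ids
    config: DetectionConfig
    registry: RelatednessRegistry
    present_keys: set = field(default_factory=set)  # (bird, winter, interval)


def classify_association_nights(nights: pd.DataFrame,
                                registry: RelatednessRegistry,
                                config: DetectionConfig | None = None,
                                country_polygon: Polygon | None = None
                                ) -> AssociationData:
    """Classify each eligible bird-night by communal roosting and
    mate-or-kin co-roosting.

    ``nights`` must carry winter_id and interval_index (see
    :func:`roostkit.detection.assign_intervals`); the communal flag of a
    night is the bird's five-night-block attendance flag.  A bird-night
    is eligible when at least one labelled partner has a night location
    in the same block (and inside ``country_polygon`` when given).
    Co-roosting uses the detection radius on the same night (closed ball).
    """
    config = config or DetectionConfig()
    _, units = detect_attendance(nights, config)
    att = units.set_index(["bird_id", "winter_id", "interval_index"])["attendance"]

    # same-night proximity sets
    proximity: dict = {}
    for night, g in nights.groupby("night_date"):
        xy = g[["x", "y"]].to_numpy()
        ids = g.bird_id.to_numpy()
        tree = cKDTree(xy)
        for i, j in tree.query_pairs(config.radius, output_type="ndarray"):
            if ids[i] == ids[j]:
                continue
            proximity.setdefault((ids[i], night), set()).add(ids[j])
            proximity.setdefault((ids[j], night), set()).add(ids[i])

    # partner presence per (bird, winter, interval)
    present = nights.copy()
    if country_polygon is not None:
        inside = [country_polygon.covers(Point(x, y))
                  for x, y in zip(present.x, present.y)]
        present = present.loc[inside]
    present_keys = set(zip(present.bird_id, present.winter_id,
                           present.interval_index))

    rows = []
    for _, r in nights.iterrows():
        partners = registry.partners(r.bird_id, int(r.winter_id))
        present_partners = {p: lab for p, lab in partners.items()
                            if (p, r.winter_id, r.interval_index) in present_keys}
        eligible = int(bool(present_partners))
        prox = proximity.get((r.bird_id, r.night_date), set())
        hit = {lab for p, lab in present_partners.items() if p in prox}
        types = [t for t in PARTNER_PRECEDENCE if t in hit]
        nest = registry.nest_of(r.bird_id, int(r.winter_id))
        dist = (float(np.hypot(r.x - nest[0], r.y - nest[1]))
                if nest is not None else np.nan)
        rows.append(dict(
            bird_id=r.bird_id, night_date=r.night_date,
            winter_id=int(r.winter_id), interval_index=int(r.interval_index),
            communal=int(att.get((r.bird_id, r.winter_id, r.interval_index), 0)),
            with_mate_or_kin=int(bool(types)),
            partner_types=";".join(types),
            nest_distance=dist, eligible=eligible,
            x=float(r.x), y=float(r.y),
        ))
    records = pd.DataFrame(rows)
    return AssociationData(records=records, proximity=proximity,
                           config=config, registry=registry,
                           present_keys=present_keys)


CATEGORY_NAMES = {
    (1, 1): "cr_with", (0, 1): "ncr_with",
    (1, 0): "cr_without", (0, 0): "ncr_without",
}


def observed_summaries(records: pd.DataFrame) -> dict:
    """Category shares, per-category mean nest distances and association-
    type composition over the eligible bird-nights.

    Type percentages are relative to all co-roosting events (with-mate-or-
    kin records of both contexts), classified by the highest-precedence
    partner type present.
    """
    df = records[records.eligible == 1]
    if not len(df):
        raise ValueError("no eligible records")
    n = len(df)
    out = {"n_records": n}
    cat = list(zip(df.communal, df.with_mate_or_kin))
    cat = pd.Series([CATEGORY_NAMES[c] for c in cat], index=df.index)
    for name in ("cr_with", "ncr_with", "cr_without", "ncr_without"):
        m = cat == name
        out[f"pct_{name}"] = 100.0 * m.sum() / n
        out[f"n_{name}"] = int(m.sum())
        d = df.loc[m, "nest_distance"].dropna()
        out[f"dist_{name}"] = float(d.mean()) if len(d) else np.nan
    withs = df[df.with_mate_or_kin == 1]
    n_with = len(withs)
    for t, label in (("mate", "pair"), ("parent_offspring", "parent_offspring"),
                     ("sibling", "sibling")):
        for com, ctx in ((1, "cr"), (0, "ncr")):
            m = (withs.communal == com) & (
                withs.partner_types.str.split(";").str[0] == t)
            out[f"pct_type_{ctx}_{label}"] = (100.0 * m.sum() / n_with
                                              if n_with else np.nan)
    return out


STATISTIC_KEYS = (
    ["pct_cr_with", "pct_ncr_with", "pct_cr_without", "pct_ncr_without"]
    + ["dist_cr_with", "dist_ncr_with", "dist_cr_without", "dist_ncr_without"]
    + [f"pct_type_{ctx}_{lab}" for ctx in ("cr", "ncr")
       for lab in ("pair", "parent_offspring", "sibling")]
)


def permute_nests(assoc: AssociationData, n_iter: int = 1000, seed: int = 0,
                  allow_self: bool = True,
                  permute_pair_nests: bool = True) -> pd.DataFrame:
    """Node-permutation null for the association statistics.

    Each iteration randomises the family identity of every bird and
    recomputes all observed statistics on the unchanged spatial data:

    * the natal-brood assignments of each cohort year are shuffled among
      that year's birds, so the multiset of broods (and brood sizes) is
      preserved exactly; sibling and parent-offspring links follow from
      the shared assigned broods.  With ``allow_self=False`` shuffles
      where some bird keeps its own brood are redrawn (best effort);
    * with ``permute_pair_nests`` (default), the nest-slot assignments of
      each season's tagged-pair members are likewise shuffled, and two
      birds count as mates in the null only when assigned the same
      nest-year -- mirroring the definition of mates as birds nesting
      together and preserving the number of tagged-tagged pairs; the
      parent-offspring relation follows from pair members and chicks
      assigned the same nest-year.  With ``permute_pair_nests=False``
      pair bonds stay fixed, which leaves mate-driven statistics with a
      degenerate null;
    * the full breeding-nest assignments (including breeders with
      untagged mates) are shuffled within season for the nest-distance
      statistics.

    Eligibility is recomputed per iteration (a record counts only when a
    permuted partner is transmitting in its five-night block), and the
    observed values come from the identical evaluation with the identity
    assignment, so the two are exchangeable under the null.  Years with a
    single brood stay fixed (logged).  Returns one row per statistic with
    the observed value, null mean/SD, direction and directional p-value
    (a zero proportion is reported as p < 1/n_iter via ``p_label``).
    """
    reg = assoc.registry
    records = assoc.records.reset_index(drop=True)
    if not len(records):
        raise ValueError("no records to permute")
    if not reg.brood_members:
        raise ValueError("no broods available for permutation")

    broods_by_year: dict = {}
    for nid, year in sorted(reg.brood_members):
        broods_by_year.setdefault(year, []).append((nid, year))
    for year, bs in broods_by_year.items():
        if len(bs) < 2:
            log.info("permute_nests: year %s has a single brood; its birds "
                     "stay fixed", year)

    # birds whose natal assignment is shuffled, grouped by cohort year
    natal_groups: dict = {}
    for b in sorted(reg.natal_brood):
        year = reg.natal_brood[b][1]
        if len(broods_by_year.get(year, [])) >= 2:
            natal_groups.setdefault(year, []).append(b)

    # tagged-pair nest slots (mate/parent structure) per season; the shuffle
    # is stratified by sex where known, so null mates stay male-female pairs
    # (sex shapes presence and attendance, so mixing slots across sexes
    # would break exchangeability)
    pair_slot: dict = {}
    pair_groups: dict = {}
    for y, m in reg.mates_by_year.items():
        for b in sorted(m):
            nid = reg.breeding_nest.get((b, y))
            if nid is not None:
                pair_slot[(b, y)] = nid
                stratum = (y, reg.sex.get(b, "?"))
                pair_groups.setdefault(stratum, []).append(b)

    # full breeding-nest assignments (distance statistics) per season
    breeder_groups: dict = {}
    for (b, y) in sorted(reg.breeding_nest):
        breeder_groups.setdefault(y, []).append(b)

    # bird universe: record birds plus every possible partner
    birds = set(records.bird_id) | set(reg.natal_brood) | set(reg.parents) \
        | set(reg.siblings)
    for (b, _y) in reg.breeding_nest:
        birds.add(b)
    for m in reg.mates_by_year.values():
        for b, ms in m.items():
            birds.add(b)
            birds.update(ms)
    birds = sorted(birds)
    code = {b: i for i, b in enumerate(birds)}
    n_b = len(birds)

    n_rec = len(records)
    r_b = records.bird_id.map(code).to_numpy()
    r_year = records.winter_id.to_numpy()
    r_com = records.communal.to_numpy()
    r_xy = records[["x", "y"]].to_numpy()

    # same-night proximity and same-block presence as record x bird masks
    prox_m = np.zeros((n_rec, n_b), dtype=bool)
    for i, (b, night) in enumerate(zip(records.bird_id, records.night_date)):
        for other in assoc.proximity.get((b, night), ()):
            prox_m[i, code[other]] = True
    pres_by_block: dict = {}
    for (b, w, k) in assoc.present_keys:
        if b in code:
            pres_by_block.setdefault((w, k), np.zeros(n_b, dtype=bool))[code[b]] = True
    none_present = np.zeros(n_b, dtype=bool)
    pres_m = np.vstack([
        pres_by_block.get((w, k), none_present)
        for w, k in zip(records.winter_id, records.interval_index)])
    # a bird is never its own partner
    pres_m = pres_m.copy()
    pres_m[np.arange(n_rec), r_b] = False

    # unique (bird, year) combos for nest coordinates
    combo_keys = list(dict.fromkeys(zip(records.bird_id, r_year)))
    combo_idx = {kk: i for i, kk in enumerate(combo_keys)}
    r_combo = np.array([combo_idx[(b, y)]
                        for b, y in zip(records.bird_id, r_year)])

    years = sorted(set(int(y) for y in r_year))
    year_rows = {y: np.flatnonzero(r_year == y) for y in years}

    def _shuffled(rng, group, assignment):
        values = [assignment[b] for b in group]
        idx = np.arange(len(group))
        for _ in range(100):
            idx = rng.permutation(len(group))
            if allow_self or all(values[i] != values[j]
                                 for j, i in enumerate(idx)):
                break
        return {b: values[i] for b, i in zip(group, idx)}

    def _evaluate(natal_assign, pair_assign, dist_assign) -> dict:
        members: dict = {}
        for b, br in natal_assign.items():
            members.setdefault(br, []).append(code[b])
        sib_m = np.zeros((n_b, n_b), dtype=bool)
        for mem in members.values():
            ix = np.asarray(mem)
            sib_m[np.ix_(ix, ix)] = True
        np.fill_diagonal(sib_m, False)

        breeders_at: dict = {}
        for (b, y), nid in pair_assign.items():
            breeders_at.setdefault((nid, y), []).append(code[b])
        par_m = np.zeros((n_b, n_b), dtype=bool)
        for (nid, year), kids in members.items():
            parents = breeders_at.get((nid, year))
            if parents:
                par_m[np.ix_(kids, parents)] = True
                par_m[np.ix_(parents, kids)] = True
        np.fill_diagonal(par_m, False)

        mate_hit = np.zeros(n_rec, dtype=bool)
        elig = np.zeros(n_rec, dtype=bool)
        kin_m = sib_m | par_m
        for y in years:
            rows = year_rows[y]
            mate_y = np.zeros((n_b, n_b), dtype=bool)
            for (nid, yy), bs in breeders_at.items():
                if yy == y and len(bs) > 1:
                    ix = np.asarray(bs)
                    mate_y[np.ix_(ix, ix)] = True
            np.fill_diagonal(mate_y, False)
            partner = kin_m | mate_y
            elig[rows] = (partner[r_b[rows]] & pres_m[rows]).any(axis=1)
            mate_hit[rows] = (mate_y[r_b[rows]] & prox_m[rows]).any(axis=1)
        par_hit = (par_m[r_b] & prox_m).any(axis=1)
        sib_hit = (sib_m[r_b] & prox_m).any(axis=1)
        with_flag = mate_hit | par_hit | sib_hit
        top = np.where(mate_hit, 1, np.where(par_hit, 2,
                                             np.where(sib_hit, 3, 0)))

        nest_c = np.full((len(combo_keys), 2), np.nan)
        for (b, y), ci in combo_idx.items():
            nid = dist_assign.get((b, int(y)))
            if nid is None and b in natal_assign:
                nid = natal_assign[b][0]
            if nid is not None and nid in reg.nest_xy:
                nest_c[ci] = reg.nest_xy[nid]
        dist = np.hypot(r_xy[:, 0] - nest_c[r_combo, 0],
                        r_xy[:, 1] - nest_c[r_combo, 1])

        e = elig
        n_e = int(e.sum())
        stats = {}
        if n_e == 0:
            return {k: np.nan for k in STATISTIC_KEYS}
        n_with = int((with_flag & e).sum())
        for name, (com, wf) in (("cr_with", (1, True)), ("ncr_with", (0, True)),
                                ("cr_without", (1, False)),
                                ("ncr_without", (0, False))):
            m = e & (r_com == com) & (with_flag == wf)
            stats[f"pct_{name}"] = 100.0 * m.sum() / n_e
            d = dist[m]
            d = d[np.isfinite(d)]
            stats[f"dist_{name}"] = float(d.mean()) if len(d) else np.nan
        for t_code, label in ((1, "pair"), (2, "parent_offspring"),
                              (3, "sibling")):
            for com, ctx in ((1, "cr"), (0, "ncr")):
                m = e & (r_com == com) & (top == t_code)
                stats[f"pct_type_{ctx}_{label}"] = (100.0 * m.sum() / n_with
                                                    if n_with else np.nan)
        return stats

    observed = _evaluate(dict(reg.natal_brood), dict(pair_slot),
                         dict(reg.breeding_nest))

    rng = np.random.default_rng(seed)
    null_rows = {k: [] for k in STATISTIC_KEYS}
    for _ in range(n_iter):
        natal_assign = dict(reg.natal_brood)
        for year, group in natal_groups.items():
            natal_assign.update(_shuffled(rng, group, reg.natal_brood))
        if permute_pair_nests:
            pair_assign = {}
            for (year, _sex), group in pair_groups.items():
                season = {b: pair_slot[(b, year)] for b in group}
                for b, nid in _shuffled(rng, group, season).items():
                    pair_assign[(b, year)] = nid
            dist_assign = {}
            for year, group in breeder_groups.items():
                season = {b: reg.breeding_nest[(b, year)] for b in group}
                for b, nid in _shuffled(rng, group, season).items():
                    dist_assign[(b, year)] = nid
        else:
            pair_assign = dict(pair_slot)
            dist_assign = dict(reg.breeding_nest)
        stats = _evaluate(natal_assign, pair_assign, dist_assign)
        for k in STATISTIC_KEYS:
            null_rows[k].append(stats[k])

    out = []
    for k in STATISTIC_KEYS:
        null = np.asarray(null_rows[k], dtype=float)
        obs = observed.get(k, np.nan)
        valid = np.isfinite(null)
        if not np.isfinite(obs) or not valid.any():
            continue
        null_v = null[valid]
        p_greater = float(np.mean(null_v >= obs))
        p_less = float(np.mean(null_v <= obs))
        direction = "greater" if obs >= np.nanmean(null_v) else "less"
        p = p_greater if direction == "greater" else p_less
        out.append(dict(
            statistic=k, observed=float(obs),
            null_mean=float(np.mean(null_v)), null_sd=float(np.std(null_v)),
            direction=direction, p_value=p,
            p_label=(f"<{1.0 / n_iter:g}" if p == 0 else f"{p:.3g}"),
            p_greater=p_greater, p_less=p_less,
            n_iter=int(valid.sum()),
        ))
    return pd.DataFrame(out)


def seasonal_association_trend(assoc: AssociationData,
                               engine_options: dict | None = None) -> dict:
    """Within-winter trend of mate and kin co-roosting.

    Aggregates eligible bird-nights to bird x block (response: any mate
    co-roosting night; separately any kin co-roosting night) and fits a
    logistic mixed model with the standardised block sequence as the
    predictor and a bird random intercept.  A response without variation
    is skipped with a warning (kin co-roosting can be too rare to test).
    """
    engine_options = dict(engine_options or {})
    df = assoc.records[assoc.records.eligible == 1].copy()
    if not len(df):
        raise ValueError("no eligible records")
    first = df.partner_types.str.split(";").str[0]
    df["with_mate"] = ((df.with_mate_or_kin == 1) & (first == "mate")).astype(int)
    df["with_kin"] = ((df.with_mate_or_kin == 1) & (first != "mate")
                      & (first != "")).astype(int)
    agg = df.groupby(["bird_id", "winter_id", "interval_index"], as_index=False).agg(
        with_mate=("with_mate", "max"), with_kin=("with_kin", "max"))
    z = standardize_interval_index(agg.interval_index.to_numpy())
    X = np.column_stack([np.ones(len(agg)), z])
    results = {}
    for name in ("mate", "kin"):
        y = agg[f"with_{name}"].to_numpy(dtype=float)
        if y.min() == y.max():
            warnings.warn(f"{name} co-roosting shows no variation; trend skipped")
            results[name] = None
            continue
        terms = [RandomTerm("bird", pd.factorize(agg.bird_id)[0])]
        fit = fit_glmm(y, X, terms, fixed_names=["intercept", "interval_seq"],
                       **engine_options)
        ci = fit.wald_interval()
        results[name] = dict(
            slope=float(fit.beta[1]), lower=float(ci[1, 0]),
            upper=float(ci[1, 1]), intercept=float(fit.beta[0]),
            sd_bird=fit.sd("bird"), n=len(agg), fit=fit)
    return results
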