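import numpy as np
import pandas as pd
import pytest

from roostkit.synthetic import (
    AttendanceTruth,
    PopulationConfig,
    make_fixture,
)


@pytest.fixture(scope="session")
def small_fixture():
    """A compact assortative population with two winters."""
    cfg = PopulationConfig(n_juvenile_tagged=40, n_adult_tagged=20,
                           n_winters=2, seed=9)
    pop, fixes, truth = make_fixture(cfg, AttendanceTruth())
    return pop, fixes, truth


@pytest.fixture(scope="session")
def small_nights(small_fixture):
    from roostkit.detection import assign_intervals, extract_night_locations

    _, fixes, _ = small_fixture
    return assign_intervals(extract_night_locations(fixes))


@pytest.fixture(scope="session")
def small_registry(small_fixture):
    from roostkit.validation import _registry_from_pop

    pop, _, _ = small_fixture
    return _registry_from_pop(pop)


def random_nights(seed, n_birds=12, n_nights=10, spread=2000.0,
                  winter=2016) -> pd.DataFrame:
    """Random night-location frame used by brute-force oracle tests."""
    rng = np.random.default_rng(seed)
    rows = []
    start = pd.Timestamp(f"{winter}-11-01")
    for b in range(n_birds):
        for k in range(n_nights):
            if rng.random() < 0.25:
                continue  # missing nights
            rows.append(dict(
                bird_id=f"B{b:02d}",
                night_date=start + pd.Timedelta(days=int(rng.integers(0, 92))),
                x=float(rng.uniform(0, spread)),
                y=float(rng.uniform(0, spread)),
                n_fixes=1,
            ))
    df = pd.DataFrame(rows).drop_duplicates(["bird_id", "night_date"])
    from roostkit.detection import assign_intervals

    return assign_intervals(df)


def brute_force_attendance(nights, radius=300.0, min_others=2,
                           matching="cross_night"):
    """O(n^2) reference classifier for communal-roost attendance."""
    out = {}
    for (w, blk), g in nights.groupby(["winter_id", "interval_index"]):
        rows = list(g.itertuples())
        for focal in {r.bird_id for r in rows}:
            others = set()
            for a in rows:
                if a.bird_id != focal:
                    continue
                for b in rows:
                    if b.bird_id == focal:
                        continue
                    if matching == "same_night" and a.night_date != b.night_date:
                        continue
                    if np.hypot(a.x - b.x, a.y - b.y) <= radius:
                        others.add(b.bird_id)
            out[(focal, w, blk)] = int(len(others) >= min_others)
    return out
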