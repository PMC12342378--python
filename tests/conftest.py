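import numpy as np
import pandas as pd
import pytest

from mrpscene.data_model import Cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_records(rows: list[dict]) -> pd.DataFrame:
    """Build a probe-records frame from sparse row dicts (test helper)."""
    defaults = dict(
        participant_id="P0001", age_group="adult", trial_index=1,
        probe_index=1, probe_type="present", location=1, image_id=1,
        initial_congruency="congruent", response="absolutely_present",
        rt_ms=1000.0,
    )
    dxc_map = {"absolutely_present": 3, "maybe_present": 1,
               "maybe_absent": -1, "absolutely_absent": -3}
    out = []
    for i, row in enumerate(rows):
        r = {**defaults, **row}
        r.setdefault("probe_index", (i % 6) + 1)
        r.setdefault("trial_index", i // 6 + 1)
        r["dxc"] = dxc_map[r["response"]]
        out.append(r)
    return pd.DataFrame(out)


def make_meta(participants: list[tuple[str, str]], **overrides) -> pd.DataFrame:
    rows = []
    for pid, age in participants:
        rows.append(dict(participant_id=pid, age_group=age, practice_correct=7,
                         completed_trials=30, catch_n=10, catch_correct=10,
                         **overrides))
    return pd.DataFrame(rows)


def records_from_dxc(dxc_signal, dxc_noise) -> pd.DataFrame:
    """Single-participant records with given signal/noise D x C multisets."""
    from mrpscene.data_model import DXC_MAP

    inv = {v: k for k, v in DXC_MAP.items()}
    rows = []
    for v in dxc_signal:
        rows.append(dict(probe_type="present", response=inv[v]))
    for v in dxc_noise:
        rows.append(dict(probe_type="absent", response=inv[v]))
    return make_records(rows)


@pytest.fixture(scope="session")
def small_cohort() -> Cohort:
    """A small simulated four-group cohort reused by read-only tests."""
    from mrpscene.synthetic import simulate_cohort

    return simulate_cohort((0.75, 0.80, 0.85, 0.90), sd=0.05,
                           ns=(4, 4, 4, 4), seed=11)
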