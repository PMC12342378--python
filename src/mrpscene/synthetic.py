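"""Synthetic massive-report-paradigm cohorts from an equal-variance SDT model.

The generator reproduces the statistical structure the analysis pipeline
assumes, without any image content:

* **Design**: 30 trials per session, each probing one initial image with six
  patches (1 original, 1 modified, 1 present, 3 absent) in random order.
  Per trial all probe locations come from one of two location sets
  ({1,3,5,7,9} or {2,4,6,8}); the original and modified patches share the
  critical-object location.  Absent patches are drawn from a large pool and
  never repeat within a session (90 distinct ids across 30 trials).  Catch
  questions (click the instructed panel; chance 1/4) are appended to 8-12
  randomly chosen trials.
* **Responses**: evidence x ~ Normal(mu, 1) with mu = 0 for absent patches,
  ``d_present`` (+ an optional log-object-size term) for original/present
  patches and ``d_modified`` shifted by the congruence coefficient for
  modified patches.  The presence decision compares x with the criterion c;
  confidence thresholds t1 < c < t2 are read out on x plus independent
  metacognitive noise (SD ``sigma_meta``), so Type 1 and Type 2 accuracy are
  separately controllable.
* **Cohorts**: each participant's latent Type 1 AUC is drawn from
  Normal(mu_g, sd) for its age group, mapped to d' by calibration, and a
  full session is simulated.  An exclusion profile appends participants
  engineered to fail the practice, completeness or catch filters.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data_model import (
    AGE_GROUPS,
    CONGRUENCY_LEVELS,
    DXC_VALUES,
    META_COLUMNS,
    RECORD_COLUMNS,
    RESPONSES,
    Cohort,
)

#: Absent patches come from other images; their ids live above this offset
#: so they can never collide with initial-image ids (1..n_images).
ABSENT_ID_OFFSET = 100_000


@dataclasses.dataclass(frozen=True)
class DesignSpec:
    """Session design constants of the probe schedule."""

    n_trials: int = 30
    n_images: int = 120
    location_sets: tuple[tuple[int, ...], ...] = ((1, 3, 5, 7, 9), (2, 4, 6, 8))
    congruent_fraction: float = 0.5
    catch_min: int = 8
    catch_max: int = 12
    absent_pool_size: int = 7044

    @property
    def n_absent_per_session(self) -> int:
        return 3 * self.n_trials

    @property
    def catch_chance(self) -> float:
        """Chance level of a catch question: one panel out of four."""
        return 1.0 / len(RESPONSES)


@dataclasses.dataclass(frozen=True)
class GeneratorParams:
    """SDT generative parameters of a simulated observer.

    ``criterion=None`` places the decision criterion midway between the
    noise and signal evidence means (unbiased observer); the confidence
    thresholds sit at ``criterion +/- conf_width``.  ``d_modified=None``
    defaults to half of ``d_present`` (a partial content match at the same
    location).  ``kappa_cong`` lowers modified-patch evidence under a
    congruent initial image and raises it under an incongruent one, making
    original/modified discrimination better in the congruent condition.
    ``beta_size`` adds a centred log-object-size term to original/present
    evidence.  ``p_catch_attend`` is the probability of following the catch
    instruction; otherwise the click is uniform over the four panels.
    """

    d_present: float = 2.0
    d_modified: float | None = None
    criterion: float | None = None
    conf_width: float = 0.8
    sigma_meta: float = 0.6
    kappa_cong: float = 0.0
    beta_size: float = 0.0
    p_catch_attend: float = 0.95

    def __post_init__(self) -> None:
        if self.conf_width <= 0:
            raise ValueError("conf_width must be positive (t1 < c < t2)")
        if self.sigma_meta < 0:
            raise ValueError("sigma_meta must be nonnegative")
        if not 0.0 <= self.p_catch_attend <= 1.0:
            raise ValueError("p_catch_attend must be a probability")

    def with_dprime(self, d: float) -> "GeneratorParams":
        return dataclasses.replace(self, d_present=d)

    def resolved(self, d: float | None = None) -> tuple[float, float, float, float, float]:
        """(d_present, d_modified, t1, c, t2) with defaults filled in."""
        dp = self.d_present if d is None else d
        dm = 0.5 * dp if self.d_modified is None else self.d_modified
        c = 0.5 * dp if self.criterion is None else self.criterion
        return dp, dm, c - self.conf_width, c, c + self.conf_width


# ---------------------------------------------------------------------------
# design schedule


def _pick_two_locations(rng: np.random.Generator, sets: np.ndarray,
                        set_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two distinct locations per trial from that trial's location set."""
    n = len(set_idx)
    loc_a = np.empty(n, dtype=int)
    loc_b = np.empty(n, dtype=int)
    for s, members in enumerate(sets):
        mask = set_idx == s
        k = int(mask.sum())
        if k == 0:
            continue
        keys = rng.random((k, len(members)))
        order = np.argsort(keys, axis=1)
        loc_a[mask] = np.asarray(members)[order[:, 0]]
        loc_b[mask] = np.asarray(members)[order[:, 1]]
    return loc_a, loc_b


def _build_design_arrays(spec: DesignSpec, rng: np.random.Generator) -> dict:
    """Probe schedule for one session as parallel numpy arrays."""
    nt = spec.n_trials
    if spec.absent_pool_size < spec.n_absent_per_session:
        raise ValueError(
            f"absent pool ({spec.absent_pool_size}) smaller than the "
            f"{spec.n_absent_per_session} distinct absent patches a session needs"
        )
    if spec.n_images < nt:
        raise ValueError("need at least one initial image per trial")

    images = rng.choice(spec.n_images, size=nt, replace=False) + 1
    n_cong = int(round(spec.congruent_fraction * nt))
    cong = np.zeros(nt, dtype=bool)
    cong[:n_cong] = True
    rng.shuffle(cong)

    set_idx = rng.integers(0, len(spec.location_sets), size=nt)
    sets = [np.asarray(s) for s in spec.location_sets]
    loc_om, loc_present = _pick_two_locations(rng, sets, set_idx)
    # three absent locations per trial, drawn within the trial's set (the
    # 4-member set cannot host 5 distinct locations, so draws are independent)
    absent_loc = np.stack(
        [np.asarray(spec.location_sets[s])[rng.integers(0, len(spec.location_sets[s]), size=3)]
         for s in set_idx]
    )
    absent_ids = rng.choice(spec.absent_pool_size, size=3 * nt,
                            replace=False) + ABSENT_ID_OFFSET

    # per trial: slots [original, modified, present, absent x3], then shuffled
    ptype = np.tile(np.array([0, 1, 2, 3, 3, 3]), nt)  # codes, see PROBE_CODE
    trial = np.repeat(np.arange(1, nt + 1), 6)
    loc = np.empty(6 * nt, dtype=int)
    loc[0::6] = loc_om
    loc[1::6] = loc_om
    loc[2::6] = loc_present
    loc[3::6] = absent_loc[:, 0]
    loc[4::6] = absent_loc[:, 1]
    loc[5::6] = absent_loc[:, 2]
    img = np.repeat(images, 6)
    img[3::6] = absent_ids[0::3]
    img[4::6] = absent_ids[1::3]
    img[5::6] = absent_ids[2::3]

    order = np.argsort(rng.random((nt, 6)), axis=1)
    probe_index = np.empty((nt, 6), dtype=int)
    np.put_along_axis(probe_index, order, np.arange(1, 7)[None, :].repeat(nt, 0), axis=1)
    probe_index = probe_index.ravel()

    n_catch = min(int(rng.integers(spec.catch_min, spec.catch_max + 1)), nt)
    catch_trials = rng.choice(nt, size=n_catch, replace=False) + 1

    return dict(
        trial_index=trial, probe_index=probe_index, probe_type=ptype,
        location=loc, image_id=img, congruent=np.repeat(cong, 6),
        catch_trials=np.sort(catch_trials),
        trial_congruent=cong, images=images,
    )


#: probe-type code -> label (absent expanded from code 3)
PROBE_CODE = np.array(["original", "modified", "present", "absent"])


def build_design(spec: DesignSpec, seed: int | None = None,
                 rng: np.random.Generator | None = None) -> pd.DataFrame:
    """One session's probe schedule (catch rows included, probe_index 7).

    Columns: trial_index, probe_index, probe_type, location, image_id,
    initial_congruency.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    arr = _build_design_arrays(spec, rng)
    df = pd.DataFrame(
        dict(
            trial_index=arr["trial_index"],
            probe_index=arr["probe_index"],
            probe_type=PROBE_CODE[arr["probe_type"]],
            location=arr["location"],
            image_id=arr["image_id"],
            initial_congruency=np.where(arr["congruent"], *CONGRUENCY_LEVELS[:2]),
        )
    )
    cong_of_trial = dict(
        zip(range(1, spec.n_trials + 1),
            np.where(arr["trial_congruent"], *CONGRUENCY_LEVELS[:2]))
    )
    img_of_trial = dict(zip(range(1, spec.n_trials + 1), arr["images"]))
    catch = pd.DataFrame(
        dict(
            trial_index=arr["catch_trials"],
            probe_index=7,
            probe_type="catch",
            location=0,
            image_id=[img_of_trial[t] for t in arr["catch_trials"]],
            initial_congruency=[cong_of_trial[t] for t in arr["catch_trials"]],
        )
    )
    out = pd.concat([df, catch], ignore_index=True)
    return out.sort_values(["trial_index", "probe_index"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# response simulation


_RESPONSE_ARR = np.array(RESPONSES)
_DXC_ARR = np.array(DXC_VALUES)


def _simulate_scored_responses(
    params: GeneratorParams, d: float, ptype: np.ndarray, congruent: np.ndarray,
    rng: np.random.Generator, size_term: np.ndarray | None = None,
) -> np.ndarray:
    """Response-category codes (0..3 indexing RESPONSES) for scored probes."""
    dp, dm, t1, c, t2 = params.resolved(d)
    mu = np.zeros(len(ptype))
    sig = (ptype == 0) | (ptype == 2)  # original | present
    mu[sig] = dp
    if size_term is not None:
        mu[sig] += size_term[sig]
    mod = ptype == 1
    mu[mod] = dm + np.where(congruent[mod], -0.5, 0.5) * params.kappa_cong
    x = mu + rng.standard_normal(len(ptype))
    y = x + params.sigma_meta * rng.standard_normal(len(ptype))
    present = x > c
    code = np.where(
        present,
        np.where(y > t2, 0, 1),          # absolutely / maybe present
        np.where(y < t1, 3, 2),          # absolutely / maybe absent
    )
    return code


def _simulate_catch(params: GeneratorParams, n_catch: int,
                    rng: np.random.Generator) -> tuple[np.ndarray, int]:
    """Catch response codes and the number answered correctly."""
    instructed = rng.integers(0, 4, size=n_catch)
    attends = rng.random(n_catch) < params.p_catch_attend
    random_click = rng.integers(0, 4, size=n_catch)
    resp = np.where(attends, instructed, random_click)
    return resp, int((resp == instructed).sum())


def simulate_participant(
    params: GeneratorParams,
    spec: DesignSpec | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    participant_id: str = "P0001",
    age_group: str = "adult",
    log_sizes: dict[int, float] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate one full session; returns (records, meta-row dict).

    ``log_sizes`` optionally maps initial-image id to a centred log object
    size entering original/present evidence through ``beta_size``.
    """
    spec = spec or DesignSpec()
    if rng is None:
        rng = np.random.default_rng(seed)
    arr = _build_design_arrays(spec, rng)
    size_term = None
    if log_sizes is not None and params.beta_size != 0.0:
        size_term = params.beta_size * np.array(
            [log_sizes.get(int(i), 0.0) for i in arr["image_id"]]
        )
    code = _simulate_scored_responses(
        params, params.d_present, arr["probe_type"], arr["congruent"], rng,
        size_term=size_term,
    )
    catch_resp, catch_correct = _simulate_catch(
        params, len(arr["catch_trials"]), rng
    )
    records = _records_frame(
        participant_id, age_group, arr, code, catch_resp, rng, spec
    )
    meta = dict(
        participant_id=participant_id,
        age_group=age_group,
        practice_correct=int(5 + rng.binomial(2, 0.8)),
        completed_trials=spec.n_trials,
        catch_n=len(arr["catch_trials"]),
        catch_correct=catch_correct,
    )
    return records, meta


def _records_frame(pid: str, age: str, arr: dict, code: np.ndarray,
                   catch_resp: np.ndarray, rng: np.random.Generator,
                   spec: DesignSpec) -> pd.DataFrame:
    n_scored = len(code)
    n_catch = len(catch_resp)
    cong_label = np.where(arr["congruent"], *CONGRUENCY_LEVELS[:2])
    cong_of_trial = dict(zip(arr["trial_index"], cong_label))
    img_of_trial = dict(zip(arr["trial_index"], np.repeat(arr["images"], 6)))
    resp_all = np.concatenate([code, catch_resp])
    rt = np.round(rng.lognormal(mean=7.0, sigma=0.4, size=n_scored + n_catch), 1)
    return pd.DataFrame(
        dict(
            participant_id=pid,
            age_group=age,
            trial_index=np.concatenate([arr["trial_index"], arr["catch_trials"]]),
            probe_index=np.concatenate(
                [arr["probe_index"], np.full(n_catch, 7)]
            ),
            probe_type=np.concatenate(
                [PROBE_CODE[arr["probe_type"]], np.full(n_catch, "catch")]
            ),
            location=np.concatenate([arr["location"], np.zeros(n_catch, int)]),
            image_id=np.concatenate(
                [arr["image_id"],
                 np.array([img_of_trial[t] for t in arr["catch_trials"]], int)]
            ),
            initial_congruency=np.concatenate(
                [cong_label,
                 np.array([cong_of_trial[t] for t in arr["catch_trials"]])]
            ),
            response=_RESPONSE_ARR[resp_all],
            rt_ms=rt,
            dxc=_DXC_ARR[resp_all],
        )
    )


# ---------------------------------------------------------------------------
# d' calibration against the analytic trapezoid Type 1 AUC


def _bvn_cdf(a: np.ndarray, b: np.ndarray, rho: float) -> np.ndarray:
    """Standard bivariate normal P(X <= a, Y <= b) with correlation rho."""
    if rho >= 1.0 - 1e-12:
        return stats.norm.cdf(np.minimum(a, b))
    cov = np.array([[1.0, rho], [rho, 1.0]])
    mvn = stats.multivariate_normal(mean=[0.0, 0.0], cov=cov)
    pts = np.stack([np.atleast_1d(a), np.atleast_1d(b)], axis=-1)
    return mvn.cdf(pts)


def _class_cum_rates(mu: float, t1: float, c: float, t2: float,
                     sigma_meta: float) -> np.ndarray:
    """Cumulative P(dxc >= theta) at theta = +3, +1, -1 for evidence mean mu.

    The decision compares x ~ N(mu, 1) with c; confidence compares
    y = x + N(0, sigma_meta^2) with t1/t2.  (x, y) are jointly normal with
    correlation 1/sqrt(1 + sigma_meta^2).
    """
    s = np.sqrt(1.0 + sigma_meta**2)
    rho = 1.0 / s
    # P(+3) = P(x > c, y > t2);  P(-3) = P(x <= c, y <= t1)
    F_c_t2 = float(_bvn_cdf(np.array(c - mu), np.array((t2 - mu) / s), rho))
    F_c_t1 = float(_bvn_cdf(np.array(c - mu), np.array((t1 - mu) / s), rho))
    p_present = 1.0 - stats.norm.cdf(c - mu)
    p3 = 1.0 - stats.norm.cdf(c - mu) - stats.norm.cdf((t2 - mu) / s) + F_c_t2
    pm3 = F_c_t1
    return np.array([p3, p_present, 1.0 - pm3])


def analytic_type1_auc(d: float, params: GeneratorParams | None = None) -> float:
    """Population trapezoid Type 1 AUC of the generative observer at d'."""
    params = params or GeneratorParams()
    _, _, t1, c, t2 = params.resolved(d)
    hits = _class_cum_rates(d, t1, c, t2, params.sigma_meta)
    fas = _class_cum_rates(0.0, t1, c, t2, params.sigma_meta)
    x = np.concatenate([[0.0], fas, [1.0]])
    y = np.concatenate([[0.0], hits, [1.0]])
    return float(np.trapezoid(y, x))


@dataclasses.dataclass
class CalibrationResult:
    target_auc: float
    d_present: float
    achieved_auc: float
    tolerance: float


def calibrate_dprime(target_auc: float, params: GeneratorParams | None = None,
                     tol: float = 1e-3, d_max: float = 12.0) -> CalibrationResult:
    """Find d' whose analytic trapezoid Type 1 AUC equals the target.

    Root-finds on the analytic AUC, which is continuous and strictly
    increasing in d'.  Targets at or above 1 (or below 0.5) are unattainable
    and raise ``ValueError``.
    """
    if not 0.5 <= target_auc < 1.0:
        raise ValueError("target AUC must lie in [0.5, 1)")
    if target_auc == 0.5:
        return CalibrationResult(0.5, 0.0, 0.5, tol)
    f = lambda d: analytic_type1_auc(d, params) - target_auc
    if f(d_max) < 0:
        raise ValueError(f"target AUC {target_auc} unattainable below d'={d_max}")
    d = float(optimize.brentq(f, 0.0, d_max, xtol=1e-6))
    achieved = analytic_type1_auc(d, params)
    if abs(achieved - target_auc) > tol:
        raise RuntimeError("calibration failed to reach tolerance")
    return CalibrationResult(target_auc, d, achieved, tol)


_calibration_maps: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


def _dprime_map(params: GeneratorParams) -> tuple[np.ndarray, np.ndarray]:
    """Cached monotone grid AUC(d) for fast inverse lookup in cohorts."""
    key = (params.sigma_meta, params.conf_width, params.criterion,
           params.d_modified)
    if key not in _calibration_maps:
        grid = np.linspace(0.0, 10.0, 161)
        aucs = np.array([analytic_type1_auc(d, params) for d in grid])
        _calibration_maps[key] = (aucs, grid)
    return _calibration_maps[key]


def dprime_for_auc(target_auc: np.ndarray | float,
                   params: GeneratorParams) -> np.ndarray:
    """Vectorized inverse calibration by interpolation on a cached grid."""
    aucs, grid = _dprime_map(params)
    return np.interp(target_auc, aucs, grid)


# ---------------------------------------------------------------------------
# cohorts


#: Latent AUC clipping bounds: an AUC of 1 (or 0.5 from below) cannot be
#: realized by a finite observer, so latent draws are censored here.
LATENT_AUC_BOUNDS = (0.5005, 0.9995)


def censored_group_mean(mu: float, sd: float,
                        bounds: tuple[float, float] = LATENT_AUC_BOUNDS) -> float:
    """Mean of a Normal(mu, sd) draw censored to the latent AUC bounds.

    Closed form E[min(max(X, lo), hi)]; this is the group mean the
    behavioural generator actually realizes, slightly below mu when mu is
    near ceiling.
    """
    lo, hi = bounds
    a, b = (lo - mu) / sd, (hi - mu) / sd
    phi, Phi = stats.norm.pdf, stats.norm.cdf
    # E[X; a<Z<b] + lo P(Z<a) + hi P(Z>b)
    mid = mu * (Phi(b) - Phi(a)) - sd * (phi(b) - phi(a))
    return float(mid + lo * Phi(a) + hi * (1.0 - Phi(b)))


def make_image_covariates(n_images: int = 120, seed: int | None = None,
                          size_mean: float = 8.0, size_sd: float = 1.0) -> pd.DataFrame:
    """Synthetic per-image covariates: log object size and knowledge rating.

    Log object size is Normal(size_mean, size_sd) (log pixel area of the
    critical object); knowledge is a 1-4 familiarity rating drawn uniformly,
    decoupled from responses unless explicitly wired into the generator.
    """
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        dict(
            image_id=np.arange(1, n_images + 1),
            log_object_size=rng.normal(size_mean, size_sd, n_images),
            knowledge_rating=rng.integers(1, 5, n_images),
        )
    )


def simulate_cohort(
    group_means: tuple[float, ...],
    sd: float = 0.1,
    ns: tuple[int, ...] = (35, 35, 35, 35),
    seed: int | None = None,
    params: GeneratorParams | None = None,
    design: DesignSpec | None = None,
    exclusion_profile: dict[str, tuple[int, int, int, int]] | None = None,
    covariates: pd.DataFrame | None = None,
    group_params: dict[str, dict] | None = None,
    rng: np.random.Generator | None = None,
) -> Cohort:
    """Simulate a full cohort of sessions, optionally with excluded extras.

    Per retained participant a latent Type 1 AUC is drawn Normal(mu_g, sd),
    censored to the attainable range, inverted to d' and a full session is
    simulated.  ``exclusion_profile`` maps age group to
    (n_recruited, n_fail_practice, n_incomplete, n_fail_catch); the three
    failure counts are synthesized on top of the retained participants so
    that :func:`mrpscene.data_model.apply_exclusions` reproduces the profile
    exactly.  ``covariates`` (image_id, log_object_size, ...) activates the
    object-size effect when ``params.beta_size != 0``.  ``group_params``
    maps an age group to :class:`GeneratorParams` field overrides (e.g. a
    higher ``sigma_meta`` for adults, so metacognition can stay flat while
    discrimination improves with age).
    """
    params = params or GeneratorParams()
    design = design or DesignSpec()
    if rng is None:
        rng = np.random.default_rng(seed)
    if len(group_means) != len(ns) or len(group_means) > len(AGE_GROUPS):
        raise ValueError("group_means and ns must align with the age groups")

    log_sizes = None
    if covariates is not None:
        centred = covariates["log_object_size"] - covariates["log_object_size"].mean()
        log_sizes = dict(zip(covariates["image_id"].astype(int), centred))

    record_frames: list[pd.DataFrame] = []
    meta_rows: list[dict] = []
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"P{counter:04d}"

    for g, (mu, n) in enumerate(zip(group_means, ns)):
        age = AGE_GROUPS[g]
        params_g = params
        if group_params and age in group_params:
            params_g = dataclasses.replace(params, **group_params[age])
        latent = np.clip(rng.normal(mu, sd, n), *LATENT_AUC_BOUNDS)
        dvals = dprime_for_auc(latent, params_g)
        for d in dvals:
            pid = next_id()
            rec, meta = simulate_participant(
                params_g.with_dprime(float(d)), spec=design, rng=rng,
                participant_id=pid, age_group=age, log_sizes=log_sizes,
            )
            # retained-by-construction: floor the catch score at threshold so
            # the exclusion profile is reproduced exactly, never stochastically
            meta["catch_correct"] = max(
                meta["catch_correct"], int(np.ceil(0.70 * meta["catch_n"]))
            )
            record_frames.append(rec)
            meta_rows.append(meta)

        if exclusion_profile is not None:
            _, n_prac, n_inc, n_catch = exclusion_profile[age]
            mid = 0.5 * (LATENT_AUC_BOUNDS[0] + mu)
            d_fail = float(dprime_for_auc(mid, params_g))
            for _ in range(n_prac):
                # session ended during practice: summary counts only
                meta_rows.append(dict(
                    participant_id=next_id(), age_group=age,
                    practice_correct=int(rng.integers(0, 5)),
                    completed_trials=0, catch_n=1, catch_correct=1,
                ))
            for _ in range(n_inc):
                pid = next_id()
                rec, meta = simulate_participant(
                    params_g.with_dprime(d_fail), spec=design, rng=rng,
                    participant_id=pid, age_group=age, log_sizes=log_sizes,
                )
                done = int(rng.integers(1, design.n_trials))
                rec = rec[rec["trial_index"] <= done]
                meta["completed_trials"] = done
                meta["catch_n"] = max(1, int(rec["probe_type"].eq("catch").sum()))
                meta["catch_correct"] = meta["catch_n"]
                record_frames.append(rec)
                meta_rows.append(meta)
            for _ in range(n_catch):
                pid = next_id()
                fail_params = dataclasses.replace(
                    params_g, d_present=d_fail,
                    p_catch_attend=float(rng.uniform(0.0, 0.4)),
                )
                rec, meta = simulate_participant(
                    fail_params, spec=design, rng=rng,
                    participant_id=pid, age_group=age, log_sizes=log_sizes,
                )
                # force the catch rate below the 70% threshold
                max_ok = int(np.ceil(0.70 * meta["catch_n"])) - 1
                meta["catch_correct"] = min(meta["catch_correct"], max(0, max_ok))
                record_frames.append(rec)
                meta_rows.append(meta)

    records = pd.concat(record_frames, ignore_index=True)
    meta = pd.DataFrame(meta_rows, columns=META_COLUMNS)
    return Cohort(records=records[RECORD_COLUMNS + ["dxc"]], meta=meta)


def simulate_uniform_responder(n_signal: int, n_noise: int,
                               seed: int | None = None,
                               rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Probe records of an observer clicking uniformly over the four panels.

    Useful as a chance-level reference: its expected Type 1 AUC is 0.5.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n = n_signal + n_noise
    code = rng.integers(0, 4, size=n)
    ptype = np.concatenate(
        [np.full(n_signal, "present"), np.full(n_noise, "absent")]
    )
    return pd.DataFrame(
        dict(
            participant_id="U0001",
            age_group="adult",
            trial_index=1,
            probe_index=1,
            probe_type=ptype,
            location=1,
            image_id=1,
            initial_congruency="congruent",
            response=_RESPONSE_ARR[code],
            rt_ms=1000.0,
            dxc=_DXC_ARR[code],
        )
    )
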