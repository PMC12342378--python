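"""Nonparametric Type 1 and Type 2 ROC/AUC and the age-slope fit.

Type 1 (objective discrimination): original/present probes are "signal
present", absent probes "signal absent"; modified probes are excluded.  The
ROC accumulates hit and false-alarm proportions at the three D x C criteria
(>= +3, >= +1, >= -1) and the AUC is the trapezoidal area over the anchored
polyline, which equals the tie-corrected concordance probability
P(dxc_signal > dxc_noise) + 0.5 P(tie).

Type 2 (metacognitive accuracy): correct responses are "signal present",
incorrect responses "signal absent", and the single criterion is high
(|D x C| = 3) versus low confidence, giving the closed-form area
(1 + h2 - f2) / 2.

AUC is used rather than d'/meta-d' because the latter are inappropriate for
strongly asymmetric ROC curves, which rating data of this kind produce.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data_model import (
    AGE_CODING,
    DXC_VALUES,
    NOISE_PROBES,
    SIGNAL_PROBES,
    Cohort,
)

logger = logging.getLogger(__name__)

#: Type 1 ROC criteria on the D x C scale, most stringent first.
TYPE1_CRITERIA: tuple[int, ...] = (3, 1, -1)


@dataclasses.dataclass
class RocCurve:
    """Ordered (false-alarm, hit) points with (0,0)/(1,1) anchors."""

    points: np.ndarray  # shape (k, 2), columns (fa, hit), fa nondecreasing
    kind: str  # "type1" | "type2"
    criteria: tuple

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (k, 2) array")
        if (pts < -1e-12).any() or (pts > 1 + 1e-12).any():
            raise ValueError("ROC coordinates must lie in [0, 1]")
        if np.any(np.diff(pts[:, 0]) < -1e-12):
            raise ValueError("false-alarm coordinates must be nondecreasing")
        self.points = pts


@dataclasses.dataclass
class AucResult:
    """Per-participant area under the ROC, or an undefined marker.

    ``auc`` is NaN when one of the two response classes is empty (no signal
    or no noise probes for Type 1; no correct or no incorrect responses for
    Type 2), in which case ``defined`` is False.
    """

    participant_id: str
    age_group: str
    kind: str
    auc: float
    n_signal: int
    n_noise: int

    @property
    def defined(self) -> bool:
        return not np.isnan(self.auc)


def _dxc_of(records: pd.DataFrame) -> pd.Series:
    if "dxc" in records.columns:
        return records["dxc"]
    from .data_model import DXC_MAP

    return records["response"].map(DXC_MAP)


def _roc_from_counts(signal_counts: np.ndarray, noise_counts: np.ndarray,
                     kind: str, criteria: tuple) -> RocCurve:
    """Counts are per D x C category ordered (+3, +1, -1, -3)."""
    n_s, n_n = signal_counts.sum(), noise_counts.sum()
    hits = np.cumsum(signal_counts)[:-1] / n_s
    fas = np.cumsum(noise_counts)[:-1] / n_n
    pts = np.vstack([(0.0, 0.0), *zip(fas, hits), (1.0, 1.0)])
    return RocCurve(points=pts, kind=kind, criteria=criteria)


def _category_counts(dxc: np.ndarray) -> np.ndarray:
    return np.array([(dxc == v).sum() for v in DXC_VALUES])


def type1_roc(records: pd.DataFrame) -> RocCurve:
    """Three-criterion Type 1 ROC for one participant's scored probes.

    Signal = original and present probes; noise = absent probes; modified
    probes do not enter.  Raises ``ValueError`` when either class is empty
    (callers convert this into an undefined AUC marker).
    """
    dxc = _dxc_of(records).to_numpy()
    ptype = records["probe_type"].to_numpy()
    signal = np.isin(ptype, SIGNAL_PROBES)
    noise = np.isin(ptype, NOISE_PROBES)
    if signal.sum() == 0 or noise.sum() == 0:
        raise ValueError("Type 1 ROC requires both signal and noise probes")
    return _roc_from_counts(
        _category_counts(dxc[signal]), _category_counts(dxc[noise]),
        kind="type1", criteria=TYPE1_CRITERIA,
    )


def correctness(records: pd.DataFrame, include_modified: bool = False) -> pd.Series:
    """Boolean correctness of each scored probe response.

    Original/present probes are correct when answered "present" (dxc > 0),
    absent probes when answered "absent" (dxc < 0).  Modified probes (whose
    content was altered, so "absent" is the accurate report) are excluded by
    default and scored as absent-correct when ``include_modified`` is set.
    Catch probes are never scored; excluded rows come back as NA.
    """
    dxc = _dxc_of(records)
    ptype = records["probe_type"]
    correct = pd.Series(pd.NA, index=records.index, dtype="boolean")
    sig = ptype.isin(SIGNAL_PROBES)
    correct[sig] = dxc[sig] > 0
    noi = ptype.isin(NOISE_PROBES)
    correct[noi] = dxc[noi] < 0
    if include_modified:
        mod = ptype == "modified"
        correct[mod] = dxc[mod] < 0
    return correct


def type2_roc(records: pd.DataFrame, include_modified: bool = False) -> RocCurve:
    """Single-criterion Type 2 ROC (high vs low confidence given correctness).

    The interior point is (f2, h2) with h2 = P(|dxc| = 3 | correct) and
    f2 = P(|dxc| = 3 | incorrect).  Raises ``ValueError`` when there are no
    correct or no incorrect responses.
    """
    correct = correctness(records, include_modified=include_modified)
    scored = correct.notna()
    dxc = _dxc_of(records)[scored].to_numpy()
    corr = correct[scored].to_numpy(dtype=bool)
    high = np.abs(dxc) == 3
    n_c, n_i = corr.sum(), (~corr).sum()
    if n_c == 0 or n_i == 0:
        raise ValueError("Type 2 ROC requires both correct and incorrect responses")
    h2 = high[corr].mean()
    f2 = high[~corr].mean()
    pts = np.array([(0.0, 0.0), (f2, h2), (1.0, 1.0)])
    return RocCurve(points=pts, kind="type2", criteria=("high_vs_low",))


def auc(roc: RocCurve) -> float:
    """Trapezoidal area under the anchored ROC polyline."""
    return float(np.trapezoid(roc.points[:, 1], roc.points[:, 0]))


def type2_auc(records: pd.DataFrame, include_modified: bool = False) -> float:
    """Convenience: area of the Type 2 ROC, (1 + h2 - f2) / 2."""
    return auc(type2_roc(records, include_modified=include_modified))


def _participant_auc(pid: str, age: str, records: pd.DataFrame, kind: str,
                     include_modified: bool) -> AucResult:
    try:
        if kind == "type1":
            ptype = records["probe_type"].to_numpy()
            n_s = int(np.isin(ptype, SIGNAL_PROBES).sum())
            n_n = int(np.isin(ptype, NOISE_PROBES).sum())
            roc = type1_roc(records)
        elif kind == "type2":
            correct = correctness(records, include_modified=include_modified)
            n_s = int((correct == True).sum())  # noqa: E712 - pandas boolean
            n_n = int((correct == False).sum())  # noqa: E712
            roc = type2_roc(records, include_modified=include_modified)
        else:
            raise ValueError(f"unknown AUC kind {kind!r}")
        value = auc(roc)
    except ValueError as err:
        if "requires both" not in str(err):
            raise
        value = float("nan")
    return AucResult(participant_id=pid, age_group=age, kind=kind,
                     auc=value, n_signal=n_s, n_noise=n_n)


def cohort_auc_table(cohort: Cohort, kind: str,
                     include_modified: bool = False) -> pd.DataFrame:
    """One AUC row per participant of a (post-exclusion) cohort.

    Columns: participant_id, age_group, kind, auc, n_signal, n_noise,
    defined.  Undefined participants are kept with auc = NaN.
    """
    rows = []
    scored = cohort.scored_records()
    age_of = dict(zip(cohort.meta["participant_id"], cohort.meta["age_group"]))
    for pid, sub in scored.groupby("participant_id", sort=True):
        res = _participant_auc(pid, age_of[pid], sub, kind, include_modified)
        rows.append(
            dict(participant_id=res.participant_id, age_group=res.age_group,
                 kind=res.kind, auc=res.auc, n_signal=res.n_signal,
                 n_noise=res.n_noise, defined=res.defined)
        )
    cols = ["participant_id", "age_group", "kind", "auc",
            "n_signal", "n_noise", "defined"]
    return pd.DataFrame(rows, columns=cols)


def write_auc_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


@dataclasses.dataclass
class AgeSlopeFit:
    """OLS fit of per-participant AUC on coded age group (0..3)."""

    slope: float
    intercept: float
    slope_se: float
    resid_sd: float
    n_used: int
    n_dropped: int
    coding: dict[str, int]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def fit_age_slope(auc_table: pd.DataFrame,
                  coding: dict[str, int] | None = None) -> AgeSlopeFit:
    """Ordinary least squares of AUC on the age-group index.

    Age groups are coded as consecutive integers (default 0..3 in
    recruitment order); undefined AUCs are dropped with a logged count.
    Raises ``ValueError`` when fewer than two distinct groups remain.
    """
    coding = dict(AGE_CODING) if coding is None else coding
    defined = auc_table[auc_table["auc"].notna()]
    n_dropped = len(auc_table) - len(defined)
    if n_dropped:
        logger.info("fit_age_slope: dropped %d undefined AUC(s)", n_dropped)
    x = defined["age_group"].map(coding).to_numpy(dtype=float)
    y = defined["auc"].to_numpy(dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("age-slope fit needs >= 2 distinct age groups with defined AUCs")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    resid_sd = float(np.sqrt(model.scale))
    return AgeSlopeFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        slope_se=float(model.bse[1]),
        resid_sd=resid_sd,
        n_used=len(defined),
        n_dropped=n_dropped,
        coding=coding,
    )
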