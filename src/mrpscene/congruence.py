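"""Per-image congruence statistics: delta-DxC, delta-delta-DxC, test screens.

For a given image pair, ``delta_dxc = mean DxC(original) - mean DxC(modified)``
measures how well the actual content is discriminated from its altered
version; computed separately under the congruent and incongruent initial
image.  The congruence effect is the second difference

    ddxc = delta_dxc(congruent) - delta_dxc(incongruent)

(positive = better discrimination when the initial scene was congruent).
The design is between-participant at the image level: a given participant
saw a given initial image in only one congruency condition, so per-image
cell means are taken across participants.

The screen runs, per image, one-sample t-tests of delta-DxC against zero in
each age x condition cell and a two-way between-subjects ANOVA
(age x condition) whose interaction p-value is corrected across images by
Bonferroni, Benjamini-Hochberg and Holm.  Covariate correlations relate
per-image delta-DxC to the log size of the critical object (or a knowledge
rating).  The hierarchical model comparison for age-by-image interaction
uses maximum-likelihood linear mixed models with a BIC-based Laplace
approximation to the marginal likelihood; this is an approximation to the
MCMC bridge-sampling comparison such analyses are usually run with, and
every report carries that caveat.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_model import AGE_CODING, CONGRUENCY_LEVELS, Cohort

logger = logging.getLogger(__name__)

MODEL_COMPARISON_CAVEAT = (
    "approximate marginal likelihood (ML mixed model + BIC/Laplace); "
    "not an MCMC bridge-sampling estimate"
)


def participant_delta_dxc(cohort: Cohort) -> pd.DataFrame:
    """Per (participant, image) delta-DxC from the original/modified pair.

    Each participant saw one original and one modified probe per initial
    image, so the row value is simply their DxC difference.  Columns:
    participant_id, age_group, image_id, initial_congruency, delta_dxc.
    """
    rec = cohort.scored_records()
    om = rec[rec["probe_type"].isin(["original", "modified"])]
    wide = om.pivot_table(
        index=["participant_id", "age_group", "image_id", "initial_congruency"],
        columns="probe_type", values="dxc", aggfunc="mean",
    ).reset_index()
    missing = wide["original"].isna() | wide["modified"].isna()
    if missing.any():
        logger.warning("dropping %d image cells missing one probe type",
                       int(missing.sum()))
        wide = wide[~missing]
    wide["delta_dxc"] = wide["original"] - wide["modified"]
    return wide[["participant_id", "age_group", "image_id",
                 "initial_congruency", "delta_dxc"]].reset_index(drop=True)


def delta_dxc_table(cohort: Cohort) -> pd.DataFrame:
    """Cell means of delta-DxC per (image, age group, congruency condition).

    Columns: image_id, age_group, condition, mean_dxc_original,
    mean_dxc_modified, delta_dxc, n_participants.  Empty cells are omitted
    (with a logged count when an image loses a condition entirely).
    """
    rec = cohort.scored_records()
    om = rec[rec["probe_type"].isin(["original", "modified"])]
    grouped = om.groupby(
        ["image_id", "age_group", "initial_congruency", "probe_type"],
        observed=True,
    )["dxc"].agg(["mean", "count"]).reset_index()
    wide = grouped.pivot_table(
        index=["image_id", "age_group", "initial_congruency"],
        columns="probe_type", values=["mean", "count"],
    )
    wide.columns = [f"{a}_{b}" for a, b in wide.columns]
    wide = wide.reset_index().rename(
        columns={
            "initial_congruency": "condition",
            "mean_original": "mean_dxc_original",
            "mean_modified": "mean_dxc_modified",
        }
    )
    ok = wide["mean_dxc_original"].notna() & wide["mean_dxc_modified"].notna()
    if (~ok).any():
        logger.warning("omitting %d cells missing a probe type", int((~ok).sum()))
    wide = wide[ok].copy()
    wide["delta_dxc"] = wide["mean_dxc_original"] - wide["mean_dxc_modified"]
    wide["n_participants"] = (
        wide[["count_original", "count_modified"]].min(axis=1).astype(int)
    )
    return wide[["image_id", "age_group", "condition", "mean_dxc_original",
                 "mean_dxc_modified", "delta_dxc", "n_participants"]]


def ddxc(table: pd.DataFrame) -> pd.DataFrame:
    """Congruence-effect table: ddxc per (image, age group).

    Exact subtraction of the incongruent from the congruent cell mean.
    Images with only one condition present for an age group are dropped
    with a logged count.
    """
    cong, incong = CONGRUENCY_LEVELS
    wide = table.pivot_table(
        index=["image_id", "age_group"], columns="condition",
        values="delta_dxc",
    ).reset_index()
    for level in CONGRUENCY_LEVELS:
        if level not in wide.columns:
            wide[level] = np.nan
    ok = wide[cong].notna() & wide[incong].notna()
    if (~ok).any():
        logger.warning("dropping %d one-condition (image, age) cells",
                       int((~ok).sum()))
    out = wide[ok].copy()
    out["ddxc"] = out[cong] - out[incong]
    return out[["image_id", "age_group", "ddxc"]].reset_index(drop=True)


def per_image_screen(cohort: Cohort, alpha: float = 0.05) -> pd.DataFrame:
    """Per-image t-tests and two-way ANOVA interaction screen.

    For every image: one-sample t-tests of participant-level delta-DxC
    against 0 in each age x condition cell (columns ``t_p_<group>_<cond>``,
    NaN when the cell has < 2 participants), and the age x condition
    interaction p-value of a two-way between-subjects ANOVA
    (``p_interaction``), corrected across images by Bonferroni, BH and Holm
    (``p_bonferroni``, ``p_bh``, ``p_holm``).
    """
    pl = participant_delta_dxc(cohort)
    rows = []
    for image_id, sub in pl.groupby("image_id", sort=True):
        row: dict = {"image_id": image_id}
        for (age, cond), cell in sub.groupby(["age_group", "initial_congruency"],
                                             observed=True):
            key = f"t_p_{age}_{cond}"
            if len(cell) < 2 or cell["delta_dxc"].std(ddof=1) == 0:
                row[key] = np.nan
            else:
                row[key] = stats.ttest_1samp(cell["delta_dxc"], 0.0).pvalue
        row["p_interaction"] = _interaction_pvalue(sub)
        rows.append(row)
    out = pd.DataFrame(rows)
    defined = out["p_interaction"].notna()
    for method, col in (("bonferroni", "p_bonferroni"), ("fdr_bh", "p_bh"),
                        ("holm", "p_holm")):
        out[col] = np.nan
        if defined.any():
            out.loc[defined, col] = multipletests(
                out.loc[defined, "p_interaction"], alpha=alpha, method=method
            )[1]
    return out


def _interaction_pvalue(sub: pd.DataFrame) -> float:
    """Age x condition interaction p from a classical two-way ANOVA."""
    cells = sub.groupby(["age_group", "initial_congruency"], observed=True).size()
    if (cells < 2).any() or sub["age_group"].nunique() < 2 \
            or sub["initial_congruency"].nunique() < 2:
        return np.nan
    model = smf.ols(
        "delta_dxc ~ C(age_group) * C(initial_congruency)", data=sub
    ).fit()
    table = sm.stats.anova_lm(model, typ=2)
    return float(table.loc["C(age_group):C(initial_congruency)", "PR(>F)"])


def covariate_correlation(
    delta_table: pd.DataFrame,
    covariates: pd.DataFrame,
    covariate: str = "log_object_size",
) -> pd.DataFrame:
    """Pearson r of per-image delta-DxC against a covariate, per scope.

    ``delta_table`` is the output of :func:`delta_dxc_table`;
    ``covariates`` holds one row per image (columns ``image_id`` and the
    covariate).  One (r, p) per age group x condition; undefined (NaN) when
    fewer than 3 images or the covariate has zero variance in scope.
    Pearson correlation is invariant to affine rescaling of the covariate.
    """
    merged = delta_table.merge(covariates[["image_id", covariate]], on="image_id")
    rows = []
    for (age, cond), sub in merged.groupby(["age_group", "condition"],
                                           observed=True):
        x = sub[covariate].to_numpy(dtype=float)
        y = sub["delta_dxc"].to_numpy(dtype=float)
        if len(sub) < 3 or np.std(x) == 0 or np.std(y) == 0:
            r, p = np.nan, np.nan
        else:
            res = stats.pearsonr(x, y)
            r, p = float(res.statistic), float(res.pvalue)
        rows.append(dict(age_group=age, condition=cond, covariate=covariate,
                         r=r, p=p, n_images=len(sub)))
    return pd.DataFrame(rows)


@dataclasses.dataclass
class ModelComparison:
    """Approximate marginal-likelihood comparison of two mixed models.

    ``log_ml_interaction`` is for ddxc ~ age + (age | image),
    ``log_ml_image`` for ddxc ~ age + (1 | image);
    ``bf10 = exp(log_ml_interaction - log_ml_image)``.
    """

    log_ml_interaction: float
    log_ml_image: float
    bf10: float
    backend: str
    converged: bool
    caveat: str = MODEL_COMPARISON_CAVEAT

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def _bic_log_marginal(result, n: int) -> float:
    """Laplace/BIC approximation: log p(y|M) ~= llf - (k/2) log n."""
    k = result.params.shape[0] + len(result.cov_re.to_numpy().ravel()) + 1
    return float(result.llf - 0.5 * k * np.log(n))


def compare_hierarchical_models(ctable: pd.DataFrame) -> ModelComparison:
    """Random age-slope-by-image versus random-intercept-by-image model.

    Fits both linear mixed models by maximum likelihood (age coded 0..3 as
    a numeric predictor, image as the grouping factor) and compares
    BIC-approximated log marginal likelihoods.  Requires >= 2 age groups
    and >= 10 images; non-convergence is flagged, never silently replaced.
    """
    if ctable["image_id"].nunique() < 10:
        raise ValueError("model comparison needs >= 10 images")
    if ctable["age_group"].nunique() < 2:
        raise ValueError("model comparison needs >= 2 age groups")
    df = ctable.copy()
    df["age"] = df["age_group"].map(AGE_CODING).astype(float)
    n = len(df)

    converged = True
    results = {}
    for name, re_formula in (("interaction", "~age"), ("image", "~1")):
        model = smf.mixedlm("ddxc ~ age", df, groups=df["image_id"],
                            re_formula=re_formula)
        fit = None
        for method in ("lbfgs", "powell", "nm"):
            try:
                cand = model.fit(reml=False, method=method, maxiter=500)
            except Exception as err:  # singular Hessian etc.; try next optimizer
                logger.info("mixed model %s via %s failed: %s", name, method, err)
                continue
            fit = cand
            if cand.converged:
                break
        if fit is None:
            raise RuntimeError(f"mixed model {name!r} failed under all optimizers")
        converged = converged and bool(fit.converged)
        results[name] = _bic_log_marginal(fit, n)

    bf10 = float(np.exp(results["interaction"] - results["image"]))
    return ModelComparison(
        log_ml_interaction=results["interaction"],
        log_ml_image=results["image"],
        bf10=bf10,
        backend="statsmodels-mixedlm-bic",
        converged=converged,
    )
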