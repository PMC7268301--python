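"""Result surfaces: pre-treatment comparison tables, score exports, and
the two-group ANOVA that detects a grain-angle artifact in predictions.

The headline check works as follows: predict the trait on the held-out
validation set, split the predictions by grain angle (0 vs 90 degrees)
and run a one-way ANOVA. A significant angle effect on the *predictions*
of a trait that is independent of angle means the calibration has
absorbed the confounder; a successful deconfounding removes it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import SpectraSet
from .errors import ValidationError
from .pls import CVResult, FitMetrics, PLSModel, fit_pls1, loo_cv, metrics, predict, transform
from .preprocess import PreprocessConfig, apply_pretreatment
from .smc import DeconfoundSelection, refit_on_selection, select_deconfounded, smc

#: significance stars: p below key -> label
STARS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass
class AnovaResult:
    """One-way ANOVA of a value vector over group labels."""

    f_stat: float
    p_value: float
    group_means: dict
    df: tuple[int, int]

    @property
    def stars(self) -> str:
        for cut, label in STARS:
            if self.p_value < cut:
                return label
        return "ns"


@dataclass
class EvaluationReport:
    """Metrics for one (pre-treatment, response) model."""

    pretreatment: str
    response: str
    cal_metrics: FitMetrics
    val_metrics: FitMetrics
    chosen_lv: int
    n_variables: int
    anova: AnovaResult | None = None
    scores: pd.DataFrame | None = None  # per-sample score1, score2, angle, set
    model: PLSModel | None = None
    cv: CVResult | None = None


@dataclass
class DeconfoundReport:
    """Full-spectrum vs sMC-reduced models for trait and confounder."""

    trait_full: EvaluationReport
    trait_reduced: EvaluationReport
    confounder_full: EvaluationReport
    confounder_reduced: EvaluationReport
    selection: DeconfoundSelection

    def __iter__(self):
        # unpacks as the (full, reduced) trait report pair
        return iter((self.trait_full, self.trait_reduced))


def anova_two_group(values: np.ndarray, groups: np.ndarray) -> AnovaResult:
    """Classical one-way ANOVA of ``values`` across the labels in ``groups``."""
    values = np.asarray(values, dtype=float).ravel()
    groups = np.asarray(groups).ravel()
    if values.size != groups.size:
        raise ValidationError("values and groups must have equal length")
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValidationError(f"need >= 2 groups (got {len(labels)})")
    members = [values[groups == g] for g in labels]
    for g, v in zip(labels, members):
        if v.size < 2:
            raise ValidationError(f"group {g!r} has {v.size} member(s); need >= 2")

    n = values.size
    k = len(labels)
    grand = values.mean()
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in members)
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in members)
    df = (k - 1, n - k)
    if ss_within == 0.0:
        f = np.inf if ss_between > 0 else 0.0
        p = 0.0 if ss_between > 0 else 1.0
    else:
        f = (ss_between / df[0]) / (ss_within / df[1])
        p = float(stats.f.sf(f, *df))
    return AnovaResult(
        f_stat=float(f), p_value=p,
        group_means={g: float(v.mean()) for g, v in zip(labels, members)},
        df=df,
    )


def _score_table(
    model: PLSModel, s_cal: SpectraSet, s_val: SpectraSet, cols: np.ndarray
) -> pd.DataFrame:
    """First two score components per sample, with angle label and set."""
    frames = []
    for s, tag in ((s_cal, "cal"), (s_val, "val")):
        T = transform(model, s.absorbance[:, cols])
        frames.append(pd.DataFrame({
            "sample_id": s.sample_ids,
            "score1": T[:, 0],
            "score2": T[:, 1] if T.shape[1] > 1 else np.zeros(T.shape[0]),
            "angle": s.meta["angle"].to_numpy(),
            "set": tag,
        }))
    return pd.concat(frames, ignore_index=True)


def _fit_and_report(
    s_cal: SpectraSet,
    s_val: SpectraSet,
    response: str,
    label: str,
    max_lv: int,
    columns: np.ndarray | None = None,
) -> EvaluationReport:
    cols = np.arange(s_cal.n_wavenumbers) if columns is None else np.asarray(columns, int)
    Xc, Xv = s_cal.absorbance[:, cols], s_val.absorbance[:, cols]
    yc, yv = s_cal.response(response), s_val.response(response)
    cv = loo_cv(Xc, yc, max_lv=max_lv)
    model = fit_pls1(Xc, yc, cv.chosen_lv, wavenumbers=s_cal.wavenumbers[cols])
    yv_hat = predict(model, Xv)
    if np.ptp(yv) == 0:  # e.g. single-angle validation set: R^2 undefined
        val_metrics = FitMetrics(r2=np.nan,
                                 rmse=float(np.sqrt(np.mean((yv - yv_hat) ** 2))))
    else:
        val_metrics = metrics(yv, yv_hat)
    return EvaluationReport(
        pretreatment=label,
        response=response,
        cal_metrics=metrics(yc, predict(model, Xc)),
        val_metrics=val_metrics,
        chosen_lv=model.n_lv,
        n_variables=cols.size,
        model=model,
        cv=cv,
    )


def pretreatment_grid(
    s_cal: SpectraSet,
    s_val: SpectraSet,
    response: str,
    configs: list[PreprocessConfig],
    max_lv: int = 20,
) -> list[EvaluationReport]:
    """One full-spectrum model per pre-treatment variant.

    Each variant is applied consistently to calibration and validation
    (SNV and derivatives are per-spectrum operations with nothing to fit,
    so there is no train/test leakage); the LV count is chosen by LOO-CV
    on the calibration set only.
    """
    if s_cal.wavenumbers.size != s_val.wavenumbers.size or not np.allclose(
        s_cal.wavenumbers, s_val.wavenumbers
    ):
        raise ValidationError("calibration and validation axes differ")
    reports = []
    for cfg in configs:
        pc = apply_pretreatment(s_cal, cfg)
        pv = apply_pretreatment(s_val, cfg)
        reports.append(_fit_and_report(pc, pv, response, cfg.method, max_lv))
    return reports


def _maybe_anova(values: np.ndarray, s_val: SpectraSet) -> AnovaResult | None:
    angles = s_val.meta["angle"].to_numpy(dtype=float)
    present = pd.unique(angles[~np.isnan(angles)])
    counts = [(angles == a).sum() for a in present]
    if len(present) < 2 or min(counts) < 2:
        warnings.warn(
            "validation set lacks two angle groups with >= 2 members; "
            "ANOVA omitted", stacklevel=3,
        )
        return None
    return anova_two_group(values, angles)


def deconfound_report(
    s_cal: SpectraSet,
    s_val: SpectraSet,
    trait: str = "ec",
    confounder: str = "angle",
    preprocess: PreprocessConfig | None = None,
    alpha: float = 0.05,
    top_k: int | None = None,
    max_lv: int = 20,
) -> DeconfoundReport:
    """Run the full-spectrum and sMC-deconfounded pipelines side by side.

    Both pipelines use the same pre-treatment (SNV + 1st derivative by
    default). sMC profiles for the trait and the confounder are computed
    on the calibration set only; the reduced models use the wavenumbers
    significant for the trait but not for the confounder. Each trait
    report carries a one-way ANOVA of the validation predictions across
    angle groups and a score export for the first two latent variables.
    """
    if preprocess is None:
        preprocess = PreprocessConfig(method="snv_sg1")
    pc = apply_pretreatment(s_cal, preprocess)
    pv = apply_pretreatment(s_val, preprocess)

    # full-spectrum models
    trait_full = _fit_and_report(pc, pv, trait, preprocess.method, max_lv)
    conf_full = _fit_and_report(pc, pv, confounder, preprocess.method, max_lv)

    # sMC profiles on calibration only; dual-response selection
    prof_trait = smc(pc.absorbance, pc.response(trait), trait_full.model, alpha)
    prof_conf = smc(pc.absorbance, pc.response(confounder), conf_full.model, alpha)
    sel = select_deconfounded(prof_trait, prof_conf, top_k=top_k)
    cols = np.asarray(sel.selected, int)

    trait_red = _fit_and_report(pc, pv, trait, f"{preprocess.method}+smc", max_lv, cols)
    conf_red = _fit_and_report(pc, pv, confounder, f"{preprocess.method}+smc", max_lv, cols)

    all_cols = np.arange(pc.n_wavenumbers)
    for rep, sub_cols in ((trait_full, all_cols), (trait_red, cols)):
        rep.anova = _maybe_anova(predict(rep.model, pv.absorbance[:, sub_cols]), pv)
        rep.scores = _score_table(rep.model, pc, pv, sub_cols)

    return DeconfoundReport(
        trait_full=trait_full,
        trait_reduced=trait_red,
        confounder_full=conf_full,
        confounder_reduced=conf_red,
        selection=sel,
    )


def reports_table(reports: list[EvaluationReport]) -> pd.DataFrame:
    """Tabulate reports in the layout of a calibration summary table."""
    rows = []
    for r in reports:
        rows.append({
            "pretreatment": r.pretreatment,
            "response": r.response,
            "n_variables": r.n_variables,
            "lv": r.chosen_lv,
            "r2_cal": r.cal_metrics.r2,
            "rmse_cal": r.cal_metrics.rmse,
            "r2_val": r.val_metrics.r2,
            "rmse_val": r.val_metrics.rmse,
            "anova_p": np.nan if r.anova is None else r.anova.p_value,
            "anova_stars": "" if r.anova is None else r.anova.stars,
        })
    return pd.DataFrame(rows)
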