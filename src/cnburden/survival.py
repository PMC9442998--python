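"""Non-linear survival modelling of copy-number burden.

Cox proportional-hazards models (Efron tie handling, via lifelines) with the
functional form of the burden covariate chosen by first-degree fractional
polynomial — FP(1) — selection over the power catalogue
{-2, -1, -0.5, ln, 0.5, 1, 2, 3}, using the standard closed test: the best
power is kept over the linear form only when the 1-df likelihood-ratio
comparison shows evidence at the 10% level.  On top of the selected form:
metastatic-state interaction models with a likelihood-ratio test, relative-
hazard curves against a reference burden, and Kaplan-Meier estimates by
burden quartile with the 4-year survival table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats

FP_POWERS = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)   # 0 = ln
FP_SCALE = 10.0     # burden % divided by this before the power transform
LINEAR_POWER = 1.0
FP_ALPHA = 0.10     # closed-test level


def fp1_transform(burden, power: float, scale: float = FP_SCALE) -> np.ndarray:
    """x^p (ln for p = 0) of burden% / scale.  Burdens must be positive."""
    x = np.asarray(burden, dtype=float) / scale
    if np.any(x <= 0):
        raise ValueError("fp1_transform requires strictly positive burdens "
                         "(apply the zero-shift rule first)")
    return np.log(x) if power == 0 else x ** power


def shift_zero_burdens(burden) -> tuple[np.ndarray, float]:
    """If any burden is 0, add half the smallest positive burden to all."""
    b = np.asarray(burden, dtype=float)
    if np.any(b < 0):
        raise ValueError("negative burden")
    if np.any(b == 0):
        shift = float(b[b > 0].min()) / 2.0
        warnings.warn(f"zero burdens present; shifting all burdens by {shift:.4g}%")
        return b + shift, shift
    return b, 0.0


def null_partial_loglik(times, events) -> float:
    """Efron partial log-likelihood of the covariate-free Cox model.

    With all relative hazards equal to 1, each event time with d tied events
    and risk-set size n contributes -sum_{j=0..d-1} log(n - j).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    order = np.argsort(t)
    t, e = t[order], e[order]
    n = len(t)
    ll = 0.0
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        d = int(e[i:j].sum())
        at_risk = n - i
        for k in range(d):
            ll -= np.log(at_risk - k)
        i = j
    return float(ll)


@dataclass
class FPFit:
    """Outcome of FP(1) functional-form selection for one endpoint."""

    outcome: str
    selected_power: float            # 1.0 when the closed test keeps linear
    best_power: float                # likelihood-best power
    coef: float                      # burden-transform coefficient (selected model)
    coef_se: float
    coef_ci: tuple
    params: pd.Series                # all coefficients of the selected model
    loglik_null: float
    loglik_linear: float
    loglik_best: float
    loglik_by_power: dict
    p_inclusion: float               # best FP1 vs covariate omitted (2 df)
    p_linearity: float               # best FP1 vs linear (1 df)
    n: int
    n_events: int
    scale: float = FP_SCALE
    shift: float = 0.0
    model: object = field(default=None, repr=False)

    @property
    def nonlinear_selected(self) -> bool:
        return self.selected_power != LINEAR_POWER

    def transform(self, burden) -> np.ndarray:
        b = np.asarray(burden, dtype=float) + self.shift
        return fp1_transform(b, self.selected_power, self.scale)


def _fit_cox(df: pd.DataFrame, duration_col: str, event_col: str):
    cph = CoxPHFitter(penalizer=0.0)
    cph.fit(df, duration_col=duration_col, event_col=event_col)
    return cph


def select_fp1_cox(df: pd.DataFrame, outcome: str, burden_col: str = "burden",
                   duration_col: str | None = None, event_col: str | None = None,
                   adjusters: tuple = (), powers=FP_POWERS,
                   alpha: float = FP_ALPHA, scale: float = FP_SCALE) -> FPFit:
    """FP(1) Cox functional-form selection for one outcome.

    ``adjusters`` are names of already-numeric columns entered untransformed.
    Closed test: (i) best FP1 vs covariate-omitted model, 2 df; (ii) best
    FP1 vs linear, 1 df; linear is kept unless (ii) has p < ``alpha``.
    Log-likelihood ties below 1e-8 resolve toward linear, then catalogue
    order.  Powers whose fit fails to converge are skipped with a warning.
    """
    duration_col = duration_col or f"{outcome}_time"
    event_col = event_col or f"{outcome}_event"
    cols = [burden_col, duration_col, event_col, *adjusters]
    data = df[cols].dropna().copy()
    n, n_events = len(data), int(data[event_col].sum())
    if n_events < 10:
        raise ValueError(f"{outcome}: only {n_events} events (< 10)")
    shifted, shift = shift_zero_burdens(data[burden_col])

    if adjusters:
        null_model = _fit_cox(data[[duration_col, event_col, *adjusters]],
                              duration_col, event_col)
        ll_null = float(null_model.log_likelihood_)
    else:
        ll_null = null_partial_loglik(data[duration_col], data[event_col])

    fits, lls = {}, {}
    powers = tuple(powers) if LINEAR_POWER in powers else (*powers, LINEAR_POWER)
    for p in powers:
        sub = data[[duration_col, event_col, *adjusters]].copy()
        sub["fp_burden"] = fp1_transform(shifted, p, scale)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = _fit_cox(sub, duration_col, event_col)
        except Exception as err:       # noqa: BLE001 — any solver failure
            warnings.warn(f"{outcome}: power {p} failed to converge ({err}); skipped")
            continue
        fits[p], lls[p] = m, float(m.log_likelihood_)
    if LINEAR_POWER not in lls:
        raise RuntimeError(f"{outcome}: linear Cox fit failed; cannot run closed test")

    ll_linear = lls[LINEAR_POWER]
    best_ll = max(lls.values())
    # ties toward linear, then catalogue order
    if best_ll - ll_linear < 1e-8:
        best_power = LINEAR_POWER
    else:
        best_power = next(p for p in powers if p in lls and best_ll - lls[p] < 1e-8)
    ll_best = lls[best_power]

    p_inclusion = float(stats.chi2.sf(2.0 * (ll_best - ll_null), df=2))
    p_linearity = float(stats.chi2.sf(2.0 * max(ll_best - ll_linear, 0.0), df=1))
    selected = best_power if p_linearity < alpha else LINEAR_POWER
    model = fits[selected]
    summ = model.summary.loc["fp_burden"]
    return FPFit(outcome=outcome, selected_power=selected, best_power=best_power,
                 coef=float(model.params_["fp_burden"]),
                 coef_se=float(summ["se(coef)"]),
                 coef_ci=(float(summ["coef lower 95%"]), float(summ["coef upper 95%"])),
                 params=model.params_.copy(),
                 loglik_null=ll_null, loglik_linear=ll_linear, loglik_best=ll_best,
                 loglik_by_power={p: lls[p] for p in lls},
                 p_inclusion=p_inclusion, p_linearity=p_linearity,
                 n=n, n_events=n_events, scale=scale, shift=shift, model=model)


def interaction_lrt(df: pd.DataFrame, outcome: str, fpfit: FPFit,
                    state_col: str = "state", burden_col: str = "burden",
                    adjusters: tuple = (), reference_state: str = "M0N0") -> dict:
    """Burden-transform x metastatic-state interaction, tested by LRT.

    The functional form is frozen to ``fpfit``'s selection.  The main model
    has the transform plus state indicators (and adjusters); the interaction
    model adds transform x state terms (one per non-reference state).
    """
    duration_col, event_col = f"{outcome}_time", f"{outcome}_event"
    cols = [burden_col, state_col, duration_col, event_col, *adjusters]
    data = df[cols].dropna().copy()
    states = sorted(data[state_col].unique())
    if reference_state not in states:
        raise ValueError(f"reference state {reference_state!r} absent")
    counts = data[state_col].value_counts()
    if (counts < 2).any():
        raise ValueError(f"empty/degenerate state cell: {counts.to_dict()}")
    fp = fpfit.transform(data[burden_col])
    base = data[[duration_col, event_col, *adjusters]].copy()
    base["fp_burden"] = fp
    others = [s for s in states if s != reference_state]
    for s in others:
        base[f"state_{s}"] = (data[state_col] == s).astype(float)
    main = _fit_cox(base, duration_col, event_col)
    inter = base.copy()
    for s in others:
        inter[f"fp_x_{s}"] = inter["fp_burden"] * inter[f"state_{s}"]
    inter_model = _fit_cox(inter, duration_col, event_col)
    extra_df = len(others)
    lrt = 2.0 * (float(inter_model.log_likelihood_) - float(main.log_likelihood_))
    return {"outcome": outcome, "lrt_stat": float(max(lrt, 0.0)), "df": extra_df,
            "p": float(stats.chi2.sf(max(lrt, 0.0), df=extra_df)),
            "main_loglik": float(main.log_likelihood_),
            "interaction_loglik": float(inter_model.log_likelihood_),
            "main_model": main, "interaction_model": inter_model}


def relative_hazard_curve(fpfit: FPFit, grid, reference: float,
                          state_coefs: dict | None = None) -> pd.DataFrame:
    """exp(beta * (f(b) - f(reference))) along a burden grid.

    With ``state_coefs`` (state -> burden-transform coefficient, e.g. from an
    interaction model) one curve per state is produced; otherwise the shared-
    effect curve.  The ratio between any two curve heights is independent of
    the reference choice.
    """
    grid = np.asarray(grid, dtype=float)
    if not (grid.min() <= reference <= grid.max()):
        warnings.warn("reference burden outside the curve grid")
    f = fpfit.transform(grid) - fpfit.transform([reference])[0]
    out = {"burden": grid}
    if state_coefs is None:
        out["relative_hazard"] = np.exp(fpfit.coef * f)
    else:
        for state, beta in state_coefs.items():
            out[f"relative_hazard_{state}"] = np.exp(beta * f)
    return pd.DataFrame(out)


def km_by_quartile(df: pd.DataFrame, outcome: str, quartile_col: str = "quartile",
                   horizon: float = 4.0) -> tuple[dict, pd.DataFrame]:
    """Kaplan-Meier estimate per burden quartile plus the horizon-year table.

    The horizon estimate is read from the step function (last value at a
    time <= horizon).  Empty groups are omitted with a warning.
    """
    duration_col, event_col = f"{outcome}_time", f"{outcome}_event"
    curves, rows = {}, []
    for q in ("Q1", "Q2", "Q3", "Q4"):
        sub = df.loc[df[quartile_col] == q]
        if sub.empty:
            warnings.warn(f"quartile {q} empty; omitted from KM")
            continue
        kmf = KaplanMeierFitter(label=q)
        kmf.fit(sub[duration_col], sub[event_col])
        curves[q] = kmf
        rows.append({"quartile": q, "n": len(sub),
                     "events": int(sub[event_col].sum()),
                     f"survival_{horizon:g}y": float(kmf.predict(horizon))})
    return curves, pd.DataFrame(rows)


def encode_clinical(df: pd.DataFrame, pool_low_grades: bool = True,
                    min_grade_count: int = 15) -> tuple[pd.DataFrame, list]:
    """Numeric adjuster columns for multivariable Cox models.

    Metastatic state enters as indicators with M0N0 reference; grading group
    as indicators with the lowest group as reference, pooling groups 1-3
    when jointly sparse; PSA is log-transformed; age and cellularity enter
    untransformed.  Returns (augmented df, adjuster column names).
    """
    out = df.copy()
    adjusters = []
    gg = out["grading_group"]
    if pool_low_grades and (gg <= 3).sum() < min_grade_count:
        grade = gg.where(gg > 3, 3).astype(int)   # 3 = pooled GG1-3
    else:
        grade = gg.astype(int)
    ref = int(grade.min())
    for g in sorted(grade.unique()):
        if g == ref:
            continue
        col = f"gg_{g}"
        out[col] = (grade == g).astype(float)
        adjusters.append(col)
    for s in sorted(out["state"].unique()):
        if s == "M0N0":
            continue
        col = f"state_{s}"
        out[col] = (out["state"] == s).astype(float)
        adjusters.append(col)
    out["log_psa"] = np.log(out["psa"])
    adjusters += ["log_psa", "age", "cellularity"]
    return out, adjusters
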