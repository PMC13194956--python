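"""Mixed-effects analysis of rEZR: group contrasts, ring model, VA models.

Three model families cover the analysis plan:

* **Location models** — one per analysis region: region rEZR on DR group
  (noDR reference) adjusted for disease duration, age, gender (male
  reference) and eye side (right reference), with a patient random
  intercept for between-eye correlation.  The group effect gets a type
  III F-test; pairwise group contrasts (NPDR−noDR, PDR−noDR, PDR−NPDR)
  are reported without multiplicity adjustment and flagged ``gated`` when
  the overall F-test is not significant.
* **Ring model** — per-scan ring rEZR on ring × DR group (interaction),
  the same covariates, a patient random intercept and an eye-within-
  patient intercept for the three replicates per eye.  Within-stage ring
  contrasts use Tukey adjustment over the three comparisons.
* **VA models** — visual acuity (logMAR) on total-area or foveolar rEZR,
  univariable or adjusted for age, duration and DR stage, with a patient
  random intercept.

Estimation is REML (statsmodels ``MixedLM``, optimum polished on the
package's own restricted likelihood); t/F tests and confidence intervals
use Satterthwaite denominator degrees of freedom from
:mod:`rezr.inference`.  Contrasts are differences of model-adjusted means
and, because covariates enter additively, reduce to exact linear
combinations of the fixed-effect coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .inference import RandomInterceptModel

__all__ = [
    "FitResult",
    "Contrast",
    "fit_location_model",
    "pairwise_group_contrasts",
    "fit_ring_model",
    "ring_contrasts",
    "fit_va_model",
    "describe",
    "GROUP_ORDER",
    "RING_ORDER",
]

GROUP_ORDER = ("noDR", "NPDR", "PDR")
RING_ORDER = ("central_1mm", "inner_ring", "outer_ring")

_GROUP_TERM = "C(dr_stage, Treatment('noDR'))"
_RING_TERM = "C(ring, Treatment('central_1mm'))"


@dataclass
class Contrast:
    """A pairwise comparison on the response scale."""

    label: str
    estimate: float
    se: float
    df: float
    ci_low: float
    ci_high: float
    p: float
    adjustment: str = "none"  # none | tukey
    gated: bool = False  # overall F-test was not significant


@dataclass
class FitResult:
    """A fitted mixed model with small-sample tests attached.

    ``params`` has one row per fixed effect (estimate, se, df, t, p and
    95% CI); ``ftests`` one row per tested factor.  ``vc`` holds the
    variance components on the response scale.  Counts follow the
    complete-case convention: ``n_obs`` model rows from ``n_eyes`` eyes of
    ``n_patients`` patients, with ``n_dropped`` rows lost to missing data.
    """

    params: pd.DataFrame
    ftests: pd.DataFrame
    vc: dict
    n_obs: int
    n_eyes: int
    n_patients: int
    n_dropped: int
    response: str
    formula: str
    converged: bool = True
    warnings: list = field(default_factory=list)
    # internal handles for contrast computation
    _engine: object = None
    _beta: np.ndarray | None = None
    _theta: np.ndarray | None = None
    _acov_theta: np.ndarray | None = None
    _exog_names: list = field(default_factory=list)

    def contrast(self, coefs: dict[str, float] | np.ndarray, label: str) -> Contrast:
        """Test a linear combination of fixed effects.

        ``coefs`` maps coefficient names (as in ``params.index``) to
        weights, or gives the full weight vector directly.
        """
        if self._engine is None:
            est = 0.0
            return Contrast(label, est, 0.0, np.inf, est, est, 1.0)
        if isinstance(coefs, dict):
            c = np.zeros(len(self._exog_names))
            for name, w in coefs.items():
                c[self._exog_names.index(name)] = w
        else:
            c = np.asarray(coefs, dtype=float)
        est, se, df, t, p = self._engine.contrast_test(
            c, self._beta, self._theta, self._acov_theta
        )
        half = sps.t.ppf(0.975, df) * se
        return Contrast(label, est, se, df, est - half, est + half, p)

    def term_names(self, prefix: str) -> list[str]:
        return [n for n in self._exog_names if n.startswith(prefix)]


def _prettify(name: str) -> str:
    """Collapse patsy's categorical term syntax to readable labels."""
    return (
        name.replace(_GROUP_TERM, "group")
        .replace(_RING_TERM, "ring")
        .replace("C(gender, Treatment('male'))", "gender")
        .replace("C(eye_side, Treatment('right'))", "eye_side")
        .replace("[T.", "[")
    )


def _degenerate_result(data, response, formula, note) -> FitResult:
    value = float(data[response].iloc[0]) if len(data) else float("nan")
    params = pd.DataFrame(
        {
            "estimate": [value],
            "se": [0.0],
            "df": [np.inf],
            "t": [np.nan],
            "p": [np.nan],
            "ci_low": [value],
            "ci_high": [value],
        },
        index=["Intercept"],
    )
    ftests = pd.DataFrame(
        {"F": [0.0], "df_num": [2], "df_den": [np.inf], "p": [1.0]}, index=["group"]
    )
    return FitResult(
        params=params,
        ftests=ftests,
        vc={},
        n_obs=len(data),
        n_eyes=data["eye_id"].nunique() if "eye_id" in data else len(data),
        n_patients=data["patient_id"].nunique(),
        n_dropped=0,
        response=response,
        formula=formula,
        converged=True,
        warnings=[note],
    )


def _fit_mixed(
    data: pd.DataFrame,
    formula: str,
    response: str,
    ftest_terms: dict[str, str],
    nest_eye: bool = False,
) -> FitResult:
    """Shared REML fit + Satterthwaite post-processing."""
    import statsmodels.formula.api as smf

    if np.ptp(data[response].to_numpy(dtype=float)) == 0.0:
        return _degenerate_result(data, response, formula, "degenerate: constant response")

    notes: list[str] = []
    vcf = {"eye": "0 + C(eye_id)"} if nest_eye else None
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        md = smf.mixedlm(
            formula,
            data,
            groups=data["patient_id"],
            re_formula="1",
            vc_formula=vcf,
        )
        res = None
        for method in ("lbfgs", "bfgs", "cg"):
            try:
                res = md.fit(reml=True, method=method)
                break
            except (np.linalg.LinAlgError, ValueError):
                continue
    for w in caught:
        notes.append(str(w.message))

    if res is not None:
        theta0 = [float(res.cov_re.iloc[0, 0])]
        if nest_eye:
            theta0.append(float(np.asarray(res.vcomp).ravel()[0]))
        theta0.append(float(res.scale))
    else:
        # rare optimizer breakdown: start the REML polish from an even
        # split of the response variance across the components
        notes.append("fitting backend failed; REML optimised from heuristic start")
        v = float(np.var(data[response].to_numpy(dtype=float)))
        theta0 = [v / 2, v / 4, v / 2] if nest_eye else [v / 2, v / 2]

    extra = [data["eye_id"].to_numpy()] if nest_eye else []
    engine = RandomInterceptModel(
        md.endog, md.exog, data["patient_id"].to_numpy(), extra_levels=extra
    )
    theta = engine.fit(theta0)
    ll, beta, _ = engine.profile(theta)
    acov = engine.theta_acov(theta)

    exog_names = list(md.exog_names)
    rows = []
    for i, name in enumerate(exog_names):
        c = np.zeros(len(exog_names))
        c[i] = 1.0
        est, se, df, t, p = engine.contrast_test(c, beta, theta, acov)
        half = sps.t.ppf(0.975, df) * se
        rows.append(
            {
                "estimate": est,
                "se": se,
                "df": df,
                "t": t,
                "p": p,
                "ci_low": est - half,
                "ci_high": est + half,
            }
        )
    params = pd.DataFrame(rows, index=[_prettify(n) for n in exog_names])

    frows = {}
    for label, prefix in ftest_terms.items():
        idx = [i for i, n in enumerate(exog_names) if n.startswith(prefix)]
        L = np.zeros((len(idx), len(exog_names)))
        for r, i in enumerate(idx):
            L[r, i] = 1.0
        F, q, df_den, p = engine.ftest(L, beta, theta, acov)
        frows[label] = {"F": F, "df_num": q, "df_den": df_den, "p": p}
    ftests = pd.DataFrame(frows).T

    vc = {"patient_var": theta[0], "residual_var": theta[-1]}
    if nest_eye:
        vc["eye_var"] = theta[1]
    if min(theta) < 1e-8:
        notes.append("singular fit: a variance component is at the zero boundary")

    return FitResult(
        params=params,
        ftests=ftests,
        vc=vc,
        n_obs=len(data),
        n_eyes=data["eye_id"].nunique() if "eye_id" in data else len(data),
        n_patients=data["patient_id"].nunique(),
        n_dropped=0,
        response=response,
        formula=formula,
        converged=bool(getattr(res, "converged", True)) if res is not None else True,
        warnings=notes,
        _engine=engine,
        _beta=beta,
        _theta=theta,
        _acov_theta=acov,
        _exog_names=exog_names,
    )


def _complete_cases(data: pd.DataFrame, cols: list[str]) -> tuple[pd.DataFrame, int]:
    keep = data.dropna(subset=[c for c in cols if c in data.columns])
    return keep.copy(), len(data) - len(keep)


def fit_location_model(
    eye_table: pd.DataFrame,
    region: str,
    covariates: tuple[str, ...] = ("duration", "age", "gender", "eye_side"),
) -> FitResult:
    """Region rEZR on DR group with covariates and a patient intercept.

    ``eye_table`` is wide (one row per eye) with the region column, the
    covariates, ``dr_stage`` and ``patient_id``.  Rows with missing
    response or covariates are dropped (complete-case) and counted in
    ``n_dropped``; the type III F-test of the group factor uses
    Satterthwaite denominator df.
    """
    cols = [region, "dr_stage", "patient_id", *covariates]
    data, dropped = _complete_cases(eye_table, cols)
    if data["dr_stage"].nunique() < 2:
        raise ValueError("need at least two DR groups to compare")
    terms = [f"{_GROUP_TERM}"]
    for cov in covariates:
        if cov == "gender":
            terms.append("C(gender, Treatment('male'))")
        elif cov == "eye_side":
            terms.append("C(eye_side, Treatment('right'))")
        else:
            terms.append(cov)
    formula = f"{region} ~ " + " + ".join(terms)
    out = _fit_mixed(data, formula, region, ftest_terms={"group": _GROUP_TERM})
    out.n_dropped = dropped
    return out


def pairwise_group_contrasts(fit: FitResult, alpha: float = 0.05) -> list[Contrast]:
    """The three group comparisons as differences of adjusted means.

    Computed unconditionally, without multiplicity adjustment, but
    flagged ``gated`` when the overall group F-test p is at or above
    ``alpha`` — mirroring a reporting rule that only follows up a
    significant overall test.
    """
    gated = bool(fit.ftests.loc["group", "p"] >= alpha)
    names = fit.term_names(_GROUP_TERM)
    npdr = next((n for n in names if "NPDR" in n.split("T.")[-1]), None)
    pdr = next((n for n in names if n.split("T.")[-1].startswith("PDR")), None)
    out = []
    if fit._engine is None:  # degenerate fit: all contrasts zero
        for label in ("NPDR - noDR", "PDR - noDR", "PDR - NPDR"):
            out.append(Contrast(label, 0.0, 0.0, np.inf, 0.0, 0.0, 1.0, gated=gated))
        return out
    specs = [
        ("NPDR - noDR", {npdr: 1.0}),
        ("PDR - noDR", {pdr: 1.0}),
        ("PDR - NPDR", {pdr: 1.0, npdr: -1.0}),
    ]
    for label, coefs in specs:
        con = fit.contrast(coefs, label)
        con.gated = gated
        out.append(con)
    return out


def fit_ring_model(
    ring_long: pd.DataFrame,
    covariates: tuple[str, ...] = ("duration", "age", "gender", "eye_side"),
) -> FitResult:
    """Per-scan ring rEZR with ring × group interaction and nested eyes.

    ``ring_long`` has one row per eye × scan replicate × ring (columns
    ``rezr``, ``ring``, ``dr_stage``, ``patient_id``, ``eye_id`` and the
    covariates).  Random effects: patient intercept plus eye-within-
    patient intercept.  The reported F-test is for the interaction term.
    """
    cols = ["rezr", "ring", "dr_stage", "patient_id", "eye_id", *covariates]
    data, dropped = _complete_cases(ring_long, cols)
    terms = [f"{_RING_TERM} * {_GROUP_TERM}"]
    for cov in covariates:
        if cov == "gender":
            terms.append("C(gender, Treatment('male'))")
        elif cov == "eye_side":
            terms.append("C(eye_side, Treatment('right'))")
        else:
            terms.append(cov)
    formula = "rezr ~ " + " + ".join(terms)
    out = _fit_mixed(
        data,
        formula,
        "rezr",
        ftest_terms={
            "ring": f"{_RING_TERM}[",
            "group": f"{_GROUP_TERM}[",
            "ring:group": f"{_RING_TERM}[T.",
        },
        nest_eye=True,
    )
    # type III tests: main effects averaged over the other factor's levels
    names = out._exog_names
    p_dim = len(names)

    def _idx(pred):
        return [i for i, n in enumerate(names) if pred(n)]

    inter = _idx(lambda n: _RING_TERM in n and _GROUP_TERM in n and ":" in n)
    main_ring = _idx(lambda n: _RING_TERM in n and ":" not in n)
    main_group = _idx(lambda n: _GROUP_TERM in n and ":" not in n)

    def _main_L(main_idx, n_other):
        L = np.zeros((len(main_idx), p_dim))
        for r, i in enumerate(main_idx):
            L[r, i] = 1.0
            tag = names[i][names[i].index("[T.") :]
            for j in inter:
                if tag in names[j]:
                    L[r, j] = 1.0 / n_other
        return L

    L_inter = np.zeros((len(inter), p_dim))
    for r, i in enumerate(inter):
        L_inter[r, i] = 1.0
    frows = {}
    for label, L in (
        ("ring", _main_L(main_ring, len(GROUP_ORDER))),
        ("group", _main_L(main_group, len(RING_ORDER))),
        ("ring:group", L_inter),
    ):
        F, q, df_den, p = out._engine.ftest(L, out._beta, out._theta, out._acov_theta)
        frows[label] = {"F": F, "df_num": q, "df_den": df_den, "p": p}
    out.ftests = pd.DataFrame(frows).T
    out.n_dropped = dropped
    return out


from functools import lru_cache


@lru_cache(maxsize=256)
def _tukey_critical(k: int, df_rounded: float, level: float = 0.95) -> float:
    """Studentized-range critical value, cached (the ppf is expensive)."""
    return float(sps.studentized_range.ppf(level, k, df_rounded))


def _ring_contrast_vector(fit: FitResult, ring_a: str, ring_b: str, group: str):
    """Weights for mean(ring_a | group) − mean(ring_b | group)."""
    names = fit._exog_names
    c = np.zeros(len(names))
    for ring, sign in ((ring_a, 1.0), (ring_b, -1.0)):
        if ring == RING_ORDER[0]:
            continue  # reference level contributes nothing
        for i, n in enumerate(names):
            if _RING_TERM not in n or f"[T.{ring}]" not in n.replace(" ", ""):
                continue
            if ":" not in n:
                c[i] += sign
            elif f"[T.{group}]" in n:
                c[i] += sign
    return c


def ring_contrasts(fit: FitResult, adjustment: str = "tukey") -> list[Contrast]:
    """Within-stage pairwise ring comparisons from the ring model.

    For each DR group, the three ring differences (central−inner,
    central−outer, inner−outer) as adjusted-mean differences.  With
    ``adjustment="tukey"`` the p-value and CI use the studentized-range
    distribution for a family of three comparisons (so Tukey p ≥
    unadjusted p always); ``"none"`` gives the plain t machinery.
    """
    if adjustment not in ("tukey", "none"):
        raise ValueError("adjustment must be 'tukey' or 'none'")
    k = len(RING_ORDER)
    out = []
    for group in GROUP_ORDER:
        for a, b in ((0, 1), (0, 2), (1, 2)):
            ring_a, ring_b = RING_ORDER[a], RING_ORDER[b]
            c = _ring_contrast_vector(fit, ring_a, ring_b, group)
            con = fit.contrast(c, f"{ring_a} - {ring_b} ({group})")
            if adjustment == "tukey":
                q_obs = abs(con.estimate / con.se) * np.sqrt(2.0) if con.se > 0 else 0.0
                con.p = float(sps.studentized_range.sf(q_obs, k, con.df))
                df_r = float(min(round(con.df, 1), 1e4))
                half = _tukey_critical(k, df_r) / np.sqrt(2.0) * con.se
                con.ci_low = con.estimate - half
                con.ci_high = con.estimate + half
                con.adjustment = "tukey"
            out.append(con)
    return out


def fit_va_model(
    eye_table: pd.DataFrame,
    predictor: str = "total",
    multivariable: bool = False,
) -> FitResult:
    """Visual acuity (logMAR) on a region rEZR with a patient intercept.

    ``predictor`` selects the rEZR column (``"total"`` for the total
    area, ``"foveola"`` for the foveolar value; any region column works).
    The multivariable variant adds age, disease duration and DR stage;
    the DR-stage p-value comes from a type III F-test.
    """
    pred_col = predictor if predictor in eye_table.columns else f"rezr_{predictor}"
    cols = ["bcva_logmar", pred_col, "patient_id"]
    terms = [pred_col]
    ftest_terms = {}
    if multivariable:
        cols += ["age", "duration", "dr_stage"]
        terms += ["age", "duration", _GROUP_TERM]
        ftest_terms["group"] = _GROUP_TERM
    data, dropped = _complete_cases(eye_table, cols)
    formula = "bcva_logmar ~ " + " + ".join(terms)
    out = _fit_mixed(data, formula, "bcva_logmar", ftest_terms=ftest_terms or {"slope": pred_col})
    out.n_dropped = dropped
    return out


def describe(
    table: pd.DataFrame,
    group_col: str = "dr_stage",
    metric_cols: tuple[str, ...] = (),
    categorical_cols: tuple[str, ...] = (),
    shapiro_alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-group descriptive statistics in cohort-table format.

    Metric variables report mean ± SD when approximately normal (Shapiro–
    Wilk p ≥ ``shapiro_alpha``, assessed on the pooled values) and median
    (Q1; Q3) otherwise; categorical variables report count (percent).
    """
    rows = []
    groups = list(pd.unique(table[group_col]))
    for col in metric_cols:
        pooled = table[col].dropna().to_numpy(dtype=float)
        normal = True
        if len(pooled) >= 3 and np.ptp(pooled) > 0:
            normal = sps.shapiro(pooled).pvalue >= shapiro_alpha
        row = {"variable": col, "summary": "mean ± SD" if normal else "median (Q1; Q3)"}
        for g in groups:
            vals = table.loc[table[group_col] == g, col].dropna().to_numpy(dtype=float)
            if len(vals) == 0:
                row[g] = ""
            elif normal:
                row[g] = f"{vals.mean():.1f} ± {vals.std(ddof=1):.1f}"
            else:
                q1, med, q3 = np.percentile(vals, [25, 50, 75])
                row[g] = f"{med:.2f} ({q1:.2f}; {q3:.2f})"
            row[f"{g}_missing"] = int(table[group_col].eq(g).sum() - len(vals))
        rows.append(row)
    for col in categorical_cols:
        for level in pd.unique(table[col].dropna()):
            row = {"variable": f"{col} = {level}", "summary": "n (%)"}
            for g in groups:
                sub = table[table[group_col] == g]
                n = int((sub[col] == level).sum())
                pct = 100.0 * n / len(sub) if len(sub) else 0.0
                row[g] = f"{n} ({pct:.0f}%)"
            rows.append(row)
    return pd.DataFrame(rows)
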