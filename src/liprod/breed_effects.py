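"""Descriptive breed summaries and the linear mixed-effects breed comparison.

Breeds are compared on each LI-P variable with a linear mixed model: breed
as the fixed factor and crossed random intercepts for farm and season
(sampling date), estimated by REML. Because farms are observed repeatedly
across the four dates, the random factors absorb the non-independence of
records; the reported test is the omnibus Wald F test for the breed factor
(no post-hoc pairwise tests are produced, by design: with eight levels and
uneven replication a family of pairwise comparisons invites false
positives). Significance labels follow the conventional star map
(*** p<0.001, ** p<0.01, * p<0.05, t p<0.1, ns otherwise).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .herd_model import (
    LIP_VARIABLES,
    HerdDataset,
    HerdError,
)

__all__ = [
    "SUMMARY_VARIABLES",
    "BreedSummary",
    "BreedEffectsResult",
    "ModelFitError",
    "summarize_breeds",
    "fit_breed_model",
    "star_label",
]

#: Variables summarized per breed (LI-P variables plus feeding and lactation
#: stage; feeding variables get no model fit).
SUMMARY_VARIABLES: tuple[str, ...] = (
    "days_in_milk", "concentrate_kg_day", "forage_kg_day",
) + LIP_VARIABLES


class ModelFitError(HerdError):
    """The mixed model failed to converge; carries the optimizer diagnostics."""


@dataclass
class BreedSummary:
    """Mean +- SD per variable for one breed group, with median SCC."""

    breed: str
    n_records: int
    means: dict[str, float]
    sds: dict[str, float]
    median_scc: float


@dataclass
class BreedEffectsResult:
    """Mixed-model comparison of breeds for one response variable."""

    response: str
    breed_means: dict[str, float]        # model-implied group means
    vc_farm: float                       # farm random-intercept variance
    vc_season: float                     # season random-intercept variance
    resid_var: float
    f_statistic: float
    df_num: int
    df_den: float
    p_value: float
    significance: str
    n_records: int
    converged: bool = True


def star_label(p: float) -> str:
    """Map a p-value to the conventional significance label."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value must be in [0, 1], got {p}")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "t"
    return "ns"


def _records_frame(data: HerdDataset | pd.DataFrame) -> pd.DataFrame:
    if isinstance(data, HerdDataset):
        return data.to_frame()
    df = data.copy()
    if "season" not in df.columns and "date_code" in df.columns:
        from .herd_model import SEASON_OF_DATE
        df["season"] = df["date_code"].map(SEASON_OF_DATE)
    return df


def summarize_breeds(dataset: HerdDataset | pd.DataFrame) -> dict[str, BreedSummary]:
    """Per-breed mean +- SD for all summary variables, plus median SCC.

    The median is reported alongside the mean for SCC because the count is
    heavily right-skewed (a handful of very high cell counts inflate both
    mean and SD); the median is the more representative location.
    """
    df = _records_frame(dataset)
    out: dict[str, BreedSummary] = {}
    for breed, sub in df.groupby("breed_code"):
        means, sds = {}, {}
        for var in SUMMARY_VARIABLES:
            if var in sub.columns:
                vals = sub[var].dropna()
                means[var] = float(vals.mean()) if len(vals) else float("nan")
                sds[var] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        scc = sub["scc_kcells_ml"].dropna()
        out[str(breed)] = BreedSummary(
            breed=str(breed), n_records=int(len(sub)),
            means=means, sds=sds,
            median_scc=float(scc.median()) if len(scc) else float("nan"),
        )
    return out


def fit_breed_model(
    data: HerdDataset | pd.DataFrame,
    response: str,
    include_random: bool = True,
) -> BreedEffectsResult:
    """REML fit of ``response ~ breed`` with crossed farm and season
    random intercepts.

    With ``include_random=False`` the random terms are fixed at zero variance
    and the fit reduces to ordinary least squares (breed estimates are then
    exactly the group means under balance). Singular random-effect variances
    are reported as 0 with a warning rather than raised.
    """
    df = _records_frame(data)
    needed = [response, "breed_code", "farm_id", "season"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise HerdError(f"fit_breed_model missing column(s): {missing}")
    df = df.dropna(subset=[response]).copy()
    if df["breed_code"].nunique() < 2:
        raise HerdError("need at least 2 breed groups to compare")
    df["farm_id"] = df["farm_id"].astype(str)

    formula = f"{response} ~ C(breed_code)"
    if include_random:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM.from_formula(
                formula, data=df,
                groups=np.ones(len(df)),
                re_formula="0",
                vc_formula={"farm": "0 + C(farm_id)", "season": "0 + C(season)"},
            )
            res = None
            last_exc: Optional[Exception] = None
            for method in ("lbfgs", "bfgs", "powell"):
                try:
                    res = model.fit(reml=True, method=method, maxiter=500)
                except Exception as exc:  # numerical failure inside the optimizer
                    last_exc = exc
                    continue
                if res.converged:
                    break
        if res is None:
            raise ModelFitError(f"mixed model fit failed: {last_exc}") from last_exc
        if not res.converged:
            raise ModelFitError(
                f"mixed model did not converge for {response!r}; "
                f"optimizer trace: {getattr(res, 'hist', None)}")
        vc_names = list(model.exog_vc.names)
        vcomp = dict(zip(vc_names, np.asarray(res.vcomp, dtype=float)))
        vc_farm = max(float(vcomp.get("farm", 0.0)), 0.0)
        vc_season = max(float(vcomp.get("season", 0.0)), 0.0)
        for name, v in (("farm", vc_farm), ("season", vc_season)):
            if v < 1e-10:
                warnings.warn(f"{name} variance component is singular; reported as 0",
                              stacklevel=2)
        resid_var = float(res.scale)
        params = res.fe_params
    else:
        res = smf.ols(formula, data=df).fit()
        vc_farm = vc_season = 0.0
        resid_var = float(res.mse_resid)
        params = res.params

    breed_terms = [name for name in params.index if name.startswith("C(breed_code)")]
    q = len(breed_terms)
    constraint = ", ".join(f"{name} = 0" for name in breed_terms)
    wald = res.wald_test(constraint, scalar=True)
    chi2 = float(np.squeeze(wald.statistic))
    df_den = float(len(df) - params.size - 2 * int(include_random))
    fstat = chi2 / q
    p = float(sps.f.sf(fstat, q, df_den))

    breeds = sorted(df["breed_code"].unique())
    means = {}
    intercept = float(params["Intercept"])
    for b in breeds:
        term = f"C(breed_code)[T.{b}]"
        means[b] = intercept + (float(params[term]) if term in params.index else 0.0)

    return BreedEffectsResult(
        response=response, breed_means=means,
        vc_farm=vc_farm, vc_season=vc_season, resid_var=resid_var,
        f_statistic=fstat, df_num=q, df_den=df_den, p_value=p,
        significance=star_label(p), n_records=len(df),
        converged=True,
    )


def breed_effects_table(
    dataset: HerdDataset | pd.DataFrame,
    responses: Optional[list[str]] = None,
) -> pd.DataFrame:
    """Summary table: mean +- SD cells per breed, median SCC row and a
    significance star per modelled response.

    Feeding variables (concentrate, forage) are summarized but carry no
    p-value: rations are set per farm, not per cow, so the model assumptions
    do not hold for them.
    """
    summaries = summarize_breeds(dataset)
    breeds = sorted(summaries)
    if responses is None:
        responses = ["days_in_milk", *LIP_VARIABLES]
    rows = []
    no_fit = {"concentrate_kg_day", "forage_kg_day"}
    for var in SUMMARY_VARIABLES:
        row: dict[str, object] = {"variable": var}
        for b in breeds:
            s = summaries[b]
            if var in s.means and np.isfinite(s.means[var]):
                row[b] = f"{s.means[var]:.4g} ± {s.sds[var]:.4g}"
            else:
                row[b] = ""
        if var in no_fit:
            row["sig"] = "NA"
        elif var in responses:
            try:
                row["sig"] = fit_breed_model(dataset, var).significance
            except HerdError:
                row["sig"] = "NA"
        else:
            row["sig"] = ""
        rows.append(row)
    med = {"variable": "median_scc_kcells_ml",
           **{b: f"{summaries[b].median_scc:.4g}" for b in breeds}, "sig": ""}
    rows.append(med)
    n_row = {"variable": "n_records",
             **{b: str(summaries[b].n_records) for b in breeds}, "sig": ""}
    return pd.DataFrame([n_row, *rows])
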