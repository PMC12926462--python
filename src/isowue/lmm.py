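"""Linear mixed-effects trend estimation with marginal/conditional R².

Fits a random-intercept model (REML) with species as the grouping factor,
backed by ``statsmodels`` ``MixedLM``, and decomposes explained variance
into the marginal R² (fixed effects only) and conditional R² (fixed +
random effects): with σ²_f the variance of the fixed-effect linear
predictor, σ²_g the random-intercept variance and σ²_e the residual
variance,

    R²_m = σ²_f / (σ²_f + σ²_g + σ²_e)
    R²_c = (σ²_f + σ²_g) / (σ²_f + σ²_g + σ²_e)

Fixed-effect p-values are Wald z tests (stated in the fit metadata).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LmmSpec:
    """What to fit: response ~ fixed effects + (1 | group)."""

    response: str
    fixed: tuple[str, ...]
    group: str = "species_id"
    reml: bool = True

    def __init__(
        self,
        response: str,
        fixed: Sequence[str] | str,
        group: str = "species_id",
        reml: bool = True,
    ) -> None:
        if isinstance(fixed, str):
            fixed = (fixed,)
        object.__setattr__(self, "response", response)
        object.__setattr__(self, "fixed", tuple(fixed))
        object.__setattr__(self, "group", group)
        object.__setattr__(self, "reml", reml)


@dataclass
class LmmFit:
    """Fitted model summary: coefficients, variance components, R²."""

    spec: LmmSpec
    coef: dict[str, float]
    se: dict[str, float]
    pvalues: dict[str, float]
    conf_int: dict[str, tuple[float, float]]
    var_fixed: float
    var_group: float
    var_resid: float
    r2_marginal: float
    r2_conditional: float
    n_obs: int
    n_groups: int
    n_dropped: int
    singular: bool
    metadata: dict = field(default_factory=dict)


def r2_nakagawa(
    var_fixed: float, var_group: float, var_resid: float
) -> tuple[float, float]:
    """Marginal and conditional R² from variance components."""
    for name, v in (("fixed", var_fixed), ("group", var_group), ("resid", var_resid)):
        if v < 0:
            raise ValueError(f"negative {name} variance component: {v}")
    total = var_fixed + var_group + var_resid
    if total == 0:
        raise ValueError("all variance components are zero; R² undefined")
    return var_fixed / total, (var_fixed + var_group) / total


def fit_lmm(table: pd.DataFrame, spec: LmmSpec) -> LmmFit:
    """REML random-intercept fit of ``spec`` on ``table``.

    Rows with missing response/covariate/group values are dropped
    listwise (count logged and recorded).  A singular fit (zero
    random-intercept variance) is returned with ``singular=True`` and a
    warning, never raised.
    """
    cols = [spec.response, *spec.fixed, spec.group]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise KeyError(f"columns not in table: {missing}")
    data = table[cols].dropna()
    n_dropped = len(table) - len(data)
    if n_dropped:
        logger.info("listwise deletion dropped %d rows with missing values", n_dropped)
    if len(data) < 10:
        raise ValueError(f"need at least 10 complete observations, have {len(data)}")
    groups = data[spec.group].astype(str)
    if groups.nunique() < 2:
        raise ValueError("grouping factor must have at least 2 levels")

    endog = data[spec.response].astype(float)
    exog = sm.add_constant(data[list(spec.fixed)].astype(float), has_constant="add")
    model = MixedLM(endog, exog, groups=groups)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence chatter on near-singular fits
        try:
            result = model.fit(reml=spec.reml)
        except (np.linalg.LinAlgError, ValueError):
            result = model.fit(reml=spec.reml, method="powell")

    beta = result.fe_params
    var_group = float(np.asarray(result.cov_re)[0, 0])
    var_resid = float(result.scale)
    # variance of the fixed-effect linear predictor over the estimation sample
    var_fixed = float(np.var(np.asarray(exog) @ np.asarray(beta), ddof=0))
    r2m, r2c = r2_nakagawa(var_fixed, var_group, var_resid)

    singular = var_group <= max(1e-8, 1e-6 * var_resid)
    if singular:
        warnings.warn(
            "singular fit: random-intercept variance is (numerically) zero",
            stacklevel=2,
        )
    ci = result.conf_int(alpha=0.05)
    names = list(beta.index)
    return LmmFit(
        spec=spec,
        coef={k: float(beta[k]) for k in names},
        se={k: float(result.bse_fe[k]) for k in names},
        pvalues={k: float(result.pvalues[k]) for k in names},
        conf_int={k: (float(ci.loc[k, 0]), float(ci.loc[k, 1])) for k in names},
        var_fixed=var_fixed,
        var_group=var_group,
        var_resid=var_resid,
        r2_marginal=r2m,
        r2_conditional=r2c,
        n_obs=len(data),
        n_groups=int(groups.nunique()),
        n_dropped=n_dropped,
        singular=singular,
        metadata={
            "estimator": "REML" if spec.reml else "ML",
            "pvalue_method": "Wald z on fixed effects",
            "backend": "statsmodels.MixedLM",
        },
    )


def fit_pathway_trends(
    table: pd.DataFrame,
    response: str = "iWUE",
    fixed: str = "elevation_m",
    group: str = "species_id",
) -> dict[str, Optional[LmmFit]]:
    """Fit the elevational trend separately for C3 and C4 subsets.

    Returns ``{"C3": fit, "C4": fit}``; a pathway absent from the table
    (or with a single species) maps to ``None``.
    """
    out: dict[str, Optional[LmmFit]] = {}
    for pathway in ("C3", "C4"):
        sub = table.loc[table["pathway"].astype(str).str.upper() == pathway]
        if len(sub) < 10 or sub[group].nunique() < 2:
            logger.warning("pathway %s: too few data for an LMM; skipped", pathway)
            out[pathway] = None
            continue
        out[pathway] = fit_lmm(sub, LmmSpec(response=response, fixed=fixed, group=group))
    return out
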