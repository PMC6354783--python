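"""Normative log-log allometric models of regional volume on total brain
volume, with tiered sex-term selection and scaling classification.

The scaling law is the classic power-law regression

    log10(V_region) = beta0 + beta1 * log10(V_tbv) [+ beta2*Sex
                      [+ beta3 * log10(V_tbv) x Sex]] + error

fitted by OLS in a normative (typically developing) sample.  Model
complexity is chosen by sequential testing: the sex-by-size interaction
model is fitted first; if the interaction is non-significant the additive
sex model is fitted; if the sex main effect is non-significant the simple
model is retained.  A fitted exponent beta1 significantly below 1 marks
hypoallometric scaling (the region grows proportionally slower than the
whole brain), above 1 hyperallometric, otherwise isometric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .synthesize import volume_column

__all__ = [
    "TIERS",
    "AllometricModel",
    "ScalingClassification",
    "fit_loglog",
    "select_tier",
    "classify_scaling",
    "predict_log_volume",
]

TIERS = ("interaction", "additive_sex", "simple")

#: sex indicator coding used throughout: female = 0, male = 1
SEX_CODE = {"F": 0.0, "M": 1.0}


class InputError(ValueError):
    """Invalid input data for a statistical operation."""


@dataclass
class AllometricModel:
    """A fitted normative scaling model for one region.

    Coefficients are on the log10 scale; ``beta1`` is the dimensionless
    scaling exponent.  ``beta2``/``beta3`` are present only for the tiers
    that include them (sex coded female = 0, male = 1).
    """

    region: str
    tier: str
    beta0: float
    beta1: float
    beta2: Optional[float] = None
    beta3: Optional[float] = None
    se: dict = field(default_factory=dict)
    pvalues: dict = field(default_factory=dict)
    resid_sd: float = 0.0
    n: int = 0
    sample_id: str = ""
    sex_coding: str = "female=0,male=1"

    @property
    def k_params(self) -> int:
        return 2 + (self.beta2 is not None) + (self.beta3 is not None)

    @property
    def dof(self) -> int:
        return self.n - self.k_params


def _design(sample: pd.DataFrame, region: str, tier: str):
    if tier not in TIERS:
        raise ValueError(f"unknown tier {tier!r}")
    vols = sample[volume_column(region)].to_numpy(dtype=float)
    tbv = sample["tbv_cm3"].to_numpy(dtype=float)
    bad = np.flatnonzero((vols <= 0) | (tbv <= 0))
    if bad.size:
        ids = sample["subject_id"].iloc[bad].tolist()
        raise InputError(f"non-positive volume for subject(s) {ids}")
    y = np.log10(vols)
    x = np.log10(tbv)
    cols = {"const": np.ones_like(x), "log_tbv": x}
    if tier in ("interaction", "additive_sex"):
        sex = sample["sex"].map(SEX_CODE)
        if sex.isna().any():
            ids = sample.loc[sex.isna(), "subject_id"].tolist()
            raise InputError(f"missing/unknown sex for subject(s) {ids}")
        cols["sex"] = sex.to_numpy(dtype=float)
        if tier == "interaction":
            cols["log_tbv_x_sex"] = cols["log_tbv"] * cols["sex"]
    X = pd.DataFrame(cols, index=sample.index)
    return y, X


def fit_loglog(sample: pd.DataFrame, region: str, tier: str = "simple") -> AllometricModel:
    """OLS fit of the log-log scaling model at the requested tier."""
    y, X = _design(sample, region, tier)
    if len(sample) < X.shape[1] + 2:
        raise InputError(
            f"need at least {X.shape[1] + 2} subjects for tier {tier!r}, got {len(sample)}"
        )
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise InputError(
            f"rank-deficient design for tier {tier!r} (e.g. single-sex sample "
            "with a sex term)"
        )
    res = sm.OLS(y, X).fit()
    params = res.params
    model = AllometricModel(
        region=region,
        tier=tier,
        beta0=float(params["const"]),
        beta1=float(params["log_tbv"]),
        beta2=float(params["sex"]) if "sex" in params else None,
        beta3=float(params["log_tbv_x_sex"]) if "log_tbv_x_sex" in params else None,
        se={k: float(v) for k, v in res.bse.items()},
        pvalues={k: float(v) for k, v in res.pvalues.items()},
        resid_sd=float(np.sqrt(res.mse_resid)),
        n=int(res.nobs),
        sample_id=sample.attrs.get("sample_id", ""),
    )
    return model


def select_tier(sample: pd.DataFrame, region: str, alpha: float = 0.05) -> AllometricModel:
    """Sequential tier selection: interaction -> additive sex -> simple.

    The interaction model is retained if the sex-by-size term is significant
    at ``alpha`` (two-sided Wald t); otherwise the additive model is retained
    if its sex main effect is significant; otherwise the simple model.
    Single-sex samples skip the sex tiers with a warning.
    """
    sexes = set(sample["sex"].dropna().unique())
    if len(sexes) < 2:
        warnings.warn(
            f"single-sex sample for region {region!r}: skipping sex tiers",
            stacklevel=2,
        )
        return fit_loglog(sample, region, "simple")
    inter = fit_loglog(sample, region, "interaction")
    if inter.pvalues["log_tbv_x_sex"] <= alpha:
        return inter
    additive = fit_loglog(sample, region, "additive_sex")
    if additive.pvalues["sex"] <= alpha:
        return additive
    return fit_loglog(sample, region, "simple")


@dataclass
class ScalingClassification:
    """Wald classification of the scaling exponent against isometry."""

    label: str                 # hypoallometric | isometric | hyperallometric
    beta1: float
    ci: tuple[float, float]
    pvalue: float
    alpha: float = 0.05


def classify_scaling(model: AllometricModel, alpha: float = 0.05) -> ScalingClassification:
    """Test H0: beta1 = 1 (isometry) with a t-based Wald CI.

    Hypoallometric iff the upper confidence bound is below 1,
    hyperallometric iff the lower bound is above 1, isometric otherwise.
    """
    se = model.se.get("log_tbv", 0.0)
    if se == 0.0:
        if model.beta1 != 1.0:
            warnings.warn(
                "zero standard error for beta1: classifying by point value "
                "with a degenerate CI",
                stacklevel=2,
            )
        ci = (model.beta1, model.beta1)
        p = 0.0 if model.beta1 != 1.0 else 1.0
    else:
        tcrit = sps.t.ppf(1.0 - alpha / 2.0, model.dof)
        ci = (model.beta1 - tcrit * se, model.beta1 + tcrit * se)
        tstat = (model.beta1 - 1.0) / se
        p = float(2.0 * sps.t.sf(abs(tstat), model.dof))
    if ci[1] < 1.0:
        label = "hypoallometric"
    elif ci[0] > 1.0:
        label = "hyperallometric"
    else:
        label = "isometric"
    return ScalingClassification(label=label, beta1=model.beta1, ci=ci,
                                 pvalue=p, alpha=alpha)


def predict_log_volume(model: AllometricModel, subjects: pd.DataFrame) -> np.ndarray:
    """Predicted log10 regional volume for each subject under ``model``."""
    tbv = subjects["tbv_cm3"].to_numpy(dtype=float)
    if np.any(tbv <= 0):
        ids = subjects.loc[tbv <= 0, "subject_id"].tolist()
        raise InputError(f"non-positive total brain volume for subject(s) {ids}")
    log_tbv = np.log10(tbv)
    pred = model.beta0 + model.beta1 * log_tbv
    if model.beta2 is not None:
        sex = subjects["sex"].map(SEX_CODE)
        if sex.isna().any():
            ids = subjects.loc[sex.isna(), "subject_id"].tolist()
            raise InputError(
                f"tier {model.tier!r} requires sex; missing for subject(s) {ids}"
            )
        pred = pred + model.beta2 * sex.to_numpy(dtype=float)
        if model.beta3 is not None:
            pred = pred + model.beta3 * log_tbv * sex.to_numpy(dtype=float)
    return np.asarray(pred, dtype=float)
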