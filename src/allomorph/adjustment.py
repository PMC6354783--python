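"""Bulk-volume group inference: omnibus tests, raw pairwise contrasts,
effect sizes against the XY reference, and three strategies for adjusting
regional volume for total brain volume (TBV) before group comparison:

* allometric — deviations (observed minus predicted log10 volume) from a
  normative scaling model fitted in an independent sample;
* normalization — the regional volume fraction V_region / V_tbv;
* covariation — raw volume with TBV as a linear covariate.

Each strategy reduces to an OLS regression of the response on a binary
group indicator (comparison group coded 1, gonadal control 0), so a
negative estimate means a smaller measure in the aneuploid group.  The
five karyotype-versus-control contrasts are Bonferroni-corrected together;
raw pairwise contrasts use Benjamini-Hochberg within each region's family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .allometry import AllometricModel, InputError, predict_log_volume, select_tier
from .config import GONADAL_CONTROL, KARYOTYPES, REGIONS
from .stats import BatchOLS, bh_adjust, bonferroni_adjust
from .synthesize import volume_column

__all__ = [
    "ContrastSpec",
    "ContrastResult",
    "LeakageError",
    "sca_contrasts",
    "omnibus_group_test",
    "posthoc_raw_contrast",
    "effect_size_vs_reference",
    "allometric_contrast",
    "normalization_contrast",
    "covariation_contrast",
    "run_volume_battery",
]

METHODS = ("raw", "allometric", "normalization", "covariation")


class LeakageError(RuntimeError):
    """Normative model was fitted on the sample it is being applied to."""


@dataclass(frozen=True)
class ContrastSpec:
    """One group-versus-control comparison of one region by one method."""

    group: str
    control: str
    region: str
    method: str = "raw"
    covariates: str = "none"  # "none" | "age_tanner"

    @property
    def label(self) -> str:
        return f"{self.group}-{self.control}"


@dataclass
class ContrastResult:
    spec: ContrastSpec
    estimate: float
    se: float
    t: float
    p: float
    p_adj: float
    family_size: int
    effect_size_d: float
    n_group: int
    n_control: int


def sca_contrasts(region: str, method: str = "raw",
                  covariates: str = "none") -> list[ContrastSpec]:
    """The five supernumerary-karyotype contrasts against gonadal controls."""
    return [
        ContrastSpec(k, GONADAL_CONTROL[k], region, method, covariates)
        for k in ("XXX", "XXY", "XYY", "XXYY", "XXXXY")
    ]


def sex_contrast(region: str, method: str = "raw",
                 covariates: str = "none") -> ContrastSpec:
    return ContrastSpec("XX", "XY", region, method, covariates)


# --------------------------------------------------------------------------
# omnibus and raw comparisons
# --------------------------------------------------------------------------

def omnibus_group_test(core: pd.DataFrame, measure: str) -> tuple[float, float]:
    """One-way fixed-effects ANOVA of ``measure`` across karyotype groups.

    Groups with fewer than two subjects are excluded with a warning.
    """
    samples = []
    for k in KARYOTYPES:
        vals = core.loc[core["karyotype"] == k, measure].dropna().to_numpy()
        if len(vals) == 0:
            continue
        if len(vals) < 2:
            warnings.warn(f"group {k} has <2 subjects; excluded from omnibus test",
                          stacklevel=2)
            continue
        samples.append(vals)
    if len(samples) < 2:
        raise InputError("omnibus test needs at least two groups with >=2 subjects")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant input handled below
        f, p = sps.f_oneway(*samples)
    if not np.isfinite(f):
        # zero within-group variance: F is 0 when all group means agree,
        # infinite otherwise
        means = [s.mean() for s in samples]
        if np.ptp(means) == 0:
            f, p = 0.0, 1.0
        else:
            f, p = np.inf, 0.0
    return float(f), float(p)


def _two_group_frame(core: pd.DataFrame, spec: ContrastSpec) -> pd.DataFrame:
    sub = core[core["karyotype"].isin([spec.group, spec.control])].copy()
    n_g = int((sub["karyotype"] == spec.group).sum())
    n_c = int((sub["karyotype"] == spec.control).sum())
    if n_g == 0 or n_c == 0:
        raise InputError(
            f"empty group in contrast {spec.label}: n({spec.group})={n_g}, "
            f"n({spec.control})={n_c}"
        )
    sub["group_indicator"] = (sub["karyotype"] == spec.group).astype(float)
    return sub


def _group_ols(sub: pd.DataFrame, response: np.ndarray, spec: ContrastSpec):
    """OLS of response on the group indicator (+ optional age and Tanner).

    Returns (estimate, se, t, p, n_group, n_control).  Missing Tanner stage
    leads to listwise deletion when covariates are requested.
    """
    cols = [np.ones(len(sub)), sub["group_indicator"].to_numpy(dtype=float)]
    keep = np.ones(len(sub), dtype=bool)
    if spec.covariates == "age_tanner":
        tanner = sub["tanner"].to_numpy(dtype=float)
        keep = np.isfinite(tanner) & np.isfinite(sub["age"].to_numpy(dtype=float))
        dropped = int((~keep).sum())
        if dropped:
            warnings.warn(
                f"{dropped} subject(s) dropped from {spec.label} for missing "
                "age/Tanner stage", stacklevel=3)
        cols += [sub["age"].to_numpy(dtype=float), tanner]
    elif spec.covariates != "none":
        raise ValueError(f"unknown covariate set {spec.covariates!r}")
    X = np.column_stack(cols)[keep]
    y = np.asarray(response, dtype=float)[keep]
    fit = BatchOLS.fit(X, y)
    g = X[:, 1]
    return (
        float(fit.coef[1, 0]),
        float(fit.se[1, 0]),
        float(fit.tvalues[1, 0]),
        float(fit.pvalues[1, 0]),
        int(g.sum()),
        int((1 - g).sum()),
    )


def _cohens_d_vs_control(response: np.ndarray, indicator: np.ndarray) -> float:
    """(mean of control - mean of comparison group) / SD of control."""
    comp = response[indicator == 1]
    ctrl = response[indicator == 0]
    sd = ctrl.std(ddof=1)
    if sd == 0:
        raise InputError("zero reference-group SD in effect size")
    return float((ctrl.mean() - comp.mean()) / sd)


def posthoc_raw_contrast(
    core: pd.DataFrame,
    spec: ContrastSpec,
    family: Optional[Sequence[ContrastSpec]] = None,
) -> ContrastResult:
    """Pooled-variance two-sample t-test on raw volumes.

    The BH-adjusted p-value is computed within ``family`` (defaulting to
    the region's five karyotype contrasts plus the requested one).
    """
    spec = replace(spec, method="raw")
    if family is None:
        family = sca_contrasts(spec.region)
        if spec not in family:
            family = list(family) + [spec]
    pvals, results = [], {}
    for fs in family:
        fs = replace(fs, method="raw")
        sub = _two_group_frame(core, fs)
        resp = sub[volume_column(fs.region)].to_numpy(dtype=float)
        est, se, t, p, n_g, n_c = _group_ols(sub, resp, fs)
        d = _cohens_d_vs_control(resp, sub["group_indicator"].to_numpy())
        results[fs.label] = ContrastResult(fs, est, se, t, p, np.nan,
                                           len(family), d, n_g, n_c)
        pvals.append(p)
    qvals = bh_adjust(np.array(pvals))
    for q, fs_label in zip(qvals, results):
        results[fs_label].p_adj = float(q)
    return results[spec.label]


def effect_size_vs_reference(core: pd.DataFrame, group: str, measure: str) -> float:
    """Effect-size shift of ``group`` relative to the XY distribution:
    (mean of XY - mean of group) / sample SD of XY."""
    xy = core.loc[core["karyotype"] == "XY", measure].dropna().to_numpy()
    gv = core.loc[core["karyotype"] == group, measure].dropna().to_numpy()
    if len(xy) < 2:
        raise InputError("XY reference group needs >=2 subjects")
    if len(gv) == 0:
        raise InputError(f"no subjects in group {group}")
    sd = xy.std(ddof=1)
    if sd == 0:
        raise InputError("zero XY reference SD")
    return float((xy.mean() - gv.mean()) / sd)


# --------------------------------------------------------------------------
# size-adjusted contrasts
# --------------------------------------------------------------------------

def allometric_contrast(
    core: pd.DataFrame,
    model: AllometricModel,
    spec: ContrastSpec,
    m: int = 5,
    allow_core_fit: bool = False,
) -> ContrastResult:
    """Group contrast of allometric deviations (observed - predicted log10
    volume under the independent normative model), Bonferroni family ``m``.
    """
    core_id = core.attrs.get("sample_id", "")
    if model.sample_id and core_id and model.sample_id == core_id and not allow_core_fit:
        raise LeakageError(
            f"normative model was fitted on sample {model.sample_id!r}, which "
            "is the sample being tested; pass allow_core_fit=True to override"
        )
    spec = replace(spec, method="allometric")
    sub = _two_group_frame(core, spec)
    dev = (
        np.log10(sub[volume_column(spec.region)].to_numpy(dtype=float))
        - predict_log_volume(model, sub)
    )
    est, se, t, p, n_g, n_c = _group_ols(sub, dev, spec)
    d = _cohens_d_vs_control(dev, sub["group_indicator"].to_numpy())
    return ContrastResult(spec, est, se, t, p,
                          float(bonferroni_adjust(p, m)), m, d, n_g, n_c)


def normalization_contrast(core: pd.DataFrame, spec: ContrastSpec,
                           m: int = 5) -> ContrastResult:
    """Group contrast of the regional volume fraction V_region / V_tbv."""
    spec = replace(spec, method="normalization")
    sub = _two_group_frame(core, spec)
    ratio = (
        sub[volume_column(spec.region)].to_numpy(dtype=float)
        / sub["tbv_cm3"].to_numpy(dtype=float)
    )
    est, se, t, p, n_g, n_c = _group_ols(sub, ratio, spec)
    d = _cohens_d_vs_control(ratio, sub["group_indicator"].to_numpy())
    return ContrastResult(spec, est, se, t, p,
                          float(bonferroni_adjust(p, m)), m, d, n_g, n_c)


def covariation_contrast(core: pd.DataFrame, spec: ContrastSpec,
                         m: int = 5) -> ContrastResult:
    """Group contrast of raw volume with TBV as a linear covariate."""
    spec = replace(spec, method="covariation")
    sub = _two_group_frame(core, spec)
    resp = sub[volume_column(spec.region)].to_numpy(dtype=float)
    cols = [np.ones(len(sub)), sub["group_indicator"].to_numpy(dtype=float),
            sub["tbv_cm3"].to_numpy(dtype=float)]
    keep = np.ones(len(sub), dtype=bool)
    if spec.covariates == "age_tanner":
        tanner = sub["tanner"].to_numpy(dtype=float)
        keep = np.isfinite(tanner) & np.isfinite(sub["age"].to_numpy(dtype=float))
        dropped = int((~keep).sum())
        if dropped:
            warnings.warn(
                f"{dropped} subject(s) dropped from {spec.label} for missing "
                "age/Tanner stage", stacklevel=2)
        cols += [sub["age"].to_numpy(dtype=float), tanner]
    X = np.column_stack(cols)[keep]
    fit = BatchOLS.fit(X, resp[keep])
    d = _cohens_d_vs_control(resp, sub["group_indicator"].to_numpy())
    g = X[:, 1]
    return ContrastResult(
        spec,
        float(fit.coef[1, 0]), float(fit.se[1, 0]),
        float(fit.tvalues[1, 0]), float(fit.pvalues[1, 0]),
        float(bonferroni_adjust(fit.pvalues[1, 0], m)), m, d,
        int(g.sum()), int((1 - g).sum()),
    )


# --------------------------------------------------------------------------
# battery
# --------------------------------------------------------------------------

RESULT_COLUMNS = [
    "region", "method", "contrast", "covariates", "n_comparison", "n_control",
    "estimate", "se", "t", "p", "p_adj", "effect_size_d",
]


def _result_row(r: ContrastResult) -> dict:
    return dict(
        region=r.spec.region, method=r.spec.method, contrast=r.spec.label,
        covariates=r.spec.covariates, n_comparison=r.n_group,
        n_control=r.n_control, estimate=r.estimate, se=r.se, t=r.t, p=r.p,
        p_adj=r.p_adj, effect_size_d=r.effect_size_d,
    )


def run_volume_battery(
    core: pd.DataFrame,
    normative: pd.DataFrame,
    m: int = 5,
    alpha_tier: float = 0.05,
    covariate_sets: Sequence[str] = ("none", "age_tanner"),
    allow_core_fit: bool = False,
) -> pd.DataFrame:
    """All methods x regions x contrasts, as a tidy sorted results table.

    Karyotype contrasts are evaluated in the core sample.  The sex contrast
    (XX vs XY) is evaluated on core-sample deviations for the allometric
    method and within the normative sample for normalization/covariation
    (whose size-adjusted sex comparison is defined there).  The
    ``age_tanner`` variants re-run every contrast with age and Tanner stage
    as covariates, dropping subjects with missing Tanner stage.
    """
    rows = []
    for region in REGIONS:
        model = select_tier(normative, region, alpha=alpha_tier)
        for cov in covariate_sets:
            specs = sca_contrasts(region, covariates=cov)
            raw_family = specs + [sex_contrast(region, covariates=cov)]
            for spec in raw_family:
                rows.append(_result_row(posthoc_raw_contrast(core, spec,
                                                             family=raw_family)))
            for spec in specs + [sex_contrast(region, covariates=cov)]:
                rows.append(_result_row(allometric_contrast(
                    core, model, spec, m=m, allow_core_fit=allow_core_fit)))
            for spec in specs:
                rows.append(_result_row(normalization_contrast(core, spec, m=m)))
                rows.append(_result_row(covariation_contrast(core, spec, m=m)))
            # size-adjusted sex comparisons in the normative sample
            rows.append(_result_row(normalization_contrast(
                normative, sex_contrast(region, covariates=cov), m=m)))
            rows.append(_result_row(covariation_contrast(
                normative, sex_contrast(region, covariates=cov), m=m)))
    table = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    table = table.sort_values(
        ["region", "method", "contrast", "covariates"]
    ).reset_index(drop=True)
    return table
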