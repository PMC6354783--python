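"""Vertex-wise normative surface allometry and mass-univariate shape
contrasts.

Every vertex's local surface area is modelled against the subject's total
bilateral surface area of that structure (amygdala vertices on amygdala
total, hippocampus vertices on hippocampus total) with the same tiered
log-log models used for bulk volume.  A single tier is retained for all
vertices: the interaction model is kept if any vertex shows a significant
sex-by-size interaction after BH FDR correction (families per region),
otherwise the additive sex model is screened the same way, otherwise the
simple model.  Core-sample deviations from the retained normative field
are compared between karyotype groups vertex-by-vertex; per-contrast
p-values are BH-corrected within each region at q = 0.05 and signed into
contraction (smaller proportional area in the aneuploid group) versus
expansion maps.  Convergence of shape effects across karyotypes is
summarised by Pearson correlation of uncorrected t-maps per region.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .adjustment import ContrastSpec, _two_group_frame
from .allometry import SEX_CODE, InputError
from .config import REGIONS
from .stats import BatchOLS, bh_adjust, pearson_r
from .synthesize import MeshSpec, VertexTable, surface_column

__all__ = [
    "VertexModelField",
    "VertexContrastMap",
    "MapCorrelationMatrix",
    "fit_vertex_normative",
    "vertex_deviations",
    "vertex_contrast",
    "map_correlation",
    "robustness_vertex_survival",
]

_TIER_COLUMNS = {
    "interaction": ("const", "log_area", "sex", "log_area_x_sex"),
    "additive_sex": ("const", "log_area", "sex"),
    "simple": ("const", "log_area"),
}


@dataclass
class VertexModelField:
    """Per-vertex normative allometric fits sharing one global tier.

    ``coef`` maps region -> (k x V_region) coefficient matrix in the order
    of ``_TIER_COLUMNS[tier]``; ``vertex_index`` maps region -> mesh vertex
    ids in column order.  ``gate`` records the per-region minimum q-value of
    each screened tier term.
    """

    mesh: MeshSpec
    tier: str
    coef: dict[str, np.ndarray]
    sigma: dict[str, np.ndarray]
    vertex_index: dict[str, np.ndarray]
    n: int
    sample_id: str = ""
    gate: dict = field(default_factory=dict)
    excluded: dict[str, np.ndarray] = field(default_factory=dict)

    def slope(self) -> np.ndarray:
        """Local scaling exponents over the full mesh (vertex order)."""
        out = np.full(self.mesh.n_vertices, np.nan)
        for region, idx in self.vertex_index.items():
            out[idx] = self.coef[region][1]
        return out


def _tier_design(subjects: pd.DataFrame, region: str, tier: str) -> np.ndarray:
    s = subjects[surface_column(region)].to_numpy(dtype=float)
    if np.any(s <= 0):
        raise InputError(f"non-positive total surface area for region {region}")
    log_s = np.log10(s * 100.0)  # cm^2 -> mm^2, matching vertex areas
    cols = [np.ones_like(log_s), log_s]
    if tier in ("interaction", "additive_sex"):
        sex = subjects["sex"].map(SEX_CODE)
        if sex.isna().any():
            raise InputError("missing sex in vertex model design")
        cols.append(sex.to_numpy(dtype=float))
        if tier == "interaction":
            cols.append(log_s * sex.to_numpy(dtype=float))
    return np.column_stack(cols)


def _log_areas(vertices: VertexTable, idx: np.ndarray) -> np.ndarray:
    a = vertices.areas.iloc[:, idx].to_numpy(dtype=float)
    if np.any(a <= 0):
        raise InputError("non-positive vertex surface area")
    return np.log10(a)


def fit_vertex_normative(
    vertices: VertexTable,
    subjects: pd.DataFrame,
    alpha_fdr: float = 0.05,
) -> VertexModelField:
    """Fit the tiered vertex-wise normative model in the normative sample.

    Tier gates are evaluated on BH q-values of the candidate term, with
    correction families per region; a single significant vertex anywhere
    retains that tier globally for every vertex.  Vertices with zero
    residual variance are excluded from the gate families and recorded.
    """
    if len(vertices.areas) != len(subjects):
        raise InputError("vertex table and subject table differ in length")
    mesh = vertices.mesh

    chosen = None
    fits: dict[str, BatchOLS] = {}
    gate: dict = {}
    excluded: dict[str, np.ndarray] = {}
    for tier, gate_term in (("interaction", 3), ("additive_sex", 2), ("simple", None)):
        fits = {}
        triggered = False
        for region in REGIONS:
            idx = mesh.region_index(region)
            X = _tier_design(subjects, region, tier)
            Y = _log_areas(vertices, idx)
            fit = BatchOLS.fit(X, Y)
            fits[region] = fit
            degenerate = fit.sigma == 0.0
            if degenerate.any():
                warnings.warn(
                    f"{int(degenerate.sum())} zero-variance vertices in "
                    f"{region} excluded from the tier gate", stacklevel=2)
            excluded[region] = idx[degenerate]
            if gate_term is not None:
                p = fit.pvalues[gate_term].copy()
                p[degenerate] = np.nan
                q = bh_adjust(p)
                gate[(tier, region)] = float(np.nanmin(q)) if np.isfinite(q).any() else np.nan
                if np.any(q[np.isfinite(q)] <= alpha_fdr):
                    triggered = True
        if gate_term is None or triggered:
            chosen = tier
            break

    assert chosen is not None
    return VertexModelField(
        mesh=mesh,
        tier=chosen,
        coef={r: fits[r].coef for r in REGIONS},
        sigma={r: fits[r].sigma for r in REGIONS},
        vertex_index={r: mesh.region_index(r) for r in REGIONS},
        n=len(subjects),
        sample_id=subjects.attrs.get("sample_id", ""),
        gate=gate,
        excluded=excluded,
    )


def vertex_deviations(
    field_: VertexModelField,
    core_vertices: VertexTable,
    subjects: pd.DataFrame,
) -> pd.DataFrame:
    """Observed minus predicted log10 vertex area, per subject and vertex."""
    if core_vertices.mesh.n_vertices != field_.mesh.n_vertices:
        raise InputError("mesh mismatch between model field and vertex table")
    if len(core_vertices.areas) != len(subjects):
        raise InputError("vertex table and subject table differ in length")
    out = np.empty((len(subjects), field_.mesh.n_vertices))
    for region in REGIONS:
        idx = field_.vertex_index[region]
        X = _tier_design(subjects, region, field_.tier)
        out[:, idx] = _log_areas(core_vertices, idx) - X @ field_.coef[region]
    return pd.DataFrame(out, index=core_vertices.areas.index,
                        columns=np.arange(field_.mesh.n_vertices))


@dataclass
class VertexContrastMap:
    """Per-vertex statistics for one group contrast.

    ``direction`` is ``-1`` for contraction (smaller proportional area in
    the comparison group), ``+1`` for expansion, 0 where t is exactly 0.
    The significance ``mask`` is BH q < the requested level, per region.
    """

    spec: ContrastSpec
    mesh: MeshSpec
    t: np.ndarray
    p: np.ndarray
    q: np.ndarray
    mask: np.ndarray
    direction: np.ndarray
    q_level: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "vertex": np.arange(self.mesh.n_vertices),
                "structure": self.mesh.vertices["structure"],
                "t": self.t,
                "p": self.p,
                "q": self.q,
                "significant": self.mask,
                "direction": self.direction,
            }
        )


def vertex_contrast(
    deviations: pd.DataFrame,
    subjects: pd.DataFrame,
    spec: ContrastSpec,
    mesh: MeshSpec,
    q: float = 0.05,
) -> VertexContrastMap:
    """Vertex-wise two-group OLS of deviations on the group indicator,
    BH-corrected within each region."""
    sub = _two_group_frame(subjects, spec)
    if min((sub["group_indicator"] == 1).sum(),
           (sub["group_indicator"] == 0).sum()) < 2:
        raise InputError(f"contrast {spec.label} needs >=2 subjects per group")
    cols = [np.ones(len(sub)), sub["group_indicator"].to_numpy(dtype=float)]
    keep = np.ones(len(sub), dtype=bool)
    if spec.covariates == "age_tanner":
        tanner = sub["tanner"].to_numpy(dtype=float)
        keep = np.isfinite(tanner) & np.isfinite(sub["age"].to_numpy(dtype=float))
        dropped = int((~keep).sum())
        if dropped:
            warnings.warn(
                f"{dropped} subject(s) dropped from vertex contrast "
                f"{spec.label} for missing age/Tanner stage", stacklevel=2)
        cols += [sub["age"].to_numpy(dtype=float), tanner]
    elif spec.covariates != "none":
        raise ValueError(f"unknown covariate set {spec.covariates!r}")
    rows = subjects.index.get_indexer(sub.index)
    dev = deviations.to_numpy(dtype=float)[rows][keep]
    X = np.column_stack(cols)[keep]
    fit = BatchOLS.fit(X, dev)
    t = fit.tvalues[1]
    p = fit.pvalues[1].copy()
    p[fit.sigma == 0.0] = np.nan
    qvals = np.full_like(p, np.nan)
    for region in REGIONS:
        idx = mesh.region_index(region)
        qvals[idx] = bh_adjust(p[idx])
    mask = np.isfinite(qvals) & (qvals < q)
    direction = np.sign(t).astype(int)
    return VertexContrastMap(spec=spec, mesh=mesh, t=t, p=p, q=qvals,
                             mask=mask, direction=direction, q_level=q)


@dataclass
class MapCorrelationMatrix:
    """Pearson correlations between uncorrected t-maps, per region."""

    labels: list[str]
    matrices: dict[str, pd.DataFrame]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for region, mat in self.matrices.items():
            for a in mat.index:
                for b in mat.columns:
                    rows.append(dict(region=region, map_a=a, map_b=b,
                                     r=mat.loc[a, b]))
        return pd.DataFrame(rows)


def map_correlation(maps: list[VertexContrastMap]) -> MapCorrelationMatrix:
    """Pairwise Pearson r between the maps' uncorrected t-vectors, computed
    separately for each region.  Constant maps yield NaN with a warning."""
    if not maps:
        raise InputError("no maps supplied")
    nv = maps[0].mesh.n_vertices
    for m in maps:
        if m.mesh.n_vertices != nv:
            raise InputError("maps do not share a mesh")
    labels = [m.spec.label for m in maps]
    matrices = {}
    for region in REGIONS:
        idx = maps[0].mesh.region_index(region)
        mat = pd.DataFrame(np.eye(len(maps)), index=labels, columns=labels)
        for (i, a), (j, b) in itertools.combinations(enumerate(maps), 2):
            r = pearson_r(a.t[idx], b.t[idx])
            if np.isnan(r):
                warnings.warn(
                    f"constant t-map in {region} for {a.spec.label} or "
                    f"{b.spec.label}; correlation undefined", stacklevel=2)
            mat.iloc[i, j] = mat.iloc[j, i] = r
        matrices[region] = mat
    return MapCorrelationMatrix(labels=labels, matrices=matrices)


def robustness_vertex_survival(
    masks_main: dict[str, np.ndarray],
    masks_covaried: dict[str, np.ndarray],
) -> pd.DataFrame:
    """Fraction of significant vertices in the main run that remain
    significant in the covariate-adjusted run, per contrast and pooled."""
    if set(masks_main) != set(masks_covaried):
        raise InputError("contrast sets differ between runs")
    rows = []
    total_main = total_surv = 0
    for label in masks_main:
        a = np.asarray(masks_main[label], dtype=bool)
        b = np.asarray(masks_covaried[label], dtype=bool)
        if a.shape != b.shape:
            raise InputError(f"mask shapes differ for contrast {label}")
        n_main = int(a.sum())
        n_surv = int((a & b).sum())
        total_main += n_main
        total_surv += n_surv
        rows.append(dict(contrast=label, n_significant=n_main,
                         n_surviving=n_surv,
                         fraction=n_surv / n_main if n_main else np.nan))
    rows.append(dict(contrast="pooled", n_significant=total_main,
                     n_surviving=total_surv,
                     fraction=total_surv / total_main if total_main else np.nan))
    return pd.DataFrame(rows)
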