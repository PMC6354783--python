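"""Synthetic cohort and vertex-wise surface-area generator.

Subject-level model
-------------------
Per karyotype group, total brain volume is log-normal: log10(TBV) is
Gaussian with moments matched (delta method, with the half-variance mean
correction) to the configured arithmetic mean and SD, which guarantees
positive volumes and coheres with the log-log analysis models.  Regional
volumes follow the normative power law

    log10(V_region) = beta0 + beta1 * log10(TBV)
                      + beta2 * male + beta3 * male * (log10 TBV - centre)
                      + offset[karyotype] + Normal(0, residual_sd)

with offsets fixed at exactly 0 for the euploid reference groups.  Total
bilateral surface area per structure follows a geometric power-law link
S = c * V^(2/3) * 10^eps with a small log10 coupling noise eps.

Vertex-level model
------------------
Each structure is a deterministic Fibonacci point cloud on an ellipsoid
(left/right mirrored and translated apart).  A spatially smooth field of
true local scaling exponents (Gaussian-kernel smoothing of white noise,
rescaled to the configured hypo-to-hyper range and centred so the
template-weighted mean exponent is 1) drives

    log10(a_vertex) = log10(w_v * S_ref) + b1_v * (log10 S - log10 S_ref)
                      + focal_v * scale[karyotype] + Normal(0, vertex_noise_sd)

followed by an exact per-subject renormalisation so vertex areas sum to the
subject's total bilateral surface area.  Focal shape effects are smooth
Gaussian bumps at fixed anatomical positions shared across aneuploid
karyotypes, with karyotype-specific amplitude scaling (half strength for
XYY).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (
    GONADAL_CONTROL,
    KARYOTYPES,
    KARYOTYPE_SEX,
    REGIONS,
    STRUCTURES,
    STRUCTURE_REGION,
    ConfigError,
    GeneratorConfig,
)

__all__ = [
    "SUBJECT_COLUMNS",
    "MeshSpec",
    "VertexFields",
    "VertexTable",
    "generate_subjects",
    "generate_mesh",
    "make_vertex_fields",
    "generate_vertex_table",
    "volume_column",
    "surface_column",
]

LN10 = np.log(10.0)

SUBJECT_COLUMNS = [
    "subject_id",
    "karyotype",
    "sex",
    "age",
    "tanner",
    "tbv_cm3",
    "amygdala_cm3",
    "hippocampus_cm3",
    "amygdala_surface_cm2",
    "hippocampus_surface_cm2",
]

#: ellipsoid semi-axes (mesh units ~ mm); x is the principal (rostro-caudal) axis
_STRUCTURE_AXES = {
    "right_amygdala": (9.0, 7.0, 6.0),
    "left_amygdala": (9.0, 7.0, 6.0),
    "right_hippocampus": (20.0, 8.0, 6.0),
    "left_hippocampus": (20.0, 8.0, 6.0),
}
_HEMI_SHIFT = 40.0  # separates hemispheres so smoothing never bridges them


def volume_column(region: str) -> str:
    return f"{region}_cm3"


def surface_column(region: str) -> str:
    return f"{region}_surface_cm2"


def _split_rng(config: GeneratorConfig, rng=None) -> np.random.Generator:
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    return rng


# --------------------------------------------------------------------------
# subjects
# --------------------------------------------------------------------------

def generate_subjects(config: GeneratorConfig, rng=None) -> pd.DataFrame:
    """Draw a subject table (one row per subject) under ``config``.

    Returns a DataFrame with columns ``SUBJECT_COLUMNS`` and
    ``attrs['sample_id']`` set to the config's sample label.  Identical
    (config, seed) pairs yield identical tables.
    """
    config.validate()
    rng = _split_rng(config, rng)

    # centre for the sex-by-size interaction: grand log10 TBV of requested groups
    active = [k for k in KARYOTYPES if config.group_sizes.get(k, 0) > 0]
    if not active:
        raise ConfigError("no subjects requested")
    centre = float(
        np.mean([np.log10(config.tbv_mean[k]) for k in active])
    )

    rows = []
    for k in active:
        n = config.group_sizes[k]
        mean, sd = config.tbv_mean[k], config.tbv_sd[k]
        if sd < 0:
            raise ConfigError(f"negative SD for group {k}")
        # delta-method moment matching on the log scale; the half-variance
        # term makes the log-normal arithmetic mean equal the target exactly
        sigma = sd / (mean * LN10)
        mu = np.log10(mean) - sigma**2 * LN10 / 2.0
        log_tbv = rng.normal(mu, sigma, size=n)
        male = 1.0 if KARYOTYPE_SEX[k] == "M" else 0.0

        age = rng.normal(config.age_mean[k], config.age_sd[k], size=n)
        age = np.clip(age, *config.age_range)
        tanner = 1.0 + 4.0 * (age - 8.0) / 9.0 + rng.normal(0.0, 0.7, size=n)
        tanner = np.clip(np.rint(tanner), 1, 5)

        rec = {
            "karyotype": k,
            "sex": KARYOTYPE_SEX[k],
            "age": age,
            "tanner": tanner,
            "log_tbv": log_tbv,
            "male": male,
        }
        for region in REGIONS:
            log_v = (
                config.scaling_intercept[region]
                + config.scaling_exponent[region] * log_tbv
                + config.sex_effect[region] * male
                + config.sex_size_interaction[region] * male * (log_tbv - centre)
                + config.group_offsets[region].get(k, 0.0)
                + rng.normal(0.0, config.residual_sd[region], size=n)
            )
            log_s = (
                np.log10(config.surface_coefficient[region])
                + config.surface_exponent * log_v
                + rng.normal(0.0, config.surface_noise_sd[region], size=n)
            )
            rec[volume_column(region)] = 10.0**log_v
            rec[surface_column(region)] = 10.0**log_s
        rows.append(rec)

    frames = []
    offset = 0
    for rec in rows:
        n = len(rec["age"])
        df = pd.DataFrame(
            {
                "subject_id": [f"{rec['karyotype']}_{i:03d}" for i in range(n)],
                "karyotype": rec["karyotype"],
                "sex": rec["sex"],
                "age": rec["age"],
                "tanner": rec["tanner"],
                "tbv_cm3": 10.0 ** rec["log_tbv"],
            }
        )
        for region in REGIONS:
            df[volume_column(region)] = rec[volume_column(region)]
            df[surface_column(region)] = rec[surface_column(region)]
        frames.append(df)
        offset += n
    table = pd.concat(frames, ignore_index=True)

    # Tanner missingness: a seeded subset per karyotype
    for k, n_missing in config.tanner_missing.items():
        idx = table.index[table["karyotype"] == k]
        if n_missing > 0 and len(idx):
            chosen = rng.choice(idx, size=min(n_missing, len(idx)), replace=False)
            table.loc[chosen, "tanner"] = np.nan

    table = table[SUBJECT_COLUMNS]
    table.attrs["sample_id"] = config.sample_label
    return table


# --------------------------------------------------------------------------
# mesh
# --------------------------------------------------------------------------

@dataclass
class MeshSpec:
    """A synthetic amygdalo-hippocampal surface point cloud.

    ``vertices`` has one row per vertex with columns
    ``vertex, structure, hemisphere, x, y, z``; vertex ids are a contiguous
    0-based range over the whole mesh, contiguous per structure.
    """

    vertices: pd.DataFrame

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def structure_index(self, structure: str) -> np.ndarray:
        return self.vertices.index[self.vertices["structure"] == structure].to_numpy()

    def region_index(self, region: str) -> np.ndarray:
        mask = self.vertices["structure"].map(STRUCTURE_REGION) == region
        return self.vertices.index[mask].to_numpy()

    def structure_counts(self) -> dict[str, int]:
        return self.vertices["structure"].value_counts().to_dict()

    def to_json(self, path) -> None:
        self.vertices.to_json(path, orient="records", double_precision=10)

    @classmethod
    def from_json(cls, path) -> "MeshSpec":
        df = pd.read_json(path, orient="records")
        df = df[["vertex", "structure", "hemisphere", "x", "y", "z"]]
        df = df.sort_values("vertex").reset_index(drop=True)
        return cls(df)


def _fibonacci_ellipsoid(n: int, axes, mirror: bool, shift: float) -> np.ndarray:
    """Deterministic quasi-uniform points on an ellipsoid surface."""
    i = np.arange(n, dtype=float)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - 2.0 * (i + 0.5) / n
    theta = 2.0 * np.pi * i / golden
    r = np.sqrt(np.maximum(0.0, 1.0 - z**2))
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    pts *= np.asarray(axes)
    if mirror:
        pts[:, 1] = -pts[:, 1]
    pts[:, 1] += shift if not mirror else -shift
    return pts


def generate_mesh(config: GeneratorConfig) -> MeshSpec:
    """Build the synthetic mesh with the configured per-structure counts.

    The point cloud is deterministic given the vertex counts (it carries no
    sampling noise); it exists to give the smooth fields a geometry.
    """
    config.validate()
    frames = []
    start = 0
    for structure in STRUCTURES:
        n = config.vertex_counts[structure]
        mirror = structure.startswith("left")
        pts = _fibonacci_ellipsoid(n, _STRUCTURE_AXES[structure], mirror, _HEMI_SHIFT)
        frames.append(
            pd.DataFrame(
                {
                    "vertex": np.arange(start, start + n),
                    "structure": structure,
                    "hemisphere": "left" if mirror else "right",
                    "x": pts[:, 0],
                    "y": pts[:, 1],
                    "z": pts[:, 2],
                }
            )
        )
        start += n
    mesh = MeshSpec(pd.concat(frames, ignore_index=True))
    if mesh.n_vertices != config.n_vertices:
        raise ConfigError("mesh vertex count does not match configuration")
    return mesh


# --------------------------------------------------------------------------
# smooth fields
# --------------------------------------------------------------------------

@dataclass
class VertexFields:
    """Per-vertex generator truth: template weights, local scaling
    exponents, and the unit-amplitude focal shape field."""

    mesh: MeshSpec
    template_weight: np.ndarray   # sums to 1 within each region
    exponent: np.ndarray          # true local scaling exponent per vertex
    focal: np.ndarray             # log10-unit focal field (before karyotype scale)
    region_ref_log_s: dict[str, float] = field(default_factory=dict)


def _smooth_field(coords: np.ndarray, z: np.ndarray, length: float) -> np.ndarray:
    """Nadaraya-Watson Gaussian smoothing of per-vertex noise ``z``."""
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    k = np.exp(-0.5 * d2 / length**2)
    return (k @ z) / k.sum(axis=1)


def make_vertex_fields(config: GeneratorConfig, mesh: MeshSpec, rng=None) -> VertexFields:
    """Draw the smooth exponent/template/focal fields for ``mesh``.

    Fields are smoothed per structure (hemispheres are far apart in mesh
    coordinates, so each hemisphere's field is effectively independent),
    then rescaled per bilateral region.  By default the draw is seeded by
    ``config.field_seed`` (not the sampling seed): the fields are the
    population's anatomy and are shared across cohorts drawn from it.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.field_seed))
    nv = mesh.n_vertices
    template = np.empty(nv)
    exponent = np.empty(nv)
    focal = np.zeros(nv)
    coords_all = mesh.vertices[["x", "y", "z"]].to_numpy()

    smooth = np.empty(nv)
    smooth_t = np.empty(nv)
    for structure in STRUCTURES:
        idx = mesh.structure_index(structure)
        coords = coords_all[idx]
        smooth[idx] = _smooth_field(coords, rng.normal(size=len(idx)),
                                    config.smoothness_length)
        smooth_t[idx] = _smooth_field(coords, rng.normal(size=len(idx)),
                                      config.smoothness_length)

    lo, hi = config.exponent_range
    for region in REGIONS:
        idx = mesh.region_index(region)
        f = smooth[idx]
        span = f.max() - f.min()
        if span == 0 or hi == lo:
            exponent[idx] = (lo + hi) / 2.0
        else:
            exponent[idx] = lo + (f - f.min()) * (hi - lo) / span
        w = np.exp(0.25 * (smooth_t[idx] - smooth_t[idx].mean()))
        w /= w.sum()
        template[idx] = w
        # centre so the template-weighted mean exponent is 1: per-subject
        # renormalisation then leaves local exponents as generated
        exponent[idx] += 1.0 - float(w @ exponent[idx])

        for bump in config.focal_bumps:
            if bump.region != region:
                continue
            for structure in STRUCTURES:
                if STRUCTURE_REGION[structure] != region:
                    continue
                sidx = mesh.structure_index(structure)
                coords = coords_all[sidx]
                centre = coords.mean(axis=0)
                centre[0] = bump.axis_fraction * _STRUCTURE_AXES[structure][0]
                d2 = ((coords - centre) ** 2).sum(-1)
                focal[sidx] += bump.amplitude * np.exp(-0.5 * d2 / bump.extent**2)

    return VertexFields(mesh=mesh, template_weight=template,
                        exponent=exponent, focal=focal)


# --------------------------------------------------------------------------
# vertex table
# --------------------------------------------------------------------------

@dataclass
class VertexTable:
    """Subjects-by-vertices matrix of local surface areas (mm^2).

    ``areas`` is indexed by subject id with one column per vertex id; row
    order matches the subject table it was generated from.
    """

    mesh: MeshSpec
    areas: pd.DataFrame

    @property
    def n_subjects(self) -> int:
        return len(self.areas)

    def region_areas(self, region: str) -> pd.DataFrame:
        return self.areas.iloc[:, self.mesh.region_index(region)]

    def to_csv(self, path) -> None:
        out = self.areas.copy()
        out.insert(0, "subject_id", out.index)
        out.to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path, mesh: MeshSpec) -> "VertexTable":
        df = pd.read_csv(path)
        df = df.set_index("subject_id")
        df.columns = df.columns.astype(int)
        if list(df.columns) != list(range(mesh.n_vertices)):
            raise ValueError("vertex table columns do not match the mesh")
        return cls(mesh, df)


def generate_vertex_table(
    config: GeneratorConfig,
    subjects: pd.DataFrame,
    rng=None,
    mesh: MeshSpec | None = None,
    fields: VertexFields | None = None,
) -> tuple[MeshSpec, VertexTable]:
    """Generate per-subject vertex areas consistent with ``subjects``.

    Pass precomputed ``mesh``/``fields`` to amortise field construction
    across repeated cohorts; by default both are derived deterministically
    from the config seed.
    """
    config.validate()
    rng = _split_rng(config, rng)
    if mesh is None:
        mesh = generate_mesh(config)
    if mesh.n_vertices != config.n_vertices:
        raise ConfigError("mesh does not match configured vertex counts")
    if fields is None:
        fields = make_vertex_fields(config, mesh)

    n_sub = len(subjects)
    areas = np.empty((n_sub, mesh.n_vertices))
    amp = subjects["karyotype"].map(config.focal_scale).fillna(0.0).to_numpy()

    for region in REGIONS:
        idx = mesh.region_index(region)
        s_mm2 = subjects[surface_column(region)].to_numpy() * 100.0  # cm^2 -> mm^2
        if np.any(s_mm2 <= 0):
            raise ConfigError(f"non-positive surface area for region {region}")
        log_s = np.log10(s_mm2)
        # fixed reference size: surface implied by the XY reference volume
        ref = fields.region_ref_log_s.get(region)
        if ref is None:
            from .config import REFERENCE_GROUPS

            s_ref = (
                config.surface_coefficient[region]
                * REFERENCE_GROUPS["XY"][region] ** config.surface_exponent
            )
            ref = float(np.log10(s_ref * 100.0))
            fields.region_ref_log_s[region] = ref

        w = fields.template_weight[idx]
        b1 = fields.exponent[idx]
        log_a = (
            np.log10(w)[None, :]
            + ref
            + b1[None, :] * (log_s - ref)[:, None]
            + fields.focal[idx][None, :] * amp[:, None]
            + rng.normal(0.0, config.vertex_noise_sd, size=(n_sub, len(idx)))
        )
        a = 10.0**log_a
        # exact renormalisation: vertex areas sum to the subject's total
        a *= (s_mm2 / a.sum(axis=1))[:, None]
        areas[:, idx] = a

    table = pd.DataFrame(areas, index=pd.Index(subjects["subject_id"], name="subject_id"),
                         columns=np.arange(mesh.n_vertices))
    vt = VertexTable(mesh=mesh, areas=table)
    vt.areas.attrs["sample_id"] = subjects.attrs.get("sample_id", "")
    return mesh, vt
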