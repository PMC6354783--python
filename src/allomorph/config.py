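"""Generator configuration for synthetic sex-chromosome-aneuploidy cohorts.

The default configuration reproduces the statistical structure of a
cross-sectional MRI study of limbic anatomy across seven karyotype groups
(XX, XY, XXX, XXY, XYY, XXYY, XXXXY): group-specific total brain volume
(TBV) distributions, hypoallometric regional scaling of amygdala and
hippocampus volume on TBV, karyotype-specific proportional volume deficits,
a power-law volume-surface link, and spatially smooth vertex-wise shape
fields on a fixed 5245-vertex amygdalo-hippocampal mesh.

All volumes are cm^3, surface areas cm^2 (vertex areas mm^2), and every
logarithm in the generative model is base 10.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
import yaml

CONFIG_SCHEMA_VERSION = 1

#: Canonical karyotype ordering used for row ordering and reporting.
KARYOTYPES = ("XX", "XY", "XXX", "XXY", "XYY", "XXYY", "XXXXY")

#: Gonadal sex implied by the sex-chromosome complement.
KARYOTYPE_SEX = {
    "XX": "F",
    "XXX": "F",
    "XY": "M",
    "XXY": "M",
    "XYY": "M",
    "XXYY": "M",
    "XXXXY": "M",
}

#: Gonadal control group for each supernumerary karyotype.
GONADAL_CONTROL = {
    "XXX": "XX",
    "XXY": "XY",
    "XYY": "XY",
    "XXYY": "XY",
    "XXXXY": "XY",
}

REGIONS = ("amygdala", "hippocampus")

#: The four surface structures (region x hemisphere) and their vertex counts.
STRUCTURES = (
    "right_amygdala",
    "left_amygdala",
    "right_hippocampus",
    "left_hippocampus",
)
DEFAULT_VERTEX_COUNTS = {
    "right_amygdala": 1405,
    "left_amygdala": 1473,
    "right_hippocampus": 1215,
    "left_hippocampus": 1152,
}
STRUCTURE_REGION = {
    "right_amygdala": "amygdala",
    "left_amygdala": "amygdala",
    "right_hippocampus": "hippocampus",
    "left_hippocampus": "hippocampus",
}

# Per-karyotype descriptive calibration: group size, TBV mean (cm^3),
# TBV SEM (cm^3), and group-mean regional volumes (cm^3).  SDs used by the
# generator are SEM * sqrt(n).
REFERENCE_GROUPS: dict[str, dict[str, float]] = {
    "XX": dict(n=87, tbv_mean=1261.0, tbv_sem=9.74, amygdala=2.32, hippocampus=4.30),
    "XY": dict(n=79, tbv_mean=1392.0, tbv_sem=13.8, amygdala=2.54, hippocampus=4.57),
    "XXX": dict(n=28, tbv_mean=1179.0, tbv_sem=22.8, amygdala=2.05, hippocampus=3.98),
    "XXY": dict(n=56, tbv_mean=1287.0, tbv_sem=17.8, amygdala=2.26, hippocampus=4.32),
    "XYY": dict(n=25, tbv_mean=1418.0, tbv_sem=24.9, amygdala=2.43, hippocampus=4.68),
    "XXYY": dict(n=19, tbv_mean=1291.0, tbv_sem=29.7, amygdala=2.19, hippocampus=4.33),
    "XXXXY": dict(n=5, tbv_mean=1131.0, tbv_sem=36.1, amygdala=1.86, hippocampus=3.82),
}

#: Normative scaling exponents used as generator truth.
DEFAULT_SCALING_EXPONENT = {"amygdala": 0.89, "hippocampus": 0.76}


def _default_intercepts() -> dict[str, float]:
    """Intercepts beta0 such that the euploid (XX, XY) group means sit on the
    normative scaling line; averaged over the two reference groups so both
    carry an exactly zero karyotype offset."""
    out = {}
    for region in REGIONS:
        implied = []
        for k in ("XX", "XY"):
            g = REFERENCE_GROUPS[k]
            implied.append(
                np.log10(g[region])
                - DEFAULT_SCALING_EXPONENT[region] * np.log10(g["tbv_mean"])
            )
        out[region] = float(np.mean(implied))
    return out


def _default_offsets() -> dict[str, dict[str, float]]:
    """Additive log10 offsets per karyotype, chosen so each group's mean
    regional volume lands on its reference value given its TBV mean."""
    beta0 = _default_intercepts()
    offsets: dict[str, dict[str, float]] = {r: {} for r in REGIONS}
    for region in REGIONS:
        b1 = DEFAULT_SCALING_EXPONENT[region]
        for k in KARYOTYPES:
            if k in ("XX", "XY"):
                offsets[region][k] = 0.0
                continue
            g = REFERENCE_GROUPS[k]
            predicted = beta0[region] + b1 * np.log10(g["tbv_mean"])
            offsets[region][k] = float(np.log10(g[region]) - predicted)
    return offsets


@dataclass
class FocalBump:
    """A spatially smooth focal perturbation of proportional vertex area.

    Placed at a fractional position along the structure's principal axis
    (mirrored into both hemispheres).  Amplitude is in log10 area units at
    the bump centre (negative = contraction); extent is the Gaussian spatial
    scale in mesh coordinate units.
    """

    region: str
    axis_fraction: float
    amplitude: float
    extent: float


@dataclass
class GeneratorConfig:
    """Full parameterisation of the synthetic cohort generator."""

    # --- subject-level volumetrics -----------------------------------------
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {k: int(v["n"]) for k, v in REFERENCE_GROUPS.items()}
    )
    tbv_mean: dict[str, float] = field(
        default_factory=lambda: {k: v["tbv_mean"] for k, v in REFERENCE_GROUPS.items()}
    )
    # SD = SEM * sqrt(n) from the reference descriptives
    tbv_sd: dict[str, float] = field(
        default_factory=lambda: {
            k: float(v["tbv_sem"] * np.sqrt(v["n"])) for k, v in REFERENCE_GROUPS.items()
        }
    )
    scaling_exponent: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SCALING_EXPONENT)
    )
    scaling_intercept: dict[str, float] = field(default_factory=_default_intercepts)
    group_offsets: dict[str, dict[str, float]] = field(default_factory=_default_offsets)
    #: residual SD of log10 regional volume around the scaling law
    residual_sd: dict[str, float] = field(
        default_factory=lambda: {"amygdala": 0.021, "hippocampus": 0.029}
    )
    #: additive sex effect on log10 regional volume (male - female), default 0
    sex_effect: dict[str, float] = field(
        default_factory=lambda: {"amygdala": 0.0, "hippocampus": 0.0}
    )
    #: sex x centred-log-size interaction on log10 regional volume, default 0
    sex_size_interaction: dict[str, float] = field(
        default_factory=lambda: {"amygdala": 0.0, "hippocampus": 0.0}
    )

    # --- volume-surface coupling -------------------------------------------
    #: geometric baseline: S = coeff * V^(2/3) * 10^noise
    surface_exponent: float = 2.0 / 3.0
    surface_coefficient: dict[str, float] = field(
        default_factory=lambda: {"amygdala": 9.5, "hippocampus": 12.9}
    )
    #: SD of the log10 coupling noise; calibrated so the core-sample
    #: volume-surface Pearson correlation is ~0.97 (amygdala) / ~0.89
    #: (hippocampus)
    surface_noise_sd: dict[str, float] = field(
        default_factory=lambda: {"amygdala": 0.0083, "hippocampus": 0.0159}
    )

    # --- vertex-level shape model ------------------------------------------
    vertex_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_VERTEX_COUNTS)
    )
    #: range spanned by the spatially smooth true local scaling exponents
    exponent_range: tuple[float, float] = (0.5, 1.5)
    #: Gaussian length-scale (mesh units ~ mm) of the smooth fields
    smoothness_length: float = 8.0
    #: SD of log10 vertex-area noise
    vertex_noise_sd: float = 0.03
    focal_bumps: list[FocalBump] = field(
        default_factory=lambda: [
            FocalBump("amygdala", 0.8, -0.030, 6.0),
            FocalBump("hippocampus", 0.0, -0.030, 7.0),
            FocalBump("hippocampus", -0.8, -0.025, 6.0),
            FocalBump("hippocampus", 0.85, 0.012, 5.0),
        ]
    )
    #: karyotype-specific multiplier on all focal amplitudes (weakest in XYY)
    focal_scale: dict[str, float] = field(
        default_factory=lambda: {
            "XX": 0.0,
            "XY": 0.0,
            "XXX": 1.0,
            "XXY": 1.0,
            "XYY": 0.5,
            "XXYY": 1.0,
            "XXXXY": 1.0,
        }
    )

    # --- covariates ---------------------------------------------------------
    age_mean: dict[str, float] = field(
        default_factory=lambda: {
            "XX": 12.7, "XY": 12.7, "XXX": 12.3, "XXY": 12.7,
            "XYY": 12.2, "XXYY": 14.0, "XXXXY": 12.9,
        }
    )
    age_sd: dict[str, float] = field(
        default_factory=lambda: {
            "XX": 5.1, "XY": 4.6, "XXX": 5.7, "XXY": 4.9,
            "XYY": 4.9, "XXYY": 5.5, "XXXXY": 4.8,
        }
    )
    age_range: tuple[float, float] = (5.0, 26.0)
    #: number of subjects per karyotype with missing Tanner stage
    tanner_missing: dict[str, int] = field(
        default_factory=lambda: {"XY": 3, "XX": 1, "XXY": 1}
    )

    sample_label: str = "core"
    seed: int = 0
    #: seed of the population-level vertex truth (template proportions,
    #: local scaling exponents, focal-bump geometry).  Deliberately separate
    #: from ``seed`` so core and normative cohorts drawn with different
    #: sampling seeds share one underlying anatomy.
    field_seed: int = 20181129

    # ------------------------------------------------------------------ api
    def validate(self) -> None:
        """Raise ``ConfigError`` on an internally inconsistent configuration."""
        for k, n in self.group_sizes.items():
            if k not in KARYOTYPES:
                raise ConfigError(f"unknown karyotype {k!r}")
            if n < 0:
                raise ConfigError(f"negative group size for {k}")
            if n > 0 and (k not in self.tbv_mean or k not in self.tbv_sd):
                raise ConfigError(f"missing TBV parameters for requested group {k}")
        for k, sd in self.tbv_sd.items():
            if sd < 0:
                raise ConfigError(f"negative TBV SD for {k}")
        for region in REGIONS:
            if self.residual_sd[region] < 0:
                raise ConfigError(f"negative residual SD for {region}")
            if self.surface_noise_sd[region] < 0:
                raise ConfigError(f"negative surface noise SD for {region}")
            for ref in ("XX", "XY"):
                if self.group_offsets[region].get(ref, 0.0) != 0.0:
                    raise ConfigError(
                        f"offset for reference karyotype {ref} must be exactly 0"
                    )
        if self.vertex_noise_sd < 0:
            raise ConfigError("negative vertex noise SD")
        if set(self.vertex_counts) != set(STRUCTURES):
            raise ConfigError("vertex_counts must cover exactly the four structures")
        if any(v <= 0 for v in self.vertex_counts.values()):
            raise ConfigError("vertex counts must be positive")
        lo, hi = self.exponent_range
        if not lo <= hi:
            raise ConfigError("exponent_range must be (lo, hi) with lo <= hi")

    @property
    def n_vertices(self) -> int:
        return int(sum(self.vertex_counts.values()))

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["schema_version"] = CONFIG_SCHEMA_VERSION
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "GeneratorConfig":
        d = dict(d)
        d.pop("schema_version", None)
        if "focal_bumps" in d:
            d["focal_bumps"] = [
                b if isinstance(b, FocalBump) else FocalBump(**b)
                for b in d["focal_bumps"]
            ]
        for key in ("exponent_range", "age_range"):
            if key in d:
                d[key] = tuple(d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(self.to_dict()), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def content_hash(self) -> str:
        """SHA-256 over the canonical serialised form (used in run manifests)."""
        blob = yaml.safe_dump(_plain(self.to_dict()), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


class ConfigError(ValueError):
    """Invalid generator or pipeline configuration."""


def _plain(obj):
    """Recursively convert to YAML-safe builtins."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def core_config(seed: int = 0) -> GeneratorConfig:
    """Default configuration for the 298-subject, 7-karyotype core sample."""
    cfg = GeneratorConfig(seed=seed, sample_label="core")
    cfg.validate()
    return cfg


def normative_config(seed: int = 0) -> GeneratorConfig:
    """Configuration for the independent normative (allometric) sample:
    79 typically developing subjects (34 XX, 45 XY), narrow age band."""
    cfg = GeneratorConfig(seed=seed, sample_label="normative")
    cfg.group_sizes = {k: 0 for k in KARYOTYPES}
    cfg.group_sizes.update({"XX": 34, "XY": 45})
    cfg.age_mean = {k: 13.0 for k in KARYOTYPES}
    cfg.age_sd = {k: 0.6 for k in KARYOTYPES}
    cfg.age_range = (12.0, 14.0)
    cfg.tanner_missing = {}
    cfg.validate()
    return cfg
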