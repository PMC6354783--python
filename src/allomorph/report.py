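"""Summary outputs: descriptive grids, contrast grids, surface masks,
correlation tables, and the reproducibility manifest.

All report artifacts are plain CSV/JSON with numerics at fixed precision,
so re-runs with identical inputs produce byte-identical files.  Plots
(optional) are thin matplotlib wrappers over the same data frames.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .adjustment import effect_size_vs_reference, omnibus_group_test
from .config import KARYOTYPES, REGIONS
from .synthesize import volume_column
from .vertexwise import MapCorrelationMatrix, VertexContrastMap

FLOAT_FORMAT = "%.10g"


def summarize_table2(core: pd.DataFrame) -> pd.DataFrame:
    """Per-karyotype mean and SEM of TBV and regional volumes, with the
    omnibus F and -log10 p per measure (descriptive-grid layout)."""
    measures = [("tbv_cm3", "Total brain volume, cm^3")] + [
        (volume_column(r), f"{r.capitalize()}, cm^3") for r in REGIONS
    ]
    rows = []
    present = [k for k in KARYOTYPES if (core["karyotype"] == k).any()]
    skipped = [k for k in KARYOTYPES if k not in present]
    if skipped:
        import warnings

        warnings.warn(f"empty group(s) omitted from summary: {skipped}",
                      stacklevel=2)
    for col, label in measures:
        f, p = omnibus_group_test(core, col)
        row = {"measure": label, "F": f, "neg_log10_p": -np.log10(p)}
        for k in present:
            vals = core.loc[core["karyotype"] == k, col].to_numpy(dtype=float)
            row[f"{k}_mean"] = vals.mean()
            row[f"{k}_sem"] = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def effect_size_shifts(core: pd.DataFrame) -> pd.DataFrame:
    """Effect-size shift of every group vs the XY distribution per measure."""
    measures = ["tbv_cm3"] + [volume_column(r) for r in REGIONS]
    rows = []
    for measure in measures:
        for k in KARYOTYPES:
            if not (core["karyotype"] == k).any():
                continue
            rows.append(dict(measure=measure, karyotype=k,
                             d_vs_XY=effect_size_vs_reference(core, k, measure)))
    return pd.DataFrame(rows)


def contrast_grid(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Signed -log10(p_adj) grid over (region, method) x contrast; the sign
    follows the estimate (negative = smaller in the comparison group) and
    cells not significant after adjustment are set to 0."""
    out = results.copy()
    logp = -np.log10(np.maximum(out["p_adj"].to_numpy(dtype=float), 1e-300))
    signed = np.sign(out["estimate"].to_numpy(dtype=float)) * logp
    signed[out["p_adj"].to_numpy(dtype=float) >= alpha] = 0.0
    out["signed_neg_log10_p_adj"] = signed
    grid = out.pivot_table(index=["region", "method", "covariates"],
                           columns="contrast",
                           values="signed_neg_log10_p_adj")
    return grid.reset_index()


def render_reports(
    out_dir,
    results: pd.DataFrame | None = None,
    core: pd.DataFrame | None = None,
    maps: list[VertexContrastMap] | None = None,
    correlations: MapCorrelationMatrix | None = None,
    make_plots: bool = False,
) -> list[Path]:
    """Write the report artifacts that the supplied inputs support.

    Missing sections are skipped with a log entry; empty inputs yield empty
    but schema-valid files.
    """
    import logging

    log = logging.getLogger("allomorph")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write(df: pd.DataFrame, name: str) -> None:
        path = out_dir / name
        df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
        written.append(path)

    if core is not None and len(core):
        _write(summarize_table2(core), "descriptives.csv")
        _write(effect_size_shifts(core), "effect_sizes.csv")
    else:
        log.info("no core sample supplied; skipping descriptive reports")
    if results is not None:
        _write(results, "volume_contrasts.csv")
        _write(contrast_grid(results), "volume_contrast_grid.csv")
    else:
        log.info("no volume results supplied; skipping contrast grid")
    if maps:
        frames = []
        for m in maps:
            df = m.to_frame()
            df.insert(0, "contrast", m.spec.label)
            frames.append(df)
        _write(pd.concat(frames, ignore_index=True), "vertex_masks.csv")
    else:
        log.info("no vertex maps supplied; skipping surface masks")
    if correlations is not None:
        _write(correlations.to_frame(), "map_correlations.csv")

    if make_plots and results is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        grid = contrast_grid(results).set_index(["region", "method", "covariates"])
        fig, ax = plt.subplots(figsize=(8, 6))
        im = ax.imshow(grid.to_numpy(dtype=float), cmap="RdBu_r", vmin=-6, vmax=6)
        ax.set_xticks(range(grid.shape[1]), grid.columns, rotation=45)
        ax.set_yticks(range(grid.shape[0]),
                      ["/".join(map(str, i)) for i in grid.index])
        fig.colorbar(im, ax=ax, label="signed -log10 adjusted p")
        fig.tight_layout()
        path = out_dir / "volume_contrast_grid.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written


@dataclass
class RunManifest:
    """Provenance record tying outputs to configuration, seed and inputs."""

    config_hash: str
    seed: int
    package_version: str = __version__
    input_checksums: dict[str, str] = field(default_factory=dict)
    operations: list[dict] = field(default_factory=list)
    timestamp: str = ""

    def record(self, operation: str, **params) -> None:
        self.operations.append({"operation": operation, **params})

    def to_json(self, path) -> None:
        d = asdict(self)
        if not d["timestamp"]:
            d["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime())
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


def checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
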