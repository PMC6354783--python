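"""Vertex-wise normative models, FDR-controlled contrasts, map correlation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from allomorph import (
    ContrastSpec,
    fit_vertex_normative,
    generate_subjects,
    generate_vertex_table,
    map_correlation,
    normative_config,
    robustness_vertex_survival,
    vertex_contrast,
    vertex_deviations,
)
from allomorph.allometry import InputError
from allomorph.config import KARYOTYPES, REGIONS
from allomorph.stats import bh_adjust, bh_reject, pearson_r
from allomorph.synthesize import generate_mesh, make_vertex_fields

from conftest import small_vertex_config


def brute_force_bh(p: np.ndarray, q: float) -> np.ndarray:
    """Step-up definition: largest k with p_(k) <= k*q/m; reject those."""
    m = len(p)
    order = np.argsort(p)
    k_max = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_max = k
    mask = np.zeros(m, dtype=bool)
    mask[order[:k_max]] = True
    return mask


class TestBH:
    def test_hand_example(self):
        p = np.array([0.01, 0.02, 0.04, 0.5])
        mask = bh_reject(p, q=0.05)
        # thresholds k*q/m = 0.0125, 0.025, 0.0375, 0.05: two smallest pass
        np.testing.assert_array_equal(mask, [True, True, False, False])

    @given(st.integers(0, 5000))
    def test_matches_brute_force_step_up(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.integers(1, 60)
        p = rng.uniform(size=m) ** rng.uniform(0.3, 3.0)
        np.testing.assert_array_equal(bh_reject(p, 0.05),
                                      brute_force_bh(p, 0.05))
        # adjusted p-values agree with the rejection set at every level
        q = bh_adjust(p)
        for level in (0.01, 0.05, 0.2):
            np.testing.assert_array_equal(q <= level,
                                          brute_force_bh(p, level))


def _small_cohorts(seed=0, focal_scale=None):
    cfg = small_vertex_config(seed=seed)
    if focal_scale is not None:
        cfg.focal_scale = focal_scale
    subs = generate_subjects(cfg)
    mesh, vt = generate_vertex_table(cfg, subs)
    ncfg = normative_config(seed=seed + 500)
    ncfg.vertex_counts = cfg.vertex_counts
    nsubs = generate_subjects(ncfg)
    _, nvt = generate_vertex_table(ncfg, nsubs, mesh=mesh)
    return cfg, subs, mesh, vt, nsubs, nvt


class TestNormativeField:
    def test_training_deviations_mean_zero(self):
        _, _, mesh, _, nsubs, nvt = _small_cohorts()
        field = fit_vertex_normative(nvt, nsubs)
        dev = vertex_deviations(field, nvt, nsubs)
        assert np.abs(dev.mean(axis=0)).max() < 1e-10

    def test_noiseless_uniform_isometry_slope_one(self):
        cfg = small_vertex_config(seed=2, label="normative")
        cfg.group_sizes = {k: 0 for k in KARYOTYPES}
        cfg.group_sizes.update({"XX": 20, "XY": 20})
        cfg.vertex_noise_sd = 0.0
        cfg.exponent_range = (1.0, 1.0)
        cfg.focal_scale = {k: 0.0 for k in KARYOTYPES}
        subs = generate_subjects(cfg)
        _, vt = generate_vertex_table(cfg, subs)
        field = fit_vertex_normative(vt, subs)
        np.testing.assert_allclose(field.slope(), 1.0, atol=1e-8)

    def test_exponent_field_recovery(self):
        cfg, _, mesh, _, nsubs, nvt = _small_cohorts(seed=3)
        field = fit_vertex_normative(nvt, nsubs)
        truth = make_vertex_fields(cfg, mesh)
        r = pearson_r(field.slope(), truth.exponent)
        assert r >= 0.8

    def test_gate_mostly_simple_under_null(self):
        tiers = []
        for seed in range(10):
            _, _, _, _, nsubs, nvt = _small_cohorts(seed=100 + seed)
            tiers.append(fit_vertex_normative(nvt, nsubs).tier)
        assert sum(t == "simple" for t in tiers) >= 6

    def test_doubling_invariance_only_at_isometry(self):
        # scaling a subject's areas and total by 2 preserves deviations
        # iff the local exponent is 1 (log-log predictor algebra)
        _, _, mesh, _, nsubs, nvt = _small_cohorts(seed=4)
        field = fit_vertex_normative(nvt, nsubs)
        dev = vertex_deviations(field, nvt, nsubs)
        doubled = nvt.areas * 2.0
        nsubs2 = nsubs.copy()
        for region in REGIONS:
            nsubs2[f"{region}_surface_cm2"] *= 2.0
        nvt2 = type(nvt)(mesh=mesh, areas=doubled)
        dev2 = vertex_deviations(field, nvt2, nsubs2)
        delta = (dev2 - dev).iloc[0].to_numpy()
        slope = field.slope()
        np.testing.assert_allclose(delta, (1.0 - slope) * np.log10(2.0),
                                   atol=1e-10)


class TestContrasts:
    def test_identical_groups_empty_mask(self):
        _, subs, mesh, _, _, _ = _small_cohorts(seed=5)
        sub = subs[subs["karyotype"].isin(["XY", "XXY"])].reset_index(drop=True)
        xy = sub[sub["karyotype"] == "XY"].head(20)
        fake = xy.copy()
        fake["karyotype"] = "XXY"
        fake["subject_id"] = [f"dup{i}" for i in range(len(fake))]
        both = pd.concat([xy, fake], ignore_index=True)
        both.attrs["sample_id"] = "core"
        dev = pd.DataFrame(
            np.vstack([np.tile(np.arange(mesh.n_vertices, dtype=float), (20, 1))] * 2)
            + np.random.default_rng(0).normal(size=(40, 1)),
            index=both["subject_id"], columns=np.arange(mesh.n_vertices))
        dev.iloc[20:] = dev.iloc[:20].to_numpy()
        m = vertex_contrast(dev, both, ContrastSpec("XXY", "XY", "amygdala"),
                            mesh)
        assert np.allclose(m.t, 0.0)
        assert not m.mask.any()

    def test_group_too_small_raises(self):
        _, subs, mesh, vt, nsubs, nvt = _small_cohorts(seed=6)
        field = fit_vertex_normative(nvt, nsubs)
        dev = vertex_deviations(field, vt, subs)
        one = subs[subs["karyotype"].isin(["XY"])].copy()
        lone = subs[subs["karyotype"] == "XXY"].head(1)
        small = pd.concat([one, lone], ignore_index=True)
        small.attrs["sample_id"] = "core"
        with pytest.raises(InputError):
            vertex_contrast(dev.loc[small["subject_id"]], small,
                            ContrastSpec("XXY", "XY", "amygdala"), mesh)

    def test_focal_contraction_detected_and_attenuated(
            self, core_subjects, default_vertex_data, normative_subjects,
            default_mesh, default_fields):
        cvt, nvt = default_vertex_data
        field = fit_vertex_normative(nvt, normative_subjects)
        dev = vertex_deviations(field, cvt, core_subjects)
        m_xxy = vertex_contrast(dev, core_subjects,
                                ContrastSpec("XXY", "XY", "amygdala"),
                                default_mesh)
        m_xyy = vertex_contrast(dev, core_subjects,
                                ContrastSpec("XYY", "XY", "amygdala"),
                                default_mesh)
        # XXY recovers the focal contraction; XYY (half amplitude, n=25)
        # yields far fewer significant vertices
        assert m_xxy.mask.sum() > 100
        assert m_xyy.mask.sum() < m_xxy.mask.sum() / 2
        support = np.abs(default_fields.focal) > 0.8 * np.abs(
            default_fields.focal).max()
        hits = m_xxy.mask & support
        assert hits.sum() > 0.5 * support.sum()
        # significant contraction vertices point in the contraction direction
        assert (m_xxy.direction[m_xxy.mask & support] == -1).mean() > 0.9

    def test_masks_respect_q_invariant(self, core_subjects,
                                       default_vertex_data,
                                       normative_subjects, default_mesh):
        cvt, nvt = default_vertex_data
        field = fit_vertex_normative(nvt, normative_subjects)
        dev = vertex_deviations(field, cvt, core_subjects)
        m = vertex_contrast(dev, core_subjects,
                            ContrastSpec("XXX", "XX", "hippocampus"),
                            default_mesh, q=0.05)
        assert (m.q[m.mask] < 0.05).all()
        assert np.array_equal(np.sign(m.t[m.mask]), m.direction[m.mask])

    def test_focal_amplitude_monotonicity(self):
        counts = []
        for mult in (0.5, 1.0, 2.0):
            total = 0
            for seed in range(3):
                scale = {k: 0.0 for k in KARYOTYPES}
                scale.update({"XXX": mult, "XXY": mult, "XXYY": mult,
                              "XXXXY": mult, "XYY": 0.5 * mult})
                cfg, subs, mesh, vt, nsubs, nvt = _small_cohorts(
                    seed=200 + seed, focal_scale=scale)
                field = fit_vertex_normative(nvt, nsubs)
                dev = vertex_deviations(field, vt, subs)
                m = vertex_contrast(dev, subs,
                                    ContrastSpec("XXY", "XY", "amygdala"), mesh)
                total += int(m.mask.sum())
            counts.append(total)
        assert counts[0] <= counts[1] <= counts[2]


class TestMapCorrelation:
    def test_hand_pearson(self):
        # by hand: cov = 4.5, sd_x*sd_y = sqrt(2)*sqrt(10.1667) -> 0.99794
        assert pearson_r([1, 2, 3], [2, 4, 6.5]) == pytest.approx(0.99794,
                                                                  abs=1e-4)

    def test_self_and_negation(self, core_subjects, default_vertex_data,
                               normative_subjects, default_mesh):
        cvt, nvt = default_vertex_data
        field = fit_vertex_normative(nvt, normative_subjects)
        dev = vertex_deviations(field, cvt, core_subjects)
        m = vertex_contrast(dev, core_subjects,
                            ContrastSpec("XXY", "XY", "amygdala"), default_mesh)
        import copy

        neg = copy.deepcopy(m)
        neg.t = -neg.t
        neg.spec = ContrastSpec("XYY", "XY", "amygdala")
        mc = map_correlation([m, neg])
        for region in REGIONS:
            mat = mc.matrices[region]
            assert mat.iloc[0, 0] == pytest.approx(1.0)
            assert mat.iloc[0, 1] == pytest.approx(-1.0)

    def test_reorder_invariance(self, rng):
        a = rng.normal(size=50)
        b = rng.normal(size=50)
        perm = rng.permutation(50)
        assert pearson_r(a, b) == pytest.approx(pearson_r(a[perm], b[perm]),
                                                abs=1e-12)

    def test_sca_maps_converge(self, core_subjects, default_vertex_data,
                               normative_subjects, default_mesh):
        cvt, nvt = default_vertex_data
        field = fit_vertex_normative(nvt, normative_subjects)
        dev = vertex_deviations(field, cvt, core_subjects)
        maps = [vertex_contrast(dev, core_subjects,
                                ContrastSpec(g, c, "amygdala"), default_mesh)
                for g, c in [("XXX", "XX"), ("XXY", "XY"), ("XYY", "XY"),
                             ("XXYY", "XY")]]
        mc = map_correlation(maps)
        for region in REGIONS:
            mat = mc.matrices[region].to_numpy()
            off = mat[np.triu_indices_from(mat, k=1)]
            assert (off > 0).all()


class TestRobustness:
    def test_identical_runs_fraction_one(self):
        masks = {"XXY-XY": np.array([True, True, False, True])}
        out = robustness_vertex_survival(masks, masks)
        assert out.loc[out["contrast"] == "XXY-XY", "fraction"].iloc[0] == 1.0
        assert out.loc[out["contrast"] == "pooled", "fraction"].iloc[0] == 1.0

    def test_empty_covaried_fraction_zero(self):
        main = {"XXY-XY": np.array([True, False, True])}
        cov = {"XXY-XY": np.zeros(3, dtype=bool)}
        out = robustness_vertex_survival(main, cov)
        assert out["fraction"].iloc[0] == 0.0

    def test_partial_overlap(self):
        main = {"c": np.arange(20) < 10}
        cov = {"c": (np.arange(20) < 9) | (np.arange(20) == 15)}
        out = robustness_vertex_survival(main, cov)
        assert out.loc[out["contrast"] == "c", "fraction"].iloc[0] == \
            pytest.approx(0.9)

    def test_covariate_robust_survival_on_default(self, core_subjects,
                                                  default_vertex_data,
                                                  normative_subjects,
                                                  default_mesh):
        # age/Tanner covariation leaves most significant vertices intact
        cvt, nvt = default_vertex_data
        field = fit_vertex_normative(nvt, normative_subjects)
        dev = vertex_deviations(field, cvt, core_subjects)
        main, covaried = {}, {}
        for g, c in [("XXX", "XX"), ("XXY", "XY")]:
            spec = ContrastSpec(g, c, "amygdala")
            main[spec.label] = vertex_contrast(dev, core_subjects, spec,
                                               default_mesh).mask
            spec_cov = ContrastSpec(g, c, "amygdala", covariates="age_tanner")
            covaried[spec.label] = vertex_contrast(dev, core_subjects,
                                                   spec_cov, default_mesh).mask
        out = robustness_vertex_survival(main, covaried)
        pooled = out.loc[out["contrast"] == "pooled"].iloc[0]
        assert pooled["n_significant"] > 0
        assert pooled["fraction"] > 0.7
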