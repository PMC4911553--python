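"""Generator contracts: determinism, design realism, generative consistency."""

import numpy as np
import pandas as pd
import pytest

from metgp import (
    SimConfig,
    additive_relationship,
    simulate_dataset,
    simulate_design,
    simulate_env_covariates,
    simulate_markers,
    simulate_pedigree,
    simulate_phenotypes,
)
from metgp.kernels import genomic_relationship


class TestMarkers:
    def test_panel_scale_frequencies(self):
        mk = simulate_markers(803, 2000, (0.05, 0.95), seed=1)
        assert mk.codes.shape == (803, 2000)
        means = mk.codes.mean(axis=0)
        assert means.min() >= 0.05 - 1e-12 and means.max() <= 0.95 + 1e-12

    def test_dosage_dialect(self):
        mk = simulate_markers(100, 50, (0.1, 0.9), seed=2, dialect="dosage")
        assert set(np.unique(mk.codes)) <= {0.0, 1.0, 2.0}
        freq = mk.codes.mean(axis=0) / 2
        assert freq.min() >= 0.1 - 1e-12 and freq.max() <= 0.9 + 1e-12

    def test_single_column_polymorphic(self):
        mk = simulate_markers(2, 1, (0.5, 0.5), seed=99)
        assert mk.codes[:, 0].std() > 0

    def test_seed_determinism(self):
        a = simulate_markers(200, 500, (0.1, 0.9), seed=42)
        b = simulate_markers(200, 500, (0.1, 0.9), seed=42)
        np.testing.assert_array_equal(a.codes, b.codes)

    def test_bad_range(self):
        with pytest.raises(ValueError, match="lo <= hi"):
            simulate_markers(10, 5, (0.9, 0.1), seed=0)


class TestPedigree:
    def test_founder_diagonal(self):
        ped = simulate_pedigree(10, 3, 4, seed=7)
        ids, A = additive_relationship(ped)
        founders = [i for i, (f, m) in
                    {x: (p1, p2) for x, p1, p2 in ped.records}.items()
                    if f is None]
        idx = {x: k for k, x in enumerate(ids)}
        for f in founders:
            assert A[idx[f], idx[f]] == 1.0

    def test_parent_offspring(self):
        ped = simulate_pedigree(2, 1, 1, seed=1)
        ids, A = additive_relationship(ped)
        child = ped.records[-1][0]
        parent = ped.records[-1][1]
        idx = {x: k for k, x in enumerate(ids)}
        assert A[idx[child], idx[parent]] == 0.5

    def test_full_sib_pairs(self):
        ped = simulate_pedigree(50, 4, 2, seed=3)
        ids, A = additive_relationship(ped)
        idx = {x: k for k, x in enumerate(ids)}
        parents = {x: (p1, p2) for x, p1, p2 in ped.records}
        gen1 = [x for x, (f, m) in parents.items()
                if f is not None and f.startswith("F") and m.startswith("F")]
        sib_pairs = [(a, b) for i, a in enumerate(gen1) for b in gen1[i + 1:]
                     if parents[a] == parents[b] or parents[a] == parents[b][::-1]]
        assert sib_pairs, "generator should produce full-sib pairs"
        for a, b in sib_pairs:
            assert A[idx[a], idx[b]] == 0.5

    def test_topological_validity(self):
        ped = simulate_pedigree(6, 4, 3, seed=5)
        seen = set()
        for ind, p1, p2 in ped.records:
            for p in (p1, p2):
                assert p is None or p in seen
            seen.add(ind)


class TestEnvCovariates:
    def test_shape_and_spread(self):
        t = simulate_env_covariates(5, 5, seed=2)
        assert t.values.shape == (5, 5)
        assert (t.values.std(axis=0) > 0).all()

    def test_two_point_standardization(self):
        t = simulate_env_covariates(2, 1, seed=9)
        z = (t.values - t.values.mean(0)) / t.values.std(0)
        np.testing.assert_allclose(np.abs(z), 1.0)

    def test_determinism(self):
        a = simulate_env_covariates(4, 3, seed=5)
        b = simulate_env_covariates(4, 3, seed=5)
        np.testing.assert_array_equal(a.values, b.values)


class TestDesign:
    def test_prep_proportions_at_panel_scale(self):
        cfg = SimConfig(n_lines=803, n_sites=5, n_checks=3, seed=1)
        skel = simulate_design(cfg)
        df = skel.df
        for site, grp in df.groupby("site"):
            acc = grp[~grp.is_check]
            reps = acc.groupby("line").size().value_counts(normalize=True)
            assert abs(reps.get(1, 0) - 0.81) <= 0.02
            assert abs(reps.get(2, 0) - 0.15) <= 0.02
            assert abs(reps.get(3, 0) - 0.04) <= 0.02
            assert abs(grp.is_check.mean() - 0.06) <= 0.005

    def test_unreplicated_no_checks(self):
        cfg = SimConfig(n_lines=40, n_sites=2, n_checks=0,
                        prep_fractions=(1.0, 0.0, 0.0), check_plot_fraction=0.0,
                        seed=2)
        df = simulate_design(cfg).df
        assert (df.groupby(["site", "line"]).size() == 1).all()
        assert df.groupby("site").size().eq(40).all()

    def test_referential_integrity(self):
        cfg = SimConfig(n_lines=50, n_sites=3, n_checks=2, seed=3)
        df = simulate_design(cfg).df
        registry = {f"L{j + 1:04d}" for j in range(50)} | {"CHK1", "CHK2"}
        assert set(df.line) <= registry

    def test_replicates_in_distinct_blocks(self):
        cfg = SimConfig(n_lines=60, n_sites=2, n_checks=1, seed=4)
        df = simulate_design(cfg).df
        acc = df[~df.is_check]
        per = acc.groupby(["site", "line"])["block"].nunique()
        counts = acc.groupby(["site", "line"]).size()
        assert (per == counts).all()

    def test_invalid_fractions(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimConfig(n_lines=10, prep_fractions=(0.5, 0.1, 0.1))


def _tiny_config(**var):
    base = {"E": 0, "W": 0, "L": 0, "G": 0, "A": 0, "GE": 0, "AE": 0,
            "block": 0, "residual": 0}
    base.update(var)
    return SimConfig(n_lines=12, n_markers=60, n_sites=2, n_checks=0, seed=5,
                     variance_components=base)


class TestPhenotypes:
    def test_pure_noise_variance(self):
        cfg = SimConfig(n_lines=200, n_markers=50, n_sites=3, n_checks=0, seed=8,
                        variance_components={"E": 0, "W": 0, "L": 0, "G": 0, "A": 0,
                                             "GE": 0, "AE": 0, "block": 0,
                                             "residual": 1.0})
        bundle, truth = simulate_dataset(cfg)
        v = bundle.phenotypes.df.y.var()
        n = len(bundle.phenotypes)
        from scipy.stats import chi2
        lo, hi = chi2.ppf([0.0005, 0.9995], n - 1) / (n - 1)
        assert lo <= v <= hi

    def test_line_level_genetic_effect_shared(self):
        cfg = SimConfig(n_lines=60, n_markers=100, n_sites=2, n_checks=0, seed=6,
                        prep_fractions=(0.0, 1.0, 0.0),
                        variance_components={"E": 0, "W": 0, "L": 0, "G": 1.0,
                                             "A": 0, "GE": 0, "AE": 0, "block": 0,
                                             "residual": 0})
        bundle, truth = simulate_dataset(cfg)
        df = bundle.phenotypes.df
        per_line = df.groupby(["site", "line"]).y.nunique()
        assert (per_line == 1).all()

    def test_zero_variance_terms_identically_zero(self):
        cfg = _tiny_config(residual=1.0)
        bundle, truth = simulate_dataset(cfg)
        for key in ("site_effects", "w_site", "g", "a", "gE", "aE"):
            assert np.all(truth.components[key] == 0)

    def test_bit_for_bit_determinism(self):
        cfg = _tiny_config(G=1.0, GE=0.5, residual=1.0)
        b1, t1 = simulate_dataset(cfg)
        b2, t2 = simulate_dataset(cfg)
        np.testing.assert_array_equal(b1.phenotypes.df.y, b2.phenotypes.df.y)
        np.testing.assert_array_equal(t1.true_genetic_values, t2.true_genetic_values)
        np.testing.assert_array_equal(t1.true_marker_effects, t2.true_marker_effects)

    def test_mismatched_lines_error(self, small_bundle):
        bundle, _ = small_bundle
        cfg = SimConfig(n_lines=100, n_markers=300, n_sites=3, n_checks=2, seed=9)
        skel = simulate_design(cfg)
        bad = skel.df.copy()
        bad.loc[0, "line"] = "UNKNOWN_LINE"
        from metgp.data import PhenotypeTable
        with pytest.raises(ValueError, match="UNKNOWN_LINE"):
            simulate_phenotypes(PhenotypeTable(bad), bundle.markers, bundle.pedigree,
                                bundle.env_covariates, cfg)

    def test_ge_covariance_matches_kernel_oracle(self):
        """Monte-Carlo covariance of gE equals σ²·G within site, 0 across."""
        n_rep = 500
        cfg0 = _tiny_config(GE=1.0, residual=0.01)
        bundle, truth0 = simulate_dataset(cfg0)
        rowmap = bundle.markers.row_index()
        rows = [rowmap[l] for l in truth0.line_ids]
        G_ref = genomic_relationship(bundle.markers)[np.ix_(rows, rows)]
        draws = []
        for rep in range(n_rep):
            cfg = SimConfig(**{**cfg0.__dict__, "seed": 1000 + rep})
            _, truth = simulate_phenotypes(
                bundle.phenotypes, bundle.markers, bundle.pedigree,
                bundle.env_covariates, cfg)
            draws.append(truth.components["gE"])
        draws = np.stack(draws)  # rep × lines × sites
        scale = truth.true_variance_components["GE"]
        C = scale * G_ref
        same_site = np.einsum("rjs,rks->jk", draws, draws) / (draws.shape[2] * n_rep)
        cross_site = np.einsum("rj,rk->jk", draws[:, :, 0], draws[:, :, 1]) / n_rep
        d = np.diag(C)
        se_same = np.sqrt((np.outer(d, d) + C**2) / (draws.shape[2] * n_rep))
        se_cross = np.sqrt(np.outer(d, d) / n_rep)
        assert np.all(np.abs(same_site - C) <= 3 * se_same + 1e-12)
        assert np.all(np.abs(cross_site) <= 3 * se_cross + 1e-12)

    def test_generative_covariance_consistency(self):
        """Cov(y) over replicates ≈ Σ σ²_t K_t + σ²_ε I elementwise."""
        from metgp.kernels import build_kernel_set

        n_rep = 800
        cfg0 = SimConfig(n_lines=8, n_markers=40, n_sites=2, n_checks=0, seed=0,
                         prep_fractions=(1.0, 0.0, 0.0),
                         variance_components={"E": 0.5, "W": 0.4, "L": 0, "G": 0.6,
                                              "A": 0.3, "GE": 0.4, "AE": 0.2,
                                              "block": 0, "residual": 0.5})
        bundle, truth0 = simulate_dataset(cfg0)
        ks = build_kernel_set("E+W+G+A+GE+AE", bundle.phenotypes, bundle.markers,
                              bundle.pedigree, bundle.env_covariates, validate=False)
        tv = truth0.true_variance_components
        V = sum(tv[t] * ks.kernels[t].matrix for t in ks.term_names)
        V = V + tv["residual"] * np.eye(ks.n_obs)
        ys = []
        for rep in range(n_rep):
            cfg = SimConfig(**{**cfg0.__dict__, "seed": 2000 + rep})
            pheno, _ = simulate_phenotypes(
                bundle.phenotypes, bundle.markers, bundle.pedigree,
                bundle.env_covariates, cfg)
            ys.append(pheno.df.y.to_numpy())
        ys = np.stack(ys)
        emp = np.cov(ys.T, bias=True)
        d = np.diag(V)
        se = np.sqrt((np.outer(d, d) + V**2) / n_rep)
        assert np.all(np.abs(emp - V) <= 3.5 * se)

    def test_truth_records_consistent_dimensions(self, small_bundle):
        bundle, truth = small_bundle
        J, S = truth.true_genetic_values.shape
        assert J == len(truth.line_ids) and S == len(truth.site_ids)
        assert truth.true_marker_effects.size == bundle.markers.n_markers
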