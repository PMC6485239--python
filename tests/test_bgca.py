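import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

from bioregions.bgca import between_group_ca, class_counts, correspondence_analysis
from bioregions.incidence import IncidenceMatrix, SpeciesClassTable
from bioregions.modularity import Partition
from bioregions.synth import MetacommunityConfig, generate


def _inc(site_sets):
    species = sorted(set().union(*site_sets.values()))
    occ = np.array(
        [[1 if sp in s else 0 for sp in species] for s in site_sets.values()]
    )
    return IncidenceMatrix(list(site_sets), species, occ)


class TestClassCounts:
    def test_counting(self):
        inc = _inc({"a": {"me1", "me2", "co1"}, "b": {"me1"}})
        classes = SpeciesClassTable({"me1": "ME", "me2": "ME", "co1": "COSMP"})
        counts = class_counts(inc, classes)
        assert counts.loc["a", "ME"] == 2
        assert counts.loc["a", "COSMP"] == 1
        assert counts.loc["a"].sum() == 3

    def test_unclassified_excluded_and_empty_site_dropped(self):
        inc = _inc({"a": {"me1", "u1"}, "b": {"u1"}})
        classes = SpeciesClassTable({"me1": "ME"})
        with pytest.warns(UserWarning, match="b"):
            counts = class_counts(inc, classes)
        assert list(counts.index) == ["a"]

    def test_no_classified_species_is_error(self):
        inc = _inc({"a": {"u1"}, "b": {"u2"}})
        with pytest.raises(ValueError):
            class_counts(inc, SpeciesClassTable({"other": "ME"}))

    def test_synthetic_one_to_one_design(self):
        cfg = MetacommunityConfig(
            n_modules=3, sites_per_module=[3, 3, 3],
            private_pool_sizes=[6, 6, 6], p_in=1.0, p_out=0.0,
            n_cosmo=2, p_cosmo=1.0, seed=0,
        )
        inc, truth, classes = generate(cfg)
        counts = class_counts(inc, classes)
        for site, row in counts.iterrows():
            nonzero = set(row[row > 0].index)
            assert len(nonzero - {"COSMP"}) == 1  # own module class + COSMP


class TestCorrespondenceAnalysis:
    def test_perfect_association_2x2(self):
        t = pd.DataFrame([[10, 0], [0, 10]], index=list("ab"),
                         columns=list("xy"))
        ca = correspondence_analysis(t)
        assert ca.eigenvalues == pytest.approx([1.0])
        assert ca.total_inertia == pytest.approx(1.0)

    def test_outer_product_zero_inertia(self):
        t = pd.DataFrame(np.outer([2, 3, 5], [1, 4, 2]))
        t.index = t.index.astype(str)
        t.columns = t.columns.astype(str)
        ca = correspondence_analysis(t)
        assert ca.total_inertia == pytest.approx(0.0, abs=1e-14)
        assert np.allclose(ca.row_coords.to_numpy(), 0.0)

    def test_inertia_equals_chi2_over_n(self):
        rng = np.random.default_rng(1)
        t = pd.DataFrame(rng.integers(1, 40, (6, 4)),
                         index=[f"s{i}" for i in range(6)],
                         columns=list("abcd"))
        ca = correspondence_analysis(t)
        chi2 = chi2_contingency(t.to_numpy(), correction=False)[0]
        assert ca.total_inertia == pytest.approx(
            chi2 / t.to_numpy().sum(), abs=1e-10
        )

    def test_eigenvalues_non_increasing_and_contribs_sum_to_one(self):
        rng = np.random.default_rng(2)
        t = pd.DataFrame(rng.integers(0, 25, (7, 5)) + 1)
        t.index, t.columns = t.index.astype(str), t.columns.astype(str)
        ca = correspondence_analysis(t)
        assert (np.diff(ca.eigenvalues) <= 1e-12).all()
        assert np.allclose(ca.col_contrib.sum(axis=0), 1.0)
        assert np.allclose(ca.row_contrib.sum(axis=0), 1.0)
        assert ca.pct_inertia.sum() == pytest.approx(100.0)

    def test_negative_or_empty_tables_rejected(self):
        with pytest.raises(ValueError):
            correspondence_analysis(pd.DataFrame([[1, -1], [0, 2]]))
        with pytest.raises(ValueError):
            correspondence_analysis(pd.DataFrame([[0, 0], [0, 0]]))


class TestBetweenGroupCA:
    def test_identical_group_profiles_zero_between(self):
        t = pd.DataFrame([[2, 4], [2, 4], [1, 2], [3, 6]],
                         index=list("abcd"), columns=list("xy"))
        res = between_group_ca(t, {"a": 0, "b": 0, "c": 1, "d": 1})
        assert res.between_inertia == pytest.approx(0.0, abs=1e-14)
        assert res.between_total_ratio == pytest.approx(0.0, abs=1e-14)

    def test_singleton_groups_reduce_to_plain_ca(self):
        rng = np.random.default_rng(3)
        t = pd.DataFrame(rng.integers(1, 30, (5, 4)),
                         index=[f"s{i}" for i in range(5)],
                         columns=list("wxyz"))
        plain = correspondence_analysis(t)
        res = between_group_ca(t, {f"s{i}": i for i in range(5)})
        assert res.eigenvalues == pytest.approx(plain.eigenvalues)
        assert res.between_total_ratio == pytest.approx(1.0)

    def test_site_scores_average_to_group_centroid(self):
        rng = np.random.default_rng(4)
        t = pd.DataFrame(rng.integers(1, 30, (6, 4)),
                         index=[f"s{i}" for i in range(6)],
                         columns=list("wxyz"))
        groups = {"s0": 0, "s1": 0, "s2": 1, "s3": 1, "s4": 2, "s5": 2}
        res = between_group_ca(t, groups)
        masses = t.sum(axis=1).astype(float)
        for label in (0, 1, 2):
            sites = [s for s, g in groups.items() if g == label]
            w = masses[sites] / masses[sites].sum()
            mean = res.site_scores.loc[sites].mul(w, axis=0).sum()
            assert np.allclose(
                mean.to_numpy(), res.group_scores.loc[label].to_numpy()
            )

    def test_between_ratio_in_unit_interval(self):
        rng = np.random.default_rng(5)
        t = pd.DataFrame(rng.integers(0, 20, (8, 5)) + 1)
        t.index, t.columns = t.index.astype(str), t.columns.astype(str)
        groups = {s: i % 3 for i, s in enumerate(t.index)}
        res = between_group_ca(t, groups)
        assert 0.0 <= res.between_total_ratio <= 1.0 + 1e-12

    def test_synthetic_design_separates_modules(self):
        cfg = MetacommunityConfig(
            n_modules=4, sites_per_module=[5] * 4,
            private_pool_sizes=[20] * 4, p_in=0.9, p_out=0.05,
            n_cosmo=5, p_cosmo=0.7, seed=6,
        )
        inc, truth, classes = generate(cfg)
        counts = class_counts(inc, classes)
        res = between_group_ca(counts, {s: truth[s] for s in counts.index})
        # 4 groups x 9 classes -> 3 axes; module classes dominate the axes
        assert len(res.eigenvalues) == 3
        assert res.between_total_ratio > 0.5
        # each axis's top contributor is one of the module-private classes
        private = {classes[sp] for sp in inc.species_ids
                   if not sp.startswith("sp_cosmo")}
        for axis in res.class_contrib.columns:
            assert res.class_contrib[axis].idxmax() in private

    def test_sign_invariant_axis_comparison(self):
        # CA axes are determined up to sign: flipping must not matter
        rng = np.random.default_rng(7)
        t = pd.DataFrame(rng.integers(1, 30, (5, 4)),
                         index=[f"s{i}" for i in range(5)],
                         columns=list("wxyz"))
        res = between_group_ca(t, {f"s{i}": i % 2 for i in range(5)})
        ca = res.ca
        # reconstruct inertia from coordinates regardless of sign
        recon = (ca.row_masses.to_numpy()[:, None]
                 * ca.row_coords.to_numpy() ** 2).sum()
        assert recon == pytest.approx(ca.total_inertia)
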