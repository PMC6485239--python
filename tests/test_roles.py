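import numpy as np
import pytest

from bioregions.incidence import IncidenceMatrix, SpeciesClassTable
from bioregions.modularity import Partition
from bioregions.roles import (
    compute_roles,
    module_summaries,
    shared_species_ledger,
    species_module_map,
)
from bioregions.synth import MetacommunityConfig, generate


def _inc(site_sets: dict[str, set[str]]) -> IncidenceMatrix:
    species = sorted(set().union(*site_sets.values()))
    occ = np.array(
        [[1 if sp in s else 0 for sp in species] for s in site_sets.values()]
    )
    return IncidenceMatrix(list(site_sets), species, occ)


@pytest.fixture
def planted():
    cfg = MetacommunityConfig(
        n_modules=3, sites_per_module=[4, 4, 4],
        private_pool_sizes=[12, 12, 12], p_in=1.0, p_out=0.0,
        n_cosmo=2, p_cosmo=1.0, seed=0,
    )
    inc, truth, classes = generate(cfg)
    part = Partition(truth)
    return inc, part, classes


class TestSpeciesModuleMap:
    def test_exclusive_and_shared_species(self):
        inc = _inc({
            "a": {"x", "shared"}, "b": {"x", "shared"},
            "c": {"y", "shared"}, "d": {"y", "shared"},
        })
        part = Partition({"a": 0, "b": 0, "c": 1, "d": 1})
        smm = species_module_map(inc, part)
        assert smm.exclusivity["x"] == part["a"]
        assert smm.exclusivity["y"] == part["c"]
        assert smm.exclusivity["shared"] is None
        assert smm.spans["shared"] == {part["a"], part["c"]}

    def test_planted_private_exclusive_cosmo_everywhere(self, planted):
        inc, part, _ = planted
        smm = species_module_map(inc, part)
        for sp, mods in smm.spans.items():
            if sp.startswith("sp_cosmo"):
                assert len(mods) == 3
            else:
                assert len(mods) == 1

    def test_species_partition_identity(self, planted):
        # exclusives per module + multi-module species == all species
        inc, part, _ = planted
        smm = species_module_map(inc, part)
        n_exclusive = sum(
            len(smm.exclusives_of(m)) for m in set(part.mapping.values())
        )
        n_multi = sum(1 for mods in smm.spans.values() if len(mods) > 1)
        assert n_exclusive + n_multi == inc.n_species


class TestComputeRoles:
    def test_confined_site_has_zero_participation(self, planted):
        inc, part, _ = planted
        cfg_no_cosmo = MetacommunityConfig(
            n_modules=3, sites_per_module=[4, 4, 4],
            private_pool_sizes=[12, 12, 12], p_in=1.0, p_out=0.0,
            n_cosmo=0, p_cosmo=0.0, seed=0,
        )
        inc0, truth0, _ = generate(cfg_no_cosmo)
        roles = compute_roles(inc0, Partition(truth0))
        assert (roles["r"] == 0).all()
        assert set(roles["role"]) <= {"peripheral", "provincial hub"}

    def test_even_spread_participation(self):
        # every species of the focal site spans all 4 modules: f_M = 1/4 each
        sets = {f"m{k}": {"p0", "p1", "p2", "p3"} for k in range(4)}
        sets["hub"] = {"p0", "p1", "p2", "p3"}
        inc = _inc(sets)
        part = Partition({"m0": 0, "m1": 1, "m2": 2, "m3": 3, "hub": 0})
        roles = compute_roles(inc, part).set_index("site")
        assert roles.loc["hub", "r"] == pytest.approx(0.75)

    def test_role_quadrants(self):
        rows = {
            # module 0: two species-rich sites with exclusives, one poor site
            "rich1": {"e1", "e2", "e3", "e4", "w"},
            "rich2": {"e1", "e2", "e3", "w"},
            "poor": {"w"},
            # module 1
            "other1": {"f1", "f2", "w"},
            "other2": {"f1", "f2"},
        }
        inc = _inc(rows)
        part = Partition({"rich1": 0, "rich2": 0, "poor": 0,
                          "other1": 1, "other2": 1})
        roles = compute_roles(inc, part, cuts=(0.5, 0.3)).set_index("site")
        assert roles.loc["rich1", "role"] in ("provincial hub", "connector hub")
        assert roles.loc["poor", "role"] in ("peripheral", "non-hub connector")

    def test_single_site_module_flagged(self):
        inc = _inc({"a": {"x"}, "b": {"y", "z"}, "c": {"y"}})
        part = Partition({"a": 0, "b": 1, "c": 1})
        roles = compute_roles(inc, part).set_index("site")
        assert roles.loc["a", "flag"] == "single-site-module"
        assert roles.loc["a", "l"] == 0.0

    def test_relabeling_invariance(self, planted):
        inc, part, _ = planted
        roles_a = compute_roles(inc, part)
        shuffled = Partition(
            {s: (m + 1) % 3 for s, m in part.mapping.items()}
        )
        roles_b = compute_roles(inc, shuffled)
        assert (roles_a["role"] == roles_b["role"]).all()
        assert np.allclose(roles_a["l"], roles_b["l"])
        assert np.allclose(roles_a["r"], roles_b["r"])

    def test_r_in_unit_interval(self, planted):
        inc, part, _ = planted
        roles = compute_roles(inc, part)
        assert ((roles["r"] >= 0) & (roles["r"] < 1)).all()


class TestModuleSummaries:
    def test_block_diagonal_fully_exclusive(self):
        cfg = MetacommunityConfig(
            n_modules=2, sites_per_module=[3, 3],
            private_pool_sizes=[8, 8], p_in=1.0, p_out=0.0,
            n_cosmo=0, p_cosmo=0.0, seed=1,
        )
        inc, truth, classes = generate(cfg)
        part = Partition(truth)
        summary = module_summaries(inc, part, classes=classes)
        assert (summary["pct_exclusive"] == 100.0).all()
        assert (summary["L"] == 3).all()
        assert (summary["s"] == 8).all()
        ledger = shared_species_ledger(species_module_map(inc, part))
        assert (ledger["n_modules"] == 1).all()

    def test_one_cosmopolitan_shared_by_all(self):
        cfg = MetacommunityConfig(
            n_modules=3, sites_per_module=[3, 3, 3],
            private_pool_sizes=[5, 5, 5], p_in=1.0, p_out=0.0,
            n_cosmo=1, p_cosmo=1.0, seed=2,
        )
        inc, truth, _ = generate(cfg)
        smm = species_module_map(inc, Partition(truth))
        ledger = shared_species_ledger(smm)
        allmod = ledger[ledger["n_modules"] == 3]
        assert len(allmod) == 1 and allmod["count"].iloc[0] == 1

    def test_class_percentages_sum_to_100(self, planted):
        inc, part, classes = planted
        summary = module_summaries(inc, part, classes=classes)
        pct_cols = [c for c in summary.columns if c.startswith("pct_")
                    and c != "pct_exclusive"]
        assert np.allclose(summary[pct_cols].sum(axis=1), 100.0)

    def test_unclassified_bucket(self):
        inc = _inc({"a": {"x", "u"}, "b": {"x"}, "c": {"y"}})
        part = Partition({"a": 0, "b": 0, "c": 1})
        classes = SpeciesClassTable({"x": "ME", "y": "COSMP"})
        summary = module_summaries(inc, part, classes=classes).set_index("module")
        m_a = part["a"]
        assert summary.loc[m_a, "pct_unclassified"] == pytest.approx(50.0)
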