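"""Locality roles and module composition summaries.

Once sites are partitioned into biogeographic modules, each locality is
placed in a two-dimensional (l, r) space:

* ``l`` — local topological richness: the z-score, within the site's module,
  of its count of module-exclusive species (species whose whole occurrence
  range lies inside that one module).
* ``r`` — regional topological linkage: a Simpson-type participation index
  ``1 - sum_M f_M^2`` over the modules spanned by the site's species, where
  f_M is the fraction of the site's species-module incidences that fall on
  module M.  r = 0 when every species of the site is confined to the site's
  own module; it approaches 1 when the site's species spread evenly over
  many modules.

Two configurable cut lines (defaults l_cut = 1.0 z-units, r_cut = 0.5) split
the plane into the four classic roles: peripheral (low l, low r), non-hub
connector (low l, high r), provincial hub (high l, low r) and connector hub
(high l, high r).  Hubs read as biogeographic sources, peripherals as sinks.

Module summaries report, per module, the number of localities L, species
count s, the percentage of module-exclusive species, the percentage of
species per biogeographic class, and a disjoint shared-species ledger: every
species is counted once, under the exact set of modules its occurrences
span.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .incidence import BIOGEOGRAPHIC_CLASSES, IncidenceMatrix, SpeciesClassTable
from .modularity import Partition

__all__ = [
    "SpeciesModuleMap",
    "species_module_map",
    "compute_roles",
    "module_summaries",
    "shared_species_ledger",
]

ROLES = ("peripheral", "non-hub connector", "provincial hub", "connector hub")
DEFAULT_L_CUT = 1.0
DEFAULT_R_CUT = 0.5


@dataclass
class SpeciesModuleMap:
    """Species -> set of modules spanned by its occurrence sites."""

    spans: dict[str, frozenset[int]]

    def __post_init__(self) -> None:
        empty = [s for s, mods in self.spans.items() if not mods]
        if empty:
            raise ValueError(f"species with empty module span: {empty}")

    @property
    def exclusivity(self) -> dict[str, int | None]:
        """Module label if the species spans a single module, else None."""
        return {
            s: (next(iter(mods)) if len(mods) == 1 else None)
            for s, mods in self.spans.items()
        }

    def exclusives_of(self, module: int) -> set[str]:
        return {s for s, mods in self.spans.items() if mods == frozenset({module})}


def species_module_map(inc: IncidenceMatrix, part: Partition) -> SpeciesModuleMap:
    """Map each species to the modules of the sites where it occurs."""
    missing = [s for s in inc.site_ids if s not in part.mapping]
    if missing:
        raise ValueError(f"partition does not cover site(s): {missing}")
    site_labels = np.array([part[s] for s in inc.site_ids])
    spans = {}
    for j, sp in enumerate(inc.species_ids):
        present = inc.occ[:, j] == 1
        spans[sp] = frozenset(int(x) for x in site_labels[present])
    return SpeciesModuleMap(spans)


def compute_roles(
    inc: IncidenceMatrix,
    part: Partition,
    smm: SpeciesModuleMap | None = None,
    cuts: tuple[float, float] = (DEFAULT_L_CUT, DEFAULT_R_CUT),
) -> pd.DataFrame:
    """Classify every site into one of the four (l, r) roles.

    Returns a DataFrame with columns site, module, richness, l, r, role and
    a ``flag`` column marking sites whose l is undefined by z-score (single
    site in its module, or zero spread) and was set to 0.
    """
    if smm is None:
        smm = species_module_map(inc, part)
    l_cut, r_cut = cuts
    richness = inc.site_richness()
    if (richness == 0).any():
        bad = richness[richness == 0].index.tolist()
        raise ValueError(f"site(s) with no species: {bad}")

    # exclusive-species count per site w.r.t. its own module
    exclusivity = smm.exclusivity
    excl_count = {}
    sets = inc.species_sets()
    for site in inc.site_ids:
        own = part[site]
        excl_count[site] = sum(1 for sp in sets[site] if exclusivity[sp] == own)

    rows = []
    modules = part.modules()
    for site in inc.site_ids:
        own = part[site]
        peers = [s for s in modules[own] if s in sets]
        counts = np.array([excl_count[s] for s in peers], dtype=float)
        flag = ""
        if len(peers) < 2:
            l_val = 0.0
            flag = "single-site-module"
        else:
            sd = counts.std(ddof=0)
            if sd == 0:
                l_val = 0.0
                flag = "zero-variance-module"
            else:
                l_val = (excl_count[site] - counts.mean()) / sd

        # participation over spanned modules
        span_counts: dict[int, int] = {}
        for sp in sets[site]:
            for mod in smm.spans[sp]:
                span_counts[mod] = span_counts.get(mod, 0) + 1
        total = sum(span_counts.values())
        r_val = 1.0 - sum((c / total) ** 2 for c in span_counts.values())

        if l_val >= l_cut:
            role = "connector hub" if r_val >= r_cut else "provincial hub"
        else:
            role = "non-hub connector" if r_val >= r_cut else "peripheral"
        rows.append(
            {
                "site": site,
                "module": own,
                "richness": int(richness[site]),
                "l": l_val,
                "r": r_val,
                "role": role,
                "flag": flag,
            }
        )
    return pd.DataFrame(rows)


def shared_species_ledger(smm: SpeciesModuleMap) -> pd.DataFrame:
    """Disjoint accounting of species by the exact module set they span."""
    buckets: dict[frozenset[int], list[str]] = {}
    for sp, mods in smm.spans.items():
        buckets.setdefault(mods, []).append(sp)
    rows = [
        {
            "module_set": "+".join(str(m) for m in sorted(mods)),
            "n_modules": len(mods),
            "count": len(sps),
            "species": ";".join(sorted(sps)),
        }
        for mods, sps in sorted(
            buckets.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))
        )
    ]
    return pd.DataFrame(rows, columns=["module_set", "n_modules", "count", "species"])


def module_summaries(
    inc: IncidenceMatrix,
    part: Partition,
    smm: SpeciesModuleMap | None = None,
    classes: SpeciesClassTable | None = None,
) -> pd.DataFrame:
    """Per-module composition table: L, s, % exclusive, % per class.

    Species without a class entry fall into an ``unclassified`` bucket.
    Percentages are relative to the module's species count s.
    """
    if smm is None:
        smm = species_module_map(inc, part)
    modules = part.modules()
    rows = []
    for label in sorted(modules):
        sites = modules[label]
        in_module = {
            sp for sp, mods in smm.spans.items() if label in mods
        }
        s = len(in_module)
        exclusives = smm.exclusives_of(label)
        row = {
            "module": label,
            "L": len(sites),
            "s": s,
            "pct_exclusive": 100.0 * len(exclusives) / s if s else 0.0,
        }
        for cls in BIOGEOGRAPHIC_CLASSES + ("unclassified",):
            if classes is None:
                n_cls = 0 if cls != "unclassified" else s
            else:
                n_cls = sum(
                    1 for sp in in_module
                    if (classes.get(sp) or "unclassified") == cls
                )
            row[f"pct_{cls}"] = 100.0 * n_cls / s if s else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
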