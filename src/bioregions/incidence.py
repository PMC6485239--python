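"""Reading, validation and writing of incidence matrices and species tables.

The analysis substrate is a binary sites × species incidence matrix: rows are
sampling localities (the future network nodes), columns are species, and a cell
is 1 when the species has been recorded at the locality.  Files on disk may be
stored either way round; everything downstream consumes the canonical
sites × species orientation produced here.

Species are optionally annotated with one of nine biogeographic range classes
(WM, EM, ADR, ME, AFR, ATL, NATL, INDP, COSMP).  Source tables sometimes use a
finer Atlantic subdivision (Iberian / French / British coasts, Norwegian /
Arctic); those tokens can be merged into ATL and NATL on read.
"""

from __future__ import annotations

import csv
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The nine biogeographic range classes used throughout the package.
BIOGEOGRAPHIC_CLASSES: tuple[str, ...] = (
    "WM", "EM", "ADR", "ME", "AFR", "ATL", "NATL", "INDP", "COSMP",
)

#: Finer-grained source vocabulary -> nine-class vocabulary (applied when
#: ``merge_subcategories`` is on): Iberian/French/British coasts fold into the
#: Atlantic class, Norwegian/Arctic into the North Atlantic class.
CLASS_SYNONYMS: dict[str, str] = {
    "IB": "ATL",
    "FR": "ATL",
    "BR": "ATL",
    "NORW": "NATL",
    "ARCT": "NATL",
    "ADR": "ADR",
    "AFR": "AFR",
    "IND-P": "INDP",
    "INDP": "INDP",
    "COSM": "COSMP",
    "COSMP": "COSMP",
}

DEFAULT_TRUTHY = ("1", "x", "X", "true", "True")
DEFAULT_FALSY = ("0", "", "false", "False", "NA", "nan")


class IncidenceError(ValueError):
    """Raised on malformed or invalid incidence / class / metadata input."""


@dataclass
class IncidenceMatrix:
    """Binary sites × species occurrence matrix.

    Attributes
    ----------
    site_ids : list of str
        Ordered, unique site (locality) labels; one per matrix row.
    species_ids : list of str
        Ordered, unique species labels; one per matrix column.
    occ : ndarray of shape (n_sites, n_species)
        0/1 incidence, ``occ[i, j] = 1`` iff species *j* was recorded at
        site *i*.
    """

    site_ids: list[str]
    species_ids: list[str]
    occ: np.ndarray

    def __post_init__(self) -> None:
        self.occ = np.asarray(self.occ)
        if self.occ.shape != (len(self.site_ids), len(self.species_ids)):
            raise IncidenceError(
                f"occ shape {self.occ.shape} does not match "
                f"{len(self.site_ids)} sites x {len(self.species_ids)} species"
            )
        if not np.isin(self.occ, (0, 1)).all():
            raise IncidenceError("incidence entries must be 0 or 1")
        self.occ = self.occ.astype(np.int8)
        for name, labels in (("site", self.site_ids), ("species", self.species_ids)):
            if len(set(labels)) != len(labels):
                dupes = sorted({x for x in labels if labels.count(x) > 1})
                raise IncidenceError(f"duplicate {name} labels: {dupes}")
            if any(not isinstance(x, str) or not x for x in labels):
                raise IncidenceError(f"{name} labels must be non-empty strings")

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def n_occurrences(self) -> int:
        return int(self.occ.sum())

    def site_richness(self) -> pd.Series:
        """Species count per site."""
        return pd.Series(self.occ.sum(axis=1), index=self.site_ids, name="richness")

    def species_sets(self) -> dict[str, frozenset[str]]:
        """Map each site to its set of recorded species."""
        sp = np.asarray(self.species_ids, dtype=object)
        return {
            site: frozenset(sp[self.occ[i] == 1])
            for i, site in enumerate(self.site_ids)
        }

    def sites_of_species(self) -> dict[str, frozenset[str]]:
        """Map each species to the set of sites where it occurs."""
        st = np.asarray(self.site_ids, dtype=object)
        return {
            species: frozenset(st[self.occ[:, j] == 1])
            for j, species in enumerate(self.species_ids)
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.occ, index=self.site_ids, columns=self.species_ids)

    def drop_empty(self, policy: str = "drop") -> "IncidenceMatrix":
        """Remove all-zero site rows and species columns.

        policy='drop' removes them with a warning; policy='reject' raises.
        """
        row_empty = self.occ.sum(axis=1) == 0
        col_empty = self.occ.sum(axis=0) == 0
        if not row_empty.any() and not col_empty.any():
            return self
        empties = [s for s, e in zip(self.site_ids, row_empty) if e] + [
            s for s, e in zip(self.species_ids, col_empty) if e
        ]
        if policy == "reject":
            raise IncidenceError(f"empty rows/columns present: {empties}")
        warnings.warn(
            f"dropping {int(row_empty.sum())} empty site(s) and "
            f"{int(col_empty.sum())} empty species: {empties}",
            stacklevel=2,
        )
        return IncidenceMatrix(
            [s for s, e in zip(self.site_ids, row_empty) if not e],
            [s for s, e in zip(self.species_ids, col_empty) if not e],
            self.occ[~row_empty][:, ~col_empty],
        )


@dataclass
class SpeciesClassTable:
    """Species -> biogeographic class assignment (nine-class vocabulary)."""

    classes: dict[str, str]

    def __post_init__(self) -> None:
        bad = {c for c in self.classes.values() if c not in BIOGEOGRAPHIC_CLASSES}
        if bad:
            raise IncidenceError(
                f"unknown biogeographic class token(s): {sorted(bad)}; "
                f"expected one of {BIOGEOGRAPHIC_CLASSES}"
            )

    def __getitem__(self, species: str) -> str:
        return self.classes[species]

    def __len__(self) -> int:
        return len(self.classes)

    def get(self, species: str, default: str | None = None) -> str | None:
        return self.classes.get(species, default)

    def coverage_report(self, inc: IncidenceMatrix) -> list[str]:
        """Species present in the incidence matrix but lacking a class entry."""
        return [s for s in inc.species_ids if s not in self.classes]


@dataclass
class SiteMetadata:
    """Optional per-site label and coordinates."""

    records: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, rec in self.records.items():
            lon, lat = rec.get("lon"), rec.get("lat")
            if lon is not None and not -180 <= lon <= 180:
                raise IncidenceError(f"site {sid}: longitude {lon} out of range")
            if lat is not None and not -90 <= lat <= 90:
                raise IncidenceError(f"site {sid}: latitude {lat} out of range")


def _read_table(path: str | Path, delimiter: str | None) -> pd.DataFrame:
    # sep=None lets pandas sniff comma/semicolon/tab; callers may override.
    return pd.read_csv(
        path,
        sep=delimiter,
        engine="python" if delimiter is None else "c",
        index_col=0,
        dtype=str,
        keep_default_na=False,
        encoding="utf-8",
    )


def read_incidence(
    path: str | Path,
    orientation: str = "sites-rows",
    *,
    delimiter: str | None = None,
    truthy: Iterable[str] = DEFAULT_TRUTHY,
    falsy: Iterable[str] = DEFAULT_FALSY,
    empty_policy: str = "drop",
) -> IncidenceMatrix:
    """Read an incidence matrix from delimited text.

    Parameters
    ----------
    path
        Delimited text file with a header row and a leading label column.
    orientation
        ``'sites-rows'`` if file rows are sites, ``'species-rows'`` if file
        rows are species (the layout used by most published supplementary
        tables).  The returned matrix is always sites × species.
    delimiter
        Explicit field delimiter; autodetected among comma/semicolon/tab
        when None.
    truthy, falsy
        Cell tokens interpreted as presence / absence.
    empty_policy
        'drop' (default) removes all-zero rows/columns with a warning;
        'reject' raises on them.
    """
    if orientation not in ("sites-rows", "species-rows"):
        raise IncidenceError(f"unknown orientation {orientation!r}")
    df = _read_table(path, delimiter)
    truthy, falsy = set(truthy), set(falsy)

    occ = np.empty(df.shape, dtype=np.int8)
    values = df.to_numpy(dtype=object)
    for (i, j), cell in np.ndenumerate(values):
        token = str(cell).strip()
        if token in truthy:
            occ[i, j] = 1
        elif token in falsy:
            occ[i, j] = 0
        else:
            raise IncidenceError(
                f"non-binary cell {cell!r} at row {df.index[i]!r}, "
                f"column {df.columns[j]!r}"
            )

    rows = [str(x).strip() for x in df.index]
    cols = [str(x).strip() for x in df.columns]
    if orientation == "species-rows":
        occ = occ.T
        rows, cols = cols, rows
    inc = IncidenceMatrix(rows, cols, occ)
    return inc.drop_empty(policy=empty_policy)


def read_species_classes(
    path: str | Path,
    *,
    delimiter: str | None = None,
    merge_subcategories: bool = True,
) -> SpeciesClassTable:
    """Read a two-column (species, class) table.

    With ``merge_subcategories`` the finer Atlantic source tokens are folded
    into the nine-class vocabulary (Ib/Fr/Br -> ATL, Norw/Arct -> NATL,
    Cosm -> COSMP, Ind-P -> INDP); unknown tokens raise.
    """
    df = _read_table(path, delimiter)
    if df.shape[1] < 1:
        raise IncidenceError("species class table needs two columns")
    raw = df.iloc[:, 0].astype(str).str.strip()
    out: dict[str, str] = {}
    for species, token in raw.items():
        cls = token
        if merge_subcategories:
            cls = CLASS_SYNONYMS.get(token.upper(), token)
        if cls not in BIOGEOGRAPHIC_CLASSES:
            raise IncidenceError(
                f"unknown biogeographic class {token!r} for species {species!r}"
            )
        out[str(species).strip()] = cls
    return SpeciesClassTable(out)


def read_site_metadata(path: str | Path, *, delimiter: str | None = None) -> SiteMetadata:
    df = _read_table(path, delimiter)
    records = {}
    for sid, row in df.iterrows():
        rec = {"label": str(row.iloc[0]) if len(row) else str(sid)}
        for key in ("lon", "lat"):
            if key in df.columns:
                rec[key] = float(row[key])
        if "region" in df.columns:
            rec["region"] = str(row["region"])
        records[str(sid)] = rec
    return SiteMetadata(records)


# --------------------------------------------------------------------------
# writers

def write_incidence(inc: IncidenceMatrix, path: str | Path) -> None:
    inc.to_frame().to_csv(path, sep="\t")


def write_species_classes(table: SpeciesClassTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["species", "class"])
        for species, cls in table.classes.items():
            w.writerow([species, cls])


def write_site_metadata(meta: SiteMetadata, path: str | Path) -> None:
    rows = []
    for sid, rec in meta.records.items():
        rows.append({"site_id": sid, **rec})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_outputs(results: Mapping[str, object], out_dir: str | Path) -> dict[str, int]:
    """Write a dictionary of pipeline products to ``out_dir``.

    Keys select the writer: DataFrames become TSV, dicts become JSON,
    IncidenceMatrix / SpeciesClassTable use their dedicated formats.
    Returns a manifest of ``{filename: data row count}``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, int] = {}
    for name, obj in results.items():
        if isinstance(obj, IncidenceMatrix):
            fname = f"{name}.tsv"
            write_incidence(obj, out_dir / fname)
            manifest[fname] = obj.n_sites
        elif isinstance(obj, SpeciesClassTable):
            fname = f"{name}.tsv"
            write_species_classes(obj, out_dir / fname)
            manifest[fname] = len(obj)
        elif isinstance(obj, SiteMetadata):
            fname = f"{name}.tsv"
            write_site_metadata(obj, out_dir / fname)
            manifest[fname] = len(obj.records)
        elif isinstance(obj, pd.DataFrame):
            fname = f"{name}.tsv"
            obj.to_csv(out_dir / fname, sep="\t", index=False)
            manifest[fname] = len(obj)
        elif isinstance(obj, (dict, list)):
            fname = f"{name}.json"
            with open(out_dir / fname, "w", encoding="utf-8") as fh:
                json.dump(obj, fh, indent=2, default=_json_default)
            manifest[fname] = len(obj)
        else:
            raise TypeError(f"no writer for {name!r} of type {type(obj).__name__}")
    logger.info("wrote %d file(s) to %s", len(manifest), out_dir)
    return manifest


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
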