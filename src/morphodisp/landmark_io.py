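"""Landmark coordinate I/O, specimen metadata, and landmark schemes.

Supported coordinate formats
----------------------------
``csv_long``
    One row per landmark: ``specimen_id, species, landmark_id, x, y, z``
    with 1-based landmark ids.
``csv_wide``
    One row per specimen: ``specimen_id, species, x1, y1, z1, x2, ...``.
``tps3d``
    A 3D dialect of the TPS keyword layout: each specimen block opens with
    ``LM3=<k>``, followed by k lines of three whitespace-separated reals,
    then ``SPECIES=`` and ``ID=`` lines.

Metadata is a CSV with required columns ``species`` and ``clade`` and
optional ``order, sex, diet, habitat, activity``; ecological vocabularies
are closed sets and unknown tokens are rejected.

A landmark scheme maps landmark ids to skull-region tags.  The built-in
``"table3"`` scheme covers 32 cranial landmarks spanning the oral region,
the viscerocranium and the neurocranium.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    DatasetError,
    DegenerateRegionError,
    MetadataConflictError,
    ParseError,
    SchemeError,
    VocabularyError,
)

__all__ = [
    "LandmarkConfiguration",
    "TaxonMetadata",
    "LandmarkScheme",
    "LandmarkDataset",
    "CLADES",
    "SEXES",
    "DIETS",
    "HABITATS",
    "ACTIVITIES",
    "REGION_TAGS",
    "REGION_QUERIES",
    "load_scheme",
    "region_subset_ids",
    "read_landmark_table",
    "write_landmark_table",
    "read_metadata",
    "write_metadata",
    "read_scheme",
    "write_scheme",
    "subset_dataset",
    "filter_by_group",
]

# Closed vocabularies for metadata fields.
CLADES = frozenset({"marsupial", "placental", "fossil_metatherian"})
SEXES = frozenset({"male", "female", "unknown"})
DIETS = frozenset({"folivore", "frugivore", "carnivore_insectivore", "omnivore", "none"})
HABITATS = frozenset({"arboreal", "terrestrial", "fossorial", "none"})
ACTIVITIES = frozenset({"nocturnal_crepuscular", "diurnal", "cathemeral", "none"})

# Per-landmark region tags.
REGION_TAGS = ("oral", "viscerocranium_non_oral", "viscerocranium_both", "neurocranium")

# Queryable region subsets (see region_subset_ids for the tag algebra).
REGION_QUERIES = (
    "whole_skull",
    "neurocranium",
    "viscerocranium",
    "viscerocranium_non_oral",
    "oral",
)

_VOCABS = {
    "clade": CLADES,
    "sex": SEXES,
    "diet": DIETS,
    "habitat": HABITATS,
    "activity": ACTIVITIES,
}


@dataclass(frozen=True)
class LandmarkConfiguration:
    """One specimen's landmark coordinates.

    Parameters
    ----------
    specimen_id : str
        Unique specimen identifier.
    species : str
        Species the specimen belongs to.
    coords : (k, 3) ndarray
        Landmark coordinates in a shared arbitrary length unit.
    """

    specimen_id: str
    species: str
    coords: np.ndarray

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise DatasetError(
                f"specimen {self.specimen_id!r}: coords must be (k, 3), got {coords.shape}"
            )
        if not np.all(np.isfinite(coords)):
            raise DatasetError(f"specimen {self.specimen_id!r}: non-finite coordinates")
        object.__setattr__(self, "coords", coords)

    @property
    def k(self) -> int:
        """Landmark count."""
        return self.coords.shape[0]


@dataclass(frozen=True)
class TaxonMetadata:
    """Species-level classification and ecology labels."""

    species: str
    clade: str
    order: str = "unknown"
    sex: str = "unknown"
    diet: str = "none"
    habitat: str = "none"
    activity: str = "none"

    def __post_init__(self):
        for fname in ("clade", "sex", "diet", "habitat", "activity"):
            value = getattr(self, fname)
            if value not in _VOCABS[fname]:
                raise VocabularyError(
                    f"species {self.species!r}: unknown {fname} token {value!r} "
                    f"(allowed: {sorted(_VOCABS[fname])})"
                )


@dataclass(frozen=True)
class LandmarkScheme:
    """Named landmark numbering with skull-region assignments.

    ``regions`` maps each landmark id to exactly one tag in
    :data:`REGION_TAGS`.  ``variants`` holds named landmark-id subsets
    (e.g. reduced landmark sets optimizing taxon coverage).
    """

    name: str
    landmark_ids: tuple[int, ...]
    regions: Mapping[int, str]
    landmark_names: Mapping[int, str] = field(default_factory=dict)
    variants: Mapping[str, tuple[int, ...]] = field(default_factory=dict)

    def __post_init__(self):
        for lid in self.landmark_ids:
            tag = self.regions.get(lid)
            if tag is None:
                raise SchemeError(f"scheme {self.name!r}: landmark {lid} lacks a region tag")
            if tag not in REGION_TAGS:
                raise SchemeError(
                    f"scheme {self.name!r}: landmark {lid} has unknown region {tag!r}"
                )
        id_set = set(self.landmark_ids)
        for vname, vids in self.variants.items():
            if not set(vids) <= id_set:
                raise SchemeError(
                    f"scheme {self.name!r}: variant {vname!r} is not a subset of the scheme ids"
                )

    @property
    def k(self) -> int:
        return len(self.landmark_ids)

    def ids_with_tag(self, tag: str) -> tuple[int, ...]:
        """Landmark ids carrying exactly the given region tag, in scheme order."""
        return tuple(lid for lid in self.landmark_ids if self.regions[lid] == tag)


@dataclass(frozen=True)
class LandmarkDataset:
    """A scheme, a list of specimen configurations, and species metadata."""

    scheme: LandmarkScheme
    configurations: tuple[LandmarkConfiguration, ...]
    metadata: Mapping[str, TaxonMetadata] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "configurations", tuple(self.configurations))
        k = self.scheme.k
        for cfg in self.configurations:
            if cfg.k != k:
                raise DatasetError(
                    f"specimen {cfg.specimen_id!r} has {cfg.k} landmarks, "
                    f"scheme {self.scheme.name!r} defines {k}"
                )
        if self.metadata:
            for cfg in self.configurations:
                if cfg.species not in self.metadata:
                    raise DatasetError(
                        f"specimen {cfg.specimen_id!r}: species {cfg.species!r} "
                        "has no metadata record"
                    )

    @property
    def n(self) -> int:
        return len(self.configurations)

    def coords_array(self) -> np.ndarray:
        """Stacked (n, k, 3) coordinate array in configuration order."""
        return np.stack([c.coords for c in self.configurations])

    def specimen_ids(self) -> list[str]:
        return [c.specimen_id for c in self.configurations]

    def with_metadata(self, metadata: Mapping[str, TaxonMetadata]) -> "LandmarkDataset":
        return LandmarkDataset(self.scheme, self.configurations, dict(metadata))


# ---------------------------------------------------------------------------
# Built-in 32-landmark cranial scheme
# ---------------------------------------------------------------------------

def _bilateral(start: int, stem: str) -> list[tuple[int, str]]:
    return [(start, f"{stem}_left"), (start + 1, f"{stem}_right")]


_TABLE3_ROWS: list[tuple[int, str, str]] = (
    [
        (1, "premaxilla_incisor_midline", "oral"),
        (2, "internasal_suture_anterior", "viscerocranium_non_oral"),
        (3, "nasal_frontal_midline", "viscerocranium_non_oral"),
        (4, "frontal_parietal_midline", "neurocranium"),
        (5, "vault_posterior_midpoint", "neurocranium"),
    ]
    + [(i, n, "viscerocranium_both") for i, n in _bilateral(6, "nasal_aperture")]
    + [(i, n, "oral") for i, n in _bilateral(8, "premaxilla_maxilla_alveolar")]
    + [(i, n, "viscerocranium_both") for i, n in _bilateral(10, "nasal_frontal_maxilla")]
    + [(i, n, "viscerocranium_both") for i, n in _bilateral(12, "maxilla_lacrimal_medial")]
    + [(i, n, "viscerocranium_both") for i, n in _bilateral(14, "maxilla_lacrimal_lateral")]
    + [(i, n, "viscerocranium_non_oral") for i, n in _bilateral(16, "jugal_squamosal_dorsal")]
    + [(i, n, "viscerocranium_non_oral") for i, n in _bilateral(18, "jugal_squamosal_ventral")]
    + [(i, n, "neurocranium") for i, n in _bilateral(20, "occipital_condyle_dorsal")]
    + [(i, n, "neurocranium") for i, n in _bilateral(22, "frontal_parietal_ventral")]
    + [(24, "interpalatine_suture_posterior", "oral")]
    + [(i, n, "viscerocranium_non_oral") for i, n in _bilateral(25, "jugal_maxilla_ventral")]
    + [(i, n, "oral") for i, n in _bilateral(27, "maxilla_palatine_posterior")]
    + [(i, n, "oral") for i, n in _bilateral(29, "molar_row_posterior")]
    + [(i, n, "oral") for i, n in _bilateral(31, "molar_row_anterior")]
)


def _table3_scheme() -> LandmarkScheme:
    rows = sorted(_TABLE3_ROWS)
    ids = tuple(r[0] for r in rows)
    return LandmarkScheme(
        name="table3",
        landmark_ids=ids,
        regions={r[0]: r[2] for r in rows},
        landmark_names={r[0]: r[1] for r in rows},
        variants={"maximum_landmarks": ids},
    )


def load_scheme(name_or_path: str | Path) -> LandmarkScheme:
    """Return a built-in scheme by name, or read a scheme file.

    ``"table3"`` names the built-in 32-landmark cranial scheme (10 oral,
    8 both-oral-and-non-oral viscerocranial, 8 non-oral viscerocranial,
    6 neurocranial landmarks).  Any other argument is treated as a path to
    a scheme CSV (columns ``landmark_id, name, region``).
    """
    if str(name_or_path) == "table3":
        return _table3_scheme()
    return read_scheme(name_or_path)


def region_subset_ids(scheme: LandmarkScheme, region_query: str) -> tuple[int, ...]:
    """Ordered landmark ids for a skull-region query.

    Landmarks tagged as belonging to both the oral and non-oral
    viscerocranium are included in every viscerocranial query::

        whole_skull              -> all ids
        neurocranium             -> neurocranium tag
        viscerocranium           -> oral + both + non-oral tags
        viscerocranium_non_oral  -> non-oral + both tags
        oral                     -> oral + both tags
    """
    if region_query not in REGION_QUERIES:
        raise ValueError(
            f"unknown region query {region_query!r} (allowed: {REGION_QUERIES})"
        )
    tag_sets = {
        "whole_skull": set(REGION_TAGS),
        "neurocranium": {"neurocranium"},
        "viscerocranium": {"oral", "viscerocranium_both", "viscerocranium_non_oral"},
        "viscerocranium_non_oral": {"viscerocranium_non_oral", "viscerocranium_both"},
        "oral": {"oral", "viscerocranium_both"},
    }
    wanted = tag_sets[region_query]
    ids = tuple(lid for lid in scheme.landmark_ids if scheme.regions[lid] in wanted)
    if len(ids) < 3:
        raise DegenerateRegionError(
            f"region {region_query!r} selects {len(ids)} landmarks in scheme "
            f"{scheme.name!r}; at least 3 are required"
        )
    return ids


# ---------------------------------------------------------------------------
# Coordinate tables
# ---------------------------------------------------------------------------

LANDMARK_FORMATS = ("csv_long", "csv_wide", "tps3d")


def read_landmark_table(
    path: str | Path, format: str = "csv_long", scheme: LandmarkScheme | None = None
) -> LandmarkDataset:
    """Read a landmark coordinate file into a dataset (without metadata).

    When no ``scheme`` is given, an anonymous scheme is synthesized with
    sequential ids and no region information, so datasets can be read
    before a scheme is chosen.
    """
    path = Path(path)
    if format == "csv_long":
        configs = _read_csv_long(path)
    elif format == "csv_wide":
        configs = _read_csv_wide(path)
    elif format == "tps3d":
        configs = _read_tps3d(path)
    else:
        raise ValueError(f"unknown landmark format {format!r} (allowed: {LANDMARK_FORMATS})")
    if not configs:
        raise DatasetError(f"{path}: no specimens found")
    k0 = configs[0].k
    for cfg in configs[1:]:
        if cfg.k != k0:
            raise DatasetError(
                f"{path}: specimen {cfg.specimen_id!r} has {cfg.k} landmarks "
                f"but specimen {configs[0].specimen_id!r} has {k0}"
            )
    if scheme is None:
        ids = tuple(range(1, k0 + 1))
        scheme = LandmarkScheme(
            name=f"anonymous_{k0}",
            landmark_ids=ids,
            regions={i: "oral" for i in ids},
        )
    return LandmarkDataset(scheme=scheme, configurations=tuple(configs))


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path: Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")


def _read_csv_long(path: Path) -> list[LandmarkConfiguration]:
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ["specimen_id", "species", "landmark_id", "x", "y", "z"], path)
    for col in ("landmark_id", "x", "y", "z"):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ParseError(
                f"{path}: non-numeric value {df[col][row]!r} in column {col!r}",
                line=row + 2,  # header + 1-based
            )
        # python float() round-trips repr() exactly; pandas' parser may not
        df[col] = [float(v) for v in df[col]]
    configs = []
    for spec_id, block in df.groupby("specimen_id", sort=False):
        block = block.sort_values("landmark_id", kind="stable")
        species = block["species"].iloc[0]
        coords = block[["x", "y", "z"]].to_numpy(dtype=float)
        configs.append(LandmarkConfiguration(str(spec_id), str(species), coords))
    return configs


def _read_csv_wide(path: Path) -> list[LandmarkConfiguration]:
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ["specimen_id", "species"], path)
    coord_cols = [c for c in df.columns if c not in ("specimen_id", "species")]
    if len(coord_cols) % 3 != 0:
        raise ParseError(f"{path}: coordinate column count {len(coord_cols)} is not a multiple of 3")
    for col in coord_cols:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ParseError(
                f"{path}: non-numeric value {df[col][row]!r} in column {col!r}",
                line=row + 2,
            )
        df[col] = [float(v) for v in df[col]]
    configs = []
    for _, row in df.iterrows():
        coords = row[coord_cols].to_numpy(dtype=float).reshape(-1, 3)
        configs.append(LandmarkConfiguration(str(row["specimen_id"]), str(row["species"]), coords))
    return configs


def _read_tps3d(path: Path) -> list[LandmarkConfiguration]:
    configs: list[LandmarkConfiguration] = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM3="):
            raise ParseError(f"{path}: expected LM3= block header, got {line!r}", line=i + 1)
        try:
            k = int(line.split("=", 1)[1])
        except ValueError:
            raise ParseError(f"{path}: bad landmark count in {line!r}", line=i + 1) from None
        i += 1
        coords = np.empty((k, 3))
        for j in range(k):
            parts = lines[i].split()
            if len(parts) != 3:
                raise ParseError(
                    f"{path}: expected 3 coordinates, got {len(parts)}", line=i + 1
                )
            try:
                coords[j] = [float(p) for p in parts]
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric coordinate in {lines[i]!r}", line=i + 1
                ) from None
            i += 1
        species = spec_id = None
        while i < len(lines) and "=" in lines[i] and not lines[i].upper().startswith("LM3="):
            key, value = lines[i].split("=", 1)
            key = key.strip().upper()
            if key == "SPECIES":
                species = value.strip()
            elif key == "ID":
                spec_id = value.strip()
            i += 1
        if spec_id is None:
            raise ParseError(f"{path}: specimen block without ID= line", line=i)
        configs.append(LandmarkConfiguration(spec_id, species or spec_id, coords))
    return configs


def write_landmark_table(
    dataset: LandmarkDataset, path: str | Path, format: str = "csv_long"
) -> None:
    """Write dataset coordinates in the named format (full float precision)."""
    path = Path(path)
    if format == "csv_long":
        rows = []
        for cfg in dataset.configurations:
            for lid, (x, y, z) in zip(dataset.scheme.landmark_ids, cfg.coords):
                rows.append((cfg.specimen_id, cfg.species, lid, repr(float(x)), repr(float(y)), repr(float(z))))
        pd.DataFrame(
            rows, columns=["specimen_id", "species", "landmark_id", "x", "y", "z"]
        ).to_csv(path, index=False)
    elif format == "csv_wide":
        k = dataset.scheme.k
        cols = ["specimen_id", "species"] + [
            f"{axis}{i}" for i in range(1, k + 1) for axis in ("x", "y", "z")
        ]
        rows = [
            [cfg.specimen_id, cfg.species] + [repr(float(v)) for v in cfg.coords.ravel()]
            for cfg in dataset.configurations
        ]
        pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
    elif format == "tps3d":
        with open(path, "w") as fh:
            for cfg in dataset.configurations:
                fh.write(f"LM3={cfg.k}\n")
                for x, y, z in cfg.coords:
                    fh.write(f"{float(x)!r} {float(y)!r} {float(z)!r}\n")
                fh.write(f"SPECIES={cfg.species}\n")
                fh.write(f"ID={cfg.specimen_id}\n")
    else:
        raise ValueError(f"unknown landmark format {format!r} (allowed: {LANDMARK_FORMATS})")


# ---------------------------------------------------------------------------
# Metadata
# ---------------------------------------------------------------------------

def read_metadata(path: str | Path) -> dict[str, TaxonMetadata]:
    """Read a species metadata CSV into a species -> record mapping.

    Duplicate rows for one species must agree on every field; conflicting
    duplicates raise :class:`MetadataConflictError`.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str).fillna("")
    _require_columns(df, ["species", "clade"], path)
    records: dict[str, TaxonMetadata] = {}
    for _, row in df.iterrows():
        kwargs = {"species": row["species"], "clade": row["clade"]}
        for fname, default in (
            ("order", "unknown"),
            ("sex", "unknown"),
            ("diet", "none"),
            ("habitat", "none"),
            ("activity", "none"),
        ):
            kwargs[fname] = row[fname] if fname in df.columns and row[fname] else default
        record = TaxonMetadata(**kwargs)
        existing = records.get(record.species)
        if existing is not None and existing != record:
            raise MetadataConflictError(
                f"{path}: conflicting duplicate rows for species {record.species!r}"
            )
        records[record.species] = record
    return records


def write_metadata(metadata: Mapping[str, TaxonMetadata], path: str | Path) -> None:
    cols = ["species", "clade", "order", "sex", "diet", "habitat", "activity"]
    rows = [[getattr(m, c) for c in cols] for m in metadata.values()]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Scheme files
# ---------------------------------------------------------------------------

def read_scheme(path: str | Path) -> LandmarkScheme:
    """Read a scheme CSV (columns ``landmark_id, name, region``)."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ["landmark_id", "region"], path)
    ids, regions, names = [], {}, {}
    for idx, row in df.iterrows():
        try:
            lid = int(row["landmark_id"])
        except ValueError:
            raise ParseError(
                f"{path}: non-integer landmark_id {row['landmark_id']!r}", line=int(idx) + 2
            ) from None
        region = row["region"]
        if not isinstance(region, str) or region not in REGION_TAGS:
            raise SchemeError(
                f"{path}: landmark {lid} has missing or unknown region {region!r}"
            )
        ids.append(lid)
        regions[lid] = region
        if "name" in df.columns and isinstance(row["name"], str):
            names[lid] = row["name"]
    return LandmarkScheme(
        name=path.stem, landmark_ids=tuple(ids), regions=regions, landmark_names=names
    )


def write_scheme(scheme: LandmarkScheme, path: str | Path) -> None:
    rows = [
        (lid, scheme.landmark_names.get(lid, f"landmark_{lid}"), scheme.regions[lid])
        for lid in scheme.landmark_ids
    ]
    pd.DataFrame(rows, columns=["landmark_id", "name", "region"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Subsetting and filtering
# ---------------------------------------------------------------------------

def subset_dataset(dataset: LandmarkDataset, landmark_ids: Iterable[int]) -> LandmarkDataset:
    """Restrict every configuration to the given landmark ids (reordered as given)."""
    landmark_ids = tuple(landmark_ids)
    if len(landmark_ids) < 3:
        raise DegenerateRegionError(
            f"landmark subset of size {len(landmark_ids)} is degenerate (need >= 3)"
        )
    scheme_ids = dataset.scheme.landmark_ids
    unknown = set(landmark_ids) - set(scheme_ids)
    if unknown:
        raise SchemeError(f"landmark ids {sorted(unknown)} are not in scheme {dataset.scheme.name!r}")
    pos = {lid: i for i, lid in enumerate(scheme_ids)}
    idx = np.array([pos[lid] for lid in landmark_ids])
    sub_scheme = LandmarkScheme(
        name=f"{dataset.scheme.name}[{len(landmark_ids)}]",
        landmark_ids=landmark_ids,
        regions={lid: dataset.scheme.regions[lid] for lid in landmark_ids},
        landmark_names={
            lid: dataset.scheme.landmark_names[lid]
            for lid in landmark_ids
            if lid in dataset.scheme.landmark_names
        },
    )
    configs = tuple(
        replace(cfg, coords=cfg.coords[idx]) for cfg in dataset.configurations
    )
    return LandmarkDataset(sub_scheme, configs, dict(dataset.metadata))


_FILTER_FIELDS = ("species", "clade", "order", "sex", "diet", "habitat", "activity")


def filter_by_group(dataset: LandmarkDataset, field_name: str, value) -> LandmarkDataset:
    """Keep only specimens whose species metadata matches ``value``.

    ``value`` may be a single token or a set of tokens (union semantics).
    An empty result is allowed but warned about.
    """
    if field_name not in _FILTER_FIELDS:
        raise ValueError(f"unknown metadata field {field_name!r} (allowed: {_FILTER_FIELDS})")
    if not dataset.metadata:
        raise DatasetError("dataset has no metadata to filter on")
    allowed = {value} if isinstance(value, str) else set(value)
    configs = tuple(
        cfg
        for cfg in dataset.configurations
        if getattr(dataset.metadata[cfg.species], field_name) in allowed
    )
    if not configs:
        warnings.warn(
            f"filter {field_name}={value!r} matched no specimens", stacklevel=2
        )
    return LandmarkDataset(dataset.scheme, configs, dict(dataset.metadata))
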