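"""Sporocarp association records: reading, validation, taxonomic filtering and
aggregation into per-region bipartite plant-genus x fungal-taxon count matrices.

The raw unit of evidence is a single sporocarp (fruiting-body) collection with a
putative host plant. National fungal-record databases hold such observations with
mixed taxonomic resolution: plant hosts often identified only to genus, fungi to
genus or species. The operations here encode the curation rules needed before any
diversity or network statistic is meaningful:

* keep only plant genera known to form ectomycorrhizas (whitelist),
* drop fungi curated as non-ectomycorrhizal (a small fixed exclusion list plus a
  genus-level status table),
* resolve the Nothofagaceae split (records of the old broad genus *Nothofagus*
  are re-assigned to *Lophozonia* / *Fuscospora* by species epithet and dropped
  when no species was recorded),
* aggregate to a count matrix at the plant-genus level, keeping genus-only fungal
  identifications as their own taxa unless a sensitivity flag excludes them,
* drop plant genera with fewer than ``min_n`` collections (default 8).

All label orderings are canonical (lexicographic) so repeated runs are
byte-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptySelectionError,
    FormatError,
    MissingLookupError,
    ValidationError,
)

logger = logging.getLogger(__name__)

MANDATORY_COLUMNS = ("region", "plant_genus", "fungal_name", "fungal_rank")
OPTIONAL_COLUMNS = ("plant_species", "source_id")
VALID_RANKS = frozenset({"genus", "species"})

#: Fungal genera curated as non-ectomycorrhizal despite appearing in EcM
#: checklists; always excluded from analysis.
CURATED_NON_ECM_GENERA = frozenset(
    {
        "Chalciporus",
        "Chloridium",
        "Gyromitra",
        "Lachnum",
        "Leptodontidium",
        "Leucopaxillus",
        "Paurocotylis",
        "Phialocephala",
    }
)

#: Species epithets that decide the genus of ex-*Nothofagus* records.
NOTHOFAGUS_SPLIT: Mapping[str, str] = {
    "menziesii": "Lophozonia",
    "solandri": "Fuscospora",
    "fusca": "Fuscospora",
    "truncata": "Fuscospora",
    # Alien South American species stay in Nothofagus sensu stricto.
    "antarctica": "Nothofagus",
    "nitida": "Nothofagus",
}

GENUS_ONLY_SUFFIX = " (genus-level)"


@dataclass(frozen=True)
class SporocarpRecord:
    """One fungal collection and its putative host plant."""

    region: str
    plant_genus: str
    fungal_name: str
    fungal_rank: str
    plant_species: Optional[str] = None
    source_id: Optional[str] = None

    def __post_init__(self):
        for attr in ("region", "plant_genus", "fungal_name"):
            if not str(getattr(self, attr)).strip():
                raise ValidationError(f"{attr} must be non-empty")
        if self.fungal_rank not in VALID_RANKS:
            raise ValidationError(
                f"fungal_rank must be one of {sorted(VALID_RANKS)}, "
                f"got {self.fungal_rank!r}"
            )
        if self.fungal_rank == "species" and len(self.fungal_name.split()) < 2:
            raise ValidationError(
                f"species-rank fungal_name needs a specific epithet: "
                f"{self.fungal_name!r}"
            )

    @property
    def fungal_genus(self) -> str:
        """Genus for lookups: first whitespace-delimited token of the name."""
        return self.fungal_name.split()[0]

    @property
    def fungal_key(self) -> str:
        """Column label in the interaction matrix.

        Species-level identifications use the full name; genus-only
        identifications are kept as their own taxon, flagged so they can be
        excluded in the sensitivity analysis.
        """
        if self.fungal_rank == "species":
            return self.fungal_name
        return self.fungal_name + GENUS_ONLY_SUFFIX


@dataclass(frozen=True)
class RecordSet:
    """Ordered, immutable collection of sporocarp records."""

    records: tuple[SporocarpRecord, ...]
    provenance: str = ""

    def __post_init__(self):
        object.__setattr__(self, "records", tuple(self.records))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SporocarpRecord]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def regions(self) -> list[str]:
        return sorted({r.region for r in self.records})

    def for_region(self, region: str) -> "RecordSet":
        """Exact string match on the region label."""
        return RecordSet(
            tuple(r for r in self.records if r.region == region),
            provenance=f"{self.provenance} | region={region}",
        )

    def to_dataframe(self) -> pd.DataFrame:
        cols = MANDATORY_COLUMNS + OPTIONAL_COLUMNS
        return pd.DataFrame(
            [
                {c: ("" if getattr(r, c) is None else getattr(r, c)) for c in cols}
                for r in self.records
            ],
            columns=list(cols),
        )


@dataclass(frozen=True)
class StatusTable:
    """Curated lookup tables controlling record filtering.

    ``plant_status`` maps region -> plant genus -> {"native", "alien"};
    ``ecm_plant_whitelist`` lists plant genera known to be ectomycorrhizal;
    ``fungal_ecm_status`` maps fungal genus -> {"ecm", "non-ecm"};
    ``non_ecm_exclusions`` are curated non-EcM genera (merged into the status
    map so the subset invariant holds by construction).
    """

    plant_status: Mapping[str, Mapping[str, str]]
    ecm_plant_whitelist: frozenset
    fungal_ecm_status: Mapping[str, str]
    non_ecm_exclusions: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        merged = dict(self.fungal_ecm_status)
        for g in self.non_ecm_exclusions:
            if merged.get(g, "non-ecm") != "non-ecm":
                raise ValidationError(
                    f"excluded genus {g!r} is classified {merged[g]!r}"
                )
            merged[g] = "non-ecm"
        object.__setattr__(self, "fungal_ecm_status", merged)
        object.__setattr__(
            self, "ecm_plant_whitelist", frozenset(self.ecm_plant_whitelist)
        )
        object.__setattr__(
            self, "non_ecm_exclusions", frozenset(self.non_ecm_exclusions)
        )
        for region, statuses in self.plant_status.items():
            for genus, status in statuses.items():
                if status not in ("native", "alien"):
                    raise ValidationError(
                        f"plant status for {genus!r} in {region!r} must be "
                        f"'native' or 'alien', got {status!r}"
                    )

    def status_for(self, region: str, genus: str) -> str:
        try:
            return self.plant_status[region][genus]
        except KeyError:
            raise MissingLookupError("plant status", [f"{region}:{genus}"])


def _separator_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_records(path, dialect: Optional[str] = None) -> RecordSet:
    """Read a records CSV/TSV into a :class:`RecordSet`.

    ``dialect`` may force the field separator ("," or "\\t"); by default it is
    inferred from the file extension.
    """
    path = Path(path)
    sep = dialect or _separator_for(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing mandatory column(s): {', '.join(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        row = row._asdict()
        if not str(row["fungal_name"]).strip():
            raise ValidationError(f"{path.name} row {i}: empty fungal_name")
        try:
            records.append(
                SporocarpRecord(
                    region=row["region"].strip(),
                    plant_genus=row["plant_genus"].strip(),
                    fungal_name=" ".join(row["fungal_name"].split()),
                    fungal_rank=row["fungal_rank"].strip(),
                    plant_species=(row.get("plant_species", "").strip() or None),
                    source_id=(row.get("source_id", "").strip() or None),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path.name} row {i}: {exc}") from exc
    return RecordSet(tuple(records), provenance=str(path))


def write_records(rs: RecordSet, path) -> None:
    """Write a RecordSet back to CSV/TSV (inverse of :func:`read_records`)."""
    path = Path(path)
    rs.to_dataframe().to_csv(path, sep=_separator_for(path), index=False)


def load_status_table(
    plant_status_path, ecm_plants_path, fungal_status_path
) -> StatusTable:
    """Assemble a :class:`StatusTable` from the three lookup CSVs.

    The curated non-EcM exclusion list is always applied on top of the
    user-supplied fungal status table.
    """
    ps = pd.read_csv(plant_status_path, dtype=str, keep_default_na=False)
    ep = pd.read_csv(ecm_plants_path, dtype=str, keep_default_na=False)
    fs = pd.read_csv(fungal_status_path, dtype=str, keep_default_na=False)
    for df, cols, name in (
        (ps, ("region", "plant_genus", "status"), "plant_status"),
        (ep, ("plant_genus",), "ecm_plants"),
        (fs, ("fungal_genus", "status"), "fungal_status"),
    ):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise FormatError(f"{name}: missing column(s): {', '.join(missing)}")
    plant_status: dict[str, dict[str, str]] = {}
    for _, row in ps.iterrows():
        region = plant_status.setdefault(row["region"], {})
        prev = region.get(row["plant_genus"])
        if prev is not None and prev != row["status"]:
            raise ValidationError(
                f"conflicting status for {row['plant_genus']} in {row['region']}"
            )
        region[row["plant_genus"]] = row["status"]
    fungal = dict(zip(fs["fungal_genus"], fs["status"]))
    return StatusTable(
        plant_status=plant_status,
        ecm_plant_whitelist=frozenset(ep["plant_genus"]),
        fungal_ecm_status=fungal,
        non_ecm_exclusions=CURATED_NON_ECM_GENERA,
    )


def filter_ecm_plants(rs: RecordSet, table: StatusTable) -> RecordSet:
    """Keep only records whose host plant genus is on the EcM whitelist."""
    if not table.ecm_plant_whitelist:
        raise ValidationError("ecm_plant_whitelist must be non-empty")
    kept = tuple(r for r in rs if r.plant_genus in table.ecm_plant_whitelist)
    logger.info("filter_ecm_plants: %d -> %d records", len(rs), len(kept))
    return RecordSet(kept, provenance=rs.provenance)


def filter_ecm_fungi(rs: RecordSet, table: StatusTable, strict: bool = False) -> RecordSet:
    """Drop records of non-ectomycorrhizal fungal genera.

    Genera absent from the status table are dropped with a warning by default;
    ``strict=True`` raises :class:`MissingLookupError` listing them instead.
    """
    status = table.fungal_ecm_status
    unknown = sorted({r.fungal_genus for r in rs if r.fungal_genus not in status})
    if unknown:
        if strict:
            raise MissingLookupError("fungal EcM status", unknown)
        logger.warning(
            "filter_ecm_fungi: dropping %d genera with unknown EcM status: %s",
            len(unknown),
            ", ".join(unknown),
        )
    kept = tuple(r for r in rs if status.get(r.fungal_genus) == "ecm")
    logger.info("filter_ecm_fungi: %d -> %d records", len(rs), len(kept))
    return RecordSet(kept, provenance=rs.provenance)


def resolve_nothofagaceae(rs: RecordSet) -> RecordSet:
    """Re-assign broad-sense *Nothofagus* records to their modern genera.

    Records with a recorded species epithet are mapped through
    :data:`NOTHOFAGUS_SPLIT`; records with no species, or an unrecognized
    epithet, are dropped (with a warning for the latter). Other genera pass
    through untouched.
    """
    out = []
    dropped_no_species = 0
    for r in rs:
        if r.plant_genus != "Nothofagus":
            out.append(r)
            continue
        if r.plant_species is None:
            dropped_no_species += 1
            continue
        epithet = r.plant_species.split()[-1].lower()
        target = NOTHOFAGUS_SPLIT.get(epithet)
        if target is None:
            logger.warning(
                "resolve_nothofagaceae: dropping Nothofagus with unrecognized "
                "species %r",
                r.plant_species,
            )
            continue
        out.append(replace(r, plant_genus=target))
    if dropped_no_species:
        logger.info(
            "resolve_nothofagaceae: dropped %d Nothofagus records without species",
            dropped_no_species,
        )
    return RecordSet(tuple(out), provenance=rs.provenance)


@dataclass(frozen=True)
class InteractionMatrix:
    """Plant-genus x fungal-taxon observation counts for one region."""

    counts: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    region: str
    row_status: Mapping[str, str]

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
            raise ValidationError("counts must be non-negative integers")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "row_labels", tuple(self.row_labels))
        object.__setattr__(self, "col_labels", tuple(self.col_labels))
        if len(set(self.row_labels)) != len(self.row_labels):
            raise ValidationError("duplicate row labels")
        if len(set(self.col_labels)) != len(self.col_labels):
            raise ValidationError("duplicate column labels")
        if counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValidationError("counts shape does not match labels")
        missing = [g for g in self.row_labels if g not in self.row_status]
        if missing:
            raise ValidationError(f"row_status missing genera: {missing}")

    @property
    def shape(self):
        return self.counts.shape

    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def col_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def total(self) -> int:
        return int(self.counts.sum())

    def status_array(self) -> np.ndarray:
        return np.array([self.row_status[g] for g in self.row_labels])

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=list(self.col_labels))
        df.insert(0, "plant_genus", list(self.row_labels))
        return df

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def read_matrix_csv(
    path, region: str = "", row_status: Optional[Mapping[str, str]] = None
) -> InteractionMatrix:
    """Read a wide interaction-matrix CSV (row label column ``plant_genus``)."""
    df = pd.read_csv(path)
    if "plant_genus" not in df.columns:
        raise FormatError("matrix CSV must have a 'plant_genus' column")
    genera = [str(g) for g in df["plant_genus"]]
    counts = df.drop(columns="plant_genus").to_numpy()
    if not np.issubdtype(counts.dtype, np.integer):
        rounded = np.rint(counts)
        if not np.allclose(counts, rounded):
            raise FormatError("matrix CSV contains non-integer counts")
        counts = rounded.astype(np.int64)
    status = dict(row_status) if row_status else {g: "unknown" for g in genera}
    return InteractionMatrix(
        counts=counts.astype(np.int64),
        row_labels=tuple(genera),
        col_labels=tuple(str(c) for c in df.columns if c != "plant_genus"),
        region=region,
        row_status=status,
    )


def build_matrix(
    rs: RecordSet,
    region: str,
    status: Mapping[str, str] | StatusTable,
    exclude_genus_only_fungi: bool = False,
) -> InteractionMatrix:
    """Aggregate a filtered RecordSet into a count matrix for one region.

    ``status`` supplies the native/alien classification of each plant genus,
    either directly (genus -> status) or via a :class:`StatusTable`. With
    ``exclude_genus_only_fungi`` the sensitivity variant omitting genus-only
    fungal identifications is built.
    """
    subset = [r for r in rs if r.region == region]
    if exclude_genus_only_fungi:
        subset = [r for r in subset if r.fungal_rank == "species"]
    if not subset:
        raise EmptySelectionError(f"no records for region {region!r}")
    genera = sorted({r.plant_genus for r in subset})
    taxa = sorted({r.fungal_key for r in subset})
    gi = {g: i for i, g in enumerate(genera)}
    ti = {t: i for i, t in enumerate(taxa)}
    counts = np.zeros((len(genera), len(taxa)), dtype=np.int64)
    for r in subset:
        counts[gi[r.plant_genus], ti[r.fungal_key]] += 1
    if isinstance(status, StatusTable):
        row_status = {g: status.status_for(region, g) for g in genera}
    else:
        missing = [g for g in genera if g not in status]
        if missing:
            raise MissingLookupError("plant status", missing)
        row_status = {g: status[g] for g in genera}
    return InteractionMatrix(
        counts=counts,
        row_labels=tuple(genera),
        col_labels=tuple(taxa),
        region=region,
        row_status=row_status,
    )


def apply_min_collections(m: InteractionMatrix, min_n: int = 8) -> InteractionMatrix:
    """Drop plant genera with fewer than ``min_n`` collections.

    Fungal taxa left without any observation are removed too. Raises
    :class:`EmptySelectionError` when nothing survives.
    """
    if min_n < 1:
        raise ValidationError("min_n must be >= 1")
    keep_rows = m.row_sums() >= min_n
    if not keep_rows.any():
        raise EmptySelectionError(f"no genera pass the {min_n}-collection threshold")
    counts = m.counts[keep_rows]
    keep_cols = counts.sum(axis=0) > 0
    counts = counts[:, keep_cols]
    rows = tuple(g for g, k in zip(m.row_labels, keep_rows) if k)
    cols = tuple(t for t, k in zip(m.col_labels, keep_cols) if k)
    dropped = [g for g, k in zip(m.row_labels, keep_rows) if not k]
    if dropped:
        logger.info(
            "apply_min_collections: dropped %d genera below %d collections: %s",
            len(dropped),
            min_n,
            ", ".join(dropped),
        )
    return InteractionMatrix(
        counts=counts,
        row_labels=rows,
        col_labels=cols,
        region=m.region,
        row_status={g: m.row_status[g] for g in rows},
    )
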