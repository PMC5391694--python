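"""Hyphal exploration types: genus-level trait lookup and the functional matrix.

Ectomycorrhizal fungi are classified into six hyphal exploration types —
morphological foraging strategies ranging from contact mycorrhizas with almost
no emanating hyphae to long-distance types with differentiated rhizomorphs.
Exploration type correlates with nutrient-foraging strategy (hydrophilic
short-range types take up labile N; hydrophobic longer-range types reach
dispersed organic N), so the mix of types on a host plant is a functional
profile of its symbiont community.

Types are catalogued at the fungal genus level; optional species-keyed
overrides accommodate known within-genus variation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .errors import FormatError, MissingLookupError, ValidationError
from .records import InteractionMatrix

logger = logging.getLogger(__name__)


class ExplorationType(str, Enum):
    CONTACT = "contact"
    SHORT = "short"
    MEDIUM_SMOOTH = "medium_smooth"
    MEDIUM_FRINGE = "medium_fringe"
    MEDIUM_MATT = "medium_matt"
    LONG_DISTANCE = "long_distance"


#: Canonical column order for every functional matrix and output file.
EXPLORATION_TYPES: tuple[str, ...] = tuple(t.value for t in ExplorationType)
_TYPE_INDEX = {t: i for i, t in enumerate(EXPLORATION_TYPES)}


@dataclass(frozen=True)
class ExplorationLookup:
    """Fungal genus -> exploration type, with optional per-species overrides."""

    genus_types: Mapping[str, str]
    species_overrides: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for mapping in (self.genus_types, self.species_overrides):
            for name, t in mapping.items():
                if t not in _TYPE_INDEX:
                    raise ValidationError(
                        f"unknown exploration type {t!r} for {name!r}"
                    )

    def resolve(self, fungal_taxon: str) -> Optional[str]:
        """Type for a matrix column label (species name or genus-only key)."""
        if fungal_taxon in self.species_overrides:
            return self.species_overrides[fungal_taxon]
        genus = fungal_taxon.split()[0]
        return self.genus_types.get(genus)


def load_exploration_lookup(path) -> ExplorationLookup:
    """Read exploration_types.csv.

    Columns: ``fungal_genus``, ``exploration_type`` and, optionally,
    ``fungal_species`` — rows with a non-blank species become species-keyed
    overrides.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for c in ("fungal_genus", "exploration_type"):
        if c not in df.columns:
            raise FormatError(f"exploration_types: missing column {c!r}")
    genus_types: dict[str, str] = {}
    overrides: dict[str, str] = {}
    for _, row in df.iterrows():
        species = row.get("fungal_species", "").strip() if "fungal_species" in df.columns else ""
        if species:
            overrides[species] = row["exploration_type"].strip()
        else:
            genus_types[row["fungal_genus"].strip()] = row["exploration_type"].strip()
    return ExplorationLookup(genus_types=genus_types, species_overrides=overrides)


def write_exploration_lookup(lookup: ExplorationLookup, path) -> None:
    rows = [
        {"fungal_genus": g, "fungal_species": "", "exploration_type": t}
        for g, t in sorted(lookup.genus_types.items())
    ]
    rows += [
        {"fungal_genus": s.split()[0], "fungal_species": s, "exploration_type": t}
        for s, t in sorted(lookup.species_overrides.items())
    ]
    pd.DataFrame(rows, columns=["fungal_genus", "fungal_species", "exploration_type"]).to_csv(
        path, index=False
    )


@dataclass(frozen=True)
class FunctionalMatrix:
    """Plant-genus x exploration-type summed observation counts."""

    counts: np.ndarray
    row_labels: tuple[str, ...]
    row_status: Mapping[str, str]
    region: str

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[1] != len(EXPLORATION_TYPES):
            raise ValidationError(
                f"counts must have exactly {len(EXPLORATION_TYPES)} columns"
            )
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
            raise ValidationError("counts must be non-negative integers")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "row_labels", tuple(self.row_labels))
        if counts.shape[0] != len(self.row_labels):
            raise ValidationError("counts shape does not match row labels")
        missing = [g for g in self.row_labels if g not in self.row_status]
        if missing:
            raise ValidationError(f"row_status missing genera: {missing}")

    @property
    def col_labels(self) -> tuple[str, ...]:
        return EXPLORATION_TYPES

    def total(self) -> int:
        return int(self.counts.sum())

    def status_array(self) -> np.ndarray:
        return np.array([self.row_status[g] for g in self.row_labels])

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=list(EXPLORATION_TYPES))
        df.insert(0, "plant_genus", list(self.row_labels))
        df.insert(1, "status", [self.row_status[g] for g in self.row_labels])
        return df

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def assign_exploration_types(
    m: InteractionMatrix,
    lookup: ExplorationLookup,
    on_missing: str = "drop",
) -> FunctionalMatrix:
    """Sum observations by exploration type within each plant genus.

    Fungal taxa whose genus has no lookup entry are dropped with a warning
    (``on_missing="drop"``) or raise (``on_missing="error"``).
    """
    if on_missing not in ("drop", "error"):
        raise ValidationError("on_missing must be 'drop' or 'error'")
    if m.counts.size == 0:
        raise ValidationError("interaction matrix is empty")
    type_idx = np.full(len(m.col_labels), -1, dtype=int)
    unmapped = []
    for j, taxon in enumerate(m.col_labels):
        t = lookup.resolve(taxon)
        if t is None:
            unmapped.append(taxon.split()[0])
        else:
            type_idx[j] = _TYPE_INDEX[t]
    if unmapped:
        if on_missing == "error":
            raise MissingLookupError("exploration type", unmapped)
        logger.warning(
            "assign_exploration_types: dropping %d taxa of %d unmapped genera",
            int((type_idx < 0).sum()),
            len(set(unmapped)),
        )
    counts = np.zeros((len(m.row_labels), len(EXPLORATION_TYPES)), dtype=np.int64)
    for j, k in enumerate(type_idx):
        if k >= 0:
            counts[:, k] += m.counts[:, j]
    return FunctionalMatrix(
        counts=counts,
        row_labels=m.row_labels,
        row_status=dict(m.row_status),
        region=m.region,
    )


def type_proportions(fm: FunctionalMatrix) -> np.ndarray:
    """Row-stochastic version of the functional matrix."""
    sums = fm.counts.sum(axis=1)
    zero = sums == 0
    if zero.any():
        bad = [g for g, z in zip(fm.row_labels, zero) if z]
        raise ValidationError(f"zero observation total for: {', '.join(bad)}")
    return fm.counts / sums[:, None]
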