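import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from symbionet.records import (
    InteractionMatrix,
    RecordSet,
    SporocarpRecord,
    StatusTable,
)
from symbionet.traits import ExplorationLookup, FunctionalMatrix


def record(
    plant_genus,
    fungal_name,
    region="NZ",
    fungal_rank="species",
    plant_species=None,
):
    return SporocarpRecord(
        region=region,
        plant_genus=plant_genus,
        fungal_name=fungal_name,
        fungal_rank=fungal_rank,
        plant_species=plant_species,
    )


@pytest.fixture
def toy_records():
    """Mixed record set: EcM and non-EcM fungi, whitelisted and rogue plants."""
    return RecordSet(
        (
            record("Pinus", "Amanita muscaria"),
            record("Pinus", "Amanita muscaria"),
            record("Pinus", "Suillus luteus"),
            record("Pinus", "Chalciporus piperatus"),
            record("Rosa", "Amanita muscaria"),
            record("Kunzea", "Cortinarius", fungal_rank="genus"),
            record("Kunzea", "Russula nothofagi"),
        ),
        provenance="toy",
    )


@pytest.fixture
def toy_table():
    return StatusTable(
        plant_status={
            "NZ": {
                "Pinus": "alien",
                "Kunzea": "native",
                "Lophozonia": "native",
                "Fuscospora": "native",
                "Nothofagus": "alien",
            }
        },
        ecm_plant_whitelist=frozenset(
            {"Pinus", "Kunzea", "Lophozonia", "Fuscospora", "Nothofagus"}
        ),
        fungal_ecm_status={
            "Amanita": "ecm",
            "Suillus": "ecm",
            "Cortinarius": "ecm",
            "Russula": "ecm",
        },
        non_ecm_exclusions=frozenset({"Chalciporus", "Phialocephala"}),
    )


@pytest.fixture
def toy_lookup():
    return ExplorationLookup(
        genus_types={
            "Amanita": "medium_smooth",
            "Suillus": "long_distance",
            "Cortinarius": "medium_fringe",
            "Russula": "contact",
            "Laccaria": "medium_smooth",
            "Hysterangium": "medium_matt",
        }
    )


def make_matrix(counts, statuses, region="NZ", row_labels=None, col_labels=None):
    counts = np.asarray(counts, dtype=np.int64)
    rows = row_labels or [f"Genus{i + 1:02d}" for i in range(counts.shape[0])]
    cols = col_labels or [f"Fungus{j + 1:02d} sp" for j in range(counts.shape[1])]
    return InteractionMatrix(
        counts=counts,
        row_labels=tuple(rows),
        col_labels=tuple(cols),
        region=region,
        row_status=dict(zip(rows, statuses)),
    )


def make_functional(counts, statuses, region="NZ", row_labels=None):
    counts = np.asarray(counts, dtype=np.int64)
    rows = row_labels or [f"Genus{i + 1:02d}" for i in range(counts.shape[0])]
    return FunctionalMatrix(
        counts=counts,
        row_labels=tuple(rows),
        row_status=dict(zip(rows, statuses)),
        region=region,
    )
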