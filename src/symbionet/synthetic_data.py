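"""Synthetic sporocarp record sets with known ground truth.

The generator emulates the structure of national fungal-record databases well
enough to exercise every pipeline stage without any download: a set of plant
genera split into natives and aliens, fungal species pools with tunable host
specificity, per-fungus exploration types drawn from status-specific
distributions, and long-tailed per-association observation counts.

Construction:

* Native genera are grouped into planted modules (consecutive pairs). Each
  module owns a private pool of fungi; a fraction (``specialist_fraction``) of
  those are single-host specialists, the rest are shared by every genus in the
  module — these shared fungi are what makes planted modules recoverable from
  the projected network. Private fungi draw their exploration type from
  ``type_distribution_native``.
* A common generalist pool (typed from ``type_distribution_alien``) occurs on
  each alien genus with probability ``generalist_on_alien_p`` and on each
  native genus with the (typically much lower) ``generalist_on_native_p``.
* ``cointroduction_fraction`` of the native-module fungi additionally turn up
  on one random alien genus, emulating co-introduced symbionts.
* Every realized fungus-host association receives a negative-binomial number
  of observation records (mean ``mean_records_per_association``, dispersion
  ``count_dispersion``); a zero draw removes the association. Dispersion 1
  gives geometric counts — the long-tailed recording-effort model used by the
  presets.

Everything is reproducible from ``seed``; ground truth (planted modules, fungal
types, realized host sets) is returned alongside the records and can be written
to a JSON sidecar so tests never re-derive it from pipeline output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from typing import Mapping, Optional

import numpy as np

from .errors import ValidationError
from .records import RecordSet, SporocarpRecord, StatusTable
from .traits import EXPLORATION_TYPES, ExplorationLookup

REGION = "SYN"


@dataclass(frozen=True)
class SyntheticParams:
    n_native: int = 8
    n_alien: int = 15
    fungi_per_native_module: int = 100
    n_generalist_fungi: int = 30
    specialist_fraction: float = 0.15
    cointroduction_fraction: float = 0.1
    type_distribution_native: tuple[float, ...] = (0.21, 0.21, 0.21, 0.21, 0.06, 0.10)
    type_distribution_alien: tuple[float, ...] = (0.44, 0.25, 0.15, 0.10, 0.0, 0.06)
    count_dispersion: float = 1.0
    mean_records_per_association: float = 3.0
    seed: int = 0
    module_size: int = 2
    generalist_on_native_p: float = 0.1
    generalist_on_alien_p: float = 0.6

    def __post_init__(self):
        for name in ("specialist_fraction", "cointroduction_fraction",
                     "generalist_on_native_p", "generalist_on_alien_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")
        for name in ("type_distribution_native", "type_distribution_alien"):
            p = np.asarray(getattr(self, name), dtype=float)
            if p.size != len(EXPLORATION_TYPES) or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
                raise ValidationError(f"{name} must be a probability vector over "
                                      f"{len(EXPLORATION_TYPES)} exploration types")
            object.__setattr__(self, name, tuple(float(x) for x in p))
        if self.count_dispersion <= 0 or self.mean_records_per_association <= 0:
            raise ValidationError("count_dispersion and mean_records_per_association must be > 0")
        if self.n_native < 0 or self.n_alien < 0 or self.module_size < 1:
            raise ValidationError("invalid pool sizes")


@dataclass(frozen=True)
class GroundTruth:
    planted_module: Mapping[str, int]
    fungal_type: Mapping[str, str]
    fungal_hosts: Mapping[str, frozenset]

    def write_json(self, path) -> None:
        payload = {
            "planted_module": dict(self.planted_module),
            "fungal_type": dict(self.fungal_type),
            "fungal_hosts": {f: sorted(h) for f, h in self.fungal_hosts.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def _negbin_counts(rng: np.random.Generator, mean: float, dispersion: float, size: int):
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def generate_dataset(
    params: SyntheticParams,
) -> tuple[RecordSet, GroundTruth, StatusTable, ExplorationLookup]:
    """Generate records, ground truth and matching lookup tables."""
    rng = np.random.default_rng(params.seed)
    natives = [f"Nativus{i + 1:02d}" for i in range(params.n_native)]
    aliens = [f"Alienus{i + 1:02d}" for i in range(params.n_alien)]
    if not natives and not aliens:
        raise ValidationError("no plant genera requested")

    # Planted modules: consecutive native pairs (last may be smaller); all
    # aliens share one module.
    modules: list[list[str]] = [
        natives[i : i + params.module_size]
        for i in range(0, len(natives), params.module_size)
    ]
    planted = {g: m for m, members in enumerate(modules) for g in members}
    alien_module = len(modules)
    planted.update({g: alien_module for g in aliens})

    fungal_type: dict[str, str] = {}
    fungal_hosts: dict[str, set] = {}
    idx = 0

    def new_fungus(type_dist) -> str:
        nonlocal idx
        idx += 1
        name = f"Specigenus{idx:04d} typicus"
        fungal_type[name] = EXPLORATION_TYPES[rng.choice(6, p=type_dist)]
        fungal_hosts[name] = set()
        return name

    # Module-private native fungi.
    for members in modules:
        for _ in range(params.fungi_per_native_module):
            f = new_fungus(params.type_distribution_native)
            if rng.random() < params.specialist_fraction or len(members) == 1:
                fungal_hosts[f].add(members[int(rng.integers(len(members)))])
            else:
                fungal_hosts[f].update(members)
            if aliens and rng.random() < params.cointroduction_fraction:
                fungal_hosts[f].add(aliens[int(rng.integers(len(aliens)))])

    # Shared generalist pool.
    for _ in range(params.n_generalist_fungi):
        f = new_fungus(params.type_distribution_alien)
        for g in aliens:
            if rng.random() < params.generalist_on_alien_p:
                fungal_hosts[f].add(g)
        for g in natives:
            if rng.random() < params.generalist_on_native_p:
                fungal_hosts[f].add(g)
        if not fungal_hosts[f]:
            pool = aliens or natives
            fungal_hosts[f].add(pool[int(rng.integers(len(pool)))])

    # Observation counts per realized association.
    records: list[SporocarpRecord] = []
    realized_hosts: dict[str, set] = {}
    for f in sorted(fungal_hosts):
        hosts = sorted(fungal_hosts[f])
        if not hosts:
            continue
        counts = _negbin_counts(
            rng, params.mean_records_per_association, params.count_dispersion, len(hosts)
        )
        for g, c in zip(hosts, counts):
            if c == 0:
                continue
            realized_hosts.setdefault(f, set()).add(g)
            for k in range(int(c)):
                records.append(
                    SporocarpRecord(
                        region=REGION,
                        plant_genus=g,
                        fungal_name=f,
                        fungal_rank="species",
                        source_id=f"syn-{f.split()[0]}-{g}-{k + 1}",
                    )
                )
    if not records:
        raise ValidationError("parameter combination produced zero records")

    realized_fungi = sorted(realized_hosts)
    status_table = StatusTable(
        plant_status={
            REGION: {**{g: "native" for g in natives}, **{g: "alien" for g in aliens}}
        },
        ecm_plant_whitelist=frozenset(natives + aliens),
        fungal_ecm_status={f.split()[0]: "ecm" for f in fungal_type},
        non_ecm_exclusions=frozenset(),
    )
    lookup = ExplorationLookup(
        genus_types={f.split()[0]: t for f, t in fungal_type.items()}
    )
    truth = GroundTruth(
        planted_module=planted,
        fungal_type={f: fungal_type[f] for f in realized_fungi},
        fungal_hosts={f: frozenset(realized_hosts[f]) for f in realized_fungi},
    )
    rs = RecordSet(
        tuple(records),
        provenance=f"synthetic seed={params.seed}",
    )
    return rs, truth, status_table, lookup


_PRESETS = {
    # Strong native modularity, alien merging, alien medium-matt deficit.
    "nz_like": SyntheticParams(),
    # Natives and aliens functionally alike, host pools overlapping.
    "uk_like": SyntheticParams(
        n_native=10,
        n_alien=9,
        fungi_per_native_module=80,
        n_generalist_fungi=60,
        specialist_fraction=0.15,
        cointroduction_fraction=0.6,
        type_distribution_native=(0.55, 0.18, 0.11, 0.07, 0.04, 0.05),
        type_distribution_alien=(0.55, 0.18, 0.11, 0.07, 0.04, 0.05),
        generalist_on_native_p=0.5,
        generalist_on_alien_p=0.5,
    ),
    # No group structure at all: one shared pool, identical type distributions.
    "null": SyntheticParams(
        n_native=5,
        n_alien=5,
        fungi_per_native_module=0,
        n_generalist_fungi=40,
        specialist_fraction=0.0,
        cointroduction_fraction=0.0,
        type_distribution_native=(1 / 6,) * 6,
        type_distribution_alien=(1 / 6,) * 6,
        generalist_on_native_p=0.5,
        generalist_on_alien_p=0.5,
    ),
}


def preset(name: str, seed: Optional[int] = None) -> SyntheticParams:
    """Documented parameter bundles: ``nz_like``, ``uk_like``, ``null``."""
    try:
        params = _PRESETS[name]
    except KeyError:
        raise ValidationError(
            f"unknown preset {name!r}; choose from {sorted(_PRESETS)}"
        )
    if seed is not None:
        params = replace(params, seed=seed)
    return params
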