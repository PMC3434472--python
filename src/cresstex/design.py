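"""Blinded, randomized experimental design for the cress biocrystallisation assay.

The assay compares two homeopathically processed preparations — verum
(*Stannum metallicum* 30x) and control (water 30x), each produced in
triplicate ("internal replicates") — on repeated experimental days in two
laboratories (LBI, BRAD).  On each day the six coded extracts are examined in
six glass-plate replicates (36 crystallisation plates) plus a fixed number of
open reference-standard plates, filling the crystallisation chamber.

This module builds that crossed design, randomizes and codes it (blinding),
decodes it against a coding key, applies technical-error discards, and
provides the potency/recipe arithmetic (nominal dilution, nominal molarity,
extract mass fraction).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

VERUM = "verum"
CONTROL = "control"
REFERENCE = "reference"
LABS = ("LBI", "BRAD")

__all__ = [
    "PotencySpec",
    "PlateRecord",
    "ExperimentDesign",
    "build_design",
    "randomize_and_code",
    "decode",
    "apply_discards",
    "nominal_dilution",
    "nominal_molarity",
    "extract_mass_fraction",
    "design_to_csv",
    "design_from_csv",
    "VERUM",
    "CONTROL",
    "REFERENCE",
    "LABS",
]


# ---------------------------------------------------------------------------
# Potency / recipe arithmetic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PotencySpec:
    """Serial-dilution specification of a homeopathic potency.

    Parameters
    ----------
    n_steps
        Number of 1-in-10 potentisation steps (30 for a "30x" preparation).
    step_dilution
        Fraction retained per step; 0.1 for the 1:9 dilution ratio used
        throughout (1 part substance in 9 parts medium).
    molar_mass
        Molar mass of the source substance in g/mol (needed for molarity).
    reference_concentration
        Concentration of the undiluted source in g/L.  Defaults to pure
        substance at 1000 g/L.
    """

    n_steps: int
    step_dilution: float = 0.1
    molar_mass: float | None = None
    reference_concentration: float = 1000.0


def nominal_dilution(spec: PotencySpec) -> float:
    """Nominal dilution factor of a potency, ``step_dilution ** n_steps``.

    A 30x preparation (30 steps at 1:9) has nominal dilution 1e-30.
    """
    if spec.n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    return float(spec.step_dilution) ** spec.n_steps


def nominal_molarity(spec: PotencySpec) -> float:
    """Nominal molar concentration (mol/L) of the source in the potency.

    dilution x reference_concentration / molar_mass.  For tin
    (118.71 g/mol) at 30x this is 8.4e-30 M; for lactose (342.30 g/mol) at
    24x it is 2.9e-24 M.
    """
    if spec.molar_mass is None or spec.molar_mass <= 0:
        raise ValueError("molar_mass must be positive")
    return nominal_dilution(spec) * spec.reference_concentration / spec.molar_mass


def extract_mass_fraction(seedling_mass: float, fluid_mass: float) -> float:
    """Mass percent of seedlings in the extraction solution.

    The recipe (3.00 g seedlings in 27.00 g potency fluid) yields a 10 %
    solution on weight basis.
    """
    if seedling_mass < 0 or fluid_mass < 0:
        raise ValueError("masses must be non-negative")
    total = seedling_mass + fluid_mass
    if total <= 0:
        raise ValueError("total mass must be positive")
    return 100.0 * seedling_mass / total


# ---------------------------------------------------------------------------
# Records and design container
# ---------------------------------------------------------------------------

@dataclass
class PlateRecord:
    """One crystallisation plate slot of the design.

    ``truth`` is the unblinded preparation identity (verum/control).  It is
    populated at build time, moved into the private coding map when the
    design is coded, and restored by :func:`decode`.  Reference-standard
    slots carry ``truth == "reference"`` and no treatment code.
    """

    lab: str
    day: int
    is_reference: bool = False
    truth: str | None = None
    internal_replicate: int | None = None
    plate_replicate: int | None = None
    code: str | None = None
    processing_order: int | None = None
    position: int | None = None
    evaporation_time: float | None = None
    discarded: bool = False

    @property
    def record_id(self) -> str:
        return f"{self.lab}-d{self.day:02d}-p{self.position:02d}"


@dataclass
class ExperimentDesign:
    """Ordered collection of plate records plus blinding state.

    The coding map (code -> truth per lab/day) is private; the public table
    returned by :meth:`to_frame` shows truth labels only after decoding.
    """

    records: list[PlateRecord] = field(default_factory=list)
    scheme: str | None = None
    coded: bool = False
    decoded: bool = False
    audit_log: list[str] = field(default_factory=list)
    _truth_map: dict[tuple[str, int, str], tuple[str, int]] = field(
        default_factory=dict, repr=False
    )

    # -- views ------------------------------------------------------------

    def treatment_records(self, include_discarded: bool = False) -> list[PlateRecord]:
        recs = [r for r in self.records if not r.is_reference]
        if not include_discarded:
            recs = [r for r in recs if not r.discarded]
        return recs

    @property
    def n_treatment_plates(self) -> int:
        return len([r for r in self.records if not r.is_reference])

    @property
    def n_usable(self) -> int:
        return len(self.treatment_records())

    def days(self) -> list[tuple[str, int]]:
        seen: dict[tuple[str, int], None] = {}
        for r in self.records:
            seen.setdefault((r.lab, r.day), None)
        return list(seen)

    def day_slots(self, lab: str, day: int) -> list[PlateRecord]:
        return [r for r in self.records if r.lab == lab and r.day == day]

    def to_frame(self) -> pd.DataFrame:
        """Public design table; truth is blank while the design is blinded."""
        rows = []
        for r in self.records:
            truth: str | None
            if r.is_reference:
                truth = REFERENCE
            elif self.coded and not self.decoded:
                truth = None
            else:
                truth = r.truth
            rows.append(
                dict(
                    lab=r.lab,
                    day=r.day,
                    code=r.code,
                    truth=truth,
                    internal_replicate=r.internal_replicate,
                    plate_replicate=r.plate_replicate,
                    processing_order=r.processing_order,
                    position=r.position,
                    evaporation_h=r.evaporation_time,
                    discarded=r.discarded,
                    record_id=r.record_id,
                )
            )
        return pd.DataFrame(rows)

    def coding_key(self) -> dict[str, dict[str, str]]:
        """Coding key for the code holder: ``{"LAB:day": {code: truth}}``."""
        if not self.coded:
            raise ValueError("design is not coded; no key exists")
        key: dict[str, dict[str, str]] = {}
        for (lab, day, code), (truth, _internal) in self._truth_map.items():
            key.setdefault(f"{lab}:{day}", {})[code] = truth
        return key

    def save_coding_key(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.coding_key(), indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------

def _reference_positions(total: int, n_reference: int) -> list[int]:
    """Spread reference-standard slots evenly over positions 1..total."""
    if n_reference == 0:
        return []
    pts = np.linspace(1, total, n_reference + 2)[1:-1]
    chosen: list[int] = []
    for p in pts:
        q = int(round(p))
        while q in chosen and q < total:
            q += 1
        chosen.append(q)
    # fill any residual duplicates with first free slots
    free = [p for p in range(1, total + 1) if p not in chosen]
    uniq: list[int] = []
    for q in chosen:
        if q in uniq:
            q = free.pop(0)
        uniq.append(q)
    return sorted(uniq)


def _truth_labels(n_treatments: int) -> list[str]:
    if n_treatments == 2:
        return [VERUM, CONTROL]
    return [f"prep{i}" for i in range(1, n_treatments + 1)]


def build_design(
    n_labs: int = 2,
    days_per_lab: Sequence[int] = (7, 8),
    n_treatments: int = 2,
    n_internal: int = 3,
    n_plate_reps: int = 6,
    n_reference: int = 7,
    labs: Sequence[str] = LABS,
) -> ExperimentDesign:
    """Build the crossed (uncoded) design.

    Per (lab, day) there are ``n_treatments * n_internal`` extract groups,
    each examined in ``n_plate_reps`` plate replicates, plus ``n_reference``
    open reference-standard slots.  Days are numbered consecutively across
    labs (LBI 1-7, BRAD 8-15 for the default shape).
    """
    counts = dict(
        n_labs=n_labs,
        n_treatments=n_treatments,
        n_internal=n_internal,
        n_plate_reps=n_plate_reps,
        n_reference=n_reference,
    )
    for name, v in counts.items():
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    if len(days_per_lab) != n_labs:
        raise ValueError("days_per_lab must give one day count per lab")
    if any(d < 0 for d in days_per_lab):
        raise ValueError("day counts must be >= 0")
    if n_labs > len(labs):
        raise ValueError(f"at most {len(labs)} lab names available")

    truths = _truth_labels(n_treatments)
    n_groups = n_treatments * n_internal
    total_slots = n_groups * n_plate_reps + n_reference

    design = ExperimentDesign()
    day_counter = 0
    for lab_idx in range(n_labs):
        lab = labs[lab_idx]
        for _ in range(days_per_lab[lab_idx]):
            day_counter += 1
            ref_pos = _reference_positions(total_slots, n_reference)
            treat_pos = [p for p in range(1, total_slots + 1) if p not in ref_pos]
            k = 0
            for truth in truths:
                for internal in range(1, n_internal + 1):
                    for rep in range(1, n_plate_reps + 1):
                        design.records.append(
                            PlateRecord(
                                lab=lab,
                                day=day_counter,
                                truth=truth,
                                internal_replicate=internal,
                                plate_replicate=rep,
                                position=treat_pos[k],
                            )
                        )
                        k += 1
            for pos in ref_pos:
                design.records.append(
                    PlateRecord(lab=lab, day=day_counter, is_reference=True,
                                truth=REFERENCE, position=pos)
                )
    design.audit_log.append(
        f"built design: {n_labs} labs, days {tuple(days_per_lab)}, "
        f"{n_groups} groups x {n_plate_reps} reps + {n_reference} reference/day"
    )
    return design


# ---------------------------------------------------------------------------
# Randomization / coding / decoding
# ---------------------------------------------------------------------------

def _balanced_patterns(n_groups: int, truths: list[str], n_internal: int):
    """Two complementary order patterns whose per-day order sums swap.

    Pattern A gives the first truth the odd processing orders, pattern B the
    even ones; alternating A/B across days balances the per-lab mean
    processing order exactly for even day counts.
    """
    orders = list(range(1, n_groups + 1))
    a: dict[str, list[int]] = {t: [] for t in truths}
    for i, o in enumerate(orders):
        a[truths[i % len(truths)]].append(o)
    b = {t: [n_groups + 1 - o for o in a[t]] for t in truths}
    return a, b


def randomize_and_code(
    design: ExperimentDesign,
    scheme: str = "manual_emulated",
    seed: int = 0,
) -> ExperimentDesign:
    """Randomize code/processing-order allocation per day and blind the design.

    ``manual_emulated`` permutes the six codes uniformly per day (emulating
    the study's manual randomization, which can leave processing order
    unbalanced between truth groups).  ``balanced`` alternates complementary
    order patterns so the per-lab mean processing order is equal across
    truth groups (exact for even day counts per lab).

    Codes are "1".."6"; the processing order equals the code number, since
    extracts are handled in code sequence in the laboratory.
    """
    if design.coded:
        raise ValueError("design is already coded")
    if scheme not in ("manual_emulated", "balanced"):
        raise ValueError(f"unknown scheme {scheme!r}")

    rng = np.random.default_rng(seed)
    for lab, day in design.days():
        recs = [r for r in design.day_slots(lab, day) if not r.is_reference]
        if not recs:
            continue
        groups = sorted({(r.truth, r.internal_replicate) for r in recs})
        truths = sorted({t for t, _ in groups})
        n_groups = len(groups)

        if scheme == "manual_emulated":
            perm = rng.permutation(n_groups)
            order_of = {groups[i]: int(perm[i]) + 1 for i in range(n_groups)}
        else:
            n_internal = n_groups // len(truths)
            a, b = _balanced_patterns(n_groups, truths, n_internal)
            lab_days = sorted(d for l, d in design.days() if l == lab)
            pattern = a if lab_days.index(day) % 2 == 0 else b
            order_of = {}
            for t in truths:
                slots = list(pattern[t])
                rng.shuffle(slots)
                for i, internal in enumerate(
                    sorted(i2 for t2, i2 in groups if t2 == t)
                ):
                    order_of[(t, internal)] = int(slots[i])

        for r in recs:
            o = order_of[(r.truth, r.internal_replicate)]
            r.code = str(o)
            r.processing_order = o
            design._truth_map[(lab, day, r.code)] = (r.truth, r.internal_replicate)
            r.truth = None
    design.scheme = scheme
    design.coded = True
    design.audit_log.append(f"coded with scheme={scheme}, seed={seed}")
    return design


def decode(design: ExperimentDesign, key: dict[str, dict[str, str]]) -> ExperimentDesign:
    """Reveal truth labels using the coding key; refuses on any mismatch.

    Validation is all-or-nothing: a tampered key leaves the design unchanged.
    Decoding an already-decoded design with the correct key is a no-op.
    """
    if not design.coded:
        raise ValueError("design is not coded")
    merged: dict[str, dict[str, str]] = {}
    for (lab, day, code), (truth, _i) in design._truth_map.items():
        merged.setdefault(f"{lab}:{day}", {})[code] = truth
    if key != merged:
        raise ValueError("coding key does not match this design; decode refused")
    if design.decoded:
        return design
    for r in design.records:
        if r.is_reference or r.code is None:
            continue
        truth, internal = design._truth_map[(r.lab, r.day, r.code)]
        r.truth = truth
        r.internal_replicate = internal
    design.decoded = True
    design.audit_log.append("decoded with matching key")
    return design


# ---------------------------------------------------------------------------
# Discards
# ---------------------------------------------------------------------------

def apply_discards(design: ExperimentDesign, flagged: Iterable[str]) -> ExperimentDesign:
    """Mark plates discarded for technical error; they leave downstream counts.

    ``flagged`` holds record ids (``"LBI-d03-p17"``); unknown ids raise.
    """
    flagged = list(flagged)
    by_id = {r.record_id: r for r in design.records}
    unknown = [f for f in flagged if f not in by_id]
    if unknown:
        raise KeyError(f"unknown record ids: {unknown}")
    for f in flagged:
        by_id[f].discarded = True
    design.audit_log.append(f"discarded {len(flagged)} plates")
    return design


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

def design_to_csv(design: ExperimentDesign, path: str | Path) -> None:
    design.to_frame().to_csv(path, index=False)


def design_from_csv(path: str | Path) -> pd.DataFrame:
    """Load a design table (one row per plate) as a DataFrame."""
    df = pd.read_csv(path, dtype={"code": "string"})
    return df
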