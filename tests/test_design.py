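"""Design construction, blinding/decoding, discards and potency arithmetic."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cresstex import design as dz


# ---------------------------------------------------------------------------
# Potency / recipe arithmetic
# ---------------------------------------------------------------------------

def test_nominal_dilution_30x():
    assert dz.nominal_dilution(dz.PotencySpec(30)) == pytest.approx(1e-30, rel=1e-12)


def test_nominal_dilution_identity_and_small_cases():
    assert dz.nominal_dilution(dz.PotencySpec(0)) == 1.0
    assert dz.nominal_dilution(dz.PotencySpec(4)) == pytest.approx(1e-4, rel=1e-12)


def test_nominal_dilution_rejects_negative_steps():
    with pytest.raises(ValueError):
        dz.nominal_dilution(dz.PotencySpec(-1))


def test_nominal_molarity_tin_30x():
    m = dz.nominal_molarity(dz.PotencySpec(30, molar_mass=118.71))
    assert float(f"{m:.1e}") == pytest.approx(8.4e-30)


def test_nominal_molarity_lactose_24x():
    m = dz.nominal_molarity(dz.PotencySpec(24, molar_mass=342.30))
    assert float(f"{m:.1e}") == pytest.approx(2.9e-24)


def test_nominal_molarity_unit_case():
    m = dz.nominal_molarity(
        dz.PotencySpec(0, molar_mass=50.0, reference_concentration=50.0)
    )
    assert m == pytest.approx(1.0)


def test_nominal_molarity_requires_molar_mass():
    with pytest.raises(ValueError):
        dz.nominal_molarity(dz.PotencySpec(30))
    with pytest.raises(ValueError):
        dz.nominal_molarity(dz.PotencySpec(30, molar_mass=-1.0))


def test_extract_mass_fraction_recipe():
    assert dz.extract_mass_fraction(3.00, 27.00) == pytest.approx(10.0)
    assert dz.extract_mass_fraction(0.0, 5.0) == 0.0
    assert dz.extract_mass_fraction(4.2, 4.2) == pytest.approx(50.0)


def test_extract_mass_fraction_errors():
    with pytest.raises(ValueError):
        dz.extract_mass_fraction(0.0, 0.0)
    with pytest.raises(ValueError):
        dz.extract_mass_fraction(-1.0, 2.0)


# ---------------------------------------------------------------------------
# Crossed design construction
# ---------------------------------------------------------------------------

def test_default_design_counts():
    d = dz.build_design()
    assert d.n_treatment_plates == 540
    # 36 treatment + 7 reference slots scheduled per day
    assert len(d.day_slots("LBI", 1)) == 43
    assert len(d.days()) == 15
    labs = {lab for lab, _ in d.days()}
    assert labs == {"LBI", "BRAD"}


def test_day_positions_unique_and_complete():
    d = dz.build_design()
    slots = d.day_slots("BRAD", 10)
    positions = sorted(r.position for r in slots)
    assert positions == list(range(1, 44))


def test_empty_design():
    d = dz.build_design(n_labs=1, days_per_lab=(0,))
    assert d.n_treatment_plates == 0
    assert d.days() == []


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        dz.build_design(n_plate_reps=-1)
    with pytest.raises(ValueError):
        dz.build_design(days_per_lab=(7,))  # wrong length


@given(
    days=st.tuples(st.integers(0, 3), st.integers(0, 3)),
    n_internal=st.integers(1, 3),
    n_reps=st.integers(1, 4),
    n_ref=st.integers(0, 5),
)
def test_crossed_count_formula(days, n_internal, n_reps, n_ref):
    d = dz.build_design(
        days_per_lab=days, n_internal=n_internal, n_plate_reps=n_reps,
        n_reference=n_ref,
    )
    assert d.n_treatment_plates == sum(days) * 2 * n_internal * n_reps
    assert len(d.records) == sum(days) * (2 * n_internal * n_reps + n_ref)


# ---------------------------------------------------------------------------
# Randomization, coding, blinding, decoding
# ---------------------------------------------------------------------------

def _small(scheme="manual_emulated", seed=0, days=(2, 2)):
    d = dz.build_design(days_per_lab=days, n_plate_reps=2, n_reference=1)
    dz.randomize_and_code(d, scheme=scheme, seed=seed)
    return d


def test_coding_blinds_public_table():
    d = _small()
    frame = d.to_frame()
    treat = frame[frame["truth"] != dz.REFERENCE]
    assert treat["truth"].isna().all()
    assert set(treat["code"]) == {"1", "2", "3", "4", "5", "6"}


def test_processing_order_constant_within_group_and_equals_code():
    d = _small(seed=3)
    for r in d.treatment_records():
        assert r.processing_order == int(r.code)


def test_decode_round_trip_three_verum_three_control_per_day():
    d = _small(seed=1)
    key = d.coding_key()
    dz.decode(d, key)
    for lab, day in d.days():
        recs = [r for r in d.day_slots(lab, day) if not r.is_reference]
        truths = [r.truth for r in recs]
        assert truths.count(dz.VERUM) == len(recs) // 2
        assert truths.count(dz.CONTROL) == len(recs) // 2


def test_decode_tampered_key_refused_design_unchanged():
    d = _small(seed=2)
    key = d.coding_key()
    bad = {k: dict(v) for k, v in key.items()}
    first = next(iter(bad))
    bad[first]["1"] = (
        dz.CONTROL if bad[first]["1"] == dz.VERUM else dz.VERUM
    )
    with pytest.raises(ValueError, match="refused"):
        dz.decode(d, bad)
    assert not d.decoded
    assert all(r.truth is None for r in d.treatment_records())


def test_decode_idempotent():
    d = _small(seed=4)
    key = d.coding_key()
    dz.decode(d, key)
    before = [r.truth for r in d.treatment_records()]
    dz.decode(d, key)
    assert [r.truth for r in d.treatment_records()] == before


def test_coding_twice_and_uncoded_paths_error():
    d = _small()
    with pytest.raises(ValueError):
        dz.randomize_and_code(d)
    u = dz.build_design(days_per_lab=(1, 1))
    with pytest.raises(ValueError):
        u.coding_key()
    with pytest.raises(ValueError):
        dz.decode(u, {})
    with pytest.raises(ValueError):
        dz.randomize_and_code(u, scheme="bogus")


@given(seed=st.integers(0, 50), half_days=st.integers(1, 3))
def test_balanced_scheme_equalizes_mean_order(seed, half_days):
    d = dz.build_design(days_per_lab=(2 * half_days, 2 * half_days),
                        n_plate_reps=1, n_reference=0)
    dz.randomize_and_code(d, scheme="balanced", seed=seed)
    dz.decode(d, d.coding_key())
    frame = d.to_frame()
    for lab in ("LBI", "BRAD"):
        sub = frame[frame["lab"] == lab]
        means = sub.groupby("truth")["processing_order"].mean()
        assert means[dz.VERUM] == pytest.approx(means[dz.CONTROL])


def test_manual_emulated_can_be_unbalanced():
    found = False
    for seed in range(40):
        d = dz.build_design(days_per_lab=(2, 2), n_plate_reps=1, n_reference=0)
        dz.randomize_and_code(d, scheme="manual_emulated", seed=seed)
        dz.decode(d, d.coding_key())
        frame = d.to_frame()
        sub = frame[frame["lab"] == "LBI"]
        means = sub.groupby("truth")["processing_order"].mean()
        if abs(means[dz.VERUM] - means[dz.CONTROL]) > 1e-12:
            found = True
            break
    assert found, "no seed produced an order/treatment imbalance"


def test_same_seed_identical_assignment():
    a = _small(seed=11)
    b = _small(seed=11)
    assert a.coding_key() == b.coding_key()
    assert [r.code for r in a.records] == [r.code for r in b.records]


# ---------------------------------------------------------------------------
# Discards
# ---------------------------------------------------------------------------

def test_discards_540_to_535():
    d = dz.build_design()
    flagged = [r.record_id for r in d.treatment_records()[:5]]
    dz.apply_discards(d, flagged)
    assert d.n_treatment_plates == 540
    assert d.n_usable == 535


def test_discards_unknown_id_and_identity():
    d = dz.build_design(days_per_lab=(1, 1))
    with pytest.raises(KeyError, match="unknown"):
        dz.apply_discards(d, ["LBI-d99-p99"])
    n = d.n_usable
    dz.apply_discards(d, [])
    assert d.n_usable == n


def test_all_discarded_degenerate():
    d = dz.build_design(days_per_lab=(1, 0), n_reference=0)
    dz.apply_discards(d, [r.record_id for r in d.treatment_records()])
    assert d.n_usable == 0


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

def test_design_csv_round_trip(tmp_path):
    d = _small(seed=5)
    path = tmp_path / "design.csv"
    dz.design_to_csv(d, path)
    df = dz.design_from_csv(path)
    assert len(df) == len(d.records)
    assert list(df.columns) == [
        "lab", "day", "code", "truth", "internal_replicate", "plate_replicate",
        "processing_order", "position", "evaporation_h", "discarded", "record_id",
    ]
    treat = df[df["truth"] != dz.REFERENCE]
    assert treat["truth"].isna().all()  # blinded on disk too
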