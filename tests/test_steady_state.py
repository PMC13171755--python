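"""Steady-state closure: arithmetic oracles and balance audits."""
import numpy as np
import pytest

from bcellqsp import balance_residuals, build_parameters, derive_rates
from bcellqsp.steady_state import PAPER_K7, is_balanced

# Reference counts/rates used by the closure (independent copy).
COUNTS = {
    "ImmBone_ss": 1.97e6,
    "T1Bone_ss": 0.76e6,
    "T1Blood_ss": 4.0e3,
    "T1Spleen_ss": 4.40e6,
    "NaiveSpleen_ss": 24.30e6,
    "NaiveBlood_ss": 4.64e6,
    "NaiveLN_ss": 1.90e6,
}
FIXED = {"ksyn_imm": 2.0e7, "k2": 1.01, "k4": 10.08, "k6": 4.9, "kdeg_ln": 0.05}


def oracle_closure(k7):
    """Hand-computed sequential balance solves (plain arithmetic)."""
    kmat_1 = FIXED["ksyn_imm"] / COUNTS["ImmBone_ss"]
    k1 = kmat_1 * COUNTS["ImmBone_ss"] / COUNTS["T1Bone_ss"]
    k3 = (
        k1 * COUNTS["T1Bone_ss"] + FIXED["k2"] * COUNTS["T1Spleen_ss"]
    ) / COUNTS["T1Blood_ss"]
    kmat_2 = k3 * COUNTS["T1Blood_ss"] / COUNTS["T1Spleen_ss"] - FIXED["k2"]
    k5 = (
        FIXED["k4"] * COUNTS["NaiveSpleen_ss"] + k7 * COUNTS["NaiveLN_ss"]
    ) / COUNTS["NaiveBlood_ss"] - FIXED["k6"]
    kdeg_spl = (
        kmat_2 * COUNTS["T1Spleen_ss"] + k5 * COUNTS["NaiveBlood_ss"]
    ) / COUNTS["NaiveSpleen_ss"] - FIXED["k4"]
    return dict(
        kmat_1=kmat_1, k1=k1, k3=k3, kmat_2=kmat_2, k5=k5, kdeg_spl=kdeg_spl
    )


def test_paper_mode_matches_arithmetic_oracle():
    d = derive_rates(COUNTS, FIXED, mode="paper")
    oracle = oracle_closure(PAPER_K7)
    for name, expected in oracle.items():
        assert getattr(d, name) == pytest.approx(expected, rel=1e-12), name
    assert d.k7 == PAPER_K7


def test_paper_mode_rounds_to_published_table():
    d = derive_rates(COUNTS, FIXED, mode="paper")
    assert round(d.kmat_1, 2) == 10.15
    assert round(d.k1, 2) == 26.32
    assert round(d.k3) == 6111
    assert round(d.kmat_2, 2) == 4.55
    assert round(d.k5, 2) == 73.53
    assert round(d.kdeg_spl, 2) == 4.78


def test_paper_mode_leaves_ln_balance_open():
    d = derive_rates(COUNTS, FIXED, mode="paper")
    # LN residual = k6*NaiveBlood - (k7 + kdeg_ln)*NaiveLN, hand-computed
    expected = (
        FIXED["k6"] * COUNTS["NaiveBlood_ss"]
        - (PAPER_K7 + FIXED["kdeg_ln"]) * COUNTS["NaiveLN_ss"]
    )
    assert expected == pytest.approx(-9.637e7, rel=1e-3)
    assert d.residuals["NaiveLN"] == pytest.approx(expected, rel=1e-12)
    # every other compartment closes to rounding error
    for name, r in d.residuals.items():
        if name != "NaiveLN":
            assert abs(r) < 1e-4 * FIXED["ksyn_imm"], name


def test_self_consistent_mode_closes_every_compartment():
    d = derive_rates(COUNTS, FIXED, mode="self_consistent")
    # k7 solved from the LN balance itself
    k7 = FIXED["k6"] * COUNTS["NaiveBlood_ss"] / COUNTS["NaiveLN_ss"] - FIXED[
        "kdeg_ln"
    ]
    assert d.k7 == pytest.approx(k7, rel=1e-12)
    assert d.k7 == pytest.approx(11.916, abs=5e-3)
    for name, r in d.residuals.items():
        assert abs(r) < 1e-6 * FIXED["ksyn_imm"], name
    oracle = oracle_closure(k7)
    for name, expected in oracle.items():
        assert getattr(d, name) == pytest.approx(expected, rel=1e-12), name


def test_balance_residuals_table_and_is_balanced():
    p_sc = build_parameters(mode="self_consistent")
    table = balance_residuals(p_sc)
    assert list(table.columns) == ["compartment", "influx", "efflux", "net"]
    assert len(table) == 7
    assert np.allclose(
        table["net"], table["influx"] - table["efflux"], rtol=0, atol=1e-6
    )
    assert is_balanced(p_sc)
    assert not is_balanced(build_parameters(mode="paper"))


def test_missing_inputs_raise():
    with pytest.raises(KeyError):
        derive_rates({k: v for k, v in COUNTS.items() if k != "NaiveLN_ss"}, FIXED)
    with pytest.raises(KeyError):
        derive_rates(COUNTS, {k: v for k, v in FIXED.items() if k != "k2"})
    with pytest.raises(ValueError):
        derive_rates({**COUNTS, "T1Bone_ss": 0.0}, FIXED)
    with pytest.raises(ValueError):
        derive_rates(COUNTS, FIXED, mode="bogus")


def test_infeasible_closure_rejected():
    # a huge LN elimination rate makes the solved LN return rate negative
    with pytest.raises(ValueError, match="negative solved rate"):
        derive_rates(COUNTS, {**FIXED, "kdeg_ln": 100.0}, mode="self_consistent")
    # in paper mode (k7 pinned) a huge k6 drives the blood-solved k5 negative
    with pytest.raises(ValueError, match="negative solved rate"):
        derive_rates(COUNTS, {**FIXED, "k6": 1e3}, mode="paper")


def test_random_counts_self_consistent_closure_property():
    rng = np.random.default_rng(7)
    n_ok = 0
    for _ in range(25):
        counts = {k: v * rng.uniform(0.3, 3.0) for k, v in COUNTS.items()}
        fixed = {k: v * rng.uniform(0.3, 3.0) for k, v in FIXED.items()}
        try:
            d = derive_rates(counts, fixed, mode="self_consistent")
        except ValueError:
            continue  # infeasible draw
        n_ok += 1
        for name, r in d.residuals.items():
            assert abs(r) < 1e-6 * max(fixed["ksyn_imm"], 1.0), name
    assert n_ok >= 10  # the property was actually exercised
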