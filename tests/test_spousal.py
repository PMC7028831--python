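import numpy as np
import pandas as pd
import pytest

from exped.simulate import simulate_spousal_from_correlations
from exped.spousal import (
    LRTResult,
    PARAM_NAMES,
    ROLES,
    SpousalFamilyRecord,
    SpousalModelError,
    assemble_spousal_dataset,
    battery_table,
    build_role_correlation_matrix,
    classify_mechanism,
    fit_spousal_model,
    joint_resemblance_test,
    n_constraints,
    run_hypothesis_battery,
)

from .conftest import make_pedigree

TABLE_PARAMS = {
    "r1": 0.20, "r2_MZ": 0.11, "r2_DZ": 0.11,
    "r3_MZ": 0.06, "r3_DZ": 0.12, "r4": 0.35,
    "r_po": 0.22, "r_pos": 0.10, "r_tw_MZ": 0.58, "r_tw_DZ": 0.40,
}


# ---------------------------------------------------------------------------
# Correlation structure
# ---------------------------------------------------------------------------

def test_role_matrix_structure():
    for z in ("MZ", "DZ"):
        R = build_role_correlation_matrix(TABLE_PARAMS, z)
        np.testing.assert_allclose(R, R.T)
        np.testing.assert_allclose(np.diag(R), 1.0)
        ix = {r: i for i, r in enumerate(ROLES)}
        assert R[ix["father"], ix["mother"]] == 0.35                 # r4
        assert R[ix["twin1"], ix["spouse1"]] == 0.20                 # r1
        assert R[ix["twin2"], ix["spouse2"]] == 0.20
        assert R[ix["twin1"], ix["spouse2"]] == 0.11                 # r2
        assert R[ix["spouse1"], ix["spouse2"]] == (0.06 if z == "MZ" else 0.12)
        assert R[ix["twin1"], ix["twin2"]] == (0.58 if z == "MZ" else 0.40)
        # positive definite with the completed nuisance correlations
        assert np.linalg.eigvalsh(R).min() > 0


# ---------------------------------------------------------------------------
# Constraints
# ---------------------------------------------------------------------------

def test_constraint_degrees_of_freedom():
    assert n_constraints(None) == 0
    assert n_constraints({"fix": {"r1": 0.0}}) == 1
    assert n_constraints({"tie": [["r1", "r2_MZ", "r2_DZ"]]}) == 2
    assert n_constraints({"tie": [["r2_MZ", "r3_MZ"], ["r2_DZ", "r3_DZ"]]}) == 2
    # fixing one member of a tie group fixes the whole group
    assert n_constraints({"fix": {"r1": 0.0}, "tie": [["r1", "r4"]]}) == 2


def test_unknown_parameter_rejected():
    with pytest.raises(SpousalModelError, match="unknown parameter"):
        n_constraints({"fix": {"r9": 0.0}})


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

def _phen(rows):
    return pd.DataFrame(rows, columns=["participant_id", "value", "age", "sex"])


def test_assemble_dataset_roles_and_missingness():
    ped = make_pedigree("f1", [
        ("F", None, None, "male", 1950, None, "M"),
        ("M", None, None, "female", 1952, None, "F"),
        ("T1", "F", "M", "male", 1978, "mz", "S1"),
        ("T2", "F", "M", "male", 1978, "mz", None),
        ("S1", None, None, "female", 1979, None, "T1"),
    ])
    phen = _phen([
        ("F", 1.0, 55.0, "male"),
        ("T1", 0.3, 27.0, "male"),
        ("T2", -0.2, 27.0, "male"),
        ("S1", 0.4, 26.0, "female"),
        # mother unphenotyped, spouse2 nonexistent
    ])
    recs = assemble_spousal_dataset([ped], phen)
    assert len(recs) == 1
    r = recs[0]
    assert r.zygosity == "MZ"
    np.testing.assert_allclose(
        r.y, [1.0, np.nan, 0.3, -0.2, 0.4, np.nan])
    assert r.sex[0] == 0.0 and r.sex[4] == 1.0


def test_assemble_dataset_drops_dos_and_empty():
    dos = make_pedigree("f2", [
        ("F", None, None, "male", 1950, None, "M"),
        ("M", None, None, "female", 1952, None, "F"),
        ("T1", "F", "M", "male", 1978, None, None),
        ("T2", "F", "M", "female", 1978, None, None),
    ])
    phen = _phen([("T1", 0.1, 27.0, "male"), ("T2", 0.2, 27.0, "female")])
    assert assemble_spousal_dataset([dos], phen) == []


# ---------------------------------------------------------------------------
# Estimation
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def table_records():
    return simulate_spousal_from_correlations(
        TABLE_PARAMS, n_families=3000, sigma2=1.3, seed=99)


def test_fit_recovers_generating_correlations(table_records):
    fit = fit_spousal_model(table_records, seed=1)
    assert fit.converged
    for name in ("r1", "r4", "r_tw_MZ", "r_tw_DZ", "r_po"):
        assert fit.correlations[name] == pytest.approx(
            TABLE_PARAMS[name], abs=0.05), name
    assert fit.sigma2 == pytest.approx(1.3, rel=0.08)
    assert fit.n_families == 3000
    # attribute passthrough
    assert fit.r1 == fit.correlations["r1"]


def test_constrained_fit_respects_constraints(table_records):
    fit = fit_spousal_model(
        table_records,
        constraints={"fix": {"r1": 0.0}, "tie": [["r2_MZ", "r2_DZ"]]},
        seed=1,
    )
    assert fit.correlations["r1"] == 0.0
    assert fit.correlations["r2_MZ"] == fit.correlations["r2_DZ"]
    base = fit_spousal_model(table_records, seed=1)
    assert base.log_likelihood >= fit.log_likelihood - 1e-4


def test_free_variances_recover_common_scale(table_records):
    fit = fit_spousal_model(table_records[:1500], free_variances=True, seed=2)
    np.testing.assert_allclose(fit.variances, 1.3, rtol=0.15)


def test_fit_handles_missing_members(table_records):
    rng = np.random.default_rng(0)
    records = []
    for r in table_records[:1200]:
        y = r.y.copy()
        # knock out each spouse independently 30% of the time
        for k in (4, 5):
            if rng.random() < 0.3:
                y[k] = np.nan
        records.append(SpousalFamilyRecord(r.zygosity, y, r.age, r.sex))
    fit = fit_spousal_model(records, seed=3)
    assert fit.converged
    assert fit.correlations["r1"] == pytest.approx(0.20, abs=0.09)
    assert fit.correlations["r4"] == pytest.approx(0.35, abs=0.09)


# ---------------------------------------------------------------------------
# Hypothesis battery
# ---------------------------------------------------------------------------

def test_battery_labels_and_dfs(table_records):
    base, results = run_hypothesis_battery(table_records[:800], seed=4)
    table = battery_table(results)
    assert list(table["hypothesis"]) == [
        "r1=0", "r4=0", "r1=r2", "r2=r3", "r2_MZ=r2_DZ", "r3_MZ=r3_DZ",
        "r4=r1"]
    assert list(table["df"]) == [1, 1, 2, 2, 1, 1, 1]
    assert (table["delta_minus2ll"] >= 0).all()
    assert ((0 <= table["p"]) & (table["p"] <= 1)).all()


def test_battery_detects_resemblance_and_excess_parent_correlation(table_records):
    """Under the generating structure r1 > 0, r4 > 0, and r4 > r1."""
    base, results = run_hypothesis_battery(table_records, seed=4)
    by = {r.hypothesis_label: r for r in results}
    assert by["r1=0"].supported          # spousal resemblance present
    assert by["r4=0"].supported
    assert by["r4=r1"].supported         # parents correlate more strongly


def test_joint_resemblance_test(table_records):
    res = joint_resemblance_test(table_records)
    assert res.df == 2
    assert res.supported
    assert res.p < 0.001


def test_battery_retains_true_equalities():
    """Data generated with r2 = r3 and no zygosity differences should not
    reject those equalities."""
    params = dict(TABLE_PARAMS)
    params.update({"r2_MZ": 0.10, "r2_DZ": 0.10,
                   "r3_MZ": 0.10, "r3_DZ": 0.10})
    records = simulate_spousal_from_correlations(params, 2500, seed=123)
    base, results = run_hypothesis_battery(records, seed=5)
    by = {r.hypothesis_label: r for r in results}
    assert not by["r2=r3"].supported
    assert not by["r2_MZ=r2_DZ"].supported
    assert not by["r3_MZ=r3_DZ"].supported


# ---------------------------------------------------------------------------
# Mechanism classification (pure function)
# ---------------------------------------------------------------------------

def _result(label, p, supported):
    return LRTResult(label, 0.0, 1, p, supported)


def _battery(support):
    return [_result(lbl, 0.001 if s else 0.6, s)
            for lbl, s in support.items()]


def test_classify_assortment_by_zygosity_pattern():
    flags = classify_mechanism(_battery({
        "r1=0": True, "r4=0": True, "r1=r2": True, "r2=r3": True,
        "r2_MZ=r2_DZ": True, "r3_MZ=r3_DZ": True, "r4=r1": False,
    }))
    assert flags["spousal_resemblance"]
    assert flags["phenotypic_assortment"]
    assert not flags["social_homogamy"]
    assert not flags["marital_interaction"]


def test_classify_homogamy_pattern():
    flags = classify_mechanism(_battery({
        "r1=0": True, "r4=0": True, "r1=r2": True, "r2=r3": False,
        "r2_MZ=r2_DZ": False, "r3_MZ=r3_DZ": False, "r4=r1": False,
    }))
    assert flags["spousal_resemblance"]
    assert flags["social_homogamy"]
    assert not flags["phenotypic_assortment"]
    assert flags["partial_assortment"]   # r1 > r2 still rejected


def test_classify_interaction_pattern():
    flags = classify_mechanism(_battery({
        "r1=0": True, "r4=0": True, "r1=r2": False, "r2=r3": False,
        "r2_MZ=r2_DZ": False, "r3_MZ=r3_DZ": False, "r4=r1": True,
    }))
    assert flags["marital_interaction"]
    assert not flags["phenotypic_assortment"]


def test_classify_no_resemblance():
    flags = classify_mechanism(_battery({
        "r1=0": False, "r4=0": False, "r1=r2": False, "r2=r3": False,
        "r2_MZ=r2_DZ": False, "r3_MZ=r3_DZ": False, "r4=r1": False,
    }))
    assert not flags["spousal_resemblance"]
    assert not flags["social_homogamy"]
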