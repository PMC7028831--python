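import numpy as np
import pandas as pd
import pytest
from scipy import stats

from exped.pedigree import relationship_matrices
from exped.simulate import SimulationConfig, generate_structure, simulate_acde_phenotypes
from exped.varcomp import (
    Block,
    ModelSpecError,
    VarCompSpec,
    assemble_blocks,
    block_loglik,
    block_sigma,
    compare_models,
    fit_varcomp,
    fit_varcomp_pedigrees,
    lrt,
    total_loglik,
)

from .conftest import make_pedigree


# ---------------------------------------------------------------------------
# Specification validation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("comps, message", [
    (("A", "C"), "E must always"),
    (("D", "E"), "alongside A"),
    (("A", "Q", "E"), "unknown components"),
])
def test_spec_validation(comps, message):
    with pytest.raises(ModelSpecError, match=message):
        VarCompSpec(free_components=comps)


def test_spec_canonical_name():
    assert VarCompSpec(("E", "A", "C")).name == "ACE"
    assert VarCompSpec(("A", "C", "D", "E")).name == "ACDE"


# ---------------------------------------------------------------------------
# Likelihood oracle
# ---------------------------------------------------------------------------

def _random_block(ped, rng):
    mats = relationship_matrices(ped, "full")
    k = len(mats.member_order)
    y = rng.standard_normal(k)
    X = np.column_stack([np.ones(k), rng.standard_normal((k, 3))])
    return Block("f", list(mats.member_order), y, X, mats.A, mats.D, mats.H)


def test_block_loglik_matches_scipy_dense(extended_family, three_generations):
    """Cholesky-based block log-likelihood equals the dense MVN density."""
    rng = np.random.default_rng(7)
    for ped in (extended_family, three_generations):
        block = _random_block(ped, rng)
        variances = {"A": 0.3, "D": 0.15, "C": 0.2, "E": 0.5}
        beta = rng.standard_normal(4)
        expected = stats.multivariate_normal.logpdf(
            block.y,
            mean=block.X @ beta,
            cov=block_sigma(block, variances),
        )
        assert block_loglik(block, variances, beta) == pytest.approx(expected)


def test_block_loglik_single_individual(extended_family):
    """A singleton block reduces to the scalar normal density."""
    b = _random_block(extended_family, np.random.default_rng(3))
    single = Block("f", b.member_ids[:1], b.y[:1], b.X[:1],
                   b.A[:1, :1], b.D[:1, :1], b.H[:1, :1])
    variances = {"A": 0.0, "D": 0.0, "C": 0.0, "E": 2.0}
    beta = np.zeros(4)
    mu = float(single.X[0] @ beta)
    expected = stats.norm.logpdf(single.y[0], mu, np.sqrt(2.0))
    assert block_loglik(single, variances, beta) == pytest.approx(expected)


def test_block_loglik_permutation_invariant(extended_family):
    rng = np.random.default_rng(11)
    block = _random_block(extended_family, rng)
    perm = rng.permutation(len(block.y))
    permuted = Block(
        "f", [block.member_ids[i] for i in perm],
        block.y[perm], block.X[perm],
        block.A[np.ix_(perm, perm)], block.D[np.ix_(perm, perm)],
        block.H[np.ix_(perm, perm)],
    )
    variances = {"A": 0.25, "D": 0.1, "C": 0.25, "E": 0.4}
    beta = np.array([0.1, -0.2, 0.3, 0.0])
    assert block_loglik(block, variances, beta) == pytest.approx(
        block_loglik(permuted, variances, beta))


def test_block_loglik_rejects_non_pd(extended_family):
    block = _random_block(extended_family, np.random.default_rng(0))
    with pytest.raises(np.linalg.LinAlgError):
        block_loglik(block, {"A": 0.0, "D": 0.0, "C": 0.0, "E": 0.0},
                     np.zeros(4))


def test_total_loglik_sums_blocks(extended_family, three_generations):
    rng = np.random.default_rng(5)
    blocks = [_random_block(extended_family, rng),
              _random_block(three_generations, rng)]
    variances = {"A": 0.2, "D": 0.1, "C": 0.2, "E": 0.5}
    beta = np.zeros(4)
    assert total_loglik(blocks, variances, beta) == pytest.approx(
        sum(block_loglik(b, variances, beta) for b in blocks))


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def test_assemble_blocks_drops_unphenotyped(extended_family):
    phen = pd.DataFrame({
        "participant_id": ["F", "M", "T1", "T2"],
        "value": [1.0, np.nan, 0.5, -0.5],
        "age": [55.0, 53.0, 27.0, 27.0],
        "sex": ["male", "female", "male", "male"],
    })
    blocks = assemble_blocks([extended_family], phen, VarCompSpec())
    assert len(blocks) == 1
    b = blocks[0]
    assert b.member_ids == ["F", "T1", "T2"]
    # relationship submatrices follow the retained members
    assert b.A[1, 2] == pytest.approx(1.0)   # MZ pair
    assert b.A[0, 1] == pytest.approx(0.5)   # father-son
    # design: intercept, centered age, sex, interaction
    assert b.X.shape == (3, 4)
    np.testing.assert_allclose(b.X[:, 0], 1.0)
    assert b.X[:, 1].sum() == pytest.approx(55 + 27 + 27 - 3 * (55 + 27 + 27) / 3)


# ---------------------------------------------------------------------------
# Estimation
# ---------------------------------------------------------------------------

def test_fit_recovers_pure_noise():
    """With i.i.d. data the E-only model recovers variance and fixed effects."""
    rng = np.random.default_rng(21)
    peds, phen_rows = [], []
    for i in range(300):
        ped = make_pedigree(f"f{i}", [
            (f"f{i}a", None, None, "male", 1970, None, None),
            (f"f{i}b", None, None, "female", 1972, None, None),
        ])
        peds.append(ped)
        for iid, sex, age in ((f"f{i}a", "male", 35.0), (f"f{i}b", "female", 33.0)):
            phen_rows.append({
                "participant_id": iid, "value": np.nan,
                "age": age + rng.normal(0, 5), "sex": sex,
            })
    phen = pd.DataFrame(phen_rows)
    beta_true = np.array([1.0, 0.05, -0.4, 0.0])
    age_c = phen["age"] - phen["age"].mean()
    sex = (phen["sex"] == "female").astype(float)
    X = np.column_stack([np.ones(len(phen)), age_c, sex, age_c * sex])
    phen["value"] = X @ beta_true + rng.normal(0, 1.5, len(phen))

    fit = fit_varcomp_pedigrees(peds, phen, VarCompSpec(("E",)), seed=4)
    assert fit.converged
    assert fit.variances["E"] == pytest.approx(1.5 ** 2, rel=0.15)
    np.testing.assert_allclose(fit.beta, beta_true, atol=0.25)
    assert fit.broad_h2 == pytest.approx(0.0)


def test_fit_matches_twin_covariances():
    """ML on twin-only data reproduces the observed twin covariances.

    With only MZ and DZ twin pairs phenotyped, the ADE model implies
    cov(MZ) = a + d and cov(DZ) = a/2 + d/4; the ML fit's implied
    covariances must track the sample covariances, and the components
    must recover the generating values.
    """
    config = SimulationConfig(
        n_families=1500,
        p_extra_sib=0.0, p_twin_spouse=0.0, p_twin_offspring=0.0,
        proportions={"A": 0.30, "C": 0.0, "D": 0.25, "E": 0.45},
        beta=(0.0, 0.0, 0.0, 0.0),
        seed=77,
    )
    peds = generate_structure(config)
    phen = simulate_acde_phenotypes(peds, config)
    # keep only the twins (parents stay in the pedigrees, unphenotyped)
    twins = phen["participant_id"].str.contains("_T")
    phen.loc[~twins, "value"] = np.nan

    # method-of-moments oracle from raw twin cross-products
    by_fam = phen[twins].dropna(subset=["value"])
    piv = by_fam.pivot_table(index="family_id", columns=by_fam.groupby(
        "family_id").cumcount(), values="value")
    mz_fams = {p.family_id for p in peds
               if any(ind.mz_group_id for ind in p)}
    cmz = piv.loc[piv.index.isin(mz_fams)].cov().iloc[0, 1]
    cdz = piv.loc[~piv.index.isin(mz_fams)].cov().iloc[0, 1]

    spec = VarCompSpec(("A", "D", "E"))
    fit = fit_varcomp_pedigrees(peds, phen, spec, seed=5)
    assert fit.converged
    a, d = fit.variances["A"], fit.variances["D"]
    # implied twin covariances track the sample moments
    assert a + d == pytest.approx(cmz, abs=0.06)
    assert a / 2 + d / 4 == pytest.approx(cdz, abs=0.06)
    # and the components recover the generating values
    assert fit.broad_h2 == pytest.approx(0.55, abs=0.06)
    assert a == pytest.approx(0.30, abs=0.15)
    assert d == pytest.approx(0.25, abs=0.15)


def test_fit_proportions_sum_to_one():
    config = SimulationConfig(n_families=250, seed=3)
    peds = generate_structure(config)
    phen = simulate_acde_phenotypes(peds, config)
    fit = fit_varcomp_pedigrees(peds, phen, VarCompSpec(), seed=1)
    assert sum(fit.proportions.values()) == pytest.approx(1.0)
    assert fit.broad_h2 == pytest.approx(
        fit.proportions["A"] + fit.proportions["D"])
    assert 0.0 <= fit.narrow_h2 <= fit.broad_h2 <= 1.0
    s = fit.summary()
    assert s["model"] == "ACDE"
    assert s["n_pedigrees"] == 250


def test_fit_requires_multiple_blocks(extended_family):
    blocks = [_random_block(extended_family, np.random.default_rng(0))]
    with pytest.raises(ValueError, match="at least 2"):
        fit_varcomp(blocks, VarCompSpec())


# ---------------------------------------------------------------------------
# Model comparison
# ---------------------------------------------------------------------------

def test_lrt_rejects_non_nested():
    spec_a = VarCompSpec(("A", "E"))
    spec_c = VarCompSpec(("C", "E"))
    from exped.varcomp import VarCompFit
    fa = VarCompFit(spec_a, {"A": 0.5, "E": 0.5}, np.zeros(4), -100.0,
                    10, 5, True, 0)
    fc = VarCompFit(spec_c, {"C": 0.5, "E": 0.5}, np.zeros(4), -101.0,
                    10, 5, True, 0)
    with pytest.raises(ModelSpecError, match="not nested"):
        lrt(fa, fc)


def test_compare_models_selection():
    """Selection keeps the simplest model when a drop is not rejected."""
    from exped.varcomp import VarCompFit

    def fit_for(comps, ll):
        v = {c: 0.2 for c in comps}
        return VarCompFit(VarCompSpec(comps), v, np.zeros(4), ll, 100, 50,
                          True, 0)

    # dropping C from ACE costs nothing -> AE should win over ACE
    full = fit_for(("A", "C", "E"), -500.0)
    ae = fit_for(("A", "E"), -500.2)        # not significant (1 df)
    e = fit_for(("E",), -540.0)             # hugely significant drop
    table = compare_models([full, ae, e])
    assert table.attrs["best_model"] == "AE"
    row = table[(table["full"] == "ACE") & (table["sub"] == "AE")].iloc[0]
    assert not row["reject"]
    row = table[(table["full"] == "AE") & (table["sub"] == "E")].iloc[0]
    assert row["reject"] and row["df"] == 1

    # if AE vs E were also non-significant, E would win
    ae2 = fit_for(("A", "E"), -539.9)
    table = compare_models([fit_for(("A", "C", "E"), -539.8), ae2, e])
    assert table.attrs["best_model"] == "E"


def test_compare_models_flags_boundary():
    from exped.varcomp import VarCompFit
    full = VarCompFit(VarCompSpec(("A", "C", "E")),
                      {"A": 0.5, "C": 1e-12, "E": 0.5}, np.zeros(4),
                      -500.0, 100, 50, True, 0)
    sub = VarCompFit(VarCompSpec(("A", "E")), {"A": 0.5, "E": 0.5},
                     np.zeros(4), -500.0, 100, 50, True, 0)
    table = compare_models([full, sub])
    assert bool(table.iloc[0]["boundary"])
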