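"""Synthetic extended twin families and phenotypes.

The generator emulates a twin-register family composition: each family
has two parents and a twin pair (MZ, same-sex DZ, or opposite-sex DZ),
optionally extra non-twin siblings, spouses of twins, and children of
twin couples.  Phenotypes are drawn from the exact model the estimators
assume — a zero-mean multivariate normal per pedigree with covariance

    Sigma = pA * A + pD * D + pC * H + pE * I

on a unit total variance, plus age/sex/age*sex fixed effects.  Dominance
and household effects are generated through this joint draw (exactly
model-consistent); allelic gene-dropping is kept separately as an
independent oracle for the additive relationship matrix.

Spousal-resemblance mechanisms are simulated at the six-role family
level: phenotypic assortment (Gaussian coupling of a spouse to the twin's
phenotype), social homogamy (a family-level social factor loading on all
members), and marital interaction (partners converging toward the couple
mean at a rate increasing with relationship duration).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .pedigree import Individual, Pedigree, relationship_matrices
from .phenotype_scoring import ActivityDefinition, ExerciseRecord
from .spousal import SpousalFamilyRecord, build_role_correlation_matrix

SURVEY_YEAR = 2005


@dataclass
class MatingConfig:
    """Mechanism generating spousal resemblance in six-role families."""

    kind: str = "random"            # random | assortment | homogamy | interaction
    mu: float = 0.0                 # assortment coupling, in [0, 1)
    s: float = 0.0                  # homogamy shared-factor variance share, [0, 1)
    lam: float = 0.0                # interaction convergence rate, >= 0 (per year)
    parent_duration: float = 20.0   # years parents have been a couple
    twin_duration: float = 5.0      # years twin couples have been together

    def __post_init__(self):
        if self.kind not in ("random", "assortment", "homogamy", "interaction"):
            raise ValueError(f"unknown mating mechanism {self.kind!r}")
        if not (0.0 <= self.mu < 1.0) or not (0.0 <= self.s < 1.0):
            raise ValueError("mu and s must lie in [0, 1)")
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic family generator.

    Defaults approximate the register's composition: zygosity mix close
    to the observed MZ / same-sex-DZ / opposite-sex-DZ shares, parents in
    their late forties, twins in their late twenties, and unit-variance
    phenotypes split into the four ACDE proportions.
    """

    n_families: int = 1000
    zygosity_mix: tuple[float, float, float] = (0.46, 0.28, 0.26)  # MZ, DZss, DOS
    p_extra_sib: float = 0.34       # per potential extra sibling slot
    max_extra_sibs: int = 2
    p_twin_spouse: float = 0.25     # per twin
    p_twin_offspring: float = 0.4   # per twin couple (requires a spouse)
    parent_age: tuple[float, float] = (47.0, 7.5)     # mean, sd
    twin_age: tuple[float, float] = (28.0, 11.0)
    sib_age: tuple[float, float] = (27.5, 12.0)
    spouse_age_offset_sd: float = 3.0
    proportions: dict = field(default_factory=lambda: {
        "A": 0.19, "C": 0.20, "D": 0.21, "E": 0.40})
    household_definition: str = "full"
    beta: tuple[float, float, float, float] = (0.0, -0.01, 0.2, 0.005)
    mating: MatingConfig = field(default_factory=MatingConfig)
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.zygosity_mix) - 1.0) > 1e-8:
            raise ValueError("zygosity mix must sum to 1")
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-8:
            raise ValueError("variance proportions must sum to 1")
        if any(not (0.0 <= v <= 1.0) for v in self.proportions.values()):
            raise ValueError("variance proportions must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Family structure
# ---------------------------------------------------------------------------

def _trunc_normal(rng, mean, sd, lo, hi, size=None):
    x = rng.normal(mean, sd, size=size)
    return np.clip(x, lo, hi)


def generate_structure(config: SimulationConfig,
                       seed: Optional[int] = None) -> list[Pedigree]:
    """Generate family pedigrees under the configured composition.

    Every family has two parents and a twin pair; extra siblings, spouses
    of twins, and twin offspring are added with the configured
    probabilities.  Deterministic under the seed.  Ages are encoded as
    birth years relative to a fixed survey year.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    pedigrees: list[Pedigree] = []
    zyg_codes = rng.choice(3, size=config.n_families, p=list(config.zygosity_mix))
    for i in range(config.n_families):
        fam = f"fam{i:06d}"
        inds: dict[str, Individual] = {}

        def add(iid, father=None, mother=None, sex="male", age=None,
                mz=None, spouse=None):
            inds[iid] = Individual(
                individual_id=iid, family_id=fam,
                father_id=father, mother_id=mother, sex=sex,
                birth_year=SURVEY_YEAR - round(float(age)),
                mz_group_id=mz, spouse_id=spouse,
            )

        fid, mid = f"{fam}_F", f"{fam}_M"
        f_age = _trunc_normal(rng, *config.parent_age, 30, 90)
        m_age = _trunc_normal(rng, *config.parent_age, 30, 90)
        add(fid, sex="male", age=f_age, spouse=mid)
        add(mid, sex="female", age=m_age, spouse=fid)

        zyg = zyg_codes[i]
        twin_age = _trunc_normal(rng, *config.twin_age, 16, 65)
        if zyg == 0:        # MZ
            sexes = [("male", "male"), ("female", "female")][rng.integers(2)]
            mz = f"{fam}_mz"
        elif zyg == 1:      # same-sex DZ
            sexes = [("male", "male"), ("female", "female")][rng.integers(2)]
            mz = None
        else:               # opposite-sex DZ
            sexes = ("male", "female")
            mz = None
        t1, t2 = f"{fam}_T1", f"{fam}_T2"
        add(t1, fid, mid, sexes[0], twin_age, mz=mz)
        add(t2, fid, mid, sexes[1], twin_age, mz=mz)

        n_sibs = int(rng.binomial(config.max_extra_sibs, config.p_extra_sib))
        for b in range(n_sibs):
            sib_age = _trunc_normal(rng, *config.sib_age, 16, 65)
            # keep singleton sibs' birth years distinct from the twins'
            if round(float(sib_age)) == round(float(twin_age)):
                sib_age = sib_age + 1.0
            add(f"{fam}_B{b + 1}", fid, mid,
                "male" if rng.random() < 0.5 else "female", sib_age)

        for k, tid in enumerate((t1, t2), start=1):
            if rng.random() >= config.p_twin_spouse:
                continue
            sid = f"{fam}_S{k}"
            sp_age = np.clip(
                twin_age + rng.normal(0, config.spouse_age_offset_sd), 16, 65)
            sp_sex = "female" if inds[tid].sex == "male" else "male"
            add(sid, sex=sp_sex, age=sp_age, spouse=tid)
            inds[tid].spouse_id = sid
            if rng.random() < config.p_twin_offspring:
                oid = f"{fam}_O{k}"
                o_age = twin_age - 23.0  # may be under 16 -> non-respondent
                father = tid if inds[tid].sex == "male" else sid
                mother = sid if inds[tid].sex == "male" else tid
                add(oid, father, mother,
                    "male" if rng.random() < 0.5 else "female", max(o_age, 0.0))
        pedigrees.append(Pedigree(fam, inds))
    return pedigrees


def respondent_age(ind: Individual) -> float:
    return float(SURVEY_YEAR - ind.birth_year)


# ---------------------------------------------------------------------------
# ACDE phenotypes
# ---------------------------------------------------------------------------

def simulate_acde_phenotypes(
    pedigrees: Iterable[Pedigree],
    config: SimulationConfig,
    seed: Optional[int] = None,
    age_range: tuple[float, float] = (16.0, 65.0),
) -> pd.DataFrame:
    """Draw phenotypes from the exact ACDE pedigree model.

    Per pedigree, y = X beta + chol(Sigma) z with z standard normal and
    Sigma assembled from the pedigree's A, D, and household matrices under
    the configured proportions (unit total variance).  Members outside the
    respondent age window get NaN phenotypes (present in the pedigree but
    unphenotyped).  Age enters the mean centered at 40.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    p = config.proportions
    b0, ba, bs, bas = config.beta
    rows = []
    for ped in pedigrees:
        order = ped.member_ids
        mats = relationship_matrices(ped, config.household_definition, order)
        k = len(order)
        sigma = (p["A"] * mats.A + p["D"] * mats.D + p["C"] * mats.H
                 + p["E"] * np.eye(k))
        try:
            L = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                f"family {ped.family_id}: model covariance not positive "
                "definite"
            ) from exc
        z = rng.standard_normal(k)
        dev = L @ z
        for iid, d in zip(order, dev):
            ind = ped[iid]
            age = respondent_age(ind)
            sex = 1.0 if ind.sex == "female" else 0.0
            ac = age - 40.0
            value = b0 + ba * ac + bs * sex + bas * ac * sex + d
            if not (age_range[0] <= age <= age_range[1]):
                value = np.nan
            rows.append({
                "participant_id": iid,
                "family_id": ped.family_id,
                "value": value,
                "age": age,
                "sex": ind.sex,
            })
    return pd.DataFrame(rows)


def gene_drop(
    ped: Pedigree,
    sigma2_a: float = 1.0,
    seed: int = 0,
    n_replicates: int = 1,
) -> tuple[list[str], np.ndarray]:
    """Simulate additive (breeding) values by gene dropping.

    Founders draw N(0, sigma2_a); each non-founder is the parental mean
    plus an independent segregation deviation N(0, sigma2_a / 2); MZ
    co-twins copy their twin's value.  Returns (member_order, values) with
    values of shape (n_replicates, n_members).  The empirical covariance
    across replicates converges to sigma2_a * A, which makes this an
    independent oracle for the additive matrix recursion.
    """
    rng = np.random.default_rng(seed)
    order = ped.topological_order()
    pos = {iid: k for k, iid in enumerate(order)}
    vals = np.zeros((n_replicates, len(order)))
    mz_first: dict[str, str] = {}
    for iid in order:
        ind = ped[iid]
        i = pos[iid]
        gid = ind.mz_group_id
        if gid is not None and gid in mz_first:
            vals[:, i] = vals[:, pos[mz_first[gid]]]
        elif ind.is_founder:
            vals[:, i] = rng.normal(0.0, math.sqrt(sigma2_a), n_replicates)
        else:
            f, m = pos[ind.father_id], pos[ind.mother_id]
            seg = rng.normal(0.0, math.sqrt(sigma2_a / 2.0), n_replicates)
            vals[:, i] = 0.5 * (vals[:, f] + vals[:, m]) + seg
        if gid is not None and gid not in mz_first:
            mz_first[gid] = iid
    return order, vals


# ---------------------------------------------------------------------------
# Spousal-resemblance mechanisms (six-role families)
# ---------------------------------------------------------------------------

def _couple_converge(x: np.ndarray, y: np.ndarray, kappa: float):
    """Move each partner toward the couple mean by factor kappa."""
    m = 0.5 * (x + y)
    return x + kappa * (m - x), y + kappa * (m - y)


def simulate_mating_mechanism(
    config: SimulationConfig,
    seed: Optional[int] = None,
    heritability: float = 0.5,
) -> list[SpousalFamilyRecord]:
    """Six-role family records under a spousal-resemblance mechanism.

    All roles have unit-variance phenotypes built from a heritable
    additive part (gene-dropped from the parents) plus unique environment;
    the configured mechanism then induces spousal resemblance:

    * ``assortment`` — each spouse's phenotype is Gaussian-coupled to the
      twin's phenotype with correlation ``mu`` (and the parents to each
      other), so r1 = mu while r2 and r3 echo mu through the twin-twin
      correlation, more strongly in MZ than DZ pairs.
    * ``homogamy`` — a family-level social factor with variance share
      ``s`` enters every member symmetrically, so all spousal pairings
      correlate equally (~ s) with no zygosity difference.
    * ``interaction`` — mates pair at random, then converge toward the
      couple mean at rate 1 - exp(-lambda * duration); parents (longer
      duration) end up more alike than twin couples, so r4 > r1.
    """
    cfg = config.mating
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_families
    h2 = heritability
    is_mz = rng.random(n) < (config.zygosity_mix[0]
                             / (config.zygosity_mix[0] + config.zygosity_mix[1]))

    c2 = cfg.s if cfg.kind == "homogamy" else 0.0  # social-factor variance
    g_var = h2 * (1.0 - c2)
    e_var = (1.0 - h2) * (1.0 - c2)
    soc = math.sqrt(c2) * rng.standard_normal(n)

    def person(bv):
        return bv + rng.normal(0, math.sqrt(e_var), n) + soc

    def couple_for(phen_partner):
        """Mate phenotype, coupled to the partner under assortment."""
        base = (rng.normal(0, math.sqrt(g_var + e_var), n) + soc)
        if cfg.kind == "assortment":
            # standardize partner deviation before coupling
            dev = phen_partner - soc
            sd = math.sqrt(g_var + e_var)
            base = (cfg.mu * dev
                    + math.sqrt(1 - cfg.mu ** 2) * rng.normal(0, sd, n) + soc)
        return base

    bv_f = rng.normal(0, math.sqrt(g_var), n)
    phen_f = person(bv_f)
    phen_m = couple_for(phen_f)
    if cfg.kind == "assortment":
        # decompose the assorted mother's phenotype into a consistent
        # breeding value: BV | phen ~ N(h2 * dev, g_var * (1 - h2))
        dev_m = phen_m - soc
        bv_m = (g_var / (g_var + e_var)) * dev_m + rng.normal(
            0, math.sqrt(g_var * e_var / (g_var + e_var)), n)
    else:
        bv_m = (g_var / (g_var + e_var)) * (phen_m - soc) + rng.normal(
            0, math.sqrt(g_var * e_var / (g_var + e_var)), n)

    mid_bv = 0.5 * (bv_f + bv_m)
    seg = math.sqrt(g_var / 2.0)
    bv_t1 = mid_bv + rng.normal(0, seg, n)
    bv_t2 = np.where(is_mz, bv_t1, mid_bv + rng.normal(0, seg, n))
    phen_t1 = person(bv_t1)
    phen_t2 = person(bv_t2)
    phen_s1 = couple_for(phen_t1)
    phen_s2 = couple_for(phen_t2)

    if cfg.kind == "interaction":
        kp = 1.0 - math.exp(-cfg.lam * cfg.parent_duration)
        kt = 1.0 - math.exp(-cfg.lam * cfg.twin_duration)
        phen_f, phen_m = _couple_converge(phen_f, phen_m, kp)
        phen_t1, phen_s1 = _couple_converge(phen_t1, phen_s1, kt)
        phen_t2, phen_s2 = _couple_converge(phen_t2, phen_s2, kt)

    parent_age = rng.normal(*config.parent_age, size=(n, 2))
    twin_age = rng.normal(*config.twin_age, size=n)
    records = []
    for i in range(n):
        tw_sex = 0.0 if rng.random() < 0.5 else 1.0
        y = np.array([phen_f[i], phen_m[i], phen_t1[i], phen_t2[i],
                      phen_s1[i], phen_s2[i]])
        age = np.array([parent_age[i, 0], parent_age[i, 1],
                        twin_age[i], twin_age[i], twin_age[i], twin_age[i]])
        sex = np.array([0.0, 1.0, tw_sex, tw_sex, 1 - tw_sex, 1 - tw_sex])
        records.append(SpousalFamilyRecord(
            "MZ" if is_mz[i] else "DZ", y, age, sex))
    return records


def simulate_spousal_from_correlations(
    params: Mapping[str, float],
    n_families: int,
    mz_fraction: float = 0.62,
    sigma2: float = 1.0,
    seed: int = 0,
    parent_age: tuple[float, float] = (47.0, 7.5),
    twin_age: tuple[float, float] = (28.0, 11.0),
    beta: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0),
) -> list[SpousalFamilyRecord]:
    """Draw complete six-role records from a given correlation structure.

    ``params`` names the ten structured correlations (r1, r2_MZ, r2_DZ,
    r3_MZ, r3_DZ, r4, r_po, r_pos, r_tw_MZ, r_tw_DZ).  Used for parameter
    recovery against a printed correlation table.
    """
    rng = np.random.default_rng(seed)
    chol = {}
    for z in ("MZ", "DZ"):
        R = build_role_correlation_matrix(params, z)
        chol[z] = np.linalg.cholesky(sigma2 * R)
    b0, ba, bs, bas = beta
    records = []
    for i in range(n_families):
        z = "MZ" if rng.random() < mz_fraction else "DZ"
        dev = chol[z] @ rng.standard_normal(6)
        pa = rng.normal(*parent_age, size=2)
        ta = rng.normal(*twin_age)
        tw_sex = 0.0 if rng.random() < 0.5 else 1.0
        age = np.array([pa[0], pa[1], ta, ta, ta, ta])
        sex = np.array([0.0, 1.0, tw_sex, tw_sex, 1 - tw_sex, 1 - tw_sex])
        ac = age - 40.0
        y = b0 + ba * ac + bs * sex + bas * ac * sex + dev
        records.append(SpousalFamilyRecord(z, y, age, sex))
    return records


# ---------------------------------------------------------------------------
# Survey-record round trip
# ---------------------------------------------------------------------------

FREQ_GRID = tuple(range(1, 8))      # sessions per week


def records_from_phenotype(
    targets: Mapping[str, float],
    table: Mapping[str, ActivityDefinition],
    participant_id: str = "p1",
    seed: int = 0,
    age: float = 30.0,
    sex: str = "female",
) -> list[ExerciseRecord]:
    """Survey records whose scored MET-minutes approximate per-activity targets.

    Frequencies are integers (1-7 per week) and minutes are integers, so a
    target is realized on the nearest representable grid point; the
    relative error is bounded by half a MET-minute per session.
    """
    rng = np.random.default_rng(seed)
    records = []
    for name, target in targets.items():
        if name not in table:
            raise KeyError(f"unknown activity {name!r}")
        if target < 0:
            raise ValueError(f"negative target for {name!r}")
        if target == 0:
            continue
        met = table[name].met_value
        best = None
        for f in FREQ_GRID:
            minutes = max(round(target / (met * f)), 0)
            err = abs(met * f * minutes - target)
            if best is None or err < best[0]:
                best = (err, f, minutes)
        _, f, minutes = best
        records.append(ExerciseRecord(
            participant_id=participant_id,
            activity_name=name,
            times_per_week=float(f),
            minutes_per_session=float(minutes),
            age_at_survey=age,
            sex=sex,
        ))
    return records


def random_activity_targets(
    table: Mapping[str, ActivityDefinition],
    rng: np.random.Generator,
    max_activities: int = 3,
    mean_weekly_metmin: float = 1500.0,
) -> dict[str, float]:
    """Random per-activity weekly MET-minute targets for one participant."""
    names = list(table)
    k = int(rng.integers(0, max_activities + 1))
    chosen = rng.choice(names, size=k, replace=False)
    return {
        str(name): float(rng.gamma(2.0, mean_weekly_metmin / 2.0))
        for name in chosen
    }
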