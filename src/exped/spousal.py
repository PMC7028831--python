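"""Six-member structured-covariance model of spousal resemblance.

Families consisting of a father, mother, same-sex twin pair, and the two
twins' spouses carry information about why spouses resemble each other.
The model estimates a structured 6x6 correlation matrix by
full-information ML, with four focal correlations:

* ``r1`` — twin with own spouse (shared across zygosity),
* ``r2`` — twin with co-twin's spouse (separate for MZ and DZ),
* ``r3`` — spouse of twin 1 with spouse of twin 2 (separate by zygosity),
* ``r4`` — father with mother.

Nuisance correlations (parent-offspring, parent to offspring-spouse, and
twin-twin by zygosity) are free in all models.  A battery of
likelihood-ratio tests on this structure separates three mechanisms:

* phenotypic assortment predicts ``r1 > r2 > r3`` with MZ exceeding DZ
  for ``r2`` and ``r3``;
* social homogamy predicts ``r1 = r2 >= r3`` with no zygosity difference;
* marital interaction predicts ``r4 > r1`` (longer-exposed couples more
  alike).

Opposite-sex DZ twin families are excluded, since twin-spouse sex
pairings would otherwise differ systematically between ``r2``/``r3`` and
the within-zygosity comparisons.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import solve_triangular

from .pedigree import Pedigree

logger = logging.getLogger(__name__)

ROLES = ("father", "mother", "twin1", "twin2", "spouse1", "spouse2")
_F, _M, _T1, _T2, _S1, _S2 = range(6)

PARAM_NAMES = (
    "r1", "r2_MZ", "r2_DZ", "r3_MZ", "r3_DZ", "r4",
    "r_po", "r_pos", "r_tw_MZ", "r_tw_DZ",
)

_PENALTY = 1e10
_RBOUND = 0.99


class SpousalModelError(ValueError):
    pass


@dataclass
class SpousalFamilyRecord:
    """Phenotypes and covariates for the six roles of one twin family.

    Missing members are NaN; sex is coded 0 (male) / 1 (female).
    """

    zygosity: str               # "MZ" or "DZ"
    y: np.ndarray               # (6,)
    age: np.ndarray             # (6,)
    sex: np.ndarray             # (6,)

    def __post_init__(self):
        if self.zygosity not in ("MZ", "DZ"):
            raise SpousalModelError(f"zygosity must be MZ/DZ, got {self.zygosity!r}")
        self.y = np.asarray(self.y, dtype=float)
        self.age = np.asarray(self.age, dtype=float)
        self.sex = np.asarray(self.sex, dtype=float)


@dataclass
class LRTResult:
    hypothesis_label: str
    delta_minus2ll: float
    df: int
    p: float
    supported: bool
    estimates: dict[str, float] = field(default_factory=dict)


@dataclass
class SpousalModelFit:
    correlations: dict[str, float]
    sigma2: float
    variances: np.ndarray       # per-role variances (all sigma2 unless freed)
    beta: np.ndarray            # intercept, age, sex, age*sex
    log_likelihood: float
    n_families: int
    converged: bool
    constraints: Optional[dict] = None

    def __getattr__(self, name):
        cors = object.__getattribute__(self, "correlations")
        if name in cors:
            return cors[name]
        raise AttributeError(name)

    def summary(self) -> dict:
        return {
            "correlations": self.correlations,
            "sigma2": self.sigma2,
            "beta": list(self.beta),
            "log_likelihood": self.log_likelihood,
            "n_families": self.n_families,
            "converged": self.converged,
        }


def build_role_correlation_matrix(params: Mapping[str, float], zygosity: str) -> np.ndarray:
    """Structured 6x6 correlation matrix for one zygosity group."""
    z = zygosity
    R = np.eye(6)

    def s(i, j, v):
        R[i, j] = R[j, i] = v

    s(_F, _M, params["r4"])
    for t in (_T1, _T2):
        s(_F, t, params["r_po"])
        s(_M, t, params["r_po"])
    for sp in (_S1, _S2):
        s(_F, sp, params["r_pos"])
        s(_M, sp, params["r_pos"])
    s(_T1, _T2, params[f"r_tw_{z}"])
    s(_T1, _S1, params["r1"])
    s(_T2, _S2, params["r1"])
    s(_T1, _S2, params[f"r2_{z}"])
    s(_T2, _S1, params[f"r2_{z}"])
    s(_S1, _S2, params[f"r3_{z}"])
    return R


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

def assemble_spousal_dataset(
    pedigrees: Iterable[Pedigree],
    phenotypes: pd.DataFrame,
    value_column: str = "value",
) -> list[SpousalFamilyRecord]:
    """One record per same-sex twin family; DOS families are dropped.

    ``phenotypes`` needs columns participant_id, ``value_column``, age, sex.
    Members without phenotypes stay in the record as NaN (used downstream
    by full-information ML).  Families with no phenotyped member among the
    six roles are dropped.
    """
    phen = phenotypes.dropna(subset=[value_column]).copy()
    phen = phen.set_index(phen["participant_id"].astype(str))
    records: list[SpousalFamilyRecord] = []
    n_dos = 0
    for ped in pedigrees:
        twins = sorted(ped.twin_pairs(), key=lambda p: tuple(sorted(p)))
        if not twins:
            continue
        t1, t2 = sorted(twins[0])
        i1, i2 = ped[t1], ped[t2]
        if i1.sex != i2.sex:
            n_dos += 1
            continue
        zyg = ("MZ" if i1.mz_group_id is not None
               and i1.mz_group_id == i2.mz_group_id else "DZ")
        role_ids = {
            "father": i1.father_id,
            "mother": i1.mother_id,
            "twin1": t1,
            "twin2": t2,
            "spouse1": i1.spouse_id,
            "spouse2": i2.spouse_id,
        }
        y = np.full(6, np.nan)
        age = np.full(6, np.nan)
        sex = np.full(6, np.nan)
        for k, role in enumerate(ROLES):
            rid = role_ids[role]
            if rid is None or rid not in phen.index:
                continue
            row = phen.loc[rid]
            y[k] = float(row[value_column])
            age[k] = float(row["age"])
            sx = row["sex"]
            sex[k] = 1.0 if sx in ("female", 1, 1.0) else 0.0
        if np.all(np.isnan(y)):
            continue
        records.append(SpousalFamilyRecord(zyg, y, age, sex))
    if n_dos:
        logger.info("dropped %d opposite-sex DZ families", n_dos)
    return records


# ---------------------------------------------------------------------------
# Constraint handling
# ---------------------------------------------------------------------------

def _resolve_constraints(constraints: Optional[dict]):
    """Return (free_names, expand) where expand maps a free vector to the
    full parameter dict.  ``constraints`` may contain ``fix`` (name->value)
    and ``tie`` (list of name groups estimated as one parameter)."""
    constraints = constraints or {}
    fixed: dict[str, float] = dict(constraints.get("fix", {}))
    ties: list[list[str]] = [list(g) for g in constraints.get("tie", [])]
    for name in set(fixed) | {n for g in ties for n in g}:
        if name not in PARAM_NAMES:
            raise SpousalModelError(f"unknown parameter {name!r}")

    rep: dict[str, str] = {}          # param -> representative
    for group in ties:
        head = group[0]
        head = rep.get(head, head)
        for name in group:
            target = rep.get(name, name)
            if target in fixed and head not in fixed:
                fixed[head] = fixed[target]
            for k, v in list(rep.items()):
                if v == target:
                    rep[k] = head
            rep[name] = head
    free_names = []
    for name in PARAM_NAMES:
        r = rep.get(name, name)
        if r in fixed:
            continue
        if r not in free_names:
            free_names.append(r)

    def expand(theta: np.ndarray) -> dict[str, float]:
        lookup = dict(zip(free_names, theta))
        out = {}
        for name in PARAM_NAMES:
            r = rep.get(name, name)
            out[name] = fixed[r] if r in fixed else lookup[r]
        return out

    def collapse(values: Mapping[str, float]) -> np.ndarray:
        # starting point for the free vector: average over tied members
        theta = []
        for fname in free_names:
            members = [n for n in PARAM_NAMES if rep.get(n, n) == fname]
            theta.append(float(np.mean([values[m] for m in members])))
        return np.asarray(theta)

    return free_names, expand, collapse


def n_constraints(constraints: Optional[dict]) -> int:
    """Degrees of freedom removed by a constraint set."""
    free_full, _, _ = _resolve_constraints(None)
    free_con, _, _ = _resolve_constraints(constraints)
    return len(free_full) - len(free_con)


# ---------------------------------------------------------------------------
# Full-information ML
# ---------------------------------------------------------------------------

class _SpousalData:
    """Records grouped by (zygosity, missingness pattern) for batched FIML."""

    def __init__(self, records: Sequence[SpousalFamilyRecord]):
        groups: dict[tuple, list[SpousalFamilyRecord]] = {}
        for r in records:
            obs = tuple(np.flatnonzero(~np.isnan(r.y)))
            groups.setdefault((r.zygosity, obs), []).append(r)
        self.groups = []
        self.n_obs = 0
        for (zyg, obs), recs in groups.items():
            obs = np.asarray(obs, dtype=int)
            Y = np.stack([r.y[obs] for r in recs])
            age = np.stack([np.nan_to_num(r.age[obs]) for r in recs])
            sex = np.stack([np.nan_to_num(r.sex[obs]) for r in recs])
            ones = np.ones_like(age)
            X = np.stack([ones, age, sex, age * sex], axis=-1)  # (n, k, 4)
            self.groups.append((zyg, obs, Y, X))
            self.n_obs += Y.size
        self.p = 4

    def profiled_nll(self, params: Mapping[str, float],
                     log_variances: Optional[np.ndarray] = None):
        """NLL with beta profiled by GLS; the common scale sigma2 is also
        profiled unless per-role variances are supplied."""
        Rs = {z: build_role_correlation_matrix(params, z) for z in ("MZ", "DZ")}
        if log_variances is not None:
            sd = np.exp(0.5 * log_variances)
            for z in Rs:
                Rs[z] = Rs[z] * np.outer(sd, sd)
        M = np.zeros((self.p, self.p))
        v = np.zeros(self.p)
        yy = 0.0
        logdet = 0.0
        cache = {}
        for zyg, obs, Y, X in self.groups:
            key = (zyg, obs.tobytes())
            if key not in cache:
                sub = Rs[zyg][np.ix_(obs, obs)]
                try:
                    cache[key] = np.linalg.cholesky(sub)
                except np.linalg.LinAlgError:
                    eig = float(np.linalg.eigvalsh(sub).min())
                    return _PENALTY * (1.0 - eig), None, None
            L = cache[key]
            n, k = Y.shape
            Yt = solve_triangular(L, Y.T, lower=True)
            Xw = solve_triangular(
                L, X.transpose(1, 0, 2).reshape(k, n * self.p), lower=True
            ).reshape(k, n, self.p)
            M += np.einsum("kni,knj->ij", Xw, Xw)
            v += np.einsum("kni,kn->i", Xw, Yt)
            yy += float((Yt ** 2).sum())
            logdet += n * 2.0 * float(np.log(np.diag(L)).sum())
        beta = np.linalg.solve(M, v)
        quad = yy - float(v @ beta)
        N = self.n_obs
        if log_variances is None:
            sigma2 = max(quad / N, 1e-300)
            nll = 0.5 * (N * math.log(2 * math.pi * sigma2) + logdet + N)
        else:
            sigma2 = 1.0
            nll = 0.5 * (N * math.log(2 * math.pi) + logdet + quad)
        return nll, beta, sigma2


def fit_spousal_model(
    records: Sequence[SpousalFamilyRecord],
    constraints: Optional[dict] = None,
    free_variances: bool = False,
    seed: int = 0,
    x0: Optional[Mapping[str, float]] = None,
    check_psd: bool = True,
) -> SpousalModelFit:
    """Full-information ML fit of the six-role correlation structure.

    ``constraints`` is a dict with optional ``fix`` (parameter -> value)
    and ``tie`` (groups of parameters estimated as one).  With
    ``free_variances`` each role gets its own variance instead of the
    default single common scale.
    """
    records = list(records)
    n_spousal = sum(
        1 for r in records
        if (~np.isnan(r.y[[_T1, _S1]])).all() or (~np.isnan(r.y[[_T2, _S2]])).all()
        or (~np.isnan(r.y[[_F, _M]])).all()
    )
    if n_spousal < 30:
        logger.warning("only %d families with an observed spousal pairing; "
                       "estimates may be unstable", n_spousal)
    data = _SpousalData(records)
    free_names, expand, collapse = _resolve_constraints(constraints)
    start_vals = {name: 0.1 for name in PARAM_NAMES}
    start_vals.update({"r_tw_MZ": 0.4, "r_tw_DZ": 0.25})
    if x0:
        start_vals.update(x0)
    theta0 = np.clip(collapse(start_vals), -_RBOUND + 0.01, _RBOUND - 0.01)
    nv = 6 if free_variances else 0
    if free_variances:
        theta0 = np.concatenate([theta0, np.zeros(6)])

    def objective(theta):
        params = expand(theta[:len(free_names)])
        logv = theta[len(free_names):] if free_variances else None
        nll, _, _ = data.profiled_nll(params, logv)
        return nll

    bounds = [(-_RBOUND, _RBOUND)] * len(free_names) + [(-8.0, 8.0)] * nv
    res = optimize.minimize(objective, theta0, method="L-BFGS-B",
                            bounds=bounds, options={"maxiter": 1000})
    params = expand(res.x[:len(free_names)])
    logv = res.x[len(free_names):] if free_variances else None
    nll, beta, sigma2 = data.profiled_nll(params, logv)
    if beta is None:
        raise SpousalModelError(
            "implied correlation matrix not positive definite at the "
            "optimum; inspect the data"
        )
    if check_psd:
        for z in ("MZ", "DZ"):
            eigs = np.linalg.eigvalsh(build_role_correlation_matrix(params, z))
            if eigs.min() < -1e-8:
                raise SpousalModelError(
                    f"implied {z} correlation matrix not positive "
                    "semidefinite at the optimum; inspect the data"
                )
    variances = (np.exp(logv) * sigma2 if free_variances
                 else np.full(6, sigma2))
    return SpousalModelFit(
        correlations={k: float(v) for k, v in params.items()},
        sigma2=float(sigma2),
        variances=variances,
        beta=beta,
        log_likelihood=-float(nll),
        n_families=len(records),
        converged=bool(res.success),
        constraints=constraints,
    )


# ---------------------------------------------------------------------------
# Hypothesis battery and mechanism classification
# ---------------------------------------------------------------------------

BATTERY = (
    # label, constraints, df, direction check (params -> bool)
    ("r1=0", {"fix": {"r1": 0.0}}, 1,
     lambda c: c["r1"] > 0),
    ("r4=0", {"fix": {"r4": 0.0}}, 1,
     lambda c: c["r4"] > 0),
    ("r1=r2", {"tie": [["r1", "r2_MZ", "r2_DZ"]]}, 2,
     lambda c: c["r1"] > 0.5 * (c["r2_MZ"] + c["r2_DZ"])),
    ("r2=r3", {"tie": [["r2_MZ", "r3_MZ"], ["r2_DZ", "r3_DZ"]]}, 2,
     lambda c: 0.5 * (c["r2_MZ"] + c["r2_DZ"]) > 0.5 * (c["r3_MZ"] + c["r3_DZ"])),
    ("r2_MZ=r2_DZ", {"tie": [["r2_MZ", "r2_DZ"]]}, 1,
     lambda c: c["r2_MZ"] > c["r2_DZ"]),
    ("r3_MZ=r3_DZ", {"tie": [["r3_MZ", "r3_DZ"]]}, 1,
     lambda c: c["r3_MZ"] > c["r3_DZ"]),
    ("r4=r1", {"tie": [["r1", "r4"]]}, 1,
     lambda c: c["r4"] > c["r1"]),
)

_LL_TOL = 1e-4


def run_hypothesis_battery(
    records: Sequence[SpousalFamilyRecord],
    alpha: float = 0.05,
    base_fit: Optional[SpousalModelFit] = None,
    seed: int = 0,
    labels: Optional[Sequence[str]] = None,
) -> tuple[SpousalModelFit, list[LRTResult]]:
    """Fit the base model and the seven constrained models of the battery.

    Each row compares a constrained model against the base by a naive
    chi-squared likelihood-ratio test; ``supported`` additionally requires
    the base-model point estimates to lie in the hypothesized direction.
    If a constrained fit beats the base (optimizer slack), the base is
    refit warm-started from the constrained solution.
    """
    if base_fit is None:
        base_fit = fit_spousal_model(records, seed=seed)
    results: list[LRTResult] = []
    for label, constraints, df, direction in BATTERY:
        if labels is not None and label not in labels:
            continue
        sub = fit_spousal_model(records, constraints=constraints, seed=seed,
                                x0=base_fit.correlations)
        delta = 2.0 * (base_fit.log_likelihood - sub.log_likelihood)
        if delta < -_LL_TOL:
            logger.warning("constrained fit %s beat base; refitting base", label)
            base_fit = fit_spousal_model(records, seed=seed,
                                         x0=sub.correlations)
            delta = 2.0 * (base_fit.log_likelihood - sub.log_likelihood)
            if delta < -_LL_TOL:
                raise SpousalModelError(
                    f"constrained model {label!r} exceeds base log-likelihood"
                )
        delta = max(delta, 0.0)
        p = float(stats.chi2.sf(delta, df))
        results.append(LRTResult(
            hypothesis_label=label,
            delta_minus2ll=delta,
            df=df,
            p=p,
            supported=bool(p < alpha and direction(base_fit.correlations)),
            estimates=dict(base_fit.correlations),
        ))
    return base_fit, results


def joint_resemblance_test(
    records: Sequence[SpousalFamilyRecord],
    base_fit: Optional[SpousalModelFit] = None,
    alpha: float = 0.05,
    seed: int = 0,
) -> LRTResult:
    """Joint 2-df test of r1 = r4 = 0 (the combined-resemblance variant)."""
    if base_fit is None:
        base_fit = fit_spousal_model(records, seed=seed)
    sub = fit_spousal_model(
        records, constraints={"fix": {"r1": 0.0, "r4": 0.0}}, seed=seed,
        x0=base_fit.correlations,
    )
    delta = max(0.0, 2.0 * (base_fit.log_likelihood - sub.log_likelihood))
    p = float(stats.chi2.sf(delta, 2))
    c = base_fit.correlations
    return LRTResult("r1=r4=0", delta, 2, p,
                     bool(p < alpha and (c["r1"] > 0 or c["r4"] > 0)),
                     estimates=dict(c))


def classify_mechanism(
    battery: Sequence[LRTResult],
    alpha: float = 0.05,
) -> dict[str, bool]:
    """Boolean mechanism flags from the battery outcomes.

    * ``spousal_resemblance`` — either zero-correlation test rejects in the
      positive direction.
    * ``phenotypic_assortment`` — the zygosity comparisons both reject in
      the MZ > DZ direction, or the full ordering r1 > r2 > r3 rejects;
      ``partial_assortment`` records an r1 > r2 rejection alone.
    * ``social_homogamy`` — resemblance present while all equality tests
      that discriminate assortment (r2=r3 and the zygosity comparisons)
      are retained.
    * ``marital_interaction`` — r4 = r1 rejected with the estimate of r4
      above r1.
    """
    by_label = {r.hypothesis_label: r for r in battery}

    def rejected(label):
        r = by_label[label]
        return r.p < alpha and r.supported

    resemblance = rejected("r1=0") or rejected("r4=0")
    zygosity_assort = rejected("r2_MZ=r2_DZ") and rejected("r3_MZ=r3_DZ")
    ordering_assort = rejected("r1=r2") and rejected("r2=r3")
    homogamy = resemblance and not (
        rejected("r2=r3") or rejected("r2_MZ=r2_DZ") or rejected("r3_MZ=r3_DZ")
    )
    return {
        "spousal_resemblance": resemblance,
        "phenotypic_assortment": zygosity_assort or ordering_assort,
        "partial_assortment": rejected("r1=r2"),
        "social_homogamy": homogamy,
        "marital_interaction": rejected("r4=r1"),
    }


def battery_table(battery: Sequence[LRTResult]) -> pd.DataFrame:
    """Battery results as a table shaped like a hypothesis-summary table."""
    return pd.DataFrame([
        {
            "hypothesis": r.hypothesis_label,
            "delta_minus2ll": r.delta_minus2ll,
            "df": r.df,
            "p": r.p,
            "supported": r.supported,
        }
        for r in battery
    ])
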