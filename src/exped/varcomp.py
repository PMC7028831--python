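"""Maximum-likelihood ACDE variance components on pedigree blocks.

The phenotype vector of each pedigree is modelled as multivariate normal,

    y ~ N(X beta, Sigma),
    Sigma = sigma2_A * A + sigma2_D * D + sigma2_C * H + sigma2_E * I,

where A and D are the expected additive and dominance relationship
matrices, H is a 0/1 household-sharing indicator, and X holds an
intercept, centered age, sex, and age*sex.  The total log-likelihood is
the sum over independent pedigree blocks; missing phenotypes are handled
by subsetting each block to its phenotyped members (full-information ML
under ignorable missingness).

Fitting profiles the fixed effects by generalized least squares inside
each objective evaluation and optimizes the variance components on a log
scale (keeping them non-negative) with seeded random restarts.  Blocks
with identical relationship structure are batched so datasets of
thousands of families evaluate in a few matrix factorizations.
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

from .pedigree import Pedigree, relationship_matrices

logger = logging.getLogger(__name__)

COMPONENTS = ("A", "C", "D", "E")
_PENALTY = 1e10


class ModelSpecError(ValueError):
    pass


@dataclass(frozen=True)
class VarCompSpec:
    """Which variance components are free, and the household definition."""

    free_components: tuple[str, ...] = ("A", "C", "D", "E")
    household_definition: str = "full"
    covariates: tuple[str, ...] = ("age", "sex", "age_sex")

    def __post_init__(self):
        comps = tuple(self.free_components)
        unknown = set(comps) - set(COMPONENTS)
        if unknown:
            raise ModelSpecError(f"unknown components {sorted(unknown)}")
        if "E" not in comps:
            raise ModelSpecError("E must always be a free component")
        if "D" in comps and "A" not in comps:
            raise ModelSpecError("D may only be free alongside A")

    @property
    def name(self) -> str:
        order = {c: i for i, c in enumerate(COMPONENTS)}
        return "".join(sorted(self.free_components, key=order.get))


@dataclass
class Block:
    """One pedigree's phenotyped members, ready for likelihood evaluation."""

    family_id: str
    member_ids: list[str]
    y: np.ndarray            # (k,)
    X: np.ndarray            # (k, p)
    A: np.ndarray            # (k, k)
    D: np.ndarray
    H: np.ndarray


@dataclass
class VarCompFit:
    spec: VarCompSpec
    variances: dict[str, float]
    beta: np.ndarray
    log_likelihood: float
    n_individuals: int
    n_pedigrees: int
    converged: bool
    seed: int
    proportions: dict[str, float] = field(init=False)
    broad_h2: float = field(init=False)
    narrow_h2: float = field(init=False)

    def __post_init__(self):
        total = sum(self.variances.values())
        self.proportions = {c: v / total for c, v in self.variances.items()}
        self.broad_h2 = (self.proportions.get("A", 0.0)
                         + self.proportions.get("D", 0.0))
        self.narrow_h2 = self.proportions.get("A", 0.0)

    @property
    def n_free_components(self) -> int:
        return len(self.spec.free_components)

    def summary(self) -> dict:
        return {
            "model": self.spec.name,
            "household": self.spec.household_definition,
            "variances": self.variances,
            "proportions": self.proportions,
            "broad_h2": self.broad_h2,
            "narrow_h2": self.narrow_h2,
            "beta": list(self.beta),
            "log_likelihood": self.log_likelihood,
            "n_individuals": self.n_individuals,
            "n_pedigrees": self.n_pedigrees,
            "converged": self.converged,
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

def _encode_sex(values: pd.Series) -> np.ndarray:
    if values.dtype == object:
        return (values == "female").to_numpy(dtype=float)
    return values.to_numpy(dtype=float)


def assemble_blocks(
    pedigrees: Iterable[Pedigree],
    phenotypes: pd.DataFrame,
    spec: VarCompSpec,
    value_column: str = "value",
) -> list[Block]:
    """Build per-pedigree likelihood blocks restricted to phenotyped members.

    ``phenotypes`` needs columns ``participant_id``, ``value_column``,
    ``age``, ``sex``.  Age is centered at the phenotyped-sample mean; sex
    is coded 0 (male) / 1 (female).
    """
    phen = phenotypes.dropna(subset=[value_column]).copy()
    if phen["participant_id"].duplicated().any():
        dup = phen.loc[phen["participant_id"].duplicated(), "participant_id"]
        raise ValueError(
            f"duplicate participant ids in phenotype table, e.g. {dup.iloc[0]!r}"
        )
    phen = phen.set_index(phen["participant_id"].astype(str))
    age_mean = float(phen["age"].mean())
    sex_num = _encode_sex(phen["sex"])
    phen["_age_c"] = phen["age"].to_numpy(dtype=float) - age_mean
    phen["_sex"] = sex_num

    blocks: list[Block] = []
    for ped in pedigrees:
        members = [iid for iid in ped.member_ids if iid in phen.index]
        if not members:
            logger.debug("family %s: no phenotyped members, block skipped",
                         ped.family_id)
            continue
        mats = relationship_matrices(ped, spec.household_definition, order=ped.member_ids)
        pos = {iid: k for k, iid in enumerate(mats.member_order)}
        idx = np.array([pos[m] for m in members])
        sub = phen.loc[members]
        y = sub[value_column].to_numpy(dtype=float)
        age_c = sub["_age_c"].to_numpy()
        sex = sub["_sex"].to_numpy()
        X = np.column_stack([np.ones_like(y), age_c, sex, age_c * sex])
        blocks.append(Block(
            family_id=ped.family_id,
            member_ids=members,
            y=y,
            X=X,
            A=mats.A[np.ix_(idx, idx)],
            D=mats.D[np.ix_(idx, idx)],
            H=mats.H[np.ix_(idx, idx)],
        ))
    return blocks


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def block_sigma(block: Block, variances: Mapping[str, float]) -> np.ndarray:
    k = len(block.y)
    return (
        variances.get("A", 0.0) * block.A
        + variances.get("D", 0.0) * block.D
        + variances.get("C", 0.0) * block.H
        + variances.get("E", 0.0) * np.eye(k)
    )


def block_loglik(
    block: Block,
    variances: Mapping[str, float],
    beta: np.ndarray,
) -> float:
    """Multivariate-normal log density of one block's residuals.

    Raises ``np.linalg.LinAlgError`` if Sigma is not positive definite at
    the evaluated point.
    """
    sigma = block_sigma(block, variances)
    L = np.linalg.cholesky(sigma)
    r = block.y - block.X @ np.asarray(beta)
    z = solve_triangular(L, r, lower=True)
    k = len(r)
    return -0.5 * (k * math.log(2 * math.pi) + 2 * np.log(np.diag(L)).sum()
                   + z @ z)


class _GroupedData:
    """Blocks batched by identical (A, D, H) structure for fast evaluation."""

    def __init__(self, blocks: Sequence[Block]):
        groups: dict[bytes, list[Block]] = {}
        for b in blocks:
            key = (np.round(np.concatenate(
                [b.A.ravel(), b.D.ravel(), b.H.ravel()]), 9).tobytes())
            groups.setdefault(key, []).append(b)
        self.groups = []
        self.n_obs = 0
        for blist in groups.values():
            Y = np.stack([b.y for b in blist])          # (n, k)
            X = np.stack([b.X for b in blist])          # (n, k, p)
            b0 = blist[0]
            self.groups.append((b0.A, b0.D, b0.H, Y, X))
            self.n_obs += Y.size
        self.p = blocks[0].X.shape[1]
        self.pd_failures = 0

    def profiled_nll(self, variances: Mapping[str, float]):
        """Negative log-likelihood with beta profiled out by GLS.

        Returns (nll, beta) or (penalty, None) when any Sigma is not PD.
        """
        M = np.zeros((self.p, self.p))
        v = np.zeros(self.p)
        yy = 0.0
        logdet = 0.0
        for A, D, H, Y, X in self.groups:
            k = A.shape[0]
            sigma = (
                variances.get("A", 0.0) * A
                + variances.get("D", 0.0) * D
                + variances.get("C", 0.0) * H
                + variances.get("E", 0.0) * np.eye(k)
            )
            try:
                L = np.linalg.cholesky(sigma)
            except np.linalg.LinAlgError:
                self.pd_failures += 1
                return _PENALTY, None
            n = Y.shape[0]
            Yt = solve_triangular(L, Y.T, lower=True)            # (k, n)
            Xw = solve_triangular(
                L, X.transpose(1, 0, 2).reshape(k, n * self.p), lower=True
            ).reshape(k, n, self.p)
            M += np.einsum("kni,knj->ij", Xw, Xw)
            v += np.einsum("kni,kn->i", Xw, Yt)
            yy += float((Yt ** 2).sum())
            logdet += n * 2.0 * float(np.log(np.diag(L)).sum())
        beta = np.linalg.solve(M, v)
        quad = yy - float(v @ beta)
        nll = 0.5 * (self.n_obs * math.log(2 * math.pi) + logdet + quad)
        return nll, beta


def total_loglik(
    blocks: Sequence[Block],
    variances: Mapping[str, float],
    beta: np.ndarray,
) -> float:
    """Sum of block log-likelihoods at fixed variances and beta."""
    return sum(block_loglik(b, variances, beta) for b in blocks)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def fit_varcomp(
    blocks: Sequence[Block],
    spec: VarCompSpec,
    seed: int = 0,
    n_restarts: int = 3,
) -> VarCompFit:
    """ML fit of the variance components named in ``spec``.

    Variances are parameterized as ``exp(theta)`` (non-negative by
    construction); fixed effects are profiled by GLS inside every
    objective evaluation.  ``n_restarts`` seeded restarts guard against
    local optima; the best is kept.
    """
    blocks = list(blocks)
    if len(blocks) < 2:
        raise ValueError("need at least 2 pedigree blocks")
    data = _GroupedData(blocks)
    comps = list(spec.free_components)
    m = len(comps)

    # crude scale from pooled OLS residual variance
    Xall = np.concatenate([b.X for b in blocks])
    yall = np.concatenate([b.y for b in blocks])
    coef, *_ = np.linalg.lstsq(Xall, yall, rcond=None)
    v0 = float(np.var(yall - Xall @ coef))
    v0 = max(v0, 1e-12)

    def objective(theta: np.ndarray) -> float:
        variances = dict(zip(comps, np.exp(theta)))
        nll, _ = data.profiled_nll(variances)
        return nll

    rng = np.random.default_rng(seed)
    theta0 = np.full(m, math.log(v0 / m))
    best = None
    for restart in range(max(1, n_restarts)):
        start = theta0 if restart == 0 else theta0 + rng.normal(0, 1.0, m)
        res = optimize.minimize(
            objective, start, method="L-BFGS-B",
            bounds=[(math.log(v0) - 25.0, math.log(v0) + 6.0)] * m,
            options={"maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
    variances = {c: 0.0 for c in COMPONENTS}
    variances.update(dict(zip(comps, np.exp(best.x))))
    nll, beta = data.profiled_nll({c: variances[c] for c in comps})
    converged = bool(best.success) and nll < _PENALTY / 2
    if not converged:
        logger.warning("fit %s did not converge cleanly: %s", spec.name,
                       best.message)
    return VarCompFit(
        spec=spec,
        variances=variances,
        beta=beta,
        log_likelihood=-nll,
        n_individuals=sum(len(b.y) for b in blocks),
        n_pedigrees=len(blocks),
        converged=converged,
        seed=seed,
    )


def fit_varcomp_pedigrees(
    pedigrees: Iterable[Pedigree],
    phenotypes: pd.DataFrame,
    spec: Optional[VarCompSpec] = None,
    value_column: str = "value",
    seed: int = 0,
    n_restarts: int = 3,
) -> VarCompFit:
    """Convenience wrapper: assemble blocks from pedigrees, then fit."""
    if spec is None:
        spec = VarCompSpec()
    blocks = assemble_blocks(pedigrees, phenotypes, spec, value_column)
    return fit_varcomp(blocks, spec, seed=seed, n_restarts=n_restarts)


# ---------------------------------------------------------------------------
# Model comparison
# ---------------------------------------------------------------------------

def lrt(full: VarCompFit, sub: VarCompFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of a nested submodel against a fuller model.

    Returns (delta_minus2ll, df, p).  The p-value is the naive chi-squared
    tail; note that variances on the boundary make it conservative.
    """
    full_set = set(full.spec.free_components)
    sub_set = set(sub.spec.free_components)
    if not sub_set < full_set:
        raise ModelSpecError(
            f"{sub.spec.name} is not nested in {full.spec.name}"
        )
    delta = max(0.0, 2.0 * (full.log_likelihood - sub.log_likelihood))
    df = len(full_set) - len(sub_set)
    p = float(stats.chi2.sf(delta, df))
    return delta, df, p


def compare_models(fits: Sequence[VarCompFit], alpha: float = 0.05) -> pd.DataFrame:
    """Nested-model selection table over a collection of fits.

    Every nested pair is tested; the "best" model is the most complex one
    for which dropping components (to any provided submodel) is rejected
    at ``alpha``.  Tests involving boundary variance components carry a
    conservative naive chi-squared p-value (flagged in the table).
    """
    fits = sorted(fits, key=lambda f: -f.n_free_components)
    rows = []
    best_name = fits[-1].spec.name  # simplest as fallback
    chosen = False
    for f in fits:
        subs = [g for g in fits
                if set(g.spec.free_components) < set(f.spec.free_components)]
        all_reject = bool(subs)
        for g in subs:
            delta, df, p = lrt(f, g)
            boundary = any(
                f.variances[c] < 1e-8
                for c in set(f.spec.free_components) - set(g.spec.free_components)
            )
            rows.append({
                "full": f.spec.name, "sub": g.spec.name,
                "delta_minus2ll": delta, "df": df, "p": p,
                "reject": p < alpha, "boundary": boundary,
            })
            if p >= alpha:
                all_reject = False
        if not chosen and all_reject:
            best_name = f.spec.name
            chosen = True
    table = pd.DataFrame(rows)
    table.attrs["best_model"] = best_name
    return table
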