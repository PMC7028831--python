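"""Mid-parent offspring regression.

The regression of an offspring's phenotype on the mean of its two
parents' phenotypes estimates narrow-sense heritability directly, and —
unlike variance-component estimates — is insensitive to phenotypic
assortment and to marital interaction (both change each parent's
phenotype but leave the parental sum, and hence the mid-parent value and
its covariance with the child, intact under convergence toward the couple
mean).  Dominance and sibling-household variance do not bias the slope
either, since parent-offspring pairs share neither.

Phenotypes are residualized on age, sex, and age*sex jointly (one
regression over all members) before averaging; one child per family is
selected uniformly at random to avoid within-family dependence; slopes
are reported within bins of mean parental age because additive variance
declines across adulthood.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .kincorr import residualize
from .pedigree import Pedigree

DEFAULT_BINS = ((20.0, 45.0), (45.0, 50.0), (50.0, 55.0), (55.0, 70.0))


@dataclass
class MidparentResult:
    age_bin: tuple[float, float]    # [low, high) years of mean parental age
    n_pairs: int
    coefficient: float              # narrow-sense h2 estimate
    standard_error: float
    seed: int


def _validate_bins(bins: Sequence[tuple[float, float]]) -> None:
    for lo, hi in bins:
        if hi <= lo:
            raise ValueError(f"empty age bin ({lo}, {hi})")
    ordered = sorted(bins)
    for (lo1, hi1), (lo2, hi2) in zip(ordered, ordered[1:]):
        if lo2 < hi1:
            raise ValueError("age bins overlap")


def midparent_regression(
    pedigrees: Iterable[Pedigree],
    phenotypes: pd.DataFrame,
    bins: Sequence[tuple[float, float]] = DEFAULT_BINS,
    seed: int = 0,
    value_column: str = "value",
) -> list[MidparentResult]:
    """Per-age-bin OLS slope of one random child on the mid-parent value.

    Families qualify when both parents and at least one child are
    phenotyped.  Bins are half-open [low, high) except the last, which is
    closed; bins with fewer than 2 families are omitted.  The child draw
    is uniform per family under ``seed``.
    """
    _validate_bins(bins)
    rng = np.random.default_rng(seed)
    phen = phenotypes.dropna(subset=[value_column]).copy()
    phen = phen.set_index(phen["participant_id"].astype(str))
    res = residualize(
        phen[value_column].to_numpy(),
        phen["age"].to_numpy(),
        phen["sex"].to_numpy(),
    )
    phen["_resid"] = res

    triples = []  # (mean parental age, midparent residual, child residual)
    for ped in pedigrees:
        by_parents: dict[tuple[str, str], list[str]] = {}
        for ind in ped:
            if ind.is_founder:
                continue
            if (ind.father_id in phen.index and ind.mother_id in phen.index
                    and ind.individual_id in phen.index):
                by_parents.setdefault(
                    (ind.father_id, ind.mother_id), []
                ).append(ind.individual_id)
        for (fid, mid), children in by_parents.items():
            child = children[int(rng.integers(len(children)))]
            page = 0.5 * (phen.loc[fid, "age"] + phen.loc[mid, "age"])
            midp = 0.5 * (phen.loc[fid, "_resid"] + phen.loc[mid, "_resid"])
            triples.append((float(page), float(midp),
                            float(phen.loc[child, "_resid"])))
    if not triples:
        return []
    arr = np.asarray(triples)

    results = []
    last_hi = max(hi for _, hi in bins)
    for lo, hi in bins:
        if hi == last_hi:
            mask = (arr[:, 0] >= lo) & (arr[:, 0] <= hi)
        else:
            mask = (arr[:, 0] >= lo) & (arr[:, 0] < hi)
        n = int(mask.sum())
        if n < 2:
            continue
        X = sm.add_constant(arr[mask, 1])
        fit = sm.OLS(arr[mask, 2], X).fit()
        results.append(MidparentResult(
            age_bin=(lo, hi),
            n_pairs=n,
            coefficient=float(fit.params[1]),
            standard_error=float(fit.bse[1]),
            seed=seed,
        ))
    return results


def midparent_table(results: Sequence[MidparentResult]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "age_low": r.age_bin[0],
            "age_high": r.age_bin[1],
            "n_pairs": r.n_pairs,
            "coefficient": r.coefficient,
            "standard_error": r.standard_error,
        }
        for r in results
    ])
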