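"""Relation-specific kinship correlations.

Phenotypes are first residualized on age, sex, and age*sex by ordinary
least squares; Pearson correlations of the residuals are then computed
within each family relation (spouse pairs, twin pairs by zygosity and
sex, sibling pairs by sex composition, and the four parent-offspring
combinations).

Symmetric relations (twins, siblings, spouses) are double-entered — each
pair contributes both orderings — so the correlation does not depend on
an arbitrary within-pair order.  Directed relations (parent-offspring)
use the fixed parent-first ordering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .pedigree import Pedigree

RELATION_LABELS = (
    "all_spouses", "parents_of_twins", "twin_spouse",
    "MZM", "MZF", "DZM", "DZF", "DOS",
    "brother_brother", "brother_sister", "sister_sister",
    "mother_daughter", "mother_son", "father_daughter", "father_son",
)

# relations where pair order is arbitrary (double-entered in correlations)
SYMMETRIC_LABELS = frozenset(RELATION_LABELS[:11])

MIN_PAIRS = 3


@dataclass(frozen=True)
class RelationPair:
    relation_label: str
    member1_id: str
    member2_id: str


def residualize(
    values: np.ndarray,
    age: np.ndarray,
    sex: np.ndarray,
) -> np.ndarray:
    """OLS residuals of values on intercept + age + sex + age*sex.

    ``sex`` is 0/1 coded (or male/female strings).  Raises on a singular
    design (e.g., a single sex with constant age).
    """
    values = np.asarray(values, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.asarray(sex).dtype == object or isinstance(sex[0], str):
        sex = np.array([1.0 if s == "female" else 0.0 for s in sex])
    sex = np.asarray(sex, dtype=float)
    if len(values) < 4:
        raise ValueError("need at least 4 observations to residualize")
    X = np.column_stack([np.ones_like(values), age, sex, age * sex])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError(
            "singular design for residualization (collinear covariates)"
        )
    coef, *_ = np.linalg.lstsq(X, values, rcond=None)
    return values - X @ coef


# ---------------------------------------------------------------------------
# Pair extraction
# ---------------------------------------------------------------------------

def _twin_info(ped: Pedigree):
    """Twin pairs with zygosity plus ids of twins having twin offspring."""
    pairs = []
    for pair in ped.twin_pairs():
        a, b = sorted(pair)
        ia, ib = ped[a], ped[b]
        mz = ia.mz_group_id is not None and ia.mz_group_id == ib.mz_group_id
        pairs.append((a, b, mz))
    return pairs


def extract_pairs(
    pedigrees: Iterable[Pedigree],
    label: str,
) -> list[RelationPair]:
    """All distinct pairs for one relation label across pedigrees.

    Twins who themselves have twin offspring are counted with their spouse
    under ``twin_spouse`` and excluded from ``parents_of_twins`` (no pair
    reuse across those two rows).
    """
    if label not in RELATION_LABELS:
        raise ValueError(f"unknown relation label {label!r}")
    out: list[RelationPair] = []
    for ped in pedigrees:
        twin_pairs = _twin_info(ped)
        twin_members = {m for a, b, _ in twin_pairs for m in (a, b)}
        parents_of_twin_pairs = {
            frozenset((ped[a].father_id, ped[a].mother_id))
            for a, b, _ in twin_pairs
            if ped[a].father_id is not None
        }

        if label == "all_spouses":
            for pair in ped.spouse_pairs():
                a, b = sorted(pair)
                out.append(RelationPair(label, a, b))
        elif label == "parents_of_twins":
            for pair in parents_of_twin_pairs:
                # twins with twin offspring stay in the twin_spouse row only
                if any(m in twin_members for m in pair):
                    continue
                a, b = sorted(pair)
                out.append(RelationPair(label, a, b))
        elif label == "twin_spouse":
            for a, b, _ in twin_pairs:
                for t in (a, b):
                    sid = ped[t].spouse_id
                    if sid is not None and sid in ped.individuals:
                        out.append(RelationPair(label, t, sid))
        elif label in ("MZM", "MZF", "DZM", "DZF", "DOS"):
            for a, b, mz in twin_pairs:
                sa, sb = ped[a].sex, ped[b].sex
                if sa != sb:
                    got = "DOS"
                elif mz:
                    got = "MZM" if sa == "male" else "MZF"
                else:
                    got = "DZM" if sa == "male" else "DZF"
                if got == label:
                    out.append(RelationPair(label, a, b))
        elif label in ("brother_brother", "brother_sister", "sister_sister"):
            twin_sets = {frozenset((a, b)) for a, b, _ in twin_pairs}
            for pair in ped.full_sib_pairs():
                if pair in twin_sets:
                    continue  # twin pairs are reported in the twin rows
                a, b = sorted(pair)
                sexes = tuple(sorted((ped[a].sex, ped[b].sex)))
                got = {
                    ("male", "male"): "brother_brother",
                    ("female", "male"): "brother_sister",
                    ("female", "female"): "sister_sister",
                }[sexes]
                if got == label:
                    if got == "brother_sister" and ped[a].sex == "female":
                        a, b = b, a  # brother listed first
                    out.append(RelationPair(label, a, b))
        else:  # parent-offspring labels, parent listed first
            parent_sex, child_sex = {
                "mother_daughter": ("female", "female"),
                "mother_son": ("female", "male"),
                "father_daughter": ("male", "female"),
                "father_son": ("male", "male"),
            }[label]
            for ind in ped:
                pid = ind.mother_id if parent_sex == "female" else ind.father_id
                if pid is not None and ind.sex == child_sex:
                    out.append(RelationPair(label, pid, ind.individual_id))
    # de-duplicate while preserving order
    seen = set()
    unique = []
    for p in out:
        key = (p.relation_label, p.member1_id, p.member2_id)
        if key not in seen:
            seen.add(key)
            unique.append(p)
    return unique


# ---------------------------------------------------------------------------
# Correlation table
# ---------------------------------------------------------------------------

def pair_correlation(
    pairs: Sequence[RelationPair],
    residuals: pd.Series,
    double_entry: bool,
) -> tuple[float, int]:
    """Pearson correlation over complete pairs; (nan, n) below MIN_PAIRS."""
    x, y = [], []
    for p in pairs:
        if p.member1_id in residuals.index and p.member2_id in residuals.index:
            a = residuals[p.member1_id]
            b = residuals[p.member2_id]
            if np.isnan(a) or np.isnan(b):
                continue
            x.append(a)
            y.append(b)
    n = len(x)
    if n < MIN_PAIRS:
        return float("nan"), n
    x = np.asarray(x)
    y = np.asarray(y)
    if double_entry:
        x, y = np.concatenate([x, y]), np.concatenate([y, x])
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), n
    return float(np.corrcoef(x, y)[0, 1]), n


def correlation_table(
    pedigrees: Sequence[Pedigree],
    phenotypes: pd.DataFrame,
    trait_columns: Sequence[str],
    labels: Sequence[str] = RELATION_LABELS,
) -> pd.DataFrame:
    """Kinship-correlation table: one row per relation, one column per trait.

    ``phenotypes`` needs participant_id, age, sex, and the trait columns.
    Each trait is residualized on age, sex, and age*sex before computing
    the correlations.  Cells with fewer than three complete pairs are NaN.
    """
    phen = phenotypes.copy()
    phen = phen.set_index(phen["participant_id"].astype(str))
    resids = {}
    for col in trait_columns:
        ok = phen[col].notna()
        res = residualize(
            phen.loc[ok, col].to_numpy(),
            phen.loc[ok, "age"].to_numpy(),
            phen.loc[ok, "sex"].to_numpy(),
        )
        series = pd.Series(np.nan, index=phen.index)
        series[ok] = res
        resids[col] = series

    rows = []
    for label in labels:
        pairs = extract_pairs(pedigrees, label)
        double = label in SYMMETRIC_LABELS
        row = {"relation": label}
        n_ref = 0
        for col in trait_columns:
            r, n = pair_correlation(pairs, resids[col], double)
            row[col] = r
            n_ref = max(n_ref, n)
        row["n_pairs"] = n_ref
        rows.append(row)
    return pd.DataFrame(rows).set_index("relation")
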