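"""Pedigree parsing, validation, and expected relationship matrices.

A pedigree is a directed acyclic family graph with optional monozygotic
(MZ) twin annotation.  From it we build the three matrices that
parameterize familial covariance in the variance-component model:

* ``A = 2 * Phi`` — expected additive genetic sharing, where ``Phi`` is the
  kinship coefficient (probability that randomly drawn alleles from two
  individuals are identical by descent).
* ``D`` — expected dominance sharing, weighted by the fraternity
  coefficient ``Delta`` (probability of sharing both alleles IBD).
* ``H`` — a 0/1 household-sharing indicator under one of four
  definitions (full, spouse, sib, twin).

MZ co-twins are treated as genotype-identical: the kinship recursion
copies a co-twin's row from the first-processed twin, so spouses and
children of each twin remain distinct pedigree members while the genetic
entries reflect identity.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

HOUSEHOLD_DEFINITIONS = ("full", "spouse", "sib", "twin")


class PedigreeError(ValueError):
    """Raised when a pedigree violates structural invariants."""


@dataclass
class Individual:
    individual_id: str
    family_id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    sex: str = "male"  # "male" or "female"
    birth_year: Optional[float] = None
    mz_group_id: Optional[str] = None
    spouse_id: Optional[str] = None

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None

    def __post_init__(self):
        if (self.father_id is None) != (self.mother_id is None):
            raise PedigreeError(
                f"individual {self.individual_id}: both parent ids must be "
                "present or both absent"
            )
        if self.sex not in ("male", "female"):
            raise PedigreeError(
                f"individual {self.individual_id}: sex must be male/female, "
                f"got {self.sex!r}"
            )


@dataclass
class Pedigree:
    """A validated single-family pedigree."""

    family_id: str
    individuals: dict[str, Individual] = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    # -- container conveniences -------------------------------------------
    def __len__(self) -> int:
        return len(self.individuals)

    def __iter__(self):
        return iter(self.individuals.values())

    def __getitem__(self, individual_id: str) -> Individual:
        return self.individuals[individual_id]

    @property
    def member_ids(self) -> list[str]:
        return list(self.individuals)

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        for ind in self.individuals.values():
            for pid, want_sex, role in (
                (ind.father_id, "male", "father"),
                (ind.mother_id, "female", "mother"),
            ):
                if pid is None:
                    continue
                if pid not in self.individuals:
                    raise PedigreeError(
                        f"family {self.family_id}: {role} {pid!r} of "
                        f"{ind.individual_id} not in pedigree"
                    )
                if self.individuals[pid].sex != want_sex:
                    raise PedigreeError(
                        f"family {self.family_id}: {role} {pid!r} of "
                        f"{ind.individual_id} is not {want_sex}"
                    )
        self._check_acyclic()
        self._check_mz_groups()

    def _check_acyclic(self) -> None:
        self.topological_order()  # raises on cycle

    def _check_mz_groups(self) -> None:
        groups: dict[str, list[Individual]] = {}
        for ind in self.individuals.values():
            if ind.mz_group_id is not None:
                groups.setdefault(ind.mz_group_id, []).append(ind)
        for gid, members in groups.items():
            sexes = {m.sex for m in members}
            parents = {(m.father_id, m.mother_id) for m in members}
            if len(sexes) > 1:
                raise PedigreeError(
                    f"family {self.family_id}: MZ group {gid!r} spans sexes"
                )
            if len(parents) > 1:
                raise PedigreeError(
                    f"family {self.family_id}: MZ group {gid!r} members do "
                    "not share both parents"
                )

    def topological_order(self) -> list[str]:
        """Member ids, parents before children; raises on ancestry cycles."""
        order: list[str] = []
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(iid: str, stack: list[str]):
            st = state.get(iid)
            if st == 1:
                return
            if st == 0:
                raise PedigreeError(
                    f"family {self.family_id}: ancestry cycle involving {iid!r}"
                )
            state[iid] = 0
            ind = self.individuals[iid]
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None:
                    visit(pid, stack + [iid])
            state[iid] = 1
            order.append(iid)

        for iid in self.individuals:
            visit(iid, [])
        return order

    # -- derived role helpers ---------------------------------------------
    def spouse_pairs(self) -> set[frozenset[str]]:
        """Spouse pairs from explicit links plus inferred shared-children."""
        pairs: set[frozenset[str]] = set()
        for ind in self.individuals.values():
            if ind.spouse_id is not None and ind.spouse_id in self.individuals:
                pairs.add(frozenset((ind.individual_id, ind.spouse_id)))
            if not ind.is_founder:
                pairs.add(frozenset((ind.father_id, ind.mother_id)))
        return {p for p in pairs if len(p) == 2}

    def full_sib_pairs(self) -> set[frozenset[str]]:
        pairs: set[frozenset[str]] = set()
        by_parents: dict[tuple, list[str]] = {}
        for ind in self.individuals.values():
            if not ind.is_founder:
                by_parents.setdefault(
                    (ind.father_id, ind.mother_id), []
                ).append(ind.individual_id)
        for sibs in by_parents.values():
            for i in range(len(sibs)):
                for j in range(i + 1, len(sibs)):
                    pairs.add(frozenset((sibs[i], sibs[j])))
        return pairs

    def twin_pairs(self) -> set[frozenset[str]]:
        """Twin pairs: shared MZ group, or full sibs with equal birth year."""
        pairs: set[frozenset[str]] = set()
        for pair in self.full_sib_pairs():
            a, b = (self.individuals[i] for i in pair)
            if a.mz_group_id is not None and a.mz_group_id == b.mz_group_id:
                pairs.add(pair)
            elif (
                a.birth_year is not None
                and a.birth_year == b.birth_year
            ):
                pairs.add(pair)
        return pairs

    def parent_offspring_pairs(self) -> set[frozenset[str]]:
        pairs: set[frozenset[str]] = set()
        for ind in self.individuals.values():
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None:
                    pairs.add(frozenset((ind.individual_id, pid)))
        return pairs


# ---------------------------------------------------------------------------
# File I/O (PED-like, extended with an MZ-group column)
# ---------------------------------------------------------------------------

PED_COLUMNS = (
    "family", "id", "father", "mother", "sex", "mz_group", "birth_year",
    "spouse",
)

_SEX_CODES = {"1": "male", "2": "female", "male": "male", "female": "female",
              "m": "male", "f": "female"}


def read_pedigree(path_or_buffer) -> list[Pedigree]:
    """Read pedigrees from a PED-like text file.

    Columns (tab, comma, or whitespace separated; header optional; ``#``
    comments allowed)::

        family id father mother sex mz_group birth_year [spouse]

    ``0`` denotes a missing parent / MZ group / spouse, per PED convention.
    Sex is coded ``1``/``male`` or ``2``/``female``.
    """
    if hasattr(path_or_buffer, "read"):
        text = path_or_buffer.read()
    else:
        with open(path_or_buffer) as fh:
            text = fh.read()
    rows: list[list[str]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "\t" in line:
            parts = [p.strip() for p in line.split("\t")]
        elif "," in line:
            parts = [p.strip() for p in line.split(",")]
        else:
            parts = line.split()
        if parts[0].lower() in ("family", "fid", "famid") and len(rows) == 0:
            continue  # header
        if len(parts) < 7:
            raise PedigreeError(
                f"line {lineno}: expected >=7 columns, got {len(parts)}"
            )
        rows.append(parts)

    families: dict[str, dict[str, Individual]] = {}
    for parts in rows:
        fam, iid, fid, mid, sex, mz, by = parts[:7]
        spouse = parts[7] if len(parts) > 7 else "0"
        sex_label = _SEX_CODES.get(sex.lower())
        if sex_label is None:
            raise PedigreeError(f"unknown sex code {sex!r} for {iid!r}")
        ind = Individual(
            individual_id=iid,
            family_id=fam,
            father_id=None if fid == "0" else fid,
            mother_id=None if mid == "0" else mid,
            sex=sex_label,
            mz_group_id=None if mz == "0" else mz,
            birth_year=None if by in ("0", "", ".") else float(by),
            spouse_id=None if spouse == "0" else spouse,
        )
        fam_dict = families.setdefault(fam, {})
        if iid in fam_dict:
            raise PedigreeError(f"duplicate individual {iid!r} in family {fam!r}")
        fam_dict[iid] = ind

    return [Pedigree(fam, inds) for fam, inds in families.items()]


def write_pedigree(pedigrees: Iterable[Pedigree], path_or_buffer) -> None:
    """Write pedigrees in the PED-like format accepted by read_pedigree."""
    own = False
    if hasattr(path_or_buffer, "write"):
        fh = path_or_buffer
    else:
        fh = open(path_or_buffer, "w")
        own = True
    try:
        fh.write("\t".join(PED_COLUMNS) + "\n")
        for ped in pedigrees:
            for ind in ped:
                by = ind.birth_year
                fh.write("\t".join([
                    ped.family_id,
                    ind.individual_id,
                    ind.father_id or "0",
                    ind.mother_id or "0",
                    "1" if ind.sex == "male" else "2",
                    ind.mz_group_id or "0",
                    "0" if by is None else format(by, "g"),
                    ind.spouse_id or "0",
                ]) + "\n")
    finally:
        if own:
            fh.close()


# ---------------------------------------------------------------------------
# Relationship matrices
# ---------------------------------------------------------------------------

@dataclass
class RelationshipMatrices:
    member_order: list[str]
    A: np.ndarray
    D: np.ndarray
    H: np.ndarray


def kinship_matrix(ped: Pedigree, order: Optional[Sequence[str]] = None) -> np.ndarray:
    """Kinship coefficients Phi via the tabular recursion.

    Founders are unrelated and non-inbred (Phi_ii = 1/2).  Within an MZ
    group the first-processed twin's row is copied to its co-twins before
    any of their descendants are processed, which makes the group
    genotype-identical without collapsing nodes.
    """
    topo = ped.topological_order()
    if order is None:
        order = ped.member_ids
    idx = {iid: k for k, iid in enumerate(order)}
    n = len(order)
    phi = np.zeros((n, n))
    done: dict[str, int] = {}
    mz_first: dict[str, str] = {}  # mz_group -> first processed member

    for iid in topo:
        ind = ped[iid]
        i = idx[iid]
        gid = ind.mz_group_id
        if gid is not None and gid in mz_first:
            t = idx[mz_first[gid]]
            for jid, j in done.items():
                phi[i, j] = phi[j, i] = phi[t, j]
            phi[i, i] = phi[t, t]
            phi[i, t] = phi[t, i] = phi[t, t]
        elif ind.is_founder:
            phi[i, i] = 0.5
        else:
            f, m = idx[ind.father_id], idx[ind.mother_id]
            phi[i, i] = 0.5 * (1.0 + phi[f, m])
            for jid, j in done.items():
                v = 0.5 * (phi[f, j] + phi[m, j])
                phi[i, j] = phi[j, i] = v
        if gid is not None and gid not in mz_first:
            mz_first[gid] = iid
        done[iid] = i
    return phi


def additive_matrix(ped: Pedigree, order: Optional[Sequence[str]] = None) -> np.ndarray:
    """Expected additive relationship matrix A = 2 * Phi."""
    return 2.0 * kinship_matrix(ped, order)


def dominance_matrix(ped: Pedigree, order: Optional[Sequence[str]] = None) -> np.ndarray:
    """Expected dominance relationship matrix from fraternity coefficients.

    For a non-inbred pedigree and individuals i, j with both parents known,

        Delta_ij = Phi_f(i)f(j) * Phi_m(i)m(j) + Phi_f(i)m(j) * Phi_m(i)f(j)

    MZ pairs are set to 1 (full genotype identity), the diagonal is 1, and
    any pair involving a founder (other than an MZ co-twin) has Delta 0.
    """
    if order is None:
        order = ped.member_ids
    phi = kinship_matrix(ped, order)
    idx = {iid: k for k, iid in enumerate(order)}
    n = len(order)
    if np.any(np.diag(phi) > 0.5 + 1e-12):
        raise PedigreeError(
            f"family {ped.family_id}: inbreeding detected; the dominance "
            "formula assumes a non-inbred pedigree"
        )
    D = np.eye(n)
    members = [ped[iid] for iid in order]
    for a in range(n):
        ia = members[a]
        for b in range(a + 1, n):
            ib = members[b]
            same_mz = (
                ia.mz_group_id is not None
                and ia.mz_group_id == ib.mz_group_id
            )
            if same_mz:
                D[a, b] = D[b, a] = 1.0
            elif not ia.is_founder and not ib.is_founder:
                fa, ma = idx[ia.father_id], idx[ia.mother_id]
                fb, mb = idx[ib.father_id], idx[ib.mother_id]
                d = phi[fa, fb] * phi[ma, mb] + phi[fa, mb] * phi[ma, fb]
                D[a, b] = D[b, a] = d
    return D


def household_matrix(
    ped: Pedigree,
    definition: str,
    order: Optional[Sequence[str]] = None,
) -> np.ndarray:
    """0/1 household-sharing indicator under one of four definitions.

    * ``full`` — spouses, all parent-offspring pairs, and all twin and
      non-twin sibling pairs share a household factor.
    * ``spouse`` — spouse pairs only.
    * ``sib`` — twin and non-twin sibling pairs only (ever shared a
      household while growing up).
    * ``twin`` — twin pairs only.

    Sibling/parent-offspring sharing is interpreted as "ever shared",
    independent of current age.
    """
    if definition not in HOUSEHOLD_DEFINITIONS:
        raise ValueError(
            f"unknown household definition {definition!r}; "
            f"expected one of {HOUSEHOLD_DEFINITIONS}"
        )
    if order is None:
        order = ped.member_ids
    idx = {iid: k for k, iid in enumerate(order)}
    n = len(order)
    H = np.eye(n)

    if definition == "spouse":
        pairs = ped.spouse_pairs()
    elif definition == "sib":
        pairs = ped.full_sib_pairs()
    elif definition == "twin":
        pairs = ped.twin_pairs()
    else:  # full
        pairs = (
            ped.spouse_pairs()
            | ped.full_sib_pairs()
            | ped.parent_offspring_pairs()
        )

    for pair in pairs:
        a, b = tuple(pair)
        if a in idx and b in idx:
            H[idx[a], idx[b]] = H[idx[b], idx[a]] = 1.0
    return H


def relationship_matrices(
    ped: Pedigree,
    household_definition: str = "full",
    order: Optional[Sequence[str]] = None,
) -> RelationshipMatrices:
    """All three expected relationship matrices in one member order."""
    if order is None:
        order = ped.member_ids
    return RelationshipMatrices(
        member_order=list(order),
        A=additive_matrix(ped, order),
        D=dominance_matrix(ped, order),
        H=household_matrix(ped, household_definition, order),
    )
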