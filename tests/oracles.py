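"""Independent brute-force oracles used by the test suite.

These deliberately avoid the recursions used in the package: kinship and
fraternity coefficients are computed by exact enumeration of all allele
inheritance patterns, feasible for pedigrees with a handful of
non-founders.
"""

from itertools import product

import numpy as np

from exped.pedigree import Pedigree


def enumerate_relationships(ped: Pedigree):
    """Exact kinship and fraternity matrices by allele-path enumeration.

    Each non-founder independently inherits one of the father's two
    alleles and one of the mother's two alleles (4 combinations); MZ
    co-twins copy their twin's realized pair.  Averaging identity
    indicators over all patterns gives the exact coefficients.

    Returns (member_order, Phi, Delta).
    """
    order = ped.topological_order()
    pos = {iid: k for k, iid in enumerate(order)}
    mz_rep = {}
    choosers = []  # non-founders that draw their own alleles
    for iid in order:
        ind = ped[iid]
        gid = ind.mz_group_id
        if gid is not None:
            if gid in mz_rep:
                continue
            mz_rep[gid] = iid
        if not ind.is_founder:
            choosers.append(iid)

    n = len(order)
    phi = np.zeros((n, n))
    delta = np.zeros((n, n))
    patterns = list(product(range(4), repeat=len(choosers)))
    for pattern in patterns:
        choice = dict(zip(choosers, pattern))
        alleles = {}
        for iid in order:
            ind = ped[iid]
            gid = ind.mz_group_id
            if gid is not None and mz_rep[gid] != iid:
                alleles[iid] = alleles[mz_rep[gid]]
                continue
            if ind.is_founder:
                alleles[iid] = (f"{iid}.a", f"{iid}.b")
            else:
                c = choice[iid]
                pa = alleles[ind.father_id][c & 1]
                ma = alleles[ind.mother_id][(c >> 1) & 1]
                alleles[iid] = (pa, ma)
        for i, a in enumerate(order):
            xa = alleles[a]
            for j, b in enumerate(order):
                xb = alleles[b]
                phi[i, j] += 0.25 * sum(
                    x == y for x in xa for y in xb
                )
                both = (xa[0] == xb[0] and xa[1] == xb[1]) or (
                    xa[0] == xb[1] and xa[1] == xb[0]
                )
                delta[i, j] += float(both)
    phi /= len(patterns)
    delta /= len(patterns)
    return order, phi, delta
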