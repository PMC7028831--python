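"""Build the relationship matrices an extended twin pedigree implies.

The additive matrix A doubles the kinship coefficients, the dominance
matrix D holds fraternity coefficients (1 for MZ twins, 1/4 for full
sibs), and the household matrix H encodes who shared a home under a
chosen definition (full, spouse, sib, or twin).
"""

import io

import pandas as pd

from exped import read_pedigree, relationship_matrices

PED = """\
family  id  father  mother  sex  mz_group  birth_year  spouse
fam1    F   0       0       1    0         1950        M
fam1    M   0       0       2    0         1952        F
fam1    T1  F       M       1    mz1       1978        S1
fam1    T2  F       M       1    mz1       1978        0
fam1    B1  F       M       2    0         1981        0
fam1    S1  0       0       2    0         1979        T1
fam1    O1  T1      S1      1    0         2003        0
"""

ped = read_pedigree(io.StringIO(PED))[0]
mats = relationship_matrices(ped, household_definition="full")

for name, M in (("A (additive)", mats.A), ("D (dominance)", mats.D),
                ("H (household)", mats.H)):
    print(f"\n{name}:")
    print(pd.DataFrame(M, index=mats.member_order,
                       columns=mats.member_order).round(3))
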