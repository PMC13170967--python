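"""Parse, repair and annotate a pedigree; compute inbreeding and A^-1.

Builds a small registry-style pedigree file, runs it through the
validation rules, and prints the inbreeding coefficients and the
sparsity of the relationship-matrix inverse.
"""

import tempfile
from pathlib import Path

import numpy as np

from kennelquant import (
    build_a_inverse,
    compute_inbreeding,
    parse_pedigree,
    show_breeding_score,
    tabular_relationship,
    validate_and_correct,
)

csv = """id,sire,dam,sex,dob,colour,sbn,registration
GS,,,male,2008-03-01,brindle,1,RKC
GD,,,female,2008-06-10,fawn,1,RKC
S,GS,GD,male,2011-02-05,brindle,1,RKC
D,GS,GD,female,2011-02-05,blue,0,RKC
X,S,D,male,2014-07-21,fawn,0,RKC
BAD,X,X,female,2012-01-01,fawn,0,RKC
"""

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "pedigree.csv"
    path.write_text(csv)
    ped = parse_pedigree(path, {"brindle": "BS", "fawn": "BS", "blue": "NBS"})

ped, log = validate_and_correct(ped)
print("corrections applied:")
for c in log:
    print(f"  {c.id}: {c.field} was {c.old_value!r} -> nulled ({c.reason})")

ped = compute_inbreeding(ped)
print("\ninbreeding coefficients:")
for rec in ped.records:
    print(f"  {rec.id:4s} f = {rec.f:.4f}  ({rec.colour_group})")

A = tabular_relationship(ped)
Ainv = build_a_inverse(ped)
print(f"\nA diagonal (1 + f): {np.round(np.diag(A), 3)}")
print(f"A^-1 has {Ainv.nnz} nonzeros for {len(ped)} animals")
print(f"show-breeding score of X: {show_breeding_score(ped, 'X')} (parents and grandparents with studbook numbers)")
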