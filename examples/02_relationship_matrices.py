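"""The four relationship matrices on worked toy inputs.

A (pedigree expectation), G (VanRaden realized genomic), D (dominance) and
the additive-by-dominance epistatic matrix G ∘ D.  The single-SNP genotype
column [0, 1, 2] has allele frequency 0.5, so every entry can be checked
by hand.
"""

import numpy as np

import opbreed as ob

# pedigree: one dam, two half-sib offspring, one selfed offspring
ped = ob.PedigreeTable.from_records(
    [("DAM", None, None), ("HS1", "DAM", None), ("HS2", "DAM", None),
     ("SELF", "DAM", "DAM")]
)
A = ob.build_A(ped)
print("A(HS1, HS2)  =", A.loc("HS1", "HS2"), " (half-sibs: 1/4)")
print("A(SELF,SELF) =", A.loc("SELF", "SELF"), "(selfing: 1 + F = 1.5)")

gm = ob.GenotypeMatrix(["a", "b", "c"], ["snp1"], np.array([[0.0], [1.0], [2.0]]))
G = ob.build_G(gm)
D = ob.build_D(gm)
E = ob.build_epistatic(G, D)
print("\nG = WW'/2Σp(1-p):\n", G.values)
print("D (Vitezica covariates -2p², 2pq, -2q²):\n", D.values)
print("epistatic G∘D:\n", E.values)
# G is singular here (1 SNP, 3 trees); blend before any model inverts it
Gb = ob.blend(G, 0.01)
print("\nblended G diagonal:", np.diag(Gb.values), f"(weight {Gb.blending_weight})")
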