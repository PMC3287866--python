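"""Build a pedigree and compute kinship and inbreeding coefficients.

The kinship matrix Phi is the backbone of every test in the package: it
is the null correlation structure of genotypes among relatives.
"""

from famqls import Individual, Pedigree, Sex, compute_kinship

ped = Pedigree(
    [
        Individual("FAM", "GF", sex=Sex.MALE),            # founder grandfather
        Individual("FAM", "GM", sex=Sex.FEMALE),          # founder grandmother
        Individual("FAM", "DAD", "GF", "GM", Sex.MALE),
        Individual("FAM", "UNCLE", "GF", "GM", Sex.MALE),
        Individual("FAM", "MOM", sex=Sex.FEMALE),         # married-in founder
        Individual("FAM", "KID", "DAD", "MOM", Sex.FEMALE),
    ]
)

kin = compute_kinship(ped)
kin.assert_positive_definite()
dense = kin.dense()

pairs = [("DAD", "KID"), ("DAD", "UNCLE"), ("UNCLE", "KID"), ("GF", "KID"), ("MOM", "GF")]
for a, b in pairs:
    print(f"kinship({a:>5}, {b:>5}) = {dense[ped.row('FAM', a), ped.row('FAM', b)]:.4f}")
print("inbreeding coefficients:", kin.inbreeding())

# parent-offspring and sib pairs share alleles IBD with kinship 1/4; an
# avuncular pair 1/8; grandparent-grandchild 1/8; unrelated founders 0.
# Everyone here is outbred, so all inbreeding coefficients are 0.
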