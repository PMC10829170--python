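"""Canonical SMILES, randomized enumeration views, scaffolds and fingerprints.

One molecule admits many valid SMILES spellings; enumeration by atom-order
randomization produces the augmented "views" the contrastive encoder trains
on, and the Murcko scaffold names the molecule's structural family.
"""

import ddikit as dk

aspirin = "CC(=O)Oc1ccccc1C(=O)O"

canonical = dk.canonicalize(aspirin)
print("canonical SMILES:    ", canonical)
print("Murcko scaffold:     ", dk.murcko_scaffold(aspirin))

views = dk.enumerate_randomized(aspirin, n_requested=5, seed=0)
print("\n5 randomized views (all the same molecule):")
for v in views:
    assert dk.canonicalize(v) == canonical
    print("  ", v)

fp_aspirin = dk.circular_fingerprint(aspirin, radius=2, n_bits=2048)
fp_benzene = dk.circular_fingerprint("c1ccccc1")
print("\nECFP4 bits set for aspirin:", int(fp_aspirin.bits.sum()), "of", fp_aspirin.n_bits)
print("Tanimoto(aspirin, benzene):", round(dk.tanimoto(fp_aspirin, fp_benzene), 4))
# a low Tanimoto: the shared benzene ring is a small part of aspirin's
# substructure environment set
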