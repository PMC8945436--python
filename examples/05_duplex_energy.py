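"""Nearest-neighbor duplex free energies for seed vs bulged sites.

The dynamic program aligns the seed against a target fragment, allowing
Watson-Crick and G:U pairs, bulges and internal loops, and returns the
minimum free energy with one optimal pairing.
"""

from mirbulge import duplex_mfe
from mirbulge.io import dna_to_rna

seed = "GGACGGA"  # miR-184

for label, target in [
    ("perfect seed site", "TCCGTCC"),
    ("CG-bulge site (A)", "TCCAGTCC"),
    ("CG-bulge site (T)", "TCCTGTCC"),
    ("random-gap bulge", "TCCGTACC"),
    ("unrelated", "AAAAAAAA"),
]:
    res = duplex_mfe(seed, dna_to_rna(target))
    print(f"{label:20s} {target:9s} MFE {res.mfe:7.2f} kcal/mol  "
          f"bulges {res.n_bulges}  pairing {res.mirna_struct} / {res.target_struct}")
# The perfect duplex is most stable; a single-nucleotide bulge costs the
# bulge-initiation penalty (the stack across it is retained), and an
# unrelated fragment scores 0 (no stable duplex).
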