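"""Decoy frustration of native contacts.

Builds a structure with a buried and a surface residue pair at the same
distance, computes each contact's frustration z-score against exhaustive
identity decoys, and classifies the contacts.
"""

from fps import fixtures, frustration

arr = fixtures.synth_toy_structure(fixtures.contact_plan())
contacts = frustration.native_contacts(arr, cutoff=6.5)
print("contact classes from the planted geometry (equal 5 A distances):")
for pair in contacts:
    if (pair.res_i, pair.res_j) in [(1, 3), (31, 33)]:
        print(f"  {pair.res_i}-{pair.res_j}: {pair.contact_class}")

# identity matters more than geometry for the index: compare a salt bridge,
# a hydrophobic core pair and a like-charge clash at the same distance
import dataclasses

results = []
for ti, tj in [("K", "E"), ("I", "L"), ("E", "E"), ("A", "A")]:
    pair = dataclasses.replace(contacts[0], type_i=ti, type_j=tj)
    results.append(frustration.decoy_frustration_index(pair, exhaustive=True))

print(f"\n{'types':>7} {'E_native':>9} {'decoy mean':>11} {'dEfr':>7} {'label':>10}")
for r in results:
    label = "highly" if r.delta_e_fr > 0.78 else ("minimally" if r.delta_e_fr < -1.0 else "neutral")
    print(f"{r.pair.type_i + '-' + r.pair.type_j:>7} {r.e_native:9.2f} "
          f"{r.decoy_mean:11.2f} {r.delta_e_fr:7.2f} {label:>10}")

# dEfr = (E_native - mean(E_decoy)) / sd(E_decoy): positive values mark
# contacts whose native identities are less favourable than random decoys
# (energetically stressed); strongly negative ones are minimally frustrated.
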