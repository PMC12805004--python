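"""Prove each canonical structure's parity verdict by exhaustion.

For every structure kind this enumerates all connected category systems at
two or more resolutions, keeps those invariant under the structure's
transformation group, and reports which parities occur among nontrivial
symmetric systems.  "odd" means every symmetric system has an odd number
of categories (the bisected line: a privileged centre such as 'today'
forces a middle category), "even" means every nontrivial one is even (the
bisected circle and feature spaces: the half-turn or a feature swap pairs
categories up), "both" means the structure imposes no parity constraint.
"""

import catsym as cs

CASES = [
    ("linear", (4, 6, 8)),
    ("bisected_linear", (3, 5, 7, 9)),
    ("bisected_circular", (4, 8, 12)),
    ("binary_feature", (1, 2, 3)),
]

for kind, resolutions in CASES:
    verdict = cs.classify_parity(kind, resolutions)
    witnesses = {
        parity: [sorted(b) for b in system.blocks]
        for parity, system in verdict.witnesses.items()
    }
    print(f"{kind:18s} resolutions={resolutions}  ->  {verdict.verdict}")
    for parity, blocks in witnesses.items():
        print(f"    smallest nontrivial {parity} witness: {blocks}")

s = cs.make_structure("bisected_circular", 8)
print(f"\nbisected_circular(8): group order {s.group.order} "
      f"(reflection + half-turn and their composition)")
sizes = [p.size for p in cs.enumerate_symmetric_systems(s)]
print(f"symmetric system sizes: {sizes} — every nontrivial size is even")
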