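"""Build the toy signalling cascade and inspect its conservation laws.

A mass-action network of a Ras-like GTPase cycle driving a three-tier
kinase cascade.  Every protein moiety (Ras, each kinase, each phosphatase,
...) yields one semi-positive conservation law: the weighted total over its
free, phosphorylated and complexed forms is constant in time.
"""

import crndose as cd

net = cd.build_mapk_toy()
report = cd.validate_network(net)
print(f"network: {net.n} species, {net.r} reactions, "
      f"{len(report.errors)} errors, {len(report.warnings)} warnings")

basis = cd.find_conservation_laws(net)
print(f"\n{basis.p} conservation laws (weakly elemented: {basis.weakly_elemented})")
for l in range(basis.p):
    members = [
        f"{basis.rows[l][i]}*{basis.species[i]}" if basis.rows[l][i] != 1 else basis.species[i]
        for i in range(basis.n)
        if basis.rows[l][i] != 0
    ]
    total = basis.N[l] @ net.x0
    elem = basis.species[basis.elemental_index[l]]
    print(f"  {elem:>7s} moiety: total {total:6.1f} nM = " + " + ".join(members))

# Each line is one conserved moiety: the sum of that protein over all its
# forms never changes along any trajectory, which pins the equilibrium to
# the stoichiometric compatibility class of the initial state.
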