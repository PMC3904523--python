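"""Compute a cutoff-scanning signature for one mutation.

Builds a small synthetic structure, labels its atoms with pharmacophore
classes, and computes the full feature vector for a mutation at one site.
"""

from pathlib import Path
import tempfile

from csmpred import SignatureParams, compute_signature
from csmpred.structure import THREE_TO_ONE, assign_pharmacophores, compute_rsa, read_pdb
from csmpred.synthetic import FixtureSpec, generate_structure

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "demo.pdb"
    path.write_text(generate_structure(FixtureSpec(kind="point-cloud", n_residues=20, seed=1)))
    structure = assign_pharmacophores(read_pdb(path))

site = structure.residues()[5]
chain, position, _ = site
wt = THREE_TO_ONE[structure.residue_name(site)]
mt = "W" if wt != "W" else "G"
rsa = compute_rsa(structure, site)

sig = compute_signature(
    structure, chain, position, wt, mt,
    params=SignatureParams(), ph=7.0, temperature=25.0, rsa=rsa,
)

print(f"mutation {wt}{position}{mt} on chain {chain} of a 20-residue synthetic structure")
print(f"feature vector length: {len(sig.features)}")
named = sig.as_dict()
print(f"total atom pairs within 10 A of the site centre: {named['one_class:atom|atom:10']:.0f}")
print(f"hydrophobic|polar pairs at 8 A: {named['binary:hydrophobic|polar:8']:.0f}")
print("pharmacophore change (mutant - wild type):",
      {k.split(':')[1]: int(v) for k, v in named.items() if k.startswith('p_change:') and v})
print(f"relative solvent accessibility of the site: {named['rsa']:.3f}")
# The distance-pattern counts describe how densely packed (and how polar)
# the wild-type environment is; the p_change entries describe what the
# substitution adds or removes chemically.
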