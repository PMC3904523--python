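"""Convert binding affinities to Gibbs free energies.

Dissociation constants K_D (molar) become binding free energies via
ΔG = R·T·ln K_D, and a mutation's effect on affinity is
ΔΔG = ΔG(mutant) − ΔG(wild type): a positive value means the mutant
binds more weakly (larger K_D).
"""

from csmpred import ddg_binding, delta_g_from_kd

kd_wt = 1e-9   # wild-type complex: 1 nM
kd_mt = 1e-7   # mutant complex: 100 nM, binds worse
t = 298.0      # Kelvin

dg_wt = delta_g_from_kd(kd_wt, t)
dg_mt = delta_g_from_kd(kd_mt, t)
ddg = ddg_binding(kd_wt, kd_mt, t)

print(f"dG(wild type, KD = {kd_wt:g} M) = {dg_wt:.3f} kcal/mol")
print(f"dG(mutant,    KD = {kd_mt:g} M) = {dg_mt:.3f} kcal/mol")
print(f"ddG(binding) = {ddg:+.3f} kcal/mol")
# A 100-fold loss of affinity costs R*T*ln(100) = +2.73 kcal/mol at 298 K:
# the mutant complex is less stable by that amount.
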