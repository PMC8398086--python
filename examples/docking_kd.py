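"""Convert docking binding energies to dissociation constants.

Kd = exp(Eb / R'T) with R' = 1.987207e-3 kcal/(mol K): a lower (more
negative) docking score corresponds to a tighter complex.
"""

import specbind as sb

poses = [-7.53, -7.17, -7.01, -6.42, -5.67]  # kcal/mol

print("Eb (kcal/mol)    Kd (mol/L)")
for eb in poses:
    kd = sb.eb_to_kd(eb, T=298.15)
    print(f"   {eb:+.2f}       {kd:.2e}")

# The map is strictly increasing: each ~1.4 kcal/mol of extra binding energy
# tightens Kd by a factor of ten.  Scores near -7.5 kcal/mol correspond to
# low-micromolar dissociation constants.
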