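"""Layered multistability survey of the TGFb-general EMT parameter graph.

TGFb is the canonical inducer of the epithelial-mesenchymal transition.
Letting its factor graph range over all (essential and inessential) regions
while every other gene stays essential, and sampling parameter nodes per
layer of TGFb actuation, shows how the epithelial (E) and mesenchymal (M)
attractors trade places as TGFb rises -- and how often neither is the whole
story.  A few hundred samples per layer already shows the pattern; the
reported study statistics use 2000.
"""

from switchgraph import multistability_spectrum, survey_layers

survey = survey_layers("TGFb", n_per_layer=400, seed=0)

print("layer   monoE   monoM   E-present  M-present  max-k")
for ls in survey.layers:
    print(
        f"{ls.layer:5d}  {ls.mono_E:6.2f}  {ls.mono_M:6.2f}  "
        f"{ls.E_present:9.2f}  {ls.M_present:9.2f}  {max(ls.k_hist):5d}"
    )

print("\nk-stability spectrum (proportion of parameter nodes per layer):")
print(multistability_spectrum(survey).round(3).to_string(index=False))

print(
    "\nReading: at the lowest TGFb actuation the E state exists everywhere"
    "\nand is often the only attractor; in the middle layers E and M always"
    "\ncoexist (pure multistability); at the top layer the E state survives"
    "\nin roughly a fifth of parameter nodes and complete EMT (monostable M)"
    "\nis guaranteed in only about a quarter."
)
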