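"""From raw feeding-trial assays to model currencies.

A feeding trial reports feed intake in grams per day and feed composition
as mass fractions; the model wants biomass-specific molar carbon rates.
"""

from geostoich import (
    compute_lipid_intake_IH,
    compute_protein_intake_IV,
    consumer_mass_to_molC,
    crude_protein_from_nitrogen,
)

lobster_mass_g = 10.0        # wet mass
feed_intake_g = 0.5          # g day^-1
protein_n_fraction = 0.08    # fraction of feed mass that is protein N
lipid_c_fraction = 0.03      # fraction of feed mass that is lipid C

mass_molC = consumer_mass_to_molC(lobster_mass_g)
iv = compute_protein_intake_IV(feed_intake_g, protein_n_fraction, mass_molC)
ih = compute_lipid_intake_IH(feed_intake_g, lipid_c_fraction, mass_molC)

print(f"a {lobster_mass_g} g lobster is {mass_molC:.5f} mol C")
print(f"crude protein in 1 g of feed N: {crude_protein_from_nitrogen(1.0):.2f} g")
print(f"protein intake I_V = {iv:.5f} mol C (mol C)^-1 day^-1")
print(f"lipid intake   I_H = {ih:.5f} mol C (mol C)^-1 day^-1")
print("these are the units of the packaged trial table")
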