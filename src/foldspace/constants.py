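"""Physical constants used throughout the package.

Free energies are expressed in kcal/mol at the selection temperature.
Model parameters theta are dimensionless; dG = theta * RT.
"""

#: Gas constant, kcal K^-1 mol^-1.
R = 0.001987

#: Selection temperature, K.
T = 303.0

#: RT at the selection temperature, kcal/mol.
RT = R * T

#: Floor applied to predicted growth rates before geometric means.
GROWTH_EPS = 1e-6

PHENOTYPE_ABUNDANCE = "abundance"
PHENOTYPE_BINDING = "binding"
TRAIT_FOLDING = "folding"
TRAIT_BINDING = "binding"

#: Traits entering each phenotype's state model.
PHENOTYPE_TRAITS = {
    PHENOTYPE_ABUNDANCE: (TRAIT_FOLDING,),
    PHENOTYPE_BINDING: (TRAIT_FOLDING, TRAIT_BINDING),
}
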