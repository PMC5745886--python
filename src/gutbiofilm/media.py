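"""Shared namespace for the simulated gut medium.

The biofilm model transports 23 extracellular metabolites: four
monosaccharides, ten amino acids, oxygen, the three short-chain fatty
acids (SCFAs), four organic-acid byproducts and CO2.  All modules index
fields in the canonical orders defined here.
"""

from __future__ import annotations

# Species identifiers: B. thetaiotaomicron, F. prausnitzii, E. coli
BT, FP, EC = "Bt", "Fp", "Ec"
SPECIES: tuple[str, ...] = (BT, FP, EC)

SUGARS: tuple[str, ...] = ("arabinose", "fructose", "galactose", "glucose")
AMINO_ACIDS: tuple[str, ...] = (
    "cysteine", "isoleucine", "leucine", "lysine", "methionine",
    "proline", "serine", "threonine", "tryptophan", "valine",
)
OXYGEN = "o2"

#: nutrient fields in state order (15)
NUTRIENTS: tuple[str, ...] = SUGARS + AMINO_ACIDS + (OXYGEN,)

#: byproduct fields in state order (8)
BYPRODUCTS: tuple[str, ...] = (
    "acetate", "propionate", "butyrate", "ethanol",
    "formate", "lactate", "succinate", "co2",
)
SCFAS: tuple[str, ...] = ("acetate", "propionate", "butyrate")

#: all transported extracellular metabolites, in state order (23)
TRANSPORTED: tuple[str, ...] = NUTRIENTS + BYPRODUCTS

#: carbon atoms per molecule
CARBON: dict[str, int] = {
    "arabinose": 5, "fructose": 6, "galactose": 6, "glucose": 6,
    "cysteine": 3, "isoleucine": 6, "leucine": 6, "lysine": 6,
    "methionine": 5, "proline": 5, "serine": 3, "threonine": 4,
    "tryptophan": 11, "valine": 5,
    "o2": 0,
    "acetate": 2, "propionate": 3, "butyrate": 4, "ethanol": 2,
    "formate": 1, "lactate": 3, "succinate": 4, "co2": 1,
}

#: kinetic class of each transported metabolite (shared uptake kinetics
#: within a class)
KINETIC_CLASS: dict[str, str] = (
    {m: "carbohydrate" for m in SUGARS}
    | {m: "amino_acid" for m in AMINO_ACIDS}
    | {OXYGEN: "oxygen"}
    | {m: "byproduct" for m in BYPRODUCTS}
)

#: metabolite order used for the secondary lexicographic objectives:
#: sugars, amino acids, oxygen, SCFAs, then remaining organic byproducts,
#: each group alphabetical.
LEX_METABOLITE_ORDER: tuple[str, ...] = (
    SUGARS
    + AMINO_ACIDS
    + (OXYGEN,)
    + ("acetate", "butyrate", "propionate")
    + ("co2", "ethanol", "formate", "lactate", "succinate")
)

TRANSPORTED_INDEX: dict[str, int] = {m: i for i, m in enumerate(TRANSPORTED)}
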