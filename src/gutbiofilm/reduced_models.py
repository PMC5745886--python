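"""Reduced metabolic networks for the three-species gut community.

Each species is represented by a lumped-pathway stoichiometric network
(~20-30 reactions) instead of its full genome-scale reconstruction:
catabolism of the four dietary sugars and ten amino acids into a common
six-carbon unit (``g6``), species-specific fermentation routes with
integer-ish carbon and ATP stoichiometry, optional aerobic respiration,
a non-growth ATP maintenance drain (ATPM) and a biomass reaction.

The networks encode the community's qualitative metabolic phenotypes:

* *B. thetaiotaomicron* (Bt) — nutritionally efficient generalist; best
  anaerobic ATP yield from sugars; secretes acetate, propionate,
  succinate, formate and CO2; consumes ethanol (cross-feeding); modest
  aerobic benefit.
* *F. prausnitzii* (Fp) — butyrate producer; consumes acetate and
  succinate; its only oxygen sink is an extracellular flavin/thiol
  electron shuttle giving a small ATP benefit.
* *E. coli* (Ec) — facultative anaerobe; mixed-acid fermentation
  (acetate, ethanol, formate, lactate, succinate); best amino-acid
  utilization; large aerobic respiration benefit.

Genuine genome-scale reconstructions can be loaded from SBML and used
in place of the reduced networks via :func:`load_sbml_model`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .media import (
    AMINO_ACIDS,
    BT,
    BYPRODUCTS,
    CARBON,
    EC,
    FP,
    NUTRIENTS,
    OXYGEN,
    SPECIES,
    SUGARS,
    TRANSPORTED,
)

#: Table-default non-growth ATP maintenance fluxes, mmol/gDW/h
DEFAULT_ATPM: dict[str, float] = {BT: 8.43, FP: 4.75, EC: 5.5}

#: carbon content of 1 gDW biomass, mmol C (sets the g6 demand of the
#: biomass reaction; 40 mmol C/gDW is a standard bacterial value)
BIOMASS_CARBON = 40.0
_G6_PER_BIOMASS = BIOMASS_CARBON / 6.0
#: ATP demand of the biomass reaction, mmol/gDW (growth-associated
#: maintenance; identical across species so that competitive differences
#: come from pathway ATP yields)
ATP_PER_BIOMASS = 40.0

#: fraction of amino-acid carbon converted to g6 (remainder oxidized to
#: CO2); encodes Bt as a carbohydrate specialist and Ec as the best
#: protein utilizer
AA_EFFICIENCY: dict[str, float] = {BT: 0.5, FP: 0.6, EC: 1.0}
#: direct substrate-level ATP per mmol amino acid catabolized
#: (deamination pathways; Ec's specific protein-niche advantage)
AA_ATP_BONUS: dict[str, float] = {BT: 0.0, FP: 0.0, EC: 0.4}

#: ATP yield of aerobic respiration, mmol ATP per mmol g6 (6 O2)
RESPIRATION_ATP: dict[str, float] = {BT: 14.0, EC: 40.0}
#: ATP per mmol O2 through the Fp flavin/thiol electron shuttle
SHUTTLE_ATP = 0.4

#: metabolites each species can take up (negative exchange bound);
#: oxygen uptake by Fp is only feasible through the shuttle reaction
CONSUMABLE: dict[str, tuple[str, ...]] = {
    BT: SUGARS + AMINO_ACIDS + (OXYGEN, "ethanol"),
    FP: SUGARS + AMINO_ACIDS + (OXYGEN, "acetate", "succinate"),
    EC: SUGARS + AMINO_ACIDS + (OXYGEN,),
}

#: byproducts each species can secrete
SECRETED: dict[str, tuple[str, ...]] = {
    BT: ("acetate", "propionate", "succinate", "formate", "co2"),
    FP: ("butyrate", "formate", "co2"),
    EC: ("acetate", "ethanol", "formate", "lactate", "succinate", "co2"),
}

_BIG = 1000.0


@dataclass
class Reaction:
    """One reaction: stoichiometry map plus flux bounds (mmol/gDW/h)."""

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = _BIG

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0.0 < self.upper_bound


@dataclass
class ReducedMetabolicNetwork:
    """Stoichiometric model of one species.

    ``metabolites`` maps metabolite id to compartment tag (``internal``
    or ``exchange``).  Exchange reactions are named ``EX_<metabolite>``
    over the shared medium namespace; by convention a positive exchange
    flux is secretion and a negative flux is uptake.
    """

    species_id: str
    metabolites: dict[str, str]
    reactions: list[Reaction]
    objective_reaction_id: str
    atpm_reaction_id: str
    shuttle_reaction_id: str | None = None
    carbon: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}
        if len(self._rxn_index) != len(self.reactions):
            raise ValueError("duplicate reaction ids")

    # -- lookups ----------------------------------------------------------
    def reaction(self, rxn_id: str) -> Reaction:
        return self.reactions[self._rxn_index[rxn_id]]

    @property
    def atpm(self) -> float:
        return self.reaction(self.atpm_reaction_id).lower_bound

    def set_atpm(self, value: float) -> None:
        if value < 0:
            raise ValueError("ATPM must be non-negative")
        self.reaction(self.atpm_reaction_id).lower_bound = value

    def set_shuttle_enabled(self, enabled: bool) -> None:
        if self.shuttle_reaction_id is None:
            raise ValueError(f"{self.species_id} has no shuttle reaction")
        self.reaction(self.shuttle_reaction_id).upper_bound = _BIG if enabled else 0.0

    def exchange_reaction_id(self, metabolite: str) -> str | None:
        rid = f"EX_{metabolite}"
        return rid if rid in self._rxn_index else None

    @property
    def exchanged_metabolites(self) -> list[str]:
        """Transported medium metabolites with an exchange reaction."""
        return [m for m in TRANSPORTED if f"EX_{m}" in self._rxn_index]

    @property
    def consumable_metabolites(self) -> list[str]:
        """Metabolites whose exchange admits uptake (lb < 0)."""
        return [
            m for m in self.exchanged_metabolites
            if self.reaction(f"EX_{m}").lower_bound < 0
        ]

    def copy(self) -> "ReducedMetabolicNetwork":
        return ReducedMetabolicNetwork(
            species_id=self.species_id,
            metabolites=dict(self.metabolites),
            reactions=[replace(r, stoichiometry=dict(r.stoichiometry))
                       for r in self.reactions],
            objective_reaction_id=self.objective_reaction_id,
            atpm_reaction_id=self.atpm_reaction_id,
            shuttle_reaction_id=self.shuttle_reaction_id,
            carbon=dict(self.carbon),
        )

    # -- diagnostics ------------------------------------------------------
    def carbon_imbalance(self) -> dict[str, float]:
        """Net carbon created by each non-exchange reaction (should be 0).

        Exchange reactions are system boundaries and are excluded, as is
        the biomass sink.
        """
        out: dict[str, float] = {}
        for r in self.reactions:
            if r.id.startswith("EX_"):
                continue
            out[r.id] = sum(
                coef * self.carbon.get(met, 0.0)
                for met, coef in r.stoichiometry.items()
            )
        return out

    # -- interop ----------------------------------------------------------
    def to_cobra(self):
        """Convert to a :class:`cobra.Model` (for SBML export and as an
        independent FBA cross-check)."""
        import cobra

        model = cobra.Model(f"{self.species_id}_reduced")
        mets = {}
        for mid, comp in self.metabolites.items():
            m = cobra.Metabolite(mid, compartment="e" if comp == "exchange" else "c")
            c = self.carbon.get(mid, 0.0)
            if c == int(c):
                m.formula = f"C{int(c)}" if c else ""
            mets[mid] = m
        model.add_metabolites(list(mets.values()))
        rxns = []
        for r in self.reactions:
            cr = cobra.Reaction(r.id, lower_bound=r.lower_bound,
                                upper_bound=r.upper_bound)
            rxns.append(cr)
        model.add_reactions(rxns)
        for r in self.reactions:
            model.reactions.get_by_id(r.id).add_metabolites(
                {mets[m]: c for m, c in r.stoichiometry.items()})
        model.objective = self.objective_reaction_id
        return model


@dataclass(frozen=True)
class CrossFeedingTopology:
    """Directed byproduct cross-feeding edges (producer, metabolite, consumer)."""

    edges: frozenset[tuple[str, str, str]]


def default_cross_feeding() -> CrossFeedingTopology:
    """The modeled cross-feeding: acetate and succinate flow to Fp from
    both producers, ethanol flows from Ec to Bt."""
    return CrossFeedingTopology(frozenset({
        (BT, "acetate", FP),
        (EC, "acetate", FP),
        (BT, "succinate", FP),
        (EC, "succinate", FP),
        (EC, "ethanol", BT),
    }))


def _catabolic_reactions(species_id: str) -> list[Reaction]:
    """Sugar and amino-acid entry reactions into the g6 pool."""
    rxns = []
    for s in SUGARS:
        rxns.append(Reaction(
            f"CAT_{s}", {f"{s}_e": -1.0, "g6_c": CARBON[s] / 6.0}))
    alpha = AA_EFFICIENCY[species_id]
    bonus = AA_ATP_BONUS[species_id]
    for a in AMINO_ACIDS:
        c = CARBON[a]
        st = {f"{a}_e": -1.0,
              "g6_c": alpha * c / 6.0,
              "co2_e": (1.0 - alpha) * c}
        if bonus:
            st["atp_c"] = bonus
        rxns.append(Reaction(f"CAT_{a}", st))
    return rxns


def _fermentation_reactions(species_id: str) -> list[Reaction]:
    """Species-specific energy pathways (all carbon-closed)."""
    if species_id == BT:
        return [
            # branched fermentation with redox-balanced product ratios:
            # acetate, propionate and succinate are co-secreted
            Reaction("FERM_branched", {"g6_c": -1.0, "acetate_e": 1.0,
                                       "propionate_e": 1.0, "succinate_e": 0.25,
                                       "atp_c": 4.0}),
            Reaction("FERM_formate", {"g6_c": -1.0, "acetate_e": 2.0,
                                      "formate_e": 2.0, "atp_c": 3.25}),
            Reaction("ETOH_catabolism", {"ethanol_e": -3.0, "g6_c": 1.0,
                                         "atp_c": 0.5}, upper_bound=2.0),
            Reaction("RESP", {"g6_c": -1.0, "o2_e": -6.0, "co2_e": 6.0,
                              "atp_c": RESPIRATION_ATP[BT]}),
        ]
    if species_id == FP:
        return [
            Reaction("FERM_butyrate", {"g6_c": -1.0, "butyrate_e": 1.0,
                                       "co2_e": 2.0, "atp_c": 2.5}),
            Reaction("FERM_butyrate_formate", {"g6_c": -1.0, "butyrate_e": 1.0,
                                               "formate_e": 2.0, "atp_c": 2.25}),
            # acetate co-utilization into butyrate (slightly more ATP than
            # the pure g6 route, so acetate uptake is strictly beneficial;
            # finite pathway capacity keeps cross-feeding a supplement)
            Reaction("ACCOA_butyrate", {"acetate_e": -2.0, "g6_c": -0.5,
                                        "butyrate_e": 1.75, "atp_c": 1.5},
                     upper_bound=1.5),
            Reaction("SUCC_catabolism", {"succinate_e": -1.0, "g6_c": 0.5,
                                         "co2_e": 1.0},
                     upper_bound=1.5),
            # flavin/thiol extracellular electron shuttle: Fp's only O2 sink
            Reaction("FLVX", {"o2_e": -1.0, "atp_c": SHUTTLE_ATP}),
        ]
    if species_id == EC:
        return [
            # mixed-acid fermentation is Ec's main anaerobic route, with
            # redox-fixed acetate:ethanol:formate = 1:1:2 (the ethanol
            # output is the cross-feeding supply to Bt)
            Reaction("FERM_mixed", {"g6_c": -1.0, "acetate_e": 1.0,
                                    "ethanol_e": 1.0, "formate_e": 2.0,
                                    "atp_c": 2.25}),
            Reaction("FERM_lactate", {"g6_c": -1.0, "lactate_e": 2.0,
                                      "atp_c": 1.5}),
            Reaction("FERM_succinate", {"g6_c": -1.0, "succinate_e": 1.5,
                                        "atp_c": 1.25}),
            Reaction("RESP", {"g6_c": -1.0, "o2_e": -6.0, "co2_e": 6.0,
                              "atp_c": RESPIRATION_ATP[EC]}),
        ]
    raise ValueError(f"unknown species_id {species_id!r}")


def build_reduced_model(
    species_id: str,
    atpm: float | None = None,
    shuttle_enabled: bool = True,
    riboflavin_present: bool = True,
    thiol_present: bool = True,
) -> ReducedMetabolicNetwork:
    """Build the committed reduced network for one species.

    Parameters
    ----------
    species_id :
        One of ``"Bt"``, ``"Fp"``, ``"Ec"``.
    atpm :
        Non-growth ATP maintenance flux (mmol/gDW/h); defaults to the
        species' nominal value.
    shuttle_enabled :
        Fp only — whether the flavin/thiol electron shuttle is active
        (knockout corresponds to clamping its upper bound to zero).  The
        shuttle additionally requires riboflavin and a thiol (cysteine or
        glutathione) in the medium.
    """
    if species_id not in SPECIES:
        raise ValueError(f"unknown species_id {species_id!r}")
    if atpm is None:
        atpm = DEFAULT_ATPM[species_id]
    if atpm < 0:
        raise ValueError("ATPM must be non-negative")

    rxns = _catabolic_reactions(species_id) + _fermentation_reactions(species_id)
    rxns.append(Reaction("ATPM", {"atp_c": -1.0}, lower_bound=atpm))
    rxns.append(Reaction("BIOMASS", {"g6_c": -_G6_PER_BIOMASS,
                                     "atp_c": -ATP_PER_BIOMASS,
                                     "biomass_c": 1.0}))
    rxns.append(Reaction("EX_biomass", {"biomass_c": -1.0}))

    consumable = set(CONSUMABLE[species_id])
    secreted = set(SECRETED[species_id])
    for m in TRANSPORTED:
        if m not in consumable and m not in secreted:
            continue
        lb = -_BIG if m in consumable else 0.0
        ub = _BIG if m in secreted else 0.0
        rxns.append(Reaction(f"EX_{m}", {f"{m}_e": -1.0},
                             lower_bound=lb, upper_bound=ub))

    mets: dict[str, str] = {}
    carbon: dict[str, float] = {}
    for r in rxns:
        for m in r.stoichiometry:
            if m.endswith("_e"):
                mets[m] = "exchange"
                carbon[m] = float(CARBON[m[:-2]])
            else:
                mets[m] = "internal"
    carbon["g6_c"] = 6.0
    carbon["atp_c"] = 0.0  # energy currency, carbon bookkeeping excluded
    carbon["biomass_c"] = BIOMASS_CARBON

    net = ReducedMetabolicNetwork(
        species_id=species_id,
        metabolites=mets,
        reactions=rxns,
        objective_reaction_id="BIOMASS",
        atpm_reaction_id="ATPM",
        shuttle_reaction_id="FLVX" if species_id == FP else None,
        carbon=carbon,
    )
    if species_id == FP:
        active = shuttle_enabled and riboflavin_present and thiol_present
        net.set_shuttle_enabled(active)
    return net


def build_community(
    atpm: dict[str, float] | None = None,
    shuttle_enabled: bool = True,
) -> dict[str, ReducedMetabolicNetwork]:
    """Reduced networks for all three species, keyed by species id."""
    atpm = atpm or {}
    return {
        sp: build_reduced_model(sp, atpm.get(sp), shuttle_enabled=shuttle_enabled)
        for sp in SPECIES
    }


# ---------------------------------------------------------------------------
# SBML interoperability

#: common aliases for medium metabolites in published reconstructions
#: (BiGG-style identifiers); used to auto-map exchange reactions
_SBML_ALIASES: dict[str, str] = {
    "arab__L": "arabinose", "fru": "fructose", "gal": "galactose",
    "glc__D": "glucose", "cys__L": "cysteine", "ile__L": "isoleucine",
    "leu__L": "leucine", "lys__L": "lysine", "met__L": "methionine",
    "pro__L": "proline", "ser__L": "serine", "thr__L": "threonine",
    "trp__L": "tryptophan", "val__L": "valine", "o2": "o2",
    "ac": "acetate", "ppa": "propionate", "but": "butyrate",
    "etoh": "ethanol", "for": "formate", "lac__L": "lactate",
    "lac__D": "lactate", "succ": "succinate", "co2": "co2",
}


def from_cobra(model, species_id: str) -> ReducedMetabolicNetwork:
    """Convert a :class:`cobra.Model` into the network representation."""
    mets = {}
    carbon = {}
    boundary = {m.id for r in model.boundary for m in r.metabolites}
    for m in model.metabolites:
        mets[m.id] = "exchange" if m.id in boundary else "internal"
        carbon[m.id] = float(m.elements.get("C", 0)) if m.formula else 0.0
    rxns = [
        Reaction(r.id, {m.id: c for m, c in r.metabolites.items()},
                 lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        for r in model.reactions
    ]
    from cobra.util.solver import linear_reaction_coefficients

    coeffs = linear_reaction_coefficients(model)
    if len(coeffs) != 1:
        raise ValueError("model must have a single linear objective reaction")
    objective_id = next(iter(coeffs)).id
    atpm_id = "ATPM" if "ATPM" in {r.id for r in model.reactions} else objective_id
    return ReducedMetabolicNetwork(
        species_id=species_id, metabolites=mets, reactions=rxns,
        objective_reaction_id=objective_id, atpm_reaction_id=atpm_id,
        carbon=carbon,
    )


def load_sbml_model(
    path,
    species_id: str,
    exchange_map: dict[str, str] | None = None,
    atpm: float | None = None,
) -> ReducedMetabolicNetwork:
    """Load a reconstruction from SBML and remap its exchange reactions
    onto the medium namespace.

    ``exchange_map`` maps SBML exchange reaction ids to medium metabolite
    names; metabolites not covered are auto-mapped from common
    identifier aliases.  All metabolites the species must exchange
    (its consumables and secreted byproducts, plus oxygen) have to be
    mappable; otherwise a :class:`ValueError` lists the missing names.
    """
    import cobra.io

    if species_id not in SPECIES:
        raise ValueError(f"unknown species_id {species_id!r}")
    model = cobra.io.read_sbml_model(str(path))

    mapping: dict[str, str] = {}  # exchange reaction id -> medium name
    for rxn in model.boundary:
        if len(rxn.metabolites) != 1:
            continue
        met = next(iter(rxn.metabolites))
        base = met.id[:-2] if met.id.endswith("_e") else met.id
        if exchange_map and rxn.id in exchange_map:
            mapping[rxn.id] = exchange_map[rxn.id]
        elif base in _SBML_ALIASES:
            mapping[rxn.id] = _SBML_ALIASES[base]
        elif base in TRANSPORTED:
            mapping[rxn.id] = base

    required = set(CONSUMABLE[species_id]) | set(SECRETED[species_id])
    missing = sorted(required - set(mapping.values()))
    if missing:
        raise ValueError(
            f"SBML model for {species_id} lacks exchange reactions for: "
            + ", ".join(missing)
        )

    net = from_cobra(model, species_id)
    # rename mapped exchange reactions and metabolites into the medium
    # namespace without touching stoichiometry
    rename_met: dict[str, str] = {}
    for rxn_id, name in mapping.items():
        r = net.reaction(rxn_id)
        old_met = next(iter(r.stoichiometry))
        rename_met[old_met] = f"{name}_e"
    for r in net.reactions:
        r.stoichiometry = {rename_met.get(m, m): c
                           for m, c in r.stoichiometry.items()}
    net.metabolites = {rename_met.get(m, m): c for m, c in net.metabolites.items()}
    net.carbon = {rename_met.get(m, m): c for m, c in net.carbon.items()}
    for rxn_id, name in mapping.items():
        net.reaction(rxn_id).id = f"EX_{name}"
    net.__post_init__()
    if atpm is not None:
        net.set_atpm(atpm)
    return net


def write_sbml_model(network: ReducedMetabolicNetwork, path) -> None:
    """Serialize a network to SBML via cobra."""
    import cobra.io

    cobra.io.write_sbml_model(network.to_cobra(), str(path))
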