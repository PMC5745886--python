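"""Lexicographic flux balance analysis with kinetic uptake bounds.

At every spatial node and time the local nutrient concentrations set
Michaelis-Menten uptake bounds, which are imposed as (signed) lower
bounds on the exchange reactions of each species' LP.  Growth
maximization is the primary objective; because the growth-optimal flux
distribution is generally degenerate, exchange fluxes are made unique by
lexicographic optimization: after fixing the biomass optimum, each
exchange flux is maximized in a fixed, documented metabolite order
(sugars, amino acids, oxygen, SCFAs, remaining organic byproducts —
each group alphabetical).  Maximizing an exchange flux simultaneously
minimizes uptake magnitude (uptake is negative) and maximizes secretion.

The solver is GLPK (via swiglpk) with a persistent problem object per
network, warm-started between lexicographic stages; each stage objective
is a single flux, so fixing a stage optimum reduces to clamping one
column.  Solutions are memoized on the quantized uptake-bound vector,
which both accelerates the PDE right-hand side and makes repeated calls
bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import swiglpk as glp

glp.glp_term_out(glp.GLP_OFF)

from .media import KINETIC_CLASS, LEX_METABOLITE_ORDER, TRANSPORTED, TRANSPORTED_INDEX
from .reduced_models import ReducedMetabolicNetwork

#: concentrations below this (mM) are treated as exactly zero before
#: kinetic-bound evaluation (guards against integrator round-off)
CLIP_CONCENTRATION = 1e-12
#: concentrations more negative than this raise (integrator overshoot)
NEGATIVE_TOLERANCE = -1e-9
#: solver outputs are quantized to this many decimals for determinism
_RESULT_DECIMALS = 10
#: uptake-bound vectors are quantized to this many decimals before the
#: LP sees them (cache granularity; 1e-4 mmol/gDW/h)
_KEY_DECIMALS = 4


def mm_bound(concentration: float, v_max: float, K_m: float) -> float:
    """Michaelis-Menten uptake bound v_max*C/(K_m+C), mmol/gDW/h."""
    if concentration < NEGATIVE_TOLERANCE:
        raise ValueError(
            f"negative concentration {concentration!r} (integrator overshoot)")
    if concentration < CLIP_CONCENTRATION:
        return 0.0
    return v_max * concentration / (K_m + concentration)


@dataclass(frozen=True)
class KineticBound:
    """Uptake kinetics for one metabolite."""

    metabolite: str
    v_max: float  # mmol/gDW/h
    K_m: float    # mM

    def __post_init__(self) -> None:
        if self.v_max < 0 or self.K_m <= 0:
            raise ValueError("require v_max >= 0 and K_m > 0")

    def bound_at(self, concentration: float) -> float:
        return mm_bound(concentration, self.v_max, self.K_m)


#: nominal uptake kinetics per metabolite class: (v_max, K_m)
DEFAULT_CLASS_KINETICS: dict[str, tuple[float, float]] = {
    "carbohydrate": (10.0, 0.5),
    "amino_acid": (1.0, 0.1),
    "oxygen": (20.0, 0.003),
    "byproduct": (10.0, 0.5),
}


def default_kinetics() -> dict[str, KineticBound]:
    """Per-metabolite kinetic bounds at their nominal class values."""
    return {
        m: KineticBound(m, *DEFAULT_CLASS_KINETICS[KINETIC_CLASS[m]])
        for m in TRANSPORTED
    }


@dataclass
class FluxSolution:
    """Growth rate and uniquely resolved exchange fluxes for one species
    at one grid node (uptake negative, secretion positive)."""

    growth_rate: float
    exchange_fluxes: dict[str, float]
    feasible: bool = True


class LexicographicSolver:
    """Persistent lexicographic LP solver for one network.

    Parameters
    ----------
    network :
        The stoichiometric model.
    objective_order :
        Ordered list of ``(reaction_id, sense)`` with sense ``"max"`` or
        ``"min"``; must begin with biomass maximization.  Defaults to
        biomass followed by every exchange flux (maximized) in the
        canonical metabolite order.
    """

    def __init__(
        self,
        network: ReducedMetabolicNetwork,
        objective_order: list[tuple[str, str]] | None = None,
        cache_size: int = 300_000,
    ):
        self.network = network
        if objective_order is None:
            objective_order = [(network.objective_reaction_id, "max")] + [
                (f"EX_{m}", "max")
                for m in LEX_METABOLITE_ORDER
                if network.exchange_reaction_id(m) is not None
            ]
        if not objective_order or objective_order[0][0] != network.objective_reaction_id:
            raise ValueError("objective_order must begin with biomass maximization")
        self.objective_order = list(objective_order)

        self._rxn_ids = [r.id for r in network.reactions]
        self._col = {rid: j + 1 for j, rid in enumerate(self._rxn_ids)}
        self._static_bounds = {
            r.id: (r.lower_bound, r.upper_bound) for r in network.reactions}
        #: consumable metabolites in fixed order; the bound vector given
        #: to :meth:`solve_array` follows this order
        self.consumables: list[str] = network.consumable_metabolites
        self._cache: dict[tuple, tuple] = {}
        self._cache_size = cache_size
        self._build_problem()
        # precomputed index tables for the hot solve path
        self._cons_cols = [self._col[f"EX_{m}"] for m in self.consumables]
        self._cons_ubs = [self._static_bounds[f"EX_{m}"][1]
                          for m in self.consumables]
        self._ex_cols = [(self._col[f"EX_{m}"], TRANSPORTED_INDEX[m])
                         for m in network.exchanged_metabolites]
        cons_by_col = {j: i for i, j in enumerate(self._cons_cols)}
        self._stages = []
        for rxn_id, sense in self.objective_order:
            j = self._col[rxn_id]
            self._stages.append((j, 1.0 if sense == "max" else -1.0,
                                 cons_by_col.get(j)))

    def _build_problem(self) -> None:
        net = self.network
        met_ids = list(net.metabolites)
        mrow = {m: i + 1 for i, m in enumerate(met_ids)}
        lp = glp.glp_create_prob()
        glp.glp_set_obj_dir(lp, glp.GLP_MAX)
        glp.glp_add_rows(lp, len(met_ids))
        for m, i in mrow.items():
            glp.glp_set_row_bnds(lp, i, glp.GLP_FX, 0.0, 0.0)
        glp.glp_add_cols(lp, len(net.reactions))
        entries = []
        for r in net.reactions:
            j = self._col[r.id]
            self._set_col(lp, j, r.lower_bound, r.upper_bound)
            for m, c in r.stoichiometry.items():
                entries.append((mrow[m], j, float(c)))
        ia = glp.intArray(len(entries) + 1)
        ja = glp.intArray(len(entries) + 1)
        ar = glp.doubleArray(len(entries) + 1)
        for k, (i, j, c) in enumerate(entries, start=1):
            ia[k], ja[k], ar[k] = i, j, c
        glp.glp_load_matrix(lp, len(entries), ia, ja, ar)
        parm = glp.glp_smcp()
        glp.glp_init_smcp(parm)
        parm.msg_lev = glp.GLP_MSG_OFF
        # guard against degenerate-vertex cycling: bound the work per
        # solve and fall back to a fresh basis if the limit is hit
        parm.it_lim = 20_000
        parm.tm_lim = 2_000  # ms
        self._lp = lp
        self._parm = parm
        glp.glp_adv_basis(lp, 0)

    @staticmethod
    def _set_col(lp, j: int, lb: float, ub: float) -> None:
        if lb == ub:
            glp.glp_set_col_bnds(lp, j, glp.GLP_FX, lb, ub)
        else:
            glp.glp_set_col_bnds(lp, j, glp.GLP_DB, lb, ub)

    # -- core solve -------------------------------------------------------
    def solve_array(self, uptake_bounds,
                    quantized: bool = False) -> tuple[float, np.ndarray, bool]:
        """Solve for a bound vector over :attr:`consumables`.

        Returns ``(growth_rate, exchange_flux_vector, feasible)`` where
        the flux vector is aligned with :data:`~gutbiofilm.media.TRANSPORTED`.
        ``quantized`` marks bound vectors already rounded to the cache
        granularity.
        """
        if quantized:
            key = tuple(uptake_bounds)
        else:
            key = tuple(round(float(b), _KEY_DECIMALS) for b in uptake_bounds)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        result = self._solve_uncached(key)
        if len(self._cache) >= self._cache_size:
            self._cache.clear()
        self._cache[key] = result
        return result

    def _solve_uncached(self, bounds: tuple) -> tuple[float, np.ndarray, bool]:
        lp, parm = self._lp, self._parm
        for j, ub, b in zip(self._cons_cols, self._cons_ubs, bounds):
            self._set_col(lp, j, -b if b > 0.0 else 0.0, ub)

        fixed: list[int] = []
        growth = 0.0
        feasible = True
        for stage, (j, coef, cons_idx) in enumerate(self._stages):
            if stage > 0 and cons_idx is not None:
                # an exchange clamped to zero by its kinetic bound (and a
                # zero secretion capacity) is already unique: no LP needed
                if bounds[cons_idx] == 0.0 and self._cons_ubs[cons_idx] == 0.0:
                    continue
            glp.glp_set_obj_coef(lp, j, coef)
            ret = glp.glp_simplex(lp, parm)
            status = glp.glp_get_status(lp)
            if ret != 0 or status != glp.GLP_OPT:
                # retry from a fresh basis before declaring infeasibility
                glp.glp_std_basis(lp)
                ret = glp.glp_simplex(lp, parm)
                status = glp.glp_get_status(lp)
            glp.glp_set_obj_coef(lp, j, 0.0)
            if ret != 0 or status != glp.GLP_OPT:
                feasible = False
                break
            val = glp.glp_get_col_prim(lp, j)
            if stage == 0:
                growth = val
            glp.glp_set_col_bnds(lp, j, glp.GLP_FX, val, val)
            fixed.append(j)

        ex = np.zeros(len(TRANSPORTED))
        if feasible:
            for j, t_idx in self._ex_cols:
                ex[t_idx] = glp.glp_get_col_prim(lp, j)
            ex = np.round(ex, _RESULT_DECIMALS)
            ex[np.abs(ex) < 1e-9] = 0.0
            growth = round(max(growth, 0.0), _RESULT_DECIMALS)
        else:
            growth = 0.0

        # restore static column bounds of fixed stage variables
        cons_by_col = dict(zip(self._cons_cols, bounds))
        for j in fixed:
            lb, ub = self._static_bounds[self._rxn_ids[j - 1]]
            if j in cons_by_col:
                b = cons_by_col[j]
                lb = -b if b > 0.0 else 0.0
            self._set_col(lp, j, lb, ub)
        ex.setflags(write=False)
        return growth, ex, feasible

    def solve(self, uptake_bounds: dict[str, float]) -> FluxSolution:
        """Solve with a metabolite -> max-uptake-rate mapping (mmol/gDW/h).

        Metabolites absent from the mapping get a zero uptake bound.
        """
        vec = [uptake_bounds.get(m, 0.0) for m in self.consumables]
        growth, ex, feasible = self.solve_array(vec)
        fluxes = {
            m: float(ex[TRANSPORTED_INDEX[m]])
            for m in self.network.exchanged_metabolites
        }
        return FluxSolution(growth_rate=float(growth),
                            exchange_fluxes=fluxes, feasible=feasible)

    def bounds_from_concentrations(
        self, concentrations: dict[str, float],
        kinetics: dict[str, KineticBound] | None = None,
    ) -> dict[str, float]:
        """Evaluate the Michaelis-Menten bound of every consumable."""
        kin = kinetics or default_kinetics()
        return {
            m: kin[m].bound_at(concentrations.get(m, 0.0))
            for m in self.consumables
        }


def solve_lexicographic(
    model: ReducedMetabolicNetwork,
    uptake_bounds: dict[str, float],
    objective_order: list[tuple[str, str]] | None = None,
) -> FluxSolution:
    """One-shot lexicographic solve (convenience wrapper).

    For repeated solves of the same network construct a
    :class:`LexicographicSolver` once and reuse it.
    """
    return LexicographicSolver(model, objective_order).solve(uptake_bounds)
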