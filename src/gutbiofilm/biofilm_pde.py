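"""Reaction-diffusion biofilm model with embedded flux balance analysis.

The biofilm occupies a fixed depth ``[0, L]`` with ``z = 0`` at the
intestine(mucosa)-biofilm boundary and ``z = L`` at the biofilm-stool
boundary where nutrients (including oxygen) enter.  The method of lines
discretizes each field on a uniform grid of ``N`` nodes with
second-order central differences; Robin (mass-transfer) boundary
conditions are implemented with ghost nodes.  For 3 species, 15
nutrients and 8 byproducts the discretized system has ``26 N`` ODEs.

Field equations (per node, internal units: h, cm, mM, g/L)::

    dX_i/dt = D_X d2X_i/dz2 + (mu_i - k_death,i) X_i
    dS_j/dt = D_j d2S_j/dz2 + sum_i v_ij X_i      (v < 0 for uptake)
    dP_k/dt = D_k d2P_k/dz2 + sum_i v_ik X_i

with boundary conditions: nutrients enter at the stool side against the
diet bulk concentration and leave at the mucosa side against zero bulk;
byproducts leave at both boundaries against zero bulk; biomass is
eroded at the stool side against zero bulk and has a zero-flux mucosa
boundary.  The exchange fluxes ``v`` and growth rates ``mu`` come from
the lexicographic FBA of each species at the local concentrations.

Steady states are found with an adaptive semi-implicit (linearly
implicit) scheme: diffusion, boundary exchange and consumption terms
are treated implicitly (guaranteeing positivity), production and growth
explicitly.  The scheme's fixed points are exact steady states of the
semi-discrete system, independent of the step size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

from .fba_engine import CLIP_CONCENTRATION, LexicographicSolver
from .media import (
    BYPRODUCTS,
    KINETIC_CLASS,
    NUTRIENTS,
    SPECIES,
    TRANSPORTED,
    TRANSPORTED_INDEX,
)
from .media import CARBON
from .reduced_models import (
    BIOMASS_CARBON,
    DEFAULT_ATPM,
    ReducedMetabolicNetwork,
    build_community,
)

_SECONDS_PER_HOUR = 3600.0
_CM_PER_UM = 1e-4

N_FIELDS = len(SPECIES) + len(TRANSPORTED)  # 26


def count_odes(N: int) -> int:
    """Number of ODEs after discretizing on ``N`` grid nodes (26 per node)."""
    if N < 1:
        raise ValueError("grid size must be at least 1")
    return N_FIELDS * N


@dataclass
class ParameterSet:
    """Nominal model parameters in their tabulated units.

    Diffusion coefficients are cm^2/s, mass-transfer coefficients cm/s,
    the biofilm thickness is in micrometers, concentrations in mM and
    biomass in g/L.  :meth:`internal` converts exactly once to the
    internal hour/cm/mM/(g/L) system.
    """

    L_um: float = 40.0
    # biomass
    D_X: float = 1e-10
    k_X: float = 1e-7
    X_b: float = 0.0
    # nutrients
    D_carbohydrate: float = 2e-6
    D_amino_acid: float = 2e-6
    D_oxygen: float = 8e-6
    k_carbohydrate: float = 2e-4
    k_amino_acid: float = 2e-4
    k_oxygen: float = 2e-2
    O_b: float = 0.0
    # byproducts
    D_byproduct: float = 2e-6
    k_byproduct: float = 5e-6
    k_butyrate: float = 5e-5
    k_propionate: float = 1e-5
    P_b: float = 0.0
    # uptake kinetics per class: (v_max mmol/gDW/h, K_m mM)
    v_max: dict[str, float] = field(default_factory=lambda: {
        "carbohydrate": 10.0, "amino_acid": 1.0,
        "oxygen": 20.0, "byproduct": 10.0})
    K_m: dict[str, float] = field(default_factory=lambda: {
        "carbohydrate": 0.5, "amino_acid": 0.1,
        "oxygen": 0.003, "byproduct": 0.5})
    # non-growth ATP maintenance per species, mmol/gDW/h
    atpm: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ATPM))

    def __post_init__(self) -> None:
        for name in ("L_um", "D_X", "k_X", "X_b", "D_carbohydrate",
                     "D_amino_acid", "D_oxygen", "k_carbohydrate",
                     "k_amino_acid", "k_oxygen", "O_b", "D_byproduct",
                     "k_byproduct", "k_butyrate", "k_propionate", "P_b"):
            if getattr(self, name) < 0:
                raise ValueError(f"parameter {name} must be non-negative")

    def internal(self) -> "InternalParams":
        """Convert to internal units (hours and cm)."""
        s = _SECONDS_PER_HOUR
        D = np.empty(len(TRANSPORTED))
        k = np.empty(len(TRANSPORTED))
        vmax = np.empty(len(TRANSPORTED))
        km = np.empty(len(TRANSPORTED))
        for m, idx in TRANSPORTED_INDEX.items():
            cls = KINETIC_CLASS[m]
            D[idx] = getattr(self, f"D_{cls}") * s
            if m == "butyrate":
                k[idx] = self.k_butyrate * s
            elif m == "propionate":
                k[idx] = self.k_propionate * s
            else:
                k[idx] = getattr(self, f"k_{cls}") * s
            vmax[idx] = self.v_max[cls]
            km[idx] = self.K_m[cls]
        return InternalParams(
            L=self.L_um * _CM_PER_UM,
            D_X=self.D_X * s, k_X=self.k_X * s, X_b=self.X_b,
            D=D, k=k, v_max=vmax, K_m=km,
            O_b=self.O_b, P_b=self.P_b, atpm=dict(self.atpm),
            table=self,
        )


@dataclass
class InternalParams:
    """Parameters converted to h/cm/mM/(g/L); arrays follow
    :data:`~gutbiofilm.media.TRANSPORTED` order."""

    L: float
    D_X: float
    k_X: float
    X_b: float
    D: np.ndarray
    k: np.ndarray
    v_max: np.ndarray
    K_m: np.ndarray
    O_b: float
    P_b: float
    atpm: dict[str, float]
    table: ParameterSet

    def to_table_units(self) -> ParameterSet:
        """Inverse of :meth:`ParameterSet.internal` (round-trip check)."""
        return replace(self.table)


@dataclass
class BiofilmState:
    """Biomass, nutrient and byproduct fields on the spatial grid.

    ``X`` is (3, N) in g/L over species order (Bt, Fp, Ec); ``S`` is
    (15, N) and ``P`` (8, N) in mM over the canonical metabolite orders.
    Node 0 is the mucosa boundary, node N-1 the stool boundary.
    """

    z: np.ndarray
    X: np.ndarray
    S: np.ndarray
    P: np.ndarray

    @property
    def N(self) -> int:
        return self.z.size

    @property
    def C(self) -> np.ndarray:
        """All transported concentrations stacked, (23, N)."""
        return np.vstack([self.S, self.P])

    def pack(self) -> np.ndarray:
        return np.concatenate([self.X.ravel(), self.S.ravel(), self.P.ravel()])

    @classmethod
    def unpack(cls, y: np.ndarray, z: np.ndarray) -> "BiofilmState":
        N = z.size
        nX, nS = len(SPECIES) * N, len(NUTRIENTS) * N
        return cls(z=z,
                   X=y[:nX].reshape(len(SPECIES), N),
                   S=y[nX:nX + nS].reshape(len(NUTRIENTS), N),
                   P=y[nX + nS:].reshape(len(BYPRODUCTS), N))

    @classmethod
    def homogeneous(cls, N: int, L: float, X0: float = 10.0,
                    S0: np.ndarray | None = None,
                    P0: np.ndarray | None = None) -> "BiofilmState":
        """Spatially homogeneous initial condition (biomass in g/L)."""
        z = np.linspace(0.0, L, N)
        X = np.full((len(SPECIES), N), float(X0))
        S = np.zeros((len(NUTRIENTS), N)) if S0 is None \
            else np.tile(np.asarray(S0, float)[:, None], N)
        P = np.zeros((len(BYPRODUCTS), N)) if P0 is None \
            else np.tile(np.asarray(P0, float)[:, None], N)
        return cls(z=z, X=X, S=S, P=P)

    def copy(self) -> "BiofilmState":
        return BiofilmState(self.z.copy(), self.X.copy(),
                            self.S.copy(), self.P.copy())

    def regrid(self, N: int) -> "BiofilmState":
        """Linear interpolation of every field onto an N-node grid."""
        z = np.linspace(self.z[0], self.z[-1], N)

        def interp(A):
            return np.vstack([np.interp(z, self.z, row) for row in A])

        return BiofilmState(z=z, X=interp(self.X), S=interp(self.S),
                            P=interp(self.P))


def boundary_flux(side: str, field_class: str, value_at_boundary: float,
                  bulk: float, k: float) -> float:
    """Outward Robin boundary flux ``k (C_boundary - C_bulk)``.

    Biomass has a zero-flux mucosa (intestine) boundary; all other
    combinations exchange against the given bulk concentration.
    """
    if side not in ("stool", "intestine"):
        raise ValueError(f"unknown side {side!r}")
    if field_class not in ("biomass", "nutrient", "byproduct"):
        raise ValueError(f"unknown field class {field_class!r}")
    if k < 0:
        raise ValueError("mass-transfer coefficient must be non-negative")
    if field_class == "biomass" and side == "intestine":
        return 0.0
    return k * (value_at_boundary - bulk)


@dataclass
class FeedbackConfig:
    """Linear host-microbiota feedback on the bulk oxygen concentration.

    A sustained perturbation ``O_pert`` is applied at time zero when the
    biofilm-averaged *F. prausnitzii* biomass is at its anaerobic value;
    the bulk oxygen concentration then rises linearly as Fp declines,
    reaching ``O_max`` when Fp is extinct.
    """

    O_pert: float            # mM
    fp_anaerobic_mean: float  # g/L
    O_max: float = 5e-3      # mM


def feedback_bulk_oxygen(mean_fp: float, mean_fp_anaerobic: float,
                         O_pert: float, O_max: float = 5e-3) -> float:
    """Bulk oxygen under linear host feedback, clamped to [O_pert, O_max]."""
    if mean_fp_anaerobic <= 0:
        raise ValueError("anaerobic Fp mean must be positive")
    o = O_pert + (O_max - O_pert) * (1.0 - mean_fp / mean_fp_anaerobic)
    return float(min(max(o, O_pert), O_max))


class BiofilmModel:
    """Couples the species LPs to the reaction-diffusion transport.

    Parameters
    ----------
    networks :
        Mapping species id -> stoichiometric network; defaults to the
        committed reduced community.
    params :
        Model parameters (tabulated units).
    N :
        Number of grid nodes.
    diet_bulk :
        Mapping nutrient -> bulk concentration at the stool boundary
        (mM, actual basis).
    feedback :
        Optional :class:`FeedbackConfig`; mutually exclusive with a
        nonzero fixed ``params.O_b``.
    death_rates :
        Optional per-species first-order death rates (1/h), e.g. from
        antibiotic exposure; spatially uniform.
    """

    def __init__(
        self,
        params: ParameterSet,
        diet_bulk: dict[str, float],
        networks: dict[str, ReducedMetabolicNetwork] | None = None,
        N: int = 20,
        feedback: FeedbackConfig | None = None,
        death_rates: dict[str, float] | None = None,
        objective_orders: dict[str, list] | None = None,
    ):
        if feedback is not None and params.O_b != 0.0:
            raise ValueError("feedback and a fixed bulk oxygen are exclusive")
        if networks is None:
            networks = build_community(atpm=params.atpm)
        else:
            networks = {sp: net.copy() for sp, net in networks.items()}
            for sp, net in networks.items():
                net.set_atpm(params.atpm[sp])
        self.networks = networks
        self.params = params
        self.ip = params.internal()
        self.N = int(N)
        self.z = np.linspace(0.0, self.ip.L, self.N)
        self.dz = self.ip.L / (self.N - 1) if self.N > 1 else self.ip.L
        self.feedback = feedback
        self.death = np.array([
            (death_rates or {}).get(sp, 0.0) for sp in SPECIES])
        self.solvers = {
            sp: LexicographicSolver(
                networks[sp],
                None if objective_orders is None else objective_orders.get(sp))
            for sp in SPECIES
        }
        # per-species index of consumable metabolites into the 23-vector
        self._cons_idx = {
            sp: np.array([TRANSPORTED_INDEX[m] for m in self.solvers[sp].consumables],
                         dtype=int)
            for sp in SPECIES
        }
        self.diet_bulk = dict(diet_bulk)
        self._bulk_stool = np.zeros(len(TRANSPORTED))
        for m, v in diet_bulk.items():
            self._bulk_stool[TRANSPORTED_INDEX[m]] = v
        self._o2_idx = TRANSPORTED_INDEX["o2"]
        self._bulk_stool[self._o2_idx] = params.O_b
        for m in BYPRODUCTS:
            self._bulk_stool[TRANSPORTED_INDEX[m]] = params.P_b
        self._bulk_intestine = np.zeros(len(TRANSPORTED))
        self._bulk_intestine[[TRANSPORTED_INDEX[m] for m in BYPRODUCTS]] = params.P_b
        self._carbon = np.array([float(CARBON[m]) for m in TRANSPORTED])
        self.lp_solves = 0

    # -- bulk oxygen (possibly state-dependent through feedback) ----------
    def bulk_oxygen(self, state: BiofilmState) -> float:
        if self.feedback is None:
            return self.params.O_b
        mean_fp = float(np.trapezoid(state.X[1], state.z) /
                        (state.z[-1] - state.z[0]))
        return feedback_bulk_oxygen(mean_fp, self.feedback.fp_anaerobic_mean,
                                    self.feedback.O_pert, self.feedback.O_max)

    # -- local FBA --------------------------------------------------------
    def flux_field(self, state: BiofilmState) -> tuple[np.ndarray, np.ndarray]:
        """Solve the per-node LPs.

        Returns ``(mu, ex)`` with ``mu`` (3, N) growth rates (1/h) and
        ``ex`` (3, 23, N) exchange fluxes (mmol/gDW/h).
        """
        C = np.maximum(state.C, 0.0)
        C[C < CLIP_CONCENTRATION] = 0.0
        ip = self.ip
        mu = np.zeros((len(SPECIES), self.N))
        ex = np.zeros((len(SPECIES), len(TRANSPORTED), self.N))
        for i, sp in enumerate(SPECIES):
            idx = self._cons_idx[sp]
            conc = C[idx]
            bounds = ip.v_max[idx, None] * conc / (ip.K_m[idx, None] + conc)
            solver = self.solvers[sp]
            cols = np.round(bounds, 4).T.tolist()
            for n in range(self.N):
                g, fluxes, _feasible = solver.solve_array(cols[n],
                                                          quantized=True)
                self.lp_solves += 1
                mu[i, n] = g
                ex[i, :, n] = fluxes
        return mu, ex

    # -- transport operators ----------------------------------------------
    def _transport_terms(self, o2_bulk: float):
        """Banded diffusion+Robin operators: per field, (A bands, b)."""
        bulk_stool = self._bulk_stool.copy()
        bulk_stool[self._o2_idx] = o2_bulk
        ops = []
        # transported fields
        for f in range(len(TRANSPORTED)):
            D, k = self.ip.D[f], self.ip.k[f]
            ops.append(self._robin_bands(D, k, self._bulk_intestine[f],
                                         k, bulk_stool[f]))
        # biomass: zero-flux mucosa, erosion at stool side
        bm = self._robin_bands(self.ip.D_X, 0.0, 0.0, self.ip.k_X, self.ip.X_b)
        return ops, bm

    def _band_arrays(self, o2_bulk: float):
        """Stacked transport bands for all 26 fields (3 biomass + 23
        transported): arrays (lower, diag, upper, b), each (26, N)."""
        cached = getattr(self, "_band_cache", None)
        if cached is not None and cached[0] == o2_bulk:
            return cached[1]
        ops, bm = self._transport_terms(o2_bulk)
        rows = [bm] * len(SPECIES) + ops
        arrs = tuple(np.array([r[j] for r in rows]) for j in range(4))
        self._band_cache = (o2_bulk, arrs)
        return arrs

    @staticmethod
    def _thomas(lo: np.ndarray, dg: np.ndarray, up: np.ndarray,
                rhs: np.ndarray) -> np.ndarray:
        """Vectorized Thomas solve of many independent tridiagonal
        systems; row i couples y[i-1] (lo), y[i] (dg), y[i+1] (up)."""
        n = rhs.shape[1]
        cp = np.empty_like(rhs)
        dp = np.empty_like(rhs)
        cp[:, 0] = up[:, 0] / dg[:, 0]
        dp[:, 0] = rhs[:, 0] / dg[:, 0]
        for i in range(1, n):
            m = dg[:, i] - lo[:, i] * cp[:, i - 1]
            cp[:, i] = up[:, i] / m
            dp[:, i] = (rhs[:, i] - lo[:, i] * dp[:, i - 1]) / m
        x = np.empty_like(rhs)
        x[:, -1] = dp[:, -1]
        for i in range(n - 2, -1, -1):
            x[:, i] = dp[:, i] - cp[:, i] * x[:, i + 1]
        return x

    def _robin_bands(self, D: float, k_left: float, bulk_left: float,
                     k_right: float, bulk_right: float):
        """Bands (lower, diag, upper) of the transport operator A and the
        constant boundary source b, such that transport = A y + b."""
        N, dz = self.N, self.dz
        diag = np.zeros(N)
        lower = np.zeros(N)
        upper = np.zeros(N)
        b = np.zeros(N)
        if D <= 0.0 or N < 2:
            return lower, diag, upper, b
        w = D / dz**2
        diag[:] = -2.0 * w
        lower[:] = w
        upper[:] = w
        # ghost-node Robin closure at both ends
        upper[0] = 2.0 * w
        diag[0] -= 2.0 * k_left / dz
        b[0] = 2.0 * k_left / dz * bulk_left
        lower[-1] = 2.0 * w
        diag[-1] -= 2.0 * k_right / dz
        b[-1] = 2.0 * k_right / dz * bulk_right
        return lower, diag, upper, b

    @staticmethod
    def _apply_bands(bands, y: np.ndarray) -> np.ndarray:
        lower, diag, upper, b = bands
        out = diag * y + b
        out[:-1] += upper[:-1] * y[1:]
        out[1:] += lower[1:] * y[:-1]
        return out

    # -- right-hand side ---------------------------------------------------
    def assemble_rhs(self, state: BiofilmState,
                     flux_field: tuple[np.ndarray, np.ndarray] | None = None
                     ) -> BiofilmState:
        """Time derivative of every field (same shapes as the state)."""
        if flux_field is None:
            flux_field = self.flux_field(state)
        mu, ex = flux_field
        if mu.shape != (len(SPECIES), self.N) or \
                ex.shape != (len(SPECIES), len(TRANSPORTED), self.N):
            raise ValueError("flux field shape mismatch")
        ops, bm = self._transport_terms(self.bulk_oxygen(state))
        dX = np.empty_like(state.X)
        for i in range(len(SPECIES)):
            dX[i] = self._apply_bands(bm, state.X[i]) \
                + (mu[i] - self.death[i]) * state.X[i]
        # mmol/gDW/h * g/L = mM/h
        reaction = np.einsum("ifn,in->fn", ex, state.X)
        C = state.C
        dC = np.empty_like(C)
        for f in range(len(TRANSPORTED)):
            dC[f] = self._apply_bands(ops[f], C[f]) + reaction[f]
        nS = len(NUTRIENTS)
        return BiofilmState(z=state.z, X=dX, S=dC[:nS], P=dC[nS:])

    def rhs_flat(self, t: float, y: np.ndarray) -> np.ndarray:
        """Flat RHS for use with generic ODE integrators."""
        state = BiofilmState.unpack(np.maximum(y, 0.0), self.z)
        return self.assemble_rhs(state).pack()

    # -- steady-state integration -----------------------------------------
    def integrate_to_steady_state(
        self,
        initial: BiofilmState,
        t_max: float = 50_000.0,
        tol: float = 1e-8,
        dt0: float = 1e-3,
        dt_max: float = 25.0,
        rel_target: float = 0.08,
        tau_flux: float = 0.5,
        window: float = 100.0,
        record_every: int = 10,
        callback: Callable | None = None,
    ) -> tuple[pd.DataFrame, BiofilmState, dict]:
        """Advance to steady state with the adaptive semi-implicit scheme.

        The LP flux field is passed through a first-order lag with time
        constant ``tau_flux`` (h) before entering the balance equations.
        This models the finite speed of metabolic readjustment and, more
        importantly, regularizes the discontinuous substrate-switching
        behavior of the embedded LPs: where the growth-optimal flux
        choice flips between substitutable substrates, the lagged system
        approaches the well-defined sliding (Filippov) equilibrium
        instead of chattering.  Away from switching surfaces the lag
        does not alter steady states.

        Steady state is declared when the scaled time derivative drops
        below ``tol`` (1/h).  Two criteria are used: the instantaneous
        per-step relative change divided by the step size, and — because
        residual chatter around LP switching surfaces keeps the
        instantaneous residual bounded away from zero — the drift rate
        of consecutive time-window averages of the full state.  When
        window drift dominates, the lag constant is annealed upward,
        shrinking the chatter amplitude; the reported steady state and
        flux field are then the final window averages.

        Returns ``(trajectory, steady_state, info)`` where the
        trajectory is a tidy frame of biofilm-averaged quantities and
        ``info`` reports convergence, final time, residual, steps and
        the final (window-averaged) flux field.
        """
        if t_max <= 0:
            raise ValueError("t_max must be positive")
        state = initial.copy()
        nS = len(NUTRIENTS)
        t, dt = 0.0, dt0
        records = []
        # absolute scale floors for the relative-change norms (g/L, mM).
        # Concentration fields are implicitly-stabilized fast slaves of
        # the biomass fields; trace pools with large turnover must not
        # pin the step size, so the dt controller uses a coarse floor
        # for them while steady-state drift is judged on a tight floor.
        floor_X, floor_C = 0.02, 1.0
        ctrl_floor_C = 1.0
        dt_min = 1e-4
        converged = False
        residual = np.inf
        self._window_residuals: list[tuple[float, float]] = []
        step = 0
        calm_steps = 0
        calm_windows = 0
        width = state.z[-1] - state.z[0] if self.N > 1 else 1.0

        def record():
            means_X = (np.trapezoid(state.X, state.z, axis=1) / width
                       if self.N > 1 else state.X[:, 0])
            means_C = (np.trapezoid(state.C, state.z, axis=1) / width
                       if self.N > 1 else state.C[:, 0])
            rec = {"t": t, "dt": dt, "O_b": self.bulk_oxygen(state)}
            for i, sp in enumerate(SPECIES):
                rec[f"X_{sp}"] = means_X[i]
            for f, m in enumerate(TRANSPORTED):
                rec[m] = means_C[f]
            records.append(rec)

        record()
        mu_s, ex_s = self.flux_field(state)
        nsp = len(SPECIES)
        floor = np.empty((N_FIELDS, self.N))
        floor[:nsp] = floor_X
        floor[nsp:] = floor_C
        ctrl_floor = np.empty((N_FIELDS, self.N))
        ctrl_floor[:nsp] = floor_X
        ctrl_floor[nsp:] = ctrl_floor_C
        tau = tau_flux
        # the lag may anneal upward to damp switching chatter, but must
        # stay fast relative to the slow community dynamics so that it
        # cannot freeze a transient into a spurious steady state
        tau_max = 50.0
        # windowed-mean accumulators for chatter-robust steady detection
        acc_y = np.zeros((N_FIELDS, self.N))
        acc_mu = np.zeros_like(mu_s)
        acc_ex = np.zeros_like(ex_s)
        acc_T = 0.0
        prev_mean = None
        prev_tmid = 0.0
        mean_flux = (mu_s.copy(), ex_s.copy())
        mean_state = None
        while t < t_max:
            mu_raw, ex_raw = self.flux_field(state)
            # explicit growth limits the stable step size (only where
            # biomass is actually present)
            live = state.X > 0
            mu_max = max(float((mu_raw * live).max()),
                         float((mu_s * live).max()), 1e-2)
            dt = min(dt, 2.0 / mu_max)
            lam = min(dt / tau, 0.6) if tau > 0 else 1.0
            mu_prev, ex_prev = mu_s.copy(), ex_s.copy()
            mu_s += lam * (mu_raw - mu_s)
            ex_s += lam * (ex_raw - ex_s)
            mu, ex = mu_s, ex_s
            lo, dg, up, bc = self._band_arrays(self.bulk_oxygen(state))
            y = np.vstack([state.X, state.C])  # (26, N)
            C = y[nsp:]
            per_uptake = np.maximum(-ex, 0.0)  # (3, 23, N), per gDW
            secretion = np.einsum("ifn,in->fn", np.maximum(ex, 0.0), state.X)
            uptake = np.einsum("ifn,in->fn", per_uptake, state.X)
            # uptake enters as an implicit first-order loss (rate
            # |v| X / C), which guarantees positivity
            cons = np.where(C > CLIP_CONCENTRATION,
                            uptake / np.maximum(C, 1e-300), 0.0)
            new_C = self._thomas(-dt * lo[nsp:],
                                 1.0 - dt * dg[nsp:] + dt * cons,
                                 -dt * up[nsp:],
                                 C + dt * (secretion + bc[nsp:]))
            # the implicit treatment realizes uptake scaled by
            # C_new/C_old; debit the carbon shortfall from the growth
            # rate so the applied fluxes stay carbon-closed
            ratio = np.where(C > CLIP_CONCENTRATION,
                             new_C / np.maximum(C, 1e-300), 1.0)
            shortfall = np.einsum("ifn,f,fn->in", per_uptake, self._carbon,
                                  1.0 - ratio) / BIOMASS_CARBON
            mu_eff = mu - shortfall
            prod_X = np.maximum(mu_eff, 0.0) * state.X
            loss_X = self.death[:, None] + np.maximum(-mu_eff, 0.0)
            new_X = self._thomas(-dt * lo[:nsp],
                                 1.0 - dt * dg[:nsp] + dt * loss_X,
                                 -dt * up[:nsp],
                                 state.X + dt * (prod_X + bc[:nsp]))
            new_y = np.vstack([new_X, new_C])
            scaled = np.abs(new_y - y) / np.maximum(np.abs(y), ctrl_floor)
            d_rel = float(scaled.max())
            self._limit = np.unravel_index(int(scaled.argmax()), scaled.shape)
            if d_rel > 1.0 and dt > dt_min:
                # reject: restore the lagged fluxes and retry smaller
                mu_s, ex_s = mu_prev, ex_prev
                dt = max(0.2 * dt, dt_min)
                continue
            new_y = np.maximum(new_y, 0.0)
            state.X = new_y[:nsp]
            state.S = new_y[nsp:nsp + nS]
            state.P = new_y[nsp + nS:]
            t += dt
            step += 1
            inst_residual = d_rel / dt
            acc_y += new_y * dt
            acc_mu += mu_s * dt
            acc_ex += ex_s * dt
            acc_T += dt
            if acc_T >= window:
                mean_y = acc_y / acc_T
                tmid = t - 0.5 * acc_T
                mean_flux = (acc_mu / acc_T, acc_ex / acc_T)
                mean_state = BiofilmState(z=state.z, X=mean_y[:nsp],
                                          S=mean_y[nsp:nsp + nS],
                                          P=mean_y[nsp + nS:])
                if prev_mean is not None:
                    scaled_drift = (np.abs(mean_y - prev_mean)
                                    / np.maximum(np.abs(mean_y), floor))
                    drift = float(scaled_drift.max())
                    self._drift_limit = np.unravel_index(
                        int(scaled_drift.argmax()), scaled_drift.shape)
                    residual = drift / (tmid - prev_tmid)
                    self._window_residuals.append((tmid, residual))
                    if residual < tol:
                        calm_windows += 1
                        if calm_windows >= 2:
                            converged = True
                            state = mean_state
                            break
                    else:
                        calm_windows = 0
                    # chatter: window drift far below per-step noise
                    if residual < 0.02 * inst_residual and tau < tau_max:
                        tau *= 2.0
                prev_mean, prev_tmid = mean_y, tmid
                acc_y = np.zeros_like(acc_y)
                acc_mu = np.zeros_like(acc_mu)
                acc_ex = np.zeros_like(acc_ex)
                acc_T = 0.0
            if step % record_every == 0:
                record()
            if callback is not None:
                callback(t, state)
            if inst_residual < tol:
                calm_steps += 1
                if calm_steps >= 3:
                    converged = True
                    break
            else:
                calm_steps = 0
            dt = min(max(dt * min(max(rel_target / max(d_rel, 1e-12), 0.25), 1.4),
                         dt_min),
                     dt_max, window / 4.0, t_max - t + 1e-12)
        record()
        info = {"converged": converged, "t_end": t, "residual": residual,
                "steps": step, "lp_solves": self.lp_solves, "tau_flux": tau,
                "flux_field": mean_flux if converged and mean_state is not None
                else (mu_s, ex_s)}
        return pd.DataFrame(records), state, info


def assemble_rhs(state: BiofilmState, model: BiofilmModel,
                 flux_field=None) -> BiofilmState:
    """Module-level convenience for :meth:`BiofilmModel.assemble_rhs`."""
    return model.assemble_rhs(state, flux_field)


def trajectory_to_tidy(trajectory: pd.DataFrame) -> pd.DataFrame:
    """Long-format (time, variable, value) view of a trajectory frame."""
    return trajectory.melt(id_vars=["t"], var_name="variable",
                           value_name="value")


def state_to_tidy(state: BiofilmState) -> pd.DataFrame:
    """Long-format (z, variable, value) view of a state."""
    rows = []
    for i, sp in enumerate(SPECIES):
        for n in range(state.N):
            rows.append({"z": state.z[n], "variable": f"X_{sp}",
                         "value": state.X[i, n]})
    for f, m in enumerate(TRANSPORTED):
        col = state.C[f]
        for n in range(state.N):
            rows.append({"z": state.z[n], "variable": m, "value": col[n]})
    return pd.DataFrame(rows)
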