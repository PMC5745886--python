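"""Diet construction, the simulation battery and the two calibrations.

The experimental protocol is two-staged: every perturbation run
(applied oxygen, host feedback, antibiotic) starts from the anaerobic
steady state of its diet, which is itself computed from a spatially
homogeneous initial condition.

Diets are specified on a six-carbon (C6) basis and corrected for the
carbon count of each nutrient; the carbohydrate fraction is 40% glucose
and 20% each arabinose/fructose/galactose, and the protein fraction is
split equally over the ten amino acids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .analysis_outputs import SteadySummary, biofilm_average, sweep_table
from .biofilm_pde import (
    BiofilmModel,
    BiofilmState,
    FeedbackConfig,
    ParameterSet,
    feedback_bulk_oxygen,
)
from .media import AMINO_ACIDS, BYPRODUCTS, CARBON, SCFAS, SPECIES, SUGARS
from .reduced_models import DEFAULT_ATPM

#: maximum bulk oxygen concentration studied, mM
O_MAX = 5e-3

#: diet definitions on the C6 basis: (total CHO, total protein), mM
DIET_C6: dict[str, tuple[float, float]] = {
    "high_CHO": (5.0, 1.5),
    "high_PRO": (1.5, 5.0),
    "equal": (3.25, 3.25),
}

#: split of the carbohydrate C6 pool over the four sugars
CHO_SPLIT: dict[str, float] = {
    "glucose": 0.40, "arabinose": 0.20, "fructose": 0.20, "galactose": 0.20,
}

#: ATP maintenance values calibrated so the reduced community reproduces
#: healthy-gut abundance fractions (~60:30:10 Bt:Fp:Ec) on the high-CHO
#: diet under anaerobic conditions, with Bt fixed at its published value
CALIBRATED_ATPM: dict[str, float] = {"Bt": 8.43, "Fp": 5.2, "Ec": 3.9}

#: default first-order antibiotic kill constants per species, 1/h per
#: unit antibiotic level (level is a normalized [0, 1] concentration)
DEFAULT_KILL_CONSTANTS: dict[str, float] = {"Bt": 0.04, "Fp": 0.04, "Ec": 0.04}


def c6_to_actual(c6: float, carbons: int) -> float:
    """Convert a six-carbon-equivalent concentration to the actual
    concentration: ``c6 * 6 / carbons`` (mM)."""
    if carbons < 1:
        raise ValueError("carbon count must be at least 1")
    if c6 < 0:
        raise ValueError("concentration must be non-negative")
    return c6 * 6.0 / carbons


@dataclass(frozen=True)
class DietNutrient:
    name: str
    c6_mM: float
    carbons: int
    actual_mM: float


@dataclass(frozen=True)
class DietSpec:
    """Bulk nutrient concentrations of one diet (C6 and actual basis)."""

    name: str
    nutrients: tuple[DietNutrient, ...]

    @property
    def total_cho_c6(self) -> float:
        return sum(n.c6_mM for n in self.nutrients if n.name in SUGARS)

    @property
    def total_cho_actual(self) -> float:
        return sum(n.actual_mM for n in self.nutrients if n.name in SUGARS)

    @property
    def total_aa_c6(self) -> float:
        return sum(n.c6_mM for n in self.nutrients if n.name in AMINO_ACIDS)

    @property
    def total_aa_actual(self) -> float:
        return sum(n.actual_mM for n in self.nutrients if n.name in AMINO_ACIDS)

    def bulk_concentrations(self) -> dict[str, float]:
        """Actual bulk concentrations keyed by nutrient (mM)."""
        return {n.name: n.actual_mM for n in self.nutrients}

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"nutrient": n.name, "C6_mM": n.c6_mM, "carbons": n.carbons,
              "actual_mM": n.actual_mM} for n in self.nutrients])


def build_diet(name: str) -> DietSpec:
    """Build a named diet (``high_CHO``, ``high_PRO`` or ``equal``)."""
    if name not in DIET_C6:
        raise ValueError(f"unknown diet {name!r}; options: {sorted(DIET_C6)}")
    cho_c6, pro_c6 = DIET_C6[name]
    nutrients = []
    for s in SUGARS:
        c6 = cho_c6 * CHO_SPLIT[s]
        nutrients.append(DietNutrient(s, c6, CARBON[s],
                                      c6_to_actual(c6, CARBON[s])))
    per_aa = pro_c6 / len(AMINO_ACIDS)
    for a in AMINO_ACIDS:
        nutrients.append(DietNutrient(a, per_aa, CARBON[a],
                                      c6_to_actual(per_aa, CARBON[a])))
    return DietSpec(name=name, nutrients=tuple(nutrients))


@dataclass
class ScenarioConfig:
    """One simulation scenario.

    Exactly one of a fixed bulk oxygen (``O_b``) or host feedback with a
    perturbation (``feedback=True`` with ``O_pert``) may be active.
    """

    diet: str = "high_CHO"
    O_b: float = 0.0
    feedback: bool = False
    O_pert: float = 0.0
    antibiotic_level: float = 0.0
    kill_constants: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_KILL_CONSTANTS))
    shuttle_enabled: bool = True
    grid_N: int = 20
    t_max: float = 60_000.0
    tol: float = 1e-5
    window: float = 500.0  # h; steady detection averages windows this long
    atpm: dict[str, float] = field(default_factory=lambda: dict(CALIBRATED_ATPM))
    params: ParameterSet | None = None
    initial_biomass: float = 10.0  # g/L per species, homogeneous start

    def __post_init__(self) -> None:
        if self.feedback and self.O_b != 0.0:
            raise ValueError(
                "feedback and a fixed bulk oxygen concentration are "
                "mutually exclusive")
        if self.O_b < 0 or self.O_pert < 0:
            raise ValueError("oxygen concentrations must be non-negative")
        if self.grid_N < 2:
            raise ValueError("grid_N must be at least 2")

    def parameter_set(self, O_b: float | None = None) -> ParameterSet:
        base = self.params if self.params is not None else ParameterSet()
        return replace(base, O_b=self.O_b if O_b is None else O_b,
                       atpm=dict(self.atpm))


@dataclass
class RunResult:
    """Trajectory, steady state and summary of one scenario run."""

    config: ScenarioConfig
    trajectory: pd.DataFrame
    steady: BiofilmState
    info: dict
    summary: SteadySummary

    @property
    def converged(self) -> bool:
        return bool(self.info.get("converged", False))


def antibiotic_death_rate(level: float, kill_constant: float) -> float:
    """First-order antibiotic death rate (1/h), spatially uniform."""
    if level < 0 or kill_constant < 0:
        raise ValueError("antibiotic level and kill constant must be >= 0")
    return kill_constant * level


def _death_rates(config: ScenarioConfig) -> dict[str, float] | None:
    if config.antibiotic_level == 0:
        return None
    return {sp: antibiotic_death_rate(config.antibiotic_level,
                                      config.kill_constants.get(sp, 0.0))
            for sp in SPECIES}


def make_model(config: ScenarioConfig, O_b: float | None = None,
               feedback: FeedbackConfig | None = None) -> BiofilmModel:
    """Assemble the biofilm model for a scenario."""
    from .reduced_models import build_community

    diet = build_diet(config.diet)
    networks = build_community(atpm=config.atpm,
                               shuttle_enabled=config.shuttle_enabled)
    return BiofilmModel(
        params=config.parameter_set(0.0 if feedback is not None else O_b),
        diet_bulk=diet.bulk_concentrations(),
        networks=networks,
        N=config.grid_N,
        feedback=feedback,
        death_rates=_death_rates(config),
    )


def _run(model: BiofilmModel, config: ScenarioConfig,
         initial: BiofilmState | None, **kwargs) -> RunResult:
    if initial is None:
        initial = BiofilmState.homogeneous(
            config.grid_N, model.ip.L, X0=config.initial_biomass)
    kwargs.setdefault("window", config.window)
    traj, steady, info = model.integrate_to_steady_state(
        initial, t_max=config.t_max, tol=config.tol, **kwargs)
    summary = SteadySummary.from_state(steady)
    summary.extras["O_b_final"] = model.bulk_oxygen(steady)
    return RunResult(config=config, trajectory=traj, steady=steady,
                     info=info, summary=summary)


def equilibrate(config: ScenarioConfig | None = None,
                initial: BiofilmState | None = None, **kwargs) -> RunResult:
    """Anaerobic equilibration for a diet (the stage-one protocol).

    Any fixed ``O_b`` in the config is ignored; the run is anaerobic.
    """
    config = config or ScenarioConfig()
    model = make_model(config, O_b=0.0)
    return _run(model, config, initial, **kwargs)


def run_fixed_oxygen(config: ScenarioConfig, anaerobic: BiofilmState,
                     O_b: float | None = None, **kwargs) -> RunResult:
    """Applied-oxygen run started from the anaerobic steady state."""
    model = make_model(config, O_b=config.O_b if O_b is None else O_b)
    return _run(model, config, anaerobic.copy(), **kwargs)


def run_oxygen_sweep(
    config: ScenarioConfig | None = None,
    o_b_values: np.ndarray | None = None,
    anaerobic: RunResult | None = None,
    **kwargs,
) -> tuple[pd.DataFrame, dict[float, RunResult]]:
    """Steady states across a bulk-oxygen sweep (default 11 evenly
    spaced values on [0, 5e-3] mM).

    Each point starts from the diet's anaerobic steady state; a failure
    at one point is recorded and does not abort the sweep.  The O_b = 0
    entry is the anaerobic equilibration itself.
    """
    config = config or ScenarioConfig()
    if o_b_values is None:
        o_b_values = np.linspace(0.0, O_MAX, 11)
    if anaerobic is None:
        anaerobic = equilibrate(config, **kwargs)
    results: dict[float, RunResult] = {}
    errors: dict[float, str] = {}
    for ob in o_b_values:
        ob = float(ob)
        if ob == 0.0:
            results[ob] = anaerobic
            continue
        try:
            results[ob] = run_fixed_oxygen(config, anaerobic.steady, O_b=ob,
                                           **kwargs)
        except Exception as exc:  # per-point isolation
            errors[ob] = f"{type(exc).__name__}: {exc}"
    table = sweep_table({ob: r.summary for ob, r in results.items()})
    table.attrs["errors"] = errors
    return table, results


def run_feedback(config: ScenarioConfig, anaerobic: RunResult,
                 O_pert: float | None = None, **kwargs) -> RunResult:
    """Host-feedback run: the bulk oxygen follows the linear feedback
    law anchored at the anaerobic Fp biomass, on top of a sustained
    perturbation ``O_pert``."""
    O_pert = config.O_pert if O_pert is None else O_pert
    fp_mean = biofilm_average(anaerobic.steady.X[SPECIES.index("Fp")],
                              anaerobic.steady.z)
    fb = FeedbackConfig(O_pert=O_pert, fp_anaerobic_mean=fp_mean, O_max=O_MAX)
    model = make_model(config, feedback=fb)
    return _run(model, config, anaerobic.steady.copy(), **kwargs)


def run_antibiotic(config: ScenarioConfig, anaerobic: RunResult,
                   level: float | None = None, **kwargs) -> RunResult:
    """Sustained antibiotic treatment with host feedback active and no
    direct oxygen perturbation: oxygen can rise only because the
    antibiotic depresses the Fp population."""
    level = config.antibiotic_level if level is None else level
    cfg = replace(config, antibiotic_level=level, O_b=0.0,
                  feedback=True, O_pert=0.0)
    return run_feedback(cfg, anaerobic, O_pert=0.0, **kwargs)


def response_time(result: RunResult, fraction: float = 0.95) -> float:
    """Time for the biofilm-averaged Fp biomass to cover ``fraction`` of
    the distance from its initial to its final value (a settling-time
    measure that is defined for partial declines and full collapses
    alike)."""
    traj = result.trajectory
    x = traj["X_Fp"].to_numpy()
    t = traj["t"].to_numpy()
    x0, xf = x[0], x[-1]
    if abs(xf - x0) < 1e-12:
        return 0.0
    target = x0 + fraction * (xf - x0)
    crossed = np.nonzero((x - target) * np.sign(xf - x0) >= 0)[0]
    return float(t[crossed[0]]) if crossed.size else float(t[-1])


def collapse_time(result: RunResult, fp_anaerobic_mean: float,
                  threshold: float = 0.5) -> float | None:
    """Simulated time at which the biofilm-averaged Fp biomass first
    falls below ``threshold`` times its anaerobic value (None if never)."""
    traj = result.trajectory
    level = threshold * fp_anaerobic_mean
    below = traj[traj["X_Fp"] < level]
    return None if below.empty else float(below["t"].iloc[0])


# ---------------------------------------------------------------------------
# Calibrations

@dataclass
class CalibrationResult:
    values: dict[str, float]
    achieved: dict[str, float]
    targets: dict[str, float]
    within_tolerance: bool
    trace: list[dict] = field(default_factory=list)


def _anaerobic_fractions(atpm: dict[str, float], config: ScenarioConfig,
                         warm: BiofilmState | None, **kwargs
                         ) -> tuple[np.ndarray, BiofilmState]:
    cfg = replace(config, atpm=dict(atpm), O_b=0.0, feedback=False)
    model = make_model(cfg, O_b=0.0)
    if warm is not None:
        init = warm.copy()
        # re-seed species that went extinct in the previous evaluation so
        # they can re-invade under the new maintenance values
        init.X = np.maximum(init.X, 0.5)
    else:
        init = BiofilmState.homogeneous(cfg.grid_N, model.ip.L,
                                        X0=cfg.initial_biomass)
    kwargs.setdefault("window", cfg.window)
    _, steady, _ = model.integrate_to_steady_state(
        init, t_max=cfg.t_max, tol=cfg.tol, **kwargs)
    means = np.array([biofilm_average(steady.X[i], steady.z)
                      for i in range(len(SPECIES))])
    if means.sum() <= 0:
        raise RuntimeError("community went extinct during calibration")
    return 100.0 * means / means.sum(), steady


def calibrate_atpm(
    targets: tuple[float, float, float] = (60.0, 30.0, 10.0),
    tolerance_pp: float = 5.0,
    config: ScenarioConfig | None = None,
    initial: dict[str, float] | None = None,
    bounds: tuple[float, float] = (0.0, DEFAULT_ATPM["Bt"]),
    max_rounds: int = 3,
    max_iter_per_knob: int = 4,
    **kwargs,
) -> CalibrationResult:
    """Tune the Fp and Ec ATP maintenance values until the anaerobic
    community reaches the target abundance fractions.

    Bt's ATPM stays fixed at its published value; the two knobs are
    adjusted by alternating damped-secant iterations exploiting that a
    species' fraction decreases monotonically in its own maintenance
    cost.  If the targets cannot be reached within the bounds the best
    achieved fractions are reported (``within_tolerance=False``).
    """
    config = config or ScenarioConfig()
    targets_d = dict(zip(SPECIES, targets))
    if abs(sum(targets) - 100.0) > 1e-9:
        raise ValueError("target fractions must sum to 100")
    atpm = dict(config.atpm if initial is None else
                {"Bt": DEFAULT_ATPM["Bt"]} | initial)
    atpm["Bt"] = DEFAULT_ATPM["Bt"]
    lo, hi = bounds
    trace: list[dict] = []
    warm: BiofilmState | None = None

    fractions, warm = _anaerobic_fractions(atpm, config, warm, **kwargs)
    trace.append({"atpm": dict(atpm), "fractions": fractions.tolist()})
    best = (np.max(np.abs(fractions - np.array(targets))), dict(atpm),
            fractions)

    for _ in range(max_rounds):
        if best[0] <= tolerance_pp:
            break
        for knob, sp_idx in (("Fp", 1), ("Ec", 2)):
            target = targets_d[knob]
            a0, f0 = atpm[knob], fractions[sp_idx]
            if abs(f0 - target) <= tolerance_pp / 2:
                continue
            # initial secant partner from a conservative nudge
            a1 = float(np.clip(a0 + (0.4 if f0 > target else -0.4), lo, hi))
            for _ in range(max_iter_per_knob):
                atpm[knob] = a1
                fractions, warm = _anaerobic_fractions(atpm, config, warm,
                                                       **kwargs)
                f1 = fractions[sp_idx]
                trace.append({"atpm": dict(atpm),
                              "fractions": fractions.tolist()})
                err = np.max(np.abs(fractions - np.array(targets)))
                if err < best[0]:
                    best = (err, dict(atpm), fractions)
                if abs(f1 - target) <= tolerance_pp / 2:
                    break
                slope = (f1 - f0) / (a1 - a0) if a1 != a0 else 0.0
                if slope == 0.0 or not math.isfinite(slope):
                    break
                step = (target - f1) / slope
                a0, f0 = a1, f1
                a1 = float(np.clip(a1 + np.clip(step, -1.0, 1.0), lo, hi))
                if a1 == a0:
                    break
        if best[0] <= tolerance_pp:
            break

    err, atpm_best, fr = best
    achieved = dict(zip(SPECIES, map(float, fr)))
    return CalibrationResult(values=atpm_best, achieved=achieved,
                             targets=targets_d,
                             within_tolerance=bool(err <= tolerance_pp),
                             trace=trace)


def calibrate_scfa_mtc(
    targets: tuple[float, float, float] = (60.0, 20.0, 20.0),
    tolerance_pp: float = 5.0,
    config: ScenarioConfig | None = None,
    bounds: tuple[float, float] = (5e-6, 1e-2),
    max_rounds: int = 3,
    max_iter_per_knob: int = 4,
    **kwargs,
) -> CalibrationResult:
    """Tune the butyrate and propionate mass-transfer coefficients until
    the anaerobic acetate:propionate:butyrate split reaches the target.

    The acetate coefficient stays at its nominal value; each knob is
    searched on a log scale (a larger coefficient removes that SCFA
    faster, lowering its share monotonically).  If the targets cannot be
    reached within the bounds the best achieved split is reported.
    """
    config = config or ScenarioConfig()
    targets_d = dict(zip(SCFAS, targets))
    base = config.params if config.params is not None else ParameterSet()
    k = {"butyrate": base.k_butyrate, "propionate": base.k_propionate}
    lo, hi = math.log(bounds[0]), math.log(bounds[1])
    trace: list[dict] = []
    warm: BiofilmState | None = None

    def evaluate() -> np.ndarray:
        nonlocal warm
        params = replace(base, k_butyrate=k["butyrate"],
                         k_propionate=k["propionate"], atpm=dict(config.atpm))
        cfg = replace(config, params=params, O_b=0.0, feedback=False)
        model = make_model(cfg, O_b=0.0)
        init = (warm.copy() if warm is not None else
                BiofilmState.homogeneous(cfg.grid_N, model.ip.L,
                                         X0=cfg.initial_biomass))
        if warm is not None:
            init.X = np.maximum(init.X, 0.5)
        kwargs.setdefault("window", cfg.window)
        _, steady, _ = model.integrate_to_steady_state(
            init, t_max=cfg.t_max, tol=cfg.tol, **kwargs)
        warm = steady
        idx = [BYPRODUCTS.index(m) for m in SCFAS]
        means = np.array([biofilm_average(steady.P[i], steady.z) for i in idx])
        return 100.0 * means / means.sum()

    fractions = evaluate()
    trace.append({"k": dict(k), "fractions": fractions.tolist()})
    best = (np.max(np.abs(fractions - np.array(targets))), dict(k), fractions)

    for _ in range(max_rounds):
        if best[0] <= tolerance_pp:
            break
        for knob, idx in (("butyrate", 2), ("propionate", 1)):
            target = targets_d[knob if knob != "butyrate" else "butyrate"]
            x0, f0 = math.log(k[knob]), fractions[idx]
            if abs(f0 - target) <= tolerance_pp / 2:
                continue
            x1 = float(np.clip(x0 + (0.7 if f0 > target else -0.7), lo, hi))
            for _ in range(max_iter_per_knob):
                k[knob] = math.exp(x1)
                fractions = evaluate()
                f1 = fractions[idx]
                trace.append({"k": dict(k), "fractions": fractions.tolist()})
                err = np.max(np.abs(fractions - np.array(targets)))
                if err < best[0]:
                    best = (err, dict(k), fractions)
                if abs(f1 - target) <= tolerance_pp / 2:
                    break
                slope = (f1 - f0) / (x1 - x0) if x1 != x0 else 0.0
                if slope == 0.0 or not math.isfinite(slope):
                    break
                step = (target - f1) / slope
                x0, f0 = x1, f1
                x1 = float(np.clip(x1 + np.clip(step, -1.5, 1.5), lo, hi))
                if x1 == x0:
                    break
        if best[0] <= tolerance_pp:
            break

    err, k_best, fr = best
    achieved = dict(zip(SCFAS, map(float, fr)))
    return CalibrationResult(values=k_best, achieved=achieved,
                             targets=targets_d,
                             within_tolerance=bool(err <= tolerance_pp),
                             trace=trace)
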