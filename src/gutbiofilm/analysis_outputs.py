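"""Summary statistics for biofilm states and trajectories.

Everything the scenario battery reports is computed here: biofilm
averages, species abundance fractions, SCFA fractions, oxygen metrics
(peak, average, penetration depth), flux profiles scaled by their
anaerobic baselines, and the steady-state carbon balance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .media import (
    BYPRODUCTS,
    CARBON,
    NUTRIENTS,
    SCFAS,
    SPECIES,
    TRANSPORTED,
    TRANSPORTED_INDEX,
)
from .reduced_models import BIOMASS_CARBON

#: depth threshold used for the oxygen penetration metric, mM (100 nM)
O2_PENETRATION_THRESHOLD = 1e-4
#: baseline magnitudes below this are masked in scaled profiles
SCALED_PROFILE_MASK_THRESHOLD = 1e-9


def biofilm_average(values: np.ndarray, z: np.ndarray | None = None) -> float:
    """Trapezoidal mean of a nodal field over the biofilm depth."""
    values = np.asarray(values, float)
    if values.size == 0:
        raise ValueError("empty field")
    if values.size == 1:
        return float(values[0])
    if z is None:
        z = np.linspace(0.0, 1.0, values.size)
    return float(np.trapezoid(values, z) / (z[-1] - z[0]))


def abundance_fractions(X: np.ndarray, z: np.ndarray | None = None) -> np.ndarray:
    """Species abundance percentages from biofilm-averaged biomass."""
    X = np.asarray(X, float)
    if np.any(X < 0):
        raise ValueError("negative biomass")
    means = np.array([biofilm_average(row, z) for row in np.atleast_2d(X)])
    total = means.sum()
    if total <= 0:
        raise ValueError("all-zero biomass")
    return 100.0 * means / total


def scfa_fractions(P: np.ndarray, z: np.ndarray | None = None) -> np.ndarray:
    """Acetate:propionate:butyrate percentages of total SCFA."""
    idx = [BYPRODUCTS.index(m) for m in SCFAS]
    means = np.array([biofilm_average(P[i], z) for i in idx])
    total = means.sum()
    if total <= 0:
        raise ValueError("no SCFA present")
    return 100.0 * means / total


def scaled_profiles(field_values: np.ndarray, baseline: np.ndarray,
                    threshold: float = SCALED_PROFILE_MASK_THRESHOLD
                    ) -> np.ma.MaskedArray:
    """Pointwise ratio of a perturbed profile to its anaerobic baseline.

    Locations where the baseline magnitude is below ``threshold`` are
    masked rather than divided (the anaerobic profile is a flat line at
    unity under this scaling).
    """
    field_values = np.asarray(field_values, float)
    baseline = np.asarray(baseline, float)
    mask = np.abs(baseline) < threshold
    ratio = np.divide(field_values, baseline,
                      out=np.zeros_like(field_values), where=~mask)
    return np.ma.MaskedArray(ratio, mask=mask)


def oxygen_metrics(state) -> dict[str, float]:
    """Peak and biofilm-average O2 (nM) and penetration depth (um).

    The penetration depth is measured from the stool boundary (where
    oxygen enters) to the deepest point at which the O2 concentration
    still exceeds 100 nM; linear interpolation is used between nodes.
    """
    o2 = state.S[NUTRIENTS.index("o2")]
    z = state.z
    L = z[-1]
    peak = float(o2.max())
    avg = biofilm_average(o2, z)
    thr = O2_PENETRATION_THRESHOLD
    depth = 0.0
    if o2[-1] >= thr:
        depth = L - z[0]  # may be shortened below
        for n in range(state.N - 1, 0, -1):
            if o2[n - 1] < thr:
                frac = (o2[n] - thr) / max(o2[n] - o2[n - 1], 1e-300)
                z_cross = z[n] - frac * (z[n] - z[n - 1])
                depth = L - z_cross
                break
    um = 1e4
    return {"peak_o2_nM": peak * 1e6, "mean_o2_nM": avg * 1e6,
            "penetration_um": depth * um}


@dataclass
class SteadySummary:
    """Biofilm-averaged summary of one steady state."""

    abundance_pct: dict[str, float]
    scfa_pct: dict[str, float]
    total_biomass: float           # g/L, biofilm-averaged sum over species
    mean_biomass: dict[str, float]  # g/L per species
    mean_concentrations: dict[str, float]  # mM per transported metabolite
    peak_o2_nM: float
    mean_o2_nM: float
    o2_penetration_um: float
    extras: dict = field(default_factory=dict)

    @classmethod
    def from_state(cls, state) -> "SteadySummary":
        z = state.z
        mean_X = {sp: biofilm_average(state.X[i], z)
                  for i, sp in enumerate(SPECIES)}
        ab = abundance_fractions(state.X, z)
        sc = scfa_fractions(state.P, z)
        conc = {m: biofilm_average(state.C[f], z)
                for f, m in enumerate(TRANSPORTED)}
        o2m = oxygen_metrics(state)
        return cls(
            abundance_pct=dict(zip(SPECIES, map(float, ab))),
            scfa_pct=dict(zip(SCFAS, map(float, sc))),
            total_biomass=float(sum(mean_X.values())),
            mean_biomass=mean_X,
            mean_concentrations=conc,
            peak_o2_nM=o2m["peak_o2_nM"],
            mean_o2_nM=o2m["mean_o2_nM"],
            o2_penetration_um=o2m["penetration_um"],
        )

    def validate(self) -> None:
        """Assert the structural invariants of a summary."""
        if abs(sum(self.abundance_pct.values()) - 100.0) > 1e-6:
            raise AssertionError("abundance fractions must sum to 100")
        if abs(sum(self.scfa_pct.values()) - 100.0) > 1e-6:
            raise AssertionError("SCFA fractions must sum to 100")

    def to_frame(self) -> pd.DataFrame:
        rows = [{"variable": f"abundance_{sp}", "value": v}
                for sp, v in self.abundance_pct.items()]
        rows += [{"variable": f"scfa_{m}", "value": v}
                 for m, v in self.scfa_pct.items()]
        rows += [{"variable": f"X_{sp}", "value": v}
                 for sp, v in self.mean_biomass.items()]
        rows += [{"variable": m, "value": v}
                 for m, v in self.mean_concentrations.items()]
        rows += [{"variable": "total_biomass", "value": self.total_biomass},
                 {"variable": "peak_o2_nM", "value": self.peak_o2_nM},
                 {"variable": "mean_o2_nM", "value": self.mean_o2_nM},
                 {"variable": "o2_penetration_um", "value": self.o2_penetration_um}]
        return pd.DataFrame(rows)


def top_middle_bottom(state, values: np.ndarray) -> dict[str, float]:
    """Field values at the nodes nearest the stool boundary (top), the
    mid-depth and the mucosa boundary (bottom)."""
    z = state.z
    L = z[-1]
    idx = {name: int(np.argmin(np.abs(z - target)))
           for name, target in (("top", L), ("middle", L / 2), ("bottom", 0.0))}
    return {name: float(values[i]) for name, i in idx.items()}


def carbon_balance(model, state, flux_field=None) -> dict[str, float]:
    """Steady-state boundary carbon balance.

    With trapezoidal quadrature the discrete transport operator
    telescopes exactly to the Robin boundary fluxes, so at steady state
    the carbon entering as nutrients must equal the carbon leaving as
    unconsumed nutrients, byproducts and eroded biomass.  Returns the
    influx, outflux (mmol C per cm^2 per h, up to a fixed volumetric
    constant) and their relative mismatch.
    """
    ip = model.ip
    carbon = np.array([float(CARBON[m]) for m in TRANSPORTED])
    C = state.C
    o2b = model.bulk_oxygen(state)
    bulk_stool = model._bulk_stool.copy()
    bulk_stool[TRANSPORTED_INDEX["o2"]] = o2b
    bulk_int = model._bulk_intestine

    influx = 0.0
    outflux = 0.0
    for f in range(len(TRANSPORTED)):
        k = ip.k[f]
        flux_stool = k * (bulk_stool[f] - C[f, -1])   # inward positive
        flux_int = k * (C[f, 0] - bulk_int[f])        # outward positive
        cf = carbon[f]
        if flux_stool >= 0:
            influx += cf * flux_stool
        else:
            outflux += cf * (-flux_stool)
        if flux_int >= 0:
            outflux += cf * flux_int
        else:
            influx += cf * (-flux_int)
    # biomass erosion at the stool boundary carries biomass carbon
    erosion = ip.k_X * state.X[:, -1].sum()
    outflux += BIOMASS_CARBON * erosion
    rel = abs(influx - outflux) / max(influx, 1e-300)
    return {"influx": influx, "outflux": outflux, "relative_error": rel}


def sweep_table(results: dict[float, SteadySummary]) -> pd.DataFrame:
    """Tidy table of steady summaries across a bulk-oxygen sweep."""
    rows = []
    for ob, s in sorted(results.items()):
        row = {"O_b": ob, "total_biomass": s.total_biomass,
               "peak_o2_nM": s.peak_o2_nM, "mean_o2_nM": s.mean_o2_nM,
               "o2_penetration_um": s.o2_penetration_um}
        row |= {f"abundance_{sp}": v for sp, v in s.abundance_pct.items()}
        row |= {f"scfa_{m}": v for m, v in s.scfa_pct.items()}
        row |= {f"X_{sp}": v for sp, v in s.mean_biomass.items()}
        rows.append(row)
    return pd.DataFrame(rows)
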