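"""Whole-cell voltage-clamp analysis: QC, current density, Boltzmann fits.

The analysis chain for a voltage-step protocol (hold −80 mV, 200 ms steps in
10 mV increments up to +20 mV):

1. quality control — cells with series resistance above 10 MΩ are excluded;
2. steady-state current density — the mean current over the last 40 ms of
   each step, minus the holding baseline, divided by cell capacitance
   (pA/pF);
3. conductance — current density divided by the K⁺ driving force
   ``V − E_K`` with the Nernst reversal potential E_K (−91.34 mV for
   4 mM out / 140 mM in at 25 °C);
4. Boltzmann fit — each cell's conductance–voltage curve is fitted with the
   rising sigmoid ``G(V) = A1 + (A2 − A1)/(1 + exp((V0.5 − V)/k))`` and
   normalized to its own A1/A2; pooled normalized data can be refit with a
   single group-level Boltzmann.

Also provides the Nernst equation and a Henderson-equation estimate of the
liquid junction potential between pipette and bath solutions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .synthetic import IVDataset, boltzmann

__all__ = [
    "GAS_CONSTANT",
    "FARADAY",
    "StepProtocol",
    "BoltzmannFit",
    "SolutionSpec",
    "nernst_potential",
    "qc_filter_cells",
    "steady_state_current_density",
    "conductance_curve",
    "fit_boltzmann",
    "fit_group_boltzmann",
    "henderson_ljp",
    "DEFAULT_MOBILITIES",
    "pipette_solution_kcl",
    "bath_solution_standard",
]

# Textbook-precision constants, the convention in electrophysiology
# (RT/F = 25.69 mV at 25 degC). With these, E_K(4/140 mM) = -91.34 mV.
GAS_CONSTANT = 8.314  # J / (mol K)
FARADAY = 96_485.0  # C / mol


def nernst_potential(
    c_out: float, c_in: float, valence: int = 1, temperature: float = 298.15
) -> float:
    """Nernst equilibrium potential in mV.

    ``(RT / zF) · ln(c_out / c_in)``. For K⁺ with 4 mM outside and 140 mM
    inside at 298.15 K this gives −91.34 mV.
    """
    if c_out <= 0 or c_in <= 0:
        raise ValueError("concentrations must be positive")
    if valence == 0:
        raise ValueError("valence must be non-zero")
    return (
        GAS_CONSTANT * temperature / (valence * FARADAY) * math.log(c_out / c_in) * 1000.0
    )


@dataclass
class StepProtocol:
    """Voltage-step protocol geometry (defaults match the standard protocol)."""

    holding: float = -80.0
    step_duration_ms: float = 200.0
    step_levels: tuple[float, ...] = tuple(range(-80, 30, 10))
    steady_state_window_ms: float = 40.0
    tail_step: tuple[float, float] = (-100.0, 40.0)

    def __post_init__(self) -> None:
        if not 0 < self.steady_state_window_ms <= self.step_duration_ms:
            raise ValueError("steady-state window must fit inside the step")
        levels = np.asarray(self.step_levels, dtype=float)
        if np.any(np.diff(levels) <= 0):
            raise ValueError("step levels must be strictly increasing")


def qc_filter_cells(
    records: list, rs_max: float = 10.0
) -> tuple[list, dict]:
    """Exclude cells with series resistance strictly above ``rs_max`` MΩ.

    The rule is strict: Rs exactly at the limit passes. Records must expose
    ``series_resistance`` and ``cell_id``; a missing/NaN Rs is an error
    naming the cell.
    """
    passing, excluded = [], []
    for rec in records:
        rs = getattr(rec, "series_resistance", None)
        if rs is None or (isinstance(rs, float) and math.isnan(rs)):
            raise ValueError(f"cell {getattr(rec, 'cell_id', '?')}: missing series resistance")
        (excluded if rs > rs_max else passing).append(rec)
    report = {
        "n_in": len(records),
        "n_passing": len(passing),
        "excluded": [(r.cell_id, r.series_resistance) for r in excluded],
    }
    return passing, report


def steady_state_current_density(
    dataset: IVDataset, window_ms: float = 40.0
) -> np.ndarray:
    """Per-step steady-state current density (pA/pF).

    Evoked current = mean over the last ``window_ms`` of each step minus the
    holding baseline; divided by capacitance.
    """
    fs = dataset.trace_sampling_rate
    n_win = int(round(window_ms / 1000.0 * fs))
    if n_win < 1 or n_win > dataset.traces.shape[1]:
        raise ValueError("steady-state window exceeds trace length")
    plateau = dataset.traces[:, -n_win:].mean(axis=1)
    return (plateau - dataset.holding_current) / dataset.capacitance


def conductance_curve(
    current_density: np.ndarray,
    voltages: np.ndarray,
    reversal: float,
    guard_mv: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Driving-force-corrected conductance G(V) = J(V) / (V − E_rev).

    Steps within ``guard_mv`` of the reversal potential are excluded (the
    division is ill-conditioned there); returns ``(voltages_kept, G)`` in
    nS/pF for J in pA/pF and V in mV.
    """
    v = np.asarray(voltages, dtype=float)
    j = np.asarray(current_density, dtype=float)
    keep = np.abs(v - reversal) >= guard_mv
    return v[keep], j[keep] / (v[keep] - reversal)


@dataclass
class BoltzmannFit:
    """Fitted Boltzmann activation curve.

    A1/A2 are the minimum/maximum conductance, V0.5 the half-activation
    voltage (mV) and k the slope factor (mV, positive for a rising curve).
    """

    a1: float
    a2: float
    v_half: float
    k: float
    residual_norm: float
    converged: bool
    covariance: np.ndarray | None = None

    @property
    def params(self) -> tuple[float, float, float, float]:
        return (self.a1, self.a2, self.v_half, self.k)

    def normalized(self, g: np.ndarray) -> np.ndarray:
        """Normalize raw conductances to this fit's own A1 and A2."""
        return (np.asarray(g, dtype=float) - self.a1) / (self.a2 - self.a1)

    def curve(self, v: np.ndarray) -> np.ndarray:
        return boltzmann(np.asarray(v, dtype=float), *self.params)


def fit_boltzmann(g: np.ndarray, v: np.ndarray) -> BoltzmannFit:
    """Least-squares Boltzmann fit of a conductance–voltage curve.

    Initialization: A1 = min G, A2 = max G, V0.5 = voltage nearest the
    mid-conductance point, k = 10 mV; k is bounded positive so the fitted
    curve rises with depolarization. Non-convergence returns a flagged fit
    rather than raising.
    """
    g = np.asarray(g, dtype=float)
    v = np.asarray(v, dtype=float)
    if g.size < 5:
        raise ValueError("need at least 5 (V, G) points to fit a Boltzmann")
    a1_0, a2_0 = float(g.min()), float(g.max())
    if a2_0 <= a1_0:
        a2_0 = a1_0 + 1e-6
    mid = 0.5 * (a1_0 + a2_0)
    v0_0 = float(v[np.argmin(np.abs(g - mid))])
    p0 = [a1_0, a2_0, v0_0, 10.0]
    span = float(v.max() - v.min())
    bounds = (
        [-np.inf, -np.inf, v.min() - 2 * span, 1e-6],
        [np.inf, np.inf, v.max() + 2 * span, np.inf],
    )
    try:
        popt, pcov = curve_fit(boltzmann, v, g, p0=p0, bounds=bounds, maxfev=20_000)
        resid = g - boltzmann(v, *popt)
        converged = bool(np.all(np.isfinite(popt)))
    except RuntimeError:
        popt, pcov = p0, None
        resid = g - boltzmann(v, *p0)
        converged = False
    return BoltzmannFit(
        a1=float(popt[0]),
        a2=float(popt[1]),
        v_half=float(popt[2]),
        k=float(popt[3]),
        residual_norm=float(np.linalg.norm(resid)),
        converged=converged,
        covariance=pcov,
    )


def fit_group_boltzmann(
    fits: list[BoltzmannFit], g_per_cell: list[np.ndarray], v_per_cell: list[np.ndarray]
) -> BoltzmannFit:
    """Single Boltzmann refit of pooled per-cell *normalized* conductances.

    Each cell's raw conductances are normalized to its own A1/A2 before
    pooling, mirroring the group-level activation-curve analysis.
    """
    vs = np.concatenate([np.asarray(v, dtype=float) for v in v_per_cell])
    gn = np.concatenate([f.normalized(g) for f, g in zip(fits, g_per_cell)])
    return fit_boltzmann(gn, vs)


# ---------------------------------------------------------------------------
# Henderson liquid junction potential
# ---------------------------------------------------------------------------

# Limiting ionic mobilities relative to K+ (dimensionless ratios of limiting
# equivalent conductances, 25 °C). Standard electrochemical reference values;
# HEPES(-) and EGTA(2-) are the values commonly used for patch-clamp
# junction-potential estimates.
DEFAULT_MOBILITIES: dict[str, tuple[int, float]] = {
    # species: (valence, mobility relative to K+)
    "K": (1, 1.000),
    "Na": (1, 0.682),
    "Li": (1, 0.526),
    "Cs": (1, 1.050),
    "Ca": (2, 0.4048),
    "Mg": (2, 0.3610),
    "Cl": (-1, 1.0388),
    "F": (-1, 0.753),
    "HCO3": (-1, 0.605),
    "HEPES": (-1, 0.30),
    "EGTA": (-2, 0.24),
    "gluconate": (-1, 0.33),
}


@dataclass
class SolutionSpec:
    """An electrolyte solution as ionic species with concentrations in mM.

    ``species`` maps species names to concentrations; valences and relative
    mobilities come from ``mobilities`` (default table above). Weak-acid
    buffers should be entered at their *ionized* concentration — e.g. HEPES
    at pH 7.35 is treated as roughly half anionic.
    """

    species: dict[str, float]
    temperature: float = 298.15
    mobilities: dict[str, tuple[int, float]] = field(
        default_factory=lambda: dict(DEFAULT_MOBILITIES)
    )

    def __post_init__(self) -> None:
        for name, conc in self.species.items():
            if conc < 0:
                raise ValueError(f"negative concentration for {name}")
            if name not in self.mobilities:
                raise ValueError(f"no mobility for species {name!r}")

    def charge_imbalance(self) -> float:
        """Net charge (mEq) — positive means excess cations."""
        return sum(
            self.mobilities[n][0] * c for n, c in self.species.items()
        )

    def titrated(self, cation: str = "K") -> "SolutionSpec":
        """Add titrant ions to reach electroneutrality (e.g. KOH/NaOH —
        the hydroxide is consumed by the buffer, leaving the cation)."""
        species = dict(self.species)
        imbalance = self.charge_imbalance()
        if imbalance < 0:  # excess anions -> add cation
            z = self.mobilities[cation][0]
            species[cation] = species.get(cation, 0.0) + (-imbalance) / z
        elif imbalance > 0:  # excess cations -> add Cl
            species["Cl"] = species.get("Cl", 0.0) + imbalance
        return SolutionSpec(species, self.temperature, self.mobilities)


def pipette_solution_kcl() -> SolutionSpec:
    """140 KCl / 10 HEPES / 10 EGTA intracellular solution at pH 7.35.

    HEPES is entered ~50% anionic and EGTA as the divalent anion. The
    composition is taken as written (titrant ions are not added), the usual
    convention of junction-potential calculators.
    """
    return SolutionSpec({"K": 140.0, "Cl": 140.0, "HEPES": 5.0, "EGTA": 10.0})


def bath_solution_standard() -> SolutionSpec:
    """140 NaCl / 4 KCl / 1.8 CaCl2 / 2 MgCl2 / 10 HEPES bath at pH 7.35."""
    return SolutionSpec(
        {
            "Na": 140.0,
            "K": 4.0,
            "Ca": 1.8,
            "Mg": 2.0,
            "Cl": 140.0 + 4.0 + 2 * 1.8 + 2 * 2.0,
            "HEPES": 5.0,
        }
    )


def henderson_ljp(pipette: SolutionSpec, bath: SolutionSpec) -> float:
    """Henderson-equation liquid junction potential in mV.

    Sign convention: the potential of the bath relative to the pipette
    solution at the open tip, i.e. the value a whole-cell amplifier zeroed
    in the bath should be corrected by. For a 140 KCl pipette against a
    physiological NaCl bath this is about +4 mV (the less mobile Na⁺ makes
    the bath side positive).
    """
    names = sorted(set(pipette.species) | set(bath.species))
    for n in names:
        if n not in pipette.mobilities or n not in bath.mobilities:
            raise ValueError(f"no mobility for species {n!r}")
    z = np.array([pipette.mobilities[n][0] for n in names], dtype=float)
    u = np.array([pipette.mobilities[n][1] for n in names], dtype=float)
    cp = np.array([pipette.species.get(n, 0.0) for n in names])
    cb = np.array([bath.species.get(n, 0.0) for n in names])

    dz_u = np.sum(z * u * (cb - cp))
    dz2_u = np.sum(z**2 * u * (cb - cp))
    s_p = np.sum(z**2 * u * cp)
    s_b = np.sum(z**2 * u * cb)
    if s_p <= 0 or s_b <= 0:
        raise ValueError("solutions must contain charged species")
    rt_f = GAS_CONSTANT * pipette.temperature / FARADAY * 1000.0  # mV
    if dz2_u == 0:
        return 0.0
    # potential of bath minus pipette
    return float(-rt_f * (dz_u / dz2_u) * math.log(s_b / s_p))
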