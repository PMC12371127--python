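"""Forward models for irreversible protein thermal denaturation by DSC.

A differential scanning calorimeter ramps temperature at a constant scan
rate v (K/min) and records the excess molar heat capacity of a protein
sample.  For kinetically controlled (irreversible) unfolding, each
transition is governed by a first-order rate constant with Arrhenius
temperature dependence,

    k(T) = exp(-(Ea/R) * (1/T - 1/T*)),

parameterized by an activation energy Ea (J/mol) and a reference
temperature T* (K) at which k = 1/s.  T* is an alternative to quoting the
frequency factor A, related through T* = Ea / (R ln A).

Three candidate denaturation schemes are modelled:

* ``reversible_two_state`` - rapid equilibrium N <-> D (van 't Hoff);
  the endotherm is independent of scan rate.
* ``irreversible_one_step`` - N -> D; the peak shifts with scan rate but
  keeps its shape.
* ``irreversible_two_step`` - N -> I -> D through an intermediate
  (a Lumry-Eyring-type scheme with both steps irreversible); both the
  position and the shape of the endotherm depend on scan rate.

Along a linear ramp the state populations obey

    dx_N/dT = -k1 x_N / v,      dx_I/dT = (k1 x_N - k2 x_I) / v,

with v in K/s, and the excess heat capacity is the enthalpy-weighted
transition flux

    Cp_exc(T) = dH1 * k1 x_N / v  +  dH2 * k2 x_I / v.

x_N has the exact quadrature solution exp(-(1/v) int k1 dT); x_I is
propagated with an exponential-integrator recurrence that is
unconditionally stable in the stiff late-transition regime.  No heat
capacity change between states is modelled (thermograms are assumed
baseline-corrected to pure excess heat capacity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np
from numba import njit

from .constants import R

__all__ = [
    "ArrheniusTransition",
    "EquilibriumTwoState",
    "DenaturationScheme",
    "StateTrajectory",
    "Thermogram",
    "ScanRateSeries",
    "arrhenius_rate",
    "frequency_factor",
    "simulate_states",
    "simulate_thermogram",
    "apparent_tm",
    "MODEL_IDS",
]

MODEL_IDS = ("reversible_two_state", "irreversible_one_step", "irreversible_two_step")

#: Default plausibility window for reference / midpoint temperatures, K.
T_WINDOW = (250.0, 450.0)

#: Rate constants are capped here to keep quadratures finite far above T*.
_K_CAP = 1.0e12

#: Default maximum internal integration step, K.
_MAX_STEP_K = 0.02


class StartTemperatureWarning(UserWarning):
    """Raised when a simulation grid starts with non-negligible flux."""


@dataclass(frozen=True)
class ArrheniusTransition:
    """One kinetic transition: (dH_cal, Ea, T*) triple.

    Parameters
    ----------
    label : str
        Free-text name, e.g. ``"N->I"``.
    dH_cal : float
        Calorimetric enthalpy of the transition, J/mol. Positive.
    Ea : float
        Arrhenius activation energy, J/mol. Positive.
    T_star : float
        Reference temperature at which k = 1/s, in K. Must lie inside
        ``t_window``.
    """

    label: str
    dH_cal: float
    Ea: float
    T_star: float
    t_window: Tuple[float, float] = T_WINDOW

    def __post_init__(self) -> None:
        if not (self.dH_cal > 0):
            raise ValueError(f"dH_cal must be > 0, got {self.dH_cal}")
        if not (self.Ea > 0):
            raise ValueError(f"Ea must be > 0, got {self.Ea}")
        lo, hi = self.t_window
        if not (lo <= self.T_star <= hi):
            raise ValueError(
                f"T_star={self.T_star} K outside plausibility window {self.t_window}"
            )
        if not np.isfinite(self.ln_A) or self.ln_A <= 0:
            raise ValueError("derived ln A must be finite and positive")

    @property
    def ln_A(self) -> float:
        """Natural log of the Arrhenius frequency factor, ln A = Ea/(R T*)."""
        return self.Ea / (R * self.T_star)

    def rate(self, T):
        """Rate constant k(T) in 1/s; accepts scalar or array temperature."""
        return arrhenius_rate(self, T)

    @classmethod
    def from_rate_at(cls, k, T, Ea, dH_cal=1.0, label="transition"):
        """Build a transition with the given Ea whose rate at ``T`` equals ``k``.

        Inverts the Arrhenius relationship for T*:
        1/T* = 1/T + R ln(k) / Ea.
        """
        if not (k > 0 and T > 0):
            raise ValueError("k and T must be positive")
        inv_t_star = 1.0 / T + R * np.log(k) / Ea
        return cls(label=label, dH_cal=dH_cal, Ea=Ea, T_star=1.0 / inv_t_star)


@dataclass(frozen=True)
class EquilibriumTwoState:
    """Two-state van 't Hoff equilibrium N <-> D.

    dH_vH is the van 't Hoff enthalpy setting the sharpness of the
    transition, Tm_eq the midpoint where half the molecules are unfolded,
    and dH_cal the calorimetric enthalpy scaling the endotherm area.
    """

    dH_vH: float
    Tm_eq: float
    dH_cal: float
    t_window: Tuple[float, float] = T_WINDOW

    def __post_init__(self) -> None:
        if not (self.dH_vH > 0 and self.dH_cal > 0):
            raise ValueError("enthalpies must be positive")
        lo, hi = self.t_window
        if not (lo <= self.Tm_eq <= hi):
            raise ValueError(
                f"Tm_eq={self.Tm_eq} K outside plausibility window {self.t_window}"
            )

    def equilibrium_constant(self, T):
        """K(T) = exp(-(dH_vH/R)(1/T - 1/Tm_eq))."""
        T = np.asarray(T, dtype=float)
        return np.exp(-(self.dH_vH / R) * (1.0 / T - 1.0 / self.Tm_eq))

    def unfolded_fraction(self, T):
        K = self.equilibrium_constant(T)
        return K / (1.0 + K)


@dataclass(frozen=True)
class DenaturationScheme:
    """A candidate denaturation model with its transitions.

    ``transitions`` is ordered native->intermediate then
    intermediate->denatured for the two-step model; ``equilibrium`` is
    populated only for the reversible model.
    """

    model_id: str
    transitions: Tuple[ArrheniusTransition, ...] = ()
    equilibrium: Optional[EquilibriumTwoState] = None

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"unknown model_id {self.model_id!r}; one of {MODEL_IDS}")
        object.__setattr__(self, "transitions", tuple(self.transitions))
        n = len(self.transitions)
        if self.model_id == "reversible_two_state":
            if self.equilibrium is None or n != 0:
                raise ValueError(
                    "reversible_two_state requires equilibrium and no transitions"
                )
        else:
            want = 1 if self.model_id == "irreversible_one_step" else 2
            if n != want or self.equilibrium is not None:
                raise ValueError(
                    f"{self.model_id} requires {want} transition(s) and no equilibrium"
                )

    @property
    def n_parameters(self) -> int:
        """Free parameters of the scheme (3 per transition, 3 reversible)."""
        if self.model_id == "reversible_two_state":
            return 3
        return 3 * len(self.transitions)

    @property
    def total_enthalpy(self) -> float:
        if self.model_id == "reversible_two_state":
            return self.equilibrium.dH_cal
        return sum(t.dH_cal for t in self.transitions)


@dataclass(frozen=True)
class StateTrajectory:
    """State fractions x_N, x_I, x_D on an increasing temperature grid."""

    temperatures: np.ndarray
    x_N: np.ndarray
    x_I: np.ndarray
    x_D: np.ndarray

    def __post_init__(self) -> None:
        T = np.asarray(self.temperatures, float)
        if T.ndim != 1 or np.any(np.diff(T) <= 0):
            raise ValueError("temperature grid must be 1-D strictly increasing")
        for name in ("x_N", "x_I", "x_D"):
            x = np.asarray(getattr(self, name), float)
            if x.shape != T.shape:
                raise ValueError("state arrays must match the grid shape")
            if np.any(x < -1e-9) or np.any(x > 1.0 + 1e-9):
                raise ValueError(f"{name} outside [0, 1]")
        total = self.x_N + self.x_I + self.x_D
        if np.max(np.abs(total - 1.0)) > 1e-6:
            raise ValueError("state fractions do not sum to 1 within 1e-6")
        if np.any(np.diff(self.x_N) > 1e-9):
            raise ValueError("x_N must be non-increasing")
        if np.any(np.diff(self.x_D) < -1e-9):
            raise ValueError("x_D must be non-decreasing")


@dataclass(frozen=True)
class Thermogram:
    """One excess-heat-capacity curve at a single scan rate.

    temperatures in K (strictly increasing), cp_excess in J/(mol K),
    scan_rate in K/min; ``concentration`` (mg/mL) is optional metadata.
    """

    enzyme_id: str
    scan_rate: float
    temperatures: np.ndarray
    cp_excess: np.ndarray
    concentration: Optional[float] = None

    def __post_init__(self) -> None:
        T = np.asarray(self.temperatures, dtype=float)
        cp = np.asarray(self.cp_excess, dtype=float)
        object.__setattr__(self, "temperatures", T)
        object.__setattr__(self, "cp_excess", cp)
        if T.ndim != 1 or cp.shape != T.shape:
            raise ValueError("temperatures and cp_excess must be equal-length 1-D")
        if T.size < 10:
            raise ValueError("a thermogram needs at least 10 points")
        if np.any(np.diff(T) <= 0):
            raise ValueError("temperature grid must be strictly increasing")
        if not (self.scan_rate > 0):
            raise ValueError("scan_rate must be positive (K/min)")
        if not (np.all(np.isfinite(T)) and np.all(np.isfinite(cp))):
            raise ValueError("thermogram values must be finite")

    @property
    def area(self) -> float:
        """Trapezoidal area under the curve, J/mol."""
        return float(np.trapezoid(self.cp_excess, self.temperatures))


@dataclass(frozen=True)
class ScanRateSeries:
    """A per-enzyme set of thermograms at pairwise-distinct scan rates."""

    enzyme_id: str
    thermograms: Tuple[Thermogram, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "thermograms", tuple(self.thermograms))
        if len(self.thermograms) < 2:
            raise ValueError("a scan-rate series needs at least 2 thermograms")
        rates = [t.scan_rate for t in self.thermograms]
        if len(set(rates)) != len(rates):
            raise ValueError("scan rates must be pairwise distinct")
        if any(t.enzyme_id != self.enzyme_id for t in self.thermograms):
            raise ValueError("all thermograms must share the series enzyme_id")

    @property
    def scan_rates(self) -> Tuple[float, ...]:
        return tuple(t.scan_rate for t in self.thermograms)

    def sorted_by_rate(self) -> "ScanRateSeries":
        return replace(
            self,
            thermograms=tuple(sorted(self.thermograms, key=lambda t: t.scan_rate)),
        )


# ---------------------------------------------------------------------------
# Rate law
# ---------------------------------------------------------------------------

def arrhenius_rate(transition: ArrheniusTransition, T):
    """Arrhenius rate constant k(T) = exp(-(Ea/R)(1/T - 1/T*)), in 1/s.

    Strictly increasing in T and exactly 1/s at T = T*.  ``T`` may be a
    scalar or array of temperatures in K; all must be positive.
    """
    T_arr = np.asarray(T, dtype=float)
    if np.any(T_arr <= 0):
        raise ValueError("temperature must be positive (K)")
    arg = -(transition.Ea / R) * (1.0 / T_arr - 1.0 / transition.T_star)
    k = np.exp(np.minimum(arg, np.log(_K_CAP)))
    return k if T_arr.ndim else float(k)


def frequency_factor(transition: ArrheniusTransition) -> float:
    """Arrhenius frequency factor A = exp(Ea/(R T*)), in 1/s.

    The inverse relation T* = Ea/(R ln A) holds to machine precision.
    """
    return float(np.exp(transition.ln_A))


# ---------------------------------------------------------------------------
# Ramp integration
# ---------------------------------------------------------------------------

@njit(cache=False)
def _intermediate_recurrence(g, dE2, h):  # pragma: no cover - numba kernel
    """Propagate x_I through the N -> I -> D source/decay balance.

    g = k1 x_N / v on the fine grid (per K); dE2[i] = int of k2/v over
    interval i; h[i] = interval width (K).  Uses the exact decay factor
    exp(-dE2) per step with trapezoidal, attenuation-weighted source
    accumulation, hence remains stable however stiff k2/v becomes.
    """
    n = g.shape[0]
    x = np.empty(n)
    x[0] = 0.0
    for i in range(n - 1):
        a = np.exp(-dE2[i])
        x[i + 1] = x[i] * a + 0.5 * h[i] * (g[i] * a + g[i + 1])
    return x


def _refine_grid(T: np.ndarray, max_step: float):
    """Subdivide each grid interval to at most ``max_step`` K.

    Returns (fine_grid, node_indices) with the original points preserved.
    """
    dT = np.diff(T)
    reps = np.maximum(1, np.ceil(dT / max_step - 1e-12).astype(np.int64))
    starts = np.repeat(T[:-1], reps)
    steps = np.repeat(dT / reps, reps)
    offsets = np.arange(reps.sum()) - np.repeat(np.cumsum(reps) - reps, reps)
    fine = np.append(starts + steps * offsets, T[-1])
    node_idx = np.concatenate(([0], np.cumsum(reps)))
    return fine, node_idx


def _cumtrapz0(y, x):
    out = np.empty_like(y)
    out[0] = 0.0
    np.cumsum(0.5 * (y[1:] + y[:-1]) * np.diff(x), out=out[1:])
    return out


def _irreversible_states_fine(scheme: DenaturationScheme, v_K_s: float, T_fine):
    """x_N, x_I and per-transition fluxes on a fine grid (irreversible)."""
    tr1 = scheme.transitions[0]
    k1 = arrhenius_rate(tr1, T_fine)
    E1 = _cumtrapz0(k1, T_fine) / v_K_s
    x_N = np.exp(-np.minimum(E1, 745.0))
    flux1 = k1 * x_N / v_K_s  # -dx_N/dT, per K
    if scheme.model_id == "irreversible_one_step":
        x_I = np.zeros_like(x_N)
        flux2 = np.zeros_like(x_N)
    else:
        tr2 = scheme.transitions[1]
        k2 = arrhenius_rate(tr2, T_fine)
        dE2 = 0.5 * (k2[1:] + k2[:-1]) * np.diff(T_fine) / v_K_s
        x_I = _intermediate_recurrence(flux1, dE2, np.diff(T_fine))
        np.clip(x_I, 0.0, 1.0, out=x_I)
        flux2 = k2 * x_I / v_K_s
    return x_N, x_I, flux1, flux2


def _check_start(scheme, v_K_s, T, threshold, on_violation):
    if scheme.model_id == "reversible_two_state" or on_violation == "ignore":
        return
    # Only the first transition matters at the start: the native state is
    # the sole populated reservoir there, so later-step rates carry no flux.
    span = T[-1] - T[0]
    worst = float(arrhenius_rate(scheme.transitions[0], T[0])) * span / v_K_s
    if worst >= threshold:
        msg = (
            f"initial flux measure {worst:.3g} exceeds {threshold:.1g}; the grid "
            "may not start far enough below the transition"
        )
        if on_violation == "error":
            raise ValueError(msg)
        warnings.warn(msg, StartTemperatureWarning, stacklevel=3)


def _validate_grid(T_grid) -> np.ndarray:
    T = np.asarray(T_grid, dtype=float)
    if T.ndim != 1 or T.size < 2 or np.any(np.diff(T) <= 0):
        raise ValueError("T_grid must be a 1-D strictly increasing array (K)")
    if np.any(T <= 0):
        raise ValueError("temperatures must be positive (K)")
    return T


def simulate_states(
    scheme: DenaturationScheme,
    scan_rate: float,
    T_grid,
    *,
    start_flux_threshold: float = 1e-4,
    on_start_violation: str = "warn",
    max_step: float = _MAX_STEP_K,
) -> StateTrajectory:
    """State populations along a linear temperature ramp.

    Parameters
    ----------
    scheme : DenaturationScheme
    scan_rate : float
        Ramp rate in K/min.
    T_grid : array
        Strictly increasing output grid, K.  Should start where the
        transition flux is still negligible; a check (k(T0) * span / v <
        ``start_flux_threshold``) warns or errors per
        ``on_start_violation`` ("warn", "error" or "ignore").

    Returns
    -------
    StateTrajectory
        With x_N + x_I + x_D = 1 (x_I identically zero for one-step and
        reversible models).  For the reversible model the fractions are
        the equilibrium populations x_N = 1/(1+K), x_D = K/(1+K).
    """
    T = _validate_grid(T_grid)
    if not scan_rate > 0:
        raise ValueError("scan_rate must be positive (K/min)")
    v = scan_rate / 60.0
    _check_start(scheme, v, T, start_flux_threshold, on_start_violation)
    if scheme.model_id == "reversible_two_state":
        alpha = scheme.equilibrium.unfolded_fraction(T)
        return StateTrajectory(T, 1.0 - alpha, np.zeros_like(alpha), alpha)
    fine, idx = _refine_grid(T, max_step)
    x_N, x_I, _, _ = _irreversible_states_fine(scheme, v, fine)
    x_N, x_I = x_N[idx], x_I[idx]
    x_D = np.clip(1.0 - x_N - x_I, 0.0, 1.0)
    return StateTrajectory(T, x_N, x_I, x_D)


def simulate_thermogram(
    scheme: DenaturationScheme,
    scan_rate: float,
    T_grid,
    *,
    enzyme_id: str = "simulated",
    start_flux_threshold: float = 1e-4,
    on_start_violation: str = "warn",
    max_step: float = _MAX_STEP_K,
    components: bool = False,
):
    """Synthesize the excess heat capacity curve for a scheme.

    Cp_exc(T) = sum_i dH_cal,i * (flux of transition i)/v; for the
    reversible model Cp_exc = dH_cal * dalpha/dT.  With ``components=True``
    returns ``(thermogram, [per-transition component arrays])``.
    """
    T = _validate_grid(T_grid)
    if not scan_rate > 0:
        raise ValueError("scan_rate must be positive (K/min)")
    v = scan_rate / 60.0
    _check_start(scheme, v, T, start_flux_threshold, on_start_violation)
    if scheme.model_id == "reversible_two_state":
        eq = scheme.equilibrium
        alpha = eq.unfolded_fraction(T)
        cp = eq.dH_cal * alpha * (1.0 - alpha) * eq.dH_vH / (R * T**2)
        comps = [cp]
    else:
        fine, idx = _refine_grid(T, max_step)
        _, _, flux1, flux2 = _irreversible_states_fine(scheme, v, fine)
        comps = [scheme.transitions[0].dH_cal * flux1[idx]]
        if scheme.model_id == "irreversible_two_step":
            comps.append(scheme.transitions[1].dH_cal * flux2[idx])
        cp = np.sum(comps, axis=0)
    tg = Thermogram(
        enzyme_id=enzyme_id, scan_rate=scan_rate, temperatures=T, cp_excess=cp
    )
    return (tg, comps) if components else tg


def apparent_tm(thermogram: Thermogram, *, noise_floor: float = 0.0) -> float:
    """Temperature of the thermogram maximum (the apparent Tm), in K.

    The grid maximum is refined by a quadratic fit through the three
    surrounding points.  The maximum must be an interior point above
    ``noise_floor``; for exactly tied adjacent maxima the lower
    temperature wins.

    Raises
    ------
    ValueError
        If the maximum sits on the grid boundary (the transition is not
        contained in the scan window) or the curve is flat.
    """
    T, cp = thermogram.temperatures, thermogram.cp_excess
    i = int(np.argmax(cp))
    if cp[i] - np.min(cp) <= 1e-12 * max(1.0, abs(cp[i])):
        raise ValueError("flat thermogram: no peak")
    if cp[i] <= noise_floor:
        raise ValueError(f"maximum {cp[i]:.4g} not above noise floor {noise_floor:.4g}")
    if i == 0 or i == cp.size - 1:
        raise ValueError("maximum on grid boundary: transition not contained")
    a, b, _ = np.polyfit(T[i - 1 : i + 2], cp[i - 1 : i + 2], 2)
    if a >= 0:  # degenerate local fit; keep the grid point
        return float(T[i])
    return float(-b / (2.0 * a))
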