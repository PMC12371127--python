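"""Operating-temperature stability metrics from fitted transitions.

Once the global DSC fit has delivered (Ea, T*) for the
native-to-intermediate (k1) and intermediate-to-denatured (k2) steps,
the Arrhenius law extrapolates the rate constants to any process
temperature.  Since the intermediate is assumed catalytically inactive,
the functionally relevant lifetime is that of the native state,
t_1/2 = ln(2)/k1.  This module computes rate/half-life profiles over a
temperature range, the fractional lifetime loss per +1 degC, and
variant-vs-variant rate ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd

from .constants import kelvin_to_celsius
from .kinetics import ArrheniusTransition, DenaturationScheme, arrhenius_rate

__all__ = [
    "StabilityProfile",
    "native_half_life",
    "lifetime_change_per_degree",
    "rate_ratio",
    "stability_profile",
    "round_paper_style",
]

_S_PER_H = 3600.0


@dataclass(frozen=True)
class StabilityProfile:
    """Rate constants and native-state half-life on a temperature grid.

    ``k1`` and ``k2`` in 1/s (``k2`` is NaN for a one-step scheme);
    ``half_life_native`` in hours, equal to ln(2)/k1 pointwise.
    """

    enzyme_id: str
    temperatures: np.ndarray
    k1: np.ndarray
    k2: np.ndarray
    half_life_native: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.k1 <= 0):
            raise ValueError("k1 must be positive everywhere")
        if np.any(np.diff(self.k1) <= 0):
            raise ValueError("k1 must increase with temperature")
        if not np.allclose(
            self.half_life_native, np.log(2.0) / self.k1 / _S_PER_H, rtol=1e-12
        ):
            raise ValueError("half-life column inconsistent with ln(2)/k1")

    def to_frame(self) -> pd.DataFrame:
        """Profile as a DataFrame with deg C at the boundary."""
        return pd.DataFrame(
            {
                "temperature_C": kelvin_to_celsius(self.temperatures),
                "k1_per_s": self.k1,
                "k2_per_s": self.k2,
                "half_life_h": self.half_life_native,
            }
        )

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t_c = kelvin_to_celsius(self.temperatures)
        ax.semilogy(t_c, self.half_life_native, label=self.enzyme_id)
        ax.set_xlabel("temperature (deg C)")
        ax.set_ylabel("native-state half-life (h)")
        ax.legend()
        return ax


def native_half_life(k1) -> Union[float, np.ndarray]:
    """Native-state half-life in hours from a first-order rate constant.

    t_1/2 = ln(2)/k1, with k1 in 1/s.  Vectorized over arrays.
    """
    k1_arr = np.asarray(k1, dtype=float)
    if np.any(k1_arr <= 0):
        raise ValueError("k1 must be positive (1/s)")
    out = np.log(2.0) / k1_arr / _S_PER_H
    return out if k1_arr.ndim else float(out)


def lifetime_change_per_degree(transition: ArrheniusTransition, T: float) -> float:
    """Percent decrease of the native-state lifetime per +1 degC at ``T`` (K).

    Lifetime is inversely proportional to the rate, so the loss is
    100 * (1 - k(T)/k(T+1)); it lies in (0, 100) for any Ea > 0 and is
    independent of whether lifetime is expressed in seconds or hours.
    """
    if not T > 0:
        raise ValueError("temperature must be positive (K)")
    return 100.0 * (1.0 - arrhenius_rate(transition, T) / arrhenius_rate(transition, T + 1.0))


def rate_ratio(
    transition_a: ArrheniusTransition,
    transition_b: ArrheniusTransition,
    T_grid,
) -> np.ndarray:
    """Percent excess of k_a over k_b per grid temperature.

    100 * (k_a(T)/k_b(T) - 1); e.g. +40 means transition ``a`` is 40%
    faster.  For equal Ea the ratio is constant across temperature.
    """
    T = np.asarray(T_grid, dtype=float)
    return 100.0 * (arrhenius_rate(transition_a, T) / arrhenius_rate(transition_b, T) - 1.0)


def stability_profile(
    fit_or_scheme,
    T_range,
    step: float = 0.5,
    enzyme_id: Optional[str] = None,
) -> StabilityProfile:
    """Rate-constant and half-life profile over ``T_range`` = (T_lo, T_hi) in K.

    Accepts a ``FitResult`` or a ``DenaturationScheme``; the scheme must be
    kinetic (irreversible), otherwise no rate constant is defined and a
    ``ValueError`` is raised.
    """
    scheme = getattr(fit_or_scheme, "scheme", fit_or_scheme)
    if not isinstance(scheme, DenaturationScheme):
        raise TypeError("expected a FitResult or DenaturationScheme")
    if scheme.model_id == "reversible_two_state":
        raise ValueError("a reversible fit defines no kinetic rate constant")
    lo, hi = T_range
    if not (hi > lo):
        raise ValueError("T_range must be increasing")
    T = np.arange(lo, hi + step / 2.0, step)
    k1 = arrhenius_rate(scheme.transitions[0], T)
    if len(scheme.transitions) > 1:
        k2 = arrhenius_rate(scheme.transitions[1], T)
    else:
        k2 = np.full_like(T, np.nan)
    if enzyme_id is None:
        series = getattr(fit_or_scheme, "series", None)
        enzyme_id = series.enzyme_id if series is not None else "enzyme"
    return StabilityProfile(
        enzyme_id=enzyme_id,
        temperatures=T,
        k1=k1,
        k2=k2,
        half_life_native=native_half_life(k1),
    )


def round_paper_style(value: float, kind: str) -> float:
    """Reporting-mode rounding: half-lives to 0.1 h, percents to nearest 10.

    Machine output elsewhere keeps full precision; this helper exists only
    for side-by-side comparison with conventionally rounded literature
    values ("3.2 h", "~40%").
    """
    if kind == "half_life_h":
        return round(value, 1)
    if kind == "percent_ten":
        return float(10 * round(value / 10.0))
    raise ValueError(f"unknown rounding kind {kind!r}")
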