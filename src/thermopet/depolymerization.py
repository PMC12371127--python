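"""Analytics for PET depolymerization readouts.

Enzymatic PET hydrolysis releases the aromatic monomers terephthalic
acid (TPA), mono(2-hydroxyethyl) terephthalate (MHET) and
bis(2-hydroxyethyl) terephthalate (BHET), quantified by HPLC over time.
This module converts those monomer time courses into the summary
quantities used to compare enzyme variants: total aromatic product
(molar and mass basis), conversion relative to the PET loaded, initial
rates, fold changes vs. a reference enzyme, absorbance-based BHET
equivalents, pH-stat degree of hydrolysis from cumulative base
consumption, residual-mass loss, and heat-retention fractions.

Conventions: replicates aggregate as mean +/- 1 SD; complete hydrolysis
of one PET repeat unit liberates one diprotic TPA, i.e. two base
equivalents, which defines the 100% point of the pH-stat readout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd

from .constants import CONSTANTS

__all__ = [
    "ReactionCondition",
    "TimeCourse",
    "TitrationTrace",
    "RetentionAssay",
    "QualityFlagWarning",
    "total_aromatic_products",
    "conversion_fraction",
    "initial_rate",
    "fold_change",
    "bhet_equivalents",
    "phstat_hydrolysis",
    "mass_loss_percent",
    "retained_fraction",
]

_MONOMERS = ("tpa", "mhet", "bhet")
_MONOMER_MASS = {
    "tpa": CONSTANTS.molar_mass["TPA"],
    "mhet": CONSTANTS.molar_mass["MHET"],
    "bhet": CONSTANTS.molar_mass["BHET"],
}
M_PET_REPEAT = CONSTANTS.molar_mass["PET_repeat"]


class QualityFlagWarning(UserWarning):
    """Non-fatal data-quality condition (clipping, carry-over, range)."""


@dataclass(frozen=True)
class ReactionCondition:
    """Reaction metadata attached to a time course."""

    pH: Optional[float] = None
    temperature_C: Optional[float] = None
    buffer_mM: Optional[float] = None
    pet_loading_pct_wv: Optional[float] = None  # % w/v, g per 100 mL
    enzyme_loading_mg_per_g: Optional[float] = None


@dataclass
class TimeCourse:
    """Monomer concentrations over time for one enzyme and condition.

    ``data`` columns: ``replicate``, ``time_h``, ``tpa``, ``mhet``,
    ``bhet``; one consistent ``unit`` ("g_per_L" or "mM") for all three
    monomer columns.
    """

    enzyme_id: str
    data: pd.DataFrame
    unit: str = "g_per_L"
    condition: ReactionCondition = field(default_factory=ReactionCondition)

    def __post_init__(self) -> None:
        if self.unit not in ("g_per_L", "mM"):
            raise ValueError("unit must be 'g_per_L' or 'mM'")
        df = self.data.copy()
        if "replicate" not in df.columns:
            df["replicate"] = 1
        missing = {"time_h", *_MONOMERS} - set(df.columns)
        if missing:
            raise ValueError(f"time course missing columns: {sorted(missing)}")
        for col in _MONOMERS:
            if (df[col] < 0).any():
                raise ValueError(f"negative {col.upper()} concentration")
        for _, grp in df.groupby("replicate"):
            if (np.diff(grp["time_h"].to_numpy()) < 0).any():
                raise ValueError("times must be non-decreasing within a replicate")
        self.data = df.reset_index(drop=True)

    def in_unit(self, unit: str) -> "TimeCourse":
        """Return a copy with monomer columns converted to ``unit``."""
        if unit == self.unit:
            return self
        df = self.data.copy()
        for col in _MONOMERS:
            m = _MONOMER_MASS[col]
            if unit == "mM":  # g/L -> mM
                df[col] = df[col] / m * 1e3
            else:  # mM -> g/L
                df[col] = df[col] * m / 1e3
        return TimeCourse(self.enzyme_id, df, unit, self.condition)


@dataclass(frozen=True)
class TitrationTrace:
    """pH-stat record: cumulative base volume vs. time.

    times in h, cumulative_base_volume in mL (non-decreasing),
    base_molarity in mol/L, pet_mass in g, reaction_volume in L.
    """

    times: np.ndarray
    cumulative_base_volume: np.ndarray
    base_molarity: float
    pet_mass: float
    reaction_volume: float = 0.2

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.cumulative_base_volume, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "cumulative_base_volume", v)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and volumes must be equal-length 1-D")
        if np.any(np.diff(v) < -1e-12):
            raise ValueError("cumulative base volume must be non-decreasing")
        if not (self.base_molarity > 0 and self.pet_mass > 0):
            raise ValueError("base molarity and PET mass must be positive")


@dataclass(frozen=True)
class RetentionAssay:
    """Split-GFP fluorescence readings for a thermostability retention assay."""

    fluorescence_initial: float
    fluorescence_treated: float
    fluorescence_background: float
    treatment_temperature_C: Optional[float] = None
    treatment_duration_h: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.fluorescence_initial > self.fluorescence_background:
            raise ValueError("initial fluorescence must exceed background")


def total_aromatic_products(tc: TimeCourse) -> pd.DataFrame:
    """Per-timepoint totals of TPA + MHET + BHET in both mM and g/L.

    Returns the input rows (replicate, time_h) with ``total_mM`` and
    ``total_g_per_L`` columns; the molar total is the plain sum of molar
    concentrations, the mass total the sum of c_i * M_i.
    """
    molar = tc.in_unit("mM").data
    mass = tc.in_unit("g_per_L").data
    out = molar[["replicate", "time_h"]].copy()
    out["total_mM"] = molar[list(_MONOMERS)].sum(axis=1)
    out["total_g_per_L"] = mass[list(_MONOMERS)].sum(axis=1)
    return out


def conversion_fraction(tc: TimeCourse) -> pd.DataFrame:
    """Fraction of theoretical conversion per timepoint.

    Basis: moles of aromatic units released over moles of PET repeat
    units loaded; the loading (% w/v) converts to g/L as 10 * pct.
    Values above 1.02 are clipped and flagged.
    """
    pct = tc.condition.pet_loading_pct_wv
    if pct is None:
        raise ValueError("conversion requires pet_loading_pct_wv in the condition")
    theoretical_M = 10.0 * pct / M_PET_REPEAT  # mol repeat units per L
    out = total_aromatic_products(tc)
    frac = out["total_mM"] / 1e3 / theoretical_M
    if (frac > 1.02).any():
        warnings.warn(
            "conversion exceeds 102% of theoretical; clipped",
            QualityFlagWarning,
            stacklevel=2,
        )
    out["conversion"] = np.minimum(frac, 1.02)
    return out


class InitialRate(NamedTuple):
    g_per_L_h: float
    mM_h: float
    n_points: int
    window_h: float


def initial_rate(tc: TimeCourse, window_end: float) -> InitialRate:
    """OLS slope of total aromatic product vs. time over [0, window_end] h.

    Replicates are pooled; the intercept is free.  At least two distinct
    timepoints must fall inside the window.
    """
    totals = total_aromatic_products(tc)
    sel = totals[totals["time_h"] <= window_end]
    t = sel["time_h"].to_numpy(float)
    if np.unique(t).size < 2:
        raise ValueError("need >= 2 timepoints inside the rate window")
    slope_mass = np.polyfit(t, sel["total_g_per_L"].to_numpy(float), 1)[0]
    slope_molar = np.polyfit(t, sel["total_mM"].to_numpy(float), 1)[0]
    return InitialRate(float(slope_mass), float(slope_molar), int(t.size), float(window_end))


class FoldChange(NamedTuple):
    ratio: float
    sd: float
    timepoint_h: float


def _total_at(tc: TimeCourse, timepoint: float, interpolate: bool):
    totals = total_aromatic_products(tc)
    per_rep = []
    for _, grp in totals.groupby("replicate"):
        t = grp["time_h"].to_numpy(float)
        y = grp["total_g_per_L"].to_numpy(float)
        exact = np.isclose(t, timepoint)
        if exact.any():
            per_rep.append(float(y[exact][0]))
        elif interpolate and t.min() <= timepoint <= t.max():
            per_rep.append(float(np.interp(timepoint, t, y)))
        else:
            raise ValueError(
                f"timepoint {timepoint} h absent for {tc.enzyme_id} "
                "(pass interpolate=True for linear interpolation)"
            )
    arr = np.asarray(per_rep)
    return float(arr.mean()), float(arr.std(ddof=1)) if arr.size > 1 else 0.0


def fold_change(
    variant_tc: TimeCourse,
    reference_tc: TimeCourse,
    timepoint: float,
    interpolate: bool = False,
) -> FoldChange:
    """Activity of a variant standardized to a reference at one timepoint.

    Ratio of replicate-mean total aromatic product (variant/reference),
    with the SD propagated from the replicate SDs:
    sd = ratio * sqrt((sd_v/mean_v)^2 + (sd_r/mean_r)^2).
    """
    mv, sv = _total_at(variant_tc, timepoint, interpolate)
    mr, sr = _total_at(reference_tc, timepoint, interpolate)
    if mr == 0:
        raise ValueError("reference total is zero at the requested timepoint")
    ratio = mv / mr
    rel = np.sqrt((sv / mv) ** 2 + (sr / mr) ** 2) if mv > 0 else 0.0
    return FoldChange(float(ratio), float(ratio * rel), float(timepoint))


def bhet_equivalents(
    a240,
    standards_mM,
    standards_a240,
    baseline: float = 0.0,
) -> np.ndarray:
    """Convert A240 absorbances to mM BHET equivalents via a standard curve.

    A linear least-squares curve through the (concentration, absorbance)
    standards is inverted for the baseline-subtracted samples (the t = 0
    absorbance of each enzyme is the baseline).  Requires >= 3 standards
    with monotone absorbance; out-of-range samples are flagged.
    """
    c = np.asarray(standards_mM, dtype=float)
    a = np.asarray(standards_a240, dtype=float)
    if c.size < 3 or c.size != a.size:
        raise ValueError("need >= 3 (concentration, absorbance) standards")
    order = np.argsort(c)
    c, a = c[order], a[order]
    if not (np.all(np.diff(a) > 0) or np.all(np.diff(a) < 0)):
        raise ValueError("standard absorbances must be monotone in concentration")
    slope, intercept = np.polyfit(c, a, 1)
    samples = np.asarray(a240, dtype=float) - baseline
    conc = (samples - intercept) / slope
    if np.any(samples > a.max()) or np.any(samples < min(a.min(), 0.0)):
        warnings.warn(
            "sample absorbance outside the standard-curve range",
            QualityFlagWarning,
            stacklevel=2,
        )
    return conc


def phstat_hydrolysis(trace: TitrationTrace) -> pd.DataFrame:
    """Percent hydrolysis from cumulative base consumption.

    Complete hydrolysis of one PET repeat unit yields one TPA (diprotic
    at the reaction pH) and neutral ethylene glycol, i.e. two base
    equivalents per repeat unit, so

        %(t) = 100 * V_cum(t) * C_base / (2 * m_PET / M_repeat).

    Values above 102% are flagged (not clipped).
    """
    equivalents = 2.0 * trace.pet_mass / M_PET_REPEAT  # mol base at 100%
    moles_base = trace.cumulative_base_volume * 1e-3 * trace.base_molarity
    pct = 100.0 * moles_base / equivalents
    if np.any(pct > 102.0):
        warnings.warn(
            "hydrolysis exceeds 102% of theoretical base demand",
            QualityFlagWarning,
            stacklevel=2,
        )
    return pd.DataFrame({"time_h": trace.times, "hydrolysis_pct": pct})


def mass_loss_percent(initial_mass: float, residual_mass: float) -> float:
    """Percent mass loss, 100 * (initial - residual)/initial.

    A residual above the initial mass (salt carry-over) is flagged but
    reported as-is (a negative loss).
    """
    if not initial_mass > 0:
        raise ValueError("initial mass must be positive")
    if residual_mass < 0:
        raise ValueError("residual mass cannot be negative")
    if residual_mass > initial_mass:
        warnings.warn(
            "residual exceeds initial mass (salt carry-over?)",
            QualityFlagWarning,
            stacklevel=2,
        )
    return 100.0 * (initial_mass - residual_mass) / initial_mass


def retained_fraction(assay: RetentionAssay) -> float:
    """Fraction of protein retained after heat treatment.

    (treated - background) / (initial - background), clipped to
    [0, 1.02] with a flag when clipping occurs.
    """
    denom = assay.fluorescence_initial - assay.fluorescence_background
    frac = (assay.fluorescence_treated - assay.fluorescence_background) / denom
    if frac < 0 or frac > 1.02:
        warnings.warn(
            f"retained fraction {frac:.3f} clipped to [0, 1.02]",
            QualityFlagWarning,
            stacklevel=2,
        )
    return float(np.clip(frac, 0.0, 1.02))
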