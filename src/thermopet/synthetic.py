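"""Seeded synthetic-data generators for every pipeline stage.

Each generator is a pure function of its parameters and a seed, so the
whole analysis chain can be exercised, and parameter recovery verified
against known truth, without any external data.  Defaults mirror the
experimental design the analyses assume: DSC scans at 0.2, 0.4, 0.8,
1.6 and 3.2 K/min over 50-100 degC; saturating product release limited
by first-order enzyme deactivation; titration traces that are the exact
stoichiometric inverse of the pH-stat hydrolysis readout; alignments in
which queried site frequencies are realized as exact counts.
"""

from __future__ import annotations

from dataclasses import replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .constants import CONSTANTS, celsius_to_kelvin
from .depolymerization import ReactionCondition, TimeCourse, TitrationTrace
from .alignment import AMINO_ACIDS, AlignedHomologSet
from .kinetics import (
    ArrheniusTransition,
    DenaturationScheme,
    ScanRateSeries,
    Thermogram,
    simulate_thermogram,
)

__all__ = [
    "DEFAULT_SCAN_RATES",
    "default_two_step_scheme",
    "gen_thermogram_series",
    "gen_timecourse",
    "gen_titration_trace",
    "gen_alignment",
]

#: Ramp rates of the emulated DSC acquisition, K/min.
DEFAULT_SCAN_RATES = (0.2, 0.4, 0.8, 1.6, 3.2)

#: Default master seed for every generator.
DEFAULT_SEED = 20250821


def default_two_step_scheme(
    Ea1: float = 550e3,
    T_star1: float = 355.7,
    dH1: float = 400e3,
    Ea2: float = 400e3,
    T_star2: float = 364.0,
    dH2: float = 120e3,
) -> DenaturationScheme:
    """A typical two-step irreversible truth for a thermophilic hydrolase.

    The defaults put k1(65 degC) at ~6e-5 1/s (native half-life ~3 h),
    a ~44% lifetime loss per +1 degC, apparent Tm in the low/high 70s degC
    across 0.2-3.2 K/min, and an endotherm dominated (~80/20) by the
    native-to-intermediate transition, with the two component transitions
    separated enough to deconvolve into discrete peaks.
    """
    return DenaturationScheme(
        "irreversible_two_step",
        transitions=(
            ArrheniusTransition("N->I", dH_cal=dH1, Ea=Ea1, T_star=T_star1),
            ArrheniusTransition("I->D", dH_cal=dH2, Ea=Ea2, T_star=T_star2),
        ),
    )


def random_two_step_scheme(rng: np.random.Generator) -> DenaturationScheme:
    """Draw a realistic two-step truth for recovery experiments.

    Ranges bracket the default scheme: Ea1 480-620 kJ/mol, T*1 353-358 K,
    dH1 350-450 kJ/mol; Ea2 350-450 kJ/mol, T*2 = T*1 + 7-10 K,
    dH2 90-140 kJ/mol (first transition always dominant).
    """
    t_star1 = rng.uniform(353.0, 358.0)
    return default_two_step_scheme(
        Ea1=rng.uniform(480e3, 620e3),
        T_star1=t_star1,
        dH1=rng.uniform(350e3, 450e3),
        Ea2=rng.uniform(350e3, 450e3),
        T_star2=t_star1 + rng.uniform(7.0, 10.0),
        dH2=rng.uniform(90e3, 140e3),
    )


def random_one_step_scheme(rng: np.random.Generator) -> DenaturationScheme:
    """Draw a realistic one-step irreversible truth."""
    return DenaturationScheme(
        "irreversible_one_step",
        transitions=(
            ArrheniusTransition(
                "N->D",
                dH_cal=rng.uniform(350e3, 500e3),
                Ea=rng.uniform(400e3, 620e3),
                T_star=rng.uniform(353.0, 359.0),
            ),
        ),
    )


def random_reversible_scheme(rng: np.random.Generator) -> DenaturationScheme:
    """Draw a realistic reversible two-state truth."""
    from .kinetics import EquilibriumTwoState

    return DenaturationScheme(
        "reversible_two_state",
        equilibrium=EquilibriumTwoState(
            dH_vH=rng.uniform(300e3, 500e3),
            Tm_eq=rng.uniform(343.0, 352.0),
            dH_cal=rng.uniform(350e3, 500e3),
        ),
    )


def gen_thermogram_series(
    truth: DenaturationScheme,
    scan_rates: Sequence[float] = DEFAULT_SCAN_RATES,
    T_range_C: Tuple[float, float] = (50.0, 100.0),
    grid_step: float = 0.2,
    noise_sd: float = 0.02,
    seed: int = DEFAULT_SEED,
    enzyme_id: str = "synthetic",
) -> ScanRateSeries:
    """Forward-simulated thermograms with peak-scaled Gaussian noise.

    ``noise_sd`` is the i.i.d. noise standard deviation expressed as a
    fraction of each curve's peak height (0 reproduces the forward model
    exactly).  Deterministic in (arguments, seed).
    """
    if len(scan_rates) == 0:
        raise ValueError("scan-rate list must be non-empty")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    lo, hi = celsius_to_kelvin(T_range_C[0]), celsius_to_kelvin(T_range_C[1])
    T = np.arange(lo, hi + grid_step / 2.0, grid_step)
    thermograms: List[Thermogram] = []
    for v in scan_rates:
        clean = simulate_thermogram(
            truth, v, T, enzyme_id=enzyme_id, on_start_violation="ignore"
        )
        sd = noise_sd * float(np.max(clean.cp_excess))
        noisy = clean.cp_excess + rng.normal(0.0, sd, T.size) if sd > 0 else clean.cp_excess
        thermograms.append(replace(clean, cp_excess=np.asarray(noisy)))
    return ScanRateSeries(enzyme_id=enzyme_id, thermograms=tuple(thermograms))


def gen_timecourse(
    r0: float = 3.0,
    k_inact: float = 0.2,
    mhet_to_tpa_rate: float = 0.15,
    theoretical_max: float = 29.0,
    times: Sequence[float] = (0, 2, 4, 6, 8, 24, 48, 72),
    noise_sd: float = 0.0,
    replicates: int = 3,
    seed: int = DEFAULT_SEED,
    mhet_release_fraction: float = 0.6,
    bhet_release_fraction: float = 0.0,
    enzyme_id: str = "synthetic",
    condition: Optional[ReactionCondition] = None,
) -> TimeCourse:
    """Saturating monomer release limited by first-order enzyme decay.

    Total product follows P(t) = (r0/k_inact)(1 - exp(-k_inact t)) in
    g/L (the r0 * t limit as k_inact -> 0), capped at
    ``theoretical_max``.  Released product is split between BHET
    (``bhet_release_fraction``, 0 by default - a transient minor
    species), MHET (``mhet_release_fraction``) and TPA; the MHET pool
    matures to TPA with first-order rate ``mhet_to_tpa_rate`` (1/h).
    Gaussian noise (``noise_sd``, g/L, absolute) is truncated at zero.
    """
    t = np.asarray(list(times), dtype=float)
    if t.size == 0:
        raise ValueError("time list must be non-empty")
    if min(r0, k_inact, mhet_to_tpa_rate) < 0:
        raise ValueError("rates must be >= 0")
    rng = np.random.default_rng(seed)
    if k_inact > 0:
        total = (r0 / k_inact) * (1.0 - np.exp(-k_inact * t))
    else:
        total = r0 * t
    # MHET released at fraction phi of the instantaneous release rate
    # rho(t) = r0 exp(-k t), maturing to TPA at rate rm:
    # MHET(t) = phi * r0 * (exp(-k t) - exp(-rm t)) / (rm - k).
    phi, rm, k = mhet_release_fraction, mhet_to_tpa_rate, k_inact
    if rm > 0 or k > 0:
        if abs(rm - k) > 1e-12:
            mhet = phi * r0 * (np.exp(-k * t) - np.exp(-rm * t)) / (rm - k)
        else:
            mhet = phi * r0 * t * np.exp(-k * t)
    else:
        mhet = phi * total
    bhet = bhet_release_fraction * total
    mhet = np.minimum(mhet, np.maximum(total - bhet, 0.0))
    cap = np.minimum(total, theoretical_max)
    scale = np.where(total > 0, cap / np.maximum(total, 1e-300), 1.0)
    total, mhet, bhet = cap, mhet * scale, bhet * scale
    tpa = np.maximum(total - mhet - bhet, 0.0)
    rows = []
    for rep in range(1, replicates + 1):
        noise = rng.normal(0.0, noise_sd, (3, t.size)) if noise_sd > 0 else np.zeros((3, t.size))
        rows.append(
            pd.DataFrame(
                {
                    "replicate": rep,
                    "time_h": t,
                    "tpa": np.maximum(tpa + noise[0], 0.0),
                    "mhet": np.maximum(mhet + noise[1], 0.0),
                    "bhet": np.maximum(bhet + noise[2], 0.0),
                }
            )
        )
    if condition is None:
        condition = ReactionCondition(
            pH=8.0, temperature_C=70.0, buffer_mM=1000.0,
            pet_loading_pct_wv=2.9, enzyme_loading_mg_per_g=0.7,
        )
    return TimeCourse(
        enzyme_id=enzyme_id, data=pd.concat(rows, ignore_index=True),
        unit="g_per_L", condition=condition,
    )


def gen_titration_trace(
    fractions,
    times,
    pet_mass: float,
    base_molarity: float,
    reaction_volume: float = 0.2,
) -> TitrationTrace:
    """Titration trace realizing given hydrolysis fractions exactly.

    V_cum(t) = fraction(t) * 2 * (m_PET / M_repeat) / C_base, the exact
    inverse of the pH-stat hydrolysis computation, so the round trip
    reproduces the input fractions to numerical precision.
    """
    f = np.asarray(fractions, dtype=float)
    t = np.asarray(times, dtype=float)
    if np.any(f < 0) or np.any(f > 1):
        raise ValueError("fractions must lie in [0, 1]")
    if np.any(np.diff(f) < 0):
        raise ValueError("fractions must be non-decreasing")
    moles = 2.0 * pet_mass / CONSTANTS.molar_mass["PET_repeat"]
    v_ml = f * moles / base_molarity * 1e3
    return TitrationTrace(
        times=t, cumulative_base_volume=v_ml,
        base_molarity=base_molarity, pet_mass=pet_mass,
        reaction_volume=reaction_volume,
    )


def gen_alignment(
    reference: str,
    n_homologs: int,
    site_freqs: Sequence[Tuple[int, str, float]],
    background_rate: float = 0.05,
    seed: int = DEFAULT_SEED,
    reference_id: str = "reference",
) -> AlignedHomologSet:
    """Ungapped alignment with exact residue counts at queried sites.

    ``site_freqs`` lists (1-based reference position, residue, target
    percent); each target must be realizable as an integer count of
    ``n_homologs`` (else a ValueError names the nearest realizable
    count).  Exactly that many homologs carry the residue at the site;
    the rest keep the reference residue there.  All other columns mutate
    independently at ``background_rate``.
    """
    reference = reference.upper()
    if set(reference) - AMINO_ACIDS:
        raise ValueError("reference must be an ungapped amino-acid sequence")
    if n_homologs < 1:
        raise ValueError("need at least one homolog")
    rng = np.random.default_rng(seed)
    length = len(reference)
    counts = {}
    for pos, residue, pct in site_freqs:
        residue = residue.upper()
        if not (1 <= pos <= length):
            raise ValueError(f"position {pos} beyond reference length {length}")
        exact = pct / 100.0 * n_homologs
        count = round(exact)
        if abs(exact - count) > 1e-6:
            raise ValueError(
                f"{pct}% of {n_homologs} homologs is not an integer count; "
                f"nearest realizable is {count} ({100.0 * count / n_homologs:.4g}%)"
            )
        counts[pos - 1] = (residue, int(count))
    aa = sorted(AMINO_ACIDS)
    seqs = np.array([list(reference) for _ in range(n_homologs)])
    # Background substitutions everywhere except queried columns.
    controlled = set(counts)
    free_cols = [j for j in range(length) if j not in controlled]
    if free_cols and background_rate > 0:
        mask = rng.random((n_homologs, len(free_cols))) < background_rate
        draws = rng.integers(0, len(aa) - 1, size=int(mask.sum()))
        for (i, jj), d in zip(np.argwhere(mask), draws):
            col = free_cols[jj]
            ref_res = reference[col]
            others = [x for x in aa if x != ref_res]
            seqs[i, col] = others[d]
    for col, (residue, count) in counts.items():
        carriers = rng.choice(n_homologs, size=count, replace=False)
        seqs[:, col] = reference[col]
        seqs[carriers, col] = residue
    records = [(reference_id, reference)]
    width = len(str(n_homologs))
    for i in range(n_homologs):
        records.append((f"homolog_{i + 1:0{width}d}", "".join(seqs[i])))
    return AlignedHomologSet(records=tuple(records), reference_id=reference_id)
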