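"""Global fitting of multi-scan-rate DSC series to denaturation models.

The discriminating information in a DSC experiment on an irreversible
unfolder lies in how the endotherm moves and reshapes with scan rate, so
all thermograms of a series are fitted *globally*: one shared parameter
set must reproduce every scan rate simultaneously.  The interface follows
the statsmodels convention: build a :class:`DenaturationModel` from the
data, call :meth:`~DenaturationModel.fit`, and work with the returned
:class:`FitResult` (estimates, standard errors, AICc, fitted and
deconvolved curves, ``summary()``).  ``global_fit`` / ``select_model`` /
``deconvolve`` are thin functional wrappers over the same machinery.

Parameterization: Ea and dH_cal are optimized in log space (positivity),
T* directly with plausibility bounds.  Starting values are data driven:
T* is seeded from the apparent Tm of the median-rate thermogram through
the one-step peak condition k(Tm) = v Ea/(R Tm^2); dH is seeded from the
curve area, split 80/20 between transitions for the two-step model
(mirroring the usual dominance of the first endotherm).  A seeded
multi-start loop guards against local minima.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

from .constants import R, kelvin_to_celsius
from .kinetics import (
    MODEL_IDS,
    ArrheniusTransition,
    DenaturationScheme,
    EquilibriumTwoState,
    ScanRateSeries,
    T_WINDOW,
    _irreversible_states_fine,
    _refine_grid,
    apparent_tm,
)

__all__ = [
    "DenaturationModel",
    "FitResult",
    "ModelComparison",
    "global_fit",
    "select_model",
    "deconvolve",
]

#: Default seed for the multi-start perturbations.
DEFAULT_SEED = 20250821

#: Optimization bounds (log space for Ea and dH).
_LN_EA_BOUNDS = (np.log(5.0e4), np.log(2.0e6))
_LN_DH_BOUNDS = (np.log(1.0e3), np.log(1.0e7))

_PARAM_NAMES = {
    "irreversible_one_step": ("Ea", "T_star", "dH_cal"),
    "irreversible_two_step": (
        "Ea_1", "T_star_1", "dH_cal_1", "Ea_2", "T_star_2", "dH_cal_2",
    ),
    "reversible_two_state": ("dH_vH", "Tm_eq", "dH_cal"),
}


@dataclass
class FitResult:
    """Result of a global fit of one candidate scheme to a series.

    Attributes
    ----------
    scheme : DenaturationScheme
        The scheme populated with the fitted parameter values.
    params : dict
        Named parameter estimates (J/mol and K).
    param_se : dict
        Linearized standard errors from the Jacobian at the optimum,
        same keys and units as ``params``.
    rss, n_obs, aicc, converged
        Residual sum of squares over all fitted points, the number of
        points, the corrected information criterion and the optimizer
        status.
    fitted_curves : list of ndarray
        Predicted Cp on each thermogram's own grid (series order).
    deconvolution : list of list of ndarray
        Per-thermogram, per-transition Cp components; they sum to the
        fitted curve identically.
    """

    model_id: str
    scheme: DenaturationScheme
    params: Dict[str, float]
    param_se: Dict[str, float]
    rss: float
    n_obs: int
    aicc: float
    converged: bool
    fitted_curves: List[np.ndarray]
    deconvolution: List[List[np.ndarray]]
    series: ScanRateSeries
    n_starts_used: int = 1

    @property
    def n_params(self) -> int:
        return len(self.params)

    def deconvolve(self) -> List[List[np.ndarray]]:
        """Per-transition component curves; see :func:`deconvolve`."""
        return deconvolve(self)

    def summary(self) -> str:
        """Human-readable parameter table, kJ/mol and deg C at the boundary."""
        lines = [
            f"Global DSC fit: {self.model_id}  (enzyme {self.series.enzyme_id})",
            f"  scan rates (K/min): {', '.join(f'{r:g}' for r in self.series.scan_rates)}",
            f"  n_obs = {self.n_obs}   rss = {self.rss:.6g}   AICc = {self.aicc:.2f}"
            f"   converged = {self.converged}",
            f"  {'parameter':<12} {'estimate':>12} {'std err':>12}",
        ]
        for name, value in self.params.items():
            se = self.param_se.get(name, float("nan"))
            if name.startswith(("Ea", "dH")):
                lines.append(
                    f"  {name + ' kJ/mol':<12} {value / 1e3:>12.2f} {se / 1e3:>12.2f}"
                )
            else:
                lines.append(
                    f"  {name + ' degC':<12} {kelvin_to_celsius(value):>12.2f} {se:>12.2f}"
                )
        return "\n".join(lines)

    def plot(self, ax=None):
        """Overlay data, fit and deconvolved components per scan rate."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for tg, fit, comps in zip(
            self.series.thermograms, self.fitted_curves, self.deconvolution
        ):
            t_c = kelvin_to_celsius(tg.temperatures)
            ax.plot(t_c, tg.cp_excess / 1e3, ".", ms=2, alpha=0.5)
            ax.plot(t_c, fit / 1e3, "-", label=f"{tg.scan_rate:g} K/min")
            for comp in comps if len(comps) > 1 else []:
                ax.plot(t_c, comp / 1e3, "--", lw=0.8)
        ax.set_xlabel("temperature (deg C)")
        ax.set_ylabel("excess Cp (kJ mol$^{-1}$ K$^{-1}$)")
        ax.legend(title=self.model_id, fontsize="small")
        return ax


@dataclass
class ModelComparison:
    """Outcome of fitting several candidate schemes to one series."""

    results: Dict[str, FitResult]
    ranking: List[str]  # by ascending AICc among successful fits
    selected: str
    errors: Dict[str, str] = field(default_factory=dict)

    @property
    def selected_result(self) -> FitResult:
        return self.results[self.selected]

    def summary(self) -> str:
        lines = ["Model comparison (ascending AICc):"]
        for mid in self.ranking:
            r = self.results[mid]
            mark = " <- selected" if mid == self.selected else ""
            lines.append(
                f"  {mid:<24} AICc = {r.aicc:10.2f}  k = {r.n_params}{mark}"
            )
        for mid, msg in self.errors.items():
            lines.append(f"  {mid:<24} failed: {msg}")
        return "\n".join(lines)


class DenaturationModel:
    """Global model of a :class:`ScanRateSeries` under one candidate scheme.

    Parameters
    ----------
    series : ScanRateSeries
        At least two thermograms at distinct scan rates, each containing
        a full endotherm (interior maximum).
    model_id : str
        One of ``irreversible_two_step`` (default), ``irreversible_one_step``,
        ``reversible_two_state``.
    weights : sequence of float, optional
        Per-thermogram weights (e.g. inverse variances). Default:
        unweighted least squares over all points.
    """

    def __init__(
        self,
        series: ScanRateSeries,
        model_id: str = "irreversible_two_step",
        weights: Optional[Sequence[float]] = None,
    ):
        if model_id not in MODEL_IDS:
            raise ValueError(f"unknown model_id {model_id!r}")
        self.series = series.sorted_by_rate()
        self.model_id = model_id
        n_rates = len(set(self.series.scan_rates))
        if model_id != "reversible_two_state" and n_rates < 2:
            raise ValueError(
                "irreversible models are unidentifiable from a single scan rate"
            )
        if weights is None:
            self.weights = np.ones(len(self.series.thermograms))
        else:
            self.weights = np.asarray(list(weights), dtype=float)
            if self.weights.shape != (len(self.series.thermograms),):
                raise ValueError("one weight per thermogram required")
        # Precompute refined integration grids per thermogram (fixed data).
        self._grids = [
            _refine_grid(tg.temperatures, 0.02) for tg in self.series.thermograms
        ]
        self._v = [tg.scan_rate / 60.0 for tg in self.series.thermograms]
        self.n_obs = int(sum(tg.temperatures.size for tg in self.series.thermograms))

    # -- forward evaluation --------------------------------------------------

    def _predict_components(self, theta) -> List[List[np.ndarray]]:
        """Per-thermogram, per-transition Cp components for raw params."""
        out = []
        if self.model_id == "reversible_two_state":
            dH_vH, Tm_eq, dH_cal = np.exp(theta[0]), theta[1], np.exp(theta[2])
            for tg in self.series.thermograms:
                T = tg.temperatures
                K = np.exp(-(dH_vH / R) * (1.0 / T - 1.0 / Tm_eq))
                alpha = K / (1.0 + K)
                out.append([dH_cal * alpha * (1 - alpha) * dH_vH / (R * T**2)])
            return out
        scheme = self._theta_to_scheme(theta)
        for (fine, idx), v in zip(self._grids, self._v):
            _, _, flux1, flux2 = _irreversible_states_fine(scheme, v, fine)
            comps = [scheme.transitions[0].dH_cal * flux1[idx]]
            if self.model_id == "irreversible_two_step":
                comps.append(scheme.transitions[1].dH_cal * flux2[idx])
            out.append(comps)
        return out

    def predict(self, theta) -> List[np.ndarray]:
        return [np.sum(c, axis=0) for c in self._predict_components(theta)]

    def _residuals(self, theta) -> np.ndarray:
        res = []
        for pred, tg, w in zip(
            self.predict(theta), self.series.thermograms, self.weights
        ):
            res.append(np.sqrt(w) * (pred - tg.cp_excess))
        r = np.concatenate(res)
        return np.nan_to_num(r, nan=1e6, posinf=1e6, neginf=-1e6)

    # -- parameter packing ---------------------------------------------------

    def _theta_to_scheme(self, theta) -> DenaturationScheme:
        if self.model_id == "reversible_two_state":
            eq = EquilibriumTwoState(
                dH_vH=float(np.exp(theta[0])),
                Tm_eq=float(theta[1]),
                dH_cal=float(np.exp(theta[2])),
            )
            return DenaturationScheme(self.model_id, equilibrium=eq)
        labels = ("N->I", "I->D") if self.model_id == "irreversible_two_step" else ("N->D",)
        transitions = []
        for j, label in enumerate(labels):
            ea, t_star, dh = theta[3 * j : 3 * j + 3]
            transitions.append(
                ArrheniusTransition(
                    label=label,
                    dH_cal=float(np.exp(dh)),
                    Ea=float(np.exp(ea)),
                    T_star=float(t_star),
                )
            )
        return DenaturationScheme(self.model_id, transitions=tuple(transitions))

    @staticmethod
    def _scheme_to_theta(scheme: DenaturationScheme) -> np.ndarray:
        if scheme.model_id == "reversible_two_state":
            eq = scheme.equilibrium
            return np.array([np.log(eq.dH_vH), eq.Tm_eq, np.log(eq.dH_cal)])
        theta = []
        for tr in scheme.transitions:
            theta += [np.log(tr.Ea), tr.T_star, np.log(tr.dH_cal)]
        return np.asarray(theta)

    def _bounds(self):
        per = ([_LN_EA_BOUNDS[0], T_WINDOW[0], _LN_DH_BOUNDS[0]],
               [_LN_EA_BOUNDS[1], T_WINDOW[1], _LN_DH_BOUNDS[1]])
        n_blocks = 2 if self.model_id == "irreversible_two_step" else 1
        return (np.array(per[0] * n_blocks), np.array(per[1] * n_blocks))

    def _initial_theta(self) -> np.ndarray:
        """Data-driven starting point (see module docstring)."""
        thermos = self.series.thermograms
        mid = thermos[len(thermos) // 2]
        try:
            tm = apparent_tm(mid)
        except ValueError:
            tm = float(mid.temperatures[np.argmax(mid.cp_excess)])
        area = max(mid.area, 1.5e3)
        if self.model_id == "reversible_two_state":
            cp_max = float(np.max(mid.cp_excess))
            dh_vh = np.clip(4.0 * R * tm**2 * cp_max / area, 5e4, 2e6)
            return np.array([np.log(dh_vh), tm, np.log(area)])
        ea0 = 300e3
        v = mid.scan_rate / 60.0
        k_tm = v * ea0 / (R * tm**2)
        t_star = 1.0 / (1.0 / tm + R * np.log(k_tm) / ea0)
        if self.model_id == "irreversible_one_step":
            return np.array([np.log(ea0), t_star, np.log(area)])
        return np.array(
            [
                np.log(ea0), t_star, np.log(0.8 * area),
                np.log(ea0), t_star + 3.0, np.log(0.2 * area),
            ]
        )

    # -- fitting -------------------------------------------------------------

    def fit(
        self,
        starts: int = 8,
        seed: int = DEFAULT_SEED,
        verbose: bool = False,
    ) -> FitResult:
        """Trust-region least squares with a seeded multi-start loop.

        The first start is the data-driven seed; subsequent starts perturb
        it (T* by N(0, 1.5 K), log parameters by N(0, 0.15)).  The loop
        stops early once two independent starts agree on the best rss to
        1e-6 relative.  Returns the best fit found; ``converged`` is False
        if no start satisfied the optimizer's convergence criteria.
        """
        if starts < 1:
            raise ValueError("starts must be >= 1")
        rng = np.random.default_rng(seed)
        lo, hi = self._bounds()
        theta0 = np.clip(self._initial_theta(), lo + 1e-9, hi - 1e-9)
        best = None
        hits_of_best = 0
        for i in range(starts):
            if i == 0:
                x0 = theta0
            else:
                x0 = theta0.copy()
                is_temp = np.array([n in (1, 4) for n in range(x0.size)])
                x0[is_temp] += rng.normal(0.0, 1.5, is_temp.sum())
                x0[~is_temp] += rng.normal(0.0, 0.15, (~is_temp).sum())
                x0 = np.clip(x0, lo + 1e-9, hi - 1e-9)
            try:
                sol = least_squares(
                    self._residuals, x0, bounds=(lo, hi), method="trf",
                    x_scale="jac", ftol=1e-12, xtol=1e-12, gtol=1e-12,
                )
            except Exception:
                continue
            rss = float(2.0 * sol.cost)
            if verbose:
                print(f"  start {i}: rss = {rss:.6g} (status {sol.status})")
            if best is None or rss < best[0] * (1 - 1e-9):
                if best is not None and abs(rss - best[0]) <= 1e-6 * max(best[0], 1e-30):
                    hits_of_best += 1
                else:
                    hits_of_best = 1
                best = (rss, sol, i + 1)
            elif abs(rss - best[0]) <= 1e-6 * max(best[0], 1e-30):
                hits_of_best += 1
            if hits_of_best >= 2:
                break
        if best is None:
            raise RuntimeError("all optimization starts failed")
        rss, sol, used = best
        return self._package(sol, rss, used)

    def _package(self, sol, rss: float, n_starts_used: int) -> FitResult:
        theta = sol.x
        scheme = self._theta_to_scheme(theta)
        names = _PARAM_NAMES[self.model_id]
        values = self._theta_values(theta)
        se = self._standard_errors(sol, rss, theta)
        components = self._predict_components(theta)
        fitted = [np.sum(c, axis=0) for c in components]
        n, p = self.n_obs, theta.size
        k = p + 1  # + residual variance
        aicc = n * np.log(max(rss, 1e-300) / n) + 2 * k
        if n - k - 1 > 0:
            aicc += 2.0 * k * (k + 1) / (n - k - 1)
        return FitResult(
            model_id=self.model_id,
            scheme=scheme,
            params=dict(zip(names, values)),
            param_se=dict(zip(names, se)),
            rss=rss,
            n_obs=n,
            aicc=float(aicc),
            converged=bool(sol.status > 0),
            fitted_curves=fitted,
            deconvolution=components,
            series=self.series,
            n_starts_used=n_starts_used,
        )

    def _theta_values(self, theta) -> List[float]:
        vals = []
        for j, x in enumerate(theta):
            vals.append(float(x) if j % 3 == 1 else float(np.exp(x)))
        return vals

    def _standard_errors(self, sol, rss, theta) -> List[float]:
        """Delta-method SEs on the natural scale from the optimum Jacobian."""
        n, p = self.n_obs, theta.size
        dof = max(n - p, 1)
        s2 = rss / dof
        J = sol.jac
        try:
            _, sing, VT = np.linalg.svd(J, full_matrices=False)
            tol = np.finfo(float).eps * max(J.shape) * sing[0]
            inv = np.where(sing > tol, 1.0 / sing**2, 0.0)
            cov = (VT.T * inv) @ VT * s2
            se_theta = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            se_theta = np.full(p, np.nan)
        se = []
        for j, (x, s) in enumerate(zip(theta, se_theta)):
            se.append(float(s) if j % 3 == 1 else float(np.exp(x) * s))
        return se


def global_fit(
    series: ScanRateSeries,
    model_id: str,
    *,
    starts: int = 8,
    seed: int = DEFAULT_SEED,
    weights: Optional[Sequence[float]] = None,
    verbose: bool = False,
) -> FitResult:
    """Fit one candidate scheme globally across all scan rates of a series.

    Convenience wrapper over ``DenaturationModel(series, model_id).fit()``.
    """
    return DenaturationModel(series, model_id, weights=weights).fit(
        starts=starts, seed=seed, verbose=verbose
    )


#: Models within this AICc distance of the best are considered equivalent;
#: the simplest (fewest parameters) of an equivalent set is selected.
AICC_EQUIVALENCE = 2.0


def select_model(
    series: ScanRateSeries,
    candidates: Sequence[str] = MODEL_IDS,
    *,
    starts: int = 8,
    seed: int = DEFAULT_SEED,
    equivalence_delta: float = AICC_EQUIVALENCE,
) -> ModelComparison:
    """Fit every candidate scheme and pick the simplest satisfactory one.

    Candidates are ranked by AICc.  Among models within
    ``equivalence_delta`` AICc units of the best (statistically
    indistinguishable fits), the one with the fewest parameters is
    selected, so a needlessly complex model never wins on noise alone.
    Individual fit failures are recorded and do not abort the others.
    """
    if len(candidates) < 2 and len(candidates) != 1:
        raise ValueError("at least one candidate model is required")
    results: Dict[str, FitResult] = {}
    errors: Dict[str, str] = {}
    for mid in candidates:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                results[mid] = global_fit(series, mid, starts=starts, seed=seed)
        except Exception as exc:  # propagate per-candidate without aborting
            errors[mid] = str(exc)
    if not results:
        raise RuntimeError(f"every candidate fit failed: {errors}")
    ranking = sorted(results, key=lambda m: (results[m].aicc, results[m].n_params))
    best_aicc = results[ranking[0]].aicc
    equivalent = [m for m in ranking if results[m].aicc <= best_aicc + equivalence_delta]
    selected = min(equivalent, key=lambda m: (results[m].n_params, results[m].aicc))
    return ModelComparison(results=results, ranking=ranking, selected=selected, errors=errors)


def deconvolve(fit: FitResult) -> List[List[np.ndarray]]:
    """Split each fitted thermogram into its per-transition components.

    For the two-step model, returns two non-negative component curves per
    thermogram (native->intermediate and intermediate->denatured); their
    sum is the fitted total and each component's area is the fitted
    dH_cal of its transition.  For one-step or reversible fits a single
    component is returned with a notice.
    """
    if fit.model_id != "irreversible_two_step":
        warnings.warn(
            f"deconvolution of a {fit.model_id} fit has a single component",
            UserWarning,
            stacklevel=2,
        )
    return fit.deconvolution
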