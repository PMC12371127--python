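"""Readers and writers for the plain-text formats the analyses exchange.

Units convert exactly once at these boundaries: thermogram CSVs carry
deg C and kJ/(mol K), scheme JSON carries kJ/mol and deg C, while the
in-memory objects hold K and J/mol throughout.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Union

import numpy as np
import pandas as pd
import yaml

from .alignment import AlignedHomologSet, MutationQuery
from .constants import celsius_to_kelvin, kelvin_to_celsius
from .depolymerization import ReactionCondition, TimeCourse, TitrationTrace
from .fitting import FitResult
from .kinetics import (
    ArrheniusTransition,
    DenaturationScheme,
    EquilibriumTwoState,
    ScanRateSeries,
    Thermogram,
)

__all__ = [
    "read_thermogram_csv",
    "read_scan_rate_series",
    "write_scan_rate_series_csv",
    "scheme_to_json",
    "scheme_from_json",
    "fit_result_to_dict",
    "read_timecourse_csv",
    "read_titration_csv",
    "read_mutation_csv",
    "write_alignment_fasta",
]

PathLike = Union[str, Path]


def read_thermogram_csv(
    path: PathLike,
    enzyme_id: str = "enzyme",
    scan_rate: Optional[float] = None,
) -> List[Thermogram]:
    """Read thermograms from CSV.

    Two dialects: per-scan-rate files with columns ``temperature_C,
    cp_excess_kJ_per_mol_K`` (pass ``scan_rate`` in K/min), or long
    format with an additional ``scan_rate_C_per_min`` column.
    """
    df = pd.read_csv(path)
    needed = {"temperature_C", "cp_excess_kJ_per_mol_K"}
    if not needed <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(needed)}")
    if "scan_rate_C_per_min" in df.columns:
        groups = [(float(v), g) for v, g in df.groupby("scan_rate_C_per_min")]
    else:
        if scan_rate is None:
            raise ValueError(
                f"{path}: no scan_rate_C_per_min column; pass scan_rate explicitly"
            )
        groups = [(float(scan_rate), df)]
    out = []
    for rate, g in groups:
        out.append(
            Thermogram(
                enzyme_id=enzyme_id,
                scan_rate=rate,
                temperatures=celsius_to_kelvin(g["temperature_C"].to_numpy(float)),
                cp_excess=g["cp_excess_kJ_per_mol_K"].to_numpy(float) * 1e3,
            )
        )
    return out


def read_scan_rate_series(path: PathLike, enzyme_id: str = "enzyme") -> ScanRateSeries:
    """Read a series from a long-format CSV file or a directory of CSVs."""
    p = Path(path)
    if p.is_dir():
        thermograms = []
        for f in sorted(p.glob("*.csv")):
            thermograms.extend(read_thermogram_csv(f, enzyme_id=enzyme_id))
    else:
        thermograms = read_thermogram_csv(p, enzyme_id=enzyme_id)
    return ScanRateSeries(enzyme_id=enzyme_id, thermograms=tuple(thermograms))


def write_scan_rate_series_csv(series: ScanRateSeries, path: PathLike) -> None:
    """Write a series as one long-format CSV."""
    frames = []
    for tg in series.thermograms:
        frames.append(
            pd.DataFrame(
                {
                    "scan_rate_C_per_min": tg.scan_rate,
                    "temperature_C": kelvin_to_celsius(tg.temperatures),
                    "cp_excess_kJ_per_mol_K": tg.cp_excess / 1e3,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def _transition_to_dict(tr: ArrheniusTransition) -> Dict:
    return {
        "label": tr.label,
        "dH_cal_kJ_mol": tr.dH_cal / 1e3,
        "Ea_kJ_mol": tr.Ea / 1e3,
        "T_star_C": kelvin_to_celsius(tr.T_star),
    }


def scheme_to_json(scheme: DenaturationScheme, path: Optional[PathLike] = None) -> str:
    """Serialize a scheme (kJ/mol and deg C at the boundary)."""
    payload: Dict = {"model_id": scheme.model_id}
    payload["transitions"] = [_transition_to_dict(t) for t in scheme.transitions]
    if scheme.equilibrium is not None:
        eq = scheme.equilibrium
        payload["equilibrium"] = {
            "dH_vH_kJ_mol": eq.dH_vH / 1e3,
            "Tm_eq_C": kelvin_to_celsius(eq.Tm_eq),
            "dH_cal_kJ_mol": eq.dH_cal / 1e3,
        }
    text = json.dumps(payload, indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text


def scheme_from_json(source: Union[PathLike, str, Dict]) -> DenaturationScheme:
    """Inverse of :func:`scheme_to_json`; accepts a path, JSON text or dict."""
    if isinstance(source, dict):
        payload = source
    else:
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        payload = json.loads(text)
    transitions = tuple(
        ArrheniusTransition(
            label=t.get("label", f"transition_{i + 1}"),
            dH_cal=t["dH_cal_kJ_mol"] * 1e3,
            Ea=t["Ea_kJ_mol"] * 1e3,
            T_star=celsius_to_kelvin(t["T_star_C"]),
        )
        for i, t in enumerate(payload.get("transitions", []))
    )
    eq = None
    if payload.get("equilibrium"):
        e = payload["equilibrium"]
        eq = EquilibriumTwoState(
            dH_vH=e["dH_vH_kJ_mol"] * 1e3,
            Tm_eq=celsius_to_kelvin(e["Tm_eq_C"]),
            dH_cal=e["dH_cal_kJ_mol"] * 1e3,
        )
    return DenaturationScheme(payload["model_id"], transitions=transitions, equilibrium=eq)


def fit_result_to_dict(fit: FitResult) -> Dict:
    """JSON-ready summary of a fit (kJ/mol and deg C at the boundary)."""
    params = {}
    for name, value in fit.params.items():
        se = fit.param_se.get(name)
        if name.startswith(("Ea", "dH")):
            params[name + "_kJ_mol"] = {"estimate": value / 1e3, "se": se / 1e3}
        else:
            params[name + "_C"] = {"estimate": kelvin_to_celsius(value), "se": se}
    return {
        "model_id": fit.model_id,
        "enzyme_id": fit.series.enzyme_id,
        "converged": fit.converged,
        "n_obs": fit.n_obs,
        "rss": fit.rss,
        "aicc": fit.aicc,
        "parameters": params,
        "scheme": json.loads(scheme_to_json(fit.scheme)),
    }


def _load_sidecar(path: PathLike) -> Dict:
    p = Path(path)
    text = p.read_text()
    if p.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def read_timecourse_csv(
    path: PathLike,
    meta: Optional[PathLike] = None,
) -> List[TimeCourse]:
    """Read monomer time courses from CSV.

    Columns: ``enzyme_id, replicate, time_h, tpa, mhet, bhet, unit``
    (unit ``g_per_L`` or ``mM``, consistent per enzyme).  ``meta`` is an
    optional YAML/JSON side-car holding :class:`ReactionCondition`
    fields, either flat or keyed by enzyme_id.
    """
    df = pd.read_csv(path)
    needed = {"enzyme_id", "time_h", "tpa", "mhet", "bhet", "unit"}
    if not needed <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(needed)}")
    meta_payload = _load_sidecar(meta) if meta is not None else {}
    out = []
    for enzyme_id, grp in df.groupby("enzyme_id", sort=False):
        units = grp["unit"].unique()
        if units.size != 1:
            raise ValueError(f"{enzyme_id}: mixed unit tags {list(units)}")
        cond_fields = meta_payload.get(enzyme_id, meta_payload)
        cond = ReactionCondition(
            **{
                k: v
                for k, v in cond_fields.items()
                if k in ReactionCondition.__dataclass_fields__
            }
        )
        out.append(
            TimeCourse(
                enzyme_id=str(enzyme_id),
                data=grp.drop(columns=["enzyme_id", "unit"]).reset_index(drop=True),
                unit=str(units[0]),
                condition=cond,
            )
        )
    return out


def read_titration_csv(
    path: PathLike,
    pet_mass: float,
    base_molarity: float,
    reaction_volume: float = 0.2,
) -> TitrationTrace:
    """Read a pH-stat trace CSV with columns ``time_h, cum_base_mL``."""
    df = pd.read_csv(path)
    needed = {"time_h", "cum_base_mL"}
    if not needed <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(needed)}")
    return TitrationTrace(
        times=df["time_h"].to_numpy(float),
        cumulative_base_volume=df["cum_base_mL"].to_numpy(float),
        base_molarity=base_molarity,
        pet_mass=pet_mass,
        reaction_volume=reaction_volume,
    )


def read_mutation_csv(path: PathLike) -> MutationQuery:
    """Read a mutation list CSV with columns ``position, ref_aa, mut_aa``."""
    df = pd.read_csv(path)
    needed = {"position", "ref_aa", "mut_aa"}
    if not needed <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(needed)}")
    return MutationQuery(
        entries=tuple(
            (int(r.position), str(r.ref_aa), str(r.mut_aa)) for r in df.itertuples()
        )
    )


def write_alignment_fasta(aln: AlignedHomologSet, path: PathLike) -> None:
    """Write an aligned FASTA file."""
    with open(path, "w") as fh:
        for rid, seq in aln.records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
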