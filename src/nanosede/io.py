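"""Config parsing and CSV schemas for the command-line pipeline.

All CSVs are comma-delimited UTF-8 with a header row and units embedded in
the column names (flux_m_per_s, dP_MPa, rp_nm, ...) so unit drift is caught
at the schema level. Configuration is YAML with explicit unit-tagged keys
(rp_nm, dx_eff_um); unknown keys are rejected with the full field path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .charge import ChargeProfile
from .physchem import Species
from .transport import Membrane

__all__ = [
    "PipelineConfig",
    "load_config",
    "read_rejection_csv",
    "write_pore_report",
    "write_curve_csv",
]

_MEMBRANE_KEYS = {"rp_nm", "dx_eff_um", "eps_p", "charge", "lambda_max"}
_CHARGE_KEYS = {"c_entrance", "c_exit", "x0", "w"}
_SPECIES_KEYS = {"z", "D_inf", "r_stokes_nm", "r_cav_nm", "pKa1", "pKa2"}
_TOP_KEYS = {"membranes", "species", "run", "output"}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration."""

    membranes: dict[str, Membrane] = field(default_factory=dict)
    species: dict[str, Species] = field(default_factory=dict)
    run: dict = field(default_factory=dict)
    output: dict = field(default_factory=dict)


def _require(mapping: dict, key: str, path: str):
    if key not in mapping:
        raise KeyError(f"missing required field '{path}.{key}'")
    return mapping[key]


def _check_keys(mapping: dict, allowed: set[str], path: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise KeyError(f"unknown field(s) {sorted(unknown)} at '{path}'")


def _parse_membrane(name: str, raw: dict) -> Membrane:
    path = f"membranes.{name}"
    if not isinstance(raw, dict):
        raise TypeError(f"'{path}' must be a mapping")
    _check_keys(raw, _MEMBRANE_KEYS, path)
    ch = _require(raw, "charge", path)
    _check_keys(ch, _CHARGE_KEYS, f"{path}.charge")
    profile = ChargeProfile(
        c_entrance=float(_require(ch, "c_entrance", f"{path}.charge")),
        c_exit=float(_require(ch, "c_exit", f"{path}.charge")),
        x0=float(ch.get("x0", 0.65)),
        w=float(ch.get("w", 0.08)),
    )
    return Membrane(
        rp=float(_require(raw, "rp_nm", path)) * 1e-9,
        dx_eff=float(_require(raw, "dx_eff_um", path)) * 1e-6,
        eps_p=float(_require(raw, "eps_p", path)),
        profile=profile,
        name=name,
        lambda_max=float(raw.get("lambda_max", 0.98)),
    )


def _parse_species(name: str, raw: dict) -> Species:
    path = f"species.{name}"
    if not isinstance(raw, dict):
        raise TypeError(f"'{path}' must be a mapping")
    _check_keys(raw, _SPECIES_KEYS, path)
    r_cav = raw.get("r_cav_nm")
    return Species(
        name=name,
        z=int(_require(raw, "z", path)),
        D_inf=float(_require(raw, "D_inf", path)),
        r_stokes=float(_require(raw, "r_stokes_nm", path)) * 1e-9,
        r_cav=None if r_cav is None else float(r_cav) * 1e-9,
        pKa1=raw.get("pKa1"),
        pKa2=raw.get("pKa2"),
    )


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline config; errors carry field paths."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise TypeError("config root must be a mapping")
    _check_keys(raw, _TOP_KEYS, "<root>")
    cfg = PipelineConfig(run=dict(raw.get("run", {})), output=dict(raw.get("output", {})))
    for name, m in (raw.get("membranes") or {}).items():
        cfg.membranes[name] = _parse_membrane(name, m)
    for name, s in (raw.get("species") or {}).items():
        cfg.species[name] = _parse_species(name, s)
    return cfg


def dump_config(cfg: PipelineConfig, path: str | Path) -> None:
    """Write a config back out in the same schema ``load_config`` reads."""
    doc: dict = {"membranes": {}, "species": {}, "run": cfg.run, "output": cfg.output}
    for name, m in cfg.membranes.items():
        doc["membranes"][name] = {
            "rp_nm": m.rp * 1e9, "dx_eff_um": m.dx_eff * 1e6, "eps_p": m.eps_p,
            "lambda_max": m.lambda_max,
            "charge": {"c_entrance": m.profile.c_entrance, "c_exit": m.profile.c_exit,
                       "x0": m.profile.x0, "w": m.profile.w},
        }
    for name, s in cfg.species.items():
        entry = {"z": s.z, "D_inf": s.D_inf, "r_stokes_nm": s.r_stokes * 1e9,
                 "r_cav_nm": s.r_cav * 1e9}
        if s.pKa1 is not None:
            entry["pKa1"] = s.pKa1
        if s.pKa2 is not None:
            entry["pKa2"] = s.pKa2
        doc["species"][name] = entry
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True), encoding="utf-8")


_REJECTION_COLUMNS = {"membrane", "flux_m_per_s", "rejection"}


def read_rejection_csv(path: str | Path) -> pd.DataFrame:
    """Strict reader for tracer/solute rejection tables.

    Requires columns membrane, tracer (or solute), flux_m_per_s, rejection;
    rejects NaN and negative fluxes with the offending line number.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty rejection table")
    cols = set(df.columns)
    if "tracer" not in cols and "solute" not in cols:
        raise ValueError(f"{path}: need a 'tracer' or 'solute' column")
    missing = _REJECTION_COLUMNS - cols
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    for col in ("flux_m_per_s", "rejection"):
        bad = df.index[df[col].isna()]
        if len(bad):
            raise ValueError(f"{path}: NaN in '{col}' at line {bad[0] + 2}")
    bad = df.index[df["flux_m_per_s"] <= 0]
    if len(bad):
        raise ValueError(f"{path}: non-positive flux at line {bad[0] + 2}")
    return df


def write_pore_report(report: pd.DataFrame, path: str | Path) -> None:
    """Characterization report CSV; rp columns rounded to 2 decimals (nm)."""
    out = report.copy()
    for col in out.columns:
        if col.startswith("rp") or col == "mean_rp_nm":
            out[col] = np.round(out[col].astype(float), 2)
    out.to_csv(path, index=False)


def write_curve_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)
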