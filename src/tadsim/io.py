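"""Readers/writers for the documented file formats, config loading, provenance.

All tabular data is CSV, structured results are JSON, configuration is a
small YAML schema.  Temperatures in files are deg C and concentrations uM;
unit conversion to the internal kelvin/mol-per-litre happens here and only
here.  Every CLI run writes a provenance record (config hash, seed, package
version) beside its outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .design import TADDesign, build_design
from .meltfit import PLATE_COLUMNS, MeltFitResult
from .thermo import DomainSeq

__all__ = [
    "read_plate",
    "write_plate",
    "design_from_yaml",
    "design_to_yaml",
    "fit_to_json",
    "write_json",
    "write_provenance",
]


def read_plate(path: str | Path) -> pd.DataFrame:
    """Read a plate table, enforcing the bit-exact CSV dialect header."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
    if header != ",".join(PLATE_COLUMNS):
        raise ValueError(
            f"{path}: unexpected plate header {header!r}; expected {','.join(PLATE_COLUMNS)!r}"
        )
    df = pd.read_csv(path)
    df["temperature_C"] = df["temperature_C"].astype(float)
    return df


def write_plate(df: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"plate table missing columns {missing}")
    df.loc[:, PLATE_COLUMNS].to_csv(path, index=False)


def design_from_yaml(path: str | Path) -> TADDesign:
    """Load a design config (concentrations in uM in the file)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    domains = {k: DomainSeq(k, v) for k, v in cfg["domains"].items()}
    d, _ = build_design(
        domains["alpha"],
        domains["beta"],
        domains["gamma"],
        N=int(cfg.get("N", 0)),
        L=int(cfg.get("L", 8)),
        H_L=int(cfg.get("H_L", 6)),
        H_l=int(cfg.get("H_l", 4)),
        C=float(cfg.get("C_uM", 10.0)) * 1e-6,
        I_total=float(cfg.get("I_total_uM", 1.0)) * 1e-6,
        S_total=float(cfg.get("S_total_uM", 1.0)) * 1e-6,
        name=str(cfg.get("name", "tad")),
    )
    return d


def design_to_yaml(d: TADDesign, path: str | Path) -> None:
    """Write the canonical form of a design config."""
    cfg = {
        "name": d.name,
        "domains": {"alpha": d.alpha.bases, "beta": d.beta.bases, "gamma": d.gamma.bases},
        "N": d.N,
        "L": d.L,
        "H_L": d.H_L,
        "H_l": d.H_l,
        "C_uM": d.C * 1e6,
        "I_total_uM": d.I_total * 1e6,
        "S_total_uM": d.S_total * 1e6,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def fit_to_json(fit: MeltFitResult) -> dict:
    s = fit.melt_summary
    return {
        "dH_vH_kcal_mol": fit.dH_vH,
        "T_half_C": fit.T_half,
        "baseline_lo": fit.baseline_lo,
        "baseline_hi": fit.baseline_hi,
        "stderr": {k: (v if v == v else None) for k, v in fit.stderr.items()},
        "residual_rms": fit.residual_rms,
        "n_obs": fit.n_obs,
        "T_d_C": s.T_d,
        "delta_T_C": s.delta_T,
    }


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_jsonable)
        fh.write("\n")


def _jsonable(o):
    try:
        return asdict(o)
    except TypeError:
        pass
    if hasattr(o, "tolist"):
        return o.tolist()
    return str(o)


def write_provenance(out_path: str | Path, config: dict, seed: int | None = None) -> Path:
    """Write ``<out>.provenance.json`` with a config hash and package version."""
    out_path = Path(out_path)
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    record = {
        "package": "tadsim",
        "version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "config": config,
    }
    prov = out_path.with_suffix(out_path.suffix + ".provenance.json")
    with open(prov, "w") as fh:
        json.dump(record, fh, indent=2, default=str)
        fh.write("\n")
    return prov
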