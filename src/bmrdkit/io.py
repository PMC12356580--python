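"""Table readers/writers, configuration handling and run provenance.

Delimited text (comma or tab, auto-detected) for all tables; YAML for the
spin-system/experiment configuration; JSON-style sidecars for metadata.
Numeric output is locale-independent with a fixed column order.
"""

from __future__ import annotations

import json
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .processing import DecayCurve, DispersionProfile, OnePointSeries
from .systems import RelaxationSpec, SpinSystem, system_from_coordinates

__all__ = [
    "SCHEMAS",
    "read_table",
    "write_table",
    "read_one_point",
    "read_anchor_curves",
    "write_profile",
    "read_profile",
    "read_shift_table",
    "load_config",
    "default_config",
    "config_to_system",
    "write_provenance",
]

SCHEMAS: dict[str, dict] = {
    "one_point": {
        "required": ["site", "nu1_nominal_hz", "intensity", "sigma",
                     "duration_s", "carrier_hz", "site_freq_hz", "r1_s"],
        "numeric": ["nu1_nominal_hz", "intensity", "sigma", "duration_s",
                    "carrier_hz", "site_freq_hz", "r1_s"],
    },
    "anchors": {
        "required": ["site", "nu1_nominal_hz", "duration_s", "intensity", "sigma"],
        "numeric": ["nu1_nominal_hz", "duration_s", "intensity", "sigma"],
    },
    "profile": {
        "required": ["site", "nu1_hz", "r1rho_s-1", "u_s-1", "theta_deg"],
        "numeric": ["nu1_hz", "r1rho_s-1", "u_s-1", "theta_deg"],
    },
    "shifts": {
        "required": ["residue", "atom", "shift_ppm"],
        "numeric": ["residue", "shift_ppm"],
    },
    "sim_profile": {
        "required": ["nu1_hz", "r1rho_s-1"],
        "numeric": ["nu1_hz", "r1rho_s-1"],
    },
}


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate a delimited table against a named schema.

    The delimiter (comma or tab) is auto-detected.  Missing required columns
    raise with the full schema listed; malformed numeric cells are reported
    with 1-based line numbers.
    """
    if schema not in SCHEMAS:
        raise KeyError(f"unknown schema {schema!r}; known: {sorted(SCHEMAS)}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=None, engine="python")
    spec = SCHEMAS[schema]
    missing = [c for c in spec["required"] if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required column(s) {missing}; "
            f"schema {schema!r} requires {spec['required']}"
        )
    for col in spec["numeric"]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            lineno = int(bad[0]) + 2  # header + 1-based
            raise ValueError(
                f"{path}: non-numeric value {df[col].iloc[bad[0]]!r} in column "
                f"{col!r} at line {lineno}"
            )
        df[col] = coerced
    return df


def write_table(df: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, index=False, float_format="%.10g")


def read_one_point(path: str | Path) -> list[OnePointSeries]:
    """All one-point series in a table, one per site."""
    df = read_table(path, "one_point")
    out = []
    for site, grp in df.groupby("site", sort=True):
        out.append(
            OnePointSeries(
                str(site),
                grp["nu1_nominal_hz"].to_numpy(),
                grp["intensity"].to_numpy(),
                grp["sigma"].to_numpy(),
                float(grp["duration_s"].iloc[0]),
                float(grp["carrier_hz"].iloc[0]),
                float(grp["site_freq_hz"].iloc[0]),
                float(grp["r1_s"].iloc[0]),
            )
        )
    return out


def read_anchor_curves(path: str | Path) -> dict[str, list[DecayCurve]]:
    """Anchor decay curves grouped by site then nominal frequency."""
    df = read_table(path, "anchors")
    out: dict[str, list[DecayCurve]] = {}
    for (site, nu1p), grp in df.groupby(["site", "nu1_nominal_hz"], sort=True):
        grp = grp.sort_values("duration_s")
        out.setdefault(str(site), []).append(
            DecayCurve(
                str(site),
                float(nu1p),
                grp["duration_s"].to_numpy(),
                grp["intensity"].to_numpy(),
                grp["sigma"].to_numpy(),
            )
        )
    return out


def write_profile(profiles: list[DispersionProfile], path: str | Path) -> None:
    frames = []
    for p in profiles:
        d = p.data.copy()
        d.insert(0, "site", p.site)
        frames.append(d)
    write_table(pd.concat(frames, ignore_index=True), path)


def read_profile(path: str | Path) -> list[DispersionProfile]:
    df = read_table(path, "profile")
    return [
        DispersionProfile(str(site), grp.drop(columns="site").reset_index(drop=True))
        for site, grp in df.groupby("site", sort=True)
    ]


def read_shift_table(path: str | Path) -> pd.DataFrame:
    return read_table(path, "shifts")


def read_star_shifts(path: str | Path) -> pd.DataFrame:
    """NMR-STAR-subset import: whitespace table with residue, atom name,
    shift value columns (Seq_ID / Atom_ID / Val header names accepted)."""
    df = pd.read_csv(path, sep=r"\s+", engine="python")
    rename = {}
    for col in df.columns:
        low = col.lower().strip("_.")
        if low in ("seq_id", "residue", "res"):
            rename[col] = "residue"
        elif low in ("atom_id", "atom"):
            rename[col] = "atom"
        elif low in ("val", "shift", "shift_ppm", "chem_shift_val"):
            rename[col] = "shift_ppm"
    df = df.rename(columns=rename)
    missing = {"residue", "atom", "shift_ppm"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: could not identify column(s) {sorted(missing)}")
    df["residue"] = pd.to_numeric(df["residue"])
    df["shift_ppm"] = pd.to_numeric(df["shift_ppm"])
    return df[["residue", "atom", "shift_ppm"]]


# ---------------------------------------------------------------------------
# configuration


def default_config() -> dict:
    """Printable default spin-system and experiment configuration."""
    return {
        "system": {
            "spins": [
                {"label": "H1", "channel": "I", "isotope": "1H", "xyz": [0.0, 0.0, 1.02]},
                {"label": "H2", "channel": "I", "isotope": "1H",
                 "xyz": [0.9755, 0.0, -0.2982]},
                {"label": "N", "channel": "S", "isotope": "15N", "xyz": [0.0, 0.0, 0.0]},
            ],
            "offsets_hz": [-700.0, 700.0, 0.0],
        },
        "relaxation_s": {"H1": 30.0, "H2": 30.0},
        "experiment": {
            "nu_r_hz": 55560.0,
            "duration_s": 0.030,
            "decoupling_mode": "none",
            "nu1_i_hz": 0.0,
            "n_steps": 100,
            "n_orientations": 100,
        },
    }


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    known = {"system", "relaxation_s", "experiment"}
    unknown = set(cfg) - known
    if unknown:
        raise ValueError(f"unknown config section(s) {sorted(unknown)}; known: {sorted(known)}")
    return cfg


def config_to_system(cfg: dict) -> tuple[SpinSystem, RelaxationSpec, dict]:
    sys_cfg = cfg["system"]
    spins = sys_cfg["spins"]
    system = system_from_coordinates(
        [s["label"] for s in spins],
        [s["channel"] for s in spins],
        [s.get("isotope", "1H") for s in spins],
        [s["xyz"] for s in spins],
        sys_cfg["offsets_hz"],
    )
    relax = RelaxationSpec(dict(cfg.get("relaxation_s", {})))
    return system, relax, cfg.get("experiment", {})


def write_provenance(out_dir: str | Path, subcommand: str, params: dict, seed: int | None) -> Path:
    """Append a machine-parseable key=value provenance record."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log = out_dir / "run.log"
    with open(log, "a") as fh:
        fh.write(f"timestamp={time.strftime('%Y-%m-%dT%H:%M:%S')} ")
        fh.write(f"subcommand={subcommand} ")
        fh.write(f"python={sys.version.split()[0]} numpy={np.__version__} ")
        fh.write(f"seed={seed} ")
        fh.write(" ".join(f"{k}={json.dumps(v)}" for k, v in params.items()))
        fh.write("\n")
    return log
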