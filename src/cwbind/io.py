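"""Table readers/writers and run configuration shared by all stages.

All tabular input is TSV or CSV (delimiter chosen by extension) with an
optional metadata header of ``# key = value`` lines; all numeric output is
written as TSV with units spelled out in the column names so that re-reading
a result table reproduces its values exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .csp import Peak, PeakList
from .relax import DecaySeries
from .thermo import Isotherm, TitrationDesign

__all__ = [
    "read_table",
    "read_metadata",
    "write_table",
    "read_isotherm",
    "read_melt_table",
    "read_peaklist",
    "read_noe_table",
    "read_decay_tables",
    "RunConfig",
    "write_manifest",
]

SCHEMAS = {
    "itc": ["injection_index", "volume_ul", "heat_uJ"],
    "melt_long": ["temperature_C", "wavelength_nm", "intensity"],
    "melt_ratio": ["temperature_C", "ratio_328_352"],
    "peaks": ["id", "dH_ppm", "dN_ppm"],
    "noe": ["id", "I_sat", "I_ref"],
    "decay": ["id", "delay_s", "intensity"],
}


def _delimiter(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_metadata(path) -> dict[str, str]:
    """Parse leading ``# key = value`` header lines."""
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
    return meta


def read_table(path, schema: str) -> pd.DataFrame:
    """Read and validate a stage input table.

    ``schema`` names one of the known column sets; missing columns are
    reported by name, non-numeric cells by row and column.  Lines starting
    with '#' are metadata/comments.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    required = SCHEMAS[schema]
    df = pd.read_csv(path, sep=_delimiter(path), comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    numeric = [c for c in required if c != "id"]
    for col in numeric:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric value in column '{col}', row {bad[0]}"
            )
        if converted.isna().any():
            raise ValueError(f"{path}: empty cell in column '{col}'")
        df[col] = converted
    return df


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_isotherm(path, config: dict | None = None) -> Isotherm:
    """Read an ITC heat table; experiment metadata comes from '#' header
    lines or an explicit config dict (config wins)."""
    meta = read_metadata(path)
    if config:
        meta.update({k: str(v) for k, v in config.items()})
    needed = ["V0_ul", "cell_conc_uM", "syringe_conc_uM"]
    missing = [k for k in needed if k not in meta]
    if missing:
        raise ValueError(f"{path}: missing experiment metadata {missing}")
    df = read_table(path, "itc").sort_values("injection_index")
    design = TitrationDesign(
        V0=float(meta["V0_ul"]) * 1e-6,
        M0=float(meta["cell_conc_uM"]) * 1e-6,
        X0=float(meta["syringe_conc_uM"]) * 1e-6,
        inj_volumes=tuple(df["volume_ul"] * 1e-6),
        T=float(meta.get("temperature_C", 25.0)) + 273.15,
    )
    return Isotherm(design=design, heats=tuple(df["heat_uJ"]))


def read_melt_table(path) -> pd.DataFrame:
    """Read melting data in either long-spectral or precomputed-ratio form;
    a 'kind' attribute records which."""
    path = Path(path)
    head = pd.read_csv(path, sep=_delimiter(path), comment="#", nrows=0)
    kind = "melt_long" if "wavelength_nm" in head.columns else "melt_ratio"
    df = read_table(path, kind)
    df.attrs["kind"] = kind
    return df


def read_peaklist(path, assigned: bool = True) -> PeakList:
    df = read_table(path, "peaks")
    return PeakList(
        tuple(
            Peak(
                id=int(r.id) if str(r.id).lstrip("-").isdigit() else str(r.id),
                dH=float(r.dH_ppm),
                dN=float(r.dN_ppm),
                assigned=assigned,
            )
            for r in df.itertuples()
        )
    )


def read_noe_table(path) -> pd.DataFrame:
    df = read_table(path, "noe")
    for col in ("sigma_sat", "sigma_ref"):
        if col not in df.columns:
            df[col] = 0.0
    return df


def read_decay_tables(path) -> list[DecaySeries]:
    """Long-format (id, delay_s, intensity) table -> one series per id."""
    df = read_table(path, "decay")
    out = []
    for rid, grp in df.groupby("id", sort=False):
        grp = grp.sort_values("delay_s")
        out.append(
            DecaySeries(
                id=rid, delays=tuple(grp["delay_s"]), intensities=tuple(grp["intensity"])
            )
        )
    return out


_KNOWN_KEYS = {
    "stage", "inputs", "params", "out_dir", "log_level", "seed",
}


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline stage run."""

    stage: str
    inputs: dict[str, str] = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    out_dir: str = "."
    log_level: str = "INFO"
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(config: RunConfig, outputs: list[str]) -> str:
    """Write a JSON manifest echoing the resolved config, package version,
    input checksums and outputs; returns the manifest path."""
    manifest = {
        "package": "cwbind",
        "version": __version__,
        "stage": config.stage,
        "seed": config.seed,
        "params": config.params,
        "inputs": {
            name: {"path": p, "sha256": _sha256(p) if Path(p).exists() else None}
            for name, p in config.inputs.items()
        },
        "outputs": outputs,
    }
    out = Path(config.out_dir) / f"{config.stage}_manifest.json"
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return str(out)
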