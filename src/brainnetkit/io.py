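"""File formats, configuration, and run manifests.

All artifacts are plain delimited text or JSON: GMV cohorts as one CSV with
header ``subject,group,age,sex,<region labels...>``; per-subject time series
as TSV (rows = volumes, columns = region labels); atlases as JSON with a
region-label list (order defines matrix axes) and optional MNI coordinates;
configuration as TOML.  Every output directory gets a manifest recording
each file with the config hash and seed so runs are regenerable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Atlas",
    "ConfigError",
    "DataError",
    "read_gmv_table",
    "write_gmv_table",
    "read_timeseries_dir",
    "write_timeseries",
    "read_atlas",
    "write_atlas",
    "load_config",
    "write_results",
]

log = logging.getLogger("brainnetkit")


class ConfigError(ValueError):
    """Invalid or missing configuration (exit code 2 at the CLI)."""


class DataError(ValueError):
    """Malformed input data (exit code 3 at the CLI)."""


@dataclass
class Atlas:
    labels: list[str]
    coordinates: list[tuple[float, float, float]] | None = None

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise DataError("atlas labels must be unique")
        if self.coordinates is not None and len(self.coordinates) != len(self.labels):
            raise DataError("atlas coordinates must match labels")

    def __len__(self) -> int:
        return len(self.labels)


def read_atlas(path) -> Atlas:
    with open(path) as f:
        obj = json.load(f)
    coords = obj.get("coordinates")
    if coords is not None:
        coords = [tuple(c) for c in coords]
    return Atlas(labels=list(obj["labels"]), coordinates=coords)


def write_atlas(atlas: Atlas, path) -> None:
    obj = {"labels": atlas.labels}
    if atlas.coordinates is not None:
        obj["coordinates"] = [list(c) for c in atlas.coordinates]
    Path(path).write_text(json.dumps(obj, indent=1))


META_COLUMNS = ["subject", "group", "age", "sex"]


def read_gmv_table(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except Exception as e:  # pragma: no cover - pandas error text varies
        raise DataError(f"cannot parse GMV table {path}: {e}") from e
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"GMV table {path} missing column(s) {missing}")
    regions = [c for c in df.columns if c not in META_COLUMNS]
    bad = df[regions].isna()
    if bad.to_numpy().any():
        row = int(np.nonzero(bad.to_numpy().any(axis=1))[0][0])
        raise DataError(f"GMV table {path}: missing/non-numeric value at data row {row + 1}")
    if not all(np.issubdtype(df[c].dtype, np.number) for c in regions):
        raise DataError(f"GMV table {path}: non-numeric region column")
    return df


def write_gmv_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_timeseries_dir(path, atlas: Atlas | None = None) -> dict[str, pd.DataFrame]:
    """Read every ``*.tsv`` in a directory as one subject's volumes x regions."""
    path = Path(path)
    out = {}
    for f in sorted(path.glob("*.tsv")):
        try:
            df = pd.read_csv(f, sep="\t")
        except Exception as e:
            raise DataError(f"cannot parse time series {f}: {e}") from e
        if atlas is not None:
            if list(df.columns) != atlas.labels:
                raise DataError(
                    f"{f}: columns ({len(df.columns)}) do not match atlas labels "
                    f"({len(atlas.labels)})"
                )
        if df.isna().to_numpy().any():
            row = int(np.nonzero(df.isna().to_numpy().any(axis=1))[0][0])
            raise DataError(f"{f}: missing/non-numeric value at data row {row + 1}")
        out[f.stem] = df
    if not out:
        raise DataError(f"no .tsv time-series files found in {path}")
    return out


def write_timeseries(series: dict[str, pd.DataFrame], outdir) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, df in series.items():
        p = outdir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

KNOWN_KEYS = {
    "paths": {"gmv_table", "timeseries_dir", "atlas", "output_dir"},
    "scn": {"sparsity_min", "sparsity_max", "sparsity_step", "n_perm", "n_random", "seed"},
    "ml": {"window", "step", "omegas", "gammas", "n_repeats", "seed"},
    "dcm": {"band", "prior_sd", "n_restarts", "seed", "segment_length"},
    "stats": {"fdr_q", "pooled"},
    "sim": {
        "n_group1", "n_group2", "n_regions", "n_subjects", "n_volumes",
        "tr_seconds", "noise_sd", "within_module_corr", "n_modules",
        "switch_nodes", "n_switches", "perturbed_regions", "perturbation_scale",
        "age_beta", "sex_beta",
    },
    "": {"seed", "log_level"},
}


def load_config(path) -> dict:
    """Parse a TOML run config, failing fast on unknown keys."""
    try:
        with open(path, "rb") as f:
            cfg = tomllib.load(f)
    except tomllib.TOMLDecodeError as e:
        raise ConfigError(f"invalid TOML in {path}: {e}") from e
    for section, val in cfg.items():
        if isinstance(val, dict):
            if section not in KNOWN_KEYS:
                raise ConfigError(f"unknown config section [{section}]")
            unknown = set(val) - KNOWN_KEYS[section]
            if unknown:
                raise ConfigError(f"unknown key(s) {sorted(unknown)} in section [{section}]")
        else:
            if section not in KNOWN_KEYS[""]:
                raise ConfigError(f"unknown top-level key '{section}'")
    return cfg


def require(cfg: dict, section: str, key: str):
    try:
        return cfg[section][key]
    except KeyError:
        raise ConfigError(f"missing required config key '{section}.{key}'") from None


# ---------------------------------------------------------------------------
# Results and manifests
# ---------------------------------------------------------------------------

def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def config_hash(cfg: dict, seed: int | None = None) -> str:
    payload = json.dumps({"config": cfg, "seed": seed}, sort_keys=True, default=_json_default)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_results(outdir, artifacts: dict, config: dict | None = None,
                  seed: int | None = None) -> Path:
    """Write artifacts (DataFrame -> CSV, ndarray -> CSV, dict/list -> JSON)
    and a manifest listing every file with the config hash and seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for name, obj in artifacts.items():
        if isinstance(obj, pd.DataFrame):
            p = outdir / f"{name}.csv"
            obj.to_csv(p, index=False)
        elif isinstance(obj, np.ndarray):
            p = outdir / f"{name}.csv"
            pd.DataFrame(obj).to_csv(p, index=False, header=False)
        else:
            p = outdir / f"{name}.json"
            p.write_text(json.dumps(obj, indent=1, default=_json_default))
        entries.append({"file": p.name, "sha256": hashlib.sha256(p.read_bytes()).hexdigest()})
    manifest = {
        "config_hash": config_hash(config or {}, seed),
        "seed": seed,
        "outputs": entries,
    }
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1))
    log.info("wrote %d artifact(s) to %s", len(entries), outdir)
    return mpath
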