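"""Bundled reference tables and configuration presets.

The package ships the published study inputs as plain-text fixtures:

- ``ct_distances.csv`` — the CT gold-standard distance for each of the nine
  within-plane marker pairs (mm);
- ``system_errors.csv`` — the per-system, per-pair measurement errors (mm)
  in tidy form, with each system's acquisition method;
- ``bead_diameters.csv`` — imaged bead diameters (mm) per system and plane;
- ``circularity.csv`` — Hough circularity metrics per system and marker;
- ``geometries.yaml`` — acquisition-geometry presets per system;
- ``printed_results.json`` — the published summary statistics, used only to
  diff the recomputed values against the printed ones.

Unicode minus signs are normalized to ASCII on ingest.  Every fixture is
checksum-verified against ``checksums.json`` before use.
"""

from __future__ import annotations

import hashlib
import json
from functools import lru_cache
from importlib import resources

import pandas as pd
import yaml

from .phantom import MarkerPair

__all__ = [
    "FixtureError",
    "load_ct_distance_table",
    "load_system_errors",
    "load_bead_diameters",
    "load_circularity",
    "load_geometry_presets",
    "load_printed_results",
]


class FixtureError(RuntimeError):
    pass


def _data_path(name: str):
    return resources.files("radphantom.data").joinpath(name)


@lru_cache(maxsize=1)
def _checksums() -> dict:
    with _data_path("checksums.json").open("r") as fh:
        return json.load(fh)


def _read_verified(name: str) -> str:
    raw = _data_path(name).read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    expected = _checksums().get(name)
    if expected is None:
        raise FixtureError(f"no checksum registered for fixture {name}")
    if digest != expected:
        raise FixtureError(
            f"fixture {name} is corrupted (sha256 {digest} != {expected})"
        )
    return raw.decode("utf-8").replace("−", "-")


def _read_csv(name: str) -> pd.DataFrame:
    from io import StringIO

    return pd.read_csv(StringIO(_read_verified(name)))


def load_ct_distance_table(as_dict: bool = True):
    """CT gold-standard distances; by default a MarkerPair -> mm mapping."""
    df = _read_csv("ct_distances.csv")
    if not as_dict:
        return df
    return {MarkerPair.from_name(r.pair): float(r.distance_mm)
            for r in df.itertuples()}


def load_system_errors() -> pd.DataFrame:
    df = _read_csv("system_errors.csv")
    from .phantom import canonical_pairs

    want = canonical_pairs()
    for system, g in df.groupby("system"):
        present = [MarkerPair.from_name(p) for p in g.pair]
        missing = [p.name for p in want if p not in present]
        if missing:
            raise FixtureError(
                f"error table for {system} is missing pairs {missing}"
            )
    return df


def load_bead_diameters() -> pd.DataFrame:
    return _read_csv("bead_diameters.csv")


def load_circularity() -> pd.DataFrame:
    return _read_csv("circularity.csv")


@lru_cache(maxsize=1)
def load_geometry_presets() -> dict:
    presets = yaml.safe_load(_read_verified("geometries.yaml"))
    for name, p in presets.items():
        p["detector_size"] = tuple(p["detector_size"])
    return presets


@lru_cache(maxsize=1)
def load_printed_results() -> dict:
    return json.loads(_read_verified("printed_results.json"))
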