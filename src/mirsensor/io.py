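"""Readers and writers for event tables, activity tables and configs.

CSV is the canonical interchange format (columns ``ebfp2``, ``mkate2`` and
optionally ``eyfp``, ``lineage_label``); FCS files can be ingested through
a channel-name map when the optional ``fcsparser`` dependency is
installed.  Activity tables are comma- or tab-separated with the header
``mirna_id, cell_line, M, K_m``.  Configs (rate constants, per-channel
calibration, designs, cell-line profiles) are YAML or JSON.

Every table written here starts with ``#``-prefixed provenance comments
(package version, config hash, seed) and is read back with those lines
ignored.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .fit import validate_events
from .model import Calibration, MiRNAActivity, RateConstants
from .simulate import CellLineProfile, DesignInput, SensorDesign

RATE_KEYS = ("k_trs", "k_tln_ebfp2", "k_tln_mkate2",
             "delta_m", "delta_p", "k_cat")
ACTIVITY_COLUMNS = ("mirna_id", "cell_line", "M", "K_m")


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_header(**meta) -> str:
    lines = [f"# mirsensor {__version__}"]
    lines += [f"# {k}: {v}" for k, v in meta.items()]
    return "\n".join(lines) + "\n"


def write_table(df: pd.DataFrame, path, **meta) -> Path:
    """Write a CSV with a provenance comment header, full precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(provenance_header(**meta))
        df.to_csv(fh, index=False, float_format="%.17g")
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_events(path, fmt: str | None = None,
                channel_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a per-cell event table from CSV or FCS.

    ``channel_map`` renames source channels to the canonical names, e.g.
    ``{"Pacific Blue-A": "ebfp2", "PE-TexasRed-A": "mkate2"}``.  The
    format is inferred from the extension when not given.  A missing
    canonical channel raises a ValueError naming it.
    """
    path = Path(path)
    if fmt is None:
        fmt = "fcs" if path.suffix.lower() == ".fcs" else "csv"
    if fmt == "csv":
        events = read_table(path)
    elif fmt == "fcs":
        try:
            import fcsparser
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "FCS ingestion requires the optional 'fcsparser' package "
                "(pip install mirsensor[fcs]); alternatively export the "
                "events to CSV") from exc
        _, events = fcsparser.parse(str(path), reformat_meta=True)
    else:
        raise ValueError(f"unknown event format {fmt!r}")
    if channel_map:
        events = events.rename(columns=channel_map)
    return validate_events(events)


def write_events(events: pd.DataFrame, path, **meta) -> Path:
    return write_table(events, path, **meta)


def read_activity_table(path) -> list[MiRNAActivity]:
    """Read fitted activities (CSV or TSV with header mirna_id, cell_line,
    M, K_m)."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, comment="#")
    missing = [c for c in ACTIVITY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"activity table is missing columns {missing}")
    return [MiRNAActivity(str(r.mirna_id), str(r.cell_line),
                          M=float(r.M), K_m=float(r.K_m))
            for r in df.itertuples()]


def activities_frame(activities: list[MiRNAActivity]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"mirna_id": a.mirna_id, "cell_line": a.cell_line,
          "M": a.M, "K_m": a.K_m} for a in activities],
        columns=list(ACTIVITY_COLUMNS))


def write_activity_table(activities: list[MiRNAActivity], path,
                         **meta) -> Path:
    return write_table(activities_frame(activities), path, **meta)


def _load_structured(path) -> dict:
    path = Path(path)
    with open(path) as fh:
        if path.suffix.lower() == ".json":
            return json.load(fh)
        return yaml.safe_load(fh)


def read_rates_config(path) -> tuple[RateConstants, dict[str, Calibration]]:
    """Load rate constants and optional per-channel calibration.

    YAML/JSON with the keys ``k_trs, k_tln_ebfp2, k_tln_mkate2, delta_m,
    delta_p, k_cat`` (missing keys fall back to the documented defaults)
    and an optional ``calib`` mapping of channel -> {gain, background}.
    """
    raw = _load_structured(path) or {}
    unknown = set(raw) - set(RATE_KEYS) - {"calib"}
    if unknown:
        raise ValueError(f"unknown keys in rates config: {sorted(unknown)}")
    rates = RateConstants(**{k: float(raw[k]) for k in RATE_KEYS if k in raw})
    calib = {
        ch: Calibration(gain=float(c.get("gain", 1.0)),
                        background=float(c.get("background", 0.0)))
        for ch, c in (raw.get("calib") or {}).items()
    }
    return rates, calib


def read_design(path) -> SensorDesign:
    """Load a sensor design: ``label`` plus ``inputs`` of
    {mirna_id, utr_position}."""
    raw = _load_structured(path) or {}
    inputs = tuple(
        DesignInput(str(i["mirna_id"]),
                    str(i.get("utr_position", "three_prime")))
        for i in raw.get("inputs", ()))
    return SensorDesign(inputs=inputs, label=str(raw.get("label", "sensor")))


def read_profiles(path) -> list[CellLineProfile]:
    """Load cell-line profiles: per line a name, lineage flag, and a list
    of {mirna_id, M, K_m} activities."""
    raw = _load_structured(path) or []
    if isinstance(raw, dict):
        raw = raw.get("profiles", [])
    profiles = []
    for p in raw:
        name = str(p["name"])
        acts = {
            str(a["mirna_id"]): MiRNAActivity(
                str(a["mirna_id"]), name, M=float(a["M"]), K_m=float(a["K_m"]))
            for a in p.get("activities", ())
        }
        profiles.append(CellLineProfile(
            name, acts, lineage_marker_on=bool(p.get("lineage_marker_on",
                                                     False))))
    return profiles
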