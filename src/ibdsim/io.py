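"""Configuration loading, CSV contracts and run manifests."""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd

from ibdsim.engine import CHANNELS, DemandSeries, SERIES_COLUMNS
from ibdsim.errors import ConfigError, SeriesFormatError
from ibdsim.population import AGENT_COLUMNS, MarginalTargetSet

_PACKAGED_REGIONS = ("tokyo", "hokkaido")


def load_population_config(source: str | Path | Mapping) -> MarginalTargetSet:
    """Load a regional marginal-target configuration.

    ``source`` may be a packaged region name (``"tokyo"``, ``"hokkaido"``),
    a path to a JSON file with the same schema, or an already-parsed mapping.
    """
    if isinstance(source, Mapping):
        raw = dict(source)
    else:
        name = str(source)
        if name.lower() in _PACKAGED_REGIONS:
            raw = json.loads(
                resources.files("ibdsim.data").joinpath(f"{name.lower()}.json").read_text()
            )
        else:
            path = Path(name)
            if not path.exists():
                raise ConfigError(f"population config not found: {path}")
            try:
                raw = json.loads(path.read_text())
            except json.JSONDecodeError as exc:
                raise ConfigError(f"population config is not valid JSON: {path}: {exc}") from exc
    missing = [
        k
        for k in ("region", "total_patients", "sex_proportions", "condition_proportions",
                  "age_targets")
        if k not in raw
    ]
    if missing:
        raise ConfigError(f"population config missing keys: {missing}")
    try:
        age_targets = {
            (condition, sex): (entry["mean"], entry["sd"])
            for condition, by_sex in raw["age_targets"].items()
            for sex, entry in by_sex.items()
        }
    except (TypeError, KeyError) as exc:
        raise ConfigError(f"age_targets: malformed entry ({exc})") from exc
    kwargs = {}
    for key in ("severity_proportions", "initial_diagnosed_fraction",
                "initial_biologic_fraction", "care_seeking_propensity"):
        if key in raw:
            kwargs[key] = raw[key]
    return MarginalTargetSet(
        region_name=raw["region"],
        total_patients=raw["total_patients"],
        sex_proportions=raw["sex_proportions"],
        condition_proportions=raw["condition_proportions"],
        age_targets=age_targets,
        age_bounds=tuple(raw.get("age_bounds", (18.0, 74.0))),
        **kwargs,
    )


def write_agents(table: pd.DataFrame, path: str | Path) -> None:
    """Write an agent table to CSV with the canonical column order."""
    table[AGENT_COLUMNS].to_csv(path, index=False)


def read_agents(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in AGENT_COLUMNS if c not in table.columns]
    if missing:
        raise SeriesFormatError(
            f"agent table {path} missing columns {missing}; expected header "
            + ",".join(AGENT_COLUMNS)
        )
    return table[AGENT_COLUMNS]


def write_series(series: DemandSeries, path: str | Path) -> None:
    """Write a demand series to the canonical weekly CSV."""
    frame = series.frame.copy()
    frame["week_start"] = frame["week_start"].dt.strftime("%Y-%m-%d")
    frame[SERIES_COLUMNS].to_csv(path, index=False)


def read_series(path: str | Path, region: str = "") -> DemandSeries:
    """Read a weekly demand-series CSV.

    Columns may appear in any order but every canonical column must be
    present; weeks must be contiguous (7-day steps) — a gap raises a format
    error naming the first missing week.
    """
    frame = pd.read_csv(path)
    missing = [c for c in SERIES_COLUMNS if c not in frame.columns]
    if missing:
        raise SeriesFormatError(
            f"series {path} missing columns {missing}; expected header "
            + ",".join(SERIES_COLUMNS)
        )
    frame = frame[SERIES_COLUMNS]
    frame["week_start"] = pd.to_datetime(frame["week_start"])
    gaps = frame["week_start"].diff().iloc[1:]
    bad = gaps[gaps != pd.Timedelta(days=7)]
    if len(bad):
        first_bad = frame["week_start"].iloc[bad.index[0] - 1] + pd.Timedelta(days=7)
        raise SeriesFormatError(
            f"series {path} has non-contiguous weeks: missing week starting "
            f"{first_bad.date()}"
        )
    if (frame[list(CHANNELS)].to_numpy() < 0).any():
        raise SeriesFormatError(f"series {path} contains negative counts")
    return DemandSeries(frame=frame, region=region)


def write_ensemble(summary, path: str | Path) -> None:
    frame = summary.frame.copy()
    frame["week_start"] = pd.to_datetime(frame["week_start"]).dt.strftime("%Y-%m-%d")
    frame.to_csv(path, index=False)


def config_digest(config: Mapping | str | Path) -> str:
    """Stable sha256 digest of a config mapping or file."""
    if isinstance(config, (str, Path)) and Path(str(config)).exists():
        payload = Path(str(config)).read_bytes()
    else:
        payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()


def make_manifest(
    task: str,
    seed: int,
    configs: Mapping[str, object],
    outputs: list[str],
    extra: Mapping[str, object] | None = None,
) -> dict:
    """Run manifest: config digests, seed, version, timestamps, outputs."""
    from ibdsim import __version__

    manifest = {
        "task": task,
        "seed": seed,
        "version": __version__,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "config_digests": {name: config_digest(cfg) for name, cfg in configs.items()},
        "outputs": outputs,
    }
    if extra:
        manifest.update(extra)
    return manifest


def write_manifest(manifest: Mapping, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
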