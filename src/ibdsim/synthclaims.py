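"""Synthetic weekly claims-aggregate series with known ground truth.

Real calibration data for this kind of model are proprietary claims panels;
this module emulates their aggregate behavior so calibration and end-to-end
tests run self-contained: exponential growth in new diagnoses (stock-flow
consistent totals), utilization channels tied to the patient stock through
periodic visit/procedure/refill intervals, wave-shaped disruption dips with
recovery (optionally a second, attenuated wave), and overdispersed
negative-binomial observation noise typical of claims counts.

The Tokyo and Hokkaido fixture presets differ in scale and in disruption
shape: the regional preset recovers later and more slowly, and its biologic
channel shows a transient stock-up increase before dropping — the
urban-versus-regional contrast in supply-chain behavior.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from ibdsim.engine import CHANNELS, DemandSeries
from ibdsim.errors import ConfigError

#: channels that take an explicit dip depth
DIP_CHANNELS = ("new_patients", "outpatient_visits", "procedures", "biologics")


@dataclass(frozen=True)
class DisruptionProfile:
    """Trapezoidal disruption dip: full depth for ``duration_weeks`` from
    ``onset_week``, then linear recovery over ``recovery_weeks``.  An
    optional second wave repeats the profile scaled by ``second_wave_ratio``
    (in [0, 1]: later waves are less disruptive).  ``biologic_rise`` models a
    transient stock-up increase of the biologic channel during the first
    ``biologic_rise_weeks`` of the disruption before its dip applies."""

    onset_week: int
    depth: Mapping[str, float]
    duration_weeks: int = 8
    recovery_weeks: int = 12
    second_wave_start: int | None = None
    second_wave_ratio: float = 0.4
    biologic_rise: float = 0.0
    biologic_rise_weeks: int = 0

    def __post_init__(self) -> None:
        problems = []
        for ch, d in self.depth.items():
            if ch not in DIP_CHANNELS:
                problems.append(f"depth: unknown channel {ch!r}")
            elif not 0.0 <= d <= 1.0:
                problems.append(f"depth[{ch}]: must lie in [0,1], got {d}")
        if not 0.0 <= self.second_wave_ratio <= 1.0:
            problems.append(f"second_wave_ratio must lie in [0,1], got {self.second_wave_ratio}")
        if self.duration_weeks < 0 or self.recovery_weeks < 0:
            problems.append("duration_weeks and recovery_weeks must be >= 0")
        if problems:
            raise ConfigError("invalid disruption profile: " + "; ".join(problems))

    def dip(self, n_weeks: int, channel: str) -> np.ndarray:
        """Fractional reduction of ``channel`` per week, in [0, 1]."""
        depth = self.depth.get(channel, 0.0)
        out = np.zeros(n_weeks)
        waves = [(self.onset_week, 1.0)]
        if self.second_wave_start is not None:
            waves.append((self.second_wave_start, self.second_wave_ratio))
        for start, scale in waves:
            for k in range(self.duration_weeks + self.recovery_weeks + 1):
                w = start + k
                if not 0 <= w < n_weeks:
                    continue
                if k <= self.duration_weeks:
                    level = 1.0
                else:
                    level = 1.0 - (k - self.duration_weeks) / max(self.recovery_weeks, 1)
                out[w] += depth * scale * level
        return np.clip(out, 0.0, 1.0)

    def biologic_multiplier(self, n_weeks: int) -> np.ndarray:
        """(1 - dip) for the biologic channel, with the transient rise."""
        mult = 1.0 - self.dip(n_weeks, "biologics")
        if self.biologic_rise > 0 and self.biologic_rise_weeks > 0:
            lo = self.onset_week
            hi = min(self.onset_week + self.biologic_rise_weeks, n_weeks)
            mult[lo:hi] = 1.0 + self.biologic_rise
        return mult


@dataclass(frozen=True)
class ClaimsGroundTruth:
    """Ground-truth generative parameters for one synthetic claims series."""

    base_weekly_new_patients: float = 30.0
    annual_growth: float = 1.08
    base_total_patients: float = 6000.0
    visit_interval: float = 10.0
    procedure_interval: float = 44.0
    biologic_interval: float = 8.0
    biologic_share: float = 0.15
    disruption: DisruptionProfile | None = None
    dispersion: float | None = 10.0
    start_date: str = "2015-01-05"
    region: str = "synthetic"

    def __post_init__(self) -> None:
        problems = []
        if self.base_weekly_new_patients < 0:
            problems.append("base_weekly_new_patients must be >= 0")
        if not self.annual_growth > 0:
            problems.append("annual_growth must be > 0")
        for name in ("visit_interval", "procedure_interval", "biologic_interval"):
            if getattr(self, name) < 1:
                problems.append(f"{name} must be >= 1 week")
        if self.dispersion is not None and not self.dispersion > 0:
            problems.append("dispersion must be > 0 (or None for noise-free)")
        if not 0.0 <= self.biologic_share <= 1.0:
            problems.append("biologic_share must lie in [0,1]")
        if problems:
            raise ConfigError("invalid claims ground truth: " + "; ".join(problems))


def mean_curves(truth: ClaimsGroundTruth, n_weeks: int) -> pd.DataFrame:
    """Deterministic weekly mean of every channel.

    new(w)      = B g^(w/52) (1 - dip_new(w))
    total(w)    = T0 + cumulative new mean          (stock-flow consistency)
    visits(w)   = total(w) / visit_interval x (1 - dip_visits)
    procedures, biologics analogously; biologics carry ``biologic_share`` of
    the stock and may transiently rise (regional stock-up pattern).
    """
    if n_weeks < 1:
        raise ConfigError(f"n_weeks must be >= 1, got {n_weeks}")
    w = np.arange(n_weeks)
    growth = truth.annual_growth ** (w / 52.0)
    if truth.disruption is not None:
        dip = {ch: truth.disruption.dip(n_weeks, ch) for ch in DIP_CHANNELS}
        bio_mult = truth.disruption.biologic_multiplier(n_weeks)
    else:
        dip = {ch: np.zeros(n_weeks) for ch in DIP_CHANNELS}
        bio_mult = np.ones(n_weeks)
    new = truth.base_weekly_new_patients * growth * (1.0 - dip["new_patients"])
    total = truth.base_total_patients + np.concatenate([[0.0], np.cumsum(new)[:-1]])
    visits = total / truth.visit_interval * (1.0 - dip["outpatient_visits"])
    procedures = total / truth.procedure_interval * (1.0 - dip["procedures"])
    biologics = truth.biologic_share * total / truth.biologic_interval * bio_mult
    starts = truth.biologic_share * new
    return pd.DataFrame(
        {
            "new_patients": new,
            "total_patients": total,
            "outpatient_visits": visits,
            "procedures": procedures,
            "biologics": biologics,
            "vedolizumab_infusions": biologics,
            "new_vedolizumab_starts": starts,
        }
    )


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, k: float) -> np.ndarray:
    out = np.zeros_like(mean)
    pos = mean > 0
    p = k / (k + mean[pos])
    out[pos] = rng.negative_binomial(k, p)
    return out


def generate_claims_series(
    truth: ClaimsGroundTruth, n_weeks: int, seed: int
) -> DemandSeries:
    """Sample one synthetic claims series; deterministic in (truth, seed).

    Flow channels get independent negative-binomial noise around their mean
    curves (variance mean + mean^2/dispersion); the patient-stock channel is
    accumulated from the sampled new-patient flow so the series stays
    stock-flow consistent, as a claims panel would be.
    """
    means = mean_curves(truth, n_weeks)
    if truth.dispersion is None:
        frame = means.copy()
    else:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC1A1]))
        k = float(truth.dispersion)
        frame = means.copy()
        for ch in ("new_patients", "outpatient_visits", "procedures", "biologics",
                   "new_vedolizumab_starts"):
            frame[ch] = _nb_sample(rng, means[ch].to_numpy(), k)
        frame["vedolizumab_infusions"] = frame["biologics"]
        new = frame["new_patients"].to_numpy()
        frame["total_patients"] = truth.base_total_patients + np.concatenate(
            [[0.0], np.cumsum(new)[:-1]]
        )
    frame = frame[list(CHANNELS)]
    frame.insert(0, "week_start", pd.date_range(truth.start_date, periods=n_weeks, freq="7D"))
    return DemandSeries(frame=frame, region=truth.region)


def _truth_from_dict(cfg: dict) -> ClaimsGroundTruth:
    dis = cfg.pop("disruption", None)
    disruption = DisruptionProfile(**dis) if dis is not None else None
    return ClaimsGroundTruth(disruption=disruption, **cfg)


def load_fixture(name: str) -> ClaimsGroundTruth:
    """Load a packaged fixture preset (``"tokyo"`` or ``"hokkaido"``)."""
    path = resources.files("ibdsim.data").joinpath(f"{name}_fixture.json")
    try:
        raw = json.loads(path.read_text())
    except FileNotFoundError as exc:
        raise ConfigError(f"unknown synthclaims fixture {name!r}") from exc
    return _truth_from_dict(raw)
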