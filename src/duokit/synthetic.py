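"""Synthetic dopaminergic-ultradian-oscillator (DUO) cohorts.

The generator emulates the dual-oscillator picture of rodent locomotor
control: an ultradian arousal oscillator whose period scales with dopamine
tone, gated (or not) by a circadian process, with the two outputs integrated
at a common downstream effector into the observed activity pattern.

The activity intensity is

    lambda(t) = peak_rate * G(t) * max(0, cos(2*pi*phi_u(t)))**p

where ``phi_u`` is the ultradian phase, advancing with per-cycle periods
drawn Normal(tau(tone), cycle_jitter_sd) — cycle-to-cycle *phase* jitter, the
kind of intra-animal period variability wavelet ridge statistics are meant to
recover.  The period law is linear in dopamine tone,

    tau(tone) = tau0 + k * (tone - 1),

calibrated so that tripling the tone (the dopamine-transporter-knockout
regime) triples a 4-hr baseline period.  ``G`` is the circadian gate: unity
everywhere (arrhythmic, lesioned or clockless animals), or attenuated to
``gate_depth`` during the light phase (masking in an LD cycle) or during a
fixed subjective-rest half of the 24-hr day (intact endogenous clock).
Counts per bin are Poisson around ``lambda * dt``.

A coupled dialysate profile samples dopamine at 20-min intervals:

    DA(t) = mean_da * (1 + rel_amplitude * cos(2*pi*phi_u(t) + phase_offset)) + noise,

phase-locked to the same ultradian oscillator, so activity bouts and dopamine
peaks coincide at zero offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ParameterError, SizeError, WindowError
from .timeseries import AnimalRecord, DialysateProfile, LightingSchedule, UniformSeries

__all__ = [
    "DuoConfig",
    "DaCouplingConfig",
    "ActivityTruth",
    "Cohort",
    "simulate_activity",
    "simulate_da_profile",
    "simulate_cohort",
    "dose_to_tone",
    "PRESETS",
    "preset_config",
]


@dataclass
class DuoConfig:
    """Parameters of one simulated animal.

    tau0 : baseline ultradian period at tone 1 (hours).
    tone : dimensionless dopamine tone (1 = control).
    period_slope : hours of period gained per unit tone above 1.
    circadian_gate : 'none', 'ld_mask' or 'endogenous_24h'.
    gate_depth : fraction of activity permitted in the light/rest phase.
    bout_shape : exponent of the rectified cosine bout envelope (larger =
        narrower bouts).
    mean_rate : expected counts per 0.1-hr bin at a bout peak.
    cycle_jitter_sd : SD of per-cycle period (hours).
    phase0 : initial ultradian phase in cycles; the default 0.5 centers the
        first bout peak half a period into the record.
    """

    tau0: float = 4.0
    tone: float = 1.0
    period_slope: float = 4.0
    circadian_gate: str = "none"
    gate_depth: float = 0.1
    bout_shape: float = 2.0
    mean_rate: float = 50.0
    cycle_jitter_sd: float = 0.2
    phase0: float = 0.5
    duration: float = 168.0
    dt: float = 0.1
    seed: int | None = None
    lights_on: float = 0.0
    photoperiod: float = 12.0

    def __post_init__(self) -> None:
        if self.circadian_gate not in ("none", "ld_mask", "endogenous_24h"):
            raise ParameterError(f"unknown circadian gate {self.circadian_gate!r}")
        if not 0 <= self.gate_depth <= 1:
            raise ParameterError("gate_depth must lie in [0, 1]")
        if self.mean_rate < 0:
            raise ParameterError("mean_rate must be non-negative")
        if self.tau() <= 2 * self.dt:
            raise ParameterError("tau(tone) must exceed twice the bin width")
        if self.cycle_jitter_sd < 0:
            raise ParameterError("cycle_jitter_sd must be non-negative")

    def tau(self) -> float:
        """Ultradian period implied by the tone: tau0 + k*(tone - 1)."""
        return self.tau0 + self.period_slope * (self.tone - 1.0)


@dataclass
class DaCouplingConfig:
    """Parameters of the dialysate dopamine trace coupled to the activity phase."""

    mean_da: float = 2.0  # nM
    rel_amplitude: float = 0.3
    phase_offset: float = 0.0  # radians
    noise_sd: float = 0.2  # nM
    interval: float = 1.0 / 3.0  # hours: one sample per 20 min
    n_samples: int = 12  # 4 hr of sampling

    def __post_init__(self) -> None:
        if self.mean_da <= 0:
            raise ParameterError("mean_da must be positive")
        if not 0 <= self.rel_amplitude < 1:
            raise ParameterError("rel_amplitude must lie in [0, 1)")
        if self.n_samples < 4:
            raise ParameterError("need at least 4 dialysate samples")


@dataclass
class ActivityTruth:
    """Ground truth of one simulated animal: cycle structure and phase map."""

    config: DuoConfig
    cycle_starts: np.ndarray  # hours; knots where phase passes integer+phase0
    cycle_periods: np.ndarray  # realized per-cycle periods (hours)

    def phase(self, t: np.ndarray | float) -> np.ndarray:
        """Ultradian phase (cycles, unwrapped) at arbitrary times."""
        knots_t = np.concatenate([[self.cycle_starts[0]], self.cycle_starts[0] + np.cumsum(self.cycle_periods)])
        knots_phi = self.config.phase0 + np.arange(knots_t.size, dtype=float)
        return np.interp(np.asarray(t, dtype=float), knots_t, knots_phi)

    @property
    def tau_nominal(self) -> float:
        return self.config.tau()

    @property
    def tone(self) -> float:
        return self.config.tone


def _gate(cfg: DuoConfig, t: np.ndarray) -> np.ndarray:
    if cfg.circadian_gate == "none":
        return np.ones_like(t)
    if cfg.circadian_gate == "ld_mask":
        light = ((t - cfg.lights_on) % 24.0) < cfg.photoperiod
        return np.where(light, cfg.gate_depth, 1.0)
    # endogenous clock: rest during the first half of each subjective day
    rest = (t % 24.0) < 12.0
    return np.where(rest, cfg.gate_depth, 1.0)


def simulate_activity(cfg: DuoConfig) -> tuple[AnimalRecord, ActivityTruth]:
    """Simulate one animal's binned activity counts plus its ground truth."""
    rng = np.random.default_rng(cfg.seed)
    tau = cfg.tau()
    # realized per-cycle periods; truncated well away from zero
    n_cycles = int(np.ceil(cfg.duration / max(tau - 5 * cfg.cycle_jitter_sd, 1e-3))) + 3
    periods = rng.normal(tau, cfg.cycle_jitter_sd, size=n_cycles)
    periods = np.clip(periods, tau / 4, None)
    while np.sum(periods) < cfg.duration + tau:
        extra = np.clip(rng.normal(tau, cfg.cycle_jitter_sd, size=8), tau / 4, None)
        periods = np.concatenate([periods, extra])
    truth = ActivityTruth(config=cfg, cycle_starts=np.array([0.0]), cycle_periods=periods)

    n_bins = int(np.rint(cfg.duration / cfg.dt))
    t_mid = (np.arange(n_bins) + 0.5) * cfg.dt
    phi = truth.phase(t_mid)
    envelope = np.maximum(0.0, np.cos(2 * np.pi * phi)) ** cfg.bout_shape
    lam = (cfg.mean_rate / 0.1) * _gate(cfg, t_mid) * envelope  # counts per hour
    counts = rng.poisson(lam * cfg.dt).astype(float)
    series = UniformSeries(t0=0.0, dt=cfg.dt, values=counts, kind="activity")
    regime = "LD" if cfg.circadian_gate == "ld_mask" else "DD"
    lighting = LightingSchedule(regime=regime, lights_on=cfg.lights_on, photoperiod=cfg.photoperiod)
    record = AnimalRecord(
        animal_id=f"sim-{cfg.seed}", genotype_tag=_genotype_tag(cfg), activity=series, lighting=lighting
    )
    return record, truth


def _genotype_tag(cfg: DuoConfig) -> str:
    gate = {"none": "arrhythmic", "ld_mask": "LD-masked", "endogenous_24h": "clock-intact"}[
        cfg.circadian_gate
    ]
    return f"{gate}, tone={cfg.tone:g}"


def simulate_da_profile(
    truth: ActivityTruth,
    cfg: DaCouplingConfig | None = None,
    start_time: float = 0.0,
    seed: int | None = None,
) -> DialysateProfile:
    """Dialysate dopamine trace phase-locked to the activity oscillator."""
    cfg = cfg or DaCouplingConfig()
    times = start_time + (np.arange(cfg.n_samples) + 0.5) * cfg.interval
    span_end = truth.cycle_starts[0] + np.sum(truth.cycle_periods)
    if times[0] < truth.cycle_starts[0] - 1e-9 or times[-1] > span_end + 1e-9:
        raise WindowError("dialysate window outside the simulated span")
    rng = np.random.default_rng(seed)
    phi = truth.phase(times)
    da = cfg.mean_da * (1.0 + cfg.rel_amplitude * np.cos(2 * np.pi * phi + cfg.phase_offset))
    da = da + rng.normal(0.0, cfg.noise_sd, size=times.size)
    da = np.clip(da, 0.0, None)
    return DialysateProfile(sample_times=times, concentrations=da, interval=cfg.interval)


@dataclass
class Cohort:
    """A simulated cohort: per-animal records, dialysate profiles and truth table."""

    records: list[AnimalRecord]
    truths: list[ActivityTruth]
    profiles: list[DialysateProfile]
    table: pd.DataFrame  # animal_id, tone, tau_true, mean_da


def simulate_cohort(
    n_animals: int,
    tone_range: tuple[float, float] = (1.0, 3.0),
    base_cfg: DuoConfig | None = None,
    da_cfg: DaCouplingConfig | None = None,
    da_per_tone: float = 2.0,
    seed: int | None = None,
) -> Cohort:
    """Simulate a cohort with tones drawn uniformly and dopamine ~ tone.

    Each animal's mean dialysate dopamine is ``da_per_tone * tone`` (nM), so
    the generative period-vs-dopamine slope is ``period_slope / da_per_tone``
    hours per nM.
    """
    if n_animals < 3:
        raise SizeError("need at least 3 animals for a cohort")
    base_cfg = base_cfg or DuoConfig()
    da_cfg = da_cfg or DaCouplingConfig()
    rng = np.random.default_rng(seed)
    tones = rng.uniform(tone_range[0], tone_range[1], size=n_animals)
    records, truths, profiles, rows = [], [], [], []
    for i, tone in enumerate(tones):
        a_seed = int(rng.integers(0, 2**31 - 1))
        d_seed = int(rng.integers(0, 2**31 - 1))
        # free-running animals: dialysate sampling starts at an arbitrary
        # oscillator phase, so each animal gets a random initial phase
        phase0 = float(rng.uniform(0.0, 1.0))
        cfg = replace(base_cfg, tone=float(tone), seed=a_seed, phase0=phase0)
        rec, truth = simulate_activity(cfg)
        rec.animal_id = f"animal-{i:02d}"
        dac = replace(da_cfg, mean_da=da_per_tone * float(tone))
        prof = simulate_da_profile(truth, dac, start_time=0.0, seed=d_seed)
        records.append(rec)
        truths.append(truth)
        profiles.append(prof)
        rows.append(
            {
                "animal_id": rec.animal_id,
                "tone": float(tone),
                "tau_true": cfg.tau(),
                "mean_da": dac.mean_da,
            }
        )
    return Cohort(records=records, truths=truths, profiles=profiles, table=pd.DataFrame(rows))


def dose_to_tone(drug: str, dose: float) -> float:
    """Map a drug dose to a dopamine-tone multiplier (monotone, 1 at dose 0).

    Methamphetamine and amphetamine block dopamine reuptake and raise tone
    (meth with the larger gain; 100 mg/l drinking water maps to tone 3);
    haloperidol, a D2 antagonist, lowers effective tone toward a floor.
    Doses in mg/l (stimulants, drinking water) or mg/day (haloperidol).
    """
    if dose < 0:
        raise ParameterError("dose must be non-negative")
    if drug in ("meth", "methamphetamine"):
        return 1.0 + 0.02 * dose
    if drug == "amphetamine":
        return 1.0 + 0.01 * dose
    if drug in ("haloperidol", "hal"):
        floor = 0.4
        return floor + (1.0 - floor) * float(np.exp(-dose / 2.0))
    raise ParameterError(f"unknown drug {drug!r}")


PRESETS: dict[str, dict] = {
    # SCN-lesioned wildtype: no circadian gate, control tone -> ~4-hr rhythm
    "scnx-wt": dict(circadian_gate="none", tone=1.0),
    # SCN-lesioned DAT knockout: tripled tone -> ~12-hr rhythm
    "scnx-datko": dict(circadian_gate="none", tone=3.0),
    # clock-gene knockout in constant dark: behaves like the lesioned control
    "bmal1ko": dict(circadian_gate="none", tone=1.0),
    # intact animal in LD: light masks activity, 3 bouts per night
    "intact-wt": dict(circadian_gate="ld_mask", tone=1.0, cycle_jitter_sd=0.0),
    "intact-datko": dict(circadian_gate="ld_mask", tone=3.0, cycle_jitter_sd=0.0),
}


def preset_config(name: str, days: float = 7.0, seed: int | None = None, **overrides) -> DuoConfig:
    """DuoConfig for a named animal preset."""
    if name not in PRESETS:
        raise ParameterError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    kw = dict(PRESETS[name])
    kw.update(overrides)
    return DuoConfig(duration=days * 24.0, seed=seed, **kw)
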