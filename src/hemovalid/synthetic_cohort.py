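"""Synthetic cohorts with the protocol structure of a controlled hemorrhagic-shock study.

The generator emulates an experiment in which instrumented swine are observed
through three phases — a ~30-min baseline ("pre_bleeding"), a controlled
withdrawal of 35% of blood volume over 20-60 min ("bleeding", rate-limited so
mean arterial pressure never falls below a floor), and an untreated follow-up
of up to 7 h ("post_bleeding") — while four hemodynamic variables (SBP, DBP,
HR, CO) are recorded simultaneously by an invasive reference and a
non-invasive test device. Sampling is every 5 min through the end of bleeding
and every 20 min afterwards.

Reference trajectories are latent per-animal paths: a random animal level
around the phase target mean, a smooth eased decline during bleeding to a
trough solved so the phase time-average matches the configured bleeding mean
(rapid withdrawal over the first part of the phase, then a hold, emulating
bleeding paused to respect the MAP floor), and a drift toward the follow-up
target afterwards (heart rate rising, pressures and cardiac output staying
depressed). DBP is generated jointly with SBP (phase-specific fraction of SBP
plus independent variation) so that MAP = (SBP + 2*DBP)/3 is well defined and
can be floored. The device channel adds a proportional slope, a per-animal
calibration offset drawn once at baseline (the device is offset-calibrated a
single time against the reference), and AR(1) observation noise. Optional
spike artifacts, per-animal dropout (early death during follow-up) and
thinning of cardiac-output observations reproduce the blemishes of the real
data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .data_model import Dataset, PHASES, VARIABLES, BP_VARIABLES

__all__ = [
    "PhaseSpec",
    "DeviceErrorModel",
    "SimConfig",
    "simulate_experiment",
    "make_fixture",
    "FIXTURE_NAMES",
]


class ConfigError(ValueError):
    """A simulation configuration violates its invariants."""


def _check_prob(name: str, p: float) -> None:
    if not (0.0 <= p <= 1.0):
        raise ConfigError(f"{name} must be in [0, 1], got {p}")


@dataclass
class PhaseSpec:
    """Targets for one protocol phase.

    ``duration_min`` is the (lo, hi) range from which each animal's phase
    duration is drawn (uniform, rounded to the sampling cadence);
    ``level_mean``/``level_sd`` give the phase target mean and marginal SD of
    the invasive reference channel per variable, in that variable's units.
    """

    name: str
    duration_min: tuple[float, float]
    cadence_min: float
    level_mean: dict[str, float]
    level_sd: dict[str, float]

    def validate(self) -> None:
        if self.name not in PHASES:
            raise ConfigError(f"unknown phase name {self.name!r}")
        lo, hi = self.duration_min
        if not (0 < lo <= hi):
            raise ConfigError(f"{self.name}: duration range must be positive, got {self.duration_min}")
        if self.cadence_min <= 0:
            raise ConfigError(f"{self.name}: cadence_min must be > 0")
        for v in VARIABLES:
            if v not in self.level_mean or v not in self.level_sd:
                raise ConfigError(f"{self.name}: level_mean/level_sd missing variable {v}")
            if self.level_mean[v] <= 0:
                raise ConfigError(f"{self.name}: level_mean[{v}] must be > 0")
            if self.level_sd[v] < 0:
                raise ConfigError(f"{self.name}: level_sd[{v}] must be >= 0")


@dataclass
class DeviceErrorModel:
    """Error structure of the device channel.

    device = reference * (1 + proportional_bias) + offset_a + e_t, where
    offset_a ~ N(0, calibration_offset_sd[var]) is drawn once per animal
    (one-time baseline calibration offset) and e_t is stationary AR(1) noise
    with marginal SD noise_sd[var] and lag-1 autocorrelation ar1_rho.
    """

    calibration_offset_sd: dict[str, float] = field(
        default_factory=lambda: {"SBP": 4.0, "DBP": 4.0, "HR": 2.0, "CO": 0.4}
    )
    proportional_bias: float = 0.0
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {"SBP": 5.0, "DBP": 5.0, "HR": 3.0, "CO": 0.35}
    )
    ar1_rho: float = 0.3

    def validate(self) -> None:
        for v in VARIABLES:
            if v not in self.noise_sd or v not in self.calibration_offset_sd:
                raise ConfigError(f"device error model missing variable {v}")
            if self.noise_sd[v] < 0:
                raise ConfigError(f"noise_sd[{v}] must be >= 0")
            if self.calibration_offset_sd[v] < 0:
                raise ConfigError(f"calibration_offset_sd[{v}] must be >= 0")
        if not (0.0 <= self.ar1_rho < 1.0):
            raise ConfigError(f"ar1_rho must be in [0, 1), got {self.ar1_rho}")


def _default_phases() -> list[PhaseSpec]:
    return [
        PhaseSpec(
            name="pre_bleeding",
            duration_min=(25.0, 35.0),
            cadence_min=5.0,
            level_mean={"SBP": 79.0, "DBP": 57.0, "HR": 96.0, "CO": 3.8},
            level_sd={"SBP": 14.0, "DBP": 18.0, "HR": 20.0, "CO": 1.0},
        ),
        PhaseSpec(
            name="bleeding",
            duration_min=(20.0, 60.0),
            cadence_min=5.0,
            level_mean={"SBP": 51.0, "DBP": 32.0, "HR": 99.0, "CO": 2.4},
            level_sd={"SBP": 20.0, "DBP": 12.0, "HR": 20.0, "CO": 1.1},
        ),
        PhaseSpec(
            name="post_bleeding",
            duration_min=(420.0, 420.0),
            cadence_min=20.0,
            level_mean={"SBP": 58.0, "DBP": 30.0, "HR": 125.0, "CO": 2.2},
            level_sd={"SBP": 12.0, "DBP": 18.0, "HR": 25.0, "CO": 0.5},
        ),
    ]


@dataclass
class SimConfig:
    """Full parameterization of a synthetic cohort.

    Defaults encode the study conditions: 11 animals; baseline ~30 min at
    5-min cadence; bleeding 20-60 min at 5-min cadence with a 30 mmHg MAP
    floor; follow-up 7 h at 20-min cadence; phase means/SDs of the invasive
    channel per variable; ~18% chance an animal dies early during follow-up;
    ~18% of cardiac-output observations missing during and after bleeding;
    rare +50% spike artifacts.
    """

    n_animals: int = 11
    phases: list[PhaseSpec] = field(default_factory=_default_phases)
    device: DeviceErrorModel = field(default_factory=DeviceErrorModel)
    dropout_prob: float = 0.18
    co_missing_prob: float = 0.18
    spike_prob: float = 0.004
    spike_magnitude: float = 0.5
    map_floor: float = 30.0
    seed: int = 0

    # structural constants of the latent-path model (not study parameters):
    # share of marginal variance assigned to the persistent animal level,
    # lag-1 autocorrelation of the smooth within-phase path, and the phase
    # fraction over which the bleeding decline / post-bleeding drift occurs.
    BETWEEN_ANIMAL_FRAC = 0.5
    PATH_RHO = 0.6
    BLEED_RAMP_FRAC = 0.4
    POST_RAMP_FRAC = 0.3

    # physiological floors applied to reference values (units of each variable)
    REF_FLOOR = {"SBP": 15.0, "DBP": 5.0, "HR": 25.0, "CO": 0.3}

    def validate(self) -> None:
        if self.n_animals < 1:
            raise ConfigError(f"n_animals must be >= 1, got {self.n_animals}")
        if len(self.phases) != 3 or [p.name for p in self.phases] != list(PHASES):
            raise ConfigError(f"phases must be the three protocol phases in order {PHASES}")
        for p in self.phases:
            p.validate()
        self.device.validate()
        for name in ("dropout_prob", "co_missing_prob", "spike_prob"):
            _check_prob(name, getattr(self, name))
        if self.spike_magnitude < 0:
            raise ConfigError("spike_magnitude must be >= 0")
        if self.map_floor <= 0:
            raise ConfigError("map_floor must be > 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        if "phases" in d:
            d["phases"] = [
                PhaseSpec(
                    name=p["name"],
                    duration_min=tuple(p["duration_min"]),
                    cadence_min=p["cadence_min"],
                    level_mean=dict(p["level_mean"]),
                    level_sd=dict(p["level_sd"]),
                )
                for p in d["phases"]
            ]
        if "device" in d:
            d["device"] = DeviceErrorModel(**d["device"])
        cfg = cls(**d)
        cfg.validate()
        return cfg


def _ar1(rng: np.random.Generator, n: int, rho: float) -> np.ndarray:
    """Stationary AR(1) sequence with unit marginal variance."""
    z = rng.standard_normal(n)
    u = np.empty(n)
    if n == 0:
        return u
    u[0] = z[0]
    c = math.sqrt(1.0 - rho * rho)
    for t in range(1, n):
        u[t] = rho * u[t - 1] + c * z[t]
    return u


def _eased_path(s: np.ndarray, a: float, b: float, frac: float) -> np.ndarray:
    """Cosine-eased transition from level ``a`` to ``b`` over the first
    ``frac`` of the phase (s in (0, 1]), holding at ``b`` afterwards.

    The time-average over the phase is frac*(a+b)/2 + (1-frac)*b, which the
    trough solvers below invert.
    """
    s = np.asarray(s, dtype=float)
    out = np.full(s.shape, b, dtype=float)
    ramp = s < frac
    out[ramp] = a + (b - a) * (1.0 - np.cos(np.pi * s[ramp] / frac)) / 2.0
    return out


def _solve_hold_level(target_mean: float, start: float, frac: float) -> float:
    """Hold level b such that an eased start->b path has the given phase mean."""
    return (target_mean - frac * start / 2.0) / (1.0 - frac / 2.0)


def _round_to_cadence(x: float, cadence: float, lo: float, hi: float) -> float:
    r = round(x / cadence) * cadence
    return float(min(max(r, math.ceil(lo / cadence) * cadence), math.floor(hi / cadence) * cadence))


def _ramp_variance(times_s: np.ndarray, a: float, b: float, frac: float) -> float:
    """Variance over sample times of the eased phase-mean path."""
    if len(times_s) < 2:
        return 0.0
    path = _eased_path(times_s, a, b, frac)
    return float(np.var(path))


def simulate_experiment(config: SimConfig) -> Dataset:
    """Generate one synthetic cohort; fully reproducible from ``config.seed``.

    Returns a validated :class:`Dataset` with provenance "simulated". Two
    calls with identical config produce identical datasets.
    """
    config.validate()
    pre, bleed, post = config.phases
    dev = config.device
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_animals)

    frames: list[pd.DataFrame] = []
    for i in range(config.n_animals):
        rng = np.random.default_rng(children[i])
        animal = f"A{i + 1:02d}"

        pre_dur = _round_to_cadence(
            rng.uniform(*pre.duration_min), pre.cadence_min, *pre.duration_min)
        bleed_dur = _round_to_cadence(
            rng.uniform(*bleed.duration_min), bleed.cadence_min, *bleed.duration_min)
        post_dur = _round_to_cadence(
            rng.uniform(*post.duration_min), post.cadence_min, *post.duration_min)

        t_pre = np.arange(0.0, pre_dur + 1e-9, pre.cadence_min)
        t_bleed = np.arange(pre_dur + bleed.cadence_min, pre_dur + bleed_dur + 1e-9,
                            bleed.cadence_min)
        bleed_end = pre_dur + bleed_dur
        t_post = np.arange(bleed_end + post.cadence_min, bleed_end + post_dur + 1e-9,
                           post.cadence_min)

        # early death during follow-up truncates every series of the animal
        dies = rng.random() < config.dropout_prob
        death_time = rng.uniform(bleed_end, bleed_end + post_dur)
        if dies:
            t_post = t_post[t_post <= death_time]

        times = np.concatenate([t_pre, t_bleed, t_post])
        phase_lab = np.concatenate([
            np.repeat("pre_bleeding", len(t_pre)),
            np.repeat("bleeding", len(t_bleed)),
            np.repeat("post_bleeding", len(t_post)),
        ])
        n_t = len(times)
        s_bleed = (t_bleed - pre_dur) / bleed_dur          # in (0, 1]
        s_post = (t_post - bleed_end) / post_dur           # in (0, 1]

        ref: dict[str, np.ndarray] = {}
        path_parts: dict[str, np.ndarray] = {}
        # SBP first (DBP derives from it), then the independents.
        for var in ("SBP", "HR", "CO"):
            mu_pre = pre.level_mean[var]
            mu_b = bleed.level_mean[var]
            mu_post = post.level_mean[var]
            trough = _solve_hold_level(mu_b, mu_pre, config.BLEED_RAMP_FRAC)
            hold_post = _solve_hold_level(mu_post, trough, config.POST_RAMP_FRAC)

            path = np.concatenate([
                np.full(len(t_pre), mu_pre),
                _eased_path(s_bleed, mu_pre, trough, config.BLEED_RAMP_FRAC),
                _eased_path(s_post, trough, hold_post, config.POST_RAMP_FRAC),
            ])
            path_parts[var] = path

            # split residual marginal variance (per phase, after the ramp's
            # own contribution) between animal level and smooth AR(1) path
            resid_sd = np.empty(n_t)
            for lab, spec, tv, a, b, fr in (
                ("pre_bleeding", pre, None, mu_pre, mu_pre, 1.0),
                ("bleeding", bleed, s_bleed, mu_pre, trough, config.BLEED_RAMP_FRAC),
                ("post_bleeding", post, s_post, trough, hold_post, config.POST_RAMP_FRAC),
            ):
                mask = phase_lab == lab
                v_ramp = _ramp_variance(tv, a, b, fr) if tv is not None else 0.0
                v_res = max(spec.level_sd[var] ** 2 - v_ramp,
                            (0.2 * spec.level_sd[var]) ** 2)
                resid_sd[mask] = math.sqrt(v_res)

            z_animal = rng.standard_normal()
            u = _ar1(rng, n_t, config.PATH_RHO)
            w_between = math.sqrt(config.BETWEEN_ANIMAL_FRAC)
            w_within = math.sqrt(1.0 - config.BETWEEN_ANIMAL_FRAC)
            x = path + resid_sd * (w_between * z_animal + w_within * u)
            ref[var] = np.maximum(x, config.REF_FLOOR[var])

        # DBP = phase fraction of SBP + independent variation, so MAP is
        # well defined and the floor couples the two pressures.
        frac = np.empty(n_t)
        extra_sd = np.empty(n_t)
        for lab, spec in (("pre_bleeding", pre), ("bleeding", bleed), ("post_bleeding", post)):
            mask = phase_lab == lab
            f_p = spec.level_mean["DBP"] / spec.level_mean["SBP"]
            frac[mask] = f_p
            e2 = spec.level_sd["DBP"] ** 2 - (f_p * spec.level_sd["SBP"]) ** 2
            extra_sd[mask] = math.sqrt(max(e2, (0.2 * spec.level_sd["DBP"]) ** 2))
        z_dbp = rng.standard_normal()
        u_dbp = _ar1(rng, n_t, config.PATH_RHO)
        dbp = frac * ref["SBP"] + extra_sd * (
            math.sqrt(config.BETWEEN_ANIMAL_FRAC) * z_dbp
            + math.sqrt(1.0 - config.BETWEEN_ANIMAL_FRAC) * u_dbp
        )
        ref["DBP"] = np.maximum(dbp, config.REF_FLOOR["DBP"])

        # MAP floor during bleeding: scale both pressures up where the rate
        # control would have paused the bleed.
        in_bleed = phase_lab == "bleeding"
        map_ = (ref["SBP"] + 2.0 * ref["DBP"]) / 3.0
        low = in_bleed & (map_ < config.map_floor)
        if low.any():
            # tiny safety factor keeps MAP >= floor after float rounding
            scale = (1.0 + 1e-12) * config.map_floor / map_[low]
            ref["SBP"][low] *= scale
            ref["DBP"][low] *= scale

        # device channel: proportional slope + one-time calibration offset +
        # AR(1) observation noise
        devvals: dict[str, np.ndarray] = {}
        for var in VARIABLES:
            offset_a = rng.normal(0.0, dev.calibration_offset_sd[var])
            e = dev.noise_sd[var] * _ar1(rng, n_t, dev.ar1_rho)
            d = ref[var] * (1.0 + dev.proportional_bias) + offset_a + e
            devvals[var] = np.maximum(d, 1e-3)

        # spike artifacts on either or both channels
        for var in VARIABLES:
            hits = rng.random(n_t) < config.spike_prob
            which = rng.random(n_t)  # drawn unconditionally to keep streams stable
            for j in np.nonzero(hits)[0]:
                m = 1.0 + config.spike_magnitude
                if which[j] < 0.45:
                    ref[var][j] *= m
                elif which[j] < 0.90:
                    devvals[var][j] *= m
                else:
                    ref[var][j] *= m
                    devvals[var][j] *= m

        # thin cardiac-output observations during/after bleeding
        co_keep = np.ones(n_t, dtype=bool)
        co_miss_draw = rng.random(n_t)
        late = phase_lab != "pre_bleeding"
        co_keep[late & (co_miss_draw < config.co_missing_prob)] = False

        for var in VARIABLES:
            keep = co_keep if var == "CO" else np.ones(n_t, dtype=bool)
            frames.append(pd.DataFrame({
                "animal_id": animal,
                "phase": phase_lab[keep],
                "time_min": times[keep],
                "variable": var,
                "reference_value": ref[var][keep],
                "device_value": devvals[var][keep],
            }))

    df = pd.concat(frames, ignore_index=True)
    return Dataset(df, provenance="simulated", metadata={"seed": config.seed})


# ---------------------------------------------------------------------------
# Deterministic unit-test fixtures with known ground truth
# ---------------------------------------------------------------------------

FIXTURE_NAMES = ("perfect", "biased", "noisy", "spiky")

# gentle handcrafted protocol: 7 baseline points, 13 bleeding points (60-min
# bleed), 4 follow-up points; smooth eased decline plus a small physiological
# oscillation so successive differences are non-degenerate but bounded
_FIX_T_PRE = np.arange(0.0, 31.0, 5.0)
_FIX_T_BLEED = np.arange(35.0, 96.0, 5.0)
_FIX_T_POST = np.arange(115.0, 176.0, 20.0)
_FIX_LEVELS = {
    # var: (baseline, bleed trough, follow-up level)
    "SBP": (79.0, 55.0, 58.0),
    "DBP": (57.0, 38.0, 40.0),
    "HR": (96.0, 104.0, 120.0),
    "CO": (3.8, 2.6, 2.4),
}
# relative oscillation amplitude per variable: CO swings harder so its
# successive changes clear the 0.5 l/min trending exclusion zone
_FIX_WIGGLE_AMP = {"SBP": 0.02, "DBP": 0.02, "HR": 0.02, "CO": 0.12}
_FIX_WIGGLE_PERIOD = 3.4   # samples per oscillation cycle


def _fixture_reference(scale: float) -> dict[str, np.ndarray]:
    """Smooth reference paths for one fixture animal, scaled by ``scale``."""
    n_pre, n_bleed, n_post = len(_FIX_T_PRE), len(_FIX_T_BLEED), len(_FIX_T_POST)
    s_bleed = np.arange(1, n_bleed + 1) / n_bleed
    s_post = np.arange(1, n_post + 1) / n_post
    out = {}
    for var, (base, trough, fup) in _FIX_LEVELS.items():
        path = np.concatenate([
            np.full(n_pre, base),
            _eased_path(s_bleed, base, trough, 1.0),
            _eased_path(s_post, trough, fup, 1.0),
        ])
        i = np.arange(len(path))
        wiggle = 1.0 + _FIX_WIGGLE_AMP[var] * np.sin(
            2.0 * np.pi * i / _FIX_WIGGLE_PERIOD)
        out[var] = scale * path * wiggle
    return out


def _fixture_frame() -> pd.DataFrame:
    times = np.concatenate([_FIX_T_PRE, _FIX_T_BLEED, _FIX_T_POST])
    phase = np.concatenate([
        np.repeat("pre_bleeding", len(_FIX_T_PRE)),
        np.repeat("bleeding", len(_FIX_T_BLEED)),
        np.repeat("post_bleeding", len(_FIX_T_POST)),
    ])
    rows = []
    for animal, scale in (("P1", 1.0), ("P2", 1.05)):
        ref = _fixture_reference(scale)
        for var in VARIABLES:
            rows.append(pd.DataFrame({
                "animal_id": animal,
                "phase": phase,
                "time_min": times,
                "variable": var,
                "reference_value": ref[var],
                "device_value": ref[var],
            }))
    return pd.concat(rows, ignore_index=True)


#: (animal, variable, time) keys that the "spiky" fixture corrupts on the
#: reference channel; the second follow-up sample sits on a flat plateau so
#: the +50% spike is the only large two-sided successive change.
_FIX_SPIKES = (
    ("P1", "SBP", float(_FIX_T_POST[1])),
    ("P1", "HR", float(_FIX_T_POST[2])),
    ("P1", "CO", float(_FIX_T_POST[1])),
    ("P2", "DBP", float(_FIX_T_POST[1])),
    ("P2", "SBP", float(_FIX_T_POST[2])),
    ("P2", "CO", float(_FIX_T_POST[1])),
)

_FIX_NOISE_SD = {"SBP": 6.0, "DBP": 6.0, "HR": 3.0, "CO": 0.4}


def make_fixture(name: str) -> Dataset:
    """Small (< 200 row) deterministic datasets with known ground truth.

    - ``perfect``: device equals reference exactly; every downstream agreement
      statistic is perfect.
    - ``biased``: constant +4 mmHg device offset on SBP and DBP.
    - ``noisy``: additive device noise of known SD per variable
      (metadata ``noise_sd``), fixed seed.
    - ``spiky``: +50% reference-channel spikes at known points
      (metadata ``spike_keys``).
    """
    if name not in FIXTURE_NAMES:
        raise ValueError(f"unknown fixture {name!r}; valid names: {', '.join(FIXTURE_NAMES)}")
    df = _fixture_frame()
    meta: dict = {}
    if name == "biased":
        bp = df["variable"].isin(BP_VARIABLES)
        df.loc[bp, "device_value"] += 4.0
        meta["bias_mmHg"] = 4.0
    elif name == "noisy":
        rng = np.random.default_rng(777)
        sd = df["variable"].map(_FIX_NOISE_SD).to_numpy()
        df["device_value"] = np.maximum(
            df["device_value"] + rng.normal(0.0, 1.0, len(df)) * sd, 1e-3)
        meta["noise_sd"] = dict(_FIX_NOISE_SD)
    elif name == "spiky":
        for animal, var, t in _FIX_SPIKES:
            sel = (
                (df["animal_id"] == animal)
                & (df["variable"] == var)
                & (df["time_min"] == t)
            )
            df.loc[sel, "reference_value"] *= 1.5
        meta["spike_keys"] = [tuple(k) for k in _FIX_SPIKES]
    return Dataset(df, provenance=f"fixture:{name}", metadata=meta)
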