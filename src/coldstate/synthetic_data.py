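"""Seeded generators emulating every input the analysis pipeline consumes.

Each generator is a pure function of its config plus a seed and exports the
ground truth alongside the emitted data, so every analysis stage can be
scored against a known answer:

* ``simulate_ethogram``  — behaviour labels emitted by a known three-state
  Markov chain over the 15-action vocabulary (the chain's states ARE the
  semantic states 1/2/3).
* ``simulate_photometry`` — two-channel traces with shared multiplicative
  bleaching and motion artifact, Gaussian sensor noise, and double-exponential
  calcium transients injected at specified event times (by default only
  state 1->2 transitions carry transients).
* ``simulate_calorimetry`` — per-animal VO2/VCO2 with a cold-onset step
  (linear 3-h ramp), slow metabolic fluctuations, and pellet intake that is
  Poisson at a constant rate before the programmed coupling onset and
  proportional to the EE excess above basal after it.
* ``simulate_rtpp``      — a two-chamber random walk whose expected dwell
  fraction on the stimulated side equals a target preference.

The generators target the statistical structure the pipeline assumes (state
block structure, transient kinetics, EE-intake coupling), not mouse
physiology in any mechanistic sense.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ethogram import BehaviorVocabulary, Ethogram
from .hmm import HMMParams, StateSequence
from .photometry import PhotometryTrace
from .calorimetry import CalorimetrySeries, PELLET_MASS_G
from .state_metrics import RTPPSession

__all__ = [
    "true_ethogram_params",
    "EthogramGenConfig",
    "TransientKernel",
    "PhotometryGenConfig",
    "CalorimetryGenConfig",
    "simulate_ethogram",
    "simulate_photometry",
    "simulate_calorimetry",
    "simulate_rtpp",
]


def true_ethogram_params(vocab: BehaviorVocabulary | None = None) -> HMMParams:
    """Well-separated ground-truth HMM for the default generator config.

    Transitions are diagonal-heavy (0.95 self-transition) so bouts form the
    multi-second blocks seen in real ethograms; emission rows concentrate on
    disjoint action groups (total-variation separation >= 0.5 between rows).
    """
    vocab = vocab or BehaviorVocabulary.default()
    idx = vocab.index
    A = np.full((3, 3), 0.025)
    np.fill_diagonal(A, 0.95)
    B = np.full((3, vocab.size), 0.004)
    concentrations = (
        {"sitting": 0.60, "shivering": 0.25, "standing up": 0.05},
        {"eating": 0.50, "moving out": 0.15, "moving back": 0.15, "drinking": 0.10},
        {
            "walking": 0.30,
            "digging": 0.15,
            "bedding retrieval": 0.12,
            "pushing bedding": 0.12,
            "standing up": 0.08,
            "head grooming": 0.05,
            "lower body grooming": 0.05,
            "grooming tail": 0.03,
        },
    )
    for k, conc in enumerate(concentrations):
        for action, p in conc.items():
            B[k, idx[action]] += p
    B = B / B.sum(axis=1, keepdims=True)
    pi = np.array([0.6, 0.2, 0.2])
    return HMMParams(pi=pi, A=A, B=B)


@dataclass
class EthogramGenConfig:
    """Three animals x 180 min of 1-s bins by default."""

    params: HMMParams = field(default_factory=true_ethogram_params)
    duration_s: int = 10_800
    n_animals: int = 3
    bin_s: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s < 2:
            raise ValueError("duration must be at least 2 bins")


def _simulate_chain(params: HMMParams, T: int, rng: np.random.Generator) -> np.ndarray:
    cum_pi = np.cumsum(params.pi)
    cum_A = np.cumsum(params.A, axis=1)
    u = rng.random(T)
    states = np.empty(T, dtype=np.int64)
    states[0] = np.searchsorted(cum_pi, u[0])
    for t in range(1, T):
        states[t] = np.searchsorted(cum_A[states[t - 1]], u[t])
    return states


def simulate_ethogram(
    cfg: EthogramGenConfig, vocab: BehaviorVocabulary | None = None
) -> tuple[list[Ethogram], list[StateSequence]]:
    """Draw per-animal ethograms from the ground-truth chain.

    Returns the ethograms and the true state sequences (semantic 1/2/3).
    """
    vocab = vocab or BehaviorVocabulary.default()
    if cfg.params.V != vocab.size:
        raise ValueError("ground-truth emissions do not match the vocabulary")
    rng = np.random.default_rng(cfg.seed)
    ethograms, truths = [], []
    cum_B = np.cumsum(cfg.params.B, axis=1)
    for a in range(cfg.n_animals):
        states = _simulate_chain(cfg.params, cfg.duration_s, rng)
        u = rng.random(cfg.duration_s)
        codes = np.array(
            [np.searchsorted(cum_B[s], x) for s, x in zip(states, u)], dtype=np.int64
        )
        labels = [vocab.actions[c] for c in codes]
        animal_id = f"sim{a}"
        ethograms.append(
            Ethogram(
                labels=labels,
                animal_id=animal_id,
                condition="4C",
                bin_s=cfg.bin_s,
            )
        )
        truths.append(
            StateSequence(
                states=states + 1,  # chain states are the semantic states
                semantic=True,
                animal_id=animal_id,
                bin_s=cfg.bin_s,
            )
        )
    return ethograms, truths


@dataclass(frozen=True)
class TransientKernel:
    """Double-exponential calcium transient, k(t) = a*(e^(-t/tau_d) - e^(-t/tau_r))."""

    amplitude: float = 0.05
    tau_rise_s: float = 0.5
    tau_decay_s: float = 2.0

    def __post_init__(self) -> None:
        if not 0 < self.tau_rise_s < self.tau_decay_s:
            raise ValueError("require 0 < tau_rise < tau_decay")

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.where(
            t >= 0,
            np.exp(-np.clip(t, 0, None) / self.tau_decay_s)
            - np.exp(-np.clip(t, 0, None) / self.tau_rise_s),
            0.0,
        )
        return self.amplitude * out

    @property
    def peak_time_s(self) -> float:
        """Analytic argmax of the kernel."""
        r, d = self.tau_rise_s, self.tau_decay_s
        return float(np.log(d / r) / (1 / r - 1 / d))

    @property
    def peak_value(self) -> float:
        return float(self(np.array(self.peak_time_s)))


@dataclass
class PhotometryGenConfig:
    rate_hz: float = 20.0
    duration_s: float = 600.0
    baseline_470: float = 200.0
    baseline_410: float = 150.0
    bleach_tau_s: float = 3600.0
    motion_amp: float = 0.02
    motion_period_s: float = 37.0
    noise_sd: float = 0.2
    kernel: TransientKernel = field(default_factory=TransientKernel)
    seed: int = 0


def simulate_photometry(
    cfg: PhotometryGenConfig,
    event_times_s,
    event_scales=None,
) -> tuple[PhotometryTrace, np.ndarray]:
    """Two-channel trace with transients at ``event_times_s``.

    ``event_scales`` multiplies the kernel per event (0 silences an event).
    Both channels share the bleaching envelope and the multiplicative motion
    artifact; only the 470 channel carries transients.  Returns the trace and
    the (possibly scaled) event-time array used.
    """
    events = np.atleast_1d(np.asarray(event_times_s, dtype=float))
    if np.any(events < 0) or np.any(events > cfg.duration_s):
        raise ValueError("event times must lie within the recording")
    scales = (
        np.ones(len(events))
        if event_scales is None
        else np.broadcast_to(np.asarray(event_scales, dtype=float), (len(events),))
    )
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.rate_hz)) + 1
    t = np.arange(n) / cfg.rate_hz
    bleach = np.exp(-t / cfg.bleach_tau_s)
    motion = 1.0 + cfg.motion_amp * np.sin(2 * np.pi * t / cfg.motion_period_s)
    signal = np.zeros(n)
    for ev, sc in zip(events, scales):
        signal += sc * cfg.kernel(t - ev)
    f470 = cfg.baseline_470 * bleach * motion * (1.0 + signal)
    f410 = cfg.baseline_410 * bleach * motion
    if cfg.noise_sd > 0:
        f470 = f470 + cfg.noise_sd * rng.standard_normal(n)
        f410 = f410 + cfg.noise_sd * rng.standard_normal(n)
    return PhotometryTrace(t_s=t, f470=f470, f410=f410, rate_hz=cfg.rate_hz), events


@dataclass
class CalorimetryGenConfig:
    """Cold-switch respirometry with a programmed EE-intake coupling onset.

    EE steps up by ``cold_multiplier`` over a linear 3-h ramp starting at
    ``pre_cold_h`` hours into the recording.  Before ``coupling_onset_h``
    (hours after cold onset) pellets arrive at a constant Poisson rate; after
    it the pellet rate is ``coupling_k`` times the EE excess over basal, so
    hourly intake tracks hourly EE.
    """

    n_animals: int = 24
    pre_cold_h: float = 2.0
    cold_h: float = 12.0
    sample_min: float = 1.0
    basal_vo2_ml_min: float = 1.4
    rer: float = 0.80
    animal_sd: float = 0.10  # between-animal spread of basal metabolism
    cold_multiplier: float = 1.8
    ramp_h: float = 3.0
    coupling_onset_h: float = 5.0
    base_pellet_rate_h: float = 4.0
    coupling_k: float = 60.0  # pellets/h per kcal/h of EE excess; puts post-onset hourly r near 0.8
    fluct_sd: float = 0.15  # slow metabolic fluctuation (relative)
    fluct_tau_min: float = 60.0
    obs_noise_ml_min: float = 0.02
    pellet_g: float = PELLET_MASS_G
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cold_multiplier < 1:
            raise ValueError("cold multiplier must be >= 1")
        if self.coupling_onset_h < 0:
            raise ValueError("coupling onset must be >= 0")


def simulate_calorimetry(
    cfg: CalorimetryGenConfig,
) -> tuple[list[CalorimetrySeries], dict]:
    """Per-animal series plus ground truth (cold onset and coupling onset)."""
    rng = np.random.default_rng(cfg.seed)
    dt = cfg.sample_min
    total_min = (cfg.pre_cold_h + cfg.cold_h) * 60.0
    t = np.arange(0.0, total_min + dt / 2, dt)
    cold_onset = cfg.pre_cold_h * 60.0
    rel_min = t - cold_onset
    # multiplier profile: 1 before onset, linear ramp to cold_multiplier
    ramp = np.clip(rel_min / (cfg.ramp_h * 60.0), 0.0, 1.0)
    mult = 1.0 + (cfg.cold_multiplier - 1.0) * ramp
    temp = 23.0 - 19.0 * ramp  # 23 C -> 4 C over the ramp
    decay = np.exp(-dt / cfg.fluct_tau_min)
    innov_sd = cfg.fluct_sd * np.sqrt(1 - decay**2)
    kcal_per_ml_vo2 = 60.0 * (3.941 + 1.106 * cfg.rer) / 1000.0
    series: list[CalorimetrySeries] = []
    for a in range(cfg.n_animals):
        basal = cfg.basal_vo2_ml_min * (1.0 + cfg.animal_sd * rng.standard_normal())
        basal = max(basal, 0.2 * cfg.basal_vo2_ml_min)
        fluct = np.empty(len(t))
        fluct[0] = cfg.fluct_sd * rng.standard_normal()
        for i in range(1, len(t)):
            fluct[i] = decay * fluct[i - 1] + innov_sd * rng.standard_normal()
        vo2_true = basal * mult * np.clip(1.0 + fluct, 0.05, None)
        ee_true = kcal_per_ml_vo2 * vo2_true  # kcal/h
        ee_basal = kcal_per_ml_vo2 * basal
        # pellet intensity per minute
        coupled = rel_min >= cfg.coupling_onset_h * 60.0
        rate_h = np.where(
            coupled,
            cfg.coupling_k * np.clip(ee_true - ee_basal, 0.0, None),
            cfg.base_pellet_rate_h,
        )
        pellets = rng.poisson(rate_h * dt / 60.0)
        intake = np.cumsum(pellets) * cfg.pellet_g
        vo2 = np.clip(vo2_true + cfg.obs_noise_ml_min * rng.standard_normal(len(t)), 0, None)
        vco2 = np.clip(
            cfg.rer * vo2_true + cfg.obs_noise_ml_min * rng.standard_normal(len(t)),
            0,
            None,
        )
        series.append(
            CalorimetrySeries(
                t_min=t,
                vo2_ml_min=vo2,
                vco2_ml_min=vco2,
                intake_cum_g=intake,
                temp_c=temp,
                animal_id=f"sim{a}",
            )
        )
    truth = {
        "cold_onset_min": cold_onset,
        "coupling_onset_h": cfg.coupling_onset_h,
        "seed": cfg.seed,
    }
    return series, truth


def simulate_rtpp(
    preference_pct: float,
    duration_s: float = 1800.0,
    seed: int = 0,
    rate_hz: float = 5.0,
    mean_dwell_s: float = 10.0,
    stim_side: str = "right",
    arena_w: float = 60.0,
    arena_h: float = 25.0,
) -> RTPPSession:
    """Two-chamber random walk with expected stim-side dwell = preference_pct.

    Side occupancy follows a two-state Markov chain whose stationary
    distribution equals the target preference; within a chamber the position
    performs a clipped random walk.  ``preference_pct=100`` pins the animal
    to the stimulated side for the whole session.
    """
    if not 0 < preference_pct <= 100:
        raise ValueError("preference must be in (0, 100]")
    p = preference_pct / 100.0
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate_hz))
    dt = 1.0 / rate_hz
    divider = arena_w / 2.0
    # leave probabilities chosen so stationary stim fraction = p and the
    # faster side keeps the target mean dwell
    leave = dt / mean_dwell_s
    q_stim = leave * (1.0 - p) / max(p, 1.0 - p)
    q_other = leave * p / max(p, 1.0 - p)
    on_stim = np.empty(n, dtype=bool)
    on_stim[0] = rng.random() < p
    u = rng.random(n)
    for i in range(1, n):
        q = q_stim if on_stim[i - 1] else q_other
        on_stim[i] = (not on_stim[i - 1]) if u[i] < q else on_stim[i - 1]
    stim_right = stim_side == "right"
    x = np.empty(n)
    y = np.empty(n)
    step = 2.0 * dt  # cm per sample, a few cm/s walking speed
    xi = divider + (5.0 if (on_stim[0] == stim_right) else -5.0)
    yi = arena_h / 2.0
    margin = 2.0
    for i in range(n):
        right_half = on_stim[i] == stim_right
        lo = divider + margin if right_half else margin
        hi = arena_w - margin if right_half else divider - margin
        if not (lo <= xi <= hi):  # chamber switch: re-enter near the divider
            xi = lo + 1.0 if right_half else hi - 1.0
        xi = float(np.clip(xi + step * rng.standard_normal(), lo, hi))
        yi = float(np.clip(yi + step * rng.standard_normal(), margin, arena_h - margin))
        x[i] = xi
        y[i] = yi
    return RTPPSession(
        t_s=np.arange(n) * dt,
        x_cm=x,
        y_cm=y,
        stim_side=stim_side,
        divider_x=divider,
        arena_w=arena_w,
        arena_h=arena_h,
    )
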