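"""Seeded synthetic CGM cohort generator.

Emulates the shape of a real type-1-diabetes CGM study record — per-patient
multi-week series on a 5-minute grid with meal/bolus events, glucose
dynamics that rise after carbohydrate intake and fall under insulin action,
sensor noise, dropout gaps, and a chronological train/test partition — so
every downstream stage (imputation, windowing, training, evaluation,
comparison) is exercisable without restricted data.

The latent glucose model is a deliberately minimal one-compartment balance

    G(t+1) = G(t) + k1*(Gb - G(t))*dt + k2*Ra(t)*dt - k3*Ia(t)*dt

with first-order absorption kernels for meal carbohydrate (rate of
appearance ``Ra``) and bolus insulin activity ``Ia``; the observed CGM
trace is the latent trajectory plus independent sensor noise,
bg(t) = clip(G(t) + eps_t). It is not a physiological simulator; it only
guarantees carb-up / insulin-down causality strong enough for forecasting
models to learn.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import OverMaskingError
from .series import BG_MAX, BG_MIN, SAMPLE_MINUTES, PatientSeries

__all__ = [
    "SimConfig",
    "glucose_response",
    "simulate_patient",
    "simulate_cohort",
    "inject_gaps",
]

STEPS_PER_DAY = 24 * 60 // SAMPLE_MINUTES  # 288


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate the emulated study's scale: six patients, eight weeks
    each, ~3 meals/day of 20-100 g carbohydrate covered by boluses at a
    1:10 g/U carb ratio, constant basal, CGM noise of 5 mg/dL, and about
    one sensor gap per day of 15-60 minutes. The last 20% of each record
    is the test partition.
    """

    n_patients: int = 6
    days: int = 56
    meals_per_day: float = 3.0
    carb_range: tuple = (20.0, 100.0)  # grams
    carb_ratio: float = 10.0  # grams covered per insulin unit
    basal_rate: float = 1.0  # units/hour
    baseline_bg: float = 140.0  # Gb, mg/dL
    k_return: float = 0.02  # k1, 1/min pull toward baseline
    k_carb: float = 3.0  # k2, mg/dL rise per gram appearing per min
    k_insulin: float = 25.0  # k3, mg/dL fall per unit acting per min
    tau_carb: float = 25.0  # carb absorption time constant, min
    tau_insulin: float = 55.0  # insulin action time constant, min
    noise_sd: float = 5.0  # mg/dL sensor noise
    gap_rate: float = 1.0  # gaps per day
    gap_length: tuple = (15.0, 60.0)  # minutes
    test_fraction: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        positive = (
            self.carb_ratio,
            self.baseline_bg,
            self.k_return,
            self.k_carb,
            self.k_insulin,
            self.tau_carb,
            self.tau_insulin,
        )
        if any(v <= 0 for v in positive):
            raise ValueError("rates, gains and time constants must be positive")
        if self.n_patients < 1 or self.days < 1:
            raise ValueError("need at least one patient and one day")
        if self.meals_per_day < 0 or self.noise_sd < 0 or self.gap_rate < 0:
            raise ValueError("rates must be non-negative")


def _first_order_kernel(n_steps: int, tau: float) -> np.ndarray:
    """Normalized impulse response (t/tau^2)*exp(-t/tau) on the 5-min grid.

    Sums to ~1 so a D-gram meal contributes ~D grams of appearance overall.
    """
    t = np.arange(n_steps) * SAMPLE_MINUTES
    k = (t / tau**2) * np.exp(-t / tau) * SAMPLE_MINUTES
    return k


def glucose_response(config: SimConfig, ch: np.ndarray, bol: np.ndarray) -> np.ndarray:
    """Latent (noise-free) glucose trajectory for given event channels.

    Discretized one-compartment balance on the 5-min grid: return toward
    baseline at rate k_return, carbohydrate rate of appearance raising and
    insulin activity lowering glucose through first-order kernels.
    """
    n = len(ch)
    dt = float(SAMPLE_MINUTES)
    klen = min(n, int(12 * 60 / SAMPLE_MINUTES))  # 12-h kernel support is ample
    ra = np.convolve(ch, _first_order_kernel(klen, config.tau_carb) / dt)[:n]
    ia = np.convolve(bol, _first_order_kernel(klen, config.tau_insulin) / dt)[:n]
    latent = np.empty(n)
    latent[0] = config.baseline_bg
    for t in range(n - 1):
        drift = config.k_return * (config.baseline_bg - latent[t]) * dt
        rise = config.k_carb * ra[t] * dt
        fall = config.k_insulin * ia[t] * dt
        latent[t + 1] = np.clip(latent[t] + drift + rise - fall, BG_MIN, BG_MAX)
    return latent


def simulate_patient(config: SimConfig, patient_index: int) -> PatientSeries:
    """Simulate one patient; the (seed, patient_index) pair fixes every byte."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, patient_index]))
    n = config.days * STEPS_PER_DAY

    # meal events: Poisson process at meals_per_day
    p_meal = config.meals_per_day / STEPS_PER_DAY
    meal_mask = rng.random(n) < p_meal
    ch = np.zeros(n)
    ch[meal_mask] = rng.uniform(*config.carb_range, size=int(meal_mask.sum()))
    bol = ch / config.carb_ratio
    bas = np.full(n, config.basal_rate)

    # latent glucose is smooth; the observed CGM trace adds independent
    # sensor noise on top, which is the component a forecaster can beat
    # the persistence baseline by filtering out
    latent = glucose_response(config, ch, bol)
    noise = rng.normal(0.0, config.noise_sd, size=n) if config.noise_sd > 0 else 0.0
    bg = np.clip(latent + noise, BG_MIN, BG_MAX)

    n_test = int(round(config.test_fraction * n))
    split = np.array(["train"] * (n - n_test) + ["test"] * n_test, dtype=object)
    return PatientSeries(
        patient_id=f"sim{patient_index:03d}",
        timestamps=np.arange(n, dtype=float) * SAMPLE_MINUTES,
        bg=bg,
        bas=bas,
        bol=bol,
        ch=ch,
        split=split,
    )


def simulate_cohort(config: SimConfig) -> list:
    return [simulate_patient(config, i) for i in range(config.n_patients)]


def inject_gaps(series: PatientSeries, config: SimConfig) -> PatientSeries:
    """Mask glucose in random contiguous blocks to emulate sensor dropouts.

    The first and last sample of each partition are never removed, so the
    spline imputation stays an interpolation. Refuses to mask more than
    half of the series.
    """
    pid_key = int.from_bytes(series.patient_id.encode()[-4:], "little") % (2**31)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, pid_key, 7]))
    n = len(series)
    n_gaps = rng.poisson(config.gap_rate * config.days)
    protected = set()
    for part in ("train", "test"):
        idx = series.partition_index(part)
        if idx.size:
            protected.update((int(idx[0]), int(idx[-1])))
    mask = np.zeros(n, dtype=bool)
    for _ in range(n_gaps):
        length = int(
            round(rng.uniform(*config.gap_length) / SAMPLE_MINUTES)
        )
        start = int(rng.integers(0, max(1, n - length)))
        block = [i for i in range(start, min(n, start + length)) if i not in protected]
        mask[block] = True
    if mask.sum() > n / 2:
        raise OverMaskingError(f"gap specification masks {mask.sum()}/{n} samples")
    bg = series.bg.copy()
    bg[mask] = np.nan
    return replace(series, bg=bg)
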