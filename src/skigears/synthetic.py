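"""Synthetic gear-labeled accelerometer sessions.

The study's raw treadmill recordings are not publicly deposited, so this
module generates sessions with the structure the classifier assumes:
five gear-specific periodic triaxial templates (low-order Fourier series
of cycle phase), concatenated cycle by cycle with jittered durations and
amplitudes, sampled at a nominal 80 Hz with timestamp jitter, plus
additive Gaussian noise and gravity on the vertical axis.

Template shapes are hand-designed to echo the qualitative plane patterns
of chest acceleration during skating — the lateral/horizontal
"half-moon" coupling of G2, the near-symmetric "butterfly" of G3 — not
fits to any measured data.  Structural invariants are built in: G2R/G4R
are the lateral mirrors (ax -> -ax) of G2L/G4L, and the G3 lateral axis
is half-cycle antisymmetric (ax(phi) = -ax(phi + 1/2), odd harmonics
only).  All templates place the dominant vertical-axis minimum at phase
0, so constructed cycle boundaries coincide with the minima the
segmentation stage detects.

Two protocols are provided: fixed-gear trials (~50 cycles of one gear)
and a variable protocol calibrated to the study's means (~140 cycles in
blocks, ~23 gear transitions, per-gear shares ~30/27/30/26/26).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from typing import Sequence

import numpy as np

from .exceptions import ConfigError
from .gears import GEARS, check_gear
from .io import AccelerometerStream, LabelInterval

GRAVITY = 9.81  # m/s², added to the vertical (y) axis

_TWO_PI = 2.0 * np.pi

#: mean per-gear cycle counts over the variable protocol (study means)
_VARIABLE_SHARES = {"G2L": 30.0, "G2R": 27.0, "G3": 30.0,
                    "G4L": 26.0, "G4R": 26.0}
_VARIABLE_TOTAL_CYCLES = 140.0
_VARIABLE_TRANSITIONS = 23.0


@dataclass(frozen=True)
class GearTemplate:
    """Periodic triaxial acceleration pattern of one gear.

    ``cos_coeffs``/``sin_coeffs`` are (3, 5) and (3, 4) arrays: rows are
    the x/y/z axes, columns the harmonics (cos includes the constant
    a0).  Gravity is added to the y row at evaluation, so the stored
    coefficients describe only the dynamic part of the movement.
    """

    gear: str
    cos_coeffs: np.ndarray
    sin_coeffs: np.ndarray
    gravity: float = GRAVITY

    def __post_init__(self) -> None:
        check_gear(self.gear)
        c = np.asarray(self.cos_coeffs, float).reshape(3, 5)
        s = np.asarray(self.sin_coeffs, float).reshape(3, 4)
        object.__setattr__(self, "cos_coeffs", c)
        object.__setattr__(self, "sin_coeffs", s)

    def dynamic(self, phase: np.ndarray) -> np.ndarray:
        """Gravity-free acceleration at cycle phase(s) in [0, 1); (m, 3)."""
        phi = np.atleast_1d(np.asarray(phase, float))
        k = np.arange(1, 5)
        ang = _TWO_PI * phi[:, None] * k[None, :]          # (m, 4)
        out = (np.cos(ang) @ self.cos_coeffs[:, 1:].T
               + np.sin(ang) @ self.sin_coeffs.T
               + self.cos_coeffs[:, 0])
        return out

    def __call__(self, phase: np.ndarray) -> np.ndarray:
        """Full acceleration (gravity included on y) at phase(s); (m, 3)."""
        out = self.dynamic(phase)
        out[:, 1] += self.gravity
        return out

    def mirrored(self, gear: str) -> "GearTemplate":
        """Lateral mirror: negate the x-axis coefficients."""
        c = self.cos_coeffs.copy()
        s = self.sin_coeffs.copy()
        c[0] *= -1.0
        s[0] *= -1.0
        return GearTemplate(gear=gear, cos_coeffs=c, sin_coeffs=s,
                            gravity=self.gravity)


def _base_templates() -> dict[str, GearTemplate]:
    # rows: x (lateral), y (vertical, dynamic part), z (horizontal)
    # cos columns: a0, a1..a4; sin columns: b1..b4
    g2l = GearTemplate(
        "G2L",
        cos_coeffs=[[0.0, 0.4, 0.0, 0.0, 0.0],
                    [0.0, -2.2, 0.3, 0.0, 0.0],
                    [-0.3, 1.6, 0.0, 0.0, 0.0]],
        sin_coeffs=[[2.2, 0.5, 0.0, 0.0],
                    [0.0, 0.0, 0.0, 0.0],
                    [0.0, 0.6, 0.0, 0.0]],
    )
    # G3 lateral axis: odd harmonics only -> ax(phi) = -ax(phi + 1/2)
    g3 = GearTemplate(
        "G3",
        cos_coeffs=[[0.0, 0.0, 0.0, 0.0, 0.0],
                    [0.0, -2.5, -0.4, 0.0, 0.0],
                    [0.2, -1.8, 0.9, 0.0, 0.0]],
        sin_coeffs=[[1.5, 0.0, 0.8, 0.0],
                    [0.0, 0.0, 0.0, 0.0],
                    [0.0, 0.0, 0.0, 0.0]],
    )
    g4l = GearTemplate(
        "G4L",
        cos_coeffs=[[0.0, 0.0, 0.5, 0.0, 0.0],
                    [0.0, -2.8, 0.2, 0.0, 0.0],
                    [0.4, 0.0, 0.8, 0.0, 0.0]],
        sin_coeffs=[[1.0, -0.9, 0.0, 0.0],
                    [0.0, 0.3, 0.0, 0.0],
                    [-1.4, 0.0, 0.0, 0.0]],
    )
    return {"G2L": g2l, "G2R": g2l.mirrored("G2R"), "G3": g3,
            "G4L": g4l, "G4R": g4l.mirrored("G4R")}


_TEMPLATES = _base_templates()


def make_gear_template(gear: str) -> GearTemplate:
    """Built-in template for *gear*; raises on unknown labels."""
    check_gear(gear)
    return _TEMPLATES[gear]


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings emulating the study's recording conditions.

    Defaults: 1.4 ± 0.1 s cycles, 0.3 m/s² additive noise per axis,
    nominal 80 Hz sampling with 1 ms timestamp jitter, per-cycle
    amplitude scale 1.0 ± 0.05.  ``seed`` is mandatory so every fixture
    is bit-reproducible.
    """

    seed: int
    cycle_duration_mean: float = 1.4
    cycle_duration_sd: float = 0.1
    noise_sd: float = 0.3
    sample_rate: float = 80.0
    timestamp_jitter_sd: float = 0.001
    amplitude_scale_mean: float = 1.0
    amplitude_scale_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.cycle_duration_mean <= 0 or self.sample_rate <= 0 \
                or self.amplitude_scale_mean <= 0:
            raise ConfigError("means and rates must be positive")
        if min(self.cycle_duration_sd, self.noise_sd,
               self.timestamp_jitter_sd, self.amplitude_scale_sd) < 0:
            raise ConfigError("standard deviations must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown simulate keys: {sorted(unknown)}")
        return cls(**d)

    def with_(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


def _synthesize(gears: Sequence[str], cfg: SimulationConfig,
                rng: np.random.Generator
                ) -> tuple[AccelerometerStream, np.ndarray]:
    """Render one stream from a per-cycle gear sequence.

    Returns the stream and the constructed cycle boundaries (length
    n_cycles + 1), which are also stored in ``stream.meta``.
    """
    n = len(gears)
    lo = max(1e-3, cfg.cycle_duration_mean - 4 * cfg.cycle_duration_sd)
    hi = cfg.cycle_duration_mean + 4 * cfg.cycle_duration_sd
    durations = np.clip(
        rng.normal(cfg.cycle_duration_mean, cfg.cycle_duration_sd, n), lo, hi)
    amplitudes = np.clip(
        rng.normal(cfg.amplitude_scale_mean, cfg.amplitude_scale_sd, n),
        0.0, None)
    boundaries = np.concatenate([[0.0], np.cumsum(durations)])
    total = boundaries[-1]
    dt = 1.0 / cfg.sample_rate
    base = np.arange(0.0, total, dt)
    jitter = np.clip(
        rng.normal(0.0, cfg.timestamp_jitter_sd, base.size),
        -0.4 * dt, 0.4 * dt)
    t = np.clip(base + jitter, 0.0, total - 1e-9)
    idx = np.clip(np.searchsorted(boundaries, t, side="right") - 1, 0, n - 1)
    phase = (t - boundaries[idx]) / durations[idx]
    signal = np.zeros((t.size, 3))
    gears_arr = np.asarray(gears)
    for gear in dict.fromkeys(gears):            # preserve first-seen order
        mask = gears_arr[idx] == gear
        tpl = make_gear_template(gear)
        signal[mask] = tpl.dynamic(phase[mask]) * amplitudes[idx[mask], None]
    signal[:, 1] += GRAVITY
    signal += rng.normal(0.0, cfg.noise_sd, signal.shape)
    stream = AccelerometerStream(
        t, signal[:, 0], signal[:, 1], signal[:, 2],
        meta={"generator": "skigears.synthetic", "seed": cfg.seed,
              "sample_rate": cfg.sample_rate,
              "cycle_boundaries": boundaries.tolist(),
              "cycle_gears": list(gears)},
    )
    return stream, boundaries


def simulate_trial(gear: str, n_cycles: int, cfg: SimulationConfig
                   ) -> tuple[AccelerometerStream, list[LabelInterval]]:
    """Fixed-gear trial: *n_cycles* consecutive cycles of one gear.

    Returns the stream plus a single label interval covering it.
    Deterministic given ``cfg.seed``; ground-truth cycle boundaries are
    recorded in ``stream.meta['cycle_boundaries']``.
    """
    check_gear(gear)
    if n_cycles < 1:
        raise ConfigError("n_cycles must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    stream, boundaries = _synthesize([gear] * n_cycles, cfg, rng)
    return stream, [LabelInterval(0.0, float(boundaries[-1]), gear)]


def _draw_block_sequence(rng: np.random.Generator) -> list[tuple[str, int]]:
    n_blocks = max(2, 1 + int(rng.poisson(_VARIABLE_TRANSITIONS)))
    mean_len = _VARIABLE_TOTAL_CYCLES / (_VARIABLE_TRANSITIONS + 1.0)
    shares = np.array([_VARIABLE_SHARES[g] for g in GEARS])
    shares = shares / shares.sum()
    blocks: list[tuple[str, int]] = []
    prev = None
    for _ in range(n_blocks):
        p = shares.copy()
        if prev is not None:
            p[GEARS.index(prev)] = 0.0
            p = p / p.sum()
        gear = str(rng.choice(GEARS, p=p))
        length = 1 + int(rng.poisson(mean_len - 1.0))
        blocks.append((gear, length))
        prev = gear
    return blocks


def simulate_variable_protocol(cfg: SimulationConfig,
                               gear_sequence: Sequence[tuple[str, int]] | None
                               = None
                               ) -> tuple[AccelerometerStream,
                                          list[LabelInterval]]:
    """Variable protocol: blocks of gears with instantaneous transitions.

    Without an explicit ``gear_sequence`` (list of (gear, n_cycles)
    blocks), a random block sequence is drawn whose expected totals
    match the study's means: ~140 cycles, ~23 transitions, per-gear
    shares ~30/27/30/26/26.  Label intervals (one per block, adjacent
    same-gear blocks merged) exactly tile the constructed time span.
    """
    rng = np.random.default_rng(cfg.seed)
    if gear_sequence is None:
        blocks = _draw_block_sequence(rng)
    else:
        blocks = [(check_gear(g), int(n)) for g, n in gear_sequence]
        if any(n < 1 for _, n in blocks):
            raise ConfigError("block cycle counts must be >= 1")
    # merge adjacent same-gear blocks so label intervals are maximal
    merged: list[tuple[str, int]] = []
    for gear, n in blocks:
        if merged and merged[-1][0] == gear:
            merged[-1] = (gear, merged[-1][1] + n)
        else:
            merged.append((gear, n))
    per_cycle = [g for g, n in merged for _ in range(n)]
    stream, boundaries = _synthesize(per_cycle, cfg, rng)
    labels = []
    pos = 0
    for gear, n in merged:
        labels.append(LabelInterval(float(boundaries[pos]),
                                    float(boundaries[pos + n]), gear))
        pos += n
    return stream, labels
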