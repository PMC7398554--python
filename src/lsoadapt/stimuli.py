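"""Binaural stimulus protocols: level mapping, staircases, adapter-test
sequences and ITD-delayed onset pairs.

Conventions
-----------
* Levels are in dB within [0, 40]; drive = level / 40 in [0, 1].
* ILD = ipsi level - contra level (positive = ipsilateral louder).
* Durations passed to protocol builders are wall-clock seconds; one model
  second corresponds to ``WALL_SECONDS_PER_MODEL_SECOND`` wall seconds, and
  ``dt`` is the Euler step in model seconds.
* ITDs are in microseconds of wall time.  A negative ITD delays the
  contralateral channel (sound source on the ipsilateral side).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WALL_SECONDS_PER_MODEL_SECOND",
    "wall_to_model",
    "LevelMap",
    "Segment",
    "BinauralStimulus",
    "ild_to_drives",
    "staircase_protocol",
    "adapter_test_protocol",
    "itd_protocol",
]

#: wall-clock seconds represented by one model second (time-base calibration)
WALL_SECONDS_PER_MODEL_SECOND = 0.1

#: default Euler step in model seconds (0.1 ms wall)
DEFAULT_DT = 0.001

#: fine Euler step for onset-timing protocols (10 us wall)
FINE_DT = 1e-4


def wall_to_model(seconds: float) -> float:
    """Convert a wall-clock duration in seconds to model seconds."""
    return seconds / WALL_SECONDS_PER_MODEL_SECOND


@dataclass(frozen=True)
class LevelMap:
    """Linear map between sound level in dB and input drive in [0, 1]."""

    max_abs_ild: float = 40.0

    def level_to_drive(self, level_db) -> np.ndarray:
        level = np.asarray(level_db, dtype=float)
        if np.any(level < -1e-9) or np.any(level > self.max_abs_ild + 1e-9):
            raise ValueError(
                f"level {level} dB outside [0, {self.max_abs_ild}] dB"
            )
        return np.clip(level / self.max_abs_ild, 0.0, 1.0)

    def drive_to_level(self, drive) -> np.ndarray:
        return np.asarray(drive, dtype=float) * self.max_abs_ild


DEFAULT_MAP = LevelMap()


def ild_to_drives(ild: float, base_level: float = 20.0,
                  level_map: LevelMap = DEFAULT_MAP) -> tuple[float, float]:
    """Drive pair (ipsi, contra) for a nominal ILD around a base level.

    ipsi level = base + ild/2, contra level = base - ild/2.
    """
    ipsi = base_level + ild / 2.0
    contra = base_level - ild / 2.0
    for side, level in (("ipsi", ipsi), ("contra", contra)):
        if level < -1e-9 or level > level_map.max_abs_ild + 1e-9:
            raise ValueError(
                f"{side} level {level:g} dB out of range for ild={ild:g}, "
                f"base={base_level:g}"
            )
    return (float(level_map.level_to_drive(ipsi)),
            float(level_map.level_to_drive(contra)))


@dataclass(frozen=True)
class Segment:
    """Measurement bookkeeping for one homogeneous stretch of a stimulus."""

    start: int
    end: int  # exclusive
    ild: float | None
    itd: float | None
    label: str


@dataclass
class BinauralStimulus:
    """Time-sampled ipsi/contra drive matrices plus segment metadata."""

    dt: float
    s_ipsi: np.ndarray  # (T, n)
    s_contra: np.ndarray  # (T, n)
    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.s_ipsi = np.asarray(self.s_ipsi, dtype=float)
        self.s_contra = np.asarray(self.s_contra, dtype=float)
        if self.s_ipsi.shape != self.s_contra.shape:
            raise ValueError("ipsi/contra shapes differ")
        for name, arr in (("s_ipsi", self.s_ipsi), ("s_contra", self.s_contra)):
            if np.any(arr < -1e-12) or np.any(arr > 1 + 1e-12):
                raise ValueError(f"{name} drives outside [0, 1]")

    @property
    def n_steps(self) -> int:
        return self.s_ipsi.shape[0]

    @property
    def n_bands(self) -> int:
        return self.s_ipsi.shape[1]

    def segment(self, label: str) -> Segment:
        for seg in self.segments:
            if seg.label == label:
                return seg
        raise KeyError(f"no segment labelled {label!r}")

    # -- serialization ------------------------------------------------------
    def save(self, csv_path, json_path) -> None:
        t = np.arange(self.n_steps) * self.dt
        data = np.column_stack([t, self.s_ipsi, self.s_contra])
        header = "time," + ",".join(
            [f"ipsi_{i}" for i in range(self.n_bands)]
            + [f"contra_{i}" for i in range(self.n_bands)]
        )
        np.savetxt(csv_path, data, delimiter=",", header=header, comments="")
        meta = {
            "dt": self.dt,
            "segments": [
                {"start": s.start, "end": s.end, "ild": s.ild,
                 "itd": s.itd, "label": s.label}
                for s in self.segments
            ],
        }
        with open(json_path, "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, csv_path, json_path) -> "BinauralStimulus":
        data = np.loadtxt(csv_path, delimiter=",", skiprows=1, ndmin=2)
        with open(json_path) as fh:
            meta = json.load(fh)
        n = (data.shape[1] - 1) // 2
        return cls(
            dt=meta["dt"],
            s_ipsi=data[:, 1 : 1 + n],
            s_contra=data[:, 1 + n : 1 + 2 * n],
            segments=[Segment(**s) for s in meta["segments"]],
        )


def _constant_block(steps: int, drive: float, n_bands: int) -> np.ndarray:
    return np.full((steps, n_bands), drive, dtype=float)


def staircase_protocol(
    n_plateaus: int = 41,
    steps_per_plateau: int = 400,
    level_map: LevelMap = DEFAULT_MAP,
    n_bands: int = 5,
    dt: float = DEFAULT_DT,
) -> BinauralStimulus:
    """Descending-ipsi / ascending-contra staircase sweeping ILD +40 -> -40.

    Each plateau holds a constant level for ``steps_per_plateau`` Euler steps
    (default 400, enough for dynamical convergence of r and q).
    """
    if n_plateaus < 2:
        raise ValueError("n_plateaus must be >= 2")
    if steps_per_plateau < 400:
        raise ValueError("steps_per_plateau must be >= 400")
    ilds = np.linspace(level_map.max_abs_ild, -level_map.max_abs_ild, n_plateaus)
    ipsi, contra, segments = [], [], []
    for k, ild in enumerate(ilds):
        e, c = ild_to_drives(ild, level_map=level_map)
        ipsi.append(_constant_block(steps_per_plateau, e, n_bands))
        contra.append(_constant_block(steps_per_plateau, c, n_bands))
        segments.append(
            Segment(k * steps_per_plateau, (k + 1) * steps_per_plateau,
                    float(ild), 0.0, f"ild={ild:g}")
        )
    return BinauralStimulus(dt, np.vstack(ipsi), np.vstack(contra), segments)


def adapter_test_protocol(
    adapter_ild: float,
    test_ild: float,
    base_level: float = 20.0,
    level_map: LevelMap = DEFAULT_MAP,
    ramp_s: float = 0.010,
    adapter_s: float = 1.2,
    silence_s: float = 0.5,
    test_s: float = 2.0,
    n_bands: int = 5,
    dt: float = DEFAULT_DT,
) -> BinauralStimulus:
    """Adapter tone, silence, then test tone (durations in wall seconds).

    The adapter carries linear on/off ramps of ``ramp_s``; the silence is
    zero drive on both channels; measurements are customarily taken a fixed
    delay after the test onset (see simulation.readout).
    """
    step_wall = dt * WALL_SECONDS_PER_MODEL_SECOND
    n_ad = int(round(adapter_s / step_wall))
    n_sil = int(round(silence_s / step_wall))
    n_test = int(round(test_s / step_wall))
    n_ramp = int(round(ramp_s / step_wall))
    if 2 * n_ramp > n_ad:
        raise ValueError("ramps longer than adapter")
    e_ad, c_ad = ild_to_drives(adapter_ild, base_level, level_map)
    e_te, c_te = ild_to_drives(test_ild, base_level, level_map)
    env = np.ones(n_ad)
    if n_ramp:
        env[:n_ramp] = np.linspace(0.0, 1.0, n_ramp, endpoint=False)
        env[-n_ramp:] = np.linspace(1.0, 0.0, n_ramp)
    ipsi = np.concatenate(
        [env * e_ad, np.zeros(n_sil), np.full(n_test, e_te)]
    )[:, None] * np.ones(n_bands)
    contra = np.concatenate(
        [env * c_ad, np.zeros(n_sil), np.full(n_test, c_te)]
    )[:, None] * np.ones(n_bands)
    segments = [
        Segment(0, n_ad, float(adapter_ild), 0.0, "adapter"),
        Segment(n_ad, n_ad + n_sil, None, None, "silence"),
        Segment(n_ad + n_sil, n_ad + n_sil + n_test, float(test_ild), 0.0,
                "test"),
    ]
    return BinauralStimulus(dt, ipsi, contra, segments)


def itd_protocol(
    ild: float,
    itd_us: float,
    level_map: LevelMap = DEFAULT_MAP,
    trading_rate_us_per_db: float = 10.0,
    duration_s: float = 0.020,
    preroll_s: float = 0.005,
    base_level: float = 20.0,
    n_bands: int = 5,
    dt: float = FINE_DT,
) -> BinauralStimulus:
    """Constant binaural drives with onset timing offsets at a fine step.

    The contralateral onset is delayed by ``-itd_us`` relative to the
    ipsilateral one (negative ITD = contra later).  Additionally each
    channel's onset is advanced by ``trading_rate_us_per_db`` microseconds
    per dB of its own level (louder signals are transmitted faster).  Both
    channels stay on until the end of the trace.
    """
    if abs(itd_us) > 1000.0:
        raise ValueError("|itd| must be <= 1000 us")
    step_us = dt * WALL_SECONDS_PER_MODEL_SECOND * 1e6
    max_shift_us = (abs(itd_us)
                    + trading_rate_us_per_db * level_map.max_abs_ild)
    if preroll_s * 1e6 < max_shift_us:
        raise ValueError("preroll too short for requested onset shifts")
    level_i = base_level + ild / 2.0
    level_c = base_level - ild / 2.0
    e, c = ild_to_drives(ild, base_level, level_map)
    t0_us = preroll_s * 1e6
    onset_i_us = t0_us - trading_rate_us_per_db * level_i
    onset_c_us = t0_us - itd_us - trading_rate_us_per_db * level_c
    for name, onset in (("ipsi", onset_i_us), ("contra", onset_c_us)):
        if abs(onset / step_us - round(onset / step_us)) > 1e-6:
            raise ValueError(
                f"{name} onset {onset:g} us is not representable at a "
                f"{step_us:g} us step; use a smaller dt"
            )
    on_i = int(round(onset_i_us / step_us))
    on_c = int(round(onset_c_us / step_us))
    n_total = int(round((preroll_s + duration_s) * 1e6 / step_us))
    ipsi = np.zeros((n_total, n_bands))
    contra = np.zeros((n_total, n_bands))
    ipsi[on_i:] = e
    contra[on_c:] = c
    segments = [
        Segment(0, min(on_i, on_c), None, None, "preroll"),
        Segment(min(on_i, on_c), n_total, float(ild), float(itd_us),
                "stimulus"),
    ]
    return BinauralStimulus(dt, ipsi, contra, segments)
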