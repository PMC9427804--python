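"""Forward kinetic models of early erythrocyte aggregation.

When stirring of a whole-blood sample stops, isolated erythrocytes
("A forms") begin to stick together two-by-two into doublets ("B forms"),
then into rouleaux and three-dimensional aggregates.  Isolated cells
backscatter far more light than aggregates, so the backscattered-light
intensity recorded by the device — the *syllectogram* — decays as
aggregation proceeds.  This module holds the domain types and the
closed-form forward evaluation of the three kinetic models used to
describe that decay:

* **second-order kinetics** (`eval_model1`): doublet formation limited by
  the concentration of isolated cells, ``d[B]/dt = k [A]^2``, whose
  solution is ``1/[A] = k t + 1/A0``;
* **first-order (mono-exponential) kinetics** (`eval_mono_exp`): the
  aggregation step itself is limiting, ``[A] = A0 exp(-k t)``;
* **bi-exponential syllectogram** (`eval_bi_exp`): the conventional
  description of a full 20 s recording as a fast (rouleaux) plus a slow
  (3-D aggregate) exponential above a baseline.

Two rate conventions coexist in this field and both are kept, typed and
documented rather than collapsed: the mono-exponential and second-order
models use a *rate constant* ``k`` in 1/s, while the bi-exponential model
uses *time constants* ``tau`` in seconds (decay ``exp(-t/tau)``).

Intensity is treated as directly proportional to the concentration of
isolated erythrocytes; absolute units are arbitrary and never interpreted.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
from numpy.typing import ArrayLike, NDArray

__all__ = [
    "LN2",
    "Syllectogram",
    "MonoExpParams",
    "Model1Params",
    "BiExpParams",
    "TubeGeometry",
    "eval_mono_exp",
    "eval_model1",
    "eval_bi_exp",
    "half_life",
]

LN2 = math.log(2.0)


def _as_time_array(times: ArrayLike) -> NDArray[np.float64]:
    t = np.asarray(times, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("times must be finite")
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    return t


@dataclass(frozen=True)
class Syllectogram:
    """A recorded (or simulated) backscattered-intensity time series.

    Parameters
    ----------
    times
        Sample times in seconds, strictly increasing, with ``times[0] == 0``
        (t = 0 is the end of stirring).
    intensities
        Backscattered-light intensity in arbitrary positive units.
    meta
        Free-form labels (subject id, tube id, minutes after blood draw...).
    """

    times: NDArray[np.float64]
    intensities: NDArray[np.float64]
    meta: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensities", y)
        if t.ndim != 1 or y.ndim != 1:
            raise ValueError("times and intensities must be 1-D")
        if len(t) != len(y):
            raise ValueError(
                f"length mismatch: {len(t)} times vs {len(y)} intensities"
            )
        if len(t) < 2:
            raise ValueError("a syllectogram needs at least 2 samples")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
            raise ValueError("times and intensities must be finite")
        if abs(t[0]) > 1e-9:
            raise ValueError(
                f"times must start at 0 (got {t[0]!r}); re-base before constructing"
            )
        if np.any(np.diff(t) <= 0):
            i = int(np.argmax(np.diff(t) <= 0))
            raise ValueError(f"times must be strictly increasing (violated at index {i + 1})")
        if np.any(y <= 0):
            i = int(np.argmax(y <= 0))
            raise ValueError(f"intensities must be positive (violated at index {i})")

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return float(self.times[-1])

    @property
    def n_samples(self) -> int:
        return len(self.times)

    def with_meta(self, **extra: Any) -> "Syllectogram":
        return Syllectogram(self.times, self.intensities, {**self.meta, **extra})


@dataclass(frozen=True)
class MonoExpParams:
    """First-order decay ``I(t) = a0 * exp(-k t)``.

    ``a0`` is the initial isolated-erythrocyte signal (arbitrary units);
    ``k`` is a **rate constant in 1/s** — half-life is ``ln 2 / k``.
    """

    a0: float
    k: float

    def __post_init__(self) -> None:
        if not (self.a0 > 0):
            raise ValueError(f"a0 must be > 0, got {self.a0}")
        if not (self.k > 0):
            raise ValueError(f"k must be > 0, got {self.k}")


@dataclass(frozen=True)
class Model1Params:
    """Second-order decay ``1/I(t) = k t + 1/a0``.

    ``a0`` is the initial concentration proxy; ``k`` the second-order rate
    constant (per intensity-unit per second).
    """

    a0: float
    k: float

    def __post_init__(self) -> None:
        if not (self.a0 > 0):
            raise ValueError(f"a0 must be > 0, got {self.a0}")
        if not (self.k > 0):
            raise ValueError(f"k must be > 0, got {self.k}")


@dataclass(frozen=True)
class BiExpParams:
    """Bi-exponential syllectogram model.

    ``I(t) = i_fast * exp(-t/tau_fast) + i_slow * exp(-t/tau_slow) + baseline``

    ``tau_fast`` and ``tau_slow`` are **time constants in seconds** (note
    the convention change relative to :class:`MonoExpParams`).  The fast
    component describes rouleaux formation, the slow one three-dimensional
    aggregation, the baseline the residual backscatter of fully aggregated
    blood.  When both amplitudes are positive the fast component must decay
    faster: ``tau_fast <= tau_slow``.
    """

    i_fast: float
    tau_fast: float
    i_slow: float
    tau_slow: float
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if not (self.tau_fast > 0 and self.tau_slow > 0):
            raise ValueError("time constants must be > 0")
        if self.i_fast < 0 or self.i_slow < 0 or self.baseline < 0:
            raise ValueError("amplitudes and baseline must be >= 0")
        if self.i_fast + self.i_slow <= 0:
            raise ValueError("at least one exponential amplitude must be positive")
        if self.i_fast > 0 and self.i_slow > 0 and self.tau_fast > self.tau_slow:
            raise ValueError(
                f"fast component must decay faster: tau_fast={self.tau_fast} > tau_slow={self.tau_slow}"
            )


@dataclass(frozen=True)
class TubeGeometry:
    """Geometry of the blood-collection tube during upside-down stirring.

    The stirring motion drives the air bubble along the tube axis; blood is
    forced through the gap between bubble and tube wall, which sets the
    shear rate.  All lengths in meters, volume in liters, frequency in Hz.
    """

    internal_diameter: float = 13e-3
    bubble_diameter: float = 12.76e-3
    blood_volume: float = 4e-3
    stroke_length: float = 60e-3
    frequency: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.bubble_diameter < self.internal_diameter):
            raise ValueError(
                "bubble_diameter must lie in (0, internal_diameter); "
                f"got {self.bubble_diameter} vs {self.internal_diameter}"
            )
        if not (self.frequency > 0 and self.stroke_length > 0 and self.blood_volume > 0):
            raise ValueError("frequency, stroke_length and blood_volume must be > 0")


def eval_mono_exp(params: MonoExpParams, times: ArrayLike) -> NDArray[np.float64]:
    """Evaluate the first-order model ``a0 * exp(-k t)`` elementwise."""
    t = _as_time_array(times)
    return params.a0 * np.exp(-params.k * t)


def eval_model1(params: Model1Params, times: ArrayLike) -> NDArray[np.float64]:
    """Evaluate the second-order model ``1 / (k t + 1/a0)`` elementwise."""
    t = _as_time_array(times)
    return 1.0 / (params.k * t + 1.0 / params.a0)


def eval_bi_exp(params: BiExpParams, times: ArrayLike) -> NDArray[np.float64]:
    """Evaluate the bi-exponential syllectogram model elementwise."""
    t = _as_time_array(times)
    return (
        params.i_fast * np.exp(-t / params.tau_fast)
        + params.i_slow * np.exp(-t / params.tau_slow)
        + params.baseline
    )


def half_life(k: float) -> float:
    """Half-life ``ln 2 / k`` of a first-order decay with rate constant ``k`` (1/s).

    Applied to the rate fitted on the first 5 s of a syllectogram this is
    the headline aggregation statistic (the 5 s half-life).
    """
    if not (k > 0):
        raise ValueError(f"rate constant must be > 0, got {k}")
    return LN2 / k
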