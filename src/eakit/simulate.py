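"""Synthetic syllectograms, subjects and cohorts; shear-rate estimation.

No public repository of raw syllectograms exists, so this module emulates
the measurement device and the three validation-study populations well
enough to exercise every other module end to end:

* :func:`simulate_syllectogram` — one noisy decay curve from a forward
  kinetic model (the device's 5 s or 20 s output);
* :func:`simulate_subject` — repeated measurements on one subject, with
  the repeat-to-repeat half-life variability observed on real blood
  (intra-individual CV ~2.6%);
* :func:`simulate_cohort` — a study group with normally distributed
  subject-level half-lives (healthy donors: 2.51 +/- 0.38 s);
* :func:`simulate_hematocrit_pairs` — paired hematocrit / half-life draws
  with a prescribed population correlation;
* :func:`estimate_shear_rate` — the bubble-stirring shear-rate estimate
  from tube geometry (velocity over bubble-to-wall gap, ~1000 1/s at 1 Hz).

Every stochastic operation is a pure function of its seed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .fitting import compute_eak5s
from .kinetics import (
    LN2,
    BiExpParams,
    MonoExpParams,
    Syllectogram,
    TubeGeometry,
    eval_bi_exp,
    eval_mono_exp,
)

__all__ = [
    "NoiseSpec",
    "CohortSpec",
    "ShearEstimate",
    "COHORT_PRESETS",
    "DEFAULT_A0",
    "simulate_syllectogram",
    "simulate_subject",
    "simulate_cohort",
    "simulate_hematocrit_pairs",
    "estimate_shear_rate",
]

logger = logging.getLogger(__name__)

#: Arbitrary initial intensity used by the generators (absolute units are
#: not meaningful for the kinetics, only the decay shape is).
DEFAULT_A0 = 1000.0

#: Default photodiode noise: additive Gaussian at 0.5% of the initial
#: intensity, which puts the closed-loop repeat CV of the fitted half-life
#: on the scale observed on real tubes (~2.3-2.6%).
DEFAULT_NOISE_FRACTION = 0.005

_MIN_HALF_LIFE = 0.2  # s; truncation floor for subject-level draws


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise model for simulated syllectograms.

    ``gaussian-additive`` adds N(0, sd) in intensity units; with
    ``gaussian-proportional`` the sd is a fraction of the instantaneous
    model intensity.  ``none`` returns the exact forward model.
    """

    kind: Literal["gaussian-additive", "gaussian-proportional", "none"] = "gaussian-additive"
    sd: float = DEFAULT_NOISE_FRACTION * DEFAULT_A0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian-additive", "gaussian-proportional", "none"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sd < 0:
            raise ValueError("noise sd must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """Distribution parameters of one study group.

    Subject-level 5 s half-lives are Normal(``eak5s_mean``, ``eak5s_sd``),
    truncated below at 0.2 s; each subject is measured
    ``repeats_per_subject`` times (an int, or an inclusive (lo, hi) range)
    with repeat-level variability ``intra_cv``.
    """

    n_subjects: int
    eak5s_mean: float
    eak5s_sd: float
    intra_cv: float = 0.026
    repeats_per_subject: int | tuple[int, int] = 1
    label: str = "cohort"

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not (self.eak5s_mean > 0):
            raise ValueError("eak5s_mean must be > 0")
        if self.eak5s_sd < 0 or self.intra_cv < 0:
            raise ValueError("eak5s_sd and intra_cv must be >= 0")
        r = self.repeats_per_subject
        if isinstance(r, tuple):
            if len(r) != 2 or r[0] > r[1] or r[0] < 0:
                raise ValueError(f"bad repeats range {r!r}")
        elif r < 0:
            raise ValueError("repeats_per_subject must be >= 0")


#: The four validation-study groups: healthy blood donors, cardiology
#: intensive-care patients, and the latter split by recent acute coronary
#: syndrome (ACS).  Repeat counts in the repeatability study ranged from
#: 19 to 22 measurements per patient.
COHORT_PRESETS: dict[str, CohortSpec] = {
    "healthy": CohortSpec(51, 2.51, 0.38, label="healthy"),
    "cardiology": CohortSpec(14, 1.73, 0.34, label="cardiology"),
    "acs": CohortSpec(6, 1.70, 0.17, label="acs"),
    "non-acs": CohortSpec(8, 1.76, 0.44, label="non-acs"),
}


@dataclass(frozen=True)
class ShearEstimate:
    """Shear-rate estimate for bubble stirring: ``shear_rate = velocity / gap``."""

    velocity: float  # m/s, mean bubble speed along the tube axis
    gap: float  # m, bubble-to-wall distance
    shear_rate: float  # 1/s

    def to_dict(self) -> dict:
        return {"velocity_m_per_s": self.velocity, "gap_m": self.gap,
                "shear_rate_per_s": self.shear_rate}


def _apply_noise(y: np.ndarray, noise: NoiseSpec, rng: np.random.Generator) -> np.ndarray:
    if noise.kind == "none" or noise.sd == 0:
        return y.copy()
    if noise.kind == "gaussian-additive":
        return y + rng.normal(0.0, noise.sd, size=y.shape)
    return y * (1.0 + rng.normal(0.0, noise.sd, size=y.shape))


def simulate_syllectogram(
    params: MonoExpParams | BiExpParams,
    duration: float = 5.0,
    sampling_rate: float = 100.0,
    noise: NoiseSpec | None = None,
    *,
    seed: int | None = None,
    meta: dict | None = None,
) -> Syllectogram:
    """Generate one syllectogram from a forward model plus measurement noise.

    The time grid runs from 0 to ``duration`` inclusive at ``sampling_rate``
    Hz (a 5 s recording at 100 Hz has 501 samples).  ``seed`` overrides
    ``noise.seed``.  Samples driven non-positive by noise are clipped to a
    tiny positive floor; each clip is logged, and a warning is emitted if
    more than 1% of samples clip.
    """
    if not (duration > 0 and sampling_rate > 0):
        raise ValueError("duration and sampling_rate must be > 0")
    noise = noise or NoiseSpec()
    if seed is not None:
        noise = replace(noise, seed=seed)
    n = int(round(duration * sampling_rate)) + 1
    t = np.arange(n) / sampling_rate

    if isinstance(params, MonoExpParams):
        clean = eval_mono_exp(params, t)
    elif isinstance(params, BiExpParams):
        clean = eval_bi_exp(params, t)
    else:
        raise TypeError(f"unsupported model parameters: {type(params).__name__}")

    rng = np.random.default_rng(noise.seed)
    y = _apply_noise(clean, noise, rng)
    floor = float(np.max(clean)) * 1e-9
    clipped = int(np.sum(y < floor))
    if clipped:
        logger.info("clipped %d/%d non-positive samples to %.3g", clipped, n, floor)
        if clipped > 0.01 * n:
            import warnings

            warnings.warn(
                f"noise sd {noise.sd:.3g} clipped {clipped}/{n} samples (> 1%)",
                stacklevel=2,
            )
        y = np.maximum(y, floor)
    return Syllectogram(t, y, meta or {})


def simulate_subject(
    true_eak5s: float,
    n_repeats: int,
    intra_cv: float,
    *,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    duration: float = 5.0,
    sampling_rate: float = 100.0,
    a0: float = DEFAULT_A0,
) -> list[Syllectogram]:
    """Repeated measurements on one subject.

    Each repeat draws its own half-life from Normal(``true_eak5s``,
    ``intra_cv * true_eak5s``) — the biological + handling variability seen
    between consecutive measurements of the same blood — converts it to a
    rate constant ``k = ln2 / half_life`` and generates a syllectogram at
    that rate.  Non-positive draws are redrawn (and logged).
    """
    if not (true_eak5s > 0):
        raise ValueError("true_eak5s must be > 0")
    if not (0 <= intra_cv < 0.5):
        raise ValueError("intra_cv must be in [0, 0.5)")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    rng = np.random.default_rng(seed)
    noise = noise or NoiseSpec(sd=DEFAULT_NOISE_FRACTION * a0)

    out: list[Syllectogram] = []
    for i in range(n_repeats):
        hl = rng.normal(true_eak5s, intra_cv * true_eak5s) if intra_cv > 0 else true_eak5s
        while hl <= 0:
            logger.info("redrawing non-positive half-life draw (%.3g)", hl)
            hl = rng.normal(true_eak5s, intra_cv * true_eak5s)
        params = MonoExpParams(a0=a0, k=LN2 / hl)
        rep_seed = int(rng.integers(0, 2**31 - 1))
        out.append(
            simulate_syllectogram(
                params, duration, sampling_rate, noise, seed=rep_seed,
                meta={"repeat_idx": i, "true_half_life_s": hl},
            )
        )
    return out


def _draw_repeats(spec: CohortSpec, rng: np.random.Generator) -> int:
    r = spec.repeats_per_subject
    if isinstance(r, tuple):
        return int(rng.integers(r[0], r[1] + 1))
    return int(r)


def simulate_cohort(
    spec: CohortSpec,
    seed: int = 0,
    *,
    duration: float = 5.0,
    sampling_rate: float = 100.0,
    noise: NoiseSpec | None = None,
    span_minutes: float = 60.0,
) -> pd.DataFrame:
    """Draw a study group and (optionally) measure every subject.

    Returns a tidy table with one row per measurement: ``subject_id``,
    ``group``, ``repeat_idx``, ``minutes_after_draw``, ``eak5s_true`` and
    ``eak5s_fitted``.  Repeats are spread evenly over ``span_minutes``
    after the blood draw.  With ``repeats_per_subject=0`` only the
    subject-level truth is returned (``eak5s_fitted`` is NaN) — handy for
    large sampling-distribution checks where fitting every curve is
    pointless.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for sid in range(spec.n_subjects):
        hl = rng.normal(spec.eak5s_mean, spec.eak5s_sd) if spec.eak5s_sd > 0 else spec.eak5s_mean
        while hl <= _MIN_HALF_LIFE:
            logger.info("redrawing subject half-life below %.2g s", _MIN_HALF_LIFE)
            hl = rng.normal(spec.eak5s_mean, spec.eak5s_sd)
        n_rep = _draw_repeats(spec, rng)
        if n_rep == 0:
            rows.append(
                {"subject_id": sid, "group": spec.label, "repeat_idx": pd.NA,
                 "minutes_after_draw": 0.0, "eak5s_true": hl, "eak5s_fitted": np.nan}
            )
            continue
        minutes = (
            np.linspace(0.0, span_minutes, n_rep) if n_rep > 1 else np.array([0.0])
        )
        reps = simulate_subject(
            hl, n_rep, spec.intra_cv,
            noise=noise, seed=int(rng.integers(0, 2**31 - 1)),
            duration=duration, sampling_rate=sampling_rate,
        )
        for i, s in enumerate(reps):
            fit = compute_eak5s(s)
            rows.append(
                {"subject_id": sid, "group": spec.label, "repeat_idx": i,
                 "minutes_after_draw": float(minutes[i]), "eak5s_true": hl,
                 "eak5s_fitted": fit.half_life_s}
            )
    return pd.DataFrame(rows)


def simulate_hematocrit_pairs(
    n: int,
    target_r: float,
    seed: int = 0,
    *,
    hct_range: tuple[float, float] = (23.6, 55.3),
    eak5s_mean: float = 2.51,
    eak5s_sd: float = 0.38,
) -> pd.DataFrame:
    """Paired (hematocrit %, half-life s) draws with population correlation ``target_r``.

    Hematocrit is uniform over ``hct_range`` (the span seen in emergency
    patients); the half-life is built as ``r * z_hct + sqrt(1-r^2) * e``
    on standardized scales, which gives the prescribed *population*
    correlation regardless of the marginals.
    """
    if n < 3:
        raise ValueError("need n >= 3 pairs")
    if not (-1.0 < target_r < 1.0):
        raise ValueError("target_r must be in (-1, 1)")
    rng = np.random.default_rng(seed)
    lo, hi = hct_range
    hct = rng.uniform(lo, hi, size=n)
    z_hct = (hct - (lo + hi) / 2.0) / ((hi - lo) / np.sqrt(12.0))
    e = rng.normal(0.0, 1.0, size=n)
    z = target_r * z_hct + np.sqrt(1.0 - target_r**2) * e
    eak5s = np.maximum(eak5s_mean + eak5s_sd * z, _MIN_HALF_LIFE)
    return pd.DataFrame({"hematocrit_pct": hct, "eak5s": eak5s})


def estimate_shear_rate(g: TubeGeometry) -> ShearEstimate:
    """Shear-rate estimate for the upside-down stirring motion.

    The bubble traverses the stroke once per half-cycle, so its mean speed
    is ``2 * stroke_length * frequency``; blood is sheared in the annular
    gap ``(internal_diameter - bubble_diameter) / 2`` between bubble and
    wall.  The estimate ``velocity / gap`` is an order-of-magnitude figure
    (~1000 1/s at 1 Hz with the default tube), not a flow-field solution.
    """
    gap = (g.internal_diameter - g.bubble_diameter) / 2.0
    if gap <= 0:
        raise ValueError("bubble-to-wall gap must be > 0")
    velocity = 2.0 * g.stroke_length * g.frequency
    return ShearEstimate(velocity=velocity, gap=gap, shear_rate=velocity / gap)
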