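"""Estimation of aggregation-kinetics parameters from syllectograms.

The workhorse is :func:`fit_mono_exp`: a nonlinear least-squares fit of
``I(t) = a0 * exp(-k t)`` (no offset by default — absolute intensities are
not meaningful, only the kinetics) to an initial segment of the recording.
The half-life ``ln 2 / k`` fitted on the first 5 s is the headline
statistic, computed by :func:`compute_eak5s`.

:func:`fit_inverse_linear` fits the competing second-order model by
ordinary least squares of ``1/I`` against ``t``; comparing its r²
with the mono-exponential one discriminates the two mechanisms.

:func:`fit_bi_exp` decomposes a full-length (>= 15 s) recording into fast
and slow exponential components above a baseline, initialized by classical
curve peeling (fit the slow tail, strip it, fit the fast remainder) and
refined by nonlinear least squares.

All r² values are ``1 - SS_res/SS_tot`` computed on the scale actually
fitted: the intensity scale for the exponential models, the inverse
intensity scale for the second-order (linear) model.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from numpy.typing import NDArray
from scipy.optimize import least_squares

from .kinetics import (
    LN2,
    BiExpParams,
    MonoExpParams,
    Syllectogram,
    eval_bi_exp,
    eval_mono_exp,
    half_life,
)

__all__ = [
    "NonDecayingSignalError",
    "PoorlyIdentifiableWarning",
    "MonoExpFit",
    "Model1Fit",
    "BiExpFit",
    "SegmentSelection",
    "DEFAULT_SEGMENT_DURATIONS",
    "extract_segment",
    "fit_mono_exp",
    "fit_inverse_linear",
    "fit_bi_exp",
    "select_best_segment",
    "compute_eak5s",
]

#: Segment lengths (s) routinely compared when choosing the best fit window.
DEFAULT_SEGMENT_DURATIONS: tuple[float, ...] = (1.5, 3.0, 5.0, 10.0)

# least-squares convergence: relative parameter tolerance and iteration cap
_XTOL = 1e-10
_MAX_ITER = 200

_MIN_FIT_SAMPLES = 8


class NonDecayingSignalError(ValueError):
    """The intensity does not decay, so no aggregation kinetics can be fitted."""


class PoorlyIdentifiableWarning(UserWarning):
    """The two exponential components are too close in time scale to separate."""


def _r2(observed: NDArray[np.float64], predicted: NDArray[np.float64]) -> float:
    ss_res = float(np.sum((observed - predicted) ** 2))
    ss_tot = float(np.sum((observed - np.mean(observed)) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else -math.inf
    return 1.0 - ss_res / ss_tot


@dataclass(frozen=True)
class MonoExpFit:
    """Mono-exponential fit of a syllectogram segment.

    ``half_life_s`` equals ``ln 2 / params.k``; when ``segment_duration``
    is 5 s this is the 5 s aggregation half-life.
    """

    params: MonoExpParams
    segment_duration: float
    r2: float
    half_life_s: float
    n_points: int
    converged: bool
    offset: float | None = None

    def to_dict(self) -> dict:
        d = {
            "a0": self.params.a0,
            "k_per_s": self.params.k,
            "half_life_s": self.half_life_s,
            "r2": self.r2,
            "segment_duration_s": self.segment_duration,
            "n_points": self.n_points,
            "converged": self.converged,
        }
        if self.offset is not None:
            d["offset"] = self.offset
        return d


@dataclass(frozen=True)
class Model1Fit:
    """Ordinary least-squares fit of ``1/I`` against ``t`` (second-order model).

    ``slope`` estimates the second-order rate constant k, ``intercept``
    estimates ``1/a0``; ``r2`` is computed on the inverse-intensity scale.
    """

    slope: float
    intercept: float
    r2: float
    n_points: int
    underdetermined: bool = False

    def to_dict(self) -> dict:
        return {
            "slope_k": self.slope,
            "intercept_inv_a0": self.intercept,
            "r2": self.r2,
            "n_points": self.n_points,
            "underdetermined": self.underdetermined,
        }


@dataclass(frozen=True)
class BiExpFit:
    """Bi-exponential decomposition of a full-length syllectogram."""

    params: BiExpParams
    r2: float
    converged: bool
    init_params: BiExpParams
    clamped: bool = False

    def to_dict(self) -> dict:
        p = self.params
        return {
            "i_fast": p.i_fast,
            "tau_fast_s": p.tau_fast,
            "i_slow": p.i_slow,
            "tau_slow_s": p.tau_slow,
            "baseline": p.baseline,
            "r2": self.r2,
            "converged": self.converged,
            "clamped": self.clamped,
        }


@dataclass(frozen=True)
class SegmentSelection:
    """Mono-exponential fits over several segment lengths and the best one."""

    fits: Mapping[float, MonoExpFit]
    best_duration: float
    rule: str

    @property
    def best(self) -> MonoExpFit:
        return self.fits[self.best_duration]

    def to_dict(self) -> dict:
        return {
            "best_duration_s": self.best_duration,
            "rule": self.rule,
            "fits": {str(d): f.to_dict() for d, f in self.fits.items()},
        }


def extract_segment(s: Syllectogram, duration: float) -> Syllectogram:
    """Return the initial segment with ``t <= duration`` (endpoint inclusive)."""
    if not (duration > 0):
        raise ValueError(f"duration must be > 0, got {duration}")
    if s.duration + 1e-12 < duration:
        raise ValueError(
            f"requested {duration} s segment but recording covers only {s.duration} s"
        )
    mask = s.times <= duration + 1e-12
    return Syllectogram(s.times[mask], s.intensities[mask], dict(s.meta))


def _log_linear_init(t: NDArray[np.float64], y: NDArray[np.float64]) -> tuple[float, float]:
    """Slope/intercept of ln(I) on t; deterministic, seed-free starting point."""
    slope, intercept = np.polyfit(t, np.log(y), 1)
    return float(slope), float(intercept)


def fit_mono_exp(segment: Syllectogram, *, with_offset: bool = False) -> MonoExpFit:
    """Least-squares fit of ``a0 * exp(-k t)`` to a syllectogram segment.

    Starting values come from a log-linear regression of ``ln I`` on ``t``;
    the nonlinear refinement minimises residuals on the intensity scale.
    ``with_offset=True`` adds a constant baseline term (off by default: the
    first-order model has none and absolute intensities carry no meaning).

    Raises
    ------
    NonDecayingSignalError
        If the log-linear slope of the segment is >= 0 (constant or rising
        signal): there is no decay to quantify.
    """
    t, y = segment.times, segment.intensities
    if len(t) < _MIN_FIT_SAMPLES:
        raise ValueError(f"need >= {_MIN_FIT_SAMPLES} samples, got {len(t)}")

    slope, intercept = _log_linear_init(t, y)
    # tolerance absorbs round-off on flat signals (polyfit of a constant can
    # return a slope of order 1e-17 of either sign)
    if slope >= -1e-10 * (1.0 + abs(intercept)):
        raise NonDecayingSignalError(
            f"signal does not decay (log-linear slope {slope:.3g} >= 0)"
        )
    a0_init, k_init = math.exp(intercept), -slope

    if with_offset:
        x0 = np.array([a0_init, k_init, float(np.min(y)) * 0.1])
        lower = np.array([1e-300, 1e-300, 0.0])

        def resid(p: NDArray[np.float64]) -> NDArray[np.float64]:
            return p[0] * np.exp(-p[1] * t) + p[2] - y

    else:
        x0 = np.array([a0_init, k_init])
        lower = np.array([1e-300, 1e-300])

        def resid(p: NDArray[np.float64]) -> NDArray[np.float64]:
            return p[0] * np.exp(-p[1] * t) - y

    res = least_squares(
        resid, x0, bounds=(lower, np.inf), xtol=_XTOL, ftol=_XTOL, gtol=None,
        max_nfev=_MAX_ITER * (len(x0) + 1),
    )
    a0_hat, k_hat = float(res.x[0]), float(res.x[1])
    offset = float(res.x[2]) if with_offset else None
    params = MonoExpParams(a0=a0_hat, k=k_hat)
    pred = eval_mono_exp(params, t) + (offset or 0.0)
    return MonoExpFit(
        params=params,
        segment_duration=segment.duration,
        r2=_r2(y, pred),
        half_life_s=half_life(k_hat),
        n_points=len(t),
        converged=bool(res.success),
        offset=offset,
    )


def fit_inverse_linear(segment: Syllectogram) -> Model1Fit:
    """OLS fit of ``1/I`` against ``t``: the second-order (linear) model.

    With only two points the line is exact by construction; the fit is then
    flagged ``underdetermined`` rather than rejected.
    """
    t, y = segment.times, segment.intensities
    inv = 1.0 / y
    slope, intercept = np.polyfit(t, inv, 1)
    pred = slope * t + intercept
    return Model1Fit(
        slope=float(slope),
        intercept=float(intercept),
        r2=_r2(inv, pred),
        n_points=len(t),
        underdetermined=len(t) <= 2,
    )


def _peel(t: NDArray[np.float64], y: NDArray[np.float64]) -> BiExpParams:
    """Curve-peeling initialization of the bi-exponential model.

    Baseline from the mean of the final 5% of samples; slow component from a
    log-linear fit of the baseline-subtracted last third of the recording;
    fast component from the same fit of the stripped first 3 s.
    """
    n = len(t)
    n_tail = max(2, int(round(0.05 * n)))
    baseline = float(np.mean(y[-n_tail:]))

    duration = t[-1]
    tail = t >= duration * (2.0 / 3.0)
    y_tail = y[tail] - baseline
    ok = y_tail > 0
    if ok.sum() < 2:
        # tail already at baseline: assume no resolvable slow component
        tau_slow, i_slow = duration, 0.0
    else:
        slope, intercept = np.polyfit(t[tail][ok], np.log(y_tail[ok]), 1)
        if slope >= 0:
            tau_slow, i_slow = duration, 0.0
        else:
            tau_slow, i_slow = -1.0 / slope, math.exp(intercept)

    head = t <= min(3.0, duration / 3.0)
    y_head = y[head] - baseline - i_slow * np.exp(-t[head] / tau_slow)
    ok = y_head > 0
    if ok.sum() < 2:
        tau_fast, i_fast = tau_slow / 10.0, 0.0
    else:
        slope, intercept = np.polyfit(t[head][ok], np.log(y_head[ok]), 1)
        if slope >= 0:
            tau_fast, i_fast = tau_slow / 10.0, 0.0
        else:
            tau_fast, i_fast = -1.0 / slope, math.exp(intercept)

    if tau_fast > tau_slow:
        tau_fast, tau_slow = tau_slow, tau_fast
        i_fast, i_slow = i_slow, i_fast
    if i_fast <= 0 and i_slow <= 0:
        # pathological stripping; fall back to a crude but valid start
        i_fast = max(float(y[0] - baseline), 1e-6)
    return BiExpParams(
        i_fast=max(i_fast, 0.0),
        tau_fast=tau_fast,
        i_slow=max(i_slow, 0.0),
        tau_slow=tau_slow,
        baseline=max(baseline, 0.0),
    )


def _biexp_resid(p: NDArray[np.float64], t: NDArray[np.float64], y: NDArray[np.float64]
                 ) -> NDArray[np.float64]:
    return p[0] * np.exp(-t / p[1]) + p[2] * np.exp(-t / p[3]) + p[4] - y


def fit_bi_exp(s: Syllectogram) -> BiExpFit:
    """Bi-exponential decomposition of a full-length (>= 15 s) recording.

    Initialized by curve peeling (see :func:`_peel`), refined by nonlinear
    least squares on all five constants.  Components are ordered so the
    fast one decays faster.  If the two time constants end up separated by
    less than a factor of two, a :class:`PoorlyIdentifiableWarning` is
    issued; a negative fitted amplitude triggers a refit with that
    amplitude clamped to zero (``clamped=True`` on the result).
    """
    t, y = s.times, s.intensities
    if len(t) < _MIN_FIT_SAMPLES:
        raise ValueError(f"need >= {_MIN_FIT_SAMPLES} samples, got {len(t)}")
    if s.duration < 15.0:
        raise ValueError(
            f"bi-exponential decomposition needs >= 15 s of recording, got {s.duration} s"
        )

    init = _peel(t, y)
    x0 = np.array([init.i_fast, init.tau_fast, init.i_slow, init.tau_slow, init.baseline])
    # time constants strictly positive; amplitudes free so a sign flip is
    # detectable and handled by the clamped refit below
    lower = np.array([-np.inf, 1e-6, -np.inf, 1e-6, -np.inf])
    res = least_squares(
        _biexp_resid, x0, args=(t, y), bounds=(lower, np.inf),
        xtol=_XTOL, ftol=_XTOL, gtol=None, max_nfev=_MAX_ITER * 6,
    )
    x = res.x
    converged = bool(res.success)

    clamped = False
    if x[0] < 0 or x[2] < 0 or x[4] < 0:
        clamped = True
        lower2 = np.array([0.0, 1e-6, 0.0, 1e-6, 0.0])
        x0c = np.clip(x0, lower2 + 1e-12, None)
        res = least_squares(
            _biexp_resid, x0c, args=(t, y), bounds=(lower2, np.inf),
            xtol=_XTOL, ftol=_XTOL, gtol=None, max_nfev=_MAX_ITER * 6,
        )
        x = res.x
        converged = bool(res.success)

    i_f, tau_f, i_s, tau_s, base = (float(v) for v in x)
    if tau_f > tau_s:
        i_f, i_s = i_s, i_f
        tau_f, tau_s = tau_s, tau_f
    if tau_s / tau_f < 2.0:
        warnings.warn(
            f"time constants poorly identifiable: tau_slow/tau_fast = {tau_s / tau_f:.2f} < 2",
            PoorlyIdentifiableWarning,
            stacklevel=2,
        )
    elif min(i_f, i_s) < 1e-3 * (abs(i_f) + abs(i_s)):
        # one component carries essentially no amplitude: the data are
        # single-exponential and the second time constant is arbitrary
        warnings.warn(
            "second component poorly identifiable: its amplitude is negligible",
            PoorlyIdentifiableWarning,
            stacklevel=2,
        )
    params = BiExpParams(
        i_fast=max(i_f, 0.0), tau_fast=tau_f,
        i_slow=max(i_s, 0.0), tau_slow=tau_s,
        baseline=max(base, 0.0),
    )
    pred = eval_bi_exp(params, t)
    return BiExpFit(params=params, r2=_r2(y, pred), converged=converged,
                    init_params=init, clamped=clamped)


def select_best_segment(
    s: Syllectogram,
    durations: Sequence[float] = DEFAULT_SEGMENT_DURATIONS,
    *,
    tie_tol: float = 1e-4,
) -> SegmentSelection:
    """Fit every segment length and pick the one with the highest r².

    Ties (r² within ``tie_tol`` of the maximum) resolve to the shortest
    segment: the early two-by-two aggregation phase is the one the
    first-order model actually describes, so when fit quality is equal the
    shortest window is the most defensible.
    """
    durations = sorted(float(d) for d in durations)
    if s.duration + 1e-12 < durations[-1]:
        raise ValueError(
            f"recording of {s.duration} s cannot cover the {durations[-1]} s segment"
        )
    fits: dict[float, MonoExpFit] = {}
    for d in durations:
        fits[d] = fit_mono_exp(extract_segment(s, d))
    usable = {d: f for d, f in fits.items() if f.converged}
    if not usable:
        raise RuntimeError("no segment fit converged")
    best_r2 = max(f.r2 for f in usable.values())
    tied = [d for d, f in usable.items() if best_r2 - f.r2 < tie_tol]
    if len(tied) > 1:
        return SegmentSelection(fits=fits, best_duration=min(tied), rule="tie-shortest")
    return SegmentSelection(fits=fits, best_duration=tied[0], rule="max-r2")


def compute_eak5s(s: Syllectogram) -> MonoExpFit:
    """The headline statistic: mono-exponential half-life of the first 5 s.

    Equivalent to ``fit_mono_exp(extract_segment(s, 5))``; the returned
    fit's ``half_life_s`` is the 5 s aggregation half-life.
    """
    return fit_mono_exp(extract_segment(s, 5.0))
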