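"""FRAP recovery kinetics.

Double normalization of photobleaching traces and half-life estimation by
logarithmic regression.  A trace carries four channels: time, bleach-spot
intensity, an unbleached control cell (photobleaching/drift reference) and
background.  The normalized fluorescence is

    N(t) = (control_prebleach_mean - bg(t)) / (control(t) - bg(t))
         * (frap(t) - bg(t)) / (frap_prebleach_mean - bg(t)),

which is ~1 before the bleach for a photostable control.  Recovery is
summarized by fitting F = a + b*ln t over post-bleach times in (0, 150] s
(recovery curves are close to log-linear in that window) and inverting the
fitted curve at the level halfway between the post-bleach minimum F0 and
the end-of-series plateau F' (mean of the last 10 points):

    t_1/2 = t((F' - F0) * 0.5 + F0) - t(F0),   t(L) = exp((L - a) / b).

Times are measured from the first post-bleach frame, which defines F0 but
is excluded from the log fit (ln 0 undefined).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import (
    DegenerateTraceError,
    InvalidConfigurationError,
    NoRecoveryError,
)


@dataclass
class FrapTrace:
    """One cell's intensity series: prebleach frames then post-bleach frames."""

    times: np.ndarray
    frap: np.ndarray
    control: np.ndarray
    background: np.ndarray
    n_prebleach: int = 5

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.frap = np.asarray(self.frap, dtype=float)
        self.control = np.asarray(self.control, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        n = self.times.size
        for name in ("frap", "control", "background"):
            if getattr(self, name).size != n:
                raise DegenerateTraceError(f"channel {name} length != times")
        if n < 2 or (np.diff(self.times) <= 0).any():
            raise DegenerateTraceError("times must be strictly increasing")
        if self.n_prebleach < 1:
            raise InvalidConfigurationError("n_prebleach must be >= 1")
        if n - self.n_prebleach < 10:
            raise DegenerateTraceError("need >= 10 post-bleach points")


@dataclass
class RecoveryFit:
    a: float          # intercept of F = a + b ln t
    b: float          # slope (must be > 0 for recovery)
    f0: float         # post-bleach minimum (first post-bleach frame)
    f_prime: float    # plateau: mean of the last 10 normalized points
    half_life: float  # seconds
    n_fit: int
    fit_window: float
    extrapolated: bool  # half-recovery level beyond the fitted time range


def normalize_trace(trace: FrapTrace) -> np.ndarray:
    """Double-normalized fluorescence N(t) for the whole series."""
    npre = trace.n_prebleach
    bg = trace.background
    # raw prebleach channel means, used against bg(t) at every frame
    control_pre = float(np.mean(trace.control[:npre]))
    frap_pre = float(np.mean(trace.frap[:npre]))
    den_control = trace.control - bg
    den_frap = frap_pre - bg
    if (den_control <= 0).any() or (den_frap <= 0).any():
        raise DegenerateTraceError("nonpositive normalization denominator")
    return ((control_pre - bg) / den_control) * ((trace.frap - bg) / den_frap)


def fit_half_life(
    times: np.ndarray,
    normalized: np.ndarray,
    n_prebleach: int = 5,
    fit_window: float = 150.0,
    t0_mode: str = "inversion",
) -> RecoveryFit:
    """Half-life of recovery from a normalized series.

    ``t0_mode='inversion'`` evaluates t(F0) on the fitted curve (so the
    reported half-life is t(L) - t(F0)); ``'zero'`` takes t(F0) = 0.
    """
    if t0_mode not in ("inversion", "zero"):
        raise InvalidConfigurationError(f"unknown t0_mode {t0_mode!r}")
    if fit_window <= 0:
        raise InvalidConfigurationError("fit_window must be positive")
    times = np.asarray(times, dtype=float)
    normalized = np.asarray(normalized, dtype=float)
    post_t = times[n_prebleach:] - times[n_prebleach]
    post_v = normalized[n_prebleach:]
    if post_v.size < 10:
        raise DegenerateTraceError("need >= 10 post-bleach points")
    f0 = float(post_v[0])
    f_prime = float(post_v[-10:].mean())
    mask = (post_t > 0) & (post_t <= fit_window)
    if mask.sum() < 10:
        raise DegenerateTraceError(
            f"fewer than 10 post-bleach points in (0, {fit_window}] s"
        )
    res = stats.linregress(np.log(post_t[mask]), post_v[mask])
    a, b = float(res.intercept), float(res.slope)
    if b <= 1e-12:  # flat series regress to slope 0 up to rounding
        raise NoRecoveryError("log-fit slope <= 0: no recovery detected")
    level = f0 + 0.5 * (f_prime - f0)
    t_level = float(np.exp((level - a) / b))
    t_f0 = float(np.exp((f0 - a) / b)) if t0_mode == "inversion" else 0.0
    extrapolated = t_level > float(post_t[mask].max())
    return RecoveryFit(
        a=a,
        b=b,
        f0=f0,
        f_prime=f_prime,
        half_life=t_level - t_f0,
        n_fit=int(mask.sum()),
        fit_window=fit_window,
        extrapolated=extrapolated,
    )


def half_life(trace: FrapTrace, fit_window: float = 150.0,
              t0_mode: str = "inversion") -> RecoveryFit:
    """Normalize a trace and fit its recovery half-life."""
    return fit_half_life(
        trace.times,
        normalize_trace(trace),
        n_prebleach=trace.n_prebleach,
        fit_window=fit_window,
        t0_mode=t0_mode,
    )
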