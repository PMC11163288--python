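"""FRAP trace normalization, recovery fitting, and trace averaging.

Recovery is modelled with a single exponential,

    F(t) = (1 - d) + d * m * (1 - exp(-k (t - t0))),

where ``d`` is the bleach depth (fixed from the first post-bleach sample),
``m`` the mobile fraction and ``k`` the recovery rate.  The model cleanly
separates the regimes of interest: no recovery (solid-like aggregates,
m = 0), partial recovery (condensates with an immobile component) and full
recovery (m = 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit


@dataclass
class FRAPTrace:
    """Normalized recovery time series; ``bleach_index`` is the first
    post-bleach sample."""

    time_s: np.ndarray
    intensity: np.ndarray
    bleach_index: int

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time_s.shape != self.intensity.shape:
            raise ValueError("time and intensity must have equal length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")
        if not 0 < self.bleach_index < self.time_s.size:
            raise ValueError("bleach_index out of range")

    @property
    def post(self) -> tuple[np.ndarray, np.ndarray]:
        i = self.bleach_index
        return self.time_s[i:], self.intensity[i:]


@dataclass
class FRAPFit:
    """Single-exponential recovery fit result."""

    mobile_fraction: float
    rate_per_s: float
    bleach_depth: float
    residual_rms: float
    rate_identifiable: bool = True

    @property
    def plateau(self) -> float:
        return (1 - self.bleach_depth) + self.bleach_depth * self.mobile_fraction


class FitError(RuntimeError):
    pass


def normalize_trace(raw, bleach_index: int, time_s=None) -> FRAPTrace:
    """Divide every sample by the first pre-bleach intensity."""
    raw = np.asarray(raw, dtype=float)
    if raw[0] <= 0:
        raise ValueError("first pre-bleach intensity must be > 0 to normalize")
    if time_s is None:
        time_s = np.arange(raw.size, dtype=float)
    return FRAPTrace(time_s=np.asarray(time_s, float), intensity=raw / raw[0],
                     bleach_index=bleach_index)


def fit_recovery(trace: FRAPTrace) -> FRAPFit:
    """Fit the single-exponential recovery of a normalized trace.

    The bleach depth ``d`` is fixed from the first post-bleach sample
    (d = 1 - F(t0)); mobile fraction m in [0, 1] and rate k >= 0 are fitted
    by least squares over the post-bleach samples.  A flat trace returns
    m = 0 with the rate flagged unidentifiable rather than an arbitrary k.
    """
    if trace.bleach_index < 2:
        raise ValueError("need >= 2 pre-bleach samples")
    t, f = trace.post
    if t.size < 5:
        raise ValueError("need >= 5 post-bleach samples for a fit")
    t0, f0 = t[0], f[0]
    d = 1.0 - f0
    if d <= 0:
        raise FitError(f"no bleach detected: first post-bleach value {f0:.3g} >= 1")
    rise = float(np.mean(f[-max(3, t.size // 5):]) - f0)
    if rise <= 1e-9:
        resid = f - f0
        return FRAPFit(0.0, float("nan"), d, float(np.sqrt(np.mean(resid**2))),
                       rate_identifiable=False)

    def model(tt, m, k):
        return (1 - d) + d * m * (1 - np.exp(-k * (tt - t0)))

    m0 = min(max(rise / d, 1e-3), 1.0)
    span = t[-1] - t0
    k0 = 2.0 / span if span > 0 else 1.0
    try:
        popt, _ = curve_fit(model, t, f, p0=[m0, k0],
                            bounds=([0.0, 0.0], [1.0, np.inf]), maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - defensive
        raise FitError(
            f"recovery fit did not converge (p0=m{m0:.3g},k{k0:.3g}; "
            f"n={t.size}, rise={rise:.3g})"
        ) from exc
    m_hat, k_hat = float(popt[0]), float(popt[1])
    resid = f - model(t, *popt)
    rms = float(np.sqrt(np.mean(resid**2)))
    if m_hat < 1e-6:
        return FRAPFit(0.0, float("nan"), d, rms, rate_identifiable=False)
    return FRAPFit(m_hat, k_hat, d, rms, rate_identifiable=True)


def average_traces(traces: list[FRAPTrace]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pointwise mean and SE across traces.

    Traces on a common time grid are averaged directly; otherwise each is
    linearly interpolated onto the union grid restricted to the overlap of
    all time supports.  Returns ``(time, mean, se)``.
    """
    if len(traces) < 2:
        raise ValueError("need >= 2 traces")
    grids = [tr.time_s for tr in traces]
    same = all(g.shape == grids[0].shape and np.allclose(g, grids[0]) for g in grids)
    if same:
        time = grids[0]
        mat = np.vstack([tr.intensity for tr in traces])
    else:
        lo = max(g[0] for g in grids)
        hi = min(g[-1] for g in grids)
        if lo >= hi:
            raise ValueError("traces have disjoint time supports")
        union = np.unique(np.concatenate(grids))
        time = union[(union >= lo) & (union <= hi)]
        mat = np.vstack([np.interp(time, tr.time_s, tr.intensity) for tr in traces])
    mean = mat.mean(axis=0)
    se = mat.std(axis=0, ddof=1) / np.sqrt(len(traces))
    return time, mean, se
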