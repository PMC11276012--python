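"""Interaction persistence: indicator series, autocorrelation, lifetimes.

The persistence of an interaction (direct polar contact or water bridge)
is quantified through its binary presence indicator h(t) and the
*intermittent* (history-independent) autocorrelation

    C(t) = <h(s) h(s+t)>_s / <h(s)^2>_s ,

which equals 1 at t = 0 and decays to the stationary occupancy for an
uncorrelated process.  The correlation time tau is extracted either by
integrating the plateau-corrected curve,

    tau = integral_0^L  (C(t) - C_inf) / (1 - C_inf) dt ,

with C_inf estimated from the tail of the curve, or by least-squares fit
of C(t) = C_inf + (1 - C_inf) exp(-t / tau).  A curve that never decays
below (1 - plateau_tol) is *censored*: tau is then only a lower bound,
equal to the maximum usable lag.

The intermittent definition is the appropriate one when an interaction
breaks and reforms on timescales short against the decay of interest —
in particular for water bridges whose bridging water exchanges rapidly
with bulk solvent while the bridge as a connectivity pattern persists.
Correlation times of the same order as the trajectory length are only
meaningful with this definition (a continuous/first-passage lifetime
could never exceed the longest unbroken stretch).

Replica aggregation: independent simulations are the statistical unit;
values are summarised as mean ± SEM over replicas.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .contacts import WaterBridge
from .errors import ContractViolationError, NoEventError

__all__ = [
    "IndicatorSeries",
    "CorrelationResult",
    "ReplicaAggregate",
    "WaterExchangeSummary",
    "indicator_series",
    "indicator_from_categories",
    "autocorrelation",
    "correlation_time",
    "aggregate_replicas",
    "water_exchange",
]

INDICATOR_MODES = ("direct", "water_mediated", "any_polar")


@dataclass
class IndicatorSeries:
    """Binary presence indicator of one interaction in one replica."""

    replica_id: int
    times_ns: np.ndarray
    h: np.ndarray
    interaction_key: tuple | str = ""

    def __post_init__(self) -> None:
        self.times_ns = np.asarray(self.times_ns, dtype=float)
        self.h = np.asarray(self.h, dtype=np.int8)
        if len(self.h) != len(self.times_ns):
            raise ValueError("h and times_ns length mismatch")
        if len(self.times_ns) == 0:
            raise ValueError("empty indicator series")
        if len(self.times_ns) > 1:
            dt = np.diff(self.times_ns)
            if np.any(dt <= 0):
                raise ValueError("times must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("times must be uniformly spaced")

    @property
    def dt_ns(self) -> float:
        if len(self.times_ns) < 2:
            return 0.0
        return float(self.times_ns[1] - self.times_ns[0])

    @property
    def mean_occupancy(self) -> float:
        return float(self.h.mean())


@dataclass
class CorrelationResult:
    """Autocorrelation curve and (optionally) its correlation time."""

    lags_ns: np.ndarray
    C: np.ndarray
    mean_occupancy: float
    tau_ns: float | None = None
    tau_method: str | None = None
    censored: bool = False
    replica_id: int | None = None
    interaction_key: tuple | str = ""

    def __post_init__(self) -> None:
        self.lags_ns = np.asarray(self.lags_ns, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        if len(self.lags_ns) != len(self.C):
            raise ValueError("lags and C length mismatch")
        if len(self.lags_ns) == 0 or self.lags_ns[0] != 0.0:
            raise ValueError("lags must start at 0")


@dataclass
class ReplicaAggregate:
    """Per-replica values with mean and standard error across replicas."""

    values: list[float]
    mean: float
    sem: float  # NaN when n == 1 (undefined)
    n: int


@dataclass
class WaterExchangeSummary:
    """Identity turnover of bridging waters for one interaction."""

    interaction_key: tuple | str
    n_bridge_frames: int
    n_identity_switches: int
    distinct_waters: int

    @property
    def switch_fraction(self) -> float:
        """Switches per opportunity (pairs of successive bridge frames)."""
        opportunities = max(0, self.n_bridge_frames - 1)
        return self.n_identity_switches / opportunities if opportunities else 0.0


# ---------------------------------------------------------------------------
# Indicator construction
# ---------------------------------------------------------------------------


def indicator_series(
    frame_contacts: Sequence[Mapping],
    times_ns: Sequence[float],
    mode: str,
    replica_id: int = 0,
    interaction_key: tuple | str = "",
) -> IndicatorSeries:
    """Build h(t) from per-frame contact bundles.

    ``frame_contacts`` is one mapping per frame with keys ``"direct"``
    (direct H-bonds/salt bridges to the focal residue) and ``"bridges"``
    (water bridges to the pocket set).  Modes:

    * ``direct`` — any direct contact present;
    * ``water_mediated`` — any water bridge present, *regardless of the
      identity of the bridging water* (identity-agnostic: a bridge via
      water #501 in one frame and #733 in the next is one uninterrupted
      water-mediated interaction);
    * ``any_polar`` — either of the above.
    """
    if mode not in INDICATOR_MODES:
        raise ValueError(f"mode must be one of {INDICATOR_MODES}")
    if len(frame_contacts) == 0:
        raise ValueError("empty frame range")
    h = np.zeros(len(frame_contacts), dtype=np.int8)
    for i, fc in enumerate(frame_contacts):
        direct = bool(fc.get("direct"))
        bridged = bool(fc.get("bridges"))
        if mode == "direct":
            h[i] = direct
        elif mode == "water_mediated":
            h[i] = bridged
        else:
            h[i] = direct or bridged
    return IndicatorSeries(
        replica_id=replica_id,
        times_ns=np.asarray(times_ns, dtype=float),
        h=h,
        interaction_key=interaction_key or mode,
    )


def indicator_from_categories(
    categories: Sequence,
    times_ns: Sequence[float],
    mode: str = "direct",
    replica_id: int = 0,
) -> IndicatorSeries:
    """h(t) from a per-frame category series.

    ``direct`` marks DIRECT_INTERACTION frames, ``water_only`` marks
    WATER_MEDIATED_ONLY frames, ``any_polar`` marks any polar contact.
    (Categories cannot express "water bridge alongside direct contact";
    use :func:`indicator_series` on contact bundles for that.)
    """
    from .contacts import ContactCategory

    names = [c.value if isinstance(c, ContactCategory) else str(c) for c in categories]
    if mode == "direct":
        h = [n == "DIRECT_INTERACTION" for n in names]
    elif mode == "water_only":
        h = [n == "WATER_MEDIATED_ONLY" for n in names]
    elif mode == "any_polar":
        h = [n != "NO_POLAR_CONTACT" for n in names]
    else:
        raise ValueError("mode must be direct, water_only or any_polar")
    return IndicatorSeries(
        replica_id=replica_id,
        times_ns=np.asarray(times_ns, dtype=float),
        h=np.asarray(h, dtype=np.int8),
        interaction_key=mode,
    )


# ---------------------------------------------------------------------------
# Autocorrelation and correlation time
# ---------------------------------------------------------------------------


def autocorrelation(
    series: IndicatorSeries, max_lag_ns: float | None = None
) -> CorrelationResult:
    """Intermittent autocorrelation C(t) of a binary indicator.

    C(t) = <h(s) h(s+t)>_s / <h(s)^2>_s, with both averages taken over
    the same valid time origins s in [0, n-t): this windowed
    normalisation keeps the finite-sample estimate inside [0, 1] for
    binary h and pins C(0) = 1 exactly (a full-series denominator can
    push C above 1 when events cluster late in the series).  The default
    maximum lag is half the series duration — longer lags have too few
    origins for stable estimates.
    """
    h = series.h.astype(float)
    n = len(h)
    if not np.any(h):
        raise NoEventError("indicator is identically zero", mean_occupancy=0.0)
    duration = series.times_ns[-1] - series.times_ns[0]
    dt = series.dt_ns if n > 1 else 1.0
    if max_lag_ns is None:
        max_lag_ns = duration / 2.0
    elif max_lag_ns > duration / 2.0 + 1e-9:
        raise ValueError("max_lag_ns exceeds half the series duration")
    max_k = int(round(max_lag_ns / dt)) if n > 1 else 0
    max_k = min(max_k, n - 1)

    # lagged products Sum_s h[s] h[s+k] via correlation; denominator is
    # Sum over the same origins of h[s]^2 (= prefix sums for binary h)
    raw = np.correlate(h, h, mode="full")[n - 1 : n + max_k]
    prefix = np.cumsum(h * h)
    denom = prefix[n - 1 - np.arange(max_k + 1)]
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.where(denom > 0, raw / denom, 0.0)
    lags = np.arange(max_k + 1) * dt
    return CorrelationResult(
        lags_ns=lags,
        C=C,
        mean_occupancy=series.mean_occupancy,
        replica_id=series.replica_id,
        interaction_key=series.interaction_key,
    )


def pooled_correlation(curves: Sequence[CorrelationResult]) -> CorrelationResult:
    """Average C(t) over replicas (truncated to the shortest lag grid).

    Pooling before estimating tau suppresses the per-replica wander of
    the long-lag plateau and is the package's preferred route to a single
    aggregate correlation time; per-replica taus remain the input to the
    SEM.
    """
    if not curves:
        raise ValueError("pooled_correlation: no curves")
    n = min(len(c.C) for c in curves)
    dt0 = curves[0].lags_ns[: n]
    for c in curves:
        if not np.allclose(c.lags_ns[:n], dt0):
            raise ValueError("pooled_correlation: lag grids differ")
    C = np.mean([c.C[:n] for c in curves], axis=0)
    occ = float(np.mean([c.mean_occupancy for c in curves]))
    return CorrelationResult(
        lags_ns=dt0,
        C=C,
        mean_occupancy=occ,
        replica_id=None,
        interaction_key=curves[0].interaction_key,
    )


def _plateau(corr: CorrelationResult, plateau: str, tail_fraction: float) -> float:
    if plateau == "occupancy":
        # exact stationary plateau of the intermittent estimator for a
        # binary indicator: <h(0)h(inf)>/<h^2> = <h>^2/<h> = <h>
        c_inf = corr.mean_occupancy
    elif plateau == "tail":
        n_tail = max(1, int(round(tail_fraction * len(corr.C))))
        c_inf = float(np.mean(corr.C[-n_tail:]))
    else:
        raise ValueError("plateau must be 'occupancy' or 'tail'")
    return min(max(c_inf, 0.0), 1.0 - 1e-9)


def correlation_time(
    corr: CorrelationResult,
    method: str = "integral",
    plateau_tol: float = 0.02,
    plateau: str = "occupancy",
    tail_fraction: float = 0.1,
    window_factor: float = 10.0,
    sokal_c: float = 6.0,
) -> CorrelationResult:
    """Correlation time tau from a C(t) curve.

    Both estimators first remove the plateau C_inf — by default the
    indicator's mean occupancy (the exact stationary plateau of the
    intermittent estimator), optionally the tail-window mean of the
    curve (``plateau="tail"``).

    ``integral``: trapezoid integral of (C - C_inf)/(1 - C_inf),
    truncated at the first zero crossing of the corrected curve or at
    the self-consistent window t >= sokal_c * tau (whichever comes
    first).  Truncation is essential: beyond the decay the integrand is
    statistical noise whose contribution grows with the upper limit.

    ``exponential_fit``: least squares of
    C(t) = C_inf + (1 - C_inf) exp(-t/tau) with C_inf fixed at the
    plateau estimate, over the adaptive window
    [0, window_factor * tau_0] where tau_0 is the corrected curve's 1/e
    crossing (long lags carry no decay information, only plateau noise).

    A curve that never decays below (1 - plateau_tol) is censored:
    tau is then a lower bound equal to the maximum usable lag.
    """
    if method not in ("integral", "exponential_fit"):
        raise ValueError("method must be 'integral' or 'exponential_fit'")
    C = corr.C
    lags = corr.lags_ns
    if len(C) == 0 or abs(C[0] - 1.0) > 1e-6:
        raise ContractViolationError("C(0) must equal 1")
    if len(C) < 2:
        raise ContractViolationError("need at least two lags")

    if float(np.min(C)) > 1.0 - plateau_tol:
        return replace(
            corr, tau_ns=float(lags[-1]), tau_method=method, censored=True
        )

    c_inf = _plateau(corr, plateau, tail_fraction)
    norm = (C - c_inf) / (1.0 - c_inf)
    dt = float(lags[1] - lags[0])

    if method == "integral":
        tau = 0.0
        for k in range(1, len(norm)):
            tau += 0.5 * (norm[k - 1] + norm[k]) * dt
            if norm[k] <= 0.0 or lags[k] >= sokal_c * max(tau, dt):
                break
        tau = max(float(tau), 0.0)
    else:
        below = np.flatnonzero(norm < np.exp(-1.0))
        tau0 = float(lags[below[0]]) if below.size else float(lags[-1]) / 4.0
        tau0 = max(tau0, dt)
        window = lags <= min(window_factor * tau0, float(lags[-1]))

        def model(t, tau):
            return c_inf + (1.0 - c_inf) * np.exp(-t / tau)

        popt, _ = curve_fit(
            model,
            lags[window],
            C[window],
            p0=[tau0],
            bounds=([dt * 1e-6], [np.inf]),
            maxfev=10000,
        )
        tau = float(popt[0])
    return replace(corr, tau_ns=tau, tau_method=method, censored=False)


def aggregate_replicas(values: Sequence[float]) -> ReplicaAggregate:
    """Mean and SEM (sample SD / sqrt(n)) over per-replica values.

    With a single replica the SEM is undefined and reported as NaN.
    """
    vals = [float(v) for v in values]
    if not vals:
        raise ValueError("aggregate_replicas: empty value list")
    n = len(vals)
    mean = float(np.mean(vals))
    sem = float(np.std(vals, ddof=1) / np.sqrt(n)) if n >= 2 else float("nan")
    return ReplicaAggregate(values=vals, mean=mean, sem=sem, n=n)


def water_exchange(
    bridge_records: Sequence[Sequence[WaterBridge]],
    interaction_key: tuple | str = "",
) -> WaterExchangeSummary:
    """Bridging-water identity turnover over a frame-ordered record list.

    An identity switch is a pair of successive bridge-containing frames
    whose sets of bridging-water residues are disjoint — the bridge
    persisted but every water carrying it was replaced.
    """
    n_bridge_frames = 0
    switches = 0
    seen: set[int] = set()
    prev_waters: set[int] | None = None
    for records in bridge_records:
        waters = {int(b.water_residue) for b in records}
        if not waters:
            continue
        n_bridge_frames += 1
        seen |= waters
        if prev_waters is not None and prev_waters.isdisjoint(waters):
            switches += 1
        prev_waters = waters
    return WaterExchangeSummary(
        interaction_key=interaction_key,
        n_bridge_frames=n_bridge_frames,
        n_identity_switches=switches,
        distinct_waters=len(seen),
    )
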