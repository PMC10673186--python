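"""Maximum-likelihood binding kinetics from bond-count event traces.

Binding and unbinding events map a trajectory onto a one-dimensional
birth-death Markov chain over the number of complexes n = 0..N,
N = min(NR, NL), with transition rates

    k+(n) = (NR - n)(NL - n) kon(n) / A,      k-(n) = n koff(n).

With Nn+ (Nn-) the number of observed n -> n+1 (n -> n-1) transitions and
Tn the total dwell time in state n, the likelihood of the trace is

    L = prod_n k+(n)^{Nn+} k-(n)^{Nn-} exp(-(k+(n) + k-(n)) Tn)

whose maximizers are the closed-form estimators

    kon(n) = Nn+ A / ((NR - n)(NL - n) Tn),    koff(n) = Nn- / (n Tn).

Near the mean bond number the state dependence is weak; the plateau values
kon = kon(round(n_bar)) and koff = koff(round(n_bar)) define the rate
constants of the run, and kon/koff is the kinetic estimate of the 2D
affinity. Dwell times are in MC cycles; one cycle corresponds to a physical
time tau (about 60 us for 15 nm patches and a ligand diffusion coefficient
of ~1 um^2/s).

Leading and trailing dwell segments of the analysis window, which are not
terminated by an observed transition, contribute dwell time but no counts —
the standard treatment of censored dwell times.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .model import ModelParams

__all__ = [
    "EventTrace",
    "StateTally",
    "RateEstimates",
    "trace_from_trajectory",
    "tally",
    "mle_rates",
    "to_physical",
    "to_cycles",
    "log_likelihood",
]


@dataclass(frozen=True)
class EventTrace:
    """Time-ordered bond-count changes within an analysis window.

    times are in cycles (fractional), strictly increasing inside
    [t_start, t_end]; n_after[k] is the bond count right after event k;
    n_initial is the count at t_start. Consecutive counts differ by exactly
    one: single-site moves change the bond number by at most one.

    ``channels`` optionally tags each event with the move type that caused
    it (0 = vertical membrane displacement, 1 = ligand hop). The vertical
    channel is dominated by sub-cycle recrossings of the sharp well edge
    (bond "flicker"); the hop channel records actual arrival/departure of a
    ligand at a receptor patch. Traces without channel tags (e.g. external
    birth-death processes) treat every event as a kinetic transition.
    """

    times: np.ndarray
    n_after: np.ndarray
    t_start: float
    t_end: float
    n_initial: int
    channels: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=np.float64)
        n = np.asarray(self.n_after, dtype=np.int64)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "n_after", n)
        if self.channels is not None:
            c = np.asarray(self.channels, dtype=np.int8)
            if c.shape != t.shape:
                raise ValueError("channels must match times in length")
            object.__setattr__(self, "channels", c)
        if t.shape != n.shape or t.ndim != 1:
            raise ValueError("times and n_after must be 1-D arrays of equal length")
        if self.t_end <= self.t_start:
            raise ValueError("need t_end > t_start")
        if t.size:
            if t[0] < self.t_start or t[-1] > self.t_end:
                raise ValueError("event times outside the analysis window")
            if not (np.diff(t) > 0).all():
                raise ValueError("event times must be strictly increasing")
            steps = np.diff(np.concatenate(([self.n_initial], n)))
            if not (np.abs(steps) == 1).all():
                raise ValueError("corrupt trace: consecutive bond counts must differ by 1")
            if n.min() < 0:
                raise ValueError("negative bond count in trace")


def trace_from_trajectory(traj, t_start: float | None = None, t_end: float | None = None) -> EventTrace:
    """Extract the post-equilibration event trace of a simulation run."""
    if t_start is None:
        t_start = float(traj.schedule.n_equil)
    if t_end is None:
        t_end = float(traj.schedule.n_cycles)
    lo = int(np.searchsorted(traj.event_times, t_start, side="left"))
    hi = int(np.searchsorted(traj.event_times, t_end, side="right"))
    return EventTrace(
        times=traj.event_times[lo:hi].copy(),
        n_after=traj.event_nb[lo:hi].astype(np.int64),
        t_start=t_start,
        t_end=t_end,
        n_initial=traj.nb_at(t_start),
        channels=traj.event_channel[lo:hi].copy(),
    )


@dataclass(frozen=True)
class StateTally:
    """Per-state transition counts and dwell times: Nn+, Nn-, Tn for n = 0..N."""

    n_plus: np.ndarray  # int64[N+1]
    n_minus: np.ndarray  # int64[N+1]
    dwell: np.ndarray  # float64[N+1], cycles; sums to window length
    window: float  # t_end - t_start


def tally(trace: EventTrace, n_max: int | None = None, channels: str = "hop") -> StateTally:
    """Count transitions and accumulate dwell times per bond-count state.

    The segment before the first event and the segment after the last event
    contribute dwell time to the state occupied there but no transitions
    (censored end segments).

    ``channels`` selects which events count as kinetic transitions:

    * ``"hop"`` (default): only bond changes caused by ligand translocation.
      Vertical-move bond flips are treated as internal breathing of the
      adhered state — the sharp square-well edge makes the geometric bond
      indicator recross it many times within a cycle, and counting those
      recrossings as dissociations would overstate koff by roughly an order
      of magnitude relative to what surface-sensitive experiments resolve.
      Dwell times still come from the full geometric bond-count trace.
    * ``"all"``: every bond-indicator change is a transition (also the
      behaviour for traces without channel tags, such as synthetic
      birth-death processes).
    """
    if channels not in ("hop", "all"):
        raise ValueError(f"channels must be 'hop' or 'all', got {channels!r}")
    n_seq = np.concatenate(([trace.n_initial], trace.n_after)).astype(np.int64)
    bounds = np.concatenate(([trace.t_start], trace.times, [trace.t_end]))
    dur = np.diff(bounds)
    if n_max is None:
        n_max = int(n_seq.max())
    if n_seq.max() > n_max:
        raise ValueError(f"trace visits state {n_seq.max()} > n_max={n_max}")
    n_plus = np.zeros(n_max + 1, dtype=np.int64)
    n_minus = np.zeros(n_max + 1, dtype=np.int64)
    dwell = np.zeros(n_max + 1, dtype=np.float64)
    np.add.at(dwell, n_seq, dur)
    if trace.times.size:
        steps = np.diff(n_seq)
        origins = n_seq[:-1]
        if channels == "hop" and trace.channels is not None:
            keep = trace.channels == 1
        else:
            keep = np.ones(steps.shape, dtype=bool)
        np.add.at(n_plus, origins[(steps == 1) & keep], 1)
        np.add.at(n_minus, origins[(steps == -1) & keep], 1)
    return StateTally(n_plus=n_plus, n_minus=n_minus, dwell=dwell,
                      window=float(trace.t_end - trace.t_start))


@dataclass(frozen=True)
class RateEstimates:
    """State-resolved and plateau rate constants.

    In "cycle" units kon_n is in nm^2/cycle and koff_n in 1/cycle; after
    conversion with tau, kon is in um^2/s (numerically equal to nm^2/us)
    and koff in 1/s. States never visited, or with undefined denominators
    (koff(0); kon at n = min(NR, NL)), hold NaN. ``kon``/``koff`` are the
    estimates at round(n_bar); the dwell-weighted averages over the states
    covering the central 68% of dwell time are exported alongside as a
    robustness check.
    """

    n: np.ndarray
    n_plus: np.ndarray
    n_minus: np.ndarray
    dwell: np.ndarray
    kon_n: np.ndarray
    koff_n: np.ndarray
    n_bar: float
    kon: float
    koff: float
    kon_window: float
    koff_window: float
    units: str = "cycle"  # "cycle" or "physical"

    @property
    def K2D(self) -> float:
        """Kinetic 2D affinity kon/koff: nm^2 in cycle units, um^2 in physical.

        NaN when either plateau rate is undefined or no unbinding was seen.
        """
        if not np.isfinite(self.kon) or not np.isfinite(self.koff) or self.koff == 0:
            return float("nan")
        return self.kon / self.koff


def _dwell_window(dwell: np.ndarray, center: int, coverage: float = 0.68) -> np.ndarray:
    """Indices of a contiguous state window around ``center`` holding >= coverage of dwell."""
    total = dwell.sum()
    lo = max(center - 1, 0)
    hi = min(center + 1, dwell.size - 1)
    while dwell[lo : hi + 1].sum() < coverage * total:
        grow_lo = dwell[lo - 1] if lo > 0 else -1.0
        grow_hi = dwell[hi + 1] if hi + 1 < dwell.size else -1.0
        if grow_lo < 0 and grow_hi < 0:
            break
        if grow_hi >= grow_lo:
            hi += 1
        else:
            lo -= 1
    return np.arange(lo, hi + 1)


def mle_rates(counts: StateTally, p: ModelParams) -> RateEstimates:
    """Closed-form maximum-likelihood on/off rate constants per state."""
    NR, NL, A = p.n_receptors, p.NL, p.area_nm2
    n = np.arange(counts.dwell.size, dtype=np.int64)
    T = counts.dwell
    with np.errstate(divide="ignore", invalid="ignore"):
        pair_factor = (NR - n).astype(float) * (NL - n).astype(float)
        kon_n = np.where((T > 0) & (pair_factor > 0),
                         counts.n_plus * A / (pair_factor * T), np.nan)
        koff_n = np.where((T > 0) & (n > 0), counts.n_minus / (n * T), np.nan)
    if T.sum() <= 0:
        raise ValueError("empty tally: no dwell time")
    n_bar = float((n * T).sum() / T.sum())
    nc = int(round(n_bar))
    win = _dwell_window(T, nc)

    def _at_plateau(k):
        # value at round(n_bar); if undefined there (e.g. kon at n = NL),
        # the nearest defined state — rates hardly change near n_bar
        if not np.isnan(k[nc]):
            return float(k[nc])
        defined = np.flatnonzero(~np.isnan(k))
        if defined.size == 0:
            return np.nan
        return float(k[defined[np.argmin(np.abs(defined - nc))]])

    def _wavg(k):
        m = ~np.isnan(k[win])
        if not m.any():
            return np.nan
        return float((k[win][m] * T[win][m]).sum() / T[win][m].sum())

    return RateEstimates(
        n=n, n_plus=counts.n_plus, n_minus=counts.n_minus, dwell=T,
        kon_n=kon_n, koff_n=koff_n, n_bar=n_bar,
        kon=_at_plateau(kon_n), koff=_at_plateau(koff_n),
        kon_window=_wavg(kon_n), koff_window=_wavg(koff_n),
        units="cycle",
    )


def to_physical(est: RateEstimates, tau_us: float = 60.0) -> RateEstimates:
    """Convert cycle-unit estimates to physical units via the cycle time tau.

    koff: 1/cycle -> 1/s; kon: nm^2/cycle -> um^2/s (= nm^2/us).
    """
    if tau_us <= 0:
        raise ValueError("tau_us must be positive")
    if est.units != "cycle":
        raise ValueError("estimates already in physical units")
    tau_s = tau_us * 1e-6
    f_on = 1e-6 / tau_s  # nm^2/cycle -> um^2/s
    f_off = 1.0 / tau_s
    return replace(
        est,
        kon_n=est.kon_n * f_on, koff_n=est.koff_n * f_off,
        kon=est.kon * f_on, koff=est.koff * f_off,
        kon_window=est.kon_window * f_on, koff_window=est.koff_window * f_off,
        units="physical",
    )


def to_cycles(est: RateEstimates, tau_us: float = 60.0) -> RateEstimates:
    """Inverse of :func:`to_physical`."""
    if tau_us <= 0:
        raise ValueError("tau_us must be positive")
    if est.units != "physical":
        raise ValueError("estimates already in cycle units")
    tau_s = tau_us * 1e-6
    f_on = tau_s / 1e-6
    f_off = tau_s
    return replace(
        est,
        kon_n=est.kon_n * f_on, koff_n=est.koff_n * f_off,
        kon=est.kon * f_on, koff=est.koff * f_off,
        kon_window=est.kon_window * f_on, koff_window=est.koff_window * f_off,
        units="cycle",
    )


def log_likelihood(counts: StateTally, kon_n: np.ndarray, koff_n: np.ndarray,
                   p: ModelParams) -> float:
    """Log of the trace likelihood for given per-state rate constants.

    States with zero counts and zero dwell contribute nothing; 0*log(0)
    terms are treated as 0.
    """
    NR, NL, A = p.n_receptors, p.NL, p.area_nm2
    n = np.arange(counts.dwell.size, dtype=np.float64)
    k_plus = (NR - n) * (NL - n) * np.nan_to_num(kon_n) / A
    k_minus = n * np.nan_to_num(koff_n)
    ll = 0.0
    for Nn, kn in ((counts.n_plus, k_plus), (counts.n_minus, k_minus)):
        m = Nn > 0
        if (kn[m] <= 0).any():
            return -np.inf
        ll += float((Nn[m] * np.log(kn[m])).sum())
    ll -= float(((k_plus + k_minus) * counts.dwell).sum())
    return ll
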