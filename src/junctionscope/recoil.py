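"""Laser-ablation recoil kinetics.

After a junction is cut, the two tricellular vertices flanking it
separate; the distance trace d(t) relaxes like a Kelvin-Voigt element,
d(t) = d0 + A(1 - e^(-t/tau)).  The peak instantaneous velocity over
the first seconds is the standard relative proxy for the tension the
junction carried before the cut.  Traces are sampled at a fixed frame
interval (2 s by default) starting from the immediately-pre-ablation
distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats


@dataclass
class RecoilTrace:
    times_s: np.ndarray          # t = 0 is the pre-ablation frame
    distances_um: np.ndarray
    edge_orientation_class: str = ""     # "ML" or "AP"
    stage: str = ""                      # "early" or "late"
    trace_id: str = ""
    embryo_id: str = ""

    def __post_init__(self):
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.distances_um = np.asarray(self.distances_um, dtype=float)
        if len(self.times_s) < 2:
            raise ValueError("a trace needs at least 2 samples")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.distances_um <= 0):
            raise ValueError("distances must be positive")


@dataclass
class RecoilResult:
    trace_id: str
    velocities_um_per_s: np.ndarray
    peak_velocity_um_per_s: float
    discard: bool
    fit: dict | None = None      # {"A_um", "tau_s", "v0_um_per_s", "d0_um"}


def recoil_velocities(trace: RecoilTrace) -> np.ndarray:
    """Instantaneous (frame-to-frame) velocities, including the interval
    from the pre-ablation frame to the first post-cut frame."""
    return np.diff(trace.distances_um) / np.diff(trace.times_s)


def peak_recoil_velocity(trace: RecoilTrace, noise_floor: float = 0.0,
                         pre_frames: int = 0) -> tuple[float, bool]:
    """Maximum instantaneous velocity and a discard flag.

    A trace with no measurable recoil (peak at or below the noise floor)
    is flagged for discard.  When ``pre_frames`` > 1 pre-ablation frames
    are present, the floor is raised to twice the velocity SD estimated
    from them.
    """
    v = recoil_velocities(trace)
    floor = noise_floor
    if pre_frames > 1:
        floor = max(floor, 2.0 * float(np.std(v[: pre_frames - 1], ddof=1)))
    peak = float(np.max(v))
    return peak, peak <= floor


def fit_exponential_recoil(trace: RecoilTrace) -> dict | None:
    """Least-squares fit of d(t) = d0 + A(1 - e^(-t/tau)).

    Returns None (flagged, non-fatal) when the optimizer fails; the peak
    velocity remains available regardless.  v0 = A/tau is the fitted
    initial recoil velocity, a denoised tension proxy.
    """
    t = trace.times_s
    d = trace.distances_um
    if len(t) < 4:
        raise ValueError("need at least 4 samples to fit")

    def model(t, d0, A, tau):
        return d0 + A * (1.0 - np.exp(-t / tau))

    amp0 = max(d[-1] - d[0], 1e-6)
    p0 = (d[0], amp0, max((t[-1] - t[0]) / 2.0, 1e-3))
    try:
        popt, _ = optimize.curve_fit(
            model, t, d, p0=p0,
            bounds=([0.0, -np.inf, 1e-6], [np.inf, np.inf, np.inf]),
            maxfev=10000, xtol=1e-12, ftol=1e-12)
    except (RuntimeError, ValueError):
        return None
    d0, A, tau = map(float, popt)
    return {"d0_um": d0, "A_um": A, "tau_s": tau, "v0_um_per_s": A / tau}


def analyze_trace(trace: RecoilTrace, noise_floor: float = 0.0,
                  do_fit: bool = True) -> RecoilResult:
    v = recoil_velocities(trace)
    peak, discard = peak_recoil_velocity(trace, noise_floor)
    fit = None
    if do_fit and len(trace.times_s) >= 4:
        fit = fit_exponential_recoil(trace)
    return RecoilResult(trace_id=trace.trace_id, velocities_um_per_s=v,
                        peak_velocity_um_per_s=peak, discard=discard, fit=fit)


def compare_recoil_groups(results_a: list[RecoilResult],
                          results_b: list[RecoilResult]) -> dict:
    """Group means of peak recoil velocity with Welch's unequal-variance
    t-test; discarded traces are excluded (and counted)."""
    a = np.array([r.peak_velocity_um_per_s for r in results_a if not r.discard])
    b = np.array([r.peak_velocity_um_per_s for r in results_b if not r.discard])
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 retained traces per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        t, p = (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
    else:
        t, p = stats.ttest_ind(a, b, equal_var=False)
    return {
        "mean_a": float(a.mean()), "mean_b": float(b.mean()),
        "n_a": len(a), "n_b": len(b),
        "n_discarded_a": sum(r.discard for r in results_a),
        "n_discarded_b": sum(r.discard for r in results_b),
        "t_statistic": float(t), "p_value": float(p),
    }


def peak_underestimates_v0_factor(tau_s: float, dt_s: float) -> float:
    """For a noiseless exponential trace the first-interval (= peak)
    velocity equals v0 * tau/dt * (1 - e^(-dt/tau)); this returns that
    attenuation factor."""
    return tau_s * (1.0 - np.exp(-dt_s / tau_s)) / dt_s


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

def traces_from_table(df: pd.DataFrame) -> list[RecoilTrace]:
    """Build traces from a long table with columns
    trace_id, t_s, distance_um [, orientation, stage, embryo_id]."""
    out = []
    for tid, grp in df.groupby("trace_id", sort=True):
        grp = grp.sort_values("t_s")
        out.append(RecoilTrace(
            times_s=grp["t_s"].to_numpy(),
            distances_um=grp["distance_um"].to_numpy(),
            edge_orientation_class=str(grp["orientation"].iloc[0])
            if "orientation" in grp else "",
            stage=str(grp["stage"].iloc[0]) if "stage" in grp else "",
            embryo_id=str(grp["embryo_id"].iloc[0]) if "embryo_id" in grp else "",
            trace_id=str(tid)))
    return out


def results_table(results: list[RecoilResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        fit = r.fit or {}
        rows.append((r.trace_id, r.peak_velocity_um_per_s, r.discard,
                     fit.get("A_um", np.nan), fit.get("tau_s", np.nan),
                     fit.get("v0_um_per_s", np.nan)))
    return pd.DataFrame(rows, columns=[
        "trace_id", "peak_velocity_um_per_s", "discard",
        "fit_A_um", "fit_tau_s", "fit_v0_um_per_s"])
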