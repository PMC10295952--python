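"""Impedance-based killing kinetics: double normalization and simulation.

Electric cell-substrate impedance sensing (ECIS) reports adherent
target-cell coverage; effector-mediated killing shows up as an impedance
decline after treatment start.  The analysis here follows the standard
double normalization: replicate traces are averaged, divided by their
value at treatment start (so every condition starts at 1), and then
divided pointwise by the non-transduced (NT) T-cell control, which removes
target-intrinsic drift.  The NT control itself maps to the constant 1
exactly.

A synthetic generator produces condition families with a logistic
pre-treatment rise to plateau, a post-treatment exponential kill whose
rate ramps up after a condition-specific lag, an NT drift, and
multiplicative noise, so the pipeline's ordering and identity properties
can be verified against known kinetics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "ImpedanceTrace",
    "KillingCurveConfig",
    "normalize_to_start",
    "normalize_to_control",
    "average_replicates",
    "double_normalize",
    "simulate_killing",
    "traces_to_frame",
    "traces_from_frame",
]


@dataclass
class ImpedanceTrace:
    """Impedance vs time with a treatment-start marker."""

    time_h: np.ndarray
    values: np.ndarray
    treat_start: float  # hours
    condition: str = ""
    replicate: int = 0
    normalized: bool = False

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.time_h.shape != self.values.shape or self.time_h.ndim != 1:
            raise ValueError("time and values must be matching 1D arrays")
        if np.any(np.diff(self.time_h) <= 0):
            raise ValueError("time must be strictly increasing")
        if not (self.time_h[0] <= self.treat_start <= self.time_h[-1]):
            raise ValueError("treatment start must lie within the time range")
        if not self.normalized and np.any(self.values <= 0):
            raise ValueError("raw impedance values must be positive")

    @property
    def treat_index(self) -> int:
        return int(np.argmin(np.abs(self.time_h - self.treat_start)))

    def value_at_start(self) -> float:
        return float(self.values[self.treat_index])


@dataclass(frozen=True)
class KillingCurveConfig:
    """Kinetic parameters for one simulated condition."""

    plateau: float = 1000.0  # ohm
    initial: float = 100.0  # ohm at seeding
    growth_rate: float = 0.4  # 1/h logistic rise to plateau
    kill_lag: float = 0.0  # h after treatment before killing ramps up
    kill_rate: float = 0.2  # 1/h maximal exponential kill rate
    kill_ramp: float = 1.0  # h over which the rate rises from 0 to max
    nt_drift: float = 0.0  # 1/h exponential drift of untreated impedance
    noise_sd: float = 0.0  # multiplicative lognormal noise sigma
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kill_rate < 0 or self.kill_lag < 0 or self.growth_rate < 0:
            raise ValueError("rates and lag must be non-negative")
        if self.plateau <= 0 or self.initial <= 0 or self.initial > self.plateau:
            raise ValueError("need 0 < initial <= plateau")
        if self.kill_ramp <= 0:
            raise ValueError("kill ramp must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")


def normalize_to_start(trace: ImpedanceTrace) -> ImpedanceTrace:
    """Divide by the value at treatment start (start value becomes exactly 1).

    Idempotent: applying it twice equals applying it once.
    """
    v0 = trace.value_at_start()
    if v0 <= 0:
        raise ValueError("impedance at treatment start must be positive")
    return replace(trace, values=trace.values / v0, normalized=True)


def normalize_to_control(treated: ImpedanceTrace, control: ImpedanceTrace) -> ImpedanceTrace:
    """Pointwise ratio treated/control (control interpolated if grids differ)."""
    if treated.time_h.shape == control.time_h.shape and np.allclose(
        treated.time_h, control.time_h
    ):
        ctrl_vals = control.values
    else:
        if (treated.time_h[0] < control.time_h[0] - 1e-9
                or treated.time_h[-1] > control.time_h[-1] + 1e-9):
            raise ValueError("control does not cover the treated time range")
        ctrl_vals = np.interp(treated.time_h, control.time_h, control.values)
    if np.any(ctrl_vals == 0):
        raise ValueError("control impedance is zero at some time point")
    return replace(treated, values=treated.values / ctrl_vals, normalized=True)


def average_replicates(traces: list[ImpedanceTrace]) -> tuple[ImpedanceTrace, np.ndarray]:
    """Pointwise mean trace and per-timepoint SD across replicates.

    With a single trace the SD is returned as NaN (flagged undefined).
    """
    if not traces:
        raise ValueError("no traces to average")
    t0 = traces[0]
    for t in traces[1:]:
        if t.time_h.shape != t0.time_h.shape or not np.allclose(t.time_h, t0.time_h):
            raise ValueError("replicates must share a time grid")
        if abs(t.treat_start - t0.treat_start) > 1e-9:
            raise ValueError("replicates must share the treatment start")
    vals = np.stack([t.values for t in traces])
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1) if len(traces) > 1 else np.full_like(mean, np.nan)
    out = replace(t0, values=mean, replicate=-1, normalized=t0.normalized)
    return out, sd


def double_normalize(
    traces: list[ImpedanceTrace],
    control_condition: str = "NT",
    average_first: bool = True,
) -> dict[str, tuple[ImpedanceTrace, np.ndarray]]:
    """Full pipeline: average replicates, normalize to start, then to NT.

    ``average_first=True`` averages raw replicates before start
    normalization (the default protocol); ``False`` normalizes each
    replicate first and averages afterwards, as a sensitivity check.
    Returns per condition the double-normalized mean trace and the
    replicate SD propagated through the control division.
    """
    by_cond: dict[str, list[ImpedanceTrace]] = {}
    for t in traces:
        by_cond.setdefault(t.condition, []).append(t)
    if control_condition not in by_cond:
        raise ValueError(f"missing control condition {control_condition!r}")

    start_norm: dict[str, tuple[ImpedanceTrace, np.ndarray]] = {}
    for cond, reps in by_cond.items():
        if average_first:
            mean, sd = average_replicates(reps)
            norm = normalize_to_start(mean)
            sd = sd / mean.value_at_start()
        else:
            normed = [normalize_to_start(t) for t in reps]
            norm, sd = average_replicates(normed)
        start_norm[cond] = (norm, sd)

    control = start_norm[control_condition][0]
    out: dict[str, tuple[ImpedanceTrace, np.ndarray]] = {}
    for cond, (norm, sd) in start_norm.items():
        ratio = normalize_to_control(norm, control)
        out[cond] = (ratio, sd / np.where(control.values == 0, np.nan, control.values))
    return out


def _kill_integral(t_after: np.ndarray, lag: float, rate: float, ramp: float) -> np.ndarray:
    """Integral of the ramped kill rate k(t) from treatment start to t_after.

    k(t) = rate * clip((t - lag)/ramp, 0, 1); piecewise-closed form.
    """
    u = np.clip(t_after - lag, 0.0, None)
    ramp_part = np.minimum(u, ramp)
    full_part = np.clip(u - ramp, 0.0, None)
    return rate * (ramp_part**2 / (2.0 * ramp) + full_part)


def simulate_killing(
    configs: dict[str, KillingCurveConfig],
    duration_pre: float = 25.0,
    duration_post: float = 25.0,
    dt: float = 0.25,
    n_replicates: int = 2,
    seed: int = 0,
) -> list[ImpedanceTrace]:
    """Simulate impedance trace families for a set of conditions.

    Pre-treatment: logistic rise of impedance to the plateau (confluent
    monolayer).  Post-treatment: dZ/dt = -k(t) Z with k ramping from 0 to
    the condition's kill rate after its lag; the NT-like condition uses
    kill rate 0 plus its drift.  Multiplicative lognormal noise is applied
    per sample.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    time = np.arange(0.0, duration_pre + duration_post + dt / 2, dt)
    traces: list[ImpedanceTrace] = []
    for cond, cfg in configs.items():
        # logistic rise Z(t) = P / (1 + ((P - Z0)/Z0) exp(-r t))
        a = (cfg.plateau - cfg.initial) / cfg.initial
        pre = cfg.plateau / (1.0 + a * np.exp(-cfg.growth_rate * time))
        z_treat = cfg.plateau / (1.0 + a * np.exp(-cfg.growth_rate * duration_pre))
        after = time - duration_pre
        decay = np.exp(-_kill_integral(after, cfg.kill_lag, cfg.kill_rate, cfg.kill_ramp))
        drift = np.exp(cfg.nt_drift * np.clip(after, 0.0, None))
        post = z_treat * decay * drift
        clean = np.where(time <= duration_pre, pre, post)
        for rep in range(n_replicates):
            if cfg.noise_sd > 0:
                noise = np.exp(rng.normal(0.0, cfg.noise_sd, size=time.size))
            else:
                noise = 1.0
            traces.append(
                ImpedanceTrace(
                    time_h=time,
                    values=clean * noise,
                    treat_start=duration_pre,
                    condition=cond,
                    replicate=rep,
                )
            )
    return traces


def traces_to_frame(traces: list[ImpedanceTrace]) -> pd.DataFrame:
    """Long-format DataFrame (time_h, value, condition, replicate, treat_start)."""
    frames = [
        pd.DataFrame(
            {
                "time_h": t.time_h,
                "value": t.values,
                "condition": t.condition,
                "replicate": t.replicate,
                "treat_start": t.treat_start,
            }
        )
        for t in traces
    ]
    return pd.concat(frames, ignore_index=True)


def traces_from_frame(df: pd.DataFrame) -> list[ImpedanceTrace]:
    """Rebuild traces from a long-format DataFrame (inverse of traces_to_frame)."""
    out = []
    for (cond, rep), grp in df.groupby(["condition", "replicate"], sort=False):
        grp = grp.sort_values("time_h")
        out.append(
            ImpedanceTrace(
                time_h=grp["time_h"].to_numpy(),
                values=grp["value"].to_numpy(),
                treat_start=float(grp["treat_start"].iloc[0]),
                condition=str(cond),
                replicate=int(rep),
            )
        )
    return out
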