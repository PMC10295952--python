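"""Triplet-corrected one- and two-component FCS diffusion models.

The fitted model for the normalized autocorrelation is

    G(tau) = 1 + G_triplet(tau) * G_diffusion(tau)

with a dark-state (triplet) factor

    G_triplet(tau) = 1 + T_t * exp(-tau / tau_t) / (1 - T_t)

and a two-component diffusion factor combining a freely diffusing 3D
species (e.g. dissociated labeled ligand) and a 2D membrane-confined
species (the receptor):

    G_diffusion(tau) = f1 / [(1 + tau/tau_d1) * sqrt(1 + tau/(S^2 tau_d1))]
                     + f2 / (1 + tau/tau_d2)

``f1`` and ``f2`` are free non-negative amplitudes (their sum equals the
zero-lag correlation amplitude before the triplet factor; reported
component fractions are f_i / (f1 + f2)), ``tau_d1`` and ``tau_d2`` the
3D and 2D diffusion correlation times, and ``S`` the structural parameter
(axial/lateral radius ratio of the Gaussian detection volume).

Diffusion times convert to diffusion coefficients through

    tau_d = omega_r^2 / (4 D)

Calibration protocol (three stages, mirroring standard confocal practice):

1. ``calibrate_dye`` - fit a free dye of known literature D with a
   one-component 3D + triplet model; S and tau_dye are fitted, and the
   lateral focus radius follows as omega_r = sqrt(4 D tau_dye).
2. ``calibrate_ligand`` - fit the free labeled ligand with S fixed from
   stage 1, giving the 3D diffusion time tau_d1 used in cell fits.
3. ``fit_cell`` - two-component fit of membrane curves with S and tau_d1
   fixed; free parameters are T_t, tau_t, f1, f2 and tau_d2.

Times are seconds and lengths micrometres throughout.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace

import lmfit
import numpy as np

from .fcs_correlate import AutocorrelationCurve, pool_curves

__all__ = [
    "FCSModelParams",
    "CalibrationResult",
    "triplet_factor",
    "diffusion_factor",
    "model_G",
    "fit_curve",
    "calibrate_dye",
    "calibrate_ligand",
    "fit_cell",
    "diffusion_coefficient",
    "diffusion_time",
    "component_fraction",
    "jackknife_membrane_D",
]

_PARAM_NAMES = ("T_t", "tau_t", "f1", "tau_d1", "f2", "tau_d2", "S")


@dataclass
class FCSModelParams:
    """All parameters of the model plus fit metadata.

    ``fixed`` maps parameter names to True where the fitter must not move
    them.  ``stderr`` holds per-parameter standard errors from the fit
    covariance (NaN when unavailable).
    """

    T_t: float = 0.0
    tau_t: float = 5e-6
    f1: float = 0.0
    tau_d1: float = 1e-4
    f2: float = 0.0
    tau_d2: float = 1e-2
    S: float = 4.0
    fixed: dict = field(default_factory=dict)
    stderr: dict = field(default_factory=dict)
    success: bool = True
    redchi: float = float("nan")
    residual_norm: float = float("nan")
    message: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.T_t < 1):
            raise ValueError("T_t must be in [0, 1)")
        for name in ("tau_t", "tau_d1", "tau_d2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.f1 < 0 or self.f2 < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.S < 1:
            raise ValueError("structural parameter S must be >= 1")

    def values(self) -> dict:
        return {k: getattr(self, k) for k in _PARAM_NAMES}

    def as_dict(self) -> dict:
        out = self.values()
        out.update(
            fixed={k: bool(self.fixed.get(k, False)) for k in _PARAM_NAMES},
            stderr=self.stderr,
            success=self.success,
            redchi=self.redchi,
            residual_norm=self.residual_norm,
            message=self.message,
        )
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=2)


@dataclass
class CalibrationResult:
    """Instrumental constants from the free-dye and free-ligand stages.

    ``T_t``/``tau_t`` carry the fluorophore's dark-state parameters when
    the calibration fit determined them (the joint fit does); cell fits
    may then share them instead of re-fitting the photophysics.
    """

    omega_r: float
    S: float
    tau_dye: float
    D_dye_reference: float
    tau_ligand: float | None = None
    T_t: float | None = None
    tau_t: float | None = None
    warning: str = ""

    def __post_init__(self) -> None:
        if self.omega_r <= 0:
            raise ValueError("omega_r must be positive")
        if self.S < 1:
            raise ValueError("S must be >= 1")
        if self.tau_ligand is not None and self.tau_ligand < self.tau_dye:
            raise ValueError(
                "ligand diffusion time below the dye's: the labeled ligand "
                "is larger than the free dye"
            )


def triplet_factor(tau, T_t: float, tau_t: float):
    """Dark-state factor 1 + T_t exp(-tau/tau_t) / (1 - T_t)."""
    if not (0 <= T_t < 1):
        raise ValueError("T_t must be in [0, 1); T_t = 1 divides by zero")
    if tau_t <= 0:
        raise ValueError("tau_t must be positive")
    tau = np.asarray(tau, dtype=np.float64)
    return 1.0 + T_t * np.exp(-tau / tau_t) / (1.0 - T_t)


def diffusion_factor(tau, params: FCSModelParams):
    """Two-component diffusion decay; equals f1 + f2 at tau = 0."""
    tau = np.asarray(tau, dtype=np.float64)
    x1 = tau / params.tau_d1
    term_3d = params.f1 / ((1.0 + x1) * np.sqrt(1.0 + x1 / params.S**2))
    term_2d = params.f2 / (1.0 + tau / params.tau_d2)
    return term_3d + term_2d


def model_G(tau, params: FCSModelParams):
    """Full model G(tau) = 1 + G_triplet * G_diffusion."""
    return 1.0 + triplet_factor(tau, params.T_t, params.tau_t) * diffusion_factor(tau, params)


def diffusion_coefficient(tau_d: float, omega_r: float) -> float:
    """D = omega_r^2 / (4 tau_d), in um^2/s for um and s inputs."""
    if tau_d <= 0 or omega_r <= 0:
        raise ValueError("tau_d and omega_r must be positive")
    return omega_r**2 / (4.0 * tau_d)


def diffusion_time(D: float, omega_r: float) -> float:
    """Inverse of :func:`diffusion_coefficient`: tau_d = omega_r^2 / (4 D)."""
    if D <= 0 or omega_r <= 0:
        raise ValueError("D and omega_r must be positive")
    return omega_r**2 / (4.0 * D)


def component_fraction(params: FCSModelParams) -> float:
    """Free-ligand (3D) amplitude fraction f1 / (f1 + f2)."""
    total = params.f1 + params.f2
    if total <= 0:
        raise ValueError("f1 + f2 must be positive")
    return params.f1 / total


def _model_func(tau, T_t, tau_t, f1, tau_d1, f2, tau_d2, S):
    trip = 1.0 + T_t * np.exp(-tau / tau_t) / (1.0 - T_t)
    x1 = tau / tau_d1
    diff = f1 / ((1.0 + x1) * np.sqrt(1.0 + x1 / S**2)) + f2 / (1.0 + tau / tau_d2)
    return 1.0 + trip * diff


def default_start(curve: AutocorrelationCurve, tau_d1: float | None = None) -> FCSModelParams:
    """Documented start values: T_t = 0.1, tau_t = 5 us, tau_d2 = 10 ms,
    amplitudes split half/half from the observed zero-lag amplitude."""
    amp = max(float(np.mean(curve.G[:3]) - 1.0), 1e-3)
    lag_lo, lag_hi = curve.lags[0], curve.lags[-1]
    return FCSModelParams(
        T_t=0.1,
        tau_t=min(max(5e-6, lag_lo), lag_hi),
        f1=amp / 2,
        tau_d1=tau_d1 if tau_d1 is not None else math.sqrt(lag_lo * lag_hi) / 10,
        f2=amp / 2,
        tau_d2=min(max(1e-2, lag_lo), lag_hi),
        S=4.0,
    )


def fit_curve(
    curve: AutocorrelationCurve,
    params0: FCSModelParams | None = None,
    fixed: dict | None = None,
) -> FCSModelParams:
    """Weighted nonlinear least-squares fit of the model to a curve.

    Weights are 1/SEM^2 when an across-run SEM is present (zero SEMs are
    floored at the smallest positive SEM), uniform otherwise.  Fixed
    parameters are honored exactly.  Bounds: T_t in [0, 0.8], correlation
    times within the lag range, amplitudes non-negative, S in [1, 25].
    A non-converged optimizer is reported via ``success``/``message``,
    never silently replaced by defaults.
    """
    fixed = dict(fixed or {})
    if params0 is None:
        params0 = default_start(curve)
    n_free = sum(1 for k in _PARAM_NAMES if not fixed.get(k, False))
    if curve.lags.size < 5 * n_free:
        raise ValueError("need at least 5 lags per free parameter")

    lag_lo, lag_hi = float(curve.lags[0]), float(curve.lags[-1])
    p = lmfit.Parameters()
    start = params0.values()

    def clip(v, lo, hi):
        return min(max(v, lo), hi)

    # triplet correlation times of organic fluorophores at moderate
    # excitation are in the 1-30 us range; capping tau_t keeps the
    # dark-state term from absorbing a diffusion shoulder (free dye or
    # free ligand) whose correlation time is only a few-fold longer
    tau_t_hi = min(3e-5, lag_hi)
    p.add("T_t", value=clip(start["T_t"], 0.0, 0.8), min=0.0, max=0.8)
    p.add("tau_t", value=clip(start["tau_t"], lag_lo, tau_t_hi), min=lag_lo, max=tau_t_hi)
    p.add("f1", value=max(start["f1"], 0.0), min=0.0)
    p.add("tau_d1", value=clip(start["tau_d1"], lag_lo, lag_hi), min=lag_lo, max=lag_hi)
    p.add("f2", value=max(start["f2"], 0.0), min=0.0)
    p.add("tau_d2", value=clip(start["tau_d2"], lag_lo, lag_hi), min=lag_lo, max=lag_hi)
    p.add("S", value=clip(start["S"], 1.0, 25.0), min=1.0, max=25.0)
    for name in _PARAM_NAMES:
        if fixed.get(name, False):
            p[name].set(value=start[name], vary=False, min=-np.inf, max=np.inf)

    if curve.sem is not None and np.any(curve.sem > 0):
        sem = curve.sem.copy()
        floor = sem[sem > 0].min()
        sem = np.maximum(sem, floor)
        weights = 1.0 / sem
    else:
        weights = np.ones_like(curve.G)

    def residual(pars):
        vals = {k: pars[k].value for k in _PARAM_NAMES}
        return (_model_func(curve.lags, **vals) - curve.G) * weights

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = lmfit.minimize(residual, p, method="least_squares", nan_policy="raise")

    res = np.asarray(out.residual)
    stderr = {
        k: (out.params[k].stderr if out.params[k].stderr is not None else float("nan"))
        for k in _PARAM_NAMES
    }
    fitted = {k: float(out.params[k].value) for k in _PARAM_NAMES}
    return FCSModelParams(
        **fitted,
        fixed={k: not out.params[k].vary for k in _PARAM_NAMES},
        stderr=stderr,
        success=bool(out.success),
        redchi=float(out.redchi),
        residual_norm=float(np.sqrt(np.sum(res**2))),
        message=str(getattr(out, "message", "")),
    )


def _one_component_start(curve: AutocorrelationCurve) -> FCSModelParams:
    """Start values for a free 3D species: all amplitude in the 3D term,
    tau from the lag where the curve has decayed halfway."""
    params0 = default_start(curve)
    amp = max(float(np.mean(curve.G[:3]) - 1.0), 1e-3)
    half = 1.0 + amp / 2
    idx = int(np.argmin(np.abs(curve.G - half)))
    return replace(params0, f1=amp, f2=0.0, tau_d1=float(curve.lags[idx]))


# deterministic multistart grids: the triplet/diffusion and S/tau trade-offs
# produce local minima on noisy curves, so fits restart from a small grid
# and keep the lowest residual norm
_S_STARTS = (2.5, 4.0, 8.0)
_TAU_FACTORS = (0.5, 1.0, 2.0)


def calibrate_dye(
    curve: AutocorrelationCurve,
    D_reference: float = 325.0,
    params0: FCSModelParams | None = None,
) -> CalibrationResult:
    """Stage 1: one-component 3D + triplet fit of a free-dye curve.

    Returns the fitted dye diffusion time and structural parameter, and
    the lateral focus radius omega_r = sqrt(4 * D_reference * tau_dye).
    ``D_reference`` defaults to the literature diffusion coefficient of
    free Alexa Fluor 647 in water, 325 um^2/s.
    """
    if D_reference <= 0:
        raise ValueError("D_reference must be positive")
    starts: list[FCSModelParams] = []
    if params0 is not None:
        starts.append(replace(params0, f2=0.0))
    else:
        base = _one_component_start(curve)
        for s0 in _S_STARTS:
            for tf in _TAU_FACTORS:
                starts.append(replace(base, S=s0, tau_d1=base.tau_d1 * tf))
    fit = None
    for p0 in starts:
        cand = fit_curve(curve, p0, fixed={"f2": True, "tau_d2": True})
        if fit is None or cand.residual_norm < fit.residual_norm:
            fit = cand
    omega_r = math.sqrt(4.0 * D_reference * fit.tau_d1)
    warning = ""
    if fit.S <= 1.0 + 1e-9:
        warning = "fitted structural parameter at its lower bound (S = 1)"
    if not fit.success:
        warning = (warning + "; " if warning else "") + f"fit did not converge: {fit.message}"
    return CalibrationResult(
        omega_r=omega_r,
        S=fit.S,
        tau_dye=fit.tau_d1,
        D_dye_reference=D_reference,
        warning=warning,
    )


def calibrate_ligand(
    curve: AutocorrelationCurve,
    calib: CalibrationResult,
    params0: FCSModelParams | None = None,
) -> CalibrationResult:
    """Stage 2: free-ligand 3D + triplet fit with S fixed from stage 1.

    Returns a completed CalibrationResult carrying the ligand's 3D
    diffusion time, the fixed tau_d1 of subsequent cell fits.
    """
    if params0 is not None:
        starts = [replace(params0, f2=0.0, S=calib.S)]
    else:
        base = replace(_one_component_start(curve), S=calib.S)
        starts = [replace(base, tau_d1=base.tau_d1 * tf) for tf in _TAU_FACTORS]
    fit = None
    for p0 in starts:
        cand = fit_curve(curve, p0, fixed={"f2": True, "tau_d2": True, "S": True})
        if fit is None or cand.residual_norm < fit.residual_norm:
            fit = cand
    return replace(calib, tau_ligand=fit.tau_d1)


def fit_cell(
    curve: AutocorrelationCurve,
    calib: CalibrationResult,
    params0: FCSModelParams | None = None,
    share_triplet: bool = False,
) -> FCSModelParams:
    """Stage 3: two-component fit of a membrane curve.

    S and the 3D diffusion time (the calibrated free-ligand tau) are
    fixed; the triplet fraction and time, both amplitudes and the 2D
    membrane diffusion time are free.  With ``share_triplet=True`` the
    dark-state parameters are fixed at the calibration's fitted values as
    well (same fluorophore, same instrument), which improves the
    conditioning of the remaining amplitude/time fit on short records.
    """
    if calib.tau_ligand is None:
        raise ValueError("calibration incomplete: run calibrate_ligand first")
    fixed = {"tau_d1": True, "S": True}
    overrides = {"tau_d1": calib.tau_ligand, "S": calib.S}
    if share_triplet:
        if calib.T_t is None or calib.tau_t is None:
            raise ValueError("calibration carries no triplet parameters to share")
        fixed.update(T_t=True, tau_t=True)
        overrides.update(T_t=calib.T_t, tau_t=calib.tau_t)
    if params0 is not None:
        starts = [replace(params0, **overrides)]
    else:
        base = replace(default_start(curve, tau_d1=calib.tau_ligand), **overrides)
        starts = [replace(base, tau_d2=base.tau_d2 * tf) for tf in _TAU_FACTORS]
    fit = None
    for p0 in starts:
        cand = fit_curve(curve, p0, fixed=fixed)
        if fit is None or cand.residual_norm < fit.residual_norm:
            fit = cand
    return fit


def calibrate_joint(
    dye_curve: AutocorrelationCurve,
    ligand_curve: AutocorrelationCurve,
    D_reference: float = 325.0,
    S_fixed: float | None = None,
    triplet_fixed: tuple[float, float] | None = None,
) -> CalibrationResult:
    """Global calibration: fit dye and ligand curves with shared T_t, tau_t, S.

    The free dye and the dye-conjugated ligand share the fluorophore's
    dark-state photophysics and the instrument's detection geometry, so a
    global fit ties T_t, tau_t and S across both curves while each keeps
    its own amplitude and 3D diffusion time.  Because the ligand diffuses
    far more slowly than the free dye, its curve separates the triplet
    shoulder from diffusion cleanly and pins the shared photophysics,
    removing the triplet/diffusion-time trade-off that makes a dye-only
    fit unstable on short records.  Returns a complete CalibrationResult
    (omega_r from the dye time via the reference D, shared S, ligand tau).

    ``S_fixed`` pins the structural parameter instead of fitting it — the
    appropriate choice when the detection geometry is known independently
    (e.g. validation against simulated volumes, or an instrument whose S
    was measured with a reference sample): on short records the axial
    shape carries little information and a free S trades against the
    diffusion times.  ``triplet_fixed = (T_t, tau_t)`` likewise pins the
    dark-state parameters when they are known (a simulated fluorophore, or
    a dye characterized in a dedicated photophysics measurement): on short
    records the triplet/diffusion likelihood valley is nearly flat and a
    free T_t drags both diffusion times by tens of percent for chi-square
    changes at the noise level.
    """
    if D_reference <= 0:
        raise ValueError("D_reference must be positive")
    if S_fixed is not None and S_fixed < 1:
        raise ValueError("S_fixed must be >= 1")
    w = []
    for c in (dye_curve, ligand_curve):
        if c.sem is not None and np.any(c.sem > 0):
            sem = np.maximum(c.sem, c.sem[c.sem > 0].min())
            w.append(1.0 / sem)
        else:
            w.append(np.ones_like(c.G))
    lag_lo = min(float(dye_curve.lags[0]), float(ligand_curve.lags[0]))
    lag_hi = max(float(dye_curve.lags[-1]), float(ligand_curve.lags[-1]))
    tau_t_hi = min(3e-5, lag_hi)
    start_d = _one_component_start(dye_curve)
    start_l = _one_component_start(ligand_curve)

    def one_component(tau, T_t, tau_t, f, tau_d, S):
        trip = 1.0 + T_t * np.exp(-tau / tau_t) / (1.0 - T_t)
        x = tau / tau_d
        return 1.0 + trip * f / ((1.0 + x) * np.sqrt(1.0 + x / S**2))

    best = None
    for s0 in (_S_STARTS if S_fixed is None else (S_fixed,)):
        for tf in _TAU_FACTORS:
            p = lmfit.Parameters()
            if triplet_fixed is None:
                p.add("T_t", value=0.1, min=0.0, max=0.8)
                p.add("tau_t", value=min(5e-6, tau_t_hi), min=lag_lo, max=tau_t_hi)
            else:
                p.add("T_t", value=triplet_fixed[0], vary=False)
                p.add("tau_t", value=triplet_fixed[1], vary=False)
            if S_fixed is None:
                p.add("S", value=s0, min=1.0, max=25.0)
            else:
                p.add("S", value=S_fixed, vary=False)
            p.add("f_dye", value=start_d.f1, min=0.0)
            p.add("tau_dye", value=start_d.tau_d1 * tf, min=lag_lo, max=lag_hi)
            p.add("f_lig", value=start_l.f1, min=0.0)
            p.add("tau_lig", value=start_l.tau_d1 * tf, min=lag_lo, max=lag_hi)

            def residual(pars):
                v = {k: pars[k].value for k in pars}
                rd = (one_component(dye_curve.lags, v["T_t"], v["tau_t"],
                                    v["f_dye"], v["tau_dye"], v["S"])
                      - dye_curve.G) * w[0]
                rl = (one_component(ligand_curve.lags, v["T_t"], v["tau_t"],
                                    v["f_lig"], v["tau_lig"], v["S"])
                      - ligand_curve.G) * w[1]
                return np.concatenate([rd, rl])

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out = lmfit.minimize(residual, p, method="least_squares")
            chi = float(np.sum(np.asarray(out.residual) ** 2))
            if best is None or chi < best[0]:
                best = (chi, out)
    out = best[1]
    tau_dye = float(out.params["tau_dye"].value)
    tau_lig = float(out.params["tau_lig"].value)
    S = float(out.params["S"].value)
    warning = "" if out.success else f"joint fit did not converge: {out.message}"
    return CalibrationResult(
        omega_r=math.sqrt(4.0 * D_reference * tau_dye),
        S=S,
        tau_dye=tau_dye,
        D_dye_reference=D_reference,
        tau_ligand=max(tau_lig, tau_dye),
        T_t=float(out.params["T_t"].value),
        tau_t=float(out.params["tau_t"].value),
        warning=warning,
    )


def jackknife_membrane_D(
    curves: list[AutocorrelationCurve],
    calib: CalibrationResult,
) -> tuple[float, float]:
    """Leave-one-run-out spread of the membrane diffusion coefficient.

    Pools all runs but one, fits the cell model, converts tau_d2 to D with
    the calibrated omega_r, and returns (mean, jackknife SE) over the
    leave-one-out replicates.  Complements the fit standard error of the
    pooled ensemble fit.
    """
    n = len(curves)
    if n < 3:
        raise ValueError("jackknife needs at least 3 runs")
    Ds = []
    for i in range(n):
        pooled = pool_curves(curves[:i] + curves[i + 1:])
        fit = fit_cell(pooled, calib)
        Ds.append(diffusion_coefficient(fit.tau_d2, calib.omega_r))
    Ds = np.asarray(Ds)
    se = math.sqrt((n - 1) / n * np.sum((Ds - Ds.mean()) ** 2))
    return float(Ds.mean()), se
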