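"""Estimation of the optical/hemorheological model constants from recordings.

Each protocol has a matching fit, presented as a scikit-learn style
estimator plus a thin recording-level wrapper:

- static pressure steps  -> ordinary least squares of plateau-mean PPG on
  plateau pressure (``PressureSlopeRegressor`` / :func:`fit_pressure_slope`);
- flow sweeps            -> nonlinear least squares of plateau-mean PPG
  against the saturating orientation law, recovering m' and Q_c
  (``FlowSaturationRegressor`` / :func:`fit_flow_saturation`);
- intermittent flow      -> per-pause biexponential decay fits recovering
  tau_d, tau_a and the amplitude ratio n_d/n_a
  (``BiexponentialDecayRegressor`` / :func:`fit_biexponential`);
- pressure inflation     -> ordinary least squares of diameter on pressure
  for the wall-law slope b (:func:`fit_pressure_diameter`).

:func:`wall_shear_rate` converts between the flow and shear domains under
the Poiseuille assumption, gamma = 32*Q/(pi*D^3).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .containers import HemodynamicRecording

__all__ = [
    "FitResult",
    "PressureSlopeRegressor",
    "PressureDiameterRegressor",
    "FlowSaturationRegressor",
    "BiexponentialDecayRegressor",
    "detect_plateaus",
    "fit_pressure_slope",
    "fit_flow_saturation",
    "fit_biexponential",
    "fit_pressure_diameter",
    "wall_shear_rate",
    "solve_reference_diameter",
    "aggregation_change",
    "compare_ratio_batches",
]

#: mL/min -> mm^3/s
_MLMIN_TO_MM3S = 1000.0 / 60.0


@dataclass
class FitResult:
    """Parameter estimates with uncertainties from one calibration fit."""

    params: dict
    std_errors: dict
    r_squared: float
    n_points: int
    converged: bool
    residuals: Optional[np.ndarray] = None
    warnings_: list = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "parameters": {
                k: {"estimate": float(v), "se": float(self.std_errors.get(k, np.nan))}
                for k, v in self.params.items()
            },
            "r_squared": float(self.r_squared),
            "n": int(self.n_points),
            "converged": bool(self.converged),
            "warnings": list(self.warnings_),
            **{k: v for k, v in self.extras.items() if _jsonable(v)},
        }

    def to_json(self, path=None, **kwargs) -> str:
        text = json.dumps(self.to_dict(), indent=2, **kwargs)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def _as_1d(x) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim == 2 and a.shape[1] == 1:
        a = a[:, 0]
    if a.ndim != 1:
        raise ValueError("expected a 1-D array or a single-column matrix")
    return a


# ---------------------------------------------------------------------------
# plateau segmentation


def detect_plateaus(
    x,
    fs: float,
    window_s: float = 1.0,
    min_duration_s: float = 4.0,
    rel_tol: float = 0.02,
):
    """Locate steady plateaus of a stepped channel.

    The channel is cut into ``window_s`` blocks; consecutive blocks whose
    means agree within ``rel_tol`` of the overall excursion are grouped
    (``rel_tol`` must stay below half the smallest level step relative to
    the sweep span, or adjacent levels chain through the ramp blocks).
    Groups shorter than ``min_duration_s`` (ramps) are discarded, and each
    plateau is reported as the *last* ``min_duration_s`` seconds of its
    group so that transients have settled — this realizes the 4-s averaging
    convention of the sweep protocols.

    Returns a list of (start, stop) sample-index pairs.
    """
    x = _as_1d(x)
    nblk = int(round(window_s * fs))
    if nblk < 1 or x.size < 2 * nblk:
        raise ValueError("signal too short for plateau detection")
    nb = x.size // nblk
    means = x[: nb * nblk].reshape(nb, nblk).mean(axis=1)
    span = float(means.max() - means.min())
    tol = rel_tol * span if span > 0 else np.inf

    groups = []
    start = 0
    for i in range(1, nb):
        if abs(means[i] - means[i - 1]) > tol:
            groups.append((start, i))
            start = i
    groups.append((start, nb))

    min_blocks = int(round(min_duration_s / window_s))
    out = []
    for b0, b1 in groups:
        if b1 - b0 >= max(min_blocks, 1):
            stop = b1 * nblk
            out.append((stop - min_blocks * nblk, stop))
    return out


def _plateau_means(values: np.ndarray, plateaus) -> np.ndarray:
    return np.array([values[s:e].mean() for s, e in plateaus])


# ---------------------------------------------------------------------------
# linear fits


class PressureSlopeRegressor(BaseEstimator, RegressorMixin):
    """Ordinary least squares of PPG (a.u.) on pressure (mmHg).

    Fitted attributes: ``slope_`` (a.u./mmHg), ``intercept_``,
    ``stderr_slope_``, ``stderr_intercept_``, ``r_squared_``,
    ``residuals_``, ``n_points_``.
    """

    #: units of the fitted slope, for reports
    slope_units = "a.u./mmHg"
    slope_name = "slope_b"
    intercept_name = "intercept_a"

    def fit(self, X, y):
        x = _as_1d(X)
        y = _as_1d(y)
        if x.size != y.size:
            raise ValueError("X and y must have equal lengths")
        if x.size < 3:
            raise ValueError("at least 3 points are required")
        if np.ptp(x) == 0:
            raise ValueError("predictor is constant: degenerate design")
        res = stats.linregress(x, y)
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        self.stderr_slope_ = float(res.stderr)
        self.stderr_intercept_ = float(res.intercept_stderr)
        self.r_squared_ = float(res.rvalue**2)
        self.residuals_ = y - self.predict(x)
        self.n_points_ = int(x.size)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        return self.intercept_ + self.slope_ * _as_1d(X)

    def to_fit_result(self) -> FitResult:
        return FitResult(
            params={self.slope_name: self.slope_, self.intercept_name: self.intercept_},
            std_errors={
                self.slope_name: self.stderr_slope_,
                self.intercept_name: self.stderr_intercept_,
            },
            r_squared=self.r_squared_,
            n_points=self.n_points_,
            converged=True,
            residuals=self.residuals_,
            extras={"slope_units": self.slope_units},
        )


class PressureDiameterRegressor(PressureSlopeRegressor):
    """OLS of diameter (mm) on pressure (mmHg): the wall-law slope b."""

    slope_units = "mm/mmHg"
    slope_name = "pd_slope_b"
    intercept_name = "intercept_mm"


def fit_pressure_slope(
    recording: HemodynamicRecording,
    rel_tol: float = 0.02,
    flow_tolerance: float = 5.0,
) -> FitResult:
    """Pressure-pathway slope b' from a static pressure-step recording.

    Plateau-averaged PPG is regressed on plateau pressure. Requires zero
    flow (plateau-mean |flow| below ``flow_tolerance`` mL/min) and at least
    three plateaus.
    """
    if recording.ppg is None:
        raise ValueError("recording has no PPG channel")
    plateaus = detect_plateaus(recording.pressure, recording.sampling_rate, rel_tol=rel_tol)
    if len(plateaus) < 3:
        raise ValueError(f"need at least 3 pressure plateaus, found {len(plateaus)}")
    flow_means = _plateau_means(recording.flow, plateaus)
    if np.max(np.abs(flow_means)) > flow_tolerance:
        raise ValueError("flow is not zero: not a static recording")
    p = _plateau_means(recording.pressure, plateaus)
    v = _plateau_means(recording.ppg, plateaus)
    reg = PressureSlopeRegressor().fit(p, v)
    out = reg.to_fit_result()
    out.extras["n_plateaus"] = len(plateaus)
    return out


def fit_pressure_diameter(pressure, diameter, min_range: float = 50.0) -> FitResult:
    """Wall-law slope b (mm/mmHg) by OLS of diameter on pressure."""
    p = _as_1d(pressure)
    d = _as_1d(diameter)
    if np.ptp(p) == 0:
        raise ValueError("pressure is constant: degenerate design")
    if np.ptp(p) < min_range:
        warnings.warn(
            f"pressure spans only {np.ptp(p):.1f} mmHg (< {min_range:g}); "
            "the slope estimate may be unstable",
            stacklevel=2,
        )
    reg = PressureDiameterRegressor().fit(p, d)
    return reg.to_fit_result()


# ---------------------------------------------------------------------------
# flow saturation


def _saturation(q, m_prime, q_c):
    x = q / q_c
    return m_prime * x / (1.0 + x)


class FlowSaturationRegressor(BaseEstimator, RegressorMixin):
    """Nonlinear least squares of PPG on flow under the orientation law.

    Model: ``y = c0 + sign * m' * (Q/Qc)/(1 + Q/Qc)`` with ``sign = -1`` by
    default (reflected light rises with flow, PPG falls). Initialization is
    multi-start over log-spaced Q_c guesses; standard errors come from the
    Gauss-Newton approximation at the optimum.

    Fitted attributes: ``m_prime_`` (a.u., positive), ``q_c_`` (mL/min),
    ``offset_``, ``stderr_``, ``r_squared_``, ``converged_``.
    """

    def __init__(self, sign: float = -1.0, n_starts: int = 5, q_c_init: float = 328.0):
        self.sign = sign
        self.n_starts = n_starts
        self.q_c_init = q_c_init

    def fit(self, X, y):
        q = _as_1d(X)
        y = _as_1d(y)
        if np.any(q < 0):
            raise ValueError("flow must be non-negative")
        if q.size < 4:
            raise ValueError("at least 4 plateau means are required")
        qmax = float(q.max())
        if qmax < 0.2 * self.q_c_init:
            raise ValueError(
                "all flows are below 0.2 * the initial Q_c guess; the "
                "saturation is not identifiable from this sweep"
            )

        def resid(theta):
            c0, m, qc = theta
            return y - (c0 + self.sign * _saturation(q, m, qc))

        amp0 = max(float(np.ptp(y)), 1e-6)
        best = None
        for qc0 in np.geomspace(0.05 * qmax, 2.0 * qmax, self.n_starts):
            x0 = np.array([y[np.argmin(q)], 2.0 * amp0, qc0])
            try:
                sol = optimize.least_squares(
                    resid, x0, bounds=([-np.inf, 0.0, 1e-9], [np.inf, np.inf, np.inf])
                )
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise RuntimeError("flow-saturation fit failed from every start")

        c0, m, qc = best.x
        ss_res = 2.0 * best.cost
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        se, cond = _gauss_newton_se(best.jac, ss_res, q.size, 3)
        self.offset_ = float(c0)
        self.m_prime_ = float(m)
        self.q_c_ = float(qc)
        self.stderr_ = {"offset": se[0], "m_prime": se[1], "q_c": se[2]}
        self.r_squared_ = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
        self.jacobian_cond_ = cond
        # unidentifiable curvature shows up as an exploding Q_c uncertainty
        self.converged_ = bool(best.success and np.isfinite(se[2]) and se[2] < abs(qc))
        self.residuals_ = y - self.predict(q)
        self.n_points_ = int(q.size)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        return self.offset_ + self.sign * _saturation(_as_1d(X), self.m_prime_, self.q_c_)

    def to_fit_result(self) -> FitResult:
        res = FitResult(
            params={"m_prime": self.m_prime_, "q_c": self.q_c_, "offset": self.offset_},
            std_errors=dict(self.stderr_),
            r_squared=self.r_squared_,
            n_points=self.n_points_,
            converged=self.converged_,
            residuals=self.residuals_,
            extras={"jacobian_condition": float(self.jacobian_cond_)},
        )
        if not self.converged_:
            res.warnings_.append(
                "saturation parameters poorly identified (no curvature in the sweep?)"
            )
        if self.jacobian_cond_ > 1e6:
            res.warnings_.append("ill-conditioned Jacobian")
        return res


def _gauss_newton_se(jac: np.ndarray, ss_res: float, n: int, p: int):
    """Standard errors and condition number from the residual Jacobian."""
    dof = max(n - p, 1)
    s2 = ss_res / dof
    try:
        jtj_inv = np.linalg.pinv(jac.T @ jac)
        se = np.sqrt(np.clip(np.diag(jtj_inv) * s2, 0.0, np.inf))
        cond = np.linalg.cond(jac)
    except np.linalg.LinAlgError:
        se = np.full(p, np.inf)
        cond = np.inf
    return se, float(cond)


def fit_flow_saturation(
    recording: HemodynamicRecording,
    rel_tol: float = 0.02,
    **regressor_kwargs,
) -> FitResult:
    """Saturation amplitude m' and critical flow Q_c from a flow sweep.

    Plateaus are located on the flow channel and averaged over their final
    4 s (both flow and PPG), then passed to
    :class:`FlowSaturationRegressor`.
    """
    if recording.ppg is None:
        raise ValueError("recording has no PPG channel")
    plateaus = detect_plateaus(recording.flow, recording.sampling_rate, rel_tol=rel_tol)
    if len(plateaus) < 4:
        raise ValueError(f"need at least 4 flow plateaus, found {len(plateaus)}")
    q = np.clip(_plateau_means(recording.flow, plateaus), 0.0, None)
    v = _plateau_means(recording.ppg, plateaus)
    reg = FlowSaturationRegressor(**regressor_kwargs).fit(q, v)
    out = reg.to_fit_result()
    out.extras["n_plateaus"] = len(plateaus)
    return out


# ---------------------------------------------------------------------------
# biexponential relaxation


class BiexponentialDecayRegressor(BaseEstimator, RegressorMixin):
    """Biexponential decay fit y(t) = C + A*(r*exp(-t/tau_d) + exp(-t/tau_a)).

    Recovers the disorientation and aggregation time constants and their
    amplitude ratio r = n_d/n_a from one post-deceleration pause. The
    ordering tau_d < tau_a is enforced by parameterization
    (tau_a = tau_d * (1 + exp(phi))), and r and tau_d are fitted on the log
    scale; A may take either sign, so the same fit serves reflected-light
    and PPG-sign data. Multi-start initialization guards against the
    well-known multimodality of biexponential least squares.

    Fitted attributes: ``tau_d_``, ``tau_a_`` (s), ``amplitude_ratio_``,
    ``amplitude_``, ``offset_``, ``stderr_``, ``r_squared_``,
    ``converged_``, ``jacobian_cond_``.
    """

    def __init__(self, n_starts: int = 5, tau_d_grid: Optional[Sequence[float]] = None):
        self.n_starts = n_starts
        self.tau_d_grid = tau_d_grid

    @staticmethod
    def _unpack(theta):
        c, a, log_r, log_td, phi = theta
        tau_d = np.exp(log_td)
        tau_a = tau_d * (1.0 + np.exp(phi))
        return c, a, np.exp(log_r), tau_d, tau_a

    def _model(self, t, theta):
        c, a, r, tau_d, tau_a = self._unpack(theta)
        return c + a * (r * np.exp(-t / tau_d) + np.exp(-t / tau_a))

    def fit(self, X, y):
        t = _as_1d(X)
        y = _as_1d(y)
        if t.size != y.size:
            raise ValueError("t and y must have equal lengths")
        if t.size < 10:
            raise ValueError("too few samples for a biexponential fit")
        if np.any(np.diff(t) <= 0):
            raise ValueError("t must be strictly increasing")
        t = t - t[0]

        span = float(t[-1])
        grid = self.tau_d_grid
        if grid is None:
            grid = np.geomspace(0.02 * span, 0.3 * span, self.n_starts)
        c0 = float(np.mean(y[-max(t.size // 20, 5):]))
        a0 = (float(y[0]) - c0) / 3.0
        if a0 == 0.0:
            a0 = 1e-6

        def resid(theta):
            return y - self._model(t, theta)

        best = None
        for td0 in grid:
            x0 = np.array([c0, a0, np.log(2.0), np.log(td0), np.log(3.0)])
            try:
                sol = optimize.least_squares(resid, x0, method="lm", max_nfev=4000)
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise RuntimeError("biexponential fit failed from every start")

        c, a, r, tau_d, tau_a = self._unpack(best.x)
        ss_res = 2.0 * best.cost
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        se_theta, cond = _gauss_newton_se(best.jac, ss_res, t.size, 5)
        # delta method for the natural-scale parameters
        _, _, log_r, log_td, phi = best.x
        se = {
            "offset": se_theta[0],
            "amplitude": se_theta[1],
            "nd_na_ratio": r * se_theta[2],
            "tau_d": tau_d * se_theta[3],
            # tau_a = tau_d*(1+e^phi): combine both partials in quadrature
            "tau_a": float(
                np.hypot(tau_a * se_theta[3], tau_d * np.exp(phi) * se_theta[4])
            ),
        }
        self.offset_ = float(c)
        self.amplitude_ = float(a)
        self.amplitude_ratio_ = float(r)
        self.tau_d_ = float(tau_d)
        self.tau_a_ = float(tau_a)
        self.stderr_ = se
        self.r_squared_ = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
        self.jacobian_cond_ = cond
        self.converged_ = bool(best.success)
        self.residuals_ = resid(best.x)
        self.n_points_ = int(t.size)
        self.n_features_in_ = 1
        self._theta_ = best.x
        return self

    def predict(self, X):
        t = _as_1d(X)
        return self._model(t - t[0] if t.size and t[0] != 0 else t, self._theta_)

    def to_fit_result(self) -> FitResult:
        res = FitResult(
            params={
                "tau_d": self.tau_d_,
                "tau_a": self.tau_a_,
                "nd_na_ratio": self.amplitude_ratio_,
                "amplitude": self.amplitude_,
                "offset": self.offset_,
            },
            std_errors=dict(self.stderr_),
            r_squared=self.r_squared_,
            n_points=self.n_points_,
            converged=self.converged_,
            residuals=self.residuals_,
            extras={"jacobian_condition": float(self.jacobian_cond_)},
        )
        if abs(self.tau_a_ - self.tau_d_) < 0.05 * self.tau_a_:
            res.warnings_.append("tau_d ~ tau_a within 5%: ill-conditioned biexponential")
        if self.jacobian_cond_ > 1e6:
            res.warnings_.append("ill-conditioned Jacobian")
        return res


def fit_biexponential(
    recording: HemodynamicRecording,
    pauses=None,
    **regressor_kwargs,
) -> FitResult:
    """Pooled biexponential decay constants from an intermittent recording.

    Each pause (t = 0 at deceleration end) is fitted separately with
    :class:`BiexponentialDecayRegressor`; per-pause estimates of tau_d,
    tau_a and n_d/n_a are pooled into mean (SD) across pauses, mirroring
    the usual syllectometry-style reporting. With a single pause the
    per-pause estimate is returned without a pooled SD.
    """
    if recording.ppg is None:
        raise ValueError("recording has no PPG channel")
    if pauses is None:
        pauses = recording.pauses
    if not pauses:
        raise ValueError("no pause segments available (intermittent protocol required)")

    per_pause = []
    warns: list = []
    for s, e in pauses:
        t = recording.time[s:e] - recording.time[s]
        reg = BiexponentialDecayRegressor(**regressor_kwargs).fit(t, recording.ppg[s:e])
        per_pause.append(reg)
        if t[-1] < 5.0 * reg.tau_a_:
            warns.append(
                f"pause of {t[-1]:.1f} s is shorter than 5*tau_a "
                f"({5 * reg.tau_a_:.1f} s): decay not fully observed"
            )

    names = ("tau_d", "tau_a", "nd_na_ratio")
    stacked = {
        "tau_d": np.array([r.tau_d_ for r in per_pause]),
        "tau_a": np.array([r.tau_a_ for r in per_pause]),
        "nd_na_ratio": np.array([r.amplitude_ratio_ for r in per_pause]),
    }
    params = {k: float(stacked[k].mean()) for k in names}
    if len(per_pause) > 1:
        sds = {k: float(stacked[k].std(ddof=1)) for k in names}
    else:
        sds = {k: float("nan") for k in names}
    res = FitResult(
        params=params,
        std_errors=sds,
        r_squared=float(np.mean([r.r_squared_ for r in per_pause])),
        n_points=int(sum(r.n_points_ for r in per_pause)),
        converged=all(r.converged_ for r in per_pause),
        warnings_=warns,
        extras={
            "n_pauses": len(per_pause),
            "per_pause": {k: [float(v) for v in stacked[k]] for k in names},
            "se_is_pooled_sd": True,
        },
    )
    return res


# ---------------------------------------------------------------------------
# shear-domain conversion and treatment-effect arithmetic


def wall_shear_rate(flow, diameter):
    """Poiseuille wall shear rate gamma = 32*Q/(pi*D^3), in 1/s.

    ``flow`` in mL/min, ``diameter`` in mm. Homogeneous of degree 1 in Q
    and degree -3 in D.
    """
    q = np.asarray(flow, dtype=float)
    d = np.asarray(diameter, dtype=float)
    if np.any(q < 0):
        raise ValueError("flow must be non-negative")
    if np.any(d <= 0):
        raise ValueError("diameter must be positive")
    out = 32.0 * (q * _MLMIN_TO_MM3S) / (np.pi * d**3)
    return out if out.ndim else float(out)


def solve_reference_diameter(q_c: float, gamma_c: float) -> float:
    """Diameter (mm) at which flow q_c (mL/min) gives wall shear gamma_c (1/s)."""
    if q_c <= 0 or gamma_c <= 0:
        raise ValueError("q_c and gamma_c must be positive")
    return float((32.0 * q_c * _MLMIN_TO_MM3S / (np.pi * gamma_c)) ** (1.0 / 3.0))


def aggregation_change(ratio_control: float, ratio_treated: float):
    """Percent change in n_d/n_a and the implied aggregation reduction.

    An aggregation inhibitor lowers n_a while leaving n_d unchanged, so the
    ratio increase by a factor f = r_treated/r_control corresponds to an
    aggregation (n_a) reduction of 100*(1 - 1/f) percent. Returns
    ``(ratio_increase_pct, aggregation_reduction_pct)``.
    """
    if ratio_control <= 0 or ratio_treated <= 0:
        raise ValueError("ratios must be positive")
    f = ratio_treated / ratio_control
    return 100.0 * (f - 1.0), 100.0 * (1.0 - 1.0 / f)


def compare_ratio_batches(ratios_a, ratios_b):
    """Welch's unequal-variance t-test between two batches of fitted ratios.

    Returns ``(t_statistic, p_value)``.
    """
    res = stats.ttest_ind(_as_1d(ratios_a), _as_1d(ratios_b), equal_var=False)
    return float(res.statistic), float(res.pvalue)
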