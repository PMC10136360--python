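"""Forward optical model of reflective arterial photoplethysmography.

The reflected irradiance reaching the probe is decomposed into a constant
background (surrounding tissue and reflector), a blood-volume pathway driven
by intraluminal pressure through the arterial wall law, and a blood-flow
pathway driven by red-blood-cell (RBC) orientation and aggregation:

    E = E_DC + E_V + E_Q

The volume pathway is linear in pressure over the physiological range. The
flow pathway saturates hyperbolically with flow rate (half-saturation at the
critical flow rate Q_c) during acceleration/high shear, and relaxes along a
biexponential — disorientation (tau_d) plus aggregation (tau_a), amplitude
ratio n_d/n_a — during deceleration/low shear. The measured PPG signal is a
monotone transform of E; by the usual sign convention a pressure rise
increases PPG while a flow rise decreases it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from scipy import signal as sps
from sklearn.base import BaseEstimator

from .containers import HemodynamicRecording, VesselModel

__all__ = [
    "SensorModel",
    "PressureOpticsParams",
    "FlowOpticsParams",
    "IrradianceComponents",
    "ev_from_pressure",
    "ev_diffusion",
    "diffusion_irradiance",
    "aligned_fraction",
    "eq_high",
    "decay_kernel",
    "flow_response_kernel",
    "classify_regimes",
    "eq_flow_series",
    "compose_irradiance",
    "sensor_response",
    "predict_ppg",
    "PPGForwardModel",
]

HIGH_SHEAR = 0
LOW_SHEAR = 1


@dataclass
class SensorModel:
    """Receiver (phototransistor) response: V = c * E**d + offset.

    The exponent d is a property of the photodetector operating curve
    (d = 1.3 for the probes modelled here); the gain c depends on the
    circuit. The wavelength is metadata only — the model is
    single-wavelength.
    """

    response_coefficient_c: float = 1.0
    response_exponent_d: float = 1.3
    wavelength: float = 830.0
    dc_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.response_exponent_d <= 0:
            raise ValueError("response_exponent_d must be positive")


@dataclass
class PressureOpticsParams:
    """Volume-pathway constants.

    ``intercept_a``/``slope_b`` are the linearized constants a', b' mapping
    pressure (mmHg) to the pressure-related PPG contribution (a.u.); the
    slope is positive under the PPG sign convention. The optional constants
    parameterize the underlying small-angle-scattering diffusion form
    ``E0 * exp(-mu_a z) * cosh(z * sqrt(2 mu_a mu_s'))`` with the optical
    path ``z`` taken as the pressure-dependent diameter.
    """

    intercept_a: float = 0.0
    slope_b: float = 2.15
    incident_irradiance_E0: Optional[float] = None
    absorption_mu_a: Optional[float] = None
    reduced_scattering_mu_s_prime: Optional[float] = None

    def __post_init__(self) -> None:
        if self.slope_b <= 0:
            raise ValueError(
                "slope_b must be positive: the pressure-PPG relationship is "
                "positive under the sign convention used here"
            )

    def has_diffusion_constants(self) -> bool:
        return not any(
            v is None
            for v in (
                self.incident_irradiance_E0,
                self.absorption_mu_a,
                self.reduced_scattering_mu_s_prime,
            )
        )


@dataclass
class FlowOpticsParams:
    """Flow-pathway constants.

    m_prime (a.u.) and q_c (mL/min) set the saturating orientation law;
    tau_d and tau_a (s) are the disorientation and aggregation decay
    constants, combined with amplitude ratio nd_na_ratio (only the ratio is
    identifiable, since the relaxation kernel is normalized). alignment_m
    and gamma_c carry the equivalent shear-domain law. decel_flow_fraction
    sets the flow threshold (as a fraction of q_c) below which a
    decelerating flow is treated as low-shear.
    """

    m_prime: float = 1613.0
    q_c: float = 328.0
    tau_d: float = 0.39
    tau_a: float = 1.78
    nd_na_ratio: float = 2.2
    alignment_m: Optional[float] = None
    gamma_c: Optional[float] = None
    decel_flow_fraction: float = 0.5
    kernel_horizon: Optional[float] = None

    def __post_init__(self) -> None:
        if self.m_prime < 0:
            raise ValueError("m_prime must be non-negative")
        if self.q_c <= 0:
            raise ValueError("q_c must be positive")
        if self.tau_d <= 0 or self.tau_a <= 0:
            raise ValueError("decay constants must be positive")
        if self.nd_na_ratio <= 0:
            raise ValueError("nd_na_ratio must be positive")
        if not 0 < self.decel_flow_fraction <= 1:
            raise ValueError("decel_flow_fraction must lie in (0, 1]")
        if self.kernel_horizon is not None and self.kernel_horizon < 5 * max(self.tau_d, self.tau_a):
            raise ValueError("kernel_horizon must be at least 5*max(tau_d, tau_a)")

    @property
    def horizon(self) -> float:
        """Kernel truncation horizon, default 8*max(tau_d, tau_a) seconds."""
        if self.kernel_horizon is not None:
            return self.kernel_horizon
        return 8.0 * max(self.tau_d, self.tau_a)


@dataclass
class IrradianceComponents:
    """Constant, volume-related and flow-related irradiance of a recording."""

    e_dc: float
    e_v: np.ndarray
    e_q: np.ndarray
    regimes: Optional[np.ndarray] = field(default=None)

    def __post_init__(self) -> None:
        self.e_v = np.asarray(self.e_v, dtype=float)
        self.e_q = np.asarray(self.e_q, dtype=float)
        if self.e_v.shape != self.e_q.shape:
            raise ValueError("e_v and e_q must have equal lengths")

    @property
    def total(self) -> np.ndarray:
        return self.e_dc + self.e_v + self.e_q


# ---------------------------------------------------------------------------
# volume pathway


def ev_from_pressure(pressure, params: PressureOpticsParams) -> np.ndarray:
    """Linearized volume-pathway contribution a' + b'*P (elementwise)."""
    p = np.asarray(pressure, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("pressure contains non-finite values")
    return params.intercept_a + params.slope_b * p


def diffusion_irradiance(z, e0: float, mu_a: float, mu_s_prime: float):
    """Small-angle-scattering diffusion form E0*exp(-mu_a z)*cosh(z*sqrt(2 mu_a mu_s')).

    ``z`` is the optical path length in blood (mm); ``mu_a`` and
    ``mu_s_prime`` are the absorption and reduced scattering coefficients
    (1/mm). With mu_s' = 0 this reduces to the Beer-Lambert limit
    E0*exp(-mu_a z).
    """
    z = np.asarray(z, dtype=float)
    out = e0 * np.exp(-mu_a * z) * np.cosh(z * np.sqrt(2.0 * mu_a * mu_s_prime))
    return out if out.ndim else float(out)


def ev_diffusion(pressure, params: PressureOpticsParams, vessel: VesselModel) -> np.ndarray:
    """Nonlinear volume pathway: the diffusion form evaluated at z = D(P).

    Returns physical reflected irradiance, which *decreases* with pressure;
    the linearized :func:`ev_from_pressure` works in PPG-sign units instead.
    The two agree to first order around the vessel's reference pressure when
    the linear constants are derived from the same optical constants.
    """
    if not params.has_diffusion_constants():
        raise ValueError(
            "diffusion constants (incident_irradiance_E0, absorption_mu_a, "
            "reduced_scattering_mu_s_prime) are not set; use the linear form "
            "ev_from_pressure instead"
        )
    z = vessel.diameter(pressure)
    return diffusion_irradiance(
        z,
        params.incident_irradiance_E0,
        params.absorption_mu_a,
        params.reduced_scattering_mu_s_prime,
    )


# ---------------------------------------------------------------------------
# flow pathway


def aligned_fraction(shear_rate, m: float, gamma_c: float):
    """Fraction of flow-aligned RBCs, m*(g/gc)/(1+g/gc), bounded in [0, m)."""
    if gamma_c <= 0:
        raise ValueError("gamma_c must be positive")
    g = np.asarray(shear_rate, dtype=float)
    if np.any(g < 0):
        raise ValueError("shear rate must be non-negative")
    x = g / gamma_c
    out = m * x / (1.0 + x)
    return out if out.ndim else float(out)


def eq_high(flow, params: FlowOpticsParams):
    """High-shear flow-related irradiance m'*(Q/Qc)/(1+Q/Qc), a.u."""
    q = np.asarray(flow, dtype=float)
    if np.any(q < 0):
        raise ValueError("flow must be non-negative (retrograde flow is not modelled)")
    x = q / params.q_c
    out = params.m_prime * x / (1.0 + x)
    return out if out.ndim else float(out)


def decay_kernel(params: FlowOpticsParams, dt: float) -> np.ndarray:
    """Sampled biexponential relaxation shape, normalized to unit time-integral.

    h[k] is proportional to r*exp(-t_k/tau_d) + exp(-t_k/tau_a) on
    t_k = k*dt up to the kernel horizon, scaled so that sum(h)*dt == 1.
    This is the shape of the PPG relaxation after an abrupt flow stop
    (disorientation plus aggregation); see :func:`flow_response_kernel` for
    the convolution weights that realize it as a causal unit-DC-gain filter.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    horizon = params.horizon
    if horizon < 5 * max(params.tau_d, params.tau_a):
        raise ValueError("kernel horizon shorter than 5*max(tau_d, tau_a)")
    t = np.arange(0.0, horizon + 0.5 * dt, dt)
    h = params.nd_na_ratio * np.exp(-t / params.tau_d) + np.exp(-t / params.tau_a)
    h /= h.sum() * dt
    return h


def flow_response_kernel(params: FlowOpticsParams, dt: float, n: int) -> np.ndarray:
    """Discrete causal weights of the low-shear relaxation filter.

    The filter is the r:1 mixture of two exact-decay first-order lags,

        w[k] = (r*(1-a_d)*a_d**k + (1-a_a)*a_a**k) / (r+1),  a = exp(-dt/tau),

    whose response to a step-to-zero input is exactly the normalized
    biexponential (r*exp(-t/tau_d) + exp(-t/tau_a))/(r+1), and whose DC gain
    is 1 (a sustained high-shear input passes through unchanged, keeping the
    regime transition continuous).
    """
    if dt <= 0 or n <= 0:
        raise ValueError("dt and n must be positive")
    k = np.arange(n)
    r = params.nd_na_ratio
    a_d = np.exp(-dt / params.tau_d)
    a_a = np.exp(-dt / params.tau_a)
    return (r * (1.0 - a_d) * a_d**k + (1.0 - a_a) * a_a**k) / (r + 1.0)


def _smoothed_derivative(q: np.ndarray, fs: float, window_s: float = 0.05) -> np.ndarray:
    """Savitzky-Golay first derivative of the flow channel (units/s)."""
    n = q.size
    win = max(int(round(window_s * fs)), 5)
    if win % 2 == 0:
        win += 1
    if win >= n:
        return np.gradient(q, 1.0 / fs)
    return sps.savgol_filter(q, win, polyorder=2, deriv=1, delta=1.0 / fs)


def _suppress_short_runs(labels: np.ndarray, min_len: int) -> np.ndarray:
    """Merge label runs shorter than min_len into the preceding run."""
    if min_len <= 1 or labels.size == 0:
        return labels
    out = labels.copy()
    boundaries = np.flatnonzero(np.diff(out)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [out.size]))
    for s, e in zip(starts, ends):
        if e - s < min_len and s > 0:
            out[s:e] = out[s - 1]
    return out


def classify_regimes(
    flow,
    params: FlowOpticsParams,
    fs: float,
    zero_flow_tol: Optional[float] = None,
    hysteresis_s: float = 0.02,
    exit_fraction: float = 0.1,
) -> np.ndarray:
    """Per-sample shear-regime labels (0 = high shear, 1 = low shear).

    A sample enters the low-shear regime when the smoothed flow derivative
    is negative while the flow is below ``decel_flow_fraction * q_c``, or
    when the flow is (near) zero; it returns to high shear once the flow
    re-accelerates above ``exit_fraction * q_c``. A minimum dwell time
    (``hysteresis_s``) removes noise-induced label chatter.
    """
    q = np.asarray(flow, dtype=float)
    if q.ndim != 1:
        raise ValueError("flow must be one-dimensional")
    if zero_flow_tol is None:
        zero_flow_tol = 0.02 * params.q_c
    dq = _smoothed_derivative(q, fs)
    thresh = params.decel_flow_fraction * params.q_c
    exit_thresh = exit_fraction * params.q_c

    labels = np.empty(q.size, dtype=np.int8)
    state = LOW_SHEAR if q[0] < zero_flow_tol else HIGH_SHEAR
    for i in range(q.size):
        if state == HIGH_SHEAR:
            if (dq[i] < 0 and q[i] < thresh) or q[i] < zero_flow_tol:
                state = LOW_SHEAR
        else:
            if dq[i] > 0 and q[i] > exit_thresh:
                state = HIGH_SHEAR
        labels[i] = state
    min_len = max(1, int(round(hysteresis_s * fs)))
    return _suppress_short_runs(labels, min_len)


def eq_flow_series(
    flow,
    params: FlowOpticsParams,
    fs: float,
    input_mode: str = "instantaneous",
    labels: Optional[np.ndarray] = None,
):
    """Flow-related irradiance E_Q over a uniformly sampled flow series.

    High-shear samples follow the instantaneous saturation law
    :func:`eq_high` (RBC orientation is fast and treated as immediate). On
    entering a low-shear stretch the output follows the causal relaxation
    filter of :func:`flow_response_kernel` driven by the instantaneous
    high-shear input (``input_mode='instantaneous'``, default) or decaying
    freely from the value at entry (``input_mode='frozen'``); both reduce to
    the normalized biexponential decay for an abrupt stop. The output is
    continuous at regime boundaries.

    Returns
    -------
    e_q : ndarray
    labels : ndarray of {0, 1}
    """
    if input_mode not in ("instantaneous", "frozen"):
        raise ValueError("input_mode must be 'instantaneous' or 'frozen'")
    q = np.asarray(flow, dtype=float)
    u = np.atleast_1d(eq_high(q, params))
    if labels is None:
        labels = classify_regimes(q, params, fs)
    dt = 1.0 / fs
    r = params.nd_na_ratio
    a_d = np.exp(-dt / params.tau_d)
    a_a = np.exp(-dt / params.tau_a)

    e = u.copy()
    low = labels == LOW_SHEAR
    if low.any():
        # contiguous low-shear runs
        idx = np.flatnonzero(np.diff(low.astype(np.int8)))
        starts = [i + 1 for i in idx if low[i + 1]]
        ends = [i + 1 for i in idx if not low[i + 1]]
        if low[0]:
            starts.insert(0, 0)
        if low[-1]:
            ends.append(low.size)
        for s, t_end in zip(starts, ends):
            init = e[s - 1] if s > 0 else u[s]
            drive = u[s:t_end] if input_mode == "instantaneous" else np.zeros(t_end - s)
            x_d = sps.lfilter([1.0 - a_d], [1.0, -a_d], drive, zi=np.array([a_d * init]))[0]
            x_a = sps.lfilter([1.0 - a_a], [1.0, -a_a], drive, zi=np.array([a_a * init]))[0]
            e[s:t_end] = (r * x_d + x_a) / (r + 1.0)
    return e, labels


def compose_irradiance(e_dc: float, e_v, e_q, regimes=None) -> IrradianceComponents:
    """Assemble the total irradiance E = E_DC + E_V + E_Q."""
    return IrradianceComponents(e_dc=float(e_dc), e_v=e_v, e_q=e_q, regimes=regimes)


def sensor_response(irradiance, sensor: SensorModel, mode: str = "power"):
    """Receiver transfer c*E**d + offset, or its linearization about mean(E).

    The linearized mode is the first-order Taylor expansion around the
    series mean, valid when irradiance fluctuations are small relative to
    the mean (relative error bounded by (dE/E)**2 terms).
    """
    e = np.asarray(irradiance, dtype=float)
    c, d = sensor.response_coefficient_c, sensor.response_exponent_d
    if mode == "power":
        if np.any(e <= 0) and not float(d).is_integer():
            raise ValueError("irradiance must be positive for non-integer exponent d")
        out = c * np.power(e, d) + sensor.dc_offset
    elif mode == "linear":
        mean = float(np.mean(e))
        if mean <= 0:
            raise ValueError("mean irradiance must be positive to linearize")
        out = c * mean**d + c * d * mean ** (d - 1.0) * (e - mean) + sensor.dc_offset
    else:
        raise ValueError("mode must be 'power' or 'linear'")
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# end-to-end prediction


def predict_ppg(
    recording: HemodynamicRecording,
    pressure_params: PressureOpticsParams,
    flow_params: FlowOpticsParams,
    sensor: Optional[SensorModel] = None,
    mode: str = "P_and_Q",
    reference_mean: Optional[float] = None,
    return_components: bool = False,
):
    """Predict the uncalibrated PPG series from pressure (and flow).

    Sign convention: a pressure rise increases PPG (reduced reflected
    light), so the volume pathway enters as +(a' + b'*P) while the
    flow-related reflected irradiance enters with a negative sign,

        PPG = a' + b'*P - E_Q(Q)  (+ sensor dc offset).

    ``mode='P_only'`` zeroes the flow term (the volume-only hypothesis);
    ``mode='P_and_Q'`` requires the flow channel. Small negative flow
    excursions from measurement noise are clipped to zero; clearly
    retrograde flow raises. If ``reference_mean`` is given, a constant
    offset is added so the output mean matches it.
    """
    if mode not in ("P_and_Q", "P_only"):
        raise ValueError("mode must be 'P_and_Q' or 'P_only'")
    e_v = ev_from_pressure(recording.pressure, pressure_params)
    regimes = None
    if mode == "P_and_Q":
        q = np.asarray(recording.flow, dtype=float)
        if np.min(q) < -0.2 * flow_params.q_c:
            raise ValueError("flow channel contains strongly negative values")
        q = np.clip(q, 0.0, None)
        e_q, regimes = eq_flow_series(q, flow_params, recording.sampling_rate)
    else:
        e_q = np.zeros_like(e_v)
    ppg = e_v - e_q
    if sensor is not None:
        ppg = ppg + sensor.dc_offset
    if reference_mean is not None:
        ppg = ppg + (reference_mean - float(np.mean(ppg)))
    if return_components:
        return ppg, IrradianceComponents(e_dc=0.0, e_v=e_v, e_q=e_q, regimes=regimes)
    return ppg


class PPGForwardModel(BaseEstimator):
    """Predict-shaped estimator wrapping the pressure+flow forward model.

    Parameters mirror :func:`predict_ppg`; ``predict`` maps a
    :class:`~rppgflow.containers.HemodynamicRecording` to a PPG series in
    arbitrary units. The estimator is stateless (its parameters come from
    calibration, see :mod:`rppgflow.calibration`) and composes with sklearn
    tooling through ``get_params``/``set_params``.
    """

    def __init__(
        self,
        pressure_params: Optional[PressureOpticsParams] = None,
        flow_params: Optional[FlowOpticsParams] = None,
        sensor: Optional[SensorModel] = None,
        mode: str = "P_and_Q",
    ):
        self.pressure_params = pressure_params
        self.flow_params = flow_params
        self.sensor = sensor
        self.mode = mode

    def fit(self, X=None, y=None):
        """No-op; present for sklearn API compatibility."""
        self.n_features_in_ = 0
        return self

    def predict(self, recording: HemodynamicRecording, **kwargs) -> np.ndarray:
        pp = self.pressure_params or PressureOpticsParams()
        fp = self.flow_params or FlowOpticsParams()
        return predict_ppg(recording, pp, fp, sensor=self.sensor, mode=self.mode, **kwargs)


def params_to_dict(obj) -> dict:
    """Serialize a parameter dataclass to a plain dict (JSON-friendly)."""
    return asdict(obj)
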