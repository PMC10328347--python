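"""Cellular calcium/active-tension surrogates and passive Guccione mechanics.

The calcium transient is a phenomenological double-exponential surrogate
whose shape parameters are driven by multipliers named after the ionic
quantities they stand for: ``amp_scale`` (L-type calcium conductance,
P_Ca / g_CaL), ``decay_scale`` (calcium removal, G_NCX / I_up(max)) and
``buffer_scale`` (troponin buffering, [TRPN]).  Active tension follows a
reduced troponin / tropomyosin / three-state crossbridge scheme with the
field's standard parameter names (T_ref, ca_50, n_TRPN, n_Tm, k_TRPN,
k_u, nu, mu, r_s, r_w, A_eff, phi); the length-dependence parameters
(beta_0, beta_1) and distortion rates (gamma_s, gamma_w) are accepted
for interface completeness but inert in the isometric surrogate.

Passive myocardium follows the transversely isotropic exponential
strain-energy law

    Psi(E) = a/2 (e^Q - 1) + kappa/2 (log J)^2
    Q = b_f E_ff^2 + 2 b_ft (E_fs^2 + E_fn^2) + b_t (E_ss^2 + E_nn^2 + 2 E_sn^2)

and chamber inflation solves thin-wall spherical equilibrium
p = 2 sigma(lambda) h(lambda) / r(lambda) for the equibiaxial stretch.

Units: ms, uM (calcium), kPa (tension/stress), mL, mmHg (cavity pressure).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CalciumParams",
    "LandParams",
    "GuccioneParams",
    "CalciumTransient",
    "TensionTransient",
    "TransientFeatures",
    "simulate_calcium",
    "simulate_tension",
    "transient_features",
    "strain_energy",
    "pk2_stress",
    "inflate_chamber",
    "unload_chamber",
    "KPA_TO_MMHG",
]

KPA_TO_MMHG = 7.50062

# base crossbridge cycling rate (1/ms); nu and mu multiply it for the
# U->W and W->S transitions respectively
_K0 = 0.009


@dataclass(frozen=True)
class CalciumParams:
    """Shape parameters of the calcium-transient surrogate (uM, ms)."""

    Ca_dias: float = 0.10
    Ca_amp: float = 1.05
    tau_rise: float = 15.0
    tau_decay: float = 150.0
    amp_scale: float = 1.0    # stands for P_Ca / g_CaL
    decay_scale: float = 1.0  # stands for G_NCX / I_up(max)
    buffer_scale: float = 1.0  # stands for [TRPN] / [Trpn]_max

    def __post_init__(self) -> None:
        vals = (self.Ca_dias, self.Ca_amp, self.tau_rise, self.tau_decay,
                self.amp_scale, self.decay_scale, self.buffer_scale)
        if any(v <= 0 for v in vals):
            raise ValueError("all calcium parameters must be positive")
        if self.tau_rise >= self.tau_decay * self.decay_scale:
            raise ValueError("tau_rise must be below the effective tau_decay")


#: atrial default: smaller, faster transient
ATRIAL_CALCIUM = CalciumParams(Ca_dias=0.12, Ca_amp=0.55, tau_rise=10.0,
                               tau_decay=110.0)


@dataclass(frozen=True)
class LandParams:
    """Active-tension parameters (kPa, ms, uM)."""

    T_ref: float = 120.0
    ca_50: float = 0.55
    n_TRPN: float = 2.0
    k_TRPN: float = 0.1
    TRPN_50: float = 0.35
    n_Tm: float = 5.0
    k_u: float = 0.03
    nu: float = 7.0
    mu: float = 3.0
    r_s: float = 0.25
    r_w: float = 0.5
    A_eff: float = 25.0
    phi: float = 2.23
    beta_0: float = 2.3   # inert in the isometric surrogate
    beta_1: float = -2.4  # inert
    gamma_s: float = 0.0085  # inert
    gamma_w: float = 0.615   # inert

    def __post_init__(self) -> None:
        if not 0 < self.r_s < 1:
            raise ValueError("r_s must be in (0, 1)")
        if self.r_w <= 0:
            raise ValueError("r_w must be positive")
        if self.r_s * (1 + self.r_w) >= 1:
            raise ValueError("r_s (1 + r_w) must stay below 1")
        if min(self.n_TRPN, self.n_Tm) < 1:
            raise ValueError("Hill exponents must be >= 1")
        if min(self.T_ref, self.ca_50, self.k_TRPN, self.TRPN_50, self.k_u,
               self.nu, self.mu) <= 0:
            raise ValueError("rates and sensitivities must be positive")


#: atrial default: faster, weaker twitch
ATRIAL_LAND = LandParams(T_ref=60.0, ca_50=0.45, k_u=0.06, mu=4.0)


@dataclass(frozen=True)
class GuccioneParams:
    a: float = 1.0      # kPa
    b_f: float = 8.0
    b_ft: float = 4.0
    b_t: float = 3.0
    kappa: float = 1000.0  # kPa

    def __post_init__(self) -> None:
        if min(self.a, self.b_f, self.b_ft, self.b_t, self.kappa) <= 0:
            raise ValueError("all stiffness parameters must be positive")


#: atrial default passive stiffness
ATRIAL_GUCCIONE = GuccioneParams(a=2.0, b_f=8.0, b_ft=4.0, b_t=3.0)
VENTRICULAR_GUCCIONE = GuccioneParams(a=1.0, b_f=8.0, b_ft=4.0, b_t=3.0)


@dataclass
class CalciumTransient:
    t: np.ndarray          # ms, uniform grid over all simulated beats
    value: np.ndarray      # uM; may be batched with shape (B, nt)
    bcl: float
    activation_offset: float = 0.0
    converged: bool = True


@dataclass
class TensionTransient:
    t: np.ndarray
    value: np.ndarray      # kPa
    bcl: float
    activation_offset: float = 0.0


@dataclass
class TransientFeatures:
    peak: float
    rest: float
    amplitude: float
    time_to_peak: float
    duration90: float
    max_upstroke: float

    def to_dict(self) -> dict:
        return self.__dict__.copy()


# ---------------------------------------------------------------------------
# calcium surrogate
# ---------------------------------------------------------------------------

def simulate_calcium(
    params: CalciumParams, bcl: float, n_beats: int = 4, dt: float = 1.0
) -> CalciumTransient:
    """Paced calcium transient: double-exponential beats superposed.

    Per beat, Ca(t') = Ca_dias + Ca_amp * amp_scale * g(t') with
    g = (exp(-t'/(tau_decay*decay_scale)) - exp(-t'/tau_rise)) normalised
    to unit peak.  Beats superpose additively; steady state is declared
    when the beat-to-beat peak change drops below 0.1%.
    """
    if bcl <= 0:
        raise ValueError("bcl must be positive")
    if dt > 1.0:
        raise ValueError("calcium time step must be <= 1 ms")
    td = params.tau_decay * params.decay_scale
    tr = params.tau_rise
    t_peak = np.log(td / tr) * td * tr / (td - tr)
    norm = np.exp(-t_peak / td) - np.exp(-t_peak / tr)
    t = np.arange(0.0, n_beats * bcl + dt / 2, dt)
    ca = np.full_like(t, params.Ca_dias)
    peaks = []
    for b in range(n_beats):
        tp = t - b * bcl
        g = np.where(
            tp >= 0, (np.exp(-tp / td) - np.exp(-np.minimum(tp, 7e2 * tr) / tr)), 0.0
        )
        ca = ca + params.Ca_amp * params.amp_scale * g / norm
        lo, hi = int(b * bcl / dt), int(min((b + 1) * bcl / dt, len(t) - 1))
        peaks.append(ca[lo : hi + 1].max())
    converged = (
        len(peaks) < 2 or abs(peaks[-1] - peaks[-2]) / peaks[-1] < 1e-3
    )
    if not converged:
        warnings.warn(
            f"calcium pacing not converged in {n_beats} beats "
            f"(last peak delta {abs(peaks[-1]-peaks[-2]):.3g} uM)"
        )
    return CalciumTransient(t, ca, bcl, converged=converged)


# ---------------------------------------------------------------------------
# active tension surrogate
# ---------------------------------------------------------------------------

def _tension_rates(params):
    """Crossbridge rates; off-rates pinned by the P=1 steady state."""
    k_uw = params.nu * _K0
    k_ws = params.mu * _K0
    S = params.r_s
    W = params.r_w * S
    U = 1.0 - S - W
    k_wu = k_uw * U / W          # U k_uw = W k_wu at steady state (P=1)
    k_sw = k_ws * params.r_w     # W k_ws = S k_sw with W/S = r_w
    return k_uw, k_ws, k_wu, k_sw


class _ParamArrays:
    """Field-wise stacking of a sequence of LandParams into (B,) arrays."""

    def __init__(self, params_seq):
        for name in LandParams.__dataclass_fields__:
            setattr(self, name,
                    np.array([getattr(p, name) for p in params_seq], float))


def simulate_tension(
    ca: CalciumTransient,
    params: "LandParams | list[LandParams]",
    velocity_series: np.ndarray | None = None,
    dt: float = 0.02,
    buffer_scale: float | np.ndarray = 1.0,
) -> TensionTransient:
    """Integrate the troponin/tropomyosin/crossbridge scheme (RK4).

    State: CaTRPN (troponin occupancy), P (permissive tropomyosin
    fraction), W and S crossbridge fractions (U = 1 - W - S):

        CaTRPN' = k_TRPN * buffer * [ (Ca/ca_50)^n_TRPN (1-CaTRPN) - CaTRPN ]
        P'      = k_u (P_inf - P),  P_inf = CaTRPN^n_Tm/(CaTRPN^n_Tm+TRPN_50^n_Tm)
        W'      = nu*k0 * P * U - (k_wu + mu*k0) W + k_sw S
        S'      = mu*k0 * W - k_sw S

    Off-rates are pinned so the sustained P=1 steady state has S = r_s
    and W/S = r_w; isometric tension is T = T_ref * S / r_s, so
    saturating calcium drives T to T_ref.  A shortening-velocity series
    (normalised units) applies the factor (1 - A_eff tanh(phi v)),
    clamped to [0, 1].  Calcium may be batched (B, nt), and ``params``
    may be a matching list of parameter sets (with ``buffer_scale`` an
    array); states are then integrated for all batch members
    simultaneously.
    """
    t_ca = ca.t
    v_ca = np.atleast_2d(ca.value)
    buffer = np.asarray(buffer_scale, float)
    if isinstance(params, (list, tuple)):
        if len(params) != v_ca.shape[0]:
            raise ValueError("params list and calcium batch size differ")
        params = _ParamArrays(params)
    k_uw, k_ws, k_wu, k_sw = _tension_rates(params)
    t = np.arange(t_ca[0], t_ca[-1] + dt / 2, dt)
    # sample calcium on the integration grid once (linear interpolation)
    ca_fine = np.vstack([np.interp(t, t_ca, row) for row in v_ca])
    B = ca_fine.shape[0]

    c = np.zeros(B)
    P = np.zeros(B)
    W = np.zeros(B)
    S = np.zeros(B)
    n_trpn, n_tm = params.n_TRPN, params.n_Tm
    trpn50n = params.TRPN_50**n_tm
    kt = params.k_TRPN * buffer
    T = np.empty((B, len(t)))
    e_ku = np.exp(-params.k_u * dt)

    # CaTRPN and P are pure relaxation equations whose rate can become
    # arbitrarily stiff at high calcium; integrate them with exact
    # exponential updates (coefficients frozen at the step midpoint).
    # The crossbridge pair (W, S) has bounded rates; Heun's method.
    for i in range(len(t)):
        T[:, i] = params.T_ref * S / params.r_s
        if i == len(t) - 1:
            break
        ca_mid = 0.5 * (ca_fine[:, i] + ca_fine[:, i + 1])
        x = (ca_mid / params.ca_50) ** n_trpn
        rate = kt * (1.0 + x)
        c_star = x / (1.0 + x)
        c = c_star + (c - c_star) * np.exp(-rate * dt)
        cn = np.maximum(c, 0.0) ** n_tm
        p_inf = cn / (cn + trpn50n)
        P = p_inf + (P - p_inf) * e_ku

        dw1 = k_uw * P * (1.0 - W - S) - (k_wu + k_ws) * W + k_sw * S
        ds1 = k_ws * W - k_sw * S
        W1, S1 = W + dt * dw1, S + dt * ds1
        dw2 = k_uw * P * (1.0 - W1 - S1) - (k_wu + k_ws) * W1 + k_sw * S1
        ds2 = k_ws * W1 - k_sw * S1
        W = W + 0.5 * dt * (dw1 + dw2)
        S = S + 0.5 * dt * (ds1 + ds2)
        if not (np.all(np.isfinite(W)) and np.all(np.isfinite(S))):
            raise RuntimeError(
                f"unstable tension integration at step {i} (t={t[i]:.2f} ms)"
            )
        W = np.clip(W, 0.0, 1.0)
        S = np.clip(S, 0.0, 1.0)
    if velocity_series is not None:
        v = np.interp(t, t_ca, np.asarray(velocity_series, float))
        factor = np.clip(1.0 - params.A_eff * np.tanh(params.phi * v), 0.0, 1.0)
        T = T * factor
    value = T[0] if np.ndim(ca.value) == 1 else T
    return TensionTransient(t, value, ca.bcl, ca.activation_offset)


def transient_features(
    series: CalciumTransient | TensionTransient,
) -> TransientFeatures:
    """Features of the last (steady-state) beat of a transient.

    Duration is measured from beat activation to 90% recovery toward the
    pre-beat baseline; crossings are linearly interpolated so features
    are stable under grid refinement.
    """
    t = np.asarray(series.t, float)
    v = np.asarray(series.value, float)
    if v.ndim != 1:
        raise ValueError("transient_features expects a single (unbatched) series")
    bcl = series.bcl
    t0 = t[-1] - bcl
    if t0 < t[0] - 1e-9:
        raise ValueError("need at least one full beat")
    m = t >= t0 - 1e-9
    tb, vb = t[m] - t[m][0], v[m]
    rest = float(vb[0])
    ipk = int(np.argmax(vb))
    peak = float(vb[ipk])
    amp = peak - rest
    if amp <= 0 or peak - rest < 1e-12 * max(abs(peak), 1.0):
        return TransientFeatures(peak, rest, 0.0, 0.0, 0.0, 0.0)
    ttp = float(tb[ipk])
    level = peak - 0.9 * amp
    dur = float(tb[-1])
    for i in range(ipk, len(vb) - 1):
        if vb[i + 1] <= level < vb[i] or (vb[i] > level >= vb[i + 1]):
            frac = (vb[i] - level) / (vb[i] - vb[i + 1])
            dur = float(tb[i] + frac * (tb[i + 1] - tb[i]))
            break
    dv = np.gradient(vb, tb)
    return TransientFeatures(peak, rest, amp, ttp, dur, float(dv.max()))


# ---------------------------------------------------------------------------
# passive Guccione mechanics
# ---------------------------------------------------------------------------

def _exponent_Q(E: np.ndarray, p: GuccioneParams) -> np.ndarray:
    E = np.asarray(E, float)
    return (
        p.b_f * E[..., 0, 0] ** 2
        + 2.0 * p.b_ft * (E[..., 0, 1] ** 2 + E[..., 0, 2] ** 2)
        + p.b_t * (E[..., 1, 1] ** 2 + E[..., 2, 2] ** 2 + 2.0 * E[..., 1, 2] ** 2)
    )


def strain_energy(E: np.ndarray, J: float, params: GuccioneParams) -> float:
    """Psi(E) in kPa; E is the Green-Lagrange strain in fibre coordinates."""
    if J <= 0:
        raise ValueError("J must be positive")
    E = np.asarray(E, float)
    if not np.allclose(E, np.swapaxes(E, -1, -2), atol=1e-12):
        raise ValueError("strain tensor must be symmetric")
    Q = _exponent_Q(E, params)
    psi = 0.5 * params.a * (np.exp(Q) - 1.0) + 0.5 * params.kappa * np.log(J) ** 2
    return float(psi) if np.ndim(psi) == 0 else psi


def pk2_stress(E: np.ndarray, params: GuccioneParams) -> np.ndarray:
    """Second Piola-Kirchhoff stress, the exact gradient of the energy.

    Derivatives are taken with respect to the independent (upper
    triangle) strain components, e.g. S_ff = a b_f E_ff e^Q and
    S_fs = 2 a b_ft E_fs e^Q.
    """
    E = np.asarray(E, float)
    Q = _exponent_Q(E, params)
    fac = params.a * np.exp(Q)
    S = np.zeros_like(E)
    S[..., 0, 0] = params.b_f * E[..., 0, 0]
    S[..., 1, 1] = params.b_t * E[..., 1, 1]
    S[..., 2, 2] = params.b_t * E[..., 2, 2]
    S[..., 0, 1] = S[..., 1, 0] = 2.0 * params.b_ft * E[..., 0, 1]
    S[..., 0, 2] = S[..., 2, 0] = 2.0 * params.b_ft * E[..., 0, 2]
    S[..., 1, 2] = S[..., 2, 1] = 2.0 * params.b_t * E[..., 1, 2]
    return fac[..., None, None] * S if np.ndim(fac) else fac * S


def _biaxial_strain(lam):
    """Green strains of an incompressible equibiaxial membrane stretch."""
    E = np.zeros(np.shape(lam) + (3, 3))
    E[..., 0, 0] = E[..., 1, 1] = 0.5 * (lam**2 - 1.0)
    E[..., 2, 2] = 0.5 * (lam**-4 - 1.0)
    return E


def wall_stress_biaxial(lam, params: GuccioneParams):
    """In-plane Cauchy stress (kPa) under plane-stress equibiaxial stretch."""
    lam = np.asarray(lam, float)
    E = _biaxial_strain(lam)
    S = pk2_stress(E, params)
    return lam**2 * S[..., 0, 0] - lam**-4 * S[..., 2, 2]


def cavity_pressure(
    V, unloaded_volume: float, wall_volume: float, params: GuccioneParams
):
    """Thin-wall transmural pressure (mmHg) at cavity volume V (mL)."""
    lam = np.cbrt(np.asarray(V, float) / unloaded_volume)
    r0 = (3.0 * unloaded_volume / (4.0 * np.pi)) ** (1.0 / 3.0)
    h0 = wall_volume / (4.0 * np.pi * r0**2)
    sigma = wall_stress_biaxial(lam, params)
    p_kpa = 2.0 * sigma * (h0 / lam**2) / (lam * r0)
    return p_kpa * KPA_TO_MMHG


def inflate_chamber(
    params: GuccioneParams,
    wall_volume: float,
    unloaded_volume: float,
    pressure: float,
    lam_max: float = 3.0,
) -> tuple[float, float]:
    """Quasi-static inflation of a thin-wall spherical chamber.

    Solves p = 2 sigma_biax(lambda) h(lambda) / r(lambda) for the
    equibiaxial stretch (bisection, 1e-8 relative) with the wall
    incompressible (h r^2 conserved).  Returns (volume mL, fibre Green
    strain E_ff).
    """
    if pressure < 0:
        raise ValueError("pressure must be >= 0")
    if pressure == 0.0:
        return float(unloaded_volume), 0.0

    def f(lam):
        return cavity_pressure(
            unloaded_volume * lam**3, unloaded_volume, wall_volume, params
        ) - pressure

    lo, hi = 1.0, lam_max
    if f(hi) < 0:
        raise ValueError(
            f"no equilibrium below lambda={lam_max}: pressure {pressure} mmHg "
            "beyond thin-wall model validity"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            hi = mid
        else:
            lo = mid
        if hi - lo < 1e-8 * hi:
            break
    lam = 0.5 * (lo + hi)
    return float(unloaded_volume * lam**3), float(0.5 * (lam**2 - 1.0))


def unload_chamber(
    params: GuccioneParams,
    wall_volume: float,
    loaded_volume: float,
    edp: float,
) -> float:
    """Unloaded volume whose inflation at the given EDP recovers the loaded one."""
    if edp < 0:
        raise ValueError("edp must be >= 0")
    if edp == 0.0:
        return float(loaded_volume)

    def g(v0):
        try:
            return inflate_chamber(params, wall_volume, v0, edp)[0] - loaded_volume
        except ValueError:
            return -loaded_volume  # pressure beyond validity: v0 too small

    lo, hi = 1e-3 * loaded_volume, loaded_volume
    if g(hi) < 0:
        raise ValueError("no unloaded volume reproduces the loaded state")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if g(mid) > 0:
            hi = mid
        else:
            lo = mid
        if hi - lo < 1e-6 * hi:
            break
    return float(0.5 * (lo + hi))
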