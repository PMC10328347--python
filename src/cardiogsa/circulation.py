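"""Closed-loop 0D four-chamber circulation.

A lumped surrogate of the heart + circulatory loop: four contracting
chambers (thin-wall passive law + one-fibre active pressure), four
one-way valves and two always-open venous inlet orifices (Bernoulli),
four power-law elastic tubes (aorta, pulmonary artery, systemic and
pulmonary veins) and two linear peripheral resistances, with a
volume-excess pericardial pressure coupling the chambers.  The 20
pressure-volume features used for emulator training are extracted from
the final beat.

Constitutive laws (stated exactly so behaviour is deterministic):

* chamber:  p(V, t) = p_passive(V)
              + (1/3) T_drive(t) [1 + beta_0 (lambda - 1)]_+ ln(1 + V_wall/V)
              + p_peri
  with lambda = (V/V_unloaded)^(1/3): the Land length-dependence factor
  applied at the chamber level supplies Frank-Starling recruitment,
  without which a fixed-volume closed loop loses output monotonicity
  against afterload
* valve:    q = A_open sqrt(2 max(dp,0)/rho)       (no regurgitation)
* inlet:    q = A_open sign(dp) sqrt(2 |dp|/rho)   (bidirectional orifice)
* tube:     p = pX0 p_ref (V/V_ref)^(k/3)
* periphery q = dp / (R_scale dp_ref / q_ref)
* pericard. p_peri = k_peri max(0, sum V - 0.85 sum V_init) / A_peri
  (the sac is taut through diastole - diastolic ventricular interaction -
  and slack in systole; A_peri is the effective displacement area)

T_drive is the cellular isometric tension waveform smeared uniformly
over [onset, onset + TAT] activation offsets; the RV active and passive
terms are scaled by T_ref,LvRv and a_LvRv.  Units: mmHg, mL, s at the
circuit level; blood density 1.05 g/mL.  Runs that reach non-physical
states are flagged failed, not raised.

Many parameter points can be integrated simultaneously: see
:func:`build_circuit_batch`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .cell_and_passive import (
    KPA_TO_MMHG,
    GuccioneParams,
    TensionTransient,
    inflate_chamber,
    unload_chamber,
)

__all__ = [
    "CircParams",
    "ChamberSpec",
    "Circuit",
    "CircTrace",
    "build_circuit",
    "build_circuit_batch",
    "run_beats",
    "pv_features",
    "default_chambers",
    "patient_derived_constants",
    "PV_FEATURE_NAMES",
]

RHO_BLOOD = 1.05e3  # kg/m^3
MMHG_TO_PA = 133.322
_ORIFICE_EPS = 0.2  # mmHg, regularisation of the Bernoulli law near dp=0
_PERI_REF_FRAC = 0.85  # pericardial reserve volume / initial chamber sum

CHAMBERS = ("LA", "LV", "RA", "RV")
TUBES = ("Ao", "Pa", "Ve", "Pve")
#: surrogate tube reference pressures (mmHg), scaled by pAo0 ... pPve0
TUBE_P_REF = {"Ao": 92.0, "Pa": 13.25, "Ve": 2.0, "Pve": 2.0}
#: initial tube pressures (mmHg): fixes the total blood volume identically
#: across parameter points
TUBE_P_INIT = np.array([75.0, 13.25, 1.8, 2.5])

PV_FEATURE_NAMES = [
    "EDV_LV", "EDP_LV", "ESV_LV", "p_max_LV", "dpdt_max_LV", "dpdt_min_LV",
    "EDV_RV", "EDP_RV", "ESV_RV", "p_max_RV", "dpdt_max_RV", "dpdt_min_RV",
    "EDV_LA", "ESV_LA", "EDV_vwave_LA", "p_max_LA",
    "EDV_RA", "ESV_RA", "EDV_vwave_RA", "p_max_RA",
]


@dataclass
class CircParams:
    """Circulatory parameters; defaults are the patient-derived values."""

    # cavity wall volumes (mL); septum split equally between LV and RV
    V_LV_wall: float = 93.6 + 16.2
    V_RV_wall: float = 37.6 + 16.2
    V_LA_wall: float = 25.7
    V_RA_wall: float = 22.2
    # valve open orifice areas (mm^2)
    AMVopen: float = 508.3
    ATVopen: float = 508.3
    AAVopen: float = 336.7
    APVopen: float = 336.7
    ASOopen: float = 518.7
    APOopen: float = 296.1
    # tubes
    pAo0: float = 1.0
    pPa0: float = 1.0
    pVe0: float = 1.0
    pPve0: float = 1.0
    l_Ao: float = 400.0
    l_Pa: float = 200.06
    l_Ve: float = 400.11
    l_Pve: float = 200.06
    k_Ao: float = 8.0
    k_Pa: float = 8.0
    k_Ve: float = 10.0
    k_Pve: float = 10.0
    # systemic / pulmonary circulation
    q_ref: float = 82.0            # mL/s
    dp_sys_ref: float = 90.01      # mmHg
    dp_pulm_ref: float = 11.25     # mmHg
    R_sys: float = 1.0             # dimensionless scaling
    R_pulm: float = 1.0
    # boundary conditions / LV-RV scalings
    k_peri: float = 1.0            # kPa/mm
    EDP_shift_LV: float = 6.0      # mmHg
    EDP_unload_RV: float = 5.5     # mmHg
    T_ref_LvRv: float = 0.8
    a_LvRv: float = 1.5

    @property
    def R_sys_value(self) -> float:
        """Systemic peripheral resistance, mmHg s / mL."""
        return self.R_sys * self.dp_sys_ref / self.q_ref

    @property
    def R_pulm_value(self) -> float:
        return self.R_pulm * self.dp_pulm_ref / self.q_ref


@dataclass
class ChamberSpec:
    """Passive description of one chamber."""

    guccione: GuccioneParams
    unloaded_volume: float  # mL
    wall_volume: float      # mL
    beta_0: float = 2.3     # length-dependence of active tension


@dataclass
class Circuit:
    """Assembled closed-loop model; all per-row quantities carry a batch
    dimension B (B = 1 for a single parameter point)."""

    params: CircParams               # representative (first) parameter set
    chambers: list[dict[str, ChamberSpec]]
    drive: np.ndarray                # (4, B, n_grid) active tension, kPa
    drive_dt: float
    bcl: float
    v0_chambers: np.ndarray          # (B, 4) initial chamber volumes, mL
    v_ref_tubes: np.ndarray          # (B, 4) tube reference volumes, mL
    a_peri: np.ndarray               # (B,) mm^2
    batch: int
    ch_a: np.ndarray                 # (B, 4) chamber stiffness arrays
    ch_bf: np.ndarray
    ch_bt: np.ndarray
    ch_v0: np.ndarray                # (B, 4) unloaded volumes
    ch_wall: np.ndarray
    ch_geom: np.ndarray              # 2 h0 / r0
    ch_beta0: np.ndarray
    tube_pref: np.ndarray            # (B, 4)
    tube_k3: np.ndarray              # (B, 4)
    areas: np.ndarray                # (B, 6) orifice areas MV,AV,SO,TV,PV,PO
    r_sys: np.ndarray                # (B,)
    r_pulm: np.ndarray
    k_peri: np.ndarray

    _ONE_WAY = np.array([True, True, False, True, True, False])


@dataclass
class CircTrace:
    t: np.ndarray              # record grid, ms
    volumes: np.ndarray        # (B, nt, 4) chamber volumes, mL
    pressures: np.ndarray      # (B, nt, 4) chamber pressures, mmHg
    tube_volumes: np.ndarray   # (B, nt, 4)
    tube_pressures: np.ndarray
    av_open: np.ndarray        # (B, nt, 2) mitral, tricuspid open flags
    success: np.ndarray        # (B,)
    periodicity: np.ndarray    # (B,) relative last-two-beat volume residual
    circuit: Circuit


def _beat_waveform(driver: TensionTransient, bcl: float, grid: np.ndarray):
    """Last-beat tension waveform sampled on the cycle grid."""
    t, v = np.asarray(driver.t, float), np.atleast_2d(driver.value)
    t0 = t[-1] - bcl
    m = t >= t0 - 1e-9
    tb = t[m] - t[m][0]
    return np.vstack([np.interp(grid, tb, row[m], period=bcl) for row in v])


def _smeared_drive(wave: np.ndarray, grid: np.ndarray, bcl: float,
                   onset, tat, n_off: int = 21) -> np.ndarray:
    """Mean of the waveform shifted by offsets uniform on [onset, onset+TAT]."""
    onset = np.atleast_1d(np.asarray(onset, float))
    tat = np.atleast_1d(np.asarray(tat, float))
    B = max(wave.shape[0], len(onset), len(tat))
    n = len(grid)
    out = np.zeros((B, n))
    wv = np.broadcast_to(wave, (B, n))
    on = np.broadcast_to(onset, (B,))
    ta = np.broadcast_to(tat, (B,))
    for b in range(B):
        offs = on[b] + np.linspace(0.0, max(ta[b], 1e-9), n_off)
        acc = np.zeros(n)
        for o in offs:
            shift = (grid - o) % bcl
            acc += np.interp(shift, grid, wv[b], period=bcl)
        out[b] = acc / n_off
    return out


def default_chambers(params: CircParams) -> dict[str, ChamberSpec]:
    """Patient-scale chamber specs: unloaded volumes from end-diastolic
    volumes via thin-wall unloading at the (shifted) end-diastolic pressures."""
    from .cell_and_passive import ATRIAL_GUCCIONE, VENTRICULAR_GUCCIONE

    gv = VENTRICULAR_GUCCIONE
    gv_rv = replace(gv, a=gv.a * params.a_LvRv)
    ga = ATRIAL_GUCCIONE
    edp_lv = 2.8 + params.EDP_shift_LV
    return {
        "LA": ChamberSpec(ga, unload_chamber(ga, params.V_LA_wall, 70.0, 2.0),
                          params.V_LA_wall),
        "LV": ChamberSpec(gv, unload_chamber(gv, params.V_LV_wall, 150.0, edp_lv),
                          params.V_LV_wall),
        "RA": ChamberSpec(ga, unload_chamber(ga, params.V_RA_wall, 70.0, 2.0),
                          params.V_RA_wall),
        "RV": ChamberSpec(gv_rv,
                          unload_chamber(gv_rv, params.V_RV_wall, 150.0,
                                         params.EDP_unload_RV),
                          params.V_RV_wall),
    }


def build_circuit_batch(
    params_list: list[CircParams],
    chambers_list: list[dict[str, ChamberSpec] | None],
    drivers_list: list[dict[str, TensionTransient]],
    activation_list: list[dict[str, tuple]],
    drive_dt: float = 1.0,
) -> Circuit:
    """Assemble one vectorised circuit for B parameter points.

    Each list entry describes one closed loop (same basic cycle length
    across the batch); the integrator then advances all of them
    simultaneously, which is far cheaper than B separate runs.
    """
    B = len(params_list)
    if not (len(chambers_list) == len(drivers_list) == len(activation_list) == B):
        raise ValueError("batch lists must have equal length")
    bcls = {np.round(d.bcl, 6) for drv in drivers_list for d in drv.values()}
    if len(bcls) != 1:
        raise ValueError(f"inconsistent BCLs among tension drivers: {bcls}")
    bcl = float(bcls.pop())
    for act in activation_list:
        on_a = max(act["LA"][0], act["RA"][0])
        on_v = min(act["LV"][0], act["RV"][0])
        if on_v < on_a:
            raise ValueError("ventricular activation precedes atrial activation")
    chambers_list = [
        ch if ch is not None else default_chambers(p)
        for p, ch in zip(params_list, chambers_list)
    ]
    grid = np.arange(0.0, bcl, drive_dt)
    n = len(grid)

    drive = np.zeros((4, B, n))
    for j, ch in enumerate(CHAMBERS):
        for b in range(B):
            wave = _beat_waveform(drivers_list[b][ch], bcl, grid)
            onset, tat = activation_list[b][ch]
            d = _smeared_drive(wave, grid, bcl, onset, tat)
            if ch == "RV":
                d = d * params_list[b].T_ref_LvRv
            drive[j, b] = d[0]

    ch_a = np.zeros((B, 4))
    ch_bf = np.zeros((B, 4))
    ch_bt = np.zeros((B, 4))
    ch_v0 = np.zeros((B, 4))
    ch_wall = np.zeros((B, 4))
    ch_beta0 = np.zeros((B, 4))
    v0 = np.zeros((B, 4))
    init_p = {"LA": 2.0, "LV": 4.0, "RA": 2.0, "RV": 3.0}
    for b, specs in enumerate(chambers_list):
        for j, ch in enumerate(CHAMBERS):
            s = specs[ch]
            ch_a[b, j] = s.guccione.a
            ch_bf[b, j] = s.guccione.b_f
            ch_bt[b, j] = s.guccione.b_t
            ch_v0[b, j] = s.unloaded_volume
            ch_wall[b, j] = s.wall_volume
            ch_beta0[b, j] = s.beta_0
            v0[b, j] = inflate_chamber(
                s.guccione, s.wall_volume, s.unloaded_volume, init_p[ch]
            )[0]
    r0 = (3.0 * ch_v0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    h0 = ch_wall / (4.0 * np.pi * r0**2)
    ch_geom = 2.0 * h0 / r0

    v_ref_tubes = np.array([
        [p.AAVopen * p.l_Ao, p.APVopen * p.l_Pa,
         p.ASOopen * p.l_Ve, p.APOopen * p.l_Pve]
        for p in params_list
    ]) / 1000.0  # mm^3 -> mL
    tube_pref = np.array([
        [p.pAo0 * TUBE_P_REF["Ao"], p.pPa0 * TUBE_P_REF["Pa"],
         p.pVe0 * TUBE_P_REF["Ve"], p.pPve0 * TUBE_P_REF["Pve"]]
        for p in params_list
    ])
    tube_k3 = np.array([
        [p.k_Ao, p.k_Pa, p.k_Ve, p.k_Pve] for p in params_list
    ]) / 3.0
    areas = np.array([
        [p.AMVopen, p.AAVopen, p.ASOopen, p.ATVopen, p.APVopen, p.APOopen]
        for p in params_list
    ])
    r_sys = np.array([p.R_sys_value for p in params_list])
    r_pulm = np.array([p.R_pulm_value for p in params_list])
    k_peri = np.array([p.k_peri for p in params_list])

    wall_total = ch_wall.sum(axis=1)
    v_total_ref = v0.sum(axis=1) + wall_total
    # effective displacement area: the penalty concentrates over roughly a
    # third of the spherical envelope (apex/free walls move, base is held)
    a_peri = (36.0 * np.pi) ** (1.0 / 3.0) * (v_total_ref * 1e3) ** (2.0 / 3.0) / 3.0
    return Circuit(
        params_list[0], chambers_list, drive, drive_dt, bcl, v0, v_ref_tubes,
        a_peri, B, ch_a, ch_bf, ch_bt, ch_v0, ch_wall, ch_geom, ch_beta0,
        tube_pref, tube_k3, areas, r_sys, r_pulm, k_peri,
    )


def build_circuit(
    params: CircParams,
    chamber_passive: dict[str, ChamberSpec] | None,
    tension_drivers: dict[str, TensionTransient],
    activation: dict[str, tuple],
    drive_dt: float = 1.0,
) -> Circuit:
    """Assemble a single closed-loop model (batch of one).

    ``tension_drivers`` maps LA/LV/RA/RV to periodic tension transients
    (a common basic cycle length is required); ``activation`` maps each
    chamber to (onset ms, TAT ms) with the ventricular onset after the
    atrial one (the AV delay).  RV active tension is scaled by
    T_ref,LvRv inside the circuit.
    """
    return build_circuit_batch(
        [params], [chamber_passive], [tension_drivers], [activation], drive_dt
    )


def _rhs(y, drive_now, cir: Circuit, p_out=None):
    """Time derivative (mL/ms) of [V_LA, V_LV, V_RA, V_RV, V_Ao, V_Pa, V_Ve, V_Pve]."""
    Vc = np.maximum(y[:, :4], 1e-3)
    Vt = np.maximum(y[:, 4:], 1e-3)
    # chamber pressures: thin-wall equibiaxial response, vectorised over
    # the four chambers (shear-free: Q = b_f E^2 + b_t (E^2 + E_nn^2))
    lam = np.cbrt(Vc / cir.ch_v0)
    lam = np.clip(lam, 0.3, 3.0)
    E = 0.5 * (lam**2 - 1.0)
    E_nn = 0.5 * (lam**-4 - 1.0)
    Q = cir.ch_bf * E**2 + cir.ch_bt * (E**2 + E_nn**2)
    aeQ = cir.ch_a * np.exp(np.minimum(Q, 200.0))
    S_ff = aeQ * cir.ch_bf * E
    S_nn = aeQ * cir.ch_bt * E_nn
    sigma = lam**2 * S_ff - lam**-4 * S_nn
    p_pass = sigma * cir.ch_geom / lam**3 * KPA_TO_MMHG
    excess = (Vc.sum(axis=1) - _PERI_REF_FRAC * cir.v0_chambers.sum(axis=1)) * 1e3
    p_peri = cir.k_peri * np.maximum(excess, 0.0) / cir.a_peri * KPA_TO_MMHG
    starling = np.maximum(1.0 + cir.ch_beta0 * (lam - 1.0), 0.0)
    p_act = (drive_now.T / 3.0) * starling * np.log1p(cir.ch_wall / Vc) \
        * KPA_TO_MMHG
    pc = p_pass + p_act + p_peri[:, None]
    pt = cir.tube_pref * (Vt / cir.v_ref_tubes) ** cir.tube_k3

    pLA, pLV, pRA, pRV = pc.T
    pAo, pPa, pVe, pPve = pt.T
    # orifices, stacked: MV, AV, systemic inlet, TV, PV, pulmonary inlet
    dps = np.stack([pLA - pLV, pLV - pAo, pVe - pRA,
                    pRA - pRV, pRV - pPa, pPve - pLA], axis=-1)
    dps = np.where(Circuit._ONE_WAY, np.maximum(dps, 0.0), dps)
    qs = cir.areas * dps * np.sqrt(
        2.0 * MMHG_TO_PA / (RHO_BLOOD * (np.abs(dps) + _ORIFICE_EPS)))
    q_mv, q_av, q_so, q_tv, q_pv, q_po = qs.T
    q_sys = (pAo - pVe) / cir.r_sys
    q_pulm = (pPa - pPve) / cir.r_pulm
    # flows are mL/s; the integrator steps in ms
    dy = 1e-3 * np.column_stack([
        q_po - q_mv,     # LA
        q_mv - q_av,     # LV
        q_so - q_tv,     # RA
        q_tv - q_pv,     # RV
        q_av - q_sys,    # Ao
        q_pv - q_pulm,   # Pa
        q_sys - q_so,    # Ve
        q_pulm - q_po,   # Pve
    ])
    if p_out is not None:
        p_out["pc"] = pc
        p_out["pt"] = pt
        p_out["q_mv"] = q_mv
        p_out["q_tv"] = q_tv
    return dy


def _drive_at(cir: Circuit, t: float) -> np.ndarray:
    g = (t % cir.bcl) / cir.drive_dt
    n = cir.drive.shape[2]
    i0 = int(g) % n
    i1 = (i0 + 1) % n
    f = g - int(g)
    return cir.drive[:, :, i0] * (1 - f) + cir.drive[:, :, i1] * f


def run_beats(
    circuit: Circuit,
    n_beats: int = 8,
    dt: float = 1.0,
    substep: float = 1.0,
) -> CircTrace:
    """Integrate the loop for n_beats (explicit RK4, fixed substep).

    Traces are recorded every ``dt`` ms.  A batch member that reaches a
    negative volume or a non-finite state is flagged failed and frozen;
    no exception is raised (failures are data).
    """
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    cir = circuit
    B = cir.batch
    vt0 = cir.v_ref_tubes * (TUBE_P_INIT / cir.tube_pref) ** (1.0 / cir.tube_k3)
    y = np.hstack([cir.v0_chambers, vt0])
    n_rec = int(round(n_beats * cir.bcl / dt)) + 1
    sub = max(1, int(round(dt / substep)))
    h = dt / sub
    alive = np.ones(B, dtype=bool)

    t_arr = np.arange(n_rec) * dt
    vols = np.empty((B, n_rec, 4))
    prs = np.empty((B, n_rec, 4))
    tvols = np.empty((B, n_rec, 4))
    tprs = np.empty((B, n_rec, 4))
    av_open = np.zeros((B, n_rec, 2), dtype=bool)

    probe: dict = {}
    with np.errstate(over="ignore", invalid="ignore"):
        for i in range(n_rec):
            t = t_arr[i]
            _rhs(y, _drive_at(cir, t), cir, p_out=probe)
            vols[:, i] = y[:, :4]
            tvols[:, i] = y[:, 4:]
            prs[:, i] = probe["pc"]
            tprs[:, i] = probe["pt"]
            av_open[:, i, 0] = probe["q_mv"] > 1e-9
            av_open[:, i, 1] = probe["q_tv"] > 1e-9
            if i == n_rec - 1:
                break
            for s in range(sub):
                ts = t + s * h
                k1 = _rhs(y, _drive_at(cir, ts), cir)
                k2 = _rhs(y + 0.5 * h * k1, _drive_at(cir, ts + 0.5 * h), cir)
                k3 = _rhs(y + 0.5 * h * k2, _drive_at(cir, ts + 0.5 * h), cir)
                k4 = _rhs(y + h * k3, _drive_at(cir, ts + h), cir)
                y_new = y + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
                bad = (
                    (~np.isfinite(y_new).all(axis=1))
                    | (np.min(y_new, axis=1) <= 0.0)
                    | (y_new[:, :4] > 15.0 * cir.ch_v0).any(axis=1)
                )
                alive &= ~bad
                y = np.where(alive[:, None], y_new, y)

    per_beat = int(round(cir.bcl / dt))
    last = vols[:, -per_beat - 1:, :]
    prev = vols[:, -2 * per_beat - 1: -per_beat, :]
    nmin = min(last.shape[1], prev.shape[1])
    resid = np.abs(last[:, :nmin] - prev[:, :nmin]).max(axis=(1, 2))
    periodicity = resid / np.maximum(vols.max(axis=(1, 2)), 1e-9)
    return CircTrace(t_arr, vols, prs, tvols, tprs, av_open, alive,
                     periodicity, cir)


def pv_features(trace: CircTrace, activation) -> dict:
    """The 20 pressure-volume features from the final beat.

    Ventricular EDV/EDP are read at ventricular activation onset; ESV is
    the beat minimum; dp/dt extrema use centred differences (mmHg/s).
    Atrial EDV is the volume just before atrial activation onset, ESV
    the minimum during atrial contraction, the v-wave EDV the maximum
    while the AV valve is closed, and atrial p_max the contraction-window
    maximum.  ``activation`` is a single {chamber: (onset, TAT)} dict or
    a per-batch-row list of them.  Returns {name: (B,) array}; failed
    runs carry NaN.
    """
    cir = trace.circuit
    dt = trace.t[1] - trace.t[0]
    per_beat = int(round(cir.bcl / dt))
    if trace.volumes.shape[1] < per_beat + 1:
        raise ValueError("trace does not contain a complete final beat")
    B = trace.volumes.shape[0]
    acts = activation if isinstance(activation, list) else [activation] * B
    sl = slice(trace.volumes.shape[1] - per_beat - 1, trace.volumes.shape[1])
    V = trace.volumes[:, sl]
    P = trace.pressures[:, sl]
    AV = trace.av_open[:, sl]
    nt = V.shape[1]
    rows = np.arange(B)

    feats: dict[str, np.ndarray] = {}
    for ch in ("LV", "RV"):
        j = CHAMBERS.index(ch)
        i_on = np.array([
            int(round((acts[b][ch][0] % cir.bcl) / dt)) % nt for b in range(B)
        ])
        dpdt = np.gradient(P[:, :, j], dt, axis=1) * 1e3  # mmHg/s
        feats[f"EDV_{ch}"] = V[rows, i_on, j]
        feats[f"EDP_{ch}"] = P[rows, i_on, j]
        feats[f"ESV_{ch}"] = V[:, :, j].min(axis=1)
        feats[f"p_max_{ch}"] = P[:, :, j].max(axis=1)
        feats[f"dpdt_max_{ch}"] = dpdt.max(axis=1)
        feats[f"dpdt_min_{ch}"] = dpdt.min(axis=1)
    grid = np.arange(cir.drive.shape[2]) * cir.drive_dt
    tau = np.arange(nt) * dt
    for ch, av_col in (("LA", 0), ("RA", 1)):
        j = CHAMBERS.index(ch)
        d = cir.drive[j]
        esv = np.empty(B)
        pmax = np.empty(B)
        vwave = np.empty(B)
        i_pre = np.empty(B, dtype=int)
        for b in range(B):
            onset_a = acts[b][ch][0] % cir.bcl
            i_pre[b] = (int(round(onset_a / dt)) - 1) % nt
            # contraction window: while the atrial drive exceeds 5% of peak
            thr = 0.05 * d[b].max()
            win = np.interp(tau, grid, (d[b] > thr).astype(float),
                            period=cir.bcl) > 0.5
            if not win.any():
                win = np.zeros(nt, bool)
                win[: max(1, nt // 3)] = True
            esv[b] = V[b, win, j].min()
            pmax[b] = P[b, win, j].max()
            closed = ~AV[b, :, av_col]
            vwave[b] = V[b, closed, j].max() if closed.any() else np.nan
        feats[f"EDV_{ch}"] = V[rows, i_pre, j]
        feats[f"ESV_{ch}"] = esv
        feats[f"EDV_vwave_{ch}"] = vwave
        feats[f"p_max_{ch}"] = pmax
    bad = ~trace.success
    for k in feats:
        feats[k] = np.where(bad, np.nan, feats[k])
    return feats


def patient_derived_constants(
    stroke_volume_mL: float = 70.0,
    bcl_ms: float = 854.0,
    aortic_valve_area_mm2: float = 336.7,
    pulmonary_valve_area_mm2: float = 336.7,
    arterial_wall_thickness_mm: float = 2.0,
) -> dict[str, float]:
    """Worked-example constants derived from the clinical measurements.

    * reference systemic flow  q_ref = SV / BCL
    * heart rate               HR = 60 / BCL
    * arterial tube wall areas from the adjacent valve orifice assuming a
      circular cross-section and the stated wall thickness.
    """
    bcl_s = bcl_ms / 1000.0

    def wall_area(orifice_mm2: float, thickness: float) -> float:
        r = np.sqrt(orifice_mm2 / np.pi)
        return float(np.pi * ((r + thickness) ** 2 - r**2))

    return {
        "q_ref_mL_per_s": stroke_volume_mL / bcl_s,
        "heart_rate_bpm": 60.0 / bcl_s,
        "aortic_wall_area_mm2": wall_area(
            aortic_valve_area_mm2, arterial_wall_thickness_mm
        ),
        "pulmonary_artery_wall_area_mm2": wall_area(
            pulmonary_valve_area_mm2, arterial_wall_thickness_mm
        ),
    }
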