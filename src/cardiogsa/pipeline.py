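"""Hierarchical sub-model -> whole-organ analysis pipeline.

The coupled four-chamber electromechanics surrogate has ~110 named
parameters (tissue conduction, ventricular and atrial cell models,
passive stiffness, circulation, boundary conditions).  The pipeline
mirrors the hierarchical reduction workflow: per sub-model Gaussian
process emulation, Sobol ranking with 90% retention, history matching
of the cell and tissue models against self-consistent targets, then a
global analysis of the fully coupled chain (activation -> tension ->
circulation) on a space-filling design drawn from the intersection of
the plausible regions, with plausibility-screened Sobol total effects
and a signed-effect heatmap.

Two presets are provided: ``paper`` (the full transcribed parameter
table; sampling sizes at literature scale) and ``desk`` (12 free
parameters, reduced design sizes) suitable for a single CPU.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cell_and_passive import (
    CalciumParams,
    GuccioneParams,
    LandParams,
    CalciumTransient,
    TensionTransient,
    inflate_chamber,
    simulate_calcium,
    simulate_tension,
    transient_features,
)
from .circulation import (
    CHAMBERS,
    CircParams,
    PV_FEATURE_NAMES,
    build_circuit,
    default_chambers,
    pv_features,
    run_beats,
)
from .eikonal_activation import (
    ATRIAL_GROUP,
    VENTRICULAR_GROUP,
    build_velocity_field,
    solve_eikonal,
    total_activation_time,
    two_slab_grid,
)
from .emulator import CVReport, EmulatorModel, cross_validate, fit_gpe
from .history_matching import (
    Target,
    WaveState,
    final_threshold_check,
    intersect_regions,
    run_wave,
)
from .parameter_space import (
    DesignMatrix,
    ParameterSpace,
    SimulationBatch,
    latin_hypercube,
    saltelli_design,
    space_from_table,
    subsample_space_filling,
)
from .sensitivity import (
    ConstraintSet,
    RankingResult,
    SobolResult,
    rank_and_retain,
    screen_samples,
    signed_effects,
    total_effects,
)

log = logging.getLogger("cardiogsa")

STAGES = ("tissue-ep", "ventricular-cell", "atrial-cell", "passive", "circulation")

# ---------------------------------------------------------------------------
# parameter table (name, role, bounds-or-value, unit, submodel, default)
# ---------------------------------------------------------------------------

_T = [
    # --- tissue electrophysiology -----------------------------------------
    ("CV_f_v", "hm-constrained", (0.3, 1.2), "mm/ms", "tissue-ep", 0.6),
    ("k_ft_v", "fixed", 0.4, "-", "tissue-ep", None),
    ("k_FEC", "hm-constrained", (1.0, 6.0), "-", "tissue-ep", 3.0),
    ("CV_f_a", "hm-constrained", (0.3, 1.5), "mm/ms", "tissue-ep", 0.7),
    ("k_ft_a", "fixed", 0.4, "-", "tissue-ep", None),
    ("k_BB", "hm-constrained", (1.0, 6.0), "-", "tissue-ep", 3.0),
    ("AV_delay", "free", (100.0, 200.0), "ms", "tissue-ep", 150.0),
    ("BCL", "data-derived", 854.0, "ms", "tissue-ep", None),
    # --- ventricular cell: ionic conductances (multipliers for HM rows) ---
    ("G_Na", "fixed", 11.7802, "-", "ventricular-cell", None),
    ("G_NaL", "fixed", 0.0279, "-", "ventricular-cell", None),
    ("G_to", "fixed", 0.16, "-", "ventricular-cell", None),
    ("P_Ca", "hm-constrained", (0.5, 2.0), "multiplier", "ventricular-cell", 1.0),
    ("G_Kr", "fixed", 0.0321, "-", "ventricular-cell", None),
    ("G_Ks", "fixed", 0.0011, "-", "ventricular-cell", None),
    ("G_K1", "fixed", 0.6992, "-", "ventricular-cell", None),
    ("G_NCX", "hm-constrained", (0.5, 2.0), "multiplier", "ventricular-cell", 1.0),
    ("G_NaK", "fixed", 15.4509, "-", "ventricular-cell", None),
    ("G_Ca", "fixed", 5e-4, "-", "ventricular-cell", None),
    ("G_Kb", "fixed", 0.0189, "-", "ventricular-cell", None),
    ("P_Nab", "fixed", 1.9239e-9, "-", "ventricular-cell", None),
    ("P_Cab", "fixed", 5.9194e-8, "-", "ventricular-cell", None),
    ("G_ClCa", "fixed", 0.2843, "-", "ventricular-cell", None),
    ("G_Clb", "fixed", 1.98e-3, "-", "ventricular-cell", None),
    ("Jrel_bar", "fixed", 1.5378, "-", "ventricular-cell", None),
    ("Jup_bar", "fixed", 1.0, "-", "ventricular-cell", None),
    ("INaCa_SS_frac", "fixed", 0.35, "-", "ventricular-cell", None),
    ("ICaL_SS_frac", "fixed", 0.8, "-", "ventricular-cell", None),
    ("alpha_CaMK", "fixed", 0.05, "-", "ventricular-cell", None),
    ("beta_CaMK", "fixed", 0.00068, "-", "ventricular-cell", None),
    ("CaMK_o", "fixed", 0.05, "-", "ventricular-cell", None),
    ("CMDN_bar", "fixed", 0.05, "mM", "ventricular-cell", None),
    ("TRPN_bar", "hm-constrained", (0.5, 2.0), "multiplier", "ventricular-cell", 1.0),
    ("BSR_bar", "fixed", 0.047, "mM", "ventricular-cell", None),
    ("BSL_bar", "fixed", 1.124, "mM", "ventricular-cell", None),
    ("CSQN_bar", "fixed", 10.0, "mM", "ventricular-cell", None),
    ("tau_diff_Ca", "fixed", 0.2, "ms", "ventricular-cell", None),
    ("tau_tr_v", "fixed", 60.0, "ms", "ventricular-cell", None),
    # --- ventricular cell: active tension ---------------------------------
    ("T_ref_v", "hm-constrained", (60.0, 180.0), "kPa", "ventricular-cell", 120.0),
    ("n_Tm_v", "hm-constrained", (2.0, 7.0), "-", "ventricular-cell", 5.0),
    ("n_TRPN_v", "hm-constrained", (1.5, 2.5), "-", "ventricular-cell", 2.0),
    ("k_TRPN_v", "fixed", 0.1, "1/ms", "ventricular-cell", None),
    ("A_eff_v", "hm-constrained", (10.0, 40.0), "-", "ventricular-cell", 25.0),
    ("k_u_v", "hm-constrained", (0.01, 0.1), "1/ms", "ventricular-cell", 0.03),
    ("beta_0_v", "fixed", 2.3, "-", "ventricular-cell", None),
    ("beta_1_v", "fixed", -2.4, "-", "ventricular-cell", None),
    ("gamma_s_v", "fixed", 0.0085, "-", "ventricular-cell", None),
    ("gamma_w_v", "fixed", 0.615, "-", "ventricular-cell", None),
    ("phi_v", "fixed", 2.23, "-", "ventricular-cell", None),
    ("ca_50_v", "hm-constrained", (0.3, 1.0), "uM", "ventricular-cell", 0.55),
    ("nu_v", "fixed", 7.0, "-", "ventricular-cell", None),
    ("mu_v", "hm-constrained", (1.0, 6.0), "-", "ventricular-cell", 3.0),
    ("TRPN_50_v", "hm-constrained", (0.2, 0.5), "-", "ventricular-cell", 0.35),
    ("r_s_v", "hm-constrained", (0.1, 0.5), "-", "ventricular-cell", 0.25),
    ("r_w_v", "hm-constrained", (0.2, 0.9), "-", "ventricular-cell", 0.5),
    # --- atrial cell -------------------------------------------------------
    ("g_Na_a", "fixed", 7.8, "-", "atrial-cell", None),
    ("g_to_a", "fixed", 0.1652, "-", "atrial-cell", None),
    ("g_CaL", "hm-constrained", (0.5, 2.0), "multiplier", "atrial-cell", 1.0),
    ("g_Kr_a", "fixed", 0.0294, "-", "atrial-cell", None),
    ("g_Ks_a", "fixed", 0.129, "-", "atrial-cell", None),
    ("g_K1_a", "fixed", 0.09, "-", "atrial-cell", None),
    ("g_bNa_a", "fixed", 0.000674, "-", "atrial-cell", None),
    ("g_bCa_a", "fixed", 0.00113, "-", "atrial-cell", None),
    ("g_Kur", "hm-constrained", (0.5, 2.0), "multiplier", "atrial-cell", 1.0),
    ("I_NaCa_max_a", "fixed", 16.0, "-", "atrial-cell", None),
    ("I_NaK_max_a", "fixed", 0.60, "-", "atrial-cell", None),
    ("I_pCa_max_a", "fixed", 0.275, "-", "atrial-cell", None),
    ("I_up_max", "hm-constrained", (0.5, 2.0), "multiplier", "atrial-cell", 1.0),
    ("k_rel_a", "fixed", 30.0, "-", "atrial-cell", None),
    ("Cmdn_max_a", "fixed", 0.05, "mM", "atrial-cell", None),
    ("Trpn_max_a", "hm-constrained", (0.5, 2.0), "multiplier", "atrial-cell", 1.0),
    ("Csqn_max_a", "fixed", 10.0, "mM", "atrial-cell", None),
    ("tau_tr_a", "fixed", 180.0, "ms", "atrial-cell", None),
    ("T_ref_a", "hm-constrained", (30.0, 120.0), "kPa", "atrial-cell", 60.0),
    ("n_Tm_a", "hm-constrained", (2.0, 7.0), "-", "atrial-cell", 5.0),
    ("n_TRPN_a", "hm-constrained", (1.5, 2.5), "-", "atrial-cell", 2.0),
    ("k_TRPN_a", "fixed", 0.1, "1/ms", "atrial-cell", None),
    ("A_eff_a", "hm-constrained", (10.0, 40.0), "-", "atrial-cell", 25.0),
    ("k_u_a", "fixed", 1.0, "1/ms", "atrial-cell", None),
    ("beta_0_a", "fixed", 2.3, "-", "atrial-cell", None),
    ("beta_1_a", "fixed", -2.4, "-", "atrial-cell", None),
    ("gamma_s_a", "fixed", 0.0085, "-", "atrial-cell", None),
    ("gamma_w_a", "fixed", 0.615, "-", "atrial-cell", None),
    ("phi_a", "hm-constrained", (1.0, 4.0), "-", "atrial-cell", 2.23),
    ("ca_50_a", "hm-constrained", (0.25, 0.9), "uM", "atrial-cell", 0.45),
    ("nu_a", "fixed", 7.0, "-", "atrial-cell", None),
    ("mu_a", "hm-constrained", (1.0, 6.0), "-", "atrial-cell", 4.0),
    ("TRPN_50_a", "hm-constrained", (0.2, 0.5), "-", "atrial-cell", 0.35),
    ("r_s_a", "hm-constrained", (0.1, 0.5), "-", "atrial-cell", 0.25),
    ("r_w_a", "hm-constrained", (0.2, 0.9), "-", "atrial-cell", 0.5),
    # --- passive mechanics --------------------------------------------------
    ("a_v", "free", (0.5, 1.5), "kPa", "passive", 1.0),
    ("b_f_v", "fixed", 8.0, "-", "passive", None),
    ("b_ft_v", "fixed", 4.0, "-", "passive", None),
    ("b_t_v", "free", (1.5, 4.5), "-", "passive", 3.0),
    ("a_a", "free", (1.5, 2.5), "kPa", "passive", 2.0),
    ("b_f_a", "free", (4.0, 12.0), "-", "passive", 8.0),
    ("b_ft_a", "fixed", 4.0, "-", "passive", None),
    ("b_t_a", "free", (1.5, 4.5), "-", "passive", 3.0),
    ("T_ref_LvRv", "free", (0.5, 1.0), "-", "passive", 0.8),
    ("a_LvRv", "free", (1.0, 2.0), "-", "passive", 1.5),
    # --- circulation --------------------------------------------------------
    ("V_LV_wall", "data-derived", 93.6, "mL", "circulation", None),
    ("V_RV_wall", "data-derived", 37.6, "mL", "circulation", None),
    ("V_SV_wall", "data-derived", 32.4, "mL", "circulation", None),
    ("V_LA_wall", "data-derived", 25.7, "mL", "circulation", None),
    ("V_RA_wall", "data-derived", 22.2, "mL", "circulation", None),
    ("AMVopen", "data-derived", 508.3, "mm^2", "circulation", None),
    ("ATVopen", "data-derived", 508.3, "mm^2", "circulation", None),
    ("AAVopen", "data-derived", 336.7, "mm^2", "circulation", None),
    ("APVopen", "data-derived", 336.7, "mm^2", "circulation", None),
    ("ASOopen", "data-derived", 518.7, "mm^2", "circulation", None),
    ("APOopen", "data-derived", 296.1, "mm^2", "circulation", None),
    ("pAo0", "fixed", 1.0, "-", "circulation", None),
    ("pPa0", "fixed", 1.0, "-", "circulation", None),
    ("pVe0", "fixed", 1.0, "-", "circulation", None),
    ("pPve0", "fixed", 1.0, "-", "circulation", None),
    ("l_Ao", "free", (300.0, 500.0), "mm", "circulation", 400.0),
    ("l_Pa", "fixed", 200.06, "mm", "circulation", None),
    ("l_Ve", "fixed", 400.11, "mm", "circulation", None),
    ("l_Pve", "fixed", 200.06, "mm", "circulation", None),
    ("k_Ao", "free", (6.0, 10.0), "-", "circulation", 8.0),
    ("k_Pa", "fixed", 8.0, "-", "circulation", None),
    ("k_Ve", "fixed", 10.0, "-", "circulation", None),
    ("k_Pve", "fixed", 10.0, "-", "circulation", None),
    ("AAowall", "data-derived", 142.7, "mm^2", "circulation", None),
    ("APawall", "data-derived", 142.7, "mm^2", "circulation", None),
    ("AVewall", "data-derived", 83.7, "mm^2", "circulation", None),
    ("APvewall", "data-derived", 64.7, "mm^2", "circulation", None),
    ("q_ref", "data-derived", 82.0, "mL/s", "circulation", None),
    ("dp_sys_ref", "data-derived", 90.01, "mmHg", "circulation", None),
    ("dp_pulm_ref", "data-derived", 11.25, "mmHg", "circulation", None),
    ("R_sys", "free", (1.0, 4.0), "-", "circulation", 1.5),
    ("R_pulm", "free", (1.0, 4.0), "-", "circulation", 1.5),
    # --- boundary conditions -----------------------------------------------
    ("k_peri", "free", (0.5, 2.0), "kPa/mm", "boundary", 1.0),
    ("EDP_shift_LV", "free", (3.0, 9.0), "mmHg", "boundary", 6.0),
    ("EDP_unload_RV", "free", (3.0, 8.0), "mmHg", "boundary", 5.5),
]

#: reduced free-parameter set for the single-CPU preset
DESK_FREE = (
    "CV_f_v", "k_FEC", "AV_delay",
    "P_Ca", "T_ref_v", "ca_50_v",
    "g_CaL", "T_ref_a",
    "a_v",
    "R_sys", "R_pulm", "k_peri",
)


def paper_parameter_table() -> list[dict]:
    """The full transcribed parameter table as config-style rows."""
    rows = []
    for name, role, bv, unit, sub, default in _T:
        row = {"name": name, "role": role, "unit": unit, "submodel": sub}
        if role in ("free", "hm-constrained"):
            row["bounds"] = list(bv)
            row["default"] = default if default is not None else 0.5 * sum(bv)
        else:
            row["value"] = bv
        rows.append(row)
    return rows


def desk_parameter_table() -> list[dict]:
    """Reduced table: only :data:`DESK_FREE` stay sampled, the rest fixed."""
    rows = []
    for row in paper_parameter_table():
        r = dict(row)
        if "bounds" in r and r["name"] not in DESK_FREE:
            r["role"] = "fixed"
            r["value"] = r.pop("default")
            r.pop("bounds")
        rows.append(r)
    return rows


def table_defaults(rows: list[dict]) -> dict[str, float]:
    """Every parameter at its default (fixed value or stated default)."""
    out = {}
    for r in rows:
        out[r["name"]] = float(r["value"] if "value" in r else r["default"])
    return out


def _strip(rows: list[dict]) -> list[dict]:
    return [{k: v for k, v in r.items() if k != "default"} for r in rows]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class StageConfig:
    n_train: int
    hm_waves: int = 0
    n_test: int = 2000
    n_simul: int = 20
    I_th: tuple[float, ...] = (3.0,)


@dataclass
class PipelineConfig:
    table: list[dict]
    stages: dict[str, StageConfig]
    seed: int = 0
    retention_threshold: float = 0.90
    gsa_n_base: int = 256
    gsa_n_draws: int = 50
    n_base_screen: int = 2000
    n_final_design: int = 120
    final_n_beats: int = 8
    cell_dt: float = 0.05
    circ_substep: float = 1.0
    cv_folds: int = 3
    fit_restarts: int = 3
    sigma_frac: float = 0.05
    outdir: str = "cardiogsa_out"

    def hash(self) -> str:
        blob = json.dumps(
            {**{k: v for k, v in asdict(self).items() if k != "outdir"}},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        data["stages"] = {
            k: StageConfig(**{**v, "I_th": tuple(v.get("I_th", (3.0,)))})
            for k, v in data["stages"].items()
        }
        return cls(**data)


def desk_config(outdir: str = "cardiogsa_out", seed: int = 0) -> PipelineConfig:
    """Single-CPU preset: 12 free parameters, reduced design sizes."""
    return PipelineConfig(
        table=desk_parameter_table(),
        stages={
            "tissue-ep": StageConfig(40, hm_waves=2, n_test=50000, n_simul=16),
            "ventricular-cell": StageConfig(48, hm_waves=2, n_test=50000,
                                            n_simul=16),
            "atrial-cell": StageConfig(48, hm_waves=2, n_test=50000, n_simul=16),
            "passive": StageConfig(40),
            "circulation": StageConfig(48),
        },
        seed=seed,
        outdir=outdir,
    )


def paper_config(outdir: str = "cardiogsa_out", seed: int = 0) -> PipelineConfig:
    """Literature-scale preset (documented sizes; cluster-scale runtimes)."""
    return PipelineConfig(
        table=paper_parameter_table(),
        stages={
            "tissue-ep": StageConfig(200, hm_waves=3, n_test=100000, n_simul=100),
            "ventricular-cell": StageConfig(300, hm_waves=3, n_test=100000,
                                            n_simul=100),
            "atrial-cell": StageConfig(300, hm_waves=3, n_test=100000, n_simul=100),
            "passive": StageConfig(150),
            "circulation": StageConfig(200),
        },
        seed=seed,
        gsa_n_base=2048,
        gsa_n_draws=1000,
        n_final_design=500,
        cell_dt=0.02,
        circ_substep=0.5,
        cv_folds=5,
        fit_restarts=5,
        outdir=outdir,
    )


# ---------------------------------------------------------------------------
# forward models
# ---------------------------------------------------------------------------

_GRID_CACHE: dict = {}


def _fixture_grid():
    if "grid" not in _GRID_CACHE:
        _GRID_CACHE["grid"] = two_slab_grid(nx=41, ny_vent=10, ny_atria=8, h=1.0)
    return _GRID_CACHE["grid"]


def _eikonal_tats(p: dict) -> tuple[float, float]:
    grid, sites = _fixture_grid()
    field = build_velocity_field(
        grid,
        {"atrial": p["CV_f_a"], "ventricular": p["CV_f_v"]},
        {"atrial": p["k_ft_a"], "ventricular": p["k_ft_v"]},
        {"FEC": p["k_FEC"], "BB": p["k_BB"]},
    )
    amap = solve_eikonal(
        grid, field,
        [(sites["atrial"], 0.0), (sites["ventricular"], p["AV_delay"])],
    )
    tat_v = total_activation_time(amap, VENTRICULAR_GROUP)
    tat_a = total_activation_time(amap, ATRIAL_GROUP)
    return tat_v, tat_a


TISSUE_OUTPUTS = ["TAT_v", "TAT_a", "act_span"]


def simulate_tissue_ep(space: ParameterSpace, X: np.ndarray):
    Y = np.empty((len(X), 3))
    for i, x in enumerate(np.atleast_2d(X)):
        p = space.row_dict(x)
        tat_v, tat_a = _eikonal_tats(p)
        Y[i] = (tat_v, tat_a, p["AV_delay"] + tat_v)
    return Y, np.ones(len(Y), bool)


CELL_OUTPUTS = ["ca_peak", "ca_dur90", "T_peak", "T_rest", "T_dur90", "T_ttp"]


def _cell_setup(p: dict, chamber: str):
    """Map table parameters onto the surrogate cell parameters."""
    if chamber == "v":
        ca = CalciumParams(
            Ca_dias=0.10, Ca_amp=0.60, tau_rise=15.0, tau_decay=180.0,
            amp_scale=p["P_Ca"], decay_scale=1.0 / p["G_NCX"],
            buffer_scale=p["TRPN_bar"],
        )
        land = LandParams(
            T_ref=p["T_ref_v"], ca_50=p["ca_50_v"], n_TRPN=p["n_TRPN_v"],
            k_TRPN=p["k_TRPN_v"], TRPN_50=p["TRPN_50_v"], n_Tm=p["n_Tm_v"],
            k_u=p["k_u_v"], nu=p["nu_v"], mu=p["mu_v"], r_s=p["r_s_v"],
            r_w=min(p["r_w_v"], 0.999 / p["r_s_v"] - 1.0 - 1e-6),
            A_eff=p["A_eff_v"], phi=p["phi_v"],
        )
    else:
        ca = CalciumParams(
            Ca_dias=0.12, Ca_amp=0.45, tau_rise=10.0, tau_decay=130.0,
            amp_scale=p["g_CaL"], decay_scale=1.0 / p["I_up_max"],
            buffer_scale=p["Trpn_max_a"],
        )
        land = LandParams(
            T_ref=p["T_ref_a"], ca_50=p["ca_50_a"], n_TRPN=p["n_TRPN_a"],
            k_TRPN=p["k_TRPN_a"], TRPN_50=p["TRPN_50_a"], n_Tm=p["n_Tm_a"],
            k_u=p["k_u_a"], nu=p["nu_a"], mu=p["mu_a"], r_s=p["r_s_a"],
            r_w=min(p["r_w_a"], 0.999 / p["r_s_a"] - 1.0 - 1e-6),
            A_eff=p["A_eff_a"], phi=p["phi_a"],
        )
    return ca, land


def _tension_batch(param_dicts, chamber: str, cfg: PipelineConfig,
                   n_beats: int = 4):
    """Batched tension transients for many parameter points (common grid)."""
    bcl = float(param_dicts[0].get("BCL", 854.0))
    setups = [_cell_setup(p, chamber) for p in param_dicts]
    cas = [simulate_calcium(cp_, bcl, n_beats=n_beats) for cp_, _ in setups]
    stacked = CalciumTransient(
        cas[0].t, np.vstack([c.value for c in cas]), bcl
    )
    T = simulate_tension(
        stacked, [land for _, land in setups], dt=cfg.cell_dt,
        buffer_scale=np.array([cp_.buffer_scale for cp_, _ in setups]),
    )
    transients = [
        TensionTransient(T.t, T.value[i], bcl) for i in range(len(param_dicts))
    ]
    return cas, transients


def simulate_cell(space: ParameterSpace, X: np.ndarray, chamber: str,
                  cfg: PipelineConfig):
    X = np.atleast_2d(X)
    rows = [space.row_dict(x) for x in X]
    Y = np.full((len(X), len(CELL_OUTPUTS)), np.nan)
    ok = np.zeros(len(X), bool)
    cas, tens = _tension_batch(rows, chamber, cfg)
    for i in range(len(X)):
        try:
            fc = transient_features(cas[i])
            ft = transient_features(tens[i])
            Y[i] = (fc.peak, fc.duration90, ft.peak, ft.rest, ft.duration90,
                    ft.time_to_peak)
            ok[i] = np.isfinite(Y[i]).all()
        except (ValueError, RuntimeError):
            ok[i] = False
    return Y, ok


PASSIVE_OUTPUTS = ["V_LV_p8", "Eff_LV_p8", "V_LA_p8", "Eff_LA_p8"]
_PASSIVE_V0 = {"LV": 60.0, "LA": 30.0}  # mL, reference unloaded volumes
_PASSIVE_P = 8.0  # mmHg inflation test pressure


def simulate_passive(space: ParameterSpace, X: np.ndarray):
    X = np.atleast_2d(X)
    Y = np.full((len(X), 4), np.nan)
    ok = np.zeros(len(X), bool)
    for i, x in enumerate(X):
        p = space.row_dict(x)
        try:
            gv = GuccioneParams(p["a_v"], p["b_f_v"], p["b_ft_v"], p["b_t_v"])
            ga = GuccioneParams(p["a_a"], p["b_f_a"], p["b_ft_a"], p["b_t_a"])
            vlv, elv = inflate_chamber(gv, 110.0, _PASSIVE_V0["LV"], _PASSIVE_P)
            vla, ela = inflate_chamber(ga, 26.0, _PASSIVE_V0["LA"], _PASSIVE_P)
            Y[i] = (vlv, elv, vla, ela)
            ok[i] = True
        except ValueError:
            ok[i] = False
    return Y, ok


def _circ_params(p: dict) -> CircParams:
    return CircParams(
        V_LV_wall=p["V_LV_wall"] + 0.5 * p["V_SV_wall"],
        V_RV_wall=p["V_RV_wall"] + 0.5 * p["V_SV_wall"],
        V_LA_wall=p["V_LA_wall"], V_RA_wall=p["V_RA_wall"],
        AMVopen=p["AMVopen"], ATVopen=p["ATVopen"], AAVopen=p["AAVopen"],
        APVopen=p["APVopen"], ASOopen=p["ASOopen"], APOopen=p["APOopen"],
        pAo0=p["pAo0"], pPa0=p["pPa0"], pVe0=p["pVe0"], pPve0=p["pPve0"],
        l_Ao=p["l_Ao"], l_Pa=p["l_Pa"], l_Ve=p["l_Ve"], l_Pve=p["l_Pve"],
        k_Ao=p["k_Ao"], k_Pa=p["k_Pa"], k_Ve=p["k_Ve"], k_Pve=p["k_Pve"],
        q_ref=p["q_ref"], dp_sys_ref=p["dp_sys_ref"],
        dp_pulm_ref=p["dp_pulm_ref"], R_sys=p["R_sys"], R_pulm=p["R_pulm"],
        k_peri=p["k_peri"], EDP_shift_LV=p["EDP_shift_LV"],
        EDP_unload_RV=p["EDP_unload_RV"], T_ref_LvRv=p["T_ref_LvRv"],
        a_LvRv=p["a_LvRv"],
    )


def _chambers_from_params(p: dict, params: CircParams):
    from .cell_and_passive import unload_chamber
    from .circulation import ChamberSpec

    gv = GuccioneParams(p["a_v"], p["b_f_v"], p["b_ft_v"], p["b_t_v"])
    ga = GuccioneParams(p["a_a"], p["b_f_a"], p["b_ft_a"], p["b_t_a"])
    gv_rv = GuccioneParams(p["a_v"] * p["a_LvRv"], p["b_f_v"], p["b_ft_v"],
                           p["b_t_v"])
    edp_lv = 2.8 + p["EDP_shift_LV"]
    return {
        "LA": ChamberSpec(ga, unload_chamber(ga, params.V_LA_wall, 70.0, 2.0),
                          params.V_LA_wall),
        "LV": ChamberSpec(gv, unload_chamber(gv, params.V_LV_wall, 150.0, edp_lv),
                          params.V_LV_wall),
        "RA": ChamberSpec(ga, unload_chamber(ga, params.V_RA_wall, 70.0, 2.0),
                          params.V_RA_wall),
        "RV": ChamberSpec(gv_rv, unload_chamber(gv_rv, params.V_RV_wall, 150.0,
                                                p["EDP_unload_RV"]),
                          params.V_RV_wall),
    }


def _run_circulation_batch(rows, drivers_list, tats_list, cfg: PipelineConfig):
    """Vectorised closed-loop runs; returns (Y (N, 20), success (N,))."""
    from .circulation import build_circuit_batch

    N = len(rows)
    Y = np.full((N, len(PV_FEATURE_NAMES)), np.nan)
    ok = np.zeros(N, bool)
    params_list, chambers_list, act_list, keep = [], [], [], []
    for i, p in enumerate(rows):
        try:
            params = _circ_params(p)
            chambers = _chambers_from_params(p, params)
        except (ValueError, RuntimeError):
            continue
        tat_v, tat_a = tats_list[i]
        act_list.append({
            "LA": (0.0, tat_a), "RA": (0.0, tat_a),
            "LV": (p["AV_delay"], tat_v), "RV": (p["AV_delay"], tat_v),
        })
        params_list.append(params)
        chambers_list.append(chambers)
        keep.append(i)
    if not keep:
        return Y, ok
    drivers = [drivers_list[i] for i in keep]
    cir = build_circuit_batch(params_list, chambers_list, drivers, act_list)
    trace = run_beats(cir, n_beats=cfg.final_n_beats, dt=1.0,
                      substep=cfg.circ_substep)
    feats = pv_features(trace, act_list)
    Yb = np.column_stack([feats[k] for k in PV_FEATURE_NAMES])
    okb = trace.success & np.isfinite(Yb).all(axis=1)
    Y[keep] = Yb
    ok[keep] = okb
    return Y, ok


def simulate_circulation(space: ParameterSpace, X: np.ndarray,
                         cfg: PipelineConfig):
    """Circulation-alone stage: cell and tissue surrogates at defaults."""
    X = np.atleast_2d(X)
    defaults = table_defaults(cfg.table)
    d0 = dict(defaults)
    tats = _eikonal_tats(d0)
    _, [Tv] = _tension_batch([d0], "v", cfg)
    _, [Ta] = _tension_batch([d0], "a", cfg)
    drivers = {"LV": Tv, "RV": Tv, "LA": Ta, "RA": Ta}
    rows = [{**defaults, **space.row_dict(x)} for x in X]
    return _run_circulation_batch(rows, [drivers] * len(rows),
                                  [tats] * len(rows), cfg)


def simulate_whole_organ(space: ParameterSpace, X: np.ndarray,
                         cfg: PipelineConfig):
    """The coupled chain: activation -> cell tension -> circulation."""
    X = np.atleast_2d(X)
    defaults = table_defaults(cfg.table)
    rows = [{**defaults, **space.row_dict(x)} for x in X]
    _, tens_v = _tension_batch(rows, "v", cfg)
    _, tens_a = _tension_batch(rows, "a", cfg)
    drivers_list = [
        {"LV": tens_v[i], "RV": tens_v[i], "LA": tens_a[i], "RA": tens_a[i]}
        for i in range(len(rows))
    ]
    tats_list = [_eikonal_tats(p) for p in rows]
    return _run_circulation_batch(rows, drivers_list, tats_list, cfg)


# ---------------------------------------------------------------------------
# stage orchestration
# ---------------------------------------------------------------------------

@dataclass
class StageReport:
    name: str
    space: ParameterSpace
    batch: SimulationBatch
    models: dict[str, EmulatorModel]
    cv: dict[str, CVReport]
    sobol: SobolResult
    ranking: RankingResult
    waves: list[WaveState]
    targets: list[Target]
    flagged: list[str]

    @property
    def plausible_cloud(self) -> DesignMatrix | None:
        return self.waves[-1].plausible_cloud if self.waves else None


@dataclass
class AnalysisReport:
    stage_reports: dict[str, StageReport]
    final_space: ParameterSpace
    final_batch: SimulationBatch
    final_models: dict[str, EmulatorModel]
    final_cv: dict[str, CVReport]
    sobol: SobolResult
    ranking: RankingResult
    signed: np.ndarray
    heatmap: np.ndarray
    retained_counts: dict[str, int]
    n_failed: int
    screen_fraction: float
    config: PipelineConfig


def stage_space(cfg: PipelineConfig, name: str) -> ParameterSpace:
    subs = {name} | ({"boundary"} if name == "circulation" else set())
    rows = [r for r in _strip(cfg.table) if r["submodel"] in subs]
    return space_from_table(rows)


def _stage_simulator(name: str, cfg: PipelineConfig):
    if name == "tissue-ep":
        return lambda sp, X: simulate_tissue_ep(sp, X), TISSUE_OUTPUTS
    if name == "ventricular-cell":
        return lambda sp, X: simulate_cell(sp, X, "v", cfg), CELL_OUTPUTS
    if name == "atrial-cell":
        return lambda sp, X: simulate_cell(sp, X, "a", cfg), CELL_OUTPUTS
    if name == "passive":
        return lambda sp, X: simulate_passive(sp, X), PASSIVE_OUTPUTS
    if name == "circulation":
        return lambda sp, X: simulate_circulation(sp, X, cfg), PV_FEATURE_NAMES
    raise ValueError(f"unknown stage {name!r}")


def stage_targets(name: str, cfg: PipelineConfig) -> list[Target]:
    """Self-consistent targets: simulate the true (default) point, attach
    sigma = sigma_frac * |value| (floored)."""
    space = stage_space(cfg, name)
    sim, out_names = _stage_simulator(name, cfg)
    defaults = table_defaults(cfg.table)
    x_true = np.array([[defaults[n] for n in space.names]])
    Y, ok = sim(space, x_true)
    if not ok[0]:
        raise RuntimeError(f"true-point simulation failed for stage {name}")
    return [
        Target(n, float(v), max(cfg.sigma_frac * abs(v), 1e-3))
        for n, v in zip(out_names, Y[0])
    ]


def run_submodel_stage(
    name: str, cfg: PipelineConfig, seed: int | None = None
) -> StageReport:
    """Design -> simulate -> emulate -> cross-validate -> GSA -> rank;
    optionally history-match against self-consistent targets."""
    t0 = time.time()
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng([seed, hash(name) % 2**16])
    s_design, s_hm, s_gsa = (int(rng.integers(2**31)) for _ in range(3))
    space = stage_space(cfg, name)
    sim, out_names = _stage_simulator(name, cfg)
    scfg = cfg.stages[name]

    design = latin_hypercube(space, scfg.n_train, s_design)
    Y, ok = sim(space, design.values)
    if ok.mean() < 0.5:
        warnings.warn(f"stage {name}: simulator failure rate above 50%")
    batch = SimulationBatch(design, np.nan_to_num(Y), list(out_names), ok)

    fit_kw = dict(n_restarts=cfg.fit_restarts)
    models, cv, flagged = {}, {}, []
    for j, out in enumerate(out_names):
        Xok, yok = batch.X_ok, batch.y_ok(out)
        informative = np.std(yok) > 1e-9 * (1.0 + abs(np.mean(yok)))
        if informative and cfg.cv_folds >= 2 and len(yok) >= 2 * cfg.cv_folds:
            rep = cross_validate(Xok, yok, k_folds=cfg.cv_folds, seed=s_design,
                                 bounds=space.bounds, **fit_kw)
            cv[out] = rep
            if rep.mean_r2 < 0.5:
                flagged.append(out)
                warnings.warn(
                    f"stage {name}: emulator for {out!r} has mean CV R^2 "
                    f"{rep.mean_r2:.2f} < 0.5"
                )
        models[out] = fit_gpe(Xok, yok, bounds=space.bounds, seed=s_design,
                              **fit_kw)

    waves: list[WaveState] = []
    targets: list[Target] = []
    if scfg.hm_waves > 0:
        targets = stage_targets(name, cfg)
        sched = final_threshold_check(
            list(scfg.I_th) * scfg.hm_waves if len(scfg.I_th) == 1
            else list(scfg.I_th)
        )[: scfg.hm_waves]
        state: WaveState | SimulationBatch = batch
        for w in range(scfg.hm_waves):
            state = run_wave(
                state, lambda X: sim(space, X), targets,
                I_th=sched[min(w, len(sched) - 1)],
                n_test=scfg.n_test, n_simul=scfg.n_simul,
                seed=s_hm + w, fit_kwargs=fit_kw,
            )
            waves.append(state)
            if state.exhausted:
                break
        batch = waves[-1].batch
        models = waves[-1].models | {
            k: v for k, v in models.items() if k not in waves[-1].models
        }

    sobol = total_effects(
        [models[o] for o in out_names], space, cfg.gsa_n_base,
        n_draws=cfg.gsa_n_draws, seed=s_gsa, output_names=list(out_names),
    )
    ranking = rank_and_retain(sobol, cfg.retention_threshold)
    log.info("stage %s done in %.1f s (retained %d/%d)", name,
             time.time() - t0, len(ranking.retained), space.D)
    return StageReport(name, space, batch, models, cv, sobol, ranking, waves,
                       targets, flagged)


# ---------------------------------------------------------------------------
# whole-organ analysis
# ---------------------------------------------------------------------------

def _project_constraints(
    rep: StageReport, final_space: ParameterSpace, cfg: PipelineConfig,
    seed: int,
) -> ConstraintSet | None:
    """Refit a stage's screening emulators on the final-space columns."""
    if not rep.targets:
        return None
    keep = [n for n in rep.space.names if n in final_space.names]
    if not keep:
        return None
    cols_stage = [rep.space.names.index(n) for n in keep]
    cols_final = [final_space.names.index(n) for n in keep]
    sub = rep.space.subspace(keep)
    models = [
        fit_gpe(rep.batch.X_ok[:, cols_stage], rep.batch.y_ok(t.name),
                bounds=sub.bounds, seed=seed, n_restarts=cfg.fit_restarts)
        for t in rep.targets
    ]
    return ConstraintSet(models, rep.targets, cols_final, name=rep.name)


def _plausible_saltelli(
    final_space: ParameterSpace,
    constraints: list[ConstraintSet],
    n_base: int,
    seed: int,
    cfg: PipelineConfig,
) -> DesignMatrix:
    """Saltelli design whose base samples respect the sub-model constraints.

    For every history-matched block the A/B columns are drawn from that
    block's non-implausible region (resampled base sequences); remaining
    columns come from a scrambled Sobol' sequence.  The radial AB_i rows
    mix A and B rows and can leave the plausible region, which is why the
    assembled design is screened again before the estimator runs.
    """
    from scipy.stats import qmc
    from .sensitivity import generate_plausible_base

    D = final_space.D
    rng = np.random.default_rng(seed)
    A = np.empty((n_base, D))
    Bm = np.empty((n_base, D))
    free_cols = list(range(D))
    for cset in constraints:
        cols = list(cset.columns)
        sub = final_space.subspace([final_space.names[c] for c in cols])
        local = ConstraintSet(cset.models, cset.targets,
                              list(range(len(cols))), cset.name)
        pool = generate_plausible_base(
            sub, [local], n_required=2 * n_base,
            I_th=3.0, seed=int(rng.integers(2**31)),
            max_iter=12,
        )
        pick = rng.choice(len(pool), size=2 * n_base, replace=False)
        A[:, cols] = pool.values[pick[:n_base]]
        Bm[:, cols] = pool.values[pick[n_base:]]
        free_cols = [c for c in free_cols if c not in cols]
    if free_cols:
        sob = qmc.Sobol(d=2 * len(free_cols), scramble=True,
                        seed=int(rng.integers(2**31))).random(n_base)
        b = final_space.bounds[free_cols]
        lo, span = b[:, 0], b[:, 1] - b[:, 0]
        A[:, free_cols] = lo + sob[:, : len(free_cols)] * span
        Bm[:, free_cols] = lo + sob[:, len(free_cols):] * span
    blocks = [A, Bm]
    for i in range(D):
        ABi = A.copy()
        ABi[:, i] = Bm[:, i]
        blocks.append(ABi)
    return DesignMatrix(np.vstack(blocks), final_space, kind="saltelli",
                        seed=seed, n_base=n_base)


def run_full_analysis(cfg: PipelineConfig) -> AnalysisReport:
    """The end-to-end hierarchical analysis."""
    t0 = time.time()
    rng = np.random.default_rng([cfg.seed, 777])
    seeds = {k: int(rng.integers(2**31)) for k in
             ("stage", "intersect", "subsample", "final", "gsa", "screen")}
    stage_reports = {
        name: run_submodel_stage(name, cfg, seeds["stage"] + i)
        for i, name in enumerate(STAGES)
    }

    # retained parameters, in stable full-table order
    retained: list[str] = []
    counts = {}
    for name in STAGES:
        rep = stage_reports[name]
        counts[name] = len(rep.ranking.retained)
        retained.extend(rep.ranking.retained)
    full_space = space_from_table(_strip(cfg.table))
    final_names = [n for n in full_space.names if n in set(retained)]
    final_space = full_space.subspace(final_names)

    # plausible clouds from the HM stages, projected to retained columns;
    # everything else comes from a plain LHS block
    clouds = []
    lhs_names = list(final_names)
    for name in STAGES:
        rep = stage_reports[name]
        cloud = rep.plausible_cloud
        if cloud is None or len(cloud) == 0:
            continue
        keep = [n for n in rep.space.names
                if n in final_names and n in cloud.space.names]
        if not keep:
            continue
        cols = [cloud.space.names.index(n) for n in keep]
        clouds.append(DesignMatrix(cloud.values[:, cols],
                                   cloud.space.subspace(keep), kind="cloud"))
        lhs_names = [n for n in lhs_names if n not in keep]
    extra = (latin_hypercube(full_space.subspace(lhs_names),
                             max(max((len(c) for c in clouds), default=0),
                                 4 * cfg.n_final_design),
                             seeds["intersect"])
             if lhs_names else None)
    joint = intersect_regions(clouds, extra, seed=seeds["intersect"])
    # column order must match the final space
    order = [joint.space.names.index(n) for n in final_names]
    joint = DesignMatrix(joint.values[:, order], final_space, kind="cloud")

    n_final = min(cfg.n_final_design, len(joint))
    design = subsample_space_filling(joint, n_final, seeds["subsample"])
    if n_final < final_space.D + 2:
        raise ValueError("fewer than D+2 design points for the final fit")

    Y, ok = simulate_whole_organ(final_space, design.values, cfg)
    n_failed = int((~ok).sum())
    batch = SimulationBatch(design, np.nan_to_num(Y), list(PV_FEATURE_NAMES), ok)
    if ok.sum() < final_space.D + 2:
        raise ValueError("fewer than D+2 successful whole-organ runs")

    fit_kw = dict(n_restarts=cfg.fit_restarts)
    final_models, final_cv = {}, {}
    for out in PV_FEATURE_NAMES:
        Xok, yok = batch.X_ok, batch.y_ok(out)
        if cfg.cv_folds >= 2:
            final_cv[out] = cross_validate(Xok, yok, k_folds=cfg.cv_folds,
                                           seed=seeds["final"],
                                           bounds=final_space.bounds, **fit_kw)
        final_models[out] = fit_gpe(Xok, yok, bounds=final_space.bounds,
                                    seed=seeds["final"], **fit_kw)

    # plausibility-screened GSA
    constraints = [
        c for c in (
            _project_constraints(stage_reports[n], final_space, cfg,
                                 seeds["screen"])
            for n in STAGES
        ) if c is not None
    ]
    if constraints:
        sdesign = _plausible_saltelli(final_space, constraints,
                                      cfg.gsa_n_base, seeds["gsa"], cfg)
        mask = screen_samples(sdesign, constraints, I_th=3.0)
        D, n = final_space.D, cfg.gsa_n_base
        blocks = np.vstack([mask[:n], mask[n:2 * n],
                            mask[2 * n:].reshape(D, n)])
        base_keep = blocks.all(axis=0)
        screen_fraction = float(base_keep.mean())
        if base_keep.sum() < 16:
            warnings.warn("screening left too few Saltelli base rows; "
                          "screening disabled for the estimator")
            base_keep = None
            screen_fraction = float(mask.mean())
    else:
        sdesign = saltelli_design(final_space, cfg.gsa_n_base, seeds["gsa"])
        base_keep = None
        screen_fraction = 1.0

    models_list = [final_models[o] for o in PV_FEATURE_NAMES]
    sobol = total_effects(
        models_list, final_space, cfg.gsa_n_base, n_draws=cfg.gsa_n_draws,
        seed=seeds["gsa"], output_names=list(PV_FEATURE_NAMES),
        design=sdesign, base_keep=base_keep,
    )
    ranking = rank_and_retain(sobol, cfg.retention_threshold)
    signed = signed_effects(sobol, models_list)
    pos = np.clip(sobol.total_effects, 0.0, None)
    colmax = np.maximum(pos.max(axis=0, keepdims=True), 1e-12)
    heatmap = pos / colmax
    counts["final"] = len(ranking.retained)
    log.info("full analysis done in %.1f s", time.time() - t0)
    return AnalysisReport(
        stage_reports, final_space, batch, final_models, final_cv, sobol,
        ranking, signed, heatmap, counts, n_failed, screen_fraction, cfg,
    )


# ---------------------------------------------------------------------------
# reporting & fixtures
# ---------------------------------------------------------------------------

def report(analysis: AnalysisReport, outdir: str | Path) -> dict:
    """Persist CSV matrices, the ranking, a manifest and a heatmap figure."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    sb = analysis.sobol
    idx = sb.param_names
    pd.DataFrame(sb.total_effects, index=idx, columns=sb.output_names).to_csv(
        out / "total_effects.csv")
    pd.DataFrame(sb.total_effects_sd, index=idx, columns=sb.output_names
                 ).to_csv(out / "total_effects_sd.csv")
    pd.DataFrame(analysis.signed, index=idx, columns=sb.output_names).to_csv(
        out / "signed_effects.csv")
    pd.DataFrame(analysis.heatmap, index=idx, columns=sb.output_names).to_csv(
        out / "heatmap.csv")
    rows = []
    for stage, rep in analysis.stage_reports.items():
        for o, r in rep.cv.items():
            rows.append({"stage": stage, "output": o, "mean_R2": r.mean_r2,
                         "mean_ISE": r.mean_ise})
    for o, r in analysis.final_cv.items():
        rows.append({"stage": "final", "output": o, "mean_R2": r.mean_r2,
                     "mean_ISE": r.mean_ise})
    pd.DataFrame(rows).to_csv(out / "cv_scores.csv", index=False)

    ranking = {
        "order": analysis.ranking.order,
        "normalized_max": analysis.ranking.normalized_max.tolist(),
        "retained": analysis.ranking.retained,
        "threshold": analysis.ranking.threshold,
        "retained_counts": analysis.retained_counts,
    }
    (out / "ranking.json").write_text(json.dumps(ranking, indent=2))

    # per-output bars: top parameters up to the 90% set, capped at 10
    bars = {}
    for j, o in enumerate(sb.output_names):
        col = np.clip(sb.total_effects[:, j], 0, None)
        if col.sum() <= 0:
            continue
        order = np.argsort(-col, kind="stable")
        shares = col[order] / col.sum()
        n_keep = min(int(np.searchsorted(np.cumsum(shares), 0.9) + 1), 10)
        bars[o] = {
            sb.param_names[i]: float(analysis.signed[i, j])
            for i in order[:n_keep]
        }
    (out / "signed_bars.json").write_text(json.dumps(bars, indent=2))

    diag = {
        s: [w.diagnostics.to_dict() for w in rep.waves]
        for s, rep in analysis.stage_reports.items()
    }
    (out / "wave_diagnostics.json").write_text(json.dumps(diag, indent=2))

    manifest = {
        "version": __version__,
        "seed": analysis.config.seed,
        "config_hash": analysis.config.hash(),
        "n_failed": analysis.n_failed,
        "screen_fraction": analysis.screen_fraction,
        "retained_counts": analysis.retained_counts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(
            figsize=(0.5 * len(sb.output_names) + 3, 0.3 * len(idx) + 2))
        im = ax.imshow(analysis.heatmap, aspect="auto", cmap="viridis",
                       vmin=0, vmax=1)
        ax.set_xticks(range(len(sb.output_names)), sb.output_names,
                      rotation=90, fontsize=7)
        ax.set_yticks(range(len(idx)), idx, fontsize=7)
        fig.colorbar(im, ax=ax, label="normalised total effect")
        fig.tight_layout()
        fig.savefig(out / "heatmap.png", dpi=120)
        plt.close(fig)
    except Exception as exc:  # plotting must never fail the pipeline
        warnings.warn(f"heatmap figure skipped: {exc}")
    return manifest


def generate_fixtures(outdir: str | Path, seed: int = 0,
                      cfg: PipelineConfig | None = None) -> dict:
    """Emit the default geometry, parameter tables and HM target files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = cfg or desk_config(str(out))
    yaml_safe = yaml.safe_dump({"parameters": _strip(paper_parameter_table())})
    (out / "parameter_table.yaml").write_text(yaml_safe)
    (out / "desk_parameter_table.yaml").write_text(
        yaml.safe_dump({"parameters": _strip(desk_parameter_table())}))

    grid, sites = _fixture_grid()
    ny, nx = grid.labels.shape
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    df = pd.DataFrame({
        "iy": yy.ravel(), "ix": xx.ravel(),
        "y_mm": yy.ravel() * grid.h, "x_mm": xx.ravel() * grid.h,
        "label": grid.labels.ravel(),
        "fibre_y": grid.fibres[..., 0].ravel(),
        "fibre_x": grid.fibres[..., 1].ravel(),
    })
    df.to_csv(out / "two_slab_grid.csv", index=False)
    (out / "sites.json").write_text(json.dumps({k: list(v) for k, v in
                                                sites.items()}))
    targets = {}
    for name in ("tissue-ep", "ventricular-cell", "atrial-cell"):
        targets[name] = [
            {"name": t.name, "mu": t.mu, "sigma": t.sigma}
            for t in stage_targets(name, cfg)
        ]
    (out / "targets.json").write_text(json.dumps(targets, indent=2))
    return {"outdir": str(out), "n_targets": sum(map(len, targets.values()))}
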