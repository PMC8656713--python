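"""End-to-end cohort study: plan, simulate all workflow arms, score.

This is the orchestration layer used by the command-line interface and the
reproduction script.  It exploits the structural independence of the
adapted weights from the post-adaptation offsets: for each fraction the
daily geometry, influence matrix and adapted weights are computed once and
shared by every arm (base plan, no-offset adaptation, and the three offset
scenarios), which both pairs the arms statistically and keeps a ten-patient
multi-arm study at desk scale.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics as dm
from .cohort import PatientModel, generate_cohort
from .config import Profile, get_profile
from .course import _FractionEngine, default_scenarios, offset_rng
from .grid import VoxelGrid
from .planner import BasePlan, Prescription, make_base_plan

__all__ = ["StudyResult", "run_study", "plan_for", "accumulated_metrics"]

METRIC_SPECS = (
    ("ctv_high", "d98_pct"),
    ("ctv_high", "d2_pct"),
    ("ctv_low", "d98_pct"),
    ("larynx", "dmean_gy"),
    ("parotid_r", "dmean_gy"),
    ("parotid_l", "dmean_gy"),
    ("constrictors", "dmean_gy"),
    ("cord", "d1cc_gy"),
    ("healthy", "dv_gyl"),
)


def accumulated_metrics(
    dose: VoxelGrid,
    phantom,
    prescription: Prescription,
    scale: float = 1.0,
    target_dose: VoxelGrid | None = None,
) -> dict[tuple[str, str], float]:
    """The standard accumulated-DVH metric set for one course dose.

    CTV D98/D2 in % of the (scaled) structure prescription; OAR mean doses
    and cord D1cc in Gy; healthy-tissue integral dose in Gy*L.  When the
    tumor drifts relative to the setup reference, ``target_dose`` is the
    accumulation warped through the target-region correspondence (the
    exact-DIR analog) and is used for the CTV metrics only.
    """
    s = phantom.structures
    tdose = target_dose if target_dose is not None else dose
    out = {}
    for structure, metric in METRIC_SPECS:
        if metric == "d98_pct":
            q = dm.dose_at_volume(tdose, s[structure], 98.0)
            out[(structure, metric)] = 100.0 * q / (prescription.target(structure) * scale)
        elif metric == "d2_pct":
            q = dm.dose_at_volume(tdose, s[structure], 2.0)
            out[(structure, metric)] = 100.0 * q / (prescription.target(structure) * scale)
        elif metric == "dmean_gy":
            out[(structure, metric)] = dm.mean_dose(dose, s[structure])
        elif metric == "d1cc_gy":
            out[(structure, metric)] = dm.d_1cc(dose, s[structure], dose.voxel_volume)
        else:  # dv_gyl on external minus CTVs
            out[(structure, metric)] = dm.integral_dose(dose, phantom.healthy_mask())
    return out


@dataclass
class StudyResult:
    """Cohort study outputs in long format."""

    metrics: pd.DataFrame          # patient x arm x structure x metric
    traces: pd.DataFrame           # per-fraction CTV D98 traces
    cohort: list[PatientModel]
    base_plans: dict[str, BasePlan]
    goal_reports: dict[str, list] = field(default_factory=dict)
    accumulated: dict[tuple[str, str], VoxelGrid] = field(default_factory=dict)
    dvh_curves: pd.DataFrame | None = None
    timings: dict[str, float] = field(default_factory=dict)


def plan_for(patient: PatientModel, profile: Profile, **kwargs) -> BasePlan:
    """Base plan for a patient at the given resolution profile."""
    return make_base_plan(
        patient.planning_phantom,
        prescription=Prescription(n_fractions=patient.n_fractions),
        spot_spacing=profile.spot_spacing,
        layer_spacing=profile.layer_spacing,
        maxiter=profile.base_maxiter,
        adapt_maxiter=profile.adapt_maxiter,
        **kwargs,
    )


def run_study(
    master_seed: int,
    n_patients: int = 10,
    profile: str | Profile = "coarse",
    scenario_names: tuple[str, ...] = ("none", "s1", "s2", "s3"),
    include_bp: bool = True,
    keep_accumulated: bool = False,
    collect_dvh: bool = False,
    dvh_bin_width: float = 0.5,
    progress: bool = False,
) -> StudyResult:
    """Simulate the full multi-arm adaptive course study on a seeded cohort.

    Arms are named ``bp`` and ``oa_<scenario>``.  All randomness derives
    from ``master_seed``; paired arms share daily geometry, adapted weights
    and (scaled) offset draws.
    """
    prof = get_profile(profile) if isinstance(profile, str) else profile
    scenarios = default_scenarios()
    unknown = set(scenario_names) - set(scenarios)
    if unknown:
        raise ValueError(f"unknown scenarios: {sorted(unknown)}")

    t0 = time.perf_counter()
    cohort = generate_cohort(n_patients, master_seed, grid=prof.grid)

    # The planning phantom is shared across the synthetic cohort; plan once
    # at a reference fractionation and rescale per patient (exactly optimal
    # because the per-fraction objective is scale-invariant).
    ref_plan = make_base_plan(
        cohort[0].planning_phantom,
        prescription=Prescription(n_fractions=33),
        spot_spacing=prof.spot_spacing,
        layer_spacing=prof.layer_spacing,
        maxiter=prof.base_maxiter,
        adapt_maxiter=prof.adapt_maxiter,
    )
    t_plan = time.perf_counter() - t0

    metric_rows = []
    trace_rows = []
    dvh_rows = []
    accumulated: dict[tuple[str, str], VoxelGrid] = {}
    arm_list = (["bp"] if include_bp else []) + [f"oa_{s}" for s in scenario_names]

    t1 = time.perf_counter()
    for patient in cohort:
        phantom = patient.planning_phantom
        prescription = Prescription(n_fractions=patient.n_fractions)
        engine = _FractionEngine(patient, ref_plan)
        acc = {arm: phantom.grid.zeros() for arm in arm_list}
        acc_target = {arm: phantom.grid.zeros() for arm in arm_list}
        scale = prescription.per_fraction_scale
        for j in range(1, patient.n_fractions + 1):
            rng_z = offset_rng(patient.seed, j)
            z = rng_z.normal(0.0, 1.0, 3)  # shared standard-normal draw
            for arm in arm_list:
                if arm == "bp":
                    mode, scen = "bp", None
                else:
                    mode, scen = "oa", scenarios[arm[3:]]
                state = engine.daily_state(j)
                offset = np.zeros(3) if scen is None else scen.sigma * z
                outcome = _deliver_with_offset(engine, state, mode, scen, offset)
                warped = dm.warp_to_planning(
                    outcome.delivered_dose, outcome.total_transform
                )
                warped_target = dm.warp_to_planning(
                    outcome.delivered_dose, outcome.target_transform
                )
                acc[arm].values += warped.values
                acc_target[arm].values += warped_target.values
                for level in ("ctv_high", "ctv_low"):
                    d98 = dm.dose_at_volume(warped_target, phantom.structures[level], 98.0)
                    trace_rows.append(
                        {
                            "patient_id": patient.patient_id,
                            "arm": arm,
                            "fraction": j,
                            "structure": level,
                            "d98_pct": 100.0 * d98 / (prescription.target(level) * scale),
                        }
                    )
        for arm in arm_list:
            values = accumulated_metrics(
                acc[arm], phantom, prescription, target_dose=acc_target[arm]
            )
            for (structure, metric), value in values.items():
                metric_rows.append(
                    {
                        "patient_id": patient.patient_id,
                        "arm": arm,
                        "structure": structure,
                        "metric": metric,
                        "value": float(value),
                    }
                )
            if collect_dvh:
                for structure in ("ctv_high", "ctv_low", "cord"):
                    src = acc_target[arm] if structure.startswith("ctv") else acc[arm]
                    curve = dm.dvh(src, phantom.structures[structure], dvh_bin_width)
                    for edge, vol in zip(
                        curve.dose_edges, curve.cumulative_volume_fraction
                    ):
                        dvh_rows.append(
                            {
                                "patient_id": patient.patient_id,
                                "arm": arm,
                                "structure": structure,
                                "dose_gy": float(edge),
                                "volume_fraction": float(vol),
                            }
                        )
            if keep_accumulated:
                accumulated[(patient.patient_id, arm)] = acc[arm]
        if progress:
            print(
                f"{patient.patient_id}: {patient.n_fractions} fractions, "
                f"{time.perf_counter() - t1:.1f}s elapsed",
                flush=True,
            )

    return StudyResult(
        metrics=pd.DataFrame(metric_rows),
        traces=pd.DataFrame(trace_rows),
        cohort=cohort,
        base_plans={"reference": ref_plan},
        accumulated=accumulated,
        dvh_curves=pd.DataFrame(dvh_rows) if collect_dvh else None,
        timings={
            "planning_s": t_plan,
            "simulation_s": time.perf_counter() - t1,
        },
    )


def _deliver_with_offset(engine: _FractionEngine, state, mode, scenario, offset):
    """Deliver one fraction arm with a pre-drawn offset (pairing helper)."""
    from .course import FractionOutcome
    from .engine import shift_wed
    from .planner import PlanWeights

    daily = state["daily"]
    weights = state["adapted"] if mode == "oa" else PlanWeights(
        engine.w_base, provenance="base"
    )
    colplan = engine.bp_colplan() if mode == "bp" else state["colplan"]
    if np.any(offset):
        spacing = daily.phantom.rsp.spacing
        wed_rows = engine.builder.wed_rows(
            [shift_wed(w, offset, spacing) for w in state["wed_full"]]
        )
        dose_rows = engine.builder.forward(
            wed_rows, engine.plan.beamlets, weights.w, plan=colplan
        )
    elif mode == "bp":
        dose_rows = engine.builder.forward(
            state["wed"], engine.plan.beamlets, weights.w, plan=colplan
        )
    else:
        dose_rows = np.asarray(state["im"].entries @ weights.w).ravel()
    return FractionOutcome(
        fraction_index=daily.fraction_index,
        mode=mode,
        scenario=scenario,
        offset=tuple(float(v) for v in offset),
        weights_used=weights,
        delivered_dose=engine.builder.scatter(dose_rows),
        daily_transform=daily.setup_transform,
        target_drift=tuple(daily.anatomy_descriptor.get("target_drift", (0.0, 0.0, 0.0))),
    )
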