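"""Treatment-course simulation for adaptive workflows with execution offsets.

Four workflows are simulated per patient:

* ``BP`` — the unadapted base plan delivered at its original absolute
  isocenter and recomputed on the daily geometry (the daily-image-visible
  displacement is what adaptation corrects and the unadapted plan suffers);
* ``OA`` with no offset — per-fraction re-optimization of the beamlet
  weights on the daily geometry (CBCT-like workflow, the reference);
* ``OA`` with a post-adaptation offset scenario — after the daily
  re-optimization the patient is displaced by a random per-axis Gaussian
  offset before delivery (CT-on-rails-like workflow).

The total execution uncertainty combines the isocenter-matching term and
the couch-motion term in quadrature, ``sigma = sqrt(sigma_i^2 +
sigma_m^2)``; the three standard scenarios use sigma_i = 1 mm with
sigma_m = 1, 2, 3 mm.  The offset is sampled *after* adaptation — the
adapted weights never depend on it, which the test suite asserts
structurally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import metrics as dm
from .cohort import DailyInstance, PatientModel, daily_instance
from .engine import InfluenceBuilder, shift_wed
from .grid import VoxelGrid
from .planner import PlanWeights, build_objective, optimize

__all__ = [
    "UncertaintyScenario",
    "FractionOutcome",
    "CourseResult",
    "combine_sigma",
    "default_scenarios",
    "sample_offset",
    "offset_rng",
    "simulate_fraction",
    "simulate_course",
]


def combine_sigma(sigma_i: float, sigma_m: float) -> float:
    """Total execution uncertainty: quadrature sum of the two components."""
    if sigma_i < 0 or sigma_m < 0:
        raise ValueError("uncertainty components must be nonnegative")
    return math.hypot(sigma_i, sigma_m)


@dataclass(frozen=True)
class UncertaintyScenario:
    """Post-adaptation offset distribution (per-axis Gaussian, mm)."""

    name: str
    sigma_i: float  # isocenter-matching component
    sigma_m: float  # couch-motion-induced component

    def __post_init__(self) -> None:
        if self.sigma_i < 0 or self.sigma_m < 0:
            raise ValueError("uncertainty components must be nonnegative")

    @property
    def sigma(self) -> float:
        return combine_sigma(self.sigma_i, self.sigma_m)


def default_scenarios() -> dict[str, UncertaintyScenario | None]:
    """The standard scenario table: no offset plus sigma_m = 1, 2, 3 mm."""
    return {
        "none": None,
        "s1": UncertaintyScenario("s1", 1.0, 1.0),
        "s2": UncertaintyScenario("s2", 1.0, 2.0),
        "s3": UncertaintyScenario("s3", 1.0, 3.0),
    }


def sample_offset(scenario: UncertaintyScenario | None, rng: np.random.Generator) -> np.ndarray:
    """Three independent zero-mean Gaussian draws, one per axis (mm)."""
    if scenario is None or scenario.sigma == 0:
        return np.zeros(3)
    return rng.normal(0.0, scenario.sigma, 3)


def offset_rng(seed: int, j: int) -> np.random.Generator:
    """Per-fraction offset substream.

    Keyed by (seed, fraction, purpose) only — not by scenario — so paired
    scenario arms share the same standard-normal draw scaled by their
    sigma (common random numbers) and adding arms never perturbs the
    geometry substreams.
    """
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(j, 10)))


@dataclass
class FractionOutcome:
    fraction_index: int
    mode: str                          # 'bp' | 'oa'
    scenario: UncertaintyScenario | None
    offset: tuple[float, float, float]
    weights_used: PlanWeights
    delivered_dose: VoxelGrid          # on the (possibly offset) daily geometry
    daily_transform: tuple[float, float, float]
    target_drift: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.scenario is None and any(self.offset):
            raise ValueError("offset must be zero without a scenario")

    @property
    def total_transform(self) -> np.ndarray:
        """Planning -> delivery translation (setup plus offset), mm."""
        return np.asarray(self.daily_transform) + np.asarray(self.offset)

    @property
    def target_transform(self) -> np.ndarray:
        """Planning -> delivery mapping for the tumor region, which
        additionally follows the internal target drift (the exact-DIR
        analog used when scoring CTV metrics in the planning frame)."""
        return self.total_transform + np.asarray(self.target_drift)


@dataclass
class CourseResult:
    patient_id: str
    mode: str
    scenario_name: str
    outcomes: list[FractionOutcome]
    accumulated_dose: VoxelGrid
    rng_seed: int


class _FractionEngine:
    """Shared per-fraction machinery: daily geometry, influence, adaptation.

    One instance serves all workflow arms of one patient so that paired
    arms reuse the identical daily influence matrix and adapted weights.
    """

    def __init__(self, patient: PatientModel, base_plan) -> None:
        self.patient = patient
        self.plan = base_plan
        self.builder: InfluenceBuilder = base_plan.builder
        # Rescale base weights to this patient's fractionation (the
        # per-fraction objective is scale-invariant, so this is optimal).
        self.w_base = base_plan.weights.w * (
            base_plan.prescription.n_fractions / patient.n_fractions
        )
        self._cache: dict[int, dict] = {}
        # BP delivers at the original absolute isocenter (the daily
        # displacement is exactly what adaptation corrects and the
        # unadapted plan suffers); its spot geometry is fraction-independent.
        self._bp_colplan = None

    def bp_colplan(self):
        if self._bp_colplan is None:
            self._bp_colplan = self.builder.column_plan(self.plan.beamlets)
        return self._bp_colplan

    def daily_state(self, j: int) -> dict:
        if j in self._cache:
            return self._cache[j]
        daily = daily_instance(self.patient, j)
        wed_full = self.builder.wed_full(daily.phantom)
        wed = self.builder.wed_rows(wed_full)
        colplan = self.builder.column_plan(
            self.plan.beamlets, iso_shift=daily.setup_transform
        )
        im = self.builder.matrix(wed, self.plan.beamlets, plan=colplan)
        objective = build_objective(
            daily.phantom,
            self.plan.prescription,
            self.plan.goals,
            fraction_scale=1.0 / self.patient.n_fractions,
        )
        adapted = optimize(
            im,
            objective,
            w_init=self.w_base,
            maxiter=self.plan.adapt_maxiter,
            provenance=f"adapted({j})",
        )
        state = {
            "daily": daily,
            "wed": wed,
            "wed_full": wed_full,
            "im": im,
            "adapted": adapted,
            "colplan": colplan,
        }
        self._cache[j] = state
        if len(self._cache) > 2:  # keep memory bounded over a course
            self._cache.pop(next(iter(k for k in self._cache if k != j)))
        return state

    def deliver(self, j: int, mode: str, scenario: UncertaintyScenario | None,
                rng: np.random.Generator | None) -> FractionOutcome:
        state = self.daily_state(j)
        daily: DailyInstance = state["daily"]
        weights = state["adapted"] if mode == "oa" else PlanWeights(
            self.w_base, provenance="base"
        )
        offset = sample_offset(scenario, rng) if scenario is not None else np.zeros(3)
        colplan = self.bp_colplan() if mode == "bp" else state["colplan"]
        if np.any(offset):
            spacing = daily.phantom.rsp.spacing
            wed_rows = self.builder.wed_rows(
                [shift_wed(w_full, offset, spacing) for w_full in state["wed_full"]]
            )
            dose_rows = self.builder.forward(
                wed_rows, self.plan.beamlets, weights.w, plan=colplan
            )
        elif mode == "bp":
            dose_rows = self.builder.forward(
                state["wed"], self.plan.beamlets, weights.w, plan=colplan
            )
        else:
            dose_rows = np.asarray(state["im"].entries @ weights.w).ravel()
        dose = self.builder.scatter(dose_rows)
        return FractionOutcome(
            fraction_index=j,
            mode=mode,
            scenario=scenario,
            offset=tuple(float(v) for v in offset),
            weights_used=weights,
            delivered_dose=dose,
            daily_transform=daily.setup_transform,
            target_drift=tuple(daily.anatomy_descriptor.get("target_drift", (0.0, 0.0, 0.0))),
        )

def simulate_fraction(
    patient: PatientModel,
    j: int,
    mode: str,
    scenario: UncertaintyScenario | None,
    base_plan,
    rng: np.random.Generator | None = None,
) -> FractionOutcome:
    """Simulate one fraction of one workflow arm.

    Pipeline: daily geometry -> (OA only) re-optimize weights on the daily
    influence matrix, warm-started from the base weights -> sample the
    post-adaptation offset -> compute the delivered dose on the offset
    geometry.  The offset is sampled after adaptation, so the adapted
    weights are independent of it by construction.
    """
    if mode not in ("bp", "oa"):
        raise ValueError("mode must be 'bp' or 'oa'")
    eng = _FractionEngine(patient, base_plan)
    if rng is None and scenario is not None:
        rng = offset_rng(patient.seed, j)
    return eng.deliver(j, mode, scenario, rng)


def simulate_course(
    patient: PatientModel,
    mode: str,
    scenario: UncertaintyScenario | None,
    base_plan,
    seed: int | None = None,
) -> CourseResult:
    """Simulate a full course of one workflow arm and accumulate its dose.

    Per-fraction offset draws come from substreams of ``seed`` (default:
    the patient seed), so the result is deterministic.
    """
    if mode not in ("bp", "oa"):
        raise ValueError("mode must be 'bp' or 'oa'")
    seed = patient.seed if seed is None else seed
    eng = _FractionEngine(patient, base_plan)
    outcomes = []
    for j in range(1, patient.n_fractions + 1):
        rng = offset_rng(seed, j) if scenario is not None else None
        outcomes.append(eng.deliver(j, mode, scenario, rng))
    accumulated = dm.accumulate(outcomes, patient.planning_phantom)
    return CourseResult(
        patient_id=patient.patient_id,
        mode=mode,
        scenario_name=scenario.name if scenario else "none",
        outcomes=outcomes,
        accumulated_dose=accumulated,
        rng_seed=seed,
    )
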