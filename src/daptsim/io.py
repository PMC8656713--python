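"""Volume and manifest I/O (NRRD/NIfTI via SimpleITK, JSON manifests)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .cohort import PatientModel, Phantom, PhantomGeometry
from .grid import GridSpec, VoxelGrid

__all__ = [
    "write_volume",
    "read_volume",
    "write_phantom",
    "read_phantom",
    "write_cohort_manifest",
    "read_cohort_manifest",
    "write_plan",
    "read_plan",
    "save_influence",
    "load_influence",
]


def _to_image(grid: VoxelGrid) -> sitk.Image:
    # SimpleITK images are indexed (z, y, x) in the numpy view.
    img = sitk.GetImageFromArray(np.ascontiguousarray(grid.values.T))
    img.SetSpacing(tuple(float(s) for s in grid.spacing))
    img.SetOrigin(tuple(float(o) for o in grid.origin))
    return img


def write_volume(grid: VoxelGrid, path: str | Path) -> None:
    """Write a grid as NRRD or NIfTI (by file extension)."""
    sitk.WriteImage(_to_image(grid), str(path), useCompression=True)


def read_volume(path: str | Path) -> VoxelGrid:
    img = sitk.ReadImage(str(path))
    values = sitk.GetArrayFromImage(img).T
    return VoxelGrid(tuple(img.GetSpacing()), tuple(img.GetOrigin()), np.asarray(values, float))


def write_phantom(phantom: Phantom, directory: str | Path) -> None:
    """Write the RSP volume plus one mask volume per structure."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_volume(phantom.rsp, directory / "rsp.nrrd")
    for name, mask in phantom.structures.items():
        write_volume(
            phantom.rsp.spec.wrap(mask.astype(np.uint8)), directory / f"{name}.nrrd"
        )


def read_phantom(directory: str | Path) -> Phantom:
    directory = Path(directory)
    rsp = read_volume(directory / "rsp.nrrd")
    structures = {}
    for path in sorted(directory.glob("*.nrrd")):
        if path.stem == "rsp":
            continue
        structures[path.stem] = read_volume(path).values > 0.5
    return Phantom(rsp=rsp, structures=structures)


def write_plan(plan, path: str | Path) -> None:
    """Persist a plan (beamlets, weights, provenance, calibration) as JSON."""
    payload = {
        "provenance": plan.weights.provenance,
        "calibration": plan.calibration,
        "prescription": {
            "dose_low": plan.prescription.dose_low,
            "dose_high": plan.prescription.dose_high,
            "n_fractions": plan.prescription.n_fractions,
        },
        "fields": [
            {"gantry_angle": f.gantry_angle, "isocenter": list(f.isocenter)}
            for f in plan.fields
        ],
        "beamlets": [
            {
                "field_index": b.field_index,
                "energy": b.energy,
                "lateral_position": list(b.lateral_position),
                "sigma_air": b.sigma_air,
            }
            for b in plan.beamlets
        ],
        "weights": [float(w) for w in plan.weights.w],
    }
    Path(path).write_text(json.dumps(payload))


def read_plan(path: str | Path):
    """Load a plan written by :func:`write_plan` (no builder attached)."""
    from .engine import Beamlet, Field
    from .planner import BasePlan, ClinicalGoals, PlanWeights, Prescription

    payload = json.loads(Path(path).read_text())
    fields = [Field(f["gantry_angle"], tuple(f["isocenter"])) for f in payload["fields"]]
    beamlets = [
        Beamlet(b["field_index"], b["energy"], tuple(b["lateral_position"]), b["sigma_air"])
        for b in payload["beamlets"]
    ]
    weights = PlanWeights(np.asarray(payload["weights"]), provenance=payload["provenance"])
    return BasePlan(
        fields=fields,
        beamlets=beamlets,
        weights=weights,
        prescription=Prescription(**payload["prescription"]),
        goals=ClinicalGoals(),
        calibration=payload["calibration"],
    )


def save_influence(im, path: str | Path) -> None:
    """Persist an influence matrix in a compressed sparse container."""
    m = im.entries.tocsc()
    np.savez_compressed(
        path,
        data=m.data,
        indices=m.indices,
        indptr=m.indptr,
        shape=m.shape,
        row_index=im.row_index,
        grid_shape=np.asarray(im.grid_ref.shape),
        grid_spacing=np.asarray(im.grid_ref.spacing),
        beamlets=np.array(
            [
                (b.field_index, b.energy, *b.lateral_position, b.sigma_air)
                for b in im.beamlets
            ]
        ),
    )


def load_influence(path: str | Path):
    from scipy import sparse

    from .engine import Beamlet, InfluenceMatrix

    with np.load(path) as z:
        mat = sparse.csc_matrix(
            (z["data"], z["indices"], z["indptr"]), shape=tuple(z["shape"])
        )
        beamlets = [
            Beamlet(int(fi), float(e), (float(u), float(v)), float(s))
            for fi, e, u, v, s in z["beamlets"]
        ]
        return InfluenceMatrix(
            entries=mat,
            beamlets=beamlets,
            grid_ref=GridSpec(
                tuple(int(v) for v in z["grid_shape"]),
                tuple(float(v) for v in z["grid_spacing"]),
            ),
            row_index=z["row_index"],
        )


def write_cohort_manifest(cohort: list[PatientModel], path: str | Path) -> None:
    """JSON cohort manifest: ids, seeds, fraction counts, variation params."""
    payload = []
    for p in cohort:
        payload.append(
            {
                "patient_id": p.patient_id,
                "seed": p.seed,
                "n_fractions": p.n_fractions,
                "grid": {"shape": list(p.grid.shape), "spacing": list(p.grid.spacing)},
                "variation_params": {
                    "systematic_mm": list(p.systematic),
                    "random_sigma_mm": p.random_sigma,
                    "shrink_max_mm": p.shrink_max,
                    "drift_mm": list(p.drift),
                    "cavity_prob": p.cavity_prob,
                },
            }
        )
    Path(path).write_text(json.dumps(payload, indent=2))


def read_cohort_manifest(path: str | Path, geometry: PhantomGeometry | None = None) -> list[PatientModel]:
    payload = json.loads(Path(path).read_text())
    geometry = geometry or PhantomGeometry()
    out = []
    for item in payload:
        vp = item["variation_params"]
        out.append(
            PatientModel(
                patient_id=item["patient_id"],
                grid=GridSpec(tuple(item["grid"]["shape"]), tuple(item["grid"]["spacing"])),
                geometry=geometry,
                n_fractions=item["n_fractions"],
                systematic=tuple(vp["systematic_mm"]),
                random_sigma=vp["random_sigma_mm"],
                shrink_max=vp["shrink_max_mm"],
                drift=tuple(vp.get("drift_mm", (0.0, 0.0, 0.0))),
                cavity_prob=vp["cavity_prob"],
                seed=item["seed"],
            )
        )
    return out
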