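"""Resolution/planning profiles and YAML/JSON config loading.

Three built-in profiles trade spatial resolution against runtime:

``default``
    2 mm isotropic grid, 120 x 120 x 80 voxels; 5 mm spot spacing and
    5 mm-water energy-layer spacing.  Sub-voxel offsets of 1-3 mm are
    resolved by interpolation at this resolution.
``coarse``
    3 mm isotropic grid, 56 x 56 x 40 voxels; 6 mm spot / 6 mm layer
    spacing.  Used for cohort-scale simulation studies.
``tiny``
    4 mm grid, 40 x 40 x 30 voxels; 8 mm spot / 8 mm layer spacing.
    For quick smoke runs and unit tests only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

from .grid import GridSpec

__all__ = ["Profile", "PROFILES", "get_profile", "load_config", "dump_config"]


@dataclass(frozen=True)
class Profile:
    name: str
    grid: GridSpec
    spot_spacing: float       # mm, lateral spot grid pitch
    layer_spacing: float      # mm water, Bragg-peak depth pitch
    base_maxiter: int = 400   # cold-start optimizer iteration cap
    adapt_maxiter: int = 100  # warm-started daily adaptation cap


PROFILES: dict[str, Profile] = {
    "default": Profile("default", GridSpec((120, 120, 80), (2.0, 2.0, 2.0)), 5.0, 5.0),
    "coarse": Profile("coarse", GridSpec((56, 56, 40), (3.0, 3.0, 3.0)), 6.0, 6.0),
    "tiny": Profile("tiny", GridSpec((40, 40, 30), (4.0, 4.0, 4.0)), 8.0, 8.0),
}


def get_profile(name: str) -> Profile:
    try:
        return PROFILES[name]
    except KeyError:
        raise KeyError(
            f"unknown profile {name!r}; available: {sorted(PROFILES)}"
        ) from None


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON run configuration file into a plain dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def dump_config(config: dict, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(config, indent=2, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(config, sort_keys=True))


def profile_dict(profile: Profile) -> dict:
    d = asdict(profile)
    d["grid"] = {"shape": list(profile.grid.shape), "spacing": list(profile.grid.spacing)}
    return d
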