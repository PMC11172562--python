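"""Named study-condition presets, shipped as YAML data files.

Each preset bundles the cohort design (LFQCohortSpec), the per-cell ER
population (ERDistParams) and the imaging-field geometry (FieldSpec) for
one study condition: ``study`` (the default 9-fresh + 6-stored cohort),
``fresh-donor`` and ``stored-unit``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import yaml

from .errors import ParameterError
from .lfq import GENES
from .synthimage import ERDistParams, FieldSpec
from .synthlfq import LFQCohortSpec

__all__ = ["Preset", "default_presets", "load_preset", "PRESET_NAMES"]

PRESET_NAMES = ("study", "fresh-donor", "stored-unit")
DEFAULT_PRESET = "study"


@dataclass(frozen=True)
class Preset:
    name: str
    cohort: LFQCohortSpec
    er: ERDistParams
    field: FieldSpec

    def field_spec(self, *, seed: int = 0, **overrides) -> FieldSpec:
        """The imaging FieldSpec with this preset's ER distribution."""
        return replace(self.field, er_dist=self.er, seed=seed, **overrides)


def _cohort_from_mapping(raw: dict) -> LFQCohortSpec:
    mu = tuple(float(raw["mu"][g]) for g in GENES)
    sigma = tuple(float(raw["sigma"][g]) for g in GENES)
    aer_corr = tuple(float(raw["aer_corr"][g]) for g in GENES)
    corr = np.asarray(raw["subunit_corr"], dtype=float)
    return LFQCohortSpec(
        n_fresh=int(raw["n_fresh"]),
        n_stored=int(raw["n_stored"]),
        mu=mu,
        sigma=sigma,
        subunit_corr=tuple(tuple(row) for row in corr),
        aer_corr=aer_corr,
        aer_mean=float(raw["aer_mean"]),
        aer_sd=float(raw["aer_sd"]),
        stored_gamma_shift=float(raw["stored_gamma_shift"]),
        psd_repair=bool(raw.get("psd_repair", False)),
    )


def load_preset(name: str) -> Preset:
    """Load one named preset from its packaged YAML file."""
    if name not in PRESET_NAMES:
        raise ParameterError(f"unknown preset {name!r}; available: {PRESET_NAMES}")
    fname = name.replace("-", "_") + ".yaml"
    with resources.files("rbcdeform").joinpath("_data", fname).open() as fh:
        raw = yaml.safe_load(fh)
    er = ERDistParams(**{k: float(v) for k, v in raw["er"].items()})
    f = raw["field"]
    field = FieldSpec(
        width_px=int(f["width_px"]),
        height_px=int(f["height_px"]),
        n_cells=int(f["n_cells"]),
        er_dist=er,
        mean_cell_area_px=float(f["mean_cell_area_px"]),
        orientation_jitter_deg=float(f["orientation_jitter_deg"]),
        noise_sd=float(f["noise_sd"]),
        background_gradient=float(f["background_gradient"]),
        allow_touching=bool(f["allow_touching"]),
    )
    return Preset(name=raw["name"], cohort=_cohort_from_mapping(raw["cohort"]),
                  er=er, field=field)


def default_presets() -> dict[str, Preset]:
    """All named presets keyed by name."""
    return {name: load_preset(name) for name in PRESET_NAMES}
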