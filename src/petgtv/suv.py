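"""Body-weight standardized uptake value (SUV_bw) computation.

SUV_bw normalizes a tissue activity concentration by the injected dose per
body weight, assuming a tissue density of 1 g/mL:

    SUV(v) = C(v) [kBq/mL] * weight [g] / dose_at_scan [kBq]

where the injected dose is decay-corrected forward from injection time to
acquisition start using the isotope half-life. With those conventions a voxel
whose concentration equals the average whole-body concentration has SUV 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .volume import ImageVolume

__all__ = [
    "F18_HALF_LIFE_S",
    "C11_HALF_LIFE_S",
    "InjectionRecord",
    "SUVVolume",
    "compute_suv_bw",
]

F18_HALF_LIFE_S = 6586.2  # fluorine-18
C11_HALF_LIFE_S = 1221.8  # carbon-11


@dataclass
class InjectionRecord:
    """Tracer administration metadata needed for SUV_bw."""

    injected_dose_MBq: float
    body_weight_kg: float
    injection_time_s: float
    acquisition_time_s: float
    isotope_half_life_s: float

    def __post_init__(self) -> None:
        if self.injected_dose_MBq <= 0:
            raise ValueError("injected dose must be > 0")
        if self.body_weight_kg <= 0:
            raise ValueError("body weight must be > 0")
        if self.isotope_half_life_s <= 0:
            raise ValueError("half-life must be > 0")
        if self.acquisition_time_s < self.injection_time_s:
            raise ValueError("acquisition must not precede injection")

    @property
    def uptake_delay_s(self) -> float:
        return self.acquisition_time_s - self.injection_time_s

    @property
    def decay_corrected_dose_kBq(self) -> float:
        """Injected dose decayed to acquisition start, in kBq."""
        decay = 2.0 ** (-self.uptake_delay_s / self.isotope_half_life_s)
        return self.injected_dose_MBq * 1000.0 * decay

    @classmethod
    def from_json(cls, path: str) -> "InjectionRecord":
        """Read a JSON sidecar with the field names of this dataclass."""
        with open(path) as fh:
            payload = json.load(fh)
        return cls(**{k: payload[k] for k in (
            "injected_dose_MBq",
            "body_weight_kg",
            "injection_time_s",
            "acquisition_time_s",
            "isotope_half_life_s",
        )})


class SUVVolume(ImageVolume):
    """An :class:`ImageVolume` whose values are unitless SUV_bw."""


def compute_suv_bw(activity: ImageVolume, rec: InjectionRecord) -> SUVVolume:
    """Convert an activity-concentration volume (kBq/mL) to SUV_bw.

    Raises if any activity voxel is negative (a negative concentration is
    unphysical and would silently corrupt downstream thresholds).
    """
    data = np.asarray(activity.data, dtype=float)
    if np.any(data < 0):
        raise ValueError("activity volume contains negative voxels")
    weight_g = rec.body_weight_kg * 1000.0
    suv = data * weight_g / rec.decay_corrected_dose_kBq
    return SUVVolume(
        suv,
        activity.spacing_mm.copy(),
        activity.origin_mm.copy(),
        activity.direction.copy(),
    )
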