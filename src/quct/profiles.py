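"""Study profiles: matched phantom / acquisition / model configurations.

A profile fixes every scale-dependent setting of the pipeline so that the
phantom generator, the acoustic simulator and the network agree on shapes.

* ``full`` — the full-scale conditions: 32 transducers on a 64 mm ring
  (256 px at 0.25 mm), 153x153 ROI, 1000+1 time samples at 0.1 us,
  8 SoS classes.
* ``tiny``  — a desk-scale analogue used by the tests and the demo:
  8 transducers on a 15 mm ring, 27x27 ROI, 200+1 time samples,
  4 SoS classes.  Identical machinery, small shapes.
"""

from __future__ import annotations

from dataclasses import dataclass

from .acoustics import AcquisitionConfig, SensorArray, build_sensor_array
from .model import ModelConfig, full_config, tiny_config
from .phantoms import (DEFAULT_SCHEME, BrainPhantomSpec, DiscPhantomConfig,
                       QuantizationScheme)

__all__ = ["Profile", "get_profile", "TINY_SCHEME"]

#: 4-class scheme for the tiny profile: water plus three levels spanning the
#: same low/high-contrast range as the full grid.
TINY_SCHEME = QuantizationScheme(class_values=(1125.0, 1575.0, 2025.0))


@dataclass(frozen=True)
class Profile:
    name: str
    scheme: QuantizationScheme
    disc_config: DiscPhantomConfig
    brain_spec: BrainPhantomSpec
    acquisition: AcquisitionConfig
    array_size_mm: float
    n_sensors: int

    def sensor_array(self, geometry: str = "circle") -> SensorArray:
        return build_sensor_array(geometry, self.n_sensors, self.array_size_mm,
                                  self.acquisition)

    def model_config(self, variant: str = "large") -> ModelConfig:
        if self.name == "full":
            return full_config(variant)
        return tiny_config(variant, n_sensors=self.n_sensors,
                           in_time=self.acquisition.n_steps + 1,
                           out_hw=self.disc_config.size,
                           n_classes=self.scheme.n_classes)


def get_profile(name: str) -> Profile:
    if name == "full":
        return Profile(
            name="full",
            scheme=DEFAULT_SCHEME,
            disc_config=DiscPhantomConfig(),
            brain_spec=BrainPhantomSpec(),
            acquisition=AcquisitionConfig(),
            array_size_mm=64.0,
            n_sensors=32,
        )
    if name == "tiny":
        return Profile(
            name="tiny",
            scheme=TINY_SCHEME,
            disc_config=DiscPhantomConfig(
                size=27, roi_radius=11.0, n_discs_range=(1, 2),
                disc_radius_range=(3.0, 6.0), scheme=TINY_SCHEME),
            # thicker relative shells so every tissue layer spans >= 1 px
            brain_spec=BrainPhantomSpec(
                size=27, outer_radius=11.0,
                thickness=(0.10, 0.10, 0.12, 0.10, 0.14, 0.20)),
            acquisition=AcquisitionConfig(
                grid_extent=85, pml_px=10, n_steps=200),
            array_size_mm=15.0,
            n_sensors=8,
        )
    raise ValueError(f"unknown profile {name!r} (use 'tiny' or 'full')")
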