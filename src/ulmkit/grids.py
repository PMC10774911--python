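"""Coordinate grids for CEUS frames and super-resolved center maps.

Conventions used throughout the package:

* axis 0 is depth, axis 1 is lateral;
* positions are continuous, in microns, measured from the top-left image
  corner;
* pixel ``i`` covers the half-open interval ``[i * delta, (i + 1) * delta)``
  and its center sits at ``(i + 0.5) * delta``.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class GridSpec:
    """Resolution hierarchy of the imaging and localization grids.

    Parameters
    ----------
    wavelength_um:
        Ultrasound wavelength (lambda). 280 um for the 5.5 MHz clinical
        transducer the defaults emulate.
    native_pixel_um:
        Pixel pitch of the exported CEUS frames (60 um, lambda / 4.6).
    superres_factor:
        Integer upscaling of the localization output grid. The default 3
        gives a 20 um pitch, i.e. lambda / 14.
    synthesis_factor:
        Integer upscaling of the synthesis grid on which point scatterers
        are placed. The default 10 gives a 6 um pitch, comparable to the
        microbubble diameter.
    window:
        Interrogation-window side length in native pixels (80 -> 4.8 mm).
    frame_interval_s:
        Time between frames; 1/48 s matches the 48 fps acquisition rate.
    """

    wavelength_um: float = 280.0
    native_pixel_um: float = 60.0
    superres_factor: int = 3
    synthesis_factor: int = 10
    window: int = 80
    frame_interval_s: float = 1.0 / 48.0

    def __post_init__(self) -> None:
        if self.superres_factor < 1 or self.superres_factor != int(self.superres_factor):
            raise ValueError("superres_factor must be a positive integer")
        if self.synthesis_factor < 1 or self.synthesis_factor != int(self.synthesis_factor):
            raise ValueError("synthesis_factor must be a positive integer")
        if self.window < 1:
            raise ValueError("window must be positive")

    @property
    def superres_pixel_um(self) -> float:
        return self.native_pixel_um / self.superres_factor

    @property
    def synthesis_pixel_um(self) -> float:
        return self.native_pixel_um / self.synthesis_factor

    @property
    def window_um(self) -> float:
        """Window side length in microns."""
        return self.window * self.native_pixel_um

    @property
    def window_area_mm2(self) -> float:
        side_mm = self.window * self.native_pixel_um / 1000.0
        return side_mm * side_mm

    @property
    def superres_shape(self) -> tuple[int, int]:
        n = self.window * self.superres_factor
        return (n, n)

    @property
    def synthesis_shape(self) -> tuple[int, int]:
        n = self.window * self.synthesis_factor
        return (n, n)

    @property
    def fps(self) -> float:
        return 1.0 / self.frame_interval_s
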