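"""Screen model for the stimulation display.

All stimuli are defined on a monochromatic display whose pixels measure
7.5 x 7.5 um on the retina.  The display refreshes at 60 Hz but stimulus
frames are updated only every second refresh, i.e. at 30 Hz, so the basic
stimulus clock tick is ``frame_dt = 1/30 s`` (~33 ms).  Luminance is kept in
normalized units on [0, 1] with the mean (gray) level at 0.5; the physical
mean irradiance of the experiments this emulates (6.33 mW/m^2) is metadata
only and never enters any computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class ScreenModel:
    """Geometry and timing of the stimulation display.

    Parameters
    ----------
    pixel_pitch : float
        Size of one display pixel on the retina, in micrometers.
    refresh_rate : float
        Display refresh rate in Hz.
    update_rate : float
        Stimulus update rate in Hz; one stimulus frame per update.
    mean_level : float
        Background (gray) luminance in normalized units.
    luminance_range : tuple of float
        Minimum and maximum displayable luminance.
    """

    pixel_pitch: float = 7.5
    refresh_rate: float = 60.0
    update_rate: float = 30.0
    mean_level: float = 0.5
    luminance_range: tuple[float, float] = (0.0, 1.0)
    mean_irradiance_mw_m2: float = field(default=6.33, compare=False)

    def __post_init__(self) -> None:
        lo, hi = self.luminance_range
        if not lo <= self.mean_level <= hi:
            raise ValueError(
                f"mean_level {self.mean_level} outside luminance range {self.luminance_range}"
            )
        if self.update_rate <= 0 or self.pixel_pitch <= 0:
            raise ValueError("update_rate and pixel_pitch must be positive")

    @property
    def frame_dt(self) -> float:
        """Duration of one stimulus frame in seconds (1 / update_rate)."""
        return 1.0 / self.update_rate


#: Default screen shared by all generators.
DEFAULT_SCREEN = ScreenModel()
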