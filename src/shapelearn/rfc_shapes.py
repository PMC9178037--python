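"""Radial-frequency-component (RFC) shape space.

A shape is a closed contour whose radius is a sum of sinusoidal modulations
of polar angle ("radial frequency components").  A one-dimensional shape
continuum is built by co-varying the amplitudes of three of seven
components (1.11, 1.54 and 4.94 cycles/revolution); five equally spaced
shapes are drawn from that continuum.  A fourth component (3.18
cycles/revolution) is reserved for a small task "warp" that is orthogonal
to the shape dimension: it modulates a frequency disjoint from the three
that define the continuum.

Because several of the printed frequencies are non-integer, the radius
profile has a seam at angle 0 (r(2*pi) != r(0) in general); contours are
therefore sampled on the half-open interval [0, 2*pi) and closure is only
checked against a caller-supplied tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "RFCComponent",
    "ShapeSpace",
    "ShapeContour",
    "make_shape_space",
    "shape_amplitudes",
    "render_contour",
    "contour_to_text",
    "contour_to_svg_path",
]

#: frequencies (cycles per revolution) of the three components that define
#: the 1-D shape continuum, the warp component, and three fixed fillers.
VARIED_FREQUENCIES = (1.11, 1.54, 4.94)
WARP_FREQUENCY = 3.18
FIXED_FREQUENCIES = (2.12, 6.0, 9.09)

#: amplitude endpoints of the continuum for the three varied components.
AMPLITUDE_RANGES = ((0.0, 36.0), (0.0, 36.0), (15.58, 33.58))


@dataclass(frozen=True)
class RFCComponent:
    """One sinusoidal radius modulation: ``a * sin(f * theta + phi)``."""

    frequency: float  # cycles per revolution, > 0
    amplitude: float = 0.0  # unitless modulation depth, >= 0
    phase: float = 0.0  # radians

    def __post_init__(self) -> None:
        if not np.isfinite(self.frequency) or self.frequency <= 0:
            raise ValueError(f"frequency must be > 0, got {self.frequency}")
        if not np.isfinite(self.amplitude) or self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")


@dataclass(frozen=True)
class ShapeSpace:
    """The RFC-parameterised 1-D shape continuum.

    ``components`` holds the seven component templates; the amplitudes of
    the components at ``varied_indices`` are replaced per shape by linear
    interpolation between ``amplitude_ranges`` endpoints.  ``scale``
    converts the raw printed amplitude units into radius units so that
    radii stay positive with base radius 1.
    """

    components: tuple[RFCComponent, ...]
    varied_indices: tuple[int, int, int]
    amplitude_ranges: tuple[tuple[float, float], ...]
    n_shapes: int = 5
    warp_index: int = 3
    base_radius: float = 1.0
    scale: float = 0.01

    def __post_init__(self) -> None:
        if self.n_shapes < 2:
            raise ValueError("n_shapes must be >= 2")
        if len(self.components) != 7:
            raise ValueError("shape space uses exactly 7 RFC components")
        if len(self.varied_indices) != len(self.amplitude_ranges):
            raise ValueError("one amplitude range per varied component")
        if self.warp_index in self.varied_indices:
            raise ValueError("warp component must not be a varied component")
        for lo, hi in self.amplitude_ranges:
            if not (np.isfinite(lo) and np.isfinite(hi)):
                raise ValueError("amplitude range endpoints must be finite")
            if hi < lo:
                raise ValueError(f"reversed amplitude range ({lo}, {hi})")

    @property
    def warp_frequency(self) -> float:
        return self.components[self.warp_index].frequency


@dataclass(frozen=True)
class ShapeContour:
    """A sampled contour: radius as a function of polar angle."""

    angles: np.ndarray  # radians, uniform on [0, 2*pi)
    radii: np.ndarray  # unitless, all > 0

    def __post_init__(self) -> None:
        if self.angles.shape != self.radii.shape:
            raise ValueError("angles and radii must have equal length")
        if np.any(self.radii <= 0):
            raise ValueError("contour radii must be positive")

    def closes(self, tol: float = 1e-6) -> bool:
        """Whether the periodic extension is continuous at angle 0."""
        gap = abs(float(self.radii[0]) - float(self.radii[-1]))
        step = float(self.angles[1] - self.angles[0])
        # compare the wrap-around jump against the typical sample-to-sample
        # variation plus the absolute tolerance
        typical = float(np.median(np.abs(np.diff(self.radii)))) if len(self.radii) > 2 else 0.0
        return gap <= tol + 3.0 * typical


def make_shape_space(
    varied_frequencies: Sequence[float] = VARIED_FREQUENCIES,
    amplitude_ranges: Sequence[tuple[float, float]] = AMPLITUDE_RANGES,
    warp_frequency: float = WARP_FREQUENCY,
    fixed_frequencies: Sequence[float] = FIXED_FREQUENCIES,
    fixed_amplitudes: Sequence[float] | None = None,
    phases: Sequence[float] | None = None,
    n_shapes: int = 5,
    base_radius: float = 1.0,
    scale: float = 0.01,
) -> ShapeSpace:
    """Build the seven-component shape space.

    Component order: the three varied components, then the warp component,
    then the three fixed components.  Shape ``i`` (1-based) has its varied
    amplitudes linearly interpolated between the range endpoints, so shape 1
    sits at the low endpoints and shape ``n_shapes`` at the high endpoints.
    """
    if len(varied_frequencies) != 3 or len(amplitude_ranges) != 3:
        raise ValueError("exactly 3 varied components are expected")
    if fixed_amplitudes is None:
        fixed_amplitudes = (0.0,) * len(fixed_frequencies)
    n_total = len(varied_frequencies) + 1 + len(fixed_frequencies)
    if phases is None:
        phases = (0.0,) * n_total
    freqs = [*varied_frequencies, warp_frequency, *fixed_frequencies]
    amps = [0.0, 0.0, 0.0, 0.0, *fixed_amplitudes]
    components = tuple(
        RFCComponent(frequency=f, amplitude=a, phase=p)
        for f, a, p in zip(freqs, amps, phases)
    )
    return ShapeSpace(
        components=components,
        varied_indices=(0, 1, 2),
        amplitude_ranges=tuple((float(lo), float(hi)) for lo, hi in amplitude_ranges),
        n_shapes=n_shapes,
        warp_index=3,
        base_radius=base_radius,
        scale=scale,
    )


def shape_amplitudes(space: ShapeSpace, shape_index: int) -> np.ndarray:
    """Amplitudes of the varied components for 1-based ``shape_index``."""
    if not 1 <= shape_index <= space.n_shapes:
        raise ValueError(
            f"shape_index must be in 1..{space.n_shapes}, got {shape_index}"
        )
    frac = (shape_index - 1) / (space.n_shapes - 1)
    return np.array([lo + frac * (hi - lo) for lo, hi in space.amplitude_ranges])


def _component_amplitudes(space: ShapeSpace, shape_index: int, warp: float) -> np.ndarray:
    amps = np.array([c.amplitude for c in space.components], dtype=float)
    amps[list(space.varied_indices)] = shape_amplitudes(space, shape_index)
    amps[space.warp_index] = space.components[space.warp_index].amplitude + warp
    return amps


def render_contour(
    space: ShapeSpace,
    shape_index: int,
    warp: float = 0.0,
    n_samples: int = 360,
) -> ShapeContour:
    """Sample the radius profile of one shape.

    ``warp`` is a signed amplitude (raw units, like the printed ranges)
    added to the 3.18 cycles/revolution component only; it implements the
    same/different task modulation and leaves the shape-continuum
    components untouched.
    """
    if n_samples < 64:
        raise ValueError("n_samples must be >= 64")
    amps = _component_amplitudes(space, shape_index, warp)
    theta = np.linspace(0.0, 2.0 * np.pi, n_samples, endpoint=False)
    radii = np.full(n_samples, 1.0)
    for comp, amp in zip(space.components, amps):
        radii += amp * space.scale * np.sin(comp.frequency * theta + comp.phase)
    radii *= space.base_radius
    if np.any(radii <= 0):
        raise ValueError(
            "non-positive radius: warp/amplitude too large for this scale"
        )
    return ShapeContour(angles=theta, radii=radii)


def contour_to_text(contour: ShapeContour) -> str:
    """Two-column plain text (angle, radius), one sample per line."""
    lines = ["# angle_rad\tradius"]
    for a, r in zip(contour.angles, contour.radii):
        lines.append(f"{a:.8f}\t{r:.8f}")
    return "\n".join(lines) + "\n"


def contour_to_svg_path(contour: ShapeContour, size: float = 100.0) -> str:
    """Closed SVG path centred in a ``size`` x ``size`` viewbox."""
    r = contour.radii / contour.radii.max() * (size * 0.45)
    x = size / 2 + r * np.cos(contour.angles)
    y = size / 2 - r * np.sin(contour.angles)
    parts = [f"M {x[0]:.2f} {y[0]:.2f}"]
    parts += [f"L {xi:.2f} {yi:.2f}" for xi, yi in zip(x[1:], y[1:])]
    return " ".join(parts) + " Z"
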