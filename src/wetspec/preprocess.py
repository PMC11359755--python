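"""Savitzky-Golay derivative filtering for absorbance spectra.

The filter fits a least-squares polynomial of degree ``polyorder`` to a
sliding window of ``window`` points and evaluates its ``deriv``-th
derivative at the window's evaluation point.  Unlike most off-the-shelf
implementations, even window lengths are supported: the evaluation point
is taken at index ``floor(window/2)`` (the later of the two central
points), which keeps the output on the sampling grid.  A convenience
switch promotes even windows to the next odd length for users who prefer
the symmetric convention.

Derivatives are returned per nm (the convolution output is divided by
``step_nm**deriv``) so that loading spectra are comparable across
instruments with different native steps.  Boundary points are handled by
refitting the polynomial to the nearest full window rather than by
padding, which avoids reflection artefacts at the range edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np

from .spectra import GRID_TOL_NM, SpectraSet

__all__ = ["SGParams", "sg_coefficients", "apply_sg"]


@dataclass(frozen=True)
class SGParams:
    window: int = 4
    polyorder: int = 3
    deriv: int = 1
    edge_mode: str = "polyfit_extend"
    promote_even_window: bool = False

    def __post_init__(self) -> None:
        if self.window < 2:
            raise ValueError("window must be >= 2")
        if self.polyorder < 0 or self.deriv < 0:
            raise ValueError("polyorder and deriv must be >= 0")
        if self.polyorder >= self.window:
            raise ValueError("polyorder must be < window")
        if self.deriv > self.polyorder:
            raise ValueError("deriv must be <= polyorder")
        if self.edge_mode != "polyfit_extend":
            raise ValueError(f"unknown edge_mode {self.edge_mode!r}")

    @property
    def effective_window(self) -> int:
        if self.promote_even_window and self.window % 2 == 0:
            return self.window + 1
        return self.window


def sg_coefficients(p: SGParams, step_nm: float) -> np.ndarray:
    """Convolution weights for the window, scaled to a per-nm derivative.

    The weights ``w`` satisfy ``sum_j w[j] * f(x[i - c + j])`` = deriv-th
    derivative at point ``i`` of the least-squares polynomial fit, where
    ``c = floor(window/2)`` is the evaluation index within the window.
    """
    if step_nm <= 0:
        raise ValueError("step_nm must be > 0")
    window = p.effective_window
    c = window // 2
    offsets = (np.arange(window) - c) * step_nm
    # design matrix of the polynomial fit in local coordinates
    M = np.vander(offsets, p.polyorder + 1, increasing=True)
    # row `deriv` of pinv(M) gives the coefficient of x^deriv as a linear
    # functional of the data; times deriv! it is the derivative at x = 0
    weights = factorial(p.deriv) * np.linalg.pinv(M)[p.deriv]
    return weights


def _edge_derivative(x: np.ndarray, y: np.ndarray, x0: float, p: SGParams) -> float:
    """Derivative at x0 of the polynomial least-squares fitted to (x, y)."""
    M = np.vander(x - x0, p.polyorder + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(M, y, rcond=None)
    return factorial(p.deriv) * coef[p.deriv]


def apply_sg(s: SpectraSet, p: SGParams) -> SpectraSet:
    """Apply the filter to every spectrum; output length equals input length.

    Requires a uniform wavelength grid (resample first) and absorbance
    input when deriv >= 1 produces a 'derivative' domain set.
    """
    steps = np.diff(s.wavelengths_nm)
    step = steps[0]
    if np.any(np.abs(steps - step) > GRID_TOL_NM):
        raise ValueError(
            "non-uniform wavelength grid; resample_to_grid before apply_sg"
        )
    if s.domain_kind != "absorbance":
        raise ValueError(f"expected absorbance domain, got {s.domain_kind!r}")
    window = p.effective_window
    n = s.wavelengths_nm.size
    if window > n:
        raise ValueError("window longer than spectrum")
    c = window // 2
    w = sg_coefficients(p, step)
    # interior: sliding windows times the weight vector
    sw = np.lib.stride_tricks.sliding_window_view(s.values, window, axis=1)
    interior = sw @ w  # (n_spectra, n - window + 1)
    out = np.empty_like(s.values)
    # interior output index i uses points [i - c, i - c + window); valid
    # for c <= i <= n - window + c
    out[:, c : n - window + 1 + c] = interior
    x = s.wavelengths_nm
    for i in range(c):  # leading edge: fit to the first full window
        for r in range(s.values.shape[0]):
            out[r, i] = _edge_derivative(x[:window], s.values[r, :window], x[i], p)
    for i in range(n - window + 1 + c, n):  # trailing edge: last full window
        for r in range(s.values.shape[0]):
            out[r, i] = _edge_derivative(x[-window:], s.values[r, -window:], x[i], p)
    kind = "derivative" if p.deriv >= 1 else "absorbance"
    return s.with_values(
        out,
        domain_kind=kind,
        note=f"apply_sg(window={p.window}, polyorder={p.polyorder}, deriv={p.deriv})",
    )
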