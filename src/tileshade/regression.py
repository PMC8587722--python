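"""Polynomial intensity-transfer regression over match tables.

A match table is only observed at the intensities actually present in the
source stripe; the interior of a tile can contain any level, so the transfer
must be interpolated and extrapolated.  Assuming the illumination distortion
has one smooth characteristic across the intensity range, an ordinary
least-squares polynomial (second order by default — the distortions are
near-linear with a mild exponential-like bend) fitted to the supported
(i, hm(i)) pairs provides that extension.

Numerically the fit scales intensities to [0, 1] before solving (the raw
Vandermonde basis over [0, 255] is badly conditioned) and maps the
coefficients back, so ``coeffs`` are always in raw intensity units:
``pr(i) = b0 + b1*i + b2*i**2 + ...``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .histograms import MatchTable

DEFAULT_DEGREE = 2


@dataclass
class RegressionModel:
    """Fitted intensity-transfer polynomial for one patch.

    ``kind`` records degenerate-support fallbacks:

    - ``"poly"``: a determinate least-squares fit of the requested (or reduced)
      degree;
    - ``"shift"``: one supported intensity — a constant additive shift
      ``pr(i) = i + delta``;
    - ``"identity"``: empty support — ``pr(i) = i``.
    """

    coeffs: np.ndarray  # (degree+1,) raw-basis b0..bm; for shift/identity encodes (b0, 1)
    kind: str = "poly"
    support_x: np.ndarray = field(default_factory=lambda: np.empty(0))
    support_y: np.ndarray = field(default_factory=lambda: np.empty(0))
    residual: float = 0.0

    def __post_init__(self) -> None:
        self.coeffs = np.atleast_1d(np.asarray(self.coeffs, dtype=np.float64))

    @property
    def degree(self) -> int:
        return len(self.coeffs) - 1

    @classmethod
    def identity(cls) -> "RegressionModel":
        return cls(np.array([0.0, 1.0]), kind="identity")

    def __call__(self, i: np.ndarray | float) -> np.ndarray | float:
        return evaluate_regression(self, i)


def fit_patch_regression(
    table: MatchTable,
    degree: int = DEFAULT_DEGREE,
    weighted: bool = False,
    pixel_counts: np.ndarray | None = None,
) -> RegressionModel:
    """Least-squares polynomial fit of a match table over its supported intensities.

    Each supported intensity contributes one (i, hm(i)) point regardless of
    how many pixels carry it; pass ``weighted=True`` with ``pixel_counts`` to
    weight points by pixel count instead.  If the support holds fewer than
    ``degree + 1`` points the degree is reduced (2 -> 1 -> 0); zero support
    yields the identity model.  Never raises for thin support — background-only
    patches must not break the pipeline.
    """
    if degree < 1:
        raise ValueError(f"degree must be >= 1, got {degree}")
    mask = table.fit_support if table.fit_support is not None else table.support
    if not mask.any():  # every match is a smoothing artifact: fall back to raw support
        mask = table.support
    x = np.flatnonzero(mask).astype(np.float64)
    y = table.values[mask].astype(np.float64)
    n_pts = len(np.unique(x))
    if n_pts == 0:
        return RegressionModel.identity()
    if n_pts == 1:
        delta = float(np.mean(y - x))
        return RegressionModel(np.array([delta, 1.0]), kind="shift",
                               support_x=x, support_y=y)
    deg = min(degree, n_pts - 1)
    scale = max(table.n_levels - 1, 1)
    xs = x / scale
    w = None
    if weighted:
        if pixel_counts is None:
            raise ValueError("weighted fit requires pixel_counts")
        w = np.sqrt(pixel_counts[mask].astype(np.float64))
    # numpy's polyfit solves the scaled Vandermonde system by SVD-backed lstsq
    c_scaled = np.polynomial.polynomial.polyfit(xs, y, deg, w=w)
    powers = np.arange(deg + 1)
    coeffs = c_scaled / scale ** powers.astype(np.float64)
    resid = float(np.sum((np.polynomial.polynomial.polyval(xs, c_scaled) - y) ** 2))
    return RegressionModel(coeffs, kind="poly", support_x=x, support_y=y, residual=resid)


def evaluate_regression(model: RegressionModel, i: np.ndarray | float) -> np.ndarray | float:
    """Evaluate ``pr(i)`` — unclamped; clamping happens at final application.

    Defined for every intensity, including extrapolation outside the fit
    support.
    """
    return np.polynomial.polynomial.polyval(np.asarray(i, dtype=np.float64), model.coeffs)
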