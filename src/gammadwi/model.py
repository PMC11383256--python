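"""Closed-form mathematics of the gamma diffusion model.

The model assumes the water diffusion coefficient ``D`` inside a voxel (or
ROI) is not a single number but a gamma-distributed random variable with
shape ``kappa`` and scale ``theta`` (mm^2/s).  The measured DWI signal at
diffusion weighting ``b`` is then the Laplace transform of that density,

    S(b) = S0 * (1 + theta*b)**(-kappa),

and area fractions of the density below/between clinically chosen
diffusion thresholds quantify how much of the voxel behaves like
intracellular water (slow), extracellular water (intermediate) or
perfusing blood (fast).

Everything here is pure math on typed records: no file I/O, no fitting.
All diffusivities are stored in SI mm^2/s; the conventional display unit
for ``theta`` in the brain-tumor literature is 1e-4 mm^2/s and conversion
helpers are provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special

__all__ = [
    "THETA_DISPLAY_UNIT",
    "GammaParams",
    "DiffusionThresholds",
    "FractionSet",
    "gamma_pdf",
    "signal_model",
    "fraction_between",
    "staging_fractions",
    "grading_fractions",
]

#: mm^2/s per display unit; Table-style reports print theta in units of
#: 1e-4 mm^2/s (so a printed 74.55 means 74.55e-4 mm^2/s).
THETA_DISPLAY_UNIT = 1e-4


@dataclass(frozen=True)
class GammaParams:
    """Shape/scale parameters of the diffusion-coefficient distribution.

    Parameters
    ----------
    kappa : float
        Dimensionless shape parameter, > 0.  Small values (<< 1) pile
        probability mass near D = 0, i.e. heavily restricted diffusion.
    theta : float
        Scale parameter in mm^2/s, > 0.  ``kappa * theta`` is the mean
        diffusivity of the distribution.
    """

    kappa: float
    theta: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.kappa) and self.kappa > 0):
            raise ValueError(f"kappa must be finite and > 0, got {self.kappa}")
        if not (np.isfinite(self.theta) and self.theta > 0):
            raise ValueError(f"theta must be finite and > 0, got {self.theta}")

    @property
    def mean_diffusivity(self) -> float:
        """Mean of the diffusion-coefficient distribution, mm^2/s."""
        return self.kappa * self.theta

    @property
    def theta_display(self) -> float:
        """theta expressed in the conventional 1e-4 mm^2/s display unit."""
        return self.theta / THETA_DISPLAY_UNIT

    @classmethod
    def from_display(cls, kappa: float, theta_display: float) -> "GammaParams":
        """Build from a theta given in 1e-4 mm^2/s display units."""
        return cls(kappa=kappa, theta=theta_display * THETA_DISPLAY_UNIT)


@dataclass(frozen=True)
class DiffusionThresholds:
    """Diffusion-coefficient cut points for the area fractions (mm^2/s).

    ``staging_low``/``staging_high`` split the density into the staging
    fractions f1/f2/f3 (intracellular / extracellular / perfusion);
    ``grading`` is the ordered triple of heavily-restricted-diffusion cuts
    defining the grading fractions f11/f12/f13.
    """

    staging_low: float = 1e-4
    staging_high: float = 3e-4
    grading: tuple[float, float, float] = (0.3e-4, 0.5e-4, 0.8e-4)

    def __post_init__(self) -> None:
        g = tuple(float(x) for x in self.grading)
        object.__setattr__(self, "grading", g)
        if len(g) != 3:
            raise ValueError("grading must be a triple of thresholds")
        ok = 0 < g[0] < g[1] < g[2] <= self.staging_low < self.staging_high
        if not ok:
            raise ValueError(
                "thresholds must satisfy 0 < grading[0] < grading[1] < "
                f"grading[2] <= staging_low < staging_high; got {self}"
            )


@dataclass(frozen=True)
class FractionSet:
    """Area fractions of the diffusion-coefficient density, each in [0, 1].

    f1/f2/f3 partition the density at the staging thresholds and sum to 1;
    f11/f12/f13 are cumulative fractions below the three grading thresholds
    and are nondecreasing, each bounded above by f1.  Reports conventionally
    print them as percentages (``as_percent``).
    """

    f1: float
    f2: float
    f3: float
    f11: float
    f12: float
    f13: float

    def __post_init__(self) -> None:
        vals = (self.f1, self.f2, self.f3, self.f11, self.f12, self.f13)
        if any(not (-1e-12 <= v <= 1 + 1e-12) for v in vals):
            raise ValueError(f"fractions must lie in [0, 1], got {vals}")
        if abs(self.f1 + self.f2 + self.f3 - 1.0) > 1e-12:
            raise ValueError(
                f"staging fractions must sum to 1, got {self.f1 + self.f2 + self.f3!r}"
            )
        if not (self.f11 <= self.f12 + 1e-12 and self.f12 <= self.f13 + 1e-12
                and self.f13 <= self.f1 + 1e-12):
            raise ValueError("grading fractions must satisfy f11 <= f12 <= f13 <= f1")

    def as_percent(self) -> dict[str, float]:
        """All six fractions scaled to percent, keyed by name."""
        return {
            name: 100.0 * getattr(self, name)
            for name in ("f1", "f2", "f3", "f11", "f12", "f13")
        }


def gamma_pdf(d, params: GammaParams):
    """Probability density of the diffusion coefficient at ``d`` (mm^2/s).

    P(D=d) = d**(kappa-1) * exp(-d/theta) / (Gamma(kappa) * theta**kappa),
    evaluated in log space to stay finite for the very small shape
    parameters (kappa ~ 0.05) typical of tumor tissue, where the density
    is integrable but singular at d = 0.

    Accepts scalars or arrays; d < 0 raises ``ValueError``.  At d = 0 the
    density is +inf for kappa < 1, 1/theta for kappa = 1 and 0 for
    kappa > 1.
    """
    d_arr = np.asarray(d, dtype=float)
    if np.any(d_arr < 0):
        raise ValueError("diffusion coefficient d must be >= 0")
    k, t = params.kappa, params.theta
    with np.errstate(divide="ignore", invalid="ignore"):
        log_pdf = (
            (k - 1.0) * np.log(d_arr)
            - d_arr / t
            - special.gammaln(k)
            - k * math.log(t)
        )
        out = np.exp(log_pdf)
    if k == 1.0:
        out = np.where(d_arr == 0.0, 1.0 / t, out)
    elif k > 1.0:
        out = np.where(d_arr == 0.0, 0.0, out)
    else:
        out = np.where(d_arr == 0.0, np.inf, out)
    return out if out.ndim else float(out)


def signal_model(b, s0: float, params: GammaParams):
    """Predicted DWI signal S(b) = s0 * (1 + theta*b)**(-kappa).

    This is s0 times the Laplace transform of :func:`gamma_pdf` evaluated
    at b, i.e. the signal of a voxel whose diffusion coefficients are
    gamma-distributed.  ``b`` is in s/mm^2 and may be a scalar or array;
    the result has the units of ``s0``.
    """
    if s0 <= 0:
        raise ValueError(f"s0 must be > 0, got {s0}")
    b_arr = np.asarray(b, dtype=float)
    if np.any(b_arr < 0):
        raise ValueError("b must be >= 0")
    out = s0 * np.exp(-params.kappa * np.log1p(params.theta * b_arr))
    return out if out.ndim else float(out)


def fraction_between(params: GammaParams, lo: float, hi: float) -> float:
    """Probability that the diffusion coefficient lies in [lo, hi].

    Computed through the regularized lower incomplete gamma function
    P(kappa, x/theta) rather than quadrature: for kappa << 1 the density
    is singular at 0 and direct numerical integration is fragile.  ``hi``
    may be ``math.inf`` for an unbounded upper limit.
    """
    if not (0 <= lo < hi):
        raise ValueError(f"require 0 <= lo < hi, got lo={lo}, hi={hi}")
    k, t = params.kappa, params.theta
    upper = 1.0 if math.isinf(hi) else float(special.gammainc(k, hi / t))
    lower = float(special.gammainc(k, lo / t))
    return min(max(upper - lower, 0.0), 1.0)


def _cdf(params: GammaParams, x: float) -> float:
    return float(special.gammainc(params.kappa, x / params.theta))


def staging_fractions(
    params: GammaParams, thresholds: DiffusionThresholds | None = None
) -> FractionSet:
    """Staging and grading fractions of the density at the given cuts.

    f1 is the mass below ``staging_low`` (intracellular, restricted
    diffusion), f2 between the staging cuts (extracellular), and f3 above
    ``staging_high`` (perfusion); f3 is computed as 1 - CDF(staging_high)
    so the three always sum to exactly 1.  The grading fractions come
    along for free and are filled in as well.
    """
    thresholds = thresholds or DiffusionThresholds()
    f1 = _cdf(params, thresholds.staging_low)
    c_high = _cdf(params, thresholds.staging_high)
    f2 = max(c_high - f1, 0.0)
    f3 = max(1.0 - c_high, 0.0)
    # guard the exact-sum invariant against rounding in the subtraction
    f2 = 1.0 - f1 - f3
    g = [_cdf(params, t) for t in thresholds.grading]
    return FractionSet(f1=f1, f2=f2, f3=f3, f11=g[0], f12=g[1], f13=g[2])


def grading_fractions(
    params: GammaParams, thresholds: DiffusionThresholds | None = None
) -> FractionSet:
    """Fractions below the three heavily-restricted-diffusion cuts.

    Same complete :class:`FractionSet` as :func:`staging_fractions`; the
    two entry points exist because staging (benign vs malignant) and
    grading (low vs high grade) workflows read different fields.
    """
    return staging_fractions(params, thresholds)
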