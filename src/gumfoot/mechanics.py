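"""True stress-true strain mechanics of suspended glue droplets.

A gumfoot glue droplet sits at the midpoint of a horizontal support line
(one or more major-ampullate fibers spanning 4800 um between supports).
Pulling the droplet perpendicular to the line deflects each 2400 um side by
an angle ``theta``; the Hookean stretch of the fibers supplies the force on
the adhesive filament that forms between the support line and the probe.
From per-interval droplet lengths and deflection angles we build a true
stress-true strain curve for the adhesive core and derive its elastic
(Young's) modulus and toughness.

Units contract: lengths in um, areas in um^2, volumes in um^3, forces in uN,
stresses and moduli in MPa (1 MPa * 1 um^2 = 1 uN), toughness in MJ/m^3
(numerically MPa times dimensionless true strain). Angles are degrees at
every public interface and radians internally.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.diagnostic import normal_ad

__all__ = [
    "DropletGeometry",
    "SupportLine",
    "ExtensionSeries",
    "StressStrainCurve",
    "MaterialProperties",
    "GroupComparison",
    "droplet_volume",
    "droplet_thickness",
    "core_volume",
    "droplet_geometry",
    "initial_filament_length",
    "support_line_strain",
    "deflection_from_strain",
    "support_line_elongation",
    "percent_elongation",
    "droplet_force",
    "filament_csa",
    "true_stress",
    "true_strain",
    "build_stress_strain_curve",
    "elastic_modulus",
    "elastic_modulus_wls",
    "toughness",
    "modulus_sensitivity",
    "extension_per_volume",
    "area_per_volume",
    "compare_groups",
    "MODULUS_WINDOWS",
]

Convention = Literal["radius", "diameter"]

#: Default modulus-fit windows (fractions of time to pull-off) per species.
#: The linear portion of the stress-strain curve sits late in extension:
#: 60-80% for Latrodectus hesperus, 80-100% for Parasteatoda tepidariorum.
MODULUS_WINDOWS: dict[str, tuple[float, float]] = {
    "L_hesperus": (0.6, 0.8),
    "P_tepidariorum": (0.8, 1.0),
}


class DegenerateCurveError(ValueError):
    """Raised when a stress-strain fit window has no strain increment."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DropletGeometry:
    """Suspended and flattened geometry of one glue droplet.

    ``DL`` is the suspended droplet length (axis parallel to the support
    line) and ``DW`` its width, both in um.  ``DV`` is the parabolic-arc
    droplet volume, ``thickness`` the flattened-droplet thickness and
    ``core_volume`` the adhesive-core volume (flattened core area times
    thickness), all derived on construction via :func:`droplet_geometry`.
    """

    DL: float
    DW: float
    DV: float
    flattened_droplet_area: float
    flattened_core_area: float
    thickness: float
    core_volume: float

    def __post_init__(self) -> None:
        if self.DL <= 0 or self.DW <= 0:
            raise ValueError("droplet length and width must be positive")
        if self.flattened_core_area > self.flattened_droplet_area * (1 + 1e-9):
            raise ValueError("flattened core area exceeds flattened droplet area")


@dataclass(frozen=True)
class SupportLine:
    """The fiber bundle suspending a droplet between two fixed supports."""

    fiber_count: int
    fiber_diameter: float  # um
    fiber_modulus: float  # MPa
    span: float = 4800.0  # um

    def __post_init__(self) -> None:
        if self.fiber_count < 1:
            raise ValueError("support line needs at least one fiber")
        if self.fiber_diameter <= 0 or self.fiber_modulus <= 0 or self.span <= 0:
            raise ValueError("fiber diameter, modulus and span must be positive")

    @property
    def half_span(self) -> float:
        return self.span / 2.0

    @property
    def fiber_csa(self) -> float:
        """Combined fiber cross-section, um^2."""
        return self.fiber_count * math.pi * self.fiber_diameter**2 / 4.0


@dataclass(frozen=True)
class ExtensionSeries:
    """Per-interval measurements for one droplet extension trial.

    ``fractions`` are fractions of the elapsed time between initiation of
    extension and pull-off (0, 0.2, ..., 1.0 in the standard protocol);
    ``lengths`` are droplet lengths (um) and ``angles`` support-line
    deflection angles (degrees) measured at those instants.
    """

    fractions: tuple[float, ...]
    lengths: tuple[float, ...]
    angles: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.fractions) == len(self.lengths) == len(self.angles)):
            raise ValueError("fractions, lengths and angles must align")
        if len(self.fractions) < 2:
            raise ValueError("an extension series needs at least two intervals")
        if any(b <= a for a, b in zip(self.fractions, self.fractions[1:])):
            raise ValueError("interval fractions must be strictly increasing")
        for i, th in enumerate(self.angles):
            if i == 0 and math.isnan(th):
                continue  # interval-0 angle may be unrecorded
            if not (0.0 <= th < 90.0):
                raise ValueError("deflection angles must lie in [0, 90) degrees")


@dataclass(frozen=True)
class StressStrainCurve:
    """Paired true strain / true stress points for one trial.

    The first point is the zero-strain anchor at the initial filament
    length. Measured strains must be non-decreasing among themselves;
    under the diameter length convention early measured lengths can sit
    below the initial length (strain dips below the anchor), which is
    allowed.
    """

    fractions: tuple[float, ...]
    strain: tuple[float, ...]
    stress: tuple[float, ...]  # MPa
    initial_stress: float  # MPa, sigma_0
    convention: Convention = "radius"

    def __post_init__(self) -> None:
        measured = self.strain[1:]
        if any(b < a for a, b in zip(measured, measured[1:])):
            raise ValueError("measured true strains must be non-decreasing")
        if self.strain and self.strain[0] != 0.0:
            raise ValueError("first point must be at zero strain")


@dataclass(frozen=True)
class MaterialProperties:
    elastic_modulus: float  # MPa
    toughness: float  # MJ/m^3
    modulus_window: tuple[float, float] = (0.6, 0.8)


@dataclass(frozen=True)
class GroupComparison:
    """Outcome of the normality-gated two-group comparison."""

    branch: Literal["t", "wilcoxon"]
    statistic: float
    pvalue: float
    ad_pvalues: tuple[float, float]


# ---------------------------------------------------------------------------
# droplet geometry
# ---------------------------------------------------------------------------


def droplet_volume(DL: float, DW: float) -> float:
    """Volume of a suspended droplet, ``DV = 2*pi*DW^2*DL/15`` (um^3).

    The droplet profile is modeled as a parabolic arc rotated about the
    support line, which yields the 2*pi/15 prefactor.
    """
    if DL <= 0 or DW <= 0:
        raise ValueError("DL and DW must be positive")
    return 2.0 * math.pi * DW**2 * DL / 15.0


def droplet_thickness(DV: float, flattened_droplet_area: float) -> float:
    """Flattened-droplet thickness: droplet volume over flattened area (um)."""
    if flattened_droplet_area <= 0:
        raise ValueError("flattened droplet area must be positive")
    if DV < 0:
        raise ValueError("droplet volume must be non-negative")
    return DV / flattened_droplet_area


def core_volume(flattened_core_area: float, thickness: float) -> float:
    """Adhesive core volume: flattened core area times thickness (um^3)."""
    if flattened_core_area < 0 or thickness < 0:
        raise ValueError("area and thickness must be non-negative")
    return flattened_core_area * thickness


def droplet_geometry(
    DL: float,
    DW: float,
    flattened_droplet_area: float,
    flattened_core_area: float,
) -> DropletGeometry:
    """Assemble a :class:`DropletGeometry`, deriving DV, thickness and V_c."""
    DV = droplet_volume(DL, DW)
    t = droplet_thickness(DV, flattened_droplet_area)
    vc = core_volume(flattened_core_area, t)
    return DropletGeometry(
        DL=DL,
        DW=DW,
        DV=DV,
        flattened_droplet_area=flattened_droplet_area,
        flattened_core_area=flattened_core_area,
        thickness=t,
        core_volume=vc,
    )


def initial_filament_length(V_c: float, convention: Convention = "radius") -> float:
    """Initial adhesive filament length: sphere radius (or diameter) of V_c.

    The adhesive core, configured as a sphere of volume ``V_c``, has radius
    ``(3 V_c / 4 pi)^(1/3)``.  Gumfoot droplets are core-rich, so extension
    begins when the support-line/probe gap is about one core radius; the
    orb-web convention uses the diameter instead.
    """
    if V_c <= 0:
        raise ValueError("core volume must be positive")
    r = (3.0 * V_c / (4.0 * math.pi)) ** (1.0 / 3.0)
    if convention == "radius":
        return r
    if convention == "diameter":
        return 2.0 * r
    raise ValueError(f"unknown length convention: {convention!r}")


# ---------------------------------------------------------------------------
# support-line force resolution
# ---------------------------------------------------------------------------


def support_line_strain(theta_deg: float) -> float:
    """Engineering strain of one side of a deflected support line.

    A side of initial length L0 deflected by ``theta`` spans L0/cos(theta),
    so its strain is ``sec(theta) - 1``.
    """
    if not (0.0 <= theta_deg < 90.0):
        raise ValueError("deflection angle must lie in [0, 90) degrees")
    return 1.0 / math.cos(math.radians(theta_deg)) - 1.0


def deflection_from_strain(strain: float) -> float:
    """Inverse of :func:`support_line_strain`: degrees for a side strain."""
    if strain < 0:
        raise ValueError("strain must be non-negative")
    return math.degrees(math.acos(1.0 / (1.0 + strain)))


def support_line_elongation(theta_deg: float, half_span: float = 2400.0) -> float:
    """Length increase (um) of one half-span at deflection ``theta``."""
    return half_span * support_line_strain(theta_deg)


def percent_elongation(delta_length: float, half_span: float = 2400.0) -> float:
    """Percent elongation of a half-span that lengthened by ``delta_length``."""
    if half_span <= 0:
        raise ValueError("half span must be positive")
    return 100.0 * delta_length / half_span


def droplet_force(theta_deg: float, line: SupportLine) -> float:
    """Force (uN) pulling the droplet perpendicular to the support line.

    Hookean fibers: each side carries tension n_f * (pi d_f^2/4) * E_f *
    (sec theta - 1) along the deflected line; the two sides' components
    perpendicular to the line sum to ``2 * side_tension * sin(theta)``.
    """
    eps = support_line_strain(theta_deg)
    side = line.fiber_csa * line.fiber_modulus * eps
    return 2.0 * side * math.sin(math.radians(theta_deg))


def filament_csa(V_c: float, length: float) -> float:
    """Instantaneous filament cross-section: core volume over length (um^2)."""
    if V_c <= 0 or length <= 0:
        raise ValueError("core volume and length must be positive")
    return V_c / length


def true_stress(force: float, csa: float) -> float:
    """True stress (MPa): force over instantaneous cross-sectional area."""
    if csa <= 0:
        raise ValueError("cross-sectional area must be positive")
    return force / csa


def true_strain(length: float, initial_length: float) -> float:
    """True strain: natural log of length over initial length."""
    if length <= 0 or initial_length <= 0:
        raise ValueError("lengths must be positive")
    return math.log(length / initial_length)


# ---------------------------------------------------------------------------
# curve assembly and material properties
# ---------------------------------------------------------------------------


def build_stress_strain_curve(
    series: ExtensionSeries,
    geom: DropletGeometry,
    line: SupportLine,
    convention: Convention = "radius",
) -> StressStrainCurve:
    """Assemble the true stress-true strain curve for one extension trial.

    The first point sits at zero strain with the initial length taken as the
    core-sphere radius (or diameter) and sigma_0 resolved from the interval-0
    deflection angle; subsequent points use the measured droplet lengths.
    A NaN interval-0 angle is treated as "not recorded": sigma_0 = 0 with a
    warning.
    """
    L0 = initial_filament_length(geom.core_volume, convention)
    vc = geom.core_volume

    theta0 = series.angles[0]
    if math.isnan(theta0):
        warnings.warn(
            "interval-0 deflection angle missing; taking initial stress as 0",
            stacklevel=2,
        )
        sigma0 = 0.0
    else:
        sigma0 = true_stress(droplet_force(theta0, line), filament_csa(vc, L0))

    strains = [0.0]
    stresses = [sigma0]
    for L, th in zip(series.lengths[1:], series.angles[1:]):
        strains.append(true_strain(L, L0))
        stresses.append(true_stress(droplet_force(th, line), filament_csa(vc, L)))
    return StressStrainCurve(
        fractions=tuple(series.fractions),
        strain=tuple(strains),
        stress=tuple(stresses),
        initial_stress=sigma0,
        convention=convention,
    )


def _window_points(
    curve: StressStrainCurve, window: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = window
    if not (0.0 <= lo < hi <= 1.0):
        raise ValueError("modulus window must satisfy 0 <= lo < hi <= 1")
    frac = np.asarray(curve.fractions)
    mask = (frac >= lo - 1e-12) & (frac <= hi + 1e-12)
    eps = np.asarray(curve.strain)[mask]
    sig = np.asarray(curve.stress)[mask]
    if eps.size < 2:
        raise ValueError(
            f"modulus window {window} covers fewer than two measured intervals"
        )
    return eps, sig


def elastic_modulus(
    curve: StressStrainCurve, window: tuple[float, float] = (0.6, 0.8)
) -> float:
    """Slope (MPa) of the stress-strain curve over the linear window.

    With exactly two points in the window this is the secant slope
    (sigma_b - sigma_a)/(eps_b - eps_a); with more, the least-squares slope.
    """
    eps, sig = _window_points(curve, window)
    if float(eps.max() - eps.min()) == 0.0:
        raise DegenerateCurveError("zero strain increment across modulus window")
    if eps.size == 2:
        return float((sig[1] - sig[0]) / (eps[1] - eps[0]))
    slope, _ = np.polyfit(eps, sig, 1)
    return float(slope)


def _force_log_sensitivity(theta_deg: float) -> float:
    """d ln F / d theta (per radian) for the support-line force model."""
    t = math.radians(theta_deg)
    if t <= 0.0:
        return math.inf
    sec = 1.0 / math.cos(t)
    f = (sec - 1.0) * math.sin(t)
    fp = sec * math.tan(t) * math.sin(t) + (sec - 1.0) * math.cos(t)
    return fp / f


def elastic_modulus_wls(
    curve: StressStrainCurve,
    series: ExtensionSeries,
    angle_sd_deg: float,
    window: tuple[float, float] = (0.0, 1.0),
) -> float:
    """Modulus fit weighted by propagated angle-measurement uncertainty.

    Deflection-angle noise enters stress multiplicatively through the force
    resolution, so each point's stress standard error is
    ``sigma_i * (d ln F/d theta)(theta_i) * sd_theta``. Weighting the
    least-squares slope by the inverse squared standard error makes the fit
    efficient under that noise model; points at zero deflection (infinite
    log-sensitivity) get zero weight. Falls back to the unweighted slope
    when no point carries finite weight or the noise is zero.
    """
    if angle_sd_deg < 0:
        raise ValueError("angle noise SD must be non-negative")
    if angle_sd_deg == 0:
        return elastic_modulus(curve, window)
    lo, hi = window
    frac = np.asarray(curve.fractions)
    mask = (frac >= lo - 1e-12) & (frac <= hi + 1e-12)
    eps = np.asarray(curve.strain)[mask]
    sig = np.asarray(curve.stress)[mask]
    th = np.asarray(series.angles)[mask]
    if eps.size < 2:
        raise ValueError("window covers fewer than two measured intervals")
    sd_rad = math.radians(angle_sd_deg)
    se = np.array(
        [s * _force_log_sensitivity(t) * sd_rad for s, t in zip(sig, th)]
    )
    w = np.where(np.isfinite(se) & (se > 0), 1.0 / np.square(se), 0.0)
    if np.count_nonzero(w) < 2:
        return elastic_modulus(curve, window)
    W = w.sum()
    xm = float((w * eps).sum() / W)
    ym = float((w * sig).sum() / W)
    denom = float((w * (eps - xm) ** 2).sum())
    if denom == 0.0:
        raise DegenerateCurveError("zero weighted strain variance in window")
    return float((w * (eps - xm) * (sig - ym)).sum() / denom)


def toughness(curve: StressStrainCurve) -> float:
    """Energy per volume absorbed during extension (MJ/m^3).

    The area under the curve is summed as rectangles spanning consecutive
    intervals whose heights are the mean true stress of the bounding points;
    the narrow rectangle ``sigma_0 * eps_total`` is subtracted because the
    adhesive was pre-stressed before extension began.
    """
    eps = np.asarray(curve.strain)
    sig = np.asarray(curve.stress)
    if eps.size < 2:
        raise ValueError("toughness needs at least two curve points")
    area = float(np.sum(0.5 * (sig[1:] + sig[:-1]) * np.diff(eps)))
    return area - curve.initial_stress * float(eps[-1] - eps[0])


def material_properties(
    series: ExtensionSeries,
    geom: DropletGeometry,
    line: SupportLine,
    window: tuple[float, float] = (0.6, 0.8),
    convention: Convention = "radius",
) -> MaterialProperties:
    """Full pipeline: curve, elastic modulus over ``window``, toughness."""
    curve = build_stress_strain_curve(series, geom, line, convention)
    return MaterialProperties(
        elastic_modulus=elastic_modulus(curve, window),
        toughness=toughness(curve),
        modulus_window=window,
    )


def modulus_sensitivity(
    series: ExtensionSeries,
    geom: DropletGeometry,
    line: SupportLine,
    delta: float = 0.1,
    window: tuple[float, float] = (0.6, 0.8),
    convention: Convention = "radius",
) -> tuple[MaterialProperties, MaterialProperties]:
    """Recompute properties with fiber modulus scaled by (1+delta), (1-delta).

    Models uncertainty in the support-line stiffness (e.g. humidity
    softening).  Force, hence every stress, is linear in the fiber modulus,
    so both the fitted modulus and the toughness scale by the same factor.
    """
    if delta <= -1.0:
        raise ValueError("delta must exceed -1 (fiber modulus must stay positive)")
    out = []
    for s in (1.0 + delta, 1.0 - delta):
        if s <= 0:
            raise ValueError("scaled fiber modulus must stay positive")
        scaled = SupportLine(
            fiber_count=line.fiber_count,
            fiber_diameter=line.fiber_diameter,
            fiber_modulus=line.fiber_modulus * s,
            span=line.span,
        )
        out.append(material_properties(series, geom, scaled, window, convention))
    return out[0], out[1]


def extension_per_volume(
    series: ExtensionSeries,
    geom: DropletGeometry,
    at_fraction: float = 0.8,
    convention: Convention = "radius",
) -> float:
    """Adhesive extension per core volume at a given interval (um / um^3).

    Reported at 80% of full extension by default because force on some
    droplets drops near pull-off.
    """
    try:
        i = next(
            j
            for j, f in enumerate(series.fractions)
            if abs(f - at_fraction) <= 1e-9
        )
    except StopIteration:
        raise ValueError(f"{at_fraction} is not a measured interval") from None
    L0 = initial_filament_length(geom.core_volume, convention)
    return (series.lengths[i] - L0) / geom.core_volume


def area_per_volume(geom: DropletGeometry) -> float:
    """Flattened core area per core volume (um^2 / um^3 = 1/um)."""
    return geom.flattened_core_area / geom.core_volume


# ---------------------------------------------------------------------------
# normality-gated group comparison
# ---------------------------------------------------------------------------


def compare_groups(
    a: Sequence[float], b: Sequence[float], alpha: float = 0.05
) -> GroupComparison:
    """Two-group comparison with an Anderson-Darling normality gate.

    Each group is tested for normality (AD P >= ``alpha`` counts as normal).
    Both normal: two-tailed t-test.  Otherwise: two-sided Wilcoxon rank-sum
    (Mann-Whitney), the two-group case of the Kruskal-Wallis chi-square.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 values")
    p_a = float(normal_ad(a)[1])
    p_b = float(normal_ad(b)[1])
    if p_a >= alpha and p_b >= alpha:
        t, p = stats.ttest_ind(a, b)
        return GroupComparison("t", float(t), float(p), (p_a, p_b))
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return GroupComparison("wilcoxon", float(u), float(p), (p_a, p_b))
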