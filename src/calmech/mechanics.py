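"""AFM nanoindentation and rheology computations.

Covers the elastomechanical half of the pipeline: deflection-sensitivity
calibration on a rigid substrate, contact-point estimation, Hertz
sphere-on-plane fitting of force curves to a Young modulus, hierarchical
aggregation (curves -> locations -> samples), selection of the rheological
storage modulus at a target frequency, and the incompressible-gel conversion
E = 2 G' (1 + nu).

The reported modulus keeps the (1 - nu^2) factor inside the fit (the JPK
instrument convention), i.e. ``fit_hertz_sphere`` returns the Young modulus
E of the sample, not the reduced modulus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "ForceCurve",
    "ModulusResult",
    "RheologySweep",
    "calibrate_sensitivity",
    "find_contact_point",
    "fit_hertz_sphere",
    "aggregate_modulus",
    "select_storage_at_frequency",
    "storage_to_young",
]

logger = logging.getLogger(__name__)

# Plausibility band for the optical-lever detection sensitivity of a stiff
# cantilever on glass; values outside it usually indicate a bad calibration
# curve rather than a real probe property.
SENSITIVITY_BAND_M_PER_V = (1e-9, 100e-9)


@dataclass
class ForceCurve:
    """One force-displacement record with its probe constants.

    ``displacement`` is either piezo extension or indentation (metres);
    ``is_indentation`` flags which.  Either calibrated ``force`` (N) or a
    raw deflection ``signal`` (V) plus ``sensitivity`` (m/V) must be set.
    """

    displacement: np.ndarray
    force: np.ndarray | None = None
    signal: np.ndarray | None = None        # raw deflection, V
    sensitivity: float | None = None        # m/V
    spring_constant: float = 4.0            # N/m
    sphere_radius: float = 3.325e-6         # m
    poisson_ratio: float = 0.5
    is_indentation: bool = False
    loading_rate: float | None = None       # m/s, metadata only

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=float)
        if self.force is not None:
            self.force = np.asarray(self.force, dtype=float)
        if self.signal is not None:
            self.signal = np.asarray(self.signal, dtype=float)
        if self.spring_constant <= 0 or self.sphere_radius <= 0:
            raise ValueError("spring_constant and sphere_radius must be positive")
        if not 0 <= self.poisson_ratio <= 0.5:
            raise ValueError("poisson_ratio must lie in [0, 0.5]")
        if np.any(np.diff(self.displacement) < 0):
            raise ValueError("displacement grid must be monotone non-decreasing")
        if self.force is None and self.signal is None:
            raise ValueError("either force or signal must be provided")

    def force_values(self) -> np.ndarray:
        """Calibrated force in N, converting from V if necessary."""
        if self.force is not None:
            return self.force
        if self.sensitivity is None:
            raise ValueError("signal given without a sensitivity factor")
        return self.signal * self.sensitivity * self.spring_constant


@dataclass
class ModulusResult:
    """Hierarchically aggregated Young moduli.

    The group aggregate is the mean of sample means; each sample mean is the
    mean of its location means; each location mean is the mean of its
    per-curve fits.
    """

    per_curve_E: list[float]
    location_means: list[float]
    sample_means: list[float]
    mean: float
    sd: float
    n_curves: int
    n_locations: int
    n_samples: int
    sd_defined: bool = True


@dataclass
class RheologySweep:
    """An oscillatory-rheology frequency sweep."""

    frequency: np.ndarray               # Hz, strictly increasing
    storage_modulus: np.ndarray         # G', Pa
    loss_modulus: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frequency = np.asarray(self.frequency, dtype=float)
        self.storage_modulus = np.asarray(self.storage_modulus, dtype=float)
        if np.any(np.diff(self.frequency) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if self.frequency.shape != self.storage_modulus.shape:
            raise ValueError("frequency and storage_modulus lengths differ")


def calibrate_sensitivity(hard_surface_curve: ForceCurve) -> float:
    """Deflection sensitivity (m/V) from a rigid-substrate contact curve.

    On a hard surface the deflection signal rises linearly with piezo
    displacement once in contact; the sensitivity is the inverse slope of a
    least-squares line through the upper half of the deflection range.
    """
    curve = hard_surface_curve
    if curve.signal is None:
        raise ValueError("calibration needs a raw deflection signal in V")
    sig = curve.signal
    z = curve.displacement
    span = sig.max() - sig.min()
    if span <= 0:
        raise ValueError("flat calibration curve: no contact region")
    in_contact = sig >= sig.min() + 0.5 * span
    if in_contact.sum() < 2:
        raise ValueError("contact region too short for a linear fit")
    slope, _ = np.polyfit(z[in_contact], sig[in_contact], 1)
    if slope <= 0:
        raise ValueError("non-positive contact slope: no contact region")
    sensitivity = 1.0 / slope
    lo, hi = SENSITIVITY_BAND_M_PER_V
    if not lo <= sensitivity <= hi:
        logger.warning(
            "detection sensitivity %.3g m/V outside the plausible band "
            "[%.0f, %.0f] nm/V", sensitivity, lo * 1e9, hi * 1e9,
        )
    return float(sensitivity)


def find_contact_point(curve: ForceCurve, baseline_fraction: float = 0.2,
                       refine: bool = True) -> int:
    """Index of the estimated tip-sample contact point.

    The pre-contact baseline is taken from the first ``baseline_fraction``
    of the record; contact is the first sample exceeding the baseline mean
    by 3 baseline SDs (or any rise above baseline on a noiseless record),
    optionally refined by a Hertz fit with the contact offset free.
    """
    force = curve.force_values()
    n_base = max(int(len(force) * baseline_fraction), 2)
    base = force[:n_base]
    thresh = base.mean() + 3.0 * base.std()
    if base.std() == 0:
        thresh = base.mean() + 1e-12 * max(abs(force).max(), 1.0)
    above = np.nonzero(force > thresh)[0]
    above = above[above >= 1] if len(above) else above
    if len(above) == 0:
        raise ValueError("no supra-threshold region: curve appears all baseline")
    idx = int(above[0])
    if not refine:
        return idx
    _, z0 = _hertz_fit_with_offset(curve, idx)
    z = curve.displacement
    return int(np.searchsorted(z, z0))


def _indentation(curve: ForceCurve, force: np.ndarray,
                 z0: float = 0.0) -> np.ndarray:
    """Indentation depth: piezo displacement minus cantilever deflection."""
    z = curve.displacement - z0
    if curve.is_indentation:
        return z
    return z - force / curve.spring_constant


def _hertz_fit_with_offset(curve: ForceCurve,
                           contact_idx: int) -> tuple[float, float]:
    """Fit (E, contact offset z0) jointly; returns (E_Pa, z0_m)."""
    force = curve.force_values()
    z = curve.displacement
    z0_guess = z[contact_idx]
    R, nu = curve.sphere_radius, curve.poisson_ratio

    def model(zv: np.ndarray, E: float, z0: float) -> np.ndarray:
        delta = np.clip(zv - z0, 0.0, None)
        if not curve.is_indentation:
            delta = np.clip(delta - np.clip(force, 0, None) / curve.spring_constant,
                            0.0, None)
        return (4.0 / 3.0) * (E / (1.0 - nu**2)) * np.sqrt(R) * delta**1.5

    E_guess = _linear_hertz_solution(curve, z0_guess)
    popt, _ = optimize.curve_fit(
        model, z, force, p0=[max(E_guess, 1.0), z0_guess],
        maxfev=10000,
    )
    E, z0 = popt
    return float(E), float(z0)


def _linear_hertz_solution(curve: ForceCurve, z0: float) -> float:
    """Closed-form least-squares E for a fixed contact offset."""
    force = curve.force_values()
    delta = np.clip(_indentation(curve, force, z0), 0.0, None)
    g = (4.0 / 3.0) / (1.0 - curve.poisson_ratio**2) \
        * np.sqrt(curve.sphere_radius) * delta**1.5
    denom = np.sum(g * g)
    if denom == 0:
        return 0.0
    return float(np.sum(force * g) / denom)


def fit_hertz_sphere(curve: ForceCurve, contact_idx: int | None = None,
                     refine_contact: bool = False,
                     min_points: int = 20) -> float:
    """Young modulus (Pa) from a Hertz sphere-on-plane fit.

    Fits F = (4/3) E/(1-nu^2) sqrt(R) delta^(3/2) over the in-contact part
    of the curve.  For an indentation-abscissa curve with contact at the
    origin no contact search is needed; otherwise pass ``contact_idx`` or
    set ``refine_contact`` to fit the offset as a nuisance parameter.
    """
    force = curve.force_values()
    if refine_contact:
        idx = contact_idx if contact_idx is not None \
            else find_contact_point(curve, refine=False)
        E, _ = _hertz_fit_with_offset(curve, idx)
    else:
        z0 = curve.displacement[contact_idx] if contact_idx is not None else 0.0
        delta = _indentation(curve, force, z0)
        if np.count_nonzero(delta > 0) < min_points:
            raise ValueError(
                f"fewer than {min_points} in-contact points; cannot fit"
            )
        E = _linear_hertz_solution(curve, z0)
    if E <= 0:
        raise ValueError("fitted Young modulus is non-positive")
    return float(E)


def aggregate_modulus(
    per_curve: dict[str, dict[str, list[float]]] | list[float],
) -> ModulusResult:
    """Hierarchical mean of per-curve moduli.

    ``per_curve`` is either a flat list (treated as one location of one
    sample) or a nested mapping ``{sample: {location: [E, ...]}}``.  The
    aggregate is mean-of-sample-means; the SD is across sample means and is
    flagged undefined when only one sample is present.
    """
    if isinstance(per_curve, list):
        per_curve = {"sample": {"location": per_curve}}
    all_E: list[float] = []
    location_means: list[float] = []
    sample_means: list[float] = []
    for locations in per_curve.values():
        loc_means = []
        for values in locations.values():
            if len(values) == 0:
                continue
            all_E.extend(values)
            loc_means.append(float(np.mean(values)))
        if loc_means:
            location_means.extend(loc_means)
            sample_means.append(float(np.mean(loc_means)))
    if not all_E:
        raise ValueError("no curves to aggregate")
    if any(E <= 0 for E in all_E):
        raise ValueError("all moduli must be positive")
    sd_defined = len(sample_means) > 1
    return ModulusResult(
        per_curve_E=all_E,
        location_means=location_means,
        sample_means=sample_means,
        mean=float(np.mean(sample_means)),
        sd=float(np.std(sample_means, ddof=1)) if sd_defined else 0.0,
        n_curves=len(all_E),
        n_locations=len(location_means),
        n_samples=len(sample_means),
        sd_defined=sd_defined,
    )


def select_storage_at_frequency(sweep: RheologySweep,
                                f_target: float = 10.0) -> float:
    """Storage modulus G' (Pa) at ``f_target`` by log-frequency interpolation."""
    f = sweep.frequency
    if not f[0] <= f_target <= f[-1]:
        raise ValueError(
            f"target frequency {f_target} Hz outside sweep range "
            f"[{f[0]}, {f[-1]}] Hz"
        )
    return float(np.interp(np.log10(f_target), np.log10(f),
                           sweep.storage_modulus))


def storage_to_young(g_prime_pa: float, poisson_ratio: float = 0.5) -> float:
    """Young modulus from the shear storage modulus: E = 2 G' (1 + nu).

    For incompressible hydrogels nu = 0.5, giving E = 3 G'.
    """
    if g_prime_pa < 0:
        raise ValueError("storage modulus must be non-negative")
    if not 0 <= poisson_ratio <= 0.5:
        raise ValueError("poisson_ratio must lie in [0, 0.5]")
    return 2.0 * g_prime_pa * (1.0 + poisson_ratio)
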