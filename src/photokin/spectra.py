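"""Steady-state absorption spectra and two-component isomer unmixing.

Microbial rhodopsins that photoconvert between all-*trans* and 13-*cis*
retinal show illumination-dependent absorption spectra: the dark-adapted and
light-adapted spectra are different linear mixtures of the same two pure
chromophore spectra.  Given the two mixture spectra and the isomer molar
fractions of each (e.g. from HPLC), the pure all-*trans* and 13-*cis*
spectra follow from a per-wavelength 2x2 linear solve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Spectrum",
    "IsomerFractions",
    "gaussian_band",
    "compose_mixture",
    "unmix_pure_spectra",
    "find_lambda_max",
]


@dataclass
class Spectrum:
    """Absorbance versus wavelength on a strictly increasing nm grid."""

    wavelengths: np.ndarray
    absorbance: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavelengths.ndim != 1 or self.wavelengths.size < 2:
            raise ValueError("wavelength grid must be 1-D with >= 2 points")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if self.absorbance.shape != self.wavelengths.shape:
            raise ValueError("absorbance and wavelength grids differ in shape")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance must be finite")

    def at(self, wavelength: float) -> float:
        """Linearly interpolated absorbance at ``wavelength`` (nm)."""
        lo, hi = self.wavelengths[0], self.wavelengths[-1]
        if not lo <= wavelength <= hi:
            raise ValueError(f"{wavelength} nm outside scanned range [{lo}, {hi}]")
        return float(np.interp(wavelength, self.wavelengths, self.absorbance))

    @property
    def lambda_max(self) -> float:
        return find_lambda_max(self)


@dataclass
class IsomerFractions:
    """Molar fractions of the retinal chromophore isomers.

    ``f_at`` is the all-*trans* fraction; the 13-*cis* fraction is its
    complement.  ``sd`` carries the replicate standard deviation of ``f_at``.
    """

    f_at: float
    sd: float = 0.0
    condition: str = "dark"

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_at <= 1.0:
            raise ValueError("f_at must lie in [0, 1]")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")

    @property
    def f_13c(self) -> float:
        return 1.0 - self.f_at


def gaussian_band(
    wavelengths: np.ndarray,
    center_nm: float,
    fwhm_cm1: float = 3800.0,
    amplitude: float = 1.0,
    label: str = "",
) -> Spectrum:
    """A single absorption band, Gaussian in wavenumber (1/lambda) space.

    Retinal-protein bands are approximately symmetric on an energy axis, so
    the canonical synthetic lineshape is a Gaussian in wavenumber with the
    stated full width at half maximum (default 3800 cm^-1).  The peak of the
    resulting A(lambda) falls exactly at ``center_nm`` because the
    wavelength -> wavenumber map is monotone.
    """
    wl = np.asarray(wavelengths, dtype=float)
    nu = 1.0e7 / wl          # cm^-1
    nu0 = 1.0e7 / center_nm
    sigma = fwhm_cm1 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    a = amplitude * np.exp(-0.5 * ((nu - nu0) / sigma) ** 2)
    return Spectrum(wl, a, label=label)


def compose_mixture(s_at: Spectrum, s_13c: Spectrum, f_at: float, label: str = "") -> Spectrum:
    """Linear mixture ``f_at * S_AT + (1 - f_at) * S_13C``."""
    if not 0.0 <= f_at <= 1.0:
        raise ValueError("f_at must lie in [0, 1]")
    if not np.array_equal(s_at.wavelengths, s_13c.wavelengths):
        raise ValueError("spectra are on different wavelength grids")
    mix = f_at * s_at.absorbance + (1.0 - f_at) * s_13c.absorbance
    return Spectrum(s_at.wavelengths.copy(), mix, label=label)


def unmix_pure_spectra(
    s_dark: Spectrum,
    s_light: Spectrum,
    f_dark: IsomerFractions,
    f_light: IsomerFractions,
) -> tuple[Spectrum, Spectrum]:
    """Recover pure all-*trans* and 13-*cis* spectra from two mixtures.

    Solves, at every wavelength, the 2x2 system

        S_dark  = f_dark  * S_AT + (1 - f_dark)  * S_13C
        S_light = f_light * S_AT + (1 - f_light) * S_13C

    The system is rejected as ill-conditioned when the two all-*trans*
    fractions differ by less than 0.05 (the matrix determinant equals the
    fraction difference).  Negative values in the recovered pure spectra are
    reported with a warning, not clipped: they diagnose wrong input
    fractions.
    """
    if not np.array_equal(s_dark.wavelengths, s_light.wavelengths):
        raise ValueError("spectra are on different wavelength grids")
    det = f_dark.f_at - f_light.f_at
    if abs(det) < 0.05:
        raise ValueError(
            "unmixing ill-conditioned: |f_dark - f_light| = "
            f"{abs(det):.3f} < 0.05 (2x2 determinant too small)"
        )
    # Inverse of [[f_d, 1-f_d], [f_l, 1-f_l]] applied per wavelength.
    s_at = ((1.0 - f_light.f_at) * s_dark.absorbance
            - (1.0 - f_dark.f_at) * s_light.absorbance) / det
    s_13c = (f_dark.f_at * s_light.absorbance
             - f_light.f_at * s_dark.absorbance) / det
    for name, vals in (("all-trans", s_at), ("13-cis", s_13c)):
        if np.any(vals < -1e-12 * max(1.0, np.abs(vals).max())):
            warnings.warn(
                f"recovered pure {name} spectrum has negative values; "
                "check the input isomer fractions",
                stacklevel=2,
            )
    return (
        Spectrum(s_dark.wavelengths.copy(), s_at, label="pure all-trans"),
        Spectrum(s_dark.wavelengths.copy(), s_13c, label="pure 13-cis"),
    )


def find_lambda_max(spectrum: Spectrum, resolution_nm: float = 0.1) -> float:
    """Absorption maximum in nm by parabolic interpolation.

    Fits a parabola through the maximal sample and its two neighbours and
    reports the vertex rounded to ``resolution_nm``.  A maximum on the grid
    boundary is an error (the true peak lies outside the scanned range); a
    flat three-point plateau returns the middle point with a warning.
    """
    wl, a = spectrum.wavelengths, spectrum.absorbance
    if wl.size < 3:
        raise ValueError("need at least 3 grid points")
    i = int(np.argmax(a))
    # contiguous run of maximal samples containing i
    left = i
    while left > 0 and a[left - 1] == a[i]:
        left -= 1
    right = i
    while right < a.size - 1 and a[right + 1] == a[i]:
        right += 1
    if left == 0 or right == wl.size - 1:
        raise ValueError("lambda_max outside scanned range (boundary maximum)")
    if right > left:  # flat plateau
        warnings.warn("flat plateau at maximum; reporting its midpoint", stacklevel=2)
        peak = 0.5 * (wl[left] + wl[right])
    else:
        # vertex of the parabola through the three samples (uniform or not)
        y0, y1, y2 = a[i - 1], a[i], a[i + 1]
        c2, c1, _ = np.polyfit(wl[i - 1 : i + 2] - wl[i], [y0, y1, y2], 2)
        peak = wl[i] + (-c1 / (2.0 * c2) if c2 < 0 else 0.0)
    return float(np.round(peak / resolution_nm) * resolution_nm)
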