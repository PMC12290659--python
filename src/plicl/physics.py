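"""Physical signal model of 3D polarized light imaging (3D-PLI).

A birefringent tissue section placed between a rotating linear polarizer and a
circular analyzer transmits, at polarizer angle ``rho``, the intensity

    I(rho) = IT/2 * (1 + sin(2*rho - 2*phi) * sin(delta)),

a sinusoid whose mean encodes the transmittance ``IT``, whose phase encodes the
in-plane fiber direction ``phi`` (defined modulo pi), and whose relative
amplitude encodes the retardation ``|sin(delta)|``.  The phase shift delta
depends on the cumulative birefringent thickness ``t``, the birefringence
``dn``, the light wavelength ``lam`` and the out-of-plane inclination
``alpha``:

    delta ~= (2*pi * t * dn / lam) * cos(alpha)**2,

while the transmittance follows the Bouguer-Lambert attenuation law
``IT = I0 * exp(-t * mu)``.

This module provides the forward model (:func:`forward_profiles`), the inverse
harmonic (Fourier) retrieval of the three parameter maps
(:func:`retrieve_parameters`), an approximate inclination estimate
(:func:`estimate_inclination`), and the cyclic-safe 3-channel encoding used to
feed parameter maps to convolutional encoders (:func:`channel_encode`).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from pathlib import Path

import h5py
import numpy as np
import tifffile

__all__ = [
    "N_ANGLES",
    "ROTATION_ANGLES",
    "OpticalConstants",
    "FiberVoxelField",
    "RawPLISeries",
    "ParameterMaps",
    "forward_profiles",
    "retrieve_parameters",
    "estimate_inclination",
    "channel_encode",
    "channel_decode",
    "wrap_direction",
]

#: Number of equidistant polarizer rotation angles covering 180 degrees.
N_ANGLES = 9

#: The rotation angles rho_k = k * 20 degrees, in radians.
ROTATION_ANGLES = np.deg2rad(20.0 * np.arange(N_ANGLES))


def wrap_direction(phi: np.ndarray | float) -> np.ndarray:
    """Canonicalize direction angles to the half-open interval [0, pi)."""
    return np.mod(phi, np.pi)


@dataclass(frozen=True)
class OpticalConstants:
    """Calibration constants of the imaging setup.

    Parameters
    ----------
    wavelength_nm:
        Center wavelength of the band-pass filtered light source.  550 nm for
        the polarizing microscope modeled here.
    birefringence:
        Effective (negative uniaxial) birefringence magnitude ``|dn|`` of
        myelinated tissue; dimensionless calibration value.
    mu_ref_per_um:
        Reference attenuation coefficient in 1/um used when inverting the
        Bouguer-Lambert law for thickness.
    incident_intensity:
        Incident light intensity ``I0`` in arbitrary units.
    """

    wavelength_nm: float = 550.0
    birefringence: float = 0.001
    mu_ref_per_um: float = 0.01
    incident_intensity: float = 1.0


@dataclass
class FiberVoxelField:
    """Per-pixel ground-truth fiber parameters feeding the forward model.

    ``direction_phi`` is the in-plane fiber angle (radians, mod pi),
    ``inclination_alpha`` the out-of-plane angle in [0, pi/2],
    ``thickness_t`` the cumulative birefringent thickness in um and
    ``attenuation_mu`` the attenuation coefficient in 1/um.
    """

    direction_phi: np.ndarray
    inclination_alpha: np.ndarray
    thickness_t: np.ndarray
    attenuation_mu: np.ndarray
    constants: OpticalConstants = dataclass_field(default_factory=OpticalConstants)

    def __post_init__(self) -> None:
        self.direction_phi = wrap_direction(np.asarray(self.direction_phi, dtype=float))
        self.inclination_alpha = np.asarray(self.inclination_alpha, dtype=float)
        self.thickness_t = np.asarray(self.thickness_t, dtype=float)
        self.attenuation_mu = np.asarray(self.attenuation_mu, dtype=float)
        if np.any(self.inclination_alpha < 0) or np.any(self.inclination_alpha > np.pi / 2 + 1e-12):
            raise ValueError("inclination must lie in [0, pi/2]")
        if np.any(self.thickness_t < 0):
            raise ValueError("thickness must be non-negative")
        if np.any(self.attenuation_mu < 0):
            raise ValueError("attenuation must be non-negative")
        if self.constants.incident_intensity <= 0:
            raise ValueError("incident intensity I0 must be positive")

    @property
    def phase_delta(self) -> np.ndarray:
        """Phase shift delta between ordinary and extraordinary ray."""
        c = self.constants
        # thickness in um, wavelength in nm -> convert to common units (um)
        lam_um = c.wavelength_nm * 1e-3
        return (
            2.0
            * np.pi
            * self.thickness_t
            * c.birefringence
            / lam_um
            * np.cos(self.inclination_alpha) ** 2
        )

    @property
    def transmittance(self) -> np.ndarray:
        """Bouguer-Lambert transmittance I0 * exp(-t * mu)."""
        c = self.constants
        return c.incident_intensity * np.exp(-self.thickness_t * self.attenuation_mu)


@dataclass
class RawPLISeries:
    """Intensity image series at the nine polarizer rotation angles.

    ``intensities`` has shape (9, ...) with one image per angle
    rho_k = k * 20 degrees, k = 0..8.
    """

    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape[0] != N_ANGLES:
            raise ValueError(f"expected {N_ANGLES} rotation angles, got {self.intensities.shape[0]}")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def angles(self) -> np.ndarray:
        return ROTATION_ANGLES

    def save_tiff(self, path: str | Path) -> None:
        """Write one TIFF page per rotation angle (float32)."""
        tifffile.imwrite(str(path), self.intensities.astype(np.float32), photometric="minisblack")

    @classmethod
    def load_tiff(cls, path: str | Path) -> "RawPLISeries":
        return cls(intensities=tifffile.imread(str(path)))


@dataclass
class ParameterMaps:
    """The per-section triplet (transmittance, direction, retardation).

    The universal currency of this package: transmittance in intensity units,
    direction in radians stored canonically in [0, pi), retardation
    (|sin delta|) dimensionless in [0, 1].
    """

    transmittance: np.ndarray
    direction: np.ndarray
    retardation: np.ndarray
    pixel_size_um: float = 1.3

    def __post_init__(self) -> None:
        self.transmittance = np.asarray(self.transmittance, dtype=float)
        self.direction = wrap_direction(np.asarray(self.direction, dtype=float))
        self.retardation = np.asarray(self.retardation, dtype=float)
        if self.transmittance.shape != self.direction.shape or self.direction.shape != self.retardation.shape:
            raise ValueError("parameter maps must share a common shape")
        if np.any(self.retardation < -1e-9) or np.any(self.retardation > 1 + 1e-9):
            raise ValueError("retardation must lie in [0, 1]")
        self.retardation = np.clip(self.retardation, 0.0, 1.0)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.transmittance.shape

    def copy(self) -> "ParameterMaps":
        return ParameterMaps(
            self.transmittance.copy(),
            self.direction.copy(),
            self.retardation.copy(),
            self.pixel_size_um,
        )

    # -- IO ---------------------------------------------------------------
    def save_tiff(self, path: str | Path) -> None:
        """Multi-page TIFF in the order transmittance, direction, retardation."""
        stack = np.stack([self.transmittance, self.direction, self.retardation])
        tifffile.imwrite(
            str(path),
            stack.astype(np.float32),
            photometric="minisblack",
            metadata={"pixel_size_um": self.pixel_size_um},
        )

    @classmethod
    def load_tiff(cls, path: str | Path, pixel_size_um: float = 1.3) -> "ParameterMaps":
        stack = tifffile.imread(str(path))
        return cls(stack[0], stack[1], stack[2], pixel_size_um=pixel_size_um)

    def save_h5(self, group: h5py.Group) -> None:
        for name, arr in (
            ("transmittance", self.transmittance),
            ("direction", self.direction),
            ("retardation", self.retardation),
        ):
            group.create_dataset(name, data=arr.astype(np.float32))
        group.attrs["pixel_size_um"] = self.pixel_size_um

    @classmethod
    def load_h5(cls, group: h5py.Group) -> "ParameterMaps":
        return cls(
            group["transmittance"][()],
            group["direction"][()],
            group["retardation"][()],
            pixel_size_um=float(group.attrs.get("pixel_size_um", 1.3)),
        )


def forward_profiles(field: FiberVoxelField) -> RawPLISeries:
    """Evaluate the sinusoidal intensity profiles of the forward model.

    Returns the 9-angle series ``I(rho_k) = IT/2 * (1 + sin(2 rho_k - 2 phi)
    * sin(delta))`` with the transmittance from the Bouguer-Lambert law.
    """
    it = field.transmittance
    delta = field.phase_delta
    phi = field.direction_phi
    rho = ROTATION_ANGLES.reshape((-1,) + (1,) * it.ndim)
    profiles = it / 2.0 * (1.0 + np.sin(2.0 * rho - 2.0 * phi) * np.sin(delta))
    return RawPLISeries(intensities=profiles)


def retrieve_parameters(series: RawPLISeries, pixel_size_um: float = 1.3) -> tuple[ParameterMaps, np.ndarray]:
    """Harmonic Fourier retrieval of (IT, phi, |sin delta|) from a 9-angle series.

    At nine equidistant angles over 180 degrees the discrete Fourier
    coefficients of order 2 (in ``rho``) are exact, so for a noiseless forward
    profile the round trip is an identity:

    * ``IT = 2 * mean(I)``
    * ``a = (2/9) * sum_k I_k cos(2 rho_k)`` and
      ``b = (2/9) * sum_k I_k sin(2 rho_k)`` give the amplitude
      ``(IT/2) * |sin delta| = sqrt(a^2 + b^2)``
    * ``phi = atan2(-a, b) / 2  (mod pi)``.

    Returns the retrieved maps and a boolean ``undefined`` mask marking pixels
    with an all-zero profile, where direction and retardation are returned as
    zero by convention.
    """
    intensities = series.intensities
    rho = ROTATION_ANGLES.reshape((-1,) + (1,) * (intensities.ndim - 1))
    mean = intensities.mean(axis=0)
    a = 2.0 / N_ANGLES * np.sum(intensities * np.cos(2.0 * rho), axis=0)
    b = 2.0 / N_ANGLES * np.sum(intensities * np.sin(2.0 * rho), axis=0)
    amplitude = np.hypot(a, b)
    undefined = mean <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        retardation = np.where(undefined, 0.0, amplitude / np.where(undefined, 1.0, mean))
    retardation = np.clip(retardation, 0.0, 1.0)
    phi = wrap_direction(0.5 * np.arctan2(-a, b))
    phi = np.where(undefined | (amplitude == 0), 0.0, phi)
    maps = ParameterMaps(
        transmittance=2.0 * mean,
        direction=phi,
        retardation=retardation,
        pixel_size_um=pixel_size_um,
    )
    return maps, undefined


def estimate_inclination(
    maps: ParameterMaps,
    constants: OpticalConstants | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Approximate out-of-plane inclination from transmittance and retardation.

    A simplified two-step inversion: thickness is estimated from the
    Bouguer-Lambert law with a single reference attenuation coefficient,
    ``t_hat = -ln(IT / I0) / mu_ref``, and the phase relation is then solved
    for the inclination via ``cos(alpha)^2 = arcsin(r) * lam / (2 pi t_hat
    dn)``, clipped to [0, 1].  This is a deliberately coarse model: real
    retrievals use a transmittance-weighted calibration, and ``arcsin``
    resolves only the principal branch of ``|sin delta|``.

    Returns ``(alpha, invalid)`` where ``alpha`` is in [0, pi/2] and
    ``invalid`` marks pixels with non-positive transmittance (undefined
    thickness) or zero estimated thickness.
    """
    c = constants or OpticalConstants()
    it = maps.transmittance
    invalid = it <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t_hat = -np.log(np.where(invalid, 1.0, it) / c.incident_intensity) / c.mu_ref_per_um
    invalid = invalid | (t_hat <= 0)
    lam_um = c.wavelength_nm * 1e-3
    denom = 2.0 * np.pi * np.where(invalid, 1.0, t_hat) * c.birefringence
    cos2_alpha = np.clip(np.arcsin(np.clip(maps.retardation, 0.0, 1.0)) * lam_um / denom, 0.0, 1.0)
    alpha = np.arccos(np.sqrt(cos2_alpha))
    alpha = np.where(invalid, np.nan, alpha)
    return alpha, invalid


def channel_encode(maps: ParameterMaps, normalize_transmittance: float | None = None) -> np.ndarray:
    """Stack parameter maps as the 3-channel image (IT, r cos 2phi, r sin 2phi).

    Doubling the direction angle resolves its cyclic nature: the channels are
    continuous across the 0/pi wrap and invertible wherever r > 0.  Channels
    are stacked along a leading axis (shape ``(3, ...)``).  If
    ``normalize_transmittance`` is given, the first channel is divided by it.
    """
    it = maps.transmittance
    if normalize_transmittance is not None:
        it = it / normalize_transmittance
    r = maps.retardation
    two_phi = 2.0 * maps.direction
    return np.stack([it, r * np.cos(two_phi), r * np.sin(two_phi)])


def channel_decode(channels: np.ndarray, pixel_size_um: float = 1.3) -> ParameterMaps:
    """Invert :func:`channel_encode` (direction arbitrary where r == 0)."""
    it = channels[0]
    r = np.hypot(channels[1], channels[2])
    phi = wrap_direction(0.5 * np.arctan2(channels[2], channels[1]))
    return ParameterMaps(it, phi, np.clip(r, 0.0, 1.0), pixel_size_um=pixel_size_um)
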