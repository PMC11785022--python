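"""Multi-wavelength reflectance to hemoglobin, and fluorescence correction.

The modified Beer-Lambert model used throughout:

    dA(lambda) = -ln(I / I0)
               = [eps_HbO(lambda) * dHbO + eps_HbR(lambda) * dHbR] * X(lambda)

with concentrations in micromolar, extinctions in cm^-1 M^-1 and estimated
optical pathlengths X in cm. The two-species inversion is an ordinary
least-squares solve across wavelengths; dHbT = dHbO + dHbR by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .errors import ConditioningWarning, ParameterError

# Tabulated molar extinction coefficients for hemoglobin (cm^-1 / M),
# standard compiled spectra, at the illumination wavelengths used here.
EXTINCTION_TABLE: dict[float, tuple[float, float]] = {
    # nm: (eps_HbO, eps_HbR)
    480.0: (14550.4, 26629.2),
    530.0: (39956.8, 39036.4),
    568.0: (44496.0, 45072.0),
    630.0: (610.0, 5148.8),
}

# Default estimated differential pathlengths (cm) per wavelength; published
# widefield estimates, configurable because they are not measured here.
DEFAULT_PATHLENGTH_CM: dict[float, float] = {
    480.0: 0.048,
    530.0: 0.057,
    568.0: 0.060,
    630.0: 0.300,
}

ISOSBESTIC_NM = 530.0
# HbO/HbR extinctions at 530 nm differ by ~2.4% in the standard tables.
ISOSBESTIC_RTOL = 0.025


@dataclass
class SpectroscopyConstants:
    """Extinction coefficients and pathlengths for the Beer-Lambert inversion."""

    wavelengths: np.ndarray
    epsilon_hbo: np.ndarray  # cm^-1 M^-1
    epsilon_hbr: np.ndarray  # cm^-1 M^-1
    pathlength_cm: np.ndarray
    baseline_total_hb_uM: float = 100.0

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.epsilon_hbo = np.asarray(self.epsilon_hbo, dtype=float)
        self.epsilon_hbr = np.asarray(self.epsilon_hbr, dtype=float)
        self.pathlength_cm = np.asarray(self.pathlength_cm, dtype=float)
        if not (self.epsilon_hbo > 0).all() or not (self.epsilon_hbr > 0).all():
            raise ParameterError("extinction coefficients must be positive")
        if not (self.pathlength_cm > 0).all():
            raise ParameterError("pathlengths must be positive")
        for i, wl in enumerate(self.wavelengths):
            if abs(wl - ISOSBESTIC_NM) <= 2.0:
                if abs(self.epsilon_hbo[i] - self.epsilon_hbr[i]) > ISOSBESTIC_RTOL * self.epsilon_hbr[i]:
                    raise ParameterError(
                        "isosbestic wavelength extinctions for HbO and HbR must agree"
                    )

    @classmethod
    def default(cls, wavelengths=(480.0, 530.0, 630.0)) -> "SpectroscopyConstants":
        wl = [float(w) for w in wavelengths]
        return cls(
            wavelengths=np.array(wl),
            epsilon_hbo=np.array([EXTINCTION_TABLE[w][0] for w in wl]),
            epsilon_hbr=np.array([EXTINCTION_TABLE[w][1] for w in wl]),
            pathlength_cm=np.array([DEFAULT_PATHLENGTH_CM[w] for w in wl]),
        )

    @classmethod
    def from_yaml(cls, path) -> "SpectroscopyConstants":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        return cls(
            wavelengths=np.asarray(cfg["wavelengths"], dtype=float),
            epsilon_hbo=np.asarray(cfg["epsilon_hbo"], dtype=float),
            epsilon_hbr=np.asarray(cfg["epsilon_hbr"], dtype=float),
            pathlength_cm=np.asarray(cfg["pathlength_cm"], dtype=float),
            baseline_total_hb_uM=float(cfg.get("baseline_total_hb_uM", 100.0)),
        )

    def design_matrix(self) -> np.ndarray:
        """(n_wavelengths, 2) matrix mapping (dHbO, dHbR) in uM to dA."""
        return 1e-6 * np.stack(
            [self.epsilon_hbo * self.pathlength_cm, self.epsilon_hbr * self.pathlength_cm],
            axis=1,
        )


@dataclass
class HemoglobinSet:
    """Hemoglobin concentration changes (uM) plus corrected fluorescence."""

    dhbt: np.ndarray
    dhbo: np.ndarray | None = None
    dhbr: np.ndarray | None = None
    dff_corrected: np.ndarray | None = None
    residual: float = 0.0


def delta_absorbance(I: np.ndarray, I0) -> np.ndarray:
    """``dA = -ln(I / I0)``; ``I0`` is the awake-rest baseline intensity."""
    I = np.asarray(I, dtype=float)
    I0 = np.asarray(I0, dtype=float)
    if (I <= 0).any() or (I0 <= 0).any():
        raise ParameterError("intensities must be strictly positive")
    return -np.log(I / I0)


def forward_absorbance(dhbo_uM, dhbr_uM, constants: SpectroscopyConstants) -> np.ndarray:
    """Forward Beer-Lambert: dA per wavelength from concentrations in uM.

    Shape: (n_wavelengths, ...) broadcast over the trace axis.
    """
    E = constants.design_matrix()
    conc = np.stack([np.asarray(dhbo_uM, dtype=float), np.asarray(dhbr_uM, dtype=float)])
    return np.tensordot(E, conc, axes=(1, 0))


def invert_beer_lambert(
    dA: np.ndarray,
    constants: SpectroscopyConstants,
    cond_limit: float = 1e8,
) -> HemoglobinSet:
    """Least-squares two-species inversion of dA across wavelengths.

    ``dA`` has shape (n_wavelengths,) or (n_wavelengths, n_samples). With a
    single (isosbestic) wavelength, only dHbT is returned, using the mean of
    the HbO/HbR extinctions.
    """
    dA = np.atleast_1d(np.asarray(dA, dtype=float))
    one_d = dA.ndim == 1
    dA2 = dA[:, None] if one_d else dA
    n_wl = dA2.shape[0]
    if n_wl != constants.wavelengths.size:
        raise ParameterError("dA rows must match the number of wavelengths")
    if n_wl == 1:
        eps_t = 0.5 * (constants.epsilon_hbo[0] + constants.epsilon_hbr[0])
        dhbt = dA2[0] / (eps_t * constants.pathlength_cm[0] * 1e-6)
        return HemoglobinSet(dhbt=dhbt if not one_d else dhbt.ravel())
    E = constants.design_matrix()
    if np.linalg.cond(E) > cond_limit:
        raise np.linalg.LinAlgError(
            "extinction vectors are collinear; two-species inversion ill-conditioned"
        )
    sol, res, _, _ = np.linalg.lstsq(E, dA2, rcond=None)
    dhbo, dhbr = sol[0], sol[1]
    residual = float(np.sqrt(res.sum())) if res.size else 0.0
    if one_d:
        dhbo, dhbr = dhbo.ravel(), dhbr.ravel()
    return HemoglobinSet(dhbt=dhbo + dhbr, dhbo=dhbo, dhbr=dhbr, residual=residual)


def correct_fluorescence(
    F: np.ndarray,
    G: np.ndarray,
    G0: float | np.ndarray,
    baseline: np.ndarray | slice = slice(None),
    literal_baseline_ratio: float | None = None,
) -> np.ndarray:
    """Hemodynamic-attenuation-corrected dF/F.

    Default (attenuation-division) model::

        Fc(t)   = F(t) / (G(t) / G0)
        dF/F(t) = (Fc(t) - mean(Fc[baseline])) / mean(Fc[baseline])

    i.e. the fluorescence is divided by the normalized 530-nm reflectance
    before computing dF/F, which exactly inverts multiplicative absorption
    of the emission/excitation path.

    ``literal_baseline_ratio``, when given, instead multiplies F by that
    time-independent green/blue baseline ratio before the dF/F step (the
    alternative, literal reading of the acquisition description; it cannot
    remove dynamic contamination and exists for comparison only).
    """
    F = np.asarray(F, dtype=float)
    G = np.asarray(G, dtype=float)
    if np.any(G <= 0) or np.any(np.asarray(G0) <= 0):
        raise ParameterError("reflectance must be strictly positive")
    if literal_baseline_ratio is not None:
        Fc = F * literal_baseline_ratio
    else:
        Fc = F / (G / G0)
    f0 = np.mean(Fc[baseline])
    if f0 == 0:
        raise ParameterError("zero baseline fluorescence")
    return (Fc - f0) / f0
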