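"""Density-based empirical solubility correlations for supercritical CO2.

Eleven closed-form correlations relating the equilibrium solubility of a
solid solute in supercritical carbon dioxide to temperature ``T`` (K),
pressure ``P`` (MPa) and pure-CO2 density ``rho`` (kg/m3).  Ten are the
classical literature forms (Chrastil, Jouyban, Kumar-Johnston,
Garlapati-Madras, Bian, Bartle, Mendez-Santiago-Teja, Sodeifian, Tan,
Gordillo); the eleventh is the modified Arrhenius correlation

    y2 = (a1*T + a2*rho + a3) * exp(-a4/P) + a5*ln(rho/T) + a6,

an Arrhenius-shaped term (pre-exponential linear in T and rho, exponential
decay in inverse pressure) plus a departure function linear in ln(rho/T).

All correlations except Chrastil predict the solute mole fraction ``y2``;
Chrastil natively predicts ``c2``, the solute mass per solvent volume, and
conversion helpers are provided.  Evaluation is vectorised and total:
overflowing exponentials yield non-finite values (never exceptions) so a
fitting objective can penalise them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "CO2_MOLAR_MASS",
    "EXP_CLAMP",
    "CatalogueError",
    "ConfigurationError",
    "CorrelationSpec",
    "CoefficientSet",
    "CATALOG",
    "MODEL_IDS",
    "evaluate",
    "evaluate_y2",
    "kumar_johnston_density",
    "chrastil_mass_to_mole",
    "chrastil_mole_to_mass",
]

#: Molar mass of CO2, kg/kmol.
CO2_MOLAR_MASS = 44.01

#: Exponent arguments are clamped here; larger arguments flag as non-finite.
EXP_CLAMP = 700.0


class CatalogueError(KeyError):
    """Unknown correlation or drug identifier."""


class ConfigurationError(ValueError):
    """A required configuration item (e.g. drug molar mass) is missing."""


@dataclass(frozen=True)
class CorrelationSpec:
    """Identity and shape of one correlation.

    Attributes
    ----------
    id : str
        Catalogue identifier.
    n_coeff : int
        Number of adjustable coefficients (3 to 6).
    output_space : str
        ``"mole_fraction_y2"`` or ``"mass_per_volume_c2"`` (Chrastil only).
    constants : dict
        Fixed reference values embedded in the functional form
        (Bartle: P_ref = 0.1 MPa, rho_ref = 700 kg/m3).
    """

    id: str
    n_coeff: int
    output_space: str = "mole_fraction_y2"
    constants: dict = field(default_factory=dict)


@dataclass(frozen=True)
class CoefficientSet:
    """Adjusted coefficients a1..an of one (correlation, drug) pair.

    Coefficients are stored in natural units (any table scaling undone).
    """

    model_id: str
    drug_id: str
    a: tuple
    provenance: str = "user"

    def __post_init__(self):
        a = tuple(float(v) for v in self.a)
        object.__setattr__(self, "a", a)
        if not all(np.isfinite(a)):
            raise ValueError("coefficients must be finite")
        spec = get_spec(self.model_id)
        if len(a) != spec.n_coeff:
            raise ValueError(
                f"{self.model_id} takes {spec.n_coeff} coefficients, got {len(a)}"
            )


def _guarded_exp(arg):
    """exp with the overflow policy: arg > EXP_CLAMP -> inf (flagged)."""
    arg = np.asarray(arg, dtype=float)
    out = np.exp(np.clip(arg, -EXP_CLAMP, EXP_CLAMP))
    return np.where(arg > EXP_CLAMP, np.inf, out)


def kumar_johnston_density(rho_mass):
    """Convert a mass density (kg/m3) to molar density (kmol/m3).

    The Kumar-Johnston form takes the CO2 density in kmol/m3 while datasets
    carry kg/m3; division by the CO2 molar mass (44.01 kg/kmol) bridges them.
    """
    rho_mass = np.asarray(rho_mass, dtype=float)
    if np.any(rho_mass <= 0):
        raise ValueError("density must be positive")
    out = rho_mass / CO2_MOLAR_MASS
    return float(out) if out.ndim == 0 else out


def chrastil_mass_to_mole(c2, rho, mw_drug):
    """Convert Chrastil's c2 (kg solute / m3 solvent) to mole fraction y2.

    y2 = (c2/Ms) / (c2/Ms + rho/M_CO2) with Ms the drug molar mass in
    kg/kmol.  Exact (not a dilute-limit approximation), so the round trip
    with :func:`chrastil_mole_to_mass` is the identity.
    """
    if mw_drug is None:
        raise ConfigurationError("drug molar mass required for Chrastil conversion")
    if mw_drug <= 0:
        raise ValueError("drug molar mass must be positive")
    c2 = np.asarray(c2, dtype=float)
    rho = np.asarray(rho, dtype=float)
    if np.any(rho <= 0):
        raise ValueError("density must be positive")
    n_solute = c2 / mw_drug
    n_solvent = rho / CO2_MOLAR_MASS
    out = n_solute / (n_solute + n_solvent)
    return float(out) if out.ndim == 0 else out


def chrastil_mole_to_mass(y2, rho, mw_drug):
    """Inverse of :func:`chrastil_mass_to_mole`: c2 = Ms*(rho/M_CO2)*y2/(1-y2)."""
    if mw_drug is None:
        raise ConfigurationError("drug molar mass required for Chrastil conversion")
    if mw_drug <= 0:
        raise ValueError("drug molar mass must be positive")
    y2 = np.asarray(y2, dtype=float)
    rho = np.asarray(rho, dtype=float)
    out = mw_drug * (rho / CO2_MOLAR_MASS) * y2 / (1.0 - y2)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Functional forms.  Each takes (a, T, P, rho) with arrays already float64
# and returns the prediction in the correlation's native output space.
# ---------------------------------------------------------------------------

def _chrastil(a, T, P, rho):
    # c2 = rho**a1 * exp(a2/T + a3)
    return _guarded_exp(a[0] * np.log(rho) + a[1] / T + a[2])


def _jouyban(a, T, P, rho):
    return _guarded_exp(
        a[0] + a[1] * rho + a[2] * P**2 + a[3] * P * T + a[4] * T / P
        + a[5] * np.log(rho)
    )


def _kumar_johnston(a, T, P, rho):
    rho_molar = rho / CO2_MOLAR_MASS  # kmol/m3
    return _guarded_exp(a[0] + a[1] * rho_molar + a[2] / T)


def _garlapati_madras(a, T, P, rho):
    return _guarded_exp(
        a[0] + (a[1] + a[2] * rho) * np.log(rho) + a[3] / T + a[4] * np.log(rho * T)
    )


def _bian(a, T, P, rho):
    # y2 = rho**(a1 + a2*rho) * exp(a3/T + a4*rho/T + a5)
    return _guarded_exp(
        (a[0] + a[1] * rho) * np.log(rho) + a[2] / T + a[3] * rho / T + a[4]
    )


def _bartle(a, T, P, rho, P_ref=0.1, rho_ref=700.0):
    # ln(y2*P/P_ref) = a1 + a2/T + a3*(rho - rho_ref)
    return (P_ref / P) * _guarded_exp(a[0] + a[1] / T + a[2] * (rho - rho_ref))


def _mendez_santiago_teja(a, T, P, rho):
    # T*ln(y2*P) = a1 + a2*rho + a3*T
    return _guarded_exp((a[0] + a[1] * rho + a[2] * T) / T) / P


def _sodeifian(a, T, P, rho):
    return _guarded_exp(
        a[0] + a[1] * P**2 / T + a[2] * np.log(rho * T) + a[3] * rho * np.log(rho)
        + a[4] * P * np.log(T) + a[5] * np.log(rho) / T
    )


def _tan(a, T, P, rho):
    return _guarded_exp(a[0] * np.log(rho * T) + a[1] * rho + a[2] / T + a[3])


def _gordillo(a, T, P, rho):
    return _guarded_exp(
        a[0] + a[1] * P + a[2] * P**2 + a[3] * P * T + a[4] * T + a[5] * T**2
    )


def _modified_arrhenius(a, T, P, rho):
    pre = a[0] * T + a[1] * rho + a[2]
    return pre * _guarded_exp(-a[3] / P) + a[4] * np.log(rho / T) + a[5]


_FORMS: dict[str, Callable] = {
    "chrastil": _chrastil,
    "jouyban": _jouyban,
    "kumar_johnston": _kumar_johnston,
    "garlapati_madras": _garlapati_madras,
    "bian": _bian,
    "bartle": _bartle,
    "mendez_santiago_teja": _mendez_santiago_teja,
    "sodeifian": _sodeifian,
    "tan": _tan,
    "gordillo": _gordillo,
    "modified_arrhenius": _modified_arrhenius,
}

CATALOG: dict[str, CorrelationSpec] = {
    "chrastil": CorrelationSpec("chrastil", 3, "mass_per_volume_c2"),
    "jouyban": CorrelationSpec("jouyban", 6),
    "kumar_johnston": CorrelationSpec("kumar_johnston", 3),
    "garlapati_madras": CorrelationSpec("garlapati_madras", 5),
    "bian": CorrelationSpec("bian", 5),
    "bartle": CorrelationSpec("bartle", 3, constants={"P_ref": 0.1, "rho_ref": 700.0}),
    "mendez_santiago_teja": CorrelationSpec("mendez_santiago_teja", 3),
    "sodeifian": CorrelationSpec("sodeifian", 6),
    "tan": CorrelationSpec("tan", 4),
    "gordillo": CorrelationSpec("gordillo", 6),
    "modified_arrhenius": CorrelationSpec("modified_arrhenius", 6),
}

MODEL_IDS = tuple(CATALOG)


def get_spec(model_id: str) -> CorrelationSpec:
    try:
        return CATALOG[model_id]
    except KeyError:
        raise CatalogueError(
            f"unknown correlation {model_id!r}; known: {', '.join(CATALOG)}"
        ) from None


def _validate_point(T, P, rho):
    T = np.asarray(T, dtype=float)
    P = np.asarray(P, dtype=float)
    rho = np.asarray(rho, dtype=float)
    if np.any(T <= 0) or np.any(P <= 0) or np.any(rho <= 0):
        raise ValueError("T, P and rho must all be positive")
    return T, P, rho


def evaluate(model_id, a, T, P, rho):
    """Evaluate a correlation in its native output space.

    Parameters
    ----------
    model_id : str
        Catalogue identifier.
    a : sequence or CoefficientSet
        Coefficient vector in natural units, length matching the spec.
    T, P, rho : array_like
        Temperature (K), pressure (MPa), pure CO2 density (kg/m3);
        broadcast together.

    Returns
    -------
    float or ndarray
        y2 (mole fraction) for every correlation except Chrastil, which
        returns c2 (kg/m3).  Overflowing points come back non-finite
        rather than raising, so optimisers can penalise them.
    """
    spec = get_spec(model_id)
    if isinstance(a, CoefficientSet):
        if a.model_id != model_id:
            raise ValueError(
                f"coefficient set is for {a.model_id!r}, not {model_id!r}"
            )
        a = a.a
    a = np.asarray(a, dtype=float)
    if a.shape != (spec.n_coeff,):
        raise ValueError(f"{model_id} takes {spec.n_coeff} coefficients, got {a.shape}")
    T, P, rho = _validate_point(T, P, rho)
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        out = _FORMS[model_id](a, T, P, rho)
    out = np.asarray(out, dtype=float)
    return float(out) if out.ndim == 0 else out


def evaluate_y2(model_id, a, T, P, rho, mw_drug=None):
    """Evaluate a correlation in mole-fraction space.

    Identical to :func:`evaluate` except that Chrastil's native c2 output is
    converted to y2, which requires the drug molar mass (kg/kmol).
    """
    out = evaluate(model_id, a, T, P, rho)
    if get_spec(model_id).output_space == "mass_per_volume_c2":
        out = chrastil_mass_to_mole(out, np.asarray(rho, dtype=float), mw_drug)
    return out
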