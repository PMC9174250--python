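"""Synthetic solubility datasets with the structure of the published studies.

The published solubility measurements live in the original experimental
papers and are not redistributed; this module generates stand-in datasets
with the same structure: a full temperature x pressure grid inside a
drug's published operating envelope, a pure-CO2 density attached to every
grid point, a noiseless solubility surface from one of the catalogue
correlations, and multiplicative lognormal measurement noise.

The density surface is a documented closed-form surrogate — a saturating
rational in pressure with a linear temperature shift — chosen only to be
smooth, strictly increasing in P, strictly decreasing in T and to span
realistic supercritical densities.  It is *not* a thermodynamic equation
of state; substitute a property-library callable for physical accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .correlations import CoefficientSet, evaluate_y2, get_spec
from .data import SolubilityDataset

__all__ = [
    "EnvelopeSpec",
    "NoiseSpec",
    "density_surrogate",
    "generate_dataset",
    "BUSULFAN_ENVELOPE",
]

_T_DOMAIN = (300.0, 360.0)
_P_DOMAIN = (8.0, 45.0)


@dataclass(frozen=True)
class EnvelopeSpec:
    """A rectangular (T, P) operating box with grid sizes.

    Defaults mirror a typical published study design: four isotherms over
    308-338 K crossed with eight pressures over 12-40 MPa (32 records).
    """

    T_min: float = 308.0
    T_max: float = 338.0
    P_min: float = 12.0
    P_max: float = 40.0
    n_T: int = 4
    n_P: int = 8

    def __post_init__(self):
        if not (self.T_min < self.T_max and self.P_min < self.P_max):
            raise ValueError("ranges must be non-degenerate (min < max)")
        if self.n_T < 2 or self.n_P < 2:
            raise ValueError("grid sizes must be at least 2")

    def grid(self):
        """Flattened full factorial (T, P) grid, pressure fastest."""
        T = np.linspace(self.T_min, self.T_max, self.n_T)
        P = np.linspace(self.P_min, self.P_max, self.n_P)
        TT, PP = np.meshgrid(T, P, indexing="ij")
        return TT.ravel(), PP.ravel()


#: Busulfan-style study envelope (4 isotherms x 8 pressures = 32 records).
BUSULFAN_ENVELOPE = EnvelopeSpec()


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise model.

    ``lognormal_multiplicative`` multiplies the noiseless solubility by
    exp(eps), eps ~ Normal(0, sigma^2) — the natural scatter model for a
    response spanning four orders of magnitude (additive noise would be
    non-physical at the low-solubility end).  sigma ~ 0.05 corresponds to
    a ~4% mean absolute relative error.
    """

    kind: str = "lognormal_multiplicative"
    sigma: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("none", "lognormal_multiplicative"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


def density_surrogate(T, P):
    """Surrogate pure-CO2 density (kg/m3) on the (T, P) operating domain.

    rho(T, P) = (1100 - 2*(T - 300)) * P / (P + 6)

    for T in [300, 360] K and P in [8, 45] MPa: strictly increasing in P,
    strictly decreasing in T, with range inside [300, 1000] kg/m3 over the
    published envelopes.  A documented stand-in, not an equation of state.
    """
    T = np.asarray(T, dtype=float)
    P = np.asarray(P, dtype=float)
    if np.any(T < _T_DOMAIN[0]) or np.any(T > _T_DOMAIN[1]):
        raise ValueError(f"T outside surrogate domain {_T_DOMAIN}")
    if np.any(P < _P_DOMAIN[0]) or np.any(P > _P_DOMAIN[1]):
        raise ValueError(f"P outside surrogate domain {_P_DOMAIN}")
    out = (1100.0 - 2.0 * (T - 300.0)) * P / (P + 6.0)
    return float(out) if out.ndim == 0 else out


def generate_dataset(
    model_id: str = "modified_arrhenius",
    coeffs=None,
    envelope: EnvelopeSpec = BUSULFAN_ENVELOPE,
    noise: NoiseSpec = NoiseSpec(),
    drug_id: str | None = None,
    rho_fn=density_surrogate,
    mw_drug: float | None = None,
) -> SolubilityDataset:
    """Generate one drug's synthetic dataset on a full (T, P) grid.

    y2 = evaluate(model, coeffs) * exp(eps) with eps ~ N(0, sigma^2) from
    the noise spec's seed.  Generation fails loudly (naming the offending
    grid points) if the noiseless surface is non-positive anywhere, since
    a mole fraction must be positive.
    """
    get_spec(model_id)
    if coeffs is None:
        raise ValueError("coeffs is required (CoefficientSet or vector)")
    if isinstance(coeffs, CoefficientSet):
        if drug_id is None:
            drug_id = coeffs.drug_id
        coeffs = coeffs.a
    if drug_id is None:
        drug_id = "synthetic"
    T, P = envelope.grid()
    rho = np.asarray(rho_fn(T, P), dtype=float)
    y_clean = np.asarray(
        evaluate_y2(model_id, coeffs, T, P, rho, mw_drug=mw_drug), dtype=float
    )
    bad = ~(np.isfinite(y_clean) & (y_clean > 0))
    if bad.any():
        pts = [f"(T={T[i]:g} K, P={P[i]:g} MPa)" for i in np.flatnonzero(bad)[:5]]
        raise ValueError(
            f"{model_id} yields non-positive/non-finite solubility at "
            f"{int(bad.sum())} grid points, e.g. {', '.join(pts)}"
        )
    if noise.kind == "none" or noise.sigma == 0.0:
        y2 = y_clean
    else:
        rng = np.random.default_rng(noise.seed)
        y2 = y_clean * np.exp(rng.normal(0.0, noise.sigma, size=y_clean.shape))
    return SolubilityDataset(
        drug_id=drug_id, T=T, P=P, rho=rho, y2=y2,
        source=f"synthetic:{model_id}",
    )
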