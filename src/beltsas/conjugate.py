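"""SEC-MALS protein-conjugate arithmetic for detergent-bound proteins.

Protein conjugate analysis decomposes the molar mass of a
protein–detergent complex, measured by multi-angle light scattering,
into a protein part and a modifier (detergent) part using
component-specific refractive-index increments (dn/dc).  From the
modifier mass and the detergent monomer molar mass the number of bound
detergent molecules follows directly.  A forward three-detector model
(light scattering, refractive index, UV) is provided for synthetic
round trips.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import constants as C


@dataclass
class ConjugateSpec:
    """dn/dc values and modifier monomer mass for conjugate analysis.

    Defaults: protein 0.1850 ml/g, DM detergent 0.1473 ml/g, DM
    monomer 482.6 g/mol.
    """

    dndc_protein: float = C.DNDC_PROTEIN
    dndc_modifier: float = C.DNDC_DM
    monomer_mass: float = C.DM_MOLAR_MASS      # g/mol
    extinction: float = 1.0                     # ml/(mg·cm), protein at 280 nm

    def __post_init__(self) -> None:
        if self.dndc_protein <= 0 or self.dndc_modifier <= 0:
            raise ValueError("dn/dc values must be positive")
        if self.monomer_mass <= 0:
            raise ValueError("monomer mass must be positive")


@dataclass
class ConjugateResult:
    """Mass decomposition of a protein–modifier complex."""

    mw_total: float      # kDa
    mw_protein: float    # kDa
    mw_modifier: float   # kDa
    modifier_fraction: float  # weight fraction, 0–1
    bound_monomers: int

    def as_dict(self) -> dict:
        return {
            "mw_total_kda": self.mw_total,
            "mw_protein_kda": self.mw_protein,
            "mw_modifier_kda": self.mw_modifier,
            "modifier_weight_percent": 100.0 * self.modifier_fraction,
            "bound_monomers": self.bound_monomers,
        }


def conjugate_split(
    mw_total: float, mw_protein: float, spec: ConjugateSpec | None = None
) -> ConjugateResult:
    """Split a complex mass (kDa) into protein and modifier parts.

    The modifier mass is MW_total − MW_protein; its weight fraction is
    MW_modifier / MW_total.  Bound monomer count uses the spec's
    monomer mass (nearest-integer rounding).
    """
    if mw_protein <= 0:
        raise ValueError("protein mass must be positive")
    if mw_total < mw_protein:
        raise ValueError("total mass below protein mass")
    spec = spec or ConjugateSpec()
    mw_modifier = mw_total - mw_protein
    return ConjugateResult(
        mw_total=mw_total,
        mw_protein=mw_protein,
        mw_modifier=mw_modifier,
        modifier_fraction=mw_modifier / mw_total,
        bound_monomers=bound_monomers(mw_modifier, spec),
    )


def bound_monomers(mw_modifier: float, spec: ConjugateSpec | None = None) -> int:
    """Number of bound modifier monomers: MW_modifier (kDa → Da) divided
    by the monomer molar mass, rounded to the nearest integer."""
    spec = spec or ConjugateSpec()
    if mw_modifier < 0:
        raise ValueError("modifier mass must be >= 0")
    return int(round(mw_modifier * 1000.0 / spec.monomer_mass))


def mixture_dndc(fraction_protein: float, spec: ConjugateSpec | None = None) -> float:
    """dn/dc of a two-component conjugate by weight-fraction mixing:
    w_p·(dn/dc)_protein + (1 − w_p)·(dn/dc)_modifier."""
    if not 0.0 <= fraction_protein <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    spec = spec or ConjugateSpec()
    return (fraction_protein * spec.dndc_protein
            + (1.0 - fraction_protein) * spec.dndc_modifier)


def conjugate_roundtrip(
    signals: dict, spec: ConjugateSpec | None = None
) -> ConjugateResult:
    """Invert three-detector signals back to a mass decomposition.

    Expects the signal dictionary produced by the synthetic MALS
    generator: 'ls' ∝ c·MW·(dn/dc)², 'ri' ∝ c·(dn/dc), 'uv' ∝ c·w_p·ε,
    with unit instrument constants.  Solves for concentration, protein
    weight fraction and total mass; noiseless signals invert exactly.
    """
    spec = spec or ConjugateSpec()
    ls, ri, uv = signals["ls"], signals["ri"], signals["uv"]
    if uv <= 0:
        raise ValueError("zero UV signal: protein fraction undetermined")
    dp, dm = spec.dndc_protein, spec.dndc_modifier
    c_wp = uv / spec.extinction               # c · w_p  (mg/ml)
    c = (ri - c_wp * (dp - dm)) / dm          # from ri = c(w_p dp + (1-w_p) dm)
    if c <= 0 or c < c_wp:
        raise ValueError("inconsistent signals: negative inferred mass")
    wp = c_wp / c
    dndc = mixture_dndc(wp, spec)
    mw_total = ls / (c * dndc**2)             # kDa with unit LS constant
    mw_protein = wp * mw_total
    if mw_total <= 0 or mw_protein <= 0:
        raise ValueError("inconsistent signals: negative inferred mass")
    return conjugate_split(mw_total, mw_protein, spec)
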