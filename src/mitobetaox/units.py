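"""Compartment geometry and flux-unit conversions.

Internal model fluxes are concentrations per second (mM s⁻¹) referenced to
the mitochondrial matrix water volume.  The experimental literature
reports specific fluxes per mass of mitochondrial protein
(µmol / nmol / pmol min⁻¹ mg⁻¹).  The two scales are related through the
mitochondrial volume per mg of protein: at the reference value of
1 µl mg⁻¹, 1 µmol min⁻¹ mg⁻¹ = 1 µmol µl⁻¹ min⁻¹ = 1 M min⁻¹
= 1000/60 mM s⁻¹ ≈ 16.67 mM s⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class CompartmentLayout:
    """Geometry of the two-compartment system.

    Parameters
    ----------
    matrix_volume_fraction, extra_matrix_volume_fraction
        Relative water volumes of the two compartments (their ratio is
        what enters cross-membrane flux bookkeeping).
    mito_volume_per_mg_protein
        Mitochondrial matrix volume per mg of mitochondrial protein,
        in µl mg⁻¹ (reference value 1.0).
    membrane_capacitance
        Inner-membrane capacitance in mM mV⁻¹ (charge concentration per
        volt, referenced to matrix volume).
    """

    matrix_volume_fraction: float = 1.0
    extra_matrix_volume_fraction: float = 10.0
    mito_volume_per_mg_protein: float = 1.0
    membrane_capacitance: float = 1.812e-3

    def __post_init__(self) -> None:
        for field in (
            "matrix_volume_fraction",
            "extra_matrix_volume_fraction",
            "mito_volume_per_mg_protein",
            "membrane_capacitance",
        ):
            if getattr(self, field) <= 0:
                raise ValueError(f"{field} must be strictly positive")

    @property
    def volume_ratio_extra_to_matrix(self) -> float:
        return self.extra_matrix_volume_fraction / self.matrix_volume_fraction

    @property
    def flux_conversion_factor(self) -> float:
        """mM s⁻¹ per µmol min⁻¹ mg⁻¹ (≈16.67 at 1 µl mg⁻¹)."""
        return 1000.0 / (60.0 * self.mito_volume_per_mg_protein)


# scale of each supported unit relative to µmol min⁻¹ mg⁻¹ or mM s⁻¹
_PER_MG_UNITS = {
    "umol/min/mg": 1.0,
    "nmol/min/mg": 1e-3,
    "pmol/min/mg": 1e-6,
}
_PER_VOLUME_UNITS = {
    "mM/s": 1.0,
    "uM/s": 1e-3,
}


def convert_flux_units(
    value: float,
    from_units: str,
    to_units: str,
    layout: CompartmentLayout | None = None,
) -> float:
    """Convert a flux between specific (per-mg-protein) and volumetric units.

    Supported units: ``umol/min/mg``, ``nmol/min/mg``, ``pmol/min/mg``,
    ``mM/s``, ``uM/s``.  The per-mg ↔ per-volume bridge uses the layout's
    ``mito_volume_per_mg_protein`` (default 1 µl mg⁻¹, giving the factor
    1 µmol min⁻¹ mg⁻¹ = 16.67 mM s⁻¹).
    """
    layout = layout or CompartmentLayout()

    def classify(u: str) -> tuple[str, float]:
        if u in _PER_MG_UNITS:
            return "mg", _PER_MG_UNITS[u]
        if u in _PER_VOLUME_UNITS:
            return "vol", _PER_VOLUME_UNITS[u]
        raise ValueError(f"unsupported flux unit {u!r}")

    from_kind, from_scale = classify(from_units)
    to_kind, to_scale = classify(to_units)

    # express in the base unit of the source family
    base = value * from_scale
    if from_kind == to_kind:
        return base / to_scale
    if from_kind == "mg":  # µmol/min/mg -> mM/s
        return base * layout.flux_conversion_factor / to_scale
    # mM/s -> µmol/min/mg
    return base / layout.flux_conversion_factor / to_scale
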