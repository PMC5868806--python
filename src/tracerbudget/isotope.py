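"""Unit-safe arithmetic from delta notation to tracer fluxes.

Isotope-ratio mass spectrometers report enrichment in delta notation,

    deltaX (permil) = (R_sample / R_ref - 1) * 1000,

where ``R`` is the heavy:light isotope ratio and ``R_ref`` the ratio of the
international reference material (VPDB for carbon, atmospheric N2 for
nitrogen).  Tracer bookkeeping is done on the atomic-fraction scale,
``F = R / (R + 1)``, because atomic fractions — unlike delta values — mix
linearly with pool sizes.  The excess fraction ``E = F_sample - F_control``
above the natural-abundance background is proportional to the amount of
label in a pool; dividing by the atom-fraction enrichment of the labeled
food converts label to food-derived element, and normalizing by biomass and
time yields the specific uptake rates compared across taxa.

All pool amounts are micromoles, biomasses millimoles, durations days.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "R_REF",
    "ReferenceRatio",
    "FoodSource",
    "Specimen",
    "RateRecord",
    "delta_to_ratio",
    "ratio_to_fraction",
    "fraction_to_delta",
    "delta_to_fraction",
    "excess_fraction",
    "tracer_uptake",
    "biomass_normalized_rate",
    "respiration_rate",
    "calcification_uptake",
]

#: Heavy:light isotope ratio of the international reference material,
#: keyed by element symbol (C: VPDB; N: atmospheric N2).
R_REF: dict[str, float] = {"C": 0.0111797, "N": 0.0036765}


def _check_element(element: str) -> str:
    if element not in R_REF:
        raise ValueError(
            f"unknown element {element!r}; expected one of {sorted(R_REF)}"
        )
    return element


@dataclass(frozen=True)
class ReferenceRatio:
    """Reference heavy:light ratio for one element."""

    element: str
    r_ref: float

    @classmethod
    def for_element(cls, element: str) -> "ReferenceRatio":
        return cls(element, R_REF[_check_element(element)])


@dataclass(frozen=True)
class FoodSource:
    """A labeled diet component added to an incubation chamber.

    Parameters
    ----------
    name
        Identifier, e.g. ``"algae"`` or ``"bacteria"``.
    labeled_element
        Which element carries the heavy label in this treatment, ``"C"``
        or ``"N"``.
    enrichment
        Atom fraction (0-1] of the heavy isotope in the labeled element of
        the food.  All excess tracer amounts are divided by this value to
        convert label to food-derived element.
    cn_ratio
        Molar C:N ratio of the food.
    added_c, added_n
        Total amount added per chamber over the experiment (umol).
    """

    name: str
    labeled_element: str
    enrichment: float
    cn_ratio: float
    added_c: float
    added_n: float = 0.0

    def __post_init__(self) -> None:
        _check_element(self.labeled_element)
        if not 0.0 < self.enrichment <= 1.0:
            raise ValueError(
                f"food {self.name!r}: enrichment must be in (0, 1], "
                f"got {self.enrichment}"
            )
        if self.cn_ratio <= 0:
            raise ValueError(f"food {self.name!r}: cn_ratio must be > 0")
        if self.added_c < 0 or self.added_n < 0:
            raise ValueError(f"food {self.name!r}: added amounts must be >= 0")


@dataclass(frozen=True)
class Specimen:
    """An organism's elemental pools.

    Tissue pools are mmol of organic C or N; ``skeleton_c`` is mmol
    inorganic (carbonate) C and is absent for non-calcifying taxa.
    """

    taxon: str
    tissue_c: float
    tissue_n: float
    skeleton_c: float | None = None

    def __post_init__(self) -> None:
        if self.tissue_c <= 0 or self.tissue_n <= 0:
            raise ValueError(f"{self.taxon}: tissue pools must be > 0")
        if self.skeleton_c is not None and self.skeleton_c <= 0:
            raise ValueError(f"{self.taxon}: skeleton_c must be > 0 when present")


@dataclass(frozen=True)
class RateRecord:
    """One biomass-normalized tracer flux.

    ``value`` is umol tracer per mmol biomass per day for incorporation and
    respiration; calcification is kept in the same internal units (per mmol
    skeleton C) and only scaled to nmol at the reporting layer.
    """

    kind: str  # incorporation | respiration | calcification
    element: str
    value: float
    taxon: str
    food_source: str
    treatment: str
    replicate: object
    composition: str = ""
    flagged_negative: bool = field(default=False, compare=False)


def delta_to_ratio(
    delta_permil: float, element: str, ref: ReferenceRatio | None = None
) -> float:
    """Invert delta notation to the heavy:light isotope ratio.

    ``R = R_ref * (delta/1000 + 1)``.  Deltas at or below -1000 permil would
    imply a non-positive heavy-isotope ratio and are rejected.
    """
    if ref is None:
        ref = ReferenceRatio.for_element(element)
    elif ref.element != element:
        raise ValueError(
            f"delta value is for element {element!r} but the reference "
            f"ratio is for {ref.element!r}"
        )
    if delta_permil <= -1000.0:
        raise ValueError(
            f"delta = {delta_permil} permil implies a non-positive isotope ratio"
        )
    return ref.r_ref * (delta_permil / 1000.0 + 1.0)


def ratio_to_fraction(r: float) -> float:
    """Atomic fraction of the heavy isotope, ``F = R / (R + 1)``."""
    if r <= 0:
        raise ValueError(f"isotope ratio must be > 0, got {r}")
    return r / (r + 1.0)


def fraction_to_delta(f: float, element: str) -> float:
    """Delta value (permil) of an atomic fraction; inverse of the chain
    ``ratio_to_fraction(delta_to_ratio(.))``."""
    if not 0.0 < f < 1.0:
        raise ValueError(f"atomic fraction must be in (0, 1), got {f}")
    r = f / (1.0 - f)
    return (r / R_REF[_check_element(element)] - 1.0) * 1000.0


def delta_to_fraction(delta_permil: float, element: str) -> float:
    """Convenience chain: delta -> ratio -> atomic fraction."""
    return ratio_to_fraction(delta_to_ratio(delta_permil, element))


def excess_fraction(f_sample: float, f_control: float) -> float:
    """Atom fraction above background, ``E = F_sample - F_control``.

    Returned signed: small negative values from measurement noise in
    unlabeled samples are preserved (clamping is a reporting policy, not an
    arithmetic one — zeroing here would bias means upward).
    """
    for name, f in (("sample", f_sample), ("control", f_control)):
        if not 0.0 < f < 1.0:
            raise ValueError(f"{name} atomic fraction must be in (0, 1), got {f}")
    return f_sample - f_control


def tracer_uptake(excess: float, pool_umol: float, food: FoodSource) -> float:
    """Food-derived element in a pool (umol).

    ``E * pool / enrichment``: the excess label amount scaled up by the
    food's atom-fraction enrichment.
    """
    if pool_umol <= 0:
        raise ValueError(f"pool size must be > 0 umol, got {pool_umol}")
    if food.enrichment <= 0:
        raise ZeroDivisionError(
            f"food {food.name!r} has zero atom-fraction enrichment; cannot "
            "convert excess label to food-derived element"
        )
    return excess * pool_umol / food.enrichment


def biomass_normalized_rate(
    uptake_umol: float, biomass_mmol: float, duration_d: float
) -> float:
    """Specific uptake rate, umol tracer per mmol biomass per day."""
    if biomass_mmol <= 0:
        raise ValueError(f"biomass must be > 0 mmol, got {biomass_mmol}")
    if duration_d <= 0:
        raise ValueError(f"duration must be > 0 d, got {duration_d}")
    return uptake_umol / biomass_mmol / duration_d


def respiration_rate(
    f_end: float,
    f_start: float,
    dic_umol_per_l: float,
    volume_l: float,
    food: FoodSource,
    duration_d: float,
    chamber_biomass_mmol: float,
) -> float:
    """Respiration of labeled food from DIC enrichment in a closed chamber.

    The excess atomic fraction accumulated in the dissolved inorganic carbon
    pool over the closed incubation is scaled by the DIC inventory
    (concentration x volume), converted to food carbon via the food's
    enrichment, divided by the incubation time, and normalized to the total
    organic C biomass in the chamber (all specimens present).
    """
    if dic_umol_per_l <= 0 or volume_l <= 0:
        raise ValueError("DIC concentration and chamber volume must be > 0")
    excess = excess_fraction(f_end, f_start)
    dic_tracer = tracer_uptake(excess, dic_umol_per_l * volume_l, food)
    return biomass_normalized_rate(dic_tracer, chamber_biomass_mmol, duration_d)


def calcification_uptake(
    total_tracer_umol: float, organic_tracer_umol: float
) -> float:
    """Label routed into the carbonate skeleton (umol C).

    Whole-sample (organic + skeleton) tracer minus organic-fraction tracer.
    May be slightly negative from measurement noise; the sign is preserved.
    """
    return total_tracer_umol - organic_tracer_umol
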