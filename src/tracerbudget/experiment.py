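"""Chamber-level synthesis: net growth efficiency, stoichiometry, carbon budget.

Per-specimen tracer rates are integrated back to whole-experiment amounts
under the assumption that rates were constant over the feeding period, and
closed against the amount of food added to each chamber.  The budget's
closure term ("unaccounted") is defined as added food minus tissue
incorporation, respiration and calcification — it absorbs everything the
experiment does not measure (uneaten food, dissolved organic release, cell
shedding).
"""

from __future__ import annotations

from dataclasses import dataclass

from .isotope import FoodSource, Specimen

__all__ = [
    "Chamber",
    "BudgetRow",
    "NGEResult",
    "StoichRecord",
    "net_growth_efficiency",
    "carbon_budget",
    "total_processed",
    "fraction_accounted",
    "stoichiometric_uptake",
]


@dataclass(frozen=True)
class Chamber:
    """One incubation chamber of the factorial design."""

    treatment: str
    composition: str  # e.g. "coral", "sponge", "coral+sponge"
    replicate: object
    volume_l: float
    specimens: tuple[Specimen, ...]
    foods: tuple[FoodSource, ...]
    feeding_days: float = 10.0

    def __post_init__(self) -> None:
        taxa = sorted({s.taxon for s in self.specimens})
        expected = sorted(self.composition.split("+"))
        if taxa != expected:
            raise ValueError(
                f"composition {self.composition!r} inconsistent with "
                f"specimens {taxa}"
            )

    @property
    def tissue_c_mmol(self) -> float:
        """Total organic C biomass in the chamber (mmol)."""
        return sum(s.tissue_c for s in self.specimens)


@dataclass(frozen=True)
class BudgetRow:
    """Whole-experiment carbon budget for one taxon x food source (umol C).

    ``unaccounted`` is always the exact difference
    ``added - (tissue + respiration + calcification)``.
    """

    taxon: str
    food_source: str
    tissue: float
    respiration: float
    calcification: float
    added: float
    unaccounted: float
    flagged_negative: bool = False


@dataclass(frozen=True)
class NGEResult:
    taxon: str
    food_source: str
    value: float


@dataclass(frozen=True)
class StoichRecord:
    """Molar C:N of food incorporation, with the reference ratios it is
    compared against (food and bulk tissue)."""

    taxon: str
    food_source: str
    group: str
    uptake_cn: float | None
    tissue_cn: float
    food_cn: float


def net_growth_efficiency(
    tissue_rate: float, respiration_rate: float, taxon: str = "", food_source: str = ""
) -> NGEResult:
    """NGE = tissue incorporation / (tissue incorporation + respiration).

    Defined only when the denominator is positive; meaningful only for
    single-species chambers where respiration is attributable to one taxon.
    """
    denom = tissue_rate + respiration_rate
    if denom <= 0:
        return NGEResult(taxon, food_source, float("nan"))
    return NGEResult(taxon, food_source, tissue_rate / denom)


def carbon_budget(
    tissue_rate: float,
    respiration_rate: float,
    calcification_rate: float,
    biomass_mmol: float,
    skeleton_mmol: float,
    feeding_days: float,
    food: FoodSource,
    taxon: str = "",
) -> BudgetRow:
    """Integrate daily rates over the feeding period and close the budget.

    Rates are umol per mmol biomass per day; tissue and respiration scale on
    the organic-C pool, calcification on the skeleton-C pool.  Negative
    components (possible from noisy excess measurements) are flagged, never
    silently dropped.
    """
    if feeding_days <= 0:
        raise ValueError("feeding_days must be > 0")
    tissue = tissue_rate * biomass_mmol * feeding_days
    respiration = respiration_rate * biomass_mmol * feeding_days
    calcification = calcification_rate * skeleton_mmol * feeding_days
    unaccounted = food.added_c - (tissue + respiration + calcification)
    flagged = min(tissue, respiration, calcification, unaccounted) < 0
    return BudgetRow(
        taxon=taxon,
        food_source=food.name,
        tissue=tissue,
        respiration=respiration,
        calcification=calcification,
        added=food.added_c,
        unaccounted=unaccounted,
        flagged_negative=flagged,
    )


def total_processed(budget: BudgetRow) -> float:
    """Total carbon processed by the organism: incorporation + respiration
    + calcification (umol C)."""
    return budget.tissue + budget.respiration + budget.calcification


def fraction_accounted(budget: BudgetRow) -> float:
    """Fraction of the added food carbon recovered in measured fates."""
    if budget.added <= 0:
        raise ValueError("added food must be > 0")
    return total_processed(budget) / budget.added


def stoichiometric_uptake(
    c_rate_mean: float,
    n_rate_mean: float,
    food: FoodSource,
    tissue_cn: float,
    taxon: str = "",
    group: str = "",
) -> StoichRecord:
    """Molar C:N of incorporation from mean C- and N-uptake rates.

    C and N uptake of a given food are measured in complementary treatments
    (on different specimens), so the ratio is taken on treatment means and
    only broad-scale differences are interpretable.  Undefined (None) when
    the mean N rate is not positive.
    """
    uptake_cn = c_rate_mean / n_rate_mean if n_rate_mean > 0 else None
    return StoichRecord(
        taxon=taxon,
        food_source=food.name,
        group=group,
        uptake_cn=uptake_cn,
        tissue_cn=tissue_cn,
        food_cn=food.cn_ratio,
    )
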