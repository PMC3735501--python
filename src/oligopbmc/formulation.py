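"""Incubation-mixture arithmetic for oligosaccharide cell-culture experiments.

Commercial oligosaccharide preparations are not pure: a galacto-oligosaccharide
(GOS) syrup carries substantial glucose, lactose and water, a long-chain
fructo-oligosaccharide (FOS) product carries maltodextrin, and a pectin-derived
acidic oligosaccharide (AOS) powder carries monomers and moisture.  To dose a
culture at a nominal oligosaccharide concentration one must weigh in *more*
product than oligosaccharide, and the co-carried sugars come along for the
ride.  This module does that bookkeeping: given target oligosaccharide masses
and product compositions it computes the full per-10-ml composition of an
incubation mixture, supports serial dilution, and converts Limulus-assay
endotoxin activities between solids concentrations and to nanogram-of-LPS
ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal

__all__ = [
    "ProductSpec",
    "IncubationComposition",
    "EndotoxinMeasurement",
    "DEFAULT_PRODUCTS",
    "round_mass",
    "compose_incubation",
    "dilute",
    "extrapolate_endotoxin",
    "eu_to_ng_range",
]

_FRACTION_SUM_TOL = 1e-6

#: Co-carried (non-oligosaccharide) components tracked per product.
CO_COMPONENTS = ("glucose", "lactose", "maltodextrin", "monomers", "moisture")


def round_mass(mass_mg: float, ndigits: int = 2) -> float:
    """Round a mass to `ndigits` decimals, half away from zero.

    Python's builtin ``round`` uses banker's rounding; reported compositions
    follow the conventional half-up rule (e.g. 62.225 -> 62.23).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(mass_mg)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ProductSpec:
    """Mass-fraction composition of a commercial carbohydrate product.

    Fractions are on a total-product basis and must sum to at most 1 (a
    shortfall is tolerated: trace components need not be itemised).
    """

    name: str
    oligo_fraction: float
    glucose_fraction: float = 0.0
    lactose_fraction: float = 0.0
    maltodextrin_fraction: float = 0.0
    monomer_fraction: float = 0.0
    moisture_fraction: float = 0.0

    def __post_init__(self) -> None:
        fracs = {
            "oligo_fraction": self.oligo_fraction,
            "glucose_fraction": self.glucose_fraction,
            "lactose_fraction": self.lactose_fraction,
            "maltodextrin_fraction": self.maltodextrin_fraction,
            "monomer_fraction": self.monomer_fraction,
            "moisture_fraction": self.moisture_fraction,
        }
        for key, value in fracs.items():
            if value < 0:
                raise ValueError(f"{self.name}: {key} must be >= 0, got {value}")
        total = sum(fracs.values())
        if total > 1 + _FRACTION_SUM_TOL:
            raise ValueError(
                f"{self.name}: mass fractions sum to {total:.6f} > 1"
            )

    def co_fraction(self, component: str) -> float:
        return getattr(self, _CO_ATTR[component])


_CO_ATTR = {
    "glucose": "glucose_fraction",
    "lactose": "lactose_fraction",
    "maltodextrin": "maltodextrin_fraction",
    "monomers": "monomer_fraction",
    "moisture": "moisture_fraction",
}

#: Nominal product compositions: GOS syrup ~45% GOS / 14% glucose / 16%
#: lactose / 25% water; FOS preparation ~96.5% FOS / 3.5% maltodextrin; AOS
#: preparation ~85.5% AOS / 7.25% monomers / 7.25% moisture.
DEFAULT_PRODUCTS: dict[str, ProductSpec] = {
    "GOS": ProductSpec(
        name="GOS syrup",
        oligo_fraction=0.45,
        glucose_fraction=0.14,
        lactose_fraction=0.16,
        moisture_fraction=0.25,
    ),
    "FOS": ProductSpec(
        name="long-chain FOS",
        oligo_fraction=0.965,
        maltodextrin_fraction=0.035,
    ),
    "AOS": ProductSpec(
        name="pectin-derived AOS",
        oligo_fraction=0.855,
        monomer_fraction=0.0725,
        moisture_fraction=0.0725,
    ),
}


@dataclass(frozen=True)
class IncubationComposition:
    """Full composition of one incubation mixture, as mg per 10 ml of medium.

    ``oligo_masses_mg`` holds the target oligosaccharide masses per component
    (GOS/FOS/AOS); ``co_masses_mg`` the co-carried sugars and moisture summed
    across products.  Maltodextrin and monomers are tracked but never counted
    toward the oligosaccharide total.
    """

    oligo_masses_mg: dict[str, float] = field(default_factory=dict)
    co_masses_mg: dict[str, float] = field(default_factory=dict)
    product_masses_mg: dict[str, float] = field(default_factory=dict)
    volume_ml: float = 10.0

    def __post_init__(self) -> None:
        for name, mapping in (
            ("oligo", self.oligo_masses_mg),
            ("co-carried", self.co_masses_mg),
            ("product", self.product_masses_mg),
        ):
            for comp, mass in mapping.items():
                if mass < 0:
                    raise ValueError(f"negative {name} mass for {comp}: {mass}")

    @property
    def total_oligo_mass_mg(self) -> float:
        return sum(self.oligo_masses_mg.values())

    @property
    def total_oligo_concentration_pct(self) -> float:
        """Total oligosaccharide concentration in % w/v (g per 100 ml)."""
        return self.total_oligo_mass_mg / self.volume_ml / 10.0

    def rounded(self, ndigits: int = 2) -> "IncubationComposition":
        """Composition with all masses rounded half-up to `ndigits` decimals."""
        return IncubationComposition(
            oligo_masses_mg={k: round_mass(v, ndigits) for k, v in self.oligo_masses_mg.items()},
            co_masses_mg={k: round_mass(v, ndigits) for k, v in self.co_masses_mg.items()},
            product_masses_mg={k: round_mass(v, ndigits) for k, v in self.product_masses_mg.items()},
            volume_ml=self.volume_ml,
        )


@dataclass(frozen=True)
class EndotoxinMeasurement:
    """A Limulus amebocyte lysate (LAL) endotoxin activity for one solution.

    The assay's quantifiable window per dilution is 0.1-1 EU/ml; activities of
    concentrated solutions are obtained by measuring a dilution and scaling.
    """

    solution_label: str
    concentration_pct: float
    endotoxin_eu_per_ml: float
    sd_eu_per_ml: float | None = None

    def __post_init__(self) -> None:
        if self.endotoxin_eu_per_ml < 0:
            raise ValueError("endotoxin activity must be >= 0")
        if self.sd_eu_per_ml is not None and self.sd_eu_per_ml < 0:
            raise ValueError("endotoxin SD must be >= 0")


def compose_incubation(
    target_oligo_masses_mg: dict[str, float],
    products: dict[str, ProductSpec] | None = None,
) -> IncubationComposition:
    """Compute the full mixture needed to hit target oligosaccharide masses.

    For each component the required product mass is ``target / oligo_fraction``
    and every co-carried component contributes ``product mass x fraction``.

    Parameters
    ----------
    target_oligo_masses_mg
        Target oligosaccharide mass in mg per 10 ml, keyed by component
        (e.g. ``{"GOS": 180, "FOS": 20}`` for a 9:1 blend at 2% w/v).
    products
        Product compositions keyed by component; defaults to the nominal
        commercial products in :data:`DEFAULT_PRODUCTS`.
    """
    if products is None:
        products = DEFAULT_PRODUCTS
    oligo: dict[str, float] = {}
    co: dict[str, float] = {comp: 0.0 for comp in CO_COMPONENTS}
    product_masses: dict[str, float] = {}
    for component, target in target_oligo_masses_mg.items():
        if target < 0:
            raise ValueError(f"target mass for {component} must be >= 0")
        spec = products.get(component)
        if spec is None:
            raise KeyError(f"no product specification for component {component!r}")
        if spec.oligo_fraction <= 0:
            raise ValueError(
                f"product for {component!r} has zero oligosaccharide fraction; "
                "cannot compose"
            )
        product_mass = target / spec.oligo_fraction
        oligo[component] = target
        product_masses[component] = product_mass
        for co_comp in CO_COMPONENTS:
            co[co_comp] += product_mass * spec.co_fraction(co_comp)
    co = {k: v for k, v in co.items() if v > 0}
    return IncubationComposition(
        oligo_masses_mg=oligo, co_masses_mg=co, product_masses_mg=product_masses
    )


def dilute(comp: IncubationComposition, factor: float) -> IncubationComposition:
    """Dilute a composition by `factor` (>= 1): every mass divided by factor.

    Working solutions at 1% and 0.5% are obtained from the 2% stock by serial
    1:1 dilution in medium, i.e. factors 2 and 4.
    """
    if factor < 1:
        raise ValueError(
            f"dilution factor must be >= 1 (concentration cannot increase), got {factor}"
        )
    scale = 1.0 / factor
    return replace(
        comp,
        oligo_masses_mg={k: v * scale for k, v in comp.oligo_masses_mg.items()},
        co_masses_mg={k: v * scale for k, v in comp.co_masses_mg.items()},
        product_masses_mg={k: v * scale for k, v in comp.product_masses_mg.items()},
    )


def extrapolate_endotoxin(measured: EndotoxinMeasurement, target_pct: float) -> float:
    """Scale an endotoxin activity linearly with solids concentration.

    A 2% solution carries twice the contaminating endotoxin of the 1% solution
    it was measured in (activity scales with the amount of dissolved product).
    """
    if measured.concentration_pct <= 0:
        raise ValueError("measured concentration must be > 0 to extrapolate")
    return measured.endotoxin_eu_per_ml * target_pct / measured.concentration_pct


def eu_to_ng_range(
    eu_per_ml: float,
    eu_per_ng_low: float = 5.0,
    eu_per_ng_high: float = 10.0,
) -> tuple[float, float]:
    """Convert an endotoxin activity to an LPS mass range in ng/ml.

    Follows the reporting convention of the source assay sheets, which state
    the potency of the LPS preparation as 1 ng = 5-10 EU and derive the mass
    range as ``(eu_per_ml * 5, eu_per_ml * 10)``.  Note this multiplies where
    a strict unit analysis of "EU per ng" would divide; the multiplicative
    convention is kept deliberately because it is what the published ranges
    follow (e.g. 1.92 EU/ml reported as 9.6-19.2 ng/ml).  See docs/methods.md.
    """
    if eu_per_ml < 0:
        raise ValueError("endotoxin activity must be >= 0")
    return eu_per_ml * eu_per_ng_low, eu_per_ml * eu_per_ng_high
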