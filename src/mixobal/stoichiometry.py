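"""Compound registry, degree-of-reduction and C-mol yield/balance arithmetic.

All bookkeeping is done on a carbon-mole (C-mol) basis: one mole of carbon
atoms of a compound.  The degree of reduction gamma of a compound is the
number of electrons it releases per C-mol on complete oxidation to CO2,
H2O and NH3 (ammonia nitrogen basis):

    gamma = 4 + h/c - 2 o/c - 3 n/c

so CO2 carries 0, carbohydrates 4, n-butanol 6 and a standard biomass
CH1.8O0.5N0.2 carries 4.2.  Molecular hydrogen is carbon free and carries
2 electrons per mole.

Apparent yields divide by the carbon of the sugar substrate only; this is
what makes values above the heterotrophic ceiling of 2/3 diagnostic of
inorganic carbon capture in a mixotrophic fermentation.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

__all__ = [
    "ATOMIC_MASS",
    "CompoundSpec",
    "CompoundRegistry",
    "YieldSet",
    "BalanceResult",
    "InorganicAttribution",
    "parse_formula",
    "degree_of_reduction",
    "cmol_yield",
    "carbon_balance",
    "electron_balance",
    "theoretical_max_yield",
    "excess_recovery",
    "attribute_inorganic_carbon",
    "load_default_registry",
]

ATOMIC_MASS = {"C": 12.011, "H": 1.008, "O": 15.999, "N": 14.007}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*\.?\d*)")


def parse_formula(formula: str) -> dict[str, float]:
    """Parse an elemental formula such as ``C4H10O`` or ``CH1.8O0.5N0.2``.

    Subscripts may be fractional (biomass pseudo-formulas).  Only C, H, O
    and N are accepted; anything else raises ``ValueError``.
    """
    counts: dict[str, float] = {"C": 0.0, "H": 0.0, "O": 0.0, "N": 0.0}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        pos = match.end()
        element, count = match.group(1), match.group(2)
        if element not in ATOMIC_MASS:
            raise ValueError(f"unknown element {element!r} in formula {formula!r}")
        counts[element] += float(count) if count else 1.0
    if pos != len(formula) or pos == 0:
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


@dataclass(frozen=True)
class CompoundSpec:
    """A fermentation species with its elemental composition.

    Parameters
    ----------
    name : str
        Registry identifier (lower case by convention).
    atoms : mapping
        Moles of C, H, O, N per mole of compound (fractions allowed).
    molar_mass : float
        g/mol; must agree with the composition within 1 %.
    role : str
        One of ``substrate``, ``product``, ``biomass``, ``gas``.
    """

    name: str
    atoms: Mapping[str, float]
    molar_mass: float
    role: str

    _ROLES = ("substrate", "product", "biomass", "gas")

    def __post_init__(self) -> None:
        if self.role not in self._ROLES:
            raise ValueError(f"role must be one of {self._ROLES}, got {self.role!r}")
        atoms = {el: float(self.atoms.get(el, 0.0)) for el in ATOMIC_MASS}
        if any(v < 0 for v in atoms.values()):
            raise ValueError("atom counts must be nonnegative")
        object.__setattr__(self, "atoms", atoms)
        if self.molar_mass <= 0:
            raise ValueError("molar_mass must be positive")
        computed = sum(ATOMIC_MASS[el] * n for el, n in atoms.items())
        if computed <= 0:
            raise ValueError(f"{self.name}: empty formula")
        if abs(computed - self.molar_mass) > 0.01 * self.molar_mass:
            raise ValueError(
                f"{self.name}: molar mass {self.molar_mass} inconsistent with "
                f"composition ({computed:.3f})"
            )
        if atoms["C"] == 0 and self.role != "gas":
            raise ValueError(f"{self.name}: carbon-free species must have role 'gas'")

    @property
    def carbons(self) -> float:
        return self.atoms["C"]

    @property
    def cmol_per_gram(self) -> float:
        return self.carbons / self.molar_mass

    @classmethod
    def from_formula(cls, name: str, formula: str, molar_mass: float, role: str) -> "CompoundSpec":
        return cls(name=name, atoms=parse_formula(formula), molar_mass=molar_mass, role=role)


def degree_of_reduction(compound: CompoundSpec) -> float:
    """Electrons available per C-mol (per mol for carbon-free H2/N2).

    Ammonia nitrogen basis: gamma = 4 + h/c - 2 o/c - 3 n/c.  CO2 returns
    exactly 0.  Among carbon-free species only H2 (2 electrons/mol) and
    the inert N2 (0) are meaningful; anything else is rejected.
    """
    a = compound.atoms
    if a["C"] > 0:
        return 4.0 + a["H"] / a["C"] - 2.0 * a["O"] / a["C"] - 3.0 * a["N"] / a["C"]
    if a["H"] > 0 and a["O"] == 0 and a["N"] == 0:  # H2
        return a["H"]  # 2 electrons for H2
    if a["N"] > 0 and a["H"] == 0 and a["O"] == 0:  # N2, inert
        return 0.0
    raise ValueError(
        f"{compound.name}: degree of reduction undefined for zero-carbon "
        "species other than H2/N2"
    )


class CompoundRegistry:
    """Dictionary-like collection of :class:`CompoundSpec`, user extensible."""

    def __init__(self, compounds: Iterable[CompoundSpec] = ()) -> None:
        self._by_name: dict[str, CompoundSpec] = {}
        for c in compounds:
            self.add(c)

    def add(self, compound: CompoundSpec) -> None:
        self._by_name[compound.name] = compound

    def __getitem__(self, name: str) -> CompoundSpec:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"compound {name!r} not in registry") from None

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __iter__(self):
        return iter(self._by_name.values())

    def __len__(self) -> int:
        return len(self._by_name)

    def gamma(self, name: str) -> float:
        return degree_of_reduction(self[name])

    @classmethod
    def from_table(cls, path_or_buffer) -> "CompoundRegistry":
        """Load from a tab-separated table with columns name/formula/molar_mass/role."""
        import pandas as pd

        table = pd.read_csv(path_or_buffer, sep="\t")
        required = {"name", "formula", "molar_mass", "role"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"registry table missing columns: {sorted(missing)}")
        return cls(
            CompoundSpec.from_formula(r["name"], r["formula"], float(r["molar_mass"]), r["role"])
            for _, r in table.iterrows()
        )


def load_default_registry() -> CompoundRegistry:
    """The shipped registry of ABE-fermentation species and gases."""
    ref = resources.files("mixobal.data").joinpath("compounds.tsv")
    with ref.open("r", encoding="utf-8") as fh:
        return CompoundRegistry.from_table(fh)


@dataclass
class YieldSet:
    """Apparent yields on a sugar C-mol basis.

    ``product_yields`` maps product name -> C-mol product per C-mol of
    sugar consumed, ``biomass_yield`` likewise, ``h2_yield`` is mol H2 per
    C-mol sugar.  ``substrate_cmol`` is the C-mol of sugar consumed (per
    litre or per hour, the basis cancels in the ratios).
    """

    product_yields: dict[str, float] = field(default_factory=dict)
    biomass_yield: float = 0.0
    h2_yield: float = 0.0
    co2_yield: float = 0.0
    substrate_cmol: float = 1.0
    substrate: str = "sucrose"

    def __post_init__(self) -> None:
        if self.substrate_cmol <= 0:
            raise ValueError("substrate C-mol consumed must be positive")
        bad = {k: v for k, v in self.product_yields.items() if v < 0}
        if bad or self.biomass_yield < 0 or self.h2_yield < 0 or self.co2_yield < 0:
            raise ValueError(f"yields must be nonnegative (offending: {bad or 'biomass/h2/co2'})")


@dataclass
class BalanceResult:
    """Carbon and available-electron recoveries and their excess over a baseline."""

    carbon_recovery: float
    electron_recovery: float
    excess_carbon: float | None = None
    excess_electron: float | None = None
    baseline_mode: str = "heterotrophic_control"


@dataclass
class InorganicAttribution:
    """Inorganic (C-1) carbon uptake attributed against the sugar carbon flux."""

    c1_uptake_cmol_h: float
    sugar_flux_cmol_h: float
    c1_fraction: float
    produced_cmol_h: dict[str, float]
    inconsistent: bool


def cmol_yield(delta_product_g_l: float, product: CompoundSpec, delta_substrate_cmol: float) -> float:
    """Apparent yield: C-mol of product formed per C-mol of sugar consumed."""
    if delta_substrate_cmol <= 0:
        raise ValueError("substrate C-mol consumed must be positive")
    if delta_product_g_l < 0:
        raise ValueError(
            f"{product.name}: product concentration change is negative; products "
            "only accumulate at steady state"
        )
    return delta_product_g_l * product.cmol_per_gram / delta_substrate_cmol


def carbon_balance(yields: YieldSet) -> float:
    """Carbon recovery: sum of product, biomass and CO2 C-mol yields."""
    return sum(yields.product_yields.values()) + yields.biomass_yield + yields.co2_yield


def electron_balance(yields: YieldSet, registry: CompoundRegistry) -> float:
    """Available-electron recovery over the sugar's electrons.

    Returns ``sum(Yp*gamma_p)/gamma_s + Yx*gamma_x/gamma_s`` with H2 as an
    additional product carrying 2 electrons per mole and CO2 contributing
    nothing (gamma = 0).
    """
    gamma_s = registry.gamma(yields.substrate)
    if gamma_s <= 0:
        raise ValueError("substrate degree of reduction must be positive")
    electrons = 0.0
    for name, yp in yields.product_yields.items():
        if yp == 0:
            continue
        if name not in registry:
            raise KeyError(f"no degree of reduction available for product {name!r}")
        electrons += yp * registry.gamma(name)
    electrons += yields.biomass_yield * registry.gamma("biomass")
    electrons += yields.h2_yield * 2.0
    return electrons / gamma_s


def theoretical_max_yield(as_reported: bool = False) -> float:
    """Ceiling on acetyl-CoA-derived product yield for a sugar-only fermentation.

    One of the three pyruvate carbons is lost as CO2 on decarboxylation to
    acetyl-CoA, so at most 2/3 of sugar carbon can reach ABE products.
    With ``as_reported=True`` the value is truncated to two decimals (0.66),
    the form usually quoted.
    """
    exact = 2.0 / 3.0
    return math.floor(exact * 100) / 100 if as_reported else exact


def excess_recovery(condition: float, baseline: float) -> float:
    """Percent excess of a recovery over its baseline, sign preserved."""
    if baseline <= 0:
        raise ValueError("baseline recovery must be positive")
    return 100.0 * (condition - baseline) / baseline


def attribute_inorganic_carbon(
    gas_consumption_mol_h: Mapping[str, float],
    sugar_flux_cmol_h: float,
    product_flux_cmol_h: float | None = None,
) -> InorganicAttribution:
    """Attribute consumed CO/CO2 carbon against the sugar carbon flux.

    ``gas_consumption_mol_h`` uses the positive-equals-consumed convention;
    negative entries are production and contribute nothing to the attributed
    C-1 uptake (they are echoed in ``produced_cmol_h``).  When the product
    carbon flux is given, the result is flagged inconsistent if products
    exceed sugar plus inorganic carbon inputs.
    """
    if sugar_flux_cmol_h <= 0:
        raise ValueError("sugar carbon flux must be positive")
    uptake = 0.0
    produced: dict[str, float] = {}
    for gas in ("co", "co2"):
        rate = float(gas_consumption_mol_h.get(gas, 0.0))
        if rate > 0:
            uptake += rate  # 1 C per molecule for both CO and CO2
        elif rate < 0:
            produced[gas] = -rate
    inconsistent = False
    if product_flux_cmol_h is not None:
        inconsistent = product_flux_cmol_h > sugar_flux_cmol_h + uptake + 1e-9
    return InorganicAttribution(
        c1_uptake_cmol_h=uptake,
        sugar_flux_cmol_h=sugar_flux_cmol_h,
        c1_fraction=uptake / sugar_flux_cmol_h,
        produced_cmol_h=produced,
        inconsistent=inconsistent,
    )
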