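"""Chemical-formula arithmetic and silver-adduct mass annotation.

The mass engine behind the whole package: parse elemental formulas (with
bracketed isotope labels such as ``[107Ag]``), compute monoisotopic masses and
adduct m/z with electron-mass correction, express mass accuracy in ppm, and
assign neutral-loss formulas to tandem-MS product ions of silver-cationized
precursors.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

from .constants import ELECTRON_MASS, MONOISOTOPIC_MASS

__all__ = [
    "ChemicalFormula",
    "AdductSpec",
    "Assignment",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "ppm_error",
    "assign_product_ion",
]

_TOKEN = re.compile(r"\[(\d+)([A-Z][a-z]?)\](\d*)|([A-Z][a-z]?)(\d*)|(.)")


def _hill_key(symbol: str) -> tuple:
    # Hill order: C first, H second, everything else alphabetical.  Isotope
    # labels sort with their element, label after the plain symbol.
    m = re.fullmatch(r"\[(\d+)([A-Z][a-z]?)\]", symbol)
    iso, elem = (int(m.group(1)), m.group(2)) if m else (0, symbol)
    rank = {"C": 0, "H": 1}.get(elem, 2)
    return (rank, elem, iso)


@dataclass(frozen=True)
class ChemicalFormula:
    """Elemental composition of a neutral species or a neutral loss."""

    counts: tuple[tuple[str, int], ...] = ()

    @staticmethod
    def from_counts(counts: dict[str, int]) -> "ChemicalFormula":
        for sym, n in counts.items():
            if sym not in MONOISOTOPIC_MASS:
                raise ValueError(f"unknown element symbol: {sym!r}")
            if n < 0:
                raise ValueError(f"negative count for {sym}: {n}")
        items = tuple(
            (s, n) for s, n in sorted(counts.items(), key=lambda kv: _hill_key(kv[0])) if n > 0
        )
        return ChemicalFormula(items)

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __add__(self, other: "ChemicalFormula") -> "ChemicalFormula":
        out = self.as_dict()
        for s, n in other.counts:
            out[s] = out.get(s, 0) + n
        return ChemicalFormula.from_counts(out)

    def __sub__(self, other: "ChemicalFormula") -> "ChemicalFormula":
        out = self.as_dict()
        for s, n in other.counts:
            out[s] = out.get(s, 0) - n
            if out[s] < 0:
                raise ValueError(
                    f"invalid subtraction: {other} is not contained in {self} (element {s})"
                )
        return ChemicalFormula.from_counts(out)

    def contains(self, other: "ChemicalFormula") -> bool:
        mine = self.as_dict()
        return all(mine.get(s, 0) >= n for s, n in other.counts)

    @property
    def is_empty(self) -> bool:
        return not self.counts

    def __str__(self) -> str:
        parts = []
        for sym, n in self.counts:
            parts.append(f"{sym}{n if n != 1 else ''}")
        return "".join(parts)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ChemicalFormula({str(self)!r})"


def parse_formula(text: str) -> ChemicalFormula:
    """Parse a formula string like ``"C20H32O5"`` or ``"C20H23[2H]9O5"``.

    The empty string parses to the empty formula (mass 0).  Bracketed isotope
    prefixes denote specific isotopes, e.g. ``[107Ag]`` for monoisotopic
    silver.
    """
    counts: dict[str, int] = {}
    for m in _TOKEN.finditer(text.strip()):
        if m.group(6) is not None:
            if m.group(6).isspace():
                continue
            raise ValueError(f"malformed formula {text!r}: unexpected {m.group(6)!r}")
        if m.group(2):
            sym = f"[{int(m.group(1))}{m.group(2)}]"
            n = int(m.group(3)) if m.group(3) else 1
        else:
            sym = m.group(4)
            n = int(m.group(5)) if m.group(5) else 1
        if sym not in MONOISOTOPIC_MASS:
            raise ValueError(f"unknown element symbol {sym!r} in {text!r}")
        counts[sym] = counts.get(sym, 0) + n
    return ChemicalFormula.from_counts(counts)


def monoisotopic_mass(f: ChemicalFormula) -> float:
    """Neutral monoisotopic mass in Da (no electron correction)."""
    return sum(MONOISOTOPIC_MASS[s] * n for s, n in f.counts)


#: Supported ionizing species: (formula added to the neutral, charge).
_ADDUCTS: dict[str, tuple[str, int]] = {
    "+107Ag": ("[107Ag]", +1),
    "+Ag": ("[107Ag]", +1),
    "+Na": ("Na", +1),
    "+H": ("H", +1),
    "-H": ("-H", -1),
}


@dataclass(frozen=True)
class AdductSpec:
    """A singly charged adduct ion of a neutral molecule."""

    neutral: ChemicalFormula
    adduct_species: str = "+107Ag"
    charge: int = +1

    def __post_init__(self):
        if self.adduct_species not in _ADDUCTS:
            raise ValueError(
                f"unsupported adduct species {self.adduct_species!r}; "
                f"supported: {sorted(_ADDUCTS)}"
            )
        if abs(self.charge) != 1:
            raise ValueError("only singly charged ions are supported")
        if self.charge != _ADDUCTS[self.adduct_species][1]:
            raise ValueError(
                f"charge {self.charge:+d} inconsistent with species {self.adduct_species!r}"
            )

    @property
    def ion_formula(self) -> ChemicalFormula:
        """Elemental composition of the ion (adduct bookkeeping applied)."""
        spec, _ = _ADDUCTS[self.adduct_species]
        if spec.startswith("-"):
            return self.neutral - parse_formula(spec[1:])
        return self.neutral + parse_formula(spec)


def adduct_mz(a: AdductSpec) -> float:
    """Theoretical m/z of an adduct ion, with electron-mass correction.

    m/z = (neutral mass + adduct mass − charge × mₑ) / |charge|.  The
    electron term is ~1.2 ppm at m/z 459 and is required to match measured
    high-resolution values.
    """
    return monoisotopic_mass(a.ion_formula) - a.charge * ELECTRON_MASS


def ppm_error(measured: float, theoretical: float) -> float:
    """Relative mass error (measured − theoretical)/theoretical × 1e6."""
    if measured <= 0 or theoretical <= 0:
        raise ValueError("m/z values must be positive")
    return (measured - theoretical) / theoretical * 1e6


@dataclass(frozen=True)
class Assignment:
    """One candidate product-ion identification."""

    measured_mz: float
    formula: ChemicalFormula  # ion elemental composition
    loss: ChemicalFormula  # neutral loss from the precursor ion
    theoretical_mz: float
    ppm_error: float
    rank: int = 0

    @property
    def retains_silver(self) -> bool:
        return any("Ag" in s for s, _ in self.formula.counts)


def _heavy_atoms(f: ChemicalFormula) -> int:
    return sum(n for s, n in f.counts if s != "H" and s != "[2H]")


def assign_product_ion(
    measured: float,
    precursor: AdductSpec,
    tol: float = 10.0,
    allow_metal_losses: bool = True,
) -> list[Assignment]:
    """Assign neutral-loss formulas to a product ion of a charged precursor.

    Candidate losses are element-bounded subformulas of the precursor ion
    composition over C/H/O and, when ``allow_metal_losses``, losses that also
    carry ``[107Ag]H`` (silver departing as a hydride, leaving the charge on
    the organic fragment).  All candidates within ``tol`` ppm are returned
    ranked by |ppm error|; ties go to the loss with fewer heavy atoms.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    ion = precursor.ion_formula
    bounds = ion.as_dict()
    precursor_mz = adduct_mz(precursor)
    ag_sym = next((s for s in bounds if "Ag" in s), None)

    cmax = bounds.get("C", 0)
    hmax = bounds.get("H", 0)
    omax = bounds.get("O", 0)
    ag_options = [0, 1] if (allow_metal_losses and ag_sym) else [0]

    out: list[Assignment] = []
    for c, o, ag in itertools.product(range(cmax + 1), range(omax + 1), ag_options):
        # Losses of bare heavy skeletons with no H are chemically implausible
        # except for CO/CO2-type losses; we still enumerate them and let the
        # ppm window decide (the brute-force oracle does the same).
        for h in range(hmax + 1):
            if ag and h == 0:
                continue  # metal loss is modelled as AgH-containing
            loss_counts = {k: v for k, v in {"C": c, "H": h, "O": o}.items() if v}
            if ag:
                loss_counts[ag_sym] = 1
            loss = ChemicalFormula.from_counts(loss_counts)
            theo = precursor_mz - monoisotopic_mass(loss)
            if theo <= 0:
                continue
            err = ppm_error(measured, theo)
            if abs(err) <= tol:
                out.append(
                    Assignment(
                        measured_mz=measured,
                        formula=ion - loss,
                        loss=loss,
                        theoretical_mz=theo,
                        ppm_error=err,
                    )
                )
    out.sort(key=lambda a: (abs(a.ppm_error), _heavy_atoms(a.loss), str(a.loss)))
    return [
        Assignment(a.measured_mz, a.formula, a.loss, a.theoretical_mz, a.ppm_error, rank=i)
        for i, a in enumerate(out)
    ]
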