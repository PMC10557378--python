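"""Pinned physical constants for all mass arithmetic.

Every m/z computed anywhere in the package routes through this table so that
theoretical masses are reproducible to well below 0.1 ppm.  Values are IUPAC/
CODATA monoisotopic atomic masses in Da.  Isotope-labelled species are keyed
with bracket notation, e.g. ``[2H]`` (deuterium) and ``[107Ag]``.

A bare ``Ag`` is treated as the light isotope ¹⁰⁷Ag: the experiments this
package models use isotopically enriched monoisotopic silver, so natural-
abundance silver never occurs in practice.
"""

MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.0078250319,
    "[2H]": 2.0141017781,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "Na": 22.98976928,
    "S": 31.97207069,
    "P": 30.97376151,
    "Ag": 106.905092,
    "[107Ag]": 106.905092,
    "[109Ag]": 108.904756,
}

#: CODATA electron mass in Da.  Applied to every charged species (never to
#: neutrals): a singly charged cation is one electron short of its formula.
ELECTRON_MASS: float = 0.000548579909
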