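"""Monoisotopic mass and adduct m/z arithmetic for feature annotation.

Provides elemental-formula parsing, monoisotopic masses, theoretical m/z for
configurable negative/positive ion species, ppm mass errors, brute-force
elemental-composition search within a mass tolerance, and the screening
positive-predictive-value calculator used to judge clinical relevance.

Conventions
-----------
Theoretical m/z uses the *H-atom convention* by default: a deprotonated ion
[M-H]- is M minus the mass of a hydrogen atom, with no electron-mass
correction.  Mass-spectrometry software reports deprotonated species this way
far more often than with the physically exact electron-corrected proton mass;
the two differ by ~0.5 mDa per charge.  Pass ``electron_correction=True`` (or
build an :class:`IonSpec` with the flag set) for the exact convention.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

__all__ = [
    "ElementalFormula", "IonSpec", "MassMatch", "ION_PRESETS",
    "monoisotopic_mass", "ion_mz", "ppm_error", "formula_candidates",
    "screening_ppv", "ATOMIC_MASS", "ELECTRON_MASS",
]

#: Most-abundant-isotope atomic masses (Da), CODATA/IUPAC values.
ATOMIC_MASS = {
    "C": 12.0,
    "H": 1.00782503,
    "N": 14.00307401,
    "O": 15.99491462,
    "P": 30.97376200,
    "S": 31.97207117,
    "Na": 22.98976928,
    "Cl": 34.96885268,
    "K": 38.96370649,
}

ELECTRON_MASS = 0.000548579909

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalFormula:
    """Element -> count map, e.g. C34H67NO3."""

    counts: tuple[tuple[str, int], ...]

    @classmethod
    def parse(cls, text: str) -> "ElementalFormula":
        pos = 0
        counts: dict[str, int] = {}
        for m in _FORMULA_RE.finditer(text):
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {text!r} at {text[pos:]!r}")
            pos = m.end()
            el, num = m.group(1), int(m.group(2) or 1)
            if el not in ATOMIC_MASS:
                raise ValueError(f"unknown element {el!r} in formula {text!r}")
            counts[el] = counts.get(el, 0) + num
        if pos != len(text) or not counts:
            raise ValueError(f"cannot parse formula {text!r}")
        if all(v == 0 for v in counts.values()):
            raise ValueError(f"formula {text!r} has no atoms")
        return cls(tuple(sorted(counts.items())))

    @classmethod
    def from_dict(cls, counts: dict[str, int]) -> "ElementalFormula":
        for el, v in counts.items():
            if el not in ATOMIC_MASS:
                raise ValueError(f"unknown element {el!r}")
            if v < 0:
                raise ValueError(f"negative count for {el!r}")
        items = tuple(sorted((el, v) for el, v in counts.items() if v > 0))
        if not items:
            raise ValueError("formula has no atoms")
        return cls(items)

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __str__(self) -> str:
        d = self.as_dict()
        out = []
        for el in ("C", "H"):  # Hill order
            if el in d:
                out.append(el + (str(d[el]) if d[el] != 1 else ""))
        for el in sorted(k for k in d if k not in ("C", "H")):
            out.append(el + (str(d[el]) if d[el] != 1 else ""))
        return "".join(out)


def _as_formula(f) -> ElementalFormula:
    return f if isinstance(f, ElementalFormula) else ElementalFormula.parse(str(f))


def monoisotopic_mass(formula) -> float:
    """Sum of most-abundant-isotope atomic masses (Da)."""
    f = _as_formula(formula)
    return sum(ATOMIC_MASS[el] * n for el, n in f.counts)


@dataclass(frozen=True)
class IonSpec:
    """Ion species: atoms gained/lost relative to the neutral molecule M,
    charge magnitude and polarity."""

    name: str
    gained: dict[str, int] = field(default_factory=dict)
    lost: dict[str, int] = field(default_factory=dict)
    z: int = 1
    polarity: str = "-"
    electron_correction: bool = False

    def __post_init__(self):
        if self.z < 1:
            raise ValueError(f"charge magnitude must be >= 1, got {self.z}")
        if self.polarity not in ("+", "-"):
            raise ValueError(f"polarity must be '+' or '-', got {self.polarity!r}")


#: Named ion species presets (negative mode).  "[M-CHO-H]-" encodes the loss
#: of CH2O plus a proton: the printed theoretical m/z of the cortisone-type
#: entry this label is used for corresponds to M - CH2O - H, not to the
#: label's literal arithmetic (M - CHO - H is 1.008 Da lower); the preset
#: reproduces the reported value and the discrepancy is documented here.
ION_PRESETS: dict[str, IonSpec] = {
    "[M-H]-": IonSpec("[M-H]-", lost={"H": 1}),
    "[M+Na-2H]-": IonSpec("[M+Na-2H]-", gained={"Na": 1}, lost={"H": 2}),
    "[M-2H]2-": IonSpec("[M-2H]2-", lost={"H": 2}, z=2),
    # "[M-H]2-" as printed in feature tables: the m/z is consistent with the
    # doubly deprotonated species (M-2H)/2, so it aliases [M-2H]2-.
    "[M-H]2-": IonSpec("[M-H]2-", lost={"H": 2}, z=2),
    "[M-CHO-H]-": IonSpec("[M-CHO-H]-", lost={"C": 1, "H": 3, "O": 1}),
    "[M-H2O-H]-": IonSpec("[M-H2O-H]-", lost={"H": 3, "O": 1}),
}


def _resolve_ion(ion) -> IonSpec:
    if isinstance(ion, IonSpec):
        return ion
    key = str(ion).replace("−", "-").replace(" ", "")
    key = re.sub(r"\^|_", "", key)
    if key in ION_PRESETS:
        return ION_PRESETS[key]
    raise ValueError(f"unknown ion species {ion!r}; known presets: "
                     f"{sorted(ION_PRESETS)}")


def ion_mz(formula, ion, electron_correction: bool | None = None) -> float:
    """Theoretical m/z of an ion species of the neutral molecule.

    ``m/z = (M + mass(gained) - mass(lost) +/- z*m_e) / z``, with the
    electron term included only when electron correction is enabled (added
    for negative polarity, subtracted for positive).
    """
    f = _as_formula(formula)
    spec = _resolve_ion(ion)
    if electron_correction is not None:
        spec = replace(spec, electron_correction=electron_correction)
    avail = f.as_dict()
    for el, nlost in spec.lost.items():
        have = avail.get(el, 0) + spec.gained.get(el, 0)
        if nlost > have:
            raise ValueError(
                f"ion {spec.name} loses {nlost} {el} but the molecule plus "
                f"gains provides only {have}")
    m = monoisotopic_mass(f)
    m += sum(ATOMIC_MASS[el] * n for el, n in spec.gained.items())
    m -= sum(ATOMIC_MASS[el] * n for el, n in spec.lost.items())
    if spec.electron_correction:
        m += spec.z * ELECTRON_MASS * (1 if spec.polarity == "-" else -1)
    return m / spec.z


def ppm_error(observed: float, theoretical: float) -> float:
    """(observed - theoretical) / theoretical * 1e6."""
    if theoretical <= 0:
        raise ValueError(f"theoretical m/z must be positive, got {theoretical}")
    return (observed - theoretical) / theoretical * 1e6


@dataclass
class MassMatch:
    """Observed vs theoretical m/z with errors in ppm and mDa."""

    observed: float
    theoretical: float
    ppm: float
    mda: float

    @classmethod
    def build(cls, observed: float, theoretical: float) -> "MassMatch":
        return cls(observed, theoretical, ppm_error(observed, theoretical),
                   (observed - theoretical) * 1e3)


def _rdbe(counts: dict[str, int]) -> float:
    """Ring-plus-double-bond equivalents for CHNOPS(+Na,Cl,K) formulas."""
    return (counts.get("C", 0) + 1
            + (counts.get("N", 0) + counts.get("P", 0)) / 2
            - (counts.get("H", 0) + counts.get("Na", 0)
               + counts.get("Cl", 0) + counts.get("K", 0)) / 2)


def formula_candidates(target_mass: float, tolerance_mda: float,
                       bounds: dict[str, int], rdbe_filter: bool = False,
                       nitrogen_rule: bool = False,
                       max_combinations: float = 1e7,
                       ) -> list[tuple[ElementalFormula, float]]:
    """Exhaustively enumerate formulas within ``bounds`` whose monoisotopic
    mass lies within ``tolerance_mda`` of ``target_mass``.

    Returns (formula, error in mDa) sorted by |error|.  ``rdbe_filter``
    requires a non-negative integer-or-half ring/double-bond count;
    ``nitrogen_rule`` requires nitrogen parity consistent with the nominal
    mass.  Bounds generating more than ``max_combinations`` candidate
    combinations are refused with guidance.
    """
    if tolerance_mda <= 0:
        raise ValueError(f"tolerance must be positive, got {tolerance_mda}")
    bounds = {el: int(v) for el, v in bounds.items() if v > 0}
    for el in bounds:
        if el not in ATOMIC_MASS:
            raise ValueError(f"unknown element {el!r} in bounds")
    if not bounds:
        return []
    n_comb = 1.0
    for v in bounds.values():
        n_comb *= v + 1
    if n_comb > max_combinations:
        raise ValueError(
            f"bounds span {n_comb:.2g} combinations (> {max_combinations:.0g}); "
            "tighten the per-element limits or search a narrower mass window")
    tol = tolerance_mda * 1e-3
    elements = sorted(bounds, key=lambda el: -ATOMIC_MASS[el])
    out: list[tuple[ElementalFormula, float]] = []
    counts: dict[str, int] = {}

    def recurse(i: int, mass: float) -> None:
        if mass > target_mass + tol:
            return
        if i == len(elements):
            err = mass - target_mass
            if abs(err) <= tol and any(counts.values()):
                f = ElementalFormula.from_dict(counts)
                d = f.as_dict()
                if rdbe_filter and _rdbe(d) < 0:
                    return
                if nitrogen_rule and \
                        (round(mass) % 2 == 1) != (d.get("N", 0) % 2 == 1):
                    return
                out.append((f, err * 1e3))
            return
        el = elements[i]
        for k in range(bounds[el] + 1):
            counts[el] = k
            recurse(i + 1, mass + k * ATOMIC_MASS[el])
        counts.pop(el, None)

    recurse(0, 0.0)
    return sorted(out, key=lambda t: abs(t[1]))


def screening_ppv(prevalence: float, sensitivity: float,
                  specificity: float) -> float:
    """Positive predictive value of a screening test at a given disease
    prevalence: ``sens*prev / (sens*prev + (1-spec)*(1-prev))``."""
    for name, v in (("prevalence", prevalence), ("sensitivity", sensitivity),
                    ("specificity", specificity)):
        if not 0 < v <= 1:
            raise ValueError(f"{name} must be in (0, 1], got {v}")
    tp = sensitivity * prevalence
    fp = (1.0 - specificity) * (1.0 - prevalence)
    return tp / (tp + fp) if (tp + fp) > 0 else 1.0
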