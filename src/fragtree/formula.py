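"""Elemental-formula arithmetic over CHNOPS and candidate enumeration.

The package assigns elemental formulas to fragment ions observed in
multistage (MS^n) spectra.  All formulas here are *ion* compositions
(protonation included), restricted to the elements C, H, N, O, P and S;
singly charged even-electron cations/anions are the working currency,
so RDBE of a valid ion is a half-integer.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

__all__ = [
    "ELEMENTS",
    "MONOISOTOPIC_MASS",
    "ELECTRON_MASS",
    "ElementalFormula",
    "IonSpec",
    "FormulaConstraints",
    "monoisotopic_mass",
    "ion_mz",
    "rdbe",
    "ppm_error",
    "is_subformula",
    "subtract_formula",
    "add_formula",
    "passes_ratio_rules",
    "enumerate_candidates",
    "serialize_formula",
    "parse_formula",
]

#: canonical element order used in all serializations (Hill-like, CHNOPS)
ELEMENTS: Tuple[str, ...] = ("C", "H", "N", "O", "P", "S")

#: monoisotopic atomic masses, Da (IUPAC/CODATA)
MONOISOTOPIC_MASS: Dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
}

#: electron rest mass, Da
ELECTRON_MASS: float = 0.00054857990946

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class ElementalFormula:
    """Immutable element -> count map over C,H,N,O,P,S.

    Equality and hashing are by per-element counts.  Construct from a
    mapping (``ElementalFormula({"C": 10, "H": 18, ...})``) or via
    :func:`parse_formula`.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Optional[Dict[str, int]] = None):
        vec = [0] * len(ELEMENTS)
        if counts:
            for elem, n in counts.items():
                if elem not in MONOISOTOPIC_MASS:
                    raise ValueError(f"element {elem!r} outside CHNOPS")
                if not isinstance(n, (int,)) or isinstance(n, bool):
                    raise TypeError(f"count for {elem} must be an integer, got {n!r}")
                if n < 0:
                    raise ValueError(f"negative count for {elem}: {n}")
                vec[ELEMENTS.index(elem)] += n
        self._counts = tuple(vec)

    # -- basic protocol -------------------------------------------------
    def __getitem__(self, elem: str) -> int:
        return self._counts[ELEMENTS.index(elem)]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ElementalFormula) and self._counts == other._counts

    def __hash__(self) -> int:
        return hash(self._counts)

    def __bool__(self) -> bool:
        return any(self._counts)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"ElementalFormula({serialize_formula(self) or 'empty'!r})"

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        return subtract_formula(self, other)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        return add_formula(self, other)

    @property
    def counts(self) -> Dict[str, int]:
        """Per-element counts as a plain dict (zero counts included)."""
        return dict(zip(ELEMENTS, self._counts))

    @property
    def count_vector(self) -> Tuple[int, ...]:
        return self._counts

    @classmethod
    def _from_vector(cls, vec: Tuple[int, ...]) -> "ElementalFormula":
        obj = object.__new__(cls)
        object.__setattr__(obj, "_counts", tuple(vec))
        return obj

    def mass(self) -> float:
        return monoisotopic_mass(self)


@dataclass(frozen=True)
class IonSpec:
    """A charged ion: composition (protonation included), polarity, charge."""

    formula: ElementalFormula
    polarity: int = +1
    charge: int = 1

    def __post_init__(self) -> None:
        if self.polarity not in (+1, -1):
            raise ValueError("polarity must be +1 or -1")
        if self.charge < 1:
            raise ValueError("charge must be a positive integer")


# Kind-Fiehn style heuristics: extended element-ratio ranges plus
# per-element maxima for the < 500 Da window; both configurable.
_DEFAULT_ELEMENT_MAX = {"C": 39, "H": 72, "N": 20, "O": 20, "P": 9, "S": 10}
_DEFAULT_RATIO_BOUNDS = {
    "H/C": (0.1, 6.0),
    "N/C": (0.0, 4.0),
    "O/C": (0.0, 3.0),
    "P/C": (0.0, 2.0),
    "S/C": (0.0, 3.0),
}


@dataclass
class FormulaConstraints:
    """Candidate-formula search space and plausibility filters.

    Parameters
    ----------
    tol_ppm:
        Mass tolerance for accepting a candidate, in ppm (default 6).
    element_max:
        Per-element maximum counts.
    ratio_rules_enabled:
        Apply the heuristic element-ratio ranges (H/C etc.).
    rdbe_rule:
        ``"non_integer_required"`` keeps only ions whose ring-double-bond
        equivalents fall on the half-integer grid with RDBE >= -0.5
        (even-electron CHNOPS ions); ``"none"`` disables the filter.
    precursor_cap:
        Optional element-wise upper bound (the precursor ion's formula).
    """

    tol_ppm: float = 6.0
    element_max: Dict[str, int] = field(default_factory=lambda: dict(_DEFAULT_ELEMENT_MAX))
    ratio_rules_enabled: bool = True
    rdbe_rule: str = "non_integer_required"
    precursor_cap: Optional[ElementalFormula] = None
    ratio_bounds: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_RATIO_BOUNDS)
    )

    def __post_init__(self) -> None:
        if self.tol_ppm <= 0:
            raise ValueError("tol_ppm must be positive")
        if self.rdbe_rule not in ("non_integer_required", "none"):
            raise ValueError(f"unknown rdbe_rule {self.rdbe_rule!r}")
        for elem, n in self.element_max.items():
            if elem not in MONOISOTOPIC_MASS or n < 0:
                raise ValueError(f"bad element_max entry {elem}={n}")

    def with_cap(self, cap: Optional[ElementalFormula]) -> "FormulaConstraints":
        """Copy of these constraints with a different precursor cap."""
        return FormulaConstraints(
            tol_ppm=self.tol_ppm,
            element_max=dict(self.element_max),
            ratio_rules_enabled=self.ratio_rules_enabled,
            rdbe_rule=self.rdbe_rule,
            precursor_cap=cap,
            ratio_bounds=dict(self.ratio_bounds),
        )


def monoisotopic_mass(formula: ElementalFormula) -> float:
    """Monoisotopic mass in Da (sum of count x atomic monoisotopic mass)."""
    return sum(
        n * MONOISOTOPIC_MASS[e] for e, n in zip(ELEMENTS, formula.count_vector) if n
    )


def ion_mz(ion: IonSpec) -> float:
    """Theoretical m/z of an ion, electron mass included.

    For a cation the electron deficit is subtracted; for an anion the
    extra electron is added:  (m - polarity * z * m_e) / z.
    """
    m = monoisotopic_mass(ion.formula)
    return (m - ion.polarity * ion.charge * ELECTRON_MASS) / ion.charge


def rdbe(formula: ElementalFormula) -> float:
    """Ring and double bond equivalents: C + 1 - H/2 + (N + P)/2.

    O and S contribute nothing; P is treated as trivalent.  On integer
    counts the result lies on the 0.5 grid.
    """
    c = formula["C"]
    h = formula["H"]
    n = formula["N"]
    p = formula["P"]
    return c + 1.0 - h / 2.0 + (n + p) / 2.0


def ppm_error(observed_mz: float, theoretical_mz: float) -> float:
    """Signed relative mass error in ppm, measured against the theory."""
    if theoretical_mz <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (observed_mz - theoretical_mz) / theoretical_mz * 1e6


def is_subformula(a: ElementalFormula, b: ElementalFormula) -> bool:
    """True iff every element count of ``a`` is <= the count in ``b``."""
    return all(x <= y for x, y in zip(a.count_vector, b.count_vector))


def subtract_formula(
    precursor: ElementalFormula, fragment: ElementalFormula
) -> ElementalFormula:
    """Element-wise difference precursor - fragment (the neutral loss).

    Raises ``ValueError`` when any count would go negative, which signals
    a precursor-product hierarchy violation.
    """
    diff = tuple(
        p - f for p, f in zip(precursor.count_vector, fragment.count_vector)
    )
    if any(d < 0 for d in diff):
        raise ValueError(
            "fragment is not a sub-formula of the precursor "
            f"({serialize_formula(fragment)} vs {serialize_formula(precursor)})"
        )
    return ElementalFormula._from_vector(diff)


def add_formula(a: ElementalFormula, b: ElementalFormula) -> ElementalFormula:
    return ElementalFormula._from_vector(
        tuple(x + y for x, y in zip(a.count_vector, b.count_vector))
    )


def passes_ratio_rules(
    formula: ElementalFormula, constraints: Optional[FormulaConstraints] = None
) -> bool:
    """Heuristic element-count/ratio plausibility filter.

    Checks per-element maxima always; element ratios (H/C, N/C, O/C,
    P/C, S/C) only when the formula contains carbon — a carbon-free
    formula is judged on the maxima alone.
    """
    c = constraints or FormulaConstraints()
    counts = formula.counts
    for elem, n in counts.items():
        if n > c.element_max.get(elem, 0):
            return False
    n_c = counts["C"]
    if n_c == 0:
        return True
    ratios = {
        "H/C": counts["H"] / n_c,
        "N/C": counts["N"] / n_c,
        "O/C": counts["O"] / n_c,
        "P/C": counts["P"] / n_c,
        "S/C": counts["S"] / n_c,
    }
    for name, value in ratios.items():
        lo, hi = c.ratio_bounds[name]
        if not (lo <= value <= hi):
            return False
    return True


def _passes_rdbe_rule(formula: ElementalFormula, rule: str) -> bool:
    if rule == "none":
        return True
    r2 = round(2 * rdbe(formula))  # exact: H, N, P are integers
    return (r2 % 2 != 0) and r2 >= -1


def candidate_ok(
    formula: ElementalFormula, constraints: FormulaConstraints
) -> bool:
    """All enabled plausibility predicates (cap, ratios, RDBE) in one place."""
    if constraints.precursor_cap is not None and not is_subformula(
        formula, constraints.precursor_cap
    ):
        return False
    if constraints.ratio_rules_enabled and not passes_ratio_rules(formula, constraints):
        return False
    return _passes_rdbe_rule(formula, constraints.rdbe_rule)


def enumerate_candidates(
    target_mz: float,
    polarity: int = +1,
    constraints: Optional[FormulaConstraints] = None,
) -> List[Tuple[ElementalFormula, float]]:
    """All CHNOPS ion formulas matching ``target_mz`` within tolerance.

    Iterates over the heavy elements (C, N, O, P, S) with cumulative-mass
    pruning and solves the admissible hydrogen count range directly from
    the residual mass window, so the cost is governed by the number of
    feasible heavy-atom combinations rather than the full grid.

    Returns ``(formula, ppm_error)`` pairs sorted by \\|ppm\\| ascending,
    ties broken by the serialized formula token.  An empty list is a
    valid result (the peak is a candidate artifact).
    """
    if target_mz <= 0:
        raise ValueError("target m/z must be positive")
    c = constraints or FormulaConstraints()
    tol = c.tol_ppm * 1e-6
    # theoretical ion m/z admissible window, then ion-mass window (z = 1)
    theo_lo = target_mz / (1.0 + tol)
    theo_hi = target_mz / (1.0 - tol)
    m_lo = theo_lo + polarity * ELECTRON_MASS
    m_hi = theo_hi + polarity * ELECTRON_MASS

    cap = c.precursor_cap
    limits = {}
    for elem in ELEMENTS:
        lim = c.element_max.get(elem, 0)
        if cap is not None:
            lim = min(lim, cap[elem])
        lim = min(lim, int(m_hi // MONOISOTOPIC_MASS[elem]))
        limits[elem] = max(lim, 0)

    m_h = MONOISOTOPIC_MASS["H"]
    heavy = ("C", "N", "O", "P", "S")
    results: List[Tuple[ElementalFormula, float]] = []

    def recurse(idx: int, counts: Dict[str, int], mass: float) -> None:
        if idx == len(heavy):
            residual_lo = m_lo - mass
            residual_hi = m_hi - mass
            h_min = max(0, math.ceil(residual_lo / m_h))
            h_max = min(limits["H"], math.floor(residual_hi / m_h))
            for h in range(h_min, h_max + 1):
                vec = counts.copy()
                vec["H"] = h
                formula = ElementalFormula(vec)
                if not formula:
                    continue
                if not candidate_ok(formula, c):
                    continue
                theo = monoisotopic_mass(formula) - polarity * ELECTRON_MASS
                err = ppm_error(target_mz, theo)
                if abs(err) <= c.tol_ppm + 1e-12:
                    results.append((formula, err))
            return
        elem = heavy[idx]
        m_e = MONOISOTOPIC_MASS[elem]
        for n in range(limits[elem] + 1):
            new_mass = mass + n * m_e
            if new_mass > m_hi:
                break
            counts[elem] = n
            recurse(idx + 1, counts, new_mass)
        counts.pop(elem, None)

    recurse(0, {}, 0.0)
    results.sort(key=lambda item: (abs(item[1]), serialize_formula(item[0], "efp_token")))
    return results


def serialize_formula(formula: ElementalFormula, dialect: str = "display") -> str:
    """Serialize in CHNOPS order.

    ``display`` omits unit counts (``C5H8NO3S``); ``efp_token`` writes
    every non-zero count explicitly (``C5H8N1O3S1``), the convention used
    inside elemental formula paths.  The empty formula serializes to "".
    """
    if dialect not in ("display", "efp_token"):
        raise ValueError(f"unknown dialect {dialect!r}")
    parts = []
    for elem, n in zip(ELEMENTS, formula.count_vector):
        if n == 0:
            continue
        if dialect == "display" and n == 1:
            parts.append(elem)
        else:
            parts.append(f"{elem}{n}")
    return "".join(parts)


def parse_formula(text: str) -> ElementalFormula:
    """Parse either serialization dialect back into a formula.

    Left inverse of :func:`serialize_formula`; raises ``ValueError`` on
    unknown element symbols, repeated elements or malformed counts.
    """
    counts: Dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(text):
        if match.start() != pos:
            raise ValueError(f"malformed formula {text!r} at position {pos}")
        elem, digits = match.groups()
        if elem not in MONOISOTOPIC_MASS:
            raise ValueError(f"unknown element {elem!r} in {text!r}")
        if elem in counts:
            raise ValueError(f"repeated element {elem!r} in {text!r}")
        counts[elem] = int(digits) if digits else 1
        pos = match.end()
    if pos != len(text):
        raise ValueError(f"malformed formula {text!r} at position {pos}")
    return ElementalFormula(counts)
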