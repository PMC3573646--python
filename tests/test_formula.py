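"""Formula arithmetic, plausibility filters and candidate enumeration."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fragtree import (
    ELECTRON_MASS,
    MONOISOTOPIC_MASS,
    ElementalFormula,
    FormulaConstraints,
    IonSpec,
    enumerate_candidates,
    ion_mz,
    is_subformula,
    monoisotopic_mass,
    parse_formula,
    passes_ratio_rules,
    ppm_error,
    rdbe,
    serialize_formula,
    subtract_formula,
)
from fragtree.formula import candidate_ok

formulas = st.builds(
    ElementalFormula,
    st.fixed_dictionaries(
        {e: st.integers(min_value=0, max_value=20) for e in "CHNOPS"}
    ),
)


# ---------------------------------------------------------------------------
# construction / serialization
# ---------------------------------------------------------------------------

def test_construction_rejects_bad_input():
    with pytest.raises(ValueError):
        ElementalFormula({"Na": 1})
    with pytest.raises(ValueError):
        ElementalFormula({"C": -1})
    assert ElementalFormula({}) == ElementalFormula()
    assert not ElementalFormula()  # empty formula is falsy


@pytest.mark.parametrize(
    "text,counts",
    [
        ("C10H18N3O6S1", {"C": 10, "H": 18, "N": 3, "O": 6, "S": 1}),
        ("C5H8NO3S", {"C": 5, "H": 8, "N": 1, "O": 3, "S": 1}),
        ("H", {"H": 1}),
        ("", {}),
    ],
)
def test_parse_formula(text, counts):
    parsed = parse_formula(text)
    assert {e: n for e, n in parsed.counts.items() if n} == counts


@pytest.mark.parametrize("bad", ["C10X2", "c10", "C-1", "CC", "C10 H2"])
def test_parse_formula_rejects_malformed(bad):
    with pytest.raises(ValueError):
        parse_formula(bad)


def test_serialize_dialects():
    f = parse_formula("C5H8NO3S")
    assert serialize_formula(f, "display") == "C5H8NO3S"
    assert serialize_formula(f, "efp_token") == "C5H8N1O3S1"
    assert serialize_formula(ElementalFormula()) == ""


@given(formulas)
@settings(deadline=None)
def test_serialize_parse_round_trip(f):
    for dialect in ("display", "efp_token"):
        assert parse_formula(serialize_formula(f, dialect)) == f


# ---------------------------------------------------------------------------
# masses
# ---------------------------------------------------------------------------

def test_monoisotopic_mass_basics():
    assert monoisotopic_mass(ElementalFormula()) == 0.0
    assert monoisotopic_mass(parse_formula("H")) == MONOISOTOPIC_MASS["H"]
    assert monoisotopic_mass(parse_formula("C10H18N3O6S")) == pytest.approx(
        308.0916313, abs=1e-6
    )


@pytest.mark.parametrize(
    "token,expected",
    [("C10H18N3O6S", 308.091), ("C5H6NO2S", 144.011), ("C4H6NOS", 116.016)],
)
def test_ion_mz_matches_published_cation_masses(token, expected):
    """Cation m/z reproduces the worked-example masses at 3 decimals."""
    mz = ion_mz(IonSpec(parse_formula(token), polarity=+1))
    assert round(mz, 3) == expected


def test_ion_mz_charge_validation():
    with pytest.raises(ValueError):
        IonSpec(parse_formula("CH4"), +1, charge=0)
    with pytest.raises(ValueError):
        IonSpec(parse_formula("CH4"), polarity=2)


@given(formulas.filter(bool))
@settings(deadline=None)
def test_electron_mass_sign(f):
    """Cation m/z < neutral mass < anion m/z for every non-empty formula."""
    m = monoisotopic_mass(f)
    assert ion_mz(IonSpec(f, +1)) < m < ion_mz(IonSpec(f, -1))
    assert ion_mz(IonSpec(f, -1)) - ion_mz(IonSpec(f, +1)) == pytest.approx(
        2 * ELECTRON_MASS
    )


# ---------------------------------------------------------------------------
# rdbe / ppm
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "token,expected",
    [("CH4", 0.0), ("C10H18N3O6S", 3.5), ("C3H6NS", 1.5), ("C20H31O5", 5.5)],
)
def test_rdbe(token, expected):
    assert rdbe(parse_formula(token)) == expected


def test_ppm_error_definition():
    assert ppm_error(100.0, 100.0) == 0.0
    assert ppm_error(100.0 * (1 - 1e-6), 100.0) == pytest.approx(-1.0)
    assert ppm_error(308.09093, 308.09108) == pytest.approx(-0.49, abs=0.01)
    with pytest.raises(ValueError):
        ppm_error(100.0, 0.0)


# ---------------------------------------------------------------------------
# subformula / subtraction
# ---------------------------------------------------------------------------

def test_subformula_examples():
    glut = parse_formula("C10H18N3O6S")
    assert is_subformula(parse_formula("C5H11N2O3S"), glut)
    assert is_subformula(glut, glut)
    assert not is_subformula(parse_formula("C5H11N2O3S2"), glut)


@given(formulas, formulas, formulas)
@settings(deadline=None)
def test_subformula_partial_order(a, b, c):
    assert is_subformula(a, a)
    if is_subformula(a, b) and is_subformula(b, a):
        assert a == b
    if is_subformula(a, b) and is_subformula(b, c):
        assert is_subformula(a, c)


def test_subtract_formula_examples():
    glut = parse_formula("C10H18N3O6S")
    frag = parse_formula("C5H11N2O3S")
    assert subtract_formula(glut, frag) == parse_formula("C5H7NO3")
    assert subtract_formula(glut, glut) == ElementalFormula()
    with pytest.raises(ValueError):
        subtract_formula(frag, glut)


@given(formulas, formulas)
@settings(deadline=None)
def test_mass_conservation(precursor, fragment):
    """Fragment + neutral-loss masses add up to the precursor mass."""
    if not is_subformula(fragment, precursor):
        return
    loss = subtract_formula(precursor, fragment)
    assert monoisotopic_mass(fragment) + monoisotopic_mass(loss) == pytest.approx(
        monoisotopic_mass(precursor), abs=1e-9
    )
    assert (loss + fragment) == precursor


# ---------------------------------------------------------------------------
# heuristic filters
# ---------------------------------------------------------------------------

def test_ratio_rules():
    assert passes_ratio_rules(parse_formula("C10H18N3O6S"))
    assert passes_ratio_rules(parse_formula("C3H6NS"))
    assert not passes_ratio_rules(parse_formula("CH20"))  # H/C = 20
    # carbon-free: maxima only
    assert passes_ratio_rules(parse_formula("H2O"))
    assert not passes_ratio_rules(parse_formula("S11"))  # S max is 10


# ---------------------------------------------------------------------------
# candidate enumeration vs brute force
# ---------------------------------------------------------------------------

def brute_force_candidates(target_mz, polarity, constraints):
    """Exhaustive nested-loop oracle over all CHNOPS count vectors."""
    tol = constraints.tol_ppm
    out = []
    cap = constraints.precursor_cap
    limit = {}
    m_hi = target_mz / (1 - tol * 1e-6) + polarity * ELECTRON_MASS
    for e in "CHNOPS":
        lim = constraints.element_max.get(e, 0)
        if cap is not None:
            lim = min(lim, cap[e])
        limit[e] = min(lim, int(m_hi // MONOISOTOPIC_MASS[e]))
    mass = MONOISOTOPIC_MASS
    for c in range(limit["C"] + 1):
        mc = c * mass["C"]
        if mc > m_hi:
            break
        for n in range(limit["N"] + 1):
            mn = mc + n * mass["N"]
            if mn > m_hi:
                break
            for o in range(limit["O"] + 1):
                mo = mn + o * mass["O"]
                if mo > m_hi:
                    break
                for p in range(limit["P"] + 1):
                    mp = mo + p * mass["P"]
                    if mp > m_hi:
                        break
                    for s in range(limit["S"] + 1):
                        ms = mp + s * mass["S"]
                        if ms > m_hi:
                            break
                        for h in range(limit["H"] + 1):
                            if ms + h * mass["H"] > m_hi:
                                break
                            if c + h + n + o + p + s == 0:
                                continue
                            f = ElementalFormula(
                                {"C": c, "H": h, "N": n, "O": o, "P": p, "S": s}
                            )
                            theo = monoisotopic_mass(f) - polarity * ELECTRON_MASS
                            if theo <= 0:
                                continue
                            err = ppm_error(target_mz, theo)
                            if abs(err) > tol:
                                continue
                            if not candidate_ok(f, constraints):
                                continue
                            out.append((f, err))
    out.sort(key=lambda t: (abs(t[1]), serialize_formula(t[0], "efp_token")))
    return out


@pytest.mark.parametrize(
    "target,cap",
    [
        (308.0911, None),
        (179.0485, "C10H18N3O6S"),
        (144.0114, "C10H18N3O6S"),
        (88.0215, "C4H6NOS"),
        (116.0165, "C5H8NO3S"),
        (212.0300, None),
        (341.9000, None),
    ],
)
def test_enumerate_matches_brute_force(target, cap):
    constraints = FormulaConstraints(
        precursor_cap=parse_formula(cap) if cap else None
    )
    fast = enumerate_candidates(target, +1, constraints)
    slow = brute_force_candidates(target, +1, constraints)
    assert [(f, round(e, 6)) for f, e in fast] == [
        (f, round(e, 6)) for f, e in slow
    ]


def test_enumerate_examples():
    top = enumerate_candidates(308.0911, +1)
    assert parse_formula("C10H18N3O6S") in {f for f, _ in top}
    capped = enumerate_candidates(
        179.0485, +1, FormulaConstraints(precursor_cap=parse_formula("C10H18N3O6S"))
    )
    assert [f for f, _ in capped] == [parse_formula("C5H11N2O3S")]
    assert (
        enumerate_candidates(
            500.0, +1, FormulaConstraints(precursor_cap=parse_formula("CH4"))
        )
        == []
    )


def test_enumerate_all_within_tolerance():
    for f, err in enumerate_candidates(233.0591, +1):
        theo = ion_mz(IonSpec(f, +1))
        assert abs(ppm_error(233.0591, theo)) <= 6.0 + 1e-9
        assert err == pytest.approx(ppm_error(233.0591, theo))
        assert math.isclose(rdbe(f) % 1, 0.5)  # non-integer RDBE filter active
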