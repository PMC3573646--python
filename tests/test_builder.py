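"""Hierarchy-constrained assignment, consensus and exports."""

import numpy as np
import pytest

from fragtree import (
    FormulaConstraints,
    NoiseModel,
    Peak,
    Scan,
    SpectrumTree,
    assign_root,
    assign_tree,
    consensus,
    efp_strings,
    export_cml,
    export_json,
    glutathione_fixture,
    link_precursors,
    load_json,
    parse_formula,
    simulate_acquisition,
    spectrum_tree_from_truth,
)
from fragtree.builder import FragmentationTree, FragmentNode


def build_glutathione_tree():
    truth, expected, ppm = glutathione_fixture()
    stree = spectrum_tree_from_truth(truth, ppm_by_efp=ppm)
    return assign_tree(stree, root_formula=parse_formula("C10H18N3O6S")), expected


# ---------------------------------------------------------------------------
# root assignment
# ---------------------------------------------------------------------------

def single_scan_tree(mz):
    scan = Scan("1", 1, peaks=[Peak(mz, 1e6)])
    return SpectrumTree([scan], {"1": None})


def test_assign_root_with_known_formula():
    glut = parse_formula("C10H18N3O6S")
    formula, err = assign_root(single_scan_tree(308.0909), known_formula=glut)
    assert formula == glut
    assert err == pytest.approx(-0.5, abs=0.15)


def test_assign_root_enumerates_when_unknown():
    formula, _ = assign_root(single_scan_tree(308.0909))
    assert formula == parse_formula("C10H18N3O6S")


def test_assign_root_rejects_out_of_tolerance():
    with pytest.raises(ValueError, match="unassignable"):
        assign_root(
            single_scan_tree(308.2000),
            known_formula=parse_formula("C10H18N3O6S"),
        )


# ---------------------------------------------------------------------------
# full assignment on the worked example
# ---------------------------------------------------------------------------

def test_glutathione_tree_reconstruction():
    """The published 21-EFP glutathione tree is reproduced verbatim from
    its printed masses, ppm errors and hierarchy."""
    tree, expected = build_glutathione_tree()
    assert efp_strings(tree) == expected
    assert len(efp_strings(tree)) == 21


def test_glutathione_ppm_errors_recovered():
    tree, _ = build_glutathione_tree()
    _, _, expected_ppm = glutathione_fixture()
    for node in tree.iter_nodes():
        assert node.ppm_error == pytest.approx(
            expected_ppm[node.efp_string], abs=0.05
        )


def test_artifact_peak_dropped():
    """A peak admitting no CHNOPS sub-formula under the precursor cap is
    discarded rather than annotated."""
    ms1 = Scan("1", 1, peaks=[Peak(308.0911, 1e6)])
    ms2 = Scan("2", 2, precursor_mz=308.0911, precursor_scan_id="1",
               peaks=[Peak(179.0487, 5e4), Peak(298.000, 4e4)])
    stree = SpectrumTree([ms1, ms2], {"1": None, "2": "1"})
    tree = assign_tree(stree, root_formula=parse_formula("C10H18N3O6S"))
    efps = efp_strings(tree)
    assert efps == {
        "C10H18N3O6S1",
        "C10H18N3O6S1||C5H11N2O3S1",
    }


def test_root_only_tree():
    tree = assign_tree(
        single_scan_tree(308.0911), root_formula=parse_formula("C10H18N3O6S")
    )
    assert efp_strings(tree) == {"C10H18N3O6S1"}


def test_hierarchy_soundness_on_noisy_run():
    from fragtree import is_subformula

    truth, expected, _ = glutathione_fixture()
    scans = simulate_acquisition(
        truth,
        noise=NoiseModel(mass_sigma_ppm=1.5, intensity_cv=0.05,
                         artifact_rate=2.0, seed=11),
        repetitions=3,
    )
    for stree in link_precursors(scans):
        tree = assign_tree(stree, root_formula=parse_formula("C10H18N3O6S"))
        for node in tree.iter_nodes():
            for parent, child in zip(node.efp, node.efp[1:]):
                assert is_subformula(child, parent)
        assert efp_strings(tree) <= expected  # never invents paths


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def tree_with_efps(paths, rels=None):
    """Small hand-built fragmentation tree from EFP token paths."""
    glut = parse_formula("C10H18N3O6S")
    root = FragmentNode((glut,), 308.0911, 100.0, 0.0)
    nodes = {("C10H18N3O6S1",): root}
    rels = rels or {}
    for path in sorted(paths, key=lambda p: p.count("||")):
        tokens = tuple(path.split("||"))
        if tokens in nodes:
            continue
        parent = nodes[tokens[:-1]]
        node = FragmentNode(
            parent.efp + (parse_formula(tokens[-1]),),
            100.0,
            rels.get(path, 50.0),
            0.0,
        )
        parent.children.append(node)
        nodes[tokens] = node
    return FragmentationTree(root=root)


BRANCH = "C10H18N3O6S1||C5H11N2O3S1"


def test_consensus_forty_percent_rule_is_inclusive():
    """Present in exactly 2 of 5 repetitions (40%) -> retained;
    1 of 5 (20%) -> discarded."""
    rare = "C10H18N3O6S1||C8H13N2O4S1"
    trees = (
        [tree_with_efps([BRANCH, rare])]
        + [tree_with_efps([BRANCH])]
        + [tree_with_efps([])] * 3
    )
    trees[1].root.children[0].rel_intensity = 50.0
    cons = consensus(trees, min_fraction=0.4)
    assert BRANCH in cons.entries  # 2/5 = 40%, inclusive
    assert rare not in cons.entries  # 1/5
    assert cons.entries[BRANCH].presence_fraction == pytest.approx(0.4)


def test_consensus_statistics():
    trees = [
        tree_with_efps([BRANCH], rels={BRANCH: 40.0}),
        tree_with_efps([BRANCH], rels={BRANCH: 60.0}),
    ]
    cons = consensus(trees)
    entry = cons.entries[BRANCH]
    assert entry.mean_rel_intensity == pytest.approx(50.0)
    assert entry.sd_rel_intensity == pytest.approx(np.std([40, 60], ddof=1))
    # constant intensity across repetitions -> sd 0
    root_entry = cons.entries["C10H18N3O6S1"]
    assert root_entry.sd_rel_intensity == 0.0


def test_consensus_monotone_in_min_fraction():
    rng = np.random.default_rng(3)
    pool = [BRANCH, "C10H18N3O6S1||C8H13N2O4S1", "C10H18N3O6S1||C5H8N1O3S1"]
    trees = [
        tree_with_efps([p for p in pool if rng.random() < 0.6]) for _ in range(6)
    ]
    previous = None
    for fraction in (0.2, 0.4, 0.6, 0.8, 1.0):
        kept = set(consensus(trees, fraction).entries)
        if previous is not None:
            assert kept <= previous
        previous = kept


def test_consensus_rejects_mixed_roots():
    a = tree_with_efps([])
    b = FragmentationTree(
        root=FragmentNode((parse_formula("C5H11N2O3S"),), 179.0, 100.0, 0.0)
    )
    with pytest.raises(ValueError, match="identical root"):
        consensus([a, b])


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def test_json_round_trip_and_determinism(tmp_path):
    tree, _ = build_glutathione_tree()
    p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
    export_json(tree, str(p1))
    export_json(tree, str(p2))
    assert p1.read_bytes() == p2.read_bytes()  # byte-identical
    back = load_json(str(p1))
    assert efp_strings(back) == efp_strings(tree)
    for n1, n2 in zip(
        sorted(tree.iter_nodes(), key=lambda n: n.efp_string),
        sorted(back.iter_nodes(), key=lambda n: n.efp_string),
    ):
        assert n2.rel_intensity == pytest.approx(n1.rel_intensity)


def test_consensus_json_round_trip(tmp_path):
    tree, _ = build_glutathione_tree()
    cons = consensus([tree])
    path = tmp_path / "cons.json"
    export_json(cons, str(path))
    back = load_json(str(path))
    assert back.efp_set() == cons.efp_set()
    assert back.n_repetitions == 1


def test_cml_has_one_molecule_per_efp(tmp_path):
    from lxml import etree

    tree, expected = build_glutathione_tree()
    path = tmp_path / "tree.cml"
    export_cml(tree, str(path))
    doc = etree.parse(str(path))
    ns = {"cml": "http://www.xml-cml.org/schema"}
    molecules = doc.findall(".//cml:molecule", ns)
    assert len(molecules) == 21
    labels = {m.find("cml:label", ns).get("value") for m in molecules}
    assert labels == expected
    # one spectrum element per MS level
    spectra = doc.findall(".//cml:spectrum", ns)
    assert [s.get("id") for s in spectra] == ["ms1", "ms2", "ms3", "ms4", "ms5"]


def test_cml_empty_consensus(tmp_path):
    from lxml import etree

    cons = consensus([tree_with_efps([])], min_fraction=0.4)
    cons.entries.clear()
    path = tmp_path / "empty.cml"
    export_cml(cons, str(path))
    doc = etree.parse(str(path))
    assert doc.getroot().tag.endswith("cml")
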