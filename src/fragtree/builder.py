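"""Hierarchy-constrained elemental-formula assignment.

This is the core of the package: every peak of a linked MS^n spectrum
tree receives candidate elemental formulas enumerated under the
constraint that a fragment ion cannot contain more atoms of any element
than its precursor ion (equivalently, the implied neutral loss is
non-negative element-wise and fragment + loss = precursor exactly).
Peaks admitting no candidate are artifacts and are discarded; the
survivors form a fragmentation tree whose nodes are identified by their
Elemental Formula Path (EFP) — the list of ion formulas from the root
precursor down to the fragment, serialized with ``||`` separators.

Repeated acquisitions are aggregated into a consensus tree retaining
the EFPs present in at least a minimum fraction (default 40%) of the
single-repetition trees.
"""

from __future__ import annotations

import json
import logging
import statistics
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from lxml import etree

from .formula import (
    ElementalFormula,
    FormulaConstraints,
    IonSpec,
    enumerate_candidates,
    ion_mz,
    is_subformula,
    parse_formula,
    ppm_error,
    serialize_formula,
)
from .spectra import Scan, SpectrumTree, normalize_intensities

log = logging.getLogger(__name__)

__all__ = [
    "FragmentNode",
    "FragmentationTree",
    "ConsensusTree",
    "assign_root",
    "assign_tree",
    "efp_strings",
    "consensus",
    "export_json",
    "load_json",
    "export_cml",
]


@dataclass
class FragmentNode:
    """A formula-annotated fragment ion in a fragmentation tree."""

    efp: Tuple[ElementalFormula, ...]
    observed_mz: float
    rel_intensity: float
    ppm_error: float
    children: List["FragmentNode"] = field(default_factory=list)
    ambiguous: bool = False

    @property
    def formula(self) -> ElementalFormula:
        return self.efp[-1]

    @property
    def ms_level(self) -> int:
        return len(self.efp)

    @property
    def efp_string(self) -> str:
        return "||".join(serialize_formula(f, "efp_token") for f in self.efp)


@dataclass
class FragmentationTree:
    """A rooted, formula-annotated fragmentation tree of one compound."""

    root: FragmentNode
    compound_id: str = ""
    polarity: int = +1
    params: Optional[FormulaConstraints] = None

    def iter_nodes(self) -> List[FragmentNode]:
        out: List[FragmentNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return out


@dataclass
class ConsensusEntry:
    presence_fraction: float
    mean_rel_intensity: float
    sd_rel_intensity: float
    mean_ppm_error: float
    ms_level: int


@dataclass
class ConsensusTree:
    """EFP-keyed statistics over repeated acquisitions of one compound."""

    entries: Dict[str, ConsensusEntry]
    n_repetitions: int
    root_formula: ElementalFormula
    polarity: int = +1
    min_fraction: float = 0.4

    def efp_set(self) -> Set[str]:
        return set(self.entries)


# ---------------------------------------------------------------------------
# Assignment
# ---------------------------------------------------------------------------

def assign_root(
    tree: SpectrumTree,
    known_formula: Optional[ElementalFormula] = None,
    constraints: Optional[FormulaConstraints] = None,
    polarity: int = +1,
) -> Tuple[ElementalFormula, float]:
    """Assign the precursor-ion formula to the MS1 root peak.

    With ``known_formula`` the observed root m/z merely validates it
    (within the ppm tolerance); otherwise the best-ranked enumeration
    candidate is taken.  Isotope-pattern information plays no role.
    """
    c = constraints or FormulaConstraints()
    root_mz = tree.root_mz
    if root_mz is None:
        raise ValueError("spectrum tree has no root m/z")
    if known_formula is not None:
        theo = ion_mz(IonSpec(known_formula, polarity))
        err = ppm_error(root_mz, theo)
        if abs(err) > c.tol_ppm:
            raise ValueError(
                f"unassignable precursor: {serialize_formula(known_formula)} is "
                f"{err:.1f} ppm from the observed root m/z {root_mz:.4f}"
            )
        return known_formula, err
    candidates = enumerate_candidates(root_mz, polarity, c.with_cap(None))
    if not candidates:
        raise ValueError(
            f"unassignable precursor: no formula within {c.tol_ppm} ppm "
            f"of m/z {root_mz:.4f}"
        )
    return candidates[0]


def _closest_peak_index(scan: Scan, mz: float, tol: float) -> Optional[int]:
    best, best_d = None, tol
    for i, peak in enumerate(scan.peaks):
        d = abs(peak.mz - mz)
        if d <= best_d:
            best, best_d = i, d
    return best


def assign_tree(
    tree: SpectrumTree,
    root_formula: Optional[ElementalFormula] = None,
    constraints: Optional[FormulaConstraints] = None,
    polarity: int = +1,
    link_tol_mz: float = 0.5,
    compound_id: str = "",
) -> FragmentationTree:
    """Assign formulas to every peak of a spectrum tree, top down.

    Each scan's peaks are matched against candidate formulas capped by
    the scan's precursor-ion formula; peaks with no surviving candidate
    are dropped as artifacts, residual ambiguities are resolved by
    minimum \\|ppm\\| then lexicographic order (and flagged).  A peak
    that was fragmented but received no formula takes its subtree down
    with it.
    """
    c = constraints or FormulaConstraints()
    root_ion, root_err = assign_root(tree, root_formula, c, polarity)

    root_node = FragmentNode(
        efp=(root_ion,),
        observed_mz=tree.root_mz,
        rel_intensity=100.0,
        ppm_error=root_err,
    )

    def process_scan(scan: Scan, parent_node: FragmentNode) -> None:
        """Assign a scan's peaks under the parent ion's formula cap."""
        try:
            normalized = normalize_intensities(scan)
        except ValueError:
            log.warning("scan %s empty after filtering; skipped", scan.scan_id)
            return
        scan_constraints = c.with_cap(parent_node.formula)
        nodes_by_peak: Dict[int, FragmentNode] = {}
        chosen_by_formula: Dict[ElementalFormula, int] = {}
        for i, peak in enumerate(normalized.peaks):
            candidates = enumerate_candidates(peak.mz, polarity, scan_constraints)
            if not candidates:
                log.debug(
                    "peak %.4f in scan %s dropped: no formula under cap %s",
                    peak.mz,
                    scan.scan_id,
                    serialize_formula(parent_node.formula),
                )
                continue
            formula, err = candidates[0]
            if formula in chosen_by_formula:
                # duplicate EFP within one scan: keep the more intense peak
                other = nodes_by_peak[chosen_by_formula[formula]]
                if peak.rel_intensity <= other.rel_intensity:
                    continue
                del nodes_by_peak[chosen_by_formula[formula]]
            node = FragmentNode(
                efp=parent_node.efp + (formula,),
                observed_mz=peak.mz,
                rel_intensity=peak.rel_intensity,
                ppm_error=err,
                ambiguous=len(candidates) > 1,
            )
            nodes_by_peak[i] = node
            chosen_by_formula[formula] = i
        for i in sorted(nodes_by_peak):
            parent_node.children.append(nodes_by_peak[i])
        # recurse into child scans hanging off this scan's peaks
        for child_id in tree.children[scan.scan_id]:
            child_scan = tree.scans[child_id]
            idx = _closest_peak_index(normalized, child_scan.precursor_mz, link_tol_mz)
            if idx is None or idx not in nodes_by_peak:
                log.warning(
                    "fragmented peak at %.4f in scan %s lost its formula; "
                    "subtree of scan %s dropped",
                    child_scan.precursor_mz,
                    scan.scan_id,
                    child_id,
                )
                continue
            process_scan(child_scan, nodes_by_peak[idx])

    for child_id in tree.children[tree.root_id]:
        process_scan(tree.scans[child_id], root_node)

    result = FragmentationTree(
        root=root_node,
        compound_id=compound_id,
        polarity=polarity,
        params=c,
    )
    _assert_hierarchy(result)
    return result


def _assert_hierarchy(tree: FragmentationTree) -> None:
    """Hierarchy soundness: every child is a sub-formula of its parent."""
    seen: Set[str] = set()
    for node in tree.iter_nodes():
        key = node.efp_string
        if key in seen:
            raise AssertionError(f"duplicate EFP in tree: {key}")
        seen.add(key)
        for parent, child in zip(node.efp, node.efp[1:]):
            if not is_subformula(child, parent):
                raise AssertionError(f"hierarchy violation along EFP {key}")


def efp_strings(tree: FragmentationTree) -> Set[str]:
    """The tree as a set of EFP strings (root included)."""
    return {node.efp_string for node in tree.iter_nodes()}


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------

def consensus(
    trees: Sequence[FragmentationTree], min_fraction: float = 0.4
) -> ConsensusTree:
    """Aggregate repeated acquisitions into a consensus tree.

    An EFP is retained iff it is present in at least ``min_fraction``
    of the trees (inclusive: 2 of 5 survives the default 40% rule).
    Mean and sample (n-1) standard deviation of the relative intensity
    are computed over the trees where the EFP is present.
    """
    if not trees:
        raise ValueError("consensus requires at least one tree")
    roots = {t.root.formula for t in trees}
    if len(roots) != 1:
        raise ValueError("consensus requires identical root formulas")
    by_efp: Dict[str, List[FragmentNode]] = {}
    for tree in trees:
        for node in tree.iter_nodes():
            by_efp.setdefault(node.efp_string, []).append(node)
    n = len(trees)
    entries: Dict[str, ConsensusEntry] = {}
    for efp, nodes in by_efp.items():
        fraction = len(nodes) / n
        if fraction < min_fraction:
            continue
        rels = [node.rel_intensity for node in nodes]
        entries[efp] = ConsensusEntry(
            presence_fraction=fraction,
            mean_rel_intensity=statistics.fmean(rels),
            sd_rel_intensity=statistics.stdev(rels) if len(rels) > 1 else 0.0,
            mean_ppm_error=statistics.fmean(node.ppm_error for node in nodes),
            ms_level=nodes[0].ms_level,
        )
    return ConsensusTree(
        entries=entries,
        n_repetitions=n,
        root_formula=next(iter(roots)),
        polarity=trees[0].polarity,
        min_fraction=min_fraction,
    )


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def _node_to_dict(node: FragmentNode) -> dict:
    return {
        "efp": node.efp_string,
        "formula": serialize_formula(node.formula),
        "mz": node.observed_mz,
        "rel_intensity": node.rel_intensity,
        "ppm_error": node.ppm_error,
        "ambiguous": node.ambiguous,
        "children": [
            _node_to_dict(c)
            for c in sorted(node.children, key=lambda n: n.efp_string)
        ],
    }


def export_json(obj, path: str) -> None:
    """Write a fragmentation or consensus tree as deterministic JSON.

    Identical inputs yield byte-identical files (sorted keys, sorted
    children, fixed separators).
    """
    if isinstance(obj, FragmentationTree):
        doc = {
            "type": "fragmentation_tree",
            "compound_id": obj.compound_id,
            "polarity": "+" if obj.polarity >= 0 else "-",
            "root": _node_to_dict(obj.root),
        }
    elif isinstance(obj, ConsensusTree):
        doc = {
            "type": "consensus_tree",
            "polarity": "+" if obj.polarity >= 0 else "-",
            "root_formula": serialize_formula(obj.root_formula),
            "n_repetitions": obj.n_repetitions,
            "min_fraction": obj.min_fraction,
            "entries": {
                efp: {
                    "presence_fraction": e.presence_fraction,
                    "mean_rel_intensity": e.mean_rel_intensity,
                    "sd_rel_intensity": e.sd_rel_intensity,
                    "mean_ppm_error": e.mean_ppm_error,
                    "ms_level": e.ms_level,
                }
                for efp, e in obj.entries.items()
            },
        }
    else:
        raise TypeError(f"cannot export object of type {type(obj).__name__}")
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(doc, handle, indent=1, sort_keys=True, separators=(",", ": "))
        handle.write("\n")


def _node_from_dict(raw: dict) -> FragmentNode:
    efp = tuple(parse_formula(tok) for tok in raw["efp"].split("||"))
    return FragmentNode(
        efp=efp,
        observed_mz=float(raw["mz"]),
        rel_intensity=float(raw["rel_intensity"]),
        ppm_error=float(raw["ppm_error"]),
        ambiguous=bool(raw.get("ambiguous", False)),
        children=[_node_from_dict(c) for c in raw.get("children", [])],
    )


def load_json(path: str):
    """Read back a tree written by :func:`export_json`."""
    with open(path, "r", encoding="utf-8") as handle:
        doc = json.load(handle)
    kind = doc.get("type")
    polarity = +1 if doc.get("polarity", "+") == "+" else -1
    if kind == "fragmentation_tree":
        return FragmentationTree(
            root=_node_from_dict(doc["root"]),
            compound_id=doc.get("compound_id", ""),
            polarity=polarity,
        )
    if kind == "consensus_tree":
        entries = {
            efp: ConsensusEntry(
                presence_fraction=float(e["presence_fraction"]),
                mean_rel_intensity=float(e["mean_rel_intensity"]),
                sd_rel_intensity=float(e["sd_rel_intensity"]),
                mean_ppm_error=float(e["mean_ppm_error"]),
                ms_level=int(e["ms_level"]),
            )
            for efp, e in doc["entries"].items()
        }
        return ConsensusTree(
            entries=entries,
            n_repetitions=int(doc["n_repetitions"]),
            root_formula=parse_formula(doc["root_formula"]),
            polarity=polarity,
            min_fraction=float(doc.get("min_fraction", 0.4)),
        )
    raise ValueError(f"unrecognized tree JSON (type={kind!r})")


_CML_NS = "http://www.xml-cml.org/schema"


def export_cml(obj, path: str) -> None:
    """Write a tree in a documented Chemical Markup Language subset.

    One ``molecule`` element per ion (EFP id, display-dialect formula),
    one ``spectrum`` element per MS level, parent-child links through
    ``ref`` attributes.  See docs/formats.md; full CML conformance is
    not claimed.
    """
    if isinstance(obj, FragmentationTree):
        rows = [
            (n.efp_string, n.ms_level, serialize_formula(n.formula), n.observed_mz,
             n.rel_intensity, n.ppm_error)
            for n in obj.iter_nodes()
        ]
        polarity = obj.polarity
    elif isinstance(obj, ConsensusTree):
        rows = [
            (efp, e.ms_level, serialize_formula(parse_formula(efp.split("||")[-1])),
             None, e.mean_rel_intensity, e.mean_ppm_error)
            for efp, e in obj.entries.items()
        ]
        polarity = obj.polarity
    else:
        raise TypeError(f"cannot export object of type {type(obj).__name__}")
    rows.sort(key=lambda r: (r[1], r[0]))

    ids = {efp: f"ion{i + 1}" for i, (efp, *_) in enumerate(rows)}
    root = etree.Element("{%s}cml" % _CML_NS, nsmap={None: _CML_NS})
    mol_list = etree.SubElement(root, "{%s}moleculeList" % _CML_NS)
    for efp, level, formula, mz, rel, ppm in rows:
        mol = etree.SubElement(mol_list, "{%s}molecule" % _CML_NS)
        mol.set("id", ids[efp])
        mol.set("formalCharge", "1" if polarity > 0 else "-1")
        etree.SubElement(mol, "{%s}formula" % _CML_NS).set("concise", formula)
        label = etree.SubElement(mol, "{%s}label" % _CML_NS)
        label.set("dictRef", "fragtree:efp")
        label.set("value", efp)
    spec_list = etree.SubElement(root, "{%s}spectrumList" % _CML_NS)
    for level in sorted({r[1] for r in rows}):
        spectrum = etree.SubElement(spec_list, "{%s}spectrum" % _CML_NS)
        spectrum.set("id", f"ms{level}")
        spectrum.set("type", "massSpectrum")
        spectrum.set("title", f"MS{level}")
        peak_list = etree.SubElement(spectrum, "{%s}peakList" % _CML_NS)
        for efp, lvl, formula, mz, rel, ppm in rows:
            if lvl != level:
                continue
            peak = etree.SubElement(peak_list, "{%s}peak" % _CML_NS)
            peak.set("id", f"peak-{ids[efp]}")
            peak.set("moleculeRefs", ids[efp])
            parent_efp = "||".join(efp.split("||")[:-1])
            if parent_efp:
                # documented subset extension: precursor-product link
                peak.set("ref", ids[parent_efp])
            if mz is not None:
                peak.set("xValue", f"{mz:.6f}")
            peak.set("yValue", f"{rel:.4f}")
            peak.set("title", f"ppm={ppm:.2f}")
    etree.ElementTree(root).write(
        path, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )
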