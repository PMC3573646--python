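"""Synthetic MS^n acquisitions from ground-truth fragmentation trees.

The generator emulates the data-dependent acquisition used for the
glutathione and prostaglandin studies: one full scan, fragmentation of
the five most intense peaks of each MS2 and MS3 spectrum and the three
most intense peaks of each MS4 spectrum down to MS5, a precursor
intensity threshold of 4500 ion counts, ppm-scale mass noise,
multiplicative relative-intensity noise, and injected artifact peaks
that admit no valid elemental formula under the precursor constraint.

Defaults mirror the study conditions: mass noise sigma of 1 ppm
(bracketing the observed -1.0..+1.7 ppm errors), 2% intensity CV
(relative-intensity standard deviations were typically below 2%), and
five repetitions of the MS^n sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .formula import (
    ELECTRON_MASS,
    MONOISOTOPIC_MASS,
    ElementalFormula,
    FormulaConstraints,
    IonSpec,
    candidate_ok,
    ion_mz,
    is_subformula,
    parse_formula,
    serialize_formula,
    subtract_formula,
)
from .spectra import Peak, Scan, SpectrumTree

__all__ = [
    "TruthNode",
    "GroundTruthTree",
    "AcquisitionScheme",
    "NoiseModel",
    "count_scan_events",
    "simulate_acquisition",
    "spectrum_tree_from_truth",
    "make_random_truth",
    "make_saturating_truth",
    "make_isomer_pair_fixture",
    "glutathione_fixture",
    "GLUTATHIONE_TABLE",
]


# ---------------------------------------------------------------------------
# Ground truth trees
# ---------------------------------------------------------------------------

@dataclass
class TruthNode:
    """An ion in a ground-truth fragmentation tree.

    ``rel_intensity`` is the ion's relative intensity (percent of the
    base peak) *within its spectrum*, i.e. among its siblings.
    """

    formula: ElementalFormula
    rel_intensity: float = 100.0
    children: List["TruthNode"] = field(default_factory=list)


class GroundTruthTree:
    """Rooted tree of ion formulas with per-spectrum relative intensities."""

    def __init__(self, root: TruthNode):
        self.root = root
        self._validate()

    def _validate(self) -> None:
        def walk(node: TruthNode) -> None:
            if node.children:
                seen = set()
                top = max(c.rel_intensity for c in node.children)
                if abs(top - 100.0) > 1e-9:
                    raise ValueError(
                        "each sibling group must contain a base peak at 100%"
                    )
                for child in node.children:
                    if not is_subformula(child.formula, node.formula):
                        raise ValueError(
                            "child formula exceeds its precursor: "
                            f"{serialize_formula(child.formula)} under "
                            f"{serialize_formula(node.formula)}"
                        )
                    if child.formula == node.formula:
                        raise ValueError("fragmentation step must lose mass")
                    if child.formula in seen:
                        raise ValueError("duplicate sibling formula")
                    seen.add(child.formula)
                    walk(child)

        walk(self.root)

    def depth(self) -> int:
        def walk(node: TruthNode) -> int:
            return 1 + max((walk(c) for c in node.children), default=0)

        return walk(self.root)

    def efp_set(self) -> Set[str]:
        """All elemental formula paths of the tree, root included."""
        out: Set[str] = set()

        def walk(node: TruthNode, prefix: Tuple[str, ...]) -> None:
            path = prefix + (serialize_formula(node.formula, "efp_token"),)
            out.add("||".join(path))
            for child in node.children:
                walk(child, path)

        walk(self.root, ())
        return out

    def iter_nodes(self) -> Iterable[TruthNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(node.children)

    @classmethod
    def from_efp_rows(
        cls, rows: Sequence[Tuple[str, float]]
    ) -> "GroundTruthTree":
        """Build a tree from (EFP string, relative intensity) rows.

        Every proper prefix of each path must itself appear as a row.
        """
        by_path: Dict[Tuple[str, ...], TruthNode] = {}
        for efp, rel in rows:
            tokens = tuple(efp.split("||"))
            by_path[tokens] = TruthNode(parse_formula(tokens[-1]), rel)
        root_key = None
        for tokens, node in sorted(by_path.items(), key=lambda kv: len(kv[0])):
            if len(tokens) == 1:
                if root_key is not None:
                    raise ValueError("multiple root rows")
                root_key = tokens
                continue
            parent = by_path.get(tokens[:-1])
            if parent is None:
                raise ValueError(f"missing prefix row for {'||'.join(tokens)}")
            parent.children.append(node)
        if root_key is None:
            raise ValueError("no root row")
        return cls(by_path[root_key])


# ---------------------------------------------------------------------------
# Acquisition scheme and noise
# ---------------------------------------------------------------------------

@dataclass
class AcquisitionScheme:
    """Data-dependent MS^n scheme.

    ``top_n_by_level[L]`` is the number of peaks of an MS^L spectrum
    selected for fragmentation (producing MS^(L+1) scans).  MS1 always
    contributes exactly one selected precursor.
    """

    top_n_by_level: Dict[int, int] = field(default_factory=lambda: {2: 5, 3: 5, 4: 3})
    max_level: int = 5
    precursor_threshold: float = 4500.0
    isolation_width: float = 2.0

    def __post_init__(self) -> None:
        if self.max_level < 2:
            raise ValueError("max_level must be >= 2")
        if any(n < 0 for n in self.top_n_by_level.values()):
            raise ValueError("top_n values must be non-negative")


@dataclass
class NoiseModel:
    """Measurement noise and artifact injection parameters."""

    mass_sigma_ppm: float = 1.0
    intensity_cv: float = 0.02
    artifact_rate: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mass_sigma_ppm", "intensity_cv", "artifact_rate"):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be finite and non-negative")

    @classmethod
    def noiseless(cls, seed: int = 0) -> "NoiseModel":
        return cls(mass_sigma_ppm=0.0, intensity_cv=0.0, artifact_rate=0.0, seed=seed)


def count_scan_events(
    scheme: AcquisitionScheme, assume_full_trees: bool = True
) -> int:
    """Scan events per repetition when every spectrum saturates the scheme.

    One full scan, one MS2 scan of the selected precursor, then at each
    deeper level the running product of the top-N selections:
    1 + 1 + N2 + N2*N3 + ... (defaults 5/5/3 to MS5 give 107).
    """
    del assume_full_trees  # the closed form assumes saturation
    total = 1  # full scan
    width = 1  # number of scans at the current fragmented level
    total += width  # the MS2 scan of the selected MS1 precursor
    for level in range(3, scheme.max_level + 1):
        width *= scheme.top_n_by_level.get(level - 1, 0)
        total += width
    return total


# ---------------------------------------------------------------------------
# Acquisition simulation
# ---------------------------------------------------------------------------

_ROOT_ABS_INTENSITY = 1.0e6
_LEVEL_ATTENUATION = 0.5


_SUBFORMULA_MZ_CACHE: Dict[Tuple[Tuple[int, ...], int], np.ndarray] = {}


def _subformula_ion_mzs(cap: ElementalFormula, polarity: int) -> np.ndarray:
    """Sorted ion m/z of every non-empty sub-formula of ``cap``."""
    key = (cap.count_vector, polarity)
    cached = _SUBFORMULA_MZ_CACHE.get(key)
    if cached is not None:
        return cached
    per_element = [
        np.arange(n + 1) * MONOISOTOPIC_MASS[elem]
        for elem, n in zip(("C", "H", "N", "O", "P", "S"), cap.count_vector)
    ]
    masses = np.zeros(1)
    for axis in per_element:
        masses = (masses[:, None] + axis[None, :]).ravel()
    masses = np.sort(masses[masses > 0]) - polarity * ELECTRON_MASS
    _SUBFORMULA_MZ_CACHE[key] = masses
    return masses


def _artifact_mz(
    rng: np.random.Generator,
    cap: ElementalFormula,
    polarity: int,
    tol_ppm: float,
    lo: float,
    hi: float,
) -> float:
    """Random m/z at least 2 x ``tol_ppm`` away from every sub-formula ion mass.

    Rejection sampling makes "artifact" well-defined at generation time:
    such a peak can never receive a formula under the precursor cap.
    """
    arr = _subformula_ion_mzs(cap, polarity)
    for _ in range(10_000):
        mz = float(rng.uniform(lo, hi))
        idx = int(np.searchsorted(arr, mz))
        nearest = min(
            abs(mz - arr[j]) / arr[j] * 1e6
            for j in (max(idx - 1, 0), min(idx, len(arr) - 1))
        )
        if nearest > 2.0 * tol_ppm:
            return mz
    raise RuntimeError("could not sample an artifact m/z (window too dense)")


def simulate_acquisition(
    truth: GroundTruthTree,
    scheme: Optional[AcquisitionScheme] = None,
    noise: Optional[NoiseModel] = None,
    repetitions: int = 1,
    polarity: int = +1,
    tol_ppm: float = 6.0,
) -> List[Scan]:
    """Simulate repeated data-dependent MS^n acquisitions of one compound.

    Per repetition: an MS1 scan carrying the root ion; each fragmented
    peak (top-N by observed intensity, above the precursor threshold)
    yields a child scan containing the truth node's children with
    m/z = theoretical ion m/z x (1 + eps), eps ~ N(0, mass_sigma_ppm e-6),
    intensities perturbed multiplicatively (log-normal, given CV), plus
    Poisson(artifact_rate) artifact peaks.  Fully deterministic given
    the noise model's seed.
    """
    scheme = scheme or AcquisitionScheme()
    noise = noise or NoiseModel()
    if truth.depth() > scheme.max_level:
        raise ValueError(
            f"truth tree depth {truth.depth()} exceeds max_level {scheme.max_level}"
        )
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")

    scans: List[Scan] = []
    counter = 0

    for rep in range(repetitions):
        # fixed-arithmetic child seed per repetition (kept below 2**31)
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=noise.seed, spawn_key=(rep,))
        )

        def next_id() -> str:
            nonlocal counter
            counter += 1
            return str(counter)

        def observe(node: TruthNode, scale: float) -> Tuple[float, float]:
            """Noisy (m/z, absolute intensity) of a truth ion."""
            theo = ion_mz(IonSpec(node.formula, polarity))
            eps = rng.normal(0.0, noise.mass_sigma_ppm * 1e-6) if noise.mass_sigma_ppm else 0.0
            mz = theo * (1.0 + eps)
            abs_int = scale * node.rel_intensity / 100.0
            if noise.intensity_cv:
                sigma = math.sqrt(math.log(1.0 + noise.intensity_cv**2))
                abs_int *= float(rng.lognormal(-0.5 * sigma**2, sigma))
            return mz, abs_int

        def artifacts(cap: ElementalFormula, lo: float, hi: float) -> List[Peak]:
            if not noise.artifact_rate:
                return []
            k = int(rng.poisson(noise.artifact_rate))
            out = []
            for _ in range(k):
                mz = _artifact_mz(rng, cap, polarity, tol_ppm, lo, hi)
                # below the precursor threshold: DDA never selects these
                out.append(Peak(mz, float(rng.uniform(1.0, 0.5 * scheme.precursor_threshold))))
            return out

        def emit(
            truth_nodes: Sequence[TruthNode],
            level: int,
            scale: float,
            precursor_mz: Optional[float],
            precursor_id: Optional[str],
            cap: ElementalFormula,
        ) -> None:
            observed = [(node, *observe(node, scale)) for node in truth_nodes]
            peaks = [Peak(mz, inten) for _, mz, inten in observed]
            root_ion_mz = ion_mz(IonSpec(truth.root.formula, polarity))
            peaks += artifacts(cap, 50.0, root_ion_mz * 1.05)
            scan = Scan(
                scan_id=next_id(),
                ms_level=level,
                polarity=polarity,
                precursor_mz=precursor_mz,
                precursor_scan_id=precursor_id,
                peaks=peaks,
            )
            scans.append(scan)
            if level >= scheme.max_level:
                return
            top_n = 1 if level == 1 else scheme.top_n_by_level.get(level, 0)
            eligible = [
                (node, mz, inten)
                for node, mz, inten in observed
                if inten >= scheme.precursor_threshold
            ]
            eligible.sort(key=lambda item: (-item[2], item[1]))
            for node, mz, inten in eligible[:top_n]:
                if not node.children:
                    continue
                emit(
                    node.children,
                    level + 1,
                    scale * _LEVEL_ATTENUATION,
                    precursor_mz=mz,
                    precursor_id=scan.scan_id,
                    cap=node.formula,
                )

        emit(
            [truth.root],
            level=1,
            scale=_ROOT_ABS_INTENSITY,
            precursor_mz=None,
            precursor_id=None,
            cap=truth.root.formula,
        )
    return scans


def spectrum_tree_from_truth(
    truth: GroundTruthTree,
    ppm_by_efp: Optional[Dict[str, float]] = None,
    polarity: int = +1,
    abs_scale: float = _ROOT_ABS_INTENSITY,
) -> SpectrumTree:
    """Deterministic spectrum hierarchy of a truth tree (no DDA, no noise).

    Every truth node with children contributes one scan holding those
    children; observed m/z values are the theoretical ion m/z, each
    optionally offset by a per-EFP ppm error.  This is how the printed
    worked example (theoretical masses perturbed by the listed ppm
    errors) is turned back into an input spectrum hierarchy.
    """
    ppm_by_efp = ppm_by_efp or {}
    scans: List[Scan] = []
    parent_ids: Dict[str, Optional[str]] = {}
    counter = 0

    def observed_mz(node: TruthNode, path: Tuple[str, ...]) -> float:
        theo = ion_mz(IonSpec(node.formula, polarity))
        ppm = ppm_by_efp.get("||".join(path), 0.0)
        return theo * (1.0 + ppm * 1e-6)

    def new_scan(
        level: int, peaks: List[Peak], pmz: Optional[float], pid: Optional[str]
    ) -> Scan:
        nonlocal counter
        counter += 1
        scan = Scan(
            scan_id=str(counter),
            ms_level=level,
            polarity=polarity,
            precursor_mz=pmz,
            precursor_scan_id=pid,
            peaks=peaks,
        )
        scans.append(scan)
        parent_ids[scan.scan_id] = pid
        return scan

    root_path = (serialize_formula(truth.root.formula, "efp_token"),)
    root_mz = observed_mz(truth.root, root_path)
    ms1 = new_scan(1, [Peak(root_mz, abs_scale)], None, None)

    def walk(
        node: TruthNode,
        node_mz: float,
        path: Tuple[str, ...],
        level: int,
        scale: float,
        parent_scan: Scan,
    ) -> None:
        if not node.children:
            return
        child_info = []
        for child in node.children:
            cpath = path + (serialize_formula(child.formula, "efp_token"),)
            child_info.append(
                (child, observed_mz(child, cpath), cpath, scale * child.rel_intensity / 100.0)
            )
        scan = new_scan(
            level + 1,
            [Peak(mz, inten) for _, mz, _, inten in child_info],
            node_mz,
            parent_scan.scan_id,
        )
        for child, mz, cpath, _ in child_info:
            walk(child, mz, cpath, level + 1, scale * _LEVEL_ATTENUATION, scan)

    walk(truth.root, root_mz, root_path, 1, _ROOT_ABS_INTENSITY, ms1)
    return SpectrumTree(scans, parent_ids, repetition_id=0)


# ---------------------------------------------------------------------------
# Truth-tree generators
# ---------------------------------------------------------------------------

#: neutral-loss pool used to grow plausible fragment formulas; every loss
#: is a real neutral molecule (integer RDBE), so a half-integer-RDBE ion
#: stays on the half-integer grid after each loss.
_NEUTRAL_LOSSES = [
    "H2O", "CO", "CO2", "NH3", "CH2O", "CH4", "C2H4", "H2S",
    "CH2O2", "C2H4O", "C2H4O2", "HCN", "CH3N", "SO", "H2O2", "C2H2",
    "CH4O", "C3H6", "NO", "C2H6",
]


def _valid_child(
    parent: ElementalFormula, loss: ElementalFormula, constraints: FormulaConstraints
) -> Optional[ElementalFormula]:
    if not is_subformula(loss, parent):
        return None
    child = subtract_formula(parent, loss)
    if not child or child["C"] == 0:
        return None
    if not candidate_ok(child, constraints.with_cap(parent)):
        return None
    return child


def make_random_truth(
    rng: np.random.Generator,
    root: ElementalFormula,
    branching: Sequence[int],
    constraints: Optional[FormulaConstraints] = None,
) -> GroundTruthTree:
    """Random feasible truth tree rooted at ``root``.

    ``branching[d]`` is the target number of children at depth d (root =
    depth 0); actual counts may be lower when the formula space is
    exhausted.  All generated formulas pass the default plausibility
    filters, so a noise-free acquisition of the tree is fully
    assignable.
    """
    constraints = constraints or FormulaConstraints()
    losses = [parse_formula(t) for t in _NEUTRAL_LOSSES]

    def grow(node: TruthNode, depth: int) -> None:
        if depth >= len(branching):
            return
        want = branching[depth]
        children: List[TruthNode] = []
        seen = set()
        order = rng.permutation(len(losses))
        for idx in order:
            if len(children) >= want:
                break
            child = _valid_child(node.formula, losses[idx], constraints)
            if child is None or child in seen:
                continue
            seen.add(child)
            rel = 100.0 if not children else float(rng.uniform(20.0, 95.0))
            children.append(TruthNode(child, rel))
        node.children = children
        for child in children:
            grow(child, depth + 1)

    root_node = TruthNode(root, 100.0)
    grow(root_node, 0)
    return GroundTruthTree(root_node)


def make_saturating_truth(
    scheme: Optional[AcquisitionScheme] = None,
    root: Optional[ElementalFormula] = None,
) -> GroundTruthTree:
    """A truth tree wide and deep enough to saturate the DDA scheme.

    With the default 5/5/3 scheme to MS5 a simulated repetition emits
    exactly :func:`count_scan_events` scans (107 by default).
    """
    scheme = scheme or AcquisitionScheme()
    root = root or parse_formula("C30H48N5O10S2")
    constraints = FormulaConstraints()
    losses = [parse_formula(t) for t in _NEUTRAL_LOSSES]

    def grow(node: TruthNode, level: int) -> None:
        # children of a depth-L node form the MS^(L+1) scan; that scan
        # needs top_n_by_level[L+1] fragmentable peaks, or just one peak
        # when it is the terminal level
        if level >= scheme.max_level:
            return
        if level + 1 == scheme.max_level:
            want = 1
        else:
            want = scheme.top_n_by_level.get(level + 1, 0)
        children: List[TruthNode] = []
        seen = set()
        for loss in losses:
            if len(children) >= want:
                break
            child = _valid_child(node.formula, loss, constraints)
            if child is None or child in seen:
                continue
            seen.add(child)
            rel = 100.0 if not children else 100.0 - 10.0 * len(children)
            children.append(TruthNode(child, rel))
        if len(children) < want:
            raise RuntimeError("loss pool exhausted while saturating the scheme")
        node.children = children
        for child in children:
            grow(child, level + 1)

    root_node = TruthNode(root, 100.0)
    grow(root_node, 1)
    return GroundTruthTree(root_node)


def make_isomer_pair_fixture(
    n_a: int,
    n_b: int,
    n_shared: int,
    seed: int = 0,
    root: Optional[ElementalFormula] = None,
) -> Tuple[GroundTruthTree, GroundTruthTree]:
    """Two same-root truth trees with prescribed EFP-set overlap.

    Emulates a pair of structural isomers (e.g. two prostaglandins
    measured as [M-H]- ions): both trees share the root EFP, their EFP
    sets have sizes ``n_a`` and ``n_b`` and intersect in exactly
    ``n_shared`` paths.  Raises ``ValueError`` for infeasible counts
    (the shared root makes ``n_shared = 0`` impossible).
    """
    root = root or parse_formula("C20H31O5")  # deprotonated prostaglandin
    if n_shared < 1:
        raise ValueError("the root EFP is always shared, so n_shared must be >= 1")
    if n_shared > min(n_a, n_b):
        raise ValueError("n_shared cannot exceed either set size")
    constraints = FormulaConstraints()
    rng = np.random.default_rng(seed)

    # distinct child formulas of the root, via composite neutral losses
    pool: List[ElementalFormula] = []
    seen = set()
    base_losses = [parse_formula(t) for t in _NEUTRAL_LOSSES]
    for first in base_losses:
        for second in [None] + base_losses:
            loss = first if second is None else first + second
            child = _valid_child(root, loss, constraints)
            if child is not None and child not in seen:
                seen.add(child)
                pool.append(child)
    needed = (n_shared - 1) + (n_a - n_shared) + (n_b - n_shared)
    if needed > len(pool):
        raise ValueError(
            f"cannot build {needed} distinct fragment formulas under "
            f"{serialize_formula(root)} (pool size {len(pool)})"
        )
    order = rng.permutation(len(pool))
    picks = [pool[i] for i in order[:needed]]
    shared = picks[: n_shared - 1]
    only_a = picks[n_shared - 1 : n_shared - 1 + (n_a - n_shared)]
    only_b = picks[n_shared - 1 + (n_a - n_shared) :]

    def build(extras: List[ElementalFormula]) -> GroundTruthTree:
        children = []
        for i, formula in enumerate(shared + extras):
            rel = 100.0 if i == 0 else max(10.0, 95.0 - 2.0 * i)
            children.append(TruthNode(formula, rel))
        if not children:
            return GroundTruthTree(TruthNode(root, 100.0))
        children[0].rel_intensity = 100.0
        return GroundTruthTree(TruthNode(root, 100.0, children))

    return build(only_a), build(only_b)


# ---------------------------------------------------------------------------
# Glutathione worked example
# ---------------------------------------------------------------------------

#: the published glutathione fragmentation tree: one row per elemental
#: formula path with its MS level, relative intensity (percent of its
#: spectrum's base peak), observed mass error (ppm) and the
#: between-repetition standard deviation of the relative intensity.
GLUTATHIONE_TABLE: Tuple[Tuple[str, int, float, float, float], ...] = (
    ("C10H18N3O6S1", 1, 100.0, -0.5, 0.0),
    ("C10H18N3O6S1||C5H11N2O3S1", 2, 100.0, 1.3, 0.0),
    ("C10H18N3O6S1||C5H11N2O3S1||C5H8N1O3S1", 3, 100.0, 0.2, 0.0),
    ("C10H18N3O6S1||C5H11N2O3S1||C5H8N1O3S1||C4H6N1O1S1", 4, 27.0, -0.3, 1.4),
    ("C10H18N3O6S1||C5H11N2O3S1||C5H8N1O3S1||C5H6N1O2S1", 4, 100.0, 0.1, 0.0),
    ("C10H18N3O6S1||C5H11N2O3S1||C5H8N1O3S1||C5H6N1O2S1||C4H6N1O1S1", 5, 100.0, -0.4, 0.0),
    ("C10H18N3O6S1||C5H8N1O3S1", 2, 33.0, 1.3, 1.8),
    ("C10H18N3O6S1||C5H8N1O3S1||C4H6N1O1S1", 3, 27.0, -0.4, 1.4),
    ("C10H18N3O6S1||C5H8N1O3S1||C5H6N1O2S1", 3, 100.0, 0.1, 0.0),
    ("C10H18N3O6S1||C5H8N1O3S1||C5H6N1O2S1||C4H6N1O1S1", 4, 100.0, -0.5, 0.0),
    ("C10H18N3O6S1||C8H13N2O4S1", 2, 25.0, 1.7, 1.4),
    ("C10H18N3O6S1||C8H13N2O4S1||C7H11N2O2S1", 3, 100.0, 0.8, 0.0),
    ("C10H18N3O6S1||C8H13N2O4S1||C7H11N2O2S1||C7H8N1O2S1", 4, 100.0, 0.5, 0.0),
    ("C10H18N3O6S1||C8H13N2O4S1||C7H11N2O2S1||C7H8N1O2S1||C6H6N1S1", 5, 100.0, -0.4, 0.0),
    ("C10H18N3O6S1||C8H13N2O4S1||C8H11N2O3S1", 3, 32.0, 0.9, 3.5),
    ("C10H18N3O6S1||C8H13N2O4S1||C8H11N2O3S1||C7H11N2O2S1", 4, 100.0, 0.8, 0.0),
    ("C10H18N3O6S1||C8H13N2O4S1||C8H11N2O3S1||C7H11N2O2S1||C6H9N2S1", 5, 100.0, -0.1, 0.0),
    ("C10H18N3O6S1||C8H13N2O4S1||C8H11N2O3S1||C7H11N2O2S1||C7H8N1O2S1", 5, 82.0, 0.3, 8.7),
    ("C10H18N3O6S1||C5H11N2O3S1||C5H8N1O3S1||C4H6N1O1S1||C3H6N1S1", 5, 100.0, -1.0, 0.0),
    ("C10H18N3O6S1||C5H8N1O3S1||C4H6N1O1S1||C3H6N1S1", 4, 100.0, -1.0, 0.0),
    ("C10H18N3O6S1||C5H8N1O3S1||C5H6N1O2S1||C4H6N1O1S1||C3H6N1S1", 5, 100.0, -1.0, 0.0),
)


def glutathione_fixture() -> Tuple[GroundTruthTree, Set[str], Dict[str, float]]:
    """The published glutathione fragmentation tree as a packaged fixture.

    Returns the ground-truth tree (protonated glutathione,
    C10H18N3O6S, and its 21 elemental formula paths), the expected EFP
    strings, and the per-EFP observed mass errors (ppm) used to perturb
    theoretical masses when reconstructing the input spectra.
    """
    truth = GroundTruthTree.from_efp_rows(
        [(efp, rel) for efp, _, rel, _, _ in GLUTATHIONE_TABLE]
    )
    expected = {efp for efp, *_ in GLUTATHIONE_TABLE}
    ppm = {efp: err for efp, _, _, err, _ in GLUTATHIONE_TABLE}
    return truth, expected, ppm
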