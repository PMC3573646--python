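"""Reading, linking and normalizing MS^n spectra.

An MS^n acquisition is a flat sequence of scans; the precursor m/z
attributes recoverable from mzXML link each MS^n (n >= 2) scan to a peak
in a parent scan of level n-1, turning the run into one rooted spectrum
tree per within-run repetition of the acquisition sequence.
"""

from __future__ import annotations

import base64
import json
import logging
import struct
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from pyteomics import mzxml as _pyteomics_mzxml

log = logging.getLogger(__name__)

__all__ = [
    "Peak",
    "Scan",
    "SpectrumTree",
    "read_mzxml",
    "write_mzxml",
    "link_precursors",
    "normalize_intensities",
    "threshold_filter",
    "composite_spectrum",
    "write_peaktree_json",
    "read_peaktree_json",
]


@dataclass(frozen=True)
class Peak:
    """A centroided mass peak."""

    mz: float
    intensity: float
    rel_intensity: Optional[float] = None  # percent of the scan's base peak

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"non-positive m/z {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"negative intensity {self.intensity}")


@dataclass
class Scan:
    """One centroided scan with its precursor linkage attributes."""

    scan_id: str
    ms_level: int
    polarity: int = +1
    precursor_mz: Optional[float] = None
    precursor_scan_id: Optional[str] = None
    peaks: List[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.ms_level < 1:
            raise ValueError("ms_level must be >= 1")
        if self.ms_level == 1 and self.precursor_mz is not None:
            raise ValueError("MS1 scan cannot carry a precursor m/z")
        if self.ms_level > 1 and self.precursor_mz is None:
            raise ValueError("MS^n scan (n >= 2) requires a precursor m/z")

    @property
    def base_peak(self) -> Optional[Peak]:
        return max(self.peaks, key=lambda p: p.intensity, default=None)


class SpectrumTree:
    """Scans arranged as a rooted hierarchy by precursor links.

    The root is an MS1 scan; each child scan's level is its parent's
    level plus one.  Construction validates acyclicity and level
    consistency.
    """

    def __init__(
        self,
        scans: Sequence[Scan],
        parent_ids: Dict[str, Optional[str]],
        repetition_id: int = 0,
    ):
        self.scans: Dict[str, Scan] = {}
        for scan in scans:
            if scan.scan_id in self.scans:
                raise ValueError(f"duplicate scan id {scan.scan_id!r}")
            self.scans[scan.scan_id] = scan
        self.parent_ids = dict(parent_ids)
        self.repetition_id = repetition_id
        self.children: Dict[str, List[str]] = {sid: [] for sid in self.scans}
        roots = []
        for sid in self.scans:
            pid = self.parent_ids.get(sid)
            if pid is None:
                roots.append(sid)
            else:
                if pid not in self.scans:
                    raise ValueError(f"scan {sid!r} links to unknown parent {pid!r}")
                self.children[pid].append(sid)
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root scan, found {len(roots)}")
        self.root_id = roots[0]
        self._validate()

    def _validate(self) -> None:
        seen = set()
        stack = [self.root_id]
        while stack:
            sid = stack.pop()
            if sid in seen:
                raise ValueError("cycle detected in precursor links")
            seen.add(sid)
            level = self.scans[sid].ms_level
            for child in self.children[sid]:
                if self.scans[child].ms_level != level + 1:
                    raise ValueError(
                        f"scan {child!r} at level {self.scans[child].ms_level} "
                        f"linked under level {level}"
                    )
                stack.append(child)
        if seen != set(self.scans):
            raise ValueError("cycle detected in precursor links (unreachable scans)")
        if self.scans[self.root_id].ms_level != 1:
            raise ValueError("root scan must be MS1")

    @property
    def root_scan(self) -> Scan:
        return self.scans[self.root_id]

    @property
    def root_mz(self) -> Optional[float]:
        """m/z of the selected MS1 precursor.

        Taken from the precursor attribute of the first MS2 child when
        one exists, else the MS1 base peak.
        """
        for sid in self.children[self.root_id]:
            pmz = self.scans[sid].precursor_mz
            if pmz is not None:
                return pmz
        bp = self.root_scan.base_peak
        return bp.mz if bp is not None else None

    def iter_scans(self) -> Iterable[Scan]:
        """Depth-first iteration from the root, children in insertion order."""
        stack = [self.root_id]
        while stack:
            sid = stack.pop()
            yield self.scans[sid]
            stack.extend(reversed(self.children[sid]))

    def parent_of(self, scan_id: str) -> Optional[Scan]:
        pid = self.parent_ids.get(scan_id)
        return self.scans[pid] if pid is not None else None

    def __len__(self) -> int:
        return len(self.scans)


# ---------------------------------------------------------------------------
# mzXML
# ---------------------------------------------------------------------------

def read_mzxml(path: str) -> List[Scan]:
    """Read centroided scans from an mzXML file.

    Decoding of the base64 peak arrays, byte order and precision are
    handled by pyteomics.  ``precursorScanNum`` is kept when present;
    otherwise the precursor scan is left for :func:`link_precursors` to
    infer from acquisition order.
    """
    scans: List[Scan] = []
    with _pyteomics_mzxml.read(path) as reader:
        for entry in reader:
            if "msLevel" not in entry or entry["msLevel"] is None:
                raise ValueError(f"scan {entry.get('num')} lacks msLevel")
            level = int(entry["msLevel"])
            polarity = -1 if str(entry.get("polarity", "+")).strip() == "-" else +1
            if str(entry.get("centroided", "1")) in ("0", "false", "False"):
                log.warning(
                    "scan %s is profile mode; peak picking is out of scope, "
                    "passing peaks through unchanged",
                    entry.get("num"),
                )
            precursor_mz = None
            precursor_scan = None
            if level > 1:
                info = (entry.get("precursorMz") or [{}])[0]
                precursor_mz = float(info.get("precursorMz"))
                if "precursorScanNum" in info:
                    precursor_scan = str(info["precursorScanNum"])
            mzs = entry.get("m/z array")
            intensities = entry.get("intensity array")
            peaks = []
            if mzs is not None and intensities is not None:
                peaks = [
                    Peak(float(mz), float(inten))
                    for mz, inten in zip(mzs, intensities)
                ]
            scans.append(
                Scan(
                    scan_id=str(entry["num"]),
                    ms_level=level,
                    polarity=polarity,
                    precursor_mz=precursor_mz,
                    precursor_scan_id=precursor_scan,
                    peaks=peaks,
                )
            )
    return scans


def _encode_peaks(peaks: Sequence[Peak]) -> str:
    """Base64 of 64-bit network-order m/z,intensity pairs (mzXML spec)."""
    raw = b"".join(struct.pack(">dd", p.mz, p.intensity) for p in peaks)
    return base64.b64encode(raw).decode("ascii")


def write_mzxml(scans: Sequence[Scan], path: str) -> None:
    """Write scans as a minimal, standard-conforming mzXML document.

    Scans are written as a flat sequence under ``msRun`` with
    ``msLevel``, ``polarity`` and (for MS^n) ``precursorMz`` /
    ``precursorScanNum`` attributes — the attributes the linking step
    relies on.  Peak arrays are 64-bit network byte order, uncompressed.
    """
    id_to_num = {scan.scan_id: i + 1 for i, scan in enumerate(scans)}
    lines = [
        '<?xml version="1.0" encoding="ISO-8859-1"?>',
        '<mzXML xmlns="http://sashimi.sourceforge.net/schema_revision/mzXML_3.2">',
        f' <msRun scanCount="{len(scans)}">',
    ]
    for i, scan in enumerate(scans):
        pol = "+" if scan.polarity >= 0 else "-"
        lines.append(
            f'  <scan num="{i + 1}" msLevel="{scan.ms_level}" '
            f'peaksCount="{len(scan.peaks)}" polarity="{pol}" centroided="1">'
        )
        if scan.ms_level > 1:
            attrs = ""
            if scan.precursor_scan_id in id_to_num:
                attrs += f' precursorScanNum="{id_to_num[scan.precursor_scan_id]}"'
            lines.append(
                f"   <precursorMz{attrs} precursorIntensity="
                f'"0">{scan.precursor_mz!r}</precursorMz>'
            )
        payload = _encode_peaks(scan.peaks)
        lines.append(
            '   <peaks precision="64" byteOrder="network" '
            f'contentType="m/z-int" compressionType="none" '
            f'compressedLen="0">{payload}</peaks>'
        )
        lines.append("  </scan>")
    lines.append(" </msRun>")
    lines.append("</mzXML>")
    with open(path, "w", encoding="ascii") as handle:
        handle.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Linking
# ---------------------------------------------------------------------------

def link_precursors(
    scans: Sequence[Scan],
    link_tol_mz: float = 0.5,
    repetition_split: bool = True,
) -> List[SpectrumTree]:
    """Attach each MS^n scan to its parent and split repetitions.

    Each MS^n (n >= 2) scan is attached to the most recent preceding
    scan of level n-1 (within the current repetition) that contains a
    peak within ``link_tol_mz`` of the scan's precursor m/z; an explicit
    ``precursor_scan_id`` wins when it is consistent.  A new MS1 scan
    opens a new repetition when ``repetition_split`` is on.  Orphan
    scans (no candidate parent) are logged and dropped.
    """
    trees: List[SpectrumTree] = []
    current: List[Scan] = []
    parent_ids: Dict[str, Optional[str]] = {}
    dropped = 0

    def flush() -> None:
        nonlocal current, parent_ids
        if current:
            trees.append(SpectrumTree(current, parent_ids, repetition_id=len(trees)))
        current = []
        parent_ids = {}

    def has_matching_peak(parent: Scan, mz: float) -> bool:
        return any(abs(p.mz - mz) <= link_tol_mz for p in parent.peaks)

    kept_ids: set = set()
    for scan in scans:
        if scan.ms_level == 1:
            if repetition_split or not current:
                flush()
            if current:
                log.warning("extra MS1 scan %s ignored within repetition", scan.scan_id)
                dropped += 1
                continue
            current.append(scan)
            parent_ids[scan.scan_id] = None
            kept_ids.add(scan.scan_id)
            continue
        # candidate parents: most recent first
        parent = None
        if (
            scan.precursor_scan_id is not None
            and any(s.scan_id == scan.precursor_scan_id for s in current)
        ):
            candidate = next(
                s for s in current if s.scan_id == scan.precursor_scan_id
            )
            if candidate.ms_level == scan.ms_level - 1 and has_matching_peak(
                candidate, scan.precursor_mz
            ):
                parent = candidate
        if parent is None:
            for candidate in reversed(current):
                if candidate.ms_level != scan.ms_level - 1:
                    continue
                if has_matching_peak(candidate, scan.precursor_mz):
                    parent = candidate
                    break
        if parent is None:
            log.warning(
                "orphan MS%d scan %s (precursor %.4f): no candidate parent",
                scan.ms_level,
                scan.scan_id,
                scan.precursor_mz,
            )
            dropped += 1
            continue
        current.append(scan)
        parent_ids[scan.scan_id] = parent.scan_id
        kept_ids.add(scan.scan_id)
    flush()
    if dropped:
        log.info("link_precursors dropped %d orphan scan(s)", dropped)
    return trees


# ---------------------------------------------------------------------------
# Intensity handling
# ---------------------------------------------------------------------------

def normalize_intensities(scan: Scan) -> Scan:
    """Fill relative intensities as percent of the scan's base peak."""
    if not scan.peaks or all(p.intensity == 0 for p in scan.peaks):
        raise ValueError(f"scan {scan.scan_id!r} has no non-zero peak to normalize")
    top = max(p.intensity for p in scan.peaks)
    peaks = [replace(p, rel_intensity=100.0 * p.intensity / top) for p in scan.peaks]
    return replace(scan, peaks=peaks)


def threshold_filter(
    scan: Scan, min_intensity: float = 4500.0, min_snr: float = 0.0
) -> Scan:
    """Drop peaks below an absolute count or below ``min_snr`` x median.

    A coarse surrogate for upstream peak-picking noise gates; the
    absolute default matches the instrument's precursor-selection
    threshold of 4500 ion counts.
    """
    if not scan.peaks:
        return scan
    intensities = sorted(p.intensity for p in scan.peaks)
    mid = len(intensities) // 2
    if len(intensities) % 2:
        median = intensities[mid]
    else:
        median = 0.5 * (intensities[mid - 1] + intensities[mid])
    floor = max(min_intensity, min_snr * median)
    peaks = [p for p in scan.peaks if p.intensity >= floor]
    return replace(scan, peaks=peaks)


def composite_spectrum(tree: SpectrumTree, bin_tol_mz: float = 0.01) -> List[Peak]:
    """Merge all scans of a spectrum tree into one composite spectrum.

    All peaks are pooled, sorted by m/z and greedily coalesced: a peak
    joins the current bin while it lies within ``bin_tol_mz`` of the
    bin's running intensity-weighted mean m/z.  Output is renormalized
    to base peak = 100 and is invariant to scan order.
    """
    pool = sorted(
        (p for scan in tree.iter_scans() for p in scan.peaks), key=lambda p: p.mz
    )
    if not pool:
        return []
    bins: List[Tuple[float, float]] = []  # (weighted mean mz, summed intensity)
    for peak in pool:
        if bins and abs(peak.mz - bins[-1][0]) <= bin_tol_mz:
            mz0, inten0 = bins[-1]
            total = inten0 + peak.intensity
            if total > 0:
                mz = (mz0 * inten0 + peak.mz * peak.intensity) / total
            else:
                mz = 0.5 * (mz0 + peak.mz)
            bins[-1] = (mz, total)
        else:
            bins.append((peak.mz, peak.intensity))
    top = max(i for _, i in bins)
    if top <= 0:
        raise ValueError("composite spectrum has no non-zero intensity")
    return [
        Peak(mz, inten, rel_intensity=100.0 * inten / top) for mz, inten in bins
    ]


# ---------------------------------------------------------------------------
# Internal peak-tree JSON
# ---------------------------------------------------------------------------
# Schema (documented in docs/formats.md):
# {"run": {"polarity": "+"|"-",
#          "trees": [{"repetition": int,
#                     "scans": [{"id": str, "level": int,
#                                "precursor_mz": float|null,
#                                "precursor_id": str|null,
#                                "peaks": [[mz, intensity], ...]}, ...]},
#                    ...]}}

def write_peaktree_json(trees: Sequence[SpectrumTree], path: str) -> None:
    polarity = "+"
    for tree in trees:
        polarity = "+" if tree.root_scan.polarity >= 0 else "-"
        break
    doc = {
        "run": {
            "polarity": polarity,
            "trees": [
                {
                    "repetition": tree.repetition_id,
                    "scans": [
                        {
                            "id": scan.scan_id,
                            "level": scan.ms_level,
                            "precursor_mz": scan.precursor_mz,
                            "precursor_id": tree.parent_ids.get(scan.scan_id),
                            "peaks": [[p.mz, p.intensity] for p in scan.peaks],
                        }
                        for scan in tree.iter_scans()
                    ],
                }
                for tree in trees
            ],
        }
    }
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(doc, handle, indent=1, sort_keys=True)
        handle.write("\n")


def _require(cond: bool, where: str, message: str) -> None:
    if not cond:
        raise ValueError(f"peak-tree JSON error at {where}: {message}")


def read_peaktree_json(path: str) -> List[SpectrumTree]:
    """Read the internal JSON format back into validated spectrum trees."""
    with open(path, "r", encoding="utf-8") as handle:
        doc = json.load(handle)
    _require(isinstance(doc, dict) and "run" in doc, "$", "missing 'run' object")
    run = doc["run"]
    _require(isinstance(run, dict), "$.run", "must be an object")
    polarity = +1 if run.get("polarity", "+") == "+" else -1
    raw_trees = run.get("trees")
    _require(isinstance(raw_trees, list), "$.run.trees", "must be a list")
    trees: List[SpectrumTree] = []
    for t_idx, raw in enumerate(raw_trees):
        where = f"$.run.trees[{t_idx}]"
        _require(isinstance(raw, dict), where, "must be an object")
        raw_scans = raw.get("scans")
        _require(isinstance(raw_scans, list) and raw_scans, where, "needs scans")
        scans = []
        parent_ids: Dict[str, Optional[str]] = {}
        for s_idx, rs in enumerate(raw_scans):
            swhere = f"{where}.scans[{s_idx}]"
            _require(isinstance(rs, dict), swhere, "must be an object")
            for key in ("id", "level", "peaks"):
                _require(key in rs, swhere, f"missing {key!r}")
            peaks = []
            for p_idx, pair in enumerate(rs["peaks"]):
                _require(
                    isinstance(pair, list) and len(pair) == 2,
                    f"{swhere}.peaks[{p_idx}]",
                    "must be [mz, intensity]",
                )
                peaks.append(Peak(float(pair[0]), float(pair[1])))
            scan = Scan(
                scan_id=str(rs["id"]),
                ms_level=int(rs["level"]),
                polarity=polarity,
                precursor_mz=rs.get("precursor_mz"),
                precursor_scan_id=rs.get("precursor_id"),
                peaks=peaks,
            )
            scans.append(scan)
            parent_ids[scan.scan_id] = (
                str(rs["precursor_id"]) if rs.get("precursor_id") is not None else None
            )
        try:
            trees.append(
                SpectrumTree(
                    scans, parent_ids, repetition_id=int(raw.get("repetition", t_idx))
                )
            )
        except ValueError as exc:
            raise ValueError(f"peak-tree JSON error at {where}: {exc}") from exc
    return trees
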