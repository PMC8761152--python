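"""Topology annotations and experimental hydrophobic-thickness records.

Consensus topology predictors (CCTOP and the Human Transmembrane Proteome
database built on it) describe a protein as a string of per-residue labels:
``I`` (inside loop), ``M`` (membrane-spanning segment), ``O`` (outside
loop), plus non-spanning membrane-associated labels such as re-entrant
loops.  This module parses a compact XML dialect carrying those labels and
a prediction-reliability score, collapses label runs into TM segments with
membrane-side assignments, and reads membrane half-thickness values from a
PDBTM-style XML.

XML dialects (documented in ``docs/formats.md``, examples in ``examples/``):

Topology::

    <topologies>
      <protein id="P1" length="40" reliability="95.3">
        <region start="1" end="10" label="I"/>
        <region start="11" end="30" label="M"/>
        <region start="31" end="40" label="O"/>
      </protein>
    </topologies>

Thickness (the membrane element stores the half-thickness along the
membrane normal, as PDBTM does)::

    <pdbtm_entries>
      <entry id="1abc"><membrane half_thickness="15.2"/></entry>
    </pdbtm_entries>
"""

from __future__ import annotations

import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

from .errors import TopologyError

__all__ = [
    "SIDE1",
    "SIDE2",
    "TMSegment",
    "TopologyAnnotation",
    "ExperimentalThickness",
    "SideAssignment",
    "parse_topology_xml",
    "write_topology_xml",
    "parse_pdbtm_thickness",
    "assign_membrane_sides",
    "labels_to_annotation",
    "annotation_to_labels",
]

SIDE1 = "side1"  # topology label "inside" (I)
SIDE2 = "side2"  # topology label "outside" (O)

_SIDE_OF_LABEL = {"I": SIDE1, "O": SIDE2}
_LABEL_OF_SIDE = {SIDE1: "I", SIDE2: "O"}
# Non-spanning membrane-associated labels: excluded from side assignment.
_NON_SPANNING = {"L"}
_KNOWN_LABELS = {"I", "O", "M", "L", "U"}


@dataclass(frozen=True)
class TMSegment:
    """A membrane-spanning segment with 1-based inclusive bounds."""

    start: int
    end: int
    start_side: str
    end_side: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment start {self.start} > end {self.end}")
        for side in (self.start_side, self.end_side):
            if side not in (SIDE1, SIDE2):
                raise ValueError(f"unknown side {side!r}")

    @property
    def spans_membrane(self) -> bool:
        return self.start_side != self.end_side


@dataclass
class TopologyAnnotation:
    """TM segments plus the predictor's reliability score for one protein."""

    protein_id: str
    sequence_length: int
    segments: list[TMSegment] = field(default_factory=list)
    reliability: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.reliability <= 100.0):
            raise ValueError(f"reliability must be in [0, 100], got {self.reliability}")
        prev_end = 0
        for seg in self.segments:
            if seg.start <= prev_end:
                raise ValueError(
                    f"{self.protein_id}: segments must be sorted and non-overlapping"
                )
            if seg.end > self.sequence_length:
                raise ValueError(
                    f"{self.protein_id}: segment {seg.start}-{seg.end} exceeds "
                    f"sequence length {self.sequence_length}"
                )
            prev_end = seg.end

    @property
    def tm_positions(self) -> set[int]:
        out: set[int] = set()
        for seg in self.segments:
            out.update(range(seg.start, seg.end + 1))
        return out


@dataclass(frozen=True)
class ExperimentalThickness:
    """Full hydrophobic thickness of one membrane-embedded PDB entry, in A."""

    pdb_id: str
    thickness: float
    source: str = "pdbtm"

    def __post_init__(self) -> None:
        import math

        if not (math.isfinite(self.thickness) and self.thickness > 0):
            raise ValueError(f"thickness must be positive and finite: {self.thickness}")


@dataclass
class SideAssignment:
    """Helix-endpoint positions split by membrane side.

    Iterating yields ``(side1_positions, side2_positions)`` so callers can
    unpack the pair directly; ``diagnostics`` lists human-readable notes on
    segments whose two endpoints resolved to the same side.
    """

    side1_positions: list[int]
    side2_positions: list[int]
    diagnostics: list[str] = field(default_factory=list)

    def __iter__(self):
        return iter((self.side1_positions, self.side2_positions))


def labels_to_annotation(
    protein_id: str,
    labels: str,
    reliability: float = 0.0,
) -> TopologyAnnotation:
    """Collapse a per-residue label string into a :class:`TopologyAnnotation`.

    Membrane-side of each TM-segment endpoint comes from the nearest
    flanking loop label (``I`` -> side1, ``O`` -> side2); when a flank is
    missing, the opposite side of the other endpoint is assumed.
    Non-spanning membrane labels (``L``) are not turned into segments.
    """
    unknown = set(labels) - _KNOWN_LABELS
    if unknown:
        raise TopologyError(f"{protein_id}: unknown topology labels {sorted(unknown)}")
    runs: list[tuple[str, int, int]] = []  # (label, start, end) 1-based
    for i, lab in enumerate(labels, start=1):
        if runs and runs[-1][0] == lab:
            runs[-1] = (lab, runs[-1][1], i)
        else:
            runs.append((lab, i, i))

    segments: list[TMSegment] = []
    n_non_spanning = 0
    for idx, (lab, start, end) in enumerate(runs):
        if lab in _NON_SPANNING:
            n_non_spanning += 1
            continue
        if lab != "M":
            continue
        prev_side = next_side = None
        for j in range(idx - 1, -1, -1):
            if runs[j][0] in _SIDE_OF_LABEL:
                prev_side = _SIDE_OF_LABEL[runs[j][0]]
                break
        for j in range(idx + 1, len(runs)):
            if runs[j][0] in _SIDE_OF_LABEL:
                next_side = _SIDE_OF_LABEL[runs[j][0]]
                break
        if prev_side is None and next_side is None:
            prev_side, next_side = SIDE1, SIDE2
        elif prev_side is None:
            prev_side = SIDE1 if next_side == SIDE2 else SIDE2
        elif next_side is None:
            next_side = SIDE1 if prev_side == SIDE2 else SIDE2
        segments.append(
            TMSegment(start=start, end=end, start_side=prev_side, end_side=next_side)
        )
    if n_non_spanning:
        warnings.warn(
            f"{protein_id}: {n_non_spanning} non-spanning membrane segment(s) "
            "excluded from side assignment",
            stacklevel=2,
        )
    return TopologyAnnotation(
        protein_id=protein_id,
        sequence_length=len(labels),
        segments=segments,
        reliability=reliability,
    )


def annotation_to_labels(annotation: TopologyAnnotation) -> str:
    """Expand an annotation back into a per-residue label string."""
    labels = ["?"] * annotation.sequence_length
    pos = 1
    for seg in annotation.segments:
        loop_label = _LABEL_OF_SIDE[seg.start_side]
        for i in range(pos, seg.start):
            labels[i - 1] = loop_label
        for i in range(seg.start, seg.end + 1):
            labels[i - 1] = "M"
        pos = seg.end + 1
    tail_label = (
        _LABEL_OF_SIDE[annotation.segments[-1].end_side] if annotation.segments else "I"
    )
    for i in range(pos, annotation.sequence_length + 1):
        labels[i - 1] = tail_label
    return "".join(labels)


def parse_topology_xml(path: str | Path) -> list[TopologyAnnotation]:
    """Parse the documented topology XML into annotations, one per protein.

    Proteins without any ``M`` region come back with empty ``segments``
    (soluble), they are not dropped.
    """
    path = Path(path)
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise TopologyError(f"malformed topology XML {path}: {exc}") from exc
    root = tree.getroot()
    annotations: list[TopologyAnnotation] = []
    for prot in root.iter("protein"):
        pid = prot.get("id")
        if pid is None:
            raise TopologyError(f"{path}: <protein> element without id attribute")
        try:
            length = int(prot.get("length", "0"))
            reliability = float(prot.get("reliability", "0"))
        except ValueError as exc:
            raise TopologyError(f"{path}: bad numeric attribute on {pid}") from exc
        labels = ["U"] * length
        for region in prot.iter("region"):
            try:
                start = int(region.get("start"))
                end = int(region.get("end"))
            except (TypeError, ValueError) as exc:
                raise TopologyError(f"{path}: bad region bounds in {pid}") from exc
            label = region.get("label", "U")
            if not (1 <= start <= end <= length):
                raise TopologyError(
                    f"{path}: region {start}-{end} outside [1, {length}] in {pid}"
                )
            for i in range(start, end + 1):
                labels[i - 1] = label
        annotations.append(labels_to_annotation(pid, "".join(labels), reliability))
    return annotations


def write_topology_xml(
    annotations: list[TopologyAnnotation], path: str | Path
) -> None:
    """Emit annotations in the documented topology XML dialect."""
    root = ET.Element("topologies")
    for ann in annotations:
        prot = ET.SubElement(
            root,
            "protein",
            id=ann.protein_id,
            length=str(ann.sequence_length),
            reliability=f"{ann.reliability:.2f}",
        )
        labels = annotation_to_labels(ann)
        start = 1
        for i in range(2, len(labels) + 2):
            if i > len(labels) or labels[i - 1] != labels[start - 1]:
                ET.SubElement(
                    prot,
                    "region",
                    start=str(start),
                    end=str(i - 1),
                    label=labels[start - 1],
                )
                start = i
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(str(path), encoding="unicode", xml_declaration=True)


def parse_pdbtm_thickness(path: str | Path) -> list[ExperimentalThickness]:
    """Read experimental hydrophobic thicknesses from PDBTM-style XML.

    The file stores a half-thickness (distance from the membrane midplane
    to the hydrophobic boundary along the normal); the returned records
    carry the full hydrophobic thickness, i.e. twice that value, so they
    are directly comparable with the predicted-structure statistic.
    Entries lacking a thickness element are skipped with a warning.
    """
    path = Path(path)
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise TopologyError(f"malformed PDBTM XML {path}: {exc}") from exc
    records: list[ExperimentalThickness] = []
    n_skipped = 0
    for entry in tree.getroot().iter("entry"):
        pdb_id = entry.get("id", "?")
        membrane = entry.find("membrane")
        half = membrane.get("half_thickness") if membrane is not None else None
        if half is None:
            n_skipped += 1
            continue
        records.append(
            ExperimentalThickness(pdb_id=pdb_id, thickness=2.0 * float(half))
        )
    if n_skipped:
        warnings.warn(
            f"{path}: {n_skipped} entr(ies) lacking a thickness element skipped",
            stacklevel=2,
        )
    return records


def assign_membrane_sides(annotation: TopologyAnnotation) -> SideAssignment:
    """Split TM-helix endpoint positions into the two membrane-side sets.

    Each segment contributes its start position to the side of the
    preceding loop and its end position to the side of the following loop.
    A segment whose endpoints resolve to the same side (inconsistent
    topology, e.g. a mis-predicted half-helix) is still assigned by that
    rule but a diagnostic is recorded.
    """
    if not annotation.segments:
        raise TopologyError(
            f"{annotation.protein_id}: no TM segments; not a TM protein"
        )
    side1: list[int] = []
    side2: list[int] = []
    diagnostics: list[str] = []
    for seg in annotation.segments:
        (side1 if seg.start_side == SIDE1 else side2).append(seg.start)
        (side1 if seg.end_side == SIDE1 else side2).append(seg.end)
        if not seg.spans_membrane:
            diagnostics.append(
                f"segment {seg.start}-{seg.end}: both endpoints on {seg.start_side}"
            )
    return SideAssignment(side1, side2, diagnostics)
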