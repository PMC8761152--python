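"""Per-protein confidence statistics and the hydrophobic-thickness screen.

Two complementary quality signals for a predicted membrane-protein
structure are computed here:

* **pLDDT bookkeeping** — the arithmetic mean of the per-residue
  confidence over the whole chain, over the TM region, and over the
  non-TM region, plus the fraction of residues falling into the
  conventional confidence bins (<50, 50-70, 70-90, >90).

* **Hydrophobic thickness** — TM helices cross the membrane, so their
  end-point C-alpha atoms cluster on the two membrane surfaces.  The
  distance between the centroids of the two end-point sets estimates the
  hydrophobic thickness of the modelled bilayer span.  A physiological
  span lies in the 15-35 A band; values outside it flag a structure whose
  helices cannot all be membrane-spanning as annotated — either the model
  or the topology prediction is wrong.  Cross-classifying the flag with
  the topology predictor's reliability separates the two cases: an
  out-of-band thickness with high topology reliability points at a model
  error, with low reliability the call is in a twilight zone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientEndpointsError, RegionError
from .structure_io import Structure
from .topology_io import TopologyAnnotation, assign_membrane_sides

__all__ = [
    "DEFAULT_THICKNESS_BAND",
    "DEFAULT_RELIABILITY_THRESHOLD",
    "DEFAULT_BIN_EDGES",
    "PlddtSummary",
    "ThicknessResult",
    "mean_plddt",
    "plddt_bins",
    "summarize_plddt",
    "hydrophobic_thickness",
    "classify_confidence",
]

#: Physiological hydrophobic-thickness band in Angstrom (inclusive).
DEFAULT_THICKNESS_BAND: tuple[float, float] = (15.0, 35.0)
#: Topology reliability at or above which a prediction counts as "high".
DEFAULT_RELIABILITY_THRESHOLD: float = 90.0
#: Confidence bin edges used for whole-proteome summaries.
DEFAULT_BIN_EDGES: tuple[float, ...] = (0.0, 50.0, 70.0, 90.0, 100.0)
_DEFAULT_BIN_LABELS = ("very_low", "low", "confident", "very_high")


@dataclass
class PlddtSummary:
    """Mean confidences and bin fractions for one protein."""

    protein_id: str
    mean_all: float
    mean_tm: float | None = None
    mean_non_tm: float | None = None
    bin_fractions: dict[str, float] = field(default_factory=dict)


@dataclass
class ThicknessResult:
    """The thickness statistic plus its flag and confidence class."""

    protein_id: str
    thickness: float
    n_side1: int
    n_side2: int
    flag: str  # "ok" | "suspect"
    confidence_class: str  # "likely_af2_error" | "twilight" | "consistent"
    cctop_reliability: float


def mean_plddt(s: Structure, region: set[int] | None = None) -> float:
    """Arithmetic mean confidence, optionally over a set of author positions.

    Residues without a confidence value are excluded (and counted via a
    warning if a region was requested but partially lacks scores).
    """
    if region is not None:
        values = [
            r.confidence
            for r in s.residues
            if r.seq_number in region and r.confidence is not None
        ]
        if not values:
            raise RegionError(
                f"{s.id}: requested region has no residues with confidence"
            )
    else:
        values = s.confidences()
        if not values:
            raise RegionError(f"{s.id}: structure has no confidence values")
    return float(np.mean(values))


def plddt_bins(
    values,
    edges: tuple[float, ...] = DEFAULT_BIN_EDGES,
) -> dict[str, float]:
    """Fraction of confidence values per bin.

    Bins are half-open ``[lo, hi)`` with the last bin closed, following the
    whole-proteome confidence-range convention (edges 50/70/90).  With the
    default edges the labels are ``very_low``, ``low``, ``confident`` and
    ``very_high``; custom edges get interval labels.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("plddt_bins requires at least one value")
    if np.any(arr < 0) or np.any(arr > 100):
        bad = arr[(arr < 0) | (arr > 100)]
        raise ValueError(f"confidence values outside [0, 100]: {bad[:5]}")
    edges_arr = np.asarray(edges, dtype=float)
    counts, _ = np.histogram(arr, bins=edges_arr)
    fractions = counts / arr.size
    if tuple(edges) == DEFAULT_BIN_EDGES:
        labels = _DEFAULT_BIN_LABELS
    else:
        labels = tuple(
            f"[{edges_arr[i]:g},{edges_arr[i + 1]:g})" for i in range(len(edges_arr) - 1)
        )
    return dict(zip(labels, fractions.tolist()))


def summarize_plddt(
    s: Structure,
    annotation: TopologyAnnotation | None = None,
    edges: tuple[float, ...] = DEFAULT_BIN_EDGES,
) -> PlddtSummary:
    """Whole-chain, TM-region, and loop-region mean confidence for one protein.

    Means are residue-weighted.  ``mean_tm`` is defined only when the
    annotation places at least one confidence-bearing residue in a TM
    segment.
    """
    mean_all = mean_plddt(s)
    mean_tm = mean_non_tm = None
    if annotation is not None and annotation.segments:
        tm_pos = annotation.tm_positions
        tm_vals = [
            r.confidence
            for r in s.residues
            if r.confidence is not None and r.seq_number in tm_pos
        ]
        non_tm_vals = [
            r.confidence
            for r in s.residues
            if r.confidence is not None and r.seq_number not in tm_pos
        ]
        if tm_vals:
            mean_tm = float(np.mean(tm_vals))
        if non_tm_vals:
            mean_non_tm = float(np.mean(non_tm_vals))
    return PlddtSummary(
        protein_id=s.id,
        mean_all=mean_all,
        mean_tm=mean_tm,
        mean_non_tm=mean_non_tm,
        bin_fractions=plddt_bins(s.confidences(), edges=edges),
    )


def classify_confidence(
    thickness: float,
    reliability: float,
    reliability_threshold: float = DEFAULT_RELIABILITY_THRESHOLD,
    band: tuple[float, float] = DEFAULT_THICKNESS_BAND,
) -> str:
    """Cross-classify a thickness value with the topology reliability.

    In-band thickness -> ``consistent``.  Out-of-band with reliable
    topology -> ``likely_af2_error`` (the model contradicts a trustworthy
    annotation).  Out-of-band with unreliable topology -> ``twilight``
    (either could be wrong).
    """
    if not (np.isfinite(thickness) and np.isfinite(reliability)):
        raise ValueError("thickness and reliability must be finite")
    lo, hi = band
    if lo <= thickness <= hi:
        return "consistent"
    return "likely_af2_error" if reliability >= reliability_threshold else "twilight"


def hydrophobic_thickness(
    s: Structure,
    annotation: TopologyAnnotation,
    reliability_threshold: float = DEFAULT_RELIABILITY_THRESHOLD,
    band: tuple[float, float] = DEFAULT_THICKNESS_BAND,
) -> ThicknessResult:
    """Distance between the two membrane-side endpoint centroids.

    TM-segment start/end positions are split by membrane side, their
    C-alpha coordinates averaged per side (unweighted), and the Euclidean
    distance between the two centroids reported.  Endpoint positions with
    no resolvable C-alpha are skipped with a warning; a side emptied by
    skipping is an error.  The ``suspect`` flag marks thickness outside
    the closed ``band``.
    """
    sides = assign_membrane_sides(annotation)
    coords: list[np.ndarray] = []
    counts: list[int] = []
    for positions in (sides.side1_positions, sides.side2_positions):
        found: list[np.ndarray] = []
        missing: list[int] = []
        for pos in positions:
            res = s.find(pos)
            if res is None or res.ca_coord is None:
                missing.append(pos)
            else:
                found.append(res.ca_coord)
        if missing:
            warnings.warn(
                f"{s.id}: {len(missing)} endpoint position(s) without C-alpha "
                f"skipped: {missing}",
                stacklevel=2,
            )
        if not found:
            raise InsufficientEndpointsError(
                f"{s.id}: a membrane side has no usable endpoint C-alpha atoms"
            )
        coords.append(np.mean(np.vstack(found), axis=0))
        counts.append(len(found))
    thickness = float(np.linalg.norm(coords[0] - coords[1]))
    lo, hi = band
    flag = "ok" if lo <= thickness <= hi else "suspect"
    return ThicknessResult(
        protein_id=s.id,
        thickness=thickness,
        n_side1=counts[0],
        n_side2=counts[1],
        flag=flag,
        confidence_class=classify_confidence(
            thickness, annotation.reliability, reliability_threshold, band
        ),
        cctop_reliability=annotation.reliability,
    )
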