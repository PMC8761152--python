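"""Batch orchestration: proteome QC, fold survey, and pairwise reports.

Each run joins a directory of structure files with its annotations by
file stem, applies the per-protein statistics, and renders a
deterministic tab-separated report whose ``#``-prefixed header echoes
every threshold used (audit trail).  Repeated runs on the same inputs
are byte-identical: nothing time- or locale-dependent enters the output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from . import __version__
from .errors import ConfigError, MemqaError
from .fold_classify import (
    SAME_FOLD_THRESHOLD,
    UNRELATED_THRESHOLD,
    ReferenceFold,
    classify_fold,
    parse_domtbl,
    pfam_filter,
)
from .membrane_metrics import (
    DEFAULT_RELIABILITY_THRESHOLD,
    DEFAULT_THICKNESS_BAND,
    hydrophobic_thickness,
    summarize_plddt,
)
from .structure_io import load_structure, select_residues, write_structure
from .superposition import structural_align, tm_score
from .topology_io import parse_topology_xml

logger = logging.getLogger("memqa")

__all__ = ["RunConfig", "run_proteome_qc", "run_fold_survey", "run_pairwise"]


@dataclass
class RunConfig:
    """Thresholds and choices shared by the batch commands."""

    thickness_band: tuple[float, float] = DEFAULT_THICKNESS_BAND
    reliability_threshold: float = DEFAULT_RELIABILITY_THRESHOLD
    tm_same_fold: float = SAME_FOLD_THRESHOLD
    tm_unrelated: float = UNRELATED_THRESHOLD
    pfam_max_e: float = 1e-3
    pfam_min_cov: float = 0.9
    normalization: str = "reference"

    def __post_init__(self) -> None:
        lo, hi = self.thickness_band
        if not (0 < lo < hi):
            raise ConfigError(f"bad thickness band {self.thickness_band}")
        if not (0 <= self.reliability_threshold <= 100):
            raise ConfigError("reliability_threshold must be in [0, 100]")
        if not (0 < self.tm_unrelated < self.tm_same_fold <= 1):
            raise ConfigError("need 0 < tm_unrelated < tm_same_fold <= 1")
        if self.normalization not in ("reference", "query"):
            raise ConfigError("normalization must be 'reference' or 'query'")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "thickness_band" in d:
            d["thickness_band"] = tuple(d["thickness_band"])
        return cls(**d)

    def header_lines(self, tool: str) -> list[str]:
        lines = [f"# memqa {tool} v{__version__}"]
        for key, value in sorted(self.to_dict().items()):
            lines.append(f"# {key}={value}")
        return lines


def _fmt(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, float):
        return f"{value:.4f}"
    return str(value)


def _structure_files(directory: str | Path) -> list[Path]:
    directory = Path(directory)
    files = sorted(
        p for p in directory.iterdir() if p.suffix.lower() in (".pdb", ".cif", ".ent")
    )
    return files


def run_proteome_qc(
    structure_dir: str | Path,
    topology_xml: str | Path,
    config: RunConfig | None = None,
) -> str:
    """Per-protein confidence and thickness QC over a structure directory.

    Structures join their topology annotation by file stem == protein id;
    a structure without topology gets a ``no_topology`` row rather than
    being dropped.  Returns the rendered TSV report (rows sorted by
    protein id, aggregate block at the end).
    """
    config = config or RunConfig()
    files = _structure_files(structure_dir)
    if not files:
        raise MemqaError(f"no structure files found in {structure_dir}")
    annotations = {a.protein_id: a for a in parse_topology_xml(topology_xml)}

    columns = [
        "protein_id", "status", "mean_plddt", "mean_plddt_tm", "mean_plddt_non_tm",
        "frac_very_low", "frac_low", "frac_confident", "frac_very_high",
        "thickness", "n_side1", "n_side2", "flag", "confidence_class", "reliability",
    ]
    rows: list[dict] = []
    for path in files:
        structure = load_structure(path)
        ann = annotations.get(path.stem)
        row: dict = {c: None for c in columns}
        row["protein_id"] = path.stem
        summary = summarize_plddt(structure, ann)
        row["mean_plddt"] = summary.mean_all
        row["mean_plddt_tm"] = summary.mean_tm
        row["mean_plddt_non_tm"] = summary.mean_non_tm
        for label in ("very_low", "low", "confident", "very_high"):
            row[f"frac_{label}"] = summary.bin_fractions.get(label)
        if ann is None:
            row["status"] = "no_topology"
            logger.warning("no topology annotation for %s", path.stem)
        elif not ann.segments:
            row["status"] = "soluble"
        else:
            row["status"] = "ok"
            result = hydrophobic_thickness(
                structure,
                ann,
                reliability_threshold=config.reliability_threshold,
                band=config.thickness_band,
            )
            row.update(
                thickness=result.thickness,
                n_side1=result.n_side1,
                n_side2=result.n_side2,
                flag=result.flag,
                confidence_class=result.confidence_class,
                reliability=result.cctop_reliability,
            )
        rows.append(row)
    rows.sort(key=lambda r: r["protein_id"])

    lines = config.header_lines("qc")
    lines.append("\t".join(columns))
    for row in rows:
        lines.append("\t".join(_fmt(row[c]) for c in columns))
    scored = [r for r in rows if r["flag"] is not None]
    flagged = [r for r in scored if r["flag"] == "suspect"]
    lines.append(f"#= n_structures {len(rows)}")
    lines.append(f"#= n_with_thickness {len(scored)}")
    lines.append(f"#= n_flagged {len(flagged)}")
    if scored:
        lines.append(f"#= fraction_flagged {_fmt(len(flagged) / len(scored))}")
    lines.append(f"#= n_no_topology {sum(1 for r in rows if r['status'] == 'no_topology')}")
    for label in ("very_low", "low", "confident", "very_high"):
        vals = [r[f"frac_{label}"] for r in rows if r[f"frac_{label}"] is not None]
        if vals:
            lines.append(f"#= mean_frac_{label} {_fmt(float(np.mean(vals)))}")
    return "\n".join(lines) + "\n"


def run_fold_survey(
    query_dir: str | Path,
    library: list[ReferenceFold],
    config: RunConfig | None = None,
    domtbl: str | Path | None = None,
) -> str:
    """Classify every query structure against the fold library.

    With a per-domain table given, queries whose stem does not survive the
    PFAM filter are excluded (and logged).  Per-fold counts include only
    ``same_fold`` assignments; the aggregate block adds the five-number
    summary of best scores per fold.
    """
    config = config or RunConfig()
    files = _structure_files(query_dir)
    if not files:
        raise MemqaError(f"no structure files found in {query_dir}")
    if domtbl is not None:
        kept = {
            h.target_id
            for h in pfam_filter(
                parse_domtbl(domtbl), max_e=config.pfam_max_e, min_cov=config.pfam_min_cov
            )
        }
        dropped = [p.stem for p in files if p.stem not in kept]
        for stem in dropped:
            logger.info("query %s removed by PFAM filter", stem)
        files = [p for p in files if p.stem in kept]
        if not files:
            raise MemqaError("PFAM filter removed every query")

    fold_names = [ref.fold_name for ref in library]
    columns = ["query_id", "best_fold", "best_score", "verdict"] + [
        f"tm_{name}" for name in fold_names
    ]
    rows = []
    for path in files:
        query = load_structure(path)
        assignment = classify_fold(query, library, normalization=config.normalization)
        row = {
            "query_id": path.stem,
            "best_fold": assignment.best_fold,
            "best_score": assignment.best_score,
            "verdict": assignment.verdict,
        }
        for name in fold_names:
            row[f"tm_{name}"] = assignment.scores[name]
        rows.append(row)
    rows.sort(key=lambda r: r["query_id"])

    lines = config.header_lines("survey")
    lines.append("\t".join(columns))
    for row in rows:
        lines.append("\t".join(_fmt(row[c]) for c in columns))
    for name in fold_names:
        members = [r["best_score"] for r in rows if r["best_fold"] == name and r["verdict"] == "same_fold"]
        lines.append(f"#= fold {name} count {len(members)}")
        if members:
            qs = np.percentile(members, [0, 25, 50, 75, 100])
            lines.append(
                f"#= fold {name} best_score_summary "
                + " ".join(_fmt(float(v)) for v in qs)
            )
    n_unrelated = sum(1 for r in rows if r["verdict"] == "unrelated")
    lines.append(f"#= n_queries {len(rows)}")
    lines.append(f"#= n_unrelated {n_unrelated}")
    return "\n".join(lines) + "\n"


def run_pairwise(
    query_path: str | Path,
    reference_path: str | Path,
    config: RunConfig | None = None,
    query_ranges: list[tuple[str, int, int]] | None = None,
    reference_ranges: list[tuple[str, int, int]] | None = None,
    out_pdb: str | Path | None = None,
) -> dict:
    """Align two structures and report RMSD, TM-score (both norms), GDT_TS.

    Optional residue ranges carve TM domains before alignment; with
    ``out_pdb`` the superposed query C-alpha trace is written.
    """
    config = config or RunConfig()
    query = load_structure(query_path)
    reference = load_structure(reference_path)
    if query_ranges:
        query = select_residues(query, query_ranges)
    if reference_ranges:
        reference = select_residues(reference, reference_ranges)
    corr = structural_align(query, reference)
    result = tm_score(query, reference, corr, normalization=config.normalization)
    if out_pdb is not None:
        coords = query.ca_array() @ result.rotation.T + result.translation
        write_structure(query.with_coords(coords), out_pdb)
    return {
        "query_id": query.id,
        "reference_id": reference.id,
        "n_aligned": result.n_aligned,
        "rmsd": result.rmsd,
        "tm_score": result.tm_score,
        "tm_score_query_norm": result.tm_score_query_norm,
        "gdt_ts": result.gdt_ts,
        "normalization_length": result.normalization_length,
    }
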