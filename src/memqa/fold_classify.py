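"""Fold classification against a reference library and PFAM target filtering.

A query TM domain is aligned (sequence-independently) against every
reference fold and scored by TM-score; the best score decides the call:
above 0.5 the two share a fold, below 0.3 they are structurally
unrelated, in between lies the twilight zone.

Target selection from hmmsearch output follows the stringent
profile-match rule: domain E-value at most 0.001 and a match covering at
least 90% of the HMM profile length, one (best) hit per target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import yaml
from Bio import SearchIO

from .errors import ConfigError, DomtblParseError, SequenceError
from .structure_io import Structure, load_structure, select_residues
from .superposition import structural_align, tm_score

__all__ = [
    "SAME_FOLD_THRESHOLD",
    "UNRELATED_THRESHOLD",
    "ReferenceFold",
    "FoldAssignment",
    "PfamHit",
    "DimerConstruct",
    "classify_fold",
    "verdict_from_score",
    "pfam_filter",
    "parse_domtbl",
    "prepare_dimer_sequence",
    "load_reference_library",
]

SAME_FOLD_THRESHOLD = 0.5
UNRELATED_THRESHOLD = 0.3

_AA_LETTERS = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass
class ReferenceFold:
    """One reference TM-domain structure of the fold library."""

    fold_name: str
    structure: Structure
    source_id: str = ""
    tm_ranges: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.structure) == 0:
            raise ConfigError(f"reference fold {self.fold_name!r} has an empty structure")


@dataclass
class FoldAssignment:
    """All per-reference TM-scores plus the best-match verdict."""

    query_id: str
    scores: dict[str, float]
    best_fold: str
    best_score: float
    verdict: str  # "same_fold" | "twilight" | "unrelated"


@dataclass(frozen=True)
class PfamHit:
    """One domain line of an hmmsearch per-domain table."""

    target_id: str
    hmm_name: str
    hmm_length: int
    e_value: float
    hmm_from: int
    hmm_to: int

    def __post_init__(self) -> None:
        if not (1 <= self.hmm_from <= self.hmm_to <= self.hmm_length):
            raise ValueError(
                f"bad hmm coordinates {self.hmm_from}-{self.hmm_to} "
                f"for profile length {self.hmm_length}"
            )
        if self.e_value <= 0:
            raise ValueError(f"e_value must be positive, got {self.e_value}")

    @property
    def profile_coverage(self) -> float:
        return (self.hmm_to - self.hmm_from + 1) / self.hmm_length


@dataclass(frozen=True)
class DimerConstruct:
    """A concatenated dimer sequence with 1-based segment coordinates."""

    sequence: str
    range_a: tuple[int, int]
    range_linker: tuple[int, int] | None
    range_b: tuple[int, int]


def verdict_from_score(score: float) -> str:
    """Fold verdict from the best TM-score (>=0.5 same, <=0.3 unrelated)."""
    if score >= SAME_FOLD_THRESHOLD:
        return "same_fold"
    if score <= UNRELATED_THRESHOLD:
        return "unrelated"
    return "twilight"


def classify_fold(
    query: Structure,
    library: list[ReferenceFold],
    normalization: str = "reference",
) -> FoldAssignment:
    """Score a query TM domain against every reference fold.

    Each reference is aligned with :func:`structural_align` and scored
    with :func:`tm_score`; all scores are recorded and the argmax (ties
    broken by fold-name order) yields the verdict.
    """
    if not library:
        raise ConfigError("reference library is empty")
    names = [ref.fold_name for ref in library]
    if len(set(names)) != len(names):
        raise ConfigError("fold names must be unique within a library")
    scores: dict[str, float] = {}
    for ref in library:
        corr = structural_align(query, ref.structure)
        result = tm_score(
            query, ref.structure, corr, normalization=normalization, compute_gdt=False
        )
        scores[ref.fold_name] = result.tm_score
    best_fold = sorted(scores, key=lambda name: (-scores[name], name))[0]
    best_score = scores[best_fold]
    return FoldAssignment(
        query_id=query.id,
        scores=scores,
        best_fold=best_fold,
        best_score=best_score,
        verdict=verdict_from_score(best_score),
    )


def parse_domtbl(path: str | Path, e_value_field: str = "independent") -> list[PfamHit]:
    """Parse an hmmsearch per-domain table (``--domtblout``) into hits.

    One hit per domain line.  ``e_value_field`` selects the domain-level
    independent E-value (default) or the full-sequence E-value.  A
    malformed line raises :class:`DomtblParseError` naming the line.
    """
    if e_value_field not in ("independent", "full"):
        raise ValueError("e_value_field must be 'independent' or 'full'")
    path = Path(path)
    # Cheap structural pre-check so errors carry line numbers.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 23:
                raise DomtblParseError(
                    f"{path}:{lineno}: expected >= 23 columns, got {len(fields)}"
                )
            try:
                float(fields[6]), float(fields[12]), int(fields[5])
                int(fields[15]), int(fields[16])
            except ValueError as exc:
                raise DomtblParseError(f"{path}:{lineno}: {exc}") from exc
    hits: list[PfamHit] = []
    for qresult in SearchIO.parse(str(path), "hmmsearch3-domtab"):
        for hit in qresult:
            for hsp in hit:
                hits.append(
                    PfamHit(
                        target_id=hit.id,
                        hmm_name=qresult.id,
                        hmm_length=qresult.seq_len,
                        e_value=float(hsp.evalue if e_value_field == "independent" else hit.evalue),
                        hmm_from=hsp.query_start + 1,
                        hmm_to=hsp.query_end,
                    )
                )
    return hits


def pfam_filter(
    hits,
    max_e: float = 1e-3,
    min_cov: float = 0.9,
) -> list[PfamHit]:
    """Stringent profile-match filter with per-target deduplication.

    Keeps hits with E-value <= ``max_e`` whose hmm-coordinate span covers
    at least ``min_cov`` of the profile length (inclusive boundaries),
    then keeps only the lowest-E hit per target.  Output order is sorted
    by target id, so the result is independent of input order and the
    filter is idempotent.
    """
    surviving = [
        h
        for h in hits
        if h.e_value <= max_e
        and (h.hmm_to - h.hmm_from + 1) >= min_cov * h.hmm_length - 1e-9
    ]
    best: dict[str, PfamHit] = {}
    for h in sorted(surviving, key=lambda h: (h.target_id, h.e_value, h.hmm_name)):
        if h.target_id not in best:
            best[h.target_id] = h
    return [best[t] for t in sorted(best)]


def prepare_dimer_sequence(seq_a: str, seq_b: str, linker: str) -> DimerConstruct:
    """Concatenate two chains with a disordered linker for single-chain prediction.

    Returns the joined sequence and the 1-based coordinate ranges of the
    three segments so the prediction can later be split back into chains.
    """
    for label, seq in (("seq_a", seq_a), ("seq_b", seq_b), ("linker", linker)):
        bad = set(seq.upper()) - _AA_LETTERS
        if bad:
            raise SequenceError(f"{label} contains invalid characters {sorted(bad)}")
        if label != "linker" and not seq:
            raise SequenceError(f"{label} must be non-empty")
    seq_a, seq_b, linker = seq_a.upper(), seq_b.upper(), linker.upper()
    sequence = seq_a + linker + seq_b
    la, ll = len(seq_a), len(linker)
    return DimerConstruct(
        sequence=sequence,
        range_a=(1, la),
        range_linker=(la + 1, la + ll) if ll else None,
        range_b=(la + ll + 1, len(sequence)),
    )


def load_reference_library(config: str | Path | dict) -> list[ReferenceFold]:
    """Load a fold library from a YAML/JSON config (or an equivalent dict).

    Config layout::

        folds:
          - name: Pgp
            path: refs/pgp_tmd.pdb
            ranges: [[A, 100, 300]]   # optional TM-domain carving

    Relative paths resolve against the config file's directory.
    """
    base = Path(".")
    if not isinstance(config, dict):
        cfg_path = Path(config)
        base = cfg_path.parent
        with open(cfg_path) as fh:
            config = yaml.safe_load(fh)
    folds = config.get("folds") if isinstance(config, dict) else None
    if not folds:
        raise ConfigError("library config must define a non-empty 'folds' list")
    library: list[ReferenceFold] = []
    for entry in folds:
        try:
            name = entry["name"]
            path = Path(entry["path"])
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"bad library entry {entry!r}: {exc}") from exc
        if not path.is_absolute():
            path = base / path
        structure = load_structure(path)
        ranges = [
            (str(c), int(s), int(e)) for c, s, e in entry.get("ranges", [])
        ]
        if ranges:
            structure = select_residues(structure, ranges)
            if len(structure) == 0:
                warnings.warn(f"fold {name}: TM ranges matched zero residues")
        library.append(
            ReferenceFold(
                fold_name=name,
                structure=structure,
                source_id=path.stem,
                tm_ranges=ranges,
            )
        )
    return library
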