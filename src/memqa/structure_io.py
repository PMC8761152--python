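"""Reading and writing macromolecular structures as C-alpha traces.

Predicted models (e.g. from AlphaFold) store the per-residue confidence
score (pLDDT, 0-100) in the B-factor column.  This module exposes each
residue's C-alpha coordinate and that confidence value to the rest of the
package.  Only model 1 is used; hetero records are skipped; for altloc'd
atoms the first listed location wins.  Author residue numbering is kept
verbatim because topology annotations refer to it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gemmi
import numpy as np

from .errors import EmptyStructureError, StructureParseError, RegionError

__all__ = [
    "Residue",
    "Structure",
    "load_structure",
    "select_residues",
    "write_structure",
]


@dataclass(frozen=True, eq=False)
class Residue:
    """One residue of a chain.

    ``confidence`` is the per-residue model confidence read from the
    B-factor of the C-alpha atom (pLDDT for predicted models); it is
    ``None`` when absent or outside the meaningful [0, 100] range.
    """

    chain_id: str
    seq_number: int
    insertion_code: str | None = None
    name: str = "ALA"
    ca_coord: np.ndarray | None = None
    confidence: float | None = None

    def __post_init__(self) -> None:
        if self.ca_coord is not None:
            coord = np.asarray(self.ca_coord, dtype=float)
            if coord.shape != (3,) or not np.all(np.isfinite(coord)):
                raise ValueError(
                    f"ca_coord must be a finite 3-vector, got {self.ca_coord!r}"
                )
            object.__setattr__(self, "ca_coord", coord)
        if self.confidence is not None:
            conf = float(self.confidence)
            if not (0.0 <= conf <= 100.0):
                raise ValueError(f"confidence must lie in [0, 100], got {conf}")
            object.__setattr__(self, "confidence", conf)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Residue):
            return NotImplemented
        same_coord = (
            (self.ca_coord is None and other.ca_coord is None)
            or (
                self.ca_coord is not None
                and other.ca_coord is not None
                and np.array_equal(self.ca_coord, other.ca_coord)
            )
        )
        return (
            same_coord
            and self.chain_id == other.chain_id
            and self.seq_number == other.seq_number
            and self.insertion_code == other.insertion_code
            and self.name == other.name
            and self.confidence == other.confidence
        )

    def __hash__(self) -> int:
        return hash((self.chain_id, self.seq_number, self.insertion_code, self.name))


@dataclass
class Structure:
    """An ordered C-alpha trace grouped by chain, in file order."""

    id: str
    residues: list[Residue] = field(default_factory=list)
    source_format: str = "pdb"

    def __post_init__(self) -> None:
        seen: set[tuple[str, int, str | None]] = set()
        for res in self.residues:
            key = (res.chain_id, res.seq_number, res.insertion_code)
            if key in seen:
                raise ValueError(f"duplicate residue {key} in structure {self.id!r}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    @property
    def chain_ids(self) -> list[str]:
        out: list[str] = []
        for res in self.residues:
            if res.chain_id not in out:
                out.append(res.chain_id)
        return out

    def ca_residues(self) -> list[Residue]:
        """Residues that actually carry a C-alpha coordinate."""
        return [r for r in self.residues if r.ca_coord is not None]

    def ca_array(self) -> np.ndarray:
        """(N, 3) array over residues that have a C-alpha coordinate."""
        res = self.ca_residues()
        if not res:
            return np.empty((0, 3))
        return np.vstack([r.ca_coord for r in res])

    def confidences(self) -> list[float]:
        return [r.confidence for r in self.residues if r.confidence is not None]

    def find(self, seq_number: int, chain_id: str | None = None) -> Residue | None:
        """First residue with the given author number (any chain by default)."""
        for res in self.residues:
            if res.seq_number == seq_number and (
                chain_id is None or res.chain_id == chain_id
            ):
                return res
        return None

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Copy of this structure with the C-alpha coordinates replaced.

        ``coords`` must have one row per C-alpha-bearing residue, in order.
        """
        coords = np.asarray(coords, dtype=float)
        ca_res = self.ca_residues()
        if coords.shape != (len(ca_res), 3):
            raise ValueError(
                f"expected coords of shape ({len(ca_res)}, 3), got {coords.shape}"
            )
        new_residues: list[Residue] = []
        k = 0
        for res in self.residues:
            if res.ca_coord is None:
                new_residues.append(res)
            else:
                new_residues.append(
                    Residue(
                        chain_id=res.chain_id,
                        seq_number=res.seq_number,
                        insertion_code=res.insertion_code,
                        name=res.name,
                        ca_coord=coords[k],
                        confidence=res.confidence,
                    )
                )
                k += 1
        return Structure(id=self.id, residues=new_residues, source_format=self.source_format)


_FORMAT_MAP = {
    "pdb": gemmi.CoorFormat.Pdb,
    "mmcif": gemmi.CoorFormat.Mmcif,
    "auto": gemmi.CoorFormat.Detect,
}


def load_structure(path: str | Path, format: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into a C-alpha :class:`Structure`.

    Confidence is taken from the B-factor / isotropic-displacement field of
    the C-alpha atom; values outside [0, 100] (possible for experimental
    B-factors) yield ``confidence=None``.  Residues lacking a C-alpha are
    retained with ``ca_coord=None``.  Model 1 only; hetero residues are
    skipped; the first altloc wins.
    """
    path = Path(path)
    if format not in _FORMAT_MAP:
        raise ValueError(f"format must be one of {sorted(_FORMAT_MAP)}, got {format!r}")
    try:
        st = gemmi.read_structure(str(path), format=_FORMAT_MAP[format])
    except (RuntimeError, ValueError, OSError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: file contains no models")

    source_format = "mmcif" if st.input_format == gemmi.CoorFormat.Mmcif else "pdb"
    residues: list[Residue] = []
    n_ca = 0
    n_conf_out_of_range = 0
    model = st[0]
    for chain in model:
        for res in chain:
            if res.het_flag == "H":
                continue
            ca = None
            for atom in res:
                if atom.name == "CA":
                    ca = atom  # first listed altloc wins
                    break
            coord = None
            conf: float | None = None
            if ca is not None:
                n_ca += 1
                coord = np.array([ca.pos.x, ca.pos.y, ca.pos.z])
                b = float(ca.b_iso)
                if 0.0 <= b <= 100.0:
                    conf = b
                else:
                    n_conf_out_of_range += 1
            icode = res.seqid.icode.strip() or None
            residues.append(
                Residue(
                    chain_id=chain.name,
                    seq_number=res.seqid.num,
                    insertion_code=icode,
                    name=res.name,
                    ca_coord=coord,
                    confidence=conf,
                )
            )
    if n_ca == 0:
        raise EmptyStructureError(f"{path}: no C-alpha atoms found")
    if n_conf_out_of_range:
        warnings.warn(
            f"{path}: {n_conf_out_of_range} C-alpha B-factors outside [0, 100]; "
            "confidence set to None for those residues",
            stacklevel=2,
        )
    return Structure(id=path.stem, residues=residues, source_format=source_format)


def select_residues(
    s: Structure, ranges: Sequence[tuple[str, int, int]]
) -> Structure:
    """Carve residues whose author number falls in a range on the named chain.

    ``ranges`` holds ``(chain_id, start, end)`` with inclusive 1-based bounds
    in author numbering.  File order is preserved; an empty selection is
    returned with a warning rather than raising, so the caller decides.
    """
    if not ranges:
        raise RegionError("ranges must be non-empty")
    for chain_id, start, end in ranges:
        if start > end:
            raise RegionError(f"range ({chain_id}, {start}, {end}) has start > end")
    selected = [
        res
        for res in s.residues
        if any(
            res.chain_id == chain_id and start <= res.seq_number <= end
            for chain_id, start, end in ranges
        )
    ]
    if not selected:
        warnings.warn(
            f"selection on {s.id!r} matched zero residues for ranges {list(ranges)}",
            stacklevel=2,
        )
    return Structure(id=s.id, residues=selected, source_format=s.source_format)


def write_structure(s: Structure, path: str | Path) -> None:
    """Write a minimal C-alpha-only PDB that round-trips through the loader.

    Absent confidence is written as B-factor 0.00 by convention.  All
    residues must carry a coordinate.
    """
    if len(s) == 0:
        raise EmptyStructureError(f"refusing to write empty structure {s.id!r}")
    missing = [r for r in s.residues if r.ca_coord is None]
    if missing:
        raise ValueError(
            f"{len(missing)} residues lack ca_coord; cannot write {s.id!r}"
        )
    st = gemmi.Structure()
    st.name = s.id
    model = gemmi.Model("1")
    chain_obj: gemmi.Chain | None = None
    current_chain = None
    serial = 0
    for res in s.residues:
        if res.chain_id != current_chain:
            if chain_obj is not None:
                model.add_chain(chain_obj)
            chain_obj = gemmi.Chain(res.chain_id)
            current_chain = res.chain_id
        gres = gemmi.Residue()
        gres.name = res.name
        gres.seqid = gemmi.SeqId(res.seq_number, res.insertion_code or " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        serial += 1
        atom.serial = serial
        atom.pos = gemmi.Position(*res.ca_coord)
        atom.occ = 1.0
        atom.b_iso = res.confidence if res.confidence is not None else 0.0
        gres.add_atom(atom)
        chain_obj.add_residue(gres)
    if chain_obj is not None:
        model.add_chain(chain_obj)
    st.add_model(model)
    st.setup_entities()
    try:
        st.write_pdb(str(path))
    except (RuntimeError, OSError) as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc
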