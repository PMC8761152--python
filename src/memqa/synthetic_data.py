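"""Synthetic membrane-protein fixtures with known ground truth.

Everything downstream of the file parsers is exercised on data built
here: idealised antiparallel alpha-helix bundles with a prescribed
hydrophobic thickness and tilt, matching topology annotations, painted
per-residue confidence, deliberately broken decoy variants, rigidly
perturbed copies for superposition tests, random-coil negatives, a small
synthetic reference-fold library, and format-valid hmmsearch domain
tables.

Geometry conventions: ideal helix rise 1.5 A per residue, 100 degree
twist, 2.3 A C-alpha radius.  The two boundary residues of each helix
are placed on the helix axis exactly at z = +/- thickness/2 (before
noise), and a global z-shear cancels any lateral offset between the two
endpoint centroids, so the generated thickness is exact by construction
for any helix count or tilt.  Loops are semicircular arcs outside the
membrane slab; only their side matters to any consumer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import MemqaError
from .structure_io import Residue, Structure
from .topology_io import SIDE1, SIDE2, TMSegment, TopologyAnnotation

__all__ = [
    "RISE_PER_RESIDUE",
    "TWIST_DEG",
    "CA_RADIUS",
    "BundleSpec",
    "generate_bundle",
    "make_decoy",
    "perturb_structure",
    "generate_coil",
    "synthetic_reference_library",
    "d0_displaced_cloud",
    "write_fixture_domtbl",
    "DISORDERED_LINKER_126",
]

RISE_PER_RESIDUE = 1.5  # A along the helix axis
TWIST_DEG = 100.0
CA_RADIUS = 2.3  # A, C-alpha distance from the helix axis

#: Synthetic 126-residue disordered-linker stand-in (glycine/serine-rich,
#: same length as the intrinsically disordered regulatory-domain fragment
#: used to join dimer chains).  Not a natural sequence.
DISORDERED_LINKER_126 = ("GSGSGSEGSGNSGSGSTEGSGSDGSGSGNSGSGSE" * 4)[:126]


@dataclass(frozen=True)
class BundleSpec:
    """Parameters of one synthetic helix bundle."""

    n_helices: int = 4
    helix_length: int = 24
    target_thickness: float = 30.0
    tilt_deg: float = 0.0
    loop_length: int = 4
    radius: float = 8.0
    noise_sigma: float = 0.0
    seed: int = 0
    plddt_tm: float = 90.0
    plddt_loop: float = 60.0
    reliability: float = 95.0

    def __post_init__(self) -> None:
        if self.n_helices < 1:
            raise MemqaError("n_helices must be >= 1")
        if self.helix_length < 4:
            raise MemqaError("helix_length must be >= 4")
        for name in ("target_thickness", "loop_length", "radius"):
            if getattr(self, name) <= 0:
                raise MemqaError(f"{name} must be positive")
        if self.noise_sigma < 0:
            raise MemqaError("noise_sigma must be >= 0")
        if not (0.0 <= self.tilt_deg <= 45.0):
            raise MemqaError("tilt_deg must lie in [0, 45]")
        max_span = self.helix_length * RISE_PER_RESIDUE
        needed = self.target_thickness / math.cos(math.radians(self.tilt_deg))
        if max_span < needed:
            raise MemqaError(
                f"unachievable spec: helix span {max_span:.1f} A < required "
                f"{needed:.1f} A for thickness {self.target_thickness} at "
                f"tilt {self.tilt_deg} deg"
            )


def _rot_z(angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _helix_coords(a: np.ndarray, b: np.ndarray, n_res: int, flip: bool) -> np.ndarray:
    """Ideal helix along the axis a->b; first/last C-alpha exactly at a and b.

    Interior residues follow the ideal geometry (1.5 A rise, 100 deg
    twist, 2.3 A radius) around the axis; the two boundary residues are
    axial caps so that membrane-side endpoints sit exactly on the slab
    surfaces.
    """
    axis = b - a
    length = np.linalg.norm(axis)
    d = axis / length
    # Orthonormal frame around the axis.
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(ref, d)) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    n1 = np.cross(d, ref)
    n1 /= np.linalg.norm(n1)
    n2 = np.cross(d, n1)
    coords = np.empty((n_res, 3))
    coords[0] = a
    coords[-1] = b
    # Interior residues: centred run of ideal rise along the axis.
    span = (n_res - 3) * RISE_PER_RESIDUE
    start_s = (length - span) / 2.0
    for k in range(1, n_res - 1):
        s = start_s + (k - 1) * RISE_PER_RESIDUE
        psi = math.radians(TWIST_DEG) * k
        coords[k] = a + s * d + CA_RADIUS * (math.cos(psi) * n1 + math.sin(psi) * n2)
    if flip:
        coords = coords[::-1].copy()
    return coords


def _loop_coords(p: np.ndarray, q: np.ndarray, n_res: int, z_sign: float) -> np.ndarray:
    """Semicircular arc between p and q bulging away from the slab in z."""
    centre = (p + q) / 2.0
    half = (q - p) / 2.0
    bulge = max(3.0, float(np.linalg.norm(half)))
    coords = np.empty((n_res, 3))
    for j in range(n_res):
        ang = math.pi * (j + 1) / (n_res + 1)
        coords[j] = centre - math.cos(ang) * half
        coords[j, 2] += z_sign * bulge * math.sin(ang)
    return coords


def generate_bundle(spec: BundleSpec) -> tuple[Structure, TopologyAnnotation]:
    """Build an antiparallel helix bundle and its topology annotation.

    Helices stand on a circle of ``spec.radius``, alternate direction,
    and are tilted tangentially by ``spec.tilt_deg``.  The first helix
    runs from side1 (z < 0) to side2, so the annotation starts
    inside-out.  Identical specs produce identical structures.
    """
    n = spec.n_helices
    T = spec.target_thickness
    theta = math.radians(spec.tilt_deg)
    half_axis = (T / 2.0) / math.cos(theta)

    helix_coords: list[np.ndarray] = []
    anchors: list[tuple[np.ndarray, np.ndarray]] = []
    for k in range(n):
        phi = 2.0 * math.pi * k / n
        mid = np.array([spec.radius * math.cos(phi), spec.radius * math.sin(phi), 0.0])
        # Tilt toward the tangential direction of the bundle circle.
        tangent = np.array([-math.sin(phi), math.cos(phi), 0.0])
        direction = math.cos(theta) * np.array([0.0, 0.0, 1.0]) + math.sin(theta) * tangent
        a = mid - half_axis * direction  # z = -T/2 exactly
        b = mid + half_axis * direction  # z = +T/2 exactly
        anchors.append((a, b))
        helix_coords.append(_helix_coords(a, b, spec.helix_length, flip=(k % 2 == 1)))

    # Exactness correction: shear xy by z so the two endpoint-set centroids
    # coincide laterally (no-op for symmetric even bundles).
    side1_pts = [anchors[k][0] for k in range(n)]  # all at z=-T/2
    side2_pts = [anchors[k][1] for k in range(n)]
    delta_xy = np.mean(side2_pts, axis=0)[:2] - np.mean(side1_pts, axis=0)[:2]
    g = -delta_xy / T

    def _shear(c: np.ndarray) -> np.ndarray:
        out = c.copy()
        out[:, 0] += out[:, 2] * g[0]
        out[:, 1] += out[:, 2] * g[1]
        return out

    helix_coords = [_shear(c) for c in helix_coords]

    residues: list[Residue] = []
    segments: list[TMSegment] = []
    seq = 0

    def _add(coords: np.ndarray, name: str, conf: float) -> tuple[int, int]:
        nonlocal seq
        first = seq + 1
        for row in coords:
            seq += 1
            residues.append(
                Residue(
                    chain_id="A",
                    seq_number=seq,
                    name=name,
                    ca_coord=row,
                    confidence=conf,
                )
            )
        return first, seq

    all_blocks: list[np.ndarray] = []
    for k in range(n):
        start, end = _add(helix_coords[k], "ALA", spec.plddt_tm)
        all_blocks.append(helix_coords[k])
        if k % 2 == 0:
            segments.append(TMSegment(start, end, SIDE1, SIDE2))
        else:
            segments.append(TMSegment(start, end, SIDE2, SIDE1))
        if k < n - 1:
            p = helix_coords[k][-1]
            q = helix_coords[k + 1][0]
            z_sign = 1.0 if k % 2 == 0 else -1.0
            loop = _loop_coords(p, q, spec.loop_length, z_sign)
            _add(loop, "GLY", spec.plddt_loop)
            all_blocks.append(loop)

    structure = Structure(id=f"bundle_{spec.seed}", residues=residues, source_format="pdb")
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        coords = structure.ca_array()
        coords = coords + rng.normal(0.0, spec.noise_sigma, coords.shape)
        structure = structure.with_coords(coords)
    annotation = TopologyAnnotation(
        protein_id=structure.id,
        sequence_length=seq,
        segments=segments,
        reliability=spec.reliability,
    )
    return structure, annotation


def make_decoy(
    s: Structure,
    annotation: TopologyAnnotation,
    mode: str,
    magnitude: float | None = None,
) -> Structure:
    """Break a bundle the way a mis-built predicted structure would be.

    ``invert_helix`` reflects the first TM helix through the slab midplane
    (its endpoints land on the wrong sides); ``collapse`` rescales all z
    by 0.4 (magnitude overridable), squeezing the apparent thickness;
    ``shear`` translates the second half of the helices (and trailing
    residues) by +20 A in z (magnitude overridable).  The caller keeps
    the original annotation so the thickness statistic sees the mismatch.

    Note that shearing is a deliberate blind spot of the thickness
    statistic: every helix contributes one endpoint to each side, so a
    per-helix rigid z-shift moves both side centroids identically and
    leaves the centroid distance unchanged.  Sheared decoys are caught by
    structural comparison, not by the thickness flag.
    """
    if not annotation.segments:
        raise MemqaError("decoy construction needs at least one TM segment")
    coords = s.ca_array().copy()
    seq_numbers = [r.seq_number for r in s.ca_residues()]
    if mode == "invert_helix":
        seg = annotation.segments[0]
        for i, num in enumerate(seq_numbers):
            if seg.start <= num <= seg.end:
                coords[i, 2] = -coords[i, 2]
    elif mode == "collapse":
        factor = 0.4 if magnitude is None else magnitude
        coords[:, 2] *= factor
    elif mode == "shear":
        offset = 20.0 if magnitude is None else magnitude
        half_idx = len(annotation.segments) // 2
        cut = annotation.segments[half_idx].start
        for i, num in enumerate(seq_numbers):
            if num >= cut:
                coords[i, 2] += offset
    else:
        raise MemqaError(f"unknown decoy mode {mode!r}")
    out = s.with_coords(coords)
    out.id = f"{s.id}_{mode}"
    return out


def perturb_structure(
    s: Structure, rotation_seed: int, noise_sigma: float = 0.0
) -> Structure:
    """Random rigid transform plus optional Gaussian coordinate noise.

    The rotation is drawn uniformly from SO(3) (normalised Gaussian
    quaternion), the translation uniformly from [-50, 50]^3 A; both are
    deterministic per seed.
    """
    if len(s) == 0:
        raise MemqaError("cannot perturb an empty structure")
    rng = np.random.default_rng(rotation_seed)
    quat = rng.normal(size=4)
    quat /= np.linalg.norm(quat)
    w, x, y, z = quat
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    trans = rng.uniform(-50.0, 50.0, 3)
    coords = s.ca_array() @ rot.T + trans
    if noise_sigma > 0:
        coords = coords + rng.normal(0.0, noise_sigma, coords.shape)
    return s.with_coords(coords)


def generate_coil(length: int, seed: int, step: float = 3.8) -> Structure:
    """Seeded random C-alpha walk with consecutive spacing ``step`` A.

    Serves as a structurally unrelated negative control; direction changes
    are mildly persistent so the walk is chain-like rather than a dense
    blob.
    """
    if length < 2:
        raise MemqaError("coil length must be >= 2")
    rng = np.random.default_rng(seed)
    coords = np.zeros((length, 3))
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    for i in range(1, length):
        kick = rng.normal(size=3)
        direction = 0.6 * direction + 0.4 * kick / np.linalg.norm(kick)
        direction /= np.linalg.norm(direction)
        coords[i] = coords[i - 1] + step * direction
    residues = [
        Residue(chain_id="A", seq_number=i + 1, name="GLY", ca_coord=coords[i])
        for i in range(length)
    ]
    return Structure(id=f"coil_{seed}", residues=residues, source_format="pdb")


#: Geometry presets for the synthetic stand-in reference folds.  The
#: eight names follow the conventional membrane-fold families of the ABC
#: superfamily; the structures themselves are synthetic bundles with
#: deliberately distinct helix counts, radii, tilts and lengths so they
#: are mutually distinguishable by TM-score.
_LIBRARY_PRESETS: dict[str, dict] = {
    "Pgp": dict(n_helices=6, helix_length=22, radius=9.0, tilt_deg=12.0, target_thickness=30.0),
    "ABCG2": dict(n_helices=6, helix_length=13, radius=7.0, tilt_deg=0.0, target_thickness=19.0),
    "MalFG": dict(n_helices=5, helix_length=18, radius=10.5, tilt_deg=25.0, target_thickness=24.0),
    "BtuC": dict(n_helices=8, helix_length=14, radius=11.0, tilt_deg=6.0, target_thickness=20.0),
    "EcfT": dict(n_helices=4, helix_length=19, radius=7.5, tilt_deg=18.0, target_thickness=26.0),
    "LptFG": dict(n_helices=4, helix_length=13, radius=9.5, tilt_deg=0.0, target_thickness=18.0),
    "MacB": dict(n_helices=3, helix_length=23, radius=8.0, tilt_deg=8.0, target_thickness=32.0),
    "MlaE": dict(n_helices=5, helix_length=12, radius=6.5, tilt_deg=10.0, target_thickness=17.0),
}


def synthetic_reference_library(seed: int = 0):
    """Eight synthetic stand-in reference folds (TM domains only).

    Returns a list of :class:`memqa.fold_classify.ReferenceFold`.  These
    are not the experimental family representatives; they are geometry
    stand-ins for tests and examples, with one bundle per family name.
    """
    from .fold_classify import ReferenceFold

    library = []
    for i, (name, preset) in enumerate(_LIBRARY_PRESETS.items()):
        spec = BundleSpec(loop_length=3, seed=seed * 1000 + i, **preset)
        structure, _ = generate_bundle(spec)
        structure.id = f"synthetic_{name}"
        library.append(
            ReferenceFold(
                fold_name=name,
                structure=structure,
                source_id=structure.id,
                tm_ranges=[("A", 1, len(structure))],
            )
        )
    return library


def _rigid_mode_max_eig(centred: np.ndarray, dirs: np.ndarray) -> float:
    """Largest eigenvalue of the TM-sum second-order form over rigid modes.

    At unit displacement distance the TM integrand gains 2(v.d)^2 - |v|^2
    (in units of the common curvature) for a rigid velocity field v; the
    form is assembled in the 6-dimensional basis of translations and
    rotations about the centroid.  Negative-definite means no rigid move
    improves the all-pairs-at-d0 score.
    """
    n = centred.shape[0]
    fields = []
    for k in range(3):
        e = np.zeros(3)
        e[k] = 1.0
        fields.append(np.tile(e, (n, 1)))
    for k in range(3):
        e = np.zeros(3)
        e[k] = 1.0
        fields.append(np.cross(e, centred))
    q = np.zeros((6, 6))
    for a in range(6):
        pa = np.einsum("ij,ij->i", fields[a], dirs)
        for b in range(a, 6):
            pb = np.einsum("ij,ij->i", fields[b], dirs)
            q[a, b] = q[b, a] = float(
                np.sum(2.0 * pa * pb - np.einsum("ij,ij->i", fields[a], fields[b]))
            )
    return float(np.linalg.eigvalsh(q)[-1])


def d0_displaced_cloud(
    n: int = 24, seed: int = 0, box: float = 44.0, min_dist: float = 8.0
) -> tuple[Structure, Structure]:
    """Reference/query pair with every aligned pair exactly d0 apart.

    Builds a well-separated random point cloud and displaces each point
    by d0(n) along unit directions balanced so that (a) the net
    displacement and net torque vanish — making the identity transform
    the Kabsch optimum — and (b) the second-order change of the TM sum
    along every rigid-body mode is strictly negative, so no rigid
    perturbation improves on the identity.  The TM-score of the pair is
    then exactly 1/(1+1) = 0.5 under the optimal superposition.  Used to
    calibrate the scoring search.  Direction draws failing (b) are
    rejected deterministically.
    """
    from .superposition import d0 as _d0

    rng = np.random.default_rng(seed)
    pts: list[np.ndarray] = []
    while len(pts) < n:
        cand = rng.uniform(-box / 2, box / 2, 3)
        if all(np.linalg.norm(cand - p) >= min_dist for p in pts):
            pts.append(cand)
    ref = np.vstack(pts)
    centred = ref - ref.mean(axis=0)
    for _attempt in range(200):
        dirs = rng.normal(size=(n, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        # Project onto zero net displacement and zero net torque,
        # renormalise, iterate to convergence.
        for _ in range(500):
            dirs -= dirs.mean(axis=0)
            torque = np.sum(np.cross(centred, dirs), axis=0)
            a = np.zeros((3, 3))
            for rvec in centred:
                rx = np.array(
                    [[0, -rvec[2], rvec[1]], [rvec[2], 0, -rvec[0]], [-rvec[1], rvec[0], 0]]
                )
                a += rx @ rx.T
            omega = np.linalg.solve(a, torque)
            dirs -= np.cross(omega, centred)
            dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        if _rigid_mode_max_eig(centred, dirs) < -0.5:
            break
    else:  # pragma: no cover - rejection virtually always succeeds early
        raise MemqaError("could not balance displacement directions")
    scale = _d0(n)
    query = ref + scale * dirs

    def _as_structure(coords: np.ndarray, sid: str) -> Structure:
        return Structure(
            id=sid,
            residues=[
                Residue(chain_id="A", seq_number=i + 1, name="GLY", ca_coord=coords[i])
                for i in range(coords.shape[0])
            ],
        )

    return _as_structure(ref, f"d0cloud_ref_{seed}"), _as_structure(query, f"d0cloud_query_{seed}")


_DOMTBL_HEADER = (
    "#                                                               --- full sequence ---"
    " --- this domain --- hmm coord ali coord env coord\n"
    "# target name        accession   tlen query name           accession   qlen"
    "   E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias  from    to"
    "  from    to  from    to  acc description of target\n"
    "#------------------- ---------- ----- -------------------- ---------- -----"
    " --------- ------ ----- --- --- --------- --------- ------ ----- ----- -----"
    " ----- ----- ----- ----- ---- ---------------------\n"
)


def write_fixture_domtbl(hits, path: str | Path) -> None:
    """Emit a format-valid hmmsearch per-domain table for the given hits.

    Each :class:`memqa.fold_classify.PfamHit` becomes one domain line;
    unspecified columns are filled with plausible values.  Round-trips
    through :func:`memqa.fold_classify.parse_domtbl`.
    """
    lines = [_DOMTBL_HEADER]
    for i, h in enumerate(hits):
        span = h.hmm_to - h.hmm_from + 1
        lines.append(
            f"{h.target_id:<20} -          {h.hmm_length + 100:5d} "
            f"{h.hmm_name:<20} -          {h.hmm_length:5d} "
            f"{h.e_value:9.2g} {50.0:6.1f} {0.1:5.1f} {1:3d} {1:3d} "
            f"{h.e_value:9.2g} {h.e_value:9.2g} {49.0:6.1f} {0.1:5.1f} "
            f"{h.hmm_from:5d} {h.hmm_to:5d} {h.hmm_from:5d} {h.hmm_to:5d} "
            f"{max(1, h.hmm_from - 2):5d} {h.hmm_to + 2:5d} 0.90 -\n"
        )
    lines.append("#\n# Program:         hmmsearch\n# Version:         3.4\n")
    Path(path).write_text("".join(lines))
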