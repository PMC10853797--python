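"""All-atom B-DNA built by rigid placement of idealized base-pair templates.

Each base pair of the duplex is the template rigidly transformed so its
origin sits on the coarse-grained trace point, its z-axis follows the local
curve tangent, and its in-plane orientation advances by the helical twist on
top of a rotation-minimizing (parallel-transport) frame.  Rigid placement
means the bases are exact; only the backbone concatenation strains, which is
what :func:`bond_strain_report` measures.

Lengths are nm internally; PDB/mmCIF files are written in Angstrom.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .spiral import Trace

__all__ = [
    "BasePairTemplate",
    "AtomicModel",
    "DuplexSegment",
    "StrainReport",
    "StructureWriteError",
    "load_templates",
    "build_duplex",
    "bond_strain_report",
    "write_structure",
    "parallel_transport_frames",
    "chain_id_pair",
]

COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}

#: canonical B-DNA helical twist, degrees per base pair
DEFAULT_TWIST = 36.0
#: canonical B-DNA rise used for straight-helix bond references, nm
DEFAULT_RISE = 0.34

_PDB_MAX_ATOMS = 99999


class StructureWriteError(RuntimeError):
    pass


@dataclass(frozen=True)
class BasePairTemplate:
    """One idealized Watson-Crick pair in its local reference frame.

    Frame convention: origin at the pair center, z along the helix axis,
    y along the C1'(B) -> C1'(A) direction orthogonal to z.  ``code`` is the
    strand-A base letter; strand B holds the complement.
    """

    code: str
    res_names: Dict[str, str]  # strand -> residue name (DA/DC/DG/DT)
    atom_names: Dict[str, Tuple[str, ...]]
    elements: Dict[str, Tuple[str, ...]]
    coords: Dict[str, np.ndarray]  # strand -> (n_atoms, 3) nm

    @property
    def c1c1_distance(self) -> float:
        """C1'-C1' distance, nm -- a template constant."""
        a = self.coords["A"][self.atom_names["A"].index("C1'")]
        b = self.coords["B"][self.atom_names["B"].index("C1'")]
        return float(np.linalg.norm(a - b))

    def atom(self, strand: str, name: str) -> np.ndarray:
        return self.coords[strand][self.atom_names[strand].index(name)]


_TEMPLATE_CACHE: Optional[Dict[str, BasePairTemplate]] = None


def load_templates() -> Dict[str, BasePairTemplate]:
    """Load the versioned base-pair template data file (one per base letter)."""
    global _TEMPLATE_CACHE
    if _TEMPLATE_CACHE is not None:
        return _TEMPLATE_CACHE
    path = resources.files("spooltrace").joinpath("data/bp_templates.csv")
    with path.open() as fh:
        table = pd.read_csv(fh, comment="#")
    templates = {}
    for code, group in table.groupby("pair"):
        res_names, atom_names, elements, coords = {}, {}, {}, {}
        for strand, rows in group.groupby("strand"):
            res_names[strand] = rows["res_name"].iloc[0]
            atom_names[strand] = tuple(rows["atom_name"])
            elements[strand] = tuple(rows["element"])
            coords[strand] = rows[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
        templates[code] = BasePairTemplate(code, res_names, atom_names, elements, coords)
    missing = set("ACGT") - set(templates)
    if missing:
        raise RuntimeError(f"template data file lacks pairs for {sorted(missing)}")
    _TEMPLATE_CACHE = templates
    return templates


# ---------------------------------------------------------------------------
# frames along the trace


def _rotate_about(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    k = axis / np.linalg.norm(axis)
    return (
        v * math.cos(angle)
        + np.cross(k, v) * math.sin(angle)
        + k * float(np.dot(k, v)) * (1.0 - math.cos(angle))
    )


def _transport(v: np.ndarray, t_from: np.ndarray, t_to: np.ndarray) -> np.ndarray:
    """Rotate ``v`` by the minimal rotation taking tangent ``t_from`` to ``t_to``."""
    c = float(np.dot(t_from, t_to))
    w = np.cross(t_from, t_to)
    s2 = float(np.dot(w, w))
    if s2 < 1e-24:
        if c > 0:
            return v
        raise ValueError("tangent reversal: trace doubles back on itself")
    return v * c + np.cross(w, v) + w * float(np.dot(w, v)) * (1.0 - c) / s2


def parallel_transport_frames(points: np.ndarray, twist_per_bp: float) -> List[np.ndarray]:
    """Rotation-minimizing frames with explicit helical twist.

    Tangents come from central finite differences (one-sided at the ends);
    the frame normal is parallel-transported along the tangent sequence and
    then rotated about the local tangent by ``i * twist_per_bp`` degrees at
    point ``i``.  Returns one 3x3 matrix per point with columns (x, y, z);
    z is the tangent, y the twisted normal.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n < 2:
        raise ValueError("need at least two trace points to orient base pairs")
    diffs = np.diff(pts, axis=0)
    if np.any(np.linalg.norm(diffs, axis=1) < 1e-12):
        raise ValueError("coincident consecutive trace points: cannot orient base pairs")
    tangents = np.empty_like(pts)
    tangents[0] = diffs[0]
    tangents[-1] = diffs[-1]
    if n > 2:
        tangents[1:-1] = pts[2:] - pts[:-2]
    tangents /= np.linalg.norm(tangents, axis=1)[:, None]

    # reference normal: global axis least aligned with the first tangent
    seed = np.eye(3)[int(np.argmin(np.abs(tangents[0])))]
    normal = seed - float(np.dot(seed, tangents[0])) * tangents[0]
    normal /= np.linalg.norm(normal)

    twist = math.radians(twist_per_bp)
    frames = []
    for i in range(n):
        if i > 0:
            normal = _transport(normal, tangents[i - 1], tangents[i])
            normal -= float(np.dot(normal, tangents[i])) * tangents[i]
            normal /= np.linalg.norm(normal)
        y = _rotate_about(normal, tangents[i], twist * i)
        z = tangents[i]
        x = np.cross(y, z)
        frames.append(np.stack([x, y, z], axis=1))
    return frames


# ---------------------------------------------------------------------------
# model container


def chain_id_pair(segment_index: int) -> Tuple[str, str]:
    """Deterministic chain IDs for segment k: (A,B), (C,D), ... then (AA,AB), ..."""
    letters = string.ascii_uppercase
    i, j = 2 * segment_index, 2 * segment_index + 1

    def make(idx: int) -> str:
        if idx < 26:
            return letters[idx]
        hi, lo = divmod(idx - 26, 26)
        return letters[hi] + letters[lo]

    return make(i), make(j)


@dataclass
class DuplexSegment:
    """One double-stranded segment built on one entry strand of a trace."""

    chain_a: str
    chain_b: str
    sequence: str  # strand A, 5'->3' in trace order
    bp_codes: Tuple[str, ...]
    frames: List[np.ndarray]
    centers: np.ndarray  # (n_bp, 3) nm == the trace points

    @property
    def n_bp(self) -> int:
        return len(self.bp_codes)


@dataclass
class AtomicModel:
    """All-atom double-stranded DNA as rigidly placed base-pair templates.

    Atom coordinates are generated lazily from segment frames and the
    template library, so base-pair centers reproduce the trace exactly.
    """

    segments: List[DuplexSegment]
    twist_per_bp: float = DEFAULT_TWIST
    templates: Dict[str, BasePairTemplate] = field(default_factory=load_templates)

    @property
    def n_bp(self) -> int:
        return sum(seg.n_bp for seg in self.segments)

    def bp_centers(self) -> np.ndarray:
        return np.concatenate([seg.centers for seg in self.segments])

    def bp_atoms(self, segment: int, i: int, strand: str):
        """(atom_names, elements, world coords nm) of one placed nucleotide."""
        seg = self.segments[segment]
        tmpl = self.templates[seg.bp_codes[i]]
        world = seg.centers[i] + tmpl.coords[strand] @ seg.frames[i].T
        return tmpl.atom_names[strand], tmpl.elements[strand], world

    def atom_records(self):
        """Yield (chain_id, res_id, res_name, atom_name, element, coord_nm).

        Chain A of each segment runs 5'->3' in trace order (res_id 1..n);
        chain B is the antiparallel complement (res_id j pairs trace point
        n - j).  Atoms are emitted chain by chain in residue order.
        """
        for s, seg in enumerate(self.segments):
            n = seg.n_bp
            for i in range(n):
                tmpl = self.templates[seg.bp_codes[i]]
                names, elements, coords = self.bp_atoms(s, i, "A")
                for name, elem, xyz in zip(names, elements, coords):
                    yield (seg.chain_a, i + 1, tmpl.res_names["A"], name, elem, xyz)
            for j in range(n):
                i = n - 1 - j  # res_id j+1 of chain B sits at trace point i
                tmpl = self.templates[seg.bp_codes[i]]
                names, elements, coords = self.bp_atoms(s, i, "B")
                for name, elem, xyz in zip(names, elements, coords):
                    yield (seg.chain_b, j + 1, tmpl.res_names["B"], name, elem, xyz)

    def atom_count(self) -> int:
        total = 0
        for seg in self.segments:
            for code in seg.bp_codes:
                tmpl = self.templates[code]
                total += len(tmpl.atom_names["A"]) + len(tmpl.atom_names["B"])
        return total


# ---------------------------------------------------------------------------
# building


def _default_sequence(n: int) -> str:
    return ("AT" * (n // 2 + 1))[:n]


def build_duplex(
    trace: Trace,
    sequence: Optional[str] = None,
    twist_per_bp: float = DEFAULT_TWIST,
    templates: Optional[Dict[str, BasePairTemplate]] = None,
) -> AtomicModel:
    """Convert a coarse trace into an all-atom B-DNA model.

    ``sequence`` is the strand-A sequence over the whole trace in point
    order (defaults to an AT alternation); each entry strand of the trace
    becomes one duplex segment with two antiparallel chains.
    """
    templates = templates or load_templates()
    n = len(trace)
    if n == 0:
        raise ValueError("trace is empty")
    if sequence is None:
        sequence = _default_sequence(n)
    sequence = sequence.upper()
    if len(sequence) != n:
        raise ValueError(
            f"sequence length {len(sequence)} does not match trace point count {n}"
        )
    bad = set(sequence) - set("ACGT")
    if bad:
        raise ValueError(f"sequence contains non-ACGT symbols: {sorted(bad)}")

    segments = []
    offset = 0
    for k in range(trace.n_strands):
        pts = trace.strand(k)
        seq_k = sequence[offset : offset + len(pts)]
        offset += len(pts)
        frames = parallel_transport_frames(pts, twist_per_bp)
        chain_a, chain_b = chain_id_pair(k)
        segments.append(
            DuplexSegment(chain_a, chain_b, seq_k, tuple(seq_k), frames, pts.copy())
        )
    return AtomicModel(segments, twist_per_bp, templates)


# ---------------------------------------------------------------------------
# bond strain


@dataclass(frozen=True)
class StrainReport:
    """Inter-residue O3'-P distances and their deviation from reference."""

    table: pd.DataFrame
    n_skipped: int

    @property
    def max_abs_deviation(self) -> float:
        return float(self.table["deviation"].abs().max()) if len(self.table) else float("nan")

    @property
    def mean_abs_deviation(self) -> float:
        return float(self.table["deviation"].abs().mean()) if len(self.table) else float("nan")


def straight_bond_reference(
    tmpl_5p: BasePairTemplate,
    tmpl_3p: BasePairTemplate,
    strand: str,
    rise: float = DEFAULT_RISE,
    twist_per_bp: float = DEFAULT_TWIST,
) -> float:
    """O3'-P distance the two templates produce in an ideal straight helix.

    The 3' pair is the 5' pair's frame advanced by ``rise`` along z and
    ``twist_per_bp`` about z.  Chain A bonds O3'(5' bp) -> P(3' bp); chain B
    runs antiparallel, bonding O3'(3' bp) -> P(5' bp).
    """
    a = math.radians(twist_per_bp)
    rot = np.array([[math.cos(a), -math.sin(a), 0], [math.sin(a), math.cos(a), 0], [0, 0, 1.0]])
    shift = np.array([0.0, 0.0, rise])
    if strand == "A":
        o3 = tmpl_5p.atom("A", "O3'")
        p = rot @ tmpl_3p.atom("A", "P") + shift
    else:
        o3 = rot @ tmpl_3p.atom("B", "O3'") + shift
        p = tmpl_5p.atom("B", "P")
    return float(np.linalg.norm(p - o3))


def bond_strain_report(
    model: AtomicModel,
    reference_length: Optional[float] = None,
    rise: float = DEFAULT_RISE,
) -> StrainReport:
    """Tabulate every inter-residue O3'-P distance against its reference.

    With ``reference_length`` unset, each bond is compared to the value the
    same two templates give in an ideal straight helix (rise ``rise``, the
    model's twist) -- the template's own strain-free value; a rigid model on
    a straight trace therefore reports zero deviation, while bent traces
    show compression (negative) inside the curve and extension (positive)
    outside.  Bonds with missing backbone atoms are skipped and counted.
    """
    rows = []
    skipped = 0
    for s, seg in enumerate(model.segments):
        if seg.n_bp < 2:
            continue
        for i in range(seg.n_bp - 1):
            t5 = model.templates[seg.bp_codes[i]]
            t3 = model.templates[seg.bp_codes[i + 1]]
            for strand in ("A", "B"):
                chain = seg.chain_a if strand == "A" else seg.chain_b
                try:
                    if strand == "A":
                        names5, _, coords5 = model.bp_atoms(s, i, "A")
                        names3, _, coords3 = model.bp_atoms(s, i + 1, "A")
                        o3 = coords5[names5.index("O3'")]
                        p = coords3[names3.index("P")]
                        res_5p, res_3p = i + 1, i + 2
                    else:
                        names3, _, coords3 = model.bp_atoms(s, i + 1, "B")
                        names5, _, coords5 = model.bp_atoms(s, i, "B")
                        o3 = coords3[names3.index("O3'")]
                        p = coords5[names5.index("P")]
                        res_5p, res_3p = seg.n_bp - (i + 1), seg.n_bp - i
                except ValueError:
                    skipped += 1
                    continue
                length = float(np.linalg.norm(p - o3))
                ref = (
                    reference_length
                    if reference_length is not None
                    else straight_bond_reference(t5, t3, strand, rise, model.twist_per_bp)
                )
                rows.append(
                    {
                        "segment": s,
                        "chain": chain,
                        "res_5p": res_5p,
                        "res_3p": res_3p,
                        "bond": "O3'-P",
                        "length": length,
                        "reference": ref,
                        "deviation": length - ref,
                        "midpoint_x": (p[0] + o3[0]) / 2,
                        "midpoint_y": (p[1] + o3[1]) / 2,
                        "midpoint_z": (p[2] + o3[2]) / 2,
                    }
                )
    columns = [
        "segment", "chain", "res_5p", "res_3p", "bond",
        "length", "reference", "deviation", "midpoint_x", "midpoint_y", "midpoint_z",
    ]
    return StrainReport(pd.DataFrame(rows, columns=columns), skipped)


# ---------------------------------------------------------------------------
# structure output


def _trace_to_atom_array(trace: Trace):
    import biotite.structure as struc

    n = len(trace)
    array = struc.AtomArray(n)
    array.coord = np.asarray(trace.points, dtype=np.float32) * 10.0  # nm -> A
    res_ids = np.zeros(n, dtype=int)
    chains = np.empty(n, dtype="U4")
    for k in range(trace.n_strands):
        mask = trace.entry_index == k
        res_ids[mask] = np.arange(1, int(mask.sum()) + 1)
        chains[mask] = chain_id_pair(k)[0]
    array.chain_id = chains
    array.res_id = res_ids
    array.res_name = np.full(n, "MG")
    array.atom_name = np.full(n, "MG")
    array.element = np.full(n, "MG")
    array.hetero = np.full(n, True)
    array.set_annotation("occupancy", np.ones(n, dtype=float))
    array.set_annotation("b_factor", np.zeros(n, dtype=float))
    return array


def _model_to_atom_array(model: AtomicModel):
    import biotite.structure as struc

    records = list(model.atom_records())
    array = struc.AtomArray(len(records))
    array.coord = np.array([r[5] for r in records], dtype=np.float32) * 10.0
    array.chain_id = np.array([r[0] for r in records])
    array.res_id = np.array([r[1] for r in records])
    array.res_name = np.array([r[2] for r in records])
    array.atom_name = np.array([r[3] for r in records])
    array.element = np.array([r[4] for r in records])
    array.hetero = np.full(len(records), False)
    array.set_annotation("occupancy", np.ones(len(records), dtype=float))
    array.set_annotation("b_factor", np.zeros(len(records), dtype=float))
    return array


def write_structure(model_or_trace, path, format: Optional[str] = None) -> None:
    """Write a trace (as MG pseudoatoms) or an all-atom model to PDB/mmCIF.

    ``format`` defaults from the file extension (.pdb / .cif / .mmcif).
    PDB output refuses more than 99,999 atoms; use mmCIF for large models.
    """
    path = str(path)
    if format is None:
        lower = path.lower()
        if lower.endswith(".pdb"):
            format = "pdb"
        elif lower.endswith((".cif", ".mmcif")):
            format = "mmcif"
        else:
            raise StructureWriteError(
                f"cannot infer format from {path!r}; pass format='pdb' or 'mmcif'"
            )
    if format not in ("pdb", "mmcif"):
        raise StructureWriteError(f"format must be 'pdb' or 'mmcif', got {format!r}")

    if isinstance(model_or_trace, Trace):
        array = _trace_to_atom_array(model_or_trace)
    elif isinstance(model_or_trace, AtomicModel):
        array = _model_to_atom_array(model_or_trace)
    else:
        raise TypeError(f"expected Trace or AtomicModel, got {type(model_or_trace)}")

    if format == "pdb":
        if array.array_length() > _PDB_MAX_ATOMS:
            raise StructureWriteError(
                f"{array.array_length()} atoms exceed the PDB limit of {_PDB_MAX_ATOMS}; "
                "write mmCIF instead"
            )
        import biotite.structure.io.pdb as pdb

        pdb_file = pdb.PDBFile()
        pdb_file.set_structure(array)
        pdb_file.write(path)
    else:
        import biotite.structure.io.pdbx as pdbx

        cif = pdbx.CIFFile()
        pdbx.set_structure(cif, array, data_block="spooltrace")
        cif.write(path)
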