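import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from spooltrace.atomistic import (
    AtomicModel,
    StructureWriteError,
    bond_strain_report,
    build_duplex,
    chain_id_pair,
    load_templates,
    parallel_transport_frames,
    write_structure,
)
from spooltrace.spiral import SpiralSpec, Trace, make_cylindrical_trace


def straight_trace(n=21, rise=0.34):
    pts = np.zeros((n, 3))
    pts[:, 2] = rise * np.arange(n)
    return _as_trace(pts)


def circular_trace(radius=5.0, rise=0.34):
    n = int(2 * math.pi * radius / rise)
    ang = 2 * math.pi * np.arange(n) / n
    pts = np.stack([radius * np.cos(ang), radius * np.sin(ang), np.zeros(n)], axis=1)
    return _as_trace(pts)


def _as_trace(pts, entry=None):
    spec = SpiralSpec(geometry="cylindrical", r=1.0, p=1.0, h=1.0)
    entry = np.zeros(len(pts), dtype=int) if entry is None else entry
    return Trace(pts, entry, spec)


def oracle_frames(points, twist_deg):
    """Independent rigid-placement oracle: sequential minimal-rotation
    transport implemented with scipy Rotation instead of Rodrigues."""
    pts = np.asarray(points, float)
    n = len(pts)
    tangents = np.empty_like(pts)
    tangents[0] = pts[1] - pts[0]
    tangents[-1] = pts[-1] - pts[-2]
    if n > 2:
        tangents[1:-1] = pts[2:] - pts[:-2]
    tangents /= np.linalg.norm(tangents, axis=1)[:, None]
    seed = np.eye(3)[int(np.argmin(np.abs(tangents[0])))]
    normal = seed - seed @ tangents[0] * tangents[0]
    normal /= np.linalg.norm(normal)
    frames = []
    for i in range(n):
        if i > 0:
            a, b = tangents[i - 1], tangents[i]
            w = np.cross(a, b)
            s = np.linalg.norm(w)
            if s > 1e-12:
                angle = math.atan2(s, float(a @ b))
                normal = Rotation.from_rotvec(w / s * angle).apply(normal)
            normal -= normal @ tangents[i] * tangents[i]
            normal /= np.linalg.norm(normal)
        y = Rotation.from_rotvec(tangents[i] * math.radians(twist_deg) * i).apply(normal)
        z = tangents[i]
        frames.append(np.stack([np.cross(y, z), y, z], axis=1))
    return frames


class TestTemplates:
    def test_all_four_pairs_present(self):
        templates = load_templates()
        assert set(templates) == set("ACGT")

    def test_c1c1_template_constant(self):
        templates = load_templates()
        values = [t.c1c1_distance for t in templates.values()]
        np.testing.assert_allclose(values, values[0], atol=1e-9)
        assert values[0] == pytest.approx(1.07, abs=0.02)  # nm

    def test_standard_residue_names(self):
        templates = load_templates()
        assert templates["A"].res_names == {"A": "DA", "B": "DT"}
        assert templates["G"].res_names == {"A": "DG", "B": "DC"}

    def test_full_heavy_atom_sets(self):
        backbone = {"P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "C1'"}
        for tmpl in load_templates().values():
            for strand in ("A", "B"):
                names = set(tmpl.atom_names[strand])
                assert backbone <= names
                assert not any(e == "H" for e in tmpl.elements[strand])


class TestBuildDuplex:
    def test_straight_helix_canonical_bdna(self):
        model = build_duplex(straight_trace(n=21), twist_per_bp=36.0)
        centers = model.bp_centers()
        rise = np.diff(centers[:, 2])
        np.testing.assert_allclose(rise, 0.34, atol=1e-9)
        # helical repeat: bp 11 superimposes on bp 1 translated 3.4 nm
        _, _, bp1 = model.bp_atoms(0, 0, "A")
        _, _, bp11 = model.bp_atoms(0, 10, "A")
        np.testing.assert_allclose(bp11, bp1 + [0.0, 0.0, 3.4], atol=1e-6)

    def test_bp_centers_coincide_with_trace(self):
        trace = make_cylindrical_trace(
            SpiralSpec(geometry="cylindrical", r=8.0, p=10.0, h=4.0)
        )
        model = build_duplex(trace)
        np.testing.assert_allclose(model.bp_centers(), trace.points, atol=1e-6)

    def test_sequence_assignment_and_complement(self):
        model = build_duplex(straight_trace(4), sequence="ACGT")
        seg = model.segments[0]
        assert seg.sequence == "ACGT"
        records = list(model.atom_records())
        chain_a = {r[1]: r[2] for r in records if r[0] == seg.chain_a}
        chain_b = {r[1]: r[2] for r in records if r[0] == seg.chain_b}
        assert [chain_a[i] for i in range(1, 5)] == ["DA", "DC", "DG", "DT"]
        # chain B res 1 pairs trace point 4 (T) -> complement A
        assert [chain_b[i] for i in range(1, 5)] == ["DA", "DC", "DG", "DT"]

    def test_sequence_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            build_duplex(straight_trace(5), sequence="ACGT")

    def test_bad_symbols_rejected(self):
        with pytest.raises(ValueError, match="non-ACGT"):
            build_duplex(straight_trace(4), sequence="ACGU")

    def test_coincident_points_rejected(self):
        pts = np.zeros((3, 3))
        pts[1] = [0, 0, 0.34]
        pts[2] = [0, 0, 0.34]
        with pytest.raises(ValueError, match="coincident"):
            build_duplex(_as_trace(pts))

    def test_circular_inner_outer_pp_asymmetry(self):
        radius = 5.0
        model = build_duplex(circular_trace(radius))
        oracle = oracle_frames(circular_trace(radius).points, 36.0)
        # implementation frames match the independent oracle
        for frame, expected in zip(model.segments[0].frames, oracle):
            np.testing.assert_allclose(frame, expected, atol=1e-6)
        # intra-strand P-P distances: shorter inside the circle than outside
        seg = model.segments[0]
        p_coords = []
        for i in range(seg.n_bp):
            names, _, coords = model.bp_atoms(0, i, "A")
            p_coords.append(coords[names.index("P")])
        p_coords = np.array(p_coords)
        d = np.linalg.norm(np.diff(p_coords, axis=0), axis=1)
        mid_r = np.hypot(*(0.5 * (p_coords[1:, :2] + p_coords[:-1, :2])).T)
        assert d[mid_r < radius].mean() < d[mid_r > radius].mean()

    def test_rigid_transform_equivariance(self):
        trace = straight_trace(11)
        rot = Rotation.from_euler("zyx", [30, 40, 50], degrees=True).as_matrix()
        shift = np.array([1.0, -2.0, 3.0])
        moved = trace.transformed(rotation=rot, translation=shift)
        m1 = build_duplex(trace)
        m2 = build_duplex(moved)
        # same construction in the transformed frame: centers map exactly
        np.testing.assert_allclose(m2.bp_centers(), m1.bp_centers() @ rot.T + shift, atol=1e-9)

    def test_twist_accumulation_on_straight_trace(self):
        twist = 34.3
        model = build_duplex(straight_trace(15), twist_per_bp=twist)
        frames = model.segments[0].frames
        for i in range(len(frames) - 1):
            y0, y1 = frames[i][:, 1], frames[i + 1][:, 1]
            z = frames[i][:, 2]
            ang = math.degrees(math.atan2(float(np.cross(y0, y1) @ z), float(y0 @ y1)))
            assert ang == pytest.approx(twist, abs=1e-6)

    def test_c1c1_constant_in_built_model(self):
        model = build_duplex(circular_trace(4.0), twist_per_bp=36.0)
        ref = load_templates()["A"].c1c1_distance
        for i in range(0, model.segments[0].n_bp, 7):
            na, _, ca = model.bp_atoms(0, i, "A")
            nb, _, cb = model.bp_atoms(0, i, "B")
            d = np.linalg.norm(ca[na.index("C1'")] - cb[nb.index("C1'")])
            assert d == pytest.approx(ref, abs=1e-9)

    def test_multi_entry_trace_gives_segments(self):
        pts = np.concatenate([straight_trace(6).points,
                              straight_trace(6).points + [3.0, 0.0, 0.0]])
        entry = np.repeat([0, 1], 6)
        model = build_duplex(_as_trace(pts, entry))
        assert len(model.segments) == 2
        assert model.segments[0].chain_a == "A"
        assert model.segments[1].chain_a == "C"

    def test_default_sequence_is_at_alternation(self):
        model = build_duplex(straight_trace(5))
        assert model.segments[0].sequence == "ATATA"


class TestStrainReport:
    def test_straight_helix_strain_free(self):
        model = build_duplex(straight_trace(21))
        report = bond_strain_report(model)
        assert len(report.table) == 40  # 20 steps x 2 strands
        assert report.max_abs_deviation < 1e-6

    def test_heterogeneous_sequence_straight_still_strain_free(self):
        model = build_duplex(straight_trace(12), sequence="ACGTTGCAACGT")
        report = bond_strain_report(model)
        assert report.max_abs_deviation < 1e-6

    def test_circular_signs_inner_negative_outer_positive(self):
        radius = 5.0
        model = build_duplex(circular_trace(radius))
        report = bond_strain_report(model)
        table = report.table
        mid_r = np.hypot(table.midpoint_x, table.midpoint_y)
        inner = table.deviation[mid_r < radius]
        outer = table.deviation[mid_r > radius]
        assert inner.mean() < 0 < outer.mean()
        assert (inner < 0).mean() > 0.9
        assert (outer > 0).mean() > 0.9

    def test_single_bp_empty_table(self):
        model = build_duplex(_as_trace(np.array([[0, 0, 0.0], [0, 0, 0.34]])))
        seg = model.segments[0]  # truncate to a single base pair
        seg.bp_codes, seg.frames, seg.centers = seg.bp_codes[:1], seg.frames[:1], seg.centers[:1]
        report = bond_strain_report(model)
        assert len(report.table) == 0

    def test_explicit_reference_length(self):
        model = build_duplex(straight_trace(5))
        report = bond_strain_report(model, reference_length=0.16)
        assert np.allclose(report.table.reference, 0.16)


class TestWriteStructure:
    def test_trace_mg_count(self, tmp_path):
        trace = straight_trace(17)
        path = tmp_path / "trace.pdb"
        write_structure(trace, path)
        text = path.read_text()
        assert text.count("MG") >= 17
        assert sum(1 for line in text.splitlines() if line.startswith("HETATM")) == 17

    def test_pdb_round_trip_precision(self, tmp_path):
        from Bio.PDB import PDBParser

        model = build_duplex(straight_trace(6))
        path = tmp_path / "m.pdb"
        write_structure(model, path)
        structure = PDBParser(QUIET=True).get_structure("m", path)
        got = np.array([a.coord for a in structure.get_atoms()])
        want = np.array([r[5] for r in model.atom_records()]) * 10.0
        assert len(got) == len(want)
        np.testing.assert_allclose(got, want, atol=1.1e-3)  # PDB fixed width

    def test_mmcif_independent_parser_hierarchy(self, tmp_path):
        from Bio.PDB import MMCIFParser

        model = build_duplex(straight_trace(8), sequence="ACGTACGT")
        path = tmp_path / "m.cif"
        write_structure(model, path)
        structure = MMCIFParser(QUIET=True).get_structure("m", path)
        chains = {chain.id: [res.get_resname() for res in chain] for chain in structure[0]}
        assert set(chains) == {"A", "B"}
        assert chains["A"] == ["DA", "DC", "DG", "DT", "DA", "DC", "DG", "DT"]
        assert len(chains["B"]) == 8

    def test_mmcif_round_trip_precision(self, tmp_path):
        import biotite.structure.io.pdbx as pdbx

        model = build_duplex(straight_trace(6))
        path = tmp_path / "m.cif"
        write_structure(model, path)
        arr = pdbx.get_structure(pdbx.CIFFile.read(str(path)), model=1)
        want = np.array([r[5] for r in model.atom_records()], dtype=np.float32) * 10.0
        np.testing.assert_allclose(arr.coord, want, atol=1e-4)

    def test_pdb_overflow_suggests_mmcif(self, tmp_path):
        trace = straight_trace(3000)  # 3000 bp -> ~120k atoms
        model = build_duplex(trace)
        with pytest.raises(StructureWriteError, match="mmCIF"):
            write_structure(model, tmp_path / "big.pdb")

    def test_unknown_extension(self, tmp_path):
        with pytest.raises(StructureWriteError, match="format"):
            write_structure(straight_trace(3), tmp_path / "x.xyz")

    def test_chain_id_sequence(self):
        assert chain_id_pair(0) == ("A", "B")
        assert chain_id_pair(1) == ("C", "D")
        assert chain_id_pair(13) == ("AA", "AB")
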