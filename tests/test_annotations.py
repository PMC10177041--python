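import numpy as np
import pytest
from lxml import etree

from wtseg.annotations import (
    AnnotationSet,
    CaseRecord,
    PolygonAnnotation,
    rasterize,
    read_annotations,
    split_by_case,
    write_annotations,
)
from wtseg.taxonomy import UNANNOTATED


def point_in_polygon(x, y, verts):
    """Crossing-number test, independent of shapely."""
    inside = False
    n = len(verts)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            xcross = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xcross:
                inside = not inside
    return inside


def make_set(polys, spacing=1.0):
    anns = [
        PolygonAnnotation("c0", cls, verts, i)
        for i, (cls, verts) in enumerate(polys)
    ]
    return AnnotationSet(anns, [CaseRecord("c0", spacing=spacing)])


class TestXmlRoundTrip:
    def test_write_then_read_is_identity(self, taxonomy, tmp_path):
        rng = np.random.default_rng(3)
        polys = []
        for cls in (0, 4, 14):
            cx, cy = rng.uniform(20, 80, 2)
            ang = np.sort(rng.uniform(0, 2 * np.pi, 6))
            verts = [
                (cx + 10 * np.cos(a), cy + 10 * np.sin(a)) for a in ang
            ]
            polys.append((cls, verts))
        annset = make_set(polys)
        path = tmp_path / "c0.xml"
        write_annotations(path, annset.annotations, taxonomy)
        back = read_annotations(path, taxonomy)
        assert len(back.annotations) == len(annset.annotations)
        for a, b in zip(annset.annotations, back.annotations):
            assert a.class_id == b.class_id
            assert a.annotation_id == b.annotation_id
            assert a.vertices == b.vertices  # exact float round trip

    def test_excluded_classes_dropped(self, taxonomy, tmp_path):
        root = etree.Element("ASAP_Annotations")
        anns = etree.SubElement(root, "Annotations")
        tri = [(0, 0), (10, 0), (0, 10)]
        for i, name in enumerate(["Blastema", "Stroma", "Anaplasia"]):
            el = etree.SubElement(
                anns, "Annotation", Name=f"Annotation {i}", PartOfGroup=name
            )
            coords = etree.SubElement(el, "Coordinates")
            for j, (x, y) in enumerate(tri):
                etree.SubElement(
                    coords, "Coordinate", Order=str(j), X=str(x), Y=str(y)
                )
        path = tmp_path / "mix.xml"
        etree.ElementTree(root).write(str(path))
        out = read_annotations(path, taxonomy)
        assert len(out.annotations) == 2

    def test_empty_annotation_list_ok(self, taxonomy, tmp_path):
        path = tmp_path / "empty.xml"
        write_annotations(path, [], taxonomy)
        assert read_annotations(path, taxonomy).annotations == []

    def test_unknown_class_errors_with_name(self, taxonomy, tmp_path):
        root = etree.Element("ASAP_Annotations")
        anns = etree.SubElement(root, "Annotations")
        el = etree.SubElement(anns, "Annotation", PartOfGroup="Osteoid")
        coords = etree.SubElement(el, "Coordinates")
        for j, (x, y) in enumerate([(0, 0), (5, 0), (0, 5)]):
            etree.SubElement(coords, "Coordinate", Order=str(j), X=str(x), Y=str(y))
        path = tmp_path / "bad.xml"
        etree.ElementTree(root).write(str(path))
        with pytest.raises(ValueError, match="Osteoid"):
            read_annotations(path, taxonomy)

    def test_malformed_xml_errors(self, taxonomy, tmp_path):
        path = tmp_path / "broken.xml"
        path.write_text("<ASAP_Annotations><unclosed>")
        with pytest.raises(ValueError, match="malformed"):
            read_annotations(path, taxonomy)


class TestRasterize:
    def test_axis_aligned_square_covers_exact_block(self):
        annset = make_set(
            [(3, [(10.0, 10.0), (20.0, 10.0), (20.0, 20.0), (10.0, 20.0)])]
        )
        labels = rasterize(annset, "c0", (32, 32))
        assert (labels == 3).sum() == 100
        assert (labels[10:20, 10:20] == 3).all()

    def test_overlap_resolved_by_last_drawn(self):
        sq1 = [(5.0, 5.0), (15.0, 5.0), (15.0, 15.0), (5.0, 15.0)]
        sq2 = [(10.0, 10.0), (20.0, 10.0), (20.0, 20.0), (10.0, 20.0)]
        annset = make_set([(1, sq1), (2, sq2)])
        labels = rasterize(annset, "c0", (32, 32))
        assert (labels[10:15, 10:15] == 2).all()  # overlap -> id 2's class
        assert (labels[5:10, 5:10] == 1).all()

    def test_matches_point_in_polygon_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            cx, cy = rng.uniform(5, 20, 2)
            ang = np.sort(rng.uniform(0, 2 * np.pi, 7))
            radius = rng.uniform(3, 9)
            verts = [
                (cx + radius * np.cos(a), cy + radius * np.sin(a)) for a in ang
            ]
            annset = make_set([(5, verts)])
            labels = rasterize(annset, "c0", (26, 26))
            for r in range(26):
                for c in range(26):
                    expect = point_in_polygon(c + 0.5, r + 0.5, verts)
                    assert (labels[r, c] == 5) == expect

    def test_resolution_consistency(self):
        verts = [(8.1, 8.3), (24.2, 9.1), (22.7, 25.4), (7.9, 23.8)]
        annset = make_set([(2, verts)], spacing=0.25)
        fine = rasterize(annset, "c0", (32, 32), spacing=0.25)
        coarse = rasterize(annset, "c0", (16, 16), spacing=0.5)
        # block-reduce the fine mask: interior 2x2 blocks fully inside the
        # polygon must map to labeled coarse pixels
        blocks = (fine == 2).reshape(16, 2, 16, 2).all(axis=(1, 3))
        assert (coarse[blocks] == 2).all()

    def test_unknown_case_errors(self):
        annset = make_set([(0, [(0, 0), (5, 0), (0, 5)])])
        with pytest.raises(KeyError):
            rasterize(annset, "nope", (8, 8))


def synthetic_annset(rng, n_cases, max_ann=12):
    cases = [CaseRecord(f"c{i:02d}") for i in range(n_cases)]
    anns = []
    k = 0
    tri = [(0.0, 0.0), (5.0, 0.0), (0.0, 5.0)]
    for c in cases:
        for _ in range(int(rng.integers(1, max_ann + 1))):
            anns.append(PolygonAnnotation(c.case_id, int(rng.integers(15)), tri, k))
            k += 1
    return AnnotationSet(anns, cases)


class TestSplitByCase:
    def test_every_case_in_exactly_one_partition(self):
        annset = synthetic_annset(np.random.default_rng(0), 20)
        split = split_by_case(annset, (0.7, 0.15, 0.15), seed=1)
        assert sorted(split.assignment) == sorted(c.case_id for c in annset.cases)
        partitions = {a.case_id: split.assignment[a.case_id]
                      for a in annset.annotations}
        # case exclusivity: a case id maps to one partition by construction
        assert set(split.assignment.values()) == {"train", "validation", "test"}
        assert len(partitions) == 20

    def test_three_cases_one_per_partition(self):
        annset = synthetic_annset(np.random.default_rng(1), 3)
        split = split_by_case(annset, (0.7, 0.15, 0.15), seed=0)
        assert sorted(split.assignment.values()) == ["test", "train", "validation"]

    def test_fewer_cases_than_partitions_errors(self):
        annset = synthetic_annset(np.random.default_rng(2), 2)
        with pytest.raises(ValueError):
            split_by_case(annset, seed=0)

    def test_equal_annotation_cohort_hits_fractions_within_one_case(self):
        cases = [CaseRecord(f"c{i:03d}") for i in range(100)]
        tri = [(0.0, 0.0), (5.0, 0.0), (0.0, 5.0)]
        anns = [
            PolygonAnnotation(c.case_id, 0, tri, i * 4 + j)
            for i, c in enumerate(cases)
            for j in range(4)
        ]
        annset = AnnotationSet(anns, cases)
        split = split_by_case(annset, (0.7, 0.15, 0.15), seed=3)
        counts = {p: 0 for p in ("train", "validation", "test")}
        for a in anns:
            counts[split.assignment[a.case_id]] += 1
        total = len(anns)
        case_worth = 4 / total
        for p, f in zip(("train", "validation", "test"), (0.7, 0.15, 0.15)):
            assert abs(counts[p] / total - f) <= case_worth + 1e-12

    def test_invariant_to_annotation_order(self):
        rng = np.random.default_rng(5)
        annset = synthetic_annset(rng, 15)
        shuffled = AnnotationSet(
            [annset.annotations[i] for i in rng.permutation(len(annset.annotations))],
            list(reversed(annset.cases)),
        )
        s1 = split_by_case(annset, seed=9)
        s2 = split_by_case(shuffled, seed=9)
        assert s1.assignment == s2.assignment

    def test_deterministic_given_seed(self):
        annset = synthetic_annset(np.random.default_rng(6), 12)
        assert (
            split_by_case(annset, seed=4).assignment
            == split_by_case(annset, seed=4).assignment
        )
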