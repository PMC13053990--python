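"""SLiM scanning, mutagenesis, and motif→domain partner inference."""

import numpy as np
import pytest

from mipepkit import (
    DomainAnnotation,
    MotifClass,
    MotifMatch,
    SeqEntry,
    generate_sequences,
    infer_partners,
    mutate_motif,
    overlap_predicted_experimental,
    read_motif_library,
    scan_motifs,
    toy_motif_library,
    write_motif_library,
)
from mipepkit.motifs import MotifLibraryError


class TestScanMotifs:
    def test_planted_motif_reported_at_its_coordinates(self):
        records, _ = generate_sequences(1, 71, [("REKSIL", 21)], seed=1)
        lib = [m for m in toy_motif_library() if m.class_id == "MOD_PLK_TOY"]
        matches = scan_motifs(records[0], lib)
        assert [(m.start, m.end, m.matched) for m in matches] == [(21, 26, "REKSIL")]

    def test_empty_library_and_empty_sequence(self):
        assert scan_motifs(SeqEntry("s", "ACDEF"), []) == []
        assert scan_motifs(SeqEntry("s", ""), toy_motif_library()) == []

    def test_overlapping_matches_all_reported(self):
        lib = [MotifClass("AA2", "AA")]
        matches = scan_motifs(SeqEntry("s", "AAA"), lib)
        assert [(m.start, m.end) for m in matches] == [(1, 2), (2, 3)]

    def test_matches_exhaustive_enumeration_on_random_sequences(self):
        """Every (position, class) hit found by direct per-position regex
        matching is reported, and nothing else."""
        import re

        lib = toy_motif_library()
        records, _ = generate_sequences(5, 120, seed=33)
        for rec in records:
            reported = {
                (m.class_id, m.start, m.end) for m in scan_motifs(rec, lib)
            }
            expected = set()
            for cls in lib:
                rx = re.compile(cls.pattern)
                for pos in range(len(rec.seq)):
                    m = rx.match(rec.seq, pos)
                    if m and m.end() > pos and not cls.requires_disorder:
                        expected.add((cls.class_id, pos + 1, m.end()))
            assert reported == expected

    def test_disorder_flag_and_requirement(self):
        lib = [
            MotifClass("FREE", "KK", requires_disorder=False),
            MotifClass("DISONLY", "KK", requires_disorder=True),
        ]
        seq = SeqEntry("s", "KKAAAKK")
        matches = scan_motifs(seq, lib, disorder_regions=[(5, 7)])
        by_class: dict[str, list] = {}
        for m in matches:
            by_class.setdefault(m.class_id, []).append((m.start, m.end, m.in_disorder))
        assert by_class["FREE"] == [(1, 2, False), (6, 7, True)]
        assert by_class["DISONLY"] == [(6, 7, True)]

    def test_invalid_pattern_rejected_at_load(self):
        with pytest.raises(MotifLibraryError):
            MotifClass("BAD", "[A-")

    def test_duplicate_class_ids_rejected(self):
        lib = [MotifClass("X", "AA"), MotifClass("X", "CC")]
        with pytest.raises(MotifLibraryError):
            scan_motifs(SeqEntry("s", "AACC"), lib)


class TestMutateMotif:
    def _record_and_match(self):
        records, _ = generate_sequences(1, 71, [("REKSIL", 21)], seed=1)
        lib = [m for m in toy_motif_library() if m.class_id == "MOD_PLK_TOY"]
        (match,) = scan_motifs(records[0], lib)
        return records[0], match, lib

    def test_span_replaced_by_alanine_stretch(self):
        rec, match, _ = self._record_and_match()
        mutated = mutate_motif(rec, match)
        assert mutated.seq[20:26] == "AAAAAA"
        assert len(mutated.seq) == len(rec.seq)
        assert mutated.seq[:20] == rec.seq[:20] and mutated.seq[26:] == rec.seq[26:]

    def test_rescan_after_mutation_finds_no_overlapping_match(self):
        rec, match, lib = self._record_and_match()
        mutated = mutate_motif(rec, match)
        rescan = scan_motifs(mutated, lib)
        assert not any(m.start <= match.end and m.end >= match.start for m in rescan)

    def test_idempotent_on_alanine_run(self):
        rec = SeqEntry("s", "CCAAAACC")
        match = MotifMatch("s", "X", 3, 6, "AAAA", False)
        assert mutate_motif(rec, match).seq == rec.seq

    def test_wrong_sequence_or_bounds_rejected(self):
        rec, match, _ = self._record_and_match()
        with pytest.raises(ValueError):
            mutate_motif(SeqEntry("other", rec.seq), match)
        bad = MotifMatch(rec.id, "X", 70, 75, "AAAAAA", False)
        with pytest.raises(ValueError):
            mutate_motif(rec, bad)


class TestInferPartners:
    def test_no_matches_no_predictions(self):
        assert infer_partners([], toy_motif_library(), []) == {}

    def test_domain_carriers_predicted(self):
        lib = [MotifClass("M1", "AA", partner_domain_ids=["D1"])]
        match = MotifMatch("seq", "M1", 1, 2, "AA", False)
        annotations = [
            DomainAnnotation(f"P{i}", frozenset({"D1"} if i < 3 else {"D9"}))
            for i in range(10)
        ]
        predictions = infer_partners([match], lib, annotations)
        assert set(predictions) == {"P0", "P1", "P2"}
        assert all(pairs == {("M1", "D1")} for pairs in predictions.values())

    def test_two_template_domains_one_prediction_two_pairs(self):
        lib = [MotifClass("M1", "AA", partner_domain_ids=["D1", "D2"])]
        match = MotifMatch("seq", "M1", 1, 2, "AA", False)
        ann = [DomainAnnotation("P1", frozenset({"D1", "D2"}))]
        predictions = infer_partners([match], lib, ann)
        assert predictions == {"P1": {("M1", "D1"), ("M1", "D2")}}

    def test_unknown_class_id_rejected(self):
        match = MotifMatch("seq", "NOPE", 1, 2, "AA", False)
        with pytest.raises(MotifLibraryError):
            infer_partners([match], toy_motif_library(), [])

    def test_taxon_validated_filter(self):
        lib = toy_motif_library()
        match = MotifMatch("seq", "DOC_UNVALIDATED_TOY", 1, 4, "PPAY", False)
        ann = [DomainAnnotation("P1", frozenset({"PF00397"}))]
        assert infer_partners([match], lib, ann, taxon_validated_only=True) == {}
        assert "P1" in infer_partners([match], lib, ann)

    def test_matches_bruteforce_triple_loop(self):
        rng = np.random.default_rng(5)
        domains = [f"D{i}" for i in range(6)]
        for trial in range(30):
            lib = [
                MotifClass(
                    f"M{j}",
                    "AA",
                    partner_domain_ids=list(
                        rng.choice(domains, size=rng.integers(0, 4), replace=False)
                    ),
                )
                for j in range(3)
            ]
            matched = [
                MotifMatch("seq", f"M{j}", 1, 2, "AA", False)
                for j in range(3)
                if rng.random() < 0.7
            ]
            anns = [
                DomainAnnotation(
                    f"P{k}",
                    frozenset(rng.choice(domains, size=rng.integers(0, 4), replace=False)),
                )
                for k in range(8)
            ]
            expected: dict[str, set] = {}
            for m in matched:
                for cls in lib:
                    if cls.class_id != m.class_id:
                        continue
                    for ann in anns:
                        for dom in cls.partner_domain_ids:
                            if dom in ann.domain_ids:
                                expected.setdefault(ann.protein_id, set()).add(
                                    (cls.class_id, dom)
                                )
            assert infer_partners(matched, lib, anns) == expected


class TestOverlap:
    def test_intersection(self):
        assert overlap_predicted_experimental({"A", "B", "C"}, {"B", "C", "D"}) == ["B", "C"]

    def test_disjoint(self):
        assert overlap_predicted_experimental({"A"}, {"B"}) == []

    def test_identity_at_nineteen(self):
        ids = {f"K{i:02d}" for i in range(19)}
        assert overlap_predicted_experimental(ids, set(ids)) == sorted(ids)


class TestLibraryIO:
    def test_round_trip(self, tmp_path):
        lib = toy_motif_library()
        path = tmp_path / "lib.tsv"
        write_motif_library(lib, path)
        back = read_motif_library(path)
        assert [(m.class_id, m.pattern, m.requires_disorder, m.taxon_validated,
                 m.partner_domain_ids) for m in lib] == [
            (m.class_id, m.pattern, m.requires_disorder, m.taxon_validated,
             m.partner_domain_ids) for m in back
        ]
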