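"""Exact mapping, precursor excision, hairpin criteria and classification."""

import numpy as np
import pandas as pd
import pytest

from heatmir._util import revcomp, to_rna
from heatmir.discovery import (
    GenomeHit,
    HairpinCriteria,
    MiRNARecord,
    PrecursorCandidate,
    classify_known,
    evaluate_hairpin,
    evaluate_hairpin_structure,
    extract_precursor,
    group_families,
    map_exact,
    select_candidates,
    validate_novel,
)
from heatmir.fold import fold_rna
from heatmir.oracles import naive_scan

MATURE = "TGACAGAAGAGAGTGAGCACA"


class TestMapExact:
    def test_single_planted_hit(self, small_genome):
        chrom = next(iter(small_genome))
        genome = {chrom: small_genome[chrom][:500] + MATURE + small_genome[chrom][521:]}
        hits = map_exact([MATURE], genome)[MATURE]
        plus = [h for h in hits if h.strand == "+"]
        assert GenomeHit(chrom, 500, 521, "+") in plus

    def test_absent_tag_empty(self, small_genome):
        assert map_exact(["TTAGGGTTAGGGTTAGGGTTA"], small_genome)["TTAGGGTTAGGGTTAGGGTTA"] == []

    def test_multihit_matches_naive_scan(self, rng):
        """25 planted copies: the k-mer mapper returns exactly the naive
        full-scan hit list."""
        base = "".join("ACGT"[i] for i in rng.integers(0, 4, 12_000))
        tag = "GATTACAGATTACAGATTAGC"
        pieces, pos = [], 0
        for i in range(25):
            at = 100 + i * 450
            pieces.append(base[pos:at])
            pieces.append(tag if i % 3 else revcomp(tag))
            pos = at
        pieces.append(base[pos:])
        genome = {"chr1": "".join(pieces)}
        hits = map_exact([tag], genome)[tag]
        expected = naive_scan(tag, genome)
        assert [(h.chrom, h.start0, h.strand) for h in hits] == expected
        assert len(hits) >= 25

    def test_reverse_complement_symmetry(self, rng):
        """Mapping against the reverse-complemented genome swaps strands and
        mirrors coordinates."""
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 3000))
        seq = seq[:1000] + MATURE + seq[1000:]
        fwd = map_exact([MATURE], {"c": seq})[MATURE]
        rev = map_exact([MATURE], {"c": revcomp(seq)})[MATURE]
        n = len(seq)
        mirrored = sorted(
            (n - h.end0, n - h.start0, "-" if h.strand == "+" else "+") for h in fwd
        )
        assert mirrored == sorted((h.start0, h.end0, h.strand) for h in rev)


class TestSelectCandidates:
    def _tpm(self, tags, peaks):
        return pd.DataFrame({"lib": peaks}, index=tags)

    def test_rule_application(self):
        tag = "A" * 24
        tpm = self._tpm([tag], [15.0])
        hits = {tag: [GenomeHit("c", 0, 24, "+")] * 3}
        assert select_candidates(tpm, hits) == [tag]

    def test_too_many_hits_excluded(self):
        tag = "A" * 21
        tpm = self._tpm([tag], [1000.0])
        hits = {tag: [GenomeHit("c", i, i + 21, "+") for i in range(25)]}
        assert select_candidates(tpm, hits) == []

    def test_length_window_excludes_short(self):
        tag = "A" * 16
        tpm = self._tpm([tag], [1000.0])
        hits = {tag: [GenomeHit("c", 0, 16, "+")]}
        assert select_candidates(tpm, hits) == []

    def test_low_tpm_excluded(self):
        tag = "A" * 21
        tpm = self._tpm([tag], [9.9])
        hits = {tag: [GenomeHit("c", 0, 21, "+")]}
        assert select_candidates(tpm, hits) == []


class TestExtractPrecursor:
    def test_window_arithmetic(self):
        chroms = {"c": "A" * 1000}
        seq, ws, we, off = extract_precursor(GenomeHit("c", 500, 521, "+"), chroms)
        assert (ws, we) == (300, 721)
        assert len(seq) == 421
        assert off == 200

    def test_boundary_clip(self):
        chroms = {"c": "A" * 1000}
        seq, ws, we, off = extract_precursor(GenomeHit("c", 10, 31, "+"), chroms)
        assert (ws, we) == (0, 231)
        assert off == 10

    def test_minus_strand_reverse_complement(self, rng):
        raw = "".join("ACGT"[i] for i in rng.integers(0, 4, 1000))
        chroms = {"c": raw}
        seq, ws, we, off = extract_precursor(GenomeHit("c", 500, 521, "-"), chroms)
        assert seq == to_rna(revcomp(raw[300:721]))
        assert off == 200
        # the oriented mature slice is the reverse complement of the genomic one
        assert seq[off : off + 21] == to_rna(revcomp(raw[500:521]))


class TestHairpinCriteria:
    def test_ideal_stem_passes(self):
        # 22-bp perfectly complementary stem, 10-nt loop, mature = 5p arm
        arm = "GCGAUACGGUCAGCUAAGCGUA".replace("U", "T")
        precursor = arm + "AUAUAUAUAU".replace("U", "T") + revcomp(arm)
        db, _ = fold_rna(to_rna(precursor))
        verdict = evaluate_hairpin_structure(db, 0, 22)
        assert verdict.passed, verdict.reasons

    def test_mature_spanning_loop_fails(self):
        arm = "GCGATACGGTCAGCTAAGCGTA"
        precursor = arm + "ATATATATAT" + revcomp(arm)
        db, _ = fold_rna(to_rna(precursor))
        # mature placed across the terminal loop
        verdict = evaluate_hairpin_structure(db, 18, 21)
        assert not verdict.passed
        assert "mature_in_loop" in verdict.reasons

    def test_too_many_unpaired_mature_bases(self):
        # hand-built structure: 21-nt mature with 6 interior bases unpaired
        db = "((((((((......(((((((...)))))))......))))))))"
        #     mature = positions 0..20: 8 paired, 6 dots, then 7 paired
        verdict = evaluate_hairpin_structure(db, 0, 21)
        assert "too_many_mispairs" in verdict.reasons

    def test_asymmetric_bulge_detected(self):
        # 5' arm carries a 4-nt bulge with no counterpart on the 3' arm
        db = "(" * 8 + "...." + "(" * 8 + "...." + ")" * 16
        verdict = evaluate_hairpin_structure(db, 0, 20)
        assert "asymmetric_bulge" in verdict.reasons


class TestClassifyKnown:
    REF = {"sly-miR160a miR160": "TGCCTGGCTCCCTGTATGCCA",
           "sly-miR395a miR395": "CTGAAGTGTTTGGGGGAACTC"}

    def test_identity(self):
        name, family, mm = classify_known("TGCCTGGCTCCCTGTATGCCA", self.REF)
        assert (name, family, mm) == ("sly-miR160a", "miR160", 0)

    def test_two_substitutions_still_known(self):
        query = "CTGAAGTGTTTGGGGGAACTC"
        query = "A" + query[1:-1] + "G"  # 2 substitutions
        name, _, mm = classify_known(query, self.REF)
        assert name == "sly-miR395a" and mm == 2

    def test_three_substitutions_rejected(self):
        query = list("CTGAAGTGTTTGGGGGAACTC")
        for i in (2, 8, 14):
            query[i] = {"A": "C"}.get(query[i], "A")
        assert classify_known("".join(query), self.REF) is None

    def test_length_slide_counts_overhang(self):
        # 1-nt 3' extension: best alignment has 0 substitutions + 1 overhang
        name, _, mm = classify_known("TGCCTGGCTCCCTGTATGCCAA", self.REF)
        assert name == "sly-miR160a" and mm == 1

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            classify_known("TGCCTGGCTCCCTGTATGCCA", {})


def _planted_candidate(seed=13):
    from heatmir.simdata import plant_hairpin, simulate_genome

    genome, _ = simulate_genome(5000, 0.4, 7)
    genome, hp = plant_hairpin(genome, MATURE, 2000, "5p", seed=seed)
    window, ws, we, off = extract_precursor(
        GenomeHit("chr1", 2000 + hp.mature_offset, 2000 + hp.mature_offset + 21, "+"),
        {"chr1": genome},
    )
    db, mfe = fold_rna(window)
    return hp, PrecursorCandidate(
        hit=GenomeHit("chr1", 2000 + hp.mature_offset, 2000 + hp.mature_offset + 21, "+"),
        wstart0=ws, wend0=we, sequence=window, dotbracket=db, mfe=mfe,
        mature_offset=off, mature_len=21,
    )


class TestValidateNovel:
    def test_planted_hairpin_with_star_reads(self):
        hp, cand = _planted_candidate()
        verdict = validate_novel(cand, tag_sequences={hp.star_seq, hp.mature_seq})
        assert verdict.is_novel
        assert verdict.star_seq == hp.star_seq
        assert verdict.star_supported

    def test_unstable_precursor_rejected(self):
        _, cand = _planted_candidate()
        cand.mfe = -10.0
        verdict = validate_novel(cand, tag_sequences=set())
        assert not verdict.is_novel
        assert "mfe_above_threshold" in verdict.reasons

    def test_known_precedence_blocks_novel_path(self):
        """A sequence within 2 mismatches of the reference is classified
        known and never reaches the novel path."""
        hp, cand = _planted_candidate()
        query = "A" + MATURE[1:]  # 1 mismatch
        reference = {"sly-miRX miRX": MATURE}
        assert classify_known(query, reference) is not None
        # the discovery orchestration only calls validate_novel when
        # classify_known returns None; assert that contract directly
        assert classify_known(MATURE, reference)[2] == 0


def _rec(name, seq):
    return MiRNARecord(
        name=name, mature_seq=seq, status="novel", family=None,
        mismatches_to_ref=None, precursor=None,
    )


class TestGroupFamilies:
    def test_identical_matures_grouped(self):
        a, b = _rec("pc-1", MATURE), _rec("pc-2", MATURE)
        groups = group_families([a, b])
        assert len(groups) == 1
        assert a.family == b.family == "fam-01"

    def test_two_mismatches_within_threshold(self):
        variant = "AC" + MATURE[2:]
        a, b = _rec("pc-1", MATURE), _rec("pc-2", variant)
        groups = group_families([a, b], max_mismatch=3)
        assert len(groups) == 1

    def test_distant_sequences_stay_singletons(self, rng):
        """All-pairs distances > 3 leave every record ungrouped."""
        seqs = []
        while len(seqs) < 3:
            s = "".join("ACGT"[i] for i in rng.integers(0, 4, 21))
            if all(sum(a != b for a, b in zip(s, t)) > 6 for t in seqs):
                seqs.append(s)
        records = [_rec(f"pc-{i}", s) for i, s in enumerate(seqs)]
        groups = group_families(records)
        assert groups == {}
        assert all(r.family is None for r in records)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            group_families([])
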