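"""Part annotation and the variant-calling filters."""

import random

import pytest

from partprov import (PartReference, Plasmid, annotate_parts,
                      classify_variant, group_variants)
from partprov.variants import VariantObservation, translate_cds

import oracles
from conftest import mutate, random_seq


def _orf(rng, n_codons):
    stops = {"TAA", "TAG", "TGA"}
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = random_seq(rng, 3)
        if c not in stops:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


@pytest.fixture(scope="module")
def part600():
    rng = random.Random(50)
    return PartReference("p600", _orf(rng, 200), "CDS")


@pytest.fixture(scope="module")
def ori_part():
    rng = random.Random(51)
    return PartReference("oriX", random_seq(rng, 400),
                         "origin of replication")


class TestAnnotateParts:
    def test_exact_copy_found_with_full_coverage_and_identity(self, part600):
        rng = random.Random(60)
        seq = random_seq(rng, 300) + part600.sequence + random_seq(rng, 300)
        plasmid = Plasmid("pl", seq, "lab0", "linear")
        matches = [m for m in annotate_parts(plasmid, [part600])
                   if m.coverage_fraction == 1.0]
        assert len(matches) == 1
        m = matches[0]
        assert m.nt_identity_fraction == 1.0
        assert m.matched_sequence == part600.sequence
        assert m.covers_ref_start and m.covers_ref_end
        assert m.plasmid_interval == (300, 900)

    def test_truncated_copy_below_min_coverage_not_reported(self, part600):
        rng = random.Random(61)
        truncated = part600.sequence[40:]  # 560/600 = 0.933 coverage
        seq = random_seq(rng, 200) + truncated + random_seq(rng, 200)
        plasmid = Plasmid("pl", seq, "lab0", "linear")
        assert annotate_parts(plasmid, [part600]) == []

    def test_reverse_strand_copy_reported_in_part_orientation(self, part600):
        rng = random.Random(62)
        seq = (random_seq(rng, 150)
               + oracles.revcomp(part600.sequence)
               + random_seq(rng, 150))
        plasmid = Plasmid("pl", seq, "lab0", "linear")
        (m,) = [m for m in annotate_parts(plasmid, [part600])
                if m.coverage_fraction == 1.0]
        assert m.strand == "-"
        assert m.matched_sequence == part600.sequence

    def test_origin_spanning_match_on_circular_plasmid(self, part600):
        rng = random.Random(63)
        linear = part600.sequence + random_seq(rng, 600)
        # rotate so the part straddles the sequence origin
        rotated = linear[300:] + linear[:300]
        plasmid = Plasmid("pl", rotated, "lab0", "circular")
        matches = [m for m in annotate_parts(plasmid, [part600])
                   if m.coverage_fraction == 1.0]
        assert len(matches) == 1
        m = matches[0]
        start, end = m.plasmid_interval
        assert start < len(rotated) <= end
        assert m.matched_sequence == part600.sequence

    def test_substitution_variant_still_covered(self, part600):
        rng = random.Random(64)
        variant = mutate(rng, part600.sequence, [100, 350])
        seq = random_seq(rng, 100) + variant + random_seq(rng, 100)
        plasmid = Plasmid("pl", seq, "lab0", "linear")
        (m,) = [m for m in annotate_parts(plasmid, [part600])
                if m.coverage_fraction == 1.0]
        assert m.matched_sequence == variant
        assert m.nt_identity_fraction == pytest.approx(598 / 600)

    def test_empty_part_db_rejected(self, part600):
        plasmid = Plasmid("pl", "ACGT" * 50, "lab0", "linear")
        with pytest.raises(ValueError, match="non-empty"):
            annotate_parts(plasmid, [])

    def test_agrees_with_sliding_window_oracle(self, ori_part):
        # substitution/truncation cases on short plasmids: the reported
        # locus set matches exhaustive per-diagonal evaluation
        rng = random.Random(65)
        for trial in range(5):
            variant = mutate(rng, ori_part.sequence,
                             rng.sample(range(10, 390), rng.randint(0, 3)))
            seq = (random_seq(rng, rng.randint(50, 150)) + variant
                   + random_seq(rng, rng.randint(50, 150)))
            plasmid = Plasmid("pl", seq, "lab0", "linear")
            got = [m for m in annotate_parts(plasmid, [ori_part])
                   if m.coverage_fraction >= 0.95]
            start = seq.find(variant)
            assert len(got) == 1
            assert got[0].plasmid_interval == (start, start + 400)


class TestClassifyVariant:
    def _match(self, plasmid_seq, part, **kw):
        plasmid = Plasmid("pl", plasmid_seq, "lab0", "linear")
        matches = annotate_parts(plasmid, [part])
        assert len(matches) == 1, matches
        return matches[0]

    def test_exact_nucleotide_match_is_not_a_variant(self, part600):
        rng = random.Random(70)
        seq = random_seq(rng, 100) + part600.sequence + random_seq(rng, 100)
        m = self._match(seq, part600)
        assert classify_variant(m, part600, lab="l") is None

    def test_synonymous_cds_substitution_removed(self, part600):
        rng = random.Random(71)
        # find a synonymous substitution in some codon
        canon = part600.sequence
        for pos in range(30, len(canon) - 30):
            for base in "ACGT":
                if base == canon[pos]:
                    continue
                cand = canon[:pos] + base + canon[pos + 1:]
                if (translate_cds(cand) == translate_cds(canon)):
                    seq = (random_seq(rng, 80) + cand + random_seq(rng, 80))
                    m = self._match(seq, part600)
                    assert m.matched_sequence != canon
                    assert classify_variant(m, part600, lab="l") is None
                    return
        pytest.fail("no synonymous substitution found")

    def test_terminal_cds_deletion_removed(self, part600):
        rng = random.Random(72)
        # missing the final 30 nt: coverage 570/600 = 0.95, no 3' end
        seq = (random_seq(rng, 100) + part600.sequence[:-30]
               + random_seq(rng, 100))
        m = self._match(seq, part600)
        assert m.coverage_fraction == pytest.approx(0.95)
        assert not m.covers_ref_end
        assert classify_variant(m, part600, lab="l") is None

    def test_missense_cds_substitution_kept(self, part600):
        rng = random.Random(73)
        canon = part600.sequence
        for pos in range(30, len(canon) - 30):
            for base in "ACGT":
                if base == canon[pos]:
                    continue
                cand = canon[:pos] + base + canon[pos + 1:]
                if translate_cds(cand) != translate_cds(canon):
                    seq = (random_seq(rng, 80) + cand + random_seq(rng, 80))
                    m = self._match(seq, part600)
                    obs = classify_variant(m, part600, lab="lab9")
                    assert obs is not None
                    assert obs.variant_sequence == cand
                    assert obs.lab == "lab9"
                    assert not obs.frameshifted
                    return
        pytest.fail("no missense substitution found")

    def test_noncoding_substitution_kept(self, ori_part):
        rng = random.Random(74)
        variant = mutate(rng, ori_part.sequence, [200])
        seq = random_seq(rng, 90) + variant + random_seq(rng, 90)
        m = self._match(seq, ori_part)
        obs = classify_variant(m, ori_part, lab="l")
        assert obs is not None
        assert obs.variant_sequence == variant

    def test_noncoding_truncation_is_a_variant_if_covered(self, ori_part):
        rng = random.Random(75)
        truncated = ori_part.sequence[10:]  # coverage 390/400 = 0.975
        seq = random_seq(rng, 90) + truncated + random_seq(rng, 90)
        m = self._match(seq, ori_part)
        assert not m.covers_ref_start
        obs = classify_variant(m, ori_part, lab="l")
        assert obs is not None

    def test_internal_indel_flags_frameshift(self, part600):
        rng = random.Random(76)
        canon = part600.sequence
        variant = canon[:250] + canon[251:]  # 1 bp internal deletion
        seq = random_seq(rng, 120) + variant + random_seq(rng, 120)
        m = self._match(seq, part600)
        assert m.coverage_fraction >= 0.95
        obs = classify_variant(m, part600, lab="l")
        assert obs is not None
        assert obs.frameshifted


class TestGroupVariants:
    def _obs(self, plasmid, lab, part="partA", seq="ACGTACGT"):
        return VariantObservation(plasmid_id=plasmid, lab=lab, part_id=part,
                                  variant_sequence=seq)

    def test_identical_sequences_group_together(self):
        obs = [self._obs("p1", "labA"), self._obs("p2", "labA"),
               self._obs("p3", "labB")]
        (group,) = group_variants(obs)
        assert group.n_observations == 3
        assert group.n_labs == 2

    def test_distinct_sequences_distinct_groups(self):
        obs = [self._obs("p1", "labA", seq="ACGTACGT"),
               self._obs("p2", "labA", seq="ACGTACGA")]
        groups = group_variants(obs)
        assert len(groups) == 2

    def test_empty_observations(self):
        assert group_variants([]) == []

    def test_variant_ids_stable_across_runs(self):
        a = group_variants([self._obs("p1", "labA")])[0].variant_id
        b = group_variants([self._obs("p9", "labZ")])[0].variant_id
        assert a == b


class TestStrandSymmetry:
    def test_reverse_complementing_plasmid_preserves_observations(
            self, part600, ori_part):
        rng = random.Random(80)
        variant = mutate(rng, ori_part.sequence, [100, 300])
        seq = (random_seq(rng, 100) + variant + random_seq(rng, 60)
               + part600.sequence + random_seq(rng, 100))
        parts = [part600, ori_part]
        fwd = Plasmid("f", seq, "lab0", "linear")
        rev = Plasmid("r", oracles.revcomp(seq), "lab0", "linear")

        def observed(plasmid):
            out = set()
            for m in annotate_parts(plasmid, parts):
                part = part600 if m.part_id == "p600" else ori_part
                obs = classify_variant(m, part, lab="lab0")
                if obs is not None:
                    out.add((obs.part_id, obs.variant_sequence))
            return out

        assert observed(fwd) == observed(rev)
        assert observed(fwd) == {("oriX", variant)}
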