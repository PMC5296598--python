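"""Variant filters, deletion calling, continuity check and classification."""

import numpy as np
import pytest
from Bio.Seq import Seq

from attmut.errors import InputError, ParameterError
from attmut.sim import random_genome
from attmut.variants import (
    DeletionCall,
    GeneModel,
    VariantRecord,
    check_lineage_consistency,
    classify_snp,
    detect_deletions,
    exclude_unreliable,
    filter_fixed,
    grand_total,
    lineage_totals,
    per_round_rows,
    tabulate_counts,
)


def _rec(pos=100, frac=0.9, ref="A", alt="G", contig="contig_1", lineage="L1", rnd=1):
    return VariantRecord(
        lineage_id=lineage, round=rnd, contig=contig, position=pos,
        ref=ref, alt=alt, read_fraction=frac,
    )


class TestFilterFixed:
    def test_strict_threshold_boundary(self):
        kept = filter_fixed([_rec(frac=0.81), _rec(frac=0.80), _rec(frac=0.79)])
        assert [r.read_fraction for r in kept] == [0.81]

    def test_empty_and_order_preserved(self):
        assert filter_fixed([]) == []
        recs = [_rec(pos=p, frac=0.95) for p in (5, 3, 9)]
        assert [r.position for r in filter_fixed(recs)] == [5, 3, 9]

    def test_idempotent(self):
        recs = [_rec(frac=f) for f in (0.2, 0.81, 0.9, 0.8)]
        once = filter_fixed(recs)
        assert filter_fixed(once) == once

    def test_threshold_domain(self):
        with pytest.raises(ParameterError):
            filter_fixed([], threshold=0.0)


class TestDetectDeletions:
    def test_strict_length_boundary(self):
        track = np.ones(1000)
        track[100:201] = 0  # 101-bp zero run
        calls = detect_deletions(track, min_len=100)
        assert [(c.start, c.end) for c in calls] == [(100, 201)]
        track2 = np.ones(1000)
        track2[100:200] = 0  # exactly 100 bp: below the strict rule
        assert detect_deletions(track2, min_len=100) == []

    def test_empty_track(self):
        assert detect_deletions(np.array([]), min_len=100) == []

    def test_runs_are_maximal_disjoint_and_reconstruct_track(self, rng):
        depth = (rng.random(5000) > 0.3).astype(int)
        calls = detect_deletions(depth, min_len=1)
        # oracle: simple linear scan
        expected, start = [], None
        for i, v in enumerate(depth):
            if v == 0 and start is None:
                start = i
            elif v != 0 and start is not None:
                if i - start > 1:
                    expected.append((start, i))
                start = None
        if start is not None and len(depth) - start > 1:
            expected.append((start, len(depth)))
        assert [(c.start, c.end) for c in calls] == expected
        for a, b in zip(calls, calls[1:]):
            assert a.end < b.start  # disjoint, ordered


class TestExcludeUnreliable:
    CONTIGS = {"contig_1": 100_000}

    def test_contig_end_margin(self):
        kept, removed = exclude_unreliable([_rec(pos=10)], self.CONTIGS, end_margin=50)
        assert kept == [] and removed[0].contig_end

    def test_inside_deletion(self):
        dels = [DeletionCall("contig_1", 500, 700)]
        kept, removed = exclude_unreliable(
            [_rec(pos=600), _rec(pos=800)], self.CONTIGS, 50, dels
        )
        assert [r.position for r in kept] == [800]
        assert removed[0].in_deletion

    def test_identity_with_zero_margin(self):
        recs = [_rec(pos=1), _rec(pos=100_000)]
        kept, removed = exclude_unreliable(recs, self.CONTIGS, end_margin=0)
        assert kept == recs and removed == []

    def test_unknown_contig(self):
        with pytest.raises(InputError):
            exclude_unreliable([_rec(contig="contig_9")], self.CONTIGS)


class TestLineageConsistency:
    def test_nested_sets_pass(self):
        ok, missing = check_lineage_consistency([{1}, {1, 2}, {1, 2, 3}])
        assert ok and missing == {}

    def test_dropped_mutation_is_reported(self):
        ok, missing = check_lineage_consistency([{1}, {1, 2}, {1, 3}])
        assert not ok
        assert missing == {2: [2]}

    def test_single_round_vacuously_passes(self):
        assert check_lineage_consistency([{1, 2}]) == (True, {})


class TestClassifySnp:
    def test_transition_and_transversion_definitions(self):
        genome = {"contig_1": "A" * 200}
        ti = classify_snp(_rec(pos=100, ref="A", alt="G"), genome, [])
        tv = classify_snp(_rec(pos=100, ref="A", alt="C"), genome, [])
        assert ti.substitution_class == "transition"
        assert tv.substitution_class == "transversion"
        assert ti.region == "noncoding" and ti.effect == "n.a."

    def test_third_position_wobble_is_synonymous(self):
        # GGA -> GGG in a forward CDS: both glycine
        genome = {"contig_1": "TT" + "ATGGGATAA" + "TT"}
        model = GeneModel("contig_1", start=2, end=11, strand="+")
        rec = _rec(pos=8, ref="A", alt="G")  # third base of GGA
        classify_snp(rec, genome, [model])
        assert rec.region == "coding" and rec.effect == "synonymous"

    def test_reference_mismatch_is_error(self):
        with pytest.raises(InputError):
            classify_snp(_rec(pos=1, ref="C", alt="T"), {"contig_1": "AAAA"}, [])

    def test_ambiguous_base_classifies_na(self):
        rec = _rec(pos=2, ref="N", alt="A")
        classify_snp(rec, {"contig_1": "ANAA"}, [])
        assert rec.substitution_class is None and rec.effect == "n.a."

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_agrees_with_full_cds_translation_oracle(self, strand, rng):
        genome_seq = random_genome(3000, seed=99)
        start, end = 600, 600 + 900
        model = GeneModel("contig_1", start, end, strand)
        genome = {"contig_1": genome_seq}
        for _ in range(500):
            p0 = int(rng.integers(start, end))
            ref = genome_seq[p0]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            rec = _rec(pos=p0 + 1, ref=ref, alt=str(alt))
            classify_snp(rec, genome, [model])
            # oracle: translate the whole CDS before and after the change
            mutated = genome_seq[:p0] + str(alt) + genome_seq[p0 + 1 :]
            cds_ref, cds_alt = genome_seq[start:end], mutated[start:end]
            if strand == "-":
                cds_ref = str(Seq(cds_ref).reverse_complement())
                cds_alt = str(Seq(cds_alt).reverse_complement())
            same = str(Seq(cds_ref).translate(table=11)) == str(
                Seq(cds_alt).translate(table=11)
            )
            assert rec.effect == ("synonymous" if same else "nonsynonymous")


class TestTabulateCounts:
    def _classified(self, n_ti, n_tv, lineage="L1", rnd=1):
        out = []
        for i in range(n_ti):
            r = _rec(pos=1000 + i, ref="A", alt="G", lineage=lineage, rnd=rnd)
            r.substitution_class = "transition"
            out.append(r)
        for i in range(n_tv):
            r = _rec(pos=5000 + i, ref="A", alt="C", lineage=lineage, rnd=rnd)
            r.substitution_class = "transversion"
            out.append(r)
        return out

    def test_printed_strain_comparison_counts(self):
        # 71 transitions among 105 SNPs, the close-relative comparison
        table = tabulate_counts(self._classified(71, 34))
        assert grand_total(table) == (71, 105)

    def test_empty_input(self):
        table = tabulate_counts([])
        assert table.empty

    def test_per_lineage_rows_sum_to_total(self):
        recs = self._classified(10, 2, "L1") + self._classified(7, 5, "L2", rnd=2)
        table = tabulate_counts(recs)
        per_lineage = lineage_totals(table)
        assert per_lineage["k"].sum() == 17 and per_lineage["n"].sum() == 24
        assert grand_total(table) == (17, 24)
        rows = per_round_rows(table)
        assert rows["n"].sum() == 24

    def test_unclassified_record_is_error(self):
        with pytest.raises(InputError):
            tabulate_counts([_rec()])
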