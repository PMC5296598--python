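"""Excision reconstruction: products, scars, direct repeats, in-silico PCR."""

import numpy as np
import pytest

from attmut.errors import ConfigurationError, ParameterError
from attmut.excision import (
    assay_state,
    design_assay_primers,
    find_direct_repeats,
    insilico_pcr,
    predict_excision,
    revcomp,
)
from attmut.sim import build_att_locus, random_genome


class TestPredictExcision:
    def test_scarred_locus_loses_two_host_bases(self, scarred_locus):
        p = scarred_locus.products
        host = scarred_locus.locus.preinsertion_host
        assert len(host) - len(p.attB_sequence) == 2
        assert p.scar_length == 2
        assert p.frameshift

    def test_scarred_locus_has_premature_stop(self, scarred_locus):
        p = scarred_locus.products
        assert p.premature_stop_codon_position is not None
        assert p.premature_stop_codon_position < p.wildtype_stop_codon_position

    def test_clean_excision_restores_host_gene(self, clean_locus):
        p = clean_locus.products
        assert p.attB_sequence == clean_locus.locus.preinsertion_host
        assert not p.frameshift
        assert p.premature_stop_codon_position is None

    @pytest.mark.parametrize("scar_offset", range(6))
    def test_base_conservation_and_roundtrip(self, scar_offset):
        bundle = build_att_locus(
            upstream_len=90, element_len=300, core_len=10,
            scar_offset=scar_offset, seed=scar_offset, downstream_len=180,
        )
        locus, p = bundle.locus, bundle.products
        integrated = locus.integrated_sequence
        # recombination conserves every base between the two products
        assert len(p.attB_sequence) + len(p.attP_sequence) == len(integrated)
        # excision then integration is the identity on the locus
        assert p.reintegrated() == integrated
        # the stored pieces concatenate to the integrated locus
        assert (
            locus.host_upstream + locus.core_left + locus.element
            + locus.core_right + locus.host_downstream == integrated
        )

    @pytest.mark.parametrize("scar_offset", range(6))
    def test_frameshift_iff_scar_not_multiple_of_three(self, scar_offset):
        bundle = build_att_locus(90, 300, 10, scar_offset, seed=100 + scar_offset)
        assert bundle.products.frameshift == (scar_offset % 3 != 0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(upstream_len=90, element_len=0, core_len=8, scar_offset=0),
            dict(upstream_len=90, element_len=300, core_len=0, scar_offset=0),
            dict(upstream_len=90, element_len=300, core_len=8, scar_offset=8),
            dict(upstream_len=90, element_len=300, core_len=8, scar_offset=-1),
        ],
    )
    def test_invalid_geometry_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            build_att_locus(seed=0, **kwargs)


class TestFindDirectRepeats:
    def test_planted_core_is_top_candidate(self, rng):
        core = "".join(rng.choice(list("ACGT"), 12))
        left = random_genome(60, 1) + core + random_genome(60, 2)
        right = random_genome(60, 3) + core + random_genome(60, 4)
        hits = find_direct_repeats(left, right, min_core=8)
        assert hits
        assert hits[0].length >= 12
        assert core in hits[0].sequence or hits[0].sequence in left

    def test_random_junctions_usually_empty(self):
        empties = 0
        for seed in range(20):
            left = random_genome(80, 2 * seed)
            right = random_genome(80, 2 * seed + 1)
            if not find_direct_repeats(left, right, min_core=8):
                empties += 1
        assert empties >= 18  # an 8-bp chance match has probability ~4^-8 per pair

    def test_results_ranked_longest_then_leftmost(self):
        left = "AAAA" + "GATTACAGATTACA" + "CCCC" + "TTTTTT"
        right = "GGGG" + "GATTACAGATTACA" + "AAAA"
        hits = find_direct_repeats(left, right, min_core=4)
        assert hits[0].length == max(h.length for h in hits)
        same_len = [h for h in hits if h.length == hits[0].length]
        assert same_len[0].left_start == min(h.left_start for h in same_len)

    def test_min_core_below_four_rejected(self):
        with pytest.raises(ParameterError):
            find_direct_repeats("ACGTACGT", "ACGTACGT", min_core=3)


def _brute_force_pcr(template, circular, fwd, rev, max_len):
    """Quadratic scan oracle: check every (start, length) pair directly."""
    tpl = template.upper()
    n = len(tpl)
    doubled = tpl + tpl if circular else tpl
    site = revcomp(rev.upper())
    found = set()
    cap = min(max_len, n) if circular else max_len
    for i in range(n):
        if doubled[i : i + len(fwd)] != fwd.upper():
            continue
        for length in range(1, cap + 1):
            end = i + length
            if end > len(doubled):
                break
            if doubled[end - len(site) : end] == site:
                found.add((i % n, length))
    return found


class TestInsilicoPcr:
    def test_linear_toy_template(self, rng):
        tpl = random_genome(200, 5)
        fwd = tpl[10:30]
        site = tpl[130:150]  # reverse primer binds here, product ends at 150
        amps = insilico_pcr(tpl, False, fwd, revcomp(site), max_len=500)
        assert len(amps) == 1
        assert (amps[0].start, amps[0].length) == (10, 140)
        assert not amps[0].crosses_origin

    def test_circular_product_spans_origin(self):
        tpl = random_genome(300, 6)
        fwd = tpl[260:280]
        site = tpl[40:60]
        amps = insilico_pcr(tpl, True, fwd, revcomp(site), max_len=300)
        assert len(amps) == 1
        assert amps[0].crosses_origin
        # rotation oracle: shift the origin so the product no longer crosses
        rot = tpl[200:] + tpl[:200]
        lin = insilico_pcr(rot, True, fwd, revcomp(site), max_len=300)
        assert [a.length for a in lin] == [amps[0].length]

    def test_absent_primer_yields_empty(self):
        tpl = "A" * 100
        with_no_match = insilico_pcr(tpl, False, "C" * 20, "G" * 20, 100)
        assert with_no_match == []

    def test_short_primer_rejected(self):
        with pytest.raises(ParameterError):
            insilico_pcr("ACGT" * 30, False, "ACGT", "ACGTACGTACGTACGT", 100)

    @pytest.mark.parametrize("circular", [False, True])
    def test_matches_brute_force_oracle(self, circular, rng):
        for trial in range(40):
            n = int(rng.integers(100, 260))
            tpl = random_genome(n, 1000 + trial)
            i = int(rng.integers(0, n - 40))
            j = int(rng.integers(i + 20, n - 20))
            fwd, site = tpl[i : i + 16], tpl[j : j + 16]
            max_len = int(rng.integers(30, n + 50))
            got = {
                (a.start, a.length)
                for a in insilico_pcr(tpl, circular, fwd, revcomp(site), max_len)
            }
            assert got == _brute_force_pcr(tpl, circular, fwd, revcomp(site), max_len)


class TestAssay:
    def test_three_population_states(self, rng):
        bundle = build_att_locus(300, 3000, 12, 2, seed=21)
        primers = design_assay_primers(bundle.locus, max_len=1000)
        integrated = assay_state(bundle.locus, primers)
        excised = assay_state(bundle.products, primers)
        mixed = assay_state([bundle.locus, bundle.products], primers)
        assert integrated == {"attL": True, "attR": True, "attB": False, "attP": False}
        assert excised == {"attL": False, "attR": False, "attB": True, "attP": True}
        assert mixed == {"attL": True, "attR": True, "attB": True, "attP": True}

    def test_broken_primer_set_is_configuration_error(self):
        bundle = build_att_locus(300, 3000, 12, 2, seed=22)
        primers = design_assay_primers(bundle.locus, max_len=1000)
        primers.pairs["attB"] = ("T" * 20, "G" * 20)  # cannot amplify anything
        with pytest.raises(ConfigurationError):
            assay_state(bundle.locus, primers)

    def test_design_rejects_overlong_max_len(self):
        # with max_len larger than the element the attB pair would amplify
        # across the integrated locus and the assay loses its specificity
        bundle = build_att_locus(300, 800, 12, 2, seed=23)
        with pytest.raises(ConfigurationError):
            design_assay_primers(bundle.locus, max_len=5000)
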