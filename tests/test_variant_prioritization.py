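import math

import numpy as np
import pytest
from scipy.stats import fisher_exact

import _oracles
from relocus.enhancer_model import Peak
from relocus.io_formats import (
    ContactRecord,
    GeneModel,
    GenomicInterval,
    PWMRecord,
    Variant,
)
from relocus.synthetic_data import default_pwms
from relocus.variant_prioritization import (
    PrioritizationConfig,
    VariantAnnotation,
    build_shortlist,
    link_targets,
    promoter_flag,
    scan_motif_disruption,
    score_alleles,
    tag_count,
)


def variant(pos, rsid="rs1", chrom="chr1", ref="A", alt="G", p=1e-5):
    return Variant(rsid, chrom, pos, ref, alt, p)


def peak(start, end, value=1.0, chrom="chr1"):
    return Peak(GenomicInterval(chrom, start, end), value, value)


class TestTagCount:
    def test_variant_inside_peak_reads_peak_max(self):
        assert tag_count(variant(150), [peak(100, 200, 7.2)]) == 7.2

    def test_one_base_outside_reads_zero(self):
        # peak covers 0-based [100, 200); pos 201 is base 200, just outside
        assert tag_count(variant(201), [peak(100, 200, 7.2)]) == 0.0
        assert tag_count(variant(200), [peak(100, 200, 7.2)]) == 7.2

    def test_signal_mode_reads_track_value(self):
        from relocus.io_formats import SignalTrack

        track = SignalTrack.from_records([("chr1", 100, 200, 3.5)])
        assert tag_count(variant(150), track=track, mode="signal") == 3.5

    def test_matches_bruteforce_on_random_variants(self, rng):
        peaks = [
            peak(int(s), int(s) + int(w), float(v))
            for s, w, v in zip(
                rng.integers(0, 9_000, 30),
                rng.integers(10, 400, 30),
                rng.uniform(1, 10, 30),
            )
        ]
        variants = [variant(int(p), rsid=f"rs{i}") for i, p in enumerate(rng.integers(1, 10_000, 1000))]
        got = [tag_count(v, peaks) for v in variants]
        assert got == _oracles.tag_counts_bruteforce(variants, peaks)


class TestPromoterFlag:
    GENES = [
        GeneModel.from_body("gPlus", "gPlus", "chr1", 10_000 - 1, 20_000, "+"),
        GeneModel.from_body("gMinus", "gMinus", "chr1", 5_000, 10_000, "-"),
    ]
    # gPlus TSS base 9999 = 1-based 10000; gMinus TSS base 9999 = 1-based 10000

    def test_variant_at_tss_is_in_promoter(self):
        flag, genes = promoter_flag(variant(10_000), self.GENES)
        assert flag and "gPlus" in genes

    def test_plus_strand_upstream_boundary_inclusive(self):
        cfg = PrioritizationConfig()
        genes = [self.GENES[0]]
        assert promoter_flag(variant(10_000 - 1500), genes, cfg)[0]
        assert not promoter_flag(variant(10_000 - 1501), genes, cfg)[0]

    def test_plus_strand_downstream_boundary_inclusive(self):
        genes = [self.GENES[0]]
        assert promoter_flag(variant(10_000 + 500), genes)[0]
        assert not promoter_flag(variant(10_000 + 501), genes)[0]

    def test_minus_strand_window_flips(self):
        genes = [self.GENES[1]]
        # window is 1-based [9500, 11500] for TSS 10000 on the minus strand
        assert promoter_flag(variant(10_400), genes)[0]
        assert promoter_flag(variant(9_500), genes)[0]
        assert promoter_flag(variant(11_500), genes)[0]
        assert not promoter_flag(variant(9_499), genes)[0]
        assert not promoter_flag(variant(11_501), genes)[0]

    def test_variant_in_two_promoters_reports_both(self):
        flag, genes = promoter_flag(variant(10_000), self.GENES)
        assert set(genes) == {"gPlus", "gMinus"}


def consensus_pwm(consensus="ACGTCA", strong=20.0):
    m = np.full((4, len(consensus)), 1.0)
    for j, base in enumerate(consensus):
        m["ACGT".index(base), j] = strong
    return PWMRecord("TEST", m)


class TestMotifDisruption:
    def _sequences(self, seq):
        return {"chr1": seq}

    def test_alt_completing_consensus_gives_positive_delta(self):
        pwm = consensus_pwm("ACGTCA")
        # genome carries the consensus with position 3 (T) broken to G
        seq = "TTTTT" + "ACGGCA" + "TTTTT"
        sequences = self._sequences(seq)
        v = Variant("rsX", "chr1", 9, "G", "T", 1e-5)  # base index 8 = broken T
        (hit,) = scan_motif_disruption(v, sequences, [pwm])
        assert hit.delta > 0
        # hand-computed log-odds difference at the consensus placement
        probs = (pwm.matrix + 0.5) / (pwm.matrix + 0.5).sum(axis=0)
        expected = math.log2(probs["ACGT".index("T"), 3] / 0.25) - math.log2(
            probs["ACGT".index("G"), 3] / 0.25
        )
        assert hit.delta == pytest.approx(expected)
        assert hit.alt_is_hit

    def test_uniform_pwm_gives_zero_delta(self):
        pwm = PWMRecord("FLAT", np.full((4, 6), 5.0))
        seq = "ACGTACGTACGTACGT"
        v = Variant("rsX", "chr1", 8, "T", "C", 1e-5)
        hits = scan_motif_disruption(v, self._sequences(seq), [pwm])
        (hit,) = hits
        assert hit.delta == pytest.approx(0.0)

    def test_equal_alleles_scored_identically(self):
        # degenerate allele input is exercised at the scoring level, where
        # no Variant object (which forbids ref == alt) is required
        pwm = consensus_pwm("ACGTCA")
        seq = "TTTTTACGTCATTTTT"
        ref_s, alt_s, _, _ = score_alleles(seq, 8, "T", "T", pwm)
        assert ref_s == alt_s

    def test_ref_mismatch_with_genome_is_an_error(self):
        pwm = consensus_pwm("ACGTCA")
        v = Variant("rsX", "chr1", 3, "G", "T", 1e-5)
        with pytest.raises(ValueError, match="rsX"):
            scan_motif_disruption(v, self._sequences("AAAAAAAA"), [pwm])

    def test_matches_exhaustive_enumeration_oracle(self, rng):
        bases = "ACGT"
        for trial in range(8):
            L = int(rng.integers(4, 9))
            pwm = PWMRecord(f"P{trial}", rng.integers(0, 30, size=(4, L)).astype(float))
            seq = "".join(bases[i] for i in rng.integers(0, 4, size=40))
            pos0 = int(rng.integers(10, 30))
            ref = seq[pos0]
            alt = bases[(bases.index(ref) + 1 + int(rng.integers(0, 3))) % 4]
            got_ref, got_alt, _, _ = score_alleles(seq, pos0, ref, alt, pwm)
            exp_ref, exp_alt = _oracles.motif_best_scores_bruteforce(
                seq, pos0, ref, alt, pwm
            )
            assert got_ref == pytest.approx(exp_ref)
            assert got_alt == pytest.approx(exp_alt)

    def test_reverse_strand_placement_found(self):
        pwm = consensus_pwm("AAAACC")
        # reverse complement GGTTTT planted on the forward strand
        seq = "TTTTT" + "GGTTTT" + "TTTTT"
        v = Variant("rsX", "chr1", 7, "G", "A", 1e-5)  # base index 6
        hits = scan_motif_disruption(v, self._sequences(seq), [pwm])
        assert hits and hits[0].score_ref > hits[0].score_alt


class TestLinkTargets:
    GENE = GeneModel.from_body("gT", "gT", "chr1", 50_000, 60_000, "+")

    def test_variant_in_anchor_with_tagged_candidate(self):
        contact = ContactRecord(
            GenomicInterval("chr1", 100, 200),
            GenomicInterval("chr1", 48_000, 52_000),
            0.8,
            "gT",
        )
        assert link_targets(variant(150), [contact], [self.GENE]) == ("gT",)

    def test_gene_below_threshold_not_in_candidates_excluded(self):
        # anchor touches only the gene body, not the promoter window, and the
        # tagged gene is not a candidate: nothing links
        contact = ContactRecord(
            GenomicInterval("chr1", 100, 200),
            GenomicInterval("chr1", 52_000, 56_000),
            0.8,
            "gOther",
        )
        assert link_targets(variant(150), [contact], [self.GENE]) == ()

    def test_promoter_overlap_links_untagged_contact(self):
        contact = ContactRecord(
            GenomicInterval("chr1", 100, 200),
            GenomicInterval("chr1", 49_000, 50_100),  # overlaps gT promoter
            0.8,
            None,
        )
        assert link_targets(variant(150), [contact], [self.GENE]) == ("gT",)

    def test_variant_outside_all_anchors_links_nothing(self):
        contact = ContactRecord(
            GenomicInterval("chr1", 100, 200),
            GenomicInterval("chr1", 48_000, 52_000),
            0.8,
            "gT",
        )
        assert link_targets(variant(5_000), [contact], [self.GENE]) == ()


def _annotation(rsid, atac, emerge, promoter, motif, linked):
    return VariantAnnotation(
        variant=variant(1000, rsid=rsid),
        locus_id="L1",
        atac_tag=atac,
        emerge_tag=emerge,
        in_promoter=promoter,
        motif_hits=(object(),) if motif else (),
        linked_genes=("gX",) if linked else (),
    )


class TestShortlist:
    def test_no_signal_anywhere_gives_empty_tiers(self):
        anns = [_annotation(f"rs{i}", 0, 0, False, False, False) for i in range(5)]
        tiers, summary = build_shortlist(anns)
        assert all(len(v) == 0 for v in tiers.values())
        assert (summary["count"] == 0).all()

    def test_variant_satisfying_everything_in_all_tiers(self):
        anns = [_annotation("rsAll", 2.0, 0.3, True, True, True)]
        tiers, _ = build_shortlist(anns)
        for tier, members in tiers.items():
            assert members == anns, tier

    def test_tier_counts_match_bruteforce_set_algebra(self, rng):
        anns = [
            _annotation(
                f"rs{i}",
                float(rng.random() < 0.4) * rng.uniform(1, 5),
                float(rng.random() < 0.4) * rng.uniform(0.06, 1),
                bool(rng.random() < 0.2),
                bool(rng.random() < 0.3),
                bool(rng.random() < 0.3),
            )
            for i in range(400)
        ]
        tiers, summary = build_shortlist(anns)
        atac = {a.variant.rsid for a in anns if a.atac_tag > 0}
        emerge = {a.variant.rsid for a in anns if a.emerge_tag > 0}
        prom = {a.variant.rsid for a in anns if a.in_promoter}
        motif = {a.variant.rsid for a in anns if a.motif_hits}
        linked = {a.variant.rsid for a in anns if a.linked_genes}
        expected = {
            "T_RE_both": atac & emerge,
            "T_RE_any": atac | emerge,
            "T_promoter": (atac | emerge) & prom,
            "T_linked": (atac | emerge) & linked,
            "T_motif_open": motif & atac,
            "T_motif_linked": motif & atac & linked,
        }
        for tier, members in tiers.items():
            assert {a.variant.rsid for a in members} == expected[tier]
        assert summary["percent"].tolist() == [
            pytest.approx(100 * len(expected[t]) / 400) for t in summary["tier"]
        ]

    def test_subset_chain_invariant(self, rng):
        anns = [
            _annotation(
                f"rs{i}",
                float(rng.random() < 0.5),
                float(rng.random() < 0.5),
                bool(rng.random() < 0.5),
                bool(rng.random() < 0.5),
                bool(rng.random() < 0.5),
            )
            for i in range(200)
        ]
        tiers, _ = build_shortlist(anns)
        ids = {t: {a.variant.rsid for a in m} for t, m in tiers.items()}
        atac_ids = {a.variant.rsid for a in anns if a.atac_tag > 0}
        assert ids["T_motif_linked"] <= ids["T_motif_open"] <= atac_ids <= ids["T_RE_any"]
        assert ids["T_RE_both"] <= ids["T_RE_any"]
        assert ids["T_linked"] <= ids["T_RE_any"]


def test_planted_functional_variants_enrich_motif_linked_tier(pipeline_products):
    """Planted motif-altering, enhancer-resident variants concentrate in the
    motif-in-open-chromatin-with-target tier far beyond other members."""
    products = pipeline_products
    truth = products["bundle"].truth
    tiers = products["tiers"]
    functional = set(truth.functional_rsids)
    all_members = {a.variant.rsid for a in products["annotations"]}
    in_tier = {a.variant.rsid for a in tiers["T_motif_linked"]}
    table = [
        [len(functional & in_tier), len(functional - in_tier)],
        [len(in_tier - functional), len(all_members - functional - in_tier)],
    ]
    odds, p = fisher_exact(table)
    assert p < 0.01
    assert len(functional & in_tier) / len(functional) > 0.8
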