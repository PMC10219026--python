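"""The per-gene SNP screen and its tallies."""

import random

import pandas as pd
import pytest

from tatascan import CountSplit, SnpVariant, screen, tally_directions, tally_health
from tatascan.marker_screen import screen_summary
from tatascan.sequence_io import SequenceError
from tatascan.snp_comparator import DEFICIENCY, EXCESS
from tatascan.synthetic_data import (
    SIM_TRUTH_COEFFICIENTS,
    SimConfig,
    gen_promoters,
    gen_snps,
)


def _sim_bundle(seed: int, n_promoters: int = 10, snps_per_promoter: int = 5):
    cfg = SimConfig(
        seed=seed,
        region_sizes={"ABC": n_promoters},
        n_genes=n_promoters,
        n_hub_genes=n_promoters,
        transcripts_per_gene=1,
        tata_fraction=1.0,
        tata_strength=0.8,
        snps_per_promoter=snps_per_promoter,
        in_box_fraction=0.5,
    )
    promoters, truth = gen_promoters(cfg)
    promoters, snps, labels = gen_snps(promoters, truth, cfg)
    return promoters, snps, labels


class TestScreen:
    def test_planted_significant_set_recovered_exactly(self):
        """On a 10-promoter / 50-SNP planted fixture the screen calls
        exactly the SNPs planted with an affinity effect, with the planted
        direction."""
        promoters, snps, labels = _sim_bundle(seed=2)
        result = screen(promoters, snps, coef=SIM_TRUTH_COEFFICIENTS, keep_log=True)
        called = {m.variant.rsid: m.comparison.direction for m in result.markers}
        planted = {
            row.rsid: row.expected
            for row in labels.itertuples()
            if row.expected != "neutral"
        }
        assert called == planted

    def test_empty_snp_table(self, crp_promoter):
        result = screen([crp_promoter], [])
        assert result.markers == []
        split = tally_directions(result.markers)
        assert (split.k_a, split.k_b) == (0, 0)

    def test_crp_fixture_yields_two_deficiency_markers(self, crp_promoter):
        """Both published CRP promoter SNPs significantly lower TBP affinity."""
        snps = [
            SnpVariant(rsid="rs1660782480", position=-11, ref="A", alt="G",
                       transcript_id="CRP-201"),
            SnpVariant(rsid="rs1660782424", position=-10, ref="T", alt="C",
                       transcript_id="CRP-201"),
        ]
        result = screen([crp_promoter], snps)
        assert len(result.markers) == 2
        assert all(m.comparison.direction == DEFICIENCY for m in result.markers)

    def test_unresolvable_snp_skipped_with_warning(self, crp_promoter, caplog):
        orphan = SnpVariant(rsid="rsO", position=-5, ref="A", alt="G",
                            transcript_id="NOPE-1")
        with caplog.at_level("WARNING"):
            result = screen([crp_promoter], [orphan])
        assert result.n_skipped == 1
        assert result.markers == []

    def test_unresolvable_snp_raises_in_strict_mode(self, crp_promoter):
        orphan = SnpVariant(rsid="rsO", position=-5, ref="A", alt="G",
                            transcript_id="NOPE-1")
        with pytest.raises(SequenceError):
            screen([crp_promoter], [orphan], strict=True)

    def test_order_invariance(self):
        promoters, snps, _ = _sim_bundle(seed=3)
        r1 = screen(promoters, snps, coef=SIM_TRUTH_COEFFICIENTS)
        shuffled = list(snps)
        random.Random(0).shuffle(shuffled)
        r2 = screen(list(reversed(promoters)), shuffled, coef=SIM_TRUTH_COEFFICIENTS)
        key = lambda m: (m.variant.rsid, m.transcript_id)
        assert sorted(
            (key(m), m.comparison.direction) for m in r1.markers
        ) == sorted((key(m), m.comparison.direction) for m in r2.markers)

    def test_gene_level_snp_hits_every_transcript(self, crp_promoter):
        """A SNP resolved by gene contributes one comparison per transcript
        of that gene (the transcript-level counting unit)."""
        import dataclasses

        second = dataclasses.replace(crp_promoter, transcript_id="CRP-202")
        snp = SnpVariant(rsid="rs1660782480", position=-11, ref="A", alt="G",
                         gene_symbol="CRP")
        result = screen([crp_promoter, second], [snp])
        assert result.n_comparisons == 2
        assert len(result.markers) == 2
        assert result.n_unique_rsids == 1


class TestTallies:
    def _markers(self, directions):
        promoters, snps, labels = _sim_bundle(seed=2)
        result = screen(promoters, snps, coef=SIM_TRUTH_COEFFICIENTS)
        return [m for m in result.markers if m.comparison.direction in directions]

    def test_direction_tally_counts(self):
        markers = self._markers({DEFICIENCY, EXCESS})
        split = tally_directions(markers)
        n_exc = sum(1 for m in markers if m.comparison.direction == EXCESS)
        assert split.k_a == n_exc
        assert split.n == len(markers)

    def test_conservation_against_summary(self):
        promoters, snps, _ = _sim_bundle(seed=4)
        result = screen(promoters, snps, coef=SIM_TRUTH_COEFFICIENTS)
        summary = screen_summary(result)
        split = tally_directions(result.markers)
        assert split.n == summary["n_markers_per_transcript"] == len(result.markers)
        assert summary["direction_split"] == {"increase": split.k_a, "decrease": split.k_b}

    def test_health_tally_manual_enumeration(self, hub_annotations):
        """Six hand-annotated markers tally to the hand-counted splits."""
        from tatascan import compare_kd
        from tatascan.snp_comparator import CandidateMarker, annotate_health
        from tatascan import AffinityEstimate

        def mk(gene, kd_b):
            m = CandidateMarker(
                variant=SnpVariant(rsid=f"rs{gene}{kd_b}", position=-9, ref="A", alt="G"),
                gene_symbol=gene,
                transcript_id=f"{gene}-T1",
                ancestral=AffinityEstimate.from_nM(5.0, 0.5),
                minor=AffinityEstimate.from_nM(kd_b, kd_b / 10),
                comparison=compare_kd(5.0, 0.5, kd_b, kd_b / 10),
            )
            return annotate_health(m, hub_annotations)

        markers = [mk("CRP", 15.0), mk("CRP", 1.5), mk("SERPINF1", 15.0),
                   mk("SERPINF1", 1.5), mk("CRP", 20.0), mk("SERPINF1", 2.0)]
        tall = tally_health(markers)
        # hand count: CRP under x2 -> relief x3 each; CRP over -> worsen x3;
        # SERPINF1 under -> R/W/R; SERPINF1 over x2 -> W/R/W
        assert (tall["atherogenesis"].k_a, tall["atherogenesis"].k_b) == (3, 3)
        assert (tall["atherosclerosis"].k_a, tall["atherosclerosis"].k_b) == (2, 4)
        assert (tall["atheroprotection"].k_a, tall["atheroprotection"].k_b) == (3, 3)
        for split in tall.values():
            assert split.n == len(markers)

    def test_all_relief_row(self, hub_annotations):
        markers = []
        from tatascan import AffinityEstimate, compare_kd
        from tatascan.snp_comparator import CandidateMarker, annotate_health

        for i in range(4):
            m = CandidateMarker(
                variant=SnpVariant(rsid=f"rs{i}", position=-9, ref="A", alt="G"),
                gene_symbol="CRP",
                transcript_id="CRP-201",
                ancestral=AffinityEstimate.from_nM(2.0, 0.2),
                minor=AffinityEstimate.from_nM(8.0, 0.8),
                comparison=compare_kd(2.0, 0.2, 8.0, 0.8),
            )
            markers.append(annotate_health(m, hub_annotations))
        tall = tally_health(markers)
        assert all((s.k_a, s.k_b) == (0, 4) for s in tall.values())
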