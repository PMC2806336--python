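"""Simulator determinism, fixture invariants, and frequency/label consistency."""

import numpy as np
import pytest

from trbrep.germline import Cluster, GermlineGene, LocusModel
from trbrep.pipeline import run_pipeline
from trbrep.simulate import (
    FixtureLocus,
    SimConfig,
    SimConfigError,
    fixture_anchor,
    make_fixture_locus,
    simulate,
)

ZERO_NOISE = dict(
    trim_v3=(0.5, 0),
    trim_d5=(0.5, 0),
    trim_d3=(0.5, 0),
    trim_j5=(0.35, 0),
    n_dist=("uniform", 0, 0),
    d_sub_rate=0.0,
    exon_swap_rate=0.0,
    recombinant_rate=0.0,
)


class TestFixtureLocus:
    def test_passes_all_locus_invariants(self, fixture_locus):
        locus = fixture_locus.locus
        assert locus.j_census() == {"1": 6, "3": 5, "2": 7}
        assert [c.cluster_id for c in locus.clusters_by_rank()] == ["1", "3", "2"]
        assert all(len(d.sequence) >= 12 for d in locus.genes("D"))

    def test_marker_census_is_12_exon1_plus_2_exon3(self, markers):
        blocks = markers.region_blocks()
        assert len(blocks["EX1"]) == 12
        assert len(blocks["EX3"]) == 2
        assert len(markers) == 14

    def test_two_alleles_per_isotype_pairwise_informative(self, alleles, markers):
        entries = list(alleles.items())
        assert len(entries) == 6
        boundary = len(markers.region_blocks()["EX1"])
        for i, (_, _, a) in enumerate(entries):
            for _, _, b in entries[i + 1 :]:
                assert a[:boundary] != b[:boundary]
                assert a[boundary:] != b[boundary:]

    def test_distinct_seeds_same_topology_different_sequences(self):
        f0, f1 = make_fixture_locus(0), make_fixture_locus(1)
        assert f0.locus.j_census() == f1.locus.j_census()
        assert [c.cluster_id for c in f0.locus.clusters] == [c.cluster_id for c in f1.locus.clusters]
        assert f0.locus.gene("TRBD1").sequence != f1.locus.gene("TRBD1").sequence

    def test_same_seed_identical(self):
        f0, f1 = make_fixture_locus(3), make_fixture_locus(3)
        assert all(
            f0.locus.gene(g.name).sequence == g.sequence for g in f1.locus.genes()
        )
        assert f0.alleles.alleles == f1.alleles.alleles


class TestDeterminism:
    def test_identical_config_gives_identical_bytes(self, fixture_locus):
        cfg = SimConfig(seed=9, n_transcripts=40)
        r1 = simulate(cfg, fixture_locus)
        r2 = simulate(cfg, fixture_locus)
        assert [t.sequence for t in r1.transcripts] == [t.sequence for t in r2.transcripts]
        assert r1.truth.equals(r2.truth)

    def test_different_seed_differs(self, fixture_locus):
        r1 = simulate(SimConfig(seed=9, n_transcripts=10), fixture_locus)
        r2 = simulate(SimConfig(seed=10, n_transcripts=10), fixture_locus)
        assert [t.sequence for t in r1.transcripts] != [t.sequence for t in r2.transcripts]


class TestConfigValidation:
    def test_mixtures_must_sum_to_one(self):
        with pytest.raises(SimConfigError):
            SimConfig(seed=1, rearrangement_mix=(0.5, 0.5, 0.5))

    def test_trans_classes_infeasible_on_single_cluster_locus(self):
        d = GermlineGene("TRBD1", "D", "1", "GATTACAGGCAT")
        j = GermlineGene("TRBJ1.1", "J", "1", "ACGTACGTACGTTTTGGAGCTGGCACCGTGACC")
        c = GermlineGene("TRBC1", "C", "1", "ATGGCCACC", exons=((0, 9),))
        locus = LocusModel(clusters=(Cluster("1", d, (j,), c, 1),))
        single = FixtureLocus(locus=locus, markers=None, alleles=None)
        cfg = SimConfig(
            seed=1,
            n_transcripts=5,
            rearrangement_mix=(0.9, 0.0, 0.1),
            splice_mix=(1.0, 0.0, 0.0),
        )
        with pytest.raises(SimConfigError, match="trans_rearrangement"):
            simulate(cfg, single)

    def test_zero_trans_probability_emits_no_trans_labels(self, fixture_locus):
        cfg = SimConfig(
            seed=4,
            n_transcripts=300,
            rearrangement_mix=(0.5, 0.5, 0.0),
            splice_mix=(0.8, 0.2, 0.0),
        )
        res = simulate(cfg, fixture_locus)
        assert not (res.truth.rearrangement_class == "trans_rearrangement").any()
        assert not (res.truth.splice_class == "trans_splice").any()


class TestTruthConsistency:
    def test_truth_parts_concatenate_to_the_junction(self, fixture_locus):
        res = simulate(SimConfig(seed=6, n_transcripts=100), fixture_locus)
        locus = fixture_locus.locus
        for _, row in res.truth.iterrows():
            j = locus.gene(row.j_gene)
            rebuilt = (
                "GCCAGCAGC" + row.v_retained + row.n1 + row.d_observed + row.n2
                + j.sequence[row.j_5_trim : 12]
            )
            assert rebuilt == row.junction

    def test_labels_respect_locus_topology(self, fixture_locus):
        res = simulate(SimConfig(seed=7, n_transcripts=200), fixture_locus)
        locus = fixture_locus.locus
        for _, row in res.truth.iterrows():
            dc, jc, cc = (
                locus.cluster_of(row.d_gene),
                locus.cluster_of(row.j_gene),
                locus.cluster_of(row.c_gene),
            )
            if row.rearrangement_class == "intra_cluster":
                assert dc == jc
            elif row.rearrangement_class == "inter_cluster":
                assert locus.upstream_of(dc, jc)
            else:
                assert locus.upstream_of(jc, dc)
            if row.splice_class == "canonical":
                assert cc == jc
            elif row.splice_class == "cis_splice":
                assert locus.upstream_of(jc, cc)
            else:
                assert locus.upstream_of(cc, jc)

    def test_nonproductive_fraction_generated_and_flagged(self, fixture_locus):
        cfg = SimConfig(seed=8, n_transcripts=200, nonproductive_rate=0.3)
        res = simulate(cfg, fixture_locus)
        frac = 1 - res.truth.productive.mean()
        assert 0.2 < frac < 0.4
        table, anns = run_pipeline(
            res.transcripts, fixture_locus.locus, fixture_anchor(), fixture_locus.markers
        )
        merged = table.merge(res.truth[["sequence_id", "productive"]], on="sequence_id",
                             suffixes=("", "_truth"))
        assert (merged.productive == merged.productive_truth).all()


class TestFrequencyRecovery:
    def test_class_mixtures_recovered_within_3_sigma(self, fixture_locus):
        cfg = SimConfig(seed=17, n_transcripts=2000)
        res = simulate(cfg, fixture_locus)
        n = len(res.truth)
        for cls, p in zip(
            ("intra_cluster", "inter_cluster", "trans_rearrangement"), cfg.rearrangement_mix
        ):
            f = (res.truth.rearrangement_class == cls).mean()
            assert abs(f - p) <= 3 * np.sqrt(p * (1 - p) / n), cls
        for cls, p in zip(("canonical", "cis_splice", "trans_splice"), cfg.splice_mix):
            f = (res.truth.splice_class == cls).mean()
            assert abs(f - p) <= 3 * np.sqrt(p * (1 - p) / n), cls


class TestZeroNoiseRoundTrip:
    def test_pipeline_reproduces_truth_on_every_field(self, fixture_locus):
        cfg = SimConfig(seed=2, n_transcripts=80, **ZERO_NOISE)
        res = simulate(cfg, fixture_locus)
        table, anns = run_pipeline(
            res.transcripts, fixture_locus.locus, fixture_anchor(), fixture_locus.markers
        )
        assert (table.status == "ok").all()
        merged = table.merge(res.truth, on="sequence_id", suffixes=("", "_t"))
        assert (merged.d_call == merged.d_gene).all()
        assert (merged.j_call == merged.j_gene).all()
        assert (merged.c_call == merged.c_gene).all()
        assert (merged.junction == merged.junction_t).all()
        assert (merged.rearrangement_class == merged.rearrangement_class_t).all()
        assert (merged.splice_class == merged.splice_class_t).all()
        assert (merged.c_vector == merged.c_vector_t).all()
        truth = res.truth.set_index("sequence_id")
        for a in anns:
            row = truth.loc[a.transcript_id]
            assert a.v_retained == row.v_retained
            assert a.n1 == row.n1 and a.n2 == row.n2
            assert a.d_call.five_prime_trim == row.d_5_trim
            assert a.d_call.three_prime_trim == row.d_3_trim
            assert a.j_five_prime_trim == row.j_5_trim
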