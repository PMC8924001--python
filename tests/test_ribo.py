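"""P-site offsets, periodicity, region RPKM and codon occupancy."""

import numpy as np
import pandas as pd
import pytest

from oracles import region_counts_by_position
from ribopes import (RiboProfile, TranscriptModel, codon_occupancy,
                     estimate_psite_offsets, periodicity_report,
                     quantify_regions, rpkm)
from ribopes.ribo import PSiteOffsetTable


def _model(u5=30, ncod=40, u3=30, seed=0):
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=u5 + 3 * ncod + u3))
    return TranscriptModel(transcript_id="T", gene_id="G", sequence=seq,
                           cds_start=u5, cds_end=u5 + 3 * ncod)


def _profile(model, placements, library_total=1000):
    """placements: {read_length: {five_prime_end: count}}"""
    counts = {}
    for L, pos_counts in placements.items():
        vec = np.zeros(model.length, dtype=np.int32)
        for pos, c in pos_counts.items():
            vec[pos] = c
        counts[L] = vec
    return RiboProfile(transcript_id=model.transcript_id, counts=counts,
                       library_total=library_total)


class TestOffsets:
    def test_single_read_defines_offset(self):
        model = _model()
        prof = _profile(model, {29: {model.cds_start - 13: 1}})
        table = estimate_psite_offsets([prof], {"T": model}, min_reads_per_length=1)
        assert table.offsets[29] == 13

    def test_tie_breaks_toward_smaller_offset(self):
        model = _model()
        prof = _profile(model, {30: {model.cds_start - 12: 100,
                                     model.cds_start - 13: 100}})
        table = estimate_psite_offsets([prof], {"T": model}, min_reads_per_length=1)
        assert table.offsets[30] == 12

    def test_sparse_length_inherits_global_mode(self):
        model = _model()
        prof = _profile(model, {30: {model.cds_start - 12: 500},
                                33: {model.cds_start - 14: 3}})
        table = estimate_psite_offsets([prof], {"T": model}, min_reads_per_length=50)
        assert table.offsets[30] == 12
        assert table.offsets[33] == table.global_offset == 12

    def test_planted_offsets_recovered_exactly(self, small_simulation):
        sim = small_simulation
        rpf = [p for (c, r, a), lib in sim["profiles"].items() if a == "rpf"
               for p in lib.values()]
        table = estimate_psite_offsets(rpf, sim["by_id"])
        assert table.offsets == sim["params"].offset_by_length

    def test_no_reads_in_window_is_an_error(self):
        model = _model()
        prof = _profile(model, {30: {model.cds_start + 60: 5}})
        with pytest.raises(ValueError, match="start-codon window"):
            estimate_psite_offsets([prof], {"T": model})


class TestPeriodicity:
    def test_all_frame0(self):
        model = _model()
        off = PSiteOffsetTable(offsets={30: 12}, global_offset=12)
        prof = _profile(model, {30: {model.cds_start + 3 * k - 12: 10
                                     for k in range(5)}})
        rep = periodicity_report([prof], off, {"T": model})
        assert rep.frame_fractions == (1.0, 0.0, 0.0)
        assert rep.region_percent["cds"] == pytest.approx(100.0)

    def test_uniform_positions_give_equal_frames(self):
        model = _model(ncod=200)
        off = PSiteOffsetTable(offsets={30: 12}, global_offset=12)
        vec = {30: {p - 12: 7 for p in range(model.cds_start, model.cds_end)}}
        rep = periodicity_report([_profile(model, vec)], off, {"T": model})
        assert rep.frame_fractions == pytest.approx((1 / 3, 1 / 3, 1 / 3))
        assert sum(rep.region_percent.values()) == pytest.approx(100.0)

    def test_frame_bias_recovered_within_3se(self, small_simulation):
        sim = small_simulation
        rpf = [p for (c, r, a), lib in sim["profiles"].items() if a == "rpf"
               for p in lib.values()]
        table = estimate_psite_offsets(rpf, sim["by_id"])
        rep = periodicity_report(rpf, table, sim["by_id"])
        f0_true = sim["params"].frame0_prob
        se = np.sqrt(f0_true * (1 - f0_true) / rep.n_psites_cds)
        assert abs(rep.frame_fractions[0] - f0_true) < 3 * se

    def test_invariant_to_sharding(self, small_simulation):
        sim = small_simulation
        lib = sim["profiles"][("wt", 1, "rpf")]
        rpf = list(lib.values())
        table = estimate_psite_offsets(rpf, sim["by_id"])
        whole = periodicity_report(rpf, table, sim["by_id"])
        half = len(rpf) // 2
        shard_counts = np.zeros(3)
        n = 0
        for shard in (rpf[:half], rpf[half:]):
            rep = periodicity_report(shard, table, sim["by_id"])
            shard_counts += np.array(rep.frame_fractions) * rep.n_psites_cds
            n += rep.n_psites_cds
        assert tuple(shard_counts / n) == pytest.approx(whole.frame_fractions)


class TestRegionQuant:
    def test_rpkm_arithmetic(self):
        assert rpkm(100, 1000, 1_000_000) == pytest.approx(100.0)
        assert np.isnan(rpkm(0, 0, 1_000_000))

    def test_all_zero_counts(self):
        model = _model()
        prof = _profile(model, {30: {}})
        df = quantify_regions([prof], None, {"T": model}, mode="rna_fragment")
        assert (df[["utr5_count", "cds_count", "utr3_count", "exon_count"]] == 0).all().all()
        assert (df[["exon_rpkm", "cds_rpkm"]] == 0).all().all()

    def test_counts_match_per_position_oracle_and_are_conserved(self, toy_models):
        rng = np.random.default_rng(99)
        by_id = {m.transcript_id: m for m in toy_models}
        offsets = PSiteOffsetTable(offsets={28: 11, 30: 12}, global_offset=12)
        profiles = []
        for m in toy_models:
            counts = {L: rng.poisson(0.3, size=m.length).astype(np.int32)
                      for L in (28, 30)}
            profiles.append(RiboProfile(m.transcript_id, counts, library_total=50_000))
        for mode, table in (("rpf_psite", offsets), ("rna_fragment", None)):
            df = quantify_regions(profiles, table, by_id, mode=mode,
                                  length_range=(25, 35))
            for prof in profiles:
                row = df[df["transcript_id"] == prof.transcript_id].iloc[0]
                expect = region_counts_by_position(prof, by_id[prof.transcript_id],
                                                   table)
                for region in ("utr5", "cds", "utr3"):
                    assert row[f"{region}_count"] == expect[region]
                assert (row["exon_count"]
                        == row["utr5_count"] + row["cds_count"] + row["utr3_count"])

    def test_zero_length_region_gives_nan_not_error(self):
        seq = "ATG" + "AAA" * 9 + "TAA" + "G" * 20
        model = TranscriptModel("T", "G", seq, cds_start=0, cds_end=33)
        prof = _profile(model, {30: {5: 4}})
        df = quantify_regions([prof], None, {"T": model}, mode="rna_fragment")
        assert np.isnan(df["utr5_rpkm"].iloc[0])
        assert df["cds_rpkm"].iloc[0] > 0


class TestCodonOccupancy:
    def test_uniform_coverage_is_flat(self):
        model = _model(ncod=64, seed=4)
        off = PSiteOffsetTable(offsets={30: 12}, global_offset=12)
        vec = {30: {model.cds_start + 3 * k - 12: 5 for k in range(model.n_codons)}}
        df = codon_occupancy([_profile(model, vec)], off, {"T": model}, site="P")
        present = df[df["usage_count"] > 0]
        assert np.allclose(present["occupancy"], 1.0)

    def test_a_site_shift_scores_next_codon(self):
        model = _model(ncod=40, seed=5)
        off = PSiteOffsetTable(offsets={30: 12}, global_offset=12)
        i = 7
        vec = {30: {model.cds_start + 3 * i - 12: 10}}
        prof = _profile(model, vec)
        seq = model.sequence
        a_codon = seq[model.cds_start + 3 * (i + 1): model.cds_start + 3 * (i + 2)]
        df = codon_occupancy([prof], off, {"T": model}, site="A", rescale=False)
        hit = df[df["site_count"] > 0]
        assert list(hit["codon"]) == [a_codon]

    def test_planted_dwell_recovered(self):
        # 3x dwell on AAA codons over an otherwise uniform profile
        model = _model(ncod=100, seed=6)
        off = PSiteOffsetTable(offsets={30: 12}, global_offset=12)
        seq = model.sequence
        placements = {}
        for k in range(model.n_codons):
            codon = seq[model.cds_start + 3 * k: model.cds_start + 3 * k + 3]
            placements[model.cds_start + 3 * k - 12] = 300 if codon == "AAA" else 100
        df = codon_occupancy([_profile(model, {30: placements})], off,
                             {"T": model}, site="P")
        occ = df.set_index("codon")["occupancy"]
        others = df[(df["usage_count"] > 0) & (df["codon"] != "AAA")]["occupancy"]
        assert occ["AAA"] / others.median() == pytest.approx(3.0, rel=0.01)
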