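"""Generator contracts: determinism, planted truth, and closed-form limits."""

import numpy as np
import pandas as pd
import pytest

from ribopes import (SimBindingParams, SimHDXParams, SimRiboParams,
                     SimTranscriptomeParams, classify_5prime_motif, fit_kd,
                     max_exchangeable, simulate_binding, simulate_hdx,
                     simulate_ribo_counts, simulate_transcriptome, substreams,
                     write_bed12, write_fasta)


class TestTranscriptome:
    def test_truth_table_matches_classifier(self):
        params = SimTranscriptomeParams(n_transcripts=300, pes_fraction=0.4, seed=7)
        models, truth = simulate_transcriptome(params)
        for model, row in zip(models, truth.itertuples()):
            assert classify_5prime_motif(model.utr5_sequence) == row.motif_class
        n_pes = truth["pes_flag"].sum()
        # Binomial(300, 0.4) within 5 sd of its mean
        assert abs(n_pes - 120) < 5 * np.sqrt(300 * 0.4 * 0.6)

    def test_zero_pes_fraction_plants_nothing(self):
        _, truth = simulate_transcriptome(
            SimTranscriptomeParams(n_transcripts=100, pes_fraction=0.0, seed=1))
        assert not truth["pes_flag"].any()
        assert not truth["top_flag"].any()

    def test_seed_gives_byte_identical_outputs(self, tmp_path):
        params = SimTranscriptomeParams(n_transcripts=40, seed=11)
        for tag in ("a", "b"):
            models, _ = simulate_transcriptome(params)
            write_fasta(models, tmp_path / f"{tag}.fasta")
            write_bed12(models, tmp_path / f"{tag}.bed")
        assert (tmp_path / "a.fasta").read_bytes() == (tmp_path / "b.fasta").read_bytes()
        assert (tmp_path / "a.bed").read_bytes() == (tmp_path / "b.bed").read_bytes()

    def test_cds_lengths_are_codon_multiples(self):
        models, _ = simulate_transcriptome(SimTranscriptomeParams(n_transcripts=50, seed=3))
        assert all((m.cds_end - m.cds_start) % 3 == 0 for m in models)

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError):
            SimTranscriptomeParams(utr5_length_range=(50, 20))


class TestRiboCounts:
    def test_pure_frame0_psites(self):
        models, truth = simulate_transcriptome(
            SimTranscriptomeParams(n_transcripts=20, seed=5))
        params = SimRiboParams(frame0_prob=1.0, depth_rpf=20_000, depth_rna=1_000,
                               replicates=1, seed=6)
        profiles, _ = simulate_ribo_counts(models, truth, params)
        by_id = {m.transcript_id: m for m in models}
        for prof in profiles[("wt", 1, "rpf")].values():
            model = by_id[prof.transcript_id]
            for L, vec in prof.counts.items():
                off = params.offset_by_length[L]
                for pos in np.nonzero(vec)[0]:
                    psite = pos + off
                    assert (psite - model.cds_start) % 3 == 0

    def test_te_effect_reflected_in_truth(self):
        models, truth = simulate_transcriptome(
            SimTranscriptomeParams(n_transcripts=400, pes_fraction=0.3, seed=8))
        _, te_truth = simulate_ribo_counts(
            models, truth, SimRiboParams(te_effect_on_pes=4.0, depth_rpf=1_000,
                                         depth_rna=1_000, replicates=1, seed=9))
        pes = te_truth["pes_flag"]
        ratio = (te_truth.loc[pes, "te_ko"].mean()
                 / te_truth.loc[~pes, "te_ko"].mean())
        base = (te_truth.loc[pes, "te_wt"].mean()
                / te_truth.loc[~pes, "te_wt"].mean())
        assert ratio / base == pytest.approx(4.0, rel=0.05)

    def test_empty_models_rejected(self):
        with pytest.raises(ValueError):
            simulate_ribo_counts([], pd.DataFrame(), SimRiboParams())

    def test_offset_exceeding_read_length_rejected(self):
        with pytest.raises(ValueError):
            SimRiboParams(read_length_dist={28: 1.0}, offset_by_length={28: 28})


class TestHdx:
    def test_zero_time_zero_uptake_without_noise(self):
        params = SimHDXParams(centroid_noise_sd=0.0, seed=2)
        state, _, _ = simulate_hdx(params)
        t0 = state[state["exposure_s"] == 0]
        merged = state.merge(
            t0[["peptide_start", "peptide_end", "sequence", "state",
                "centroid_mass_da"]],
            on=["peptide_start", "peptide_end", "sequence", "state"],
            suffixes=("", "_t0"))
        assert (merged.loc[merged["exposure_s"] == 0, "centroid_mass_da"]
                == merged.loc[merged["exposure_s"] == 0, "centroid_mass_da_t0"]).all()

    def test_no_protection_means_identical_states(self):
        params = SimHDXParams(protection_factor=1.0, centroid_noise_sd=0.0, seed=4)
        state, _, _ = simulate_hdx(params)
        wide = state.pivot_table(index=["peptide_start", "peptide_end", "sequence",
                                        "charge", "exposure_s"],
                                 columns="state", values="centroid_mass_da",
                                 aggfunc="first")
        assert np.allclose(wide["apo"], wide["ligand"])

    def test_long_time_limit_reaches_max_exchangeable(self):
        params = SimHDXParams(timepoints=(0.0, 1e12), centroid_noise_sd=0.0,
                              d2o_fraction=1.0, recovery=1.0,
                              protection_factor=1.0, seed=6)
        state, _, _ = simulate_hdx(params)
        for (s, e, seq), grp in state.groupby(["peptide_start", "peptide_end",
                                               "sequence"]):
            apo = grp[grp["state"] == "apo"].sort_values("exposure_s")
            uptake = apo["centroid_mass_da"].iloc[-1] - apo["centroid_mass_da"].iloc[0]
            assert uptake == pytest.approx(max_exchangeable(seq), abs=1e-6)

    def test_peptides_within_protein_bounds(self):
        _, protein, truth = simulate_hdx(SimHDXParams(seed=8))
        peps = truth["peptides"]
        assert (peps["peptide_start"] >= 1).all()
        assert (peps["peptide_end"] <= len(protein)).all()

    def test_timepoints_must_include_zero(self):
        with pytest.raises(ValueError):
            SimHDXParams(timepoints=(30.0, 300.0))


class TestBinding:
    def test_half_saturation_at_kd(self):
        params = SimBindingParams(kd_true=2.0, conc_grid=(0.5, 1.0, 2.0, 8.0),
                                  noise_sd=0.0, replicates=1, seed=1)
        curve = simulate_binding(params)
        at_kd = curve[curve["concentration_um"] == 2.0]["fraction_bound"].iloc[0]
        assert at_kd == pytest.approx(0.5)

    def test_saturation_limit(self):
        params = SimBindingParams(kd_true=0.01, conc_grid=(1.0, 10.0, 100.0, 1e6),
                                  noise_sd=0.0, replicates=1, seed=1)
        curve = simulate_binding(params)
        assert curve["fraction_bound"].iloc[-1] == pytest.approx(1.0, abs=1e-4)

    def test_noiseless_roundtrip_through_fit(self):
        params = SimBindingParams(kd_true=2.0, noise_sd=0.0, replicates=1, seed=3)
        curve = simulate_binding(params)
        fit = fit_kd(curve["concentration_um"], curve["fraction_bound"])
        assert fit.verdict == "binding"
        assert fit.kd_um == pytest.approx(2.0, rel=1e-6)

    def test_unsorted_grid_rejected(self):
        with pytest.raises(ValueError):
            SimBindingParams(conc_grid=(2.0, 1.0, 4.0, 8.0))


def test_substreams_are_deterministic_and_distinct():
    a = substreams(17)
    b = substreams(17)
    assert a == b
    assert len(set(a)) == len(a)
    assert all(0 <= s < 2**31 for s in a)
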