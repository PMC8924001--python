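"""Deuterium uptake, differential thresholds and residue-level aggregation."""

import numpy as np
import pandas as pd
import pytest

from oracles import residue_map_brute_force
from ribopes import (SimHDXParams, compute_uptake, differential_uptake,
                     hdx_qc, max_exchangeable, normalize_uptake,
                     read_state_table, residue_delta_map, simulate_hdx)


class TestMaxExchangeable:
    @pytest.mark.parametrize("seq,expected", [
        ("ACDEFGHIKL", 8),    # len-2, no proline
        ("ACDPFG", 3),        # P at position 4 counts
        ("APCDEF", 4),        # P inside the excluded two-residue prefix
        ("PPP", 0),
    ])
    def test_counting_rule(self, seq, expected):
        assert max_exchangeable(seq) == expected

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            max_exchangeable("AC")


class TestUptake:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["peptide_start", "peptide_end",
                                           "sequence", "state", "exposure_s",
                                           "centroid_mass_da"])

    def test_uptake_is_mass_difference(self):
        df = self._table([
            (1, 10, "ACDEFGHIKL", "apo", 0, 1542.20),
            (1, 10, "ACDEFGHIKL", "apo", 300, 1545.20),
        ])
        up = compute_uptake(read_state_table(df))
        assert up[up["exposure_s"] == 300]["uptake_da"].iloc[0] == pytest.approx(3.00)
        assert up[up["exposure_s"] == 0]["uptake_da"].iloc[0] == 0.0

    def test_missing_t0_drops_peptide(self):
        df = self._table([(1, 10, "ACDEFGHIKL", "apo", 300, 1545.2)])
        up = compute_uptake(read_state_table(df))
        assert up.empty

    def test_negative_uptake_retained_and_flagged(self):
        df = self._table([
            (1, 10, "ACDEFGHIKL", "apo", 0, 1542.2),
            (1, 10, "ACDEFGHIKL", "apo", 30, 1541.9),
        ])
        up = compute_uptake(read_state_table(df))
        row = up[up["exposure_s"] == 30].iloc[0]
        assert row["uptake_da"] == pytest.approx(-0.3)
        assert bool(row["below_zero"])

    def test_rt_window_collapses_duplicates(self):
        df = self._table([
            (1, 10, "ACDEFGHIKL", "apo", 0, 1542.0),
            (1, 10, "ACDEFGHIKL", "apo", 0, 1542.4),
        ])
        df["retention_time_min"] = [5.0, 5.3]
        st = read_state_table(df)
        assert len(st) == 1
        assert st["centroid_mass_da"].iloc[0] == pytest.approx(1542.2)


class TestNormalize:
    def test_arithmetic(self):
        assert normalize_uptake(3.2, "ACDEFGHIKL", 1.0, 0.8) == pytest.approx(0.5)
        assert normalize_uptake(0.0, "ACDEFGHIKL") == 0.0
        assert normalize_uptake(4.0, "ACDEFGHIKL", 1.0, 1.0) == pytest.approx(0.5)

    def test_no_exchangeable_is_nan(self):
        assert np.isnan(normalize_uptake(1.0, "APP"))

    def test_invalid_recovery_rejected(self):
        with pytest.raises(ValueError):
            normalize_uptake(1.0, "ACDEFGHIKL", recovery=0.0)


class TestDifferential:
    def _uptake(self, deltas):
        rows = []
        for t, (a, l) in deltas.items():
            for state, v in (("apo", a), ("ligand", l)):
                rows.append({"peptide_id": "1-10:X", "peptide_start": 1,
                             "peptide_end": 10, "sequence": "ACDEFGHIKL",
                             "state": state, "exposure_s": t, "uptake_da": v})
        return pd.DataFrame(rows)

    @pytest.mark.parametrize("delta,expected", [
        (-0.6, "protected"), (0.3, "ns"), (0.7, "exposed"),
        (-0.5, "protected"), (0.5, "exposed"), (-0.49, "ns"),
    ])
    def test_threshold_rule(self, delta, expected):
        up = self._uptake({0: (0.0, 0.0), 300: (2.0, 2.0 + delta)})
        d = differential_uptake(up)
        call = d[d["exposure_s"] == 300]["significance"].iloc[0]
        assert call == expected

    def test_max_uptake_difference(self):
        up = self._uptake({0: (0.0, 0.0), 300: (2.0, 1.0), 3000: (4.0, 2.5)})
        d = differential_uptake(up)
        assert d[d["exposure_s"] == "max"]["delta_da"].iloc[0] == pytest.approx(-1.5)


class TestResidueMap:
    def test_single_peptide_paints_competent_residues(self):
        protein = "A" * 30
        deltas = pd.DataFrame([{"peptide_id": "p1", "peptide_start": 5,
                                "peptide_end": 15, "sequence": protein[4:15],
                                "exposure_s": "max", "delta_da": -1.0}])
        rmap = residue_delta_map(deltas, protein, smoothing_window=1)
        vals = rmap.raw_values["max"]
        assert np.allclose(vals.loc[7:15], -1.0)
        assert vals.loc[[5, 6]].isna().all()
        assert vals.loc[16:].isna().all()
        assert (rmap.calls.loc[7:15, "max"] == "protected").all()
        assert (rmap.calls.loc[16:, "max"] == "uncovered").all()

    def test_overlap_takes_unweighted_mean(self):
        protein = "A" * 40
        deltas = pd.DataFrame([
            {"peptide_id": "p1", "peptide_start": 5, "peptide_end": 20,
             "sequence": protein[4:20], "exposure_s": "max", "delta_da": -1.0},
            {"peptide_id": "p2", "peptide_start": 10, "peptide_end": 25,
             "sequence": protein[9:25], "exposure_s": "max", "delta_da": 0.0},
        ])
        rmap = residue_delta_map(deltas, protein, smoothing_window=1)
        assert np.allclose(rmap.raw_values["max"].loc[12:20], -0.5)

    def test_prolines_stay_blank(self):
        protein = "AAAAAAAPAAAAAAA"
        deltas = pd.DataFrame([{"peptide_id": "p1", "peptide_start": 1,
                                "peptide_end": 15, "sequence": protein,
                                "exposure_s": "max", "delta_da": -2.0}])
        rmap = residue_delta_map(deltas, protein, smoothing_window=1)
        assert np.isnan(rmap.raw_values["max"].loc[8])
        assert rmap.calls.loc[8, "max"] == "uncovered"

    def test_matches_brute_force_on_random_maps(self):
        rng = np.random.default_rng(31)
        protein = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=200))
        rows = []
        for i in range(50):
            start = int(rng.integers(1, 190))
            end = min(200, start + int(rng.integers(5, 25)))
            for t in (30.0, 300.0, "max"):
                rows.append({"peptide_id": f"p{i}", "peptide_start": start,
                             "peptide_end": end, "sequence": protein[start - 1:end],
                             "exposure_s": t,
                             "delta_da": float(rng.normal(0, 1))})
        deltas = pd.DataFrame(rows)
        rmap = residue_delta_map(deltas, protein, smoothing_window=1)
        for col in (30.0, 300.0, "max"):
            expect = residue_map_brute_force(deltas, protein, col)
            got = rmap.raw_values[col].to_numpy()
            assert np.allclose(got, expect, equal_nan=True)

    def test_even_smoothing_window_rejected(self):
        with pytest.raises(ValueError):
            residue_delta_map(pd.DataFrame(columns=["peptide_id", "peptide_start",
                                                    "peptide_end", "exposure_s",
                                                    "delta_da"]),
                              "AAAA", smoothing_window=4)


class TestQc:
    def test_half_covered_protein(self):
        peps = pd.DataFrame({"peptide_start": [1], "peptide_end": [50]})
        qc = hdx_qc(peps, 100)
        assert qc.sequence_coverage == pytest.approx(50.0)
        assert qc.redundancy == pytest.approx(1.0)
        assert qc.mean_length == 50.0

    def test_duplicate_peptide_doubles_redundancy(self):
        peps = pd.DataFrame({"peptide_start": [1, 1], "peptide_end": [50, 50]})
        assert hdx_qc(peps, 100).redundancy == pytest.approx(2.0)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(7)
        starts = rng.integers(1, 80, 30)
        peps = pd.DataFrame({"peptide_start": starts,
                             "peptide_end": starts + rng.integers(5, 20, 30)})
        a = hdx_qc(peps, 100)
        b = hdx_qc(peps.sample(frac=1, random_state=3), 100)
        assert a == b

    def test_simulated_map_hits_target_redundancy(self):
        params = SimHDXParams(target_redundancy=7.0, seed=19)
        _, protein, truth = simulate_hdx(params)
        qc = hdx_qc(truth["peptides"], len(protein))
        assert qc.redundancy == pytest.approx(7.0, rel=0.10)


def test_end_to_end_protection_recovery():
    """Zero-noise planted protection is detected inside the planted interval."""
    params = SimHDXParams(protein_length=120, protected_interval=(40, 70),
                          protection_factor=0.1, centroid_noise_sd=0.0,
                          low_confidence_fraction=0.0, seed=23)
    state, protein, truth = simulate_hdx(params)
    up = compute_uptake(read_state_table(state))
    deltas = differential_uptake(up)
    # every significantly protected peptide overlaps the planted interval
    prot = deltas[(deltas["significance"] == "protected")]
    lo, hi = truth["protected_interval"]
    assert len(prot) > 0
    assert ((prot["peptide_end"] >= lo) & (prot["peptide_start"] + 2 <= hi)).all()
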