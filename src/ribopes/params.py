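"""Parameter blocks for the simulators and the translatome classifier.

Pydantic models double as the YAML-config schema: unknown keys are rejected
and the field validators encode the invariants each stage relies on.
Defaults are the study conditions of the analyses the package reimplements
(e.g. HDX labelling timepoints 0/30/300/1000/3000/9000 s, 80% deuterium
recovery, a binding-concentration grid spanning 0.5-60 uM).
"""

from __future__ import annotations

import math
from typing import Sequence

from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator


class _Params(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


def _check_range(rng: tuple[int, int], name: str) -> None:
    lo, hi = rng
    if lo > hi or lo < 0:
        raise ValueError(f"{name} is a degenerate interval: {rng}")


class SimTranscriptomeParams(_Params):
    """Synthetic one-transcript-per-gene annotation with planted 5' motifs."""

    n_transcripts: int = Field(1000, gt=0)
    utr5_length_range: tuple[int, int] = (20, 150)
    cds_codons_range: tuple[int, int] = (100, 400)
    utr3_length_range: tuple[int, int] = (30, 200)
    gc_background: float = Field(0.5, ge=0.0, le=1.0)
    pes_fraction: float = Field(0.15, ge=0.0, le=1.0)
    top_fraction_of_pes: float = Field(0.5, ge=0.0, le=1.0)
    seed: int = 0

    @model_validator(mode="after")
    def _ranges(self):
        _check_range(self.utr5_length_range, "utr5_length_range")
        _check_range(self.cds_codons_range, "cds_codons_range")
        _check_range(self.utr3_length_range, "utr3_length_range")
        if self.cds_codons_range[0] < 2:
            raise ValueError("cds_codons_range must allow start+stop (>= 2 codons)")
        if self.utr5_length_range[0] < 15:
            raise ValueError("utr5_length_range minimum must be >= 15 nt so a "
                             "pyrimidine motif can be planted within the first 10 nt")
        return self


# read-length distribution and offsets typical of 26-34 nt footprints
_DEFAULT_LENGTH_DIST = {
    26: 0.03, 27: 0.07, 28: 0.15, 29: 0.22, 30: 0.22,
    31: 0.15, 32: 0.09, 33: 0.05, 34: 0.02,
}
_DEFAULT_OFFSETS = {26: 10, 27: 10, 28: 11, 29: 12, 30: 12, 31: 13, 32: 13, 33: 13, 34: 14}


class SimRiboParams(_Params):
    """Footprint + total-RNA count generator with planted TE effects.

    ``te_effect_on_pes`` multiplies the translational efficiency of
    PES-bearing transcripts in the perturbed condition; ``start_codon_boost``
    is the relative ribosome dwell at the initiation codon (an initiation
    peak is what makes metagene offset estimation identifiable).
    """

    conditions: tuple[str, str] = ("wt", "ko")
    abundance_log_mean: float = 3.0
    abundance_log_sd: float = Field(1.0, ge=0.0)
    base_te_log_mean: float = 0.0
    base_te_log_sd: float = Field(0.35, ge=0.0)
    te_effect_on_pes: float = Field(1.0, gt=0.0)
    read_length_dist: dict[int, float] = Field(default_factory=lambda: dict(_DEFAULT_LENGTH_DIST))
    offset_by_length: dict[int, int] = Field(default_factory=lambda: dict(_DEFAULT_OFFSETS))
    frame0_prob: float = Field(0.9, ge=0.0, le=1.0)
    start_codon_boost: float = Field(5.0, ge=1.0)
    depth_rpf: int = Field(2_000_000, gt=0)
    depth_rna: int = Field(2_000_000, gt=0)
    replicates: int = Field(2, gt=0)
    seed: int = 0

    @model_validator(mode="after")
    def _dists(self):
        total = sum(self.read_length_dist.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"read-length probabilities sum to {total}, not 1")
        for L in self.read_length_dist:
            if L not in self.offset_by_length:
                raise ValueError(f"no P-site offset for read length {L}")
        for L, off in self.offset_by_length.items():
            if not 1 <= off <= L - 1:
                raise ValueError(f"offset {off} outside [1, {L - 1}] for length {L}")
        return self


class SimHDXParams(_Params):
    """Exponential-kinetics deuterium uptake with a planted protection footprint."""

    protein_length: int = Field(200, gt=0)
    peptide_mean_length: float = Field(14.6, gt=0)
    peptide_sd_length: float = Field(7.9, ge=0)
    target_redundancy: float = Field(6.9, gt=0)
    timepoints: tuple[float, ...] = (0.0, 30.0, 300.0, 1000.0, 3000.0, 9000.0)
    protected_interval: tuple[int, int] = (60, 90)  # 1-based inclusive residues
    protection_factor: float = Field(0.1, gt=0.0, le=1.0)
    rate_log_mean: float = -6.9  # ln s^-1; median intrinsic rate ~1e-3 s^-1, mid-grid
    rate_log_sd: float = Field(1.0, ge=0.0)
    centroid_noise_sd: float = Field(0.05, ge=0.0)
    d2o_fraction: float = Field(0.83, gt=0.0, le=1.0)
    recovery: float = Field(0.8, gt=0.0, le=1.0)
    low_confidence_fraction: float = Field(0.05, ge=0.0, le=1.0)
    seed: int = 0

    @model_validator(mode="after")
    def _bounds(self):
        if 0.0 not in self.timepoints:
            raise ValueError("timepoints must include 0")
        if tuple(self.timepoints) != tuple(sorted(self.timepoints)):
            raise ValueError("timepoints must be sorted")
        lo, hi = self.protected_interval
        if not (1 <= lo <= hi <= self.protein_length):
            raise ValueError("protected_interval outside protein bounds")
        return self


def _default_conc_grid() -> tuple[float, ...]:
    # 12 log-spaced points over 0.5-60 uM
    return tuple(round(0.5 * (60 / 0.5) ** (i / 11), 4) for i in range(12))


class SimBindingParams(_Params):
    """Hyperbolic one-site binding curves with Gaussian noise on fractions."""

    kd_true: float = Field(2.0, gt=0.0)  # uM
    conc_grid: tuple[float, ...] = Field(default_factory=_default_conc_grid)
    noise_sd: float = Field(0.02, ge=0.0)
    replicates: int = Field(3, gt=0)
    seed: int = 0

    @model_validator(mode="after")
    def _grid(self):
        g = self.conc_grid
        if any(c <= 0 for c in g):
            raise ValueError("concentrations must be strictly positive")
        if tuple(g) != tuple(sorted(g)):
            raise ValueError("concentrations must be sorted ascending")
        return self


class ThresholdSet(_Params):
    """Differential-translation cutoffs (strict inequalities as printed)."""

    min_log2fc_te: float = Field(1.0, gt=0)
    max_abs_log2fc_mrna: float = Field(1.0, gt=0)
    max_fdr: float = Field(0.2, gt=0)
    pseudocount: float = Field(0.5, gt=0)
    min_counts: int = Field(10, gt=0)


__all__: Sequence[str] = [
    "SimTranscriptomeParams",
    "SimRiboParams",
    "SimHDXParams",
    "SimBindingParams",
    "ThresholdSet",
]
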