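"""Ribosome-profiling core: P-site offsets, periodicity QC, region RPKM, codon occupancy.

The P-site offset for each footprint length is estimated by the metagene-mode
method: over all transcripts, footprints whose 5' end falls in a window
immediately upstream of the start codon vote with the distance
``cds_start - five_prime_end``; the modal distance is the offset (ties break
toward the smaller offset, lengths with too few votes inherit the global
modal offset).  P-site position is then ``five_prime_end + offset`` and the
reading frame is ``(psite - cds_start) mod 3``.

Region densities are RPKM: reads per kilobase of region per million mapped
reads of the library; footprints are assigned to the region containing their
P-site, total-RNA fragments to the region containing their 5' end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

from .annotation import TranscriptModel

logger = logging.getLogger(__name__)

DEFAULT_OFFSET_WINDOW = 30
DEFAULT_MIN_READS_PER_LENGTH = 50
DEFAULT_READ_LENGTH_RANGE = (25, 35)

SITE_SHIFTS = {"E": -3, "P": 0, "A": +3}


@dataclass
class RiboProfile:
    """Per-transcript 5'-end count vectors, keyed by read length."""

    transcript_id: str
    counts: dict[int, np.ndarray]
    library_total: int

    def __post_init__(self) -> None:
        for L, vec in self.counts.items():
            if np.any(vec < 0):
                raise ValueError(f"{self.transcript_id}: negative counts at length {L}")

    @property
    def length(self) -> int:
        return len(next(iter(self.counts.values())))

    def total(self) -> int:
        return int(sum(int(v.sum()) for v in self.counts.values()))


@dataclass(frozen=True)
class PSiteOffsetTable:
    """Mapping read length -> P-site offset (nt from 5' end), plus fallback."""

    offsets: Mapping[int, int]
    global_offset: int
    votes: Mapping[int, int] = field(default_factory=dict)

    def get(self, read_length: int) -> int:
        return self.offsets.get(read_length, self.global_offset)


@dataclass(frozen=True)
class PeriodicityReport:
    frame_fractions: tuple[float, float, float]
    region_percent: Mapping[str, float]  # percent of P-sites in utr5/cds/utr3
    n_psites_cds: int


def _restrict_lengths(profile: RiboProfile,
                      length_range: tuple[int, int]) -> dict[int, np.ndarray]:
    lo, hi = length_range
    return {L: v for L, v in profile.counts.items() if lo <= L <= hi}


def estimate_psite_offsets(
    profiles: Iterable[RiboProfile],
    models: Mapping[str, TranscriptModel],
    offset_window: int = DEFAULT_OFFSET_WINDOW,
    min_reads_per_length: int = DEFAULT_MIN_READS_PER_LENGTH,
    length_range: tuple[int, int] = DEFAULT_READ_LENGTH_RANGE,
) -> PSiteOffsetTable:
    """Metagene-mode P-site offset per read length.

    For each length L the histogram over d = cds_start - five_prime_end,
    d in [1, min(offset_window, L-1)], is accumulated across transcripts;
    the mode wins, ties break toward smaller d.
    """
    hist: dict[int, np.ndarray] = {}
    for profile in profiles:
        model = models.get(profile.transcript_id)
        if model is None:
            continue
        cs = model.cds_start
        for L, vec in _restrict_lengths(profile, length_range).items():
            dmax = min(offset_window, L - 1)
            h = hist.setdefault(L, np.zeros(offset_window + 1, dtype=np.int64))
            lo = max(0, cs - dmax)
            window = vec[lo:cs]
            if window.size:
                # distance d = cs - position, position in [cs-dmax, cs)
                d = cs - np.arange(lo, cs)
                np.add.at(h, d, window)

    if not hist or all(h.sum() == 0 for h in hist.values()):
        raise ValueError(
            "no reads found in any start-codon window; offsets cannot be "
            "estimated (verify inputs on a synthetic control)"
        )

    pooled = np.zeros(max(h.size for h in hist.values()), dtype=np.int64)
    for h in hist.values():
        pooled[: h.size] += h
    global_offset = int(np.argmax(pooled[1:]) + 1)  # argmax takes first (smallest) on ties

    offsets: dict[int, int] = {}
    votes: dict[int, int] = {}
    for L, h in sorted(hist.items()):
        n = int(h[1:].sum())
        votes[L] = n
        if n >= min_reads_per_length:
            offsets[L] = int(np.argmax(h[1:]) + 1)
        else:
            offsets[L] = global_offset
            logger.info("read length %d has %d in-window reads (<%d); using global offset %d",
                        L, n, min_reads_per_length, global_offset)
    return PSiteOffsetTable(offsets=offsets, global_offset=global_offset, votes=votes)


def periodicity_report(
    profiles: Iterable[RiboProfile],
    offsets: PSiteOffsetTable,
    models: Mapping[str, TranscriptModel],
    length_range: tuple[int, int] = DEFAULT_READ_LENGTH_RANGE,
) -> PeriodicityReport:
    """Frame fractions over CDS-internal P-sites and region occupancy percentages."""
    frame_counts = np.zeros(3, dtype=np.int64)
    region_counts = {"utr5": 0, "cds": 0, "utr3": 0}
    for profile in profiles:
        model = models.get(profile.transcript_id)
        if model is None:
            continue
        cs, ce, n = model.cds_start, model.cds_end, model.length
        for L, vec in _restrict_lengths(profile, length_range).items():
            off = offsets.get(L)
            nz = np.nonzero(vec)[0]
            if nz.size == 0:
                continue
            psites = nz + off
            weights = vec[nz]
            ok = psites < n
            psites, weights = psites[ok], weights[ok]
            in_utr5 = psites < cs
            in_cds = (psites >= cs) & (psites < ce)
            region_counts["utr5"] += int(weights[in_utr5].sum())
            region_counts["cds"] += int(weights[in_cds].sum())
            region_counts["utr3"] += int(weights[~(in_utr5 | in_cds)].sum())
            frames = (psites[in_cds] - cs) % 3
            np.add.at(frame_counts, frames, weights[in_cds])

    total_cds = int(frame_counts.sum())
    if total_cds == 0:
        logger.warning("no CDS-internal P-sites; periodicity undefined")
        return PeriodicityReport((np.nan, np.nan, np.nan),
                                 {k: np.nan for k in region_counts}, 0)
    fractions = tuple(float(c) / total_cds for c in frame_counts)
    total_regions = sum(region_counts.values())
    percent = {k: 100.0 * v / total_regions for k, v in region_counts.items()}
    return PeriodicityReport(fractions, percent, total_cds)


REGIONS = ("exon", "utr5", "cds", "utr3")


def quantify_regions(
    profiles: Iterable[RiboProfile],
    offsets: PSiteOffsetTable | None,
    models: Mapping[str, TranscriptModel],
    mode: Literal["rpf_psite", "rna_fragment"],
    length_range: tuple[int, int] = DEFAULT_READ_LENGTH_RANGE,
) -> pd.DataFrame:
    """Per-transcript counts and RPKM for exon (whole transcript), UTR5, CDS, UTR3.

    ``rpf_psite`` assigns each read to the region containing its P-site
    (requires an offset table); ``rna_fragment`` assigns by 5' end and
    ignores read length.  Zero-length regions get RPKM = NaN.
    """
    if mode == "rpf_psite" and offsets is None:
        raise ValueError("rpf_psite mode requires a P-site offset table")

    rows = []
    for profile in profiles:
        model = models.get(profile.transcript_id)
        if model is None:
            continue
        cs, ce, n = model.cds_start, model.cds_end, model.length
        counts = {"utr5": 0, "cds": 0, "utr3": 0}
        if mode == "rpf_psite":
            items = _restrict_lengths(profile, length_range).items()
        else:
            items = profile.counts.items()
        for L, vec in items:
            nz = np.nonzero(vec)[0]
            if nz.size == 0:
                continue
            pos = nz + (offsets.get(L) if mode == "rpf_psite" else 0)
            w = vec[nz]
            ok = pos < n
            pos, w = pos[ok], w[ok]
            counts["utr5"] += int(w[pos < cs].sum())
            counts["cds"] += int(w[(pos >= cs) & (pos < ce)].sum())
            counts["utr3"] += int(w[pos >= ce].sum())
        row = {
            "transcript_id": profile.transcript_id,
            "library_total": profile.library_total,
            "exon_length": n, "utr5_length": cs,
            "cds_length": ce - cs, "utr3_length": n - ce,
            "utr5_count": counts["utr5"], "cds_count": counts["cds"],
            "utr3_count": counts["utr3"],
            "exon_count": counts["utr5"] + counts["cds"] + counts["utr3"],
        }
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    for region in REGIONS:
        df[f"{region}_rpkm"] = rpkm(df[f"{region}_count"], df[f"{region}_length"],
                                    df["library_total"])
    return df


def rpkm(count, region_length_nt, library_total):
    """Reads per kilobase of region per million mapped reads (NaN for empty regions)."""
    length_kb = np.asarray(region_length_nt, dtype=float) / 1e3
    millions = np.asarray(library_total, dtype=float) / 1e6
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.asarray(count, dtype=float) / (length_kb * millions)
    return np.where(length_kb > 0, out, np.nan)


def codon_occupancy(
    profiles: Iterable[RiboProfile],
    offsets: PSiteOffsetTable,
    models: Mapping[str, TranscriptModel],
    site: Literal["E", "P", "A"] = "P",
    rescale: bool = True,
    length_range: tuple[int, int] = DEFAULT_READ_LENGTH_RANGE,
) -> pd.DataFrame:
    """Codon occupancy for the E, P or A site.

    The site codon is the codon containing ``psite + shift`` (E = -3 nt,
    P = 0, A = +3 nt).  Occupancy is the site count divided by the codon's
    usage frequency across the analyzed CDS regions, optionally rescaled to
    mean 1 over observed codons; codons absent from the CDSs are NaN.
    """
    if site not in SITE_SHIFTS:
        raise ValueError(f"site must be one of {sorted(SITE_SHIFTS)}")
    shift = SITE_SHIFTS[site]

    bases = "ACGT"
    codons = [a + b + c for a in bases for b in bases for c in bases]
    codon_index = {c: i for i, c in enumerate(codons)}
    site_counts = np.zeros(64, dtype=np.int64)
    usage = np.zeros(64, dtype=np.int64)

    models_seen: dict[str, np.ndarray] = {}
    for profile in profiles:
        model = models.get(profile.transcript_id)
        if model is None:
            continue
        cs, ce = model.cds_start, model.cds_end
        seq = model.sequence.upper().replace("U", "T")
        codon_ids = models_seen.get(model.transcript_id)
        if codon_ids is None:
            codon_ids = np.array(
                [codon_index.get(seq[i : i + 3], -1) for i in range(cs, ce, 3)],
                dtype=np.int64,
            )
            models_seen[model.transcript_id] = codon_ids
            np.add.at(usage, codon_ids[codon_ids >= 0], 1)
        for L, vec in _restrict_lengths(profile, length_range).items():
            off = offsets.get(L)
            nz = np.nonzero(vec)[0]
            if nz.size == 0:
                continue
            spos = nz + off + shift
            w = vec[nz]
            ok = (spos >= cs) & (spos < ce)
            ids = codon_ids[(spos[ok] - cs) // 3]
            keep = ids >= 0
            np.add.at(site_counts, ids[keep], w[ok][keep])

    total_usage = usage.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        usage_freq = usage / total_usage if total_usage else np.full(64, np.nan)
        occ = np.where(usage > 0, site_counts / np.where(usage_freq > 0, usage_freq, np.nan), np.nan)
    if rescale:
        mean = np.nanmean(occ[usage > 0]) if (usage > 0).any() else np.nan
        if mean and np.isfinite(mean) and mean > 0:
            occ = occ / mean
    return pd.DataFrame({
        "codon": codons, "site": site, "site_count": site_counts,
        "usage_count": usage, "occupancy": occ,
    })
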