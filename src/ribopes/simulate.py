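"""Seeded synthetic-data generators with planted ground truth.

Every input class the pipeline consumes can be generated here: a
one-transcript-per-gene annotation with pyrimidine motifs planted at known
transcripts, footprint and total-RNA count profiles with length-dependent
P-site offsets, frame bias and condition-specific TE effects, exponential-
kinetics deuterium-uptake tables with a planted protection footprint, and
hyperbolic binding curves.  Each generator is deterministic under its seed
(numpy Generator streams; identical outputs across platforms for a fixed
numpy major version), and each returns its truth table alongside the data so
parameter-recovery tests can compare estimate against plant.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.SeqUtils import molecular_weight

from .annotation import TranscriptModel
from .motifs import DEFAULT_MIN_RUN, DEFAULT_WINDOW, classify_5prime_motif
from .params import (SimBindingParams, SimHDXParams, SimRiboParams,
                     SimTranscriptomeParams)
from .ribo import RiboProfile

RNA_FRAGMENT_LENGTH = 50  # nominal length key for total-RNA fragment profiles

_NT = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")
_PURINES = "AG"
_PYR = "CT"

# amino-acid alphabet with a realistic proline share for HDX proteins
_AA = np.array(list("ACDEFGHIKLMNQRSTVWY" + "P"))
_AA_P = np.full(20, 0.05)


def substreams(seed: int, n: int = 4) -> list[int]:
    """Expand one global seed into independent per-stage child seeds (< 2**31)."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def _random_nt(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_NT[rng.choice(4, size=n, p=p)])


def _plant_prefix(rng: np.random.Generator, utr: str, kind: str,
                  window: int = DEFAULT_WINDOW, min_run: int = DEFAULT_MIN_RUN) -> str:
    """Rewrite the start of a UTR so its motif class equals ``kind``."""
    n = len(utr)
    for _ in range(200):
        if kind == "none":
            cand = utr
        elif kind == "TOP":
            run = int(rng.integers(min_run, min_run + 6))
            run = min(run, n)
            body = "C" + "".join(rng.choice(list(_PYR), size=run - 1))
            term = "" if run >= n else rng.choice(list(_PURINES))
            cand = (body + term + utr[len(body) + len(term):])[:n]
        else:  # PES_non_TOP: run starts strictly after position 1
            max_start = min(window - 1, n - min_run)
            start = int(rng.integers(1, max_start + 1))
            run = int(rng.integers(min_run, min_run + 6))
            run = min(run, n - start)
            prefix = "".join(rng.choice(list(_PURINES), size=start))
            body = "".join(rng.choice(list(_PYR), size=run))
            term = "" if start + run >= n else rng.choice(list(_PURINES))
            cand = (prefix + body + term + utr[start + run + len(term):])[:n]
        if classify_5prime_motif(cand, window=window, min_run=min_run) == kind:
            return cand
        utr = _shuffle_prefix(rng, utr, window + min_run)
    raise RuntimeError(f"could not plant motif class {kind!r}")


def _shuffle_prefix(rng: np.random.Generator, utr: str, k: int) -> str:
    k = min(k, len(utr))
    fresh = "".join(_NT[rng.integers(0, 4, size=k)])
    return fresh + utr[k:]


def simulate_transcriptome(
    params: SimTranscriptomeParams,
) -> tuple[list[TranscriptModel], pd.DataFrame]:
    """Generate transcript models plus a truth table of planted motif flags.

    PES-flagged transcripts carry a pyrimidine run satisfying the default
    classifier rule within their first 10 UTR nt; non-flagged transcripts are
    rejection-sampled until they carry none, so the truth table matches the
    classifier output exactly by construction.
    """
    rng = np.random.default_rng(params.seed)
    models = []
    rows = []
    for i in range(params.n_transcripts):
        tx_id = f"TX{i:05d}"
        gene_id = f"G{i:05d}"
        u5 = int(rng.integers(params.utr5_length_range[0], params.utr5_length_range[1] + 1))
        ncod = int(rng.integers(params.cds_codons_range[0], params.cds_codons_range[1] + 1))
        u3 = int(rng.integers(params.utr3_length_range[0], params.utr3_length_range[1] + 1))

        is_pes = bool(rng.random() < params.pes_fraction)
        is_top = bool(is_pes and rng.random() < params.top_fraction_of_pes)
        kind = "TOP" if is_top else ("PES_non_TOP" if is_pes else "none")

        utr5 = _plant_prefix(rng, _random_nt(rng, u5, params.gc_background), kind)
        internal = _random_nt(rng, (ncod - 2) * 3, params.gc_background)
        cds = "ATG" + internal + _STOPS[int(rng.integers(0, 3))]
        utr3 = _random_nt(rng, u3, params.gc_background)
        seq = utr5 + cds + utr3
        models.append(TranscriptModel(
            transcript_id=tx_id, gene_id=gene_id, sequence=seq,
            cds_start=u5, cds_end=u5 + len(cds),
        ))
        rows.append({"transcript_id": tx_id, "gene_id": gene_id,
                     "utr5_length": u5, "cds_length": len(cds), "utr3_length": u3,
                     "pes_flag": is_pes, "top_flag": is_top,
                     "motif_class": kind})
    return models, pd.DataFrame(rows)


def simulate_ribo_counts(
    models: Sequence[TranscriptModel],
    truth: pd.DataFrame,
    params: SimRiboParams,
) -> tuple[dict[tuple[str, int, str], dict[str, RiboProfile]], pd.DataFrame]:
    """Generate footprint and total-RNA 5'-end profiles for every library.

    Returns ``profiles[(condition, replicate, assay)] -> {transcript_id:
    RiboProfile}`` with ``assay`` in {"rpf", "rna"}, plus a truth table with
    per-transcript abundance and the true TE per condition.  Expected
    footprint counts are proportional to abundance x TE x CDS length;
    P-sites are drawn over CDS codons with an initiation-dwell boost at the
    start codon and ``frame0_prob`` mass on frame 0; the 5' end of a
    footprint of length L is ``psite - offset_by_length[L]``.  RNA fragment
    5' ends are uniform over the transcript.
    """
    if not models:
        raise ValueError("no transcript models supplied")
    rng = np.random.default_rng(params.seed)
    ref, alt = params.conditions

    n = len(models)
    tx_ids = [m.transcript_id for m in models]
    tx_len = np.array([m.length for m in models], dtype=np.int64)
    cds_start = np.array([m.cds_start for m in models], dtype=np.int64)
    ncod = np.array([m.n_codons for m in models], dtype=np.int64)
    cds_len = 3 * ncod
    tx_off = np.concatenate([[0], np.cumsum(tx_len)])
    total_len = int(tx_off[-1])
    pes = truth.set_index("transcript_id")["pes_flag"].reindex(tx_ids).to_numpy(bool)

    abundance = rng.lognormal(params.abundance_log_mean, params.abundance_log_sd, size=n)
    base_te = rng.lognormal(params.base_te_log_mean, params.base_te_log_sd, size=n)
    te = {ref: base_te,
          alt: base_te * np.where(pes, params.te_effect_on_pes, 1.0)}

    lengths_arr = np.array(sorted(params.read_length_dist), dtype=np.int64)
    length_p = np.array([params.read_length_dist[L] for L in lengths_arr])
    length_p = length_p / length_p.sum()
    off_arr = np.array([params.offset_by_length[L] for L in lengths_arr], dtype=np.int64)
    frame_p = np.array([params.frame0_prob,
                        (1 - params.frame0_prob) / 2,
                        (1 - params.frame0_prob) / 2])

    profiles: dict[tuple[str, int, str], dict[str, RiboProfile]] = {}
    for cond in params.conditions:
        w_rpf = abundance * te[cond] * cds_len
        w_rpf = w_rpf / w_rpf.sum()
        w_rna = abundance * tx_len
        w_rna = w_rna / w_rna.sum()
        for rep in range(1, params.replicates + 1):
            # footprints (multinomial + repeat == iid categorical, order-free)
            tx = np.repeat(np.arange(n), rng.multinomial(params.depth_rpf, w_rpf))
            li = rng.choice(lengths_arr.size, size=params.depth_rpf, p=length_p)
            boost = params.start_codon_boost
            p_start = boost / (boost + np.maximum(ncod[tx] - 1, 0))
            at_start = rng.random(params.depth_rpf) < p_start
            alt_codon = (rng.random(params.depth_rpf)
                         * np.maximum(ncod[tx] - 1, 1)).astype(np.int64) + 1
            codon = np.where(at_start | (ncod[tx] == 1), 0, alt_codon)
            frame = rng.choice(3, size=params.depth_rpf, p=frame_p)
            psite = cds_start[tx] + 3 * codon + frame
            five = psite - off_arr[li]
            keep = (five >= 0) & (five < tx_len[tx])
            tx_k, li_k, five_k = tx[keep], li[keep], five[keep]
            lib_total = int(keep.sum())
            counts_by_len = {}
            for j, L in enumerate(lengths_arr):
                sel = li_k == j
                if not sel.any():
                    continue
                flat = np.bincount(tx_off[tx_k[sel]] + five_k[sel], minlength=total_len)
                counts_by_len[int(L)] = flat.astype(np.int32)
            profiles[(cond, rep, "rpf")] = _split(counts_by_len, tx_ids, tx_off, lib_total)

            # total-RNA fragments: 5' ends uniform over the transcript
            tx_r = np.repeat(np.arange(n), rng.multinomial(params.depth_rna, w_rna))
            pos = (rng.random(params.depth_rna) * tx_len[tx_r]).astype(np.int64)
            flat = np.bincount(tx_off[tx_r] + pos, minlength=total_len)
            profiles[(cond, rep, "rna")] = _split(
                {RNA_FRAGMENT_LENGTH: flat.astype(np.int32)}, tx_ids, tx_off,
                params.depth_rna)

    te_truth = pd.DataFrame({
        "transcript_id": tx_ids,
        "abundance": abundance,
        f"te_{ref}": te[ref],
        f"te_{alt}": te[alt],
        "pes_flag": pes,
        "true_up": pes & (params.te_effect_on_pes > 1.0),
    })
    return profiles, te_truth


def _split(counts_by_len: Mapping[int, np.ndarray], tx_ids, tx_off,
           lib_total: int) -> dict[str, RiboProfile]:
    out = {}
    for i, tx_id in enumerate(tx_ids):
        per_len = {
            L: flat[tx_off[i]: tx_off[i + 1]].copy()
            for L, flat in counts_by_len.items()
        }
        out[tx_id] = RiboProfile(transcript_id=tx_id, counts=per_len,
                                 library_total=lib_total)
    return out


def simulate_hdx(params: SimHDXParams) -> tuple[pd.DataFrame, str, dict]:
    """Generate a two-state HDX state-data table with a planted protection footprint.

    Per-residue intrinsic exchange rates are lognormal; within the protected
    interval the ligand state multiplies rates by ``protection_factor``.
    Peptide uptake is the sum of single-exponential residue kinetics over the
    peptide's exchange-competent residues, scaled by D2O fraction and
    recovery; centroid masses get independent Gaussian noise.  Returns the
    state table, the protein sequence, and a truth dict (rates, protection
    mask, peptide map).
    """
    rng = np.random.default_rng(params.seed)
    n = params.protein_length
    protein = "".join(_AA[rng.choice(len(_AA), size=n, p=_AA_P)])
    rates = rng.lognormal(params.rate_log_mean, params.rate_log_sd, size=n)
    lo, hi = params.protected_interval
    protected_mask = np.zeros(n, dtype=bool)
    protected_mask[lo - 1: hi] = True

    n_pep = max(1, int(round(params.target_redundancy * n / params.peptide_mean_length)))
    lengths = np.clip(
        np.rint(rng.normal(params.peptide_mean_length, params.peptide_sd_length, n_pep)),
        5, min(40, n),
    ).astype(int)
    starts = np.array([int(rng.integers(1, n - L + 2)) for L in lengths])
    charges = rng.integers(2, 5, size=n_pep)
    rts = np.round(rng.uniform(2.0, 12.0, size=n_pep), 2)
    conf_p = [params.low_confidence_fraction,
              (1 - params.low_confidence_fraction) * 0.35,
              (1 - params.low_confidence_fraction) * 0.65]
    confidences = rng.choice(["low", "high", "medium"], size=n_pep, p=conf_p)

    rows = []
    pep_rows = []
    for i in range(n_pep):
        s, L = int(starts[i]), int(lengths[i])
        e = s + L - 1
        seq = protein[s - 1: e]
        base_mass = molecular_weight(seq, seq_type="protein", monoisotopic=True)
        competent = np.array(
            [r for r in range(s + 2, e + 1) if protein[r - 1] != "P"], dtype=int)
        pep_rows.append({"peptide_id": f"{s}-{e}:{seq}", "peptide_start": s,
                         "peptide_end": e, "sequence": seq,
                         "charge": int(charges[i]), "confidence": confidences[i],
                         "retention_time_min": float(rts[i])})
        for state in ("apo", "ligand"):
            k = rates[competent - 1].copy() if competent.size else np.empty(0)
            if state == "ligand" and competent.size:
                prot = protected_mask[competent - 1]
                k[prot] *= params.protection_factor
            for t in params.timepoints:
                d = float(np.sum(params.d2o_fraction * params.recovery
                                 * (1 - np.exp(-k * t)))) if competent.size else 0.0
                noise = rng.normal(0, params.centroid_noise_sd) if params.centroid_noise_sd else 0.0
                rows.append({
                    "peptide_start": s, "peptide_end": e, "sequence": seq,
                    "charge": int(charges[i]), "confidence": confidences[i],
                    "retention_time_min": float(rts[i]), "state": state,
                    "exposure_s": float(t),
                    "centroid_mass_da": base_mass + d + noise,
                })
    truth = {
        "protein_sequence": protein,
        "rates": rates,
        "protected_mask": protected_mask,
        "protected_interval": (lo, hi),
        "protection_factor": params.protection_factor,
        "peptides": pd.DataFrame(pep_rows),
    }
    return pd.DataFrame(rows), protein, truth


def simulate_binding(params: SimBindingParams) -> pd.DataFrame:
    """Hyperbolic binding curves f = C/(Kd + C) + noise, clipped to [0, 1]."""
    rng = np.random.default_rng(params.seed)
    conc = np.asarray(params.conc_grid, dtype=float)
    rows = []
    for rep in range(1, params.replicates + 1):
        f = conc / (params.kd_true + conc)
        if params.noise_sd > 0:
            f = f + rng.normal(0, params.noise_sd, size=conc.size)
        f = np.clip(f, 0.0, 1.0)
        for c, y in zip(conc, f):
            rows.append({"concentration_um": float(c), "fraction_bound": float(y),
                         "replicate": rep})
    return pd.DataFrame(rows)
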