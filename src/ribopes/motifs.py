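"""5' UTR feature extraction, TOP/PES motif classification and enrichment.

A transcript carries a 5' pyrimidine-enriched sequence (PES) when a run of at
least ``min_run`` consecutive pyrimidines (C/U) begins within the first
``window`` nucleotides of the 5' UTR.  The classical 5' terminal
oligopyrimidine tract (TOP) is the special case where the transcript starts
with a C and the run begins at the very first nucleotide; TOP is therefore
always a subset of PES.  Enrichment of PES among a transcript sample (for
example the up-translated set) against a tested population is scored with the
exact upper-tail hypergeometric test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .annotation import TranscriptModel, _VALID_NT

DEFAULT_WINDOW = 10
DEFAULT_MIN_RUN = 5

_PYRIMIDINES = frozenset("CT")

MotifClass = str  # "TOP" | "PES_non_TOP" | "none"


def classify_5prime_motif(
    utr5_sequence: str,
    window: int = DEFAULT_WINDOW,
    min_run: int = DEFAULT_MIN_RUN,
) -> MotifClass:
    """Classify the 5' end of a UTR as TOP, PES_non_TOP or none.

    Ambiguity codes other than C/T/U never count as pyrimidines, so an
    ambiguous base conservatively breaks a run.  An empty UTR is 'none'.
    """
    s = utr5_sequence.upper().replace("U", "T")
    bad = set(s) - _VALID_NT
    if bad:
        raise ValueError(f"non-IUPAC characters in UTR sequence: {sorted(bad)}")
    limit = min(window, len(s))
    run_end = -1
    for start in range(limit):
        if s[start] not in _PYRIMIDINES or start <= run_end:
            continue
        end = start
        while end < len(s) and s[end] in _PYRIMIDINES:
            end += 1
        run_end = end - 1
        if end - start >= min_run:
            if start == 0 and s[0] == "C":
                return "TOP"
            return "PES_non_TOP"
    return "none"


def utr_features(
    models: Iterable[TranscriptModel],
    window: int = DEFAULT_WINDOW,
    min_run: int = DEFAULT_MIN_RUN,
) -> pd.DataFrame:
    """Per-transcript 5' UTR length, GC content and motif class."""
    rows = []
    for m in models:
        utr = m.utr5_sequence.upper().replace("U", "T")
        n = len(utr)
        gc = (utr.count("G") + utr.count("C")) / n if n else np.nan
        motif = classify_5prime_motif(utr, window=window, min_run=min_run) if n else "none"
        rows.append({
            "transcript_id": m.transcript_id,
            "utr5_length": n,
            "gc_content": gc,
            "motif_class": motif,
            "pes_flag": motif in ("TOP", "PES_non_TOP"),
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class EnrichmentResult:
    """Upper-tail hypergeometric enrichment of a flag within a sample."""

    N: int  # population size
    K: int  # flagged in population
    n: int  # sample size
    k: int  # flagged in sample
    p_hyper: float
    fold_enrichment: float

    def as_dict(self) -> dict:
        return {
            "N": self.N, "K": self.K, "n": self.n, "k": self.k,
            "p_hyper": self.p_hyper, "fold_enrichment": self.fold_enrichment,
        }


def hypergeometric_enrichment(
    population_flags: Mapping[str, bool] | pd.Series,
    sample_ids: Sequence[str],
) -> EnrichmentResult:
    """P(X >= k) for X ~ Hypergeometric(N, K, n); sample must be within population."""
    flags = dict(population_flags.items())
    N = len(flags)
    if N == 0:
        raise ValueError("empty population")
    sample = list(sample_ids)
    n = len(sample)
    if n == 0:
        raise ValueError("empty sample")
    missing = [s for s in sample if s not in flags]
    if missing:
        raise ValueError(f"sample ids not in population: {missing[:5]}...")
    K = int(sum(bool(v) for v in flags.values()))
    k = int(sum(bool(flags[s]) for s in sample))
    p = float(hypergeom.sf(k - 1, N, K, n))
    fold = (k / n) / (K / N) if K > 0 else np.nan
    return EnrichmentResult(N=N, K=K, n=n, k=k, p_hyper=min(p, 1.0), fold_enrichment=fold)


def pes_fraction(features: pd.DataFrame) -> dict:
    """Share of PES-flagged transcripts in a sample, with the TOP/non-TOP split."""
    if features.empty:
        raise ValueError("empty sample")
    n = len(features)
    n_top = int((features["motif_class"] == "TOP").sum())
    n_pes_non_top = int((features["motif_class"] == "PES_non_TOP").sum())
    return {
        "n": n,
        "n_top": n_top,
        "n_pes_non_top": n_pes_non_top,
        "n_pes": n_top + n_pes_non_top,
        "fraction_pes": (n_top + n_pes_non_top) / n,
    }
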