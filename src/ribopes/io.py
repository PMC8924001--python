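"""Readers and writers for the pipeline's tabular interchange formats.

Counts are exchanged as long-form TSV (transcript_id, condition, replicate,
assay, read_length, position, count) holding only non-zero positions; HDX
state data as CSV; binding curves and truth tables as TSV.  All writers are
plain text so that write(read(x)) round-trips exactly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .annotation import TranscriptModel
from .ribo import RiboProfile

COUNTS_COLUMNS = ["transcript_id", "condition", "replicate", "assay",
                  "read_length", "position", "count"]


def write_counts_tsv(
    profiles: Mapping[tuple[str, int, str], Mapping[str, RiboProfile]],
    path: str | Path,
) -> None:
    chunks = []
    for (cond, rep, assay), lib in sorted(profiles.items()):
        for tx_id in sorted(lib):
            prof = lib[tx_id]
            for L in sorted(prof.counts):
                vec = prof.counts[L]
                nz = np.nonzero(vec)[0]
                if nz.size == 0:
                    continue
                chunks.append(pd.DataFrame({
                    "transcript_id": tx_id, "condition": cond, "replicate": rep,
                    "assay": assay, "read_length": L, "position": nz,
                    "count": vec[nz],
                }))
    df = (pd.concat(chunks, ignore_index=True) if chunks
          else pd.DataFrame(columns=COUNTS_COLUMNS))
    df.to_csv(path, sep="\t", index=False)


def read_counts_tsv(
    path: str | Path,
    models: Mapping[str, TranscriptModel],
) -> dict[tuple[str, int, str], dict[str, RiboProfile]]:
    """Rebuild per-library RiboProfiles; library_total is the library's summed count."""
    df = pd.read_csv(path, sep="\t")
    missing = set(COUNTS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"counts TSV missing columns: {sorted(missing)}")
    out: dict[tuple[str, int, str], dict[str, RiboProfile]] = {}
    for (cond, rep, assay), lib_df in df.groupby(["condition", "replicate", "assay"]):
        lib_total = int(lib_df["count"].sum())
        lib: dict[str, RiboProfile] = {}
        for tx_id, tx_df in lib_df.groupby("transcript_id"):
            model = models.get(tx_id)
            if model is None:
                raise KeyError(f"transcript {tx_id} absent from annotation")
            counts: dict[int, np.ndarray] = {}
            for L, len_df in tx_df.groupby("read_length"):
                vec = np.zeros(model.length, dtype=np.int32)
                pos = len_df["position"].to_numpy()
                if np.any((pos < 0) | (pos >= model.length)):
                    raise ValueError(f"{tx_id}: position outside transcript")
                vec[pos] = len_df["count"].to_numpy()
                counts[int(L)] = vec
            lib[tx_id] = RiboProfile(transcript_id=tx_id, counts=counts,
                                     library_total=lib_total)
        # transcripts with zero reads still need (empty) profiles
        for tx_id, model in models.items():
            if tx_id not in lib:
                lengths = sorted({int(L) for L in lib_df["read_length"].unique()})
                lib[tx_id] = RiboProfile(
                    transcript_id=tx_id,
                    counts={L: np.zeros(model.length, dtype=np.int32) for L in lengths},
                    library_total=lib_total)
        out[(str(cond), int(rep), str(assay))] = lib
    return out


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")
    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
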