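"""Transcript models and annotation ingest.

All downstream coordinates are 0-based half-open in *transcript* space: a
transcript is segmented into 5'UTR ``[0, cds_start)``, CDS
``[cds_start, cds_end)`` and 3'UTR ``[cds_end, length)``.  Genome-space
annotation (GTF, 1-based closed; BED12, 0-based half-open) is converted on
ingest and strand is resolved, so everything after the readers is strand-free.
One transcript per gene is assumed throughout.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_VALID_NT = set("ACGTUNRYSWKMBDHV")


@dataclass(frozen=True)
class TranscriptModel:
    """A single spliced transcript with UTR/CDS segmentation and sequence."""

    transcript_id: str
    gene_id: str
    sequence: str
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if not (0 <= self.cds_start < self.cds_end <= n):
            raise ValueError(
                f"{self.transcript_id}: CDS [{self.cds_start}, {self.cds_end}) "
                f"outside transcript of length {n}"
            )
        if (self.cds_end - self.cds_start) % 3 != 0:
            raise ValueError(
                f"{self.transcript_id}: CDS length not a multiple of 3"
            )
        bad = set(self.sequence.upper()) - _VALID_NT
        if bad:
            raise ValueError(f"{self.transcript_id}: non-IUPAC characters {bad}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def utr5(self) -> tuple[int, int]:
        return (0, self.cds_start)

    @property
    def cds(self) -> tuple[int, int]:
        return (self.cds_start, self.cds_end)

    @property
    def utr3(self) -> tuple[int, int]:
        return (self.cds_end, self.length)

    @property
    def utr5_sequence(self) -> str:
        return self.sequence[: self.cds_start]

    @property
    def cds_sequence(self) -> str:
        return self.sequence[self.cds_start : self.cds_end]

    @property
    def n_codons(self) -> int:
        return (self.cds_end - self.cds_start) // 3

    def region_of(self, position: int) -> str:
        """Region ('utr5' | 'cds' | 'utr3') containing a transcript position."""
        if not 0 <= position < self.length:
            raise IndexError(position)
        if position < self.cds_start:
            return "utr5"
        if position < self.cds_end:
            return "cds"
        return "utr3"


def write_fasta(models: Iterable[TranscriptModel], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(m.sequence), id=m.transcript_id, description=f"gene={m.gene_id}")
        for m in models
    ]
    SeqIO.write(records, str(path), "fasta")


def write_bed12(models: Iterable[TranscriptModel], path: str | Path) -> None:
    """One BED12 line per transcript, in transcript coordinates (chrom = id)."""
    with open(path, "w") as fh:
        for m in models:
            fields = [
                m.transcript_id, "0", str(m.length), m.gene_id, "0", "+",
                str(m.cds_start), str(m.cds_end), "0", "1",
                f"{m.length},", "0,",
            ]
            fh.write("\t".join(fields) + "\n")


def read_bed12_fasta(bed_path: str | Path, fasta_path: str | Path) -> list[TranscriptModel]:
    """Read transcript models from a BED12 + FASTA pair.

    Entries are expected in transcript space (single block, chromStart 0),
    as written by :func:`write_bed12`; thickStart/thickEnd delimit the CDS.
    """
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    gene_by_tx = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        desc = rec.description
        gene_by_tx[rec.id] = desc.split("gene=")[-1] if "gene=" in desc else rec.id

    models = []
    with open(bed_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 8:
                raise ValueError(f"BED12 line with {len(f)} fields: {line!r}")
            tx_id, start = f[0], int(f[1])
            if start != 0:
                raise ValueError(f"{tx_id}: expected transcript-space BED (chromStart 0)")
            name = f[3]
            cds_start, cds_end = int(f[6]), int(f[7])
            if tx_id not in seqs:
                raise KeyError(f"{tx_id} missing from FASTA")
            models.append(
                TranscriptModel(
                    transcript_id=tx_id,
                    gene_id=gene_by_tx.get(tx_id, name),
                    sequence=seqs[tx_id],
                    cds_start=cds_start,
                    cds_end=cds_end,
                )
            )
    return models


def read_gtf_fasta(gtf_path: str | Path, fasta_path: str | Path) -> list[TranscriptModel]:
    """Read transcript models from a GTF + transcript FASTA pair.

    The GTF is parsed with gffutils; exon and CDS features are mapped into
    transcript coordinates by cumulating exon lengths in transcription order
    (minus-strand exons reversed), so downstream code never sees the strand.
    Requires attribute keys ``transcript_id`` and ``gene_id``.
    """
    import gffutils

    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    with tempfile.NamedTemporaryFile(suffix=".db") as tmp:
        db = gffutils.create_db(
            str(gtf_path), tmp.name, force=True, keep_order=True,
            merge_strategy="merge", disable_infer_transcripts=True,
            disable_infer_genes=True,
        )
        models = []
        tx_ids = {
            f.attributes["transcript_id"][0]
            for f in db.all_features()
            if "transcript_id" in f.attributes and f.featuretype in ("exon", "CDS")
        }
        for tx_id in sorted(tx_ids):
            exons = sorted(
                (f for f in db.all_features(featuretype="exon")
                 if f.attributes["transcript_id"][0] == tx_id),
                key=lambda f: f.start,
            )
            cdss = sorted(
                (f for f in db.all_features(featuretype="CDS")
                 if f.attributes["transcript_id"][0] == tx_id),
                key=lambda f: f.start,
            )
            if not exons or not cdss:
                continue
            strand = exons[0].strand
            gene_id = exons[0].attributes["gene_id"][0]
            if strand == "-":
                exons = exons[::-1]
            # genome -> transcript projection, exon by exon
            def to_tx(gpos: int) -> int:
                offset = 0
                for ex in exons:
                    if ex.start <= gpos <= ex.end:
                        if strand == "-":
                            return offset + (ex.end - gpos)
                        return offset + (gpos - ex.start)
                    offset += ex.end - ex.start + 1
                raise ValueError(f"{tx_id}: position {gpos} not exonic")

            cds_coords = []
            for c in cdss:
                cds_coords.extend([to_tx(c.start), to_tx(c.end)])
            cds_start, cds_end = min(cds_coords), max(cds_coords) + 1
            models.append(
                TranscriptModel(
                    transcript_id=tx_id, gene_id=gene_id, sequence=seqs[tx_id],
                    cds_start=cds_start, cds_end=cds_end,
                )
            )
    return models


def models_by_id(models: Iterable[TranscriptModel]) -> Mapping[str, TranscriptModel]:
    return {m.transcript_id: m for m in models}
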