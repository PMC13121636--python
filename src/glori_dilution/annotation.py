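"""Transcript models and annotation / reference sequence I/O.

Coordinate conventions, stated once and applied everywhere:

* internal coordinates are 0-based, half-open, genomic;
* GTF is read and written as 1-based inclusive (GTF2.2) and converted on
  ingest; BED12 is 0-based half-open;
* the CDS segment *includes* the stop codon, so the first base after the CDS
  belongs to the 3'-UTR;
* transcript coordinates run 5'→3' in transcript orientation (position 0 is
  the transcript's first base regardless of genomic strand).

Transcripts are single-exon: the simulator emits single-exon models and the
per-site arithmetic (region assignment, metagene scaling, stop-codon offsets)
only needs contiguous UTR5/CDS/UTR3 segments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
import gffutils

from .errors import InputError

UTR5 = "UTR5"
CDS = "CDS"
UTR3 = "UTR3"
INTERGENIC = "intergenic"


@dataclass(frozen=True)
class TranscriptModel:
    """Strand-aware UTR5/CDS/UTR3 segmentation of a single-exon transcript."""

    transcript_id: str
    contig: str
    strand: str  # '+' or '-'
    tx_start: int  # genomic 0-based start of the transcript interval
    utr5_len: int
    cds_len: int
    utr3_len: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise InputError(f"bad strand {self.strand!r} for {self.transcript_id}")
        if min(self.utr5_len, self.cds_len, self.utr3_len) < 0:
            raise InputError(f"negative segment length in {self.transcript_id}")

    @property
    def length(self) -> int:
        return self.utr5_len + self.cds_len + self.utr3_len

    @property
    def tx_end(self) -> int:
        """Genomic end (exclusive)."""
        return self.tx_start + self.length

    def contains(self, genomic_pos: int) -> bool:
        return self.tx_start <= genomic_pos < self.tx_end

    def to_transcript_pos(self, genomic_pos: int) -> int:
        """Map a genomic position to a 5'→3' transcript position."""
        if not self.contains(genomic_pos):
            raise InputError(
                f"position {genomic_pos} outside transcript {self.transcript_id}"
            )
        if self.strand == "+":
            return genomic_pos - self.tx_start
        return (self.tx_end - 1) - genomic_pos

    def to_genomic_pos(self, tpos: int) -> int:
        if not 0 <= tpos < self.length:
            raise InputError(
                f"transcript position {tpos} outside {self.transcript_id}"
            )
        if self.strand == "+":
            return self.tx_start + tpos
        return (self.tx_end - 1) - tpos

    def region(self, tpos: int) -> str:
        if not 0 <= tpos < self.length:
            raise InputError(
                f"transcript position {tpos} outside {self.transcript_id}"
            )
        if tpos < self.utr5_len:
            return UTR5
        if tpos < self.utr5_len + self.cds_len:
            return CDS
        return UTR3

    def stop_offset(self, tpos: int) -> int:
        """Offset relative to the CDS/3'-UTR junction.

        The first 3'-UTR base has offset 0; the last CDS base (third base of
        the stop codon) has offset -1.
        """
        return tpos - (self.utr5_len + self.cds_len)

    # genomic spans of the three segments, 0-based half-open
    def cds_genomic_span(self) -> Tuple[int, int]:
        if self.strand == "+":
            start = self.tx_start + self.utr5_len
        else:
            start = self.tx_start + self.utr3_len
        return start, start + self.cds_len


class Annotation:
    """A set of transcript models with (contig, pos, strand) lookup."""

    def __init__(self, transcripts: Iterable[TranscriptModel]):
        self.transcripts: Dict[str, TranscriptModel] = {
            t.transcript_id: t for t in transcripts
        }
        self._by_contig: Dict[str, List[TranscriptModel]] = {}
        for t in self.transcripts.values():
            self._by_contig.setdefault(t.contig, []).append(t)

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self):
        return iter(self.transcripts.values())

    def locate(self, contig: str, pos: int, strand: str) -> Optional[TranscriptModel]:
        """Return the transcript covering a stranded genomic position, if any."""
        for t in self._by_contig.get(contig, ()):
            if t.strand == strand and t.contains(pos):
                return t
        return None

    # ------------------------------------------------------------------ GTF
    def to_gtf(self, path: str) -> None:
        lines = []
        for t in sorted(self.transcripts.values(), key=lambda x: x.transcript_id):
            attrs = f'gene_id "{t.transcript_id}_g"; transcript_id "{t.transcript_id}";'

            def feat(ftype: str, start0: int, end0: int) -> str:
                # GTF is 1-based inclusive
                return (
                    f"{t.contig}\tglori_dilution\t{ftype}\t{start0 + 1}\t{end0}"
                    f"\t.\t{t.strand}\t.\t{attrs}"
                )

            lines.append(feat("transcript", t.tx_start, t.tx_end))
            lines.append(feat("exon", t.tx_start, t.tx_end))
            cds_s, cds_e = t.cds_genomic_span()
            if t.utr5_len:
                if t.strand == "+":
                    lines.append(feat("five_prime_utr", t.tx_start, cds_s))
                else:
                    lines.append(feat("five_prime_utr", cds_e, t.tx_end))
            if t.cds_len:
                lines.append(feat("CDS", cds_s, cds_e))
            if t.utr3_len:
                if t.strand == "+":
                    lines.append(feat("three_prime_utr", cds_e, t.tx_end))
                else:
                    lines.append(feat("three_prime_utr", t.tx_start, cds_s))
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + ("\n" if lines else ""))

    @classmethod
    def from_gtf(cls, path: str) -> "Annotation":
        db = gffutils.create_db(
            path,
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
        models = []
        for tx in db.features_of_type("transcript"):
            tid = tx.attributes["transcript_id"][0]
            seg_len = {"five_prime_utr": 0, "CDS": 0, "three_prime_utr": 0}
            for child in db.children(tx):
                if child.featuretype in seg_len:
                    seg_len[child.featuretype] += child.end - child.start + 1
            models.append(
                TranscriptModel(
                    transcript_id=tid,
                    contig=tx.seqid,
                    strand=tx.strand,
                    tx_start=tx.start - 1,
                    utr5_len=seg_len["five_prime_utr"],
                    cds_len=seg_len["CDS"],
                    utr3_len=seg_len["three_prime_utr"],
                )
            )
        return cls(models)

    # ---------------------------------------------------------------- BED12
    def to_bed12(self, path: str) -> None:
        rows = []
        for t in sorted(self.transcripts.values(), key=lambda x: x.transcript_id):
            cds_s, cds_e = t.cds_genomic_span()
            rows.append(
                (
                    t.contig,
                    t.tx_start,
                    t.tx_end,
                    t.transcript_id,
                    0,
                    t.strand,
                    cds_s,
                    cds_e,
                    0,
                    1,
                    f"{t.length},",
                    "0,",
                )
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_bed12(cls, path: str) -> "Annotation":
        cols = [
            "contig", "start", "end", "name", "score", "strand",
            "thick_start", "thick_end", "rgb", "block_count",
            "block_sizes", "block_starts",
        ]
        df = pd.read_csv(path, sep="\t", header=None, names=cols)
        models = []
        for row in df.itertuples(index=False):
            cds_len = row.thick_end - row.thick_start
            if row.strand == "+":
                utr5 = row.thick_start - row.start
                utr3 = row.end - row.thick_end
            else:
                utr5 = row.end - row.thick_end
                utr3 = row.thick_start - row.start
            models.append(
                TranscriptModel(
                    transcript_id=row.name,
                    contig=row.contig,
                    strand=row.strand,
                    tx_start=row.start,
                    utr5_len=utr5,
                    cds_len=cds_len,
                    utr3_len=utr3,
                )
            )
        return cls(models)


# --------------------------------------------------------------- reference IO
def read_fasta(path: str) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(sequences: Dict[str, str], path: str) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sorted(sequences.items())
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())
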