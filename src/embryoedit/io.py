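"""File formats: FASTA/FASTQ, the CDS-annotation sidecar TSV, truth tables,
reports and a minimal SAM export of read alignments."""

from __future__ import annotations

import csv
import json
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .align import Alignment
from .genome import Amplicon

ANNOTATION_COLUMNS = ["seq_id", "segment_start", "segment_end", "phase"]
TRUTH_COLUMNS = ["embryo_id", "allele_json", "fraction", "true_genotype"]


def write_fasta(path: str | Path, records: dict[str, str]) -> None:
    """Write sequences wrapped at 60 columns."""
    recs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(recs)


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_annotation(path: str | Path, amplicon: Amplicon) -> None:
    """CDS annotation sidecar: tab-delimited, header line required."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(ANNOTATION_COLUMNS)
        offset = 0
        for start, end in amplicon.cds_segments:
            phase = (amplicon.cds_phase_at_start + offset) % 3
            w.writerow([amplicon.id, start, end, phase])
            offset += end - start


def read_annotation(
    path: str | Path, sequence: str, seq_id: str | None = None,
    cds_start_index: int | None = None,
) -> Amplicon:
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != ANNOTATION_COLUMNS:
            raise ValueError(
                f"bad annotation header {header}; expected {ANNOTATION_COLUMNS}"
            )
        rows = [row for row in reader if row]
    if not rows:
        raise ValueError("annotation has no segments")
    sid = seq_id or rows[0][0]
    rows = [r for r in rows if r[0] == sid]
    segments = tuple(sorted((int(r[1]), int(r[2])) for r in rows))
    phase = int(rows[0][3])
    return Amplicon(sid, sequence, segments, phase, cds_start_index=cds_start_index)


def write_fastq(path: str | Path, reads: list[tuple[str, str, str]]) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str, str]]:
    reads = []
    with open(path) as fh:
        while True:
            header = fh.readline().rstrip("\n")
            if not header:
                break
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not header.startswith("@") or not plus.startswith("+"):
                raise ValueError(f"malformed FASTQ near {header!r}")
            reads.append((header[1:].split()[0], seq.upper(), qual))
    return reads


def write_truth(path: str | Path, rows: list[dict]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(
            fh, fieldnames=TRUTH_COLUMNS, delimiter="\t", lineterminator="\n"
        )
        w.writeheader()
        w.writerows(rows)


def read_truth(path: str | Path) -> list[dict]:
    with open(path) as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


def write_json(path: str | Path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_sam(
    path: str | Path,
    amplicon: Amplicon,
    alignments: list[tuple[str, str, Alignment]],
) -> None:
    """Minimal SAM export: header plus one line per (read_id, seq, alignment)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        fh.write(f"@SQ\tSN:{amplicon.id}\tLN:{len(amplicon)}\n")
        for rid, seq, aln in alignments:
            fh.write(
                "\t".join(
                    [
                        rid,
                        "0",
                        amplicon.id,
                        str(aln.ref_start + 1),
                        "60",
                        aln.cigar(),
                        "*",
                        "0",
                        "0",
                        seq,
                        "*",
                    ]
                )
                + "\n"
            )
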