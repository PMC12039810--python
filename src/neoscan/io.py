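"""File I/O: FASTA/FASTQ via Biopython, tables via pandas, locus JSON."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ValidationError
from .locus import NcrnaLocus
from .simulate import SimRead


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except (ValueError, FileNotFoundError) as exc:
        raise ValidationError(f"could not parse FASTA {path}: {exc}") from exc
    if not records:
        raise ValidationError(f"no FASTA records in {path}")
    return [(r.id, str(r.seq).upper()) for r in records]


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records],
        str(path),
        "fasta",
    )


def read_reads(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTQ or FASTA reads, sniffing the format from the first byte."""
    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
    if first == "":
        return []
    fmt = "fastq" if first == "@" else "fasta"
    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), fmt)]


def write_fastq(reads: list[SimRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            qual = read.quality or "I" * len(read.sequence)
            fh.write(f"@{read.id}\n{read.sequence}\n+\n{qual}\n")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def locus_to_json(locus: NcrnaLocus, path: str | Path) -> None:
    payload = {
        "id": locus.id,
        "template_start": locus.template_start,
        "template_end": locus.template_end,
        "aca_positions": locus.aca_positions,
        "pbs_interval": list(locus.pbs_interval),
        "primer": locus.primer,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def locus_from_files(fasta_path: str | Path, json_path: str | Path | None = None) -> NcrnaLocus:
    """Load a locus from FASTA, with optional JSON annotation sidecar."""
    rid, seq = read_fasta(fasta_path)[0]
    if json_path is None:
        return NcrnaLocus(id=rid, sequence=seq)
    meta = json.loads(Path(json_path).read_text())
    return NcrnaLocus(
        id=meta.get("id", rid),
        sequence=seq,
        template_start=meta["template_start"],
        template_end=meta["template_end"],
        aca_positions=list(meta.get("aca_positions", [])),
        pbs_interval=tuple(meta["pbs_interval"]),
        primer=meta.get("primer", "GATAT"),
    )
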