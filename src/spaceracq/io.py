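"""File formats: FASTA (via Biopython), plain-text locus definitions, TSVs.

All writers emit deterministic bytes for identical inputs so pipeline runs
can be compared file-by-file.
"""
from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .arrays import CRISPRLocus
from .mapping import Replicon
from .synthetic import TruthRecord

TRUTH_COLUMNS = [
    "clone_id",
    "event_index",
    "spacer_seq",
    "source_replicon_id",
    "source_start",
    "source_end",
    "strand",
    "planted_mode",
    "slip_offset",
]


def read_fasta(path) -> list[tuple[str, str]]:
    """FASTA records as (id, upper-case sequence) pairs."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records, path) -> None:
    """Write (id, seq) pairs; description left empty."""
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(seq_records, fh, "fasta")


def read_replicons(path) -> list[Replicon]:
    """Replicons from FASTA with ids of the form ``kind:name``."""
    out = []
    for name, seq in read_fasta(path):
        kind = name.split(":", 1)[0]
        out.append(Replicon(id=name, kind=kind, seq=seq, circular=kind != "host"))
    return out


def write_locus(locus: CRISPRLocus, path) -> None:
    lines = [f"leader={locus.leader_seq}", f"repeat={locus.repeat_seq}"]
    lines += [
        f"spacer{i + 1}={sp}" for i, sp in enumerate(locus.parental_spacers)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_locus(path) -> CRISPRLocus:
    """Parse a locus definition file (leader=, repeat=, spacer1=, ...)."""
    fields: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        fields[key.strip()] = value.strip().upper()
    spacer_keys = sorted(
        (k for k in fields if k.startswith("spacer")),
        key=lambda k: int(k[len("spacer") :]),
    )
    if "leader" not in fields or "repeat" not in fields or not spacer_keys:
        raise ValueError(f"incomplete locus definition in {path}")
    return CRISPRLocus(
        leader_seq=fields["leader"],
        repeat_seq=fields["repeat"],
        parental_spacers=tuple(fields[k] for k in spacer_keys),
    )


def write_truth(truth: list[TruthRecord], path) -> None:
    df = pd.DataFrame([vars(t) for t in truth], columns=TRUTH_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"slip_offset": "Int64"})


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def read_counts(path) -> pd.DataFrame:
    """Gene-count table: gene_id, length_bp, one column per sample-replicate."""
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns or "length_bp" not in df.columns:
        raise ValueError("counts table needs gene_id and length_bp columns")
    return df.set_index("gene_id")


def sha256_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
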