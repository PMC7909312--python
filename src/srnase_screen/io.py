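"""Sequence and annotation I/O plus run configuration.

All coordinates are 0-based half-open in memory; file output (GFF3) is
1-based inclusive, following the format conventions.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

NT_ALPHABET = set("ACGTUNRYSWKMBDHV-")
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYBXZJUO*-")


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide or amino-acid sequence.

    ``moltype`` is ``"nt"`` or ``"aa"``; gap characters ('-') are only
    expected when the record is a row of an alignment.
    """

    id: str
    residues: str
    moltype: str = "nt"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has no residues")
        if self.moltype not in ("nt", "aa"):
            raise ValueError(f"moltype must be 'nt' or 'aa', got {self.moltype!r}")
        alphabet = NT_ALPHABET if self.moltype == "nt" else AA_ALPHABET
        bad = set(self.residues.upper()) - alphabet
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-{self.moltype} characters: "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def ungapped(self) -> "SequenceRecord":
        return replace(self, residues=self.residues.replace("-", ""))


def read_fasta(path: str | Path, moltype: str = "nt") -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords, preserving order.

    Raises ``ValueError`` on duplicate ids or an empty file.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(
            SequenceRecord(id=rec.id, residues=str(rec.seq), moltype=moltype,
                           description=desc)
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 70) -> None:
    """Write SequenceRecords to FASTA (wrapped at ``width`` columns)."""
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# Gene-model GFF3 I/O (exon/intron structures from spliced CDS mapping)
# ---------------------------------------------------------------------------

def write_gene_models_gff3(models, path: str | Path) -> None:
    """Write GeneModels as GFF3 gene/mRNA/exon features (1-based inclusive).

    ``models`` is an iterable of ``structure.GeneModel``.  Overlapping exons
    within a model are rejected.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = ["##gff-version 3"]
    for m in models:
        prev_end = -1
        for s, e in m.exons:
            if s < prev_end:
                raise ValueError(f"overlapping exons in gene model {m.gene_id!r}")
            prev_end = e
        span_start, span_end = m.exons[0][0], m.exons[-1][1]
        gid = m.gene_id
        lines.append("\t".join(
            [gid, "srnase_screen", "gene", str(span_start + 1), str(span_end),
             ".", "+", ".", f"ID=gene:{gid}"]))
        lines.append("\t".join(
            [gid, "srnase_screen", "mRNA", str(span_start + 1), str(span_end),
             ".", "+", ".", f"ID=mrna:{gid};Parent=gene:{gid}"]))
        for i, (s, e) in enumerate(m.exons, 1):
            lines.append("\t".join(
                [gid, "srnase_screen", "exon", str(s + 1), str(e), ".", "+",
                 ".", f"ID=exon:{gid}.{i};Parent=mrna:{gid}"]))
    path.write_text("\n".join(lines) + "\n")


def read_gene_models_gff3(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """Parse exon coordinates back from a GFF3 written by this package.

    Returns gene_id -> list of 0-based half-open exon intervals.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    for line in Path(path).read_text().splitlines():
        if line.startswith("#") or not line.strip():
            continue
        fields = line.split("\t")
        if fields[2] != "exon":
            continue
        gid = fields[0]
        exons.setdefault(gid, []).append((int(fields[3]) - 1, int(fields[4])))
    for gid in exons:
        exons[gid].sort()
    return exons


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Pipeline thresholds and reproducibility settings.

    Attributes
    ----------
    cluster_identity : redundancy-collapse identity for the screen stage.
    lpsc_identity : single-linkage floor for low-polymorphic subclusters.
    class_floor : minimum nearest-reference identity for class assignment.
    pi_basic_cutoff : pI above which a protein is called basic (S-RNase-like).
    min_orf_aa : shortest protein retained by the ORF screen.
    fdr_level : BH false-discovery-rate level for expression calls.
    alpha : significance level for segregation-ratio fits.
    pka_table : name of the pKa constant set used for pI.
    seed : master random seed, recorded in every report header.
    """

    cluster_identity: float = 0.95
    lpsc_identity: float = 0.85
    class_floor: float = 0.30
    pi_basic_cutoff: float = 7.0
    min_orf_aa: int = 200
    fdr_level: float = 0.05
    alpha: float = 0.05
    pka_table: str = "EMBOSS"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cluster_identity", "lpsc_identity", "class_floor"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if not 0.0 < self.fdr_level < 1.0:
            raise ValueError("fdr_level must be in (0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_orf_aa < 1:
            raise ValueError("min_orf_aa must be >= 1")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a flat ``key = value`` config file; kwargs override the file."""
        values: dict = {}
        fields = {f: t for f, t in cls.__annotations__.items()}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            m = re.match(r"^(\w+)\s*[=:]\s*(.+)$", line)
            if not m:
                raise ValueError(f"unparseable config line: {raw!r}")
            key, val = m.group(1), m.group(2).strip()
            if key not in fields:
                raise ValueError(f"unknown config key {key!r}")
            if key == "pka_table":
                values[key] = val
            elif key in ("seed", "min_orf_aa"):
                values[key] = int(val)
            else:
                values[key] = float(val)
        values.update(overrides)
        return cls(**values)

    def config_hash(self) -> str:
        payload = repr(sorted(self.__dict__.items())).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def report_header(self) -> str:
        """Header lines stamped on every report file."""
        return (f"# srnase-screen report\n"
                f"# config_hash={self.config_hash()} seed={self.seed} "
                f"pka_table={self.pka_table}\n"
                f"# tree method: neighbor-joining with nearest-reference "
                f"class labels (no bootstrap)\n")
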