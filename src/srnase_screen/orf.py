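"""Longest-ORF protein extraction and greedy identity clustering.

Together these implement the first stage of the candidate screen: turn
assembled transcripts into non-redundant protein sequences, discarding
short products, in the manner of a Transdecoder + CD-HIT step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

from .align import pairwise_identity
from .io import SequenceRecord

#: six-frame scan order used for tie-breaking: forward frames first.
FRAME_ORDER = (1, 2, 3, -1, -2, -3)


@dataclass(frozen=True)
class OrfCall:
    """The selected open reading frame of one transcript.

    ``nt_start``/``nt_end`` are 0-based half-open on the *forward* strand
    and include the stop codon when the ORF is stop-terminated.
    """

    transcript_id: str
    frame: int
    nt_start: int
    nt_end: int
    protein: str

    def __post_init__(self) -> None:
        span = self.nt_end - self.nt_start
        if not (3 * len(self.protein) <= span <= 3 * len(self.protein) + 3):
            raise ValueError(
                f"ORF span {span} inconsistent with protein length "
                f"{len(self.protein)} for {self.transcript_id!r}")
        if "*" in self.protein:
            raise ValueError("protein must not contain a stop symbol")


def _frame_orfs(prot: str, require_start: bool):
    """Yield (aa_start, aa_len) for every candidate ORF in one translated frame."""
    pos = 0
    for segment in prot.split("*"):
        if segment:
            if require_start:
                m = segment.find("M")
                if m >= 0:
                    yield pos + m, len(segment) - m
            else:
                yield pos, len(segment)
        pos += len(segment) + 1


def longest_orf(transcript: SequenceRecord, min_aa: int = 200,
                require_start: bool = False) -> OrfCall | None:
    """Pick the longest open reading frame across all six frames.

    Ties are broken by frame order (+1, +2, +3, -1, -2, -3), then by the
    leftmost start within the frame.  Returns ``None`` when the best ORF
    is shorter than ``min_aa`` residues.
    """
    if transcript.moltype != "nt":
        raise ValueError("longest_orf requires a nucleotide record")
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    seq = transcript.residues.upper().replace("U", "T")
    L = len(seq)
    rc = str(Seq(seq).reverse_complement())
    best: OrfCall | None = None
    for frame in FRAME_ORDER:
        strand_seq = seq if frame > 0 else rc
        offset = abs(frame) - 1
        sub = strand_seq[offset:]
        sub = sub[: len(sub) - len(sub) % 3]
        if not sub:
            continue
        prot = str(Seq(sub).translate())
        for aa_start, aa_len in _frame_orfs(prot, require_start):
            if best is not None and aa_len <= len(best.protein):
                continue
            nt_lo = offset + 3 * aa_start
            nt_hi = offset + 3 * (aa_start + aa_len)
            # include the terminating stop codon when present
            if aa_start + aa_len < len(prot):
                nt_hi += 3
            if frame < 0:  # map reverse-strand coords back to forward
                nt_lo, nt_hi = L - nt_hi, L - nt_lo
            best = OrfCall(transcript.id, frame, nt_lo, nt_hi,
                           prot[aa_start:aa_start + aa_len])
    if best is None or len(best.protein) < min_aa:
        return None
    return best


@dataclass
class Cluster:
    """A greedy identity cluster; the representative is the longest member."""

    representative_id: str
    member_ids: list[str] = field(default_factory=list)
    threshold: float = 0.95


def greedy_cluster(proteins: list[SequenceRecord],
                   threshold: float = 0.95) -> list[Cluster]:
    """CD-HIT-style greedy incremental clustering on global-alignment identity.

    Sequences are taken longest-first (input order breaks length ties);
    each joins the first existing cluster whose representative it matches
    at >= ``threshold`` identity, else it founds a new cluster.  The
    result partitions the input.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    order = sorted(range(len(proteins)),
                   key=lambda i: (-len(proteins[i].residues), i))
    clusters: list[Cluster] = []
    reps: dict[str, str] = {}
    for idx in order:
        rec = proteins[idx]
        for cl in clusters:
            if pairwise_identity(rec.residues, reps[cl.representative_id]) >= threshold:
                cl.member_ids.append(rec.id)
                break
        else:
            clusters.append(Cluster(rec.id, [rec.id], threshold))
            reps[rec.id] = rec.residues
    return clusters
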