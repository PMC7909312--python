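"""Exon/intron inference by exact spliced mapping of a CDS onto genomic DNA.

The structural S-RNase criterion is a single intron located in the
hypervariable (HV) region of the protein.  Inputs are clone-grade
(Sanger-verified or synthetic) sequences, so exon matches are exact;
a mismatch-tolerant spliced aligner is deliberately out of scope.

The search minimises intron count, prefers canonical GT..AG splice
dinucleotides among equal-count solutions, then leftmost donors; a CDS
with no exon chain (e.g. a chimeric mis-assembly) raises, as does an
ambiguity that survives all tie-breaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .io import SequenceRecord


@dataclass
class HvWindows:
    """Named alignment-column windows (0-based half-open) on a reference
    protein alignment: hypervariable HV1–HV5 and conserved C1–C5."""

    windows: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        spans = sorted((s, e, name) for name, s, e in self.windows)
        for (s1, e1, n1), (s2, e2, n2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError(f"windows {n1!r} and {n2!r} overlap")
        for name, s, e in self.windows:
            if not 0 <= s < e:
                raise ValueError(f"bad window {name!r}: [{s}, {e})")

    def hv_window_at(self, column: int) -> Optional[str]:
        for name, s, e in self.windows:
            if name.startswith("HV") and s <= column < e:
                return name
        return None


@dataclass
class GeneModel:
    """Exon/intron structure of one gene (0-based half-open coordinates)."""

    gene_id: str
    exons: list[tuple[int, int]]
    splice_sites: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError("gene model needs >= 1 exon")
        prev_end = None
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"empty exon ({s}, {e})")
            if prev_end is not None and s <= prev_end:
                raise ValueError("exons overlap or touch (intron length < 1)")
            prev_end = e

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [(e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])]

    @property
    def intron_lengths(self) -> list[int]:
        return [e - s for s, e in self.introns]

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def intron_cds_offsets(self) -> list[int]:
        """CDS coordinate of each intron's donor site."""
        out, cum = [], 0
        for s, e in self.exons[:-1]:
            cum += e - s
            out.append(cum)
        return out


def _z_array(s: str) -> list[int]:
    """Z[i] = length of the longest common prefix of s and s[i:]."""
    n = len(s)
    z = [0] * n
    z[0] = n
    l = r = 0
    for i in range(1, n):
        if i < r:
            z[i] = min(r - i, z[i - l])
        while i + z[i] < n and s[z[i]] == s[i + z[i]]:
            z[i] += 1
        if i + z[i] > r:
            l, r = i, i + z[i]
    return z


def _match_arrays(cds: str, genomic: str) -> tuple[list[int], list[int]]:
    """Prefix/suffix exact-match lengths of the CDS against the genome.

    ``P[g]`` = longest k with genomic[g:g+k] == cds[:k];
    ``S[e]`` = longest k with genomic[e-k:e] == cds[-k:].
    """
    sep = "\x00"
    zf = _z_array(cds + sep + genomic)
    P = zf[len(cds) + 1:]
    zr = _z_array(cds[::-1] + sep + genomic[::-1])
    Sr = zr[len(cds) + 1:]
    n = len(genomic)
    S = [0] * (n + 1)
    for i in range(n):
        S[n - i] = Sr[i]
    return P, S


def _find_chains(cds: str, genomic: str, max_introns: int):
    """All exon chains reproducing the CDS with the minimal intron count."""
    L, n = len(cds), len(genomic)
    P, S = _match_arrays(cds, genomic)
    # suffix-candidate ends sorted by decreasing match length for fast
    # threshold queries
    suffix_ends = sorted(range(n + 1), key=lambda e: -S[e])

    def terminal_exons(ci: int, gi: int) -> list[tuple[int, int]]:
        """Placements of the final exon covering cds[ci:] starting >= gi."""
        need = L - ci
        out = []
        for e in suffix_ends:
            if S[e] < need:
                break
            t = e - need
            if t >= gi:
                out.append((t, e))
        return out

    def lcp(ci: int, g: int) -> int:
        k = 0
        while ci + k < L and g + k < n and cds[ci + k] == genomic[g + k]:
            k += 1
        return k

    def rec(ci: int, gi: int, introns_left: int) -> list[list[tuple[int, int]]]:
        chains = [[exon] for exon in terminal_exons(ci, gi)]
        if introns_left > 0:
            remaining = L - ci
            first_char = cds[ci]
            for s in range(gi, n):
                if genomic[s] != first_char:
                    continue
                run = min(lcp(ci, s), remaining - 1)
                for e_len in range(1, run + 1):
                    for tail in rec(ci + e_len, s + e_len + 1, introns_left - 1):
                        chains.append([(s, s + e_len)] + tail)
        return chains

    for k in range(0, max_introns + 1):
        if k == 0:
            chains = [[exon] for exon in terminal_exons(0, 0)]
        else:
            chains = [c for c in rec(0, 0, k) if len(c) == k + 1]
        if chains:
            return k, chains
    return None, []


def infer_gene_structure(cds: SequenceRecord, genomic: SequenceRecord,
                         max_introns: int = 3) -> GeneModel:
    """Infer the exon chain whose concatenation reproduces the CDS exactly.

    Minimises intron count; among equal-count chains prefers more
    canonical GT..AG introns, then leftmost donor coordinates.  Raises
    ``ValueError("unmappable CDS")`` when no chain exists within
    ``max_introns``, and an ambiguity error when distinct chains survive
    all tie-breaks.
    """
    c = cds.residues.upper()
    g = genomic.residues.upper()
    if len(c) > len(g):
        raise ValueError("CDS longer than genomic sequence")
    k, chains = _find_chains(c, g, max_introns)
    if not chains:
        raise ValueError(f"unmappable CDS: {cds.id!r} has no exon chain with "
                         f"<= {max_introns} introns in {genomic.id!r}")

    def splice_sites(chain):
        return [(g[e1:e1 + 2], g[s2 - 2:s2])
                for (_, e1), (s2, _) in zip(chain, chain[1:])]

    def sort_key(chain):
        gtag = sum(1 for d, a in splice_sites(chain) if (d, a) == ("GT", "AG"))
        donors = [e for _, e in chain[:-1]]
        return (-gtag, donors)

    chains.sort(key=sort_key)
    best_key = sort_key(chains[0])
    ties = [ch for ch in chains if sort_key(ch) == best_key]
    distinct = {tuple(ch) for ch in ties}
    if len(distinct) > 1:
        raise ValueError(
            f"ambiguous gene structure for {cds.id!r}: candidates "
            f"{sorted(distinct)}")
    chain = chains[0]
    model = GeneModel(cds.id, chain, splice_sites(chain))
    # hard postcondition: exons reconstruct the CDS byte for byte
    assert "".join(g[s:e] for s, e in chain) == c
    return model


def intron_length_check(model: GeneModel,
                        plausible: tuple[int, int] = (50, 2000),
                        observed_band: tuple[int, int] = (87, 374)
                        ) -> list[dict]:
    """Per-intron plausibility annotation.

    ``ok`` is True iff the length falls in the configured plausible
    range; ``in_observed_band`` annotates (without filtering) whether it
    also lies in the empirically observed S-RNase intron band.
    """
    lo, hi = plausible
    out = []
    for length in model.intron_lengths:
        out.append({"length": length,
                    "ok": lo <= length <= hi,
                    "in_observed_band": observed_band[0] <= length
                                        <= observed_band[1]})
    return out


def intron_in_hv(model: GeneModel, protein_alignment_row: str,
                 hv: HvWindows) -> tuple[bool, str]:
    """Test the S-RNase structural criterion: one intron, inside HV.

    Each intron's donor CDS coordinate is mapped to the codon containing
    it, then to the codon's alignment column on the given protein row.
    Returns (count_ok, position_label); ``count_ok`` is True iff the
    model has exactly one intron and its column falls inside an HV
    window.  Labels for multi-intron models are comma-joined.
    """
    # residue index -> alignment column for this row
    columns = [i for i, ch in enumerate(protein_alignment_row) if ch != "-"]
    labels = []
    inside = []
    for offset in model.intron_cds_offsets():
        codon = offset // 3
        if codon >= len(columns):
            labels.append("unalignable")
            inside.append(False)
            continue
        window = hv.hv_window_at(columns[codon])
        labels.append(window if window else "outside")
        inside.append(window is not None)
    count_ok = len(inside) == 1 and inside[0]
    return count_ok, ",".join(labels) if labels else "no_intron"
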