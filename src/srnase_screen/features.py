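"""Protein-level S-RNase-likeness features.

S-RNases are characteristically basic (pI > 8), roughly 25 kDa, and carry
two catalytic histidines in the conserved CAS I / CAS II segments.  This
module computes isoelectric point (Henderson–Hasselbalch net charge with a
pluggable pKa constant set, solved by bisection), average molecular
weight, and CAS-histidine presence from an annotated alignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from types import MappingProxyType
from typing import Mapping, Optional

from Bio.SeqUtils import molecular_weight as _bio_mw

#: side chains that titrate, and the sign they contribute when charged
ACIDIC_GROUPS = ("Cterm", "D", "E", "C", "Y")
BASIC_GROUPS = ("Nterm", "H", "K", "R")


@dataclass(frozen=True)
class PkaTable:
    """An immutable named set of acid dissociation constants (pK_a)."""

    name: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", MappingProxyType(dict(self.values)))
        missing = (set(ACIDIC_GROUPS) | set(BASIC_GROUPS)) - set(self.values)
        if missing:
            raise ValueError(f"pKa table {self.name!r} missing groups {missing}")
        for g, v in self.values.items():
            if not 0.0 < v < 14.0:
                raise ValueError(f"pKa[{g}]={v} outside (0, 14)")


#: EMBOSS `iep` constant set — the package default, recorded in outputs.
EMBOSS_PKA = PkaTable("EMBOSS", {
    "Nterm": 8.6, "Cterm": 3.6,
    "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
    "H": 6.5, "K": 10.8, "R": 12.5,
})

_warned_residues: set[str] = set()


def _group_counts(protein: str, cys_ionizable: bool = True) -> dict[str, int]:
    counts = {g: 0 for g in ACIDIC_GROUPS + BASIC_GROUPS}
    counts["Nterm"] = 1
    counts["Cterm"] = 1
    for res in protein.upper():
        if res == "C" and not cys_ionizable:
            continue
        if res in counts:
            counts[res] += 1
        elif res not in "ACDEFGHIKLMNPQRSTVWY" and res not in _warned_residues:
            _warned_residues.add(res)
            warnings.warn(f"residue {res!r} treated as non-ionizable")
    return counts


def net_charge(protein: str, pH: float, pka: PkaTable = EMBOSS_PKA,
               cys_ionizable: bool = True) -> float:
    """Net protein charge at ``pH`` in elementary-charge units.

    charge = Σ_basic 1/(1+10^(pH−pKa)) − Σ_acidic 1/(1+10^(pKa−pH)),
    termini included; strictly decreasing in pH.
    """
    if not protein:
        raise ValueError("empty protein")
    if not 0.0 <= pH <= 14.0:
        raise ValueError(f"pH {pH} outside [0, 14]")
    counts = _group_counts(protein, cys_ionizable)
    pos = sum(counts[g] / (1.0 + 10.0 ** (pH - pka.values[g]))
              for g in BASIC_GROUPS)
    neg = sum(counts[g] / (1.0 + 10.0 ** (pka.values[g] - pH))
              for g in ACIDIC_GROUPS)
    return pos - neg


def isoelectric_point(protein: str, pka: PkaTable = EMBOSS_PKA,
                      tol: float = 1e-4, cys_ionizable: bool = True,
                      max_iter: int = 200) -> float:
    """The pH at which net charge is zero, by bisection on [0, 14].

    The solution is unique because net charge is strictly monotone
    decreasing in pH.  Raises if the peptide has no ionizable groups.
    """
    counts = _group_counts(protein, cys_ionizable)
    if sum(counts.values()) == 0:
        raise ValueError("pI undefined: no ionizable groups")
    lo, hi = 0.0, 14.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if net_charge(protein, mid, pka, cys_ionizable) > 0.0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def protein_molecular_weight(protein: str) -> float:
    """Average (non-monoisotopic) molecular weight in daltons."""
    if not protein:
        raise ValueError("empty protein")
    return float(_bio_mw(protein.upper(), seq_type="protein"))


def detect_cas_histidines(query_aligned_row: str,
                          cas_columns: tuple[int, int]) -> tuple[bool, bool]:
    """Check the two catalytic CAS histidines on an alignment row.

    ``cas_columns`` are the 0-based alignment columns of the CAS I and
    CAS II histidines on the annotated reference.  Returns a flag per
    site: True iff the query carries 'H' in that column.
    """
    width = len(query_aligned_row)
    for col in cas_columns:
        if not 0 <= col < width:
            raise ValueError(f"CAS column {col} outside alignment width {width}")
    c1, c2 = cas_columns
    return (query_aligned_row[c1].upper() == "H",
            query_aligned_row[c2].upper() == "H")


@dataclass(frozen=True)
class ProteinFeatureRecord:
    """Per-sequence screening features."""

    id: str
    length: int
    pI: float
    mw: float
    cas1_his: bool = False
    cas2_his: bool = False
    localization: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.pI < 14.0:
            raise ValueError(f"pI {self.pI} outside (0, 14)")
        if self.mw <= 0 or self.length < 1:
            raise ValueError("mw must be > 0 and length >= 1")


def compute_features(records, pka: PkaTable = EMBOSS_PKA,
                     cys_ionizable: bool = True) -> list[ProteinFeatureRecord]:
    """Compute pI and molecular weight for a list of protein SequenceRecords."""
    out = []
    for rec in records:
        seq = rec.residues.replace("-", "")
        out.append(ProteinFeatureRecord(
            id=rec.id, length=len(seq),
            pI=isoelectric_point(seq, pka, cys_ionizable=cys_ionizable),
            mw=protein_molecular_weight(seq)))
    return out


def classwise_pi_summary(features: list[ProteinFeatureRecord],
                         class_of: Mapping[str, str]) -> dict[str, float]:
    """Mean pI per phylogenetic class, mirroring class-wise aggregation."""
    sums: dict[str, list[float]] = {}
    for f in features:
        cls = class_of.get(f.id)
        if cls is not None:
            sums.setdefault(cls, []).append(f.pI)
    return {cls: sum(v) / len(v) for cls, v in sorted(sums.items())}
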