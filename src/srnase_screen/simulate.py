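"""Synthetic study generator with known ground truth.

Emulates the structure of a style-transcriptome S-RNase survey in a
semi-compatible pair of citrus-like parents: a three-class T2-RNase
protein family whose class III is basic and contains a low-polymorphic
subcluster, genomic sequences with planted introns (class III: exactly
one, inside the hypervariable region), reciprocal GSI cross datasets
with S-linked and unlinked markers, negative-binomial count matrices
with one down-regulated S-RNase in a self-compatible mutant, and
tissue detection panels.

Every generator is deterministic in (parameters, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .expression import TISSUE_VOCABULARY, PISTIL_TISSUES
from .genetics import (MarkerSpec, ProgenyTable, SGenotype, attach_markers,
                       gsi_cross)
from .io import SequenceRecord
from .structure import GeneModel

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: catalytic histidine residue positions (0-based) on the family backbone
CAS_RESIDUES = (45, 108)

#: residue-coordinate windows on the family backbone (0-based half-open);
#: conserved (C) and hypervariable (HV) segments of the mature protein
BACKBONE_WINDOWS = [
    ("C1", 10, 22), ("HV1", 25, 40), ("C2", 42, 52), ("HV2", 55, 80),
    ("C3", 85, 95), ("HV3", 98, 104), ("C4", 105, 115), ("HV4", 120, 150),
    ("C5", 160, 175), ("HV5", 180, 200),
]

DEFAULT_PROTEIN_LENGTH = 230  # aa, ~25 kDa


# ---------------------------------------------------------------------------
# Protein family
# ---------------------------------------------------------------------------

@dataclass
class MemberTruth:
    class_label: str
    lpsc: bool = False
    cas_intact: tuple[bool, bool] = (True, True)
    is_reference: bool = False


@dataclass
class FamilyTruth:
    """Ground truth for every emitted family member."""

    members: dict[str, MemberTruth]
    cas_residues: tuple[int, int] = CAS_RESIDUES
    params: dict = field(default_factory=dict)
    seed: int = 0

    def ids_in_class(self, label: str, include_refs: bool = False) -> list[str]:
        return [i for i, t in self.members.items()
                if t.class_label == label
                and (include_refs or not t.is_reference)]

    @property
    def reference_labels(self) -> dict[str, str]:
        return {i: t.class_label for i, t in self.members.items()
                if t.is_reference}


def _random_protein(rng: np.random.Generator, length: int,
                    weights: Optional[np.ndarray] = None) -> list[str]:
    probs = weights if weights is not None else np.full(20, 0.05)
    return list(rng.choice(list(AA20), size=length, p=probs / probs.sum()))


def _mutate(seq: list[str], rate: float, rng: np.random.Generator,
            preserve: Sequence[int] = ()) -> list[str]:
    """Per-site substitution at probability ``rate`` to a uniform other
    residue; ``preserve`` columns are never touched."""
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    keep = set(preserve)
    for i in hits:
        if int(i) in keep:
            continue
        choices = [a for a in AA20 if a != out[i]]
        out[i] = choices[rng.integers(len(choices))]
    return out


def rate_for_pairwise_identity(identity: float) -> float:
    """Per-site substitution rate from a common ancestor such that two
    descendants differ at a fraction (1 - identity) of sites.

    P(differ) = 1 - [(1-r)^2 + r^2/19]  =>  solve the quadratic in r.
    """
    p = 1.0 - identity
    a = 20.0 / 19.0
    disc = 4.0 - 4.0 * a * p
    return (2.0 - math.sqrt(disc)) / (2.0 * a)


def _bias_composition(seq: list[str], residues: str, fraction: float,
                      rng: np.random.Generator,
                      preserve: Sequence[int] = ()) -> list[str]:
    out = list(seq)
    keep = set(preserve)
    candidates = [i for i in range(len(seq)) if i not in keep]
    k = int(round(fraction * len(candidates)))
    for i in rng.choice(candidates, size=k, replace=False):
        out[i] = residues[rng.integers(len(residues))]
    return out


def gen_family(n_per_class: int | dict[str, int] = 6,
               within_class_div: float = 0.15,
               between_class_div: float = 0.6,
               s_allele_div: float = 0.35,
               classIII_basic_bias: float = 0.25,
               lpsc_spec: Optional[tuple[int, float]] = (3, 0.90),
               seed: int = 0,
               length: int = DEFAULT_PROTEIN_LENGTH,
               n_cas_knockouts: int = 0,
               ) -> tuple[list[SequenceRecord], FamilyTruth]:
    """Generate a three-class T2-RNase-like protein family.

    One random ancestor seeds each class (classes diverge at
    ``between_class_div``); members substitute per site at
    ``within_class_div``, except class III non-LPSC members (the
    S-allele pool) which diverge at ``s_allele_div``: S alleles are
    hypervariable relative to other family members, and a detectable
    low-polymorphic subcluster requires its identity to sit clearly
    above the polymorphic background.  Class III composition is biased
    toward K/R/H so the expected class-wise pI ordering (III basic,
    I/II acidic) holds; classes I and II receive a mild D/E bias.
    ``lpsc_spec`` = (size, target identity) plants a low-polymorphic
    subcluster inside class III.  The two catalytic CAS histidines are
    preserved except in ``n_cas_knockouts`` class-I members flagged in
    the truth.  Ancestors are emitted as labeled reference sequences
    REF_I..REF_III.
    """
    if not 0.0 <= within_class_div < between_class_div <= 0.8:
        raise ValueError("need 0 <= within_class_div < between_class_div <= 0.8")
    if not within_class_div <= s_allele_div < between_class_div:
        raise ValueError(
            "need within_class_div <= s_allele_div < between_class_div")
    sizes = (dict(n_per_class) if isinstance(n_per_class, dict)
             else {c: n_per_class for c in ("I", "II", "III")})
    rng = np.random.default_rng(seed)
    base = _random_protein(rng, length)
    ancestors: dict[str, list[str]] = {}
    for label in ("I", "II", "III"):
        anc = _mutate(base, between_class_div / 2.0, rng, preserve=CAS_RESIDUES)
        if label == "III":
            anc = _bias_composition(anc, "KRKRH", classIII_basic_bias, rng,
                                    preserve=CAS_RESIDUES)
        else:
            anc = _bias_composition(anc, "DEDE", 0.10, rng,
                                    preserve=CAS_RESIDUES)
        anc[CAS_RESIDUES[0]] = "H"
        anc[CAS_RESIDUES[1]] = "H"
        ancestors[label] = anc

    records: list[SequenceRecord] = []
    truth = FamilyTruth(members={}, params={
        "within_class_div": within_class_div,
        "between_class_div": between_class_div,
        "s_allele_div": s_allele_div,
        "classIII_basic_bias": classIII_basic_bias,
        "lpsc_spec": lpsc_spec, "length": length}, seed=seed)

    for label in ("I", "II", "III"):
        rid = f"REF_{label}"
        records.append(SequenceRecord(rid, "".join(ancestors[label]),
                                      moltype="aa"))
        truth.members[rid] = MemberTruth(label, is_reference=True)

    knockouts_left = n_cas_knockouts
    member_rate = rate_for_pairwise_identity(1.0 - within_class_div)
    s_allele_rate = rate_for_pairwise_identity(1.0 - s_allele_div)
    for label in ("I", "II", "III"):
        rate = s_allele_rate if label == "III" else member_rate
        for k in range(sizes.get(label, 0)):
            mid = f"C{label}_{k + 1}"
            seq = _mutate(ancestors[label], rate, rng,
                          preserve=CAS_RESIDUES)
            cas_intact = (True, True)
            if label == "I" and knockouts_left > 0:
                seq[CAS_RESIDUES[0]] = "A"
                cas_intact = (False, True)
                knockouts_left -= 1
            records.append(SequenceRecord(mid, "".join(seq), moltype="aa"))
            truth.members[mid] = MemberTruth(label, cas_intact=cas_intact)

    if lpsc_spec is not None:
        size, identity = lpsc_spec
        lpsc_anc = _mutate(ancestors["III"], member_rate, rng,
                           preserve=CAS_RESIDUES)
        r = rate_for_pairwise_identity(identity)
        for k in range(size):
            mid = f"LPSC_{k + 1}"
            seq = _mutate(lpsc_anc, r, rng, preserve=CAS_RESIDUES)
            records.append(SequenceRecord(mid, "".join(seq), moltype="aa"))
            truth.members[mid] = MemberTruth("III", lpsc=True)
    return records, truth


# ---------------------------------------------------------------------------
# Coding sequences, transcripts and genomic sequences
# ---------------------------------------------------------------------------

_CODONS = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}
_SYNONYMS = {
    "A": ("GCT", "GCC", "GCA", "GCG"), "C": ("TGT", "TGC"),
    "D": ("GAT", "GAC"), "E": ("GAA", "GAG"), "F": ("TTT", "TTC"),
    "G": ("GGT", "GGC", "GGA", "GGG"), "H": ("CAT", "CAC"),
    "I": ("ATT", "ATC", "ATA"), "K": ("AAA", "AAG"),
    "L": ("CTT", "CTC", "CTA", "CTG", "TTA", "TTG"), "M": ("ATG",),
    "N": ("AAT", "AAC"), "P": ("CCT", "CCC", "CCA", "CCG"),
    "Q": ("CAA", "CAG"), "R": ("CGT", "CGC", "CGA", "CGG", "AGA", "AGG"),
    "S": ("TCT", "TCC", "TCA", "TCG", "AGT", "AGC"),
    "T": ("ACT", "ACC", "ACA", "ACG"), "V": ("GTT", "GTC", "GTA", "GTG"),
    "W": ("TGG",), "Y": ("TAT", "TAC"),
}


def reverse_translate(protein: str, rng: Optional[np.random.Generator] = None
                      ) -> str:
    """A CDS encoding ``protein`` (random synonymous codons if ``rng``)."""
    if rng is None:
        return "".join(_CODONS[a] for a in protein.upper())
    return "".join(
        _SYNONYMS[a][rng.integers(len(_SYNONYMS[a]))] for a in protein.upper())


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def make_transcript(gene_id: str, cds: str, rng: np.random.Generator,
                    utr5: int = 45, utr3: int = 60) -> SequenceRecord:
    """Embed a CDS in UTRs; an in-frame upstream stop pins the ORF."""
    five = _random_dna(rng, max(utr5 - 3, 0)) + "TAA"
    three = _random_dna(rng, utr3)
    return SequenceRecord(gene_id, five + cds + "TAA" + three, moltype="nt")


def make_clean_transcript(gene_id: str, protein: str,
                          rng: np.random.Generator, utr5: int = 45,
                          utr3: int = 60, max_tries: int = 100
                          ) -> tuple[SequenceRecord, str]:
    """A transcript whose longest six-frame ORF is exactly ``protein``.

    Random synonymous coding occasionally leaves a longer stop-free
    stretch in another frame (typically the reverse complement of the
    CDS), which would make an ORF caller recover an artifact instead of
    the planted product.  Codon choices and UTRs are resampled until
    the planted ORF wins.  Returns (transcript, cds).
    """
    from .orf import longest_orf  # local import: orf does not import simulate
    for _ in range(max_tries):
        cds = reverse_translate(protein, rng)
        transcript = make_transcript(gene_id, cds, rng, utr5, utr3)
        call = longest_orf(transcript, min_aa=1)
        if call is not None and call.protein == protein:
            return transcript, cds
    raise RuntimeError(
        f"could not pin the planted ORF for {gene_id!r} in {max_tries} tries")


def plant_gene(cds: SequenceRecord,
               intron_specs: Sequence[tuple[int, int, str]],
               flank_lengths: tuple[int, int] = (100, 100),
               seed: int | np.random.Generator = 0
               ) -> tuple[SequenceRecord, GeneModel]:
    """Build a genomic sequence with introns planted into a CDS.

    ``intron_specs`` are (cds_offset, length, splice) with offsets
    strictly inside the CDS and ascending; splice "GT..AG" writes
    canonical dinucleotides.  Returns the genomic record and the true
    GeneModel in genomic coordinates.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    c = cds.residues.upper()
    L = len(c)
    specs = sorted(intron_specs)
    prev = 0
    for off, length, _ in specs:
        if not 0 < off < L:
            raise ValueError(f"intron offset {off} not strictly inside CDS")
        if off <= prev and prev != 0:
            raise ValueError("intron offsets must be distinct and ascending")
        if length < 4:
            raise ValueError("intron length must be >= 4 to carry splice sites")
        prev = off
    left, right = flank_lengths
    parts = [_random_dna(rng, left)]
    exons: list[tuple[int, int]] = []
    pos = left
    prev_off = 0
    for off, length, splice in specs:
        exon = c[prev_off:off]
        parts.append(exon)
        exons.append((pos, pos + len(exon)))
        pos += len(exon)
        if splice == "GT..AG":
            intron = "GT" + _random_dna(rng, length - 4) + "AG"
        else:
            if len(splice) != 4:
                raise ValueError("splice spec must be 'GT..AG' or 4 letters")
            intron = splice[:2] + _random_dna(rng, length - 4) + splice[2:]
        parts.append(intron)
        pos += length
        prev_off = off
    tail = c[prev_off:]
    parts.append(tail)
    exons.append((pos, pos + len(tail)))
    pos += len(tail)
    parts.append(_random_dna(rng, right))
    genomic = SequenceRecord(cds.id + "_genomic", "".join(parts), moltype="nt")
    sites = [("GT", "AG") if sp == "GT..AG" else (sp[:2], sp[2:])
             for _, _, sp in specs]
    return genomic, GeneModel(cds.id, exons, sites)


# ---------------------------------------------------------------------------
# GSI cross datasets
# ---------------------------------------------------------------------------

@dataclass
class ScenarioTruth:
    """A reciprocal-cross study design with known marker roles.

    ``parent_a`` is the seed (mother) parent of the forward cross.
    Marker copy numbers in the specs refer to parent_a (mother slot)
    and parent_b (father slot) of that forward orientation.
    """

    parent_a: SGenotype
    parent_b: SGenotype
    markers: list[MarkerSpec]
    true_roles: dict[str, str]

    def __post_init__(self) -> None:
        for m in self.markers:
            if m.linkage == "s_linked":
                if not (self.parent_a.carries(m.linked_allele)
                        or self.parent_b.carries(m.linked_allele)):
                    raise ValueError(
                        f"marker {m.marker_id} references allele "
                        f"{m.linked_allele} carried by neither parent")

    def parent_presence(self) -> dict[str, tuple[bool, bool]]:
        out = {}
        for m in self.markers:
            if m.linkage == "s_linked":
                out[m.marker_id] = (self.parent_a.carries(m.linked_allele),
                                    self.parent_b.carries(m.linked_allele))
            else:
                out[m.marker_id] = (m.mother_copies > 0, m.father_copies > 0)
        return out


def default_scenario(r: float = 0.0, include_het_one: bool = False,
                     marker_prefix: str = "M_") -> ScenarioTruth:
    """The semi-compatible reciprocal design: S1Sx mother x S1Sy father.

    Five planted markers (six with ``include_het_one``): a shared
    S-linked marker, one unique S-linked marker per parent, an unlinked
    marker hemizygous in both parents, and a marker homozygous in the
    mother.
    """
    p = marker_prefix
    markers = [
        MarkerSpec(p + "S1", "s_linked", "S1", r),
        MarkerSpec(p + "Sx", "s_linked", "Sx", r),
        MarkerSpec(p + "Sy", "s_linked", "Sy", r),
        MarkerSpec(p + "unl", "unlinked", mother_copies=1, father_copies=1),
        MarkerSpec(p + "hom", "unlinked", mother_copies=2, father_copies=0),
    ]
    roles = {p + "S1": "shared_S", p + "Sx": "unique_S_mother",
             p + "Sy": "unique_S_father", p + "unl": "unlinked_het_both",
             p + "hom": "homozygous_non_S"}
    if include_het_one:
        markers.append(MarkerSpec(p + "unl1", "unlinked", mother_copies=0,
                                  father_copies=1))
        roles[p + "unl1"] = "unlinked_het_one"
    return ScenarioTruth(SGenotype(("S1", "Sx")), SGenotype(("S1", "Sy")),
                         markers, roles)


def _swap_orientation(m: MarkerSpec) -> MarkerSpec:
    return MarkerSpec(m.marker_id, m.linkage, m.linked_allele, m.r,
                      mother_copies=m.father_copies,
                      father_copies=m.mother_copies)


def gen_cross_dataset(scenario: ScenarioTruth, n_forward: int = 81,
                      n_reciprocal: int = 95, miscall_rate: float = 0.0,
                      seed: int = 0
                      ) -> tuple[ProgenyTable, ProgenyTable, dict[str, str]]:
    """Simulate both directions of the reciprocal cross with markers.

    Optional genotyping noise flips each presence call with probability
    ``miscall_rate`` (applied to both directions).
    """
    if not 0.0 <= miscall_rate <= 0.05:
        raise ValueError("miscall_rate must be in [0, 0.05]")
    rng = np.random.default_rng(seed)
    fwd = gsi_cross(scenario.parent_a, scenario.parent_b, n_forward, rng)
    fwd = attach_markers(fwd, scenario.markers, rng)
    rec = gsi_cross(scenario.parent_b, scenario.parent_a, n_reciprocal, rng)
    rec = attach_markers(rec, [_swap_orientation(m) for m in scenario.markers],
                         rng)
    if miscall_rate > 0.0:
        for table in (fwd, rec):
            for mid in table.marker_ids:
                flips = rng.random(table.n) < miscall_rate
                table.data[mid] = table.data[mid].to_numpy() ^ flips
    return fwd, rec, dict(scenario.true_roles)


# ---------------------------------------------------------------------------
# Counts and tissue panels
# ---------------------------------------------------------------------------

def gen_counts(genes: Sequence[str] | int = 200, n_per_group: int = 3,
               nb_dispersion: float = 0.1,
               planted: Sequence[tuple[str, float]] = (),
               mean_log_expression: float = math.log(100.0),
               sd_log_expression: float = 1.2,
               lib_size_sd: float = 0.15,
               seed: int = 0) -> tuple[pd.DataFrame, dict[str, float]]:
    """Negative-binomial count matrix for a two-group comparison.

    Per-gene base means are log-normal; library sizes are log-normal
    factors (sd ``lib_size_sd`` on the log scale) emulating sequencing
    depth variation at desk scale.  ``planted`` scales group-2 means by
    the given fold (fold < 1 = down-regulated in group 2).  Returns the
    genes x samples DataFrame and the truth fold map.
    """
    if nb_dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    rng = np.random.default_rng(seed)
    if isinstance(genes, int):
        genes = [f"g{i:04d}" for i in range(genes)]
    genes = list(genes)
    folds = dict(planted)
    for g, f in folds.items():
        if f <= 0:
            raise ValueError(f"planted fold for {g} must be > 0")
        if g not in genes:
            raise ValueError(f"planted gene {g!r} not in gene list")
    base = np.exp(rng.normal(mean_log_expression, sd_log_expression,
                             len(genes)))
    samples = ([f"group1_{i + 1}" for i in range(n_per_group)]
               + [f"group2_{i + 1}" for i in range(n_per_group)])
    lib = np.exp(rng.normal(0.0, lib_size_sd, len(samples)))
    size = 1.0 / nb_dispersion
    data = np.zeros((len(genes), len(samples)), dtype=int)
    for gi, g in enumerate(genes):
        for si, s in enumerate(samples):
            mu = base[gi] * lib[si]
            if s.startswith("group2"):
                mu *= folds.get(g, 1.0)
            p = size / (size + mu)
            data[gi, si] = rng.negative_binomial(size, p)
    df = pd.DataFrame(data, index=genes, columns=samples)
    return df, folds


def gen_tissue_panel(genes: Sequence[str], truth_labels: dict[str, str],
                     tissues: Sequence[str] = TISSUE_VOCABULARY,
                     seed: int = 0) -> pd.DataFrame:
    """Boolean detection matrix consistent with each gene's truth label."""
    rng = np.random.default_rng(seed)
    tissues = list(tissues)
    pistil = [t for t in tissues if t in PISTIL_TISSUES]
    other = [t for t in tissues if t not in PISTIL_TISSUES]
    rows = {}
    for g in genes:
        label = truth_labels[g]
        detected: set[str] = set()
        if label == "pistil_specific":
            k = int(rng.integers(1, len(pistil) + 1))
            detected = set(rng.choice(pistil, size=k, replace=False))
        elif label == "pistil_plus_other":
            detected = set(rng.choice(pistil,
                                      size=int(rng.integers(1, len(pistil) + 1)),
                                      replace=False))
            # at least one non-pistil tissue, but never the full panel
            # (the full panel would read back as ubiquitous)
            n_other = (int(rng.integers(1, len(other))) if len(other) > 1
                       else len(other))
            detected |= set(rng.choice(other, size=n_other, replace=False))
            if detected == set(tissues):
                detected.discard(sorted(detected & set(pistil))[-1])
        elif label == "ubiquitous":
            detected = set(tissues)
        elif label != "not_detected":
            raise ValueError(f"unknown truth label {label!r} for {g}")
        rows[g] = {t: t in detected for t in tissues}
    return pd.DataFrame.from_dict(rows, orient="index", columns=tissues)
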