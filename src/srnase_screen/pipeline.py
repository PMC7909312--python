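"""End-to-end S-RNase candidate screen.

Chains the pipeline stages over one study: ORF extraction and
redundancy clustering, protein features, alignment-based class/LPSC
assignment, intron structure, tissue specificity, and reciprocal-cross
segregation roles.  A gene is designated an S-RNase candidate when it
satisfies every line of evidence expected of the female GSI
determinant:

* class III, outside any low-polymorphic subcluster;
* basic isoelectric point and both CAS catalytic histidines;
* exactly one intron, located in the hypervariable region;
* pistil-specific expression;
* S-linked inheritance (shared or parent-unique) in reciprocal crosses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import simulate
from .expression import tissue_specificity
from .features import (EMBOSS_PKA, compute_features, detect_cas_histidines)
from .genetics import classify_markers, make_segregation_record
from .io import RunConfig, SequenceRecord
from .orf import greedy_cluster, longest_orf
from .phylo import Msa, assign_class, detect_lpsc, progressive_msa
from .simulate import BACKBONE_WINDOWS, CAS_RESIDUES
from .structure import HvWindows, infer_gene_structure, intron_in_hv


@dataclass
class CandidateReport:
    """Per-gene screening verdict with per-criterion evidence."""

    gene_id: str
    class_label: str = "unclassified"
    class_support: float = 0.0
    lpsc: bool = False
    pI: float = float("nan")
    mw: float = float("nan")
    basic_pi: bool = False
    cas1_his: bool = False
    cas2_his: bool = False
    intron_count: Optional[int] = None
    intron_position: str = "no_structure"
    single_intron_in_hv: bool = False
    tissue_label: str = "no_panel"
    pistil_specific: bool = False
    role: str = "no_markers"
    s_linked_role: bool = False
    s_haplotype: Optional[str] = None
    is_candidate: bool = False

    def evaluate(self) -> None:
        self.is_candidate = (
            self.class_label == "III" and not self.lpsc and self.basic_pi
            and self.cas1_his and self.cas2_his and self.single_intron_in_hv
            and self.pistil_specific and self.s_linked_role)


@dataclass
class StudyData:
    """All synthetic inputs of one study plus the planted truth."""

    transcripts: list[SequenceRecord]
    genomic: dict[str, SequenceRecord]
    family_truth: simulate.FamilyTruth
    references: list[SequenceRecord]
    tissue_panel: pd.DataFrame
    forward_progeny: object
    reciprocal_progeny: object
    marker_roles_truth: dict[str, str]
    gene_to_marker: dict[str, str]
    counts: pd.DataFrame
    planted_folds: dict[str, float]
    planted_candidates: list[str]
    tissue_truth: dict[str, str]
    scenario: Optional[simulate.ScenarioTruth] = None


def columns_from_row(row: str, residue_positions) -> list[int]:
    """Map ungapped residue indices to alignment columns on a row."""
    cols = [i for i, ch in enumerate(row) if ch != "-"]
    return [cols[p] for p in residue_positions]


def hv_windows_from_row(row: str, residue_windows=BACKBONE_WINDOWS) -> HvWindows:
    """Translate residue-coordinate windows on a reference into
    alignment-column windows via the reference's aligned row."""
    cols = [i for i, ch in enumerate(row) if ch != "-"]
    out = []
    for name, s, e in residue_windows:
        if s < len(cols):
            out.append((name, cols[s], cols[min(e, len(cols)) - 1] + 1))
    return HvWindows(out)


def generate_study(seed: int = 0, n_class1: int = 2, n_class2: int = 2,
                   lpsc_size: int = 3, de_fold: float = 0.125,
                   n_forward: int = 81, n_reciprocal: int = 95,
                   n_background_genes: int = 60) -> StudyData:
    """Generate a complete synthetic study mirroring a semi-compatible
    reciprocal-cross S-RNase survey.

    The family carries three true S-RNases (shared S1 plus one unique
    allele per parent) and a three-member class III LPSC of decoys; the
    mother-unique S-RNase is planted ``de_fold``-fold down-regulated in
    the self-compatible mutant count matrix, and the first LPSC decoy
    is expressed in anther/pollen.
    """
    rng = np.random.default_rng(seed)
    family, truth = simulate.gen_family(
        n_per_class={"I": n_class1, "II": n_class2, "III": 3},
        lpsc_spec=(lpsc_size, 0.90), seed=int(rng.integers(2 ** 31)))
    class3 = truth.ids_in_class("III")
    lpsc_ids = [i for i in class3 if truth.members[i].lpsc]
    srnase_ids = [i for i in class3 if not truth.members[i].lpsc]
    g_s1, g_sx, g_sy = srnase_ids[:3]

    references = [r for r in family if truth.members[r.id].is_reference]
    members = [r for r in family if not truth.members[r.id].is_reference]

    # transcripts + genomic sequences with planted introns
    transcripts: list[SequenceRecord] = []
    genomic: dict[str, SequenceRecord] = {}
    hv2 = next(w for w in BACKBONE_WINDOWS if w[0] == "HV2")
    for rec in members:
        transcript, cds_seq = simulate.make_clean_transcript(rec.id,
                                                             rec.residues, rng)
        cds = SequenceRecord(rec.id, cds_seq, moltype="nt")
        transcripts.append(transcript)
        label = truth.members[rec.id].class_label
        if label == "III":
            codon = int(rng.integers(hv2[1], hv2[2]))
            length = int(rng.integers(87, 375))
            specs = [(codon * 3, length, "GT..AG")]
        elif label == "I":
            c1 = int(rng.integers(20, 60))
            c2 = int(rng.integers(90, 150))
            specs = [(c1 * 3, int(rng.integers(87, 375)), "GT..AG"),
                     (c2 * 3, int(rng.integers(87, 375)), "GT..AG")]
        else:
            specs = []
        g, _ = simulate.plant_gene(cds, specs, seed=rng)
        genomic[rec.id] = g

    # markers named after the genes they tag
    scenario = simulate.default_scenario(include_het_one=True)
    marker_map = {"M_S1": g_s1, "M_Sx": g_sx, "M_Sy": g_sy,
                  "M_unl": lpsc_ids[1], "M_hom": lpsc_ids[0],
                  "M_unl1": lpsc_ids[2]}
    fwd, rec_tab, roles_truth = simulate.gen_cross_dataset(
        scenario, n_forward, n_reciprocal, seed=int(rng.integers(2 ** 31)))
    gene_to_marker = {g: m for m, g in marker_map.items()}

    # tissue truth: S-RNases pistil-specific; first LPSC decoy leaks into
    # anther/pollen; classes I/II are broadly expressed
    tissue_truth = {}
    for rec in members:
        label = truth.members[rec.id].class_label
        if rec.id in srnase_ids:
            tissue_truth[rec.id] = "pistil_specific"
        elif rec.id == lpsc_ids[0]:
            tissue_truth[rec.id] = "pistil_plus_other"
        elif truth.members[rec.id].lpsc:
            tissue_truth[rec.id] = "pistil_specific"
        else:
            tissue_truth[rec.id] = ("ubiquitous" if label == "I"
                                    else "pistil_plus_other")
    panel = simulate.gen_tissue_panel([r.id for r in members], tissue_truth,
                                      seed=int(rng.integers(2 ** 31)))

    # SI vs SC-mutant style counts: the mother-unique S-RNase is silenced
    gene_names = [r.id for r in members] + [
        f"bg{i:03d}" for i in range(n_background_genes)]
    counts, folds = simulate.gen_counts(
        gene_names, planted=[(g_sx, de_fold)],
        seed=int(rng.integers(2 ** 31)))

    return StudyData(transcripts, genomic, truth, references, panel,
                     fwd, rec_tab, roles_truth, gene_to_marker, counts, folds,
                     planted_candidates=sorted(srnase_ids),
                     tissue_truth=tissue_truth, scenario=scenario)


def run_screen(study: StudyData, config: RunConfig | None = None
               ) -> dict[str, CandidateReport]:
    """Run the full screen on a study and return per-gene reports."""
    cfg = config or RunConfig()

    # stage 1: ORFs and redundancy collapse
    proteins: list[SequenceRecord] = []
    for t in study.transcripts:
        call = longest_orf(t, min_aa=cfg.min_orf_aa)
        if call is not None:
            proteins.append(SequenceRecord(t.id, call.protein, moltype="aa"))
    clusters = greedy_cluster(proteins, cfg.cluster_identity)
    reps = {c.representative_id for c in clusters}
    proteins = [p for p in proteins if p.id in reps]

    # stage 2: alignment, classes, LPSC
    msa = progressive_msa(study.references + proteins)
    ref_labels = {r.id: study.family_truth.members[r.id].class_label
                  for r in study.references}
    assignments = assign_class([p.id for p in proteins], ref_labels, msa,
                               floor=cfg.class_floor)
    class3 = [p.id for p in proteins if assignments[p.id].label == "III"]
    lpsc_groups = detect_lpsc(class3, msa, cfg.lpsc_identity)
    lpsc_members = {m for grp in lpsc_groups for m in grp}

    # stage 3: protein features and CAS histidines on the class III
    # reference row
    feats = {f.id: f for f in compute_features(proteins, EMBOSS_PKA)}
    ref3_row = msa.row("REF_III")
    cas_cols = tuple(columns_from_row(ref3_row,
                                      study.family_truth.cas_residues))
    hv = hv_windows_from_row(ref3_row)

    # stage 4: segregation roles
    presence = _marker_presence(study)
    seg_f, seg_r = {}, {}
    for mid in presence:
        seg_f[mid] = make_segregation_record(
            mid, *study.forward_progeny.marker_counts(mid))
        seg_r[mid] = make_segregation_record(
            mid, *study.reciprocal_progeny.marker_counts(mid))
    roles = classify_markers(presence, seg_f, seg_r, study.forward_progeny,
                             alpha=cfg.alpha)

    reports: dict[str, CandidateReport] = {}
    for p in proteins:
        rep = CandidateReport(p.id)
        a = assignments[p.id]
        rep.class_label, rep.class_support = a.label, a.support
        rep.lpsc = p.id in lpsc_members
        f = feats[p.id]
        rep.pI, rep.mw = f.pI, f.mw
        rep.basic_pi = f.pI > cfg.pi_basic_cutoff
        rep.cas1_his, rep.cas2_his = detect_cas_histidines(msa.row(p.id),
                                                           cas_cols)
        if p.id in study.genomic:
            model = _structure_for(study, p.id)
            if model is not None:
                rep.intron_count = len(model.introns)
                ok, label = intron_in_hv(model, msa.row(p.id), hv)
                rep.single_intron_in_hv = ok
                rep.intron_position = label
        if p.id in study.tissue_panel.index:
            rep.tissue_label = tissue_specificity(
                study.tissue_panel.loc[p.id].to_dict())
            rep.pistil_specific = rep.tissue_label == "pistil_specific"
        mid = study.gene_to_marker.get(p.id)
        if mid is not None:
            rep.role = roles[mid]
            rep.s_linked_role = rep.role in ("shared_S", "unique_S_mother",
                                             "unique_S_father")
            if rep.s_linked_role:
                rep.s_haplotype = {"shared_S": "S1",
                                   "unique_S_mother": "Sx",
                                   "unique_S_father": "Sy"}[rep.role]
        rep.evaluate()
        reports[p.id] = rep
    return reports


def _marker_presence(study: StudyData) -> dict[str, tuple[bool, bool]]:
    scenario = study.scenario or simulate.default_scenario(include_het_one=True)
    return scenario.parent_presence()


def _structure_for(study: StudyData, gene_id: str):
    """Infer the gene model from the transcript's own CDS and genome."""
    transcript = next(t for t in study.transcripts if t.id == gene_id)
    call = longest_orf(transcript, min_aa=1)
    cds_start = call.nt_start
    cds = transcript.residues[call.nt_start:call.nt_end - 3]  # strip stop
    try:
        return infer_gene_structure(
            SequenceRecord(gene_id, cds, moltype="nt"),
            study.genomic[gene_id])
    except ValueError:
        return None


def designated_candidates(reports: dict[str, CandidateReport]) -> list[str]:
    return sorted(g for g, r in reports.items() if r.is_candidate)


def reports_to_frame(reports: dict[str, CandidateReport]) -> pd.DataFrame:
    rows = {g: vars(r).copy() for g, r in reports.items()}
    for r in rows.values():
        r.pop("gene_id")
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()
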