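"""Expression evidence: tissue specificity, qPCR fold change, and a
permutation differential-expression test.

The female S determinant of a GSI species must be pistil-specific;
detection of a candidate in anther/pollen disqualifies it.  Relative
qPCR quantification uses the 2^-ddCt method against a reference gene
and a control condition.  The differential-expression test is a
pooled-null permutation test on library-size-normalised counts — it is
NOT equivalent to a negative-binomial Wald test (DESeq2-style), and all
outputs carry that label.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DE_TEST_LABEL = "pooled-permutation (NON-EQUIVALENT to DESeq2)"

TISSUE_VOCABULARY = ("style", "stigma", "ovary", "anther_pollen", "filament",
                     "sepal", "petal", "albedo", "flavedo", "juice_sac")
PISTIL_TISSUES = frozenset({"stigma", "style", "ovary"})


def tissue_specificity(panel_row: Mapping[str, float | bool],
                       pistil_set: frozenset = PISTIL_TISSUES,
                       detect_threshold: float = 0.5) -> str:
    """Classify a gene's detection pattern across a tissue panel.

    * ``not_detected`` — no tissue above threshold;
    * ``pistil_specific`` — detected only in pistil tissues;
    * ``ubiquitous`` — detected in every tissue of the panel;
    * ``pistil_plus_other`` — any non-pistil detection otherwise
      (anther/pollen detection always lands here: the disqualifier).

    The result is invariant to tissue column order.
    """
    unknown = set(panel_row) - set(TISSUE_VOCABULARY)
    if unknown:
        raise ValueError(f"unknown tissue name(s): {sorted(unknown)}")
    detected = {t for t, v in panel_row.items() if float(v) > detect_threshold}
    if not detected:
        return "not_detected"
    if detected == set(panel_row):
        return "ubiquitous"
    if detected <= pistil_set:
        return "pistil_specific"
    return "pistil_plus_other"


@dataclass(frozen=True)
class QpcrMeasurement:
    """Ct replicates for target and reference genes in two conditions."""

    ct_target_test: tuple[float, ...]
    ct_reference_test: tuple[float, ...]
    ct_target_control: tuple[float, ...]
    ct_reference_control: tuple[float, ...]

    def __post_init__(self) -> None:
        for name, reps in self.__dict__.items():
            if len(reps) < 1:
                raise ValueError(f"{name} has no replicates")
            if any(ct <= 0 for ct in reps):
                raise ValueError(f"{name} contains non-positive Ct")


@dataclass(frozen=True)
class DdctResult:
    fold_change: float
    ddct: float
    se_ddct: float  # replicate SE propagated through the two subtractions


def _mean_sem(reps: Sequence[float]) -> tuple[float, float]:
    m = sum(reps) / len(reps)
    if len(reps) < 2:
        return m, 0.0
    var = sum((x - m) ** 2 for x in reps) / (len(reps) - 1)
    return m, math.sqrt(var / len(reps))


def ddct(m: QpcrMeasurement) -> DdctResult:
    """Relative expression by the 2^-ddCt method.

    dCt = Ct_target - Ct_reference per condition; ddCt = dCt_test -
    dCt_control; fold change = 2^-ddCt.  Replicate standard errors are
    propagated in quadrature onto ddCt.
    """
    tt, se_tt = _mean_sem(m.ct_target_test)
    rt, se_rt = _mean_sem(m.ct_reference_test)
    tc, se_tc = _mean_sem(m.ct_target_control)
    rc, se_rc = _mean_sem(m.ct_reference_control)
    dd = (tt - rt) - (tc - rc)
    se = math.sqrt(se_tt ** 2 + se_rt ** 2 + se_tc ** 2 + se_rc ** 2)
    return DdctResult(2.0 ** (-dd), dd, se)


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------

def benjamini_hochberg(pvals: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p-values (q-values), capped at 1."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def median_of_ratios_size_factors(counts: pd.DataFrame) -> pd.Series:
    """DESeq-style library size factors.

    Per sample, the median ratio of counts to the per-gene geometric
    mean, over genes with counts in every sample.
    """
    log_counts = np.log(counts.where(counts > 0))
    # skipna=False: only genes with nonzero counts in EVERY sample enter
    log_geo = log_counts.mean(axis=1, skipna=False)
    usable = np.isfinite(log_geo)
    if not usable.any():
        raise ValueError("no gene has nonzero counts in every sample")
    ratios = log_counts.loc[usable].sub(log_geo[usable], axis=0)
    return np.exp(ratios.median(axis=0))


@dataclass(frozen=True)
class DeResult:
    gene: str
    log2_fold_change: float
    p: float
    q: float
    direction: str  # "up" | "down" | "none"
    all_zero: bool = False


def _moderated_stats(log_norm: np.ndarray, idx1: np.ndarray,
                     idx2: np.ndarray, s0: float | None = None
                     ) -> tuple[np.ndarray, float]:
    g1 = log_norm[:, idx1]
    g2 = log_norm[:, idx2]
    diff = g2.mean(axis=1) - g1.mean(axis=1)
    se = np.sqrt(g1.var(axis=1, ddof=1) / g1.shape[1]
                 + g2.var(axis=1, ddof=1) / g2.shape[1])
    if s0 is None:
        s0 = float(np.median(se))
        if s0 == 0.0:
            s0 = 1.0
    return diff / (se + s0), s0


def simple_de_test(counts: pd.DataFrame, group1: Sequence[str],
                   group2: Sequence[str], n_perm: int = 1000,
                   seed: int = 0) -> list[DeResult]:
    """Permutation differential-expression test with a pooled null.

    Counts are normalised by median-of-ratios size factors; the
    per-gene statistic is a moderated difference of group means of log2
    normalised counts (group2 minus group1).  P values compare each
    gene's |statistic| to the permutation distribution pooled across
    all genes — label assignments are enumerated exhaustively when
    there are <= 20 distinct ones (e.g. 3 vs 3), else ``n_perm`` random
    draws are used.  BH correction yields q.  All-zero genes get p = 1
    and are flagged.

    This test is NOT equivalent to DESeq2's negative-binomial model;
    see ``DE_TEST_LABEL``.
    """
    if len(group1) < 2 or len(group2) < 2:
        raise ValueError("need >= 2 samples per group")
    samples = list(group1) + list(group2)
    sub = counts[samples]
    sf = median_of_ratios_size_factors(sub)
    norm = sub / sf
    log_norm = np.log2(norm.to_numpy(dtype=float) + 1.0)
    n1 = len(group1)
    idx1 = np.arange(n1)
    idx2 = np.arange(n1, n1 + len(group2))
    obs, s0 = _moderated_stats(log_norm, idx1, idx2)

    cols = np.arange(len(samples))
    assignments = [a for a in itertools.combinations(cols, n1)]
    if len(assignments) <= 20:
        perms = assignments
    else:
        rng = np.random.default_rng(seed)
        perms = [tuple(rng.permutation(cols)[:n1]) for _ in range(n_perm)]
    null_pool: list[np.ndarray] = []
    for a in perms:
        ia = np.array(a)
        ib = np.array([c for c in cols if c not in set(a)])
        stats, _ = _moderated_stats(log_norm, ia, ib, s0=s0)
        null_pool.append(np.abs(stats))
    null = np.sort(np.concatenate(null_pool))

    abs_obs = np.abs(obs)
    # P(|null| >= |obs|) over the pooled permutation distribution
    ge = len(null) - np.searchsorted(null, abs_obs, side="left")
    p = ge / len(null)
    all_zero = (sub.to_numpy() == 0).all(axis=1)
    p = np.where(all_zero, 1.0, np.clip(p, 0.0, 1.0))
    q = benjamini_hochberg(p)

    lfc = (log_norm[:, idx2].mean(axis=1) - log_norm[:, idx1].mean(axis=1))
    results = []
    for i, gene in enumerate(sub.index):
        direction = "none"
        if not all_zero[i] and lfc[i] > 0:
            direction = "up"
        elif not all_zero[i] and lfc[i] < 0:
            direction = "down"
        results.append(DeResult(str(gene), float(lfc[i]), float(p[i]),
                                float(q[i]), direction, bool(all_zero[i])))
    return results
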