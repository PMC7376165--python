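"""Annotation enrichment analyses.

Two complementary views of what a particle panel samples:

* :func:`fisher_enrichment` — binary panel-versus-reference enrichment per
  annotation term (two-sided Fisher's exact test on the 2×2 of panel
  membership × term membership within the reference universe, BH-adjusted
  per space, infinite log2 odds clamped to the extreme finite value for
  reporting only);
* :func:`one_d_enrichment` — rank-based continuous enrichment of
  per-particle difference scores: for each (term, particle) a two-sided
  Mann–Whitney test of member versus non-member scores with the summary
  score s = 2U/(n1·n2) − 1 ∈ [−1, 1] (s > 0: members sit high in the
  score distribution, i.e. the annotation is enriched on that particle).

Difference scores follow the median-normalized log10 intensity
convention: per protein, the median on one particle minus the mean of its
medians on all other particles, restricted to proteins quantified in all
replicates on at least one particle.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrixio import AnnotationCatalog, IntensityTensor

logger = logging.getLogger(__name__)


@dataclass
class FisherRecord:
    term_id: str
    space: str
    table: tuple  # ((in-panel annotated, in-panel not), (out annotated, out not))
    log2_odds: float
    p_value: float
    fdr: float
    enriched: bool  # True: log2 odds > 0


def fisher_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the 2×2 table [[a, b], [c, d]]."""
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def fisher_enrichment(
    panel_proteins,
    reference,
    catalog: AnnotationCatalog,
    fdr_level: float = 0.01,
) -> list[FisherRecord]:
    """Fisher's exact enrichment of panel-detected proteins within a
    reference universe, per annotation term of one space.

    Panel proteins outside the reference are dropped with a warning. Terms
    with no member in the reference are skipped. BH adjustment is applied
    across the terms of this space; records are returned for all tested
    terms (filter on ``fdr`` downstream; ``fdr_level`` is carried for the
    enriched/depleted call convention only, threshold decisions belong to
    the caller).
    """
    reference = frozenset(reference)
    panel = frozenset(panel_proteins)
    outside = panel - reference
    if outside:
        warnings.warn(
            f"{len(outside)} panel proteins outside the reference universe were dropped"
        )
        panel &= reference
    records = []
    for term, members in catalog.terms.items():
        members = members & reference
        if not members:
            continue
        a = len(panel & members)
        b = len(panel) - a
        c = len(members) - a
        d = len(reference) - a - b - c
        p = fisher_p(a, b, c, d)
        with np.errstate(divide="ignore", invalid="ignore"):
            log2_or = np.log2((a * d) / (b * c)) if (b * c) != 0 else np.inf
            if a * d == 0 and b * c != 0:
                log2_or = -np.inf
            elif a * d == 0 and b * c == 0:
                log2_or = 0.0
        records.append(
            FisherRecord(term, catalog.space, ((a, b), (c, d)),
                         float(log2_or), float(p), np.nan, bool(log2_or > 0))
        )
    if not records:
        return records
    _, fdrs, _, _ = multipletests([r.p_value for r in records], method="fdr_bh")
    finite = [r.log2_odds for r in records if np.isfinite(r.log2_odds)]
    hi = max(finite) if finite else 0.0
    lo = min(finite) if finite else 0.0
    for r, q in zip(records, fdrs):
        r.fdr = float(q)
        if np.isposinf(r.log2_odds):
            r.log2_odds = hi  # clamp affects the reported score only, never p
        elif np.isneginf(r.log2_odds):
            r.log2_odds = lo
    return records


# ---------------------------------------------------------------------
# difference scores and 1D enrichment
# ---------------------------------------------------------------------

def difference_scores(tensor: IntensityTensor, require_full_quant: bool = True) -> pd.DataFrame:
    """Per-(protein, particle) difference score: the protein's median
    normalized log10 intensity on that particle minus the mean of its
    per-particle medians over all other particles.

    Expects a median-normalized log-scale tensor (matrixio.median_normalize_log).
    Proteins not quantified in all replicates on at least one particle are
    removed when ``require_full_quant``. Returns proteins × particles.
    """
    if tensor.scale != "log10":
        raise ValueError("difference scores expect a median-normalized log10 tensor")
    np_ids = tensor.np_ids
    if len(np_ids) < 2:
        raise ValueError("difference scores need at least two particles")
    medians = {}
    full = {}
    for np_id in np_ids:
        sub = tensor.select(np_id=np_id).data
        medians[np_id] = sub.median(axis=1, skipna=True)
        full[np_id] = sub.notna().all(axis=1)
    med = pd.DataFrame(medians)
    if require_full_quant:
        keep = pd.DataFrame(full).any(axis=1)
        med = med.loc[keep]
    scores = {}
    for np_id in np_ids:
        others = [c for c in np_ids if c != np_id]
        scores[np_id] = med[np_id] - med[others].mean(axis=1)
    return pd.DataFrame(scores)


@dataclass
class OneDRecord:
    term_id: str
    space: str
    np_id: str
    score: float  # s in [-1, 1]
    p_value: float
    fdr: float
    group_size: int
    term_significant: bool = False  # FDR below level for >= 1 particle


def one_d_score(member_scores: np.ndarray, other_scores: np.ndarray) -> float:
    """s = 2U/(n1·n2) − 1, U counting member-over-non-member rank wins with
    ties as 1/2 (equivalently s = 2·P(member > other) − 1)."""
    n1, n2 = len(member_scores), len(other_scores)
    pooled = np.concatenate([member_scores, other_scores])
    ranks = stats.rankdata(pooled)
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return float(2.0 * u / (n1 * n2) - 1.0)


def _rank_test_p(member: np.ndarray, other: np.ndarray) -> float:
    exact = len(member) * len(other) <= 200 and len(np.unique(np.concatenate([member, other]))) == len(member) + len(other)
    res = stats.mannwhitneyu(member, other, alternative="two-sided",
                             method="exact" if exact else "asymptotic")
    return float(res.pvalue)


def one_d_enrichment(
    scores: pd.DataFrame,
    catalogs,
    min_size: int = 11,
    fdr_level: float = 0.02,
) -> list[OneDRecord]:
    """1D rank-based annotation enrichment of difference scores.

    For every (term, particle): two-sided Mann–Whitney test of member
    versus non-member scores with summary s = 2U/(n1 n2) − 1. Terms with
    fewer than ``min_size`` scored members on a particle are filtered (the
    "group size greater than 10" rule → minimal size 11). BH adjustment is
    per annotation space across all (term, particle) tests; a term is
    flagged significant if any particle reaches FDR < ``fdr_level``.
    """
    if isinstance(catalogs, AnnotationCatalog):
        catalogs = [catalogs]
    records: list[OneDRecord] = []
    for catalog in catalogs:
        space_records: list[OneDRecord] = []
        for np_id in scores.columns:
            col = scores[np_id].dropna()
            if col.empty:
                continue
            ids = frozenset(col.index)
            values = col.to_numpy()
            index_of = {p: i for i, p in enumerate(col.index)}
            for term, members in catalog.terms.items():
                hit = [index_of[p] for p in members if p in ids]
                n1 = len(hit)
                n2 = len(values) - n1
                if n1 < min_size or n2 < 1:
                    continue
                mask = np.zeros(len(values), dtype=bool)
                mask[hit] = True
                member, other = values[mask], values[~mask]
                s = one_d_score(member, other)
                p = _rank_test_p(member, other)
                space_records.append(
                    OneDRecord(term, catalog.space, np_id, s, p, np.nan, n1)
                )
        if space_records:
            _, fdrs, _, _ = multipletests([r.p_value for r in space_records], method="fdr_bh")
            for r, q in zip(space_records, fdrs):
                r.fdr = float(q)
            significant_terms = {r.term_id for r in space_records if r.fdr < fdr_level}
            for r in space_records:
                r.term_significant = r.term_id in significant_terms
        records.extend(space_records)
    return records


def one_d_score_matrix(records, significant_only: bool = True) -> pd.DataFrame:
    """Pivot 1D records to a (space, term) × particle score matrix, by
    default restricted to terms significant for at least one particle
    (clustering-ready)."""
    rows = [r for r in records if r.term_significant or not significant_only]
    if not rows:
        return pd.DataFrame()
    frame = pd.DataFrame(
        {"space": r.space, "term": r.term_id, "np_id": r.np_id, "score": r.score}
        for r in rows
    )
    return frame.pivot_table(index=["space", "term"], columns="np_id", values="score")
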