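"""Dataset-level (DSRank) and family-level (FAMRank) variant ranking.

DSRank averages the available normalized model scores per variant,

    D_i = (sum_j 1_i^j * S_i^(j)) / M_i,   M_i >= 2,

and flags as candidate-pathogenic every variant whose D_i lies at least two
standard deviations above the mean of D over the eligible dataset (inclusive
threshold; population-SD convention by default, recorded in the summary).
Variants scored by fewer than two models receive no D.

FAMRank ranks each variant within the subset of its carrying family's
variants and assigns one of five risk groups from rule conditions:

    5  interface-proximal (rung < 4 A) and top decile by >= 1 model,
       or top decile by all three models,
       or recurring in all affected members of >= 2 multi-patient families
       and top decile by >= 1 model in one of those families
    4  top decile by two models, or interface-proximal
    3  top decile by one model and carried by all (affected) members of a
       multi-patient family
    2  top decile by one model
    1  otherwise

"Top decile" is rank-based: the top ceil(0.10 * n_scored) variants of the
family by a model's normalized score, with ties at the cutoff included.
Groups 4-5 form the family-level candidate set; a variant carried by several
families takes its maximum group. The final candidate set is the union of
DSRank and FAMRank candidates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy import stats as sstats

from .cohort import CohortVariantSet, Variant, recurrence_across_families
from .errors import DataError
from .scoring import MODELS, ScoreRecord
from .structure import DistScore


@dataclass
class DSRankSummary:
    mu: float
    sigma: float
    threshold: float
    n_eligible: int
    sd_convention: Literal["population", "sample"] = "population"

    def to_dict(self) -> dict:
        return {"mu": self.mu, "sigma": self.sigma, "threshold": self.threshold,
                "n_eligible": self.n_eligible, "sd_convention": self.sd_convention}


@dataclass
class DSRankResult:
    variant_id: str
    D: float | None
    eligible: bool
    candidate: bool


def dsrank(
    records: Iterable[ScoreRecord],
    sd_convention: Literal["population", "sample"] = "population",
) -> tuple[list[DSRankResult], DSRankSummary]:
    """Average available normalized scores per variant and flag the >= 2 SD
    upper tail of the eligible (M >= 2) dataset."""
    records = list(records)
    ds: dict[str, float | None] = {}
    for rec in records:
        if rec.dsrank_eligible:
            ds[rec.variant_id] = sum(rec.S.values()) / rec.M
        else:
            ds[rec.variant_id] = None
    eligible = np.array([d for d in ds.values() if d is not None], dtype=float)
    if eligible.size < 2:
        raise DataError("fewer than 2 DSRank-eligible variants; summary degenerate")
    mu = float(eligible.mean())
    sigma = float(eligible.std(ddof=0 if sd_convention == "population" else 1))
    threshold = mu + 2.0 * sigma
    summary = DSRankSummary(mu=mu, sigma=sigma, threshold=threshold,
                            n_eligible=int(eligible.size),
                            sd_convention=sd_convention)
    results = [
        DSRankResult(variant_id=rec.variant_id, D=ds[rec.variant_id],
                     eligible=rec.dsrank_eligible,
                     candidate=(ds[rec.variant_id] is not None
                                and ds[rec.variant_id] >= threshold))
        for rec in records
    ]
    return results, summary


def family_top_decile(
    records: Mapping[str, ScoreRecord],
    family_variant_ids: Sequence[str],
    model: str,
    fraction: float = 0.10,
) -> set[str]:
    """Variants in the top ``ceil(fraction * n_scored)`` of a family's subset
    by one model's normalized score; ties at the cutoff are all included.
    Variants unscored by the model are never flagged."""
    scored = [(vid, records[vid].S[model]) for vid in family_variant_ids
              if vid in records and model in records[vid].S]
    if not scored:
        return set()
    k = math.ceil(fraction * len(scored))
    ordered = sorted(scored, key=lambda t: -t[1])
    cutoff = ordered[k - 1][1]
    return {vid for vid, s in scored if s >= cutoff}


@dataclass
class FamRankContext:
    """Boolean rule inputs for one (variant, family) pair. Prevalence and
    recurrence flags must already respect the multi-patient-family
    eligibility gate."""
    top_decile: dict[str, bool] = field(default_factory=dict)  # per model
    interface: bool = False
    prevalent_all: bool = False
    recurrent_multi_family: bool = False
    recurrent_top_decile: bool = False


@dataclass
class FamRankResult:
    variant_id: str
    family_id: str
    F: int
    fired_rules: list[str] = field(default_factory=list)
    top_decile_flags: dict[str, bool] = field(default_factory=dict)

    @property
    def candidate(self) -> bool:
        return self.F >= 4


def famrank_assign(variant_id: str, family_id: str, ctx: FamRankContext) -> FamRankResult:
    """Assign the highest risk group whose condition holds; order of rule
    evaluation does not matter."""
    n_top = sum(bool(v) for v in ctx.top_decile.values())
    fired: list[tuple[int, str]] = []
    if ctx.interface and n_top >= 1:
        fired.append((5, "interface+top_decile"))
    if n_top == len(MODELS):
        fired.append((5, "top_decile_all_models"))
    if ctx.recurrent_multi_family and ctx.recurrent_top_decile:
        fired.append((5, "recurrent+top_decile"))
    if n_top >= 2:
        fired.append((4, "top_decile_two_models"))
    if ctx.interface:
        fired.append((4, "interface"))
    if n_top >= 1 and ctx.prevalent_all:
        fired.append((3, "top_decile+prevalent_all"))
    if n_top >= 1:
        fired.append((2, "top_decile_one_model"))
    group = max((g for g, _ in fired), default=1)
    return FamRankResult(
        variant_id=variant_id, family_id=family_id, F=group,
        fired_rules=[r for g, r in fired if g == group],
        top_decile_flags=dict(ctx.top_decile))


def famrank(
    records: Iterable[ScoreRecord],
    cohort: CohortVariantSet,
    dist_scores: Mapping[str, DistScore] | None = None,
    fraction: float = 0.10,
    prevalence_scope: Literal["affected", "all_members"] = "affected",
) -> list[FamRankResult]:
    """FAMRank over every (variant, carrying family) pair of the cohort.

    ``prevalence_scope`` selects whether the group-3 "prevalent in all family
    members" condition counts affected members only (default) or every
    sequenced member. Both the prevalence and recurrence conditions apply
    only to families with more than one affected patient.
    """
    rec_by_id = {r.variant_id: r for r in records}
    dist_scores = dist_scores or {}
    recurrence = recurrence_across_families(cohort)

    families = cohort.families
    multi_patient = {fid for fid in families
                     if len(cohort.affected_members(fid)) > 1}
    fam_variant_ids = {fid: [v.variant_id for v in cohort.family_variants(fid)]
                       for fid in families}
    top = {
        (fid, model): family_top_decile(rec_by_id, vids, model, fraction)
        for fid, vids in fam_variant_ids.items() for model in MODELS
    }

    results: list[FamRankResult] = []
    for v in cohort.variants:
        recurring_fams = recurrence.get(v.variant_id, [])
        recurrent_multi = len(recurring_fams) >= 2
        recurrent_top = recurrent_multi and any(
            v.variant_id in top[(fid, model)]
            for fid in recurring_fams for model in MODELS)
        for fid in sorted(v.carrier_families()):
            if prevalence_scope == "affected":
                scope = cohort.affected_members(fid)
            else:
                scope = {m.member_id for m in families[fid]}
            carriers_here = {mem for fam, mem in v.carriers if fam == fid}
            prevalent = (fid in multi_patient and bool(scope)
                         and scope <= carriers_here)
            ctx = FamRankContext(
                top_decile={m: v.variant_id in top[(fid, m)] for m in MODELS},
                interface=(v.variant_id in dist_scores
                           and dist_scores[v.variant_id].interface_flag),
                prevalent_all=prevalent,
                recurrent_multi_family=recurrent_multi,
                recurrent_top_decile=recurrent_top,
            )
            results.append(famrank_assign(v.variant_id, fid, ctx))
    return results


@dataclass
class CandidateSet:
    ds_candidates: set[str]
    fam_candidates: set[str]
    genes: list[str] = field(default_factory=list)

    @property
    def union(self) -> set[str]:
        return self.ds_candidates | self.fam_candidates

    @property
    def overlap(self) -> set[str]:
        return self.ds_candidates & self.fam_candidates


def candidate_union(
    ds_results: Iterable[DSRankResult],
    fam_results: Iterable[FamRankResult],
    variants: Iterable[Variant] | None = None,
) -> CandidateSet:
    """Union of DSRank candidates and FAMRank groups 4-5 (per variant, the
    maximum group over its carrying families)."""
    ds = {r.variant_id for r in ds_results if r.candidate}
    fam_max: dict[str, int] = {}
    for r in fam_results:
        fam_max[r.variant_id] = max(fam_max.get(r.variant_id, 1), r.F)
    fam = {vid for vid, g in fam_max.items() if g >= 4}
    genes: list[str] = []
    if variants is not None:
        union = ds | fam
        seen = set()
        for v in variants:
            if v.variant_id in union and v.gene not in seen:
                seen.add(v.gene)
                genes.append(v.gene)
    return CandidateSet(ds_candidates=ds, fam_candidates=fam, genes=sorted(genes))


@dataclass
class FamilySizeRelation:
    rows: list[dict]  # family_id, n_variants, n_group_4_5
    r: float | None
    p: float | None
    note: str = ""


def famrank_family_size_relation(fam_results: Iterable[FamRankResult]) -> FamilySizeRelation:
    """Per-family variant count versus count of group-4/5 variants, with the
    Pearson correlation of the two columns (the family-size noise check)."""
    counts: dict[str, set[str]] = {}
    flagged: dict[str, set[str]] = {}
    for r in fam_results:
        counts.setdefault(r.family_id, set()).add(r.variant_id)
        if r.F >= 4:
            flagged.setdefault(r.family_id, set()).add(r.variant_id)
    rows = [{"family_id": fid, "n_variants": len(vids),
             "n_group_4_5": len(flagged.get(fid, set()))}
            for fid, vids in sorted(counts.items())]
    xs = np.array([row["n_variants"] for row in rows], dtype=float)
    ys = np.array([row["n_group_4_5"] for row in rows], dtype=float)
    if len(rows) < 2 or xs.std() == 0 or ys.std() == 0:
        return FamilySizeRelation(rows=rows, r=None, p=None,
                                  note="degenerate (zero variance or < 2 families)")
    res = sstats.pearsonr(xs, ys)
    note = "low-n (fewer than 3 families)" if len(rows) < 3 else ""
    return FamilySizeRelation(rows=rows, r=float(res.statistic),
                              p=float(res.pvalue), note=note)
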