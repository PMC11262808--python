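"""Synthetic study cohorts with known planted truth.

The generator emulates the statistical shape of a 12-family hereditary
breast-cancer study: per-family affected/unaffected counts as in the study
cohort, per-family variant counts drawn from a negative binomial spanning
roughly 9-243, three partially correlated predictor scores with per-model
coverage of about 82% / 97% / 73%, sparse (~12%) structural coverage, and a
handful of variants planted with extreme scores in every model they are
covered by. Model-score correlation is induced by a Gaussian copula: one
latent pathogenicity draw per variant from a trivariate normal with the
target pairwise correlations, pushed through monotone model-specific margins
(probit for the two [0,1]-scaled models; a negative linear margin for the
language-model log-odds, whose raw orientation is reversed).

Planted variants are covered by all three predictors by default and receive
raw scores beyond the most extreme unplanted score, which guarantees their
normalized scores sit at or above any configured quantile in every model.
Toy structures are minimal two-chain poly-glycine models whose closest
inter-chain atom pair sits at an exactly controlled distance; only the
geometry matters to the DIST score.

Everything is deterministic under (config, seed), and ``SyntheticCohort.write``
emits exactly the file dialects the pipeline consumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy.stats import norm

from .cohort import CohortVariantSet, Member, Variant, write_variant_table
from .enrichment import AnnotationMap
from .errors import ParameterError
from .ranking import CandidateSet, FamRankResult
from .scoring import MODELS
from .structure import (AtomRecord, ResidueMapping, ResidueRecord,
                        StructureModel, write_structure_pdb)

AA = "ACDEFGHIKLMNPQRSTVWY"

# affected / unaffected sequenced members per family, mirroring the study
STUDY_AFFECTED = (3, 1, 3, 5, 2, 3, 5, 3, 2, 3, 2, 3)
STUDY_UNAFFECTED = (0, 0, 0, 0, 1, 0, 0, 0, 1, 0, 0, 1)


@dataclass
class GeneratorConfig:
    n_families: int = 12
    affected_per_family: tuple[int, ...] = STUDY_AFFECTED
    unaffected_per_family: tuple[int, ...] = STUDY_UNAFFECTED
    variant_count_mean: float = 120.0     # negative binomial across families
    variant_count_shape: float = 2.0      # dispersion (smaller = wider)
    variant_count_min: int = 3
    coverage: dict[str, float] = field(default_factory=lambda: {
        "EVE": 0.82, "ESM": 0.97, "FIRM": 0.73})
    eve_direct_fraction: float = 0.07     # of covered EVE scores, not imputed
    structure_coverage: float = 0.12
    r_eve_esm: float = 0.60               # sequence models correlate more
    r_eve_firm: float = 0.35
    r_esm_firm: float = 0.35
    esm_mean: float = -6.11               # raw log-odds location / scale
    esm_scale: float = 1.5
    n_planted: int = 12
    planted_quantile: float = 0.99
    planted_full_coverage: bool = True
    n_recurrent: int = 5                  # cross-family recurrent variants
    common_fraction: float = 0.0          # contaminating >1%-frequency variants
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ParameterError("need at least one family")
        if len(self.affected_per_family) < self.n_families:
            raise ParameterError("affected_per_family shorter than n_families")
        if any(a < 1 for a in self.affected_per_family[: self.n_families]):
            raise ParameterError("every family needs >= 1 affected member")
        for p in (*self.coverage.values(), self.structure_coverage,
                  self.common_fraction):
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"probability {p} outside [0,1]")
        if not 0.0 < self.planted_quantile < 1.0:
            raise ParameterError("planted_quantile must be in (0,1)")
        if np.linalg.eigvalsh(self.correlation_matrix()).min() < -1e-9:
            raise ParameterError("correlation targets are not positive semi-definite")

    def correlation_matrix(self) -> np.ndarray:
        return np.array([
            [1.0, self.r_eve_esm, self.r_eve_firm],
            [self.r_eve_esm, 1.0, self.r_esm_firm],
            [self.r_eve_firm, self.r_esm_firm, 1.0],
        ])


@dataclass
class SyntheticCohort:
    cohort: CohortVariantSet
    raw_scores: dict[str, dict[str, float]]
    eve_source: dict[str, str]
    structures: dict[str, StructureModel]
    mappings: list[ResidueMapping]
    planted: list[str]
    common_ids: list[str]
    annotations: AnnotationMap
    config: GeneratorConfig

    def write(self, outdir: str | Path) -> None:
        """Emit the file dialects the pipeline consumes plus a truth JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_variant_table(self.cohort, outdir / "variants.tsv")
        with open(outdir / "families.tsv", "w") as fh:
            fh.write("family_id\tmember_id\taffected\n")
            for m in self.cohort.members:
                fh.write(f"{m.family_id}\t{m.member_id}\t{int(m.affected)}\n")
        by_vid = {v.variant_id: v for v in self.cohort.variants}
        with open(outdir / "scores_eve.tsv", "w") as fh:
            fh.write("protein_accession\tposition\tmut_aa\tscore\tsource\tvariant_id\n")
            for vid in sorted(self.raw_scores["EVE"]):
                v = by_vid[vid]
                fh.write(f"{v.protein_accession}\t{v.position}\t{v.mut_aa}\t"
                         f"{self.raw_scores['EVE'][vid]:.10g}\t"
                         f"{self.eve_source.get(vid, 'direct')}\t{vid}\n")
        for model, fname in (("ESM", "scores_esm.tsv"), ("FIRM", "scores_firm.tsv")):
            with open(outdir / fname, "w") as fh:
                fh.write("variant_id\tscore\n")
                for vid in sorted(self.raw_scores[model]):
                    fh.write(f"{vid}\t{self.raw_scores[model][vid]:.10g}\n")
        pdb_dir = outdir / "structures"
        pdb_dir.mkdir(exist_ok=True)
        for sid in sorted(self.structures):
            write_structure_pdb(self.structures[sid], pdb_dir / f"{sid}.pdb")
        with open(outdir / "structure_map.tsv", "w") as fh:
            fh.write("variant_id\tstructure_id\tchain_id\tresidue_number\tmatch_mode\n")
            for m in sorted(self.mappings, key=lambda x: (x.variant_id, x.structure_id)):
                fh.write(f"{m.variant_id}\t{m.structure_id}\t{m.chain_id}\t"
                         f"{m.residue_number}\t{m.match_mode}\n")
        with open(outdir / "annotations.tsv", "w") as fh:
            fh.write("term\tgene\tname\tnamespace\n")
            for term in sorted(self.annotations.terms):
                for gene in sorted(self.annotations.terms[term]):
                    fh.write(f"{term}\t{gene}\t{self.annotations.names.get(term, '')}"
                             f"\t{self.annotations.namespaces.get(term, '')}\n")
        truth = {"planted": sorted(self.planted),
                 "common": sorted(self.common_ids),
                 "config": {k: (list(v) if isinstance(v, tuple) else v)
                            for k, v in asdict(self.config).items()}}
        (outdir / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")


def _make_members(cfg: GeneratorConfig) -> list[Member]:
    members = []
    for i in range(cfg.n_families):
        fid = f"F{i + 1}"
        for j in range(cfg.affected_per_family[i]):
            members.append(Member(member_id=f"A{j + 1}", family_id=fid, affected=True))
        for j in range(cfg.unaffected_per_family[i]
                       if i < len(cfg.unaffected_per_family) else 0):
            members.append(Member(member_id=f"U{j + 1}", family_id=fid, affected=False))
    return members


def simulate_cohort(cfg: GeneratorConfig | None = None,
                    seed: int | None = None) -> SyntheticCohort:
    """Generate a full synthetic study: families, variants, scores,
    structures, annotations and truth labels. Deterministic under
    (config, seed); ``seed`` overrides ``cfg.seed``."""
    cfg = cfg or GeneratorConfig()
    if seed is not None:
        cfg = GeneratorConfig(**{**asdict(cfg), "seed": seed})
    rng = np.random.default_rng(cfg.seed)
    members = _make_members(cfg)
    affected = {f"F{i + 1}": [m.member_id for m in members
                              if m.family_id == f"F{i + 1}" and m.affected]
                for i in range(cfg.n_families)}

    # per-family variant counts: negative binomial around the study's spread
    shape = cfg.variant_count_shape
    p_nb = shape / (shape + cfg.variant_count_mean)
    counts = np.maximum(rng.negative_binomial(shape, p_nb, cfg.n_families),
                        cfg.variant_count_min)

    variants: list[Variant] = []
    common_ids: list[str] = []
    k = 0
    for i in range(cfg.n_families):
        fid = f"F{i + 1}"
        aff = affected[fid]
        for _ in range(int(counts[i])):
            k += 1
            vid = f"V{k:05d}"
            wt, mut = rng.choice(list(AA), size=2, replace=False)
            n_aff = len(aff)
            n_carry = n_aff if n_aff < 2 else int(rng.integers(2, n_aff + 1))
            carriers = {(fid, m) for m in
                        rng.choice(aff, size=n_carry, replace=False)}
            if rng.random() < cfg.common_fraction:
                af = float(rng.uniform(0.011, 0.2))
                common_ids.append(vid)
            else:
                af = float(rng.uniform(1e-6, 0.01))
            variants.append(Variant(
                variant_id=vid, gene=f"GENE{k:04d}",
                protein_accession=f"P{k:05d}",
                wt_aa=str(wt), position=int(rng.integers(6, 400)),
                mut_aa=str(mut), pop_af=af, carriers=carriers))

    # cross-family recurrence: carried by all affected of >= 2 multi-patient families
    multi = [fid for fid, aff in affected.items() if len(aff) > 1]
    if cfg.n_recurrent and len(multi) >= 2:
        eligible = [v for v in variants if v.variant_id not in common_ids]
        picks = rng.choice(len(eligible), size=min(cfg.n_recurrent, len(eligible)),
                           replace=False)
        for idx in picks:
            v = eligible[int(idx)]
            fams = rng.choice(multi, size=2, replace=False)
            for fid in fams:
                v.carriers |= {(str(fid), m) for m in affected[str(fid)]}

    cohort = CohortVariantSet(variants=variants, members=members)

    # planted pathogenic variants: spread across families, rare only
    rare = [v for v in variants if v.variant_id not in common_ids]
    by_family: dict[str, list[Variant]] = {}
    for v in rare:
        for fid in sorted(v.carrier_families()):
            by_family.setdefault(fid, []).append(v)
    planted: list[str] = []
    fams_cycle = sorted(by_family)
    fi = 0
    while len(planted) < min(cfg.n_planted, len(rare)):
        fid = fams_cycle[fi % len(fams_cycle)]
        pool = [v for v in by_family[fid] if v.variant_id not in planted]
        if pool:
            planted.append(pool[int(rng.integers(len(pool)))].variant_id)
        fi += 1
        if fi > 10 * cfg.n_planted * max(1, len(fams_cycle)):
            break

    raw_scores, eve_source = simulate_scores(cohort, cfg, planted=planted, rng=rng)

    # sparse structural coverage with controlled contact distances
    structures: dict[str, StructureModel] = {}
    mappings: list[ResidueMapping] = []
    for v in variants:
        if rng.random() < cfg.structure_coverage:
            dmin = float(rng.uniform(1.6, 18.0))
            model, mapping = simulate_structure(v, interface=dmin < 4.0,
                                                min_distance=dmin)
            structures[model.structure_id] = model
            mappings.append(mapping)

    annotations = _simulate_annotations(cohort, planted, rng)
    return SyntheticCohort(cohort=cohort, raw_scores=raw_scores,
                           eve_source=eve_source, structures=structures,
                           mappings=mappings, planted=planted,
                           common_ids=common_ids, annotations=annotations,
                           config=cfg)


def simulate_scores(
    cohort: CohortVariantSet,
    cfg: GeneratorConfig,
    planted: Iterable[str] = (),
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, dict[str, float]], dict[str, str]]:
    """Draw correlated raw scores for every variant via a Gaussian copula,
    apply per-model coverage masks, then force planted variants beyond the
    most extreme unplanted raw score in every model that covers them."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    planted = set(planted)
    vids = [v.variant_id for v in cohort.variants]
    n = len(vids)
    C = cfg.correlation_matrix()
    z = rng.multivariate_normal(np.zeros(3), C, size=n, method="cholesky")

    margins = {
        "EVE": norm.cdf(z[:, 0]),                                # (0,1), high = pathogenic
        "ESM": cfg.esm_mean - cfg.esm_scale * z[:, 1],           # negative = deleterious
        "FIRM": norm.cdf(z[:, 2]),
    }
    covered = {m: rng.random(n) < cfg.coverage[m] for m in MODELS}
    if cfg.planted_full_coverage:
        for j, vid in enumerate(vids):
            if vid in planted:
                for m in MODELS:
                    covered[m][j] = True

    raw: dict[str, dict[str, float]] = {m: {} for m in MODELS}
    for m in MODELS:
        vals = {vid: float(margins[m][j]) for j, vid in enumerate(vids)
                if covered[m][j]}
        unplanted = [s for vid, s in vals.items() if vid not in planted]
        if unplanted and planted:
            # a single extreme value per model: planted variants tie at the
            # deleterious end, so they sit at or above any configured
            # quantile by construction even when they exceed 1% of a
            # model's covered set
            if m == "ESM":  # lower = more deleterious
                qv = float(np.quantile(unplanted, 1.0 - cfg.planted_quantile))
                extreme = min(min(unplanted), qv) - max(qv - min(unplanted), 0.5)
            else:
                extreme = 1.0  # raw upper bound, most pathogenic
            for vid in vals:
                if vid in planted:
                    vals[vid] = extreme
        raw[m] = vals

    source = {}
    for vid in raw["EVE"]:
        source[vid] = ("direct" if rng.random() < cfg.eve_direct_fraction
                       else "knn-imputed")
    return raw, source


def simulate_structure(
    variant: Variant,
    interface: bool,
    min_distance: float | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[StructureModel, ResidueMapping]:
    """Two-chain toy structure whose closest inter-chain atom pair is exactly
    ``min_distance`` from the variant residue (within float precision).

    Chain A is a short poly-glycine strand in the y=0 plane containing the
    variant residue; chain B is a single glycine whose CA sits directly above
    the variant CA at the requested distance, with its remaining atoms
    farther away. If ``min_distance`` is not given it is drawn below 4 A for
    ``interface=True`` and in [4, 18) otherwise.
    """
    if min_distance is None:
        rng = rng if rng is not None else np.random.default_rng(0)
        min_distance = float(rng.uniform(1.6, 3.9) if interface
                             else rng.uniform(4.1, 18.0))
    if min_distance <= 0:
        raise ParameterError("min_distance must be positive")
    r0 = variant.position
    chain_a: list[ResidueRecord] = []
    for j, num in enumerate(range(max(1, r0 - 2), r0 + 3)):
        x0 = 4.0 * j
        atoms = [
            AtomRecord("N", "N", x0 - 1.2, 0.0, 0.3),
            AtomRecord("CA", "C", x0, 0.0, 0.0),
            AtomRecord("C", "C", x0 + 1.2, 0.0, -0.3),
            AtomRecord("O", "O", x0 + 1.8, 0.0, -1.4),
        ]
        chain_a.append(ResidueRecord(number=num, name="GLY", atoms=atoms))
    xa = 4.0 * (r0 - max(1, r0 - 2))  # x of the variant CA
    chain_b = [ResidueRecord(number=1, name="GLY", atoms=[
        AtomRecord("CA", "C", xa, min_distance, 0.0),
        AtomRecord("N", "N", xa - 1.2, min_distance + 1.0, 0.0),
        AtomRecord("C", "C", xa + 1.2, min_distance + 1.0, 0.0),
    ])]
    sid = f"SYN_{variant.variant_id}"
    model = StructureModel(structure_id=sid, chains={"A": chain_a, "B": chain_b})
    mapping = ResidueMapping(variant_id=variant.variant_id, structure_id=sid,
                             chain_id="A", residue_number=r0)
    return model, mapping


def _simulate_annotations(cohort: CohortVariantSet, planted: list[str],
                          rng: np.random.Generator,
                          n_terms: int = 16) -> AnnotationMap:
    """Random annotation terms over the gene universe plus one term enriched
    in the planted genes (an end-to-end enrichment positive control)."""
    genes = sorted({v.gene for v in cohort.variants})
    planted_genes = sorted({v.gene for v in cohort.variants
                            if v.variant_id in planted})
    ann = AnnotationMap()
    namespaces = ("component", "function")
    for t in range(n_terms):
        size = int(rng.integers(10, max(11, len(genes) // 10)))
        size = min(size, len(genes))
        term_genes = rng.choice(genes, size=size, replace=False)
        ann.add(f"TERM{t:03d}", term_genes.tolist(), name=f"random term {t}",
                namespace=namespaces[t % 2])
    extra = rng.choice(genes, size=min(15, len(genes)), replace=False).tolist()
    ann.add("TERM_PLANTED", planted_genes + extra, name="planted pathway",
            namespace="function")
    return ann


@dataclass
class RecoveryReport:
    recall: float | None
    n_planted: int
    n_recovered: int
    false_positives: int
    attribution: dict[str, list[str]]

    def to_dict(self) -> dict:
        return asdict(self)


def evaluate_recovery(
    candidates: CandidateSet,
    planted: Iterable[str],
    fam_results: Iterable[FamRankResult] = (),
) -> RecoveryReport:
    """Recall of planted variants in the candidate union, with per-rule
    attribution of how each recovered variant was captured."""
    planted = sorted(set(planted))
    union = candidates.union
    recovered = [vid for vid in planted if vid in union]
    fam_rules: dict[str, set[str]] = {}
    for r in fam_results:
        if r.F >= 4:
            fam_rules.setdefault(r.variant_id, set()).update(r.fired_rules)
    attribution = {}
    for vid in recovered:
        sources = []
        if vid in candidates.ds_candidates:
            sources.append("dsrank")
        sources.extend(sorted(fam_rules.get(vid, ())))
        attribution[vid] = sources
    recall = None if not planted else len(recovered) / len(planted)
    return RecoveryReport(recall=recall, n_planted=len(planted),
                          n_recovered=len(recovered),
                          false_positives=len(union) - len(recovered),
                          attribution=attribution)
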