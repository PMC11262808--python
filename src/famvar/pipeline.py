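"""End-to-end pipeline: filter -> score -> normalize -> DIST -> rank ->
candidate union -> enrichment/export, with run logging and a reproducibility
manifest.

The pipeline is config-driven (:class:`RunConfig`, loadable from YAML). Each
stage writes its tabular output to the run directory; the manifest records
input digests, per-stage counts, normalization statistics and the
dataset-rank summary so a run can be compared byte-for-byte with a rerun.
A stage failure leaves partial outputs plus a ``FAILED`` marker naming the
stage.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import yaml

from . import cohort as co
from . import enrichment as en
from . import ranking as rk
from . import scoring as sc
from . import structure as st
from .errors import ConfigError, PipelineError

__version__ = "0.1.0"


@dataclass
class RunConfig:
    variants: str
    families: str
    outdir: str
    eve_scores: str | None = None
    esm_scores: str | None = None
    firm_scores: str | None = None
    eve_sequences: str | None = None
    structures_dir: str | None = None
    structure_map: str | None = None
    annotations: str | None = None
    truth: str | None = None
    max_af: float = 0.01
    missing_af: Literal["keep", "drop"] = "keep"
    min_affected: int = 2
    small_family_rule: Literal["all_affected", "strict"] = "all_affected"
    ladder: tuple[float, ...] = st.DEFAULT_LADDER
    top_fraction: float = 0.10
    sd_convention: Literal["population", "sample"] = "population"
    prevalence_scope: Literal["affected", "all_members"] = "affected"
    bh_scope: Literal["namespace", "global"] = "namespace"
    background_sample_size: int = 80
    background_n_samples: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("variants", "families", "eve_scores", "esm_scores",
                     "firm_scores", "eve_sequences", "structures_dir",
                     "structure_map", "annotations", "truth"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{name} path does not exist: {p}")
        if self.missing_af not in ("keep", "drop"):
            raise ConfigError(f"missing_af must be keep/drop, got {self.missing_af}")
        if self.small_family_rule not in ("all_affected", "strict"):
            raise ConfigError(f"bad small_family_rule {self.small_family_rule}")
        if self.sd_convention not in ("population", "sample"):
            raise ConfigError(f"bad sd_convention {self.sd_convention}")
        if self.prevalence_scope not in ("affected", "all_members"):
            raise ConfigError(f"bad prevalence_scope {self.prevalence_scope}")
        if not 0 < self.top_fraction <= 1:
            raise ConfigError("top_fraction must be in (0,1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "ladder" in data:
            data["ladder"] = tuple(float(x) for x in data["ladder"])
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    version: str
    config_hash: str
    input_digests: dict[str, str]
    counts: dict[str, int | float | None]
    normalization: dict[str, dict]
    dsrank_summary: dict | None
    correlations: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n"


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def _load_eve_scores(path: str | Path, variants: list[co.Variant]
                     ) -> tuple[dict[str, float], dict[str, str]]:
    """Evolutionary-model TSV: direct per-variant mapping when a variant_id
    column is present, otherwise exact (accession, position, mut_aa) keys."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        fields = set(reader.fieldnames or [])
        rows = list(reader)
    scores: dict[str, float] = {}
    source: dict[str, str] = {}
    if "variant_id" in fields:
        for row in rows:
            scores[row["variant_id"]] = float(row["score"])
            source[row["variant_id"]] = row.get("source") or "direct"
        return scores, source
    required = {"protein_accession", "position", "mut_aa", "score"}
    if not required <= fields:
        raise ConfigError(f"EVE table must have columns {sorted(required)} "
                          "or a variant_id column")
    by_key = {(r["protein_accession"], int(r["position"]), r["mut_aa"]): r
              for r in rows}
    for v in variants:
        row = by_key.get((v.protein_accession, v.position, v.mut_aa))
        if row is not None:
            scores[v.variant_id] = float(row["score"])
            source[v.variant_id] = row.get("source") or "direct"
    return scores, source


def study_counts(
    vs: co.CohortVariantSet,
    records: list[sc.ScoreRecord],
    ds_results: list[rk.DSRankResult],
    fam_results: list[rk.FamRankResult],
    cs: rk.CandidateSet,
) -> dict[str, int]:
    """The headline pipeline counts: dataset size, model-coverage-eligible
    variants, candidates per ranker, union, overlap, cross-family recurrence."""
    recurrence = co.recurrence_across_families(vs)
    return {
        "n_variants": len(vs.variants),
        "n_genes": len({v.gene for v in vs.variants}),
        "n_m_ge2": sum(1 for r in records if r.M >= 2),
        "n_dsrank_candidates": len(cs.ds_candidates),
        "n_famrank_candidates": len(cs.fam_candidates),
        "n_union": len(cs.union),
        "n_union_genes": len({v.gene for v in vs.variants
                              if v.variant_id in cs.union}),
        "n_overlap": len(cs.overlap),
        "n_recurrent": sum(1 for fams in recurrence.values() if len(fams) >= 2),
    }


def analyze_cohort(syn) -> dict:
    """Run the full analysis in memory on a synthetic cohort: filters,
    normalization, DIST, both rankers, candidate union and recovery.

    Returns a dict with the intermediate artifacts (``vs``, ``records``,
    ``ds_results``, ``summary``, ``fam_results``, ``dist_scores``, ``cs``,
    ``recovery``).
    """
    from .synthetic import SyntheticCohort, evaluate_recovery

    assert isinstance(syn, SyntheticCohort)
    vs = co.filter_by_frequency(syn.cohort)
    vs = co.filter_by_shared_affected(vs)
    vids = set(vs.variant_ids())
    raw = {m: {vid: s for vid, s in scores.items() if vid in vids}
           for m, scores in syn.raw_scores.items()}
    normalized, norm_stats = sc.normalize_model_scores(raw)
    records = sc.assemble_score_matrix(vs.variants, normalized, raw=raw,
                                       eve_source=syn.eve_source)
    by_vid = {v.variant_id: v for v in vs.variants}
    dist_scores = {
        m.variant_id: st.dist_score(by_vid[m.variant_id], syn.mappings,
                                    syn.structures)
        for m in syn.mappings if m.variant_id in by_vid}
    ds_results, summary = rk.dsrank(records)
    fam_results = rk.famrank(records, vs, dist_scores)
    cs = rk.candidate_union(ds_results, fam_results, vs.variants)
    recovery = evaluate_recovery(cs, syn.planted, fam_results)
    return {"vs": vs, "records": records, "normalization": norm_stats,
            "ds_results": ds_results, "summary": summary,
            "fam_results": fam_results, "dist_scores": dist_scores,
            "cs": cs, "recovery": recovery}


def run_pipeline(cfg: RunConfig) -> RunManifest:
    """Execute every stage and write all outputs under ``cfg.outdir``."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        members = co.read_family_table(cfg.families)
        vs = co.read_variant_table(cfg.variants, members)
        n_input = len(vs.variants)

        stage = "filter"
        vs = co.filter_by_frequency(vs, max_af=cfg.max_af, missing_af=cfg.missing_af)
        n_after_af = len(vs.variants)
        vs = co.filter_by_shared_affected(vs, min_affected=cfg.min_affected,
                                          small_family_rule=cfg.small_family_rule)
        co.write_variant_table(vs, outdir / "filtered_variants.tsv")
        with open(outdir / "filter_log.tsv", "w") as fh:
            fh.write("variant_id\trule\taction\n")
            for entry in vs.provenance:
                fh.write(f"{entry['variant_id']}\t{entry['rule']}\t{entry['action']}\n")

        stage = "score"
        raw: dict[str, dict[str, float]] = {m: {} for m in sc.MODELS}
        eve_source: dict[str, str] = {}
        if cfg.eve_scores:
            raw["EVE"], eve_source = _load_eve_scores(cfg.eve_scores, vs.variants)
        if cfg.esm_scores:
            raw["ESM"] = sc.read_per_variant_scores(cfg.esm_scores)
        if cfg.firm_scores:
            raw["FIRM"] = sc.read_per_variant_scores(cfg.firm_scores)
        vids = set(vs.variant_ids())
        raw = {m: {vid: s for vid, s in scores.items() if vid in vids}
               for m, scores in raw.items()}
        normalized, norm_stats = sc.normalize_model_scores(raw)
        records = sc.assemble_score_matrix(vs.variants, normalized, raw=raw,
                                           eve_source=eve_source)
        correlations = sc.pairwise_model_correlation(records)
        with open(outdir / "scores.tsv", "w") as fh:
            cols = [f"S_{m}" for m in sc.MODELS]
            fh.write("variant_id\t" + "\t".join(cols) + "\tM\teve_source\n")
            for rec in records:
                vals = ["" if m not in rec.S else f"{rec.S[m]:.6g}" for m in sc.MODELS]
                fh.write(f"{rec.variant_id}\t" + "\t".join(vals)
                         + f"\t{rec.M}\t{rec.eve_source}\n")
        (outdir / "normalization.json").write_text(json.dumps(
            {m: s.to_dict() for m, s in norm_stats.items()}, indent=2,
            sort_keys=True) + "\n")

        stage = "dist"
        dist_scores: dict[str, st.DistScore] = {}
        if cfg.structures_dir and cfg.structure_map:
            mappings = st.read_mapping_table(cfg.structure_map)
            sdir = Path(cfg.structures_dir)
            structures = {}
            for sid in sorted({m.structure_id for m in mappings}):
                for ext in (".pdb", ".cif"):
                    p = sdir / f"{sid}{ext}"
                    if p.exists():
                        structures[sid] = st.read_structure(p)
                        break
            by_vid = {v.variant_id: v for v in vs.variants}
            for vid in sorted({m.variant_id for m in mappings} & vids):
                dist_scores[vid] = st.dist_score(by_vid[vid], mappings, structures,
                                                 ladder=cfg.ladder)
            st.write_dist_table(dist_scores.values(), outdir / "dist.tsv")

        stage = "rank"
        ds_results, summary = rk.dsrank(records, sd_convention=cfg.sd_convention)
        fam_results = rk.famrank(records, vs, dist_scores,
                                 fraction=cfg.top_fraction,
                                 prevalence_scope=cfg.prevalence_scope)
        cs = rk.candidate_union(ds_results, fam_results, vs.variants)
        with open(outdir / "dsrank.tsv", "w") as fh:
            fh.write("variant_id\tD\teligible\tcandidate\n")
            for r in ds_results:
                fh.write(f"{r.variant_id}\t"
                         f"{'' if r.D is None else f'{r.D:.6g}'}\t"
                         f"{int(r.eligible)}\t{int(r.candidate)}\n")
        with open(outdir / "famrank.tsv", "w") as fh:
            fh.write("variant_id\tfamily_id\tF\tcandidate\tfired_rules\n")
            for r in sorted(fam_results, key=lambda x: (x.variant_id, x.family_id)):
                fh.write(f"{r.variant_id}\t{r.family_id}\t{r.F}\t"
                         f"{int(r.candidate)}\t{';'.join(r.fired_rules)}\n")
        with open(outdir / "candidates.tsv", "w") as fh:
            fh.write("variant_id\tgene\tdsrank\tfamrank\n")
            by_vid = {v.variant_id: v for v in vs.variants}
            for vid in sorted(cs.union):
                fh.write(f"{vid}\t{by_vid[vid].gene}\t"
                         f"{int(vid in cs.ds_candidates)}\t"
                         f"{int(vid in cs.fam_candidates)}\n")

        stage = "enrich"
        enrichment_rows: list[en.EnrichmentRow] = []
        background = sorted({v.gene for v in vs.variants})
        if cfg.annotations:
            ann = en.read_annotation_table(cfg.annotations)
            enrichment_rows = en.fisher_enrichment(cs.genes, background, ann,
                                                   bh_scope=cfg.bh_scope)
            en.write_enrichment_table(enrichment_rows, outdir / "enrichment.tsv")
        samples = en.random_background_samples(
            background, k=min(cfg.background_sample_size, len(background)),
            n_samples=cfg.background_n_samples, seed=cfg.seed)
        gene_sets = {"candidates": cs.genes}
        gene_sets.update({f"background_sample_{i:02d}": s
                          for i, s in enumerate(samples)})
        en.export_gene_lists(gene_sets, outdir / "gene_lists")

        stage = "manifest"
        counts = study_counts(vs, records, ds_results, fam_results, cs)
        counts["n_input_variants"] = n_input
        counts["n_removed_by_frequency"] = n_input - n_after_af
        counts["n_removed_by_segregation"] = n_after_af - len(vs.variants)
        counts["n_with_dist"] = sum(1 for d in dist_scores.values()
                                    if d.threshold is not None)
        inputs = {}
        for name in ("variants", "families", "eve_scores", "esm_scores",
                     "firm_scores", "structure_map", "annotations"):
            p = getattr(cfg, name)
            if p:
                inputs[name] = _digest(p)
        manifest = RunManifest(
            version=__version__, config_hash=cfg.config_hash(),
            input_digests=inputs, counts=counts,
            normalization={m: s.to_dict() for m, s in norm_stats.items()},
            dsrank_summary=summary.to_dict(),
            correlations=[dataclasses.asdict(c) for c in correlations])
        (outdir / "manifest.json").write_text(manifest.to_json())
        (outdir / "report.txt").write_text(report(manifest, outdir, cfg))
        return manifest
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc)) from exc


def report(manifest: RunManifest, outdir: str | Path,
           cfg: RunConfig | None = None) -> str:
    """Human-readable run report: per-family candidate table (both column
    semantics), model correlations, dataset-rank distribution by family
    group, and planted-truth recovery when a truth file is supplied."""
    outdir = Path(outdir)
    lines = ["# famvar run report", ""]
    c = manifest.counts
    lines += [
        f"variants in: {c.get('n_input_variants')}  "
        f"removed by frequency: {c.get('n_removed_by_frequency')}  "
        f"removed by segregation: {c.get('n_removed_by_segregation')}",
        f"final dataset: {c['n_variants']} variants / {c['n_genes']} genes; "
        f"{c['n_m_ge2']} scored by >= 2 models",
        f"candidates: dataset-rank {c['n_dsrank_candidates']}, "
        f"family-rank {c['n_famrank_candidates']}, union {c['n_union']} "
        f"({c['n_union_genes']} genes), overlap {c['n_overlap']}",
        f"cross-family recurrent variants: {c['n_recurrent']}",
        "",
    ]
    if manifest.dsrank_summary:
        s = manifest.dsrank_summary
        lines += [f"DSRank: mu={s['mu']:.4f} sigma={s['sigma']:.4f} "
                  f"threshold={s['threshold']:.4f} ({s['sd_convention']} SD, "
                  f"n={s['n_eligible']})", ""]
    if manifest.correlations:
        lines.append("pairwise model correlations (normalized scores):")
        for corr in manifest.correlations:
            if corr["r"] is None:
                lines.append(f"  {corr['model_a']}-{corr['model_b']}: {corr['note']}")
            else:
                lines.append(f"  {corr['model_a']}-{corr['model_b']}: "
                             f"r={corr['r']:.3f} p={corr['p']:.3g} n={corr['n']}")
        lines.append("")

    fam_path = outdir / "famrank.tsv"
    ds_path = outdir / "dsrank.tsv"
    if fam_path.exists() and ds_path.exists():
        ds_cand = set()
        d_by_vid: dict[str, float] = {}
        with open(ds_path) as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                if row["candidate"] == "1":
                    ds_cand.add(row["variant_id"])
                if row["D"]:
                    d_by_vid[row["variant_id"]] = float(row["D"])
        fam_rows = list(csv.DictReader(open(fam_path), delimiter="\t"))
        fam_max: dict[str, int] = {}
        per_family: dict[str, set[str]] = {}
        for row in fam_rows:
            fam_max[row["variant_id"]] = max(fam_max.get(row["variant_id"], 1),
                                             int(row["F"]))
            per_family.setdefault(row["family_id"], set()).add(row["variant_id"])
        fam_cand = {vid for vid, g in fam_max.items() if g >= 4}
        lines.append("per-family candidates "
                     "(totals semantics: DS, FAM, both | exclusive: DS-only, FAM-only):")
        lines.append("family\tn_variants\tDS\tFAM\tboth\tDS_only\tFAM_only")
        for fid in sorted(per_family):
            vids = per_family[fid]
            nds = len(vids & ds_cand)
            nfam = len(vids & fam_cand)
            nboth = len(vids & ds_cand & fam_cand)
            lines.append(f"{fid}\t{len(vids)}\t{nds}\t{nfam}\t{nboth}"
                         f"\t{nds - nboth}\t{nfam - nboth}")
        lines.append("")
        # dataset-rank distribution per family-rank group
        lines.append("DSRank distribution by FAMRank group (max over families):")
        for g in range(1, 6):
            ds_vals = sorted(d_by_vid[vid] for vid, gg in fam_max.items()
                             if gg == g and vid in d_by_vid)
            if ds_vals:
                lines.append(f"  group {g}: n={len(ds_vals)} "
                             f"median D={np.median(ds_vals):.3f} "
                             f"max D={max(ds_vals):.3f}")
            else:
                lines.append(f"  group {g}: n=0")
        lines.append("")
    if (not (outdir / "dist.tsv").exists()) or c.get("n_with_dist", 0) == 0:
        lines.append("structural coverage: 0% (no DIST scores computed)")
        lines.append("")
    if cfg and cfg.truth:
        truth = json.loads(Path(cfg.truth).read_text())
        planted = set(truth.get("planted", []))
        cand_union = set()
        cand_path = outdir / "candidates.tsv"
        if cand_path.exists():
            with open(cand_path) as fh:
                cand_union = {row["variant_id"]
                              for row in csv.DictReader(fh, delimiter="\t")}
        recovered = planted & cand_union
        lines.append("planted-truth recovery:")
        lines.append(f"  planted {len(planted)}, recovered {len(recovered)}, "
                     f"recall "
                     f"{'n/a' if not planted else f'{len(recovered) / len(planted):.3f}'}")
        lines.append("")
    return "\n".join(lines) + "\n"
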