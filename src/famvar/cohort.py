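"""Cohort ingestion and preprocessing for family-based missense variant studies.

The unit of analysis is a missense variant observed in one or more sequenced
family members. Variants arrive pre-annotated (gene, protein change, optional
genomic coordinates, population allele frequency, carriers); this module loads
them, applies the rarity and family-segregation filters, and detects variants
recurring across families.

Filter semantics
----------------
* Rarity: variants with population allele frequency strictly above ``max_af``
  (default 1%) are excluded; a frequency of exactly ``max_af`` is kept.
  Missing frequencies are kept by default (rare-by-absence), switchable.
* Segregation: a variant is kept if, within at least one family, it is carried
  by at least ``min_affected`` affected members. Unaffected carriers never
  count. Families with fewer than ``min_affected`` affected members (e.g. a
  single sequenced patient) retain variants carried by *all* of their affected
  members under the default ``small_family_rule="all_affected"``; set
  ``small_family_rule="strict"`` to drop such families' variants entirely.
* Recurrence: a variant "recurs" in a family when every sequenced affected
  member of that family carries it; only families with more than one affected
  patient are eligible.

Every filter appends to a provenance log so that removed + retained always
sums to the input count.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal

from .errors import ConfigError, DataError

VARIANT_COLUMNS = [
    "variant_id", "gene", "protein_accession", "wt_aa", "position", "mut_aa",
    "chrom", "gpos", "ref", "alt", "pop_af", "carriers",
]
_REQUIRED_COLUMNS = ["variant_id", "gene", "wt_aa", "position", "mut_aa", "carriers"]


@dataclass(frozen=True)
class Member:
    member_id: str
    family_id: str
    affected: bool
    phenotype_note: str | None = None


@dataclass(frozen=True)
class GenomicLocus:
    contig: str
    position: int  # 1-based
    ref: str
    alt: str
    build: str = "hg19"


@dataclass
class Variant:
    variant_id: str
    gene: str
    wt_aa: str
    position: int  # 1-based residue index
    mut_aa: str
    protein_accession: str = ""
    genomic: GenomicLocus | None = None
    pop_af: float | None = None
    carriers: set[tuple[str, str]] = field(default_factory=set)  # (family, member)

    def validate(self) -> None:
        if self.wt_aa == self.mut_aa:
            raise DataError(f"{self.variant_id}: wt_aa equals mut_aa ({self.wt_aa})")
        if self.position < 1:
            raise DataError(f"{self.variant_id}: position must be >= 1")
        if self.pop_af is not None and not (0.0 <= self.pop_af <= 1.0):
            raise DataError(f"{self.variant_id}: pop_af {self.pop_af} outside [0,1]")

    def carrier_families(self) -> set[str]:
        return {fam for fam, _ in self.carriers}


@dataclass
class RowError:
    row: int
    variant_id: str
    message: str


@dataclass
class CohortVariantSet:
    """Variants plus family membership and a filter provenance log."""

    variants: list[Variant]
    members: list[Member]
    provenance: list[dict] = field(default_factory=list)
    load_errors: list[RowError] = field(default_factory=list)

    def __post_init__(self) -> None:
        known = {(m.family_id, m.member_id) for m in self.members}
        if known:
            for v in self.variants:
                unknown = v.carriers - known
                if unknown:
                    raise DataError(
                        f"{v.variant_id}: carriers reference unknown members {sorted(unknown)}"
                    )

    @property
    def families(self) -> dict[str, list[Member]]:
        out: dict[str, list[Member]] = {}
        for m in self.members:
            out.setdefault(m.family_id, []).append(m)
        return out

    def affected_members(self, family_id: str) -> set[str]:
        return {m.member_id for m in self.members
                if m.family_id == family_id and m.affected}

    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    def family_variants(self, family_id: str) -> list[Variant]:
        """Variants carried by at least one member of the family."""
        return [v for v in self.variants if family_id in v.carrier_families()]

    def _log(self, rule: str, removed: Iterable[Variant], retained: Iterable[Variant]) -> None:
        for v in removed:
            self.provenance.append(
                {"variant_id": v.variant_id, "rule": rule, "action": "removed"})
        for v in retained:
            self.provenance.append(
                {"variant_id": v.variant_id, "rule": rule, "action": "retained"})


def read_family_table(path: str | Path) -> list[Member]:
    """Read the family/member TSV: family_id, member_id, affected (0/1)."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"family file not found: {path}")
    members: list[Member] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"family_id", "member_id", "affected"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ConfigError(f"family file must have columns {sorted(required)}")
        for row in reader:
            members.append(Member(
                member_id=row["member_id"],
                family_id=row["family_id"],
                affected=row["affected"].strip() in {"1", "true", "True"},
                phenotype_note=row.get("phenotype_note") or None,
            ))
    seen: set[tuple[str, str]] = set()
    for m in members:
        key = (m.family_id, m.member_id)
        if key in seen:
            raise DataError(f"duplicate member {m.member_id} in family {m.family_id}")
        seen.add(key)
    return members


def _parse_carriers(token: str) -> set[tuple[str, str]]:
    carriers = set()
    for item in token.split(";"):
        item = item.strip()
        if not item:
            continue
        if ":" not in item:
            raise DataError(f"carrier token '{item}' not in family:member form")
        fam, mem = item.split(":", 1)
        carriers.add((fam, mem))
    return carriers


def _merge_variant(existing: Variant, new: Variant) -> Variant:
    identity = ("gene", "wt_aa", "position", "mut_aa", "protein_accession")
    for f in identity:
        if getattr(existing, f) != getattr(new, f):
            raise DataError(
                f"duplicate variant_id {existing.variant_id} with conflicting {f}: "
                f"{getattr(existing, f)!r} vs {getattr(new, f)!r}")
    if (existing.pop_af is not None and new.pop_af is not None
            and existing.pop_af != new.pop_af):
        raise DataError(f"duplicate variant_id {existing.variant_id} with conflicting pop_af")
    merged = replace(existing)
    merged.carriers = existing.carriers | new.carriers
    if merged.pop_af is None:
        merged.pop_af = new.pop_af
    return merged


def read_variant_table(
    path: str | Path,
    members: list[Member],
    dialect: Literal["tsv", "vcf-annotated"] = "tsv",
    sample_map: str | Path | None = None,
) -> CohortVariantSet:
    """Load the variant table.

    TSV dialect columns: variant_id, gene, protein_accession, wt_aa, position,
    mut_aa, chrom, gpos, ref, alt, pop_af, carriers (semicolon-separated
    family:member tokens). Rows violating invariants go into ``load_errors``
    instead of being silently dropped; duplicate rows of the same variant merge
    their carrier sets (conflicting identity fields raise :class:`DataError`).
    """
    if dialect == "vcf-annotated":
        return _read_vcf(path, members, sample_map)
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"variant file not found: {path}")
    by_id: dict[str, Variant] = {}
    errors: list[RowError] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        cols = set(reader.fieldnames or [])
        missing = [c for c in _REQUIRED_COLUMNS if c not in cols]
        if missing:
            raise ConfigError(f"variant table missing required columns: {missing}")
        for i, row in enumerate(reader, start=2):
            vid = row["variant_id"]
            try:
                genomic = None
                if row.get("chrom") and row.get("gpos"):
                    genomic = GenomicLocus(
                        contig=row["chrom"], position=int(row["gpos"]),
                        ref=row.get("ref", ""), alt=row.get("alt", ""),
                        build=row.get("build", "hg19"))
                af_raw = (row.get("pop_af") or "").strip()
                v = Variant(
                    variant_id=vid,
                    gene=row["gene"],
                    protein_accession=row.get("protein_accession", ""),
                    wt_aa=row["wt_aa"].strip(),
                    position=int(row["position"]),
                    mut_aa=row["mut_aa"].strip(),
                    genomic=genomic,
                    pop_af=float(af_raw) if af_raw else None,
                    carriers=_parse_carriers(row["carriers"]),
                )
                v.validate()
            except (DataError, ValueError) as exc:
                errors.append(RowError(row=i, variant_id=vid, message=str(exc)))
                continue
            if vid in by_id:
                try:
                    by_id[vid] = _merge_variant(by_id[vid], v)
                except DataError:
                    raise
            else:
                by_id[vid] = v
    return CohortVariantSet(variants=list(by_id.values()), members=members,
                            load_errors=errors)


def _read_vcf(path: str | Path, members: list[Member],
              sample_map: str | Path | None) -> CohortVariantSet:
    """VCF dialect: missense records carrying INFO keys GENE, PACC, PCHANGE
    (e.g. ``T305M``) and optionally AF; carriers come from non-reference
    genotypes via the sample -> (family, member) map."""
    import cyvcf2  # optional heavy import

    path = Path(path)
    if not path.exists():
        raise ConfigError(f"VCF not found: {path}")
    if sample_map is None:
        raise ConfigError("vcf-annotated dialect requires a sample_map TSV "
                          "(columns: sample, family_id, member_id)")
    smap: dict[str, tuple[str, str]] = {}
    with open(sample_map, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"sample", "family_id", "member_id"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ConfigError(f"sample map must have columns {sorted(required)}")
        for row in reader:
            smap[row["sample"]] = (row["family_id"], row["member_id"])

    vcf = cyvcf2.VCF(str(path))
    samples = list(vcf.samples)
    errors: list[RowError] = []
    by_id: dict[str, Variant] = {}
    for i, rec in enumerate(vcf):
        gene = rec.INFO.get("GENE")
        pchange = rec.INFO.get("PCHANGE")
        if gene is None or pchange is None:
            errors.append(RowError(row=i, variant_id=str(rec.ID or rec.POS),
                                   message="missing GENE/PCHANGE annotation"))
            continue
        pchange = pchange.removeprefix("p.")
        wt, pos, mut = pchange[0], pchange[1:-1], pchange[-1]
        carriers = set()
        for sample, gt in zip(samples, rec.gt_types):
            # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
            if gt in (1, 3) and sample in smap:
                carriers.add(smap[sample])
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}:{rec.REF}:{rec.ALT[0]}"
        af = rec.INFO.get("AF")
        try:
            v = Variant(
                variant_id=vid, gene=gene,
                protein_accession=rec.INFO.get("PACC", ""),
                wt_aa=wt, position=int(pos), mut_aa=mut,
                genomic=GenomicLocus(rec.CHROM, rec.POS, rec.REF, rec.ALT[0]),
                pop_af=float(af) if af is not None else None,
                carriers=carriers)
            v.validate()
        except (DataError, ValueError) as exc:
            errors.append(RowError(row=i, variant_id=vid, message=str(exc)))
            continue
        by_id[vid] = _merge_variant(by_id[vid], v) if vid in by_id else v
    return CohortVariantSet(variants=list(by_id.values()), members=members,
                            load_errors=errors)


def filter_by_frequency(
    vs: CohortVariantSet,
    max_af: float = 0.01,
    missing_af: Literal["keep", "drop"] = "keep",
) -> CohortVariantSet:
    """Exclude variants with population frequency strictly above ``max_af``."""
    if not (0.0 < max_af <= 1.0) and max_af != 0.0:
        raise ConfigError(f"max_af must be in [0,1], got {max_af}")
    kept, removed = [], []
    for v in vs.variants:
        if v.pop_af is None:
            (kept if missing_af == "keep" else removed).append(v)
        elif v.pop_af > max_af:
            removed.append(v)
        else:
            kept.append(v)
    out = CohortVariantSet(variants=kept, members=vs.members,
                           provenance=list(vs.provenance),
                           load_errors=list(vs.load_errors))
    out._log(f"frequency>{max_af}", removed, kept)
    return out


def filter_by_shared_affected(
    vs: CohortVariantSet,
    min_affected: int = 2,
    small_family_rule: Literal["all_affected", "strict"] = "all_affected",
) -> CohortVariantSet:
    """Keep variants carried by >= ``min_affected`` affected members of at
    least one family (evaluated per family, never pooled across families)."""
    if not vs.members:
        raise ConfigError("families must be loaded before segregation filtering")
    affected_by_family = {fid: vs.affected_members(fid) for fid in vs.families}
    kept, removed = [], []
    for v in vs.variants:
        ok = False
        for fid in v.carrier_families():
            affected = affected_by_family.get(fid, set())
            n_affected_carriers = sum(
                1 for fam, mem in v.carriers if fam == fid and mem in affected)
            if n_affected_carriers >= min_affected:
                ok = True
            elif (small_family_rule == "all_affected"
                  and 0 < len(affected) < min_affected
                  and n_affected_carriers == len(affected)):
                ok = True
            if ok:
                break
        (kept if ok else removed).append(v)
    out = CohortVariantSet(variants=kept, members=vs.members,
                           provenance=list(vs.provenance),
                           load_errors=list(vs.load_errors))
    out._log(f"shared_affected<{min_affected}", removed, kept)
    return out


def recurrence_across_families(vs: CohortVariantSet) -> dict[str, list[str]]:
    """For each variant, the families in which *every* sequenced affected
    member carries it. Only families with more than one affected patient are
    eligible; the result lists those families (a variant is cross-family
    recurrent when two or more appear)."""
    affected_by_family = {fid: vs.affected_members(fid) for fid in vs.families}
    eligible = {fid for fid, aff in affected_by_family.items() if len(aff) > 1}
    out: dict[str, list[str]] = {}
    for v in vs.variants:
        fams = []
        for fid in sorted(v.carrier_families() & eligible):
            affected = affected_by_family[fid]
            carriers_here = {mem for fam, mem in v.carriers if fam == fid}
            if affected <= carriers_here:
                fams.append(fid)
        out[v.variant_id] = fams
    return out


def write_variant_table(vs: CohortVariantSet, path: str | Path) -> None:
    """Write variants back out in the canonical TSV dialect."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(VARIANT_COLUMNS)
        for v in sorted(vs.variants, key=lambda x: x.variant_id):
            g = v.genomic
            writer.writerow([
                v.variant_id, v.gene, v.protein_accession, v.wt_aa, v.position,
                v.mut_aa,
                g.contig if g else "", g.position if g else "",
                g.ref if g else "", g.alt if g else "",
                "" if v.pop_af is None else f"{v.pop_af:.6g}",
                ";".join(f"{fam}:{mem}" for fam, mem in sorted(v.carriers)),
            ])
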