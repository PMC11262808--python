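"""Annotation enrichment and background sampling for candidate gene sets.

Over-representation of an annotation term among candidate genes is tested
with a one-sided Fisher exact test (hypergeometric upper tail): with N
background genes of which K carry the term, drawing the n candidates and
observing a annotated, p = P(X >= a), X ~ Hypergeom(N, K, n). Candidates are
a subset of the background, and background genes without any annotation are
removed before testing. P-values are corrected with the Benjamini-Hochberg
step-up procedure, by default within each annotation namespace separately
(e.g. cellular component vs function).

Random background samples (default 20 draws of 80 genes) are exported for
external protein-interaction enrichment services as a negative control for
the dataset's pathogenic propensity.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, ParameterError


@dataclass
class AnnotationMap:
    """term_id -> set of (uppercased) gene symbols, with term metadata."""
    terms: dict[str, set[str]] = field(default_factory=dict)
    names: dict[str, str] = field(default_factory=dict)
    namespaces: dict[str, str] = field(default_factory=dict)

    def add(self, term_id: str, genes: Iterable[str],
            name: str = "", namespace: str = "") -> None:
        gset = {g.upper() for g in genes}
        if not gset:
            return  # terms with empty gene sets are dropped
        self.terms.setdefault(term_id, set()).update(gset)
        if name:
            self.names[term_id] = name
        if namespace:
            self.namespaces[term_id] = namespace

    def annotated_genes(self) -> set[str]:
        out: set[str] = set()
        for genes in self.terms.values():
            out |= genes
        return out


def read_annotation_table(path: str | Path) -> AnnotationMap:
    """Two-column TSV (term, gene) with optional name/namespace columns."""
    ann = AnnotationMap()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not {"term", "gene"} <= set(reader.fieldnames):
            raise ConfigError("annotation table must have columns term, gene")
        for row in reader:
            ann.add(row["term"], [row["gene"]],
                    name=row.get("name", ""), namespace=row.get("namespace", ""))
    return ann


def read_gmt(path: str | Path) -> AnnotationMap:
    """GMT gene-set format: term <tab> description <tab> gene1 <tab> gene2..."""
    ann = AnnotationMap()
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            ann.add(parts[0], parts[2:], name=parts[1])
    return ann


@dataclass
class EnrichmentRow:
    term_id: str
    a: int  # candidates annotated
    b: int  # candidates not annotated
    c: int  # background (non-candidate) annotated
    d: int  # background (non-candidate) not annotated
    p: float
    q: float = float("nan")
    name: str = ""
    namespace: str = ""


def fisher_enrichment(
    candidates: Iterable[str],
    background: Iterable[str],
    ann: AnnotationMap,
    bh_scope: Literal["namespace", "global"] = "namespace",
) -> list[EnrichmentRow]:
    """One-sided Fisher enrichment of candidate genes per annotation term,
    BH-corrected. Background genes with no annotation are removed first;
    candidates must be a subset of the background."""
    bg = {g.upper() for g in background}
    cand = {g.upper() for g in candidates}
    if not cand <= bg:
        raise ConfigError("candidate genes must be a subset of the background")
    annotated = ann.annotated_genes()
    bg &= annotated
    cand &= annotated
    if not cand:
        return []
    N, n = len(bg), len(cand)
    rows: list[EnrichmentRow] = []
    for term_id, genes in sorted(ann.terms.items()):
        term_bg = genes & bg
        K = len(term_bg)
        if K == 0:
            continue
        a = len(genes & cand)
        # upper tail P(X >= a) for X ~ Hypergeom(N, K, n)
        p = float(hypergeom.sf(a - 1, N, K, n))
        rows.append(EnrichmentRow(
            term_id=term_id, a=a, b=n - a, c=K - a, d=(N - n) - (K - a),
            p=min(p, 1.0), name=ann.names.get(term_id, ""),
            namespace=ann.namespaces.get(term_id, "")))
    # BH within namespace (or globally)
    groups: dict[str, list[EnrichmentRow]] = {}
    for row in rows:
        key = row.namespace if bh_scope == "namespace" else ""
        groups.setdefault(key, []).append(row)
    for grp in groups.values():
        qs = multipletests([r.p for r in grp], method="fdr_bh")[1]
        for row, q in zip(grp, qs):
            row.q = float(max(q, row.p))
    rows.sort(key=lambda r: (r.q, r.p, r.term_id))
    return rows


def random_background_samples(
    background: Iterable[str],
    k: int = 80,
    n_samples: int = 20,
    seed: int = 0,
) -> list[list[str]]:
    """Draw ``n_samples`` gene sets of size ``k`` without replacement (within
    each sample) from the background; reproducible under the seed."""
    genes = sorted({g.upper() for g in background})
    if k > len(genes):
        raise ParameterError(f"sample size {k} exceeds background size {len(genes)}")
    rng = np.random.default_rng(seed)
    return [sorted(rng.choice(genes, size=k, replace=False).tolist())
            for _ in range(n_samples)]


def export_gene_lists(
    gene_sets: dict[str, Iterable[str]],
    outdir: str | Path,
) -> dict:
    """Write plain-text one-gene-per-line files (deduplicated, order
    preserved) plus a manifest with counts and warnings for empty sets."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"files": {}, "warnings": []}
    for name, genes in gene_sets.items():
        seen: list[str] = []
        for g in genes:
            if g not in seen:
                seen.append(g)
        path = outdir / f"{name}.txt"
        path.write_text("".join(f"{g}\n" for g in seen))
        manifest["files"][name] = {"path": path.name, "n_genes": len(seen)}
        if not seen:
            manifest["warnings"].append(f"gene set '{name}' is empty")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def write_enrichment_table(rows: Sequence[EnrichmentRow], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["term_id", "name", "namespace", "a", "b", "c", "d", "p", "q"])
        for r in rows:
            writer.writerow([r.term_id, r.name, r.namespace, r.a, r.b, r.c, r.d,
                             f"{r.p:.6g}", f"{r.q:.6g}"])
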