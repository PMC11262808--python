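"""Annotation enrichment of a candidate gene set with BH correction, plus
reproducible random background samples for external interaction services."""

from famvar.enrichment import (AnnotationMap, fisher_enrichment,
                               random_background_samples)

background = [f"GENE{i:03d}" for i in range(100)]
candidates = background[:10]

ann = AnnotationMap()
ann.add("PEROXISOME", background[:12], namespace="component")  # enriched
ann.add("MEMBRANE", background[40:90], namespace="component")
ann.add("ENZYME", background, namespace="function")

rows = fisher_enrichment(candidates, background, ann)
for r in rows:
    print(f"{r.term_id:<12} a={r.a:<3} p={r.p:.3g}  q={r.q:.3g}")
# Only the term concentrated in the candidates reaches a small q; a term
# covering the whole background can never be enriched (p = 1).

samples = random_background_samples(background, k=10, n_samples=3, seed=42)
print(f"\n3 reproducible background samples of 10 genes, e.g. {samples[0][:4]}...")
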