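"""Functional classification and term enrichment of gene sets.

Term maps (gene -> terms, term -> label/namespace) are user-supplied
two-column TSVs; no ontology database is bundled. Enrichment is the
hypergeometric upper tail, optionally in the conservative EASE variant
(one study hit removed before computing the tail), with Benjamini-Hochberg
adjustment within each namespace; results pass both a raw-p and an
adjusted-p threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

NAMESPACES = ("biological_process", "cellular_component", "molecular_function", "pathway")


@dataclass
class AnnotationMap:
    gene_terms: dict[str, set[str]]
    term_labels: dict[str, tuple[str, str]] = field(default_factory=dict)  # term -> (label, namespace)

    def __post_init__(self) -> None:
        self.gene_terms = {g: set(t) for g, t in self.gene_terms.items() if t}

    def terms_in_namespace(self, namespace: str | None) -> set[str]:
        terms = {t for ts in self.gene_terms.values() for t in ts}
        if namespace is None:
            return terms
        return {t for t in terms if self.term_labels.get(t, ("", namespace))[1] == namespace}

    @classmethod
    def from_tsv(cls, gene_term_path, term_label_path=None) -> "AnnotationMap":
        gt: dict[str, set[str]] = {}
        with open(gene_term_path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                gene, term = line.rstrip("\n").split("\t")[:2]
                gt.setdefault(gene, set()).add(term)
        labels: dict[str, tuple[str, str]] = {}
        if term_label_path is not None:
            with open(term_label_path) as fh:
                for line in fh:
                    if not line.strip() or line.startswith("#"):
                        continue
                    f = line.rstrip("\n").split("\t")
                    labels[f[0]] = (f[1], f[2] if len(f) > 2 else "pathway")
        return cls(gt, labels)


@dataclass
class EnrichmentResult:
    term: str
    k: int  # study hits
    n: int  # study size (annotated)
    K: int  # background hits
    N: int  # background size (annotated)
    pvalue: float
    adjusted_p: float


def classify_terms(
    genes: Iterable[str], amap: AnnotationMap, namespace: str | None = None
) -> dict[str, tuple[int, float]]:
    """Per-term gene counts and percentages among the input genes.

    Percentages are relative to input genes carrying >= 1 term in the
    namespace; a gene with several terms contributes to each, so summed
    percentages may exceed 100.
    """
    terms = amap.terms_in_namespace(namespace)
    annotated = 0
    counts: dict[str, int] = {}
    for g in genes:
        hit_terms = amap.gene_terms.get(g, set()) & terms
        if not hit_terms:
            continue
        annotated += 1
        for t in hit_terms:
            counts[t] = counts.get(t, 0) + 1
    if annotated == 0:
        raise ValueError("no input gene carries a term in this namespace")
    return {t: (n, round(100.0 * n / annotated, 2)) for t, n in sorted(counts.items())}


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) drawing n from N with K successes; 1.0 when k == 0."""
    if k <= 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def ease_pvalue(k: int, N: int, K: int, n: int) -> float:
    """EASE score: hypergeometric tail with one study hit removed."""
    return hypergeom_upper_tail(k - 1, N, K, n)


def enrich_terms(
    study_genes: Iterable[str],
    background_genes: Iterable[str],
    amap: AnnotationMap,
    namespace: str | None = None,
    p_threshold: float = 0.005,
    adj_threshold: float = 0.05,
    score: str = "ease",
) -> list[EnrichmentResult]:
    """Term enrichment of a study set against a background.

    Both thresholds must pass (raw p < p_threshold and BH-adjusted
    p < adj_threshold); results sorted by p.
    """
    study = set(study_genes)
    background = set(background_genes)
    if not study:
        raise ValueError("empty study set")
    if not study <= background:
        raise ValueError("study genes must be a subset of the background")
    if score not in ("ease", "hypergeometric"):
        raise ValueError(f"unknown score {score!r}")
    terms = sorted(amap.terms_in_namespace(namespace))
    study_annot = {g for g in study if amap.gene_terms.get(g, set()) & set(terms)}
    bg_annot = {g for g in background if amap.gene_terms.get(g, set()) & set(terms)}
    if not study_annot or not bg_annot:
        raise ValueError("no annotated genes in study or background")
    N, n = len(bg_annot), len(study_annot)
    rows = []
    for term in terms:
        members = {g for g, ts in amap.gene_terms.items() if term in ts}
        K = len(members & bg_annot)
        k = len(members & study_annot)
        if K == 0:
            continue
        p = ease_pvalue(k, N, K, n) if score == "ease" else hypergeom_upper_tail(k, N, K, n)
        rows.append((term, k, K, p))
    if not rows:
        return []
    adj = multipletests([r[3] for r in rows], method="fdr_bh")[1]
    results = [
        EnrichmentResult(term, k, n, K, N, p, float(q))
        for (term, k, K, p), q in zip(rows, adj)
        if p < p_threshold and q < adj_threshold
    ]
    return sorted(results, key=lambda r: r.pvalue)


def write_enrichment_tsv(results: list[EnrichmentResult], amap: AnnotationMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("term\tlabel\tk\tn\tK\tN\tpvalue\tadjusted_p\n")
        for r in results:
            label = amap.term_labels.get(r.term, (r.term, ""))[0]
            fh.write(
                f"{r.term}\t{label}\t{r.k}\t{r.n}\t{r.K}\t{r.N}"
                f"\t{r.pvalue:.3g}\t{r.adjusted_p:.3g}\n"
            )
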