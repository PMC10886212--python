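"""SNP-to-gene annotation and hypergeometric gene-set enrichment.

SNPs are classified against gene models into genomic-element categories with
a fixed precedence: inside a gene they are ``exonic`` (when the model carries
exons and the SNP hits one) or ``intronic``; otherwise, within a 1 kb flank
of a gene start (strand-aware) they are ``upstream``, within 1 kb of a gene
end ``downstream``, within both (possibly of two different genes)
``upstream/downstream``; everything else is ``intergenic``, with the nearest
flanking gene on each side recorded up to a search cap. Candidate genes are
the union of genes attached to candidate SNPs, and enrichment of a candidate
set against GMT gene sets uses the upper-tail hypergeometric test with
Benjamini–Hochberg FDR reported alongside the raw p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .genotype_io import GenotypeMatrix

log = logging.getLogger("selsig")

CATEGORIES = (
    "exonic", "intronic", "upstream", "downstream", "upstream/downstream", "intergenic",
)


@dataclass(frozen=True)
class GeneModel:
    """One gene: 1-based inclusive span, strand, optional exon intervals."""

    gene_id: str
    name: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise ValueError(f"gene {self.gene_id}: exon outside gene span")


@dataclass(frozen=True)
class AnnotatedSNP:
    chrom: str
    pos: int
    vid: str
    category: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


# ---------------------------------------------------------------------------
# gene model loading
# ---------------------------------------------------------------------------

def load_gene_models(path: str | Path) -> list[GeneModel]:
    """Load gene models from GFF3 (``gene`` features + exon children) or BED12.

    Internal coordinates are 1-based inclusive; output is sorted by
    (chrom, start, gene_id).
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".bed", ".bed12") or _looks_like_bed12(text):
        genes = _parse_bed12(text, str(path))
    else:
        genes = _parse_gff3(text, str(path))
    return sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id))


def _looks_like_bed12(text: str) -> bool:
    for line in text.splitlines():
        if line.strip() and not line.startswith(("#", "track", "browser")):
            return len(line.split("\t")) >= 12 and "=" not in line.split("\t")[-4]
    return False


def _parse_gff3(text: str, origin: str) -> list[GeneModel]:
    import gffutils

    # basic structural validation first: gffutils swallows malformed lines
    for ln, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) != 9:
            raise ValueError(f"{origin}:{ln}: expected 9 GFF3 columns, got {len(f)}")
        if not (f[3].isdigit() and f[4].isdigit()):
            raise ValueError(f"{origin}:{ln}: non-integer coordinates")
    db = gffutils.create_db(
        text, dbfn=":memory:", from_string=True, force=True,
        merge_strategy="create_unique", keep_order=True,
    )
    out = []
    for gene in db.features_of_type("gene"):
        exons = tuple(
            sorted(
                {(e.start, e.end) for e in db.children(gene, featuretype="exon")}
            )
        )
        name = gene.attributes.get("Name", [gene.id])[0]
        out.append(
            GeneModel(
                gene_id=gene.id,
                name=name,
                chrom=gene.seqid,
                start=gene.start,
                end=gene.end,
                strand=gene.strand if gene.strand in "+-" else "+",
                exons=exons,
            )
        )
    return out


def _parse_bed12(text: str, origin: str) -> list[GeneModel]:
    out = []
    for ln, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        if len(f) < 12:
            raise ValueError(f"{origin}:{ln}: expected 12 BED columns, got {len(f)}")
        chrom, cs, ce, name, _, strand = f[:6]
        try:
            chrom_start, chrom_end = int(cs), int(ce)
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
        except ValueError as exc:
            raise ValueError(f"{origin}:{ln}: malformed BED12 numeric field") from exc
        if len(sizes) != n_blocks or len(offsets) != n_blocks:
            raise ValueError(f"{origin}:{ln}: block count mismatch")
        exons = tuple(
            (chrom_start + off + 1, chrom_start + off + sz)
            for off, sz in zip(offsets, sizes)
        )
        out.append(
            GeneModel(
                gene_id=name,
                name=name,
                chrom=chrom,
                start=chrom_start + 1,
                end=chrom_end,
                strand=strand if strand in "+-" else "+",
                exons=exons,
            )
        )
    return out


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def annotate_snp(
    chrom: str,
    pos: int,
    genes: Sequence[GeneModel],
    flank: int = 1_000,
    max_flank_search: int = 1_000_000,
    vid: str = "",
) -> AnnotatedSNP:
    """Classify one SNP against gene models (precedence: genic > flank > intergenic)."""
    inside = [g for g in genes if g.chrom == chrom and g.start <= pos <= g.end]
    if inside:
        hit_exon = [
            g for g in inside if g.exons and any(s <= pos <= e for s, e in g.exons)
        ]
        if hit_exon:
            return AnnotatedSNP(chrom, pos, vid, "exonic",
                                tuple(g.gene_id for g in hit_exon))
        return AnnotatedSNP(chrom, pos, vid, "intronic",
                            tuple(g.gene_id for g in inside))

    up_genes, down_genes = [], []
    for g in genes:
        if g.chrom != chrom:
            continue
        # strand-aware transcription start/end
        tss, tes = (g.start, g.end) if g.strand == "+" else (g.end, g.start)
        if g.strand == "+":
            in_up = tss - flank <= pos < tss
            in_down = tes < pos <= tes + flank
        else:
            in_up = tss < pos <= tss + flank
            in_down = tes - flank <= pos < tes
        if in_up:
            up_genes.append(g.gene_id)
        if in_down:
            down_genes.append(g.gene_id)
    if up_genes and down_genes:
        return AnnotatedSNP(chrom, pos, vid, "upstream/downstream",
                            tuple(dict.fromkeys(up_genes + down_genes)))
    if up_genes:
        return AnnotatedSNP(chrom, pos, vid, "upstream", tuple(up_genes))
    if down_genes:
        return AnnotatedSNP(chrom, pos, vid, "downstream", tuple(down_genes))

    # intergenic: nearest gene on each side within the search cap
    left, right = None, None
    left_d = right_d = max_flank_search + 1
    for g in genes:
        if g.chrom != chrom:
            continue
        if g.end < pos and pos - g.end < left_d:
            left, left_d = g.gene_id, pos - g.end
        if g.start > pos and g.start - pos < right_d:
            right, right_d = g.gene_id, g.start - pos
    neighbors = tuple(x for x in (left, right) if x is not None)
    return AnnotatedSNP(chrom, pos, vid, "intergenic", neighbors)


def annotate_snps(
    variants: pd.DataFrame | GenotypeMatrix,
    genes: Sequence[GeneModel],
    flank: int = 1_000,
    max_flank_search: int = 1_000_000,
) -> list[AnnotatedSNP]:
    """Annotate a variant table (or a GenotypeMatrix's variants)."""
    v = variants.variants if isinstance(variants, GenotypeMatrix) else variants
    return [
        annotate_snp(str(r.chrom), int(r.pos), genes, flank, max_flank_search,
                     vid=str(getattr(r, "vid", "")))
        for r in v.itertuples(index=False)
    ]


def category_counts(snps: Iterable[AnnotatedSNP]) -> pd.DataFrame:
    """Count per genomic-element category (partition of the SNP set)."""
    counts = {c: 0 for c in CATEGORIES}
    for s in snps:
        counts[s.category] += 1
    return pd.DataFrame(
        {"category": list(counts), "n_snps": list(counts.values())}
    )


def annotation_frame(snps: Iterable[AnnotatedSNP]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"chrom": s.chrom, "pos": s.pos, "vid": s.vid,
             "category": s.category, "genes": ",".join(s.genes)}
            for s in snps
        ]
    )


def candidate_genes(
    snps: Iterable[AnnotatedSNP], include_intergenic_neighbors: bool = True
) -> list[str]:
    """Deduplicated gene ids attached to the SNPs, in first-seen order.

    With ``include_intergenic_neighbors`` off, intergenic SNPs contribute
    nothing (their recorded genes are flanking neighbors, not hosts).
    """
    out: dict[str, None] = {}
    for s in snps:
        if s.category == "intergenic" and not include_intergenic_neighbors:
            continue
        for gid in s.genes:
            out[gid] = None
    return list(out)


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int  # candidate genes in term
    K: int  # universe genes in term
    n: int  # candidate genes
    N: int  # universe size
    p: float
    fdr: float
    significant: bool

    def __post_init__(self) -> None:
        if self.k > min(self.K, self.n):
            raise ValueError("k cannot exceed min(K, n)")


def read_gmt(path: str | Path) -> dict[str, tuple[str, list[str]]]:
    """GMT: one line per term — term_id <TAB> description <TAB> gene..."""
    out = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) < 3:
            raise ValueError(f"{path}:{ln}: GMT line needs id, description, >=1 gene")
        out[f[0]] = (f[1], [g for g in f[2:] if g])
    return out


def hypergeom_enrich(
    candidates: Iterable[str],
    universe: Iterable[str],
    gmt: Mapping[str, tuple[str, Sequence[str]]],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of the candidate set per GMT term.

    p = P(X >= k) with X ~ Hypergeom(N, K, n); the ``significant`` flag uses
    the raw p < alpha; BH-adjusted FDR is reported alongside. Term gene sets
    are intersected with the universe before testing.
    """
    universe_set = set(universe)
    cand_set = set(candidates)
    if not cand_set:
        raise ValueError("empty candidate gene set")
    if not cand_set <= universe_set:
        extra = sorted(cand_set - universe_set)[:5]
        raise ValueError(f"candidate genes outside universe: {extra}")
    N, n = len(universe_set), len(cand_set)
    rows = []
    for term_id, (term_name, members) in gmt.items():
        term = set(members) & universe_set
        if not term:
            continue
        K = len(term)
        k = len(term & cand_set)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((term_id, term_name, k, K, p))
    if not rows:
        return []
    pvals = [r[4] for r in rows]
    fdr = multipletests(pvals, method="fdr_bh")[1]
    results = [
        EnrichmentResult(
            term_id=tid, term_name=tname, k=k, K=K, n=n, N=N,
            p=min(1.0, p), fdr=float(q), significant=p < alpha,
        )
        for (tid, tname, k, K, p), q in zip(rows, fdr)
    ]
    return sorted(results, key=lambda r: (r.p, r.term_id))


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
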