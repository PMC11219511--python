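"""Attach genomic region, gene identity and product to digested sites.

A site is *genic* if its motif start falls inside any gene span, *promoter*
if it lies within a fixed window upstream of a gene's strand-aware start
(the promoter site carries that downstream gene's id), and *intergenic*
otherwise.  Overlapping genes are resolved deterministically: the first
gene in start-sorted order wins, and the tie is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from methylrad.digestion import DigestedSite, RecognitionMotif
from methylrad.io import GeneAnnotation

__all__ = ["AnnotatedSite", "annotate_sites"]

logger = logging.getLogger(__name__)

REGIONS = ("genic", "promoter", "intergenic")


@dataclass(frozen=True)
class AnnotatedSite:
    """A digested site plus its region label and (optional) gene identity."""

    site_id: str
    start: int
    motif: RecognitionMotif
    strand: str
    region: str
    gene_id: str | None = None
    product: str | None = None

    @property
    def context(self) -> str:
        return self.motif.context


def annotate_sites(
    sites: Iterable[DigestedSite],
    annotation: GeneAnnotation,
    promoter_len: int = 200,
) -> list[AnnotatedSite]:
    """Label each site genic / promoter / intergenic (a partition).

    The promoter window is ``promoter_len`` bases immediately upstream of a
    gene's transcriptional start: positions ``[start - promoter_len, start)``
    for a ``+`` gene and ``[end, end + promoter_len)`` for a ``-`` gene.
    Genic takes precedence over promoter; among overlapping candidates the
    first gene in start-sorted order wins.  An empty annotation labels every
    site intergenic.
    """
    if promoter_len < 0:
        raise ValueError("promoter_len must be non-negative")
    genes = list(annotation.genes)  # already start-sorted
    out: list[AnnotatedSite] = []
    for site in sites:
        pos = site.start
        gene = next((g for g in genes if g.start <= pos < g.end), None)
        if gene is not None:
            n_hits = sum(1 for g in genes if g.start <= pos < g.end)
            if n_hits > 1:
                logger.info(
                    "site %s overlaps %d genes; keeping first-sorted %s",
                    site.site_id, n_hits, gene.gene_id,
                )
            region, gene_id, product = "genic", gene.gene_id, gene.product
        else:
            promoter_gene = None
            for g in genes:
                if g.strand == "+":
                    upstream = range(max(0, g.start - promoter_len), g.start)
                else:
                    upstream = range(g.end, g.end + promoter_len)
                if pos in upstream:
                    promoter_gene = g
                    break
            if promoter_gene is not None:
                region = "promoter"
                gene_id, product = promoter_gene.gene_id, promoter_gene.product
            else:
                region, gene_id, product = "intergenic", None, None
        out.append(
            AnnotatedSite(
                site_id=site.site_id,
                start=site.start,
                motif=site.motif,
                strand=site.strand,
                region=region,
                gene_id=gene_id,
                product=product,
            )
        )
    return out


def gene_map(annotated: Sequence[AnnotatedSite]) -> dict[str, str | None]:
    """site_id -> gene_id (None for intergenic sites)."""
    return {s.site_id: s.gene_id for s in annotated}
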