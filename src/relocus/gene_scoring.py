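"""Weighted multi-evidence target-gene scoring at GWAS loci.

For every gene whose TSS lies within 1.9 Mb of a locus lead SNP, an
evidence vector is assembled -- shared TAD membership (0/1, weight 2),
promoter contact with the variant region (0-1, weight 3), expression
category in each of five atrial datasets (0-2, weight 1 each), and eQTL
support (0/1/2 studies, weight 4) -- and summed into a composite score with
maximum 23.  Genes scoring at least 11 are candidate target genes: the
cutoff is the smallest integer exceeding the expression-only maximum of 10,
so conformation or eQTL evidence is required.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .io_formats import ContactRecord, GeneModel, GenomicInterval, Variant
from .variant_regions import VariantRegion

__all__ = [
    "ScoreConfig",
    "EvidenceVector",
    "GeneScore",
    "genes_in_window",
    "tad_evidence",
    "contact_evidence",
    "eqtl_evidence",
    "compute_score",
    "score_locus",
    "score_all",
    "select_candidates",
    "scores_to_frame",
]


@dataclass(frozen=True)
class ScoreConfig:
    window_bp: int = 1_900_000
    w_tad: float = 2.0
    w_contact: float = 3.0
    w_expr: float = 1.0  # per dataset, five datasets
    w_eqtl: float = 4.0
    threshold: float = 11.0
    threshold_strict: bool = False  # True: candidates need total > threshold
    contact_mode: str = "binary"  # or "continuous"
    promoter_upstream_bp: int = 1500
    promoter_downstream_bp: int = 500

    def __post_init__(self) -> None:
        if min(self.w_tad, self.w_contact, self.w_expr, self.w_eqtl) <= 0:
            raise ValueError("weights must be positive")
        if self.contact_mode not in ("binary", "continuous"):
            raise ValueError("contact_mode must be 'binary' or 'continuous'")
        if self.threshold > self.max_score():
            raise ValueError("threshold exceeds the maximum achievable score")

    def max_score(self) -> float:
        return self.w_tad + self.w_contact + 5 * 2 * self.w_expr + 2 * self.w_eqtl


@dataclass(frozen=True)
class EvidenceVector:
    tad: int = 0  # 0/1: gene TSS in the lead SNP's TAD
    contact: float = 0.0  # 0-1: promoter contact with the variant region
    expr: tuple[int, ...] = (0, 0, 0, 0, 0)  # five dataset categories, 0-2
    eqtl: int = 0  # 0/1/2 supporting studies

    def __post_init__(self) -> None:
        if self.tad not in (0, 1):
            raise ValueError("tad evidence must be 0 or 1")
        if not (0.0 <= self.contact <= 1.0):
            raise ValueError("contact evidence must lie in [0, 1]")
        if len(self.expr) != 5 or any(c not in (0, 1, 2) for c in self.expr):
            raise ValueError("expr must be five categories in {0, 1, 2}")
        if self.eqtl not in (0, 1, 2):
            raise ValueError("eqtl evidence must be 0, 1 or 2")


@dataclass(frozen=True)
class GeneScore:
    locus_id: str
    gene_id: str
    evidence: EvidenceVector
    total: float
    is_candidate: bool


def genes_in_window(
    lead: Variant, genes: Sequence[GeneModel], config: ScoreConfig = ScoreConfig()
) -> list[GeneModel]:
    """Genes whose TSS lies within window_bp of the lead SNP (inclusive)."""
    out = []
    for g in genes:
        tss_pos1 = g.tss + 1  # compare on the 1-based scale of lead.pos
        if g.chrom == lead.chrom and abs(tss_pos1 - lead.pos) <= config.window_bp:
            out.append(g)
    return out


def _containing_tad(
    tads: Sequence[GenomicInterval], chrom: str, pos0: int
) -> GenomicInterval | None:
    for tad in tads:
        if tad.contains(chrom, pos0):
            return tad
    return None


def tad_evidence(
    gene: GeneModel, region: VariantRegion, tads: Sequence[GenomicInterval]
) -> int:
    """1 iff the TAD containing the lead SNP also contains the gene's TSS.

    Half-open TAD intervals decide boundary bases; a lead in no TAD gives 0.
    """
    lead_tad = _containing_tad(tads, region.chrom, region.lead.pos - 1)
    if lead_tad is None:
        return 0
    return int(lead_tad.contains(gene.chrom, gene.tss))


def contact_evidence(
    gene: GeneModel,
    region: VariantRegion,
    contacts: Sequence[ContactRecord],
    config: ScoreConfig = ScoreConfig(),
) -> float:
    """Promoter-contact evidence between the gene and the variant region.

    A contact qualifies when one anchor overlaps the region's extended
    interval and the record is annotated with the gene (``target_gene_id``)
    or its other anchor overlaps the gene's promoter window.  Binary mode
    returns 0/1; continuous mode the maximum qualifying contact score.
    """
    promoter = gene.promoter(config.promoter_upstream_bp, config.promoter_downstream_bp)
    best = 0.0
    for c in contacts:
        for gene_anchor, region_anchor in ((c.anchor_a, c.anchor_b), (c.anchor_b, c.anchor_a)):
            if not region_anchor.overlaps(region.extended):
                continue
            if c.target_gene_id == gene.gene_id or gene_anchor.overlaps(promoter):
                best = max(best, c.score)
                break
    if config.contact_mode == "binary":
        return 1.0 if best > 0 else 0.0
    return best


def eqtl_evidence(
    gene: GeneModel, region: VariantRegion, eqtl_table: pd.DataFrame
) -> int:
    """Number of distinct eQTL studies (capped at 2) linking the locus to the gene.

    A record counts when its gene matches and its variant position falls
    inside the region's extended interval.
    """
    if len(eqtl_table) == 0:
        return 0
    sub = eqtl_table[
        (eqtl_table["gene_id"] == gene.gene_id)
        & (eqtl_table["chrom"].astype(str) == region.chrom)
        & (eqtl_table["pos"].astype(int) - 1 >= region.extended.start)
        & (eqtl_table["pos"].astype(int) - 1 < region.extended.end)
    ]
    return min(2, sub["study"].nunique())


def compute_score(
    evidence: EvidenceVector,
    config: ScoreConfig = ScoreConfig(),
    locus_id: str = "",
    gene_id: str = "",
) -> GeneScore:
    """Weighted total: 2*tad + 3*contact + sum(expr) + 4*eqtl at defaults."""
    total = (
        config.w_tad * evidence.tad
        + config.w_contact * evidence.contact
        + config.w_expr * sum(evidence.expr)
        + config.w_eqtl * evidence.eqtl
    )
    if config.threshold_strict:
        is_candidate = total > config.threshold
    else:
        is_candidate = total >= config.threshold
    return GeneScore(locus_id, gene_id, evidence, total, is_candidate)


def score_locus(
    region: VariantRegion,
    genes: Sequence[GeneModel],
    tads: Sequence[GenomicInterval],
    contacts: Sequence[ContactRecord],
    expr_categories: pd.DataFrame,
    eqtl_table: pd.DataFrame,
    config: ScoreConfig = ScoreConfig(),
    dataset_names: Sequence[str] | None = None,
) -> list[GeneScore]:
    """Score every gene in the locus window.

    ``expr_categories`` is the table from
    :func:`relocus.expression.categorize_datasets`; genes missing from it
    get all-zero expression categories.
    """
    from .expression import DATASETS

    names = tuple(dataset_names) if dataset_names is not None else DATASETS
    scores = []
    for gene in genes_in_window(region.lead, genes, config):
        if gene.gene_id in expr_categories.index:
            row = expr_categories.loc[gene.gene_id]
            expr = tuple(int(row[name]) for name in names)
        else:
            expr = (0, 0, 0, 0, 0)
        ev = EvidenceVector(
            tad=tad_evidence(gene, region, tads),
            contact=contact_evidence(gene, region, contacts, config),
            expr=expr,
            eqtl=eqtl_evidence(gene, region, eqtl_table),
        )
        scores.append(compute_score(ev, config, region.locus_id, gene.gene_id))
    return scores


def score_all(
    regions: Sequence[VariantRegion],
    genes: Sequence[GeneModel],
    tads: Sequence[GenomicInterval],
    contacts: Sequence[ContactRecord],
    expr_categories: pd.DataFrame,
    eqtl_table: pd.DataFrame,
    config: ScoreConfig = ScoreConfig(),
) -> list[GeneScore]:
    out: list[GeneScore] = []
    for region in regions:
        out.extend(
            score_locus(region, genes, tads, contacts, expr_categories, eqtl_table, config)
        )
    return out


def select_candidates(
    scores: Sequence[GeneScore], config: ScoreConfig = ScoreConfig()
) -> list[GeneScore]:
    """Candidate genes, de-duplicated genome-wide.

    A gene falling in the window of several loci is counted once at its
    maximum score; inclusion is total >= threshold (or strict > with
    ``threshold_strict``).
    """
    best: dict[str, GeneScore] = {}
    for s in scores:
        if not s.is_candidate:
            continue
        if s.gene_id not in best or s.total > best[s.gene_id].total:
            best[s.gene_id] = s
    return sorted(best.values(), key=lambda s: (-s.total, s.gene_id))


def scores_to_frame(scores: Sequence[GeneScore]) -> pd.DataFrame:
    from .expression import DATASETS

    rows = []
    for s in scores:
        row = {
            "locus_id": s.locus_id,
            "gene_id": s.gene_id,
            "tad": s.evidence.tad,
            "contact": s.evidence.contact,
        }
        for name, cat in zip(DATASETS, s.evidence.expr):
            row[f"expr_{name}"] = cat
        row["eqtl"] = s.evidence.eqtl
        row["total"] = s.total
        row["candidate"] = s.is_candidate
        rows.append(row)
    return pd.DataFrame(rows)
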