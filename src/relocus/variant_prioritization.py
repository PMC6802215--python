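"""Regulatory annotation and tiered shortlisting of member variants.

Every subthreshold member variant of a locus is annotated with: its
ATAC-seq and enhancer-prediction tag-counts (the peak or signal value at
the variant's base), promoter membership (-1500/+500 bp of a TSS,
strand-oriented), allele-specific motif-disruption hits against a PWM set,
and candidate target genes linked through promoter-capture contacts.  The
annotations are then rolled up into the nested shortlist tiers: variants in
a regulatory element by both or either evidence stream, the promoter subset,
contact-linked variants, and motif-disrupting variants in open chromatin
with and without a linked candidate gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    ContactRecord,
    GeneModel,
    GenomicInterval,
    PWMRecord,
    SignalTrack,
    Variant,
    _BASE_INDEX,
)
from .enhancer_model import Peak

__all__ = [
    "PrioritizationConfig",
    "MotifHit",
    "VariantAnnotation",
    "TIER_NAMES",
    "tag_count",
    "promoter_flag",
    "scan_motif_disruption",
    "score_alleles",
    "link_targets",
    "annotate_variants",
    "build_shortlist",
    "annotations_to_frame",
]

TIER_NAMES = (
    "T_RE_both",
    "T_RE_any",
    "T_promoter",
    "T_linked",
    "T_motif_open",
    "T_motif_linked",
)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass(frozen=True)
class PrioritizationConfig:
    promoter_upstream_bp: int = 1500
    promoter_downstream_bp: int = 500
    motif_score_fraction: float = 0.8  # min fraction of a PWM's max log-odds
    pwm_pseudocount: float = 0.5
    tag_mode: str = "peak"  # 'peak': max over containing peaks; 'signal': track value

    def __post_init__(self) -> None:
        if self.promoter_upstream_bp < 0 or self.promoter_downstream_bp < 0:
            raise ValueError("promoter offsets must be >= 0")
        if not (0.0 < self.motif_score_fraction <= 1.0):
            raise ValueError("motif_score_fraction must lie in (0, 1]")
        if self.tag_mode not in ("peak", "signal"):
            raise ValueError("tag_mode must be 'peak' or 'signal'")


@dataclass(frozen=True)
class MotifHit:
    rsid: str
    tf_name: str
    window: GenomicInterval  # best-scoring placement covering the variant
    strand: str
    score_ref: float  # best log-odds over all offsets/strands, ref allele
    score_alt: float
    delta: float  # score_alt - score_ref
    ref_is_hit: bool
    alt_is_hit: bool


@dataclass
class VariantAnnotation:
    variant: Variant
    locus_id: str
    atac_tag: float = 0.0
    emerge_tag: float = 0.0
    in_promoter: bool = False
    promoter_genes: tuple[str, ...] = ()
    motif_hits: tuple[MotifHit, ...] = ()
    linked_genes: tuple[str, ...] = ()


def tag_count(
    variant: Variant,
    peaks: Sequence[Peak] | None = None,
    track: SignalTrack | None = None,
    mode: str = "peak",
) -> float:
    """Signal read-out at the variant's single base; 0 outside all peaks.

    ``peak`` mode returns the maximum ``max_value`` of the peaks containing
    the base; ``signal`` mode reads the track value directly.
    """
    pos0 = variant.pos - 1
    if mode == "signal":
        if track is None:
            raise ValueError("signal mode requires a track")
        return track.value_at(variant.chrom, pos0)
    if peaks is None:
        raise ValueError("peak mode requires peaks")
    best = 0.0
    for p in peaks:
        if p.interval.contains(variant.chrom, pos0):
            best = max(best, p.max_value)
    return best


def promoter_flag(
    variant: Variant,
    genes: Sequence[GeneModel],
    config: PrioritizationConfig = PrioritizationConfig(),
) -> tuple[bool, tuple[str, ...]]:
    """Whether the variant base lies in any gene's promoter window.

    The window is [TSS - upstream, TSS + downstream] on the + strand,
    mirrored on -, inclusive at both ends; all matching genes are returned.
    """
    pos0 = variant.pos - 1
    hits = []
    for g in genes:
        if g.chrom != variant.chrom:
            continue
        window = g.promoter(config.promoter_upstream_bp, config.promoter_downstream_bp)
        if window.contains(variant.chrom, pos0):
            hits.append(g.gene_id)
    return bool(hits), tuple(hits)


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT.get(b, "N") for b in reversed(seq))


def _window_score(seq: str, log_odds: np.ndarray) -> float:
    """Log-odds of one placement; N bases contribute the background (0)."""
    total = 0.0
    for j, base in enumerate(seq):
        idx = _BASE_INDEX.get(base)
        if idx is not None:
            total += log_odds[idx, j]
    return total


def score_alleles(
    sequence: str,
    pos0: int,
    ref_allele: str,
    alt_allele: str,
    pwm: PWMRecord,
    pseudocount: float = 0.5,
) -> tuple[float, float, GenomicInterval | None, str]:
    """Best log-odds per allele over all placements covering position pos0.

    Every offset that places the PWM window over the variant base is scored
    on both strands, for the sequence carrying each allele; the maxima and
    the best-scoring placement (window, strand) are returned.  The window
    coordinates are relative to ``sequence`` (caller translates to genomic).
    """
    L = pwm.length
    lo = pwm.log_odds(pseudocount)
    n = len(sequence)
    best = {"ref": -np.inf, "alt": -np.inf}
    best_window: tuple[int, str] | None = None
    best_score = -np.inf
    for allele_name, allele in (("ref", ref_allele), ("alt", alt_allele)):
        seq = sequence[:pos0] + allele + sequence[pos0 + 1 :]
        for start in range(max(0, pos0 - L + 1), min(pos0, n - L) + 1):
            window = seq[start : start + L]
            for strand in ("+", "-"):
                s = _window_score(window if strand == "+" else _revcomp(window), lo)
                if s > best[allele_name]:
                    best[allele_name] = s
                if s > best_score:
                    best_score = s
                    best_window = (start, strand)
    if best_window is None:
        return float("-inf"), float("-inf"), None, "+"
    start, strand = best_window
    return best["ref"], best["alt"], GenomicInterval("_", start, start + L), strand


def scan_motif_disruption(
    variant: Variant,
    sequences: Mapping[str, str],
    pwms: Sequence[PWMRecord],
    config: PrioritizationConfig = PrioritizationConfig(),
) -> list[MotifHit]:
    """Allele-specific motif scores for every PWM at the variant.

    For each PWM, both alleles are substituted at the variant base and every
    placement covering the base is scored on both strands with pseudocounted
    log2 odds against the background.  A hit is emitted when either allele's
    maximum reaches ``motif_score_fraction`` of the PWM's maximum score;
    ``delta = score_alt - score_ref`` measures disruption (negative) or
    creation (positive) of the site by the alternate allele.
    """
    if variant.chrom not in sequences:
        raise ValueError(f"no sequence for chromosome {variant.chrom!r}")
    chrom_seq = sequences[variant.chrom]
    pos0 = variant.pos - 1
    if not (0 <= pos0 < len(chrom_seq)):
        raise ValueError(f"{variant.rsid}: position outside sequence")
    genome_base = chrom_seq[pos0].upper()
    if genome_base != variant.ref_allele.upper():
        raise ValueError(
            f"{variant.rsid}: ref allele {variant.ref_allele!r} disagrees with "
            f"genome base {genome_base!r} at {variant.chrom}:{variant.pos}"
        )
    hits = []
    max_len = max(p.length for p in pwms) if pwms else 0
    ctx_lo = max(0, pos0 - max_len + 1 - 1)
    ctx_hi = min(len(chrom_seq), pos0 + max_len)
    context = chrom_seq[ctx_lo:ctx_hi].upper()
    rel = pos0 - ctx_lo
    for pwm in pwms:
        score_ref, score_alt, window, strand = score_alleles(
            context,
            rel,
            variant.ref_allele.upper(),
            variant.alt_allele.upper(),
            pwm,
            config.pwm_pseudocount,
        )
        if window is None:
            continue
        cutoff = config.motif_score_fraction * pwm.max_score(config.pwm_pseudocount)
        ref_hit = score_ref >= cutoff
        alt_hit = score_alt >= cutoff
        if ref_hit or alt_hit:
            gwindow = GenomicInterval(
                variant.chrom,
                window.start + ctx_lo,
                window.end + ctx_lo,
                strand,
            )
            hits.append(
                MotifHit(
                    rsid=variant.rsid,
                    tf_name=pwm.tf_name,
                    window=gwindow,
                    strand=strand,
                    score_ref=score_ref,
                    score_alt=score_alt,
                    delta=score_alt - score_ref,
                    ref_is_hit=ref_hit,
                    alt_is_hit=alt_hit,
                )
            )
    return hits


def link_targets(
    variant: Variant,
    contacts: Sequence[ContactRecord],
    candidate_genes: Sequence[GeneModel],
    config: PrioritizationConfig = PrioritizationConfig(),
) -> tuple[str, ...]:
    """Candidate genes contacted from the variant's position.

    A gene qualifies when some contact has one anchor containing the variant
    base and the other anchor either carries the gene's id or overlaps its
    promoter window.
    """
    pos0 = variant.pos - 1
    linked: list[str] = []
    by_id = {g.gene_id: g for g in candidate_genes}
    for c in contacts:
        for var_anchor, gene_anchor in ((c.anchor_a, c.anchor_b), (c.anchor_b, c.anchor_a)):
            if not var_anchor.contains(variant.chrom, pos0):
                continue
            if c.target_gene_id in by_id and c.target_gene_id not in linked:
                linked.append(c.target_gene_id)
            for g in candidate_genes:
                if g.gene_id in linked:
                    continue
                promoter = g.promoter(
                    config.promoter_upstream_bp, config.promoter_downstream_bp
                )
                if gene_anchor.overlaps(promoter):
                    linked.append(g.gene_id)
    return tuple(sorted(linked))


def annotate_variants(
    members_by_locus: Mapping[str, Sequence[Variant]],
    atac_peaks: Sequence[Peak],
    emerge_peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    contacts: Sequence[ContactRecord],
    candidate_genes: Sequence[GeneModel],
    sequences: Mapping[str, str] | None = None,
    pwms: Sequence[PWMRecord] = (),
    config: PrioritizationConfig = PrioritizationConfig(),
    atac_track: SignalTrack | None = None,
    emerge_track: SignalTrack | None = None,
) -> list[VariantAnnotation]:
    """Full per-variant annotation across all loci."""
    annotations = []
    for locus_id, members in members_by_locus.items():
        for v in members:
            motif_hits: tuple[MotifHit, ...] = ()
            if sequences is not None and pwms:
                motif_hits = tuple(scan_motif_disruption(v, sequences, pwms, config))
            in_prom, prom_genes = promoter_flag(v, genes, config)
            annotations.append(
                VariantAnnotation(
                    variant=v,
                    locus_id=locus_id,
                    atac_tag=tag_count(v, atac_peaks, atac_track, config.tag_mode),
                    emerge_tag=tag_count(v, emerge_peaks, emerge_track, config.tag_mode),
                    in_promoter=in_prom,
                    promoter_genes=prom_genes,
                    motif_hits=motif_hits,
                    linked_genes=link_targets(v, contacts, candidate_genes, config),
                )
            )
    return annotations


def build_shortlist(
    annotations: Sequence[VariantAnnotation],
    config: PrioritizationConfig = PrioritizationConfig(),
) -> tuple[dict[str, list[VariantAnnotation]], pd.DataFrame]:
    """The nested shortlist tiers with counts and percentages.

    - T_RE_both:      ATAC and enhancer-prediction signal at the variant
    - T_RE_any:       either signal
    - T_promoter:     T_RE_any variants inside a promoter window
    - T_linked:       T_RE_any variants contacted to >= 1 candidate gene
    - T_motif_open:   motif hit and ATAC signal (open chromatin)
    - T_motif_linked: T_motif_open with >= 1 linked candidate gene
    """
    tiers: dict[str, list[VariantAnnotation]] = {name: [] for name in TIER_NAMES}
    for a in annotations:
        re_any = a.atac_tag > 0 or a.emerge_tag > 0
        if a.atac_tag > 0 and a.emerge_tag > 0:
            tiers["T_RE_both"].append(a)
        if re_any:
            tiers["T_RE_any"].append(a)
            if a.in_promoter:
                tiers["T_promoter"].append(a)
            if a.linked_genes:
                tiers["T_linked"].append(a)
        if a.motif_hits and a.atac_tag > 0:
            tiers["T_motif_open"].append(a)
            if a.linked_genes:
                tiers["T_motif_linked"].append(a)
    n = len(annotations)
    summary = pd.DataFrame(
        {
            "tier": TIER_NAMES,
            "count": [len(tiers[t]) for t in TIER_NAMES],
            "percent": [100.0 * len(tiers[t]) / n if n else 0.0 for t in TIER_NAMES],
        }
    )
    return tiers, summary


def annotations_to_frame(annotations: Sequence[VariantAnnotation]) -> pd.DataFrame:
    rows = []
    for a in annotations:
        best_hit = max(a.motif_hits, key=lambda h: max(h.score_ref, h.score_alt), default=None)
        rows.append(
            {
                "locus_id": a.locus_id,
                "rsid": a.variant.rsid,
                "chrom": a.variant.chrom,
                "pos": a.variant.pos,
                "pvalue": a.variant.pvalue,
                "atac_tag": a.atac_tag,
                "emerge_tag": a.emerge_tag,
                "in_promoter": a.in_promoter,
                "promoter_genes": ",".join(a.promoter_genes),
                "n_motif_hits": len(a.motif_hits),
                "best_motif_tf": best_hit.tf_name if best_hit else "",
                "best_motif_delta": best_hit.delta if best_hit else 0.0,
                "linked_genes": ",".join(a.linked_genes),
            }
        )
    return pd.DataFrame(rows)
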