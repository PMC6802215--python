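"""Construction of per-locus variant regions from summary statistics.

A variant region is built in three steps: a genome-wide-significant *core*
(p < 1e-8), *extension* of each boundary to the outermost flanking variant
with p < 1e-6, and collection of subthreshold *member* variants (p < 1e-4)
inside the extended span.  All thresholds are strict ``<``.

Clusters of significant variants separated by more than ``gap_bp`` (default
1 Mb, the typical TAD scale) start separate regions; GWAS loci are usually
given externally, so a gap rule is needed for generic input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

from .io_formats import GenomicInterval, Variant

__all__ = [
    "RegionConfig",
    "VariantRegion",
    "define_core_regions",
    "extend_region",
    "collect_members",
    "merge_overlapping_regions",
    "build_regions",
]


@dataclass(frozen=True)
class RegionConfig:
    p_core: float = 1e-8
    p_extend: float = 1e-6
    p_member: float = 1e-4
    gap_bp: int = 1_000_000
    merge_overlapping: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.p_core < self.p_extend < self.p_member <= 1):
            raise ValueError("require 0 < p_core < p_extend < p_member <= 1")
        if self.gap_bp < 1:
            raise ValueError("gap_bp must be positive")


@dataclass(frozen=True)
class VariantRegion:
    """One locus: lead variant, core and extended spans, member variants."""

    locus_id: str
    lead: Variant
    core: GenomicInterval
    extended: GenomicInterval
    members: tuple[Variant, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.core.chrom != self.extended.chrom:
            raise ValueError("core and extended must share a chromosome")
        if not (
            self.extended.start <= self.core.start and self.core.end <= self.extended.end
        ):
            raise ValueError("core must be contained in extended")

    @property
    def chrom(self) -> str:
        return self.core.chrom


def _point(chrom: str, pos1: int) -> GenomicInterval:
    """Width-1 interval for a 1-based variant position."""
    return GenomicInterval(chrom, pos1 - 1, pos1)


def _span(chrom: str, lo_pos1: int, hi_pos1: int) -> GenomicInterval:
    """Interval covering the 1-based positions lo..hi inclusive."""
    return GenomicInterval(chrom, lo_pos1 - 1, hi_pos1)


def define_core_regions(
    variants: Sequence[Variant], config: RegionConfig = RegionConfig()
) -> list[VariantRegion]:
    """Cluster genome-wide-significant variants into core regions.

    Significant variants (p < p_core) on the same chromosome within
    ``gap_bp`` of each other belong to one region; the core spans the
    outermost significant variants, and the lead is the p-minimum.
    Returns an empty list when nothing reaches significance.
    """
    regions: list[VariantRegion] = []
    by_chrom: dict[str, list[Variant]] = {}
    for v in variants:
        if v.pvalue < config.p_core:
            by_chrom.setdefault(v.chrom, []).append(v)
    counter = 0
    for chrom in sorted(by_chrom):
        sig = sorted(by_chrom[chrom], key=lambda v: v.pos)
        cluster: list[Variant] = []
        for v in sig + [None]:  # sentinel flushes the last cluster
            if cluster and (v is None or v.pos - cluster[-1].pos > config.gap_bp):
                counter += 1
                lead = min(cluster, key=lambda u: (u.pvalue, u.pos))
                core = _span(chrom, cluster[0].pos, cluster[-1].pos)
                regions.append(
                    VariantRegion(
                        locus_id=f"L{counter:03d}",
                        lead=lead,
                        core=core,
                        extended=core,
                    )
                )
                cluster = []
            if v is not None:
                cluster.append(v)
    return regions


def extend_region(
    region: VariantRegion,
    variants: Sequence[Variant],
    config: RegionConfig = RegionConfig(),
) -> VariantRegion:
    """Push each core boundary out to the last flanking p < p_extend variant.

    Extension is chained: a qualifying variant within ``gap_bp`` of the
    current boundary moves the boundary, which may bring further variants
    within reach.  A side with no qualifying variants keeps its core boundary.
    """
    flank = sorted(
        (
            v
            for v in variants
            if v.chrom == region.chrom and v.pvalue < config.p_extend
        ),
        key=lambda v: v.pos,
    )
    lo = region.core.start + 1  # leftmost covered 1-based position
    hi = region.core.end  # rightmost covered 1-based position
    changed = True
    while changed:
        changed = False
        for v in flank:
            if lo - config.gap_bp <= v.pos < lo:
                lo = v.pos
                changed = True
            elif hi < v.pos <= hi + config.gap_bp:
                hi = v.pos
                changed = True
    return replace(region, extended=_span(region.chrom, lo, hi))


def collect_members(
    region: VariantRegion,
    variants: Sequence[Variant],
    config: RegionConfig = RegionConfig(),
) -> VariantRegion:
    """Fill in subthreshold members: p < p_member inside the extended span.

    Both boundary positions of the extended interval are inclusive.
    """
    members = tuple(
        sorted(
            (
                v
                for v in variants
                if v.chrom == region.chrom
                and v.pvalue < config.p_member
                and region.extended.start <= v.pos - 1 < region.extended.end
            ),
            key=lambda v: (v.pos, v.rsid),
        )
    )
    return replace(region, members=members)


def merge_overlapping_regions(regions: Sequence[VariantRegion]) -> list[VariantRegion]:
    """Merge regions whose extended intervals overlap; idempotent.

    The merged lead is the overall p-minimum and locus ids are concatenated.
    """
    by_chrom: dict[str, list[VariantRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    out: list[VariantRegion] = []
    for chrom in sorted(by_chrom):
        group = sorted(by_chrom[chrom], key=lambda r: r.extended.start)
        current: list[VariantRegion] = []
        for r in group + [None]:
            if current and (r is None or r.extended.start >= max(x.extended.end for x in current)):
                if len(current) == 1:
                    out.append(current[0])
                else:
                    lead = min((x.lead for x in current), key=lambda v: (v.pvalue, v.pos))
                    core = GenomicInterval(
                        chrom,
                        min(x.core.start for x in current),
                        max(x.core.end for x in current),
                    )
                    extended = GenomicInterval(
                        chrom,
                        min(x.extended.start for x in current),
                        max(x.extended.end for x in current),
                    )
                    seen: dict[tuple, Variant] = {}
                    for x in current:
                        for m in x.members:
                            seen[(m.rsid, m.pos)] = m
                    members = tuple(
                        sorted(seen.values(), key=lambda v: (v.pos, v.rsid))
                    )
                    out.append(
                        VariantRegion(
                            locus_id="+".join(x.locus_id for x in current),
                            lead=lead,
                            core=core,
                            extended=extended,
                            members=members,
                        )
                    )
                current = []
            if r is not None:
                current.append(r)
    return out


def build_regions(
    variants: Sequence[Variant], config: RegionConfig = RegionConfig()
) -> list[VariantRegion]:
    """Full pipeline: cores -> extension -> members (-> merge)."""
    regions = [
        collect_members(extend_region(r, variants, config), variants, config)
        for r in define_core_regions(variants, config)
    ]
    if config.merge_overlapping:
        regions = merge_overlapping_regions(regions)
    return regions
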