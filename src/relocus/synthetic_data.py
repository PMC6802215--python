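"""Miniature-genome simulator with the statistical structure the pipeline assumes.

Generates, from a single seed, a fully self-consistent input bundle: a TAD-
partitioned annotation with genes and random genome sequence; GWAS summary
statistics whose -log10 p decays exponentially with distance from planted
lead SNPs; enhancer-shaped bumps in a set of epigenomic signal tracks (some
deliberately uninformative); negative-binomial expression counts for the
five atrial datasets with designated stable reference genes; promoter
contacts wiring planted enhancers to their true target genes; eQTL records
for a fraction of loci; and planted motif-altering alleles inside the
enhancers.  A ground-truth manifest records what was planted so recovery
can be tested downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
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
    write_bed,
    write_bedgraph,
    write_bedpe,
    write_counts,
    write_fasta,
    write_genes_tsv,
    write_gwas_tsv,
    write_pfm,
)

__all__ = [
    "SimulationConfig",
    "LocusTruth",
    "GroundTruth",
    "Bundle",
    "default_pwms",
    "simulate_annotation",
    "simulate_gwas",
    "simulate_tracks",
    "simulate_expression",
    "simulate_contacts_and_eqtl",
    "simulate_bundle",
    "write_bundle",
]

_BASES = "ACGT"
DATASET_NAMES = ("adult_LA", "adult_RA", "adult_LA_CM", "fetal_LA", "fetal_RA")
REFERENCE_SYMBOLS = ("RPL32", "RPL4", "H2AF2")


def default_pwms() -> list[PWMRecord]:
    """A toy cardiac-like PWM set: TBX-, MEF2- and CTCF-like motifs.

    Count matrices are synthetic (strong consensus with light noise), built
    to resemble the information content of the real motif families, not
    copied from any database.
    """

    def from_consensus(name: str, consensus: str, strong: float = 90.0) -> PWMRecord:
        L = len(consensus)
        m = np.full((4, L), 3.0)
        for j, base in enumerate(consensus):
            m[_BASES.index(base), j] = strong
        return PWMRecord(name, m)

    return [
        from_consensus("TBX_like", "AGGTGTGA"),
        from_consensus("MEF2_like", "CTATTTTTAG"),
        from_consensus("CTCF_like", "CCACCAGGGG"),
    ]


@dataclass
class SimulationConfig:
    """Study conditions of the desk-scale bundle; the seed fixes everything."""

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 10_000_000
    n_loci: int = 8
    n_genes: int = 400
    tad_mean_length: int = 1_000_000
    lead_pvalue_exponent_range: tuple[float, float] = (15.0, 30.0)
    pvalue_decay_scale: float = 20_000.0
    n_assoc_per_locus: int = 120
    n_background_variants: int = 3000
    n_enhancers_per_locus: int = 3
    n_functional_per_locus: int = 2
    enhancer_width_range: tuple[int, int] = (300, 800)
    enhancer_max_offset: int = 15_000  # enhancers lie within this of the lead
    track_names: tuple[str, ...] = ("atac", "h3k27ac", "h3k4me1", "input_a", "input_b")
    informative_tracks: tuple[str, ...] = ("atac", "h3k27ac", "h3k4me1")
    track_bin_bp: int = 50
    background_block_bp: int = 500
    background_noise_mean: float = 0.1
    background_noise_sd: float = 0.05
    enhancer_amplitude_range: tuple[float, float] = (1.0, 3.0)
    nb_dispersion: float = 0.3
    reference_nb_dispersion: float = 0.01
    n_samples_per_dataset: int = 3
    fraction_silent: float = 0.25
    fraction_high: float = 0.25
    mean_medium: float = 40.0
    mean_high: float = 400.0
    mean_reference: float = 1000.0
    mean_target: float = 2000.0
    dataset_fold_jitter_sd: float = 0.2
    reference_fold_jitter_sd: float = 0.05
    sample_size_factor_sd: float = 0.2
    fraction_eqtl_loci: float = 0.35
    contact_fp_rate: float = 0.1
    planted_motif: PWMRecord | None = None  # defaults to the TBX-like PWM

    def __post_init__(self) -> None:
        if self.planted_motif is None:
            self.planted_motif = default_pwms()[0]
        if min(self.n_chromosomes, self.n_loci, self.n_genes) < 1:
            raise ValueError("counts must be >= 1")
        if self.chrom_length < 10 * self.tad_mean_length:
            raise ValueError("chrom_length must be >= 10 x tad_mean_length")
        if self.n_functional_per_locus > self.n_enhancers_per_locus:
            raise ValueError("n_functional_per_locus exceeds n_enhancers_per_locus")
        if self.n_genes > self.n_chromosomes * self.chrom_length // 1000:
            raise ValueError("infeasible gene density for genome size")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]


@dataclass
class LocusTruth:
    locus_id: str
    chrom: str
    lead_rsid: str
    lead_pos: int  # 1-based, like Variant.pos
    true_target_gene: str
    decoy_genes: list[str]
    enhancers: list[GenomicInterval]
    functional_rsids: list[str]


@dataclass
class GroundTruth:
    """Manifest of planted structure, the oracle for recovery tests."""

    loci: list[LocusTruth]
    reference_gene_ids: list[str]

    @property
    def true_targets(self) -> list[str]:
        return [l.true_target_gene for l in self.loci]

    @property
    def functional_rsids(self) -> list[str]:
        return [r for l in self.loci for r in l.functional_rsids]

    @property
    def enhancers(self) -> list[GenomicInterval]:
        return [e for l in self.loci for e in l.enhancers]

    def to_json(self) -> str:
        payload = {
            "reference_gene_ids": self.reference_gene_ids,
            "loci": [
                {
                    "locus_id": l.locus_id,
                    "chrom": l.chrom,
                    "lead_rsid": l.lead_rsid,
                    "lead_pos": l.lead_pos,
                    "true_target_gene": l.true_target_gene,
                    "decoy_genes": l.decoy_genes,
                    "enhancers": [[e.chrom, e.start, e.end] for e in l.enhancers],
                    "functional_rsids": l.functional_rsids,
                }
                for l in self.loci
            ],
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        payload = json.loads(text)
        loci = [
            LocusTruth(
                locus_id=l["locus_id"],
                chrom=l["chrom"],
                lead_rsid=l["lead_rsid"],
                lead_pos=l["lead_pos"],
                true_target_gene=l["true_target_gene"],
                decoy_genes=list(l["decoy_genes"]),
                enhancers=[GenomicInterval(c, s, e) for c, s, e in l["enhancers"]],
                functional_rsids=list(l["functional_rsids"]),
            )
            for l in payload["loci"]
        ]
        return cls(loci, list(payload["reference_gene_ids"]))


@dataclass
class Bundle:
    """All simulated inputs, in memory."""

    config: SimulationConfig
    genes: list[GeneModel]
    tads: list[GenomicInterval]
    sequences: dict[str, str]
    variants: list[Variant]
    tracks: dict[str, SignalTrack]
    counts: dict[str, pd.DataFrame]
    contacts: list[ContactRecord]
    eqtl: pd.DataFrame
    truth: GroundTruth
    pwms: list[PWMRecord]


# ---------------------------------------------------------------------------
# annotation


def simulate_annotation(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[GeneModel], list[GenomicInterval], dict[str, np.ndarray]]:
    """Genes, TADs and raw genome sequences (as mutable base-index arrays).

    TADs exactly partition each chromosome with lengths jittered around the
    configured mean; gene TSSs are uniform along each chromosome.  Sequences
    are returned as uint8 arrays (0..3 = ACGT) so later stages can plant
    motif instances before freezing them to strings.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    tads: list[GenomicInterval] = []
    for chrom in config.chrom_names:
        n_tads = max(1, round(config.chrom_length / config.tad_mean_length))
        weights = rng.gamma(shape=8.0, scale=1.0, size=n_tads)
        edges = np.concatenate(
            [[0], np.round(np.cumsum(weights) / weights.sum() * config.chrom_length)]
        ).astype(int)
        edges[-1] = config.chrom_length
        for i in range(n_tads):
            if edges[i + 1] > edges[i]:
                tads.append(GenomicInterval(chrom, int(edges[i]), int(edges[i + 1])))

    genes: list[GeneModel] = []
    per_chrom = np.full(config.n_chromosomes, config.n_genes // config.n_chromosomes)
    per_chrom[: config.n_genes % config.n_chromosomes] += 1
    gid = 0
    for chrom, n in zip(config.chrom_names, per_chrom):
        tss_positions = np.sort(
            rng.integers(60_000, config.chrom_length - 60_000, size=int(n))
        )
        for tss in tss_positions:
            gid += 1
            length = int(rng.integers(5_000, 50_000))
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "+":
                start, end = int(tss), int(tss) + length
            else:
                start, end = int(tss) - length + 1, int(tss) + 1
            name = f"G{gid:04d}"
            genes.append(GeneModel.from_body(name, name, chrom, start, end, strand))

    sequences = {
        chrom: rng.integers(0, 4, size=config.chrom_length, dtype=np.uint8)
        for chrom in config.chrom_names
    }
    return genes, tads, sequences


def _seq_to_str(seq: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lut[seq].tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# loci placement


def _place_loci(
    config: SimulationConfig,
    genes: list[GeneModel],
    tads: list[GenomicInterval],
    rng: np.random.Generator,
    exclude_target_ids: set[str] | None = None,
) -> list[LocusTruth]:
    """Choose lead positions, true targets, decoys and enhancer intervals.

    Leads are spread evenly (with jitter) so regions stay well separated;
    the true target is a gene in the lead's TAD, forced away from the
    reference genes; enhancers sit within ``enhancer_max_offset`` of the
    lead, clear of promoters.
    """
    loci: list[LocusTruth] = []
    n_per_chrom = np.full(config.n_chromosomes, config.n_loci // config.n_chromosomes)
    n_per_chrom[: config.n_loci % config.n_chromosomes] += 1
    counter = 0
    taken_targets: set[str] = set(exclude_target_ids or ())
    for chrom, n in zip(config.chrom_names, n_per_chrom):
        if n == 0:
            continue
        anchors = np.linspace(0.12, 0.88, int(n)) * config.chrom_length
        for anchor in anchors:
            counter += 1
            lead_pos0 = int(anchor + rng.integers(-100_000, 100_000))
            lead_tad = next(
                (t for t in tads if t.contains(chrom, lead_pos0)), None
            )
            in_tad = [
                g
                for g in genes
                if lead_tad is not None
                and lead_tad.contains(g.chrom, g.tss)
                and g.gene_id not in taken_targets
                and abs(g.tss - lead_pos0) > config.enhancer_max_offset + 5_000
            ]
            if in_tad:
                target = in_tad[int(rng.integers(0, len(in_tad)))]
            else:  # no eligible gene in the TAD: fall back to the nearest gene
                target = min(
                    (g for g in genes if g.chrom == chrom and g.gene_id not in taken_targets),
                    key=lambda g: abs(g.tss - lead_pos0),
                )
            taken_targets.add(target.gene_id)
            decoys = [
                g.gene_id
                for g in genes
                if g.chrom == chrom
                and g.gene_id != target.gene_id
                and abs(g.tss - lead_pos0) <= 1_900_000
            ]
            enhancers: list[GenomicInterval] = []
            attempts = 0
            while len(enhancers) < config.n_enhancers_per_locus and attempts < 200:
                attempts += 1
                width = int(rng.integers(*config.enhancer_width_range))
                offset = int(
                    rng.integers(2_000, config.enhancer_max_offset - width)
                ) * (1 if rng.random() < 0.5 else -1)
                start = lead_pos0 + offset - width // 2
                cand = GenomicInterval(chrom, start, start + width)
                near_tss = any(
                    g.chrom == chrom and abs(g.tss - (start + width // 2)) < 3_000
                    for g in genes
                )
                if near_tss or any(cand.overlaps(e) for e in enhancers):
                    continue
                enhancers.append(cand)
            loci.append(
                LocusTruth(
                    locus_id=f"locus{counter:02d}",
                    chrom=chrom,
                    lead_rsid=f"rs{counter}000000",
                    lead_pos=lead_pos0 + 1,
                    true_target_gene=target.gene_id,
                    decoy_genes=decoys,
                    enhancers=enhancers,
                    functional_rsids=[],
                )
            )
    return loci


# ---------------------------------------------------------------------------
# GWAS


def simulate_gwas(
    config: SimulationConfig,
    sequences: Mapping[str, np.ndarray],
    loci: Sequence[LocusTruth],
    rng: np.random.Generator,
) -> list[Variant]:
    """Summary statistics with planted leads, decaying -log10 p, and noise.

    Per locus: the lead gets -log10 p drawn from the configured range;
    associated variants at distance d have expected -log10 p of
    peak * exp(-d / scale) plus non-negative noise (clipped just below the
    lead so the lead stays the locus minimum).  Functional variants are
    placed at planted-enhancer midpoints and their motif-altering alleles
    are written into the genome: the reference allele breaks the planted
    motif consensus, the alternate completes it.  A uniform background of
    non-associated variants (p ~ U(0,1)) covers the rest of the genome.
    """
    variants: list[Variant] = []
    rs_counter = 0

    def base_at(chrom: str, pos0: int) -> str:
        return _BASES[sequences[chrom][pos0]]

    def random_alt(ref: str) -> str:
        choices = [b for b in _BASES if b != ref]
        return choices[int(rng.integers(0, 3))]

    motif = config.planted_motif
    consensus = motif.consensus()
    L = motif.length

    for locus in loci:
        chrom = locus.chrom
        lead_pos0 = locus.lead_pos - 1
        lead_mlogp = float(rng.uniform(*config.lead_pvalue_exponent_range))
        ref = base_at(chrom, lead_pos0)
        variants.append(
            Variant(
                rsid=locus.lead_rsid,
                chrom=chrom,
                pos=locus.lead_pos,
                ref_allele=ref,
                alt_allele=random_alt(ref),
                pvalue=10.0 ** (-lead_mlogp),
            )
        )
        used = {lead_pos0}

        # functional variants at enhancer midpoints, motif planted around them
        for enh in locus.enhancers[: config.n_functional_per_locus]:
            mid = (enh.start + enh.end) // 2
            if mid in used:
                mid += 1
            used.add(mid)
            rs_counter += 1
            rsid = f"rs{rs_counter:07d}"
            motif_start = mid - L // 2
            planted = list(consensus)
            var_col = mid - motif_start
            # choose the weakest base at the variant column as the broken ref
            weak = _BASES[int(motif.matrix[:, var_col].argmin())]
            if weak == consensus[var_col]:
                weak = random_alt(consensus[var_col])
            seq = sequences[chrom]
            for j, b in enumerate(planted):
                seq[motif_start + j] = _BASES.index(b)
            seq[mid] = _BASES.index(weak)
            d = abs(mid - lead_pos0)
            mlogp = min(
                lead_mlogp - 0.1,
                lead_mlogp * float(np.exp(-d / config.pvalue_decay_scale))
                + float(abs(rng.normal(0.0, 0.3))),
            )
            variants.append(
                Variant(
                    rsid=rsid,
                    chrom=chrom,
                    pos=mid + 1,
                    ref_allele=weak,
                    alt_allele=consensus[var_col],
                    pvalue=10.0 ** (-mlogp),
                )
            )
            locus.functional_rsids.append(rsid)

        # the decaying cloud of associated variants
        for _ in range(config.n_assoc_per_locus):
            d = int(rng.exponential(scale=3 * config.pvalue_decay_scale))
            sign = 1 if rng.random() < 0.5 else -1
            pos0 = int(np.clip(lead_pos0 + sign * d, 0, config.chrom_length - 1))
            if pos0 in used:
                continue
            used.add(pos0)
            rs_counter += 1
            mlogp = lead_mlogp * float(
                np.exp(-abs(pos0 - lead_pos0) / config.pvalue_decay_scale)
            ) + float(rng.normal(0.0, 0.5))
            mlogp = float(np.clip(mlogp, 0.05, lead_mlogp - 0.1))
            ref = base_at(chrom, pos0)
            variants.append(
                Variant(
                    rsid=f"rs{rs_counter:07d}",
                    chrom=chrom,
                    pos=pos0 + 1,
                    ref_allele=ref,
                    alt_allele=random_alt(ref),
                    pvalue=10.0 ** (-mlogp),
                )
            )

    # genome-wide background of non-associated variants
    for _ in range(config.n_background_variants):
        chrom = config.chrom_names[int(rng.integers(0, config.n_chromosomes))]
        pos0 = int(rng.integers(0, config.chrom_length))
        rs_counter += 1
        ref = base_at(chrom, pos0)
        variants.append(
            Variant(
                rsid=f"rs{rs_counter:07d}",
                chrom=chrom,
                pos=pos0 + 1,
                ref_allele=ref,
                alt_allele=random_alt(ref),
                pvalue=float(rng.uniform(1e-3, 1.0)),
            )
        )
    variants.sort(key=lambda v: (v.chrom, v.pos, v.rsid))
    return variants


# ---------------------------------------------------------------------------
# tracks


def simulate_tracks(
    config: SimulationConfig,
    enhancers: Sequence[GenomicInterval],
    rng: np.random.Generator,
) -> dict[str, SignalTrack]:
    """Per-track run-length signal: noise background plus enhancer plateaus.

    Informative tracks gain a per-enhancer amplitude plateau over each
    planted enhancer; uninformative tracks are background only.  Background
    noise is constant within blocks of ``background_block_bp`` so the runs
    stay compact; the working resolution is ``track_bin_bp``.
    """
    res = config.track_bin_bp
    block = max(1, config.background_block_bp // res)
    n_bins = config.chrom_length // res
    tracks: dict[str, SignalTrack] = {}
    for name in config.track_names:
        informative = name in config.informative_tracks
        runs = {}
        for chrom in config.chrom_names:
            n_blocks = int(np.ceil(n_bins / block))
            noise = np.clip(
                rng.normal(
                    config.background_noise_mean,
                    config.background_noise_sd,
                    size=n_blocks,
                ),
                0.0,
                None,
            )
            values = np.repeat(noise, block)[:n_bins].copy()
            if informative:
                for enh in enhancers:
                    if enh.chrom != chrom:
                        continue
                    amp = float(rng.uniform(*config.enhancer_amplitude_range))
                    b0 = enh.start // res
                    b1 = int(np.ceil(enh.end / res))
                    values[b0:b1] += amp
            elif len(enhancers):
                # burn the same number of draws so uninformative tracks do not
                # shift the stream depending on enhancer placement
                n_here = sum(e.chrom == chrom for e in enhancers)
                rng.uniform(*config.enhancer_amplitude_range, size=n_here)
            starts = np.arange(n_bins, dtype=np.int64) * res
            ends = starts + res
            ends[-1] = config.chrom_length
            # merge equal adjacent bins for compactness
            keep = np.concatenate([[True], values[1:] != values[:-1]])
            idx = np.flatnonzero(keep)
            run_starts = starts[idx]
            run_ends = np.concatenate([starts[idx[1:]], [config.chrom_length]])
            runs[chrom] = (run_starts, run_ends, values[idx])
        tracks[name] = SignalTrack(runs)
    return tracks


# ---------------------------------------------------------------------------
# expression


def simulate_expression(
    config: SimulationConfig,
    genes: Sequence[GeneModel],
    truth: GroundTruth,
    rng: np.random.Generator,
    n_samples: int | None = None,
) -> dict[str, pd.DataFrame]:
    """Five negative-binomial count matrices with shared per-gene strata.

    Each gene draws a stratum (silent / medium / high) and a base mean that
    is shared across the five datasets up to dataset-specific fold jitter,
    so cross-dataset categories are correlated as in real atria.  True
    target genes sit at the top of the high stratum; reference genes have
    high stable means and a much smaller dispersion (they are chosen in
    practice precisely because they are stable).
    """
    if n_samples is None:
        n_samples = config.n_samples_per_dataset
    gene_ids = [g.gene_id for g in genes]
    targets = set(truth.true_targets)
    refs = set(truth.reference_gene_ids)
    n = len(gene_ids)

    strata = rng.choice(
        ["silent", "medium", "high"],
        size=n,
        p=[
            config.fraction_silent,
            1.0 - config.fraction_silent - config.fraction_high,
            config.fraction_high,
        ],
    )
    base_mean = np.zeros(n)
    for i, g in enumerate(gene_ids):
        if g in refs:
            base_mean[i] = config.mean_reference
        elif g in targets:
            base_mean[i] = config.mean_target * float(rng.lognormal(0.0, 0.1))
        elif strata[i] == "medium":
            base_mean[i] = config.mean_medium * float(rng.lognormal(0.0, 0.5))
        elif strata[i] == "high":
            base_mean[i] = config.mean_high * float(rng.lognormal(0.0, 0.4))

    is_ref = np.array([g in refs for g in gene_ids])
    counts: dict[str, pd.DataFrame] = {}
    for dataset in DATASET_NAMES:
        jitter = rng.lognormal(0.0, config.dataset_fold_jitter_sd, size=n)
        jitter[is_ref] = rng.lognormal(
            0.0, config.reference_fold_jitter_sd, size=int(is_ref.sum())
        )
        mu_gene = base_mean * jitter
        size_factors = rng.lognormal(0.0, config.sample_size_factor_sd, size=n_samples)
        mat = np.zeros((n, n_samples), dtype=np.int64)
        disp = np.where(is_ref, config.reference_nb_dispersion, config.nb_dispersion)
        for s in range(n_samples):
            mu = mu_gene * size_factors[s]
            active = mu > 0
            r = 1.0 / disp[active]
            p = r / (r + mu[active])
            mat[active, s] = rng.negative_binomial(r, p)
        counts[dataset] = pd.DataFrame(
            mat,
            index=pd.Index(gene_ids, name="gene_id"),
            columns=[f"{dataset}_s{s + 1}" for s in range(n_samples)],
        )
    return counts


# ---------------------------------------------------------------------------
# contacts + eQTL


def simulate_contacts_and_eqtl(
    config: SimulationConfig,
    genes: Sequence[GeneModel],
    truth: GroundTruth,
    rng: np.random.Generator,
) -> tuple[list[ContactRecord], pd.DataFrame]:
    """Promoter contacts for true targets (and false-positive decoys) + eQTL.

    Every planted enhancer contacts its locus's true-target promoter; each
    decoy gene gains a contact into the locus's variant-dense span with
    probability ``contact_fp_rate``.  A ``fraction_eqtl_loci`` subset of
    loci gets one or two study records linking the lead to the true target.
    """
    by_id = {g.gene_id: g for g in genes}
    contacts: list[ContactRecord] = []
    eqtl_rows = []
    studies = ("RA_appendage_study", "LV_study", "skeletal_muscle_study")
    n_eqtl = int(round(config.fraction_eqtl_loci * len(truth.loci)))
    eqtl_loci = set(
        rng.choice(len(truth.loci), size=n_eqtl, replace=False).tolist()
        if n_eqtl
        else []
    )
    for li, locus in enumerate(truth.loci):
        target = by_id[locus.true_target_gene]
        promoter = target.promoter()
        for enh in locus.enhancers:
            contacts.append(
                ContactRecord(
                    anchor_a=promoter,
                    anchor_b=enh,
                    score=float(rng.uniform(0.6, 1.0)),
                    target_gene_id=target.gene_id,
                )
            )
        for decoy_id in locus.decoy_genes:
            if rng.random() < config.contact_fp_rate:
                decoy = by_id[decoy_id]
                span = config.enhancer_max_offset
                start = int(
                    np.clip(
                        locus.lead_pos - 1 + int(rng.integers(-span, span - 1_000)),
                        0,
                        config.chrom_length - 1_001,
                    )
                )
                contacts.append(
                    ContactRecord(
                        anchor_a=decoy.promoter(),
                        anchor_b=GenomicInterval(locus.chrom, start, start + 1_000),
                        score=float(rng.uniform(0.1, 0.9)),
                        target_gene_id=decoy_id,
                    )
                )
        if li in eqtl_loci:
            n_studies = 1 if rng.random() < 0.5 else 2
            for study in rng.choice(studies, size=n_studies, replace=False):
                eqtl_rows.append(
                    {
                        "rsid": locus.lead_rsid,
                        "chrom": locus.chrom,
                        "pos": locus.lead_pos,
                        "gene_id": locus.true_target_gene,
                        "study": str(study),
                    }
                )
    eqtl = pd.DataFrame(eqtl_rows, columns=["rsid", "chrom", "pos", "gene_id", "study"])
    return contacts, eqtl


# ---------------------------------------------------------------------------
# orchestration


def simulate_bundle(config: SimulationConfig | None = None) -> Bundle:
    """Generate the full in-memory bundle; everything derives from the seed."""
    if config is None:
        config = SimulationConfig()
    rng = np.random.default_rng(config.seed)
    genes, tads, raw_sequences = simulate_annotation(config, rng)

    # designate reference genes: stable housekeeping-like genes, never targets
    reference_ids = []
    stride = max(1, len(genes) // 3)
    for symbol, gene in zip(REFERENCE_SYMBOLS, genes[::stride][:3]):
        idx = genes.index(gene)
        genes[idx] = GeneModel.from_body(
            symbol, symbol, gene.chrom, gene.body.start, gene.body.end, gene.strand
        )
        reference_ids.append(symbol)

    loci = _place_loci(config, genes, tads, rng, exclude_target_ids=set(reference_ids))
    truth = GroundTruth(loci=loci, reference_gene_ids=reference_ids)
    variants = simulate_gwas(config, raw_sequences, loci, rng)
    tracks = simulate_tracks(config, truth.enhancers, rng)
    counts = simulate_expression(config, genes, truth, rng)
    contacts, eqtl = simulate_contacts_and_eqtl(config, genes, truth, rng)
    sequences = {chrom: _seq_to_str(arr) for chrom, arr in raw_sequences.items()}
    return Bundle(
        config=config,
        genes=genes,
        tads=tads,
        sequences=sequences,
        variants=variants,
        tracks=tracks,
        counts=counts,
        contacts=contacts,
        eqtl=eqtl,
        truth=truth,
        pwms=default_pwms(),
    )


def write_bundle(
    config: SimulationConfig | None, out_dir: str | Path, bundle: Bundle | None = None
) -> dict[str, str]:
    """Write the bundle as the pipeline's external file formats + manifest.

    Returns a manifest mapping logical names to file paths; a fixed seed
    yields a byte-identical file set.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if bundle is None:
        bundle = simulate_bundle(config)
    manifest: dict[str, str] = {}

    def record(key: str, filename: str) -> Path:
        manifest[key] = filename
        return out / filename

    write_gwas_tsv(bundle.variants, record("gwas", "gwas.tsv"))
    write_genes_tsv(bundle.genes, record("genes", "genes.tsv"))
    write_bed(bundle.tads, record("tads", "tads.bed"))
    write_bedpe(bundle.contacts, record("contacts", "contacts.bedpe"))
    for dataset, df in bundle.counts.items():
        write_counts(df, record(f"counts_{dataset}", f"counts_{dataset}.tsv"))
    bundle.eqtl.to_csv(record("eqtl", "eqtl.tsv"), sep="\t", index=False)
    for name, track in bundle.tracks.items():
        write_bedgraph(track, record(f"track_{name}", f"track_{name}.bedgraph"))
    enh = bundle.truth.enhancers
    write_bed(
        enh,
        record("enhancers_truth", "enhancers_truth.bed"),
        names=[
            l.locus_id for l in bundle.truth.loci for _ in l.enhancers
        ],
    )
    write_pfm(bundle.pwms, record("pwms", "pwms.pfm"))
    for chrom, seq in bundle.sequences.items():
        write_fasta({chrom: seq}, record(f"genome_{chrom}", f"genome_{chrom}.fa"))
    (out / "truth_manifest.json").write_text(bundle.truth.to_json())
    manifest["truth"] = "truth_manifest.json"
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
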