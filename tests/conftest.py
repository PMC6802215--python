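import numpy as np
import pytest
from hypothesis import settings

from relocus import enhancer_model as em
from relocus import expression as ex
from relocus import gene_scoring as gs
from relocus import variant_prioritization as vp
from relocus.synthetic_data import SimulationConfig, simulate_bundle
from relocus.variant_regions import build_regions

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def small_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A fast, reduced-scale simulation for unit tests."""
    params = dict(
        seed=seed,
        n_chromosomes=1,
        chrom_length=2_000_000,
        tad_mean_length=200_000,
        n_loci=2,
        n_genes=60,
        n_assoc_per_locus=60,
        n_background_variants=300,
    )
    params.update(overrides)
    return SimulationConfig(**params)


@pytest.fixture(scope="session")
def default_bundle():
    """The default desk-scale bundle: 2 x 10 Mb, 8 loci, 400 genes."""
    return simulate_bundle(SimulationConfig(seed=20260927))


@pytest.fixture(scope="session")
def pipeline_products(default_bundle):
    """Every downstream stage run once on the default bundle."""
    b = default_bundle
    regions = build_regions(b.variants)
    categories = ex.categorize_datasets(b.counts)
    scores = gs.score_all(regions, b.genes, b.tads, b.contacts, categories, b.eqtl)
    candidates = gs.select_candidates(scores)

    chrom_sizes = {c: b.config.chrom_length for c in b.config.chrom_names}
    enh_cfg = em.EnhancerModelConfig(seed=b.config.seed)
    features, labels, intervals = em.build_training_data(
        b.tracks, b.truth.enhancers, enh_cfg, chrom_sizes
    )
    model = em.fit_model(features, labels, enh_cfg)
    prediction = em.predict_track(model, b.tracks, enh_cfg, chrom_sizes)
    emerge_peaks = em.call_peaks(prediction, enh_cfg)
    atac_peaks = em.call_peaks(
        b.tracks["atac"], em.EnhancerModelConfig(peak_threshold=0.5)
    )

    members = {r.locus_id: list(r.members) for r in regions}
    candidate_ids = {c.gene_id for c in candidates}
    candidate_genes = [g for g in b.genes if g.gene_id in candidate_ids]
    annotations = vp.annotate_variants(
        members,
        atac_peaks,
        emerge_peaks,
        b.genes,
        b.contacts,
        candidate_genes,
        b.sequences,
        b.pwms,
    )
    tiers, tier_summary = vp.build_shortlist(annotations)
    return {
        "bundle": b,
        "regions": regions,
        "categories": categories,
        "scores": scores,
        "candidates": candidates,
        "features": features,
        "labels": labels,
        "training_intervals": intervals,
        "model": model,
        "prediction": prediction,
        "emerge_peaks": emerge_peaks,
        "atac_peaks": atac_peaks,
        "annotations": annotations,
        "tiers": tiers,
        "tier_summary": tier_summary,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
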