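"""Reference-gene normalization and 0/1/2 expression categorization.

Each of the five atrial expression datasets (adult LA, adult RA, adult LA
cardiomyocyte, fetal LA, fetal RA) is normalized to a shared set of
reference genes, summarized per gene, and binned into the categories
consumed by the gene score: 0 (below the dataset median), 1 (median up to
the third quartile, "expressed") and 2 (at or above Q3, "highly expressed").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DATASETS",
    "ExpressionConfig",
    "normalize_to_reference",
    "summarize",
    "categorize",
    "categorize_datasets",
]

DATASETS = ("adult_LA", "adult_RA", "adult_LA_CM", "fetal_LA", "fetal_RA")


@dataclass(frozen=True)
class ExpressionConfig:
    reference_gene_ids: tuple[str, ...] = ("RPL32", "RPL4", "H2AF2")
    datasets: tuple[str, ...] = DATASETS
    category_quantiles: tuple[float, float] = (0.5, 0.75)
    min_value: float | None = None  # optional expression floor, off by default

    def __post_init__(self) -> None:
        q1, q2 = self.category_quantiles
        if not (0 < q1 < q2 < 1):
            raise ValueError("category_quantiles must be strictly increasing in (0,1)")
        if not self.reference_gene_ids:
            raise ValueError("at least one reference gene is required")


def normalize_to_reference(
    counts: pd.DataFrame, config: ExpressionConfig = ExpressionConfig()
) -> pd.DataFrame:
    """Scale each sample by its reference-gene size factor.

    The per-sample factor is the geometric mean of the reference-gene counts
    in that sample (geometric, so one outlying reference cannot dominate),
    rescaled so the factors average 1; the normalized value is
    count / factor.  Raises if a reference gene is absent or has a zero
    count anywhere, naming the gene and sample.
    """
    refs = list(config.reference_gene_ids)
    missing = [g for g in refs if g not in counts.index]
    if missing:
        raise ValueError(f"reference gene(s) absent from counts: {missing}")
    ref_block = counts.loc[refs]
    zero = ref_block <= 0
    if zero.any().any():
        gene = ref_block.index[zero.any(axis=1)][0]
        sample = ref_block.columns[zero.any(axis=0)][0]
        raise ValueError(
            f"reference gene {gene!r} has zero count in sample {sample!r}"
        )
    factors = np.exp(np.log(ref_block.to_numpy(dtype=float)).mean(axis=0))
    factors = factors / factors.mean()
    return counts / factors


def summarize(normalized: pd.DataFrame) -> pd.Series:
    """Per-gene summary value: mean of normalized values across samples."""
    return normalized.mean(axis=1)


def categorize(
    summaries: pd.Series, config: ExpressionConfig = ExpressionConfig()
) -> tuple[pd.Series, float, float]:
    """Bin per-gene summaries into categories 0/1/2 for one dataset.

    Thresholds (median and Q3 by default, linear-interpolation quantiles)
    are computed over ALL genes in the table; boundary ties resolve upward,
    so a value equal to a threshold earns the higher category.
    Returns (categories, median_threshold, q3_threshold).
    """
    if len(summaries) < 4:
        raise ValueError("need >= 4 genes to define quantile thresholds")
    values = summaries.to_numpy(dtype=float)
    if config.min_value is not None:
        values = np.where(values < config.min_value, 0.0, values)
    q_lo, q_hi = config.category_quantiles
    lo = float(np.quantile(values, q_lo))
    hi = float(np.quantile(values, q_hi))
    cats = np.zeros(len(values), dtype=int)
    cats[values >= lo] = 1
    cats[values >= hi] = 2
    return pd.Series(cats, index=summaries.index), lo, hi


def categorize_datasets(
    counts_by_dataset: Mapping[str, pd.DataFrame],
    config: ExpressionConfig = ExpressionConfig(),
) -> pd.DataFrame:
    """Normalize, summarize and categorize every dataset.

    Returns a table indexed by gene with, per dataset, the normalized
    summary value (``<dataset>_value``) and the category (``<dataset>``).
    Genes absent from a dataset get category 0 there.
    """
    all_genes: list[str] = []
    for name in config.datasets:
        if name not in counts_by_dataset:
            raise ValueError(f"missing counts for dataset {name!r}")
        for g in counts_by_dataset[name].index:
            if g not in all_genes:
                all_genes.append(g)
    out = pd.DataFrame(index=pd.Index(all_genes, name="gene_id"))
    for name in config.datasets:
        normalized = normalize_to_reference(counts_by_dataset[name], config)
        summaries = summarize(normalized)
        cats, _, _ = categorize(summaries, config)
        out[f"{name}_value"] = summaries.reindex(out.index).fillna(0.0)
        out[name] = cats.reindex(out.index).fillna(0).astype(int)
    return out
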