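"""Independent brute-force oracles used by unit and conformance tests.

Every function here re-derives a quantity by exhaustive or per-base
computation, sharing no code path with the implementation it checks.
"""

import math

import numpy as np

_BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def cluster_regions_bruteforce(variants, p_core, gap_bp):
    """O(n^2) transitive clustering of significant variants.

    Returns a list of clusters, each a list of variants, grouped per
    chromosome by repeated pairwise merging (no sorting-based shortcut).
    """
    sig = [v for v in variants if v.pvalue < p_core]
    clusters = [[v] for v in sig]
    changed = True
    while changed:
        changed = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                close = any(
                    a.chrom == b.chrom and abs(a.pos - b.pos) <= gap_bp
                    for a in clusters[i]
                    for b in clusters[j]
                )
                if close:
                    clusters[i] = clusters[i] + clusters[j]
                    del clusters[j]
                    changed = True
                    break
            if changed:
                break
    return clusters


def extend_bruteforce(core_lo, core_hi, chrom, variants, p_extend, gap_bp):
    """Chained boundary extension by repeated full scans (1-based bounds)."""
    lo, hi = core_lo, core_hi
    while True:
        cand = [
            v.pos
            for v in variants
            if v.chrom == chrom
            and v.pvalue < p_extend
            and (lo - gap_bp <= v.pos < lo or hi < v.pos <= hi + gap_bp)
        ]
        if not cand:
            return lo, hi
        lo = min([lo] + cand)
        hi = max([hi] + cand)


def peaks_bruteforce(track, threshold):
    """Per-base scan: maximal runs of bases with value strictly > threshold."""
    peaks = []
    for chrom in track.chroms:
        extent = track.extent(chrom)
        values = np.array([track.value_at(chrom, p) for p in range(extent)])
        above = values > threshold
        start = None
        for p in range(extent + 1):
            if p < extent and above[p]:
                if start is None:
                    start = p
            elif start is not None:
                peaks.append((chrom, start, p))
                start = None
    return peaks


def motif_best_scores_bruteforce(sequence, pos0, ref, alt, pwm, pseudocount=0.5):
    """Exhaustive per-allele maxima over all offsets x strands covering pos0."""
    L = pwm.matrix.shape[1]
    probs = pwm.matrix + pseudocount
    probs = probs / probs.sum(axis=0)
    lo = {
        (base, j): math.log2(probs[_BASES.index(base), j] / pwm.background[_BASES.index(base)])
        for j in range(L)
        for base in _BASES
    }

    def score(window):
        return sum(lo[(b, j)] for j, b in enumerate(window) if b in _BASES)

    out = {}
    for name, allele in (("ref", ref), ("alt", alt)):
        seq = sequence[:pos0] + allele + sequence[pos0 + 1 :]
        best = -math.inf
        for start in range(max(0, pos0 - L + 1), min(pos0, len(seq) - L) + 1):
            window = seq[start : start + L]
            rc = "".join(_COMP.get(b, "N") for b in reversed(window))
            best = max(best, score(window), score(rc))
        out[name] = best
    return out["ref"], out["alt"]


def auroc_by_pair_counting(scores, labels):
    """AUROC as the fraction of concordant positive/negative pairs (ties 1/2)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def tag_counts_bruteforce(variants, peaks):
    """Per-variant max peak value via a literal base -> value map."""
    base_value = {}
    for p in peaks:
        for b in range(p.interval.start, p.interval.end):
            key = (p.interval.chrom, b)
            base_value[key] = max(base_value.get(key, 0.0), p.max_value)
    return [base_value.get((v.chrom, v.pos - 1), 0.0) for v in variants]
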