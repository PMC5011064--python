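"""Meta-exon construction and expression normalization.

The quantification unit is the meta-exon: the interval union of all
overlapping (or bookended) annotated exons of a gene. Counts are corrected
for sequencing depth by scaling each sample to the median number of
well-mapped reads, exons quantified in more than a configurable fraction of
individuals are retained, and expression is rank-based inverse normal
transformed (INT) before modelling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix, MetaExon


def merge_meta_exons(exons: list[MetaExon]) -> list[MetaExon]:
    """Merge each gene's exons into pairwise non-overlapping meta-exons.

    Intervals that overlap by at least one base, or are bookended (next start
    == end + 1), are unioned per gene. Output is sorted by gene, then start.
    """
    by_gene: dict[str, list[MetaExon]] = {}
    for ex in exons:
        by_gene.setdefault(ex.gene_id, []).append(ex)
    merged: list[MetaExon] = []
    for gene_id in sorted(by_gene):
        ivs = sorted(by_gene[gene_id], key=lambda e: (e.chromosome, e.start, e.end))
        cur = ivs[0]
        cur_start, cur_end = cur.start, cur.end
        for ex in ivs[1:]:
            if ex.chromosome == cur.chromosome and ex.start <= cur_end + 1:
                cur_end = max(cur_end, ex.end)
            else:
                merged.append(MetaExon(gene_id, cur.chromosome, cur_start, cur_end, cur.strand))
                cur, cur_start, cur_end = ex, ex.start, ex.end
        merged.append(MetaExon(gene_id, cur.chromosome, cur_start, cur_end, cur.strand))
    return merged


def normalize_depth(matrix: ExpressionMatrix, well_mapped_reads: pd.Series) -> ExpressionMatrix:
    """Scale each sample's counts by median(depths) / depth_sample.

    A sample sequenced at exactly the median depth is unchanged; zeros stay
    zero.
    """
    matrix.require_state("raw")
    depths = well_mapped_reads.reindex(matrix.sample_ids)
    if depths.isna().any():
        missing = list(depths.index[depths.isna()])[:5]
        raise ValueError(f"missing depth for samples {missing}")
    if (depths <= 0).any():
        raise ValueError("sequencing depths must all be > 0")
    scale = depths.median() / depths
    return matrix.advance(matrix.values * scale, "depth_normalized")


def filter_expressed(matrix: ExpressionMatrix, min_fraction: float = 0.90) -> ExpressionMatrix:
    """Retain meta-exons quantified (nonzero) in strictly more than
    ``min_fraction`` of samples."""
    if not 0.0 < min_fraction <= 1.0:
        raise ValueError("min_fraction must lie in (0, 1]")
    matrix.require_state("raw", "depth_normalized")
    frac = (matrix.values != 0).mean(axis=1)
    keep = frac > min_fraction
    dropped = matrix.values.index[~keep]
    result = matrix.advance(matrix.values.loc[keep], "filtered")
    result.dropped_meta_exons = list(dropped)  # type: ignore[attr-defined]
    return result


def inverse_normal_transform(values: np.ndarray | pd.Series, offset: str = "rankit") -> np.ndarray:
    """Rank-based inverse normal transform of one vector.

    Maps average ranks r (ties averaged) to normal quantiles. The default
    rankit convention uses Phi^-1((r - 0.5) / n); ``offset='blom'`` uses
    Phi^-1((r - 3/8) / (n + 1/4)). Missing entries stay missing and are
    excluded from n.
    """
    arr = np.asarray(values, dtype=float)
    out = np.full(arr.shape, np.nan)
    ok = ~np.isnan(arr)
    x = arr[ok]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 non-missing values")
    if np.all(x == x[0]):
        raise ValueError("degenerate input: all values identical")
    ranks = stats.rankdata(x, method="average")
    if offset == "rankit":
        q = (ranks - 0.5) / n
    elif offset == "blom":
        q = (ranks - 0.375) / (n + 0.25)
    else:
        raise ValueError(f"unknown INT offset {offset!r}")
    out[ok] = stats.norm.ppf(q)
    return out


def int_transform_matrix(matrix: ExpressionMatrix, offset: str = "rankit") -> ExpressionMatrix:
    """Apply the inverse normal transform to every meta-exon (row)."""
    matrix.require_state("filtered")
    vals = matrix.values.to_numpy(dtype=float)
    out = np.empty_like(vals)
    for i in range(vals.shape[0]):
        out[i] = inverse_normal_transform(vals[i], offset=offset)
    return matrix.advance(
        pd.DataFrame(out, index=matrix.meta_exon_ids, columns=matrix.sample_ids),
        "int_transformed",
    )


def assign_reads_to_meta_exons(read_ends: pd.DataFrame, meta_exons: list[MetaExon]) -> pd.Series:
    """Count fragments per meta-exon: a fragment is assigned if either aligned
    end coordinate falls within [start, end].

    ``read_ends`` needs columns ``chromosome``, ``start``, ``end`` (1-based
    inclusive aligned end coordinates of the fragment).
    """
    counts = pd.Series(0, index=[m.meta_exon_id for m in meta_exons], dtype=int)
    by_chrom: dict[str, list[MetaExon]] = {}
    for m in meta_exons:
        by_chrom.setdefault(m.chromosome, []).append(m)
    for _, row in read_ends.iterrows():
        for m in by_chrom.get(row["chromosome"], ()):
            if m.start <= row["start"] <= m.end or m.start <= row["end"] <= m.end:
                counts[m.meta_exon_id] += 1
    return counts
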