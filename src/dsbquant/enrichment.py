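"""Fragile-region detection and annotation-enrichment testing.

Fragile regions are genomic windows with significantly more break-labeled
reads in a treated than a control sample, judged by a one-sided
hypergeometric test with Benjamini-Hochberg correction (q < 0.05).
Feature enrichment inside fragile regions is the ratio of the mappable-
nucleotide fraction of the regions overlapping the annotation to the
same fraction for the whole (mappable) genome, with an empirical p-value
from length-preserving uniform re-placement of the regions within
mappable space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import Genome, GenomicInterval, ReadSet

__all__ = [
    "EnrichmentResult",
    "fragile_regions",
    "annotation_enrichment",
]


@dataclass
class EnrichmentResult:
    annotation: str
    ratio: float
    p_value: float
    n_permutations: int
    observed_overlap: int
    region_nt: int
    annotation_fraction: float


def _merge_intervals(ivs: list[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    out: list[tuple[str, int, int]] = []
    for chrom, s, e in sorted(ivs):
        if out and out[-1][0] == chrom and s <= out[-1][2]:
            out[-1] = (chrom, out[-1][1], max(out[-1][2], e))
        else:
            out.append((chrom, s, e))
    return out


def fragile_regions(
    treated: ReadSet,
    control: ReadSet,
    genome: Genome,
    window: int = 5000,
    mappable: list[GenomicInterval] | None = None,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Windows with significant treated-over-control read enrichment.

    Each window draws its (treated + control) reads from the pooled
    library; the one-sided tail for >= the observed treated count gives
    the p-value, corrected by Benjamini-Hochberg across windows.  Fold
    changes are computed on depth-normalized counts.
    """
    if len(control) == 0:
        raise ValueError("empty control sample")
    t_pos, t_chrom = treated.five_prime(), treated.df["chrom"].to_numpy()
    c_pos, c_chrom = control.five_prime(), control.df["chrom"].to_numpy()

    if mappable:
        windows = []
        for iv in mappable:
            for s in range(iv.start, iv.end, window):
                windows.append((iv.chrom, s, min(s + window, iv.end)))
    else:
        windows = []
        for chrom in genome:
            L = genome.lengths[chrom]
            for s in range(0, L, window):
                windows.append((chrom, s, min(s + window, L)))

    rows = []
    by_chrom_t = {c: np.sort(t_pos[t_chrom == c]) for c in genome}
    by_chrom_c = {c: np.sort(c_pos[c_chrom == c]) for c in genome}
    for chrom, s, e in windows:
        tp = by_chrom_t.get(chrom, np.empty(0))
        cp = by_chrom_c.get(chrom, np.empty(0))
        nt = int(np.searchsorted(tp, e) - np.searchsorted(tp, s))
        nc = int(np.searchsorted(cp, e) - np.searchsorted(cp, s))
        rows.append((chrom, s, e, nt, nc))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "treatment_count", "control_count"])

    T = int(df["treatment_count"].sum())
    C = int(df["control_count"].sum())
    N = T + C
    n_draw = (df["treatment_count"] + df["control_count"]).to_numpy()
    k = df["treatment_count"].to_numpy()
    p = stats.hypergeom.sf(k - 1, N, T, n_draw) if N > 0 and T > 0 else np.ones(len(df))
    df["p_value"] = p
    _, q, _, _ = multipletests(p, method="fdr_bh")
    df["q_value"] = q
    depth_ratio = C / T if T > 0 else np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        df["fold_change"] = np.where(
            df["control_count"] > 0,
            df["treatment_count"] * depth_ratio / df["control_count"],
            np.inf,
        )
        df.loc[(df["control_count"] == 0) & (df["treatment_count"] == 0), "fold_change"] = np.nan
    df["significant"] = df["q_value"] < q_threshold
    return df


class _MappableSpace:
    """Concatenated mappable segments as one virtual coordinate axis."""

    def __init__(self, genome: Genome, mappable: list[GenomicInterval] | None):
        if mappable is None:
            ivs = [(c, 0, genome.lengths[c]) for c in genome]
        else:
            ivs = _merge_intervals([(iv.chrom, iv.start, iv.end) for iv in mappable])
        self.segments = ivs
        lens = np.array([e - s for _, s, e in ivs], dtype=np.int64)
        self.offsets = np.concatenate([[0], np.cumsum(lens)])
        self.total = int(self.offsets[-1])

    def project(self, intervals: list[tuple[str, int, int]]) -> list[tuple[int, int]]:
        """Map genomic intervals to virtual coordinates, clipping to mappable."""
        out = []
        for vi, (chrom, s0, e0) in enumerate(self.segments):
            off = int(self.offsets[vi])
            for c, s, e in intervals:
                if c != chrom:
                    continue
                a, b = max(s, s0), min(e, e0)
                if a < b:
                    out.append((off + (a - s0), off + (b - s0)))
        return sorted(out)


def _overlap_length(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> int:
    """Total overlap of two sorted, merged virtual-interval lists."""
    total = 0
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo < hi:
            total += hi - lo
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return total


def _merge_virtual(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def annotation_enrichment(
    regions: list[GenomicInterval],
    annotation: list[GenomicInterval],
    genome: Genome,
    mappable: list[GenomicInterval] | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    annotation_name: str = "annotation",
) -> EnrichmentResult:
    """Enrichment of an annotation inside a set of regions.

    ratio = (mappable nt of regions inside the annotation / mappable nt
    of regions) / (mappable nt of the annotation / mappable genome).
    The null re-places each region, length preserved, uniformly within
    mappable space ``n_perm`` times; the empirical p-value is
    (1 + #null >= observed) / (1 + n_perm), never below 1/(1 + n_perm).
    """
    space = _MappableSpace(genome, mappable)
    if space.total == 0:
        raise ValueError("no mappable space")
    ann_v = _merge_virtual(space.project([(iv.chrom, iv.start, iv.end) for iv in annotation]))
    ann_len = sum(e - s for s, e in ann_v)
    if ann_len == 0:
        raise ValueError("annotation has no mappable overlap")
    ann_fraction = ann_len / space.total

    reg_v = space.project([(iv.chrom, iv.start, iv.end) for iv in regions])
    reg_lens = [e - s for s, e in reg_v]
    reg_total = sum(reg_lens)
    if reg_total == 0:
        raise ValueError("regions have no mappable overlap")
    if max(reg_lens) > space.total:
        raise ValueError("a region is longer than the mappable space")

    def ratio_of(placed: list[tuple[int, int]], total_nt: int) -> float:
        ov = _overlap_length(_merge_virtual(placed), ann_v)
        return (ov / total_nt) / ann_fraction

    observed_overlap = _overlap_length(_merge_virtual(reg_v), ann_v)
    observed = (observed_overlap / reg_total) / ann_fraction

    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(21,)))
    lens = np.array(reg_lens, dtype=np.int64)
    hits = 0
    for _ in range(n_perm):
        starts = rng.integers(0, np.maximum(space.total - lens, 1))
        placed = list(zip(starts.tolist(), (starts + lens).tolist()))
        if ratio_of(placed, reg_total) >= observed:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return EnrichmentResult(
        annotation=annotation_name,
        ratio=float(observed),
        p_value=float(p),
        n_permutations=n_perm,
        observed_overlap=observed_overlap,
        region_nt=reg_total,
        annotation_fraction=float(ann_fraction),
    )
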