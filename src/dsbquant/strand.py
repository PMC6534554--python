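"""One-ended DSB detection from Watson/Crick read imbalance.

A two-ended break labels both strands around the break point; a broken
replication fork exposes a single double-strand end and therefore labels
only one strand.  The genome is tiled into non-overlapping windows
(500 nt by default) and each window's Watson count is tested against the
genome-wide strand composition with a one-sided hypergeometric test
(both polarities), Bonferroni-corrected over windows x 2 tests.  The
Watson-Crick difference in called windows, divided by the spike-in
calibration alpha, quantifies one-ended DSBs per cell.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import Genome, GenomicInterval, ReadSet

__all__ = [
    "window_strand_counts",
    "one_ended_test",
    "merge_called_windows",
    "quantify_one_ended",
]


def window_strand_counts(
    reads: ReadSet,
    genome: Genome,
    window: int = 500,
    drop_empty: bool = False,
) -> pd.DataFrame:
    """Non-overlapping tiling with per-strand 5'-end counts (W, C)."""
    pos5 = reads.five_prime()
    chroms = reads.df["chrom"].to_numpy()
    plus = (reads.df["strand"] == "+").to_numpy()
    frames = []
    for chrom in genome:
        L = genome.lengths[chrom]
        starts = np.arange(0, L, window, dtype=np.int64)
        ends = np.minimum(starts + window, L)
        sel = chroms == chrom
        wp = np.sort(pos5[sel & plus])
        cp = np.sort(pos5[sel & ~plus])
        W = np.searchsorted(wp, ends) - np.searchsorted(wp, starts)
        C = np.searchsorted(cp, ends) - np.searchsorted(cp, starts)
        frames.append(
            pd.DataFrame({"chrom": chrom, "start": starts, "end": ends, "W": W, "C": C})
        )
    df = pd.concat(frames, ignore_index=True)
    if drop_empty:
        df = df[(df["W"] + df["C"]) > 0].reset_index(drop=True)
    return df


def one_ended_test(
    windows: pd.DataFrame,
    totals_w: int | None = None,
    totals_c: int | None = None,
    p_threshold: float = 1e-10,
    threshold_after_correction: bool = True,
) -> pd.DataFrame:
    """Call strand-polarized windows against the genome-wide composition.

    The null urn holds all reads with all Watson reads as successes; a
    window drawing (W + C) reads is tested one-sided for Watson
    enrichment and, symmetrically, for Crick enrichment.  Bonferroni
    multiplies by (number of windows) * 2.  ``threshold_after_correction``
    applies ``p_threshold`` to the corrected value (the default); set it
    False to threshold the raw p-value instead.
    """
    df = windows.copy()
    W = df["W"].to_numpy(dtype=np.int64)
    C = df["C"].to_numpy(dtype=np.int64)
    K = int(totals_w) if totals_w is not None else int(W.sum())
    Kc = int(totals_c) if totals_c is not None else int(C.sum())
    N = K + Kc
    if N <= 0:
        raise ValueError("strand totals must be positive")
    n = W + C
    # evaluate the tail only once per distinct (count, draw) pair; the
    # survival function is expensive and windows repeat combinations
    def _sf(k: np.ndarray, good: int, draw: np.ndarray) -> np.ndarray:
        pairs = np.stack([k, draw], axis=1)
        uniq, inverse = np.unique(pairs, axis=0, return_inverse=True)
        vals = stats.hypergeom.sf(uniq[:, 0] - 1, N, good, uniq[:, 1])
        return vals[inverse]

    p_w = _sf(W, K, n)
    p_c = _sf(C, Kc, n)
    m = 2 * len(df)
    df["p_watson"] = p_w
    df["p_crick"] = p_c
    df["p_value"] = np.minimum(p_w, p_c)
    df["corrected_p"] = np.minimum(df["p_value"] * m, 1.0)
    tested = df["corrected_p"] if threshold_after_correction else df["p_value"]
    call = np.where(
        tested < p_threshold,
        np.where(p_w <= p_c, "watson_one_ended", "crick_one_ended"),
        "balanced",
    )
    # a window with no reads is never a call
    call[n == 0] = "balanced"
    df["call"] = call
    return df


def merge_called_windows(called: pd.DataFrame) -> pd.DataFrame:
    """Merge adjacent significant windows of the same polarity.

    Splitting one broken fork across window boundaries would double-count
    it; merged regions carry summed W and C.
    """
    sig = called[called["call"] != "balanced"].sort_values(["chrom", "start"])
    rows = []
    prev = None
    for row in sig.itertuples(index=False):
        if (
            prev is not None
            and row.chrom == prev["chrom"]
            and row.call == prev["call"]
            and row.start == prev["end"]
        ):
            prev["end"] = row.end
            prev["W"] += row.W
            prev["C"] += row.C
            prev["corrected_p"] = min(prev["corrected_p"], row.corrected_p)
        else:
            if prev is not None:
                rows.append(prev)
            prev = {
                "chrom": row.chrom,
                "start": row.start,
                "end": row.end,
                "W": row.W,
                "C": row.C,
                "call": row.call,
                "corrected_p": row.corrected_p,
            }
    if prev is not None:
        rows.append(prev)
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "W", "C", "call", "corrected_p"]
    )


def quantify_one_ended(
    called: pd.DataFrame,
    alpha: float,
    annotations: list[GenomicInterval] | None = None,
    merge: bool = True,
) -> dict:
    """One-ended DSBs per cell from called windows: sum |W - C| / alpha.

    With ``annotations`` (e.g. +/-10 kb around replication origins) also
    reports the total restricted to regions overlapping an annotation.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    regions = merge_called_windows(called) if merge else called[called["call"] != "balanced"]
    if len(regions) == 0:
        return {
            "total_per_cell": 0.0,
            "n_regions": 0,
            "in_annotation_per_cell": 0.0 if annotations is not None else None,
            "regions": regions,
        }
    diff = np.abs(regions["W"].to_numpy() - regions["C"].to_numpy())
    total = float(diff.sum() / alpha)
    in_ann = None
    if annotations is not None:
        hit = np.zeros(len(regions), dtype=bool)
        starts = regions["start"].to_numpy()
        ends = regions["end"].to_numpy()
        chroms = regions["chrom"].to_numpy()
        for iv in annotations:
            hit |= (chroms == iv.chrom) & (starts < iv.end) & (ends > iv.start)
        in_ann = float(diff[hit].sum() / alpha)
    return {
        "total_per_cell": total,
        "n_regions": int(len(regions)),
        "in_annotation_per_cell": in_ann,
        "regions": regions,
    }
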