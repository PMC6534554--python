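"""Absolute DSB quantification via spike-in normalization.

The spike-in break frequency per cell is B_cut = f_cut * N_sites * p,
where p is the proportion of digested cells.  The labeled reads observed
at the cutting sites, R_cut, then calibrate the reads-per-break
coefficient alpha = R_cut / B_cut, and the studied breaks per cell follow
as B_studied = R_studied / alpha, with R_studied the labeled reads left
after removing spike-in, telomeric and masked reads.  Because alpha and
R_studied scale together with sequencing depth, the estimate is
depth-invariant in expectation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CutSite, Genome, GenomicInterval, ReadSet, reverse_complement

__all__ = [
    "SpikeInDesign",
    "QuantResult",
    "FilterAudit",
    "TELOMERE_PATTERN",
    "is_telomeric_sequence",
    "spike_in_breaks",
    "count_reads_at_sites",
    "filter_studied_reads",
    "quantify",
    "per_site_sd",
    "propagated_sd",
    "window_density",
    "remove_replication_background",
    "compare_samples_poisson",
]

#: Whole-read AC-rich telomere rule: one or more repeats of C{0,3}AC{1,10}.
TELOMERE_PATTERN = re.compile(r"(?:C{0,3}AC{1,10})+")


@dataclass
class SpikeInDesign:
    """Spike-in digestion design used to calibrate alpha."""

    sites: list[CutSite]
    p: float = 1.0
    enzyme_name: str = ""

    def __post_init__(self):
        if not 0 < self.p <= 1:
            raise ValueError("proportion of digested cells p must be in (0, 1]")

    @property
    def n_sites(self) -> int:
        return len(self.sites)


@dataclass
class QuantResult:
    b_cut: float
    r_cut: float
    alpha: float
    r_studied: float
    b_studied: float
    sd_b: float = float("nan")
    sd_method: str = ""


@dataclass
class FilterAudit:
    n_input: int
    removed_at_sites: int
    removed_telomeric: int
    removed_masked: int
    r_studied: int
    retained: ReadSet

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "category": ["input", "spike_in_sites", "telomeric", "masked", "studied"],
                "reads": [
                    self.n_input,
                    self.removed_at_sites,
                    self.removed_telomeric,
                    self.removed_masked,
                    self.r_studied,
                ],
            }
        )


def spike_in_breaks(f_cut: float, n_sites: int, p: float = 1.0) -> float:
    """Spike-in DSBs per cell: B_cut = f_cut * N_sites * p."""
    if p <= 0:
        raise ValueError("proportion of digested cells p must be positive")
    if not 0 <= f_cut <= 1:
        raise ValueError("f_cut must lie in [0, 1]")
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    return float(f_cut * n_sites * p)


def _site_assignment_mask(
    reads: ReadSet, sites: list[CutSite], w: int
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean mask of reads at sites and the per-read site index (-1 = none).

    A read belongs to a site when its 5' end lies within
    [cut_pos - w, cut_pos + w]; each read goes to at most one site (the
    nearest; ties break toward the lower coordinate).
    """
    pos5 = reads.five_prime()
    chroms = reads.df["chrom"].to_numpy()
    mask = np.zeros(len(reads), dtype=bool)
    site_idx = np.full(len(reads), -1, dtype=np.int64)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for i, s in enumerate(sites):
        by_chrom.setdefault(s.chrom, []).append((s.cut_pos, i))
    for chrom, pairs in by_chrom.items():
        pairs.sort()
        cuts = np.array([c for c, _ in pairs], dtype=np.int64)
        idxs = np.array([i for _, i in pairs], dtype=np.int64)
        sel = np.flatnonzero(chroms == chrom)
        if len(sel) == 0:
            continue
        p = pos5[sel]
        right = np.searchsorted(cuts, p, side="left")
        left = right - 1
        d_left = np.where(left >= 0, np.abs(p - cuts[np.clip(left, 0, None)]), np.iinfo(np.int64).max)
        d_right = np.where(
            right < len(cuts), np.abs(cuts[np.clip(right, None, len(cuts) - 1)] - p), np.iinfo(np.int64).max
        )
        use_left = d_left <= d_right  # tie -> lower coordinate
        nearest = np.where(use_left, np.clip(left, 0, None), np.clip(right, None, len(cuts) - 1))
        dist = np.where(use_left, d_left, d_right)
        hit = dist <= w
        mask[sel[hit]] = True
        site_idx[sel[hit]] = idxs[nearest[hit]]
    return mask, site_idx


def count_reads_at_sites(
    reads: ReadSet, sites: list[CutSite], w: int = 3, per_site: bool = False
):
    """R_cut: labeled reads whose 5' end falls in a site vicinity.

    With ``per_site=True`` also returns the count for each site in input
    order.
    """
    mask, site_idx = _site_assignment_mask(reads, sites, w)
    total = int(mask.sum())
    if not per_site:
        return total
    counts = np.bincount(site_idx[mask], minlength=len(sites))
    return total, counts


def is_telomeric_sequence(seq: str | None) -> bool:
    """Whole-read match of the AC-rich telomere rule, either orientation."""
    if not seq:
        return False
    return bool(
        TELOMERE_PATTERN.fullmatch(seq)
        or TELOMERE_PATTERN.fullmatch(reverse_complement(seq))
    )


def _in_intervals_mask(reads: ReadSet, intervals: list[GenomicInterval]) -> np.ndarray:
    mask = np.zeros(len(reads), dtype=bool)
    if not intervals:
        return mask
    pos5 = reads.five_prime()
    chroms = reads.df["chrom"].to_numpy()
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom, ivs in by_chrom.items():
        sel = chroms == chrom
        p = pos5[sel]
        hit = np.zeros(len(p), dtype=bool)
        for iv in ivs:
            hit |= (p >= iv.start) & (p < iv.end)
        mask[np.flatnonzero(sel)[hit]] = True
    return mask


def filter_studied_reads(
    reads: ReadSet,
    sites: list[CutSite],
    w: int = 3,
    telomere_filter: bool = True,
    masks: list[GenomicInterval] | None = None,
) -> FilterAudit:
    """Remove spike-in, telomeric and masked reads; count the remainder.

    Removal categories are disjoint with priority site > telomere > mask,
    so the audit counts sum exactly to input - studied.
    """
    n = len(reads)
    at_sites, _ = _site_assignment_mask(reads, sites, w)
    if telomere_filter:
        seqs = reads.df["seq"].to_numpy()
        telo = np.fromiter(
            (is_telomeric_sequence(s) for s in seqs), dtype=bool, count=n
        )
    else:
        telo = np.zeros(n, dtype=bool)
    telo &= ~at_sites
    masked = _in_intervals_mask(reads, masks or [])
    masked &= ~at_sites & ~telo
    removed = at_sites | telo | masked
    retained = reads.subset(~removed)
    return FilterAudit(
        n_input=n,
        removed_at_sites=int(at_sites.sum()),
        removed_telomeric=int(telo.sum()),
        removed_masked=int(masked.sum()),
        r_studied=n - int(removed.sum()),
        retained=retained,
    )


def quantify(r_studied: float, r_cut: float, b_cut: float) -> QuantResult:
    """Convert read counts to studied DSBs per cell via alpha = R_cut/B_cut."""
    if b_cut <= 0:
        raise ValueError("B_cut must be positive (no spike-in breaks)")
    if r_cut <= 0:
        raise ValueError("no spike-in signal: R_cut must be positive")
    if r_studied < 0:
        raise ValueError("R_studied must be non-negative")
    alpha = r_cut / b_cut
    return QuantResult(
        b_cut=float(b_cut),
        r_cut=float(r_cut),
        alpha=float(alpha),
        r_studied=float(r_studied),
        b_studied=float(r_studied / alpha),
    )


def per_site_sd(
    r_cut_per_site: np.ndarray,
    f_per_site: np.ndarray,
    p: float,
    r_studied: float,
) -> tuple[float, np.ndarray]:
    """Conservative SD of B_studied from single-site quantifications.

    Each site yields an independent estimate
    B_i = R_studied * (f_i * p) / R_cut_i (one-site calibration); the
    sample SD across sites bounds the quantification uncertainty from
    above because site-to-site alpha variability is included wholesale.
    """
    r = np.asarray(r_cut_per_site, dtype=float)
    f = np.asarray(f_per_site, dtype=float)
    ok = (r > 0) & (f > 0)
    if ok.sum() < 2:
        raise ValueError("need >= 2 sites with signal for a per-site SD")
    b = r_studied * (f[ok] * p) / r[ok]
    return float(np.std(b, ddof=1)), b


def propagated_sd(b_studied: float, f_cut: float, sigma_total: float) -> float:
    """SD of B_studied propagated from the efficiency SD (quotient rule).

    B_studied is proportional to f_cut at fixed read counts, so the
    relative errors coincide.
    """
    if f_cut <= 0:
        raise ValueError("f_cut must be positive")
    return float(b_studied * sigma_total / f_cut)


def window_density(
    reads: ReadSet,
    genome: Genome,
    alpha: float,
    window: int = 500,
    step: int = 50,
    scale: str = "per_cell",
) -> pd.DataFrame:
    """Sliding-window DSB density track (chrom, start, end, value).

    Per-window labeled-read counts (5' ends, half-open windows) divided
    by alpha; ``scale='per_million_cells'`` multiplies by 1e6.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if scale not in ("per_cell", "per_million_cells"):
        raise ValueError("scale must be 'per_cell' or 'per_million_cells'")
    factor = 1.0 if scale == "per_cell" else 1e6
    pos5 = reads.five_prime()
    chroms = reads.df["chrom"].to_numpy()
    frames = []
    for chrom in genome:
        L = genome.lengths[chrom]
        if L < window:
            continue
        starts = np.arange(0, L - window + 1, step, dtype=np.int64)
        p = np.sort(pos5[chroms == chrom])
        counts = np.searchsorted(p, starts + window) - np.searchsorted(p, starts)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": starts + window,
                    "value": counts / alpha * factor,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end", "value"])
    return pd.concat(frames, ignore_index=True)


def remove_replication_background(track: pd.DataFrame) -> pd.DataFrame:
    """Subtract the modal window density; clamp negatives to zero.

    The peak (mode) of the window-value distribution is taken as the
    non-replication background level.  The mode is located with a
    histogram at Freedman-Diaconis bin width (ties toward the lowest
    bin) and refined to the median of the values inside the modal bin,
    so a discrete baseline is recovered exactly.
    """
    if len(track) == 0:
        raise ValueError("empty track")
    values = track["value"].to_numpy(dtype=float)
    uniq = np.unique(values)
    if len(uniq) == 1:
        mode = uniq[0]
    else:
        edges = np.histogram_bin_edges(values, bins="fd")
        counts, edges = np.histogram(values, bins=edges)
        k = int(np.argmax(counts))  # argmax takes the first (lowest) modal bin
        in_bin = (values >= edges[k]) & (
            values <= edges[k + 1] if k == len(counts) - 1 else values < edges[k + 1]
        )
        mode = float(np.median(values[in_bin]))
    out = track.copy()
    out["value"] = np.maximum(values - mode, 0.0)
    return out


def compare_samples_poisson(
    control: ReadSet,
    treated: ReadSet,
    genome: Genome,
    alpha_control: float,
    alpha_treated: float,
    k_sd: float = 5.0,
    window: int = 5000,
) -> pd.DataFrame:
    """Per-window induction test between two quantified samples.

    Treated counts are first rescaled to the control's read-per-break
    scale via the two alphas.  A window is flagged enriched when the
    rescaled treated count exceeds control + k_sd * sqrt(control)
    (a conservative Poisson band around the control count); a one-sided
    hypergeometric p-value with Bonferroni correction over windows is
    reported alongside.
    """
    c_pos, c_chrom = control.five_prime(), control.df["chrom"].to_numpy()
    t_pos, t_chrom = treated.five_prime(), treated.df["chrom"].to_numpy()
    rows = []
    for chrom in genome:
        L = genome.lengths[chrom]
        starts = np.arange(0, L, window, dtype=np.int64)
        ends = np.minimum(starts + window, L)
        cp = np.sort(c_pos[c_chrom == chrom])
        tp = np.sort(t_pos[t_chrom == chrom])
        cc = np.searchsorted(cp, ends) - np.searchsorted(cp, starts)
        tc = np.searchsorted(tp, ends) - np.searchsorted(tp, starts)
        for s, e, nc, nt in zip(starts, ends, cc, tc):
            rows.append((chrom, int(s), int(e), int(nc), int(nt)))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "control_count", "treated_count"])

    scale = alpha_control / alpha_treated
    df["treated_scaled"] = df["treated_count"] * scale
    df["enriched"] = df["treated_scaled"] > (
        df["control_count"] + k_sd * np.sqrt(df["control_count"])
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        df["fold_change"] = np.where(
            df["control_count"] > 0, df["treated_scaled"] / df["control_count"], np.inf
        )
        df.loc[(df["control_count"] == 0) & (df["treated_count"] == 0), "fold_change"] = np.nan

    # hypergeometric: draw the window's treated+control reads from the
    # pooled library and ask for >= the observed treated count
    T, C = int(df["treated_count"].sum()), int(df["control_count"].sum())
    N = T + C
    if N > 0 and T > 0:
        n_draw = (df["treated_count"] + df["control_count"]).to_numpy()
        k = df["treated_count"].to_numpy()
        p = stats.hypergeom.sf(k - 1, N, T, n_draw)
    else:
        p = np.ones(len(df))
    df["p_value"] = p
    df["p_bonferroni"] = np.minimum(p * len(df), 1.0)
    return df
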