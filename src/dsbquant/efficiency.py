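"""Restriction cutting-efficiency estimation from gDNA fragments or qPCR.

The molecule fraction cleaved at a site, f_cut, is estimated from
paired-end gDNA fragments as

    f_cut = N_cut / (N_cut + 2 N_uncut) - f_bg

where N_cut counts fragments with an end inside the site's counting
vicinity (a cut molecule contributes two such fragments, one per side of
the scission), N_uncut counts fragments spanning the vicinity (an intact
molecule contributes one), and f_bg is the same ratio evaluated in
randomly placed windows away from any site, absorbing sonication ends
that land in a vicinity by chance.

Uncertainty combines two components in quadrature: sigma_bg, the SD of
the per-window background ratios, and sigma_Poisson, a finite-count
term obtained by perturbing N_cut and N_uncut by one Poisson SD in
opposite directions:

    sigma_Poisson = 1/2 * [ (N_c + sqrt(N_c)) / ((N_c + sqrt(N_c)) + 2 (N_u - sqrt(N_u)))
                          - (N_c - sqrt(N_c)) / ((N_c - sqrt(N_c)) + 2 (N_u + sqrt(N_u))) ]
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CutSite, FragmentSet, Genome

__all__ = [
    "CutSiteCounts",
    "BackgroundEstimate",
    "EfficiencyEstimate",
    "classify_fragments_at_site",
    "classify_fragments",
    "site_efficiency",
    "pooled_efficiency",
    "estimate_background",
    "poisson_sd",
    "qpcr_efficiency",
    "linearity_check",
]


@dataclass(frozen=True)
class CutSiteCounts:
    site: CutSite
    n_cut: int
    n_uncut: int

    def __post_init__(self):
        if self.n_cut < 0 or self.n_uncut < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class BackgroundEstimate:
    f_bg: float
    sigma_bg: float
    n_windows: int
    window_size: int
    seed: int


@dataclass
class EfficiencyEstimate:
    f_cut: float
    sigma_poisson: float
    sigma_bg: float
    sigma_total: float
    per_site: pd.DataFrame
    n_sites_used: int


class _ChromFragments:
    """Sorted per-chromosome fragment coordinates for windowed counting."""

    def __init__(self, fragments: FragmentSet):
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self.max_len = 0
        df = fragments.df
        for chrom, grp in df.groupby("chrom", sort=False):
            s = grp["start"].to_numpy(np.int64)
            e = grp["end"].to_numpy(np.int64)
            order = np.argsort(s, kind="stable")
            self.by_chrom[chrom] = (s[order], e[order])
            if len(s):
                self.max_len = max(self.max_len, int((e - s).max()))

    def window_counts(self, chrom: str, lo: int, hi: int) -> tuple[int, int]:
        """(n_cut, n_uncut) for the vicinity [lo, hi] (inclusive).

        A fragment [start, end) is CUT when start or end lies in
        [lo, hi]; UNCUT when start < lo and end > hi.  Fragments merely
        overlapping the vicinity are ignored; cut takes priority.
        """
        if chrom not in self.by_chrom:
            return 0, 0
        starts, ends = self.by_chrom[chrom]
        # only fragments starting within max_len of the window can touch it
        a = np.searchsorted(starts, lo - self.max_len, side="left")
        b = np.searchsorted(starts, hi, side="right")
        s = starts[a:b]
        e = ends[a:b]
        cut = ((s >= lo) & (s <= hi)) | ((e >= lo) & (e <= hi))
        uncut = (s < lo) & (e > hi) & ~cut
        return int(cut.sum()), int(uncut.sum())


def classify_fragments_at_site(
    fragments: FragmentSet | _ChromFragments, site: CutSite, w: int | None = None
) -> CutSiteCounts:
    """Count cut and spanning (uncut) fragments at one restriction site."""
    if w is None:
        w = site.vicinity_w
    if w < 0:
        raise ValueError("vicinity half-width w must be >= 0")
    index = fragments if isinstance(fragments, _ChromFragments) else _ChromFragments(fragments)
    n_cut, n_uncut = index.window_counts(site.chrom, site.cut_pos - w, site.cut_pos + w)
    return CutSiteCounts(site, n_cut, n_uncut)


def classify_fragments(
    fragments: FragmentSet, sites: list[CutSite], w: int | None = None
) -> list[CutSiteCounts]:
    """Classify fragments at every site, sharing one sorted index."""
    index = _ChromFragments(fragments)
    return [classify_fragments_at_site(index, site, w) for site in sites]


def site_efficiency(counts: CutSiteCounts, f_bg: float = 0.0) -> float:
    """Background-corrected cutting efficiency at one site, clamped to [0, 1]."""
    total = counts.n_cut + counts.n_uncut
    if total == 0:
        raise ValueError("no fragments classified at site; efficiency undefined")
    raw = counts.n_cut / (counts.n_cut + 2 * counts.n_uncut) - f_bg
    return float(min(max(raw, 0.0), 1.0))


def poisson_sd(counts: CutSiteCounts) -> float:
    """Finite-count SD of the efficiency ratio under Poisson counts."""
    nc, nu = counts.n_cut, counts.n_uncut
    if nc < 1 or nu < 1:
        raise ValueError(
            "Poisson SD approximation requires N_cut >= 1 and N_uncut >= 1"
        )
    rc, ru = np.sqrt(nc), np.sqrt(nu)
    if nu - ru < 0:
        raise ValueError("counts too small for the Poisson SD approximation")
    hi = (nc + rc) / ((nc + rc) + 2 * (nu - ru))
    lo = (nc - rc) / ((nc - rc) + 2 * (nu + ru))
    return float(0.5 * (hi - lo))


def pooled_efficiency(
    all_counts: list[CutSiteCounts],
    f_bg: float | BackgroundEstimate = 0.0,
    min_reads: int = 100,
) -> EfficiencyEstimate:
    """Pool counts over sites passing depth and positivity filters.

    Sites enter the pool when (N_cut + N_uncut) > min_reads and their
    background-corrected per-site efficiency exceeds 0; counts of passing
    sites are summed before applying the single-site formula, so deep
    sites dominate.  ``per_site`` retains every site with its pass/fail
    reason.
    """
    bg = f_bg if isinstance(f_bg, BackgroundEstimate) else None
    f_bg_value = bg.f_bg if bg is not None else float(f_bg)
    sigma_bg = bg.sigma_bg if bg is not None else 0.0

    rows = []
    passing = []
    for c in all_counts:
        total = c.n_cut + c.n_uncut
        f_site = np.nan
        if total > 0:
            f_site = c.n_cut / (c.n_cut + 2 * c.n_uncut) - f_bg_value
        if total <= min_reads:
            passed, reason = False, f"<= {min_reads} fragments"
        elif not (f_site > 0):
            passed, reason = False, "efficiency <= 0"
        else:
            passed, reason = True, ""
            passing.append(c)
        rows.append(
            {
                "chrom": c.site.chrom,
                "cut_pos": c.site.cut_pos,
                "n_cut": c.n_cut,
                "n_uncut": c.n_uncut,
                "f_site": np.nan if np.isnan(f_site) else float(min(max(f_site, 0.0), 1.0)),
                "passed": passed,
                "reason": reason,
            }
        )
    per_site = pd.DataFrame(rows)
    if not passing:
        raise ValueError(
            f"no site passed the filters (> {min_reads} fragments and "
            "positive background-corrected efficiency)"
        )
    nc = sum(c.n_cut for c in passing)
    nu = sum(c.n_uncut for c in passing)
    f_pooled = float(min(max(nc / (nc + 2 * nu) - f_bg_value, 0.0), 1.0))
    if nc >= 1 and nu >= 1:
        sp = poisson_sd(CutSiteCounts(passing[0].site, nc, nu))
    else:
        sp = float("nan")
    sigma_total = float(np.sqrt(sigma_bg**2 + sp**2)) if np.isfinite(sp) else sigma_bg
    return EfficiencyEstimate(
        f_cut=f_pooled,
        sigma_poisson=sp,
        sigma_bg=sigma_bg,
        sigma_total=sigma_total,
        per_site=per_site,
        n_sites_used=len(passing),
    )


def estimate_background(
    fragments: FragmentSet,
    genome: Genome,
    window_size: int,
    n_windows: int = 1500,
    seed: int = 0,
    exclude_sites: list[CutSite] | None = None,
    exclusion_margin: int | None = None,
) -> BackgroundEstimate:
    """Chance cut-classification rate in randomly placed windows.

    Draws ``n_windows`` windows of the site-vicinity size uniformly over
    the genome, avoiding real cut-site neighborhoods (vicinity plus the
    longest observed fragment, so no enzyme-derived end can leak in), and
    averages the per-window ratio N_cut / (N_cut + 2 N_uncut); windows
    with no classified fragments contribute 0.  The SD across windows is
    sigma_bg.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    if not 1 <= n_windows:
        raise ValueError("n_windows must be positive")
    usable = [c for c in genome if genome.lengths[c] > window_size]
    if not usable:
        raise ValueError("genome shorter than window_size")
    index = _ChromFragments(fragments)
    if exclusion_margin is None:
        exclusion_margin = index.max_len + window_size
    excluded: dict[str, list[tuple[int, int]]] = {}
    for s in exclude_sites or []:
        excluded.setdefault(s.chrom, []).append(
            (s.cut_pos - exclusion_margin, s.cut_pos + exclusion_margin)
        )

    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(11,)))
    lengths = np.array([genome.lengths[c] for c in usable], dtype=float)
    probs = lengths / lengths.sum()
    half = window_size // 2
    values = np.empty(n_windows)
    got = 0
    attempts = 0
    while got < n_windows:
        attempts += 1
        if attempts > 100 * n_windows:
            raise ValueError("could not place background windows outside site exclusions")
        ci = rng.choice(len(usable), p=probs)
        chrom = usable[ci]
        center = int(rng.integers(half, genome.lengths[chrom] - half))
        if any(a <= center <= b for a, b in excluded.get(chrom, [])):
            continue
        nc, nu = index.window_counts(chrom, center - half, center + half)
        values[got] = nc / (nc + 2 * nu) if (nc + nu) > 0 else 0.0
        got += 1
    return BackgroundEstimate(
        f_bg=float(values.mean()),
        sigma_bg=float(values.std(ddof=1)) if n_windows > 1 else 0.0,
        n_windows=n_windows,
        window_size=window_size,
        seed=seed,
    )


def qpcr_efficiency(
    ct_treated: float | np.ndarray,
    ct_untreated: float | np.ndarray,
    calibration_offset: float = 0.0,
) -> float:
    """Cutting efficiency from qPCR threshold cycles: 1 - 2**(-dCT).

    dCT = CT(treated) - CT(untreated) + calibration_offset.  Arrays are
    interpreted as per-dilution replicates and the mean efficiency over
    dilutions is returned.  Negative dCT (amplification anomaly) clamps
    to 0 with a warning.
    """
    ct_t = np.atleast_1d(np.asarray(ct_treated, dtype=float))
    ct_u = np.atleast_1d(np.asarray(ct_untreated, dtype=float))
    if (ct_t <= 0).any() or (ct_u <= 0).any():
        raise ValueError("threshold cycles must be positive")
    dct = ct_t - ct_u + calibration_offset
    if (dct < 0).any():
        warnings.warn(
            "negative delta-CT clamped to 0 (amplification anomaly)",
            stacklevel=2,
        )
        dct = np.maximum(dct, 0.0)
    return float(np.mean(1.0 - 2.0 ** (-dct)))


def linearity_check(
    per_site: list[tuple[float, float]] | np.ndarray,
    r_threshold: float = 0.5,
) -> dict:
    """Pearson correlation between per-site labeled reads and efficiencies.

    A strong linear relationship (r > 0.5) indicates the proportionality
    between labeled reads and break frequency holds across sites; weak
    correlation flags an unreliable spike-in regime.
    """
    arr = np.asarray(per_site, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need >= 3 (labeled_read_count, site_efficiency) pairs")
    x, y = arr[:, 1], arr[:, 0]  # efficiency on x, reads on y
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        return {
            "r": float("nan"),
            "slope": float("nan"),
            "intercept": float("nan"),
            "weak_linearity": True,
            "n_sites": len(arr),
        }
    r, _ = stats.pearsonr(x, y)
    fit = stats.linregress(x, y)
    return {
        "r": float(r),
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "weak_linearity": bool(r <= r_threshold),
        "n_sites": len(arr),
    }
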