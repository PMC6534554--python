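"""Model/Results interface tying the estimation pipeline together.

:class:`SpikeInQuantModel` is built from the data of one experiment --
labeled reads, paired-end gDNA fragments, the genome and the spike-in
enzyme -- and ``fit()`` runs the full chain: background estimation,
cutting-efficiency pooling, alpha calibration, read filtering and
absolute quantification.  The returned :class:`SpikeInQuantResults`
carries the estimates with uncertainties, per-site detail, a
``summary()`` table, window tracks and one-ended DSB analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import efficiency as eff
from . import quantify as qt
from . import strand as st
from .io_formats import CutSite, EnzymeSpec, FragmentSet, Genome, GenomicInterval, ReadSet, find_cut_sites

__all__ = ["SpikeInQuantModel", "SpikeInQuantResults"]


class SpikeInQuantModel:
    """Absolute DSB quantification of one sample with a spike-in digest.

    Parameters
    ----------
    reads
        Break-proximal labeled reads of the sample.
    fragments
        Paired-end gDNA fragments of the matching digestion control.
    genome
        Reference genome; defines the coordinate frame.
    enzyme
        The spike-in enzyme.  Cut sites are located in silico unless
        ``sites`` is given explicitly.
    p
        Proportion of digested cells (1 for in-vitro digestion of the
        whole sample; e.g. 0.02 for a 2:98 in-vivo mix).
    vicinity_w
        Half-width in bp of the counting vicinity around each cut.
    min_reads
        Minimum classified fragments for a site to enter the efficiency
        pool.
    bg_windows
        Number of random windows for background estimation.
    masks
        Intervals (e.g. rDNA) whose reads are excluded from the studied
        count.
    """

    def __init__(
        self,
        reads: ReadSet,
        fragments: FragmentSet,
        genome: Genome,
        enzyme: EnzymeSpec | None = None,
        sites: list[CutSite] | None = None,
        p: float = 1.0,
        vicinity_w: int = 3,
        min_reads: int = 100,
        bg_windows: int = 1500,
        masks: list[GenomicInterval] | None = None,
        telomere_filter: bool = True,
        seed: int = 0,
    ):
        if sites is None:
            if enzyme is None:
                raise ValueError("provide an enzyme or explicit cut sites")
            sites = find_cut_sites(genome, enzyme, vicinity_w)
        if not sites:
            raise ValueError("no spike-in cut sites in the genome")
        self.reads = reads
        self.fragments = fragments
        self.genome = genome
        self.enzyme = enzyme
        self.sites = sites
        self.p = p
        self.w = vicinity_w
        self.min_reads = min_reads
        self.bg_windows = bg_windows
        self.masks = masks or []
        self.telomere_filter = telomere_filter
        self.seed = seed

    @classmethod
    def from_files(
        cls,
        reads_path: str,
        fragments_path: str,
        genome_path: str,
        enzyme: EnzymeSpec,
        reads_format: str = "BED",
        fragments_format: str = "BED",
        **kwargs,
    ) -> "SpikeInQuantModel":
        from .io_formats import read_fasta, read_intervals

        genome = read_fasta(genome_path)
        reads = read_intervals(reads_path, reads_format, kind="reads", genome=genome)
        fragments = read_intervals(
            fragments_path, fragments_format, kind="fragments", genome=genome
        )
        return cls(reads, fragments, genome, enzyme, **kwargs)

    def fit(self) -> "SpikeInQuantResults":
        counts = eff.classify_fragments(self.fragments, self.sites, self.w)
        background = eff.estimate_background(
            self.fragments,
            self.genome,
            window_size=2 * self.w + 1,
            n_windows=self.bg_windows,
            seed=self.seed,
            exclude_sites=self.sites,
        )
        efficiency = eff.pooled_efficiency(counts, background, self.min_reads)
        b_cut = qt.spike_in_breaks(efficiency.f_cut, len(self.sites), self.p)
        r_cut, r_cut_per_site = qt.count_reads_at_sites(
            self.reads, self.sites, self.w, per_site=True
        )
        audit = qt.filter_studied_reads(
            self.reads,
            self.sites,
            self.w,
            telomere_filter=self.telomere_filter,
            masks=self.masks,
        )
        quant = qt.quantify(audit.r_studied, r_cut, b_cut)

        per_site = efficiency.per_site.copy()
        per_site["r_cut"] = r_cut_per_site
        passed = per_site["passed"].to_numpy()
        sd_method = "per_site"
        try:
            if passed.sum() < 2:
                raise ValueError("fewer than 2 passing sites")
            sd_b, b_per_site = qt.per_site_sd(
                per_site.loc[passed, "r_cut"].to_numpy(),
                per_site.loc[passed, "f_site"].to_numpy(),
                self.p,
                audit.r_studied,
            )
            per_site.loc[passed, "b_studied_site"] = b_per_site
        except ValueError:
            sd_b = qt.propagated_sd(
                quant.b_studied, efficiency.f_cut, efficiency.sigma_total
            )
            sd_method = "propagated"
        quant.sd_b = sd_b
        quant.sd_method = sd_method

        return SpikeInQuantResults(
            model=self,
            efficiency=efficiency,
            background=background,
            quant=quant,
            audit=audit,
            per_site=per_site,
        )


@dataclass
class SpikeInQuantResults:
    """Estimates, uncertainties and diagnostics of one quantification."""

    model: SpikeInQuantModel
    efficiency: eff.EfficiencyEstimate
    background: eff.BackgroundEstimate
    quant: qt.QuantResult
    audit: qt.FilterAudit
    per_site: pd.DataFrame
    _one_ended_cache: dict = field(default_factory=dict, repr=False)

    # -- convenience accessors -------------------------------------------
    @property
    def f_cut(self) -> float:
        return self.efficiency.f_cut

    @property
    def alpha(self) -> float:
        return self.quant.alpha

    @property
    def b_studied(self) -> float:
        return self.quant.b_studied

    @property
    def sd_b(self) -> float:
        return self.quant.sd_b

    # -- analyses hanging off the fit ------------------------------------
    def window_track(
        self, window: int = 500, step: int = 50, scale: str = "per_cell",
        remove_background: bool = False,
    ) -> pd.DataFrame:
        track = qt.window_density(
            self.audit.retained, self.model.genome, self.alpha, window, step, scale
        )
        if remove_background:
            track = qt.remove_replication_background(track)
        return track

    def one_ended(
        self,
        window: int = 500,
        p_threshold: float = 1e-10,
        annotations: list[GenomicInterval] | None = None,
    ) -> dict:
        key = (window, p_threshold, id(annotations))
        if key not in self._one_ended_cache:
            counts = st.window_strand_counts(
                self.audit.retained, self.model.genome, window
            )
            called = st.one_ended_test(counts, p_threshold=p_threshold)
            self._one_ended_cache[key] = st.quantify_one_ended(
                called, self.alpha, annotations
            )
        return self._one_ended_cache[key]

    def linearity(self) -> dict:
        pairs = self.per_site.loc[
            self.per_site["passed"], ["r_cut", "f_site"]
        ].to_numpy()
        return eff.linearity_check(pairs)

    def plot_track(self, chrom: str, window: int = 500, step: int = 50, ax=None):
        """Quantified break-density profile along one chromosome."""
        import matplotlib.pyplot as plt

        track = self.window_track(window, step, scale="per_million_cells")
        sub = track[track["chrom"] == chrom]
        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        ax.fill_between(sub["start"], sub["value"], step="post", lw=0)
        ax.set_xlabel(f"{chrom} position (bp)")
        ax.set_ylabel("DSBs per million cells")
        return ax

    def summary(self) -> str:
        q = self.quant
        e = self.efficiency
        lines = [
            "Spike-in DSB quantification",
            "=" * 52,
            f"{'Spike-in enzyme':32s}{self.model.enzyme.name if self.model.enzyme else 'custom sites'}",
            f"{'Cut sites (N_sites)':32s}{len(self.model.sites)}",
            f"{'Digested-cell proportion (p)':32s}{self.model.p:g}",
            f"{'Vicinity half-width (bp)':32s}{self.model.w}",
            "-" * 52,
            f"{'Cutting efficiency f_cut':32s}{e.f_cut:.4f} +/- {e.sigma_total:.4f}",
            f"{'  sigma_Poisson':32s}{e.sigma_poisson:.4g}",
            f"{'  sigma_background':32s}{e.sigma_bg:.4g}",
            f"{'  background f_bg':32s}{self.background.f_bg:.4g}",
            f"{'  sites in pool':32s}{e.n_sites_used}",
            f"{'Spike-in breaks/cell (B_cut)':32s}{q.b_cut:.4g}",
            f"{'Reads at sites (R_cut)':32s}{q.r_cut:.0f}",
            f"{'Reads per break (alpha)':32s}{q.alpha:.4g}",
            f"{'Studied reads (R_studied)':32s}{q.r_studied:.0f}",
            "-" * 52,
            f"{'Studied DSBs per cell':32s}{q.b_studied:.3g} +/- {q.sd_b:.3g}"
            f"  ({q.sd_method} SD)",
            "=" * 52,
        ]
        return "\n".join(lines)
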