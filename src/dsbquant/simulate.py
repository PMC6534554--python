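"""Synthetic genomes, gDNA fragments, break-labeled reads and UMI tables.

Every generator plants explicit ground truth (a :class:`SimTruth` ledger)
so estimators downstream can be validated by parameter recovery.  All
emitters are seed-deterministic: each one derives an independent stream
from ``numpy.random.SeedSequence(seed, stream_id)`` so changing one signal
class never perturbs another.

The gDNA generator emulates paired-end sequencing of a population in
which a fraction ``f_cut`` of molecules is cleaved at each restriction
site.  A cleaved molecule yields two fragments abutting the scission
(ends within <=1 bp sequencer jitter of the cut); an intact molecule
yields one fragment placed uniformly over the site, so its sonication
ends fall inside the counting vicinity at the same per-coverage rate as
in real uniform-coverage data.  Sonication-only background fragments are
laid down uniformly genome-wide; random-window background estimation
therefore sees the same end-in-window process that contaminates the
sites, which is the premise of the background subtraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import (
    CutSite,
    EnzymeSpec,
    FragmentSet,
    Genome,
    ReadSet,
    find_cut_sites,
    reverse_complement,
)

__all__ = [
    "BreakLandscape",
    "SimTruth",
    "make_genome",
    "sample_site_efficiencies",
    "simulate_gdna",
    "simulate_dsb_reads",
    "simulate_umi_reads",
]


@dataclass
class BreakLandscape:
    """Planted studied-break signal classes.

    two_ended: (chrom, pos, per-cell frequency) tuples -- breaks with two
        detectable ends, emitting reads on both strands.
    one_ended: (chrom, pos, per-cell frequency, polarity) tuples -- broken
        replication forks emitting strictly single-strand signal;
        polarity '+' emits Watson reads, '-' Crick reads.
    uniform_background: DSBs per cell per bp, spread uniformly.
    telomere_read_fraction: proportion of emitted reads that carry a
        telomere-motif sequence (structures resembling breaks, removed by
        the sequence filter rather than quantified).
    """

    two_ended: list[tuple[str, int, float]] = field(default_factory=list)
    one_ended: list[tuple[str, int, float, str]] = field(default_factory=list)
    uniform_background: float = 0.0
    telomere_read_fraction: float = 0.0

    def __post_init__(self):
        for _, _, f in self.two_ended:
            if f < 0:
                raise ValueError("two-ended frequency must be >= 0")
        for _, _, f, pol in self.one_ended:
            if f < 0:
                raise ValueError("one-ended frequency must be >= 0")
            if pol not in "+-":
                raise ValueError("one-ended polarity must be '+' or '-'")
        if self.uniform_background < 0:
            raise ValueError("uniform_background must be >= 0")
        if not 0 <= self.telomere_read_fraction < 1:
            raise ValueError("telomere_read_fraction must be in [0, 1)")

    def total_per_cell(self, genome_length: int) -> float:
        """Total planted studied DSBs per cell (telomere reads excluded)."""
        return (
            sum(f for _, _, f in self.two_ended)
            + sum(f for _, _, f, _ in self.one_ended)
            + self.uniform_background * genome_length
        )


@dataclass
class SimTruth:
    """Ground-truth ledger written by every generator."""

    seed: int
    f_cut_planted: np.ndarray | None = None
    alpha_planted: float | None = None
    b_studied_planted: float | None = None
    b_one_ended_planted: float | None = None
    n_breaks_planted: int | None = None
    detail: dict = field(default_factory=dict)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_sequence(n: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=n, p=p)
    return _BASES[idx].tobytes().decode()


def _scrub_motif(seq: list, motif: str, rng: np.random.Generator) -> None:
    """Destroy every occurrence of motif (either strand) in-place."""
    import re

    from .io_formats import _iupac_regex

    pats = [re.compile(f"(?=({_iupac_regex(m)}))") for m in {motif, reverse_complement(motif)}]
    changed = True
    while changed:
        changed = False
        s = "".join(seq)
        for pat in pats:
            for m in pat.finditer(s):
                i = m.start() + rng.integers(len(motif))
                old = seq[i]
                choices = [b for b in "ACGT" if b != old]
                seq[i] = choices[rng.integers(3)]
                changed = True
            if changed:
                break


def make_genome(
    lengths: list[int] | dict[str, int],
    gc_content: float = 0.38,
    embed_motifs: list[tuple[EnzymeSpec, int]] | None = None,
    seed: int = 0,
    vicinity_w: int = 3,
    margin: int = 500,
) -> tuple[Genome, dict[str, list[CutSite]]]:
    """Random genome with exactly the requested motif occurrences.

    Accidental occurrences of every requested motif are scrubbed before
    embedding; requested copies are then placed at uniformly drawn,
    non-overlapping positions (>= ``margin`` bp from chromosome ends and
    from each other).  Returns the genome and, per enzyme, the cut sites
    as they would be found by in-silico digestion.
    """
    if isinstance(lengths, dict):
        chrom_lengths = dict(lengths)
    else:
        chrom_lengths = {f"chr{i + 1}": L for i, L in enumerate(lengths)}
    embed_motifs = embed_motifs or []
    rng = _rng(seed, 0)

    seqs: dict[str, list] = {
        name: list(_random_sequence(L, gc_content, rng))
        for name, L in chrom_lengths.items()
    }
    for enz, _ in embed_motifs:
        for seq in seqs.values():
            _scrub_motif(seq, enz.recognition, rng)

    # place motifs round-robin across chromosomes, rejection-sampling
    # positions so placements never overlap
    total = sum(chrom_lengths.values())
    placed: dict[str, list[CutSite]] = {}
    occupied: dict[str, list[tuple[int, int]]] = {name: [] for name in seqs}
    chroms = list(chrom_lengths)
    weights = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    for enz, n_occ in embed_motifs:
        sites: list[CutSite] = []
        motif = enz.recognition
        for _ in range(n_occ):
            for _attempt in range(10_000):
                chrom = chroms[rng.choice(len(chroms), p=weights)]
                L = chrom_lengths[chrom]
                if L < 2 * margin + len(motif):
                    continue
                start = int(rng.integers(margin, L - margin - len(motif)))
                span = (start - margin, start + len(motif) + margin)
                if any(a < span[1] and span[0] < b for a, b in occupied[chrom]):
                    continue
                seqs[chrom][start : start + len(motif)] = list(motif)
                occupied[chrom].append(span)
                sites.append(
                    CutSite(chrom, start + enz.cut_offset_top, "+", vicinity_w)
                )
                break
            else:
                raise ValueError(
                    f"could not place {n_occ} non-overlapping copies of "
                    f"{enz.name} in {total} bp"
                )
        placed[enz.name] = sorted(sites, key=lambda s: (s.chrom, s.cut_pos))

    genome = Genome({name: "".join(seq) for name, seq in seqs.items()})
    # embedding could in principle create new cross-boundary occurrences;
    # verify the in-silico digest agrees with the placement ledger
    for enz, n_occ in embed_motifs:
        found = find_cut_sites(genome, enz, vicinity_w)
        if len(found) != n_occ:
            raise ValueError(
                f"{enz.name}: embedding produced {len(found)} occurrences, "
                f"requested {n_occ}; retry with a different seed"
            )
    return genome, placed


def sample_site_efficiencies(
    f_cut: float, n_sites: int, rel_sd: float = 0.3, seed: int = 0
) -> np.ndarray:
    """Per-site efficiencies with site-to-site variability.

    Real digests show substantial spread around the mean efficiency; we
    draw ``Normal(f, rel_sd * f * (1 - f))`` clipped to (0.005, 0.995).
    """
    rng = _rng(seed, 7)
    f = rng.normal(f_cut, rel_sd * f_cut * (1 - f_cut), size=n_sites)
    return np.clip(f, 0.005, 0.995)


def _truncated_normal_lengths(
    n: int, mean: float, sd: float, minimum: int, rng: np.random.Generator
) -> np.ndarray:
    out = rng.normal(mean, sd, size=n)
    bad = out < minimum
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out < minimum
    return np.round(out).astype(np.int64)


def simulate_gdna(
    genome: Genome,
    sites: list[CutSite],
    f_cut: float | np.ndarray,
    coverage: int = 10_000,
    fragment_length_mean: float = 400.0,
    fragment_length_sd: float = 80.0,
    min_fragment_length: int = 100,
    sonication_rate: float = 0.05,
    seed: int = 0,
) -> tuple[FragmentSet, SimTruth]:
    """Paired-end gDNA fragments from a partially digested population.

    ``coverage`` molecules span each site; each is cleaved with its site's
    probability.  ``sonication_rate`` background fragments per bp are
    added genome-wide.
    """
    f = np.broadcast_to(np.asarray(f_cut, dtype=float), (len(sites),)).copy()
    if ((f < 0) | (f > 1)).any():
        raise ValueError("f_cut must lie in [0, 1]")
    rng = _rng(seed, 1)

    chroms: list[np.ndarray] = []
    starts: list[np.ndarray] = []
    ends: list[np.ndarray] = []

    for i, site in enumerate(sites):
        L = _truncated_normal_lengths(
            coverage, fragment_length_mean, fragment_length_sd, min_fragment_length, rng
        )
        # molecule covers the cut: start uniform in (cut - L, cut]
        mol_start = site.cut_pos - rng.integers(0, L)  # elementwise high=L
        mol_end = mol_start + L
        cut_mask = rng.random(coverage) < f[i]

        n_cut = int(cut_mask.sum())
        if n_cut:
            j1 = rng.integers(-1, 2, size=n_cut)
            j2 = rng.integers(-1, 2, size=n_cut)
            left_end = site.cut_pos + j1
            right_start = site.cut_pos + j2
            ls, le = mol_start[cut_mask], left_end
            rs, re_ = right_start, mol_end[cut_mask]
            ok_l = ls < le
            ok_r = rs < re_
            starts.append(ls[ok_l]); ends.append(le[ok_l])
            starts.append(rs[ok_r]); ends.append(re_[ok_r])
            chroms.append(np.full(int(ok_l.sum()) + int(ok_r.sum()), site.chrom, dtype=object))
        n_uncut = coverage - n_cut
        if n_uncut:
            starts.append(mol_start[~cut_mask])
            ends.append(mol_end[~cut_mask])
            chroms.append(np.full(n_uncut, site.chrom, dtype=object))

    # sonication-only background, uniform genome-wide
    for chrom in genome:
        Lc = genome.lengths[chrom]
        n_bg = rng.poisson(sonication_rate * Lc)
        if n_bg == 0:
            continue
        bl = _truncated_normal_lengths(
            n_bg, fragment_length_mean, fragment_length_sd, min_fragment_length, rng
        )
        bs = rng.integers(0, np.maximum(Lc - bl, 1))
        starts.append(bs)
        ends.append(bs + bl)
        chroms.append(np.full(n_bg, chrom, dtype=object))

    if starts:
        df = pd.DataFrame(
            {
                "chrom": np.concatenate(chroms),
                "start": np.concatenate(starts).astype(np.int64),
                "end": np.concatenate(ends).astype(np.int64),
            }
        )
    else:
        df = pd.DataFrame(columns=["chrom", "start", "end"])
    # clip rare fragments protruding past chromosome ends
    if len(df):
        lengths = df["chrom"].map(genome.lengths).to_numpy()
        df["start"] = np.maximum(df["start"].to_numpy(), 0)
        df["end"] = np.minimum(df["end"].to_numpy(), lengths)
        df = df[df["start"] < df["end"]].reset_index(drop=True)

    truth = SimTruth(
        seed=seed,
        f_cut_planted=f,
        detail={"coverage": coverage, "sonication_rate": sonication_rate},
    )
    return FragmentSet(df), truth


def _telomere_sequence(n: int, rng: np.random.Generator) -> str:
    """A read matching the AC-rich telomere rule: repeats of C{0,3}AC{1,10}."""
    parts = []
    total = 0
    while total < n:
        c1 = int(rng.integers(0, 4))
        c2 = int(rng.integers(1, 11))
        unit = "C" * c1 + "A" + "C" * c2
        parts.append(unit)
        total += len(unit)
    seq = "".join(parts)
    # trim to an exact repeat boundary is unnecessary: the filter matches
    # whole reads, so emit complete units only
    return seq


def simulate_dsb_reads(
    genome: Genome,
    sites: list[CutSite],
    f_cut: float | np.ndarray,
    landscape: BreakLandscape,
    alpha_planted: float,
    read_length: int = 50,
    seed: int = 0,
) -> tuple[ReadSet, SimTruth]:
    """Break-proximal labeled reads for spike-ins plus the studied signal.

    Expected read count for a source with per-cell frequency ``b`` is
    ``alpha_planted * b`` (Poisson); spike-in sites receive reads on both
    strands with 5' ends within 1 bp of the cut.
    """
    if alpha_planted <= 0:
        raise ValueError("alpha_planted must be positive")
    f = np.broadcast_to(np.asarray(f_cut, dtype=float), (len(sites),)).copy()
    rng = _rng(seed, 2)

    chrom_l, start_l, end_l, strand_l, seq_l = [], [], [], [], []

    def emit(chrom: str, pos5: np.ndarray, strand: np.ndarray) -> None:
        Lc = genome.lengths[chrom]
        pos5 = np.clip(pos5, 0, Lc - 1)
        plus = strand == "+"
        start = np.where(plus, pos5, np.maximum(pos5 - read_length + 1, 0))
        end = np.where(plus, np.minimum(pos5 + read_length, Lc), pos5 + 1)
        chrom_l.append(np.full(len(pos5), chrom, dtype=object))
        start_l.append(start)
        end_l.append(end)
        strand_l.append(strand)
        seq_l.append(np.full(len(pos5), None, dtype=object))

    # spike-in reads: both strands face the cut
    for i, site in enumerate(sites):
        n = rng.poisson(alpha_planted * f[i])
        if n == 0:
            continue
        strands = np.where(rng.random(n) < 0.5, "+", "-").astype(object)
        jitter = rng.integers(-1, 2, size=n)
        emit(site.chrom, site.cut_pos + jitter, strands)

    # two-ended studied DSBs
    for chrom, pos, freq in landscape.two_ended:
        n = rng.poisson(alpha_planted * freq)
        if n == 0:
            continue
        strands = np.where(rng.random(n) < 0.5, "+", "-").astype(object)
        jitter = rng.integers(-1, 2, size=n)
        emit(chrom, pos + jitter, strands)

    # one-ended studied DSBs: strictly single-strand signal
    for chrom, pos, freq, pol in landscape.one_ended:
        n = rng.poisson(alpha_planted * freq)
        if n == 0:
            continue
        strands = np.full(n, pol, dtype=object)
        jitter = rng.integers(-1, 2, size=n)
        emit(chrom, pos + jitter, strands)

    # uniform background breaks
    if landscape.uniform_background > 0:
        for chrom in genome:
            Lc = genome.lengths[chrom]
            n = rng.poisson(alpha_planted * landscape.uniform_background * Lc)
            if n == 0:
                continue
            pos = rng.integers(0, Lc, size=n)
            strands = np.where(rng.random(n) < 0.5, "+", "-").astype(object)
            emit(chrom, pos, strands)

    n_signal = sum(len(a) for a in start_l)
    # telomere-motif reads (structures resembling breaks)
    tf = landscape.telomere_read_fraction
    if tf > 0 and n_signal > 0:
        n_tel = rng.poisson(tf / (1 - tf) * n_signal)
        chrom = genome.chrom_names[0]
        Lc = genome.lengths[chrom]
        for _ in range(n_tel):
            pos = int(rng.integers(0, max(Lc - read_length, 1)))
            seq = _telomere_sequence(read_length, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            chrom_l.append(np.array([chrom], dtype=object))
            start_l.append(np.array([pos]))
            end_l.append(np.array([pos + len(seq)]))
            strand_l.append(np.array([strand], dtype=object))
            # minus-strand telomere reads store the Watson-strand sequence's
            # reverse complement; the filter tests both orientations
            seq_l.append(np.array([seq if strand == "+" else reverse_complement(seq)], dtype=object))

    if chrom_l:
        df = pd.DataFrame(
            {
                "chrom": np.concatenate(chrom_l),
                "start": np.concatenate(start_l).astype(np.int64),
                "end": np.concatenate(end_l).astype(np.int64),
                "strand": np.concatenate(strand_l),
                "seq": np.concatenate(seq_l),
            }
        )
    else:
        df = pd.DataFrame(columns=["chrom", "start", "end", "strand", "seq"])

    truth = SimTruth(
        seed=seed,
        f_cut_planted=f,
        alpha_planted=alpha_planted,
        b_studied_planted=landscape.total_per_cell(genome.total_length),
        b_one_ended_planted=sum(fr for _, _, fr, _ in landscape.one_ended),
        detail={"n_reads": len(df)},
    )
    return ReadSet(df), truth


_UMI_BASES = np.array(list("ACGT"))


def simulate_umi_reads(
    sites: list[CutSite],
    dsbs_per_cell_per_site: float | np.ndarray,
    n_cells: int,
    umi_length: int = 8,
    duplication_rate: float = 5.0,
    position_jitter: int = 50,
    barcode: str = "CATCACGC",
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """UMI-tagged read table emulating UMI-based break labeling.

    Each true break emits one (position, UMI) molecule plus
    ``Poisson(duplication_rate)`` PCR duplicates; positions scatter within
    ``position_jitter`` bp of the site.
    """
    if umi_length < 4:
        raise ValueError("umi_length must be >= 4")
    rates = np.broadcast_to(
        np.asarray(dsbs_per_cell_per_site, dtype=float), (len(sites),)
    )
    rng = _rng(seed, 3)

    rows_chrom, rows_pos, rows_umi = [], [], []
    n_breaks = 0
    for site, rate in zip(sites, rates):
        k = rng.poisson(rate * n_cells)
        n_breaks += int(k)
        if k == 0:
            continue
        pos = site.cut_pos + rng.integers(-position_jitter, position_jitter + 1, size=k)
        umis = [
            "".join(_UMI_BASES[rng.integers(0, 4, size=umi_length)]) for _ in range(k)
        ]
        copies = 1 + rng.poisson(duplication_rate, size=k)
        for p, u, c in zip(pos, umis, copies):
            rows_chrom.extend([site.chrom] * c)
            rows_pos.extend([int(p)] * c)
            rows_umi.extend([u] * c)

    df = pd.DataFrame(
        {
            "chrom": rows_chrom,
            "pos": rows_pos,
            "umi": rows_umi,
            "barcode": barcode,
        }
    )
    if len(df):
        df = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
    truth = SimTruth(
        seed=seed,
        n_breaks_planted=n_breaks,
        detail={
            "expected_breaks": float(rates.sum() * n_cells),
            "n_cells": n_cells,
        },
    )
    return df, truth
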