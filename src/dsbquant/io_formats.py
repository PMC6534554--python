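"""Genomic formats, enzyme definitions and in-silico digestion.

All coordinates are 0-based, half-open internally.  BED input is taken
natively in that frame; SAM records are converted on read.  A restriction
site is represented by its top-strand scission coordinate ``cut_pos`` (the
first base 3' of the cut) together with a symmetric counting vicinity
``[cut_pos - w, cut_pos + w]`` used everywhere downstream to assign
fragment ends and read 5' ends to the site.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "Genome",
    "EnzymeSpec",
    "CutSite",
    "GenomicInterval",
    "ReadSet",
    "FragmentSet",
    "ENZYMES",
    "read_fasta",
    "reverse_complement",
    "find_cut_sites",
    "digestion_stats",
    "read_intervals",
    "read_bed",
    "write_bed",
    "write_bedgraph",
    "read_bedgraph",
    "load_enzyme_config",
]

# IUPAC nucleotide codes -> set of concrete bases.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

VALID_GENOME_ALPHABET = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _iupac_regex(motif: str) -> str:
    parts = []
    for ch in motif:
        bases = IUPAC.get(ch)
        if bases is None:
            raise ValueError(f"invalid IUPAC code {ch!r} in motif {motif!r}")
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return "".join(parts)


class Genome:
    """Named chromosome sequences in a single coordinate frame.

    Sequences are uppercase strings over A/C/G/T/N; chromosome names are
    unique and ordering is preserved.
    """

    def __init__(self, sequences: dict[str, str]):
        if len(sequences) == 0:
            raise ValueError("genome must contain at least one chromosome")
        self._seqs: dict[str, str] = {}
        for name, seq in sequences.items():
            if name in self._seqs:
                raise ValueError(f"duplicate chromosome name {name!r}")
            seq = seq.upper()
            bad = set(seq) - VALID_GENOME_ALPHABET
            if bad:
                raise ValueError(
                    f"chromosome {name!r} contains non-A/C/G/T/N characters: "
                    f"{sorted(bad)}"
                )
            self._seqs[name] = seq

    @property
    def chrom_names(self) -> list[str]:
        return list(self._seqs)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self._seqs.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self._seqs.values())

    def __getitem__(self, chrom: str) -> str:
        return self._seqs[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def __iter__(self):
        return iter(self._seqs)

    def __eq__(self, other) -> bool:
        return isinstance(other, Genome) and self._seqs == other._seqs

    def __repr__(self) -> str:
        return f"Genome({len(self._seqs)} chromosomes, {self.total_length} bp)"


@dataclass(frozen=True)
class EnzymeSpec:
    """A restriction endonuclease: recognition motif and scission offsets.

    ``cut_offset_top``/``cut_offset_bottom`` give the scission position on
    the top and bottom strand, both measured in top-strand coordinates from
    the motif start.  Equal offsets produce blunt ends; top < bottom leaves
    5' overhangs, top > bottom leaves 3' overhangs.
    """

    name: str
    recognition: str
    cut_offset_top: int
    cut_offset_bottom: int
    end_type: str = field(default="")

    def __post_init__(self):
        if len(self.recognition) < 4:
            raise ValueError("recognition motif must be at least 4 nt")
        for ch in self.recognition:
            if ch not in IUPAC:
                raise ValueError(f"invalid IUPAC code {ch!r} in recognition motif")
        inferred = self.infer_end_type()
        if self.end_type == "":
            object.__setattr__(self, "end_type", inferred)
        elif self.end_type != inferred:
            raise ValueError(
                f"end_type {self.end_type!r} inconsistent with cut offsets "
                f"(expected {inferred!r})"
            )

    def infer_end_type(self) -> str:
        if self.cut_offset_top == self.cut_offset_bottom:
            return "blunt"
        return "5'-overhang" if self.cut_offset_top < self.cut_offset_bottom else "3'-overhang"

    @property
    def is_palindromic(self) -> bool:
        return self.recognition == reverse_complement(self.recognition)


#: Enzymes commonly used to induce spike-in breaks.
ENZYMES: dict[str, EnzymeSpec] = {
    "NotI": EnzymeSpec("NotI", "GCGGCCGC", 2, 6),
    "SrfI": EnzymeSpec("SrfI", "GCCCGGGC", 4, 4),
    "AsiSI": EnzymeSpec("AsiSI", "GCGATCGC", 5, 3),
    "BamHI": EnzymeSpec("BamHI", "GGATCC", 1, 5),
    "EcoRI": EnzymeSpec("EcoRI", "GAATTC", 1, 5),
    "I-SceI": EnzymeSpec("I-SceI", "TAGGGATAACAGGGTAAT", 9, 5),
}


@dataclass(frozen=True)
class CutSite:
    """One recognition occurrence with its double-strand cut coordinate."""

    chrom: str
    cut_pos: int
    strand_of_motif: str = "+"
    vicinity_w: int = 3

    def __post_init__(self):
        if self.cut_pos < 0:
            raise ValueError("cut_pos must be non-negative")
        if self.vicinity_w < 0:
            raise ValueError("vicinity_w must be non-negative")
        if self.strand_of_motif not in "+-":
            raise ValueError("strand_of_motif must be '+' or '-'")


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str | None = None
    name: str | None = None

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )
        if self.strand is not None and self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


class _IntervalTable:
    """Shared DataFrame-backed container for reads and fragments."""

    required = ("chrom", "start", "end")

    def __init__(self, df: pd.DataFrame, genome: Genome | None = None):
        df = df.reset_index(drop=True)
        for col in self.required:
            if col not in df.columns:
                raise ValueError(f"missing column {col!r}")
        if len(df) and not (df["start"] < df["end"]).all():
            bad = df.index[df["start"] >= df["end"]][0]
            raise ValueError(f"record {bad}: start >= end")
        if genome is not None and len(df):
            for chrom, grp in df.groupby("chrom", sort=False):
                if chrom not in genome:
                    raise ValueError(f"unknown chromosome {chrom!r}")
                L = genome.lengths[chrom]
                if (grp["start"] < 0).any() or (grp["end"] > L).any():
                    bad = grp.index[(grp["start"] < 0) | (grp["end"] > L)][0]
                    raise ValueError(
                        f"record {bad} out of bounds for {chrom} (length {L})"
                    )
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def chrom_subset(self, chrom: str) -> pd.DataFrame:
        return self.df[self.df["chrom"] == chrom]


class ReadSet(_IntervalTable):
    """DSB-labeled single-end reads; every record carries a strand.

    The ``seq`` column is optional and only consulted by the telomere
    filter.  The 5' (break-proximal) end of a read is ``start`` on the
    Watson strand and ``end - 1`` on the Crick strand.
    """

    def __init__(self, df: pd.DataFrame, genome: Genome | None = None):
        super().__init__(df, genome)
        if "strand" not in self.df.columns:
            raise ValueError("reads require a 'strand' column")
        if len(self.df) and not self.df["strand"].isin(["+", "-"]).all():
            raise ValueError("read strands must be '+' or '-'")
        if "seq" not in self.df.columns:
            self.df = self.df.assign(seq=None)

    def five_prime(self) -> np.ndarray:
        s = self.df["start"].to_numpy()
        e = self.df["end"].to_numpy()
        plus = (self.df["strand"] == "+").to_numpy()
        return np.where(plus, s, e - 1)

    def subset(self, mask: np.ndarray) -> "ReadSet":
        return ReadSet(self.df[mask])


class FragmentSet(_IntervalTable):
    """Paired-end gDNA fragments stored as their outer spans."""


def read_fasta(path: str | Path) -> Genome:
    """Parse a FASTA file into a :class:`Genome`.

    Lowercase is normalized to uppercase; characters outside A/C/G/T/N are
    rejected.
    """
    path = Path(path)
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"{path}: duplicate record {rec.id!r}")
        seqs[rec.id] = str(rec.seq)
    if not seqs:
        raise ValueError(f"{path}: no FASTA records found")
    try:
        return Genome(seqs)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def find_cut_sites(
    genome: Genome, enzyme: EnzymeSpec, vicinity_w: int = 3
) -> list[CutSite]:
    """Locate every recognition occurrence and return its cut coordinate.

    Motifs are matched on both strands (overlapping occurrences included);
    palindromic motifs are reported once per position.  For a minus-strand
    occurrence starting at ``p`` the top-strand scission falls at
    ``p + len(motif) - cut_offset_bottom``.  Duplicate cut positions are
    merged; output is sorted by (chrom, cut_pos).
    """
    fwd = re.compile(f"(?=({_iupac_regex(enzyme.recognition)}))")
    L = len(enzyme.recognition)
    sites: dict[tuple[str, int], CutSite] = {}
    for chrom in genome:
        seq = genome[chrom]
        for m in fwd.finditer(seq):
            pos = m.start() + enzyme.cut_offset_top
            if 0 <= pos < len(seq):
                sites.setdefault(
                    (chrom, pos), CutSite(chrom, pos, "+", vicinity_w)
                )
        if not enzyme.is_palindromic:
            rev = re.compile(f"(?=({_iupac_regex(reverse_complement(enzyme.recognition))}))")
            for m in rev.finditer(seq):
                pos = m.start() + (L - enzyme.cut_offset_bottom)
                if 0 <= pos < len(seq):
                    sites.setdefault(
                        (chrom, pos), CutSite(chrom, pos, "-", vicinity_w)
                    )
    order = {c: i for i, c in enumerate(genome.chrom_names)}
    return sorted(sites.values(), key=lambda s: (order[s.chrom], s.cut_pos))


def digestion_stats(
    genome: Genome, enzymes: Sequence[EnzymeSpec], vicinity_w: int = 3
) -> pd.DataFrame:
    """Per-enzyme site counts and densities for spike-in design.

    Returns a table (enzyme, n_sites, sites_per_Mb,
    median_inter_site_distance) sorted descending by sites_per_Mb.
    """
    total = genome.total_length
    if total == 0:
        raise ValueError("zero-length genome")
    rows = []
    for enz in enzymes:
        sites = find_cut_sites(genome, enz, vicinity_w)
        dists = []
        by_chrom: dict[str, list[int]] = {}
        for s in sites:
            by_chrom.setdefault(s.chrom, []).append(s.cut_pos)
        for positions in by_chrom.values():
            dists.extend(np.diff(positions).tolist())
        rows.append(
            {
                "enzyme": enz.name,
                "n_sites": len(sites),
                "sites_per_Mb": len(sites) / total * 1e6,
                "median_inter_site_distance": float(np.median(dists)) if dists else np.nan,
            }
        )
    out = pd.DataFrame(rows).sort_values(
        "sites_per_Mb", ascending=False, kind="stable"
    )
    return out.reset_index(drop=True)


def read_bed(path: str | Path, genome: Genome | None = None) -> pd.DataFrame:
    """Read a BED3/BED6 file into a DataFrame (0-based half-open)."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED fields")
            rows.append(fields[:6])
    if not rows:
        df = pd.DataFrame(columns=names[:3])
    else:
        width = max(len(r) for r in rows)
        df = pd.DataFrame(rows, columns=names[:width])
    if len(df):
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ("chrom", "start", "end", "name", "score", "strand") if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def _fragments_from_sam(path: str | Path) -> pd.DataFrame:
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or not rec.is_paired or not rec.is_proper_pair:
                continue
            # emit the outer span once, from the leftmost mate
            if rec.template_length > 0:
                rows.append(
                    {
                        "chrom": rec.reference_name,
                        "start": rec.reference_start,
                        "end": rec.reference_start + rec.template_length,
                    }
                )
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _reads_from_sam(path: str | Path) -> pd.DataFrame:
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            rows.append(
                {
                    "chrom": rec.reference_name,
                    "start": rec.reference_start,
                    "end": rec.reference_end,
                    "strand": "-" if rec.is_reverse else "+",
                    "seq": rec.query_sequence,
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "seq"])


def read_intervals(
    path: str | Path,
    format: str = "BED",
    kind: str = "reads",
    genome: Genome | None = None,
) -> ReadSet | FragmentSet:
    """Load mapped reads or paired-end fragments from BED or SAM/BAM.

    ``kind`` selects the container: ``"reads"`` -> :class:`ReadSet`
    (strand required), ``"fragments"`` -> :class:`FragmentSet` (outer span
    of properly paired mates for SAM input).  Out-of-bounds records raise
    when a genome is supplied.
    """
    fmt = format.upper()
    if fmt == "BED":
        df = read_bed(path)
    elif fmt in ("SAM", "BAM"):
        df = _reads_from_sam(path) if kind == "reads" else _fragments_from_sam(path)
    else:
        raise ValueError(f"unsupported format {format!r}")
    if kind == "reads":
        return ReadSet(df, genome)
    if kind == "fragments":
        return FragmentSet(df[["chrom", "start", "end"]], genome)
    raise ValueError(f"unsupported kind {kind!r}")


def write_bedgraph(track: pd.DataFrame, path: str | Path, header: str | None = None) -> None:
    """Write a (chrom, start, end, value) table as 4-column bedGraph.

    Windows must be sorted within each chromosome; values are written with
    6 decimals so a round-trip read reproduces them exactly at that
    precision.
    """
    for chrom, grp in track.groupby("chrom", sort=False):
        if not grp["start"].is_monotonic_increasing:
            raise ValueError(f"bedGraph windows for {chrom} are not sorted")
    with open(path, "w") as fh:
        if header:
            fh.write(header.rstrip("\n") + "\n")
        for row in track.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.value:.6f}\n")


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            chrom, start, end, value = line.split("\t")
            rows.append((chrom, int(start), int(end), float(value)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def load_enzyme_config(path: str | Path) -> dict[str, EnzymeSpec]:
    """Load enzyme definitions from a YAML mapping.

    Each entry: ``name: {recognition: ..., cut_offset_top: ...,
    cut_offset_bottom: ..., end_type: ...}``; end_type is optional and
    validated against the offsets when present.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    out = {}
    for name, spec in raw.items():
        out[name] = EnzymeSpec(
            name=name,
            recognition=spec["recognition"],
            cut_offset_top=int(spec["cut_offset_top"]),
            cut_offset_bottom=int(spec["cut_offset_bottom"]),
            end_type=spec.get("end_type", ""),
        )
    return out
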