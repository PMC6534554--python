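"""UMI-based DSB counting for comparison with spike-in quantification.

Counts unique (chromosome, position, UMI) molecules near restriction
sites and divides by the number of cells, as done with UMI-labeled break
libraries.  Unlike spike-in normalization, the resulting estimate scales
with sequencing depth: molecules never sequenced are never counted,
which is the central weakness this module exists to demonstrate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_formats import CutSite

__all__ = [
    "dedup_umis",
    "count_umis_near_sites",
    "bliss_dsbs_per_cell",
]


def dedup_umis(records: pd.DataFrame, barcode: str | None = None) -> pd.DataFrame:
    """Exact-match deduplication on (chrom, pos, umi).

    No edit-distance collapsing is applied.  With ``barcode`` given,
    records whose barcode differs are dropped first.
    """
    for col in ("chrom", "pos", "umi"):
        if col not in records.columns:
            raise ValueError(f"missing column {col!r}")
    df = records
    if barcode is not None and "barcode" in df.columns:
        df = df[df["barcode"] == barcode]
    return df.drop_duplicates(subset=["chrom", "pos", "umi"]).reset_index(drop=True)


def count_umis_near_sites(
    unique: pd.DataFrame,
    sites: list[CutSite],
    half_window: int = 100,
    merge_distance: int = 200,
    exclude_chroms: set[str] = frozenset({"chrY"}),
) -> int:
    """Unique UMIs within +/- half_window of any site, double-count free.

    Site intervals closer than ``merge_distance`` (cut-to-cut) are merged
    into one counting interval so a molecule between two nearby sites is
    counted once; sites on excluded chromosomes are dropped.
    """
    kept = [s for s in sites if s.chrom not in exclude_chroms]
    if not kept or len(unique) == 0:
        return 0
    intervals: dict[str, list[list[int]]] = {}
    for s in sorted(kept, key=lambda x: (x.chrom, x.cut_pos)):
        lo, hi = s.cut_pos - half_window, s.cut_pos + half_window
        ivs = intervals.setdefault(s.chrom, [])
        if ivs and (s.cut_pos - ivs[-1][2]) < merge_distance:
            ivs[-1][1] = max(ivs[-1][1], hi)
            ivs[-1][2] = s.cut_pos
        else:
            ivs.append([lo, hi, s.cut_pos])
    total = 0
    for chrom, grp in unique.groupby("chrom", sort=False):
        ivs = intervals.get(chrom)
        if not ivs:
            continue
        pos = grp["pos"].to_numpy(np.int64)
        hit = np.zeros(len(pos), dtype=bool)
        for lo, hi, _ in ivs:
            hit |= (pos >= lo) & (pos <= hi)
        total += int(hit.sum())
    return total


def bliss_dsbs_per_cell(n_umi: int, n_cell: int) -> tuple[float, float]:
    """DSBs per cell from unique-UMI and cell counts, with Poisson SD.

    estimate = N_UMI / N_cell;
    SD = 1/2 * [ (N_UMI + sqrt(N_UMI)) / (N_cell - sqrt(N_cell))
               - (N_UMI - sqrt(N_UMI)) / (N_cell + sqrt(N_cell)) ].
    A zero UMI count returns (0, 0).
    """
    if n_cell < 1:
        raise ValueError("N_cell must be >= 1")
    if n_umi < 0:
        raise ValueError("N_UMI must be >= 0")
    if n_cell - np.sqrt(n_cell) <= 0:
        raise ValueError("N_cell too small for the Poisson SD approximation")
    if n_umi == 0:
        return 0.0, 0.0
    ru, rc = np.sqrt(n_umi), np.sqrt(n_cell)
    sd = 0.5 * ((n_umi + ru) / (n_cell - rc) - (n_umi - ru) / (n_cell + rc))
    return float(n_umi / n_cell), float(sd)
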