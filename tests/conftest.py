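import numpy as np
import pandas as pd
import pytest

from dsbquant import ENZYMES, Genome, ReadSet, FragmentSet
from dsbquant.simulate import make_genome


@pytest.fixture(scope="session")
def small_genome_with_sites():
    """200 kb genome with 10 embedded NotI sites (session-wide, seeded)."""
    genome, placed = make_genome(
        [200_000], embed_motifs=[(ENZYMES["NotI"], 10)], seed=1
    )
    return genome, placed["NotI"]


@pytest.fixture
def toy_genome():
    return Genome({"chr1": "ACGT" * 2500})  # 10 kb


def make_reads(records, genome=None):
    """records: list of (chrom, start, end, strand[, seq])."""
    rows = []
    for rec in records:
        row = {"chrom": rec[0], "start": rec[1], "end": rec[2], "strand": rec[3]}
        row["seq"] = rec[4] if len(rec) > 4 else None
        rows.append(row)
    return ReadSet(pd.DataFrame(rows), genome)


def make_fragments(records, genome=None):
    df = pd.DataFrame(records, columns=["chrom", "start", "end"])
    return FragmentSet(df, genome)
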