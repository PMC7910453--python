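import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from natseeker import synthetic_data as sd
from natseeker.core_model import ExpressionMatrix, GenomeStore, Transcript


@pytest.fixture(scope="session")
def default_fix():
    """The study-condition synthetic fixture (seed 42), shared read-only."""
    return sd.default_fixture(seed=42)


@pytest.fixture(scope="session")
def discovered_pairs(default_fix):
    """Candidate pairs discovered on the shared fixture (pre-filter)."""
    from natseeker.nat_discovery import discover

    return discover(default_fix.transcripts, default_fix.expression)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def small_expr():
    """Two transcripts, three tissues x one or two replicates."""
    df = pd.DataFrame(
        {
            "p01_f": [0.5, 0.0],
            "p02_f": [0.5, 0.0],
            "p01_l": [0.8, 1.2],
            "p01_r": [0.9, 0.0],
        },
        index=["low", "leaf_only"],
    )
    return ExpressionMatrix(df)


def random_transcript_pair(rng, contig_len=3000, max_exons=4):
    """A random opposite-strand transcript pair on one contig (may or may
    not overlap) for overlap-oracle property tests."""

    def exons():
        n = int(rng.integers(1, max_exons + 1))
        points = np.sort(rng.choice(np.arange(0, contig_len - 1), size=2 * n, replace=False))
        ivs = [(int(points[2 * k]), int(points[2 * k + 1]) + 1) for k in range(n)]
        merged = [ivs[0]]
        for s, e in ivs[1:]:
            if s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        return merged

    st = Transcript(id="ST", chrom="c", strand="+", exons=exons(), biotype="coding")
    nat = Transcript(id="NAT", chrom="c", strand="-", exons=exons(), biotype="unknown")
    return st, nat


@pytest.fixture()
def toy_genome():
    rng = np.random.default_rng(7)
    return GenomeStore({"chr1": "".join(rng.choice(list("ACGT"), 6000))})
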