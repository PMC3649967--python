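import numpy as np
import pandas as pd
import pytest


def make_universe(rows):
    """Gene table from (gene_id, exon_length_bp, gc_pct, ess_class) tuples."""
    return pd.DataFrame(
        {
            "gene_id": [r[0] for r in rows],
            "symbol": [r[0] for r in rows],
            "chrom": "1",
            "tss": np.arange(1, len(rows) + 1) * 10_000,
            "strand": "+",
            "exon_length_bp": [r[1] for r in rows],
            "gc_pct": [r[2] for r in rows],
            "ess_class": [r[3] for r in rows],
        }
    )


@pytest.fixture
def small_universe():
    """Six genes with hand-enumerable match pools (len tol 100, GC tol 2.5)."""
    return make_universe(
        [
            ("g1", 1000, 40.0, "EG"),
            ("g2", 1050, 41.0, "OTHER"),
            ("g3", 1080, 39.0, "EG"),
            ("g4", 1200, 40.0, "OTHER"),
            ("g5", 1000, 45.0, "OTHER"),
            ("g6", 5000, 50.0, "NLG"),
        ]
    )


@pytest.fixture
def homogeneous_universe():
    """200 interchangeable genes (identical length and GC), half EG."""
    return make_universe(
        [(f"h{i:03d}", 1000, 40.0, "EG" if i < 100 else "OTHER") for i in range(200)]
    )
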