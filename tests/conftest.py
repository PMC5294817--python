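import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from cistrovar.ld import HaplotypePanel, Site


@pytest.fixture
def two_site_panel():
    """Haplotypes over two sites {11, 11, 01, 00}: hand-computable r^2 = 1/3."""
    H = np.array([[1, 1], [1, 1], [0, 1], [0, 0]], dtype=np.uint8)
    sites = [Site("chr1", 100, "A", "G", "snp_a"), Site("chr1", 200, "C", "T", "snp_b")]
    return HaplotypePanel(sites, H)


@pytest.fixture
def block_panel():
    """Two perfectly correlated 5-site blocks, far apart, plus a rare site."""
    rng = np.random.default_rng(42)
    founder1 = (rng.random(60) < 0.4).astype(np.uint8)
    founder2 = (rng.random(60) < 0.3).astype(np.uint8)
    rare = np.zeros(60, dtype=np.uint8)
    rare[0] = 1  # maf 1/60 < 0.05
    cols = [founder1] * 5 + [rare] + [founder2] * 5
    H = np.stack(cols, axis=1)
    sites = [Site("chr1", 1000 + 100 * i, "A", "G", f"b1_{i}") for i in range(5)]
    sites.append(Site("chr1", 1600, "A", "G", "rare"))
    sites += [Site("chr1", 2_000_000 + 100 * i, "A", "G", f"b2_{i}") for i in range(5)]
    return HaplotypePanel(sites, H)
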