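import numpy as np
import pytest

from ogdscan import scan as sc
from ogdscan import substmodel as sm
from ogdscan import synthdata as sd
from ogdscan import treecore as tc


@pytest.fixture(scope="session")
def jtt():
    return sm.jtt_model("model")


@pytest.fixture(scope="session")
def quartet():
    return tc.parse_newick("((A:1,B:1):1,C:1,D:1);")


@pytest.fixture(scope="session")
def default_fixture():
    """The standard synthetic dataset: 12 taxa, 5 families (2 with transfers)."""
    return sd.make_fixture(seed=42)


@pytest.fixture(scope="session")
def default_scans(default_fixture):
    """Full scans of every family of the default fixture (shared: expensive)."""
    cfg = sc.ScanConfig(seed=42)
    fix = default_fixture
    return cfg, [
        sc.scan_family(fix.species, aln, cfg, family=name)
        for name, aln in sorted(fix.families.items())
    ]


def random_tree(n, seed, total_length=8.0):
    return sd.simulate_tree(n, seed=seed, total_length=total_length)
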