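import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ystrpop import HaplotypeTable
from ystrpop.loci import PANEL_15, YFILER_17

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_table(columns: dict, populations, panel=None, normalized=True):
    """Build a small normalized table; unspecified panel loci are monomorphic 20.

    ``columns`` maps locus name -> list of repeat counts; all listed
    columns must share a length n, and every other locus of the panel is
    filled with 20s.
    """
    if panel is None:
        panel = PANEL_15
    n = len(next(iter(columns.values()))) if columns else len(populations)
    reps = {}
    for locus in panel:
        reps[locus] = list(columns.get(locus, [20] * n))
    if isinstance(populations, str):
        populations = [populations] * n
    data = pd.DataFrame(reps, index=[f"S{i+1}" for i in range(n)])
    data = data.astype("Int64")
    data.insert(0, "Population", populations)
    data.index.name = "SampleID"
    return HaplotypeTable(data=data, panel=tuple(panel), normalized=normalized)


@pytest.fixture
def raw_tsv_17(tmp_path):
    """A 3-record, 17-locus un-normalized haplotype TSV on disk."""
    header = "SampleID\tPopulation\t" + "\t".join(YFILER_17)
    rows = []
    base = {l: 20 for l in YFILER_17}
    base.update({"DYS389I": 13, "DYS389II": 29, "DYS385a": 14, "DYS385b": 18})
    for i, pop in enumerate(["Tonga", "Tonga", "Amis"]):
        vals = dict(base)
        vals["DYS391"] = 10 + i
        rows.append(
            f"IND{i+1}\t{pop}\t" + "\t".join(str(vals[l]) for l in YFILER_17)
        )
    path = tmp_path / "haps.tsv"
    path.write_text(header + "\n" + "\n".join(rows) + "\n", encoding="utf-8")
    return path


@pytest.fixture
def rates_tsv(tmp_path):
    from ystrpop import SYNTHETIC_RATES

    path = tmp_path / "rates.tsv"
    lines = ["Locus\tRate"] + [f"{l}\t{r}" for l, r in SYNTHETIC_RATES.items()]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


@pytest.fixture
def two_pop_table():
    """Two clearly separated populations, complete, normalized."""
    rng = np.random.default_rng(7)
    n = 12
    cols_a = {"DYS391": list(10 + rng.integers(0, 2, n))}
    cols_b = {"DYS391": list(14 + rng.integers(0, 2, n))}
    a = make_table(cols_a, "A")
    b = make_table(cols_b, "B")
    data = pd.concat([a.data, b.data])
    data.index = [f"S{i+1}" for i in range(2 * n)]
    data.index.name = "SampleID"
    return HaplotypeTable(data=data, panel=a.panel, normalized=True)
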