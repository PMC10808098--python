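"""Stepwise-mutation-model simulation of Y-STR haplotype tables.

Generates integer repeat-count haplotypes on star or Kingman-coalescent
genealogies under a symmetric single-step mutation model: per locus,
the number of mutations on a lineage of length t generations is
Poisson(μ_l·t) and each mutation moves the repeat count by ±1 with
probability ½. A two-population split mode produces tables for Rst
calibration.

Star genealogies (all lineages independent from the founder) are the
regime in which rho dating is unbiased; the Kingman mode exposes the
correlated-genealogy regime where founder-based estimators are
downwardly biased. Both are bit-reproducible under a fixed seed and
emit tables that pass io validation unchanged.

The bundled 15-locus rate set is SYNTHETIC: plausible per-locus values
on the Yfiler panel (slow markers near 1e-4–1e-3, fast ones up to
~6e-3; total ≈ 0.034/haplotype/generation), for simulation defaults
and examples only — real dating should use a user-supplied,
provenance-labelled rate table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError
from .io import HaplotypeTable, MutationRateTable
from .loci import MAX_REPEAT, MIN_REPEAT, PANEL_15

#: Synthetic per-locus mutation rates (mutations/locus/generation) on the
#: normalized 15-locus panel. Values are invented but realistic in rank
#: and magnitude for Y-STR markers; labelled synthetic on purpose.
SYNTHETIC_RATES: dict[str, float] = {
    "DYS19": 0.0015,
    "DYS389I": 0.0019,
    "DYS389II": 0.0025,
    "DYS390": 0.0021,
    "DYS391": 0.0026,
    "DYS392": 0.0004,
    "DYS393": 0.0008,
    "DYS437": 0.0010,
    "DYS438": 0.0003,
    "DYS439": 0.0048,
    "DYS448": 0.0015,
    "DYS456": 0.0042,
    "DYS458": 0.0063,
    "DYS635": 0.0021,
    "GATA_H4": 0.0026,
}


def synthetic_rate_table() -> MutationRateTable:
    """The bundled synthetic rate set as a MutationRateTable."""
    return MutationRateTable(
        rates=dict(SYNTHETIC_RATES), source_label="synthetic (bundled with ystrpop)"
    )


@dataclass
class SimulationConfig:
    """One population's simulation settings.

    Parameters
    ----------
    n : int
        Sample size (lineages).
    loci : dict of str -> float
        Locus name → per-generation mutation rate.
    tmrca : float
        Genealogical depth in generations.
    genealogy : {"star", "kingman"}
    founder : sequence of int or None
        Root repeat vector (default: all 20).
    population_label : str
    seed : int or None
    """

    n: int
    loci: dict[str, float] = field(
        default_factory=lambda: dict(SYNTHETIC_RATES)
    )
    tmrca: float = 100.0
    genealogy: str = "star"
    founder: tuple[int, ...] | None = None
    population_label: str = "POP"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("n must be >= 1")
        if self.tmrca < 0:
            raise ValidationError("tmrca must be >= 0")
        if self.genealogy not in ("star", "kingman"):
            raise ValidationError(f"unknown genealogy {self.genealogy!r}")
        for locus, rate in self.loci.items():
            if rate < 0:
                raise ValidationError(f"negative rate for {locus}")
        if self.founder is None:
            self.founder = tuple([20] * len(self.loci))
        elif len(self.founder) != len(self.loci):
            raise ValidationError("founder length must match locus count")

    @property
    def panel(self) -> tuple[str, ...]:
        return tuple(self.loci)

    @property
    def mu(self) -> np.ndarray:
        return np.array(list(self.loci.values()), dtype=float)


@dataclass
class SplitConfig:
    """Two-population divergence settings for Rst calibration.

    The two population founders diverge from a common ancestral
    haplotype ``split_time`` generations before each population's own
    founder (so the founders are separated by 2·split_time of
    independent drift); each population then evolves below its founder
    with its configured genealogy and depth. ``split_time = 0`` makes
    the two samples draws from a single population.
    """

    pop_a: SimulationConfig
    pop_b: SimulationConfig
    split_time: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.split_time < 0:
            raise ValidationError("split_time must be >= 0")
        if self.pop_a.panel != self.pop_b.panel:
            raise ValidationError("populations must share a locus panel")


def _step_displacements(
    rng: np.random.Generator, lam: np.ndarray, size: tuple
) -> np.ndarray:
    """Net ±1 random-walk displacement after Poisson(lam) mutations."""
    counts = rng.poisson(np.broadcast_to(lam, size))
    up = rng.binomial(counts, 0.5)
    return 2 * up - counts


def _clip_repeats(values: np.ndarray) -> np.ndarray:
    # keeps tables inside the validated repeat range; at realistic μT the
    # clip probability is negligible, so SMM moments are unaffected
    return np.clip(values, MIN_REPEAT, MAX_REPEAT)


def simulate_star(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> HaplotypeTable:
    """Star genealogy: n independent lineages of length tmrca."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    founder = np.asarray(config.founder, dtype=np.int64)
    disp = _step_displacements(
        rng, config.mu * config.tmrca, (config.n, len(config.loci))
    )
    repeats = _clip_repeats(founder[None, :] + disp)
    return HaplotypeTable.from_arrays(
        repeats,
        panel=config.panel,
        populations=config.population_label,
        sample_ids=[f"{config.population_label}_{i + 1:04d}" for i in range(config.n)],
        normalized=True,
    )


# ----------------------------------------------------------------------
# Kingman coalescent
# ----------------------------------------------------------------------
def _kingman_tree(
    n: int, rng: np.random.Generator
) -> tuple[list[int], list[float], int]:
    """Draw a Kingman n-coalescent.

    Returns (parent, node_time, root) over 2n−1 nodes: leaves 0..n−1 at
    time 0, internal nodes in coalescence order, times in coalescent
    units (pairwise rate 1).
    """
    parent = [-1] * (2 * n - 1)
    node_time = [0.0] * (2 * n - 1)
    active = list(range(n))
    t = 0.0
    next_node = n
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        a, b = active[i], active[j]
        parent[a] = parent[b] = next_node
        node_time[next_node] = t
        active = [x for idx, x in enumerate(active) if idx not in (i, j)]
        active.append(next_node)
        next_node += 1
    return parent, node_time, next_node - 1


def _tree_to_newick(
    parent: list[int], node_time: list[float], root: int, labels: list[str]
) -> str:
    children: dict[int, list[int]] = {}
    for child, p in enumerate(parent):
        if p >= 0:
            children.setdefault(p, []).append(child)

    def render(node: int) -> str:
        length = (
            node_time[parent[node]] - node_time[node] if parent[node] >= 0 else 0.0
        )
        if node not in children:
            return f"{labels[node]}:{length:.6g}"
        inner = ",".join(render(c) for c in children[node])
        return f"({inner}):{length:.6g}"

    return render(root) + ";"


def simulate_kingman(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    fixed_depth: bool = True,
    return_tree: bool = False,
):
    """Kingman coalescent genealogy with SMM mutations on branches.

    With ``fixed_depth`` (default) the drawn tree is rescaled so the
    root sits exactly ``tmrca`` generations in the past, which makes
    the configured depth exact rather than an expectation. Mutations
    per branch and locus are Poisson(μ_l × branch length).

    Returns the table, or ``(table, newick)`` when ``return_tree``.
    """
    if config.n < 2:
        raise ValidationError("kingman mode needs n >= 2")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    parent, node_time, root = _kingman_tree(config.n, rng)
    depth = node_time[root]
    scale = (config.tmrca / depth) if (fixed_depth and depth > 0) else 1.0
    times = [t * scale for t in node_time]

    L = len(config.loci)
    mu = config.mu
    values = np.zeros((2 * config.n - 1, L), dtype=np.int64)
    values[root] = np.asarray(config.founder, dtype=np.int64)
    # walk root -> leaves in reverse creation order (parents precede children)
    for node in sorted(range(2 * config.n - 1), key=lambda x: -times[x]):
        if node == root:
            continue
        branch = times[parent[node]] - times[node]
        disp = _step_displacements(rng, mu * branch, (L,))
        values[node] = values[parent[node]] + disp

    sample_ids = [
        f"{config.population_label}_{i + 1:04d}" for i in range(config.n)
    ]
    table = HaplotypeTable.from_arrays(
        _clip_repeats(values[: config.n]),
        panel=config.panel,
        populations=config.population_label,
        sample_ids=sample_ids,
        normalized=True,
    )
    if return_tree:
        return table, _tree_to_newick(parent, times, root, sample_ids)
    return table


def simulate_split(config: SplitConfig) -> HaplotypeTable:
    """Two diverged populations in one table (for Rst calibration)."""
    rng = np.random.default_rng(config.seed)
    shared = np.asarray(config.pop_a.founder, dtype=np.int64)
    L = len(config.pop_a.loci)

    tables = []
    for pop_cfg in (config.pop_a, config.pop_b):
        drift = _step_displacements(rng, pop_cfg.mu * config.split_time, (L,))
        pop_founder = tuple(int(x) for x in _clip_repeats(shared + drift))
        cfg = SimulationConfig(
            n=pop_cfg.n,
            loci=dict(pop_cfg.loci),
            tmrca=pop_cfg.tmrca,
            genealogy=pop_cfg.genealogy,
            founder=pop_founder,
            population_label=pop_cfg.population_label,
        )
        sim = simulate_star if cfg.genealogy == "star" else simulate_kingman
        tables.append(sim(cfg, rng=rng))

    import pandas as pd

    data = pd.concat([t.data for t in tables])
    return HaplotypeTable(
        data=data, panel=config.pop_a.panel, normalized=True
    )


__all__ = [
    "SYNTHETIC_RATES",
    "synthetic_rate_table",
    "SimulationConfig",
    "SplitConfig",
    "simulate_star",
    "simulate_kingman",
    "simulate_split",
]
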