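"""Structured-coalescent simulator for synthetic genotype datasets.

Generates the study conditions the analysis modules assume: population
splits, piecewise-constant sizes (bottlenecks), continuous migration, a
localized admixture pulse from a donor into a recipient population, and
neutral vs. deleterious site classes with distinct frequency spectra.

The genealogy simulator is a standard structured Kingman coalescent run
backward in time: within a population of diploid size N, each pair of
lineages coalesces at rate 1/(2N) per generation; each lineage migrates
from population p to q at the backward rate m[p, q]; at an admixture pulse
(forward-time source -> recipient with fraction f) every lineage currently
in the recipient jumps to the source with probability f; at a split the
derived population's lineages move into the ancestral population.
Mutations follow the infinite-sites model: Poisson on total branch length,
placed uniformly on branches, each at a unique position.  Windows are
independent genealogies (no intra-window recombination).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, PopulationMap, SiteRecord, ValidationError
from .mutation_load import DELETERIOUS_LABELS, NEUTRAL_LABELS


# ---------------------------------------------------------------------------
# Demography
# ---------------------------------------------------------------------------


@dataclass
class DemographyModel:
    """Populations with diploid sizes and the events joining them.

    populations  : name -> present-day diploid size N
    splits       : (time_generations, derived, ancestral) — backward in time
                   the derived population's lineages join the ancestral one
    migration    : (from_pop, to_pop) -> backward per-lineage rate/generation
    pulses       : (time, source, recipient, fraction f) — forward-time
                   admixture of fraction f from source into recipient
    size_changes : (time, pop, new_diploid_size) applying backward from time
    """

    populations: dict[str, float]
    splits: list[tuple[float, str, str]] = field(default_factory=list)
    migration: dict[tuple[str, str], float] = field(default_factory=dict)
    pulses: list[tuple[float, str, str, float]] = field(default_factory=list)
    size_changes: list[tuple[float, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, n in self.populations.items():
            if n <= 0:
                raise ValidationError(f"population {name!r} size must be positive")
        for t, d, a in self.splits:
            if t <= 0:
                raise ValidationError("split times must be strictly positive")
            for p in (d, a):
                if p not in self.populations:
                    raise ValidationError(f"split references unknown population {p!r}")
        for t, s, r, f in self.pulses:
            if t <= 0:
                raise ValidationError("pulse times must be strictly positive")
            if not 0.0 <= f <= 1.0:
                raise ValidationError("pulse fraction must be in [0, 1]")
            for p in (s, r):
                if p not in self.populations:
                    raise ValidationError(f"pulse references unknown population {p!r}")
        for (p, q), m in self.migration.items():
            if m < 0:
                raise ValidationError("migration rates must be non-negative")
            for x in (p, q):
                if x not in self.populations:
                    raise ValidationError(f"migration references unknown population {x!r}")

    def validate_terminating(self) -> None:
        """All populations must be joined by splits or positive migration."""
        if len(self.populations) == 1:
            return
        adj: dict[str, set[str]] = {p: set() for p in self.populations}
        for _, d, a in self.splits:
            adj[d].add(a)
            adj[a].add(d)
        for (p, q), m in self.migration.items():
            if m > 0:
                adj[p].add(q)
                adj[q].add(p)
        seen = set()
        stack = [next(iter(self.populations))]
        while stack:
            p = stack.pop()
            if p in seen:
                continue
            seen.add(p)
            stack.extend(adj[p] - seen)
        if seen != set(self.populations):
            raise ValidationError(
                "demography does not terminate: populations "
                f"{sorted(set(self.populations) - seen)} are never joined"
            )


@dataclass
class SimParams:
    """Simulation run parameters; the seed fixes all randomness."""

    samples_per_population: dict[str, int]  # diploid individuals
    mu: float  # per site per generation
    window_length: int
    n_windows: int
    seed: int
    chrom: str = "chr1"
    #: window indices (0-based) where pulses apply; None = all windows
    pulse_windows: set[int] | None = None

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValidationError("mutation rate must be non-negative")
        if self.window_length < 1 or self.n_windows < 0:
            raise ValidationError("window dimensions must be positive")
        for p, n in self.samples_per_population.items():
            if n < 1:
                raise ValidationError(f"need >= 1 diploid sample in {p!r}")


# ---------------------------------------------------------------------------
# Genealogy
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    id: int
    time: float
    population: str | None
    children: tuple[int, ...] = ()


@dataclass
class GenealogyTree:
    """Binary rooted coalescent tree over sampled haploid lineages."""

    nodes: list[TreeNode]  # tips first (ids 0..n-1), internal nodes appended
    n_tips: int
    root: int
    tip_populations: list[str]
    event_log: list[tuple] = field(default_factory=list)

    @property
    def tmrca(self) -> float:
        return self.nodes[self.root].time

    def total_branch_length(self) -> float:
        total = 0.0
        for node in self.nodes:
            for c in node.children:
                total += node.time - self.nodes[c].time
        return total

    def branches(self) -> list[tuple[int, float]]:
        """(child node id, branch length) for every non-root node."""
        out = []
        for node in self.nodes:
            for c in node.children:
                out.append((c, node.time - self.nodes[c].time))
        return out

    def tips_below(self, node_id: int) -> list[int]:
        out: list[int] = []
        stack = [node_id]
        while stack:
            x = stack.pop()
            node = self.nodes[x]
            if not node.children:
                out.append(x)
            else:
                stack.extend(node.children)
        return sorted(out)


def simulate_genealogy(
    model: DemographyModel,
    samples: dict[str, int],
    rng: np.random.Generator,
    haploid: bool = False,
) -> GenealogyTree:
    """Simulate one genealogy under the structured coalescent.

    ``samples`` gives diploid individuals per population (two haploid
    lineages each) unless ``haploid`` is set.  Returns the tree with an
    event log of migrations, pulses and splits.
    """
    model.validate_terminating()
    sizes = dict(model.populations)

    nodes: list[TreeNode] = []
    tip_pops: list[str] = []
    active: dict[int, str] = {}  # node id -> current population
    for pop, n_dip in samples.items():
        if pop not in model.populations:
            raise ValidationError(f"sampled population {pop!r} not in model")
        for _ in range(n_dip if haploid else 2 * n_dip):
            nid = len(nodes)
            nodes.append(TreeNode(id=nid, time=0.0, population=pop))
            tip_pops.append(pop)
            active[nid] = pop
    n_tips = len(nodes)
    if n_tips < 1:
        raise ValidationError("need at least one sampled lineage")

    events: list[tuple[float, int, tuple]] = []
    for t, d, a in model.splits:
        events.append((t, 1, ("split", d, a)))
    for t, s, r, f in model.pulses:
        events.append((t, 0, ("pulse", s, r, f)))
    for t, p, n in model.size_changes:
        events.append((t, 2, ("size", p, n)))
    events.sort(key=lambda e: (e[0], e[1]))

    log: list[tuple] = []
    t = 0.0
    ev_i = 0
    mig = {k: v for k, v in model.migration.items() if v > 0}

    while len(active) > 1:
        pop_counts: dict[str, int] = {}
        for p in active.values():
            pop_counts[p] = pop_counts.get(p, 0) + 1
        coal_rates = {
            p: k * (k - 1) / 2.0 / (2.0 * sizes[p])
            for p, k in pop_counts.items()
            if k >= 2
        }
        mig_rates = {
            (p, q): pop_counts.get(p, 0) * m
            for (p, q), m in mig.items()
            if pop_counts.get(p, 0) > 0
        }
        total = sum(coal_rates.values()) + sum(mig_rates.values())

        next_ev_t = events[ev_i][0] if ev_i < len(events) else np.inf
        if total == 0.0:
            if not np.isfinite(next_ev_t):
                raise ValidationError("simulation stalled: no rates and no events left")
            wait = np.inf
        else:
            wait = rng.exponential(1.0 / total)

        if t + wait >= next_ev_t:
            t = next_ev_t
            _, _, payload = events[ev_i]
            ev_i += 1
            kind = payload[0]
            if kind == "split":
                _, d, a = payload
                moved = [nid for nid, p in active.items() if p == d]
                for nid in moved:
                    active[nid] = a
                log.append(("split", t, d, a, len(moved)))
            elif kind == "pulse":
                _, s, r, f = payload
                in_r = [nid for nid, p in active.items() if p == r]
                moved = [nid for nid in in_r if rng.random() < f]
                for nid in moved:
                    active[nid] = s
                log.append(("pulse", t, s, r, len(moved), len(in_r)))
            else:
                _, p, n = payload
                sizes[p] = n
                log.append(("size", t, p, n))
            continue

        t += wait
        u = rng.random() * total
        acc = 0.0
        chosen = None
        for p, rate in coal_rates.items():
            acc += rate
            if u < acc:
                chosen = ("coal", p)
                break
        if chosen is None:
            last_key = None
            for key, rate in mig_rates.items():
                last_key = key
                acc += rate
                if u < acc:
                    chosen = ("mig", key)
                    break
            if chosen is None:  # float round-off at the upper edge
                if last_key is not None:
                    chosen = ("mig", last_key)
                else:
                    chosen = ("coal", max(coal_rates, key=coal_rates.get))

        if chosen[0] == "coal":
            p = chosen[1]
            in_p = [nid for nid, q in active.items() if q == p]
            pair = rng.choice(len(in_p), size=2, replace=False)
            c1, c2 = in_p[pair[0]], in_p[pair[1]]
            nid = len(nodes)
            nodes.append(
                TreeNode(id=nid, time=t, population=p, children=(c1, c2))
            )
            del active[c1], active[c2]
            active[nid] = p
        else:
            p, q = chosen[1]
            in_p = [nid for nid, x in active.items() if x == p]
            nid = in_p[int(rng.integers(len(in_p)))]
            active[nid] = q
            log.append(("migration", t, nid, p, q))

    root = next(iter(active))
    return GenealogyTree(
        nodes=nodes,
        n_tips=n_tips,
        root=root,
        tip_populations=tip_pops,
        event_log=log,
    )


def drop_mutations(
    tree: GenealogyTree,
    mu_per_site: float,
    length: int,
    rng: np.random.Generator,
) -> list[tuple[int, list[int]]]:
    """Infinite-sites mutations: (1-based position, carrier tip ids), sorted.

    The mutation count is Poisson(total branch length x mu x length); each
    mutation falls on a branch with probability proportional to its length
    and gets a unique position.
    """
    if mu_per_site < 0:
        raise ValidationError("mutation rate must be non-negative")
    branches = tree.branches()
    total_len = sum(b for _, b in branches)
    if total_len <= 0 or mu_per_site == 0:
        return []
    n_mut = int(rng.poisson(total_len * mu_per_site * length))
    if n_mut == 0:
        return []
    n_mut = min(n_mut, length)  # infinite-sites cap: one mutation per position
    weights = np.array([b for _, b in branches]) / total_len
    branch_idx = rng.choice(len(branches), size=n_mut, p=weights)
    positions = rng.choice(length, size=n_mut, replace=False) + 1
    out = [
        (int(pos), tree.tips_below(branches[bi][0]))
        for pos, bi in zip(positions, branch_idx)
    ]
    out.sort(key=lambda x: x[0])
    return out


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------


def simulate_dataset(
    model: DemographyModel, params: SimParams
) -> tuple[GenotypeMatrix, PopulationMap, pd.DataFrame]:
    """Simulate an n_windows x window_length diploid SNP dataset.

    One genealogy per window; diploids are formed by pairing consecutive
    haplotypes within a population.  Returns the genotype matrix, a
    population map, and a truth log (per-window TMRCA, pulse flag, site
    count).  Identical parameters and seed give bit-identical output.
    """
    rng = np.random.default_rng(params.seed)
    sample_names: list[str] = []
    assignment: dict[str, str] = {}
    for pop, n_dip in params.samples_per_population.items():
        for i in range(n_dip):
            name = f"{pop}_{i}"
            sample_names.append(name)
            assignment[name] = pop

    no_pulse_model = None
    if params.pulse_windows is not None and model.pulses:
        no_pulse_model = DemographyModel(
            populations=dict(model.populations),
            splits=list(model.splits),
            migration=dict(model.migration),
            pulses=[],
            size_changes=list(model.size_changes),
        )

    sites: list[SiteRecord] = []
    truth_rows = []
    for w in range(params.n_windows):
        pulse_active = model.pulses and (
            params.pulse_windows is None or w in params.pulse_windows
        )
        m = model if (pulse_active or no_pulse_model is None) else no_pulse_model
        tree = simulate_genealogy(m, params.samples_per_population, rng)
        muts = drop_mutations(tree, params.mu, params.window_length, rng)
        offset = w * params.window_length
        n_sites_w = 0
        for pos, carriers in muts:
            hap = np.zeros(tree.n_tips, dtype=np.int16)
            hap[carriers] = 1
            dosage = hap[0::2] + hap[1::2]
            sites.append(
                SiteRecord(
                    chrom=params.chrom,
                    pos=offset + pos,
                    ref_allele="A",
                    alt_allele="T",
                    genotypes=dosage,
                )
            )
            n_sites_w += 1
        truth_rows.append(
            {
                "window": w,
                "start": offset + 1,
                "end": offset + params.window_length,
                "tmrca": tree.tmrca,
                "pulse": bool(pulse_active),
                "n_sites": n_sites_w,
            }
        )
    matrix = GenotypeMatrix(samples=sample_names, sites=sites)
    popmap = PopulationMap(assignment=assignment)
    return matrix, popmap, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Reference scenarios
# ---------------------------------------------------------------------------
#
# The canned models below are the study conditions the statistical modules
# are validated against: a neutral constant-size population, a recent 10x
# bottleneck (the demographic signature of the focal butterfly species), and
# a four-taxon tree with a localized admixture pulse from the donor lineage
# into one recipient subspecies (the mimicry-locus introgression scenario).
# Population sizes and the mutation rate are Heliconius-like: Ne ~ 4 x 10^5
# diploids and mu = 2.9e-9 per site per generation, giving within-population
# diversity near the observed ~0.005/site.

HELICONIUS_MU = 2.9e-9
HELICONIUS_NE = 4.0e5


def constant_size_scenario(
    n_diploids: int = 6,
    n_windows: int = 1000,
    window_length: int = 10_000,
    theta_per_window: float = 10.0,
    seed: int = 0,
) -> tuple[DemographyModel, SimParams]:
    """Neutral single population; theta*L per window sets the mutation rate."""
    n = HELICONIUS_NE
    mu = theta_per_window / (4.0 * n * window_length)
    model = DemographyModel(populations={"P": n})
    params = SimParams(
        samples_per_population={"P": n_diploids},
        mu=mu,
        window_length=window_length,
        n_windows=n_windows,
        seed=seed,
    )
    return model, params


def bottleneck_scenario(
    n_diploids: int = 6,
    n_windows: int = 300,
    window_length: int = 10_000,
    seed: int = 0,
    drop: float = 10.0,
) -> tuple[DemographyModel, SimParams]:
    """Recent contraction: size N/drop since 0.1*2N generations ago.

    The surviving small population shows the bottleneck signature: positive
    Tajima's D and an intermediate-frequency excess in the unfolded SFS.
    """
    n_anc = HELICONIUS_NE
    t_drop = 0.1 * 2.0 * n_anc
    model = DemographyModel(
        populations={"P": n_anc / drop},
        size_changes=[(t_drop, "P", n_anc)],
    )
    params = SimParams(
        samples_per_population={"P": n_diploids},
        mu=HELICONIUS_MU,
        window_length=window_length,
        n_windows=n_windows,
        seed=seed,
    )
    return model, params


def quartet_introgression_scenario(
    pulse_fraction: float,
    n_windows: int = 200,
    window_length: int = 10_000,
    seed: int = 0,
    pulse_windows: set[int] | None = None,
    n_diploids: int = 4,
) -> tuple[DemographyModel, SimParams]:
    """Four-taxon tree (((P1, P2), P3), O) with a pulse from P3 into P2.

    Split times: subspecies pair at 1e6 generations, donor lineage at 2.5e6,
    outgroup at 6e6; the pulse hits P2 at 5e5 generations (after the
    subspecies split, emulating mimicry-allele introgression from the
    co-mimic donor into one subspecies).
    """
    n = HELICONIUS_NE
    model = DemographyModel(
        populations={"P1": n, "P2": n, "P3": n, "O": n},
        splits=[(1.0e6, "P2", "P1"), (2.5e6, "P3", "P1"), (6.0e6, "O", "P1")],
        pulses=(
            [(5.0e5, "P3", "P2", pulse_fraction)] if pulse_fraction > 0 else []
        ),
    )
    params = SimParams(
        samples_per_population={"P1": n_diploids, "P2": n_diploids,
                                "P3": n_diploids, "O": n_diploids},
        mu=HELICONIUS_MU,
        window_length=window_length,
        n_windows=n_windows,
        seed=seed,
        pulse_windows=pulse_windows,
    )
    return model, params


# ---------------------------------------------------------------------------
# SFS fabrication for the mutation-load pipeline
# ---------------------------------------------------------------------------


def sample_sfs_sites(
    n_chromosomes: int,
    class_weights: np.ndarray,
    n_sites: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw derived-allele counts from a normalized weight distribution over
    frequency classes 1..len(class_weights)."""
    w = np.asarray(class_weights, dtype=float)
    if (w < 0).any() or w.sum() == 0:
        raise ValidationError("class weights must be non-negative and not all zero")
    if len(w) > n_chromosomes:
        raise ValidationError("more weight classes than chromosomes")
    if n_sites == 0:
        return np.empty(0, dtype=np.int64)
    return rng.choice(np.arange(1, len(w) + 1), size=n_sites, p=w / w.sum())


def neutral_class_weights(n_chromosomes: int) -> np.ndarray:
    """Neutral-equilibrium weights over polymorphic classes: 1/i."""
    return 1.0 / np.arange(1, n_chromosomes)


def annotate_sites(
    sites: list[tuple[str, int]],
    deleterious_fraction: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Fabricate an effect-annotation table over (chrom, pos) sites: each site
    deleterious with the given probability, labels drawn uniformly from the
    class vocabulary."""
    if not 0.0 <= deleterious_fraction <= 1.0:
        raise ValidationError("deleterious fraction must be in [0, 1]")
    neutral = sorted(NEUTRAL_LABELS)
    deleterious = sorted(DELETERIOUS_LABELS)
    rows = []
    for chrom, pos in sites:
        if rng.random() < deleterious_fraction:
            label = deleterious[int(rng.integers(len(deleterious)))]
        else:
            label = neutral[int(rng.integers(len(neutral)))]
        rows.append({"chrom": chrom, "pos": pos, "effect": label})
    return pd.DataFrame(rows, columns=["chrom", "pos", "effect"])
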