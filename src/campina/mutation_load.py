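"""Derived-allele mutation-load analysis.

Polarizes biallelic SNPs against outgroup samples (ancestral = strict
majority of outgroup allele copies, all outgroup samples called), classifies
derived variants as neutral or deleterious from their functional-effect
labels, builds unfolded site-frequency spectra split by effect class,
tabulates fixed derived substitutions per population, and compares
deleterious fractions between populations with Pearson chi-square tests.

Under neutrality at equilibrium the unfolded SFS has expected class
proportions proportional to 1/i; a recent bottleneck inflates intermediate
and high frequency classes, and a raised deleterious fraction of fixed
substitutions indicates inefficient purifying selection in a small
population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import (
    MISSING,
    GenotypeMatrix,
    PopulationMap,
    SiteRecord,
    ValidationError,
)

NEUTRAL_LABELS = frozenset({"synonymous_variant", "intron_variant", "NONE"})
DELETERIOUS_LABELS = frozenset({"missense_variant", "start_lost", "stop_gained"})


@dataclass
class PolarizedSite:
    """A site with an assigned ancestral allele and per-population derived counts."""

    chrom: str
    pos: int
    ancestral: str  # "ref" or "alt"
    #: population -> (called allele copies n, derived copies k)
    derived_counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    #: population -> every called individual carries >= 1 derived copy
    derived_in_all_individuals: dict[str, bool] = field(default_factory=dict)
    effect_class: str = "excluded"


@dataclass
class SiteFrequencySpectrum:
    """Unfolded SFS: counts[i-1] = number of sites with derived count i,
    for i in 1..n (the last class is fixed derived)."""

    n_chromosomes: int
    counts: np.ndarray
    effect_class: str

    @property
    def proportions(self) -> np.ndarray:
        total = self.counts.sum()
        return self.counts / total if total > 0 else self.counts.astype(float)


def polarize(
    site: SiteRecord,
    outgroup_samples: list[str],
    matrix: GenotypeMatrix,
) -> str | None:
    """Ancestral allele ("ref"/"alt") from the outgroup, or None (unassigned).

    Requires every outgroup sample called; the ancestral allele is the one
    carried by a strict majority of outgroup allele copies; ties are
    unassigned.
    """
    idx = matrix.sample_index(outgroup_samples)
    g = site.genotypes[idx]
    if (g == MISSING).any():
        return None
    alt_copies = int(g.sum())
    ref_copies = 2 * g.size - alt_copies
    if alt_copies > ref_copies:
        return "alt"
    if ref_copies > alt_copies:
        return "ref"
    return None


def classify_effect(annotation: str | None) -> str:
    """neutral | deleterious | excluded, by exact effect-label membership."""
    if annotation in NEUTRAL_LABELS:
        return "neutral"
    if annotation in DELETERIOUS_LABELS:
        return "deleterious"
    return "excluded"


def polarize_sites(
    matrix: GenotypeMatrix,
    outgroup_samples: list[str],
    populations: list[str],
    popmap: PopulationMap,
    annotations: dict[tuple[str, int], str] | None = None,
) -> list[PolarizedSite]:
    """Polarize every site in the matrix; unassignable sites are skipped.

    Derived counts are computed per target population (derived = the
    non-ancestral allele).  Effect labels come from ``annotations`` keyed by
    (chrom, pos) or, failing that, from each site's own annotation field.
    """
    pop_idx = {
        p: matrix.sample_index(popmap.samples_in(p)) for p in populations
    }
    out: list[PolarizedSite] = []
    for site in matrix.sites:
        anc = polarize(site, outgroup_samples, matrix)
        if anc is None:
            continue
        label = None
        if annotations is not None:
            label = annotations.get((site.chrom, site.pos))
        if label is None:
            label = site.annotation
        counts: dict[str, tuple[int, int]] = {}
        in_all: dict[str, bool] = {}
        for p, idx in pop_idx.items():
            g = site.genotypes[idx]
            called = g != MISSING
            n = 2 * int(called.sum())
            alt = int(g[called].sum())
            k = alt if anc == "ref" else n - alt
            counts[p] = (n, k)
            gg = g[called]
            derived_dosage = gg if anc == "ref" else 2 - gg
            in_all[p] = bool(n > 0 and (derived_dosage >= 1).all())
        out.append(
            PolarizedSite(
                chrom=site.chrom,
                pos=site.pos,
                ancestral=anc,
                derived_counts=counts,
                derived_in_all_individuals=in_all,
                effect_class=classify_effect(label),
            )
        )
    return out


def derived_sfs(
    polarized: list[PolarizedSite],
    population: str,
    n_chromosomes: int,
    effect_class: str | None = None,
) -> SiteFrequencySpectrum:
    """Unfolded SFS for one population at fixed sample size ``n_chromosomes``.

    Only sites with exactly ``n_chromosomes`` called allele copies contribute
    (no projection/downsampling); sites where the derived allele is absent
    are excluded.
    """
    if n_chromosomes < 2:
        raise ValidationError("SFS needs n_chromosomes >= 2")
    counts = np.zeros(n_chromosomes, dtype=np.int64)
    for ps in polarized:
        if effect_class is not None and ps.effect_class != effect_class:
            continue
        n, k = ps.derived_counts.get(population, (0, 0))
        if n != n_chromosomes or k == 0:
            continue
        counts[k - 1] += 1
    return SiteFrequencySpectrum(
        n_chromosomes=n_chromosomes,
        counts=counts,
        effect_class=effect_class or "all",
    )


def neutral_sfs_expectation(n_chromosomes: int) -> np.ndarray:
    """Expected neutral proportions of the polymorphic SFS classes 1..n-1:
    (1/i) / a_{n-1} with a_{n-1} = sum_{i=1}^{n-1} 1/i."""
    i = np.arange(1, n_chromosomes)
    w = 1.0 / i
    return w / w.sum()


def fixed_in_population(
    polarized_site: PolarizedSite,
    population: str,
    per_individual: bool = False,
) -> bool | None:
    """Is the derived allele fixed in the population?

    Default: derived frequency 1 among called allele copies (the standard
    substitution definition).  With ``per_individual=True``, the literal
    reading — at least one derived copy in every called individual — is used
    instead.  ``None`` when the population has no called alleles.
    """
    n, k = polarized_site.derived_counts.get(population, (0, 0))
    if n == 0:
        return None
    if per_individual:
        return polarized_site.derived_in_all_individuals.get(population, False)
    return k == n


def substitution_table(
    polarized: list[PolarizedSite],
    populations: list[str],
    per_individual: bool = False,
) -> pd.DataFrame:
    """Fixed derived alleles per population split by effect class, with the
    deleterious fraction deleterious/(deleterious + neutral)."""
    if not polarized:
        raise ValidationError("no polarized sites")
    rows = []
    for pop in populations:
        counts = {"neutral": 0, "deleterious": 0}
        for ps in polarized:
            if ps.effect_class not in counts:
                continue
            if fixed_in_population(ps, pop, per_individual=per_individual):
                counts[ps.effect_class] += 1
        total = counts["neutral"] + counts["deleterious"]
        frac = counts["deleterious"] / total if total > 0 else np.nan
        rows.append(
            {
                "population": pop,
                "neutral_fixed": counts["neutral"],
                "deleterious_fixed": counts["deleterious"],
                "deleterious_fraction": frac,
            }
        )
    return pd.DataFrame(rows)


def pearson_chi_square(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on an r x c count table.

    Returns (chi2, df, p); no continuity correction, matching the plain
    chi-square comparisons of substitution-class counts.
    """
    table = np.asarray(table, dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValidationError("contingency table has a zero margin")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


def read_annotations(path: str) -> dict[tuple[str, int], str]:
    """Read a chrom<TAB>pos<TAB>effect annotation table."""
    out: dict[tuple[str, int], str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if ln == 1 and parts[0].lower() == "chrom":
                continue
            if len(parts) < 3:
                raise ValidationError(f"{path}:{ln}: expected 3 columns")
            out[(parts[0], int(parts[1]))] = parts[2]
    return out
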