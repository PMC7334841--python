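"""Four-taxon introgression statistics: Patterson's D, f_d, jackknife, dating.

The ABBA-BABA framework compares the two discordant site patterns on the
tree (((P1, P2), P3), O).  Under incomplete lineage sorting alone ABBA and
BABA are equally frequent; an excess of ABBA (derived allele shared by P2
and P3) indicates gene flow between P2 and P3.  All statistics here use the
frequency-weighted formulation: per-site derived-allele frequencies rather
than fixed patterns, with the outgroup contributing weight (1 - p4) even
when polymorphic.

f_d normalises the D numerator by its value under complete sharing, using a
per-site donor proxy (whichever of P2/P3 has the higher derived frequency),
giving a window-scale estimate of the admixture fraction.

Uncertainty for genome-wide D comes from a delete-one block jackknife over
contiguous blocks (default 20 blocks, so each pseudo-replicate keeps 95% of
the data), which respects linkage within blocks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .genotype_io import (
    MISSING,
    GenotypeMatrix,
    PopulationMap,
    SiteRecord,
    ValidationError,
    iter_windows,
)
from .window_stats import MIN_CALLED_ALLELES

DEFAULT_N_BLOCKS = 20
DEFAULT_PEAK_Z = 4.0


@dataclass(frozen=True)
class QuartetFrequencies:
    """Per-site derived-allele frequencies for taxa ordered (P1, P2, P3, O)."""

    chrom: str
    pos: int
    p1: float
    p2: float
    p3: float
    p4: float

    def __post_init__(self) -> None:
        for f in (self.p1, self.p2, self.p3, self.p4):
            if not 0.0 <= f <= 1.0:
                raise ValidationError(f"frequency {f} outside [0, 1]")


@dataclass
class JackknifeEstimate:
    mean: float
    sd: float
    n_blocks: int
    z: float | None


def quartet_frequencies(
    sites: Sequence[SiteRecord],
    pops: tuple[str, str, str, str],
    popmap: PopulationMap,
    matrix_samples: list[str],
    min_alleles: int = MIN_CALLED_ALLELES,
) -> list[QuartetFrequencies]:
    """Derived (alternate) allele frequencies per site for a (P1, P2, P3, O)
    quartet; sites with < ``min_alleles`` called copies in any taxon are
    dropped."""
    idx = [
        np.array([matrix_samples.index(s) for s in popmap.samples_in(p)], dtype=int)
        for p in pops
    ]
    out: list[QuartetFrequencies] = []
    for site in sites:
        freqs = []
        for ix in idx:
            g = site.genotypes[ix]
            called = g != MISSING
            n = 2 * int(called.sum())
            if n < min_alleles:
                freqs = None
                break
            freqs.append(float(g[called].sum()) / n)
        if freqs is not None:
            out.append(QuartetFrequencies(site.chrom, site.pos, *freqs))
    return out


def site_pattern_sums(
    quartet_sites: Sequence[QuartetFrequencies],
) -> tuple[float, float]:
    """Frequency-weighted ABBA and BABA sums."""
    abba = 0.0
    baba = 0.0
    for q in quartet_sites:
        abba += (1.0 - q.p1) * q.p2 * q.p3 * (1.0 - q.p4)
        baba += q.p1 * (1.0 - q.p2) * q.p3 * (1.0 - q.p4)
    return abba, baba


def patterson_d(abba_sum: float, baba_sum: float) -> float | None:
    """D = (ABBA - BABA) / (ABBA + BABA); None when the total is zero."""
    total = abba_sum + baba_sum
    if total == 0.0:
        return None
    return (abba_sum - baba_sum) / total


def fd_window(quartet_sites: Sequence[QuartetFrequencies]) -> float | None:
    """Martin et al. (2015) f_d: the D numerator normalised by its value with
    the donor maximised per site; clamped to >= 0, None when the denominator
    vanishes."""
    num = 0.0
    den = 0.0
    for q in quartet_sites:
        num += (1.0 - q.p1) * q.p2 * q.p3 * (1.0 - q.p4) - q.p1 * (1.0 - q.p2) * (
            q.p3
        ) * (1.0 - q.p4)
        pd_ = max(q.p2, q.p3)
        den += (1.0 - q.p1) * pd_ * pd_ * (1.0 - q.p4) - q.p1 * (1.0 - pd_) * pd_ * (
            1.0 - q.p4
        )
    if den == 0.0:
        return None
    if num < 0.0:  # BABA excess: negative f_d is meaningless, set to 0
        return 0.0
    return max(num / den, 0.0)


def block_jackknife(
    per_block_sums: Sequence[tuple[float, ...]],
    statistic: Callable[..., float | None],
) -> JackknifeEstimate:
    """Delete-one block jackknife for a statistic of summed components.

    ``per_block_sums`` holds one tuple of component sums (e.g. (abba, baba))
    per contiguous block; ``statistic`` maps total component sums to the
    estimate.  The reported mean is the statistic on the full sums; the SD is
    the standard delete-one jackknife estimate over the m leave-out values.
    """
    m = len(per_block_sums)
    if m < 2:
        raise ValidationError("block jackknife needs >= 2 blocks")
    arr = np.asarray(per_block_sums, dtype=float)
    totals = arr.sum(axis=0)
    mean = statistic(*totals)
    if mean is None:
        raise ValidationError("statistic undefined on the full data")
    loo = []
    for j in range(m):
        t = totals - arr[j]
        v = statistic(*t)
        if v is None:
            raise ValidationError(f"statistic undefined when dropping block {j}")
        loo.append(v)
    loo_arr = np.array(loo)
    if np.all(loo_arr == loo_arr[0]):  # sd exactly 0 iff all leave-outs equal
        sd = 0.0
    else:
        sd = float(np.sqrt((m - 1.0) / m * np.sum((loo_arr - loo_arr.mean()) ** 2)))
    z = mean / sd if sd > 0 else None
    return JackknifeEstimate(mean=float(mean), sd=sd, n_blocks=m, z=z)


def partition_blocks(
    items: Sequence, n_blocks: int = DEFAULT_N_BLOCKS
) -> list[list]:
    """Contiguous, near-equal-count partition of an ordered site sequence."""
    if n_blocks < 2:
        raise ValidationError("need >= 2 blocks")
    if len(items) < n_blocks:
        raise ValidationError("fewer items than blocks")
    edges = np.linspace(0, len(items), n_blocks + 1).astype(int)
    return [list(items[edges[i] : edges[i + 1]]) for i in range(n_blocks)]


def genome_wide_d(
    quartet_sites: Sequence[QuartetFrequencies],
    n_blocks: int = DEFAULT_N_BLOCKS,
) -> JackknifeEstimate:
    """Genome-wide Patterson's D (ratio of summed patterns) with block-jackknife
    mean, SD and Z over contiguous equal-count blocks."""
    blocks = partition_blocks(quartet_sites, n_blocks)
    per_block = [site_pattern_sums(b) for b in blocks]
    return block_jackknife(per_block, patterson_d)


def divergence_ratio_timing(
    d_focal: float, d_genomewide: float, t_div: float | None = None
) -> tuple[float, float | None]:
    """Date an introgressed haplotype by its divergence relative to the genome:
    ratio = d_focal / d_genomewide, and ratio * t_div (Myr) when supplied."""
    if d_genomewide <= 0:
        raise ValidationError("genome-wide divergence must be positive")
    ratio = d_focal / d_genomewide
    return ratio, (ratio * t_div if t_div is not None else None)


def scan_peaks(
    values: Sequence[float],
    z_threshold: float = DEFAULT_PEAK_Z,
    merge_gap: int = 0,
) -> list[tuple[int, int, int]]:
    """Flag windows whose robust z-score (median/MAD) exceeds the threshold and
    merge flagged windows within ``merge_gap``; returns (start_idx, end_idx,
    argmax_idx) triples over window indices.  NaN values never flag."""
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 2:
        raise ValidationError("need >= 2 defined values to call peaks")
    med = float(np.median(x[finite]))
    mad = float(np.median(np.abs(x[finite] - med)))
    if mad > 0:
        z = (x - med) / (1.4826 * mad)
    else:
        import logging

        # MAD degenerates when most values tie (common for clamped f_d);
        # next-most-robust scale: mean absolute deviation about the median,
        # scaled for normal consistency. Mean/SD only when all values tie.
        meanad = float(np.mean(np.abs(x[finite] - med)))
        if meanad > 0:
            z = (x - med) / (np.sqrt(np.pi / 2.0) * meanad)
        else:
            logging.getLogger("campina").warning(
                "scan_peaks: all values identical, falling back to mean/SD z-scores"
            )
            sd = float(np.std(x[finite]))
            if sd == 0:
                return []
            z = (x - float(np.mean(x[finite]))) / sd
    flagged = np.where(finite & (z >= z_threshold))[0]
    if flagged.size == 0:
        return []
    peaks: list[tuple[int, int, int]] = []
    start = prev = int(flagged[0])
    for i in flagged[1:]:
        i = int(i)
        if i - prev - 1 <= merge_gap:
            prev = i
        else:
            seg = slice(start, prev + 1)
            peaks.append((start, prev, start + int(np.nanargmax(x[seg]))))
            start = prev = i
    seg = slice(start, prev + 1)
    peaks.append((start, prev, start + int(np.nanargmax(x[seg]))))
    return peaks


def introgression_scan(
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    pops: tuple[str, str, str, str],
    size: int,
    step: int | None = None,
) -> pd.DataFrame:
    """Windowed ABBA/BABA table: per window the pattern sums, D and f_d."""
    rows = []
    for window, sites in iter_windows(matrix, size, step):
        q = quartet_frequencies(sites, pops, popmap, matrix.samples)
        abba, baba = site_pattern_sums(q)
        d = patterson_d(abba, baba)
        fd = fd_window(q)
        rows.append(
            {
                "chrom": window.chrom,
                "start": window.start,
                "end": window.end,
                "n_sites": len(q),
                "abba": abba,
                "baba": baba,
                "D": np.nan if d is None else d,
                "fd": np.nan if fd is None else fd,
            }
        )
    return pd.DataFrame(rows)
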