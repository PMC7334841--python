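"""Genotype data model, VCF / population-map ingestion, filtering, windowing.

The central container is :class:`GenotypeMatrix`: an ordered collection of
biallelic SNP sites with per-sample diploid allele dosages (0, 1, 2 or
missing), the plumbing every downstream statistic consumes.  Coordinates are
VCF-native 1-based throughout; windows are 1-based inclusive ``[k*L+1,
(k+1)*L]`` so a site at position 10000 falls in the first 10-kb window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

logger = logging.getLogger("campina")

#: Sentinel dosage for a missing diploid genotype.
MISSING = -1

_NUCS = frozenset("ACGT")


class FormatError(ValueError):
    """Input file violates its declared format."""


class ValidationError(ValueError):
    """Input values violate a documented constraint."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class SiteRecord:
    """One biallelic SNP: position, alleles, per-sample dosages.

    ``genotypes`` holds alternate-allele dosages per sample (0, 1, 2) with
    ``-1`` for missing; ``genotype_quality`` is a parallel float array
    (``nan`` where absent) or ``None`` when the VCF carried no GQ field.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    genotypes: np.ndarray
    genotype_quality: np.ndarray | None = None
    annotation: str | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int16)
        if self.pos < 1:
            raise ValidationError(f"position must be >= 1, got {self.pos}")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValidationError(
                f"dosages must be 0/1/2/missing at {self.chrom}:{self.pos}"
            )

    @property
    def n_samples(self) -> int:
        return self.genotypes.size


@dataclass
class GenotypeMatrix:
    """Ordered sites x samples diploid genotype matrix."""

    samples: list[str]
    sites: list[SiteRecord] = field(default_factory=list)
    #: Records dropped during VCF ingestion (multi-allelic, indel, symbolic).
    n_dropped: int = 0

    def __post_init__(self) -> None:
        seen: set[tuple[str, int]] = set()
        last: tuple[str, int] | None = None
        for s in self.sites:
            if s.n_samples != len(self.samples):
                raise ValidationError(
                    f"site {s.chrom}:{s.pos} has {s.n_samples} genotypes "
                    f"for {len(self.samples)} samples"
                )
            key = (s.chrom, s.pos)
            if key in seen:
                raise ValidationError(f"duplicate site {s.chrom}:{s.pos}")
            seen.add(key)
            if last is not None and last[0] == s.chrom and s.pos < last[1]:
                raise ValidationError(
                    f"sites out of order within {s.chrom} at pos {s.pos}"
                )
            last = key

    def __len__(self) -> int:
        return len(self.sites)

    def sample_index(self, names: Sequence[str]) -> np.ndarray:
        try:
            return np.array([self.samples.index(n) for n in names], dtype=int)
        except ValueError as exc:
            raise LookupError(f"sample not in matrix: {exc}") from None

    def chroms(self) -> list[str]:
        out: list[str] = []
        for s in self.sites:
            if not out or out[-1] != s.chrom:
                out.append(s.chrom)
        return out


@dataclass
class PopulationMap:
    """Sample -> population assignment, with optional lat/lon coordinates."""

    assignment: dict[str, str]
    coordinates: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sample, (lat, lon) in self.coordinates.items():
            if not -90.0 <= lat <= 90.0:
                raise ValidationError(f"latitude {lat} out of range for {sample}")
            if not -180.0 <= lon <= 180.0:
                raise ValidationError(f"longitude {lon} out of range for {sample}")

    def samples_in(self, population: str) -> list[str]:
        out = [s for s, p in self.assignment.items() if p == population]
        if not out:
            raise LookupError(f"population {population!r} has no samples")
        return out

    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.assignment.values():
            seen.setdefault(p)
        return list(seen)


@dataclass(frozen=True)
class Window:
    """1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


# ---------------------------------------------------------------------------
# VCF ingestion
# ---------------------------------------------------------------------------


def _decode_gt(gt: list) -> int:
    # cyvcf2 genotype entry: [allele_1, allele_2, phased]; -1 = missing.
    a, b = gt[0], gt[1]
    if a < 0 or b < 0:  # half-calls conservative -> missing
        return MISSING
    return int(a > 0) + int(b > 0)


def read_vcf(path: str, sample_subset: Sequence[str] | None = None) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF v4.x file into a :class:`GenotypeMatrix`.

    Multi-allelic records, indels, multi-nucleotide and symbolic alleles are
    dropped; the count of dropped records is kept on the returned matrix as
    ``n_dropped`` and logged.  Phased and unphased genotypes are treated
    identically; half-calls become missing.
    """
    import cyvcf2

    with open(path, "rb") as fh:
        magic = fh.read(2)
        if magic != b"\x1f\x8b":  # plain text: check header line
            fh.seek(0)
            first = fh.readline().decode(errors="replace")
            if not first.startswith("##fileformat"):
                raise FormatError(f"{path}: missing ##fileformat header line")

    try:
        vcf = cyvcf2.VCF(path, gts012=False)
    except Exception as exc:  # unparsable header
        raise FormatError(f"{path}: cannot parse VCF: {exc}") from exc

    all_samples = list(vcf.samples)
    if sample_subset is not None:
        missing = [s for s in sample_subset if s not in all_samples]
        if missing:
            raise LookupError(f"samples not in VCF header: {missing}")
        keep = np.array([all_samples.index(s) for s in sample_subset], dtype=int)
        samples = list(sample_subset)
    else:
        keep = np.arange(len(all_samples))
        samples = all_samples

    sites: list[SiteRecord] = []
    n_dropped = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_dropped += 1
            continue
        ref, alt = rec.REF.upper(), rec.ALT[0].upper()
        if ref not in _NUCS or alt not in _NUCS:
            n_dropped += 1
            continue
        dosages = np.array([_decode_gt(g) for g in rec.genotypes], dtype=np.int16)
        gq = None
        try:
            raw = rec.format("GQ")
        except KeyError:
            raw = None
        if raw is not None:
            gq = np.asarray(raw, dtype=float).reshape(-1)
            gq[gq < 0] = np.nan
        sites.append(
            SiteRecord(
                chrom=rec.CHROM,
                pos=rec.POS,
                ref_allele=ref,
                alt_allele=alt,
                genotypes=dosages[keep],
                genotype_quality=None if gq is None else gq[keep],
            )
        )
    vcf.close()
    if n_dropped:
        logger.info("read_vcf: dropped %d non-biallelic-SNP records", n_dropped)
    return GenotypeMatrix(samples=samples, sites=sites, n_dropped=n_dropped)


def write_vcf(matrix: GenotypeMatrix, path: str) -> None:
    """Write a matrix as a minimal plain-text VCF v4.2 (round-trip safe)."""
    with open(path, "w") as out:
        out.write("##fileformat=VCFv4.2\n")
        out.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        out.write(
            '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype Quality">\n'
        )
        for chrom in matrix.chroms():
            out.write(f"##contig=<ID={chrom}>\n")
        out.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for s in matrix.sites:
            has_gq = s.genotype_quality is not None
            fmt = "GT:GQ" if has_gq else "GT"
            cells = []
            for i, d in enumerate(s.genotypes):
                cell = gt_str[int(d)]
                if has_gq:
                    q = s.genotype_quality[i]
                    cell += ":." if np.isnan(q) else f":{int(q)}"
                cells.append(cell)
            out.write(
                f"{s.chrom}\t{s.pos}\t.\t{s.ref_allele}\t{s.alt_allele}\t.\t.\t.\t"
                + fmt
                + "\t"
                + "\t".join(cells)
                + "\n"
            )


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------


def filter_sites(
    matrix: GenotypeMatrix,
    min_gq: float | None = None,
    max_missing_fraction: float = 1.0,
    min_maf: float = 0.0,
) -> GenotypeMatrix:
    """Apply genotype-quality masking, then site-level missingness/MAF filters.

    Genotypes with quality below ``min_gq`` are set to missing *before* the
    site-level filters, matching the order of the SNP-filtering pipeline this
    package models.  Site order is preserved; an empty result is allowed.
    """
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise ValidationError("max_missing_fraction must be in [0, 1]")
    if not 0.0 <= min_maf <= 0.5:
        raise ValidationError("min_maf must be in [0, 0.5]")

    kept: list[SiteRecord] = []
    n_masked = 0
    for s in matrix.sites:
        geno = s.genotypes.copy()
        gq = s.genotype_quality
        if min_gq is not None and gq is not None:
            low = (~np.isnan(gq)) & (gq < min_gq) & (geno != MISSING)
            n_masked += int(low.sum())
            geno[low] = MISSING
        called = geno != MISSING
        n_called = int(called.sum())
        miss_frac = 1.0 - n_called / geno.size
        if miss_frac > max_missing_fraction:
            continue
        if min_maf > 0.0:
            if n_called == 0:
                continue
            alt = int(geno[called].sum())
            total = 2 * n_called
            af = alt / total
            if min(af, 1.0 - af) < min_maf:
                continue
        kept.append(
            SiteRecord(
                chrom=s.chrom,
                pos=s.pos,
                ref_allele=s.ref_allele,
                alt_allele=s.alt_allele,
                genotypes=geno,
                genotype_quality=gq,
                annotation=s.annotation,
            )
        )
    if n_masked:
        logger.info("filter_sites: masked %d genotypes below GQ threshold", n_masked)
    logger.info("filter_sites: kept %d of %d sites", len(kept), len(matrix.sites))
    if not kept:
        logger.warning("filter_sites: no sites remain after filtering")
    return GenotypeMatrix(samples=list(matrix.samples), sites=kept)


def allele_counts(
    site: SiteRecord, population: str, popmap: PopulationMap, matrix: GenotypeMatrix
) -> tuple[int, int]:
    """(called allele copies, alternate/derived copies) within one population."""
    idx = matrix.sample_index(popmap.samples_in(population))
    geno = site.genotypes[idx]
    called = geno != MISSING
    return 2 * int(called.sum()), int(geno[called].sum())


# ---------------------------------------------------------------------------
# Windowing
# ---------------------------------------------------------------------------


def iter_windows(
    matrix: GenotypeMatrix, size: int, step: int | None = None
) -> Iterator[tuple[Window, list[SiteRecord]]]:
    """Yield windows tiling each chromosome from position 1, with member sites.

    With no ``step`` the windows are non-overlapping and partition the sites;
    with a ``step`` < ``size`` they slide.  Empty windows up to the last
    site's position are yielded (length-normalised diversity needs them).
    """
    if size < 1:
        raise ValidationError("window size must be >= 1")
    if step is not None:
        if step == 0:
            raise ValidationError("window step must be >= 1")
        if step > size:
            raise ValidationError("step must be <= size")
    stride = size if step is None else step

    by_chrom: dict[str, list[SiteRecord]] = {}
    for s in matrix.sites:
        by_chrom.setdefault(s.chrom, []).append(s)

    for chrom, sites in by_chrom.items():
        max_pos = sites[-1].pos
        positions = np.array([s.pos for s in sites])
        start = 1
        while start <= max_pos:
            end = start + size - 1
            lo = int(np.searchsorted(positions, start, side="left"))
            hi = int(np.searchsorted(positions, end, side="right"))
            yield Window(chrom, start, end), sites[lo:hi]
            start += stride


# ---------------------------------------------------------------------------
# Population map I/O
# ---------------------------------------------------------------------------


def read_popmap(path: str) -> PopulationMap:
    """Read a TSV population map: sample, population, optional lat, lon."""
    assignment: dict[str, str] = {}
    coordinates: dict[str, tuple[float, float]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if ln == 1 and parts[0].lower() == "sample":
                continue
            if len(parts) < 2:
                raise FormatError(f"{path}:{ln}: expected >= 2 tab-separated columns")
            sample, pop = parts[0], parts[1]
            if sample in assignment:
                raise ValidationError(f"{path}:{ln}: duplicate sample {sample!r}")
            assignment[sample] = pop
            if len(parts) >= 4 and parts[2] and parts[3]:
                try:
                    lat, lon = float(parts[2]), float(parts[3])
                except ValueError as exc:
                    raise FormatError(f"{path}:{ln}: bad coordinate: {exc}") from None
                coordinates[sample] = (lat, lon)
    return PopulationMap(assignment=assignment, coordinates=coordinates)


def write_popmap(popmap: PopulationMap, path: str) -> None:
    with open(path, "w") as out:
        out.write("sample\tpopulation\tlat\tlon\n")
        for sample, pop in popmap.assignment.items():
            if sample in popmap.coordinates:
                lat, lon = popmap.coordinates[sample]
                out.write(f"{sample}\t{pop}\t{lat}\t{lon}\n")
            else:
                out.write(f"{sample}\t{pop}\t\t\n")
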