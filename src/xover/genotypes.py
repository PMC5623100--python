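"""From per-SNP haploid calls to a 1-Mbp binned consensus genotype matrix.

The consensus convention follows the biparental cross being analysed:
code 2 = parent-1 ("Morex") allele, code 0 = parent-2 ("Barke") allele,
missing otherwise.  Bins are 0-based half-open ``[k*bin_size, (k+1)*bin_size)``
and a 1-based marker at position ``p`` belongs to bin ``(p - 1) // bin_size``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .genome import GenomeMap
from .simulate import CALL_MISSING, CALL_PARENT1, CALL_PARENT2, PopulationCalls

log = logging.getLogger(__name__)

CODE_PARENT1 = np.int8(2)
CODE_PARENT2 = np.int8(0)
CODE_MISSING = np.int8(-1)


@dataclass
class GenotypeMatrix:
    """Samples x 1-Mbp bins consensus genotypes.

    ``codes[chrom]`` is an ``(n_samples, n_bins)`` int8 matrix over
    {0, 2, -1}; ``support[chrom]`` counts the SNP calls behind each cell;
    ``bin_starts[chrom]`` gives the retained bins' start coordinates (bp),
    strictly increasing but not necessarily contiguous after filtering.
    """

    samples: list[str]
    bin_starts: dict[str, np.ndarray]
    codes: dict[str, np.ndarray]
    support: dict[str, np.ndarray]
    bin_size: int
    chrom_lengths: dict[str, int]

    def __post_init__(self) -> None:
        for chrom, starts in self.bin_starts.items():
            if len(starts) > 1 and not np.all(np.diff(starts) > 0):
                raise ValueError(f"bin starts not increasing on {chrom}")
            bad = ~np.isin(self.codes[chrom], [CODE_PARENT1, CODE_PARENT2, CODE_MISSING])
            if bad.any():
                raise ValueError(f"invalid genotype codes on {chrom}")

    @property
    def chroms(self) -> list[str]:
        return list(self.bin_starts)

    def n_samples(self) -> int:
        return len(self.samples)

    def bin_ends(self, chrom: str) -> np.ndarray:
        return np.minimum(self.bin_starts[chrom] + self.bin_size, self.chrom_lengths[chrom])

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            samples=list(self.samples),
            bin_starts={c: v.copy() for c, v in self.bin_starts.items()},
            codes={c: v.copy() for c, v in self.codes.items()},
            support={c: v.copy() for c, v in self.support.items()},
            bin_size=self.bin_size,
            chrom_lengths=dict(self.chrom_lengths),
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per bin, one column per sample (NA = missing)."""
        parts = []
        for chrom in self.chroms:
            d = pd.DataFrame(
                self.codes[chrom].T.astype(float), columns=self.samples
            ).replace(float(CODE_MISSING), np.nan)
            d.insert(0, "chrom", chrom)
            d.insert(1, "start", self.bin_starts[chrom])
            d.insert(2, "end", self.bin_ends(chrom))
            parts.append(d)
        return pd.concat(parts, ignore_index=True)

    def write_tsv(self, path) -> None:
        tab = self.to_frame()
        for s in self.samples:
            tab[s] = tab[s].map(lambda v: "NA" if pd.isna(v) else str(int(v)))
        tab.to_csv(path, sep="\t", index=False)


def read_matrix_tsv(path, bin_size: int = 1_000_000, chrom_lengths: dict[str, int] | None = None) -> GenotypeMatrix:
    tab = pd.read_csv(path, sep="\t", dtype={"chrom": str}, na_values=["NA"])
    samples = [c for c in tab.columns if c not in ("chrom", "start", "end")]
    bin_starts, codes, support, lengths = {}, {}, {}, {}
    for chrom, grp in tab.groupby("chrom", sort=False):
        bin_starts[chrom] = grp["start"].to_numpy(np.int64)
        m = grp[samples].to_numpy(float)
        m[np.isnan(m)] = CODE_MISSING
        codes[chrom] = m.T.astype(np.int8)
        support[chrom] = np.zeros_like(codes[chrom], np.int32)
        lengths[chrom] = int(grp["end"].max())
    if chrom_lengths:
        lengths.update(chrom_lengths)
    return GenotypeMatrix(samples, bin_starts, codes, support, bin_size, lengths)


# --------------------------------------------------------------------------
# VCF -> parental-origin calls
# --------------------------------------------------------------------------


def read_calls(vcf_path, genome: GenomeMap) -> tuple[PopulationCalls, dict]:
    """Map VCF genotypes to parental-origin calls at the genome's marker sites.

    Haploid GTs are preferred; homozygous diploid GTs are collapsed to the
    corresponding haploid call, and heterozygous GTs — impossible for a
    haploid nucleus, hence a contamination/error flag — are treated as
    missing and counted.  Sites absent from the marker table, or whose
    REF/ALT do not match the parental alleles, are dropped and counted.
    """
    vcf = VCF(str(vcf_path), gts012=True)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError("VCF contains no samples")
    index = {
        chrom: {int(p): i for i, p in enumerate(genome.markers[chrom]["pos"])}
        for chrom in genome.names
        if chrom in genome.markers
    }
    mats = {
        chrom: np.full((len(samples), len(genome.markers[chrom])), CALL_MISSING, np.int8)
        for chrom in index
    }
    stats = {"sites": 0, "dropped_not_in_table": 0, "dropped_allele_mismatch": 0, "het_calls": 0}
    for var in vcf:
        stats["sites"] += 1
        chrom_idx = index.get(var.CHROM)
        if chrom_idx is None or var.POS not in chrom_idx:
            stats["dropped_not_in_table"] += 1
            continue
        j = chrom_idx[var.POS]
        tab = genome.markers[var.CHROM]
        p1, p2 = tab["parent1_allele"].iat[j], tab["parent2_allele"].iat[j]
        alt = var.ALT[0] if var.ALT else None
        if var.REF == p1 and alt == p2:
            ref_call, alt_call = CALL_PARENT1, CALL_PARENT2
        elif var.REF == p2 and alt == p1:
            ref_call, alt_call = CALL_PARENT2, CALL_PARENT1
        else:
            stats["dropped_allele_mismatch"] += 1
            continue
        gt = var.gt_types  # gts012: 0=hom ref, 1=het, 2=hom alt, 3=missing
        col = np.full(len(samples), CALL_MISSING, np.int8)
        col[gt == 0] = ref_call
        col[gt == 2] = alt_call
        stats["het_calls"] += int((gt == 1).sum())
        mats[var.CHROM][:, j] = col
    if stats["dropped_not_in_table"] or stats["dropped_allele_mismatch"] or stats["het_calls"]:
        log.info(
            "read_calls: %(dropped_not_in_table)d sites not in marker table, "
            "%(dropped_allele_mismatch)d allele mismatches, %(het_calls)d het calls set missing",
            stats,
        )
    return PopulationCalls(samples=samples, calls=mats), stats


# --------------------------------------------------------------------------
# Binned consensus
# --------------------------------------------------------------------------


def bin_consensus(
    calls: PopulationCalls,
    genome: GenomeMap,
    bin_size: int = 1_000_000,
    min_support: int = 1,
    purity: float = 0.8,
) -> GenotypeMatrix:
    """Aggregate per-SNP calls into per-bin consensus genotypes.

    A bin is called for the majority parent when it has at least
    ``min_support`` non-missing calls and the majority fraction is at least
    ``purity``; otherwise it is missing.  Bins without markers are missing in
    every sample.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    S = calls.n_samples()
    bin_starts, codes, support = {}, {}, {}
    for chrom in genome.names:
        L = genome.length(chrom)
        n_bins = int(np.ceil(L / bin_size))
        c1 = np.zeros((S, n_bins), np.int32)
        c2 = np.zeros((S, n_bins), np.int32)
        if chrom in calls.calls and calls.calls[chrom].shape[1]:
            pos = genome.markers[chrom]["pos"].to_numpy(np.int64)
            b = (pos - 1) // bin_size
            mat = calls.calls[chrom]
            # markers are position-sorted so bins are contiguous: reduceat
            starts_idx = np.flatnonzero(np.r_[True, np.diff(b) != 0])
            present_bins = b[starts_idx]
            c1[:, present_bins] = np.add.reduceat(mat == CALL_PARENT1, starts_idx, axis=1)
            c2[:, present_bins] = np.add.reduceat(mat == CALL_PARENT2, starts_idx, axis=1)
        tot = c1 + c2
        maj = np.maximum(c1, c2)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(tot > 0, maj / np.maximum(tot, 1), 0.0)
        code = np.full((S, n_bins), CODE_MISSING, np.int8)
        ok = (tot >= max(min_support, 1)) & (frac >= purity) & (c1 != c2)
        code[ok & (c1 > c2)] = CODE_PARENT1
        code[ok & (c2 > c1)] = CODE_PARENT2
        bin_starts[chrom] = np.arange(n_bins, dtype=np.int64) * bin_size
        codes[chrom] = code
        support[chrom] = tot
    return GenotypeMatrix(
        samples=list(calls.samples),
        bin_starts=bin_starts,
        codes=codes,
        support=support,
        bin_size=bin_size,
        chrom_lengths={c: genome.length(c) for c in genome.names},
    )


def filter_missing(
    matrix: GenotypeMatrix, max_missing: float = 0.5
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Drop bins whose missing fraction across samples exceeds ``max_missing``.

    The comparison is strict (>), so a bin missing in exactly half the
    samples is retained at the default threshold.  Returns the filtered
    matrix and the per-chromosome count of removed bins.
    """
    out = matrix.copy()
    removed: dict[str, int] = {}
    for chrom in matrix.chroms:
        miss_frac = (matrix.codes[chrom] == CODE_MISSING).mean(axis=0)
        keep = miss_frac <= max_missing
        removed[chrom] = int((~keep).sum())
        out.bin_starts[chrom] = matrix.bin_starts[chrom][keep]
        out.codes[chrom] = matrix.codes[chrom][:, keep]
        out.support[chrom] = matrix.support[chrom][:, keep]
    if any(removed.values()):
        log.info("filter_missing removed bins: %s", removed)
    return out, removed
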