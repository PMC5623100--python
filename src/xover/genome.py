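"""Genome description shared by the simulator and the analysis modules.

A :class:`GenomeMap` holds chromosome names and physical lengths, the
biparental SNP marker table (position plus the two parental alleles), and
an optional genetic map per chromosome.  The genetic map is a monotone
piecewise-linear function from physical position (bp) to genetic position
(Morgans); it is only needed by the simulator, which places crossovers on
the genetic scale and projects them onto the physical map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Physical chromosome lengths (bp) of the default synthetic genome:
#: seven chromosomes spanning the 558-767 Mbp range typical of barley.
BARLEY_LIKE_LENGTHS = {
    "chr1H": 558_000_000,
    "chr2H": 767_000_000,
    "chr3H": 700_000_000,
    "chr4H": 647_000_000,
    "chr5H": 670_000_000,
    "chr6H": 583_000_000,
    "chr7H": 657_000_000,
}

MARKER_COLUMNS = ["pos", "parent1_allele", "parent2_allele"]


def uniform_map(length_bp: int, genetic_length: float) -> tuple[np.ndarray, np.ndarray]:
    """Genetic map with constant recombination rate along the chromosome."""
    return (
        np.array([0.0, float(length_bp)]),
        np.array([0.0, float(genetic_length)]),
    )


def distal_elevated_map(
    length_bp: int,
    genetic_length: float,
    distal_phys_frac: float = 0.15,
    distal_gen_frac: float = 0.45,
) -> tuple[np.ndarray, np.ndarray]:
    """Genetic map concentrating recombination in the chromosome ends.

    By default each distal 15% of the physical chromosome carries 45% of the
    genetic length, i.e. ~90% of crossovers fall in the distal 30% of the
    chromosome while the interstitial/pericentromeric 70% is recombination
    poor.  This mimics the strongly distal recombination landscape of large
    cereal chromosomes.
    """
    if not 0 < distal_phys_frac < 0.5:
        raise ValueError("distal_phys_frac must be in (0, 0.5)")
    if not 0 <= distal_gen_frac <= 0.5:
        raise ValueError("distal_gen_frac must be in [0, 0.5]")
    L, G = float(length_bp), float(genetic_length)
    phys = np.array([0.0, distal_phys_frac * L, (1 - distal_phys_frac) * L, L])
    gen = np.array([0.0, distal_gen_frac * G, (1 - distal_gen_frac) * G, G])
    return phys, gen


@dataclass
class GenomeMap:
    """Chromosome lengths, SNP marker table and optional genetic maps.

    Parameters
    ----------
    chromosomes
        Mapping of chromosome name to physical length in bp.
    markers
        Per-chromosome DataFrame with columns ``pos`` (1-based bp, strictly
        increasing), ``parent1_allele`` and ``parent2_allele``.
    genetic_maps
        Optional per-chromosome ``(phys_bp, genetic_morgans)`` knot arrays of a
        monotone piecewise-linear map.
    """

    chromosomes: dict[str, int]
    markers: dict[str, pd.DataFrame] = field(default_factory=dict)
    genetic_maps: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    def __post_init__(self) -> None:
        for name, length in self.chromosomes.items():
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        for name, tab in self.markers.items():
            if name not in self.chromosomes:
                raise ValueError(f"markers given for unknown chromosome {name}")
            pos = np.asarray(tab["pos"])
            if len(pos) and not np.all(np.diff(pos) > 0):
                raise ValueError(f"marker positions not strictly increasing on {name}")
            if len(pos) and (pos[0] < 1 or pos[-1] > self.chromosomes[name]):
                raise ValueError(f"marker position outside [1, length] on {name}")
        if self.genetic_maps is not None:
            for name, (phys, gen) in self.genetic_maps.items():
                phys, gen = np.asarray(phys, float), np.asarray(gen, float)
                if np.any(np.diff(phys) <= 0) or np.any(np.diff(gen) < 0):
                    raise ValueError(f"genetic map not monotone on {name}")
                if gen[0] != 0 or gen[-1] < 0:
                    raise ValueError(f"genetic map of {name} must start at 0")
                self.genetic_maps[name] = (phys, gen)

    @property
    def names(self) -> list[str]:
        return list(self.chromosomes)

    def length(self, chrom: str) -> int:
        return self.chromosomes[chrom]

    def genetic_length(self, chrom: str) -> float:
        if self.genetic_maps is None or chrom not in self.genetic_maps:
            raise KeyError(f"no genetic map for {chrom}")
        return float(self.genetic_maps[chrom][1][-1])

    def n_markers(self) -> int:
        return sum(len(t) for t in self.markers.values())

    # ------------------------------------------------------------------ I/O
    def marker_frame(self) -> pd.DataFrame:
        """All markers as one DataFrame with a ``chrom`` column."""
        parts = []
        for name in self.names:
            if name in self.markers and len(self.markers[name]):
                t = self.markers[name].copy()
                t.insert(0, "chrom", name)
                parts.append(t)
        if not parts:
            return pd.DataFrame(columns=["chrom", *MARKER_COLUMNS])
        return pd.concat(parts, ignore_index=True)

    def write_marker_table(self, path) -> None:
        self.marker_frame().to_csv(path, sep="\t", index=False)


def read_marker_table(path) -> dict[str, pd.DataFrame]:
    """Read a marker table TSV (chrom, pos, parent1_allele, parent2_allele)."""
    tab = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = {"chrom", *MARKER_COLUMNS} - set(tab.columns)
    if missing:
        raise ValueError(f"marker table lacks columns: {sorted(missing)}")
    return {
        str(chrom): grp[MARKER_COLUMNS].reset_index(drop=True)
        for chrom, grp in tab.groupby("chrom", sort=False)
    }


def _marker_positions(length: int, spacing: int, gap_size: int, gap_centers: tuple[float, ...]) -> np.ndarray:
    pos = np.arange(spacing, length + 1, spacing, dtype=np.int64)
    keep = np.ones(len(pos), bool)
    for frac in gap_centers:
        c = frac * length
        keep &= ~((pos >= c - gap_size / 2) & (pos < c + gap_size / 2))
    return pos[keep]


def default_genome(
    lengths: dict[str, int] | None = None,
    marker_spacing: int = 100_000,
    gap_size: int = 10_000_000,
    gap_centers: tuple[float, ...] = (0.25, 0.5, 0.75),
    genetic_length: float = 1.36,
    map_kind: str = "distal",
    seed: int = 0,
) -> GenomeMap:
    """Build the default synthetic biparental genome.

    Seven chromosomes of 558-767 Mbp with one SNP marker per 100 kb and three
    10-Mbp marker-free gaps per chromosome (monomorphic regions where the two
    parents carry identical sequence).  Each chromosome gets a genetic length
    of 1.36 Morgans — matching ~9.5 crossovers per gamete over 7 chromosomes —
    and either a uniform or a distally elevated genetic map.  Parental alleles
    are arbitrary distinct nucleotides drawn reproducibly from ``seed``.
    """
    lengths = dict(lengths or BARLEY_LIKE_LENGTHS)
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    markers: dict[str, pd.DataFrame] = {}
    gmaps: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for name, L in lengths.items():
        pos = _marker_positions(L, marker_spacing, gap_size, gap_centers)
        ref_idx = rng.integers(0, 4, size=len(pos))
        alt_idx = (ref_idx + rng.integers(1, 4, size=len(pos))) % 4
        markers[name] = pd.DataFrame(
            {
                "pos": pos,
                "parent1_allele": bases[ref_idx],
                "parent2_allele": bases[alt_idx],
            }
        )
        if map_kind == "uniform":
            gmaps[name] = uniform_map(L, genetic_length)
        elif map_kind == "distal":
            gmaps[name] = distal_elevated_map(L, genetic_length)
        else:
            raise ValueError(f"unknown map_kind {map_kind!r}")
    return GenomeMap(chromosomes=lengths, markers=markers, genetic_maps=gmaps)
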