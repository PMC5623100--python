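"""Synthetic meiosis and sparse-genotyping simulator.

Crossovers are placed by a stationary gamma renewal process on the genetic
scale of the four-chromatid bundle: inter-event distances are i.i.d.
Gamma(shape ``nu``, rate ``2*nu`` per Morgan), giving a bundle intensity of 2
events/Morgan, and the first event is drawn from the equilibrium
forward-recurrence distribution so event counts are stationary along the
chromosome.  ``nu`` is the interference strength: ``nu = 1`` is a Poisson
process (no interference), ``nu > 1`` spaces events apart (positive
interference).  A single gamete carries one of the four chromatids, so bundle
events are thinned independently with probability 1/2, leaving a chromatid
intensity of 1 crossover/Morgan.

Genetic event positions are projected to physical bp through the genome's
monotone genetic map; a "distal-elevated" map reproduces the distal
concentration of crossovers typical of large cereal chromosomes.  Observation
is modelled at the genotype-call level: each marker is seen with probability
``detect_prob`` (the analogue of ~0.1x shotgun coverage) and an observed call
is wrong with probability ``error_rate``.  Transmission bias at selected loci
(the driver of segregation-distortion regions in DH-like populations) is
implemented by rejection sampling of whole gametes.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeMap

CALL_PARENT1 = np.int8(1)
CALL_PARENT2 = np.int8(2)
CALL_MISSING = np.int8(-1)


@dataclass(frozen=True)
class MeiosisModel:
    """Gamma renewal model of crossover formation.

    ``genetic_length`` (Morgans) is the chromatid map length, i.e. the mean
    number of crossovers per gamete on that chromosome; ``None`` takes the
    length from the genome's genetic map.  ``obligate_co`` resamples
    chromatids until at least one crossover is present.
    """

    nu: float = 3.0
    genetic_length: float | None = None
    obligate_co: bool = False

    def __post_init__(self) -> None:
        if not self.nu > 0:
            raise ValueError("nu must be > 0")
        if self.genetic_length is not None and self.genetic_length < 0:
            raise ValueError("genetic_length must be >= 0")


@dataclass(frozen=True)
class ObservationModel:
    """Sparse noisy genotype observation.

    ``detect_prob`` — probability a marker yields a call in a given sample;
    ``error_rate`` — baseline probability an observed call reports the wrong
    parent; ``detect_sd`` — optional between-sample overdispersion of the
    detection probability (Beta-distributed per-sample detection with this
    SD).  ``bad_region_frac`` puts that fraction of each chromosome into
    error-prone regions of ``bad_region_size`` bp where calls are wrong with
    probability ``bad_region_error`` — the systematic, position-anchored
    miscalls (mismapping, paralogy) that marker curation is meant to remove,
    as opposed to the independent per-call noise of ``error_rate``.
    """

    detect_prob: float = 0.1
    error_rate: float = 0.0005
    detect_sd: float = 0.0
    bad_region_frac: float = 0.005
    bad_region_error: float = 0.4
    bad_region_size: int = 1_000_000

    def __post_init__(self) -> None:
        for name in ("detect_prob", "error_rate", "bad_region_frac", "bad_region_error"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.detect_sd < 0:
            raise ValueError("detect_sd must be >= 0")

    def draw_error_regions(self, genome: GenomeMap, rng) -> dict[str, np.ndarray]:
        """Per-chromosome marker mask of the error-prone regions.

        Regions are drawn once per population (not per gamete) so the
        elevated error is consistent across samples.
        """
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        masks: dict[str, np.ndarray] = {}
        for chrom in genome.names:
            pos = genome.markers[chrom]["pos"].to_numpy()
            mask = np.zeros(len(pos), bool)
            n_regions = int(round(self.bad_region_frac * genome.length(chrom) / self.bad_region_size))
            for start in rng.integers(0, max(genome.length(chrom) - self.bad_region_size, 1), size=n_regions):
                mask |= (pos > start) & (pos <= start + self.bad_region_size)
            masks[chrom] = mask
        return masks


@dataclass(frozen=True)
class SelectionModel:
    """Transmission bias at selected loci.

    ``loci`` is a list of ``(chrom, pos_bp, p1_transmission)`` tuples; the
    marginal frequency of the parent-1 allele at each locus equals the given
    transmission probability (0.5 = Mendelian).
    """

    loci: tuple[tuple[str, int, float], ...] = ()

    def __post_init__(self) -> None:
        for chrom, pos, p in self.loci:
            if not 0 <= p <= 1:
                raise ValueError(f"transmission probability {p} outside [0, 1]")


NEUTRAL_SELECTION = SelectionModel()


@dataclass
class TrueGamete:
    """Ground-truth gamete: crossover positions and parental haplotype."""

    crossovers: dict[str, np.ndarray]  # sorted bp positions per chromosome
    start_parent: dict[str, int]  # 1 or 2: parent at the chromosome start

    def parent_at(self, chrom: str, pos) -> np.ndarray:
        """Parental origin (1 or 2) at physical position(s) ``pos``."""
        xo = self.crossovers[chrom]
        n = np.searchsorted(xo, np.asarray(pos, float), side="right")
        start = self.start_parent[chrom]
        return np.where(n % 2 == 0, start, 3 - start).astype(np.int8)

    def n_crossovers(self) -> int:
        return sum(len(v) for v in self.crossovers.values())


# --------------------------------------------------------------------------
# Gamma renewal process on the bundle
# --------------------------------------------------------------------------

_FR_GRID_N = 4096


@functools.lru_cache(maxsize=256)
def forward_recurrence_table(nu: float) -> tuple[np.ndarray, np.ndarray]:
    """CDF table of the equilibrium forward-recurrence distribution.

    For inter-event law Gamma(shape nu, rate 2*nu) with mean 1/2 Morgan the
    stationary-excess CDF has the closed form
    ``F_e(x) = 2*x*(1 - F_nu(x)) + F_{nu+1}(x)`` (same rate), obtained by
    integrating the tail by parts.  Returns ``(x, F_e(x))`` for inverse-CDF
    sampling by interpolation.
    """
    if not nu > 0:
        raise ValueError("nu must be > 0")
    scale = 1.0 / (2.0 * nu)
    xmax = stats.gamma.ppf(1.0 - 1e-12, nu + 1.0, scale=scale) * 1.25
    x = np.linspace(0.0, xmax, _FR_GRID_N)
    fe = 2.0 * x * stats.gamma.sf(x, nu, scale=scale) + stats.gamma.cdf(
        x, nu + 1.0, scale=scale
    )
    fe[0] = 0.0
    fe[-1] = 1.0
    return x, np.maximum.accumulate(fe)  # guard monotonicity against roundoff


def forward_recurrence_ppf(u, nu: float) -> np.ndarray:
    """Inverse CDF of the equilibrium first-event distribution."""
    x, fe = forward_recurrence_table(float(nu))
    return np.interp(np.asarray(u, float), fe, x)


def simulate_bundle_crossovers(nu: float, genetic_length: float, rng) -> np.ndarray:
    """Stationary gamma-renewal event positions (Morgans) on the bundle.

    Events have intensity 2/Morgan on ``[0, genetic_length]``; the first event
    is an equilibrium forward-recurrence draw, subsequent gaps are
    Gamma(nu, rate 2*nu).
    """
    if not nu > 0:
        raise ValueError("nu must be > 0")
    if genetic_length < 0:
        raise ValueError("genetic_length must be >= 0")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    G = float(genetic_length)
    if G == 0:
        return np.empty(0)
    events = []
    x = float(forward_recurrence_ppf(rng.random(), nu))
    scale = 1.0 / (2.0 * nu)
    while x <= G:
        events.append(x)
        x += rng.gamma(nu, scale)
    return np.asarray(events)


def thin_to_chromatid(bundle_events: np.ndarray, rng) -> np.ndarray:
    """Keep each bundle event independently with probability 1/2.

    A gamete carries one of the four chromatids and each crossover involves
    two of them, so every bundle event is present on the sampled chromatid
    with probability 1/2 (no chromatid interference).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    bundle_events = np.asarray(bundle_events, float)
    if bundle_events.size == 0:
        return bundle_events.copy()
    return bundle_events[rng.random(bundle_events.size) < 0.5]


def genetic_to_physical(positions, genome: GenomeMap, chrom: str) -> np.ndarray:
    """Project genetic positions (Morgans) to physical bp via the genome map."""
    if genome.genetic_maps is None or chrom not in genome.genetic_maps:
        raise KeyError(f"no genetic map for {chrom}")
    phys, gen = genome.genetic_maps[chrom]
    positions = np.asarray(positions, float)
    if positions.size and (positions.min() < 0 or positions.max() > gen[-1]):
        raise ValueError("genetic position outside [0, G]")
    return np.interp(positions, gen, phys)


def sample_chromatids(nu: float, genetic_length: float, n: int, rng) -> list[np.ndarray]:
    """Vectorised draw of ``n`` chromatid crossover-position arrays (Morgans).

    Equivalent to ``thin_to_chromatid(simulate_bundle_crossovers(...))`` per
    chromatid, but simulated as a batch for speed.
    """
    if not nu > 0:
        raise ValueError("nu must be > 0")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    G = float(genetic_length)
    if G == 0 or n == 0:
        return [np.empty(0) for _ in range(n)]
    K = int(np.ceil(4.0 * G)) + 24  # gaps have mean 1/2; overflow is negligible
    x0 = forward_recurrence_ppf(rng.random(n), nu)
    gaps = rng.gamma(nu, 1.0 / (2.0 * nu), size=(n, K))
    pos = x0[:, None] + np.concatenate([np.zeros((n, 1)), np.cumsum(gaps, axis=1)], axis=1)
    keep = (pos <= G) & (rng.random((n, K + 1)) < 0.5)
    return [pos[i][keep[i]] for i in range(n)]


def simulate_true_events(
    genome: GenomeMap,
    nu: float,
    n_samples: int,
    seed: int = 0,
    sample_prefix: str = "g",
) -> pd.DataFrame:
    """Ground-truth crossover events for a population, skipping observation.

    Batch-samples chromatids for every chromosome and projects them through
    the genome's genetic map; returns the same zero-width event table as
    :func:`events_from_truth`.  Useful when only crossover positions matter
    (landscape and interference analyses on noiseless data).
    """
    rng = np.random.default_rng(seed)
    rows = []
    names = [f"{sample_prefix}{i:04d}" for i in range(n_samples)]
    for chrom in genome.names:
        G = genome.genetic_length(chrom)
        for name, chromatid in zip(names, sample_chromatids(nu, G, n_samples, rng)):
            for x in genetic_to_physical(chromatid, genome, chrom):
                rows.append({"sample": name, "chrom": chrom, "midpoint": float(x)})
    ev = pd.DataFrame(rows, columns=["sample", "chrom", "midpoint"])
    ev["left"] = ev["midpoint"]
    ev["right"] = ev["midpoint"]
    return ev


def events_from_truth(gametes: list[TrueGamete], samples: list[str]) -> pd.DataFrame:
    """Ground-truth crossovers as a zero-width event table.

    Matches the column layout of the event caller (left = right = midpoint =
    the true position), so landscape/interference functions can run directly
    on simulated truth.
    """
    rows = []
    for name, g in zip(samples, gametes):
        for chrom, xo in g.crossovers.items():
            lc = g.start_parent[chrom]
            for k, x in enumerate(xo):
                left_parent = lc if k % 2 == 0 else 3 - lc
                rows.append(
                    {
                        "sample": name,
                        "chrom": chrom,
                        "left": float(x),
                        "right": float(x),
                        "midpoint": float(x),
                        "left_code": 2 if left_parent == 1 else 0,
                        "right_code": 0 if left_parent == 1 else 2,
                    }
                )
    return pd.DataFrame(
        rows, columns=["sample", "chrom", "left", "right", "midpoint", "left_code", "right_code"]
    )


# --------------------------------------------------------------------------
# Whole gametes
# --------------------------------------------------------------------------


def _draw_chromatid(nu: float, G: float, obligate: bool, rng) -> np.ndarray:
    while True:
        chromatid = thin_to_chromatid(simulate_bundle_crossovers(nu, G, rng), rng)
        if not obligate or chromatid.size > 0:
            return chromatid


def make_gamete(
    genome: GenomeMap,
    meiosis: MeiosisModel | dict[str, MeiosisModel],
    selection: SelectionModel = NEUTRAL_SELECTION,
    rng=None,
) -> TrueGamete:
    """Draw one gamete: crossovers per chromosome plus parental haplotype.

    Transmission bias is applied by rejection: a candidate gamete is accepted
    with probability proportional to the product over selection loci of
    ``p`` (if it carries the parent-1 allele there) or ``1 - p``, which makes
    the marginal parent-1 transmission at each locus equal ``p``.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    while True:
        crossovers: dict[str, np.ndarray] = {}
        start: dict[str, int] = {}
        for chrom in genome.names:
            model = meiosis[chrom] if isinstance(meiosis, dict) else meiosis
            G = (
                model.genetic_length
                if model.genetic_length is not None
                else genome.genetic_length(chrom)
            )
            chromatid = _draw_chromatid(model.nu, G, model.obligate_co, rng)
            crossovers[chrom] = genetic_to_physical(chromatid, genome, chrom)
            start[chrom] = 1 if rng.random() < 0.5 else 2
        gamete = TrueGamete(crossovers=crossovers, start_parent=start)
        if not selection.loci:
            return gamete
        w = 1.0
        for chrom, pos, p in selection.loci:
            carried = int(gamete.parent_at(chrom, pos))
            w *= p if carried == 1 else 1.0 - p
            w /= max(p, 1.0 - p)
        if rng.random() < w:
            return gamete


def observe_gamete(
    gamete: TrueGamete,
    genome: GenomeMap,
    obs: ObservationModel,
    rng=None,
    error_regions: dict[str, np.ndarray] | None = None,
) -> dict[str, np.ndarray]:
    """Sparse noisy per-marker calls for one gamete.

    Returns per chromosome an int8 array aligned with the marker table:
    1 = parent-1 call, 2 = parent-2 call, -1 = missing.  ``error_regions``
    (from :meth:`ObservationModel.draw_error_regions`) marks markers whose
    calls are wrong with the elevated ``bad_region_error`` probability.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    detect = obs.detect_prob
    if obs.detect_sd > 0 and 0 < obs.detect_prob < 1:
        m, v = obs.detect_prob, min(obs.detect_sd**2, obs.detect_prob * (1 - obs.detect_prob) * 0.99)
        k = m * (1 - m) / v - 1
        detect = rng.beta(m * k, (1 - m) * k)
    calls: dict[str, np.ndarray] = {}
    for chrom in genome.names:
        pos = genome.markers[chrom]["pos"].to_numpy()
        truth = gamete.parent_at(chrom, pos)
        out = np.full(len(pos), CALL_MISSING, np.int8)
        seen = rng.random(len(pos)) < detect
        err_p = np.full(len(pos), obs.error_rate)
        if error_regions is not None and chrom in error_regions:
            err_p[error_regions[chrom]] = obs.bad_region_error
        flip = rng.random(len(pos)) < err_p
        obs_call = np.where(flip, 3 - truth, truth).astype(np.int8)
        out[seen] = obs_call[seen]
        calls[chrom] = out
    return calls


# --------------------------------------------------------------------------
# Populations and I/O
# --------------------------------------------------------------------------


@dataclass
class PopulationCalls:
    """Per-marker parental-origin calls for a set of haploid samples.

    ``calls[chrom]`` is an ``(n_samples, n_markers)`` int8 matrix with values
    1 (parent 1), 2 (parent 2) and -1 (missing), columns aligned with the
    genome's marker table.
    """

    samples: list[str]
    calls: dict[str, np.ndarray]

    def n_samples(self) -> int:
        return len(self.samples)


def simulate_population(
    genome: GenomeMap,
    meiosis: MeiosisModel | dict[str, MeiosisModel],
    obs: ObservationModel,
    selection: SelectionModel = NEUTRAL_SELECTION,
    n_samples: int = 40,
    seed: int = 0,
    sample_prefix: str = "g",
) -> tuple[list[TrueGamete], PopulationCalls]:
    """Simulate ``n_samples`` gametes and their sparse observations.

    Each gamete gets an independent RNG stream spawned by index from the base
    seed, so results do not depend on evaluation order.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_samples + 1)
    error_regions = obs.draw_error_regions(genome, np.random.default_rng(children[-1]))
    gametes: list[TrueGamete] = []
    mats = {c: np.full((n_samples, len(genome.markers[c])), CALL_MISSING, np.int8) for c in genome.names}
    for i, child in enumerate(children[:n_samples]):
        rng = np.random.default_rng(child)
        g = make_gamete(genome, meiosis, selection, rng)
        obs_calls = observe_gamete(g, genome, obs, rng, error_regions)
        gametes.append(g)
        for c in genome.names:
            mats[c][i] = obs_calls[c]
    names = [f"{sample_prefix}{i:03d}" for i in range(n_samples)]
    return gametes, PopulationCalls(samples=names, calls=mats)


_GT_STR = np.array([".", "0", "1"])  # index by code + 1 after mapping


def write_population_vcf(calls: PopulationCalls, genome: GenomeMap, path) -> None:
    """Write haploid genotype calls as a VCF.

    REF is the parent-1 allele and ALT the parent-2 allele, so GT "0" means a
    parent-1 call, "1" a parent-2 call and "." missing.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=xover-simulator\n")
        for chrom, L in genome.chromosomes.items():
            fh.write(f"##contig=<ID={chrom},length={L}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(calls.samples)
            + "\n"
        )
        for chrom in genome.names:
            tab = genome.markers[chrom]
            mat = calls.calls[chrom]
            # map call codes {-1, 1, 2} -> GT strings {., 0, 1}
            idx = np.zeros(mat.shape, np.int8)
            idx[mat == CALL_PARENT1] = 1
            idx[mat == CALL_PARENT2] = 2
            gt = _GT_STR[idx]
            pos = tab["pos"].to_numpy()
            ref = tab["parent1_allele"].to_numpy()
            alt = tab["parent2_allele"].to_numpy()
            for j in range(len(tab)):
                fh.write(
                    f"{chrom}\t{pos[j]}\t.\t{ref[j]}\t{alt[j]}\t.\t.\t.\tGT\t"
                    + "\t".join(gt[:, j])
                    + "\n"
                )


def write_truth_table(gametes: list[TrueGamete], samples: list[str], path) -> None:
    """Ground-truth crossovers: one row per sample/chromosome."""
    rows = []
    for name, g in zip(samples, gametes):
        for chrom, xo in g.crossovers.items():
            rows.append(
                {
                    "sample": name,
                    "chrom": chrom,
                    "start_parent": g.start_parent[chrom],
                    "crossovers_bp": ",".join(str(int(round(x))) for x in xo),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_truth_table(path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t", dtype={"crossovers_bp": str}, keep_default_na=False)
    tab["crossovers_bp"] = tab["crossovers_bp"].map(
        lambda s: np.array([int(x) for x in s.split(",")] if s else [], dtype=np.int64)
    )
    return tab
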