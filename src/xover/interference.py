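"""Crossover interference: inter-crossover distances and gamma-model fits.

Interference strength is summarised by the gamma shape ``nu`` of a renewal
model of crossover placement (``nu = 1`` no interference, ``nu > 1`` positive
interference).  ``nu`` is estimated by simulation: for each candidate value,
gamete chromatids are simulated with the chromosome's observed crossover
intensity, conditioned on carrying at least two crossovers, and the simulated
inter-crossover distance distribution is compared with the observed one by a
Cramér-von Mises (default) or Kolmogorov-Smirnov statistic; the estimate is
the grid argmin of the discrepancy.

Distances are analysed on chromosome-normalised coordinates (position / L) so
chromosomes of different physical lengths can be pooled.  The simulation uses
common random numbers across the candidate grid — one fixed set of uniform
draws mapped through each candidate's inverse CDFs — so the discrepancy
profile is smooth in ``nu`` and bit-reproducible for a given seed.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeMap
from .simulate import forward_recurrence_ppf

DEFAULT_GRID = np.round(np.arange(0.5, 12.0 + 1e-9, 0.25), 4)


@dataclass
class DistanceSet:
    """Observed inter-crossover distances plus the context needed to refit them.

    ``distances`` has one row per adjacent event pair (sample, chrom,
    distance_bp); ``mean_events`` is the per-chromosome mean crossover count
    per gamete over *all* samples — it fixes the simulated intensity — and
    ``n_ge2`` counts the samples with >= 2 events per chromosome, which sets
    the simulation weights.
    """

    distances: pd.DataFrame
    chrom_lengths: dict[str, int]
    mean_events: dict[str, float]
    n_ge2: dict[str, int]
    n_samples: int
    pooled: bool = True
    #: optional per-chromosome (phys_bp, genetic_M) knots; when present the
    #: refit simulates on the same genetic-to-physical coordinate map that
    #: produced the data instead of assuming a uniform map
    genetic_maps: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    def n_distances(self) -> int:
        return len(self.distances)

    def normalized(self) -> np.ndarray:
        """Distances divided by their chromosome's physical length."""
        L = self.distances["chrom"].map(self.chrom_lengths).to_numpy(float)
        return self.distances["distance_bp"].to_numpy(float) / L

    def subset(self, mask) -> "DistanceSet":
        return DistanceSet(
            distances=self.distances.loc[mask].reset_index(drop=True),
            chrom_lengths=self.chrom_lengths,
            mean_events=self.mean_events,
            n_ge2=self.n_ge2,
            n_samples=self.n_samples,
            pooled=self.pooled,
            genetic_maps=self.genetic_maps,
        )


@dataclass
class GammaFit:
    """Result of a simulation-based gamma-model fit."""

    nu: float
    grid: np.ndarray
    discrepancy: np.ndarray
    statistic: str
    replicates: int
    seed: int
    n_obs: int
    censor_bp: tuple[float, float] | None = None
    ci: tuple[float, float] | None = None

    def profile(self) -> pd.DataFrame:
        return pd.DataFrame({"nu": self.grid, "discrepancy": self.discrepancy})


def inter_co_distances(
    events: pd.DataFrame,
    n_samples: int,
    genome: GenomeMap,
    min_events: int = 2,
) -> DistanceSet:
    """Distances between adjacent crossover midpoints.

    Every sample/chromosome with at least ``min_events`` events contributes
    ``events - 1`` adjacent-pair distances; chromosomes are pooled.
    """
    rows = []
    n_ge2 = {c: 0 for c in genome.names}
    ev_count = {c: 0 for c in genome.names}
    for (sample, chrom), grp in events.groupby(["sample", "chrom"]):
        mids = np.sort(grp["midpoint"].to_numpy(float))
        ev_count[chrom] = ev_count.get(chrom, 0) + len(mids)
        if len(mids) >= max(min_events, 2):
            n_ge2[chrom] = n_ge2.get(chrom, 0) + 1
            for d in np.diff(mids):
                rows.append({"sample": sample, "chrom": chrom, "distance_bp": float(d)})
    distances = pd.DataFrame(rows, columns=["sample", "chrom", "distance_bp"])
    return DistanceSet(
        distances=distances,
        chrom_lengths={c: genome.length(c) for c in genome.names},
        mean_events={c: ev_count.get(c, 0) / n_samples for c in genome.names},
        n_ge2=n_ge2,
        n_samples=n_samples,
        genetic_maps=genome.genetic_maps,
    )


def distance_histogram(
    dset: DistanceSet, class_width: float = 100e6, n_classes: int = 8
) -> pd.DataFrame:
    """Relative frequencies of inter-crossover distances in fixed-width classes.

    Classes run ``<w, w-2w, ..., >(n-1)w`` (default "<100" up to ">700" Mbp).
    Per-chromosome frequencies and their SD across chromosomes are retained
    alongside the pooled values.
    """
    if dset.n_distances() == 0:
        raise ValueError("empty distance set")
    d = dset.distances
    cls = np.minimum((d["distance_bp"] // class_width).astype(int), n_classes - 1)
    labels = [
        f"<{class_width / 1e6:g}"
        if k == 0
        else (f">{k * class_width / 1e6:g}" if k == n_classes - 1 else f"{k * class_width / 1e6:g}-{(k + 1) * class_width / 1e6:g}")
        for k in range(n_classes)
    ]
    out = pd.DataFrame({"class": labels, "low_bp": [k * class_width for k in range(n_classes)]})
    pooled = np.bincount(cls, minlength=n_classes)
    out["count"] = pooled
    out["frequency"] = pooled / pooled.sum()
    per_chrom = []
    for chrom, grp in d.groupby("chrom"):
        c = np.minimum((grp["distance_bp"] // class_width).astype(int), n_classes - 1)
        f = np.bincount(c, minlength=n_classes) / len(grp)
        out[f"freq_{chrom}"] = f
        per_chrom.append(f)
    out["sd_across_chroms"] = (
        np.std(np.vstack(per_chrom), axis=0, ddof=1) if len(per_chrom) > 1 else np.nan
    )
    return out


# --------------------------------------------------------------------------
# Simulation-based nu estimation
# --------------------------------------------------------------------------

_GAP_GRID_N = 4096


@functools.lru_cache(maxsize=512)
def _gap_ppf_table(nu: float) -> tuple[np.ndarray, np.ndarray]:
    """Dense quantile table of the Gamma(nu, rate 2*nu) gap distribution."""
    q = (np.arange(_GAP_GRID_N) + 0.5) / _GAP_GRID_N
    return q, stats.gamma.ppf(q, nu, scale=1.0 / (2.0 * nu))


def _conditioned_distances(
    nu: float,
    G: float,
    u0: np.ndarray,
    U: np.ndarray,
    Uthin: np.ndarray,
    need: int,
    coord_map: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Normalised inter-CO distances of simulated chromatids with >= 2 events.

    Uniform draws are fixed by the caller (common random numbers); here they
    are mapped through the candidate ``nu``'s inverse CDFs.  Genetic event
    positions on [0, G] are projected to normalised physical coordinates —
    linearly, or through ``coord_map`` (phys_bp, genetic_M) knots when the
    data's genetic-to-physical map is known.  Returns pooled adjacent-pair
    distances over the first ``need`` qualifying chromatids.
    """
    q, xtab = _gap_ppf_table(float(nu))
    x0 = forward_recurrence_ppf(u0, nu)
    gaps = np.interp(U, q, xtab)
    pos = x0[:, None] + np.concatenate(
        [np.zeros((len(x0), 1)), np.cumsum(gaps, axis=1)], axis=1
    )
    keep = (pos <= G) & (Uthin < 0.5)
    counts = keep.sum(axis=1)
    rows = np.flatnonzero(counts >= 2)[:need]
    if len(rows) == 0:
        return np.empty(0)
    if coord_map is None:
        return np.concatenate([np.diff(pos[r][keep[r]]) / G for r in rows])
    phys, gen = coord_map
    scale = gen[-1] / G if G > 0 else 1.0
    L = phys[-1]
    return np.concatenate(
        [np.diff(np.interp(pos[r][keep[r]] * scale, gen, phys)) / L for r in rows]
    )


def estimate_nu(
    dset: DistanceSet,
    grid: np.ndarray | None = None,
    replicates: int = 200,
    seed: int = 0,
    statistic: str = "cvm",
    censor_bp: tuple[float, float] | None = None,
    min_distances: int = 10,
    min_per_chrom: int = 10,
) -> GammaFit:
    """Estimate interference strength ``nu`` on a candidate grid.

    For every grid value, ``replicates`` chromatids (allocated across
    chromosomes in proportion to their observed >= 2-event sample counts) are
    simulated at the chromosome's observed crossover intensity, conditioned
    on >= 2 events, and their normalised inter-crossover distances are
    compared with the observed ones.  Ties in the discrepancy profile break
    toward smaller ``nu``.  ``censor_bp`` restricts both observed and
    simulated distances to a physical-distance window, for class-split fits.
    """
    if grid is None:
        grid = DEFAULT_GRID
    grid = np.asarray(grid, float)
    if len(grid) < 2 or np.any(np.diff(grid) <= 0) or grid[0] <= 0:
        raise ValueError("grid must be increasing positive nu values")
    obs = dset.normalized()
    if censor_bp is not None:
        L = dset.distances["chrom"].map(dset.chrom_lengths).to_numpy(float)
        lo, hi = censor_bp
        mask = (dset.distances["distance_bp"] > lo) & (dset.distances["distance_bp"] < hi)
        obs = obs[mask.to_numpy()]
    if len(obs) < min_distances:
        raise ValueError(
            f"only {len(obs)} inter-crossover distances; need >= {min_distances} to fit nu"
        )
    chroms = [
        c
        for c in dset.chrom_lengths
        if dset.n_ge2.get(c, 0) > 0 and dset.mean_events.get(c, 0.0) > 0
    ]
    if not chroms:
        raise ValueError("no chromosome with >= 2-event samples")
    wsum = sum(dset.n_ge2[c] for c in chroms)
    rng = np.random.default_rng(seed)
    draws = {}
    for c in chroms:
        n_c = max(min_per_chrom, int(round(replicates * dset.n_ge2[c] / wsum)))
        G = dset.mean_events[c]
        n_raw = 6 * n_c + 64
        K = int(np.ceil(4.0 * G)) + 24
        draws[c] = (
            G,
            n_c,
            rng.random(n_raw),
            rng.random((n_raw, K)),
            rng.random((n_raw, K + 1)),
        )
    disc = np.empty(len(grid))
    for i, nu in enumerate(grid):
        sims = []
        for c in chroms:
            G, n_c, u0, U, Uthin = draws[c]
            coord_map = None
            if dset.genetic_maps is not None and c in dset.genetic_maps:
                coord_map = dset.genetic_maps[c]
            d = _conditioned_distances(nu, G, u0, U, Uthin, n_c, coord_map)
            if censor_bp is not None:
                Lc = dset.chrom_lengths[c]
                d = d[(d > censor_bp[0] / Lc) & (d < censor_bp[1] / Lc)]
            sims.append(d)
        sim = np.concatenate(sims) if sims else np.empty(0)
        if len(sim) < 2:
            disc[i] = np.inf
            continue
        if statistic == "cvm":
            disc[i] = stats.cramervonmises_2samp(obs, sim, method="asymptotic").statistic
        elif statistic == "ks":
            disc[i] = stats.ks_2samp(obs, sim).statistic
        else:
            raise ValueError(f"unknown statistic {statistic!r}")
    best = int(np.argmin(disc))  # first minimum = smallest nu on ties
    return GammaFit(
        nu=float(grid[best]),
        grid=grid,
        discrepancy=disc,
        statistic=statistic,
        replicates=replicates,
        seed=seed,
        n_obs=len(obs),
        censor_bp=censor_bp,
    )


def bootstrap_nu_ci(
    dset: DistanceSet,
    n_boot: int = 20,
    level: float = 0.9,
    seed: int = 0,
    **fit_kwargs,
) -> tuple[float, float]:
    """Percentile bootstrap CI for ``nu`` by resampling samples with replacement."""
    rng = np.random.default_rng(seed)
    ids = dset.distances["sample"].unique()
    if len(ids) < 2:
        raise ValueError("need >= 2 samples to bootstrap")
    est = []
    for b in range(n_boot):
        pick = rng.choice(ids, size=len(ids), replace=True)
        parts = [
            dset.distances[dset.distances["sample"] == s].assign(sample=f"b{j}")
            for j, s in enumerate(pick)
        ]
        boot = dset.subset(slice(None))
        boot.distances = pd.concat(parts, ignore_index=True)
        try:
            est.append(estimate_nu(boot, seed=int(rng.integers(2**31)), **fit_kwargs).nu)
        except ValueError:
            continue
    if len(est) < 2:
        raise ValueError("bootstrap produced too few fits")
    lo, hi = np.quantile(est, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)


def class_split_fit(
    dset: DistanceSet,
    near: float = 100e6,
    far: float = 400e6,
    grid: np.ndarray | None = None,
    replicates: int = 200,
    seed: int = 0,
    min_distances: int = 10,
) -> dict[str, GammaFit]:
    """Separate gamma fits for short- and long-range inter-crossover distances.

    Distances below ``near`` and above ``far`` (bp) are fitted separately,
    with the simulated comparison distances censored to the same physical
    window; a mixture of interference-sensitive (class I) and insensitive
    (class II) crossovers shows a smaller ``nu`` in the near group.
    """
    d = dset.distances["distance_bp"]
    near_set = dset.subset((d < near).to_numpy())
    far_set = dset.subset((d > far).to_numpy())
    for name, sub in (("near", near_set), ("far", far_set)):
        if sub.n_distances() < min_distances:
            raise ValueError(
                f"{name} group has only {sub.n_distances()} distances (< {min_distances})"
            )
    return {
        "near": estimate_nu(
            near_set, grid, replicates, seed, censor_bp=(0.0, near), min_distances=min_distances
        ),
        "far": estimate_nu(
            far_set, grid, replicates, seed, censor_bp=(far, np.inf), min_distances=min_distances
        ),
    }


def co_position_scatter(events: pd.DataFrame, genome: GenomeMap) -> pd.DataFrame:
    """First vs second crossover positions for samples with >= 2 events.

    The quadrant classifies the pair relative to the chromosome midpoint:
    both proximal ("same arm, proximal-left"), both distal
    ("same arm, distal-right"), or one on each arm ("opposite arms").
    """
    rows = []
    for (sample, chrom), grp in events.groupby(["sample", "chrom"]):
        mids = np.sort(grp["midpoint"].to_numpy(float))
        if len(mids) < 2:
            continue
        first, second = mids[0], mids[1]
        centre = genome.length(chrom) / 2.0
        if second <= centre:
            quadrant = "same arm, proximal-left"
        elif first >= centre:
            quadrant = "same arm, distal-right"
        else:
            quadrant = "opposite arms"
        rows.append(
            {
                "sample": sample,
                "chrom": chrom,
                "first_bp": first,
                "second_bp": second,
                "quadrant": quadrant,
            }
        )
    return pd.DataFrame(rows, columns=["sample", "chrom", "first_bp", "second_bp", "quadrant"])
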