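"""Crossover calling from binned genotype vectors, with marker curation.

A crossover is a transition between two adjacent *informative* (non-missing)
bins with different parental codes, e.g. ``0 0 0 2 2 2``; missing bins are
skipped, never used as boundaries.  Before calling, bins showing a high rate
of the singleton-flip motif (``0 2 0`` / ``2 0 2`` with agreeing flanks,
missing bins bridged) across samples are masked: an isolated double-crossover
within ~2 Mbp is far more likely a genotyping artefact than two real,
tightly-spaced crossovers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import CODE_MISSING, GenotypeMatrix

EVENT_COLUMNS = ["sample", "chrom", "left", "right", "midpoint", "left_code", "right_code"]


@dataclass
class CurationReport:
    """Outcome of singleton-flip curation."""

    flip_rates: dict[str, np.ndarray]  # initial per-bin rate, aligned with bin_starts
    removed: dict[str, np.ndarray]  # bin start coordinates masked per chromosome
    threshold: float
    iterations: int

    def n_removed(self) -> int:
        return sum(len(v) for v in self.removed.values())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom, starts in self.removed.items():
            for s in starts:
                rows.append({"chrom": chrom, "bin_start": int(s), "threshold": self.threshold})
        return pd.DataFrame(rows, columns=["chrom", "bin_start", "threshold"])


def _flip_counts_vector(codes: np.ndarray) -> np.ndarray:
    """Per-bin singleton-flip indicator for one sample vector."""
    out = np.zeros(codes.shape, np.int32)
    idx = np.flatnonzero(codes != CODE_MISSING)
    if len(idx) < 3:
        return out
    v = codes[idx]
    hit = (v[1:-1] != v[:-2]) & (v[:-2] == v[2:])
    out[idx[1:-1][hit]] = 1
    return out


def singleton_flip_rate(matrix: GenotypeMatrix) -> dict[str, np.ndarray]:
    """Fraction of samples in which each bin is a singleton flip.

    A bin counts as flipped in a sample when its call differs from both
    nearest non-missing flanking calls while those flanks agree with each
    other.
    """
    if matrix.n_samples() < 2:
        raise ValueError("need at least 2 samples to estimate flip rates")
    rates = {}
    for chrom in matrix.chroms:
        codes = matrix.codes[chrom]
        counts = np.zeros(codes.shape[1], np.int32)
        for s in range(codes.shape[0]):
            counts += _flip_counts_vector(codes[s])
        rates[chrom] = counts / matrix.n_samples()
    return rates


def curate(
    matrix: GenotypeMatrix, max_flip_rate: float = 0.1
) -> tuple[GenotypeMatrix, CurationReport]:
    """Mask bins whose singleton-flip rate exceeds ``max_flip_rate``.

    Masking a bin can bridge its flanks and expose a new singleton motif, so
    the rule is applied to a fixed point; the result is therefore idempotent.
    Masked bins are set to missing in all samples (positions retained).
    """
    out = matrix.copy()
    initial_rates: dict[str, np.ndarray] | None = None
    removed = {chrom: np.zeros(0, np.int64) for chrom in matrix.chroms}
    iterations = 0
    while True:
        rates = singleton_flip_rate(out)
        if initial_rates is None:
            initial_rates = rates
        hit = False
        for chrom in out.chroms:
            bad = rates[chrom] > max_flip_rate
            if bad.any():
                hit = True
                out.codes[chrom][:, bad] = CODE_MISSING
                removed[chrom] = np.union1d(removed[chrom], out.bin_starts[chrom][bad])
        iterations += 1
        if not hit:
            break
    report = CurationReport(
        flip_rates=initial_rates, removed=removed, threshold=max_flip_rate, iterations=iterations
    )
    return out, report


def mask_singletons(matrix: GenotypeMatrix) -> tuple[GenotypeMatrix, int]:
    """Set each sample's singleton-flip bins to missing, to a fixed point.

    Bin-level curation removes systematically error-prone bins; this step
    additionally discards the isolated double-crossover motif within single
    samples (a lone bin disagreeing with both agreeing flanks), the signature
    of a sporadic miscall.  A real crossover pair produces a run of
    opposite-parent bins, which is untouched unless only one of them was
    observed — the price is losing double crossovers tighter than the bin
    resolution, which are undetectable here anyway.  Returns the masked
    matrix and the number of masked cells.
    """
    out = matrix.copy()
    n_masked = 0
    for chrom in out.chroms:
        codes = out.codes[chrom]
        for s in range(codes.shape[0]):
            while True:
                hits = _flip_counts_vector(codes[s]).astype(bool)
                if not hits.any():
                    break
                codes[s, hits] = CODE_MISSING
                n_masked += int(hits.sum())
    return out, n_masked


# --------------------------------------------------------------------------
# Event detection
# --------------------------------------------------------------------------


def detect_events_vector(
    codes: np.ndarray, bin_starts: np.ndarray, bin_ends: np.ndarray
) -> list[tuple[int, int, int, int]]:
    """Crossovers in one sample vector: ``(left, right, left_code, right_code)``.

    ``left`` is the end of the last informative bin of the preceding parent
    and ``right`` the start of the first informative bin of the following
    parent; for directly adjacent informative bins the interval collapses to
    the shared bin boundary (left == right), reflecting sub-bin resolution.
    """
    idx = np.flatnonzero(codes != CODE_MISSING)
    events = []
    for a, b in zip(idx[:-1], idx[1:]):
        if codes[a] != codes[b]:
            events.append((int(bin_ends[a]), int(bin_starts[b]), int(codes[a]), int(codes[b])))
    return events


def detect_events(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Crossover events for every sample and chromosome.

    Returns a DataFrame with columns ``sample, chrom, left, right, midpoint,
    left_code, right_code``; events are ordered along each chromosome and the
    flanking codes of consecutive events alternate.
    """
    rows = []
    for chrom in matrix.chroms:
        starts = matrix.bin_starts[chrom]
        ends = matrix.bin_ends(chrom)
        for s, sample in enumerate(matrix.samples):
            for left, right, lc, rc in detect_events_vector(matrix.codes[chrom][s], starts, ends):
                rows.append(
                    {
                        "sample": sample,
                        "chrom": chrom,
                        "left": left,
                        "right": right,
                        "midpoint": (left + right) / 2.0,
                        "left_code": lc,
                        "right_code": rc,
                    }
                )
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def write_events_bed(events: pd.DataFrame, path) -> None:
    bed = events[["chrom", "left", "right", "sample"]].copy()
    bed["score"] = 1
    bed.to_csv(path, sep="\t", index=False, header=False)


# --------------------------------------------------------------------------
# Event-count summaries
# --------------------------------------------------------------------------


@dataclass
class EventCountSummary:
    """Per-chromosome and pooled distribution of events per sample."""

    class_counts: pd.DataFrame  # rows = event classes 0..k, cols = chroms + "pooled"
    class_freq: pd.DataFrame  # same, as relative frequencies
    total_events: int
    n_samples: int
    mean_per_sample: float
    se_per_sample: float


def mean_events_per_sample(total_events: int, n_samples: int) -> float:
    """Population mean crossovers per gamete from the total event count."""
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    return total_events / n_samples


def count_per_chromosome(
    events: pd.DataFrame, samples: list[str], chroms: list[str]
) -> EventCountSummary:
    """Distribution of per-chromosome event counts across samples.

    Every (sample, chromosome) pair counts, including those with zero
    events; "pooled" aggregates the seven per-chromosome distributions.
    """
    counts = np.zeros((len(samples), len(chroms)), np.int64)
    s_idx = {s: i for i, s in enumerate(samples)}
    c_idx = {c: i for i, c in enumerate(chroms)}
    for (sample, chrom), grp in events.groupby(["sample", "chrom"]):
        if sample in s_idx and chrom in c_idx:
            counts[s_idx[sample], c_idx[chrom]] = len(grp)
    kmax = int(counts.max()) if counts.size else 0
    classes = np.arange(kmax + 1)
    table = pd.DataFrame(index=pd.Index(classes, name="n_events"))
    for j, chrom in enumerate(chroms):
        table[chrom] = [(counts[:, j] == k).sum() for k in classes]
    table["pooled"] = table[chroms].sum(axis=1)
    freq = table / table.sum(axis=0)
    per_sample_tot = counts.sum(axis=1)
    n = len(samples)
    return EventCountSummary(
        class_counts=table,
        class_freq=freq,
        total_events=int(counts.sum()),
        n_samples=n,
        mean_per_sample=mean_events_per_sample(int(counts.sum()), n),
        se_per_sample=float(per_sample_tot.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
    )


def chi2_goodness_of_fit(
    counts_obs: np.ndarray, counts_ref: np.ndarray, min_expected: float = 1.0
) -> tuple[float, float]:
    """Chi-square of observed class counts against another population's proportions.

    Tail classes are pooled until every expected count reaches
    ``min_expected``.  Returns ``(statistic, P)``.
    """
    obs = np.asarray(counts_obs, float)
    ref = np.asarray(counts_ref, float)
    if obs.sum() <= 0 or ref.sum() <= 0:
        raise ValueError("class counts must have positive totals")
    if obs.shape != ref.shape:
        raise ValueError("class supports differ")
    exp = obs.sum() * ref / ref.sum()
    # pool from the tail so expected counts are not tiny
    while len(exp) > 1 and exp[-1] < min_expected:
        exp = np.r_[exp[:-2], exp[-2] + exp[-1]]
        obs = np.r_[obs[:-2], obs[-2] + obs[-1]]
    stat = float(((obs - exp) ** 2 / exp).sum())
    dof = len(exp) - 1
    p = float(stats.chi2.sf(stat, dof)) if dof > 0 else 1.0
    return stat, p


def chi2_homogeneity(
    counts_a: np.ndarray, counts_b: np.ndarray, min_expected: float = 1.0
) -> tuple[float, float]:
    """Two-sample chi-square test that both class counts share one distribution.

    Unlike :func:`chi2_goodness_of_fit` — which conditions on the reference
    proportions and is anticonservative when the reference is itself a small
    sample — the homogeneity test accounts for sampling noise in both
    populations, so its P-values are calibrated for two finite samples.
    Tail classes are pooled until expected counts reach ``min_expected``.
    """
    a = np.asarray(counts_a, float)
    b = np.asarray(counts_b, float)
    if a.sum() <= 0 or b.sum() <= 0:
        raise ValueError("class counts must have positive totals")
    if a.shape != b.shape:
        raise ValueError("class supports differ")
    exp_min = (a + b) * min(a.sum(), b.sum()) / (a.sum() + b.sum())
    while len(a) > 1 and exp_min[-1] < min_expected:
        a = np.r_[a[:-2], a[-2] + a[-1]]
        b = np.r_[b[:-2], b[-2] + b[-1]]
        exp_min = np.r_[exp_min[:-2], exp_min[-2] + exp_min[-1]]
    if len(a) < 2:
        return 0.0, 1.0
    stat, p = stats.chi2_contingency(np.vstack([a, b]), correction=False)[:2]
    return float(stat), float(p)
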