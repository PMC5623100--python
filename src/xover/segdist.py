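"""Segregation-distortion scan: allele frequencies in sliding windows,
chi-square tests against the Mendelian 1:1 ratio, and SDR delineation.

Two counting modes are available for the per-window test.  The default
"sample" mode reduces each sample to one consensus call per window (majority
of its non-missing bins) before counting, so the chi-square operates on
independent units and holds its nominal type-I error.  The "bin" mode pools
raw bin calls across samples and bins; it mirrors testing the window's
average allele frequency directly but is anticonservative, because adjacent
bins of one gamete share parental origin and are far from independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeMap
from .genotypes import CODE_MISSING, CODE_PARENT1, CODE_PARENT2, GenotypeMatrix

TRACK_COLUMNS = [
    "chrom",
    "start",
    "end",
    "n_parent1",
    "n_parent2",
    "freq_parent1",
    "freq_parent2",
    "chi2",
    "p_value",
    "tested",
]


def chi2_1to1(count_a, count_b) -> tuple[np.ndarray, np.ndarray]:
    """One-df chi-square of two counts against equal expectation (no continuity
    correction).  Accepts scalars or arrays; returns ``(statistic, P)``."""
    a = np.asarray(count_a, float)
    b = np.asarray(count_b, float)
    tot = a + b
    if np.any(tot < 1):
        raise ValueError("need count_a + count_b >= 1")
    stat = (a - b) ** 2 / tot
    return stat, stats.chi2.sf(stat, 1)


def _window_counts_sample_mode(c1_cum, c2_cum, i0, i1) -> tuple[np.ndarray, np.ndarray]:
    """Counts of samples whose within-window majority call is parent 1 / 2."""
    n1 = c1_cum[:, i1] - c1_cum[:, i0]  # (S, W)
    n2 = c2_cum[:, i1] - c2_cum[:, i0]
    a = (n1 > n2).sum(axis=0)
    b = (n2 > n1).sum(axis=0)
    return a, b


def allele_freq_windows(
    matrix: GenotypeMatrix,
    window: int = 10_000_000,
    step: int = 1_000_000,
    mode: str = "sample",
) -> pd.DataFrame:
    """Parental allele frequencies and 1:1 chi-square per sliding window.

    Windows with no informative calls are flagged ``tested = False`` and get
    no statistic.  ``mode`` is "sample" (one consensus call per sample per
    window; calibrated) or "bin" (pooled bin calls).
    """
    if mode not in ("sample", "bin"):
        raise ValueError("mode must be 'sample' or 'bin'")
    parts = []
    for chrom in matrix.chroms:
        L = matrix.chrom_lengths[chrom]
        starts = np.arange(0, L, step, dtype=np.int64)
        ends = np.minimum(starts + window, L)
        bs = matrix.bin_starts[chrom]
        codes = matrix.codes[chrom]
        is1 = (codes == CODE_PARENT1).astype(np.int64)
        is2 = (codes == CODE_PARENT2).astype(np.int64)
        zero = np.zeros((codes.shape[0], 1), np.int64)
        c1_cum = np.concatenate([zero, np.cumsum(is1, axis=1)], axis=1)
        c2_cum = np.concatenate([zero, np.cumsum(is2, axis=1)], axis=1)
        # bins are assigned to a window by their start coordinate
        i0 = np.searchsorted(bs, starts, side="left")
        i1 = np.searchsorted(bs, ends, side="left")
        if mode == "bin":
            a = c1_cum[:, i1].sum(axis=0) - c1_cum[:, i0].sum(axis=0)
            b = c2_cum[:, i1].sum(axis=0) - c2_cum[:, i0].sum(axis=0)
        else:
            a, b = _window_counts_sample_mode(c1_cum, c2_cum, i0, i1)
        tot = a + b
        tested = tot >= 1
        stat = np.full(len(starts), np.nan)
        pval = np.full(len(starts), np.nan)
        if tested.any():
            stat[tested], pval[tested] = chi2_1to1(a[tested], b[tested])
        with np.errstate(invalid="ignore"):
            f1 = np.where(tested, a / np.maximum(tot, 1), np.nan)
        parts.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": ends,
                    "n_parent1": a,
                    "n_parent2": b,
                    "freq_parent1": f1,
                    "freq_parent2": 1.0 - f1,
                    "chi2": stat,
                    "p_value": pval,
                    "tested": tested,
                },
                columns=TRACK_COLUMNS,
            )
        )
    return pd.concat(parts, ignore_index=True)


SDR_COLUMNS = ["chrom", "start", "end", "direction", "size_bp", "frac_chrom_pct", "min_p"]


def call_sdrs(
    track: pd.DataFrame,
    chrom_lengths: dict[str, int],
    alpha: float = 0.05,
    correction: str | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Merge significant windows into segregation-distortion regions.

    Windows with P < ``alpha`` (uncorrected by default; ``correction="bh"``
    applies Benjamini-Hochberg across all tested windows) are merged into
    maximal runs of overlapping/adjacent windows distorted toward the same
    parent.  The summary reports, per population, the fraction of the genome
    inside SDRs as the union of significant base pairs (overlapping windows
    are never double-counted).
    """
    t = track.copy()
    pv = t["p_value"].to_numpy(float)
    if correction == "bh":
        tested = t["tested"].to_numpy(bool) & ~np.isnan(pv)
        padj = np.full(len(t), np.nan)
        p = pv[tested]
        order = np.argsort(p)
        m = len(p)
        ranked = p[order] * m / (np.arange(m) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        adj = np.empty(m)
        adj[order] = np.minimum(ranked, 1.0)
        padj[tested] = adj
        pv = padj
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")
    sig = t["tested"].to_numpy(bool) & (pv < alpha)
    direction = np.where(t["freq_parent1"].to_numpy(float) > 0.5, 1, 2)
    regions = []
    sig_bp = 0
    for chrom in t["chrom"].unique():
        m = (t["chrom"] == chrom).to_numpy()
        sub = t[m]
        s_sig = sig[m]
        s_dir = direction[m]
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        ps = pv[m]
        cur = None
        for i in np.flatnonzero(s_sig):
            if (
                cur is not None
                and s_dir[i] == cur["direction"]
                and starts[i] <= cur["end"]
            ):
                cur["end"] = max(cur["end"], ends[i])
                cur["min_p"] = min(cur["min_p"], ps[i])
            else:
                if cur is not None:
                    regions.append(cur)
                cur = {
                    "chrom": chrom,
                    "start": int(starts[i]),
                    "end": int(ends[i]),
                    "direction": int(s_dir[i]),
                    "min_p": float(ps[i]),
                }
        if cur is not None:
            regions.append(cur)
        # union of significant base pairs, direction-agnostic
        iv = sorted(zip(starts[s_sig], ends[s_sig]))
        last_end = -1
        for a, b in iv:
            a = max(a, last_end)
            if b > a:
                sig_bp += b - a
                last_end = b
            last_end = max(last_end, b)
    out = pd.DataFrame(regions, columns=["chrom", "start", "end", "direction", "min_p"])
    if len(out):
        out["size_bp"] = out["end"] - out["start"]
        out["frac_chrom_pct"] = [
            100.0 * r.size_bp / chrom_lengths[r.chrom] for r in out.itertuples()
        ]
        out["direction"] = out["direction"].map({1: "parent1", 2: "parent2"})
        out = out[SDR_COLUMNS]
    else:
        out = pd.DataFrame(columns=SDR_COLUMNS)
    genome_bp = sum(chrom_lengths.values())
    summary = {
        "n_sdrs": len(out),
        "significant_bp": int(sig_bp),
        "genome_pct": 100.0 * sig_bp / genome_bp,
        "alpha": alpha,
        "correction": correction,
    }
    return out, summary


def write_sdr_bed(sdrs: pd.DataFrame, path) -> None:
    bed = sdrs[["chrom", "start", "end", "direction"]].copy()
    bed["score"] = np.round(-np.log10(np.maximum(sdrs["min_p"], 1e-300)), 3)
    bed.to_csv(path, sep="\t", index=False, header=False)
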