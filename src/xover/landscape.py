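"""Sliding-window recombination landscape in cM/Mbp.

Each window's genetic length is ``cM = 100 * events / N`` where ``events``
counts crossover midpoints falling in the window and ``N`` is the number of
gametes; dividing by the window span in Mbp gives the local recombination
rate.  With non-overlapping windows the track sums exactly to the chromosome
genetic length ``100 * total_events / N`` cM.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import GenomeMap

TRACK_COLUMNS = ["chrom", "start", "end", "count", "cM", "cM_per_Mbp", "n_samples"]


def recomb_frequency(
    events: pd.DataFrame,
    chrom: str,
    chrom_length: int,
    n_samples: int,
    window: int = 5_000_000,
    step: int = 1_000_000,
) -> pd.DataFrame:
    """Recombination-rate track for one chromosome.

    Windows are 0-based half-open, starting every ``step`` bp; the final
    partial window is truncated at the chromosome end and its cM/Mbp uses the
    actual span.  An event belongs to every window containing its midpoint.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if not (window >= step > 0):
        raise ValueError("need window >= step > 0")
    mids = np.sort(
        events.loc[events["chrom"] == chrom, "midpoint"].to_numpy(float)
    )
    starts = np.arange(0, chrom_length, step, dtype=np.int64)
    ends = np.minimum(starts + window, chrom_length)
    counts = np.searchsorted(mids, ends, side="left") - np.searchsorted(mids, starts, side="left")
    cm = 100.0 * counts / n_samples
    span_mbp = (ends - starts) / 1e6
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": ends,
            "count": counts,
            "cM": cm,
            "cM_per_Mbp": cm / span_mbp,
            "n_samples": n_samples,
        },
        columns=TRACK_COLUMNS,
    )


def landscape_tracks(
    events: pd.DataFrame,
    genome: GenomeMap,
    n_samples: int,
    window: int = 5_000_000,
    step: int = 1_000_000,
) -> pd.DataFrame:
    """Concatenated recombination tracks for all chromosomes."""
    return pd.concat(
        [
            recomb_frequency(events, c, genome.length(c), n_samples, window, step)
            for c in genome.names
        ],
        ignore_index=True,
    )


def genetic_length_cM(events: pd.DataFrame, chrom: str, chrom_length: int, n_samples: int) -> float:
    """Chromosome genetic length implied by the event counts (cM)."""
    n_ev = int((events["chrom"] == chrom).sum())
    return 100.0 * n_ev / n_samples


def write_bedgraph(track: pd.DataFrame, path, value: str = "cM_per_Mbp") -> None:
    track[["chrom", "start", "end", value]].to_csv(
        path, sep="\t", index=False, header=False, float_format="%.6g"
    )
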