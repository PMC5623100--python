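"""End-to-end runs: simulate (or load) -> bin -> curate -> call -> tracks.

A run is driven by a :class:`RunConfig` (YAML-serialisable; every parameter
defaults to the documented module default), writes all tables into a run
directory together with a manifest of parameters and input checksums, and is
deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import crossovers, genotypes, interference, landscape, segdist
from .genome import GenomeMap, default_genome, read_marker_table
from .simulate import (
    MeiosisModel,
    ObservationModel,
    SelectionModel,
    simulate_population,
    write_population_vcf,
    write_truth_table,
)

FLOAT_FMT = "%.10g"


@dataclass
class SimulateConfig:
    n_samples: int = 40
    nu: float = 3.0
    genetic_length: float = 1.36
    obligate_co: bool = False
    map_kind: str = "distal"
    marker_spacing: int = 100_000
    detect_prob: float = 0.1
    error_rate: float = 0.0005
    bad_region_frac: float = 0.005
    bad_region_error: float = 0.4
    selection_loci: list = field(default_factory=list)  # [chrom, pos, p] triples


@dataclass
class InputConfig:
    vcf: str = ""
    markers: str = ""
    chrom_lengths: dict = field(default_factory=dict)  # name -> bp


@dataclass
class Params:
    bin_size: int = 1_000_000
    min_support: int = 1
    purity: float = 0.8
    max_flip_rate: float = 0.1
    drop_singletons: bool = True
    max_missing: float = 0.5
    landscape_window: int = 5_000_000
    landscape_step: int = 1_000_000
    sd_window: int = 10_000_000
    sd_step: int = 1_000_000
    sd_mode: str = "sample"
    alpha: float = 0.05
    nu_grid: list = field(default_factory=lambda: [0.5, 12.0, 0.25])  # lo, hi, step
    nu_replicates: int = 200
    fit_interference: bool = True


@dataclass
class RunConfig:
    seed: int = 0
    label: str = "run"
    simulate: SimulateConfig | None = None
    input: InputConfig | None = None
    params: Params = field(default_factory=Params)

    def validate(self) -> None:
        if (self.simulate is None) == (self.input is None):
            raise ValueError("config must set exactly one of 'simulate' or 'input'")
        if self.input is not None:
            for key in ("vcf", "markers"):
                p = getattr(self.input, key)
                if not p or not Path(p).exists():
                    raise ValueError(f"input.{key} missing or does not exist: {p!r}")
            if not self.input.chrom_lengths:
                raise ValueError("input.chrom_lengths must map chromosome -> length")
        p = self.params
        if p.bin_size <= 0 or p.purity < 0.5 or not 0 <= p.alpha <= 1:
            raise ValueError("invalid params")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: v for k, v in d.items() if v is not None}

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("simulate", None)
        inp = d.pop("input", None)
        par = d.pop("params", {})
        return cls(
            simulate=SimulateConfig(**sim) if sim is not None else None,
            input=InputConfig(**inp) if inp is not None else None,
            params=Params(**par),
            **d,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def write_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _md5(path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _nu_grid(bounds: list) -> np.ndarray:
    lo, hi, step = bounds
    return np.round(np.arange(lo, hi + 1e-9, step), 6)


def simulate_inputs(config: RunConfig, out_dir: Path) -> tuple[GenomeMap, Path]:
    """Generate the synthetic population and write VCF/markers/truth files."""
    sim = config.simulate
    genome = default_genome(
        marker_spacing=sim.marker_spacing,
        genetic_length=sim.genetic_length,
        map_kind=sim.map_kind,
        seed=config.seed,
    )
    meiosis = MeiosisModel(nu=sim.nu, obligate_co=sim.obligate_co)
    obs = ObservationModel(
        detect_prob=sim.detect_prob,
        error_rate=sim.error_rate,
        bad_region_frac=sim.bad_region_frac,
        bad_region_error=sim.bad_region_error,
    )
    selection = SelectionModel(
        loci=tuple((c, int(p), float(q)) for c, p, q in sim.selection_loci)
    )
    gametes, calls = simulate_population(
        genome, meiosis, obs, selection, n_samples=sim.n_samples, seed=config.seed
    )
    genome.write_marker_table(out_dir / "markers.tsv")
    write_truth_table(gametes, calls.samples, out_dir / "truth.tsv")
    vcf_path = out_dir / "population.vcf"
    write_population_vcf(calls, genome, vcf_path)
    return genome, vcf_path


def run_all(config: RunConfig, out_dir) -> dict:
    """Execute the full pipeline; returns in-memory results and writes files."""
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    par = config.params
    config.write_yaml(out_dir / "config.yaml")

    if config.simulate is not None:
        genome, vcf_path = simulate_inputs(config, out_dir)
        markers_path = out_dir / "markers.tsv"
    else:
        markers_path = Path(config.input.markers)
        genome = GenomeMap(
            chromosomes={k: int(v) for k, v in config.input.chrom_lengths.items()},
            markers=read_marker_table(markers_path),
        )
        vcf_path = Path(config.input.vcf)

    calls, call_stats = genotypes.read_calls(vcf_path, genome)
    matrix = genotypes.bin_consensus(
        calls, genome, bin_size=par.bin_size, min_support=par.min_support, purity=par.purity
    )
    matrix.write_tsv(out_dir / "matrix.tsv")

    curated, report = crossovers.curate(matrix, max_flip_rate=par.max_flip_rate)
    report.to_frame().to_csv(out_dir / "curation.tsv", sep="\t", index=False)
    n_singletons = 0
    if par.drop_singletons:
        curated, n_singletons = crossovers.mask_singletons(curated)

    events = crossovers.detect_events(curated)
    events.to_csv(out_dir / "events.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
    crossovers.write_events_bed(events, out_dir / "events.bed")
    summary = crossovers.count_per_chromosome(events, curated.samples, genome.names)
    summary.class_freq.to_csv(out_dir / "event_classes.tsv", sep="\t", float_format=FLOAT_FMT)

    track = landscape.landscape_tracks(
        events, genome, curated.n_samples(), window=par.landscape_window, step=par.landscape_step
    )
    track.to_csv(out_dir / "landscape.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
    landscape.write_bedgraph(track, out_dir / "landscape.bedgraph")

    filtered, removed = genotypes.filter_missing(curated, max_missing=par.max_missing)
    sd_track = segdist.allele_freq_windows(
        filtered, window=par.sd_window, step=par.sd_step, mode=par.sd_mode
    )
    sd_track.to_csv(out_dir / "segdist.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
    sdrs, sd_summary = segdist.call_sdrs(sd_track, genome.chromosomes, alpha=par.alpha)
    sdrs.to_csv(out_dir / "sdrs.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
    segdist.write_sdr_bed(sdrs, out_dir / "sdrs.bed")

    dset = interference.inter_co_distances(events, curated.n_samples(), genome)
    dset.distances.to_csv(out_dir / "distances.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
    fit = None
    if par.fit_interference:
        try:
            fit = interference.estimate_nu(
                dset,
                grid=_nu_grid(par.nu_grid),
                replicates=par.nu_replicates,
                seed=config.seed,
            )
            fit.profile().to_csv(
                out_dir / "gamma_profile.tsv", sep="\t", index=False, float_format=FLOAT_FMT
            )
        except ValueError:
            fit = None
    if dset.n_distances() > 0:
        interference.distance_histogram(dset).to_csv(
            out_dir / "distance_histogram.tsv", sep="\t", index=False, float_format=FLOAT_FMT
        )

    run_summary = {
        "label": config.label,
        "n_samples": curated.n_samples(),
        "total_events": summary.total_events,
        "mean_events_per_sample": summary.mean_per_sample,
        "se_events_per_sample": summary.se_per_sample,
        "event_class_counts": summary.class_counts["pooled"].tolist(),
        "nu": None if fit is None else fit.nu,
        "sdr_genome_pct": sd_summary["genome_pct"],
        "n_sdrs": sd_summary["n_sdrs"],
        "curated_bins": report.n_removed(),
        "masked_singletons": n_singletons,
        "filtered_bins": sum(removed.values()),
    }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(run_summary, fh, indent=1, sort_keys=True)

    manifest = {
        "package": "xover",
        "config": config.to_dict(),
        "inputs": {
            "vcf": {"path": str(vcf_path), "md5": _md5(vcf_path)},
            "markers": {"path": str(markers_path), "md5": _md5(markers_path)},
        },
        "call_stats": call_stats,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)

    return {
        "genome": genome,
        "config": config,
        "matrix": matrix,
        "curated": curated,
        "curation_report": report,
        "events": events,
        "event_summary": summary,
        "landscape": track,
        "sd_track": sd_track,
        "sdrs": sdrs,
        "sd_summary": sd_summary,
        "distances": dset,
        "gamma_fit": fit,
        "summary": run_summary,
        "out_dir": out_dir,
    }


def compare_populations(res_a: dict, res_b: dict) -> dict:
    """Side-by-side comparison of two completed runs on the same genome.

    Reports the event-class chi-square (are per-chromosome crossover counts
    distributed alike?), the two interference estimates, the SDR genome
    fractions, and every config parameter that differs.
    """
    ga, gb = res_a["genome"], res_b["genome"]
    if ga.chromosomes != gb.chromosomes:
        raise ValueError("runs use different genome maps")
    ca = np.asarray(res_a["summary"]["event_class_counts"], float)
    cb = np.asarray(res_b["summary"]["event_class_counts"], float)
    k = max(len(ca), len(cb))
    ca = np.pad(ca, (0, k - len(ca)))
    cb = np.pad(cb, (0, k - len(cb)))
    stat, p = crossovers.chi2_goodness_of_fit(ca, cb)
    pa = dataclasses.asdict(res_a["config"].params)
    pb = dataclasses.asdict(res_b["config"].params)
    sa = dataclasses.asdict(res_a["config"].simulate) if res_a["config"].simulate else {}
    sb = dataclasses.asdict(res_b["config"].simulate) if res_b["config"].simulate else {}
    diffs = {
        k: {"a": pa.get(k, sa.get(k)), "b": pb.get(k, sb.get(k))}
        for k in set(pa) | set(pb) | set(sa) | set(sb)
        if pa.get(k, sa.get(k)) != pb.get(k, sb.get(k))
    }
    overlay = pd.merge(
        res_a["landscape"][["chrom", "start", "end", "cM_per_Mbp"]],
        res_b["landscape"][["chrom", "start", "end", "cM_per_Mbp"]],
        on=["chrom", "start", "end"],
        suffixes=("_a", "_b"),
    )
    return {
        "labels": (res_a["summary"]["label"], res_b["summary"]["label"]),
        "event_class_chi2": stat,
        "event_class_p": p,
        "nu": (res_a["summary"]["nu"], res_b["summary"]["nu"]),
        "sdr_genome_pct": (
            res_a["summary"]["sdr_genome_pct"],
            res_b["summary"]["sdr_genome_pct"],
        ),
        "mean_events_per_sample": (
            res_a["summary"]["mean_events_per_sample"],
            res_b["summary"]["mean_events_per_sample"],
        ),
        "parameter_diffs": diffs,
        "landscape_overlay": overlay,
    }


def write_comparison(cmp: dict, out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cmp = dict(cmp)
    overlay = cmp.pop("landscape_overlay")
    overlay.to_csv(out_dir / "landscape_overlay.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
    with open(out_dir / "comparison.json", "w") as fh:
        json.dump(cmp, fh, indent=1, sort_keys=True)
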