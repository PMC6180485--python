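"""Shared test utilities: independent oracles and simulation runners.

The oracles here are deliberately naive (O(n^2) scans, brute-force
enumeration) and independent of the library code paths they check.
"""

from __future__ import annotations

import numpy as np

import polterm as pt
from polterm import calibration as cal
from polterm import termination as term
from polterm.annotation import GeneModel, SelectionCriteria


def brute_force_selection(genes: list[GeneModel], criteria: SelectionCriteria) -> set[str]:
    """All-pairs reference implementation of the non-overlap gene filter."""
    kept = set()
    for g in genes:
        ok = True
        for other in genes:
            if other.gene_id == g.gene_id or other.chrom != g.chrom:
                continue
            if other.strand == g.strand:
                # downstream-TSS gap, measured in g's transcription direction
                if g.strand == "+":
                    gap = other.tss - g.pas
                else:
                    gap = g.pas - other.tss
                if 0 <= gap <= criteria.min_downstream_tss_gap:
                    ok = False
            else:
                # opposite-strand overlap with the oriented PAS window
                if g.strand == "+":
                    lo = g.pas - criteria.opposite_overlap_upstream
                    hi = g.pas + criteria.opposite_overlap_downstream
                else:
                    lo = g.pas - criteria.opposite_overlap_downstream
                    hi = g.pas + criteria.opposite_overlap_upstream
                if other.start < hi and lo < other.end:
                    ok = False
        if ok:
            kept.add(g.gene_id)
    return kept


def small_annotation_config(seed: int, n_genes: int = 40) -> pt.SimulationConfig:
    return pt.SimulationConfig(
        seed=seed,
        n_genes=n_genes,
        chrom_sizes_pombe={"chrA": 45_000, "chrB": 35_000},
        chrom_sizes_spikein={"spikein_chrI": 10_000},
        gene_length_median=500.0,
        fail_fraction=0.3,
        reads_per_sample=10_000,
    )


def calibrated_gene_body_ratio(occupancy_scale: dict[str, float], seed: int) -> float:
    """Mean per-gene calibrated body-signal ratio strain b / strain a under
    2x IP-efficiency and 0.2 mixing-jitter nuisance."""
    cfg = pt.SimulationConfig(
        seed=seed,
        readthrough_decay_nt={"a": 50.0, "b": 50.0},
        ip_efficiency={"a": 1.0, "b": 2.0},
        occupancy_scale=occupancy_scale,
        mixing_jitter_sd=0.2,
    )
    genes = pt.simulate_annotation(cfg)
    samples, _ = pt.simulate_chip_samples(cfg, genes)
    sizes = cfg.chrom_sizes_pombe
    tracks = {}
    for s in ("a", "b"):
        counts_ip, reads_ip = cal.partition_and_filter(
            samples[f"{s}_pol2_ip"].reads, "ip", "IP", dedup=False
        )
        counts_in, _ = cal.partition_and_filter(
            samples[f"{s}_pol2_input"].reads, "in", "input", dedup=False
        )
        alpha = cal.spikein_scale_factor(counts_ip, counts_in)
        pombe = reads_ip[~reads_ip["chrom"].str.startswith(cal.SPIKEIN_PREFIX)]
        cov = cal.coverage_from_reads(pombe, sizes, cfg.read_length)
        tracks[s] = cal.calibrate_track(cov, alpha).coverage
    ratios = []
    for g in genes:
        a = tracks["a"][g.chrom][g.start:g.end].mean()
        b = tracks["b"][g.chrom][g.start:g.end].mean()
        if a > 0:
            ratios.append(b / a)
    return float(np.mean(ratios))


def null_index_sample(seed: int) -> np.ndarray:
    """Unscaled B2 indices from one wild-type-only simulation whose genes are
    spaced so that PAS+/-500 windows are disjoint (independent values)."""
    cfg = pt.SimulationConfig(
        seed=seed,
        n_genes=30,
        chrom_sizes_pombe={"chrA": 75_000},
        chrom_sizes_spikein={"spikein_chrI": 10_000},
        reads_per_sample=30_000,
        gene_length_median=600.0,
        fail_fraction=0.0,
        clean_gap_range=(1001, 1200),
        readthrough_decay_nt={"a": 50.0},
    )
    genes = pt.simulate_annotation(cfg)
    samples, _ = pt.simulate_chip_samples(cfg, genes)
    sel = pt.select_genes(genes).selected
    _, reads = cal.partition_and_filter(samples["a_pol2_ip"].reads)
    pombe = reads[~reads["chrom"].str.startswith(cal.SPIKEIN_PREFIX)]
    cov = cal.coverage_from_reads(pombe, cfg.chrom_sizes_pombe, cfg.read_length)
    return term.termination_index(cov, sel, "a")["index_B2"].to_numpy()


def scaled_b2_by_strain(cfg: pt.SimulationConfig) -> dict[str, np.ndarray]:
    """Full pipeline to per-strain scaled B2 values (selection, positional
    dedup, calibration, termination indices, median-of-B1 scaling)."""
    genes = pt.simulate_annotation(cfg)
    samples, _ = pt.simulate_chip_samples(cfg, genes)
    sel = pt.select_genes(genes).selected
    out = {}
    for strain in cfg.strains:
        counts_ip, reads_ip = cal.partition_and_filter(
            samples[f"{strain}_pol2_ip"].reads, "ip", "IP"
        )
        pombe = reads_ip[~reads_ip["chrom"].str.startswith(cal.SPIKEIN_PREFIX)]
        cov = cal.coverage_from_reads(pombe, cfg.chrom_sizes_pombe, cfg.read_length)
        table = term.scale_by_median_B1(term.termination_index(cov, sel, strain))
        out[strain] = table["scaled_B2"].to_numpy()
    return out
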