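"""Synthetic two-species ChIP-seq, structure, and titration generators.

Everything downstream of read alignment is exercised against data produced
here with known ground truth: a toy two-chromosome fission-yeast-like genome
plus one spike-in chromosome, gene annotations engineered to both pass and
fail the non-overlap selection filter, species-mixed IP/input read samples
with configurable post-PAS readthrough, CTD phospho-mark shape profiles,
planted cross-link/structure fixtures, and anisotropy titrations.

The generative model for a ChIP sample: each gene carries a lognormal body
occupancy level; the mark shape modulates it along the body; past the PAS the
signal decays as exp(-d / readthrough_decay_nt), the strain parameter whose
increase constitutes a termination defect. Spike-in chromatin contributes
reads in proportion to the realized cell-mixing ratio, and input samples draw
reads in proportion to genomic DNA content, which is what lets the
calibration module estimate the mixing ratio and cancel IP-efficiency and
depth nuisance. Read counts are Poisson or gamma-overdispersed Poisson
(negative binomial) per base.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .annotation import GeneModel, SelectionCriteria, select_genes, write_bed, write_gff3

__all__ = [
    "SimulationConfig",
    "ChipSample",
    "GroundTruth",
    "SimulationError",
    "DEFAULT_MARK_PROFILES",
    "simulate_annotation",
    "simulate_chip_samples",
    "simulate_structure_fixture",
    "simulate_titration",
    "occupancy_profile",
    "write_sam",
    "write_bedgraph",
    "read_bedgraph",
]


class SimulationError(ValueError):
    """Invalid simulation configuration or infeasible request."""


# Shape parameters per CTD mark. Ser5P tracks initiated Pol II and is flat
# across the body; Ser2P/Tyr1P accumulate toward the 3' end (logistic rise
# centered `rise_offset` nt before the PAS); Thr4P is 3'-distal, a Gaussian
# bump centered past the PAS riding on a low body baseline. "pol2" is the
# total-polymerase (8WG16-like) track.
DEFAULT_MARK_PROFILES: dict[str, dict[str, float]] = {
    "pol2": {"shape": 0, "base": 1.0},
    "ser5p": {"shape": 0, "base": 1.0},
    "ser2p": {"shape": 1, "base": 0.2, "rise_offset": 500.0, "rise_scale": 150.0},
    "tyr1p": {"shape": 1, "base": 0.15, "rise_offset": 400.0, "rise_scale": 150.0},
    "thr4p": {"shape": 2, "base": 0.15, "bump_center": 300.0, "bump_sd": 150.0, "bump_amp": 1.0},
}
_SHAPE_FLAT, _SHAPE_LOGISTIC, _SHAPE_POSTPAS_BUMP = 0, 1, 2


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with field-realistic defaults.

    Defaults describe the study conditions: a 15% spike-in cell fraction,
    two strains distinguished only by the post-PAS readthrough decay length
    (50 nt wild type vs 400 nt termination-defective), 300 genes on a
    2 x 250 kb toy genome, 2e5 single-end 50 nt reads per sample, and
    negative-binomial count noise (dispersion 0.1).
    """

    seed: int = 0
    n_genes: int = 300
    chrom_sizes_pombe: dict[str, int] = field(
        default_factory=lambda: {"chrI": 250_000, "chrII": 250_000}
    )
    chrom_sizes_spikein: dict[str, int] = field(
        default_factory=lambda: {"spikein_chrI": 100_000}
    )
    spikein_cell_fraction: float = 0.15
    mixing_jitter_sd: float = 0.0
    ip_efficiency: dict[str, float] = field(default_factory=dict)  # per strain; 1.0 default
    readthrough_decay_nt: dict[str, float] = field(
        default_factory=lambda: {"wt": 50.0, "dis2d": 400.0}
    )
    occupancy_scale: dict[str, float] = field(default_factory=dict)  # per strain; 1.0
    marks: tuple[str, ...] = ("pol2",)
    mark_profiles: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MARK_PROFILES.items()}
    )
    reads_per_sample: int = 200_000
    read_length: int = 50
    noise: str = "negative_binomial"  # or "poisson"
    nb_dispersion: float = 0.1
    pcr_duplicate_rate: float = 0.0
    multimap_rate: float = 0.0
    fail_fraction: float = 0.2  # genes deliberately violating the selection filter
    gene_length_median: float = 800.0
    gene_length_sigma: float = 0.3
    min_gene_length: int = 300
    clean_gap_range: tuple[int, int] = (520, 700)
    background_level: float = 0.05
    spikein_occupancy: float = 1.0
    body_level_sigma: float = 0.4

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise SimulationError("n_genes must be > 0")
        for name, sizes in (
            ("chrom_sizes_pombe", self.chrom_sizes_pombe),
            ("chrom_sizes_spikein", self.chrom_sizes_spikein),
        ):
            if any(s <= 0 for s in sizes.values()):
                raise SimulationError(f"{name}: all chromosome sizes must be > 0")
        if not 0.0 < self.spikein_cell_fraction < 1.0:
            raise SimulationError("spikein_cell_fraction must lie in (0, 1)")
        if any(d <= 0 for d in self.readthrough_decay_nt.values()):
            raise SimulationError("readthrough_decay_nt must be > 0 for every strain")
        if self.mixing_jitter_sd < 0:
            raise SimulationError("mixing_jitter_sd must be >= 0")
        if self.noise not in ("poisson", "negative_binomial"):
            raise SimulationError(f"unknown noise model {self.noise!r}")
        for mark in self.marks:
            if mark not in self.mark_profiles:
                raise SimulationError(
                    f"unknown mark {mark!r}; configured marks: "
                    f"{sorted(self.mark_profiles)}"
                )

    @property
    def strains(self) -> tuple[str, ...]:
        return tuple(self.readthrough_decay_nt)


@dataclass
class ChipSample:
    """One sequenced sample: reads over the concatenated two-species genome."""

    sample_id: str
    strain: str
    mark: str
    role: str  # "IP" or "input"
    reads: pd.DataFrame  # columns: chrom, start, strand, n_hits
    realized_mixing: float
    ip_efficiency: float


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline must recover."""

    config: SimulationConfig
    body_levels: dict[str, float]  # gene_id -> lognormal body level
    readthrough_decay_nt: dict[str, float]  # strain -> decay length
    realized_mixing: dict[str, float]  # (strain:mark) key -> realized cell ratio
    ip_efficiency: dict[str, float]  # sample_id -> realized efficiency
    selected_gene_ids: list[str]  # genes passing the default selection filter

    def to_json(self, path: str) -> None:
        payload = {
            "config": _config_dict(self.config),
            "body_levels": self.body_levels,
            "readthrough_decay_nt": self.readthrough_decay_nt,
            "realized_mixing": self.realized_mixing,
            "ip_efficiency": self.ip_efficiency,
            "selected_gene_ids": self.selected_gene_ids,
        }
        with open(path, "w") as out:
            json.dump(payload, out, indent=1, sort_keys=True)


def _config_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["marks"] = list(config.marks)
    d["clean_gap_range"] = list(config.clean_gap_range)
    return d


# ---------------------------------------------------------------------------
# Annotation simulation
# ---------------------------------------------------------------------------

def _draw_length(rng: np.random.Generator, config: SimulationConfig) -> int:
    L = rng.lognormal(math.log(config.gene_length_median), config.gene_length_sigma)
    return max(config.min_gene_length, int(round(L)))


def simulate_annotation(config: SimulationConfig) -> list[GeneModel]:
    """Place genes on the toy genome; a ``fail_fraction`` of them violate
    the selection filter by construction.

    Clean genes get >= 520 nt clearance on both sides, enough to pass both
    the 275 nt downstream-TSS and the 250/500 nt opposite-strand criteria.
    Failure modes are emitted as tandem pairs: same-strand pairs with a
    short (<= 250 nt) TSS gap, and antisense pairs overlapping the PAS
    window. Raises if the genes cannot be packed into the chromosomes.
    """
    rng = np.random.default_rng([config.seed, 101])
    chroms = list(config.chrom_sizes_pombe)
    total = sum(config.chrom_sizes_pombe.values())
    quota = {
        c: max(1, int(round(config.n_genes * config.chrom_sizes_pombe[c] / total)))
        for c in chroms
    }
    # keep the exact requested count
    diff = config.n_genes - sum(quota.values())
    quota[chroms[0]] += diff
    if quota[chroms[0]] < 0:
        raise SimulationError("infeasible packing: more chromosomes than genes")

    genes: list[GeneModel] = []
    idx = 0
    for chrom in chroms:
        size = config.chrom_sizes_pombe[chrom]
        cursor = 600  # leave room for upstream windows of the first gene
        placed = 0
        while placed < quota[chrom]:
            mode = rng.choice(3, p=[
                1.0 - config.fail_fraction,
                config.fail_fraction / 2.0,
                config.fail_fraction / 2.0,
            ])
            pair = mode != 0 and placed + 1 < quota[chrom]
            strand = "+" if rng.random() < 0.5 else "-"
            L1 = _draw_length(rng, config)
            gap_clean = int(rng.integers(*config.clean_gap_range))
            if not pair:
                start, end = cursor, cursor + L1
                if end + 600 > size:
                    raise SimulationError(
                        f"infeasible packing: gene {idx} does not fit on {chrom} "
                        f"({size} bp); reduce n_genes or enlarge chromosomes"
                    )
                genes.append(_make_gene(idx, chrom, strand, start, end))
                idx += 1
                placed += 1
                cursor = end + gap_clean
                continue
            L2 = _draw_length(rng, config)
            if mode == 1:
                # tandem same-strand pair with a short TSS gap: the upstream
                # member fails the 275 nt criterion
                short_gap = int(rng.integers(30, 251))
                span = L1 + short_gap + L2
            else:
                # antisense pair overlapping the first gene's PAS window
                short_gap = int(rng.integers(20, 200))
                span = L1 + short_gap + L2
            if cursor + span + 600 > size:
                raise SimulationError(
                    f"infeasible packing: gene pair at index {idx} does not fit on "
                    f"{chrom} ({size} bp); reduce n_genes or enlarge chromosomes"
                )
            if mode == 1:
                if strand == "+":
                    a = _make_gene(idx, chrom, "+", cursor, cursor + L1)
                    b = _make_gene(
                        idx + 1, chrom, "+", cursor + L1 + short_gap, cursor + span
                    )
                else:
                    # on '-' the downstream neighbor sits to the left
                    b = _make_gene(idx + 1, chrom, "-", cursor, cursor + L2)
                    a = _make_gene(
                        idx, chrom, "-", cursor + L2 + short_gap, cursor + span
                    )
                genes.extend([a, b])
            elif strand == "+":
                # '+' gene a, antisense b starting short_gap nt past a's PAS:
                # b intersects [PAS-250, PAS+500) since short_gap < 500
                a = _make_gene(idx, chrom, "+", cursor, cursor + L1)
                b = _make_gene(
                    idx + 1, chrom, "-", cursor + L1 + short_gap, cursor + span
                )
                genes.extend([a, b])
            else:
                # '-' gene a with PAS at its left edge; sense gene b ends
                # short_gap nt past that PAS, inside [PAS-500, PAS+250)
                b = _make_gene(idx + 1, chrom, "+", cursor, cursor + L2)
                a = _make_gene(
                    idx, chrom, "-", cursor + L2 - short_gap, cursor + span
                )
                genes.extend([a, b])
            idx += 2
            placed += 2
            cursor = cursor + span + gap_clean
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


def _make_gene(idx: int, chrom: str, strand: str, start: int, end: int) -> GeneModel:
    gid = f"g{idx:04d}"
    if strand == "+":
        return GeneModel(gid, chrom, "+", tss=start, pas=end)
    return GeneModel(gid, chrom, "-", tss=end, pas=start)


# ---------------------------------------------------------------------------
# Occupancy model
# ---------------------------------------------------------------------------

def _mark_shape_fn(params: dict[str, float]) -> Callable[[np.ndarray, float], np.ndarray]:
    """Return shape(t, L): relative occupancy at oriented position t from the
    TSS for a gene of body length L. t may run past L (readthrough region);
    the post-PAS exponential decay is applied separately."""
    shape = int(params.get("shape", _SHAPE_FLAT))
    base = float(params.get("base", 1.0))
    if shape == _SHAPE_FLAT:
        def fn(t: np.ndarray, L: float) -> np.ndarray:
            return np.full_like(t, base, dtype=float)
    elif shape == _SHAPE_LOGISTIC:
        off = float(params.get("rise_offset", 500.0))
        scale = float(params.get("rise_scale", 150.0))
        def fn(t: np.ndarray, L: float) -> np.ndarray:
            return base + (1.0 - base) / (1.0 + np.exp(-(t - (L - off)) / scale))
    elif shape == _SHAPE_POSTPAS_BUMP:
        center = float(params.get("bump_center", 300.0))
        sd = float(params.get("bump_sd", 150.0))
        amp = float(params.get("bump_amp", 1.0))
        def fn(t: np.ndarray, L: float) -> np.ndarray:
            d = t - L  # distance past the PAS; bump only downstream
            bump = amp * np.exp(-0.5 * ((d - center) / sd) ** 2)
            return base + np.where(d > -2 * sd, bump, 0.0)
    else:
        raise SimulationError(f"unknown mark shape code {shape}")
    return fn


def occupancy_profile(
    gene: GeneModel,
    body_level: float,
    mark_params: dict[str, float],
    decay_nt: float,
    t: np.ndarray,
) -> np.ndarray:
    """True mean occupancy at oriented positions ``t`` (nt from the TSS,
    may exceed the body length = readthrough region)."""
    L = float(gene.length)
    shape = _mark_shape_fn(mark_params)(np.asarray(t, dtype=float), L)
    d_past = np.maximum(np.asarray(t, dtype=float) - L, 0.0)
    return body_level * shape * np.exp(-d_past / decay_nt)


def _ip_weights(
    config: SimulationConfig,
    genes: list[GeneModel],
    body_levels: dict[str, float],
    strain: str,
    mark: str,
) -> dict[str, np.ndarray]:
    """Expected per-base read-midpoint density over the fission-yeast genome."""
    decay = config.readthrough_decay_nt[strain]
    scale = float(config.occupancy_scale.get(strain, 1.0))
    params = config.mark_profiles[mark]
    # a per-strain occupancy change scales all immunoprecipitated chromatin,
    # non-specific background included
    weights = {
        c: np.full(size, scale * config.background_level, dtype=float)
        for c, size in config.chrom_sizes_pombe.items()
    }
    ext = int(min(1500, 6 * decay + 900))  # readthrough region simulated
    for g in genes:
        arr = weights[g.chrom]
        n = g.length + ext
        t = np.arange(n, dtype=float)
        occ = scale * occupancy_profile(g, body_levels[g.gene_id], params, decay, t)
        if g.strand == "+":
            lo = g.tss
            hi = min(lo + n, arr.size)
            arr[lo:hi] += occ[: hi - lo]
        else:
            hi = g.tss  # exclusive upper boundary
            lo = max(hi - n, 0)
            arr[lo:hi] += occ[: hi - lo][::-1]
    return weights


def _draw_counts(
    rng: np.random.Generator, lam: np.ndarray, config: SimulationConfig
) -> np.ndarray:
    if config.noise == "poisson":
        return rng.poisson(lam)
    r = 1.0 / config.nb_dispersion
    mult = rng.gamma(shape=r, scale=1.0 / r, size=lam.size)
    return rng.poisson(lam * mult)


def _counts_to_reads(
    rng: np.random.Generator,
    counts_by_chrom: dict[str, np.ndarray],
    sizes: dict[str, int],
    config: SimulationConfig,
) -> pd.DataFrame:
    frames = []
    for chrom, counts in counts_by_chrom.items():
        pos = np.nonzero(counts)[0]
        if pos.size == 0:
            continue
        mids = np.repeat(pos, counts[pos])
        starts = np.clip(
            mids - config.read_length // 2, 0, sizes[chrom] - config.read_length
        )
        strands = np.where(rng.random(mids.size) < 0.5, "+", "-")
        frames.append(
            pd.DataFrame({"chrom": chrom, "start": starts, "strand": strands})
        )
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "strand", "n_hits"])
    reads = pd.concat(frames, ignore_index=True)
    reads["n_hits"] = 1
    n = len(reads)
    if config.multimap_rate > 0 and n:
        k = rng.binomial(n, config.multimap_rate)
        if k:
            reads.loc[rng.choice(n, size=k, replace=False), "n_hits"] = 2
    if config.pcr_duplicate_rate > 0 and n:
        k = rng.binomial(n, config.pcr_duplicate_rate)
        if k:
            dup = reads.iloc[rng.choice(n, size=k, replace=True)]
            reads = pd.concat([reads, dup], ignore_index=True)
    # shuffle so duplicates are not trivially adjacent
    order = rng.permutation(len(reads))
    return reads.iloc[order].reset_index(drop=True)


def simulate_chip_samples(
    config: SimulationConfig, genes: list[GeneModel]
) -> tuple[dict[str, ChipSample], GroundTruth]:
    """Generate IP and input samples for every strain x mark combination.

    The realized spike-in mixing ratio is shared between an IP and its input
    (they come from the same cell mixture) and jittered per strain x mark by
    a lognormal factor of sd ``mixing_jitter_sd``. Sequencing yield is
    ``reads_per_sample`` scaled by the per-strain ``ip_efficiency``.
    """
    if config.reads_per_sample <= 0:
        raise SimulationError("reads_per_sample must be > 0")
    for mark in config.marks:
        if mark not in config.mark_profiles:
            raise SimulationError(
                f"unknown mark {mark!r}; configured marks: {sorted(config.mark_profiles)}"
            )
    rng_levels = np.random.default_rng([config.seed, 202])
    body_levels = {
        g.gene_id: float(rng_levels.lognormal(0.0, config.body_level_sigma))
        for g in genes
    }
    sizes_all = dict(config.chrom_sizes_pombe) | dict(config.chrom_sizes_spikein)
    g_spike = sum(config.chrom_sizes_spikein.values())

    samples: dict[str, ChipSample] = {}
    realized_mixing: dict[str, float] = {}
    ip_eff_truth: dict[str, float] = {}
    for si, strain in enumerate(config.strains):
        eff = float(config.ip_efficiency.get(strain, 1.0))
        for mi, mark in enumerate(config.marks):
            rng = np.random.default_rng([config.seed, 303, si, mi])
            jitter = (
                math.exp(rng.normal(0.0, config.mixing_jitter_sd))
                if config.mixing_jitter_sd > 0
                else 1.0
            )
            m = config.spikein_cell_fraction * jitter
            realized_mixing[f"{strain}:{mark}"] = m

            # IP: fission-yeast occupancy vs uniform spike-in chromatin
            w_pombe = _ip_weights(config, genes, body_levels, strain, mark)
            w_spike = {
                c: np.full(size, m * config.spikein_occupancy)
                for c, size in config.chrom_sizes_spikein.items()
            }
            n_ip = max(1, int(round(config.reads_per_sample * eff)))
            total_w = sum(float(w.sum()) for w in (*w_pombe.values(), *w_spike.values()))
            counts = {
                c: _draw_counts(rng, w * (n_ip / total_w), config)
                for c, w in {**w_pombe, **w_spike}.items()
            }
            sid = f"{strain}_{mark}_ip"
            samples[sid] = ChipSample(
                sid, strain, mark, "IP",
                _counts_to_reads(rng, counts, sizes_all, config), m, eff,
            )
            ip_eff_truth[sid] = eff

            # input: genomic DNA in proportion to cell number x genome size
            w_in = {c: np.full(size, 1.0) for c, size in config.chrom_sizes_pombe.items()}
            w_in |= {c: np.full(size, m) for c, size in config.chrom_sizes_spikein.items()}
            n_in = config.reads_per_sample
            total_in = sum(float(w.sum()) for w in w_in.values())
            counts_in = {
                c: _draw_counts(rng, w * (n_in / total_in), config)
                for c, w in w_in.items()
            }
            sid_in = f"{strain}_{mark}_input"
            samples[sid_in] = ChipSample(
                sid_in, strain, mark, "input",
                _counts_to_reads(rng, counts_in, sizes_all, config), m, 1.0,
            )
            ip_eff_truth[sid_in] = 1.0

    truth = GroundTruth(
        config=config,
        body_levels=body_levels,
        readthrough_decay_nt=dict(config.readthrough_decay_nt),
        realized_mixing=realized_mixing,
        ip_efficiency=ip_eff_truth,
        selected_gene_ids=sorted(select_genes(genes, SelectionCriteria()).selected_ids),
    )
    return samples, truth


# ---------------------------------------------------------------------------
# File output for the two-reference layout
# ---------------------------------------------------------------------------

def write_sam(sample: ChipSample, path: str, chrom_sizes: dict[str, int],
              read_length: int = 50) -> None:
    """Write reads as unsorted single-end SAM; multi-mappers carry NH > 1."""
    with open(path, "w") as out:
        out.write("@HD\tVN:1.6\tSO:unsorted\n")
        for chrom, size in chrom_sizes.items():
            out.write(f"@SQ\tSN:{chrom}\tLN:{size}\n")
        for i, row in enumerate(sample.reads.itertuples(index=False)):
            flag = 16 if row.strand == "-" else 0
            mapq = 0 if row.n_hits > 1 else 42
            out.write(
                f"r{i:07d}\t{flag}\t{row.chrom}\t{row.start + 1}\t{mapq}\t"
                f"{read_length}M\t*\t0\t0\t*\t*\tNH:i:{row.n_hits}\n"
            )


def write_bedgraph(coverage: dict[str, np.ndarray], path: str) -> None:
    """Write per-base coverage as run-length-collapsed bedGraph."""
    with open(path, "w") as out:
        for chrom in coverage:
            arr = np.asarray(coverage[chrom])
            if arr.size == 0:
                continue
            change = np.nonzero(np.diff(arr))[0]
            starts = np.concatenate([[0], change + 1])
            ends = np.concatenate([change + 1, [arr.size]])
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    out.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def read_bedgraph(path: str, chrom_sizes: dict[str, int]) -> dict[str, np.ndarray]:
    cov = {c: np.zeros(size) for c, size in chrom_sizes.items()}
    with open(path) as handle:
        for line in handle:
            chrom, s, e, v = line.split()
            if chrom in cov:
                cov[chrom][int(s):int(e)] += float(v)
    return cov


# ---------------------------------------------------------------------------
# Structure + cross-link fixture
# ---------------------------------------------------------------------------

def simulate_structure_fixture(
    seed: int,
    n_residues: int,
    n_links: int,
    max_planted_distance: float = 30.0,
    n_decoys: int = 0,
) -> tuple[str, pd.DataFrame, pd.DataFrame]:
    """Build a two-chain CA-only structure with planted cross-links.

    Returns (pdb_text, links, truth). Chains A and B each get
    ``n_residues // 2`` (at least 1) residues laid out as a 3.8 Å random
    walk. Planted links join residue pairs within ``max_planted_distance``
    (Å, CA-CA) and carry E-values below 1e-5; decoys exceed the distance and
    the E-value threshold. ``truth`` tabulates the planted geometry.
    """
    if n_residues < 2:
        raise SimulationError("n_residues must be >= 2")
    if n_links > n_residues * n_residues:
        raise SimulationError("n_links exceeds the number of residue pairs")
    rng = np.random.default_rng([seed, 404])
    n_a = max(1, n_residues // 2)
    n_b = n_residues - n_a
    coords: dict[str, np.ndarray] = {}
    # chain B is displaced ~1.5x the planting cutoff from chain A so that
    # both satisfiable pairs (within/near chains) and long decoy pairs exist
    offsets = {"A": np.zeros(3), "B": np.array([1.5 * max_planted_distance, 0.0, 0.0])}
    for chain, n in (("A", n_a), ("B", n_b)):
        steps = rng.normal(size=(n, 3))
        steps /= np.linalg.norm(steps, axis=1, keepdims=True)
        xyz = np.cumsum(3.8 * steps, axis=0)
        xyz += offsets[chain] + rng.uniform(-3, 3, size=3)
        coords[chain] = xyz

    flat = [(c, i + 1) for c in ("A", "B") for i in range(coords[c].shape[0])]

    def dist(a, b):
        return float(np.linalg.norm(coords[a[0]][a[1] - 1] - coords[b[0]][b[1] - 1]))

    pairs = [(a, b) for ai, a in enumerate(flat) for b in flat[ai + 1:]]
    rng.shuffle(pairs)
    close_pairs = [p for p in pairs if dist(*p) <= max_planted_distance]
    far = [p for p in pairs if dist(*p) > max_planted_distance]
    if len(close_pairs) < n_links:
        raise SimulationError(
            f"cannot plant {n_links} links within {max_planted_distance} A; "
            f"only {len(close_pairs)} residue pairs qualify"
        )
    if len(far) < n_decoys:
        raise SimulationError(f"cannot place {n_decoys} decoys beyond the cutoff")

    rows = []
    truth_rows = []
    for a, b in close_pairs[:n_links]:
        e = 10.0 ** rng.uniform(-9, -5.31)  # strictly below 1e-5
        rows.append(("prot" + a[0], a[1], "prot" + b[0], b[1], e))
        truth_rows.append((a[0], a[1], b[0], b[1], dist(a, b), True))
    for a, b in far[:n_decoys]:
        e = 10.0 ** rng.uniform(-4.9, -2)
        rows.append(("prot" + a[0], a[1], "prot" + b[0], b[1], e))
        truth_rows.append((a[0], a[1], b[0], b[1], dist(a, b), False))
    links = pd.DataFrame(
        rows, columns=["protein_a", "residue_a", "protein_b", "residue_b", "e_value"]
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["chain_a", "residue_a", "chain_b", "residue_b", "distance", "planted"],
    )

    lines = []
    serial = 1
    for chain in ("A", "B"):
        for i, (x, y, z) in enumerate(coords[chain], start=1):
            lines.append(
                f"ATOM  {serial:5d}  CA  ALA {chain}{i:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
            )
            serial += 1
        lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n", links, truth


# ---------------------------------------------------------------------------
# Anisotropy titration
# ---------------------------------------------------------------------------

def simulate_titration(
    kd: float,
    a_free: float,
    a_bound: float,
    concentrations,
    ligand: float = 75.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Anisotropy titration from the 1:1 ligand-depletion isotherm.

    ``kd`` and all concentrations in nM; ``ligand`` is the fixed labeled
    peptide concentration (default 75 nM). Gaussian noise of sd ``noise_sd``
    is added to each anisotropy value.
    """
    from .binding import fraction_bound

    if kd <= 0 or ligand <= 0:
        raise SimulationError("kd and ligand concentration must be > 0")
    if noise_sd < 0:
        raise SimulationError("noise_sd must be >= 0")
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc < 0):
        raise SimulationError("protein concentrations must be >= 0")
    f = fraction_bound(conc, ligand, kd)
    a = a_free + (a_bound - a_free) * f
    if noise_sd > 0:
        a = a + np.random.default_rng([seed, 505]).normal(0.0, noise_sd, conc.size)
    return pd.DataFrame({"concentration": conc, "anisotropy": a})
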