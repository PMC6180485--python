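"""Species partitioning, read filtering, and spike-in scale factors.

Reads aligned to the concatenated two-species reference are split by
reference-name prefix (``spikein_`` marks the spike-in genome), multi-mappers
are discarded, and PCR duplicates — identical (chromosome, 5' position,
strand) — are collapsed. The spike-in scale factor for a strain's IP is

    alpha = 1e6 * (spikein_input / pombe_input) / spikein_IP

i.e. the spike-in IP depth corrected by the input-estimated cell-mixing
ratio, so that calibrated tracks are comparable across strains even when IP
efficiency, sequencing depth, or the realized cell mixture drift. The 1e6
constant only keeps magnitudes readable; it cancels in every strain ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SampleCounts",
    "CalibratedTrack",
    "CalibrationError",
    "SPIKEIN_PREFIX",
    "read_sam",
    "partition_and_filter",
    "coverage_from_reads",
    "spikein_scale_factor",
    "calibrate_track",
    "estimate_mixing_fraction",
]

SPIKEIN_PREFIX = "spikein_"


class CalibrationError(ValueError):
    """Invalid counts or calibration inputs."""


@dataclass
class SampleCounts:
    """Unique-mapping, deduplicated read counts per species for one sample."""

    sample_id: str
    role: str  # "IP" or "input"
    strain: str = ""
    mark: str = ""
    reads_pombe: int = 0
    reads_spikein: int = 0
    reads_unassigned: int = 0
    reads_multimapped: int = 0
    reads_duplicate: int = 0

    def __post_init__(self) -> None:
        if self.role not in ("IP", "input"):
            raise CalibrationError(f"{self.sample_id}: role must be IP or input")
        if self.reads_pombe < 0 or self.reads_spikein < 0:
            raise CalibrationError(f"{self.sample_id}: negative read counts")


@dataclass
class CalibratedTrack:
    """Spike-in calibrated per-base coverage over the fission-yeast genome."""

    strain: str
    mark: str
    coverage: dict[str, np.ndarray]
    scale_factor: float = 1.0
    provenance: dict = field(default_factory=dict)


def read_sam(path: str) -> pd.DataFrame:
    """Load a SAM file into the internal alignment table.

    Multi-mapping evidence comes from the NH tag when present, else a read
    is treated as unique. Returns columns chrom/start/strand/n_hits with
    0-based starts.
    """
    import pysam

    rows = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                continue
            n_hits = aln.get_tag("NH") if aln.has_tag("NH") else 1
            rows.append(
                (aln.reference_name, aln.reference_start,
                 "-" if aln.is_reverse else "+", int(n_hits))
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "strand", "n_hits"])


def partition_and_filter(
    alignments: pd.DataFrame,
    sample_id: str = "sample",
    role: str = "IP",
    strain: str = "",
    mark: str = "",
    pombe_chroms: set[str] | None = None,
    dedup: bool = True,
) -> tuple[SampleCounts, pd.DataFrame]:
    """Split reads by species and apply the uniqueness/duplicate filters.

    Reads whose reference starts with ``spikein_`` go to the spike-in
    bucket; anything else is fission yeast unless ``pombe_chroms`` is given,
    in which case unknown references are counted as unassigned and excluded.
    Multi-mappers (n_hits > 1) are discarded; duplicates — identical
    (chrom, start, strand) — collapse to a single read. Returns the counts
    and the filtered read table.
    """
    df = alignments
    required = {"chrom", "start", "strand"}
    if not required.issubset(df.columns):
        raise CalibrationError(f"alignment table lacks columns {required - set(df.columns)}")
    if "n_hits" not in df.columns:
        df = df.assign(n_hits=1)

    multi = df["n_hits"] > 1
    n_multi = int(multi.sum())
    df = df[~multi]

    is_spike = df["chrom"].str.startswith(SPIKEIN_PREFIX)
    if pombe_chroms is not None:
        is_pombe = df["chrom"].isin(pombe_chroms)
        unassigned = ~(is_spike | is_pombe)
    else:
        unassigned = pd.Series(False, index=df.index)
    n_unassigned = int(unassigned.sum())
    df = df[~unassigned]

    n_before = len(df)
    if dedup:
        df = df.drop_duplicates(subset=["chrom", "start", "strand"])
    n_dup = n_before - len(df)

    is_spike = df["chrom"].str.startswith(SPIKEIN_PREFIX)
    counts = SampleCounts(
        sample_id=sample_id,
        role=role,
        strain=strain,
        mark=mark,
        reads_pombe=int((~is_spike).sum()),
        reads_spikein=int(is_spike.sum()),
        reads_unassigned=n_unassigned,
        reads_multimapped=n_multi,
        reads_duplicate=n_dup,
    )
    return counts, df.reset_index(drop=True)


def coverage_from_reads(
    reads: pd.DataFrame,
    chrom_sizes: dict[str, int],
    read_length: int = 50,
) -> dict[str, np.ndarray]:
    """Per-base coverage from single-end reads extended to ``read_length``."""
    cov = {c: np.zeros(size) for c, size in chrom_sizes.items()}
    for chrom, grp in reads.groupby("chrom", sort=False):
        if chrom not in cov:
            continue
        size = chrom_sizes[chrom]
        starts = np.clip(grp["start"].to_numpy(), 0, size - 1)
        ends = np.clip(starts + read_length, 0, size)
        delta = np.zeros(size + 1)
        np.add.at(delta, starts, 1.0)
        np.add.at(delta, ends, -1.0)
        cov[chrom] += np.cumsum(delta[:-1])
    return cov


def spikein_scale_factor(ip: SampleCounts, input_: SampleCounts) -> float:
    """Mixture-corrected spike-in scale factor for one strain's IP.

    alpha = 1e6 * (input spike-in / input pombe) / (IP spike-in reads).
    Raises on any zero count — a silent pseudocount would corrupt the
    between-strain comparison.
    """
    if ip.role != "IP":
        raise CalibrationError(f"{ip.sample_id}: expected an IP sample")
    if input_.role != "input":
        raise CalibrationError(f"{input_.sample_id}: expected an input sample")
    if ip.strain and input_.strain and ip.strain != input_.strain:
        raise CalibrationError(
            f"strain mismatch: {ip.sample_id} ({ip.strain}) vs "
            f"{input_.sample_id} ({input_.strain})"
        )
    for s in (ip, input_):
        for attr in ("reads_pombe", "reads_spikein"):
            if getattr(s, attr) == 0:
                raise CalibrationError(f"{s.sample_id}: {attr} is zero")
    m_hat = input_.reads_spikein / input_.reads_pombe
    return 1e6 * m_hat / ip.reads_spikein


def calibrate_track(
    coverage: dict[str, np.ndarray],
    scale_factor: float,
    strain: str = "",
    mark: str = "",
    provenance: dict | None = None,
) -> CalibratedTrack:
    """Multiply raw coverage by the spike-in scale factor."""
    if not np.isfinite(scale_factor) or scale_factor <= 0:
        raise CalibrationError(f"scale factor must be finite and > 0, got {scale_factor}")
    scaled = {c: np.asarray(v, dtype=float) * scale_factor for c, v in coverage.items()}
    prov = dict(provenance or {})
    prov["scale_factor"] = scale_factor
    return CalibratedTrack(
        strain=strain, mark=mark, coverage=scaled,
        scale_factor=scale_factor, provenance=prov,
    )


def estimate_mixing_fraction(
    input_: SampleCounts,
    genome_size_pombe: int,
    genome_size_spikein: int,
) -> float:
    """Genome-size-normalized spike-in cell-fraction estimate from an input.

    (spike-in reads / spike-in genome) / (pombe reads / pombe genome); with
    genomic-DNA input reads this estimates the cell-mixing ratio (0.15 at
    the nominal 15% spike-in).
    """
    if genome_size_pombe <= 0 or genome_size_spikein <= 0:
        raise CalibrationError("genome sizes must be > 0")
    if input_.reads_pombe == 0:
        raise CalibrationError(f"{input_.sample_id}: zero pombe input reads")
    return (input_.reads_spikein / genome_size_spikein) / (
        input_.reads_pombe / genome_size_pombe
    )
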