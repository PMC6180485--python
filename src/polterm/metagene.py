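"""TSS/PAS-anchored metagene matrices, averaged profiles, and overlays.

Positions are strand-oriented: negative offsets are upstream of the anchor
and positive offsets downstream, in the direction of transcription, so '+'
and '-' genes superimpose. Offset 0 at the PAS anchor is the first base past
the 3' end of the gene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import GeneModel
from .calibration import CalibratedTrack

__all__ = [
    "MetageneMatrix",
    "MetageneError",
    "build_matrix",
    "meta_profile",
    "average_profiles",
    "equalize_upstream",
    "render_profile",
    "render_heatmap",
]


class MetageneError(ValueError):
    pass


@dataclass
class MetageneMatrix:
    """Genes x bins matrix of signal around an anchor."""

    anchor: str  # "TSS" or "PAS"
    window: tuple[int, int]  # [-U, +D) oriented nt
    bin_size: int
    gene_ids: list[str]
    matrix: np.ndarray  # shape (n_genes, n_bins)
    dropped: list[str]  # genes falling outside chromosome bounds

    @property
    def bin_centers(self) -> np.ndarray:
        lo, hi = self.window
        return np.arange(lo, hi, self.bin_size) + self.bin_size / 2.0

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[1]


def _anchor_coord(gene: GeneModel, anchor: str) -> int:
    if anchor == "PAS":
        return gene.pas
    if anchor == "TSS":
        return gene.tss
    raise MetageneError(f"unknown anchor {anchor!r}")


def _oriented_window(track: dict[str, np.ndarray], gene: GeneModel,
                     anchor: str, lo: int, hi: int) -> np.ndarray | None:
    """Per-base signal at oriented offsets [lo, hi) around the anchor.

    For '+' genes offset d maps to genomic a+d; for '-' genes to a-1-d,
    the mirror image, so downstream is always positive. Returns None when
    the window leaves the chromosome.
    """
    arr = track.get(gene.chrom)
    if arr is None:
        return None
    a = _anchor_coord(gene, anchor)
    if gene.strand == "+":
        g_lo, g_hi = a + lo, a + hi
        if g_lo < 0 or g_hi > arr.size:
            return None
        return arr[g_lo:g_hi]
    g_lo, g_hi = a - hi, a - lo
    if g_lo < 0 or g_hi > arr.size:
        return None
    return arr[g_lo:g_hi][::-1]


def build_matrix(
    track: CalibratedTrack | dict[str, np.ndarray],
    genes: list[GeneModel],
    anchor: str = "PAS",
    window: tuple[int, int] = (-500, 1000),
    bin_size: int = 10,
) -> MetageneMatrix:
    """Anchored per-gene signal matrix; bin value = mean per-base signal."""
    cov = track.coverage if isinstance(track, CalibratedTrack) else track
    lo, hi = window
    if hi <= lo:
        raise MetageneError("window must be non-empty")
    if bin_size <= 0 or (hi - lo) % bin_size != 0:
        raise MetageneError(
            f"bin_size {bin_size} does not tile the window [{lo}, {hi})"
        )
    if not genes:
        raise MetageneError("empty gene list")
    rows, ids, dropped = [], [], []
    for g in genes:
        sig = _oriented_window(cov, g, anchor, lo, hi)
        if sig is None:
            dropped.append(g.gene_id)
            continue
        rows.append(sig.reshape(-1, bin_size).mean(axis=1))
        ids.append(g.gene_id)
    if not rows:
        raise MetageneError("no gene fits the requested window")
    return MetageneMatrix(
        anchor=anchor, window=window, bin_size=bin_size,
        gene_ids=ids, matrix=np.vstack(rows), dropped=dropped,
    )


def meta_profile(
    matrix: MetageneMatrix,
    estimator: str = "mean",
    bootstrap: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Column-wise profile with optional 95% gene-bootstrap band.

    Returns a DataFrame with columns position/value (+ ci_lo/ci_hi when
    ``bootstrap`` resamples are requested).
    """
    if matrix.matrix.shape[0] < 1:
        raise MetageneError("matrix has no gene rows")
    est = {"mean": np.nanmean, "median": np.nanmedian}.get(estimator)
    if est is None:
        raise MetageneError(f"unknown estimator {estimator!r}")
    with np.errstate(invalid="ignore"):
        values = est(matrix.matrix, axis=0)
    out = pd.DataFrame({"position": matrix.bin_centers, "value": values})
    if bootstrap:
        rng = np.random.default_rng(seed)
        n = matrix.matrix.shape[0]
        reps = np.empty((bootstrap, matrix.n_bins))
        for b in range(bootstrap):
            idx = rng.integers(0, n, size=n)
            reps[b] = est(matrix.matrix[idx], axis=0)
        out["ci_lo"] = np.quantile(reps, 0.025, axis=0)
        out["ci_hi"] = np.quantile(reps, 0.975, axis=0)
    return out


def average_profiles(profiles: list[pd.DataFrame]) -> pd.DataFrame:
    """Replicate handling: average profiles at the profile level."""
    if not profiles:
        raise MetageneError("no profiles to average")
    base = profiles[0]["position"].to_numpy()
    for p in profiles[1:]:
        if not np.array_equal(p["position"].to_numpy(), base):
            raise MetageneError("profiles have mismatched binning")
    value = np.mean([p["value"].to_numpy() for p in profiles], axis=0)
    return pd.DataFrame({"position": base, "value": value})


def equalize_upstream(
    profiles: dict[str, pd.DataFrame],
    reference: str,
    upstream_window: tuple[int, int] = (-500, 0),
    mode: str = "additive",
) -> tuple[dict[str, pd.DataFrame], dict[str, float]]:
    """Adjust profiles so their mean over ``upstream_window`` matches the
    reference strain's, isolating post-PAS divergence in overlays.

    ``mode='additive'`` applies a vertical offset (default); multiplicative
    rescaling is available as an alternative reading of level matching.
    Returns adjusted profiles and the per-strain shifts/factors.
    """
    if reference not in profiles:
        raise MetageneError(f"reference strain {reference!r} not among profiles")
    lo, hi = upstream_window
    if hi <= lo or lo >= 0 or hi > 0:
        raise MetageneError("upstream_window must be a non-empty interval in [-U, 0]")

    def upstream_mean(p: pd.DataFrame) -> float:
        pos = p["position"].to_numpy()
        mask = (pos >= lo) & (pos < hi)
        if not mask.any():
            raise MetageneError("upstream_window contains no bins")
        return float(p["value"].to_numpy()[mask].mean())

    ref_level = upstream_mean(profiles[reference])
    adjusted: dict[str, pd.DataFrame] = {}
    shifts: dict[str, float] = {}
    for strain, p in profiles.items():
        level = upstream_mean(p)
        q = p.copy()
        if mode == "additive":
            shift = ref_level - level
            q["value"] = q["value"] + shift
        elif mode == "multiplicative":
            if level == 0:
                raise MetageneError(f"{strain}: zero upstream level, cannot rescale")
            shift = ref_level / level
            q["value"] = q["value"] * shift
        else:
            raise MetageneError(f"unknown mode {mode!r}")
        adjusted[strain] = q
        shifts[strain] = shift
    return adjusted, shifts


def render_profile(profiles: dict[str, pd.DataFrame], out_prefix: str,
                   title: str = "") -> tuple[str, str]:
    """Line plot + side-by-side TSV (the TSV is the test surface)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tsv = out_prefix + ".tsv"
    wide = None
    for strain, p in profiles.items():
        col = p.set_index("position")["value"].rename(strain)
        wide = col.to_frame() if wide is None else wide.join(col)
    wide.to_csv(tsv, sep="\t")

    fig, ax = plt.subplots(figsize=(6, 4))
    for strain in profiles:
        ax.plot(wide.index, wide[strain], label=strain)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel("position relative to anchor (nt)")
    ax.set_ylabel("calibrated signal")
    if title:
        ax.set_title(title)
    ax.legend()
    png = out_prefix + ".png"
    fig.savefig(png, dpi=120)
    plt.close(fig)
    return tsv, png


def render_heatmap(matrix: MetageneMatrix, out_prefix: str,
                   lengths: dict[str, int] | None = None) -> tuple[str, str]:
    """Heatmap (rows min-max scaled for display only) plus raw TSV.

    Rows are sorted by gene length then ID when lengths are supplied,
    otherwise by ID — a stable, reproducible order either way.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if lengths is not None:
        keys = [(lengths.get(g, 0), g) for g in matrix.gene_ids]
    else:
        keys = [(0, g) for g in matrix.gene_ids]
    order = sorted(range(len(keys)), key=keys.__getitem__)
    m = matrix.matrix[order]
    ids = [matrix.gene_ids[i] for i in order]

    tsv = out_prefix + ".tsv"
    pd.DataFrame(m, index=ids, columns=matrix.bin_centers).to_csv(tsv, sep="\t")

    span = m.max(axis=1, keepdims=True) - m.min(axis=1, keepdims=True)
    span[span == 0] = 1.0
    display = (m - m.min(axis=1, keepdims=True)) / span
    fig, ax = plt.subplots(figsize=(5, 6))
    ax.imshow(display, aspect="auto", interpolation="nearest", cmap="viridis",
              extent=(matrix.window[0], matrix.window[1], len(ids), 0))
    ax.set_xlabel(f"position relative to {matrix.anchor} (nt)")
    ax.set_ylabel("genes")
    png = out_prefix + ".png"
    fig.savefig(png, dpi=120)
    plt.close(fig)
    return tsv, png
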