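"""Pol II termination index and strain-level comparison statistics.

The termination index of a gene is the fraction of signal mass in a
post-PAS window relative to the PAS +/- 500 nt region: B1 = [PAS, PAS+50)
captures polymerase just past the cleavage site, B2 = [PAS+350, PAS+400)
captures readthrough polymerase that has escaped termination. Within each
strain, indices are rescaled so the median B1 equals 1; elevated scaled B2
in a mutant relative to wild type is the quantitative signature of a
termination (readthrough) defect, assessed with a two-sided Wilcoxon
rank-sum test.

Being a within-sample ratio, the index is invariant to the spike-in scale
factor; calibration matters for metagene level comparisons, not here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GeneModel
from .calibration import CalibratedTrack

__all__ = [
    "TerminationError",
    "StrainComparison",
    "B1_WINDOW",
    "B2_WINDOW",
    "DENOMINATOR_WINDOW",
    "termination_index",
    "scale_by_median_B1",
    "compare_strains",
]

B1_WINDOW = (0, 50)
B2_WINDOW = (350, 400)
DENOMINATOR_WINDOW = (-500, 500)


class TerminationError(ValueError):
    pass


def _window_mass(arr: np.ndarray, gene: GeneModel, lo: int, hi: int) -> float | None:
    """Signal mass in oriented offsets [lo, hi) around the PAS; None if the
    window leaves the chromosome."""
    if gene.strand == "+":
        g_lo, g_hi = gene.pas + lo, gene.pas + hi
    else:
        g_lo, g_hi = gene.pas - hi, gene.pas - lo
    if g_lo < 0 or g_hi > arr.size:
        return None
    return float(arr[g_lo:g_hi].sum())


def termination_index(
    track: CalibratedTrack | dict[str, np.ndarray],
    genes: list[GeneModel],
    strain: str = "",
    b1: tuple[int, int] = B1_WINDOW,
    b2: tuple[int, int] = B2_WINDOW,
    denominator: tuple[int, int] = DENOMINATOR_WINDOW,
) -> pd.DataFrame:
    """Per-gene unscaled termination indices.

    Returns a table with reads_B1/reads_B2/reads_denominator and
    index_B1/index_B2 = window mass / denominator mass. Genes whose windows
    leave the chromosome or whose denominator is zero are excluded (counted
    in the table attrs under 'excluded').
    """
    cov = track.coverage if isinstance(track, CalibratedTrack) else track
    rows = []
    excluded: list[str] = []
    for g in genes:
        arr = cov.get(g.chrom)
        if arr is None:
            excluded.append(g.gene_id)
            continue
        masses = [_window_mass(arr, g, lo, hi) for lo, hi in (b1, b2, denominator)]
        if any(m is None for m in masses) or masses[2] == 0:
            excluded.append(g.gene_id)
            continue
        m1, m2, md = masses
        rows.append((g.gene_id, m1, m2, md, m1 / md, m2 / md))
    if not rows:
        raise TerminationError("no gene has usable termination windows")
    table = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "reads_B1", "reads_B2", "reads_denominator",
            "index_B1", "index_B2",
        ],
    )
    table.attrs["strain"] = strain
    table.attrs["excluded"] = excluded
    return table


def scale_by_median_B1(table: pd.DataFrame) -> pd.DataFrame:
    """Set the strain's median B1 index to 1 and scale B2 accordingly.

    Even-length medians are the mean of the two central order statistics
    (numpy convention), so median(scaled_B1) == 1 exactly.
    """
    if "index_B1" not in table.columns:
        raise TerminationError("table lacks index_B1; run termination_index first")
    med = float(np.median(table["index_B1"].to_numpy()))
    if med == 0 or not np.isfinite(med):
        raise TerminationError(f"median index_B1 is {med}; cannot scale")
    out = table.copy()
    out["scaled_B1"] = out["index_B1"] / med
    out["scaled_B2"] = out["index_B2"] / med
    out.attrs.update(table.attrs)
    out.attrs["median_index_B1"] = med
    return out


@dataclass
class StrainComparison:
    strain_a: str
    strain_b: str
    n_a: int
    n_b: int
    statistic: float
    p_value: float
    hodges_lehmann_shift: float
    method: str


def _hodges_lehmann(x: np.ndarray, y: np.ndarray) -> float:
    # median of pairwise differences y - x; fine at desk-scale n
    return float(np.median(np.subtract.outer(y, x)))


def compare_strains(
    values_by_strain: dict[str, np.ndarray | list[float]],
    exact_max_n: int = 20,
) -> StrainComparison:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) comparison of two strains.

    Exact enumeration when both samples have <= ``exact_max_n`` values and
    no ties; tie-corrected normal approximation otherwise. Also reports the
    Hodges-Lehmann shift (median of pairwise differences, second strain
    minus first).
    """
    if len(values_by_strain) != 2:
        raise TerminationError("compare_strains expects exactly two strains")
    (name_a, xs), (name_b, ys) = values_by_strain.items()
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.size < 2 or y.size < 2:
        raise TerminationError("each strain needs at least 2 values")
    ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    if x.size <= exact_max_n and y.size <= exact_max_n and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return StrainComparison(
        strain_a=name_a,
        strain_b=name_b,
        n_a=int(x.size),
        n_b=int(y.size),
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        hodges_lehmann_shift=_hodges_lehmann(x, y),
        method=method,
    )
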