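"""Cross-link filtering, structural validation, and cross-species transfer.

Lysine-lysine cross-links (BS3-type, pLink-style tables) are filtered by
spectral-match E-value (strictly below 1e-5), deduplicated on the unordered
residue-pair key, and validated against a structure by the Ca-Ca distance:
the crosslinker spacer makes ~30 A the satisfiability bound. Inter-chain
residue contacts (default 15 A, Ca-Ca) can be extracted from a structure of
one species and transferred to another by global pairwise sequence alignment
of the corresponding subunits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "XLError",
    "ResidueContact",
    "filter_links",
    "load_structure",
    "ca_coordinates",
    "map_distances",
    "extract_contacts",
    "align_residue_map",
    "transfer_by_alignment",
    "export_links",
]

E_VALUE_MAX = 1.0e-5
VALIDATION_CUTOFF = 30.0  # A, Ca-Ca, BS3 spacer geometry
CONTACT_CUTOFF = 15.0  # A, "close contact" between chains


class XLError(ValueError):
    pass


@dataclass(frozen=True)
class ResidueContact:
    chain_a: str
    residue_a: int
    chain_b: str
    residue_b: int
    distance: float


# ---------------------------------------------------------------------------
# Cross-link table handling
# ---------------------------------------------------------------------------

def _pair_key(row) -> tuple:
    a = (row.protein_a, int(row.residue_a))
    b = (row.protein_b, int(row.residue_b))
    return (a, b) if a <= b else (b, a)


def filter_links(links: pd.DataFrame, e_max: float = E_VALUE_MAX) -> pd.DataFrame:
    """Keep rows with e_value strictly below ``e_max``; collapse duplicate
    residue pairs (unordered) summing their spectral counts."""
    if e_max <= 0:
        raise XLError("e_max must be > 0")
    if "e_value" not in links.columns:
        raise XLError("links table lacks an e_value column")
    kept = links[links["e_value"] < e_max].copy()
    if kept.empty:
        return kept.assign(count=pd.Series(dtype=int))
    if "count" not in kept.columns:
        kept["count"] = 1
    keys = [_pair_key(r) for r in kept.itertuples(index=False)]
    kept["_key"] = keys
    rows = []
    for key, grp in kept.groupby("_key", sort=True):
        (pa, ra), (pb, rb) = key
        rows.append(
            {
                "protein_a": pa, "residue_a": ra,
                "protein_b": pb, "residue_b": rb,
                "e_value": float(grp["e_value"].min()),
                "count": int(grp["count"].sum()),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Structure access (PDB / mmCIF via gemmi)
# ---------------------------------------------------------------------------

def load_structure(path: str):
    """Read PDB or mmCIF; the first model is used downstream."""
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    return st


def ca_coordinates(structure, chains: list[str] | None = None) -> dict[tuple[str, int], np.ndarray]:
    """(chain, author residue number) -> Ca position from the first model.

    Altlocs resolve to the highest-occupancy atom; residues with insertion
    codes are rejected (unsupported numbering).
    """
    model = structure[0]
    out: dict[tuple[str, int], np.ndarray] = {}
    for chain in model:
        if chains is not None and chain.name not in chains:
            continue
        for res in chain:
            best = None
            for atom in res:
                if atom.name != "CA":
                    continue
                if best is None or atom.occ > best.occ:
                    best = atom
            if best is None:
                continue
            seqid = res.seqid
            if seqid.icode not in (" ", "", "\x00"):
                raise XLError(
                    f"residue {chain.name}{seqid.num}{seqid.icode}: insertion "
                    "codes are not supported"
                )
            out[(chain.name, seqid.num)] = np.array(
                [best.pos.x, best.pos.y, best.pos.z]
            )
    return out


def map_distances(
    links: pd.DataFrame,
    structure,
    chain_map: dict[str, str],
    cutoff: float = VALIDATION_CUTOFF,
) -> pd.DataFrame:
    """Annotate links with Ca-Ca distance and a satisfied flag (<= cutoff).

    Residues absent from the structure are flagged 'unmapped' rather than
    dropped. The returned table's attrs carry the satisfied / violated /
    unmapped tallies.
    """
    for protein, chain in chain_map.items():
        model = structure[0]
        if chain not in [c.name for c in model]:
            raise XLError(f"chain {chain!r} (protein {protein!r}) absent from structure")
    coords = ca_coordinates(structure)
    dist, status = [], []
    for row in links.itertuples(index=False):
        ca = chain_map.get(row.protein_a)
        cb = chain_map.get(row.protein_b)
        pa = coords.get((ca, int(row.residue_a))) if ca else None
        pb = coords.get((cb, int(row.residue_b))) if cb else None
        if pa is None or pb is None:
            dist.append(np.nan)
            status.append("unmapped")
            continue
        d = float(np.linalg.norm(pa - pb))
        dist.append(d)
        status.append("satisfied" if d <= cutoff else "violated")
    out = links.copy()
    out["ca_distance"] = dist
    out["status"] = status
    out.attrs["summary"] = {
        s: int((out["status"] == s).sum())
        for s in ("satisfied", "violated", "unmapped")
    }
    return out


def extract_contacts(
    structure,
    chains_a: list[str],
    chains_b: list[str],
    cutoff: float = CONTACT_CUTOFF,
) -> list[ResidueContact]:
    """All inter-set residue pairs with Ca-Ca distance <= cutoff,
    deterministically sorted."""
    if not chains_a or not chains_b:
        raise XLError("both chain sets must be non-empty")
    coords = ca_coordinates(structure)
    set_a = [(k, v) for k, v in coords.items() if k[0] in chains_a]
    set_b = [(k, v) for k, v in coords.items() if k[0] in chains_b]
    for name, chains, found in (("a", chains_a, set_a), ("b", chains_b, set_b)):
        if not found:
            raise XLError(f"chain set {name} {chains} has no Ca atoms in the structure")
    xa = np.vstack([v for _, v in set_a])
    xb = np.vstack([v for _, v in set_b])
    from scipy.spatial.distance import cdist

    dm = cdist(xa, xb)
    contacts = []
    for i, j in zip(*np.nonzero(dm <= cutoff)):
        ca, ra = set_a[i][0]
        cb, rb = set_b[j][0]
        contacts.append(ResidueContact(ca, ra, cb, rb, float(dm[i, j])))
    contacts.sort(key=lambda c: (c.chain_a, c.residue_a, c.chain_b, c.residue_b))
    return contacts


# ---------------------------------------------------------------------------
# Cross-species transfer
# ---------------------------------------------------------------------------

def align_residue_map(
    seq_source: str,
    seq_target: str,
    min_identity: float = 0.20,
) -> tuple[dict[int, int], float]:
    """Global Needleman-Wunsch residue-number map (1-based both sides).

    BLOSUM62, gap open 10 / extend 0.5. Source positions aligned to a gap
    are absent from the map. Raises when alignment identity falls below
    ``min_identity`` (unreliable transfer).
    """
    if not seq_source or not seq_target:
        raise XLError("both sequences must be non-empty")
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aln = aligner.align(seq_source, seq_target)[0]
    mapping: dict[int, int] = {}
    n_match = 0
    n_aligned = 0
    for (s_lo, s_hi), (t_lo, t_hi) in zip(*aln.aligned):
        for k in range(s_hi - s_lo):
            si, ti = s_lo + k, t_lo + k
            mapping[si + 1] = ti + 1
            n_aligned += 1
            if seq_source[si] == seq_target[ti]:
                n_match += 1
    identity = n_match / max(1, n_aligned)
    if identity < min_identity:
        raise XLError(
            f"alignment identity {identity:.1%} below the {min_identity:.0%} "
            "floor; transfer would be unreliable"
        )
    return mapping, identity


def transfer_by_alignment(
    items: pd.DataFrame | list[ResidueContact],
    seqs_source: dict[str, str],
    seqs_target: dict[str, str],
    min_identity: float = 0.20,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Renumber links/contacts into the target species' residue numbering.

    ``seqs_source``/``seqs_target`` map the chain/protein label to its
    sequence. Positions opposite an alignment gap are kept in the output
    flagged 'untransferable'. Returns (renumbered table, per-chain report
    with percent identity).
    """
    if isinstance(items, list):
        table = pd.DataFrame(
            [
                {
                    "protein_a": c.chain_a, "residue_a": c.residue_a,
                    "protein_b": c.chain_b, "residue_b": c.residue_b,
                    "distance": c.distance,
                }
                for c in items
            ]
        )
    else:
        table = items.copy()
    maps: dict[str, dict[int, int]] = {}
    report_rows = []
    for label in sorted(set(table["protein_a"]) | set(table["protein_b"])):
        if label not in seqs_source or label not in seqs_target:
            raise XLError(f"no sequence pair provided for {label!r}")
        mapping, identity = align_residue_map(
            seqs_source[label], seqs_target[label], min_identity
        )
        maps[label] = mapping
        report_rows.append(
            {"protein": label, "identity": identity, "mapped": len(mapping)}
        )
    out_rows = []
    for row in table.itertuples(index=False):
        ra = maps[row.protein_a].get(int(row.residue_a))
        rb = maps[row.protein_b].get(int(row.residue_b))
        rec = row._asdict()
        rec["residue_a_target"] = ra
        rec["residue_b_target"] = rb
        rec["transfer_status"] = (
            "ok" if ra is not None and rb is not None else "untransferable"
        )
        out_rows.append(rec)
    return pd.DataFrame(out_rows), pd.DataFrame(report_rows)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def export_links(
    links: pd.DataFrame,
    path: str,
    format: str = "xinet_csv",
    chain_map: dict[str, str] | None = None,
) -> str:
    """Write links as an xiNET CSV or Chimera pseudobond file.

    xiNET columns: Protein1, PepPos1, Protein2, PepPos2, Score (score =
    -log10 E-value when available). Pseudobond lines reference Ca atoms as
    ``#0:<res>.<chain>@CA``; a chain_map translates protein labels.
    """
    if links.empty:
        raise XLError("no links to export")
    if format == "xinet_csv":
        score = (
            -np.log10(links["e_value"])
            if "e_value" in links.columns
            else pd.Series(1.0, index=links.index)
        )
        out = pd.DataFrame(
            {
                "Protein1": links["protein_a"],
                "PepPos1": links["residue_a"],
                "Protein2": links["protein_b"],
                "PepPos2": links["residue_b"],
                "Score": score,
            }
        )
        out.to_csv(path, index=False)
    elif format == "chimera_pseudobond":
        cm = chain_map or {}
        with open(path, "w") as fh:
            for row in links.itertuples(index=False):
                ca = cm.get(row.protein_a, row.protein_a)
                cb = cm.get(row.protein_b, row.protein_b)
                fh.write(
                    f"#0:{int(row.residue_a)}.{ca}@CA "
                    f"#0:{int(row.residue_b)}.{cb}@CA\n"
                )
    else:
        raise XLError(f"unknown export format {format!r}")
    return path
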