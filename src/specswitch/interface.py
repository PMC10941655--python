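"""Inter-chain contact analysis and differential-interface identification.

The central operation of the pipeline: find residues of a shared subunit
that contact one complex-specific partner (e.g. Kog1 in TORC1) while
staying clear of every component of the alternative complex state (e.g.
Avo3 in TORC2) — the geometric reading of "interacts with X but not Y".
Also provides Shrake–Rupley solvent-accessible surface area and detection
of partner regions absent from orthologues (the unique loops whose
contacts make good clash targets).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .align_superpose import AlignmentMap
from .chem import VDW_RADII, element_radius
from .model_graft import ComplexModel
from .structio import Chain, Structure


class InterfaceError(ValueError):
    pass


@dataclass
class ContactMap:
    """Residue pairs of two chains with min heavy-atom distance ≤ cutoff."""

    chain_pair: tuple[str, str]
    cutoff: float
    contacts: list[tuple[object, object, float]]  # (rid_a, rid_b, min distance Å)

    def residues_a(self) -> set:
        return {a for a, _, _ in self.contacts}

    def residues_b(self) -> set:
        return {b for _, b, _ in self.contacts}

    def partners_of(self, rid_a) -> set:
        return {b for a, b, _ in self.contacts if a == rid_a}


@dataclass
class InterfaceSet:
    focal_chain_id: str
    partner_chain_id: str
    residues: set
    cutoff: float


@dataclass
class DifferentialInterface:
    """Shared-subunit residues binding the included partner only.

    ``per_residue_provenance[rid]`` records the min heavy-atom distance to
    the included partner and to every excluded partner (np.inf when the
    partner is entirely out of range), plus the unique-loop annotation
    once :func:`annotate_differential` has run.
    """

    focal_chain_id: str
    included_partner: str
    excluded_partners: list[str]
    residues: set
    cutoff: float
    exclusion_margin: float
    per_residue_provenance: dict = field(default_factory=dict)
    unresolved: list = field(default_factory=list)


@dataclass
class SasaProfile:
    per_atom: list  # (chain_id, rid, atom_name, area Å²)
    per_residue: dict  # (chain_id, rid) -> area Å²
    probe_radius: float
    n_sphere_points: int

    def residue_sasa(self, chain_id: str, rid) -> float:
        return self.per_residue.get((chain_id, rid), 0.0)

    def total(self) -> float:
        return float(sum(a for *_, a in self.per_atom))


@dataclass
class UniqueRegionSet:
    """Half-open reference-residue intervals gapped in all other MSA rows."""

    partner_id: str
    regions: list[tuple[int, int]]
    msa_id: str = ""

    def __post_init__(self) -> None:
        regions = sorted(self.regions)
        for (s1, e1), (s2, e2) in zip(regions, regions[1:]):
            if s2 < e1:
                raise InterfaceError("unique regions overlap")
        self.regions = regions

    def contains(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.regions)


def _chain_heavy_by_residue(chain: Chain):
    coords, rids = [], []
    for res in chain.residues:
        for a in res.atoms:
            if a.is_heavy:
                coords.append(a.coords)
                rids.append(res.rid)
    return np.asarray(coords, dtype=float).reshape(-1, 3), rids


def contact_map(structure: Structure, chain_a: str, chain_b: str, cutoff: float = 4.5) -> ContactMap:
    """All residue pairs across two chains within a heavy-atom distance cutoff.

    Uses a k-d tree for the pair search; a residue pair is a contact iff
    the minimum over its heavy-atom pairs is ≤ ``cutoff``.
    """
    if chain_a == chain_b:
        raise InterfaceError("contact map requires two distinct chains")
    if cutoff <= 0:
        raise InterfaceError("cutoff must be positive")
    ca, rids_a = _chain_heavy_by_residue(structure.chain(chain_a))
    cb, rids_b = _chain_heavy_by_residue(structure.chain(chain_b))
    best: dict[tuple, float] = {}
    if len(ca) and len(cb):
        tree_b = cKDTree(cb)
        for i, neighbours in enumerate(cKDTree(ca).query_ball_tree(tree_b, cutoff)):
            for j in neighbours:
                d = float(np.linalg.norm(ca[i] - cb[j]))
                key = (rids_a[i], rids_b[j])
                if d < best.get(key, np.inf):
                    best[key] = d
    contacts = [(a, b, d) for (a, b), d in sorted(best.items(), key=lambda kv: (str(kv[0][0]), str(kv[0][1])))]
    return ContactMap(chain_pair=(chain_a, chain_b), cutoff=cutoff, contacts=contacts)


def interface_residues(cmap: ContactMap, focal_chain_id: str) -> InterfaceSet:
    """Focal-chain residues that appear in at least one contact."""
    if focal_chain_id == cmap.chain_pair[0]:
        residues, partner = cmap.residues_a(), cmap.chain_pair[1]
    elif focal_chain_id == cmap.chain_pair[1]:
        residues, partner = cmap.residues_b(), cmap.chain_pair[0]
    else:
        raise InterfaceError(f"chain {focal_chain_id!r} is not part of this contact map")
    return InterfaceSet(focal_chain_id=focal_chain_id, partner_chain_id=partner,
                        residues=residues, cutoff=cmap.cutoff)


def min_distances_to_chain(focal_chain: Chain, partner_chain: Chain) -> dict:
    """Min heavy-atom distance from each focal residue to a partner chain."""
    pc, _ = _chain_heavy_by_residue(partner_chain)
    out = {}
    if len(pc) == 0:
        return {res.rid: float("inf") for res in focal_chain.residues}
    tree = cKDTree(pc)
    for res in focal_chain.residues:
        xyz = res.heavy_coords()
        if len(xyz) == 0:
            out[res.rid] = float("inf")
            continue
        d, _ = tree.query(xyz, k=1)
        out[res.rid] = float(np.min(d))
    return out


def _find_partner(partner_id: str, *models: ComplexModel):
    """Locate a partner chain by id in the given models (first match wins)."""
    for m in models:
        if partner_id in m.structure.chain_ids:
            return m, m.structure.chain(partner_id)
    raise InterfaceError(f"partner chain {partner_id!r} absent from all models")


def differential_interface(
    model_1: ComplexModel,
    model_2: ComplexModel,
    shared_map: AlignmentMap,
    included_partner: str,
    excluded_partners: list[str],
    cutoff: float = 4.5,
    exclusion_margin: float = 1.5,
) -> DifferentialInterface:
    """Shared-subunit residues contacting the included partner in model 1
    while clear of every excluded partner in either model.

    A residue qualifies iff (i) its min heavy-atom distance to the included
    partner is ≤ ``cutoff`` in model 1 and (ii) its min distance to every
    excluded partner exceeds ``cutoff + exclusion_margin`` (the margin
    absorbs coordinate error of template-grafted models). Excluded partners
    are looked up in model 2 first, then model 1 (components shared by both
    complex states may live in either). Residues unresolved in either model
    are dropped and reported.
    """
    shared_1 = model_1.shared_chain()
    shared_2 = model_2.shared_chain()
    if included_partner not in model_1.structure.chain_ids:
        raise InterfaceError(f"included partner {included_partner!r} not in model 1")

    mapped = dict(shared_map.aligned_pairs)
    inc_dist = min_distances_to_chain(shared_1, model_1.structure.chain(included_partner))

    exc_dist: dict[str, dict] = {}
    exc_on_model2: dict[str, bool] = {}
    for pid in excluded_partners:
        model, pchain = _find_partner(pid, model_2, model_1)
        focal = shared_2 if model is model_2 else shared_1
        exc_dist[pid] = min_distances_to_chain(focal, pchain)
        exc_on_model2[pid] = model is model_2

    residues = set()
    provenance = {}
    unresolved = []
    needs_model2 = any(exc_on_model2.values())
    for res in shared_1.residues:
        d_inc = inc_dist.get(res.rid, float("inf"))
        if d_inc > cutoff:
            continue
        if needs_model2 and res.seq_id not in mapped:
            unresolved.append(res.rid)
            continue
        d_exc = {}
        ok = True
        for pid in excluded_partners:
            # mapped identity numbering: same rid on the model-2 shared chain
            d = exc_dist[pid].get(res.rid, float("inf"))
            d_exc[pid] = d
            if d <= cutoff + exclusion_margin:
                ok = False
        provenance[res.rid] = {
            "wt_aa": res.one_letter,
            "min_dist_included": d_inc,
            "min_dist_excluded": d_exc,
            "unique_loop_contact": None,
        }
        if ok:
            residues.add(res.rid)
    return DifferentialInterface(
        focal_chain_id=shared_1.chain_id, included_partner=included_partner,
        excluded_partners=list(excluded_partners), residues=residues,
        cutoff=cutoff, exclusion_margin=exclusion_margin,
        per_residue_provenance=provenance, unresolved=unresolved,
    )


# --- solvent-accessible surface area ------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral unit-sphere quadrature points."""
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa(structure: Structure, probe_radius: float = 1.4, n_points: int = 960) -> SasaProfile:
    """Shrake–Rupley numerical SASA over all heavy atoms of a structure.

    Each atom's accessible sphere (radius r_atom + probe) is sampled at
    ``n_points`` golden-spiral points; a point is accessible if outside
    every neighbour's accessible sphere. Per-residue areas are sums of
    per-atom areas.
    """
    if n_points < 92:
        raise InterfaceError("n_points must be at least 92 for usable quadrature")
    atoms = [(c.chain_id, r.rid, a) for c in structure.chains
             for r in c.residues for a in r.atoms if a.is_heavy]
    unknown = [f"{cid}/{rid}/{a.name}({a.element})" for cid, rid, a in atoms
               if a.element.upper() not in VDW_RADII]
    if unknown:
        raise InterfaceError(f"no vdW radius for atoms: {unknown[:10]}")

    coords = np.array([a.coords for _, _, a in atoms], dtype=float)
    radii = np.array([element_radius(a.element) + probe_radius for _, _, a in atoms])
    pts = _sphere_points(n_points)
    tree = cKDTree(coords)
    max_r = radii.max()

    per_atom = []
    per_residue: dict = {}
    for i, (cid, rid, a) in enumerate(atoms):
        ri = radii[i]
        neighbours = np.array([
            j for j in tree.query_ball_point(coords[i], ri + max_r)
            if j != i and np.linalg.norm(coords[j] - coords[i]) < ri + radii[j]],
            dtype=int)
        if len(neighbours):
            surface = coords[i] + pts * ri  # (n_points, 3)
            delta = surface[:, None, :] - coords[neighbours][None, :, :]
            d2 = np.einsum("pnk,pnk->pn", delta, delta)
            accessible = np.all(d2 >= radii[neighbours][None, :] ** 2, axis=1)
            n_acc = int(accessible.sum())
        else:
            n_acc = n_points
        area = 4.0 * np.pi * ri * ri * n_acc / n_points
        per_atom.append((cid, rid, a.name, float(area)))
        per_residue[(cid, rid)] = per_residue.get((cid, rid), 0.0) + float(area)
    return SasaProfile(per_atom=per_atom, per_residue=per_residue,
                       probe_radius=probe_radius, n_sphere_points=n_points)


# --- orthologue-gap ("unique loop") regions ------------------------------

def _read_msa(msa, fmt: str | None = None) -> list[tuple[str, str]]:
    if isinstance(msa, (str, Path)):
        from Bio import AlignIO
        path = Path(msa)
        if fmt is None:
            fmt = "stockholm" if path.suffix.lower() in (".sto", ".stk", ".stockholm") else "fasta"
        aln = AlignIO.read(str(path), fmt)
        return [(rec.id, str(rec.seq)) for rec in aln]
    if isinstance(msa, dict):
        rows = list(msa.items())
    else:
        rows = [(rid, seq) for rid, seq in msa]
    lengths = {len(s) for _, s in rows}
    if len(lengths) > 1:
        raise InterfaceError(f"ragged MSA: row lengths {sorted(lengths)}")
    return rows


def unique_regions(msa, reference_row: str, min_len: int = 3, *, msa_format: str | None = None) -> UniqueRegionSet:
    """Reference-residue intervals present only in the reference MSA row.

    Scans alignment columns where the reference has a residue and *all*
    other rows have gaps; maximal runs of at least ``min_len`` such
    columns are mapped to half-open residue intervals (1-based) on the
    ungapped reference sequence.
    """
    rows = _read_msa(msa, msa_format)
    ids = [rid for rid, _ in rows]
    if reference_row not in ids:
        raise InterfaceError(f"reference row {reference_row!r} not in MSA rows {ids}")
    if len(rows) < 2:
        raise InterfaceError("MSA must contain the reference and at least one other row")
    ref_seq = dict(rows)[reference_row]
    others = [s for rid, s in rows if rid != reference_row]
    gap_chars = "-."

    regions: list[tuple[int, int]] = []
    ref_pos = 0  # 1-based position of the last reference residue seen
    run_start = None
    run_len = 0
    for col in range(len(ref_seq)):
        ref_has = ref_seq[col] not in gap_chars
        if ref_has:
            ref_pos += 1
        unique_col = ref_has and all(s[col] in gap_chars for s in others)
        if unique_col:
            if run_start is None:
                run_start = ref_pos
            run_len += 1
        elif run_start is not None:
            if run_len >= min_len:
                regions.append((run_start, run_start + run_len))
            run_start, run_len = None, 0
    if run_start is not None and run_len >= min_len:
        regions.append((run_start, run_start + run_len))
    return UniqueRegionSet(partner_id=reference_row, regions=regions,
                           msa_id=str(msa) if isinstance(msa, (str, Path)) else "")


def annotate_differential(
    diff: DifferentialInterface,
    unique: UniqueRegionSet,
    cmap_1: ContactMap,
) -> DifferentialInterface:
    """Flag differential residues whose partner contacts fall in unique regions.

    A residue's flag is true iff at least one of its contacts on the
    included partner lies inside an orthologue-gap region — the structural
    signature of a species-specific assembly contact.
    """
    for rid in diff.per_residue_provenance:
        partners = cmap_1.partners_of(rid)
        flag = any(unique.contains(p if isinstance(p, int) else int(str(p)[:-1]))
                   for p in partners)
        diff.per_residue_provenance[rid]["unique_loop_contact"] = flag
    return diff


def export_differential_tsv(diff: DifferentialInterface, path) -> None:
    """Write the differential interface as a fixed-column TSV report."""
    import pandas as pd

    rows = []
    for rid in sorted(diff.residues, key=lambda r: (isinstance(r, str), r)):
        prov = diff.per_residue_provenance[rid]
        row = {
            "residue": rid,
            "wt_aa": prov["wt_aa"],
            "min_dist_included": round(prov["min_dist_included"], 3),
        }
        for pid, d in prov["min_dist_excluded"].items():
            row[f"min_dist_{pid}"] = round(d, 3) if np.isfinite(d) else "inf"
        row["unique_loop_flag"] = prov["unique_loop_contact"]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def differential_intervals(diff: DifferentialInterface) -> list[tuple[int, int]]:
    """Collapse the differential residue set to half-open intervals."""
    ids = sorted(r for r in diff.residues if isinstance(r, int))
    intervals = []
    for rid in ids:
        if intervals and rid == intervals[-1][1]:
            intervals[-1] = (intervals[-1][0], rid + 1)
        else:
            intervals.append((rid, rid + 1))
    return intervals
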