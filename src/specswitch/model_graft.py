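"""Template-based subunit modelling by alignment-guided coordinate grafting.

Instead of full homology modelling, the target sequence is threaded onto
the template backbone: aligned positions inherit the template backbone
coordinates and carry the *target* residue identity; identical residues
keep the template side chain, mismatches are truncated to N, CA, C, O, CB
(ideal CB rebuilt when absent). Unaligned target residues are recorded as
unmodelled, never invented. This is deterministic and sufficient for
interface-residue identification, which is driven by backbone proximity.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np

from .align_superpose import (
    AlignmentMap,
    ShiftReport,
    SuperpositionResult,
    global_align,
    relieve_clashes,
    superpose_by_alignment,
)
from .chem import AA1_TO_3, build_cb
from .structio import Atom, Chain, Residue, Structure, extract_sequence

BACKBONE = ("N", "CA", "C", "O")

ROLES = ("shared_subunit", "partner_specific", "partner_shared")


class GraftError(ValueError):
    pass


@dataclass
class GraftedChain:
    chain: Chain
    template_id: str
    template_chain_id: str
    coverage: float
    mismatch_positions: list[int] = field(default_factory=list)
    unmodelled_positions: list[int] = field(default_factory=list)


@dataclass
class ComplexModel:
    """An assembled complex model with per-chain roles and provenance."""

    id: str
    structure: Structure
    subunit_roles: dict[str, str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid, role in self.subunit_roles.items():
            if role not in ROLES:
                raise GraftError(f"unknown role {role!r} for chain {cid}")
        shared = [c for c, r in self.subunit_roles.items() if r == "shared_subunit"]
        if len(shared) != 1:
            raise GraftError(f"model {self.id}: need exactly one shared_subunit, got {shared}")
        specific = [c for c, r in self.subunit_roles.items() if r == "partner_specific"]
        if not specific:
            raise GraftError(f"model {self.id}: need at least one partner_specific chain")

    @property
    def shared_chain_id(self) -> str:
        return next(c for c, r in self.subunit_roles.items() if r == "shared_subunit")

    def shared_chain(self) -> Chain:
        return self.structure.chain(self.shared_chain_id)


def graft_model(
    target_seq: str,
    template_chain: Chain,
    alignment: AlignmentMap,
    sidechain_policy: str = "keep_if_identical",
    *,
    template_id: str = "",
    chain_id: str | None = None,
    numbering_start: int = 1,
) -> GraftedChain:
    """Thread ``target_seq`` onto template backbone coordinates.

    ``alignment`` maps target positions (side a, 1-based) to template
    residue indices (side b). Grafted residues are renumbered by target
    position (``numbering_start`` + position − 1) so author numbering
    follows the target sequence.
    """
    if sidechain_policy not in ("keep_if_identical", "cb_truncate_all"):
        raise GraftError(f"unknown sidechain policy {sidechain_policy!r}")
    if not target_seq:
        raise GraftError("empty target sequence")

    cid = chain_id if chain_id is not None else template_chain.chain_id
    residues: list[Residue] = []
    mismatches: list[int] = []
    unmodelled: set[int] = set(range(1, len(target_seq) + 1))
    skipped: list[int] = []

    for a_pos, b_pos in alignment.aligned_pairs:
        if a_pos > len(target_seq):
            continue
        if b_pos > len(template_chain.residues):
            skipped.append(a_pos)
            continue
        tres = template_chain.residues[b_pos - 1]
        target_aa = target_seq[a_pos - 1]
        identical = tres.one_letter == target_aa
        keep_sidechain = identical and sidechain_policy == "keep_if_identical"

        if keep_sidechain:
            atoms = [copy.deepcopy(a) for a in tres.atoms]
        else:
            atoms = [copy.deepcopy(a) for a in tres.atoms if a.name in BACKBONE]
            n, ca, c = (tres.atom(x) for x in ("N", "CA", "C"))
            if n is None or ca is None or c is None:
                skipped.append(a_pos)
                continue
            if target_aa != "G":
                cb = tres.atom("CB")
                cb_xyz = cb.coords.copy() if cb is not None else build_cb(
                    n.coords, ca.coords, c.coords)
                atoms.append(Atom(name="CB", element="C", coords=cb_xyz))

        residues.append(Residue(
            chain_id=cid,
            seq_id=numbering_start + a_pos - 1,
            name=AA1_TO_3.get(target_aa, "UNK"),
            atoms=atoms,
        ))
        unmodelled.discard(a_pos)
        if not identical:
            mismatches.append(numbering_start + a_pos - 1)

    if skipped:
        warnings.warn(
            f"{len(skipped)} aligned target positions lack usable template "
            f"coordinates and were left unmodelled: {skipped[:10]}")
    if not residues:
        raise GraftError("no target residue could be modelled from the template")

    coverage = len(residues) / len(target_seq)
    return GraftedChain(
        chain=Chain(chain_id=cid, residues=residues),
        template_id=template_id or "template",
        template_chain_id=template_chain.chain_id,
        coverage=coverage,
        mismatch_positions=mismatches,
        unmodelled_positions=sorted(numbering_start + p - 1 for p in unmodelled),
    )


def assemble_complex(
    grafted: dict[str, GraftedChain],
    template_complex: Structure,
    roles: dict[str, str],
    *,
    model_id: str = "model",
    clash_step: float = 0.25,
    clash_max_shift: float = 5.0,
    clash_threshold: float = 0.0,
) -> ComplexModel:
    """Superpose grafted chains onto their template counterparts and relieve
    inter-chain clashes with the shared subunit held fixed.

    ``grafted`` maps output chain ids to grafted chains (each knows its
    template chain); ``roles`` maps the same chain ids to subunit roles.
    """
    if set(roles) != set(grafted):
        missing = set(grafted) ^ set(roles)
        raise GraftError(f"role map incomplete or extraneous for chains {sorted(missing)}")

    chains: list[Chain] = []
    provenance: dict = {"template": template_complex.id, "chains": {}}
    for cid, g in grafted.items():
        template_chain = template_complex.chain(g.template_chain_id)
        seq_g = extract_sequence(g.chain)
        seq_t = extract_sequence(template_chain)
        aln = global_align(seq_g, seq_t, seq_a_id=cid, seq_b_id=g.template_chain_id)
        result, moved = superpose_by_alignment(g.chain, template_chain, aln)
        moved.chain_id = cid
        for res in moved.residues:
            res.chain_id = cid
        chains.append(moved)
        provenance["chains"][cid] = {
            "template_chain": g.template_chain_id,
            "superposition_rmsd": result.rmsd,
            "n_anchor_pairs": result.n_pairs,
            "coverage": g.coverage,
        }

    structure = Structure(id=model_id, chains=chains, source_format="pdb")
    model = ComplexModel(id=model_id, structure=structure,
                         subunit_roles=dict(roles), provenance=provenance)

    # shift each partner chain off the fixed shared subunit if interpenetrating
    shared = model.shared_chain_id
    for cid in list(roles):
        if cid == shared:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            structure, report = relieve_clashes(
                structure, cid, step=clash_step,
                max_shift=clash_max_shift, overlap_threshold=clash_threshold)
        provenance["chains"][cid]["relief_shift"] = report.total_shift
        provenance["chains"][cid]["residual_overlap"] = report.residual_overlap
    model.structure = structure
    return model


def map_shared_subunit(model_1: ComplexModel, model_2: ComplexModel) -> AlignmentMap:
    """Identity mapping of the shared subunit between two complex models.

    Coordinates of the returned map are *author residue numbers* (valid in
    both models because grafting preserves target numbering). Residues
    present in only one model are excluded; residue identities must agree
    at every mapped position, otherwise the models do not derive from the
    same target sequence.
    """
    ch1 = model_1.shared_chain()
    ch2 = model_2.shared_chain()
    by_rid_2 = {r.rid: r for r in ch2.residues}
    pairs: list[tuple[int, int]] = []
    only_1, conflicts = [], []
    for r1 in ch1.residues:
        r2 = by_rid_2.get(r1.rid)
        if r2 is None:
            only_1.append(r1.rid)
            continue
        if r1.name != r2.name:
            conflicts.append((r1.rid, r1.name, r2.name))
            continue
        pairs.append((r1.seq_id, r2.seq_id))
    if conflicts:
        raise GraftError(
            "shared subunit sequences disagree at positions "
            + ", ".join(f"{rid} ({a} vs {b})" for rid, a, b in conflicts))
    only_2 = [r.rid for r in ch2.residues if r.rid not in {x.rid for x in ch1.residues}]
    if only_1 or only_2:
        warnings.warn(
            f"shared-subunit residues present in one model only: "
            f"model_1 {only_1[:10]}, model_2 {only_2[:10]}")
    n = len(pairs)
    return AlignmentMap(
        seq_a_id=f"{model_1.id}:{ch1.chain_id}", seq_b_id=f"{model_2.id}:{ch2.chain_id}",
        aligned_pairs=pairs, score=float(n), n_columns=n + len(only_1) + len(only_2),
        n_identical=n, len_a=len(ch1.residues), len_b=len(ch2.residues),
    )
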