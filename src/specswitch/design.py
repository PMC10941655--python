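"""Specificity-switch mutation design at a differential interface.

Implements the engineering rules for abolishing one complex state while
preserving the other: hydrophobic residues of the differential interface
are mutated to glutamine (larger, hydrophilic, uncharged — designed to
clash with the partner being evicted while stabilising the newly exposed
surface), and charged residues are enlarged with the same charge (K→R,
D→E). The designed clash is verified geometrically with a small fixed
rotamer library and a soft-sphere overlap score; solvent exposure of the
mutated surface is checked by relative SASA of the shared subunit alone.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .chem import (
    AA1_TO_3,
    MAX_SASA_GXG,
    STANDARD_AA1,
    element_radius,
    place_atom,
    build_cb,
    soft_sphere_overlap,
)
from .interface import DifferentialInterface, sasa
from .model_graft import ComplexModel
from .structio import Atom, Chain, Residue, Structure


class DesignError(ValueError):
    pass


class ResidueClass(str, Enum):
    HYDROPHOBIC = "hydrophobic"
    POSITIVE = "positive"
    NEGATIVE = "negative"
    POLAR_UNCHARGED = "polar_uncharged"
    SPECIAL = "special"


# Fixed classification. G/P/C/H are "special": glycine and proline shape
# the backbone, cysteine may be disulfide-bonded, histidine's charge is
# pH-dependent — none is safely covered by the two substitution rules.
RESIDUE_CLASS: dict[str, ResidueClass] = {
    **{aa: ResidueClass.HYDROPHOBIC for aa in "AVLIMFWY"},
    **{aa: ResidueClass.POSITIVE for aa in "KR"},
    **{aa: ResidueClass.NEGATIVE for aa in "DE"},
    **{aa: ResidueClass.POLAR_UNCHARGED for aa in "STNQ"},
    **{aa: ResidueClass.SPECIAL for aa in "GPCH"},
}

# The only size-up substitutions with a larger standard residue of the
# same charge; R and E have none and are flagged for manual review.
CHARGE_SIZE_UP: dict[str, str] = {"K": "R", "D": "E"}


def classify_residue(aa: str) -> ResidueClass:
    """Class of a standard one-letter amino acid for the mutation rules."""
    if aa not in STANDARD_AA1:
        raise DesignError(f"nonstandard amino acid {aa!r}")
    return RESIDUE_CLASS[aa]


@dataclass
class MutationProposal:
    position: int
    wt_aa: str
    mutant_aa: str
    rule: str  # hydrophobic_to_gln | charge_size_up | flagged_manual
    clash_score_vs_included_partner: float | None = None
    exposed: bool | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        if self.rule != "flagged_manual" and self.mutant_aa == self.wt_aa:
            raise DesignError(f"{self.wt_aa}{self.position}: rule {self.rule} "
                              "must change the residue")

    @property
    def label(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mutant_aa}"


def propose_mutation(position: int, wt_aa: str) -> MutationProposal:
    """Apply the substitution rules to one residue.

    Hydrophobic → Q; K → R and D → E (larger, same charge); everything
    else (R, E, polar uncharged, special) has no rule-compliant larger
    substitute and is flagged for manual choice with the wild type kept.
    """
    cls = classify_residue(wt_aa)
    if cls is ResidueClass.HYDROPHOBIC:
        notes = "aggressive: aromatic to Q" if wt_aa in "WYF" else ""
        return MutationProposal(position, wt_aa, "Q", "hydrophobic_to_gln", notes=notes)
    if cls in (ResidueClass.POSITIVE, ResidueClass.NEGATIVE) and wt_aa in CHARGE_SIZE_UP:
        return MutationProposal(position, wt_aa, CHARGE_SIZE_UP[wt_aa], "charge_size_up")
    return MutationProposal(position, wt_aa, wt_aa, "flagged_manual",
                            notes=f"no rule for class {cls.value}")


# --- side-chain growth ----------------------------------------------------
# Internal-coordinate topology per residue, applied after CB placement.
# Entry: (atom, element, (ref_a, ref_b, ref_c), bond Å, angle °, dihedral)
# where dihedral is a float (fixed) or ("chi", k, offset °). Ring closures
# are idealised, which is adequate for steric screening.
_SC = {
    "A": [],
    "G": [],
    "S": [("OG", "O", ("N", "CA", "CB"), 1.42, 110.8, ("chi", 1, 0))],
    "C": [("SG", "S", ("N", "CA", "CB"), 1.81, 114.4, ("chi", 1, 0))],
    "T": [("OG1", "O", ("N", "CA", "CB"), 1.43, 109.6, ("chi", 1, 0)),
          ("CG2", "C", ("N", "CA", "CB"), 1.52, 110.5, ("chi", 1, -120))],
    "V": [("CG1", "C", ("N", "CA", "CB"), 1.52, 110.5, ("chi", 1, 0)),
          ("CG2", "C", ("N", "CA", "CB"), 1.52, 110.5, ("chi", 1, 122))],
    "L": [("CG", "C", ("N", "CA", "CB"), 1.53, 116.3, ("chi", 1, 0)),
          ("CD1", "C", ("CA", "CB", "CG"), 1.52, 110.7, ("chi", 2, 0)),
          ("CD2", "C", ("CA", "CB", "CG"), 1.52, 110.7, ("chi", 2, 122))],
    "I": [("CG1", "C", ("N", "CA", "CB"), 1.53, 110.4, ("chi", 1, 0)),
          ("CG2", "C", ("N", "CA", "CB"), 1.52, 110.5, ("chi", 1, -122)),
          ("CD1", "C", ("CA", "CB", "CG1"), 1.51, 113.9, ("chi", 2, 0))],
    "M": [("CG", "C", ("N", "CA", "CB"), 1.52, 114.1, ("chi", 1, 0)),
          ("SD", "S", ("CA", "CB", "CG"), 1.80, 112.7, ("chi", 2, 0)),
          ("CE", "C", ("CB", "CG", "SD"), 1.79, 100.9, ("chi", 3, 0))],
    "F": [("CG", "C", ("N", "CA", "CB"), 1.50, 113.8, ("chi", 1, 0)),
          ("CD1", "C", ("CA", "CB", "CG"), 1.39, 120.8, ("chi", 2, 0)),
          ("CD2", "C", ("CA", "CB", "CG"), 1.39, 120.8, ("chi", 2, 180)),
          ("CE1", "C", ("CB", "CG", "CD1"), 1.39, 120.8, 180.0),
          ("CE2", "C", ("CB", "CG", "CD2"), 1.39, 120.8, 180.0),
          ("CZ", "C", ("CG", "CD1", "CE1"), 1.39, 120.0, 0.0)],
    "Y": [("CG", "C", ("N", "CA", "CB"), 1.50, 113.8, ("chi", 1, 0)),
          ("CD1", "C", ("CA", "CB", "CG"), 1.39, 120.8, ("chi", 2, 0)),
          ("CD2", "C", ("CA", "CB", "CG"), 1.39, 120.8, ("chi", 2, 180)),
          ("CE1", "C", ("CB", "CG", "CD1"), 1.39, 120.8, 180.0),
          ("CE2", "C", ("CB", "CG", "CD2"), 1.39, 120.8, 180.0),
          ("CZ", "C", ("CG", "CD1", "CE1"), 1.39, 120.0, 0.0),
          ("OH", "O", ("CD1", "CE1", "CZ"), 1.38, 120.0, 180.0)],
    "W": [("CG", "C", ("N", "CA", "CB"), 1.50, 113.8, ("chi", 1, 0)),
          ("CD1", "C", ("CA", "CB", "CG"), 1.37, 126.9, ("chi", 2, 0)),
          ("CD2", "C", ("CA", "CB", "CG"), 1.43, 126.8, ("chi", 2, 180)),
          ("NE1", "N", ("CB", "CG", "CD1"), 1.38, 110.2, 180.0),
          ("CE2", "C", ("CB", "CG", "CD2"), 1.41, 107.2, 180.0),
          ("CE3", "C", ("CB", "CG", "CD2"), 1.40, 133.9, 0.0),
          ("CZ2", "C", ("CG", "CD2", "CE2"), 1.40, 122.4, 180.0),
          ("CZ3", "C", ("CG", "CD2", "CE3"), 1.39, 118.6, 180.0),
          ("CH2", "C", ("CD2", "CE2", "CZ2"), 1.37, 117.5, 0.0)],
    "N": [("CG", "C", ("N", "CA", "CB"), 1.52, 112.6, ("chi", 1, 0)),
          ("OD1", "O", ("CA", "CB", "CG"), 1.23, 120.8, ("chi", 2, 0)),
          ("ND2", "N", ("CA", "CB", "CG"), 1.33, 116.4, ("chi", 2, 180))],
    "D": [("CG", "C", ("N", "CA", "CB"), 1.52, 112.6, ("chi", 1, 0)),
          ("OD1", "O", ("CA", "CB", "CG"), 1.25, 118.4, ("chi", 2, 0)),
          ("OD2", "O", ("CA", "CB", "CG"), 1.25, 118.4, ("chi", 2, 180))],
    "Q": [("CG", "C", ("N", "CA", "CB"), 1.52, 114.1, ("chi", 1, 0)),
          ("CD", "C", ("CA", "CB", "CG"), 1.52, 112.6, ("chi", 2, 0)),
          ("OE1", "O", ("CB", "CG", "CD"), 1.23, 120.8, ("chi", 3, 0)),
          ("NE2", "N", ("CB", "CG", "CD"), 1.33, 116.4, ("chi", 3, 180))],
    "E": [("CG", "C", ("N", "CA", "CB"), 1.52, 114.1, ("chi", 1, 0)),
          ("CD", "C", ("CA", "CB", "CG"), 1.52, 112.6, ("chi", 2, 0)),
          ("OE1", "O", ("CB", "CG", "CD"), 1.25, 118.4, ("chi", 3, 0)),
          ("OE2", "O", ("CB", "CG", "CD"), 1.25, 118.4, ("chi", 3, 180))],
    "K": [("CG", "C", ("N", "CA", "CB"), 1.52, 114.1, ("chi", 1, 0)),
          ("CD", "C", ("CA", "CB", "CG"), 1.52, 111.3, ("chi", 2, 0)),
          ("CE", "C", ("CB", "CG", "CD"), 1.52, 111.3, ("chi", 3, 0)),
          ("NZ", "N", ("CG", "CD", "CE"), 1.49, 111.9, ("chi", 4, 0))],
    "R": [("CG", "C", ("N", "CA", "CB"), 1.52, 114.1, ("chi", 1, 0)),
          ("CD", "C", ("CA", "CB", "CG"), 1.52, 111.3, ("chi", 2, 0)),
          ("NE", "N", ("CB", "CG", "CD"), 1.46, 111.5, ("chi", 3, 0)),
          ("CZ", "C", ("CG", "CD", "NE"), 1.33, 124.2, ("chi", 4, 0)),
          ("NH1", "N", ("CD", "NE", "CZ"), 1.33, 120.0, 0.0),
          ("NH2", "N", ("CD", "NE", "CZ"), 1.33, 120.0, 180.0)],
    "H": [("CG", "C", ("N", "CA", "CB"), 1.50, 113.8, ("chi", 1, 0)),
          ("ND1", "N", ("CA", "CB", "CG"), 1.38, 122.7, ("chi", 2, 0)),
          ("CD2", "C", ("CA", "CB", "CG"), 1.36, 129.7, ("chi", 2, 180)),
          ("CE1", "C", ("CB", "CG", "ND1"), 1.32, 109.0, 180.0),
          ("NE2", "N", ("CB", "CG", "CD2"), 1.37, 107.0, 180.0)],
    "P": [("CG", "C", ("N", "CA", "CB"), 1.49, 104.5, 30.0),
          ("CD", "C", ("CA", "CB", "CG"), 1.50, 106.0, -35.0)],
}

# Number of freely rotatable chi angles per residue type.
N_CHI = {"A": 0, "G": 0, "P": 0, "S": 1, "C": 1, "T": 1, "V": 1,
         "L": 2, "I": 2, "F": 2, "Y": 2, "W": 2, "H": 2, "N": 2, "D": 2,
         "M": 3, "Q": 3, "E": 3, "K": 4, "R": 4}

_CHI_VALUES = (-60.0, 60.0, 180.0)
_MAX_VARIED_CHI = 3  # 3^3 = 27 rotamers at most


def rotamer_chi_sets(aa: str) -> list[tuple[float, ...]]:
    """The fixed chi-angle library for one residue type.

    Up to three chi angles take each of −60°, 60°, 180° (≤27 rotamers);
    any further chi angles are held extended at 180°.
    """
    n_chi = N_CHI[aa]
    varied = min(n_chi, _MAX_VARIED_CHI)
    if n_chi == 0:
        return [()]
    tail = (180.0,) * (n_chi - varied)
    return [combo + tail for combo in itertools.product(_CHI_VALUES, repeat=varied)]


def grow_sidechain(
    residue: Residue,
    mutant_aa: str,
    rotamer_set: list[tuple[float, ...]] | None = None,
) -> list[list[Atom]]:
    """Build idealised mutant side chains on a residue's backbone.

    Returns one atom list (CB plus distal atoms) per rotamer; glycine
    yields a single empty set. Bond lengths and angles are ideal by
    construction; ring closures are approximate.
    """
    if mutant_aa not in STANDARD_AA1:
        raise DesignError(f"nonstandard mutant {mutant_aa!r}")
    n, ca, c = (residue.atom(x) for x in ("N", "CA", "C"))
    if n is None or ca is None or c is None:
        missing = [x for x, a in zip(("N", "CA", "C"), (n, ca, c)) if a is None]
        raise DesignError(
            f"residue {residue.rid}: backbone atoms {missing} required to grow a side chain")
    if mutant_aa == "G":
        return [[]]

    chis = rotamer_set if rotamer_set is not None else rotamer_chi_sets(mutant_aa)
    cb_xyz = build_cb(n.coords, ca.coords, c.coords)
    out: list[list[Atom]] = []
    for chi in chis:
        coords = {"N": n.coords, "CA": ca.coords, "C": c.coords, "CB": cb_xyz}
        atoms = [Atom(name="CB", element="C", coords=cb_xyz.copy())]
        for name, element, refs, bond, angle, dihedral in _SC[mutant_aa]:
            if isinstance(dihedral, tuple):
                _, k, offset = dihedral
                value = (chi[k - 1] if k - 1 < len(chi) else 180.0) + offset
            else:
                value = dihedral
            xyz = place_atom(coords[refs[0]], coords[refs[1]], coords[refs[2]],
                             bond, angle, value)
            coords[name] = xyz
            atoms.append(Atom(name=name, element=element, coords=xyz))
        out.append(atoms)
    return out


@dataclass
class ClashReport:
    position: int
    mutant_aa: str
    partner_chain_id: str
    per_rotamer: list[float]
    partner_atoms: list  # (rid, atom_name) of partner atoms in any overlap

    @property
    def min_score(self) -> float:
        return min(self.per_rotamer)

    @property
    def max_score(self) -> float:
        return max(self.per_rotamer)

    @property
    def designed_clash(self) -> bool:
        """True iff every rotamer overlaps the partner (unavoidable clash)."""
        return self.min_score > 0.0

    @property
    def any_clash(self) -> bool:
        return self.max_score > 0.0


def clash_score(
    model: ComplexModel,
    proposal: MutationProposal,
    partner_chain_id: str,
    rotamer_set: list[tuple[float, ...]] | None = None,
) -> ClashReport:
    """Soft-sphere overlap of the mutant side chain with a partner chain.

    For each rotamer of the mutant, sums max(0, r_i + r_j − d)² over
    (mutant side-chain atom, partner heavy atom) pairs. ``min_score`` is
    the optimistic view (partner avoidable if 0); a designed clash
    requires every rotamer to overlap.
    """
    shared = model.shared_chain()
    residue = shared.residue(proposal.position)
    if residue is None:
        raise DesignError(f"position {proposal.position} not modelled in {model.id}")
    partner = model.structure.chain(partner_chain_id)

    p_coords, p_radii, p_ids = [], [], []
    for res in partner.residues:
        for a in res.atoms:
            if a.is_heavy:
                p_coords.append(a.coords)
                p_radii.append(element_radius(a.element))
                p_ids.append((res.rid, a.name))
    p_coords = np.asarray(p_coords).reshape(-1, 3)
    p_radii = np.asarray(p_radii)

    per_rotamer: list[float] = []
    involved: set = set()
    for atoms in grow_sidechain(residue, proposal.mutant_aa, rotamer_set):
        if not atoms:
            per_rotamer.append(0.0)
            continue
        m_coords = np.array([a.coords for a in atoms])
        m_radii = np.array([element_radius(a.element) for a in atoms])
        per_rotamer.append(soft_sphere_overlap(m_coords, m_radii, p_coords, p_radii))
        d = np.linalg.norm(m_coords[:, None, :] - p_coords[None, :, :], axis=2)
        pen = (m_radii[:, None] + p_radii[None, :]) - d
        for j in np.unique(np.nonzero(pen > 0)[1]):
            involved.add(p_ids[j])
    return ClashReport(position=proposal.position, mutant_aa=proposal.mutant_aa,
                       partner_chain_id=partner_chain_id,
                       per_rotamer=per_rotamer, partner_atoms=sorted(involved))


def exposure_check(
    model: ComplexModel,
    position: int,
    mutant_aa: str,
    threshold: float = 0.2,
    n_points: int = 240,
) -> bool:
    """Is the mutated residue solvent-exposed on the shared subunit alone?

    Partners are removed, the mutant side chain is grown in its extended
    rotamer, and the residue SASA is normalised by the residue-type
    maximum (Gly-X-Gly). True iff relative SASA ≥ ``threshold``. The
    lighter default quadrature (240 points, <2% error) is ample for a
    binary threshold decision.
    """
    import copy

    shared = copy.deepcopy(model.shared_chain())
    residue = shared.residue(position)
    if residue is None:
        raise DesignError(f"position {position} not modelled in {model.id}")
    extended = [(180.0,) * N_CHI[mutant_aa]]
    sidechain = grow_sidechain(residue, mutant_aa, extended)[0]
    residue.atoms = [a for a in residue.atoms if a.name in ("N", "CA", "C", "O")] + sidechain
    residue.name = AA1_TO_3[mutant_aa]
    isolated = Structure(id=f"{model.id}:{shared.chain_id}", chains=[shared])
    profile = sasa(isolated, n_points=n_points)
    rel = profile.residue_sasa(shared.chain_id, residue.rid) / MAX_SASA_GXG[mutant_aa]
    return rel >= threshold


# --- grouping and combinations -------------------------------------------

def group_targets(
    proposals: list[MutationProposal],
    method: str = "sequence_window",
    *,
    window_len: int = 10,
    partition: dict[str, list[int]] | None = None,
) -> dict[str, list[MutationProposal]]:
    """Partition proposals into disjoint named groups G1..Gn.

    ``sequence_window`` merges proposals whose sequence separation from
    the previous member is at most ``window_len`` residues; ``explicit``
    takes a user partition and must cover every proposal.
    """
    if not proposals:
        raise DesignError("no proposals to group")
    ordered = sorted(proposals, key=lambda p: p.position)
    if method == "explicit":
        if partition is None:
            raise DesignError("explicit grouping requires a partition")
        covered = [pos for members in partition.values() for pos in members]
        if sorted(covered) != sorted(p.position for p in ordered):
            raise DesignError("explicit partition must cover every proposal exactly once")
        by_pos = {p.position: p for p in ordered}
        return {name: [by_pos[pos] for pos in sorted(members)]
                for name, members in partition.items()}
    if method != "sequence_window":
        raise DesignError(f"unknown grouping method {method!r}")

    groups: list[list[MutationProposal]] = [[ordered[0]]]
    for prev, cur in zip(ordered, ordered[1:]):
        if cur.position - prev.position <= window_len:
            groups[-1].append(cur)
        else:
            groups.append([cur])
    return {f"G{i + 1}": members for i, members in enumerate(groups)}


def enumerate_combinations(groups: dict[str, list[MutationProposal]]) -> dict[str, list[MutationProposal]]:
    """All non-empty unions of the groups, canonically named.

    With groups G1..Gn the names are K<sorted indices>, e.g. three groups
    give K1, K2, K3, K12, K13, K23, K123 (2^n − 1 combinations).
    """
    if not groups:
        raise DesignError("no groups to combine")
    names = sorted(groups, key=lambda g: int(g.lstrip("G")))
    combos: dict[str, list[MutationProposal]] = {}
    for r in range(1, len(names) + 1):
        for subset in itertools.combinations(range(1, len(names) + 1), r):
            label = "K" + "".join(str(i) for i in subset)
            members: list[MutationProposal] = []
            for i in subset:
                members.extend(groups[f"G{i}"])
            combos[label] = sorted(members, key=lambda p: p.position)
    return combos


@dataclass
class DesignSet:
    proposals: list[MutationProposal]
    groups: dict[str, list[MutationProposal]]
    combinations: dict[str, list[MutationProposal]]
    target_region: tuple[int, int] | None
    status: str = "ok"  # ok | no-candidates
    differential: DifferentialInterface | None = None

    def mutant_sequence(self, wild_type: str, combination: str, *, numbering_start: int = 1) -> str:
        """Apply one named combination to a wild-type sequence."""
        seq = list(wild_type)
        for p in self.combinations[combination]:
            idx = p.position - numbering_start
            if not 0 <= idx < len(seq):
                raise DesignError(f"position {p.position} outside sequence")
            if seq[idx] != p.wt_aa:
                raise DesignError(
                    f"wild type mismatch at {p.position}: sequence has "
                    f"{seq[idx]}, proposal expects {p.wt_aa}")
            seq[idx] = p.mutant_aa
        return "".join(seq)


def design_from_differential(
    model_1: ComplexModel,
    diff: DifferentialInterface,
    *,
    exposure_threshold: float = 0.2,
    require_exposed: bool = True,
    grouping_method: str = "sequence_window",
    window_len: int = 10,
    partition: dict[str, list[int]] | None = None,
) -> DesignSet:
    """Turn a differential interface into a grouped, enumerated design set.

    Every differential residue gets a rule-based proposal; the designed
    clash against the included partner and the exposure of the shared
    subunit alone are recorded on each proposal. Non-exposed positions are
    dropped when ``require_exposed`` (buried mutations risk destabilising
    the fold rather than the interface). Rule-less positions stay in the
    set flagged for manual substitution choice.
    """
    shared = model_1.shared_chain()
    proposals: list[MutationProposal] = []
    for rid in sorted(r for r in diff.residues):
        residue = shared.residue(rid)
        if residue is None or residue.one_letter == "X":
            continue
        p = propose_mutation(residue.seq_id, residue.one_letter)
        report = clash_score(model_1, p, diff.included_partner)
        p.clash_score_vs_included_partner = report.max_score
        p.exposed = exposure_check(model_1, p.position, p.mutant_aa,
                                   threshold=exposure_threshold)
        if require_exposed and not p.exposed:
            continue
        proposals.append(p)

    if not proposals:
        return DesignSet(proposals=[], groups={}, combinations={},
                         target_region=None, status="no-candidates",
                         differential=diff)
    groups = group_targets(proposals, grouping_method,
                           window_len=window_len, partition=partition)
    combos = enumerate_combinations(groups)
    region = (min(p.position for p in proposals), max(p.position for p in proposals))
    return DesignSet(proposals=proposals, groups=groups, combinations=combos,
                     target_region=region, status="ok", differential=diff)


# --- end-to-end pipeline --------------------------------------------------

def _load_sequence(value: str) -> str:
    """A literal one-letter sequence, or the first record of a FASTA file."""
    from pathlib import Path

    p = Path(value)
    if p.suffix.lower() in (".fasta", ".fa", ".faa") or (p.exists() and not value.isalpha()):
        from Bio import SeqIO
        rec = next(SeqIO.parse(str(p), "fasta"))
        return str(rec.seq).upper()
    return value.upper()


def _build_complex(cfg: dict, default_id: str) -> ComplexModel:
    from .align_superpose import global_align, identity_alignment
    from .model_graft import GraftedChain, assemble_complex, graft_model
    from .structio import extract_sequence, read_structure
    import copy

    template = read_structure(cfg["template"], cfg.get("format", "auto"))
    grafted: dict[str, GraftedChain] = {}
    roles: dict[str, str] = {}
    for cid, ccfg in cfg["chains"].items():
        roles[cid] = ccfg["role"]
        tmpl_chain = template.chain(ccfg.get("template_chain", cid))
        if "sequence" in ccfg:
            target = _load_sequence(ccfg["sequence"])
            tmpl_seq = extract_sequence(tmpl_chain)
            aln = global_align(target, tmpl_seq, seq_a_id=cid,
                               seq_b_id=tmpl_chain.chain_id)
            grafted[cid] = graft_model(
                target, tmpl_chain, aln,
                template_id=template.id, chain_id=cid,
                numbering_start=int(ccfg.get("numbering_start", 1)))
        else:
            # no target sequence: the template chain itself is the model
            chain = copy.deepcopy(tmpl_chain)
            chain.chain_id = cid
            for res in chain.residues:
                res.chain_id = cid
            grafted[cid] = GraftedChain(
                chain=chain, template_id=template.id,
                template_chain_id=tmpl_chain.chain_id, coverage=1.0)
    return assemble_complex(grafted, template, roles,
                            model_id=cfg.get("id", default_id))


def mutant_model(model: ComplexModel, design_set: DesignSet, combination: str) -> Structure:
    """Complex model with one named mutation combination applied.

    Mutated residues get the mutant identity and an extended-rotamer
    idealised side chain; all other coordinates are untouched.
    """
    import copy

    structure = model.structure.copy()
    shared = structure.chain(model.shared_chain_id)
    for p in design_set.combinations[combination]:
        residue = shared.residue(p.position)
        if residue is None:
            raise DesignError(f"position {p.position} not in model")
        if p.mutant_aa == residue.one_letter:
            continue
        extended = [(180.0,) * N_CHI[p.mutant_aa]]
        sidechain = grow_sidechain(residue, p.mutant_aa, extended)[0]
        residue.atoms = [a for a in residue.atoms
                         if a.name in ("N", "CA", "C", "O")] + copy.deepcopy(sidechain)
        residue.name = AA1_TO_3[p.mutant_aa]
    return structure


def run_design(config: dict | str) -> tuple[DesignSet, dict]:
    """Execute the full pipeline from a configuration mapping or YAML path.

    Stages: read templates → align/graft each subunit → assemble the two
    complex models (superposition + clash relief) → map the shared subunit
    → differential interface → optional unique-loop annotation → mutation
    proposals with clash and exposure checks → grouping → combination
    enumeration. Deterministic given the same config and inputs. Returns
    the design set and a JSON-serialisable run report; files (TSV, JSON,
    FASTA, PDB) are written when the config names an ``output_dir``.
    """
    import json
    from pathlib import Path

    from .interface import (annotate_differential, contact_map,
                            differential_interface, export_differential_tsv,
                            unique_regions)
    from .model_graft import map_shared_subunit
    from .structio import extract_sequence, write_structure

    if isinstance(config, (str, Path)):
        import yaml
        with open(config) as fh:
            config = yaml.safe_load(fh)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise DesignError(f"stage {name!r} failed: {exc}") from exc

    model_1 = stage("build_complex_1", _build_complex, config["complex_1"], "model_1")
    model_2 = stage("build_complex_2", _build_complex, config["complex_2"], "model_2")
    shared_map = stage("map_shared_subunit", map_shared_subunit, model_1, model_2)

    cutoff = float(config.get("cutoff", 4.5))
    margin = float(config.get("exclusion_margin", 1.5))
    included = config["included_partner"]
    excluded = list(config.get("excluded_partners", []))

    diff = stage("differential_interface", differential_interface,
                 model_1, model_2, shared_map, included, excluded,
                 cutoff=cutoff, exclusion_margin=margin)
    cmap_1 = stage("contact_map", contact_map, model_1.structure,
                   model_1.shared_chain_id, included, cutoff)

    unique = None
    if config.get("unique_msa"):
        ucfg = config["unique_msa"]
        unique = stage("unique_regions", unique_regions, ucfg["path"],
                       ucfg["reference"], int(ucfg.get("min_len", 3)))
        diff = stage("annotate_differential", annotate_differential,
                     diff, unique, cmap_1)

    dcfg = config.get("design", {})
    design_set = stage("design", design_from_differential, model_1, diff,
                       exposure_threshold=float(dcfg.get("exposure_threshold", 0.2)),
                       require_exposed=bool(dcfg.get("require_exposed", True)),
                       grouping_method=dcfg.get("grouping", "sequence_window"),
                       window_len=int(dcfg.get("window_len", 10)),
                       partition=dcfg.get("partition"))

    report = {
        "status": design_set.status,
        "parameters": {
            "cutoff": cutoff, "exclusion_margin": margin,
            "included_partner": included, "excluded_partners": excluded,
            "exposure_threshold": float(dcfg.get("exposure_threshold", 0.2)),
            "window_len": int(dcfg.get("window_len", 10)),
            "seed": config.get("seed", 0),
        },
        "provenance": {"model_1": model_1.provenance, "model_2": model_2.provenance},
        "differential_residues": sorted(diff.residues, key=str),
        "unresolved_residues": diff.unresolved,
        "unique_regions": unique.regions if unique else None,
        "proposals": [{
            "position": p.position, "wt": p.wt_aa, "mutant": p.mutant_aa,
            "rule": p.rule, "clash_score": p.clash_score_vs_included_partner,
            "exposed": p.exposed, "notes": p.notes,
        } for p in design_set.proposals],
        "groups": {g: [p.label for p in ms] for g, ms in design_set.groups.items()},
        "combinations": {k: [p.label for p in ms]
                         for k, ms in design_set.combinations.items()},
        "target_region": design_set.target_region,
    }

    out_dir = config.get("output_dir")
    if out_dir:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "design_report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        export_differential_tsv(diff, out / "differential_interface.tsv")
        write_structure(model_1.structure, out / "model_1.pdb", "pdb")
        write_structure(model_2.structure, out / "model_2.pdb", "pdb")
        if design_set.status == "ok":
            shared_seq = extract_sequence(model_1.shared_chain())
            start = model_1.shared_chain().residues[0].seq_id
            with open(out / "mutant_sequences.fasta", "w") as fh:
                for name in design_set.combinations:
                    seq = design_set.mutant_sequence(shared_seq, name,
                                                     numbering_start=start)
                    fh.write(f">{name}\n{seq}\n")
    return design_set, report
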