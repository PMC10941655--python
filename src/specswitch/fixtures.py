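"""Synthetic toy complexes with known ground-truth interfaces.

Fixture complexes are built from ideal helices with partner chains placed
analytically so that the partner contacts an exact, pre-declared residue
interval of the focal chain — the fixture analogue of one shared subunit
binding two alternative partners with partially overlapping footprints.
Ground truth (interface sets, differential sets) comes from the
construction, never from re-measuring, so recovery tests are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem import AA1_TO_3
from .structio import Atom, Chain, Residue, Structure

HELIX_RISE = 1.5        # Å per residue along the axis
HELIX_TWIST = 100.0     # degrees per residue
HELIX_RADIUS = 2.3      # CA radius, Å


class FixtureError(ValueError):
    pass


@dataclass
class PartnerSpec:
    partner_id: str
    contact_interval: tuple[int, int]  # half-open, author numbering on focal chain
    approach_distance: float = 4.0     # Å, min heavy-atom distance at the interface


@dataclass
class FixtureSpec:
    seed: int = 0
    n_res_focal: int = 60
    partner_specs: list[PartnerSpec] = field(default_factory=list)
    noise_sigma: float = 0.0
    focal_sequence: str | None = None  # default poly-alanine
    focal_chain_id: str = "A"

    def __post_init__(self) -> None:
        for p in self.partner_specs:
            s, e = p.contact_interval
            if not (1 <= s < e <= self.n_res_focal + 1):
                raise FixtureError(
                    f"interval {p.contact_interval} outside focal chain 1..{self.n_res_focal}")
            if p.approach_distance <= 0:
                raise FixtureError("approach_distance must be positive")


@dataclass
class FixtureTruth:
    """Construction-derived ground truth for a two-partner fixture."""

    interfaces: dict[str, set[int]]             # partner_id -> focal residue set
    contact_distance: dict[str, float]          # partner_id -> planted min distance
    planted_clash_pairs: list = field(default_factory=list)

    def differential(self, included: str, excluded) -> set[int]:
        if isinstance(excluded, str):
            excluded = [excluded]
        out = set(self.interfaces[included])
        for pid in excluded:
            out -= self.interfaces[pid]
        return out


def _helix_frame(i: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Point on the CA helix plus outward radial and tangent units."""
    theta = np.deg2rad(HELIX_TWIST * i)
    pos = np.array([HELIX_RADIUS * np.cos(theta), HELIX_RADIUS * np.sin(theta),
                    HELIX_RISE * i])
    radial = np.array([np.cos(theta), np.sin(theta), 0.0])
    tangent = np.array([-np.sin(theta), np.cos(theta), 0.0])
    return pos, radial, tangent


def make_helix(n_res: int, sequence: str | None = None, *,
               chain_id: str = "A", start: int = 1) -> Chain:
    """Ideal α-helix with backbone (N, CA, C, O) and CB atoms.

    CA atoms follow the canonical parametrisation (rise 1.5 Å, 100° twist,
    radius 2.3 Å); N/C sit on the same curve at ±0.5-residue phase, O and
    CB point radially outward. Fully deterministic.
    """
    if sequence is None:
        sequence = "A" * n_res
    if len(sequence) != n_res:
        raise FixtureError(f"sequence length {len(sequence)} != n_res {n_res}")

    residues = []
    for k in range(n_res):
        aa = sequence[k]
        ca, radial, _ = _helix_frame(k)
        n_pos, _, _ = _helix_frame(k - 0.35)
        c_pos, _, _ = _helix_frame(k + 0.35)
        # O points down the helix axis, not outward: keeps the fixture's
        # radial reach confined to CB so planted contact intervals stay sharp
        o_pos = c_pos - 1.23 * np.array([0.0, 0.0, 1.0])
        atoms = [
            Atom("N", "N", n_pos),
            Atom("CA", "C", ca),
            Atom("C", "C", c_pos),
            Atom("O", "O", o_pos),
        ]
        if aa != "G":
            cb = ca + radial * 1.45 + np.array([0.0, 0.0, 0.5])
            atoms.append(Atom("CB", "C", cb))
        residues.append(Residue(chain_id=chain_id, seq_id=start + k,
                                name=AA1_TO_3.get(aa, "UNK"), atoms=atoms))
    return Chain(chain_id=chain_id, residues=residues)


def _make_partner_comb(focal: Chain, spec: PartnerSpec) -> Chain:
    """Partner chain with one residue per focal residue of the interval.

    Each partner residue's CA sits on the outward radial ray through the
    matching focal CB at exactly ``approach_distance``; remaining atoms are
    placed tangentially or further out, so the planted minimum heavy-atom
    distance to focal residue i is exactly the approach distance, and
    distances to all other focal residues are several Å larger.
    """
    start, end = spec.contact_interval
    first_focal = focal.residues[0].seq_id
    z_hat = np.array([0.0, 0.0, 1.0])
    residues = []
    for j, rid in enumerate(range(start, end)):
        focal_res = focal.residues[rid - first_focal]
        cb = focal_res.atom("CB") or focal_res.atom("CA")
        i = rid - first_focal
        _, radial, _ = _helix_frame(i)
        ca = cb.coords + radial * spec.approach_distance
        # N/C offset along z only (no tangential spread), so the comb's
        # reach toward angularly adjacent focal residues stays minimal
        atoms = [
            Atom("N", "N", ca + z_hat * 0.9),
            Atom("CA", "C", ca),
            Atom("C", "C", ca - z_hat * 0.9),
            Atom("O", "O", ca - z_hat * 0.9 + radial * 1.23),
            Atom("CB", "C", ca + radial * 1.5),
        ]
        residues.append(Residue(chain_id=spec.partner_id, seq_id=j + 1,
                                name="ALA", atoms=atoms))
    return Chain(chain_id=spec.partner_id, residues=residues)


def make_two_partner_fixture(spec: FixtureSpec) -> tuple[Structure, Structure, FixtureTruth]:
    """Two single-partner complexes sharing an identical focal chain.

    ``complex_1`` holds the focal helix with partner 1, ``complex_2`` the
    same focal helix with partner 2; each partner contacts exactly its
    declared interval at its approach distance. Optional Gaussian noise
    (``noise_sigma``) is applied per complex with sub-seeds of ``seed``.
    """
    if len(spec.partner_specs) != 2:
        raise FixtureError("two-partner fixture requires exactly 2 partner specs")
    seq = spec.focal_sequence or "A" * spec.n_res_focal

    truth = FixtureTruth(
        interfaces={p.partner_id: set(range(*p.contact_interval))
                    for p in spec.partner_specs},
        contact_distance={p.partner_id: p.approach_distance
                          for p in spec.partner_specs},
    )
    complexes = []
    for idx, pspec in enumerate(spec.partner_specs, start=1):
        focal = make_helix(spec.n_res_focal, seq, chain_id=spec.focal_chain_id)
        partner = _make_partner_comb(focal, pspec)
        structure = Structure(id=f"fixture_complex_{idx}", chains=[focal, partner])
        if spec.noise_sigma > 0:
            structure = perturb(structure, seed=spec.seed * 2 + idx,
                                sigma=spec.noise_sigma)
        complexes.append(structure)
    return complexes[0], complexes[1], truth


def perturb(structure: Structure, seed: int, sigma: float) -> Structure:
    """Seeded i.i.d. Gaussian displacement of every atom (σ in Å)."""
    if sigma < 0:
        raise FixtureError("sigma must be non-negative")
    out = structure.copy()
    if sigma == 0:
        return out
    rng = np.random.default_rng(seed)
    for chain in out.chains:
        for res in chain.residues:
            for atom in res.atoms:
                atom.coords = atom.coords + rng.normal(0.0, sigma, size=3)
    return out
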