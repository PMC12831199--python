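"""Per-residue secondary structure from backbone hydrogen bonding.

The assigner is a compact re-implementation of the Kabsch–Sander
dictionary (DSSP) reduced to the three-class alphabet the motif filter
needs — ``H`` (α/3₁₀/π helix), ``E`` (strand or isolated β-bridge) and
``C`` (everything else, including turns and bends).

Backbone amide hydrogens are reconstructed geometrically (1.01 Å from N,
anti to the preceding carbonyl), the electrostatic hydrogen-bond energy

    E = 0.084 · 332 · (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)  kcal/mol

is evaluated for every candidate donor/acceptor pair, and a bond is
accepted when E < −0.5 kcal/mol.  Helices follow from pairs of
consecutive n-turns (n = 3, 4, 5); strands from parallel/antiparallel
bridge patterns.  Cα–Cα gaps wider than 4.5 Å are treated as chain
breaks: no hydrogen is inferred across the break and turn patterns may
not span it (long-range bridges between the fragments remain legal, as
they would between separate strands).

Assignment depends only on inter-atomic distances, so any rigid motion
of the input leaves the labels unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure_io import Atom, Chain, Residue, StructureModel

#: 0.084 · 332 — partial charges (0.42 e, 0.20 e) times the electrostatic
#: conversion factor, kcal·Å/mol.
HB_ENERGY_FACTOR = 27.888

#: Acceptance threshold for the electrostatic energy, kcal/mol.
HB_ENERGY_CUTOFF = -0.5

#: Energies below this are clamped (near-clashing geometries).
HB_ENERGY_FLOOR = -9.9

#: N–H bond length used when reconstructing amide hydrogens, Å.
NH_BOND_LENGTH = 1.01

#: Consecutive Cα–Cα distance above which the chain is considered broken, Å.
CHAIN_BREAK_CA_DISTANCE = 4.5

#: Minimal separation (in chain order) between H-bond partners.
MIN_SEQUENCE_SEPARATION = 2

METHOD_TAG = "ks-hbond/3-class (turns+bends→C)"

#: 8-class DSSP alphabet → 3-class filter alphabet.
SIMPLIFY = {
    "H": "H", "G": "H", "I": "H",
    "E": "E", "B": "E",
    "T": "C", "S": "C", "C": "C", "-": "C", " ": "C",
}


@dataclass(frozen=True)
class HBond:
    """Accepted backbone hydrogen bond N–H(donor) ··· O=C(acceptor)."""

    donor: int       # residue index within the chain (0-based)
    acceptor: int
    energy: float    # kcal/mol, < HB_ENERGY_CUTOFF by construction


@dataclass
class SSAnnotation:
    """Three-class labels per chain, aligned with ``chain.residues``."""

    model_id: str
    labels: dict[str, str] = field(default_factory=dict)
    method: str = METHOD_TAG

    def window(self, chain: Chain, start_author_number: int, length: int = 5) -> str | None:
        """Labels covering ``length`` consecutive residues starting at an
        author number; ``None`` if the window is absent or broken."""
        chain_labels = self.labels.get(chain.chain_id)
        if chain_labels is None:
            return None
        index = {r.author_number: i for i, r in enumerate(chain.residues)}
        idx = [index.get(start_author_number + k) for k in range(length)]
        if any(i is None for i in idx):
            return None
        if idx != list(range(idx[0], idx[0] + length)):
            return None
        return "".join(chain_labels[i] for i in idx)


def simplify_label(raw: str) -> str:
    """Map an 8-class DSSP label to the 3-class filter alphabet."""
    try:
        return SIMPLIFY[raw]
    except KeyError:
        raise ValueError(f"unknown secondary-structure symbol {raw!r}") from None


def _ca_positions(chain: Chain) -> list[np.ndarray | None]:
    return [r.atom("CA").position if r.atom("CA") else None for r in chain.residues]


def chain_breaks(chain: Chain) -> set[int]:
    """Indices i such that the peptide bond i → i+1 is broken/absent."""
    breaks: set[int] = set()
    cas = _ca_positions(chain)
    for i in range(len(chain.residues) - 1):
        if cas[i] is None or cas[i + 1] is None:
            breaks.add(i)
        elif np.linalg.norm(cas[i + 1] - cas[i]) > CHAIN_BREAK_CA_DISTANCE:
            breaks.add(i)
    return breaks


def place_amide_hydrogens(chain: Chain) -> Chain:
    """Add a backbone ``H`` atom to every eligible residue, in place.

    The hydrogen sits on the nitrogen, 1.01 Å along the direction
    opposite the preceding carbonyl C→O vector (the DSSP convention).
    Prolines, chain-initial residues, residues across a chain break and
    residues with incomplete reference atoms get no hydrogen.
    """
    breaks = chain_breaks(chain)
    for i, res in enumerate(chain.residues):
        if i == 0 or res.name3.upper() == "PRO" or (i - 1) in breaks:
            continue
        if res.atom("H") is not None:
            continue
        n = res.atom("N")
        prev = chain.residues[i - 1]
        c_prev, o_prev = prev.atom("C"), prev.atom("O")
        if n is None or c_prev is None or o_prev is None:
            continue
        co = o_prev.position - c_prev.position
        norm = np.linalg.norm(co)
        if norm == 0:
            continue
        h_pos = n.position - NH_BOND_LENGTH * co / norm
        res.atoms.append(Atom(name="H", element="H", position=h_pos))
    return chain


def hydrogen_bond_energy(donor: Residue, acceptor: Residue) -> float | None:
    """Kabsch–Sander electrostatic energy of a putative N–H···O=C bond.

    Returns ``None`` ("not evaluable") when a required atom is missing;
    energies below −9.9 kcal/mol are clamped.
    """
    n, h = donor.atom("N"), donor.atom("H")
    c, o = acceptor.atom("C"), acceptor.atom("O")
    if n is None or h is None or c is None or o is None:
        return None
    r_on = np.linalg.norm(o.position - n.position)
    r_ch = np.linalg.norm(c.position - h.position)
    r_oh = np.linalg.norm(o.position - h.position)
    r_cn = np.linalg.norm(c.position - n.position)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:  # clashing geometry
        return HB_ENERGY_FLOOR
    energy = HB_ENERGY_FACTOR * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
    return float(max(energy, HB_ENERGY_FLOOR))


def find_hbonds(chain: Chain) -> list[HBond]:
    """All accepted backbone H-bonds within one chain.

    Donor and acceptor must be separated by at least two positions in
    chain order.  Residues lacking backbone atoms are skipped.
    """
    place_amide_hydrogens(chain)
    bonds: list[HBond] = []
    n_res = len(chain.residues)
    # Cheap spatial pre-filter on Cα distance: the O···N distance of an
    # accepted bond is < ~5.2 Å, so Cα pairs beyond 9 Å cannot bond.
    cas = _ca_positions(chain)
    for d in range(n_res):
        donor = chain.residues[d]
        if donor.atom("H") is None or donor.atom("N") is None:
            continue
        for a in range(n_res):
            if abs(d - a) < MIN_SEQUENCE_SEPARATION:
                continue
            if cas[d] is not None and cas[a] is not None:
                if np.linalg.norm(cas[d] - cas[a]) > 9.0:
                    continue
            energy = hydrogen_bond_energy(donor, chain.residues[a])
            if energy is not None and energy < HB_ENERGY_CUTOFF:
                bonds.append(HBond(donor=d, acceptor=a, energy=energy))
    return bonds


def _labels_for_chain(chain: Chain) -> str:
    n_res = len(chain.residues)
    if n_res < 3:
        return "C" * n_res
    breaks = chain_breaks(chain)
    bonds = find_hbonds(chain)
    bonded = {(b.donor, b.acceptor) for b in bonds}

    def hb(donor: int, acceptor: int) -> bool:
        return (donor, acceptor) in bonded

    def contiguous(i: int, j: int) -> bool:
        return not any(k in breaks for k in range(min(i, j), max(i, j)))

    # n-turn at i: H-bond from NH(i+n) to CO(i), span unbroken.
    turns: dict[int, set[int]] = {3: set(), 4: set(), 5: set()}
    for n in (3, 4, 5):
        for i in range(n_res - n):
            if hb(i + n, i) and contiguous(i, i + n):
                turns[n].add(i)

    helix: set[int] = set()
    for n in (4, 3, 5):  # α first; all map to 'H' anyway
        for i in range(1, n_res - n):
            if i in turns[n] and (i - 1) in turns[n]:
                helix.update(range(i, i + n))

    # Bridge(i, j) for non-overlapping triples (i−1, i, i+1), (j−1, j, j+1).
    bridge: set[int] = set()
    for i in range(1, n_res - 1):
        for j in range(i + 3, n_res - 1):
            parallel = (hb(j, i - 1) and hb(i + 1, j)) or (hb(i, j - 1) and hb(j + 1, i))
            antiparallel = (hb(j, i) and hb(i, j)) or (hb(j + 1, i - 1) and hb(i + 1, j - 1))
            if parallel or antiparallel:
                bridge.add(i)
                bridge.add(j)
    # Residues are marked 'E' directly: isolated bridges ('B' in the
    # 8-class alphabet) simplify to 'E' anyway.

    out = []
    for i in range(n_res):
        if i in helix:
            out.append("H")
        elif i in bridge:
            out.append("E")
        else:
            out.append("C")
    return "".join(out)


def assign_secondary_structure(model: StructureModel) -> SSAnnotation:
    """Three-class secondary structure for every chain of a model.

    Deterministic for fixed input; chains shorter than three residues
    are labelled all-coil.
    """
    ann = SSAnnotation(model_id=model.model_id)
    for chain in model.chains:
        ann.labels[chain.chain_id] = _labels_for_chain(chain)
    return ann
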