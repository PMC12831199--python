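"""Ground-truth synthetic inputs for every pipeline stage.

This module fabricates, from ideal covalent geometry and a seed, all
four input families the search pipeline consumes — so the whole funnel
can be exercised and validated with no downloads:

* protein backbones built residue-by-residue with the natural extension
  reference frame (NeRF) from canonical bond lengths/angles and named
  dihedral presets (α-helix, β-strand, coil);
* toy proteomes with motifs planted in known helix/strand/coil context;
* protein-localization tables;
* binder / non-binder two-chain complex bundles with a mock SHD1
  receptor, constructed PAE matrices and assigned ipTM scores.

Everything is a pure function of (parameters, seed): the same call with
the same seed writes byte-identical files.

The structures are deliberately idealised: side chains beyond Cβ are
reduced to short "stub" extensions with correct atom names (enough for
heavy-atom contact counting and for the Tyr-OH / Asp-carboxylate
orientation test), and the mock receptor is a five-helix arrangement
whose residue numbering matches full-length Spa2 so that the groove
definition {48, 51, 59, 98, 101, 109; K97; D62; D112} resolves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .geometry import place_atom, rotation_matrix
from .motif_scan import (
    MOTIF_LENGTH,
    MotifPattern,
    RELAXED_FRM,
    compile_pattern,
    scan_sequence,
)
from .secstruct import assign_secondary_structure
from .structure_io import (
    Atom,
    Chain,
    ONE_TO_THREE,
    Residue,
    StructureModel,
    write_structure,
)


# --------------------------------------------------------------------------
# backbone geometry
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BackboneGeometry:
    """Canonical covalent geometry for backbone construction (Å, degrees)."""

    n_ca: float = 1.458
    ca_c: float = 1.525
    c_n: float = 1.329
    c_o: float = 1.231
    ca_cb: float = 1.521
    ang_n_ca_c: float = 111.0
    ang_ca_c_n: float = 116.2
    ang_c_n_ca: float = 121.7
    ang_ca_c_o: float = 120.8
    ang_c_ca_cb: float = 109.5
    dih_n_c_ca_cb: float = 122.6   # improper fixing Cβ chirality (L-amino acids)
    omega: float = 180.0

    def __post_init__(self) -> None:
        for name in ("n_ca", "ca_c", "c_n", "c_o", "ca_cb"):
            if getattr(self, name) <= 0:
                raise ValueError(f"bond length {name} must be positive")


DEFAULT_GEOMETRY = BackboneGeometry()

#: Named dihedral presets (φ, ψ).
HELIX_DIHEDRALS = (-57.0, -47.0)
STRAND_DIHEDRALS = (-139.0, 135.0)

#: Coil sampling window: avoids the helix basin (ψ ≈ −47°) and the
#: strand/polyproline-II basin (ψ ≳ 100°), so coil stretches assign 'C'.
COIL_PHI_RANGE = (-100.0, -70.0)
COIL_PSI_RANGE = (10.0, 60.0)


def helix_dihedrals(n: int) -> list[tuple[float, float]]:
    return [HELIX_DIHEDRALS] * n


def strand_dihedrals(n: int) -> list[tuple[float, float]]:
    return [STRAND_DIHEDRALS] * n


def coil_dihedrals(n: int, rng: np.random.Generator) -> list[tuple[float, float]]:
    phi = rng.uniform(*COIL_PHI_RANGE, size=n)
    psi = rng.uniform(*COIL_PSI_RANGE, size=n)
    return list(zip(phi.tolist(), psi.tolist()))


def build_backbone(
    sequence: str,
    dihedrals: list[tuple[float, float]],
    geometry: BackboneGeometry = DEFAULT_GEOMETRY,
    chain_id: str = "A",
    model_id: str = "synthetic",
    first_number: int = 1,
    sidechain_stubs: bool = False,
) -> StructureModel:
    """Build a chain from a sequence and per-residue (φ, ψ) dihedrals.

    Backbone N/CA/C/O are placed by NeRF extension with ω = 180°; the
    carbonyl O lies in the peptide plane (dihedral N–CA–C–O = ψ − 180°);
    Cβ is added by tetrahedral construction for every non-glycine.
    """
    if len(sequence) != len(dihedrals):
        raise ValueError(
            f"sequence length {len(sequence)} != dihedral count {len(dihedrals)}"
        )
    if not sequence:
        raise ValueError("empty sequence")
    g = geometry
    n_pos = np.array([0.0, 0.0, 0.0])
    ca_pos = np.array([g.n_ca, 0.0, 0.0])
    theta = np.deg2rad(g.ang_n_ca_c)
    c_pos = ca_pos + g.ca_c * np.array([-np.cos(theta), np.sin(theta), 0.0])

    backbone: list[dict[str, np.ndarray]] = [{"N": n_pos, "CA": ca_pos, "C": c_pos}]
    for i in range(1, len(sequence)):
        prev = backbone[-1]
        psi_prev = dihedrals[i - 1][1]
        n_i = place_atom(prev["N"], prev["CA"], prev["C"], g.c_n, g.ang_ca_c_n, psi_prev)
        ca_i = place_atom(prev["CA"], prev["C"], n_i, g.n_ca, g.ang_c_n_ca, g.omega)
        phi_i = dihedrals[i][0]
        c_i = place_atom(prev["C"], n_i, ca_i, g.ca_c, g.ang_n_ca_c, phi_i)
        backbone.append({"N": n_i, "CA": ca_i, "C": c_i})

    residues: list[Residue] = []
    for i, aa in enumerate(sequence.upper()):
        name3 = ONE_TO_THREE.get(aa)
        if name3 is None:
            raise ValueError(f"non-standard residue {aa!r} at position {i + 1}")
        bb = backbone[i]
        psi_i = dihedrals[i][1]
        o_pos = place_atom(bb["N"], bb["CA"], bb["C"], g.c_o, g.ang_ca_c_o, psi_i - 180.0)
        atoms = [
            Atom("N", "N", bb["N"]),
            Atom("CA", "C", bb["CA"]),
            Atom("C", "C", bb["C"]),
            Atom("O", "O", o_pos),
        ]
        if aa != "G":
            cb = place_atom(bb["N"], bb["C"], bb["CA"], g.ca_cb, g.ang_c_ca_cb,
                            g.dih_n_c_ca_cb)
            atoms.append(Atom("CB", "C", cb))
        residues.append(Residue(name3=name3, author_number=first_number + i, atoms=atoms))

    model = StructureModel(
        model_id=model_id,
        chains=[Chain(chain_id=chain_id, residues=residues)],
        source_format="pdb",
        metadata={"generator": "slimscan.synthetic_data", "geometry": "ideal"},
    )
    if sidechain_stubs:
        for res in residues:
            add_sidechain_stub(res, g)
    return model


#: Stub side-chain topologies: (atom, element, parent triple, length Å,
#: angle °, torsion °).  Reference frame triples name previously placed
#: atoms of the same residue.  Chi1 is fixed at −65° (gauche−); the
#: tyrosine ring is collapsed onto its para axis (CB→CG→CZ→OH nearly
#: collinear in real tyrosine), which preserves the OH–CB distance that
#: the orientation classifier measures.
_STUB_TOPOLOGY: dict[str, list[tuple[str, str, tuple[str, str, str], float, float, float]]] = {
    "ASP": [
        ("CG", "C", ("N", "CA", "CB"), 1.52, 113.8, -65.0),
        ("OD1", "O", ("CA", "CB", "CG"), 1.25, 118.3, -20.0),
        ("OD2", "O", ("CA", "CB", "CG"), 1.25, 118.3, 160.0),
    ],
    "GLU": [
        ("CG", "C", ("N", "CA", "CB"), 1.52, 113.8, -65.0),
        ("CD", "C", ("CA", "CB", "CG"), 1.52, 113.8, 180.0),
        ("OE1", "O", ("CB", "CG", "CD"), 1.25, 118.3, -20.0),
        ("OE2", "O", ("CB", "CG", "CD"), 1.25, 118.3, 160.0),
    ],
    "LEU": [
        ("CG", "C", ("N", "CA", "CB"), 1.53, 116.3, -65.0),
        ("CD1", "C", ("CA", "CB", "CG"), 1.52, 110.7, 65.0),
        ("CD2", "C", ("CA", "CB", "CG"), 1.52, 110.7, -175.0),
    ],
    "ILE": [
        ("CG1", "C", ("N", "CA", "CB"), 1.53, 110.4, -65.0),
        ("CG2", "C", ("N", "CA", "CB"), 1.53, 110.5, 170.0),
        ("CD1", "C", ("CA", "CB", "CG1"), 1.51, 113.9, 180.0),
    ],
    "VAL": [
        ("CG1", "C", ("N", "CA", "CB"), 1.53, 110.5, -65.0),
        ("CG2", "C", ("N", "CA", "CB"), 1.53, 110.5, 175.0),
    ],
    "LYS": [
        ("CG", "C", ("N", "CA", "CB"), 1.52, 113.8, -65.0),
        ("CD", "C", ("CA", "CB", "CG"), 1.52, 111.3, 180.0),
        ("CE", "C", ("CB", "CG", "CD"), 1.52, 111.3, 180.0),
        ("NZ", "N", ("CG", "CD", "CE"), 1.49, 111.9, 180.0),
    ],
    "SER": [("OG", "O", ("N", "CA", "CB"), 1.42, 110.8, -65.0)],
    "THR": [("OG1", "O", ("N", "CA", "CB"), 1.43, 109.6, -65.0)],
    "TYR": [
        ("CG", "C", ("N", "CA", "CB"), 1.51, 113.9, -65.0),
        ("CZ", "C", ("CA", "CB", "CG"), 2.79, 180.0, 0.0),
        ("OH", "O", ("CB", "CG", "CZ"), 1.38, 180.0, 0.0),
    ],
    "PHE": [
        ("CG", "C", ("N", "CA", "CB"), 1.51, 113.9, -65.0),
        ("CZ", "C", ("CA", "CB", "CG"), 2.79, 180.0, 0.0),
    ],
}


def add_sidechain_stub(res: Residue, geometry: BackboneGeometry = DEFAULT_GEOMETRY) -> None:
    """Extend a residue with idealised stub side-chain atoms (synthetic).

    Residues without a stub topology keep backbone + Cβ only.
    """
    topo = _STUB_TOPOLOGY.get(res.name3.upper())
    if topo is None or res.atom("CB") is None:
        return
    for name, element, (pa, pb, pc), length, angle, torsion in topo:
        if res.atom(name) is not None:
            continue
        a, b, c = (res.atom(x) for x in (pa, pb, pc))
        if a is None or b is None or c is None:
            continue
        # A 180° bond angle makes the NeRF frame degenerate; extend
        # collinearly instead.
        if abs(angle - 180.0) < 1e-9:
            direction = c.position - b.position
            direction = direction / np.linalg.norm(direction)
            pos = c.position + length * direction
        else:
            pos = place_atom(a.position, b.position, c.position, length, angle, torsion)
        res.atoms.append(Atom(name, element, pos))


def transform_model(model: StructureModel, rotation: np.ndarray, translation: np.ndarray) -> StructureModel:
    """Apply a rigid motion x → R·x + t to every atom, in place."""
    rotation = np.asarray(rotation, float)
    translation = np.asarray(translation, float)
    for chain in model.chains:
        for res in chain.residues:
            for atom in res.atoms:
                atom.position = rotation @ atom.position + translation
    return model


# --------------------------------------------------------------------------
# mock SHD1 receptor
# --------------------------------------------------------------------------

#: Half-separation of the two groove wall helices (Å from the groove
#: axis), sized so the docked motif helix plus stub side chains fit.
GROOVE_HALF_WIDTH = 7.5

#: Mock receptor layout: (first residue number, last, x-y centre,
#: direction along ±z, roll anchor residue whose Cβ faces the groove).
_RECEPTOR_HELICES: tuple[tuple[int, int, tuple[float, float], int, int | None], ...] = (
    (5, 30, (-5.0, -12.0), +1, None),
    (40, 66, (-GROOVE_HALF_WIDTH, 0.0), +1, 51),
    (70, 90, (5.0, -12.0), -1, None),
    (94, 116, (GROOVE_HALF_WIDTH, 0.0), -1, 101),
    (120, 140, (0.0, -16.0), +1, None),
)

#: Residue identities of the mock receptor, by full-length Spa2 number.
_RECEPTOR_SPECIALS = {
    48: "L", 51: "L", 59: "L", 98: "L", 101: "L", 109: "L",
    97: "K", 62: "D", 112: "D",
}


def _helix_axis(chain: Chain) -> tuple[np.ndarray, np.ndarray]:
    cas = np.array([r.atom("CA").position for r in chain.residues])
    centroid = cas.mean(axis=0)
    # principal direction of the Cα cloud = helix axis
    _, _, vt = np.linalg.svd(cas - centroid)
    axis = vt[0]
    if np.dot(cas[-1] - cas[0], axis) < 0:
        axis = -axis
    return centroid, axis


def _align_helix(model: StructureModel, direction: int) -> StructureModel:
    """Rotate a built helix so its axis runs along ±z, centred at origin."""
    chain = model.chains[0]
    centroid, axis = _helix_axis(chain)
    target = np.array([0.0, 0.0, float(direction)])
    v = np.cross(axis, target)
    s = np.linalg.norm(v)
    c = float(np.dot(axis, target))
    if s < 1e-12:
        rot = np.eye(3) if c > 0 else rotation_matrix(np.array([1.0, 0, 0]), 180.0)
    else:
        rot = rotation_matrix(v, float(np.degrees(np.arctan2(s, c))))
    transform_model(model, rot, -rot @ centroid)
    return model


def _roll_to_face(model: StructureModel, residue_number: int, face: np.ndarray) -> None:
    """Roll a z-aligned helix so the Cβ of one residue points along ``face``."""
    chain = model.chains[0]
    res = chain.residue_by_number(residue_number)
    radial = res.atom("CB").position - res.atom("CA").position
    radial = np.array([radial[0], radial[1], 0.0])
    if np.linalg.norm(radial) < 1e-9:
        return
    current = np.arctan2(radial[1], radial[0])
    wanted = np.arctan2(face[1], face[0])
    transform_model(
        model, rotation_matrix(np.array([0.0, 0.0, 1.0]), np.degrees(wanted - current)),
        np.zeros(3),
    )


def build_mock_shd1(geometry: BackboneGeometry = DEFAULT_GEOMETRY) -> Chain:
    """Deterministic mock SHD1 receptor chain ('A', Spa2 numbering).

    Five ideal helices; the two "wall" helices flank a groove along the
    z axis, rolled so the leucine patch {48, 51, 59} / {98, 101, 109}
    and the acceptors D62 / D112 face the groove interior.
    """
    residues: list[Residue] = []
    for start, end, (x, y), direction, anchor in _RECEPTOR_HELICES:
        length = end - start + 1
        seq = "".join(_RECEPTOR_SPECIALS.get(num, "A") for num in range(start, end + 1))
        helix = build_backbone(
            seq, helix_dihedrals(length), geometry,
            first_number=start, sidechain_stubs=False,
        )
        _align_helix(helix, direction)
        if anchor is not None:
            _roll_to_face(helix, anchor, np.array([-x, -y, 0.0]))
        transform_model(helix, np.eye(3), np.array([x, y, 0.0]))
        for res in helix.chains[0].residues:
            add_sidechain_stub(res, geometry)
        residues.extend(helix.chains[0].residues)
    return Chain(chain_id="A", residues=residues)


# --------------------------------------------------------------------------
# synthetic complexes
# --------------------------------------------------------------------------

#: Residue letters never drawn for flanking sequence: Y would allow
#: accidental motif windows, G lacks a Cβ, P breaks helix hydrogen
#: bonding in the assigner.
_FLANK_ALPHABET = "ACDEFHIKLMNQRSTVW"

LIGAND_LENGTH = 21
LIGAND_MOTIF_START = 9  # author number of motif position −2 on the ligand


@dataclass
class ComplexTruth:
    """Designed properties of one synthetic prediction bundle."""

    candidate_id: str
    binder: bool
    orientation: str | None
    failure_stage: int | None
    iptm: float
    motif_start: int = LIGAND_MOTIF_START
    motif_residues: str = ""
    ligand_mode: str = "docked"   # docked | separated | extended


def _random_motif(pattern: MotifPattern, rng: np.random.Generator,
                  force: dict[int, str] | None = None) -> str:
    letters = []
    for label, allowed in zip(pattern.labels, pattern.positions):
        if force and label in force:
            letters.append(force[label])
        else:
            letters.append(sorted(allowed)[rng.integers(len(allowed))])
    return "".join(letters)


def _ligand_sequence(motif: str, rng: np.random.Generator) -> str:
    flank = lambda n: "".join(
        _FLANK_ALPHABET[rng.integers(len(_FLANK_ALPHABET))] for _ in range(n)
    )
    pre = LIGAND_MOTIF_START - 1
    post = LIGAND_LENGTH - pre - MOTIF_LENGTH
    return flank(pre) + motif + flank(post)


#: Wall-helix residue ranges used for the docking clash check.
_WALL_RANGES = ((40, 66), (94, 116))


def _place_ligand_in_groove(
    ligand_model: StructureModel,
    receptor: Chain,
    flipped: bool,
    geometry: BackboneGeometry,
) -> StructureModel:
    """Dock the ligand helix into the mock groove.

    The helix axis is aligned with the groove (±z; flipped reverses
    the direction), then a deterministic rigid-body grid search over
    roll and small translations picks the pose that (a) places the
    Tyr(+2) hydroxyl within hydrogen-bond distance of the target
    aspartate carboxylate (D112 canonical, D62 flipped) and closer to
    it than to the other aspartate, and (b) stays as clash-free as
    possible against the groove walls.
    """
    from scipy.spatial.distance import cdist

    direction = -1 if flipped else +1
    _align_helix(ligand_model, direction)
    chain = ligand_model.chains[0]

    def carboxylate(full_number: int) -> np.ndarray:
        res = receptor.residue_by_number(full_number)
        return np.array([res.atom(n).position for n in ("OD1", "OD2")])

    target_os = carboxylate(62 if flipped else 112)
    other_os = carboxylate(112 if flipped else 62)
    wall_atoms = np.array([
        a.position
        for r in receptor.residues
        if any(lo <= r.author_number <= hi for lo, hi in _WALL_RANGES)
        for a in r.heavy_atoms()
    ])
    lig_atoms0 = np.array([
        a.position for r in chain.residues for a in r.heavy_atoms()
    ])
    oh0 = chain.residue_by_number(LIGAND_MOTIF_START + 4).atom("OH").position
    target_z = float(target_os[:, 2].mean())

    best = None
    z_axis = np.array([0.0, 0.0, 1.0])
    for roll in range(0, 360, 10):
        rot = rotation_matrix(z_axis, float(roll))
        oh1 = rot @ oh0
        lig1 = lig_atoms0 @ rot.T
        for dx in (-2.0, -1.0, 0.0, 1.0, 2.0):
            for dy in (-1.5, 0.0, 1.5):
                for dz in (-1.0, 0.0, 1.0):
                    t = np.array([dx, dy, target_z - oh1[2] + dz])
                    oh = oh1 + t
                    d_target = float(np.linalg.norm(target_os - oh, axis=1).min())
                    if d_target > 3.3:
                        continue
                    d_other = float(np.linalg.norm(other_os - oh, axis=1).min())
                    if d_other <= d_target:
                        continue
                    dmin = float(cdist(lig1 + t, wall_atoms).min())
                    clash = max(0.0, 2.8 - dmin)
                    score = (round(clash, 2), round(abs(d_target - 2.9), 2))
                    if best is None or score < best[0]:
                        best = (score, rot, t)
    if best is None:
        raise RuntimeError(
            "groove docking failed: no pose satisfies the hydrogen-bond constraint"
        )
    _, rot, t = best
    transform_model(ligand_model, rot, t)
    return ligand_model


def _synthesize_pae(n_receptor: int, n_ligand: int, cross_mean: float,
                    rng: np.random.Generator) -> np.ndarray:
    n = n_receptor + n_ligand
    pae = np.clip(rng.normal(2.0, 0.5, size=(n, n)), 0.2, 31.75)
    cross = np.clip(rng.normal(cross_mean, 1.0, size=(n_receptor, n_ligand)), 0.3, 31.75)
    cross_t = np.clip(rng.normal(cross_mean, 1.0, size=(n_ligand, n_receptor)), 0.3, 31.75)
    pae[:n_receptor, n_receptor:] = cross
    pae[n_receptor:, :n_receptor] = cross_t
    np.fill_diagonal(pae, 0.1)
    return np.round(pae, 2)


def generate_synthetic_complex(
    out_dir: str | Path,
    candidate_id: str,
    binder: bool,
    seed: int,
    orientation: str = "canonical_D112",
    failure_stage: int | None = None,
    iptm: float | None = None,
    reference_iptm: float = 0.60,
    motif_residues: str | None = None,
    pattern_spec: str = RELAXED_FRM,
    geometry: BackboneGeometry = DEFAULT_GEOMETRY,
) -> ComplexTruth:
    """Write one prediction bundle (model.pdb, pae.json, summary.json).

    Binders dock the motif helix into the mock groove with low
    cross-chain PAE and an ipTM at or above the reference; non-binders
    violate exactly their designed failure criterion:

    * ``failure_stage=4`` with even seeds → chains separated by 100 Å,
      odd seeds → ligand built extended (not helical); both can also be
      forced via ``failure_stage=4`` plus ``orientation``-independent
      ``ligand_mode`` selection below;
    * ``failure_stage=5`` → correct geometry, ipTM below the reference.
    """
    if binder and failure_stage is not None:
        raise ValueError("a binder cannot carry a designed failure stage")
    if not binder and failure_stage not in (4, 5):
        raise ValueError("non-binder bundles must fail at stage 4 or 5")
    if orientation not in ("canonical_D112", "flipped_D62"):
        raise ValueError(f"unknown orientation {orientation!r}")

    rng = np.random.default_rng(seed)
    pattern = compile_pattern(pattern_spec)
    motif = motif_residues or _random_motif(pattern, rng)
    if motif[-1] != "Y":
        raise ValueError("orientation placement requires Tyr at position +2")
    seq = _ligand_sequence(motif, rng)

    receptor = build_mock_shd1(geometry)

    ligand_mode = "docked"
    if not binder and failure_stage == 4:
        ligand_mode = "separated" if seed % 2 == 0 else "extended"

    if ligand_mode == "extended":
        ligand = build_backbone(seq, strand_dihedrals(len(seq)), geometry,
                                chain_id="B", sidechain_stubs=True)
        _align_helix(ligand, +1)
        # centre the motif window on the groove axis
        chain = ligand.chains[0]
        motif_cas = np.array([
            chain.residue_by_number(LIGAND_MOTIF_START + k).atom("CA").position
            for k in range(MOTIF_LENGTH)
        ])
        transform_model(ligand, np.eye(3), -motif_cas.mean(axis=0))
    else:
        ligand = build_backbone(seq, helix_dihedrals(len(seq)), geometry,
                                chain_id="B", sidechain_stubs=True)
        _place_ligand_in_groove(ligand, receptor, orientation == "flipped_D62", geometry)
        if ligand_mode == "separated":
            transform_model(ligand, np.eye(3), np.array([100.0, 0.0, 0.0]))

    ligand_chain = ligand.chains[0]
    model = StructureModel(
        model_id=candidate_id,
        chains=[receptor, ligand_chain],
        source_format="pdb",
        metadata={"generator": "slimscan.synthetic_data"},
    )

    if iptm is None:
        if binder:
            iptm = float(np.round(rng.uniform(reference_iptm + 0.10, 0.90), 3))
        elif failure_stage == 5:
            iptm = float(np.round(rng.uniform(0.30, reference_iptm - 0.05), 3))
        else:
            iptm = float(np.round(rng.uniform(0.10, 0.30), 3))

    cross_mean = 4.5 if ligand_mode == "docked" else 24.0
    pae = _synthesize_pae(len(receptor.residues), len(ligand_chain.residues),
                          cross_mean, rng)

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_structure(model, out_dir / "model.pdb")
    with open(out_dir / "pae.json", "w") as fh:
        json.dump(
            {
                "predicted_aligned_error": pae.tolist(),
                "chain_boundary": len(receptor.residues),
                "max_predicted_aligned_error": 31.75,
            },
            fh,
        )
    with open(out_dir / "summary.json", "w") as fh:
        json.dump({"iptm": iptm, "ptm": round(min(0.95, iptm + 0.05), 3)}, fh)

    return ComplexTruth(
        candidate_id=candidate_id,
        binder=binder,
        orientation=orientation if ligand_mode == "docked" else None,
        failure_stage=failure_stage,
        iptm=iptm,
        motif_residues=motif,
        ligand_mode=ligand_mode,
    )


# --------------------------------------------------------------------------
# toy proteomes
# --------------------------------------------------------------------------

@dataclass
class PlantedMotif:
    protein_id: str
    start: int          # author number of position −2
    residues: str
    context: str        # helix | strand | coil


@dataclass
class SyntheticTruth:
    """Everything the benchmark knows about its own construction."""

    pattern: str
    seed: int
    n_proteins: int = 0
    planted: list[PlantedMotif] = field(default_factory=list)
    accidental: list[PlantedMotif] = field(default_factory=list)
    localization: dict[str, bool] = field(default_factory=dict)
    complexes: dict[str, ComplexTruth] = field(default_factory=dict)
    failure_stage: dict[str, int | None] = field(default_factory=dict)
    reference_id: str | None = None
    reference_iptm: float | None = None

    @property
    def binder_ids(self) -> set[str]:
        return {pid for pid, stage in self.failure_stage.items() if stage is None}

    def expected_counts(self) -> dict[str, int]:
        """Stage-by-stage survivor counts implied by the design."""
        with_motif = set(self.failure_stage)
        counts = {"stage1": len(with_motif)}
        survivors = set(with_motif)
        for k, key in zip((2, 3, 4, 5), ("stage2", "stage3", "stage4", "stage5")):
            survivors = {p for p in survivors
                         if self.failure_stage[p] is None or self.failure_stage[p] > k}
            counts[key] = len(survivors)
        return counts

    def expected_survivors(self, stage: int) -> set[str]:
        return {p for p in self.failure_stage
                if self.failure_stage[p] is None or self.failure_stage[p] > stage}

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        payload["planted"] = [PlantedMotif(**p) for p in payload["planted"]]
        payload["accidental"] = [PlantedMotif(**p) for p in payload["accidental"]]
        payload["complexes"] = {
            k: ComplexTruth(**v) for k, v in payload["complexes"].items()
        }
        payload["failure_stage"] = {
            k: (None if v is None else int(v)) for k, v in payload["failure_stage"].items()
        }
        return cls(**payload)


def _random_sequence(length: int, rng: np.random.Generator) -> str:
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    return "".join(alphabet[i] for i in rng.integers(len(alphabet), size=length))


#: Strand-context hairpin layout around a planted motif at index p
#: (0-based): strand residues [p−2, p+5), a two-residue type-I′ turn,
#: partner strand of equal length.  Turn dihedrals chosen so the two
#: strands register into an antiparallel bridge pattern.
_TURN_DIHEDRALS = ((0.0, 90.0), (90.0, 0.0))


def _context_dihedrals(
    length: int, context: str, p: int, rng: np.random.Generator
) -> list[tuple[float, float]]:
    dih = coil_dihedrals(length, rng)
    if context == "helix":
        lo, hi = max(0, p - 5), min(length, p + MOTIF_LENGTH + 5)
        for i in range(lo, hi):
            dih[i] = HELIX_DIHEDRALS
    elif context == "strand":
        s1_lo, s1_hi = p - 2, p + MOTIF_LENGTH + 1   # strand carrying the motif
        turn_lo = s1_hi
        s2_lo = turn_lo + len(_TURN_DIHEDRALS)
        s2_hi = s2_lo + (s1_hi - s1_lo)
        if s1_lo < 0 or s2_hi > length:
            raise ValueError("strand-context motif too close to a terminus")
        for i in range(s1_lo, s1_hi):
            dih[i] = STRAND_DIHEDRALS
        for k, t in enumerate(_TURN_DIHEDRALS):
            dih[turn_lo + k] = t
        for i in range(s2_lo, s2_hi):
            dih[i] = STRAND_DIHEDRALS
    elif context != "coil":
        raise ValueError(f"unknown context {context!r}")
    return dih


def generate_protein(
    protein_id: str,
    length: int,
    rng: np.random.Generator,
    pattern: MotifPattern,
    plant: str | None = None,          # helix | strand | coil | None
    motif_residues: str | None = None,
    geometry: BackboneGeometry = DEFAULT_GEOMETRY,
    max_tries: int = 80,
) -> tuple[StructureModel, list[PlantedMotif], list[PlantedMotif]]:
    """One toy protein, optionally with a motif planted in a known context.

    Sequences are rejection-sampled so accidental pattern occurrences are
    avoided; any survivor of the retry budget is recorded as accidental.
    """
    margin = 12
    if plant and length < 2 * margin + MOTIF_LENGTH:
        raise ValueError(f"{protein_id}: length {length} too short to plant a motif")
    for attempt in range(max_tries):
        seq = _random_sequence(length, rng)
        planted: list[PlantedMotif] = []
        p = None
        if plant:
            p = int(rng.integers(margin, length - margin - MOTIF_LENGTH + 1))
            motif = motif_residues or _random_motif(pattern, rng)
            seq = seq[:p] + motif + seq[p + MOTIF_LENGTH:]
            planted = [PlantedMotif(protein_id, p + 1, motif, plant)]
        hits = {m.start for m in scan_sequence(seq, pattern)}
        wanted = {p + 1} if plant else set()
        if hits == wanted or attempt == max_tries - 1:
            accidental = [
                PlantedMotif(protein_id, s, seq[s - 1 : s + MOTIF_LENGTH - 1], "unknown")
                for s in sorted(hits - wanted)
            ]
            dih = _context_dihedrals(length, plant or "coil", (p or 0), rng)
            model = build_backbone(seq, dih, geometry, model_id=protein_id)
            return model, planted, accidental
    raise RuntimeError("unreachable")


def generate_toy_proteome(
    out_dir: str | Path,
    seed: int,
    plantings: list[tuple[str, int]] | None = None,
    n_extra: int = 10,
    length_range: tuple[int, int] = (60, 110),
    pattern_spec: str = RELAXED_FRM,
    geometry: BackboneGeometry = DEFAULT_GEOMETRY,
) -> SyntheticTruth:
    """Write a toy proteome with motifs planted in known contexts.

    ``plantings`` lists (context, count) pairs, e.g.
    ``[("helix", 5), ("strand", 3), ("coil", 2)]``; ``n_extra`` motif-free
    proteins are added.  Deterministic for a fixed seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    pattern = compile_pattern(pattern_spec)
    truth = SyntheticTruth(pattern=pattern_spec, seed=seed)

    jobs: list[str | None] = []
    for context, count in plantings or []:
        jobs.extend([context] * count)
    jobs.extend([None] * n_extra)

    for k, context in enumerate(jobs):
        protein_id = f"SP{k:04d}"
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        model, planted, accidental = generate_protein(
            protein_id, length, rng, pattern, plant=context, geometry=geometry
        )
        write_structure(model, out_dir / f"{protein_id}.pdb")
        truth.planted.extend(planted)
        truth.accidental.extend(accidental)
        truth.n_proteins += 1
    return truth


# --------------------------------------------------------------------------
# localization tables
# --------------------------------------------------------------------------

CYTOSOLIC_LABEL = "cytosol"
_NONCYTO_LABELS = ("nucleus", "mitochondrion", "endoplasmic reticulum",
                   "vacuole", "plasma membrane")


def generate_localization_table(
    path: str | Path,
    ids: list[str],
    cytosolic_fraction: float = 0.7,
    seed: int = 0,
    overrides: dict[str, bool] | None = None,
) -> dict[str, bool]:
    """Write a two-column (id, comma-separated labels) localization TSV.

    ``overrides`` pins individual proteins as cytosolic or not; the rest
    are drawn with probability ``cytosolic_fraction``.  Returns the
    realised id → is-cytosolic map.
    """
    if not 0.0 <= cytosolic_fraction <= 1.0:
        raise ValueError("cytosolic fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    overrides = overrides or {}
    realized: dict[str, bool] = {}
    with open(path, "w") as fh:
        fh.write("protein_id\tlocalization\n")
        for pid in ids:
            cytosolic = overrides.get(pid, bool(rng.random() < cytosolic_fraction))
            realized[pid] = cytosolic
            labels = [CYTOSOLIC_LABEL] if cytosolic else []
            labels.append(_NONCYTO_LABELS[rng.integers(len(_NONCYTO_LABELS))])
            if cytosolic and rng.random() < 0.5:
                labels = labels[:1]
            fh.write(f"{pid}\t{','.join(labels)}\n")
    return realized


# --------------------------------------------------------------------------
# the funnel benchmark preset
# --------------------------------------------------------------------------

#: Designed candidate roster: (tag, count, context, failure stage).
_BENCHMARK_ROSTER = (
    ("fail2", 3, "strand", 2),
    ("fail3", 3, "helix", 3),
    ("fail4", 4, "coil", 4),
    ("fail5", 3, "helix", 5),
    ("binder", 3, "coil", None),
    ("binder_flipped", 1, "helix", None),
    ("reference", 1, "coil", None),
)


def generate_funnel_benchmark(
    out_dir: str | Path,
    seed: int,
    reference_iptm: float = 0.60,
    n_background: int = 10,
    pattern_spec: str = RELAXED_FRM,
) -> SyntheticTruth:
    """Generate the full funnel benchmark: proteome, localization table
    and prediction bundles, with candidates designed to fail at each
    stage plus true binders (one of them groove-flipped) and a
    reference candidate whose ipTM defines the stage-5 threshold.

    Layout under ``out_dir``: ``proteome/``, ``bundles/<id>/``,
    ``localization.tsv``, ``truth.json``.
    """
    out_dir = Path(out_dir)
    proteome_dir = out_dir / "proteome"
    bundle_dir = out_dir / "bundles"
    proteome_dir.mkdir(parents=True, exist_ok=True)
    bundle_dir.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(seed)
    pattern = compile_pattern(pattern_spec)
    truth = SyntheticTruth(pattern=pattern_spec, seed=seed,
                           reference_iptm=reference_iptm)

    roster: list[tuple[str, str, int | None]] = []
    for tag, count, context, failure in _BENCHMARK_ROSTER:
        for i in range(count):
            roster.append((tag, context, failure))

    k = 0
    overrides: dict[str, bool] = {}
    for tag, context, failure in roster:
        protein_id = f"SP{k:04d}"
        k += 1
        length = int(rng.integers(70, 111))
        force = {0: "S"} if tag == "reference" else None
        motif = _random_motif(pattern, rng, force=force)
        model, planted, accidental = generate_protein(
            protein_id, length, rng, pattern, plant=context, motif_residues=motif
        )
        write_structure(model, proteome_dir / f"{protein_id}.pdb")
        truth.planted.extend(planted)
        truth.accidental.extend(accidental)
        truth.failure_stage[protein_id] = failure
        overrides[protein_id] = failure != 3
        if tag == "reference":
            truth.reference_id = protein_id

        needs_bundle = failure in (4, 5) or failure is None
        if needs_bundle:
            bundle_seed = int(rng.integers(2**31))
            if failure == 4:
                # alternate the two stage-4 failure modes deterministically
                bundle_seed = bundle_seed - (bundle_seed % 2) + (k % 2)
            ctruth = generate_synthetic_complex(
                bundle_dir / protein_id,
                candidate_id=protein_id,
                binder=failure is None,
                failure_stage=failure,
                orientation="flipped_D62" if tag == "binder_flipped" else "canonical_D112",
                iptm=reference_iptm if tag == "reference" else None,
                reference_iptm=reference_iptm,
                motif_residues=motif,
                pattern_spec=pattern_spec,
                seed=bundle_seed,
            )
            truth.complexes[protein_id] = ctruth

    for _ in range(n_background):
        protein_id = f"SP{k:04d}"
        k += 1
        length = int(rng.integers(70, 111))
        model, _, accidental = generate_protein(protein_id, length, rng, pattern)
        write_structure(model, proteome_dir / f"{protein_id}.pdb")
        truth.accidental.extend(accidental)

    truth.n_proteins = k
    all_ids = [f"SP{i:04d}" for i in range(k)]
    loc_seed = int(np.random.default_rng(seed + 1).integers(2**31))
    truth.localization = generate_localization_table(
        out_dir / "localization.tsv", all_ids, cytosolic_fraction=0.7,
        seed=loc_seed, overrides=overrides,
    )
    truth.to_json(out_dir / "truth.json")

    # construction check: the monomer context must realise the intended
    # secondary-structure filter outcome
    from .structure_io import read_structure
    for pm in truth.planted:
        if truth.failure_stage.get(pm.protein_id) in (2,) or pm.context == "strand":
            expect_e = True
        else:
            expect_e = False
        model = read_structure(proteome_dir / f"{pm.protein_id}.pdb")
        ann = assign_secondary_structure(model)
        labels = ann.window(model.chains[0], pm.start, MOTIF_LENGTH)
        has_e = labels is None or "E" in labels
        if has_e != expect_e:
            raise RuntimeError(
                f"benchmark construction failed for {pm.protein_id}: "
                f"context {pm.context!r} realised labels {labels!r}"
            )
    return truth
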