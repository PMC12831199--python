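"""Evidence extraction from two-chain complex predictions.

A candidate complex bundle consists of a receptor (the SHD1 domain of
the Spa2 scaffold, or a stand-in with Spa2 numbering), a ligand chain
carrying the motif, a predicted-aligned-error (PAE) matrix and an ipTM
score.  From these the module derives the quantities the candidate
funnel filters on:

* **groove contact** — heavy-atom contacts between the five motif
  residues and the hydrophobic patch lining the SHD1 groove
  (Spa2 residues 48, 51, 59, 98, 101 and 109);
* **motif helicity in complex** — whether the motif is α-helical when
  bound, judged by the hydrogen-bond secondary-structure assigner;
* **orientation** — which conserved aspartate the motif's Tyr(+2)
  hydroxyl hydrogen-bonds to: D112 (canonical helix direction) or D62
  (flipped direction);
* **interface PAE** — mean/min expected position error over the
  motif × receptor off-diagonal blocks of the PAE matrix.

All geometric outputs depend only on inter-atomic distances and are
therefore invariant under rigid motions of the complex.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .motif_scan import MOTIF_LENGTH
from .secstruct import assign_secondary_structure
from .structure_io import Chain, StructureModel, read_structure

#: Orientation classes for the bound motif helix.
ORIENT_CANONICAL = "canonical_D112"
ORIENT_FLIPPED = "flipped_D62"
ORIENT_INDETERMINATE = "indeterminate"
ORIENT_NOT_APPLICABLE = "not_applicable"

#: Side-chain oxygen names accepted as carboxylate H-bond acceptors.
_CARBOXYLATE_O = ("OD1", "OD2", "OE1", "OE2")


class EvidenceError(ValueError):
    """Raised for structurally unusable evidence inputs."""


@dataclass
class PAEMatrix:
    """Square matrix of expected pairwise position errors (Å).

    ``chain_boundary`` is the 0-based row/column index of the first
    residue of chain B; rows/columns before it belong to chain A.
    """

    matrix: np.ndarray
    chain_boundary: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.n
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise EvidenceError(f"PAE matrix must be square, got {self.matrix.shape}")
        if np.any(self.matrix < 0) or not np.all(np.isfinite(self.matrix)):
            raise EvidenceError("PAE entries must be finite and non-negative")
        if not 0 < self.chain_boundary < n:
            raise EvidenceError(
                f"chain boundary {self.chain_boundary} outside (0, {n})"
            )

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass
class GrooveDefinition:
    """The SHD1 binding groove in full-length Spa2 numbering.

    ``numbering_offset`` maps receptor-chain author numbers to
    full-length numbers (full = author + offset), for fragment
    constructs.  Cutoffs follow standard structural-biology
    conventions: 4.5 Å heavy-atom contacts, 3.5 Å O···O hydrogen bonds.
    """

    hydrophobic_patch: tuple[int, ...] = (48, 51, 59, 98, 101, 109)
    basic_rim: int = 97                    # K97, faces the motif Asp(0)
    canonical_acceptor: int = 112          # D112, H-bonds Tyr(+2) OH
    flipped_acceptor: int = 62             # D62, H-bonds Tyr(+2) OH when flipped
    contact_cutoff: float = 4.5
    hbond_cutoff: float = 3.5
    numbering_offset: int = 0

    def __post_init__(self) -> None:
        if not self.hydrophobic_patch:
            raise EvidenceError("hydrophobic patch residue set must be non-empty")
        if self.contact_cutoff <= 0 or self.hbond_cutoff <= 0:
            raise EvidenceError("cutoffs must be positive")

    def to_author_number(self, full_number: int) -> int:
        return full_number - self.numbering_offset


DEFAULT_SPA2_GROOVE = GrooveDefinition()


@dataclass
class ContactSummary:
    """Heavy-atom contacts between motif and groove patch residues."""

    pairs: list[tuple[int, str, int, str, float]] = field(default_factory=list)
    min_distance: float = float("inf")

    @property
    def n_contact_pairs(self) -> int:
        return len(self.pairs)

    @property
    def groove_contact(self) -> bool:
        return bool(self.pairs)


@dataclass
class InterfaceEvidence:
    """Derived per-candidate evidence feeding funnel stages 4 and 5."""

    groove_contact: bool
    n_contact_pairs: int
    min_distance: float
    motif_helical: bool | None
    orientation: str
    interface_pae_mean: float | None = None
    interface_pae_min: float | None = None
    iptm: float | None = None


@dataclass
class ComplexPrediction:
    """A two-chain predicted complex plus its confidence outputs."""

    candidate_id: str
    model: StructureModel
    receptor_chain_id: str
    ligand_chain_id: str
    iptm: float
    pae: PAEMatrix | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.iptm <= 1.0:
            raise EvidenceError(f"ipTM {self.iptm} outside [0, 1]")

    @property
    def receptor(self) -> Chain:
        return self.model.chain(self.receptor_chain_id)

    @property
    def ligand(self) -> Chain:
        return self.model.chain(self.ligand_chain_id)


def read_pae_matrix(path: str | Path, chain_boundary: int | None = None) -> PAEMatrix:
    """Parse a PAE JSON file.

    Supported dialects: a ``"predicted_aligned_error"`` (or ``"pae"``)
    list-of-lists, optionally wrapped in a one-element list; or paired
    1-based ``"residue1"``/``"residue2"``/``"distance"`` arrays.  The
    chain boundary comes from a ``"chain_boundary"`` metadata field or
    the explicit argument (the argument wins).
    """
    with open(path) as fh:
        data = json.load(fh)
    if isinstance(data, list):
        if len(data) != 1 or not isinstance(data[0], dict):
            raise EvidenceError(f"{path}: unsupported PAE JSON layout")
        data = data[0]

    if "predicted_aligned_error" in data or "pae" in data:
        rows = data.get("predicted_aligned_error", data.get("pae"))
        lengths = {len(r) for r in rows}
        if len(lengths) != 1 or lengths != {len(rows)}:
            raise EvidenceError(f"{path}: ragged or non-square PAE matrix")
        matrix = np.array(rows, dtype=float)
    elif {"residue1", "residue2", "distance"} <= set(data):
        r1 = np.asarray(data["residue1"], dtype=int) - 1
        r2 = np.asarray(data["residue2"], dtype=int) - 1
        d = np.asarray(data["distance"], dtype=float)
        n = int(max(r1.max(), r2.max())) + 1
        if len(r1) != n * n:
            raise EvidenceError(f"{path}: paired arrays do not cover a square matrix")
        matrix = np.full((n, n), np.nan)
        matrix[r1, r2] = d
        if np.any(np.isnan(matrix)):
            raise EvidenceError(f"{path}: paired arrays leave matrix entries unset")
    else:
        raise EvidenceError(f"{path}: unrecognised PAE JSON dialect")

    boundary = chain_boundary if chain_boundary is not None else data.get("chain_boundary")
    if boundary is None:
        raise EvidenceError(
            f"{path}: chain boundary not in metadata and not supplied"
        )
    return PAEMatrix(matrix=matrix, chain_boundary=int(boundary))


def _motif_residues(ligand: Chain, motif_start: int) -> list:
    residues = [ligand.residue_by_number(motif_start + k) for k in range(MOTIF_LENGTH)]
    if any(r is None for r in residues):
        raise EvidenceError(
            f"motif window {motif_start}..{motif_start + MOTIF_LENGTH - 1} "
            f"absent from ligand chain {ligand.chain_id}"
        )
    return residues


def interchain_contacts(
    prediction: ComplexPrediction,
    groove: GrooveDefinition,
    motif_start: int,
) -> ContactSummary:
    """Heavy-atom contacts between motif and groove-patch residues.

    Reports every pair within ``groove.contact_cutoff`` and the minimum
    distance even when there is no contact at all.
    """
    receptor, ligand = prediction.receptor, prediction.ligand
    patch = []
    missing = []
    for full_number in groove.hydrophobic_patch:
        res = receptor.residue_by_number(groove.to_author_number(full_number))
        if res is None:
            missing.append(full_number)
        else:
            patch.append((full_number, res))
    if missing:
        raise EvidenceError(
            f"groove residues missing from receptor chain "
            f"{receptor.chain_id}: {missing}"
        )
    motif = _motif_residues(ligand, motif_start)

    summary = ContactSummary()
    lig_atoms = [
        (r.author_number, a.name, a.position) for r in motif for a in r.heavy_atoms()
    ]
    rec_atoms = [
        (num, a.name, a.position) for num, res in patch for a in res.heavy_atoms()
    ]
    if not lig_atoms or not rec_atoms:
        return summary
    dists = cdist(
        np.array([p for *_, p in rec_atoms]), np.array([p for *_, p in lig_atoms])
    )
    summary.min_distance = float(dists.min())
    for i, j in zip(*np.nonzero(dists <= groove.contact_cutoff)):
        rnum, rname, _ = rec_atoms[i]
        lnum, lname, _ = lig_atoms[j]
        summary.pairs.append((rnum, rname, lnum, lname, float(dists[i, j])))
    summary.pairs.sort()
    return summary


def motif_helicity_in_complex(
    prediction: ComplexPrediction, motif_start: int
) -> bool | None:
    """Is the bound motif α-helical?

    True iff at least four of the five motif residues are labelled 'H'
    by the hydrogen-bond assigner run on the complex.  Returns ``None``
    ("not evaluable") when the window or its backbone is incomplete.
    """
    ligand = prediction.ligand
    try:
        residues = _motif_residues(ligand, motif_start)
    except EvidenceError:
        return None
    if any(not r.has_backbone() for r in residues):
        return None
    ann = assign_secondary_structure(prediction.model)
    labels = ann.window(ligand, motif_start, MOTIF_LENGTH)
    if labels is None:
        return None
    return labels.count("H") >= 4


def classify_orientation(
    prediction: ComplexPrediction,
    groove: GrooveDefinition,
    motif_start: int,
) -> str:
    """Which direction does the motif helix run in the groove?

    Canonical: the Tyr(+2) hydroxyl hydrogen-bonds the carboxylate of
    Spa2 D112; flipped: it bonds D62 instead.  Indeterminate when
    neither oxygen is within the H-bond cutoff; not-applicable when
    position +2 is not a tyrosine with a resolved OH.
    """
    ligand, receptor = prediction.ligand, prediction.receptor
    plus2 = ligand.residue_by_number(motif_start + MOTIF_LENGTH - 1)
    if plus2 is None or plus2.name3.upper() != "TYR" or plus2.atom("OH") is None:
        return ORIENT_NOT_APPLICABLE
    oh = plus2.atom("OH").position

    def min_carboxylate_distance(full_number: int) -> float:
        res = receptor.residue_by_number(groove.to_author_number(full_number))
        if res is None:
            raise EvidenceError(
                f"receptor lacks residue {full_number} needed for orientation"
            )
        oxygens = [res.atom(n) for n in _CARBOXYLATE_O]
        oxygens = [a for a in oxygens if a is not None]
        if not oxygens:
            raise EvidenceError(
                f"receptor residue {full_number} has no carboxylate oxygens"
            )
        return min(float(np.linalg.norm(a.position - oh)) for a in oxygens)

    d_canonical = min_carboxylate_distance(groove.canonical_acceptor)
    d_flipped = min_carboxylate_distance(groove.flipped_acceptor)
    if d_canonical <= groove.hbond_cutoff and d_canonical < d_flipped:
        return ORIENT_CANONICAL
    if d_flipped <= groove.hbond_cutoff and d_flipped < d_canonical:
        return ORIENT_FLIPPED
    return ORIENT_INDETERMINATE


def interface_pae_summary(
    pae: PAEMatrix,
    motif_indices: list[int] | np.ndarray,
    receptor_indices: list[int] | np.ndarray,
) -> tuple[float, float]:
    """Mean and min PAE over the motif × receptor cross-chain blocks.

    PAE matrices are asymmetric, so both off-diagonal blocks are
    averaged: ``mean = (mean(M[motif, receptor]) +
    mean(M[receptor, motif])) / 2``, min analogously.
    Index sets must lie on opposite sides of the chain boundary.
    """
    motif_idx = np.asarray(motif_indices, dtype=int)
    rec_idx = np.asarray(receptor_indices, dtype=int)
    if motif_idx.size == 0 or rec_idx.size == 0:
        raise EvidenceError("empty index set for interface PAE summary")
    b = pae.chain_boundary
    motif_side = {int(i >= b) for i in motif_idx}
    rec_side = {int(i >= b) for i in rec_idx}
    if len(motif_side) != 1 or len(rec_side) != 1 or motif_side == rec_side:
        raise EvidenceError(
            "interface PAE requires index sets on opposite sides of the chain boundary"
        )
    if motif_idx.max() >= pae.n or rec_idx.max() >= pae.n or motif_idx.min() < 0 or rec_idx.min() < 0:
        raise EvidenceError("indices outside PAE matrix")
    block_mr = pae.matrix[np.ix_(motif_idx, rec_idx)]
    block_rm = pae.matrix[np.ix_(rec_idx, motif_idx)]
    mean = (float(block_mr.mean()) + float(block_rm.mean())) / 2.0
    minimum = min(float(block_mr.min()), float(block_rm.min()))
    return mean, minimum


def _matrix_indices(prediction: ComplexPrediction, motif_start: int) -> tuple[list[int], list[int]]:
    """PAE row indices for the motif window (ligand side) and the whole
    receptor, assuming matrix rows follow chain A then chain B order."""
    receptor, ligand = prediction.receptor, prediction.ligand
    boundary = prediction.pae.chain_boundary
    lig_pos = {r.author_number: i for i, r in enumerate(ligand.residues)}
    motif_idx = [boundary + lig_pos[motif_start + k] for k in range(MOTIF_LENGTH)]
    rec_idx = list(range(len(receptor.residues)))
    return motif_idx, rec_idx


def gather_evidence(
    prediction: ComplexPrediction,
    motif_start: int,
    groove: GrooveDefinition = DEFAULT_SPA2_GROOVE,
) -> InterfaceEvidence:
    """Run all evidence checks on one candidate complex."""
    contacts = interchain_contacts(prediction, groove, motif_start)
    helical = motif_helicity_in_complex(prediction, motif_start)
    if contacts.groove_contact:
        orientation = classify_orientation(prediction, groove, motif_start)
    else:
        # Orientation is only meaningful for a motif sitting in the groove.
        orientation = ORIENT_INDETERMINATE
    pae_mean = pae_min = None
    if prediction.pae is not None:
        motif_idx, rec_idx = _matrix_indices(prediction, motif_start)
        pae_mean, pae_min = interface_pae_summary(prediction.pae, motif_idx, rec_idx)
    return InterfaceEvidence(
        groove_contact=contacts.groove_contact,
        n_contact_pairs=contacts.n_contact_pairs,
        min_distance=contacts.min_distance,
        motif_helical=helical,
        orientation=orientation,
        interface_pae_mean=pae_mean,
        interface_pae_min=pae_min,
        iptm=prediction.iptm,
    )


def load_prediction_bundle(
    bundle_dir: str | Path,
    candidate_id: str | None = None,
    receptor_chain_id: str = "A",
    ligand_chain_id: str = "B",
) -> ComplexPrediction:
    """Load a prediction bundle directory.

    Expected layout: ``model.pdb`` or ``model.cif``, ``pae.json``
    (optional) and ``summary.json`` with an ``"iptm"`` field.
    """
    bundle_dir = Path(bundle_dir)
    model_path = None
    for name in ("model.pdb", "model.cif", "model.mmcif"):
        if (bundle_dir / name).exists():
            model_path = bundle_dir / name
            break
    if model_path is None:
        raise FileNotFoundError(f"{bundle_dir}: no model.pdb or model.cif")
    model = read_structure(model_path)
    summary_path = bundle_dir / "summary.json"
    if not summary_path.exists():
        raise FileNotFoundError(f"{bundle_dir}: missing summary.json")
    with open(summary_path) as fh:
        summary = json.load(fh)
    if "iptm" not in summary:
        raise EvidenceError(f"{summary_path}: no 'iptm' field")
    pae = None
    if (bundle_dir / "pae.json").exists():
        pae = read_pae_matrix(bundle_dir / "pae.json")
    return ComplexPrediction(
        candidate_id=candidate_id or bundle_dir.name,
        model=model,
        receptor_chain_id=receptor_chain_id,
        ligand_chain_id=ligand_chain_id,
        iptm=float(summary["iptm"]),
        pae=pae,
    )
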