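"""Reading, writing and iterating protein structure models.

Structures are held in a small, explicit object model (``Atom`` →
``Residue`` → ``Chain`` → ``StructureModel``) that carries exactly what
the downstream geometry needs: author residue numbering, one-letter
codes, and Cartesian coordinates in Å.  Parsing and serialisation of the
PDB and mmCIF dialects is delegated to :mod:`gemmi`; proteome-scale
inputs may be a directory of files or a (optionally gzipped) tar archive
in the AlphaFold-DB layout, iterated member by member without full
extraction.

Conventions
-----------
* Author (1-based) residue numbering is authoritative everywhere.
* Only blank or ``'A'`` alternate-location copies are kept, so that
  crystal-derived inputs behave deterministically (predicted models
  carry no altlocs at all).
* Waters are dropped; every other residue is kept, with unknown
  three-letter codes mapping to ``'X'`` in sequences.  ``'X'`` never
  matches a motif position.
* Multi-model files contribute their first model only.
"""

from __future__ import annotations

import gzip
import logging
import re
import tarfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

#: Three-letter → one-letter codes for the 20 standard amino acids plus
#: the substitutions with a standard parent that we normalise (MSE → M).
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M",
}

ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items() if k != "MSE"}

STANDARD_AA = frozenset(ONE_TO_THREE)

#: AlphaFold-DB entry naming, e.g. ``AF-P38928-F1-model_v4.pdb``.
_AFDB_NAME = re.compile(r"AF-([A-Z0-9]+)-F\d+")

_WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})


class StructureError(ValueError):
    """Raised for unreadable, empty or internally inconsistent models."""


@dataclass
class Atom:
    """One atom: label (N/CA/C/O/CB/...), element, position in Å."""

    name: str
    element: str
    position: np.ndarray
    bfactor: float = 0.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if not self.name:
            raise StructureError("atom name must be non-empty")
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise StructureError(f"atom {self.name}: position must be a finite 3-vector")


@dataclass
class Residue:
    """A residue with author numbering and its atoms."""

    name3: str
    author_number: int
    atoms: list[Atom] = field(default_factory=list)
    insertion_code: str = ""

    @property
    def code1(self) -> str:
        return THREE_TO_ONE.get(self.name3.upper(), "X")

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def has_backbone(self) -> bool:
        return all(self.atom(n) is not None for n in ("N", "CA", "C", "O"))

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.element.upper() != "H"]


@dataclass
class Chain:
    """An ordered run of residues sharing one chain identifier."""

    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    def residue_by_number(self, author_number: int, insertion_code: str = "") -> Residue | None:
        for r in self.residues:
            if r.author_number == author_number and r.insertion_code == insertion_code:
                return r
        return None


@dataclass
class StructureModel:
    """One protein model: the unit of proteome iteration."""

    model_id: str
    chains: list[Chain] = field(default_factory=list)
    source_format: str = "pdb"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.model_id:
            raise StructureError("model_id must be non-empty")

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"model {self.model_id}: no chain {chain_id!r}")

    def all_coordinates(self) -> np.ndarray:
        return np.array(
            [a.position for c in self.chains for r in c.residues for a in r.atoms]
        )


def extract_sequence(chain: Chain) -> str:
    """One-letter sequence of a chain; unknown residues become ``'X'``."""
    return "".join(r.code1 for r in chain.residues)


def model_id_from_name(name: str) -> str:
    """Protein identifier from a file name.

    AlphaFold-DB style names yield the embedded accession
    (``AF-P00000-F1-model_v4.pdb`` → ``P00000``); anything else falls
    back to the file stem with compression/format suffixes stripped.
    """
    base = Path(name).name
    m = _AFDB_NAME.search(base)
    if m:
        return m.group(1)
    for suffix in (".gz", ".pdb", ".cif", ".mmcif", ".ent"):
        if base.lower().endswith(suffix):
            base = base[: -len(suffix)]
    return base


def _convert_gemmi(st: gemmi.Structure, model_id: str, source_format: str) -> StructureModel:
    if len(st) == 0:
        raise StructureError(f"{model_id}: file contains no models")
    gmodel = st[0]  # first MODEL only
    chains: list[Chain] = []
    for gchain in gmodel:
        residues: list[Residue] = []
        for gres in gchain:
            if gres.name.upper() in _WATER_NAMES or gres.is_water():
                continue
            atoms: list[Atom] = []
            for gatom in gres:
                if gatom.altloc not in ("\0", "", "A"):
                    continue
                atoms.append(
                    Atom(
                        name=gatom.name,
                        element=gatom.element.name,
                        position=np.array([gatom.pos.x, gatom.pos.y, gatom.pos.z]),
                        bfactor=gatom.b_iso,
                        altloc="" if gatom.altloc in ("\0", "") else gatom.altloc,
                    )
                )
            if atoms:
                residues.append(
                    Residue(
                        name3=gres.name,
                        author_number=gres.seqid.num,
                        insertion_code=(gres.seqid.icode or "").strip(),
                        atoms=atoms,
                    )
                )
        if residues:
            chains.append(Chain(chain_id=gchain.name, residues=residues))
    if not chains:
        raise StructureError(f"{model_id}: no polymer atoms found")
    return StructureModel(
        model_id=model_id, chains=chains, source_format=source_format
    )


def _detect_format(path_or_name: str, fmt: str) -> str:
    if fmt != "auto":
        return fmt
    name = path_or_name.lower()
    if name.endswith(".gz"):
        name = name[:-3]
    if name.endswith((".cif", ".mmcif")):
        return "mmcif"
    return "pdb"


def read_structure(path: str | Path, fmt: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Parameters
    ----------
    path
        File path; ``.gz`` compression is handled transparently.
    fmt
        ``"pdb"``, ``"mmcif"`` or ``"auto"`` (extension-based).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    source_format = _detect_format(path.name, fmt)
    try:
        if source_format == "pdb":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    return _convert_gemmi(st, model_id_from_name(path.name), source_format)


def read_structure_string(text: str, name: str, fmt: str = "auto") -> StructureModel:
    """Parse structure text (one tar member, say) without touching disk."""
    source_format = _detect_format(name, fmt)
    try:
        if source_format == "pdb":
            st = gemmi.read_pdb_string(text)
        else:
            doc = gemmi.cif.read_string(text)
            st = gemmi.make_structure_from_block(doc.sole_block())
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {name}: {exc}") from exc
    return _convert_gemmi(st, model_id_from_name(name), source_format)


def _to_gemmi(model: StructureModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = model.model_id
    gmodel = gemmi.Model("1")
    for chain in model.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name3
            gres.seqid = gemmi.SeqId(res.author_number, res.insertion_code or " ")
            for atom in res.atoms:
                gatom = gemmi.Atom()
                gatom.name = atom.name
                gatom.element = gemmi.Element(atom.element)
                gatom.pos = gemmi.Position(*atom.position)
                gatom.b_iso = atom.bfactor
                gatom.occ = 1.0
                gres.add_atom(gatom)
            gchain.add_residue(gres)
        gmodel.add_chain(gchain)
    st.add_model(gmodel)
    st.setup_entities()
    return st


def write_structure(model: StructureModel, path: str | Path, fmt: str = "auto") -> Path:
    """Write a model to PDB or mmCIF; output re-reads to an equal model."""
    if not model.chains or not any(c.residues for c in model.chains):
        raise StructureError(f"{model.model_id}: refusing to write empty model")
    path = Path(path)
    source_format = _detect_format(path.name, fmt)
    st = _to_gemmi(model)
    if source_format == "pdb":
        st.write_pdb(str(path))
    else:
        st.make_mmcif_document().write_file(str(path))
    return path


_STRUCTURE_SUFFIXES = (".pdb", ".cif", ".mmcif", ".ent",
                       ".pdb.gz", ".cif.gz", ".mmcif.gz", ".ent.gz")


def _is_structure_name(name: str) -> bool:
    return name.lower().endswith(_STRUCTURE_SUFFIXES)


def iterate_proteome(
    source: str | Path,
    fmt: str = "auto",
    on_error: str = "skip",
) -> Iterator[StructureModel]:
    """Yield every structure in a directory or (possibly gzipped) tar archive.

    Entries are visited in lexicographic order of their names, so
    iteration is deterministic.  Unparseable entries are logged and
    skipped (``on_error="skip"``, default) or raised (``"raise"``).

    Raises
    ------
    StructureError
        If the source holds no structure entries at all, or if every
        entry failed to parse (the two cases carry distinct messages).
    """
    source = Path(source)
    if not source.exists():
        raise FileNotFoundError(source)

    n_seen = n_ok = 0

    def _handle(exc: Exception, name: str) -> None:
        if on_error == "raise":
            raise exc
        logger.warning("skipping unparseable entry %s: %s", name, exc)

    if source.is_dir():
        entries = sorted(p for p in source.iterdir() if _is_structure_name(p.name))
        if not entries:
            raise StructureError(f"{source}: no structure files found")
        for p in entries:
            n_seen += 1
            try:
                if p.name.lower().endswith(".gz"):
                    text = gzip.open(p, "rt").read()
                    model = read_structure_string(text, p.name[:-3], fmt)
                else:
                    model = read_structure(p, fmt)
            except (StructureError, OSError) as exc:
                _handle(exc, p.name)
                continue
            n_ok += 1
            yield model
    else:
        with tarfile.open(source, "r:*") as tar:
            members = sorted(
                (m for m in tar if m.isfile() and _is_structure_name(m.name)),
                key=lambda m: m.name,
            )
            if not members:
                raise StructureError(f"{source}: no structure members in archive")
            for member in members:
                n_seen += 1
                name = member.name
                try:
                    raw = tar.extractfile(member).read()
                    if name.lower().endswith(".gz"):
                        raw = gzip.decompress(raw)
                        name = name[:-3]
                    model = read_structure_string(raw.decode(), name, fmt)
                except (StructureError, OSError, UnicodeDecodeError) as exc:
                    _handle(exc, member.name)
                    continue
                n_ok += 1
                yield model

    if n_seen and n_ok == 0:
        raise StructureError(f"{source}: all {n_seen} entries failed to parse")
    logger.info("iterated %s: %d entries, %d parsed", source, n_seen, n_ok)
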