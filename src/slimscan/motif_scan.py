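"""Degenerate five-position motif patterns and proteome scanning.

Patterns use bracket notation over the 20 standard one-letter codes,
e.g. ``"[VI][IL]D[LA]Y"``.  Positions are labelled −2, −1, 0, +1, +2
(the field convention for this motif family: the acidic/serine position
is 0, the tyrosine +2).  ``'X'`` in a sequence matches no position.
All, possibly overlapping, occurrences are reported; protein-level
counting deduplicates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable

from .structure_io import STANDARD_AA, Chain, StructureModel, extract_sequence

#: The strict consensus: (V/I)-(I/L)-D-(L/A)-Y.
STRICT_FRM = "[VI][IL]D[LA]Y"

#: The relaxed consensus used for the proteome scan: (V/I)-(I/L)-(D/S)-(L/A)-Y.
RELAXED_FRM = "[VI][IL][DS][LA]Y"

MOTIF_LENGTH = 5

#: Position labels, −2 … +2 with the third position as 0.
POSITION_LABELS = (-2, -1, 0, 1, 2)

_TOKEN = re.compile(r"\[([A-Za-z]+)\]|([A-Za-z])")


class PatternError(ValueError):
    """Raised for malformed pattern specifications."""


@dataclass(frozen=True)
class MotifPattern:
    """A compiled five-position pattern: one allowed-residue set per position."""

    name: str
    positions: tuple[frozenset[str], ...]
    source: str

    @property
    def labels(self) -> tuple[int, ...]:
        return POSITION_LABELS

    def allowed(self, label: int) -> frozenset[str]:
        """Allowed residues at a −2…+2 position label."""
        return self.positions[POSITION_LABELS.index(label)]

    def matches_window(self, window: str) -> bool:
        return len(window) == MOTIF_LENGTH and all(
            aa in allowed for aa, allowed in zip(window, self.positions)
        )


@dataclass(frozen=True)
class MotifMatch:
    """One located occurrence; ``start`` is the 1-based author number of
    position −2 and ``end = start + 4``."""

    model_id: str
    chain_id: str
    start: int
    residues: str

    @property
    def end(self) -> int:
        return self.start + MOTIF_LENGTH - 1

    @property
    def by_position(self) -> dict[int, str]:
        return dict(zip(POSITION_LABELS, self.residues))


def compile_pattern(spec: str, name: str = "") -> MotifPattern:
    """Compile bracket notation into a :class:`MotifPattern`.

    Raises :class:`PatternError` naming the offending position when the
    arity is not five or a letter is not a standard amino acid.
    """
    consumed = 0
    sets: list[frozenset[str]] = []
    for m in _TOKEN.finditer(spec):
        if m.start() != consumed:
            raise PatternError(f"cannot parse pattern {spec!r} at offset {consumed}")
        consumed = m.end()
        letters = (m.group(1) or m.group(2)).upper()
        bad = sorted(set(letters) - STANDARD_AA)
        if bad:
            raise PatternError(
                f"position {len(sets) + 1} of {spec!r}: non-standard letters {bad}"
            )
        sets.append(frozenset(letters))
    if consumed != len(spec):
        raise PatternError(f"cannot parse pattern {spec!r} at offset {consumed}")
    if len(sets) != MOTIF_LENGTH:
        raise PatternError(
            f"pattern {spec!r} has {len(sets)} positions, expected {MOTIF_LENGTH}"
        )
    return MotifPattern(name=name or spec, positions=tuple(sets), source=spec)


def scan_sequence(
    sequence: str,
    pattern: MotifPattern,
    offset: int = 1,
    model_id: str = "",
    chain_id: str = "",
) -> list[MotifMatch]:
    """All (possibly overlapping) pattern occurrences in a sequence.

    ``offset`` is the author number of the first sequence position, so
    reported starts are author numbers.
    """
    sequence = sequence.upper()
    out: list[MotifMatch] = []
    for i in range(len(sequence) - MOTIF_LENGTH + 1):
        window = sequence[i : i + MOTIF_LENGTH]
        if pattern.matches_window(window):
            out.append(
                MotifMatch(
                    model_id=model_id,
                    chain_id=chain_id,
                    start=offset + i,
                    residues=window,
                )
            )
    return out


def scan_chain(chain: Chain, pattern: MotifPattern, model_id: str = "") -> list[MotifMatch]:
    """Scan the residues of a chain, reporting author-number coordinates.

    Windows must be five *consecutive* residues in chain order; the
    start is the author number of the window's first residue.
    """
    residues = chain.residues
    seq = extract_sequence(chain)
    out: list[MotifMatch] = []
    for i in range(len(residues) - MOTIF_LENGTH + 1):
        window = seq[i : i + MOTIF_LENGTH]
        if pattern.matches_window(window):
            out.append(
                MotifMatch(
                    model_id=model_id,
                    chain_id=chain.chain_id,
                    start=residues[i].author_number,
                    residues=window,
                )
            )
    return out


@dataclass
class ProteomeScanResult:
    """All matches of one pattern over a proteome, grouped per protein."""

    pattern: MotifPattern
    matches: list[MotifMatch] = field(default_factory=list)
    by_protein: dict[str, list[MotifMatch]] = field(default_factory=dict)
    n_models: int = 0

    @property
    def n_proteins_with_match(self) -> int:
        """Proteins counted once regardless of occurrence multiplicity."""
        return len(self.by_protein)


def scan_proteome(
    models: Iterable[StructureModel], pattern: MotifPattern
) -> ProteomeScanResult:
    """Scan a stream of structure models for a motif pattern."""
    result = ProteomeScanResult(pattern=pattern)
    for model in models:
        result.n_models += 1
        for chain in model.chains:
            for match in scan_chain(chain, pattern, model_id=model.model_id):
                result.matches.append(match)
                result.by_protein.setdefault(model.model_id, []).append(match)
    if result.n_models == 0:
        raise ValueError("empty proteome: no models to scan")
    result.matches.sort(key=lambda m: (m.model_id, m.chain_id, m.start))
    return result
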