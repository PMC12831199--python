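"""The five-stage candidate funnel.

Stage 1 scans a proteome of predicted structures for the motif pattern;
stage 2 keeps motifs lying exclusively in helical or loop (never
strand) conformation in the monomer; stage 3 keeps cytosolic proteins;
stage 4 keeps candidates whose predicted complex docks the motif, as a
helix, into the SHD1 groove; stage 5 keeps candidates whose complex
ipTM is equal to or higher than that of the reference candidate (the
known weakest true binder, Mkk1 in the original study).  The sixth
stage — experimental validation by a fold-back competition assay — is
outside computational reach and is only echoed as a pending column.

Counts are protein-level (a protein with several occurrences counts
once) and the per-stage survivor sets are nested by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .complex_evidence import (
    DEFAULT_SPA2_GROOVE,
    GrooveDefinition,
    InterfaceEvidence,
    gather_evidence,
    load_prediction_bundle,
)
from .motif_scan import MotifMatch, compile_pattern, scan_chain, scan_proteome
from .secstruct import assign_secondary_structure
from .structure_io import StructureModel, iterate_proteome

STAGE_NAMES = {
    1: "motif_scan",
    2: "ss_context",
    3: "localization",
    4: "groove_binding",
    5: "iptm_threshold",
}


class PipelineError(ValueError):
    """Raised for unusable pipeline configurations."""


# --------------------------------------------------------------------------
# localization
# --------------------------------------------------------------------------

@dataclass
class LocalizationTable:
    """protein id → compartment labels; lookups are case-insensitive."""

    compartments: dict[str, frozenset[str]] = field(default_factory=dict)
    cytosolic_labels: frozenset[str] = frozenset({"cytosol", "cytoplasm"})

    @classmethod
    def from_tsv(cls, path: str | Path,
                 cytosolic_labels: frozenset[str] | None = None) -> "LocalizationTable":
        """Read a two-column TSV (id, comma-separated labels); a header
        row starting with 'protein_id' is skipped."""
        table = cls()
        if cytosolic_labels is not None:
            table.cytosolic_labels = frozenset(l.lower() for l in cytosolic_labels)
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.lower().startswith("protein_id"):
                    continue
                pid, _, labels = line.partition("\t")
                table.compartments[pid.strip().lower()] = frozenset(
                    l.strip().lower() for l in labels.split(",") if l.strip()
                )
        return table

    def labels(self, protein_id: str) -> frozenset[str] | None:
        return self.compartments.get(protein_id.lower())

    def is_cytosolic(self, protein_id: str) -> bool | None:
        """True/False, or None when the protein is not in the table."""
        labels = self.labels(protein_id)
        if labels is None:
            return None
        return bool(labels & self.cytosolic_labels)


# --------------------------------------------------------------------------
# candidates and report
# --------------------------------------------------------------------------

@dataclass
class Candidate:
    """One motif-bearing protein flowing through the funnel."""

    protein_id: str
    matches: list[MotifMatch] = field(default_factory=list)
    ss_labels: dict[int, str] = field(default_factory=dict)   # match start → 5 labels
    passed: dict[int, bool] = field(default_factory=dict)     # stage → outcome
    exclusion_stage: int | None = None
    exclusion_reason: str | None = None
    flags: list[str] = field(default_factory=list)
    evidence: InterfaceEvidence | None = None
    iptm: float | None = None

    def fail(self, stage: int, reason: str) -> None:
        self.passed[stage] = False
        if self.exclusion_stage is None:
            self.exclusion_stage = stage
            self.exclusion_reason = reason


@dataclass
class StageResult:
    stage: int
    name: str
    survivors: set[str]
    skipped: bool = False

    @property
    def count(self) -> int:
        return len(self.survivors)


@dataclass
class FilterReport:
    """Funnel outcome: nested survivor sets, counts and configuration echo."""

    stages: list[StageResult] = field(default_factory=list)
    candidates: dict[str, Candidate] = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def counts(self) -> dict[str, int]:
        return {f"stage{s.stage}": s.count for s in self.stages}

    def survivors(self, stage: int) -> set[str]:
        for s in self.stages:
            if s.stage == stage:
                return set(s.survivors)
        raise KeyError(stage)

    def validate_monotonic(self) -> None:
        for prev, cur in zip(self.stages, self.stages[1:]):
            if not cur.survivors <= prev.survivors:
                raise PipelineError(
                    f"stage {cur.stage} survivors not nested in stage {prev.stage}"
                )


# --------------------------------------------------------------------------
# stage predicates
# --------------------------------------------------------------------------

def ss_context_filter(labels: str | None) -> bool:
    """Keep a motif located exclusively in helical or loop conformation.

    ``labels`` are the five simplified labels of the motif residues;
    any 'E' (strand) discards, missing labels mean "unannotated" and
    the candidate is excluded by the caller with that reason.
    """
    if labels is None or len(labels) != 5:
        return False
    return "E" not in labels


def localization_filter(
    candidates: list[Candidate],
    table: LocalizationTable,
    unknown_policy: str = "keep",
) -> list[Candidate]:
    """Keep candidates whose labels intersect the cytosolic set.

    Proteins absent from the table are kept with an
    ``unknown-localization`` flag (default) or dropped
    (``unknown_policy="drop"``).
    """
    survivors = []
    for cand in candidates:
        verdict = table.is_cytosolic(cand.protein_id)
        if verdict is True:
            cand.passed[3] = True
            survivors.append(cand)
        elif verdict is None and unknown_policy == "keep":
            cand.passed[3] = True
            cand.flags.append("unknown-localization")
            survivors.append(cand)
        elif verdict is None:
            cand.fail(3, "unknown localization (strict policy)")
        else:
            cand.fail(3, "non-cytosolic")
    return survivors


def iptm_filter(candidates: list[Candidate], reference_iptm: float) -> list[Candidate]:
    """Keep candidates with ipTM equal to or higher than the reference."""
    if reference_iptm is None:
        raise PipelineError("stage 5 requires a reference ipTM")
    survivors = []
    for cand in candidates:
        if cand.iptm is None:
            cand.fail(5, "no ipTM available")
        elif cand.iptm >= reference_iptm:
            cand.passed[5] = True
            survivors.append(cand)
        else:
            cand.fail(5, f"ipTM {cand.iptm} < reference {reference_iptm}")
    return survivors


# --------------------------------------------------------------------------
# configuration and orchestration
# --------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything a funnel run needs; stages 3–5 are optional."""

    proteome_source: str | Path
    pattern: str
    localization_table: str | Path | None = None
    bundle_dir: str | Path | None = None
    reference_id: str | None = None
    reference_iptm: float | None = None
    groove: GrooveDefinition = field(default_factory=GrooveDefinition)
    unknown_localization_policy: str = "keep"
    min_helical_residues: int = 4

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        groove = GrooveDefinition(**raw.pop("groove", {}))
        return cls(groove=groove, **raw)

    def echo(self) -> dict:
        return {
            "proteome_source": str(self.proteome_source),
            "pattern": self.pattern,
            "localization_table": str(self.localization_table) if self.localization_table else None,
            "bundle_dir": str(self.bundle_dir) if self.bundle_dir else None,
            "reference_id": self.reference_id,
            "reference_iptm": self.reference_iptm,
            "contact_cutoff": self.groove.contact_cutoff,
            "hbond_cutoff": self.groove.hbond_cutoff,
            "unknown_localization_policy": self.unknown_localization_policy,
        }


def _resolve_reference_iptm(config: PipelineConfig) -> float:
    if config.reference_iptm is not None:
        return float(config.reference_iptm)
    if config.reference_id is None or config.bundle_dir is None:
        raise PipelineError(
            "stage 5 requires reference_iptm or reference_id with a bundle"
        )
    summary = Path(config.bundle_dir) / config.reference_id / "summary.json"
    if not summary.exists():
        raise PipelineError(f"reference candidate bundle missing: {summary}")
    with open(summary) as fh:
        return float(json.load(fh)["iptm"])


def run_search(config: PipelineConfig) -> FilterReport:
    """Run the funnel end to end and return the report.

    Disabled stages (no localization table / no bundle directory) copy
    survivors forward and are marked skipped.  A stage with zero
    survivors completes normally, downstream stages reporting zero.
    """
    pattern = compile_pattern(config.pattern)
    report = FilterReport(config=config.echo())
    report.provenance["pattern"] = pattern.source

    # ---- stage 1: motif scan over the proteome ------------------------
    models: dict[str, StructureModel] = {}
    for model in iterate_proteome(config.proteome_source):
        models[model.model_id] = model
    scan = scan_proteome(models.values(), pattern)
    report.provenance["n_models_scanned"] = scan.n_models

    candidates: dict[str, Candidate] = {}
    for pid, matches in scan.by_protein.items():
        cand = Candidate(protein_id=pid, matches=list(matches))
        cand.passed[1] = True
        candidates[pid] = cand
    report.candidates = candidates
    s1 = sorted(candidates)
    report.stages.append(StageResult(1, STAGE_NAMES[1], set(s1)))

    # ---- stage 2: secondary-structure context -------------------------
    survivors2: list[Candidate] = []
    for pid in s1:
        cand = candidates[pid]
        model = models[pid]
        ann = assign_secondary_structure(model)
        keep = False
        for match in cand.matches:
            chain = model.chain(match.chain_id)
            labels = ann.window(chain, match.start)
            if labels is not None:
                cand.ss_labels[match.start] = labels
            if ss_context_filter(labels):
                keep = True
        if keep:
            cand.passed[2] = True
            survivors2.append(cand)
        else:
            reason = "motif in strand conformation" if cand.ss_labels else "unannotated"
            cand.fail(2, reason)
    report.stages.append(
        StageResult(2, STAGE_NAMES[2], {c.protein_id for c in survivors2})
    )

    # ---- stage 3: localization ----------------------------------------
    if config.localization_table is None:
        survivors3 = list(survivors2)
        report.stages.append(
            StageResult(3, STAGE_NAMES[3], {c.protein_id for c in survivors3}, skipped=True)
        )
    else:
        table = LocalizationTable.from_tsv(config.localization_table)
        survivors3 = localization_filter(
            survivors2, table, config.unknown_localization_policy
        )
        report.stages.append(
            StageResult(3, STAGE_NAMES[3], {c.protein_id for c in survivors3})
        )

    # ---- stages 4 & 5: complex evidence and ipTM threshold ------------
    if config.bundle_dir is None:
        report.stages.append(
            StageResult(4, STAGE_NAMES[4], {c.protein_id for c in survivors3}, skipped=True)
        )
        report.stages.append(
            StageResult(5, STAGE_NAMES[5], {c.protein_id for c in survivors3}, skipped=True)
        )
        report.validate_monotonic()
        return report

    bundle_root = Path(config.bundle_dir)
    survivors4: list[Candidate] = []
    for cand in survivors3:
        bundle = bundle_root / cand.protein_id
        if not bundle.is_dir():
            cand.fail(4, "no prediction bundle")
            continue
        prediction = load_prediction_bundle(bundle, candidate_id=cand.protein_id)
        ligand_matches = scan_chain(prediction.ligand, pattern,
                                    model_id=cand.protein_id)
        if not ligand_matches:
            cand.fail(4, "motif not found on ligand chain of the complex")
            continue
        evidence = gather_evidence(prediction, ligand_matches[0].start, config.groove)
        cand.evidence = evidence
        cand.iptm = prediction.iptm
        if not evidence.groove_contact:
            cand.fail(4, "no groove contact")
        elif evidence.motif_helical is not True:
            cand.fail(4, "motif not helical in complex")
        else:
            cand.passed[4] = True
            survivors4.append(cand)
    report.stages.append(
        StageResult(4, STAGE_NAMES[4], {c.protein_id for c in survivors4})
    )

    reference_iptm = _resolve_reference_iptm(config)
    report.provenance["reference_iptm"] = reference_iptm
    survivors5 = iptm_filter(survivors4, reference_iptm)
    report.stages.append(
        StageResult(5, STAGE_NAMES[5], {c.protein_id for c in survivors5})
    )
    report.validate_monotonic()
    return report


# --------------------------------------------------------------------------
# report serialisation
# --------------------------------------------------------------------------

def write_report(report: FilterReport, path: str | Path, fmt: str = "json") -> Path:
    """Write the funnel report as JSON (full) or TSV (one row per stage)."""
    path = Path(path)
    if fmt == "json":
        payload = {
            "stages": [
                {
                    "stage": s.stage,
                    "name": s.name,
                    "count": s.count,
                    "skipped": s.skipped,
                    "survivors": sorted(s.survivors),
                }
                for s in report.stages
            ],
            "candidates": {
                pid: {
                    "matches": [
                        {"chain": m.chain_id, "start": m.start, "end": m.end,
                         "residues": m.residues}
                        for m in cand.matches
                    ],
                    "ss_labels": cand.ss_labels,
                    "exclusion_stage": cand.exclusion_stage,
                    "exclusion_reason": cand.exclusion_reason,
                    "flags": cand.flags,
                    "iptm": cand.iptm,
                    "orientation": cand.evidence.orientation if cand.evidence else None,
                    "experimental_validation": "pending",
                }
                for pid, cand in sorted(report.candidates.items())
            },
            "config": report.config,
            "provenance": report.provenance,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
    elif fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("stage\tname\tcount\tskipped\tsurvivors\n")
            for s in report.stages:
                fh.write(
                    f"{s.stage}\t{s.name}\t{s.count}\t{s.skipped}"
                    f"\t{','.join(sorted(s.survivors))}\n"
                )
    else:
        raise ValueError(f"unknown report format {fmt!r}")
    return path


def read_report_counts(path: str | Path) -> dict[str, int]:
    """Round-trip helper: stage counts from a JSON report file."""
    with open(path) as fh:
        payload = json.load(fh)
    return {f"stage{s['stage']}": s["count"] for s in payload["stages"]}
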