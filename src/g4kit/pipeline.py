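"""End-to-end analysis: coordinates in, structured topology report out.

Wires the stages together: read → Hoogsteen pairs → tetrads → stack →
GG steps → handedness blocks → junctions → torsions → exchange-protection
prediction, and collects everything into a JSON-serializable report.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

from . import __version__, handedness, tetrad_core, torsions
from .structure_io import Ensemble, StructureModel, read_structure

__all__ = ["AnalysisReport", "analyze", "analyze_model"]


@dataclass
class AnalysisReport:
    structure_id: str
    tables: dict = field(default_factory=dict)
    exchange: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_json(self) -> str:
        doc = {
            "structure_id": self.structure_id,
            **{k: v for k, v in self.tables.items()},
            "exchange_protection": self.exchange,
            "warnings": self.warnings,
            "provenance": self.provenance,
        }
        return json.dumps(doc, indent=1, sort_keys=True)


def analyze_model(model: StructureModel, structure_id: str = "",
                  exclusions: list | None = None) -> AnalysisReport:
    """Run the full topology analysis on one coordinate model."""
    report = AnalysisReport(structure_id=structure_id)
    pairs = tetrad_core.detect_hoogsteen_pairs(model)
    tetrads = tetrad_core.assemble_tetrads(pairs)
    report.tables["hoogsteen_pairs"] = tetrad_core.pair_table(pairs).to_dict("records")
    if not tetrads:
        report.warnings.append("no G-tetrads detected")
        for key in ("tetrads", "steps", "blocks", "junctions", "torsion_summary"):
            report.tables[key] = []
        report.exchange = {"protected": [], "exchanging": []}
        return report
    stack = tetrad_core.order_stack(tetrads, model)
    steps = handedness.enumerate_gg_steps(model, stack)
    blocks = handedness.segment_blocks(steps, stack, model)
    junctions = handedness.detect_junction(blocks, stack, model)
    profile = torsions.backbone_torsions(model)
    report.tables["tetrads"] = tetrad_core.tetrad_table(stack).to_dict("records")
    report.tables["steps"] = handedness.step_table(steps).to_dict("records")
    report.tables["blocks"] = handedness.block_table(blocks).to_dict("records")
    report.tables["junctions"] = handedness.junction_table(junctions).to_dict("records")
    report.tables["torsions"] = torsions.torsion_table(profile).to_dict("records")
    summary = torsions.block_torsion_summary(profile, blocks, stack,
                                             exclusions=exclusions)
    report.tables["torsion_summary"] = summary.to_dict("records")
    part = tetrad_core.predict_exchange_protection(stack)
    report.exchange = {
        cls: [f"{r.chain_id}/{r.label}" for r in rs] for cls, rs in part.items()
    }
    return report


def analyze(source: str, model_index: int = 0, all_models: bool = False,
            exclusions: list | None = None) -> AnalysisReport | list[AnalysisReport]:
    """Analyze a structure file (first model by default, or every model)."""
    ens = read_structure(source)
    checksum = None
    try:
        with open(source, "rb") as fh:
            checksum = hashlib.sha256(fh.read()).hexdigest()[:16]
    except OSError:
        checksum = hashlib.sha256(source.encode()).hexdigest()[:16]
    sid = source if "\n" not in source else "<text>"

    def run(m: StructureModel) -> AnalysisReport:
        rep = analyze_model(m, structure_id=f"{sid}#model{m.model_id}",
                            exclusions=exclusions)
        rep.provenance = {
            "tool": "g4kit", "version": __version__,
            "input_sha256": checksum, "model_id": m.model_id,
        }
        return rep

    if all_models:
        return [run(m) for m in ens.models]
    return run(ens.models[model_index])
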