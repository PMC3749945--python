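"""Batch orchestration: scan structure files, filter, classify, and
characterize interfaces of ID-labelled chains.

The pipeline is a pure function of (input files, configuration, seed):
reruns produce identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .contacts import HBondCriteria, find_hbonds, find_salt_bridges, summarize_contacts
from .filters import FilterConfig, apply_structure_filters
from .rg import ClassifierConfig, RgRecord, chain_record
from .sasa import DEFAULT_N_POINTS, DEFAULT_PROBE, InterfaceSummary, interface_map
from .structure import StructureModel, StructureParseError, partition_complex, read_structure

__all__ = ["RunConfig", "ComplexReport", "ScanResult", "scan", "records_table"]

logger = logging.getLogger("idrg")


@dataclass
class RunConfig:
    inputs: list[str]
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    probe: float = DEFAULT_PROBE
    n_sphere_points: int = DEFAULT_N_POINTS
    hbond: HBondCriteria = field(default_factory=HBondCriteria)
    external_exclusions: list[str] = field(default_factory=list)
    characterize_interfaces: bool = True
    output_dir: str | None = None
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


@dataclass
class ComplexReport:
    structure_id: str
    path: str
    records: list[RgRecord]
    filter_results: dict[str, tuple[bool, list[str]]]
    interfaces: dict[str, InterfaceSummary] = field(default_factory=dict)
    contacts: dict[str, dict] = field(default_factory=dict)


@dataclass
class ScanResult:
    reports: list[ComplexReport]
    skipped: list[tuple[str, str]]  # (path, reason)
    n_id: int
    n_structured: int
    mean_interface_area: float | None
    mean_salt_bridges: float | None
    mean_hbonds: float | None

    @property
    def exit_code(self) -> int:
        if not self.reports:
            return 1
        return 2 if self.skipped else 0


def _structure_paths(inputs: list[str]) -> list[Path]:
    paths: list[Path] = []
    for item in inputs:
        p = Path(item)
        if p.is_dir():
            paths.extend(sorted(q for q in p.iterdir() if q.suffix.lower() in {".pdb", ".ent", ".cif", ".mmcif"}))
        else:
            paths.append(p)
    return paths


def _process_structure(path: Path, config: RunConfig) -> ComplexReport:
    model = read_structure(path)
    report = ComplexReport(structure_id=model.id, path=str(path), records=[], filter_results={})
    filt = apply_structure_filters(model, config.filters, config.external_exclusions)
    report.filter_results = dict(filt.results)
    for chain in model.polymer_chains():
        if not filt.passed(chain.chain_id):
            logger.debug("%s:%s excluded by %s", model.id, chain.chain_id, filt.failing_rules(chain.chain_id))
            continue
        record = chain_record(chain, config.classifier, structure_id=model.id)
        report.records.append(record)
        if record.label == "ID" and config.characterize_interfaces:
            partition = partition_complex(model, chain.chain_id)
            residues, summary = interface_map(
                partition, probe=config.probe, n_points=config.n_sphere_points
            )
            report.interfaces[chain.chain_id] = summary
            bridges = find_salt_bridges(partition)
            hbonds = find_hbonds(partition, config.hbond)
            contact_summary = summarize_contacts(bridges, hbonds, summary.interface_area)
            report.contacts[chain.chain_id] = dataclasses.asdict(contact_summary)
    return report


def scan(config: RunConfig) -> ScanResult:
    """Run the full pipeline over all input structures.

    Per structure: parse → filter → classify each eligible chain against the
    union of the other chains → characterize interfaces and contacts for
    ID-labelled chains. Unreadable files are logged and skipped.
    """
    paths = _structure_paths(config.inputs)
    if not paths:
        raise ValueError("no input structures")
    reports: list[ComplexReport] = []
    skipped: list[tuple[str, str]] = []
    for path in paths:
        try:
            reports.append(_process_structure(path, config))
            logger.info("processed %s", path)
        except (StructureParseError, ValueError) as exc:
            logger.warning("skipping %s: %s", path, exc)
            skipped.append((str(path), str(exc)))
    if not reports:
        raise ValueError("no structure could be processed")

    labels = [r.label for rep in reports for r in rep.records]
    areas = [s.interface_area for rep in reports for s in rep.interfaces.values()]
    sb = [c["n_salt_bridges"] for rep in reports for c in rep.contacts.values()]
    hb = [c["n_hbonds"] for rep in reports for c in rep.contacts.values()]
    result = ScanResult(
        reports=reports,
        skipped=skipped,
        n_id=labels.count("ID"),
        n_structured=labels.count("structured"),
        mean_interface_area=sum(areas) / len(areas) if areas else None,
        mean_salt_bridges=sum(sb) / len(sb) if sb else None,
        mean_hbonds=sum(hb) / len(hb) if hb else None,
    )
    if config.output_dir:
        _write_outputs(result, config)
    return result


def records_table(result: ScanResult) -> pd.DataFrame:
    """Per-chain classification table (structure, chain, N, Rg, statistic,
    label)."""
    rows = [
        {
            "structure_id": r.structure_id,
            "chain_id": r.chain_id,
            "N": r.N,
            "Rg": round(r.Rg, 4),
            "statistic": round(r.statistic, 6),
            "label": r.label,
        }
        for rep in result.reports
        for r in rep.records
    ]
    return pd.DataFrame(rows, columns=["structure_id", "chain_id", "N", "Rg", "statistic", "label"])


def _write_outputs(result: ScanResult, config: RunConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    records_table(result).to_csv(out / "classification.tsv", sep="\t", index=False)
    summary = {
        "n_id": result.n_id,
        "n_structured": result.n_structured,
        "mean_interface_area": result.mean_interface_area,
        "mean_salt_bridges": result.mean_salt_bridges,
        "mean_hbonds": result.mean_hbonds,
        "skipped": result.skipped,
        "seed": config.seed,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    (out / "run_config.json").write_text(config.to_json())
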