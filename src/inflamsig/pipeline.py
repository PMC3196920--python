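"""End-to-end analysis driver.

Runs the full workflow from a flat config: probe collapse →
housekeeping-calibrated thresholds (one per comparison) → differential
expression (patients vs cell lines, patients vs normal tissue) →
gene-list enrichment → stromal/tumour partition → median-split survival
screen.  Every stage writes its table under the output directory; a
``report.json`` summarizes counts and a ``MANIFEST`` records which
stages completed (so a failed run leaves an explicitly incomplete
manifest rather than a silently partial one).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import diffexp as de
from . import signatures as sig
from . import survival as surv
from .io import (
    GeneList,
    bundled_housekeeping_list,
    read_clinical_table,
    read_expression_table,
    read_flag_table,
    read_gene_list,
    read_probe_gene_map,
    collapse_probes_to_genes,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """An analysis stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Flat configuration of a full run (see ``RunConfig.from_yaml``)."""

    expression: str
    expression_groups: str
    outdir: str
    gene_lists: list[str] = field(default_factory=list)
    probe_map: str | None = None
    flags: str | None = None
    flag_groups: str | None = None
    housekeeping: str | None = None
    clinical: str | None = None
    group_patient: str = "patient"
    group_cell_line: str = "cell_line"
    group_muscle: str = "muscle"
    q_threshold: float = 0.01
    t_variant: str = "pooled"
    fc_threshold_override: float | None = None
    signature_target: str = "macrophage"
    signature_backgrounds: list[str] = field(default_factory=list)
    target_present_fraction: float = 1.0
    background_absent_fraction: float = 0.5
    endpoints: list[str] = field(default_factory=lambda: ["EFS", "OVS"])
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate_paths(self) -> None:
        for name in ("expression", "expression_groups", "probe_map", "flags",
                     "flag_groups", "housekeeping", "clinical"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config path {name!r} does not exist: {p}")
        for p in self.gene_lists:
            if not Path(p).exists():
                raise FileNotFoundError(f"gene list does not exist: {p}")


def run_full(config: RunConfig) -> dict:
    """Execute the whole analysis; return the summary report dict.

    Stage order: collapse, thresholds, diffexp (both comparisons),
    signature (if a flag matrix is configured), enrichment (per gene
    list, per comparison), partition (first gene list), survival screen
    (if a clinical table is configured).  On a stage failure the outputs
    produced so far are retained and the MANIFEST marks the run
    incomplete; the error names the stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.validate_paths()
    completed: list[str] = []
    report: dict = {"stages": completed}
    manifest = outdir / "MANIFEST"

    def _finish_manifest(complete: bool) -> None:
        lines = [f"complete: {str(complete).lower()}"] + [f"stage: {s}" for s in completed]
        manifest.write_text("\n".join(lines) + "\n")

    stage = "load"
    try:
        expr = read_expression_table(config.expression, groups=config.expression_groups)

        stage = "collapse"
        if config.probe_map:
            pmap = read_probe_gene_map(config.probe_map)
            expr = collapse_probes_to_genes(expr, pmap)
        completed.append(stage)

        stage = "thresholds"
        housekeeping = (
            read_gene_list(config.housekeeping, name="housekeeping")
            if config.housekeeping
            else bundled_housekeeping_list()
        )
        de_config = de.DiffExpConfig(
            q_threshold=config.q_threshold,
            housekeeping_genes=housekeeping,
            t_variant=config.t_variant,
            fc_threshold_override=config.fc_threshold_override,
        )
        comparisons = {
            "vs_cell_lines": (config.group_patient, config.group_cell_line),
            "vs_muscle": (config.group_patient, config.group_muscle),
        }
        thresholds = {}
        for name, (ga, gb) in comparisons.items():
            if config.fc_threshold_override is not None:
                thresholds[name] = config.fc_threshold_override
            else:
                thresholds[name] = de.housekeeping_threshold(expr, ga, gb, housekeeping)
            logger.info("fold-change threshold %s: %.4f", name, thresholds[name])
        report["fc_thresholds"] = thresholds
        completed.append(stage)

        stage = "diffexp"
        calls = {}
        report["diffexp"] = {}
        for name, (ga, gb) in comparisons.items():
            table = de.diffexp_table(expr, ga, gb, de_config, fc_threshold=thresholds[name])
            calls[name] = table
            de.write_results(table, outdir / f"diffexp_{name}.tsv")
            report["diffexp"][name] = {
                "n_genes": int(len(table)),
                "n_up": int((table["call"] == "up").sum()),
                "n_down": int((table["call"] == "down").sum()),
            }
        completed.append(stage)

        if config.flags:
            stage = "signature"
            flags = read_flag_table(config.flags, groups=config.flag_groups)
            rule = sig.SignatureRule(
                target_group=config.signature_target,
                background_groups=config.signature_backgrounds
                or sorted(set(flags.groups) - {config.signature_target}),
                target_present_fraction=config.target_present_fraction,
                background_absent_fraction=config.background_absent_fraction,
            )
            probes = sig.extract_signature(flags, rule)
            (outdir / "signature_probes.txt").write_text("\n".join(probes) + "\n")
            report["signature"] = {"n_probes": len(probes)}
            completed.append(stage)

        lists = [read_gene_list(p) for p in config.gene_lists]

        if lists:
            stage = "enrichment"
            enrich_rows = []
            report["enrichment"] = {}
            for gl in lists:
                for name, table in calls.items():
                    r = sig.enrichment_test(table, gl)
                    enrich_rows.append({"comparison": name, **vars(r)})
                    report["enrichment"][f"{gl.name}/{name}"] = {
                        "observed_up": r.observed_up,
                        "expected_up": r.expected_up,
                        "observed_down": r.observed_down,
                        "expected_down": r.expected_down,
                        "p_up": r.p_up,
                        "p_down_deficit": r.p_down_deficit,
                    }
            sig.enrichment_to_frame([sig.EnrichmentResult(**{
                k: v for k, v in row.items() if k != "comparison"}) for row in enrich_rows]
            ).assign(comparison=[r["comparison"] for r in enrich_rows]).to_csv(
                outdir / "enrichment.tsv", sep="\t", index=False
            )
            completed.append(stage)

            stage = "partition"
            part = sig.partition_gene_lists(calls["vs_cell_lines"], calls["vs_muscle"], lists[0])
            prefix = outdir / lists[0].name
            part.stromal_derived.write(f"{prefix}.stromal.txt")
            part.tumour_derived.write(f"{prefix}.tumour.txt")
            report["partition"] = {
                "stromal_derived": len(part.stromal_derived),
                "tumour_derived": len(part.tumour_derived),
            }
            completed.append(stage)
        else:
            part = None

        if config.clinical and part is not None:
            stage = "survival"
            clinical = read_clinical_table(config.clinical)
            screen_genes = GeneList(
                "screen", part.stromal_derived.symbols + part.tumour_derived.symbols
            )
            patients = expr.subset_groups([config.group_patient])
            report["survival"] = {}
            if len(screen_genes):
                for endpoint in config.endpoints:
                    table = surv.survival_screen(patients, screen_genes, clinical, endpoint)
                    table.to_csv(outdir / f"survival_{endpoint}.tsv", sep="\t", index=False)
                    top = table.iloc[0]
                    report["survival"][endpoint] = {
                        "n_genes": int(len(table)),
                        "top_gene": str(top["gene"]),
                        "top_p": float(top["p"]),
                    }
            completed.append(stage)
    except Exception as exc:  # noqa: BLE001 - abort cleanly, name the stage
        _finish_manifest(complete=False)
        (outdir / "report.json").write_text(json.dumps(report, indent=1))
        raise StageError(stage, exc) from exc

    _finish_manifest(complete=True)
    (outdir / "report.json").write_text(json.dumps(report, indent=1))
    return report
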