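"""Synthetic study generator with machine-checkable planted ground truth.

Emulates the statistical structure the analysis assumes, at the study's
operating point: a patient cohort (default 44) compared against a tumour
cell-line panel (11) and normal muscle tissue (18), per-gene Gaussian
log2 expression with group-specific shifts for planted differentially
expressed genes, zero-shift housekeeping genes, a present/absent
detection-call matrix with planted cell-type-specific probes, and
survival times whose hazard depends on designated prognostic genes.

The generator favours analytic transparency over realism: no probe-level
effects, no batch structure, no gene-gene correlation.  Every planted
fact is returned in a :class:`SimTruth` sidecar so recovery is
machine-checkable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    ClinicalRecord,
    ExpressionMatrix,
    FlagMatrix,
    GeneList,
    ProbeGeneMap,
    bundled_housekeeping_list,
    write_clinical_table,
    write_group_map,
    write_probe_gene_map,
)

GROUP_PATIENT = "patient"
GROUP_CELL_LINE = "cell_line"
GROUP_MUSCLE = "muscle"


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Group sizes default to the 44/11/18 patient/cell-line/muscle design;
    planted effects are ±``effect_log2`` shifts (default 2.0, a 4-fold
    change) on a residual SD of ``sigma`` (default 0.7 log2 units, a
    typical post-normalization microarray dispersion).  Genes on the
    simulated inflammation list (default size 238) are planted as
    upregulated at ``list_enrichment`` times the background fraction,
    creating a genuinely enriched list.  ``prognostic_genes`` maps gene → log-hazard slope per
    SD of expression (negative = protective).
    """

    n_genes: int = 2000
    n_patients: int = 44
    n_cell_lines: int = 11
    n_muscle: int = 18
    frac_up_vs_cell_lines: float = 0.05
    frac_down_vs_cell_lines: float = 0.03
    frac_up_vs_muscle: float = 0.05
    frac_down_vs_muscle: float = 0.03
    effect_log2: float = 2.0
    sigma: float = 0.7
    n_inflammation_list: int = 238
    list_enrichment: float = 2.0
    stromal_fraction: float = 0.5
    n_housekeeping: int = 14
    prognostic_genes: dict[str, float] = field(default_factory=dict)
    censor_rate: float = 0.05
    event_median_months: float = 40.0
    followup_horizon_months: float = 150.0
    # detection-call (flag) matrix parameters
    n_probes: int = 1000
    n_signature: int = 50
    n_target_samples: int = 2
    background_sizes: dict[str, int] = field(
        default_factory=lambda: {"immune": 16, "normal": 30, "nci60": 20}
    )
    signature_absent_fraction: float = 0.8
    decoy_present_rate: float = 0.5
    flag_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_up_vs_cell_lines", "frac_down_vs_cell_lines",
                     "frac_up_vs_muscle", "frac_down_vs_muscle",
                     "censor_rate", "stromal_fraction", "signature_absent_fraction",
                     "decoy_present_rate", "flag_noise"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        for name in ("n_genes", "n_patients", "n_cell_lines", "n_muscle"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_housekeeping + self.n_inflammation_list > self.n_genes:
            raise ValueError("housekeeping + inflammation list exceed n_genes")
        if self.n_signature > self.n_probes:
            raise ValueError("more signature probes requested than probes")


@dataclass
class SimTruth:
    """Planted ground truth accompanying a synthetic dataset."""

    planted_up_vs_cell_lines: set[str] = field(default_factory=set)
    planted_down_vs_cell_lines: set[str] = field(default_factory=set)
    planted_up_vs_muscle: set[str] = field(default_factory=set)
    planted_down_vs_muscle: set[str] = field(default_factory=set)
    signature_probes: set[str] = field(default_factory=set)
    prognostic_gene_effects: dict[str, float] = field(default_factory=dict)
    inflammation_list: GeneList | None = None
    housekeeping: GeneList | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_up_vs_cell_lines": sorted(self.planted_up_vs_cell_lines),
            "planted_down_vs_cell_lines": sorted(self.planted_down_vs_cell_lines),
            "planted_up_vs_muscle": sorted(self.planted_up_vs_muscle),
            "planted_down_vs_muscle": sorted(self.planted_down_vs_muscle),
            "signature_probes": sorted(self.signature_probes),
            "prognostic_gene_effects": self.prognostic_gene_effects,
            "inflammation_list": list(self.inflammation_list) if self.inflammation_list else [],
            "housekeeping": list(self.housekeeping) if self.housekeeping else [],
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _gene_names(config: SimConfig) -> tuple[list[str], list[str]]:
    """All gene names; the first n_housekeeping carry real housekeeping symbols."""
    hk_symbols = list(bundled_housekeeping_list())[: config.n_housekeeping]
    if len(hk_symbols) < config.n_housekeeping:
        hk_symbols += [f"HK{i:03d}" for i in range(len(hk_symbols), config.n_housekeeping)]
    width = max(4, len(str(config.n_genes)))
    others = [f"G{i:0{width}d}" for i in range(1, config.n_genes - config.n_housekeeping + 1)]
    return hk_symbols + others, hk_symbols


def simulate_expression(config: SimConfig) -> tuple[ExpressionMatrix, SimTruth]:
    """Generate a log2 expression matrix with planted group shifts.

    Model per gene g, sample s:
    ``value = baseline_g + shift_g(group(s)) + Normal(0, sigma)`` with
    baselines Uniform(4, 12).  A gene planted as *up in patients vs X*
    has the ``effect_log2`` shift subtracted from group X (patients stay
    at baseline).  Planting uses exact counts per stratum:
    ``round(frac × pool size)`` genes are drawn without replacement, with
    the up-fraction multiplied by ``list_enrichment`` inside the
    inflammation list, so the planted enrichment factor is realized
    exactly rather than in expectation.  A ``stromal_fraction`` of the
    up-vs-muscle quota is taken from the genes already planted up versus
    cell lines, emulating stromal-derived genes that are elevated in both
    comparisons (the remainder emulates tumour-cell-derived genes, up
    only against normal tissue).
    Housekeeping genes are never planted.  Deterministic under a fixed
    seed.
    """
    rng = np.random.default_rng([config.seed, 1])
    genes, hk_symbols = _gene_names(config)
    non_hk = genes[config.n_housekeeping:]

    # inflammation list membership (uniform draw among non-housekeeping genes)
    inflammation = sorted(
        rng.choice(non_hk, size=config.n_inflammation_list, replace=False).tolist()
    )
    in_list = set(inflammation)

    truth = SimTruth(
        inflammation_list=GeneList("inflammation", inflammation),
        housekeeping=GeneList("housekeeping", hk_symbols),
        prognostic_gene_effects=dict(config.prognostic_genes),
    )

    # exact-count planting per stratum (in-list vs out-of-list), so the
    # planted enrichment factor is realized deterministically
    gene_pos = {g: i for i, g in enumerate(genes)}
    in_genes = [g for g in non_hk if g in in_list]
    out_genes = [g for g in non_hk if g not in in_list]
    shifts_cl = np.zeros(config.n_genes)
    shifts_mu = np.zeros(config.n_genes)

    def plant(pool, frac_up, frac_down, boost, shifts, up_set, down_set, seed_up=()):
        n_up = round(min(frac_up * boost, 1.0) * len(pool))
        n_down = round(frac_down * len(pool))
        if n_up + n_down > len(pool):
            raise ValueError("planted fractions exceed the available genes")
        # stromal-like genes planted up in the previous contrast go first
        forced = list(seed_up)[: round(config.stromal_fraction * n_up)]
        order = [g for g in forced] + [
            g for g in rng.permutation(pool) if g not in set(forced)
        ]
        for g in order[:n_up]:
            shifts[gene_pos[g]] = -config.effect_log2  # background below patients
            up_set.add(g)
        for g in order[n_up : n_up + n_down]:
            shifts[gene_pos[g]] = config.effect_log2
            down_set.add(g)

    for pool, boost in ((in_genes, config.list_enrichment), (out_genes, 1.0)):
        plant(pool, config.frac_up_vs_cell_lines, config.frac_down_vs_cell_lines,
              boost, shifts_cl, truth.planted_up_vs_cell_lines,
              truth.planted_down_vs_cell_lines)
        already_up = [g for g in pool if g in truth.planted_up_vs_cell_lines]
        plant(pool, config.frac_up_vs_muscle, config.frac_down_vs_muscle,
              boost, shifts_mu, truth.planted_up_vs_muscle,
              truth.planted_down_vs_muscle, seed_up=already_up)

    samples = (
        [f"P{i:02d}" for i in range(1, config.n_patients + 1)]
        + [f"CL{i:02d}" for i in range(1, config.n_cell_lines + 1)]
        + [f"MU{i:02d}" for i in range(1, config.n_muscle + 1)]
    )
    groups = pd.Series(
        [GROUP_PATIENT] * config.n_patients
        + [GROUP_CELL_LINE] * config.n_cell_lines
        + [GROUP_MUSCLE] * config.n_muscle,
        index=samples,
    )

    baselines = rng.uniform(4.0, 12.0, size=config.n_genes)
    n_samples = len(samples)
    values = baselines[:, None] + rng.normal(0.0, config.sigma, size=(config.n_genes, n_samples))
    cl_cols = np.array(groups.to_numpy() == GROUP_CELL_LINE)
    mu_cols = np.array(groups.to_numpy() == GROUP_MUSCLE)
    values[:, cl_cols] += shifts_cl[:, None]
    values[:, mu_cols] += shifts_mu[:, None]

    data = pd.DataFrame(values, index=genes, columns=samples)
    return ExpressionMatrix(data, groups), truth


def simulate_flags(config: SimConfig) -> tuple[FlagMatrix, SimTruth]:
    """Generate a detection-call matrix with planted signature probes.

    Signature probes are present in every target-group sample and absent
    in ``ceil(signature_absent_fraction × n)`` samples of each background
    group.  Decoy probes receive i.i.d. calls (present at
    ``decoy_present_rate``, a small marginal rate, absent otherwise); any
    decoy that would satisfy the canonical rule (all-present target,
    ≥50% absent per background) by chance has one target call forced to
    absent, so noiseless recovery is exact by construction.
    ``flag_noise`` then replaces each call with a uniformly random level
    with the given probability.
    """
    rng = np.random.default_rng([config.seed, 2])
    probes = [f"probe{i:04d}" for i in range(1, config.n_probes + 1)]
    signature = probes[: config.n_signature]

    group_labels = ["macrophage"] * config.n_target_samples
    samples = [f"T{i:02d}" for i in range(1, config.n_target_samples + 1)]
    for gname, size in config.background_sizes.items():
        samples += [f"{gname}{i:03d}" for i in range(1, size + 1)]
        group_labels += [gname] * size
    groups = pd.Series(group_labels, index=samples)

    n_samples = len(samples)
    calls = np.empty((config.n_probes, n_samples), dtype=object)

    # decoys: i.i.d. calls, group-independent rates
    marginal_rate = 0.05
    u = rng.uniform(size=(config.n_probes, n_samples))
    calls[u < config.decoy_present_rate] = "present"
    calls[(u >= config.decoy_present_rate) & (u < config.decoy_present_rate + marginal_rate)] = "marginal"
    calls[u >= config.decoy_present_rate + marginal_rate] = "absent"

    target_idx = np.where(groups.to_numpy() == "macrophage")[0]
    bg_indices = {g: np.where(groups.to_numpy() == g)[0] for g in config.background_sizes}

    for i in range(config.n_signature):
        calls[i, target_idx] = "present"
        for g, idx in bg_indices.items():
            n_absent = int(np.ceil(config.signature_absent_fraction * idx.size))
            absent_at = rng.choice(idx, size=n_absent, replace=False)
            rest = np.setdiff1d(idx, absent_at)
            calls[i, absent_at] = "absent"
            calls[i, rest] = "present"

    # force decoys off the canonical rule so noiseless recovery is exact
    for i in range(config.n_signature, config.n_probes):
        all_present = np.all(calls[i, target_idx] == "present")
        if not all_present:
            continue
        bg_ok = all(
            np.mean(calls[i, idx] == "absent") >= 0.5 for idx in bg_indices.values()
        )
        if bg_ok:
            calls[i, target_idx[0]] = "absent"

    if config.flag_noise > 0:
        flip = rng.uniform(size=calls.shape) < config.flag_noise
        random_levels = rng.choice(["present", "marginal", "absent"], size=calls.shape)
        calls = np.where(flip, random_levels, calls)

    flag = FlagMatrix(pd.DataFrame(calls, index=probes, columns=samples), groups)
    truth = SimTruth(signature_probes=set(signature))
    return flag, truth


def simulate_clinical(config: SimConfig, expr: ExpressionMatrix) -> list[ClinicalRecord]:
    """Generate a clinical table whose hazard tracks the prognostic genes.

    Event times are exponential with
    ``log hazard = log(ln 2 / event_median_months) + Σ_g β_g z_g`` where
    ``z_g`` is the patient-standardized expression of prognostic gene g
    (negative β = protective, i.e. high expression lengthens survival).
    Censoring times are Uniform(0, horizon) months and
    ``ovs = min(event, censor)``; an additional Bernoulli(``censor_rate``)
    forced-censoring mechanism (loss to follow-up) censors a subject at
    their censoring time regardless of the event, so ``censor_rate = 1``
    censors every record.  At the defaults this yields roughly 60%
    observed events, matching a paediatric sarcoma cohort with ~5-year
    accrual.  An earlier-event mechanism
    produces EFS ≤ OVS: a fraction of deaths relapse before death and a
    fraction of censored patients are alive with disease.
    """
    rng = np.random.default_rng([config.seed, 3])
    patients = expr.samples_in_group(GROUP_PATIENT)
    if not patients:
        raise ValueError("expression matrix has no patient samples")
    missing = [g for g in config.prognostic_genes if g not in expr.data.index]
    if missing:
        raise ValueError(f"prognostic genes absent from matrix: {missing}")

    log_hazard = np.full(len(patients), np.log(np.log(2.0) / config.event_median_months))
    for gene, beta in config.prognostic_genes.items():
        x = expr.data.loc[gene, patients].to_numpy(dtype=float)
        z = (x - x.mean()) / (x.std(ddof=0) or 1.0)
        log_hazard += beta * z

    event_t = rng.exponential(1.0 / np.exp(log_hazard))
    censor_t = rng.uniform(0.0, config.followup_horizon_months, size=len(patients))
    forced = rng.uniform(size=len(patients)) < config.censor_rate

    records = []
    for i, sid in enumerate(patients):
        if forced[i] or censor_t[i] < event_t[i]:
            ovs = censor_t[i]
            dead = False
        else:
            ovs = event_t[i]
            dead = True
        ovs = max(round(float(ovs), 1), 0.1)
        if dead:
            status = "Dead"
            efs = round(ovs * rng.uniform(0.3, 1.0), 1) if rng.uniform() < 0.5 else ovs
        elif rng.uniform() < 0.15:  # alive with disease: relapse before follow-up end
            status = "AWD"
            efs = round(ovs * rng.uniform(0.3, 1.0), 1)
        else:
            status = "NED"
            efs = ovs
        efs = min(max(efs, 0.1), ovs)
        records.append(
            ClinicalRecord(
                sample_code=sid,
                diagnosis=rng.choice(["Ewing", "PNET", "Askin"], p=[32 / 44, 10 / 44, 2 / 44]),
                state=rng.choice(["Primary", "Recurrence", "Metastasis"], p=[32 / 44, 5 / 44, 7 / 44]),
                age=int(rng.integers(4, 35)),
                sex=rng.choice(["M", "F"], p=[28 / 44, 16 / 44]),
                efs=float(efs),
                ovs=float(ovs),
                status=status,
                pretreated=bool(rng.uniform() < 15 / 44),
            )
        )
    return records


def write_study(outdir: str | Path, config: SimConfig) -> dict[str, Path]:
    """Materialize a complete toy study directory.

    Writes the expression matrix + group map, flag matrix + group map, an
    identity probe→gene map, the inflammation and housekeeping gene
    lists, a clinical table, and the planted-truth sidecar.  Returns the
    paths keyed by role.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expr, truth = simulate_expression(config)
    flags, flag_truth = simulate_flags(config)
    truth.signature_probes = flag_truth.signature_probes
    clinical = simulate_clinical(config, expr)

    paths = {
        "expression": outdir / "expression.tsv",
        "expression_groups": outdir / "expression_groups.tsv",
        "flags": outdir / "flags.tsv",
        "flag_groups": outdir / "flag_groups.tsv",
        "probe_map": outdir / "probe_map.tsv",
        "inflammation": outdir / "inflammation.txt",
        "housekeeping": outdir / "housekeeping.txt",
        "clinical": outdir / "clinical.tsv",
        "truth": outdir / "truth.json",
    }
    expr.write_tsv(paths["expression"], group_path=paths["expression_groups"])
    flags.write_tsv(paths["flags"], group_path=paths["flag_groups"])
    write_probe_gene_map(ProbeGeneMap.identity(expr.row_ids), paths["probe_map"])
    truth.inflammation_list.write(paths["inflammation"])
    truth.housekeeping.write(paths["housekeeping"])
    write_clinical_table(clinical, paths["clinical"])
    truth.to_json(paths["truth"])
    return paths
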