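"""Cell-type signatures from detection calls, gene-list enrichment, and
stromal/tumour partitioning of differential calls.

A *signature* is the set of probes whose detection pattern is specific to
one cell type: present in (a configurable fraction of) the target-group
samples and absent in at least a configurable fraction of every
background panel.  Enrichment of a curated gene list among differential
calls is quantified by observed-versus-expected counts and Fisher's exact
test.  Finally, genes of an inflammation list called up against a tumour
cell-line panel and/or against normal surrounding tissue are partitioned
into stromal-derived (up in both comparisons: the signal disappears in
pure tumour cell lines, so it must come from infiltrating/stromal cells)
versus tumour-cell-derived (up only against normal tissue) lists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import FlagMatrix, GeneList, ProbeGeneMap


@dataclass
class SignatureRule:
    """Detection-call filter defining a cell-type-specific signature.

    target_present_fraction
        Minimum fraction of target-group samples in which a probe must be
        flagged present (default 1.0: present in every target sample).
    background_absent_fraction
        Minimum fraction of *each* background group in which the probe
        must be flagged absent (default 0.5).

    Marginal calls count neither as present (target rule) nor as absent
    (background rule) — the conservative reading in both directions.
    """

    target_group: str
    background_groups: list[str]
    target_present_fraction: float = 1.0
    background_absent_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not self.background_groups:
            raise ValueError("at least one background group required")
        for f in (self.target_present_fraction, self.background_absent_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")


@dataclass
class EnrichmentResult:
    """Observed vs expected differential calls within a gene list.

    ``p_up``/``p_down`` are one-sided Fisher exact p-values for
    over-representation of up/down calls in the list;
    ``p_up_deficit``/``p_down_deficit`` test the opposite tail
    (under-representation), so both readings of a depletion are
    available.
    """

    list_name: str
    n_list_in_universe: int
    n_universe: int
    total_up: int
    total_down: int
    observed_up: int
    expected_up: float
    observed_down: int
    expected_down: float
    p_up: float
    p_down: float
    p_up_deficit: float
    p_down_deficit: float


@dataclass
class PartitionResult:
    """Disjoint split of a gene list into stromal- and tumour-derived members."""

    stromal_derived: GeneList
    tumour_derived: GeneList

    def __post_init__(self) -> None:
        overlap = set(self.stromal_derived.symbols) & set(self.tumour_derived.symbols)
        if overlap:
            raise ValueError(f"partition lists overlap: {sorted(overlap)}")


def extract_signature(flags: FlagMatrix, rule: SignatureRule) -> list[str]:
    """Probes whose detection pattern matches a cell-type signature rule.

    A probe is retained iff the fraction of *present* calls in the target
    group is at least ``target_present_fraction`` and, for every
    background group separately, the fraction of *absent* calls is at
    least ``background_absent_fraction`` (both comparisons inclusive).
    """
    target_cols = flags.samples_in_group(rule.target_group)
    if not target_cols:
        raise ValueError(f"target group {rule.target_group!r} has no samples")
    present = flags.calls[target_cols].to_numpy() == "present"
    keep = present.mean(axis=1) >= rule.target_present_fraction
    for bg in rule.background_groups:
        bg_cols = flags.samples_in_group(bg)
        if not bg_cols:
            raise ValueError(f"background group {bg!r} has no samples")
        absent = flags.calls[bg_cols].to_numpy() == "absent"
        keep &= absent.mean(axis=1) >= rule.background_absent_fraction
    return [p for p, k in zip(flags.calls.index, keep) if k]


def signature_to_genes(probes: list[str], pmap: ProbeGeneMap, name: str = "signature") -> GeneList:
    """Lift a probe-level signature to gene level.

    Every gene that any selected probe is annotated to (even ambiguously)
    is included.
    """
    genes: list[str] = []
    seen: set[str] = set()
    for probe in probes:
        for gene in sorted(pmap.genes.get(probe, ())):
            if gene not in seen:
                seen.add(gene)
                genes.append(gene)
    return GeneList(name, genes)


def _fisher(n_in_hit: int, n_in: int, n_hit: int, n_universe: int) -> tuple[float, float]:
    """One-sided Fisher p-values (excess, deficit) for a 2×2 membership table."""
    table = [
        [n_in_hit, n_in - n_in_hit],
        [n_hit - n_in_hit, (n_universe - n_in) - (n_hit - n_in_hit)],
    ]
    p_excess = stats.fisher_exact(table, alternative="greater")[1]
    p_deficit = stats.fisher_exact(table, alternative="less")[1]
    return float(p_excess), float(p_deficit)


def enrichment_test(calls: pd.DataFrame, gene_list: GeneList) -> EnrichmentResult:
    """Observed-vs-expected enrichment of a gene list among differential calls.

    ``calls`` is a differential-expression result table covering the gene
    universe (every tested gene, one row each).  The list is intersected
    with the universe first; expected counts are the list size times the
    universe-wide up (resp. down) call fraction.  Fisher p-values are
    one-sided: ``p_up``/``p_down`` toward over-representation of the
    respective call inside the list, the ``*_deficit`` fields toward
    under-representation.
    """
    universe = set(calls["gene"])
    members = [g for g in gene_list if g in universe]
    if not members:
        raise ValueError(
            f"gene list {gene_list.name!r} has no overlap with the tested universe"
        )
    n_universe = len(universe)
    n_in = len(members)
    in_list = calls["gene"].isin(set(members))
    total_up = int((calls["call"] == "up").sum())
    total_down = int((calls["call"] == "down").sum())
    observed_up = int(((calls["call"] == "up") & in_list).sum())
    observed_down = int(((calls["call"] == "down") & in_list).sum())
    p_up, p_up_def = _fisher(observed_up, n_in, total_up, n_universe)
    p_down, p_down_def = _fisher(observed_down, n_in, total_down, n_universe)
    return EnrichmentResult(
        list_name=gene_list.name,
        n_list_in_universe=n_in,
        n_universe=n_universe,
        total_up=total_up,
        total_down=total_down,
        observed_up=observed_up,
        expected_up=n_in * total_up / n_universe,
        observed_down=observed_down,
        expected_down=n_in * total_down / n_universe,
        p_up=p_up,
        p_down=p_down,
        p_up_deficit=p_up_def,
        p_down_deficit=p_down_def,
    )


def partition_gene_lists(
    calls_vs_cell_lines: pd.DataFrame,
    calls_vs_muscle: pd.DataFrame,
    gene_list: GeneList,
) -> PartitionResult:
    """Split list genes called up vs normal tissue by their cell-line behaviour.

    *Stromal-derived*: up in the patient-vs-cell-line comparison **and**
    up in the patient-vs-muscle comparison — the signal vanishes in pure
    tumour cell lines, implicating infiltrating immune/stromal cells.
    *Tumour-derived*: up vs muscle but **not** up vs cell lines — the
    malignant cells themselves carry the signal.  Genes absent from
    either universe are excluded with a warning.
    """
    up_cl = set(calls_vs_cell_lines.loc[calls_vs_cell_lines["call"] == "up", "gene"])
    up_mu = set(calls_vs_muscle.loc[calls_vs_muscle["call"] == "up", "gene"])
    uni_cl = set(calls_vs_cell_lines["gene"])
    uni_mu = set(calls_vs_muscle["gene"])

    missing = [g for g in gene_list if g not in uni_cl or g not in uni_mu]
    if missing:
        warnings.warn(
            f"{len(missing)} list gene(s) absent from a comparison universe, excluded",
            stacklevel=2,
        )
    considered = [g for g in gene_list if g in uni_cl and g in uni_mu]
    stromal = [g for g in considered if g in up_mu and g in up_cl]
    tumour = [g for g in considered if g in up_mu and g not in up_cl]
    return PartitionResult(
        stromal_derived=GeneList(f"{gene_list.name}.stromal", stromal),
        tumour_derived=GeneList(f"{gene_list.name}.tumour", tumour),
    )


def enrichment_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Tabulate enrichment results (one row per tested list)."""
    return pd.DataFrame([vars(r) for r in results])
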