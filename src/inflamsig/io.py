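"""Readers, writers and domain containers for expression studies.

Containers wrap :class:`pandas.DataFrame`/:class:`pandas.Series` and
validate their invariants on construction.  File formats are deliberately
plain: tab-separated matrices with a header row of sample identifiers
(optionally wrapped in GEO Series-Matrix table fences), one-symbol-per-line
gene lists, and delimited clinical tables accepting both decimal points and
decimal commas.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FLAG_LEVELS = ("present", "marginal", "absent")
#: Short MAS5-style codes used on disk.
FLAG_CODES = {"P": "present", "M": "marginal", "A": "absent"}

VALID_STATUS = ("Dead", "NED", "AWD")
VALID_DIAGNOSIS = ("Ewing", "PNET", "Askin")
VALID_STATE = ("Primary", "Recurrence", "Metastasis")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """log2-scale expression values, rows = probe sets or genes, columns = samples.

    Parameters
    ----------
    data
        Numeric frame indexed by row identifier with sample identifiers as
        columns.  Values are assumed already normalized to log2 scale
        (e.g. RMA output); no transformation is applied here.
    groups
        Series mapping every sample identifier to a group label such as
        ``"patient"``, ``"cell_line"`` or ``"muscle"``.
    """

    data: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate row ids: {dupes}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        arr = self.data.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if not np.isfinite(arr).all():
            r, c = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite value at row {self.data.index[r]!r}, "
                f"sample {self.data.columns[c]!r}"
            )
        self.groups = pd.Series(self.groups)
        missing = self.data.columns.difference(self.groups.index)
        if len(missing):
            raise ValueError(f"samples without group label: {missing.tolist()}")
        self.groups = self.groups.loc[self.data.columns]

    @property
    def row_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    def samples_in_group(self, group: str) -> list[str]:
        return self.groups.index[self.groups == group].tolist()

    def subset_groups(self, groups: Sequence[str]) -> "ExpressionMatrix":
        cols = self.groups.index[self.groups.isin(groups)]
        return ExpressionMatrix(self.data[cols], self.groups.loc[cols])

    def write_tsv(self, path: str | Path, *, group_path: str | Path | None = None) -> None:
        """Write the matrix (and optionally the sample→group map) as TSV.

        The plain dialect round-trips bit-identically: values are written
        with :func:`repr`-faithful float formatting.
        """
        path = Path(path)
        with path.open("w") as fh:
            fh.write("id\t" + "\t".join(map(str, self.data.columns)) + "\n")
            for rid, row in zip(self.data.index, self.data.to_numpy()):
                # repr() of a float round-trips exactly through float()
                fh.write(str(rid) + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
        if group_path is not None:
            write_group_map(self.groups, group_path)


@dataclass
class FlagMatrix:
    """MAS5-style detection calls (present/marginal/absent) per probe × sample."""

    calls: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.calls.index.has_duplicates:
            raise ValueError("duplicate probe ids in flag matrix")
        bad = set(np.unique(self.calls.to_numpy())) - set(FLAG_LEVELS)
        if bad:
            raise ValueError(f"invalid detection calls: {sorted(bad)}")
        self.groups = pd.Series(self.groups)
        missing = self.calls.columns.difference(self.groups.index)
        if len(missing):
            raise ValueError(f"samples without group label: {missing.tolist()}")
        self.groups = self.groups.loc[self.calls.columns]

    @property
    def row_ids(self) -> list[str]:
        return self.calls.index.tolist()

    def samples_in_group(self, group: str) -> list[str]:
        return self.groups.index[self.groups == group].tolist()

    def write_tsv(self, path: str | Path, *, group_path: str | Path | None = None) -> None:
        rev = {v: k for k, v in FLAG_CODES.items()}
        coded = self.calls.replace(rev)
        coded.index.name = "id"
        coded.to_csv(path, sep="\t")
        if group_path is not None:
            write_group_map(self.groups, group_path)


@dataclass
class GeneList:
    """A named, ordered, duplicate-free collection of gene symbols."""

    name: str
    symbols: list[str]

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError(f"gene list {self.name!r} contains duplicates")

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self):
        return iter(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol in set(self.symbols)

    def write(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.symbols) + "\n")


@dataclass
class ProbeGeneMap:
    """Probe set → gene symbol annotation.

    A probe is *unique* when it is annotated to exactly one gene; unique
    probes take priority when a gene's representative probe is chosen.
    """

    genes: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for probe, syms in self.genes.items():
            if not syms:
                raise ValueError(f"probe {probe!r} maps to no gene")
            self.genes[probe] = frozenset(syms)

    def is_unique(self, probe: str) -> bool:
        return len(self.genes[probe]) == 1

    @classmethod
    def identity(cls, ids: Iterable[str]) -> "ProbeGeneMap":
        """Map every identifier to itself (already gene-level matrices)."""
        return cls({i: frozenset([i]) for i in ids})

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Iterable[str]]) -> "ProbeGeneMap":
        return cls({p: frozenset([g] if isinstance(g, str) else g) for p, g in mapping.items()})


@dataclass
class ClinicalRecord:
    """One patient row of a clinical follow-up table.

    ``efs``/``ovs`` are event-free and overall survival in months measured
    from diagnosis; ``status`` is the state at last follow-up (``Dead``,
    ``NED`` = no evidence of disease, ``AWD`` = alive with disease).
    """

    sample_code: str
    diagnosis: str
    state: str
    age: float
    sex: str
    efs: float
    ovs: float
    status: str
    pretreated: bool

    def __post_init__(self) -> None:
        if self.diagnosis not in VALID_DIAGNOSIS:
            raise ValueError(f"{self.sample_code}: unknown diagnosis {self.diagnosis!r}")
        if self.state not in VALID_STATE:
            raise ValueError(f"{self.sample_code}: unknown state {self.state!r}")
        if self.status not in VALID_STATUS:
            raise ValueError(f"{self.sample_code}: unknown status code {self.status!r}")
        if self.sex not in ("M", "F"):
            raise ValueError(f"{self.sample_code}: unknown sex {self.sex!r}")
        if self.age <= 0:
            raise ValueError(f"{self.sample_code}: age must be positive")
        if self.efs < 0 or self.ovs < 0:
            raise ValueError(f"{self.sample_code}: months must be non-negative")
        if self.efs > self.ovs:
            raise ValueError(
                f"{self.sample_code}: event-free survival ({self.efs}) exceeds "
                f"overall survival ({self.ovs})"
            )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_group_map(path: str | Path) -> pd.Series:
    """Read a two-column ``sample_id<TAB>group`` sidecar file."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "group"], comment="#", dtype=str)
    return pd.Series(df["group"].to_numpy(), index=df["sample"].to_numpy())


def write_group_map(groups: pd.Series, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for sample, group in groups.items():
            fh.write(f"{sample}\t{group}\n")


def _series_matrix_payload(lines: list[str]) -> list[str]:
    """Extract the fenced table of a GEO Series-Matrix style file."""
    try:
        start = next(i for i, l in enumerate(lines) if l.startswith("!series_matrix_table_begin"))
        end = next(i for i, l in enumerate(lines) if l.startswith("!series_matrix_table_end"))
    except StopIteration:
        raise ValueError("series_matrix dialect requires begin/end table fences") from None
    return lines[start + 1 : end]


def read_expression_table(
    path: str | Path,
    dialect: str = "plain_tsv",
    *,
    groups: str | Path | pd.Series | Mapping[str, str],
) -> ExpressionMatrix:
    """Read a tab-delimited log2 expression matrix.

    Parameters
    ----------
    path
        Matrix file: first column row identifiers, remaining columns one
        per sample, header row required.
    dialect
        ``"plain_tsv"`` or ``"series_matrix"`` (table fenced by
        ``!series_matrix_table_begin`` / ``!series_matrix_table_end``;
        lines outside the fence are ignored, quoted ids are unquoted).
    groups
        Sample→group mapping, or the path of a two-column sidecar file.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if dialect == "series_matrix":
        lines = _series_matrix_payload(lines)
    elif dialect != "plain_tsv":
        raise ValueError(f"unknown dialect {dialect!r}")

    if not lines:
        raise ValueError(f"{path}: empty matrix")
    header = [c.strip().strip('"') for c in lines[0].split("\t")]
    sample_ids = header[1:]
    row_ids: list[str] = []
    values: list[list[float]] = []
    seen: set[str] = set()
    for line in lines[1:]:
        if not line.strip():
            continue
        cells = line.split("\t")
        rid = cells[0].strip().strip('"')
        if rid in seen:
            raise ValueError(f"{path}: duplicate row id {rid!r}")
        seen.add(rid)
        if len(cells) - 1 != len(sample_ids):
            raise ValueError(f"{path}: row {rid!r} has {len(cells) - 1} values, expected {len(sample_ids)}")
        row = []
        for j, cell in enumerate(cells[1:]):
            try:
                row.append(float(cell))
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric value {cell!r} at row {rid!r}, column {sample_ids[j]!r}"
                ) from None
        row_ids.append(rid)
        values.append(row)

    data = pd.DataFrame(values, index=row_ids, columns=sample_ids, dtype=float)
    if isinstance(groups, (str, Path)):
        groups = read_group_map(groups)
    elif isinstance(groups, Mapping):
        groups = pd.Series(groups)
    return ExpressionMatrix(data, groups)


def read_flag_table(
    path: str | Path, *, groups: str | Path | pd.Series | Mapping[str, str]
) -> FlagMatrix:
    """Read a detection-call matrix coded P/M/A (or spelled-out levels)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    calls = df.apply(lambda col: col.map(lambda v: FLAG_CODES.get(v, v)))
    if isinstance(groups, (str, Path)):
        groups = read_group_map(groups)
    elif isinstance(groups, Mapping):
        groups = pd.Series(groups)
    return FlagMatrix(calls, pd.Series(groups))


def read_gene_list(path: str | Path, name: str | None = None) -> GeneList:
    """Read a one-symbol-per-line gene list; ``#`` comments and blank lines allowed.

    Duplicates are removed (first occurrence kept) with a warning; an
    empty file is a hard error.
    """
    path = Path(path)
    symbols: list[str] = []
    seen: set[str] = set()
    n_dupes = 0
    for line in path.read_text().splitlines():
        sym = line.strip()
        if not sym or sym.startswith("#"):
            continue
        if sym in seen:
            n_dupes += 1
            continue
        seen.add(sym)
        symbols.append(sym)
    if not symbols:
        raise ValueError(f"{path}: gene list is empty")
    if n_dupes:
        warnings.warn(f"{path}: removed {n_dupes} duplicate symbol(s)", stacklevel=2)
    return GeneList(name or path.stem, symbols)


def read_probe_gene_map(path: str | Path) -> ProbeGeneMap:
    """Read a two-column ``probe<TAB>gene[,gene...]`` annotation file."""
    entries: dict[str, frozenset[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        probe, genes = line.split("\t")
        entries[probe.strip()] = frozenset(g.strip() for g in genes.split(",") if g.strip())
    return ProbeGeneMap(entries)


def write_probe_gene_map(pmap: ProbeGeneMap, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for probe in sorted(pmap.genes):
            fh.write(f"{probe}\t{','.join(sorted(pmap.genes[probe]))}\n")


def _parse_months(cell: str, *, context: str) -> float:
    """Parse a months value accepting both ``11.7`` and ``11,7``."""
    try:
        return float(str(cell).strip().replace(",", "."))
    except ValueError:
        raise ValueError(f"{context}: cannot parse months value {cell!r}") from None


_PRETREATED = {"+": True, "-": False, "−": False, "true": True, "false": False,
               "yes": True, "no": False, "1": True, "0": False}


def read_clinical_table(path: str | Path) -> list[ClinicalRecord]:
    """Read a patient follow-up table.

    Expects a delimited file (tab or comma) with header columns
    ``sample, diagnosis, state, age, sex, efs, ovs, status, pretreated``.
    Month columns accept decimal commas (as printed in many European
    clinical tables).  Rows violating ``efs <= ovs`` are hard errors.
    """
    path = Path(path)
    sep = "\t" if "\t" in path.read_text().splitlines()[0] else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"sample", "diagnosis", "state", "age", "sex", "efs", "ovs", "status", "pretreated"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing clinical columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        code = str(row["sample"]).strip()
        pre_raw = str(row["pretreated"]).strip().lower()
        if pre_raw not in _PRETREATED:
            raise ValueError(f"{code}: cannot parse pretreated flag {row['pretreated']!r}")
        records.append(
            ClinicalRecord(
                sample_code=code,
                diagnosis=str(row["diagnosis"]).strip(),
                state=str(row["state"]).strip(),
                age=float(str(row["age"]).replace(",", ".")),
                sex=str(row["sex"]).strip(),
                efs=_parse_months(row["efs"], context=code),
                ovs=_parse_months(row["ovs"], context=code),
                status=str(row["status"]).strip(),
                pretreated=_PRETREATED[pre_raw],
            )
        )
    return records


def write_clinical_table(records: Sequence[ClinicalRecord], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("sample\tdiagnosis\tstate\tage\tsex\tefs\tovs\tstatus\tpretreated\n")
        for r in records:
            fh.write(
                f"{r.sample_code}\t{r.diagnosis}\t{r.state}\t{r.age:g}\t{r.sex}\t"
                f"{r.efs:g}\t{r.ovs:g}\t{r.status}\t{'+' if r.pretreated else '-'}\n"
            )


def bundled_clinical_table() -> list[ClinicalRecord]:
    """The 44-patient Ewing-sarcoma-family clinical table shipped with the package."""
    with resources.as_file(resources.files("inflamsig").joinpath("data/esft_clinical.tsv")) as p:
        return read_clinical_table(p)


def bundled_housekeeping_list() -> GeneList:
    """The 14 ribosomal/constitutive housekeeping genes used for threshold calibration."""
    with resources.as_file(resources.files("inflamsig").joinpath("data/housekeeping.txt")) as p:
        return read_gene_list(p, name="housekeeping")


# ---------------------------------------------------------------------------
# probe collapsing
# ---------------------------------------------------------------------------


def collapse_probes_to_genes(expr: ExpressionMatrix, pmap: ProbeGeneMap) -> ExpressionMatrix:
    """Collapse a probe-level matrix to one representative probe per gene.

    For each gene the representative is chosen among its *uniquely*
    mapping probes whenever at least one exists (unique probes take
    strict priority); otherwise among all annotated probes.  Within the
    eligible pool the probe with the highest mean expression across all
    samples wins; mean ties break lexicographically by probe id for
    determinism.  Probes absent from the annotation are dropped with a
    logged count.
    """
    known = [p for p in expr.data.index if p in pmap.genes]
    n_dropped = len(expr.data.index) - len(known)
    if not known:
        raise ValueError("no probe of the expression matrix is present in the annotation")
    if n_dropped:
        logger.info("collapse_probes_to_genes: dropped %d unannotated probe(s)", n_dropped)

    means = expr.data.loc[known].mean(axis=1)
    candidates: dict[str, list[str]] = {}
    for probe in known:
        for gene in pmap.genes[probe]:
            candidates.setdefault(gene, []).append(probe)

    rep: dict[str, str] = {}
    for gene, probes in candidates.items():
        unique = [p for p in probes if pmap.is_unique(p)]
        pool = unique if unique else probes
        # highest mean wins; ties resolved by lexicographic probe id
        rep[gene] = min(pool, key=lambda p: (-means[p], p))

    genes = sorted(rep)
    data = expr.data.loc[[rep[g] for g in genes]].copy()
    data.index = genes
    return ExpressionMatrix(data, expr.groups)
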