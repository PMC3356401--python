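"""Genotype-frequency tables and case/control genotype-matrix simulation.

The starting point of a barcode search is a per-SNP table of genotype
counts for cases and controls (three genotype categories per biallelic
SNP, coded 1/2/3).  Published association studies typically report only
these marginal counts, so individual-level matrices are simulated:
counts are first normalized so every SNP has the same group size, then
each column of the genotype matrix is an exact random permutation of the
normalized count multiset.  Columns are mutually independent given their
margins; no linkage or Hardy-Weinberg structure is imposed.

The 23-SNP steroid-hormone-pathway table used throughout the package's
examples ships as a named fixture (:func:`load_steroid_snps`).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SnpRecord",
    "GenotypeFrequencyTable",
    "GenotypeDataset",
    "FormatError",
    "normalize_counts",
    "simulate_group",
    "simulate_dataset",
    "load_steroid_snps",
    "read_frequency_table",
    "write_frequency_table",
    "read_dataset",
    "write_dataset",
]

N_GENOTYPES = 3
DEFAULT_GROUP_SIZE = 5000

#: Fixture name -> resource file, for tables installed with the package.
_BUNDLED_TABLES = {"steroid": "steroid_hormone_snps.csv"}


class FormatError(ValueError):
    """Raised when a delimited input file violates the expected format.

    Carries the 1-based ``line`` number when the problem is local to one
    line of the file.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class SnpRecord:
    """Genotype counts of one SNP in cases and controls."""

    index: int
    rs_id: str
    gene: str
    genotype_labels: tuple[str, str, str]
    case_counts: tuple[int, int, int]
    control_counts: tuple[int, int, int]

    def __post_init__(self) -> None:
        for counts in (self.case_counts, self.control_counts):
            if len(counts) != N_GENOTYPES:
                raise ValueError(f"{self.rs_id}: expected {N_GENOTYPES} genotype counts")
            if any(c < 0 for c in counts):
                raise ValueError(f"{self.rs_id}: negative genotype count")
        if len(set(self.genotype_labels)) != N_GENOTYPES:
            raise ValueError(f"{self.rs_id}: genotype labels must be distinct")


@dataclass(frozen=True)
class GenotypeFrequencyTable:
    """Ordered collection of per-SNP genotype counts for both groups."""

    snps: tuple[SnpRecord, ...]
    group_size: int = DEFAULT_GROUP_SIZE

    def __post_init__(self) -> None:
        if self.group_size <= 0:
            raise ValueError("group_size must be positive")
        ids = [s.rs_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("SNP identifiers must be unique")

    @property
    def n_snp(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> tuple[str, ...]:
        return tuple(s.rs_id for s in self.snps)

    def is_normalized(self) -> bool:
        return all(
            sum(s.case_counts) == self.group_size and sum(s.control_counts) == self.group_size
            for s in self.snps
        )

    def normalized(self, group_size: int | None = None) -> "GenotypeFrequencyTable":
        """Return a copy whose counts sum to ``group_size`` in every SNP/group.

        Uses largest-remainder allocation per SNP and group; already-exact
        counts pass through unchanged (idempotent).
        """
        target = self.group_size if group_size is None else group_size
        snps = tuple(
            SnpRecord(
                index=s.index,
                rs_id=s.rs_id,
                gene=s.gene,
                genotype_labels=s.genotype_labels,
                case_counts=normalize_counts(s.case_counts, target),
                control_counts=normalize_counts(s.control_counts, target),
            )
            for s in self.snps
        )
        return GenotypeFrequencyTable(snps=snps, group_size=target)


@dataclass(frozen=True)
class GenotypeDataset:
    """Individual-level genotype matrices for cases and controls.

    Rows are individuals, columns SNPs; entries are genotype codes in
    {1, 2, 3}.
    """

    case_matrix: np.ndarray
    control_matrix: np.ndarray
    snp_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        for name, m in (("case", self.case_matrix), ("control", self.control_matrix)):
            if m.ndim != 2:
                raise ValueError(f"{name} matrix must be 2-D")
            if m.shape[1] != len(self.snp_ids):
                raise ValueError(f"{name} matrix width does not match snp_ids")
            if m.size and (m.min() < 1 or m.max() > 3):
                raise ValueError(f"{name} matrix contains genotype codes outside {{1,2,3}}")

    @property
    def n_case(self) -> int:
        return self.case_matrix.shape[0]

    @property
    def n_control(self) -> int:
        return self.control_matrix.shape[0]

    @property
    def n_snp(self) -> int:
        return len(self.snp_ids)


def normalize_counts(raw_counts: Sequence[int], target_size: int) -> tuple[int, int, int]:
    """Rescale three genotype counts so they sum exactly to ``target_size``.

    Largest-remainder (Hamilton) apportionment: each category receives
    ``floor(target * count / total)`` and the leftover units go to the
    categories with the largest fractional remainders.  Exact rational
    arithmetic; deterministic, with index order breaking remainder ties.
    """
    counts = list(raw_counts)
    if len(counts) != N_GENOTYPES:
        raise ValueError(f"expected {N_GENOTYPES} counts, got {len(counts)}")
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    total = sum(counts)
    if total == 0:
        raise ValueError("all-zero genotype counts: empty SNP cannot be normalized")
    if target_size <= 0:
        raise ValueError("target_size must be positive")
    floors = [c * target_size // total for c in counts]
    # remainder of c*target/total, as an exact integer numerator
    remainders = [c * target_size - f * total for c, f in zip(counts, floors)]
    short = target_size - sum(floors)
    order = sorted(range(N_GENOTYPES), key=lambda k: (-remainders[k], k))
    for k in order[:short]:
        floors[k] += 1
    return tuple(floors)


def simulate_group(
    column_counts: Sequence[int], n: int, rng: np.random.Generator
) -> np.ndarray:
    """Random genotype column with exactly ``column_counts[g-1]`` copies of g.

    The column is a uniform shuffle of the fixed genotype multiset, so the
    tabulated margins are exact for every draw.
    """
    counts = list(column_counts)
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be non-negative")
    if sum(counts) != n:
        raise ValueError(f"counts sum to {sum(counts)}, expected {n}")
    column = np.repeat(np.arange(1, N_GENOTYPES + 1, dtype=np.int8), counts)
    rng.shuffle(column)
    return column


def simulate_dataset(
    table: GenotypeFrequencyTable,
    seed: int | np.random.SeedSequence = 0,
    n_case: int | None = None,
    n_control: int | None = None,
) -> GenotypeDataset:
    """Simulate case/control genotype matrices matching the table's margins.

    Each column is drawn by :func:`simulate_group` from its own child
    random stream keyed on ``(seed, group, column)``, so adding SNPs to the
    table never perturbs the columns already simulated, and every column's
    genotype tabulation equals the table's counts exactly.

    ``n_case``/``n_control`` default to the table's group size; when given,
    the table counts are re-normalized per group to that size first.
    """
    if not isinstance(seed, np.random.SeedSequence):
        seed = np.random.SeedSequence(int(seed))
    n_case = table.group_size if n_case is None else n_case
    n_control = table.group_size if n_control is None else n_control
    if not table.is_normalized():
        raise ValueError("table must be normalized before simulation; call .normalized()")

    def build(group: int, n: int) -> np.ndarray:
        matrix = np.empty((n, table.n_snp), dtype=np.int8)
        for j, snp in enumerate(table.snps):
            counts = snp.case_counts if group == 0 else snp.control_counts
            if n != table.group_size:
                counts = normalize_counts(counts, n)
            child = np.random.SeedSequence(
                entropy=seed.entropy, spawn_key=(group, j)
            )
            matrix[:, j] = simulate_group(counts, n, np.random.default_rng(child))
        return matrix

    return GenotypeDataset(
        case_matrix=build(0, n_case),
        control_matrix=build(1, n_control),
        snp_ids=table.snp_ids,
    )


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def _sniff_delimiter(first_line: str) -> str:
    return "\t" if first_line.count("\t") >= first_line.count(",") else ","


def read_frequency_table(
    path: str | Path, group_size: int = DEFAULT_GROUP_SIZE
) -> GenotypeFrequencyTable:
    """Read a per-SNP genotype-count table.

    One row per SNP:
    ``index,rs_id,gene,label1,label2,label3,case1,case2,case3,control1,control2,control3``
    (comma or tab delimited; an optional header row is skipped).
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8").splitlines()
    if not text:
        raise FormatError(f"{path}: empty frequency table")
    delim = _sniff_delimiter(text[0])
    snps: list[SnpRecord] = []
    for lineno, line in enumerate(text, start=1):
        if not line.strip():
            continue
        fields = [f.strip() for f in line.split(delim)]
        if lineno == 1 and not fields[0].isdigit():
            continue  # header
        if len(fields) != 12:
            raise FormatError(f"expected 12 fields, got {len(fields)}", line=lineno)
        try:
            snps.append(
                SnpRecord(
                    index=int(fields[0]),
                    rs_id=fields[1],
                    gene=fields[2],
                    genotype_labels=tuple(fields[3:6]),
                    case_counts=tuple(int(x) for x in fields[6:9]),
                    control_counts=tuple(int(x) for x in fields[9:12]),
                )
            )
        except ValueError as exc:
            raise FormatError(str(exc), line=lineno) from exc
    if not snps:
        raise FormatError(f"{path}: no SNP rows found")
    return GenotypeFrequencyTable(snps=tuple(snps), group_size=group_size)


def write_frequency_table(table: GenotypeFrequencyTable, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["index", "rs_id", "gene", "label1", "label2", "label3",
             "case1", "case2", "case3", "control1", "control2", "control3"]
        )
        for s in table.snps:
            writer.writerow(
                [s.index, s.rs_id, s.gene, *s.genotype_labels,
                 *s.case_counts, *s.control_counts]
            )


def load_steroid_snps(normalized: bool = True) -> GenotypeFrequencyTable:
    """The bundled 23-SNP steroid-hormone-pathway frequency table.

    Counts are the published per-genotype case/control numbers (5000 per
    group).  One SNP's printed case counts sum to 5003 in the source
    table; with ``normalized=True`` (default) they are re-apportioned to
    the common group size, which is what simulation requires.
    """
    with resources.as_file(
        resources.files("snpbarcode") / "data" / _BUNDLED_TABLES["steroid"]
    ) as p:
        table = read_frequency_table(p)
    return table.normalized() if normalized else table


def read_dataset(path: str | Path) -> GenotypeDataset:
    """Read an individual-level dataset.

    Header ``phenotype,<rsID1>,...``; one row per individual with
    phenotype ``case`` or ``control`` and genotype codes in {1,2,3}.
    Comma or tab delimited.  Lines starting with ``#`` are ignored.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    body = [(i + 1, ln) for i, ln in enumerate(lines) if ln.strip() and not ln.startswith("#")]
    if not body:
        raise FormatError(f"{path}: empty dataset file")
    header_no, header = body[0]
    delim = _sniff_delimiter(header)
    cols = [c.strip() for c in header.split(delim)]
    if cols[0].lower() != "phenotype" or len(cols) < 2:
        raise FormatError("header must be 'phenotype,<snp ids...>'", line=header_no)
    snp_ids = tuple(cols[1:])
    cases: list[list[int]] = []
    controls: list[list[int]] = []
    for lineno, line in body[1:]:
        fields = [f.strip() for f in line.split(delim)]
        if len(fields) != len(cols):
            raise FormatError(
                f"expected {len(cols)} fields, got {len(fields)}", line=lineno
            )
        label = fields[0].lower()
        if label not in ("case", "control"):
            raise FormatError(f"unknown phenotype {fields[0]!r}", line=lineno)
        try:
            genotypes = [int(x) for x in fields[1:]]
        except ValueError as exc:
            raise FormatError(f"non-integer genotype code: {exc}", line=lineno) from exc
        if any(g not in (1, 2, 3) for g in genotypes):
            raise FormatError("genotype codes must be 1, 2 or 3", line=lineno)
        (cases if label == "case" else controls).append(genotypes)
    n = len(snp_ids)
    return GenotypeDataset(
        case_matrix=np.array(cases, dtype=np.int8).reshape(len(cases), n),
        control_matrix=np.array(controls, dtype=np.int8).reshape(len(controls), n),
        snp_ids=snp_ids,
    )


def write_dataset(
    dataset: GenotypeDataset, path: str | Path, header_comments: Iterable[str] = ()
) -> None:
    """Write a dataset in the delimited format read by :func:`read_dataset`."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        for comment in header_comments:
            fh.write(f"# {comment}\n")
        writer = csv.writer(fh)
        writer.writerow(["phenotype", *dataset.snp_ids])
        for row in dataset.case_matrix:
            writer.writerow(["case", *map(int, row)])
        for row in dataset.control_matrix:
            writer.writerow(["control", *map(int, row)])
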