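"""Readers/writers for FASTA, labeled TSV matrices, nexus distance blocks and
newick trees, plus cohort summary statistics.

All matrices handled by the pipeline are small (tens of genomes), so they are
kept dense with explicit row/column labels rather than as sparse structures.
"""
from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources

import numpy as np
import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

NT_ALPHABET = frozenset("ACGTN-")


class FastaError(ValueError):
    """Raised for malformed FASTA input."""


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path, *, alphabet: str = "nt", invalid: str = "map"):
    """Read a FASTA file into a list of ``(name, sequence)`` tuples.

    Sequences are uppercased and record order is preserved.  In nucleotide
    mode (``alphabet="nt"``), characters outside ``ACGTN-`` are either mapped
    to ``N`` with a warning (``invalid="map"``, the default, to absorb rare
    IUPAC ambiguity codes in draft genomes) or rejected (``invalid="reject"``).

    Raises :class:`FastaError` on an empty file, a record with no sequence or
    a duplicated record name.
    """
    if invalid not in ("map", "reject"):
        raise ValueError(f"invalid= must be 'map' or 'reject', got {invalid!r}")
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    with open(path) as fh:
        for header, seq in SimpleFastaParser(fh):
            name = header.split()[0] if header.strip() else header
            if name in seen:
                raise FastaError(f"duplicate FASTA record name {name!r} in {path}")
            seen.add(name)
            seq = seq.upper()
            if not seq:
                raise FastaError(f"FASTA record {name!r} in {path} has no sequence")
            if alphabet == "nt":
                bad = sorted(set(seq) - NT_ALPHABET)
                if bad:
                    if invalid == "reject":
                        raise FastaError(
                            f"record {name!r} contains non-nucleotide characters {bad}"
                        )
                    warnings.warn(
                        f"record {name!r}: mapping ambiguity characters {bad} to N"
                    )
                    seq = seq.translate(str.maketrans({c: "N" for c in bad}))
            records.append((name, seq))
    if not records:
        raise FastaError(f"no FASTA records found in {path}")
    return records


def write_fasta(path, records, *, width: int = 70) -> None:
    """Write ``(name, sequence)`` tuples to ``path`` in FASTA format."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Genomes and cohort statistics
# ---------------------------------------------------------------------------

@dataclass
class GenomeRecord:
    """A strain's contigs plus derived statistics."""

    strain_id: str
    contigs: list[str]
    source_path: str = ""

    def __post_init__(self):
        if not self.contigs:
            raise ValueError(f"genome {self.strain_id!r} has no contigs")
        if any(len(c) == 0 for c in self.contigs):
            raise ValueError(f"genome {self.strain_id!r} has an empty contig")

    @classmethod
    def from_fasta(cls, path, strain_id: str | None = None) -> "GenomeRecord":
        records = read_fasta(path)
        sid = strain_id if strain_id is not None else _strain_id_from_path(path)
        return cls(strain_id=sid, contigs=[seq for _, seq in records], source_path=str(path))

    @property
    def length(self) -> int:
        return sum(len(c) for c in self.contigs)

    @property
    def gc(self) -> float:
        """GC percent with N excluded from the denominator (NaN if all-N)."""
        gc = at = 0
        for c in self.contigs:
            gc += c.count("G") + c.count("C")
            at += c.count("A") + c.count("T")
        denom = gc + at
        if denom == 0:
            warnings.warn(f"genome {self.strain_id!r} has no unambiguous bases; GC undefined")
            return math.nan
        return 100.0 * gc / denom

    def joined(self, sep_len: int = 20) -> str:
        """Contigs concatenated with an N spacer (keeps k-mer seeds from
        spanning contig boundaries)."""
        return ("N" * sep_len).join(self.contigs)


def _strain_id_from_path(path) -> str:
    name = str(path).rsplit("/", 1)[-1]
    return re.sub(r"\.(fa|fna|fasta|faa|ffn)$", "", name)


def genome_stats(genome: GenomeRecord) -> dict:
    return {"length": genome.length, "gc": genome.gc, "n_contigs": len(genome.contigs)}


def parse_printed_number(value):
    """Parse a number as printed in a table, stripping thousands separators."""
    if isinstance(value, (int, float, np.integer, np.floating)):
        return value
    text = str(value).strip().replace(",", "")
    if re.fullmatch(r"[+-]?\d+", text):
        return int(text)
    return float(text)


def round_half_up(x: float, ndigits: int = 2) -> float:
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CohortStats:
    rows: pd.DataFrame
    length_range: int
    gc_min: float
    gc_max: float
    cds_min: int | None = None
    cds_max: int | None = None
    cds_mean: float | None = None


def cohort_summary(rows: pd.DataFrame) -> CohortStats:
    """Aggregate per-strain statistics.

    ``rows`` must contain ``strain_id``, ``length`` and ``gc`` columns and may
    contain ``n_cds``.  Numeric fields may be printed strings with thousands
    separators.  The CDS mean is reported to two decimals, rounding half-up.
    """
    if len(rows) == 0:
        raise ValueError("cohort summary requires at least one row")
    for col in ("strain_id", "length", "gc"):
        if col not in rows.columns:
            raise ValueError(f"missing required column {col!r}")
    if rows["strain_id"].duplicated().any():
        raise ValueError("duplicate strain_id in cohort table")
    df = rows.copy()
    numeric_cols = ["length", "gc"] + (["n_cds"] if "n_cds" in df.columns else [])
    for col in numeric_cols:
        df[col] = [parse_printed_number(v) for v in df[col]]
    lengths = df["length"].astype(np.int64)
    stats = CohortStats(
        rows=df,
        length_range=int(lengths.max() - lengths.min()),
        gc_min=float(df["gc"].min()),
        gc_max=float(df["gc"].max()),
    )
    if "n_cds" in df.columns:
        cds = df["n_cds"].astype(np.int64)
        stats.cds_min = int(cds.min())
        stats.cds_max = int(cds.max())
        stats.cds_mean = round_half_up(float(np.sum(cds)) / len(cds), 2)
    return stats


# ---------------------------------------------------------------------------
# Labeled matrices
# ---------------------------------------------------------------------------

@dataclass
class LabeledMatrix:
    """Square or rectangular float matrix with row/column labels."""

    row_labels: list[str]
    col_labels: list[str]
    values: np.ndarray
    unit: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("matrix shape does not match label lists")
        if len(set(self.row_labels)) != len(self.row_labels):
            raise ValueError("duplicate row labels")
        if len(set(self.col_labels)) != len(self.col_labels):
            raise ValueError("duplicate column labels")

    @property
    def is_square(self) -> bool:
        return self.row_labels == self.col_labels

    def loc(self, row: str, col: str) -> float:
        return float(self.values[self.row_labels.index(row), self.col_labels.index(col)])

    def off_diagonal(self) -> np.ndarray:
        if not self.is_square:
            raise ValueError("off_diagonal requires a square matrix")
        mask = ~np.eye(len(self.row_labels), dtype=bool)
        return self.values[mask]

    def max_asymmetry(self) -> float:
        if not self.is_square:
            raise ValueError("asymmetry requires a square matrix")
        return float(np.nanmax(np.abs(self.values - self.values.T), initial=0.0))

    def symmetrized(self, how: str = "mean") -> "LabeledMatrix":
        if not self.is_square:
            raise ValueError("cannot symmetrize a non-square matrix")
        if how == "mean":
            vals = (self.values + self.values.T) / 2.0
        elif how == "max":
            vals = np.maximum(self.values, self.values.T)
        else:
            raise ValueError(f"unknown symmetrization {how!r}")
        return LabeledMatrix(list(self.row_labels), list(self.col_labels), vals, self.unit)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_labels, columns=self.col_labels)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="")

    @classmethod
    def from_tsv(cls, path, unit: str = "") -> "LabeledMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0,
                         float_precision="round_trip")
        return cls([str(i) for i in df.index], [str(c) for c in df.columns],
                   df.to_numpy(dtype=float), unit)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, unit: str = "") -> "LabeledMatrix":
        return cls([str(i) for i in df.index], [str(c) for c in df.columns],
                   df.to_numpy(dtype=float), unit)


# ---------------------------------------------------------------------------
# Nexus distance blocks
# ---------------------------------------------------------------------------

def _nexus_label(label: str) -> str:
    if re.fullmatch(r"[A-Za-z0-9_.]+", label):
        return label
    return "'" + label.replace("'", "''") + "'"


def export_nexus_distances(matrix: LabeledMatrix, path, *, from_similarity: bool = False,
                           symmetrize: bool = False, tol: float = 1e-9) -> None:
    """Write a nexus ``TAXA`` + ``DISTANCES`` file (triangle=both, labels).

    With ``from_similarity=True`` the matrix holds percent similarities and is
    converted to distances as ``100 - similarity``.
    """
    if not matrix.is_square:
        raise ValueError("nexus export requires a square matrix")
    if matrix.max_asymmetry() > tol:
        if not symmetrize:
            raise ValueError(
                f"matrix asymmetric (max |a-b| = {matrix.max_asymmetry():.3g}); "
                "pass symmetrize=True to average"
            )
        matrix = matrix.symmetrized("mean")
    values = 100.0 - matrix.values if from_similarity else matrix.values
    labels = matrix.row_labels
    n = len(labels)
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN TAXA;\n")
        fh.write(f"    DIMENSIONS NTAX={n};\n    TAXLABELS\n")
        for lab in labels:
            fh.write(f"        {_nexus_label(lab)}\n")
        fh.write("    ;\nEND;\n\nBEGIN DISTANCES;\n")
        fh.write(f"    DIMENSIONS NTAX={n};\n")
        fh.write("    FORMAT TRIANGLE=BOTH DIAGONAL LABELS=LEFT;\n    MATRIX\n")
        for i, lab in enumerate(labels):
            row = " ".join(repr(float(v)) for v in values[i])
            fh.write(f"        {_nexus_label(lab)} {row}\n")
        fh.write("    ;\nEND;\n")


def read_nexus_distances(path) -> LabeledMatrix:
    """Minimal parser for the DISTANCES files written by
    :func:`export_nexus_distances` (triangle=both, labelled rows)."""
    text = open(path).read()
    m = re.search(r"BEGIN DISTANCES;.*?MATRIX\n(.*?)\n\s*;", text, re.S | re.I)
    if not m:
        raise ValueError(f"no DISTANCES matrix found in {path}")
    labels: list[str] = []
    rows: list[list[float]] = []
    for line in m.group(1).splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("'"):
            qm = re.match(r"'((?:[^']|'')*)'\s*(.*)", line)
            label, rest = qm.group(1).replace("''", "'"), qm.group(2)
        else:
            label, _, rest = line.partition(" ")
        labels.append(label)
        rows.append([float(tok) for tok in rest.split()])
    return LabeledMatrix(labels, list(labels), np.array(rows), unit="distance")


# ---------------------------------------------------------------------------
# Trees (newick)
# ---------------------------------------------------------------------------

class TreeNode:
    """A rooted tree node; leaves carry labels, edges carry branch lengths."""

    __slots__ = ("label", "branch_length", "children")

    def __init__(self, label=None, branch_length=None, children=None):
        self.label = label
        self.branch_length = branch_length
        self.children: list[TreeNode] = list(children) if children else []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self):
        if self.is_leaf:
            yield self
        else:
            for child in self.children:
                yield from child.leaves()

    def leaf_labels(self) -> list[str]:
        return [leaf.label for leaf in self.leaves()]

    def to_newick(self, *, lengths: bool = True) -> str:
        return self._newick(lengths) + ";"

    def _newick(self, lengths: bool) -> str:
        if self.is_leaf:
            out = self.label or ""
        else:
            out = "(" + ",".join(c._newick(lengths) for c in self.children) + ")"
            if self.label:
                out += self.label
        if lengths and self.branch_length is not None:
            out += f":{self.branch_length:.10g}"
        return out

    def __repr__(self):
        return f"TreeNode({self.to_newick()})"

    @classmethod
    def from_newick(cls, text: str) -> "TreeNode":
        text = text.strip()
        if not text.endswith(";"):
            raise ValueError("newick string must end with ';'")
        pos = 0
        s = text[:-1]

        def parse_node() -> TreeNode:
            nonlocal pos
            node = cls()
            if pos < len(s) and s[pos] == "(":
                pos += 1
                node.children.append(parse_node())
                while pos < len(s) and s[pos] == ",":
                    pos += 1
                    node.children.append(parse_node())
                if pos >= len(s) or s[pos] != ")":
                    raise ValueError("unbalanced parentheses in newick")
                pos += 1
            m = re.match(r"[^,():;]*", s[pos:])
            label = m.group(0)
            pos += len(label)
            if label:
                node.label = label
            if pos < len(s) and s[pos] == ":":
                pos += 1
                m = re.match(r"[^,();]+", s[pos:])
                node.branch_length = float(m.group(0))
                pos += len(m.group(0))
            return node

        root = parse_node()
        if pos != len(s):
            raise ValueError(f"trailing characters in newick: {s[pos:]!r}")
        labels = root.leaf_labels()
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate leaf labels in newick tree")
        return root


def leaf_depths(tree: TreeNode) -> dict[str, float]:
    """Root-to-leaf path lengths (the root's own branch is not counted;
    missing branch lengths count as 0)."""
    depths: dict[str, float] = {}

    def walk(node: TreeNode, depth: float):
        if node.is_leaf:
            depths[node.label] = depth
        for child in node.children:
            walk(child, depth + (child.branch_length or 0.0))

    walk(tree, 0.0)
    return depths


def tree_leaf_distances(tree: TreeNode) -> LabeledMatrix:
    """Pairwise leaf-to-leaf path-length matrix of a tree."""
    leaves = sorted(tree.leaf_labels())
    index = {lab: i for i, lab in enumerate(leaves)}
    n = len(leaves)
    dist = np.zeros((n, n))

    def walk(node: TreeNode) -> dict[str, float]:
        if node.is_leaf:
            return {node.label: 0.0}
        below: dict[str, float] = {}
        child_maps = []
        for child in node.children:
            cmap = {lab: d + (child.branch_length or 0.0)
                    for lab, d in walk(child).items()}
            child_maps.append(cmap)
        for i in range(len(child_maps)):
            for j in range(i + 1, len(child_maps)):
                for la, da in child_maps[i].items():
                    for lb, db in child_maps[j].items():
                        dist[index[la], index[lb]] = dist[index[lb], index[la]] = da + db
        for cmap in child_maps:
            below.update(cmap)
        return below

    walk(tree)
    return LabeledMatrix(leaves, list(leaves), dist, unit="distance")


# ---------------------------------------------------------------------------
# Packaged fixtures (printed cohort tables)
# ---------------------------------------------------------------------------

def load_table1() -> pd.DataFrame:
    """Published 17-strain cohort table (counts parsed from printed form)."""
    with resources.files("genospecies.data").joinpath("table1.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    for col in ("n_contigs", "length", "gc", "n_cds"):
        df[col] = [parse_printed_number(v) for v in df[col]]
    return df


def load_table2_ani() -> LabeledMatrix:
    """Published 17x17 ANI matrix, kept exactly as printed (slightly
    asymmetric in a few cells)."""
    with resources.files("genospecies.data").joinpath("table2_ani.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", index_col=0)
    return LabeledMatrix.from_dataframe(df, unit="percent")
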