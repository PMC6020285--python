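"""Core data containers and plain-text readers/writers.

Expression data travel as genes × samples TSV files of strictly positive
linear signal intensities, with a separate two-column design file mapping
each sample to its condition label. Gene-set categories use the standard
GMT format (name, source, then members, tab-separated). All result tables
are TSV with leading ``#`` metadata comment lines so every number written
to disk is traceable to the thresholds and seed that produced it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

__all__ = [
    "ExpressionMatrix",
    "GeneSetCategory",
    "ResultTable",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_design",
    "write_design",
    "read_gene_sets",
    "write_gene_sets",
    "read_table",
    "write_table",
]

GENE_COLUMN = "gene"


@dataclass(frozen=True)
class GeneSetCategory:
    """A named gene list used for over-representation analysis.

    ``members`` is an ordered, de-duplicated tuple so that a GMT
    write→read round trip is the identity on canonicalized categories.
    """

    name: str
    source: str
    members: tuple[str, ...]

    def __post_init__(self):
        if not self.name:
            raise ValidationError("gene-set category must have a name")
        if not self.members:
            raise ValidationError(f"category '{self.name}' has no members")
        if len(set(self.members)) != len(self.members):
            # canonicalize silently: keep first occurrence order
            seen: dict[str, None] = dict.fromkeys(self.members)
            object.__setattr__(self, "members", tuple(seen))

    @property
    def member_set(self) -> frozenset[str]:
        return frozenset(self.members)

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class ExpressionMatrix:
    """Gene-level linear signal intensities with a sample→condition design.

    Invariants enforced at construction: unique gene and sample identifiers,
    strictly positive finite intensities, every sample present in the design,
    and at least two samples per condition.
    """

    values: pd.DataFrame  # genes × samples, float
    design: dict[str, str]  # sample id -> condition label

    def __post_init__(self):
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene symbols: {dups[:5]}")
        if v.columns.has_duplicates:
            raise ValidationError("duplicate sample ids in expression matrix")
        arr = v.to_numpy(dtype=float)
        bad = ~np.isfinite(arr) | (arr <= 0)
        if bad.any():
            gi, si = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-positive or missing intensity for gene "
                f"'{v.index[gi]}' in sample '{v.columns[si]}'"
            )
        missing = [s for s in v.columns if s not in self.design]
        if missing:
            raise ValidationError(f"samples absent from design: {missing}")
        counts: dict[str, int] = {}
        for s in v.columns:
            counts[self.design[s]] = counts.get(self.design[s], 0) + 1
        for cond, n in counts.items():
            if n < 2:
                raise ValidationError(
                    f"condition '{cond}' has {n} sample(s); at least 2 required"
                )
        self.values = v.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def conditions(self) -> list[str]:
        seen = dict.fromkeys(self.design[s] for s in self.values.columns)
        return list(seen)

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.values.columns if self.design[s] == condition]


@dataclass
class ResultTable:
    """An ordered record table plus a metadata block.

    The metadata (comparison name, thresholds, seed, ...) is written as
    leading ``#`` comment lines so the provenance of each output file is
    self-contained.
    """

    frame: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.frame.columns.has_duplicates:
            raise ValidationError("result table has duplicate column names")

    def __len__(self) -> int:
        return len(self.frame)


# ---------------------------------------------------------------------------
# expression matrices and designs


def read_design(path) -> dict[str, str]:
    """Read a two-column (sample, condition) TSV into a mapping."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if "sample" not in cols or "condition" not in cols:
        raise ParseError(f"design file {path} needs 'sample' and 'condition' columns")
    if df[cols["sample"]].duplicated().any():
        raise ValidationError(f"design file {path} has duplicate sample ids")
    return dict(zip(df[cols["sample"]], df[cols["condition"]]))


def write_design(design: dict[str, str], path) -> None:
    pd.DataFrame(
        {"sample": list(design), "condition": [design[s] for s in design]}
    ).to_csv(path, sep="\t", index=False)


def read_expression_matrix(path, design_path, case_fold: bool = False) -> ExpressionMatrix:
    """Read a genes × samples intensity TSV plus its design file.

    The first column must be headed ``gene``; ``#`` comment lines are
    allowed. With ``case_fold`` gene symbols are upper-cased, the optional
    canonicalization used when reconciling symbols across array annotations.
    """
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    if df.columns[0] != GENE_COLUMN:
        raise ParseError(
            f"{path}: first column must be '{GENE_COLUMN}', got '{df.columns[0]}'"
        )
    df = df.set_index(GENE_COLUMN)
    df.index = df.index.astype(str)
    if case_fold:
        df.index = df.index.str.upper()
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate gene symbols: {dups[:5]}")
    return ExpressionMatrix(values=df, design=read_design(design_path))


def write_expression_matrix(matrix: ExpressionMatrix, path, design_path=None) -> None:
    """Write intensities at full precision so read-back is bit-identical."""
    out = matrix.values.copy()
    out.index.name = GENE_COLUMN
    out.to_csv(path, sep="\t", float_format="%.17g")
    if design_path is not None:
        write_design(matrix.design, design_path)


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gene_sets(path, case_fold: bool = False) -> list[GeneSetCategory]:
    """Parse a GMT file: ``name TAB source TAB member1 TAB member2 ...``.

    Duplicate members within a line are dropped (first occurrence kept);
    file order of categories is preserved.
    """
    categories: list[GeneSetCategory] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"GMT line has {len(fields)} field(s); need name, source "
                    "and at least one member",
                    line=lineno,
                )
            members = [m.strip() for m in fields[2:] if m.strip()]
            if case_fold:
                members = [m.upper() for m in members]
            if not members:
                raise ParseError("GMT line has no gene members", line=lineno)
            categories.append(
                GeneSetCategory(
                    name=fields[0], source=fields[1], members=tuple(dict.fromkeys(members))
                )
            )
    if not categories:
        raise ParseError(f"GMT file {path} contains no categories")
    return categories


def write_gene_sets(categories: list[GeneSetCategory], path) -> None:
    with open(path, "w") as fh:
        for cat in categories:
            fh.write("\t".join([cat.name, cat.source, *cat.members]) + "\n")


# ---------------------------------------------------------------------------
# generic result tables


def write_table(table: ResultTable, path) -> None:
    """Write a ResultTable as TSV with '#'-prefixed metadata lines.

    Floats are rendered with %.8g (at least 6 significant digits).
    """
    with open(path, "w") as fh:
        for key, value in table.metadata.items():
            fh.write(f"# {key}: {json.dumps(value)}\n")
        table.frame.to_csv(fh, sep="\t", index=False, float_format="%.8g")


def read_table(path) -> ResultTable:
    metadata: dict = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for line in lines:
        if not line.startswith("#"):
            break
        body_start += 1
        stripped = line[1:].strip()
        if ":" in stripped:
            key, _, value = stripped.partition(":")
            try:
                metadata[key.strip()] = json.loads(value.strip())
            except json.JSONDecodeError:
                metadata[key.strip()] = value.strip()
    from io import StringIO

    body = "".join(lines[body_start:])
    frame = pd.read_csv(StringIO(body), sep="\t") if body.strip() else pd.DataFrame()
    return ResultTable(frame=frame, metadata=metadata)
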