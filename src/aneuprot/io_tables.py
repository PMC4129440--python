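"""Tabular I/O for quantification matrices, gene annotation, and gene sets.

Everything is plain TSV. A quantification matrix is genes x strains of log2
ratios (strain relative to wild type); missing measurements are empty cells
or ``NA`` on disk and NaN in memory. Gene annotation maps each gene to a
chromosome and an ordinal position along it (0-based); base-pair chromosome
lengths are optional and only needed for the signature-size correlation.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

LAYERS = ("protein", "mRNA", "footprint")

_STRAIN_RE = re.compile(r"^disome[_\-]?(\d+|[IVX]+)([,_\-]ubp6)?$", re.IGNORECASE)

_ROMAN = {
    "I": 1, "II": 2, "III": 3, "IV": 4, "V": 5, "VI": 6, "VII": 7, "VIII": 8,
    "IX": 9, "X": 10, "XI": 11, "XII": 12, "XIII": 13, "XIV": 14, "XV": 15,
    "XVI": 16,
}


class FormatError(ValueError):
    """A file violated the expected tabular layout."""


def chromosome_name(number: int) -> str:
    return f"chr{number:02d}"


def strain_duplicated_chromosome(strain: str) -> str | None:
    """Parse a strain name of the form ``disomeN[,ubp6]``.

    Returns the duplicated chromosome ID (``chrNN``), or None for anything
    that does not follow the disome naming convention (e.g. wild-type
    control columns).
    """
    m = _STRAIN_RE.match(strain.strip())
    if m is None:
        return None
    token = m.group(1).upper()
    number = int(token) if token.isdigit() else _ROMAN.get(token)
    if number is None:
        return None
    return chromosome_name(number)


@dataclass
class QuantMatrix:
    """Genes x strains matrix of log2 abundance ratios for one data layer."""

    data: pd.DataFrame
    layer: str
    condition: str = ""

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene IDs: {dupes}")
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate strain IDs: {dupes}")
        values = self.data.to_numpy(dtype=float)
        if np.isinf(values).any():
            raise FormatError("non-finite (infinite) values in matrix")
        self.data = self.data.astype(float)

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def strains(self) -> list[str]:
        return list(self.data.columns)

    def duplicated_chromosomes(self) -> dict[str, str | None]:
        """Per-strain duplicated chromosome inferred from strain names."""
        return {s: strain_duplicated_chromosome(s) for s in self.strains}


@dataclass
class ComplexCatalog:
    """Curated mapping complex ID -> member gene list."""

    complexes: dict[str, list[str]]
    provenance: str = ""

    def __post_init__(self) -> None:
        for cid, members in self.complexes.items():
            if len(members) != len(set(members)):
                raise FormatError(f"duplicate members within complex {cid!r}")
            if len(members) < 2:
                raise FormatError(f"singleton complex {cid!r} (needs >= 2 members)")

    def members(self) -> set[str]:
        """Union of all complex members (each gene counted once)."""
        out: set[str] = set()
        for genes in self.complexes.values():
            out.update(genes)
        return out

    def membership(self, gene: str) -> list[str]:
        return [cid for cid, genes in self.complexes.items() if gene in genes]


@dataclass
class GeneAnnotation:
    """Gene -> (chromosome, ordinal position) plus named gene sets.

    ``table`` is indexed by gene with columns ``chromosome`` and ``position``.
    ``gene_sets`` holds flat named sets (ribosomal, ESR-up, ESR-down, APS...).
    ``bp_sizes`` optionally maps chromosome -> length in bp.
    """

    table: pd.DataFrame
    gene_sets: dict[str, set[str]] = field(default_factory=dict)
    bp_sizes: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            raise FormatError("duplicate gene IDs in annotation")
        for chrom, sub in self.table.groupby("chromosome"):
            if sub["position"].duplicated().any():
                raise FormatError(f"duplicate ordinal positions on {chrom}")
        known = set(self.table.index)
        for name, members in self.gene_sets.items():
            missing = set(members) - known
            if missing:
                raise FormatError(
                    f"gene set {name!r} contains unannotated genes: {sorted(missing)[:5]}"
                )

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    def chromosome_of(self, gene: str) -> str:
        return str(self.table.at[gene, "chromosome"])

    def genes_on(self, chromosome: str) -> list[str]:
        sub = self.table[self.table["chromosome"] == chromosome]
        return list(sub.sort_values("position").index)

    def chromosome_sizes(self, unit: str = "genes") -> dict[str, float]:
        """Chromosome sizes: gene counts, or bp lengths when available."""
        if unit == "bp":
            if not self.bp_sizes:
                raise ValueError("no bp sizes recorded on this annotation")
            return dict(self.bp_sizes)
        counts = self.table.groupby("chromosome").size()
        return {str(c): int(n) for c, n in counts.items()}

    def sorted_genes(self) -> list[str]:
        """All genes in (chromosome, position) order."""
        return list(self.table.sort_values(["chromosome", "position"]).index)


# ---------------------------------------------------------------------------
# readers / writers


def read_quant_matrix(path: str | Path, layer: str, condition: str = "") -> QuantMatrix:
    """Read a gene x strain TSV of log2 ratios.

    First column is the gene ID, remaining columns are strains. Empty cells
    and ``NA`` become missing values (never zero). Gene order is preserved.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if raw.shape[1] < 2:
        raise FormatError(f"{path}: need a gene column plus >=1 strain column")
    gene_col = raw.columns[0]
    genes = raw[gene_col]
    if genes.duplicated().any():
        first = genes[genes.duplicated()].iloc[0]
        row = int(genes[genes == first].index[1]) + 2  # 1-based incl. header
        raise FormatError(f"{path}: duplicate gene ID {first!r} at row {row}")
    data = {}
    for col in raw.columns[1:]:
        cells = raw[col].str.strip()
        cells = cells.mask(cells.isin(["", "NA", "NaN", "nan"]))
        numeric = pd.to_numeric(cells, errors="coerce")
        bad = numeric.isna() & cells.notna()
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise FormatError(
                f"{path}: non-numeric cell {cells.iloc[i]!r} at row {i + 2}, "
                f"column {col!r}"
            )
        # astype(float) parses with full round-trip precision (to_numeric
        # takes a faster, lossy path)
        data[col] = cells.astype(float)
    frame = pd.DataFrame(data)
    frame.index = pd.Index(genes, name="gene")
    return QuantMatrix(frame, layer=layer, condition=condition)


def write_quant_matrix(matrix: QuantMatrix, path: str | Path) -> None:
    """Write a matrix as TSV; missing values become empty cells.

    Floats are written as their shortest round-tripping decimal form, so
    write -> read reproduces the matrix bit-exactly.
    """
    out = matrix.data.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", na_rep="", float_format=lambda v: repr(float(v)))


def merge_layers(a: QuantMatrix, b: QuantMatrix) -> pd.DataFrame:
    """Pair measurements of the same (gene, strain) across two layers.

    Returns a long table with columns gene, strain, value_a, value_b,
    restricted to cells measured in both layers.
    """
    if a.layer == b.layer:
        raise ValueError("merge_layers expects two different layers")
    shared_strains = [s for s in a.strains if s in set(b.strains)]
    if not shared_strains:
        raise ValueError("no shared strains between the two layers")
    long_a = a.data[shared_strains].stack()
    long_b = b.data[shared_strains].stack()
    paired = pd.concat({"value_a": long_a, "value_b": long_b}, axis=1, join="inner")
    paired = paired.dropna()
    paired.index.names = ["gene", "strain"]
    if paired.empty:
        warnings.warn("merge_layers: no (gene, strain) pair measured in both layers")
    return paired.reset_index()


def read_complex_catalog(path: str | Path, provenance: str = "") -> ComplexCatalog:
    """Read a two-column TSV (complex ID, gene); insertion order preserved."""
    sets = _read_two_column_sets(path)
    return ComplexCatalog({k: list(v) for k, v in sets.items()}, provenance=provenance)


def write_complex_catalog(catalog: ComplexCatalog, path: str | Path) -> None:
    _write_two_column_sets(catalog.complexes, path, header=("complex", "gene"))


def read_gene_sets(path: str | Path) -> dict[str, list[str]]:
    """Read named gene sets from a two-column TSV (set ID, gene)."""
    return _read_two_column_sets(path)


def write_gene_sets(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    _write_two_column_sets(sets, path, header=("set", "gene"))


def _read_two_column_sets(path: str | Path) -> dict[str, list[str]]:
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if raw.shape[1] != 2:
        raise FormatError(f"{path}: expected exactly two columns (set ID, gene)")
    out: dict[str, list[str]] = {}
    n_dupes = 0
    for set_id, gene in raw.itertuples(index=False):
        members = out.setdefault(str(set_id), [])
        if gene in members:
            n_dupes += 1
            continue
        members.append(str(gene))
    if n_dupes:
        warnings.warn(f"{path}: {n_dupes} duplicate (set, gene) rows deduplicated")
    return out


def _write_two_column_sets(
    sets: Mapping[str, Iterable[str]], path: str | Path, header: tuple[str, str]
) -> None:
    rows = [(k, g) for k, members in sets.items() for g in members]
    pd.DataFrame(rows, columns=list(header)).to_csv(path, sep="\t", index=False)


def read_annotation(
    path: str | Path,
    gene_sets_path: str | Path | None = None,
    bp_sizes_path: str | Path | None = None,
) -> GeneAnnotation:
    """Read gene annotation TSV with columns gene, chromosome, position."""
    raw = pd.read_csv(path, sep="\t", dtype={"gene": str, "chromosome": str})
    required = {"gene", "chromosome", "position"}
    if not required.issubset(raw.columns):
        raise FormatError(f"{path}: requires columns {sorted(required)}")
    table = raw.set_index("gene")[["chromosome", "position"]]
    table["position"] = table["position"].astype(int)
    gene_sets: dict[str, set[str]] = {}
    if gene_sets_path is not None:
        gene_sets = {k: set(v) for k, v in read_gene_sets(gene_sets_path).items()}
    bp_sizes: dict[str, float] = {}
    if bp_sizes_path is not None:
        sizes = pd.read_csv(bp_sizes_path, sep="\t", dtype={"chromosome": str})
        bp_sizes = dict(zip(sizes["chromosome"], sizes["bp"].astype(float)))
    return GeneAnnotation(table, gene_sets=gene_sets, bp_sizes=bp_sizes)


def write_annotation(annotation: GeneAnnotation, path: str | Path) -> None:
    out = annotation.table.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def annotation_from_bed(path: str | Path) -> GeneAnnotation:
    """Build annotation from a minimal BED file (chrom, start, end, name).

    Ordinal positions are assigned by start coordinate within each
    chromosome; bp sizes are taken as the maximum end coordinate seen.
    """
    raw = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chromosome", "start", "end", "gene"], usecols=range(4),
        dtype={"chromosome": str, "gene": str},
    )
    return _ordinalize(raw)


def annotation_from_gff3(path: str | Path, feature: str = "gene") -> GeneAnnotation:
    """Build annotation from a minimal GFF3 subset (seqid, start, ID=)."""
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9 or fields[2] != feature:
            continue
        attrs = dict(
            kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
        )
        gene = attrs.get("ID") or attrs.get("Name")
        if gene is None:
            raise FormatError(f"GFF3 feature without ID/Name attribute: {line!r}")
        rows.append((fields[0], int(fields[3]), int(fields[4]), gene))
    if not rows:
        raise FormatError(f"{path}: no {feature!r} features found")
    raw = pd.DataFrame(rows, columns=["chromosome", "start", "end", "gene"])
    return _ordinalize(raw)


def _ordinalize(raw: pd.DataFrame) -> GeneAnnotation:
    raw = raw.sort_values(["chromosome", "start"], kind="stable")
    raw["position"] = raw.groupby("chromosome").cumcount()
    table = raw.set_index("gene")[["chromosome", "position"]]
    bp = raw.groupby("chromosome")["end"].max().astype(float).to_dict()
    return GeneAnnotation(table, bp_sizes={str(k): v for k, v in bp.items()})
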