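"""Readers, writers and validated containers for every external format the
pipeline touches.

All tabular inputs are tab-separated UTF-8 with Unix newlines; sequence data
is FASTA; gene structures are GFF3.  Coordinates are 0-based half-open
internally — GFF3's 1-based inclusive convention is converted at the boundary.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq


class ValidationError(ValueError):
    """An input violates a structural invariant (duplicates, bad alphabet...)."""


class ParseError(ValueError):
    """An input file is syntactically malformed."""


class ConfigurationError(ValueError):
    """Metadata (e.g. the sample→tissue map) is inconsistent with the data."""


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes × samples matrix of log2 intensities with tissue metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id, columns are sample ids, entries are
        finite log2 intensities.
    sample_tissue
        Maps every sample id to a tissue label.
    target_tissue, reference_tissue
        The tissue whose preferential genes are sought (e.g. ``root_hair``)
        and the tissue it is contrasted against in the fold rule
        (e.g. ``root``).
    """

    values: pd.DataFrame
    sample_tissue: dict[str, str]
    target_tissue: str
    reference_tissue: str

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValidationError(f"duplicate gene id: {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise ValidationError(f"duplicate sample id: {dup!r}")
        missing = [s for s in cols if s not in self.sample_tissue]
        if missing:
            raise ConfigurationError(
                f"samples without a tissue label: {missing[:5]}"
            )
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr.astype(float, copy=False)).all():
            bad = np.argwhere(~np.isfinite(arr.astype(float)))[0]
            raise ValidationError(
                f"non-finite value at gene {idx[bad[0]]!r}, sample {cols[bad[1]]!r}"
            )
        tissues = set(self.sample_tissue[s] for s in cols)
        for role, t in (("target", self.target_tissue),
                        ("reference", self.reference_tissue)):
            if t not in tissues:
                raise ConfigurationError(
                    f"{role} tissue {t!r} has no samples in the matrix"
                )

    # -- convenience views ------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def tissues(self) -> list[str]:
        """Tissue labels in first-appearance (column) order."""
        seen: dict[str, None] = {}
        for s in self.values.columns:
            seen.setdefault(self.sample_tissue[s], None)
        return list(seen)

    def samples_for(self, tissue: str) -> list[str]:
        return [s for s in self.values.columns if self.sample_tissue[s] == tissue]

    @property
    def is_collapsed(self) -> bool:
        """True when there is exactly one column per tissue (column == tissue)."""
        return all(s == self.sample_tissue[s] for s in self.values.columns)

    def restrict_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        return dataclasses.replace(self, values=self.values.loc[list(genes)])


def read_expression_matrix(
    path: str | Path,
    tissue_map: str | Path | Mapping[str, str],
    target_tissue: str,
    reference_tissue: str,
) -> ExpressionMatrix:
    """Read a tab-separated genes × samples table of log2 intensities.

    The first column holds gene ids; the header row holds sample ids.
    ``tissue_map`` is either a mapping or the path of a two-column
    tab-separated file (sample id, tissue label).
    """
    if not isinstance(tissue_map, Mapping):
        tissue_map = read_tissue_map(tissue_map)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, header=0,
                         float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message forwarded
        raise ParseError(f"cannot parse expression table {path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise ParseError(
                f"non-numeric cell in column {col!r}, gene {bad.index[0]!r}: "
                f"{bad.iloc[0]!r}"
            )
    return ExpressionMatrix(
        values=df.astype(float),
        sample_tissue=dict(tissue_map),
        target_tissue=target_tissue,
        reference_tissue=reference_tissue,
    )


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write the matrix as a tab-separated table (full float precision)."""
    matrix.values.to_csv(path, sep="\t", index_label="gene_id",
                         lineterminator="\n")


def read_tissue_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "tissue"],
                     dtype=str, comment="#")
    if df["sample"].duplicated().any():
        dup = df["sample"][df["sample"].duplicated()].iloc[0]
        raise ValidationError(f"duplicate sample in tissue map: {dup!r}")
    return dict(zip(df["sample"], df["tissue"]))


def write_tissue_map(sample_tissue: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for sample, tissue in sample_tissue.items():
            fh.write(f"{sample}\t{tissue}\n")


# ---------------------------------------------------------------------------
# Annotation table
# ---------------------------------------------------------------------------

@dataclass
class AnnotationTable:
    """Flat gene → term annotation pairs plus the genome-wide repeat total G.

    One (gene, term) pair is one *annotation repeat*; enrichment statistics
    count repeats, not distinct genes.  ``genome_total_repeats`` (G) may
    exceed the number of stored pairs when the table is a subset of the
    genome-wide annotation.
    """

    pairs: pd.DataFrame  # columns: gene_id, term_id, term_label
    genome_total_repeats: int

    def __post_init__(self) -> None:
        required = ["gene_id", "term_id", "term_label"]
        if list(self.pairs.columns)[:3] != required:
            self.pairs = self.pairs.rename(
                columns=dict(zip(self.pairs.columns[:3], required))
            )
        if self.pairs.duplicated(["gene_id", "term_id"]).any():
            row = self.pairs[self.pairs.duplicated(["gene_id", "term_id"])].iloc[0]
            raise ValidationError(
                f"duplicate annotation pair ({row.gene_id!r}, {row.term_id!r})"
            )
        if self.genome_total_repeats <= 0:
            raise ValidationError("genome_total_repeats must be positive")
        if self.genome_total_repeats < len(self.pairs):
            raise ValidationError(
                "genome_total_repeats smaller than the number of stored pairs"
            )


def read_annotation_table(path: str | Path,
                          genome_total_repeats: int) -> AnnotationTable:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.shape[1] == 2:
        df["term_label"] = df.iloc[:, 1]
    df.columns = ["gene_id", "term_id", "term_label"][: df.shape[1]]
    return AnnotationTable(pairs=df, genome_total_repeats=genome_total_repeats)


def write_annotation_table(table: AnnotationTable, path: str | Path) -> None:
    table.pairs.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Promoters
# ---------------------------------------------------------------------------

_PROMOTER_ALPHABET = frozenset("ACGTN")


@dataclass
class PromoterSet:
    """Upstream promoter windows, one per gene, at most ``window_length`` nt."""

    records: list[tuple[str, str]]  # (gene_id, uppercase sequence)
    window_length: int = 2000

    def __post_init__(self) -> None:
        seen: set[str] = set()
        clean: list[tuple[str, str]] = []
        for gene, seq in self.records:
            if gene in seen:
                raise ValidationError(f"duplicate promoter record: {gene!r}")
            seen.add(gene)
            seq = seq.upper()
            extra = set(seq) - _PROMOTER_ALPHABET
            if extra:
                raise ValidationError(
                    f"promoter {gene!r} contains invalid characters {sorted(extra)}"
                )
            if len(seq) > self.window_length:
                raise ValidationError(
                    f"promoter {gene!r} is {len(seq)} nt, longer than the "
                    f"{self.window_length} nt window"
                )
            clean.append((gene, seq))
        self.records = clean

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def gene_ids(self) -> list[str]:
        return [g for g, _ in self.records]


def read_fasta_promoters(path: str | Path, window_length: int = 2000) -> PromoterSet:
    """Read pre-windowed promoters from FASTA.

    The gene id is the first whitespace-delimited token of each header.
    Sequences are uppercased; records longer than ``window_length`` are
    rejected (use :func:`extract_promoters` to window a genome).
    """
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    return PromoterSet(records=records, window_length=window_length)


def write_fasta_promoters(promoters: PromoterSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for gene, seq in promoters:
            fh.write(f">{gene}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def extract_promoters(
    genome_path: str | Path,
    gff3_path: str | Path,
    window_length: int = 2000,
    feature_type: str = "gene",
) -> PromoterSet:
    """Window the ``window_length`` bases immediately upstream of each gene.

    For a + strand gene the window is the bases 5' of the feature start; for
    a − strand gene it is the reverse complement of the window 3' of the
    feature end, so that in the returned sequence position
    ``window_length − 1`` always abuts the transcription start.  Windows are
    truncated at contig edges.
    """
    import gffutils

    genome = {rec.id: str(rec.seq).upper()
              for rec in SeqIO.parse(str(genome_path), "fasta")}
    db = gffutils.create_db(str(gff3_path), dbfn=":memory:",
                            force=True, keep_order=True,
                            merge_strategy="create_unique")
    records: list[tuple[str, str]] = []
    for feat in db.features_of_type(feature_type, order_by="start"):
        if feat.seqid not in genome:
            raise ValidationError(
                f"contig {feat.seqid!r} of gene {feat.id!r} absent from genome"
            )
        if feat.strand not in {"+", "-"}:
            raise ValidationError(f"gene {feat.id!r} has no strand")
        contig = genome[feat.seqid]
        start0 = feat.start - 1          # GFF3 is 1-based inclusive
        end0 = feat.end                  # → 0-based half-open [start0, end0)
        if feat.strand == "+":
            lo = max(0, start0 - window_length)
            seq = contig[lo:start0]
        else:
            hi = min(len(contig), end0 + window_length)
            seq = str(Seq(contig[end0:hi]).reverse_complement())
        records.append((feat.id, seq))
    return PromoterSet(records=records, window_length=window_length)


# ---------------------------------------------------------------------------
# Edge lists and ortholog pairs
# ---------------------------------------------------------------------------

@dataclass
class EdgeList:
    """Undirected interaction edges stored canonically (a < b), duplicate-free."""

    edges: list[tuple[str, str, str]]  # (node_a, node_b, source tag)

    def __post_init__(self) -> None:
        canon: list[tuple[str, str, str]] = []
        seen: set[tuple[str, str]] = set()
        for a, b, *rest in self.edges:
            source = rest[0] if rest else ""
            if a == b:
                raise ValidationError(f"self-loop on node {a!r}")
            key = (a, b) if a < b else (b, a)
            if key in seen:
                raise ValidationError(f"duplicate edge {key}")
            seen.add(key)
            canon.append((key[0], key[1], source))
        self.edges = canon

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self):
        return iter(self.edges)

    @property
    def nodes(self) -> set[str]:
        return {n for a, b, _ in self.edges for n in (a, b)}


def read_edge_list(path: str | Path) -> EdgeList:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ParseError(f"edge list {path} needs at least two columns")
    if df.shape[1] == 2:
        df[2] = ""
    return EdgeList(edges=[tuple(r) for r in df.iloc[:, :3].itertuples(index=False)])


def write_edge_list(edges: EdgeList, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for a, b, source in edges:
            fh.write(f"{a}\t{b}\t{source}\n")


@dataclass
class OrthologTable:
    """Cross-species ortholog pairs, oriented (species 1, species 2).

    Many-to-many relationships are allowed; exact duplicate pairs are not.
    """

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for p in self.pairs:
            if p in seen:
                raise ValidationError(f"duplicate ortholog pair {p}")
            seen.add(p)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def transposed(self) -> "OrthologTable":
        return OrthologTable(pairs=[(b, a) for a, b in self.pairs])


def read_ortholog_table(path: str | Path) -> OrthologTable:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ParseError(f"ortholog table {path} needs two columns")
    return OrthologTable(pairs=[(a, b) for a, b in
                                df.iloc[:, :2].itertuples(index=False)])


def write_ortholog_table(table: OrthologTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for a, b in table:
            fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# Small helpers shared by the CLI
# ---------------------------------------------------------------------------

def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line.split()[0])
    return out


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_class_map(path: str | Path) -> dict[str, str]:
    """Two-column tab-separated gene → functional-class label table."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
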