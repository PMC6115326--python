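"""Synthetic input generators with planted ground truth.

Every pipeline stage can be exercised without external downloads: the
generators emulate a multi-tissue log2-intensity compendium with replicate
arrays, a flat gene→GO annotation table, 2-kb promoter windows with planted
motif copies, and a PPI edge list — and record exactly what was planted so
recovery can be scored.

All generators are pure functions of their parameters and a seed.  Each
draws from its own labelled substream of the master seed, so adding one
generator to a workflow never perturbs the output of another.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import (
    AnnotationTable,
    EdgeList,
    ExpressionMatrix,
    PromoterSet,
    ValidationError,
)
from .motifs import IUPAC_CODES, Motif, reverse_complement


def substream(seed: int, label: str) -> np.random.Generator:
    """Deterministic per-label random stream derived from a master seed."""
    digest = hashlib.sha256(f"{label}:{seed}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


@dataclass
class SyntheticTruth:
    """Ground truth recorded while generating synthetic inputs."""

    planted_preferential: set[str] = field(default_factory=set)
    planted_term: str | None = None
    planted_motif_positions: dict[str, list[tuple[int, str]]] = field(
        default_factory=dict)
    planted_edges: set[tuple[str, str]] = field(default_factory=set)
    generator_params: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_preferential": sorted(self.planted_preferential),
            "planted_term": self.planted_term,
            "planted_motif_positions": {
                g: [[o, s] for o, s in v]
                for g, v in self.planted_motif_positions.items()
            },
            "planted_edges": sorted(list(e) for e in self.planted_edges),
            "generator_params": self.generator_params,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True),
                              encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            planted_preferential=set(d["planted_preferential"]),
            planted_term=d["planted_term"],
            planted_motif_positions={
                g: [(int(o), s) for o, s in v]
                for g, v in d["planted_motif_positions"].items()
            },
            planted_edges={tuple(e) for e in d["planted_edges"]},
            generator_params=d["generator_params"],
        )


# ---------------------------------------------------------------------------
# Expression compendium
# ---------------------------------------------------------------------------

#: Anatomical panel emulating a multi-organ compendium around the target and
#: reference tissues.
DEFAULT_TISSUES = (
    "root_hair", "root", "leaf", "stem", "shoot_apex",
    "panicle", "anther", "pistil", "seed", "endosperm",
)


def simulate_compendium(
    n_genes: int = 2000,
    tissues: Sequence[str] = DEFAULT_TISSUES,
    target_tissue: str = "root_hair",
    reference_tissue: str = "root",
    replicates_per_tissue: int = 3,
    n_preferential: int = 100,
    effect_log2: float = 2.0,
    baseline_mean: float = 9.0,
    baseline_sd: float = 1.0,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Simulate a genes × samples log2-intensity compendium.

    Each gene draws one baseline level from Normal(baseline_mean,
    baseline_sd²) shared by all tissues; planted target-preferential genes
    add ``effect_log2`` to their target-tissue mean.  Replicate arrays add
    independent Normal(0, noise_sd²) measurement noise.
    """
    if n_preferential > n_genes:
        raise ValidationError("n_preferential exceeds n_genes")
    if effect_log2 < 0:
        raise ValidationError("effect_log2 must be ≥ 0")
    if replicates_per_tissue < 1 or n_genes < 1:
        raise ValidationError("need ≥1 gene and ≥1 replicate per tissue")
    for role, t in (("target", target_tissue), ("reference", reference_tissue)):
        if t not in tissues:
            raise ValidationError(f"{role} tissue {t!r} not in tissue panel")

    rng = substream(seed, "compendium")
    width = max(5, len(str(n_genes)))
    gene_ids = [f"g{i:0{width}d}" for i in range(1, n_genes + 1)]
    planted = sorted(rng.choice(n_genes, size=n_preferential, replace=False))
    planted_ids = {gene_ids[i] for i in planted}

    baseline = rng.normal(baseline_mean, baseline_sd, size=n_genes)
    t_index = {t: j for j, t in enumerate(tissues)}
    means = np.tile(baseline[:, None], (1, len(tissues)))
    means[planted, t_index[target_tissue]] += effect_log2

    sample_ids, sample_tissue, cols = [], {}, []
    for t in tissues:
        for r in range(1, replicates_per_tissue + 1):
            sid = f"{t}_r{r}"
            sample_ids.append(sid)
            sample_tissue[sid] = t
            cols.append(means[:, t_index[t]] +
                        rng.normal(0.0, noise_sd, size=n_genes))
    values = pd.DataFrame(np.column_stack(cols), index=gene_ids,
                          columns=sample_ids)

    matrix = ExpressionMatrix(values=values, sample_tissue=sample_tissue,
                              target_tissue=target_tissue,
                              reference_tissue=reference_tissue)
    truth = SyntheticTruth(
        planted_preferential=planted_ids,
        generator_params={
            "compendium": {
                "n_genes": n_genes, "tissues": list(tissues),
                "target_tissue": target_tissue,
                "reference_tissue": reference_tissue,
                "replicates_per_tissue": replicates_per_tissue,
                "n_preferential": n_preferential,
                "effect_log2": effect_log2, "baseline_mean": baseline_mean,
                "baseline_sd": baseline_sd, "noise_sd": noise_sd, "seed": seed,
            }
        },
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

def simulate_annotations(
    gene_ids: Sequence[str],
    planted_preferential: set[str],
    planted_term: str = "GO:PLANTED",
    planted_term_label: str = "planted process",
    n_terms: int = 20,
    genome_total_repeats: int = 39571,
    enrichment_rate: float = 0.5,
    background_rate: float = 0.02,
    seed: int = 0,
    truth: SyntheticTruth | None = None,
) -> tuple[AnnotationTable, SyntheticTruth]:
    """Annotate genes with flat terms, over-representing one planted term.

    Planted preferential genes receive ``planted_term`` with probability
    ``enrichment_rate``; every other (gene, term) assignment happens at
    ``background_rate``.
    """
    for name, r in (("enrichment_rate", enrichment_rate),
                    ("background_rate", background_rate)):
        if not 0.0 <= r <= 1.0:
            raise ValidationError(f"{name} must be in [0, 1], got {r}")
    if n_terms < 1:
        raise ValidationError("need at least one term")

    rng = substream(seed, "annotations")
    terms = [(planted_term, planted_term_label)] + [
        (f"GO:{i:07d}", f"background process {i}") for i in range(1, n_terms)
    ]
    planted_set = set(planted_preferential)
    rows = []
    for gene in gene_ids:
        for term_id, label in terms:
            p = background_rate
            if term_id == planted_term and gene in planted_set:
                p = enrichment_rate
            if rng.random() < p:
                rows.append((gene, term_id, label))
    table = AnnotationTable(
        pairs=pd.DataFrame(rows, columns=["gene_id", "term_id", "term_label"]),
        genome_total_repeats=genome_total_repeats,
    )
    truth = truth or SyntheticTruth(planted_preferential=planted_set)
    truth.planted_term = planted_term
    truth.generator_params["annotations"] = {
        "planted_term": planted_term, "n_terms": n_terms,
        "genome_total_repeats": genome_total_repeats,
        "enrichment_rate": enrichment_rate,
        "background_rate": background_rate, "seed": seed,
    }
    return table, truth


# ---------------------------------------------------------------------------
# Promoters
# ---------------------------------------------------------------------------

def _concrete_instance(consensus: str, rng: np.random.Generator) -> str:
    """Sample one concrete A/C/G/T sequence matching an IUPAC consensus."""
    return "".join(rng.choice(sorted(IUPAC_CODES[c])) for c in consensus)


def simulate_promoters(
    gene_ids: Sequence[str],
    motif: Motif | str,
    genes_with_motif: set[str],
    window_length: int = 2000,
    hits_per_gene: int = 1,
    seed: int = 0,
    truth: SyntheticTruth | None = None,
) -> tuple[PromoterSet, SyntheticTruth]:
    """Uniform-background promoters with exact motif copies planted.

    Copies are planted on a random strand at non-overlapping positions; each
    planted (offset, strand) is recorded in the truth object.  A '−' strand
    plant writes the reverse complement at that offset.
    """
    if isinstance(motif, str):
        motif = Motif(name="planted", consensus=motif)
    w = len(motif)
    if w > window_length:
        raise ValidationError("motif longer than the promoter window")
    max_hits = (window_length + 1) // w  # loose non-overlap feasibility bound
    if hits_per_gene > max_hits:
        raise ValidationError(
            f"cannot place {hits_per_gene} non-overlapping {w}-mers "
            f"in a {window_length} nt window"
        )

    rng = substream(seed, "promoters")
    bases = np.array(list("ACGT"))
    records: list[tuple[str, str]] = []
    positions: dict[str, list[tuple[int, str]]] = {}
    for gene in gene_ids:
        seq = rng.choice(bases, size=window_length)
        if gene in genes_with_motif:
            placed: list[tuple[int, str]] = []
            attempts = 0
            while len(placed) < hits_per_gene:
                attempts += 1
                if attempts > 1000 * hits_per_gene:
                    raise ValidationError(
                        f"could not place {hits_per_gene} non-overlapping "
                        f"hits in gene {gene!r}"
                    )
                off = int(rng.integers(0, window_length - w + 1))
                if any(off < p + w and p < off + w for p, _ in placed):
                    continue
                strand = "+" if rng.random() < 0.5 else "-"
                instance = _concrete_instance(motif.consensus, rng) \
                    if motif.consensus else motif.max_probability_sequence()
                if strand == "-":
                    instance = reverse_complement(instance)
                seq[off:off + w] = list(instance)
                placed.append((off, strand))
            positions[gene] = sorted(placed)
        records.append((gene, "".join(seq)))

    promoters = PromoterSet(records=records, window_length=window_length)
    truth = truth or SyntheticTruth()
    truth.planted_motif_positions.update(positions)
    truth.generator_params["promoters"] = {
        "window_length": window_length, "motif": motif.name,
        "hits_per_gene": hits_per_gene, "seed": seed,
    }
    return promoters, truth


# ---------------------------------------------------------------------------
# PPI edges
# ---------------------------------------------------------------------------

def simulate_ppi(
    gene_ids: Sequence[str],
    planted_preferential: set[str],
    n_edges_planted: int = 30,
    n_edges_background: int = 100,
    seed: int = 0,
    truth: SyntheticTruth | None = None,
) -> tuple[EdgeList, SyntheticTruth]:
    """Random PPI edges: planted edges touch preferential genes, background
    edges connect non-planted genes only.  No self-loops or duplicates."""
    rng = substream(seed, "ppi")
    genes = list(gene_ids)
    planted = sorted(set(planted_preferential) & set(genes))
    others = [g for g in genes if g not in set(planted)]

    n_pairs_planted = len(planted) * (len(genes) - 1) - \
        len(planted) * (len(planted) - 1) // 2
    n_pairs_background = len(others) * (len(others) - 1) // 2
    if n_edges_planted > max(0, n_pairs_planted):
        raise ValidationError("more planted edges requested than distinct pairs")
    if n_edges_background > n_pairs_background:
        raise ValidationError("more background edges requested than distinct pairs")

    seen: set[tuple[str, str]] = set()

    def draw(pool_a: list[str], pool_b: list[str], n: int) -> list[tuple[str, str]]:
        out: list[tuple[str, str]] = []
        attempts = 0
        while len(out) < n:
            attempts += 1
            if attempts > 10000 * max(n, 1):
                raise ValidationError("edge sampling failed to converge")
            a = pool_a[int(rng.integers(len(pool_a)))]
            b = pool_b[int(rng.integers(len(pool_b)))]
            if a == b:
                continue
            key = (a, b) if a < b else (b, a)
            if key in seen:
                continue
            seen.add(key)
            out.append(key)
        return out

    planted_edges = draw(planted, genes, n_edges_planted) if n_edges_planted else []
    background_edges = (draw(others, others, n_edges_background)
                        if n_edges_background else [])
    edges = EdgeList(edges=[(a, b, "planted") for a, b in planted_edges] +
                           [(a, b, "background") for a, b in background_edges])
    truth = truth or SyntheticTruth(planted_preferential=set(planted))
    truth.planted_edges.update(planted_edges)
    truth.generator_params["ppi"] = {
        "n_edges_planted": n_edges_planted,
        "n_edges_background": n_edges_background, "seed": seed,
    }
    return edges, truth


# ---------------------------------------------------------------------------
# Full bundle
# ---------------------------------------------------------------------------

def simulate_bundle(
    out_dir: str | Path,
    seed: int = 0,
    n_genes: int = 2000,
    n_preferential: int = 100,
    effect_log2: float = 2.0,
    noise_sd: float = 0.3,
    replicates_per_tissue: int = 3,
    motif_consensus: str = "GCACGTGCAAAGCCGT",
    window_length: int = 2000,
) -> dict[str, Path]:
    """Write a complete synthetic input set (plus truth file) to a directory.

    Returns the mapping of logical names to written paths.  The default
    16-nt motif consensus stands in for a root hair-specific cis-element; it
    is synthetic, not a published element.
    """
    from . import data_io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, truth = simulate_compendium(
        n_genes=n_genes, n_preferential=n_preferential,
        effect_log2=effect_log2, noise_sd=noise_sd,
        replicates_per_tissue=replicates_per_tissue, seed=seed)
    annotations, truth = simulate_annotations(
        matrix.gene_ids, truth.planted_preferential, seed=seed, truth=truth)
    promoters, truth = simulate_promoters(
        matrix.gene_ids, motif_consensus,
        genes_with_motif=truth.planted_preferential,
        window_length=window_length, seed=seed, truth=truth)
    ppi, truth = simulate_ppi(
        matrix.gene_ids, truth.planted_preferential, seed=seed, truth=truth)

    paths = {
        "matrix": out / "matrix.tsv",
        "tissue_map": out / "tissue_map.tsv",
        "annotations": out / "annotations.tsv",
        "promoters": out / "promoters.fasta",
        "ppi": out / "ppi.tsv",
        "motif": out / "motif.txt",
        "truth": out / "truth.json",
    }
    data_io.write_expression_matrix(matrix, paths["matrix"])
    data_io.write_tissue_map(matrix.sample_tissue, paths["tissue_map"])
    data_io.write_annotation_table(annotations, paths["annotations"])
    data_io.write_fasta_promoters(promoters, paths["promoters"])
    data_io.write_edge_list(ppi, paths["ppi"])
    paths["motif"].write_text(motif_consensus + "\n", encoding="utf-8")
    truth.to_json(paths["truth"])
    return paths
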