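"""Cross-species conservation of tissue-preferential expression.

Given the preferential gene sets of two species and an ortholog pair table
oriented (species 1, species 2), counts for each side how many genes have
any ortholog and how many are *conserved* — i.e. have at least one ortholog
partner inside the other species' preferential set.  Many-to-many orthology
counts each gene once.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable

from .data_io import OrthologTable


def _pct(count: int, total: int) -> float:
    """Percentage at 1 dp, half-up; 0.0 for an empty set."""
    if total == 0:
        return 0.0
    raw = 100.0 * count / total
    return float(Decimal(repr(raw)).quantize(Decimal("0.1"),
                                             rounding=ROUND_HALF_UP))


@dataclass
class ConservationStats:
    n_set1: int
    n_set2: int
    n_set1_with_ortholog: int
    n_set2_with_ortholog: int
    n_set1_conserved: int
    n_set2_conserved: int

    @property
    def pct_set1_with_ortholog(self) -> float:
        return _pct(self.n_set1_with_ortholog, self.n_set1)

    @property
    def pct_set2_with_ortholog(self) -> float:
        return _pct(self.n_set2_with_ortholog, self.n_set2)

    @property
    def pct_set1_conserved(self) -> float:
        return _pct(self.n_set1_conserved, self.n_set1)

    @property
    def pct_set2_conserved(self) -> float:
        return _pct(self.n_set2_conserved, self.n_set2)

    def swapped(self) -> "ConservationStats":
        return ConservationStats(
            n_set1=self.n_set2, n_set2=self.n_set1,
            n_set1_with_ortholog=self.n_set2_with_ortholog,
            n_set2_with_ortholog=self.n_set1_with_ortholog,
            n_set1_conserved=self.n_set2_conserved,
            n_set2_conserved=self.n_set1_conserved)


def conservation_stats(set1: Iterable[str], set2: Iterable[str],
                       orthologs: OrthologTable) -> ConservationStats:
    """Ortholog coverage and expression-conservation counts for two
    preferential gene sets."""
    s1, s2 = set(set1), set(set2)
    partners1: dict[str, set[str]] = {}
    partners2: dict[str, set[str]] = {}
    for a, b in orthologs:
        partners1.setdefault(a, set()).add(b)
        partners2.setdefault(b, set()).add(a)
    with1 = {g for g in s1 if g in partners1}
    with2 = {g for g in s2 if g in partners2}
    cons1 = {g for g in with1 if partners1[g] & s2}
    cons2 = {g for g in with2 if partners2[g] & s1}
    return ConservationStats(
        n_set1=len(s1), n_set2=len(s2),
        n_set1_with_ortholog=len(with1), n_set2_with_ortholog=len(with2),
        n_set1_conserved=len(cons1), n_set2_conserved=len(cons2))


def write_conservation_summary(stats: ConservationStats, path: str | Path,
                               label1: str = "species1",
                               label2: str = "species2") -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("species\tset_size\twith_ortholog\tpct_with_ortholog\t"
                 "conserved\tpct_conserved\n")
        fh.write(f"{label1}\t{stats.n_set1}\t{stats.n_set1_with_ortholog}\t"
                 f"{stats.pct_set1_with_ortholog:.1f}\t"
                 f"{stats.n_set1_conserved}\t{stats.pct_set1_conserved:.1f}\n")
        fh.write(f"{label2}\t{stats.n_set2}\t{stats.n_set2_with_ortholog}\t"
                 f"{stats.pct_set2_with_ortholog:.1f}\t"
                 f"{stats.n_set2_conserved}\t{stats.pct_set2_conserved:.1f}\n")
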