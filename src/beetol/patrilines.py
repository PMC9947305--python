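"""Queen genotype deduction and patriline grouping from microsatellites.

Workers in a honeybee colony are diploid daughters of one queen and one of
her (haploid) mates, so at every locus a worker carries one queen allele and
the sire's single allele.  The queen's diploid genotype is deduced per locus
by exhaustive scoring of candidate allele pairs against the workers; the
paternal allele of each worker is then whatever the queen cannot explain,
with an ambiguity set where the queen is heterozygous and the worker carries
both queen alleles.  Workers whose paternal haplotypes are compatible at all
mutually typed loci are grouped into one patriline (same drone father).
Two drones sharing a full multilocus haplotype are unresolvable by design
and count as one patriline.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .io_formats import GenotypeTable

log = logging.getLogger("beetol")

__all__ = [
    "QueenGenotype",
    "PaternalHaplotype",
    "PatrilineAssignment",
    "infer_queen_genotype",
    "extract_paternal",
    "group_patrilines",
    "assign_patrilines",
]


@dataclass
class QueenGenotype:
    """Per-locus deduced queen genotype with ambiguity records.

    ``pairs[locus]`` is the chosen unordered pair (None where the locus was
    uninformative); ``ambiguous[locus]`` lists every co-maximal candidate
    pair (including the chosen one) when the maximum was not unique.
    """

    pairs: dict[str, tuple[int, int] | None]
    ambiguous: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    consistency: dict[str, float] = field(default_factory=dict)

    @property
    def resolved_loci(self) -> list[str]:
        return [l for l, p in self.pairs.items() if p is not None]


def infer_queen_genotype(
    table: GenotypeTable,
    colony: str | None = None,
    max_mismatch_fraction: float = 0.05,
) -> QueenGenotype:
    """Deduce the queen's diploid genotype per locus by exhaustive scoring.

    Every candidate unordered pair (heterozygous or homozygous) over the
    worker alleles at a locus is scored by the number of typed workers
    sharing at least one allele with it; the maximizer wins.  Ties prefer a
    heterozygous pair, then the pair whose alleles are most frequent among
    workers, then the lexicographically smallest pair; all co-maximal pairs
    are kept in the ambiguity record.  A locus whose best consistency is
    below ``1 - max_mismatch_fraction`` is marked uninformative (None).
    """
    if colony is not None:
        table = table.colony(colony)
    if len(table.workers) < 2:
        raise ValueError("queen inference needs at least 2 workers")
    pairs: dict[str, tuple[int, int] | None] = {}
    ambiguous: dict[str, list[tuple[int, int]]] = {}
    consistency: dict[str, float] = {}
    for locus in table.loci:
        genos = [g for g in table.data[locus] if g is not None]
        if not genos:
            pairs[locus] = None
            consistency[locus] = 0.0
            continue
        allele_counts = Counter(a for g in genos for a in g)
        alleles = sorted(allele_counts)
        candidates = [
            tuple(sorted(p))
            for p in itertools.combinations_with_replacement(alleles, 2)
        ]
        scores = {
            cand: sum(1 for g in genos if cand[0] in g or cand[1] in g)
            for cand in candidates
        }
        best_score = max(scores.values())
        co_maximal = sorted(c for c, s in scores.items() if s == best_score)
        frac = best_score / len(genos)
        consistency[locus] = frac
        if frac < 1.0 - max_mismatch_fraction:
            log.info(
                "locus %s uninformative: best queen consistency %.3f", locus, frac
            )
            pairs[locus] = None
            ambiguous[locus] = co_maximal
            continue
        chosen = min(
            co_maximal,
            key=lambda c: (
                c[0] == c[1],  # prefer heterozygous
                -(allele_counts[c[0]] + allele_counts[c[1]]),
                c,
            ),
        )
        pairs[locus] = chosen
        if len(co_maximal) > 1:
            ambiguous[locus] = co_maximal
    if all(p is None for p in pairs.values()):
        raise ValueError("queen genotype could not be deduced at any locus")
    return QueenGenotype(pairs=pairs, ambiguous=ambiguous, consistency=consistency)


@dataclass
class PaternalHaplotype:
    """Per-locus candidate sire alleles for one worker.

    ``sets[locus]`` is a frozenset of candidate paternal alleles (singleton
    where resolved), absent where the worker is untyped or the queen
    unresolved.  ``mismatches`` lists loci where the worker shares no queen
    allele (error-tolerant: both worker alleles kept as candidates).
    """

    worker: str
    sets: dict[str, frozenset[int]]
    mismatches: list[str] = field(default_factory=list)

    @property
    def resolved_loci(self) -> list[str]:
        return [l for l, s in self.sets.items() if len(s) == 1]

    @property
    def n_resolved(self) -> int:
        return len(self.resolved_loci)


def extract_paternal(
    worker: str,
    genotypes: Mapping[str, tuple[int, int] | None],
    queen: QueenGenotype,
) -> PaternalHaplotype:
    """The sire-allele ambiguity set per locus for one worker.

    Queen homozygous or worker carrying exactly one non-queen allele →
    singleton; queen heterozygous with the worker carrying both queen
    alleles → both worker alleles stay candidates; no shared allele →
    mismatch (both worker alleles kept, mismatch counted).
    """
    sets: dict[str, frozenset[int]] = {}
    mismatches: list[str] = []
    for locus, qpair in queen.pairs.items():
        g = genotypes.get(locus)
        if g is None or qpair is None:
            continue
        a, b = g
        non_queen = [x for x in (a, b) if x not in qpair]
        if len(non_queen) == 1:
            sets[locus] = frozenset(non_queen)
        elif len(non_queen) == 0:
            if qpair[0] == qpair[1]:
                # queen homozygous (q,q), worker (q,q): paternal is q
                sets[locus] = frozenset({qpair[0]})
            else:
                sets[locus] = frozenset({a, b})
        else:  # worker shares no queen allele
            mismatches.append(locus)
            sets[locus] = frozenset({a, b})
    return PaternalHaplotype(worker=worker, sets=sets, mismatches=mismatches)


@dataclass
class PatrilineAssignment:
    """Result of grouping workers by compatible paternal haplotypes."""

    assignment: dict[str, str]  # worker -> patriline id
    counts: dict[str, int]
    consensus: dict[str, dict[str, frozenset[int]]]
    unassigned: list[tuple[str, str]]  # (worker, reason)

    @property
    def n_patrilines(self) -> int:
        return len(self.counts)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"worker_id": w, "patriline": p} for w, p in self.assignment.items()]
        rows += [{"worker_id": w, "patriline": ""} for w, _ in self.unassigned]
        return pd.DataFrame(rows)


def _compatible(
    consensus: Mapping[str, frozenset[int]], hap: PaternalHaplotype
) -> bool:
    return all(
        consensus[l] & s for l, s in hap.sets.items() if l in consensus
    )


def group_patrilines(
    haplotypes: list[PaternalHaplotype],
    min_resolved_loci: int = 6,
) -> PatrilineAssignment:
    """Greedy compatibility clustering of paternal haplotypes.

    Workers are visited by (resolved-locus count desc, worker id asc) —
    maximal information first, deterministic.  A worker joins the first
    cluster whose running consensus (per-locus intersection of member sets)
    intersects its own set at every mutually typed locus; otherwise it seeds
    a new cluster.  Workers with fewer than ``min_resolved_loci`` resolved
    (singleton) loci are left unassigned.
    """
    ordered = sorted(haplotypes, key=lambda h: (-h.n_resolved, h.worker))
    clusters: list[dict] = []
    unassigned: list[tuple[str, str]] = []
    for hap in ordered:
        if hap.n_resolved < min_resolved_loci:
            unassigned.append(
                (hap.worker, f"only {hap.n_resolved} resolved loci (<{min_resolved_loci})")
            )
            continue
        placed = False
        for cl in clusters:
            if _compatible(cl["consensus"], hap):
                for locus, s in hap.sets.items():
                    cur = cl["consensus"].get(locus)
                    cl["consensus"][locus] = s if cur is None else cur & s
                cl["members"].append(hap.worker)
                placed = True
                break
        if not placed:
            clusters.append({"consensus": dict(hap.sets), "members": [hap.worker]})

    clusters.sort(key=lambda cl: (-len(cl["members"]), min(cl["members"])))
    assignment: dict[str, str] = {}
    counts: dict[str, int] = {}
    consensus: dict[str, dict[str, frozenset[int]]] = {}
    for i, cl in enumerate(clusters):
        pid = f"P{i + 1:02d}"
        for w in cl["members"]:
            assignment[w] = pid
        counts[pid] = len(cl["members"])
        consensus[pid] = cl["consensus"]
    return PatrilineAssignment(
        assignment=assignment,
        counts=counts,
        consensus=consensus,
        unassigned=unassigned,
    )


def assign_patrilines(
    table: GenotypeTable,
    colony: str,
    max_mismatch_fraction: float = 0.05,
    min_resolved_loci: int = 6,
) -> tuple[QueenGenotype, PatrilineAssignment, dict[str, PaternalHaplotype]]:
    """Full per-colony reconstruction: queen, paternal haplotypes, grouping."""
    sub = table.colony(colony)
    queen = infer_queen_genotype(sub, max_mismatch_fraction=max_mismatch_fraction)
    haps = {
        w: extract_paternal(w, sub.worker_genotypes(w), queen) for w in sub.workers
    }
    grouping = group_patrilines(list(haps.values()), min_resolved_loci=min_resolved_loci)
    return queen, grouping, haps
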