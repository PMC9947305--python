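"""Synthetic polyandrous honeybee colonies with known genetic structure.

The generator emulates the design of an acute oral clothianidin assay on
workers from colonies headed by naturally mated queens: each colony has one
diploid queen and k haploid drones (patrilines; field observations in the
emulated study were 26 and 21), workers inherit one queen allele and the
sire's allele at each of 11 hypervariable microsatellite loci, and 24-h
survival is Bernoulli with a logit-scale death probability

    logit(p_death) = mu + colony effect + patriline effect + CYP9Q effects

with colony and patriline effects i.i.d. Normal — the standard
threshold-liability analogue, which makes the downstream broad-sense
heritability target well defined.  Drones also carry per-gene CYP9Q
amino-acid haplotype labels drawn from a frequency table, with planted
logit offsets so haplotype-association stages can be validated against
truth.  All outputs are deterministic given ``seed``.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .haplotypes import AA_TO_CODONS, ChangeProfile, parse_change
from .io_formats import GenotypeTable

__all__ = [
    "SimConfig",
    "Drone",
    "WorkerRecord",
    "GENES",
    "DEFAULT_GENE_PROFILES",
    "simulate_colony",
    "simulate_colonies",
    "apply_genotyping_errors",
    "random_reference_cds",
    "reference_for_profiles",
    "simulate_cds_set",
    "genotype_table",
    "phenotype_frame",
    "truth_frame",
]

GENES = ("CYP9Q1", "CYP9Q2", "CYP9Q3")

#: Amino-acid change profiles per gene haplotype label.  The event vocabulary
#: mirrors the published mutation table for these genes: CYP9Q1 carries
#: Gln60Glu / Pro87Ser / Ser213Ala / Met252Val / Thr257Ala (haplotype E
#: additionally truncating), CYP9Q3 carries Thr62Met, Thr152Ile, Gly238Arg/Asp,
#: Met288Thr, the Thr302 in-frame deletion (haplotype P), Leu317Ile,
#: Val380Ala and Ala387Pro; CYP9Q2 has only the conservative Ile248Val and
#: His467Tyr.  "wt" is the empty profile.
DEFAULT_GENE_PROFILES: dict[str, dict[str, tuple[str, ...]]] = {
    "CYP9Q1": {
        "wt": (),
        "A": ("Gln60Glu",),
        "B": ("Ser213Ala", "Met252Val", "Thr257Ala"),
        "D": ("Ser213Ala",),
        "E": ("Ser213Ala", "Met252Val", "Thr257Ala", "Ser300Ter"),
        "F": ("Pro87Ser",),
    },
    "CYP9Q2": {
        "wt": (),
        "A": ("Ile248Val",),
        "B": ("His467Tyr",),
        "C": ("Ile248Val", "His467Tyr"),
    },
    "CYP9Q3": {
        "wt": (),
        "K": ("Thr62Met", "Thr152Ile"),
        "L": ("Thr62Met", "Met288Thr", "Val380Ala"),
        "M": ("Thr62Met", "Gly238Asp", "Leu317Ile", "Val380Ala", "Ala387Pro"),
        "N": ("Thr62Met", "Gly238Arg", "Leu317Ile", "Val380Ala", "Ala387Pro"),
        "O": ("Thr62Met",),
        "P": ("Thr302del",),
    },
}

DEFAULT_HAPLOTYPE_FREQS: dict[str, dict[str, float]] = {
    "CYP9Q1": {"wt": 0.25, "A": 0.20, "B": 0.18, "D": 0.15, "E": 0.08, "F": 0.14},
    "CYP9Q2": {"wt": 0.40, "A": 0.25, "B": 0.20, "C": 0.15},
    "CYP9Q3": {"wt": 0.30, "K": 0.08, "L": 0.14, "M": 0.10, "N": 0.12, "O": 0.14, "P": 0.12},
}

#: Logit-scale offsets on the death probability.  CYP9Q3 L/N/P lower survival
#: strongly; CYP9Q1 B/E modulate; CYP9Q2 is inert — the planted analogue of
#: the association structure the pipeline is meant to recover.
DEFAULT_HAPLOTYPE_EFFECTS: dict[str, dict[str, float]] = {
    "CYP9Q1": {"B": 0.8, "E": 0.8},
    "CYP9Q2": {},
    "CYP9Q3": {"L": 1.6, "N": 1.6, "P": 1.6},
}


def _per_colony(value: int | Sequence[int], n: int, name: str) -> list[int]:
    if isinstance(value, (int, np.integer)):
        return [int(value)] * n
    vals = [int(v) for v in value]
    if len(vals) != n:
        raise ValueError(f"{name} must be a scalar or length-{n} sequence")
    return vals


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic colonies.

    Defaults are the emulated study's conditions: two colonies, ~248 exposed
    workers each, 26 and 21 patrilines, 11 microsatellite loci, baseline 24-h
    death probability 0.22 (the observed 109/496), with effect SDs sized to
    give patriline-level heritability of the observed order.
    """

    n_colonies: int = 2
    workers_per_colony: int | Sequence[int] = (247, 249)
    k_patrilines: int | Sequence[int] = (26, 21)
    patriline_concentration: float = 1.0
    n_loci: int = 11
    alleles_per_locus: int = 8
    allele_freq_model: float = 1.0
    mu_logit: float = float(logit(0.22))
    sigma_colony: float = 0.25
    sigma_patriline: float = 1.0
    haplotype_freq_table: dict[str, dict[str, float]] = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_HAPLOTYPE_FREQS)
    )
    haplotype_effect_table: dict[str, dict[str, float]] = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_HAPLOTYPE_EFFECTS)
    )
    group_fractions: dict[str, float] = field(
        default_factory=lambda: {"lethal": 1.0}
    )
    control_death_prob: float = 0.05
    genotyping_error_rate: float = 0.0
    consumed_below_min_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_colonies < 1 or self.n_loci < 1 or self.alleles_per_locus < 2:
            raise ValueError("need >=1 colony, >=1 locus, >=2 alleles per locus")
        if min(_per_colony(self.k_patrilines, self.n_colonies, "k_patrilines")) < 1:
            raise ValueError("k_patrilines must be >= 1")
        if self.sigma_colony < 0 or self.sigma_patriline < 0:
            raise ValueError("effect SDs must be >= 0")
        for p in (
            self.control_death_prob,
            self.genotyping_error_rate,
            self.consumed_below_min_rate,
        ):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        if self.patriline_concentration <= 0 or self.allele_freq_model <= 0:
            raise ValueError("Dirichlet concentrations must be > 0")
        tot = sum(self.group_fractions.values())
        if not np.isclose(tot, 1.0):
            raise ValueError("group_fractions must sum to 1")

    @property
    def loci(self) -> list[str]:
        return [f"L{i + 1:02d}" for i in range(self.n_loci)]


@dataclass(frozen=True)
class Drone:
    """A haploid sire: one allele per locus plus per-gene CYP9Q labels."""

    id: str
    alleles: tuple[int, ...]
    cyp: dict[str, str]


@dataclass
class WorkerRecord:
    """One exposed worker bee with full simulation truth attached."""

    id: str
    colony: str
    genotypes: dict[str, tuple[int, int]]
    true_patriline: str
    cyp: dict[str, str]
    survived: bool | None
    consumed_fraction: float
    dose_group: str


def _colony_rng(seed: int, colony_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(int(colony_index),))
    )


def simulate_colony(
    config: SimConfig, colony_index: int
) -> tuple[dict[str, tuple[int, int]], list[Drone], list[WorkerRecord]]:
    """Simulate one colony: queen genotype, drones and worker records.

    Allele fragment lengths are integers on a per-locus ladder (unlinked
    loci, no null alleles).  Drones may collide (share the full multilocus
    haplotype); collisions are retained — two such drones are operationally
    one patriline downstream — and visible through duplicate allele tuples.
    """
    n_workers = _per_colony(config.workers_per_colony, config.n_colonies, "workers_per_colony")[colony_index]
    k = _per_colony(config.k_patrilines, config.n_colonies, "k_patrilines")[colony_index]
    rng = _colony_rng(config.seed, colony_index)
    colony = f"C{colony_index + 1:02d}"
    loci = config.loci
    genes = tuple(config.haplotype_freq_table)

    # per-locus allele ladders and Dirichlet population frequencies
    ladders = [
        [100 + 10 * j + 2 * a for a in range(config.alleles_per_locus)]
        for j in range(config.n_loci)
    ]
    freqs = rng.dirichlet(
        np.full(config.alleles_per_locus, config.allele_freq_model), size=config.n_loci
    )

    def draw_allele(j: int) -> int:
        return int(rng.choice(ladders[j], p=freqs[j]))

    queen = {
        locus: tuple(sorted((draw_allele(j), draw_allele(j))))
        for j, locus in enumerate(loci)
    }

    drones: list[Drone] = []
    for d in range(k):
        alleles = tuple(draw_allele(j) for j in range(config.n_loci))
        cyp = {}
        for gene in genes:
            tab = config.haplotype_freq_table[gene]
            labels = sorted(tab)
            p = np.array([tab[l] for l in labels], dtype=float)
            cyp[gene] = labels[int(rng.choice(len(labels), p=p / p.sum()))]
        drones.append(Drone(id=f"{colony}-D{d + 1:02d}", alleles=alleles, cyp=cyp))

    shares = rng.dirichlet(np.full(k, config.patriline_concentration))
    colony_effect = rng.normal(0.0, config.sigma_colony)
    patriline_effects = rng.normal(0.0, config.sigma_patriline, size=k)

    group_names = sorted(config.group_fractions)
    group_p = np.array([config.group_fractions[g] for g in group_names])

    workers: list[WorkerRecord] = []
    for w in range(n_workers):
        sire_idx = int(rng.choice(k, p=shares))
        sire = drones[sire_idx]
        genotypes = {}
        for j, locus in enumerate(loci):
            maternal = queen[locus][int(rng.integers(2))]
            genotypes[locus] = tuple(sorted((maternal, sire.alleles[j])))
        dose_group = group_names[int(rng.choice(len(group_names), p=group_p))]
        if dose_group == "lethal":
            eta = (
                config.mu_logit
                + colony_effect
                + patriline_effects[sire_idx]
                + sum(
                    config.haplotype_effect_table.get(g, {}).get(sire.cyp[g], 0.0)
                    for g in genes
                )
            )
            p_death = float(expit(eta))
        else:
            p_death = config.control_death_prob
        survived = bool(rng.random() >= p_death)
        if rng.random() < config.consumed_below_min_rate:
            consumed = float(rng.uniform(0.5, 0.9))
        else:
            consumed = float(rng.uniform(0.9, 1.0))
        workers.append(
            WorkerRecord(
                id=f"{colony}-W{w + 1:03d}",
                colony=colony,
                genotypes=genotypes,
                true_patriline=sire.id,
                cyp=dict(sire.cyp),
                survived=survived,
                consumed_fraction=consumed,
                dose_group=dose_group,
            )
        )
    return queen, drones, workers


def simulate_colonies(
    config: SimConfig,
) -> list[tuple[dict[str, tuple[int, int]], list[Drone], list[WorkerRecord]]]:
    return [simulate_colony(config, i) for i in range(config.n_colonies)]


def apply_genotyping_errors(
    workers: Sequence[WorkerRecord],
    rate: float,
    rng: np.random.Generator,
) -> list[WorkerRecord]:
    """Return copies with each allele call miscalled with probability ``rate``.

    A miscall replaces the call with a uniformly chosen *other* allele
    observed at that locus (across the given workers).  Truth stays in the
    original records; copies keep truth labels so accuracy can be scored.
    """
    if not 0 <= rate <= 1:
        raise ValueError("rate must be in [0, 1]")
    loci = list(workers[0].genotypes) if workers else []
    universe = {
        locus: sorted({a for w in workers for a in w.genotypes[locus]})
        for locus in loci
    }
    out: list[WorkerRecord] = []
    for w in workers:
        genotypes = {}
        for locus in loci:
            pair = list(w.genotypes[locus])
            for i in (0, 1):
                if rate > 0 and rng.random() < rate:
                    others = [a for a in universe[locus] if a != pair[i]]
                    if others:
                        pair[i] = int(rng.choice(others))
            genotypes[locus] = tuple(sorted(pair))
        w2 = copy.copy(w)
        w2.genotypes = genotypes
        out.append(w2)
    return out


# ---------------------------------------------------------------------------
# coding-sequence synthesis


def random_reference_cds(n_codons: int, seed: int | np.random.Generator = 0) -> str:
    """A random in-frame CDS: ATG, ``n_codons - 1`` random non-stop codons, TAA.

    ``n_codons`` counts protein residues (the terminal stop is extra).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sense = sorted(c for aa, cs in AA_TO_CODONS.items() if aa != "*" for c in cs)
    body = [sense[int(rng.integers(len(sense)))] for _ in range(n_codons - 1)]
    return "ATG" + "".join(body) + "TAA"


_CODON_TO_AA = {c: aa for aa, cs in AA_TO_CODONS.items() for c in cs}


def reference_for_profiles(
    n_codons: int,
    profiles: Mapping[str, ChangeProfile | Sequence[str]],
    seed: int | np.random.Generator = 0,
) -> str:
    """A random reference CDS whose residues match the profiles' ref alleles.

    Event labels pin the reference residue at their position (e.g. Thr302del
    requires Thr at 302); the random CDS is patched accordingly.  Conflicting
    requirements across profiles raise ``ValueError``.
    """
    required: dict[int, str] = {}
    for name, prof in profiles.items():
        events = (
            prof.events
            if isinstance(prof, ChangeProfile)
            else tuple(parse_change(lbl) for lbl in prof)
        )
        for ev in events:
            if not 1 <= ev.position <= n_codons:
                raise ValueError(f"{name}: position {ev.position} > {n_codons} residues")
            prev = required.setdefault(ev.position, ev.ref)
            if prev != ev.ref:
                raise ValueError(
                    f"conflicting reference residues at {ev.position}: {prev} vs {ev.ref}"
                )
    ref = random_reference_cds(n_codons, seed)
    codons = [ref[3 * i : 3 * i + 3] for i in range(len(ref) // 3)]
    for pos, aa in required.items():
        if pos == 1 and aa != "M":
            raise ValueError("position 1 must be Met in a CDS")
        codons[pos - 1] = sorted(AA_TO_CODONS[aa])[0]
    return "".join(codons)


def _min_edit_codon(ref_codon: str, targets: Sequence[str]) -> str:
    def dist(c: str) -> int:
        return sum(a != b for a, b in zip(ref_codon, c))

    return min(targets, key=lambda c: (dist(c), c))


def simulate_cds_set(
    reference_cds: str,
    profiles: Mapping[str, ChangeProfile | Sequence[str]],
) -> dict[str, str]:
    """Realize amino-acid change profiles as aligned coding sequences.

    Each profile (a :class:`ChangeProfile` or a sequence of rendered labels
    like ``("Thr62Met", "Thr302del")``) yields one sequence aligned to the
    reference: substitutions are minimal codon edits, in-frame deletions
    become ``---`` codon gaps (so the degapped sequence is 3 nt shorter per
    deleted residue) and truncations become a minimal-edit premature stop.
    The wild-type (empty) profile reproduces the reference exactly.
    """
    ref = reference_cds.upper()
    if len(ref) % 3 != 0:
        raise ValueError("reference CDS length must be divisible by 3")
    n_res = len(ref) // 3 - 1  # exclude terminal stop
    out: dict[str, str] = {}
    for name, prof in profiles.items():
        if isinstance(prof, ChangeProfile):
            events = prof.events
        else:
            events = tuple(parse_change(lbl) for lbl in prof)
        codons = [ref[3 * i : 3 * i + 3] for i in range(len(ref) // 3)]
        for ev in events:
            if not 1 <= ev.position <= n_res:
                raise ValueError(
                    f"{name}: position {ev.position} outside protein (1..{n_res})"
                )
            ref_codon = codons[ev.position - 1]
            ref_aa = _CODON_TO_AA[ref_codon]
            if ref_aa != ev.ref:
                raise ValueError(
                    f"{name}: reference residue at {ev.position} is {ref_aa}, "
                    f"profile expects {ev.ref}"
                )
            if ev.alt == "-":
                codons[ev.position - 1] = "---"
            elif ev.alt == "*":
                codons[ev.position - 1] = _min_edit_codon(ref_codon, AA_TO_CODONS["*"])
            else:
                codons[ev.position - 1] = _min_edit_codon(
                    ref_codon, AA_TO_CODONS[ev.alt]
                )
        out[name] = "".join(codons)
    return out


# ---------------------------------------------------------------------------
# table exports


def genotype_table(workers: Sequence[WorkerRecord]) -> GenotypeTable:
    loci = list(workers[0].genotypes)
    data = pd.DataFrame(
        {"colony": [w.colony for w in workers]},
        index=pd.Index([w.id for w in workers], name="worker_id"),
    )
    for locus in loci:
        data[locus] = pd.Series(
            [w.genotypes[locus] for w in workers], index=data.index, dtype=object
        )
    return GenotypeTable(data, loci)


def phenotype_frame(workers: Sequence[WorkerRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "worker_id": [w.id for w in workers],
            "colony": [w.colony for w in workers],
            "dose_group": [w.dose_group for w in workers],
            "survived": pd.array([w.survived for w in workers], dtype="boolean"),
            "consumed_fraction": [w.consumed_fraction for w in workers],
        }
    )


def truth_frame(workers: Sequence[WorkerRecord]) -> pd.DataFrame:
    """Truth sidecar: true sire and CYP9Q labels per worker."""
    rows = {
        "worker_id": [w.id for w in workers],
        "colony": [w.colony for w in workers],
        "true_patriline": [w.true_patriline for w in workers],
    }
    genes = sorted(workers[0].cyp) if workers else []
    for gene in genes:
        rows[gene] = [w.cyp[gene] for w in workers]
    return pd.DataFrame(rows)
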