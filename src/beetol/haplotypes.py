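"""Amino-acid haplotype calling for CYP9Q coding sequences.

Honeybee CYP9Q1/2/3 are single-exon cytochrome P450 genes whose enzymes
metabolize neonicotinoids.  Sanger-sequenced coding windows arrive aligned to
a reference CDS; this module translates them, compares residue by residue and
emits an amino-acid change profile per sequence: substitutions ("Gln60Glu"),
in-frame codon deletions ("Thr302del") and premature stops ("Thr302Ter").
Unique profiles per gene are labelled, and unique label combinations across
genes define multigene CYP9Q haplotypes.

Positions are 1-based on the protein translated from the *full* reference
CDS; a sequenced window that starts inside the CDS is handled through
``cds_offset`` so reported positions match full-CDS numbering.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

from Bio.Data.CodonTable import standard_dna_table
from Bio.SeqUtils import seq1, seq3

__all__ = [
    "AAChange",
    "ChangeProfile",
    "HaplotypeCatalog",
    "Translation",
    "build_catalog",
    "call_changes",
    "parse_change",
    "translate_cds",
]

_STOP_CODONS = tuple(standard_dna_table.stop_codons)
_CODON_TO_AA = dict(standard_dna_table.forward_table)
_CODON_TO_AA.update({c: "*" for c in _STOP_CODONS})

#: codons encoding each amino acid (plus '*' for stops), standard code
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(_CODON_TO_AA.items()):
    AA_TO_CODONS.setdefault(_aa, ())
    AA_TO_CODONS[_aa] += (_codon,)


@dataclass(frozen=True, order=True)
class AAChange:
    """One amino-acid level event relative to the reference protein.

    ``alt`` is a one-letter amino acid for a substitution, ``"-"`` for an
    in-frame deletion of the residue and ``"*"`` for a premature stop
    (truncation).  ``position`` is 1-based on the reference protein.
    """

    position: int
    ref: str
    alt: str

    @property
    def kind(self) -> str:
        if self.alt == "-":
            return "deletion"
        if self.alt == "*":
            return "truncation"
        return "substitution"

    @property
    def label(self) -> str:
        """Field-standard rendering, e.g. ``Gln60Glu``, ``Thr302del``."""
        if self.alt == "-":
            suffix = "del"
        elif self.alt == "*":
            suffix = "Ter"
        else:
            suffix = seq3(self.alt)
        return f"{seq3(self.ref)}{self.position}{suffix}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


_CHANGE_RE = re.compile(r"^([A-Z][a-z]{2})(\d+)(del|Ter|[A-Z][a-z]{2})$")


def parse_change(label: str) -> AAChange:
    """Parse a rendered change label ("Gln60Glu", "Thr302del", "Ser300Ter")."""
    m = _CHANGE_RE.match(label)
    if m is None:
        raise ValueError(f"cannot parse amino-acid change label {label!r}")
    ref3, pos, alt3 = m.groups()
    ref = seq1(ref3)
    if ref == "X" and ref3 != "Xaa":
        raise ValueError(f"unknown reference residue in {label!r}")
    if alt3 == "del":
        alt = "-"
    elif alt3 == "Ter":
        alt = "*"
    else:
        alt = seq1(alt3)
        if alt == "X" and alt3 != "Xaa":
            raise ValueError(f"unknown substituted residue in {label!r}")
    return AAChange(position=int(pos), ref=ref, alt=alt)


@dataclass(frozen=True)
class ChangeProfile:
    """Per-gene amino-acid change profile of one sequence (haplotype)."""

    gene: str
    events: tuple[AAChange, ...] = ()

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.events, key=lambda e: e.position))
        positions = [e.position for e in ordered]
        if len(set(positions)) != len(positions):
            raise ValueError(f"duplicate event positions in profile: {positions}")
        object.__setattr__(self, "events", ordered)

    @property
    def is_wildtype(self) -> bool:
        return not self.events

    @property
    def truncated(self) -> bool:
        return any(e.alt == "*" for e in self.events)

    @property
    def key(self) -> tuple[str, ...]:
        """Canonical hashable identity: the ordered event labels."""
        return tuple(e.label for e in self.events)

    def __str__(self) -> str:
        return "+".join(self.key) if self.events else "wt"


class Translation(NamedTuple):
    protein: str
    premature_stop: bool


def translate_cds(seq: str, frame: int = 0) -> Translation:
    """Translate a (possibly gapped) DNA coding sequence.

    Gaps ("-") are removed before translation.  Translation runs to the end of
    the sequence; a stop codon before the final codon sets ``premature_stop``
    and ends the protein there.  Ambiguous codons translate to ``X`` with a
    warning.

    Raises ``ValueError`` if the gap-free length (after the frame offset) is
    not divisible by 3.
    """
    ungapped = seq.replace("-", "").upper()[frame:]
    if len(ungapped) % 3 != 0:
        raise ValueError(
            f"gap-free CDS length {len(ungapped)} is not divisible by 3"
        )
    n_codons = len(ungapped) // 3
    residues: list[str] = []
    premature = False
    for i in range(n_codons):
        codon = ungapped[3 * i : 3 * i + 3]
        aa = _CODON_TO_AA.get(codon)
        if aa is None:
            warnings.warn(f"ambiguous codon {codon!r} at codon {i + 1}; using X")
            aa = "X"
        if aa == "*":
            premature = i < n_codons - 1
            break
        residues.append(aa)
    return Translation("".join(residues), premature)


def _codon_at(seq: str, residue_index0: int) -> str:
    return seq[3 * residue_index0 : 3 * residue_index0 + 3]


def call_changes(
    sample_cds: str,
    reference_cds: str,
    gene: str = "",
    cds_offset: int = 1,
) -> ChangeProfile:
    """Call amino-acid changes of an aligned sample against a reference CDS.

    ``sample_cds`` must be aligned to the reference in a strict same-length
    sense: it covers reference CDS nucleotides ``cds_offset .. cds_offset +
    len(sample) - 1`` (1-based) with ``-`` marking deleted bases.  Deletions
    must cover whole codons; a gap touching only part of a codon is a
    frameshifting/unphased gap and raises ``ValueError`` naming the column.

    Silent (synonymous) differences are ignored.  A premature stop in the
    sample is reported as a truncation event and ends the comparison, as
    nothing downstream of the stop is part of the protein.
    """
    sample = sample_cds.upper()
    reference = reference_cds.upper().replace("-", "")
    if cds_offset < 1:
        raise ValueError("cds_offset is 1-based and must be >= 1")
    window = reference[cds_offset - 1 : cds_offset - 1 + len(sample)]
    if len(window) != len(sample):
        raise ValueError(
            f"sample ({len(sample)} nt from offset {cds_offset}) extends past "
            f"the reference CDS ({len(reference)} nt)"
        )

    phase = (cds_offset - 1) % 3
    skip = (3 - phase) % 3  # bases of a leading partial codon
    first_residue0 = (cds_offset - 1 + skip) // 3  # 0-based on full protein

    events: list[AAChange] = []
    n_full = (len(sample) - skip) // 3
    for i in range(n_full):
        start = skip + 3 * i
        ref_codon = window[start : start + 3]
        smp_codon = sample[start : start + 3]
        pos = first_residue0 + i + 1
        ref_aa = _CODON_TO_AA.get(ref_codon, "X")
        if smp_codon == "---":
            if ref_aa == "*":
                continue  # deleted terminal stop: not a protein event
            events.append(AAChange(pos, ref_aa, "-"))
            continue
        if "-" in smp_codon:
            col = start + smp_codon.index("-") + 1
            raise ValueError(
                f"gap not aligned to a codon boundary at alignment column {col}"
                " (frameshifting or unphased deletion)"
            )
        smp_aa = _CODON_TO_AA.get(smp_codon)
        if smp_aa is None:
            warnings.warn(
                f"ambiguous sample codon {smp_codon!r} at residue {pos}; skipped"
            )
            continue
        if smp_aa == ref_aa:
            continue
        if smp_aa == "*":
            events.append(AAChange(pos, ref_aa, "*"))
            break  # protein ends here
        events.append(AAChange(pos, ref_aa, smp_aa))
    return ChangeProfile(gene=gene, events=tuple(events))


@dataclass
class HaplotypeCatalog:
    """Deterministic labelling of unique per-gene profiles and their combos.

    Per gene, the empty (wild-type) profile is always present and labelled
    ``wt``; non-wild-type profiles get letters A, B, ... by descending
    frequency with ties broken by the lexicographic event-label list, so the
    labelling is a pure function of the multiset of profiles.  A user label
    map (gene -> profile key -> label) overrides the automatic letters, e.g.
    for concordance with a published lettering.
    """

    genes: tuple[str, ...]
    labels: dict[str, dict[tuple[str, ...], str]]
    profiles: dict[str, dict[str, ChangeProfile]] = field(repr=False)
    sample_labels: dict[str, dict[str, str]]
    combos: dict[str, str]

    @property
    def n_combinations(self) -> int:
        """Number of distinct multigene haplotypes observed."""
        return len(set(self.combos.values()))

    def label_of(self, gene: str, profile: ChangeProfile) -> str:
        return self.labels[gene][profile.key]


def _letter(i: int) -> str:
    # A..Z, then AA, AB, ... (same scheme as spreadsheet columns)
    out = ""
    i += 1
    while i:
        i, r = divmod(i - 1, 26)
        out = chr(ord("A") + r) + out
    return out


def build_catalog(
    sample_profiles: Mapping[str, Mapping[str, ChangeProfile]],
    genes: Sequence[str] | None = None,
    label_map: Mapping[str, Mapping[tuple[str, ...], str]] | None = None,
) -> HaplotypeCatalog:
    """Label unique per-gene profiles and form multigene combination strings.

    Parameters
    ----------
    sample_profiles
        sample id -> gene -> ChangeProfile; every sample must carry a profile
        (possibly wild type) for every gene analysed.
    genes
        Gene order for the combination string; defaults to sorted gene names.
    label_map
        Optional per-gene override mapping profile key (tuple of event
        labels) to a label.
    """
    if genes is None:
        seen: set[str] = set()
        for per_gene in sample_profiles.values():
            seen.update(per_gene)
        genes = tuple(sorted(seen))
    else:
        genes = tuple(genes)

    for sample, per_gene in sample_profiles.items():
        missing = [g for g in genes if g not in per_gene]
        if missing:
            raise ValueError(f"sample {sample!r} lacks profiles for {missing}")

    labels: dict[str, dict[tuple[str, ...], str]] = {}
    profiles: dict[str, dict[str, ChangeProfile]] = {}
    for gene in genes:
        counts: dict[tuple[str, ...], int] = {}
        by_key: dict[tuple[str, ...], ChangeProfile] = {}
        for per_gene in sample_profiles.values():
            prof = per_gene[gene]
            counts[prof.key] = counts.get(prof.key, 0) + 1
            by_key[prof.key] = prof
        by_key.setdefault((), ChangeProfile(gene=gene))  # wt always present
        gene_labels: dict[tuple[str, ...], str] = {(): "wt"}
        variant_keys = sorted(
            (k for k in by_key if k != ()),
            key=lambda k: (-counts.get(k, 0), k),
        )
        for i, key in enumerate(variant_keys):
            gene_labels[key] = _letter(i)
        if label_map and gene in label_map:
            for key, lab in label_map[gene].items():
                gene_labels[tuple(key)] = lab
        labels[gene] = gene_labels
        profiles[gene] = {gene_labels[k]: p for k, p in by_key.items()}

    sample_labels: dict[str, dict[str, str]] = {}
    combos: dict[str, str] = {}
    for sample, per_gene in sample_profiles.items():
        lab = {g: labels[g][per_gene[g].key] for g in genes}
        sample_labels[sample] = lab
        combos[sample] = "|".join(lab[g] for g in genes)
    return HaplotypeCatalog(
        genes=genes,
        labels=labels,
        profiles=profiles,
        sample_labels=sample_labels,
        combos=combos,
    )
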