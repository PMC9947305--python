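"""Table, sequence and config I/O for the tolerance-genetics pipeline.

Two CSV dialects are accepted for microsatellite genotypes:

* two columns per locus, ``L01_a1,L01_a2`` (written on output);
* one column per locus with ``a/b`` cells.

Allele calls are integer fragment lengths stored as unordered (sorted)
pairs; a fully empty cell/pair is missing data.  Phenotype tables carry one
row per bee: colony, dose group, 24-h survival and the fraction of the 20 µL
dose consumed (bees consuming <90% are excluded from analysis; control-group
mortality above 10% per 24 h fails the assay QC).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("beetol")

__all__ = [
    "GenotypeTable",
    "ControlCheck",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "filter_phenotypes",
    "check_control_mortality",
    "read_fasta",
    "write_fasta",
    "load_yaml",
]

AllelePair = tuple[int, int]


@dataclass
class GenotypeTable:
    """Worker × locus genotypes: unordered integer allele pairs or None."""

    data: pd.DataFrame  # index: worker id; columns: 'colony' + loci (object)
    loci: list[str]

    def __post_init__(self) -> None:
        if "colony" not in self.data.columns:
            raise ValueError("genotype table must have a 'colony' column")
        missing = [l for l in self.loci if l not in self.data.columns]
        if missing:
            raise ValueError(f"loci absent from table: {missing}")

    @property
    def workers(self) -> list[str]:
        return list(self.data.index)

    def colony(self, name: str) -> "GenotypeTable":
        sub = self.data[self.data["colony"] == name]
        if sub.empty:
            raise ValueError(f"no workers for colony {name!r}")
        return GenotypeTable(sub, self.loci)

    def genotype(self, worker: str, locus: str) -> AllelePair | None:
        return self.data.at[worker, locus]

    def worker_genotypes(self, worker: str) -> dict[str, AllelePair | None]:
        row = self.data.loc[worker]
        return {l: row[l] for l in self.loci}


def _normalize_pair(a: object, b: object) -> AllelePair | None:
    if pd.isna(a) and pd.isna(b):
        return None
    if pd.isna(a) or pd.isna(b):
        raise ValueError(f"half-missing allele pair ({a!r}, {b!r})")
    ai, bi = int(a), int(b)
    if ai != float(a) or bi != float(b):
        raise ValueError(f"non-integer allele call ({a!r}, {b!r})")
    return (ai, bi) if ai <= bi else (bi, ai)


def _check_rectangular(path: Path) -> None:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise ValueError(f"{path}: empty file")
        width = len(header)
        for i, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != width:
                raise ValueError(
                    f"{path}: ragged row at line {i} "
                    f"({len(row)} fields, header has {width})"
                )


def read_genotypes(path: str | Path) -> GenotypeTable:
    """Read a genotype CSV (either dialect) into a :class:`GenotypeTable`."""
    path = Path(path)
    _check_rectangular(path)
    raw = pd.read_csv(path, dtype=str)
    for col in ("worker_id", "colony"):
        if col not in raw.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    dup = raw["worker_id"][raw["worker_id"].duplicated()].tolist()
    if dup:
        raise ValueError(f"{path}: duplicate worker ids: {sorted(set(dup))}")
    raw = raw.set_index("worker_id")

    pair_cols = [c for c in raw.columns if c.endswith("_a1")]
    cells: dict[str, list[AllelePair | None]] = {}
    if pair_cols:
        loci = [c[:-3] for c in pair_cols]
        for locus in loci:
            c1, c2 = f"{locus}_a1", f"{locus}_a2"
            if c2 not in raw.columns:
                raise ValueError(f"{path}: column {c1} without matching {c2}")
            col = []
            for w, a, b in zip(raw.index, raw[c1], raw[c2]):
                try:
                    col.append(_normalize_pair(a, b))
                except ValueError as exc:
                    raise ValueError(f"{path}: worker {w}, locus {locus}: {exc}")
            cells[locus] = col
    else:
        loci = [c for c in raw.columns if c != "colony"]
        if not loci:
            raise ValueError(f"{path}: no locus columns found")
        for locus in loci:
            col = []
            for w, cell in zip(raw.index, raw[locus]):
                if pd.isna(cell) or str(cell).strip() == "":
                    col.append(None)
                    continue
                parts = str(cell).split("/")
                if len(parts) != 2:
                    raise ValueError(
                        f"{path}: worker {w}, locus {locus}: cell {cell!r} "
                        "is not of the form 'a/b'"
                    )
                try:
                    col.append(_normalize_pair(parts[0], parts[1]))
                except ValueError as exc:
                    raise ValueError(f"{path}: worker {w}, locus {locus}: {exc}")
            cells[locus] = col

    data = pd.DataFrame({"colony": raw["colony"]})
    for locus in loci:
        data[locus] = pd.Series(cells[locus], index=raw.index, dtype=object)
    return GenotypeTable(data, loci)


def write_genotypes(table: GenotypeTable, path: str | Path) -> None:
    """Write the two-column-per-locus dialect (idempotent; missing → empty)."""
    out = pd.DataFrame({"worker_id": table.data.index, "colony": table.data["colony"].values})
    for locus in table.loci:
        pairs = table.data[locus]
        out[f"{locus}_a1"] = [p[0] if p is not None else "" for p in pairs]
        out[f"{locus}_a2"] = [p[1] if p is not None else "" for p in pairs]
    out.to_csv(path, index=False)


_PHENO_COLS = ["worker_id", "colony", "dose_group", "survived", "consumed_fraction"]


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a per-bee phenotype CSV (survived may be empty for unscored bees)."""
    path = Path(path)
    _check_rectangular(path)
    df = pd.read_csv(path, dtype={"worker_id": str, "colony": str, "dose_group": str})
    missing = [c for c in _PHENO_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing phenotype columns {missing}")
    dup = df["worker_id"][df["worker_id"].duplicated()].tolist()
    if dup:
        raise ValueError(f"{path}: duplicate worker ids: {sorted(set(dup))}")

    def _to_bool(v: object) -> object:
        if pd.isna(v):
            return pd.NA
        s = str(v).strip().lower()
        if s in ("true", "1", "1.0"):
            return True
        if s in ("false", "0", "0.0"):
            return False
        raise ValueError(f"{path}: unparseable survived value {v!r}")

    df["survived"] = df["survived"].map(_to_bool).astype("boolean")
    df["consumed_fraction"] = df["consumed_fraction"].astype(float)
    bad = df[(df["consumed_fraction"] < 0) | (df["consumed_fraction"] > 1)]
    if not bad.empty:
        raise ValueError(
            f"{path}: consumed_fraction outside [0,1] for {bad['worker_id'].tolist()}"
        )
    return df


def write_phenotypes(df: pd.DataFrame, path: str | Path) -> None:
    df[_PHENO_COLS].to_csv(path, index=False)


def filter_phenotypes(df: pd.DataFrame, min_consumed: float = 0.90) -> pd.DataFrame:
    """Drop bees that consumed less than ``min_consumed`` of the dose.

    The boundary is kept (the rule is "less than 90%").  The removal count is
    logged; an all-removed result logs a warning.
    """
    if not 0 <= min_consumed <= 1:
        raise ValueError("min_consumed must be in [0, 1]")
    keep = df["consumed_fraction"] >= min_consumed
    removed = int((~keep).sum())
    log.info("consumption filter: removed %d of %d bees", removed, len(df))
    out = df[keep].copy()
    if out.empty and removed:
        log.warning("consumption filter removed every bee")
    return out


class ControlCheck(NamedTuple):
    mortality: float
    passed: bool
    n_control: int


def check_control_mortality(df: pd.DataFrame, max_mortality: float = 0.10) -> ControlCheck:
    """Control-group death proportion and the ≤10%-per-24h pass flag."""
    ctrl = df[df["dose_group"] == "control"]
    if ctrl.empty:
        raise ValueError("no control-group rows in phenotype table")
    scored = ctrl["survived"].dropna()
    if scored.empty:
        raise ValueError("control-group rows have no scored survival")
    mortality = float(1.0 - scored.mean())
    return ControlCheck(mortality, mortality <= max_mortality, len(scored))


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA → {id: sequence}; gaps ('-') are preserved."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: dict[str, str], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    SeqIO.write(seqs, str(path), "fasta")


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        out = yaml.safe_load(fh)
    if not isinstance(out, dict):
        raise ValueError(f"{path}: top-level YAML must be a mapping")
    return out
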