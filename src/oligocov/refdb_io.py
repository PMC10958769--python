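"""Readers and writers for every external format the pipeline touches.

Reference 16S FASTA files (SILVA-, MiDAS-, or plain-style headers), oligo
tables (TSV/CSV), coverage reports, uncovered-sequence exports, and the
packaged probe/primer tables.
"""

from __future__ import annotations

import csv
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from ._alphabet import AlphabetError, normalize, validate

logger = logging.getLogger(__name__)

HEADER_DIALECTS = ("silva", "midas", "plain")


class ReferenceParseError(ValueError):
    """A reference FASTA record violates the declared header dialect."""


class OligoTableError(ValueError):
    """An oligo table row is malformed (bad symbol, duplicate name, ...)."""


class OligoRole(str, Enum):
    FISH_PROBE = "fish_probe"
    PRIMER_FORWARD = "primer_forward"
    PRIMER_REVERSE = "primer_reverse"


@dataclass(frozen=True)
class RefSeq:
    """A normalized reference 16S rRNA gene sequence with its taxonomy path."""

    id: str
    sequence: str
    taxonomy: tuple[str, ...]
    source_db: str = "synthetic"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence after normalization")
        validate(self.sequence, context=f"sequence of {self.id}")
        if not self.taxonomy or any(not r for r in self.taxonomy):
            raise ValueError(f"{self.id}: taxonomy must be a non-empty path "
                             f"with no empty rank labels")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def lowest_rank(self) -> str:
        return self.taxonomy[-1]


@dataclass(frozen=True)
class Oligo:
    """A named 5'->3' IUPAC oligonucleotide (FISH probe or PCR primer)."""

    name: str
    sequence: str
    role: OligoRole = OligoRole.FISH_PROBE
    target_group_label: str = ""
    formamide_pct: float | None = None
    citation: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "role", OligoRole(self.role))
        validate(self.sequence, context=f"oligo {self.name!r}")
        if len(self.sequence) < 10:
            raise ValueError(f"oligo {self.name!r}: length {len(self.sequence)} < 10")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PrimerSet:
    """A forward/reverse primer pair with amplicon length bounds."""

    name: str
    forward: Oligo
    reverse: Oligo
    region_label: str = ""
    amplicon_length_bounds: tuple[int, int] = (50, 2500)

    def __post_init__(self) -> None:
        if self.forward.role is not OligoRole.PRIMER_FORWARD:
            raise ValueError(f"{self.name}: forward oligo must have role primer_forward")
        if self.reverse.role is not OligoRole.PRIMER_REVERSE:
            raise ValueError(f"{self.name}: reverse oligo must have role primer_reverse")
        lo, hi = self.amplicon_length_bounds
        if not (0 < lo <= hi):
            raise ValueError(f"{self.name}: bad amplicon bounds {self.amplicon_length_bounds}")


class ReferenceDB:
    """A queryable collection of :class:`RefSeq` with a rank-label index.

    The taxonomy index maps every rank label appearing anywhere in a
    taxonomy path to the set of sequence ids carrying it, so target groups
    can be defined at any rank (genus labels, MiDAS placeholder names, ...).
    """

    def __init__(self, records: Iterable[RefSeq]):
        self._by_id: dict[str, RefSeq] = {}
        self.taxonomy_index: dict[str, set[str]] = defaultdict(set)
        for rec in records:
            if rec.id in self._by_id:
                raise ReferenceParseError(f"duplicate sequence id {rec.id!r}")
            self._by_id[rec.id] = rec
            for rank in rec.taxonomy:
                self.taxonomy_index[rank].add(rec.id)

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self) -> Iterator[RefSeq]:
        return iter(self._by_id.values())

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._by_id

    def __getitem__(self, seq_id: str) -> RefSeq:
        return self._by_id[seq_id]

    def ids(self) -> list[str]:
        return list(self._by_id)

    def ids_with_rank(self, rank_label: str) -> set[str]:
        return set(self.taxonomy_index.get(rank_label, set()))


def _split_taxonomy(tax: str) -> tuple[str, ...]:
    if ":" in tax and "," in tax:
        # MiDAS "d:Bacteria,p:...,g:...,s:..." style
        parts = [p.split(":", 1)[-1].strip() for p in tax.split(",")]
    else:
        parts = [p.strip() for p in tax.split(";")]
    parts = [p for p in parts if p]
    return tuple(parts)


def _parse_header(header: str, dialect: str) -> tuple[str, tuple[str, ...]]:
    if dialect == "plain":
        if "|" not in header:
            raise ReferenceParseError("plain dialect expects '>id|tax1;tax2;...'")
        seq_id, tax = header.split("|", 1)
    elif dialect in ("silva", "midas"):
        if " " not in header:
            raise ReferenceParseError(
                f"{dialect} dialect expects '>id<space>taxonomy'")
        seq_id, tax = header.split(" ", 1)
    else:
        raise ValueError(f"unknown header dialect {dialect!r}; "
                         f"expected one of {HEADER_DIALECTS}")
    taxonomy = _split_taxonomy(tax)
    if not seq_id or not taxonomy:
        raise ReferenceParseError(f"empty id or taxonomy in header {header!r}")
    return seq_id, taxonomy


def parse_reference_fasta(path: str | Path, header_dialect: str,
                          source_db: str | None = None) -> ReferenceDB:
    """Parse a taxonomy-annotated reference FASTA into a :class:`ReferenceDB`.

    Sequences are normalized (U->T, uppercase, alignment gaps stripped);
    records whose sequence is empty after normalization are dropped with a
    logged count. A malformed header raises :class:`ReferenceParseError`
    naming the record; a duplicate id is a hard error.
    """
    path = Path(path)
    if header_dialect not in HEADER_DIALECTS:
        raise ValueError(f"unknown header dialect {header_dialect!r}; "
                         f"expected one of {HEADER_DIALECTS}")
    tag = source_db or header_dialect
    logger.info("parsing %s with the %r header dialect", path, header_dialect)
    records: list[RefSeq] = []
    n_empty = 0
    for idx, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        header = rec.description
        try:
            seq_id, taxonomy = _parse_header(header, header_dialect)
            seq = normalize(str(rec.seq))
        except (ReferenceParseError, AlphabetError) as exc:
            raise ReferenceParseError(f"{path} record {idx}: {exc}") from exc
        if not seq:
            n_empty += 1
            continue
        records.append(RefSeq(id=seq_id, sequence=seq, taxonomy=taxonomy,
                              source_db=tag))
    if n_empty:
        logger.warning("%s: dropped %d record(s) with empty sequence after "
                       "normalization", path, n_empty)
    try:
        db = ReferenceDB(records)
    except ReferenceParseError as exc:
        raise ReferenceParseError(f"{path}: {exc}") from exc
    logger.info("%s: %d reference sequences loaded", path, len(db))
    return db


def write_reference_fasta(db: ReferenceDB | Iterable[RefSeq], path: str | Path,
                          dialect: str = "plain") -> None:
    """Write references back out; only the plain dialect is emitted."""
    if dialect != "plain":
        raise ValueError("only the plain dialect is supported for writing")
    with open(path, "w") as fh:
        for rec in db:
            fh.write(f">{rec.id}|{';'.join(rec.taxonomy)}\n{rec.sequence}\n")


# ---------------------------------------------------------------------------
# oligo tables

_OLIGO_COLUMNS = ("name", "sequence", "role", "target_group")


def _sniff_sep(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def parse_oligo_table(path: str | Path) -> tuple[list[Oligo], list[PrimerSet]]:
    """Parse a TSV/CSV oligo table into oligos and primer sets.

    Regular rows need columns name, sequence, role, target_group and may
    carry formamide_pct / citation. A row with role ``primer_set`` declares
    a pair by referencing previously defined forward/reverse oligo names in
    the ``forward``/``reverse`` columns, with optional ``min_length``/
    ``max_length`` amplicon bounds.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str,
                     keep_default_na=False, comment="#")
    missing = [c for c in _OLIGO_COLUMNS if c not in df.columns]
    if missing:
        raise OligoTableError(f"{path}: missing column(s) {missing}")
    oligos: dict[str, Oligo] = {}
    primer_sets: list[PrimerSet] = []
    for i, row in df.iterrows():
        name = row["name"].strip()
        rowno = i + 2  # header is line 1
        if not name:
            raise OligoTableError(f"{path} row {rowno}: empty name")
        if name in oligos or name in {p.name for p in primer_sets}:
            raise OligoTableError(f"{path} row {rowno}: duplicate name {name!r}")
        if row["role"].strip() == "primer_set":
            try:
                fwd = oligos[row["forward"].strip()]
                rev = oligos[row["reverse"].strip()]
            except KeyError as exc:
                raise OligoTableError(
                    f"{path} row {rowno}: primer set {name!r} references "
                    f"unknown oligo {exc}") from exc
            lo = int(row.get("min_length", "") or 50)
            hi = int(row.get("max_length", "") or 2500)
            primer_sets.append(PrimerSet(
                name=name, forward=fwd, reverse=rev,
                region_label=row["target_group"].strip(),
                amplicon_length_bounds=(lo, hi)))
            continue
        fa = row.get("formamide_pct", "").strip() if "formamide_pct" in df.columns else ""
        try:
            oligo = Oligo(
                name=name,
                sequence=normalize(row["sequence"].strip()),
                role=row["role"].strip(),
                target_group_label=row["target_group"].strip(),
                formamide_pct=float(fa) if fa else None,
                citation=(row.get("citation", "").strip() or None)
                if "citation" in df.columns else None,
            )
        except (AlphabetError, ValueError) as exc:
            raise OligoTableError(f"{path} row {rowno} ({name!r}): {exc}") from exc
        oligos[name] = oligo
    return list(oligos.values()), primer_sets


def write_oligo_table(oligos: Sequence[Oligo], primer_sets: Sequence[PrimerSet],
                      path: str | Path) -> None:
    """Write oligos/primer sets in the format :func:`parse_oligo_table` reads."""
    path = Path(path)
    sep = _sniff_sep(path)
    cols = ["name", "sequence", "role", "target_group", "formamide_pct",
            "citation", "forward", "reverse", "min_length", "max_length"]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=sep)
        w.writerow(cols)
        for o in oligos:
            w.writerow([o.name, o.sequence, o.role.value, o.target_group_label,
                        "" if o.formamide_pct is None else format(o.formamide_pct, "g"),
                        o.citation or "", "", "", "", ""])
        for p in primer_sets:
            lo, hi = p.amplicon_length_bounds
            w.writerow([p.name, "", "primer_set", p.region_label, "", "",
                        p.forward.name, p.reverse.name, lo, hi])


# ---------------------------------------------------------------------------
# report writing

REPORT_COLUMNS = ("oligo_or_mix", "database_tag", "target_group", "n_target",
                  "n_target_hit", "coverage_pct", "n_nontarget_hit",
                  "nontarget_taxa_breakdown", "uncovered_ids_file")


def write_coverage_report(reports: Iterable, path: str | Path) -> None:
    """Write coverage reports as a deterministic TSV (sorted by oligo, tag)."""
    rows = []
    for r in reports:
        breakdown = ";".join(f"{taxon}:{n}" for taxon, n in
                             sorted(r.nontarget_hits.items()))
        cov = "NA" if r.coverage_pct is None else f"{r.coverage_pct:.1f}"
        rows.append((r.oligo_or_mix_name, r.database_tag, r.group_name,
                     r.n_target, r.n_target_hit, cov,
                     sum(r.nontarget_hits.values()), breakdown,
                     r.uncovered_ids_file or ""))
    rows.sort(key=lambda t: (t[0], t[1]))
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(REPORT_COLUMNS)
        w.writerows(rows)


def write_uncovered(seqs: Iterable[RefSeq], path: str | Path) -> None:
    """Export blind-spot sequences (id, taxonomy, source_db), sorted by id."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(("id", "taxonomy", "source_db"))
        for rec in sorted(seqs, key=lambda r: r.id):
            w.writerow((rec.id, ";".join(rec.taxonomy), rec.source_db))


# ---------------------------------------------------------------------------
# packaged tables (probes, primers, published evaluation counts, copy numbers)

def _data_path(name: str):
    return resources.files("oligocov.data").joinpath(name)


def builtin_probe_table() -> list[Oligo]:
    """The packaged FISH probe table for PAO/GAO taxa."""
    with resources.as_file(_data_path("fish_probes.tsv")) as p:
        oligos, _ = parse_oligo_table(p)
    return oligos


def builtin_primer_sets() -> list[PrimerSet]:
    """The packaged universal 16S primer sets (V1-V3 ... V5-V7)."""
    with resources.as_file(_data_path("primer_sets.tsv")) as p:
        _, sets = parse_oligo_table(p)
    return sets


def builtin_probe_mixes() -> dict[str, dict]:
    """Named probe mixes evaluated jointly (e.g. PAOmix)."""
    return {
        "PAOmix": {"probes": ["PAO462", "PAO651", "PAO846"],
                   "group": "Ca_Accumulibacter"},
        "GAOmix": {"probes": ["GAO431", "GAO989"],
                   "group": "Ca_Competibacter"},
    }


def published_probe_counts() -> pd.DataFrame:
    """Published per-probe evaluation counts (group sizes and targeted hits).

    Columns: kind (probe/mix), oligo_or_mix, database, group, n_target,
    n_hit, printed_coverage_pct, consistent, note. Rows flagged
    ``consistent=False`` are cases where the published coverage figure does
    not equal hits/group-size at one-decimal half-up rounding; this package
    always follows the hits/group-size definition.
    """
    with resources.as_file(_data_path("published_probe_counts.tsv")) as p:
        df = pd.read_csv(p, sep="\t", keep_default_na=False)
    df["consistent"] = df["consistent"].astype(bool)
    return df


def builtin_copy_numbers() -> dict[str, float]:
    """16S rRNA gene copy numbers per PAO/GAO genus (from genomes/MAGs)."""
    with resources.as_file(_data_path("copy_numbers.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    return dict(zip(df["taxon"], df["copies"].astype(float)))
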