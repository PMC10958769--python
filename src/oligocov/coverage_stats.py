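"""Coverage, specificity, and blind-spot statistics for probes and primers.

Coverage of a target group is the fraction of its reference sequences an
oligo (or a mix, by set union) binds at the configured stringency, reported
at one decimal with half-up rounding. Non-target (out-group) hits are
aggregated by each hit sequence's lowest-rank taxon label. Sequences bound
by no probe are the blind spots the evaluation exists to expose.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from typing import Iterable, Mapping, Sequence

from .oligo_engine import (DEFAULT_POLICY, PrimerSet, ScanPolicy, is_amplifiable,
                           probe_binds)
from .refdb_io import Oligo, RefSeq, ReferenceDB

logger = logging.getLogger(__name__)

MAX_VENN_OLIGOS = 6


@dataclass(frozen=True)
class TargetGroup:
    """The definition of "in-group" for a coverage computation."""

    name: str
    member_ids: frozenset[str]
    taxonomy_predicate: str | None = None

    def __len__(self) -> int:
        return len(self.member_ids)


@dataclass(frozen=True)
class CoverageReport:
    """Per-oligo (or per-mix) coverage and specificity on one database."""

    oligo_or_mix_name: str
    database_tag: str
    group_name: str
    n_target: int
    n_target_hit: int
    coverage_pct: float | None
    nontarget_hits: Mapping[str, int] = field(default_factory=dict)
    uncovered_ids: frozenset[str] = frozenset()
    uncovered_ids_file: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.n_target_hit <= self.n_target):
            raise ValueError("0 <= n_target_hit <= n_target violated")
        if len(self.uncovered_ids) != self.n_target - self.n_target_hit:
            raise ValueError("|uncovered_ids| must equal n_target - n_target_hit")


@dataclass(frozen=True)
class VennPartition:
    """Exact partition of a target group by probe binding signature.

    ``region_counts`` maps each subset of oligo names (as a frozenset,
    including the empty set = bound by none) to the number of target
    sequences bound by exactly that subset.
    """

    oligo_names: tuple[str, ...]
    region_counts: Mapping[frozenset[str], int]

    def count(self, *names: str) -> int:
        return self.region_counts.get(frozenset(names), 0)

    def marginal(self, name: str) -> int:
        """Total targets bound by ``name`` (the oligo's n_target_hit)."""
        return sum(n for sig, n in self.region_counts.items() if name in sig)


def coverage_percent(n_hit: int, n_total: int) -> float | None:
    """100 * n_hit / n_total at one decimal, half-up; None when undefined."""
    if n_total == 0:
        return None
    if not (0 <= n_hit <= n_total):
        raise ValueError("need 0 <= n_hit <= n_total")
    pct = Decimal(100 * n_hit) / Decimal(n_total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def build_target_group(db: ReferenceDB, predicate_or_ids: str | Iterable[str],
                       name: str | None = None) -> TargetGroup:
    """Resolve a target group from a rank label or an explicit id list.

    A string is a taxonomy predicate matched against any rank in each
    sequence's path; an iterable is an explicit refined-membership list
    (every id must exist in the database). An empty group is allowed here
    (logged); computing coverage on it yields the undefined outcome.
    """
    if isinstance(predicate_or_ids, str):
        ids = db.ids_with_rank(predicate_or_ids)
        group = TargetGroup(name=name or predicate_or_ids,
                            member_ids=frozenset(ids),
                            taxonomy_predicate=predicate_or_ids)
    else:
        ids = set(predicate_or_ids)
        missing = [i for i in ids if i not in db]
        if missing:
            raise KeyError(f"explicit ids not in database: {sorted(missing)[:5]}")
        group = TargetGroup(name=name or "explicit", member_ids=frozenset(ids))
    if not group.member_ids:
        logger.warning("target group %r resolved to zero sequences", group.name)
    else:
        logger.info("target group %r: %d sequences", group.name, len(group))
    return group


def _binder_ids(oligos: Sequence[Oligo], db: ReferenceDB,
                policy: ScanPolicy) -> set[str]:
    return {rec.id for rec in db
            if any(probe_binds(o, rec, policy) for o in oligos)}


def _assemble_report(name: str, hit_ids: set[str], db: ReferenceDB,
                     group: TargetGroup, database_tag: str) -> CoverageReport:
    in_hits = hit_ids & group.member_ids
    out_hits = hit_ids - group.member_ids
    nontarget: dict[str, int] = {}
    for sid in out_hits:
        label = db[sid].lowest_rank
        nontarget[label] = nontarget.get(label, 0) + 1
    return CoverageReport(
        oligo_or_mix_name=name,
        database_tag=database_tag,
        group_name=group.name,
        n_target=len(group),
        n_target_hit=len(in_hits),
        coverage_pct=coverage_percent(len(in_hits), len(group)),
        nontarget_hits=nontarget,
        uncovered_ids=frozenset(group.member_ids - in_hits),
    )


def evaluate_oligo_coverage(oligo: Oligo, db: ReferenceDB, group: TargetGroup,
                            policy: ScanPolicy = DEFAULT_POLICY,
                            database_tag: str = "") -> CoverageReport:
    """Coverage/specificity of a single oligo over one database.

    Every sequence in the database is scanned once; a sequence with several
    binding sites still counts once. An empty group yields an undefined
    (None) coverage, never 0.0.
    """
    hit_ids = _binder_ids([oligo], db, policy)
    tag = database_tag or next(iter(db)).source_db if len(db) else database_tag
    return _assemble_report(oligo.name, hit_ids, db, group, tag)


def evaluate_mix_coverage(oligos: Sequence[Oligo], db: ReferenceDB,
                          group: TargetGroup,
                          policy: ScanPolicy = DEFAULT_POLICY,
                          mix_name: str | None = None,
                          database_tag: str = "") -> CoverageReport:
    """Union coverage of a probe mix: a sequence is hit if any member binds."""
    if not oligos:
        raise ValueError("mix must contain at least one oligo")
    name = mix_name or "+".join(o.name for o in oligos)
    hit_ids = _binder_ids(oligos, db, policy)
    tag = database_tag or next(iter(db)).source_db if len(db) else database_tag
    return _assemble_report(name, hit_ids, db, group, tag)


def co_coverage_partition(oligos: Sequence[Oligo], db: ReferenceDB,
                          group: TargetGroup,
                          policy: ScanPolicy = DEFAULT_POLICY) -> VennPartition:
    """Partition the target group by exact binding signature (Venn regions)."""
    if not 1 <= len(oligos) <= MAX_VENN_OLIGOS:
        raise ValueError(
            f"co-coverage partition supports 1-{MAX_VENN_OLIGOS} oligos "
            f"(2^n regions); use pairwise_co_coverage for larger sets")
    names = tuple(o.name for o in oligos)
    counts: dict[frozenset[str], int] = {}
    for k in range(len(names) + 1):
        for sig in combinations(names, k):
            counts[frozenset(sig)] = 0
    for sid in group.member_ids:
        rec = db[sid]
        sig = frozenset(o.name for o in oligos if probe_binds(o, rec, policy))
        counts[sig] += 1
    return VennPartition(oligo_names=names, region_counts=counts)


def pairwise_co_coverage(oligos: Sequence[Oligo], db: ReferenceDB,
                         group: TargetGroup,
                         policy: ScanPolicy = DEFAULT_POLICY) -> dict[tuple[str, str], int]:
    """Counts of target sequences co-bound by each oligo pair (incl. self)."""
    binders = {o.name: {sid for sid in group.member_ids
                        if probe_binds(o, db[sid], policy)} for o in oligos}
    names = sorted(binders)
    return {(a, b): len(binders[a] & binders[b])
            for a in names for b in names if a <= b}


def extract_uncovered(oligos: Sequence[Oligo], db: ReferenceDB,
                      group: TargetGroup,
                      policy: ScanPolicy = DEFAULT_POLICY) -> list[RefSeq]:
    """Target sequences bound by no oligo in the set (the blind spots).

    An empty oligo set vacuously returns the whole group. Results are
    sorted by id for deterministic export.
    """
    if oligos:
        hit = _binder_ids(list(oligos), db, policy)
    else:
        hit = set()
    return sorted((db[sid] for sid in group.member_ids - hit),
                  key=lambda r: r.id)


def evaluate_primer_coverage(pair: PrimerSet, db: ReferenceDB,
                             group: TargetGroup,
                             policy: ScanPolicy = DEFAULT_POLICY,
                             database_tag: str = "",
                             evaluable_ids: set[str] | None = None) -> CoverageReport:
    """Amplifiable-sequence coverage of a primer pair over a target group.

    ``evaluable_ids``, when given, restricts the denominator (and the hit
    set) to sequences that passed a 5'-end evaluability rule.
    """
    members = group.member_ids if evaluable_ids is None \
        else group.member_ids & evaluable_ids
    eff_group = TargetGroup(name=group.name, member_ids=frozenset(members),
                            taxonomy_predicate=group.taxonomy_predicate)
    hit_ids = set()
    for rec in db:
        if evaluable_ids is not None and rec.id not in evaluable_ids:
            continue
        if is_amplifiable(pair, rec, policy):
            hit_ids.add(rec.id)
    tag = database_tag or next(iter(db)).source_db if len(db) else database_tag
    return _assemble_report(pair.name, hit_ids, db, eff_group, tag)


def copy_number_correct(abundances: Mapping[str, float],
                        copy_numbers: Mapping[str, float]) -> dict[str, float]:
    """Correct relative abundances for 16S rRNA gene copy number.

    Amplicon read fractions over-represent taxa carrying many 16S copies;
    dividing by the per-taxon copy number and renormalizing recovers
    cell-proportional abundances: corrected_i = (a_i/c_i) / sum_j (a_j/c_j).
    A taxon without a known copy number is a hard error, never silently
    defaulted.
    """
    total = sum(abundances.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"abundances must sum to 1 (got {total!r})")
    missing = [t for t in abundances if t not in copy_numbers]
    if missing:
        raise KeyError(f"no 16S copy number for taxa: {missing}")
    bad = [t for t in abundances if copy_numbers[t] < 1]
    if bad:
        raise ValueError(f"copy numbers must be >= 1: {bad}")
    weighted = {t: a / copy_numbers[t] for t, a in abundances.items()}
    z = sum(weighted.values())
    return {t: w / z for t, w in weighted.items()}
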