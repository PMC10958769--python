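"""Mock taxonomically labelled 16S reference databases with planted truth.

The generator emits a reference database in which every downstream
statistic has a machine-checkable expected value: probe-binding sites are
planted as the reverse complement of the probe (degenerate positions
resolved at random, so subject-side ambiguity is exercised), primer pairs
are planted as a forward site plus a sense-strand reverse-complement site
at an in-bounds distance, clades are simulated by mutating a shared
ancestor, and optional subject-N positions and 5'-truncated records mimic
real database artifacts. Background sequence is rejection-resampled until
no unplanted oligo site exists at the configured stringency, so the truth
object is exact, not probabilistic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from ._alphabet import EXPANSIONS
from .oligo_engine import (DEFAULT_POLICY, Oligo, PrimerSet, ScanPolicy,
                           is_amplifiable, probe_binds, reverse_complement)
from .refdb_io import RefSeq, ReferenceDB

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


class GeneratorError(RuntimeError):
    """The generator configuration is impossible or resampling failed."""


@dataclass(frozen=True)
class TaxonSpec:
    """One simulated taxon: a clade of related sequences."""

    name: str
    n_sequences: int
    lineage: tuple[str, ...] = ("Bacteria",)


@dataclass(frozen=True)
class ProbePlant:
    """Plant a probe's binding site with a per-taxon probability."""

    oligo: Oligo
    probabilities: Mapping[str, float]  # taxon name -> planting probability


@dataclass(frozen=True)
class PrimerPlant:
    """Plant a primer pair's amplicon with a per-taxon probability."""

    primer_set: PrimerSet
    probabilities: Mapping[str, float]
    forward_position: tuple[int, int] = (0, 30)  # start range for the fwd site


@dataclass(frozen=True)
class SyntheticConfig:
    taxa: tuple[TaxonSpec, ...]
    length_range: tuple[int, int] = (1200, 1500)
    inter_divergence: tuple[float, float] = (0.05, 0.15)
    intra_divergence: float = 0.013  # within the 98.7% species boundary
    probe_plants: tuple[ProbePlant, ...] = ()
    primer_plants: tuple[PrimerPlant, ...] = ()
    subject_n_fraction: float = 0.0
    truncation_fraction: float = 0.0
    truncation_length: tuple[int, int] = (100, 300)
    probe_zone_start: int = 350  # probe sites planted at/after this offset
    policy: ScanPolicy = DEFAULT_POLICY
    source_db: str = "synthetic"
    max_resample: int = 100


@dataclass
class SyntheticTruth:
    """Ground truth for every planted feature of a synthetic database."""

    planted_binders: dict[str, set[str]]       # oligo name -> seq ids
    planted_amplifiable: dict[str, set[str]]   # primer-set name -> seq ids
    clade_membership: dict[str, str]           # seq id -> taxon name
    truncated_ids: set[str]
    rng_seed: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_binders": {k: sorted(v) for k, v in
                                sorted(self.planted_binders.items())},
            "planted_amplifiable": {k: sorted(v) for k, v in
                                    sorted(self.planted_amplifiable.items())},
            "clade_membership": dict(sorted(self.clade_membership.items())),
            "truncated_ids": sorted(self.truncated_ids),
            "rng_seed": self.rng_seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            planted_binders={k: set(v) for k, v in d["planted_binders"].items()},
            planted_amplifiable={k: set(v) for k, v in
                                 d["planted_amplifiable"].items()},
            clade_membership=d["clade_membership"],
            truncated_ids=set(d["truncated_ids"]),
            rng_seed=d["rng_seed"],
        )


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _mutate(seq: str, divergence: float, rng: np.random.Generator) -> str:
    """Substitute exactly round(divergence * len) positions (no indels)."""
    k = round(divergence * len(seq))
    if k == 0:
        return seq
    chars = list(seq)
    positions = rng.choice(len(seq), size=k, replace=False)
    for pos in positions:
        alternatives = [b for b in "ACGT" if b != chars[pos]]
        chars[pos] = alternatives[rng.integers(0, len(alternatives))]
    return "".join(chars)


def mutate_from_reference(ref: RefSeq, divergence: float, seed: int,
                          indel_rate: float = 0.0,
                          new_id: str | None = None) -> RefSeq:
    """A mutated copy of a reference at an exact substitution divergence."""
    if not 0 <= divergence < 1:
        raise ValueError("divergence must be in [0, 1)")
    rng = np.random.default_rng(seed)
    seq = _mutate(ref.sequence, divergence, rng)
    if indel_rate > 0:
        chars = list(seq)
        n_indel = round(indel_rate * len(chars))
        for _ in range(n_indel):
            pos = int(rng.integers(0, len(chars)))
            if rng.random() < 0.5 and len(chars) > 1:
                del chars[pos]
            else:
                chars.insert(pos, str(_BASES[rng.integers(0, 4)]))
        seq = "".join(chars)
    return RefSeq(id=new_id or f"{ref.id}_mut", sequence=seq,
                  taxonomy=ref.taxonomy, source_db=ref.source_db)


def _resolve_degenerate(pattern: str, rng: np.random.Generator) -> str:
    """Replace each IUPAC symbol with one concrete base from its expansion."""
    out = []
    for sym in pattern:
        opts = sorted(EXPANSIONS[sym])
        out.append(opts[rng.integers(0, len(opts))])
    return "".join(out)


def _find_slot(rng: np.random.Generator, site_len: int, lo: int, hi: int,
               occupied: list[tuple[int, int]], tries: int = 200) -> int:
    if hi < lo:
        raise GeneratorError(f"no room for a {site_len} nt site in [{lo}, {hi}]")
    for _ in range(tries):
        start = int(rng.integers(lo, hi + 1))
        if all(start + site_len <= s or start >= e for s, e in occupied):
            return start
    raise GeneratorError("could not place a site without overlap")


def _validate_config(cfg: SyntheticConfig) -> None:
    lmin, _ = cfg.length_range
    if lmin <= 0 or cfg.length_range[1] < lmin:
        raise GeneratorError(f"bad length range {cfg.length_range}")
    for p in (cfg.subject_n_fraction, cfg.truncation_fraction):
        if not 0 <= p <= 1:
            raise GeneratorError("fractions must be in [0, 1]")
    for plant in cfg.probe_plants:
        if cfg.probe_zone_start + len(plant.oligo) > lmin:
            raise GeneratorError(
                f"probe {plant.oligo.name} cannot fit after offset "
                f"{cfg.probe_zone_start} in a {lmin} nt sequence")
        if any(not 0 <= p <= 1 for p in plant.probabilities.values()):
            raise GeneratorError("planting probabilities must be in [0, 1]")
    if cfg.truncation_fraction > 0 and cfg.probe_plants:
        if cfg.probe_zone_start < cfg.truncation_length[1]:
            raise GeneratorError(
                "probe_zone_start must be >= the maximum truncation length "
                "so planted probe sites survive 5'-truncation")
    if cfg.truncation_fraction > 0 and cfg.truncation_length[1] >= lmin:
        raise GeneratorError("truncation_length must stay below the minimum "
                             "sequence length")
    for plant in cfg.primer_plants:
        ps = plant.primer_set
        flen, rlen = len(ps.forward), len(ps.reverse)
        lo = max(ps.amplicon_length_bounds[0], flen + rlen)
        hi = min(ps.amplicon_length_bounds[1],
                 lmin - plant.forward_position[1])
        if lo > hi:
            raise GeneratorError(
                f"primer set {ps.name}: no feasible amplicon length")
        if cfg.truncation_fraction > 0 and \
                plant.forward_position[1] + flen > cfg.truncation_length[0]:
            raise GeneratorError(
                f"primer set {ps.name}: forward sites must lie inside the "
                f"truncated prefix (before {cfg.truncation_length[0]} nt) so "
                f"5'-truncation reliably removes them")


def _build_sequence(cfg: SyntheticConfig, rng: np.random.Generator,
                    ancestor: str, length: int,
                    planted_probes: list[ProbePlant],
                    planted_primers: list[PrimerPlant],
                    taxonomy: tuple[str, ...], seq_id: str) -> RefSeq:
    """One sequence with its planted sites; resampled until truth is exact."""
    all_probes = [p.oligo for p in cfg.probe_plants]
    all_pairs = [p.primer_set for p in cfg.primer_plants]
    planted_probe_names = {p.oligo.name for p in planted_probes}
    planted_pair_names = {p.primer_set.name for p in planted_primers}
    last_err: str = ""
    for _attempt in range(cfg.max_resample):
        intra = rng.uniform(0, cfg.intra_divergence)
        chars = list(_mutate(ancestor[:length], intra, rng))
        occupied: list[tuple[int, int]] = []
        try:
            for plant in planted_primers:
                ps = plant.primer_set
                fsite = _resolve_degenerate(ps.forward.sequence, rng)
                rsite = _resolve_degenerate(
                    reverse_complement(ps.reverse.sequence), rng)
                f_lo, f_hi = plant.forward_position
                fstart = _find_slot(rng, len(fsite), f_lo,
                                    min(f_hi, length - len(fsite)), occupied)
                amp_lo = max(ps.amplicon_length_bounds[0],
                             len(fsite) + len(rsite))
                amp_hi = min(ps.amplicon_length_bounds[1], length - fstart)
                if amp_lo > amp_hi:
                    raise GeneratorError("no feasible amplicon length")
                amp = int(rng.integers(amp_lo, amp_hi + 1))
                rstart = fstart + amp - len(rsite)
                if any(rstart + len(rsite) > s and rstart < e
                       for s, e in occupied):
                    raise GeneratorError("reverse site collision")
                chars[fstart:fstart + len(fsite)] = fsite
                chars[rstart:rstart + len(rsite)] = rsite
                occupied += [(fstart, fstart + len(fsite)),
                             (rstart, rstart + len(rsite))]
            for plant in planted_probes:
                site = _resolve_degenerate(
                    reverse_complement(plant.oligo.sequence), rng)
                start = _find_slot(rng, len(site), cfg.probe_zone_start,
                                   length - len(site), occupied)
                chars[start:start + len(site)] = site
                occupied.append((start, start + len(site)))
        except GeneratorError as exc:
            last_err = str(exc)
            continue
        if cfg.subject_n_fraction > 0:
            free = [i for i in range(length)
                    if all(not (s <= i < e) for s, e in occupied)]
            k = round(cfg.subject_n_fraction * length)
            if k > len(free):
                raise GeneratorError("subject_n_fraction leaves no free positions")
            for i in rng.choice(len(free), size=k, replace=False):
                chars[free[i]] = "N"
        rec = RefSeq(id=seq_id, sequence="".join(chars), taxonomy=taxonomy,
                     source_db=cfg.source_db)
        # exact-truth self-check: no unplanted accidental site may exist
        ok = all(probe_binds(o, rec, cfg.policy) == (o.name in planted_probe_names)
                 for o in all_probes)
        ok = ok and all(
            is_amplifiable(ps, rec, cfg.policy) == (ps.name in planted_pair_names)
            for ps in all_pairs)
        if ok:
            return rec
        last_err = "accidental oligo site in background"
    raise GeneratorError(
        f"{seq_id}: resampling budget exhausted ({cfg.max_resample}); "
        f"last failure: {last_err}")


def generate_synthetic_db(cfg: SyntheticConfig,
                          seed: int) -> tuple[ReferenceDB, SyntheticTruth]:
    """Generate a labelled reference database and its exact ground truth.

    Deterministic: the same config and seed reproduce the database
    byte-for-byte. After assembly the full database is re-scanned and the
    truth object is verified against the scan (generator self-check).
    """
    _validate_config(cfg)
    rng = np.random.default_rng(seed)
    lmin, lmax = cfg.length_range
    root = _random_seq(rng, lmax)
    ancestors = {t.name: _mutate(root, rng.uniform(*cfg.inter_divergence), rng)
                 for t in cfg.taxa}

    # plan: per-sequence plant decisions and the truncated subset
    plan: list[tuple[TaxonSpec, str]] = [
        (taxon, f"{taxon.name}_{k:04d}")
        for taxon in cfg.taxa for k in range(taxon.n_sequences)]
    n_trunc = round(cfg.truncation_fraction * len(plan))
    trunc_idx = set(rng.choice(len(plan), size=n_trunc, replace=False).tolist()) \
        if n_trunc else set()

    records: list[RefSeq] = []
    truth = SyntheticTruth(
        planted_binders={p.oligo.name: set() for p in cfg.probe_plants},
        planted_amplifiable={p.primer_set.name: set() for p in cfg.primer_plants},
        clade_membership={},
        truncated_ids=set(),
        rng_seed=seed,
    )
    for idx, (taxon, seq_id) in enumerate(plan):
        planted_probes = [p for p in cfg.probe_plants
                          if rng.random() < p.probabilities.get(taxon.name, 0.0)]
        planted_primers = [p for p in cfg.primer_plants
                           if rng.random() < p.probabilities.get(taxon.name, 0.0)]
        length = int(rng.integers(lmin, lmax + 1))
        rec = _build_sequence(cfg, rng, ancestors[taxon.name], length,
                              planted_probes, planted_primers,
                              taxon.lineage + (taxon.name,), seq_id)
        truncated = idx in trunc_idx
        if truncated:
            tlen = int(rng.integers(*cfg.truncation_length))
            rec = replace(rec, sequence=rec.sequence[tlen:])
            truth.truncated_ids.add(seq_id)
        records.append(rec)
        truth.clade_membership[seq_id] = taxon.name
        for p in planted_probes:
            truth.planted_binders[p.oligo.name].add(seq_id)
        for p in planted_primers:
            if not truncated:  # truncation removes the 5' forward site
                truth.planted_amplifiable[p.primer_set.name].add(seq_id)

    db = ReferenceDB(records)
    _verify_truth(cfg, db, truth)
    logger.info("synthetic db: %d sequences, %d taxa, %d truncated (seed %d)",
                len(db), len(cfg.taxa), len(truth.truncated_ids), seed)
    return db, truth


def _verify_truth(cfg: SyntheticConfig, db: ReferenceDB,
                  truth: SyntheticTruth) -> None:
    """Exhaustive re-scan of the emitted database against the truth object."""
    for plant in cfg.probe_plants:
        scanned = {r.id for r in db if probe_binds(plant.oligo, r, cfg.policy)}
        if scanned != truth.planted_binders[plant.oligo.name]:
            raise GeneratorError(
                f"self-check failed for probe {plant.oligo.name}: "
                f"scan and truth disagree")
    for plant in cfg.primer_plants:
        scanned = {r.id for r in db
                   if is_amplifiable(plant.primer_set, r, cfg.policy)}
        if scanned != truth.planted_amplifiable[plant.primer_set.name]:
            raise GeneratorError(
                f"self-check failed for primer set {plant.primer_set.name}: "
                f"scan and truth disagree")
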