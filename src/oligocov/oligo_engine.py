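"""Degenerate-oligo scanning against reference sequences.

The matcher is exact and exhaustive: every window of the subject is scored
under IUPAC set semantics. A subject symbol matches an oligo symbol iff its
expansion set is a subset of the oligo symbol's expansion set (so an oligo
``Y`` accepts a subject ``C`` or ``T``, but a subject ``Y`` does not match
an oligo ``C``). A subject ``N`` never matches; it is tallied against a
separate N allowance, mirroring the "0 N's" control of probe-matching web
tools. This replaces BLASTn-short at 0 mismatches for full-length ungapped
hits; gapped or partial alignments are deliberately out of scope.

FISH probes hybridize to the rRNA itself, so by default the reverse
complement of a probe is scanned against the deposited gene-sense sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._alphabet import MASKS, N_MASK, encode, validate
from ._alphabet import reverse_complement as _rc
from .refdb_io import Oligo, OligoRole, PrimerSet, RefSeq

logger = logging.getLogger(__name__)

PROBE_ORIENTATIONS = ("revcomp_of_probe", "as_is", "both")

# how far into the subject the start of a 5'-end primer site may fall for a
# sequence to count as evaluable for 27F-anchored primer sets
FIVE_PRIME_WINDOW = 25
# extra mismatches allowed when only detecting the primer *region* (not a
# strict match) for the evaluability decision
FIVE_PRIME_RELAXATION = 2


def reverse_complement(seq: str) -> str:
    """Reverse complement of an IUPAC string (full ambiguity-code table)."""
    return _rc(seq)


@dataclass(frozen=True)
class ScanPolicy:
    """Matching stringency: mismatch budget, subject-N allowance, orientation."""

    max_mismatches: int = 0
    max_subject_n: int = 0
    probe_orientation: str = "revcomp_of_probe"

    def __post_init__(self) -> None:
        if self.max_mismatches < 0 or self.max_subject_n < 0:
            raise ValueError("mismatch budget and N allowance must be >= 0")
        if self.probe_orientation not in PROBE_ORIENTATIONS:
            raise ValueError(f"probe_orientation must be one of {PROBE_ORIENTATIONS}")


DEFAULT_POLICY = ScanPolicy()


@dataclass(frozen=True)
class MatchHit:
    """A window where an oligo pattern matched, 0-based half-open coords."""

    seq_id: str
    oligo_name: str
    start: int
    length: int
    mismatches: int
    n_positions: int
    strand_searched: str = "sense"

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass(frozen=True)
class AmpliconHit:
    """A forward/reverse primer-site pair predicting an amplicon."""

    seq_id: str
    fwd: MatchHit
    rev: MatchHit

    @property
    def interval(self) -> tuple[int, int]:
        return (self.fwd.start, self.rev.end)

    @property
    def length(self) -> int:
        return self.rev.end - self.fwd.start


def mismatches_at(oligo_seq: str, subject_seq: str, start: int) -> tuple[int, int]:
    """Count (mismatches, subject-N positions) for one alignment window.

    Pure positional comparison under the subset rule; the window
    ``subject_seq[start:start+len(oligo_seq)]`` must fit in the subject.
    """
    m = len(oligo_seq)
    if start < 0 or start + m > len(subject_seq):
        raise ValueError("window does not fit inside the subject")
    mm = nn = 0
    for osym, ssym in zip(oligo_seq, subject_seq[start:start + m]):
        smask = MASKS[ssym]
        if smask == N_MASK:
            nn += 1
        elif smask & ~MASKS[osym]:
            mm += 1
    return mm, nn


def _window_counts(pattern: str, subject_codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-window (mismatch, subject-N) counts for all starts."""
    m = len(pattern)
    n_win = len(subject_codes) - m + 1
    mm = np.zeros(n_win, dtype=np.int32)
    nn = np.zeros(n_win, dtype=np.int32)
    is_n = subject_codes == N_MASK
    for j, sym in enumerate(pattern):
        window = subject_codes[j:j + n_win]
        omask = MASKS[sym]
        mm += ((window & (0xF & ~omask)) != 0) & ~is_n[j:j + n_win]
        nn += is_n[j:j + n_win]
    return mm, nn


def scan_pattern(pattern: str, subject: RefSeq, policy: ScanPolicy = DEFAULT_POLICY,
                 oligo_name: str = "") -> list[MatchHit]:
    """All windows where ``pattern`` matches within the policy budgets."""
    validate(pattern, context="pattern")
    m = len(pattern)
    if m > len(subject.sequence):
        return []
    mm, nn = _window_counts(pattern, encode(subject.sequence))
    ok = np.flatnonzero((mm <= policy.max_mismatches) & (nn <= policy.max_subject_n))
    return [MatchHit(seq_id=subject.id, oligo_name=oligo_name or pattern,
                     start=int(s), length=m, mismatches=int(mm[s]),
                     n_positions=int(nn[s]))
            for s in ok]


def _probe_patterns(oligo: Oligo, policy: ScanPolicy) -> list[str]:
    if oligo.role is not OligoRole.FISH_PROBE:
        return [oligo.sequence]
    if policy.probe_orientation == "revcomp_of_probe":
        return [reverse_complement(oligo.sequence)]
    if policy.probe_orientation == "as_is":
        return [oligo.sequence]
    return [reverse_complement(oligo.sequence), oligo.sequence]


def scan_oligo(oligo: Oligo, subject: RefSeq,
               policy: ScanPolicy = DEFAULT_POLICY) -> list[MatchHit]:
    """Scan an oligo against one reference sequence.

    FISH probes are oriented per ``policy.probe_orientation`` (default:
    reverse complement against the deposited sense-strand gene); primers
    are scanned as written. Hits are returned in ascending start order; an
    oligo longer than the subject yields an empty list.
    """
    if len(oligo.sequence) > len(subject.sequence):
        return []
    best: dict[int, MatchHit] = {}
    for pattern in _probe_patterns(oligo, policy):
        for hit in scan_pattern(pattern, subject, policy, oligo_name=oligo.name):
            prev = best.get(hit.start)
            if prev is None or hit.mismatches < prev.mismatches:
                best[hit.start] = hit
    return [best[s] for s in sorted(best)]


def probe_binds(oligo: Oligo, subject: RefSeq,
                policy: ScanPolicy = DEFAULT_POLICY) -> bool:
    """True iff the oligo has at least one in-budget site on the subject."""
    return bool(scan_oligo(oligo, subject, policy))


def simulate_pcr(pair: PrimerSet, subject: RefSeq,
                 policy: ScanPolicy = DEFAULT_POLICY) -> list[AmpliconHit]:
    """In-silico PCR: enumerate amplicons a primer pair would produce.

    The forward primer must match the sense strand; the reverse primer
    anneals to the sense strand where its reverse complement matches,
    downstream of and not overlapping the forward site, with the spanned
    interval inside the pair's amplicon length bounds.
    """
    fwd_hits = scan_pattern(pair.forward.sequence, subject, policy,
                            oligo_name=pair.forward.name)
    if not fwd_hits:
        return []
    rev_hits = scan_pattern(reverse_complement(pair.reverse.sequence), subject,
                            policy, oligo_name=pair.reverse.name)
    lo, hi = pair.amplicon_length_bounds
    out = []
    for f in fwd_hits:
        for r in rev_hits:
            if f.end <= r.start and lo <= r.end - f.start <= hi:
                out.append(AmpliconHit(seq_id=subject.id, fwd=f, rev=r))
    return out


def is_amplifiable(pair: PrimerSet, subject: RefSeq,
                   policy: ScanPolicy = DEFAULT_POLICY) -> bool:
    return bool(simulate_pcr(pair, subject, policy))


def is_27f_evaluable(subject: RefSeq, fwd_27f: Oligo,
                     policy: ScanPolicy = DEFAULT_POLICY,
                     window: int = FIVE_PRIME_WINDOW,
                     relaxation: int = FIVE_PRIME_RELAXATION) -> bool:
    """Whether a sequence retains its 5' (27F) end and can be evaluated.

    Many deposited 16S sequences are 5'-truncated (or primer-clipped) and
    cannot legitimately count against a 27F-anchored primer set. A sequence
    is evaluable iff a relaxed match to the 27F pattern (mismatch budget
    raised by ``relaxation``, which detects the primer region even where a
    strict scan would fail) starts within the first ``window`` nt.
    Non-evaluable sequences are removed from the coverage denominator.
    """
    relaxed = ScanPolicy(max_mismatches=policy.max_mismatches + relaxation,
                         max_subject_n=policy.max_subject_n,
                         probe_orientation=policy.probe_orientation)
    hits = scan_pattern(fwd_27f.sequence, subject, relaxed,
                        oligo_name=fwd_27f.name)
    return any(h.start < window for h in hits)
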