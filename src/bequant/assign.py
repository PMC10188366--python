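"""Read assignment and genotyping.

The processing chain mirrors the library analysis it re-implements:

1. discard read pairs with any base below Q28 inside the scored regions
   (target-site window on the forward read, spacer on the reverse read);
2. nominate candidate members by locality-sensitive hashing over
   non-overlapping (tiled) 6-mers across the target-site window;
3. drop candidates whose spacer does not exactly match the sequenced spacer;
4. genotype the read against the best candidate by global Needleman-Wunsch
   alignment (match +1, mismatch -1, gap open -5, gap extend 0, free start
   gaps) and record A->G, C->T, C->G and C->A substitutions at protospacer
   positions -9..20.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .align import AlignmentParams, align_codes, encode_sequence
from .library import (
    MUTATION_CLASSES,
    WINDOW_LENGTH,
    WINDOW_POSITIONS,
    WINDOW_START,
    LibraryMember,
    common_protospacer_start,
)
from .simulate import REV_SPACER_OFFSET

_ALLOWED_ALTS = {"C": ("T", "G", "A"), "A": ("G",)}


@dataclass(frozen=True)
class QualityFilterConfig:
    """Q28 region filter: every base in the scored regions must reach min_phred."""

    min_phred: int = 28

    def __post_init__(self) -> None:
        if not 0 <= self.min_phred <= 41:
            raise ValueError("min_phred must be in 0..41")


@dataclass(frozen=True)
class AssignmentConfig:
    quality: QualityFilterConfig = field(default_factory=QualityFilterConfig)
    alignment: AlignmentParams = field(default_factory=AlignmentParams)
    #: candidates passed to alignment, ranked by shared tile count
    max_candidates: int = 5
    #: alignment score floor below which a read is left unassigned
    min_alignment_score: float = 0.0
    #: offset of the 20-nt spacer within the reverse read
    rev_spacer_offset: int = REV_SPACER_OFFSET


def quality_filter(
    fwd_qual: np.ndarray,
    rev_qual: np.ndarray,
    fwd_region: tuple[int, int],
    rev_region: tuple[int, int],
    config: QualityFilterConfig,
) -> bool:
    """Keep the pair iff every base inside both regions has Phred >= min_phred.

    Regions are half-open (start, end) slices on the respective read.  A
    region extending past the read end fails the filter (the bases needed for
    assignment were not sequenced).
    """
    fs, fe = fwd_region
    rs, re = rev_region
    if fe > fwd_qual.shape[0] or re > rev_qual.shape[0] or fs < 0 or rs < 0:
        return False
    q = config.min_phred
    return bool(
        (fwd_qual[fs:fe] >= q).all() and (rev_qual[rs:re] >= q).all()
    )


class KmerIndex:
    """Tiled 6-mer index over member target-site windows.

    Tiles are non-overlapping (stride = k), anchored at window position -9.
    A read shares a tile with a member when the identical k-mer occurs at the
    identical tile slot, which is what makes the hashing locality-sensitive:
    a single substitution corrupts at most one tile.
    """

    def __init__(
        self,
        members: Sequence[LibraryMember],
        k: int = 6,
        read_window_start: int | None = None,
    ) -> None:
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k
        self.n_tiles = WINDOW_LENGTH // k
        self.members = {m.member_id: m for m in members}
        if len(self.members) != len(members):
            raise ValueError("duplicate member_id in library")
        if read_window_start is None:
            read_window_start = common_protospacer_start(list(members)) + WINDOW_START - 1
        self.read_window_start = read_window_start
        self.spacers = {m.member_id: m.spacer for m in members}
        self._tiles: dict[tuple[int, str], set[str]] = {}
        for m in members:
            win = m.window_sequence
            for t in range(self.n_tiles):
                kmer = win[t * k : (t + 1) * k]
                self._tiles.setdefault((t, kmer), set()).add(m.member_id)

    def nominate(self, read_seq: str, max_candidates: int | None = None) -> list[str]:
        """Candidate member_ids sharing >= 1 tile-matched k-mer with the read.

        Ranked by shared-tile count descending, ties broken by member_id.
        Empty when the read shares no tile with any member.
        """
        start = self.read_window_start
        window = read_seq[start : start + WINDOW_LENGTH]
        counts: Counter[str] = Counter()
        for t in range(self.n_tiles):
            kmer = window[t * self.k : (t + 1) * self.k]
            for mid in self._tiles.get((t, kmer), ()):
                counts[mid] += 1
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        if max_candidates is not None:
            ranked = ranked[:max_candidates]
        return [mid for mid, _ in ranked]


def nominate_candidates(
    read_seq: str, index: KmerIndex, max_candidates: int | None = None
) -> list[str]:
    if len(read_seq) < index.k:
        raise ValueError("read shorter than k")
    return index.nominate(read_seq, max_candidates)


def spacer_filter(rev_read_spacer: str, candidates: Sequence[str], index: KmerIndex) -> list[str]:
    """Retain candidates whose spacer equals the sequenced spacer exactly."""
    return [mid for mid in candidates if index.spacers[mid] == rev_read_spacer]


@dataclass
class GenotypeCall:
    """Per-read genotype: tracked substitutions within window -9..20."""

    read_id: str
    member_id: str
    #: position -> (ref_base, alt_base), one of A->G, C->T, C->G, C->A
    calls: dict[int, tuple[str, str]]
    #: window positions covered by aligned (non-gap) read bases
    covered: tuple[int, ...]
    alignment_score: float


def genotype(
    read_seq: str,
    member: LibraryMember,
    params: AlignmentParams | None = None,
    read_id: str = "",
) -> GenotypeCall:
    """Genotype a read against a member cassette.

    Aligned columns where the cassette base is C or A, the read base differs,
    the substitution is one of the four tracked classes and the cassette
    position lies in -9..20 become calls.  Indel columns and other
    substitutions yield no call; N never produces a call.
    """
    if params is None:
        params = AlignmentParams()
    cassette = member.cassette
    if read_seq == cassette:
        # fast path: identical sequences need no alignment
        return GenotypeCall(
            read_id=read_id,
            member_id=member.member_id,
            calls={},
            covered=WINDOW_POSITIONS,
            alignment_score=float(len(read_seq) * params.match),
        )
    score, ai, bj = align_codes(
        encode_sequence(read_seq), encode_sequence(cassette), params
    )
    calls: dict[int, tuple[str, str]] = {}
    covered: list[int] = []
    for ri, cj in zip(ai, bj):
        if ri < 0 or cj < 0:
            continue
        pos = member.position_of(int(cj))
        if pos < WINDOW_START or pos > 20:
            continue
        covered.append(pos)
        ref = cassette[cj]
        alt = read_seq[ri]
        if ref != alt and ref in _ALLOWED_ALTS and alt in _ALLOWED_ALTS[ref]:
            calls[pos] = (ref, alt)
    return GenotypeCall(
        read_id=read_id,
        member_id=member.member_id,
        calls=calls,
        covered=tuple(covered),
        alignment_score=float(score),
    )


@dataclass
class AssignmentResult:
    """Counts, per-read calls and accounting from assign_and_genotype."""

    #: rows: member_id, replicate, position, ref_base, alt_base,
    #:       edited_reads, total_reads
    counts: pd.DataFrame
    #: rows: replicate, member_id, read_index, position, ref_base, alt_base
    calls: pd.DataFrame
    #: (replicate, member_id) -> number of genotyped reads
    reads_per_member: pd.DataFrame
    #: per-replicate accounting: total, kept, discarded, unassigned
    report: dict[str, dict[str, int]]


ReadPair = tuple[str, str, np.ndarray, str, np.ndarray]


def _process_replicate(
    pairs: Iterable[ReadPair],
    index: KmerIndex,
    config: AssignmentConfig,
    replicate: str,
):
    members = index.members
    ws = index.read_window_start
    fwd_region = (ws, ws + WINDOW_LENGTH)
    so = config.rev_spacer_offset
    rev_region = (so, so + 20)

    coverage: dict[str, np.ndarray] = {}
    edited: dict[tuple[str, int, str, str], int] = {}
    call_rows: list[tuple[str, str, int, int, str, str]] = []
    n_reads: Counter[str] = Counter()
    tally = {"total": 0, "kept": 0, "discarded": 0, "unassigned": 0}

    for read_id, fwd_seq, fwd_qual, rev_seq, rev_qual in pairs:
        tally["total"] += 1
        if not quality_filter(fwd_qual, rev_qual, fwd_region, rev_region, config.quality):
            tally["discarded"] += 1
            continue
        candidates = index.nominate(fwd_seq, config.max_candidates)
        if candidates:
            candidates = spacer_filter(rev_seq[so : so + 20], candidates, index)
        if not candidates:
            tally["unassigned"] += 1
            continue
        best: GenotypeCall | None = None
        for mid in candidates:
            call = genotype(fwd_seq, members[mid], config.alignment, read_id=read_id)
            if (
                best is None
                or call.alignment_score > best.alignment_score + 1e-9
                or (
                    abs(call.alignment_score - best.alignment_score) <= 1e-9
                    and call.member_id < best.member_id
                )
            ):
                best = call
        assert best is not None
        if best.alignment_score < config.min_alignment_score:
            tally["unassigned"] += 1
            continue
        tally["kept"] += 1
        mid = best.member_id
        idx = n_reads[mid]
        n_reads[mid] += 1
        cov = coverage.get(mid)
        if cov is None:
            cov = np.zeros(WINDOW_LENGTH, dtype=np.int64)
            coverage[mid] = cov
        for pos in best.covered:
            cov[pos - WINDOW_START] += 1
        for pos, (ref, alt) in best.calls.items():
            edited[(mid, pos, ref, alt)] = edited.get((mid, pos, ref, alt), 0) + 1
            call_rows.append((replicate, mid, idx, pos, ref, alt))
    return coverage, edited, call_rows, n_reads, tally


def assign_and_genotype(
    streams: Mapping[str, Iterable[ReadPair]],
    library: Sequence[LibraryMember],
    config: AssignmentConfig | None = None,
    index: KmerIndex | None = None,
) -> AssignmentResult:
    """Run the full assignment chain over per-replicate read-pair streams.

    ``streams`` maps a replicate (batch) label to an iterable of
    ``(read_id, fwd_seq, fwd_qual, rev_seq, rev_qual)`` with qualities as
    integer arrays.  The returned counts table has one row per
    (member, replicate, window position, tracked mutation class) compatible
    with the member's cassette base at that position; ``total_reads`` is the
    number of genotyped reads whose alignment covers the position.
    """
    if config is None:
        config = AssignmentConfig()
    if index is None:
        index = KmerIndex(library)
    members = {m.member_id: m for m in library}

    rows = []
    call_frames = []
    rpm_rows = []
    report: dict[str, dict[str, int]] = {}
    for replicate, pairs in streams.items():
        coverage, edited, call_rows, n_reads, tally = _process_replicate(
            pairs, index, config, replicate
        )
        report[replicate] = tally
        for mid in sorted(members):
            member = members[mid]
            cov = coverage.get(mid)
            rpm_rows.append((replicate, mid, int(n_reads.get(mid, 0))))
            for pos in WINDOW_POSITIONS:
                ref = member.base_at(pos)
                if ref not in _ALLOWED_ALTS:
                    continue
                total = int(cov[pos - WINDOW_START]) if cov is not None else 0
                for alt in _ALLOWED_ALTS[ref]:
                    rows.append(
                        (mid, replicate, pos, ref, alt,
                         edited.get((mid, pos, ref, alt), 0), total)
                    )
        call_frames.append(
            pd.DataFrame(
                call_rows,
                columns=["replicate", "member_id", "read_index", "position",
                         "ref_base", "alt_base"],
            )
        )
    counts = pd.DataFrame(
        rows,
        columns=["member_id", "replicate", "position", "ref_base", "alt_base",
                 "edited_reads", "total_reads"],
    ).sort_values(
        ["member_id", "position", "ref_base", "alt_base", "replicate"]
    ).reset_index(drop=True)
    calls = (
        pd.concat(call_frames, ignore_index=True)
        if call_frames
        else pd.DataFrame(
            columns=["replicate", "member_id", "read_index", "position",
                     "ref_base", "alt_base"]
        )
    )
    reads_per_member = pd.DataFrame(
        rpm_rows, columns=["replicate", "member_id", "n_reads"]
    )
    return AssignmentResult(
        counts=counts, calls=calls, reads_per_member=reads_per_member, report=report
    )
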