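"""Readers and writers for on-disk artifacts.

FASTQ is Sanger / Phred+33 (optionally gzipped); tables are TSV with fixed
headers and deterministic row order; model fits and run statistics are JSON.
All writers round-trip: read(write(x)) == x.
"""

from __future__ import annotations

import gzip
import json
import logging
import sys
from dataclasses import dataclass, field
from itertools import zip_longest
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import yaml
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .align import AlignmentParams
from .assign import AssignmentConfig, QualityFilterConfig
from .library import VALID_READ_CHARS, LibraryMember, LibraryValidationError
from .motif import MotifConfig
from .quantify import AnovaConfig, NoiseFilterConfig, QuantConfig, WindowConfig

logger = logging.getLogger(__name__)

LIBRARY_COLUMNS = [
    "member_id", "spacer", "cassette", "protospacer_start",
    "target_base_pos", "target_base",
]
COUNTS_COLUMNS = [
    "member_id", "replicate", "position", "ref_base", "alt_base",
    "edited_reads", "total_reads",
]
CALLS_COLUMNS = [
    "replicate", "member_id", "read_index", "position", "ref_base", "alt_base",
]


class FastqParseError(ValueError):
    """A FASTQ stream violated format expectations."""


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq_pairs(
    forward_path, reverse_path
) -> Iterator[tuple[str, str, np.ndarray, str, np.ndarray]]:
    """Stream paired reads as (read_id, fwd_seq, fwd_qual, rev_seq, rev_qual).

    Qualities are decoded from Phred+33 into integer arrays.  Mismatched
    record counts, diverging pair IDs and non-ACGTN symbols raise
    :class:`FastqParseError` naming the offending record.
    """
    with _open_text(forward_path) as fh_f, _open_text(reverse_path) as fh_r:
        fwd_iter = FastqGeneralIterator(fh_f)
        rev_iter = FastqGeneralIterator(fh_r)
        sentinel = object()
        for i, (fwd, rev) in enumerate(zip_longest(fwd_iter, rev_iter, fillvalue=sentinel)):
            if fwd is sentinel or rev is sentinel:
                longer = reverse_path if fwd is sentinel else forward_path
                raise FastqParseError(
                    f"unequal record counts: {longer} still has records at "
                    f"pair index {i}"
                )
            (fid, fseq, fqual) = fwd
            (rid, rseq, rqual) = rev
            fid_core = fid.split()[0].removesuffix("/1")
            rid_core = rid.split()[0].removesuffix("/2")
            if fid_core != rid_core:
                raise FastqParseError(
                    f"pair IDs diverge at record {i}: {fid_core!r} vs {rid_core!r}"
                )
            for seq, which in ((fseq, "forward"), (rseq, "reverse")):
                if set(seq.upper()) - VALID_READ_CHARS:
                    raise FastqParseError(
                        f"non-ACGTN symbol in {which} read at record {i} ({fid_core})"
                    )
            yield (
                fid_core,
                fseq.upper(),
                np.frombuffer(fqual.encode("ascii"), dtype=np.uint8).astype(np.int16) - 33,
                rseq.upper(),
                np.frombuffer(rqual.encode("ascii"), dtype=np.uint8).astype(np.int16) - 33,
            )


def write_fastq(records: Iterable[tuple[str, str, str]], path) -> None:
    """Write (read_id, sequence, quality-string) records as FASTQ."""
    with _open_text(path, "wt") as fh:
        for rid, seq, qual in records:
            if len(seq) != len(qual):
                raise ValueError(f"sequence/quality length mismatch for {rid}")
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def write_read_pairs(reads, fwd_path, rev_path) -> None:
    """Write simulator records (id, fwd, fq, rev, rq) as two FASTQ files."""
    write_fastq(((r[0], r[1], r[2]) for r in reads), fwd_path)
    write_fastq(((r[0], r[3], r[4]) for r in reads), rev_path)


# ---------------------------------------------------------------------------
# library table
# ---------------------------------------------------------------------------


def write_library_table(members: list[LibraryMember], path) -> None:
    df = pd.DataFrame(
        [
            (m.member_id, m.spacer, m.cassette, m.protospacer_start,
             m.target_base_pos, m.target_base)
            for m in members
        ],
        columns=LIBRARY_COLUMNS,
    ).sort_values("member_id")
    df.to_csv(path, sep="\t", index=False)


def read_library_table(path) -> list[LibraryMember]:
    """Read and validate a library TSV; row numbers are reported on error."""
    df = pd.read_csv(path, sep="\t", dtype={c: str for c in
                     ("member_id", "spacer", "cassette", "target_base")})
    missing = set(LIBRARY_COLUMNS) - set(df.columns)
    if missing:
        raise LibraryValidationError(f"{path}: missing columns {sorted(missing)}")
    members = []
    seen: set[str] = set()
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            member = LibraryMember(
                member_id=row.member_id,
                spacer=row.spacer,
                cassette=row.cassette,
                protospacer_start=int(row.protospacer_start),
                target_base_pos=int(row.target_base_pos),
                target_base=row.target_base,
            )
        except LibraryValidationError as exc:
            raise LibraryValidationError(f"{path} row {row_no}: {exc}") from exc
        if member.member_id in seen:
            raise LibraryValidationError(
                f"{path} row {row_no}: duplicate member_id {member.member_id!r}"
            )
        seen.add(member.member_id)
        members.append(member)
    return members


# ---------------------------------------------------------------------------
# counts / calls tables
# ---------------------------------------------------------------------------

_SORT_KEYS = {
    tuple(COUNTS_COLUMNS): ["member_id", "position", "ref_base", "alt_base", "replicate"],
    tuple(CALLS_COLUMNS): ["replicate", "member_id", "read_index", "position"],
}


def write_counts(counts: pd.DataFrame, path) -> None:
    _write_table(counts, COUNTS_COLUMNS, path)


def read_counts(path) -> pd.DataFrame:
    return _read_table(path, COUNTS_COLUMNS)


def write_calls(calls: pd.DataFrame, path) -> None:
    _write_table(calls, CALLS_COLUMNS, path)


def read_calls(path) -> pd.DataFrame:
    return _read_table(path, CALLS_COLUMNS)


def _write_table(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = set(columns) - set(df.columns)
    if missing:
        raise ValueError(f"table missing columns {sorted(missing)}")
    out = df[columns]
    numeric = out.select_dtypes(include=[float]).columns
    if len(numeric) and out[numeric].isna().any().any():
        raise ValueError("refusing to write NaN cells")
    out = out.sort_values(_SORT_KEYS[tuple(columns)], kind="mergesort")
    with _open_text(path, "wt") as fh:
        out.to_csv(fh, sep="\t", index=False)


def _read_table(path, columns: list[str]) -> pd.DataFrame:
    dtypes = {
        "member_id": str, "replicate": str, "ref_base": str, "alt_base": str,
        "position": np.int64, "edited_reads": np.int64, "total_reads": np.int64,
        "read_index": np.int64,
    }
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t", dtype={c: dtypes[c] for c in columns})
    missing = set(columns) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# results JSON
# ---------------------------------------------------------------------------


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, set):
        return [_jsonify(v) for v in sorted(obj)]
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_results(results: dict, path) -> None:
    """Write a statistics dict as JSON (non-finite values become null)."""
    with open(path, "w") as fh:
        json.dump(_jsonify(results), fh, indent=2, sort_keys=True)


def read_results(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

CONFIG_SCHEMA = """\
# bequant run configuration (YAML, flat keys; all optional)
min_phred: 28            # quality floor inside spacer/target regions
match: 1.0               # alignment scores
mismatch: -1.0
gap_open: -5.0
gap_extend: 0.0
free_start_gaps: true
max_candidates: 5        # k-mer nominees passed to alignment
error_rate: 1.0e-3       # sequencing noise rate for the replicate filter
keep_threshold: 0.05     # joint noise probability below which a mutation is kept
family_alpha: 0.005      # family-wise level of the batch-effect ANOVA
peak_fraction: 0.30      # editing-window threshold relative to the peak
drop_flagged: false      # remove batch-flagged hypotheses instead of reporting
epsilon: 0.001           # stabilised-logit constant
ridge_alpha: 1.0e-5      # motif ridge penalty
train_fraction: 0.8      # motif train split
rng_seed: 0
"""


@dataclass
class RunConfig:
    """All tunables of a processing run, loadable from a flat YAML file."""

    assignment: AssignmentConfig = field(default_factory=AssignmentConfig)
    quant: QuantConfig = field(default_factory=QuantConfig)
    motif: MotifConfig = field(default_factory=MotifConfig)
    rng_seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: expected a flat key: value mapping")
        known = {
            "min_phred", "match", "mismatch", "gap_open", "gap_extend",
            "free_start_gaps", "max_candidates", "error_rate", "keep_threshold",
            "family_alpha", "peak_fraction", "drop_flagged", "epsilon",
            "ridge_alpha", "train_fraction", "rng_seed",
        }
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown keys {sorted(unknown)}")
        g = raw.get
        assignment = AssignmentConfig(
            quality=QualityFilterConfig(min_phred=int(g("min_phred", 28))),
            alignment=AlignmentParams(
                match=float(g("match", 1.0)),
                mismatch=float(g("mismatch", -1.0)),
                gap_open=float(g("gap_open", -5.0)),
                gap_extend=float(g("gap_extend", 0.0)),
                free_start_gaps=bool(g("free_start_gaps", True)),
            ),
            max_candidates=int(g("max_candidates", 5)),
        )
        quant = QuantConfig(
            noise=NoiseFilterConfig(
                error_rate=float(g("error_rate", 1e-3)),
                keep_threshold=float(g("keep_threshold", 0.05)),
            ),
            anova=AnovaConfig(family_alpha=float(g("family_alpha", 0.005))),
            window=WindowConfig(peak_fraction=float(g("peak_fraction", 0.30))),
            drop_flagged=bool(g("drop_flagged", False)),
        )
        motif = MotifConfig(
            epsilon=float(g("epsilon", 0.001)),
            ridge_alpha=float(g("ridge_alpha", 1e-5)),
            train_fraction=float(g("train_fraction", 0.8)),
            rng_seed=int(g("rng_seed", 0)),
        )
        return cls(assignment=assignment, quant=quant, motif=motif,
                   rng_seed=int(g("rng_seed", 0)))


def setup_logging(verbosity: int = 0) -> None:
    level = logging.WARNING - 10 * min(verbosity, 2)
    logging.basicConfig(
        stream=sys.stderr,
        level=level,
        format="%(levelname)s %(name)s: %(message)s",
    )
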