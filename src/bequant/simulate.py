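"""Synthetic paired sgRNA / target-site library and editing-outcome simulator.

The generator emulates a reduced-scale version of a genomically integrated
"context" library: every member carries a substrate C or A at protospacer
position 6 surrounded by variable sequence context, and is sequenced as
paired-end reads (forward over the target cassette, reverse over the spacer)
at ~300x coverage per member per biological replicate with ~1e-3 per-base
substitution error (Q30).

The editing model is additive on the log-odds scale: in reads where the
editor engages the cassette at all (a per-read Bernoulli with probability
``engage_prob``), each substrate base in the -9..20 window converts with
probability ``logistic(mu + window_weight + sum of context weights)``.
C conversions are realised as C->G / C->A byproducts with the configured
fractions and as C->T otherwise; A conversions are always A->G.  The latent
per-read engagement couples edits at different positions of the same read,
which is what makes conditional co-editing statistics non-trivial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .library import (
    A_TO_G,
    C_TO_T,
    DNA_BASES,
    WINDOW_POSITIONS,
    LibraryMember,
)

_BASE_TO_CODE = {b: i for i, b in enumerate(DNA_BASES)}
_CODE_TO_BASE = np.frombuffer("ACGT".encode(), dtype=np.uint8)

#: Fixed sequence flanking the spacer on the reverse (sgRNA-cassette) read.
REV_PREFIX = "GTGGAAAGGACGAAACAC"  # 18 nt, U6-promoter-like
REV_SUFFIX = "GTTTTAGAGCTAGAAATA"  # 18 nt, scaffold-like
REV_SPACER_OFFSET = len(REV_PREFIX)

#: Default context offsets (the library varies a 6-mer around the target base).
CONTEXT_OFFSETS = (-3, -2, -1, 1, 2, 3)

DEFAULT_CASSETTE_LEN = 94
DEFAULT_PROTOSPACER_START = 29


def logistic(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def logit(p: float) -> float:
    return math.log(p / (1.0 - p))


@dataclass(frozen=True)
class EditorModel:
    """Ground-truth editor used by the simulator.

    Parameters
    ----------
    mu
        Baseline log-odds of conversion.
    window_weights_c, window_weights_a
        Additive log-odds per protospacer position for C and A substrates.
        Positions absent from the mapping are never edited, so the mappings
        define the support of the editing window.
    context_weights
        Additive log-odds for (relative offset in -3..+3 excluding 0, base).
    byproduct_frac_g, byproduct_frac_a
        Fractions of C conversions realised as C->G and C->A; the remainder
        is C->T.
    engage_prob
        Per-read probability that the editor engages the cassette at all.
        1.0 reduces to independent per-site editing.
    seq_error_rate
        Per-base substitution probability (uniform over the 3 other bases).
    q_default
        Phred score assigned to bases (Sanger / Phred+33 dialect).
    q_fail_frac
        Fraction of bases demoted to ``q_fail`` (below the Q28 read filter).
    """

    mu: float = 0.0
    window_weights_c: Mapping[int, float] = field(default_factory=dict)
    window_weights_a: Mapping[int, float] = field(default_factory=dict)
    context_weights: Mapping[tuple[int, str], float] = field(default_factory=dict)
    byproduct_frac_g: float = 0.0
    byproduct_frac_a: float = 0.0
    engage_prob: float = 1.0
    seq_error_rate: float = 1e-3
    q_default: int = 30
    q_fail: int = 20
    q_fail_frac: float = 0.0

    def __post_init__(self) -> None:
        for name in ("byproduct_frac_g", "byproduct_frac_a", "engage_prob",
                     "seq_error_rate", "q_fail_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.byproduct_frac_g + self.byproduct_frac_a > 1.0:
            raise ValueError("byproduct fractions must sum to <= 1")
        for pos in list(self.window_weights_c) + list(self.window_weights_a):
            if pos not in WINDOW_POSITIONS:
                raise ValueError(f"window weight at position {pos} outside -9..20")
        for (off, base) in self.context_weights:
            if off == 0 or not -3 <= off <= 3:
                raise ValueError(f"context offset {off} outside -3..+3 \\ {{0}}")
            if base not in DNA_BASES:
                raise ValueError(f"invalid context base {base!r}")

    # -- per-site conversion probabilities ---------------------------------

    def context_logodds(self, member: LibraryMember, position: int) -> float:
        total = 0.0
        start = member.offset_of(position)
        for off in CONTEXT_OFFSETS:
            idx = start + off
            if 0 <= idx < len(member.cassette):
                total += self.context_weights.get((off, member.cassette[idx]), 0.0)
        return total

    def conversion_prob(self, member: LibraryMember, position: int) -> float:
        """P(conversion | engaged) for the substrate base at ``position``.

        Zero if the base is not an editable substrate or the position carries
        no window weight.
        """
        base = member.base_at(position)
        weights = (
            self.window_weights_c if base == "C"
            else self.window_weights_a if base == "A"
            else None
        )
        if weights is None or position not in weights:
            return 0.0
        return logistic(self.mu + weights[position] + self.context_logodds(member, position))

    @property
    def c_to_t_frac(self) -> float:
        return 1.0 - self.byproduct_frac_g - self.byproduct_frac_a

    def attenuated(self, fold: float) -> "EditorModel":
        """A copy whose per-member efficiencies are divided by ``fold``.

        Implemented by scaling the engagement probability, which rescales
        every per-read editing probability by exactly 1/fold.
        """
        if fold <= 0:
            raise ValueError("fold must be positive")
        return replace(self, engage_prob=self.engage_prob / fold)


# ---------------------------------------------------------------------------
# presets: the study conditions used throughout tests and the acceptance run
# ---------------------------------------------------------------------------

_CBE_WINDOW_C = {3: 0.0, 4: 0.5, 5: 1.0, 6: 1.2, 7: 0.5, 8: 0.0}
_OUTSIDE_WEIGHT = -3.5  # low bystander tail outside the 3..8 core
_CONTEXT_WEIGHTS = {
    (-1, "T"): 0.45, (-1, "C"): 0.20, (-1, "A"): -0.50, (-1, "G"): -0.15,
    (1, "A"): 0.15, (1, "T"): 0.10, (1, "G"): -0.10, (1, "C"): -0.15,
    (-2, "A"): -0.10, (-2, "C"): 0.10, (2, "C"): 0.05, (2, "G"): -0.05,
    (-3, "G"): -0.05, (3, "T"): 0.05,
}


def _full_window(core: Mapping[int, float], outside: float) -> dict[int, float]:
    w = {pos: outside for pos in WINDOW_POSITIONS}
    w.update(core)
    return w


def _selectivity_matched_a_weights(
    window_c: Mapping[int, float], mu: float, c_to_t_frac: float, selectivity: float
) -> dict[int, float]:
    """A-site weights making the per-position truth C->T : A->G ratio constant."""
    out = {}
    for pos, w in window_c.items():
        p_ct = logistic(mu + w) * c_to_t_frac
        out[pos] = logit(p_ct / selectivity) - mu
    return out


def cbe_preset() -> EditorModel:
    """A realistic narrow-window cytosine editor (TadCBE-like)."""
    window_c = _full_window(_CBE_WINDOW_C, _OUTSIDE_WEIGHT)
    window_a = _selectivity_matched_a_weights(window_c, 0.0, 0.94, 25.0)
    return EditorModel(
        mu=0.0,
        window_weights_c=window_c,
        window_weights_a=window_a,
        context_weights=dict(_CONTEXT_WEIGHTS),
        byproduct_frac_g=0.03,
        byproduct_frac_a=0.03,
        engage_prob=0.45,
    )


def benchmark_preset(selectivity: float = 25.0) -> EditorModel:
    """Parameter-recovery benchmark: truth window 3..8, exact truth selectivity.

    Context weights are zero and engagement is 1 so the per-position truth
    C->T : A->G ratio equals ``selectivity`` exactly and the truth editing
    window is exactly positions 3..8.
    """
    window_c = _full_window(_CBE_WINDOW_C, _OUTSIDE_WEIGHT)
    window_a = _selectivity_matched_a_weights(window_c, 0.0, 0.94, selectivity)
    return EditorModel(
        mu=0.0,
        window_weights_c=window_c,
        window_weights_a=window_a,
        byproduct_frac_g=0.03,
        byproduct_frac_a=0.03,
        engage_prob=1.0,
    )


def dual_preset() -> EditorModel:
    """A dual editor performing comparable C->T and A->G editing (TadDE-like)."""
    core = {3: -0.2, 4: 0.4, 5: 0.9, 6: 1.1, 7: 0.4, 8: -0.2}
    window = _full_window(core, _OUTSIDE_WEIGHT)
    return EditorModel(
        mu=0.0,
        window_weights_c=dict(window),
        window_weights_a=dict(window),
        context_weights=dict(_CONTEXT_WEIGHTS),
        byproduct_frac_g=0.02,
        byproduct_frac_a=0.02,
        engage_prob=0.6,
    )


def null_preset() -> EditorModel:
    """No editing at all: pure sequencing-noise condition."""
    return EditorModel(engage_prob=0.0)


PRESETS = {
    "cbe": cbe_preset,
    "benchmark": benchmark_preset,
    "dual": dual_preset,
    "null": null_preset,
}


# ---------------------------------------------------------------------------
# library construction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimConfig:
    """Scale of the simulated experiment."""

    n_members: int
    replicates: int = 2
    mean_depth: float = 300.0
    fwd_len: int = 94
    rev_len: int = 56
    cassette_len: int = DEFAULT_CASSETTE_LEN
    protospacer_start: int = DEFAULT_PROTOSPACER_START
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if self.cassette_len < self.protospacer_start + 23:
            raise ValueError("cassette_len too short for protospacer + PAM")

    @property
    def replicate_labels(self) -> tuple[str, ...]:
        return tuple(f"r{i + 1}" for i in range(self.replicates))


def build_library(config: SimConfig) -> list[LibraryMember]:
    """Generate a reduced-scale context library.

    Half the members carry a substrate C at protospacer position 6, half an A.
    The first 32 members enumerate all 16 (5', 3') dinucleotide contexts of
    the target base for each substrate, so full dinucleotide context coverage
    is guaranteed whenever ``n_members >= 32``; remaining contexts are drawn
    uniformly.  Spacers are unique; generation is deterministic given the
    seed.
    """
    rng = np.random.default_rng(config.rng_seed)
    ps = config.protospacer_start
    members: list[LibraryMember] = []
    seen: set[str] = set()
    target_offset_in_spacer = 5  # protospacer position 6, 0-based within spacer

    for i in range(config.n_members):
        target = "C" if i % 2 == 0 else "A"
        attempts = 0
        while True:
            attempts += 1
            if attempts > 1000:
                raise ValueError(
                    f"could not generate a unique spacer for member {i}; "
                    f"n_members={config.n_members} too large for this design"
                )
            spacer = list(rng.choice(list(DNA_BASES), size=20))
            spacer[target_offset_in_spacer] = target
            if i < 32:
                ctx = (i // 2) % 16
                spacer[target_offset_in_spacer - 1] = DNA_BASES[ctx // 4]
                spacer[target_offset_in_spacer + 1] = DNA_BASES[ctx % 4]
            spacer_str = "".join(spacer)
            if spacer_str not in seen:
                seen.add(spacer_str)
                break
        flank5 = "".join(rng.choice(list(DNA_BASES), size=ps))
        pam = str(rng.choice(list(DNA_BASES))) + "GG"
        n_flank3 = config.cassette_len - ps - 20 - 3
        flank3 = "".join(rng.choice(list(DNA_BASES), size=n_flank3))
        cassette = flank5 + spacer_str + pam + flank3
        members.append(
            LibraryMember(
                member_id=f"m{i:05d}",
                spacer=spacer_str,
                cassette=cassette,
                protospacer_start=ps,
                target_base_pos=6,
                target_base=target,
            )
        )
    return members


# ---------------------------------------------------------------------------
# outcome and read simulation
# ---------------------------------------------------------------------------


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8).copy()


def _editable_sites(member: LibraryMember, model: EditorModel):
    """(cassette offset, ref code, conversion prob, is_c) per editable site."""
    sites = []
    for pos in WINDOW_POSITIONS:
        p = model.conversion_prob(member, pos)
        if p > 0.0:
            base = member.base_at(pos)
            sites.append((member.offset_of(pos), _BASE_TO_CODE[base], p, base == "C"))
    return sites


def simulate_outcome_array(
    member: LibraryMember,
    model: EditorModel,
    depth: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate edited cassettes; returns a (depth, cassette_len) byte array."""
    if depth <= 0:
        raise ValueError("depth must be > 0")
    cas = _encode(member.cassette)
    reads = np.tile(cas, (depth, 1))
    engaged = rng.random(depth) < model.engage_prob
    if not engaged.any():
        return reads
    code = {b: ord(b) for b in DNA_BASES}
    fg, fa = model.byproduct_frac_g, model.byproduct_frac_a
    for offset, _ref, p, is_c in _editable_sites(member, model):
        hit = engaged & (rng.random(depth) < p)
        if not hit.any():
            continue
        if is_c:
            u = rng.random(depth)
            out = np.full(depth, code["T"], dtype=np.uint8)
            out[u < fg] = code["G"]
            out[(u >= fg) & (u < fg + fa)] = code["A"]
            reads[hit, offset] = out[hit]
        else:
            reads[hit, offset] = code["G"]
    return reads


def simulate_outcomes(
    member: LibraryMember,
    model: EditorModel,
    depth: int,
    rng: np.random.Generator,
) -> list[str]:
    """Simulate ``depth`` edited cassette sequences for one member."""
    arr = simulate_outcome_array(member, model, depth, rng)
    return [row.tobytes().decode() for row in arr]


def _apply_errors(arr: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each base to one of the 3 others with probability ``rate``."""
    if rate <= 0:
        return arr
    codes = _CODE_TO_BASE  # b"ACGT"
    lut = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate(codes):
        lut[b] = i
    idx = lut[arr]
    mask = rng.random(arr.shape) < rate
    shift = rng.integers(1, 4, size=arr.shape)
    idx = np.where(mask, (idx + shift) % 4, idx)
    return codes[idx].astype(np.uint8)


def _quality_array(
    shape: tuple[int, int], model: EditorModel, rng: np.random.Generator
) -> np.ndarray:
    q = np.full(shape, model.q_default + 33, dtype=np.uint8)
    if model.q_fail_frac > 0:
        fail = rng.random(shape) < model.q_fail_frac
        q[fail] = model.q_fail + 33
    return q


def simulate_reads(
    outcomes: Sequence[str] | np.ndarray,
    member: LibraryMember,
    model: EditorModel,
    config: SimConfig,
    rng: np.random.Generator,
    replicate: str = "r1",
) -> list[tuple[str, str, str, str, str]]:
    """Turn outcome cassettes into paired reads with errors and qualities.

    Returns tuples ``(read_id, fwd_seq, fwd_qual, rev_seq, rev_qual)``.  The
    forward read covers the target cassette (window -9..20 plus flanks); the
    reverse read covers the sgRNA-cassette spacer region, which is never
    edited.  Read IDs encode the ground-truth member for testing.
    """
    if len(outcomes) == 0:
        raise ValueError("outcomes must be non-empty")
    if isinstance(outcomes, np.ndarray):
        arr = outcomes
    else:
        arr = np.frombuffer("".join(outcomes).encode(), dtype=np.uint8).reshape(
            len(outcomes), -1
        )
    depth = arr.shape[0]
    if arr.shape[1] < config.fwd_len:
        raise ValueError(
            f"cassette length {arr.shape[1]} shorter than forward read "
            f"length {config.fwd_len}"
        )
    rev_template = REV_PREFIX + member.spacer + REV_SUFFIX
    if len(rev_template) < config.rev_len:
        raise ValueError("spacer cassette shorter than reverse read length")

    fwd = _apply_errors(arr[:, : config.fwd_len].copy(), model.seq_error_rate, rng)
    rev = np.tile(_encode(rev_template)[: config.rev_len], (depth, 1))
    rev = _apply_errors(rev, model.seq_error_rate, rng)
    fq = _quality_array(fwd.shape, model, rng)
    rq = _quality_array(rev.shape, model, rng)

    records = []
    for i in range(depth):
        records.append(
            (
                f"{member.member_id}:{replicate}:{i}",
                fwd[i].tobytes().decode(),
                fq[i].tobytes().decode(),
                rev[i].tobytes().decode(),
                rq[i].tobytes().decode(),
            )
        )
    return records


@dataclass
class SimulatedExperiment:
    """In-memory result of a full simulated sequencing experiment."""

    config: SimConfig
    model: EditorModel
    library: list[LibraryMember]
    #: replicate label -> list of (read_id, fwd_seq, fwd_qual, rev_seq, rev_qual)
    reads: dict[str, list[tuple[str, str, str, str, str]]]

    def read_pairs(self, replicate: str) -> Iterable[tuple[str, str, np.ndarray, str, np.ndarray]]:
        """Yield read pairs in the format consumed by the assignment stage."""
        for rid, fs, fq, rs, rq in self.reads[replicate]:
            yield (
                rid,
                fs,
                np.frombuffer(fq.encode(), dtype=np.uint8).astype(np.int16) - 33,
                rs,
                np.frombuffer(rq.encode(), dtype=np.uint8).astype(np.int16) - 33,
            )


def simulate_experiment(
    config: SimConfig,
    model: EditorModel,
    library: list[LibraryMember] | None = None,
) -> SimulatedExperiment:
    """Build the library (unless given) and simulate all replicates.

    Per-member per-replicate depth is Poisson(``mean_depth``), floored at 1.
    Deterministic given ``config.rng_seed``.
    """
    if library is None:
        library = build_library(config)
    rng = np.random.default_rng(config.rng_seed + 1)
    reads: dict[str, list[tuple[str, str, str, str, str]]] = {}
    for rep in config.replicate_labels:
        rep_reads: list[tuple[str, str, str, str, str]] = []
        for member in library:
            depth = max(1, int(rng.poisson(config.mean_depth)))
            outcomes = simulate_outcome_array(member, model, depth, rng)
            rep_reads.extend(
                simulate_reads(outcomes, member, model, config, rng, replicate=rep)
            )
        reads[rep] = rep_reads
    return SimulatedExperiment(config=config, model=model, library=library, reads=reads)


# ---------------------------------------------------------------------------
# analytic ground truth
# ---------------------------------------------------------------------------


@dataclass
class TruthStatistics:
    """Analytic expectations implied by an EditorModel on a given library."""

    #: (position, ref, alt) -> expected pooled efficiency (mean over members
    #: carrying ``ref`` at ``position``)
    position_efficiency: dict[tuple[int, str, str], float]
    window: set[int]
    selectivity: float
    #: per-member probability that a read carries >= 1 edit of the class
    member_any_edit: dict[str, dict[str, float]]  # class key -> member -> prob
    average_efficiency: dict[str, float]  # class key -> mean over members
    conditional_coediting: float
    abe_cbe_ratio: float


def _member_site_probs(member: LibraryMember, model: EditorModel):
    """Per-position conversion probabilities split by substrate base."""
    c_sites: dict[int, float] = {}
    a_sites: dict[int, float] = {}
    for pos in WINDOW_POSITIONS:
        p = model.conversion_prob(member, pos)
        if p <= 0.0:
            continue
        if member.base_at(pos) == "C":
            c_sites[pos] = p
        else:
            a_sites[pos] = p
    return c_sites, a_sites


def truth_statistics(
    model: EditorModel,
    library: Sequence[LibraryMember],
    peak_fraction: float = 0.30,
) -> TruthStatistics:
    """Expected per-position efficiencies, window, selectivity and co-editing.

    Uses the same formulas as the quantification stage, applied to analytic
    expectations instead of counts: position efficiency is the unweighted mean
    over members carrying the substrate base, the window collects positions
    with C->T efficiency >= ``peak_fraction`` of the peak, and selectivity is
    the geometric mean of the per-position C->T : A->G ratio over the window.
    """
    e = model.engage_prob
    ft = model.c_to_t_frac
    fg, fa = model.byproduct_frac_g, model.byproduct_frac_a

    acc: dict[tuple[int, str, str], list[float]] = {}
    member_any: dict[str, dict[str, float]] = {"C2T": {}, "A2G": {}}
    cond_num = 0.0
    cond_den = 0.0
    for member in library:
        c_sites, a_sites = _member_site_probs(member, model)
        for pos in WINDOW_POSITIONS:
            base = member.base_at(pos)
            if base == "C":
                p = c_sites.get(pos, 0.0)
                acc.setdefault((pos, "C", "T"), []).append(e * p * ft)
                acc.setdefault((pos, "C", "G"), []).append(e * p * fg)
                acc.setdefault((pos, "C", "A"), []).append(e * p * fa)
            elif base == "A":
                p = a_sites.get(pos, 0.0)
                acc.setdefault((pos, "A", "G"), []).append(e * p)
        p_no_ct = math.prod(1.0 - p * ft for p in c_sites.values())
        p_no_ag = math.prod(1.0 - p for p in a_sites.values())
        p_ct = 1.0 - p_no_ct
        p_ag = 1.0 - p_no_ag
        member_any["C2T"][member.member_id] = e * p_ct
        member_any["A2G"][member.member_id] = e * p_ag
        cond_num += e * p_ct * p_ag
        cond_den += e * p_ct

    position_efficiency = {k: float(np.mean(v)) for k, v in acc.items()}

    ct_profile = {
        pos: eff for (pos, r, a), eff in position_efficiency.items() if (r, a) == C_TO_T
    }
    peak = max(ct_profile.values(), default=0.0)
    window = {pos for pos, eff in ct_profile.items() if peak > 0 and eff >= peak_fraction * peak}

    ag_profile = {
        pos: eff for (pos, r, a), eff in position_efficiency.items() if (r, a) == A_TO_G
    }
    logs = [
        math.log(ct_profile[pos] / ag_profile[pos])
        for pos in sorted(window)
        if ag_profile.get(pos, 0.0) > 0 and ct_profile.get(pos, 0.0) > 0
    ]
    selectivity = math.exp(float(np.mean(logs))) if logs else float("nan")

    average_efficiency = {
        cls: float(np.mean(list(vals.values()))) for cls, vals in member_any.items()
    }
    conditional = cond_num / cond_den if cond_den > 0 else float("nan")
    ratio = (
        average_efficiency["A2G"] / average_efficiency["C2T"]
        if average_efficiency["C2T"] > 0
        else float("nan")
    )
    return TruthStatistics(
        position_efficiency=position_efficiency,
        window=window,
        selectivity=selectivity,
        member_any_edit=member_any,
        average_efficiency=average_efficiency,
        conditional_coediting=conditional,
        abe_cbe_ratio=ratio,
    )
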