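"""Design and audit of an RNAcompete-style oligonucleotide probe pool.

The pool is derived from an order-11 de Bruijn sequence over ACGT: the
linearized sequence is tiled into ~241k overlapping 35-nt variable regions,
restriction-site 7-mers (SapI/BspQI: GCTCTTC and its reverse complement
CGAGAAG) are excised by minimal substitution, the probes are split into two
interleaved half-pools (set A / set B) for internal replication, and a phi2.5
T7 initiation trinucleotide (AGA or AGG) is prepended before transcription to
RNA. Combinatorial coverage is audited exhaustively: every admissible 9-mer
must appear at least 16 times across the pool and every admissible 7-mer at
least 155 times within each set.

Design is fully deterministic for a given :class:`PoolDesignSpec`; the seed
only drives randomized fallbacks, none of which are exercised by the default
configuration.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np

from ._kmers import (
    DNA_ALPHABET,
    code_to_kmer,
    count_kmers,
    decode,
    encode,
    kmer_to_code,
    rolling_codes,
)

__all__ = [
    "PoolDesignSpec",
    "ProbeRecord",
    "KmerCoverageReport",
    "ProbePool",
    "PoolDesignError",
    "DesignResult",
    "generate_de_bruijn",
    "tile_probes",
    "excise_forbidden",
    "assign_sets",
    "add_initiation_prefix",
    "verify_coverage",
    "design_pool",
    "expand_forbidden_kmers",
    "forbidden_junction_prefixes",
    "screen_hairpins",
]


class PoolDesignError(ValueError):
    """Raised when a pool cannot be designed or repaired under the spec."""


@dataclass(frozen=True)
class PoolDesignSpec:
    """Constraint set governing pool construction.

    Defaults reproduce the published pool geometry: an order-11 de Bruijn
    backbone tiled into 241,399 probes of 35-nt variable sequence (38 nt of
    RNA with the initiation trinucleotide, within the 41-nt cap), with the
    SapI/BspQI sites excised and coverage floors of 16 per 9-mer pool-wide
    and 155 per 7-mer within each set.

    ``pool_audit_k`` / ``set_audit_k`` set the k-mer lengths of the two
    audits (9 and 7 at full scale); they scale down together with ``order``
    for toy designs. The tiling keeps consecutive windows overlapping by at
    least ``pool_audit_k - 1`` nt so no audit k-mer occurrence is orphaned.
    """

    order: int = 11
    alphabet: str = DNA_ALPHABET
    probe_count: int = 241_399
    variable_length: int = 35
    max_rna_length: int = 41
    forbidden_kmers: tuple[str, ...] = ("GCTCTTC", "CGAGAAG")
    min_9mer_count: int = 16
    min_7mer_per_set: int = 155
    init_trinucleotides: tuple[str, ...] = ("AGA", "AGG")
    seed: int = 17
    pool_audit_k: int = 9
    set_audit_k: int = 7
    patch_budget_frac: float = 0.001

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if len(set(self.alphabet)) != len(self.alphabet) or not self.alphabet:
            raise ValueError("alphabet letters must be distinct and non-empty")
        if self.probe_count < 1:
            raise ValueError("probe_count must be >= 1")
        if self.variable_length + 3 > self.max_rna_length:
            raise ValueError("variable_length + 3 must not exceed max_rna_length")
        if any(len(f) != 7 for f in self.forbidden_kmers):
            raise ValueError("forbidden_kmers must all be 7-mers")
        if self.min_9mer_count < 1 or self.min_7mer_per_set < 1:
            raise ValueError("coverage floors must be positive")
        if not (1 <= self.set_audit_k <= self.pool_audit_k <= self.variable_length):
            raise ValueError("audit k-mer lengths out of range")
        if any(len(t) != 3 for t in self.init_trinucleotides):
            raise ValueError("initiation trinucleotides must have length 3")

    @property
    def min_window_overlap(self) -> int:
        return self.pool_audit_k - 1


@dataclass
class ProbeRecord:
    """One designed probe: DNA variable region plus transcribed RNA."""

    probe_id: str
    set_label: str | None
    start: int
    variable_seq: str
    rna_seq: str | None


@dataclass
class KmerCoverageReport:
    """Exhaustive multiplicity audit of one (k, scope) constraint."""

    k: int
    scope: str
    threshold: int
    min_count: int
    argmin_kmers: list[str]
    excluded_kmers: list[str]
    total_kmers_counted: int
    passed: bool


class ProbePool:
    """Array-backed probe collection.

    Internally a (n, variable_length) uint8 code matrix plus parallel start
    offsets, ids, set labels and initiation prefixes; iterating or indexing
    materializes :class:`ProbeRecord` views.
    """

    def __init__(
        self,
        seqs: np.ndarray,
        starts: np.ndarray,
        ids: list[str],
        set_labels: np.ndarray | None = None,
        prefixes: list[str] | None = None,
    ) -> None:
        self.seqs = np.ascontiguousarray(seqs, dtype=np.uint8)
        self.starts = np.asarray(starts, dtype=np.int64)
        self.ids = list(ids)
        self.set_labels = set_labels
        self.prefixes = prefixes
        if len(self.ids) != self.seqs.shape[0] or self.starts.shape[0] != self.seqs.shape[0]:
            raise ValueError("inconsistent pool component lengths")

    @classmethod
    def from_sequences(
        cls,
        seqs: Sequence[str],
        ids: Sequence[str] | None = None,
        starts: Sequence[int] | None = None,
        set_labels: Sequence[str] | None = None,
    ) -> "ProbePool":
        lens = {len(s) for s in seqs}
        if len(lens) != 1:
            raise ValueError("all probe sequences must share one length")
        mat = np.stack([encode(s) for s in seqs])
        n = mat.shape[0]
        ids = list(ids) if ids is not None else [f"probe_{i:06d}" for i in range(n)]
        starts = np.asarray(starts if starts is not None else [-1] * n)
        labels = np.asarray(list(set_labels), dtype="<U1") if set_labels is not None else None
        return cls(mat, starts, ids, labels)

    def __len__(self) -> int:
        return self.seqs.shape[0]

    def variable_seq(self, i: int) -> str:
        return decode(self.seqs[i])

    def rna_seq(self, i: int) -> str | None:
        if self.prefixes is None:
            return None
        return self.prefixes[i] + decode(self.seqs[i], rna=True)

    def record(self, i: int) -> ProbeRecord:
        label = None if self.set_labels is None else str(self.set_labels[i])
        return ProbeRecord(
            probe_id=self.ids[i],
            set_label=label,
            start=int(self.starts[i]),
            variable_seq=self.variable_seq(i),
            rna_seq=self.rna_seq(i),
        )

    def __iter__(self) -> Iterator[ProbeRecord]:
        return (self.record(i) for i in range(len(self)))

    def records(self) -> list[ProbeRecord]:
        return list(self)

    def scope_mask(self, scope: str) -> np.ndarray:
        if scope == "pool":
            return np.ones(len(self), dtype=bool)
        if scope in ("setA", "setB"):
            if self.set_labels is None:
                raise ValueError("set labels not assigned yet")
            return self.set_labels == scope[-1]
        raise ValueError(f"unknown scope {scope!r}")

    def sequences_by_id(self) -> dict[str, str]:
        return {self.ids[i]: self.variable_seq(i) for i in range(len(self))}


@dataclass
class DesignResult:
    pool: ProbePool
    reports: list[KmerCoverageReport]
    repair_log: list[tuple[str, int, str, str]]
    n_patched: int = 0

    def __iter__(self):  # allows `pool, reports = design_pool(spec)` style use
        return iter((self.pool, self.reports))

    @property
    def passed(self) -> bool:
        return all(r.passed for r in self.reports)


# ---------------------------------------------------------------------------
# de Bruijn backbone


def generate_de_bruijn(order: int, alphabet: str = DNA_ALPHABET) -> str:
    """Lexicographically least de Bruijn sequence of the given order, linearized.

    Uses the classic Lyndon-word (FKM) concatenation, so the result is unique
    and deterministic. The cyclic sequence of length ``|alphabet|**order`` is
    returned with its first ``order - 1`` letters appended, so every window of
    ``order`` letters in the linear string corresponds to one cyclic word.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    letters = list(alphabet)
    if not letters or len(set(letters)) != len(letters):
        raise ValueError("alphabet must be non-empty with distinct letters")
    k = len(letters)
    a = [0] * (k * order)
    out: list[int] = []

    def db(t: int, p: int) -> None:
        if t > order:
            if order % p == 0:
                out.extend(a[1 : p + 1])
        else:
            a[t] = a[t - p]
            db(t + 1, p)
            for j in range(a[t - p] + 1, k):
                a[t] = j
                db(t + 1, t)

    db(1, 1)
    lut = np.frombuffer("".join(letters).encode("ascii"), dtype=np.uint8)
    cyc = lut[np.asarray(out, dtype=np.intp)].tobytes().decode("ascii")
    return cyc + cyc[: order - 1]


# ---------------------------------------------------------------------------
# tiling


def tiling_starts(seq_len: int, spec: PoolDesignSpec) -> np.ndarray:
    """Deterministic window starts: first at 0, last flush with the sequence
    end, steps taking two adjacent integer values spread evenly
    (error-accumulator schedule)."""
    w, n = spec.variable_length, spec.probe_count
    if seq_len < w:
        raise PoolDesignError("sequence shorter than the variable length")
    if n == 1:
        return np.zeros(1, dtype=np.int64)
    total = seq_len - w
    if total < n - 1:
        raise PoolDesignError(
            f"{n} distinct windows of {w} nt cannot tile a {seq_len} nt sequence"
        )
    i = np.arange(n, dtype=np.int64)
    starts = (i * total) // (n - 1)
    max_step = int(np.max(np.diff(starts)))
    if w - max_step < spec.min_window_overlap:
        raise PoolDesignError(
            f"step {max_step} leaves overlap < {spec.min_window_overlap} nt; "
            "infeasible (probe_count, variable_length, sequence length)"
        )
    return starts


def tile_probes(sequence: str, spec: PoolDesignSpec) -> ProbePool:
    """Cut ``probe_count`` windows of ``variable_length`` nt out of the
    linearized backbone, overlapping enough that every audit k-mer occurrence
    of the backbone lies wholly inside at least one window."""
    codes = encode(sequence)
    starts = tiling_starts(len(codes), spec)
    windows = codes[starts[:, None] + np.arange(spec.variable_length)]
    ids = [f"probe_{i:06d}" for i in range(len(starts))]
    return ProbePool(windows, starts, ids)


# ---------------------------------------------------------------------------
# forbidden-site excision


def _find_forbidden(row: np.ndarray, fb_codes: set[int], flen: int) -> int:
    if row.shape[0] < flen:
        return -1
    codes = rolling_codes(row, flen)
    for pos, c in enumerate(codes):
        if int(c) in fb_codes:
            return pos
    return -1


def excise_forbidden(
    pool: ProbePool, spec: PoolDesignSpec
) -> tuple[ProbePool, list[tuple[str, int, str, str]]]:
    """Remove every occurrence of a forbidden 7-mer from every variable region.

    Repairs substitute the center base (position 4 of 7) of each occurrence,
    choosing among the three alternatives the one that (a) creates no new
    forbidden 7-mer within the +/-6 nt neighbourhood and (b) destroys the
    fewest distinct audit k-mers whose pool-wide count sits at or below the
    coverage floor; ties break by alphabet order. If no single substitution
    works, a two-base repair within the occurrence is attempted. The returned
    log records every (probe_id, position, old_base, new_base).
    """
    seqs = pool.seqs.copy()
    n, L = seqs.shape
    flen = 7
    fb_codes = {kmer_to_code(f) for f in spec.forbidden_kmers}
    if not fb_codes or L < flen:
        return ProbePool(seqs, pool.starts, pool.ids, pool.set_labels, pool.prefixes), []

    all7 = rolling_codes(seqs, flen)
    hit_rows = np.unique(np.nonzero(np.isin(all7, list(fb_codes)))[0])
    log: list[tuple[str, int, str, str]] = []

    for r in hit_rows:
        row = seqs[r]
        guard = 0
        while True:
            pos = _find_forbidden(row, fb_codes, flen)
            if pos < 0:
                break
            guard += 1
            if guard > 4 * L:
                raise PoolDesignError(f"repair loop did not converge on probe {pool.ids[r]}")
            _repair_occurrence(row, pos, flen, fb_codes, log, pool.ids[r])

    out = ProbePool(seqs, pool.starts, pool.ids, pool.set_labels, pool.prefixes)
    return out, log


def _creates_forbidden(row: np.ndarray, fb_codes: set[int], flen: int, center: int) -> bool:
    L = row.shape[0]
    lo = max(0, center - flen + 1)
    hi = min(L - flen, center)
    if hi < lo:
        return False
    seg = rolling_codes(row[lo : hi + flen], flen)
    return bool(np.isin(seg, list(fb_codes)).any())


def _repair_occurrence(
    row: np.ndarray,
    pos: int,
    flen: int,
    fb_codes: set[int],
    log: list,
    probe_id: str,
) -> None:
    L = row.shape[0]
    center = pos + flen // 2
    old = int(row[center])

    def apply(mutations: list[tuple[int, int]]) -> None:
        for c, b in mutations:
            log.append((probe_id, int(c), DNA_ALPHABET[int(row[c])], DNA_ALPHABET[b]))
            row[c] = b

    # The set of k-mers destroyed by a center substitution is the same for
    # every substitute base (it is fixed by the position), so candidates are
    # equivalent on that score and the tie-break is alphabet order: the first
    # base that creates no new forbidden 7-mer wins. Any residual coverage
    # deficit is restored afterwards by the patch stage.
    for b in range(4):
        if b == old:
            continue
        trial = row.copy()
        trial[center] = b
        if not _creates_forbidden(trial, fb_codes, flen, center):
            apply([(center, b)])
            return

    # two-base fallback: mutate the center together with one other position
    # of the occurrence
    for c2 in range(pos, pos + flen):
        if c2 == center or c2 >= L:
            continue
        for b1 in range(4):
            if b1 == old:
                continue
            for b2 in range(4):
                if b2 == int(row[c2]):
                    continue
                trial = row.copy()
                trial[center] = b1
                trial[c2] = b2
                if not _creates_forbidden(trial, fb_codes, flen, center) and not _creates_forbidden(
                    trial, fb_codes, flen, c2
                ):
                    apply([(center, b1), (c2, b2)])
                    return
    raise PoolDesignError(f"no two-base repair removes forbidden 7-mer in probe {probe_id}")


# ---------------------------------------------------------------------------
# set split and initiation prefix


def assign_sets(pool: ProbePool) -> ProbePool:
    """Alternate probes between set A (even index) and set B (odd index)."""
    n = len(pool)
    labels = np.where(np.arange(n) % 2 == 0, "A", "B").astype("<U1")
    return ProbePool(pool.seqs, pool.starts, pool.ids, labels, pool.prefixes)


def forbidden_junction_prefixes(
    trinucleotide: str, forbidden_kmers: Iterable[str]
) -> set[str]:
    """Variable-region 6-prefixes that would complete a forbidden 7-mer across
    the initiation-trinucleotide junction (in DNA space)."""
    flen = 7
    bad: set[str] = set()
    for prefix6 in map("".join, itertools.product(DNA_ALPHABET, repeat=flen - 1)):
        junction = trinucleotide + prefix6
        if any(junction[s : s + flen] in set(forbidden_kmers) for s in range(len(trinucleotide))):
            bad.add(prefix6)
    return bad


def add_initiation_prefix(
    pool: ProbePool, spec: PoolDesignSpec
) -> tuple[ProbePool, list[tuple[str, str]]]:
    """Prepend the phi2.5 T7 initiation trinucleotide (first allowed choice,
    falling back to the next when the DNA-space junction would recreate a
    forbidden 7-mer) and transcribe to RNA. Length never exceeds
    ``max_rna_length``."""
    if 3 + spec.variable_length > spec.max_rna_length:
        raise PoolDesignError("prefix would exceed max_rna_length")
    n, L = pool.seqs.shape
    flen = 7
    plen = min(flen - 1, L)
    unsafe = [
        {s[:plen] for s in forbidden_junction_prefixes(tri, spec.forbidden_kmers)}
        for tri in spec.init_trinucleotides
    ]
    head = ["".join(decode(pool.seqs[i, :plen])) for i in range(n)]

    prefixes: list[str] = []
    events: list[tuple[str, str]] = []
    seqs = pool.seqs
    for i in range(n):
        chosen = None
        for tri, bad in zip(spec.init_trinucleotides, unsafe):
            if head[i] not in bad:
                chosen = tri
                break
        if chosen is None:
            # mutate the first variable base until some trinucleotide is safe
            if seqs is pool.seqs:
                seqs = pool.seqs.copy()
            fixed = False
            for b in range(4):
                trial_head = DNA_ALPHABET[b] + head[i][1:]
                for tri, bad in zip(spec.init_trinucleotides, unsafe):
                    if trial_head not in bad:
                        seqs[i, 0] = b
                        chosen = tri
                        events.append((pool.ids[i], f"junction base mutated to {DNA_ALPHABET[b]}"))
                        fixed = True
                        break
                if fixed:
                    break
            if not fixed:
                raise PoolDesignError(f"no safe initiation junction for probe {pool.ids[i]}")
        if chosen != spec.init_trinucleotides[0]:
            events.append((pool.ids[i], f"initiation trinucleotide {chosen}"))
        prefixes.append(chosen)
    return ProbePool(seqs, pool.starts, pool.ids, pool.set_labels, prefixes), events


# ---------------------------------------------------------------------------
# coverage audits


def expand_forbidden_kmers(forbidden_kmers: Iterable[str], k: int) -> list[str]:
    """All k-mers containing any forbidden 7-mer as a substring.

    These are inadmissible in an excised pool (no probe may contain them), so
    coverage floors are audited over their complement.
    """
    out: set[str] = set()
    for f in forbidden_kmers:
        if len(f) > k:
            continue
        pad = k - len(f)
        for off in range(pad + 1):
            for left in map("".join, itertools.product(DNA_ALPHABET, repeat=off)):
                for right in map("".join, itertools.product(DNA_ALPHABET, repeat=pad - off)):
                    out.add(left + f + right)
    return sorted(out)


def verify_coverage(
    pool: ProbePool,
    k: int,
    scope: str = "pool",
    threshold: int = 1,
    excluded: Iterable[str] = (),
    max_argmin: int = 50,
) -> KmerCoverageReport:
    """Exhaustive k-mer multiplicity audit over the variable regions in scope.

    Counts every k-mer occurrence (with multiplicity, DNA space, strands as
    written) across the selected probes and reports the minimum over all 4^k
    k-mers not in ``excluded``.
    """
    if len(pool) == 0:
        raise ValueError("empty pool")
    L = pool.seqs.shape[1]
    if not (1 <= k <= L):
        raise ValueError(f"k={k} exceeds the variable length {L}")
    excluded = list(excluded)
    if any(len(e) != k for e in excluded):
        raise ValueError("excluded k-mers must have length k")
    mask = pool.scope_mask(scope)
    counts = count_kmers(pool.seqs[mask], k)
    keep = np.ones(counts.shape[0], dtype=bool)
    for e in excluded:
        keep[kmer_to_code(e)] = False
    min_count = int(counts[keep].min())
    argmin = np.nonzero(keep & (counts == min_count))[0][:max_argmin]
    return KmerCoverageReport(
        k=k,
        scope=scope,
        threshold=threshold,
        min_count=min_count,
        argmin_kmers=[code_to_kmer(int(c), k) for c in argmin],
        excluded_kmers=sorted(excluded),
        total_kmers_counted=int(counts[keep].sum()),
        passed=min_count >= threshold,
    )


# ---------------------------------------------------------------------------
# coverage patching (post-excision restoration of the pool-wide floor)


def _pack_patch_probes(
    needed: dict[int, int], k: int, L: int, fb_codes: set[int]
) -> list[np.ndarray]:
    """Pack deficient k-mers (with copy counts) into clean L-nt probe bodies."""
    slots: list[str] = []
    for code in sorted(needed):
        slots.extend([code_to_kmer(code, k)] * needed[code])

    def clean(s: str) -> bool:
        return _find_forbidden(encode(s), fb_codes, 7) < 0

    def pad(body: str) -> str:
        # grow base by base, taking the first letter that stays clean
        while len(body) < L:
            for b in DNA_ALPHABET:
                if clean(body + b):
                    body += b
                    break
            else:
                raise PoolDesignError(f"cannot pad patch probe {body!r}")
        return body

    probes: list[np.ndarray] = []
    cur = ""
    for km in slots:
        placed = False
        for sep in ("",) + tuple(DNA_ALPHABET):
            cand = cur + sep + km if cur else km
            if len(cand) <= L and clean(cand):
                cur = cand
                placed = True
                break
        if not placed:
            probes.append(encode(pad(cur)))
            if not clean(km):
                raise PoolDesignError(f"deficient k-mer {km} is itself forbidden")
            cur = km
    if cur:
        probes.append(encode(pad(cur)))
    return probes


def _patch_coverage(
    pool: ProbePool,
    spec: PoolDesignSpec,
    excluded9_codes: np.ndarray,
    raise_on_budget: bool,
) -> tuple[ProbePool, int]:
    """Restore coverage floors by overwriting expendable windows in place.

    Runs after the set split so per-set 7-mer deficits can be repaired in the
    right half-pool. A window is expendable when every audit k-mer it carries
    keeps a count strictly above its floor without it; such windows (taken
    from the tail of the pool) are rewritten into synthetic patch probes
    carrying the deficient k-mers, preserving probe_count and the A/B
    alternation. With ``raise_on_budget`` false an over-budget deficit is
    left for the audits to report honestly.
    """
    kq, thr9 = spec.pool_audit_k, spec.min_9mer_count
    ks, thr7 = spec.set_audit_k, spec.min_7mer_per_set
    n, L = pool.seqs.shape
    if L < kq or pool.set_labels is None:
        return pool, 0

    counts9 = count_kmers(pool.seqs, kq).astype(np.int64)
    adm9 = np.ones(counts9.shape[0], dtype=bool)
    if excluded9_codes.size:
        adm9[excluded9_codes] = False
    fb7 = np.asarray(sorted(kmer_to_code(f) for f in spec.forbidden_kmers), dtype=np.int64)
    adm7 = np.ones(4**ks, dtype=bool)
    if ks == 7 and fb7.size:
        adm7[fb7] = False
    set_counts7 = {}
    for lab in "AB":
        mask = pool.set_labels == lab
        set_counts7[lab] = (
            count_kmers(pool.seqs[mask], ks).astype(np.int64)
            if mask.any()
            else np.zeros(4**ks, dtype=np.int64)
        )

    need9 = {
        int(c): int(thr9 - counts9[c]) for c in np.nonzero(adm9 & (counts9 < thr9))[0]
    }
    need7 = {
        lab: {
            int(c): int(thr7 - set_counts7[lab][c])
            for c in np.nonzero(adm7 & (set_counts7[lab] < thr7))[0]
        }
        for lab in "AB"
    }
    if not need9 and not any(need7.values()):
        return pool, 0

    fb_codes = {int(c) for c in fb7}
    jobs: list[tuple[str | None, np.ndarray]] = []  # (required set label, body)
    for body in _pack_patch_probes(need9, kq, L, fb_codes):
        jobs.append((None, body))
    for lab in "AB":
        for body in _pack_patch_probes(need7[lab], ks, L, fb_codes):
            jobs.append((lab, body))

    budget = max(1, int(spec.patch_budget_frac * spec.probe_count))
    if len(jobs) > budget:
        if raise_on_budget:
            raise PoolDesignError(
                f"patch budget exceeded ({len(jobs)} > {budget}); deficient k-mers: "
                f"{[code_to_kmer(c, kq) for c in list(need9)[:10]]} "
                f"{[code_to_kmer(c, ks) for lab in 'AB' for c in list(need7[lab])[:10]]}"
            )
        return pool, 0

    seqs = pool.seqs.copy()
    ids = list(pool.ids)
    starts = pool.starts.copy()
    row9 = rolling_codes(seqs, kq)
    row7 = rolling_codes(seqs, ks)
    patched = 0
    pending = list(jobs)
    for i in range(n - 1, -1, -1):
        if not pending:
            break
        lab = str(pool.set_labels[i])
        j = next(
            (jj for jj, (want, _) in enumerate(pending) if want is None or want == lab), None
        )
        if j is None:
            continue
        if not (
            np.all(counts9[row9[i]] >= thr9 + 1)
            and np.all(set_counts7[lab][row7[i]] >= thr7 + 1)
        ):
            continue
        _, body = pending.pop(j)
        np.subtract.at(counts9, row9[i], 1)
        np.subtract.at(set_counts7[lab], row7[i], 1)
        seqs[i] = body
        np.add.at(counts9, rolling_codes(body, kq), 1)
        np.add.at(set_counts7[lab], rolling_codes(body, ks), 1)
        ids[i] = f"patch_{patched:04d}"
        starts[i] = -1
        patched += 1
    if pending:
        if raise_on_budget:
            raise PoolDesignError("not enough expendable windows for coverage patching")
        return pool, 0
    return ProbePool(seqs, starts, ids, pool.set_labels, pool.prefixes), patched


# ---------------------------------------------------------------------------
# full pipeline


def design_pool(spec: PoolDesignSpec = PoolDesignSpec()) -> DesignResult:
    """Generate, tile, excise, patch, split, prefix and audit the probe pool.

    Audits report honestly (``passed`` flags) rather than raising: a spec that
    is combinatorially unable to meet a floor (e.g. a single short probe)
    yields a failing report. Errors are reserved for impossible repairs or an
    exhausted patch budget when the pre-excision pool did satisfy the floor.
    """
    backbone = generate_de_bruijn(spec.order, spec.alphabet)
    pool = tile_probes(backbone, spec)

    kq = spec.pool_audit_k
    excluded_pool_audit = expand_forbidden_kmers(spec.forbidden_kmers, kq)
    excluded_codes = np.asarray([kmer_to_code(e) for e in excluded_pool_audit], dtype=np.int64)
    pre_counts = count_kmers(pool.seqs, kq)
    admissible = np.ones(pre_counts.shape[0], dtype=bool)
    if excluded_codes.size:
        admissible[excluded_codes] = False
    pre_floor_met = bool(pre_counts[admissible].min() >= spec.min_9mer_count)

    pool, repair_log = excise_forbidden(pool, spec)
    pool = assign_sets(pool)
    pool, n_patched = _patch_coverage(pool, spec, excluded_codes, raise_on_budget=pre_floor_met)
    pool, prefix_log = add_initiation_prefix(pool, spec)
    repair_log = repair_log + [(pid, -1, "", msg) for pid, msg in prefix_log]

    excluded_set_audit = expand_forbidden_kmers(spec.forbidden_kmers, spec.set_audit_k)
    reports = [
        verify_coverage(pool, kq, "pool", spec.min_9mer_count, excluded_pool_audit),
        verify_coverage(pool, spec.set_audit_k, "setA", spec.min_7mer_per_set, excluded_set_audit),
        verify_coverage(pool, spec.set_audit_k, "setB", spec.min_7mer_per_set, excluded_set_audit),
    ]
    return DesignResult(pool=pool, reports=reports, repair_log=repair_log, n_patched=n_patched)


# ---------------------------------------------------------------------------
# optional structure screen


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes)[::-1]


def screen_hairpins(pool: ProbePool, min_stem: int = 8, min_loop: int = 3) -> list[str]:
    """Flag probes whose variable region can fold a perfect hairpin with a
    stem of at least ``min_stem`` bp (disabled by default in the design
    pipeline; the published pool's structure minimization is not reproduced)."""
    flagged = []
    for i in range(len(pool)):
        row = pool.seqs[i]
        L = row.shape[0]
        found = False
        for a in range(L - 2 * min_stem - min_loop + 1):
            stem = row[a : a + min_stem]
            rc = _revcomp_codes(stem)
            for b in range(a + min_stem + min_loop, L - min_stem + 1):
                if np.array_equal(row[b : b + min_stem], rc):
                    found = True
                    break
            if found:
                break
        if found:
            flagged.append(pool.ids[i])
    return flagged
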