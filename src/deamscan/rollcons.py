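"""Fold tandem-repeat (rolling-circle) reads into error-corrected consensi.

A rolling-circle read is a concatemer of one circularised genomic fragment,
so positions ``i`` and ``i + p`` (``p`` the fragment length, or *period*)
are independent observations of the same template base.  The caller here:

1. drops reads whose mean Phred quality is below a threshold and masks
   individual low-quality bases (the fastp-style Q<20 rule);
2. detects the period as the self-offset in the configured range that
   minimises the mismatch fraction of the read against itself;
3. folds the read modulo the period and calls, per template position, the
   plurality base among unmasked observations — ties are broken by total
   Phred score, and positions that remain tied or have fewer than
   ``min_copies`` observations are called ``N``.

Consensus calling never looks at the reference genome; error suppression
comes purely from intra-read redundancy.

Single-read functions (:func:`qc_filter`, :func:`detect_period`,
:func:`fold_consensus`) are the reference implementation;
:func:`consensus_batch` is an equivalent vectorised path for large
simulations and is tested for exact agreement with the single-read path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, MalformedInputError
from .seqs import N_CODE, decode, encode


@dataclass(frozen=True)
class QCParams:
    """Quality-control and consensus-calling thresholds.

    min_mean_quality
        Reads with mean Phred below this are dropped (default 20).
    quality_mask_threshold
        Individual bases below this Phred are masked — excluded from period
        detection and voting — but the read is kept (default 20).
    min_copies
        Minimum unmasked observations per template position for a call;
        applies per position, so trailing partial copies still vote.
    max_period_mismatch
        Maximum self-mismatch fraction for a period to be accepted.
    period_range
        Inclusive fragment-length range to search (default 90-120 bp).
    min_overlap
        Minimum number of comparable base pairs for a candidate period.
    """

    min_mean_quality: float = 20.0
    quality_mask_threshold: int = 20
    min_copies: int = 2
    max_period_mismatch: float = 0.1
    period_range: tuple = (90, 120)
    min_overlap: int = 25

    def __post_init__(self):
        if self.min_mean_quality < 0 or self.quality_mask_threshold < 0:
            raise InvalidArgumentError("quality thresholds must be nonnegative")
        if self.min_copies < 1:
            raise InvalidArgumentError("min_copies must be >= 1")
        if self.period_range[0] < 1 or self.period_range[0] > self.period_range[1]:
            raise InvalidArgumentError("invalid period_range")


@dataclass
class QCResult:
    kept: bool
    reason: str  # "ok" or "low_mean_quality"
    mask: np.ndarray  # True where the base is excluded from voting


@dataclass
class ConsensusRead:
    """An error-corrected fragment consensus.

    ``support[i]`` is the number of unmasked observations that voted at
    template position ``i``; ``copies_used`` counts (possibly partial)
    tandem copies in the source read.
    """

    read_id: str
    sequence: str
    support: np.ndarray
    copies_used: int
    period: int

    def quality_string(self) -> str:
        """Phred+33 string encoding the support count, capped at Q40."""
        return "".join(chr(33 + min(int(s), 40)) for s in self.support)


def _as_qual_array(qualities) -> np.ndarray:
    if isinstance(qualities, str):
        return np.frombuffer(qualities.encode("ascii"), dtype=np.uint8) - 33
    return np.asarray(qualities)


def qc_filter(read: str, qualities, params: QCParams = QCParams()) -> QCResult:
    """Apply the mean-quality read filter and per-base quality mask."""
    q = _as_qual_array(qualities)
    if len(read) != q.size:
        raise MalformedInputError("read and qualities differ in length")
    if q.size and q.mean() < params.min_mean_quality:
        return QCResult(False, "low_mean_quality", np.zeros(q.size, dtype=bool))
    return QCResult(True, "ok", q < params.quality_mask_threshold)


def detect_period(read, params: QCParams = QCParams(), mask=None) -> int | None:
    """Self-offset period detection; returns the period or None (abstain).

    Scans periods in ``params.period_range`` and returns the one minimising
    the mismatch fraction between the read and itself shifted by the period
    (masked positions excluded from both numerator and denominator),
    provided the fraction is at most ``max_period_mismatch`` and at least
    ``min_overlap`` base pairs were comparable.  Ties go to the smaller
    period.  Abstention is a value, not an error.
    """
    x = encode(read) if isinstance(read, str) else np.asarray(read)
    L = x.size
    ok = x != N_CODE
    if mask is not None:
        ok &= ~np.asarray(mask, dtype=bool)
    best_p, best_mm = None, None
    for p in range(params.period_range[0], params.period_range[1] + 1):
        if L - p < params.min_overlap:
            break
        valid = ok[:-p] & ok[p:]
        n = int(valid.sum())
        if n < params.min_overlap:
            continue
        mm = int(((x[:-p] != x[p:]) & valid).sum()) / n
        if best_mm is None or mm < best_mm:
            best_p, best_mm = p, mm
    if best_mm is not None and best_mm <= params.max_period_mismatch:
        return best_p
    return None


def fold_consensus(read, qualities, period: int,
                   params: QCParams = QCParams(), mask=None,
                   read_id: str = "consensus") -> ConsensusRead:
    """Fold a tandem read modulo ``period`` and call the per-position consensus.

    Unmasked observations in each residue class (position mod period) vote;
    the plurality base wins, count ties are broken by summed Phred quality,
    and positions that stay tied or have fewer than ``min_copies``
    observations are called ``N``.
    """
    x = encode(read) if isinstance(read, str) else np.asarray(read)
    q = _as_qual_array(qualities)
    if x.size != q.size:
        raise MalformedInputError("read and qualities differ in length")
    if period >= x.size:
        raise InvalidArgumentError("period must be shorter than the read")
    usable = x != N_CODE
    if mask is not None:
        usable &= ~np.asarray(mask, dtype=bool)
    cons = np.full(period, N_CODE, dtype=np.uint8)
    support = np.zeros(period, dtype=np.int64)
    for j in range(period):
        obs = x[j::period]
        use = usable[j::period]
        qs = q[j::period]
        counts = np.zeros(4, dtype=np.int64)
        qsum = np.zeros(4, dtype=np.int64)
        for b, qv in zip(obs[use], qs[use]):
            counts[b] += 1
            qsum[b] += int(qv)
        n = int(counts.sum())
        support[j] = n
        if n < params.min_copies or n == 0:
            continue
        top = counts.max()
        tied = np.flatnonzero(counts == top)
        if tied.size == 1:
            cons[j] = tied[0]
        else:
            qt = qsum[tied]
            qbest = np.flatnonzero(qt == qt.max())
            if qbest.size == 1:
                cons[j] = tied[qbest[0]]
            # else: stays N (conservative abstention)
    copies = int(np.ceil(x.size / period))
    return ConsensusRead(read_id, decode(cons), support, copies, period)


@dataclass
class ConsensusGroup:
    """All consensi of one period, as a dense matrix (N encoded as 255)."""

    period: int
    read_indices: np.ndarray  # indices into the input read order
    seqs: np.ndarray          # (m, period) uint8
    support: np.ndarray       # (m, period) int16


@dataclass
class ConsensusSet:
    """Batch consensus output grouped by period, plus per-read status."""

    read_ids: list
    groups: dict = field(default_factory=dict)  # period -> ConsensusGroup
    status: np.ndarray | None = None            # per input read: "ok"/reason
    copies_used: np.ndarray | None = None       # per input read (0 if not called)

    def __len__(self) -> int:
        return sum(g.read_indices.size for g in self.groups.values())

    def iter_consensus(self):
        for p in sorted(self.groups):
            g = self.groups[p]
            for row, ridx in enumerate(g.read_indices):
                cu = int(self.copies_used[ridx]) if self.copies_used is not None else 0
                yield ConsensusRead(self.read_ids[ridx], decode(g.seqs[row]),
                                    g.support[row].astype(np.int64), cu, p)

    def to_fastq(self, path) -> None:
        with open(path, "w") as fh:
            for c in self.iter_consensus():
                fh.write(f"@{c.read_id}\n{c.sequence}\n+\n{c.quality_string()}\n")


def _batch_fold(seqmat: np.ndarray, qualmat: np.ndarray, maskmat: np.ndarray,
                period: int, params: QCParams) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised plurality vote for a matrix of same-period reads."""
    m, L = seqmat.shape
    counts = np.zeros((m, period, 4), dtype=np.int16)
    qsum = np.zeros((m, period, 4), dtype=np.int32)
    for j in range(period):
        cols = np.arange(j, L, period)
        sub = seqmat[:, cols]
        use = ~maskmat[:, cols]
        qs = qualmat[:, cols].astype(np.int32)
        for b in range(4):
            hit = (sub == b) & use
            counts[:, j, b] = hit.sum(axis=1)
            qsum[:, j, b] = (qs * hit).sum(axis=1)
    support = counts.sum(axis=2)
    top = counts.max(axis=2)
    is_top = counts == top[:, :, None]
    n_top = is_top.sum(axis=2)
    q_masked = np.where(is_top, qsum, -1)
    q_top = q_masked.max(axis=2)
    n_q_top = (q_masked == q_top[:, :, None]).sum(axis=2)
    winner = q_masked.argmax(axis=2).astype(np.uint8)
    cons = np.where(
        (support >= params.min_copies) & ((n_top == 1) | (n_q_top == 1)),
        winner, np.uint8(N_CODE)).astype(np.uint8)
    return cons, support


def consensus_batch(reads, params: QCParams = QCParams(),
                    per_read_report: bool = False):
    """Run qc_filter -> detect_period -> fold_consensus over a read batch.

    ``reads`` may be a :class:`~deamscan.syndata.ReadSet`, a FASTQ path, or
    an iterable of ``(read_id, sequence, phred33_quality)`` tuples.  Returns
    ``(ConsensusSet, report)`` where the report carries kept/dropped/
    abstained counts and the mean number of copies used; with
    ``per_read_report=True`` it also carries a per-read table.  The whole
    path is deterministic for a fixed input.
    """
    ids, seqmat, qualmat = _normalise_reads(reads)
    n = len(ids)
    status = np.array(["ok"] * n, dtype=object)
    cset = ConsensusSet(read_ids=ids, status=status)
    n_masked = np.zeros(n, dtype=np.int64)
    periods = np.zeros(n, dtype=np.int64)
    copies = np.zeros(n, dtype=float)

    for L, rows in _rows_by_length(seqmat):
        sm = np.stack([seqmat[i] for i in rows])
        qm = np.stack([qualmat[i] for i in rows])
        mask = qm < params.quality_mask_threshold
        mask |= sm == N_CODE
        mean_q = qm.mean(axis=1) if L else np.zeros(len(rows))
        dropped = mean_q < params.min_mean_quality
        status[rows[dropped]] = "low_mean_quality"
        n_masked[rows] = (qm < params.quality_mask_threshold).sum(axis=1)

        live = rows[~dropped]
        if live.size == 0:
            continue
        smv = sm[~dropped]
        qmv = qm[~dropped]
        mkv = mask[~dropped]
        pvec = _batch_detect_period(smv, mkv, params)
        abstain = pvec < 0
        status[live[abstain]] = "no_period"
        for p in np.unique(pvec[pvec >= 0]):
            sel = pvec == p
            cons, supp = _batch_fold(smv[sel], qmv[sel], mkv[sel], int(p), params)
            gidx = live[sel]
            periods[gidx] = p
            copies[gidx] = np.ceil(L / p)
            if int(p) in cset.groups:
                g = cset.groups[int(p)]
                cset.groups[int(p)] = ConsensusGroup(
                    int(p),
                    np.concatenate([g.read_indices, gidx]),
                    np.vstack([g.seqs, cons]),
                    np.vstack([g.support, supp]))
            else:
                cset.groups[int(p)] = ConsensusGroup(int(p), gidx, cons,
                                                     supp.astype(np.int16))

    cset.copies_used = copies
    ok = status == "ok"
    report = {
        "n_reads": n,
        "n_kept": int(ok.sum()),
        "n_dropped_low_quality": int((status == "low_mean_quality").sum()),
        "n_abstained_no_period": int((status == "no_period").sum()),
        "mean_copies_used": float(copies[ok].mean()) if ok.any() else 0.0,
    }
    if per_read_report:
        report["per_read"] = pd.DataFrame({
            "read_id": ids,
            "status": status,
            "period": np.where(ok, periods, 0),
            "copies_used": np.where(ok, copies, 0),
            "n_masked": n_masked,
        })
    return cset, report


def _batch_detect_period(seqmat: np.ndarray, maskmat: np.ndarray,
                         params: QCParams) -> np.ndarray:
    """Vectorised period detection; -1 encodes abstention."""
    m, L = seqmat.shape
    best_mm = np.full(m, np.inf)
    best_p = np.full(m, -1, dtype=np.int64)
    ok = ~maskmat
    for p in range(params.period_range[0], params.period_range[1] + 1):
        if L - p < params.min_overlap:
            break
        valid = ok[:, :-p] & ok[:, p:]
        n = valid.sum(axis=1)
        mm_count = ((seqmat[:, :-p] != seqmat[:, p:]) & valid).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            mm = np.where(n > 0, mm_count / np.maximum(n, 1), np.inf)
        mm = np.where(n >= params.min_overlap, mm, np.inf)
        better = mm < best_mm  # strict: ties keep the smaller p
        best_mm[better] = mm[better]
        best_p[better] = p
    best_p[best_mm > params.max_period_mismatch] = -1
    return best_p


def _normalise_reads(reads):
    """Coerce the accepted input kinds to (ids, seq arrays, qual arrays)."""
    from .syndata import ReadSet
    if isinstance(reads, ReadSet):
        return list(reads.ids), list(reads.seqs), list(reads.quals)
    if isinstance(reads, (str,)) or hasattr(reads, "__fspath__"):
        reads = read_fastq(reads)
    ids, sm, qm = [], [], []
    for rec in reads:
        try:
            rid, s, q = rec
        except (TypeError, ValueError) as e:
            raise MalformedInputError(f"bad read record: {rec!r}") from e
        if len(s) != len(q):
            raise MalformedInputError(f"read {rid}: sequence/quality length mismatch")
        ids.append(rid)
        sm.append(encode(s))
        qm.append(_as_qual_array(q))
    return ids, sm, qm


def _rows_by_length(seq_arrays):
    lens = np.array([a.size for a in seq_arrays])
    for L in np.unique(lens):
        yield int(L), np.flatnonzero(lens == L)


def read_fastq(path):
    """Yield (id, sequence, quality string) records from a FASTQ file."""
    from Bio import SeqIO
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        yield rec.id, str(rec.seq).upper(), qual
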