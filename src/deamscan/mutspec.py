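"""Placement of consensus fragments, substitution tallying, and the
strand-collapsed mutation spectrum with 16-triplet-context rates.

The spectrum of a sample is the frequency of each of the six collapsed
substitution types: numerator = number of observed substitutions of that
type (on either strand representation), denominator = coverage-weighted
number of site-observations of the focal base pair.  For example the
C:G>T:A frequency is (#C->T + #G->A observations) / (total coverage of
C plus G sites).  Context rates assign each qualifying mutation to the
collapsed triplet of its top-strand context (a G->A inside 5'CGA3'
collapses to 5'TCG3'); by default the context
denominator is the *total* C+G (or A+T) site-observation count, identical
across the 16 rows — a per-context denominator is available as an option.

Placement is ungapped: exact-match k-mer seeding on both strands followed
by full-length comparison.  Because a rolling-circle consensus is the
circular fragment read out from an arbitrary phase, it is a *rotation* of
a genome substring; placement therefore scans the doubled consensus and
scores every rotation along the seeded diagonal, keeping the best-matching
length-p window.  Ambiguous placements (several equally good locations)
and placements above the mismatch ceiling abstain and are counted, never
silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from . import seqs
from .errors import InvalidArgumentError, InvalidDesignError
from .rollcons import ConsensusRead, ConsensusSet
from .seqs import BASES, N_CODE, SIX_TYPES, encode
from .syndata import ReferenceGenome

# type -> [(top-strand ref code, alt code), ...]
_TYPE_SUBS = {
    "C:G>T:A": [(seqs.C, seqs.T), (seqs.G, seqs.A)],
    "A:T>G:C": [(seqs.A, seqs.G), (seqs.T, seqs.C)],
    "A:T>T:A": [(seqs.A, seqs.T), (seqs.T, seqs.A)],
    "G:C>T:A": [(seqs.C, seqs.A), (seqs.G, seqs.T)],
    "A:T>C:G": [(seqs.A, seqs.C), (seqs.T, seqs.G)],
    "G:C>C:G": [(seqs.C, seqs.G), (seqs.G, seqs.C)],
}
_GC_TYPES = ("C:G>T:A", "G:C>T:A", "G:C>C:G")


class ReferenceIndex:
    """Exact-match k-mer index of a reference (forward strand).

    For circular references the sequence is virtually doubled so fragments
    spanning the origin still index and compare; reported starts stay in
    [0, L).
    """

    def __init__(self, ref: ReferenceGenome, k: int = 21, max_query_len: int = 512):
        self.ref = ref
        self.k = k
        codes = ref.codes
        self.L = codes.size
        if ref.circular:
            # doubled so k-mers spanning the origin still index; window
            # comparisons use modular indexing on `codes` directly
            ext = np.concatenate([codes, codes[:min(self.L, k)]])
        else:
            ext = codes
        self.codes = codes
        self.ext_codes = ext
        n_kmers = (self.L if ref.circular else self.L - k + 1)
        if n_kmers <= 0:
            self.kmers = {}
            return
        w = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
        windows = np.lib.stride_tricks.sliding_window_view(ext, k)[:n_kmers]
        keys = windows.astype(np.int64) @ w
        order = np.argsort(keys, kind="stable")
        sk = keys[order]
        bounds = np.flatnonzero(np.diff(sk)) + 1
        starts = np.concatenate([[0], bounds])
        ends = np.concatenate([bounds, [sk.size]])
        self.kmers = {int(sk[s]): order[s:e] for s, e in zip(starts, ends)}

    def kmer_code(self, codes: np.ndarray) -> int | None:
        """Integer key of a k-mer window, or None if it contains N."""
        if np.any(codes == N_CODE):
            return None
        w = 4 ** np.arange(self.k - 1, -1, -1, dtype=np.int64)
        return int(codes.astype(np.int64) @ w)

    def lookup(self, key: int) -> np.ndarray:
        return self.kmers.get(key, np.empty(0, dtype=np.int64))


@dataclass
class Placement:
    """An ungapped placement of a consensus on the reference top strand.

    ``mismatches`` holds (ref_pos 1-based, ref_base, obs_base) with the
    observed base already mapped to the top strand for minus placements.
    """

    consensus_id: str
    ref_start: int  # 1-based
    strand: str     # '+' or '-'
    length: int
    mismatches: list
    n_mismatch: int
    n_n: int        # abstained (N) consensus positions inside the span
    n_positions: list = field(default_factory=list)  # 0-based ref pos of Ns


@dataclass
class Abstention:
    consensus_id: str
    reason: str  # "ambiguous", "no_placement", "too_short", "reference_too_short"


def _diagonal_scores(q3: np.ndarray, base: int, p: int, idx: ReferenceIndex):
    """Score the 2p rotation windows of a tripled consensus on one diagonal.

    ``q3`` is the tripled (3p) consensus codes; the diagonal aligns
    ``q3[x]`` with reference position ``base + x``.  Window ``s`` in
    [0, 2p) compares ``q3[s:s+p]`` with reference positions
    ``base+s .. base+s+p-1``.  Any p consecutive positions of a tripled
    cyclic string cover each cyclic position exactly once, so the number of
    comparable (non-N) bases is the same for every window.  Returns the
    (2p,) mismatch-count array with invalid (out-of-genome) windows set to
    a large sentinel.
    """
    L = idx.L
    x = np.arange(3 * p)
    if idx.ref.circular:
        win = idx.codes[(base + x) % L]
        valid_g = np.ones(3 * p, dtype=bool)
    else:
        gi = base + x
        valid_g = (gi >= 0) & (gi < L)
        win = idx.codes[np.clip(gi, 0, L - 1)]
    nn = q3 == N_CODE
    v = (q3 != win) & ~nn & valid_g

    def wsum(a):
        c = np.concatenate([[0], np.cumsum(a)])
        return c[p:3 * p] - c[:2 * p]

    w_mm = wsum(v)
    w_bad = wsum(~valid_g)
    return np.where(w_bad == 0, w_mm, _BIG)


_BIG = np.iinfo(np.int32).max


def _resolve_family(cands: list, p: int):
    """Collapse a set of equally good windows into one placement, or None.

    ``cands`` holds (ref_start0, strand, rotation, q3) of all minimum-
    mismatch windows.  A circular consensus can legitimately slide by a few
    bases when the reference base just 5' of the fragment equals its last
    base; such a family (same strand, spread < p) is anchored at the
    smallest start and the boundary positions not shared by all members
    are excluded from observation.  Anything else is genuine ambiguity.
    """
    strands = {c[1] for c in cands}
    starts = sorted(c[0] for c in cands)
    if len(strands) > 1 or starts[-1] - starts[0] >= p:
        return None
    spread = starts[-1] - starts[0]
    chosen = min(cands, key=lambda c: c[0])
    return chosen, spread


def place_consensus(consensus, ref: ReferenceGenome,
                    max_mismatch_frac: float = 0.05, seed_kmer: int = 21,
                    index: ReferenceIndex | None = None):
    """Place one consensus on the reference; returns Placement or Abstention.

    A rolling-circle consensus is a rotation of the original fragment, so
    it is treated as a cyclic string: exact k-mer seeds from every rotation
    on both strands nominate diagonals, each diagonal's 2p rotation windows
    are scored ungapped, and the unique best (fewest-mismatch) window under
    the mismatch ceiling wins.  Equally good windows that are small slides
    of each other (an inherent boundary degeneracy of circular fragments)
    are merged, with the unshared boundary bases excluded from observation;
    equally good windows elsewhere abstain as ambiguous.
    """
    if isinstance(consensus, ConsensusRead):
        cid, cseq = consensus.read_id, consensus.sequence
    else:
        cid, cseq = "consensus", str(consensus)
    cs = encode(cseq)
    p = cs.size
    if int((cs != N_CODE).sum()) < seed_kmer:
        return Abstention(cid, "too_short")
    if p > len(ref):
        return Abstention(cid, "reference_too_short")
    idx = index or ReferenceIndex(ref, seed_kmer, max_query_len=p)
    if idx.k != seed_kmer:
        raise InvalidArgumentError("index k does not match seed_kmer")
    n_valid = p - int((cs == N_CODE).sum())
    windows = {}  # (ref_start0, strand) -> (n_mm, rotation, q3)
    for strand, query in (("+", cs), ("-", seqs.revcomp_codes(cs))):
        q3 = np.concatenate([query, query, query])
        seen_diag = set()
        for o in range(0, p):
            if o + seed_kmer > 2 * p:
                break
            key = idx.kmer_code(q3[o:o + seed_kmer])
            if key is None:
                continue
            for pos in idx.lookup(key):
                base = int(pos) - o - p
                if base in seen_diag:
                    continue
                seen_diag.add(base)
                w_mm = _diagonal_scores(q3, base, p, idx)
                for s in np.flatnonzero(w_mm < _BIG):
                    g = (base + int(s)) % idx.L if ref.circular else base + int(s)
                    prev = windows.get((g, strand))
                    if prev is None or w_mm[s] < prev[0]:
                        windows[(g, strand)] = (int(w_mm[s]), int(s), q3)
    viable = [(v[0], g, strand, v[1], v[2])
              for (g, strand), v in windows.items()
              if n_valid > 0 and v[0] <= max_mismatch_frac * n_valid]
    if not viable:
        return Abstention(cid, "no_placement")
    best_mm = min(v[0] for v in viable)
    best = [(g, strand, s, q3) for mm, g, strand, s, q3 in viable if mm == best_mm]
    resolved = _resolve_family(best, p) if len(best) > 1 else ((best[0]), 0)
    if resolved is None:
        return Abstention(cid, "ambiguous")
    (g, strand, s, q3), spread = resolved
    mismatches = []
    n_positions = []
    L = idx.L
    n_mm = 0
    for d in range(p):
        rp = (g + d) % L
        ob = q3[s + d]
        if ob == N_CODE or d < spread:  # N call or unshared boundary base
            n_positions.append(rp)
            continue
        rb = idx.codes[rp]
        if ob != rb:
            mismatches.append((rp + 1, BASES[rb], BASES[ob]))
            n_mm += 1
    return Placement(cid, g + 1, strand, p, mismatches, n_mm,
                     len(n_positions), n_positions)


@dataclass
class Placements:
    """A batch of accepted placements in compact array form."""

    ref: ReferenceGenome
    starts0: np.ndarray          # 0-based
    lengths: np.ndarray
    strands: np.ndarray          # '+'/'-' as +1/-1
    cons_ids: list
    mm_pos0: np.ndarray          # per mismatch: 0-based ref position
    mm_obs: np.ndarray           # observed base code on the top strand
    mm_placement: np.ndarray     # index into the placement arrays
    n_pos0: np.ndarray           # ref positions of abstained (N) consensus bases
    n_ambiguous: int = 0
    n_unplaced: int = 0

    @property
    def n_placed(self) -> int:
        return int(self.starts0.size)

    def variants_table(self) -> pd.DataFrame:
        """Variant calls as a tidy table with collapsed context annotation."""
        codes = self.ref.codes
        L = codes.size
        rows = []
        for p0, obs, pi in zip(self.mm_pos0, self.mm_obs, self.mm_placement):
            ref_b = BASES[codes[p0]]
            obs_b = BASES[obs]
            if self.ref.circular or 0 < p0 < L - 1:
                trip = "".join(BASES[codes[(p0 + d) % L]] for d in (-1, 0, 1))
                ctx = seqs.collapse_context(trip)
            else:
                ctx = ""
            rows.append((int(p0) + 1, ref_b, obs_b,
                         seqs.pair_notation(ref_b, obs_b),
                         self.cons_ids[pi],
                         "+" if self.strands[pi] > 0 else "-", ctx))
        return pd.DataFrame(rows, columns=["position", "ref", "obs", "type",
                                           "consensus_id", "strand",
                                           "triplet_context"])


def from_single_placements(results, ref: ReferenceGenome) -> Placements:
    """Pack single-read placement results into a :class:`Placements` batch."""
    starts, lens, strands, ids = [], [], [], []
    mm_pos, mm_obs, mm_pl, n_pos = [], [], [], []
    n_amb = n_un = 0
    L = len(ref)
    for r in results:
        if isinstance(r, Abstention):
            if r.reason == "ambiguous":
                n_amb += 1
            else:
                n_un += 1
            continue
        pi = len(starts)
        starts.append(r.ref_start - 1)
        lens.append(r.length)
        strands.append(1 if r.strand == "+" else -1)
        ids.append(r.consensus_id)
        for (pos1, _rb, ob) in r.mismatches:
            mm_pos.append(pos1 - 1)
            mm_obs.append(BASES.index(ob))
            mm_pl.append(pi)
        if r.n_positions:
            n_pos.extend(int(x) for x in r.n_positions)
    return Placements(ref, np.asarray(starts, dtype=np.int64),
                      np.asarray(lens, dtype=np.int64),
                      np.asarray(strands, dtype=np.int8), ids,
                      np.asarray(mm_pos, dtype=np.int64),
                      np.asarray(mm_obs, dtype=np.uint8),
                      np.asarray(mm_pl, dtype=np.int64),
                      np.asarray(n_pos, dtype=np.int64), n_amb, n_un)


def place_batch(cset: ConsensusSet, ref: ReferenceGenome,
                max_mismatch_frac: float = 0.05, seed_kmer: int = 21,
                index: ReferenceIndex | None = None) -> Placements:
    """Place a whole :class:`ConsensusSet`; vectorised with a single-read
    fallback for seeds broken by N bases, mutations, rotation boundaries,
    or repeat ambiguity."""
    idx = index or ReferenceIndex(ref, seed_kmer, max_query_len=512)
    L = idx.L
    starts_all, lens_all, strands_all, ids_all = [], [], [], []
    mm_pos_all, mm_obs_all, mm_pl_all, n_pos_all = [], [], [], []
    n_amb = n_un = 0
    n_placed_so_far = 0
    w = 4 ** np.arange(seed_kmer - 1, -1, -1, dtype=np.int64)

    for p in sorted(cset.groups):
        grp = cset.groups[p]
        m = grp.read_indices.size
        if m == 0:
            continue
        fwd = grp.seqs
        rev = np.flip(fwd, axis=1).copy()
        acgt = rev != N_CODE
        rev[acgt] = 3 - rev[acgt]
        fallback_rows = set()
        # diagonal anchor per row (reference position of q3[0]), or sentinel
        NOCAND = np.iinfo(np.int64).min
        cand_base = np.full(m, NOCAND, dtype=np.int64)
        cand_strand = np.zeros(m, dtype=np.int8)
        # up to three disjoint seed offsets within the first copy: at most
        # one can straddle the rotation boundary
        offsets = [o for o in (0, seed_kmer, 2 * seed_kmer)
                   if o + seed_kmer <= p]
        for strand, mat in ((1, fwd), (-1, rev)):
            unresolved = (cand_base == NOCAND)
            for o in offsets:
                rows = np.flatnonzero(unresolved)
                if rows.size == 0:
                    break
                seed = mat[rows, o:o + seed_kmer]
                has_n = (seed == N_CODE).any(axis=1)
                keys = seed.astype(np.int64) @ w
                for ri, i in enumerate(rows):
                    if has_n[ri]:
                        continue
                    hits = idx.lookup(int(keys[ri]))
                    if hits.size == 0:
                        continue
                    if hits.size > 1:
                        fallback_rows.add(int(i))
                        unresolved[i] = False
                        continue
                    cand_base[i] = int(hits[0]) - o - p
                    cand_strand[i] = strand
                    unresolved[i] = False
        for i in range(m):
            if cand_base[i] == NOCAND and i not in fallback_rows:
                fallback_rows.add(i)

        simple = np.array(sorted(set(np.flatnonzero(cand_base != NOCAND).tolist())
                                 - fallback_rows), dtype=np.int64)
        if simple.size:
            base = cand_base[simple]
            strv = cand_strand[simple]
            q1 = np.where(strv[:, None] > 0, fwd[simple], rev[simple])
            q3 = np.hstack([q1, q1, q1])
            n_valid = p - (q1 == N_CODE).sum(axis=1)
            x = np.arange(3 * p)
            if ref.circular:
                win = idx.codes[(base[:, None] + x[None, :]) % L]
                valid_g = np.ones_like(q3, dtype=bool)
            else:
                gi = base[:, None] + x[None, :]
                valid_g = (gi >= 0) & (gi < L)
                win = idx.codes[np.clip(gi, 0, L - 1)]
            nn = q3 == N_CODE
            v = (q3 != win) & ~nn & valid_g

            def wsum(a):
                c = np.concatenate(
                    [np.zeros((a.shape[0], 1), dtype=np.int64),
                     np.cumsum(a, axis=1)], axis=1)
                return c[:, p:3 * p] - c[:, :2 * p]

            w_mm = np.where(wsum(~valid_g) == 0, wsum(v), _BIG)
            s_min = w_mm.argmin(axis=1)
            mm_best = w_mm[np.arange(simple.size), s_min]
            s_max = (2 * p - 1) - w_mm[:, ::-1].argmin(axis=1)
            spread = s_max - s_min
            window_ok = mm_best < _BIG
            accept = (window_ok & (spread < p) & (n_valid > 0)
                      & (mm_best <= max_mismatch_frac * n_valid))
            wide = np.flatnonzero(window_ok & (spread >= p))
            fallback_rows.update(int(simple[t]) for t in wide)
            n_un += int((window_ok & ~accept).sum()) - wide.size
            n_un += int((~window_ok).sum())
            acc = np.flatnonzero(accept)
            if acc.size:
                sb = s_min[acc]
                gstart = base[acc] + sb
                gstart = gstart % L if ref.circular else gstart
                # window-aligned gather: only shared-core mismatches count,
                # Ns and unshared boundary bases are excluded
                rowsel = np.arange(q3.shape[0])[acc, None]
                colsel = sb[:, None] + np.arange(p)[None, :]
                wq = q3[rowsel, colsel]
                wwin = win[rowsel, colsel]
                excl = (wq == N_CODE) | (np.arange(p)[None, :] < spread[acc, None])
                wv = (wq != wwin) & ~excl
                for local_i in acc:
                    ids_all.append(cset.read_ids[grp.read_indices[simple[local_i]]])
                starts_all.append(gstart)
                lens_all.append(np.full(acc.size, p, dtype=np.int64))
                strands_all.append(strv[acc])
                rr, dd = np.nonzero(wv)
                mm_pos_all.append((gstart[rr] + dd) % L)
                mm_obs_all.append(wq[rr, dd])
                mm_pl_all.append(n_placed_so_far + rr.astype(np.int64))
                nr, nd = np.nonzero(excl)
                n_pos_all.append((gstart[nr] + nd) % L)
                n_placed_so_far += acc.size

        for i in sorted(fallback_rows):
            cons = ConsensusRead(cset.read_ids[grp.read_indices[i]],
                                 seqs.decode(fwd[i]), grp.support[i], 0, p)
            r = place_consensus(cons, ref, max_mismatch_frac, seed_kmer, index=idx)
            if isinstance(r, Abstention):
                if r.reason == "ambiguous":
                    n_amb += 1
                else:
                    n_un += 1
                continue
            ids_all.append(r.consensus_id)
            starts_all.append(np.array([r.ref_start - 1]))
            lens_all.append(np.array([r.length]))
            strands_all.append(np.array([1 if r.strand == "+" else -1], dtype=np.int8))
            for (pos1, _rb, ob) in r.mismatches:
                mm_pos_all.append(np.array([pos1 - 1]))
                mm_obs_all.append(np.array([BASES.index(ob)], dtype=np.uint8))
                mm_pl_all.append(np.array([n_placed_so_far]))
            if r.n_positions:
                n_pos_all.append(np.asarray(r.n_positions, dtype=np.int64))
            n_placed_so_far += 1

    def cat(parts, dtype):
        return (np.concatenate(parts).astype(dtype) if parts
                else np.empty(0, dtype=dtype))

    return Placements(ref, cat(starts_all, np.int64), cat(lens_all, np.int64),
                      cat(strands_all, np.int8), ids_all,
                      cat(mm_pos_all, np.int64), cat(mm_obs_all, np.uint8),
                      cat(mm_pl_all, np.int64), cat(n_pos_all, np.int64),
                      n_amb, n_un)


@dataclass
class SiteTally:
    """Per-reference-site coverage and top-strand base counts.

    Invariant (verified in ``validate``): at every site the base counts sum
    to the coverage.  N consensus bases are excluded from both.
    """

    coverage: np.ndarray   # (L,) int64
    counts: np.ndarray     # (L, 4) int64

    def validate(self) -> None:
        if not np.array_equal(self.counts.sum(axis=1), self.coverage):
            raise AssertionError("tally conservation violated")
        if (self.coverage < 0).any():
            raise AssertionError("negative coverage")

    def base_counts(self, position: int) -> dict:
        """Counts at a 1-based position as a base->count dict."""
        return {BASES[b]: int(self.counts[position - 1, b]) for b in range(4)}


def tally(placements: Placements, ref: ReferenceGenome) -> SiteTally:
    """Accumulate coverage and observed base counts across placements."""
    codes = ref.codes
    L = codes.size
    cov_open = np.zeros(L + 1, dtype=np.int64)
    starts = placements.starts0
    ends = starts + placements.lengths
    if ref.circular:
        wrap = ends > L
        cov_open[:L] += np.bincount(starts, minlength=L + 1)[:L]
        cov_open += np.bincount(np.minimum(ends, L), minlength=L + 1)[:L + 1] * -1
        if wrap.any():
            we = ends[wrap] - L
            cov_open[0] += int(wrap.sum())
            cov_open -= np.bincount(we, minlength=L + 1)
    else:
        cov_open[:L] += np.bincount(starts, minlength=L)[:L]
        cov_open -= np.bincount(ends, minlength=L + 1)
    cov = np.cumsum(cov_open[:L])
    counts = np.zeros((L, 4), dtype=np.int64)
    counts[np.arange(L), codes] = cov
    if placements.n_pos0.size:
        dec = np.bincount(placements.n_pos0, minlength=L)
        cov = cov - dec
        counts[np.arange(L), codes] -= dec
    if placements.mm_pos0.size:
        np.subtract.at(counts, (placements.mm_pos0, codes[placements.mm_pos0]), 1)
        np.add.at(counts, (placements.mm_pos0, placements.mm_obs), 1)
    out = SiteTally(cov, counts)
    out.validate()
    return out


@dataclass
class SpectrumResult:
    """The six collapsed substitution-type frequencies."""

    table: pd.DataFrame  # index: SIX_TYPES; columns: numerator, denominator, frequency

    def frequency(self, typ: str) -> float:
        return float(self.table.loc[typ, "frequency"])


def spectrum(t: SiteTally, ref: ReferenceGenome) -> SpectrumResult:
    """Collapsed mutation spectrum: per-type frequency per site-observation."""
    codes = ref.codes
    if codes.size != t.coverage.size:
        raise InvalidArgumentError("tally and reference lengths differ")
    cg_cov = int(t.coverage[(codes == seqs.C) | (codes == seqs.G)].sum())
    at_cov = int(t.coverage[(codes == seqs.A) | (codes == seqs.T)].sum())
    rows = []
    for typ in SIX_TYPES:
        num = sum(int(t.counts[codes == rc, ac].sum())
                  for rc, ac in _TYPE_SUBS[typ])
        den = cg_cov if typ in _GC_TYPES else at_cov
        freq = num / den if den > 0 else 0.0
        rows.append((typ, num, den, freq))
    df = pd.DataFrame(rows, columns=["type", "numerator", "denominator",
                                     "frequency"]).set_index("type")
    return SpectrumResult(df)


@dataclass
class ContextSpectrum:
    """16 collapsed triplet-context rates for each transition type."""

    tables: dict  # type -> DataFrame(index=context; numerator, denominator, rate)
    denominator_mode: str

    def table(self, typ: str) -> pd.DataFrame:
        return self.tables[typ]

    def top_context(self, typ: str) -> str:
        """Context with the highest rate (ties broken by numerator, then name)."""
        df = self.tables[typ]
        return df.sort_values(["rate", "numerator"],
                              ascending=False, kind="stable").index[0]


def context_spectrum(t: SiteTally, ref: ReferenceGenome,
                     denominator: str = "total") -> ContextSpectrum:
    """Triplet-context rates for the two transition types.

    Each qualifying mutation is assigned to the collapsed context of its
    top-strand triplet.  With ``denominator="total"`` (the default) every
    row of a table shares the total
    C+G (or A+T) site-observation count; ``denominator="per-context"``
    divides by that context's own site-observations.  Edge sites of a
    linear reference are excluded from these tables only.
    """
    if denominator not in ("total", "per-context"):
        raise InvalidArgumentError("denominator must be 'total' or 'per-context'")
    codes = ref.codes
    L = codes.size
    ctx_int = seqs.collapsed_context_ints(codes, ref.circular)
    interior = ctx_int >= 0
    tables = {}
    for typ, focal_code in (("C:G>T:A", seqs.C), ("A:T>G:C", seqs.A)):
        focal_base = BASES[focal_code]
        ctx_list = [a + focal_base + b for a in BASES for b in BASES]
        num = {c: 0 for c in ctx_list}
        for rc, ac in _TYPE_SUBS[typ]:
            sel = (codes == rc) & interior
            site_counts = t.counts[sel, ac]
            hot = site_counts > 0
            for ci, n in zip(ctx_int[sel][hot], site_counts[hot]):
                num[seqs.context_int_to_str(int(ci))] += int(n)
        if typ == "C:G>T:A":
            pair_sel = ((codes == seqs.C) | (codes == seqs.G)) & interior
        else:
            pair_sel = ((codes == seqs.A) | (codes == seqs.T)) & interior
        total_den = int(t.coverage[pair_sel].sum())
        if denominator == "total":
            den = {c: total_den for c in ctx_list}
        else:
            den = {}
            cl = ctx_int[pair_sel]
            covl = t.coverage[pair_sel]
            for c in ctx_list:
                cc = encode(c)
                key = cc[0] * 16 + cc[1] * 4 + cc[2]
                den[c] = int(covl[cl == key].sum())
        rows = [(c, num[c], den[c], (num[c] / den[c] if den[c] else 0.0))
                for c in ctx_list]
        tables[typ] = pd.DataFrame(
            rows, columns=["context", "numerator", "denominator", "rate"]
        ).set_index("context")
    return ContextSpectrum(tables, denominator)


def compare_groups(data: pd.DataFrame, value: str = "frequency",
                   group: str = "group", metric: str | None = None,
                   n_permutations: int = 10_000, seed: int = 0) -> pd.DataFrame:
    """One-way ANOVA with Tukey HSD post-test across replicate spectra.

    ``data`` is a long table with one row per replicate (and per metric,
    if ``metric`` names a column such as the substitution type).  For each
    metric the result holds one ``anova`` row (F and p), one seeded
    ``permutation`` row (label-shuffling p for the same F statistic, an
    internal cross-check), and one ``tukey`` row per group pair.
    """
    if n_permutations < 1:
        raise InvalidArgumentError("n_permutations must be >= 1")
    metrics = [None] if metric is None else list(pd.unique(data[metric]))
    rng = np.random.default_rng(seed)
    out = []
    for met in metrics:
        sub = data if met is None else data[data[metric] == met]
        labels = list(pd.unique(sub[group]))
        if len(labels) < 2:
            raise InvalidDesignError("need at least 2 groups")
        arrays = [sub.loc[sub[group] == g, value].to_numpy(dtype=float)
                  for g in labels]
        if any(a.size < 2 for a in arrays):
            raise InvalidDesignError("every group needs >= 2 replicates")
        pooled = np.concatenate(arrays)
        grand = pooled.mean()
        ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
        ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
        met_name = "all" if met is None else met
        if ss_within == 0.0:
            # degenerate: no within-group variation
            sig = ss_between > 0
            out.append((met_name, "anova", "", "", np.inf if sig else 0.0,
                        0.0 if sig else 1.0))
            out.append((met_name, "permutation", "", "", np.inf if sig else 0.0,
                        _perm_p_degenerate(arrays, rng, n_permutations) if sig else 1.0))
            for g1, g2 in combinations(range(len(labels)), 2):
                diff = arrays[g1].mean() - arrays[g2].mean()
                out.append((met_name, "tukey", labels[g1], labels[g2], diff,
                            0.0 if diff != 0 else 1.0))
            continue
        F, p = stats.f_oneway(*arrays)
        out.append((met_name, "anova", "", "", float(F), float(p)))
        n_ge = 0
        sizes = [a.size for a in arrays]
        for _ in range(n_permutations):
            perm = rng.permutation(pooled)
            parts = np.split(perm, np.cumsum(sizes)[:-1])
            Fp, _ = stats.f_oneway(*parts)
            if Fp >= F:
                n_ge += 1
        out.append((met_name, "permutation", "", "", float(F),
                    (n_ge + 1) / (n_permutations + 1)))
        hsd = stats.tukey_hsd(*arrays)
        for g1, g2 in combinations(range(len(labels)), 2):
            out.append((met_name, "tukey", labels[g1], labels[g2],
                        float(hsd.statistic[g1, g2]),
                        float(hsd.pvalue[g1, g2])))
    return pd.DataFrame(out, columns=["metric", "test", "group1", "group2",
                                      "statistic", "p_value"])


def _perm_p_degenerate(arrays, rng, n_permutations) -> float:
    """Permutation p for the separation statistic when within-group var is 0."""
    pooled = np.concatenate(arrays)
    sizes = [a.size for a in arrays]
    grand = pooled.mean()
    obs = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    n_ge = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        parts = np.split(perm, np.cumsum(sizes)[:-1])
        sb = sum(p.size * (p.mean() - grand) ** 2 for p in parts)
        if sb >= obs:
            n_ge += 1
    return (n_ge + 1) / (n_permutations + 1)
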