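"""Synthetic inputs with the statistical structure the downstream analyses assume.

This module emulates, with known ground truth:

* an E. coli-like reference genome of configurable length and GC content;
* deaminase-induced mutations concentrated at editing motifs — by default
  C->T within 5'TCG3' and A->G within 5'GAA3', applied strand-symmetrically
  (a minus-strand TCG hit appears as G->A inside 5'CGA3' on the top strand);
* rolling-circle (CirSeq-style) reads: each read is a tandem concatemer of
  one 90-120 bp circularised fragment, with i.i.d. substitution errors and a
  two-state (high/low) base-quality model;
* single-exponential deamination time courses with plateau and Gaussian noise;
* per-culture resistant-colony counts for fluctuation-style frequency assays.

Every generator takes an explicit integer seed and is byte-reproducible.
Ground truth (injected variants, fragment coordinates, phases) is returned
as pandas sidecar tables so recovery tests can score the pipeline exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import seqs
from .errors import InvalidArgumentError, InvalidModelError, MalformedInputError
from .seqs import SIX_TYPES, decode, encode

# (collapsed type) -> list of (top-strand ref code, alt code) realisations
_TYPE_SUBS = {
    "C:G>T:A": [(seqs.C, seqs.T), (seqs.G, seqs.A)],
    "A:T>G:C": [(seqs.A, seqs.G), (seqs.T, seqs.C)],
    "A:T>T:A": [(seqs.A, seqs.T), (seqs.T, seqs.A)],
    "G:C>T:A": [(seqs.C, seqs.A), (seqs.G, seqs.T)],
    "A:T>C:G": [(seqs.A, seqs.C), (seqs.T, seqs.G)],
    "G:C>C:G": [(seqs.C, seqs.G), (seqs.G, seqs.C)],
}


@dataclass(frozen=True)
class ReferenceGenome:
    """A reference sequence over {A,C,G,T}; ``circular`` genomes wrap."""

    id: str
    sequence: str
    circular: bool = False

    def __post_init__(self):
        if len(self.sequence) < 3:
            raise InvalidArgumentError("reference length must be >= 3")
        if set(self.sequence) - set("ACGT"):
            raise InvalidArgumentError("reference alphabet restricted to ACGT")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def codes(self) -> np.ndarray:
        return encode(self.sequence)

    def reverse_complement(self) -> "ReferenceGenome":
        return ReferenceGenome(self.id + "_rc", seqs.revcomp(self.sequence), self.circular)


@dataclass(frozen=True)
class MutationModel:
    """Per-site substitution probabilities with triplet-context modulation.

    ``base_rates`` maps a collapsed substitution type (e.g. ``"C:G>T:A"``)
    to a per-site, per-molecule probability.  ``context_multipliers`` maps
    ``(collapsed triplet, type)`` to a nonnegative factor; contexts are keyed
    by the orientation whose focal base is C or A, and a site whose
    top-strand base is G or T is matched through the reverse complement of
    its top-strand triplet — which is exactly what makes the model strand
    symmetric.  Contexts not listed get ``default_multiplier``.
    """

    base_rates: dict = field(default_factory=dict)
    context_multipliers: dict = field(default_factory=dict)
    default_multiplier: float = 1.0
    strand_symmetric: bool = True  # informational; the construction enforces it

    def __post_init__(self):
        for t, r in self.base_rates.items():
            if t not in SIX_TYPES:
                raise InvalidModelError(f"unknown substitution type {t!r}")
            if not 0.0 <= r <= 1.0:
                raise InvalidModelError(f"rate for {t} outside [0, 1]: {r}")
        for (ctx, t), m in self.context_multipliers.items():
            if m < 0:
                raise InvalidModelError(f"negative multiplier for ({ctx}, {t})")
            if seqs.collapse_context(ctx) != ctx:
                raise InvalidModelError(
                    f"context {ctx!r} must be keyed by its focal-C/A representation"
                )

    @classmethod
    def motif_model(cls, tcg_c_to_t: float = 0.0, gaa_a_to_g: float = 0.0) -> "MutationModel":
        """Deaminase editing confined to its two target motifs.

        C->T only within 5'TCG3' and A->G only within 5'GAA3' (each motif
        acting on both strands); all other contexts and types are silent.
        """
        return cls(
            base_rates={"C:G>T:A": tcg_c_to_t, "A:T>G:C": gaa_a_to_g},
            context_multipliers={("TCG", "C:G>T:A"): 1.0, ("GAA", "A:T>G:C"): 1.0},
            default_multiplier=0.0,
        )

    @classmethod
    def uniform(cls, rates: dict) -> "MutationModel":
        """Context-independent per-type rates (spontaneous background)."""
        return cls(base_rates=dict(rates), default_multiplier=1.0)

    def effective_rates(self, ref: ReferenceGenome) -> np.ndarray:
        """(L, 4) matrix of per-site probabilities of mutating to each base.

        Raises :class:`InvalidModelError` if any single rate x multiplier
        exceeds 1, or any site's total mutation probability exceeds 1.
        """
        codes = ref.codes
        ctx_int = seqs.collapsed_context_ints(codes, ref.circular)
        eff = np.zeros((len(codes), 4))
        for typ, rate in self.base_rates.items():
            if rate == 0.0:
                continue
            lut = np.full(64, self.default_multiplier)
            for (ctx, t), m in self.context_multipliers.items():
                if t == typ:
                    c = encode(ctx)
                    lut[c[0] * 16 + c[1] * 4 + c[2]] = m
            for ref_code, alt_code in _TYPE_SUBS[typ]:
                at = codes == ref_code
                mult = np.where(ctx_int[at] >= 0, lut[np.maximum(ctx_int[at], 0)],
                                self.default_multiplier)
                if np.any(rate * mult > 1.0):
                    raise InvalidModelError("rate x multiplier > 1 at some site")
                eff[at, alt_code] += rate * mult
        if np.any(eff.sum(axis=1) > 1.0):
            raise InvalidModelError("total per-site mutation probability > 1")
        return eff


def generate_reference(length: int, gc_fraction: float = 0.5, seed: int = 0,
                       ref_id: str = "synthetic_ref", circular: bool = False
                       ) -> ReferenceGenome:
    """I.i.d. random genome with P(G)+P(C) = ``gc_fraction``, split evenly."""
    if length < 3:
        raise InvalidArgumentError("length must be >= 3")
    if not 0.0 <= gc_fraction <= 1.0:
        raise InvalidArgumentError("gc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc_fraction) / 2, gc_fraction / 2,
                  gc_fraction / 2, (1 - gc_fraction) / 2])
    codes = rng.choice(4, size=length, p=p).astype(np.uint8)
    return ReferenceGenome(ref_id, decode(codes), circular)


@dataclass
class MoleculePool:
    """``n_molecules`` independently mutated copies of a reference.

    Molecules are stored as the shared reference plus per-molecule sparse
    diffs (0-based position, alt code), which keeps even large pools cheap.
    """

    ref: ReferenceGenome
    diffs: list  # per molecule: (positions int64 array, alt uint8 array)

    @property
    def n_molecules(self) -> int:
        return len(self.diffs)

    def sequence(self, molecule_id: int) -> str:
        codes = self.ref.codes
        pos, alt = self.diffs[molecule_id]
        codes[pos] = alt
        return decode(codes)


def inject_mutations(ref: ReferenceGenome, model: MutationModel,
                     n_molecules: int, seed: int) -> tuple[MoleculePool, pd.DataFrame]:
    """Mutate ``n_molecules`` independent copies of ``ref`` under ``model``.

    Returns the molecule pool and a ground-truth table with columns
    ``molecule_id, position`` (1-based, top strand), ``ref, alt``.
    """
    if n_molecules < 1:
        raise InvalidArgumentError("n_molecules must be >= 1")
    rng = np.random.default_rng(seed)
    eff = model.effective_rates(ref)
    p_tot = eff.sum(axis=1)
    hot = np.flatnonzero(p_tot > 0)
    p_hot = p_tot[hot]
    # conditional alt distribution at candidate sites
    cum = np.cumsum(eff[hot] / p_hot[:, None], axis=1)
    codes = ref.codes
    diffs = []
    rows = []
    for m in range(n_molecules):
        if hot.size:
            hit = rng.random(hot.size) < p_hot
            idx = np.flatnonzero(hit)
            u = rng.random(idx.size)
            alt = (u[:, None] < cum[idx]).argmax(axis=1).astype(np.uint8)
            pos = hot[idx]
        else:
            pos = np.empty(0, dtype=np.int64)
            alt = np.empty(0, dtype=np.uint8)
        diffs.append((pos, alt))
        for p0, a in zip(pos, alt):
            rows.append((m, int(p0) + 1, seqs.BASES[codes[p0]], seqs.BASES[a]))
    truth = pd.DataFrame(rows, columns=["molecule_id", "position", "ref", "alt"])
    return MoleculePool(ref, diffs), truth


def truth_type_counts(truth: pd.DataFrame) -> pd.Series:
    """Collapsed substitution-type counts of a ground-truth table."""
    counts = pd.Series(0, index=list(SIX_TYPES), dtype=int)
    if len(truth):
        labels = [seqs.pair_notation(r, a) for r, a in zip(truth["ref"], truth["alt"])]
        vc = pd.Series(labels).value_counts()
        counts.loc[vc.index] = vc.values
    return counts


def truth_context_counts(truth: pd.DataFrame, ref: ReferenceGenome) -> pd.Series:
    """Collapsed triplet-context counts of injected mutations (edge sites skipped)."""
    out: dict = {}
    L = len(ref)
    for _, row in truth.iterrows():
        p0 = row["position"] - 1
        if not ref.circular and (p0 == 0 or p0 == L - 1):
            continue
        trip = "".join(ref.sequence[(p0 + d) % L] for d in (-1, 0, 1))
        ctx = seqs.collapse_context(trip)
        out[ctx] = out.get(ctx, 0) + 1
    return pd.Series(out, dtype=int).sort_index()


@dataclass(frozen=True)
class QualityModel:
    """Two-state base-quality model: high (Q30-like) vs low (<Q20) bases.

    Qualities are assigned independently of the substitution-error process;
    low-quality bases exist so the downstream Q<20 masking rule has work
    to do, they are not extra errors.
    """

    high_q: int = 30
    low_q: int = 10
    low_prob: float = 0.02

    def __post_init__(self):
        if not 0.0 <= self.low_prob <= 1.0:
            raise InvalidArgumentError("low_prob must be in [0, 1]")


@dataclass
class ReadSet:
    """A batch of equal-length simulated reads with their truth sidecar.

    ``seqs``/``quals`` are (n_reads, read_len) uint8 matrices (base codes and
    Phred scores).  ``sidecar`` records, per read: molecule_id,
    fragment_start (1-based on the top strand), fragment_len and phase
    (0-based offset within the fragment at which the read begins).
    """

    ids: list
    seqs: np.ndarray
    quals: np.ndarray
    sidecar: pd.DataFrame

    def __len__(self) -> int:
        return len(self.ids)

    def read(self, i: int) -> tuple[str, str, str]:
        """(id, sequence, Phred+33 quality string) of read ``i``."""
        return (self.ids[i], decode(self.seqs[i]),
                "".join(chr(q + 33) for q in self.quals[i]))

    def to_fastq(self, path) -> None:
        with open(path, "w") as fh:
            for i in range(len(self.ids)):
                rid, s, q = self.read(i)
                fh.write(f"@{rid}\n{s}\n+\n{q}\n")

    def sidecar_to_tsv(self, path) -> None:
        self.sidecar.to_csv(path, sep="\t", index=False)


def simulate_rollingcircle_reads(pool: MoleculePool,
                                 n_reads: int,
                                 frag_len_range: tuple = (90, 120),
                                 read_len: int = 300,
                                 paired_or_merged: str = "merged",
                                 error_rate: float = 0.001,
                                 quality_model: QualityModel | None = None,
                                 seed: int = 0,
                                 id_prefix: str = "read") -> ReadSet:
    """Simulate tandem-concatemer (rolling-circle) reads from a molecule pool.

    Each read picks a molecule, a fragment (uniform length in
    ``frag_len_range``, uniform start; wrapping if the genome is circular)
    and a uniform random phase, then tiles the fragment to ``read_len``.
    Substitution errors are i.i.d. at ``error_rate``; qualities follow the
    two-state model.  ``paired`` mode emits two independently-phased mates
    of ``read_len // 2`` bases from the same fragment.
    """
    lo, hi = frag_len_range
    if paired_or_merged not in ("merged", "paired"):
        raise InvalidArgumentError("paired_or_merged must be 'merged' or 'paired'")
    eff_read_len = read_len if paired_or_merged == "merged" else read_len // 2
    if lo < 30 or hi > read_len or lo > hi:
        raise InvalidArgumentError("frag_len_range must lie within [30, read_len]")
    if eff_read_len < lo:
        raise InvalidArgumentError("read length shorter than minimum fragment length")
    if not 0.0 <= error_rate < 0.5:
        raise InvalidArgumentError("error_rate must be in [0, 0.5)")
    qm = quality_model or QualityModel()
    rng = np.random.default_rng(seed)
    ref = pool.ref
    L = len(ref)
    refcodes = ref.codes

    mol = rng.integers(0, pool.n_molecules, n_reads)
    flen = rng.integers(lo, hi + 1, n_reads)
    if ref.circular:
        start = rng.integers(0, L, n_reads)
    else:
        if hi > L:
            raise InvalidArgumentError("fragment longer than linear reference")
        start = np.floor(rng.random(n_reads) * (L - flen + 1)).astype(np.int64)

    if paired_or_merged == "paired":
        mol = np.repeat(mol, 2)
        flen = np.repeat(flen, 2)
        start = np.repeat(start, 2)
        n_out = 2 * n_reads
        ids = [f"{id_prefix}{i // 2}/{1 + i % 2}" for i in range(n_out)]
    else:
        n_out = n_reads
        ids = [f"{id_prefix}{i}" for i in range(n_out)]
    phase = np.floor(rng.random(n_out) * flen).astype(np.int64)

    # reads carrying each injected variant, precomputed from sparse diffs
    hits_row: list = []
    hits_off: list = []
    hits_alt: list = []
    for m, (pos, alt) in enumerate(pool.diffs):
        if pos.size == 0:
            continue
        r = np.flatnonzero(mol == m)
        if r.size == 0:
            continue
        for p0, a in zip(pos, alt):
            off = (p0 - start[r]) % L if ref.circular else p0 - start[r]
            sel = (off >= 0) & (off < flen[r])
            rr = r[sel]
            hits_row.append(rr)
            hits_off.append(off[sel])
            hits_alt.append(np.full(rr.size, a, dtype=np.uint8))
    if hits_row:
        hits_row = np.concatenate(hits_row)
        hits_off = np.concatenate(hits_off)
        hits_alt = np.concatenate(hits_alt)
    else:
        hits_row = np.empty(0, dtype=np.int64)
        hits_off = hits_alt = np.empty(0, dtype=np.int64)

    out = np.empty((n_out, eff_read_len), dtype=np.uint8)
    pos_in_group = np.empty(n_out, dtype=np.int64)
    for fl in np.unique(flen):
        g = np.flatnonzero(flen == fl)
        pos_in_group[g] = np.arange(g.size)
        idx = start[g, None] + np.arange(fl)[None, :]
        frag = refcodes[idx % L if ref.circular else idx]
        in_g = np.flatnonzero(flen[hits_row] == fl)
        if in_g.size:
            frag[pos_in_group[hits_row[in_g]], hits_off[in_g]] = hits_alt[in_g]
        tile = (phase[g, None] + np.arange(eff_read_len)[None, :]) % fl
        out[g] = frag[np.arange(g.size)[:, None], tile]

    err = rng.random(out.shape) < error_rate
    n_err = int(err.sum())
    if n_err:
        out[err] = (out[err] + rng.integers(1, 4, n_err).astype(np.uint8)) % 4
    low = rng.random(out.shape) < qm.low_prob
    quals = np.where(low, np.uint8(qm.low_q), np.uint8(qm.high_q))

    sidecar = pd.DataFrame({
        "read_id": ids,
        "molecule_id": mol,
        "fragment_start": start + 1,
        "fragment_len": flen,
        "phase": phase,
    })
    return ReadSet(ids, out, quals, sidecar)


@dataclass(frozen=True)
class TimeCourse:
    """Fraction deaminated as a function of time (minutes) for one replicate."""

    substrate_id: str
    replicate: int
    times: np.ndarray
    fractions: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.fractions, dtype=float)
        if t.shape != f.shape:
            raise MalformedInputError("times and fractions must have the same length")
        if np.any(np.diff(t) < 0):
            raise InvalidArgumentError("times must be nondecreasing")
        if np.any(t < 0):
            raise InvalidArgumentError("times must be nonnegative")
        if np.any((f < 0) | (f > 1)):
            raise InvalidArgumentError("fractions must lie in [0, 1]")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "fractions", f)


def simulate_timecourse(k_true: float, plateau: float, times,
                        noise_sd: float = 0.0, n_replicates: int = 1,
                        seed: int = 0, substrate_id: str = "substrate"
                        ) -> list[TimeCourse]:
    """Rise-to-plateau time courses: F(t) = clamp(P(1 - e^(-kt)) + noise, 0, 1)."""
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise InvalidArgumentError("times must be nonnegative")
    if not 0.0 < plateau <= 1.0:
        raise InvalidArgumentError("plateau must be in (0, 1]")
    if noise_sd < 0:
        raise InvalidArgumentError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for r in range(n_replicates):
        f = plateau * (1.0 - np.exp(-k_true * t))
        if noise_sd > 0:
            f = f + rng.normal(0.0, noise_sd, size=t.shape)
        out.append(TimeCourse(substrate_id, r, np.sort(t), np.clip(f, 0.0, 1.0)))
    return out


@dataclass
class AssayCounts:
    """Per-culture resistant-colony counts for one group.

    ``records`` columns: resistant_colonies (int), viable_cells (>0),
    dilution_factor (>0, multiplies viable cells to the full-culture scale).
    """

    group: str
    records: pd.DataFrame

    def __post_init__(self):
        req = {"resistant_colonies", "viable_cells", "dilution_factor"}
        if not req.issubset(self.records.columns):
            raise MalformedInputError(f"records must have columns {sorted(req)}")
        if (self.records["viable_cells"] <= 0).any():
            raise InvalidArgumentError("viable_cells must be > 0")
        if (self.records["resistant_colonies"] < 0).any():
            raise InvalidArgumentError("colony counts must be nonnegative")


def simulate_fluctuation_assay(n_cultures: int, viable_cells: float,
                               freq: float, seed: int = 0,
                               group: str = "group") -> AssayCounts:
    """Per-culture resistant counts ~ Poisson(freq x viable_cells)."""
    if not np.isfinite(freq * viable_cells) or freq < 0:
        raise InvalidArgumentError("freq x viable_cells must be finite and nonnegative")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(freq * viable_cells, size=n_cultures)
    rec = pd.DataFrame({
        "resistant_colonies": counts.astype(int),
        "viable_cells": float(viable_cells),
        "dilution_factor": 1.0,
    })
    return AssayCounts(group, rec)


def write_fasta(ref: ReferenceGenome, path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{ref.id}\n")
        for i in range(0, len(ref.sequence), 70):
            fh.write(ref.sequence[i:i + 70] + "\n")


def read_fasta(path) -> ReferenceGenome:
    from Bio import SeqIO
    rec = next(SeqIO.parse(str(path), "fasta"))
    return ReferenceGenome(rec.id, str(rec.seq).upper())
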