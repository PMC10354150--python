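"""Deamination kinetics and oligonucleotide substrate geometry.

Cleavage-assay gels read out deamination through enzymatic scission at the
edited base: Endonuclease V cuts the second phosphodiester bond 3' of a
deoxyinosine (A->I editing), and UDG + NaOH breaks the strand at the
abasic site left by excising uracil (C->U editing).  The fraction
deaminated at each time point is cleaved / (cleaved + uncleaved) band
intensity, and the time course is fit to a rise-to-plateau single
exponential

    F(t) = P * (1 - exp(-k_app * t)),

with the apparent first-order rate constant k_app in min^-1.  The plateau
P is fitted within (0, 1] by default (``fix_plateau`` forces it).  k_app
is reported as the mean over replicate fits with the SEM across replicates,
matching the mean +/- SEM convention for independent experiments.

Substrate annotation uses a single-hairpin model: the maximal contiguous
run of Watson-Crick pairs closing a loop of at least three bases, found by
exhaustive search (all in-scope substrates are designed single hairpins or
linear oligos, so no thermodynamic folding is needed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import (EdgeCaseError, FitFailureError, InvalidArgumentError,
                     UndefinedLaneError, UndefinedRatioError)
from .seqs import COMPLEMENT
from .syndata import TimeCourse

#: Published hairpin substrate: 5'-GTCTGCTT(X)GTTTGCAGA-3' with the variable
#: base X as the third base of the loop.
HAIRPIN_TEMPLATE = ("GTCTGCTT", "GTTTGCAGA")
#: Published linear substrate: 5'-(GGTT)x4 (X) G (GGTT)x4-3', variable base
#: at position 17.
LINEAR_TEMPLATE = ("GGTT" * 4, "G" + "GGTT" * 4)


def hairpin_substrate(variable_base: str) -> str:
    """The 18-mer hairpin substrate with the given loop base (hpDNA-X)."""
    return HAIRPIN_TEMPLATE[0] + variable_base.upper() + HAIRPIN_TEMPLATE[1]


def linear_substrate(variable_base: str) -> str:
    """The 34-mer unstructured substrate with the variable 17th base (ssDNA-X)."""
    return LINEAR_TEMPLATE[0] + variable_base.upper() + LINEAR_TEMPLATE[1]


def hairpin_linear_substrate(variable_base: str) -> str:
    """Long substrate presenting the variable base at both a hairpin-loop
    site and a linear site, flanked by poly-T tails ((h+l)DNA-X)."""
    b = variable_base.upper()
    return ("G" + "T" * 10 + "CTGCTTT" + b + "GTTGCAGA" + "T" * 11
            + b + "G" + "T" * 10)


@dataclass(frozen=True)
class GelLane:
    """One gel lane: band intensities of cleaved and uncleaved DNA."""

    substrate_id: str
    time: float  # minutes
    cleaved_intensity: float
    uncleaved_intensity: float

    def __post_init__(self):
        if self.cleaved_intensity < 0 or self.uncleaved_intensity < 0:
            raise InvalidArgumentError("band intensities must be nonnegative")


def fraction_deaminated(lane: GelLane) -> float:
    """cleaved / (cleaved + uncleaved); errors if both bands are empty."""
    total = lane.cleaved_intensity + lane.uncleaved_intensity
    if total == 0:
        raise UndefinedLaneError(
            f"lane {lane.substrate_id} @ {lane.time} min has no signal")
    return lane.cleaved_intensity / total


@dataclass
class KineticFit:
    """Result of single-exponential fits across replicates.

    ``k_app`` is the replicate-mean apparent rate constant (min^-1) and
    ``k_sem`` the standard error of that mean across replicates (0 for a
    single replicate).  ``plateau_fitted`` records whether P was free.
    """

    k_app: float
    k_sem: float
    plateau: float
    n_replicates: int
    residual_rms: float
    plateau_fitted: bool
    flags: list = field(default_factory=list)
    per_replicate: list = field(default_factory=list)  # (replicate, k, plateau)

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.plateau * (1.0 - np.exp(-self.k_app * t))


def _fit_single(tc: TimeCourse, fix_plateau: float | None) -> tuple[float, float, np.ndarray]:
    t, f = tc.times, tc.fractions
    nz = np.flatnonzero((t > 0) & (f > 0))
    p0_plateau = min(1.0, max(float(f.max()), 0.05))
    if nz.size >= 2:
        i, j = nz[0], nz[1]
        slope = abs((f[j] - f[i]) / (t[j] - t[i])) if t[j] > t[i] else f[i] / t[i]
        k0 = max(slope / p0_plateau, 1e-9)
    elif nz.size == 1:
        k0 = max(f[nz[0]] / (t[nz[0]] * p0_plateau), 1e-9)
    else:
        k0 = 1e-3
    try:
        tols = dict(xtol=1e-13, ftol=1e-13, gtol=1e-13, maxfev=10_000)
        if fix_plateau is None:
            popt, _ = curve_fit(
                lambda tt, k, P: P * (1.0 - np.exp(-k * tt)), t, f,
                p0=[k0, p0_plateau], bounds=([0.0, 1e-6], [np.inf, 1.0]), **tols)
            k, P = float(popt[0]), float(popt[1])
        else:
            P = float(fix_plateau)
            popt, _ = curve_fit(
                lambda tt, k: P * (1.0 - np.exp(-k * tt)), t, f,
                p0=[k0], bounds=([0.0], [np.inf]), **tols)
            k = float(popt[0])
    except RuntimeError as e:
        raise FitFailureError(
            f"replicate {tc.replicate} of {tc.substrate_id}: {e}") from e
    resid = f - P * (1.0 - np.exp(-k * t))
    return k, P, resid


def fit_kapp(timecourses, fix_plateau: float | None = None) -> KineticFit:
    """Fit F(t) = P(1 - e^(-kt)) per replicate and pool k_app +/- SEM.

    Requires at least three distinct time points per replicate.  A flat
    all-zero set of time courses short-circuits to k_app = 0 with the
    ``no_signal`` flag rather than a degenerate fit.
    """
    tcs = list(timecourses)
    if not tcs:
        raise InvalidArgumentError("no time courses given")
    for tc in tcs:
        if np.unique(tc.times).size < 3:
            raise InvalidArgumentError(
                f"replicate {tc.replicate}: need >= 3 distinct time points")
    if all(np.all(tc.fractions == 0) for tc in tcs):
        return KineticFit(0.0, 0.0, fix_plateau if fix_plateau else 1.0,
                          len(tcs), 0.0, fix_plateau is None, ["no_signal"],
                          [(tc.replicate, 0.0, 1.0) for tc in tcs])
    ks, ps, resids, per_rep = [], [], [], []
    for tc in tcs:
        k, P, resid = _fit_single(tc, fix_plateau)
        ks.append(k)
        ps.append(P)
        resids.append(resid)
        per_rep.append((tc.replicate, k, P))
    ks = np.asarray(ks)
    k_app = float(ks.mean())
    k_sem = float(ks.std(ddof=1) / math.sqrt(ks.size)) if ks.size > 1 else 0.0
    rms = float(np.sqrt(np.mean(np.concatenate(resids) ** 2)))
    return KineticFit(k_app, k_sem, float(np.mean(ps)), len(tcs), rms,
                      fix_plateau is None, [], per_rep)


def fold_ratio(numerator: KineticFit | float, denominator: KineticFit | float,
               rounding: str = "nearest_fold") -> float:
    """k_num / k_den rounded per mode: nearest integer or one decimal place."""
    k_num = numerator.k_app if isinstance(numerator, KineticFit) else float(numerator)
    k_den = denominator.k_app if isinstance(denominator, KineticFit) else float(denominator)
    if k_den <= 0:
        raise UndefinedRatioError("denominator rate constant must be > 0")
    ratio = k_num / k_den
    if rounding == "nearest_fold":
        return float(round(ratio))
    if rounding == "one_decimal":
        return round(ratio, 1)
    raise InvalidArgumentError("rounding must be 'nearest_fold' or 'one_decimal'")


@dataclass
class SubstrateAnnotation:
    """Single-hairpin geometry of an oligo substrate.

    ``stem_pairs`` are 1-based (i, j) Watson-Crick pairs, outermost first;
    ``loop`` is the 1-based inclusive unpaired interval between the
    innermost pair (None for linear substrates).
    """

    sequence: str
    stem_pairs: list
    loop: tuple | None
    target_index: int | None
    structure_class: str  # hairpin | linear | mixed

    @property
    def stem_length(self) -> int:
        return len(self.stem_pairs)


_MIN_LOOP = 3  # smallest loop a DNA hairpin can close


def _max_stem(seq: str, min_stem: int):
    """Exhaustive single-hairpin search: the longest contiguous WC stem.

    Considers every register (i, j, s): positions i..i+s-1 paired with
    j+s-1..j (0-based), requiring a loop of >= 3 unpaired bases between.
    Ties prefer the longer stem, then the outermost (smallest i, then
    largest j).  Returns (s, i, j) or None.
    """
    L = len(seq)
    best = None
    for i in range(L):
        for j in range(i + 1, L):
            # grow contiguous WC pairs inward from the outer pair (i, j)
            s = 0
            while True:
                a, b = i + s, j - s
                if b - a - 1 < _MIN_LOOP:
                    break
                if COMPLEMENT[seq[a]] != seq[b]:
                    break
                s += 1
            if s >= min_stem:
                key = (s, -i, j)
                if best is None or key > (best[0], -best[1], best[2]):
                    best = (s, i, j)
    return best


def annotate_substrate(sequence: str, min_stem: int = 4,
                       target_index: int | None = None) -> SubstrateAnnotation:
    """Annotate the single-hairpin geometry of an oligo.

    Classifies the substrate as ``hairpin`` when a Watson-Crick stem of at
    least ``min_stem`` contiguous pairs closes a loop, ``mixed`` when such a
    hairpin covers only a minority of the sequence (hairpin-plus-linear
    designs), and ``linear`` otherwise.  The target (editable) base is the
    caller-supplied index if given, else the unique base whose letter occurs
    exactly once, else — for hairpins — the third base of the loop.
    """
    seq = sequence.upper()
    if len(seq) < 8:
        raise InvalidArgumentError("substrate sequence must be >= 8 nt")
    if set(seq) - set("ACGT"):
        raise InvalidArgumentError("substrate alphabet restricted to ACGT")
    hit = _max_stem(seq, min_stem)
    if hit is None:
        stem_pairs: list = []
        loop = None
        structure = "linear"
    else:
        s, i, j = hit
        stem_pairs = [(i + t + 1, j - t + 1) for t in range(s)]
        loop = (i + s + 1, j - s + 1)
        span = j - i + 1
        structure = "hairpin" if span >= 0.5 * len(seq) else "mixed"
    if target_index is None:
        singles = [b for b in "ACGT" if seq.count(b) == 1]
        if len(singles) == 1:
            target_index = seq.index(singles[0]) + 1
        elif loop is not None and loop[1] - loop[0] + 1 >= 3:
            target_index = loop[0] + 2  # third base of the loop
    if target_index is not None and not 1 <= target_index <= len(seq):
        raise InvalidArgumentError("target_index outside sequence")
    return SubstrateAnnotation(seq, stem_pairs, loop, target_index, structure)


def predict_cleavage_fragment(annotation: SubstrateAnnotation,
                              chemistry: str) -> int:
    """Length (nt) of the labelled 5' fragment after cleavage read-out.

    ``endoV`` cuts the second phosphodiester bond 3' of the deoxyinosine,
    leaving a 5' fragment of target_index + 1 bases; ``udg_naoh`` breaks the
    strand at the abasic (former C) position, leaving target_index - 1
    bases.  Fragments that would be empty or full-length are edge-case
    errors.
    """
    if annotation.target_index is None:
        raise InvalidArgumentError("annotation has no target_index")
    ti, L = annotation.target_index, len(annotation.sequence)
    if chemistry == "endoV":
        out = ti + 1
    elif chemistry == "udg_naoh":
        out = ti - 1
    else:
        raise InvalidArgumentError("chemistry must be 'endoV' or 'udg_naoh'")
    if not 0 < out < L:
        raise EdgeCaseError(
            f"cleavage at target {ti} with {chemistry} gives invalid fragment {out}")
    return out


def fit_lanes(lanes, fix_plateau: float | None = None) -> dict:
    """Fit k_app per substrate from a collection of GelLane measurements.

    Lanes are grouped by substrate_id, converted to fractions, and treated
    as one replicate per substrate unless a ``replicate`` attribute is
    attached via (lane, replicate) tuples.
    """
    series: dict = {}
    for item in lanes:
        lane, rep = item if isinstance(item, tuple) else (item, 0)
        key = (lane.substrate_id, rep)
        series.setdefault(key, []).append((lane.time, fraction_deaminated(lane)))
    by_substrate: dict = {}
    for (sid, rep), pts in series.items():
        pts.sort()
        t = np.array([p[0] for p in pts])
        f = np.array([p[1] for p in pts])
        by_substrate.setdefault(sid, []).append(TimeCourse(sid, rep, t, f))
    return {sid: fit_kapp(tcs, fix_plateau) for sid, tcs in by_substrate.items()}
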