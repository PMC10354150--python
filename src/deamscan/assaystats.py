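"""Resistance-assay statistics and marker-gene clone mutation classification.

The mutagenic activity of a deaminase expressed in bacteria or yeast is
read out by fluctuation-style resistance assays: per independent culture,
mutation frequency = resistant colonies / viable cells, groups summarised
by their median and compared with a two-tailed Wilcoxon rank-sum test for
unpaired data (exact enumeration for small groups, normal approximation
with tie correction otherwise).  Note this is the frequency estimator, not
a Luria-Delbruck mutation-rate estimator.

Sequenced resistant clones carry (by selection) a single marker-gene
substitution; :func:`classify_clone_mutation` identifies it, collapses it
into pair notation (e.g. G->A reported as C:G>T:A) and its triplet
context, and, when a reading frame is supplied, labels the affected codon
in the "S512 (tct)" style.  :func:`structure_site_fraction` reports the
fraction of deamination-type calls falling on annotated hairpin-loop
positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import seqs
from .errors import (InvalidArgumentError, InvalidCultureError,
                     MalformedInputError, MissingAnnotationError, MultiHitError)
from .syndata import AssayCounts

DEAMINATION_TYPES = ("C:G>T:A", "A:T>G:C")


@dataclass
class FrequencyResult:
    """Per-culture mutation frequencies of one group, with their median."""

    group: str
    frequencies: np.ndarray
    median: float
    n_cultures: int


def mutation_frequency(counts: AssayCounts) -> FrequencyResult:
    """Per-culture frequency = resistant / (viable x dilution factor)."""
    rec = counts.records
    if (rec["viable_cells"] <= 0).any():
        raise InvalidCultureError("viable_cells must be > 0 in every culture")
    freq = (rec["resistant_colonies"]
            / (rec["viable_cells"] * rec["dilution_factor"])).to_numpy(dtype=float)
    return FrequencyResult(counts.group, freq, float(np.median(freq)), freq.size)


@dataclass
class FrequencyComparison:
    p_value: float
    fold_of_medians: float | None  # None when the denominator median is 0
    method: str                    # "exact" or "asymptotic"
    flags: list = field(default_factory=list)


def rank_sum_p(a: np.ndarray, b: np.ndarray) -> tuple[float, str]:
    """Two-tailed Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact null enumeration when both groups have at most 10 observations,
    otherwise the normal approximation with tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    method = "exact" if (a.size <= 10 and b.size <= 10) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0)), method


def compare_frequencies(a: FrequencyResult, b: FrequencyResult) -> FrequencyComparison:
    """Wilcoxon rank-sum comparison plus the fold of group medians (a / b)."""
    if a.n_cultures < 3 or b.n_cultures < 3:
        raise InvalidArgumentError("each group needs >= 3 cultures")
    p, method = rank_sum_p(a.frequencies, b.frequencies)
    if b.median > 0:
        return FrequencyComparison(p, a.median / b.median, method)
    return FrequencyComparison(p, None, method, ["undefined_fold_zero_median"])


@dataclass
class MutationCall:
    """A classified single-substitution marker-gene mutation."""

    gene: str
    position: int          # 1-based nucleotide position
    ref_base: str
    obs_base: str
    pair_notation: str
    codon_label: str | None
    triplet_context: str | None  # collapsed; None at sequence edges
    structure_site: str = "unknown"  # loop | stem | linear | unknown


_CODON_TABLE = None


def _translate(codon: str) -> str:
    global _CODON_TABLE
    if _CODON_TABLE is None:
        from Bio.Data.CodonTable import standard_dna_table
        _CODON_TABLE = dict(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            _CODON_TABLE[stop] = "*"
    return _CODON_TABLE.get(codon.upper(), "X")


def classify_clone_mutation(clone_seq: str, ref_seq: str, gene: str = "gene",
                            frame_offset: int | None = None,
                            residue_offset: int = 0,
                            strict: bool = True) -> MutationCall | None:
    """Identify and annotate the single substitution in a sequenced clone.

    Returns None for an identical clone.  With ``strict`` (default) a clone
    carrying more than one substitution raises :class:`MultiHitError`;
    otherwise the first substitution is annotated and the extra hits are
    noted in no way (selection designs expect exactly one hit per clone).

    ``frame_offset`` is the 0-based position where the reading frame's first
    complete codon starts; ``residue_offset`` shifts the reported residue
    number so toy genes can mimic native numbering (residue number =
    residue_offset + 1-based codon index).
    """
    clone = clone_seq.upper()
    ref = ref_seq.upper()
    if len(clone) != len(ref):
        raise MalformedInputError("clone and reference must align without gaps")
    diffs = [i for i, (c, r) in enumerate(zip(clone, ref)) if c != r]
    if not diffs:
        return None
    if len(diffs) > 1 and strict:
        raise MultiHitError(f"{len(diffs)} substitutions; expected exactly one")
    i = diffs[0]
    ref_b, obs_b = ref[i], clone[i]
    context = None
    if 0 < i < len(ref) - 1:
        context = seqs.collapse_context(ref[i - 1:i + 2])
    codon_label = None
    if frame_offset is not None:
        ci = (i - frame_offset) // 3
        start = frame_offset + 3 * ci
        if 0 <= start and start + 3 <= len(ref) and i >= frame_offset:
            wt_codon = ref[start:start + 3]
            codon_label = (f"{_translate(wt_codon)}{residue_offset + ci + 1}"
                           f" ({wt_codon.lower()})")
    return MutationCall(gene, i + 1, ref_b, obs_b,
                        seqs.pair_notation(ref_b, obs_b), codon_label, context)


@dataclass
class StructureSiteResult:
    fraction_loop: float | None
    n_deamination_calls: int
    n_loop: int
    flags: list = field(default_factory=list)


def structure_site_fraction(calls, structure_annotation: dict) -> StructureSiteResult:
    """Fraction of deamination-type calls (C:G>T:A, A:T>G:C) at loop sites.

    ``structure_annotation`` maps 1-based position -> {"loop","stem","linear"}.
    Every deamination-type call position must be covered.
    """
    deam = [c for c in calls if c.pair_notation in DEAMINATION_TYPES]
    n_loop = 0
    for c in deam:
        if c.position not in structure_annotation:
            raise MissingAnnotationError(
                f"position {c.position} not covered by structure annotation")
        site = structure_annotation[c.position]
        c.structure_site = site
        if site == "loop":
            n_loop += 1
    if not deam:
        return StructureSiteResult(None, 0, 0, ["no_deamination_calls"])
    return StructureSiteResult(n_loop / len(deam), len(deam), n_loop)


def read_counts_tsv(path) -> dict:
    """Read a colony-count TSV (group, culture, colonies, viable_cells,
    dilution) into per-group :class:`AssayCounts`."""
    df = pd.read_csv(path, sep="\t")
    need = {"group", "colonies", "viable_cells"}
    if not need.issubset(df.columns):
        raise MalformedInputError(f"counts TSV needs columns {sorted(need)}")
    if "dilution" not in df.columns:
        df["dilution"] = 1.0
    out = {}
    for g, sub in df.groupby("group", sort=False):
        rec = pd.DataFrame({
            "resistant_colonies": sub["colonies"].astype(int).to_numpy(),
            "viable_cells": sub["viable_cells"].astype(float).to_numpy(),
            "dilution_factor": sub["dilution"].astype(float).to_numpy(),
        })
        out[str(g)] = AssayCounts(str(g), rec)
    return out
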