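"""Chunked end-to-end pipeline: simulate reads -> consensus -> place -> tally.

Memory-bounded driver used for genome-scale recovery experiments: reads
are simulated and folded in chunks, placements accumulate into one
:class:`~deamscan.mutspec.SiteTally`, and the spectrum / context tables
are computed once at the end.  All randomness derives from a single seed
via ``numpy.random.SeedSequence`` spawning, so runs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mutspec import (ContextSpectrum, ReferenceIndex, SiteTally,
                      SpectrumResult, context_spectrum, place_batch, spectrum,
                      tally)
from .rollcons import QCParams, consensus_batch
from .syndata import MoleculePool, QualityModel, simulate_rollingcircle_reads


@dataclass
class PipelineResult:
    tally: SiteTally
    spectrum: SpectrumResult
    contexts: ContextSpectrum
    report: dict


def consensus_spectrum_pipeline(pool: MoleculePool, n_reads: int,
                                qc: QCParams = QCParams(),
                                error_rate: float = 0.001,
                                quality_model: QualityModel | None = None,
                                read_len: int = 300,
                                frag_len_range: tuple = (90, 120),
                                max_mismatch_frac: float = 0.05,
                                seed_kmer: int = 21,
                                context_denominator: str = "total",
                                seed: int = 0,
                                chunk_size: int = 100_000) -> PipelineResult:
    """Simulate rolling-circle reads from ``pool`` and call the spectrum."""
    ref = pool.ref
    index = ReferenceIndex(ref, seed_kmer, max_query_len=read_len)
    L = len(ref)
    cov = np.zeros(L, dtype=np.int64)
    counts = np.zeros((L, 4), dtype=np.int64)
    totals = {"n_reads": 0, "n_kept": 0, "n_dropped_low_quality": 0,
              "n_abstained_no_period": 0, "n_placed": 0, "n_ambiguous": 0,
              "n_unplaced": 0, "n_mismatch_observations": 0}
    ss = np.random.SeedSequence(seed)
    n_chunks = (n_reads + chunk_size - 1) // chunk_size
    children = ss.spawn(n_chunks)
    done = 0
    copies_acc = 0.0
    for c in range(n_chunks):
        n = min(chunk_size, n_reads - done)
        reads = simulate_rollingcircle_reads(
            pool, n, frag_len_range=frag_len_range, read_len=read_len,
            error_rate=error_rate, quality_model=quality_model,
            seed=children[c], id_prefix=f"c{c}_r")
        done += n
        cset, rep = consensus_batch(reads, qc)
        placements = place_batch(cset, ref, max_mismatch_frac, seed_kmer,
                                 index=index)
        t = tally(placements, ref)
        cov += t.coverage
        counts += t.counts
        totals["n_reads"] += rep["n_reads"]
        totals["n_kept"] += rep["n_kept"]
        totals["n_dropped_low_quality"] += rep["n_dropped_low_quality"]
        totals["n_abstained_no_period"] += rep["n_abstained_no_period"]
        totals["n_placed"] += placements.n_placed
        totals["n_ambiguous"] += placements.n_ambiguous
        totals["n_unplaced"] += placements.n_unplaced
        totals["n_mismatch_observations"] += int(placements.mm_pos0.size)
        copies_acc += rep["mean_copies_used"] * rep["n_kept"]
    totals["mean_copies_used"] = (copies_acc / totals["n_kept"]
                                  if totals["n_kept"] else 0.0)
    full = SiteTally(cov, counts)
    full.validate()
    return PipelineResult(full, spectrum(full, ref),
                          context_spectrum(full, ref, context_denominator),
                          totals)
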