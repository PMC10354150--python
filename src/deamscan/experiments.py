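"""Full-scale validation experiments for the whole pipeline.

Each function sets up a synthetic dataset at the scale the corresponding
analysis was designed for, runs the pipeline end to end, and returns the
summary quantities (recovery errors, false-positive rates, oracle
agreement).  They are used both by the acceptance test suite and by
``scripts/acceptance.py``.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from . import deamkin
from .assaystats import rank_sum_p
from .mutspec import (ReferenceIndex, context_spectrum, from_single_placements,
                      place_consensus, spectrum, tally)
from .pipeline import consensus_spectrum_pipeline
from .rollcons import QCParams, consensus_batch
from .seqs import revcomp
from .syndata import (MutationModel, QualityModel, generate_reference,
                      inject_mutations, simulate_rollingcircle_reads,
                      simulate_timecourse)

#: Reported apparent deamination rate constants (min^-1), used as
#: worked-example inputs for the fold-ratio computations: hairpin (hp) vs
#: linear (ss) substrates presenting a single A or C, for the deaminase
#: alone and in complex with its structural partner subunit.
REPORTED_KAPP = {
    "hpDNA-A": 0.00206,
    "ssDNA-A": 0.00032,
    "hpDNA-C": 0.00801,
    "ssDNA-C": 0.00033,
    "hpDNA-A_complex": 0.01092,
    "hpDNA-C_complex": 0.01066,
    "tRNA_complex": 0.0287,
}


def published_fold_ratios() -> dict:
    """The four fold-ratios recomputed from the reported rate constants."""
    return {
        "hpA_vs_ssA_nearest_fold": deamkin.fold_ratio(
            REPORTED_KAPP["hpDNA-A"], REPORTED_KAPP["ssDNA-A"], "nearest_fold"),
        "hpC_vs_ssC_nearest_fold": deamkin.fold_ratio(
            REPORTED_KAPP["hpDNA-C"], REPORTED_KAPP["ssDNA-C"], "nearest_fold"),
        "complex_vs_alone_hpA_one_decimal": deamkin.fold_ratio(
            REPORTED_KAPP["hpDNA-A_complex"], REPORTED_KAPP["hpDNA-A"],
            "one_decimal"),
        "complex_vs_alone_hpC_one_decimal": deamkin.fold_ratio(
            REPORTED_KAPP["hpDNA-C_complex"], REPORTED_KAPP["hpDNA-C"],
            "one_decimal"),
    }


def consensus_error_experiment(error_rate: float, n_reads: int = 1000,
                               seed: int = 0, min_copies: int = 3) -> dict:
    """Measured consensus error rate for exactly 3 tandem copies vs the
    majority-vote closed form 3e^2(1-e) + e^3.

    Fragments are fixed at 100 bp with 300 bp reads so every template
    position receives exactly three observations; the consensus is compared
    position-by-position against the simulator's true rotated fragment.
    """
    ref = generate_reference(20_000, 0.5, seed=seed, circular=True)
    pool, _ = inject_mutations(ref, MutationModel.motif_model(), 4, seed=seed + 1)
    reads = simulate_rollingcircle_reads(
        pool, n_reads, frag_len_range=(100, 100), read_len=300,
        error_rate=error_rate, quality_model=QualityModel(low_prob=0.0),
        seed=seed + 2)
    cset, _ = consensus_batch(reads, QCParams(min_copies=min_copies))
    refc = ref.codes
    L = len(ref)
    sc = reads.sidecar
    n_err = n_base = 0
    for p, grp in cset.groups.items():
        for row, ridx in enumerate(grp.read_indices):
            st = int(sc.fragment_start[ridx]) - 1
            ph = int(sc.phase[ridx])
            frag = refc[(st + np.arange(p)) % L]
            rot = np.concatenate([frag[ph:], frag[:ph]])
            cons = grp.seqs[row]
            called = cons != 255
            n_err += int((cons[called] != rot[called]).sum())
            n_base += int(called.sum())
    e = error_rate
    bound = 3 * e ** 2 * (1 - e) + e ** 3
    sigma = float(np.sqrt(bound * (1 - bound) / n_base))
    return {"error_rate": n_err / n_base, "bound": bound,
            "bound_plus_3sigma": bound + 3 * sigma, "n_bases": n_base}


def spectrum_recovery_experiment(seed: int = 0, genome_len: int = 100_000,
                                 inject_rate: float = 1e-4,
                                 n_molecules: int = 2000,
                                 target_events: float = 550.0,
                                 error_rate: float = 0.001) -> dict:
    """End-to-end recovery: inject -> reads -> consensus -> place -> spectrum.

    The C->T editing rate at 5'TCG3' motifs is injected at ``inject_rate``
    per site per molecule; the read number is sized so that the expected
    number of edited sites observed in consensus fragments is
    ``target_events``.  Returns the relative error of the recovered
    C:G>T:A rate against the realised injected truth and the top-ranked
    triplet context.
    """
    ref = generate_reference(genome_len, 0.5, seed=seed, circular=True)
    model = MutationModel.motif_model(tcg_c_to_t=inject_rate)
    eff = model.effective_rates(ref)
    k_sites = int((eff.sum(axis=1) > 0).sum())
    mean_frag = 105.0
    n_reads = int(np.ceil(target_events
                          / (k_sites * inject_rate * mean_frag / genome_len)))
    pool, truth = inject_mutations(ref, model, n_molecules, seed=seed + 1)
    res = consensus_spectrum_pipeline(pool, n_reads, QCParams(),
                                      error_rate=error_rate, seed=seed + 2)
    codes = ref.codes
    n_cg = int(np.isin(codes, (1, 2)).sum())
    truth_rate = len(truth) / (n_molecules * n_cg)
    est = res.spectrum.frequency("C:G>T:A")
    return {
        "estimated_rate": est,
        "truth_rate": truth_rate,
        "relative_error": abs(est - truth_rate) / truth_rate,
        "top_context": res.contexts.top_context("C:G>T:A"),
        "n_events_called": int(res.spectrum.table.loc["C:G>T:A", "numerator"]),
        "n_reads": n_reads,
        "report": res.report,
    }


def false_positive_experiment(seed: int = 0, n_reads: int = 100_000,
                              error_rate: float = 0.01) -> dict:
    """Called substitution rate with zero injected mutations.

    With per-base read error 1% and min_copies=3 consensus, the total
    substitution call rate per site-observation must stay below the
    3-copy majority-vote bound of 3e-4.
    """
    ref = generate_reference(20_000, 0.5, seed=seed, circular=True)
    pool, _ = inject_mutations(ref, MutationModel.motif_model(), 10, seed=seed + 1)
    res = consensus_spectrum_pipeline(pool, n_reads, QCParams(min_copies=3),
                                      error_rate=error_rate, seed=seed + 2,
                                      chunk_size=50_000)
    n_calls = int(res.spectrum.table["numerator"].sum())
    n_site_obs = int(res.tally.coverage.sum())
    return {"substitution_rate": n_calls / n_site_obs, "n_calls": n_calls,
            "n_site_observations": n_site_obs, "report": res.report}


def rc_invariance_experiment(seed: int = 0, n_reads: int = 800) -> dict:
    """Full-pipeline reverse-complement invariance (exact).

    Runs consensus -> placement -> tally -> spectrum/context tables on a
    simulated dataset, then again with the reference and every read
    reverse-complemented, and checks the outputs for exact equality.
    """
    ref = generate_reference(5000, 0.5, seed=seed, circular=True)
    pool, _ = inject_mutations(
        ref, MutationModel.motif_model(tcg_c_to_t=2e-3, gaa_a_to_g=1e-3),
        20, seed=seed + 1)
    reads = simulate_rollingcircle_reads(pool, n_reads, error_rate=0.005,
                                         seed=seed + 2)
    tuples = [reads.read(i) for i in range(len(reads))]

    def run(ref_, tuples_):
        cset, _ = consensus_batch(tuples_, QCParams())
        idx = ReferenceIndex(ref_, 21, max_query_len=512)
        pl = from_single_placements(
            [place_consensus(c, ref_, index=idx) for c in cset.iter_consensus()],
            ref_)
        t = tally(pl, ref_)
        return spectrum(t, ref_), context_spectrum(t, ref_)

    sp1, cx1 = run(ref, tuples)
    sp2, cx2 = run(ref.reverse_complement(),
                   [(rid, revcomp(s), q[::-1]) for rid, s, q in tuples])
    return {
        "spectrum_equal": bool(sp1.table.equals(sp2.table)),
        "contexts_equal": bool(
            cx1.table("C:G>T:A").equals(cx2.table("C:G>T:A"))
            and cx1.table("A:T>G:C").equals(cx2.table("A:T>G:C"))),
        "n_events": int(sp1.table["numerator"].sum()),
    }


def kinetics_recovery_experiment(seed: int = 0, n_replicates: int = 200,
                                 noise_sd: float = 0.02) -> dict:
    """Median relative error of fitted k_app across the kinetic regimes.

    Rate constants span the slow linear-substrate regime (3e-4 min^-1) to
    the fast tRNA regime (3e-2 min^-1); each replicate is one noisy time
    course sampled on a grid scaled to ~4 half-lives, as in bench kinetics.
    """
    grid = np.array([0.0, 0.1, 0.2, 0.4, 0.7, 1.0, 1.5, 2.2, 3.0, 4.0])
    out = {}
    ss = np.random.SeedSequence(seed)
    for k_true, child in zip((3e-4, 2e-3, 8e-3, 3e-2),
                             ss.spawn(4)):
        times = grid / k_true
        rel = []
        rep_seeds = child.generate_state(n_replicates) % (2 ** 31)
        for r in range(n_replicates):
            tcs = simulate_timecourse(k_true, 1.0, times, noise_sd=noise_sd,
                                      seed=int(rep_seeds[r]))
            fit = deamkin.fit_kapp(tcs)
            rel.append(abs(fit.k_app - k_true) / k_true)
        out[k_true] = float(np.median(rel))
    return out


def wilcoxon_oracle_experiment(seed: int = 0) -> dict:
    """Exact rank-sum p-values vs brute-force enumeration for all group
    sizes up to 8, on seeded continuous (tie-free) samples."""
    rng = np.random.default_rng(seed)
    max_diff = 0.0
    n_cases = 0
    for n1 in range(3, 9):
        for n2 in range(3, 9):
            a = rng.normal(0.5, 1.0, n1)
            b = rng.normal(0.0, 1.0, n2)
            p, method = rank_sum_p(a, b)
            assert method == "exact"
            pooled = np.concatenate([a, b])
            ranks = pd.Series(pooled).rank().to_numpy()
            obs = ranks[:n1].sum()
            stats_all = np.array([ranks[list(ix)].sum()
                                  for ix in combinations(range(n1 + n2), n1)])
            p_ref = min(1.0, 2 * min(float(np.mean(stats_all <= obs)),
                                     float(np.mean(stats_all >= obs))))
            max_diff = max(max_diff, abs(p - p_ref))
            n_cases += 1
    return {"max_abs_p_difference": max_diff, "n_cases": n_cases}
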