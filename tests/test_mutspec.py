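"""Placement, tallying and spectrum computation, with naive-accumulation
oracles and the reverse-complement collapsing rules."""

import numpy as np
import pandas as pd
import pytest

from deamscan.errors import InvalidDesignError
from deamscan.mutspec import (Abstention, Placement, ReferenceIndex,
                              compare_groups, context_spectrum,
                              from_single_placements, place_batch,
                              place_consensus, spectrum, tally)
from deamscan.rollcons import QCParams, consensus_batch
from deamscan.seqs import encode, revcomp
from deamscan.syndata import (MutationModel, ReferenceGenome,
                              generate_reference, inject_mutations,
                              simulate_rollingcircle_reads)


def pick_substring(ref, start, length):
    """Substring chosen so the fragment boundary cannot slide (the base just
    5' of the window differs from its last base, and symmetrically)."""
    s = ref.sequence
    while not (s[start - 1] != s[start + length - 1]
               and s[start] != s[start + length]):
        start += 1
    return start, s[start:start + length]


class TestPlaceConsensus:
    def test_exact_unique_substring(self, small_ref):
        start, frag = pick_substring(small_ref, 500, 100)
        r = place_consensus(frag, small_ref)
        assert isinstance(r, Placement)
        assert r.ref_start == start + 1
        assert r.strand == "+" and r.n_mismatch == 0 and not r.mismatches

    def test_single_substitution_recorded(self, small_ref):
        start, frag = pick_substring(small_ref, 700, 100)
        mutated = list(frag)
        old = mutated[50]
        new = {"A": "G", "C": "T", "G": "A", "T": "C"}[old]
        mutated[50] = new
        r = place_consensus("".join(mutated), small_ref)
        assert isinstance(r, Placement)
        assert r.ref_start == start + 1
        assert r.mismatches == [(start + 51, old, new)]

    def test_minus_strand_mapped_to_top(self, small_ref):
        start, frag = pick_substring(small_ref, 900, 100)
        r = place_consensus(revcomp(frag), small_ref)
        assert isinstance(r, Placement)
        assert r.strand == "-"
        assert r.ref_start == start + 1 and r.n_mismatch == 0

    def test_rotated_fragment_recovers_location(self, small_ref):
        start, frag = pick_substring(small_ref, 1100, 100)
        rot = frag[37:] + frag[:37]
        r = place_consensus(rot, small_ref)
        assert isinstance(r, Placement)
        assert r.ref_start == start + 1 and r.n_mismatch == 0

    def test_repeated_region_abstains_ambiguous(self):
        core = generate_reference(400, 0.5, seed=55).sequence
        seq = core + core  # two identical copies
        ref = ReferenceGenome("rep", seq)
        r = place_consensus(core[100:200], ref)
        assert isinstance(r, Abstention) and r.reason == "ambiguous"

    def test_reference_shorter_than_consensus_abstains(self):
        ref = ReferenceGenome("tiny", "ACGTACGTACGTACGTACGTACGTA")
        r = place_consensus("A" * 30, ref)
        assert isinstance(r, Abstention)
        assert r.reason == "reference_too_short"

    def test_unmatchable_consensus_abstains(self, small_ref):
        r = place_consensus("ACGT" * 25, small_ref)
        assert isinstance(r, Abstention) and r.reason == "no_placement"


class TestTally:
    def test_no_placements_zero(self, small_ref):
        pl = from_single_placements([], small_ref)
        t = tally(pl, small_ref)
        assert t.coverage.sum() == 0 and t.counts.sum() == 0

    def test_conservation_and_single_mismatch(self, small_ref):
        start, frag = pick_substring(small_ref, 500, 100)
        mutated = list(frag)
        mutated[10] = {"A": "G", "C": "T", "G": "A", "T": "C"}[mutated[10]]
        r = place_consensus("".join(mutated), small_ref)
        t = tally(from_single_placements([r], small_ref), small_ref)
        t.validate()
        assert t.coverage.sum() == 100
        codes = small_ref.codes
        nonref = int(t.counts.sum() - t.counts[np.arange(2000), codes].sum())
        assert nonref == 1

    def test_overlap_coverage(self, small_ref):
        s1, f1 = pick_substring(small_ref, 500, 100)
        s2, f2 = pick_substring(small_ref, 550, 100)
        rs = [place_consensus(f, small_ref) for f in (f1, f2)]
        t = tally(from_single_placements(rs, small_ref), small_ref)
        overlap = np.arange(max(s1, s2), min(s1, s2) + 100)
        assert (t.coverage[overlap] == 2).all()

    def test_matches_naive_accumulation(self, circ_ref):
        pool, _ = inject_mutations(circ_ref, MutationModel.motif_model(2e-3),
                                   5, seed=60)
        reads = simulate_rollingcircle_reads(pool, 150, error_rate=0.005, seed=61)
        cset, _ = consensus_batch(reads)
        idx = ReferenceIndex(circ_ref, 21, max_query_len=512)
        results = [place_consensus(c, circ_ref, index=idx)
                   for c in cset.iter_consensus()]
        pl = from_single_placements(results, circ_ref)
        t = tally(pl, circ_ref)
        # naive python accumulation over Placement records
        L = len(circ_ref)
        cov = np.zeros(L, dtype=int)
        cnt = np.zeros((L, 4), dtype=int)
        codes = circ_ref.codes
        for r in results:
            if isinstance(r, Abstention):
                continue
            excl = set(r.n_positions)
            mm = {p - 1: o for p, _rb, o in r.mismatches}
            for d in range(r.length):
                pos = (r.ref_start - 1 + d) % L
                if pos in excl:
                    continue
                cov[pos] += 1
                b = mm.get(pos)
                cnt[pos, encode(b)[0] if b else codes[pos]] += 1
        assert np.array_equal(t.coverage, cov)
        assert np.array_equal(t.counts, cnt)

    def test_batch_equals_single_path(self, circ_ref):
        pool, _ = inject_mutations(circ_ref, MutationModel.motif_model(2e-3),
                                   5, seed=62)
        reads = simulate_rollingcircle_reads(pool, 200, error_rate=0.01, seed=63)
        cset, _ = consensus_batch(reads, QCParams(min_copies=2))
        idx = ReferenceIndex(circ_ref, 21, max_query_len=512)
        pl_b = place_batch(cset, circ_ref, index=idx)
        pl_s = from_single_placements(
            [place_consensus(c, circ_ref, index=idx)
             for c in cset.iter_consensus()], circ_ref)
        tb, ts = tally(pl_b, circ_ref), tally(pl_s, circ_ref)
        assert np.array_equal(tb.coverage, ts.coverage)
        assert np.array_equal(tb.counts, ts.counts)
        assert pl_b.n_placed == pl_s.n_placed


def manual_tally(ref, entries, coverage_sites):
    """Build a SiteTally by hand: entries are (pos0, obs_base)."""
    from deamscan.mutspec import SiteTally
    L = len(ref)
    cov = np.zeros(L, dtype=np.int64)
    cnt = np.zeros((L, 4), dtype=np.int64)
    codes = ref.codes
    for pos in coverage_sites:
        cov[pos] += 1
        cnt[pos, codes[pos]] += 1
    for pos, obs in entries:
        cov[pos] += 1
        cnt[pos, encode(obs)[0]] += 1
    return SiteTally(cov, cnt)


class TestSpectrum:
    def test_arithmetic_from_stated_formula(self):
        # 2 C->T and 1 G->A over 300 coverage-weighted C+G site-observations
        ref = ReferenceGenome("r", "ACG" * 200)
        codes = ref.codes
        cg = np.flatnonzero((codes == 1) | (codes == 2))
        c_sites = np.flatnonzero(codes == 1)
        g_sites = np.flatnonzero(codes == 2)
        entries = [(int(c_sites[0]), "T"), (int(c_sites[1]), "T"),
                   (int(g_sites[0]), "A")]
        t = manual_tally(ref, entries, cg[:297].tolist())
        sp = spectrum(t, ref)
        assert sp.table.loc["C:G>T:A", "numerator"] == 3
        assert sp.table.loc["C:G>T:A", "denominator"] == 300
        assert sp.frequency("C:G>T:A") == pytest.approx(0.01)

    def test_zero_mutations_and_zero_denominator(self):
        ref = ReferenceGenome("r", "ATATATAT")
        t = manual_tally(ref, [], [0, 1, 2])
        sp = spectrum(t, ref)
        assert (sp.table["frequency"] == 0).all()
        # no C/G coverage at all: frequency is an explicit 0, not NaN
        assert sp.frequency("C:G>T:A") == 0.0

    def test_context_collapsing_g_to_a_in_cga(self):
        # G->A whose top-strand triplet is CGA collapses to context TCG
        ref = ReferenceGenome("r", "AACGAAA")
        t = manual_tally(ref, [(3, "A")], [1, 2, 4])
        cx = context_spectrum(t, ref)
        tab = cx.table("C:G>T:A")
        assert tab.loc["TCG", "numerator"] == 1
        assert tab["numerator"].sum() == 1

    def test_context_partition_sums_to_type_numerator(self, circ_ref):
        pool, _ = inject_mutations(circ_ref,
                                   MutationModel.motif_model(3e-3, 2e-3),
                                   10, seed=70)
        reads = simulate_rollingcircle_reads(pool, 300, error_rate=0.0, seed=71)
        cset, _ = consensus_batch(reads)
        pl = place_batch(cset, circ_ref)
        t = tally(pl, circ_ref)
        sp = spectrum(t, circ_ref)
        cx = context_spectrum(t, circ_ref)
        for typ in ("C:G>T:A", "A:T>G:C"):
            assert (cx.table(typ)["numerator"].sum()
                    == sp.table.loc[typ, "numerator"])

    def test_per_context_denominators_sum_to_total(self, circ_ref):
        pool, _ = inject_mutations(circ_ref, MutationModel.motif_model(3e-3),
                                   5, seed=72)
        reads = simulate_rollingcircle_reads(pool, 100, error_rate=0.0, seed=73)
        cset, _ = consensus_batch(reads)
        t = tally(place_batch(cset, circ_ref), circ_ref)
        total = context_spectrum(t, circ_ref, "total")
        per = context_spectrum(t, circ_ref, "per-context")
        for typ in ("C:G>T:A", "A:T>G:C"):
            tot = total.table(typ)["denominator"].iloc[0]
            assert (total.table(typ)["denominator"] == tot).all()
            assert per.table(typ)["denominator"].sum() == tot


class TestCompareGroups:
    def _frame(self, groups):
        rows = []
        for g, vals in groups.items():
            rows += [(g, v) for v in vals]
        return pd.DataFrame(rows, columns=["group", "frequency"])

    def test_identical_groups_not_significant(self):
        df = self._frame({"a": [1.0, 1.0, 1.0], "b": [1.0, 1.0, 1.0],
                          "c": [1.0, 1.0, 1.0]})
        out = compare_groups(df, n_permutations=200, seed=1)
        tukey = out[out["test"] == "tukey"]
        assert (tukey["p_value"] == 1.0).all()

    def test_large_shift_detected_by_tukey(self, rng):
        base = rng.normal(0.0, 1.0, 3)
        df = self._frame({
            "ctrl1": rng.normal(0, 1, 3),
            "ctrl2": rng.normal(0, 1, 3),
            "shifted": rng.normal(10.0, 1.0, 3),  # 10 within-group SDs away
        })
        out = compare_groups(df, n_permutations=200, seed=2)
        tukey = out[out["test"] == "tukey"]
        hit = tukey[(tukey["group1"] == "shifted") | (tukey["group2"] == "shifted")]
        assert (hit["p_value"] < 0.05).all()

    def test_anova_and_permutation_agree(self, rng):
        df = self._frame({
            "a": rng.normal(0.0, 1.0, 6),
            "b": rng.normal(1.2, 1.0, 6),
            "c": rng.normal(0.4, 1.0, 6),
        })
        out = compare_groups(df, n_permutations=20_000, seed=3)
        p_anova = float(out.loc[out["test"] == "anova", "p_value"].iloc[0])
        p_perm = float(out.loc[out["test"] == "permutation", "p_value"].iloc[0])
        assert abs(p_anova - p_perm) < 0.03  # Monte-Carlo + F-approximation slack

    def test_single_replicate_group_rejected(self):
        df = self._frame({"a": [1.0], "b": [1.0, 2.0]})
        with pytest.raises(InvalidDesignError):
            compare_groups(df, n_permutations=10)
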