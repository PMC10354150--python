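"""Generator contracts: composition, motif-biased injection, tandem reads,
time courses and fluctuation counts, plus determinism and strand symmetry."""

import re

import numpy as np
import pandas as pd
import pytest

from deamscan.errors import InvalidArgumentError, InvalidModelError
from deamscan.syndata import (MutationModel, QualityModel, ReferenceGenome,
                              generate_reference, inject_mutations,
                              simulate_fluctuation_assay,
                              simulate_rollingcircle_reads,
                              simulate_timecourse, truth_context_counts,
                              truth_type_counts)


class TestGenerateReference:
    def test_length_and_alphabet(self):
        ref = generate_reference(10_000, 0.5, seed=1)
        assert len(ref.sequence) == 10_000
        assert set(ref.sequence) <= set("ACGT")

    def test_degenerate_gc(self):
        ref = generate_reference(500, 1.0, seed=2)
        assert set(ref.sequence) <= {"G", "C"}
        ref = generate_reference(500, 0.0, seed=2)
        assert set(ref.sequence) <= {"A", "T"}

    def test_gc_fraction_within_binomial_band(self):
        # 3 sigma for n=100000, p=0.5 is ~0.0047, well inside +/-0.01
        ref = generate_reference(100_000, 0.5, seed=7)
        gc = (ref.sequence.count("G") + ref.sequence.count("C")) / 100_000
        assert abs(gc - 0.5) < 0.01

    def test_reproducible(self):
        a = generate_reference(1000, 0.4, seed=5)
        b = generate_reference(1000, 0.4, seed=5)
        assert a.sequence == b.sequence

    def test_too_short_rejected(self):
        with pytest.raises(InvalidArgumentError):
            generate_reference(2, 0.5, seed=1)


class TestInjectMutations:
    def test_null_model(self):
        ref = generate_reference(2000, 0.5, seed=3)
        pool, truth = inject_mutations(ref, MutationModel.motif_model(), 5, seed=4)
        assert truth.empty
        assert pool.sequence(0) == ref.sequence

    def test_forced_hit_at_single_motif(self):
        # TCGT: the G's own context (CGT) is not a reverse-complement TCG,
        # so exactly one editable site exists
        ref = ReferenceGenome("one_motif", "A" * 20 + "TCGT" + "A" * 20)
        model = MutationModel.motif_model(tcg_c_to_t=1.0)
        pool, truth = inject_mutations(ref, model, 8, seed=5)
        assert len(truth) == 8
        assert (truth["position"] == 22).all()
        assert (truth["ref"] == "C").all() and (truth["alt"] == "T").all()
        assert pool.sequence(0)[21] == "T"

    def test_bottom_strand_motif_is_hit_symmetrically(self):
        # poly-A flanks turn ...TCGA... into motifs on both strands:
        # top-strand TCG (C->T) and bottom-strand TCG seen as CGA (G->A)
        ref = ReferenceGenome("two_strands", "A" * 20 + "TCGA" + "A" * 20)
        model = MutationModel.motif_model(tcg_c_to_t=1.0)
        _, truth = inject_mutations(ref, model, 4, seed=6)
        per_mol = truth.groupby("molecule_id")
        assert len(truth) == 8
        for _, g in per_mol:
            assert set(zip(g["position"], g["ref"], g["alt"])) == {
                (22, "C", "T"), (23, "G", "A")}

    def test_motif_count_within_binomial_band(self):
        ref = generate_reference(30_000, 0.5, seed=6, circular=True)
        rate = 5e-3
        model = MutationModel.motif_model(tcg_c_to_t=rate)
        n_mol = 40
        pool, truth = inject_mutations(ref, model, n_mol, seed=7)
        # independent motif count: overlapping scan on both strands
        doubled = ref.sequence + ref.sequence[:2]
        k = len(re.findall(r"(?=TCG)", doubled)) + len(re.findall(r"(?=CGA)", doubled))
        mean = k * n_mol * rate
        sd = np.sqrt(k * n_mol * rate * (1 - rate))
        assert abs(len(truth) - mean) < 3 * sd
        assert set(truth_type_counts(truth).drop("C:G>T:A").unique()) == {0}

    def test_strand_symmetry_of_injected_spectrum(self):
        ref = generate_reference(20_000, 0.5, seed=8, circular=True)
        model = MutationModel.motif_model(tcg_c_to_t=2e-3, gaa_a_to_g=1e-3)
        _, truth = inject_mutations(ref, model, 20, seed=9)
        assert len(truth) > 10
        # reverse complement the genome and remap the truth records
        L = len(ref)
        rc_truth = pd.DataFrame({
            "molecule_id": truth["molecule_id"],
            "position": L + 1 - truth["position"],
            "ref": truth["ref"].map(dict(zip("ACGT", "TGCA"))),
            "alt": truth["alt"].map(dict(zip("ACGT", "TGCA"))),
        })
        rc_ref = ref.reverse_complement()
        assert truth_type_counts(truth).equals(truth_type_counts(rc_truth))
        a = truth_context_counts(truth, ref)
        b = truth_context_counts(rc_truth, rc_ref)
        assert a.equals(b)

    def test_rate_above_one_rejected(self):
        ref = generate_reference(1000, 0.5, seed=1)
        model = MutationModel(base_rates={"C:G>T:A": 0.6},
                              context_multipliers={("TCG", "C:G>T:A"): 2.0})
        with pytest.raises(InvalidModelError):
            model.effective_rates(ref)

    def test_context_key_must_be_collapsed(self):
        with pytest.raises(InvalidModelError):
            MutationModel(base_rates={"C:G>T:A": 0.1},
                          context_multipliers={("CGA", "C:G>T:A"): 1.0})


class TestRollingCircleReads:
    def test_noiseless_tandem_structure(self):
        ref = generate_reference(5000, 0.5, seed=10, circular=True)
        pool, _ = inject_mutations(ref, MutationModel.motif_model(), 3, seed=11)
        reads = simulate_rollingcircle_reads(
            pool, 20, error_rate=0.0, quality_model=QualityModel(low_prob=0),
            seed=12)
        for i in range(len(reads)):
            _, s, _ = reads.read(i)
            p = int(reads.sidecar.fragment_len[i])
            assert all(s[j] == s[j + p] for j in range(len(s) - p))

    def test_read_is_phase_rotated_fragment(self):
        ref = generate_reference(5000, 0.5, seed=13, circular=True)
        pool, _ = inject_mutations(ref, MutationModel.motif_model(), 2, seed=14)
        reads = simulate_rollingcircle_reads(
            pool, 10, frag_len_range=(120, 120), read_len=150, error_rate=0.0,
            quality_model=QualityModel(low_prob=0), seed=15)
        for i in range(len(reads)):
            _, s, _ = reads.read(i)
            sc = reads.sidecar.iloc[i]
            st, ph = int(sc.fragment_start) - 1, int(sc.phase)
            frag = "".join(ref.sequence[(st + j) % 5000] for j in range(120))
            rot = frag[ph:] + frag[:ph]
            # exactly one full copy plus a 30-base partial second copy
            assert s[:120] == rot and s[120:] == rot[:30]

    def test_error_rate_within_binomial_band(self):
        ref = generate_reference(5000, 0.5, seed=16, circular=True)
        pool, _ = inject_mutations(ref, MutationModel.motif_model(), 2, seed=17)
        e = 0.01
        reads = simulate_rollingcircle_reads(
            pool, 400, error_rate=e, quality_model=QualityModel(low_prob=0),
            seed=18)
        n = mism = 0
        for i in range(len(reads)):
            _, s, _ = reads.read(i)
            sc = reads.sidecar.iloc[i]
            st, ph, fl = int(sc.fragment_start) - 1, int(sc.phase), int(sc.fragment_len)
            frag = "".join(ref.sequence[(st + j) % 5000] for j in range(fl))
            truth = "".join(frag[(ph + j) % fl] for j in range(len(s)))
            mism += sum(a != b for a, b in zip(s, truth))
            n += len(s)
        assert n >= 100_000
        sd = np.sqrt(e * (1 - e) / n)
        assert abs(mism / n - e) < 3 * sd

    def test_fastq_byte_identical_for_same_seed(self, tmp_path):
        ref = generate_reference(3000, 0.5, seed=19, circular=True)
        pool, _ = inject_mutations(ref, MutationModel.motif_model(), 2, seed=20)
        paths = []
        for run in range(2):
            reads = simulate_rollingcircle_reads(pool, 50, error_rate=0.01, seed=21)
            p = tmp_path / f"run{run}.fq"
            reads.to_fastq(p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_paired_mode_emits_two_mates(self):
        ref = generate_reference(3000, 0.5, seed=22, circular=True)
        pool, _ = inject_mutations(ref, MutationModel.motif_model(), 2, seed=23)
        reads = simulate_rollingcircle_reads(pool, 10, paired_or_merged="paired",
                                             read_len=300, error_rate=0.0, seed=24)
        assert len(reads) == 20
        assert reads.seqs.shape[1] == 150
        assert reads.ids[0].endswith("/1") and reads.ids[1].endswith("/2")

    def test_invalid_read_geometry_rejected(self):
        ref = generate_reference(3000, 0.5, seed=25, circular=True)
        pool, _ = inject_mutations(ref, MutationModel.motif_model(), 2, seed=26)
        with pytest.raises(InvalidArgumentError):
            simulate_rollingcircle_reads(pool, 5, frag_len_range=(90, 120),
                                         read_len=80, seed=1)
        with pytest.raises(InvalidArgumentError):
            simulate_rollingcircle_reads(pool, 5, error_rate=0.6, seed=1)


class TestTimeCourse:
    def test_closed_forms(self):
        k = 0.008
        tcs = simulate_timecourse(k, 1.0, [0, np.log(2) / k, 600], noise_sd=0.0)
        f = tcs[0].fractions
        assert f[0] == 0.0
        assert f[1] == pytest.approx(0.5, abs=1e-12)

    def test_null_rate(self):
        tcs = simulate_timecourse(0.0, 1.0, [0, 10, 100], noise_sd=0.0)
        assert np.all(tcs[0].fractions == 0.0)

    def test_noise_clamped_and_seeded(self):
        a = simulate_timecourse(0.01, 0.9, range(0, 200, 20), noise_sd=0.3,
                                n_replicates=3, seed=1)
        b = simulate_timecourse(0.01, 0.9, range(0, 200, 20), noise_sd=0.3,
                                n_replicates=3, seed=1)
        for x, y in zip(a, b):
            assert np.array_equal(x.fractions, y.fractions)
            assert np.all((x.fractions >= 0) & (x.fractions <= 1))

    def test_negative_times_rejected(self):
        with pytest.raises(InvalidArgumentError):
            simulate_timecourse(0.01, 1.0, [-1, 0, 10])


class TestFluctuationAssay:
    def test_null_frequency(self):
        counts = simulate_fluctuation_assay(20, 1e8, 0.0, seed=1)
        assert (counts.records["resistant_colonies"] == 0).all()

    def test_poisson_mean_within_band(self):
        counts = simulate_fluctuation_assay(1000, 1e8, 4e-8, seed=2)
        mean = counts.records["resistant_colonies"].mean()
        assert abs(mean - 4.0) < 3 * np.sqrt(4.0 / 1000)

    def test_scaling_doubles_expected_counts(self):
        a = simulate_fluctuation_assay(2000, 1e8, 4e-8, seed=3)
        b = simulate_fluctuation_assay(2000, 2e8, 4e-8, seed=3)
        ma = a.records["resistant_colonies"].mean()
        mb = b.records["resistant_colonies"].mean()
        assert mb == pytest.approx(2 * ma, rel=0.25)
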