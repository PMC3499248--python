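import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import generosion as g
from generosion.genomes_io import revcomp
from generosion.ortholog_compare import (
    PairwiseAlignment,
    excise_is_elements,
    nonsense_codons,
)


def sw_affine_score(a, b, match=1.0, mismatch=-2.0, gap_open=-5.0, gap_ext=-1.0):
    """Exhaustive affine-gap Smith-Waterman oracle (gap length L costs
    gap_open + gap_ext*L), independent of the library aligner."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(0.0, max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s)
            X[i][j] = max(M[i - 1][j] + gap_open + gap_ext, X[i - 1][j] + gap_ext)
            Y[i][j] = max(M[i][j - 1] + gap_open + gap_ext, Y[i][j - 1] + gap_ext)
            best = max(best, M[i][j])
    return best


class TestAlignOrf:
    def test_identical_sequences(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 300))
        aln = g.align_orf(seq, seq)
        assert aln.ref_coverage == 1.0
        assert aln.indels == [] and aln.substitutions == []
        assert aln.score == 300

    def test_single_deletion_detected(self, rng):
        ref = "".join(rng.choice(list("ACGT"), 300))
        qry = ref[:150] + ref[151:]
        aln = g.align_orf(ref, qry)
        assert len(aln.indels) == 1
        pos, size, kind = aln.indels[0]
        assert (size, kind) == (1, "del")
        events = g.extract_mutations(aln)
        assert [e.category for e in events] == ["internal_deletion"]
        assert events[0].frameshifting

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        st.text(alphabet="ACGT", min_size=1, max_size=20),
        st.text(alphabet="ACGT", min_size=1, max_size=20),
    )
    def test_score_equals_bruteforce_dp_oracle(self, ref, qry):
        score = g.Scoring().aligner().score(ref, qry)
        assert score == pytest.approx(sw_affine_score(ref, qry))

    def test_fast_path_score_consistent_with_aligner(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 80))
        assert g.align_orf(seq, seq).score == g.Scoring().aligner().score(seq, seq)

    def test_score_invariant_under_joint_reverse_complement(self, rng):
        ref = "".join(rng.choice(list("ACGT"), 120))
        qry = ref[:50] + "TT" + ref[53:]
        a = g.align_orf(ref, qry)
        b = g.align_orf(revcomp(ref), revcomp(qry))
        assert a.score == b.score

    def test_gapped_strings_reproduce_sequences(self, rng):
        ref = "".join(rng.choice(list("ACGT"), 200))
        qry = ref[:60] + "ACGTA" + ref[60:140] + ref[145:]
        aln = g.align_orf(ref, qry)
        assert len(aln.aligned_ref) == len(aln.aligned_qry)
        assert aln.aligned_ref.replace("-", "") == ref[aln.ref_start : aln.ref_end]
        assert aln.aligned_qry.replace("-", "") == qry[aln.qry_start : aln.qry_end]

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            g.align_orf("", "ACGT")


def _fake_alignment(ref_len, ref_start, ref_end, **kw):
    n = ref_end - ref_start
    return PairwiseAlignment(
        gene_id="x", ref_len=ref_len, qry_len=n, ref_start=ref_start, ref_end=ref_end,
        qry_start=0, qry_end=n, aligned_ref="A" * n, aligned_qry="A" * n,
        score=float(n), **kw,
    )


class TestClassifyOrtholog:
    def test_long_gene_high_coverage_clean_is_intact(self):
        aln = _fake_alignment(1000, 0, 995)
        assert g.classify_ortholog(aln, 1000, events=[]).status == "intact"

    def test_short_gene_90_percent_rule(self):
        aln = _fake_alignment(250, 0, 230)  # coverage 0.92
        assert g.classify_ortholog(aln, 250, events=[]).status == "intact"
        aln2 = _fake_alignment(1000, 0, 920)  # 0.92 fails the >99% rule
        assert g.classify_ortholog(aln2, 1000, events=[]).status == "pseudogene"

    def test_frameshifting_indel_forces_pseudogene(self):
        aln = _fake_alignment(1000, 0, 1000)
        ev = [g.MutationEvent("x", "internal_deletion", 500, 1)]
        cls = g.classify_ortholog(aln, 1000, events=ev)
        assert cls.status == "pseudogene"
        assert "frameshift_indel" in cls.reasons

    def test_in_frame_indel_alone_keeps_intact(self):
        aln = _fake_alignment(1000, 0, 1000)
        ev = [g.MutationEvent("x", "internal_deletion", 500, 6)]
        assert g.classify_ortholog(aln, 1000, events=ev).status == "intact"

    def test_premature_stop_forces_pseudogene(self):
        aln = _fake_alignment(1000, 0, 1000)
        ev = [g.MutationEvent("x", "nonsense", 300, 0)]
        assert g.classify_ortholog(aln, 1000, events=ev).status == "pseudogene"

    def test_low_coverage_is_absent(self):
        aln = _fake_alignment(1000, 0, 50)
        assert g.classify_ortholog(aln, 1000, events=[]).status == "absent"

    def test_not_found_is_absent(self):
        assert g.classify_ortholog(None, 1000, found=False).status == "absent"


class TestExtractMutations:
    def test_nonsense_from_tgg_to_tga(self):
        ref = "ATG" + "TGG" * 10 + "AAA" + "TAA"
        qry = ref[:9] + "TGA" + ref[12:]
        aln = g.align_orf(ref, qry)
        events = g.extract_mutations(aln)
        assert [e.category for e in events] == ["nonsense"]
        assert events[0].ref_position == 9

    def test_clean_alignment_yields_no_events(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 150))
        assert g.extract_mutations(g.align_orf(seq, seq)) == []

    def test_unaligned_five_prime_region_reported(self, rng):
        ref = "".join(rng.choice(list("ACGT"), 1000))
        qry = ref[120:]
        aln = g.align_orf(ref, qry)
        events = g.extract_mutations(aln)
        assert [(e.category, e.size) for e in events] == [("five_prime_deletion", 120)]

    def test_catalog_insertion_in_alignment_is_is_element(self, rng):
        is_seq = g.make_is_element(rng, 1200)
        aln = _fake_alignment(2000, 0, 2000)
        aln.indels = [(800, 1200, "ins")]
        aln.insert_seqs = {800: is_seq}
        events = g.extract_mutations(aln, is_catalog=[is_seq])
        assert [e.category for e in events] == ["is_element"]
        events2 = g.extract_mutations(aln, is_catalog=[])
        assert [e.category for e in events2] == ["internal_insertion"]

    def test_excision_recovers_clean_gene(self, rng):
        is_seq = g.make_is_element(rng, 900)
        gene = "".join(rng.choice(list("ACGT"), 600))
        qry = gene[:300] + is_seq + gene[300:]
        cleaned, excised = excise_is_elements(qry, [is_seq])
        assert cleaned == gene
        assert excised == [(300, 900)]

    def test_frameshift_does_not_create_false_nonsense(self):
        # a 1-bp deletion shifts the biological frame, but projection onto the
        # ancestral frame through gap-free columns must stay stop-free
        ref = "ATG" + "GAACTGCTG" * 20 + "TAA"
        qry = ref[:30] + ref[31:]
        aln = g.align_orf(ref, qry)
        assert nonsense_codons(aln) == []


class TestSpectrum:
    def test_empty_events(self):
        import pandas as pd

        table = g.spectrum(pd.DataFrame(columns=["gene_id", "category"]))
        assert table["total_disrupting_mutations"].iloc[0] == 0

    def test_all_nonsense(self):
        import pandas as pd

        ev = pd.DataFrame({"gene_id": [f"g{i}" for i in range(10)], "category": ["nonsense"] * 10})
        table = g.spectrum(ev)
        assert table["nonsense_percent"].iloc[0] == 100
        assert table["internal_deletion_percent"].iloc[0] == 0


class TestDensityAndDispersion:
    def test_density_modes(self):
        assert g.mutation_density(2, 1000) == pytest.approx(2.0)
        assert g.mutation_density(2, 1000, 500, mode="current") == pytest.approx(4.0)
        assert np.isnan(g.mutation_density(2, 1000, 0, mode="current"))

    def test_constant_counts_have_zero_vmr(self):
        vmr, _, _ = g.poisson_dispersion([3, 3, 3, 3])
        assert vmr == 0.0

    def test_poisson_counts_vmr_near_one(self, rng):
        counts = rng.poisson(2.0, 2000)
        vmr, _, p = g.poisson_dispersion(counts)
        assert 0.9 < vmr < 1.1

    def test_mixture_is_overdispersed(self, rng):
        counts = np.where(rng.random(2000) < 0.5, rng.poisson(1.0, 2000), rng.poisson(6.0, 2000))
        vmr, _, p = g.poisson_dispersion(counts)
        assert vmr > 1.2
        assert p < 1e-6

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            g.poisson_dispersion([0, 0, 0])
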