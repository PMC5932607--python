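"""Cosine similarity, trinucleotide frequencies, humanization and catalog
matching."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mmrsig import channels as ch
from mmrsig.compare import (
    CPG_CT_CHANNELS,
    compute_trinuc_frequencies,
    cosine_distance_matrix,
    cosine_similarity,
    humanize,
    match_to_catalog,
)


class TestCosine:
    def test_identical_vectors(self):
        v = np.array([1.0, 2.0, 3.0])
        assert cosine_similarity(v, v) == pytest.approx(1.0)

    def test_disjoint_support(self):
        assert cosine_similarity([1, 0, 0], [0, 1, 1]) == pytest.approx(0.0)

    def test_hand_computed(self):
        assert cosine_similarity([1, 1, 0], [1, 0, 1]) == pytest.approx(0.5)

    def test_scale_invariance(self):
        a, b = np.array([0.2, 0.5, 0.1]), np.array([0.3, 0.3, 0.9])
        assert cosine_similarity(3.7 * a, b) == pytest.approx(cosine_similarity(a, 11 * b))

    def test_zero_vector_errors(self):
        with pytest.raises(ValueError):
            cosine_similarity([0, 0], [1, 1])


def oracle_trinuc_counts(seqs):
    """Brute-force 3-mer enumeration with revcomp collapse."""
    counts = {}
    for seq in seqs:
        for i in range(len(seq) - 2):
            tri = seq[i : i + 3]
            if any(b not in "ACGT" for b in tri):
                continue
            if tri[1] in "AG":
                tri = ch.reverse_complement(tri)
            counts[tri] = counts.get(tri, 0) + 1
    return counts


class TestTrinucFrequencies:
    def test_small_sequence_against_oracle(self):
        genome = {"c": "ACAACA"}
        freqs = compute_trinuc_frequencies(genome)
        expected = oracle_trinuc_counts(["ACAACA"])
        nonzero = freqs[freqs > 0].astype(int).to_dict()
        assert nonzero == expected
        assert nonzero == {"ACA": 2, "TTG": 1, "GTT": 1}

    def test_poly_a_collapses_to_ttt(self):
        freqs = compute_trinuc_frequencies({"c": "A" * 10})
        assert freqs["TTT"] == 8 and freqs.sum() == 8

    def test_total_is_conserved(self, sim_genome):
        genome, _ = sim_genome
        freqs = compute_trinuc_frequencies(genome)
        assert freqs.sum() == sum(len(s) - 2 for s in genome.values())

    def test_normalized_sums_to_one(self, tiny_genome):
        freqs = compute_trinuc_frequencies(tiny_genome, normalize=True)
        assert freqs.sum() == pytest.approx(1.0)

    def test_region_restriction_and_bounds(self, tiny_genome):
        sub = compute_trinuc_frequencies(tiny_genome, regions=[("chrT", 0, 10)])
        assert sub.sum() == 8
        with pytest.raises(ValueError, match="out of bounds"):
            compute_trinuc_frequencies(tiny_genome, regions=[("chrT", 0, 10**6)])

    def test_n_containing_3mers_skipped(self):
        freqs = compute_trinuc_frequencies({"c": "ACNGT"})
        assert freqs.sum() == 0


@pytest.fixture
def two_freq_spaces(rng):
    f1 = pd.Series(rng.uniform(0.5, 2.0, 32), index=list(ch.PYRIMIDINE_CONTEXTS))
    f2 = pd.Series(rng.uniform(0.5, 2.0, 32), index=list(ch.PYRIMIDINE_CONTEXTS))
    return f1 / f1.sum(), f2 / f2.sum()


class TestHumanize:
    def test_identity_when_spaces_equal(self, two_freq_spaces, rng):
        f1, _ = two_freq_spaces
        p = rng.dirichlet(np.ones(96))
        assert np.allclose(humanize(p, f1, f1), p, atol=1e-12)

    def test_round_trip_inverse(self, two_freq_spaces, rng):
        f1, f2 = two_freq_spaces
        p = rng.dirichlet(np.ones(96))
        assert np.allclose(humanize(humanize(p, f1, f2), f2, f1), p, atol=1e-9)

    def test_against_per_channel_oracle(self, two_freq_spaces, rng):
        f1, f2 = two_freq_spaces
        p = rng.dirichlet(np.ones(96))
        w = np.empty(96)
        for i in range(96):
            label = ch.SUBSTITUTION_CHANNELS[i]
            context = label[0] + label[2] + label[6]
            w[i] = p[i] * f2[context] / f1[context]
        assert np.allclose(humanize(p, f1, f2), w / w.sum(), atol=1e-12)

    def test_doubling_one_context_scales_its_three_channels(self, two_freq_spaces, rng):
        f1, f2 = two_freq_spaces
        p = rng.dirichlet(np.ones(96))
        f2b = f2.copy()
        f2b["ACA"] *= 2.0
        base = humanize(p, f1, f2)
        boosted = humanize(p, f1, f2b)
        idx = [i for i in range(96) if ch.context_of_channel(i) == "ACA"]
        ratio = boosted[idx] / base[idx]
        others = [i for i in range(96) if i not in idx]
        # unnormalized weights double for the ACA channels; after
        # renormalization the ratio is 2x the common rescaling factor
        common = (boosted[others] / base[others])[0]
        assert np.allclose(ratio, 2.0 * common, rtol=1e-9)

    def test_indel_block_dropped_from_104(self, two_freq_spaces, rng):
        f1, f2 = two_freq_spaces
        p104 = rng.dirichlet(np.ones(104))
        out = humanize(p104, f1, f2)
        assert out.shape == (96,) and out.sum() == pytest.approx(1.0)

    def test_zero_source_frequency_errors(self, two_freq_spaces, rng):
        f1, f2 = two_freq_spaces
        f1["ACA"] = 0.0
        with pytest.raises(ValueError, match="zero source"):
            humanize(rng.dirichlet(np.ones(96)), f1, f2)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_round_trip_property(self, seed):
        rng = np.random.default_rng(seed)
        f1 = pd.Series(rng.uniform(0.1, 3.0, 32), index=list(ch.PYRIMIDINE_CONTEXTS))
        f2 = pd.Series(rng.uniform(0.1, 3.0, 32), index=list(ch.PYRIMIDINE_CONTEXTS))
        p = rng.dirichlet(np.ones(96))
        assert np.allclose(humanize(humanize(p, f1, f2), f2, f1), p, atol=1e-9)


class TestCatalogMatching:
    @pytest.fixture
    def catalog96(self, rng):
        rows = rng.dirichlet(np.ones(96), size=4)
        return pd.DataFrame(rows, index=[f"COSMIC-{i}" for i in range(4)],
                            columns=list(ch.SUBSTITUTION_CHANNELS))

    def test_exact_member_matches_itself(self, catalog96):
        q = catalog96.iloc[[2]].rename(index={"COSMIC-2": "query"})
        res = match_to_catalog(q, catalog96)
        assert res.loc["query", "best_match"] == "COSMIC-2"
        assert res.loc["query", "similarity"] == pytest.approx(1.0)
        assert bool(res.loc["query", "high"])

    def test_orthogonal_query_scores_zero(self):
        cat = pd.DataFrame(np.eye(96)[:2], index=["a", "b"],
                           columns=list(ch.SUBSTITUTION_CHANNELS))
        q = pd.DataFrame(np.eye(96)[[5]], index=["q"], columns=cat.columns)
        res = match_to_catalog(q, cat)
        assert res.loc["q", "similarity"] == pytest.approx(0.0)
        assert not bool(res.loc["q", "high"])

    def test_cpg_ct_exclusion_against_oracle(self, catalog96, rng):
        """Dropping the 4 N[C>T]G channels and renormalizing must change the
        similarity exactly as a direct recomputation says."""
        assert len(CPG_CT_CHANNELS) == 4
        assert all(
            ch.SUBSTITUTION_CHANNELS[i][2:5] == "C>T" and ch.SUBSTITUTION_CHANNELS[i][6] == "G"
            for i in CPG_CT_CHANNELS
        )
        q = rng.dirichlet(np.ones(96))
        q[list(CPG_CT_CHANNELS)] += 0.3  # CpG-heavy query
        qf = pd.DataFrame([q / q.sum()], index=["q"], columns=catalog96.columns)
        res = match_to_catalog(qf, catalog96, exclude_cpg_ct=True)
        keep = np.ones(96, bool)
        keep[list(CPG_CT_CHANNELS)] = False
        expected = max(
            cosine_similarity(qf.values[0][keep], catalog96.loc[name].values[keep])
            for name in catalog96.index
        )
        assert res.loc["q", "similarity"] == pytest.approx(expected, abs=1e-12)

    def test_query_104_indels_dropped(self, catalog96, rng):
        p104 = rng.dirichlet(np.ones(104))
        q = pd.DataFrame([p104], index=["q"], columns=list(ch.CHANNELS_104))
        res = match_to_catalog(q, catalog96)
        expected = max(
            cosine_similarity(p104[:96], catalog96.loc[n].values) for n in catalog96.index
        )
        assert res.loc["q", "similarity"] == pytest.approx(expected, abs=1e-12)


class TestDistanceMatrix:
    def test_duplicates_and_symmetry(self, rng):
        s = rng.uniform(0.1, 1.0, size=104)
        X = pd.DataFrame([s, 2 * s, rng.uniform(0.1, 1.0, 104)], index=list("abc"))
        D = cosine_distance_matrix(X)
        assert D.loc["a", "b"] == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(D.values, D.values.T)
        assert np.allclose(np.diag(D.values), 0.0)

    def test_hand_computed_values(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        D = cosine_distance_matrix(X)
        assert D.iloc[0, 1] == pytest.approx(1.0)
        assert D.iloc[0, 2] == pytest.approx(1 - 1 / np.sqrt(2))

    def test_all_zero_spectrum_errors(self):
        with pytest.raises(ValueError):
            cosine_distance_matrix(np.array([[1.0, 0.0], [0.0, 0.0]]))
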