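import math

import numpy as np
import pandas as pd
import pytest

from conftest import random_dna, random_model
from regulonkit.genome_io import GeneRecord, assign_ranks, reverse_complement
from regulonkit.motif_scanning import (
    MotifModel,
    OperonMap,
    build_motif_model,
    counts_from_consensus,
    dinucleotide_shuffle,
    estimate_fdr,
    mononucleotide_shuffle,
    predict_operons_fallback,
    propagate_operon_scores,
    propagate_scores_df,
    scan_promoter,
    scan_promoters,
    standardize_per_species,
)
from regulonkit.synthetic_data import default_motif_counts


def brute_force_scan(promoter: str, model: MotifModel):
    """Independent oracle: enumerate every window on both strands with plain
    python loops, applying the same tie rules (smallest offset, forward first)."""
    w = model.width
    best = (-math.inf, None, None)
    for off in range(len(promoter) - w + 1):
        window = promoter[off:off + w]
        for strand, seq in (("+", window), ("-", reverse_complement(window))):
            score = 0.0
            for i, base in enumerate(seq):
                if base in "ACGT":
                    score += model.log_odds[i, "ACGT".index(base)]
            if score > best[0]:
                best = (score, off, strand)
    return best


class TestBuildMotifModel:
    def test_identical_sites_zero_pseudocount(self):
        model = build_motif_model(["TTGAT"] * 4, pseudocount=0.0)
        for i, base in enumerate("TTGAT"):
            b = "ACGT".index(base)
            assert model.log_odds[i, b] == pytest.approx(2.0)
            others = [model.log_odds[i, j] for j in range(4) if j != b]
            assert all(v == -math.inf for v in others)

    def test_background_matched_column_scores_zero(self):
        model = build_motif_model(["ACGT", "CGTA", "GTAC", "TACG"], pseudocount=0.0)
        assert np.allclose(model.log_odds, 0.0)

    def test_information_content_non_negative_without_pseudocount(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            counts = rng.multinomial(12, [0.25] * 4, size=6).astype(float)
            m = MotifModel(counts=counts, background=np.full(4, 0.25),
                           pseudocount=0.0, n_sites=12)
            assert m.information_bits() >= -1e-12

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            build_motif_model(["ACGTA", "ACGT"])

    def test_all_n_column_rejected(self):
        with pytest.raises(ValueError, match="only N"):
            build_motif_model(["ANGT", "ANTT", "ANCT"])

    def test_n_keeps_column_sums(self):
        model = build_motif_model(["ACGT", "ANGT"], pseudocount=0.5)
        assert np.allclose(model.counts.sum(axis=1), 2.0)


class TestScanPromoter:
    def test_planted_consensus_site_found_at_its_offset(self):
        rng = np.random.default_rng(5)
        site = "TTGATACGCATCAA"
        promoter = random_dna(rng, 6) + site  # planted at offset 6, length 20
        model = MotifModel(counts_from_consensus("TTGATNNNNATCAA", 20),
                           background=np.full(4, 0.25), pseudocount=0.5, n_sites=20)
        hit = scan_promoter(promoter, model)
        assert hit.best_offset == 6
        assert hit.raw_score == pytest.approx(model.score_window(site))

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(40):
            model = random_model(rng)
            promoter = random_dna(rng, int(rng.integers(model.width, 80)),
                                  alphabet="ACGTN")
            hit = scan_promoter(promoter, model)
            score, off, strand = brute_force_scan(promoter, model)
            assert hit.raw_score == pytest.approx(score)
            assert (hit.best_offset, hit.best_strand) == (off, strand)

    def test_palindromic_model_strand_invariant(self, default_model):
        rng = np.random.default_rng(23)
        assert default_model.is_palindromic()
        for _ in range(25):
            promoter = random_dna(rng, 60)
            a = scan_promoter(promoter, default_model).raw_score
            b = scan_promoter(reverse_complement(promoter), default_model).raw_score
            assert a == pytest.approx(b, abs=1e-9)

    def test_promoter_of_motif_width_scores_both_orientations(self, default_model):
        rng = np.random.default_rng(3)
        seq = random_dna(rng, default_model.width)
        hit = scan_promoter(seq, default_model)
        fwd = default_model.score_window(seq)
        rev = default_model.score_window(reverse_complement(seq))
        assert hit.best_offset == 0
        assert hit.raw_score == pytest.approx(max(fwd, rev))

    def test_too_short_promoter_gets_sentinel(self, default_model):
        hit = scan_promoter("ACGT", default_model)
        assert hit.raw_score == -math.inf
        assert hit.best_offset is None

    def test_batch_scan_agrees_with_single(self, default_model):
        rng = np.random.default_rng(9)
        proms = {f"g{i}": random_dna(rng, int(rng.integers(14, 60)))
                 for i in range(30)}
        proms["short"] = "ACG"
        df = scan_promoters(proms, default_model).set_index("gene_id")
        for g, seq in proms.items():
            single = scan_promoter(seq, default_model)
            assert df.loc[g, "raw_score"] == pytest.approx(single.raw_score)
            if single.best_offset is not None:
                assert df.loc[g, "best_offset"] == single.best_offset
                assert df.loc[g, "best_strand"] == single.best_strand


class TestStandardize:
    def _df(self, raws, species="sp1"):
        return pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(len(raws))],
            "species_id": species,
            "raw_score": raws,
        })

    def test_z_scores_have_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        df = standardize_per_species(self._df(rng.normal(5, 2, size=200)))
        assert abs(df["z"].mean()) < 1e-9
        assert abs(df["z"].std(ddof=0) - 1) < 1e-9

    def test_hand_computed_example(self):
        df = standardize_per_species(self._df([0.0, 0.0, 0.0, 10.0]))
        sd = math.sqrt((3 * 2.5 ** 2 + 7.5 ** 2) / 4)
        assert df["z"].iloc[-1] == pytest.approx(7.5 / sd)
        assert df["z"].iloc[-1] == pytest.approx(math.sqrt(3))
        assert not df["significant"].any()  # 1.73 < 3.0

    def test_sentinels_excluded_from_moments(self):
        df = self._df([1.0, 2.0, 3.0, -math.inf])
        out = standardize_per_species(df)
        finite = out[np.isfinite(out["raw_score"])]
        assert abs(finite["z"].mean()) < 1e-9
        assert out["z"].iloc[-1] == -math.inf

    def test_zero_spread_species_warns_and_flags_nothing(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING):
            out = standardize_per_species(self._df([2.0, 2.0, 2.0]))
        assert (out["z"] == 0).all()
        assert not out["significant"].any()
        assert "zero score spread" in caplog.text

    def test_threshold_boundary_exact(self):
        df = pd.DataFrame({
            "gene_id": ["a", "b"], "species_id": "sp",
            "raw_score": [1.0, 2.0], "z": [3.0, 2.999999999],
        })
        out = propagate_scores_df(df, OperonMap())
        assert out.set_index("gene_id")["significant"].tolist() == [True, False]


def recursive_propagation_oracle(z, chain, probs):
    """Independent textbook recursion over one transcription unit."""
    out = {chain[0]: z[chain[0]]}
    for prev, cur, p in zip(chain, chain[1:], probs):
        out[cur] = max(z[cur], out[prev] * p)
    return out


class TestPropagation:
    def _map(self, chain, probs):
        return OperonMap(pairs={
            (a, b): p for a, b, p in zip(chain, chain[1:], probs)})

    def test_full_propagation_chain(self):
        z = {"a": 5.0, "b": 1.0, "c": 0.0}
        out = propagate_operon_scores(z, self._map(["a", "b", "c"], [1.0, 1.0]))
        assert out == {"a": 5.0, "b": 5.0, "c": 5.0}

    def test_never_flows_upstream(self):
        z = {"a": 1.0, "b": 5.0}
        out = propagate_operon_scores(z, self._map(["a", "b"], [1.0]))
        assert out == {"a": 1.0, "b": 5.0}

    def test_matches_recursive_oracle_on_random_chains(self):
        rng = np.random.default_rng(31)
        for _ in range(100):
            n = int(rng.integers(2, 8))
            chain = [f"g{i}" for i in range(n)]
            z = {g: float(rng.normal()) for g in chain}
            probs = [float(rng.uniform(0.01, 1.0)) for _ in range(n - 1)]
            ours = propagate_operon_scores(z, self._map(chain, probs))
            oracle = recursive_propagation_oracle(z, chain, probs)
            for g in chain:
                assert ours[g] == pytest.approx(oracle[g])

    def test_idempotent_and_monotone(self):
        rng = np.random.default_rng(13)
        for _ in range(30):
            n = int(rng.integers(2, 10))
            chain = [f"g{i}" for i in range(n)]
            z = {g: float(rng.normal()) for g in chain}
            omap = self._map(chain, [float(rng.uniform(0, 1)) for _ in range(n - 1)])
            once = propagate_operon_scores(z, omap)
            twice = propagate_operon_scores(once, omap)
            assert once == twice
            assert all(once[g] >= z[g] for g in chain)


class TestOperonFallback:
    def _genes(self, rows):
        recs = [GeneRecord(gid, "sp", "chr", s, e, strand)
                for gid, s, e, strand in rows]
        return assign_ranks(recs)

    def test_same_strand_small_gap_cotranscribed(self):
        omap = predict_operons_fallback(self._genes([
            ("a", 100, 200, "+"), ("b", 211, 300, "+")]))
        assert omap.pairs == {("a", "b"): 1.0}

    def test_opposite_strands_never_cotranscribed(self):
        omap = predict_operons_fallback(self._genes([
            ("a", 100, 200, "+"), ("b", 211, 300, "-")]))
        assert omap.pairs == {}

    def test_gap_boundary(self):
        near = self._genes([("a", 100, 200, "+"), ("b", 251, 300, "+")])  # gap 50
        far = self._genes([("a", 100, 200, "+"), ("b", 252, 300, "+")])   # gap 51
        assert predict_operons_fallback(near).pairs == {("a", "b"): 1.0}
        assert predict_operons_fallback(far).pairs == {}

    def test_minus_strand_upstream_is_higher_rank(self):
        omap = predict_operons_fallback(self._genes([
            ("a", 100, 200, "-"), ("b", 211, 300, "-")]))
        assert omap.pairs == {("b", "a"): 1.0}


class TestShuffles:
    def test_mononucleotide_preserves_composition(self):
        rng = np.random.default_rng(2)
        seq = random_dna(rng, 200)
        shuf = mononucleotide_shuffle(seq, rng)
        assert sorted(shuf) == sorted(seq) and shuf != seq

    def test_dinucleotide_preserves_dinucleotide_counts(self):
        from collections import Counter
        rng = np.random.default_rng(4)
        seq = random_dna(rng, 300)
        shuf = dinucleotide_shuffle(seq, rng)
        assert Counter(zip(shuf, shuf[1:])) == Counter(zip(seq, seq[1:]))
        assert shuf[0] == seq[0] and shuf[-1] == seq[-1]


class TestEstimateFdr:
    def test_infinite_threshold_yields_undefined_sentinel(self, default_model):
        rng = np.random.default_rng(6)
        proms = {f"g{i}": random_dna(rng, 100) for i in range(50)}
        est = estimate_fdr(default_model, proms, z_threshold=math.inf,
                           n_shuffles=2, seed=0)
        assert est.fdr is None
        assert est.observed_hits == 0
        assert est.mean_shuffled_hits == 0

    def test_same_seed_same_estimate(self, default_model):
        rng = np.random.default_rng(8)
        proms = {f"g{i}": random_dna(rng, 150) for i in range(80)}
        a = estimate_fdr(default_model, proms, z_threshold=2.0, n_shuffles=3, seed=42)
        b = estimate_fdr(default_model, proms, z_threshold=2.0, n_shuffles=3, seed=42)
        assert a == b


class TestPlantedSiteRecall:
    def test_planted_sites_recovered_at_z3(self, default_model):
        """Sites sampled from the model's own count distribution, planted in a
        small fraction of background promoters, are called at z >= 3 in at
        least 90% of 500 seeded instances (model carries ~18 bits)."""
        from regulonkit.synthetic_data import _sample_site

        rng = np.random.default_rng(97)
        assert default_model.information_bits() >= 10
        # hits are a 1% minority, as per-species standardization assumes
        n_planted, n_background = 500, 49500
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)

        def fast_dna(n):
            return bases[rng.integers(0, 4, size=n)].tobytes().decode()

        planted_ids = [f"p{i}" for i in range(n_planted)]
        proms = {}
        for gid in planted_ids:
            site = _sample_site(default_model.counts, rng)
            seq = fast_dna(300)
            off = int(rng.integers(0, 300 - default_model.width + 1))
            proms[gid] = seq[:off] + site + seq[off + default_model.width:]
        for i in range(n_background):
            proms[f"b{i}"] = fast_dna(300)
        df = scan_promoters(proms, default_model)
        df["species_id"] = "one"
        df = standardize_per_species(df)
        called = df.set_index("gene_id").loc[planted_ids, "significant"]
        assert called.mean() >= 0.90
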