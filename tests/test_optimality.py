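"""tAI weight computation, gene-level scores, and classifications."""

import math

import numpy as np
import pandas as pd
import pytest

from codonstab.codon_core import (
    SENSE_CODONS,
    CodingSequence,
    codon_counts,
    count_matrix,
)
from codonstab.optimality import (
    AdaptivenessWeights,
    OptimalityClassification,
    TRNAGeneCopyTable,
    WobblePenalties,
    compute_nte,
    load_weights,
    percent_optimal,
    percent_optimal_matrix,
    relative_adaptiveness,
    reverse_complement,
    tai_g,
    tai_g_matrix,
)

PEN = WobblePenalties()


def oracle_weights(tgcn: dict[str, int], s: WobblePenalties) -> dict[str, float]:
    """Anticodon-centric enumeration of all codon-anticodon pairings.

    Independent of the codon-centric implementation: walks the tRNA table
    and asks, for each anticodon, which codons it can decode and in which
    pairing class (position-34 wobble rules; AUG reserved for the
    elongator Met tRNA).
    """
    W = {c: 0.0 for c in SENSE_CODONS}
    penalties = s.as_dict()
    for anticodon, copies in tgcn.items():
        wc_codon = reverse_complement(anticodon)
        stem = wc_codon[:2]
        contributions = [(wc_codon, "wc")]
        first = anticodon[0]
        if first == "G":
            contributions.append((stem + "T", "gu"))
        elif first == "A":
            contributions.append((stem + "C", "ic"))
            contributions.append((stem + "A", "ia"))
        elif first == "T":
            contributions.append((stem + "G", "ug"))
        for codon, cls in contributions:
            if codon not in W:
                continue  # stop codon
            if codon == "ATG" and (anticodon, cls) != ("CAT", "wc"):
                continue
            W[codon] += (1.0 - penalties[cls]) * copies
    return W


class TestRelativeAdaptiveness:
    def test_watson_crick_top_copy_codon_gets_weight_one(self):
        table = TRNAGeneCopyTable({"CAT": 10, "AGC": 2})
        with pytest.warns(UserWarning):
            w = relative_adaptiveness(table)
        assert w.w["ATG"] == 1.0

    def test_geometric_mean_replacement(self):
        # three isolated codons with w = 1, 0.5, 0.25; every other codon
        # has no decoding tRNA and receives (1 * 0.5 * 0.25)^(1/3) = 0.5
        table = TRNAGeneCopyTable({"CAT": 8, "TAT": 4, "CAA": 2})
        with pytest.warns(UserWarning):
            w = relative_adaptiveness(table)
        assert w.w["ATG"] == 1.0
        assert w.w["ATA"] == pytest.approx(0.5)
        assert w.w["TTG"] == pytest.approx(0.25)
        assert w.w["GGG"] == pytest.approx(0.5)

    def test_matches_exhaustive_pairing_oracle(self):
        table = {"AGC": 11, "GGC": 1, "TGC": 5, "CAT": 10}
        with pytest.warns(UserWarning):
            w = relative_adaptiveness(TRNAGeneCopyTable(table))
        W = oracle_weights(table, PEN)
        wmax = max(W.values())
        nonzero = [v / wmax for v in W.values() if v > 0]
        gmean = math.exp(sum(math.log(v) for v in nonzero) / len(nonzero))
        for codon in SENSE_CODONS:
            expected = W[codon] / wmax if W[codon] > 0 else gmean
            assert w.w[codon] == pytest.approx(expected, abs=1e-12), codon

    def test_full_yeast_like_table_matches_oracle(self, rng):
        # random copy numbers over all 64 possible anticodons
        table = {
            reverse_complement(c): int(rng.integers(0, 12)) for c in SENSE_CODONS
        }
        table = {ac: n for ac, n in table.items() if n > 0}
        w = relative_adaptiveness(TRNAGeneCopyTable(table))
        W = oracle_weights(table, PEN)
        wmax = max(W.values())
        for codon in SENSE_CODONS:
            if W[codon] > 0:
                assert w.w[codon] == pytest.approx(W[codon] / wmax, abs=1e-12)

    def test_scale_invariance_in_copy_number(self):
        base = {"AGC": 11, "GGC": 1, "TGC": 5, "CAT": 10}
        with pytest.warns(UserWarning):
            w1 = relative_adaptiveness(TRNAGeneCopyTable(base))
        with pytest.warns(UserWarning):
            w2 = relative_adaptiveness(
                TRNAGeneCopyTable({k: 7 * v for k, v in base.items()})
            )
        assert w1.w == pytest.approx(w2.w)

    def test_all_zero_table_rejected(self):
        with pytest.raises(ValueError):
            TRNAGeneCopyTable({"AGC": 0})

    def test_lysidine_rule_only_under_flag(self):
        table = TRNAGeneCopyTable({"CAT": 10, "TAT": 4})
        with pytest.warns(UserWarning):
            w_euk = relative_adaptiveness(table)
        with pytest.warns(UserWarning):
            w_bac = relative_adaptiveness(table, lysidine_ata=True)
        # eukaryote: ATA read by TAT (WC); bacteria: by lysidine-CAT
        assert w_euk.w["ATA"] == pytest.approx(4.0 / 10.0)
        assert w_bac.w["ATA"] == pytest.approx((1 - PEN.la) * 10.0 / 10.0)


class TestWeightIO:
    def _table(self, tmp_path, rows):
        path = tmp_path / "w.tsv"
        pd.DataFrame(rows, columns=["codon", "w"]).to_csv(path, sep="\t", index=False)
        return path

    def test_valid_61_row_table(self, tmp_path):
        rows = [(c, 0.5) for c in SENSE_CODONS[:-1]] + [(SENSE_CODONS[-1], 1.0)]
        w = load_weights(self._table(tmp_path, rows))
        assert w.provenance == "loaded"
        assert w.w["TTT"] == 1.0

    def test_missing_codon_named_in_error(self, tmp_path):
        rows = [(c, 0.5) for c in SENSE_CODONS if c != "GCA"]
        with pytest.raises(ValueError, match="GCA"):
            load_weights(self._table(tmp_path, rows))

    def test_out_of_range_weight_rejected(self, tmp_path):
        rows = [(c, 0.5) for c in SENSE_CODONS]
        rows[0] = (rows[0][0], 1.2)
        with pytest.raises(ValueError):
            load_weights(self._table(tmp_path, rows))


@pytest.fixture()
def uniformish_weights(rng):
    w = rng.uniform(0.1, 1.0, 61)
    w[0] = 1.0
    return AdaptivenessWeights(w=dict(zip(SENSE_CODONS, w)))


class TestTaiG:
    def test_single_codon_gene(self):
        w = AdaptivenessWeights(
            w={c: (0.5 if c == "ATG" else 1.0) for c in SENSE_CODONS}
        )
        profile = codon_counts(CodingSequence("g", "ATG" * 5))
        assert tai_g(profile, w) == pytest.approx(0.5)

    def test_two_codon_geometric_mean(self):
        w = {c: 1.0 for c in SENSE_CODONS}
        w["GCT"] = 0.25
        profile = codon_counts(CodingSequence("g", "GCTATG"))
        assert tai_g(profile, AdaptivenessWeights(w=w)) == pytest.approx(0.5)

    def test_matches_product_oracle_on_random_gene(self, rng, uniformish_weights):
        codons = rng.choice(list(SENSE_CODONS), 300)
        profile = codon_counts(CodingSequence("g", "".join(codons)))
        # brute force: product of weights, 300th root
        product = 1.0
        for c in codons:
            product *= uniformish_weights.w[c]
        assert tai_g(profile, uniformish_weights) == pytest.approx(
            product ** (1 / 300), rel=1e-12
        )

    def test_monotone_in_synonymous_replacement(self, uniformish_weights):
        w = uniformish_weights.w
        lo, hi = sorted(["GCT", "GCC"], key=lambda c: w[c])
        base = ["GCT", "GCC", "ATG", "TTT"] * 3
        before = tai_g(
            codon_counts(CodingSequence("g", "".join(base + [lo]))),
            uniformish_weights,
        )
        after = tai_g(
            codon_counts(CodingSequence("g", "".join(base + [hi]))),
            uniformish_weights,
        )
        assert after >= before

    def test_concatenation_lies_between(self, rng, uniformish_weights):
        a = "".join(rng.choice(list(SENSE_CODONS), 50))
        b = "".join(rng.choice(list(SENSE_CODONS), 80))
        ta = tai_g(codon_counts(CodingSequence("a", a)), uniformish_weights)
        tb = tai_g(codon_counts(CodingSequence("b", b)), uniformish_weights)
        tab = tai_g(codon_counts(CodingSequence("ab", a + b)), uniformish_weights)
        assert min(ta, tb) - 1e-12 <= tab <= max(ta, tb) + 1e-12

    def test_vectorised_matrix_agrees_with_scalar(self, rng, uniformish_weights):
        seqs = [
            CodingSequence(f"g{i}", "".join(rng.choice(list(SENSE_CODONS), 40)))
            for i in range(6)
        ]
        profiles = [codon_counts(s) for s in seqs]
        mat = count_matrix(profiles)
        vec = tai_g_matrix(mat, uniformish_weights)
        for p in profiles:
            assert vec[p.gene_id] == pytest.approx(
                tai_g(p, uniformish_weights), rel=1e-12
            )


class TestPercentOptimal:
    @pytest.fixture()
    def cls(self):
        optimal = {c: c.startswith(("GC", "TT")) for c in SENSE_CODONS}
        return OptimalityClassification(metric="cTE", optimal=optimal)

    def test_extremes_and_fraction(self, cls):
        all_opt = codon_counts(CodingSequence("g", "GCT" * 10))
        none_opt = codon_counts(CodingSequence("g", "ATG" * 10))
        assert percent_optimal(all_opt, cls) == 100.0
        assert percent_optimal(none_opt, cls) == 0.0
        mixed = codon_counts(CodingSequence("g", "GCT" * 3 + "ATG" * 9))
        assert percent_optimal(mixed, cls) == pytest.approx(25.0)

    def test_complement_sums_to_100(self, rng, cls):
        flipped = OptimalityClassification(
            metric="cTE", optimal={c: not v for c, v in cls.optimal.items()}
        )
        seqs = [
            CodingSequence(f"g{i}", "".join(rng.choice(list(SENSE_CODONS), 30)))
            for i in range(5)
        ]
        mat = count_matrix(codon_counts(s) for s in seqs)
        total = percent_optimal_matrix(mat, cls) + percent_optimal_matrix(mat, flipped)
        np.testing.assert_allclose(total, 100.0, atol=1e-9)

    def test_classification_requires_both_classes(self):
        with pytest.raises(ValueError):
            OptimalityClassification(
                metric="cTE", optimal={c: True for c in SENSE_CODONS}
            )


class TestComputeNte:
    def _weights(self, special: dict[str, float]) -> AdaptivenessWeights:
        w = {c: 0.9 for c in SENSE_CODONS}
        w.update(special)
        w["TTT"] = 1.0
        return AdaptivenessWeights(w=w)

    def test_three_gene_hand_computation(self):
        counts = pd.DataFrame(
            0, index=["g1", "g2", "g3"], columns=list(SENSE_CODONS), dtype=np.int64
        )
        counts.loc["g1", ["GCT", "GCC"]] = [2, 1]
        counts.loc["g2", "GCC"] = 3
        counts.loc["g3", ["GCA", "GCT"]] = [1, 1]
        m = pd.Series([1.0, 2.0, 4.0], index=counts.index)
        w = self._weights({"GCT": 1.0, "GCC": 0.5, "GCA": 0.25})
        with pytest.warns(UserWarning, match="zero demand"):
            nte = compute_nte(w, counts, m)
        # demands: GCT = 2*1 + 1*4 = 6, GCC = 1*1 + 3*2 = 7, GCA = 1*4 = 4;
        # normalised by 7, ratio renormalised by its max 7/6
        assert nte.w["GCT"] == pytest.approx(1.0)
        assert nte.w["GCC"] == pytest.approx(3 / 7)
        assert nte.w["GCA"] == pytest.approx(0.375)
        assert math.isnan(nte.w["ATG"])

    def test_uniform_demand_preserves_ranks(self, uniformish_weights):
        counts = pd.DataFrame(
            1, index=["g1", "g2"], columns=list(SENSE_CODONS), dtype=np.int64
        )
        m = pd.Series([3.0, 3.0], index=counts.index)
        nte = compute_nte(uniformish_weights, counts, m)
        order_w = pd.Series(uniformish_weights.w).rank()
        order_nte = pd.Series(nte.w).rank()
        assert (order_w == order_nte).all()

    def test_abundance_scale_invariance(self, rng, uniformish_weights):
        counts = pd.DataFrame(
            rng.integers(1, 20, (4, 61)), index=list("abcd"),
            columns=list(SENSE_CODONS),
        )
        m = pd.Series(rng.uniform(1, 50, 4), index=counts.index)
        a = compute_nte(uniformish_weights, counts, m)
        b = compute_nte(uniformish_weights, counts, 2 * m)
        assert a.w == pytest.approx(b.w)

    def test_frequency_mode_differs_but_stays_normalised(self, rng, uniformish_weights):
        counts = pd.DataFrame(
            rng.integers(1, 20, (4, 61)), index=list("abcd"),
            columns=list(SENSE_CODONS),
        )
        m = pd.Series(rng.uniform(1, 50, 4), index=counts.index)
        nte = compute_nte(uniformish_weights, counts, m, mode="frequency")
        assert max(nte.w.values()) == pytest.approx(1.0)
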